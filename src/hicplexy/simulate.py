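"""Synthetic genomes, karyotypes, and Hi-C contact pairs with known truth.

The generator emulates the statistical structure of a Hi-C experiment on
a rearranged tumor genome without requiring any external data:

* a genome of a few chromosomes with restriction cut sites placed by a
  memoryless (exponential-spacing) process — the expectation for a
  6-base recognition site is one site per 4^6 = 4096 bp;
* a tumor karyotype given as a list of translocations (with per-side
  orientation and an optional reciprocal product) and deletions, applied
  sequentially to one homolog of each chromosome so chained events
  compose naturally; the other homolog stays intact (diploid mixture);
* contact pairs drawn from the resulting molecules: intra-molecule pairs
  with genomic separation s distributed as (s + s0)^(-alpha) — the
  classical distance-decay of mammalian Hi-C — and a fraction tau of
  uniform inter-molecule (trans) background;
* a clonal fraction f mixing tumor and unrearranged cells.

Derivative coordinates are lifted back to the reference before pairs are
written, and read positions are re-drawn uniformly within their
restriction fragment (fragment-level resolution, as in a real library).
Junction positions are snapped to cut sites by default so the "true
fragment next to the breakpoint" is well defined for every event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contacts import make_pairs
from .genome import FragmentMap, GenomeError, GenomeIndex, GenomicInterval


@dataclass(frozen=True)
class Translocation:
    """One translocation event.

    ``side`` is the retained side of the breakpoint on each chromosome:
    '+' keeps reference coordinates below the position (the partner is
    fused toward higher coordinates), '-' keeps coordinates above it.
    """

    chrom_a: str
    pos_a: int
    side_a: str
    chrom_b: str
    pos_b: int
    side_b: str
    reciprocal: bool = False

    def __post_init__(self) -> None:
        if self.side_a not in "+-" or self.side_b not in "+-":
            raise ValueError("sides must be '+' or '-'")


@dataclass
class KaryotypeSpec:
    lengths: dict[str, int]
    translocations: list[Translocation] = field(default_factory=list)
    deletions: list[GenomicInterval] = field(default_factory=list)
    clonal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.clonal_fraction <= 1):
            raise ValueError("clonal fraction must be in (0, 1]")
        for t in self.translocations:
            for chrom, pos in ((t.chrom_a, t.pos_a), (t.chrom_b, t.pos_b)):
                if chrom not in self.lengths:
                    raise GenomeError(f"unknown chromosome {chrom!r}")
                if not (0 < pos < self.lengths[chrom]):
                    raise GenomeError(f"breakpoint {chrom}:{pos} outside chromosome")
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for d in self.deletions:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, dels in by_chrom.items():
            dels = sorted(dels, key=lambda iv: iv.start)
            for a, b in zip(dels, dels[1:]):
                if a.end > b.start:
                    raise GenomeError(f"overlapping deletions on {chrom}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KaryotypeSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            lengths={str(k): int(v) for k, v in raw["lengths"].items()},
            translocations=[
                Translocation(**t) for t in raw.get("translocations", [])
            ],
            deletions=[
                GenomicInterval(d["chrom"], int(d["start"]), int(d["end"]))
                for d in raw.get("deletions", [])
            ],
            clonal_fraction=float(raw.get("clonal_fraction", 1.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        payload = {
            "lengths": self.lengths,
            "translocations": [vars(t) for t in self.translocations],
            "deletions": [
                {"chrom": d.chrom, "start": d.start, "end": d.end}
                for d in self.deletions
            ],
            "clonal_fraction": self.clonal_fraction,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class ContactModel:
    alpha: float = 1.0
    s0: float = 10_000.0
    trans_fraction: float = 0.2
    n_pairs: int = 100_000
    seed: int = 0
    duplicate_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 <= self.trans_fraction < 1):
            raise ValueError("trans fraction must be in [0, 1)")
        if self.n_pairs < 1:
            raise ValueError("need at least one pair")
        if not (0 <= self.duplicate_fraction < 1):
            raise ValueError("duplicate fraction must be in [0, 1)")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    forward: bool = True

    def __len__(self) -> int:
        return self.end - self.start


class Molecule:
    """An ordered list of oriented reference segments (one DNA molecule)."""

    def __init__(
        self,
        name: str,
        segments: Sequence[Segment],
        junction_events: Sequence[int | None] | None = None,
    ):
        self.name = name
        self.segments = list(segments)
        # event index for the boundary between segments[i] and segments[i+1]
        if junction_events is None:
            junction_events = [None] * (len(self.segments) - 1)
        self.junction_events = list(junction_events)
        assert len(self.junction_events) == len(self.segments) - 1

    def __len__(self) -> int:
        return sum(len(s) for s in self.segments)

    def boundaries(self) -> np.ndarray:
        """Molecule-coordinate offsets of internal segment boundaries."""
        lens = np.array([len(s) for s in self.segments], dtype=np.int64)
        return np.cumsum(lens)[:-1]

    def lift(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Molecule positions -> (segment index, reference position)."""
        pos = np.asarray(pos, dtype=np.int64)
        lens = np.array([len(s) for s in self.segments], dtype=np.int64)
        ends = np.cumsum(lens)
        seg_idx = np.searchsorted(ends, pos, side="right")
        starts = ends - lens
        off = pos - starts[seg_idx]
        ref = np.empty(len(pos), dtype=np.int64)
        for i, seg in enumerate(self.segments):
            sel = seg_idx == i
            if not sel.any():
                continue
            if seg.forward:
                ref[sel] = seg.start + off[sel]
            else:
                ref[sel] = seg.end - 1 - off[sel]
        return seg_idx, ref

    def ref_chrom(self, seg_idx: np.ndarray) -> list[str]:
        return [self.segments[i].chrom for i in seg_idx]


def _flip(segments: list[Segment]) -> list[Segment]:
    return [
        Segment(s.chrom, s.start, s.end, not s.forward)
        for s in reversed(segments)
    ]


class DerivativeMap:
    """Tumor karyotype as molecules, with lifts to reference coordinates.

    One intact homolog of every chromosome is kept alongside the
    rearranged molecules, so the map represents a diploid genome with one
    rearranged homolog per chromosome.
    """

    def __init__(self, genome: GenomeIndex, molecules: list[Molecule]):
        self.genome = genome
        self.molecules = molecules

    def total_length(self) -> int:
        return sum(len(m) for m in self.molecules)

    def lift(self, mol_idx: int, pos) -> tuple[list[str], np.ndarray]:
        mol = self.molecules[mol_idx]
        scalar = np.isscalar(pos)
        seg_idx, ref = mol.lift(np.atleast_1d(pos))
        chroms = mol.ref_chrom(seg_idx)
        if scalar:
            return chroms, ref
        return chroms, ref

    def inverse_lift(self, chrom: str, ref_pos: int) -> list[tuple[int, int]]:
        """All (molecule index, molecule position) mapping to a reference
        position."""
        out: list[tuple[int, int]] = []
        for mi, mol in enumerate(self.molecules):
            offset = 0
            for seg in mol.segments:
                if seg.chrom == chrom and seg.start <= ref_pos < seg.end:
                    if seg.forward:
                        out.append((mi, offset + (ref_pos - seg.start)))
                    else:
                        out.append((mi, offset + (seg.end - 1 - ref_pos)))
                offset += len(seg)
        return out


@dataclass
class JunctionTruth:
    event_index: int
    chrom: str
    position: int  # junction coordinate (cut site when snapped)
    side: str  # retained side: '+' low coordinates, '-' high
    fragment_index: int | None = None
    fragment: GenomicInterval | None = None


@dataclass
class TruthRecord:
    junctions: list[JunctionTruth]
    deletions: list[GenomicInterval]
    clonal_fraction: float
    linking_pairs: dict[int, int] = field(default_factory=dict)

    def junctions_of(self, event_index: int) -> list[JunctionTruth]:
        return [j for j in self.junctions if j.event_index == event_index]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "clonal_fraction": self.clonal_fraction,
            "junctions": [
                {
                    "event": j.event_index,
                    "chrom": j.chrom,
                    "position": j.position,
                    "side": j.side,
                    "fragment_index": j.fragment_index,
                    "fragment": None
                    if j.fragment is None
                    else [j.fragment.chrom, j.fragment.start, j.fragment.end],
                }
                for j in self.junctions
            ],
            "deletions": [
                {"chrom": d.chrom, "start": d.start, "end": d.end}
                for d in self.deletions
            ],
            "linking_pairs": {str(k): v for k, v in self.linking_pairs.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def simulate_genome(
    lengths: Mapping[str, int],
    mean_fragment_spacing: float = 4096.0,
    gene_density: float = 0.4,
    mean_gene_length: float = 30_000.0,
    n_gaps_per_chrom: int = 0,
    gap_length: int = 100_000,
    seed: int = 0,
) -> tuple[FragmentMap, list[GenomicInterval], list[GenomicInterval]]:
    """Generate a fragment map, gene track, and optional assembly gaps.

    Cut sites follow a Poisson (memoryless) process with the given mean
    spacing; genes are non-overlapping intervals drawn by alternating
    exponential intergenic and genic lengths tuned so genes cover the
    requested fraction of the genome.
    """
    if mean_fragment_spacing <= 0:
        raise ValueError("spacing must be positive")
    if not (0 <= gene_density < 1):
        raise ValueError("gene density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genome = GenomeIndex(dict(lengths))

    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in genome:
        L = genome.length(chrom)
        n_draw = int(L / mean_fragment_spacing * 1.5) + 10
        cuts = np.cumsum(rng.exponential(mean_fragment_spacing, size=n_draw))
        while cuts[-1] <= L:
            cuts = np.concatenate(
                [cuts, cuts[-1] + np.cumsum(rng.exponential(mean_fragment_spacing, size=n_draw))]
            )
        cuts = np.unique(cuts[cuts < L].astype(np.int64))
        cuts = cuts[cuts > 0]
        bounds = np.concatenate([[0], cuts, [L]])
        starts[chrom] = bounds[:-1]
        ends[chrom] = bounds[1:]
    fragments = FragmentMap(genome, starts, ends)

    genes: list[GenomicInterval] = []
    if gene_density > 0:
        mean_gap = mean_gene_length * (1 - gene_density) / gene_density
        gid = 0
        for chrom in genome:
            L = genome.length(chrom)
            pos = 0.0
            while True:
                pos += rng.exponential(mean_gap)
                g_len = max(200.0, rng.exponential(mean_gene_length))
                if pos + g_len >= L:
                    break
                gid += 1
                genes.append(
                    GenomicInterval(chrom, int(pos), int(pos + g_len), f"gene{gid}")
                )
                pos += g_len

    gaps: list[GenomicInterval] = []
    if n_gaps_per_chrom > 0:
        for chrom in genome:
            L = genome.length(chrom)
            for _ in range(n_gaps_per_chrom):
                s = int(rng.integers(0, max(1, L - gap_length)))
                gaps.append(GenomicInterval(chrom, s, min(s + gap_length, L)))
    return fragments, genes, gaps


def _snap_to_cut(fragments: FragmentMap, chrom: str, pos: int) -> int:
    """Nearest internal cut site (fragment boundary) to a position."""
    cuts = np.concatenate(
        [fragments.cut_sites(chrom), [fragments.ends(chrom)[-1]]]
    )
    cuts = cuts[(cuts > 0) & (cuts < fragments.genome.length(chrom))]
    if len(cuts) == 0:
        raise GenomeError(f"no cut sites on {chrom} to snap to")
    return int(cuts[np.argmin(np.abs(cuts - pos))])


def build_derivative_map(
    spec: KaryotypeSpec,
    fragments: FragmentMap | None = None,
    snap_to_cut_sites: bool = True,
) -> tuple[DerivativeMap, TruthRecord]:
    """Apply the karyotype to one homolog set and derive the truth record.

    Translocations are applied in order; each splits the molecule
    currently carrying the breakpoint, so chained events (a later event
    hitting a derivative of an earlier one) compose. Deletions are
    excised afterwards; a deletion overlapping a junction, or containing
    a later breakpoint, is an error.
    """
    genome = GenomeIndex(spec.lengths)
    if snap_to_cut_sites and fragments is None:
        raise GenomeError("snapping junctions requires a fragment map")

    # homolog 1: intact copies; homolog 2: working copies to rearrange
    intact = [
        Molecule(f"{c}_homolog1", [Segment(c, 0, genome.length(c))])
        for c in genome
    ]
    working: list[Molecule] = [
        Molecule(f"{c}_homolog2", [Segment(c, 0, genome.length(c))])
        for c in genome
    ]

    junctions: list[JunctionTruth] = []

    def _locate(chrom: str, pos: int) -> tuple[int, int]:
        """(molecule index, segment index) of a forward segment covering
        the reference position among the working molecules."""
        for mi, mol in enumerate(working):
            for si, seg in enumerate(mol.segments):
                if seg.chrom == chrom and seg.start <= pos < seg.end:
                    if not seg.forward:
                        raise GenomeError(
                            f"breakpoint {chrom}:{pos} falls on an inverted "
                            "segment; reorder events"
                        )
                    return mi, si
        raise GenomeError(
            f"breakpoint {chrom}:{pos} not present on any tumor molecule "
            "(lost by an earlier event?)"
        )

    def _split(chrom: str, pos: int, event: int) -> tuple[
        tuple[list[Segment], list[int | None]],
        tuple[list[Segment], list[int | None]],
    ]:
        """Remove the covering molecule; return (low, high) reference-side
        parts, each as (segments, junction_events), with the junction at
        the right end of `low` and the left end of `high`."""
        mi, si = _locate(chrom, pos)
        mol = working.pop(mi)
        seg = mol.segments[si]
        low_segs = mol.segments[:si]
        low_junc = mol.junction_events[:si] if si > 0 else []
        if seg.start < pos:
            low_segs = low_segs + [Segment(chrom, seg.start, pos)]
        else:
            low_junc = low_junc[:-1] if low_junc else []
        high_segs = mol.segments[si + 1 :]
        high_junc = mol.junction_events[si:] if si < len(mol.segments) - 1 else []
        if pos < seg.end:
            high_segs = [Segment(chrom, pos, seg.end)] + high_segs
        else:
            high_junc = high_junc[1:] if high_junc else []
        # repair junction-event lists to match segment counts
        low_junc = (low_junc + [None] * len(low_segs))[: max(len(low_segs) - 1, 0)]
        high_junc = (high_junc + [None] * len(high_segs))[: max(len(high_segs) - 1, 0)]
        return (low_segs, low_junc), (high_segs, high_junc)

    for ei, t in enumerate(spec.translocations):
        pos_a, pos_b = t.pos_a, t.pos_b
        if snap_to_cut_sites:
            pos_a = _snap_to_cut(fragments, t.chrom_a, pos_a)
            pos_b = _snap_to_cut(fragments, t.chrom_b, pos_b)

        (low_a, low_a_j), (high_a, high_a_j) = _split(t.chrom_a, pos_a, ei)
        (low_b, low_b_j), (high_b, high_b_j) = _split(t.chrom_b, pos_b, ei)

        if t.side_a == "+":
            keep_a, keep_a_j = low_a, low_a_j  # junction at right end
            lost_a, lost_a_j = high_a, high_a_j  # junction at left end
        else:
            # orient so the junction sits at the right end of the kept part
            keep_a, keep_a_j = _flip(high_a), list(reversed(high_a_j))
            lost_a, lost_a_j = _flip(low_a), list(reversed(low_a_j))
        if t.side_b == "+":
            # junction of low_b is at its right end; flip to put it left
            keep_b, keep_b_j = _flip(low_b), list(reversed(low_b_j))
            lost_b, lost_b_j = _flip(high_b), list(reversed(high_b_j))
        else:
            keep_b, keep_b_j = high_b, high_b_j
            lost_b, lost_b_j = low_b, low_b_j

        der1 = Molecule(
            f"der{ei+1}a",
            keep_a + keep_b,
            keep_a_j + [ei] + keep_b_j,
        )
        working.append(der1)
        if t.reciprocal:
            # lost_b carries its junction at the right end, lost_a at the
            # left end, so the complementary parts join directly
            der2 = Molecule(
                f"der{ei+1}b",
                lost_b + lost_a,
                lost_b_j + [ei] + lost_a_j,
            )
            working.append(der2)

        for chrom, pos, side in (
            (t.chrom_a, pos_a, t.side_a),
            (t.chrom_b, pos_b, t.side_b),
        ):
            jt = JunctionTruth(ei, chrom, pos, side)
            if fragments is not None:
                if side == "+":
                    # first fragment past the junction (background side)
                    if pos < fragments.genome.length(chrom):
                        jt.fragment_index = fragments.fragment_index(chrom, pos)
                else:
                    jt.fragment_index = fragments.fragment_index(chrom, pos - 1)
                if jt.fragment_index is not None:
                    jt.fragment = fragments.fragment(chrom, jt.fragment_index)
            junctions.append(jt)

    # deletions: excise from whichever tumor molecule carries the interval
    for d in spec.deletions:
        placed = False
        for mol in working:
            offset = 0
            for si, seg in enumerate(mol.segments):
                if seg.chrom == d.chrom and seg.start <= d.start and d.end <= seg.end:
                    if not seg.forward:
                        raise GenomeError("deletion on inverted segment")
                    left = Segment(d.chrom, seg.start, d.start) if seg.start < d.start else None
                    right = Segment(d.chrom, d.end, seg.end) if d.end < seg.end else None
                    new_segs = [s for s in (left, right) if s is not None]
                    mol.segments[si : si + 1] = new_segs
                    juncs = mol.junction_events
                    if left is not None and right is not None:
                        juncs.insert(si, None)  # deletion scar
                    elif not new_segs:
                        # whole segment removed: merge flanking junction slots
                        if si < len(juncs):
                            juncs.pop(si)
                        elif juncs:
                            juncs.pop()
                    placed = True
                    break
                elif seg.chrom == d.chrom and not (
                    d.end <= seg.start or d.start >= seg.end
                ):
                    raise GenomeError(
                        f"deletion {d.chrom}:{d.start}-{d.end} overlaps a "
                        "junction or segment boundary"
                    )
                offset += len(seg)
            if placed:
                break
        if not placed:
            raise GenomeError(
                f"deletion {d.chrom}:{d.start}-{d.end} not on any tumor molecule"
            )

    truth = TruthRecord(junctions, list(spec.deletions), spec.clonal_fraction)
    return DerivativeMap(genome, intact + working), truth


def _sample_decay_distance(
    rng: np.random.Generator, n: int, L: float, alpha: float, s0: float
) -> np.ndarray:
    """Distances with density ~ (s + s0)^(-alpha) truncated to (0, L)."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        c = np.log((L + s0) / s0)
        return s0 * (np.exp(u * c) - 1.0)
    a = 1.0 - alpha
    lo = s0**a
    hi = (L + s0) ** a
    return (lo + u * (hi - lo)) ** (1.0 / a) - s0


def simulate_pairs(
    fragments: FragmentMap,
    derivatives: DerivativeMap,
    model: ContactModel,
    truth: TruthRecord | None = None,
    clonal_fraction: float | None = None,
    snap_to_fragments: bool = True,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw contact pairs from the tumor/normal mixture.

    Each pair comes from the tumor molecule set with probability f (the
    clonal fraction) and otherwise from the unrearranged reference
    karyotype. Cis pairs choose a molecule proportional to length, one
    end uniform and the other at a decay-distributed distance in a
    uniform direction; trans pairs (probability tau) place both ends
    uniformly on two distinct molecules. Derivative coordinates are
    lifted to the reference and, when ``snap_to_fragments``, re-drawn
    uniformly within their restriction fragment. Exactly
    ``model.n_pairs`` pairs are returned.
    """
    rng = np.random.default_rng(model.seed)
    genome = derivatives.genome
    if truth is None:
        truth = TruthRecord([], [], clonal_fraction or 1.0)
    f = clonal_fraction if clonal_fraction is not None else truth.clonal_fraction

    normal = [
        Molecule(f"{c}_normal", [Segment(c, 0, genome.length(c))]) for c in genome
    ]

    n_unique = model.n_pairs - int(round(model.n_pairs * model.duplicate_fraction))
    n_tumor = int(rng.binomial(n_unique, f))
    linking: dict[int, int] = {ji.event_index: 0 for ji in truth.junctions}

    chroms1: list[str] = []
    chroms2: list[str] = []
    pos1_all: list[np.ndarray] = []
    pos2_all: list[np.ndarray] = []

    for molecules, n_draw, is_tumor in (
        (derivatives.molecules, n_tumor, True),
        (normal, n_unique - n_tumor, False),
    ):
        if n_draw == 0:
            continue
        lengths = np.array([len(m) for m in molecules], dtype=float)
        weights = lengths / lengths.sum()
        is_trans = rng.random(n_draw) < model.trans_fraction
        n_trans = int(is_trans.sum())
        n_cis = n_draw - n_trans

        # --- cis pairs ---
        mol_choice = rng.choice(len(molecules), size=n_cis, p=weights)
        for mi in np.unique(mol_choice):
            mol = molecules[mi]
            L = float(len(mol))
            count = int((mol_choice == mi).sum())
            p1 = np.empty(count, dtype=np.int64)
            p2 = np.empty(count, dtype=np.int64)
            remaining = np.arange(count)
            while len(remaining):
                k = len(remaining)
                a = rng.integers(0, int(L), size=k)
                s = _sample_decay_distance(rng, k, L, model.alpha, model.s0)
                sign = np.where(rng.random(k) < 0.5, 1.0, -1.0)
                b = a + np.round(sign * np.maximum(s, 1.0)).astype(np.int64)
                ok = (b >= 0) & (b < L) & (b != a)
                p1[remaining[ok]] = a[ok]
                p2[remaining[ok]] = b[ok]
                remaining = remaining[~ok]
            if is_tumor and mol.junction_events:
                bounds = mol.boundaries()
                events = mol.junction_events
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                for bi, ev in zip(bounds, events):
                    if ev is None:
                        continue
                    crossed = (lo < bi) & (hi >= bi)
                    linking[ev] = linking.get(ev, 0) + int(crossed.sum())
            seg1, ref1 = mol.lift(p1)
            seg2, ref2 = mol.lift(p2)
            chroms1.extend(mol.ref_chrom(seg1))
            chroms2.extend(mol.ref_chrom(seg2))
            pos1_all.append(ref1)
            pos2_all.append(ref2)

        # --- trans pairs ---
        if n_trans and len(molecules) > 1:
            m1 = rng.choice(len(molecules), size=n_trans, p=weights)
            m2 = rng.choice(len(molecules), size=n_trans, p=weights)
            clash = m1 == m2
            while clash.any():
                m2[clash] = rng.choice(len(molecules), size=int(clash.sum()), p=weights)
                clash = m1 == m2
            for side, marr, store_c, store_p in (
                (1, m1, chroms1, pos1_all),
                (2, m2, chroms2, pos2_all),
            ):
                refs = np.empty(n_trans, dtype=np.int64)
                cs: np.ndarray = np.empty(n_trans, dtype=object)
                for mi in np.unique(marr):
                    sel = marr == mi
                    mol = molecules[mi]
                    p = rng.integers(0, len(mol), size=int(sel.sum()))
                    seg_idx, ref = mol.lift(p)
                    refs[sel] = ref
                    cs[sel] = np.array(mol.ref_chrom(seg_idx), dtype=object)
                store_c.extend(cs.tolist())
                store_p.append(refs)
        elif n_trans:
            # single molecule: fall back to cis-like uniform pairs
            mol = molecules[0]
            p1 = rng.integers(0, len(mol), size=n_trans)
            p2 = rng.integers(0, len(mol), size=n_trans)
            s1, r1 = mol.lift(p1)
            s2, r2 = mol.lift(p2)
            chroms1.extend(mol.ref_chrom(s1))
            chroms2.extend(mol.ref_chrom(s2))
            pos1_all.append(r1)
            pos2_all.append(r2)

    c1 = np.array(chroms1, dtype=object)
    c2 = np.array(chroms2, dtype=object)
    p1 = np.concatenate(pos1_all) if pos1_all else np.empty(0, dtype=np.int64)
    p2 = np.concatenate(pos2_all) if pos2_all else np.empty(0, dtype=np.int64)

    if snap_to_fragments:
        for arr_c, arr_p in ((c1, p1), (c2, p2)):
            for chrom in np.unique(arr_c.astype(str)):
                sel = arr_c == chrom
                starts = fragments.starts(chrom)
                ends = fragments.ends(chrom)
                fi = np.searchsorted(ends, arr_p[sel], side="right")
                u = rng.random(int(sel.sum()))
                arr_p[sel] = starts[fi] + (u * (ends[fi] - starts[fi])).astype(
                    np.int64
                )

    # planted PCR duplicates
    n_dup = model.n_pairs - n_unique
    idx = np.arange(n_unique)
    if n_dup > 0 and n_unique > 0:
        dup_src = rng.choice(n_unique, size=n_dup, replace=True)
        idx = np.concatenate([idx, dup_src])

    strand_pool = np.array(["+", "-"], dtype=object)
    strands1 = strand_pool[rng.integers(0, 2, size=n_unique)][idx]
    strands2 = strand_pool[rng.integers(0, 2, size=n_unique)][idx]

    df = make_pairs(
        genome,
        chrom1=c1[idx].tolist(),
        pos1=p1[idx],
        strand1=strands1.tolist(),
        chrom2=c2[idx].tolist(),
        pos2=p2[idx],
        strand2=strands2.tolist(),
        read_id=[f"r{i}" for i in range(len(idx))],
    )
    truth.linking_pairs = linking
    return df, truth


def copy_number_track(
    spec: KaryotypeSpec, bin_size: int = 100_000
) -> list:
    """Copy-number segments consistent with the implanted deletions.

    Baseline log2 = 0; heterozygous deletions at clonal fraction f give
    log2(1 - f/2). Unbalanced translocation losses are not modelled here.
    """
    from .rearrangements import CopyNumberSegment

    f = spec.clonal_fraction
    loss = float(np.log2(max(1.0 - f / 2.0, 1e-6)))
    segments: list[CopyNumberSegment] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for d in spec.deletions:
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, L in spec.lengths.items():
        dels = sorted(by_chrom.get(chrom, []), key=lambda iv: iv.start)
        pos = 0
        for d in dels:
            if d.start > pos:
                segments.append(CopyNumberSegment(chrom, pos, d.start, 0.0))
            segments.append(CopyNumberSegment(chrom, d.start, d.end, loss))
            pos = d.end
        if pos < L:
            segments.append(CopyNumberSegment(chrom, pos, L, 0.0))
    return segments


def emit_fasta(
    fragments: FragmentMap,
    path: str | Path,
    motif: str = "AAGCTT",
    cut_offset: int = 1,
    seed: int = 0,
    line_width: int = 70,
) -> None:
    """Write a genome FASTA whose digestion reproduces the fragment map.

    Random sequence with the recognition motif planted at every internal
    cut site; accidental motif occurrences are mutated away so the
    in-silico digest round-trips exactly.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    motif_arr = np.array(list(motif))
    with open(path, "w") as fh:
        for chrom in fragments.genome:
            L = fragments.genome.length(chrom)
            seq = bases[rng.integers(0, 4, size=L)]
            planted = fragments.cut_sites(chrom) - cut_offset
            planted = planted[(planted >= 0) & (planted + len(motif) <= L)]
            wanted = set(planted.tolist())
            for p in planted:
                seq[p : p + len(motif)] = motif_arr
            text = "".join(seq)
            # remove accidental motifs (may need several sweeps)
            import re as _re

            for _ in range(20):
                accidental = [
                    m.start()
                    for m in _re.finditer(f"(?={motif})", text)
                    if m.start() not in wanted
                ]
                if not accidental:
                    break
                arr = np.array(list(text))
                for a in accidental:
                    old = arr[a]
                    arr[a] = "C" if old != "C" else "G"
                text = "".join(arr)
            fh.write(f">{chrom}\n")
            for i in range(0, L, line_width):
                fh.write(text[i : i + line_width] + "\n")
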