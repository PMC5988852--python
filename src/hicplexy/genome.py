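"""Genome coordinate system, in-silico restriction digestion and annotation I/O.

Coordinates are 0-based half-open everywhere inside the package. External
tables that use 1-based inclusive conventions (the breakpoint table) are
converted at read time; BED files are already 0-based half-open.

The restriction-fragment map is the coordinate currency of breakpoints:
a breakpoint called from Hi-C data is resolved to the interval between two
consecutive cut sites of the enzyme used in the experiment (HindIII,
recognition site AAGCTT, by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

HINDIII_MOTIF = "AAGCTT"
HINDIII_CUT_OFFSET = 1  # A^AGCTT


class GenomeError(ValueError):
    """Invalid genome coordinates or annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeIndex:
    """Ordered chromosome names and lengths; the stable coordinate frame.

    The chromosome order given at construction defines the canonical
    ordering used for pair canonicalisation and global bin indexing.
    """

    def __init__(self, lengths: Mapping[str, int]):
        names = list(lengths)
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names")
        for name, length in lengths.items():
            if length <= 0:
                raise GenomeError(f"chromosome {name} has non-positive length")
        self._names: tuple[str, ...] = tuple(names)
        self._lengths: dict[str, int] = {n: int(lengths[n]) for n in names}
        self._rank = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    def rank(self, chrom: str) -> int:
        try:
            return self._rank[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self):
        return iter(self._names)

    def __len__(self) -> int:
        return len(self._names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeIndex)
            and self._names == other._names
            and self._lengths == other._lengths
        )

    def total_length(self) -> int:
        return sum(self._lengths.values())

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: len(fa[name]) for name in fa.keys()})

    @classmethod
    def from_table(cls, path: str | Path) -> "GenomeIndex":
        """Two-column TSV of chromosome name and length."""
        lengths: dict[str, int] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, size = line.split("\t")[:2]
            lengths[name] = int(size)
        return cls(lengths)


class FragmentMap:
    """Ordered restriction fragments per chromosome with usability flags.

    Fragments tile each chromosome exactly (a partition between cut
    points); a fragment flagged unusable (gap-overlapping) stays in the
    map with original coordinates so fragment indices remain stable.
    """

    def __init__(
        self,
        genome: GenomeIndex,
        starts: Mapping[str, np.ndarray],
        ends: Mapping[str, np.ndarray],
        usable: Mapping[str, np.ndarray] | None = None,
    ):
        self.genome = genome
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._usable: dict[str, np.ndarray] = {}
        for chrom in genome:
            s = np.asarray(starts[chrom], dtype=np.int64)
            e = np.asarray(ends[chrom], dtype=np.int64)
            if len(s) != len(e):
                raise GenomeError(f"start/end length mismatch on {chrom}")
            if len(s) == 0:
                raise GenomeError(f"no fragments on {chrom}")
            if s[0] != 0 or e[-1] != genome.length(chrom):
                raise GenomeError(f"fragments do not tile {chrom}")
            if np.any(e[:-1] != s[1:]) or np.any(s >= e):
                raise GenomeError(f"fragments not a sorted partition on {chrom}")
            self._starts[chrom] = s
            self._ends[chrom] = e
            if usable is None:
                self._usable[chrom] = np.ones(len(s), dtype=bool)
            else:
                u = np.asarray(usable[chrom], dtype=bool)
                if len(u) != len(s):
                    raise GenomeError(f"usable flag length mismatch on {chrom}")
                self._usable[chrom] = u

    def starts(self, chrom: str) -> np.ndarray:
        return self._starts[chrom]

    def ends(self, chrom: str) -> np.ndarray:
        return self._ends[chrom]

    def usable_mask(self, chrom: str) -> np.ndarray:
        return self._usable[chrom]

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self._starts[chrom])
        return sum(len(s) for s in self._starts.values())

    def n_usable(self) -> int:
        return int(sum(u.sum() for u in self._usable.values()))

    def fragment(self, chrom: str, index: int) -> GenomicInterval:
        return GenomicInterval(
            chrom, int(self._starts[chrom][index]), int(self._ends[chrom][index])
        )

    def fragment_index(self, chrom: str, pos: int) -> int:
        """Index of the fragment containing position ``pos``."""
        if not (0 <= pos < self.genome.length(chrom)):
            raise GenomeError(f"position {pos} outside {chrom}")
        return int(np.searchsorted(self._ends[chrom], pos, side="right"))

    def cut_sites(self, chrom: str) -> np.ndarray:
        """Internal cut points (excludes the chromosome ends)."""
        return self._starts[chrom][1:]

    def iter_fragments(
        self, chrom: str, usable_only: bool = False
    ) -> Iterable[GenomicInterval]:
        mask = self._usable[chrom]
        for i, (s, e) in enumerate(zip(self._starts[chrom], self._ends[chrom])):
            if usable_only and not mask[i]:
                continue
            yield GenomicInterval(chrom, int(s), int(e))

    def usable_fragments(self) -> list[GenomicInterval]:
        """All gap-free fragments in genome order (the permutation catalog)."""
        out: list[GenomicInterval] = []
        for chrom in self.genome:
            out.extend(self.iter_fragments(chrom, usable_only=True))
        return out

    def with_usable(self, usable: Mapping[str, np.ndarray]) -> "FragmentMap":
        return FragmentMap(self.genome, self._starts, self._ends, usable)

    def to_bed(self, path: str | Path) -> None:
        """Write BED4: name column is 'usable' or 'gap'."""
        with open(path, "w") as fh:
            for chrom in self.genome:
                for i in range(self.n_fragments(chrom)):
                    flag = "usable" if self._usable[chrom][i] else "gap"
                    fh.write(
                        f"{chrom}\t{self._starts[chrom][i]}\t"
                        f"{self._ends[chrom][i]}\t{flag}\n"
                    )


@dataclass(frozen=True)
class BreakpointRecord:
    """One row of the breakpoint table (internal half-open coordinates)."""

    translocation_id: str
    partner_id: str
    chrom: str
    start: int
    end: int
    genes: tuple[str, ...] = ()
    single_fragment: bool = True
    wgs_confirmed: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomeError(
                f"breakpoint {self.partner_id}: start >= end"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.partner_id)


def _clean_sequence(seq: str) -> str:
    return seq.upper()


def digest_genome(
    sequences: Mapping[str, str],
    motif: str = HINDIII_MOTIF,
    cut_offset: int = HINDIII_CUT_OFFSET,
) -> FragmentMap:
    """In-silico restriction digestion of a genome.

    Scans the forward strand for exact occurrences of ``motif`` (palindromic
    recognition sites make the reverse strand redundant) and cuts
    ``cut_offset`` bases into each occurrence. Fragments are the half-open
    intervals between consecutive cut points, including chromosome ends.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to nucleotide string (case-insensitive).
    motif
        Recognition sequence over A/C/G/T; degenerate IUPAC codes are
        rejected.
    cut_offset
        Cut position within the motif (1 for HindIII's A^AGCTT).
    """
    motif = motif.upper()
    if not motif or set(motif) - set("ACGT"):
        raise GenomeError(f"motif must be non-empty over ACGT, got {motif!r}")
    if not (0 <= cut_offset <= len(motif)):
        raise GenomeError("cut_offset outside motif")
    pattern = re.compile(f"(?={re.escape(motif)})")

    lengths = {}
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        if len(seq) == 0:
            raise GenomeError(f"empty sequence for {chrom}")
        seq = _clean_sequence(str(seq))
        L = len(seq)
        lengths[chrom] = L
        cuts = [
            m.start() + cut_offset
            for m in pattern.finditer(seq)
            if 0 < m.start() + cut_offset < L
        ]
        bounds = np.array([0, *cuts, L], dtype=np.int64)
        starts[chrom] = bounds[:-1]
        ends[chrom] = bounds[1:]
    return FragmentMap(GenomeIndex(lengths), starts, ends)


def digest_fasta(
    path: str | Path,
    motif: str = HINDIII_MOTIF,
    cut_offset: int = HINDIII_CUT_OFFSET,
) -> FragmentMap:
    """Digest a (multi-record, line-wrapped) FASTA file."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return digest_genome(
        {name: str(fa[name][:]) for name in fa.keys()}, motif, cut_offset
    )


def uniform_fragment_map(genome: GenomeIndex, fragment_size: int) -> FragmentMap:
    """Regularly spaced pseudo-fragments (for tests and sequence-free runs)."""
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in genome:
        L = genome.length(chrom)
        bounds = np.arange(0, L, fragment_size, dtype=np.int64)
        bounds = np.append(bounds, L) if bounds[-1] != L else bounds
        starts[chrom] = bounds[:-1]
        ends[chrom] = bounds[1:]
    return FragmentMap(genome, starts, ends)


def fragment_map_from_bed(path: str | Path) -> FragmentMap:
    """Rebuild a FragmentMap from its BED4 export (name column 'usable'/'gap')."""
    intervals = read_bed(path)
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    usable: dict[str, list[bool]] = {}
    for iv in intervals:
        starts.setdefault(iv.chrom, []).append(iv.start)
        ends.setdefault(iv.chrom, []).append(iv.end)
        usable.setdefault(iv.chrom, []).append(iv.label != "gap")
    genome = GenomeIndex({c: max(e) for c, e in ends.items()})
    return FragmentMap(
        genome,
        {c: np.array(v) for c, v in starts.items()},
        {c: np.array(v) for c, v in ends.items()},
        {c: np.array(v) for c, v in usable.items()},
    )


def subtract_gaps(
    fragments: FragmentMap, gaps: Sequence[GenomicInterval]
) -> FragmentMap:
    """Flag fragments that intersect an assembly gap as unusable.

    Coordinates are untouched: resampling treats whole fragments as units,
    so gap-overlapping fragments are excluded from the catalog rather than
    trimmed. Any overlap of >= 1 bp disqualifies a fragment.
    """
    genome = fragments.genome
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for gap in gaps:
        if gap.chrom not in genome:
            raise GenomeError(f"gap on unknown chromosome {gap.chrom!r}")
        by_chrom.setdefault(gap.chrom, []).append(gap)

    usable: dict[str, np.ndarray] = {}
    for chrom in genome:
        mask = fragments.usable_mask(chrom).copy()
        chrom_gaps = by_chrom.get(chrom, ())
        if chrom_gaps:
            starts = fragments.starts(chrom)
            ends = fragments.ends(chrom)
            for gap in chrom_gaps:
                # fragments with start < gap.end and end > gap.start
                lo = int(np.searchsorted(ends, gap.start, side="right"))
                hi = int(np.searchsorted(starts, gap.end, side="left"))
                mask[lo:hi] = False
        usable[chrom] = mask
    return fragments.with_usable(usable)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals (0-based half-open; name becomes label)."""
    out: list[GenomicInterval] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise GenomeError(f"{path}:{ln}: fewer than 3 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise GenomeError(f"{path}:{ln}: non-integer coordinates") from None
        label = parts[3] if len(parts) > 3 else None
        out.append(GenomicInterval(parts[0], start, end, label))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = f"\t{iv.label}" if iv.label is not None else ""
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


_EMPTY_GENE_MARKERS = {"", "-", "—", "."}


def read_breakpoint_table(path: str | Path) -> list[BreakpointRecord]:
    """Read the breakpoint table (TSV, 1-based inclusive coordinates).

    Expected columns: translocation_id, partner_id, chrom, start, stop,
    genes (';'-separated, dash for none), single_fragment (0/1),
    wgs_confirmed (0/1). Coordinates are converted to 0-based half-open.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenomeError(f"{path}: empty breakpoint table")
    header = lines[0].rstrip("\n").split("\t")
    required = [
        "translocation_id", "partner_id", "chrom", "start", "stop",
        "genes", "single_fragment", "wgs_confirmed",
    ]
    if header[: len(required)] != required:
        raise GenomeError(f"{path}: unexpected header {header!r}")

    records: list[BreakpointRecord] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(required):
            raise GenomeError(f"{path}:{ln}: expected {len(required)} columns")
        tid, pid, chrom, start_s, stop_s, genes_s, single_s, wgs_s = parts[:8]
        try:
            start_1based, stop = int(start_s), int(stop_s)
        except ValueError:
            raise GenomeError(f"{path}:{ln}: non-integer coordinates") from None
        genes_field = genes_s.strip()
        if genes_field in _EMPTY_GENE_MARKERS:
            genes: tuple[str, ...] = ()
        else:
            genes = tuple(g.strip() for g in genes_field.split(";") if g.strip())
        try:
            records.append(
                BreakpointRecord(
                    translocation_id=tid,
                    partner_id=pid,
                    chrom=chrom,
                    start=start_1based - 1,
                    end=stop,
                    genes=genes,
                    single_fragment=bool(int(single_s)),
                    wgs_confirmed=bool(int(wgs_s)),
                )
            )
        except (ValueError, GenomeError) as exc:
            raise GenomeError(f"{path}:{ln}: {exc}") from None
    return records


def load_table1_breakpoints() -> list[BreakpointRecord]:
    """The breakpoint fixture shipped with the package."""
    here = Path(__file__).parent / "data" / "table1_breakpoints.tsv"
    return read_breakpoint_table(here)


def unique_finemapped_fragments(
    records: Sequence[BreakpointRecord],
) -> list[GenomicInterval]:
    """Distinct single-fragment breakpoint intervals, in genome order.

    Rows not resolved to a single restriction fragment are dropped; rows
    sharing identical coordinates (breakpoints of different translocations
    that landed on the same fragment) collapse to one interval. Gene labels
    of collapsed rows are merged onto the surviving interval's label.
    """
    seen: dict[tuple[str, int, int], set[str]] = {}
    for rec in records:
        if not rec.single_fragment:
            continue
        key = (rec.chrom, rec.start, rec.end)
        seen.setdefault(key, set()).update(rec.genes)
    intervals = [
        GenomicInterval(c, s, e, ";".join(sorted(genes)) if genes else None)
        for (c, s, e), genes in seen.items()
    ]
    intervals.sort(key=lambda iv: (chrom_sort_key(iv.chrom), iv.start))
    return intervals


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr22 < chrX < chrY."""
    name = chrom[3:] if chrom.startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)
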