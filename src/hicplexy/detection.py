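"""Detection of translocation-indicating interaction anomalies.

A translocation fuses segments of two chromosomes, so contacts between
the fused segments behave like intra-chromosomal contacts: far more
frequent than the inter-chromosomal background, strongest next to the
junction and decaying away from it. Detection proceeds in three steps:

1. ``score_bins`` — per eligible bin pair, an upper-tail binomial test of
   the observed raw count against the expected-model cell probability,
   with Benjamini–Hochberg control over all eligible pairs;
2. ``cluster_calls`` — significant inter-chromosomal cells are clustered
   into candidate rearrangements by connected components with a gap
   tolerance, since one event lights up a contiguous block of cells;
3. ``infer_orientation`` — the enriched block sits on the retained side
   of each breakpoint and decays away from the junction, so the side of
   the anchor (the maximally enriched cell) carrying the signal gives the
   orientation; anti-diagonal twin blocks sharing the anchor corner mark
   a reciprocal event.

Eligible pairs are all inter-chromosomal pairs of included bins plus
intra-chromosomal pairs separated by more than a minimum genomic
distance (used for long-range intra links; candidates themselves are
inter-chromosomal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .contacts import ContactMatrix
from .normalization import (
    BalanceResult,
    ExpectedModel,
    RatioMatrix,
    _distance_pair_counts,
)


@dataclass
class DetectionParams:
    fdr: float = 0.001
    min_intra_distance: int = 25_000_000
    gap_tolerance: int = 2
    min_cluster_size: int = 2  # two adjacent called cells form a candidate
    # an isolated cell this significant is kept as a candidate on its own:
    # a junction landing near bin corners can concentrate nearly all of an
    # event's linking mass into a single cell
    singleton_q: float = 1e-12
    orientation_dominance: float = 2.0
    orientation_window: int = 10  # bins each side of the junction corner
    reciprocal_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.min_intra_distance < 0 or self.gap_tolerance < 0:
            raise ValueError("distances must be non-negative")


@dataclass
class InteractionCalls:
    """Significant bin-pair calls plus the size of the tested family."""

    table: pd.DataFrame  # bin_i, bin_j, observed, expected, p, q, inter
    n_eligible: int

    @property
    def n_calls(self) -> int:
        return len(self.table)


@dataclass
class TranslocationCandidate:
    chrom_a: str
    chrom_b: str
    bins_a: tuple[int, int]  # inclusive global-bin bounding box
    bins_b: tuple[int, int]
    anchor: tuple[int, int]
    score: float
    n_cells: int
    cells: pd.DataFrame = field(repr=False)
    orientation_a: str | None = None
    orientation_b: str | None = None
    reciprocal: bool = False

    @property
    def name(self) -> str:
        return f"{self.chrom_a}:{self.anchor[0]}|{self.chrom_b}:{self.anchor[1]}"


def _count_eligible_pairs(
    model: ExpectedModel, min_intra_bins: int
) -> int:
    scheme = model.scheme
    included = model.included
    inc_total = int(included.sum())
    inter = inc_total * inc_total
    intra_far = 0
    for chrom, (lo, hi) in scheme.bin_ranges().items():
        inc_c = int(included[lo:hi].sum())
        inter -= inc_c * inc_c
        pc = _distance_pair_counts(included[lo:hi])
        if min_intra_bins < len(pc):
            intra_far += int(pc[min_intra_bins + 1 :].sum())
    return inter // 2 + intra_far


def score_bins(
    matrix: ContactMatrix,
    balance: BalanceResult,
    model: ExpectedModel,
    params: DetectionParams | None = None,
) -> InteractionCalls:
    """Binomial upper-tail test of observed counts against expectation.

    The cell probability is the expected raw count divided by the total
    pair count; the p-value is P(X >= observed) for X ~ Binomial(N, p).
    Benjamini–Hochberg q-values are computed over the full family of
    eligible pairs (empty cells carry p = 1 and can never be called, so
    only non-empty cells need explicit p-values). A cell with zero
    expectation but non-zero observation is tested with one expected
    pseudo-unit and flagged.
    """
    params = params or DetectionParams()
    scheme = matrix.scheme
    coo = matrix.upper.tocoo()
    ranks = scheme.bin_chrom_rank
    min_intra_bins = params.min_intra_distance // scheme.bin_size

    same = ranks[coo.row] == ranks[coo.col]
    eligible = (~same) | (np.abs(coo.row - coo.col) > min_intra_bins)
    eligible &= model.included[coo.row] & model.included[coo.col]
    gi, gj = coo.row[eligible], coo.col[eligible]
    obs = coo.data[eligible]

    n_total = int(round(matrix.total))
    exp_raw = model.expected_raw(gi, gj, balance.factors)
    flagged = (exp_raw <= 0) & (obs > 0)
    exp_raw = np.where(flagged, 1.0, exp_raw)
    p_cell = np.clip(exp_raw / max(n_total, 1), 1e-300, 1.0)
    pvals = binom.sf(obs - 1, n_total, p_cell)

    n_eligible = _count_eligible_pairs(model, min_intra_bins)

    # Benjamini-Hochberg over the full eligible family
    order = np.argsort(pvals, kind="stable")
    ranks_bh = np.arange(1, len(pvals) + 1)
    q_sorted = pvals[order] * n_eligible / ranks_bh
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    q = np.maximum(q, pvals)  # q >= p always

    called = q < params.fdr
    table = pd.DataFrame(
        {
            "bin_i": gi[called],
            "bin_j": gj[called],
            "observed": obs[called],
            "expected": exp_raw[called],
            "p": pvals[called],
            "q": q[called],
            "inter": ~same[eligible][called],
            "zero_expected": flagged[called],
        }
    ).sort_values(["bin_i", "bin_j"]).reset_index(drop=True)
    return InteractionCalls(table, n_eligible)


def _connected_components(
    cells: np.ndarray, gap: int
) -> list[np.ndarray]:
    """Group 2-D lattice cells whose Chebyshev gap is within tolerance."""
    n = len(cells)
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = np.lexsort((cells[:, 1], cells[:, 0]))
    sorted_cells = cells[order]
    for ii in range(n):
        ai, aj = sorted_cells[ii]
        for jj in range(ii + 1, n):
            bi, bj = sorted_cells[jj]
            if bi - ai > gap:
                break
            if abs(bj - aj) <= gap:
                ra, rb = find(order[ii]), find(order[jj])
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(k)
    return [np.array(v) for v in groups.values()]


def cluster_calls(
    calls: InteractionCalls,
    matrix: ContactMatrix,
    params: DetectionParams | None = None,
) -> list[TranslocationCandidate]:
    """Cluster significant inter-chromosomal cells into candidates.

    Two calls on the same chromosome pair connect when they are within
    the gap tolerance (in bins) on both axes; components smaller than
    the minimum cluster size are discarded. The anchor is the cell with
    the highest observed/expected ratio (ties: smallest (i, j))."""
    params = params or DetectionParams()
    scheme = matrix.scheme
    table = calls.table[calls.table["inter"]]
    out: list[TranslocationCandidate] = []
    if len(table) == 0:
        return out

    chrom_i = scheme.chrom_of(table["bin_i"].to_numpy())
    chrom_j = scheme.chrom_of(table["bin_j"].to_numpy())
    pair_keys = pd.DataFrame({"ci": chrom_i, "cj": chrom_j}, index=table.index)

    for (ca, cb), idx in pair_keys.groupby(["ci", "cj"], sort=False).groups.items():
        sub = table.loc[idx]
        cells = sub[["bin_i", "bin_j"]].to_numpy()
        for comp in _connected_components(cells, params.gap_tolerance + 1):
            if len(comp) < params.min_cluster_size and not (
                sub["q"].iloc[comp].min() <= params.singleton_q
            ):
                continue
            comp_df = sub.iloc[comp].reset_index(drop=True)
            ratio = comp_df["observed"] / np.maximum(comp_df["expected"], 1e-12)
            best = np.lexsort(
                (comp_df["bin_j"], comp_df["bin_i"], -ratio)
            )[0]
            anchor = (
                int(comp_df["bin_i"].iloc[best]),
                int(comp_df["bin_j"].iloc[best]),
            )
            out.append(
                TranslocationCandidate(
                    chrom_a=str(ca),
                    chrom_b=str(cb),
                    bins_a=(int(comp_df["bin_i"].min()), int(comp_df["bin_i"].max())),
                    bins_b=(int(comp_df["bin_j"].min()), int(comp_df["bin_j"].max())),
                    anchor=anchor,
                    score=float(comp_df["observed"].sum()),
                    n_cells=len(comp_df),
                    cells=comp_df,
                )
            )
    out.sort(key=lambda c: (c.anchor[0], c.anchor[1]))
    return out


def _marginal_peak(cells: pd.DataFrame, key: str) -> int:
    """Bin with the largest summed signal along one axis — the best
    estimate of the junction bin on that chromosome (the block decays
    away from the junction, so its marginal peaks there)."""
    sums = cells.groupby(key)["observed"].sum()
    return int(sums.idxmax())


def _side_weights(
    cells: pd.DataFrame, reference: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Signal mass around a reference corner.

    Returns ``(axis_a, axis_b, quadrants, quadrant_cells)``: per-axis
    side masses of cells strictly below/above the reference on that axis,
    and quadrant masses with inclusive boundaries (cells on the reference
    row/column are shared between adjoining quadrants; the reference cell
    itself is excluded) — the junction bin carries signal from both
    derivatives of a reciprocal event, so its row and column must not be
    dropped."""
    ai, aj = reference
    da = cells["bin_i"].to_numpy() - ai
    db = cells["bin_j"].to_numpy() - aj
    obs = cells["observed"].to_numpy().astype(float)
    axis_a = np.array([obs[da < 0].sum(), obs[da > 0].sum()])
    axis_b = np.array([obs[db < 0].sum(), obs[db > 0].sum()])
    quad = np.zeros((2, 2))
    quad_cells = np.zeros((2, 2), dtype=int)
    off_ref = (da != 0) | (db != 0)
    for a, b in ((0, 0), (0, 1), (1, 0), (1, 1)):
        sel = off_ref & ((da <= 0) if a == 0 else (da >= 0)) & (
            (db <= 0) if b == 0 else (db >= 0)
        )
        quad[a, b] = obs[sel].sum()
        quad_cells[a, b] = int(sel.sum())
    return axis_a, axis_b, quad, quad_cells


def infer_orientation(
    ratio: RatioMatrix,
    candidate: TranslocationCandidate,
    params: DetectionParams | None = None,
) -> TranslocationCandidate:
    """Infer breakpoint orientation from the enrichment gradient.

    The enriched block occupies the retained side of each breakpoint and
    its intensity decreases away from the junction, so the anchor sits at
    the junction-proximal corner: the side of the anchor carrying the
    signal is the retained side and the opposite side is fused to the
    partner ('+' = fused toward higher coordinates). When the diagonally
    opposite quadrant also carries substantial signal the event is
    flagged reciprocal. A flat profile (no dominant side) leaves the
    orientation undetermined (None)."""
    params = params or DetectionParams()
    reference = (
        _marginal_peak(candidate.cells, "bin_i"),
        _marginal_peak(candidate.cells, "bin_j"),
    )
    # evidence: the full observed sub-matrix in a window around the
    # junction corner — the block's whole mass, not just the cells that
    # cleared the significance threshold
    scheme = ratio.scheme
    sym = ratio.balance.matrix.symmetric()
    half = params.orientation_window
    lo_a, hi_a = scheme.bin_ranges()[candidate.chrom_a]
    lo_b, hi_b = scheme.bin_ranges()[candidate.chrom_b]
    ra = np.arange(max(lo_a, reference[0] - half), min(hi_a, reference[0] + half + 1))
    rb = np.arange(max(lo_b, reference[1] - half), min(hi_b, reference[1] + half + 1))
    window = np.asarray(sym[np.ix_(ra, rb)].todense())
    gi = np.repeat(ra, len(rb))
    gj = np.tile(rb, len(ra))
    # work on the raw count scale: balancing divides the junction bins by
    # their signal-inflated marginals, which flattens the very gradient
    # read here
    f = np.where(np.isnan(ratio.balance.factors), 0.0, ratio.balance.factors)
    window = window * np.outer(f[ra], f[rb])
    expected = ratio.model.expected_raw(
        gi, gj, ratio.balance.factors
    ).reshape(len(ra), len(rb))
    # signed enrichment above expectation: clipping at zero would credit
    # every quadrant with a bias of order +0.4 counts per cell of noise
    window = window - expected
    # a 3-sigma floor on what counts as signal (Poisson noise of the
    # window background)
    noise_floor = 3.0 * float(np.sqrt(expected.sum()))

    from .refinement import fit_step

    def _axis_junction(axis: int) -> int:
        """Locate the junction on one axis as the edge of the enriched
        run: a background/signal step in the window's marginal profile
        (the same two-rate fit used for fragment-level refinement)."""
        profile = window.sum(axis=1 - axis)
        split, _, left_high = fit_step(
            np.clip(profile, 0.0, None), np.ones(len(profile))
        )
        # junction bin = enriched-run bin adjacent to the step
        return split - 1 if left_high else split

    def _strict_quadrants(
        center: tuple[int, int]
    ) -> np.ndarray:
        d_a = ra - center[0]
        d_b = rb - center[1]
        q = np.zeros((2, 2))
        for a, b in ((0, 0), (0, 1), (1, 0), (1, 1)):
            sel_a = (d_a < 0) if a == 0 else (d_a > 0)
            sel_b = (d_b < 0) if b == 0 else (d_b > 0)
            q[a, b] = window[np.ix_(sel_a, sel_b)].sum()
        return q

    reference = (int(ra[_axis_junction(0)]), int(rb[_axis_junction(1)]))
    da = ra - reference[0]
    db = rb - reference[1]

    axis_a = np.array([window[da < 0, :].sum(), window[da > 0, :].sum()])
    axis_b = np.array([window[:, db < 0].sum(), window[:, db > 0].sum()])
    # reciprocity is judged around the anchor cell (the shared corner of
    # the two derivatives' blocks), not the one-sided step edge
    quad = _strict_quadrants(candidate.anchor)

    dom = params.orientation_dominance

    def _axis_orientation(side_weights: np.ndarray) -> str | None:
        below, above = side_weights
        if below > dom * max(above, 0) and below > noise_floor:
            return "+"  # signal on low side -> fused side is high
        if above > dom * max(below, 0) and above > noise_floor:
            return "-"
        return None

    def _decays(axis: int, side_sign: int) -> bool:
        """Mean signal must fall with distance from the junction on the
        signal-carrying side (a flat block carries no orientation)."""
        if axis == 0:
            d = da * side_sign
            profile = window.sum(axis=1)
        else:
            d = db * side_sign
            profile = window.sum(axis=0)
        sel = d > 0
        if sel.sum() < 4:
            return True  # too few bins to assess a trend
        dists = d[sel]
        split = 0.5 * (dists.min() + dists.max())  # both halves non-empty
        near = profile[sel][dists <= split].mean()
        far = profile[sel][dists > split].mean()
        return near > far

    reciprocal = False
    if quad.sum() > 0:
        pa, pb = np.unravel_index(np.argmax(quad), quad.shape)
        primary = quad[pa, pb]
        opposite = quad[1 - pa, 1 - pb]
        reciprocal = bool(
            primary > noise_floor
            and opposite >= params.reciprocal_fraction * primary
            and opposite > noise_floor
        )
    if reciprocal:
        adjacent = max(quad[1 - pa, pb], quad[pa, 1 - pb])
        # adjacent quadrants comparable to the primary make the
        # two-quadrant pattern uninterpretable
        if adjacent >= 0.5 * primary and adjacent > 0:
            ori_a = ori_b = None
        else:
            ori_a = "+" if pa == 0 else "-"
            ori_b = "+" if pb == 0 else "-"
    else:
        ori_a = _axis_orientation(axis_a)
        ori_b = _axis_orientation(axis_b)
        if ori_a is not None and not _decays(0, -1 if ori_a == "+" else 1):
            ori_a = None
        if ori_b is not None and not _decays(1, -1 if ori_b == "+" else 1):
            ori_b = None
    return replace(
        candidate,
        orientation_a=ori_a,
        orientation_b=ori_b,
        reciprocal=reciprocal,
    )


def merge_reciprocal(
    candidates: list[TranslocationCandidate],
    corner_tolerance: int = 3,
) -> list[TranslocationCandidate]:
    """Merge candidate pairs that are the two quadrants of one reciprocal
    event: same chromosome pair, anchors within the corner tolerance and
    complementary orientations on both axes. The higher-scoring candidate
    survives and is flagged reciprocal."""
    out: list[TranslocationCandidate] = []
    used = [False] * len(candidates)
    for i, c in enumerate(candidates):
        if used[i]:
            continue
        merged = c
        for j in range(i + 1, len(candidates)):
            d = candidates[j]
            if used[j] or (c.chrom_a, c.chrom_b) != (d.chrom_a, d.chrom_b):
                continue
            near = (
                abs(c.anchor[0] - d.anchor[0]) <= corner_tolerance
                and abs(c.anchor[1] - d.anchor[1]) <= corner_tolerance
            )
            complementary = (
                c.orientation_a is not None
                and d.orientation_a is not None
                and c.orientation_a != d.orientation_a
                and c.orientation_b is not None
                and d.orientation_b is not None
                and c.orientation_b != d.orientation_b
            )
            if near and complementary:
                primary = merged if merged.score >= d.score else d
                merged = replace(
                    primary,
                    reciprocal=True,
                    score=merged.score + d.score,
                    n_cells=merged.n_cells + d.n_cells,
                )
                used[j] = True
        used[i] = True
        out.append(merged)
    return out


def detect_translocations(
    matrix: ContactMatrix,
    balance: BalanceResult,
    model: ExpectedModel,
    ratio: RatioMatrix,
    params: DetectionParams | None = None,
) -> tuple[InteractionCalls, list[TranslocationCandidate]]:
    """Score, cluster, orient, and merge reciprocal candidates."""
    params = params or DetectionParams()
    calls = score_bins(matrix, balance, model, params)
    candidates = cluster_calls(calls, matrix, params)
    candidates = [infer_orientation(ratio, c, params) for c in candidates]
    candidates = merge_reciprocal(candidates, corner_tolerance=params.gap_tolerance + 1)
    return calls, candidates


def candidates_to_bedpe(
    candidates: list[TranslocationCandidate],
    scheme,
    path: str | Path,
) -> None:
    """BEDPE export; strands encode the inferred orientation ('.' unknown)."""
    with open(path, "w") as fh:
        for k, c in enumerate(candidates):
            iv_a_lo = scheme.bin_interval(c.bins_a[0])
            iv_a_hi = scheme.bin_interval(c.bins_a[1])
            iv_b_lo = scheme.bin_interval(c.bins_b[0])
            iv_b_hi = scheme.bin_interval(c.bins_b[1])
            strand_a = c.orientation_a or "."
            strand_b = c.orientation_b or "."
            name = f"cand{k+1}" + ("_reciprocal" if c.reciprocal else "")
            fh.write(
                f"{c.chrom_a}\t{iv_a_lo.start}\t{iv_a_hi.end}\t"
                f"{c.chrom_b}\t{iv_b_lo.start}\t{iv_b_hi.end}\t"
                f"{name}\t{c.score:g}\t{strand_a}\t{strand_b}\n"
            )
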