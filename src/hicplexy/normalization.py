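"""Matrix balancing and the expected-interaction background model.

Balancing follows the equal-visibility assumption: every genomic bin
should contribute the same marginal interaction count once technical
biases (GC content, accessibility, restriction-site density) are removed.
We implement this as iterative proportional scaling (ICE): the symmetric
count matrix is repeatedly divided by the outer product of its marginal
sums until the marginals of included bins are uniform.

The expected model provides the denominator of observed/expected ratio
maps and the per-cell probabilities of the significance test:

* intra-chromosomal: expected(i, j) is the mean balanced count over all
  included bin pairs at the same genomic (bin) distance, with distances
  grouped into log-spaced strata merged to hold enough pairs for a stable
  mean — the classical distance-decay curve;
* inter-chromosomal: expected(i, j) = T_inter * v_i * v_j / sum(v_k v_l),
  where v are per-bin visibility shares and T_inter the total balanced
  inter-chromosomal count — i.e., uniform contact propensity between
  chromosomes apportioned by visibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .contacts import BinScheme, ContactMatrix

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 200
DEFAULT_COVERAGE_FLOOR = 10
DEFAULT_STRATUM_BASE = 1.12
DEFAULT_MIN_STRATUM_PAIRS = 50


class NormalizationError(ValueError):
    pass


@dataclass
class BalanceResult:
    """Balanced matrix plus the per-bin visibility factors that produced it.

    ``raw(i, j) ~= balanced(i, j) * factors[i] * factors[j]``; masked
    (low-coverage) bins carry factor NaN and zero balanced counts.
    """

    matrix: ContactMatrix
    factors: np.ndarray
    included: np.ndarray
    converged: bool
    n_iter: int


def balance_equal_visibility(
    matrix: ContactMatrix,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    coverage_floor: int = DEFAULT_COVERAGE_FLOOR,
) -> BalanceResult:
    """Iterative proportional scaling to uniform bin visibility.

    Bins whose raw marginal count is below ``coverage_floor`` are masked
    before balancing (their rows/columns are zeroed and they receive no
    factor). Convergence is reached when the maximum relative deviation
    of included-bin marginals from their mean falls below ``tol``. The
    balanced matrix is rescaled at the end so its total equals the raw
    total over included bins; the rescale is folded into the factors.
    """
    scheme = matrix.scheme
    n = scheme.n_bins_total
    sym = matrix.symmetric().astype(float)

    coverage = np.asarray(sym.sum(axis=1)).ravel()
    included = coverage >= coverage_floor
    if not included.any():
        raise NormalizationError("all bins masked by the coverage floor")

    # zero masked rows/columns
    keep = sp.diags(included.astype(float))
    sym = (keep @ sym @ keep).tocsr()

    factors = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        marg = np.asarray(sym.sum(axis=1)).ravel()
        m_inc = marg[included]
        nonzero = m_inc > 0
        if not nonzero.any():
            raise NormalizationError("included bins have zero marginals")
        mean = m_inc[nonzero].mean()
        dev = np.max(np.abs(m_inc[nonzero] / mean - 1.0))
        if dev < tol:
            converged = True
            break
        # square-root damping: full proportional steps oscillate on
        # near-disconnected matrices, the damped map contracts
        s = np.ones(n)
        s[included] = np.where(nonzero, np.sqrt(m_inc / mean), 1.0)
        inv = sp.diags(1.0 / s)
        sym = (inv @ sym @ inv).tocsr()
        factors *= s

    raw_total_included = float(
        sp.triu(matrix.symmetric()[included][:, included]).sum()
    )
    bal_total = float(sp.triu(sym).sum())
    if bal_total > 0:
        c = raw_total_included / bal_total
        sym = sym * c
        factors /= np.sqrt(c)
    factors = np.where(included, factors, np.nan)

    balanced = ContactMatrix(scheme, sp.triu(sym).tocsr())
    return BalanceResult(balanced, factors, included, converged, it)


def _distance_pair_counts(included_local: np.ndarray) -> np.ndarray:
    """Number of included bin pairs at each distance d = 0..n-1."""
    n = len(included_local)
    inc = included_local.astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    # d = 0: diagonal cells
    out[0] = inc.sum()
    for d in range(1, n):
        out[d] = int(np.dot(inc[:-d], inc[d:]))
    return out


class ExpectedModel:
    """Distance-decay + uniform-visibility expected counts (balanced scale)."""

    def __init__(
        self,
        scheme: BinScheme,
        included: np.ndarray,
        stratum_of_distance: np.ndarray,
        stratum_mean: np.ndarray,
        visibility: np.ndarray,
        inter_total: float,
        inter_denom: float,
        has_inter: bool,
    ):
        self.scheme = scheme
        self.included = included
        self.stratum_of_distance = stratum_of_distance
        self.stratum_mean = stratum_mean
        self.visibility = visibility
        self.inter_total = inter_total
        self.inter_denom = inter_denom
        self.has_inter = has_inter

    def expected(self, gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
        """Expected balanced count per bin pair (vectorised)."""
        gi = np.asarray(gi, dtype=np.int64)
        gj = np.asarray(gj, dtype=np.int64)
        ranks = self.scheme.bin_chrom_rank
        same = ranks[gi] == ranks[gj]
        out = np.zeros(len(gi))
        if same.any():
            d = np.abs(gi[same] - gj[same])
            out[same] = self.stratum_mean[self.stratum_of_distance[d]]
        trans = ~same
        if trans.any():
            if not self.has_inter:
                raise NormalizationError("inter-chromosomal model undefined")
            out[trans] = (
                self.inter_total
                * self.visibility[gi[trans]]
                * self.visibility[gj[trans]]
                / self.inter_denom
            )
        bad = ~(self.included[gi] & self.included[gj])
        out[bad] = 0.0
        return out

    def expected_raw(
        self, gi: np.ndarray, gj: np.ndarray, factors: np.ndarray
    ) -> np.ndarray:
        """Expected counts on the raw (unbalanced) scale."""
        e = self.expected(gi, gj)
        f = np.where(np.isnan(factors), 0.0, factors)
        return e * f[np.asarray(gi)] * f[np.asarray(gj)]

    def decay_table(self) -> np.ndarray:
        """(stratum index, mean balanced count) pairs."""
        return np.column_stack(
            [np.arange(len(self.stratum_mean)), self.stratum_mean]
        )


def _build_strata(
    max_distance: int,
    pair_counts: np.ndarray,
    base: float,
    min_pairs: int,
) -> np.ndarray:
    """Map each bin distance 0..max_distance to a stratum index.

    Strata start log-spaced (geometric with ``base``) and adjacent strata
    are merged left-to-right until each holds at least ``min_pairs`` bin
    pairs; a deficient tail is merged into its predecessor.
    """
    edges = [0, 1]
    d = 1.0
    while edges[-1] <= max_distance:
        d = max(d * base, d + 1)
        edges.append(int(np.ceil(d)))
    edges = np.unique(np.array(edges, dtype=np.int64))
    edges = edges[edges <= max_distance + 1]
    if edges[-1] != max_distance + 1:
        edges = np.append(edges, max_distance + 1)

    # merge forward until every stratum holds enough pairs
    merged: list[tuple[int, int]] = []
    lo = int(edges[0])
    for hi in edges[1:]:
        hi = int(hi)
        if pair_counts[lo:hi].sum() >= min_pairs or hi == max_distance + 1:
            merged.append((lo, hi))
            lo = hi
    if len(merged) > 1 and pair_counts[merged[-1][0]: merged[-1][1]].sum() < min_pairs:
        last_lo, last_hi = merged.pop()
        prev_lo, _ = merged.pop()
        merged.append((prev_lo, last_hi))

    stratum_of_distance = np.zeros(max_distance + 1, dtype=np.int64)
    for s, (a, b) in enumerate(merged):
        stratum_of_distance[a:b] = s
    return stratum_of_distance


def fit_expected_model(
    balance: BalanceResult,
    stratum_base: float = DEFAULT_STRATUM_BASE,
    min_stratum_pairs: int = DEFAULT_MIN_STRATUM_PAIRS,
) -> ExpectedModel:
    """Fit the distance-decay and inter-chromosomal expected model.

    Stratum means average over *all* included bin pairs at a distance
    (zero cells included), so the model reproduces the observed stratum
    means exactly and the expected total matches the observed total.
    """
    scheme = balance.matrix.scheme
    included = balance.included
    coo = balance.matrix.upper.tocoo()
    ranks = scheme.bin_chrom_rank
    same = ranks[coo.row] == ranks[coo.col]

    # pair availability per distance, restricted to included bins
    max_n = max(scheme.n_bins(c) for c in scheme.genome)
    pair_counts = np.zeros(max_n, dtype=np.int64)
    for chrom, (lo, hi) in scheme.bin_ranges().items():
        pc = _distance_pair_counts(included[lo:hi])
        pair_counts[: len(pc)] += pc

    max_distance = max_n - 1
    stratum_of_distance = _build_strata(
        max_distance, pair_counts, stratum_base, min_stratum_pairs
    )
    n_strata = int(stratum_of_distance.max()) + 1

    dist = np.abs(coo.row[same] - coo.col[same])
    sums = np.bincount(
        stratum_of_distance[dist], weights=coo.data[same], minlength=n_strata
    )
    denom = np.bincount(
        stratum_of_distance[np.arange(max_distance + 1)],
        weights=pair_counts,
        minlength=n_strata,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        stratum_mean = np.where(denom > 0, sums / np.maximum(denom, 1), 0.0)

    # inter-chromosomal component
    has_inter = len(scheme.genome) >= 2
    marg = np.asarray(balance.matrix.symmetric().sum(axis=1)).ravel()
    total = marg.sum()
    visibility = np.where(included & (total > 0), marg / max(total, 1e-300), 0.0)
    inter_total = float(coo.data[~same].sum())
    if has_inter:
        # sum over inter included pairs of v_i v_j
        per_chrom_v = [
            visibility[lo:hi].sum() for _, (lo, hi) in scheme.bin_ranges().items()
        ]
        v_all = float(visibility.sum())
        inter_denom = 0.5 * (v_all**2 - sum(v * v for v in per_chrom_v))
        if inter_denom <= 0:
            inter_denom = 1.0
            has_inter = inter_total == 0
    else:
        inter_denom = 1.0
    return ExpectedModel(
        scheme, included, stratum_of_distance, stratum_mean,
        visibility, inter_total, inter_denom, has_inter,
    )


class RatioMatrix:
    """log2(observed/expected) with a pseudocount, evaluated on demand."""

    def __init__(
        self,
        balance: BalanceResult,
        model: ExpectedModel,
        pseudocount: float = 1.0,
    ):
        if model.scheme is not balance.matrix.scheme:
            if model.scheme.bin_size != balance.matrix.scheme.bin_size or (
                model.scheme.genome != balance.matrix.scheme.genome
            ):
                raise NormalizationError("bin scheme mismatch")
        self.balance = balance
        self.model = model
        self.pseudocount = float(pseudocount)
        self.scheme = balance.matrix.scheme

    def values(self, gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
        gi = np.asarray(gi, dtype=np.int64)
        gj = np.asarray(gj, dtype=np.int64)
        sym = self.balance.matrix.symmetric()
        obs = np.asarray(sym[gi, gj]).ravel()
        exp = self.model.expected(gi, gj)
        eps = self.pseudocount
        return np.log2((obs + eps) / (exp + eps))

    def block(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        """Dense log-ratio sub-matrix for a chromosome pair."""
        lo_a, hi_a = self.scheme.bin_ranges()[chrom_a]
        lo_b, hi_b = self.scheme.bin_ranges()[chrom_b]
        rows = np.arange(lo_a, hi_a)
        cols = np.arange(lo_b, hi_b)
        gi = np.repeat(rows, len(cols))
        gj = np.tile(cols, len(rows))
        return self.values(gi, gj).reshape(len(rows), len(cols))


def ratio_map(
    balance: BalanceResult,
    model: ExpectedModel,
    pseudocount: float = 1.0,
) -> RatioMatrix:
    """Observed/expected log-ratio map on the balanced matrix."""
    return RatioMatrix(balance, model, pseudocount)
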