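"""Monte Carlo permutation test for breakpoint overrepresentation in genes.

The observed statistic is the number of breakpoint-bearing restriction
fragments that overlap at least one gene. The null distribution is
generated by repeatedly drawing the same number of fragments uniformly
without replacement from the gap-free fragment catalog and recomputing
the overlap count. The Monte Carlo p-value uses the standard conservative
correction p = (b + 1) / (m + 1), where b of the m resampled counts meet
or exceed the observed count.

Because sampling is uniform without replacement, the exact null is
hypergeometric: with n catalog fragments of which K overlap a gene, the
number of gene-overlapping fragments among k drawn is
X ~ Hypergeom(n, K, k). ``exact_tail`` exposes this closed form as an
independent check on the resampled p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .genome import FragmentMap, GenomicInterval


@dataclass
class PermutationConfig:
    k: int = 32
    m: int = 100_000
    seed: int = 0
    without_replacement: bool = True  # fixed; kept for config echoing

    def __post_init__(self) -> None:
        if self.k < 1 or self.m < 1:
            raise ValueError("k and m must be positive")
        if not self.without_replacement:
            raise ValueError("sampling is defined without replacement")


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray = field(repr=False)
    b: int
    p: float
    config: PermutationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "observed": self.observed,
            "b": self.b,
            "m": int(self.config.m),
            "k": int(self.config.k),
            "p": self.p,
            "seed": int(self.config.seed),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def null_histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.null_counts, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def _gene_trees(genes: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
    return trees


def overlap_count(
    selected: Sequence[GenomicInterval], genes: Sequence[GenomicInterval]
) -> int:
    """Number of intervals overlapping >= 1 gene by >= 1 bp (each once)."""
    trees = _gene_trees(genes)
    n = 0
    for iv in selected:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            n += 1
    return n


def catalog_gene_flags(
    catalog: Sequence[GenomicInterval], genes: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean gene-overlap flag per catalog fragment."""
    trees = _gene_trees(genes)
    flags = np.zeros(len(catalog), dtype=bool)
    for i, iv in enumerate(catalog):
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            flags[i] = True
    return flags


def permutation_test(
    catalog: FragmentMap | Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    observed: int | Sequence[GenomicInterval],
    config: PermutationConfig | None = None,
) -> PermutationResult:
    """Monte Carlo test of gene overlap against uniform fragment draws.

    ``catalog`` is either a FragmentMap (its gap-free fragments form the
    sampling frame) or an explicit fragment list. ``observed`` may be the
    observed overlap count or the observed fragment intervals themselves.
    Fully reproducible from ``config.seed``.
    """
    config = config or PermutationConfig()
    if isinstance(catalog, FragmentMap):
        frame = catalog.usable_fragments()
    else:
        frame = list(catalog)
    n = len(frame)
    if config.k > n:
        raise ValueError(f"draw size k={config.k} exceeds catalog size {n}")

    if not isinstance(observed, (int, np.integer)):
        observed = overlap_count(list(observed), genes)
    observed = int(observed)

    flags = catalog_gene_flags(frame, genes)
    rng = np.random.default_rng(config.seed)
    null_counts = np.empty(config.m, dtype=np.int64)
    # vectorised batches of without-replacement draws
    batch = max(1, min(config.m, 20_000, int(2e7) // max(n, 1)))
    done = 0
    while done < config.m:
        b_size = min(batch, config.m - done)
        # argpartition of random keys = uniform k-subsets
        keys = rng.random((b_size, n))
        picks = np.argpartition(keys, config.k - 1, axis=1)[:, : config.k]
        null_counts[done : done + b_size] = flags[picks].sum(axis=1)
        done += b_size
    b = int((null_counts >= observed).sum())
    p = (b + 1) / (config.m + 1)
    return PermutationResult(observed, null_counts, b, p, config)


def exact_tail(n: int, K: int, k: int, obs: int) -> float:
    """Exact hypergeometric upper tail P(X >= obs), X ~ Hypergeom(n, K, k)."""
    if not (0 <= K <= n):
        raise ValueError("need 0 <= K <= n")
    if not (0 <= obs <= k <= n):
        raise ValueError("need 0 <= obs <= k <= n")
    if obs == 0:
        return 1.0
    return float(hypergeom.sf(obs - 1, n, K, k))
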