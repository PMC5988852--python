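"""High-level modelling interface.

``TranslocationModel`` bundles the full inference chain — filtering,
binning, equal-visibility balancing, expected-model fitting, binomial
detection, fragment-level refinement and rearrangement-graph assembly —
behind a fit()/results pattern: build the model from a pairs table and a
genome, call :meth:`TranslocationModel.fit`, and read estimates and
diagnostics off the returned :class:`TranslocationResults`.

    >>> model = TranslocationModel(pairs, fragments, bin_size=100_000)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.to_bedpe("candidates.bedpe")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import contacts, detection, normalization, permutation, refinement
from .contacts import BinScheme, ContactMatrix, FilterReport
from .genome import BreakpointRecord, FragmentMap, GenomeIndex, GenomicInterval
from .rearrangements import (
    Chain,
    CopyNumberSegment,
    annotate_deletion_bridges,
    build_graph,
    find_chains,
)


@dataclass
class TranslocationResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    model: "TranslocationModel"
    filter_report: FilterReport
    matrix: ContactMatrix
    balance: normalization.BalanceResult
    expected: normalization.ExpectedModel
    ratio: normalization.RatioMatrix
    calls: detection.InteractionCalls
    candidates: list[detection.TranslocationCandidate]
    breakpoints: list[tuple[refinement.BreakpointCall, refinement.BreakpointCall]]
    graph: "object | None" = None
    chains: list[Chain] = field(default_factory=list)

    # -- derived accessors -------------------------------------------------
    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def breakpoint_records(self) -> list[BreakpointRecord]:
        """Refined calls as breakpoint records (graph/table currency)."""
        records: list[BreakpointRecord] = []
        for k, (a, b) in enumerate(self.breakpoints, start=1):
            tid = f"t{k}"
            for side in (a, b):
                records.append(
                    BreakpointRecord(
                        translocation_id=tid,
                        partner_id=f"{tid}_{side.chrom}",
                        chrom=side.chrom,
                        start=side.interval.start,
                        end=side.interval.end,
                        genes=side.genes,
                        single_fragment=side.resolution == "fragment",
                    )
                )
        return records

    def build_rearrangement_graph(
        self,
        link_distance: int = 2_000_000,
        segments: Sequence[CopyNumberSegment] | None = None,
    ) -> "object":
        self.graph = build_graph(self.breakpoint_records(), link_distance)
        if segments is not None:
            annotate_deletion_bridges(
                self.graph, segments,
                known_chromosomes=set(self.model.genome.names),
            )
        self.chains = find_chains(self.graph)
        return self.graph

    def test_gene_enrichment(
        self,
        genes: Sequence[GenomicInterval],
        config: permutation.PermutationConfig | None = None,
    ) -> permutation.PermutationResult:
        """Permutation test of breakpoint-fragment overlap with genes."""
        frags = self.model.fragments
        if frags is None:
            raise ValueError("gene enrichment needs a fragment map")
        observed = [
            side.interval
            for pair in self.breakpoints
            for side in pair
            if side.resolution == "fragment"
        ]
        # deduplicate shared fragments, as for the observed statistic
        seen = sorted(
            {(iv.chrom, iv.start, iv.end) for iv in observed}
        )
        unique = [GenomicInterval(c, s, e) for c, s, e in seen]
        config = config or permutation.PermutationConfig(k=max(len(unique), 1))
        if config.k != len(unique):
            config = permutation.PermutationConfig(
                k=max(len(unique), 1), m=config.m, seed=config.seed
            )
        return permutation.permutation_test(frags, genes, unique, config)

    def to_bedpe(self, path: str | Path) -> None:
        detection.candidates_to_bedpe(self.candidates, self.matrix.scheme, path)

    def breakpoint_table(self) -> pd.DataFrame:
        return refinement.calls_to_table(self.breakpoints)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Hi-C translocation analysis",
            "=" * 64,
            f"pairs retained        {self.filter_report.n_retained:>12,}"
            f"   (of {self.filter_report.n_input:,} input)",
            f"bin size              {self.matrix.scheme.bin_size:>12,} bp",
            f"bins included         {int(self.balance.included.sum()):>12,}"
            f" / {self.matrix.scheme.n_bins_total:,}",
            f"balancing             {'converged' if self.balance.converged else 'NOT converged':>12}"
            f" in {self.balance.n_iter} iterations",
            f"eligible bin pairs    {self.calls.n_eligible:>12,}",
            f"significant cells     {self.calls.n_calls:>12,}",
            f"candidates            {len(self.candidates):>12,}",
            "",
            f"{'pair':<14}{'anchor A':>16}{'anchor B':>16}"
            f"{'ori':>6}{'recip':>7}{'support':>9}{'resolution':>22}",
            "-" * 90,
        ]
        for (cand, bp) in zip(
            self.candidates,
            list(self.breakpoints) + [None] * (len(self.candidates) - len(self.breakpoints)),
        ):
            iva = self.matrix.scheme.bin_interval(cand.anchor[0])
            ivb = self.matrix.scheme.bin_interval(cand.anchor[1])
            ori = f"{cand.orientation_a or '?'}{cand.orientation_b or '?'}"
            res = (
                f"{bp[0].resolution}/{bp[1].resolution}" if bp is not None else "-"
            )
            support = bp[0].support if bp is not None else int(cand.score)
            lines.append(
                f"{cand.chrom_a + '|' + cand.chrom_b:<14}"
                f"{iva.start:>16,}{ivb.start:>16,}"
                f"{ori:>6}{str(cand.reciprocal):>7}{support:>9,}{res:>22}"
            )
        return "\n".join(lines)


class TranslocationModel:
    """Hi-C translocation model over a contact-pair table.

    Parameters
    ----------
    pairs
        Canonicalised pairs DataFrame (see :func:`hicplexy.contacts.read_pairs`).
    fragments
        Restriction-fragment map; supplies the genome index and enables
        fragment-level refinement and the cut-site distance filter.
    bin_size
        Analysis bin width in bp (100 kb default).
    detection_params, refinement_params
        Stage parameter bundles; defaults follow the package defaults.
    min_mapq, max_frag_distance, dedup
        Pair-filter settings applied before binning.
    """

    def __init__(
        self,
        pairs: pd.DataFrame,
        fragments: FragmentMap,
        bin_size: int = 100_000,
        detection_params: detection.DetectionParams | None = None,
        refinement_params: refinement.RefinementParams | None = None,
        min_mapq: int | None = None,
        max_frag_distance: int | None = None,
        dedup: bool = True,
        coverage_floor: int = normalization.DEFAULT_COVERAGE_FLOOR,
        pseudocount: float = 1.0,
    ):
        self.pairs = pairs
        self.fragments = fragments
        self.genome: GenomeIndex = fragments.genome
        self.scheme = BinScheme(self.genome, bin_size)
        self.detection_params = detection_params or detection.DetectionParams()
        self.refinement_params = refinement_params or refinement.RefinementParams()
        self.min_mapq = min_mapq
        self.max_frag_distance = max_frag_distance
        self.dedup = dedup
        self.coverage_floor = coverage_floor
        self.pseudocount = pseudocount

    @classmethod
    def from_files(
        cls,
        pairs_path: str | Path,
        fragments_fasta: str | Path | None = None,
        fragment_map: FragmentMap | None = None,
        **kwargs,
    ) -> "TranslocationModel":
        if fragment_map is None:
            if fragments_fasta is None:
                raise ValueError("need a FASTA or a fragment map")
            from .genome import digest_fasta

            fragment_map = digest_fasta(fragments_fasta)
        pairs = contacts.read_pairs(pairs_path, fragment_map.genome)
        return cls(pairs, fragment_map, **kwargs)

    def fit(self, refine: bool = True) -> TranslocationResults:
        """Run the inference chain and return the results object."""
        filtered, report = contacts.filter_pairs(
            self.pairs,
            min_mapq=self.min_mapq,
            dedup=self.dedup,
            fragments=self.fragments if self.max_frag_distance else None,
            max_frag_distance=self.max_frag_distance,
        )
        matrix = contacts.bin_contacts(filtered, self.scheme)
        balance = normalization.balance_equal_visibility(
            matrix, coverage_floor=self.coverage_floor
        )
        expected = normalization.fit_expected_model(balance)
        ratio = normalization.ratio_map(balance, expected, self.pseudocount)
        calls, candidates = detection.detect_translocations(
            matrix, balance, expected, ratio, self.detection_params
        )
        breakpoints: list[
            tuple[refinement.BreakpointCall, refinement.BreakpointCall]
        ] = []
        if refine:
            for cand in candidates:
                breakpoints.append(
                    refinement.refine_breakpoint(
                        filtered, self.fragments, cand, self.scheme,
                        self.refinement_params,
                    )
                )
        results = TranslocationResults(
            model=self,
            filter_report=report,
            matrix=matrix,
            balance=balance,
            expected=expected,
            ratio=ratio,
            calls=calls,
            candidates=candidates,
            breakpoints=breakpoints,
        )
        if refine and breakpoints:
            results.build_rearrangement_graph()
        return results
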