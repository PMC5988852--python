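"""Simulation studies validating each pipeline stage against known truth.

These are the study designs used by the validation suite and by
``scripts/acceptance.py``: fixed simulated genomes with implanted
rearrangements, run end-to-end through the package, with recovery
measured against the generator's truth records. All randomness is
derived from the caller's seed.

Study designs (rationale in docs/methods.md):

* genome: 10 chromosomes of 10 Mb at 100 kb bins — large enough for a
  non-trivial multiple-testing family (~450k inter bin pairs), small
  enough for desk-scale runtimes;
* null calibration: no rearrangements, 100,000 pairs per simulation;
* detection power: 5 translocations on distinct chromosome pairs
  covering all four orientation combinations, 200,000 pairs (well over
  200 linking pairs per event);
* refinement: one translocation, depth chosen so each 2 Mb window sees
  about 500 window-linking pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import (
    ContactModel,
    KaryotypeSpec,
    Translocation,
    TranslocationModel,
    build_derivative_map,
    simulate_genome,
    simulate_pairs,
)
from .genome import GenomicInterval, load_table1_breakpoints, unique_finemapped_fragments
from .permutation import PermutationConfig, exact_tail, permutation_test
from .rearrangements import build_graph, component_map, find_chains

TEN_CHROM_LENGTHS = {f"chr{i}": 10_000_000 for i in range(1, 11)}
ORIENTATION_COMBOS = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]

NULL_N_PAIRS = 100_000
POWER_N_PAIRS = 200_000
REFINE_N_PAIRS = 460_000  # ~500 pairs linking each 2 Mb refinement window


def _seed_stream(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# --------------------------------------------------------------------------
# breakpoint-table statistics (no simulation)
# --------------------------------------------------------------------------

def table_statistics() -> dict:
    """Counts derived from the bundled breakpoint table."""
    records = load_table1_breakpoints()
    unique = unique_finemapped_fragments(records)
    return {
        "n_rows": len(records),
        "n_translocations": len({r.translocation_id for r in records}),
        "n_unique_finemapped_fragments": len(unique),
        "n_gene_overlapping_fragments": sum(1 for iv in unique if iv.label),
        "n_wgs_confirmed_rows": sum(r.wgs_confirmed for r in records),
    }


def chain_statistics(link_distance: int = 2_000_000) -> dict:
    """Chained-translocation structure of the bundled breakpoint table."""
    records = load_table1_breakpoints()
    graph = build_graph(records, link_distance=link_distance)
    chains = find_chains(graph)
    comp = component_map(graph)
    chain_5_8_10 = next(
        (c for c in chains if {"t11", "t12", "t17"} <= set(c.translocations)),
        None,
    )
    return {
        "n_chains": len(chains),
        "chain_5_8_10_found": chain_5_8_10 is not None,
        "chain_5_8_10_translocations": (
            sorted(chain_5_8_10.translocations) if chain_5_8_10 else []
        ),
        "chain_5_8_10_chromosomes": (
            sorted(chain_5_8_10.chromosomes) if chain_5_8_10 else []
        ),
        "paired_components": {
            f"{a}/{b}": comp.get(a) == comp.get(b)
            for a, b in (("t1", "t10"), ("t7", "t8"), ("t8", "t15"), ("t13", "t14"))
        },
    }


# --------------------------------------------------------------------------
# permutation-test studies
# --------------------------------------------------------------------------

def toy_permutation_study(m: int = 100_000, seed: int = 0) -> dict:
    """Monte Carlo vs exact hypergeometric tail on the toy catalog
    (5 fragments, 3 gene-overlapping, k = 2, observed = 2)."""
    frags = [GenomicInterval("chr1", i * 100, (i + 1) * 100) for i in range(5)]
    genes = [GenomicInterval("chr1", 0, 250, "geneA")]
    res = permutation_test(
        frags, genes, observed=2, config=PermutationConfig(k=2, m=m, seed=seed)
    )
    exact = exact_tail(5, 3, 2, 2)
    se = float(np.sqrt(exact * (1 - exact) / m))
    return {
        "p_monte_carlo": res.p,
        "p_exact": exact,
        "standard_error": se,
        "abs_deviation_in_se": abs(res.p - exact) / se,
        "m": m,
    }


def permutation_null_calibration(
    n_replicates: int = 2_000, m: int = 999, seed: int = 0
) -> dict:
    """Super-uniformity of the Monte Carlo p under the null.

    The observed statistic is itself drawn from the hypergeometric null;
    the one-sided KS statistic D+ = sup_u (ECDF(u) - u) must not exceed
    the sampling band (a super-uniform p has ECDF below the diagonal).
    """
    frags = [GenomicInterval("chr1", i * 100, (i + 1) * 100) for i in range(5)]
    genes = [GenomicInterval("chr1", 0, 250, "geneA")]
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        obs = int(rng.hypergeometric(3, 2, 2))
        res = permutation_test(
            frags, genes, obs,
            PermutationConfig(k=2, m=m, seed=int(rng.integers(2**31 - 1))),
        )
        pvals[i] = res.p
    grid = np.sort(np.unique(pvals))
    ecdf = np.searchsorted(np.sort(pvals), grid, side="right") / n_replicates
    d_plus = float(np.max(ecdf - grid))
    return {
        "n_replicates": n_replicates,
        "m": m,
        "ks_d_plus": d_plus,
        "ks_critical_95": 1.358 / np.sqrt(n_replicates),
    }


# --------------------------------------------------------------------------
# detection studies
# --------------------------------------------------------------------------

def _power_events() -> list[Translocation]:
    sides = ORIENTATION_COMBOS + [("+", "-")]
    return [
        Translocation(
            f"chr{2 * i + 1}", 5_000_000, sides[i][0],
            f"chr{2 * i + 2}", 5_000_000, sides[i][1],
        )
        for i in range(5)
    ]


def null_calibration_study(
    n_sims: int = 50, n_pairs: int = NULL_N_PAIRS, seed: int = 0
) -> dict:
    """Fraction of eligible bin pairs called on rearrangement-free data."""
    n_calls = 0
    n_eligible = 0
    for s in _seed_stream(seed, n_sims):
        fragments, _, _ = simulate_genome(TEN_CHROM_LENGTHS, seed=s)
        spec = KaryotypeSpec(lengths=dict(TEN_CHROM_LENGTHS))
        dmap, truth = build_derivative_map(spec, fragments)
        pairs, _ = simulate_pairs(
            fragments, dmap, ContactModel(n_pairs=n_pairs, seed=s + 1), truth
        )
        res = TranslocationModel(pairs, fragments).fit(refine=False)
        n_calls += res.calls.n_calls
        n_eligible += res.calls.n_eligible
    rate = n_calls / max(n_eligible, 1)
    # binomial 95% upper bound at the nominal level
    fdr = 0.001
    bound = fdr + 1.96 * np.sqrt(fdr * (1 - fdr) / max(n_eligible, 1))
    return {
        "n_sims": n_sims,
        "n_pairs": n_pairs,
        "false_call_rate": rate,
        "n_calls": n_calls,
        "n_eligible": n_eligible,
        "nominal_fdr_upper_bound": float(bound),
    }


def power_study(
    n_sims: int = 50, n_pairs: int = POWER_N_PAIRS, seed: int = 0
) -> dict:
    """Detection and orientation recovery of five implanted events."""
    events = _power_events()
    want = {tuple(sorted((t.chrom_a, t.chrom_b))) for t in events}
    n_detected = 0
    n_orient_total = 0
    n_orient_correct = 0
    min_linking = np.inf
    for s in _seed_stream(seed, n_sims):
        fragments, _, _ = simulate_genome(TEN_CHROM_LENGTHS, seed=s)
        spec = KaryotypeSpec(
            lengths=dict(TEN_CHROM_LENGTHS), translocations=events
        )
        dmap, truth = build_derivative_map(spec, fragments)
        pairs, truth = simulate_pairs(
            fragments, dmap, ContactModel(n_pairs=n_pairs, seed=s + 1), truth
        )
        res = TranslocationModel(pairs, fragments).fit(refine=False)
        found = {tuple(sorted((c.chrom_a, c.chrom_b))) for c in res.candidates}
        n_detected += len(want & found)
        min_linking = min(min_linking, min(truth.linking_pairs.values()))
        for t in events:
            matching = [
                c for c in res.candidates
                if {c.chrom_a, c.chrom_b} == {t.chrom_a, t.chrom_b}
            ]
            if not matching:
                continue
            # clustering may split one event's cells; judge the event by
            # its strongest candidate
            c = max(matching, key=lambda c: c.score)
            expect = (
                (t.side_a, t.side_b)
                if c.chrom_a == t.chrom_a
                else (t.side_b, t.side_a)
            )
            n_orient_total += 1
            if (c.orientation_a, c.orientation_b) == expect:
                n_orient_correct += 1
    return {
        "n_sims": n_sims,
        "n_pairs": n_pairs,
        "detection_rate": n_detected / (5 * n_sims),
        "orientation_rate": n_orient_correct / max(n_orient_total, 1),
        "min_linking_pairs": int(min_linking),
    }


# --------------------------------------------------------------------------
# refinement studies
# --------------------------------------------------------------------------

def refinement_study(
    n_sims: int = 50, n_pairs: int = REFINE_N_PAIRS, seed: int = 0
) -> dict:
    """Exact / within-one-fragment junction recovery at ~500 window pairs."""
    exact = within1 = total = 0
    supports: list[int] = []
    for i, s in enumerate(_seed_stream(seed, n_sims)):
        sa, sb = ORIENTATION_COMBOS[i % 4]
        fragments, _, _ = simulate_genome(TEN_CHROM_LENGTHS, seed=s)
        spec = KaryotypeSpec(
            lengths=dict(TEN_CHROM_LENGTHS),
            translocations=[
                Translocation("chr1", 5_000_000, sa, "chr2", 5_000_000, sb)
            ],
        )
        dmap, truth = build_derivative_map(spec, fragments)
        pairs, truth = simulate_pairs(
            fragments, dmap, ContactModel(n_pairs=n_pairs, seed=s + 1), truth
        )
        res = TranslocationModel(pairs, fragments).fit()
        truth_by_chrom = {j.chrom: j for j in truth.junctions}
        matching = [
            (c, bp)
            for c, bp in zip(res.candidates, res.breakpoints)
            if {c.chrom_a, c.chrom_b} == {"chr1", "chr2"}
        ]
        if not matching:
            continue
        _, bp = max(matching, key=lambda pair: pair[0].score)
        for call in bp:
            tj = truth_by_chrom.get(call.chrom)
            if tj is None:
                continue
            total += 1
            supports.append(call.support)
            if call.resolution != "fragment":
                continue
            diff = call.fragment_index - tj.fragment_index
            exact += diff == 0
            within1 += abs(diff) <= 1
    return {
        "n_sims": n_sims,
        "n_pairs": n_pairs,
        "n_sides": total,
        "exact_rate": exact / max(total, 1),
        "within_one_rate": within1 / max(total, 1),
        "median_support": float(np.median(supports)) if supports else 0.0,
    }


def uniform_window_study(n_windows: int = 100, seed: int = 0) -> dict:
    """Coarse-call rate on windows with flat cross-link profiles.

    Uniform-signal windows carry no junction information: the refiner
    must fall back to a coarse (bin-resolution) call.
    """
    import pandas as pd

    from . import BinScheme, make_pairs, refine_breakpoint
    from .detection import TranslocationCandidate

    rng = np.random.default_rng(seed)
    lengths = {"chr1": 10_000_000, "chr2": 10_000_000}
    coarse = 0
    total = 0
    for w in range(n_windows):
        fragments, _, _ = simulate_genome(lengths, seed=int(rng.integers(2**31 - 1)))
        n = 500
        pairs = make_pairs(
            fragments.genome,
            chrom1=["chr1"] * n,
            pos1=rng.integers(3_900_000, 6_100_000, size=n),
            strand1=["+"] * n,
            chrom2=["chr2"] * n,
            pos2=rng.integers(3_900_000, 6_100_000, size=n),
            strand2=["-"] * n,
        )
        scheme = BinScheme(fragments.genome, 100_000)
        cand = TranslocationCandidate(
            chrom_a="chr1", chrom_b="chr2", bins_a=(49, 50), bins_b=(149, 150),
            anchor=(49, 150), score=1.0, n_cells=3,
            cells=pd.DataFrame({"bin_i": [49], "bin_j": [150], "observed": [1.0]}),
        )
        for call in refine_breakpoint(pairs, fragments, cand, scheme):
            total += 1
            coarse += call.resolution == "coarse"
    return {
        "n_windows": total,
        "coarse_rate": coarse / max(total, 1),
    }


# --------------------------------------------------------------------------
# conservation / normalization checks
# --------------------------------------------------------------------------

def conservation_study(seed: int = 0) -> dict:
    """Pair-count conservation, balancing convergence, expected totals."""
    from . import BinScheme, balance_equal_visibility, bin_contacts, fit_expected_model

    s = _seed_stream(seed, 1)[0]
    fragments, _, _ = simulate_genome(TEN_CHROM_LENGTHS, seed=s)
    spec = KaryotypeSpec(lengths=dict(TEN_CHROM_LENGTHS))
    dmap, truth = build_derivative_map(spec, fragments)
    n_pairs = 50_000
    pairs, _ = simulate_pairs(
        fragments, dmap, ContactModel(n_pairs=n_pairs, seed=s + 1), truth
    )
    matrix = bin_contacts(pairs, BinScheme(fragments.genome, 100_000))
    bal = balance_equal_visibility(matrix)
    model = fit_expected_model(bal)
    sym = bal.matrix.symmetric()
    marg = np.asarray(sym.sum(axis=1)).ravel()[bal.included]
    n = matrix.scheme.n_bins_total
    iu = np.triu_indices(n)
    total_expected = float(model.expected(iu[0], iu[1]).sum())
    return {
        "n_pairs": n_pairs,
        "matrix_total": matrix.total,
        "balanced_marginal_cv": float(marg.std() / marg.mean()),
        "balancing_converged": bool(bal.converged),
        "expected_total": total_expected,
        "observed_balanced_total": bal.matrix.total,
        "expected_over_observed": total_expected / bal.matrix.total,
    }
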