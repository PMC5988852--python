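import numpy as np
import pandas as pd
import pytest

import hicplexy as hp
from hicplexy.contacts import matrix_from_dense
from hicplexy.detection import DetectionParams, merge_reciprocal


def uniform_setup(n_bins_each=10, value=20.0):
    genome = hp.GenomeIndex(
        {"chrA": n_bins_each * 100, "chrB": n_bins_each * 100}
    )
    scheme = hp.BinScheme(genome, 100)
    n = scheme.n_bins_total
    dense = np.full((n, n), value)
    np.fill_diagonal(dense, 0)
    return scheme, dense


def fit_background(scheme, dense):
    m = matrix_from_dense(scheme, dense)
    bal = hp.balance_equal_visibility(m, coverage_floor=1)
    model = hp.fit_expected_model(bal, min_stratum_pairs=1)
    return m, bal, model


class TestScoreBins:
    def test_no_calls_when_observed_matches_expectation(self):
        scheme, dense = uniform_setup()
        m, bal, model = fit_background(scheme, dense)
        calls = hp.score_bins(m, bal, model, DetectionParams())
        assert calls.n_calls == 0
        assert calls.n_eligible > 0

    def test_extreme_cell_is_called(self):
        scheme, dense = uniform_setup()
        dense[0, 15] = dense[15, 0] = 2000.0
        m, bal, model = fit_background(scheme, dense)
        calls = hp.score_bins(m, bal, model, DetectionParams())
        hits = calls.table[(calls.table.bin_i == 0) & (calls.table.bin_j == 15)]
        assert len(hits) == 1
        assert hits.iloc[0].q < 1e-6

    def test_q_values_bounded_below_by_p(self):
        scheme, dense = uniform_setup()
        dense[0, 15] = dense[15, 0] = 500.0
        dense[2, 17] = dense[17, 2] = 300.0
        m, bal, model = fit_background(scheme, dense)
        calls = hp.score_bins(m, bal, model, DetectionParams(fdr=0.5))
        assert (calls.table.q >= calls.table.p - 1e-15).all()

    def test_monotone_in_observed_count(self):
        """Raising a called cell's count (others fixed) keeps it called."""
        scheme, dense = uniform_setup()
        dense[0, 15] = dense[15, 0] = 400.0
        m, bal, model = fit_background(scheme, dense)
        base = hp.score_bins(m, bal, model, DetectionParams())
        assert ((base.table.bin_i == 0) & (base.table.bin_j == 15)).any()
        dense[0, 15] = dense[15, 0] = 800.0
        m2 = matrix_from_dense(scheme, dense)
        more = hp.score_bins(m2, bal, model, DetectionParams())
        assert ((more.table.bin_i == 0) & (more.table.bin_j == 15)).any()

    def test_intra_eligibility_respects_min_distance(self):
        genome = hp.GenomeIndex({"chrA": 600_000_00})  # 60 Mb
        scheme = hp.BinScheme(genome, 1_000_000)
        n = scheme.n_bins_total
        rng = np.random.default_rng(2)
        a = rng.poisson(5, size=(n, n)).astype(float)
        dense = a + a.T
        dense[0, 50] = dense[50, 0] = 500.0  # 50 Mb apart -> eligible
        dense[0, 5] = dense[5, 0] = 500.0  # 5 Mb apart -> not eligible
        m, bal, model = fit_background(scheme, dense)
        calls = hp.score_bins(m, bal, model, DetectionParams())
        assert ((calls.table.bin_i == 0) & (calls.table.bin_j == 50)).any()
        assert not ((calls.table.bin_i == 0) & (calls.table.bin_j == 5)).any()


class TestClusterCalls:
    def _calls_from_cells(self, scheme, cells):
        table = pd.DataFrame(
            [
                {"bin_i": i, "bin_j": j, "observed": 10.0, "expected": 0.1,
                 "p": 1e-12, "q": 1e-10, "inter": True, "zero_expected": False}
                for i, j in cells
            ]
        )
        return hp.detection.InteractionCalls(table, 1000)

    def test_two_adjacent_cells_form_one_candidate_by_default(self):
        scheme, dense = uniform_setup()
        m = matrix_from_dense(scheme, dense)
        calls = self._calls_from_cells(scheme, [(0, 15), (1, 15)])
        cands = hp.cluster_calls(calls, m, DetectionParams())
        assert len(cands) == 1

    def test_adjacent_cells_form_one_candidate(self):
        scheme, dense = uniform_setup()
        m = matrix_from_dense(scheme, dense)
        calls = self._calls_from_cells(scheme, [(0, 15), (1, 15), (1, 16)])
        cands = hp.cluster_calls(calls, m, DetectionParams(min_cluster_size=3))
        assert len(cands) == 1
        assert cands[0].n_cells == 3

    def test_distant_cells_split_into_two_candidates(self):
        scheme, dense = uniform_setup(n_bins_each=20)
        m = matrix_from_dense(scheme, dense)
        cells1 = [(0, 25), (1, 25), (0, 26)]
        cells2 = [(10, 35), (11, 35), (10, 36)]  # 10 bins away on both axes
        cands = hp.cluster_calls(
            self._calls_from_cells(scheme, cells1 + cells2),
            m, DetectionParams(min_cluster_size=3),
        )
        assert len(cands) == 2

    def test_small_components_discarded(self):
        scheme, dense = uniform_setup()
        m = matrix_from_dense(scheme, dense)
        cands = hp.cluster_calls(
            self._calls_from_cells(scheme, [(0, 15), (1, 15)]),
            m, DetectionParams(min_cluster_size=3),
        )
        assert cands == []

    def test_five_implanted_translocations_give_five_candidates(
        self, ten_chrom_lengths
    ):
        sides = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-"), ("+", "-")]
        events = [
            hp.Translocation(f"chr{2*i+1}", 5_000_000, sides[i][0],
                             f"chr{2*i+2}", 5_000_000, sides[i][1])
            for i in range(5)
        ]
        spec = hp.KaryotypeSpec(lengths=ten_chrom_lengths, translocations=events)
        frags, _, _ = hp.simulate_genome(ten_chrom_lengths, seed=31)
        dmap, truth = hp.build_derivative_map(spec, frags)
        pairs, truth = hp.simulate_pairs(
            frags, dmap, hp.ContactModel(n_pairs=200_000, seed=32), truth
        )
        res = hp.TranslocationModel(pairs, frags).fit(refine=False)
        found = {tuple(sorted((c.chrom_a, c.chrom_b))) for c in res.candidates}
        want = {tuple(sorted((t.chrom_a, t.chrom_b))) for t in events}
        # every implanted pair recovered and nothing on a wrong pair; a
        # decay tail may split off a secondary candidate on the same pair
        assert found == want
        assert len(found) == 5


class TestOrientation:
    @pytest.mark.parametrize("sides", [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")])
    def test_orientation_recovered_for_each_combination(self, sides):
        lengths = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
        spec = hp.KaryotypeSpec(
            lengths=lengths,
            translocations=[
                hp.Translocation("chr1", 5_000_000, sides[0],
                                 "chr2", 5_000_000, sides[1])
            ],
        )
        frags, _, _ = hp.simulate_genome(lengths, seed=41)
        dmap, truth = hp.build_derivative_map(spec, frags)
        pairs, truth = hp.simulate_pairs(
            frags, dmap, hp.ContactModel(n_pairs=120_000, seed=42), truth
        )
        res = hp.TranslocationModel(pairs, frags).fit(refine=False)
        assert len(res.candidates) == 1
        c = res.candidates[0]
        assert (c.orientation_a, c.orientation_b) == sides
        assert not c.reciprocal

    def test_reciprocal_event_merged_and_flagged(self):
        lengths = {"chr1": 10_000_000, "chr2": 10_000_000}
        spec = hp.KaryotypeSpec(
            lengths=lengths,
            translocations=[
                hp.Translocation("chr1", 5_000_000, "+", "chr2", 5_000_000, "-",
                                 reciprocal=True)
            ],
        )
        frags, _, _ = hp.simulate_genome(lengths, seed=43)
        dmap, truth = hp.build_derivative_map(spec, frags)
        pairs, truth = hp.simulate_pairs(
            frags, dmap, hp.ContactModel(n_pairs=150_000, seed=44), truth
        )
        res = hp.TranslocationModel(pairs, frags).fit(refine=False)
        assert len(res.candidates) == 1
        assert res.candidates[0].reciprocal
        # the reported orientation corresponds to one of the two junctions
        assert (res.candidates[0].orientation_a,
                res.candidates[0].orientation_b) in {("+", "-"), ("-", "+")}

    def test_uniform_block_is_undetermined(self):
        scheme, dense = uniform_setup()
        m = matrix_from_dense(scheme, dense)
        cells = [(i, j) for i in range(3, 8) for j in range(13, 18)]
        table = pd.DataFrame(
            [{"bin_i": i, "bin_j": j, "observed": 10.0, "expected": 0.1,
              "p": 1e-12, "q": 1e-10, "inter": True, "zero_expected": False}
             for i, j in cells]
        )
        calls = hp.detection.InteractionCalls(table, 1000)
        cands = hp.cluster_calls(calls, m, DetectionParams())
        bal = hp.balance_equal_visibility(m, coverage_floor=1)
        model = hp.fit_expected_model(bal, min_stratum_pairs=1)
        ratio = hp.ratio_map(bal, model)
        c = hp.infer_orientation(ratio, cands[0], DetectionParams())
        assert c.orientation_a is None and c.orientation_b is None


def test_merge_reciprocal_requires_complementary_orientations():
    from hicplexy.detection import TranslocationCandidate

    def cand(anchor, ori_a, ori_b, score):
        return TranslocationCandidate(
            chrom_a="chrA", chrom_b="chrB",
            bins_a=(anchor[0], anchor[0]), bins_b=(anchor[1], anchor[1]),
            anchor=anchor, score=score, n_cells=3,
            cells=pd.DataFrame({"bin_i": [], "bin_j": [], "observed": []}),
            orientation_a=ori_a, orientation_b=ori_b,
        )

    a = cand((10, 20), "+", "-", 100)
    b = cand((11, 21), "-", "+", 80)
    merged = merge_reciprocal([a, b], corner_tolerance=3)
    assert len(merged) == 1 and merged[0].reciprocal
    c = cand((10, 20), "+", "-", 100)
    d = cand((11, 21), "+", "-", 80)
    assert len(merge_reciprocal([c, d], corner_tolerance=3)) == 2
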