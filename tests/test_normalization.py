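import numpy as np
import pytest

import hicplexy as hp
from hicplexy.contacts import matrix_from_dense
from hicplexy.normalization import NormalizationError


def two_chrom_scheme(n_bins_each=2, bin_size=100):
    genome = hp.GenomeIndex(
        {"chrA": n_bins_each * bin_size, "chrB": n_bins_each * bin_size}
    )
    return hp.BinScheme(genome, bin_size)


def marginal_cv(balance):
    sym = balance.matrix.symmetric()
    marg = np.asarray(sym.sum(axis=1)).ravel()[balance.included]
    return marg.std() / marg.mean()


class TestBalancing:
    def test_equal_marginals_converges_immediately(self):
        scheme = two_chrom_scheme()
        dense = np.full((4, 4), 2.0)
        np.fill_diagonal(dense, 0.0)
        bal = hp.balance_equal_visibility(
            matrix_from_dense(scheme, dense), coverage_floor=1
        )
        assert bal.converged and bal.n_iter == 1
        f = bal.factors
        assert np.allclose(f, f[0])

    def test_block_design_matches_closed_form_fixed_point(self):
        # two disconnected 2-bin blocks with counts 2 and 8: the balanced
        # fixed point (solved by hand) has every marginal equal to the
        # common total/2, i.e. both blocks at 5, with factors
        # sqrt(2/5) and sqrt(8/5)
        scheme = two_chrom_scheme()
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 2.0
        dense[2, 3] = dense[3, 2] = 8.0
        bal = hp.balance_equal_visibility(
            matrix_from_dense(scheme, dense), coverage_floor=1, tol=1e-10
        )
        assert bal.converged
        sym = bal.matrix.symmetric().toarray()
        expected = np.zeros((4, 4))
        expected[0, 1] = expected[1, 0] = 5.0
        expected[2, 3] = expected[3, 2] = 5.0
        assert np.allclose(sym, expected, atol=1e-6)
        assert np.allclose(
            bal.factors,
            [np.sqrt(0.4), np.sqrt(0.4), np.sqrt(1.6), np.sqrt(1.6)],
            rtol=1e-4,
        )

    def test_random_matrix_marginal_cv_below_tolerance(self):
        rng = np.random.default_rng(8)
        scheme = two_chrom_scheme(n_bins_each=10)
        a = rng.poisson(20, size=(20, 20)).astype(float)
        dense = a + a.T
        np.fill_diagonal(dense, 0)
        bal = hp.balance_equal_visibility(
            matrix_from_dense(scheme, dense), tol=1e-6
        )
        assert bal.converged
        assert marginal_cv(bal) < 1e-5

    def test_total_preserved_after_rescale(self):
        rng = np.random.default_rng(9)
        scheme = two_chrom_scheme(n_bins_each=8)
        a = rng.poisson(15, size=(16, 16)).astype(float)
        dense = a + a.T
        m = matrix_from_dense(scheme, dense)
        bal = hp.balance_equal_visibility(m, coverage_floor=1)
        assert np.isclose(bal.matrix.total, m.total, rtol=1e-6)

    def test_factor_scale_invariance_of_ratio_map(self):
        rng = np.random.default_rng(10)
        scheme = two_chrom_scheme(n_bins_each=8)
        a = rng.poisson(15, size=(16, 16)).astype(float)
        dense = a + a.T
        np.fill_diagonal(dense, 0)

        def ratios(scale):
            m = matrix_from_dense(scheme, dense * scale)
            bal = hp.balance_equal_visibility(m, coverage_floor=1)
            model = hp.fit_expected_model(bal, min_stratum_pairs=4)
            # pseudocount scaled with the data so the comparison isolates
            # the balancing factors
            return hp.ratio_map(bal, model, pseudocount=scale).block("chrA", "chrB")

        assert np.allclose(ratios(1.0) , ratios(7.0), atol=1e-6)

    def test_all_masked_is_an_error(self):
        scheme = two_chrom_scheme()
        dense = np.zeros((4, 4))
        with pytest.raises(NormalizationError):
            hp.balance_equal_visibility(matrix_from_dense(scheme, dense))


class TestExpectedModel:
    def test_uniform_inter_cells_reproduced(self):
        scheme = two_chrom_scheme(n_bins_each=5)
        dense = np.zeros((10, 10))
        dense[:5, 5:] = 3.0
        dense[5:, :5] = 3.0
        # add intra signal so no bin is empty
        for i in range(10):
            for j in range(10):
                if i != j and (i < 5) == (j < 5):
                    dense[i, j] = 5.0
        bal = hp.balance_equal_visibility(
            matrix_from_dense(scheme, dense), coverage_floor=1
        )
        model = hp.fit_expected_model(bal, min_stratum_pairs=2)
        gi, gj = np.meshgrid(np.arange(5), np.arange(5, 10))
        exp = model.expected(gi.ravel(), gj.ravel())
        assert np.allclose(exp, exp[0], rtol=1e-6)

    def test_decay_strata_decrease_monotonically(self, small_genome):
        fragments, _, _ = small_genome
        spec = hp.KaryotypeSpec(lengths={"chr1": 10_000_000, "chr2": 10_000_000})
        dmap, truth = hp.build_derivative_map(spec, fragments)
        pairs, _ = hp.simulate_pairs(
            fragments, dmap, hp.ContactModel(n_pairs=100_000, seed=21), truth
        )
        matrix = hp.bin_contacts(pairs, hp.BinScheme(fragments.genome, 100_000))
        bal = hp.balance_equal_visibility(matrix)
        model = hp.fit_expected_model(bal)
        means = model.stratum_mean[1:]  # skip the diagonal stratum
        means = means[means > 0]
        # alpha = 1 decay: stratum means fall by orders of magnitude overall
        assert means[0] > 10 * means[-1]
        # monotone up to small sampling noise between neighbours
        assert np.all(means[:-1] * 1.5 >= means[1:])

    def test_expected_total_matches_observed_within_one_percent(self, small_genome):
        fragments, _, _ = small_genome
        spec = hp.KaryotypeSpec(lengths={"chr1": 10_000_000, "chr2": 10_000_000})
        dmap, truth = hp.build_derivative_map(spec, fragments)
        pairs, _ = hp.simulate_pairs(
            fragments, dmap, hp.ContactModel(n_pairs=50_000, seed=22), truth
        )
        matrix = hp.bin_contacts(pairs, hp.BinScheme(fragments.genome, 100_000))
        bal = hp.balance_equal_visibility(matrix)
        model = hp.fit_expected_model(bal)
        n = matrix.scheme.n_bins_total
        iu = np.triu_indices(n)
        total_expected = model.expected(iu[0], iu[1]).sum()
        assert np.isclose(total_expected, bal.matrix.total, rtol=0.01)

    def test_stratum_means_self_consistent(self):
        rng = np.random.default_rng(13)
        scheme = two_chrom_scheme(n_bins_each=12)
        a = rng.poisson(10, size=(24, 24)).astype(float)
        dense = a + a.T
        bal = hp.balance_equal_visibility(
            matrix_from_dense(scheme, dense), coverage_floor=1
        )
        model = hp.fit_expected_model(bal, min_stratum_pairs=1)
        sym = bal.matrix.symmetric().toarray()
        # within one chromosome, observed mean at distance d equals the
        # model's stratum mean wherever a stratum is a single distance
        for d in range(1, 5):
            stratum = model.stratum_of_distance[d]
            dists = np.where(model.stratum_of_distance == stratum)[0]
            if len(dists) != 1:
                continue
            vals = [sym[i, i + d] for off in (0, 12) for i in range(off, off + 12 - d)]
            assert np.isclose(np.mean(vals), model.stratum_mean[stratum], rtol=1e-9)

    def test_single_chromosome_has_no_inter_model(self):
        genome = hp.GenomeIndex({"chrA": 400})
        scheme = hp.BinScheme(genome, 100)
        rng = np.random.default_rng(14)
        a = rng.poisson(15, size=(4, 4)).astype(float)
        bal = hp.balance_equal_visibility(
            matrix_from_dense(scheme, a + a.T), coverage_floor=1
        )
        model = hp.fit_expected_model(bal, min_stratum_pairs=1)
        assert not model.has_inter


class TestRatioMap:
    def test_observed_equal_expected_gives_zero(self):
        scheme = two_chrom_scheme(n_bins_each=5)
        dense = np.full((10, 10), 4.0)
        np.fill_diagonal(dense, 0)
        bal = hp.balance_equal_visibility(
            matrix_from_dense(scheme, dense), coverage_floor=1
        )
        model = hp.fit_expected_model(bal, min_stratum_pairs=1)
        block = hp.ratio_map(bal, model).block("chrA", "chrB")
        assert np.allclose(block, 0.0, atol=1e-9)

    def test_doubled_cell_against_fixed_expectation_gains_one(self):
        from dataclasses import replace as dc_replace

        scheme = two_chrom_scheme(n_bins_each=5)
        dense = np.full((10, 10), 40.0)
        np.fill_diagonal(dense, 0)
        bal = hp.balance_equal_visibility(
            matrix_from_dense(scheme, dense), coverage_floor=1
        )
        model = hp.fit_expected_model(bal, min_stratum_pairs=1)
        doubled = bal.matrix.symmetric().toarray()
        doubled[0, 7] *= 2
        doubled[7, 0] *= 2
        bal2 = dc_replace(bal, matrix=matrix_from_dense(scheme, doubled))
        ratio = hp.ratio_map(bal2, model, pseudocount=1e-9)
        assert np.isclose(ratio.values([0], [7])[0], 1.0, atol=1e-6)
        assert np.isclose(ratio.values([1], [7])[0], 0.0, atol=1e-6)
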