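import numpy as np
import pytest
from scipy import stats

import hicplexy as hp
from hicplexy.genome import GenomeError
from hicplexy.simulate import _sample_decay_distance


class TestSimulateGenome:
    def test_zero_gene_density_gives_empty_track(self):
        _, genes, _ = hp.simulate_genome({"chr1": 1_000_000}, gene_density=0, seed=1)
        assert genes == []

    def test_fragment_count_within_poisson_band(self):
        frags, _, _ = hp.simulate_genome({"chr1": 10_000_000}, seed=2)
        expected = 10_000_000 / 4096
        sd = np.sqrt(expected)
        assert abs(frags.n_fragments("chr1") - expected) < 3 * sd

    def test_seeded_determinism(self):
        a = hp.simulate_genome({"chr1": 500_000}, seed=5)
        b = hp.simulate_genome({"chr1": 500_000}, seed=5)
        assert (a[0].starts("chr1") == b[0].starts("chr1")).all()
        assert a[1] == b[1]

    def test_gene_density_approximately_met(self):
        _, genes, _ = hp.simulate_genome(
            {"chr1": 50_000_000}, gene_density=0.4, seed=3
        )
        covered = sum(len(g) for g in genes)
        assert 0.3 < covered / 50_000_000 < 0.5

    def test_genes_non_overlapping(self):
        _, genes, _ = hp.simulate_genome({"chr1": 5_000_000}, seed=4)
        genes = sorted(genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start


class TestBuildDerivativeMap:
    def test_empty_spec_is_identity(self):
        lengths = {"chr1": 1_000_000, "chr2": 800_000}
        frags, _, _ = hp.simulate_genome(lengths, seed=6)
        dmap, truth = hp.build_derivative_map(
            hp.KaryotypeSpec(lengths=lengths), frags
        )
        # diploid: two molecules per chromosome, all intact
        assert dmap.total_length() == 2 * (1_000_000 + 800_000)
        assert truth.junctions == []

    def test_balanced_translocation_conserves_length(self):
        lengths = {"chr1": 1_000_000, "chr2": 800_000}
        frags, _, _ = hp.simulate_genome(lengths, seed=7)
        spec = hp.KaryotypeSpec(
            lengths=lengths,
            translocations=[
                hp.Translocation("chr1", 400_000, "+", "chr2", 300_000, "-",
                                 reciprocal=True)
            ],
        )
        dmap, truth = hp.build_derivative_map(spec, frags)
        ders = [m for m in dmap.molecules if m.name.startswith("der")]
        assert len(ders) == 2
        assert sum(len(m) for m in ders) == 1_800_000

    def test_junction_snapped_to_cut_site(self):
        lengths = {"chr1": 1_000_000, "chr2": 800_000}
        frags, _, _ = hp.simulate_genome(lengths, seed=8)
        spec = hp.KaryotypeSpec(
            lengths=lengths,
            translocations=[
                hp.Translocation("chr1", 400_000, "+", "chr2", 300_000, "-")
            ],
        )
        _, truth = hp.build_derivative_map(spec, frags)
        for j in truth.junctions:
            assert j.position in frags.starts(j.chrom)

    def test_lift_round_trip(self):
        lengths = {"chr1": 1_000_000, "chr2": 800_000}
        frags, _, _ = hp.simulate_genome(lengths, seed=9)
        spec = hp.KaryotypeSpec(
            lengths=lengths,
            translocations=[
                hp.Translocation("chr1", 400_000, "-", "chr2", 300_000, "+",
                                 reciprocal=True)
            ],
        )
        dmap, _ = hp.build_derivative_map(spec, frags)
        rng = np.random.default_rng(10)
        for _ in range(200):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            ref = int(rng.integers(0, lengths[chrom]))
            hits = dmap.inverse_lift(chrom, ref)
            assert hits, f"{chrom}:{ref} not on any molecule"
            for mi, pos in hits:
                chroms, refs = dmap.lift(mi, [pos])
                assert chroms[0] == chrom and refs[0] == ref

    def test_deletion_overlapping_breakpoint_rejected(self):
        lengths = {"chr1": 1_000_000, "chr2": 800_000}
        frags, _, _ = hp.simulate_genome(lengths, seed=11)
        spec = hp.KaryotypeSpec(
            lengths=lengths,
            translocations=[
                hp.Translocation("chr1", 400_000, "+", "chr2", 300_000, "-")
            ],
            deletions=[hp.GenomicInterval("chr1", 350_000, 450_000)],
        )
        with pytest.raises(GenomeError):
            hp.build_derivative_map(spec, frags)

    def test_deletion_excised_from_tumor_molecule(self):
        lengths = {"chr1": 1_000_000}
        frags, _, _ = hp.simulate_genome(lengths, seed=12)
        spec = hp.KaryotypeSpec(
            lengths=lengths,
            deletions=[hp.GenomicInterval("chr1", 200_000, 300_000)],
        )
        dmap, _ = hp.build_derivative_map(spec, frags)
        assert dmap.total_length() == 2_000_000 - 100_000


class TestSimulatePairs:
    def test_pair_count_conserved_exactly(self, small_genome):
        fragments, _, _ = small_genome
        spec = hp.KaryotypeSpec(lengths={"chr1": 10_000_000, "chr2": 10_000_000})
        dmap, truth = hp.build_derivative_map(spec, fragments)
        pairs, _ = hp.simulate_pairs(
            fragments, dmap, hp.ContactModel(n_pairs=12_345, seed=13), truth
        )
        assert len(pairs) == 12_345

    def test_seeded_determinism(self, small_genome):
        fragments, _, _ = small_genome
        spec = hp.KaryotypeSpec(lengths={"chr1": 10_000_000, "chr2": 10_000_000})
        dmap, truth = hp.build_derivative_map(spec, fragments)
        m = hp.ContactModel(n_pairs=5_000, seed=14)
        p1, _ = hp.simulate_pairs(fragments, dmap, m, truth)
        p2, _ = hp.simulate_pairs(fragments, dmap, m, truth)
        assert p1.equals(p2)

    def test_no_trans_no_rearrangement_gives_zero_inter_pairs(self, small_genome):
        fragments, _, _ = small_genome
        spec = hp.KaryotypeSpec(lengths={"chr1": 10_000_000, "chr2": 10_000_000})
        dmap, truth = hp.build_derivative_map(spec, fragments)
        pairs, _ = hp.simulate_pairs(
            fragments, dmap,
            hp.ContactModel(n_pairs=5_000, seed=15, trans_fraction=0.0), truth,
        )
        assert (pairs.chrom1 == pairs.chrom2).all()

    def test_cis_distance_histogram_matches_decay_kernel(self):
        """Chi-square agreement of sampled distances with (s+s0)^-alpha."""
        rng = np.random.default_rng(16)
        L, s0, alpha, n = 10_000_000, 10_000.0, 1.0, 100_000
        s = _sample_decay_distance(rng, n, L, alpha, s0)
        edges = np.geomspace(1, L, 30)
        obs, _ = np.histogram(s, bins=edges)
        cdf = lambda x: np.log((x + s0) / s0) / np.log((L + s0) / s0)
        exp = (cdf(edges[1:]) - cdf(edges[:-1])) * n
        keep = exp > 10
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        dof = keep.sum() - 1
        assert chi2 < stats.chi2.ppf(0.999, dof)

    def test_realized_linking_pairs_match_numeric_integration(self, small_genome):
        """Expected junction-crossing count from integrating the decay
        kernel across the junction agrees with the realized count."""
        fragments, _, _ = small_genome
        lengths = {"chr1": 10_000_000, "chr2": 10_000_000}
        spec = hp.KaryotypeSpec(
            lengths=lengths,
            translocations=[
                hp.Translocation("chr1", 5_000_000, "+", "chr2", 5_000_000, "-")
            ],
        )
        dmap, truth = hp.build_derivative_map(spec, fragments)
        model = hp.ContactModel(n_pairs=200_000, seed=17)
        pairs, truth = hp.simulate_pairs(fragments, dmap, model, truth)

        der = next(m for m in dmap.molecules if m.name.startswith("der"))
        L = float(len(der))
        junction = float(der.boundaries()[0])
        total_len = sum(len(m) for m in dmap.molecules)
        n_cis_der = model.n_pairs * (1 - model.trans_fraction) * (L / total_len)
        # P(pair crosses junction) by numeric integration over (a, s):
        # a ~ U(0, L); s ~ (s+s0)^-alpha truncated to (0, L); direction
        # uniform; crossing iff the interval [min, max] straddles junction
        s0, alpha = model.s0, model.alpha
        s_grid = np.linspace(1, L - 1, 20_000)
        dens = (s_grid + s0) ** (-alpha)
        dens /= np.trapezoid(dens, s_grid)
        # start a ~ U(0, L), direction uniform, accept iff the far end is
        # in bounds; crossing needs a within s upstream of the junction
        # (per direction), truncated by the in-bounds constraint
        def crossing_starts(j):
            return np.maximum(
                0.0,
                np.minimum(j, s_grid) - np.maximum(0.0, j - (L - s_grid)),
            )
        p_cross_given_s = 0.5 * (
            crossing_starts(junction) + crossing_starts(L - junction)
        )
        p_accept = (L - s_grid) / L
        p_cross = np.trapezoid(dens * p_cross_given_s / L, s_grid)
        p_ok = np.trapezoid(dens * p_accept, s_grid)
        expected = n_cis_der * p_cross / p_ok
        realized = truth.linking_pairs[0]
        sd = np.sqrt(expected)
        assert abs(realized - expected) < 4 * sd

    def test_null_output_yields_no_candidates(self, ten_chrom_lengths):
        fragments, _, _ = hp.simulate_genome(ten_chrom_lengths, seed=18)
        spec = hp.KaryotypeSpec(lengths=ten_chrom_lengths)
        dmap, truth = hp.build_derivative_map(spec, fragments)
        pairs, _ = hp.simulate_pairs(
            fragments, dmap, hp.ContactModel(n_pairs=100_000, seed=19), truth
        )
        res = hp.TranslocationModel(pairs, fragments).fit(refine=False)
        assert res.candidates == []


class TestEmitFasta:
    def test_digest_round_trips_fragment_map(self, tmp_path):
        lengths = {"chr1": 200_000, "chr2": 150_000}
        frags, _, _ = hp.simulate_genome(lengths, seed=20)
        fasta = tmp_path / "genome.fa"
        from hicplexy.simulate import emit_fasta

        emit_fasta(frags, fasta, seed=21)
        from hicplexy.genome import digest_fasta

        redigested = digest_fasta(fasta)
        for chrom in lengths:
            assert (redigested.starts(chrom) == frags.starts(chrom)).all()
            assert (redigested.ends(chrom) == frags.ends(chrom)).all()
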