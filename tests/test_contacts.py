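import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hicplexy as hp
from hicplexy.contacts import PairsError, matrix_from_dense


@pytest.fixture()
def genome():
    return hp.GenomeIndex({"chr1": 1000, "chr2": 800})


class TestReadPairs:
    def test_canonical_order_across_chromosomes(self, genome, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("r1\tchr2\t100\t+\tchr1\t50\t-\n")
        df = hp.read_pairs(p, genome)
        row = df.iloc[0]
        assert (row.chrom1, row.pos1, row.strand1) == ("chr1", 50, "-")
        assert (row.chrom2, row.pos2, row.strand2) == ("chr2", 100, "+")

    def test_same_chromosome_positions_swapped(self, genome, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("r1\tchr1\t700\t+\tchr1\t200\t-\n")
        df = hp.read_pairs(p, genome)
        assert (df.iloc[0].pos1, df.iloc[0].pos2) == (200, 700)

    def test_wrong_field_count_rejected(self, genome, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("r1\tchr1\t700\t+\tchr1\n")
        with pytest.raises(PairsError, match=":1"):
            hp.read_pairs(p, genome)

    def test_unknown_chromosome_reports_line(self, genome, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("#header\nr1\tchrMT\t5\t+\tchr1\t50\t-\n")
        with pytest.raises(PairsError, match="chrMT"):
            hp.read_pairs(p, genome)

    def test_round_trip_is_involutive(self, genome, tmp_path):
        df = hp.make_pairs(
            genome,
            chrom1=["chr2", "chr1"], pos1=[10, 700], strand1=["+", "-"],
            chrom2=["chr1", "chr1"], pos2=[20, 100], strand2=["-", "+"],
        )
        p = tmp_path / "pairs.tsv"
        hp.write_pairs(df, p)
        again = hp.read_pairs(p, genome)
        pd.testing.assert_frame_equal(df, again)


class TestFilterPairs:
    def test_exact_duplicates_dropped(self, genome):
        df = hp.make_pairs(
            genome,
            chrom1=["chr1", "chr1"], pos1=[10, 10], strand1=["+", "+"],
            chrom2=["chr2", "chr2"], pos2=[20, 20], strand2=["-", "-"],
        )
        out, report = hp.filter_pairs(df, dedup=True)
        assert len(out) == 1
        assert report.n_duplicate == 1

    def test_all_filters_off_is_identity(self, genome):
        df = hp.make_pairs(
            genome,
            chrom1=["chr1", "chr1"], pos1=[10, 10], strand1=["+", "+"],
            chrom2=["chr2", "chr2"], pos2=[20, 20], strand2=["-", "-"],
        )
        out, report = hp.filter_pairs(df, dedup=False, fragments=None)
        assert len(out) == 2
        assert report.n_retained == 2

    def test_mapq_filter(self, genome):
        df = hp.make_pairs(
            genome,
            chrom1=["chr1", "chr1"], pos1=[10, 30], strand1=["+", "+"],
            chrom2=["chr2", "chr2"], pos2=[20, 40], strand2=["-", "-"],
            mapq1=[10, 40], mapq2=[40, 40],
        )
        out, report = hp.filter_pairs(df, min_mapq=30, dedup=False)
        assert len(out) == 1 and report.n_low_mapq == 1

    def test_planted_duplicate_count_recovered(self, small_genome):
        fragments, _, _ = small_genome
        spec = hp.KaryotypeSpec(lengths={"chr1": 10_000_000, "chr2": 10_000_000})
        dmap, truth = hp.build_derivative_map(spec, fragments)
        model = hp.ContactModel(n_pairs=10_000, seed=5, duplicate_fraction=0.05)
        pairs, _ = hp.simulate_pairs(fragments, dmap, model, truth)
        out, report = hp.filter_pairs(pairs, dedup=True)
        assert report.n_duplicate >= 500  # the 500 planted copies
        # accidental coincidences are possible but must stay rare
        assert report.n_duplicate <= 520

    def test_distance_to_cut_site_filter(self):
        fm = hp.digest_genome({"c": "GG" + "AAGCTT" + "C" * 5000})
        genome = fm.genome
        df = hp.make_pairs(
            genome,
            chrom1=["c", "c"], pos1=[4, 4000], strand1=["+", "+"],
            chrom2=["c", "c"], pos2=[5, 4001], strand2=["-", "-"],
        )
        out, report = hp.filter_pairs(
            df, dedup=False, fragments=fm, max_frag_distance=500
        )
        assert len(out) == 1 and report.n_far_from_cut == 1


class TestBinContacts:
    def test_same_bin_pair_accumulates(self, genome):
        scheme = hp.BinScheme(genome, 100)
        df = hp.make_pairs(
            genome,
            chrom1=["chr1", "chr1"], pos1=[10, 20], strand1=["+", "+"],
            chrom2=["chr2", "chr2"], pos2=[30, 40], strand2=["-", "-"],
        )
        m = hp.bin_contacts(df, scheme)
        assert m.count(scheme.bin_of("chr1", 10), scheme.bin_of("chr2", 30)) == 2

    def test_position_at_bin_size_maps_to_bin_one(self, genome):
        scheme = hp.BinScheme(genome, 100)
        assert scheme.bin_of("chr1", 100) == 1
        assert scheme.bin_of("chr1", 99) == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_grand_total_conserved(self, seed):
        genome = hp.GenomeIndex({"chr1": 1000, "chr2": 800})
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 500))
        chroms = rng.choice(["chr1", "chr2"], size=2 * n)
        pos = np.array(
            [rng.integers(0, genome.length(c)) for c in chroms]
        )
        df = hp.make_pairs(
            genome,
            chrom1=chroms[:n], pos1=pos[:n], strand1=["+"] * n,
            chrom2=chroms[n:], pos2=pos[n:], strand2=["-"] * n,
        )
        m = hp.bin_contacts(df, hp.BinScheme(genome, 64))
        assert m.total == n

    def test_matrix_symmetry(self, genome):
        scheme = hp.BinScheme(genome, 100)
        df = hp.make_pairs(
            genome,
            chrom1=["chr1"], pos1=[950], strand1=["+"],
            chrom2=["chr1"], pos2=[50], strand2=["-"],
        )
        m = hp.bin_contacts(df, scheme)
        sym = m.symmetric()
        assert sym[0, 9] == sym[9, 0] == 1


class TestFragmentLinkCounts:
    def test_no_linking_pairs_zero_vectors(self, small_genome):
        fragments, _, _ = small_genome
        df = hp.make_pairs(
            fragments.genome,
            chrom1=["chr1"], pos1=[100], strand1=["+"],
            chrom2=["chr1"], pos2=[200], strand2=["-"],
        )
        wa = hp.GenomicInterval("chr1", 4_000_000, 6_000_000)
        wb = hp.GenomicInterval("chr2", 4_000_000, 6_000_000)
        ca, cb, _, _ = hp.fragment_link_counts(df, fragments, wa, wb)
        assert ca.sum() == 0 and cb.sum() == 0

    def test_single_pair_lands_on_single_fragments(self, small_genome):
        fragments, _, _ = small_genome
        df = hp.make_pairs(
            fragments.genome,
            chrom1=["chr1"], pos1=[5_000_000], strand1=["+"],
            chrom2=["chr2"], pos2=[5_000_000], strand2=["-"],
        )
        wa = hp.GenomicInterval("chr1", 4_000_000, 6_000_000)
        wb = hp.GenomicInterval("chr2", 4_000_000, 6_000_000)
        ca, cb, idx_a, idx_b = hp.fragment_link_counts(df, fragments, wa, wb)
        assert ca.sum() == 1 and cb.sum() == 1
        fa = idx_a[np.argmax(ca)]
        assert (
            fragments.starts("chr1")[fa] <= 5_000_000 < fragments.ends("chr1")[fa]
        )

    def test_sums_conserved_for_simulated_linking_pairs(self, translocated_dataset):
        fragments, _, pairs, truth = translocated_dataset
        ja = next(j for j in truth.junctions if j.chrom == "chr1")
        jb = next(j for j in truth.junctions if j.chrom == "chr2")
        # fragment-aligned 2 Mb windows around the true junctions
        def aligned_window(chrom, pos):
            i_lo = fragments.fragment_index(chrom, max(pos - 1_000_000, 0))
            i_hi = fragments.fragment_index(chrom, min(pos + 1_000_000, 9_999_999))
            return hp.GenomicInterval(
                chrom,
                int(fragments.starts(chrom)[i_lo]),
                int(fragments.ends(chrom)[i_hi]),
            )
        wa = aligned_window("chr1", ja.position)
        wb = aligned_window("chr2", jb.position)
        ca, cb, _, _ = hp.fragment_link_counts(pairs, fragments, wa, wb)
        in_a = (pairs.chrom1 == "chr1") & (pairs.pos1 >= wa.start) & (pairs.pos1 < wa.end)
        in_b = (pairs.chrom2 == "chr2") & (pairs.pos2 >= wb.start) & (pairs.pos2 < wb.end)
        n_linking = int((in_a & in_b).sum())
        assert ca.sum() == n_linking
        assert cb.sum() == n_linking

    def test_overlapping_windows_rejected(self, small_genome):
        fragments, _, _ = small_genome
        df = hp.make_pairs(fragments.genome, ["chr1"], [1], ["+"], ["chr2"], [1], ["-"])
        with pytest.raises(PairsError):
            hp.fragment_link_counts(
                df, fragments,
                hp.GenomicInterval("chr1", 0, 2_000_000),
                hp.GenomicInterval("chr1", 1_000_000, 3_000_000),
            )


def test_matrix_from_dense_round_trip(genome):
    scheme = hp.BinScheme(genome, 100)
    n = scheme.n_bins_total
    rng = np.random.default_rng(3)
    a = rng.integers(0, 5, size=(n, n))
    dense = (a + a.T).astype(float)
    m = matrix_from_dense(scheme, dense)
    assert np.allclose(m.symmetric().toarray(), dense)
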