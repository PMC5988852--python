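import numpy as np
import pytest

import hicplexy as hp


@pytest.fixture(scope="session")
def table1_records():
    return hp.load_table1_breakpoints()


@pytest.fixture(scope="session")
def ten_chrom_lengths():
    return {f"chr{i}": 10_000_000 for i in range(1, 11)}


@pytest.fixture(scope="session")
def small_genome():
    """Two 10 Mb chromosomes with ~4 kb fragments, genes, no gaps."""
    lengths = {"chr1": 10_000_000, "chr2": 10_000_000}
    fragments, genes, gaps = hp.simulate_genome(lengths, seed=11)
    return fragments, genes, gaps


@pytest.fixture(scope="session")
def translocated_dataset(small_genome):
    """One balanced (non-reciprocal) translocation, deep enough to refine."""
    fragments, genes, _ = small_genome
    spec = hp.KaryotypeSpec(
        lengths={"chr1": 10_000_000, "chr2": 10_000_000},
        translocations=[
            hp.Translocation("chr1", 5_000_000, "+", "chr2", 5_000_000, "-")
        ],
    )
    dmap, truth = hp.build_derivative_map(spec, fragments)
    pairs, truth = hp.simulate_pairs(
        fragments, dmap, hp.ContactModel(n_pairs=120_000, seed=7), truth
    )
    return fragments, genes, pairs, truth


@pytest.fixture(scope="session")
def toy_permutation_catalog():
    """5 fragments of which 3 overlap a gene: Hypergeom(5, 3, 2) null."""
    frags = [hp.GenomicInterval("chr1", i * 100, (i + 1) * 100) for i in range(5)]
    genes = [hp.GenomicInterval("chr1", 0, 250, "geneA")]  # frags 0,1,2
    return frags, genes
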