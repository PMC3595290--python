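import pytest

from dgetag import extract_virtual_tags, filter_tags, count_genes, expression_table
from dgetag.simulate import (
    ADAPTOR_SEQUENCES,
    SimulationParams,
    simulate_genes,
    simulate_triad,
)


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        n_genes=800, library_size=200_000, singleton_noise=2_000, seed=0
    )


@pytest.fixture(scope="session")
def small_triad(small_params):
    genes = simulate_genes(small_params)
    libraries, truth = simulate_triad(genes, small_params)
    return genes, libraries, truth


def run_quantification(genes, libraries):
    """Shared pipeline tail: QC -> index -> per-strain expression tables."""
    index = extract_virtual_tags(genes)
    tables, totals = {}, {}
    for strain, raw in libraries.items():
        clean, acc = filter_tags(raw, ADAPTOR_SEQUENCES)
        counts = count_genes(clean, index, genes=list(genes))
        tables[strain] = expression_table(counts, acc.clean_total)
        totals[strain] = acc.clean_total
    return tables, totals


@pytest.fixture(scope="session")
def quantify_triad():
    return run_quantification


@pytest.fixture(scope="session")
def default_triad():
    """Full study-scale synthetic triad, quantified end to end."""
    params = SimulationParams()
    genes = simulate_genes(params)
    libraries, truth = simulate_triad(genes, params)
    tables, totals = run_quantification(genes, libraries)
    return params, truth, tables, totals


@pytest.fixture()
def toy_index():
    """Five-gene toy gene set with a shared window and distinct tags."""
    genes = {
        "g1": "AACATGAAAAAAAAAAAAAAAAAGG",  # tag CATG + 17 A
        "g2": "TTCATGCCCCCCCCCCCCCCCCCTT",
        "g3": "GGCATGGGGGGGGGGGGGGGGGGAA",
        "g4": "ACCATGACGTACGTACGTACGTACG",
        "g5": "CATGTTTTTTTTTTTTTTTTTCCCC",
    }
    return genes, extract_virtual_tags(genes)
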