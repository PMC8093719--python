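import networkx as nx
import pytest

from famnet.simulate import (SimulationConfig, apply_sampling_and_error,
                             draw_allele_frequencies, simulate_population)


def error_free_config(seed, n_founders=60, n_generations=3):
    """Full sampling, no genotyping error: downstream stages must recover
    the truth exactly under this configuration."""
    return SimulationConfig(
        n_founders=n_founders, n_generations=n_generations, seed=seed,
        sampling_fraction=1.0, dropout_rate=0.0, false_allele_rate=0.0,
        locus_failure_rate=0.0, replicate_fraction=0.0)


def simulate_error_free(seed, n_founders=60, n_generations=3):
    cfg = error_free_config(seed, n_founders, n_generations)
    freqs = draw_allele_frequencies(cfg.n_loci, cfg.alleles_per_locus,
                                    seed=seed + 1000)
    pop = simulate_population(cfg, freqs)
    samples = apply_sampling_and_error(pop, cfg, freqs)
    return cfg, freqs, pop, samples


@pytest.fixture(scope="session")
def small_truth():
    """One error-free fully sampled population shared across tests."""
    return simulate_error_free(seed=2)


@pytest.fixture
def path_graph():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def bridged_triangles():
    """Two 3-node triangles joined by one bridge edge."""
    g = nx.Graph()
    g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                      ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                      ("a1", "b1")])
    return g
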