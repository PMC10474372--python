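import numpy as np
import pytest

import ontovnn as ov


@pytest.fixture
def diamond_graph():
    """R -> {A, B} -> C (C has two parents); genes on A, B, C."""
    return ov.OntologyGraph(
        terms={"R", "A", "B", "C"},
        edges=[("R", "A", "default"), ("R", "B", "default"),
               ("A", "C", "default"), ("B", "C", "default")],
        annotations={"A": {"g1", "g2"}, "B": {"g3"}, "C": {"g4", "g5"}},
    )


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale fixture spec shared by unit tests (not the planted cohort)."""
    return ov.FixtureSpec(
        seed=11, depth=2, branching=2, genes_per_bottom_term=3,
        n_cells=30, n_drugs=6, n_responsive_drugs=4, n_causal_terms=2,
        fingerprint_bits=64,
    )


@pytest.fixture(scope="session")
def small_graph(small_spec):
    return ov.generate_ontology(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec, small_graph):
    return ov.generate_cohort(small_spec, small_graph)


@pytest.fixture(scope="session")
def small_hierarchy(small_graph):
    return ov.layerize(small_graph)


def make_model(hierarchy, k=2, drug_input_dim=64, norm_variant="post",
               activation="tanh", seed=0, **cfg_overrides):
    cfg = ov.ModelConfig(
        k=k, drug_layers=cfg_overrides.pop("drug_layers", (8, 4)),
        vnn_output=cfg_overrides.pop("vnn_output", 4),
        fusion=cfg_overrides.pop("fusion", 5),
        drug_input_dim=drug_input_dim, norm_variant=norm_variant,
        activation=activation, **cfg_overrides,
    )
    conn = ov.build_connectivity(hierarchy, cfg.k)
    return ov.compile_model(hierarchy, conn, cfg, seed=seed)


@pytest.fixture
def small_model(small_hierarchy):
    return make_model(small_hierarchy)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
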