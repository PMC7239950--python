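import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim_config():
    """A small but fully featured cohort configuration shared across tests."""
    from gemini_loh.synthetic_cohort import SimulationConfig

    return SimulationConfig(
        seed=7,
        n_genes=40,
        n_essential=8,
        n_samples_per_type={"LUAD": 30, "PAAD": 30},
        loh_rate_per_type={"LUAD": 0.21, "PAAD": 0.09},
        n_cell_lines=12,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    """Variants + contexts + genes generated once for the session."""
    from gemini_loh.synthetic_cohort import gene_layout, simulate_variants

    genes = gene_layout(small_sim_config)
    variants, contexts = simulate_variants(small_sim_config, genes)
    return genes, variants, contexts
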