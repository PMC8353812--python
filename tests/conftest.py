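import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle_parts():
    """In-memory fixture bundle: scaled paired design, perfect evidence."""
    from lactoseq.simulate import (
        SimulationConfig,
        simulate_annotation,
        simulate_counts,
        simulate_evidence,
        simulate_sequences,
    )

    cfg = SimulationConfig(
        seed=3, n_ref_genes=30, n_queries=250, dams_per_parity=(3, 3, 3, 3)
    )
    rng = np.random.default_rng(cfg.seed)
    ref, queries, truth = simulate_annotation(cfg, rng)
    seqs, truth = simulate_sequences(queries, truth, cfg, rng)
    evidence = simulate_evidence(truth, cfg.evidence_agreement, rng)
    cm, truth = simulate_counts(cfg, truth, rng)
    return cfg, ref, queries, truth, seqs, evidence, cm


@pytest.fixture(scope="session")
def de_fixture():
    """Standalone count simulation for DE unit tests (modest size)."""
    from lactoseq.simulate import SimulationConfig, simulate_counts

    cfg = SimulationConfig(
        seed=21, n_transcripts=600, dams_per_parity=(3, 3, 3, 3), dispersion=0.3
    )
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth
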