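import pytest

from ese_scan import pipeline, synthetic_data as sd


@pytest.fixture(scope="session")
def default_sim():
    """Full-size synthetic experiment at study-design defaults."""
    return sd.simulate_all(sd.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_bundle(default_sim):
    s = default_sim
    return pipeline.analyze(
        s.annotation, s.gene_counts, s.tss_counts, s.design, s.peaks, s.tracks
    )


@pytest.fixture(scope="session")
def small_config():
    return sd.SimConfig(
        seed=7,
        n_genes=20,
        n_activated=6,
        n_suppressed=3,
        genome=(("cA", 300_000), ("cB", 300_000)),
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return sd.simulate_all(small_config)


@pytest.fixture(scope="session")
def matched_eses(default_sim, default_bundle):
    """Called ESEs joined to planted truth by (chrom, summit)."""
    return default_bundle.eses.merge(
        default_sim.truth.eses, on=["chrom", "summit"], suffixes=("_called", "_true")
    )
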