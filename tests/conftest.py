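import pytest
from hypothesis import HealthCheck, settings

from spheroscreen.simulate import ScreenConfig, generate_screen

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


SMALL_SCREEN_CONFIG = dict(
    n_patients=4, n_paired_samples=1, n_drugs=6, n_2d_samples=2, noise_cv=0.03
)


@pytest.fixture(scope="session")
def small_screen():
    """A small but structurally complete simulated screen (5 samples,
    6 drugs, paired 2D plates for two samples)."""
    return generate_screen(ScreenConfig(**SMALL_SCREEN_CONFIG), seed=11)


@pytest.fixture(scope="session")
def small_screen_tables(small_screen):
    """Readouts, QC report, normalized responses and DSS table for the
    small screen, computed once."""
    from spheroscreen.dose_response import screen_dss
    from spheroscreen.qc import normalize_responses, qc_gate
    from spheroscreen.readout import well_readouts

    dataset, truth = small_screen
    readouts = well_readouts(dataset.wells)
    report = qc_gate(readouts)
    normalized = normalize_responses(readouts)
    dss_long = screen_dss(normalized, report)
    return dict(dataset=dataset, truth=truth, readouts=readouts,
                qc=report, normalized=normalized, dss_long=dss_long)
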