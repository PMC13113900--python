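import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ergraph as eg
from ergraph.synth import CohortSpec, GroupSpec, preset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_waveforms():
    """Two hand-written 8-sample recordings with full metadata."""
    return [
        eg.Waveform(samples=[0.0, -2.0, 1.0, 5.0, 4.0, 2.0, 1.0, 0.5],
                    subject_id="S1", group="ASD", sex="M", eye="RIGHT",
                    flash_td=446.0, recording_index=1),
        eg.Waveform(samples=[1.0, -1.5, 2.0, 6.0, 3.0, 2.5, 0.0, -0.5],
                    subject_id="S2", group="CONTROL", sex="F", eye="LEFT",
                    flash_td=113.0, recording_index=2),
    ]


def two_group_cohort(n_subjects=12, seed=5, recordings=2, between_sd=0.08,
                     duration_ms=None):
    """Compact-vs-expansive cohort used by pipeline tests; small
    between-subject spread makes the classes cleanly separable."""
    from dataclasses import replace

    compact = preset("COMPACT")
    expansive = preset("EXPANSIVE")
    if duration_ms is not None:
        compact = replace(compact, duration_ms=duration_ms)
        expansive = replace(expansive, duration_ms=duration_ms)
    spec = CohortSpec(
        groups={"ASD": GroupSpec(compact, n_subjects=n_subjects, between_sd=between_sd),
                "CONTROL": GroupSpec(expansive, n_subjects=n_subjects,
                                     between_sd=between_sd)},
        recordings_per_subject=recordings, eyes=[eg.Eye.RIGHT], flashes=[113.0],
        seed=seed)
    return eg.generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_feature_table():
    waves = two_group_cohort(n_subjects=20, seed=3)
    return eg.feature_table(waves, Q=50)
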