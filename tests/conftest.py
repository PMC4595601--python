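import numpy as np
import pytest

from drest.delineate import BeatSeries
from drest.synth import SubjectProfile, generate_beat_series, make_step_schedule


@pytest.fixture(scope="session")
def stepped_profile():
    """Noise-free subject with sustained heart-rate changes."""
    rng = np.random.default_rng(42)
    return SubjectProfile(
        drest_true=0.05, t90_true_s=80.0, noise_sd_ms=0.0, rr_mean_ms=850.0,
        rr_step_schedule=make_step_schedule(rng, 1800.0, 850.0), seed=7)


@pytest.fixture(scope="session")
def stepped_series(stepped_profile):
    return generate_beat_series(stepped_profile, 1800.0)


@pytest.fixture()
def fixed_beats():
    """60 beats at exactly 1000 ms with QT 400 / Tpe 90."""
    n = 60
    t = 1.0 + np.arange(n)
    rr = np.full(n, 1000.0)
    rr[0] = np.nan
    return BeatSeries(t=t, rr_ms=rr, qt_ms=np.full(n, 400.0),
                      tpe_ms=np.full(n, 90.0), valid=np.ones(n, bool))


@pytest.fixture(scope="session")
def restitution_pair():
    """Fast-profile dynamic restitution, control and 50 % IKr block.

    Session-scoped: this is the expensive in-silico arm shared by the
    tissue-level and acceptance tests.
    """
    from drest.tissue import FAST_PROFILE, TissueConfig, dynamic_restitution

    grid = FAST_PROFILE["rr_grid_ms"]
    n_beats = FAST_PROFILE["n_beats"]
    control = dynamic_restitution(TissueConfig(), rr_grid_ms=grid,
                                  n_beats=n_beats)
    block = dynamic_restitution(TissueConfig(gkr_scale=0.5), rr_grid_ms=grid,
                                n_beats=n_beats)
    return control, block
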