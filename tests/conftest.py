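import pytest
from hypothesis import HealthCheck, settings

import dyadsync as ds

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SCHEDULE_20S = tuple((c, 20.0) for c in ("FP1", "SF1", "FP2", "SF2", "RU"))


@pytest.fixture(scope="session")
def small_config() -> ds.SynthConfig:
    """Reduced-scale study configuration: 128 Hz, 20-s condition blocks."""
    return ds.SynthConfig(srate=128.0, schedule=SCHEDULE_20S, seed=11)


@pytest.fixture(scope="session")
def small_dyad(small_config):
    rec, gt = ds.generate_dyad(small_config, 0)
    return rec, gt


@pytest.fixture(scope="session")
def screened_epochs(small_config):
    """One preprocessed dyad: filtered, channel-selected, epoched, screened."""
    rec, _ = ds.generate_dyad(small_config, 0)
    rec = ds.filter_raw(rec)
    rec = ds.select_channels(rec)
    epochs = ds.make_hyper_epochs(rec)
    screened, _log = ds.reject_artifacts(epochs)
    return screened
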