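import pandas as pd
import pytest

from emoeeg.experiments import make_protocol_frame  # noqa: F401  (re-export for tests)
from emoeeg.features import SpectralConfig, extract_features
from emoeeg.preprocess import bandpass, segment, strip_baseline
from emoeeg.simulate import SimConfig, generate_subject

# a reduced montage that still contains frontal sites for EOG surrogates;
# effect channels are chosen from it so class signal exists downstream
TINY_KW = dict(
    n_subjects=1,
    n_channels=16,
    trial_seconds=8.0,
    trial_margin_seconds=2.0,
    pre_trial_seconds=2.0,
    rest_seconds=6.0,
    blink_rate=0.0,
    effect_channels=("AF7", "F5", "F8"),
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return SimConfig(**TINY_KW)


@pytest.fixture(scope="session")
def tiny_recording(tiny_cfg):
    rec, truth = generate_subject(tiny_cfg, 1)
    return rec, truth


@pytest.fixture(scope="session")
def tiny_epochs(tiny_cfg, tiny_recording):
    rec, _ = tiny_recording
    rec = bandpass(rec, 0.1, 80.0)
    rec = strip_baseline(rec, tiny_cfg.pre_trial_seconds, tiny_cfg.trial_seconds)
    return segment(rec, 2.0, 0.5)


@pytest.fixture(scope="session")
def tiny_features(tiny_epochs) -> pd.DataFrame:
    return extract_features(tiny_epochs, SpectralConfig())


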