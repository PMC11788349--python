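import pytest

import soilqual as sq


@pytest.fixture(scope="session")
def zero_noise_records():
    """Noise-free 3x3 trial at the built-in calibration: every plot sits
    exactly at its treatment's true mean."""
    specs, effects = sq.default_calibration(cv=0.0)
    design = sq.TrialDesign(seed=0)
    return sq.generate_trial(design, specs, effects)


@pytest.fixture(scope="session")
def zero_noise_frame(zero_noise_records):
    return sq.records_to_frame(zero_noise_records)


@pytest.fixture()
def noisy_records():
    specs, effects = sq.default_calibration(cv=0.05)
    return sq.generate_trial(sq.TrialDesign(seed=42), specs, effects)
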