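import numpy as np
import pytest

from vhitkit import synthetic as syn


@pytest.fixture
def clean_params():
    """Noiseless, saccade-free horizontal-canal impulse parameters."""
    return syn.ImpulseParams(
        peak_head_velocity=250.0, pulse_width=0.04, true_gain=1.0, noise_sd=0.0
    )


@pytest.fixture
def clean_trial(clean_params):
    return syn.simulate_trial(clean_params, canal="HC", side="left", rng_seed=0)


def make_trial(
    peak=250.0,
    width=0.04,
    gain=1.0,
    noise_sd=0.0,
    saccades=(),
    blink=False,
    canal="HC",
    side="left",
    seed=0,
    direction="positive",
):
    params = syn.ImpulseParams(
        peak_head_velocity=peak,
        pulse_width=width,
        direction=direction,
        true_gain=gain,
        saccades=list(saccades),
        noise_sd=noise_sd,
        blink=blink,
    )
    return syn.simulate_trial(params, canal=canal, side=side, rng_seed=seed)


@pytest.fixture
def trial_factory():
    return make_trial
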