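import numpy as np
import pytest

from rhythmkit.synthetic import (
    ChannelSpec,
    CohortSpec,
    GroupSpec,
    MoodSpec,
    generate_participant,
)


def make_spec(
    days: int = 4,
    seed: int = 0,
    hr: ChannelSpec | None = None,
    accel_z: ChannelSpec | None = None,
    mood: MoodSpec | None = None,
    **group_kwargs,
) -> CohortSpec:
    """One-group cohort spec with quiet, noiseless defaults that individual
    tests override channel by channel."""
    group = GroupSpec(
        label="G",
        n_participants=1,
        channels={
            "accel_x": ChannelSpec(phase_hours=12.8, mesor=0.012, amplitude=0.004),
            "accel_y": ChannelSpec(phase_hours=12.8, mesor=0.010, amplitude=0.003),
            "accel_z": accel_z
            or ChannelSpec(phase_hours=14.1, mesor=0.35, amplitude=0.11),
            "hr": hr or ChannelSpec(phase_hours=14.0, mesor=75.0, amplitude=8.0),
        },
        mood=mood or MoodSpec(noise_sd=0.0),
        **group_kwargs,
    )
    return CohortSpec(groups=[group], days=days, seed=seed)


@pytest.fixture
def noiseless_recording():
    spec = make_spec(days=4, seed=3)
    return generate_participant(spec, "G", np.random.default_rng(3), "G-01")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
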