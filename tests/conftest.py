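"""Shared fixtures: tiny synthetic cohorts and reusable analysis configs.

Everything is generated at test time with fixed seeds; scales are kept small
(short recordings, few channels) so the whole suite runs in minutes while the
statistical checks still have the power they need.
"""

from __future__ import annotations

import numpy as np
import pytest

from envtails.pipeline import AnalysisConfig
from envtails.synthetic import EffectSpec, generate_cohort, generate_recording


@pytest.fixture(scope="session")
def null_spec() -> EffectSpec:
    """No-burst spec: every channel is a Gaussian process (Rayleigh envelope)."""
    return EffectSpec(burst_amp_scale=0.0, effect_channels=None)


@pytest.fixture(scope="session")
def planted_spec() -> EffectSpec:
    """Monotonic burst-intensity ramp on the first 4 of 8 channels."""
    mask = np.zeros(8, dtype=bool)
    mask[:4] = True
    return EffectSpec(
        group_profile=(0.0, 0.25, 0.5, 0.75, 1.0),
        effect_channels=tuple(mask),
        carrier_freqs=(10.5,),
        burst_amp_scale=6.0,
    )


@pytest.fixture(scope="session")
def small_recording(null_spec):
    """One 70 s, 2-channel, 250 Hz no-burst recording."""
    return generate_recording(null_spec, 0, 2, 70.0, 250.0, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(planted_spec):
    """5 groups x 3 participants, 8 channels, 35 s at 200 Hz."""
    return generate_cohort(planted_spec, 3, 8, 35.0, 200.0, seed=23)


@pytest.fixture
def fast_config() -> AnalysisConfig:
    """Reduced-scale config usable on the tiny cohort (single frequency)."""
    return AnalysisConfig(
        frequencies=(10.5,),
        metrics=("skewness",),
        n_segments=3,
        segment_length=10.0,
        segment_offset=2.0,
        n_perm=50,
        n_boot=20,
        seed=5,
    )
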