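"""Shared fixtures: reduced-profile sessions generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from thumbgrip.features import build_feature_vectors
from thumbgrip.preprocess import WindowingSpec
from thumbgrip.simulate import (
    AcquisitionSpec,
    ForceProfile,
    NoiseModel,
    SessionConfig,
    build_grid_layout,
    ci_config,
    simulate_session,
)


def micro_config(seed: int = 0, effect_scale: float = 1.0, trials_per_posture: int = 2) -> SessionConfig:
    """Tiny session for structural tests: 3x3 grids, 256 Hz, 1 s holds."""
    layouts = (
        build_grid_layout(3, 3, 8.0, mask_corner=False, region="anterior"),
        build_grid_layout(3, 3, 8.0, mask_corner=False, region="posterior"),
    )
    return SessionConfig(
        layouts=layouts,
        acquisition=AcquisitionSpec(sample_rate=256.0, band_lo=3.0, band_hi=110.0, n_harmonics=2),
        protocol=ForceProfile(hold_s=1.0, ramp_s=0.2, rest_range_s=(0.3, 0.5)),
        noise=NoiseModel(carrier_band_hz=(20.0, 100.0)),
        effect_scale=effect_scale,
        trials_per_posture=trials_per_posture,
        master_seed=seed,
    )


MICRO_WINDOWING = WindowingSpec(window_ms=300.0, step_ms=250.0, segment_s=0.9)


@pytest.fixture(scope="session")
def micro_session():
    return simulate_session(micro_config(seed=21))


@pytest.fixture(scope="session")
def ci_session():
    """Reduced-profile session: 512 Hz, 3 s holds, 8 trials per posture."""
    return simulate_session(ci_config(seed=11))


@pytest.fixture(scope="session")
def ci_null_session():
    """Same profile with effect_scale = 0: postures indistinguishable."""
    return simulate_session(ci_config(seed=13, effect_scale=0.0))


@pytest.fixture(scope="session")
def ci_table_posterior(ci_session):
    return build_feature_vectors(ci_session, "posterior")


@pytest.fixture(scope="session")
def ci_table_anterior(ci_session):
    return build_feature_vectors(ci_session, "anterior")
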