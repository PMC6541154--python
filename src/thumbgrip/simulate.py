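"""Synthetic high-density surface-EMG (HD-sEMG) session generator.

Emulates a static thumb-opposition experiment: a subject holds an isometric
grip at 30% of maximal voluntary contraction (MVC) with the thumb opposed to
the base of digit 2, 3, 4 or 5 (postures P1-P4), while monopolar HD-sEMG is
sampled from two 13x5 electrode grids (8 mm inter-electrode distance, one
corner site masked, 64 active channels each) over the anterior (flexor) and
posterior (extensor) forearm.

The signal model is an interference-pattern surrogate, not a motor-unit
simulation: each channel carries zero-mean Gaussian noise band-limited to the
EMG-dominant band, amplitude-modulated by a per-channel gain times the force
envelope.  Posture affects only the per-channel gain (spatial amplitude
modulation over fixed source locations); the location of activity never moves
with posture.  Optional power-line interference (50 Hz and harmonics), a
common-mode noise term shared across channels, and white instrument noise are
added on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "POSTURES",
    "REGIONS",
    "GridLayout",
    "AcquisitionSpec",
    "ForceProfile",
    "NoiseModel",
    "PostureAmplitudeMap",
    "TrialRecording",
    "Session",
    "SessionConfig",
    "build_grid_layout",
    "make_posture_amplitude_maps",
    "simulate_trial",
    "simulate_session",
    "default_config",
    "ci_config",
]

POSTURES = ("P1", "P2", "P3", "P4")
REGIONS = ("anterior", "posterior")

# Relative mean-amplitude level of each posture per region.  The posterior
# grid decreases monotonically from P1 to P4 (thumb opposed to digit 2 ->
# digit 5 recruits progressively less extensor drive); the anterior grid
# peaks at P2.  These are session-level defaults of the generator, reachable
# through ``effect_scale`` (0 collapses all postures onto the same map).
_POSTURE_LEVELS = {
    "anterior": (0.85, 1.00, 0.72, 0.55),
    "posterior": (1.00, 0.80, 0.63, 0.47),
}

# Small per-source deviations from the global posture level, so the two
# spatial sources are not modulated in perfect lockstep.  Posterior P4 pulls
# the two sources toward similar effective strengths.
_SOURCE_DELTAS = {
    "anterior": ((+0.05, -0.05), (-0.04, +0.04), (+0.02, -0.02), (-0.06, +0.06)),
    "posterior": ((+0.06, -0.06), (+0.03, -0.03), (-0.03, +0.03), (-0.12, +0.12)),
}

_SOURCE_BASE_WEIGHTS = (1.0, 0.75)  # source 1 dominates in every posture
_PEAK_AMPLITUDE_MV = 0.35  # carrier RMS at a source peak, posture level 1.0
_BACKGROUND_FRACTION = 0.35  # spatially flat co-activation floor


@dataclass(frozen=True)
class GridLayout:
    """Regular electrode lattice with an optional masked corner site."""

    rows: int
    cols: int
    ied_mm: float
    region: str
    active_sites: tuple[tuple[int, int, float, float], ...]  # (row, col, x, y)

    @property
    def n_channels(self) -> int:
        return len(self.active_sites)

    @property
    def coords_mm(self) -> np.ndarray:
        """(n_channels, 2) array of site (x, y) positions in mm."""
        return np.array([(x, y) for _, _, x, y in self.active_sites], float)

    @property
    def site_rows_cols(self) -> np.ndarray:
        return np.array([(r, c) for r, c, _, _ in self.active_sites], int)


def build_grid_layout(
    rows: int,
    cols: int,
    ied_mm: float,
    mask_corner: bool = True,
    region: str = "posterior",
) -> GridLayout:
    """Lay out a rows x cols electrode grid at ``ied_mm`` spacing.

    When ``mask_corner`` is set the (row 1, col 1) site is excluded, matching
    HD grids whose 13x5 = 65 lattice exposes 64 recording channels.
    """
    if rows < 1 or cols < 1:
        raise ValueError(f"grid dimensions must be positive, got {rows}x{cols}")
    if ied_mm <= 0:
        raise ValueError(f"inter-electrode distance must be positive, got {ied_mm}")
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}, got {region!r}")
    sites = []
    for r in range(rows):
        for c in range(cols):
            if mask_corner and r == 0 and c == 0:
                continue
            sites.append((r, c, c * ied_mm, r * ied_mm))
    return GridLayout(rows, cols, float(ied_mm), region, tuple(sites))


@dataclass(frozen=True)
class AcquisitionSpec:
    """Amplifier settings: sampling, gain, analog band and mains notch."""

    sample_rate: float = 2048.0
    gain: float = 1000.0
    band_lo: float = 3.0
    band_hi: float = 900.0
    notch_base: float = 50.0
    n_harmonics: int = 7  # comb teeth at notch_base * (1..n), 50..350 Hz

    def __post_init__(self) -> None:
        nyq = self.sample_rate / 2.0
        if not (0 < self.band_lo < self.band_hi < nyq):
            raise ValueError(
                f"need 0 < band_lo < band_hi < Nyquist ({nyq} Hz); "
                f"got [{self.band_lo}, {self.band_hi}]"
            )
        if not (self.band_lo < self.notch_base < self.band_hi):
            raise ValueError("notch_base must lie inside the acquisition band")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be non-negative")
        if self.n_harmonics and self.notch_base * self.n_harmonics >= nyq:
            raise ValueError("highest notch harmonic exceeds Nyquist")


@dataclass(frozen=True)
class ForceProfile:
    """Ramp-hold-release grip effort expressed as a fraction of MVC."""

    mvc_fraction: float = 0.30
    ramp_s: float = 0.5
    hold_s: float = 5.0
    rest_range_s: tuple[float, float] = (5.0, 7.0)
    release_s: float = 0.3
    tail_s: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.mvc_fraction <= 1):
            raise ValueError("mvc_fraction must be in (0, 1]")
        lo, hi = self.rest_range_s
        if not (0 <= lo <= hi):
            raise ValueError("rest_range_s must be ordered and non-negative")
        if min(self.ramp_s, self.hold_s, self.release_s, self.tail_s) < 0:
            raise ValueError("durations must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic ingredients of the surrogate signal.

    carrier_band_hz:       band of the interference-pattern EMG carrier
                           (must sit inside the acquisition band).
    baseline_noise_mv:     white instrument-noise standard deviation.
    common_mode_fraction:  amplitude of a band-limited noise source shared by
                           all channels, relative to each channel's gain.
    line_amp_mv:           amplitude of the 50 Hz fundamental; harmonic k is
                           scaled by line_decay**(k-1).  0 disables mains.
    force_jitter:          relative slow fluctuation of the held force
                           (visual-feedback tracking error).
    """

    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    baseline_noise_mv: float = 0.02
    common_mode_fraction: float = 0.10
    line_amp_mv: float = 0.015
    line_decay: float = 0.6
    force_jitter: float = 0.015
    jitter_bandwidth_hz: float = 1.0


@dataclass(frozen=True)
class PostureAmplitudeMap:
    """Per-channel amplitude gain for one posture over one grid.

    Source centers are shared across the four postures of a grid: posture
    changes only the gains (amplitude modulation), never where the activity
    sits.
    """

    posture: str
    region: str
    gain_per_channel: np.ndarray
    source_centers: tuple[tuple[float, float], ...]
    source_widths_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if np.any(self.gain_per_channel < 0):
            raise ValueError("amplitude gains must be non-negative")


@dataclass(frozen=True)
class TrialRecording:
    """One grip trial: multi-channel EMG plus the synchronous force trace."""

    posture: str
    emg: np.ndarray  # (channels, samples), mV at the electrode after gain
    force: np.ndarray  # (samples,), fraction of MVC
    sample_rate: float
    hold_interval: tuple[int, int]  # [start, end) samples of the hold phase
    seed: int
    rest_pre_s: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.emg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]


@dataclass(frozen=True)
class Session:
    """A full synthetic experiment: 4 postures x ``trials_per_posture``."""

    trials: tuple[TrialRecording, ...]
    layouts: tuple[GridLayout, GridLayout]  # (anterior, posterior)
    acquisition: AcquisitionSpec
    protocol: ForceProfile
    noise: NoiseModel
    posture_order: tuple[str, ...]
    master_seed: int
    effect_scale: float
    amplitude_maps: dict[str, tuple[PostureAmplitudeMap, ...]] = field(
        default_factory=dict
    )

    def layout(self, region: str) -> GridLayout:
        for lay in self.layouts:
            if lay.region == region:
                return lay
        raise ValueError(f"no grid for region {region!r}")

    def channel_slice(self, region: str) -> slice:
        """Rows of ``trial.emg`` belonging to ``region``.

        Channel order is anterior sites row-major, then posterior.
        """
        n_ant = self.layouts[0].n_channels
        if region == "anterior":
            return slice(0, n_ant)
        if region == "posterior":
            return slice(n_ant, n_ant + self.layouts[1].n_channels)
        raise ValueError(f"unknown region {region!r}")


def make_posture_amplitude_maps(
    layout: GridLayout,
    effect_scale: float = 1.0,
    seed: int = 0,
) -> tuple[PostureAmplitudeMap, ...]:
    """Build the four posture gain maps of a grid.

    Two Gaussian spatial sources (sigma 12 mm) are placed along the grid's
    long axis with a small seeded jitter; the same centers are reused for all
    four postures.  Posture p multiplies every channel by a region-specific
    level and perturbs the two source strengths slightly, both raised to the
    power ``effect_scale`` so that ``effect_scale = 0`` yields four identical
    maps (null model) and 1 the default separation.
    """
    if effect_scale < 0:
        raise ValueError("effect_scale must be non-negative")
    rng = np.random.default_rng(seed)
    width = (layout.cols - 1) * layout.ied_mm
    height = (layout.rows - 1) * layout.ied_mm
    jitter = rng.uniform(-0.5, 0.5, size=(2, 2)) * layout.ied_mm
    centers = (
        (0.5 * width + jitter[0, 0], 0.30 * height + jitter[0, 1]),
        (0.5 * width + jitter[1, 0], 0.70 * height + jitter[1, 1]),
    )
    sigma = 12.0
    coords = layout.coords_mm
    kernels = []
    for cx, cy in centers:
        d2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
        kernels.append(np.exp(-d2 / (2.0 * sigma**2)))
    levels = _POSTURE_LEVELS[layout.region]
    deltas = _SOURCE_DELTAS[layout.region]
    maps = []
    for p, posture in enumerate(POSTURES):
        level = levels[p] ** effect_scale
        mix = np.full(layout.n_channels, _BACKGROUND_FRACTION)
        for s, kern in enumerate(kernels):
            factor = (1.0 + deltas[p][s]) ** effect_scale
            mix = mix + _SOURCE_BASE_WEIGHTS[s] * factor * kern
        gains = _PEAK_AMPLITUDE_MV * level * mix
        maps.append(
            PostureAmplitudeMap(
                posture=posture,
                region=layout.region,
                gain_per_channel=gains,
                source_centers=centers,
                source_widths_mm=(sigma, sigma),
            )
        )
    return tuple(maps)


def _carrier_sos(band: tuple[float, float], fs: float):
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"carrier band {band} must sit below Nyquist ({nyq} Hz)")
    return _sig.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def _unit_variance_scale(sos) -> float:
    """1/sqrt of the impulse-response energy: white noise filtered with
    ``sos`` and multiplied by this factor has unit variance."""
    impulse = np.zeros(8192)
    impulse[0] = 1.0
    h = _sig.sosfilt(sos, impulse)
    return 1.0 / math.sqrt(float(np.sum(h**2)))


def _band_noise(rng: np.random.Generator, sos, scale: float, shape) -> np.ndarray:
    white = rng.standard_normal(shape)
    return _sig.sosfilt(sos, white, axis=-1) * scale


def simulate_trial(
    layouts: tuple[GridLayout, GridLayout],
    maps: dict[str, tuple[PostureAmplitudeMap, ...]],
    acquisition: AcquisitionSpec,
    protocol: ForceProfile,
    posture: str,
    seed: int,
    noise: NoiseModel | None = None,
    rest_pre_s: float | None = None,
) -> TrialRecording:
    """Simulate one grip trial (rest, ramp, hold, release, short tail).

    Deterministic given ``seed``.  During the hold phase the expected RMS of
    channel c is ``gain_c * sqrt(1 + cm^2)`` plus instrument noise, i.e.
    proportional to the posture's amplitude map.
    """
    if posture not in POSTURES:
        raise ValueError(f"posture must be one of {POSTURES}, got {posture!r}")
    noise = noise or NoiseModel()
    fs = acquisition.sample_rate
    rng = np.random.default_rng(seed)
    if rest_pre_s is None:
        rest_pre_s = float(rng.uniform(*protocol.rest_range_s))

    n_rest = round(rest_pre_s * fs)
    n_ramp = round(protocol.ramp_s * fs)
    n_hold = round(protocol.hold_s * fs)
    n_rel = round(protocol.release_s * fs)
    n_tail = round(protocol.tail_s * fs)
    n = n_rest + n_ramp + n_hold + n_rel + n_tail
    hold_interval = (n_rest + n_ramp, n_rest + n_ramp + n_hold)

    env = np.zeros(n)
    if n_ramp:
        env[n_rest : n_rest + n_ramp] = np.linspace(0, 1, n_ramp, endpoint=False)
    env[hold_interval[0] : hold_interval[1]] = 1.0
    if n_rel:
        env[hold_interval[1] : hold_interval[1] + n_rel] = np.linspace(
            1, 0, n_rel, endpoint=False
        )

    # slow force-tracking jitter around the target level
    if noise.force_jitter > 0 and noise.jitter_bandwidth_hz < fs / 2:
        sos_j = _sig.butter(
            2, noise.jitter_bandwidth_hz / (fs / 2), btype="lowpass", output="sos"
        )
        j = _sig.sosfilt(sos_j, rng.standard_normal(n))
        j_std = float(np.std(j))
        j = j * (noise.force_jitter / j_std) if j_std > 0 else j * 0.0
    else:
        j = np.zeros(n)
    env_j = np.clip(env * (1.0 + j), 0.0, None)
    force = protocol.mvc_fraction * env_j + 0.002 * rng.standard_normal(n)

    gains = np.concatenate(
        [
            next(m for m in maps[lay.region] if m.posture == posture).gain_per_channel
            for lay in layouts
        ]
    )
    n_ch = gains.size

    sos_c = _carrier_sos(noise.carrier_band_hz, fs)
    scale = _unit_variance_scale(sos_c)
    carrier = _band_noise(rng, sos_c, scale, (n_ch, n))
    if noise.common_mode_fraction > 0:
        common = _band_noise(rng, sos_c, scale, n)
        carrier += noise.common_mode_fraction * common[None, :]

    emg = gains[:, None] * env_j[None, :] * carrier
    if noise.baseline_noise_mv > 0:
        emg += noise.baseline_noise_mv * rng.standard_normal((n_ch, n))
    if noise.line_amp_mv > 0 and acquisition.n_harmonics > 0:
        t = np.arange(n) / fs
        coupling = rng.uniform(0.7, 1.3, size=n_ch)
        line = np.zeros(n)
        for k in range(1, acquisition.n_harmonics + 1):
            amp = noise.line_amp_mv * noise.line_decay ** (k - 1)
            phase = rng.uniform(0, 2 * np.pi)
            line += amp * np.sin(2 * np.pi * acquisition.notch_base * k * t + phase)
        emg += coupling[:, None] * line[None, :]

    return TrialRecording(
        posture=posture,
        emg=emg.astype(np.float32),
        force=force.astype(np.float32),
        sample_rate=fs,
        hold_interval=hold_interval,
        seed=int(seed),
        rest_pre_s=float(rest_pre_s),
    )


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to generate a session deterministically."""

    layouts: tuple[GridLayout, GridLayout]
    acquisition: AcquisitionSpec = AcquisitionSpec()
    protocol: ForceProfile = ForceProfile()
    noise: NoiseModel = NoiseModel()
    effect_scale: float = 1.0
    trials_per_posture: int = 30
    master_seed: int = 0

    def with_seed(self, seed: int) -> "SessionConfig":
        return replace(self, master_seed=int(seed))


def default_config(seed: int = 0, effect_scale: float = 1.0) -> SessionConfig:
    """Full protocol: 2048 Hz, 5 s holds at 30% MVC, 30 trials/posture."""
    layouts = (
        build_grid_layout(13, 5, 8.0, mask_corner=True, region="anterior"),
        build_grid_layout(13, 5, 8.0, mask_corner=True, region="posterior"),
    )
    return SessionConfig(
        layouts=layouts, effect_scale=effect_scale, master_seed=int(seed)
    )


def ci_config(seed: int = 0, effect_scale: float = 1.0) -> SessionConfig:
    """Reduced profile for fast tests: 512 Hz, 3 s holds, 8 trials/posture."""
    layouts = (
        build_grid_layout(13, 5, 8.0, mask_corner=True, region="anterior"),
        build_grid_layout(13, 5, 8.0, mask_corner=True, region="posterior"),
    )
    return SessionConfig(
        layouts=layouts,
        acquisition=AcquisitionSpec(
            sample_rate=512.0, band_lo=3.0, band_hi=220.0, n_harmonics=4
        ),
        protocol=ForceProfile(hold_s=3.0),
        noise=NoiseModel(carrier_band_hz=(20.0, 200.0)),
        effect_scale=effect_scale,
        trials_per_posture=8,
        master_seed=int(seed),
    )


def simulate_session(config: SessionConfig) -> Session:
    """Generate the full randomized session described by ``config``.

    The posture order is a seeded permutation with ``trials_per_posture``
    occurrences of each label; inter-trial rests are drawn uniformly from the
    protocol's rest range.  Bit-identical for identical configs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 0xA11CE]))
    maps = {
        lay.region: make_posture_amplitude_maps(
            lay,
            config.effect_scale,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for lay in config.layouts
    }
    labels = np.repeat(np.array(POSTURES), config.trials_per_posture)
    order = tuple(str(p) for p in rng.permutation(labels))
    trial_seeds = rng.integers(0, 2**31 - 1, size=len(order))
    rests = rng.uniform(*config.protocol.rest_range_s, size=len(order))
    trials = tuple(
        simulate_trial(
            config.layouts,
            maps,
            config.acquisition,
            config.protocol,
            posture,
            seed=int(trial_seeds[i]),
            noise=config.noise,
            rest_pre_s=float(rests[i]),
        )
        for i, posture in enumerate(order)
    )
    return Session(
        trials=trials,
        layouts=config.layouts,
        acquisition=config.acquisition,
        protocol=config.protocol,
        noise=config.noise,
        posture_order=order,
        master_seed=config.master_seed,
        effect_scale=config.effect_scale,
        amplitude_maps=maps,
    )
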