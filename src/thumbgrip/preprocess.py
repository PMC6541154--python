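"""Signal conditioning and RMS amplitude mapping.

The conditioning chain mirrors a standard HD-sEMG amplitude analysis: a
zero-phase 3-900 Hz band-pass, a zero-phase comb of notches at 50 Hz and its
harmonics, selection of the central portion of the isometric hold, and RMS
computed over 300 ms windows advanced in 250 ms steps (i.e. 50 ms overlap).
With the default 2.8 s analysis segment this yields exactly 11 windows per
trial and channel.  Grand-averaging the window RMS over windows and
repetitions gives one iso-potential amplitude map per posture and grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .simulate import AcquisitionSpec, GridLayout, Session, TrialRecording

__all__ = [
    "WindowingSpec",
    "RmsSeries",
    "IsoPotentialMap",
    "apply_bandpass",
    "apply_notch_comb",
    "preprocess_emg",
    "select_hold_segment",
    "rms_windows",
    "window_count",
    "trial_rms",
    "grand_average_map",
    "iso_map_to_frame",
]


@dataclass(frozen=True)
class WindowingSpec:
    """RMS windowing: 300 ms windows, 250 ms step, central 2.8 s segment."""

    window_ms: float = 300.0
    step_ms: float = 250.0
    segment_s: float = 2.8

    def __post_init__(self) -> None:
        if not (0 < self.step_ms <= self.window_ms):
            raise ValueError("need 0 < step_ms <= window_ms")
        if self.segment_s < self.window_ms / 1000.0:
            raise ValueError("segment_s must fit at least one window")

    def window_samples(self, fs: float) -> int:
        return round(self.window_ms / 1000.0 * fs)

    def step_samples(self, fs: float) -> int:
        return round(self.step_ms / 1000.0 * fs)


@dataclass(frozen=True)
class RmsSeries:
    """Per-window RMS per channel: values is (channels, windows)."""

    values: np.ndarray
    window_times: np.ndarray  # window centers, s from segment start

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class IsoPotentialMap:
    """Grand-averaged RMS amplitude per electrode site of one grid."""

    grid: str
    posture: str
    mean_rms_per_channel: np.ndarray
    layout: GridLayout


def apply_bandpass(
    x: np.ndarray, sample_rate: float, lo: float, hi: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    nyq = sample_rate / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got [{lo}, {hi}]")
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    sos = _sig.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return _sig.sosfiltfilt(sos, np.asarray(x, float), axis=-1)


def _notch_sos(sample_rate: float, base: float, n_harmonics: int, bw_hz: float):
    # constant absolute bandwidth per tooth: Q grows with the harmonic, so
    # higher harmonics do not eat progressively wider slices of the EMG band
    sections = []
    for k in range(1, n_harmonics + 1):
        f0 = base * k
        b, a = _sig.iirnotch(f0, f0 / bw_hz, fs=sample_rate)
        sections.append(_sig.tf2sos(b, a))
    return np.vstack(sections)


def apply_notch_comb(
    x: np.ndarray,
    sample_rate: float,
    base: float = 50.0,
    n_harmonics: int = 7,
    bw_hz: float = 6.0,
) -> np.ndarray:
    """Zero-phase notch comb at ``base`` Hz and its harmonics."""
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if base * n_harmonics >= sample_rate / 2.0:
        raise ValueError(
            f"harmonic {base * n_harmonics} Hz at or above Nyquist "
            f"({sample_rate / 2.0} Hz)"
        )
    x = np.asarray(x, float)
    sos = _notch_sos(sample_rate, base, n_harmonics, bw_hz)
    # generous padding so the notch ring-down settles inside the extension
    padlen = min(x.shape[-1] - 2, round(sample_rate))
    return _sig.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def preprocess_emg(emg: np.ndarray, acquisition: AcquisitionSpec) -> np.ndarray:
    """Band-pass then notch-comb according to the acquisition settings."""
    out = apply_bandpass(
        emg, acquisition.sample_rate, acquisition.band_lo, acquisition.band_hi
    )
    if acquisition.n_harmonics > 0:
        out = apply_notch_comb(
            out,
            acquisition.sample_rate,
            acquisition.notch_base,
            acquisition.n_harmonics,
        )
    return out


def select_hold_segment(
    trial: TrialRecording, spec: WindowingSpec
) -> tuple[int, int]:
    """Sample interval of the central ``segment_s`` of the hold phase."""
    start, end = trial.hold_interval
    seg = round(spec.segment_s * trial.sample_rate)
    if seg > end - start:
        raise ValueError(
            f"analysis segment ({spec.segment_s} s) longer than the hold "
            f"({(end - start) / trial.sample_rate:.3f} s)"
        )
    off = (end - start - seg) // 2
    return (start + off, start + off + seg)


def window_count(segment_samples: int, window_samples: int, step_samples: int) -> int:
    """Number of fully contained windows placed at ``step`` increments."""
    if segment_samples < window_samples:
        raise ValueError("segment shorter than one window")
    return (segment_samples - window_samples) // step_samples + 1


def rms_windows(
    segment: np.ndarray, sample_rate: float, spec: WindowingSpec
) -> RmsSeries:
    """Windowed RMS along the last axis; trailing partial windows dropped."""
    segment = np.atleast_2d(np.asarray(segment, float))
    w = spec.window_samples(sample_rate)
    s = spec.step_samples(sample_rate)
    n = window_count(segment.shape[-1], w, s)
    starts = np.arange(n) * s
    # (channels, n, w) strided view would also work; explicit gather is clear
    idx = starts[:, None] + np.arange(w)[None, :]
    sq = segment[:, idx] ** 2  # (channels, n, w)
    values = np.sqrt(sq.mean(axis=-1))
    times = (starts + w / 2.0) / sample_rate
    return RmsSeries(values=values, window_times=times)


def trial_rms(
    trial: TrialRecording,
    acquisition: AcquisitionSpec,
    spec: WindowingSpec,
    channels: slice | None = None,
) -> RmsSeries:
    """Condition one trial and return its hold-phase window RMS."""
    emg = trial.emg if channels is None else trial.emg[channels]
    filtered = preprocess_emg(emg, acquisition)
    a, b = select_hold_segment(trial, spec)
    return rms_windows(filtered[:, a:b], trial.sample_rate, spec)


def grand_average_map(
    session: Session,
    posture: str,
    grid: str,
    spec: WindowingSpec | None = None,
) -> IsoPotentialMap:
    """Per-channel mean window RMS over all windows and repetitions."""
    spec = spec or WindowingSpec()
    sl = session.channel_slice(grid)
    layout = session.layout(grid)
    sums = np.zeros(layout.n_channels)
    count = 0
    for trial in session.trials:
        if trial.posture != posture:
            continue
        series = trial_rms(trial, session.acquisition, spec, channels=sl)
        sums += series.values.mean(axis=1)
        count += 1
    if count == 0:
        raise ValueError(f"session has no trials for posture {posture!r}")
    return IsoPotentialMap(
        grid=grid,
        posture=posture,
        mean_rms_per_channel=sums / count,
        layout=layout,
    )


def iso_map_to_frame(iso: IsoPotentialMap):
    """Iso-potential map as a (site row, site col, value) table for export."""
    import pandas as pd

    rc = iso.layout.site_rows_cols
    return pd.DataFrame(
        {
            "electrode_row": rc[:, 0],
            "electrode_col": rc[:, 1],
            "mean_rms": iso.mean_rms_per_channel,
        }
    )
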