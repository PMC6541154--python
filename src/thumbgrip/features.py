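"""Labeled feature vectors, channel-influence equalization and splits.

One feature vector (FV) per (electrode, trial): the sequence of window RMS
values from that electrode during that repetition's isometric hold (11 values
under the default windowing).  With 64 active sites and 30 repetitions per
posture this yields 1,920 FVs per posture and 7,680 per grid.

Channel influence is equalized by dividing every channel's values by that
channel's maximum window RMS over a designated set of fitting rows (the
training rows), so no electrode dominates the clustering by raw amplitude;
the factors are frozen and reapplied unchanged to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import WindowingSpec, trial_rms
from .simulate import POSTURES, Session

__all__ = [
    "FeatureTable",
    "SplitSpec",
    "ClusterSpread",
    "DegenerateChannelError",
    "build_feature_vectors",
    "normalize_per_channel",
    "apply_channel_scale",
    "pairwise_cluster_spread",
    "split",
    "write_feature_csv",
    "read_feature_csv",
]

_META_COLS = ["grid", "electrode", "electrode_row", "electrode_col", "trial", "posture"]


class DegenerateChannelError(ValueError):
    """A channel's fitting rows are all zero; no scale factor exists."""


def window_cols(n: int) -> list[str]:
    return [f"w{i + 1:02d}" for i in range(n)]


@dataclass(frozen=True)
class FeatureTable:
    """FVs as a DataFrame plus (optional) frozen per-channel scale factors.

    ``frame`` columns: grid, electrode, electrode_row, electrode_col, trial,
    posture, w01..wNN.  ``scale`` is indexed by electrode id.
    """

    frame: pd.DataFrame
    scale: pd.Series | None = None

    @property
    def window_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("w")]

    @property
    def matrix(self) -> np.ndarray:
        return self.frame[self.window_columns].to_numpy(float)

    @property
    def postures(self) -> np.ndarray:
        return self.frame["posture"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SplitSpec:
    """Stratified, seeded partition into len(fractions) disjoint parts."""

    fractions: tuple[float, ...]
    seed: int = 0
    stratify_by: str = "posture"

    def __post_init__(self) -> None:
        if any(not (0 < f < 1) for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


def build_feature_vectors(
    session: Session, grid: str, spec: WindowingSpec | None = None
) -> FeatureTable:
    """One FV per (electrode, trial) of ``grid``, labels carried through."""
    if not session.trials:
        raise ValueError("session contains no trials")
    spec = spec or WindowingSpec()
    sl = session.channel_slice(grid)
    layout = session.layout(grid)
    rc = layout.site_rows_cols
    n_ch = layout.n_channels
    rows_meta = []
    values = []
    for t_idx, trial in enumerate(session.trials):
        series = trial_rms(trial, session.acquisition, spec, channels=sl)
        values.append(series.values)
        for e in range(n_ch):
            rows_meta.append((grid, e, rc[e, 0], rc[e, 1], t_idx, trial.posture))
    vals = np.vstack(values)
    frame = pd.DataFrame(rows_meta, columns=_META_COLS)
    for j, col in enumerate(window_cols(vals.shape[1])):
        frame[col] = vals[:, j]
    return FeatureTable(frame=frame)


def normalize_per_channel(table: FeatureTable, fit_rows: np.ndarray) -> FeatureTable:
    """Divide each channel by its maximum window RMS over ``fit_rows``.

    ``fit_rows`` are positional row indices (typically the training part of a
    split, so held-out rows never leak into the statistics).  The factors are
    stored on the returned table and can be re-applied to new rows with
    :func:`apply_channel_scale`.
    """
    fit_rows = np.asarray(fit_rows, int)
    if fit_rows.size == 0:
        raise ValueError("fit_rows is empty")
    wcols = table.window_columns
    fit = table.frame.iloc[fit_rows]
    missing = set(table.frame["electrode"]) - set(fit["electrode"])
    if missing:
        raise ValueError(f"no fit rows for electrodes {sorted(missing)}")
    scale = fit.groupby("electrode")[wcols].max().max(axis=1)
    zero = scale[scale <= 0]
    if len(zero):
        e = int(zero.index[0])
        row, col = table.frame.loc[table.frame["electrode"] == e].iloc[0][
            ["electrode_row", "electrode_col"]
        ]
        raise DegenerateChannelError(
            f"channel {e} (site row {row}, col {col}) has all-zero fit rows"
        )
    return apply_channel_scale(table, scale)


def apply_channel_scale(table: FeatureTable, scale: pd.Series) -> FeatureTable:
    """Apply frozen per-channel factors to every row of ``table``."""
    wcols = table.window_columns
    frame = table.frame.copy()
    factors = frame["electrode"].map(scale).to_numpy(float)
    if np.any(~np.isfinite(factors)):
        raise ValueError("scale is missing factors for some electrodes")
    frame[wcols] = frame[wcols].to_numpy(float) / factors[:, None]
    return FeatureTable(frame=frame, scale=scale)


@dataclass(frozen=True)
class ClusterSpread:
    """Dispersion summary of two posture clusters in feature space."""

    posture_a: str
    posture_b: str
    centroid_distance: float
    dispersion_a: float  # RMS distance of class-a FVs to their centroid
    dispersion_b: float
    mean_amplitude_a: float
    mean_amplitude_b: float


def pairwise_cluster_spread(
    table: FeatureTable, posture_a: str, posture_b: str
) -> ClusterSpread:
    """Within-class dispersion and between-class centroid distance."""
    X = table.matrix
    y = table.postures
    out = {}
    for p in (posture_a, posture_b):
        mask = y == p
        if not mask.any():
            raise ValueError(f"no feature vectors for posture {p!r}")
        pts = X[mask]
        centroid = pts.mean(axis=0)
        out[p] = (
            centroid,
            float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean())),
            float(pts.mean()),
        )
    ca, da, ma = out[posture_a]
    cb, db, mb = out[posture_b]
    return ClusterSpread(
        posture_a=posture_a,
        posture_b=posture_b,
        centroid_distance=float(np.linalg.norm(ca - cb)),
        dispersion_a=da,
        dispersion_b=db,
        mean_amplitude_a=ma,
        mean_amplitude_b=mb,
    )


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    ideal = [n * f for f in fractions]
    base = [int(np.floor(v)) for v in ideal]
    short = n - sum(base)
    order = sorted(
        range(len(fractions)), key=lambda k: (-(ideal[k] - base[k]), k)
    )
    for k in order[:short]:
        base[k] += 1
    return base


def split(table: FeatureTable, spec: SplitSpec) -> tuple[np.ndarray, ...]:
    """Seeded stratified partition; returns positional row-index arrays.

    Sizes within each stratum are fixed by largest-remainder allocation, so
    the partition sizes are deterministic functions of the counts alone.
    """
    rng = np.random.default_rng(spec.seed)
    strata = table.frame.groupby(spec.stratify_by, sort=True).indices
    parts: list[list[np.ndarray]] = [[] for _ in spec.fractions]
    for label in sorted(strata):
        idx = np.asarray(strata[label], int)
        if len(idx) < len(spec.fractions):
            raise ValueError(
                f"stratum {label!r} has {len(idx)} rows, fewer than the "
                f"{len(spec.fractions)} parts"
            )
        sizes = _largest_remainder(len(idx), spec.fractions)
        perm = rng.permutation(idx)
        pos = 0
        for k, size in enumerate(sizes):
            parts[k].append(perm[pos : pos + size])
            pos += size
    return tuple(np.sort(np.concatenate(p)) for p in parts)


def trial_disjoint_split(
    table: FeatureTable, fractions: tuple[float, ...], seed: int = 0
) -> tuple[np.ndarray, ...]:
    """Partition FVs so that all 64 FVs of a repetition stay together.

    The protocol's splits operate on individual FVs, so the FVs of one
    repetition can land on both sides of a split; because they share
    trial-level variability (force-tracking jitter, common-mode noise), that
    leaks repetition identity across splits.  This control partitions whole
    repetitions instead (stratified by posture over trials), eliminating the
    leak at the cost of coarser split sizes.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    frame = table.frame
    parts: list[list[np.ndarray]] = [[] for _ in fractions]
    trials_by_posture = frame.groupby("posture")["trial"].unique()
    for posture in sorted(trials_by_posture.index):
        trials = np.sort(trials_by_posture[posture])
        if len(trials) < len(fractions):
            raise ValueError(
                f"posture {posture!r} has {len(trials)} trials, fewer than "
                f"the {len(fractions)} parts"
            )
        sizes = _largest_remainder(len(trials), tuple(fractions))
        perm = rng.permutation(trials)
        pos = 0
        for k, size in enumerate(sizes):
            chosen = set(perm[pos : pos + size])
            mask = (frame["posture"] == posture) & frame["trial"].isin(chosen)
            parts[k].append(np.where(mask.to_numpy())[0])
            pos += size
    return tuple(np.sort(np.concatenate(p)) for p in parts)


def write_feature_csv(table: FeatureTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> FeatureTable:
    frame = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature CSV is missing columns {missing}")
    return FeatureTable(frame=frame)
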