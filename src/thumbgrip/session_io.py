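"""Session directory serialization.

Layout: one directory per session containing ``session.json`` (layouts,
acquisition, protocol, noise model, seeds and the trial index) plus one
matrix file per trial.  The storage format of the matrices is declared in the
metadata: ``bin`` stores channels x samples float32 row-major with the force
trace appended as one extra row; ``csv`` stores the same (channels + 1) x
samples matrix as plain text.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .simulate import (
    AcquisitionSpec,
    ForceProfile,
    GridLayout,
    NoiseModel,
    PostureAmplitudeMap,
    Session,
    TrialRecording,
)

__all__ = ["SessionFormatError", "write_session", "read_session"]

_FORMAT_VERSION = 1


class SessionFormatError(ValueError):
    """Raised when a session directory is missing or malformed."""


def _layout_to_dict(lay: GridLayout) -> dict:
    return {
        "rows": lay.rows,
        "cols": lay.cols,
        "ied_mm": lay.ied_mm,
        "region": lay.region,
        "active_sites": [list(s) for s in lay.active_sites],
    }


def _layout_from_dict(d: dict) -> GridLayout:
    return GridLayout(
        rows=int(d["rows"]),
        cols=int(d["cols"]),
        ied_mm=float(d["ied_mm"]),
        region=str(d["region"]),
        active_sites=tuple(
            (int(r), int(c), float(x), float(y)) for r, c, x, y in d["active_sites"]
        ),
    )


def _map_to_dict(m: PostureAmplitudeMap) -> dict:
    return {
        "posture": m.posture,
        "region": m.region,
        "gain_per_channel": [float(g) for g in m.gain_per_channel],
        "source_centers": [list(c) for c in m.source_centers],
        "source_widths_mm": list(m.source_widths_mm),
    }


def _map_from_dict(d: dict) -> PostureAmplitudeMap:
    return PostureAmplitudeMap(
        posture=str(d["posture"]),
        region=str(d["region"]),
        gain_per_channel=np.asarray(d["gain_per_channel"], float),
        source_centers=tuple(tuple(float(v) for v in c) for c in d["source_centers"]),
        source_widths_mm=tuple(float(w) for w in d["source_widths_mm"]),
    )


def write_session(session: Session, path: str | Path, storage: str = "bin") -> None:
    """Write ``session`` to directory ``path`` (created if absent)."""
    if storage not in ("bin", "csv"):
        raise ValueError(f"storage must be 'bin' or 'csv', got {storage!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = []
    for i, trial in enumerate(session.trials):
        fname = f"trial_{i:03d}.{storage}"
        stacked = np.vstack(
            [trial.emg.astype(np.float32), trial.force.astype(np.float32)[None, :]]
        )
        if storage == "bin":
            stacked.tofile(path / fname)
        else:
            np.savetxt(path / fname, stacked, delimiter=",", fmt="%.7e")
        index.append(
            {
                "file": fname,
                "posture": trial.posture,
                "seed": trial.seed,
                "hold_interval": list(trial.hold_interval),
                "rest_pre_s": trial.rest_pre_s,
                "n_channels": trial.n_channels,
                "n_samples": trial.n_samples,
            }
        )
    meta = {
        "format_version": _FORMAT_VERSION,
        "storage": storage,
        "layouts": [_layout_to_dict(lay) for lay in session.layouts],
        "acquisition": asdict(session.acquisition),
        "protocol": asdict(session.protocol),
        "noise": asdict(session.noise),
        "posture_order": list(session.posture_order),
        "master_seed": session.master_seed,
        "effect_scale": session.effect_scale,
        "amplitude_maps": {
            region: [_map_to_dict(m) for m in maps]
            for region, maps in session.amplitude_maps.items()
        },
        "trials": index,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _require(meta: dict, key: str) -> object:
    if key not in meta:
        raise SessionFormatError(f"session.json is missing required field {key!r}")
    return meta[key]


def read_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.is_file():
        raise SessionFormatError(f"missing metadata file {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"session.json is not valid JSON: {exc}") from exc

    storage = _require(meta, "storage")
    if storage not in ("bin", "csv"):
        raise SessionFormatError(f"unknown storage format {storage!r}")
    layouts = tuple(_layout_from_dict(d) for d in _require(meta, "layouts"))
    if len(layouts) != 2:
        raise SessionFormatError("field 'layouts' must list exactly two grids")
    acquisition = AcquisitionSpec(**_require(meta, "acquisition"))
    proto = dict(_require(meta, "protocol"))
    proto["rest_range_s"] = tuple(proto["rest_range_s"])
    protocol = ForceProfile(**proto)
    noi = dict(_require(meta, "noise"))
    noi["carrier_band_hz"] = tuple(noi["carrier_band_hz"])
    noise = NoiseModel(**noi)
    amplitude_maps = {
        region: tuple(_map_from_dict(d) for d in maps)
        for region, maps in _require(meta, "amplitude_maps").items()
    }

    trials = []
    for entry in _require(meta, "trials"):
        for key in ("file", "posture", "seed", "hold_interval", "n_channels", "n_samples"):
            if key not in entry:
                raise SessionFormatError(f"trial index entry missing field {key!r}")
        fpath = path / entry["file"]
        if not fpath.is_file():
            raise SessionFormatError(f"missing trial file {fpath}")
        n_ch, n_s = int(entry["n_channels"]), int(entry["n_samples"])
        if storage == "bin":
            data = np.fromfile(fpath, dtype=np.float32)
        else:
            data = np.loadtxt(fpath, delimiter=",", dtype=np.float32).ravel()
        if data.size != (n_ch + 1) * n_s:
            raise SessionFormatError(
                f"{fpath.name}: expected {(n_ch + 1) * n_s} values, found {data.size}"
            )
        data = data.reshape(n_ch + 1, n_s)
        trials.append(
            TrialRecording(
                posture=str(entry["posture"]),
                emg=data[:n_ch],
                force=data[n_ch],
                sample_rate=acquisition.sample_rate,
                hold_interval=tuple(int(v) for v in entry["hold_interval"]),
                seed=int(entry["seed"]),
                rest_pre_s=float(entry.get("rest_pre_s", 0.0)),
            )
        )

    return Session(
        trials=tuple(trials),
        layouts=layouts,  # type: ignore[arg-type]
        acquisition=acquisition,
        protocol=protocol,
        noise=noise,
        posture_order=tuple(str(p) for p in _require(meta, "posture_order")),
        master_seed=int(_require(meta, "master_seed")),
        effect_scale=float(_require(meta, "effect_scale")),
        amplitude_maps=amplitude_maps,
    )
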