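"""End-to-end pipeline: simulate -> preprocess -> features -> SOFM -> MLP.

``run_pipeline`` executes the whole analysis for both electrode grids and
returns a structured report: session summary, iso-potential amplitude maps,
SOFM quality errors, hit histograms, BMU-label confusion matrices, the
supervised training report, and PCA projections of the trained codebooks.
Everything is seeded, so two runs of the same configuration produce
byte-identical report JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import mlp as mlp_mod
from . import sofm as sofm_mod
from .preprocess import WindowingSpec, iso_map_to_frame
from .session_io import write_session
from .simulate import (
    POSTURES,
    REGIONS,
    Session,
    SessionConfig,
    ci_config,
    default_config,
    simulate_session,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "run_grid_analysis"]

log = logging.getLogger("thumbgrip")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one full analysis run."""

    session: SessionConfig
    windowing: WindowingSpec = WindowingSpec()
    som_rows: int = 10
    som_cols: int = 10
    som_schedule: sofm_mod.TrainingSchedule = sofm_mod.TrainingSchedule()
    sofm_fractions: tuple[float, float] = (0.60, 0.40)
    mlp_fractions: tuple[float, float, float] = (0.30, 0.35, 0.35)
    mlp_spec: mlp_mod.MlpSpec = mlp_mod.MlpSpec()
    sofm_split_seed: int = 1
    mlp_split_seed: int = 2
    pca_components: int = 2

    @classmethod
    def default(cls, seed: int = 0, profile: str = "full", effect_scale: float = 1.0):
        maker = default_config if profile == "full" else ci_config
        return cls(
            session=maker(seed=seed, effect_scale=effect_scale),
            mlp_spec=mlp_mod.MlpSpec(seed=seed + 3),
            sofm_split_seed=seed + 1,
            mlp_split_seed=seed + 2,
        )


def run_grid_analysis(
    session: Session,
    grid: str,
    config: PipelineConfig,
    table: feat.FeatureTable | None = None,
) -> dict:
    """The per-grid analysis chain; returns a JSON-ready report section."""
    t0 = time.perf_counter()
    if table is None:
        table = feat.build_feature_vectors(session, grid, config.windowing)
    log.info("[%s] extracted %d feature vectors (%.1fs)", grid, len(table),
             time.perf_counter() - t0)

    iso = {
        posture: {
            "mean_rms_per_channel": [
                float(v)
                for v in table.frame.loc[table.frame["posture"] == posture]
                .groupby("electrode")[table.window_columns]
                .mean()
                .mean(axis=1)
                .sort_index()
                .to_numpy()
            ]
        }
        for posture in POSTURES
    }

    # --- unsupervised arm: 60/40 split, SOFM, errors, BMU classification
    train_idx, test_idx = feat.split(
        table,
        feat.SplitSpec(fractions=config.sofm_fractions, seed=config.sofm_split_seed),
    )
    norm = feat.normalize_per_channel(table, train_idx)
    X = norm.matrix
    y = norm.postures
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]
    som = sofm_mod.init_som(
        config.som_rows, config.som_cols, X.shape[1], "principal-plane", data=Xtr
    )
    initial_errors = sofm_mod.map_errors(som, Xtr)
    som = sofm_mod.train_batch(som, Xtr, config.som_schedule)
    errors = sofm_mod.map_errors(som, Xtr)
    hits = sofm_mod.hit_histogram(som, Xtr, ytr, classes=POSTURES)
    labeled = sofm_mod.label_units(som, hits)
    preds = sofm_mod.classify(labeled, Xte)
    conf, acc = sofm_mod.confusion(preds, yte, classes=POSTURES)
    test_hits = sofm_mod.hit_histogram(som, Xte, yte, classes=POSTURES)

    proj = sofm_mod.project_pca(som.codebook, config.pca_components)
    scores_test = proj.transform(Xte)

    # --- supervised arm: 30/35/35 split, MLP with early stopping
    tr3, va3, te3 = feat.split(
        table,
        feat.SplitSpec(fractions=config.mlp_fractions, seed=config.mlp_split_seed),
    )
    norm3 = feat.normalize_per_channel(table, tr3)
    X3 = norm3.matrix
    y3 = norm3.postures
    model = mlp_mod.train_classifier(
        config.mlp_spec, X3[tr3], y3[tr3], X3[va3], y3[va3], classes=POSTURES
    )
    report = mlp_mod.TrainingReport(
        train=mlp_mod.evaluate(model, X3[tr3], y3[tr3]),
        validation=mlp_mod.evaluate(model, X3[va3], y3[va3]),
        test=mlp_mod.evaluate(model, X3[te3], y3[te3]),
    )
    log.info(
        "[%s] SOFM test accuracy %.1f%%, MLP test accuracy %.1f%% (%.1fs)",
        grid, 100 * acc, report.test.accuracy_pct, time.perf_counter() - t0,
    )

    def _metrics(m: mlp_mod.SplitMetrics) -> dict:
        return {
            "n": m.n,
            "cross_entropy": m.cross_entropy,
            "error_pct": m.error_pct,
            "accuracy_pct": m.accuracy_pct,
            "misclassification_pct": m.misclassification_pct,
            "confusion": m.confusion.to_numpy().tolist(),
        }

    return {
        "n_feature_vectors": len(table),
        "n_vectors_per_posture": {
            p: int((table.postures == p).sum()) for p in POSTURES
        },
        "n_windows": len(table.window_columns),
        "iso_maps": iso,
        "sofm": {
            "map_rows": config.som_rows,
            "map_cols": config.som_cols,
            "n_train": int(len(train_idx)),
            "n_test": int(len(test_idx)),
            "initial_quantization_error": initial_errors.quantization,
            "errors": {
                "quantization": errors.quantization,
                "topographic": errors.topographic,
                "combined": errors.combined,
            },
            "hit_histogram_train": hits.counts.tolist(),
            "hit_histogram_test": test_hits.counts.tolist(),
            "test_accuracy_pct": 100.0 * acc,
            "confusion": conf.to_numpy().tolist(),
            "confusion_classes": list(POSTURES),
        },
        "pca": {
            "explained_variance_ratio": [float(v) for v in proj.explained_variance_ratio],
            "codebook_scores": proj.scores.tolist(),
            "test_scores_mean_per_class": {
                p: [float(v) for v in scores_test[yte == p].mean(axis=0)]
                for p in POSTURES
            },
        },
        "supervised": {
            "objective": config.mlp_spec.objective,
            "splits": {
                "train": _metrics(report.train),
                "validation": _metrics(report.validation),
                "test": _metrics(report.test),
            },
            "confusion_classes": list(POSTURES),
        },
    }


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    session: Session | None = None,
) -> dict:
    """Run the full analysis; optionally write the report bundle to disk."""
    t0 = time.perf_counter()
    if session is None:
        session = simulate_session(config.session)
    log.info(
        "simulated session: %d trials, %d channels (%.1fs)",
        len(session.trials), session.trials[0].n_channels, time.perf_counter() - t0,
    )
    report = {
        "session": {
            "n_trials": len(session.trials),
            "trials_per_posture": {
                p: int(sum(t.posture == p for t in session.trials)) for p in POSTURES
            },
            "sample_rate_hz": session.acquisition.sample_rate,
            "master_seed": session.master_seed,
            "effect_scale": session.effect_scale,
        },
        "grids": {},
    }
    for grid in REGIONS:
        report["grids"][grid] = run_grid_analysis(session, grid, config)
    if out_dir is not None:
        _write_bundle(report, config, out_dir)
    return report


def _write_bundle(report: dict, config: PipelineConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "resolved_config.json").write_text(
        json.dumps(_config_summary(config), indent=2, sort_keys=True)
    )
    for grid, section in report["grids"].items():
        for posture, iso in section["iso_maps"].items():
            pd.DataFrame({"mean_rms": iso["mean_rms_per_channel"]}).to_csv(
                out / f"iso_map_{grid}_{posture}.csv", index_label="electrode"
            )
        pd.DataFrame(
            section["sofm"]["confusion"],
            index=section["sofm"]["confusion_classes"],
            columns=section["sofm"]["confusion_classes"],
        ).to_csv(out / f"sofm_confusion_{grid}.csv")
        pd.DataFrame(
            section["supervised"]["splits"]["test"]["confusion"],
            index=section["supervised"]["confusion_classes"],
            columns=section["supervised"]["confusion_classes"],
        ).to_csv(out / f"mlp_confusion_{grid}.csv")
        errs = section["sofm"]["errors"]
        pd.DataFrame([errs]).to_csv(out / f"sofm_errors_{grid}.csv", index=False)


def _config_summary(config: PipelineConfig) -> dict:
    sc = config.session
    return {
        "master_seed": sc.master_seed,
        "effect_scale": sc.effect_scale,
        "trials_per_posture": sc.trials_per_posture,
        "sample_rate_hz": sc.acquisition.sample_rate,
        "band_hz": [sc.acquisition.band_lo, sc.acquisition.band_hi],
        "notch_base_hz": sc.acquisition.notch_base,
        "n_harmonics": sc.acquisition.n_harmonics,
        "hold_s": sc.protocol.hold_s,
        "mvc_fraction": sc.protocol.mvc_fraction,
        "rest_range_s": list(sc.protocol.rest_range_s),
        "window_ms": config.windowing.window_ms,
        "step_ms": config.windowing.step_ms,
        "segment_s": config.windowing.segment_s,
        "som_rows": config.som_rows,
        "som_cols": config.som_cols,
        "som_schedule": [list(p) for p in config.som_schedule.phases],
        "sofm_fractions": list(config.sofm_fractions),
        "mlp_fractions": list(config.mlp_fractions),
        "mlp_hidden_units": config.mlp_spec.hidden_units,
        "mlp_objective": config.mlp_spec.objective,
        "sofm_split_seed": config.sofm_split_seed,
        "mlp_split_seed": config.mlp_split_seed,
    }


def make_fixture(
    profile: str, out_dir: str | Path, seed: int = 0, storage: str = "bin"
) -> Session:
    """Write a ready-made session to disk: ``full`` protocol or fast ``ci``."""
    if profile == "full":
        cfg = default_config(seed=seed)
    elif profile == "ci":
        cfg = ci_config(seed=seed)
    else:
        raise ValueError(f"unknown fixture profile {profile!r}")
    session = simulate_session(cfg)
    write_session(session, out_dir, storage=storage)
    return session
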