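"""Generator tests: grid geometry, amplitude maps, trials, sessions, I/O."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import ks_2samp

from thumbgrip.session_io import SessionFormatError, read_session, write_session
from thumbgrip.simulate import (
    POSTURES,
    AcquisitionSpec,
    ForceProfile,
    NoiseModel,
    PostureAmplitudeMap,
    build_grid_layout,
    make_posture_amplitude_maps,
    simulate_session,
    simulate_trial,
)

from conftest import micro_config


class TestGridLayout:
    @pytest.mark.parametrize(
        "rows, cols, mask, expected",
        [(13, 5, True, 64), (1, 1, False, 1), (2, 2, False, 4), (13, 5, False, 65)],
    )
    def test_active_site_count(self, rows, cols, mask, expected):
        lay = build_grid_layout(rows, cols, 8.0, mask_corner=mask, region="anterior")
        assert lay.n_channels == expected

    def test_single_site_at_origin(self):
        lay = build_grid_layout(1, 1, 8.0, mask_corner=False, region="anterior")
        assert lay.active_sites == ((0, 0, 0.0, 0.0),)

    def test_nearest_neighbor_spacing_and_uniqueness(self):
        lay = build_grid_layout(2, 2, 8.0, mask_corner=False, region="anterior")
        pts = lay.coords_mm
        d = pdist(pts)
        # every site's nearest neighbor at exactly the inter-electrode distance
        full = np.full((4, 4), np.inf)
        full[np.triu_indices(4, 1)] = d
        full = np.minimum(full, full.T)
        assert np.allclose(full.min(axis=1), 8.0)
        assert len({tuple(p) for p in pts}) == 4

    def test_masked_corner_is_row1_col1(self):
        lay = build_grid_layout(13, 5, 8.0, mask_corner=True, region="posterior")
        assert (0, 0) not in {(r, c) for r, c, _, _ in lay.active_sites}

    @pytest.mark.parametrize("rows, cols, ied", [(0, 5, 8.0), (13, 0, 8.0), (13, 5, -1.0)])
    def test_invalid_dimensions_raise(self, rows, cols, ied):
        with pytest.raises(ValueError):
            build_grid_layout(rows, cols, ied, region="anterior")


@pytest.fixture(scope="module")
def layout():
    return build_grid_layout(13, 5, 8.0, mask_corner=True, region="posterior")


class TestAmplitudeMaps:

    def test_null_effect_gives_identical_maps(self, layout):
        maps = make_posture_amplitude_maps(layout, effect_scale=0.0, seed=4)
        base = maps[0].gain_per_channel
        for m in maps[1:]:
            assert np.max(np.abs(m.gain_per_channel - base)) == 0.0

    def test_posterior_mean_gain_decreases_p1_to_p4(self, layout):
        maps = make_posture_amplitude_maps(layout, seed=4)
        means = [m.gain_per_channel.mean() for m in maps]
        assert means[0] > means[1] > means[2] > means[3]

    def test_source_centers_shared_across_postures(self, layout):
        maps = make_posture_amplitude_maps(layout, seed=4)
        for m in maps[1:]:
            assert m.source_centers == maps[0].source_centers

    def test_per_source_peak_channel_fixed_across_postures(self, layout):
        # amplitude-only modulation: near each source, the strongest channel
        # never moves with posture
        maps = make_posture_amplitude_maps(layout, seed=4)
        coords = layout.coords_mm
        for s, (cx, cy) in enumerate(maps[0].source_centers):
            sigma = maps[0].source_widths_mm[s]
            near = np.where(np.hypot(coords[:, 0] - cx, coords[:, 1] - cy) < 1.5 * sigma)[0]
            peaks = {int(near[np.argmax(m.gain_per_channel[near])]) for m in maps}
            assert len(peaks) == 1

    def test_gain_homogeneity(self, layout):
        maps = make_posture_amplitude_maps(layout, seed=4)
        scaled = dataclasses.replace(maps[0], gain_per_channel=3.0 * maps[0].gain_per_channel)
        assert np.allclose(scaled.gain_per_channel, 3.0 * maps[0].gain_per_channel)

    def test_negative_effect_scale_raises(self, layout):
        with pytest.raises(ValueError):
            make_posture_amplitude_maps(layout, effect_scale=-0.1)

    def test_negative_gains_rejected(self, layout):
        with pytest.raises(ValueError):
            PostureAmplitudeMap(
                posture="P1",
                region="posterior",
                gain_per_channel=np.array([-1.0]),
                source_centers=((0.0, 0.0),),
                source_widths_mm=(12.0,),
            )


class TestAcquisitionSpec:
    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(sample_rate=512.0, band_hi=900.0)

    def test_harmonic_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(sample_rate=512.0, band_hi=220.0, n_harmonics=7)


def _micro_pieces(cfg):
    maps = {
        lay.region: make_posture_amplitude_maps(lay, cfg.effect_scale, seed=9)
        for lay in cfg.layouts
    }
    return cfg.layouts, maps, cfg.acquisition, cfg.protocol, cfg.noise


class TestSimulateTrial:
    def test_hold_interval_length_full_protocol(self):
        cfg = micro_config()
        layouts, maps, _, _, noise = _micro_pieces(cfg)
        trial = simulate_trial(
            layouts, maps, AcquisitionSpec(), ForceProfile(), "P1", seed=3, noise=NoiseModel()
        )
        a, b = trial.hold_interval
        assert b - a == 10240  # 5 s at 2,048 samples/s

    def test_seeded_determinism(self):
        cfg = micro_config()
        layouts, maps, acq, proto, noise = _micro_pieces(cfg)
        t1 = simulate_trial(layouts, maps, acq, proto, "P2", seed=17, noise=noise)
        t2 = simulate_trial(layouts, maps, acq, proto, "P2", seed=17, noise=noise)
        assert np.array_equal(t1.emg, t2.emg)
        assert np.array_equal(t1.force, t2.force)

    def test_zero_gain_hold_variance_is_baseline(self):
        cfg = micro_config()
        layouts, _, acq, proto, _ = _micro_pieces(cfg)
        sigma0 = 0.02
        zero_maps = {
            lay.region: tuple(
                PostureAmplitudeMap(
                    posture=p,
                    region=lay.region,
                    gain_per_channel=np.zeros(lay.n_channels),
                    source_centers=((0.0, 0.0),),
                    source_widths_mm=(12.0,),
                )
                for p in POSTURES
            )
            for lay in layouts
        }
        noise = NoiseModel(
            carrier_band_hz=(20.0, 100.0), baseline_noise_mv=sigma0,
            common_mode_fraction=0.0, line_amp_mv=0.0,
        )
        trial = simulate_trial(layouts, zero_maps, acq, proto, "P1", seed=8, noise=noise)
        a, b = trial.hold_interval
        hold = trial.emg[:, a:b].astype(float)
        n_total = hold.size
        est = hold.var()
        tol = 3.0 * sigma0**2 * np.sqrt(2.0 / n_total)
        assert abs(est - sigma0**2) <= tol

    def test_hold_rms_proportional_to_gain(self):
        cfg = micro_config()
        layouts, maps, acq, proto, _ = _micro_pieces(cfg)
        noise = NoiseModel(
            carrier_band_hz=(20.0, 100.0), baseline_noise_mv=0.0,
            common_mode_fraction=0.0, line_amp_mv=0.0, force_jitter=0.0,
        )
        trial = simulate_trial(layouts, maps, acq, proto, "P1", seed=12, noise=noise)
        a, b = trial.hold_interval
        rms = np.sqrt((trial.emg[:, a:b].astype(float) ** 2).mean(axis=1))
        gains = np.concatenate(
            [maps[lay.region][0].gain_per_channel for lay in layouts]
        )
        ratio = rms / gains
        assert ratio.std() / ratio.mean() < 0.2

    def test_unknown_posture_raises(self):
        cfg = micro_config()
        layouts, maps, acq, proto, noise = _micro_pieces(cfg)
        with pytest.raises(ValueError):
            simulate_trial(layouts, maps, acq, proto, "P9", seed=1, noise=noise)

    def test_carrier_band_beyond_nyquist_raises(self):
        cfg = micro_config()
        layouts, maps, acq, proto, _ = _micro_pieces(cfg)
        bad = NoiseModel(carrier_band_hz=(20.0, 200.0))  # fs = 256
        with pytest.raises(ValueError):
            simulate_trial(layouts, maps, acq, proto, "P1", seed=1, noise=bad)


class TestSimulateSession:
    def test_trial_counts(self, ci_session):
        assert len(ci_session.trials) == 32
        for p in POSTURES:
            assert sum(t.posture == p for t in ci_session.trials) == 8

    def test_rests_within_protocol_range(self, ci_session):
        lo, hi = ci_session.protocol.rest_range_s
        for t in ci_session.trials:
            assert lo <= t.rest_pre_s <= hi

    def test_posture_order_deterministic(self):
        cfg = micro_config(seed=33)
        s1 = simulate_session(cfg)
        s2 = simulate_session(cfg)
        assert s1.posture_order == s2.posture_order
        assert np.array_equal(s1.trials[0].emg, s2.trials[0].emg)

    def test_posture_order_is_shuffled_permutation(self, ci_session):
        order = ci_session.posture_order
        assert sorted(order) == sorted(POSTURES * 8)
        assert order != tuple(sorted(order))  # randomized, not blocked


class TestNullDistributions:
    def test_hold_rms_distribution_identical_across_postures(self, ci_null_session):
        """With effect_scale = 0 the per-channel hold RMS has the same law
        for every posture (two-sample KS, 1% level, aggregated)."""
        session = ci_null_session
        rms = {p: [] for p in POSTURES}
        for t in session.trials:
            a, b = t.hold_interval
            rms[t.posture].append(
                np.sqrt((t.emg[:, a:b].astype(float) ** 2).mean(axis=1))
            )
        rms = {p: np.array(v) for p, v in rms.items()}  # (trials, channels)
        n_ch = rms["P1"].shape[1]
        rejections = 0
        total = 0
        pairs = [("P1", "P2"), ("P1", "P3"), ("P1", "P4"), ("P2", "P3"), ("P2", "P4"), ("P3", "P4")]
        for pa, pb in pairs:
            for c in range(n_ch):
                total += 1
                if ks_2samp(rms[pa][:, c], rms[pb][:, c]).pvalue < 0.01:
                    rejections += 1
        # expected ~1% under the null; bound leaves room for dependence
        assert rejections <= max(10, int(0.04 * total))


class TestSessionIO:
    def test_bin_round_trip(self, micro_session, tmp_path):
        write_session(micro_session, tmp_path / "s", storage="bin")
        back = read_session(tmp_path / "s")
        assert len(back.trials) == len(micro_session.trials)
        assert back.posture_order == micro_session.posture_order
        assert back.acquisition == micro_session.acquisition
        assert back.protocol == micro_session.protocol
        for a, b in zip(micro_session.trials, back.trials):
            assert a.posture == b.posture
            assert a.hold_interval == b.hold_interval
            assert np.max(np.abs(a.emg - b.emg)) <= 1e-6
            assert np.max(np.abs(a.force - b.force)) <= 1e-6

    def test_csv_round_trip(self, tmp_path):
        session = simulate_session(micro_config(seed=5, trials_per_posture=1))
        write_session(session, tmp_path / "s", storage="csv")
        back = read_session(tmp_path / "s")
        for a, b in zip(session.trials, back.trials):
            assert np.max(np.abs(a.emg - b.emg)) <= 1e-6

    def test_missing_metadata_raises(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(SessionFormatError, match="session.json"):
            read_session(tmp_path / "empty")

    def test_missing_field_named_in_error(self, micro_session, tmp_path):
        write_session(micro_session, tmp_path / "s")
        meta = json.loads((tmp_path / "s" / "session.json").read_text())
        del meta["posture_order"]
        (tmp_path / "s" / "session.json").write_text(json.dumps(meta))
        with pytest.raises(SessionFormatError, match="posture_order"):
            read_session(tmp_path / "s")

    def test_missing_trial_file_raises(self, micro_session, tmp_path):
        write_session(micro_session, tmp_path / "s")
        (tmp_path / "s" / "trial_000.bin").unlink()
        with pytest.raises(SessionFormatError, match="trial_000"):
            read_session(tmp_path / "s")
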