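"""Synthetic time-lapse generator: kinetics, motion, rendering, I/O."""

import json

import numpy as np
import pytest

from focidyn.kinetics import smooth_series
from focidyn.synthetic import (
    SimulationConfig,
    TimeLapseStack,
    kinetic_profile,
    render_stack,
    simulate_confined_tracks,
    simulate_kinetics,
    simulate_nucleus,
)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(rc_true=0.0),
        dict(rc_true=-1.0),
        dict(Dc_true=-0.1),
        dict(n_frames=1),
        dict(merge_rate=-0.1),
        dict(condition="gamma"),
        dict(bleach_slope=-10.0),  # drives intensity below zero within 75 min
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_condition_defaults_resolve(self):
        cfg = SimulationConfig(condition="alpha")
        assert cfg.anchors == (6.4, 8.1, 11.0, 6.9)
        assert cfg.Dc > SimulationConfig(condition="mixed").Dc

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(condition="xray", seed=42, Dc_true=0.02)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg


class TestKinetics:
    def test_profile_hits_anchors(self):
        for cond in ("alpha", "xray", "mixed"):
            cfg = SimulationConfig(condition=cond)
            prof = kinetic_profile(cfg)
            initial, peak, tp, final = cfg.anchors
            assert prof[0] == pytest.approx(initial)
            assert prof[int(tp)] == pytest.approx(peak)
            assert prof[-1] == pytest.approx(final, abs=1e-6)
            assert int(np.argmax(prof)) == int(tp)

    def test_control_profile_flat(self):
        prof = kinetic_profile(SimulationConfig(condition="control"))
        assert np.allclose(prof, 1.5)

    def test_frozen_count_without_births_and_deaths(self):
        cfg = SimulationConfig(condition="control", initial_foci=3,
                               focus_birth_rate=0.0, focus_lifetime_mean=np.inf)
        counts = simulate_kinetics(cfg)
        assert np.all(counts == 3)

    def test_counts_nonnegative_integers(self):
        counts = simulate_kinetics(SimulationConfig(condition="xray", seed=2))
        assert counts.dtype.kind == "i"
        assert np.all(counts >= 0)

    def test_control_long_run_mean(self):
        # reported control level: 1.5 foci per cell on average
        counts = np.stack([
            simulate_kinetics(SimulationConfig(condition="control", seed=s))
            for s in range(30)
        ])
        assert counts.mean() == pytest.approx(1.5, abs=0.3)

    def test_xray_peak_frame_recovered(self):
        # 25 nuclei as recorded per condition; peak within +-3 min of 16
        counts = np.stack([
            simulate_kinetics(SimulationConfig(condition="xray", seed=s))
            for s in range(25)
        ])
        peak = int(np.argmax(smooth_series(counts.mean(axis=0))))
        assert abs(peak - 16) <= 3


class TestConfinedTracks:
    def test_frozen_limit(self):
        cfg = SimulationConfig(condition="control", Dc_true=0.0, rc_true=0.5, seed=1)
        tracks = simulate_confined_tracks(5, cfg)
        assert np.allclose(tracks, tracks[:, :1, :])

    def test_unconfined_limit_matches_free_diffusion(self):
        # rc >> displacement: MSD at short lags ~ 2*d*Dc*dt
        cfg = SimulationConfig(condition="control", Dc_true=0.05, rc_true=50.0, seed=2)
        tracks = simulate_confined_tracks(4000, cfg)
        step = tracks[:, 1, :] - tracks[:, 0, :]
        msd1 = np.mean(np.sum(step**2, axis=1))
        assert msd1 == pytest.approx(4 * 0.05, rel=0.05)

    def test_stationary_start(self):
        cfg = SimulationConfig(condition="control", Dc_true=0.01, rc_true=0.6, seed=3)
        tracks = simulate_confined_tracks(5000, cfg)
        # per-dimension stationary SD = rc/2
        assert tracks[:, 0, 0].std() == pytest.approx(0.3, rel=0.05)


class TestRendering:
    def _static_cfg(self, **kw):
        base = dict(condition="control", seed=1, shot_noise=False, read_noise_sd=0.0,
                    merge_rate=0.0, split_rate=0.0, Dc_true=1e-9, initial_foci=1,
                    focus_birth_rate=0.0, focus_lifetime_mean=np.inf)
        base.update(kw)
        return SimulationConfig(**base)

    def test_static_focus_brightest_at_centre(self):
        cfg = self._static_cfg()
        tracks = np.zeros((1, cfg.n_frames, 2))
        stack, _ = render_stack(tracks, np.ones(cfg.n_frames, int), cfg)
        h, w = cfg.image_size
        for t in (0, 37, 74):
            r, c = np.unravel_index(np.argmax(stack.data[t]), (h, w))
            assert abs(r - (h - 1) / 2) <= 0.5 and abs(c - (w - 1) / 2) <= 0.5

    def test_bleach_ratio_matches_control_fade(self):
        cfg = self._static_cfg()
        tracks = np.zeros((1, cfg.n_frames, 2))
        stack, _ = render_stack(tracks, np.ones(cfg.n_frames, int), cfg)
        peak0 = stack.data[0].max() - cfg.camera_offset
        peak74 = stack.data[74].max() - cfg.camera_offset
        assert peak74 / peak0 == pytest.approx(104.6 / 139.3, abs=0.01)

    def test_same_seed_bit_identical(self):
        a, _ = simulate_nucleus(SimulationConfig(condition="alpha", seed=9))
        b, _ = simulate_nucleus(SimulationConfig(condition="alpha", seed=9))
        assert np.array_equal(a.data, b.data)

    def test_clipped_flag_for_edge_focus(self):
        cfg = self._static_cfg(image_size=(64, 64), pixel_size=0.2)
        tracks = np.zeros((1, cfg.n_frames, 2))
        tracks[0, :, 0] = 6.2  # just inside the right edge (centre at 6.3 um)
        _, truth = render_stack(tracks, np.ones(cfg.n_frames, int), cfg)
        assert truth.clipped[0].all()

    def test_track_kinetics_length_mismatch_errors(self):
        cfg = self._static_cfg()
        with pytest.raises(ValueError):
            render_stack(np.zeros((1, 10, 2)), np.ones(cfg.n_frames, int), cfg)


class TestGroundTruth:
    def test_invariants(self, clean_alpha):
        cfg, stack, truth = clean_alpha
        # trajectories stay inside the nucleus disc
        r = np.linalg.norm(truth.positions[truth.alive], axis=-1)
        assert np.all(r <= cfg.nucleus_radius + 1e-9)
        # one transform per frame; event log ordered in time
        assert truth.transforms.shape == (cfg.n_frames, 3)
        frames = [e["frame"] for e in truth.events]
        assert frames == sorted(frames)

    def test_csv_and_json_outputs(self, tmp_path, clean_alpha):
        import pandas as pd

        _, _, truth = clean_alpha
        truth.to_csv(tmp_path / "truth.csv")
        df = pd.read_csv(tmp_path / "truth.csv")
        assert set(df.columns) == {"frame", "id", "x_um", "y_um"}
        assert len(df) == int(truth.alive.sum())
        truth.events_to_json(tmp_path / "events.json")
        events = json.loads((tmp_path / "events.json").read_text())
        assert isinstance(events, list)


class TestStackIO:
    def test_tiff_round_trip(self, tmp_path, clean_alpha):
        _, stack, _ = clean_alpha
        path = tmp_path / "stack.tif"
        stack.to_tiff(path)
        back = TimeLapseStack.from_tiff(path)
        assert back.data.shape == stack.data.shape
        assert back.pixel_size == stack.pixel_size
        # 16-bit quantisation: within half a grey level
        assert np.max(np.abs(back.data - stack.data)) <= 0.5 + 1e-6
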