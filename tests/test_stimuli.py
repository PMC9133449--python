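"""Tests for stimulus generation and controls."""

import numpy as np
import pytest

from avwm import stimuli, tasks
from avwm.architecture import build_network
from avwm.stimuli import (Segment, TonalContour, VisualShape, apply_saliency,
                          drive_energy, make_probe, make_tonal_contour,
                          make_visual_shape, noise_control, degraded_control,
                          pattern_overlap, stimulus_library)


class TestTonalContour:
    def test_single_up_sweep_monotone_peak(self):
        c = TonalContour((Segment("up", 10, 30, 250.0),))
        peaks = c.peak_channels(5.0)
        assert len(peaks) == 50
        assert np.all(np.diff(peaks) > 0)

    def test_reversal_count_and_contour_drive(self, quiet_network):
        c = TonalContour((Segment("up", 10, 30, 125.0),
                          Segment("down", 30, 10, 125.0)))
        assert c.n_direction_changes() == 1
        sched = tasks.dms_schedule(c, c, quiet_network.config)
        res = tasks.run_schedule(quiet_network, sched, seed=0)
        stim = res.epoch_steps("stimulus")[0]
        assert res.traces["A2_contour"][stim].max() > 0.05

    def test_render_frame_count(self):
        c = TonalContour((Segment("up", 10, 30, 250.0),))
        frames = c.render(5.0)
        assert frames["A1_up"].shape == (50, 81)
        assert frames["A1_down"].sum() == 0.0

    def test_channel_bounds_validated(self):
        with pytest.raises(ValueError):
            Segment("up", 0, 30, 100.0)
        with pytest.raises(ValueError):
            Segment("down", 30, 90, 100.0)
        with pytest.raises(ValueError):
            TonalContour((Segment("up", 10, 30, 100.0),
                          Segment("down", 40, 20, 100.0)))  # discontinuous

    def test_generated_durations_in_syllable_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c = make_tonal_contour(rng=rng)
            assert 200.0 <= c.duration_ms <= 300.0

    def test_loudness_equalized(self):
        rng = np.random.default_rng(4)
        energies = [drive_energy(make_tonal_contour(rng=rng)) for _ in range(5)]
        assert np.ptp(energies) < 1e-6


class TestVisualShape:
    def test_validation(self):
        with pytest.raises(ValueError):
            VisualShape(np.zeros((9, 9)))          # blank
        with pytest.raises(ValueError):
            VisualShape(np.ones((8, 8)))           # wrong geometry
        with pytest.raises(ValueError):
            VisualShape(np.full((9, 9), 2.0))      # out of range

    def test_render_with_onset_ramp(self):
        s = make_visual_shape(seed=1)
        frames = s.render(5.0)["V1"]
        assert frames.shape == (50, 81)
        assert frames[0].max() < frames[-1].max()
        np.testing.assert_allclose(frames[-1], s.frame.ravel())


class TestProbes:
    def test_match_probe_is_target(self, contours):
        assert make_probe(contours[0], True) is contours[0]

    def test_nonmatch_probe_distinct_and_reproducible(self, contours):
        p1 = make_probe(contours[0], False, seed=9)
        p2 = make_probe(contours[0], False, seed=9)
        assert pattern_overlap(p1, contours[0]) < 0.5
        assert p1 == p2

    def test_library_mutually_distinct(self):
        lib = stimulus_library(8, "a", seed=2)
        for i, a in enumerate(lib):
            for b in lib[i + 1:]:
                assert pattern_overlap(a, b) < 0.8


class TestSaliency:
    def test_out_of_range_rejected(self, contours):
        with pytest.raises(ValueError):
            apply_saliency(contours[0], 1.2)
        with pytest.raises(ValueError):
            apply_saliency(contours[0], -0.1)

    def test_zero_silences_unity_preserves(self, contours):
        z = apply_saliency(contours[0], 0.0)
        assert drive_energy(z) == 0.0
        u = apply_saliency(contours[0], 1.0)
        assert drive_energy(u) == pytest.approx(drive_energy(contours[0]))

    def test_response_monotone_in_saliency(self, quiet_network, contours):
        """Weaker saliency evokes a strictly smaller early-sensory response."""
        means = []
        for s in (0.5, 0.9):
            stim = apply_saliency(contours[0], s)
            sched = tasks.dms_schedule(stim, stim, quiet_network.config)
            res = tasks.run_schedule(quiet_network, sched, seed=0)
            sl = res.epoch_steps("stimulus")[0]
            means.append(np.mean(res.traces["A1_up"][sl] + res.traces["A1_down"][sl]))
        assert means[0] < means[1]


class TestControls:
    def test_noise_energy_matched(self, contours):
        for i, c in enumerate(contours[:4]):
            n = noise_control(c, seed=i)
            ratio = drive_energy(n) / drive_energy(c)
            assert abs(ratio - 1) < 0.10

    def test_noise_early_response_matches_object(self, quiet_network, contours):
        """A1/A2 respond to matched noise within 20% of the object response."""
        cfg = quiet_network.config
        obj, noise = contours[0], noise_control(contours[0], seed=5)
        out = {}
        for name, stim in (("obj", obj), ("noise", noise)):
            sched = tasks.dms_schedule(stim, stim, cfg)
            res = tasks.run_schedule(quiet_network, sched, seed=0)
            sl = res.epoch_steps("stimulus")[0]
            a1 = np.mean(res.traces["A1_up"][sl] + res.traces["A1_down"][sl])
            a2 = np.mean(res.traces["A2_up"][sl] + res.traces["A2_down"][sl])
            out[name] = (a1, a2)
        for k in range(2):
            assert out["noise"][k] == pytest.approx(out["obj"][k], rel=0.20)

    def test_degraded_shape_energy_matched(self, shapes):
        d = degraded_control(shapes[0], seed=1)
        assert drive_energy(d) == pytest.approx(drive_energy(shapes[0]), rel=0.10)
        assert pattern_overlap(d, shapes[0]) < 1.0


def test_distinct_objects_distinct_integrator_patterns(quiet_network, contours):
    """Different objects leave decorrelated ST steady patterns."""
    cfg = quiet_network.config
    patterns = []
    for c in (contours[0], contours[3]):
        sched = tasks.dms_schedule(c, c, cfg)
        net = build_network(cfg)
        net.reset()
        rng = np.random.default_rng(0)
        ep = sched.epochs[0]
        drives = tasks._epoch_drives(ep, cfg, cfg.dt_ms)
        net.attention.set_endo(ep.endo_v, ep.endo_a)
        for j in range(int(ep.duration_ms / cfg.dt_ms)):
            net.step({k: v[j] for k, v in drives.items()}, rng)
        patterns.append(net.modules["ST"].E.copy())
    a, b = patterns
    corr = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    assert corr < 0.8
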