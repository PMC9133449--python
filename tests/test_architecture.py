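"""Tests for the network wiring, gating circuit, and attention machinery."""

import numpy as np
import pytest

from avwm.config import Config
from avwm import architecture, stimuli, tasks
from avwm.architecture import (MODULE_INFO, N_SLOTS, build_network,
                               compute_exogenous, inject_attention, Projection)


def test_module_roster_shapes():
    """A1/A2 submodules are 1x81 tonotopic arrays; the rest are 9x9."""
    for name in ("A1_up", "A1_down", "A2_up", "A2_down", "A2_contour"):
        assert MODULE_INFO[name].shape == (1, 81)
    for name in ("V1", "V4", "IT", "EC", "ST", "MTL", "FS_a", "D1_a_1",
                 "D2_v_3", "R_a"):
        assert MODULE_INFO[name].shape == (9, 9)
    assert sum(1 for n in MODULE_INFO if n.startswith("D1_a")) == N_SLOTS
    assert sum(1 for n in MODULE_INFO if n.startswith("D2_v")) == N_SLOTS


def test_build_network_edges_and_metadata(quiet_network):
    net = quiet_network
    keys = {p.key for p in net.projections}
    # feedforward spines of both streams
    for k in ("A1_up->A2_up", "A2_contour->ST", "ST->FS_a",
              "V1->V4", "V4->IT", "IT->FS_v"):
        assert k in keys
    # ablatable prefrontal feedback
    for k in ("D2_a_1->ST", "D2_v_1->IT", "D2_a_1->A2_up", "D2_v_1->V4"):
        assert k in keys
    # aINS competition edges terminate on interneurons
    assert net.projection("aINS_v->aINS_a~I").sign == "inhibitory-via-interneurons"
    assert MODULE_INFO["aINS_a"].location_label == "(48, 12, 4)"


def test_build_network_errors():
    with pytest.raises(ValueError):
        build_network(Config(), edges=[])
    with pytest.raises(ValueError):
        build_network(Config(), edges=[Projection("A1_up", "NOT_A_MODULE", 1.0)])


def test_feedback_ablation_removes_only_feedback(quiet_network):
    removed = quiet_network.ablate_feedback()
    assert set(removed) >= {"D2_a_1->ST", "D2_v_1->IT", "D2_a_1->A2_up",
                            "D2_v_1->V4"}
    assert all(not quiet_network.projection(k).enabled for k in removed)
    # the ablated network still runs
    rec = quiet_network.run(200.0, seed=0, record_syn=False)
    assert rec.n_steps == 40
    quiet_network.restore_feedback()
    assert quiet_network.projection("D2_a_1->ST").enabled


class TestGating:
    def _encode(self, net, stim, seed=0):
        sched = tasks.dms_schedule(stim, stim, net.config)
        return tasks.run_schedule(net, sched, seed=seed)

    def test_single_stimulus_uses_one_group(self, quiet_network, contours):
        self._encode(quiet_network, contours[0])
        # the probe may consume a second group; the stimulus itself uses one
        assert quiet_network.gating["a"].used[0]
        assert not quiet_network.gating["a"].used[2]

    def test_three_items_three_groups_three_slots(self, quiet_network, contours):
        """Sequential stimuli engage distinct gating groups and slots."""
        items = [contours[0], contours[2], contours[4]]
        sched = tasks.sternberg_schedule(items, items[0], quiet_network.config)
        res = tasks.run_schedule(quiet_network, sched, seed=0)
        probe_start = res.epoch_steps("probe")[0].start
        assert quiet_network.gating["a"].used.all()
        assert (res.slots_a[probe_start] > 0.3).sum() == 3

    def test_capacity_exhaustion_blocks_fourth_item(self, quiet_network, contours):
        items = [contours[0], contours[2], contours[4]]
        sched = tasks.sternberg_schedule(items, contours[6], quiet_network.config)
        res = tasks.run_schedule(quiet_network, sched, seed=0)
        # after the probe (a fourth, novel stimulus) no slot was re-routed:
        # the three stored patterns persist and nothing else was encoded
        gs = quiet_network.gating["a"]
        assert gs.n_free == 0
        probe_sl = res.epoch_steps("probe")[0]
        assert (res.slots_a[probe_sl.stop - 1] > 0.3).sum() == 3

    def test_slot_protection(self, quiet_network, contours):
        """A later stimulus never erases an earlier stored item."""
        items = [contours[0], contours[2]]
        sched = tasks.sternberg_schedule(items, items[0], quiet_network.config)
        res = tasks.run_schedule(quiet_network, sched, seed=0)
        second_stim = res.epoch_steps("stimulus")[1]
        after = slice(second_stim.start, res.epoch_steps("probe")[0].start)
        assert res.slots_a[after, 0].min() > quiet_network.config.retention_threshold

    def test_gating_exclusivity(self, quiet_network, contours):
        """At most one gating group is meaningfully open at any step."""
        items = [contours[0], contours[2], contours[4]]
        sched = tasks.sternberg_schedule(items, items[1], quiet_network.config)
        net = quiet_network
        net.reset()
        rng = np.random.default_rng(0)
        thr = net.config.gating.open_threshold
        for ep in sched.epochs:
            n = int(ep.duration_ms / net.config.dt_ms)
            net.attention.set_endo(ep.endo_v, ep.endo_a)
            drives = tasks._epoch_drives(ep, net.config, net.config.dt_ms)
            for j in range(n):
                net.step({k: v[j] for k, v in drives.items()} or None, rng)
                open_groups = (net.gating["a"].open_levels > thr).sum()
                assert open_groups <= 1


class TestExogenousAttention:
    def test_symmetry_under_equal_drives(self, quiet_config):
        exo_v, exo_a = compute_exogenous(0.15, 0.15, quiet_config)
        assert exo_v == pytest.approx(exo_a, abs=1e-9)

    def test_zero_drive_baseline(self, quiet_config):
        exo_v, exo_a = compute_exogenous(0.0, 0.0, quiet_config)
        assert exo_v == pytest.approx(0.0, abs=0.05)
        assert exo_a == pytest.approx(0.0, abs=0.05)

    def test_larger_drive_wins(self, quiet_config):
        exo_v, exo_a = compute_exogenous(0.2, 0.12, quiet_config)
        assert exo_v > exo_a

    def test_rising_visual_saliency_shifts_competition(self, quiet_config, contours,
                                                       shapes):
        """More salient visual input raises exo_v and lowers exo_a."""
        net = build_network(quiet_config)
        lo = tasks.run_bimodal_trial(
            stimuli.apply_saliency(contours[0], 0.55),
            stimuli.apply_saliency(shapes[0], 0.3), net, seed=0)
        hi = tasks.run_bimodal_trial(
            stimuli.apply_saliency(contours[0], 0.55),
            stimuli.apply_saliency(shapes[0], 1.0), net, seed=0)
        assert hi.extras["exo_v_stim"] > lo.extras["exo_v_stim"]
        assert hi.extras["exo_a_stim"] < lo.extras["exo_a_stim"]

    def test_competition_bounded(self, quiet_config, contours, shapes):
        net = build_network(quiet_config)
        res = tasks.run_bimodal_trial(contours[0], shapes[0], net, seed=0)
        bound = 2 * quiet_config.attention.att_max
        assert (res.exo_v + res.exo_a).max() <= bound


class TestAttentionInjection:
    def test_bias_reaches_d2(self, quiet_network):
        st = quiet_network.attention
        st.set_endo(0.05, 0.3)
        tv, ta = inject_attention(st, quiet_network)
        assert ta == pytest.approx(0.3)
        assert quiet_network.modules["ATT_a"].E[0] == pytest.approx(0.3)
        # the relay projects diffusely onto every D2 unit
        rng = np.random.default_rng(0)
        quiet_network.step(None, rng)
        acc = quiet_network._accE["D2_a_1"]
        assert acc.min() >= 0.3 * quiet_network.config.weights["ATT_a->D2_a"] - 1e-9

    def test_total_is_clipped_sum(self, config):
        st = architecture.AttentionState(config)
        st.set_endo(0.3, 0.3)
        for _ in range(30):
            st.update_exo(1.0, 0.0)
        assert st.total_v == pytest.approx(config.attention.att_max)
        assert 0.3 <= st.total_a <= config.attention.att_max

    def test_zero_attention(self, config):
        st = architecture.AttentionState(config)
        assert st.total_v == 0.0 and st.total_a == 0.0


def test_high_attention_sustains_low_attention_decays(quiet_network, contours):
    """Delay activity persists at endo 0.3 but dies at endo 0.05."""
    cfg = quiet_network.config
    stim = contours[0]
    res = tasks.run_dms_trial(stim, stim, quiet_network, True, seed=0)
    delay_end = res.epoch_steps("delay")[-1].stop - 1
    assert res.slots_a[delay_end].max() > cfg.retention_threshold

    lo = cfg.attention.endo_low
    epochs = [
        tasks.Epoch("stimulus", tasks._stim_epoch_ms(stim, cfg), lo, lo, aud=stim),
        tasks.Epoch("delay", 1000.0, lo, lo),
        tasks.Epoch("probe", tasks._stim_epoch_ms(stim, cfg), lo, lo, aud=stim),
    ]
    res_lo = tasks.run_schedule(quiet_network,
                                tasks.TrialSchedule("dms", epochs), seed=0)
    delay_end = res_lo.epoch_steps("delay")[-1].stop - 1
    assert res_lo.slots_a[delay_end].max() < cfg.retention_threshold
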