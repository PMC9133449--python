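"""Behavioral trial tests: schedules, execution, and scoring."""

import numpy as np
import pytest

from avwm import stimuli, tasks
from avwm.tasks import (BehavioralOutcome, score_accuracy, dms_schedule,
                        sternberg_schedule, distractor_schedule, load_schedule)


def test_dms_match_and_nonmatch(quiet_network, contours):
    t = contours[0]
    probe_n = stimuli.make_probe(t, False, seed=7)
    rm = tasks.run_dms_trial(t, t, quiet_network, True, seed=0)
    rn = tasks.run_dms_trial(t, probe_n, quiet_network, False, seed=0)
    assert rm.outcome.responded and rm.outcome.correct
    assert not rn.outcome.responded and rn.outcome.correct
    assert rm.outcome.probe_R_mean > rn.outcome.probe_R_mean


def test_dms_low_attention_no_retention_no_response(quiet_network, contours):
    cfg = quiet_network.config
    t = contours[0]
    lo = cfg.attention.endo_low
    sched = dms_schedule(t, t, cfg)
    for ep in sched.epochs:
        ep.endo_a = lo
        ep.endo_v = lo
    res = tasks.run_schedule(quiet_network, sched, seed=0)
    out = tasks.score_probe(res, True, quiet_network, "a")
    assert not out.responded


def test_distractor_trial_ignores_distractors(quiet_network, contours, shapes):
    t = contours[0]
    ds = [contours[3], shapes[0]]
    probe_n = stimuli.make_probe(t, False, seed=11)
    rm = tasks.run_distractor_trial(t, ds, t, quiet_network, True, seed=0)
    rn = tasks.run_distractor_trial(t, ds, probe_n, quiet_network, False, seed=0)
    assert rm.outcome.correct
    assert rn.outcome.correct
    # the target representation survives the distractor period
    probe_start = rm.epoch_steps("probe")[0].start
    assert rm.slots_a[probe_start].max() > quiet_network.config.retention_threshold


def test_distractor_identical_to_target_flagged(quiet_network, contours):
    t = contours[0]
    res = tasks.run_distractor_trial(t, [t, contours[2]], t, quiet_network,
                                     True, seed=0)
    assert res.extras.get("degenerate_distractor")
    assert res.outcome.responded


def test_distractor_count_enforced(quiet_network, contours):
    with pytest.raises(ValueError):
        distractor_schedule(contours[0], [contours[1]], contours[0],
                            quiet_network.config)


def test_sternberg_match_any_position(quiet_network, contours):
    items = [contours[0], contours[2], contours[4]]
    rm = tasks.run_sternberg_trial(items, items[1], quiet_network, True, seed=0)
    assert rm.outcome.responded
    # nonmatch probe kept distinct from every stored item
    rng = np.random.default_rng(13)
    for _ in range(200):
        probe_n = stimuli.make_tonal_contour(rng=rng)
        if all(stimuli.pattern_overlap(probe_n, it) < 0.3 for it in items):
            break
    rn = tasks.run_sternberg_trial(items, probe_n, quiet_network, False, seed=0)
    assert not rn.outcome.responded


def test_sternberg_capacity_error(quiet_network, contours):
    with pytest.raises(ValueError):
        sternberg_schedule(contours[:4], contours[0], quiet_network.config)


def test_sternberg_single_item_reduces_to_dms(quiet_network, contours):
    t = contours[0]
    r1 = tasks.run_sternberg_trial([t], t, quiet_network, True, seed=0)
    r2 = tasks.run_dms_trial(t, t, quiet_network, True, seed=0)
    assert r1.outcome.responded == r2.outcome.responded


def test_bimodal_attended_modality_encodes(quiet_network, contours, shapes):
    """With endogenous attention on audition and a louder sound, the
    auditory item is encoded and the visual one treated as a distractor."""
    aud = stimuli.apply_saliency(contours[0], 0.9)
    vis = stimuli.apply_saliency(shapes[0], 0.3)
    res = tasks.run_bimodal_trial(aud, vis, quiet_network, seed=0,
                                  endo_v=0.05, endo_a=0.3)
    assert res.extras["aud_encoded"]
    assert not res.extras["vis_encoded"]
    assert res.extras["exo_a_stim"] >= res.extras["exo_v_stim"]


def test_load_trial_measures(quiet_network, contours, shapes):
    items = shapes[:2]
    dist = stimuli.apply_saliency(contours[0], 1.0)
    res = tasks.run_load_trial(items, dist, items[0], quiet_network, True, seed=0)
    assert res.outcome is not None
    assert res.extras["exo_a_distractor"] > 0
    assert res.extras["st_distractor"] > 0
    with pytest.raises(ValueError):
        load_schedule(shapes[:4], dist, shapes[0], quiet_network.config)


def test_response_monotone_in_probe_overlap(quiet_network, contours):
    """More target-probe overlap never weakens the probe response
    (identical noise realization)."""
    t = contours[0]
    partial = stimuli.make_probe(t, False, seed=21)
    r_full = tasks.run_dms_trial(t, t, quiet_network, True, seed=0)
    r_part = tasks.run_dms_trial(t, partial, quiet_network, False, seed=0)
    assert r_full.outcome.probe_R_mean >= r_part.outcome.probe_R_mean


def test_score_accuracy():
    ok = BehavioralOutcome(True, True, True, 0.1)
    bad = BehavioralOutcome(True, False, False, 0.1)
    assert score_accuracy([ok, ok]) == 100.0
    assert score_accuracy([ok, bad]) == 50.0
    with pytest.raises(ValueError):
        score_accuracy([])


def test_schedule_validation(quiet_network, contours):
    sched = dms_schedule(contours[0], contours[0], quiet_network.config)
    sched.epochs[1].duration_ms = 1001.0  # not a multiple of dt
    with pytest.raises(ValueError):
        tasks.run_schedule(quiet_network, sched, seed=0)
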