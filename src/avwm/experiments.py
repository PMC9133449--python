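"""Cohort generation and full simulated experiments.

A cohort of simulated subjects is created by perturbing every inter-module
projection weight with multiplicative Gaussian noise (a crude model of
individual anatomical variability).  Each experiment runs a fixed number
of trials per subject with a documented seed hierarchy (master seed ->
per-subject seeds -> per-trial seeds), so any single trial can be re-run
in isolation.

Experiments:

* ``dms`` / ``dms_distractors`` / ``sternberg`` — the auditory short-term
  memory battery (behavioral accuracy tables).
* ``load`` — visual working-memory load with an auditory distractor; the
  distractor-epoch exogenous auditory attention and ST activity per load
  quantify the intersensory distraction effect.
* switch-threshold scan and the feedback-ablation experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import hemodynamics, stimuli, tasks
from .architecture import Network, build_network
from .config import Config

TASKS = ("dms", "dms_distractors", "sternberg", "bimodal_dms", "load")


@dataclass
class Subject:
    index: int
    config: Config
    seed: int

    def network(self) -> Network:
        return build_network(self.config)


@dataclass
class Cohort:
    subjects: list[Subject]
    base_config: Config
    perturbation_sigma: float
    master_seed: int

    def __len__(self) -> int:
        return len(self.subjects)


@dataclass
class ExperimentResult:
    task: str
    table: pd.DataFrame          # one row per subject x trial/run
    aggregate: dict = field(default_factory=dict)

    def per_subject(self, column: str = "correct") -> pd.Series:
        return self.table.groupby("subject")[column].mean()


def perturb_weights(config: Config, sigma: float, rng: np.random.Generator) -> Config:
    """Multiplicative Gaussian jitter on every inter-module weight.

    Intra-module microcircuit parameters (local E/I couplings, sigmoid
    constants) are untouched; perturbed weights are clipped positive.
    """
    if sigma < 0:
        raise ValueError("perturbation sigma must be >= 0")
    cfg = config.copy()
    for key in cfg.weights:
        factor = max(1.0 + sigma * rng.standard_normal(), 0.05)
        cfg.weights[key] = config.weights[key] * factor
    for attr in ("w_in", "w_route", "w_pfc_fb"):
        factor = max(1.0 + sigma * rng.standard_normal(), 0.05)
        setattr(cfg.gating, attr, getattr(config.gating, attr) * factor)
    return cfg


def make_subjects(base_config: Config | None = None, sigma: float | None = None,
                  seed: int = 0, n_subjects: int | None = None) -> Cohort:
    """Create the simulated cohort by jittering inter-module weights."""
    base = Config() if base_config is None else base_config
    sigma = base.cohort.perturbation_sigma if sigma is None else sigma
    if sigma < 0:
        raise ValueError("perturbation sigma must be >= 0")
    n = base.cohort.n_subjects if n_subjects is None else n_subjects
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
    subjects = []
    for i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        cfg = perturb_weights(base, sigma, rng)
        subjects.append(Subject(index=i, config=cfg, seed=sseed))
    return Cohort(subjects=subjects, base_config=base,
                  perturbation_sigma=sigma, master_seed=seed)


def _trial_seed(subject: Subject, trial: int) -> int:
    return int(np.random.SeedSequence((subject.seed, trial)).generate_state(1)[0]
               % (2**31 - 1))


def _draw_distinct(maker, rng, existing, max_overlap=0.5, tries=300):
    for _ in range(tries):
        cand = maker(rng=rng)
        if all(stimuli.pattern_overlap(cand, e) < max_overlap for e in existing):
            return cand
    return cand  # fall back to the last draw


def _draw_lure(maker, rng, target, others=(), lo=0.5, hi=0.72, tries=300):
    """Nonmatch probe: a related lure with partial feature overlap.

    The lure overlaps the target by [lo, hi) and stays below ``hi`` overlap
    with every stimulus in ``others`` (e.g. stored distractors)."""
    best, best_ov = None, -1.0
    for _ in range(tries):
        cand = maker(rng=rng)
        ov = stimuli.pattern_overlap(cand, target)
        if ov >= hi or any(stimuli.pattern_overlap(cand, o) >= hi for o in others):
            continue
        if ov >= lo:
            return cand
        if ov > best_ov:
            best, best_ov = cand, ov
    return best


def _trial_stimuli(task: str, rng: np.random.Generator, modality: str = "a"):
    """Per-trial stimulus draw: mutually distinct target(s)/distractors."""
    maker = stimuli.make_tonal_contour if modality == "a" else stimuli.make_visual_shape
    if task == "sternberg":
        # list items are mutually distinct; strongly overlapping items would
        # merge their working-memory representations
        items = []
        for _ in range(3):
            items.append(_draw_distinct(maker, rng, items, max_overlap=0.3))
        return items
    if task == "dms_distractors":
        target = maker(rng=rng)
        d_a = _draw_distinct(stimuli.make_tonal_contour, rng, [target])
        d_v = stimuli.make_visual_shape(rng=rng)
        return target, [d_a, d_v]
    return maker(rng=rng)


def run_experiment(task: str, cohort: Cohort, n_trials: int | None = None,
                   ablate_feedback: bool = False) -> ExperimentResult:
    """Run one experiment over the whole cohort.

    Match/nonmatch trials are balanced (alternating) for the recognition
    tasks.  For the ``load`` experiment the trial index enumerates runs;
    each run is executed at loads 1, 2 and 3 with identical stimuli/seeds,
    and the distractor-epoch measures are recorded per load.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    rows = []
    for subject in cohort.subjects:
        n = subject.config.cohort.n_trials if n_trials is None else n_trials
        net = subject.network()
        if ablate_feedback:
            net.ablate_feedback()
        for trial in range(n):
            seed = _trial_seed(subject, trial)
            rng = np.random.default_rng(seed)
            if task == "load":
                rows.extend(_run_load_runs(subject, net, trial, seed, rng))
                continue
            is_match = trial % 2 == 0
            rows.append(_run_recognition_trial(task, subject, net, trial, seed,
                                               rng, is_match))
    table = pd.DataFrame(rows)
    agg: dict = {}
    if "correct" in table.columns:
        acc = table.groupby("subject")["correct"].mean() * 100.0
        agg = {
            "accuracy_mean": float(table["correct"].mean() * 100.0),
            "accuracy_sd": float((table.groupby("subject")["correct"].mean() * 100)
                                 .std(ddof=1)),
            "accuracy_pooled_sd": float(
                100.0 * table["correct"].astype(float).std(ddof=1)),
            "per_subject_accuracy": acc.to_dict(),
        }
    return ExperimentResult(task=task, table=table, aggregate=agg)


def _run_recognition_trial(task, subject, net, trial, seed, rng, is_match):
    if task == "dms":
        target = _trial_stimuli("dms", rng)
        probe = target if is_match else stimuli.make_lure(target, rng)
        res = tasks.run_dms_trial(target, probe, net, is_match, seed=seed)
    elif task == "dms_distractors":
        target, ds = _trial_stimuli("dms_distractors", rng)
        probe = target if is_match else stimuli.make_lure(target, rng,
                                                          min_shift=9.0,
                                                          max_shift=13.0)
        res = tasks.run_distractor_trial(target, ds, probe, net, is_match, seed=seed)
    elif task == "sternberg":
        items = _trial_stimuli("sternberg", rng)
        if is_match:
            probe = items[int(rng.integers(3))]
        else:
            probe = stimuli.make_lure(items[int(rng.integers(3))], rng)
        res = tasks.run_sternberg_trial(items, probe, net, is_match, seed=seed)
    else:  # bimodal_dms
        aud = stimuli.make_tonal_contour(
            rng=rng, saliency=net.config.attention.bimodal_aud_saliency)
        vis = stimuli.make_visual_shape(rng=rng, saliency=float(rng.uniform(0.3, 1.0)))
        res = tasks.run_bimodal_trial(aud, vis, net, seed=seed)
        return {"subject": subject.index, "trial": trial, "seed": seed,
                "exo_a_stim": res.extras["exo_a_stim"],
                "exo_v_stim": res.extras["exo_v_stim"],
                "aud_encoded": res.extras["aud_encoded"],
                "vis_encoded": res.extras["vis_encoded"]}
    o = res.outcome
    return {"subject": subject.index, "trial": trial, "seed": seed,
            "is_match": o.is_match, "responded": o.responded,
            "correct": o.correct, "probe_R_mean": o.probe_R_mean}


def _run_load_runs(subject, net, run_idx, seed, rng):
    """One load run: identical stimuli at loads 1, 2 and 3."""
    items = []
    for _ in range(3):
        items.append(_draw_distinct(stimuli.make_visual_shape, rng, items))
    distractor = stimuli.make_tonal_contour(rng=rng, saliency=1.0)
    is_match = run_idx % 2 == 0
    rows = []
    for load in (1, 2, 3):
        probe = items[0] if is_match else _draw_distinct(
            stimuli.make_visual_shape, rng, items)
        res = tasks.run_load_trial(items[:load], distractor, probe, net,
                                   is_match, seed=seed)
        rows.append({
            "subject": subject.index, "trial": run_idx, "seed": seed, "load": load,
            "exo_a_distractor": res.extras["exo_a_distractor"],
            "st_distractor": res.extras["st_distractor"],
            "exo_v_distractor": res.extras["exo_v_distractor"],
            "correct": res.outcome.correct,
        })
    return rows


# ----------------------------------------------------------------------
# load-effect statistics (working memory load vs intersensory distraction)


def load_effect_stats(result: ExperimentResult) -> pd.DataFrame:
    """Per-contrast percent change, t statistic and one-tailed p value.

    For each subject the distractor-epoch measures are averaged over runs
    at each load; percent changes of loads 2 and 3 relative to load 1 are
    tested against zero with a one-sample, one-tailed t test (df =
    n_subjects - 1; the hypothesized direction is a reduction).
    """
    tbl = result.table
    subjects = sorted(tbl["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("load-effect statistics require at least 2 subjects")
    per = tbl.groupby(["subject", "load"])[["exo_a_distractor", "st_distractor"]].mean()
    rows = []
    for measure, label in (("exo_a_distractor", "auditory_attention"),
                           ("st_distractor", "st_activity")):
        base = per[measure].xs(1, level="load")
        for load in (2, 3):
            vals = per[measure].xs(load, level="load")
            change = 100.0 * (vals - base) / base
            mean, sd = float(change.mean()), float(change.std(ddof=1))
            n = len(change)
            t, p_two = sps.ttest_1samp(change, 0.0)
            p_one = p_two / 2.0 if t < 0 else 1.0 - p_two / 2.0
            rows.append({"measure": label, "contrast": f"{load}v1",
                         "mean_pct_change": mean, "sd_pct_change": sd,
                         "t": float(t), "p_one_tailed": float(p_one),
                         "df": n - 1})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# saliency switch threshold

#: generator seed of the canonical bimodal stimulus pair
CANONICAL_BIMODAL_SEED = 1205


def find_switch_threshold(network_or_cohort, seed: int = 0, n_reps: int = 3,
                          grid: np.ndarray | None = None,
                          aud_saliency: float | None = None) -> dict:
    """Minimal visual saliency at which exogenous attention switches.

    Endogenous attention is set to the auditory modality (0.3 vs 0.05);
    the auditory stimulus has the fixed bimodal-schedule saliency.  For
    each grid value the trial is repeated ``n_reps`` times with common
    random numbers across grid values; the switch requires the repetition-
    mean exogenous visual attention to exceed the auditory one during the
    stimulus epoch AND the visual working memory to encode the stimulus on
    a majority of repetitions.
    """
    if isinstance(network_or_cohort, Cohort):
        net = network_or_cohort.subjects[0].network()
        cfg = network_or_cohort.subjects[0].config
    else:
        net = network_or_cohort
        cfg = net.config
    if grid is None:
        grid = np.round(np.arange(0.1, 1.01, 0.1), 10)
    s_aud = cfg.attention.bimodal_aud_saliency if aud_saliency is None else aud_saliency
    at = cfg.attention
    rep_seeds = [int(np.random.SeedSequence((seed, r)).generate_state(1)[0]
                     % (2**31 - 1)) for r in range(n_reps)]
    # one canonical stimulus pair across the whole scan: the experiment
    # varies the saliency of the same two objects, as in the bimodal series
    stim_rng = np.random.default_rng(CANONICAL_BIMODAL_SEED)
    base_aud = stimuli.make_tonal_contour(rng=stim_rng)
    base_vis = stimuli.make_visual_shape(rng=stim_rng)
    records = []
    threshold = None
    for s_v in grid:
        exo_v, exo_a, enc = [], [], []
        for rseed in rep_seeds:
            aud = stimuli.apply_saliency(base_aud, s_aud)
            vis = stimuli.apply_saliency(base_vis, float(s_v))
            res = tasks.run_bimodal_trial(aud, vis, net, seed=rseed,
                                          endo_v=at.endo_low, endo_a=at.endo_high)
            exo_v.append(res.extras["exo_v_stim"])
            exo_a.append(res.extras["exo_a_stim"])
            enc.append(res.extras["vis_encoded"])
        switched = (np.mean(exo_v) > np.mean(exo_a)) and (np.mean(enc) > 0.5)
        records.append({"visual_saliency": float(s_v),
                        "exo_v": float(np.mean(exo_v)),
                        "exo_a": float(np.mean(exo_a)),
                        "vis_encoded_frac": float(np.mean(enc)),
                        "switched": bool(switched)})
        if switched and threshold is None:
            threshold = float(s_v)
    return {"threshold": threshold, "aud_saliency": s_aud,
            "scan": pd.DataFrame(records)}


# ----------------------------------------------------------------------
# feedback ablation


FEEDBACK_EDGE_KEYS = ("D2->IT/ST", "D2->V4/A2")


def ablate_and_rerun(cohort: Cohort, task: str = "load",
                     n_trials: int | None = None,
                     edges: tuple[str, ...] = FEEDBACK_EDGE_KEYS) -> ExperimentResult:
    """Re-run an experiment with the prefrontal feedback projections removed.

    ``edges`` names the feedback families to delete; unknown names raise.
    """
    for e in edges:
        if e not in FEEDBACK_EDGE_KEYS:
            raise ValueError(f"unknown feedback edge family {e!r}")
    return run_experiment(task, cohort, n_trials=n_trials, ablate_feedback=True)


# ----------------------------------------------------------------------
# simulated fMRI experiments


def _syn_trial(net: Network, schedule, seed: int, reset: bool):
    res = tasks.run_schedule(net, schedule, seed=seed, record_syn=True, reset=reset)
    return res.syn


def fmri_block_run(config: Config | None = None, seed: int = 0, n_cycles: int = 4,
                   modality: str = "a") -> hemodynamics.BoldRecord:
    """Block-design DMS run: alternating blocks of 3 task and 3 control trials.

    Task trials are DMS trials with a 1 s delay and high endogenous
    attention; control trials present energy-matched random noise patterns
    passively (low attention) with the same timing.  The network state is
    continuous within the run.
    """
    cfg = Config() if config is None else config
    net = build_network(cfg)
    net.reset()
    rng = np.random.default_rng(seed)
    runs = []
    first = True
    for _ in range(n_cycles):
        for block, n_in_block in (("task", 3), ("control", 3)):
            for _ in range(n_in_block):
                if modality == "a":
                    target = stimuli.make_tonal_contour(rng=rng)
                    if block == "task":
                        match = rng.random() < 0.5
                        probe = target if match else _draw_lure(
                            stimuli.make_tonal_contour, rng, target)
                        sched = tasks.dms_schedule(target, probe, cfg, modality="a",
                                                   delay_ms=1000.0)
                    else:
                        noise1 = stimuli.noise_control(target, seed=int(rng.integers(2**31)))
                        noise2 = stimuli.noise_control(target, seed=int(rng.integers(2**31)))
                        sched = _passive_schedule(noise1, noise2, cfg)
                else:
                    target = stimuli.make_visual_shape(rng=rng)
                    if block == "task":
                        match = rng.random() < 0.5
                        probe = target if match else _draw_lure(
                            stimuli.make_visual_shape, rng, target)
                        sched = tasks.dms_schedule(target, probe, cfg, modality="v",
                                                   delay_ms=1000.0)
                    else:
                        d1 = stimuli.degraded_control(target, seed=int(rng.integers(2**31)))
                        d2 = stimuli.degraded_control(target, seed=int(rng.integers(2**31)))
                        sched = _passive_schedule(d1, d2, cfg)
                syn = _syn_trial(net, sched, seed=int(rng.integers(2**31)), reset=first)
                first = False
                runs.append((block, syn))
    return hemodynamics.assemble_design(runs, "block", cfg.dt_ms, params=cfg.balloon)


def _passive_schedule(stim1, stim2, cfg: Config):
    """Passive-perception control trial: same timing, low attention."""
    lo = cfg.attention.endo_low
    key = "vis" if stim1.modality == "v" else "aud"
    epochs = [
        tasks.Epoch("stimulus", tasks._stim_epoch_ms(stim1, cfg), lo, lo, **{key: stim1}),
        tasks.Epoch("delay", 1000.0, lo, lo),
        tasks.Epoch("probe", tasks._stim_epoch_ms(stim2, cfg), lo, lo, **{key: stim2}),
        tasks.Epoch("intertrial", cfg.epochs.intertrial_ms, lo, lo),
    ]
    return tasks.TrialSchedule("passive", epochs)


def fmri_dissociation(record: hemodynamics.BoldRecord,
                      modality: str = "a") -> dict:
    """Early-vs-late contrast dissociation for a block-design run.

    Returns the per-region task-control contrasts and the ratio of the
    larger early-sensory contrast (A1, A2) to the smaller high-order
    contrast (PFC, MTL); values well below 1 reproduce the equal
    early-response / differential high-order pattern.
    """
    contrast = hemodynamics.block_contrast(record)
    if modality == "a":
        early = max(contrast["A1"], contrast["A2"])
        high = min(contrast["PFC_a"], contrast["MTL"])
    else:
        early = max(contrast["V1"], contrast["V4"])
        high = min(contrast["PFC_v"], contrast["EC"])
    return {"contrasts": contrast.to_dict(), "early": float(early),
            "high": float(high), "ratio": float(early / high)}


def fmri_event_related_run(config: Config | None = None, seed: int = 0,
                           n_trials: int = 3) -> hemodynamics.BoldRecord:
    """Event-related bimodal attention-capture run.

    Visual and auditory DMS trials are presented in parallel with no task
    instruction (endogenous attention low): the first trial's visual
    stimulus is the more salient one, later trials have more salient
    auditory stimuli.  Delays are extended to 20 s so each event's BOLD
    response develops fully; successive trial onsets are 25 s apart.
    """
    cfg = Config() if config is None else config
    net = build_network(cfg)
    net.reset()
    rng = np.random.default_rng(seed)
    at = cfg.attention
    runs = []
    stim_rng = np.random.default_rng(CANONICAL_BIMODAL_SEED)
    aud = stimuli.make_tonal_contour(rng=stim_rng)
    vis = stimuli.make_visual_shape(rng=stim_rng)
    for k in range(n_trials):
        if k == 0:
            s_v, s_a = 1.0, 0.3
        else:
            s_v, s_a = 0.3, 1.0
        epochs = [
            tasks.Epoch("stimulus", 1000.0, at.endo_low, at.endo_low,
                        aud=stimuli.apply_saliency(aud, s_a),
                        vis=stimuli.apply_saliency(vis, s_v)),
            tasks.Epoch("delay", cfg.epochs.event_delay_ms, at.endo_low, at.endo_low),
            tasks.Epoch("probe", 1000.0, at.endo_low, at.endo_low,
                        aud=stimuli.apply_saliency(aud, s_a),
                        vis=stimuli.apply_saliency(vis, s_v)),
            tasks.Epoch("intertrial", 3000.0, at.endo_low, at.endo_low),
        ]
        sched = tasks.TrialSchedule("bimodal_event", epochs)
        syn = _syn_trial(net, sched, seed=int(rng.integers(2**31)), reset=(k == 0))
        runs.append((f"trial{k + 1}_{'vis' if k == 0 else 'aud'}_salient", syn))
    return hemodynamics.assemble_design(runs, "event_related", cfg.dt_ms,
                                        params=cfg.balloon)
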