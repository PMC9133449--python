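"""Trial schedules, trial execution, and behavioral scoring.

Five simulated experiments are supported:

* ``dms`` — delayed match-to-sample: stimulus, delay, probe; endogenous
  attention high (0.3) throughout.
* ``dms_distractors`` — two intervening distractors; endogenous attention
  drops to low (0.05) during the distractor presentations and is restored
  afterwards, so the distractors are perceived but not actively encoded.
* ``sternberg`` — three sequential list items, a delay, and a probe that
  must be compared against every stored item.
* ``bimodal_dms`` — simultaneous auditory and visual stimuli whose saliency
  determines, via the anterior-insula competition, which modality's
  working memory encodes its stimulus.
* ``load_distraction`` — one to three visual items held in memory, an
  auditory distractor presented mid-delay, and a visual probe; the
  distractor-epoch exogenous auditory attention and ST activity are the
  summary measures of interest.

The behavioral readout is the mean activity of the response (R) module
during the probe epoch: the model "responds" when it exceeds the response
threshold, and a response is correct iff the probe matches a stored item.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .architecture import Network
from .config import Config
from . import stimuli as stim_mod

RECORD_MODULES = None  # record mean traces for every module


@dataclass
class Epoch:
    label: str          # stimulus | delay | distractor | probe | intertrial
    duration_ms: float
    endo_v: float
    endo_a: float
    aud: object | None = None   # auditory stimulus presented in this epoch
    vis: object | None = None   # visual stimulus
    #: optional mid-epoch endogenous-attention change (reaction lag)
    endo_switch_ms: float | None = None
    endo_v_late: float = 0.0
    endo_a_late: float = 0.0


@dataclass
class TrialSchedule:
    task: str
    epochs: list[Epoch]

    @property
    def duration_ms(self) -> float:
        return sum(e.duration_ms for e in self.epochs)

    def validate(self, dt_ms: float) -> None:
        if not self.epochs:
            raise ValueError("schedule has no epochs")
        for e in self.epochs:
            if abs(round(e.duration_ms / dt_ms) - e.duration_ms / dt_ms) > 1e-9:
                raise ValueError(
                    f"epoch {e.label!r} duration {e.duration_ms} not a multiple of dt")
            for s in (e.aud, e.vis):
                if s is not None and s.duration_ms - e.duration_ms > 1e-9:
                    raise ValueError(
                        f"stimulus ({s.duration_ms} ms) longer than epoch "
                        f"{e.label!r} ({e.duration_ms} ms)")


@dataclass
class BehavioralOutcome:
    responded: bool
    correct: bool
    is_match: bool
    probe_R_mean: float


@dataclass
class TrialResult:
    schedule: TrialSchedule
    outcome: BehavioralOutcome | None
    #: per-step mean excitatory activity per module
    traces: dict[str, np.ndarray]
    #: exogenous attention traces
    exo_v: np.ndarray
    exo_a: np.ndarray
    total_v: np.ndarray
    total_a: np.ndarray
    #: per-step working-memory slot strengths, shape (n_steps, n_slots)
    slots_a: np.ndarray
    slots_v: np.ndarray
    #: step index ranges per epoch, aligned with schedule.epochs
    epoch_slices: list[slice]
    dt_ms: float
    #: per-module per-step summed absolute synaptic input (if recorded)
    syn: dict[str, np.ndarray] | None = None
    extras: dict = field(default_factory=dict)

    def epoch_steps(self, label: str) -> list[slice]:
        return [sl for e, sl in zip(self.schedule.epochs, self.epoch_slices)
                if e.label == label]

    def epoch_mean(self, series: np.ndarray, label: str) -> float:
        sls = self.epoch_steps(label)
        if not sls:
            raise ValueError(f"no epoch labeled {label!r}")
        return float(np.mean(np.concatenate([series[sl] for sl in sls])))


# ----------------------------------------------------------------------
# schedule builders


def _stim_epoch_ms(stim, cfg: Config) -> float:
    """Epoch length for a stimulus: at least the nominal epoch, stretched to
    fit longer objects (contour durations vary in [200, 300] ms)."""
    base = cfg.epochs.stimulus_ms
    dur = np.ceil(stim.duration_ms / cfg.dt_ms) * cfg.dt_ms
    return float(max(base, dur))


def dms_schedule(stimulus, probe, cfg: Config, modality: str = "a",
                 delay_ms: float | None = None) -> TrialSchedule:
    """Standard DMS timeline; endogenous attention high throughout."""
    ep, at = cfg.epochs, cfg.attention
    delay = cfg.epochs.delay_ms if delay_ms is None else delay_ms
    hi, lo = at.endo_high, at.endo_low
    ev, ea = (hi, lo) if modality == "v" else (lo, hi)
    skey = "vis" if modality == "v" else "aud"
    epochs = [
        Epoch("stimulus", _stim_epoch_ms(stimulus, cfg), ev, ea, **{skey: stimulus}),
        Epoch("delay", delay, ev, ea),
        Epoch("probe", _stim_epoch_ms(probe, cfg), ev, ea, **{skey: probe}),
        Epoch("intertrial", ep.intertrial_ms, at.endo_low, at.endo_low),
    ]
    return TrialSchedule("dms", epochs)


def distractor_schedule(target, distractors: Sequence, probe, cfg: Config,
                        modality: str = "a") -> TrialSchedule:
    """DMS with two intervening distractors (auditory or visual).

    Endogenous attention in the task modality is high at stimulus onset and
    drops to low during each distractor presentation.
    """
    if len(distractors) != 2:
        raise ValueError("exactly two distractors are required")
    ep, at = cfg.epochs, cfg.attention
    hi, lo = at.endo_high, at.endo_low

    def endo(level):
        return (level, lo) if modality == "v" else (lo, level)

    skey = "vis" if modality == "v" else "aud"
    epochs = [
        Epoch("stimulus", _stim_epoch_ms(target, cfg), *endo(hi), **{skey: target}),
        Epoch("delay", 500.0, *endo(hi)),
    ]
    lag_ms = 100.0  # endogenous reaction lag: the drop follows the onset
    for d in distractors:
        dkey = "vis" if d.modality == "v" else "aud"
        # the endogenous drop shields the task stream from encoding the
        # distractor; it is only needed when the distractor shares the task
        # modality (a cross-modal distractor is gated by its own modality's
        # low endogenous attention), and it follows the distractor's
        # appearance with a reaction lag
        level = lo if d.modality == modality else hi
        dur = _stim_epoch_ms(d, cfg)
        e = Epoch("distractor", dur, *endo(hi), **{dkey: d})
        if level == lo:
            e.endo_switch_ms = lag_ms
            e.endo_v_late, e.endo_a_late = endo(level)
        epochs.append(e)
        epochs.append(Epoch("delay", ep.isi_ms, *endo(hi)))
    epochs += [
        Epoch("delay", 500.0, *endo(hi)),
        Epoch("probe", _stim_epoch_ms(probe, cfg), *endo(hi), **{skey: probe}),
        Epoch("intertrial", ep.intertrial_ms, at.endo_low, at.endo_low),
    ]
    return TrialSchedule("dms_distractors", epochs)


def sternberg_schedule(items: Sequence, probe, cfg: Config,
                       modality: str = "a") -> TrialSchedule:
    """Sternberg recognition: sequential list, delay, probe; attention high."""
    from .architecture import N_SLOTS

    if len(items) > N_SLOTS:
        raise ValueError(f"list length {len(items)} exceeds the {N_SLOTS}-slot capacity")
    ep, at = cfg.epochs, cfg.attention
    hi, lo = at.endo_high, at.endo_low
    ev, ea = (hi, lo) if modality == "v" else (lo, hi)
    skey = "vis" if modality == "v" else "aud"
    epochs = []
    for it in items:
        epochs.append(Epoch("stimulus", _stim_epoch_ms(it, cfg), ev, ea, **{skey: it}))
        epochs.append(Epoch("delay", ep.isi_ms, ev, ea))
    epochs += [
        Epoch("delay", ep.delay_ms, ev, ea),
        Epoch("probe", _stim_epoch_ms(probe, cfg), ev, ea, **{skey: probe}),
        Epoch("intertrial", ep.intertrial_ms, at.endo_low, at.endo_low),
    ]
    return TrialSchedule("sternberg", epochs)


def bimodal_schedule(aud, vis, cfg: Config, endo_v: float | None = None,
                     endo_a: float | None = None, aud_probe=None,
                     vis_probe=None) -> TrialSchedule:
    """Simultaneous auditory + visual DMS; default endogenous attention 0.1."""
    ep, at = cfg.epochs, cfg.attention
    ev = at.endo_bimodal if endo_v is None else endo_v
    ea = at.endo_bimodal if endo_a is None else endo_a
    epochs = [
        Epoch("stimulus", max(_stim_epoch_ms(aud, cfg), _stim_epoch_ms(vis, cfg)), ev, ea, aud=aud, vis=vis),
        Epoch("delay", ep.delay_ms, ev, ea),
    ]
    if aud_probe is not None or vis_probe is not None:
        pdur = max(_stim_epoch_ms(s, cfg) for s in (aud_probe, vis_probe) if s is not None)
        epochs.append(Epoch("probe", pdur, ev, ea, aud=aud_probe, vis=vis_probe))
    epochs.append(Epoch("intertrial", ep.intertrial_ms, at.endo_low, at.endo_low))
    return TrialSchedule("bimodal_dms", epochs)


def load_schedule(vis_items: Sequence, aud_distractor, probe,
                  cfg: Config) -> TrialSchedule:
    """Visual working-memory load task with an auditory distractor.

    1-3 visual items are encoded sequentially (endogenous attention on the
    visual modality); the auditory distractor arrives mid-delay; the trial
    ends with a visual probe.
    """
    from .architecture import N_SLOTS

    if not (1 <= len(vis_items) <= N_SLOTS):
        raise ValueError(f"load must be between 1 and {N_SLOTS} items")
    ep, at = cfg.epochs, cfg.attention
    hi, lo = at.endo_high, at.endo_low
    epochs = []
    for it in vis_items:
        epochs.append(Epoch("stimulus", _stim_epoch_ms(it, cfg), hi, lo, vis=it))
        epochs.append(Epoch("delay", ep.isi_ms, hi, lo))
    epochs += [
        Epoch("delay", 750.0, hi, lo),
        Epoch("distractor", _stim_epoch_ms(aud_distractor, cfg), hi, lo, aud=aud_distractor),
        Epoch("delay", 750.0, hi, lo),
        Epoch("probe", _stim_epoch_ms(probe, cfg), hi, lo, vis=probe),
        Epoch("intertrial", ep.intertrial_ms, lo, lo),
    ]
    return TrialSchedule("load_distraction", epochs)


# ----------------------------------------------------------------------
# execution


def _epoch_drives(epoch: Epoch, cfg: Config, dt_ms: float) -> dict[str, np.ndarray]:
    """Render this epoch's stimuli into per-step input drives."""
    n = int(round(epoch.duration_ms / dt_ms))
    drives: dict[str, np.ndarray] = {}
    for stim, gain_key in ((epoch.aud, "input->A1"), (epoch.vis, "input->V1")):
        if stim is None:
            continue
        gain = cfg.weights[gain_key]
        for name, arr in stim.render(dt_ms).items():
            block = np.zeros((n, arr.shape[1]))
            block[: arr.shape[0]] = gain * arr
            drives[name] = drives.get(name, 0) + block
    return drives


def run_schedule(net: Network, schedule: TrialSchedule, seed: int | None = 0,
                 record_syn: bool = False, reset: bool = True) -> TrialResult:
    """Execute a trial schedule on the network and collect traces.

    The network starts from the quiescent state (fresh trial) unless
    ``reset`` is False (continuous fMRI runs).  Identical seed and
    configuration give bit-identical results.
    """
    cfg = net.config
    dt = cfg.dt_ms
    schedule.validate(dt)
    if reset:
        net.reset()
    else:
        # continuous run: activities persist, but the use-once gating
        # capacity is per trial, so consumed groups are released
        for gs in net.gating.values():
            gs.used[:] = False
    rng = np.random.default_rng(seed)
    n_total = int(round(schedule.duration_ms / dt))
    names = list(net.modules)
    traces = {m: np.empty(n_total) for m in names}
    exo_v = np.empty(n_total)
    exo_a = np.empty(n_total)
    total_v = np.empty(n_total)
    total_a = np.empty(n_total)
    from .architecture import N_SLOTS
    slots_a = np.empty((n_total, N_SLOTS))
    slots_v = np.empty((n_total, N_SLOTS))
    syn = {m: np.empty(n_total) for m in names} if record_syn else None
    syn_step: dict[str, float] | None = {} if record_syn else None

    epoch_slices = []
    k = 0
    for epoch in schedule.epochs:
        n = int(round(epoch.duration_ms / dt))
        epoch_slices.append(slice(k, k + n))
        net.attention.set_endo(epoch.endo_v, epoch.endo_a)
        switch_step = (None if epoch.endo_switch_ms is None
                       else int(round(epoch.endo_switch_ms / dt)))
        drives = _epoch_drives(epoch, cfg, dt)
        for j in range(n):
            if switch_step is not None and j == switch_step:
                net.attention.set_endo(epoch.endo_v_late, epoch.endo_a_late)
            step_drives = {name: arr[j] for name, arr in drives.items()} or None
            net.step(step_drives, rng, syn_out=syn_step)
            means = net.module_means()
            for m in names:
                traces[m][k] = means[m]
                if record_syn:
                    syn[m][k] = syn_step[m]
            exo_v[k] = net.attention.exo_v
            exo_a[k] = net.attention.exo_a
            total_v[k] = net.attention.total_v
            total_a[k] = net.attention.total_a
            slots_a[k] = net.slot_strengths("a")
            slots_v[k] = net.slot_strengths("v")
            k += 1

    return TrialResult(schedule=schedule, outcome=None, traces=traces,
                       exo_v=exo_v, exo_a=exo_a, total_v=total_v, total_a=total_a,
                       slots_a=slots_a, slots_v=slots_v,
                       epoch_slices=epoch_slices, dt_ms=dt, syn=syn)


def score_probe(result: TrialResult, is_match: bool, net: Network,
                modality: str = "a") -> BehavioralOutcome:
    """Score the trial from the R-module activity at the probe.

    The readout is the mean R activity over the response window at probe
    onset: match responses emerge within ~100 ms (cue units coinciding with
    stored delay activity), whereas R activity later in the probe epoch can
    reflect the probe's own encoding into a free working-memory slot.
    """
    r_name = f"R_{modality}"
    sl = result.epoch_steps("probe")[-1]
    n_win = max(1, int(round(net.config.response_window_ms / result.dt_ms)))
    stop = min(sl.start + n_win, sl.stop)
    mean_r = float(np.mean(result.traces[r_name][sl.start:stop]))
    responded = mean_r > net.config.response_threshold
    return BehavioralOutcome(responded=responded, correct=(responded == is_match),
                             is_match=is_match, probe_R_mean=mean_r)


def run_dms_trial(stimulus, probe, net: Network, is_match: bool,
                  seed: int | None = 0, modality: str = "a",
                  schedule: TrialSchedule | None = None,
                  record_syn: bool = False) -> TrialResult:
    if schedule is None:
        schedule = dms_schedule(stimulus, probe, net.config, modality=modality)
    result = run_schedule(net, schedule, seed=seed, record_syn=record_syn)
    result.outcome = score_probe(result, is_match, net, modality)
    return result


def run_distractor_trial(target, distractors, probe, net: Network, is_match: bool,
                         seed: int | None = 0, modality: str = "a") -> TrialResult:
    schedule = distractor_schedule(target, distractors, probe, net.config,
                                   modality=modality)
    if any(stim_mod.pattern_overlap(d, target) > 0.95 for d in distractors):
        result_extras = {"degenerate_distractor": True}
    else:
        result_extras = {}
    result = run_schedule(net, schedule, seed=seed)
    result.outcome = score_probe(result, is_match, net, modality)
    result.extras.update(result_extras)
    return result


def run_sternberg_trial(items, probe, net: Network, is_match: bool,
                        seed: int | None = 0, modality: str = "a") -> TrialResult:
    schedule = sternberg_schedule(items, probe, net.config, modality=modality)
    result = run_schedule(net, schedule, seed=seed)
    result.outcome = score_probe(result, is_match, net, modality)
    return result


def run_bimodal_trial(aud, vis, net: Network, seed: int | None = 0,
                      endo_v: float | None = None, endo_a: float | None = None,
                      aud_probe=None, vis_probe=None,
                      is_match_a: bool | None = None,
                      is_match_v: bool | None = None) -> TrialResult:
    """Simultaneous bimodal trial; returns attention traces and encoding flags."""
    schedule = bimodal_schedule(aud, vis, net.config, endo_v=endo_v, endo_a=endo_a,
                                aud_probe=aud_probe, vis_probe=vis_probe)
    result = run_schedule(net, schedule, seed=seed)
    thr = net.config.retention_threshold
    # encoding = peak slot activation up to the end of the delay; with low
    # endogenous attention an exogenously encoded item is transient (it
    # decays once the salience-driven attention fades), which still counts
    # as working-memory activation
    delay_end = result.epoch_steps("delay")[-1].stop
    result.extras["aud_encoded"] = bool(result.slots_a[:delay_end].max() > thr)
    result.extras["vis_encoded"] = bool(result.slots_v[:delay_end].max() > thr)
    result.extras["delay_end_step"] = delay_end - 1
    result.extras["exo_v_stim"] = result.epoch_mean(result.exo_v, "stimulus")
    result.extras["exo_a_stim"] = result.epoch_mean(result.exo_a, "stimulus")
    if is_match_a is not None and aud_probe is not None:
        result.extras["outcome_a"] = score_probe(result, is_match_a, net, "a")
    if is_match_v is not None and vis_probe is not None:
        result.extras["outcome_v"] = score_probe(result, is_match_v, net, "v")
    return result


def run_load_trial(vis_items, aud_distractor, probe, net: Network, is_match: bool,
                   seed: int | None = 0) -> TrialResult:
    """Load-distraction trial; records the two distractor-epoch measures."""
    schedule = load_schedule(vis_items, aud_distractor, probe, net.config)
    result = run_schedule(net, schedule, seed=seed)
    result.outcome = score_probe(result, is_match, net, "v")
    result.extras["exo_a_distractor"] = result.epoch_mean(result.exo_a, "distractor")
    result.extras["st_distractor"] = result.epoch_mean(result.traces["ST"], "distractor")
    result.extras["exo_v_distractor"] = result.epoch_mean(result.exo_v, "distractor")
    return result


def score_accuracy(outcomes: Sequence[BehavioralOutcome]) -> float:
    """Percent correct over a set of trial outcomes."""
    if not outcomes:
        raise ValueError("no outcomes to score")
    return 100.0 * float(np.mean([o.correct for o in outcomes]))
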