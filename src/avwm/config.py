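"""Model configuration.

All constants of the model live here: sigmoid gains/thresholds per module
type, decay rates, inter-module connection weights, attention and gating
parameters, trial epoch durations, hemodynamic (balloon) parameters, and
cohort settings.  Defaults are the calibrated values used throughout; any
subset can be overridden from a YAML/JSON mapping via :func:`load_config`.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class UnitParams:
    """Sigmoid and decay parameters of one module's Wilson-Cowan units.

    K
        gain of the sigmoid (dimensionless, > 0).
    phi
        threshold of the sigmoid, in units of summed synaptic input.
    delta
        decay rate per unit time, in (0, 1].
    w_ei
        local excitatory -> inhibitory coupling within each microcircuit.
    w_ie
        local inhibitory -> excitatory coupling.
    """

    K: float
    phi: float
    delta: float = 0.5
    w_ei: float = 0.0
    w_ie: float = 0.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"sigmoid gain K must be > 0, got {self.K}")
        if not (0 < self.delta <= 1):
            raise ValueError(f"decay delta must be in (0, 1], got {self.delta}")


@dataclass
class AttentionConfig:
    """Endogenous/exogenous attention combination parameters.

    Total attention per modality is clip(endo + exo, 0, att_max) and is
    injected as a diffuse bias into the D2 working-memory units via the
    task-specification relay units.
    """

    att_max: float = 0.35
    endo_high: float = 0.3
    endo_low: float = 0.05
    endo_bimodal: float = 0.1
    #: affine map from anterior-insula unit activity to exogenous attention
    exo_gain: float = 1.2
    exo_baseline: float = 0.3
    #: moving-average window over aINS output, ms
    smooth_ms: float = 50.0
    #: fixed auditory saliency of the bimodal competition schedule
    bimodal_aud_saliency: float = 0.55


@dataclass
class GatingConfig:
    """Medial-temporal / entorhinal gating circuit parameters."""

    n_groups: int = 3
    #: drive weight from the sensory integrator (ST or IT) mean activity
    w_in: float = 1.6
    #: winner-take-all cross-group inhibition weight
    w_wta: float = 8.0
    #: baseline excitability of every unused gating group
    base_bias: float = 0.12
    #: extra bias favoring lower group indices (deterministic tie-break)
    tie_bias: float = 0.03
    #: prefrontal feedback suppression weight (D2 slot -> own gating group)
    w_pfc_fb: float = 2.0
    #: gate considered open above this mean activity
    open_threshold: float = 0.3
    #: D2 slot mean activity confirming storage (marks the group used)
    store_threshold: float = 0.5
    #: gated routing weight, sensory pattern -> D1 slot
    w_route: float = 2.0
    #: adaptation rate (per unit time) of the gating drive; the gate responds
    #: to the onset transient of the sensory trace, so a sustained stimulus
    #: triggers exactly one gating event
    adapt_rate: float = 0.12


@dataclass
class EpochConfig:
    """Default trial epoch durations, ms."""

    stimulus_ms: float = 250.0
    delay_ms: float = 1000.0
    probe_ms: float = 250.0
    intertrial_ms: float = 500.0
    #: gap between successive list items (Sternberg) / distractors
    isi_ms: float = 250.0
    #: delay used in event-related fMRI designs
    event_delay_ms: float = 20000.0


@dataclass
class BalloonConfig:
    """Balloon-model hemodynamic parameters (standard literature values)."""

    kappa: float = 0.65  # vasodilatory signal decay, 1/s
    gamma: float = 0.41  # flow-dependent feedback, 1/s
    tau: float = 0.98    # mean transit time, s
    alpha: float = 0.32  # vessel stiffness exponent
    E0: float = 0.34     # resting oxygen extraction fraction
    V0: float = 0.02     # resting venous volume fraction
    dt_s: float = 0.01   # internal Euler step, s
    #: gain applied to the normalized synaptic drive
    gain: float = 0.6

    @property
    def k1(self) -> float:
        return 7.0 * self.E0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.E0 - 0.2


@dataclass
class CohortConfig:
    n_subjects: int = 10
    n_trials: int = 20
    #: relative std of the Gaussian perturbation on inter-module weights
    perturbation_sigma: float = 0.02


@dataclass
class Config:
    """Top-level model configuration."""

    dt_ms: float = 5.0
    #: time unit of the rate equations, ms; Euler step h = dt_ms / unit_time_ms
    unit_time_ms: float = 10.0
    #: std of additive Gaussian input noise per unit per step
    noise_amplitude: float = 0.05
    #: mean R-unit activity during the response window above which the model responds
    response_threshold: float = 0.052
    #: response readout window from probe onset, ms; keeps the behavioral
    #: readout clear of late encoding-related R activity
    response_window_ms: float = 150.0
    #: D2 slot mean activity above which an item counts as retained/encoded
    retention_threshold: float = 0.25

    units: dict[str, UnitParams] = field(default_factory=lambda: _default_units())
    weights: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    gating: GatingConfig = field(default_factory=GatingConfig)
    epochs: EpochConfig = field(default_factory=EpochConfig)
    balloon: BalloonConfig = field(default_factory=BalloonConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @property
    def h(self) -> float:
        """Dimensionless Euler step."""
        return self.dt_ms / self.unit_time_ms

    def copy(self) -> "Config":
        return copy.deepcopy(self)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _default_units() -> dict[str, UnitParams]:
    """Per-module-type unit parameters (calibrated defaults).

    Sensory stages run in a graded (semi-linear) regime so that stimulus
    saliency is preserved up the hierarchy; working-memory units are steep
    and thresholded so that delay activity is bistable and attention-gated.
    """
    return {
        # early sensory: graded response, moderate gain
        "A1": UnitParams(K=4.0, phi=0.85, delta=0.5),
        # A2 integrates over a longer spectrotemporal window: slow decay
        "A2": UnitParams(K=8.0, phi=0.7, delta=0.12),
        # contour/corner selectivity: high threshold coincidence detector
        "A2_contour": UnitParams(K=8.0, phi=0.75, delta=0.12),
        "V1": UnitParams(K=4.0, phi=0.9, delta=0.5),
        "V4": UnitParams(K=8.0, phi=0.7, delta=0.12),
        # sensory integrator (ST/IT): semi-linear to carry feedback modulation
        "ST": UnitParams(K=6.0, phi=0.75, delta=0.3),
        # gating neurons: fast, steep winner-take-all
        "MTL": UnitParams(K=10.0, phi=0.65, delta=0.5, w_ei=0.0, w_ie=1.5),
        "FS": UnitParams(K=8.0, phi=0.5, delta=0.5),
        # delay-activity units: steep, thresholded, slow decay (hysteresis)
        "D1": UnitParams(K=10.0, phi=0.505, delta=0.2),
        "D2": UnitParams(K=10.0, phi=1.15, delta=0.2, w_ie=0.5),
        "R": UnitParams(K=12.0, phi=1.9, delta=0.5),
        # anterior insula: graded competition pair
        "aINS": UnitParams(K=8.0, phi=0.55, delta=0.5, w_ei=0.0, w_ie=0.8),
    }


#: inter-module projection weights, keyed "source->target"; "~I" suffix means
#: the projection terminates on the target's inhibitory interneurons.
_DEFAULT_WEIGHTS: dict[str, float] = {
    # --- auditory stream (feedforward) ---
    "A1_up->A2_up": 1.3,
    "A1_down->A2_down": 1.3,
    "A2_up->A2_contour": 0.9,
    "A2_down->A2_contour": 0.9,
    "A2_up->ST": 1.2,
    "A2_down->ST": 1.2,
    "A2_contour->ST": 1.2,
    "ST->FS_a": 1.1,
    # --- visual stream (feedforward) ---
    "V1->V4": 1.1,
    "V4->IT": 1.2,
    "IT->FS_v": 1.1,
    # --- prefrontal working-memory loops (per slot, topographic) ---
    "D1_a->D2_a": 1.1,
    "D2_a->D1_a": 1.1,
    "D1_v->D2_v": 1.1,
    "D2_v->D1_v": 1.1,
    # --- response readout ---
    "FS_a->R_a": 2.2,
    "D2_a->R_a": 0.8,
    "FS_v->R_v": 2.2,
    "D2_v->R_v": 0.8,
    # --- capacity pressure: competition among working-memory slots ---
    "D2_slot_compete": 2.5,
    # --- prefrontal feedback (the load-effect pathway; ablatable) ---
    "D2_a->ST": 0.06,
    "D2_a->A2": 0.10,
    "D2_v->IT": 0.10,
    "D2_v->V4": 0.10,
    # --- exogenous attention (anterior insula) ---
    "ST->aINS_a": 3.6,
    "IT->aINS_v": 3.6,
    "aINS_a->aINS_v~I": 2.0,
    "aINS_v->aINS_a~I": 2.0,
    # feedforward cross-stream inhibition: salience as inter-modality contrast
    "IT->aINS_a~I": 3.0,
    "ST->aINS_v~I": 3.0,
    # --- task-specification relays -> D2 diffuse bias ---
    "ATT_a->D2_a": 1.0,
    "ATT_v->D2_v": 1.0,
    # --- external input gains ---
    "input->A1": 1.6,
    "input->V1": 1.45,
}


def _update_dataclass(obj: Any, data: Mapping[str, Any]) -> None:
    for key, value in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key: {key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, Mapping):
            _update_dataclass(current, value)
        elif isinstance(current, dict) and isinstance(value, Mapping):
            for k, v in value.items():
                if key == "units":
                    if isinstance(v, Mapping):
                        base = current.get(k)
                        merged = dataclasses.asdict(base) if base else {}
                        merged.update(v)
                        current[k] = UnitParams(**merged)
                    else:
                        raise TypeError(f"units[{k!r}] must be a mapping")
                else:
                    current[k] = v
        else:
            setattr(obj, key, value)


def load_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> Config:
    """Build a :class:`Config`, optionally updated from a YAML/JSON file.

    Parameters
    ----------
    path
        Optional path to a YAML (or JSON) mapping mirroring the Config tree;
        only the keys present are overridden.
    overrides
        Optional in-memory mapping applied after the file.
    """
    cfg = Config()
    if path is not None:
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data:
            _update_dataclass(cfg, data)
    if overrides:
        _update_dataclass(cfg, overrides)
    return cfg
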