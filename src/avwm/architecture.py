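"""Network architecture: module roster, projections, gating, and attention.

The model is two parallel cortical object-processing hierarchies joined by
an anterior-insula (aINS) salience module:

* auditory: A1 (up/down sweep-selective, 1 x 81 tonotopic) -> A2 (up/down/
  contour-selective) -> ST (feature integrator) -> MTL (gating) -> PFC
  (FS cue units, three D1/D2 working-memory slots, R response units)
* visual: V1/V2 -> V4 -> IT -> EC (gating) -> PFC, all 9 x 9 arrays

Arrows are excitatory projections; inhibitory edges terminate on the
receiving module's interneurons.  Prefrontal D2 units send feedback to
ST/IT and (more weakly) to A2/V4 — the pathway mediating the working-memory
load effect on intersensory distraction.  The aINS pair receives the mean
outputs of IT and ST and competes by mutual inhibition; its smoothed output
is the exogenous attention added to the endogenous (task) attention and
injected diffusely into the D2 units via task-specification relay units.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np

from . import dynamics
from .config import Config

N_CHANNELS = 81  # tonotopic axis length; 9 x 9 modules flatten to the same size


@dataclass(frozen=True)
class ModuleInfo:
    """Static description of one module array."""

    name: str
    shape: tuple[int, ...]
    unit_type: str          # key into Config.units
    region: str             # fMRI region this module belongs to
    modality: str           # "a", "v" or "x"
    location_label: str = ""  # Talairach coordinate metadata
    relay: bool = False


#: Talairach coordinates carried as metadata labels on outputs.
TALAIRACH = {
    "A1": "(51, -24, 8)",
    "A2": "(61, -36, 12)",
    "ST": "(59, -20, 1)",
    "MTL": "(22, -30, -12)",
    "V1": "(14, -86, 7)",
    "V4": "(30, -70, -7)",
    "IT": "(31, -39, -6)",
    "EC": "(25, -12, -25)",
    "FS_v": "(35, 19, 13)",
    "FS_a": "(47, 19, 9)",
    "D1_v": "(51, 12, 10)",
    "D1_a": "(43, 29, 21)",
    "D2_v": "(32, 29, 8)",
    "D2_a": "(42, 39, 2)",
    "R_v": "(33, 13, 28)",
    "R_a": "(29, 25, 40)",
    "aINS": "(48, 12, 4)",
}

N_SLOTS = 3  # working-memory capacity: three D1/D2 slot replicas per modality


def _roster() -> dict[str, ModuleInfo]:
    mods: dict[str, ModuleInfo] = {}

    def add(name, shape, unit_type, region, modality, loc=""):
        mods[name] = ModuleInfo(name, shape, unit_type, region, modality, loc)

    # auditory stream
    add("A1_up", (1, 81), "A1", "A1", "a", TALAIRACH["A1"])
    add("A1_down", (1, 81), "A1", "A1", "a", TALAIRACH["A1"])
    add("A2_up", (1, 81), "A2", "A2", "a", TALAIRACH["A2"])
    add("A2_down", (1, 81), "A2", "A2", "a", TALAIRACH["A2"])
    add("A2_contour", (1, 81), "A2_contour", "A2", "a", TALAIRACH["A2"])
    add("ST", (9, 9), "ST", "ST", "a", TALAIRACH["ST"])
    add("MTL", (9, 9), "MTL", "MTL", "a", TALAIRACH["MTL"])
    add("FS_a", (9, 9), "FS", "PFC_a", "a", TALAIRACH["FS_a"])
    for k in range(1, N_SLOTS + 1):
        add(f"D1_a_{k}", (9, 9), "D1", "PFC_a", "a", TALAIRACH["D1_a"])
        add(f"D2_a_{k}", (9, 9), "D2", "PFC_a", "a", TALAIRACH["D2_a"])
    add("R_a", (9, 9), "R", "PFC_a", "a", TALAIRACH["R_a"])
    # visual stream
    add("V1", (9, 9), "V1", "V1", "v", TALAIRACH["V1"])
    add("V4", (9, 9), "V4", "V4", "v", TALAIRACH["V4"])
    add("IT", (9, 9), "ST", "IT", "v", TALAIRACH["IT"])
    add("EC", (9, 9), "MTL", "EC", "v", TALAIRACH["EC"])
    add("FS_v", (9, 9), "FS", "PFC_v", "v", TALAIRACH["FS_v"])
    for k in range(1, N_SLOTS + 1):
        add(f"D1_v_{k}", (9, 9), "D1", "PFC_v", "v", TALAIRACH["D1_v"])
        add(f"D2_v_{k}", (9, 9), "D2", "PFC_v", "v", TALAIRACH["D2_v"])
    add("R_v", (9, 9), "R", "PFC_v", "v", TALAIRACH["R_v"])
    # salience and task-specification units
    add("aINS_a", (1,), "aINS", "aINS", "a", TALAIRACH["aINS"])
    add("aINS_v", (1,), "aINS", "aINS", "v", TALAIRACH["aINS"])
    mods["ATT_a"] = ModuleInfo("ATT_a", (1,), "FS", "ATT", "a", relay=True)
    mods["ATT_v"] = ModuleInfo("ATT_v", (1,), "FS", "ATT", "v", relay=True)
    return mods


MODULE_INFO: dict[str, ModuleInfo] = _roster()

#: fMRI region -> constituent module arrays
REGION_MAP: dict[str, list[str]] = {}
for _m in MODULE_INFO.values():
    REGION_MAP.setdefault(_m.region, []).append(_m.name)


@dataclass
class Projection:
    """A directed, signed, weighted connection between two module arrays.

    ``pattern`` is "topographic" (unit-to-unit, modules share the flat
    81-unit geometry), "diffuse" (source mean broadcast to every target
    unit), or "gated" (topographic routing modulated by the gating-group
    activity; applied by the gating controller, not the generic stepper).
    ``to_inhibitory`` edges terminate on the target's interneurons and are
    functionally inhibitory.
    """

    source: str
    target: str
    weight: float
    pattern: str = "topographic"
    to_inhibitory: bool = False
    special: bool = False
    enabled: bool = True

    @property
    def key(self) -> str:
        return f"{self.source}->{self.target}" + ("~I" if self.to_inhibitory else "")

    @property
    def sign(self) -> str:
        return "inhibitory-via-interneurons" if self.to_inhibitory else "excitatory"


def _slot_names(prefix: str) -> list[str]:
    return [f"{prefix}_{k}" for k in range(1, N_SLOTS + 1)]


def default_edges(cfg: Config) -> list[Projection]:
    """Expand the configured weight table into the concrete edge list."""
    w = cfg.weights
    g = cfg.gating
    edges: list[Projection] = []

    def topo(src, dst, weight, **kw):
        edges.append(Projection(src, dst, weight, "topographic", **kw))

    def diffuse(src, dst, weight, **kw):
        edges.append(Projection(src, dst, weight, "diffuse", **kw))

    # auditory feedforward
    topo("A1_up", "A2_up", w["A1_up->A2_up"])
    topo("A1_down", "A2_down", w["A1_down->A2_down"])
    topo("A2_up", "A2_contour", w["A2_up->A2_contour"])
    topo("A2_down", "A2_contour", w["A2_down->A2_contour"])
    for src in ("A2_up", "A2_down", "A2_contour"):
        topo(src, "ST", w[f"{src}->ST"])
    topo("ST", "FS_a", w["ST->FS_a"])
    # visual feedforward
    topo("V1", "V4", w["V1->V4"])
    topo("V4", "IT", w["V4->IT"])
    topo("IT", "FS_v", w["IT->FS_v"])
    # gating: sensory integrator -> gate (diffuse onset transient), gated
    # routing gate->D1, and slot-specific prefrontal suppression of the
    # consumed gate group
    edges.append(Projection("ST", "MTL", g.w_in, "diffuse", special=True))
    edges.append(Projection("IT", "EC", g.w_in, "diffuse", special=True))
    for mod, gate in (("a", "MTL"), ("v", "EC")):
        for k, d1 in enumerate(_slot_names(f"D1_{mod}"), 1):
            edges.append(Projection(gate, d1, g.w_route, "gated", special=True))
            edges.append(Projection(f"D2_{mod}_{k}", gate, g.w_pfc_fb,
                                    "gated", to_inhibitory=True, special=True))
    # working-memory loops, capacity competition, and readout
    for mod in ("a", "v"):
        for k in range(1, N_SLOTS + 1):
            topo(f"D1_{mod}_{k}", f"D2_{mod}_{k}", w[f"D1_{mod}->D2_{mod}"])
            topo(f"D2_{mod}_{k}", f"D1_{mod}_{k}", w[f"D2_{mod}->D1_{mod}"])
            topo(f"D2_{mod}_{k}", f"R_{mod}", w[f"D2_{mod}->R_{mod}"])
            for j in range(1, N_SLOTS + 1):
                if j != k:
                    diffuse(f"D2_{mod}_{k}", f"D2_{mod}_{j}",
                            w["D2_slot_compete"], to_inhibitory=True)
        topo(f"FS_{mod}", f"R_{mod}", w[f"FS_{mod}->R_{mod}"])
    # prefrontal feedback (ablatable; mediates the load effect)
    for k in range(1, N_SLOTS + 1):
        topo(f"D2_a_{k}", "ST", w["D2_a->ST"])
        topo(f"D2_a_{k}", "A2_up", w["D2_a->A2"])
        topo(f"D2_a_{k}", "A2_down", w["D2_a->A2"])
        topo(f"D2_v_{k}", "IT", w["D2_v->IT"])
        topo(f"D2_v_{k}", "V4", w["D2_v->V4"])
    # salience competition: direct drive, output mutual inhibition, and
    # feedforward cross-stream inhibition (inter-modality contrast)
    diffuse("ST", "aINS_a", w["ST->aINS_a"])
    diffuse("IT", "aINS_v", w["IT->aINS_v"])
    topo("aINS_a", "aINS_v", w["aINS_a->aINS_v~I"], to_inhibitory=True)
    topo("aINS_v", "aINS_a", w["aINS_v->aINS_a~I"], to_inhibitory=True)
    diffuse("IT", "aINS_a", w["IT->aINS_a~I"], to_inhibitory=True)
    diffuse("ST", "aINS_v", w["ST->aINS_v~I"], to_inhibitory=True)
    # task-specification attention bias into D2
    for mod in ("a", "v"):
        for d2 in _slot_names(f"D2_{mod}"):
            diffuse(f"ATT_{mod}", d2, w[f"ATT_{mod}->D2_{mod}"])
    return edges


class GatingState:
    """Use-once working-memory gating state for one modality.

    ``n_groups`` groups of gating neurons compete by winner-take-all; the
    open group routes the sensory pattern into its dedicated D1/D2 slot.
    Once the slot's activity confirms storage, prefrontal feedback
    suppresses the group and it is marked used for the rest of the trial.
    """

    def __init__(self, n_groups: int, n_units: int):
        self.n_groups = n_groups
        if n_units % n_groups:
            raise ValueError("gating module size must divide evenly into groups")
        size = n_units // n_groups
        self.slices = [slice(i * size, (i + 1) * size) for i in range(n_groups)]
        self.used = np.zeros(n_groups, dtype=bool)
        self.open_levels = np.zeros(n_groups)
        #: per-channel slow trace of the sensory drive; the gate responds to
        #: the mean rectified onset transient, so an already-represented
        #: (adapted) pattern cannot retrigger gating
        self.adapt = np.zeros(n_units)
        #: fast smoothed sensory trace (suppresses frame-level flicker)
        self.sens_smooth = np.zeros(n_units)

    def reset(self) -> None:
        self.used[:] = False
        self.open_levels[:] = 0.0
        self.adapt[:] = 0.0
        self.sens_smooth[:] = 0.0

    @property
    def active(self) -> int | None:
        """Index of the currently open group, or None."""
        if self.open_levels.max() <= 0:
            return None
        return int(np.argmax(self.open_levels))

    @property
    def n_free(self) -> int:
        return int((~self.used).sum())


class AttentionState:
    """Endogenous + exogenous attention per modality.

    ``exo`` is an affine map of the moving-average aINS output; ``total``
    is ``clip(endo + exo, 0, att_max)`` and is what the D2 units receive.
    """

    def __init__(self, cfg: Config):
        self.cfg = cfg.attention
        n_smooth = max(1, int(round(self.cfg.smooth_ms / cfg.dt_ms)))
        self._buf_v: collections.deque = collections.deque(maxlen=n_smooth)
        self._buf_a: collections.deque = collections.deque(maxlen=n_smooth)
        self.endo_v = 0.0
        self.endo_a = 0.0
        self.exo_v = 0.0
        self.exo_a = 0.0

    def reset(self) -> None:
        self._buf_v.clear()
        self._buf_a.clear()
        self.endo_v = self.endo_a = 0.0
        self.exo_v = self.exo_a = 0.0

    def set_endo(self, endo_v: float, endo_a: float) -> None:
        self.endo_v = endo_v
        self.endo_a = endo_a

    def update_exo(self, ains_v: float, ains_a: float) -> None:
        self._buf_v.append(ains_v)
        self._buf_a.append(ains_a)
        c = self.cfg
        self.exo_v = max(0.0, c.exo_gain * (np.mean(self._buf_v) - c.exo_baseline))
        self.exo_a = max(0.0, c.exo_gain * (np.mean(self._buf_a) - c.exo_baseline))

    @property
    def total_v(self) -> float:
        return float(np.clip(self.endo_v + self.exo_v, 0.0, self.cfg.att_max))

    @property
    def total_a(self) -> float:
        return float(np.clip(self.endo_a + self.exo_a, 0.0, self.cfg.att_max))


class Network:
    """The wired model: module arrays, projections, gating and attention."""

    def __init__(self, config: Config, edges: list[Projection] | None = None):
        self.config = config
        self.modules: dict[str, dynamics.ModuleArray] = {}
        for info in MODULE_INFO.values():
            params = config.units[info.unit_type]
            self.modules[info.name] = dynamics.ModuleArray(
                info.name, info.shape, params, relay=info.relay)
        if edges is None:
            edges = default_edges(config)
        if not edges:
            raise ValueError("network edge list is empty")
        for p in edges:
            for endpoint in (p.source, p.target):
                if endpoint not in self.modules:
                    raise ValueError(f"projection references unknown module {endpoint!r}")
        self.projections = edges
        self._proj_index = {p.key: p for p in edges}
        self._build_packed_state()
        g = config.gating
        self.gating = {
            "a": GatingState(g.n_groups, self.modules["MTL"].n),
            "v": GatingState(g.n_groups, self.modules["EC"].n),
        }
        self.attention = AttentionState(config)
        self._step_count = 0
        # prebound gating projections and per-step slot-strength cache
        self._gating_bind = {}
        for mod, gate_name, sens_name in (("a", "MTL", "ST"), ("v", "EC", "IT")):
            routes = [self._proj_index[f"{gate_name}->D1_{mod}_{k + 1}"]
                      for k in range(g.n_groups)]
            fbs = [self._proj_index[f"D2_{mod}_{k + 1}->{gate_name}~I"]
                   for k in range(g.n_groups)]
            drive = self._proj_index[f"{sens_name}->{gate_name}"]
            self._gating_bind[mod] = (gate_name, sens_name, drive, routes, fbs)
        self._slot_cache = {"a": np.zeros(g.n_groups), "v": np.zeros(g.n_groups)}

    def _build_packed_state(self) -> None:
        """Pack the integrated (non-relay) modules into flat state vectors.

        Each ModuleArray's E/I become views into one contiguous vector, so
        the Euler update runs as a single vectorized operation; per-module
        accumulator views are what projections and gating write into.
        """
        packed = [m for m in self.modules.values() if not m.relay]
        n_total = sum(m.n for m in packed)
        self._packed_names = [m.name for m in packed]
        self._offsets = {}
        self._E_all = np.zeros(n_total)
        self._I_all = np.zeros(n_total)
        self._accE_all = np.zeros(n_total)
        self._accI_all = np.zeros(n_total)
        self._K = np.empty(n_total)
        self._phi = np.empty(n_total)
        self._delta = np.empty(n_total)
        self._w_ie = np.empty(n_total)
        self._w_ei = np.empty(n_total)
        self._noise_mask = np.empty(n_total)
        self._accE = {}
        self._accI = {}
        pos = 0
        for m in packed:
            sl = slice(pos, pos + m.n)
            self._offsets[m.name] = sl
            m.E = self._E_all[sl]
            m.I = self._I_all[sl]
            self._accE[m.name] = self._accE_all[sl]
            self._accI[m.name] = self._accI_all[sl]
            p = m.params
            self._K[sl], self._phi[sl], self._delta[sl] = p.K, p.phi, p.delta
            self._w_ie[sl], self._w_ei[sl] = p.w_ie, p.w_ei
            self._noise_mask[sl] = 1.0 if m.noisy else 0.0
            pos += m.n
        #: reduceat boundaries for per-module sums (synaptic bookkeeping)
        self._bounds = np.array([self._offsets[n].start for n in self._packed_names])
        for m in self.modules.values():
            if m.relay:
                self._accE[m.name] = np.zeros(m.n)
                self._accI[m.name] = np.zeros(m.n)

    def module_means(self) -> dict[str, float]:
        """Mean excitatory activity per module (single vectorized pass)."""
        sums = np.add.reduceat(self._E_all, self._bounds)
        out = {}
        for name, tot in zip(self._packed_names, sums):
            out[name] = tot / self.modules[name].n
        for m in self.modules.values():
            if m.relay:
                out[m.name] = float(m.E.mean())
        return out

    # ------------------------------------------------------------------
    def reset(self) -> None:
        """Return to the quiescent state (fresh trial)."""
        self._E_all.fill(0.0)
        self._I_all.fill(0.0)
        for m in self.modules.values():
            if m.relay:
                m.reset()
        for gs in self.gating.values():
            gs.reset()
        self.attention.reset()
        self._step_count = 0
        for v in self._slot_cache.values():
            v.fill(0.0)

    def projection(self, key: str) -> Projection:
        try:
            return self._proj_index[key]
        except KeyError:
            raise KeyError(f"no projection {key!r} in the network") from None

    def set_projection_enabled(self, key: str, enabled: bool) -> None:
        self.projection(key).enabled = enabled

    def ablate_feedback(self) -> list[str]:
        """Disable the D2 -> IT/ST and D2 -> V4/A2 feedback edges."""
        removed = []
        for p in self.projections:
            if p.source.startswith("D2_") and p.target in (
                    "ST", "IT", "A2_up", "A2_down", "V4"):
                p.enabled = False
                removed.append(p.key)
        return removed

    def restore_feedback(self) -> None:
        for p in self.projections:
            p.enabled = True

    # ------------------------------------------------------------------
    def apply_special_inputs(self, accE: dict[str, np.ndarray],
                             accI: dict[str, np.ndarray]) -> None:
        """Gating winner-take-all, gated routing, and attention bias."""
        g = self.config.gating
        for mod, (gate_name, sens_name, drive, routes, fbs) in self._gating_bind.items():
            gs = self.gating[mod]
            gate = self.modules[gate_name]
            sens_E = self.modules[sens_name].E
            group_means = np.array([gate.E[sl].mean() for sl in gs.slices])
            total = group_means.sum()
            relu = np.clip(gs.sens_smooth - gs.adapt, 0.0, None)
            # pattern-level onset: mean over the most novel channels, so a
            # compact new object registers as strongly as a broad one
            onset = float(np.partition(relu, relu.size - 15)[-15:].mean())
            slot_cache = self._slot_cache[mod]
            for i, sl in enumerate(gs.slices):
                # a consumed (used) group no longer receives the onset drive
                if drive.enabled and not gs.used[i]:
                    accE[gate_name][sl] += drive.weight * onset
                    # baseline excitability plus a deterministic tie-break
                    # favoring lower group indices
                    accE[gate_name][sl] += (g.base_bias
                                            + g.tie_bias * (gs.n_groups - 1 - i))
                # cross-group winner-take-all inhibition
                accI[gate_name][sl] += g.w_wta * (total - group_means[i])
                if routes[i].enabled and group_means[i] > 1e-4:
                    accE[f"D1_{mod}_{i + 1}"] += routes[i].weight * group_means[i] * sens_E
                if fbs[i].enabled:
                    accI[gate_name][sl] += fbs[i].weight * slot_cache[i]
            gs.open_levels = group_means

    def post_step(self) -> None:
        """Book-keeping after each Euler step: storage flags, attention."""
        g = self.config.gating
        for mod, sens_name in (("a", "ST"), ("v", "IT")):
            gs = self.gating[mod]
            sens_E = self.modules[sens_name].E
            gs.sens_smooth += self.config.h * 0.6 * (sens_E - gs.sens_smooth)
            gs.adapt += self.config.h * g.adapt_rate * (gs.sens_smooth - gs.adapt)
            cache = self._slot_cache[mod]
            for k in range(g.n_groups):
                cache[k] = self.slot_strength(mod, k + 1)
            for k in range(g.n_groups):
                # a slot only receives content through its own gating group,
                # so a stored slot marks its group as consumed
                if not gs.used[k] and cache[k] > g.store_threshold:
                    gs.used[k] = True
                    # storage consumes the novelty signal: only a fresh
                    # sensory onset can trigger the next gating event
                    np.maximum(gs.adapt, gs.sens_smooth, out=gs.adapt)
        self.attention.update_exo(
            float(self.modules["aINS_v"].E[0]), float(self.modules["aINS_a"].E[0]))
        self.modules["ATT_v"].E[0] = self.attention.total_v
        self.modules["ATT_a"].E[0] = self.attention.total_a
        self._step_count += 1

    # ------------------------------------------------------------------
    def slot_strength(self, modality: str, k: int, n_top: int = 15) -> float:
        """Mean activity of the most active units of a D2 slot.

        Stimulus patterns activate a sparse subset of the 81 units, so the
        module-wide mean underestimates the stored trace; the mean over the
        top ``n_top`` units tracks the pattern's activity level.
        """
        E = self.modules[f"D2_{modality}_{k}"].E
        return float(np.partition(E, E.size - n_top)[-n_top:].mean())

    def slot_strengths(self, modality: str) -> np.ndarray:
        return self._slot_cache[modality].copy()

    def step(self, drives=None, rng: np.random.Generator | None = None,
             syn_out: dict[str, float] | None = None) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        dynamics.step_network(self, drives, rng, self._step_count, syn_out)

    def run(self, duration_ms: float, drivers=None, seed: int | None = 0,
            **kw) -> dynamics.ActivityRecord:
        return dynamics.run(self, duration_ms, drivers, seed=seed, **kw)


def build_network(config: Config | None = None,
                  edges: list[Projection] | None = None) -> Network:
    """Construct the wired auditory-visual network from a configuration."""
    if config is None:
        config = Config()
    return Network(config, edges=edges)


def compute_exogenous(it_drive: float, st_drive: float, config: Config | None = None,
                      duration_ms: float = 600.0) -> tuple[float, float]:
    """Steady-state exogenous attention pair for constant aINS drives.

    ``it_drive``/``st_drive`` are module-mean excitatory activities of IT
    and ST (already reflecting stimulus saliency).  Integrates the isolated
    mutually inhibitory aINS pair to steady state and returns (exo_v, exo_a)
    through the same affine output map the full network uses.
    """
    if config is None:
        config = Config()
    p = config.units["aINS"]
    w_in = config.weights["IT->aINS_v"]
    w_x = config.weights["aINS_a->aINS_v~I"]
    h = config.h
    Ev = Ea = Iv = Ia = 0.0
    n = int(round(duration_ms / config.dt_ms))
    for _ in range(n):
        inEv = w_in * it_drive - p.w_ie * Iv
        inEa = w_in * st_drive - p.w_ie * Ia
        inIv = w_x * Ea
        inIa = w_x * Ev
        Ev += h * (dynamics.sigmoid(inEv, p.K, p.phi) * (1 - Ev) - p.delta * Ev)
        Ea += h * (dynamics.sigmoid(inEa, p.K, p.phi) * (1 - Ea) - p.delta * Ea)
        Iv += h * (dynamics.sigmoid(inIv, p.K, p.phi) * (1 - Iv) - p.delta * Iv)
        Ia += h * (dynamics.sigmoid(inIa, p.K, p.phi) * (1 - Ia) - p.delta * Ia)
        Ev, Ea = min(max(Ev, 0.0), 1.0), min(max(Ea, 0.0), 1.0)
        Iv, Ia = min(max(Iv, 0.0), 1.0), min(max(Ia, 0.0), 1.0)
    a = config.attention
    exo_v = max(0.0, a.exo_gain * (Ev - a.exo_baseline))
    exo_a = max(0.0, a.exo_gain * (Ea - a.exo_baseline))
    return exo_v, exo_a


def inject_attention(state: AttentionState, network: Network) -> tuple[float, float]:
    """Write the combined attention values into the task-specification relays.

    The relays project diffusely onto every D2 unit of their modality, so
    this is the uniform additive bias the working-memory slots receive.
    Returns (total_v, total_a).
    """
    network.modules["ATT_v"].E[0] = state.total_v
    network.modules["ATT_a"].E[0] = state.total_a
    return state.total_v, state.total_a
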