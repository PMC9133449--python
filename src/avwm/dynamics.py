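"""Wilson-Cowan microcircuit dynamics and the network time-stepping engine.

Each basic unit is a pair of rate variables (E, I) representing the
pyramidal and interneuron populations of a cortical column.  Both follow a
shunting forward-Euler update

    E <- E + h * ( S(in_E) * (1 - E) - delta * E )

with S the logistic sigmoid, ``in_E`` the summed synaptic input (afferent
excitation, local inhibition ``-w_ie * I``, diffuse attention bias, and
additive Gaussian noise), and activities clamped to [0, 1].  There are no
transmission delays between modules; temporal structure arises from the
sigmoid rise times and per-module decay rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import UnitParams

if TYPE_CHECKING:  # pragma: no cover
    from .architecture import Network


def sigmoid(x: np.ndarray | float, K: float, phi: float) -> np.ndarray | float:
    """Logistic activation 1 / (1 + exp(-K * (x - phi))).

    Overflow-safe for arbitrarily large ``|x|`` (uses :func:`scipy.special.expit`).
    Strictly increasing in ``x`` for K > 0.
    """
    return expit(K * (np.asarray(x, dtype=float) - phi))


class ModuleArray:
    """State of one (sub)module: a 1-D array of E/I unit pairs.

    Two-dimensional modules (9 x 9) are stored flattened row-major; the
    tonotopic 1 x 81 modules are stored as-is.  ``relay`` modules (the
    task-specification attention units) have their E value written directly
    by the attention controller and are not integrated.
    """

    __slots__ = ("name", "n", "shape", "params", "E", "I", "relay", "noisy")

    def __init__(self, name: str, shape: tuple[int, ...], params: UnitParams,
                 relay: bool = False, noisy: bool = True):
        self.name = name
        self.shape = shape
        self.n = int(np.prod(shape))
        self.params = params
        self.relay = relay
        self.noisy = noisy and not relay
        self.E = np.zeros(self.n)
        self.I = np.zeros(self.n)

    def reset(self) -> None:
        self.E.fill(0.0)
        self.I.fill(0.0)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ModuleArray({self.name!r}, shape={self.shape})"


def euler_update(E: np.ndarray, I: np.ndarray, in_E: np.ndarray, in_I: np.ndarray,
                 p: UnitParams, h: float) -> None:
    """One clamped shunting-Euler step, in place."""
    E += h * (sigmoid(in_E, p.K, p.phi) * (1.0 - E) - p.delta * E)
    I += h * (sigmoid(in_I, p.K, p.phi) * (1.0 - I) - p.delta * I)
    np.clip(E, 0.0, 1.0, out=E)
    np.clip(I, 0.0, 1.0, out=I)


def fixed_point_activity(S: float, delta: float) -> float:
    """Steady-state activity for a constant sigmoid output S: E* = S / (S + delta)."""
    return S / (S + delta)


def step_network(net: "Network", drives: Mapping[str, np.ndarray] | None,
                 rng: np.random.Generator, step_index: int = 0,
                 syn_out: dict[str, float] | None = None) -> None:
    """Advance the whole network by one time step, in place.

    Parameters
    ----------
    drives
        Mapping from module name to external input current (array broadcast
        to the module size), already scaled by the input gain and saliency.
    syn_out
        If given, filled with this step's per-module summed absolute
        synaptic input (all afferent, local and bias terms; noise excluded),
        the quantity integrated by the hemodynamic stage.
    """
    accE = net._accE
    accI = net._accI
    net._accE_all.fill(0.0)
    net._accI_all.fill(0.0)
    for buf in (accE[m.name] for m in net.modules.values() if m.relay):
        buf.fill(0.0)

    if drives:
        for name, drive in drives.items():
            if name not in accE:
                raise KeyError(f"drive targets unknown module {name!r}")
            accE[name] += drive

    for p in net.projections:
        if not p.enabled or p.special:
            continue
        src = net.modules[p.source].E
        contrib = p.weight * (src.mean() if p.pattern == "diffuse" else src)
        if p.to_inhibitory:
            accI[p.target] += contrib
        else:
            accE[p.target] += contrib

    # gating routing, winner-take-all, tie-breaks, attention bias
    net.apply_special_inputs(accE, accI)

    if syn_out is not None:
        local = (np.abs(net._accE_all) + np.abs(net._accI_all)
                 + net._w_ie * net._I_all + net._w_ei * net._E_all)
        sums = np.add.reduceat(local, net._bounds)
        for name, tot in zip(net._packed_names, sums):
            syn_out[name] = float(tot)
        for m in net.modules.values():
            if m.relay:
                syn_out[m.name] = float(np.abs(accE[m.name]).sum())

    # vectorized shunting-Euler update over the packed state
    in_E = net._accE_all - net._w_ie * net._I_all
    amp = net.config.noise_amplitude
    if amp > 0:
        in_E += (amp * net._noise_mask) * rng.standard_normal(in_E.size)
    in_I = net._accI_all + net._w_ei * net._E_all
    if not (np.isfinite(in_E).all() and np.isfinite(in_I).all()):
        bad = ~np.isfinite(in_E) | ~np.isfinite(in_I)
        idx = int(np.flatnonzero(bad)[0])
        for name in net._packed_names:
            sl = net._offsets[name]
            if sl.start <= idx < sl.stop:
                raise FloatingPointError(
                    f"non-finite synaptic input at step {step_index}, "
                    f"module {name!r}, unit {idx - sl.start}")
        raise FloatingPointError(f"non-finite synaptic input at step {step_index}")
    h = net.config.h
    E, I = net._E_all, net._I_all
    SE = expit(net._K * (in_E - net._phi))
    SI = expit(net._K * (in_I - net._phi))
    E += h * (SE * (1.0 - E) - net._delta * E)
    I += h * (SI * (1.0 - I) - net._delta * I)
    np.clip(E, 0.0, 1.0, out=E)
    np.clip(I, 0.0, 1.0, out=I)

    net.post_step()


@dataclass
class ActivityRecord:
    """Full per-unit activity time series of a run.

    ``E[name]`` has shape (n_steps, n_units); ``syn[name]`` is the
    per-module summed absolute synaptic input per step (the input to the
    hemodynamic forward model, before 50 ms binning).
    """

    dt_ms: float
    E: dict[str, np.ndarray]
    I: dict[str, np.ndarray]
    syn: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return next(iter(self.E.values())).shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt_ms

    def to_frame(self, modules: Iterable[str] | None = None,
                 include_I: bool = True) -> pd.DataFrame:
        """Long-format activity table: (time_ms, module, submodule, unit_row, unit_col, E, I)."""
        from .architecture import MODULE_INFO

        rows = []
        t = self.times_ms
        names = list(self.E) if modules is None else list(modules)
        for name in names:
            info = MODULE_INFO[name]
            e = self.E[name]
            i = self.I.get(name)
            nrow, ncol = info.shape if len(info.shape) == 2 else (1, info.shape[0])
            for u in range(e.shape[1]):
                df = pd.DataFrame({
                    "time_ms": t,
                    "module": info.region,
                    "submodule": name,
                    "unit_row": u // ncol,
                    "unit_col": u % ncol,
                    "E": e[:, u],
                })
                df["I"] = i[:, u] if (include_I and i is not None) else np.nan
                rows.append(df)
        return pd.concat(rows, ignore_index=True)


def run(net: "Network", duration_ms: float,
        drivers: Callable[[int], Mapping[str, np.ndarray] | None] | None = None,
        seed: int | None = 0, record_I: bool = True,
        record_syn: bool = True, reset: bool = True) -> ActivityRecord:
    """Run the network for ``duration_ms`` and record every unit's activity.

    ``drivers`` maps a step index to the external drive dict for that step
    (None for a spontaneous run).  ``duration_ms`` must be a multiple of the
    integration step.  Identical seed and configuration yield bit-identical
    output.
    """
    dt = net.config.dt_ms
    n_steps_f = duration_ms / dt
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9 or n_steps <= 0:
        raise ValueError(f"duration {duration_ms} ms is not a positive multiple of dt={dt} ms")
    if reset:
        net.reset()
    rng = np.random.default_rng(seed)
    E = {m.name: np.empty((n_steps, m.n)) for m in net.modules.values()}
    I = {m.name: np.empty((n_steps, m.n)) for m in net.modules.values()} if record_I else {}
    syn = {m.name: np.empty(n_steps) for m in net.modules.values()} if record_syn else {}
    syn_step: dict[str, float] | None = {} if record_syn else None
    for k in range(n_steps):
        drives = drivers(k) if drivers is not None else None
        step_network(net, drives, rng, step_index=k, syn_out=syn_step)
        for name, mod in net.modules.items():
            E[name][k] = mod.E
            if record_I:
                I[name][k] = mod.I
            if record_syn:
                syn[name][k] = syn_step[name]
    return ActivityRecord(dt_ms=dt, E=E, I=I, syn=syn)
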