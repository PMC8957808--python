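"""Leaky firing-rate dynamics.

Each unit represents a neural population with voltage ``V`` obeying

    tau * dV/dt = -V + I + sum_pre w[post, pre] * F(V_pre)

integrated with the explicit Euler method, and firing rate
``F(V) = [tanh(V)]+`` (positive part), which confines rates to [0, 1].
Voltages are unbounded (inhibition may drive them negative); only the
rate is rectified. Updates are synchronous: every unit's new voltage is
computed from the rates of the previous step, so the result does not
depend on unit ordering. The dynamics are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "SimParams",
    "NetworkState",
    "ConfigurationError",
    "SimulationDivergence",
    "activation",
    "euler_step",
    "run_timesteps",
]


class ConfigurationError(ValueError):
    """A network, protocol, or manipulation is internally inconsistent."""


class SimulationDivergence(RuntimeError):
    """A voltage became non-finite during integration."""


@dataclass(frozen=True)
class SimParams:
    """Integration parameters.

    dt and tau are in the same (dimensionless) time units; the explicit
    Euler leak term is stable only for dt/tau <= 1. One behavioral trial
    lasts ``trial_length`` steps.
    """

    dt: float = 0.1
    tau: float = 1.0
    trial_length: int = 500

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if not (self.tau > 0):
            raise ConfigurationError(f"tau must be positive, got {self.tau}")
        if self.trial_length < 1:
            raise ConfigurationError(
                f"trial_length must be >= 1, got {self.trial_length}"
            )
        if self.dt / self.tau > 1.0 + 1e-12:
            raise ConfigurationError(
                f"dt/tau = {self.dt / self.tau:.3g} > 1 is unstable for the Euler leak"
            )

    @property
    def leak(self) -> float:
        """The Euler gain dt/tau."""
        return self.dt / self.tau


@dataclass
class NetworkState:
    """Voltages, rates and the current weight matrix (indexed [post, pre])."""

    V: np.ndarray
    F: np.ndarray
    W: np.ndarray

    @classmethod
    def zeros(cls, n_units: int, W: Optional[np.ndarray] = None) -> "NetworkState":
        V = np.zeros(n_units)
        if W is None:
            W = np.zeros((n_units, n_units))
        else:
            W = np.array(W, dtype=float)
            if W.shape != (n_units, n_units):
                raise ConfigurationError(
                    f"weight matrix shape {W.shape} does not match {n_units} units"
                )
        return cls(V=V, F=activation(V), W=W)

    def copy(self) -> "NetworkState":
        return NetworkState(V=self.V.copy(), F=self.F.copy(), W=self.W.copy())


def activation(v):
    """Rectified hyperbolic tangent, the population firing rate.

    Returns ``[tanh(v)]+`` elementwise: 0 for v <= 0, approaching 1 for
    large v. Raises :class:`SimulationDivergence` on non-finite input,
    which signals numerical blow-up upstream.
    """
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise SimulationDivergence("non-finite voltage passed to activation()")
    out = np.maximum(np.tanh(arr), 0.0)
    return out if arr.ndim else float(out)


def _name_of(i: int, names: Optional[Sequence[str]]) -> str:
    return names[i] if names is not None and i < len(names) else f"unit[{i}]"


def euler_step(
    state: NetworkState,
    I: np.ndarray,
    params: SimParams,
    names: Optional[Sequence[str]] = None,
) -> NetworkState:
    """One synchronous Euler step; returns a new state (inputs untouched).

    V_new = V + dt/tau * (-V + I + W @ F) using the pre-step rates F, then
    F_new = activation(V_new).
    """
    n = state.V.shape[0]
    I = np.asarray(I, dtype=float)
    if I.shape != (n,):
        raise ConfigurationError(
            f"external input has shape {I.shape}, expected ({n},)"
        )
    if state.W.shape != (n, n):
        raise ConfigurationError(
            f"weight matrix shape {state.W.shape} does not match {n} units"
        )
    V_new = state.V + params.leak * (-state.V + I + state.W @ state.F)
    bad = ~np.isfinite(V_new)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise SimulationDivergence(
            f"voltage of {_name_of(i, names)} diverged to non-finite value"
        )
    return NetworkState(V=V_new, F=activation(V_new), W=state.W)


def run_timesteps(
    state: NetworkState,
    I: np.ndarray,
    params: SimParams,
    n: int,
    plasticity_hook: Optional[Callable[[NetworkState], None]] = None,
    names: Optional[Sequence[str]] = None,
):
    """Integrate ``n`` steps under constant external input.

    The optional ``plasticity_hook`` is invoked after each step and may
    mutate ``state.W`` in place (this is how the learning rule is wired
    in). Returns ``(final_state, trace)`` where ``trace[t, i]`` is unit
    i's rate after step t.
    """
    if n < 1:
        raise ConfigurationError(f"step count must be >= 1, got {n}")
    n_units = state.V.shape[0]
    I = np.asarray(I, dtype=float)
    if I.shape != (n_units,):
        raise ConfigurationError(
            f"external input has shape {I.shape}, expected ({n_units},)"
        )
    st = state.copy()
    trace = np.empty((n, n_units))
    leak = params.leak
    V, F, W = st.V, st.F, st.W
    for t in range(n):
        V += leak * (-V + I + W @ F)
        if not np.all(np.isfinite(V)):
            i = int(np.flatnonzero(~np.isfinite(V))[0])
            raise SimulationDivergence(
                f"voltage of {_name_of(i, names)} diverged at step {t}"
            )
        np.maximum(np.tanh(V), 0.0, out=F)
        if plasticity_hook is not None:
            plasticity_hook(st)
        trace[t] = F
    return st, trace
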