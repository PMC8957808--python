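"""Simplified BCM synaptic plasticity with hard weight clipping.

The weight of a plastic connection changes by

    dW = alpha * (F_post - theta) * F_pre

per timestep: above-threshold postsynaptic activity potentiates (LTP),
below-threshold activity depresses (LTD), and a silent presynaptic unit
gates all change off. The threshold theta is fixed (no sliding-threshold
dynamics). Every plastic weight is clipped to its [w_min, w_max] range
after each update; non-plastic weights are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .dynamics import ConfigurationError, NetworkState

__all__ = ["PlasticityParams", "CompiledPlasticity", "bcm_delta", "apply_plasticity"]

Edge = Tuple[str, str]  # (pre, post)


@dataclass
class PlasticityParams:
    """Learning parameters shared by all plastic edges, with per-edge overrides.

    alpha is the learning rate per timestep; theta the BCM threshold in
    firing-rate units (rates span [0, 1], so theta splits LTD from LTP).
    ``enabled = False`` freezes every plastic weight (used by
    plasticity-freeze manipulations and as a global off switch).
    """

    alpha: float = 0.002
    theta: float = 0.5
    enabled: bool = True
    alpha_overrides: Dict[Edge, float] = field(default_factory=dict)
    theta_overrides: Dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError(f"alpha must be >= 0, got {self.alpha}")
        if not (0.0 <= self.theta <= 1.0):
            raise ConfigurationError(f"theta must lie in [0, 1], got {self.theta}")
        for edge, a in self.alpha_overrides.items():
            if a < 0:
                raise ConfigurationError(f"alpha override for {edge} must be >= 0")
        for edge, t in self.theta_overrides.items():
            if not (0.0 <= t <= 1.0):
                raise ConfigurationError(
                    f"theta override for {edge} must lie in [0, 1]"
                )

    def alpha_for(self, edge: Edge) -> float:
        return self.alpha_overrides.get(edge, self.alpha)

    def theta_for(self, edge: Edge) -> float:
        return self.theta_overrides.get(edge, self.theta)


def bcm_delta(f_pre, f_post, alpha: float, theta: float):
    """Weight increment alpha * (f_post - theta) * f_pre (vectorized)."""
    return alpha * (np.asarray(f_post, dtype=float) - theta) * np.asarray(
        f_pre, dtype=float
    )


@dataclass
class CompiledPlasticity:
    """Index-array form of the plastic edge set, for the inner loop.

    Built once per network by :meth:`socialfear.circuits.NetworkSpec.compile_plasticity`;
    arrays are aligned: edge k runs from unit pre_idx[k] to post_idx[k]
    with learning rate alpha[k] and clip range [w_min[k], w_max[k]].
    """

    edges: Tuple[Edge, ...]
    pre_idx: np.ndarray
    post_idx: np.ndarray
    alpha: np.ndarray
    w_min: np.ndarray
    w_max: np.ndarray
    theta: np.ndarray  # per-edge BCM threshold
    enabled: bool = True

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_mask(self, edges) -> np.ndarray:
        """Boolean mask over the table selecting the given (pre, post) pairs."""
        wanted = set(edges)
        unknown = wanted - set(self.edges)
        if unknown:
            raise ConfigurationError(f"not plastic edges: {sorted(unknown)}")
        return np.array([e in wanted for e in self.edges], dtype=bool)


def apply_plasticity(
    state: NetworkState,
    table: CompiledPlasticity,
    active: Optional[np.ndarray] = None,
) -> None:
    """Apply one BCM update in place to ``state.W``.

    ``active`` is an optional boolean mask over the edge table; edges with
    ``active == False`` are frozen (plasticity-freeze manipulations). With
    ``table.enabled == False`` the call is a no-op.
    """
    if not table.enabled or table.n_edges == 0:
        return
    pre, post = table.pre_idx, table.post_idx
    alpha, theta = table.alpha, table.theta
    w_min, w_max = table.w_min, table.w_max
    if active is not None:
        if not active.any():
            return
        pre, post = pre[active], post[active]
        alpha, theta = alpha[active], theta[active]
        w_min, w_max = w_min[active], w_max[active]
    F = state.F
    w = state.W[post, pre] + alpha * (F[post] - theta) * F[pre]
    state.W[post, pre] = np.clip(w, w_min, w_max)
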