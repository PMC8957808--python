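"""The social-fear conditioning/extinction protocol and in-silico manipulations.

The default protocol mirrors the sub-chronic defeat / social fear
conditioning paradigm: one baseline trial (conspecific + context 1),
three conditioning trials (adding the defeat input, which drives lPBN and
Som1), and eleven extinction trials (conspecific + context 1 again). One
trial lasts 500 timesteps; voltages are reset at every trial onset while
synaptic weights persist across trials, so trials model separate
exposures of the same animal.

Manipulations emulate opto-/pharmacogenetic interventions:

* ``silence_unit`` clamps a unit's firing rate to zero (output block;
  leak dynamics stay intact),
* ``stimulate_unit`` adds a tonic term to a unit's external input,
* ``block_connection`` / ``scale_connection`` change the *effective*
  weight used by the dynamics without mutating the stored weight,
* ``freeze_plasticity`` disables the learning rule on targeted edges.

Each manipulation carries a window (phases, trials within a phase, and
optionally a step range inside trials) outside of which it has no effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .circuits import NetworkSpec
from .dynamics import (
    ConfigurationError,
    NetworkState,
    SimParams,
    SimulationDivergence,
)
from .plasticity import CompiledPlasticity

__all__ = [
    "Phase",
    "ProtocolSpec",
    "Manipulation",
    "TrialRecord",
    "SimulationResult",
    "default_protocol",
    "run_trial",
    "run_protocol",
    "mdt_stimulation_block",
]

Edge = Tuple[str, str]

KINDS = (
    "silence_unit",
    "stimulate_unit",
    "block_connection",
    "scale_connection",
    "freeze_plasticity",
)

#: Default exogenous MDT drives emulating high-/low-frequency stimulation.
#: HFS must push the (depotentiated) MDT efferents' targets above the BCM
#: threshold, LFS must hold them strictly between 0 and the threshold.
HFS_AMPLITUDE = 2.5
LFS_AMPLITUDE = 0.25
STIM_PHASE_NAME = "mdt_stim"
STIM_TRIALS = 18


@dataclass(frozen=True)
class Phase:
    """A protocol phase: a number of identical trials with fixed inputs."""

    name: str
    n_trials: int
    inputs: Mapping[str, float]  # channel -> amplitude (1.0 = standard drive)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError(
                f"phase {self.name!r}: n_trials must be >= 1"
            )
        for ch, amp in self.inputs.items():
            if amp < 0:
                raise ConfigurationError(
                    f"phase {self.name!r}: amplitude for {ch!r} must be >= 0"
                )


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered list of phases plus the integration parameters."""

    phases: Tuple[Phase, ...]
    sim: SimParams = field(default_factory=SimParams)

    @property
    def n_trials(self) -> int:
        return sum(p.n_trials for p in self.phases)

    def phase_names(self) -> List[str]:
        return [p.name for p in self.phases]


def default_protocol(
    sim: Optional[SimParams] = None,
    n_baseline: int = 1,
    n_conditioning: int = 3,
    n_extinction: int = 11,
) -> ProtocolSpec:
    """Baseline -> conditioning -> extinction with the standard trial counts."""
    return ProtocolSpec(
        phases=(
            Phase("baseline", n_baseline, {"conspecific": 1.0, "context1": 1.0}),
            Phase(
                "conditioning",
                n_conditioning,
                {"conspecific": 1.0, "context1": 1.0, "defeat": 1.0},
            ),
            Phase("extinction", n_extinction, {"conspecific": 1.0, "context1": 1.0}),
        ),
        sim=sim or SimParams(),
    )


@dataclass(frozen=True)
class Manipulation:
    """A timed perturbation of the running network.

    ``target`` is a unit name for unit manipulations, a ``(pre, post)``
    pair for connection manipulations, and for ``freeze_plasticity``
    either ``"all"``, a unit or area name (freezing the plastic afferents
    of the matching unit(s)), or an explicit list of edges. ``phases`` /
    ``trials`` / ``steps`` bound the window (None = unrestricted; trials
    are 1-based within a phase; steps is a half-open [start, stop) range
    inside each trial).
    """

    kind: str
    target: Union[str, Edge, Sequence[Edge]]
    magnitude: float = 0.0
    phases: Optional[Sequence[str]] = None
    trials: Optional[Sequence[int]] = None
    steps: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(
                f"unknown manipulation kind {self.kind!r}; valid: {KINDS}"
            )
        if self.kind == "scale_connection" and self.magnitude < 0:
            raise ConfigurationError("scale factor must be >= 0")

    def in_window(self, phase: str, trial: int) -> bool:
        if self.phases is not None and phase not in self.phases:
            return False
        if self.trials is not None and trial not in self.trials:
            return False
        return True

    def step_range(self, n_steps: int) -> Tuple[int, int]:
        if self.steps is None:
            return (0, n_steps)
        start, stop = self.steps
        return (max(0, int(start)), min(n_steps, int(stop)))


def _freeze_edges(spec: NetworkSpec, target) -> List[Edge]:
    """Resolve a freeze_plasticity target to a list of plastic edges."""
    plastic = spec.plastic_edges
    if isinstance(target, str):
        if target == "all":
            return list(plastic)
        unit_names = set(spec.unit_names)
        areas = {u.area for u in spec.units}
        if target in unit_names:
            hits = [e for e in plastic if e[1] == target]
        elif target in areas:
            in_area = {u.name for u in spec.units if u.area == target}
            hits = [e for e in plastic if e[1] in in_area]
        else:
            raise ConfigurationError(
                f"freeze_plasticity target {target!r} is neither 'all', a unit, "
                "nor an area"
            )
        if not hits:
            raise ConfigurationError(
                f"freeze_plasticity target {target!r} matches no plastic edge"
            )
        return hits
    # sequence of edges, or a single (pre, post) pair
    if (
        len(target) == 2
        and all(isinstance(x, str) for x in target)
    ):
        target = [tuple(target)]
    edges = [tuple(e) for e in target]
    for e in edges:
        if e not in plastic:
            raise ConfigurationError(
                f"freeze_plasticity target {e[0]}->{e[1]} is not a plastic edge"
            )
    return edges


def validate_manipulations(
    spec: NetworkSpec, manipulations: Sequence[Manipulation]
) -> None:
    """Raise ConfigurationError before any integration if a target is unknown."""
    for m in manipulations:
        if m.kind in ("silence_unit", "stimulate_unit"):
            if not isinstance(m.target, str):
                raise ConfigurationError(
                    f"{m.kind} target must be a unit name, got {m.target!r}"
                )
            spec.index(m.target)
        elif m.kind in ("block_connection", "scale_connection"):
            spec.connection(tuple(m.target))
        else:
            _freeze_edges(spec, m.target)


def _segments(n_steps: int, windows: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Split [0, n_steps) at every window boundary."""
    cuts = {0, n_steps}
    for a, b in windows:
        cuts.add(a)
        cuts.add(b)
    pts = sorted(c for c in cuts if 0 <= c <= n_steps)
    return [(pts[i], pts[i + 1]) for i in range(len(pts) - 1) if pts[i] < pts[i + 1]]


def run_trial(
    spec: NetworkSpec,
    phase: Phase,
    state: NetworkState,
    sim: SimParams,
    manipulations: Sequence[Manipulation] = (),
    trial: int = 1,
    table: Optional[CompiledPlasticity] = None,
) -> np.ndarray:
    """Run one trial in place: resets V, integrates ``sim.trial_length``
    steps with per-step plasticity, and returns the (steps, units) rate
    trace. ``state.W`` is mutated by learning only; effective-weight
    manipulations never touch it.
    """
    validate_manipulations(spec, manipulations)
    n_units = spec.n_units
    n_steps = sim.trial_length
    names = spec.unit_names
    if state.V.shape[0] != n_units or state.W.shape != (n_units, n_units):
        raise ConfigurationError("state dimensions do not match network spec")
    if table is None:
        table = spec.compile_plasticity()

    active = [m for m in manipulations if m.in_window(phase.name, trial)]
    I_base = spec.input_vector(phase.inputs)

    stims: List[Tuple[int, float, int, int]] = []
    silences: List[Tuple[int, int, int]] = []
    wmods: List[Tuple[int, int, float, int, int]] = []
    freezes: List[Tuple[np.ndarray, int, int]] = []
    idx = {n: i for i, n in enumerate(names)}
    for m in active:
        a, b = m.step_range(n_steps)
        if a >= b:
            continue
        if m.kind == "stimulate_unit":
            stims.append((idx[m.target], m.magnitude, a, b))
        elif m.kind == "silence_unit":
            silences.append((idx[m.target], a, b))
        elif m.kind == "block_connection":
            pre, post = tuple(m.target)
            wmods.append((idx[post], idx[pre], 0.0, a, b))
        elif m.kind == "scale_connection":
            pre, post = tuple(m.target)
            wmods.append((idx[post], idx[pre], m.magnitude, a, b))
        else:  # freeze_plasticity
            if table.n_edges:
                freezes.append((table.edge_mask(_freeze_edges(spec, m.target)), a, b))

    windows = [(a, b) for *_, a, b in stims]
    windows += [(a, b) for _, a, b in silences]
    windows += [(a, b) for *_, a, b in wmods]
    windows += [(a, b) for _, a, b in freezes]

    state.V[:] = 0.0
    state.F[:] = 0.0
    V, F, W = state.V, state.F, state.W
    leak = sim.leak
    do_plast = table.enabled and table.n_edges > 0
    trace = np.empty((n_steps, n_units))

    for a, b in _segments(n_steps, windows):
        I = I_base.copy()
        for i, mag, s0, s1 in stims:
            if s0 <= a and b <= s1:
                I[i] += mag
        sil = [i for i, s0, s1 in silences if s0 <= a and b <= s1]
        mask = None
        for pi, pj, factor, s0, s1 in wmods:
            if s0 <= a and b <= s1:
                if mask is None:
                    mask = np.ones((n_units, n_units))
                mask[pi, pj] *= factor
        unfrozen = None
        if do_plast:
            unfrozen = np.ones(table.n_edges, dtype=bool)
            for fmask, s0, s1 in freezes:
                if s0 <= a and b <= s1:
                    unfrozen &= ~fmask

        pre_i, post_i = table.pre_idx, table.post_idx
        alpha, theta = table.alpha, table.theta
        w_lo, w_hi = table.w_min, table.w_max
        if do_plast and unfrozen is not None and not unfrozen.all():
            pre_i, post_i = pre_i[unfrozen], post_i[unfrozen]
            alpha, theta = alpha[unfrozen], theta[unfrozen]
            w_lo, w_hi = w_lo[unfrozen], w_hi[unfrozen]
        learn = do_plast and len(pre_i) > 0

        for t in range(a, b):
            Weff = W if mask is None else W * mask
            V += leak * (-V + I + Weff @ F)
            if not np.all(np.isfinite(V)):
                i = int(np.flatnonzero(~np.isfinite(V))[0])
                raise SimulationDivergence(
                    f"voltage of {names[i]} diverged at step {t} "
                    f"(phase {phase.name!r}, trial {trial})"
                )
            np.maximum(np.tanh(V), 0.0, out=F)
            for i in sil:
                F[i] = 0.0
            if learn:
                w = W[post_i, pre_i] + alpha * (F[post_i] - theta) * F[pre_i]
                W[post_i, pre_i] = np.clip(w, w_lo, w_hi)
            trace[t] = F
    return trace


@dataclass(frozen=True)
class TrialRecord:
    """One trial's coordinates and full rate trace (steps x units)."""

    phase: str
    trial: int  # 1-based within phase
    trace: np.ndarray

    def mean_rate(self, unit_index: int) -> float:
        return float(self.trace[:, unit_index].mean())


@dataclass
class SimulationResult:
    """Traces, per-trial weight snapshots, and the provenance of a run."""

    unit_names: List[str]
    trials: List[TrialRecord]
    weight_snapshots: List[np.ndarray]
    protocol: ProtocolSpec
    manipulations: Tuple[Manipulation, ...]
    initial_weights: np.ndarray
    final_state: NetworkState

    def index(self, unit: str) -> int:
        try:
            return self.unit_names.index(unit)
        except ValueError:
            raise ConfigurationError(f"unknown unit {unit!r}") from None

    def trial_means(self, unit: str) -> np.ndarray:
        """Trial-mean firing rate of one unit across all trials, in order."""
        i = self.index(unit)
        return np.array([t.mean_rate(i) for t in self.trials])

    def phase_trials(self, phase: str) -> List[TrialRecord]:
        return [t for t in self.trials if t.phase == phase]

    def phase_trial_means(self, unit: str, phase: str) -> np.ndarray:
        i = self.index(unit)
        return np.array([t.mean_rate(i) for t in self.trials if t.phase == phase])

    def weight_series(self, edge: Edge) -> np.ndarray:
        """The stored weight of one edge after each trial (snapshot series)."""
        pre, post = edge
        i, j = self.index(post), self.index(pre)
        return np.array([W[i, j] for W in self.weight_snapshots])

    def initial_weight(self, edge: Edge) -> float:
        pre, post = edge
        return float(self.initial_weights[self.index(post), self.index(pre)])


def run_protocol(
    spec: NetworkSpec,
    protocol: Optional[ProtocolSpec] = None,
    manipulations: Sequence[Manipulation] = (),
    initial_state: Optional[NetworkState] = None,
) -> SimulationResult:
    """Run all phases in order from a fresh state (or ``initial_state``).

    Weights carry across trials and phases; voltages reset at every trial
    onset. The run is completely deterministic.
    """
    if protocol is None:
        protocol = default_protocol()
    manipulations = tuple(manipulations)
    validate_manipulations(spec, manipulations)
    known = {p.name for p in protocol.phases}
    for m in manipulations:
        if m.phases is not None:
            missing = set(m.phases) - known
            if missing:
                raise ConfigurationError(
                    f"manipulation window references unknown phase(s) {sorted(missing)}"
                )
    if initial_state is None:
        state = NetworkState.zeros(spec.n_units, spec.weight_matrix())
    else:
        state = initial_state.copy()
    table = spec.compile_plasticity()
    initial_W = state.W.copy()
    records: List[TrialRecord] = []
    snapshots: List[np.ndarray] = []
    for phase in protocol.phases:
        for k in range(1, phase.n_trials + 1):
            try:
                trace = run_trial(
                    spec,
                    phase,
                    state,
                    protocol.sim,
                    manipulations,
                    trial=k,
                    table=table,
                )
            except SimulationDivergence as err:
                raise SimulationDivergence(
                    f"{err} [phase={phase.name!r}, trial={k}]"
                ) from None
            records.append(TrialRecord(phase=phase.name, trial=k, trace=trace))
            snapshots.append(state.W.copy())
    return SimulationResult(
        unit_names=list(spec.unit_names),
        trials=records,
        weight_snapshots=snapshots,
        protocol=protocol,
        manipulations=manipulations,
        initial_weights=initial_W,
        final_state=state,
    )


def mdt_stimulation_block(
    spec: NetworkSpec,
    mode: str,
    n_trials: int = STIM_TRIALS,
    amplitude: Optional[float] = None,
) -> Tuple[Phase, List[Manipulation]]:
    """A stimulation phase emulating HFS or LFS of the mediodorsal thalamus.

    Returns a phase (to insert between conditioning and extinction) plus
    the manipulations realizing it: a tonic exogenous MDT drive, with
    plasticity enabled only on the MDT efferents for the duration of the
    block. HFS drives the MDT hard enough that its targets exceed the BCM
    threshold (net LTP on MDT efferents); LFS holds them strictly between
    zero and the threshold (net LTD). The resulting rate conditions are
    verified by the prediction runner.
    """
    mode = mode.upper()
    if mode not in ("HFS", "LFS"):
        raise ConfigurationError(f"mode must be 'HFS' or 'LFS', got {mode!r}")
    if amplitude is None:
        amplitude = HFS_AMPLITUDE if mode == "HFS" else LFS_AMPLITUDE
    spec.index("MDT")
    non_mdt = [e for e in spec.plastic_edges if e[0] != "MDT"]
    phase = Phase(STIM_PHASE_NAME, n_trials, {})
    manips = [
        Manipulation(
            "stimulate_unit",
            "MDT",
            magnitude=amplitude,
            phases=[STIM_PHASE_NAME],
        )
    ]
    if non_mdt:
        manips.append(
            Manipulation("freeze_plasticity", non_mdt, phases=[STIM_PHASE_NAME])
        )
    return phase, manips
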