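"""The social-fear circuit architectures.

Two network variants are shipped:

* the **basic model** — 16 units spanning MeA (conspecific cue), vHIP
  (two context populations Hip1/Hip2), lPBN (nociceptive defeat relay),
  MDT, the VMHvl threat/interaction pair Hyp1/Hyp2 with local
  interneurons implementing winner-take-all competition, an mPFC
  microcircuit (pyramidal Pyr1/Pyr2 with Pv and Som interneurons), and
  the dPAG output unit whose activation stands for social avoidance;
* the **alternative model** — the same topology plus a lateral-septum
  unit LS, driven by the conspecific input, that sends a fixed
  inhibitory projection to the threat unit Hyp1, relocating part of the
  extinction process into the VMHvl.

Naming conventions: HypIN1 is the interneuron that inhibits Hyp1 (driven
by Hyp2) and HypIN2 the one inhibiting Hyp2 (driven by Hyp1). The
glutamatergic unit Pyr2 projects to dPag1 with a *negative* effective
weight: the top-down prefrontal control is modelled as direct inhibition,
abstracting over its (metabotropic, long-latency) mechanism; this is the
one deliberate exception to the rule that the weight sign matches the
presynaptic transmitter. Pyr1 has no direct dPAG projection — its
fear-promoting effect runs through Som2-mediated suppression of Pyr2.

All default weights were calibrated by coordinate-wise adjustment until
the full qualitative checklist of :mod:`socialfear.experiments` passes;
see docs/methods.md for the procedure and the meaning of each group.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .dynamics import ConfigurationError
from .plasticity import CompiledPlasticity, PlasticityParams

__all__ = [
    "UnitSpec",
    "ConnectionSpec",
    "NetworkSpec",
    "build_basic_model",
    "build_alternative_model",
    "validate_spec",
]

Edge = Tuple[str, str]

GLUT, GABA = "+", "-"


@dataclass(frozen=True)
class UnitSpec:
    """One neural population: name, brain-area label, transmitter sign."""

    name: str
    area: str
    sign: str = GLUT
    tau: Optional[float] = None  # None -> global tau from SimParams


@dataclass(frozen=True)
class ConnectionSpec:
    """A signed connection; plastic edges carry their clip bounds."""

    pre: str
    post: str
    weight: float
    plastic: bool = False
    bounds: Optional[Tuple[float, float]] = None
    sign_exception: bool = False

    @property
    def edge(self) -> Edge:
        return (self.pre, self.post)


@dataclass
class NetworkSpec:
    """Units, connections, input channels and plasticity parameters."""

    units: List[UnitSpec]
    connections: List[ConnectionSpec]
    input_channels: Dict[str, Dict[str, float]]
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    name: str = "network"

    # -- indexing ---------------------------------------------------------
    @property
    def unit_names(self) -> List[str]:
        return [u.name for u in self.units]

    @property
    def n_units(self) -> int:
        return len(self.units)

    def index(self, name: str) -> int:
        try:
            return self.unit_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown unit {name!r}") from None

    def unit(self, name: str) -> UnitSpec:
        return self.units[self.index(name)]

    def connection(self, edge: Edge) -> ConnectionSpec:
        for c in self.connections:
            if c.edge == tuple(edge):
                return c
        raise ConfigurationError(f"unknown connection {edge[0]}->{edge[1]}")

    def has_connection(self, edge: Edge) -> bool:
        return any(c.edge == tuple(edge) for c in self.connections)

    @property
    def edges(self) -> List[Edge]:
        return [c.edge for c in self.connections]

    @property
    def plastic_edges(self) -> List[Edge]:
        return [c.edge for c in self.connections if c.plastic]

    # -- compiled views ---------------------------------------------------
    def weight_matrix(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.unit_names)}
        W = np.zeros((self.n_units, self.n_units))
        for c in self.connections:
            W[idx[c.post], idx[c.pre]] = c.weight
        return W

    def compile_plasticity(self) -> CompiledPlasticity:
        idx = {n: i for i, n in enumerate(self.unit_names)}
        plastic = [c for c in self.connections if c.plastic]
        p = self.plasticity
        return CompiledPlasticity(
            edges=tuple(c.edge for c in plastic),
            pre_idx=np.array([idx[c.pre] for c in plastic], dtype=int),
            post_idx=np.array([idx[c.post] for c in plastic], dtype=int),
            alpha=np.array([p.alpha_for(c.edge) for c in plastic]),
            w_min=np.array([c.bounds[0] for c in plastic]),
            w_max=np.array([c.bounds[1] for c in plastic]),
            theta=np.array([p.theta_for(c.edge) for c in plastic]),
            enabled=p.enabled,
        )

    def input_vector(self, amplitudes: Mapping[str, float]) -> np.ndarray:
        """External drive per unit from channel amplitudes (e.g. conspecific=1)."""
        I = np.zeros(self.n_units)
        for channel, amp in amplitudes.items():
            if channel not in self.input_channels:
                raise ConfigurationError(f"unknown input channel {channel!r}")
            if amp < 0:
                raise ConfigurationError(f"amplitude for {channel!r} must be >= 0")
            for unit, gain in self.input_channels[channel].items():
                I[self.index(unit)] += gain * amp
        return I

    # -- structural edits (used by sensitivity analysis) ------------------
    def copy(self) -> "NetworkSpec":
        return _copy.deepcopy(self)

    def with_scaled_weight(self, edge: Edge, factor: float) -> "NetworkSpec":
        """New spec with one connection's weight (and clip bounds, if
        plastic) multiplied by ``factor``; everything else shared."""
        if factor < 0:
            raise ConfigurationError("scale factor must be >= 0")
        edge = tuple(edge)
        self.connection(edge)  # raises if absent
        out = self.copy()
        out.connections = [
            replace(
                c,
                weight=c.weight * factor,
                bounds=(
                    tuple(b * factor for b in c.bounds) if c.plastic else c.bounds
                ),
            )
            if c.edge == edge
            else c
            for c in out.connections
        ]
        return out

    def without_edge(self, edge: Edge) -> "NetworkSpec":
        edge = tuple(edge)
        self.connection(edge)
        out = self.copy()
        out.connections = [c for c in out.connections if c.edge != edge]
        return out

    def without_unit(self, name: str) -> "NetworkSpec":
        self.index(name)
        out = self.copy()
        out.units = [u for u in out.units if u.name != name]
        out.connections = [
            c for c in out.connections if name not in (c.pre, c.post)
        ]
        out.input_channels = {
            ch: {u: g for u, g in gains.items() if u != name}
            for ch, gains in out.input_channels.items()
        }
        out.plasticity.alpha_overrides = {
            e: a
            for e, a in out.plasticity.alpha_overrides.items()
            if name not in e
        }
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "units": [
                {
                    "name": u.name,
                    "area": u.area,
                    "sign": u.sign,
                    **({"tau": u.tau} if u.tau is not None else {}),
                }
                for u in self.units
            ],
            "connections": [
                {
                    "pre": c.pre,
                    "post": c.post,
                    "weight": float(c.weight),
                    "plastic": c.plastic,
                    **(
                        {"w_min": float(c.bounds[0]), "w_max": float(c.bounds[1])}
                        if c.bounds is not None
                        else {}
                    ),
                    **({"sign_exception": True} if c.sign_exception else {}),
                }
                for c in self.connections
            ],
            "input_channels": {
                ch: {u: float(g) for u, g in gains.items()}
                for ch, gains in self.input_channels.items()
            },
            "plasticity": {
                "alpha": self.plasticity.alpha,
                "theta": self.plasticity.theta,
                "enabled": self.plasticity.enabled,
                "alpha_overrides": {
                    f"{pre}->{post}": a
                    for (pre, post), a in self.plasticity.alpha_overrides.items()
                },
                "theta_overrides": {
                    f"{pre}->{post}": t
                    for (pre, post), t in self.plasticity.theta_overrides.items()
                },
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NetworkSpec":
        units = [
            UnitSpec(
                name=u["name"], area=u["area"], sign=u["sign"], tau=u.get("tau")
            )
            for u in d["units"]
        ]
        conns = []
        for c in d["connections"]:
            bounds = None
            if "w_min" in c or "w_max" in c:
                bounds = (float(c["w_min"]), float(c["w_max"]))
            conns.append(
                ConnectionSpec(
                    pre=c["pre"],
                    post=c["post"],
                    weight=float(c["weight"]),
                    plastic=bool(c.get("plastic", False)),
                    bounds=bounds,
                    sign_exception=bool(c.get("sign_exception", False)),
                )
            )
        p = d.get("plasticity", {})

        def _edge_map(key: str) -> Dict[Edge, float]:
            out: Dict[Edge, float] = {}
            for k, v in p.get(key, {}).items():
                pre, post = k.split("->")
                out[(pre, post)] = float(v)
            return out

        plasticity = PlasticityParams(
            alpha=float(p.get("alpha", 0.002)),
            theta=float(p.get("theta", 0.5)),
            enabled=bool(p.get("enabled", True)),
            alpha_overrides=_edge_map("alpha_overrides"),
            theta_overrides=_edge_map("theta_overrides"),
        )
        return cls(
            units=units,
            connections=conns,
            input_channels={
                ch: dict(gains) for ch, gains in d["input_channels"].items()
            },
            plasticity=plasticity,
            name=d.get("name", "network"),
        )


# ---------------------------------------------------------------------------
# Shipped calibrations
# ---------------------------------------------------------------------------

#: Fixed-connection weights of the basic model. Signs follow the
#: presynaptic transmitter; Pyr2->dPag1 is the documented exception.
BASIC_FIXED_WEIGHTS: Dict[Edge, float] = {
    ("MeA", "MDT"): 3.0,
    ("lPBN", "Hyp1"): 0.85,
    ("Hyp1", "HypIN2"): 1.2,
    ("HypIN2", "Hyp2"): -2.0,
    ("Hyp2", "HypIN1"): 0.3,
    ("HypIN1", "Hyp1"): -0.12,
    ("Pv", "Pyr1"): -0.86,
    ("Som1", "Pv"): -6.0,
    ("Som1", "Pyr2"): -6.0,
    ("Pyr1", "Som2"): 1.8,
    ("Som2", "Pyr2"): -1.30,
    ("Pyr2", "Som3"): 0.5,
    ("Som3", "Pyr1"): -1.0,
    ("Hyp1", "dPag1"): 2.5,
    ("Pyr2", "dPag1"): -3.2,
}

#: Plastic connections of the basic model: initial weight and clip range.
#: The hippocampal/amygdalar afferents of Hyp1 start at their lower clip
#: bound (they only ever potentiate), which also pins them when learning
#: is driven below threshold; the Hyp2 afferents start above their floor
#: so conditioning can depress them. Context symmetry before learning:
#: Hip1 and Hip2 project identically until the protocol breaks the tie.
BASIC_PLASTIC: Dict[Edge, Tuple[float, float, float]] = {
    # edge: (initial, w_min, w_max)
    ("MeA", "Hyp1"): (0.0765, 0.0765, 1.20),
    ("Hip1", "Hyp1"): (0.038, 0.038, 1.20),
    ("Hip2", "Hyp1"): (0.038, 0.038, 1.20),
    ("MeA", "Hyp2"): (0.50, 0.35, 1.20),
    ("Hip1", "Hyp2"): (0.50, 0.35, 1.20),
    ("Hip2", "Hyp2"): (0.50, 0.35, 1.20),
    ("MDT", "Pyr1"): (0.85, 0.85, 1.23),
    ("MDT", "Pyr2"): (1.20, 0.84, 1.80),
    ("MDT", "Pv"): (1.70, 0.40, 1.70),
}

BASIC_ALPHA = 0.002
BASIC_THETA = 0.5

#: Hypothalamic afferents learn faster than the thalamocortical ones:
#: conditioning must saturate the VMHvl reorganization within its three
#: trials, while the mPFC reorganization paces the slow extinction.
BASIC_ALPHA_OVERRIDES: Dict[Edge, float] = {
    ("MeA", "Hyp1"): 0.004,
    ("Hip1", "Hyp1"): 0.004,
    ("Hip2", "Hyp1"): 0.004,
    ("MeA", "Hyp2"): 0.004,
    ("Hip1", "Hyp2"): 0.004,
    ("Hip2", "Hyp2"): 0.004,
    ("MDT", "Pyr2"): 0.0012,
    ("MDT", "Pv"): 0.0009,
}

#: Alternative-model additions and recalibrated values. The LS unit turns
#: the VMHvl into a second extinction site, which requires the dPAG drive
#: to be dominated by Hyp1 (stronger Hyp1->dPag1, weaker Pyr2->dPag1) and
#: a tighter potentiation ceiling on the Hyp1 afferents so that the
#: conditioned threat drive sits just above the LS inhibition.
ALT_LS_WEIGHT = -0.65
ALT_OVERRIDE_FIXED: Dict[Edge, float] = {
    ("Hyp1", "dPag1"): 4.0,
    ("Pyr2", "dPag1"): -2.0,
    ("lPBN", "Hyp1"): 2.1,
    ("Hyp1", "HypIN2"): 1.2,
    ("Hyp2", "HypIN1"): 1.2,
    ("HypIN2", "Hyp2"): -2.0,
    ("HypIN1", "Hyp1"): -2.0,
}
ALT_OVERRIDE_PLASTIC: Dict[Edge, Tuple[float, float, float]] = {
    ("MeA", "Hyp1"): (0.36, 0.36, 0.76),
    ("Hip1", "Hyp1"): (0.18, 0.18, 0.418),
    ("Hip2", "Hyp1"): (0.18, 0.18, 0.418),
    ("MeA", "Hyp2"): (0.13, 0.13, 1.20),
    ("Hip1", "Hyp2"): (0.13, 0.13, 1.20),
    ("Hip2", "Hyp2"): (0.13, 0.13, 1.20),
}
#: The VMHvl relearns slightly faster in the alternative calibration, so
#: each extinction exposure measurably depotentiates the Hyp1 afferents
#: between successive trial-onset competitions with Hyp2.
ALT_VMHVL_ALPHA = 0.005
#: The interaction population learns at a lower BCM threshold in the
#: alternative calibration, so its afferents potentiate while it regains
#: control during extinction even at moderate firing rates.
ALT_HYP2_THETA = 0.25

_UNITS_BASIC: List[Tuple[str, str, str]] = [
    ("MeA", "MeA", GLUT),
    ("Hip1", "vHIP", GLUT),
    ("Hip2", "vHIP", GLUT),
    ("lPBN", "lPBN", GLUT),
    ("MDT", "MDT", GLUT),
    ("Hyp1", "VMHvl", GLUT),
    ("Hyp2", "VMHvl", GLUT),
    ("HypIN1", "VMHvl", GABA),
    ("HypIN2", "VMHvl", GABA),
    ("Pyr1", "mPFC", GLUT),
    ("Pyr2", "mPFC", GLUT),
    ("Pv", "mPFC", GABA),
    ("Som1", "mPFC", GABA),
    ("Som2", "mPFC", GABA),
    ("Som3", "mPFC", GABA),
    ("dPag1", "dPAG", GLUT),
]

_CHANNELS_BASIC: Dict[str, Dict[str, float]] = {
    "conspecific": {"MeA": 1.0},
    "context1": {"Hip1": 1.0},
    "context2": {"Hip2": 1.0},
    "defeat": {"lPBN": 1.0, "Som1": 1.0},
}


def _apply_overrides(spec: NetworkSpec, overrides: Optional[Mapping]) -> NetworkSpec:
    if not overrides:
        return spec
    allowed = {
        "weights",
        "bounds",
        "alpha",
        "theta",
        "alpha_overrides",
        "theta_overrides",
        "input_gains",
    }
    unknown = set(overrides) - allowed
    if unknown:
        raise ConfigurationError(f"unknown override keys: {sorted(unknown)}")
    for edge in overrides.get("weights", {}):
        spec.connection(tuple(edge))
    for edge in overrides.get("bounds", {}):
        if not spec.connection(tuple(edge)).plastic:
            raise ConfigurationError(f"bounds override on non-plastic edge {edge}")
    new_conns = []
    for c in spec.connections:
        w = overrides.get("weights", {}).get(c.edge, c.weight)
        b = overrides.get("bounds", {}).get(c.edge, c.bounds)
        new_conns.append(replace(c, weight=w, bounds=tuple(b) if b else None))
    spec.connections = new_conns
    if "alpha" in overrides:
        spec.plasticity.alpha = float(overrides["alpha"])
    if "theta" in overrides:
        spec.plasticity.theta = float(overrides["theta"])
    for edge, a in overrides.get("alpha_overrides", {}).items():
        spec.plasticity.alpha_overrides[tuple(edge)] = float(a)
    for edge, t in overrides.get("theta_overrides", {}).items():
        spec.plasticity.theta_overrides[tuple(edge)] = float(t)
    for ch, gains in overrides.get("input_gains", {}).items():
        spec.input_channels.setdefault(ch, {}).update(gains)
    violations = validate_spec(spec)
    if violations:
        raise ConfigurationError("; ".join(violations))
    return spec


def _assemble(
    units: Sequence[Tuple[str, str, str]],
    fixed: Mapping[Edge, float],
    plastic: Mapping[Edge, Tuple[float, float, float]],
    channels: Mapping[str, Mapping[str, float]],
    name: str,
    alpha_overrides: Optional[Mapping[Edge, float]] = None,
) -> NetworkSpec:
    conns = [
        ConnectionSpec(
            pre=pre,
            post=post,
            weight=w,
            sign_exception=(pre, post) == ("Pyr2", "dPag1"),
        )
        for (pre, post), w in fixed.items()
    ]
    conns += [
        ConnectionSpec(pre=pre, post=post, weight=w0, plastic=True, bounds=(lo, hi))
        for (pre, post), (w0, lo, hi) in plastic.items()
    ]
    spec = NetworkSpec(
        units=[UnitSpec(*u) for u in units],
        connections=conns,
        input_channels={ch: dict(g) for ch, g in channels.items()},
        plasticity=PlasticityParams(
            alpha=BASIC_ALPHA,
            theta=BASIC_THETA,
            alpha_overrides=dict(
                BASIC_ALPHA_OVERRIDES if alpha_overrides is None else alpha_overrides
            ),
        ),
        name=name,
    )
    violations = validate_spec(spec)
    if violations:  # pragma: no cover - shipped configs are valid
        raise ConfigurationError("; ".join(violations))
    return spec


def build_basic_model(overrides: Optional[Mapping] = None) -> NetworkSpec:
    """The 16-unit basic model (no lateral septum)."""
    spec = _assemble(
        _UNITS_BASIC, BASIC_FIXED_WEIGHTS, BASIC_PLASTIC, _CHANNELS_BASIC, "basic"
    )
    return _apply_overrides(spec, overrides)


def build_alternative_model(overrides: Optional[Mapping] = None) -> NetworkSpec:
    """The 17-unit alternative model: basic topology plus LS -> Hyp1."""
    fixed = dict(BASIC_FIXED_WEIGHTS)
    fixed.update(ALT_OVERRIDE_FIXED)
    fixed[("LS", "Hyp1")] = ALT_LS_WEIGHT
    plastic = dict(BASIC_PLASTIC)
    plastic.update(ALT_OVERRIDE_PLASTIC)
    channels = {ch: dict(g) for ch, g in _CHANNELS_BASIC.items()}
    channels["conspecific"]["LS"] = 1.0
    units = list(_UNITS_BASIC) + [("LS", "LS", GABA)]
    alphas = dict(BASIC_ALPHA_OVERRIDES)
    for edge in plastic:
        if edge[1] in ("Hyp1", "Hyp2"):
            alphas[edge] = ALT_VMHVL_ALPHA
    spec = _assemble(
        units, fixed, plastic, channels, "alternative", alpha_overrides=alphas
    )
    spec.plasticity.theta_overrides = {
        edge: ALT_HYP2_THETA for edge in plastic if edge[1] == "Hyp2"
    }
    return _apply_overrides(spec, overrides)


def validate_spec(spec: NetworkSpec) -> List[str]:
    """Check all structural invariants; violations are returned, not raised."""
    v: List[str] = []
    names = spec.unit_names
    seen = set()
    for n in names:
        if n in seen:
            v.append(f"duplicate unit name {n!r}")
        seen.add(n)
    sign_of = {}
    for u in spec.units:
        if u.sign not in (GLUT, GABA):
            v.append(f"unit {u.name!r} has invalid sign {u.sign!r}")
        sign_of[u.name] = u.sign
    for c in spec.connections:
        tag = f"{c.pre}->{c.post}"
        if c.pre not in seen:
            v.append(f"connection {tag} references unknown unit {c.pre!r}")
            continue
        if c.post not in seen:
            v.append(f"connection {tag} references unknown unit {c.post!r}")
            continue
        if c.pre == c.post:
            v.append(f"self-connection on {c.pre!r}")
        if c.weight != 0.0 and not c.sign_exception:
            expected = 1.0 if sign_of.get(c.pre) == GLUT else -1.0
            if np.sign(c.weight) != expected:
                v.append(
                    f"sign of {tag} ({c.weight:+g}) contradicts presynaptic "
                    f"transmitter ({sign_of.get(c.pre)})"
                )
        if c.plastic:
            if c.bounds is None:
                v.append(f"plastic edge {tag} lacks clip bounds")
            else:
                lo, hi = c.bounds
                if lo > hi:
                    v.append(f"plastic edge {tag} has w_min > w_max")
                elif not (lo <= c.weight <= hi):
                    v.append(f"initial weight of {tag} outside [{lo}, {hi}]")
    edge_set = set()
    for c in spec.connections:
        if c.edge in edge_set:
            v.append(f"duplicate connection {c.pre}->{c.post}")
        edge_set.add(c.edge)
    for ch, gains in spec.input_channels.items():
        for unit, gain in gains.items():
            if unit not in seen:
                v.append(f"input channel {ch!r} drives unknown unit {unit!r}")
            if gain < 0:
                v.append(f"input channel {ch!r} has negative gain on {unit!r}")
    plastic_set = {c.edge for c in spec.connections if c.plastic}
    for kind, table in (
        ("alpha", spec.plasticity.alpha_overrides),
        ("theta", spec.plasticity.theta_overrides),
    ):
        for edge in table:
            if tuple(edge) not in plastic_set:
                v.append(f"{kind} override on non-plastic edge {edge[0]}->{edge[1]}")
    return v
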