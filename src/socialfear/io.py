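"""Configuration loading, result serialization, and provenance digests.

Configs are YAML with sections ``network`` (either the name of a shipped
variant, ``basic`` or ``alternative``, or a full inline specification
with units / connections / input_channels / plasticity), ``protocol``
(phases + integration parameters; omitted = the default three-phase
protocol), and ``manipulations``. Results are written as long-format CSV
(one row per phase/trial/step/unit) plus a JSON summary carrying the
config digest, so any run is reproducible from its own outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .circuits import (
    NetworkSpec,
    build_alternative_model,
    build_basic_model,
    validate_spec,
)
from .dynamics import ConfigurationError, SimParams
from .experiments import classify_all, compute_metrics
from .protocol import Manipulation, Phase, ProtocolSpec, SimulationResult, default_protocol

__all__ = [
    "RunConfig",
    "load_config",
    "load_network",
    "config_digest",
    "write_result",
    "write_report",
]

_BUILDERS = {"basic": build_basic_model, "alternative": build_alternative_model}


@dataclass
class RunConfig:
    """A fully resolved simulation request."""

    network: NetworkSpec
    protocol: ProtocolSpec
    manipulations: List[Manipulation] = field(default_factory=list)
    source: Optional[dict] = None

    def digest(self) -> str:
        return config_digest(self.to_dict())

    def to_dict(self) -> dict:
        return {
            "network": self.network.to_dict(),
            "protocol": _protocol_to_dict(self.protocol),
            "manipulations": [_manip_to_dict(m) for m in self.manipulations],
        }


def config_digest(config: Union[Mapping, RunConfig]) -> str:
    """Short sha256 of the canonicalized config, embedded in every output."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _protocol_to_dict(p: ProtocolSpec) -> dict:
    return {
        "sim": {
            "dt": p.sim.dt,
            "tau": p.sim.tau,
            "trial_length": p.sim.trial_length,
        },
        "phases": [
            {"name": ph.name, "n_trials": ph.n_trials, "inputs": dict(ph.inputs)}
            for ph in p.phases
        ],
    }


def _protocol_from_dict(d: Mapping) -> ProtocolSpec:
    sim_d = d.get("sim", {})
    sim = SimParams(
        dt=float(sim_d.get("dt", 0.1)),
        tau=float(sim_d.get("tau", 1.0)),
        trial_length=int(sim_d.get("trial_length", 500)),
    )
    phases = tuple(
        Phase(
            name=ph["name"],
            n_trials=int(ph["n_trials"]),
            inputs={k: float(v) for k, v in ph.get("inputs", {}).items()},
        )
        for ph in d["phases"]
    )
    return ProtocolSpec(phases=phases, sim=sim)


def _manip_to_dict(m: Manipulation) -> dict:
    target = m.target
    if not isinstance(target, str):
        target = [list(t) if isinstance(t, (tuple, list)) else t for t in target] \
            if target and isinstance(target[0], (tuple, list)) else list(target)
    out = {"kind": m.kind, "target": target}
    if m.magnitude:
        out["magnitude"] = m.magnitude
    if m.phases is not None:
        out["phases"] = list(m.phases)
    if m.trials is not None:
        out["trials"] = list(m.trials)
    if m.steps is not None:
        out["steps"] = list(m.steps)
    return out


def _manip_from_dict(d: Mapping) -> Manipulation:
    target = d["target"]
    if isinstance(target, list):
        if target and isinstance(target[0], list):
            target = [tuple(t) for t in target]
        else:
            target = tuple(target) if all(
                isinstance(t, str) for t in target
            ) and len(target) == 2 else [tuple(t) for t in target]
    return Manipulation(
        kind=d["kind"],
        target=target,
        magnitude=float(d.get("magnitude", 0.0)),
        phases=d.get("phases"),
        trials=d.get("trials"),
        steps=tuple(d["steps"]) if d.get("steps") else None,
    )


def load_network(source: Union[str, Path, Mapping]) -> NetworkSpec:
    """Resolve a network reference: variant name, YAML path, or inline dict."""
    if isinstance(source, str) and source in _BUILDERS:
        return _BUILDERS[source]()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, Mapping) and set(data) <= {"network", "protocol", "manipulations"}:
            data = data["network"]
        source = data
    if isinstance(source, str) and source in _BUILDERS:
        return _BUILDERS[source]()
    spec = NetworkSpec.from_dict(source)
    violations = validate_spec(spec)
    if violations:
        raise ConfigurationError(
            "invalid network config: " + "; ".join(violations)
        )
    return spec


def shipped_config_path(variant: str) -> Path:
    """Path of a shipped, calibrated network config (basic | alternative)."""
    if variant not in _BUILDERS:
        raise ConfigurationError(f"no shipped config named {variant!r}")
    return Path(str(resources.files("socialfear").joinpath(f"configs/{variant}.yaml")))


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run config; defaults are filled in.

    Round-trips: serializing the loaded config (``RunConfig.to_dict``) and
    reloading yields an equivalent configuration.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as err:
        raise ConfigurationError(f"cannot parse {path}: {err}") from None
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    network = load_network(data.get("network", "basic"))
    protocol = (
        _protocol_from_dict(data["protocol"])
        if "protocol" in data and data["protocol"]
        else default_protocol()
    )
    manips = [_manip_from_dict(m) for m in data.get("manipulations", []) or []]
    return RunConfig(
        network=network, protocol=protocol, manipulations=manips, source=dict(data)
    )


def save_network(spec: NetworkSpec, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"network": spec.to_dict()}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------

def _traces_frame(result: SimulationResult) -> pd.DataFrame:
    rows = []
    for rec in result.trials:
        n_steps = rec.trace.shape[0]
        frame = pd.DataFrame(rec.trace, columns=result.unit_names)
        frame.insert(0, "step", range(n_steps))
        frame.insert(0, "trial", rec.trial)
        frame.insert(0, "phase", rec.phase)
        rows.append(frame)
    wide = pd.concat(rows, ignore_index=True)
    return wide.melt(
        id_vars=["phase", "trial", "step"], var_name="unit", value_name="activation"
    )


def _weights_frame(result: SimulationResult) -> pd.DataFrame:
    rows = []
    nz = result.initial_weights != 0
    for rec, W in zip(result.trials, result.weight_snapshots):
        post_idx, pre_idx = nz.nonzero()
        for i, j in zip(post_idx, pre_idx):
            rows.append(
                {
                    "phase": rec.phase,
                    "trial": rec.trial,
                    "pre": result.unit_names[j],
                    "post": result.unit_names[i],
                    "weight": W[i, j],
                }
            )
    return pd.DataFrame(rows)


def write_result(
    result: SimulationResult,
    out_dir: Union[str, Path],
    formats: Sequence[str] = ("csv", "json"),
    digest: Optional[str] = None,
    prefix: str = "run",
) -> Dict[str, Path]:
    """Write traces/weights CSVs and a JSON summary; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Path] = {}
    if "csv" in formats:
        p = out_dir / f"{prefix}_traces.csv"
        _traces_frame(result).to_csv(p, index=False, float_format="%.10g")
        manifest["traces"] = p
        p = out_dir / f"{prefix}_weights.csv"
        _weights_frame(result).to_csv(p, index=False, float_format="%.10g")
        manifest["weights"] = p
    if "json" in formats:
        has_extinction = any(t.phase == "extinction" for t in result.trials)
        if has_extinction:
            metrics = compute_metrics(result)
            tte = metrics.trials_to_extinction
            classes = {u: c.cls for u, c in classify_all(result).items()}
        else:
            tte = None
            classes = {}
        per_trial = [
            float(t.trace[:, result.index("dPag1")].mean())
            if "dPag1" in result.unit_names
            else None
            for t in result.trials
        ]
        summary = {
            "config_digest": digest,
            "avoidance_index_per_trial": per_trial,
            "trials_to_extinction": tte,
            "unit_classes": classes,
        }
        p = out_dir / f"{prefix}_summary.json"
        p.write_text(json.dumps(summary, indent=2) + "\n")
        manifest["summary"] = p
    return manifest


def write_report(report, out_dir: Union[str, Path], digest: Optional[str] = None) -> Path:
    """Serialize an ExperimentReport (criteria + metrics) to JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "name": report.name,
        "passed": report.passed,
        "description": report.description,
        "criteria": report.criteria,
        "metrics": report.metrics,
        "config_digest": digest,
    }

    def _default(o):
        import numpy as np

        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    path = out_dir / f"{report.name}.json"
    path.write_text(json.dumps(payload, indent=2, default=_default) + "\n")
    return path
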