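"""Parameter/scenario files, trajectory and metrics writers, run manifests.

Parameter files are flat YAML mappings whose keys are exactly the field
names of :class:`~ppgppsim.core.ModelParameters`.  Values are numbers, or
``{value: <num>, unit: "<unit>"}`` mappings whose unit string must match
the documented unit of that key.  Missing keys fall back to the shipped
reference set (logged); unknown keys are rejected.

Outputs of a run are written into one directory: ``trajectory.csv`` (15
significant digits, fixed column order), ``events.json``,
``metrics.json`` (when sensor metrics are supplied) and
``manifest.json``, which captures the full parameter set, scenario
settings, tolerances and package version so a run can be replayed
bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import yaml

from .core import ModelParameters, PARAMETER_UNITS, DomainError
from .simulate import Event, Scenario, Trajectory, simulate

__all__ = [
    "ParameterFileError",
    "load_parameters",
    "save_parameters",
    "write_outputs",
    "replay_manifest",
    "CSV_COLUMNS",
]

log = logging.getLogger("ppgppsim")

CSV_COLUMNS = (
    "t_min", "acyl_acp_uM", "fa_mg_per_l", "n_od", "nutr", "lim",
    "ppgpp_uM", "rib", "i", "gfp", "v_fas", "v_pls", "v_fa", "p1p2", "v_g",
)

#: numeric formatting for CSV export: 15 significant digits, locale-free
_FMT = "%.15g"


class ParameterFileError(ValueError):
    """A parameter file could not be validated; names the offending key."""


def _coerce_value(key: str, raw) -> float:
    if isinstance(raw, dict):
        extra = set(raw) - {"value", "unit"}
        if extra or "value" not in raw:
            raise ParameterFileError(
                f"parameter {key!r}: mapping values need 'value' (and optional 'unit'), got {raw!r}"
            )
        if "unit" in raw:
            expected = PARAMETER_UNITS[key]
            if str(raw["unit"]) != expected:
                raise ParameterFileError(
                    f"parameter {key!r}: unit {raw['unit']!r} does not match documented {expected!r}"
                )
        raw = raw["value"]
    if key == "acp_coupling":
        if not isinstance(raw, str):
            raise ParameterFileError(f"parameter {key!r}: expected a string, got {raw!r}")
        return raw
    if isinstance(raw, bool) or not isinstance(raw, (int, float)):
        raise ParameterFileError(f"parameter {key!r}: expected a number, got {raw!r}")
    return float(raw)


def load_parameters(path) -> ModelParameters:
    """Load and validate a parameter file.

    Missing keys are filled from the shipped reference set (with a logged
    notice); unknown keys, non-numeric values, wrong unit annotations and
    violated invariants raise :class:`ParameterFileError` naming the key.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterFileError(f"{path}: expected a flat key/value mapping")
    known = set(PARAMETER_UNITS)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ParameterFileError(f"{path}: unknown parameter key(s): {', '.join(unknown)}")
    overrides = {k: _coerce_value(k, v) for k, v in data.items()}
    missing = sorted(known - set(data))
    if missing:
        log.info(
            "%s: %d parameter(s) not given, using reference defaults: %s",
            path, len(missing), ", ".join(missing),
        )
    try:
        return ModelParameters(**overrides)
    except DomainError as exc:
        raise ParameterFileError(f"{path}: {exc}") from exc


def save_parameters(p: ModelParameters, path) -> None:
    """Write a parameter set as a flat YAML mapping with unit comments."""
    lines = ["# ppgppsim model parameters"]
    for key, val in p.to_dict().items():
        lines.append(f"{key}: {val}   # {PARAMETER_UNITS[key]}")
    Path(path).write_text("\n".join(lines) + "\n")


def _scenario_to_dict(scen: Scenario) -> dict:
    return {
        "t_end": scen.t_end,
        "output_dt": scen.output_dt,
        "rtol": scen.rtol,
        "atol": scen.atol,
        "init": None if scen.init is None else scen.init.to_array().tolist(),
        "events": [
            {"action": e.action, "value": e.value, "time": e.time,
             "trigger": list(e.trigger) if e.trigger else None, "delay": e.delay}
            for e in scen.events
        ],
    }


def _scenario_from_dict(d: dict, p: ModelParameters) -> Scenario:
    from .core import ModelState

    events = tuple(
        Event(
            action=e["action"],
            value=e["value"],
            time=e["time"],
            trigger=tuple(e["trigger"]) if e.get("trigger") else None,
            delay=e.get("delay", 0.0),
        )
        for e in d.get("events", ())
    )
    init = None if d.get("init") is None else ModelState.from_array(d["init"])
    return Scenario(
        params=p, init=init, t_end=d["t_end"], output_dt=d["output_dt"],
        events=events, rtol=d["rtol"], atol=d["atol"],
    )


def write_outputs(traj: Trajectory, metrics=None, out_dir=".", scenario: Optional[Scenario] = None) -> dict:
    """Write trajectory CSV, event log, optional metrics and a manifest.

    Returns a dict of the written paths.  An empty trajectory is an
    error and nothing is written.
    """
    if len(traj) == 0:
        raise DomainError("refusing to write an empty trajectory")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    df = traj.to_dataframe()
    csv_path = out / "trajectory.csv"
    df.to_csv(csv_path, index=False, float_format=_FMT)
    paths["trajectory"] = csv_path

    ev_path = out / "events.json"
    ev_path.write_text(json.dumps(traj.events_applied, indent=2) + "\n")
    paths["events"] = ev_path

    if metrics is not None:
        m_path = out / "metrics.json"
        m_path.write_text(json.dumps(metrics.to_json_dict(), indent=2) + "\n")
        paths["metrics"] = m_path

    from . import __version__

    manifest = {
        "package": "ppgppsim",
        "version": __version__,
        "parameters": None if traj.params is None else traj.params.to_dict(),
        "scenario": None if scenario is None else _scenario_to_dict(scenario),
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = man_path
    return paths


def replay_manifest(manifest_path, out_dir) -> dict:
    """Re-run a simulation from its manifest; outputs are bit-identical
    to the original run (the simulator is deterministic)."""
    man = json.loads(Path(manifest_path).read_text())
    if man.get("scenario") is None:
        raise DomainError("manifest has no scenario record to replay")
    p = ModelParameters(**man["parameters"])
    scen = _scenario_from_dict(man["scenario"], p)
    traj = simulate(scen)
    return write_outputs(traj, metrics=None, out_dir=out_dir, scenario=scen)
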