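"""Config and tabular I/O: YAML model definitions, CSV curves and targets.

The model config is a human-editable YAML (JSON parses too, being a
YAML subset)::

    name: female-10dof
    total_mass: 54.0
    segments:
      - {index: 1, name: head, mass: 6.91}
      ...
    couplings:
      - {id: 1, from: 1, to: 2, k: 150050.0, c: 2250.0}
      - {id: 4, from: 4, to: base, k: 150050.0, c: 2250.0}
      ...

Curves are exchanged as CSV with magnitude and phase columns; targets
as CSV with magnitude columns only.  Readers validate a strictly
increasing frequency column.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResult, TargetCurves
from .model import Coupling, ModelTopology, ParameterSet, SegmentSpec
from .modal import ModalResult
from .response import BiodynamicCurves, FrequencyGrid

__all__ = [
    "read_model_config",
    "write_model_config",
    "bundled_model_path",
    "write_curves_csv",
    "read_curves_csv",
    "write_targets_csv",
    "read_targets_csv",
    "write_modes_csv",
    "write_result_json",
]

CURVE_COLUMNS = [
    "frequency_hz",
    "stht_mag", "stht_phase_rad",
    "dpmi_mag", "dpmi_phase_rad",
    "am_mag", "am_phase_rad",
]
TARGET_COLUMNS = ["frequency_hz", "stht_mag", "dpmi_mag", "am_mag"]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent model config files."""


def bundled_model_path() -> Path:
    """Path of the bundled female 10-DOF model config."""
    return Path(str(resources.files("vibrobody").joinpath("data/female_10dof.yaml")))


def read_model_config(path: str | Path) -> tuple[ModelTopology, ParameterSet]:
    """Load and validate a topology + parameter set from YAML/JSON."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for key in ("segments", "couplings"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required key '{key}'")

    try:
        segments = tuple(
            SegmentSpec(int(s["index"]), str(s["name"]), float(s["mass"]))
            for s in raw["segments"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: segments: {exc}") from exc

    base_ids = [
        c.get("id") for c in raw["couplings"]
        if str(c.get("to", "")).lower() == "base"
    ]
    if len(base_ids) != 1:
        raise ConfigError(
            f"{path}: couplings: exactly one 'to: base' coupling required, "
            f"found {len(base_ids)} (ids {base_ids})"
        )
    try:
        couplings = tuple(
            Coupling(
                int(c["id"]),
                int(c["from"]),
                None if str(c["to"]).lower() == "base" else int(c["to"]),
                float(c["k"]),
                float(c["c"]),
            )
            for c in raw["couplings"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: couplings: {exc}") from exc

    try:
        topology = ModelTopology(
            name=str(raw.get("name", path.stem)),
            segments=segments,
            couplings=couplings,
            total_mass=float(raw.get("total_mass", sum(s.mass for s in segments))),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return topology, topology.default_parameters()


def write_model_config(
    topology: ModelTopology, path: str | Path, params: ParameterSet | None = None
) -> None:
    """Write a topology (optionally with overriding parameters) to YAML."""
    if params is None:
        params = topology.default_parameters()
    order = sorted(topology.couplings, key=lambda c: c.id)
    doc = {
        "name": topology.name,
        "total_mass": float(topology.total_mass),
        "segments": [
            {"index": s.index, "name": s.name, "mass": float(params.masses[s.index - 1])}
            for s in sorted(topology.segments, key=lambda s: s.index)
        ],
        "couplings": [
            {
                "id": c.id,
                "from": c.from_segment,
                "to": "base" if c.is_base else c.to_segment,
                "k": float(params.stiffnesses[i]),
                "c": float(params.dampings[i]),
            }
            for i, c in enumerate(order)
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# CSV curves / targets
# ---------------------------------------------------------------------------

def _validated_frequencies(df: pd.DataFrame, path) -> np.ndarray:
    f = df["frequency_hz"].to_numpy(dtype=float)
    if np.any(np.diff(f) <= 0):
        raise ValueError(f"{path}: frequency_hz column must be strictly increasing")
    return f


def write_curves_csv(curves: BiodynamicCurves, path: str | Path) -> None:
    """Write complex curves as magnitude/phase columns."""
    df = pd.DataFrame(
        {
            "frequency_hz": curves.grid.frequencies_hz,
            "stht_mag": np.abs(curves.stht),
            "stht_phase_rad": np.angle(curves.stht),
            "dpmi_mag": np.abs(curves.dpmi),
            "dpmi_phase_rad": np.angle(curves.dpmi),
            "am_mag": np.abs(curves.am),
            "am_phase_rad": np.angle(curves.am),
        }
    )
    df.to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> BiodynamicCurves:
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    f = _validated_frequencies(df, path)
    grid = FrequencyGrid(f)

    def polar(name: str) -> np.ndarray:
        return df[f"{name}_mag"].to_numpy() * np.exp(1j * df[f"{name}_phase_rad"].to_numpy())

    return BiodynamicCurves(grid, polar("stht"), polar("dpmi"), polar("am"))


def write_targets_csv(targets: TargetCurves, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency_hz": targets.grid.frequencies_hz,
            "stht_mag": targets.stht_mag,
            "dpmi_mag": targets.dpmi_mag,
            "am_mag": targets.am_mag,
        }
    ).to_csv(path, index=False)


def read_targets_csv(path: str | Path) -> TargetCurves:
    df = pd.read_csv(path)
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    f = _validated_frequencies(df, path)
    return TargetCurves(
        FrequencyGrid(f),
        df["stht_mag"].to_numpy(),
        df["dpmi_mag"].to_numpy(),
        df["am_mag"].to_numpy(),
    )


def write_modes_csv(result: ModalResult, path: str | Path) -> None:
    """One row per mode: mode index, frequency, then one column per segment."""
    n = result.mode_shapes.shape[0]
    df = pd.DataFrame(
        {
            "mode": np.arange(1, result.n_modes + 1),
            "frequency_hz": result.natural_frequencies_hz,
            **{f"segment_{i + 1}": result.mode_shapes[i] for i in range(n)},
        }
    )
    df.to_csv(path, index=False)


def write_result_json(result: CalibrationResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.as_dict(), indent=2))
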