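"""Delimited-text trial storage and the pipeline configuration file.

Trials are stored as long-format CSV, one file per condition, with columns
``trial, time_s, x_mm, y_mm, z_mm`` plus the nine joint-angle columns in
degrees (canonical order, ``_deg`` suffix).  A ``manifest.json`` alongside
records condition metadata, generative parameters and seeds.  Angles are
degrees on disk and radians in memory.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arm_model import ArmGeometry, JOINT_NAMES
from .errors import ConfigError, InvalidInputError
from .synthetic import ConditionSpec, TrialEnsemble, VariabilityModel

__all__ = [
    "ANGLE_COLUMNS",
    "write_ensemble_csv",
    "read_trials_csv",
    "write_manifest",
    "read_manifest",
    "load_config",
]

ANGLE_COLUMNS = tuple(f"{name}_deg" for name in JOINT_NAMES)
_POSITION_COLUMNS = ("x_mm", "y_mm", "z_mm")
# 10 significant digits keeps files compact while re-runs stay byte-identical.
_FLOAT_FORMAT = "%.10g"


def write_ensemble_csv(ensemble: TrialEnsemble, path) -> None:
    """Write all trials of one condition to a long-format CSV."""
    frames = []
    for i in range(ensemble.n_trials):
        df = pd.DataFrame(
            {
                "trial": i,
                "time_s": ensemble.time,
            }
        )
        for j, col in enumerate(_POSITION_COLUMNS):
            df[col] = ensemble.tips[i, :, j]
        for j, col in enumerate(ANGLE_COLUMNS):
            df[col] = np.rad2deg(ensemble.angles[i, :, j])
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )


def read_trials_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Read trials from CSV: ``(time, tips, angles)``.

    Accepts long format with a ``trial`` column or a single-trial file
    without one.  ``tips`` is ``(n_trials, n_samples, 3)`` mm; ``angles``
    is ``(n_trials, n_samples, 9)`` rad, or ``None`` when the angle
    columns are absent.  All trials must share the same time base.
    """
    df = pd.read_csv(path)
    required = {"time_s", *_POSITION_COLUMNS}
    missing = sorted(required - set(df.columns))
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    has_angles = all(c in df.columns for c in ANGLE_COLUMNS)
    if "trial" not in df.columns:
        df = df.assign(trial=0)
    groups = [g for _, g in df.groupby("trial", sort=True)]
    time = groups[0]["time_s"].to_numpy()
    tips, angles = [], []
    for g in groups:
        if g.shape[0] != time.size or not np.allclose(g["time_s"].to_numpy(), time):
            raise InvalidInputError(f"{path}: trials have inconsistent time bases")
        tips.append(g[list(_POSITION_COLUMNS)].to_numpy())
        if has_angles:
            angles.append(np.deg2rad(g[list(ANGLE_COLUMNS)].to_numpy()))
    return (
        time,
        np.asarray(tips),
        np.asarray(angles) if has_angles else None,
    )


def write_manifest(
    path,
    geometry: ArmGeometry,
    conditions: list[ConditionSpec],
    models: list[VariabilityModel] | None,
    files: list[str],
) -> None:
    """Record dataset provenance: geometry, conditions, noise models, files."""
    payload = {
        "geometry_mm": {
            "upper_arm_length": geometry.upper_arm_length,
            "forearm_length": geometry.forearm_length,
            "hand_length": geometry.hand_length,
            "finger_length": geometry.finger_length,
        },
        "conditions": [
            {
                "condition": cond.to_dict(),
                "variability": models[i].to_dict() if models else None,
                "file": files[i],
            }
            for i, cond in enumerate(conditions)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except FileNotFoundError:
        raise ConfigError(f"dataset manifest not found: {path}") from None


def condition_from_manifest(entry: dict) -> ConditionSpec:
    c = entry["condition"]
    return ConditionSpec(
        rod_length=c["rod_length_mm"],
        displaced=c["displaced"],
        start_point=tuple(c["start_point_mm"]),
        target_point=tuple(c["target_point_mm"]),
        n_trials=c["n_trials"],
        sample_rate=c["sample_rate_hz"],
        movement_time=c["movement_time_s"],
        pre_hold=c["pre_hold_s"],
        post_hold=c["post_hold_s"],
    )


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("geometry", "seed")
_GEOMETRY_KEYS = ("upper_arm_length", "forearm_length", "hand_length", "finger_length")


def load_config(path) -> dict:
    """Load and validate the pipeline YAML configuration.

    Required keys: ``geometry`` (segment lengths, mm) and ``seed``.
    Optional: ``variability`` (``sigma_gev_deg``, ``sigma_ngev_deg``,
    ``temporal_smoothness_s``), ``design`` (``n_trials``,
    ``movement_time_s``, ``sample_rate_hz``, ``start_point_mm``),
    ``thresholds`` (``speed_mm_s``, ``radius_mm``), ``data_dir`` (analyze
    an existing dataset instead of simulating), ``all_instants``.
    Missing required keys raise :class:`~ucmreach.errors.ConfigError`
    listing every absent key at once.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(p.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"config is missing required keys: {missing}")
    geo = raw["geometry"]
    geo_missing = [k for k in _GEOMETRY_KEYS if k not in geo]
    if geo_missing:
        raise ConfigError(f"config geometry is missing keys: {geo_missing}")
    return raw
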