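"""CSV schemas, config validation and run manifests for the pipeline.

Tabular interchange formats:

* concentration data — columns ``subject_id, variant, time_h,
  conc_ug_ml, censored, dose_mg_kg``;
* half-life observations — ``variant, mean_h, sd_h, n``;
* posterior draws — ``chain, draw`` plus one column per parameter;
* PK parameter tables — one row per subject (or variant mean) with the
  standard NCA column set.

Every pipeline command writes a ``manifest.json`` next to its outputs
(config echo, seed, package version, SHA-256 of each input) so a run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import HalfLifeObservation, PosteriorFit
from .pk import ConcentrationTimeSeries

__all__ = [
    "read_concentration_csv",
    "write_concentration_csv",
    "read_half_life_csv",
    "write_half_life_csv",
    "write_posterior_csv",
    "read_posterior_csv",
    "validate_config",
    "write_manifest",
    "ConfigError",
]

CONCENTRATION_COLUMNS = [
    "subject_id", "variant", "time_h", "conc_ug_ml", "censored", "dose_mg_kg",
]


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


def read_concentration_csv(path) -> list[ConcentrationTimeSeries]:
    """Load per-subject curves, rejecting malformed rows with an error
    that names the offending subject and column."""
    df = pd.read_csv(path)
    missing = [c for c in CONCENTRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (subject, variant), grp in df.groupby(["subject_id", "variant"], sort=False):
        times = grp["time_h"].to_numpy(dtype=float)
        conc = grp["conc_ug_ml"].to_numpy(dtype=float)
        if len(times) > 1 and (np.diff(times) <= 0).any():
            raise ValueError(
                f"{path}: subject {subject!r} column time_h is not strictly increasing"
            )
        if (conc[~grp["censored"].astype(bool).to_numpy()] < 0).any():
            raise ValueError(
                f"{path}: subject {subject!r} has negative values in column conc_ug_ml"
            )
        dose = grp["dose_mg_kg"].iloc[0] * 1000.0  # μg/kg
        out.append(
            ConcentrationTimeSeries(
                subject_id=str(subject),
                variant=str(variant),
                dose=float(dose),
                times=times,
                concentrations=conc,
                censored=grp["censored"].astype(bool).to_numpy(),
            )
        )
    return out


def write_concentration_csv(series: Sequence[ConcentrationTimeSeries], path) -> None:
    rows = []
    for s in series:
        for t, c, cen in zip(s.times, s.concentrations, s.censored):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "variant": s.variant,
                    "time_h": t,
                    "conc_ug_ml": c,
                    "censored": int(cen),
                    "dose_mg_kg": s.dose / 1000.0,
                }
            )
    pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS).to_csv(path, index=False)


def read_half_life_csv(path) -> list[HalfLifeObservation]:
    df = pd.read_csv(path)
    missing = [c for c in ("variant", "mean_h", "sd_h", "n") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        HalfLifeObservation(variant=str(r.variant), mean=r.mean_h, sd=r.sd_h, n=int(r.n))
        for r in df.itertuples()
    ]


def write_half_life_csv(observations: Sequence[HalfLifeObservation], path) -> None:
    pd.DataFrame(
        [
            {"variant": o.variant, "mean_h": o.mean, "sd_h": o.sd, "n": o.n}
            for o in observations
        ]
    ).to_csv(path, index=False)


def write_posterior_csv(fit: PosteriorFit, path) -> None:
    fit.to_dataframe().to_csv(path, index=False)


def read_posterior_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("chain", "draw"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df


def validate_config(
    config: Mapping[str, Any], schema: Mapping[str, type | tuple[type, ...]],
    required: Sequence[str] = (),
) -> dict[str, Any]:
    """Check a flat config block against a {key: type} schema.

    Unknown keys are rejected (typo protection); ``required`` keys must
    be present.  Returns a plain dict of the validated values.
    """
    unknown = sorted(set(config) - set(schema))
    if unknown:
        raise ConfigError(f"unknown config keys {unknown}; allowed: {sorted(schema)}")
    for key in required:
        if key not in config:
            raise ConfigError(f"missing required config key {key!r}")
    out = {}
    for key, value in config.items():
        expected = schema[key]
        if isinstance(value, bool) and expected in (int, float):
            raise ConfigError(f"config key {key!r}: expected {expected}, got bool")
        if not isinstance(value, expected):
            raise ConfigError(
                f"config key {key!r}: expected {expected}, got {type(value).__name__}"
            )
        out[key] = value
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(
    out_dir, command: str, config: Mapping[str, Any], seed: int | None,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Write manifest.json recording how a run was produced."""
    from . import __version__

    manifest = {
        "command": command,
        "config": dict(config),
        "seed": seed,
        "package_version": __version__,
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
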