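"""File-format plumbing: patient CSV, parameter YAML, fit JSON.

CSV is the sole tabular interchange (administrative-data context), JSON
holds structured fit results, YAML holds parameter configurations.  The
patient CSV dialect has header ``type,age,los_days,mode`` and permits
``#``-prefixed provenance comment lines before the header.
"""

from __future__ import annotations

import io as _io
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import FitResult, StageResult
from .likelihood import PatientRecord
from .model import DAYS_PER_YEAR, PARAM_ORDER, ModelParams

FIT_SCHEMA_VERSION = 1

_CSV_COLUMNS = ("type", "age", "los_days", "mode")


class PatientCSVError(ValueError):
    """Raised when a patient CSV has malformed rows; lists line numbers."""

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "\n".join(f"  line {ln}: {msg}" for ln, msg in self.errors)
        super().__init__(f"invalid patient rows:\n{lines}")


def read_patient_csv(path) -> list[PatientRecord]:
    """Read and validate a patient CSV; raises with row-level line numbers."""
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    body_start = 0
    while body_start < len(lines) and lines[body_start].startswith("#"):
        body_start += 1
    if body_start >= len(lines):
        raise ValueError(f"{path}: empty patient file")
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), dtype=str)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no patient rows")

    records, errors = [], []
    for i, row in df.iterrows():
        line_no = body_start + 2 + i  # 1-based, after header
        try:
            records.append(PatientRecord(
                stroke_type=row["type"], age=float(row["age"]),
                los_days=float(row["los_days"]), mode=row["mode"],
            ))
        except (TypeError, ValueError) as exc:
            errors.append((line_no, str(exc)))
    if errors:
        raise PatientCSVError(errors)
    return records


def write_patient_csv(records, path, provenance: dict | None = None) -> None:
    """Write the patient CSV dialect with an optional provenance header."""
    from .likelihood import records_to_frame

    df = records_to_frame(records)
    path = Path(path)
    prov = dict(provenance or {})
    if isinstance(records, pd.DataFrame):
        prov = {**records.attrs.get("provenance", {}), **prov}
    with path.open("w") as fh:
        for key, val in prov.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False, float_format="%.10g",
                  columns=list(_CSV_COLUMNS), lineterminator="\n")


def read_params_yaml(path) -> tuple[ModelParams, float]:
    """Load a parameter config; returns (params, days_per_year)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    days_per_year = float(raw.pop("days_per_year", DAYS_PER_YEAR))
    mask = frozenset(raw.pop("zero_mask", ["nu1", "nu2", "rho1"]))
    unknown = set(raw) - set(PARAM_ORDER)
    if unknown:
        raise ValueError(f"unknown parameter names in config: {sorted(unknown)}")
    values = {name: float(raw.get(name, 0.0)) for name in PARAM_ORDER}
    return ModelParams(**values, zero_mask=mask), days_per_year


def write_params_yaml(params: ModelParams, path,
                      days_per_year: float = DAYS_PER_YEAR) -> None:
    payload = {n: float(getattr(params, n)) for n in PARAM_ORDER}
    payload["zero_mask"] = sorted(params.zero_mask)
    payload["days_per_year"] = days_per_year
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def reference_params() -> tuple[ModelParams, float]:
    """The shipped fitted parameter set for the revised model."""
    ref = resources.files("phrex.data") / "fitted_params_revised.yaml"
    with resources.as_file(ref) as path:
        return read_params_yaml(path)


def fit_to_dict(fit: FitResult) -> dict:
    return {
        "schema_version": FIT_SCHEMA_VERSION,
        "params": fit.params.as_dict(effective=False),
        "zero_mask": sorted(fit.params.zero_mask),
        "free_names": list(fit.free_names),
        "cov": np.asarray(fit.cov).tolist(),
        "se": np.asarray(fit.se).tolist(),
        "z": np.asarray(fit.z).tolist(),
        "p": np.asarray(fit.p).tolist(),
        "loglik": fit.loglik,
        "info_pd": fit.info_pd,
        "seed": fit.seed,
        "n": fit.n,
        "stage_trace": [
            {"name": s.name, "free_names": list(s.free_names),
             "loglik": s.loglik, "converged": s.converged, "nfev": s.nfev}
            for s in fit.stage_trace
        ],
    }


def write_fit_json(fit: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fit), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit_json(path) -> FitResult:
    with open(path) as fh:
        raw = json.load(fh)
    version = raw.get("schema_version")
    if version != FIT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported fit schema version {version!r}; "
            f"expected {FIT_SCHEMA_VERSION}")
    params = ModelParams(**raw["params"], zero_mask=frozenset(raw["zero_mask"]))
    return FitResult(
        params=params,
        free_names=tuple(raw["free_names"]),
        cov=np.array(raw["cov"]),
        se=np.array(raw["se"]),
        z=np.array(raw["z"]),
        p=np.array(raw["p"]),
        loglik=float(raw["loglik"]),
        stage_trace=[StageResult(
            name=s["name"], free_names=tuple(s["free_names"]),
            loglik=s["loglik"], converged=s["converged"], nfev=s["nfev"],
        ) for s in raw["stage_trace"]],
        info_pd=bool(raw["info_pd"]),
        seed=raw["seed"],
        n=int(raw["n"]),
    )
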