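"""Readers and writers for the pipeline's CSV/JSON/YAML schemas.

All tables are UTF-8, comma-separated, header row mandatory, "." decimal.
Readers validate against the documented schema and report the first violating
row and column; writers round only at this serialization boundary and emit
deterministic column orders, so identical inputs produce byte-identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .agree import AppraisalMatrix
from .delphi import (
    BASES,
    FAMILIARITY_LEVELS,
    ExpertProfile,
    RatingMatrix,
    SelectionConfig,
)
from .nma import ArmRecord, McmcConfig
from .pool import ExtractionRecord

__all__ = [
    "read_appraisals",
    "read_arms",
    "read_config",
    "read_extractions",
    "read_profiles",
    "read_ratings",
    "write_json_report",
    "write_table",
]


class SchemaError(ValueError):
    pass


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    return df


def read_ratings(path: str | Path) -> RatingMatrix:
    """Read a long-format ratings CSV (expert_id, outcome_id, score)."""
    df = _read_csv(path, ["expert_id", "outcome_id", "score"])
    for i, v in df["score"].items():
        if pd.isna(v) or float(v) != int(float(v)) or not (1 <= int(float(v)) <= 9):
            raise SchemaError(
                f"{path}: row {i + 2}: score {v!r} is not an integer in [1, 9]"
            )
    return RatingMatrix.from_frame(df)


def read_profiles(path: str | Path) -> list[ExpertProfile]:
    """Read an expert-profile CSV: one row per expert, a column per basis plus
    a familiarity column."""
    cols = ["expert_id", *BASES, "familiarity"]
    df = _read_csv(path, cols)
    profiles = []
    for i, row in df.iterrows():
        fam = str(row["familiarity"]).strip()
        if fam not in FAMILIARITY_LEVELS:
            raise SchemaError(f"{path}: row {i + 2}: unknown familiarity {fam!r}")
        profiles.append(
            ExpertProfile(
                expert_id=str(row["expert_id"]),
                basis_levels={b: str(row[b]).strip() for b in BASES},
                familiarity=fam,
            )
        )
    return profiles


def read_appraisals(
    path: str | Path, mode: str = "per-rater"
) -> list[AppraisalMatrix]:
    """Read AGREE II appraisals.

    per-rater mode: columns document_id, appraiser_id, item, score.
    aggregated mode: columns document_id, item, mean_score, n_appraisers.
    """
    matrices = []
    if mode == "per-rater":
        df = _read_csv(path, ["document_id", "appraiser_id", "item", "score"])
        for doc, group in df.groupby("document_id", sort=True):
            wide = group.pivot_table(
                index="appraiser_id", columns="item", values="score", aggfunc="first"
            )
            if list(wide.columns) != list(range(1, 24)) or wide.isna().any().any():
                raise SchemaError(
                    f"{path}: document {doc!r}: need complete items 1..23 per appraiser"
                )
            matrices.append(
                AppraisalMatrix(
                    str(doc),
                    tuple(str(a) for a in wide.index),
                    wide.to_numpy(),
                )
            )
    elif mode == "aggregated":
        df = _read_csv(path, ["document_id", "item", "mean_score", "n_appraisers"])
        for doc, group in df.groupby("document_id", sort=True):
            g = group.sort_values("item")
            if list(g["item"]) != list(range(1, 24)):
                raise SchemaError(f"{path}: document {doc!r}: need items 1..23")
            matrices.append(
                AppraisalMatrix.from_item_means(
                    str(doc), g["mean_score"].tolist(), int(g["n_appraisers"].iloc[0])
                )
            )
    else:
        raise SchemaError(f"unknown appraisal mode {mode!r}")
    return matrices


def read_extractions(path: str | Path) -> list[ExtractionRecord]:
    """Read trial outcome extractions (trial_id, outcome_name, domain)."""
    df = _read_csv(path, ["trial_id", "outcome_name", "domain"])
    records = []
    for tid, group in df.groupby("trial_id", sort=True):
        pairs = list(zip(group["outcome_name"], group["domain"]))
        records.append(ExtractionRecord.from_pairs(str(tid), pairs))
    return records


def read_arms(path: str | Path, measure: str) -> list[ArmRecord]:
    """Read arm-level trial data.

    Continuous (measure "md"): trial_id, treatment, n, mean, sd.
    Binary (measure "rr"): trial_id, treatment, n, events.
    """
    if measure == "md":
        df = _read_csv(path, ["trial_id", "treatment", "n", "mean", "sd"])
        return [
            ArmRecord(str(r.trial_id), str(r.treatment), int(r.n),
                      mean=float(r.mean), sd=float(r.sd))
            for r in df.itertuples()
        ]
    if measure == "rr":
        df = _read_csv(path, ["trial_id", "treatment", "n", "events"])
        return [
            ArmRecord(str(r.trial_id), str(r.treatment), int(r.n), events=int(r.events))
            for r in df.itertuples()
        ]
    raise SchemaError(f"unknown measure {measure!r}")


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML/JSON run configuration into plain dictionaries."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return dict(data)


def selection_config_from_dict(data: Mapping[str, Any]) -> SelectionConfig:
    known = {
        k: data[k]
        for k in (
            "agreement_threshold", "cv_threshold", "band_edges",
            "override_set", "agreement_basis", "flag_high_cv_only", "sd_ddof",
        )
        if k in data
    }
    if "band_edges" in known:
        known["band_edges"] = tuple(known["band_edges"])
    return SelectionConfig(**known)


def mcmc_config_from_dict(data: Mapping[str, Any]) -> McmcConfig:
    known = {
        k: data[k]
        for k in (
            "n_chains", "n_iterations", "n_burnin", "thin", "seed",
            "prior_d_sd", "tau_upper", "psrf_limits",
        )
        if k in data
    }
    if "psrf_limits" in known:
        known["psrf_limits"] = tuple(known["psrf_limits"])
    return McmcConfig(**known)


def write_table(df: pd.DataFrame, path: str | Path, float_decimals: int = 4) -> Path:
    """Write a result table as CSV with fixed column order and rounding."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=f"%.{float_decimals}f")
    return path


def write_json_report(payload: Mapping[str, Any], path: str | Path) -> Path:
    """Write a JSON summary (sorted keys, so reruns are byte-identical)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
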