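"""Tabular input/output with strict schema validation.

All tables are tab-separated UTF-8 text with a header row. Spot tables are
long (tidy) format so that a spot missing from a gel is represented by the
absence of its row, not by a sentinel value.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

SPOT_TABLE_COLUMNS = ["patient_id", "replicate_index", "spot_id", "raw_volume"]

CLINICAL_COLUMNS = [
    "patient_id",
    "edss_at_lp",
    "delta_edss",
    "relapse_count",
    "dmt_2y",
    "dmt_5y",
    "class_2y",
    "class_5y",
    "diagnosis",
]

#: Clinical aggressiveness tokens. H/M/L are the associable classes; LB is the
#: benign subset of L; the remaining tokens mark patients excluded from
#: cluster-class association tables.
CLASS_TOKENS = frozenset({"H", "M", "L", "LB", "PP", "lost", "no_MS", "death"})

#: Disease-modifying treatment line tokens.
DMT_TOKENS = frozenset({"none", "I", "II", "lost", "death", "no_MS"})

HORIZONS = ("2y", "5y")


class SchemaError(ValueError):
    """Raised when an input table violates its schema."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """All thresholds used by the pipeline, with their default values.

    Thresholds expressed as fractions: ``best_pair_max = 0.30`` means a mean
    replicate %SD of 30%.
    """

    sd_accept_max: float = 0.32
    best_pair_max: float = 0.30
    presence_fraction: float = 1.0
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    k_main_clusters: int = 2
    outlier_max_size: int = 1
    phospho_ds_threshold: float = 0.08
    marker_spots: tuple[str, ...] = ("288", "289")
    apoe_spot: str = "469"
    predictive_mode: str = "within_cluster"

    def __post_init__(self) -> None:
        for name in ("sd_accept_max", "best_pair_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 <= self.presence_fraction <= 1:
            raise ValueError("presence_fraction must be in [0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.k_main_clusters < 1:
            raise ValueError("k_main_clusters must be >= 1")
        if self.outlier_max_size < 0:
            raise ValueError("outlier_max_size must be >= 0")
        if self.predictive_mode not in ("within_cluster", "observed_prevalence"):
            raise ValueError(f"unknown predictive_mode {self.predictive_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"config file {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "marker_spots" in raw:
            raw["marker_spots"] = tuple(str(s) for s in raw["marker_spots"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["marker_spots"] = list(self.marker_spots)
        return d


def _require_columns(df: pd.DataFrame, columns: list[str], path: Any) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def validate_spot_table(df: pd.DataFrame, source: Any = "<table>") -> pd.DataFrame:
    """Validate a long spot table; returns it with canonical dtypes."""
    _require_columns(df, SPOT_TABLE_COLUMNS, source)
    df = df[SPOT_TABLE_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["spot_id"] = df["spot_id"].astype(str)
    try:
        df["replicate_index"] = df["replicate_index"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{source}: non-integer replicate_index ({exc})") from None
    volumes = pd.to_numeric(df["raw_volume"], errors="coerce")
    bad = volumes.isna() | (volumes <= 0)
    if bad.any():
        # +2: header row plus 1-based numbering
        line = int(df.index[bad][0]) + 2
        raise SchemaError(
            f"{source}: raw_volume must be a positive number (first offence at line {line})"
        )
    df["raw_volume"] = volumes.astype(float)
    if (df["replicate_index"] < 0).any():
        raise SchemaError(f"{source}: replicate_index must be >= 0")
    key = ["patient_id", "replicate_index", "spot_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = df.loc[df.index[dup][0], key]
        raise SchemaError(
            f"{source}: duplicate key (patient_id={row.patient_id!r}, "
            f"replicate_index={row.replicate_index}, spot_id={row.spot_id!r})"
        )
    return df.reset_index(drop=True)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_spot_table(df, source=path)


def write_spot_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_spot_table(df)[SPOT_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_clinical_table(df: pd.DataFrame, source: Any = "<table>") -> pd.DataFrame:
    _require_columns(df, CLINICAL_COLUMNS[:-1], source)
    df = df.copy()
    if "diagnosis" not in df.columns:
        df["diagnosis"] = ""
    df = df[CLINICAL_COLUMNS]
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        raise SchemaError(f"{source}: duplicate patient_id")
    for col in ("edss_at_lp", "delta_edss"):
        df[col] = pd.to_numeric(df[col].replace({"?": None}), errors="raise")
    # "?" means unknown relapse count; keep it distinct from zero
    relapse = df["relapse_count"].astype(str).replace({"?": None, "nan": None, "None": None, "<NA>": None})
    df["relapse_count"] = pd.to_numeric(relapse).astype("Int64")
    for col in ("dmt_2y", "dmt_5y"):
        bad = ~df[col].astype(str).isin(DMT_TOKENS)
        if bad.any():
            raise SchemaError(
                f"{source}: unknown DMT token {df.loc[df.index[bad][0], col]!r} in {col}"
            )
    for col in ("class_2y", "class_5y"):
        bad = ~df[col].astype(str).isin(CLASS_TOKENS)
        if bad.any():
            raise SchemaError(
                f"{source}: unknown class token {df.loc[df.index[bad][0], col]!r} in {col}"
            )
    for horizon in HORIZONS:
        lb = df[f"class_{horizon}"] == "LB"
        treated = lb & (df[f"dmt_{horizon}"] != "none")
        if treated.any():
            pid = df.loc[df.index[treated][0], "patient_id"]
            raise SchemaError(
                f"{source}: benign (LB) patient {pid!r} must be untreated at {horizon}"
            )
    edss = df["edss_at_lp"].dropna()
    if ((edss < 0) | (edss > 10)).any():
        raise SchemaError(f"{source}: edss_at_lp outside [0, 10]")
    return df.reset_index(drop=True)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_clinical_table(df, source=path)


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_clinical_table(df).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class StratificationReport:
    """Container for all end-of-run result tables.

    ``crosstabs`` and ``predictive`` are keyed by ``(stratification, horizon)``
    e.g. ``("two_spot", "5y")``.
    """

    qc: pd.DataFrame
    cluster_assignments: pd.DataFrame
    differential: pd.DataFrame
    crosstabs: dict[tuple[str, str], pd.DataFrame]
    predictive: dict[tuple[str, str], pd.DataFrame]
    chi_square: dict[tuple[str, str], dict[str, float]]
    summary: dict[str, Any]


def write_report(report: StratificationReport, out_dir: str | Path) -> list[Path]:
    """Write the report as a fixed set of TSV files plus a JSON summary.

    Returns the list of files written. Output is deterministic: fixed column
    order, fixed float formatting, sorted keys in the summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    _write(report.qc, "qc.tsv")
    _write(report.cluster_assignments, "clusters.tsv")
    _write(report.differential, "differential.tsv")

    def _stack(tables: Mapping[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
        parts = []
        for (strat, horizon), tab in sorted(tables.items()):
            part = tab.reset_index(names="cluster")
            part.insert(0, "stratification", strat)
            part.insert(1, "horizon", horizon)
            parts.append(part)
        if not parts:
            return pd.DataFrame(columns=["stratification", "horizon", "cluster"])
        return pd.concat(parts, ignore_index=True)

    _write(_stack(report.crosstabs), "crosstabs.tsv")
    _write(_stack(report.predictive), "predictive_values.tsv")

    summary = dict(report.summary)
    summary["chi_square"] = {
        f"{strat}/{horizon}": stats_
        for (strat, horizon), stats_ in sorted(report.chi_square.items())
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
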