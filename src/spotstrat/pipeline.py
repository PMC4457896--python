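"""End-to-end orchestration of the stratification pipeline."""

from __future__ import annotations

import hashlib
import logging
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import clinical as clin
from . import cluster as clu
from . import qc
from . import stats
from .io import HORIZONS, RunConfig, StratificationReport

log = logging.getLogger("spotstrat")

STAGES = ("qc", "cluster", "diff", "discriminant", "evaluate")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _evaluate(
    assignment: clu.ClusterAssignment,
    clinical_table: pd.DataFrame,
    stratification: str,
    report_crosstabs: dict,
    report_predictive: dict,
    report_chi: dict,
    config: RunConfig,
) -> None:
    for horizon in HORIZONS:
        tab = clin.cross_tabulate(assignment, clinical_table, horizon)
        key = (stratification, horizon)
        report_crosstabs[key] = tab.column_percent
        report_predictive[key] = clin.predictive_values(
            tab.counts, mode=config.predictive_mode
        )
        report_chi[key] = {
            "chi2": tab.chi2,
            "df": tab.df,
            "p_value": tab.p_value,
            "n_classified": tab.n_classified,
            "n_excluded": int(len(tab.excluded)),
        }
        log.info(
            "%s/%s: %d classified, %d excluded, chi2 p=%s",
            stratification,
            horizon,
            tab.n_classified,
            len(tab.excluded),
            tab.p_value,
        )


def run_pipeline(
    spot_table: pd.DataFrame,
    clinical_table: pd.DataFrame,
    config: RunConfig | None = None,
    stages: Sequence[str] = STAGES,
) -> StratificationReport:
    """Run the requested pipeline stages and collect a report.

    Stages are ordered and cumulative (``diff`` implies ``qc`` and
    ``cluster`` already ran); later tables stay empty when a stage is gated
    off.
    """
    config = config or RunConfig()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    enabled = {s: s in stages for s in STAGES}

    crosstabs: dict = {}
    predictive: dict = {}
    chi_square: dict = {}
    summary: dict = {
        "config": config.to_dict(),
        "versions": {
            "spotstrat": _pkg_version,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": list(stages),
    }

    report = StratificationReport(
        qc=pd.DataFrame(),
        cluster_assignments=pd.DataFrame(columns=["patient_id", "stratification", "cluster"]),
        differential=pd.DataFrame(),
        crosstabs=crosstabs,
        predictive=predictive,
        chi_square=chi_square,
        summary=summary,
    )

    try:
        profiles, qc_table = qc.build_profiles(spot_table, best_pair_max=config.best_pair_max)
        spots = qc.select_representative_spots(
            profiles, presence_fraction=config.presence_fraction
        )
        matrix = qc.profile_matrix(profiles)
        summary["n_patients"] = len(profiles)
        summary["n_representative_spots"] = len(spots)
        log.info("QC: %d patients, %d representative spots", len(profiles), len(spots))
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc
    report.qc = qc_table
    if not enabled["cluster"]:
        return report

    try:
        assignment_rows = []
        _, full_assignment = clu.cluster_profiles(
            matrix,
            spots=spots,
            k_main=config.k_main_clusters,
            outlier_max_size=config.outlier_max_size,
        )
        marker_spots = [s for s in config.marker_spots]
        three_spots = marker_spots + [config.apoe_spot]
        _, two_spot_assignment = clu.cluster_profiles(
            matrix, spots=marker_spots, k_main=2, outlier_max_size=config.outlier_max_size
        )
        _, three_spot_assignment = clu.cluster_profiles(
            matrix, spots=three_spots, k_main=3, outlier_max_size=config.outlier_max_size
        )
        for name, a in [
            ("full", full_assignment),
            ("two_spot", two_spot_assignment),
            ("three_spot", three_spot_assignment),
        ]:
            for patient, label in sorted(a.labels.items()):
                assignment_rows.append(
                    {"patient_id": patient, "stratification": name, "cluster": label}
                )
        report.cluster_assignments = pd.DataFrame(assignment_rows)
        summary["full_clusters"] = {
            c: len(full_assignment.members(c)) for c in full_assignment.main_clusters
        }
        summary["full_outliers"] = full_assignment.outliers
    except Exception as exc:
        raise RuntimeError(f"stage cluster failed: {exc}") from exc
    if not enabled["diff"]:
        return report

    try:
        mains = full_assignment.main_clusters
        if len(mains) >= 2:
            report.differential = stats.select_differential_spots(
                matrix[spots],
                full_assignment,
                mains[0],
                mains[1],
                p_threshold=config.p_threshold,
                fc_threshold=config.fc_threshold,
            )
            summary["n_differential_selected"] = int(report.differential["selected"].sum())
            summary["n_tests"] = int(len(report.differential))
    except Exception as exc:
        raise RuntimeError(f"stage diff failed: {exc}") from exc
    if not enabled["discriminant"]:
        return report

    try:
        from . import discriminant as disc

        if len(two_spot_assignment.main_clusters) == 2:
            model = disc.fit_discriminant(matrix, two_spot_assignment, marker_spots)
            summary["discriminant"] = {
                "groups": list(model.groups),
                "feature_spots": list(model.feature_spots),
                "coefficients": {g: model.coefficients[g].tolist() for g in model.groups},
                "intercepts": model.intercepts,
            }
    except Exception as exc:
        raise RuntimeError(f"stage discriminant failed: {exc}") from exc
    if not enabled["evaluate"]:
        return report

    try:
        _evaluate(
            two_spot_assignment, clinical_table, "two_spot", crosstabs, predictive, chi_square, config
        )
        _evaluate(
            three_spot_assignment,
            clinical_table,
            "three_spot",
            crosstabs,
            predictive,
            chi_square,
            config,
        )
    except Exception as exc:
        raise RuntimeError(f"stage evaluate failed: {exc}") from exc
    return report
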