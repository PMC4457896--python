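"""Stage 5: clinical aggressiveness classes and cluster-class association.

Classes derive from the disease-modifying treatment (DMT) line at the end of
each follow-up horizon: second-line therapy -> H (highly aggressive),
first-line -> M (moderate), untreated -> L (low; the benign LB subset also
maps to L for association). Primary-progressive, deceased, lost-to-follow-up
and non-diseased patients are excluded from association tables but remain
listed with their exclusion reason.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats
from .cluster import OUTLIER_LABEL, ClusterAssignment

ASSOCIABLE_CLASSES = ("H", "L", "M")

#: class-or-excluded resolution for stored clinical tokens
_EXCLUDED_TOKENS = {
    "PP": "primary_progressive",
    "death": "deceased",
    "lost": "lost_to_follow_up",
    "no_MS": "no_disease",
}


def class_from_dmt(dmt: str, benign: bool = False) -> str:
    """Map a DMT line token to a clinical class (LB when benign & untreated)."""
    if dmt == "II":
        return "H"
    if dmt == "I":
        return "M"
    if dmt == "none":
        return "LB" if benign else "L"
    if dmt in _EXCLUDED_TOKENS:
        return dmt
    raise ValueError(f"unknown DMT token {dmt!r}")


@dataclasses.dataclass(frozen=True)
class AssignedClass:
    label: str | None  # one of H/L/M, or None when excluded
    benign: bool
    excluded_reason: str | None


def assign_class(record: Mapping[str, object], horizon: str) -> AssignedClass:
    """Resolve one patient's class at a horizon ('2y' or '5y').

    The stored class token is authoritative; LB collapses into L for
    association while keeping the benign flag. Tokens outside H/M/L/LB
    yield an exclusion.
    """
    if horizon not in ("2y", "5y"):
        raise ValueError(f"unknown horizon {horizon!r}")
    token = str(record[f"class_{horizon}"])
    if token in _EXCLUDED_TOKENS:
        return AssignedClass(label=None, benign=False, excluded_reason=_EXCLUDED_TOKENS[token])
    if token == "LB":
        return AssignedClass(label="L", benign=True, excluded_reason=None)
    if token in ASSOCIABLE_CLASSES:
        return AssignedClass(label=token, benign=False, excluded_reason=None)
    raise ValueError(f"unknown class token {token!r}")


@dataclasses.dataclass
class CrossTab:
    """Cluster x class association for one stratification and horizon.

    ``counts`` rows are clusters, columns are classes. ``column_percent``
    holds P(cluster | class) (each class column sums to 100);
    ``predictive`` holds P(class | cluster) (each cluster row sums to 100).
    """

    counts: pd.DataFrame
    column_percent: pd.DataFrame
    predictive: pd.DataFrame
    chi2: float | None
    df: int | None
    p_value: float | None
    excluded: pd.DataFrame  # patient_id, reason

    @property
    def n_classified(self) -> int:
        return int(self.counts.to_numpy().sum())


def cross_tabulate(
    assignment: ClusterAssignment,
    clinical: pd.DataFrame,
    horizon: str,
) -> CrossTab:
    """Count classified patients per (cluster, class) and test association.

    Patients are excluded when their class is not in H/M/L or their cluster
    is the outlier label; exclusions are returned with reasons so that
    classified + excluded always equals the cohort size.
    """
    clusters = dict(assignment.labels)
    records = clinical.set_index("patient_id", drop=False)
    rows: dict[str, dict[str, int]] = {}
    excluded: list[dict[str, str]] = []
    for patient in records.index:
        if patient not in clusters:
            excluded.append({"patient_id": patient, "reason": "no_cluster_assignment"})
            continue
        assigned = assign_class(records.loc[patient], horizon)
        if assigned.excluded_reason is not None:
            excluded.append({"patient_id": patient, "reason": assigned.excluded_reason})
            continue
        if clusters[patient] == OUTLIER_LABEL:
            excluded.append({"patient_id": patient, "reason": "cluster_outlier"})
            continue
        rows.setdefault(clusters[patient], {c: 0 for c in ASSOCIABLE_CLASSES})
        rows[clusters[patient]][assigned.label] += 1  # type: ignore[index]
    if not rows:
        raise ValueError("no classified patients after exclusions")
    counts = (
        pd.DataFrame.from_dict(rows, orient="index")
        .reindex(columns=list(ASSOCIABLE_CLASSES))
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    counts.index.name = "cluster"
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        column_percent = 100.0 * counts / col_tot
    predictive = predictive_values(counts, mode="within_cluster")
    chi2 = df = p = None
    if counts.shape[0] >= 2 and (col_tot > 0).sum() >= 2:
        chi2, df, p = stats.chi_square_independence(counts.loc[:, col_tot > 0])
    else:
        warnings.warn("association test undefined for a degenerate cross-tab")
    return CrossTab(
        counts=counts,
        column_percent=column_percent,
        predictive=predictive,
        chi2=chi2,
        df=df,
        p_value=p,
        excluded=pd.DataFrame(excluded, columns=["patient_id", "reason"]),
    )


def predictive_values(
    counts: pd.DataFrame,
    mode: str = "within_cluster",
    prevalence: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """P(class | cluster) as percentages; rows (clusters) sum to 100.

    ``within_cluster`` uses the direct within-cluster proportions.
    ``observed_prevalence`` applies Bayes' rule to P(cluster | class)
    weighted by class prevalence (observed prevalence unless given), which
    coincides with the direct proportions when the observed prevalence is
    used.
    """
    counts = counts.astype(float)
    row_tot = counts.sum(axis=1)
    if (row_tot == 0).any():
        raise ValueError(f"empty cluster row(s): {list(counts.index[row_tot == 0])}")
    if mode == "within_cluster":
        return 100.0 * counts.div(row_tot, axis=0)
    if mode == "observed_prevalence":
        col_tot = counts.sum(axis=0)
        keep = col_tot > 0
        p_cluster_given_class = counts.loc[:, keep] / col_tot[keep]
        if prevalence is None:
            prev = col_tot[keep] / col_tot[keep].sum()
        else:
            prev = pd.Series({c: prevalence.get(c, 0.0) for c in counts.columns[keep]})
            prev = prev / prev.sum()
        joint = p_cluster_given_class * prev
        out = 100.0 * joint.div(joint.sum(axis=1), axis=0)
        return out.reindex(columns=counts.columns).fillna(0.0)
    raise ValueError(f"unknown predictive mode {mode!r}")
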