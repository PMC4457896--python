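"""Stage 4: two-group linear discriminant classification functions.

Uses the classification-function parameterization: for group k,

    f_k(x) = mu_k' S^-1 x - 1/2 mu_k' S^-1 mu_k + ln(prior_k)

with S the pooled within-group covariance. A sample is assigned to the group
whose function scores highest; for two groups this is equivalent to the sign
of f_1(x) - f_2(x), a single linear boundary.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment

FITTED = "fitted"
FIXTURE = "fixture"


@dataclasses.dataclass(frozen=True)
class DiscriminantModel:
    groups: tuple[str, str]
    feature_spots: tuple[str, ...]
    coefficients: dict[str, np.ndarray]  # group -> vector over feature_spots
    intercepts: dict[str, float]
    provenance: str = FITTED

    def __post_init__(self) -> None:
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ValueError("need two distinct group labels")
        for g in self.groups:
            if len(self.coefficients[g]) != len(self.feature_spots):
                raise ValueError("coefficient length must match feature spots")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for spot, coef in zip(self.feature_spots, self.coefficients[g]):
                rows.append({"group": g, "term": spot, "value": float(coef)})
            rows.append({"group": g, "term": "intercept", "value": float(self.intercepts[g])})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = FIXTURE) -> "DiscriminantModel":
        groups = tuple(dict.fromkeys(df["group"].astype(str)))
        spots = tuple(
            dict.fromkeys(t for t in df["term"].astype(str) if t != "intercept")
        )
        coefficients: dict[str, np.ndarray] = {}
        intercepts: dict[str, float] = {}
        for g in groups:
            sub = df[df["group"].astype(str) == g].set_index("term")["value"]
            coefficients[g] = np.array([float(sub[s]) for s in spots])
            intercepts[g] = float(sub["intercept"])
        return cls(
            groups=groups,  # type: ignore[arg-type]
            feature_spots=spots,
            coefficients=coefficients,
            intercepts=intercepts,
            provenance=provenance,
        )


def _group_matrix(
    matrix: pd.DataFrame, assignment: ClusterAssignment, group: str, spots: Sequence[str]
) -> np.ndarray:
    members = [p for p in assignment.members(group) if p in matrix.index]
    sub = matrix.loc[members, list(spots)]
    if sub.isna().any().any():
        raise ValueError(f"group {group!r} has missing feature values")
    return sub.to_numpy(dtype=float)


def fit_discriminant(
    matrix: pd.DataFrame,
    assignment: ClusterAssignment,
    feature_spots: Sequence[str],
    groups: tuple[str, str] | None = None,
    priors: Mapping[str, float] | None = None,
) -> DiscriminantModel:
    """Fit two-group classification functions on a profile matrix.

    ``priors`` defaults to equal. Each group must have more members than
    features; a singular pooled covariance is reported with its condition
    number.
    """
    if groups is None:
        if len(assignment.main_clusters) != 2:
            raise ValueError("assignment does not have exactly 2 main clusters")
        groups = (assignment.main_clusters[0], assignment.main_clusters[1])
    spots = tuple(str(s) for s in feature_spots)
    xa = _group_matrix(matrix, assignment, groups[0], spots)
    xb = _group_matrix(matrix, assignment, groups[1], spots)
    k = len(spots)
    if xa.shape[0] <= k or xb.shape[0] <= k:
        raise ValueError("each group needs more members than features")
    if priors is None:
        priors = {groups[0]: 0.5, groups[1]: 0.5}
    mu = {groups[0]: xa.mean(axis=0), groups[1]: xb.mean(axis=0)}
    na, nb = xa.shape[0], xb.shape[0]
    pooled = ((na - 1) * np.cov(xa, rowvar=False) + (nb - 1) * np.cov(xb, rowvar=False)) / (
        na + nb - 2
    )
    pooled = np.atleast_2d(pooled)
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"pooled within-group covariance is singular (condition number {cond:.3g})"
        )
    inv = np.linalg.inv(pooled)
    coefficients = {}
    intercepts = {}
    for g in groups:
        w = inv @ mu[g]
        coefficients[g] = w
        intercepts[g] = float(-0.5 * mu[g] @ w + np.log(priors[g]))
    return DiscriminantModel(
        groups=groups,
        feature_spots=spots,
        coefficients=coefficients,
        intercepts=intercepts,
        provenance=FITTED,
    )


def _feature_vector(model: DiscriminantModel, x: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    if isinstance(x, Mapping):
        missing = [s for s in model.feature_spots if s not in x]
        if missing:
            raise ValueError(f"missing feature spot(s): {missing}")
        return np.array([float(x[s]) for s in model.feature_spots])
    vec = np.asarray(x, dtype=float)
    if vec.shape != (len(model.feature_spots),):
        raise ValueError(
            f"expected {len(model.feature_spots)} feature values, got shape {vec.shape}"
        )
    return vec


def evaluate_functions(
    model: DiscriminantModel, x: Mapping[str, float] | Sequence[float]
) -> dict[str, float]:
    """Score both classification functions at a %Vol feature vector."""
    vec = _feature_vector(model, x)
    return {
        g: float(model.coefficients[g] @ vec + model.intercepts[g]) for g in model.groups
    }


def classify(model: DiscriminantModel, x: Mapping[str, float] | Sequence[float]) -> str:
    """Argmax of the classification functions; ties go to the first group."""
    scores = evaluate_functions(model, x)
    best = model.groups[0]
    for g in model.groups[1:]:
        if scores[g] > scores[best]:
            best = g
    return best


def map_to_clusters(
    model: DiscriminantModel,
    matrix: pd.DataFrame,
    assignment: ClusterAssignment,
    anchor_spot: str | None = None,
) -> DiscriminantModel:
    """Relabel a fixture model's functions with observed cluster names.

    The cluster whose centroid is highest on ``anchor_spot`` (default: first
    feature spot) is mapped to the function with the larger coefficient on
    that spot.
    """
    anchor = anchor_spot or model.feature_spots[0]
    idx = model.feature_spots.index(anchor)
    if len(assignment.main_clusters) != 2:
        raise ValueError("need exactly two main clusters")
    c_hi, c_lo = sorted(
        assignment.main_clusters,
        key=lambda c: -float(
            matrix.loc[[p for p in assignment.members(c) if p in matrix.index], anchor].mean()
        ),
    )
    f_hi, f_lo = sorted(model.groups, key=lambda g: -model.coefficients[g][idx])
    rename = {f_hi: c_hi, f_lo: c_lo}
    groups = tuple(rename[g] for g in model.groups)
    return DiscriminantModel(
        groups=groups,  # type: ignore[arg-type]
        feature_spots=model.feature_spots,
        coefficients={rename[g]: v for g, v in model.coefficients.items()},
        intercepts={rename[g]: v for g, v in model.intercepts.items()},
        provenance=model.provenance,
    )
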