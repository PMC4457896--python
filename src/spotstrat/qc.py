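"""Stage 1: %Vol normalization, replicate QC and per-patient profiles.

The quantification unit is %Vol: each spot's raw volume divided by the total
volume of all spots matched on the same gel, times 100. Replicate agreement
is measured as the mean, over spots shared by the replicates, of the per-spot
sample standard deviation expressed as a fraction of the per-spot mean
("mean %SD"; 0.30 == 30%).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class ReplicateSD:
    """Replicate-agreement summary for one patient."""

    mean_sd: float  # mean %SD (fraction) over the full replicate set
    pair_sds: dict[tuple[int, int], float]  # per replicate pair


@dataclasses.dataclass(frozen=True)
class BestPair:
    pair: tuple[int, int]
    mean_sd: float
    needs_new_replicate: bool


@dataclasses.dataclass
class PatientProfile:
    """Per-patient spot abundances aggregated over the selected replicates."""

    patient_id: str
    stats: pd.DataFrame  # index spot_id; columns mean_pct_vol, sd_pct_vol
    selected_replicates: tuple[int, int]
    replicate_mean_sd: float
    needs_new_replicate: bool

    @property
    def spot_ids(self) -> pd.Index:
        return self.stats.index


def compute_percent_vol(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw volumes to %Vol within each (patient, replicate) gel.

    Returns a long table with a ``pct_vol`` column; per gel the %Vol values
    sum to 100 exactly (up to floating point).
    """
    if table.empty:
        raise ValueError("empty spot table")
    if (table["raw_volume"] <= 0).any():
        raise ValueError("raw volumes must be strictly positive")
    out = table.copy()
    totals = out.groupby(["patient_id", "replicate_index"])["raw_volume"].transform("sum")
    out["pct_vol"] = 100.0 * out["raw_volume"] / totals
    return out.drop(columns=["raw_volume"])


def _pivot_patient(pvols: pd.DataFrame, patient: str) -> pd.DataFrame:
    sub = pvols[pvols["patient_id"] == str(patient)]
    if sub.empty:
        raise ValueError(f"no replicates for patient {patient!r}")
    return sub.pivot(index="spot_id", columns="replicate_index", values="pct_vol")


def _mean_sd_fraction(wide: pd.DataFrame, replicates: Sequence[int]) -> float:
    """Mean over shared spots of sample SD / mean, for the given replicates."""
    cols = wide[list(replicates)].dropna(axis=0, how="any")
    if cols.empty:
        return float("nan")
    means = cols.mean(axis=1)
    sds = cols.std(axis=1, ddof=1)
    return float((sds / means).mean())


def replicate_percent_sd(
    pvols: pd.DataFrame, patient: str, replicates: Iterable[int] | None = None
) -> ReplicateSD:
    """Replicate variability (mean %SD, as a fraction) for one patient.

    Spots missing from any considered replicate are excluded (only matched
    spots enter the mean). Requires at least two replicates.
    """
    wide = _pivot_patient(pvols, patient)
    reps = sorted(int(r) for r in (replicates if replicates is not None else wide.columns))
    if len(reps) < 2:
        raise ValueError(f"patient {patient!r} has fewer than 2 replicates")
    pair_sds = {
        (i, j): _mean_sd_fraction(wide, (i, j)) for i, j in itertools.combinations(reps, 2)
    }
    return ReplicateSD(mean_sd=_mean_sd_fraction(wide, reps), pair_sds=pair_sds)


def _best_pair_from_wide(wide: pd.DataFrame, patient: str, best_pair_max: float) -> BestPair:
    reps = sorted(int(r) for r in wide.columns)
    if len(reps) < 2:
        raise ValueError(f"patient {patient!r} has fewer than 2 replicates")
    pair_sds = {
        (i, j): _mean_sd_fraction(wide, (i, j)) for i, j in itertools.combinations(reps, 2)
    }
    best_pair, best_sd = min(pair_sds.items(), key=lambda kv: (kv[1], kv[0]))
    return BestPair(
        pair=best_pair,
        mean_sd=best_sd,
        needs_new_replicate=bool(best_sd > best_pair_max),
    )


def select_best_replicate_pair(
    pvols: pd.DataFrame, patient: str, best_pair_max: float = 0.30
) -> BestPair:
    """Pick the replicate pair with minimal mean %SD over shared spots.

    Ties break toward the lexicographically smallest index pair. The pair is
    flagged (``needs_new_replicate``) rather than dropped when even the best
    pair exceeds ``best_pair_max``.
    """
    return _best_pair_from_wide(_pivot_patient(pvols, patient), str(patient), best_pair_max)


def aggregate_profile(
    pvols: pd.DataFrame,
    patient: str,
    pair: tuple[int, int],
    *,
    mean_sd: float | None = None,
    needs_new_replicate: bool = False,
) -> PatientProfile:
    """Per-spot mean and SD of %Vol over the two selected replicates.

    A spot present in only one replicate of the pair keeps its single value
    with SD marked unavailable (NaN).
    """
    return _profile_from_wide(
        _pivot_patient(pvols, patient),
        str(patient),
        pair,
        mean_sd=mean_sd,
        needs_new_replicate=needs_new_replicate,
    )


def _profile_from_wide(
    wide: pd.DataFrame,
    patient: str,
    pair: tuple[int, int],
    *,
    mean_sd: float | None = None,
    needs_new_replicate: bool = False,
) -> PatientProfile:
    for r in pair:
        if r not in wide.columns:
            raise ValueError(f"patient {patient!r} has no replicate {r}")
    cols = wide[list(pair)]
    present = cols.notna().any(axis=1)
    stats = pd.DataFrame(
        {
            "mean_pct_vol": cols.mean(axis=1),
            "sd_pct_vol": cols.std(axis=1, ddof=1),
        }
    )[present].sort_index()
    if mean_sd is None:
        mean_sd = _mean_sd_fraction(wide, pair)
    return PatientProfile(
        patient_id=str(patient),
        stats=stats,
        selected_replicates=(int(pair[0]), int(pair[1])),
        replicate_mean_sd=float(mean_sd),
        needs_new_replicate=needs_new_replicate,
    )


def build_profiles(
    table: pd.DataFrame, best_pair_max: float = 0.30
) -> tuple[list[PatientProfile], pd.DataFrame]:
    """Run QC for every patient: %Vol, best-pair selection, aggregation.

    Returns the profiles (patient order = sorted patient_id) and a QC report
    table (patient, selected pair, mean %SD, flag).
    """
    pvols = compute_percent_vol(table)
    profiles: list[PatientProfile] = []
    rows = []
    for patient, sub in pvols.groupby("patient_id", sort=True):
        wide = sub.pivot(index="spot_id", columns="replicate_index", values="pct_vol")
        best = _best_pair_from_wide(wide, str(patient), best_pair_max)
        profile = _profile_from_wide(
            wide,
            str(patient),
            best.pair,
            mean_sd=best.mean_sd,
            needs_new_replicate=best.needs_new_replicate,
        )
        profiles.append(profile)
        rows.append(
            {
                "patient_id": patient,
                "replicate_a": best.pair[0],
                "replicate_b": best.pair[1],
                "mean_sd_frac": best.mean_sd,
                "needs_new_replicate": best.needs_new_replicate,
            }
        )
    return profiles, pd.DataFrame(rows)


def select_representative_spots(
    profiles: Sequence[PatientProfile], presence_fraction: float = 1.0
) -> list[str]:
    """Spots detected in at least ``presence_fraction`` of the patients."""
    if not profiles:
        raise ValueError("need at least one profile")
    counts: dict[str, int] = {}
    for profile in profiles:
        for spot in profile.spot_ids:
            counts[spot] = counts.get(spot, 0) + 1
    n = len(profiles)
    return sorted(s for s, c in counts.items() if c / n >= presence_fraction)


def profile_matrix(
    profiles: Sequence[PatientProfile], spots: Sequence[str] | None = None
) -> pd.DataFrame:
    """Patients x spots matrix of mean %Vol; NaN where a spot is missing."""
    series = {p.patient_id: p.stats["mean_pct_vol"] for p in profiles}
    mat = pd.DataFrame(series).T.sort_index()
    mat.index.name = "patient_id"
    if spots is not None:
        missing = [s for s in spots if s not in mat.columns]
        for s in missing:
            mat[s] = np.nan
        mat = mat[list(spots)]
    return mat
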