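"""Synthetic cohort generator with a planted ground truth.

The generative model mirrors the statistical structure the downstream
analysis assumes:

- Each patient carries a latent total abundance T for a two-isoform protein
  and a modification fraction phi; marker spot "289" is the modified
  fraction T*phi and spot "288" the unmodified remainder T*(1-phi). phi is
  Beta-distributed with a class-dependent mean (higher in aggressive
  classes), which makes the two markers anti-correlated across patients.
- A third marker spot ("469") is class-shifted log-normal.
- Background spots are class-independent log-normal around per-spot
  baselines, with optional per-map dropout.
- Latent profiles are normalized to sum to 100, then each technical
  replicate is the latent profile times an arbitrary per-map total volume,
  perturbed by multiplicative log-normal noise whose CV is drawn from a
  configured range.

Randomness derives from a single seed with per-patient substreams, so adding
patients to a configuration does not change earlier patients' draws.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as tabio

MARKER_ISOFORM_LOW = "288"  # unmodified isoform: T * (1 - phi)
MARKER_ISOFORM_HIGH = "289"  # modified isoform: T * phi
MARKER_APOE = "469"

_OTHER_TOKENS = ("PP", "lost", "death", "no_MS")


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Parameters of the generative model. Defaults mirror the reference
    cohort: 24 patients (5 H, 10 M, 5 L, 4 other), 236 background spots plus
    3 markers, triplicate gels with 17-32% replicate CV."""

    class_counts: tuple[tuple[str, int], ...] = (("H", 5), ("M", 10), ("L", 5), ("other", 4))
    n_background_spots: int = 236
    replicate_count: int = 3
    replicate_cv_range: tuple[float, float] = (0.17, 0.32)
    # two-isoform marker: total T (log-normal around a class mean) and
    # modification fraction phi (Beta with class-dependent mean)
    t_class_means: tuple[tuple[str, float], ...] = (
        ("H", 0.35),
        ("M", 0.35),
        ("L", 0.35),
        ("other", 0.35),
    )
    t_log_sd: float = 0.12
    phi_class_means: tuple[tuple[str, float], ...] = (
        ("H", 0.70),
        ("M", 0.50),
        ("L", 0.30),
        ("other", 0.50),
    )
    # tuned by simulation: keeps the cohort-level marker anti-correlation
    # median near -0.5 while two planted classes stay recoverable by
    # marker-spot clustering
    phi_concentration: float = 80.0
    # third marker: class-shifted log-normal
    apoe_class_log_means: tuple[tuple[str, float], ...] = (
        ("H", math.log(0.30)),
        ("M", math.log(0.15)),
        ("L", math.log(0.08)),
        ("other", math.log(0.15)),
    )
    apoe_log_sd: float = 0.35
    background_log_mean: float = math.log(0.4)
    background_log_sd: float = 0.4
    dropout_rate: float = 0.05  # per-map background spot dropout
    total_volume_range: tuple[float, float] = (5e5, 2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(self.class_counts)
        if any(c <= 0 for c in counts.values()):
            raise ValueError("class counts must be positive")
        lo, hi = self.replicate_cv_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("replicate_cv_range must satisfy 0 <= low <= high < 1")
        if self.replicate_count < 2:
            raise ValueError("need at least 2 replicates")
        if self.n_background_spots < 0:
            raise ValueError("n_background_spots must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("phi_class_means", "t_class_means", "apoe_class_log_means"):
            param = dict(getattr(self, name))
            missing = set(counts) - set(param)
            if missing:
                raise ValueError(f"{name} missing class(es): {sorted(missing)}")
        for _, mu in self.phi_class_means:
            if not 0 < mu < 1:
                raise ValueError("phi class means must be in (0, 1)")

    @property
    def n_patients(self) -> int:
        return sum(c for _, c in self.class_counts)

    def patient_classes(self) -> list[str]:
        out: list[str] = []
        for label, count in self.class_counts:
            out.extend([label] * count)
        return out


TRUTH_COLUMNS = [
    "patient_id",
    "class_label",
    "t_total",
    "phi",
    "apoe_level",
    "spot288_expected",
    "spot289_expected",
    "spot469_expected",
]


def _lognormal_mean_preserving(rng: np.random.Generator, mean: float, log_sd: float, size=None):
    """Log-normal draws whose expectation equals ``mean``."""
    return mean * np.exp(rng.normal(-0.5 * log_sd**2, log_sd, size=size))


def _spot_baselines(config: CohortConfig) -> tuple[list[str], np.ndarray]:
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(0xB0,)))
    )
    ids = [f"b{i:03d}" for i in range(1, config.n_background_spots + 1)]
    baselines = _lognormal_mean_preserving(
        rng, math.exp(config.background_log_mean), config.background_log_sd, size=len(ids)
    )
    return ids, baselines


def _clinical_row(patient_id: str, label: str, index: int, rng: np.random.Generator) -> dict:
    edss = float(rng.integers(0, 9)) / 2.0
    relapse = int(rng.integers(0, 5))
    if label == "H":
        return dict(
            patient_id=patient_id, edss_at_lp=edss, delta_edss=float(rng.integers(0, 6)) / 2,
            relapse_count=relapse + 2, dmt_2y="II", dmt_5y="II", class_2y="H", class_5y="H",
            diagnosis="RRMS",
        )
    if label == "M":
        return dict(
            patient_id=patient_id, edss_at_lp=edss, delta_edss=float(rng.integers(0, 3)) / 2,
            relapse_count=relapse, dmt_2y="I", dmt_5y="I", class_2y="M", class_5y="M",
            diagnosis="RRMS",
        )
    if label == "L":
        benign = bool(rng.random() < 0.4)
        cls = "LB" if benign else "L"
        return dict(
            patient_id=patient_id, edss_at_lp=edss, delta_edss=0.0, relapse_count=min(relapse, 1),
            dmt_2y="none", dmt_5y="none", class_2y=cls, class_5y=cls,
            diagnosis="benign" if benign else "RRMS",
        )
    if label == "other":
        token = _OTHER_TOKENS[index % len(_OTHER_TOKENS)]
        if token == "PP":
            return dict(
                patient_id=patient_id, edss_at_lp=edss, delta_edss=1.0, relapse_count=0,
                dmt_2y="none", dmt_5y="none", class_2y="PP", class_5y="PP", diagnosis="PPMS",
            )
        if token == "lost":
            return dict(
                patient_id=patient_id, edss_at_lp=edss, delta_edss=0.0, relapse_count=None,
                dmt_2y="none", dmt_5y="lost", class_2y="lost", class_5y="lost", diagnosis="RRMS",
            )
        if token == "death":
            return dict(
                patient_id=patient_id, edss_at_lp=edss, delta_edss=1.0, relapse_count=1,
                dmt_2y="I", dmt_5y="death", class_2y="M", class_5y="death", diagnosis="RRMS",
            )
        return dict(
            patient_id=patient_id, edss_at_lp=edss, delta_edss=0.0, relapse_count=0,
            dmt_2y="no_MS", dmt_5y="no_MS", class_2y="no_MS", class_5y="no_MS",
            diagnosis="other",
        )
    raise ValueError(f"invalid class label {label!r}")


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (spot replicate table, clinical table, planted truth).

    Deterministic for a fixed config: the same seed yields byte-identical
    tables. The planted truth reports each patient's latent parameters and
    the expected %Vol of the three marker spots after profile normalization
    (so ``spot288_expected + spot289_expected`` equals the normalized total
    ``t_total`` exactly).
    """
    bg_ids, bg_baselines = _spot_baselines(config)
    t_means = dict(config.t_class_means)
    phi_means = dict(config.phi_class_means)
    apoe_means = dict(config.apoe_class_log_means)

    spot_rows: list[dict] = []
    clinical_rows: list[dict] = []
    truth_rows: list[dict] = []
    for index, label in enumerate(config.patient_classes()):
        patient_id = f"P{index + 1:02d}"
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(1, index)))
        )
        t_raw = float(_lognormal_mean_preserving(rng, t_means[label], config.t_log_sd))
        mu = phi_means[label]
        kappa = config.phi_concentration
        phi = float(rng.beta(mu * kappa, (1 - mu) * kappa))
        apoe = float(np.exp(rng.normal(apoe_means[label], config.apoe_log_sd)))
        background = bg_baselines * np.exp(
            rng.normal(-0.5 * config.background_log_sd**2, config.background_log_sd, len(bg_ids))
        )

        spot_ids = [MARKER_ISOFORM_LOW, MARKER_ISOFORM_HIGH, MARKER_APOE, *bg_ids]
        latent = np.concatenate([[t_raw * (1 - phi), t_raw * phi, apoe], background])
        latent = 100.0 * latent / latent.sum()  # latent %Vol profile

        # calibrate noise so the expected replicate-set sample %SD matches the
        # drawn CV (the sample SD of 2-3 replicates underestimates the CV by
        # the c4 bias factor)
        n_rep = config.replicate_count
        c4 = math.sqrt(2.0 / (n_rep - 1)) * math.gamma(n_rep / 2) / math.gamma((n_rep - 1) / 2)
        for replicate in range(n_rep):
            cv = float(rng.uniform(*config.replicate_cv_range))
            sigma = math.sqrt(math.log1p(cv * cv)) / c4
            scale = float(rng.uniform(*config.total_volume_range))
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, len(latent)))
            keep = np.ones(len(latent), dtype=bool)
            if config.dropout_rate > 0:
                # markers are never dropped; background spots drop per map
                drop = rng.random(len(bg_ids)) < config.dropout_rate
                keep[3:] = ~drop
            volumes = latent / 100.0 * scale * noise
            for spot, volume, k in zip(spot_ids, volumes, keep):
                if k:
                    spot_rows.append(
                        {
                            "patient_id": patient_id,
                            "replicate_index": replicate,
                            "spot_id": spot,
                            "raw_volume": volume,
                        }
                    )

        clinical_rows.append(_clinical_row(patient_id, label, index, rng))
        truth_rows.append(
            {
                "patient_id": patient_id,
                "class_label": label,
                "t_total": latent[0] + latent[1],
                "phi": phi,
                "apoe_level": apoe,
                "spot288_expected": latent[0],
                "spot289_expected": latent[1],
                "spot469_expected": latent[2],
            }
        )

    spot_table = tabio.validate_spot_table(pd.DataFrame(spot_rows))
    clinical = tabio.validate_clinical_table(pd.DataFrame(clinical_rows))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return spot_table, clinical, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the planted truth as TSV (lossless round-trip via read_truth)."""
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ValueError(f"truth table missing column(s): {missing}")
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "class_label": str})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise tabio.SchemaError(f"{path}: missing column(s) {missing}")
    return df[TRUTH_COLUMNS]


def truth_class_map(truth: pd.DataFrame) -> Mapping[str, str]:
    return dict(zip(truth["patient_id"], truth["class_label"]))
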