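"""Stage 3: statistical primitives used across the pipeline.

Conventions, chosen to match the source software of the original analysis:

- Mann-Whitney U is exact (full null enumeration) for small samples without
  ties, otherwise a mid-rank normal approximation with tie correction and no
  continuity correction; always two-sided.
- Fold change is the ratio of group means, reported as >= 1 with a direction.
- Spearman rho uses mid-ranks with the two-sided t approximation on n-2 df.
- The chi-square independence test is Pearson's, asymptotic, without
  continuity correction or small-count pooling.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cluster import ClusterAssignment

EXACT_MAX_N = 10  # largest per-group size for which the exact null is enumerated

UP_IN_B = "up_in_B"
DOWN_IN_B = "down_in_B"
NO_DIRECTION = "none"


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact when ``min(n_a, n_b) <= EXACT_MAX_N`` and the pooled sample has no
    ties; otherwise the tie-corrected normal approximation (no continuity
    correction).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class FoldChange:
    ratio: float  # >= 1; inf when one mean is zero
    direction: str  # up_in_B / down_in_B / none

    @property
    def rounded(self) -> float:
        return round(self.ratio, 1)


def fold_change(mean_a: float, mean_b: float) -> FoldChange:
    """Ratio of the larger group mean over the smaller, with direction.

    Direction is relative to group B (``up_in_B`` when B's mean is larger).
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if mean_a == 0 and mean_b == 0:
        raise ValueError("both means are zero")
    if mean_b > mean_a:
        direction = UP_IN_B
    elif mean_b < mean_a:
        direction = DOWN_IN_B
    else:
        direction = NO_DIRECTION
    if mean_a == 0 or mean_b == 0:
        return FoldChange(ratio=math.inf, direction=direction)
    return FoldChange(ratio=max(mean_b / mean_a, mean_a / mean_b), direction=direction)


def select_differential_spots(
    matrix: pd.DataFrame,
    assignment: ClusterAssignment,
    cluster_a: str,
    cluster_b: str,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-spot Mann-Whitney plus fold change between two clusters.

    ``matrix`` is the patients x spots mean-%Vol matrix. A spot is selected
    when it is significant (p < ``p_threshold``) OR its fold change reaches
    ``fc_threshold``. Per-patient mean %Vol is the analysis unit.
    """
    members_a = [p for p in assignment.members(cluster_a) if p in matrix.index]
    members_b = [p for p in assignment.members(cluster_b) if p in matrix.index]
    if len(members_a) < 2 or len(members_b) < 2:
        raise ValueError("both clusters need at least 2 members with profiles")
    rows = []
    for spot in matrix.columns:
        va = matrix.loc[members_a, spot].dropna().to_numpy()
        vb = matrix.loc[members_b, spot].dropna().to_numpy()
        if va.size < 2 or vb.size < 2:
            continue
        p_value = mann_whitney(va, vb)
        fc = fold_change(float(va.mean()), float(vb.mean()))
        significant = bool(p_value < p_threshold)
        fc_pass = bool(fc.ratio >= fc_threshold)
        rows.append(
            {
                "spot_id": spot,
                "mean_a": va.mean(),
                "sd_a": va.std(ddof=1),
                "mean_b": vb.mean(),
                "sd_b": vb.std(ddof=1),
                "p_value": p_value,
                "fold_change": fc.ratio,
                "fold_change_rounded": fc.rounded,
                "direction": fc.direction,
                "significant": significant,
                "fc_pass": fc_pass,
                "selected": significant or fc_pass,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "spot_id",
            "mean_a",
            "sd_a",
            "mean_b",
            "sd_b",
            "p_value",
            "fold_change",
            "fold_change_rounded",
            "direction",
            "significant",
            "fc_pass",
            "selected",
        ],
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mid-rank Spearman rho with two-sided t-approximation p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero variance in ranks")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_p_from_rho(rho: float, n: int) -> float:
    """Two-sided p for a given rho at sample size n (t approximation)."""
    if not -1 < rho < 1:
        return 0.0
    t = abs(rho) * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * sps.t.sf(t, df=n - 2))


def chi_square_independence(contingency: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a counts table.

    Zero-marginal rows/columns are dropped with a warning. Returns
    (chi2, df, p). No continuity correction, no pooling of small counts.
    """
    table = pd.DataFrame(contingency).astype(float)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if table.to_numpy().sum() <= 0:
        raise ValueError("empty contingency table")
    if (table.to_numpy() < 0).any():
        raise ValueError("negative counts")
    zero_rows = table.sum(axis=1) == 0
    zero_cols = table.sum(axis=0) == 0
    if zero_rows.any() or zero_cols.any():
        warnings.warn("dropping zero-marginal rows/columns from contingency table")
        table = table.loc[~zero_rows, ~zero_cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table degenerate after dropping empty margins")
    chi2, p, df, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(df), float(p)


PHOSPHORYLATED = "phosphorylated"
NOT_PHOSPHORYLATED = "not_phosphorylated"


def phospho_call(proq_signal: float, sypro_signal: float, ds_threshold: float = 0.08) -> str:
    """Call a spot not phosphorylated when phospho/total stain ratio < threshold."""
    if proq_signal < 0 or sypro_signal < 0:
        raise ValueError("stain signals must be non-negative")
    if sypro_signal == 0:
        raise ValueError("total-protein (Sypro) signal is zero")
    ratio = proq_signal / sypro_signal
    return NOT_PHOSPHORYLATED if ratio < ds_threshold else PHOSPHORYLATED
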