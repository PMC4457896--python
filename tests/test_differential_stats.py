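import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from spotstrat import (
    chi_square_independence,
    fold_change,
    mann_whitney,
    phospho_call,
    select_differential_spots,
    spearman,
    spearman_p_from_rho,
)
from spotstrat.cluster import assignment_from_mapping
from spotstrat.stats import DOWN_IN_B, NO_DIRECTION, UP_IN_B


def enumeration_p(a, b):
    """Independent oracle: full enumeration of the U null, doubled smaller tail."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n * (n + 1) / 2
            for idx in itertools.combinations(range(len(pooled)), n)
        ]
    )
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestMannWhitney:
    def test_complete_separation_4v4(self):
        # 2 of the 70 arrangements are at least as extreme
        p = mann_whitney([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    def test_complete_separation_3v3(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(2 / 20)

    def test_identical_multisets(self):
        assert mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("na,nb", [(na, nb) for na in range(1, 7) for nb in range(1, 7)])
    def test_matches_enumeration_all_small_sizes(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(3):
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            assert mann_whitney(a, b) == pytest.approx(enumeration_p(a, b), abs=1e-12)

    def test_p_bounded_below_by_extreme_arrangement(self, rng):
        for na, nb in [(3, 5), (4, 4), (6, 2)]:
            a = rng.normal(size=na)
            b = rng.normal(size=nb) + 100.0
            p = mann_whitney(a, b)
            assert 2 / math.comb(na + nb, na) - 1e-12 <= p <= 1.0


class TestFoldChange:
    def test_printed_up_example(self):
        fc = fold_change(0.125, 0.210)
        assert fc.rounded == 1.7
        assert fc.direction == UP_IN_B

    def test_printed_down_example(self):
        fc = fold_change(0.224, 0.139)
        assert fc.rounded == 1.6
        assert fc.direction == DOWN_IN_B

    def test_equal_means(self):
        fc = fold_change(0.1, 0.1)
        assert fc.ratio == 1.0
        assert fc.direction == NO_DIRECTION

    def test_zero_mean_infinite(self):
        fc = fold_change(0.0, 0.2)
        assert math.isinf(fc.ratio)
        assert fc.direction == UP_IN_B

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.0)

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_symmetry(self, a, b):
        fc_ab = fold_change(a, b)
        fc_ba = fold_change(b, a)
        assert fc_ab.ratio == pytest.approx(fc_ba.ratio)
        if a != b:
            assert {fc_ab.direction, fc_ba.direction} == {UP_IN_B, DOWN_IN_B}


def _two_cluster_matrix(rng, n_per=5, n_spots=4, shift=0.0):
    patients = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    data = rng.lognormal(0, 0.3, size=(2 * n_per, n_spots))
    data[n_per:, 0] *= math.exp(shift)
    mat = pd.DataFrame(data, index=patients,
                       columns=[f"s{j}" for j in range(n_spots)])
    labels = {p: ("A" if p.startswith("a") else "B") for p in patients}
    return mat, assignment_from_mapping(labels)


class TestSelectDifferentialSpots:
    def test_thresholds_wide_open_select_all(self, rng):
        mat, assignment = _two_cluster_matrix(rng)
        out = select_differential_spots(mat, assignment, "A", "B",
                                        p_threshold=1.0, fc_threshold=1.0)
        assert out["selected"].all()
        assert (out["selected"] == (out["significant"] | out["fc_pass"])).all()

    def test_planted_spot_selected(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            mat, assignment = _two_cluster_matrix(rng, n_per=9, shift=math.log(2.5))
            out = select_differential_spots(mat, assignment, "A", "B").set_index("spot_id")
            hits += bool(out.loc["s0", "selected"])
        assert hits >= 27

    def test_small_cluster_rejected(self, rng):
        mat, _ = _two_cluster_matrix(rng)
        assignment = assignment_from_mapping(
            {p: ("A" if i == 0 else "B") for i, p in enumerate(mat.index)}
        )
        with pytest.raises(ValueError, match="2 members"):
            select_differential_spots(mat, assignment, "A", "B")

    def test_selected_is_union_of_flags(self, rng):
        mat, assignment = _two_cluster_matrix(rng, n_per=6, shift=0.4)
        out = select_differential_spots(mat, assignment, "A", "B")
        assert (out["selected"] == (out["significant"] | out["fc_pass"])).all()


class TestSpearman:
    def test_perfectly_increasing(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_printed_convention_pair(self):
        assert spearman_p_from_rho(-0.49, 24) == pytest.approx(0.015, abs=5e-4)

    def test_equals_pearson_of_midranks(self, rng):
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12) + 0.5 * x
            rho, _ = spearman(x, y)
            oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestChiSquare:
    def test_exact_independence(self):
        rows = np.array([10, 20])
        cols = np.array([0.3, 0.7])
        table = np.outer(rows, cols)
        chi2, df, p = chi_square_independence(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_five_year_two_cluster_table(self):
        table = pd.DataFrame({"H": [1, 4], "L": [5, 0], "M": [7, 3]},
                             index=["G", "Z"])
        chi2, df, p = chi_square_independence(table)
        assert chi2 == pytest.approx(7.2527, abs=1e-3)
        assert df == 2
        assert p == pytest.approx(0.027, abs=5e-4)

    @given(st.lists(st.integers(min_value=1, max_value=40),
                    min_size=4, max_size=4))
    @settings(max_examples=50)
    def test_matches_2x2_closed_form(self, counts):
        a, b, c, d = counts
        chi2, df, p = chi_square_independence(np.array([[a, b], [c, d]]))
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed, abs=1e-10)
        assert df == 1

    def test_zero_margin_dropped_with_warning(self):
        table = np.array([[0, 0], [3, 4], [5, 1]])
        with pytest.warns(UserWarning):
            chi2, df, p = chi_square_independence(table)
        assert df == 1

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence(np.array([[1, 2]]))


class TestPhosphoCall:
    def test_below_threshold(self):
        assert phospho_call(0.05, 1.0) == "not_phosphorylated"

    def test_zero_numerator(self):
        assert phospho_call(0.0, 1.0) == "not_phosphorylated"

    def test_equal_signals(self):
        assert phospho_call(2.0, 2.0) == "phosphorylated"

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            phospho_call(1.0, 0.0)
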