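"""Validity battery: ANOVA oracle equivalence, Holm, ICC, standard setting."""

import math

import numpy as np
import pandas as pd
import pytest

from fluoroskill.validity import (
    consequences,
    contrasting_groups,
    holm_adjusted_alphas,
    icc_absolute_agreement,
    select_discriminating,
    session_effect,
    two_way_mixed_anova,
)


def random_split_plot_table(rng, n1=4, n2=4, k=6, effect=0.0):
    rows = []
    for g, n, mu in (("novice", n1, effect), ("experienced", n2, 0.0)):
        for i in range(n):
            pid = f"{g}{i}"
            subj = rng.normal(0, 1)
            for j in range(k):
                rows.append(
                    {
                        "participant_id": pid,
                        "group": g,
                        "session": 1 + j // 3,
                        "repetition": 1 + j % 3,
                        "y": mu + subj + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


def brute_force_ss(df, metric="y"):
    """Mean-based split-plot sums of squares via explicit loops."""
    y = df[metric].to_numpy(float)
    grand = y.mean()
    groups = sorted(df["group"].unique())
    reps = sorted(set(zip(df["session"], df["repetition"])))
    parts = list(dict.fromkeys(df["participant_id"]))
    k = len(reps)

    def mean_where(**kw):
        m = np.ones(len(df), bool)
        for col, val in kw.items():
            m &= (df[col] == val).to_numpy()
        return y[m].mean()

    pm = {p: mean_where(participant_id=p) for p in parts}
    pgrp = {p: df[df["participant_id"] == p]["group"].iloc[0] for p in parts}
    gm = {g: mean_where(group=g) for g in groups}
    rm = {r: y[[(s, t) == r for s, t in zip(df["session"], df["repetition"])]].mean() for r in reps}
    ng = {g: sum(1 for p in parts if pgrp[p] == g) for g in groups}

    ss_group = k * sum(ng[g] * (gm[g] - grand) ** 2 for g in groups)
    ss_subj = k * sum((pm[p] - gm[pgrp[p]]) ** 2 for p in parts)
    ss_rep = len(parts) * sum((rm[r] - grand) ** 2 for r in reps)
    ss_inter = 0.0
    for g in groups:
        for r in reps:
            mask = (df["group"] == g).to_numpy() & np.array(
                [(s, t) == r for s, t in zip(df["session"], df["repetition"])]
            )
            cell = y[mask].mean()
            ss_inter += ng[g] * (cell - gm[g] - rm[r] + grand) ** 2
    ss_total = ((y - grand) ** 2).sum()
    return {
        "group": ss_group,
        "subjects_within_group": ss_subj,
        "repetition": ss_rep,
        "interaction": ss_inter,
        "residual": ss_total - ss_group - ss_subj - ss_rep - ss_inter,
        "total": ss_total,
    }


class TestMixedAnova:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(3, 7))
        n2 = int(rng.integers(3, 7))
        df = random_split_plot_table(rng, n1, n2, effect=rng.normal())
        res = two_way_mixed_anova(df, "y")
        oracle = brute_force_ss(df)
        for key, val in oracle.items():
            assert res.ss[key] == pytest.approx(val, abs=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = random_split_plot_table(rng, 6, 5, effect=1.0)
        res = two_way_mixed_anova(df, "y")
        df2 = df.copy()
        df2["rep_idx"] = (df2["session"] - 1) * 3 + df2["repetition"]
        aov = pg.mixed_anova(
            df2, dv="y", within="rep_idx", subject="participant_id", between="group"
        )
        row = aov[aov["Source"] == "group"].iloc[0]
        assert res.f_group == pytest.approx(row["F"], rel=1e-9)
        assert res.p_group == pytest.approx(row["p_unc"], rel=1e-9)
        assert res.partial_eta_sq == pytest.approx(row["np2"], rel=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        df = random_split_plot_table(rng, 5, 4, effect=0.8)
        res0 = two_way_mixed_anova(df, "y")
        df_shift = df.assign(y=df["y"] + 100.0)
        res1 = two_way_mixed_anova(df_shift, "y")
        assert res1.f_group == pytest.approx(res0.f_group, rel=1e-9)
        assert res1.p_group == pytest.approx(res0.p_group, rel=1e-9)
        assert res1.partial_eta_sq == pytest.approx(res0.partial_eta_sq, rel=1e-9)
        for g in res0.group_means:
            assert res1.group_means[g] == pytest.approx(
                res0.group_means[g] + 100.0, rel=1e-9
            )

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(3)
        df = random_split_plot_table(rng)
        df = df.iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_mixed_anova(df, "y")

    def test_tiny_group_rejected(self):
        rng = np.random.default_rng(4)
        df = random_split_plot_table(rng, n1=1, n2=4)
        with pytest.raises(ValueError):
            two_way_mixed_anova(df, "y")


class TestHolm:
    def test_reported_adjusted_levels_for_seven_tests(self):
        p = [0.002, 0.005, 0.009, 0.07, 0.7, 0.6, 0.9]
        alphas, reject = holm_adjusted_alphas(p, 0.05)
        assert alphas[0] == pytest.approx(0.05 / 7)
        assert alphas[1] == pytest.approx(0.05 / 6)
        assert alphas[2] == pytest.approx(0.05 / 5)
        assert reject[:3] == [True, True, True]
        # step-down stops at the fourth-ranked test
        assert reject[3:] == [False] * 4

    def test_single_test_uses_full_alpha(self):
        alphas, reject = holm_adjusted_alphas([0.03], 0.05)
        assert alphas == [pytest.approx(0.05)]
        assert reject == [True]

    def test_stop_blocks_later_smaller_thresholds(self):
        # rank 2 fails (0.026 > 0.05/2), so rank 3 is retained even though
        # its p (0.03) is below the rank-3 threshold (0.05)
        alphas, reject = holm_adjusted_alphas([0.001, 0.03, 0.026], 0.05)
        assert reject == [True, False, False]

    def test_thresholds_monotone_and_superset_of_bonferroni(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 0.2, size=rng.integers(2, 10)).tolist()
            alphas, reject = holm_adjusted_alphas(p, 0.05)
            order = np.argsort(p)
            ranked = np.array(alphas)[order]
            assert (np.diff(ranked) >= -1e-15).all()
            assert ranked[0] == pytest.approx(0.05 / len(p))
            bonf = [pi < 0.05 / len(p) for pi in p]
            assert all(r or not b for r, b in zip(reject, bonf))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            holm_adjusted_alphas([], 0.05)


class TestSelectDiscriminating:
    def _fake_results(self, pvals):
        from fluoroskill.validity import AnovaResult

        return [
            AnovaResult(
                metric=m,
                group_means={},
                group_cis={},
                f_group=1.0,
                p_group=p,
                partial_eta_sq=0.1,
                df_between=(1, 18),
                ss={},
            )
            for m, p in pvals
        ]

    def test_all_null_selects_nothing(self):
        res = self._fake_results([(f"z_{v}", 0.9) for v in ("PA", "AP", "LAT", "FACET", "TANG")])
        views, _ = select_discriminating(res)
        assert views == []

    def test_time_cannot_enter_composite(self):
        res = self._fake_results(
            [("time_s", 0.0001)]
            + [(f"z_{v}", 0.9) for v in ("PA", "AP", "LAT", "FACET", "TANG")]
        )
        views, annotated = select_discriminating(res)
        assert views == []
        assert annotated[0].discriminates is True


class TestSessionEffect:
    def _table(self, s1, s2):
        rows = []
        for i, (a, b) in enumerate(zip(s1, s2)):
            for sess, val in ((1, a), (2, b)):
                for rep in (1, 2, 3):
                    rows.append(
                        {
                            "participant_id": f"p{i}",
                            "group": "novice",
                            "session": sess,
                            "repetition": rep,
                            "composite": val,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_sessions_zero_difference(self):
        m, ci = session_effect(self._table([3, 4, 5], [3, 4, 5]))
        assert m == pytest.approx(0.0)
        assert ci[0] <= 0 <= ci[1]

    def test_uniform_shift_recovered_exactly(self):
        m, ci = session_effect(self._table([3, 4, 5], [4, 5, 6]))
        assert m == pytest.approx(-1.0)

    def test_coverage_of_true_zero(self):
        # no-learning population: the 95% CI should cover 0 about 95% of runs
        rng = np.random.default_rng(123)
        hits = 0
        runs = 200
        for _ in range(runs):
            base = rng.normal(5, 2, size=10)
            s1 = base + rng.normal(0, 1, 10)
            s2 = base + rng.normal(0, 1, 10)
            _, ci = session_effect(self._table(s1, s2))
            hits += ci[0] <= 0 <= ci[1]
        assert 0.90 <= hits / runs <= 0.99


class TestIcc:
    def test_duplicated_columns_give_one(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 2, 10)
        mat = np.tile(col[:, None], (1, 4))
        res = icc_absolute_agreement(mat)
        assert res.icc == pytest.approx(1.0)

    def test_column_offset_strictly_decreases_icc(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(0, 1, (12, 5)) + rng.normal(0, 2, (12, 1))
        base = icc_absolute_agreement(mat).icc
        shifted = mat.copy()
        shifted[:, 0] += 3.0
        assert icc_absolute_agreement(shifted).icc < base

    def test_common_constant_invariance(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(0, 1, (10, 6)) + rng.normal(0, 2, (10, 1))
        a = icc_absolute_agreement(mat)
        b = icc_absolute_agreement(mat + 42.0)
        assert a.icc == pytest.approx(b.icc, rel=1e-12)

    def test_variance_component_closed_form(self):
        # subject variance 4, residual 1, k=6: ICC(A,k) = 4 / (4 + 1/6)
        rng = np.random.default_rng(7)
        n, k = 400, 6
        mat = rng.normal(0, 2, (n, 1)) + rng.normal(0, 1, (n, k))
        res = icc_absolute_agreement(mat)
        assert res.icc == pytest.approx(4 / (4 + 1 / 6), abs=0.02)
        assert res.ci95[0] < res.icc < res.ci95[1]

    def test_matches_pingouin_icc2k(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        mat = rng.normal(0, 1, (12, 6)) + rng.normal(0, 2, (12, 1))
        mine = icc_absolute_agreement(mat)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 6),
                "raters": np.tile(np.arange(6), 12),
                "ratings": mat.ravel(),
            }
        )
        table = pg.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type")
        key = "ICC(A,k)" if "ICC(A,k)" in table.index else "ICC2k"
        row = table.loc[key]
        assert mine.icc == pytest.approx(row["ICC"], rel=1e-9)
        assert mine.p_value == pytest.approx(row["pval"], rel=1e-6)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.ones((2, 6)))


class TestContrastingGroups:
    def test_equal_sd_midpoint_large_n(self):
        rng = np.random.default_rng(0)
        res = contrasting_groups(
            rng.normal(4, 1, 5000), rng.normal(0, 1, 5000), bootstrap_reps=10, seed=0
        )
        assert res.cutpoint == pytest.approx(2.0, abs=0.1)

    def test_equal_sd_closed_form_midpoint(self):
        # force exactly equal SDs: symmetric samples around different means
        nov = np.array([8.0, 9.0, 10.0, 11.0, 12.0])
        exp = nov - 6.0
        res = contrasting_groups(nov, exp, bootstrap_reps=10, seed=0)
        assert res.cutpoint == pytest.approx((nov.mean() + exp.mean()) / 2, abs=1e-9)

    def test_unequal_sd_grid_search_oracle(self):
        m1, s1, m2, s2 = 4.39, 1.5, 9.34, 3.0
        rng = np.random.default_rng(42)
        exp = m1 + s1 * ((x := rng.standard_normal(40)) - x.mean()) / x.std(ddof=1)
        nov = m2 + s2 * ((y := rng.standard_normal(40)) - y.mean()) / y.std(ddof=1)
        res = contrasting_groups(nov, exp, bootstrap_reps=10, seed=0)
        from scipy.stats import norm

        grid = np.linspace(m1, m2, 2_000_001)
        diff = norm.pdf(grid, m1, s1) - norm.pdf(grid, m2, s2)
        crossing = grid[np.nonzero(np.diff(np.sign(diff)))[0][0]]
        assert res.cutpoint == pytest.approx(crossing, abs=1e-5)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(9)
        nov = rng.normal(9, 2.5, 11)
        exp = rng.normal(4, 1.5, 9)
        a, b = 2.5, -3.0
        r0 = contrasting_groups(nov, exp, bootstrap_reps=10, seed=1)
        r1 = contrasting_groups(a * nov + b, a * exp + b, bootstrap_reps=10, seed=1)
        assert r1.cutpoint == pytest.approx(a * r0.cutpoint + b, rel=1e-12)

    def test_identical_means_rejected(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            contrasting_groups(x, x, bootstrap_reps=10, seed=0)

    def test_bootstrap_ci_brackets_cutpoint(self):
        rng = np.random.default_rng(5)
        nov = rng.normal(9.3, 2.7, 11)
        exp = rng.normal(4.4, 1.6, 9)
        res = contrasting_groups(nov, exp, bootstrap_reps=2000, seed=3)
        assert res.ci95[0] < res.cutpoint < res.ci95[1]


class TestConsequences:
    def _frame(self, novices, experienced):
        rows = [
            {"participant_id": f"n{i}", "group": "novice", "mean_composite": v}
            for i, v in enumerate(novices)
        ] + [
            {"participant_id": f"e{i}", "group": "experienced", "mean_composite": v}
            for i, v in enumerate(experienced)
        ]
        return pd.DataFrame(rows)

    def test_clean_separation(self):
        rep = consequences(self._frame([7, 8, 9], [4, 5]), 6.15)
        assert (rep.n_false_positive, rep.n_false_negative) == (0, 0)

    def test_one_each(self):
        rep = consequences(self._frame([5, 8], [4, 7]), 6.15)
        assert (rep.n_false_positive, rep.n_false_negative) == (1, 1)

    def test_ties_count_as_worse(self):
        rep = consequences(self._frame([6.15, 6.15], [6.15]), 6.15)
        assert (rep.n_false_positive, rep.n_false_negative) == (0, 1)


# ---------------------------------------------------------------------------
# property-based checks

from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        min_size=1,
        max_size=12,
    )
)
def test_holm_properties_hold_for_arbitrary_pvalues(pvals):
    """Rank thresholds are nondecreasing, rank 1 equals alpha/m, and the
    rejection set contains every Bonferroni rejection."""
    alphas, reject = holm_adjusted_alphas(pvals, 0.05)
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = np.array(alphas)[order]
    assert (np.diff(ranked) >= -1e-15).all()
    assert ranked[0] == pytest.approx(0.05 / m)
    for p, r in zip(pvals, reject):
        if p < 0.05 / m:
            assert r


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.floats(min_value=-50, max_value=50),
    st.floats(min_value=0.2, max_value=5.0),
    st.floats(min_value=-20, max_value=20),
)
def test_contrasting_groups_affine_equivariance_property(shift, scale, sep):
    """x -> a*x + b maps the cutpoint to a*cut + b for any a > 0."""
    rng = np.random.default_rng(17)
    nov = rng.normal(8 + sep, 2.0, 9)
    exp = rng.normal(4, 1.2, 8)
    if abs(nov.mean() - exp.mean()) < 1e-6:
        return
    r0 = contrasting_groups(nov, exp, bootstrap_reps=5, seed=0)
    r1 = contrasting_groups(
        scale * nov + shift, scale * exp + shift, bootstrap_reps=5, seed=0
    )
    assert r1.cutpoint == pytest.approx(scale * r0.cutpoint + shift, rel=1e-9, abs=1e-9)
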