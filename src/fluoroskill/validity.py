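"""Validity battery for the simulator test.

Implements the statistical chain used to gather validity evidence:

* per-metric two-way mixed (split-plot) ANOVA -- experience group as the
  between-subject factor, repetition as the within-subject factor --
  with estimated marginal means, t-based CIs and partial eta squared;
* Holm-Bonferroni step-down control of the familywise error over the
  seven candidate metrics (5 view total z-scores, time, image count);
* session effect on the composite (paired mean difference with CI);
* test-retest reliability as a two-way mixed, absolute-agreement,
  average-measures intraclass correlation (McGraw & Wong ICC(A,k)) with
  F-based CI and p-value;
* contrasting-groups standard setting: normal densities fitted to each
  group's mean composites, the cutpoint at their between-means
  intersection, and a seeded percentile bootstrap CI;
* consequence analysis: false positives / negatives against the
  standard (lower composite = better performance; ties count as not
  meeting the standard).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import participant_mean_composites

__all__ = [
    "AnovaResult",
    "ReliabilityResult",
    "StandardResult",
    "ConsequenceReport",
    "ValidityReport",
    "two_way_mixed_anova",
    "holm_adjusted_alphas",
    "select_discriminating",
    "session_effect",
    "icc_absolute_agreement",
    "contrasting_groups",
    "consequences",
    "run_validity",
]

VIEW_METRICS = ("z_PA", "z_AP", "z_LAT", "z_FACET", "z_TANG")
ALL_METRICS = VIEW_METRICS + ("time_s", "n_images_total")


# ---------------------------------------------------------------------------
# two-way mixed ANOVA


@dataclass(frozen=True)
class AnovaResult:
    metric: str
    group_means: dict        # group -> EM mean (group mean of participant means)
    group_cis: dict          # group -> (lo, hi), t-based 95%
    f_group: float
    p_group: float
    partial_eta_sq: float
    df_between: tuple
    ss: dict                 # full split-plot decomposition
    adjusted_alpha: float | None = None
    discriminates: bool | None = None


def two_way_mixed_anova(table: pd.DataFrame, metric: str) -> AnovaResult:
    """Split-plot ANOVA of one metric.

    ``table`` is the per-repetition score table (one row per participant
    x repetition, columns participant_id, group, session, repetition and
    the metric).  Requires complete data: every participant contributes
    the same number of repetitions.  The between-group test is
    ``F = MS_group / MS_subjects_within_group``; partial eta squared is
    ``SS_group / (SS_group + SS_subjects_within_group)``.
    """
    df = table[["participant_id", "group", "session", "repetition", metric]].copy()
    df["rep_idx"] = (df["session"] - 1) * 3 + df["repetition"]
    counts = df.groupby("participant_id")["rep_idx"].count()
    k = int(counts.iloc[0])
    if not (counts == k).all():
        raise ValueError("unbalanced data: unequal repetition counts per participant")
    if df.groupby("participant_id")["rep_idx"].nunique().ne(k).any():
        raise ValueError("duplicate repetition index for a participant")
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need two groups")
    n_per_group = df.groupby("group")["participant_id"].nunique()
    if (n_per_group < 2).any():
        raise ValueError("each group needs at least 2 participants")

    y = df[metric].to_numpy(dtype=float)
    grand = y.mean()
    n_total = int(df["participant_id"].nunique())
    a = len(groups)

    part_means = df.groupby("participant_id")[metric].mean()
    part_group = df.groupby("participant_id")["group"].first()
    group_means = df.groupby("group")[metric].mean()
    rep_means = df.groupby("rep_idx")[metric].mean()
    cell_means = df.groupby(["group", "rep_idx"])[metric].mean()

    ng = n_per_group.to_dict()
    ss_group = k * sum(ng[g] * (group_means[g] - grand) ** 2 for g in groups)
    ss_subj = k * sum(
        (part_means[p] - group_means[part_group[p]]) ** 2 for p in part_means.index
    )
    ss_rep = n_total * float(((rep_means - grand) ** 2).sum())
    ss_inter = sum(
        ng[g] * (cell_means[(g, j)] - group_means[g] - rep_means[j] + grand) ** 2
        for g in groups
        for j in rep_means.index
    )
    ss_total = float(((y - grand) ** 2).sum())
    ss_res = ss_total - ss_group - ss_subj - ss_rep - ss_inter

    df_group = a - 1
    df_subj = n_total - a
    if df_subj <= 0:
        raise ValueError("no degrees of freedom for subjects within groups")
    ms_group = ss_group / df_group
    ms_subj = ss_subj / df_subj
    if ms_subj <= 0:
        raise ValueError("zero between-subject variance: F undefined")
    f_group = ms_group / ms_subj
    p_group = float(sps.f.sf(f_group, df_group, df_subj))
    eta = ss_group / (ss_group + ss_subj)

    # EM means: group means of participant means (equal to group cell means
    # for complete data); CIs use the pooled between-subject mean square.
    tcrit = float(sps.t.ppf(0.975, df_subj))
    g_means, g_cis = {}, {}
    for g in groups:
        pm = part_means[part_group[part_group == g].index]
        m = float(pm.mean())
        se = math.sqrt(ms_subj / (k * ng[g]))
        g_means[g] = m
        g_cis[g] = (m - tcrit * se, m + tcrit * se)

    return AnovaResult(
        metric=metric,
        group_means=g_means,
        group_cis=g_cis,
        f_group=float(f_group),
        p_group=p_group,
        partial_eta_sq=float(eta),
        df_between=(df_group, df_subj),
        ss={
            "group": float(ss_group),
            "subjects_within_group": float(ss_subj),
            "repetition": float(ss_rep),
            "interaction": float(ss_inter),
            "residual": float(ss_res),
            "total": float(ss_total),
        },
    )


# ---------------------------------------------------------------------------
# Holm-Bonferroni


def holm_adjusted_alphas(p_values, familywise_alpha: float = 0.05):
    """Holm step-down: per-test adjusted alpha levels and reject flags.

    The p-values are ranked ascending; the threshold at rank r (1-based)
    is ``alpha / (m - r + 1)``.  Testing stops at the first
    non-rejection; all later hypotheses are retained.  Thresholds and
    flags are returned in the original test order.
    """
    p = [float(x) for x in p_values]
    if not p:
        raise ValueError("empty p-value list")
    if any(not (0 <= x <= 1) for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    alphas = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    still_rejecting = True
    for rank, idx in enumerate(order, start=1):
        thr = familywise_alpha / (m - rank + 1)
        alphas[idx] = thr
        if still_rejecting and p[idx] < thr:
            reject[idx] = True
        else:
            still_rejecting = False
    return alphas.tolist(), reject.tolist()


def select_discriminating(anova_results, familywise_alpha: float = 0.05):
    """Holm-select discriminating metrics; return the view subset.

    All candidate metrics enter the familywise correction, but only view
    total z-scores are eligible for the composite.
    """
    results = list(anova_results)
    alphas, reject = holm_adjusted_alphas(
        [r.p_group for r in results], familywise_alpha
    )
    annotated = []
    selected_views = []
    for r, al, rej in zip(results, alphas, reject):
        annotated.append(
            AnovaResult(
                **{
                    **r.__dict__,
                    "adjusted_alpha": float(al),
                    "discriminates": bool(rej),
                }
            )
        )
        if rej and r.metric in VIEW_METRICS:
            selected_views.append(r.metric[2:])
    return selected_views, annotated


# ---------------------------------------------------------------------------
# session effect


def session_effect(score_table: pd.DataFrame):
    """Session-1 minus session-2 participant mean composite difference.

    Returns (mean_difference, (ci_lo, ci_hi)) with a t-based 95% CI over
    complete participants.
    """
    if "composite" not in score_table.columns:
        raise ValueError("score table needs a composite column")
    piv = score_table.pivot_table(
        index="participant_id", columns="session", values="composite", aggfunc="mean"
    )
    piv = piv.dropna()
    if piv.shape[0] < 2 or piv.shape[1] != 2:
        raise ValueError("need >= 2 complete participants over both sessions")
    d = (piv[1] - piv[2]).to_numpy(dtype=float)
    m = float(d.mean())
    if d.size > 1 and d.std(ddof=1) > 0:
        se = d.std(ddof=1) / math.sqrt(d.size)
        tcrit = float(sps.t.ppf(0.975, d.size - 1))
        ci = (m - tcrit * se, m + tcrit * se)
    else:
        ci = (m, m)
    return m, ci


# ---------------------------------------------------------------------------
# ICC


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci95: tuple
    p_value: float
    n_subjects: int
    k_measures: int
    mean_squares: dict


def icc_absolute_agreement(matrix) -> ReliabilityResult:
    """Two-way mixed, absolute-agreement, average-measures ICC.

    ``matrix`` is subjects x measurements (complete).  Point estimate
    ``(MSR - MSE) / (MSR + (MSC - MSE) / n)``; the 95% CI follows the
    standard two-way F-based formulation for single measures followed by
    Spearman-Brown scaling to k measures; the p-value tests MSR against
    MSE.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x measurements)")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 measurement columns")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("matrix contains missing cells; exclude listwise upstream")

    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * ((row_m - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate matrix: zero total variance")
    icc_k = (msr - mse) / denom

    # single-measures CI (McGraw & Wong case A,1), then Spearman-Brown
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    alpha = 0.05
    a_ = (k * icc_1) / (n * (1 - icc_1)) if icc_1 < 1 else np.inf
    b_ = 1 + (k * icc_1 * (n - 1)) / (n * (1 - icc_1)) if icc_1 < 1 else np.inf
    if np.isfinite(a_):
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = float(sps.f.ppf(1 - alpha / 2, n - 1, v))
        f_u = float(sps.f.ppf(1 - alpha / 2, v, n - 1))
        lo1 = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        sb = lambda r: r * k / (1 + (k - 1) * r) if (1 + (k - 1) * r) != 0 else 1.0
        ci = (float(sb(lo1)), float(sb(hi1)))
    else:
        ci = (1.0, 1.0)
    fvalue = msr / mse if mse > 0 else np.inf
    p = float(sps.f.sf(fvalue, n - 1, (n - 1) * (k - 1))) if np.isfinite(fvalue) else 0.0
    return ReliabilityResult(
        icc=float(icc_k),
        ci95=ci,
        p_value=p,
        n_subjects=n,
        k_measures=k,
        mean_squares={"MSR": float(msr), "MSC": float(msc), "MSE": float(mse)},
    )


# ---------------------------------------------------------------------------
# contrasting groups


@dataclass(frozen=True)
class StandardResult:
    cutpoint: float
    ci95: tuple
    novice_fit: tuple        # (mean, sd)
    experienced_fit: tuple   # (mean, sd)
    bootstrap_reps: int


def _normal_intersection(m1: float, s1: float, m2: float, s2: float) -> float:
    """Root of equal normal log-densities lying between the two means."""
    if math.isclose(m1, m2, abs_tol=1e-12):
        raise ValueError("group means are identical; no discriminatory standard")
    lo, hi = (m1, m2) if m1 < m2 else (m2, m1)
    if math.isclose(s1, s2, rel_tol=1e-12, abs_tol=1e-12):
        return 0.5 * (m1 + m2)
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * math.log(s2 / s1)
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("densities do not intersect on the real line")
    r1 = (-b + math.sqrt(disc)) / (2 * a)
    r2 = (-b - math.sqrt(disc)) / (2 * a)
    between = [r for r in (r1, r2) if lo - 1e-12 <= r <= hi + 1e-12]
    if not between:
        # fall back to the root closest to the midpoint of the means
        mid = 0.5 * (lo + hi)
        return min((r1, r2), key=lambda r: abs(r - mid))
    return min(between, key=lambda r: abs(r - 0.5 * (lo + hi)))


def contrasting_groups(
    novice_scores,
    experienced_scores,
    bootstrap_reps: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> StandardResult:
    """Contrasting-groups standard: intersection of fitted normal densities.

    A normal density is fitted (mean, sample SD) to each group's mean
    composites; the discriminatory standard is the density intersection
    between the two group means.  The CI is a percentile bootstrap over
    participants resampled within their groups.
    """
    nov = np.asarray(novice_scores, dtype=float)
    exp_ = np.asarray(experienced_scores, dtype=float)
    if nov.size < 3 or exp_.size < 3:
        raise ValueError("need at least 3 participants per group")

    def fit(x):
        return float(x.mean()), float(x.std(ddof=1))

    mn, sn = fit(nov)
    me, se = fit(exp_)
    cut = _normal_intersection(mn, sn, me, se)

    if rng is None:
        rng = np.random.default_rng(seed)
    boots = []
    for _ in range(int(bootstrap_reps)):
        bn = nov[rng.integers(0, nov.size, nov.size)]
        be = exp_[rng.integers(0, exp_.size, exp_.size)]
        m1, s1 = fit(bn)
        m2, s2 = fit(be)
        if s1 <= 0 or s2 <= 0 or math.isclose(m1, m2, abs_tol=1e-12):
            continue
        try:
            boots.append(_normal_intersection(m1, s1, m2, s2))
        except ValueError:
            continue
    if boots:
        ci = tuple(float(q) for q in np.percentile(boots, [2.5, 97.5]))
    else:
        ci = (cut, cut)
    return StandardResult(
        cutpoint=float(cut),
        ci95=ci,
        novice_fit=(mn, sn),
        experienced_fit=(me, se),
        bootstrap_reps=int(bootstrap_reps),
    )


# ---------------------------------------------------------------------------
# consequences


@dataclass(frozen=True)
class ConsequenceReport:
    n_false_positive: int    # novices scoring better than the standard
    n_false_negative: int    # experienced scoring worse than (or at) the standard
    classifications: tuple   # (participant_id, group, score, meets_standard)


def consequences(mean_scores: pd.DataFrame, standard: float) -> ConsequenceReport:
    """Classify participants against the standard.

    Lower composite = better performance; a score strictly below the
    standard meets it, a tie counts as not meeting it (conservative for
    a proficiency test).
    """
    if not math.isfinite(float(standard)):
        raise ValueError("standard must be finite")
    rows = mean_scores.dropna(subset=["mean_composite"])
    cls = []
    fp = fn = 0
    for _, r in rows.iterrows():
        meets = float(r["mean_composite"]) < standard
        cls.append((r["participant_id"], r["group"], float(r["mean_composite"]), meets))
        if r["group"] == "novice" and meets:
            fp += 1
        if r["group"] == "experienced" and not meets:
            fn += 1
    return ConsequenceReport(fp, fn, tuple(cls))


# ---------------------------------------------------------------------------
# full battery


@dataclass(frozen=True)
class ValidityReport:
    anova_results: tuple
    selected_views: tuple
    composite_anova: AnovaResult | None
    session_difference: tuple   # (mean, (lo, hi))
    reliability: ReliabilityResult
    standard: StandardResult
    consequence: ConsequenceReport
    n_complete: dict

    def to_dict(self) -> dict:
        def anova_dict(r):
            return {
                "metric": r.metric,
                "em_means": r.group_means,
                "em_cis": {g: list(c) for g, c in r.group_cis.items()},
                "F": r.f_group,
                "p": r.p_group,
                "partial_eta_sq": r.partial_eta_sq,
                "adjusted_alpha": r.adjusted_alpha,
                "discriminates": r.discriminates,
            }

        return {
            "metrics": [anova_dict(r) for r in self.anova_results],
            "selected_views": list(self.selected_views),
            "composite_anova": (
                anova_dict(self.composite_anova) if self.composite_anova else None
            ),
            "session_difference": {
                "mean": self.session_difference[0],
                "ci95": list(self.session_difference[1]),
            },
            "icc": {
                "value": self.reliability.icc,
                "ci95": list(self.reliability.ci95),
                "p": self.reliability.p_value,
                "k": self.reliability.k_measures,
            },
            "standard": {
                "cutpoint": self.standard.cutpoint,
                "ci95": list(self.standard.ci95),
            },
            "consequences": {
                "false_positive": self.consequence.n_false_positive,
                "false_negative": self.consequence.n_false_negative,
            },
            "n_complete": self.n_complete,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        sel = ", ".join(self.selected_views) if self.selected_views else "(none)"
        lines = [
            f"Discriminating views (Holm, alpha=0.05): {sel}",
            "Session difference (s1 - s2): "
            f"{self.session_difference[0]:.2f} "
            f"(CI {self.session_difference[1][0]:.2f} to {self.session_difference[1][1]:.2f})",
            f"Test-retest ICC (A,k): {self.reliability.icc:.2f} "
            f"(CI {self.reliability.ci95[0]:.2f}-{self.reliability.ci95[1]:.2f}, "
            f"p={self.reliability.p_value:.2g})",
            f"Contrasting-groups standard: {self.standard.cutpoint:.2f} "
            f"(CI {self.standard.ci95[0]:.2f}-{self.standard.ci95[1]:.2f})",
            f"Consequences: {self.consequence.n_false_positive} false positive(s), "
            f"{self.consequence.n_false_negative} false negative(s)",
        ]
        if self.composite_anova is not None:
            ca = self.composite_anova
            gm = ca.group_means
            lines.insert(
                1,
                "Composite EM means: "
                + ", ".join(f"{g}={gm[g]:.2f}" for g in sorted(gm))
                + f" (p={ca.p_group:.2g}, eta_p^2={ca.partial_eta_sq:.2f})",
            )
        return "\n".join(lines)


def run_validity(
    score_table: pd.DataFrame,
    bootstrap_reps: int = 10_000,
    seed: int | None = None,
    icc_unit: str = "repetitions",
) -> ValidityReport:
    """Run the full validity battery on a per-repetition score table.

    ``score_table`` comes from :func:`fluoroskill.scoring.score_records`
    (without composites -- the discriminating views are chosen here).
    ``icc_unit`` selects the reliability unit of analysis:
    ``"repetitions"`` (participants x 6 composites, default) or
    ``"sessions"`` (participants x 2 session means).
    """
    # listwise exclusion: keep only participants with all 6 repetitions
    counts = score_table.groupby("participant_id")["repetition"].count()
    complete_ids = counts[counts == 6].index
    tab = score_table[score_table["participant_id"].isin(complete_ids)].copy()
    n_complete = (
        tab.groupby("group")["participant_id"].nunique().to_dict()
    )
    if len(n_complete) < 2 or min(n_complete.values()) < 3:
        raise ValueError("need >= 3 complete participants in each group")

    anovas = [two_way_mixed_anova(tab, m) for m in ALL_METRICS]
    selected_views, annotated = select_discriminating(anovas)

    if not selected_views:
        raise ValueError(
            "no discriminating views survived the familywise correction; "
            "cannot form a composite"
        )

    from .scoring import composite as _composite  # local to avoid cycle at import

    tab["composite"] = [
        _composite({v: row[f"z_{v}"] for v in ("PA", "AP", "LAT", "FACET", "TANG")},
                   selected_views)
        for row in tab.to_dict("records")
    ]

    composite_anova = two_way_mixed_anova(tab, "composite")
    sess = session_effect(tab)

    if icc_unit == "repetitions":
        piv = tab.pivot_table(
            index="participant_id",
            columns=["session", "repetition"],
            values="composite",
        )
    elif icc_unit == "sessions":
        piv = tab.pivot_table(
            index="participant_id", columns="session", values="composite",
            aggfunc="mean",
        )
    else:
        raise ValueError("icc_unit must be 'repetitions' or 'sessions'")
    rel = icc_absolute_agreement(piv.to_numpy())

    means = participant_mean_composites(tab)
    nov = means[means["group"] == "novice"]["mean_composite"].dropna()
    exp_ = means[means["group"] == "experienced"]["mean_composite"].dropna()
    std = contrasting_groups(nov, exp_, bootstrap_reps=bootstrap_reps, seed=seed)
    cons = consequences(means, std.cutpoint)

    return ValidityReport(
        anova_results=tuple(annotated),
        selected_views=tuple(selected_views),
        composite_anova=composite_anova,
        session_difference=sess,
        reliability=rel,
        standard=std,
        consequence=cons,
        n_complete=n_complete,
    )
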