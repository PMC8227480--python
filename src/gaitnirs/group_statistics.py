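"""Cohort statistical battery.

Normality-gated two-sample comparisons (Shapiro-Wilk at 0.05 choosing
between Student/paired t and Mann-Whitney/Wilcoxon), pooled-variance t
tests from printed summary statistics, a balanced mixed-design
(between: treatment, within: time) ANOVA without sphericity correction,
Spearman correlations, and 2x2 chi-square without continuity correction.
``analyze_cohort`` runs the full analysis plan over a cohort table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, SchemaError

ALPHA_DEFAULT = 0.05

REQUIRED_COLUMNS = (
    "subject", "cohort", "treatment", "timepoint",
    "tot_oxy_auc", "maff_oxy_auc", "laff_oxy_auc",
)
OPTIONAL_COLUMNS = (
    "edss", "age", "sex", "phenotype", "t25fw_speed", "six_mwd", "bbs",
    "rti", "rti_category",
)

_AUC_OUTCOMES = {
    "Tot": "tot_oxy_auc", "MAff": "maff_oxy_auc", "LAff": "laff_oxy_auc",
}


@dataclass
class StatTestResult:
    name: str
    test: str
    statistic: float
    p_value: float
    df: float | None = None
    direction: float | None = None   # sign of the effect (group1 - group2 etc.)
    n: tuple | None = None
    branch: str | None = None        # "parametric" | "rank" for gated tests
    note: str | None = None

    def significant(self, alpha: float = ALPHA_DEFAULT) -> bool:
        return self.p_value < alpha

    def to_dict(self) -> dict:
        return asdict(self)


def shapiro_gate_compare(
    sample_a, sample_b, paired: bool = False, name: str = "compare",
    normality_alpha: float = 0.05,
) -> StatTestResult:
    """Two-sample comparison with Shapiro-Wilk branch selection.

    Unpaired: pooled-variance Student t when both samples pass normality,
    Mann-Whitney U otherwise.  Paired: normality is assessed on the
    differences; paired t vs Wilcoxon signed-rank.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if min(a.size, b.size) < 3:
        raise InvalidInputError("need at least 3 observations per sample")
    if paired and a.size != b.size:
        raise InvalidInputError("paired samples must have equal length")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False                       # degenerate: force rank branch
        return stats.shapiro(x).pvalue > normality_alpha

    if paired:
        diff = a - b
        parametric = _normal(diff)
        if parametric:
            res = stats.ttest_rel(a, b)
            return StatTestResult(
                name, "paired t", float(res.statistic), float(res.pvalue),
                df=float(a.size - 1), direction=float(np.sign(diff.mean())),
                n=(a.size,), branch="parametric",
            )
        if np.ptp(diff) == 0 and diff[0] == 0:
            return StatTestResult(
                name, "wilcoxon", 0.0, 1.0, n=(a.size,), branch="rank",
                note="all differences zero",
            )
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=False)
        return StatTestResult(
            name, "wilcoxon", float(res.statistic), float(res.pvalue),
            direction=float(np.sign(np.median(diff))), n=(a.size,), branch="rank",
        )

    parametric = _normal(a) and _normal(b)
    if parametric:
        res = stats.ttest_ind(a, b, equal_var=True)
        return StatTestResult(
            name, "student t", float(res.statistic), float(res.pvalue),
            df=float(a.size + b.size - 2),
            direction=float(np.sign(a.mean() - b.mean())),
            n=(a.size, b.size), branch="parametric",
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return StatTestResult(
        name, "mann-whitney", float(res.statistic), float(res.pvalue),
        direction=float(np.sign(np.median(a) - np.median(b))),
        n=(a.size, b.size), branch="rank",
    )


def t_test_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled", name: str = "t_from_summary",
) -> StatTestResult:
    """Two-sample t test from summary statistics (pooled or Welch)."""
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise InvalidInputError("SDs must be >= 0")
    if variant not in ("pooled", "welch"):
        raise InvalidInputError(f"unknown variant {variant!r}")
    note = None
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return StatTestResult(
                name, f"{variant} t", 0.0, 1.0, df=float(n1 + n2 - 2),
                direction=0.0, n=(n1, n2),
            )
        note = "zero variance with unequal means"
        return StatTestResult(
            name, f"{variant} t", math.inf * np.sign(mean1 - mean2), 0.0,
            df=float(n1 + n2 - 2), direction=float(np.sign(mean1 - mean2)),
            n=(n1, n2), note=note,
        )
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatTestResult(
        name, f"{variant} t", float(res.statistic), float(res.pvalue),
        df=df, direction=float(np.sign(mean1 - mean2)), n=(n1, n2), note=note,
    )


def mixed_anova_interaction(
    table: pd.DataFrame,
    outcome: str,
    subject: str = "subject",
    between: str = "treatment",
    within: str = "timepoint",
    name: str = "group x time",
) -> StatTestResult:
    """Interaction F of a mixed-design ANOVA (between-groups x repeated
    time), computed from sums of squares without sphericity correction.

    Incomplete subjects are removed listwise; the design must be balanced
    across time within subjects.  For g groups, t times and N subjects the
    interaction df are ((g-1)(t-1), (t-1)(N-g)).
    """
    df = table[[subject, between, within, outcome]].dropna().copy()
    times = sorted(df[within].unique())
    t = len(times)
    complete = df.groupby(subject)[within].nunique()
    keep = complete[complete == t].index
    dropped = complete.size - keep.size
    df = df[df[subject].isin(keep)]
    if df.empty or t < 2:
        raise InvalidInputError("need >= 2 timepoints and complete subjects")
    groups = df.groupby(subject)[between].first()
    g = groups.nunique()
    if g < 2:
        raise InvalidInputError("need >= 2 between-subject groups")
    n_subj = keep.size

    y = df[outcome].astype(float)
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()

    subj_means = df.groupby(subject)[outcome].mean()
    ss_subjects = t * ((subj_means - grand) ** 2).sum()

    grp_counts = groups.value_counts()
    grp_means = df.groupby(between)[outcome].mean()
    ss_group = sum(
        grp_counts[gr] * t * (grp_means[gr] - grand) ** 2 for gr in grp_means.index
    )
    ss_subj_within = ss_subjects - ss_group

    time_means = df.groupby(within)[outcome].mean()
    ss_time = n_subj * ((time_means - grand) ** 2).sum()

    cell_means = df.groupby([between, within])[outcome].mean()
    ss_cells = sum(
        grp_counts[gr] * (cell_means[(gr, tp)] - grand) ** 2
        for gr, tp in cell_means.index
    )
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_subjects - ss_time - ss_inter

    df_inter = (g - 1) * (t - 1)
    df_error = (t - 1) * (n_subj - g)
    if df_error <= 0:
        raise InvalidInputError("not enough subjects for the within error term")
    ms_error = ss_error / df_error
    f_val = (ss_inter / df_inter) / ms_error if ms_error > 0 else 0.0
    p = float(stats.f.sf(f_val, df_inter, df_error)) if ms_error > 0 else 1.0
    note = f"{dropped} incomplete subject(s) dropped" if dropped else None
    return StatTestResult(
        name, "mixed anova interaction", float(f_val), p,
        df=(float(df_inter), float(df_error)), n=(n_subj,), note=note,
    )


def spearman_correlation(x, y, name: str = "spearman") -> StatTestResult:
    """Spearman rho with mid-ranks and the t-approximation p (df = n - 2)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise InvalidInputError("unequal lengths")
    if x.size < 4:
        raise InvalidInputError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("correlation undefined for constant input")
    rho, _ = stats.spearmanr(x, y)
    if abs(abs(rho) - 1.0) < 1e-12:
        rho = float(np.sign(rho))      # exact monotone: snap float dust
    n = x.size
    if abs(rho) >= 1.0:
        return StatTestResult(name, "spearman", float(rho), 0.0,
                              df=float(n - 2), n=(n,))
    t_stat = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * float(stats.t.sf(abs(t_stat), n - 2))
    return StatTestResult(
        name, "spearman", float(rho), p, df=float(n - 2),
        direction=float(np.sign(rho)), n=(n,),
    )


def chi_square_proportions(
    a: int, b: int, c: int, d: int, name: str = "chi2"
) -> StatTestResult:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1, no
    continuity correction."""
    tbl = np.array([[a, b], [c, d]], dtype=float)
    if (tbl < 0).any():
        raise InvalidInputError("counts must be >= 0")
    if (tbl.sum(axis=0) == 0).any() or (tbl.sum(axis=1) == 0).any():
        raise InvalidInputError("zero margin in the 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
    return StatTestResult(
        name, "chi-square", float(chi2), float(p), df=1.0,
        n=(int(a + b), int(c + d)),
    )


def within_subject_trend(
    table: pd.DataFrame, outcome: str, subject: str = "subject",
    within: str = "timepoint", name: str = "trend",
) -> StatTestResult:
    """Within-group trend across timepoints: per-subject OLS slope on the
    timepoint index, then a one-sample t test of the slopes against zero."""
    df = table[[subject, within, outcome]].dropna()
    times = sorted(df[within].unique())
    if len(times) < 2:
        raise InvalidInputError("need >= 2 timepoints for a trend")
    t_index = {tp: i for i, tp in enumerate(times)}
    slopes = []
    for _, grp in df.groupby(subject):
        if grp[within].nunique() < len(times):
            continue
        xs = grp[within].map(t_index).astype(float)
        ys = grp[outcome].astype(float)
        slopes.append(np.polyfit(xs, ys, 1)[0])
    if len(slopes) < 3:
        raise InvalidInputError("need >= 3 complete subjects")
    res = stats.ttest_1samp(slopes, 0.0)
    return StatTestResult(
        name, "within-subject linear trend t", float(res.statistic),
        float(res.pvalue), df=float(len(slopes) - 1),
        direction=float(np.sign(np.mean(slopes))), n=(len(slopes),),
    )


def validate_cohort_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing columns: {missing}")
    if table.empty:
        raise SchemaError("cohort table is empty")
    dup = table.duplicated(subset=["subject", "timepoint"])
    if dup.any():
        raise SchemaError("duplicate (subject, timepoint) rows")


def _change_scores(pwms: pd.DataFrame, outcome: str) -> pd.Series:
    """Per-subject T2 - T0 change, complete cases only."""
    wide = pwms.pivot(index="subject", columns="timepoint", values=outcome)
    if "T0" not in wide.columns or "T2" not in wide.columns:
        return pd.Series(dtype=float)
    return (wide["T2"] - wide["T0"]).dropna()


def analyze_cohort(table: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> dict:
    """Run the full analysis plan; returns {"results": [...], "n_tests": k}.

    Families: baseline PwMS-vs-healthy comparisons; baseline subgroup
    contrasts; baseline clinical correlations; longitudinal change tests;
    group-by-time ANOVAs; RTI correlations and category contrasts;
    change-vs-performance correlations; baseline-vs-response correlation.
    Each emitted item is a StatTestResult dict with a ``significant`` flag;
    no multiple-testing correction is applied.
    """
    validate_cohort_table(table)
    results: list[StatTestResult] = []

    def emit(fn, *args, **kwargs):
        try:
            results.append(fn(*args, **kwargs))
        except InvalidInputError:
            pass                           # family not computable on this table

    base = table[table["timepoint"] == "T0"]
    pwms0 = base[base["cohort"] == "PwMS"]
    healthy0 = base[base["cohort"] == "healthy"]
    pwms = table[table["cohort"] == "PwMS"]

    # 1. baseline PwMS vs healthy
    if len(healthy0) >= 3 and len(pwms0) >= 3:
        for label, col in _AUC_OUTCOMES.items():
            emit(shapiro_gate_compare, pwms0[col], healthy0[col],
                 name=f"baseline {label}-Oxy_AUC: PwMS vs healthy")

    # 2. baseline subgroup contrasts within PwMS
    if len(pwms0) >= 6:
        med_age = pwms0["age"].median() if "age" in pwms0 else None
        for label, col in _AUC_OUTCOMES.items():
            if med_age is not None:
                emit(shapiro_gate_compare,
                     pwms0.loc[pwms0["age"] <= med_age, col],
                     pwms0.loc[pwms0["age"] > med_age, col],
                     name=f"baseline {label}: age median split")
            if "sex" in pwms0:
                emit(shapiro_gate_compare,
                     pwms0.loc[pwms0["sex"] == "M", col],
                     pwms0.loc[pwms0["sex"] == "F", col],
                     name=f"baseline {label}: sex")
            if "phenotype" in pwms0:
                emit(shapiro_gate_compare,
                     pwms0.loc[pwms0["phenotype"] == "primary progressive", col],
                     pwms0.loc[pwms0["phenotype"] == "secondary progressive", col],
                     name=f"baseline {label}: phenotype")
            if "edss" in pwms0:
                emit(shapiro_gate_compare,
                     pwms0.loc[pwms0["edss"] <= 6.0, col],
                     pwms0.loc[pwms0["edss"] > 6.0, col],
                     name=f"baseline {label}: EDSS 6.0 vs higher")

    # 3. baseline clinical/performance correlations
    for label, col in _AUC_OUTCOMES.items():
        for clin in ("edss", "t25fw_speed", "six_mwd", "bbs"):
            if clin in pwms0:
                sub = pwms0[[col, clin]].dropna()
                if len(sub) >= 4:
                    emit(spearman_correlation, sub[col], sub[clin],
                         name=f"baseline {label} vs {clin}")

    # 4. longitudinal change tests
    changes: dict[str, dict[str, pd.Series]] = {}
    for label, col in _AUC_OUTCOMES.items():
        changes[label] = {}
        for arm in ("RAGT", "OW"):
            ch = _change_scores(pwms[pwms["treatment"] == arm], col)
            changes[label][arm] = ch
            if len(ch) >= 3:
                try:
                    t2, t0 = _paired_t0_t2(pwms[pwms["treatment"] == arm], col)
                    emit(shapiro_gate_compare, t2, t0, paired=True,
                         name=f"{arm} {label}: T0 vs T2")
                except InvalidInputError:
                    pass
                emit(within_subject_trend, pwms[pwms["treatment"] == arm], col,
                     name=f"{arm} {label}: trend across timepoints")
        ra, ow = changes[label].get("RAGT"), changes[label].get("OW")
        if ra is not None and ow is not None and len(ra) >= 3 and len(ow) >= 3:
            emit(shapiro_gate_compare, ra, ow,
                 name=f"delta {label}: RAGT vs OW")

    # 5. group x time mixed ANOVA
    for label in ("Tot", "MAff"):
        emit(mixed_anova_interaction, pwms, _AUC_OUTCOMES[label],
             name=f"group x time interaction: {label}-Oxy_AUC")

    # 6. RTI correlations and category contrasts
    if "rti" in pwms.columns and pwms["rti"].notna().any():
        rti0 = pwms[pwms["timepoint"] == "T0"][["subject", "rti", "rti_category",
                                                "treatment"]].set_index("subject")
        for label, col in _AUC_OUTCOMES.items():
            ch = _change_scores(pwms, col)
            joined = rti0.join(ch.rename("delta"), how="inner").dropna(
                subset=["rti", "delta"])
            if len(joined) >= 4:
                emit(spearman_correlation, joined["rti"], joined["delta"],
                     name=f"RTI vs delta {label} (all PwMS)")
            for arm in ("RAGT", "OW"):
                sub = joined[joined["treatment"] == arm]
                if len(sub) >= 4:
                    emit(spearman_correlation, sub["rti"], sub["delta"],
                         name=f"RTI vs delta {label} ({arm})")
                lo = sub.loc[sub["rti_category"] == "low", "delta"]
                hi = sub.loc[sub["rti_category"] == "high", "delta"]
                if len(lo) >= 3 and len(hi) >= 3:
                    emit(shapiro_gate_compare, lo, hi,
                         name=f"delta {label} by RTI category ({arm})")

    # 7. delta MAff vs delta performance
    for clin in ("t25fw_speed", "six_mwd"):
        if clin in pwms.columns:
            d_auc = _change_scores(pwms, "maff_oxy_auc")
            d_clin = _change_scores(pwms, clin)
            joined = pd.concat([d_auc.rename("a"), d_clin.rename("c")],
                               axis=1).dropna()
            if len(joined) >= 4:
                emit(spearman_correlation, joined["a"], joined["c"],
                     name=f"delta MAff vs delta {clin}")

    # 8. baseline Tot vs T25FW response
    if "t25fw_speed" in pwms.columns:
        tot0 = pwms0.set_index("subject")["tot_oxy_auc"]
        d_speed = _change_scores(pwms, "t25fw_speed")
        joined = pd.concat([tot0.rename("tot0"), d_speed.rename("d")],
                           axis=1).dropna()
        if len(joined) >= 4:
            emit(spearman_correlation, joined["tot0"], joined["d"],
                 name="baseline Tot vs delta T25FW")

    return {
        "alpha": alpha,
        "n_tests": len(results),
        "results": [
            {**r.to_dict(), "significant": r.significant(alpha)} for r in results
        ],
    }


def _paired_t0_t2(arm_table: pd.DataFrame, outcome: str):
    wide = arm_table.pivot(index="subject", columns="timepoint", values=outcome)
    wide = wide.dropna(subset=[c for c in ("T0", "T2") if c in wide.columns])
    if "T0" not in wide.columns or "T2" not in wide.columns or len(wide) < 3:
        raise InvalidInputError("missing T0/T2 pairs")
    return wide["T2"].to_numpy(), wide["T0"].to_numpy()
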