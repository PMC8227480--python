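import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitnirs.errors import InvalidInputError, SchemaError
from gaitnirs.group_statistics import (
    analyze_cohort,
    chi_square_proportions,
    mixed_anova_interaction,
    shapiro_gate_compare,
    spearman_correlation,
    t_test_from_summary,
    within_subject_trend,
)


class TestShapiroGateCompare:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = shapiro_gate_compare(a, a)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_parametric_branch_rate(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            res = shapiro_gate_compare(rng.normal(size=12), rng.normal(size=12))
            hits += res.branch == "parametric"
        # both Shapiro tests pass with prob ~0.95^2; 200 draws
        assert hits >= 170

    def test_rank_branch_on_cauchy(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            res = shapiro_gate_compare(rng.standard_cauchy(12),
                                       rng.standard_cauchy(12))
            hits += res.branch == "rank"
        assert hits > 100

    def test_paired_uses_differences(self):
        rng = np.random.default_rng(17)
        base = rng.standard_cauchy(12) * 100  # wildly non-normal levels
        a = base + rng.normal(0.5, 1.0, 12)   # but normal differences
        res = shapiro_gate_compare(a, base, paired=True)
        assert res.branch == "parametric"
        assert res.test == "paired t"

    def test_constant_sample_rank_branch(self):
        res = shapiro_gate_compare([1.0] * 6, [1.0, 2.0, 1.5, 2.5, 1.2, 2.2])
        assert res.branch == "rank"

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            shapiro_gate_compare([1, 2], [3, 4, 5])

    def test_label_swap_preserves_p(self):
        rng = np.random.default_rng(18)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        r1 = shapiro_gate_compare(a, b)
        r2 = shapiro_gate_compare(b, a)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)


class TestTTestFromSummary:
    # printed summary rows: (mean1, sd1, n1, mean2, sd2, n2) -> rounded p
    @pytest.mark.parametrize("row,expected_p", [
        ((218637, 162874, 24, 26428, 7488, 5), 0.015),
        ((163797, 104461, 24, 15543, 2075, 5), 0.004),
        ((-157031, 172496, 12, 242080, 361902, 12), 0.002),
    ])
    def test_published_rows(self, row, expected_p):
        res = t_test_from_summary(*row, variant="pooled")
        assert round(res.p_value, 3) == expected_p
        assert res.df == row[2] + row[5] - 2

    def test_total_row_below_bound(self):
        res = t_test_from_summary(382434, 174813, 24, 41971, 8549, 5,
                                  variant="pooled")
        assert res.p_value < 0.001

    def test_identical_summaries(self):
        res = t_test_from_summary(10, 2, 8, 10, 2, 8)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_unequal_means(self):
        res = t_test_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)
        assert res.p_value == 0.0
        assert res.note is not None

    def test_zero_variance_equal_means(self):
        res = t_test_from_summary(1.0, 0.0, 5, 1.0, 0.0, 5)
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_matches_raw_data_pooled_t(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1.4, 11)
        res = t_test_from_summary(a.mean(), a.std(ddof=1), a.size,
                                  b.mean(), b.std(ddof=1), b.size)
        raw = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(raw.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(raw.pvalue, rel=1e-12)

    def test_welch_df(self):
        res = t_test_from_summary(0, 1, 10, 0, 3, 20, variant="welch")
        v1, v2 = 1 / 10, 9 / 20
        expected_df = (v1 + v2) ** 2 / (v1**2 / 9 + v2**2 / 19)
        assert res.df == pytest.approx(expected_df)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            t_test_from_summary(0, 1, 1, 0, 1, 5)
        with pytest.raises(InvalidInputError):
            t_test_from_summary(0, -1, 5, 0, 1, 5)
        with pytest.raises(InvalidInputError):
            t_test_from_summary(0, 1, 5, 0, 1, 5, variant="bogus")


def _long_table(values):
    """values[g][s][t] -> long-format frame."""
    rows = []
    for g, subjects in values.items():
        for s, series in enumerate(subjects):
            for t, y in enumerate(series):
                rows.append({"subject": f"{g}{s}", "treatment": g,
                             "timepoint": f"T{t}", "y": y})
    return pd.DataFrame(rows)


def _brute_force_interaction_f(values):
    """Cell-means sums-of-squares computation, written independently."""
    ys = []
    for g, subjects in values.items():
        for series in subjects:
            ys.extend(series)
    ys = np.array(ys, float)
    grand = ys.mean()
    groups = list(values)
    t = len(values[groups[0]][0])
    n_subj = sum(len(v) for v in values.values())

    ss_total = ((ys - grand) ** 2).sum()
    subj_means = [np.mean(series) for v in values.values() for series in v]
    ss_subjects = t * sum((m - grand) ** 2 for m in subj_means)
    ss_group = sum(
        len(v) * t * (np.mean([x for s in v for x in s]) - grand) ** 2
        for v in values.values()
    )
    time_means = []
    for k in range(t):
        time_means.append(np.mean([s[k] for v in values.values() for s in v]))
    ss_time = n_subj * sum((m - grand) ** 2 for m in time_means)
    ss_cells = 0.0
    for g, v in values.items():
        for k in range(t):
            cell = np.mean([s[k] for s in v])
            ss_cells += len(v) * (cell - grand) ** 2
    ss_inter = ss_cells - ss_group - ss_time
    ss_error = ss_total - ss_subjects - ss_time - ss_inter
    df_inter = (len(groups) - 1) * (t - 1)
    df_error = (t - 1) * (n_subj - len(groups))
    return (ss_inter / df_inter) / (ss_error / df_error)


class TestMixedAnova:
    def test_null_interaction_by_construction(self):
        # identical time trajectories plus subject offsets
        traj = [10.0, 12.0, 9.0]
        values = {
            "A": [[x + off for x in traj] for off in (0.0, 1.0, -2.0, 0.5)],
            "B": [[x + off for x in traj] for off in (3.0, -1.0, 2.0, 0.0)],
        }
        res = mixed_anova_interaction(_long_table(values), "y")
        assert res.statistic < 1e-6

    def test_small_integer_design_matches_hand_computation(self):
        values = {
            "A": [[1, 2, 6], [2, 3, 5], [0, 1, 4]],
            "B": [[5, 4, 1], [6, 5, 2], [4, 6, 0]],
        }
        res = mixed_anova_interaction(_long_table(values), "y")
        assert res.statistic == pytest.approx(
            _brute_force_interaction_f(values), rel=1e-9
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(20)
        values = {
            "A": [list(rng.normal(0, 1, 3)) for _ in range(12)],
            "B": [list(rng.normal(0.5, 1, 3)) for _ in range(12)],
        }
        table = _long_table(values)
        res = mixed_anova_interaction(table, "y")
        aov = pingouin.mixed_anova(table, dv="y", within="timepoint",
                                   subject="subject", between="treatment")
        f_pg = float(aov.loc[aov["Source"] == "Interaction", "F"].iloc[0])
        assert res.statistic == pytest.approx(f_pg, rel=1e-9)
        assert res.df == (2.0, 44.0)

    def test_default_design_df(self):
        rng = np.random.default_rng(21)
        values = {
            "A": [list(rng.normal(size=3)) for _ in range(12)],
            "B": [list(rng.normal(size=3)) for _ in range(12)],
        }
        res = mixed_anova_interaction(_long_table(values), "y")
        assert res.df == (2.0, 44.0)

    def test_incomplete_subject_dropped(self):
        values = {
            "A": [[1, 2, 3], [2, 3, 4], [1, 1, 2], [0, 2, 1]],
            "B": [[3, 2, 1], [4, 3, 2], [2, 1, 1], [3, 3, 1]],
        }
        table = _long_table(values)
        table = table.drop(table[(table.subject == "A0")
                                 & (table.timepoint == "T2")].index)
        res = mixed_anova_interaction(table, "y")
        assert "dropped" in (res.note or "")
        assert res.n == (7,)


class TestSpearman:
    def test_monotone_increasing(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_correlation(x, [2, 4, 9, 16, 30]).statistic == 1.0

    def test_monotone_decreasing(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_correlation(x, [5, 4, 3, 2, 1]).statistic == -1.0

    def test_tie_handling_matches_midrank_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 5.0, 2.0]

        def midranks(v):
            v = np.asarray(v)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), float)
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        res = spearman_correlation(x, y)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidInputError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            spearman_correlation([1, 2, 3], [1, 2, 3])

    def test_p_matches_t_approximation(self):
        rng = np.random.default_rng(22)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = spearman_correlation(x, y)
        rho = res.statistic
        t_stat = rho * np.sqrt(18 / (1 - rho**2))
        expected_p = 2 * stats.t.sf(abs(t_stat), 18)
        assert res.p_value == pytest.approx(expected_p, rel=1e-9)


class TestChiSquare:
    def test_published_sex_contrast(self):
        res = chi_square_proportions(5, 7, 8, 4)
        assert round(res.p_value, 2) == 0.22

    def test_identical_proportions(self):
        res = chi_square_proportions(6, 6, 6, 6)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form(self):
        for a, b, c, d in itertools.product([1, 3, 8], repeat=4):
            n = a + b + c + d
            expected = (n * (a * d - b * c) ** 2
                        / ((a + b) * (c + d) * (a + c) * (b + d)))
            res = chi_square_proportions(a, b, c, d)
            assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidInputError):
            chi_square_proportions(0, 0, 3, 4)


class TestTrend:
    def test_positive_trend_detected(self):
        rng = np.random.default_rng(30)
        rows = []
        for s in range(10):
            slope = 1.0 + 0.05 * rng.normal()
            for t in range(3):
                rows.append({"subject": f"s{s}", "timepoint": f"T{t}",
                             "y": s + slope * t})
        res = within_subject_trend(pd.DataFrame(rows), "y")
        assert res.direction == 1.0
        assert res.p_value < 1e-6


class TestAnalyzeCohort:
    def _table(self, seed=0, n_per_arm=12, n_healthy=5):
        rng = np.random.default_rng(seed)
        rows = []
        sid = 0
        for arm in ("RAGT", "OW"):
            for _ in range(n_per_arm):
                sid += 1
                base = rng.normal(4000, 900)
                rti = rng.uniform(0.2, 1.0)
                for k, tp in enumerate(("T0", "T1", "T2")):
                    tot = base * (1 + 0.1 * k * (1 if arm == "OW" else -1))
                    maff = tot * 0.57
                    rows.append({
                        "subject": f"s{sid}", "cohort": "PwMS",
                        "treatment": arm, "timepoint": tp,
                        "tot_oxy_auc": tot, "maff_oxy_auc": maff,
                        "laff_oxy_auc": tot - maff,
                        "edss": rng.choice([6.0, 6.5, 7.0]),
                        "age": rng.normal(56, 10), "sex": rng.choice(["M", "F"]),
                        "phenotype": rng.choice(["primary progressive",
                                                 "secondary progressive"]),
                        "t25fw_speed": rng.uniform(0.3, 0.9),
                        "six_mwd": rng.uniform(60, 250),
                        "bbs": rng.integers(20, 50),
                        "rti": rti,
                        "rti_category": "high" if rti > 0.6 else "low",
                    })
        for _ in range(n_healthy):
            sid += 1
            tot = rng.normal(800, 100)
            rows.append({
                "subject": f"h{sid}", "cohort": "healthy", "treatment": "none",
                "timepoint": "T0", "tot_oxy_auc": tot,
                "maff_oxy_auc": tot * 0.55, "laff_oxy_auc": tot * 0.45,
                "edss": None, "age": rng.normal(50, 8),
                "sex": rng.choice(["M", "F"]), "phenotype": "none",
                "t25fw_speed": rng.uniform(1.0, 1.6),
                "six_mwd": rng.uniform(400, 600), "bbs": 56,
                "rti": None, "rti_category": None,
            })
        return pd.DataFrame(rows)

    def test_emits_all_families(self):
        report = analyze_cohort(self._table())
        names = [r["name"] for r in report["results"]]
        assert any("PwMS vs healthy" in n for n in names)
        assert any("age median split" in n for n in names)
        assert any("baseline Tot vs edss" in n for n in names)
        assert any("delta Tot: RAGT vs OW" in n for n in names)
        assert any("group x time" in n for n in names)
        assert any("RTI vs delta" in n for n in names)
        assert any("delta MAff vs delta" in n for n in names)
        assert any("baseline Tot vs delta T25FW" in n for n in names)
        assert report["n_tests"] == len(report["results"])

    def test_row_order_invariance(self):
        table = self._table(seed=1)
        shuffled = table.sample(frac=1.0, random_state=99).reset_index(drop=True)
        r1 = analyze_cohort(table)
        r2 = analyze_cohort(shuffled)
        p1 = {r["name"]: r["p_value"] for r in r1["results"]}
        p2 = {r["name"]: r["p_value"] for r in r2["results"]}
        assert p1.keys() == p2.keys()
        for name in p1:
            assert p1[name] == pytest.approx(p2[name], rel=1e-9), name

    def test_deterministic(self):
        table = self._table(seed=2)
        assert analyze_cohort(table) == analyze_cohort(table)

    def test_p_values_in_unit_interval(self):
        for r in analyze_cohort(self._table(seed=3))["results"]:
            assert 0.0 <= r["p_value"] <= 1.0

    def test_empty_table_schema_error(self):
        with pytest.raises(SchemaError):
            analyze_cohort(pd.DataFrame())

    def test_missing_columns_listed(self):
        with pytest.raises(SchemaError, match="tot_oxy_auc"):
            analyze_cohort(pd.DataFrame({"subject": ["a"], "timepoint": ["T0"]}))

    def test_duplicate_rows_rejected(self):
        table = self._table()
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(SchemaError):
            analyze_cohort(dup)
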