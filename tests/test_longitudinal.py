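"""GEE repeated-measures model and Bonferroni contrast machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbrqa.longitudinal import (
    bonferroni_pairwise,
    fit_gee,
    task_within_visit_contrasts,
)

VISITS = ("T1", "T2", "T3", "T4")
TASKS = ("rattle", "freeplay")


def balanced_table(seed=0, n_sub=20, effect=0.0, subject_sd=0.3, noise_sd=0.5):
    """Long-format measure table with an optional late-visit rattle effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        u = rng.normal(0, subject_sd)
        for vi, visit in enumerate(VISITS):
            for task in TASKS:
                bump = effect * (vi - 1) if task == "rattle" and vi >= 2 else 0.0
                rows.append(
                    {
                        "subject": f"S{s:02d}",
                        "visit": visit,
                        "task": task,
                        "ent": u + bump + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestFitGee:
    def test_term_degrees_of_freedom(self):
        fit = fit_gee(balanced_table(), "ent")
        assert fit.wald["task"][1] == 1
        assert fit.wald["visit"][1] == 3
        assert fit.wald["task:visit"][1] == 3

    def test_detects_strong_interaction(self):
        fit = fit_gee(balanced_table(seed=1, effect=1.0), "ent")
        assert fit.wald["task:visit"][2] < 0.001

    def test_no_repeats_matches_ols_robust_wald(self):
        # one observation per subject: GEE clustering is vacuous and the
        # sandwich Wald tests collapse to OLS heteroskedasticity-robust ones
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        rows = [
            {
                "subject": f"P{i}",
                "visit": VISITS[rng.integers(4)],
                "task": TASKS[rng.integers(2)],
                "ent": rng.normal(),
            }
            for i in range(120)
        ]
        table = pd.DataFrame(rows)
        fit = fit_gee(table, "ent", cov_type="robust", df_correction=False)
        data = table.copy()
        data["task"] = pd.Categorical(data["task"], categories=TASKS)
        data["visit"] = pd.Categorical(data["visit"], categories=VISITS, ordered=True)
        ols = smf.ols("ent ~ C(task)*C(visit)", data).fit(cov_type="HC0")
        ref = ols.wald_test_terms(scalar=True).table
        for label, term in [
            ("C(task)", "task"),
            ("C(visit)", "visit"),
            ("C(task):C(visit)", "task:visit"),
        ]:
            assert fit.wald[term][0] == pytest.approx(
                float(ref.loc[label, "statistic"]), rel=1e-8
            )

    def test_independence_correlation_matches_ols_coefficients(self):
        import statsmodels.formula.api as smf

        table = balanced_table(seed=4)
        fit = fit_gee(table, "ent", working_correlation="independence")
        data = table.copy()
        data["task"] = pd.Categorical(data["task"], categories=TASKS)
        data["visit"] = pd.Categorical(data["visit"], categories=VISITS, ordered=True)
        ols = smf.ols("ent ~ C(task)*C(visit)", data).fit()
        cell_ols = ols.predict(
            pd.DataFrame([(t, v) for t in TASKS for v in VISITS], columns=["task", "visit"])
        )
        np.testing.assert_allclose(fit.cell_means["mean"], cell_ols, rtol=1e-8)

    def test_partial_subjects_are_retained(self):
        table = balanced_table(seed=5)
        partial = table[
            ~((table.subject == "S00") & (table.visit == "T4"))
        ].reset_index(drop=True)
        fit = fit_gee(partial, "ent")
        assert fit.n_subjects == 20
        assert fit.n_obs == len(partial)

    def test_dropping_a_subject_changes_estimates(self):
        table = balanced_table(seed=6)
        full = fit_gee(table, "ent")
        reduced = fit_gee(table[table.subject != "S00"], "ent")
        assert reduced.n_subjects == 19
        assert not np.allclose(full.cell_means["mean"], reduced.cell_means["mean"])

    def test_single_task_rejected(self):
        table = balanced_table()
        with pytest.raises(ValueError, match="both tasks"):
            fit_gee(table[table.task == "rattle"], "ent")

    def test_fewer_than_two_subjects_rejected(self):
        table = balanced_table()
        with pytest.raises(ValueError, match="2 subjects"):
            fit_gee(table[table.subject == "S00"], "ent")


class TestBonferroniPairwise:
    def test_full_family_has_28_pairs(self):
        fit = fit_gee(balanced_table(seed=7), "ent")
        table = bonferroni_pairwise(fit)
        assert len(table) == 28
        assert table["estimable"].all()

    def test_adjustment_is_multiplicative_and_capped(self):
        fit = fit_gee(balanced_table(seed=8), "ent")
        table = bonferroni_pairwise(fit)
        expected = np.minimum(1.0, 28 * table["p_raw"])
        np.testing.assert_allclose(table["p_bonferroni"], expected)

    def test_family_of_one_leaves_p_unchanged(self):
        fit = fit_gee(balanced_table(seed=9), "ent")
        single = bonferroni_pairwise(fit, family=[(0, 4)])
        assert single.loc[0, "p_bonferroni"] == pytest.approx(single.loc[0, "p_raw"])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=10).map(sorted))
    def test_adjusted_p_monotone_in_raw_p(self, raws):
        adjusted = [min(1.0, 28 * p) for p in raws]
        assert all(a <= b for a, b in zip(adjusted, adjusted[1:]))
        assert all(a >= r for a, r in zip(adjusted, raws))

    def test_empty_cell_contrasts_flagged_not_dropped(self):
        table = balanced_table(seed=10)
        table = table[~((table.task == "rattle") & (table.visit == "T4"))]
        fit = fit_gee(table, "ent")
        contrasts = bonferroni_pairwise(fit)
        assert len(contrasts) == 28
        flagged = contrasts[~contrasts["estimable"]]
        assert len(flagged) == 7  # every pair touching the empty cell
        assert flagged["p_bonferroni"].isna().all()

    def test_task_within_visit_view_detects_late_effect(self):
        fit = fit_gee(balanced_table(seed=11, effect=1.2, n_sub=26), "ent")
        tw = task_within_visit_contrasts(fit).set_index("visit")["p_bonferroni"]
        assert tw["T3"] < 0.05 and tw["T4"] < 0.05
        assert tw["T1"] > 0.05 and tw["T2"] > 0.05
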