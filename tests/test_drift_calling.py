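"""Covariate screen, ANCOVA, criterion arithmetic and the full decision rule."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methdrift as md
from methdrift.drift import _design_matrices, _partial_f_rows, _welch_rows

from conftest import called_set, make_cohort, planted_grade_set

GRADES15 = ["III", "III", "IV", "IV", "V", "VI"] + ["VII"] * 9


def test_covariate_screen_constant_delta_passes():
    cohort = make_cohort(GRADES15)
    p_age, p_sex, p_pmt, passed = md.covariate_screen(np.full(15, 0.3), cohort)
    assert (p_age, p_sex, p_pmt) == (1.0, 1.0, 1.0)
    assert passed


def test_covariate_screen_flags_age_tracking_delta():
    cohort = make_cohort(GRADES15)
    age = cohort.covariates()["age"].to_numpy()
    delta = (age - age.mean()) / age.std()
    p_age, _, _, passed = md.covariate_screen(delta, cohort)
    # oracle: the same Spearman machinery applied to (delta, age)
    rho_oracle, p_oracle = md.spearman_grade(delta, age)
    assert p_age == pytest.approx(p_oracle, abs=1e-12)
    assert p_age < 0.05 and not passed


def test_covariate_screen_single_sex_cohort_warns_and_passes_sex():
    cohort = make_cohort(["III", "IV", "V", "VII"], sexes=["M"] * 4)
    with pytest.warns(UserWarning, match="sex"):
        _, p_sex, _, _ = md.covariate_screen(np.array([0.1, 0.5, 0.2, 0.9]), cohort)
    assert p_sex == 1.0


def test_ancova_noiseless_grade_effect_is_certain():
    cohort = make_cohort(GRADES15)
    grades = cohort.grades().to_numpy(dtype=float)
    delta = 0.5 * (grades - 3.0)
    p = md.ancova_grade(delta, grades, cohort)
    assert p < 1e-6


def test_ancova_pure_age_effect_is_usually_absorbed():
    """ΔM = standardized age exactly: over seeded cohorts the grade factor's
    partial F should not look significant in the median."""
    ps = []
    rng = np.random.default_rng(0)
    for _ in range(200):
        ages = rng.uniform(45, 90, 15)
        cohort = make_cohort(GRADES15, ages=ages)
        delta = (ages - ages.mean()) / ages.std()
        ps.append(md.ancova_grade(delta, cohort.grades().to_numpy(), cohort))
    assert np.median(ps) > 0.05


def test_ancova_type_i_calibration():
    cohort = make_cohort(GRADES15)
    grades = cohort.grades().to_numpy(dtype=float)
    rng = np.random.default_rng(1)
    delta = rng.normal(size=(1000, 15))
    full, reduced = _design_matrices(cohort, grade_as_numeric=False)
    p = _partial_f_rows(delta, full, reduced)
    assert 0.03 <= (p < 0.05).mean() <= 0.07


def test_ancova_agrees_with_statsmodels():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    cohort = make_cohort(GRADES15)
    cov = cohort.covariates()
    rng = np.random.default_rng(2)
    grades = cohort.grades().to_numpy(dtype=float)
    for _ in range(5):
        delta = rng.normal(size=15) + 0.2 * grades
        p_mine = md.ancova_grade(delta, grades, cohort)
        frame = pd.DataFrame(
            {"y": delta, "grade": grades, "age": cov["age"], "sex": cov["sex"], "pmt": cov["pmt"]}
        )
        fit = ols("y ~ C(grade) + age + sex + pmt", frame).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert p_mine == pytest.approx(table.loc["C(grade)", "PR(>F)"], rel=1e-8)


def test_ancova_numeric_grade_switch():
    cohort = make_cohort(GRADES15)
    grades = cohort.grades().to_numpy(dtype=float)
    delta = 0.3 * grades + np.random.default_rng(3).normal(scale=0.1, size=15)
    p_cat = md.ancova_grade(delta, grades, cohort, grade_as_numeric=False)
    p_num = md.ancova_grade(delta, grades, cohort, grade_as_numeric=True)
    assert p_cat < 0.05 and p_num < 0.05 and p_num != p_cat


@pytest.mark.parametrize(
    "d3, d7, effect, passed",
    [
        ([0.00, 0.02], [0.10, 0.06], 0.07, True),
        ([0.05, 0.05], [0.05, 0.05], 0.0, False),
        ([0.0, 0.0], [0.05, 0.05], 0.05, False),  # boundary: strict >
    ],
)
def test_extreme_grade_effect_arithmetic(d3, d7, effect, passed):
    delta = np.array(d3 + d7)
    grades = np.array([3] * len(d3) + [7] * len(d7), dtype=float)
    m3, m7, eff, ok = md.extreme_grade_effect(delta, grades, threshold=0.05)
    assert eff == pytest.approx(effect, abs=1e-12)
    assert ok is passed


def test_extreme_grade_effect_requires_both_extremes():
    with pytest.raises(md.ValidationError, match="inapplicable"):
        md.extreme_grade_effect([0.1, 0.2], np.array([4.0, 7.0]), 0.05)


def test_welch_stability_closed_form_oracle():
    a = np.array([[0.0, 0.0, 0.01]])
    b = np.array([[3.0, 3.0, 3.01]])
    p = _welch_rows(a, b)[0]
    # closed-form Welch statistic
    va, vb = a.var(ddof=1), b.var(ddof=1)
    t = (a.mean() - b.mean()) / np.sqrt(va / 3 + vb / 3)
    df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
    p_oracle = 2 * stats.t.sf(abs(t), df)
    assert p == pytest.approx(p_oracle, rel=1e-10)
    assert p < 0.01


def test_welch_equal_groups_pass():
    a = np.array([[0.1, 0.2, 0.3]])
    p = _welch_rows(a, a.copy())[0]
    assert p == pytest.approx(1.0)


def test_stability_single_extreme_donor_is_indeterminate_pass():
    cohort = make_cohort(["III", "V", "VII", "VII"])
    n_m = pd.DataFrame(np.zeros((2, 4)), index=["cg1", "cg2"], columns=cohort.donors)
    with pytest.warns(UserWarning, match="indeterminate"):
        p, ok = md.n_sample_stability(n_m, cohort)
    assert np.isnan(p).all() and ok.all()


# ---------------------------------------------------------------------------
# The full decision rule on constructed zero-noise cohorts


def _noiseless(class_counts, n_probes=200, seed=11):
    cfg = md.GeneratorConfig(seed=seed, n_probes=n_probes, noise_sd_m=0.0,
                             class_counts=class_counts)
    return md.generate_cohort_data(cfg)


def test_single_planted_probe_called_with_direction():
    cohort, beta, ann, bl, truth = _noiseless({"grade_hyper": 1})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, _ = md.call_grade_cpgs(beta, cohort, ann, bl, md.AnalysisConfig())
    called = called_set(records)
    assert called == planted_grade_set(truth)
    probe = next(iter(called))
    assert records.loc[probe, "direction"] == "hyper"
    assert records.loc[probe, "rho"] > 0


def test_blacklisted_planted_probe_is_never_called():
    cohort, beta, ann, bl, truth = _noiseless({"blacklisted": 1})
    assert len(bl) == 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, attrition = md.call_grade_cpgs(beta, cohort, ann, bl, md.AnalysisConfig())
    assert called_set(records) == set()
    assert attrition["blacklisted"] == 1
    assert attrition["tested"] == attrition["input"] - 1


def test_unstable_probe_rejected_by_stability_criterion():
    cohort, beta, ann, bl, truth = _noiseless({"unstable_N": 3})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, _ = md.call_grade_cpgs(beta, cohort, ann, bl, md.AnalysisConfig())
    unstable = truth.index[truth["class"] == "unstable_N"]
    assert not records.loc[unstable, "crit3_stability"].any()
    assert called_set(records) == set()


def test_attrition_accounting(recovery_sim):
    att = recovery_sim["attrition"]
    assert att["tested"] == att["input"] - att["blacklisted"] - att["missing_dropped"]
    assert len(recovery_sim["records"]) == att["tested"]


def test_direction_partition(recovery_sim):
    records = recovery_sim["records"]
    called = records[records["is_grade_cpg"]]
    n_hyper = (called["direction"] == "hyper").sum()
    n_hypo = (called["direction"] == "hypo").sum()
    assert n_hyper + n_hypo == len(called)
    assert ((called["direction"] == "hyper") == (called["rho"] > 0)).all()


def test_summarize_calls_arithmetic():
    ann = md.AnnotationTable([
        md.ProbeAnnotation("cg1", "chr1", 10, (("LPL", "Body"),), "OpenSea"),
        md.ProbeAnnotation("cg2", "chr1", 20, (("LPL", "TSS200"),), "Island"),
        md.ProbeAnnotation("cg3", "chr1", 30, (("ESR1", "Body"),), "Shore"),
    ])
    rows = []
    for i, (pid, direction, called) in enumerate(
        [("cg1", "hyper", True), ("cg2", "hyper", True), ("cg3", "hypo", False)]
    ):
        rows.append({
            "probe_id": pid, "rho": 0.5 if direction == "hyper" else -0.5,
            "direction": direction, "is_grade_cpg": called, "extreme_effect": 0.1 * (i + 1),
        })
    records = pd.DataFrame(rows).set_index("probe_id")
    summary = md.summarize_calls(records, ann)
    assert summary["n_called"] == 2
    assert summary["n_genes"] == 1  # both called probes on LPL
    assert summary["pct_hyper"] == 100.0
    assert summary["mean_extreme_effect"] == pytest.approx(0.15)


def test_no_calls_summary_is_zero():
    ann = md.AnnotationTable([])
    records = pd.DataFrame(
        columns=["rho", "direction", "is_grade_cpg", "extreme_effect"]
    ).astype({"is_grade_cpg": bool})
    summary = md.summarize_calls(records, ann)
    assert summary["n_called"] == 0 and summary["n_genes"] == 0


def test_bonferroni_threshold_reporting():
    assert md.bonferroni_threshold(485_512, 0.05) == pytest.approx(1.0298e-7, rel=1e-3)
    with pytest.raises(md.ValidationError):
        md.bonferroni_threshold(0)
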