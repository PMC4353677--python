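"""Per-probe drift statistics and the three-criterion grade-CpG decision rule.

A probe is a grade-CpG when, within donor-matched lesion/normal (A/N) pairs:

1. the average intra-pair ΔBeta differs by more than ``effect_delta_beta``
   (strictly) between the extreme histological grades (VII vs III);
2. the intra-pair ΔM rank-correlates with numeric grade (Spearman p < alpha),
   does NOT rank-correlate with donor age, sex or post-mortem time, and the
   grade effect survives an ANCOVA with those covariates (partial F p < alpha);
3. the normal-tissue M values are stable across the extreme grades (Welch
   p >= alpha), excluding probes whose apparent drift reflects baseline
   instability of the normal aorta rather than the lesion.

Statistics are computed on the M (logit-Beta) scale, where array noise is
closer to homoscedastic; effect sizes are reported on the Beta scale.
All per-probe screens are vectorised over the probe axis.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    GRADE_ROMAN_TO_INT,
    AnalysisConfig,
    AnnotationTable,
    BetaMatrix,
    Cohort,
    ValidationError,
)

log = logging.getLogger(__name__)

LN2 = math.log(2.0)


def beta_to_m(beta, epsilon_clip: float = 1e-6):
    """Base-2 logit transform: M = log2(beta / (1 - beta)), Beta clamped
    symmetrically to [epsilon_clip, 1 - epsilon_clip]."""
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("Beta values must lie in [0, 1]")
    b = np.clip(arr, epsilon_clip, 1 - epsilon_clip)
    out = np.log2(b / (1 - b))
    return out if arr.ndim else float(out)


def m_to_beta(m):
    """Inverse logit: Beta = 2^M / (1 + 2^M); exact inverse away from the clamp."""
    arr = np.asarray(m, dtype=float)
    from scipy.special import expit

    out = expit(arr * LN2)
    return out if arr.ndim else float(out)


def grade_to_numeral(label: str) -> int:
    """Roman AHA grade III-VII -> integer 3-7."""
    try:
        return GRADE_ROMAN_TO_INT[label]
    except KeyError:
        raise ValidationError(f"grade {label!r} outside supported range III-VII") from None


@dataclass
class DeltaMatrix:
    """Intra-pair (A - N) differences, probes x donors, on the M or Beta scale."""

    values: pd.DataFrame  # index probes, columns donor ids
    scale: str  # "M" or "Beta"

    def __post_init__(self) -> None:
        if self.scale not in ("M", "Beta"):
            raise ValidationError(f"unknown delta scale {self.scale!r}")


def intra_pair_delta(matrix: BetaMatrix, cohort: Cohort, scale: str = "M",
                     epsilon_clip: float = 1e-6) -> DeltaMatrix:
    """A-minus-N difference per probe per donor, on the requested scale."""
    for donor, (a_id, n_id) in cohort.pairing.items():
        for sid in (a_id, n_id):
            if sid not in matrix.sample_ids:
                raise ValidationError(f"donor {donor}: sample {sid} missing from Beta matrix")
    a = matrix.values[cohort.a_sample_ids()].to_numpy(dtype=float)
    n = matrix.values[cohort.n_sample_ids()].to_numpy(dtype=float)
    if scale == "M":
        delta = beta_to_m(a, epsilon_clip) - beta_to_m(n, epsilon_clip)
    elif scale == "Beta":
        delta = a - n
    else:
        raise ValidationError(f"unknown delta scale {scale!r}")
    return DeltaMatrix(pd.DataFrame(delta, index=matrix.probe_ids, columns=cohort.donors), scale)


# ---------------------------------------------------------------------------
# Spearman screen


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of 2-D x against 1-D y; constant rows -> 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r[denom == 0] = 0.0
    return np.clip(r, -1.0, 1.0)


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t approximation t = rho*sqrt((n-2)/(1-rho^2))."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1 - rho ** 2, 0.0))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(rho == 0.0, 1.0, p)
    return p


def _exact_permutation_p(delta: np.ndarray, grades: np.ndarray) -> float:
    """Exact two-sided permutation p for Spearman rho (all n! grade orders)."""
    n = len(delta)
    rd = _midrank(delta)
    rg = _midrank(grades)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    permuted = rg[perms]  # (n!, n)
    rho_perm = _pearson_rows(permuted, rd)
    rho_obs = float(_pearson_rows(rg[None, :], rd)[0])
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


EXACT_PERMUTATION_MAX_N = 9


def spearman_grade(delta_row, grades) -> tuple[float, float]:
    """Tie-corrected Spearman rho of intra-pair ΔM against numeric grade.

    Two-sided p by exact permutation when n <= 9 and the delta row is
    tie-free, otherwise by the t approximation. A constant delta row has no
    rank order and is reported as (rho=0, p=1).
    """
    delta = np.asarray(delta_row, dtype=float)
    g = np.asarray(grades, dtype=float)
    n = len(delta)
    if n < 4:
        raise ValidationError(f"Spearman screen needs >= 4 donors, got {n}")
    if np.ptp(g) == 0:
        raise ValidationError("correlation with grade undefined: all grades equal")
    if np.ptp(delta) == 0:
        return 0.0, 1.0
    rho = float(_pearson_rows(_midrank(delta)[None, :], _midrank(g))[0])
    tie_free = len(np.unique(delta)) == n
    if n <= EXACT_PERMUTATION_MAX_N and tie_free:
        p = _exact_permutation_p(delta, g)
    else:
        p = float(_t_approx_p(np.array([rho]), n)[0])
    return rho, p


def spearman_matrix(delta: np.ndarray, covariate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised tie-corrected Spearman of each delta row against one covariate.

    Uses the t approximation for p (the cohort sizes this pipeline targets
    exceed the exact-permutation regime); constant rows -> (0, 1).
    """
    n = delta.shape[1]
    ranks = _midrank(delta)
    rho = _pearson_rows(ranks, _midrank(covariate))
    return rho, _t_approx_p(rho, n)


# ---------------------------------------------------------------------------
# Covariate screen


def covariate_screen(delta_row, cohort: Cohort, alpha: float = 0.05) -> tuple[float, float, float, bool]:
    """Spearman of ΔM against age, sex (M=0/F=1) and post-mortem time.

    Passes iff all three p >= alpha. A constant covariate (e.g. a single-sex
    cohort) has an undefined correlation and is counted as non-significant
    (p = 1) with a warning.
    """
    cov = cohort.covariates()
    if cov.isna().any().any():
        raise ValidationError("missing covariate value in cohort")
    delta = np.asarray(delta_row, dtype=float)[None, :]
    ps = {}
    for name in ("age", "sex", "pmt"):
        values = cov[name].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            warnings.warn(f"covariate {name!r} is constant; correlation undefined, p set to 1")
            ps[name] = 1.0
        else:
            ps[name] = float(spearman_matrix(delta, values)[1][0])
    passed = all(p >= alpha for p in ps.values())
    return ps["age"], ps["sex"], ps["pmt"], passed


def _covariate_p_matrix(delta: np.ndarray, cohort: Cohort) -> dict[str, np.ndarray]:
    cov = cohort.covariates()
    if cov.isna().any().any():
        raise ValidationError("missing covariate value in cohort")
    out = {}
    for name in ("age", "sex", "pmt"):
        values = cov[name].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            warnings.warn(f"covariate {name!r} is constant; correlation undefined, p set to 1")
            out[name] = np.ones(delta.shape[0])
        else:
            out[name] = spearman_matrix(delta, values)[1]
    return out


# ---------------------------------------------------------------------------
# ANCOVA corroboration


def _design_matrices(cohort: Cohort, grade_as_numeric: bool) -> tuple[np.ndarray, np.ndarray]:
    """(full, reduced) design matrices; reduced omits the grade term.

    Constant covariate columns are dropped with a warning (they are collinear
    with the intercept; cf. the covariate screen's handling).
    """
    g = cohort.grades().to_numpy(dtype=float)
    cov = cohort.covariates().to_numpy(dtype=float)
    keep = np.ptp(cov, axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(("age", "sex", "pmt"), keep) if not k]
        warnings.warn(f"constant covariate(s) {dropped} dropped from ANCOVA design")
    cov = cov[:, keep]
    intercept = np.ones((len(g), 1))
    reduced = np.hstack([intercept, cov])
    if grade_as_numeric:
        grade_cols = g[:, None]
    else:
        levels = np.unique(g)
        grade_cols = (g[:, None] == levels[1:][None, :]).astype(float)  # treatment coding
    full = np.hstack([reduced, grade_cols])
    return full, reduced


def _partial_f_rows(Y: np.ndarray, full: np.ndarray, reduced: np.ndarray) -> np.ndarray:
    """Partial F-test p for the terms in `full` beyond `reduced`, per row of Y."""
    n = full.shape[0]
    rank_full = np.linalg.matrix_rank(full)
    rank_red = np.linalg.matrix_rank(reduced)
    if rank_full < full.shape[1]:
        raise ValidationError(
            f"ANCOVA design matrix rank-deficient (rank {rank_full} < {full.shape[1]} columns)"
        )
    q = rank_full - rank_red
    df2 = n - rank_full
    if df2 < 1:
        raise ValidationError("ANCOVA: no residual degrees of freedom")
    Qf, _ = np.linalg.qr(full)
    Qr, _ = np.linalg.qr(reduced)
    fit_f = (Y @ Qf) @ Qf.T
    fit_r = (Y @ Qr) @ Qr.T
    rss_f = ((Y - fit_f) ** 2).sum(axis=1)
    rss_r = ((Y - fit_r) ** 2).sum(axis=1)
    # numerical floor: a perfect fit yields F -> inf, p -> 0
    scale = np.maximum((Y ** 2).sum(axis=1), 1.0)
    rss_f = np.maximum(rss_f, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_r - rss_f) / q) / (rss_f / df2)
    F = np.where(rss_f <= 1e-14 * scale, np.inf, F)
    p = stats.f.sf(F, q, df2)
    p = np.where(np.isinf(F), 0.0, p)
    # a response orthogonal to everything (constant row) carries no grade signal
    p = np.where(rss_r <= 1e-14 * scale, 1.0, p)
    return p


def ancova_grade(delta_row, grades, cohort: Cohort, alpha: float = 0.05,
                 grade_as_numeric: bool = False) -> float:
    """Partial F-test p for grade in ΔM ~ grade + age + sex + pmt.

    Grade enters as a categorical factor by default (``grade_as_numeric``
    switches to a 1-df linear term).
    """
    del grades  # grade is taken from the cohort to keep designs consistent
    full, reduced = _design_matrices(cohort, grade_as_numeric)
    y = np.asarray(delta_row, dtype=float)[None, :]
    return float(_partial_f_rows(y, full, reduced)[0])


# ---------------------------------------------------------------------------
# Criterion 1 and 3 helpers


def extreme_grade_effect(delta_beta_row, grades, threshold: float = 0.05
                         ) -> tuple[float, float, float, bool]:
    """|mean ΔBeta at grade VII - mean ΔBeta at grade III|, strict threshold."""
    delta = np.asarray(delta_beta_row, dtype=float)
    g = np.asarray(grades, dtype=float)
    if not (np.any(g == 3) and np.any(g == 7)):
        raise ValidationError("extreme-grade criterion inapplicable: grade III or VII absent")
    mean3 = float(delta[g == 3].mean())
    mean7 = float(delta[g == 7].mean())
    effect = abs(mean7 - mean3)
    return mean3, mean7, effect, effect > threshold


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sample t-test p; degenerate zero-variance rows get
    p = 1 (equal means) or p = 0 (different means)."""
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical rows (saturated probes) trigger scipy's precision
        # warning; the degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # ptp, not var: summation rounding leaves ~1e-31 variance on constant rows
    var0 = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(var0 & equal, 1.0, p)
    p = np.where(var0 & ~equal, 0.0, p)
    return p


def n_sample_stability(n_sample_m: pd.DataFrame, cohort: Cohort, alpha: float = 0.05
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Criterion 3: Welch t between grade-VII and grade-III N-sample M values.

    ``n_sample_m`` is probes x donors (columns = donor ids, values = the
    donor's N-sample M). If either extreme-grade group has fewer than two
    donors the criterion is indeterminate: p = NaN, pass = True, warning.
    """
    g = cohort.grades()
    d7 = [d for d in cohort.donors if g[d] == 7]
    d3 = [d for d in cohort.donors if g[d] == 3]
    n_probes = len(n_sample_m)
    if len(d7) < 2 or len(d3) < 2:
        warnings.warn(
            "N-sample stability criterion skipped: fewer than 2 donors in an "
            "extreme-grade group; recorded as indeterminate-pass"
        )
        return np.full(n_probes, np.nan), np.ones(n_probes, dtype=bool)
    p = _welch_rows(n_sample_m[d7].to_numpy(dtype=float), n_sample_m[d3].to_numpy(dtype=float))
    return p, p >= alpha


def bonferroni_threshold(n_tested: int, base_alpha: float = 0.05) -> float:
    """Study-wide per-probe significance threshold: base_alpha / n_tested."""
    if n_tested < 1:
        raise ValidationError("n_tested must be >= 1")
    return base_alpha / n_tested


# ---------------------------------------------------------------------------
# The decision rule


def call_grade_cpgs(beta: BetaMatrix, cohort: Cohort, annotation: AnnotationTable,
                    blacklist=(), config: AnalysisConfig | None = None
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the full grade-CpG decision rule to every tested probe.

    Returns ``(records, attrition)``: a per-probe results frame (indexed by
    probe id; see :data:`methdrift.io.RESULTS_COLUMNS`) and the probe
    attrition counts at each filter. The frame's attrs carry the Bonferroni
    threshold (``bonferroni_base_alpha / n_tested``) and the count of probes
    below it.
    """
    config = config or AnalysisConfig()
    n_input = len(beta.probe_ids)
    blacklist = set(blacklist)
    kept = beta.values.loc[~beta.probe_ids.isin(blacklist)]
    n_blacklisted = n_input - len(kept)
    complete, n_missing = BetaMatrix(kept).drop_incomplete_probes()
    values = complete.values
    n_tested = len(values)
    attrition = {
        "input": n_input,
        "blacklisted": n_blacklisted,
        "missing_dropped": n_missing,
        "tested": n_tested,
    }
    log.info("call_grade_cpgs: %(input)d probes in, %(blacklisted)d blacklisted, "
             "%(missing_dropped)d dropped for missing values, %(tested)d tested", attrition)

    grades = cohort.grades().to_numpy(dtype=float)
    a_beta = values[cohort.a_sample_ids()].to_numpy(dtype=float)
    n_beta = values[cohort.n_sample_ids()].to_numpy(dtype=float)
    a_m = beta_to_m(a_beta, config.epsilon_clip)
    n_m = beta_to_m(n_beta, config.epsilon_clip)
    d_m = a_m - n_m
    d_beta = a_beta - n_beta

    rho, p_grade = spearman_matrix(d_m, grades)
    cov_p = _covariate_p_matrix(d_m, cohort)
    cov_pass = (cov_p["age"] >= config.alpha) & (cov_p["sex"] >= config.alpha) & (cov_p["pmt"] >= config.alpha)

    full, reduced = _design_matrices(cohort, config.grade_as_numeric)
    p_ancova = _partial_f_rows(d_m, full, reduced)

    mask3, mask7 = grades == 3, grades == 7
    if not (mask3.any() and mask7.any()):
        raise ValidationError("extreme-grade criterion inapplicable: grade III or VII absent")
    mean3 = d_beta[:, mask3].mean(axis=1)
    mean7 = d_beta[:, mask7].mean(axis=1)
    effect = np.abs(mean7 - mean3)
    crit1 = effect > config.effect_delta_beta

    n_m_frame = pd.DataFrame(n_m, index=values.index, columns=cohort.donors)
    p_stab, crit3 = n_sample_stability(n_m_frame, cohort, config.alpha)

    crit2_grade = p_grade < config.alpha
    crit2_anc = p_ancova < config.alpha
    is_grade_cpg = crit1 & crit2_grade & cov_pass & crit2_anc & crit3

    records = pd.DataFrame(
        {
            "rho": rho,
            "p_grade": p_grade,
            "p_age": cov_p["age"],
            "p_sex": cov_p["sex"],
            "p_pmt": cov_p["pmt"],
            "p_ancova": p_ancova,
            "mean_dbeta_grade3": mean3,
            "mean_dbeta_grade7": mean7,
            "extreme_effect": effect,
            "p_n_stability": p_stab,
            "crit1_effect": crit1,
            "crit2_grade": crit2_grade,
            "crit2_covariates": cov_pass,
            "crit2_ancova": crit2_anc,
            "crit3_stability": crit3,
            "direction": np.where(rho > 0, "hyper", "hypo"),
            "is_grade_cpg": is_grade_cpg,
        },
        index=values.index,
    )
    records.index.name = "probe_id"
    threshold = bonferroni_threshold(max(n_tested, 1), config.bonferroni_base_alpha)
    records.attrs["bonferroni_threshold"] = threshold
    records.attrs["n_bonferroni_survivors"] = int((p_grade < threshold).sum())
    records.attrs["attrition"] = attrition
    return records, attrition


def summarize_calls(records: pd.DataFrame, annotation: AnnotationTable) -> dict:
    """Headline summary of a call set: counts, genes, direction, effect sizes.

    Gene tally counts each unique symbol once across all its probes.
    """
    called = records[records["is_grade_cpg"]]
    genes: set[str] = set()
    for probe_id in called.index:
        if probe_id in annotation:
            genes.update(annotation[probe_id].gene_symbols)
    n_called = len(called)
    n_hyper = int((called["direction"] == "hyper").sum())
    effects = called["extreme_effect"]
    return {
        "n_tested": len(records),
        "n_called": n_called,
        "n_genes": len(genes),
        "n_hyper": n_hyper,
        "n_hypo": n_called - n_hyper,
        "pct_hyper": 100.0 * n_hyper / n_called if n_called else 0.0,
        "mean_extreme_effect": float(effects.mean()) if n_called else 0.0,
        "min_extreme_effect": float(effects.min()) if n_called else 0.0,
        "max_extreme_effect": float(effects.max()) if n_called else 0.0,
        "bonferroni_threshold": records.attrs.get("bonferroni_threshold", np.nan),
        "n_bonferroni_survivors": records.attrs.get("n_bonferroni_survivors", 0),
    }
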