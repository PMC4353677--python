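"""Synthetic paired-methylation cohorts with planted ground truth.

The generator emulates a 15-donor aortic cohort measured on a 450k-style
array: donor-matched lesion (A) and normal (N) samples, AHA grades III-VII
with most donors at grade VII, trimodal baseline methylation, and additive
logit-normal noise. Probe classes plant the signals the decision rule must
separate:

* ``grade_hyper`` / ``grade_hypo`` — intra-pair ΔM grows linearly with
  numeric grade, scaled so the Beta-scale A-N difference at grade VII is
  ±``drift_amplitude_beta``;
* ``dm_constant`` — grade-independent differential methylation (a constant
  Beta offset), the previously described severity-independent class;
* ``confound_age`` / ``confound_sex`` / ``confound_pmt`` — ΔM coupled to a
  donor covariate with grade-drift-sized amplitude;
* ``unstable_N`` — grade drift plus a normal-tissue baseline that itself
  shifts with grade (criterion-3 bait);
* ``blacklisted`` — grade drift on probes listed in the SNP blacklist;
* ``null`` — noise only (the remainder).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .drift import beta_to_m, m_to_beta
from .model import (
    GRADE_ROMAN_TO_INT,
    AnnotationTable,
    BetaMatrix,
    Cohort,
    DETable,
    ProbeAnnotation,
    Sample,
    ValidationError,
)

PROBE_CLASSES = (
    "null", "grade_hyper", "grade_hypo", "dm_constant",
    "confound_age", "confound_sex", "confound_pmt", "unstable_N", "blacklisted",
)

#: Compartment proportions loosely matching the 450k design (single gene entry
#: per annotated probe; ``None`` = intergenic).
DEFAULT_COMPARTMENT_PROPS = {
    None: 0.20, "TSS1500": 0.12, "TSS200": 0.10, "UTR5": 0.08,
    "FirstExon": 0.08, "Body": 0.37, "UTR3": 0.05,
}
DEFAULT_CGI_PROPS = {"Island": 0.31, "Shore": 0.23, "Shelf": 0.10, "OpenSea": 0.36}


def _default_grade_counts() -> dict[str, int]:
    return {"III": 2, "IV": 2, "V": 1, "VI": 1, "VII": 9}


def _default_class_counts() -> dict[str, int]:
    return {
        "grade_hyper": 100, "grade_hypo": 100, "dm_constant": 200,
        "confound_age": 100, "confound_sex": 100, "confound_pmt": 100,
        "unstable_N": 100, "blacklisted": 0,
    }


@dataclass
class BaselineMix:
    """Trimodal per-probe baseline on the M scale (mass near Beta 0.1/0.5/0.9)."""

    weights: tuple[float, float, float] = (0.3, 0.4, 0.3)
    means_m: tuple[float, float, float] = (-3.2, 0.0, 3.2)
    sds_m: tuple[float, float, float] = (0.8, 1.2, 0.8)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        comp = rng.choice(3, size=size, p=np.asarray(self.weights) / sum(self.weights))
        return rng.normal(np.asarray(self.means_m)[comp], np.asarray(self.sds_m)[comp])


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    noise_sd_m is the per-measurement M-scale noise SD; the default 0.173
    corresponds to a Beta-scale SD of about 0.03 near Beta = 0.5
    (dBeta/dM = ln2 * Beta(1-Beta) = 0.173 at the midpoint).
    """

    n_probes: int = 10_000
    grade_counts: dict[str, int] = field(default_factory=_default_grade_counts)
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    drift_amplitude_beta: float = 0.15
    dm_offset_beta: float = 0.10
    unstable_shift_m_factor: float = 2.0
    noise_sd_m: float = 0.173
    baseline_mix: BaselineMix = field(default_factory=BaselineMix)
    compartment_props: dict = field(default_factory=lambda: dict(DEFAULT_COMPARTMENT_PROPS))
    cgi_props: dict = field(default_factory=lambda: dict(DEFAULT_CGI_PROPS))
    age_range: tuple[float, float] = (45.0, 90.0)
    pmt_range: tuple[float, float] = (3.0, 26.0)  # hours
    balance_covariates: bool = True
    max_covariate_grade_rho: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.grade_counts:
            if g not in GRADE_ROMAN_TO_INT:
                raise ValidationError(f"unknown grade label {g!r}")
        if sum(self.grade_counts.values()) < 2:
            raise ValidationError("cohort needs at least 2 donors")
        for cls, count in self.class_counts.items():
            if cls not in PROBE_CLASSES or cls == "null":
                if cls not in PROBE_CLASSES:
                    raise ValidationError(f"unknown probe class {cls!r}")
            if count < 0:
                raise ValidationError("class counts must be >= 0")
        if sum(self.class_counts.values()) > self.n_probes:
            raise ValidationError("class counts exceed n_probes")
        if not (0 < self.drift_amplitude_beta < 0.9):
            raise ValidationError("drift amplitude must be in (0, 0.9) to leave Beta headroom")
        if self.dm_offset_beta <= 0 or self.noise_sd_m < 0:
            raise ValidationError("dm_offset_beta must be > 0 and noise_sd_m >= 0")
        if self.unstable_shift_m_factor <= 0:
            raise ValidationError("unstable_shift_m_factor must be > 0")


def _grade_signal(grades: np.ndarray) -> np.ndarray:
    """Linear severity ramp: 0 at grade III, 1 at grade VII."""
    return (grades - 3.0) / 4.0


def _amplitude_m(baseline_beta: np.ndarray, offset_beta: np.ndarray) -> np.ndarray:
    """M-scale amplitude whose Beta-scale effect at full signal equals offset_beta."""
    target = baseline_beta + offset_beta
    if np.any(target <= 0) or np.any(target >= 1):
        raise ValidationError("planted offset pushes Beta outside (0, 1)")
    return beta_to_m(target) - beta_to_m(baseline_beta)


def generate_cohort_data(config: GeneratorConfig
                         ) -> tuple[Cohort, BetaMatrix, AnnotationTable, list[str], pd.DataFrame]:
    """Generate (cohort, Beta matrix, annotation, blacklist, truth table)."""
    rng = np.random.default_rng(config.seed)

    # --- cohort -----------------------------------------------------------
    grade_labels: list[str] = []
    for grade in ("III", "IV", "V", "VI", "VII"):
        grade_labels.extend([grade] * config.grade_counts.get(grade, 0))
    n_cohort = len(grade_labels)
    grade_nums = np.array([GRADE_ROMAN_TO_INT[g] for g in grade_labels], dtype=float)

    # Donor covariates are drawn independently of grade; like a matched cohort
    # design, draws where a covariate happens to track severity are rejected
    # so the covariate screen tests probe-level, not cohort-level, confounding.
    for attempt in range(500):
        ages = rng.uniform(*config.age_range, size=n_cohort)
        sexes = np.where(rng.random(n_cohort) < 0.5, "M", "F")
        pmts = rng.uniform(*config.pmt_range, size=n_cohort)
        if not config.balance_covariates or np.ptp(grade_nums) == 0:
            break
        rhos = [
            abs(_spearman_abs(grade_nums, cov))
            for cov in (ages, (sexes == "F").astype(float), pmts)
        ]
        if max(rhos) <= config.max_covariate_grade_rho:
            break
    else:
        warnings.warn("could not balance covariates against grade; using last draw")

    donors, samples = [], []
    for i, grade in enumerate(grade_labels, start=1):
        donor = f"D{i:03d}"
        for tissue in ("A", "N"):
            samples.append(Sample(f"{donor}{tissue}", donor, tissue, grade,
                                  float(ages[i - 1]), str(sexes[i - 1]), float(pmts[i - 1])))
        donors.append(donor)
    cohort = Cohort(samples)
    grades = cohort.grades().to_numpy(dtype=float)
    cov = cohort.covariates()
    n_donors = len(donors)

    # --- probe classes ----------------------------------------------------
    n = config.n_probes
    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    cursor = 0
    for cls in PROBE_CLASSES:
        if cls == "null":
            continue
        count = config.class_counts.get(cls, 0)
        labels[order[cursor:cursor + count]] = cls
        cursor += count
    probe_ids = np.array([f"cg{j:08d}" for j in range(n)])

    # --- baseline, clamped so planted offsets stay inside (0, 1) ----------
    mu_m = config.baseline_mix.draw(rng, n)
    baseline_beta = m_to_beta(mu_m)
    amp = config.drift_amplitude_beta
    margin = 0.02
    sign = np.ones(n)
    effect_beta = np.zeros(n)
    for cls, offset in (("grade_hyper", amp), ("grade_hypo", -amp),
                        ("unstable_N", None), ("blacklisted", None),
                        ("dm_constant", None),
                        ("confound_age", None), ("confound_sex", None), ("confound_pmt", None)):
        mask = labels == cls
        if not mask.any():
            continue
        if offset is None:
            # random direction; dm uses its own (smaller) offset
            cls_amp = config.dm_offset_beta if cls == "dm_constant" else amp
            sign[mask] = rng.choice([-1.0, 1.0], size=mask.sum())
            offsets = sign[mask] * cls_amp
        else:
            sign[mask] = np.sign(offset)
            offsets = np.full(mask.sum(), offset)
        lo = np.where(offsets < 0, -offsets + margin, margin)
        hi = np.where(offsets > 0, 1 - offsets - margin, 1 - margin)
        baseline_beta[mask] = np.clip(baseline_beta[mask], lo, hi)
        effect_beta[mask] = offsets
    mu_m = beta_to_m(baseline_beta)

    # --- per-donor intra-pair shifts on the M scale ------------------------
    s_grade = _grade_signal(grades)  # (donors,)
    z = {name: _standardize(cov[name].to_numpy(dtype=float)) for name in ("age", "sex", "pmt")}
    delta = np.zeros((n, n_donors))
    n_shift = np.zeros((n, n_donors))
    drift_cls = np.isin(labels, ["grade_hyper", "grade_hypo", "unstable_N", "blacklisted"])
    if drift_cls.any():
        a_m = _amplitude_m(baseline_beta[drift_cls], effect_beta[drift_cls])
        delta[drift_cls] = a_m[:, None] * s_grade[None, :]
    dm = labels == "dm_constant"
    if dm.any():
        delta[dm] = _amplitude_m(baseline_beta[dm], effect_beta[dm])[:, None]
    for cls, name in (("confound_age", "age"), ("confound_sex", "sex"), ("confound_pmt", "pmt")):
        mask = labels == cls
        if mask.any():
            c_m = _amplitude_m(baseline_beta[mask], effect_beta[mask])
            delta[mask] = c_m[:, None] * z[name][None, :]
    unstable = labels == "unstable_N"
    if unstable.any():
        # the normal-tissue baseline itself drifts with grade; the shift is
        # larger than the intra-pair drift so the class is detectably unstable
        # for the low-powered 2-vs-9 extreme-grade comparison
        u_m = _amplitude_m(baseline_beta[unstable], effect_beta[unstable])
        n_shift[unstable] = config.unstable_shift_m_factor * u_m[:, None] * s_grade[None, :]

    # --- noise and emission -------------------------------------------------
    eps_n = rng.normal(0.0, config.noise_sd_m, size=(n, n_donors)) if config.noise_sd_m else 0.0
    eps_a = rng.normal(0.0, config.noise_sd_m, size=(n, n_donors)) if config.noise_sd_m else 0.0
    n_m = mu_m[:, None] + n_shift + eps_n
    a_m = n_m + delta + eps_a
    beta_frame = pd.DataFrame(
        np.hstack([m_to_beta(a_m), m_to_beta(n_m)]),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=cohort.a_sample_ids() + cohort.n_sample_ids(),
    )
    beta = BetaMatrix(beta_frame)

    # --- annotation ---------------------------------------------------------
    comp_labels = list(config.compartment_props)
    comp_p = np.asarray(list(config.compartment_props.values()), dtype=float)
    comp_idx = rng.choice(len(comp_labels), size=n, p=comp_p / comp_p.sum())
    cgi_labels = list(config.cgi_props)
    cgi_p = np.asarray(list(config.cgi_props.values()), dtype=float)
    cgi_idx = rng.choice(len(cgi_labels), size=n, p=cgi_p / cgi_p.sum())
    chroms = rng.integers(1, 23, size=n)
    pos = rng.integers(0, 200_000_000, size=n)
    annotations = []
    for j in range(n):
        comp = comp_labels[comp_idx[j]]
        entries = () if comp is None else ((f"G{j:05d}", comp),)
        annotations.append(
            ProbeAnnotation(
                probe_id=probe_ids[j],
                chrom=f"chr{chroms[j]}",
                pos=int(pos[j]) + 1,
                gene_entries=entries,
                cgi_relation=cgi_labels[cgi_idx[j]],
            )
        )
    annotation = AnnotationTable(annotations)

    blacklist = [p for p, lab in zip(probe_ids, labels) if lab == "blacklisted"]
    truth = pd.DataFrame(
        {"class": labels, "effect": effect_beta},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return cohort, beta, annotation, blacklist, truth


def _spearman_abs(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(b) == 0:
        return 0.0
    return float(stats.spearmanr(a, b).statistic)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


PROMOTER_COMPARTMENTS = ("TSS200", "TSS1500")


def _promoter_planted_genes(truth: pd.DataFrame, annotation: AnnotationTable) -> dict[str, int]:
    """Gene -> expected correlation sign (+1 hyper / -1 hypo) for genes carrying
    a planted grade probe in a promoter compartment."""
    out: dict[str, int] = {}
    planted = truth[truth["class"].isin(["grade_hyper", "grade_hypo"])]
    for probe_id, row in planted.iterrows():
        ann = annotation.get(probe_id)
        if ann is None:
            continue
        for sym, comp in ann.gene_entries:
            if comp in PROMOTER_COMPARTMENTS:
                out[sym] = 1 if row["class"] == "grade_hyper" else -1
    return out


def _mouse_symbol(human_symbol: str) -> str:
    return human_symbol[:1].upper() + human_symbol[1:].lower()


def generate_expression_data(truth: pd.DataFrame, annotation: AnnotationTable,
                             coupling_slope: float, noise_sd: float, seed: int) -> DETable:
    """Mouse-style DE table coupled to the planted promoter methylation drift.

    Genes with a promoter-planted grade probe get
    ``log2FC = coupling_slope * (+-1 by direction) + N(0, noise_sd)``;
    all other annotated genes get pure noise.
    """
    if not np.isfinite(coupling_slope):
        raise ValidationError("coupling_slope must be finite")
    missing = [p for p in truth.index if p not in annotation]
    if missing:
        raise ValidationError(f"truth probe {missing[0]} missing from annotation")
    rng = np.random.default_rng(seed)
    coupled = _promoter_planted_genes(truth, annotation)
    genes: list[str] = []
    seen = set()
    for ann in annotation.values():
        for sym, _ in ann.gene_entries:
            if sym not in seen:
                seen.add(sym)
                genes.append(sym)
    rows = []
    for sym in genes:
        base = coupling_slope * coupled[sym] if sym in coupled else 0.0
        noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
        rows.append({"gene": _mouse_symbol(sym), "log2fc": base + noise})
    return DETable(pd.DataFrame(rows, columns=["gene", "log2fc"]))


def generate_wgbs_data(cohort: Cohort, beta: BetaMatrix, truth: pd.DataFrame,
                       annotation: AnnotationTable, noise_sd: float, seed: int) -> pd.DataFrame:
    """Single-donor WGBS-style intra-pair differences at promoter planted probes.

    Picks the first grade-VII donor; ``wgbs_delta = (A - N Beta) + N(0, noise_sd)``.
    """
    grades = cohort.grades()
    grade7 = [d for d in cohort.donors if grades[d] == 7]
    if not grade7:
        raise ValidationError("WGBS generation needs at least one grade-VII donor")
    donor = grade7[0]
    a_id, n_id = cohort.pairing[donor]
    rng = np.random.default_rng(seed)
    probe_ids = []
    planted = truth[truth["class"].isin(["grade_hyper", "grade_hypo"])]
    for probe_id in planted.index:
        ann = annotation.get(probe_id)
        if ann is None or probe_id not in beta.probe_ids:
            continue
        if any(comp in PROMOTER_COMPARTMENTS for _, comp in ann.gene_entries):
            probe_ids.append(probe_id)
    delta = (
        beta.values.loc[probe_ids, a_id].to_numpy(dtype=float)
        - beta.values.loc[probe_ids, n_id].to_numpy(dtype=float)
    )
    if noise_sd:
        delta = delta + rng.normal(0.0, noise_sd, size=len(probe_ids))
    out = pd.DataFrame({"wgbs_delta": delta}, index=pd.Index(probe_ids, name="probe_id"))
    out.attrs["donor"] = donor
    return out
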