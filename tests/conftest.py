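import warnings

import numpy as np
import pandas as pd
import pytest

import methdrift as md


def make_cohort(grades, ages=None, sexes=None, pmts=None):
    """Small paired cohort; grades is a list of Roman labels, one per donor."""
    n = len(grades)
    rng = np.random.default_rng(123)
    ages = ages if ages is not None else rng.uniform(50, 85, n)
    sexes = sexes if sexes is not None else ["M" if i % 2 else "F" for i in range(n)]
    pmts = pmts if pmts is not None else rng.uniform(4, 24, n)
    samples = []
    for i, g in enumerate(grades):
        donor = f"D{i:02d}"
        for tissue in ("A", "N"):
            samples.append(
                md.Sample(f"{donor}{tissue}", donor, tissue, g, float(ages[i]), sexes[i], float(pmts[i]))
            )
    return md.Cohort(samples)


@pytest.fixture(scope="session")
def default_cohort_grades():
    return ["III", "III", "IV", "IV", "V", "VI"] + ["VII"] * 9


@pytest.fixture(scope="session")
def recovery_sim():
    """The default recovery simulation: 10,000 probes, 200 planted grade probes
    at ΔBeta amplitude 0.15, 200 grade-independent dm probes, 100 per confound
    class, 100 normal-tissue-unstable probes, seed 42 — plus its call set."""
    cfg = md.GeneratorConfig(seed=42)
    cohort, beta, annotation, blacklist, truth = md.generate_cohort_data(cfg)
    records, attrition = md.call_grade_cpgs(beta, cohort, annotation, blacklist, md.AnalysisConfig())
    return {
        "cohort": cohort, "beta": beta, "annotation": annotation,
        "blacklist": blacklist, "truth": truth, "records": records,
        "attrition": attrition,
    }


@pytest.fixture(scope="session")
def null_sim():
    """All-null cohort: 5,000 probes, 15 pairs, default grade composition, seed 1."""
    cfg = md.GeneratorConfig(seed=1, n_probes=5000, class_counts={})
    cohort, beta, annotation, blacklist, truth = md.generate_cohort_data(cfg)
    records, _ = md.call_grade_cpgs(beta, cohort, annotation, blacklist, md.AnalysisConfig())
    return {"records": records, "truth": truth}


@pytest.fixture(scope="session")
def noiseless_sim():
    """Zero-noise cohort with every planted class represented."""
    cfg = md.GeneratorConfig(
        seed=7, n_probes=2000, noise_sd_m=0.0,
        class_counts={
            "grade_hyper": 50, "grade_hypo": 50, "dm_constant": 50,
            "confound_age": 20, "confound_sex": 20, "confound_pmt": 20,
            "unstable_N": 20, "blacklisted": 10,
        },
    )
    cohort, beta, annotation, blacklist, truth = md.generate_cohort_data(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, _ = md.call_grade_cpgs(beta, cohort, annotation, blacklist, md.AnalysisConfig())
    return {
        "cohort": cohort, "beta": beta, "annotation": annotation,
        "blacklist": blacklist, "truth": truth, "records": records,
    }


def planted_grade_set(truth: pd.DataFrame) -> set:
    return set(truth.index[truth["class"].isin(["grade_hyper", "grade_hypo"])])


def called_set(records: pd.DataFrame) -> set:
    return set(records.index[records["is_grade_cpg"]])
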