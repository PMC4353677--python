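"""Domain types shared by every pipeline stage.

The central objects are a donor-paired :class:`Cohort` (one atherosclerotic
"A" and one normal "N" aortic sample per donor, graded III-VII on the AHA
scale), a probes-by-samples :class:`BetaMatrix` of methylation fractions,
and per-probe :class:`ProbeAnnotation` giving genomic context (CpG-island
relation and gene-model compartment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

GRADE_ROMAN_TO_INT: dict[str, int] = {"III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7}
GRADE_INT_TO_ROMAN: dict[int, str] = {v: k for k, v in GRADE_ROMAN_TO_INT.items()}

GENE_COMPARTMENTS = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "UTR3")
CGI_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

#: Fixed numeric coding of sex for the covariate screens (D3 in the docs).
SEX_CODE = {"M": 0.0, "F": 1.0}


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    donor_id: str
    tissue: str  # "A" (atherosclerotic) or "N" (normal)
    grade_label: str  # Roman numeral III-VII, a property of the donor's lesion
    age: float  # years
    sex: str  # "M" or "F"
    postmortem_h: float  # hours between death and dissection

    def __post_init__(self) -> None:
        if self.tissue not in ("A", "N"):
            raise ValidationError(f"sample {self.sample_id}: tissue must be A or N, got {self.tissue!r}")
        if self.grade_label not in GRADE_ROMAN_TO_INT:
            raise ValidationError(
                f"sample {self.sample_id}: grade {self.grade_label!r} outside supported range III-VII"
            )
        if self.sex not in SEX_CODE:
            raise ValidationError(f"sample {self.sample_id}: sex must be M or F, got {self.sex!r}")
        if self.age < 0 or self.postmortem_h < 0:
            raise ValidationError(f"sample {self.sample_id}: age and postmortem_h must be non-negative")

    @property
    def grade(self) -> int:
        return GRADE_ROMAN_TO_INT[self.grade_label]


@dataclass
class Cohort:
    """A set of donor-paired A/N samples with a pairing index.

    Invariant: every donor contributes exactly one A and one N sample, and
    both members of a pair share the donor-level covariates and grade.
    """

    samples: list[Sample]
    pairing: dict[str, tuple[str, str]] = field(default_factory=dict)  # donor -> (A id, N id)

    def __post_init__(self) -> None:
        by_donor: dict[str, dict[str, Sample]] = {}
        for s in self.samples:
            slot = by_donor.setdefault(s.donor_id, {})
            if s.tissue in slot:
                raise ValidationError(f"donor {s.donor_id}: more than one {s.tissue} sample")
            slot[s.tissue] = s
        for donor, slot in by_donor.items():
            if set(slot) != {"A", "N"}:
                raise ValidationError(f"donor {donor}: needs exactly one A and one N sample")
            a, n = slot["A"], slot["N"]
            if (a.grade_label, a.age, a.sex, a.postmortem_h) != (n.grade_label, n.age, n.sex, n.postmortem_h):
                raise ValidationError(f"donor {donor}: A and N samples disagree on donor covariates")
        self.pairing = {d: (slot["A"].sample_id, slot["N"].sample_id) for d, slot in by_donor.items()}
        self._by_donor = {d: slot["A"] for d, slot in by_donor.items()}

    @property
    def donors(self) -> list[str]:
        return list(self.pairing)

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def grades(self) -> pd.Series:
        """Numeric grade (3-7) per donor, in donor order."""
        return pd.Series({d: self._by_donor[d].grade for d in self.donors}, name="grade")

    def covariates(self) -> pd.DataFrame:
        """Donor-level covariates (age, sex coded M=0/F=1, post-mortem time)."""
        rows = {
            d: {
                "age": self._by_donor[d].age,
                "sex": SEX_CODE[self._by_donor[d].sex],
                "pmt": self._by_donor[d].postmortem_h,
            }
            for d in self.donors
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def a_sample_ids(self) -> list[str]:
        return [self.pairing[d][0] for d in self.donors]

    def n_sample_ids(self) -> list[str]:
        return [self.pairing[d][1] for d in self.donors]


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation Beta values in [0, 1]."""

    values: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("Beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def drop_incomplete_probes(self) -> tuple["BetaMatrix", int]:
        """Drop probes with any missing Beta; returns (matrix, n_dropped)."""
        complete = self.values.dropna(axis=0)
        return BetaMatrix(complete), len(self.values) - len(complete)


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    chrom: str
    pos: int  # 1-based coordinate of the interrogated CpG
    gene_entries: tuple[tuple[str, str], ...]  # (symbol, compartment); empty = intergenic
    cgi_relation: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"probe {self.probe_id}: position must be >= 1")
        if self.cgi_relation not in CGI_RELATIONS:
            raise ValidationError(f"probe {self.probe_id}: unknown CGI relation {self.cgi_relation!r}")
        for sym, comp in self.gene_entries:
            if comp not in GENE_COMPARTMENTS:
                raise ValidationError(f"probe {self.probe_id}: unknown gene compartment {comp!r}")

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(sym for sym, _ in self.gene_entries))


class AnnotationTable(dict):
    """Mapping probe_id -> ProbeAnnotation with a DataFrame view."""

    def __init__(self, annotations: Iterable[ProbeAnnotation] = ()):  # noqa: D107
        super().__init__((a.probe_id, a) for a in annotations)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "probe_id": a.probe_id,
                "chrom": a.chrom,
                "pos": a.pos,
                "gene_symbols": ";".join(s for s, _ in a.gene_entries) or ".",
                "compartments": ";".join(c for _, c in a.gene_entries) or ".",
                "cgi_relation": a.cgi_relation,
            }
            for a in self.values()
        ]
        return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene_symbols", "compartments", "cgi_relation"])


@dataclass
class AnalysisConfig:
    """Thresholds of the grade-CpG decision rule and its companion analyses.

    alpha: per-test significance level for the Spearman screen, covariate
        screen, ANCOVA corroboration and N-sample stability test.
    effect_delta_beta: minimum |mean ΔBeta(grade VII) - mean ΔBeta(grade III)|
        (strict inequality, criterion 1).
    strata_high / strata_low: Beta cutoffs for the baseline-methylation strata
        (high: Beta > 0.75; intermediate: 0.75 >= Beta >= 0.25; low: Beta < 0.25).
    snp_window_bp: proximity window around disease-associated SNPs.
    fold_threshold: expression fold-change filter for the mouse integration.
    bonferroni_base_alpha: study-wide alpha before division by the number of
        tested probes (reported, not used as a call filter).
    epsilon_clip: symmetric Beta clamp before the logit transform.
    grade_as_numeric: treat grade as a 1-df numeric term in the ANCOVA instead
        of a categorical factor.
    """

    alpha: float = 0.05
    effect_delta_beta: float = 0.05
    strata_high: float = 0.75
    strata_low: float = 0.25
    snp_window_bp: int = 250_000
    fold_threshold: float = 2.0
    bonferroni_base_alpha: float = 0.05
    epsilon_clip: float = 1e-6
    grade_as_numeric: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.strata_low < self.strata_high < 1):
            raise ValidationError("require 0 < strata_low < strata_high < 1")
        for name in ("alpha", "effect_delta_beta", "snp_window_bp", "fold_threshold",
                     "bonferroni_base_alpha", "epsilon_clip"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class GradeCpGRecord:
    """All per-probe statistics and criterion flags for one tested probe."""

    probe_id: str
    rho: float
    p_grade: float
    p_age: float
    p_sex: float
    p_pmt: float
    p_ancova: float
    mean_dbeta_grade3: float
    mean_dbeta_grade7: float
    extreme_effect: float
    p_n_stability: float
    crit1_effect: bool
    crit2_grade: bool
    crit2_covariates: bool
    crit2_ancova: bool
    crit3_stability: bool
    direction: str  # "hyper" iff rho > 0
    is_grade_cpg: bool

    @classmethod
    def from_row(cls, row: pd.Series) -> "GradeCpGRecord":
        return cls(probe_id=row.name if row.name is not None else row["probe_id"],
                   **{f: row[f] for f in cls.__dataclass_fields__ if f != "probe_id"})


@dataclass
class DETable:
    """Differential-expression table: gene symbol, log2 fold change, optional score."""

    frame: pd.DataFrame  # columns: gene, log2fc, (score)

    def __post_init__(self) -> None:
        required = {"gene", "log2fc"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"DE table needs columns {sorted(required)}")
        if (self.frame["gene"].astype(str).str.len() == 0).any():
            raise ValidationError("DE table contains an empty gene symbol")
        if not np.isfinite(self.frame["log2fc"].to_numpy(dtype=float)).all():
            raise ValidationError("DE table log2 fold changes must be finite")

    def __len__(self) -> int:
        return len(self.frame)
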