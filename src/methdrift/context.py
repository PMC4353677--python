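"""Genomic-distribution, stratification, overlap and SNP-proximity analyses.

These operate on a call set against the array background: chi-square tests of
category distributions (gene compartment, CGI relation), baseline-methylation
strata, hypergeometric gene-list overlaps, and proximity to disease-associated
SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AnnotationTable, ProbeAnnotation, ValidationError

#: Collapsed per-probe compartment categories (one per probe).
COMPARTMENT_CATEGORIES = ("Promoter", "UTR5", "FirstExon", "Body", "UTR3", "Intergenic")

# Promoter wins outright; the rest follow 5'-to-3' precedence across a probe's
# (possibly multi-gene) entries (D9).
_PRECEDENCE = ("UTR5", "FirstExon", "Body", "UTR3")


def assign_compartment(probe: ProbeAnnotation) -> str:
    """Collapse a probe's multi-gene annotation to one compartment category."""
    comps = {comp for _, comp in probe.gene_entries}
    if not comps:
        return "Intergenic"
    if comps & {"TSS200", "TSS1500"}:
        return "Promoter"
    for cat in _PRECEDENCE:
        if cat in comps:
            return cat
    return "Intergenic"


@dataclass
class CategoryCount:
    """Observed counts in a selection vs background counts on the array."""

    observed: dict[Hashable, int]
    background: dict[Hashable, int]


def category_background_test(selected: Iterable[str], universe: Iterable[str],
                             categorizer: Callable[[str], Hashable]
                             ) -> tuple[CategoryCount, float, int, float]:
    """Pearson chi-square of a selection's category counts against the
    expectation from background (whole-array) proportions.

    Categories with expected count zero are merged into ``"other"`` with a
    warning so the statistic stays defined (D10).
    """
    selected = list(selected)
    universe = list(universe)
    obs_raw = pd.Series([categorizer(p) for p in selected]).value_counts()
    bg_raw = pd.Series([categorizer(p) for p in universe]).value_counts()
    cats = [c for c in bg_raw.index if bg_raw[c] > 0]
    zero_bg = sorted(set(obs_raw.index) - set(cats))
    if zero_bg:
        # pool the zero-expected categories with the rarest background
        # category so every cell keeps a positive expectation
        host = min(cats, key=lambda c: bg_raw[c])
        warnings.warn(
            f"categories {zero_bg} have zero background; merged with {host!r} into 'other'"
        )
        remap = {c: "other" for c in zero_bg + [host]}
        obs_raw = obs_raw.rename(index=remap).groupby(level=0).sum()
        bg_raw = bg_raw.rename(index=remap).groupby(level=0).sum()
        cats = [c for c in bg_raw.index if bg_raw[c] > 0]
    if len(cats) < 2:
        raise ValidationError("chi-square needs >= 2 categories with nonzero background")
    observed = np.array([obs_raw.get(c, 0) for c in cats], dtype=float)
    bg = np.array([bg_raw.get(c, 0) for c in cats], dtype=float)
    expected = bg / bg.sum() * observed.sum()
    chi2, p = stats.chisquare(observed, expected)
    counts = CategoryCount(
        observed={c: int(obs_raw.get(c, 0)) for c in cats},
        background={c: int(bg_raw.get(c, 0)) for c in cats},
    )
    return counts, float(chi2), len(cats) - 1, float(p)


def hyper_hypo_contrast(records: pd.DataFrame, annotation: AnnotationTable,
                        feature: Callable[[ProbeAnnotation], bool]
                        ) -> tuple[float, float, float, float]:
    """2x2 chi-square contrasting a binary feature between the hypomethylating
    and hypermethylating called probes.

    Returns (pct_feature_in_hypo, pct_feature_in_hyper, chi2, p).
    """
    called = records[records["is_grade_cpg"]]
    groups = {}
    for direction in ("hypo", "hyper"):
        ids = called.index[called["direction"] == direction]
        if len(ids) == 0:
            raise ValidationError(f"direction group {direction!r} is empty")
        flags = np.array([feature(annotation[p]) for p in ids])
        groups[direction] = (int(flags.sum()), int((~flags).sum()))
    table = np.array([groups["hypo"], groups["hyper"]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # feature (or its complement) absent everywhere: no contrast
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    pct = 100.0 * table[:, 0] / table.sum(axis=1)
    return float(pct[0]), float(pct[1]), float(chi2), float(p)


def baseline_strata(mean_n_beta: float, strata_high: float = 0.75,
                    strata_low: float = 0.25) -> str:
    """Baseline (normal-tissue) methylation stratum of a probe.

    High: Beta > high cutoff (strict); Low: Beta < low cutoff (strict);
    Intermediate: the inclusive band in between.
    """
    if not (0 <= mean_n_beta <= 1):
        raise ValidationError(f"mean Beta {mean_n_beta} outside [0, 1]")
    if mean_n_beta > strata_high:
        return "High"
    if mean_n_beta < strata_low:
        return "Low"
    return "Intermediate"


def gene_overlap(called_genes: set[str], external_list: set[str], universe_size: int
                 ) -> tuple[set[str], int, float]:
    """Overlap of two gene sets with an upper-tail hypergeometric p (>= k).

    Symbols are uppercase-normalised before comparison.
    """
    a = {g.upper() for g in called_genes}
    b = {g.upper() for g in external_list}
    if universe_size < len(a | b):
        raise ValidationError("universe smaller than the union of the gene sets")
    overlap = a & b
    k = len(overlap)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return overlap, k, min(p, 1.0)


def snp_proximity(probes: Sequence[ProbeAnnotation], snp_table: pd.DataFrame,
                  window_bp: int = 250_000) -> pd.DataFrame:
    """Probe-SNP pairs on the same chromosome within window_bp (inclusive)."""
    required = {"id", "chrom", "pos"}
    if not required.issubset(snp_table.columns):
        raise ValidationError(f"SNP table needs columns {sorted(required)}")
    rows = []
    for _, snp in snp_table.iterrows():
        if pd.isna(snp["pos"]):
            raise ValidationError(f"SNP {snp['id']}: malformed row (missing position)")
        pos = int(snp["pos"])
        for probe in probes:
            if probe.chrom != snp["chrom"]:
                continue
            distance = abs(probe.pos - pos)
            if distance <= window_bp:
                rows.append({"probe_id": probe.probe_id, "snp_id": snp["id"], "distance": distance})
    return pd.DataFrame(rows, columns=["probe_id", "snp_id", "distance"])
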