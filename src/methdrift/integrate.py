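"""Cross-species expression integration and WGBS concordance validation.

Called probes whose genes are strongly differentially expressed in a mouse
atherosclerosis model ("mgrade"-style probes) are tested for a correlation
between the per-probe grade-drift statistic (Spearman rho of ΔM vs grade)
and the gene's expression log2 fold change, per genomic-context group.
Promoter probes are expected to correlate inversely (methylation up,
expression down).
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .context import assign_compartment
from .model import AnnotationTable, BetaMatrix, Cohort, DETable, ValidationError


def filter_de(de: DETable, fold_threshold: float = 2.0) -> DETable:
    """Keep genes with |log2FC| strictly above log2(fold_threshold).

    Adds a ``regulation`` column ("up"/"down" by sign). Idempotent.
    """
    if fold_threshold <= 1:
        raise ValidationError("fold_threshold must be > 1")
    cutoff = math.log2(fold_threshold)
    frame = de.frame[np.abs(de.frame["log2fc"]) > cutoff].copy()
    frame["regulation"] = np.where(frame["log2fc"] > 0, "up", "down")
    return DETable(frame.reset_index(drop=True))


def map_orthologs(human_symbols: set[str], mouse_symbols: set[str]) -> dict[str, str]:
    """Human -> mouse symbol map by case-insensitive exact match (D13).

    Within-species case duplicates collapse to one entry with a warning.
    """
    def collapse(symbols: set[str], species: str) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in sorted(symbols):
            key = s.upper()
            if key in out:
                warnings.warn(f"{species} symbols {out[key]!r} and {s!r} collapse case-insensitively")
            else:
                out[key] = s
        return out

    human = collapse(human_symbols, "human")
    mouse = collapse(mouse_symbols, "mouse")
    return {human[k]: mouse[k] for k in human.keys() & mouse.keys()}


def compartment_correlation(records: pd.DataFrame, annotation: AnnotationTable,
                            de_filtered: DETable, mapping: Mapping[str, str],
                            group_by: str = "compartment") -> pd.DataFrame:
    """Per-group Pearson correlation between per-probe grade-drift rho and the
    mapped gene's expression log2 fold change.

    Probes considered are the called grade-CpGs whose gene maps (via
    ``mapping``) to a gene in ``de_filtered``. Probes matching two or more
    filtered genes are excluded with a warning (D14). ``group_by`` is
    ``"compartment"`` (collapsed gene-model category) or ``"cgi_relation"``.
    Groups with n < 3 are reported with NaN r and p.
    """
    if group_by not in ("compartment", "cgi_relation"):
        raise ValidationError(f"unknown group_by {group_by!r}")
    fc = {g.upper(): v for g, v in zip(de_filtered.frame["gene"], de_filtered.frame["log2fc"])}
    mapping_upper = {h.upper(): m.upper() for h, m in mapping.items()}
    called = records[records["is_grade_cpg"]]
    pairs = []
    for probe_id, row in called.iterrows():
        ann = annotation.get(probe_id)
        if ann is None:
            continue
        hits = []
        for sym in ann.gene_symbols:
            mouse = mapping_upper.get(sym.upper())
            if mouse is not None and mouse in fc:
                hits.append(mouse)
        hits = list(dict.fromkeys(hits))
        if len(hits) > 1:
            warnings.warn(f"probe {probe_id} maps to {len(hits)} filtered genes; excluded")
            continue
        if not hits:
            continue
        group = assign_compartment(ann) if group_by == "compartment" else ann.cgi_relation
        pairs.append({"probe_id": probe_id, "group": group, "rho": row["rho"], "log2fc": fc[hits[0]]})
    pair_frame = pd.DataFrame(pairs, columns=["probe_id", "group", "rho", "log2fc"])
    out = []
    for group, sub in pair_frame.groupby("group"):
        n = len(sub)
        if n < 3:
            warnings.warn(f"group {group!r} has n = {n} < 3; reported as NA")
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(sub["rho"], sub["log2fc"])
        out.append({"group": group, "n": n, "r": float(r), "p": float(p)})
    result = pd.DataFrame(out, columns=["group", "n", "r", "p"])
    result.attrs["pairs"] = pair_frame
    return result


def wgbs_concordance(records: pd.DataFrame, beta: BetaMatrix, cohort: Cohort,
                     wgbs_table: pd.DataFrame) -> tuple[int, float, float]:
    """Pearson correlation between the grade-VII-average array ΔBeta and the
    single-donor WGBS intra-pair difference at matched probes."""
    grades = cohort.grades()
    donors7 = [d for d in cohort.donors if grades[d] == 7]
    if not donors7:
        raise ValidationError("WGBS concordance needs at least one grade-VII pair")
    matched = [p for p in wgbs_table.index if p in beta.probe_ids]
    if len(matched) < 3:
        raise ValidationError(f"WGBS concordance needs >= 3 matched probes, got {len(matched)}")
    a_ids = [cohort.pairing[d][0] for d in donors7]
    n_ids = [cohort.pairing[d][1] for d in donors7]
    x = (
        beta.values.loc[matched, a_ids].to_numpy(dtype=float)
        - beta.values.loc[matched, n_ids].to_numpy(dtype=float)
    ).mean(axis=1)
    y = wgbs_table.loc[matched, "wgbs_delta"].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)
    return len(matched), float(r), float(p)
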