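"""Readers and writers for every external file the pipeline touches.

All tabular files are UTF-8, tab-separated with a header row; "." marks a
missing optional field. Called probes are additionally exported as BED6
(0-based half-open single-base intervals).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    AnnotationTable,
    BetaMatrix,
    Cohort,
    DETable,
    ProbeAnnotation,
    Sample,
    ValidationError,
)

log = logging.getLogger(__name__)

_COHORT_COLUMNS = ["sample_id", "donor_id", "tissue", "grade", "age", "sex", "postmortem_h"]


def read_cohort(path: str | Path) -> Cohort:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet {path}: missing columns {missing}")
    samples = [
        Sample(
            sample_id=r.sample_id,
            donor_id=r.donor_id,
            tissue=r.tissue,
            grade_label=r.grade,
            age=float(r.age),
            sex=r.sex,
            postmortem_h=float(r.postmortem_h),
        )
        for r in df.itertuples()
    ]
    return Cohort(samples)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "donor_id": s.donor_id,
            "tissue": s.tissue,
            "grade": s.grade_label,
            "age": s.age,
            "sex": s.sex,
            "postmortem_h": s.postmortem_h,
        }
        for s in cohort.samples
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes x samples Beta TSV; probes with any missing value are dropped."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."])
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate probe ids")
    matrix, n_dropped = BetaMatrix(df).drop_incomplete_probes()
    if n_dropped:
        log.info("read_beta_matrix: dropped %d probe(s) with missing Beta values", n_dropped)
    return matrix


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


# Illumina-style north/south CGI labels collapse to the four-way categorisation
# used throughout the analysis (D2).
_CGI_ALIASES = {
    "N_Shore": "Shore", "S_Shore": "Shore",
    "N_Shelf": "Shelf", "S_Shelf": "Shelf",
    "Island": "Island", "Shore": "Shore", "Shelf": "Shelf", "OpenSea": "OpenSea",
}


def _split_field(value: str) -> list[str]:
    if value in (".", "", None) or (isinstance(value, float) and np.isnan(value)):
        return []
    return str(value).split(";")


def read_probe_annotation(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["probe_id", "chrom", "pos", "gene_symbols", "compartments", "cgi_relation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation {path}: missing columns {missing}")
    annotations = []
    for r in df.itertuples():
        symbols = _split_field(r.gene_symbols)
        comps = _split_field(r.compartments)
        if len(symbols) != len(comps):
            raise ValidationError(
                f"probe {r.probe_id}: gene_symbols and compartments lists are not parallel"
            )
        try:
            relation = _CGI_ALIASES[r.cgi_relation]
        except KeyError:
            raise ValidationError(f"probe {r.probe_id}: unknown CGI relation {r.cgi_relation!r}") from None
        annotations.append(
            ProbeAnnotation(
                probe_id=r.probe_id,
                chrom=r.chrom,
                pos=int(r.pos),
                gene_entries=tuple(zip(symbols, comps)),
                cgi_relation=relation,
            )
        )
    return AnnotationTable(annotations)


def write_probe_annotation(annotation: AnnotationTable, path: str | Path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


def read_id_list(path: str | Path) -> list[str]:
    """Plain-text list, one identifier per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_de_table(path: str | Path, fold: bool = False) -> DETable:
    """Read a DE table (gene, log2fc[, score]); fold=True converts fold changes.

    With ``fold=True`` the numeric column is interpreted as a (signed) linear
    fold change and converted via log2.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.empty and len(df.columns) < 2:
        return DETable(pd.DataFrame(columns=["gene", "log2fc"]))
    cols = list(df.columns)
    out = pd.DataFrame({"gene": df[cols[0]].astype(str)})
    raw = pd.to_numeric(df[cols[1]], errors="coerce")
    if raw.isna().any():
        bad = df[cols[1]][raw.isna()].iloc[0]
        raise ValidationError(f"DE table {path}: non-numeric fold value {bad!r}")
    out["log2fc"] = np.log2(raw) if fold else raw
    if "score" in df.columns:
        out["score"] = pd.to_numeric(df["score"])
    return DETable(out)


def write_de_table(table: DETable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "class": str})
    return df.set_index("probe_id")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_wgbs_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    return df.set_index("probe_id")


def write_wgbs_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def read_snp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    required = ["id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"SNP table {path}: missing columns {missing}")
    if df["pos"].isna().any():
        raise ValidationError(f"SNP table {path}: malformed row with missing position")
    df["pos"] = df["pos"].astype(int)
    return df


RESULTS_COLUMNS = [
    "probe_id", "rho", "p_grade", "p_age", "p_sex", "p_pmt", "p_ancova",
    "mean_dbeta_grade3", "mean_dbeta_grade7", "extreme_effect", "p_n_stability",
    "crit1_effect", "crit2_grade", "crit2_covariates", "crit2_ancova",
    "crit3_stability", "direction", "is_grade_cpg",
]


def write_outputs(records: pd.DataFrame, annotation: AnnotationTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the full per-probe results TSV and a BED6 of called grade-CpGs.

    BED rows are single-base, 0-based half-open intervals [pos-1, pos); the
    score is round(1000*|rho|) clipped to [0, 1000].
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = [p for p in records.index if p not in annotation]
    if missing:
        raise ValidationError(f"probe {missing[0]} missing from annotation")

    results_path = out_dir / "grade_cpg_results.tsv"
    records.reset_index(names="probe_id")[RESULTS_COLUMNS].to_csv(
        results_path, sep="\t", index=False, float_format="%.6g"
    )

    bed_path = out_dir / "grade_cpgs.bed"
    called = records[records["is_grade_cpg"]]
    with open(bed_path, "w", encoding="utf-8") as fh:
        for probe_id, row in called.iterrows():
            ann = annotation[probe_id]
            score = int(np.clip(round(1000 * abs(row["rho"])), 0, 1000))
            fh.write(f"{ann.chrom}\t{ann.pos - 1}\t{ann.pos}\t{probe_id}\t{score}\t.\n")
    return {"results": results_path, "bed": bed_path}
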