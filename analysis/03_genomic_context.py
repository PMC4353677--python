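#!/usr/bin/env python
"""Genomic context of the called probes: compartment/CGI distribution against
the array background, hyper-vs-hypo contrasts, baseline strata, a gene-list
overlap and SNP proximity.

The SNP table and external gene list are synthesized here from the simulated
annotation (a handful of positions near called probes plus decoys) purely to
exercise the machinery end to end.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import methdrift as md
from methdrift import io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--calls", type=Path, default=Path("results/calls"))
    ap.add_argument("--out", type=Path, default=Path("results/context"))
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    annotation = io.read_probe_annotation(args.sim / "probe_annotation.tsv")
    beta = io.read_beta_matrix(args.sim / "beta_matrix.tsv")
    cohort = io.read_cohort(args.sim / "sample_sheet.tsv")
    records = pd.read_csv(args.calls / "grade_cpg_results.tsv", sep="\t",
                          index_col="probe_id")
    called = records.index[records["is_grade_cpg"]].tolist()
    tested = records.index.tolist()

    counts, chi2, df, p = md.category_background_test(
        called, tested, lambda pid: md.assign_compartment(annotation[pid]))
    print(f"compartment distribution vs array: chi2 = {chi2:.2f} (df {df}), p = {p:.3g}")
    cgi_counts, cgi_chi2, cgi_df, cgi_p = md.category_background_test(
        called, tested, lambda pid: annotation[pid].cgi_relation)
    print(f"CGI distribution vs array: chi2 = {cgi_chi2:.2f} (df {cgi_df}), p = {cgi_p:.3g}")

    pct_hypo, pct_hyper, c2, cp = md.hyper_hypo_contrast(
        records, annotation, lambda a: a.cgi_relation == "Island")
    print(f"CGI rate: {pct_hypo:.1f}% of hypo vs {pct_hyper:.1f}% of hyper calls "
          f"(chi2 p = {cp:.3g})")

    mean_n = beta.values[cohort.n_sample_ids()].mean(axis=1)
    strata = mean_n.loc[called].map(md.baseline_strata).value_counts()
    print(f"baseline strata of calls: {strata.to_dict()}")

    # synthetic external resources
    rng = np.random.default_rng(args.seed)
    called_genes = {s for pid in called for s in annotation[pid].gene_symbols}
    all_genes = {s for a in annotation.values() for s in a.gene_symbols}
    external = set(rng.choice(sorted(called_genes), size=min(30, len(called_genes)),
                              replace=False)) | set(rng.choice(sorted(all_genes), 100, replace=False))
    overlap, k, hp = md.gene_overlap(called_genes, external, universe_size=len(all_genes))
    print(f"external gene list: {k} of {len(called_genes)} called genes overlap "
          f"(hypergeometric p = {hp:.3g})")

    snp_rows = []
    for i, pid in enumerate(called[:8]):
        a = annotation[pid]
        snp_rows.append({"id": f"rs{i:04d}", "chrom": a.chrom,
                         "pos": max(1, a.pos + int(rng.integers(-240_000, 240_000)))})
    for i in range(8):  # decoys far away
        snp_rows.append({"id": f"rs9{i:03d}", "chrom": "chr21",
                         "pos": int(rng.integers(1, 2_000_000))})
    snps = pd.DataFrame(snp_rows)
    pairs = md.snp_proximity([annotation[p] for p in called], snps, window_bp=250_000)
    print(f"SNP proximity: {pairs['probe_id'].nunique()} called probes within 250 kb "
          f"of {pairs['snp_id'].nunique()} SNPs")

    pd.DataFrame({
        "category": list(counts.background),
        "observed": [counts.observed.get(c, 0) for c in counts.background],
        "background": list(counts.background.values()),
    }).to_csv(args.out / "compartment_distribution.tsv", sep="\t", index=False)
    pairs.to_csv(args.out / "snp_proximity.tsv", sep="\t", index=False)
    strata.rename("n").to_csv(args.out / "baseline_strata.tsv", sep="\t")


if __name__ == "__main__":
    main()
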