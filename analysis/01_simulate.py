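#!/usr/bin/env python
"""Generate the default synthetic paired-aorta cohort and write its files.

Emulates a 15-donor cohort (grades III-VII, 9 donors at grade VII) measured
on a 450k-style array: 10,000 probes with 100 grade-hypermethylating and 100
grade-hypomethylating drift probes (ΔBeta amplitude 0.15 at grade VII), 200
grade-independent dm probes, 100 per covariate-confound class, 100
normal-tissue-unstable probes and the remainder null. Also writes the
coupled mouse-style expression table and a single-donor WGBS delta table.
"""

import argparse
from pathlib import Path

import methdrift as md
from methdrift import io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = md.GeneratorConfig(seed=args.seed)
    cohort, beta, annotation, blacklist, truth = md.generate_cohort_data(cfg)
    io.write_cohort(cohort, args.out / "sample_sheet.tsv")
    io.write_beta_matrix(beta, args.out / "beta_matrix.tsv")
    io.write_probe_annotation(annotation, args.out / "probe_annotation.tsv")
    io.write_id_list(blacklist, args.out / "blacklist.txt")
    io.write_truth_table(truth, args.out / "truth.tsv")

    de = md.generate_expression_data(truth, annotation, coupling_slope=-1.0,
                                     noise_sd=0.3, seed=args.seed + 1)
    io.write_de_table(de, args.out / "de_table.tsv")
    wgbs = md.generate_wgbs_data(cohort, beta, truth, annotation,
                                 noise_sd=0.05, seed=args.seed + 2)
    io.write_wgbs_table(wgbs, args.out / "wgbs_delta.tsv")

    classes = truth["class"].value_counts().to_dict()
    print(f"wrote {cfg.n_probes} probes x {cohort.n_pairs} donor pairs to {args.out}")
    print(f"planted classes: {classes}")
    print(f"expression table: {len(de.frame)} genes; WGBS table: {len(wgbs)} promoter probes")


if __name__ == "__main__":
    main()
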