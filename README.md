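# methdrift

Grade-correlated DNA methylation drift calling for donor-paired
lesion/normal methylation-array cohorts.

Atherosclerotic lesions accumulate DNA methylation changes. Some of these
are present as soon as a lesion exists; others *drift* — they grow with
lesion severity. `methdrift` implements a reusable pipeline for finding the
drifting CpGs ("grade-CpGs") in a cohort of donor-matched atherosclerotic
(A) and normal (N) aortic samples graded III–VII on the AHA scale, and for
characterising them: genomic distribution, hyper/hypo contrasts, Ward
biclustering of donors, overlap with external gene lists and
disease-associated SNPs, integration with mouse-model expression data, and
sequencing-based (WGBS) concordance. A synthetic-cohort generator with
planted ground truth makes every stage testable end to end without any
external download.

It is written for epigenomics practitioners who work with 450k-style Beta
matrices and want a tested, scriptable implementation of a
paired-drift screen rather than a one-off analysis.

## The decision rule

Beta values β are logit-transformed to M values, M = log2(β/(1−β)), and the
intra-pair difference ΔM = M(A) − M(N) is computed per probe and donor. A
probe is called a grade-CpG when:

1. |mean ΔBeta(grade VII) − mean ΔBeta(grade III)| > 0.05 (strict);
2. Spearman ρ of ΔM vs numeric grade has p < 0.05, ΔM shows **no**
   significant correlation with age, sex or post-mortem time, and the grade
   effect survives an ANCOVA with those covariates (partial F, p < 0.05);
3. the N-sample M values of grade-VII and grade-III donors do not differ
   (Welch t, p ≥ 0.05) — apparent drift must come from the lesion, not from
   an unstable normal-tissue baseline.

Calls are split by direction (hyper/hypo-methylating with grade), and the
study-wide Bonferroni threshold (0.05 / tested probes) is reported.
See `docs/methods.md` for the full model, the generator's planted probe
classes, and the design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (15 donor pairs, 10,000 probes, 200 planted drift probes
among confounded, unstable and null classes):

```sh
python analysis/01_simulate.py          # writes results/sim/
python analysis/02_call_grade_cpgs.py   # writes results/calls/
python analysis/03_genomic_context.py
python analysis/04_cluster.py
python analysis/05_integrate.py
```

Output of `02_call_grade_cpgs.py`:

```
tested 10000 probes (0 blacklisted, 0 incomplete)
called 183 grade-CpGs on 139 genes; 48.6% hypermethylating
mean extreme-grade |ΔBeta| among calls: 0.150 (range 0.050-0.197)
Bonferroni threshold 5e-06: 0 probes below it
vs truth: sensitivity 0.870, precision 0.951
```

183 of the 200 planted drift probes are recovered with 9 false positives;
the mean extreme-grade effect matches the planted 0.15 amplitude, and (as
in real cohorts of this size) no single probe reaches the study-wide
Bonferroni level — the rule is a screen, corroborated by the covariate
and stability criteria rather than by genome-wide significance. The
direction split is ~50/50 because the generator plants both directions
equally. `04_cluster.py` then reports:

```
  cluster 1: grades [3, 3, 4, 4]
  cluster 2: grades [5, 6, 7, 7, 7, 7, 7, 7, 7, 7, 7]
Rand index of the 2-cut vs the low (III-IV) / high (V-VII) split: 1.000
```

i.e. the called-probe ΔBeta matrix alone separates low-grade from
high-grade donors. `05_integrate.py` shows the planted inverse coupling
between promoter methylation drift and mouse expression
(`Promoter  n = 11  r = -0.980  p = 1.16e-07`) and the array/WGBS
concordance (`r = 0.967, n = 31`).

The same pipeline is available as a CLI over TSV/BED files:

```sh
methdrift all --out run1 --seed 42          # simulate → call → context → cluster → integrate
methdrift call --config cfg.yaml --out run2 # on your own Beta matrix / sample sheet
```

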