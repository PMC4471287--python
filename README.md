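# convergeomics

Multi-omic convergence analysis for perturbation studies in neural stem
cells (NSCs): do the mRNA, microRNA and DNA-methylation changes caused by a
gene knockdown (KD) overlap, agree in direction, and correlate with the
changes seen when control cells switch from proliferation to
differentiation?

The package is aimed at groups running the three-way study design common in
neurodevelopmental-disorder modelling: shRNA knockdown lines, non-target
proliferating controls (the reference), and non-target differentiating
controls (the cell-state signature). It turns each omic layer's raw tables
into directional feature lists and then asks, layer by layer, whether the
KD signature converges on the cell-state signature.

## The statistics at the core

For two significant feature sets $A$ (KD contrast) and $B$ (cell-state
contrast) drawn from a detectable background pool of size $N$, the
convergence statistic is the exact hypergeometric upper tail

$$P(X \ge k) = \sum_{i=k}^{\min(K,n)} \frac{\binom{K}{i}\binom{N-K}{n-i}}{\binom{N}{n}},
\qquad K = |A|,\; n = |B|,\; k = |A \cap B|,$$

evaluated by log-space summation (no normal approximation), together with
the directional concordance of the shared features (fraction with the same
fold-change sign) and the Pearson correlation of their log2 fold changes.

Per layer:

- **mRNA** — genes detectable at FPKM > 1 (per-condition means) form the
  pool; Welch tests on log2(FPKM+1) with Benjamini–Hochberg control at
  q ≤ 0.05 give the DE lists; overlaps are reported separately for
  increased and decreased genes.
- **miRNA** — nCounter-style tables are normalized in two per-lane steps
  (positive-spike-in geometric means, then endogenous content), probes must
  exceed a per-lane background of mean + 2 sd of the negative controls in
  enough lanes of either group, and testing is Welch on log2(normalized+1)
  with a nominal p < 0.05 list and BH q < 0.10 flags.
- **DNA methylation** — Bismark-coverage CpG calls are filtered (coverage
  > 5x, top 0.1% of coverages removed per sample, optional blacklist),
  CpG clusters are maximal runs of sites ≤ 50 bp apart with ≥ 2 sites,
  each cluster is tested by pooling per-site per-sample methylation
  frequencies in a Welch t-test, genome-wide significance is Bonferroni
  over tested clusters, cross-experiment overlap is counted on shared base
  pairs, clusters map to genes through strand-aware 5 kb upstream / 2 kb
  downstream windows, and clusters significant in both analyses are
  correlated against the proliferating and differentiating references.

Because studies of this design rarely deposit raw data, the package also
ships a synthetic multi-omics generator (`convergeomics.simulate`) that
emulates all four input formats with a controllable fraction `rho_shared`
of features perturbed concordantly in both contrasts — every pipeline stage
can therefore be validated against known planted truth.

## Worked example

Simulate a study (2000 genes, 300 miRNA probes, 500 CpG clusters, half of
the planted signal shared between contrasts) and run the full analysis:

```bash
convergeomics simulate --seed 11 --out demo/bundle
convergeomics converge --bundle demo/bundle --out demo/report.json
```

which prints:

```
convergence report
  mRNA: pool=1963, KD significant=125 (up 68 / down 57), state significant=200
    overlap k=65, hypergeometric p=2.56e-35; decreased-in-state 50.9% (same direction 50.9%); increased-in-state 52.9%
    log2FC Pearson r=0.988
  miRNA: retained 294/300, KD nominal=37 (FDR 26), overlap p=5.44e-06
    state concordance: identical direction 73.0%, Pearson r=0.703
  methylation: KD clusters tested=500, significant=50; state significant=50; overlap k=26, p=2.27e-16
    per-cluster r vs proliferating=0.253, vs differentiating=0.996 (n=26)
```

Reading the numbers: of 1963 detectable genes, 125 respond to the KD and 65
of them are also cell-state responsive — an overlap this large arises by
chance with probability 2.6e-35, so the KD signature converges on the
differentiation signature. About half of the KD genes recur in the state
list, matching the planted `rho_shared=0.5`. The same picture repeats for
miRNAs (overlap p = 5.4e-06, fold changes correlated at r = 0.70) and for
methylation, where the 26 clusters significant in both analyses track the
differentiating reference (r = 0.996) far better than the proliferating one
(r = 0.25). The JSON report carries every statistic plus an echo of all
thresholds and input-file digests.

Each layer can be run alone (`convergeomics expr|mirna|meth`), and all
thresholds (FPKM cutoff, q/p thresholds, coverage floor, cluster gap, gene
windows, detection minima) are flags or config-file keys.

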