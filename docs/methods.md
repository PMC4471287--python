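# Methods

This note documents the statistical model behind `convergeomics`, the
choices made where the design was genuinely open, the synthetic data the
package validates itself on, and the limits of what those validations show.

## Study design and contrasts

The package assumes three groups of samples: knockdown lines (`kd`),
non-target proliferating controls (`nt_prolif`) and non-target
differentiating controls (`nt_diff`). Two contrasts are analysed per omic
layer — the KD contrast (kd vs nt_prolif) and the cell-state contrast
(nt_diff vs nt_prolif) — and the question throughout is whether the KD
signature converges on the cell-state signature. The default of 4 samples
per group mirrors the typical design (two shRNA constructs × two
replicates against four non-target constructs).

## Overlap statistic

Convergence is scored by the exact hypergeometric upper tail
P(X ≥ k) with pool N, set sizes K and n, and intersection k, summed in log
space from log-gamma binomial coefficients. The upper (enrichment) tail is
used because the scientific question is whether the overlap is larger than
chance; the summation is exact to float precision for pools well beyond
10^5 and is cross-checked in the tests against exhaustive enumeration
(N ≤ 12) and Monte-Carlo urn draws.

The background pool for the mRNA layer is the intersection of the two
contrasts' detectable pools: both significant lists must be drawable from
the pool for the hypergeometric model to apply, and the intersection is the
largest set with that property. Detection defaults to "mean FPKM strictly
above 1 in at least one of the two conditions" — the most permissive of the
three implemented readings (`mean-or`, `all-samples`, `any-sample`), chosen
because detectability is an attribute of the gene, not of a single lane.

## Differential expression

The DE engine is deliberately plain: Welch's t on log2(FPKM+1), BH at
q ≤ 0.05. The convergence statistics are the package's contribution and
consume any DE table; externally produced DE lists (gene, log2fc, p, q) can
be loaded directly via `expression.read_de_table`. The +1 offset makes the
transform defined at zero but attenuates planted effects for genes near the
detection limit; power statements in the tests therefore use well-expressed
genes. Welch (unequal variances) is the default everywhere a two-sample
test appears, with pooled-variance Student available via `equal_var=True`;
with tiny group sizes neither flavour is robust to strong non-normality,
which is a known limitation of t-based RRBS testing generally.

Degenerate tests resolve deterministically rather than propagating NaN:
two constant equal groups give t=0, p=1; two constant unequal groups give
p=0; both cases carry a `degenerate` flag.

## miRNA normalization

The two-step per-lane scheme follows digital-counting practice: (1) scale
each lane so its positive-spike-in geometric mean equals the grand
geometric mean across lanes; (2) repeat the construction on the endogenous
content after step 1. Geometric means are computed over strictly positive
counts. Positive spike-ins are nonzero by design, and excluding rather than
offsetting occasional endogenous zeros keeps the normalization exactly
equivariant under per-lane scaling — multiplying a lane's counts by c > 0
leaves its normalized values unchanged, which the acceptance tests verify
to 1e-9. The +1 offset guarding zeros is applied where logarithms of probe
values are actually taken, i.e. in the log2 transform before testing.

Detection ("expressed") is normalized value strictly above the lane's
mean + 2 sd of negative controls; a probe is retained when detected in at
least `min_detected_control` control lanes or `min_detected_kd` KD lanes
(both exposed as options; the defaults are scaled to the group sizes since
lane accounting varies between runs of this platform).

## Methylation layer

Sites require coverage strictly above 5 reads; afterwards the
ceil(0.001 × n) highest-coverage sites are removed per sample (ties broken
toward higher position), guarding against PCR/clonal artefacts; the order —
floor first, then top-fraction — is fixed and tested. An optional position
blacklist drops sites confounded by genetic variation. The cluster universe
is the set of positions surviving the filters in every sample of the
comparison, so each cluster's t-test sees frequencies from all samples; a
union universe with missing-tolerance was considered and rejected because
it makes the pooled test's sample sizes uneven across sites in ways that
are hard to audit.

CpG clusters are maximal runs of consecutive sites with gaps ≤ 50 bp
(boundary: 50 joins, 51 splits — exposed as `--max-gap`) containing at
least 2 sites. The per-cluster test pools the per-site per-sample
frequencies of each group as observations — site-level values, not
per-site means — because a cluster's evidence is its sites; a per-site-mean
mode would discount large clusters. Pooled site × sample observations are
correlated within a sample, so the nominal p-values are approximate;
the null-calibration tests show they are nevertheless close to uniform
under the generator's null. Genome-wide significance defaults to Bonferroni
over the tested clusters (BH available); the correction method and alpha
are always echoed into the report because significant-cluster counts are
meaningless without them.

Cross-experiment cluster overlap counts a-side significant clusters sharing
at least one base pair with any b-side significant cluster, scored
hypergeometrically over the a-side tested-cluster universe. Since the two
analyses may have different universes, an extremely long b-side cluster
could in principle overlap more a-side clusters than |sig_b|; k is clamped
to min(K, n) with a logged warning if that ever happens. Gene mapping uses
strand-aware windows (5 kb upstream, 2 kb downstream by default): a
+ strand gene [s, e) maps clusters in [s−5000, e+2000), a − strand gene in
[s−2000, e+5000). Internally every coordinate is 0-based half-open; the
Bismark coverage dialect (1-based inclusive) is converted on read and
restored on write.

For clusters significant in both the KD and state analyses, the layer
reports the Pearson correlation of the KD-group mean frequencies against
the proliferating-control means and against the differentiating-control
means; a higher correlation with the differentiating reference is the
methylation-level signature of convergence.

## Synthetic data generator

`simulate` emulates the three data types with one integer seed (one
Generator substream per layer; identical configs give byte-identical
bundles):

- **Expression**: per-gene baseline log2 FPKM ~ Normal(4, 2); per-sample
  values add the planted group effect and Normal(0, `fpkm_dispersion`=0.5)
  noise. Planted effects are ±`effect_log2fc` (default 2), half up / half
  down; the cell-state contrast gets twice the KD effect size by default,
  reflecting that differentiation moves expression much further than a
  single-gene knockdown.
- **miRNA**: endogenous negative-binomial counts (gamma–Poisson,
  dispersion 0.05, i.e. lane CV ≈ 22%, the precision expected of
  duplicate-averaged digital counting) around per-probe log-normal means,
  multiplied by per-lane scale factors; six positive spike-ins on a fixed
  concentration ladder × lane scale; eight negative probes at Poisson(2 ×
  lane scale).
- **Methylome**: clusters of `sites_per_cluster`=5 CpGs with intra-cluster
  gaps ≈ 20 bp (capped under the 50-bp joining rule) separated by ≥ 2 kb,
  so the planted partition is exactly recoverable; per-cluster baselines
  Uniform(0.35, 0.65), coverage gamma–Poisson around 30×, methylated counts
  Binomial(coverage, baseline + planted Δ), with Δ = ±0.3 by default. The
  state contrast uses the same |Δ| as the KD contrast (not the 2× rule)
  so planted frequencies stay inside [0, 1].

Shared structure: both contrasts perturb `frac_de` of the features; a quota
of `rho_shared` × n_de features is shared with concordant signs, and the
remaining state features are sampled independently of the KD set. With
rho_shared=0 the two planted sets are therefore independent and the overlap
statistic's null holds exactly. An optional `effect_corr` draws the shared
(KD, state) fold-change pairs from a bivariate normal, which lets tests
plant a target fold-change correlation.

What the generator does **not** emulate: read-level noise and mapping
artefacts, sequence context (CpG islands, SNP confounding), batch structure
beyond per-lane scale factors, correlated co-regulation between features,
and heavy-tailed expression outliers. Passing tests therefore demonstrate
the correctness and calibration of the statistics under a clean generative
model, not robustness to every artefact of real sequencing data.

## Calibration and known limitations

- Both contrasts share the proliferating control samples (as the underlying
  study design does). Overlap p-values computed from two DE tables that
  share controls are mildly anti-conservative (≈7% rejection at α=0.05 in
  simulations at these sample sizes): a control outlier pushes the same
  gene toward significance in both contrasts. The calibration tests
  therefore evaluate the overlap statistic on independently planted sets —
  its actual null — and users comparing two DE tables with shared controls
  should treat borderline overlap p-values with care.
- The hypergeometric tail is discrete, hence conservative at its support
  points; calibration holds in the mixture over realistic set sizes.
- Bonferroni over tested clusters is intentionally conservative; the BH
  option trades family-wise control for power.
- The per-cluster correlation analysis conditions on clusters significant
  in both analyses, a selection that inflates correlations toward the
  stronger reference; it is reported as a ranking (which reference tracks
  the KD better), not as an unbiased effect size.

## Problem sizes used in validation

The simulation-based tests run at reduced scale chosen to keep Monte-Carlo
error well below the tested margins: 1000–3000 genes, 300 probes, 500–600
CpG sites per run, with 100–500 seeds for calibration and detection-rate
properties. These sizes reproduce the asymptotics that matter (pool sizes
in the thousands, set sizes in the dozens-to-hundreds) at a fraction of
genome scale.
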