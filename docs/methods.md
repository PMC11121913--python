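# Methods

## Differential expression

Counts are modelled per feature as negative binomial with a common
dispersion, variance μ + φμ²; φ = 0 degenerates to Poisson. The
workflow is the classic exact-test pipeline for designs with very few
replicates (here 3 vs 3 per regimen):

1. **Normalisation.** CPM only: counts / library size × 10⁶. Library
   sizes are column sums for matrices read from files; the simulator
   attaches its generative sequencing depths instead (see below). No
   trimmed-mean (TMM) factor is applied — the workflow this package
   realises states depth normalisation only, and the composition bias
   that TMM would absorb is therefore a property of the method, not a
   bug of the implementation.
2. **Low-expression filter.** The threshold is the CPM equivalent of
   `min_raw = 5` raw counts in the smallest library; a feature is kept
   when its CPM reaches the threshold in at least ⌈`min_fraction` ×
   n⌉ samples (`min_fraction = 0.5`). The underlying rule is stated
   ambiguously in the source workflow; this parameterisation is the
   configurable reading we committed to. Filtering is per regimen.
3. **Library equalisation.** The conditional argument of the exact
   test requires exchangeable library sizes, so counts are scaled to
   the geometric-mean library size and rounded half-to-even. This is
   deterministic, unlike quantile-based adjustment; the estimator and
   test are validated against their own enumeration oracles and
   cross-checked against the reference R implementation on equal
   libraries, where the adjustment is the identity.
4. **Dispersion.** Common φ maximises the conditional log-likelihood
   of within-group counts given group totals (the NB-sum conditioning
   removes the mean parameter), searched by golden section on
   φ ∈ [0, 10] to 10⁻⁴; the Poisson limit is evaluated in closed form
   and returned when it fits at least as well. On equal-library NB
   data the estimate matches edgeR's `estimateCommonDisp` to ~10⁻⁵
   (see `tests/test_oracle_edger.py`).
5. **Exact test.** Conditional on the two-group total T, the group-A
   sum follows the ratio of NB-sum split probabilities (binomial when
   φ = 0). The p-value sums the probabilities of all splits at most as
   likely as the observed one, with a 10⁻¹⁰ relative tie tolerance;
   T = 0 gives p = 1 by convention. p-values agree with a brute-force
   enumeration oracle to 10⁻¹² for totals ≤ 50 and with edgeR's
   `binomTest` in the Poisson limit.
6. **Calling.** BH step-up FDR (via statsmodels) across tested
   features; significant ⇔ FDR < 0.05 and |log2FC| > 0.6, both strict.
   log2FC = log2((mean treated CPM + 0.5)/(mean control CPM + 0.5));
   the 0.5 prior count stabilises ratios at low expression.

## Candidate targets

Seed = miRNA positions 2–8. Site classes on the sense-strand UTR:
8mer (revcomp(seed) + A), 7mer-m8 (revcomp(seed)), 7mer-A1
(revcomp(positions 2–7) + A). At one locus only the highest-priority
class is reported (8mer > 7mer-m8 > 7mer-A1); separate loci are
independent. Context scoring, conservation tiers and 6mer sites are
deliberately out of scope: predictions act only as a pair filter, so
candidate generation is binary. When both a prediction table and
sequences are supplied, the table wins.

## Anti-correlation network

Per candidate pair, Pearson r of log2(CPM + 1) across the six paired
samples (3 control + 3 treated) of one regimen; two-sided p from the
t-transform on n − 2 df; BH-FDR across exactly the candidate pairs of
that regimen (regimens are separate FDR families); retain r < 0 and
FDR < 0.05, both strict, sign filtered after significance. The scale
(`log2cpm` vs `cpm`) and the sample set are configurable because the
original workflow does not state them; log scale and the 6
regimen samples are the defaults — with a near-binary condition
contrast they produce retained correlations in the −0.92..−0.99 band
such analyses report. Hubs are miRNA nodes with degree ≥ 10, ordered
by descending degree then name; in a bipartite graph the hub edge
count is exactly the sum of hub degrees.

## Enrichment and annotation

Over-representation uses the hypergeometric upper tail P(X ≥ k)
(scipy, log-space stable), equivalent to the one-sided Fisher test.
The universe must always be supplied explicitly — typically all
miRNAs passing the expression filter; the package refuses to invent
one. Cluster membership strips only trailing `-3p`/`-5p` arm suffixes
(names like `miR-496` pass through) and tests half-open interval
overlap of the precursor's gene coordinates with cluster intervals,
strand-ignored. This reproduces precursor-level counting: 14 mature
panel entries → 12 unique precursors in the bundled 14q32 example.

## Synthetic data generator

The generator emulates the paired two-regimen design: 2 regimens × 2
conditions × 3 biological replicates of paired miRNA/mRNA libraries.

Latent model (log2 scale): miRNA i in sample s has
`x = log2(base_i) + Δ_i·1[treated] + e`, mRNA j has
`y = log2(base_j) − Σ_planted β(x − log2 base_i) + f`, with e, f ~
N(0, `latent_sd`). Counts are NB around `2^latent × depth/10⁶` via a
gamma–Poisson mixture. Repression acts on latent means, not realised
counts, which induces the anti-correlation the network analysis
assumes while keeping NB marginals.

Defaults, chosen once as realistic study conditions: 200 miRNAs, 300
mRNAs, baseline mean 100 (lognormal spread 0.7), φ = 0.1 (typical for
cell-line triplicates), Δ = 2 on 25 % of miRNAs (half up), 40 planted
pairs at β = 1, library depths 0.8–1.2 M, `latent_sd` = 0.25
(sample-level biological noise beyond NB sampling).

Two features reflect real small-RNA libraries rather than textbook
NB matrices:

* **Constitutive ballast.** Ten miRNAs absorb 60 % of library mass
  and never receive a treatment effect, mirroring the extreme
  abundance skew of real libraries (a handful of miRNAs dominate
  reads). Without it, planted effects shift library composition
  enough that CPM-only normalisation shows its classic composition
  bias at desk scale.
* **Known depths.** The emitted matrices carry the drawn generative
  depths as library sizes (the CountMatrix override), so CPM on the
  in-memory matrices estimates latent expression unbiasedly. Matrices
  written to disk and re-read fall back to column sums, as real data
  would.

UTR simulation gives every planted pair at least one exact 8mer site
and rejection-samples all other UTRs to contain no canonical 7-mer
match for any simulated miRNA (default UTR length 80 keeps rejection
tractable); mature sequences are drawn with distinct seeds.

What passing tests on this generator do **not** show: robustness to
batch effects, UMI/adapter artefacts, multi-mapping ambiguity,
isomiR collapsing, or composition shifts beyond the planted ones —
none are simulated.

## Numerical and design choices

* All p-value machinery works in log space (`gammaln`, `logsumexp`).
* Round-half-even for count equalisation (no stochastic rounding).
* Hub and candidate orderings break ties lexicographically for
  determinism; all randomness flows from one seeded generator with a
  fixed draw order, so equal seeds give byte-identical outputs.
* The recovery test planting 122 down- and 83 up-regulated miRNAs
  among 1500 checks direction-resolved recovery of the planted
  features (≥ 95 % per direction) plus overall precision ≥ 0.9: a
  "total calls" check at ±5 % would be unattainable by construction,
  since BH at FDR 0.05 over ~1300 null features admits ~α·π₀·R ≈ 10
  false calls in expectation.
* The network recovery suite uses a planted contrast of Δ = 5: with
  six samples and φ = 0.1, per-sample log2 noise caps attainable |r|
  near 0.91 at Δ = 3, below what a BH family of 400 pairs retains;
  Δ = 5 pushes true pairs into the −0.95..−0.99 band the filter
  targets. At Δ = 3 the suite checks precision (pooled over seeds)
  rather than recall.
* Pipeline caching is whole-run, keyed on the config plus input and
  output checksums; `--force` recomputes. Reruns are idempotent
  because every stage is deterministic.

## Known limitations

* The exact test supports a single two-level factor; no covariates,
  GLM or quasi-likelihood modes.
* Enrichment replaces ranked multi-database fusion tools with a plain
  hypergeometric + BH over user-supplied sets.
* Alias conversion is table-driven only; no registry queries.
* The disease catalogue and the 14q32 panel bundled in
  `mirnetox.reference` are small demonstration fixtures, not curated
  resources.
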