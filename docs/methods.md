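# Methods

## The problem

An immunoprecipitation mass-spectrometry (IP-MS) experiment captures a bait
protein (here a keratin, Krt17) together with whatever is bound to it, from
several related samples — in the motivating design, lysates of four basal
airway epithelial cell lines plus two no-antibody controls processed in
parallel. The protein report lists, per protein, identification-confidence
metrics (posterior error probability, q-value, unique-peptide count) and one
MS1 peak-area abundance per sample.

The inference principle is co-abundance: if two proteins are persistently
bound, their abundances keep a constant ratio across samples, so their
Pearson correlation coefficient R approaches 1 and the coefficient of
determination CD = R² is high. Negative R between a protein and every member
of a cooperating module marks mutual exclusion — an antagonistic module.
`ipmsnet` implements this chain of reasoning as a tested pipeline:

1. **ingest / QC** (`ipmsnet.ingest`) — parse the report and sample sheet;
   keep proteins with PEP < 0.01 (strict), q-value = 0, ≥ 2 unique peptides,
   and total abundance across samples ≥ 9 × 10⁶. Rejected rows carry the
   first failing clause, evaluated in that fixed order. Missing abundance
   cells are absent values, never zeros, everywhere in the pipeline.
2. **enrichment** (`ipmsnet.enrich`) — a protein is selectively recovered
   when mean IP abundance ≥ 2 × mean control abundance (inclusive), or when
   it is present under capture and absent from all controls. A one-sided
   Mann–Whitney U (IP > control) is attached; with 4-vs-2 samples the exact
   permutation p cannot go below 1/15 ≈ 0.067, so by default it is reported
   descriptively rather than gating the verdict.
3. **keratin metrics** (`ipmsnet.keratin`) — per-sample keratin mass
   fraction (keratin abundance over total quantified abundance) and the
   percentage composition of the keratin pool; the fraction vector is the
   reference for keratin-content correlation.
4. **correlation** (`ipmsnet.correlate`) — all n(n−1)/2 pairwise Pearson
   coefficients on pairwise-complete observations. A pair is valid only with
   ≥ `min_pairs` (default 5) both-present samples; in a 6-sample design a
   protein missing two samples therefore has no defined coefficient with
   anything. Excluded pairs are counted so that
   `excluded + computed = n(n−1)/2` is checkable on every run.
5. **network** (`ipmsnet.network`) — cooperating cores from the graph of
   positively correlated pairs with CD ≥ `tau_core` (default 0.75);
   antagonist modules from the all-negative sign rule against a reference
   core; class/Venn accounting and cross-linker identification from a
   user-supplied annotation map.

## Statistical and numerical choices

**Exact Mann–Whitney.** U counts (IP, control) pairs with IP > control, ties
contributing ½. For combined group sizes ≤ 12 the one-sided p is the exact
fraction of all C(n₁+n₂, n₁) group-label arrangements of the pooled values
with U′ ≥ U — valid under ties, which midrank tables are not at these sizes.
Larger groups fall back to scipy's midrank normal approximation with
continuity correction.

**Pearson on raw abundances.** Coefficients are computed on raw (unlogged)
abundances via `scipy.stats.pearsonr` over the both-present positions;
`log_transform` is available. Constant sub-vectors yield a `zero_variance`
exclusion rather than an error, and r is clamped to [−1, 1] against
floating-point overshoot.

**Pair-validity threshold.** The pipeline requires ≥ 5 complete observations
per pair. An equivalent statement of the rule is that one missing sample
still permits a (5-point) coefficient while two missing samples never do;
`min_pairs` is configurable for other designs.

**Analysis universe.** Proteins passing QC and quantified in at least
n_samples − 1 samples form the pairwise universe. In `run_all` the
bait-class (keratin) rows are additionally excluded from the pairwise
universe: they are the reference vector for keratin-content correlation,
not interactor candidates, and their per-sample totals are constrained by
the fraction targets rather than free co-abundance.

**Core extraction.** Cores are connected components of the thresholded
positive-r graph, reduced by default to their 2-core (`min_degree = 2`):
every member must be supported by at least two qualifying edges. The reason
is statistical: with only six samples the null distribution of r is wide —
the chance that two unrelated proteins show CD ≥ 0.75 with positive r is
roughly 1.3–1.8% per pair — so a single high edge is weak evidence of
membership, while "connectedness" (a member's edge count inside the module)
is the meaningful signal. `min_degree = 0` restores plain components and
`mode="clique"` gives maximal cliques.

**Antagonist rule.** Given an anchor and a reference module, a protein
qualifies with r > 0 against the anchor and r < 0 against every reference
member having a defined coefficient. Undefined (excluded) pairs do not
disqualify by default, because the missing-value rules legitimately leave
coefficients undetermined; `strict_undefined=True` reverses this.

**Class accounting.** The annotation CSV lists classes per accession with
the primary class first. Primary-class counts assign each protein once;
Venn-region counts use the full class set and are disjoint (they sum to the
universe size); cross-linkers are proteins with ≥ 2 cytoskeletal classes.
The packaged reference annotation (`load_enriched_reference_annotation`)
transcribes the classification of the rat basal-airway Krt17 IP candidate
set: 29 actin-, 6 microtubule- and 38 keratin/other-associated proteins, of
which 6 are dual-class cross-linker candidates.

## The synthetic-data generator

`ipmsnet.simulate` emulates the study layout — 4 IP samples (cell lines
4C9, 2C1, 1000W, BP3) plus 2 no-antibody controls — with planted structure
for every downstream stage. All randomness flows through one
`numpy.random.Generator` (PCG64) seeded from `SimConfig.seed`; identical
configurations give byte-identical fixture files.

* **Abundance scale.** Per-protein base abundances are lognormal,
  log10 ~ N(7.5, 0.6), mimicking MS1 peak areas spanning orders of magnitude
  above the 9 × 10⁶ summed-abundance floor.
* **Core module** (default 5 proteins): a shared latent per-sample intensity
  vector times per-protein scales times multiplicative lognormal noise
  (`core_noise_sigma`, default 0.1). The latent is built from the six
  standard-normal quantiles scaled by `latent_sigma` (default 0.9), shuffled
  and exponentiated: its dynamic range is fixed, only its orientation is
  random, so the planted module is always detectable at the configured
  noise. Orientations with |r| > 0.45 against the IP/control indicator are
  rejection-sampled away — a module profile collinear with the capture
  pattern would be indistinguishable from enrichment covariation and is not
  an identifiable planted module.
* **Antagonist module** (default 3 proteins, the first being the anchor):
  the latent vector reflected about its mid-range, so every antagonist has
  exactly r = −1 with every core member in the noise-free limit while
  antagonists correlate positively with one another.
* **Capture enrichment** (default 8 proteins): abundances multiplied by
  `capture_factor` (default 4) in IP samples. Enriched proteins carry
  independent per-sample biological variation (`background_sigma`, default
  0.25) so that shared enrichment alone does not constitute a co-abundance
  module.
* **Keratins**: seven Krt genes with fixed composition weights (Krt14+Krt5
  67%, Krt17+Krt6a 21%, minor keratins the rest); per-sample keratin totals
  are set so each sample's keratin mass fraction equals its target exactly
  when nothing is missing. Default targets are the study-style values
  0.3474 / 0.4903 / 0.5540 / 0.6243 (IP lines) and 0.5464 / 0.3468
  (controls).
* **Background** (default 12 proteins): independent per-sample lognormal
  variation, `background_sigma = 0.25`.
* **Missingness**: MCAR at a flat per-cell rate (default 0.01) plus MNAR
  left-censoring with logistic dropout probability in log10 abundance
  (steepness 3 per decade, midpoint 10⁴·⁵ — sharp censoring near the
  detection limit, negligible for abundant proteins). `mnar_steepness = 0`
  disables MNAR entirely. Every removed cell is recorded in the ground
  truth.
* **QC metadata**: a configured fraction (default 0.1) of background rows
  receives exactly one failing clause — PEP in [0.02, 0.5], q > 0, or a
  single unique peptide — chosen uniformly; planted signal rows keep clean
  metrics so that recovery tests isolate the statistical stages.

**What the generator does not emulate:** peptide-level identification,
shared/razor peptide ambiguity, batch effects, interference or
ratio-compression, and any real biological covariation beyond the planted
modules. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic under the stated model, not performance on real IP-MS
data.

**A deliberate scale choice.** The default simulated universe is small
(about 28 candidate proteins). With six samples the null distribution of r
is so wide that over hundreds of independent proteins a CD ≥ 0.75 graph
percolates by chance; a compact universe keeps chance edges rare enough
that planted-structure recovery is attributable to the planted structure.
Larger universes are a config change away, with the caveat that module
membership then needs the 2-core rule (or a higher `tau_core`) to remain
meaningful.

## Recovery behaviour at defaults

Over seeded replicates at default configuration, best-match F1 between a
recovered core and the planted core membership averages ≈ 0.95, antagonist
recall ≈ 1.0, and enrichment sensitivity ≈ 1.0 (these are recomputed by
`scripts/acceptance.py` and by the test suite, 20 replicates per run). The
residual F1 shortfall is dominated by single chance attachments (one
unrelated protein whose six-sample profile aligns with the latent at
|r| ≥ 0.866, ≈ 1.5% per protein per replicate) — the irreducible null tail
of correlation at n = 6, which is also why the method, applied to real
data of this shape, should treat any single high CD with caution.

## Known limitations

* The exact per-line candidate counts and per-pair CD values of the
  motivating study require its deposited raw reports and are outside what a
  synthetic testbed can reproduce; the pipeline reproduces the procedure
  and its structural/count arithmetic.
* The merge rule that produced the study's single cross-line universe of
  196 proteins is not printed in the source material; `pair_universe`
  implements the presence-based rule above and exposes it in config.
* No multiple-testing control is applied to fold changes or correlations,
  matching the descriptive character of the procedure.
* `keratin_vector_mode` ("fraction" vs "absolute") changes keratin
  correlations; fraction is the default because the fraction vector is
  computed immediately before keratin-correlation analysis in the
  procedure being modelled. Both are reported options, not claims.
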