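# ipmsnet

Co-abundance protein–protein interaction network inference from
immunoprecipitation mass-spectrometry (IP-MS) protein reports.

## What it does

Affinity capture with an antibody against a bait protein (the motivating
use case: keratin 17 in basal airway epithelial cells) pulls down the bait
together with its binding partners. Tandem MS then yields, per protein, an
MS1 abundance in each sample. If two proteins are persistently bound, their
abundances keep a constant ratio across samples, so their Pearson
correlation R → 1 and the coefficient of determination CD = R² is high;
a protein negatively correlated with *every* member of such a module is a
candidate for mutual exclusion. `ipmsnet` turns this reasoning into a
reproducible pipeline:

* **QC filtering** of the protein report: PEP < 0.01, q-value = 0,
  ≥ 2 unique peptides, summed abundance ≥ 9 × 10⁶; rejected rows carry the
  first failing clause.
* **Enrichment**: mean IP / mean no-antibody-control fold change with an
  inclusive two-fold rule, plus a one-sided exact Mann–Whitney U
  (at 4 IP vs 2 control samples the exact p can never go below
  1/15 ≈ 0.067, so it is reported, not gating).
* **Keratin metrics**: per-sample keratin mass fractions and the
  composition of the keratin pool; the fraction vector is the reference for
  keratin-content correlation.
* **Correlation with explicit missing-value rules**: all n(n−1)/2 pairs on
  pairwise-complete observations, valid only with ≥ 5 both-present samples
  (a protein missing two of six samples has no defined coefficient with
  anything); excluded pairs are counted so
  `excluded + computed = n(n−1)/2` always holds.
* **Module extraction**: cooperating cores = 2-cores of the graph of
  positively correlated pairs with CD ≥ 0.75 (each member needs two
  supporting edges); antagonist modules = proteins positive with an anchor
  and negative with every member of a reference core; class/Venn accounting
  and cross-linker identification from a user annotation map.
* **Synthetic data**: a seeded generator plants proportional-abundance
  modules, a reflected anti-correlated module, capture-enriched proteins,
  exact keratin-fraction targets, MNAR + MCAR missingness and failing QC
  rows — with full ground truth, so every stage is testable offline.

## Worked example

Simulate a study (4 IP cell lines + 2 controls, 35 proteins including a
planted 5-protein core, a 3-protein antagonist module, 8 capture-enriched
proteins and 7 keratins), then run the full pipeline:

```bash
ipmsnet simulate --seed 1 --out-prefix sim
ipmsnet run-all --report sim_report.csv --samples sim_samples.csv --out-dir out
```

The run prints the manifest stage counts:

```json
{
  "candidate_counts": {"1000W": 34, "2C1": 34, "4C9": 34, "BP3": 33, "pool": 34},
  "core_sizes": [7, 5, 3],
  "n_cores": 3,
  "n_enriched": 15,
  "n_kept": 34,
  "n_pairs_computed": 351,
  "n_pairs_excluded": 0,
  "n_pairs_total": 351,
  "n_parsed": 35,
  "n_rejected": 1,
  "n_universe": 27
}
```

Of 35 parsed proteins one failed QC; the 27 non-keratin candidates present
in ≥ 5 samples form 351 pairs, none excluded by the missing-value rule this
run. `out/modules.json` shows the three extracted cores — the planted
module is recovered exactly, the capture-enriched proteins cluster
separately, and the antagonists correlate with each other:

```
core_1 ['ENRI007', 'ENRI002', 'ENRI003', 'ENRI004', 'ENRI006', 'ENRI001', 'ENRI008']
core_2 ['CORE01', 'CORE02', 'CORE03', 'CORE04', 'CORE05']
core_3 ['ANTA01', 'ANTA02', 'ANTA03']
```

`out/keratin.json` carries the per-sample keratin mass fractions, which hit
the configured study-style targets up to the few cells this seed censored:

```
{'ip_4C9': 0.3476, 'ip_2C1': 0.4906, 'ip_1000W': 0.5542,
 'ip_BP3': 0.6287, 'ctrl_1': 0.5468, 'ctrl_2': 0.3472}
```

Asking for the antagonist module around the planted anchor, against the
recovered core as reference:

```bash
ipmsnet network --report sim_report.csv --samples sim_samples.csv \
    --anchor ANTA01 --reference CORE01,CORE02,CORE03,CORE04,CORE05
```

returns all three planted antagonists (`ANTA01 ANTA02 ANTA03`, the anchor
qualifying with negative r against every core member) plus a few
sign-consistent background proteins — the all-negative rule is a screen,
not a significance test.

Every stage is also a library call (`ipmsnet.read_report`,
`apply_filters`, `enrichment_table`, `keratin_fraction`,
`correlation_table`, `find_cores`, `find_antagonists`, ...); see
`docs/methods.md` for the model, parameter meanings and limitations.

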