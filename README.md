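# phosplice

Reusable pipeline for the computational core of a neurodegeneration
multi-omics study design: quantifying differential phosphorylation from
isobaric-label (iTRAQ-style) reporter intensities, calling exon-skipping
changes from junction read counts, testing kinase-downstream enrichment of
phospho-changes on a protein–protein interaction (PPI) graph, GO-term
enrichment with shared-gene term clustering, and betweenness-centrality
ranking of a pathological gene network. Every stage ships with a seeded
synthetic-data generator that plants known effects, so the whole chain is
testable end to end without any external data.

Intended users: computational biologists who want the statistical skeleton of
this kind of study — disease model vs background comparisons, a treated
(rescue) arm, and network/functional follow-up — as tested, scriptable
library code.

## The statistics at the core

* **Exon skipping.** For an internal exon, inclusion reads *I* overlap the
  exon body; skipping reads *S* carry a junction joining the two flanking
  exons (exact annotated boundaries). Differential skipping between case and
  control is tested on the 2×2 table [[S_case, I_case], [S_ctrl, I_ctrl]] by
  the two-sided Fisher exact test (probability rule), with
  Benjamini–Hochberg q-values across all exons whose table has four positive
  cells; the effect size is L = log2((S/I)_case / (S/I)_ctrl). Calls at
  q < 0.05.
* **Phospho quantification.** Reporter intensities are modelled as
  log-normal. Channels are bias-corrected to equal totals; fragment
  intensities covering a site are combined by geometric mean; peptide→site
  integration is an inverse-variance-weighted geometric mean; per-site
  case/control log ratios are tested with Welch's unequal-variance t-test
  and BH-adjusted across sites.
* **Kinase downstream.** Nodes within ≤ 2 degrees of separation from seed
  kinases on the PPI graph form the downstream set; the changed/unchanged
  split inside vs outside (detected proteins only, seeds excluded) is tested
  by Fisher's exact test.
* **Network core genes.** Significant genes are kept if present in the PPI
  database, expanded by one step, and scored by unnormalized shortest-path
  betweenness; the top 25% (boundary ties included) are core genes.
* **GO enrichment.** Hypergeometric upper-tail p per term, BH across terms,
  enriched at q < 0.01; enriched terms are clustered by Jaccard distance
  between their gene sets with Ward linkage.
* **Rescue scoring.** Exons significant in both disease models are "shared";
  a shared exon is "recovered" when it is significant in disease-vs-control
  but no longer significant in treated-vs-control.

## Worked example

```bash
phosplice run-all --outdir demo --seed 1
```

runs the full simulate-then-analyze demo (seconds on one CPU) and prints its
summary, including:

```
"phospho":  {"n_sites": 1000, "n_significant": 58, "spiked_recall": 1.0,
             "null_significant_rate": 0.0084, "spiked_log2_bias": -0.0011}
"kinase":   {"downstream_size": 27, "odds_ratio": 31.68, "p": 6.66e-13}
"splicing": {"n_shared_exons": 50, "n_shared_genes": 50,
             "n_recovered": 20, "recovered_fraction": 0.4, "power_model_a": 1.0}
"go":       {"n_enriched": 3, "enriched_terms": ["PLANTED0", "PLANTED1", "PLANTED2"]}
"network":  {"hub_rank": 1, "n_core": 41, "n_nodes": 163}
```

Reading: all 50 sites spiked at |log2 FC| = 2 are recalled with essentially
zero bias while 0.8% of null sites are called; the planted kinase-downstream
enrichment (true odds ratio 36) is estimated at 31.7 and is overwhelmingly
significant; the two disease models share all 50 planted exons, and exactly
the planted 40% of them are scored as rescued in the treated arm; the three
planted GO terms are the only enriched ones; and the node wired to the
selected genes ranks first by betweenness. `demo/` holds the per-stage TSVs,
the term tree in Newick, and a `manifest.json` with the config and SHA-256 of
every output — rerunning with the same seed reproduces every file byte for
byte.

Each stage is also exposed individually (`phosplice simulate|phospho|splice|
kinase|network|go`) and as plain library functions.

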