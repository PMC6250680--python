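# Methods

This note documents the models, parameter choices and numerical conventions
behind each stage, what the synthetic-data generators do and do not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Statistical primitives

**Fisher's exact test** is two-sided by the probability rule: the p-value
sums the hypergeometric probabilities of every table sharing the observed
margins whose probability does not exceed the observed table's. Sidedness is
a convention choice; the probability rule is the dominant one and is the one
validated exhaustively against exact rational-arithmetic enumeration for all
tables with margins ≤ 12. The reported statistic is the sample odds ratio
(ad)/(bc), with +inf when bc = 0.

**Welch's t-test** uses the Welch–Satterthwaite degrees of freedom and a
two-sided Student-t tail. Degenerate inputs return sentinels instead of
raising so pipeline stages can filter: both groups constant and equal →
(t = 0, p = 1); both constant but different → (t = ±inf, p = 0). At very
small group sizes (n ≤ 4) the Satterthwaite approximation makes the test
mildly conservative; the null-calibration test therefore uses n = 10 per
group, where the nominal level is accurate.

**Benjamini–Hochberg** is the literal step-up: q_(i) = min_{j≥i} p_(j)·n/j,
clipped at 1, mapped back to input order via a stable sort, which makes the
output equivariant under permutation of the inputs.

## Phosphoproteome quantification

Reporter intensities are treated as log-normal, so every aggregation is a
(weighted) geometric mean, i.e. arithmetic on logs with a final
back-transform: natural log internally, log2 for reported fold changes.

Chain: (1) filter fragments lacking an isobaric label, flagged as sharing
MS/MS spectra, below the intensity floor (default: 1% quantile of all
intensities — the source protocol names no threshold), or with
identification confidence not strictly above 0.95; (2) bias-correct channels
to the grand mean of the original channel totals (equal-total-signal
assumption), an idempotent rescaling; (3) combine the fragments covering a
site by geometric mean; (4) integrate peptides onto sites by a weighted
geometric mean, with weights the inverse of the estimated variance of each
peptide's per-channel mean log intensity (a stand-in for vendor "error
factors", whose exact formulas are proprietary; uniform weights are a config
fallback, and peptides with a single fragment default to weight 1);
(5) compute per-channel log2 ratios against the geometric mean of the
control channels, test case vs control per site with Welch, and BH-adjust
across all tested sites. Calls at q < 0.05 with N = 3 channels per group as
the default design.

A modelling caveat that matters: equal-total bias correction assumes the
differential signal mass is negligible or balanced. If 5% of sites carry a
uniform 4-fold increase, the correction shifts *every* log2 ratio by
−log2(1.15) ≈ −0.20 and inflates null calls. The planted-effect scenario
therefore spikes half its sites up and half down — consistent with real
phosphoproteomes, where both directions occur, and with the assumption the
correction itself encodes. Residual compositional shift at the default
scenario is log2(1.056) ≈ 0.08 per site and cancels in the signed mean.

## Exon skipping

Coordinates are 0-based half-open. Inclusion requires ≥ 1 bp block overlap
with the exon body (so a junction-spanning read from exon i to i+1 counts as
inclusion for both via its blocks); skipping requires a junction matching
the annotated end of exon i−1 and start of exon i+1, exactly by default,
with a configurable ±bp tolerance since "overlapping a splicing junction" is
not a precise rule. Skipping is defined only for internal exons. Strand is
ignored for counting.

Replicates are summed within each group before the 2×2 table is built (one
count per cell). Exons with any zero cell are excluded from testing *and*
from the BH family (not assigned p = 1), which keeps the family to exons
where the ratio is computable; the exclusion count is logged. Effect size
L = log2((S/I)_case/(S/I)_ctrl) is antisymmetric under group swap and NaN
when not computable. RPKM is provided for expression-level reporting.

Overlap between two comparisons is the intersection of their significant
(gene, exon) sets; "recovery" in the treated arm means loss of significance
(q ≥ threshold or untestable) rather than ratio reversion — reversion toward
0 is a defensible alternative reading and can be scored from the same result
tables, but non-significance is the default because the calling rule is the
study's operative definition of a splicing change.

## Kinase-downstream enrichment

The downstream set is all nodes within shortest-path distance ≤ 2 of any
seed kinase (degree-1 and degree-2 pooled into one stratum). Seeds are
excluded from the contingency table by default — they are the hypothesis,
not evidence — with a flag to include them. Undetected proteins never enter
the table. An empty stratum yields a NaN-p sentinel rather than an error so
calibration loops can skip degenerate graphs.

## Network ranking

The pathological network is the one-step expansion of the selected genes on
the database graph ("one additional edge and node" per selected node read as
neighborhood expansion; adding literally one node does not scale). Node
scores are unnormalized betweenness (the top-25% rule is scale-invariant, so
normalization is moot); pairs in different components contribute nothing.
Core = the ceil(0.25·n) highest scores, with boundary ties all included and
a secondary sort by node ID for deterministic reports. Betweenness is
computed on the expanded graph; restricting the *report* to selected genes
is a presentation choice the caller makes.

## GO enrichment and term grouping

Term enrichment is the plain hypergeometric upper tail (the EASE-style k−1
deflation used by some web tools is deliberately not the default), BH across
all tested terms, enriched at q < 0.01. The universe defaults to all genes
in the annotation table and is configurable to the tested-gene universe.
"Commonly annotated genes" is formalized as Jaccard distance between term
gene sets; Ward linkage is applied to that precomputed distance matrix via
the Lance–Williams recurrence. Ward on a non-Euclidean Jaccard matrix is a
pragmatic convention, documented as such; the merge tree is emitted in
Newick for inspection. No ancestor propagation over the GO graph is
performed.

## Synthetic-data generators

All simulators are pure functions of their config including the seed;
stage substreams derive from one global seed by hashing a stage label into a
`SeedSequence` (so any stage can be rerun alone, reproducibly).

* **Reporter matrix**: intensity = bias_k · base · 2^(δ·[case]) · exp(ε),
  ε ~ N(0, sd²), sd = 0.1 by default; one site per protein, 2 peptides × 3
  fragments; 3 case + 3 control channels (the replicate design of the study
  type this emulates). Planted δ are the ground truth for recall/bias
  measurements.
* **Junction counts**: I ~ Poisson(depth·ψ), S ~ Poisson(depth·(1−ψ)),
  depth 100, baseline ψ = 0.8, 3 replicates per group; spiked exons use
  ψ_case (default scenario 0.2, forcing a planted L of exactly 4).
  Poisson is chosen for tractable planted truth, not as a claim about
  overdispersion in real data.
* **Spliced reads**: non-overlapping exon models (100 bp exons, 100 bp
  introns, genes on disjoint coordinate ranges) with inclusion reads inside
  exon bodies and skipping reads joining the annotated flanking boundaries;
  the returned ground truth includes the inclusion credit a skipping read
  gives the flanking exons it touches, and the counting stage must reproduce
  it exactly.
* **PPI graphs**: Erdős–Rényi (n = 250, p = 0.016, mean degree ≈ 4) with
  change probability 0.8 within ≤ 2 degrees of the two seed kinases and 0.1
  outside (planted odds ratio 36).
* **Annotations**: terms draw Poisson-mean-sized random gene subsets.

What these generators do **not** emulate — and hence what green tests do not
establish about real data: overdispersed or correlated counts, isoform
structure beyond single-exon skipping, sequencing error and mapping
ambiguity, peptide identification error, missing values and
intensity-dependent variance in MS, scale-free PPI topology, and the
hierarchical dependence of real GO annotations. The pipeline's operating
characteristics on real data can differ accordingly; the simulators
establish correctness of the computations and calibration under their
stated models.

## Demo scenario and problem sizes

The packaged end-to-end demo uses 1000 phospho-sites with 50 spiked at
|log2 FC| = 2 (balanced signs, planted channel biases), two disease models
sharing 50 spiked exons out of 2000 (ΔPSI 0.8→0.2), a treated arm with 40%
of the shared exons reverted to baseline, three planted GO terms over 100
random ones, and a planted hub node wired to the selected genes. These sizes
give stable recovery of every planted quantity in seconds on one CPU while
keeping every statistical family large enough for BH behaviour to be
realistic. The acceptance script (`scripts/acceptance.py`) re-measures all
of these from scratch for any seed.

## Known limitations

* The vendor's exact bias/error-factor formulas are proprietary; the
  inverse-variance weighting here is a documented stand-in.
* Fisher-on-pooled-counts treats replicate sums as one sample and is
  conservative at these depths; it does not model biological replicate
  variability (no dispersion estimation).
* The top-25% betweenness rule and the one-step expansion reproduce the
  procedure, not any particular published gene list, which would require the
  specific historical interaction-database snapshot.
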