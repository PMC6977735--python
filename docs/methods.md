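# Methods

This note documents the statistical models, the simulators' generative
assumptions, the defaults and their rationale, and the known limitations of
the pipeline. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## MeD-seq read model and positional filter

MeD-seq libraries arise from digestion with the methylation-dependent
restriction enzyme LpnPI, which cuts near methylated CpG-containing sites;
after size selection the fragments are ~32 bp and are sequenced as 50 bp
single-end reads, so the recognition site sits at a characteristic distance
from a read end. The filter keeps a read iff the recognition motif occurs at
a 1-based offset d ∈ [13, 17] (inclusive on both sides) from the 5′ end —
measured to the motif's **first** base — or from the 3′ end — measured from
the 3′ terminus to the motif's **last** base. The source protocol does not
pin down whether the distance refers to the first base, the last base or the
cut position; the symmetric first/last convention used here is a documented
choice and is configurable through `window_min`/`window_max`.

The recognition motif is modeled as the CpG dinucleotide (the
methylation-dependent core of the LpnPI site) rather than the full enzyme
context, which suffices to exercise every pipeline stage; the motif string
is configurable. N bases never match.

**Site assignment.** Retained reads are matched exactly (both strands,
no mismatches or indels) against the reference via a k-mer index — a naive
exact mapper adequate for desk-scale references, not a replacement for a
production aligner. Reads matching more than one locus are dropped
(deterministic counts), as are reads whose in-window motif occurrences map
to more than one genomic CpG site: when a second CpG happens to sit in the
other end's window the true fragment origin is unidentifiable, and any
deterministic pick would be wrong about half of that subset. Dropping them
keeps the per-site counts essentially free of misassignment at the cost of
a few percent of depth (both are tallied in the assignment stats).

## Region classes

Per gene (one TSS/TES per annotation record — no isoform resolution): a TSS
region `[tss − 1000, tss + 1000)` and a gene body from 1 kb past the TSS, in
the direction of transcription, to the TES; genes shorter than 1 kb yield no
body region. CpG islands are scored as given. All coordinates are 0-based,
half-open; BED output stays 0-based, FASTA/GTF convert at the boundary.
Regions are clipped, not dropped, at contig edges. A site inside two
overlapping regions contributes its full count to both — the three classes
are scored independently, and no apportioning is attempted.

## Differential methylation

Within each group, sample counts are **pooled by summation** before testing;
the χ² compares pooled region (or site) counts against pooled library
totals, 1 df, no continuity correction. Degenerate tables (both pooled
counts zero, or equal to their totals) return χ² = 0, p = 1. The fold change
carries a +1 pseudocount in both numerators so zero counts give finite,
direction-preserving ratios; direction is hyper (recurrent > primary) when
the fold exceeds 1.

The genome-wide scan tests every site present in any track, adjusts the
per-site p-values (BH by default; Bonferroni available), and bins runs of
significant sites that share a direction, tolerating at most `max_gap`
non-significant sites inside a run; an opposite-direction significant site
always starts a new bin. A bin spans first-to-last significant site (+2 bp
to cover the dinucleotide), reports the number of significant member sites,
recomputes fold change and χ² over all counts in the span, and inherits the
smallest member-site adjusted p. Default thresholds are `min_sites=4`,
`min_size_bp=100`, `min_fc=1.5`, `max_gap=0`; all are exposed, and a
fold-change ≥ 2 preset reproduces the subgroup design used for
high-DMR-count comparisons. The fold-change gate keeps a DMR when its fold
lies outside the band `(1/min_fc, min_fc)`, so `min_fc=1` reduces the rule
to significance only.

**Limitation (pooling).** Because samples are pooled, between-sample
biological variability is not modeled: under per-sample methylation noise
the pooled χ² is anticonservative (the acceptance calibration measures
~9% raw p < 0.05 at nominal 5% when Beta noise with concentration 50 is
present). Type-I calibration therefore holds for the count-sampling null
the test actually addresses — identical expected methylomes with Poisson
counts — which is what the null-calibration experiments generate. Results
on real replicated cohorts should be read as enrichment scores, not
replicate-aware inference; a beta-binomial model is out of scope. Copy
number changes are likewise indistinguishable from methylation changes in
count data of this kind.

## microRNA processing

Detectability is Ct ≤ 35 by default (common TLDA practice; configurable).
Normalized expression is −(Ct − median Ct of the sample's detectable
miRNAs); since qPCR chemistry doubles per cycle, −ΔCt is already log2
relative expression and no further transform is applied. The per-sample
median of detectable values is 0 by construction. miRNAs detected in fewer
than 50% of **all** samples (boundary inclusive) are excluded. Missing
values are never imputed; each miRNA's paired test uses pairwise-complete
pairs and reports the pair count used, with miRNAs under `min_pairs=5`
left untested (NaN). Zero-variance differences are reported as p → 0
(nonzero mean) or p = 1 (all differences exactly zero) with an explicit
flag. Significance is the dual threshold p < 0.05 **and** BH q < 0.25.

**Batch adjustment.** The default is a deterministic per-miRNA
location-scale adjustment: standardize within batch, restore the miRNA's
overall mean and pooled within-batch standard deviation; batches
contributing one value to a miRNA are left unadjusted (logged), and
zero-variance batches are recentered. A parametric empirical-Bayes mode
(`mode="eb"`) shrinks the per-batch location/scale estimates across miRNAs
toward normal / inverse-gamma priors (the ComBat model) before removal.
Note that a *uniform* additive batch offset on the Ct scale is already
canceled by median normalization; what batch adjustment removes is the
miRNA-specific residue. Sample exclusion (e.g. after visual PCA review) is
an explicit list passed by the caller, never an automated rule.

## Clustering and pair cohesion

Dissimilarity is 1 − Pearson correlation computed over pairwise-complete
features (≥2 shared observations required, matching Cluster 3.0 practice),
or Euclidean distance over shared features rescaled by
`n_features/n_shared`; agglomeration is scipy's average linkage by default
(complete and single available), deterministic with scipy's tie-breaking.
Trees serialize to Newick with branch lengths from merge heights.

"A pair clusters together" is operationalized as **direct siblinghood**: the
pair's two leaves merge with each other at their first join. This is the
strictest reading of the pictorial definition (adjacent red-square pairs in
a heat map) and is deliberately conservative; supervised clustering means
clustering restricted to a supplied feature list, not a different algorithm.

## Cohort statistics

Quantiles default to the (n+1)-based "exclusive" rule — rank h = q(n+1),
linear interpolation, clipped to [1, n] — which is how clinical IQRs are
conventionally reported and which reproduces the packaged cohort's printed
median/IQR values exactly; the (n−1)-based rule and the other numpy methods
are selectable. Localization classes: extremity = {upper leg, lower leg},
retroperitoneum = {retroperitoneal}, everything else (axilla, mediastinum,
esophagus, trunk) = other. Margin codes are the four-level R classification
(R0/R1/R2/Rx); counts are tallied separately for the primary and the
recurrent surgery. The 27-pair WDLPS clinical table ships as a packaged
fixture.

## Simulators

Every generator is a pure function of (configuration, seed) and emits a
truth record of what it planted.

* **Reference**: sequence is built unit-wise — emit `CG` with probability
  q = d/(1−d), else a single base that never completes a CpG — so every CpG
  is planted and the realized density concentrates at d. Islands are
  stretches generated at a higher density (default 0.10) with the
  background density lowered to keep the global CpG budget at
  `cpg_density × length`. Genes are placed one per equal-width slot with
  random strand. Defaults: 1 contig × 50 kb, density 0.02, 10 genes, 5
  islands — desk-scale stand-ins chosen so per-site tests see ~1000
  features.
* **Methylomes**: one baseline level per site ~ Beta(1.5, 3.5) (mean 0.3)
  shared by all samples; per-sample Beta noise with concentration 50 (mean
  preserved; infinite concentration = noise-free). Planted intervals
  multiply the recurrent group's expected level by the fold, clipped to
  [0, 1] — so high-baseline sites saturate and their effective fold shrinks,
  as with real methylation proportions.
* **Reads**: per site, Poisson(mean_depth × level) fragments; the site's C
  is placed uniformly at offset 13–17 from the 5′ or 3′ end, strand
  random; 5% off-motif background reads by default (rejection-sampled to
  fail the positional filter) to exercise the filter; fragments that would
  run off a contig edge are skipped. Read names encode the true origin
  site. Defaults for depth are free parameters (the source protocol states
  no library sizes); recovery experiments use depth 150 so that even
  low-baseline sites carry power, calibration experiments use depth 30.
* **Ct matrices**: per-miRNA baseline ~ U(20, 34) Ct; per-well Gaussian
  noise (sd 1); a per-pair random effect (sd 1) shared by a patient's two
  samples — it cancels in paired differences but makes tumor pairs
  correlate, which is what drives pair cohesion in clustering; per-batch
  additive offset and scale (pairs never straddle batches); censoring
  above the detectability cutoff. The `(n, delta)` convenience form plants
  shifts with **alternating directions**: balanced up/down differential
  expression is the validity condition of global median normalization —
  planting all shifts one way biases the per-sample median and propagates
  a small spurious shift into every null miRNA, visibly inflating the
  realized FDR. Signed per-miRNA dictionaries allow unbalanced designs
  when that bias is itself the object of study.
* **Clinical tables**: marginals mirror a surgical WDLPS cohort (age ≈
  N(58, 11), time to recurrence ≈ lognormal with median 3.7 y,
  extremity-heavy localization mix, margin-code frequencies); recurrent
  age = primary age + rounded time to recurrence.

**What the simulators do not model** — and hence what passing tests do not
show about real data: hg38-scale genomes and mappability, LpnPI's actual
offset cleavage chemistry and full recognition context, adapter ligation
and sequencing errors, FFPE degradation, copy-number aberrations
(explicitly confounded with methylation in this assay), preamplification
bias in TLDA, and intra-tumor heterogeneity.

## Numerical and experiment-design choices

* Degenerate χ² tables short-circuit to (0, 1, fold) rather than raising.
* BH/Bonferroni adjustment delegates to statsmodels; the test suite checks
  it against a hand-computed step-up.
* Experiment sizes in the acceptance script are desk-scale by design:
  ~1200-site references, 4 pairs for methylation, 26 pairs × 700 miRNAs,
  with 20 null replicates, 5 DMR-recovery replicates and 100
  miRNA-recovery replicates. Sensitivity and observed FDR are reported as
  Monte-Carlo means across replicates because single-replicate realized
  FDR scatters around the BH expectation q·m0/m (≈ 0.239 at the operating
  point) with a spread of ~0.06 — a point draw would sit above 0.25 about
  half the time even for a perfectly calibrated procedure.
* All randomness flows from `numpy.random.default_rng` seeded per
  generator; derived seeds stay below 2^31.
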