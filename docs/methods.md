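# Methods

## The peak-calling model

The caller reproduces the classical threshold rule for two-colour tiling
ChIP-chip rather than a model-based approach (no HMM, no sliding-window
statistic, no peak FDR): that simplicity is deliberate, because the rule is
itself part of the analysis being reproduced. For one hybridisation the
probe values are the linear Cy3(IP)/Cy5(total DNA) ratios; the calling
threshold is

    t = mean(ratios) + k_sd * sd(ratios),      k_sd = 2.5 by default,

with the sample (n−1) standard deviation — at tens of thousands of probes
the distinction from the population SD is negligible, but a convention has
to be fixed. The mean/SD are computed per hybridisation by default: each
array has its own noise scale, and a global threshold would let a noisy
replicate dominate. A pooled mode (mean/SD over all supplied tracks) is
available as a flag since the per-array reading of "the mean of all
signals" is one of two defensible interpretations. Ratios can optionally be
log2-transformed before thresholding (`use_log_ratio`), which is more
faithful to the multiplicative noise, but the default operates on linear
ratios as the original rule does.

A peak is a maximal run of at least `min_run = 2` probes above threshold.
"Consecutive" requires both adjacency in track order *and* a genomic
centre-to-centre gap of at most `max_probe_gap_bp` (default: twice the
track's median probe spacing), so array coverage gaps cannot bridge
unrelated probes. Runs of length 1 are discarded entirely.

Reproducibility and control subtraction: peaks from the per-experiment sets
are clustered by single-linkage ≥ 1 bp overlap (no merge rule is inherent
to the threshold rule, and single-linkage overlap is the weakest assumption
that still merges jittered replicate peaks). A cluster is reported when it
is supported by at least `min_replicates = 2` distinct experiment labels;
the caller chooses whether labels denote replicates within a timepoint or
all replicate × timepoint hybridisations. Any cluster overlapping ≥ 1 bp of
any control peak — at any timepoint, since a control artefact is an
artefact whenever it appears — is excluded from the reported set and kept
in a diagnostics list. The region interval is the union of member peaks.

Target assignment: a region is *intergenic* iff it overlaps no gene. On
each side the nearest gene is found (right: smallest start at or beyond the
region start; left: largest end at or before the region end) and is a
target only if its strand points away from the region, i.e. the region is
promoter-proximal upstream of it. Divergent intergenic gaps therefore yield
two targets, tandem gaps one, convergent gaps none (logged, never dropped
silently).

## Expression analysis

The matrix holds log2 intensities (gene × strain × timepoint × replicate);
normalisation per gene to the median subtracts each row's median in log2
space. Replicates are summarised by the mean of log2 values before fold
computation, so

    fold_induction  = 2^(mean log2 T30 − mean log2 T0)
    fold_repression = 2^(mean log2 T30 − mean log2 T45)

Fold repression is T30 relative to T45 — expression falls after ammonium
re-addition — which is the orientation consistent with the canonical
strongly induced/repressed ammonium-transporter profile (76.4-fold induced,
15.0-fold repressed). Because fold changes depend only on within-gene
differences they are invariant under median centring (tested as a
property).

The dual response filter passes genes with both folds > θ (default 2).
"Non-responsive in the mutant" has no unique numeric definition; it is
operationalised as failing either arm of the dual filter at a separate
threshold `theta_responsive_mutant` (default 2), exposed as a knob, and
both the WT and mutant calls are returned so alternative definitions can be
audited. Raising the WT threshold can only shrink the dependent set
(tested).

Two-way ANOVA (genotype × time) is the classical fixed-effects
decomposition from sums of squares, vectorised across genes for balanced
replicated designs; unbalanced designs fall back to a per-gene type-II OLS
ANOVA via statsmodels (which also serves as the independent cross-check of
the balanced path in the tests). Genes with zero total variance get F = 0
and p = 1 by convention so they can never reach significance.
Benjamini–Hochberg step-up is applied per effect across genes, with
significance flags at α = 0.05 (0.01 also supported).

## Motif model

The operator is modelled as two 5-bp IUPAC half-sites with a spacer length
range: strict `GTNAC-n6-GTNAC`, the consensus derived in vivo; relaxed
`KTNAC-n6-GWNAC`, covering the observed variants in which the first
half-site starts with T or the second is the `GaAAC`-style "b-site"; and a
wide mode (spacer 6–18) for the two-a-site arrangement 18 bp apart seen at
nitrate-reductase promoters. De novo discovery (EM/Gibbs) is out of scope:
the consensus is the *product* of the discovery step and is what downstream
analysis consumes, so it is encoded directly and complemented with PWM
scoring trained on the annotated bound sites.

Scanning is case-insensitive, reports all matches on both strands for every
spacer length (reverse-strand hits in forward coordinates), and never
matches ambiguity codes in the subject. Since `GTNAC` is its own reverse
complement as a pattern, every strict hit has a mirror hit on the opposite
strand over the same footprint; `dedupe_palindromic` collapses these, and
site counts are counts of distinct footprints.

Promoter windows are 250 bp centred on the region midpoint, clipped at
replicon ends with the clipped length recorded. PWMs use a pseudocount of
0.5 per base per column (a neutral Laplace-style prior that keeps log-odds
finite without overwhelming small site sets); base counting goes through
Bio.motifs. Per-column information content is Shannon IC (2 − H, in
[0, 2] bits); log-odds scoring uses log2(freq/background) with the
background defaulting to uniform but intended to be set from the subject
genome's mononucleotide composition — the genomes in question are ~70% GC,
where a uniform background substantially mis-scores AT-rich positions.

## Regulon integration

Binding, response and dependence combine by truth table into categories
i–iv (see README). A gene is "bound" if it is a target of any reported
region at any timepoint (the published-style region table is a
cross-timepoint union). Genes responsive in expression but with no mutant
data are reported as category "none" with an explicit flag rather than
dropped; genes responsive in neither strain are likewise "none", kept
distinct from category iii. Classification is order-independent and
idempotent, and the categories partition the classified genes (tested as
properties).

## The synthetic-data generator

The generator emulates the features the analysis depends on:

* **Genome** — a linear 1 Mb replicon (default) at 70% GC carrying 300
  non-overlapping genes of 600–1400 bp with random strands, so divergent,
  convergent and tandem gaps all arise. Planted sites sit at the centres of
  intergenic gaps ≥ 1.5 kb that have at least one downstream target, with a
  strict-consensus operator instance embedded in the sequence.
* **ChIP tracks** — 60-mer probes every 180 bp (the density of a
  44,000-probe array over a full-length genome). The expected probe ratio
  is `1 + Σ_sites (fold − 1) · w(d)` with `w` a triangular kernel of 500 bp
  half-width — the modal sonication fragment length (fragments 300–1000 bp
  centred on 500 bp); only the fragment-size distribution is known, so the
  kernel shape is a modelling choice, and a triangle is the simplest
  footprint consistent with fragments centred anywhere over the site.
  Multiplicative log-normal noise (sd of log2 ratio 0.25, a realistic
  two-colour array noise level) is applied per probe. Two IP replicates and
  one empty-vector control per timepoint; 20 planted sites with enrichment
  folds drawn from [4, 10]; no enrichment at T0 except one designated
  persistent site (full enrichment at all timepoints, emulating the
  constitutively bound housekeeping glutamine-synthetase promoter), and
  full enrichment at T30 *and* T45 for the rest (binding is promoted by
  starvation but not abolished by ammonium re-addition). Three artefact
  sites are enriched in IP and control alike, exercising control
  subtraction.
* **Expression** — WT and mutant strains, T0/T30/T45, three biological
  replicates, i.i.d. Gaussian log2 noise (sd 0.25). 30 planted dependent
  genes (induction folds in [4, 80], repression in [4, 16]; the first gets
  the reference pair 76.4/15.0 so the headline fold changes are reproduced
  by construction), 30 independent-responsive genes (respond in both
  strains), 200 null genes. Ten dependent and ten null genes are designated
  bound, so the planted design populates all four categories
  (i/ii/iii/iv = 10/20/30/10 in the expression-only scenario).

All randomness flows from the single scenario seed; identical scenarios
yield byte-identical files. What passing tests on these simulations show is
that the pipeline recovers a *planted* signal of the stated effect sizes
under multiplicative/Gaussian noise of the stated level — they do not
certify behaviour under real-array features the generator omits: probe
sequence effects, dye bias, spatial artefacts, correlated noise, or RNA
half-life effects that make induction and repression asymmetric in real
data.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GFF3 is read/written
  1-based inclusive, BED/bedGraph 0-based half-open. Circular replicons are
  treated as linear.
* Non-finite or non-positive ratio values are dropped at load time with a
  logged count; a track with < 2 probes cannot be thresholded (error).
* Overlapping/nested genes are unioned before taking the intergenic
  complement, so they never create spurious regions; zero-length gaps are
  omitted.
* Top tables break fold-induction ties by lexical gene id (documented,
  deterministic).
* ANOVA sums of squares that go slightly negative through cancellation are
  floored at zero.
* Fixture tables are packaged as TSV with `n/a` kept literal (not NaN) and
  multi-site cells split into their 16-bp full sites; their checksums are
  asserted in the tests.

## Problem sizes

The default test-suite and acceptance runs use a 1 Mb genome (~5,500
probes per track, 9 tracks), 260-gene expression matrices, 200 random
500-probe tracks and 100 random 5-kb sequences for the oracle comparisons,
and a 1,000-gene null matrix for the FDR check — sizes chosen so the whole
study runs in seconds while keeping every rate estimate (recovery,
false-call, FDR) on a denominator large enough to be meaningful.

## Known limitations

* The exact published 27/9 split of regions with/without consensus sites is
  reproduced from the packaged table annotation; re-deriving it de novo
  would require the original discovery tool and its (unpublished)
  parameters.
* The peak rule has no statistical error control; it is reproduced as-is.
* The mutant-comparison machinery makes no attempt to reproduce analyses
  whose significance criterion is undefined (e.g. a GlnR-paralogue mutant
  comparison reported without a stated cutoff).
* Unbalanced ANOVA designs take the per-gene OLS path, which is orders of
  magnitude slower than the vectorised balanced path.
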