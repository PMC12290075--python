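# Methods

This note documents the models, algorithms, parameter choices and
limitations behind `imctc`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Count model and synthetic genomes

The simulator emulates sparse single-cell whole-genome sequencing summarised
at the bin level.  A genome is an ordered set of `n_bins` half-open,
variable-length bins (gamma-distributed lengths, CV 0.3, around a 600 kb
mean) partitioned over chromosomes with human-karyotype-like size ranking
for 24 chromosomes; GC fractions are Beta(2.5, 3.5) rescaled into
(0.2, 0.8).  Coordinates are abstract: the analysis depends only on bin
structure, not on a reference assembly.

Given an integer copy-state vector (baseline ploidy 2) the expected count
in bin *b* is proportional to

    state_b × length_b × bias(gc_b),

with `bias` a multiplicative quadratic polynomial in GC.  At `dispersion=0`
a cell's counts are one multinomial draw of `total_reads` (per-bin marginals
Poisson-like); for `dispersion=d>0` each bin's rate is multiplied by an
independent Gamma(1/d, d) variate before Poisson sampling, giving
negative-binomial-style overdispersion.  Defaults: `total_reads = 1e6`
(depth is not a quantity the analysis depends on — only ratios are used —
so this is a convenience choice, not a fidelity claim), flat bias, no
overdispersion.  Fusion cells are literal element-wise sums of two parents'
counts, so a fused cell's expected profile is the sum of its parents'
expectations by construction.

The packaged "index clone" carries 1p loss, 1q gain (covering the PTPRC
locus), 4q loss, a chromosome-8 firestorm, 16p gain and 16q loss.  A
firestorm is simulated as ≥ 4 alternating single-copy gain/loss blocks
tiling one chromosome — a minimal stand-in for the dense oscillating
pattern of rearranged breast-cancer chromosomes; the literature does not
fix a quantitative definition.

What the generator does **not** emulate: amplification artefacts of
whole-genome amplification (dropout, chimeras), mappability structure,
replication timing, correlated GC waves, segmented-duplication bins, or
subclonal heterogeneity within a patient.  Tests passing on this generator
show the analytics are correct under the stated count model, not that the
pipeline is robust to every artefact of real single-cell libraries.

## GC correction and ratio normalisation

Counts are first length-normalised (divided by bin length, rescaled to the
mean length).  The GC trend is a lowess fit (span 0.3, one robustness
iteration, interpolation delta of 1% of the GC range) of length-normalised
count on GC for ≥ 100 bins, or a quadratic least-squares fit below that.
Counts are divided by the trend (floored at 1% of the mean to avoid
blow-ups in empty GC strata) and rescaled so the overall mean is preserved.
Ratios are then counts divided by the genome-wide mean, so every profile
has mean exactly 1 (asserted at construction).  The original pipeline's
exact normalisation is not public; no numerical fidelity to it is claimed,
only to the stated behavior (GC detrending, mean-ratio scale).

## Circular binary segmentation

Per chromosome, on log2(ratio + 1e-6) (variance stabilisation; segment
means are reported back on the linear scale):

1. Find the circular arc [i, j) maximising the pooled-variance two-sample
   t² between in-arc and out-of-arc bins.  Because the complement of an arc
   is an arc, scanning i < j covers all circular splits.  Admissible arcs
   leave every resulting segment ≥ `min_width` (default 3) bins.
2. Accept the split if its permutation p-value is below `alpha`
   (default 0.01): bins of the segment are permuted `n_perm` (default 1000)
   times and the maximal arc statistic recomputed each time;
   p = (1 + #exceedances) / (1 + n_perm) (add-one estimator).
3. Recurse into the up-to-three resulting segments.

Implementation detail that matters for speed: t² = (n−2)·BSS/(TSS−BSS)
where TSS is the total centered sum of squares (invariant under
permutation) and BSS = n·u²/(n₁n₂) with u the centered arc sum — t² is
strictly monotone in the arc score u²/(n₁n₂), so both the arc scan and the
permutation comparison run on that score with one prefix-sum per sequence.
The test suite verifies the chosen arc and its t² against an independent
exhaustive scipy-based scan.  Permutations are evaluated in vectorised
blocks and stop early once the exceedance count already guarantees
rejection; this cannot change any accept/reject decision.  A zero-variance
split with unequal means (noise-free step) maps to t² = ∞ and is accepted
whenever no permutation ties it.

No post-hoc segment merging is applied by default; `merge_pruning=True`
merges adjacent segments whose log2 means differ by less than
`merge_sd_mult` (default 2) pooled residual SDs.  Integer states are
`floor(mean_ratio × ploidy + 0.5)` — halves round up, so a 1.25 ratio at
ploidy 2 calls state 3 — floored at 0.

## Fusion assessment

`expected_ratio(s, fused)` returns s/2, or (s+2)/4 under fusion — the
small-altered-fraction approximation for a near-diploid tumor fused 1:1
with a diploid cell at equal per-genome depth.  Deviations from those
assumptions (aneuploid mean ploidy, unequal depth) shift the fusion
expectation; they are surfaced through the attenuation value itself rather
than corrected.

The attenuation statistic regresses query bin deviations on clonal
reference **segment-mean** deviations (slope through the origin).  Using
segment means rather than the reference's noisy per-bin values avoids
errors-in-variables attenuation bias — the reference is a consensus over
many epi.CTCs, so its segment means are nearly noise-free.  Bins on chrX
are excluded by default because partial/complete X loss is subclonal in
these tumors and would contaminate the clonal reference.  Cells with fewer
than `min_informative = 50` usable bins are reported `uninformative` (the
attenuation field is set to 0.0 to keep it finite).  The verdict threshold
0.75 is the midpoint of the two hypotheses' expectations (1.0 vs 0.5).
The attenuation statistic is this package's formalisation of a comparison
that is often made visually; the threshold is configurable.

Clonality: non-neutral segments from all cells are linked when they share a
chromosome and direction with reciprocal overlap ≥ 0.5; connected
components carried by ≥ 50% of cells are clonal events, and a cell is
flagged clonal when it carries ≥ half of them.  Union-find over the full
link graph makes the result independent of cell order.

## Immunofluorescence classification

CK positivity is slide-wise: mean CK strictly greater than the slide mean
plus 6 population standard deviations (population rather than sample SD —
over millions of cells the distinction is negligible, but a convention must
be fixed; all cells on the slide enter the statistics, including
candidates).  The threshold is affine-equivariant, so calls are invariant
under linear intensity rescaling.

The CD45 classifier is a one-covariate logistic regression on mean CD45
intensity, fitted with an L2-stabilised maximum-likelihood solver
(penalty λ ≈ 1e-6, i.e. effectively unpenalised but finite under perfect
separation).  The annotated set is split stratified 2:1 into training and
held-out test; repeated stratified 5-fold CV (5 repeats) on the training
split provides the accuracy record, the final model is refit on the full
training split, and held-out accuracy is reported.  Cells are called CD45+
when the predicted probability strictly exceeds 0.5; a cell exactly on the
decision boundary is CD45−.  Fold mechanics in the original workflow are
not published; the stratified, seeded scheme here is the package's own
documented convention.

## Imaging mass cytometry

Masks are kept when area ∈ [40, 200] pixels (inclusive at both ends — the
plain reading of "between 40–200"; configurable) and DNA1 ≥ 4; rows marked
as pre-identified im.CTC/epi.CTC bypass the filter because only the
remaining, unmatched masks are being triaged.  Markers are normalised by
their 99th percentile (linear-interpolation definition; zero-percentile
columns are left unscaled and flagged) without clipping; arcsinh with
cofactor 1 is applied for gating and display, while clustering runs on the
percentile-normalised counts (the literal reading of the source workflow's
order of operations).

Clustering is Phenograph-style: Euclidean kNN graph (k = 30), edges
reweighted by the Jaccard overlap of neighbour sets, Louvain modularity
maximisation with a seeded order.  The modularity resolution defaults to
0.2 rather than the textbook 1.0: at resolution 1 Louvain fragments the
dense kNN graph of a single homogeneous population into arbitrary
sub-communities, whereas the readout wanted here is one community per
population.  Lowering the resolution merges only connected substructure —
merging two communities with no connecting edges can never raise
modularity at any resolution — so well-separated populations are never
collapsed by this choice.

Gates live in YAML (`imctc/resources/gates.yaml`), not code: the original
manual thresholds are unrecoverable, so only the gate *structure* is
reproduced (CD45/CD3/CD14+CD68/CD20/CD56 lineages with CK8/18 as negative
exclusion; CD4/CD8 resolved only within CD3+).  A cell takes the deepest
gate it satisfies; a cell matching an internal node but none of its
children keeps the internal label (CD3+ CD4− CD8− cells stay "T cell");
cells matching nothing are "ungated", which is where CK8/18-high CTCs land
by design.  Spearman correlations use average ranks under ties; 2-marker
matrices are assembled explicitly since the scipy call degenerates to a
scalar there.

## Problem sizes in the shipped experiments

The experiment drivers (used by the analysis scripts, the end-to-end tests
and the acceptance script) run at the study's own scale where that is
cheap — 5000 bins, 24 chromosomes, 43 + 30 + 4 cells, 320 annotated cells,
22 markers — and choose the remaining free parameters once: cohort
segmentation uses `n_perm = 100` with mild overdispersion (d = 0.02) and a
quadratic GC bias (0.5, 2.0, −1.6); the noise-free compression readout uses
4e6 reads so multinomial noise is negligible against its ±0.03 bracket;
CBS operating characteristics use 100 runs of a 200-bin chromosome at
noise SD 0.05 with the full `n_perm = 1000`.

## Known limitations

* CBS here is the core recursive algorithm; it does not implement the
  published refinements (hybrid p-values, undo steps, change-point
  re-estimation), so exact segment boundaries can differ from other
  implementations on marginal splits.
* The fusion expectation assumes one diploid partner at equal depth;
  multi-partner fusions or heavily aneuploid tumors need the closed form
  a ≈ (1−w) interpreted per case.
* The clonality detector reasons over segment overlaps only; it does not
  model breakpoint uncertainty or copy-state magnitude beyond direction.
* Classification consumes per-cell mean intensities; pixel-level feature
  extraction and segmentation quality are upstream concerns.
* All performance claims are relative to the synthetic generator's count
  model (see above for what it deliberately leaves out).
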