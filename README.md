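# imctc

Single-cell analytics for **immune-like circulating tumor cells (im.CTCs)**:
CD45+/CK+ cells found in the blood of carcinoma patients that look like
leukocytes by surface phenotype but carry a tumor genome.

The central question this package addresses: when a cytokeratin-positive
blood cell also expresses CD45, is it (a) a tumor cell in an immune-like
state, (b) a tumor–leukocyte fusion, or (c) not a tumor cell at all?  The
package answers it from sparse single-cell whole-genome copy-number data and
marker-expression tables, with a fully synthetic data layer so every
component can be tested against known ground truth.

## The core statistic

Sparse single-cell WGS is summarised as read counts over ~5000
variable-length genomic bins.  After GC correction, each bin is expressed as
a ratio to the genome-wide mean, so a bin with copy state *s* in a
near-diploid genome has expected ratio *s*/2: a single-copy gain reads out
as 3:2 = **1.5**, a single-copy loss as 2:1 = **0.5**.

If the cell were instead a fusion of a tumor cell with a diploid leukocyte,
every bin gains two extra copies and the same events read out as
5:4 = **1.25** and 4:3 = **0.75** — a *compressed* profile.  The package
formalises this as the **attenuation statistic**: with x<sub>b</sub> the
clonal reference's segment-mean deviation (mean ratio − 1) at bin *b* and
y<sub>b</sub> the query cell's bin deviation,

    a = Σ x_b y_b / Σ x_b²   over bins in non-neutral reference segments,

the least-squares slope through the origin.  A true tumor cell gives
a ≈ 1, a 1:1 tumor–diploid fusion gives a ≈ 0.5 (in general a ≈ 1 − w for
diploid read fraction w), and a plain leukocyte gives a ≈ 0.  Cells are
called fusion-consistent below the midpoint threshold 0.75.

Around that sit the supporting components:

* `imctc.simulate` — bin maps, clonal truth profiles (including the index
  clone: 1p loss, 1q gain, 4q loss, chromosome-8 "firestorm", 16p gain,
  16q loss), multinomial/overdispersed read counts, fusion cells by count
  summation, immunofluorescence feature tables, IMC ion-count tables.
* `imctc.cnv` — GC correction (lowess), mean-ratio normalisation, circular
  binary segmentation with a permutation test per split, integer state
  calls, and the PTPRC-region Student's t comparison.
* `imctc.fusion` — expected ratios, synthetic fusion profiles
  (sum counts → GC-correct → re-normalise), attenuation, and clonality
  scoring across cells (shared-direction, reciprocal-overlap events).
* `imctc.classify` — slide-wide mean + 6 SD cytokeratin threshold, the
  CD45 logistic classifier (2/3 train split, 5-fold CV repeated 5 times),
  CTC enumeration per mL.
* `imctc.imc` — mask QC (area 40–200 px, DNA1 ≥ 4), arcsinh transform
  (cofactor 1), 99th-percentile normalisation, kNN–Jaccard–Louvain
  clustering, YAML-configured hierarchical gating, Spearman marker matrix.

## Worked example

The numbered scripts under `analysis/` run each arm of the analysis on
simulated data and write tables under `results/`.  For example:

```sh
$ python analysis/03_fusion_followup.py --seed 1
-- synthetic fusion compression --
tumor gain/loss segment ratios:  1.503 / 0.501   (expected 1.5 / 0.5)
fusion gain/loss segment ratios: 1.253 / 0.748   (expected 1.25 / 0.75)
attenuation over 100 noisy runs: tumor 1.001, fusion 0.499; verdict accuracy 100%
-- follow-up patient with clonal im.CTCs (7 im, 6 epi, 2 WBC) --
clonal events: 2; im.CTCs flagged clonal: 7/7
-- follow-up patient without clonal im.CTCs (9 im, private losses only) --
clonal events: 0; im.CTC candidates flagged clonal: 0/9 (these candidates do not look like tumor cells)
```

The first block is the fusion argument in miniature: summing a tumor cell's
bin counts with an equal-depth WBC's counts compresses its gain from 1.5 to
1.25 and its loss from 0.5 to 0.75, and the attenuation statistic separates
tumor cells (a ≈ 1) from synthetic fusions (a ≈ 0.5) with no verdict errors
at noise levels well above what averaging over segment bins leaves behind.
The follow-up blocks show the two clonality outcomes: im.CTCs sharing every
clonal event with the epi.CTC population versus CD45+/CK+ candidates whose
only alterations are private losses and which therefore carry no evidence
of tumor origin.

The other scripts cover CTC enumeration from slide-level fluorescence
features (`01`), the full 77-cell copy-number cohort with segmentation,
clonality and attenuation for every cell (`02`), and the IMC table pipeline
from mask QC through gating, clustering and marker statistics (`04`).

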