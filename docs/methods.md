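# Methods

This note documents the models, estimators and numerical choices
behind granulekit, in the spirit of the methods documentation of
simulation- and statistics-oriented scientific packages.

## Granule partition quantification

**Procedure.** Granules are segmented from a marker channel (a
constitutive granule protein) so that the query channel (the protein
whose partitioning is measured) never influences its own mask. Each
plane is band-pass filtered with a scale-normalized Laplacian of
Gaussian, `-σ²·LoG`, signed so bright blobs respond positively; the
response is thresholded and 4-connected components below a minimum
area are discarded. The partition coefficient is computed per confocal
plane as the ratio of query means over the granule and cytoplasm
masks, and summarized as mean ± sample SD over the planes that contain
both compartments (planes without granule pixels are skipped and
counted). Per-plane ratios use 2D connectivity; granule count/volume
statistics use 3D 6-connectivity — per-slice ratio analysis and
volumetric granule statistics are distinct questions.

**Thresholding.** The threshold is a single Otsu level computed on the
whole-stack LoG response and applied to every plane. Otsu always
splits a histogram, so recomputing it per plane marks roughly half of
a granule-free plane (pure noise response) as "granule"; a stack-global
level is anchored by the planes that do contain granules and leaves
empty planes empty. Per-plane Otsu remains available as
`threshold_method="otsu-plane"` for stacks with strong plane-to-plane
intensity drift.

**Parameters.** `log_sigma_um` (default 0.2 µm) should match the
granule radius scale; `min_area_px` (default 4) suppresses hot pixels;
the cytoplasm mask is the analysis region minus nuclei minus the
granule mask dilated by a 1-px guard band, since partial-volume pixels
at granule rims belong to neither compartment cleanly. The ring metric
uses a default band of 0.5 µm around the nuclear envelope and reports
the population SD of raw intensities along the ring; an intensity-
normalized variant would be a one-line change but raw SD is the
default because the ratio of SDs between conditions is what matters
and both conditions are imaged identically.

**Properties.** The ratio is invariant under multiplicative rescaling
of the query channel (gain, exposure) but not under additive offsets:
adding a constant c moves a plane's ratio from g/y to (g+c)/(y+c),
compressing it toward 1. Offsets (camera baseline) should therefore be
subtracted upstream; this behavior is tested.

**Pooling.** Per-plane ratios are pooled across all planes of a stack
rather than first averaged per nucleus; per-nucleus aggregation can be
performed by running the measurement per nucleus mask.

## In vitro condensate partitioning

Square ROIs of equal size (default 2.47 × 2.47 µm, six inside and six
outside condensates, chosen on the marker channel) define dense- and
dilute-phase samples. Each inside-ROI mean is divided by the average
query intensity over all outside ROIs. Inside ROIs containing bright
aggregates are excluded before ratios are computed; the default rule
excludes an ROI whose maximum exceeds 5× the median over all pooled
inside-ROI pixels, a deliberately conservative automated stand-in for
manual aggregate rejection, and every exclusion is recorded.

## Small-RNA target calling

A gene is a target of condition *c* iff for **every** replicate
*r*: `IP_rpm ≥ min_rpm` and `(IP_rpm + ε)/(input_rpm + ε) ≥
min_fold_change`, with defaults 5 RPM, 2-fold and ε = 0.1 RPM. The
pseudocount only matters for near-zero input genes; ε = 0 restores
strict division with an infinite fold change when input is 0 and IP is
positive. The RPM denominator is the supplied total-mapped-reads
library size when given, else the column sum; which one was used is an
explicit attribute of the experiment. The all-replicates requirement
makes calls conservative and monotone: raising either threshold can
only remove targets (property-tested).

Differential targeting between conditions is delegated to an external
count-model engine when available (its per-gene log2FC/adjusted-p
table is consumed through the `external` method); the built-in
`simple` method flags genes whose per-replicate IP log2 fold change
has consistent sign and |median| above a threshold, and exists for
self-contained simulation studies, not as a substitute inference
engine.

## Metagene profiles

Each target gene's positions map to 100 bins by `floor(p·100/L)`
(0-based, half-open), coverage is converted to RPM, the per-gene bin
value is the mean RPM over the positions in the bin (0 for bins left
empty by genes shorter than 100 nt), and the profile is the unweighted
mean over target genes — "mean coverage per bin" read as an average
over size-normalized targets, so long genes do not dominate. The
bookkeeping identity Σ_bins (bin mean × positions in bin) = total gene
RPM holds exactly and is tested against a per-position accumulation
oracle. Input-track profiles are computed per replicate and averaged.
Profile similarity is the Pearson correlation across bins.

## Gene-set enrichment

Two-sided Fisher exact p on the 2×2 overlap table (the standard
convention: the sum of probabilities of all tables, with fixed
margins, no more probable than the observed one), delegated to
scipy; the test suite verifies it against exact integer-arithmetic
enumeration of the full hypergeometric support for every margin
combination with universes up to 60. The effect size is
log₂(observed/expected) with expected = |A||B|/|U|. A continuity
guard ε = 0.5 enters **only** when the observed or expected overlap is
zero (otherwise log₂ of the plain ratio is reported, keeping round
numbers exact); whether the guard fired is recorded in the result.
The universe is a mandatory argument — inferring it silently from the
union of the sets changes every number and is a classic source of
irreproducible enrichment values. Matrix-wide BH correction uses the
step-up procedure; cells are additionally flagged at raw p < 0.05,
matching the common figure convention.

## Dipeptide bias scanning

G-rich segments are discovered by a low-probability window scan: every
window of length 15–500 whose focus-residue count has binomial
upper-tail probability ≤ `p_max` (default 10⁻³) under the background
composition is a candidate; overlapping candidates are merged and each
merged region is trimmed to its minimal-p subwindow (ties broken
toward longer, then earlier windows), yielding sorted, non-overlapping
segments. This is a reproducible, oracle-testable formulation of
compositionally biased segment discovery. `X` is tolerated in input
but never counted. Segments are then scored for FG/GF content:
overlapping dipeptide positions are counted (FGF contains one FG and
one GF — repeat regions are the object of study, so overlaps carry
signal), and the binomial upper tail with n−1 trials at the summed
background dipeptide frequency is compared to a fixed 0.005 threshold.
No multiple-testing correction is applied across segments within a
sequence by default (the fixed threshold is the convention this scan
follows); the counting convention and the background table used are
recorded in every report. The built-in background is an average
eukaryotic proteome composition (glycine 6.91%, phenylalanine 4.05%;
FG+GF ≈ 0.56% under independence).

## Synthetic data: what it emulates, and what it does not

**Granule stacks** place spherical nuclei on a jittered grid and
granule centres uniformly on each nucleus' equatorial rim circle —
the perinuclear geometry of germline granules. The marker channel
carries Gaussian puncta (σ default 0.25 µm) for segmentation; the
query channel is flat at `cytoplasm_level` in the cytoplasm and
exactly `E × cytoplasm_level` on the true granule mask (a sphere of
radius 2σ around each centre, clipped to the cytoplasm), making the
planted enrichment ratio exact in expectation. Noise is Poisson shot
noise on expected counts followed by additive Gaussian read noise
(defaults: Poisson scale 1, read SD 2 on a cytoplasm level of 100 —
chosen once so that a ≈3-fold vs ≈1.2-fold contrast is clearly
resolvable, as it is in real confocal data of bright reporters).
Defaults follow a confocal acquisition of 54 planes at 0.1 µm steps
with 0.1 µm pixels, with a 4-nucleus field rather than a ~35-nucleus
pachytene region to keep simulations fast. Not emulated: a realistic
PSF (no z-elongation or Airy rings), depth-dependent attenuation,
drift, autofluorescence, or nucleus segmentation errors (truth nucleus
masks are supplied — nucleus segmentation is an input to the analysis,
not part of it). Passing recovery tests therefore demonstrates
estimator correctness given reasonable segmentation, not robustness to
microscope artifacts.

**IP/input experiments** draw per-gene abundances from a lognormal
(σ = 1), then counts from a negative binomial with variance
µ + αµ² (α default 0.02, the replicate quality of a good IP series;
α = 0 gives Poisson). For planted targets the IP expectation is
`ip_enrichment_fold` × the input expectation in RPM terms; a
`gene_fraction` (default 0.5) of each library's depth maps to the gene
table, emulating the structural-RNA and intergenic reads present in
real total-mapped denominators and keeping IP library totals below the
nominal depth without rescaling planted folds. Defaults are 2,000
genes at 10⁶ depth with 500 targets at 4-fold across 3 replicates per
condition — a 10×-scaled-down transcriptome with a realistic target
fraction. Coverage is drawn multinomially along each gene from a
piecewise-constant positional profile; read length, strandedness and
alignment artifacts are not modeled. Not emulated: between-replicate
library-size variation, batch effects, or the biogenesis biology
behind 5′/3′ positional bias — profiles are descriptive inputs.

**FG sequences** draw i.i.d. residues from a background composition
and overwrite planted segments with FG pairs at evenly spaced offsets
(density 0.5 gives a perfect FGFG… run), leaving the rest of the
segment at background. Real low-complexity regions have correlated,
repeat-expanded structure; the generator only controls marginal
composition, which is exactly what the binomial scan models.

All generators are pure functions of (spec, seed); no global random
state is touched.

## Numerical choices

- LoG filtering uses a generous kernel truncation (8σ) so the filter's
  DC response is negligible (≲10⁻¹³ relative), making "constant maps
  to zero" and offset-invariance of masks hold to float precision.
- Floats in pipeline outputs are serialized at 9 significant digits;
  combined with fully seeded generation this makes run outputs
  byte-identical across repeats, which is what the output manifest
  checksums assert.
- Degenerate inputs have defined behavior rather than NaNs: empty
  marker channels give empty segmentations; planes without both
  compartments are skipped and counted; zero-variance channels or
  profiles raise rather than return undefined correlations; an empty
  target set is an error, not an empty profile.
- Venn percentages are reported rounded to integer percent, matching
  how such fractions are quoted.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data at reduced scale: partition-ratio recovery uses 4-nucleus,
54-plane stacks over 10 seeds per enrichment level; caller checks use
200–2,000 genes with 3 replicates; the Fisher exactness sweep covers
all margins up to a 60-gene universe; the dipeptide oracle comparison
uses 100 random 300-mers and the calibration run 1,000 sequences.
These sizes were chosen as the smallest at which the checked
properties are non-trivial.

## Known limitations

- The segmentation-derived partition ratio is biased slightly toward 1
  (a few percent at high enrichment) because threshold masks include
  partial-volume edge pixels; truth-mask measurements on synthetic
  data quantify this bias.
- The dipeptide scan's minimal-p trimming reports one core subwindow
  per merged region; two nearby biased blocks merged by overlapping
  candidate windows are reported as the single strongest core.
- The `simple` differential-targeting method is a consistency filter,
  not a calibrated test; use an external count model for inference.
- Enrichment p-values are exact, but with large universes tiny effects
  reach significance; the log₂ effect size should always be read
  alongside p.
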