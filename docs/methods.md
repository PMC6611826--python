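# Methods

## Scope and model

dropletkit quantifies lipid-droplet (LD) biology from calibrated
multi-channel fluorescence images: how many droplets a cell carries, how
large they are, and how strongly a protein stain co-localises with the
droplet stain; plus sequence-level screening for the amphipathic helices
that mediate protein recruitment to the droplet monolayer. Because
benchmark confocal data with per-droplet ground truth do not exist, the
package pairs the analysis pipeline with a generative model of such
images whose every parameter is known, so the pipeline's estimators can
be validated by parameter recovery rather than by eye.

## Synthetic image model

An image is a field of non-overlapping discs on a dark background.

- **Geometry.** Row-major grids, origin top-left; the default
  calibration is 0.1 μm/pixel on a 256×256 frame (a 25.6 μm crop at
  63×-objective sampling; configurable). Droplet centres are placed by
  rejection sampling with a minimum centre separation of the sum of the
  two radii plus one pixel, largest droplets first; placement failure
  after a bounded number of retries raises an error naming the density
  limit rather than silently dropping objects.
- **Sizes.** Diameters are lognormal, parameterised by the median
  (default 0.6 μm) and log-standard-deviation (0.4). The lognormal is
  strictly positive and right-skewed, matching the shape of measured LD
  size distributions, and the median parameterisation matches how such
  data are reported (median + IQR).
- **Counts.** The per-image droplet count is Poisson with mean
  `n_droplets` (default 50, a typical per-cell LD count in adipogenic or
  drug-treated fibroblast imagery); a fixed-count mode exists for
  constructed tests.
- **Channels.** The droplet channel paints every droplet footprint at
  `droplet_intensity` (180 of 255) over `background` (20); the protein
  channel paints only the droplets that carry second-channel membership,
  drawn independently per droplet with probability `coloc_fraction`; the
  nuclei channel paints `n_nuclei` well-separated discs (radius 1.8 μm).
  Ring mode renders 2-px annuli instead of filled discs, mimicking the
  ring-shaped appearance of droplet-coat protein stains; segmentation is
  defined on the filled droplet channel.
- **Noise.** Additive Gaussian read noise (sd 4) plus Gaussian shot
  noise with variance `shot_noise_scale × clean signal` (0.25) — the
  mean/variance behaviour of Poisson shot noise without exact Poisson
  sampling — then clipping and quantisation to the bit depth (8 by
  default; 16 supported). Point-spread blur, 3-D stacks, photobleaching
  and cell shapes are deliberately not modelled: the generator validates
  estimator logic (thresholding, labelling, area accounting, Manders
  algebra), not optical realism. Passing recovery tests therefore shows
  the pipeline is correct on its own model assumptions, not that it is
  robust to out-of-focus light or clumped droplets in real data.
- **Cohorts.** `simulate_cohort` derives the treated arm from the
  control arm by multiplying the expected count by `number_multiplier`
  and the median *area* by `size_multiplier` (diameter scales by its
  square root, so area-based reporting matches the stated effect), and
  shifting `coloc_fraction` additively. Per-image seeds spawn
  deterministically from the master seed; identical seeds reproduce
  cohorts bit-identically.

## Droplet quantification

Foreground is the closed intensity interval `[intensity_low,
intensity_high]`; components are 8-connected (the standard particle-
counting convention; fixed and documented so counts are reproducible).
A component's "diameter" is its equivalent-circle diameter
2·√(area/π) — the natural choice when areas are the reported quantity —
and components below `min_diameter` (default 0.3 μm) are removed as
staining noise. The inclusion range is calibrated once on a designated
reference arm (lower bound = mean of the per-image μ+2σ thresholds,
upper bound = bit-depth maximum) and then frozen for every arm of an
experiment, so group contrasts cannot be driven by per-arm thresholds.

Per-cell normalisation divides by the nuclei count: nuclei are
thresholded with the same μ+2σ rule, and components above
`nucleus_min_area` (2 μm²) are counted. Touching nuclei merge (no
watershed); likewise clustered droplets would merge — the package
documents this limitation instead of inventing a declumping step, since
separating clustered objects is the known failure mode of this class of
analysis. Images with zero detected nuclei are excluded and logged, not
silently dropped. Droplets at exactly the 1 μm² category boundary count
as ≤1 μm², following the category labels of standard size-split
reporting.

## Co-localisation

Each channel is median-filtered (3×3) and then passed through an
adaptive Wiener filter (3×3): with local mean m, local variance v and
noise power ν estimated as the mean local variance, the output is
m + max(v−ν, 0)/v · (x−m). The filter is computed with reflective
boundaries so that constant images pass through unchanged and unit
kernels are the identity; filter order and kernel sizes are
configuration, logged with every run. σ in T = μ + kσ is the population
standard deviation and "exceeds" is strict (>), both read literally from
the threshold rule's definition; k defaults to 2.

Manders sums use the pre-filtered intensities — the same values the
masks were derived from — and the co-localising numerator requires
membership in both masks. M1/M2 with an empty signal mask are defined as
0 and flagged, so batch statistics can exclude degenerate images
explicitly. PCC is computed over the whole image by default; a
union-of-masks region variant is provided since the correlation region
is a genuinely open choice in thresholded co-localisation. When
estimating a droplet-labelling fraction, the convention is
`colocalize(image, "protein", "droplet").M2`: the fraction of droplet
fluorescence located at protein signal, which rises monotonically from
≈0 to ≈1 as the true labelled fraction goes from 0 to 1.

## Statistics

scipy.stats supplies the test engines; this layer fixes the variants.
Mann–Whitney U is two-sided, exact by enumeration when n_x + n_y ≤ 14
with no ties, otherwise the normal approximation with tie correction and
continuity correction; U is reported as min(U_x, U_y). An all-tied input
(zero rank variance) returns U = n_x·n_y/2 and p = 1, since the
tie-corrected normal is 0/0 there. The chi-squared test is Pearson's
without continuity correction (df = (r−1)(k−1)); Welch's t uses the
Welch–Satterthwaite df. No multiple-testing correction is applied. The
unit of replication is the image for count and total-area metrics and
for M1/M2/PCC; per-object areas pool droplets across images within an
arm. Cohorts are compared pooled (not stratified by experiment).

The test-suite checks the exact Mann–Whitney path against a brute-force
enumeration of all group assignments, and calibrates the whole chain
(generator → per-image counts → test) under the null: across 1,000
two-arm cohorts drawn from one distribution, the rejection rate at
α = 0.05 must lie in [0.03, 0.07].

## Helix scanning

Windows are scored on the Fauchère–Pliška octanol scale (the scale of
the standard helical-wheel prediction server). The hydrophobic moment
uses residue indices n = 0…N−1 at δ = 100° per residue and is
normalised by N (a per-residue moment), so thresholds quoted for
18-residue windows are directly interpretable; μH obeys
μH ≤ (Σ|Hₙ|)/N. Positions are 1-based inclusive; fixed-length sliding
windows (default 18, one helical period ×5) and explicit region queries
are both provided because reported helices vary in length. Net charge
is (+1 per K/R) − (1 per D/E); histidine is treated as neutral.

The ALPS-like classifier's normative criterion is the S/T/G count bound
(≤ 6 per window): ALPS motifs carry abundant small polar residues on the
polar face, but an excess marks the window as something else. The
remaining defaults (μH ≥ 0.4, |net charge| ≤ 2, ≥ 3 large hydrophobic
residues) are non-normative screening bounds, freely configurable, and
every criterion's individual pass/fail flag is reported alongside the
overall verdict — no vacuous verdicts from an empty criteria set.

The bundled TPD52 FASTA is a synthetic offline reconstruction of the
184-aa human isoform (its header says so): residues 1–93 are corroborated
by independent counts, the middle region is uncertain. It is a
convenience default for demonstrations; analyses that depend on exact
published residue counts should supply the database record.

## Problem sizes and numerical choices

Validation simulations are sized for a single CPU: distributional checks
pool ~10,000 droplets over 40 seeds; null calibration uses 1,000 cohorts
of 10 images/arm at ground-truth level (no rendering); effect-detection
power uses 50 cohorts of 30 images/arm through the full render→segment
path at the default 256² frame. CSV outputs are written with a fixed
float format ("%.9g") so identical runs are byte-identical. Pixel areas
are converted to μm² by `pixel_size²`; a disc's segmented area is
accurate to within one perimeter pixel-ring of the analytic value, which
bounds the discretisation error asserted in the recovery tests.

## Known limitations

- No declumping: overlapping or touching droplets/nuclei merge.
- The generator's noise is Gaussian-only (no exact Poisson sampling,
  no PSF), so sub-resolution behaviour of real optics is out of scope.
- PCC on near-binary synthetic images is dominated by mask geometry;
  it is reported for completeness but M1/M2 carry the recovery tests.
- The bundled TPD52 record is a reconstruction, not the database entry.
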