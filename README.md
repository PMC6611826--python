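# dropletkit

Quantitative analysis of lipid-droplet (LD) fluorescence microscopy, for
cell biologists studying how proteins are recruited to the droplet
surface. The package covers the four quantitative layers such studies
need, plus a synthetic-image generator that provides exact ground truth
for validating all of them:

1. **LD segmentation and per-cell quantification** (`ld_quant`) —
   droplets are segmented from the neutral-lipid (BODIPY-type) channel by
   a fixed intensity inclusion range and 8-connected labelling; objects
   with equivalent-circle diameter below 0.3 μm are filtered as
   non-specific specks. Reported metrics: LD count per cell (cells
   counted by nuclei), area per object (μm²), total LD area per cell,
   and the >1 μm² / ≤1 μm² size split.
2. **Thresholded co-localisation** (`colocal`) — channels are
   pre-filtered (median, then adaptive Wiener), and signal pixels are
   those exceeding

   T = μ + 2σ,

   with μ, σ the mean and (population) standard deviation of all pixel
   intensities in the channel. With signal sets S_A, S_B the thresholded
   Manders coefficients are

   M1 = Σ_{i∈S_A∩S_B} A_i / Σ_{i∈S_A} A_i,  M2 symmetric in B,

   the fraction of each probe's detected fluorescence lying where the
   other probe also shows signal, alongside Pearson's correlation (PCC).
3. **Group statistics** (`stats`) — Mann–Whitney U (exact when small and
   untied, tie-corrected normal otherwise) on per-image metrics,
   Pearson's chi-squared on the size categories, Welch's t, and fold
   changes of medians.
4. **Amphipathic-helix scanning** (`helix_scan`) — sliding-window mean
   hydrophobicity ⟨H⟩ and hydrophobic moment
   μH = (1/N)·|Σₙ Hₙ e^{inδ}| (δ = 100°/residue, Fauchère–Pliška scale),
   counts of large hydrophobic residues (F, I, L, M, W, Y) and of the
   small polar S/T/G class, and a configurable ALPS-like (amphipathic
   lipid-packing sensor) classifier.

The synthetic generator (`synthetic_imaging`) draws non-overlapping
droplets with lognormal diameters, renders droplet / protein / nuclei
channels with Gaussian read noise and signal-proportional shot noise,
and can produce two-arm "vehicle vs. treated" cohorts with prescribed
multiplicative effects on droplet number and size — e.g. a 15% decrease
in droplet numbers combined with a 35% increase in droplet areas, the
kind of opposing contrast a Golgi-disrupting drug treatment produces.

## Worked example

Run a two-arm synthetic experiment (10 images per arm, −15% droplet
number and +35% droplet area in the treated arm):

```python
from dropletkit import pipeline

cfg = pipeline.load_config({
    "pixel_size": 0.1,          # μm per pixel
    "n_images": 10,
    "seed": 42,
    "effects": {"number_multiplier": 0.85, "size_multiplier": 1.35},
})
report = pipeline.run_experiment(cfg)
print(report.summary["comparisons"])
```

Selected output (seed 42):

```
area_per_object:      fold_change_of_medians 1.333, p_value 1.5e-07
total_area_per_cell:  fold_change_of_medians 1.339, p_value 0.017
droplets_per_cell:    fold_change_of_medians 0.954, p_value 0.324
size_category_gt1um2: p_value 3.8e-05
M2:                   fold_change_of_medians 1.0,   p_value 1.0
```

Reading this: the +35% area effect is recovered almost exactly
(measured fold change 1.33 of the pooled per-object median areas) and is
highly significant even at 10 images per arm, as is the shift in the
>1 μm² size category; the −15% count effect is present (fold change
0.95 here) but under-powered at this cohort size — it reaches ≥90% power
at 30 images per arm (see the acceptance checks). Co-localisation
metrics do not differ, as no co-localisation shift was simulated.

The same pipeline is available from the shell:

```bash
dropletkit simulate --outdir sim --n-images 5 --seed 1
dropletkit quantify sim/*.tif --outdir quant --intensity-low 100
dropletkit coloc sim/*.tif --outdir coloc
dropletkit helix --fasta protein.fasta --region 100-172 --outdir helix
dropletkit experiment --config experiment.yaml --outdir results
```

For sequence work, `dropletkit.helix_scan` ships a bundled copy of the
184-aa human TPD52 protein labelled *synthetic*: it was reconstructed
offline and its middle region is uncertain (see the FASTA header).
Supply your own FASTA of the database record when exact published
residue counts matter.

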