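# Methods

This note records the models, conventions and design choices behind
`nanohcs`, in the spirit of a package's statistical/algorithmic appendix.

## Synthetic plate model

The generator emulates a plated monolayer of adherent stem-like cells imaged
in four fluorescence channels, with dose-dependent effects injected as known
ground truth.

**Geometry.** Each cell is a rotated ellipse with a concentric nucleus at
half the semi-axes (25% of the cell area). Ellipses were chosen because
their area and minor/major axis ratio are analytically known, so the
downstream area and form-factor measurements can be tested for exact
recovery; no claim is made that real cell outlines are elliptical. Per-cell
area is drawn from a truncated normal around `mean_cell_area ×
area_scale(dose)` (CV 0.15) and the axis ratio from a normal around
`axis_ratio(dose)` (SD 0.05, clipped to (0.1, 1]). Cells are placed by
rejection sampling (100 retries per cell) with a ≥3 px gap enforced through
a padded footprint; a monolayer has negligible overlap, so outright
rejection is appropriate. When 20 or more cells are requested, one cell is
deliberately placed across the field border to exercise the border-exclusion
rule.

**Intensity model.** 16-bit counts, flat per-channel background (default
500) plus additive Gaussian noise (default SD 20), no point-spread function,
no 3D, no time-lapse. Channel content: nuclei at 3000 counts; cell bodies at
`1000 × ros_scale(dose)` counts with a per-cell multiplicative jitter
(SD 5%, mean 1); mitochondria as Poisson-count Gaussian blobs (σ 1.5 px,
amplitude 1500) placed ≥6 px apart inside the cell, dimmed ×0.2 in dead
cells (a potential-dependent stain loses intensity in non-functional
mitochondria); the dead channel is background everywhere except dead-cell
nuclei, painted at 4× background. The 4×/1× design puts every dead cell at
≥3.5× and every live cell at ≤1.5× background — a deliberate margin around
the 3× decision rule so that classification errors, if any, come from the
pipeline and not from the phantom.

**Study conditions.** The default dose series is 0, 5, 10, 50, 100, 150,
200, 250 µg Fe/ml with ≥500 cells per condition and 3 fields per dose,
matching the screening design the package targets. The default effect
tables encode the qualitative findings such a screen reports: ROS induction
(×1.3) only at 10 and 50 µg Fe/ml, cell area shrinking only above
100 µg Fe/ml, elongation (axis-ratio drop) above 50 µg Fe/ml, and a small
flat dead fraction. Field dimensions (1024×1024 px) and pixel size
(0.65 µm/px) are declared defaults — the acquisition hardware's true
geometry is not public — and all of this lives in `EffectConfig`, which
round-trips losslessly through YAML; dose-effect "functions" are therefore
per-dose lookup tables rather than callables.

**What passing tests show.** Recovery tests prove the pipeline measures
what the generator encodes under crisp-boundary, flat-background,
Gaussian-noise conditions. Real micrographs add PSF blur, uneven
illumination, debris, touching/overlapping cells and focus drift; the
pipeline's robustness to those is *not* demonstrated by this test bed.

## Segmentation

Nuclei: Gaussian smoothing (σ 2) → Otsu threshold → Euclidean distance
transform, itself smoothed (σ 2) so an elongated nucleus's ridge yields a
single maximum → `peak_local_max` markers (min distance 7 px) → watershed →
objects < 30 px² dropped, labels compacted. Touching nuclei are split;
genuinely constant images return zero labels with a warning.

Cells: watershed seeded from nucleus labels over the Otsu foreground of the
smoothed cytoplasm channel (union with the nuclei so a nucleus without
surrounding cytoplasm keeps a cell equal to its own mask, flagged). Interior
holes are filled per cell without annexing neighbours. Any cell whose mask
touches the border is removed — the *cell* mask, not the nucleus, because
the morphology features are cell-level and a clipped cell would bias them.

Spots: difference of Gaussians (σ 1 − σ 3) local maxima with an absolute
band-pass threshold (default 50 counts, ≈9× the post-smoothing noise SD so
even 0.2×-dimmed spots are kept), discarded unless inside a cell mask.

Conventions stated once and used everywhere: 8-connectivity, 0-based
(row, col) coordinates, deterministic output for fixed input and
parameters.

## Cytometry

Background is the median of non-nuclear dead-channel pixels (requiring ≥10%
of the field outside nuclei); the median is immune to the bright debris and
saturated pixels such channels accumulate. The dead call is
`dead_nuclear_mean ≥ 3 × background`, boundary included, measured over the
nucleus mask only — the stain binds DNA of membrane-compromised cells, so
nuclear restriction enforces co-localization structurally. Form factor uses
the equivalent-ellipse minor/major axis lengths (rotation-invariant, unlike
a bounding box); a degenerate single-pixel mask returns 1.0 with a warning,
and a strictly 1-px-wide line returns 0 (zero cross-axis variance), the
limiting value of the definition. Mitochondrial intensity is the mean of
spot *peak* values (0 and flagged when no spots), reporting organelle
signal rather than diffuse cytoplasm.

## Dose statistics

Reported dispersion is the SD over cells (what screening figures print);
inference uses field/well means as the replicate unit, since per-cell values
within a well pseudo-replicate. Dunnett's many-to-one comparisons use the
equicorrelated multivariate-t critical values (`scipy.stats.dunnett`);
tests verify the adjusted p against an independent Monte-Carlo simulation
of the max-|t| null and the familywise type-I rate against [0.03, 0.07] at
α = 0.05. Viability is emitted under both conventions (relative dead-cell
number, and relative live fraction) because they disagree whenever the
control has deaths; hiding one would silently change conclusions. A control
with zero dead cells makes the relative-dead metric undefined; it is
reported as NaN with a warning rather than an arbitrary substitute.

## Assay modules

*Standard curve / relaxivity*: plain OLS; R² clipped to [0, 1]; a constant
response is a perfect flat-line fit (R² 1). Absorbance > 1 triggers a
linear-range warning. Inverse prediction clips negative concentrations to 0
and flags both clipping and extrapolation beyond the fitted range. The
well-digestion dilution factor is an explicit user parameter (the liquid
handling chain varies between labs), defaulting to 1. Uptake percentages
are reported raw and rounded to integer percent, the form assay tables
print.

*Relaxometry*: rates are element-wise reciprocals of positive times; the
relaxivity fit requires ≥3 distinct concentrations and warns when no
low/zero anchor is present (the native-rate intercept becomes an
extrapolation). Unit handling is exact: fitting in µg/ml and multiplying
the slope by 55.845 equals fitting in mM. The solution-phase relaxivity is
treated as field-strength-specific input data; no cross-field conversion is
attempted. ROI normalization divides each target ROI by a same-image
reference ROI and tests post-baseline timepoints against baseline with the
same Dunnett machinery; subjects are the replicate unit.

*Particles*: log-normal fit by closed-form MLE on log-diameters (n ≥ 30
required); the reported spread δd% is the coefficient of variation
100·SD/mean, with the log-space σ reported alongside because published size
distributions are ambiguous about which they quote. Scherrer uses K = 0.9
(spherical convention) by default; since published crystallite sizes rarely
print K, β and θ, the formula's algebra — homogeneity in β, the small-angle
limit, monotonicities — is what the tests pin down.

## Pipeline

One global seed fans out to per-field seeds through a fixed
`SeedSequence([seed, dose_index, replicate])` counter scheme, so any single
field is reproducible in isolation. Every artifact is hashed (SHA-256) into
a manifest; identical config+seed give identical manifests, and each stage
re-run from intermediates reproduces the end-to-end outputs. Problem sizes
used by the shipped tests and the acceptance script — a 3-dose plate at 170
cells/field × 3 fields (≥500 cells per dose), 100-series Monte-Carlo for
the relaxivity fits, 1000 null plates for the Dunnett calibration — were
chosen as the smallest designs that still satisfy the ≥500-cells-per-
condition screening convention and give stable Monte-Carlo estimates.

## Known limitations

- No PSF/illumination modelling; segmentation parameters are tuned for the
  phantom's scale and will need adjustment for real micrographs.
- The watershed split of touching nuclei is tested on mild contact only;
  dense clumps are out of scope.
- Dunnett for unbalanced designs falls back to scipy's simulation-based
  quantiles (seeded); balanced designs use the analytic correlation ½.
- Relaxation-time estimation from raw echo trains, Bloch simulation and
  image registration are out of scope; inputs start at scanner-reported
  T1/T2 values and ROI means.
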