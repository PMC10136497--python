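# Methods

## The measurement

SRAI-type reporters fuse an acid-stable fluorophore (TOLLES; "T") to an
acid-labile one (YPet; "Y").  In neutral compartments — cytosol, ER,
autophagosomes — both moieties fold and FRET from T to Y keeps apparent
donor emission weak while the acceptor is bright.  After delivery to the
autolysosome the acceptor is irreversibly denatured by low pH, so only
the donor fluoresces.  The per-pixel intensity ratio

    R(p) = (I_T(p) − b_T) / max(I_Y(p) − b_Y, ε)

therefore separates neutral reporter (R well below 1) from
lysosome-delivered reporter (R large, railed at a cap), and the
**TOLLES:YPet index** at threshold *t* is the area fraction

    Index(t) = |{p ∈ M : R(p) > t}| / |M|

where M is the set of pixels the reporter occupies.  Swept over
thresholds (default 0.5–4 in steps of 0.5) and read at a single
calibrated threshold, the index is a per-field proxy for autophagic /
ER-phagy flux.  The comparison "> t" is strict: ties count only in the
denominator.

For tandem RFP–GFP-type reporters, flux is instead scored by counting
acid-resistant-only puncta (reticulolysosomes) per cell: LoG blob
detection on the acid-stable channel, then classification of each
punctum's 3×3 core by mean ratio against `t_punctum` (default 2.5).

## Pipeline decisions

Manual versions of this workflow are interactive in exactly three places: choosing
the z-slice, rejecting bad fields, and choosing a background ROI.  All
three are automated with deterministic defaults and kept overridable:

* **Focus.**  Normalized variance var/mean² (scale-free; 0 for constant
  planes) on the acid-stable channel, argmax over z, ties toward the
  central slice then the lower index.
* **Analysis plane.**  Quantification runs on the single best-focus
  slice by default.  Display-style z-projection (conventionally a
  maximum projection of 5 steps of 1.5 µm) is available
  (`projection.n_slices`), but projecting defocused planes pads the
  probe-area denominator with a blurred halo and roughly doubles the
  per-field spread of the index on simulated stacks, so it is not the
  quantification default.
* **Background.**  A scalar per channel per field — the mean of the
  darkest k×k tile (k = 32), the automated analogue of picking the best
  background ROI.  A percentile estimator and explicit manual ROIs are
  selectable.  No flat-field correction is applied (limitation: slowly
  varying illumination biases the mask and ratio near the field edge).
* **Field QC.**  Reject when probe area < 500 px or > 95 % of the field,
  or when > 1 % of pixels are saturated (12-bit ceiling 4095).  Rejected
  fields keep a row (NaN indices) in the results table.

## Segmentation and ratio construction

The reporter-occupied area M is the union of per-channel robust
thresholds: channel c is "occupied" where I_c − b_c > k·σ_c with k = 3
and σ_c = 1.4826 · MAD of the below-background residuals (pixels below
the scalar background carry noise but no signal).  The union matters:
neutral reticulum is acceptor-bright, autolysosomes are donor-bright
only — either channel alone undercounts M.  Saturated pixels are
excluded; connected components below 9 px (8-connectivity) are dropped.

Numerics of the ratio:

* numerator clamped at 0 below background;
* denominator floored at ε = 1 detector unit, so fully quenched pixels
  rail at the cap r_cap = 10 rather than overflow — any sweep threshold
  up to 4 classifies them as "above";
* both planes are smoothed with a σ = 0.8 px Gaussian (below the optical
  PSF width at 40×/0.75 NA, ~0.16 µm pixels) before division.  The
  quotient of two independently noisy channels is heavy-tailed wherever
  signal is weak, and unsmoothed rim pixels of M otherwise contribute a
  few percent of spurious R > 1.5 area even when both channels carry
  identical signal.  Sub-PSF averaging suppresses this without resolving
  away real structure; `ratio_smooth_sigma = 0` restores the raw
  pixelwise quotient.
* no FRET spectral unmixing or bleed-through correction is applied
  (a deliberate simplification; documented limitation).

The sweep is computed from one sort of the valid ratios, which makes
Index(t) non-increasing in t by construction and bit-identical to naive
per-threshold counting.

**Threshold calibration.**  The single reporting threshold for an
experiment is chosen from control conditions.  A useful threshold must
sit well between the neutral-reporter ratio mode and the capped quenched
ratios, so a sweep threshold is admissible when (a) it is at least twice
the negative (flux-blocked) control's median probe-pixel ratio and
(b) the negative control's mean index — the pixel-classification
false-positive area — stays ≤ 0.02.  The smallest admissible threshold
is used: the index is non-increasing in t, so once specificity is
secured, any further increase only erodes genuinely quenched area.
This rule is deterministic; separation-maximizing alternatives estimated
from a handful of control fields flip between adjacent sweep thresholds
under sampling noise.

## Statistics

The biological replicate is the unit of analysis: fields are technical
pseudo-replicates and are averaged per replicate first; condition
summaries are mean ± sample SD over replicate means (n = replicates,
typically 3).  Group comparison is classical one-way ANOVA
(F = MSB/MSW, (k−1, N−k) df; F = 0, p = 1 when the between-group sum of
squares vanishes), followed by pairwise t comparisons sharing the pooled
within-group variance, Holm-Šídák adjusted: the i-th smallest of m
p-values becomes 1 − (1 − p_(i))^(m−i+1), with a running maximum
enforcing monotonicity and clamping at 1.  All pairs are compared by
default; comparisons against the reference condition only are a config
option.  Stars follow the usual convention (* < 0.05, ** < 0.01,
*** < 0.001).

## The simulator

`sraiflux.synthetic` renders two-channel z-stacks with exact ground
truth so that every stage is testable without external data.  Scene
model per field: random elliptical cell footprints; a smoothed-noise
reticular mesh inside footprints carries the reporter (amplitude
A = 600 detector units with mild smooth spatial variation); neutral
pixels emit (αA, βA) with α = 0.4 (static FRET donor attenuation — a
declared convention, not a measured constant) and β = 1; quenched
(autolysosomal) patches are disks covering a target fraction f of the
probe footprint, emitting (A, background) — the last disk is trimmed so
the planted pixel count is exact; dual-positive (autophagosomal) puncta
are small disks bright in both channels.  Each z-plane is blurred with
σ(z) = 0.5 + 0.7·|z − z*| px, then Poisson shot noise (1 event per
detector unit), Gaussian read noise (σ = 3), and 12-bit quantization are
applied.  Truth (quenched fraction relative to the probe footprint,
puncta coordinates and classes, cell count, backgrounds, z*) comes from
the generator's own mask arithmetic.

Plate presets encode the expected condition ordering of a starvation
experiment: quenched fraction 0.30 under starvation (EBSS), 0.04
untreated, 0.004 under lysosomal block (BafA1 during starvation) or
loss of a core autophagy gene; a bulk-autophagy preset adds
dual-positive puncta without quenching for lysosomal block alone.  A
multiplicative per-replicate effect (CV 8 %) mimics biological replicate
scatter.  Per-field RNG streams are keyed by (seed, well, field), so any
field is independently reproducible and a fixed seed is bit-identical.

What the simulator does **not** emulate — hence what passing tests do
not show about real data: spectral bleed-through and true FRET physics,
uneven illumination and flat-field structure, cell-to-cell expression
variability, motion or fixation artifacts, realistic ER sheet/tubule
morphology (the mesh is sub-resolution texture), photobleaching, and
camera fixed-pattern noise.

## Problem sizes

Desk-scale defaults keep every check fast while preserving the study
layout: 128×128 px fields (a crop of a full camera frame), 5 z-planes,
8 cells per field, plates of 4 conditions × 3 replicates × 6 fields.
The acceptance checks use 20 fields for the exact-oracle comparison, 100
fields for monotonicity, 10 fields per planted fraction
f ∈ {0, 0.05, 0.1, 0.2, 0.4} for recovery, 100 simulated plates for the
condition-ordering rate, 10,000 null experiments for the ANOVA type-I
rate, 15 spot fields at SNR 5 for puncta recall/precision, and 50 stacks
for focus selection.

## Known limitations

* Scalar background per channel; no flat-field or illumination model.
* Field-level index only; per-cell indices are out of scope (cell counts
  are used solely for puncta normalization and QC annotation).
* The fallback cell counter (connected components over a size floor) is
  crude; user-supplied counts are preferred.
* No object-level autophagosome/autolysosome counting for the FRET
  reporter; no FRET efficiency estimation.
* Proprietary microscope formats are not read; convert to TIFF/OME-TIFF.
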