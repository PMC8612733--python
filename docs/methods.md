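# Methods

`condquant` quantifies the standard readouts of a biomolecular-condensate
study: in vitro droplet partitioning, FRAP mobility, puncta dissolution in
cells, the sequence features of the driving IDR, and the tabular
statistics (proteome overlaps, exosomal miRNA enrichment) that connect
condensation to cargo sorting. This note records the models, parameter
choices, numerical conventions, and what the synthetic-data generators do
and do not emulate.

## Droplet segmentation and partition statistics

An image is dark-corrected by subtracting the scalar mean of a
shutter-closed frame (negatives clamp to 0; detector counts are
non-negative and no further photometric calibration is applied). The
droplet mask threshold is

    T = mean(image) + k_user * std(image)

with `k_user` defaulting to 3 — the conventional k·σ reading of a unitless
threshold "user parameter". Pixels strictly above T are candidate dense
phase; connected components use 8-connectivity and are labelled 1..n in
raster-scan order of their first pixel, components below `min_area_px`
(default 4) are dropped, and droplets touching the image border are
retained.

**Despeckling.** Spurious single-pixel detections are removed with a
circular median filter of radius `median_radius_px` (default 2). A plain
median filter, however, also erodes the single-pixel extremities of a
hard-edged droplet (the topmost pixel of a rasterized disk loses the
majority vote in any window), which would make measured droplet areas
disagree with the true thresholded extent. The default mode is therefore
*median-reconstruct*: the binary median decides which connected components
are real, and surviving components keep their full thresholded extent.
Isolated hot pixels vanish; genuine droplets keep their exact pixel area.
Plain mask-median (`median_mode="mask"`) and pre-threshold grayscale
median (`median_mode="image"`) are available for users who want the
classical orders.

Per field and channel:

    I_DP = unweighted mean of per-droplet mean intensities
    I_LP = mean intensity over all unmasked pixels (no exclusion buffer)
    PC   = I_DP / I_LP
    I_in, I_out = integrated intensities inside / outside the mask
    RC   = I_in / (I_in + I_out)

A field with no droplets reports RC = 0 and PC as NaN with
`pc_defined=False`. In two-channel mode the mask is built from the
protein channel only and applied to both channels, so the RNA channel's
PC/RC measure partitioning into protein-defined droplets.
`concentration_sweep` summarises a titration and flags the lowest
concentration with any droplet as the apparent phase-separation onset.

Note that with a strict `>` threshold and k > 0, an "every pixel above
threshold" mask is unreachable (min ≤ mean + k·σ always); the degenerate
warning exists for defensive completeness.

## FRAP correction and recovery fitting

The double normalization

    BL_corr2(t) = [BL(t) - BG(t)] / [REF(t) - BG(t)]
    BL_corr3(t) = BL_corr2(t) / mean(BL_corr2 over pre-bleach frames)

removes the background and any bleaching/illumination drift that is
multiplicative and shared between the bleach and reference regions; the
pre-bleach mean of BL_corr3 is 1 by construction (machine precision).
The 100 % level uses the *mean* over the pre-bleach frames (all frames
before the bleach by default) rather than a single frame.

The recovery model is the minimal single exponential

    f(t') = plateau - (plateau - f0) * exp(-t'/tau)

with t' measured from the first post-bleach frame; the bleach frame
itself defines t' = 0 and is included as the f0 observation. By default
f0 is pinned to the first post-bleach value and (plateau, tau) are fitted
by trust-region least squares (`scipy.optimize.curve_fit`, tau bounded
positive, initial guess plateau ≈ tail mean, tau ≈ span/3); `fix_f0=False`
frees f0. Mobile fraction is (plateau − f0)/(1 − f0) on the normalized
scale. A flat post-bleach trace (std < 1e-12) is reported with
mobile fraction 0, tau = ∞ and a `flat_trace` flag instead of attempting
an unidentifiable fit; a fitted plateau below f0 reports mobile fraction
0 with a `no_recovery` flag. Reaction–diffusion FRAP models and
multi-exponential selection are deliberately out of scope.

`batch_fit` fits each trace and returns the mean ± standard error of the
normalized curves (SE over traces, ddof = 1; exactly 0 where the traces
are identical, NaN and flagged for n = 1).

## Puncta dissolution

"Surviving puncta" is read as per-frame counts with no identity
tracking: each frame is masked with the same k·σ machinery, the treatment
frame maps to t = 0, survival = counts/counts[t=0], and pre-treatment
frames carry negative t and are excluded from normalization. Because the
threshold is an image statistic, survival is invariant to uniform
intensity rescaling. `fit_dissolution` fits survival = exp(−λt) by least
squares and reports (λ, half-life ln 2/λ). Counts are per field, not per
cell.

## Sequence features

Charge convention: R, K = +1; D, E = −1; histidine and everything else 0.
NCPR is the mean charge over a sliding window (default 5 residues, step
1), reported at the window's centre position; terminal positions without
a full window are omitted, not padded. Residue-class composition counts
the condensation-relevant classes (Y; R/K; D/E; Q/N; V/M/F; other).
Substitution rules replace every residue of a class within a 1-based
inclusive region (e.g. Y→S or R,K→G over the YBX1 CTD, residues
128–324, via `ctd_rule`); deletions remove an interval and record it in
the sequence id. The "Y to S/A" naming ambiguity is resolved as
all-to-S by default; any other mapping can be expressed directly as a
`SubstitutionRule`. Disorder prediction (IUPred-style) is an external
tool's job and is not reimplemented.

## Set overlaps and qPCR enrichment

Identifier normalization is deterministic string cleanup (trim,
upper-case, de-duplicate) with no alias or ortholog resolution, so
results are auditable; overlap percentages use the *reference* set as the
denominator. Fold change from cycle thresholds is 2^(Ct_cell − Ct_exo);
Ct > 40 is treated as not-detected and flagged rather than numeric.
Relative enrichment is the ratio of two exosome/cell fold changes
(condition over control). Input-mass normalization at the RT step is left
to an optional user-supplied scaling; no hypothesis test is attached to
the overlaps.

## Synthetic data and what it does (not) show

Generators are pure functions of spec + seed, and every dataset ships a
ground truth computed analytically from the spec, never from the
generated pixels.

* **Droplet fields** — hard-edged (non-anti-aliased) rasterized disks at
  `i_dense` on an `i_dilute` background, non-overlapping by construction
  (≥ 2 px gaps), plus a camera offset and additive Gaussian read noise;
  the dark frame carries the same offset and noise. Hard edges make the
  analytic PC = i_dense/i_dilute and the pixel-count RC exact on
  noiseless fields, which is what the oracle-equivalence tests rely on.
  Defaults: 256×256 fields, 8 droplets of radius 3–8 px, dense 100 /
  dilute 10 counts. Not emulated: optical PSF blur, anti-aliased droplet
  edges, intensity gradients, fluorophore cross-talk, 3-D structure.
* **FRAP traces** — the underlying normalized signal is 1 pre-bleach and
  the single exponential after; observed BL multiplies in per-frame
  acquisition bleaching (1 − rate)^frame and a scale, REF carries the
  same bleaching with its own scale, both add a background level.
  Gaussian noise (sd `noise_sd`, default 0; 0.02 in the recovery tests)
  is applied on the normalized scale of the bleach signal so the
  corrected trace is exactly signal + noise. Presets mirror the three
  acquisition settings (2 s × 120 frames with ~70 % recovery by 90 s;
  1 s × 60 with ~90 % by 30 s; 30 ms × 40 in vitro). Not emulated:
  diffusion physics, bleach-spot geometry, detector shot noise.
* **Dissolution stacks** — each punctum independently survives each
  frame interval with probability exp(−λ·Δt); survivors are re-rendered
  as disks. Default test condition: 40 puncta, λ·Δt = 0.1, 10 frames of
  128×128 — small enough that 50 replicate stacks fit in seconds while
  the mean fitted half-life lands within a few percent of ln 2/λ.
* **Gene sets** — synthetic identifiers with an exactly known
  intersection, used to reproduce overlap statistics whose set sizes and
  intersection counts are fixed inputs.

Passing on these synthetics demonstrates that the *measurement
arithmetic* is correct and unbiased under the stated noise models; it
does not validate segmentation against real point-spread functions,
uneven illumination, or crowded/overlapping droplets, which real
microscopy data would add.

## Problem sizes

Defaults were chosen so a full test run and the acceptance sweep complete
in seconds on one core: 96×96–256×256 synthetic fields (the oracle sweep
uses 100 fields at 96×96), 50-trace FRAP ensembles, 50 dissolution
stacks, and 15-field titrations. All statistics scale to larger fields
unchanged.

## Known limitations

* The k·σ threshold assumes a dominant dilute phase; dense fractions
  approaching ~40 % push the threshold above the dense intensity and
  droplets are missed. Lower `k_user` for crowded fields.
* No droplet tracking, 3-D segmentation, or deconvolution.
* Touching puncta merge under 8-connectivity and count as one.
* Exact PC/RC equality with ground truth holds for hard-edged noiseless
  synthetics; on real or blurred images PC is a biased-down estimate near
  droplet edges, as for any mask-based estimator.
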