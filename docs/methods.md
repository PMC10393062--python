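# Methods

## Scope and model

`optorecruit` quantifies optogenetic membrane-recruitment experiments in
endothelial cells. The underlying biology: a membrane-anchored bait
(an iLID-type light-induced dimer half) binds a cytosolic prey while
blue light is on and releases it in the dark, so prey redistributes
between plasma membrane and cytosol with second-scale kinetics. The
read-outs implemented here are the ones such studies report:

* **Recruitment kinetics.** The per-frame membrane-ROI mean over
  cytosol-ROI mean of the prey channel, normalized to the first frame.
  The ON phase is modelled as R(t) = R₀ + A·(1 − e^−(t−t₀)/τ) and the
  OFF phase as R(t) = R₀ + A·e^−(t−t₀)/τ, fitted by nonlinear least
  squares; half-times t½ = ln 2·τ. Recruitment efficiency is the mean
  of the normalized ratio over the last quartile of the stimulation
  window (the plateau).
* **Morphometry.** Nucleus-seeded watershed segmentation (Gaussian
  σ = 1, Otsu foreground, nuclei gated to 30–100 px equivalent
  diameter), overlap-based tracking, per-cell normalized area traces,
  form factor 4πA/P², categorical contraction/extension change maps,
  photo-activation-ROI coverage and two-channel membrane-overlap areas
  (Gaussian σ = 2 + Huang threshold per channel, intersection area).
* **Junction metrics.** Linearity index = junction arc length divided
  by the perimeter of the polygon through tricellular corner points
  (1 for a straight junction); group medians with seeded percentile
  bootstrap CIs; temporal color-coded peak-intensity projections.
* **Traces and optics.** Baseline normalization, signed
  extremum-vs-baseline response amplitudes and cross-trace Pearson
  correlation for impedance (resistance) traces sampled every 10 s;
  first-ring Airy area πr² with r = 1.22λ/(2·NA) and power density
  P/area for photo-activation dosimetry.

## Where the kinetics live

The half-times are defined on the normalized membrane/cytosol ratio —
that is the quantity experimentalists fit. The synthetic generator
therefore drives the ratio excess R − 1 with the exact piecewise
mono-exponential law (target G·r/(1−r) and τ_on inside illumination
windows, target 0 and τ_off outside, solved analytically through every
window boundary) and derives the membrane-bound pool fraction
f = (R−1)/(R−1+G), where G = n_cell/n_membrane is the geometry gain of
the disk phantom. An alternative would be to put the first-order law on
f itself; because R = 1 + G·f/(1−f) is nonlinear in f, that choice
makes the fitted τ of the ratio deviate from the generating τ by ~9%
at realistic plateau fractions, i.e. the generator and the estimator
would disagree about what "the" half-time is. Defining truth on the
observable keeps the recovery tests meaningful; at small plateau
fractions the two formulations coincide.

## Synthetic scenes: what they emulate and what they do not

The generator replaces raw microscopy with scenes whose every
measurable quantity is known by construction:

* **Recruitment movie** (default 96 frames at 2.5 s, one 30–150 s
  illumination window, τ_on = 8 s, τ_off = 20 s): a disk cell of radius
  36 px with a 3-px membrane band (matching the thin-band appearance of
  Lck-anchored bait at high magnification). The prey pool is conserved
  per frame before bleaching/noise. Default plateau pool fraction
  `recruit_fraction = 0.15` gives a normalized-ratio plateau of ≈ 2
  (the recruitment efficiency reported for iLID-class tools, above the
  ≈ 1.5 of the weaker eMags system) and ~15% cytosol depletion, the
  order of magnitude reported for these constructs. Bleaching is a
  global e^−kt factor; noise (Gaussian by default, Poisson optional) is
  applied last, after bleaching, since no specific camera model is
  claimed. One `numpy` generator per scene, seeded from the config; no
  global state.
* **Morphology sequence**: star-convex cells (circle plus low-order
  radial cosine harmonics, amplitudes 0.02–0.08) whose boundary radius
  scales with √(area profile); true areas are re-counted from the
  emitted masks, so digitization is part of the truth. Border-touching
  cells are flagged.
* **Junction paths**: chords perturbed by a perpendicular sine
  (amplitude = tortuosity in px, default period 50 px), semicircles, or
  straight segments; the true arc length comes from a 10⁴-segment
  quadrature of the generating curve, independent of the emitted
  polyline sampling.
* **Mosaic monolayer**: two axis-aligned membrane bands whose
  intersection-over-union equals the requested overlap fraction with
  integer-pixel exactness; a time series mode grows the intersection
  linearly to a requested factor. Rectangles were chosen over blob
  cells so the generator has zero digitization error and the
  overlap-growth tests exercise the measurement path (blur + Huang
  threshold + intersection), not the generator.
* **Resistance trace**: baseline + amplitude step inside each stimulus
  window (optionally a finite mono-exponential rise), mono-exponential
  relaxation (default τ = 60 s) after it, sampled every 10 s. The
  instant-rise default reflects that the measured barrier response is
  fast against the 10-s sampling and makes the noiseless
  amplitude-recovery identity exact.

None of the scenes simulate a point-spread function, LOV-domain
photocycle beyond the mono-exponential phenomenology, cell-cell
mechanics, or junction biology. Passing tests therefore demonstrate
that the *quantification* is correct and calibrated on data obeying its
assumptions — not that the assumptions hold for any particular
microscope or cell type.

## Thresholding conventions

All three thresholders (Huang–Wang minimum fuzzy entropy, Otsu
between-class variance, IsoData/Ridler–Calvard fixed point) operate on
a 256-bin histogram over the per-image min–max range — the FIJI
convention the original workflows relied on — and return the upper edge
of the selected bin; "dark background" orientation: pixels strictly
above the threshold are foreground. The Otsu objective is piecewise
constant across empty histogram gaps; the midpoint of the maximizing
plateau is returned so a balanced bimodal image splits between its
modes. Constant images raise instead of returning an arbitrary level.
The test suite checks all three against independent plain-loop
brute-force implementations for exact equality.

## Numerical choices

* Mono-exponential fits: τ initialized from the time to half the
  endpoint difference, amplitude from the endpoint difference, and τ
  bounded to (Δt/10, 100·window length); `converged` reports the
  optimizer status. Flat traces converge with |A| ≈ 0 and an
  unidentifiable τ — callers should gate on the amplitude.
* Bleach correction fits a·e^−bt to the frame means (no offset, the
  FIJI "Exponential" model) and divides by fit(t)/fit(0); a non-decaying
  series leaves the stack unchanged with a warning flag rather than
  inventing a correction.
* Mask perimeters use the Crofton multi-directional estimator
  (4 directions): naive boundary-pixel counting overestimates a
  circle's perimeter by up to ~27%, which would push the form factor of
  a disk far below 1. Analytic inputs (area, perimeter pairs) bypass
  digitization entirely.
* The change map is computed as 1·pre + 2·post categorical arithmetic —
  the clipping-safe equivalent of the 8-bit subtract-254/253 overlay
  trick — giving categories 0 (background), 1 (contraction),
  2 (extension), 3 (unchanged) and the conservation identities
  count(1)+count(3) = pre area, count(2)+count(3) = post area.
* Tracking ties (equal pixel overlap) break by larger
  intersection-over-union, then lower label id, for determinism.
* Trace correlation resamples both series by linear interpolation onto
  the coarser grid restricted to the common time span (area and
  resistance acquisitions use different intervals).
* Steps that were manual in the original workflows (hand-adjusted
  membrane thresholds, watershed edits, junction corrections) are
  exposed as optional mask/path overrides; the automated path is the
  tested one.

## Open design points

* The PIP3-style relocation statistic is reported as
  (R_act/R_pre − 1)·100 with membrane gain positive; depletion of
  cytosolic signal is reported as (1 − I_act/I_pre)·100 with depletion
  positive. The sign conventions are stated here because descriptions
  of "pre over activated" ratios in the literature are ambiguous.
* For open junction segments the minimum-distance polygon degenerates
  to the chord between the two corner points; closed per-cell contours
  use the polygon through all marked corners. Both modes are exposed
  (`JunctionPath.closed`).
* Both the per-cell and mean-trace fitting paths are available: fit
  each cell's `RatioTrace` or average traces first and fit once.

## Problem sizes

The shipped analyses and tests use desk-scale problem sizes chosen so
the whole suite runs in well under ten minutes on one CPU: 96×96-px
recruitment movies (96 frames), 100-seed recovery ensembles, 8-frame
morphology sequences at radius 50 px, 1000-replicate bootstrap
calibration with 1000 resamples each. All scale linearly if larger
scenes are needed.

## Known limitations

* The disk-phantom geometry gain G is exact only for the synthetic
  scenes; on real data the membrane/cytosol ratio depends on ROI
  placement and optical sectioning, so absolute efficiencies are
  comparable only within a protocol.
* The watershed segmentation assumes bright cells on dark background
  with one seed per cell; touching cells with dim boundaries will
  merge unless seeds are provided.
* The temporal color code maps the argmax frame; structures bright in
  several frames take the first maximum.
* Headline biological values (specific half-times, area changes,
  resistance amplitudes of particular GEF constructs) depend on the
  authors' raw data and are not reproduced here; the package
  reproduces the *methods* and verifies them on ground-truth scenes.
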