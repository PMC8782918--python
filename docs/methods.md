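# Methods

## Scope and model

`platemech` re-implements, as a tested library, the analysis stage of
single-platelet mechanophenotyping by real-time fluorescence and
deformability cytometry (RT-FDC): platelets in platelet-rich plasma are
advected through a 15 × 15 µm microfluidic constriction, each cell is imaged
in bright field, its contour is traced, and its shape is summarised by the
isoperimetric deformation

    deformation = 1 − 2·sqrt(π·A) / P

where A is the projected (cross-sectional) area and P the contour
perimeter.  Deformation is 0 for a circle and approaches 1 for elongated
shapes.  Per-event fluorescence maxima in three channels (CD61 platelet
identity, CD62P α-granule release, PAC-1 activated integrin αIIbβ3) give
molecular specificity; gating, per-sample medians, geometric means,
percent-positive fractions and stimulation fold changes produce the
condition-level summaries.  Confocal line profiles quantify the
cytoskeleton of spread platelets (marginal-band tubulin ring edge-to-edge
distance; F-actin subcortical enrichment).

Hypothesis testing (mixed-effects models, Tukey, Kruskal–Wallis/Dunn) is
deliberately *exported*: `stats.condition_panel_table` emits tidy tables
for any statistics environment.

## Synthetic populations

Because the original donor measurements are not redistributable, the
package ships a generator whose defaults encode the published
condition-level numbers, so the full pipeline can be validated by
parameter recovery.

* **Shape model.** Every cell is an ellipse parameterised by projected
  area and aspect ratio.  The real advected shapes are bullet-like, but
  the deformation metric depends only on (A, P), and ellipses span the
  needed deformation range with an exact perimeter (complete elliptic
  integral of the second kind).  `solve_aspect_for_deformation` inverts
  deformation → aspect ratio by vectorised bisection on [1, 10⁴]
  (deformation is strictly increasing in aspect ratio and scale-free), so
  a drawn deformation round-trips through (A, P) to better than 1e-9.
* **Event-level distributions.** Deformation, area and per-channel
  fluorescence are log-normal — strictly positive and right-skewed, the
  usual cytometry convention; the event-level CVs default to 0.35
  (deformation) and 0.30 (area), consistent with the broad single-donor
  scatter seen in this kind of data.  Deformation is truncated at 0.6
  (negligible mass for all presets).  Timestamps are a homogeneous
  Poisson process at 50 events/s, so a 5000-event acquisition finishes in
  well under the 10-minute stop limit.
* **Condition presets.** Non-stimulated medians per anticoagulant
  (deformation / area in µm²): ACD-A 0.127 / 5.035, Na-Citrate
  0.111 / 4.90, K2-EDTA 0.037 / 4.158, Li-Heparin 0.071 / 4.337,
  r-Hirudin 0.100 / 4.70.  Published sizes exist only for ACD-A, K2-EDTA
  and Li-Heparin; the Na-Citrate and r-Hirudin areas are the package's
  own interpolating choices consistent with the published ordering.
  TRAP-6-stimulated medians are derived by dividing by the published fold
  factors (deformation: 2.76, 2.58, 1.14, 1.72, 2.27; size: 1.28, 1.14,
  0.98, 1.04, 1.18 in the order above).  CD62P basal gMean is 10 AU for
  all anticoagulants (basal expression is anticoagulant-independent);
  stimulated CD62P/PAC-1 locations are basal × published fold.  PAC-1
  basal gMean is published only for Li-Heparin (82.48 AU); the others
  (35, 30, 12, 25 AU) are ordering-consistent choices.  Latrunculin-B
  presets multiply the matched vehicle deformation by 1.4–1.6 — a
  qualitative calibration, since only graphical values are published.
  MYH9-like (large, stiff) and matched same-day healthy-reference presets
  carry the published single-individual medians (e.g. MYH9 ACD-A resting:
  deformation 0.068, area 5.77 µm²) with no donor jitter.
* **Donor-level variability.** Each donor multiplies every preset median
  by a mean-one log-normal jitter whose relative SD (`donor_sd`, per
  metric) equals the published between-donor SD divided by the mean
  (e.g. 0.26 for ACD-A deformation, 0.10 for ACD-A area).  Paired
  stimulated conditions share the donor's baseline jitter, and the fold
  factor itself receives a mean-one jitter with relative SD equal to the
  published fold SD / fold mean — so per-donor fold changes are
  donor-consistent and their across-donor mean is unbiased at the preset
  fold.  Random streams split hierarchically (panel → donor →
  condition): adding donors never perturbs earlier donors.
* **What the generator does *not* model.** Hydrodynamics (shapes are
  sampled, not physically advected), bullet asymmetry, debris and
  doublets, fluorescence spill-over, camera shot noise statistics, and
  within-acquisition drift.  Passing recovery tests therefore validates
  the *measurement and summary chain*, not the instrument physics.

## Imaging

Rendered frames place an anti-aliased ellipse (coverage computed on an
8-fold supersampled grid and box-averaged) on a bright background between
dark channel-wall bands, with optional Gaussian blur and additive noise.
Default pixel size is 0.34 µm/px — a typical value for a 100×/0.8
bright-field setup; it is configurable everywhere.

Segmentation estimates the background from the frame border (upper
quartile, insensitive to the dark wall bands), thresholds pixels darker
than background − offset (offset default 0.25 = half the rendered cell
contrast, placing the traced level on the half-coverage boundary), and
traces outer boundaries with marching squares on a bicubic-spline
interpolation of the frame refined 8-fold (`refine`).  Open contours
(objects touching the border, e.g. walls) and components under
`min_area_px` (default 9) are discarded.  A circular moving-average vertex
smoothing (window 5) regularises the polygon; on the dense refined
contours its shrinkage is negligible, whereas on raw marching-squares
vertices it would bias platelet-sized perimeters by several percent.
Deformation values that fall below zero after smoothing are clamped to 0
and the clamp count logged.

Accuracy at 0.34 µm/px (noise-free renders): pipeline deformation within
±0.007 of the analytic value for aspect ratios 1–3 and areas 2–8 µm²,
improving as pixel size shrinks; contour areas within 2 % for
platelet-scale cells (≈ 4–8 µm²).  Below ≈ 4 µm² pixelation biases the
traced area low by up to ~3–8 % (a cell of area 2 µm² at aspect 3 has a
semi-minor axis of only ~1.4 px); the deformation, being a ratio of
consistently-biased quantities, remains within the ±0.01 band.

## Gating and summaries

Defaults follow the acquisition conventions: CD61 hard gate 150–33000 AU,
convex-hull area ratio ≤ 1.1 (roughness/aggregate filter), projected size
0–10 µm², stop at 5000 gated events or 600 s, whichever comes first.  The
size window is interpreted as *area* in µm² because sizes are reported in
µm² throughout the condition-level results.  Events failing a gate are
retained with boolean flags so audits and re-gating need no reprocessing;
the audit counts an event once per violated gate in the by-gate table and
once overall, so events are conserved.

Medians use the midpoint convention; gMean = exp(mean(ln x)) over strictly
positive intensities with exclusions counted.  The percent-positive cutoff
is not published; the default is the 99th percentile of the matched
non-stimulated (vehicle) sample per channel — a standard isotype/FMO-style
surrogate — and is configurable.  Fold-change direction follows the
reporting convention: mechanics metrics as a decrease factor
(unstim/stim), fluorescence as an increase factor (stim/unstim); both read
"changed by a factor of" against a baseline of 1.  KDE event densities use
a Gaussian product kernel with per-axis Scott's-rule bandwidth
(h = σ·n^(−1/6)), min–max scaled to [0, 1] for a linear colour scale.

## Line profiles

Profiles are sampled bilinearly along a 5 µm line, averaged over a 1 µm
perpendicular width, at half-pixel steps.  Tubulin edge-to-edge distance
is the separation of the outermost peaks exceeding 10 % of the profile
range in prominence, with three-point parabolic sub-sample refinement.
The 1 µm averaging width pulls ring peaks inward by ≈ w²/(24R); at the
default confocal pixel size (0.08 µm/px) the measured distance stays
within one pixel-equivalent of 2R and tracks the analytic width-averaged
profile.  The actin peripheral index — mean intensity over the outer 25 %
of the cell half-width divided by the mean over the central 50 % — is the
package's own quantification (published work reports these profiles
graphically); the band fractions are configurable, the index is invariant
under global intensity scaling and monotone in the generator's edge
weight.  One profile per image; centre and angle are supplied by the
caller, mirroring manual per-platelet line placement.

## Numerical choices and limitations

* Bisection tolerance for the aspect solver: 80 iterations on [1, 10⁴]
  (deformation round-trip ≪ 1e-9); inputs above deformation ≈ 0.97 exceed
  the bracket and are rejected.
* Convex-hull area ratios are clamped at 1 from below to absorb
  floating-point jitter on convex contours.
* Contours are normalised counter-clockwise, pixel-centred coordinates,
  x right / y down.
* Sample sizes in the recovery checks (6 donors × 5000 gated events per
  condition; ~1000 events for the single MYH9-like sample) mirror the
  published acquisition design; with 6 donors the published between-donor
  SDs imply a standard error of ≈ 0.23·fold/√6 on mean fold changes, so
  individual recovery runs scatter accordingly and are accepted within
  two donor-level standard errors.
* The HDF5/CSV event store records schema version, software version,
  column units, gate configuration and generator seed, sufficient to
  re-run gating bit-identically; the vendor's native acquisition format
  is intentionally not read or written.
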