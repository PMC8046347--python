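# Methods

`ivdt2` reimplements a quantitative lumbar intervertebral-disc (IVD) T2
workflow as a tested pipeline: semi-automated disc segmentation on
multi-echo sagittal MRI, five-subregion partitioning, mono-exponential T2
estimation, and a long-term test–retest reliability suite.  Because no raw
MRI accompanies the method, every stage is exercised end-to-end on a
synthetic spine phantom with full ground truth.  This note records the
models, the calibrated defaults, and the design choices where the
procedure left room.

## Signal model and T2 estimation

Each region of interest contributes one decay curve: the arithmetic mean of
in-region pixel intensities at each of the 16 echo times
TE = 10.9, 21.8, …, 174.4 ms.  The model is a pure mono-exponential,

    S(TE) = S0 · exp(−TE / T2),

fitted by bounded nonlinear least squares (T2 ∈ [1, 2000] ms for
plausibility; bound overridable), initialised from a log-linear regression
on the positive signals.  If the refinement fails the log-linear estimate
is returned with `converged=False`.  All 16 echoes are used; a
first-echo-exclusion flag and an additive noise-floor term exist for
sensitivity checks but default off.  Fitting happens on *region-mean*
signal, not per pixel: the reliability tables are built from the fits of
segment means, with a per-pixel map available only as an extra.

Two primary aggregates:

* **whole-disc T2** — the whole-disc ROI fit, averaged (unweighted) over
  the six slices.  Slices are not area-weighted; the procedure does not
  specify a weighting and the unweighted mean is the simplest estimator.
* **nuclear T2** — the single fit of subregion 3 (central fifth) on the
  third anatomical slice; no averaging.

## Segmentation

The chain operates on raw signal units and follows the published
thresholds:

1. *Median image*: 1-px-wide, 15-row vertical median of the second echo
   (highest disc/bone contrast), reflected padding at the borders.
2. *Spine centre*: the pixel column with the most pixels ≥ 100 units above
   the median image (signed difference — a pixel darker than its median
   never counts; ties go to the smallest column).
3. *Endplate seeds*: strict local minima of the centre-column profile
   below 150 units; plateaus report their lower-middle row.
4. *Contour tracking* from each seed, anteriorly and posteriorly: a step
   to the adjacent column may move ±2 rows and is accepted only if ≥ 3 of
   the target's 8-neighbours are below 150 units.  Among admissible targets
   the darkest wins; ties prefer the smaller row change, then the upper
   row.  Contours shorter than 5 px are discarded.
5. *Graph-search refinement*: ~8 support points per contour (operator
   file, or auto-placed equally spaced along the tracked contour so the
   pipeline runs unattended) are connected by a minimum-cost 8-connected
   path (Dijkstra, via `scipy.sparse.csgraph`).  The cost of entering a
   pixel is w₁·(1−cos θ)/2 + w₂·(normalised grey value), where θ is the
   angle between the pixel's gradient and the mean gradient direction at
   the two flanking support points; both terms are scaled to [0, 1] and
   w₁ = w₂ = 0.5 by default (the weighting is not specified anywhere;
   equal weights are the neutral choice and are exposed in
   `SegmentationParams`).  Gradients use central differences after
   Gaussian smoothing (σ = 1 px).  By default each pair is routed inside a
   padded bounding window for speed; `dijkstra_window_pad=None` searches
   the whole image (the setting used when validating against a brute-force
   shortest-path oracle).
6. *Anterior/posterior borders*: scanning outward from the centre column,
   the first column where |echo-averaged image − median image| ≥ 80 units.
   The pipeline scans vertebral-body rows adjacent to each disc (6–12 rows
   clear of the endplates) and takes the outermost hit per side: inside
   the spine the difference stays below threshold, so spurious early
   crossings can only pull borders inward, never outward.  Rows with no
   crossing inherit the nearest resolved row.
7. *Mask extraction*: each (superior, inferior) contour pair whose gap is
   bright on the second echo (mean ≥ 500 units — discs are far brighter
   than bone or background there) is filled strictly between the contours,
   clipped to the borders, holes filled.  Because tracked contours
   legitimately continue through dark background beyond the disc tips, the
   fill is then trimmed to pixels at or above the 150-unit level and the
   largest connected component kept (`trim_dark_pixels`, default on).
   Overlapping filled masks abort the slice: overlap always indicates a
   pairing failure upstream.

Each slice is segmented independently with the same parameters (the
central slice first).  Support-point propagation to adjacent slices —
nearest feature match within a 5-px radius on |Δgrey| + λ·|Δgradient
magnitude| + λ·gradient-angle difference, λ = 0.5 — is implemented and
tested, and is used when operator points are supplied for the middle slice
only.  Candidates are visited by increasing displacement, so identical or
featureless neighbourhoods leave a point in place.

Level labels run cephalad→caudad (T12/L1 … L5/S1 for six discs); the most
cephalad disc is segmented and recorded but excluded from default
reliability reports, which cover L1/2 … L5/S1.

## Subregions

Each disc mask is oriented by its image-moment ellipse (angle of the major
axis to the x-axis, in (−90°, 90°]; degenerate moments → 0° by
convention), rotated to the horizontal about its centroid
(nearest-neighbour for masks), and split into five contiguous column bands
of equal width; a remainder r = width mod 5 gives one extra column to each
of the r most anterior bands.  Band membership for the *original* pixels
is assigned by rotating pixel coordinates, never intensities, so the grey
values entering the T2 fit are untouched by interpolation and the five
bands partition the original mask exactly.  Anterior is at low x; the
orientation flag is explicit in the configuration rather than guessed.

## The phantom

The phantom is a calibrated test object, not an anatomical simulation.  A
sagittal scene of seven rectangular vertebral bodies separated by six
tilted elliptical disc lenses (half-width 22 px, half-height 3.2 px, tilts
±2–4°, 0.781 mm/px grid) is rendered at the 16 protocol echo times with
per-tissue mono-exponential decay and, by default, Rician magnitude noise
(σ = 20 units; `gaussian` and `none` retained for oracle tests).

Disc subregion T2 defaults carry the reported lumbar magnitudes (nucleus
≈ 120–146 ms, annulus ≈ 78–100 ms, L5/S1 nucleus lowest), disc S0 = 1400.
The remaining tissues are calibrated so the segmentation's raw-unit
thresholds are meaningful:

* vertebral body S0 = 250, T2 = 250: second echo ≈ 229 (above the 150-unit
  endplate level, so body interiors never seed) while
  |echo-average − median| ≈ 53 stays under the 80-unit border threshold;
* endplate rim (2 px around each disc) S0 = 300, T2 = 15: second echo ≈ 70,
  a deep local minimum that seeds reliably even at σ = 25;
* a 2-px *wall marker* column at the anterior/posterior spine walls,
  S0 = 300, T2 = 55: T2 ≈ 55 ms maximises the second-echo minus
  echo-average contrast for these TEs, giving |averaged − median| ≈ 127 at
  the wall — a robust 80-unit crossing.  A dark wall cannot serve here:
  under Rician noise the magnitude floor (σ√(π/2)) inflates the
  echo-average of near-zero signals and erases the crossing.

The body T2 of 250 ms is unphysiological for marrow; it is an intensity
calibration (the original scanner's receiver scaling is unknown), and the
phantom's purpose is to reproduce the *intensity regime* the thresholds
assume, with disc-minus-bone second-echo contrast ≈ 900 units.

Ground-truth subregion labels are painted by the same ellipse-rotation
partition the analysis uses (shared code), so a truth-mask analysis agrees
with the truth geometrically by construction — this is deliberate and
means geometric-disagreement error is assessed only through the full
segmentation path.  The whole-disc "true" T2 of a five-tissue disc is
defined as the mono-exponential fit to the exact noiseless mixture decay
(a mixture has no single T2).

What the phantom does *not* emulate: partial volume, B0/B1 bias fields,
motion, through-plane anatomy changes (slices are geometrically
identical), and realistic marrow/ligament texture.  Passing tests
therefore demonstrate algorithmic correctness and noise robustness, not
clinical-image performance.

## Longitudinal studies

A study is subjects × sessions with a dropout pattern; the default 12 × 9
design drops to 11, 10, 10, 8, 8 subjects over the last five sessions.
Subject i, session j shifts every disc T2 additively by bᵢ + wᵢⱼ, with
bᵢ ~ N(0, σ_B²) and wᵢⱼ ~ N(0, σ_W²), so the true ICC is
σ_B²/(σ_B²+σ_W²).  Defaults σ_B = 13 ms, σ_W = 2 ms (between-subject SD of
the order of the reported whole-disc global SDs; within-subject SD of the
order of the reported ~2% whole-disc CV).  `calibrate_study` converts a
target whole-disc CV/ICC into shift SDs through the numerically evaluated
slope of effective whole-disc T2 with respect to a uniform shift (< 1 for
a mixture).  Sessions are rendered lazily and are reproducible from
(study seed, phantom seed, subject, session).

## Reliability statistics

* **ICC(1,1)** — one-way random-effects ANOVA:
  ICC = (BMS − WMS)/(BMS + (k₀−1)·WMS).  Unbalanced tables use all
  available observations with k₀ = (N − Σkᵢ²/N)/(n−1).  The 95% CI is the
  exact F-based interval.  Implemented from scratch; validated against a
  definition-level oracle (1e-12) and pingouin's ICC(1,1).
* **SEM** = SD(all observations pooled) · √(1−ICC).  The "SD of sample
  scores" is the pooled SD over subjects and sessions, which matches the
  global-mean(SD) column convention of the reported tables.  Negative ICC
  estimates are reported as computed but clamped to 0 inside this formula
  only, with a warning.
* **MD** (minimum detectable difference) = SEM·√2·1.96; **MD%** =
  100·MD/mean.  SEM/MD confidence bounds are propagated from the ICC
  bounds (upper ICC → lower SEM); since the original tables' CI
  construction is unstated, tests assert ordering/containment, not
  equality.
* **CV** — within-subject: per subject with ≥ 2 sessions,
  CVᵢ = SDᵢ/meanᵢ; reported CV is the RMS over subjects × 100, with a
  chi-square CI on the pooled within-subject variance at Σ(kᵢ−1) degrees
  of freedom.  (The reference formula behind the original CVs is not
  reproduced in the text; this is the package's stated interpretation.)
* **Bland–Altman** — each follow-up vs baseline (not all session pairs):
  paired differences on common subjects, limits of agreement
  mean ± 1.96·SD, linear bias as the OLS slope of difference on pair mean,
  with Benjamini–Hochberg FDR over the comparisons (α = 0.05 throughout).
* **Classification** — ICC < 0.40 poor, 0.40–0.59 moderate, 0.60–0.74
  good, ≥ 0.75 excellent.
* **Tables** — one row per measure with an "AvLx" row computed on
  per-subject level-averaged values, and grade-stratified rows (pooled
  (subject, disc) units per degeneration grade) when labels are supplied.
* Session labels can be blinded by seeded random relabeling; all
  statistics are label-invariant (tested).

## Problem sizes and numerical choices

* Default phantom grid 256×128, 6 slices, 16 echoes; a session renders in
  ~0.15 s and segments in ~2.5 s.
* The many-replicate study emulation uses a reduced phantom (2 discs,
  2 slices, 64-px width) with ground-truth ROIs — segmentation accuracy is
  characterised separately (noiseless Dice ≈ 1.0; ≥ 0.90 under noise and
  geometry jitter; region-T2 bias ~1% at SNR ≈ 50) — so that 100
  replicates of a 12×9 study complete in a few minutes.
* Ties are broken by fixed rules everywhere (smallest column, lower-middle
  plateau row, smallest row change then upper row, increasing displacement
  in propagation), making the entire chain deterministic; re-running a
  seeded pipeline produces byte-identical CSVs.
* curve_fit tolerances are tightened (xtol = ftol = 1e-12) so noiseless
  round trips recover T2 to ≤ 1e-6 relative.

## Known limitations

* The phantom's intensity calibration is specific to the published
  raw-unit thresholds; applying the segmentation to other scanners
  requires re-scaling thresholds via `SegmentationParams`.
* Operator interaction is reduced to support-point files; there is no
  interactive correction loop.
* One-way ICC only; no ICC(2,1)/(3,1), no mixed-model variance
  decomposition, no equivalence testing.
* Degeneration grades are consumed as labels; grading itself is out of
  scope.
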