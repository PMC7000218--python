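# Methods

This note documents the models, parameter choices, and numerical decisions
behind `zincycle`, and what the synthetic data do and do not emulate.

## Trace model and the synthetic generator

Cells are simulated as single lineages sampled on the acquisition grid
(12-minute frame interval, 60 h duration by default). Each cell enters the
movie mid-cycle: its first division falls uniform on (2 h, 20 h) — wide
enough to cover one full cycle of an asynchronous population — and its
pre-division CDK2 ratio ramps linearly up to a maximal ratio reached at
mitosis. At mitosis the ratio resets, and the post-mitosis trajectory is
drawn from the condition's fate mixture:

| condition | p(CDK2inc) | p(CDK2emerge) | p(CDK2low) |
|-----------|-----------:|--------------:|-----------:|
| ZD        | 0.09 | 0.50 | 0.41 |
| MM        | 0.56 | 0.27 | 0.17 |
| ZR        | 0.60 | 0.26 | 0.14 |
| MM-p21KO  | 0.65 | 0.27 | 0.08 |
| ZD-p21KO  | 0.10 | 0.48 | 0.42 |

The ZD components, the MM/ZR quiescent fractions, the MM prompt-commitment
fraction, and the p21-null quiescent fractions are anchored to reported
population fractions for those conditions; the remaining components are
free parameters normalized to sum to 1. The schedule-conditioned
(zinc-withdrawal-timing) experiment instead draws each cell's mixture from
the 4-h window its division occupies relative to the perturbation:

| window (h) | p(inc) | p(emerge) | p(low) |
|------------|-------:|----------:|-------:|
| [−4, 0)  | 0.55 | 0.30 | 0.15 |
| [0, 4)   | 0.43 | 0.40 | 0.17 |
| [4, 8)   | 0.30 | 0.47 | 0.23 |
| [8, 12)  | 0.17 | 0.50 | 0.33 |
| [12, 16) | 0.05 | 0.50 | 0.45 |

Here the pre-window quiescent fraction (15%) and the inc fractions
(43/30/17/5%) are anchored; the emerge/low splits are free.

Trajectory templates (`CommitShape`): post-mitotic baseline ratio 0.5, rise
rate 0.35 ratio-units/h, maximal ratio 1.9, commitment level 1.0.
CDK2inc cells draw their commitment-crossing time uniform on (0.5 h,
3.5 h) — inside the 4-h decision window with a margin, so class membership
is a property of the trajectory rather than of sampling jitter at the
boundary. CDK2emerge crossings are uniform on (4 h, 20 h); no delay
distribution is reported for this class, so a flat prior over the plausible
range is used. Cells committing earlier than the ramp allows are born with
already-elevated activity, which matches the biology of prompt committers.

In stall conditions (ZD, ZD-p21KO, and post-withdrawal schedule cells) all
committed cells rise only to the stall plateau (default ratio 1.2), hold
it to the end of the movie, and never divide again. In replete conditions
committed cells reach the maximal ratio and keep cycling with inter-mitotic
times drawn from a lognormal parameterized by its histogram mode (13 h) and
log-dispersion (0.12) — right-skewed, as measured inter-mitotic times are.
Gaussian noise (sd 0.05 ratio units) is added to every trace and clipped
at zero.

## Movie rendering

Nuclei are isotropic discs (radius uniform on 8–12 px at 256×256), the
smallest geometry at which a 3-px perinuclear ring is well defined. Motion
is a per-frame Gaussian walk (sd 1 px) with collision rejection and
reflecting margins, exercising the tracker without ambiguous crossings.
Over the three frames before a division the nucleus condenses: total H2B
intensity rises to 1.45× while the radius shrinks to 0.58× (area 0.34×).
The rendered shrinkage is deliberately stronger than the detector's gate
(area ≤ 0.6×) because blur and thresholding inflate the segmented footprint
of the very bright condensed nucleus by roughly 10 percentage points of
area fold. At the division frame the nucleus splits into two daughter
blobs; the tracked lineage continues as one of them and the sibling
persists as an independent baseline-ratio cell.

The CDK2 channel paints a cytoplasmic disc extending 6 px beyond the
nucleus at (nuclear level × programmed ratio), then overwrites the nuclear
disc at the nuclear level. Frames are smoothed with a Gaussian (sigma 0.6)
and carry additive Gaussian noise (sd 2 intensity units against a nuclear
level of ~100). Zero-noise programmed ratios round-trip through rendering
and ring quantification within ±0.01 for nuclei ≥ 8 px radius.

Trace noise (`noise_sd`, ratio units) and image noise (`image_noise_sd`,
intensity units) are separate fields because they live on different scales.

## Segmentation, tracking, mitosis detection

Segmentation: pixels exceeding a local mean (window 41 px ≈ 2× nucleus
diameter) by a configurable offset (default 10) form the foreground; holes
are filled, regions < 30 px² dropped, and touching nuclei are split by
watershed on the Euclidean distance transform seeded at h-maxima (h = 2)
of the distance map. Regions are 8-connected.

Tracking: greedy nearest-centroid assignment with a 10 px/frame gate
(Hungarian assignment available via `TrackingParams(method="optimal")`;
on non-pathological synthetic scenes the two agree). There is no gap
closing across missing frames — at a 12-minute cadence single-frame
dropouts are rare in the synthetic data; this is a documented limitation
for real movies with segmentation dropouts.

Mitosis: a newborn object adjacent (≤ 18 px) to a mother is accepted as a
daughter only if the mother's mean H2B intensity rose ≥ 1.3× and its area
fell to ≤ 0.6× over the 3 frames before the split. The thresholds are
declared defaults exposed in `MitosisParams`, not measured constants.
Splits without the signature leave the newborn as an unrelated track, which
is what gives the detector precision 1.0 on over-segmentation fixtures.

## Reporter quantification and Zn calibration

The perinuclear ring is built with nearest-label expansion: each background
pixel within 3 px (Euclidean) of a nucleus joins the nearest nucleus's
ring, so rings never overlap each other or foreign nuclei, and a ring never
exceeds 3 px in Chebyshev distance. Nuclei touching the image border are
returned with partial rings and flagged. The cytoplasmic statistic defaults
to the ring **median** (robust to bleed-through from neighbors and to blur
at the nuclear boundary); `stat="mean"` is available. The same ring serves
the FRET reporter; for automated live-cell background estimation the mean
of the dimmest 5% of non-cell pixels stands in for a manually drawn dark
region.

Calibration follows the Hill-form sensor model with defaults
K_D = 5300 pM and n = 0.29. `zn_concentration` is the exact inverse of
`hill_response`; the round trip is tested to 1e-6 relative across the full
fractional-saturation range. R_rest = R_max raises an explicit
infinite-concentration error; R_rest = R_min returns 0 pM.

## Fate classification

Traces are aligned to a chosen mitosis (first by default); cells lacking it
are excluded and reported. Classification uses the first upward crossing of
the commitment threshold (default 1.0 — cytoplasmic equals nuclear signal)
that persists for 2 consecutive samples; the persistence rule suppresses
single-sample noise excursions that would otherwise bias crossings early
near the 4-h inc/emerge boundary. Cells with less than 10 h of post-mitosis
followup (to the next division or trace end) are "unclassifiable" and
excluded from fate fractions, avoiding censoring bias; `classify_ensemble`
keeps them (and never-dividing cells) in its output so both denominators
are available.

Stall rule: a committed cell is stalled when its ratio stays within
[commit_threshold − 0.1, 1.5) from commitment to trace end for ≥ 8 h with
no further mitosis; the plateau estimate is the median over the final 8 h.
The plateau value (~1.2) is the observable; the band and hold duration are
declared detection parameters.

Window binning uses half-open [a, a + 4 h) windows in perturbation-relative
time, so a mitosis exactly at the perturbation joins the first
post-perturbation window; cells dividing outside the binning range are
counted, not silently dropped. Inter-mitotic times are differences of
consecutive division times along each lineage; the mode is the center of
the tallest 1-h bin with integer-aligned edges. Heatmap sorting and ratio
densities follow the conventions in their docstrings; density histograms
integrate to 1 by construction.

## Fixed-cell analysis

Foci: each cell gets a 140×140 crop around its centroid. The detection
threshold is background + max(sensitivity × (peak − background),
5 robust sigmas), with background and sigma estimated from the dim half of
the cell's own nucleus pixels — bright puncta can cover a large nuclear
fraction, so plain medians over the nucleus are biased upward. The
sensitivity default (0.5) places the threshold at the puncta's half-max,
so component footprints match the planted above-half-max areas. Components
are kept if their area lies within the marker's range (53BP1 10–200 px²,
RPA2 10–100 px²), their moment-ellipse eccentricity is < 0.6, and they
overlap the cell's own nucleus (enforcing nuclear overlap rather than mere
crop membership is a deliberate choice and a possible divergence from
pipelines that score the whole crop). The noise-floor term keeps
featureless nuclei focus-free. On rendered fields recall and precision are
≥ 0.95 for in-filter puncta.

pRb classing fits a two-component Gaussian mixture on log intensity
(deterministic initialization at the 20th/80th percentiles) and cuts at the
equal-posterior point; a separation of < 2 pooled sigmas or a component
weight < 2% triggers a single-class result with a warning. Working in log
space makes the labels invariant to a global gain.

EdU background: the image is tiled by an 11-by-11 grid of equal blocks and
each block's 5th-percentile intensity is subtracted (negatives clipped).
"11 × 11" is read as a grid of 11×11 blocks tiling the image, not 11-px
blocks; the grid is an argument in case the other reading is wanted.
DNA content is the summed nuclear PI intensity; 2N/4N centers are the two
most prominent peaks of a lightly smoothed histogram, with a separation
requirement (second peak ≥ 1.4× the first) so histogram wiggle in a
unimodal population cannot fake a 4N mode; gates extend ±25% around each
center with "intermediate" between. Phase calls: EdU⁺ → S; EdU⁻ 2N →
G0/G1; EdU⁻ 4N → G2/M; EdU⁻ intermediate → unclassified. The EdU
positivity threshold is the negative-mode peak + 3 robust sd when not
supplied.

## Problem sizes, seeds, determinism

Identical configuration and seed give bit-identical ensembles, movies, and
truth tables; per-purpose child generators are derived from the seed plus a
role tag. Trace-level recovery runs use 2000 cells per condition (4000 per
seed for the window experiment, since each 4-h window receives only ~1/5 of
the cells); the image-level foci run uses 1000 cells across ~28 fields of
512×512. `scripts/acceptance.py` uses 12000 cells for the window experiment
to tighten the per-bin sampling spread. Recovery tests run over five seeds:
the classifier must match the ensemble's realized fate draw within 1.5
percentage points on every seed, and the recovered fraction must fall
inside the exact binomial 95% CI of the planted parameter in most seeds
(the draw itself is binomial, so ~1 seed in 20 legitimately falls outside
per component).

## What the synthetic data do not emulate

No point-spread function, shot noise, photobleaching, focus drift, or
uneven illumination in the movies (a smooth gradient is applied only to the
EdU channel, where block subtraction is under test); no cell death,
overlapping/touching nuclei clusters beyond the two-disc watershed case, or
segmentation dropouts; trace noise is white Gaussian rather than temporally
correlated. Passing tests therefore demonstrate the correctness of the
analysis logic under controlled conditions, not robustness to every
real-microscopy artifact; the parameter surfaces (thresholds, gates,
windows) are the knobs a user would retune on real data.
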