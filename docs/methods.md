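# Methods

## Problem and approach

In co-culture, a flagellated protist (*Trichomonas gallinae*) swims among
far smaller, slower rod-shaped bacteria (*E. coli*). Quantifying protist
motility from phase-contrast time-lapse movies therefore requires a
*selective* tracker: only protist cells may be segmented and linked, even
though both species are in the field. trichotrack re-implements such a
pipeline as a tested library and validates it end to end on synthetic
movies with per-cell ground truth, which the original imaging data cannot
provide.

The processing chain is fixed:

1. 8-bit conversion (linear min–max rescale unless already 8-bit);
2. constant subtraction of 50 grey levels (clamped at 0);
3. per-frame 2-D Gaussian smoothing, σ = 2.0 px;
4. global histogram-minimum thresholding;
5. connected-component measurement (8-connectivity, Crofton perimeter,
   circularity = 4πA/P² capped at 1);
6. particle filtering — exclude area > 40 px or circularity < 0.25;
7. 3-D Gaussian blur of the retained mask, σ = (1, 1, 1) in x, y, frame;
8. greedy nearest-neighbour linking of retained-particle centroids;
9. eight per-track motility metrics;
10. ROUT outlier trimming of metric distributions;
11. per-timepoint Kruskal–Wallis comparison between conditions (plus
    unpaired t and fold change for culture densities).

The default input is a pixel-classifier probability map (255 = certain
protist); raw frames are accepted through the same chain.

## Synthetic co-culture generator

Cells follow a persistent random walk: a per-cell speed is drawn once from
a log-normal distribution (parameterized by its median in µm/s and the SD
of the log; default dispersion 0.35 gives the broad violin-like spread
seen in real track data), and each frame the heading receives wrapped
Gaussian turning noise (flagellates 0.25 rad/step, bacteria 0.8 rad/step)
before a fixed-length step of speed × Δt. Boundaries are reflective, so
tracks are never truncated at the field edge. A stationary cell's heading
is frozen — heading is defined as the direction of motion. Cells may
overlap when rendered; there is no collision or crowding model.

Rendering: flagellates are filled ellipses (default semi-axes 4.5 × 2.7 µm)
oriented along the heading; bacteria are capsules (default 2.0 × 0.8 µm).
Both get ~1 px soft anti-aliased edges, additive Gaussian camera noise
over a uniform background, and 8-bit clipping. Probability maps render
flagellate bodies at 255 with the same distance-tapered edges, bacteria
and background at 0, plus classifier noise (default SD 6).

Calibration defaults: 1.8 µm/px and 0.09 s/frame (a ~90 s acquisition of
>1000 frames). At this pixel size a flagellate body thresholds to a
10–30 px footprint — consistent with the ≤ 40 px retention bound — while
an *E. coli*-sized rod is sub-resolution (≲ 1 px). Bacteria are therefore
rejected mostly *upstream* of the circularity filter: their dim,
sub-resolution specks fall below the histogram-minimum threshold, and any
residual detection fails the filters. The circularity bound matters for
elongated multi-pixel rods (a 16 × 1 px rod has Crofton circularity 0.21;
an 8 × 1 px rod, 0.39 — thin shapes only drop below 0.25 once they are
long enough).

Field occupancy: 20 flagellates per 384 × 384 px field corresponds to a
protist density of 2.5 × 10⁵ cells/mL for a ~0.7 × 0.7 mm, ~100 µm-deep
observation volume; the default bacteria:protist count ratio is 1:10. The
selectivity stress scene deliberately inverts this to 10 bacteria per
flagellate so that mis-segmented bacteria cannot hide in small numbers.

**Analysis-scale conditions.** The validation studies sample every fifth
frame of the acquisition cadence (Δt = 0.45 s, 40 frames per movie). At
10 µm/s this gives per-frame displacements of ~2.5 px, well above the
~0.2 px centroid localization noise of the segmentation, so recovered
speeds are not dominated by jitter; at the raw 0.09 s cadence a 10 µm/s
step is 0.5 px and sub-noise speed inflation would measure localization
error, not motility. Both cadence and movie length are plain config keys.

What the generator does *not* emulate: phase-contrast halos and PSF
optics, classifier feature noise and false positives on debris,
cell–cell adhesion, division, or focus drift. Passing tests show the
operator chain, tracker and statistics behave correctly on movies whose
geometry and kinetics match the study design — not that a real classifier
would reach the same purity on real images.

## Histogram-minimum threshold

The 256-bin histogram is repeatedly smoothed with a 3-point moving mean
(edge bins replicated) until exactly two strict local maxima remain; the
threshold is the midpoint of the lowest-valued plateau between them, and
foreground is every pixel strictly above it. The midpoint convention makes
the threshold of a wide flat valley symmetric and deterministic (the
first-crossing alternative returns the valley's left edge, which is
arbitrary for flat valleys). A 10,000-iteration cap guards non-bimodal
histograms: those raise an explicit error, and the chain can fall back to
a configured constant threshold — cell-free frames (histograms that never
become bimodal) then segment to "nothing" with a fallback of 255.
Thresholds are computed per frame by default, matching frame-wise stack
processing and tolerating illumination drift; a per-stack mode pools the
histogram.

## Tracking

Greedy shortest-link-first assignment: within each consecutive frame
pair, candidate pairs inside the linking radius are taken in ascending
(distance, end label, next label) order, each spot used at most once;
leftover spots seed new tracks. Optional gap closing lets a track end
claim a spot g frames later within radius × (g + 1). Tracks shorter than
3 spots are dropped. The default radius is 1.5× the expected maximum
per-frame step (25 µm/s at the current calibration), logged at startup.

Greedy linking is deterministic and adequate at the study's densities
(~20 cells per field), but it is *not* a minimum-total-distance or
maximum-cardinality assignment: it returns the maximal matching whose
ascending edge sequence is lexicographically smallest (it will take one
globally shortest link over a feasible two-link alternative). The test
suite verifies the implementation against an exhaustive enumeration of
that optimum on thousands of small instances, and measures ~99%
link-level agreement with ground-truth identities on default scenes.

## Track metrics

With positions p₁..p_N at frames f₁..f_N and steps dᵢ = ‖pᵢ₊₁ − pᵢ‖:
duration = f_N − f₁; total = Σdᵢ; net = ‖p_N − p₁‖; max distance =
maxᵢ‖pᵢ − p₁‖ (displacement from the first spot, not max pairwise);
mean speed = total/duration; straight-line speed = net/duration;
confinement ratio = net/total; linearity of forward progression =
straight-line/mean speed (algebraically equal to confinement; both are
reported because both appear in standard tracker output); mean
directional change rate = mean |atan2 angle between successive non-zero
steps| per second. Physical units: speed × pixel size / frame interval.
Zero-total-distance tracks get NaN confinement/linearity (0/0) and are
excluded from summaries; tracks with < 2 spots are rejected outright.

## ROUT outlier trimming

Univariate specialization (constant model) of robust regression plus
FDR-controlled outlier removal. The location is fitted by minimizing the
Lorentzian merit Σ log(1 + (r/RSDR)²), initialized at the median and
alternated with scale re-estimation; RSDR = 68.27th percentile of |r| ×
n/(n − 1). Candidates are the 30% largest |residuals|; scanning from the
least extreme candidate upward, point i (ascending |residual| rank) and
all more extreme points are flagged when its two-tailed t probability on
n − 1 df falls below Q(n − i + 1)/n — the Benjamini–Hochberg step-up
schedule, under which the most extreme point faces Q/n. Q defaults to
0.01 (the method's recommended value). Trimming is two-sided; that
trimmed values are "mostly extremely high" is an empirical property of
speed distributions, not a rule. Samples with n < 10 are returned
untrimmed with a warning. Trimming is applied per metric per condition
per timepoint. Measured behaviour (seeded): false-flag rate ~10⁻⁵ on
clean normal samples; a 10-RSDR spike is caught in 100% of repetitions.

## Group statistics

Kruskal–Wallis (tie-corrected H, χ² p on k − 1 df) per timepoint with no
multiplicity correction, mirroring per-comparison reporting; Student's
pooled-variance t by default for density comparisons with Welch as an
option; fold change = ratio of means. Degenerate inputs take their
limits: all-identical data give H = 0, p = 1; zero pooled variance gives
t = 0, p = 1 (equal means) or |t| → ∞, p → 0 (unequal). Implementations
are scipy-backed; tests verify them against first-principles rank and
pooled-variance arithmetic, and their type-I error at α = 0.05 is
measured at ~0.05 over 2,000 null simulations each.

## Numerical and design choices

- Crofton 4-direction perimeter (ImageJ-convention circularity, capped at
  1); circularity near 0.25 is estimator-sensitive, so the estimator is
  fixed and documented.
- Area/circularity bounds are strict readings of the published
  exclusions: particles with area > 40 px or circularity < 0.25 are
  removed, boundary values kept. Both bounds are config keys.
- Excluding particles *larger* than 40 px is kept verbatim; it matches
  low-magnification acquisition where the protist footprint is tens of
  pixels and merged blobs should be dropped.
- Per-movie seeds derive from the run seed via `SeedSequence` spawning;
  identical config + seed reproduces every output byte-identically.
- Condition medians default to 6.6 (monoculture) and 10.2 µm/s
  (co-culture) at all four timepoints — the only timepoint with published
  medians is 4 h; co-culture cells were faster throughout.
- The growth-curve emulation uses triplicate log-normal counts (CV 8%)
  around a course that seeds both conditions at 2.5 × 10⁵ cells/mL, puts
  monoculture ahead at 24 h and co-culture ~2.3-fold ahead at 48 h.

## Known limitations

- No watershed splitting: touching flagellates merge into one particle
  and are usually discarded by the area bound, fragmenting tracks. Track
  counts therefore exceed cell counts, and track-level speed medians
  carry a small (~3–6%) upward bias because fast cells fragment more.
- Greedy linking degrades in dense crossings; no LAP/Kalman tracker.
- The ROUT implementation covers the constant model only, not nonlinear
  regression.
- Probability maps are a geometric stand-in for a trained pixel
  classifier; real classifier errors are not modelled.
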