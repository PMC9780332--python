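# Methods

## Charge model

Net charge is the integer "expected charge" at neutral pH: +1 per lysine or
arginine, −1 per aspartate or glutamate, histidine and all other residues
neutral, chain termini and any chromophore maturation ignored.  Under this
convention the tag unit GGSKKRKKR carries +6, a 6×His purification tag is
charge-neutral, and the three globular domains used throughout the examples
carry −7, 0 and +6.  The model deliberately avoids pKa/titration treatment:
design decisions downstream (tag length, linker lysines) operate on ±1
integer steps, and the in-vivo behavior thresholds are stated on the same
integer scale.  Non-canonical letters (X, B, Z, U) are rejected by default;
a permissive mode counts them as neutral with a warning, which is the
practical choice when scanning proteome FASTA files.

The tag designer minimizes the repeat count first and the lysine-linker
count second (linker ∈ 0..5), placing the linker between the domain
C-terminus and the first repeat.  Transient mode solves
`domain + linker + 6n = +6` exactly and is infeasible for domains above +6
(cationic additions cannot lower charge); persistent mode lands on the
smallest achievable charge ≥ the target (default +12, the lowest charge
at which condensates were persistent across a growth course; the weaker
"> +6" rule is available by passing a different target).

## Synthetic scenes

A scene is a field of non-overlapping spherocylinders (rectangle + half-disk
caps), the standard 2D model of *E. coli*.  Defaults: length 2–4 µm, width
0.9–1.1 µm, pixel size 0.065 µm/px (100×/1.4 NA on a typical sCMOS),
cytoplasm 300 counts over a 20-count background.  A Bernoulli draw per cell
(probability `condensate_fraction`) assigns condensates: disks of radius
0.25–0.40 µm placed on the medial axis near a randomly chosen pole
(configurable to uniform-along-axis), with intensity ρ × cytoplasm,
ρ = `partition_ratio` ≥ 1.  The field is blurred by a Gaussian PSF
(σ = 1.2 px ≈ 0.21 λ/NA at 510 nm), degraded by Poisson shot noise
(gain 1) plus Gaussian read noise (σ = 3 counts), and quantized to 16 bits.
Rendering is fully determined by the seed; with noise and PSF off, total
intensity decomposes exactly into background + cytoplasm + (ρ−1) × focus
terms, which the tests assert.

What the generator does **not** emulate: coacervation physics (foci are hard
disks, not intensity gradients), 3D sectioning, cell-to-cell expression
variability, touching or dividing cells, debris, and uneven illumination
beyond what the rolling ball removes.  Passing tests therefore demonstrate
that the detection chain recovers known ground truth under idealized but
noisy imaging, not that it is robust to every real-world artifact.

Growth tables: OD follows a logistic curve (od0 0.05, capacity 2.0, rate
0.8 h⁻¹); total fluorescence accumulates at
`expression_rate × OD(t) × exp(−t/τ)` with τ = 5 h, so the per-cell proxy
(fluorescence/OD) rises from induction and flattens in stationary phase.
The naive closed form without the decay (fluorescence = rate × ∫OD) makes
the proxy grow without bound once OD saturates — the decay models protein
synthesis winding down as resources deplete and is what produces the
rise-then-plateau shape; setting `expression_decay_h=None` recovers the
closed form (`proxy = rate × t` at constant OD), which the tests use.

## Background subtraction

The rolling-ball background is the upper envelope of a ball of radius R
(default 100 px) rolled under the intensity surface — equivalently a
grayscale opening with the non-flat ball structuring element.  The
implementation composes `skimage.restoration.rolling_ball` (which returns
the ball-apex erosion) with the matching grayscale dilation to complete the
opening; tests verify pixel-exact agreement with an explicit-loop opening.
For R > 32 px the computation runs on a bilinearly downscaled copy (factor
4 up to R = 128, else 8) and the background is upsampled and clamped under
the image — the ImageJ-style approximation, accurate because the ball
envelope is smooth at that scale.  `downscale=1` forces the exact path.
Within one radius of the image border the ball loses support and the
background dips; this artifact is inherent to the algorithm (the brute-force
opening shows it identically).  The subtraction is translation-equivariant
and its background estimate is monotone in the input; the *subtracted*
image is not monotone in general (raising the surroundings of a peak can
raise the background under it), so only the background property is asserted.

## Li thresholding

`li_threshold` minimizes the Li & Lee cross-entropy
η(t) = −Σ_{g<t} g log μ₀(t) − Σ_{g≥t} g log μ₁(t) **exactly**: the objective
is piecewise constant between observed intensities, so every split of the
sorted pixels is scored with prefix sums (O(n log n)) and the midpoint of
the best split's bracketing intensities is returned.  The classical
iterative fixed point t ← (μ₀−μ₁)/(log μ₀ − log μ₁) converges to a
stationary point of the same objective but can settle a few gray levels
from the discrete argmin on overlapping-mode histograms; tests pin the
exact minimizer to a naive brute-force search and cross-check the scikit-image
fixed point at a 5-level tolerance.  Constant images raise a degenerate-image
error.  All-zero below-threshold mass contributes 0 (the 0·log 0 limit), so
non-negative images need no shifting.

## Segmentation

Binarize at the Li threshold, fill holes, label with 8-connectivity, discard
border-touching components, then filter on shape: area 150–2500 px², length
1–6 µm, width 0.5–1.6 µm, circularity (4πA/P²) 0.2–0.9, angularity
≤ 0.35 rad.  These windows are stand-ins for MicrobeJ-style constraints and
are fully config-exposed.  The medial axis is the skeleton pruned to its
longest path (double BFS over the 8-connected skeleton graph), smoothed with
a 5-point moving average.  Width is twice the mean distance-transform value
along the axis.  Length is the maximum of (smoothed path length + the two
endpoint distance-transform values) and (mask extent along the principal
axis + 1 px): digital skeletons retract irregularly at the poles of oblique
rods, so the principal-axis extent bounds the straight-rod case while the
path-based measure handles bent cells.  Angularity is the mean absolute
turning angle along the smoothed axis sampled every 4 px — a straight rod
scores ≈ 0, bent chains and irregular debris score high.  Components whose
skeleton degenerates below 3 px fall back to ellipse axis lengths with
angularity 0 (circularity then rejects round blobs).

## Condensate calling

The cytoplasm reference is the median intensity over a 3-px-radius disk at
the medial-axis midpoint (median rather than mean so a stray bright pixel
cannot inflate it; condensates sit near the poles by default, so the
midpoint samples the dilute phase).  Pixels in the cell at ≥ τ × reference
(τ = 1.20) form 8-connected candidate foci; foci under 4 px are discarded
as noise.  A cell is positive iff a focus survives.  Because the reference
is fixed per cell, the super-threshold sets are nested across τ and sweep
fractions are non-increasing by construction.  Detection depends only on
intensity ratios, so global rescaling of the image leaves all calls
unchanged.

The per-cell enrichment ratio divides the mean intensity of the detected
focus cores by the mean of the cell interior away from foci.  Two
refinements counteract PSF blur, which otherwise biases the naive
focus-mean/interior-mean estimator upward by ~20% at ρ = 1.6: the focus is
measured on its 1-px erosion (edge pixels are blur-diluted; the full focus
is used when erosion would empty it), and the dilute phase is measured on
the cell mask eroded by 3 px and excluding a 2-px guard ring around foci
(cell-boundary pixels are blur-dimmed and focus-adjacent pixels are
blur-brightened).  With PSF off the estimator is exact (ρ recovered to
machine precision); with default blur and noise it recovers ρ = 1.6 to
within ~4% on average.

Strain scoring: fraction = positives/cells; a strain is condensate-forming
iff fraction ≥ 0.11 (the cutoff sits just above the detector's
false-positive floor on condensate-free cells; the boundary counts as
forming since the negative regime is stated as "< 0.11").

## Time courses

Fractions are computed per biological replicate and aggregated as mean ±
sample SD (ddof = 1 — with the typical three replicates the n−1 denominator
matters).  Replicates must share timepoints; mismatches raise an alignment
error naming the offenders.  Persistence uses the replicate means: a strain
is *persistent* if the final (largest) timepoint is at or above the cutoff,
*transient* if an earlier timepoint reached the cutoff but the final did
not, else *none*.  Adding sub-cutoff timepoints never changes the class.
The cutoff rule for "disassembled" is an explicit stand-in for what is
usually a visual judgment.  The expression proxy is blank-subtracted
fluorescence over blank-subtracted OD, with non-positive OD points masked
with a warning rather than propagating infinities.

## Pipeline and reproducibility

One global seed fans out per stage: the scene for (variant, replicate,
timepoint) is seeded by `SeedSequence([global_seed, crc32(tags)])`, so any
stage can be re-run in isolation bit-identically.  Every output CSV carries
the configuration's content hash on a comment line and the JSON manifest
embeds the resolved configuration; identical config + seed reproduces
identical output bytes.  Config validation (e.g. τ ≤ 1, cutoff outside
(0,1)) fails before any computation.

## Problem sizes

The test suite exercises 20 seeded 200-cell scenes at ρ = 1.6 plus six
condensate-free scenes for the recovery/sensitivity/false-positive checks, a
500-cell scene for the fraction statistic (binomial tolerance ±0.05 at
n = 500), and small (16–18 cell, 288–320 px) scenes for end-to-end
time-course classification; these sizes give the assertions comfortable
statistical headroom while keeping the default suite around a minute of
compute.

## Known limitations

* The enrichment estimator still underestimates ρ slightly (~3–4% at
  default blur) because detected focus extents are defined by the fixed
  ratio threshold, not by deconvolution.
* A condensate wandering over the cell midpoint would inflate the reference
  and suppress detection; the median mitigates but does not resolve this,
  and the generator's polar default does not stress it (the uniform
  placement mode does).
* Angularity is a turning-angle approximation of MicrobeJ's (unpublished)
  definition; constraint defaults are stand-ins, not calibrated values.
* The proteome charge-distribution tools are exercised on synthetic records
  in the tests; analyses of a real proteome require the user to supply the
  FASTA.
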