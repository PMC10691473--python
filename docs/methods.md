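# Methods

## Scope and data model

chromodyn analyzes live-cell measurements of chromatin engagement by a
nuclear protein through two readouts: fast single-molecule tracking
(SMT) of sparse photoactivated molecules, and fluorescence recovery
after photobleaching (FRAP) of chromocenters. All stages operate on
plain containers — pandas DataFrames for localizations and
trajectories (columns `cell_id, trajectory, frame, x_um, y_um,
intensity`), numpy stacks for movies, small dataclasses for FRAP
series and summaries — and every stage can be driven by the built-in
synthetic-data generator, which carries ground truth alongside each
dataset (and never feeds it to the inference).

## Acquisition geometry

A single `ImagingConfig` is shared by the simulator and all inference
stages:

| parameter | default | meaning |
| --- | --- | --- |
| `pixel_size` | 0.16 µm | camera pixel in object space |
| `frame_interval` | 7.48 ms | exposure + camera dead time, one fixed Δt |
| `focal_depth` | 0.7 µm | axial detection slab, molecules visible within ±Δz/2 |
| `loc_error` | 0.035 µm | per-axis localization error σ |
| `roi_pixels` | 100 | 16 µm × 16 µm field |
| `psf_sigma` | 1.0 px | Gaussian PSF width for rendering and fitting |

The localization error of the real instrument is not published;
0.035 µm is a typical value for bright organic dyes at these photon
counts and is deliberately a single constant used on both sides of
every parameter-recovery test. Results should be interpreted
accordingly: tests demonstrate internal consistency at this σ, not a
calibration of any particular microscope.

## Synthetic trajectories

Each molecule draws a state once from Bernoulli(f_bound) — bound
(D = 0.02 µm²/s in every preset) or free — and performs 3D Brownian
motion with per-axis step variance 2DΔt. Observation starts at
activation (axial position uniform in the slab), and ends at the first
frame whose axial position leaves ±Δz/2 (defocalization; the exit is
absorbing, matching a tracker with no gap closing) or at photobleaching,
whose lifetime is geometric with mean 8 frames. Observed x/y positions
add i.i.d. Gaussian error σ. Molecules observed fewer than 2 frames are
dropped from the trajectory table but kept in the ground truth, and
every localization (singletons included) counts toward the per-cell
detection total used as the expression proxy. Activation times are
staggered so the mean density is ~1 localization per frame.

Within-trajectory state switching exists behind a flag (per-frame flip
probability, default off) for robustness experiments only; the
inference assigns one coefficient per trajectory and is not expected to
be calibrated under switching.

Condition presets encode the study's published values: bound fractions
0.64 (wild type), 0.39 (G118E), 0.79 (H2B), 0.11 (Halo-NLS); free-state
coefficients 3.0, 2.5, 2.0 and 12.0 µm²/s respectively (2.5 and 12 are
published figures; 3.0 and 2.0 are chosen inside the published ranges).

The photobleaching lifetime (8 frames) and the free-state coefficients
without published values are fixed package constants, chosen once as
plausible for this dye and protein class; no parameter-recovery result
in the test suite was obtained by adjusting them.

## Movie rendering and spot detection

Rendering integrates a 2D Gaussian (σ = `psf_sigma`) over pixels via
error functions, scales to an expected total photon count per spot,
adds a uniform background and per-pixel Poisson noise, and emits
unsigned 16-bit stacks.

Detection computes, at every pixel, the generalized log-likelihood-
ratio statistic for "integrated Gaussian kernel (σ = 1.3 px) plus flat
background" against "flat background alone" within a 15 × 15 window
under i.i.d. Gaussian noise of unknown variance:

    LLR = −(n/2) · log(1 − ρ²),

where ρ is the correlation between the window and the mean-subtracted
kernel. Pixels exceeding threshold 18 survive non-maximum suppression
within the kernel radius; dark (anti-correlated) extrema are rejected.
Under the null the statistic is ~χ²₁/2-tailed, so threshold 18 gives a
per-frame false-positive rate far below 0.1 on a 100 × 100 frame (the
original tracker's "llr" statistic is not published in detail; the
threshold is honored as a default but the null calibration here is this
package's own).

Localization refines each candidate by an iterative damped
least-squares fit (damping 0.3, ridge 10⁻³ on the normal equations,
≤ 10 iterations, stop when the step falls below 10⁻⁴ px) of a
pixel-integrated 2D Gaussian of fixed σ = 1 px plus flat background in
a 9 × 9 window, initialized from the background-subtracted centroid.
Candidates within half a fit window of the image edge are dropped, as
are fits that leave the window or become singular. Coordinates are
0-based; pixel *i* spans [i, i+1) pixel units, so a spot centered on
pixel *i* is at i + 0.5; µm positions are pixel units × pixel size.
Noiseless spots are recovered to < 10⁻³ px; under Poisson noise the RMS
error is within a factor 2 of the standard Gaussian-PSF precision
bound.

A movie-level QC rule excludes movies whose mean detections per frame
exceeds 3 (strictly; exactly 3.0 passes).

## Trajectory linking

Between each pair of consecutive frames, candidate pairs within a 1 µm
search radius are matched by minimum-total-distance bipartite
assignment (maximum cardinality first, then minimal distance; solved
with the Hungarian algorithm, which is deterministic). There is no gap
closing: an unmatched trajectory terminates and a reappearing molecule
starts a new trajectory. Every localization belongs to exactly one
trajectory; singletons are retained for detection counts and excluded
from kinetics. Jump lengths are consecutive-frame Euclidean
displacements; the closed-form mixture CDF
P(r ≤ R) = Σᵢ fᵢ (1 − exp(−R²/(4DᵢΔt + 4σ²))) is provided for
overlays, where the fᵢ are occupations of *observed jumps* (convert
molecule fractions with the expected-jumps weights below when
overlaying on simulated data).

## Diffusion-spectrum inference

The RBME (regular Brownian motion with localization error) likelihood
of a trajectory's jump sequence is, per axis, a zero-mean multivariate
normal with tridiagonal covariance C_ii = 2DΔt + 2σ²,
C_i,i±1 = −σ² (consecutive jumps share one noisy localization).
It is evaluated in O(n) by banded Cholesky factorization and matches a
dense multivariate-normal oracle to 10⁻⁸ relative.

Occupations live on a fixed log-spaced grid of 100 coefficients from
10⁻² to 10² µm²/s; the grid never contains 0.1 µm²/s, so the bound
fraction — the total occupation strictly below 0.1 — is unambiguous.
σ is a fixed known constant shared with the simulator (no
marginalization over localization error).

Estimation per cell:

1. **EM over trajectories.** The mixture weights over grid points are
   estimated by expectation–maximization in which each trajectory is
   one observation. (Weighting the E-step by jump count would count
   each jump twice — once inside the likelihood, once as a weight — and
   measurably smears the converged occupation; the proper ML form is
   used instead.) Iteration starts from uniform weights and stops when
   the maximum change falls below `tol` (10⁻⁶ default, 1000 iterations
   max); `max_iter=0` returns the uniform initialization untouched.
2. **Per-jump occupation.** Converged responsibilities are aggregated
   with jump-count weights, giving the share of observed jumps per grid
   coefficient.
3. **Per-molecule conversion.** Jump shares are divided by the expected
   number of observed jumps per activated molecule at each coefficient
   and renormalized. The expectation is a Monte-Carlo estimate (10⁵
   molecules, fixed internal seed, cached per parameter set) of
   E[min(bleach lifetime, slab exit) − 1] for a Brownian molecule
   started uniformly in the slab; it combines defocalization with the
   geometric photobleaching survival, because slab residence of bound
   molecules (~270 frames at D = 0.02) far exceeds the fluorophore
   lifetime (~8 frames) — a defocalization-only weight would
   over-deweight slow states roughly ninefold and collapse the bound
   fraction. The bleach-lifetime parameter of the correction defaults
   to the simulator's constant; a pure-slab weight is available by
   passing `bleach_mean_frames=None`.

Trajectories longer than 100 jumps are split; total jumps per call are
capped at 10⁶ by seeded uniform subsampling. Cells aggregate by a
jump-count-weighted mean of their occupation vectors; animals (when
present) aggregate as unweighted means of their cells' bound fractions.
A model-free per-trajectory estimator
D̂ = max(0, ⟨jump²⟩/(4Δt) − σ²/Δt) serves as an independent sanity
check on the spectrum's modes.

Numerical behavior worth knowing: when the true coefficient falls
exactly midway between two grid points (as 1.0 µm²/s does on this
grid), the estimate necessarily splits mass between the neighbors, and
the deconvolution can park some additional mass one step further out;
concentration tests are therefore run at on-grid coefficients. Recovery
of two-state mixtures is within ±0.05 of the true bound fraction at
5000 trajectories across f_bound ∈ {0.2, 0.5, 0.8} and
D_free ∈ {1, 3, 10}.

## FRAP pipeline

A FRAP series holds per-frame chromocenter, whole-nucleus and
background intensities with 5 pre-bleach frames (bleach between frames
n_pre−1 and n_pre; t = 0 at the first post-bleach frame; 6.15 s frame
interval, ~10 min records). The corrected curve is

    c(t) = [(chromo − bg)/mean_pre(chromo − bg)]
         ÷ [(nucleus − bg)/mean_pre(nucleus − bg)],

whose pre-bleach mean is 1 by construction and in which any decay
shared multiplicatively by chromocenter and nucleus — acquisition
photobleaching — cancels exactly. Cells whose background-subtracted
nuclear signal is not strictly positive at every frame are excluded and
counted (mirroring the exclusion of cells with excessive movement in
real acquisitions).

Summaries are read from the cell-averaged curve: I_min is the first
post-bleach value (not the global minimum); I_max is the mean of the
3-frame-smoothed post-bleach curve over its final 30 s — identical to
the maximum for a monotone recovery, but unbiased under noise, where a
plain maximum is systematically high by about a point at the simulated
noise level; t½ is the first crossing of I_min + (I_max − I_min)/2 by
the smoothed curve, linearly interpolated between frames. (The
half-recovery definition equates a *level*, not a time; the crossing
time is the reported quantity in seconds.) On noiseless exponentials
t½ = τ ln 2 within one frame interval for τ from 5 to 100 s.

Group comparisons use the Mann–Whitney U test on a per-cell scalar —
by default the mean corrected intensity over the first 60 s after the
bleach, configurable to per-cell I_min or a custom callable — with
exact p-values for group sizes ≤ 20 and the tie-corrected normal
approximation otherwise. The underlying per-cell statistic of the
original comparison is not published; the early-recovery mean is this
package's choice because it captures both bleach depth and early
exchange.

The FRAP generator produces the ground truth
I(t) = plateau − (plateau − depth)·e^(−t/τ) with a whole-nucleus decay
e^(−λt) (default λ: 20% loss over 10 min), per-cell lognormal
brightness (cv 0.4, the expression proxy for stratification),
multiplicative Gaussian measurement noise (cv 0.03) and an additive
background. Presets: wild type plateau 0.92, τ = 26/ln 2 s; mutant
plateau 0.97, τ = 13/ln 2 s (half-times 26 s and 13 s). The published
record bleaches chromocenters to ~40–50% of initial intensity with the
mutant's depth visibly reduced; the presets use depth 0.45 (wild type)
and 0.55 (mutant). A single exponential is a calibration target, not a
biophysical model — real chromocenter recovery mixes rebinding and
exchange and is deliberately not fit with kinetic models here. A toy
movie mode renders a drifting anti-aliased disk inside a nucleus disk
solely to exercise the Z-projection/ROI measurement path; real
volumetric chromocenter data and manual ROI drawing are out of scope.

## Expression-coupling statistics

Per-cell detection counts (every localization, singletons included) are
proportional to labeled protein copies and serve as the expression
proxy. Provided statistics: product-moment correlation with validation
(n ≥ 3, nonzero variance); a seeded random-pairing null (uniform
permutations of one margin, add-one empirical two-sided p); top-k /
bottom-k expression stratification of FRAP cells by absolute pre-bleach
chromocenter intensity (ties broken by input order); per-animal mean
bound fractions with a rank-sum comparison between conditions (default
alternative: first condition greater). No multiple-testing correction
is applied — the analyses are single planned comparisons.

A pipeline-neutrality property holds by design and is enforced by test:
when expression is independent of kinetics, the correlation between
detections and estimated bound fraction stays within ±0.1 at 200 cells.
Two subtleties matter when building such a null: if the bound/free
composition is drawn per molecule, detections and the realized bound
fraction are coupled through the longer slab residence of bound
molecules (not an estimator artifact), so the null fixes the
composition exactly; and because the per-cell estimate and the
detection count share the same realized trajectory-length randomness,
the expression spread must dominate the detections variance — the null
uses the decade-wide lognormal spread real per-cell counts show.

## What the simulations do and do not establish

The generator reproduces the statistical structure the inference
assumes: two states fixed per trajectory, exact RBME jump law, hard
detection slab, geometric bleaching, exponential FRAP recovery with a
shared multiplicative acquisition decay. Passing recovery tests
therefore establishes the pipeline's internal correctness and
calibration under those assumptions — not robustness to what real
neurons add: state switching within trajectories, anomalous or confined
diffusion, spatially varying background and PSF aberration, detector
gain and readout noise, nuclear movement, chromocenter morphology, or a
soft axial detection profile. The published real-data correlation
values (PCC ≈ 0.48 wild type, ≈ 0.3 mutant, ≈ 0 when shuffled) require
the original movies and are qualitative references only.

## Problem sizes and runtimes

Default verification sizes, chosen to make every statistical tolerance
comfortably attainable: 20 cells × 250 trajectories per SMT condition
(a few seconds of inference per condition after a one-time ~15 s
Monte-Carlo for the expected-jumps weights, which is cached); 23 cells
per FRAP condition; 200 cells for the neutrality null; 10⁵ jumps for
distribution-law checks. The acceptance script reruns all four SMT
conditions end to end in well under a minute per condition on one CPU.
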