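# Methods notes

This note documents the models, conventions and numerical choices behind
`mucuslab`, what the synthetic generators do and do not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Particle-tracking motion analysis

**Model.** Each particle's time-averaged MSD is fit to the 2D
anomalous-diffusion law `MSD(τ) = 4 D τ^α` by OLS on `log MSD` vs `log τ`.
`α` is the slope; `D = exp(intercept)/4`. `D` is a *generalized* diffusion
coefficient: its true unit is µm²/s^α, but it is labeled µm²/s throughout,
matching the convention of single-D-per-particle reporting. For Brownian
particles (α = 1) the label is exact.

**MSD.** The time average runs over all start points per lag, lags 1 to
`floor(0.25·N)` frames by default. Two implementations exist: an
O(N log N) FFT route (the default) and the O(N²) direct sum; they agree to
1e-9 relative on contiguous tracks and the equivalence is asserted in the
test suite. Tracks with frame gaps (from gap-closing in the linker) always
use the gap-aware direct sum over the pairs actually present.

**Fit window and reliability.** The fit uses lags 1–10 frames
(configurable); this is standard SPT practice — short lags carry the most
pairs and the least statistical noise. Zero MSD values are excluded from the
log fit; an all-zero window is a genuinely flat track and is reported as
α = 0, D = 0 (immobile). One or two usable lags give an unreliable fit,
which is excluded from group summaries, as are tracks shorter than 20 frames
(a log-log fit on fewer points is dominated by noise).

**Classification.** immobile: α < 0.001; free: α > 0.5; confined: the closed
interval between them. The published bins are open at both boundaries;
assigning the boundary values to the middle bin makes the rule total without
changing any generic value. A caveat inherent to the thresholds: with
localization noise, a truly immobile particle's flat MSD fluctuates, so its
fitted α is distributed around 0 and roughly half of immobile particles land
just above 0.001, i.e. in the confined bin. The immobile fraction is
therefore a lower bound under noise; the free fraction is unaffected.

**Coverage.** All trajectories are shifted to a common origin, positions
pooled, and positions beyond the 98th percentile of radial distance
discarded before binning on a 0.183 µm grid (the camera pixel). The
percentile trim is the only reading of a "98% quantile" coverage that yields
a finite, outlier-robust µm² area from an unbounded point cloud; the
occupancy grid is also returned for heatmap rendering. Area is occupied bins
× bin².

**Linking.** Greedy per-frame nearest-neighbor assignment (shortest links
first, one detection per track, links capped at `max_disp`, gaps at
`max_gap`). Greedy is not a global minimum-cost assignment; it is adequate
for the sparse fields this pipeline targets and is deliberately replaceable
(the linker sits behind a single function).

## Synthetic trajectories

* Free particles: Gaussian increments with variance `2·D·dt` per axis.
* Subdiffusive (confined-class) particles: fractional Brownian motion with
  Hurst `H = α/2`, synthesized by Cholesky factorization of the exact fBm
  position covariance and scaled so the ensemble MSD is `4·D·τ^α`. Exact
  synthesis is affordable at the 300-frame movie scale; a Davies–Harte
  circulant embedding is an acceptable faster substitute for much longer
  tracks.
* Corral model (optional): Brownian steps with specular radial reflection at
  a disk boundary — the simplest model producing a plateaued MSD.
* Immobile particles: a fixed point.

All recorded positions get i.i.d. Gaussian localization noise, default
0.02 µm — sub-pixel and typical for SPT; the acquisition geometry defaults
(300 frames, dt = 1/4.56 s, 0.183 µm pixels) are the emulated assay's, and
the default mixture (48.8/49.6/1.6 %) and D = 0.057 µm²/s are the healthy
term-animal day-5 values. Class counts follow the requested mixture
deterministically (largest-remainder apportionment), so recovery tests
compare against the exact intended mixture.

What the generator does **not** emulate: camera PSF and detection noise
beyond a Gaussian localization error, blinking/missed detections, drift,
heterogeneous per-particle D, z-escape, and real mucus microstructure
(viscoelastic memory beyond fBm, pore hopping). Passing recovery tests shows
the estimator chain is unbiased under the stated motion models — not that
real detection artifacts are handled.

## Pore quantification

"Filter size of 10" is realized as a Gaussian with σ = 2.5 px (size/4) and
kernel radius 5 (an 11-px kernel — discrete Gaussians here are odd-sized);
the σ is a convention since only the size is specified. Pores are the dark
Otsu class; components under 5 px are discarded as noise; border-touching
pores are retained because excluding them biases against large pores on
high-magnification crops. Wall density is the summed Sobel gradient
magnitude; it is reported per µm² (making crop sizes comparable) alongside
the raw sum, since the original normalization convention is not recoverable.
Percent-change reporting uses the mean pore area per image. Segmentation
accuracy degrades gracefully with noise (≈0.3% area error noiseless, still
within 15% at 10% contrast noise in the recovery checks); very small pores
(radius ≲ 8 px) acquire a relative bias from the smoothing halo.

## Permeability

The withdrawal correction `Q_i = V_r·C_i + V_s·Σ_{j<i} C_j` is exact mass
balance for instantaneous sampling with blank replacement and is the exact
inverse of the synthetic generator. The steady-state window is the longest
*suffix* of uncensored points whose OLS reaches R² ≥ 0.98 (minimum 4
points); steady state develops last, so suffixes exclude lag phases. If no
suffix qualifies, the best-R² suffix is used. The 0.98 gate is lenient
enough to admit a point or two of a lag transition, which attenuates the
slope slightly (the round-trip tests quantify this: exact at zero lag,
within ~10% with a 90-min lag). Franz-cell receiver volume is required
configuration — it cannot be inferred and is not defaulted. Censored points
are excluded from fitting but still contribute their measured value to the
cumulative sum; more than 50% censored → ND. Radiolabel activities (µCi/mL)
are handled identically to mass concentrations because P_app is ratio-scaled;
this also makes P_app invariant to rescaling C0 and the series together.

## Rheology

Interpolation is linear in log-log space everywhere (rheometer grids are
log-spaced; power laws interpolate exactly). The stress-independent region is
detected as the longest initial run of G′ within ±5% of its running median
(≥3 points required); the plateau is the mean G′ over that run, and the
yield point is where G′ first crosses 95% of it. The flow point intersects
the log-log interpolants of G′ and G″ between the bracketing grid points.
Both are ND (NaN) when the feature does not occur in the measured range —
a right-censored yield on a strong gel is reported as ND, not as the range
edge. The loss factor is defined as G″/G′ (tan δ). The synthetic gel uses a
weak power-law frequency dependence (G′ ∝ ω^0.05), a flat stress plateau
with a calibrated power-law decay that places the 5% drop and the G′–G″
crossover exactly at the requested yield and flow stresses, and a power-law
flow curve; generator validity requires tan δ < 0.95 so a 5% drop precedes
the crossover.

## Statistics

ROUT is implemented in column mode: robust center = median, robust scale =
RSDR (68.27th percentile of absolute residuals × √(n/(n−1))), per-point
two-sided t-tail p with n−1 df, and a Benjamini–Hochberg step-up at rate Q
flagging from the most extreme point inward. Full robust nonlinear
regression mode is out of scope — the pipeline applies ROUT to replicate
columns, not curves. Fewer than 4 values: nothing is removed.

Variance equality for the t test is screened by a two-sided F-ratio test at
0.05; Welch is used when it rejects. Pairing is available for within-animal
(±treatment) contrasts, the only repeated-unit design here. Mann–Whitney
uses the exact enumeration distribution when both arms have ≤8 untied
values, otherwise the tie-corrected normal approximation. Technical
replicates are always averaged within animal first.

One caveat verified by simulation: the intuition "Tukey pairwise p ≥
unadjusted t p" holds throughout the decision-relevant range but can invert
by hair-widths deep in the tail (p below ~1e-3), because Tukey's pooled MSE
carries more degrees of freedom than the pairwise t.

## Problem sizes

Recovery and calibration checks use 500 particles × 300 frames per movie,
256² px images, 16-point flux series × 100 noise replicates, 57-point stress
sweeps, and 2000-rep null simulations — sizes at which Monte-Carlo error is
comfortably below every asserted tolerance while the whole suite stays fast.
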