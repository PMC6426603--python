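# Methods

This note documents the models, estimators, and numerical choices behind
the package, in the spirit of the methods documentation of simulation
and statistics packages: what is simulated, what is estimated, what the
defaults mean, and where the design was genuinely open.

## 1. Run-and-tumble simulator

Motile cells alternate **runs** and **tumbles** as an alternating
renewal process with exponentially distributed durations.  Given a
target tumble bias `TB` (fraction of time tumbling) and a mean tumble
duration `τ_t`, the mean run duration is `τ_r = τ_t·(1−TB)/TB`, so the
stationary time fraction in the tumble state equals `TB` exactly.

During a run the heading `θ` performs rotational diffusion,
`dθ = √(2·D_r·h)·N(0,1)` per integration substep `h`, and the speed
relaxes exponentially toward the run speed after each tumble,
`v(a) = v_run·(1 − e^(−a/τ_rec))` with `a` the time since the tumble
ended.  Tumbles are stationary; on exit the heading is redrawn
uniformly on `[0, 2π)`.  Reported positions add isotropic Gaussian
localization noise.  Non-motile cells are pure Brownian walkers.
Integration uses 5 substeps per sampling interval; the per-frame
ground-truth state is the state at the sampling instant, whose
expectation is `TB` by stationarity.

Defaults (per condition, from the published condition-level values):

| parameter | liquid | swarm | hard | notes |
|---|---|---|---|---|
| run speed (μm/s) | 21 | 25 | 21 | population modes |
| tumble bias | 0.12 | 0.04 | 0.12 | population medians |
| mean tumble duration (s) | 0.2 | 0.2 | 0.2 | literature-typical; the source data constrain only the bias |
| rotational diffusion (rad²/s) | 0.06 | 0.06 | 0.06 | during runs |
| speed-recovery τ (s) | 0.17 | 0.17 | 0.17 | ≈95% recovery by 0.5 s, matching the observed ~0.5 s recovery |
| Brownian D (μm²/s) | 0.4 | 0.4 | 0.4 | Stokes–Einstein scale for ~1 μm cell |
| localization σ (μm) | 0.1 | 0.1 | 0.1 | sub-pixel at 0.65 μm/px |

Hard agar reuses the liquid behavioral parameters: hard (1.5%) agar
does not support swarming and abolishes the swarm response.

The tumble-duration and turn-angle distributions are literature-typical
placeholders (the source measurements constrain only the bias); both
are configurable on the preset.  The simulator does **not** model
cell–cell hydrodynamics, collective swarm flow, agar-surface physics,
cell growth/division, or chemotactic gradients — it emulates isolated
cells transferred to isotropic liquid, which is the measurement
condition of the assays it feeds.  Consequently, passing recovery tests
shows the estimators are unbiased for this generative model, not that
they would be unbiased on crowded or gradient-driven data.

## 2. Trajectory analysis

**Diffusion coefficient.** MSD is computed at all pair lags in a 2–10 s
window and fitted through the origin (`MSD = 4Dτ`).  Cells with
`D < 10 μm²/s` are classified non-motile and excluded from speed and
tumble-bias statistics; the boundary is inclusive for motile.

**Tumble segmentation.** A frame is a tumble candidate when its
frame-to-frame speed falls below `α = 0.18` times a per-trajectory
run-speed reference, the 80th percentile of frame speeds.  Episodes
separated by runs shorter than 0.2 s are merged (hysteresis).  A
turn-rate criterion (`ω_min`, rad/s) is implemented but off by default:
with near-stationary tumbles the displacement heading during a tumble
is localization-noise-dominated and effectively random, so a turn-rate
test fires on the episode boundaries and double-counts them.

These constants were calibrated against simulator ground truth — the
detector's job here is to invert the generator, and the generator's
speed-recovery makes naive thresholds (e.g. half the local median
speed) misclassify the first ~0.3 s of every run as tumbling, inflating
a true bias of 0.12 to ~0.18.  The low threshold balances two opposing
frame-counting errors (partial-overlap intervals at episode boundaries
vs. noise-speed frames inside tumbles) and recovers the population
median tumble bias within ±0.007 across true biases 0.02–0.2 at 10 fps.
The percentile reference, unlike a rolling median, does not sag as the
tumble fraction grows.

**Swimming speed.** Mean frame-to-frame displacement rate over RUN
frames, excluding (i) 0.5 s after each tumble episode (speed recovery),
(ii) the frame immediately before an episode (its displacement
straddles the tumble onset), and (iii) frames slower than 0.8× the
run-speed reference (unresolved micro-tumbles: at 10 fps a tumble
shorter than one frame does not push the frame speed below the
detection threshold, but still resets the speed).  With all three
exclusions the population-median speed is recovered within ±0.3 μm/s;
with none of them the bias is −1 to −2.5 μm/s depending on the tumble
bias.

**Population summaries.** Every per-cell statistic is weighted by
trajectory duration.  The weighted median is the 50% point of the
weight CDF with linear interpolation; with unit weights it reduces to
the ordinary median.

## 3. Tracking

Background is the pixelwise temporal mean, subtracted and clipped at
zero.  Detection applies a PSF-sized Gaussian matched filter (σ =
1.3 px), proposes local maxima ≥ 2 robust SDs above the frame median
within a 5-px box (noise scale from the 84.1th-percentile–median
distance, which tolerates the clipped lower tail), assigns each
candidate a p-value from the smooth-field peak-height null
`S(z) ∝ z⁴·e^(−z²/2)` conditioned on the proposal cut, and keeps
candidates by Benjamini–Hochberg at FDR 5% per frame.  The polynomial
factor in the null matters: on a smoothed (correlated) noise field,
peak heights are materially heavier-tailed than a Gaussian order
statistic, and Gaussian-tail p-values let through several false peaks
per frame.  Accepted peaks are refined to subpixel centers by the
radial-symmetry-center construction (least-squares intersection of
gradient lines on the half-pixel dual grid), which is exact for
radially symmetric spots (< 0.01 px on noiseless Gaussians).

Linking is frame-to-frame minimum-cost bipartite assignment (Hungarian
algorithm) with cost = squared distance to the nearer of a
constant-velocity prediction and the current position, a gating radius
of 1.6 × the maximum expected per-frame displacement (expected speeds
20–30 μm/s), birth/death costs at the gate, and one-frame gap closing.
Trajectories shorter than 5 s are discarded.  Multi-hypothesis
linking is out of scope.

## 4. Tethered-bead motor analysis

The orbit center is an algebraic (Kåsa) circle fit — exact on circles,
stable under jitter; the bead angle about it is unwrapped and
differentiated with a Savitzky–Golay quadratic over 8 ms (11 samples at
1,250 fps).  Sign convention: CW positive, CCW negative; right-handed
image coordinates make CCW the direction of increasing angle, so the
signed frequency is the negated angle derivative over 2π.  Reversals
are sign changes persisting ≥ 10 ms (shorter excursions are merged);
the CW bias is the positive-sign time fraction.  The smoothing window
plus debounce impose a ~16–18 ms dead time, which removes the shortest
CW intervals and undercounts the reversal rate by ~5% at 38 rv/min; the
estimate stays well inside the measurement spread and the effect is
documented rather than compensated.

The motor telegraph simulator uses switching rates
`k_CCW→CW = R/(2(1−b))`, `k_CW→CCW = R/(2b)` so the expected sign
changes per minute equal `R` and the stationary CW fraction equals `b`
(defaults b = 0.12 liquid, 0.03 swarm).

**Torque.** `τ = 2π·f·ξ` with `ξ = 8πηa³ + 6πηa·r_e²` (rotational plus
eccentric-translation drag), η = 9.6e-4 Pa·s, a = 0.375 μm (0.75-μm
bead), r_e = 0.2 μm, reported in pN·nm.  The eccentricity is not
constrained by the source measurements, so absolute torques are
calibration-sensitive; only the swarm/liquid ratio — which reduces to
the frequency ratio for any fixed drag model — is treated as a robust
output.  Every torque result logs its drag model.

## 5. Blot quantification

Band intensities are normalized lane-wise to the DnaK loading control
before any log transform, then scaled so a designated reference
condition has mean level 1.  Fold changes are ratios of mean normalized
levels with a two-sided two-sample t-test on per-replicate values.
Degradation rates come from OLS on log normalized intensity vs time
(the maximum-likelihood estimator under the lognormal noise model);
per-replicate rates are aggregated as mean ± SD and compared across
conditions by t-test.  The decay model is single-exponential with no
plateau.  The default chase design is 7 time points, 0–360 min every
60 min, 6 replicates, lognormal σ = 0.1.

A power caveat worth stating: with that design the per-replicate slope
SE is `σ/√Σ(t−t̄)² ≈ 3.2e-4 min⁻¹`, so the 6-replicate mean has SE
≈ 1.3e-4 min⁻¹.  The liquid rate (2.7e-3) is recovered to ~5%, but the
swarm rate (1.5e-4, half-life ~77 h) is the same size as its own
standard error — a chase of this length and noise level can establish
that the swarm protein is far more stable, but not pin the rate to
better than ~±90%.

## 6. Fluorescence quantification

Segmentation is Otsu threshold + connected components on a cell-body
reference image; components larger than twice the median component
area (a plausible touching pair) are split by watershed on the distance
transform.  Splitting is deliberately conservative because rod-shaped
single cells have ridge-like distance transforms that eager peak
seeding fragments.  Cells whose area deviates > 3 SD from the
population mean are discarded (< 5% on Gaussian-area scenes).  Per-cell
totals subtract a background (default: median of non-cell pixels) per
pixel and a per-cell autofluorescence constant; negative corrected
totals clip to zero with a warning.  Uneven illumination is not modeled
(synthetic scenes are flat); a flat-field hook exists for real data.
The CheZ-mCherry/CheY-mYFP comparison reports both the per-cell ratio
distribution and the ratio of per-condition medians, since either
reading of "ratio change" is defensible.

## 7. Weighted permutation ANOVA

With weights normalized to `Σw = n`, the statistic is

    F = [Σ_g W_g(ȳ_g − ȳ)²/(K−1)] / [Σ_i w_i(y_i − ȳ_g(i))²/(n−K)]

with weighted group and grand means.  Unit weights recover the
classical one-way F exactly (tested against direct sums and
`scipy.stats.f_oneway`); the exact weighted-F form was an open choice
and is validated by that equivalence plus the null-calibration test
below.  The null distribution permutes group labels at the trajectory
level (value and weight move together, 10,000 permutations by default);
the p-value uses the add-one estimator `p = (1+#{F* ≥ F})/(1+n_perm)`,
which cannot be zero and is exact under exchangeability.  Agreement
with the analytic `F(K−1, n−K)` is quantified by a KS statistic
(< 0.011 at n = 1,000, K = 3, 10,000 permutations with unit-weight
Gaussian groups).  The permutation route exists because duration
weighting and non-normal per-cell statistics void the analytic
assumptions; with heavy-tailed values the permutation p-values remain
valid while the analytic ones need not.

## 8. Futile-cycle model

CheA phosphorylates CheY; CheZ dephosphorylates CheY~P.  The
steady-state phosphorylated fraction solves
`V_A(1−Y_p)/(K_A+1−Y_p) = V_Z·Y_p/(K_Z+Y_p)` and is evaluated by the
Goldbeter–Koshland closed form (agrees with a bisection root to
< 1e-14; guaranteed < 1e-9 by test).  Tumble bias follows a Hill
response `TB = (Y_p·Y_T)ⁿ/(K_halfⁿ + (Y_p·Y_T)ⁿ)` with Y_T = 9.7 μM,
K_half = 3.1 μM, n = 10 (standard E. coli chemotaxis values; all
configurable).  Calibration solves both the Hill inverse and the
balance equation in closed form so that fold = 1 reproduces a chosen
baseline bias.  In the zero-order regime (K = 0.01) a 1.3× rise in
CheZ collapses TB from 0.12 to far below 0.06; in the first-order
regime (K = 10) the same fold moves TB orders of magnitude less — the
quantitative version of why a modest CheZ increase suffices.  This
module is an illustrative companion model with explicit parameters,
not a fitted result; adaptation kinetics (CheB/CheR) are held at steady
state.

## 9. Problem sizes and reproducibility

Recovery experiments use 500 cells × 100 s at 10 fps per condition for
motility, 200 bead traces × 60 s at 1,250 fps per condition for motors,
and 6 replicates for blot/decay analyses; unit and property tests use
smaller instances of the same machinery.  All generators take explicit
seeds (numpy `default_rng`, per-cell child generators spawned from a
master), every pipeline report embeds its resolved configuration, and
re-running a report's configuration reproduces it byte for byte.
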