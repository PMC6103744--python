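# Methods

This note documents the models implemented in `flynav`, the parameter values
and units, the numerical choices, and the scope and limits of the synthetic
data generators.

## Units and conventions

- Lengths in mm, time in seconds, angles in degrees.
- Odor concentration is dimensionless, normalized so that 1.0 corresponds to
  the strongest stimulus used behaviorally (10% apple cider vinegar).
  Dose-response fits (`HillRegressor`) work in % ACV, where 10% ACV ≡ 1.0
  normalized.
- The arena/world frame has y increasing **upwind**; the wind blows toward
  −y and the upwind direction is 90°. Headings are standard mathematical
  angles (counterclockwise from +x).

## ON and OFF response models

The odor waveform `s(t)` is transformed in two stages.

**Adaptive compression.** A slow leaky integrator tracks the odor history
and desensitizes a first-order Hill nonlinearity:

```
tau_A dA/dt = s − A
C = s / (s + kd + A)
```

with baseline half-max `kd = 0.01` (normalized). At steady state on a
constant input `c`, `A → c` and `C → c/(2c + kd)`, i.e. the compressed
response adapts to about half its unadapted value while retaining dynamic
range — the signature tested throughout the suite.

**Filtering.** The ON channel low-passes `C` with time constant `tau_ON`.
The OFF channel takes the rectified difference of a slow and a fast low-pass:
`OFF = max(0, R_slow − R_fast)`, which is zero for constant or rising inputs
and transiently positive after odor decreases.

Four structural variants are supported: **ACF** (adapt/compress, then
filter — the reference model), **FAC** (filter the raw odor, then compress;
the adaptation state is still driven by the raw odor), and the
adaptation-free **CF** and **FC**. Published best-fit parameters for all
eight variant/channel combinations are stored in `TABLE_ON`/`TABLE_OFF`;
the ACF rows are `tau_ON = 0.72 s, tau_A = 9.8 s` (ON) and
`tau_fast = 0.62 s, tau_slow = 4.84 s, tau_A = 10.08 s` (OFF). Without
adaptation, compression saturates: on frequency sweeps the CF output rides
near its maximum while ACF keeps tracking the modulation — the ordering the
acceptance suite checks.

**Numerics.** All ODEs are integrated by forward Euler at the behavioral
sampling step (20 ms by default): `y[n] = y[n−1] + (dt/tau)(x[n−1] − y[n−1])`
from zero initial state (trials begin after a long odor-free period). The
recursion is evaluated vectorized via `scipy.signal.lfilter`, which is
bit-identical to the explicit loop (tested). Euler at 20 ms matches the
analytic first-order gain `1/sqrt(1 + (2 pi f tau)^2)` within 2% over the
deliverable 0.05–1.5 Hz band, and halving `dt` converges (tested); we use
the plain Euler form because the fitted time constants are defined by it.

## Model fitting

`ResponseModelRegressor` jointly fits one variant/channel to several
(stimulus, mean-response) pairs by pooled sum-of-squares with
`scipy.optimize.least_squares` (trf). Free parameters are the time constants
and an output gain; the behavioral baseline of each target is fixed to its
pre-odor mean (first 5 s) unless `fit_baseline=True`. Parameters are
log-transformed for positivity, and the slow OFF constant is parameterized
as `tau_fast + exp(u)` so the fast/slow ordering holds throughout
optimization. Ten multi-starts (log-uniform within ×4) guard against local
minima. Noise-free self-fits recover the generating parameters to ≲ 1e-6
relative — this is the package's parameter-recovery acceptance path.

`HillRegressor` fits `R(c) = baseline + Rmax c^n / (c^n + kd^n)` the same
way and refuses under-determined problems (< 4 points, flat responses,
non-positive concentrations).

`jackknife_cycle_modulation` segments a sweep stimulus into cycles at the
smoothed waveform's local minima (or maxima) and reports the min-to-max
modulation of the across-fly mean per cycle, with leave-n-out jackknife
standard errors `sqrt((n−1)/n Σ (a_i − a_full)^2)`.

## Trajectory pipeline

Raw tracking is (t, x, y, orientation) at 50 Hz in a 140 × 40 mm arena.
Processing steps, in order:

1. **Rejection**: non-uniform sampling or missing samples (tracking gaps),
   and trials with total path length < 25 mm.
2. **Orientation-flip repair**: per-sample orientation jumps > 90° are
   treated as tracker front/back flips (a fly cannot rotate that fast in
   20 ms) and toggle a 180° offset; the remaining global ambiguity is
   resolved against the direction of travel over moving samples.
3. **Filtering**: zero-phase 2-pole Butterworth at 2.5 Hz on coordinates and
   unwrapped orientation.
4. **Gait parameters** by central differences: ground speed, upwind velocity
   (dy/dt), |angular velocity|, curvature = |angular velocity|/speed (deg/mm,
   defined only while moving ≥ 1 mm/s), and a turn indicator
   (curvature > 20 deg/mm).
5. **Odor-time warping**: each sample is shifted back by the advection delay
   `(y_inlet − y)/wind_speed` (wind 119 mm/s) so responses align to odor
   encounter at the fly, with constant shifts before onset/after offset and
   a monotone mapping (samples may repeat or be skipped, never reordered).
6. **Exclusions**: samples within 3 mm of a side wall, and everything after
   the fly first reaches the upwind end.
7. **Period statistics**: per-fly means in windows relative to odor onset —
   before (−30, 0), during (2, 3), after (11, 13) s — compared pairwise by
   two-sided Wilcoxon signed-rank (exact null up to 25 non-zero pairs,
   normal approximation with continuity correction beyond) at
   Bonferroni-corrected alpha = 0.05/3.

## Navigation model

Per time step `dt` (20 ms in the arena, one movie frame in plumes), with
`r = dt / 20 ms` the per-sample rate conversion:

```
v  = max(0, v0 + k1·ON − k2·OFF)                     ground speed
P  = clip((p0 − k3·ON + k4·OFF)·r, 0, 1)             turn probability
dH = rho·sign(g)·g²·dt                               stochastic turns
   + (k5·ON − k6)·sin(psi)·r                         wind steering
   + k7·(C_L − C_R)·dt                               bilateral comparison
```

with `rho ~ Bernoulli(P)`, `g ~ Normal(0, sigma)`, and `psi` the signed
angle from heading to upwind. Defaults (the published fitted values):
`v0 = 6 mm/s, p0 = 0.12, sigma = 20 deg/s, k1 = 0.45, k2 = 0.8, k3 = 0.03,
k4 = 0.75, k5 = 5 deg/sample, k6 = 0.5 deg/sample, k7 ∈ {0, 40, 300} deg/s`.
The squared Gaussian draw gives the heavy-tailed angular-velocity
distribution of real flies (typical turns of several hundred deg/s; we
square the draw directly — normalizing by sigma would shrink turns ~60-fold
and freeze the agents on their initial heading). A heading increment
`+k5·ON·sin(psi)` reduces `psi`, so the odor-gated term stabilizes upwind
orientation while the weak constant `k6` term stabilizes downwind — odorless
ensembles therefore drift downwind (tested). The bilateral term compresses
the concentrations at the body center and at a right antenna 0.74 mm lateral
to the heading, using the ON-channel adaptation state; `swap_antennae`
reverses the comparison.

Positions integrate `dt·v·(cos H, sin H)` and clamp to the environment
bounds. The sensory states (A, ON, R1, R2 for both channels) advance by the
same Euler updates as the response models. Ensembles are vectorized across
agents with a single seeded generator, so a 500-trial, 70-s arena ensemble
runs in seconds.

## Synthetic environments

**Arena** (`ArenaEnvironment`): the commanded waveform advects downwind at
119 mm/s from the inlet at y = 140 mm, uniform across x.

**Kinematic puff plume** (`make_synthetic_plume`): a desk-scale emulation of
a measured turbulent boundary-layer plume. Gaussian puffs are released at
the source by a Poisson process (8 puffs/s), advect downwind at 100 mm/s,
widen linearly (sigma = 6 mm + 0.08·distance), and ride a meandering
centerline (a stationary Ornstein–Uhlenbeck process, SD 8 mm, correlation
time 2 s, frozen at release). Puff amplitude combines an e-folding
absorption term `exp(−d/150 mm)` with the 2-D geometric dilution factor
`(sigma0/sigma(d))²` so each puff conserves integrated mass as it spreads;
without the dilution factor the *time-mean* centerline concentration would
grow downwind as widening puffs overlap. Frames are normalized so the
source-pixel time-mean is exactly 1. Defaults produce a 300 mm × ±80 mm
domain at 0.74 mm/pixel and 15 Hz for 240 s (the study geometry); tests use
shorter durations. The movie reproduces the qualitative structure of such
plumes — centerline maximum, monotone downwind decay of the time-mean,
lateral widening, edge intermittency — but contains no fluid dynamics:
no velocity fluctuations, no vertical structure, no filamentation, and an
exactly Gaussian instantaneous cross-section. It is an exercise field for
the navigation model, not a turbulence model, which is why the headline
success percentages of the original study (which depend on the measured
plume movie) are out of scope; the package reproduces the pipeline and its
ordering properties instead.

Movies round-trip through HDF5 (`conc` dataset, (T, Y, X) float32, chunked
per frame, with `px_mm`, `fps`, `source_xy` attributes). Lookup is
nearest-pixel, nearest-frame, zero outside the domain, looping in time.

**Synthetic behavior** (`make_synthetic_behavior`): simulates flies in the
arena and emits raw-format tracking tables, optionally with log-normal
per-fly response scales, Gaussian tracking noise, and injected 180°
orientation-flip segments — with the ground truth returned alongside, so the
pipeline's repair and statistics can be validated end to end.

## Evaluation statistics

Success means coming within 20 mm of the source at any time (boundary
inclusive); proportions carry the binomial SE `sqrt(p(1−p)/n)` and pairs are
compared with a pooled two-proportion z test (two-sided normal p). Spatial
ON/OFF maps average model state per bin; occupancy maps normalize to total
time with a one-sample floor under `log10`. `sweep_scales` runs seeded
ensembles over 2-D grids of ON/OFF scales, wind-term multipliers, or
bilateral gain, with per-cell seeds derived from a `SeedSequence`.

## Problem sizes

Everything is sized for a single CPU: self-fits take ~0.2 s, the full test
suite ~20 s (including a 40-s plume movie and several 100–500-trial
ensembles), and `scripts/acceptance.py` ~2 s. Default generator durations
(240-s plume, 180-s trials, 500-trial ensembles) remain desk-scale (minutes).
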