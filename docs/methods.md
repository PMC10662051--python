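# Methods

This note documents the model assumptions, the parameter choices that
matter, what the synthetic-data generator does and does not emulate, the
numerical choices, and known limitations.

## Transport model

One cargo (vesicle) moves along a one-dimensional coordinate parallel to a
microtubule, carried by a fixed team of motors. The microtubule is a
lattice of sites spaced d = 8 nm on 7 parallel lanes (the protofilaments
accessible from one side); lanes are indexed −3…+3 and chosen on
attachment from a discretized standard normal (probability ∝ exp(−ℓ²/2)),
so the central protofilament is preferred. At most one attached motor may
occupy a (lane, site) pair; attachments and steps into occupied sites are
suppressed (an attachment drawn onto an occupied site is an aborted,
state-preserving event).

**Team composition.** The motor number is drawn once per cargo from
N(μ, 1.0683·√μ) (rounded, clipped at 0), where μ is the mean number of
motors in the attachment area, and split binomially between DDB and
KIF16B according to the mean numbers. The σ(μ) coefficient models the
cargo-to-cargo fluctuation of motor numbers at fixed incubation
conditions and is treated as a fixed input constant. The attachment area /
reservoir picture enters as instantaneous exchange: each attachment event
re-draws the motor's activity class (active / inactive / diffusive) and
its individual maximal velocity, while the species ratio of the cargo
stays fixed.

**Forces.** Motors are Hookean springs with rest length L acting only
beyond a slack dead zone: F = κ(Δx − L) for Δx > L, κ(Δx + L) for
Δx < −L, else 0, where Δx is head position minus cargo position. Forces
are signed in the global coordinate (plus-end positive); a load is
*resisting* for a species when it points along that species' direction of
motion (then it pulls the head backwards). The cargo force channel reports
Σ|Fᵢ| over attached motors.

**Stepping.** Active motors step by d toward their polarity with the
composite Michaelis–Menten rate s([ATP], F) = k_cat(F)[ATP]/([ATP] +
k_cat(F)/k_b(F)), where k_cat and k_b are Boltzmann-distributed,
k_m(F) = k_m⁰/(p_m + q_m e^{Fδ/k_BT}), sharing one load distance δ
(the two m-channels could in principle carry different δ; a shared δ is
the minimal choice and is what the calibration constrains). k_cat⁰ = v_f/d
uses the motor's individual maximal velocity v_f, drawn at each attachment
from a log-normal matched to the species' measured single-molecule median
and IQR (0.80 ± 0.63 µm/s for KIF16B, 1.46 ± 1.63 µm/s for DDB; an IQR of
0 pins v_f to the median). δ is calibrated per attachment by bisection so
that s([ATP], F_s) = 0.1 s⁻¹ exactly at the stall force — recalibration per
motor keeps the stall constraint exact even though v_f varies between
motors. Assisting loads step at the zero-load rate; resisting loads beyond
F_s backstep at the small constant rate v_b/d.

**Detachment and diffusion.** Detachment is Bell-type,
k_d(F) = k_d⁰ e^{|F|/F_d}, increasing with load (a config switch
`detachment_load_sign=-1` selects the decreasing, catch-bond-like variant
for comparison). Inactive motors never step and use a lower force-free
detachment rate. Diffusive motors (a DDB-only class) hop ±d with rates
s₀e^{±|F|d/2k_BT}, faster toward their spring's rest position; this pair
satisfies detailed balance, so a lone diffusive motor samples the
Boltzmann distribution in its spring potential (verified by enumeration in
the tests).

**Scheduling and cargo motion.** The Gillespie algorithm draws the next
event from all attachment / detachment / step channels. After every
state-changing event the cargo relaxes by Metropolis diffusion in the
summed spring potential (overdamped limit): 100 proposals uniform in ±8 nm,
acceptance min(1, e^{−ΔE/k_BT}). The proposal step equals the lattice
step size: with 1 nm proposals the cargo could not track a motor stepping
8 nm per event (a residual lag of ~2 pN would act as a phantom load and
bias velocities by tens of percent), whereas 8 nm proposals keep the
steady-state lag below ~0.05 pN while remaining a valid
detailed-balance sampler at any amplitude. Convergence is verified in the
tests against the analytic minimizer of single- and two-spring systems.
With no motor attached the cargo position is frozen (the model tracks the
cargo only through its motor springs). A simulation starts with all motors
detached, measures from t = 4 s (relaxation window) at 10 frames/s, and
ends at 80 s or when no motor is attached after the window.

### Default parameters

| parameter | KIF16B | DDB | unit | basis |
|---|---|---|---|---|
| κ (stiffness) | 0.3 | 0.2 | pN/nm | literature range for kinesin-3 / dynein complexes |
| L (rest length) | 80 | 50 | nm | long KIF16B stalk+PX; compact DDB |
| F_s (stall) | 6.0 | 4.0 | pN | kinesin ~6 pN; activated dynein ~4 pN |
| F_d (detach scale) | 3.0 | 2.0 | pN | Bell-law scales, literature range |
| k_a (attach) | 0.5 | 0.5 | 1/s | see below |
| k_d⁰ (active) | 0.880 | 0.308 | 1/s | v·ln2/L_med from single-molecule medians |
| k_d⁰ (inactive) | 0.25 | 0.25 | 1/s | rigor-like, strongly bound |
| v_b (backstep) | 4 | 4 | nm/s | slow super-stall creep |
| d (step) | 8 | 8 | nm | tubulin dimer spacing |
| inactive / diffusive fraction | 0.2 / 0 | 0.1 / 0.1 | – | measured single-molecule fractions |
| s₀ (diffusive) | – | 156 | 1/s | D = s₀d² ≈ 0.01 µm²/s |
| k_b⁰ | 1350 | 1350 | 1/(s·mM) | K_M ≈ 75 µM at v = 800 nm/s |
| p_cat/q_cat, p_b/q_b | 0.5/0.5, 0.05/0.95 | same | – | composite-model load sharing |
| [ATP] | 2.5 | | mM | imaging buffer |
| k_BT | 4.11 | | pN·nm | room temperature |

The force-free detachment rates follow from the measured medians
(exponential run lengths: median = v·ln2/k_d⁰). The attachment rate is the
one genuinely free kinetic constant; k_a = 0.5 s⁻¹ (inside the 0.1–5 s⁻¹
range reported for motor reattachment from a cargo) was fixed during model
parameterization so that the baseline condition (mean 8 DDB + 14 KIF16B)
sits in the experimentally observed regime — unidirectional runs in both
directions, occasional reversals, and some stationary tracks — and was not
revisited afterwards. The qualitative effects the package is used to
demonstrate (single-species purity; crowding by high attachment rate
turning tracks stationary) are robust over a wide k_a range.

With this parameter set, one prediction of the original tug-of-war
picture does *not* reproduce: a single active DDB against a single active
KIF16B at high reattachment rates still shows ~10% reversal tracks
(saltatory runs carried through Bell-detachment cycles of the dragged
opponent), rather than exclusively stationary/unidirectional behavior.
This is a parameter-regime statement, not a structural property of the
model, and is noted as a limitation.

## Track segmentation

A track (tᵢ, xᵢ) is approximated by a continuous piecewise-linear f(t)
whose knots ("change points") minimize H = Σᵢ(xᵢ − f(tᵢ))² + μN_cp with
all distances in nm and μ = 10 000 nm². The endpoint knots are pinned to
the track ends; N_cp counts interior knots. Optimization is simulated
annealing: N_cp,init = max(1, ⌊ΔT/5 s⌋) knots are placed equidistant in
time on the track, 4000 updates run at β = 0.005, then β is multiplied by
10 every 1000 updates up to β = 50. One update proposes, with
probabilities 0.8/0.1/0.1: a shift of a random interior knot by uniform
(±ε_x/2, ±ε_t/2) with ε_x = 200 nm and ε_t = 2 sampling intervals (knots
are free points in (t, x)); an insertion of a knot at a random data point;
or a deletion of a random interior knot. Proposals that break time
ordering (and deletions with no interior knot) are rejected but count as
updates. ΔH is computed incrementally from the two affected
inter-knot windows; the bookkeeping is validated against full
recomputation in the tests. Because H carries units of nm² and grows with
track length, μ and β would need rescaling for sampling intervals far from
0.1 s; this is documented, not automated.

**Post-processing** applies three rules in order: a segment whose
end-to-end |slope| < 100 nm/s is a pause (the absolute value is the only
reading under which negative runs exist); one-data-point segments — under
the shared-boundary tiling used here, zero-extent segments whose two
knots fall inside one sampling interval — are merged into the following
segment; a run whose net |distance| < 500 nm becomes a pause. Adjacent
same-kind segments are *not* merged by default (pause counts would change
under merging); `AnnealConfig(merge_same_kind=True)` enables it. Segment
boundaries are the data samples at the knot times; adjacent segments share
their boundary sample, so for uniformly sampled data the end-to-end slope
of a segment equals the arithmetic mean of its instantaneous velocities
exactly.

## Classification and statistics

Tracks are classified from their run signs: minus (only negative runs),
plus (only positive), reversal (at least one of each), stationary (no
runs). Pauses are labeled by the nearest runs on either side: reversal
pause (opposite signs), non-reversal pause (same sign), edge (a flank
missing). Adjacent opposite-sign runs with no pause between count as
instantaneous reversals; every run-sign change maps to exactly one
reversal event (instantaneous or one pause block).

The spatial pause frequency weights each track's pauses-per-µm by its
share of the total distance: x̄_f = Σwᵢx_fᵢ with wᵢ = dᵢ/Σdⱼ,
σ_f = √(Σwᵢ(x_fᵢ − x̄_f)²/((N−1)/N)), SEM = σ_f/√(N−1). At N = 1 the
SD/SEM are undefined and returned as 0 with a warning. The weighted
two-sample KS statistic is the supremum difference of weighted ECDFs over
the pooled values; its p-value feeds the Kish effective sizes
(Σw)²/Σw² into the standard asymptotic two-sample null, so uniform
weights reduce the test exactly to the classical asymptotic KS test
(verified against scipy). Long simulated tracks are chopped sequentially
into pieces with durations drawn (with replacement) from a target
duration sample, discarding trailing remainders; each piece carries weight
1/(total pieces).

## Synthetic ground truth

The generator emulates exactly the statistical structure the segmentation
assumes: piecewise-constant-velocity signals with iid Gaussian
localization noise (default SD 20 nm, consistent with sub-pixel tracking
of 87 nm pixels) on a uniform 0.1 s grid, with ground-truth labels derived
from the noiseless signal by the same 100 nm/s / 500 nm rules. It does
**not** emulate velocity fluctuations within runs, gradual speed changes,
diffusive pause motion, correlated (drift-like) noise, blinking or
missed detections — so segmentation tests on it demonstrate correctness of
the optimizer and labeling rules, not robustness to every artifact of real
microscopy data. Track durations for resampling come from a log-normal
matched to a requested median and IQR (exact quantile relations), floored
at two sampling intervals.

## Numerical choices

- Stall calibration by bisection on δ ∈ [0, 10⁶] nm, 200 iterations;
  the stepping rate is strictly decreasing in δ so the root is unique;
  relative residual < 10⁻⁹ (asserted in tests).
- Cargo Metropolis relaxation: 100 proposals × ±8 nm after every
  state-changing event (see rationale above); skipped for events that do
  not change state (aborted attachments), whose rates are also reused.
- The annealer caps interior knots at 512 (never reached on 80 s tracks at
  the default μ); insertion collisions with an existing knot time are
  rejected as updates.
- Seeds: one RNG stream per cargo/track derived from the global seed
  (SeedSequence for simulations; SHA-256 of (seed, track_id) for the
  pipeline), all below 2³¹; identical config + seed reproduces tracks
  bit-identically.
- Problem sizes used by the validation suites — 5000 single-motor runs,
  1000 single-motor trajectories, 200 synthetic recovery tracks, 200
  cargoes per simulated condition — were chosen to make Monte Carlo error
  small against the tested effect sizes.

## Known limitations

- The cargo is a point: no 3D geometry, no membrane hydrodynamics, no
  explicit motor diffusion on the vesicle surface (the reservoir exchange
  stands in for it), no microtubule ends or junctions.
- Supplementary mechanical constants are literature-plausible defaults,
  not fits to the vesicle data; quantitative class proportions therefore
  depend on them (only direction-of-effect statements are asserted).
- The 1-vs-1 high-attachment condition retains a small reversal fraction
  at the default parameters (see above).
- β/μ are tuned for nm-scale residuals at 0.1 s sampling; other sampling
  rates need rescaled annealing constants.
- Pause velocity can be read either as segment slope (default) or as the
  mean instantaneous velocity; both are exposed on `Segment`/`run_mean_velocity`.
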