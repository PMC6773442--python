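# Methods

This note documents the models implemented in `helipause`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical conventions a user should know before trusting a fit.

## Duplex energetics

Per-base-pair opening free energies G_1bp(j) (kBT, positive = cost to melt)
come from the unified oligonucleotide nearest-neighbor set (dinucleotide
ΔH/ΔS at 1 M monovalent salt).  Each interior base pair is assigned the mean
of its two flanking stack free energies; terminal pairs use their single
stack.  Salt enters as a per-stack entropy correction
ΔS → ΔS + 0.368·ln[Mon⁺] cal mol⁻¹ K⁻¹, with Mg²⁺ folded into an
equivalent monovalent concentration [Mon⁺] = [Na⁺] + 3.3·√[Mg²⁺] (molar).
The assay temperature is fixed at 25 °C (kBT = 4.11 pN·nm); the buffer
default is 50 mM Na⁺ / 5 mM Mg²⁺.  Under these conditions a G/C pair in
G/C context costs ~2.1 kBT more to open than an A/T pair in an A-tract,
i.e. a ~7–8-fold Boltzmann dwell ratio — the elementary contrast that the
multi-base-pair kinetic step amplifies.

The position-resolved stability profile is the running w-bp mean of
exp(G_1bp) (default w = 6), *exponentiate first, then average*: it is a
Boltzmann dwell propensity, not an averaged energy, and the two orders
differ measurably (Jensen).  The profile value for the window [j, j+w−1] is
reported at j + ⌊w/2⌋.

Displaced-strand mismatches are annotations, not a second strand: a flagged
position's G_1bp is overridden (default 0 kBT — a broken pair opens for
free; configurable), all other positions are untouched.

## Synthetic substrates

The default hairpin emulation is 174 bp with 10-bp GC-rich clusters
(fraction 0.9) centred at 55, 90 and 120 bp on a 0.35-GC background —
a stand-in with the designed stability landscape of the experimental
construct, not its sequence, which is not public.  GC placement is
deterministic per window (exactly round(f·w) strong pairs at seeded-random
positions), so windowed GC content matches the design to 1/w.  Forked
substrates are 33-bp duplexes with an exact GC count (12, 16, 26 → the
gc36/gc48/gc79 designs) and 21-nt arms.

## Stochastic unwinding simulator

A trajectory is a sequence of kinetic steps: a pause drawn exponentially
with the model mean (simultaneous: A·exp(ΣG); delayed release: Σ A·exp(G)),
a deterministic translocation delay n/v_trans (v_trans = 100 bp/s), and an
instantaneous n-bp release.  The final partial step uses its own base
pairs.  A deterministic-pause mode exists for exact tests.  An optional
half-step mode emits two n/2-bp sub-releases per step (asynchronous strand
release); it is off by default.  No backsliding, strand switching, or
analog rebinding is modelled.

Calibration: both pause expressions are linear in A, so the pre-factor
satisfying L / E[T] = target rate (46 bp/s default) is solved directly and
verified to 0.5%.  Note the estimator subtlety: the *mean of per-trace
rates* E[L/T] exceeds L/E[T] by a Jensen term of ~2–3% under exponential
pauses; the simulated ensemble mean rate therefore reads ~47 bp/s against
the 46 bp/s harmonic calibration.  This is a property of the estimator, not
a calibration error.

The measurement model converts bp to extension with the worm-like-chain
interpolation formula (F·Lp/kBT = x + 1/(4(1−x)²) − 1/4); at 8 pN with
Lp = 1 nm and 0.65 nm per nucleotide, one unwound bp (two released
nucleotides) gains 0.785 nm (~0.8 nm).  Noise is i.i.d. Gaussian per sample
(default 14 nm at 200 Hz) — no bead low-pass filtering, no drift.  Real
bead noise is correlated and drifts; synthetic traces are therefore an
*optimistic* detection substrate at matched σ, yet see the resolution
ceiling below.

ATPγS competition: each kinetic step carries m = C·n nucleotide-binding
events (C = 1 default); each is the analog with probability
P = [ATPγS]/(k_r[ATP] + [ATPγS]) and appends an exponential dwell of mean
1/k_off (defaults k_r = 1.2, 1/k_off = 0.4 s).  With zero analog the
simulator reduces exactly to the plain one.

## Step and pause detection

Two detectors share one output contract (segment boundaries, mean levels,
durations):

* `tstep_find` — sliding Welch t-test between adjacent windows; local
  maxima of |t| above the Student critical value at level α mark steps.
  Each scan position is a level-α test, so on pure noise the false-split
  count stays below α × positions scanned.
* `km_step_find` — iterative greedy χ² step placement; the step count is
  chosen by the counter-fit quality ratio (χ² of a fit with steps placed
  mid-plateau over the best-fit χ²), threshold 1.5.

Both accept a boxcar-decimation block (`presmooth_samples`) and refine the
detected boundaries on the raw trace by coordinate-descent least squares.
Defaults (window 25 samples, α = 0.01, no decimation) suit clean or
high-SNR traces and are exact on noiseless staircases.  For 3.9-nm steps
under 14 nm/200 Hz noise the calibrated sets are
`NOISY_*` (decimation 20–40, ~2 s windows) for multi-second plateaus and
`SLOWED_*` (~1 s windows) for analog-slowed traces; both were calibrated on
synthetic benchmarks with ground-truth ledgers.

**Resolution ceiling (important).**  Distinguishing adjacent plateaus of
duration T under per-sample noise σ gives a z-score
Δ/(σ√(2/(f·T))) ≈ 2.8 for 5-bp steps with T ≈ 1 s at σ = 14 nm, 200 Hz.
No detector can reach high recall at acceptable false-positive rates from
z ≈ 3; measured recall saturates near 0.5 in that regime and missed
boundaries merge steps.  Consequently the Gaussian center of detected
step-size distributions from analog-slowed traces (mean plateau ~1 s) is
biased upward to ~7–8 bp even though the generating quantum is 5 bp.  With
multi-second plateaus (e.g. 3–6 s) recall rises above 0.7 and both
detectors center at 5.0 ± 1 bp and agree within 10%.  The practical
resolvability bound exposed as `min_resolvable_rate` (4 bp / 0.3 s ≈ 13
bp/s) marks where detection *begins* to be possible, not where it is
reliable.

Dwell-time histograms accumulate segment (or ground-truth) durations at
their bp level with exact conservation.  Pauses are interior segments with
duration ≥ threshold (default 0.14 s, the core-enzyme mean pause) bounded
by forward motion.  Step-size distributions histogram successive level
differences and fit a single Gaussian locally around the dominant positive
mode (merged steps produce satellites at multiples of the quantum, which a
global fit would drag toward).

## Pause analysis and model selection

Pause/stability peak sets are paired mutual-nearest within 10 bp (unpaired
peaks are reported) and regressed with an intercept; the slope is the
statistic of interest.  Peaks of ground-truth dwell histograms are
extracted after Gaussian smoothing (σ = 2 bp), since ideal dwell
concentrates on the discrete step lattice.  On simulated delayed-release
(n = 5) traces the slope against stability-profile peaks is 0.99 with
r = 1.00 — the sequence-programmed pausing signature.

The reduced-χ² scan simulates every (model, n) cell calibrated to the same
mean rate, analyzes reference and candidates with the identical pipeline
(t-test detector on ideal, noise-free renderings — pauses at 46 bp/s are
~0.06–0.2 s and are undetectable under 14 nm noise by any method, and the
discrimination lives in the pause statistics, not detector performance),
bins pause durations in 5-bp windows, and weights by the reference per-bin
SEM (bins with < 3 pauses excluded).  Self-generated delayed/n = 5
references return χ²ν ≈ 1 at the generating cell and select it.

Salt predictions recompute G_1bp per Na⁺ with A held at its 50 mM
calibration; both models decrease monotonically, and the simultaneous
model (exponentiating a sum) always drops faster — the discriminating
ordering.

The dwell-vs-stability power law is fitted in log–log space.  The
stability window for a dwell bin at position p looks *ahead* (bps
p+1..p+w), because dwell at p is spent melting the next base pairs.  The
pause component of delayed-release dwell is exactly linear (power 1.0);
total dwell is attenuated below 1 by the constant translocation floor.
Either way the non-amplified baseline sits orders of magnitude below the
power ≈ 17 of HRDC-amplified pausing, and the exploratory kinetic
competition baseline (capture probability k_bind/(k_bind + 1/τ_p), capture
dwell 1/k_release) saturates and cannot exceed power ≈ 2 over a 1–3 kBT
sweep.

Pause-lifetime distributions are fitted as exponential mixtures by EM with
BIC model comparison (1 vs 2 components); standard errors come from the
observed information.

## Ensemble kinetics

The single-turnover scheme has a productive fraction f_P traversing n
irreversible steps; the non-productive pool rebinds at k_rebind and
re-partitions with the same f_P (the documented alternative — always
productive on rebind — is a one-line change in the generator matrix).  The
linear system is solved by matrix exponential and cross-checked against a
per-molecule stochastic simulation.  Sequence-dependent variants set
k_(i) = 1/τ_p(i) over the 33-bp duplex (with n = 5: six full steps and a
3-bp final step).  Global fits share (k or A), f_P and k_rebind across
substrates with per-point SEM weights (uniform fallback).

With realistic 2% transient noise the χ²ν valley of the sequence-dependent
scan is shallow between adjacent n (5 vs 6 differ by a few percent) and the
argmin can flip between them across noise realizations; small step sizes
are always strongly rejected.  The uniform-variant scan on its own data
selects the generating n exactly.  A single-substrate uniform fit with k
free has a correspondingly shallow valley (identifiability caveat).

## Mechano-chemical coupling

τ = mP/k_off + 1/k_step and v = n/τ are fitted jointly across analog
fractions with per-point SE weights, n fixed from step-size analysis.
Because the observables depend on m and k_off only through m/k_off, a fit
with both free sits on an exact ridge; `CouplingModel.fit` therefore takes
k_off from an independent pause-escape measurement (the synthetic dataset
carries one with the same relative noise), and the all-free mode is
provided but flags the ridge through its covariance.  With 5% noise on six
fractions the recovered C is unbiased with SD ≈ 0.12 and the on-rate ratio
with SD ≈ 0.25 — matching the ±0.2 scale of the printed uncertainties, so
single replicates land within those envelopes at roughly the 1σ rate, and
replicate means are used where a tight point estimate is needed.  A
validity flag checks that the analog hydrolysis bound (0.2 s⁻¹) is well
below the fitted k_off, justifying the no-hydrolysis simplification; the
occupancy simulation confirms < 1 analog incorporation per bp at the 50%
fraction, justifying neglect of repeated binding.

## Problem sizes and determinism

Default analysis sizes (100 traces for rate calibration checks, 20–25
traces per χ²-scan cell, 20 traces for step-size distributions, 40
replicate coupling datasets) give standard errors comfortably inside the
tolerances asserted in the test suite.  Every stochastic entry point takes
a seed; trace sets and replicate protocols spawn child seeds from a root
`SeedSequence`, so all results are bit-reproducible for a fixed seed.

## Known limitations

* Noise is white; real bead noise is correlated and drifting, so real-data
  detection is harder than the synthetic benchmarks at equal σ.
* No analog rebinding, backsliding or strand-switching: analog-slowed
  pauses are shorter-tailed than experiment, which is the root of the
  step-size center bias discussed above.
* Mismatch energetics are a single override constant; no nearest-neighbor
  mismatch parameters.
* The hairpin loop, handles and bead mechanics are outside the model; the
  WLC conversion applies to the released ssDNA only.
* The kinetic-competition accessory-domain baseline is exploratory: it
  exists to show what saturating capture *cannot* do (large power-law
  exponents), not to model the amplified pausing mechanism itself.
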