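# Methods

This note documents the models and procedures implemented in `erlumen`,
the choices made where the underlying experimental analyses left the
method open, and what the synthetic-data tests do and do not establish.

## Spectral-count enrichment model (`erlumen.counts`)

Affinity-enrichment mass spectrometry yields, for each protein *g*
(*g* = 1..*p*), animal block *c* (*c* = 1..*C*) and condition *t* (0 =
scrambled-peptide control, 1 = bait peptide), a spectral count
*y<sub>gct</sub>*. The model is a hierarchical Poisson log-linear model
with a spike-and-slab treatment effect:

    y_gct + 1 ~ Poisson(λ_gct)
    log λ_gct = log μ_c + α_gc + t·β_g
    α_gc ~ N(0, σ_c²)
    β_g  ~ π₀·δ₀ + (1 − π₀)·N(0, τ²)
    π₀ ~ Beta(0.5, 0.5),   σ_c⁻², τ⁻² ~ Gamma(1, 1)

with the per-block scale fixed at the plug-in
μ_c = p⁻¹ Σ_g (y<sub>gc0</sub> + y<sub>gc1</sub> + 2)/2 and never
resampled. The pseudo-count of 1 avoids log(0) and biases inference
conservatively (it shrinks count ratios toward 1). Raw tables are stored
unshifted; the offset lives entirely in the likelihood.

Inference targets the local false sign rate,
lfsr<sub>g</sub> = P(β_g ≤ 0 | Y) — the posterior probability that
protein *g* is *not* preferentially bound by the bait. Spike draws
(β_g = 0 exactly) count toward the event. Proteins with
lfsr ≤ 0.2 (inclusive at the threshold) are selected; the mean lfsr over
the selected set estimates the global false sign rate of the selection.

### Sampler

Metropolis-within-Gibbs, one chain, deterministic given an integer seed:

- **π₀, τ², σ_c²** — exact conjugate draws
  (Beta / inverse-Gamma closed forms).
- **(z_g, β_g)** — exact gridded Gibbs. The treated cells contribute
  b_g·β − c_g·e^β (with b_g the summed shifted bait counts and
  c_g = Σ_c μ_c e^{α_gc}), so the slab marginal is a 1-D integral
  evaluated by trapezoid quadrature on a 400-node grid spanning 0 and the
  likelihood mode ±8·max(τ, 1). Given z_g = 1, β_g is drawn from the
  gridded conditional by inverse CDF with within-cell jitter; given
  z_g = 0, β_g = 0 exactly. The unit test suite pins this conditional to
  an independent adaptive-quadrature oracle at ≤ 1e-4 absolute error.
- **α_gc** — vectorised random-walk Metropolis with per-cell step sizes
  adapted toward ~40% acceptance during burn-in only (Robbins–Monro),
  frozen afterwards so the retained chain has a fixed kernel.

Defaults: 4000 iterations, 2000 burn-in, no thinning. Log-rates are
clamped to ±30 before exponentiation. No sum-to-zero constraint is
imposed on α_gc; with small *C* the N(0, σ_c²) prior is the only
regulariser, matching the model as stated.

### Calibration

Simulation-based calibration draws hyperparameters from the model's own
priors, generates data **on the shifted scale** (the generator emits
u ~ Poisson(λ) and the fit uses `pseudo_count=0`, so the fitted model is
exactly the generative one; emitting u−1 would be impossible at u = 0),
and checks that randomized-PIT ranks of the true β and π₀ are uniform
across 200 replicates at p = 40, C = 3 (chains of 700/350 — sized so the
whole suite stays desk-scale). Two deliberate alignments make SBC exact:
the generator applies the same ±30 log-rate clamp as the likelihood
(inverse-gamma prior tails otherwise overflow Poisson sampling), and the
SBC fit receives the true generative μ_c, because the data plug-in is an
intentional approximation outside the probabilistic model. A separate
check confirms that among lfsr ≤ 0.2 selections across model replicates
the realised false-sign fraction respects the threshold and is tracked
by the selected-set mean lfsr.

## Single-channel gating (`erlumen.gating`)

Traces are acquired at 5 kHz after 1 kHz anti-alias filtering (the
defaults throughout). Idealization is half-amplitude multi-level:
occupancy = round((i − closed)/increment) clamped at zero, followed by
dead-time merging in which runs shorter than the dead time are absorbed
into their longer neighbour until none remain. The default dead time
follows the Gaussian-filter rise-time convention T_d = 0.179/f_c
(≈179 µs at 1 kHz). Closed level, open increment and noise s.d. are
estimated, when not supplied, by a BIC-selected Gaussian-mixture fit to
the amplitude histogram; idealization refuses traces whose increment is
below 4 noise standard deviations. Hidden-Markov idealization is out of
scope.

Per-channel open probability is Σ_k k·(time at level k)/(N·duration) —
the multichannel convention. Dwell-time means are reported only for
single-channel records (first and last sojourns dropped as incomplete);
aggregated multi-channel dwell analysis is out of scope.

**Active-channel count confidence.** The published workflow accepts a
trace only when the number of active channels N_A can be asserted with
>99% confidence; the exact published rule lives in earlier work not
restated here, so this package implements a documented stand-in with the
same contract: with per-channel P̂_o estimated under candidate N (the
maximum observed level), an unseen (N+1)-th identical channel would
raise the occupancy past N at a random instant with probability
P̂_o^{N+1}; treating the record as m = duration/(mean open + mean
closed) independent gating windows, confidence = 1 − (1 − P̂_o^{N+1})^m.
The rule is conservative by construction and is verified by simulated
ensembles (N ∈ {1, 2, 3}) to undercount accepted traces in <1% of cases.

Current–voltage ramps: the closed-channel baseline is a straight line
fitted to level-0 samples (leak subtraction); open-channel current is
(i − baseline)/level at occupancy ≥ 1; least-squares polynomials of
order 1 or 4 summarise the relation, with the slope conductance read off
the linear coefficient at 0 mV.

## Hill dose-inhibition fits (`erlumen.dose_response`)

Open probability versus luminal free Ca²⁺ follows the simple inhibitory
Hill curve P_o(c) = P_max·[1 + (c/K_inh)^{H_inh}]⁻¹. Fits are
unweighted nonlinear least squares to the *mean* P_o per concentration
(1/sem² weighting available by flag), parameterised in log K for
positivity, with a deterministic multi-start (H ∈ {1, 2, 4}; K from the
first half-max crossing; P_max from the observed maximum) and curvature
standard errors. P_max floats by default, with a flag to fix it to the
low-Ca plateau. Flat datasets are rejected as unidentifiable, and a
dataset that never leaves the plateau raises a warning flag. Units are
µM throughout.

## Ca²⁺-imaging classification (`erlumen.cell_signals`)

Traces are normalized to the mean ratio over the first 30 s (R/R₀) —
all subsequent logic is scale invariant. A cell is *included* when every
baseline frame lies within [0.75, 1.25] and every frame of the final
30 s of washout is below 1.5 (strict per-frame reading; a flag relaxes
the washout test to the window mean); a *responder* reaches R/R₀ ≥ 2.0
after stimulation; a responder *oscillates* when the %CV (sample
s.d./mean × 100) over the window from the end of the initial transient
to the end of stimulation exceeds 15%.

Two points the experimental description leaves qualitative are made
operational here: (i) the "end of the initial signal" is the first time
after the first post-stimulus peak at which R/R₀ falls below
baseline + 50% of the peak elevation, falling back to peak + 20 s when
the trace never returns that far; (ii) oscillating cells are sub-typed
as *periodic oscillation* when the largest interior peak of the
autocorrelation of the analysis window exceeds 0.4, else *random
spiking*. Both definitions are recorded in the output and tested against
constructed fixtures. Note that the window CV of a smooth transient
depends on its decay rate: a long (~25 s) decay constant alone can push
the CV above 15%, so "non-oscillating responder" fixtures use fast
transients settling on modest plateaus.

Population responses: ΔR is the ratio minus its mean over the 90 s
pre-agonist baseline; the rising phase (stimulus to first maximum) is
fitted with ΔR(t) = ΔR_max·(1 − e^{−(t−t₀)/τ}) with t₀ fixed at the
stimulus, so the curve reaches (1 − 1/e)·ΔR_max at t₀ + τ. Group values
are normalized to the control mean and compared by unpaired Student
t-tests.

## Synthetic data (`erlumen.simulate`)

- **Counts** — draws (z, β, α) then Poisson counts from the model above.
  Study-scale preset: p = 486, C = 3; π₀ = 0.95, τ = 1, σ_c = 0.6,
  μ_c lognormal around 3 (effect and nuisance magnitudes are this
  package's choice of a sparse-positive enrichment regime; the layout is
  fixed by the design being emulated). Shifted mode is described above;
  raw mode emits max(Poisson(λ) − 1, 0).
- **Gating** — N independent two-state Markov channels sampled exactly
  (alternating exponential sojourns from the stationary state), summed,
  scaled (closed level 0 pA, increment 2 pA), Gaussian noise added
  (0.2 pA s.d.) and low-pass filtered by a Gaussian FIR with −3 dB at
  the cutoff (σ_t = √(ln 2)/(2π f_c); a true Bessel response is not
  required for these tests). Uninhibited defaults: P_o = 0.65 with
  10 ms mean open time (closing rate 100 s⁻¹). Setting a luminal [Ca²⁺]
  rescales the opening rate so the stationary P_o follows the Hill curve
  with (P_max, K_inh, H_inh) = (0.65, 260 µM, 2.3).
- **Dose-response datasets** — 8 log-spaced concentrations 0.07–600 µM,
  10 traces of 30 s per concentration; per-trace P_o is the exact
  open-time fraction of the continuous sojourn path, so the only scatter
  is genuine gating noise (the noisy-trace/idealization path is
  exercised separately and is statistically equivalent here).
- **Cells** — archetype profiles (non-responder, smooth responder,
  periodic oscillator, random spiker with heavy-tailed inter-spike
  gaps), multiplied by a random per-cell gain and multiplicative
  baseline noise (CV 3%) so classifier scale invariance is genuinely
  exercised; 2 s frames, 30 s baseline, stimulation to 390 s, washout
  to 480 s.

Every generator is bit-reproducible from (config, seed) and emits its
ground truth.

### What the synthetic tests do not show

The generators realise the statistical structure the analyses assume —
Poisson counts with log-normal random effects, memoryless two-state
gating, archetypal Ca²⁺ responses. Real eluate counts carry shared
contaminants and peptide-level identification artefacts; real channels
show modal gating, subconductances and drifting baselines; real imaging
adds bleaching, focus drift and movement. Passing tests therefore
establish correctness of the computations under their stated models, not
robustness to those artefacts.

## Numerical choices and limitations

- Log-rates clamped to ±30 before exponentiation (generator and fit).
- lfsr ties at the threshold are selected (≤).
- Incomplete count designs are rejected by default; an explicit option
  imputes missing cells as 0 and flags the output.
- Quadrature grids use 400 nodes; widening is automatic through the
  mode-anchored span. Inverse-CDF draws jitter uniformly within a cell.
- Dead-time merging resolves ties toward the longer neighbour;
  sub-dead-time true events are unrecoverable by construction.
- The channel-count confidence rule is a conservative stand-in (see
  above), not a reimplementation of the published reference method.
- Reported chain sizes in tests (400–1200 iterations at p ≤ 80; SBC at
  p = 40) are reduced-scale choices; production fits default to
  4000/2000 and accept the full 486-protein scale in minutes.
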