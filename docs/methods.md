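# Methods

## The problem

Atoms in a biomolecule that exchange between two conformations A ⇌ B on
the microsecond–millisecond time scale show *relaxation dispersion*: the
effective transverse relaxation rate R2eff depends on how fast the
experiment refocuses chemical-shift evolution, either through the
180°-pulse repetition frequency ν_CPMG of a CPMG train or through the
amplitude ω₁ and offset Ω of a spin-lock field (R1ρ). Fitting dispersion
curves yields the populations pA, pB = 1 − pA (thermodynamics), the
exchange rate k_ex = k_AB + k_BA (kinetics, with detailed balance
k_AB = pB·k_ex, k_BA = pA·k_ex), and the chemical-shift difference
|Δω| between the states (structure). This package converts peak
intensities to rates, fits a catalogue of thirteen two-site models, and
automates model selection and error estimation.

## Units and conventions

All model kernels work in angular frequencies (rad/s); the user-facing
parameters are shift differences in ppm (converted per static field and
isotope through the gyromagnetic-ratio table), ν_CPMG and ω₁/2π in Hz,
rates in 1/s. τ_cp is the delay between consecutive 180° pulses and
ν_CPMG = 1/(2 τ_cp); the number of pulses in the constant relaxation
period T is 2·T·ν_CPMG, rounded to the nearest integer (a mismatch above
1 % is logged). Only the magnitude of Δω is stored: the two-site models
depend on its sign through even powers or a global symmetry, so the sign
is not determinable from dispersion data.

φ_ex = pA·pB·Δω² (the fast-exchange dispersion amplitude) is *fitted* in
ppm² and converted to rad²/s² at each point's field. A single rad²/s²
value cannot describe data recorded at two static fields, because Δω in
rad/s scales with the field; the ppm² parameterization makes one number
consistent across fields.

The R1ρ condition table stores the offset of the state-A resonance from
the spin-lock carrier in ppm (signed); state B sits at that offset plus
Δω. The tilt angle θ = atan2(ω₁, Ω̄) is computed from the
population-averaged offset for the fast-exchange models and from the
state-specific offsets inside the Trott–Palmer and Miloushev–Palmer
exchange terms, following their derivations.

## Model catalogue

CPMG, analytic: No Rex (flat), LM63 (Luz–Meiboom fast exchange), CR72
(Carver–Richards, all time scales), IT99 (Ishima–Torchia, skewed
populations), TSMFK01 (Tollinger et al., very slow exchange, forward
rate k_AB only), and MMQ CR72 (the Korzhnev multiple-quantum extension,
with the proton shift difference ΔωH entering ZQ/DQ coherences as
effective shifts Δω ∓ ΔωH and the MQ coherence through a complex
generalisation of the Carver–Richards terms). R1ρ, analytic: No Rex
(R1 cos²θ + R1ρ′ sin²θ), M61 (on-resonance fast exchange), DPL94
(off-resonance fast exchange), TP02 and MP05 (skewed populations, all
time scales). IT99 uses the τ_cp⁴ truncation variant, i.e. the
denominator k_ex² + sqrt(pA²Δω⁴ + 144/τ_cp⁴).

Numeric: explicit propagation of the two-site Bloch–McConnell equations.
SQ CPMG uses the 2×2 complex evolution matrix over the (A, B) transverse
magnetizations with 180° pulses applied as complex conjugation in the
echo pattern (τ−180−τ)ⁿ; the propagator over one delay is a closed-form
2×2 matrix exponential (verified against scipy to 1e−12) applied n
times, so halving the step changes nothing — a property the test suite
asserts to guard the segmentation logic. The MQ branch propagates the
double- and zero-quantum components in parallel: within each half of the
relaxation period the heteronuclear pulses alternate the two evolution
matrices (flipping the sign of the heteronuclear shift only), a proton
180° at mid-period moves both components into the complex-conjugate
space (refocusing the proton shift), and the two components' state-A
magnetizations are averaged. R1ρ uses the 6×6 real matrix over
(x, y, z) × (A, B); the initial magnetization of both states is tilted
onto the state-A effective field (hard adiabatic alignment) and the rate
is the log-decay of the state-A projection onto that axis. Starting
magnetization for CPMG is thermal equilibrium (pA, pB), matching
constant-time preparation, and R2eff is the single-point log ratio at T,
mirroring the experimental observable; both choices matter at slow
exchange and are the reason the analytic/numeric comparisons below are
made against a finite-duration experiment rather than an asymptotic
eigenvalue.

### Validity regimes measured against the numeric reference

Over the standing sweep (pA 0.9–0.99, k_ex 500–10⁴ 1/s, Δω 1–3 ppm at
600/800 MHz, ν_CPMG 50–1000 Hz, T = 40 ms): CR72 tracks the numeric
reference to <2 % for k_ex ≥ 2Δω, degrading to ~6 % toward slow
exchange; LM63 to <2 % for k_ex ≥ 20Δω; IT99 to <10 % for pA ≥ 0.95
outside the intermediate window 0.5 < k_ex/Δω < 3; TSMFK01 to <10 % in
its very-slow regime (pA ≈ 0.99, k_ex ≤ 200 1/s); MMQ CR72 to <5 % for
skewed populations. DPL94 holds to <5 % for k_ex ≥ 10Δω and TP02/MP05 to
well under 10 % for pB ≤ 0.05, with MP05 strictly more accurate than
TP02 on a broader sweep that includes pA down to 0.8.

## Fitting

The target is weighted least squares, χ² = Σ (R_calc − R_obs)²/σ², over
all spins of a cluster. The free parameters form a deterministic vector:
cluster-global symbols (pA, k_ex, k_AB) first, then per-spin symbols
(Δω, ΔωH, φ_ex) and per-spin-per-field baselines (R2⁰ or R1ρ′), spins in
sorted id order. Default bounds: baselines 0.1–200 1/s, pA 0.5–1 (the
lower bound breaks the two-site label-swap symmetry), k_ex 1–10⁶ 1/s,
Δω and ΔωH 0–30 ppm, φ_ex 0–70 ppm².

The initial grid search uses 11 points per gridded dimension
(log-spaced for k_ex, k_AB and φ_ex, linear otherwise); baselines are
seeded from the observed rate at the largest ν_CPMG (or ω₁) per field
rather than gridded, which removes the highest-count dimensions.
Minimization is Nelder–Mead simplex under a logarithmic barrier for the
box constraints, run in box-normalized coordinates z = (x − lo)/span so
that parameter tolerances are relative to each box span (without this
the simplex is badly anisotropic across k_ex and pA). The barrier weight
is 1e−6 of the starting χ²; a restart on pure χ² from the best point
polishes away the barrier bias and guards against simplex stagnation.
Points outside the open box score +∞ without evaluating the model, so
the model is never called out of bounds. Convergence requires the
simplex to collapse below 1e−10 of each box span with the χ² spread
below max(1e−25, 64·ε·χ²); a restart that cannot improve its starting
point by more than 1e−10 relative is also classified converged, because
on very steep surfaces the spread tests sit below the floating-point
cancellation noise of χ² itself. The iteration cap is 2000 per stage
(measured to cost at most ~1e−12 in χ² against a 20 000 cap); Monte
Carlo refits, which start at the point estimate, use 500.

The four hot analytic kernels are additionally compiled (numba),
mirroring the vectorised reference implementations branch for branch;
the test suite asserts the two routes agree to 1e−10.

### Warm starts

Three devices skip the grid search, following the fixed table: *model
nesting* (IT99 from CR72; DPL94 from M61; TP02 from DPL94 with
Δω = sqrt(φ_ex/(pA·pB)) at pA seeded 0.95), *model equivalence* (the
numeric models copy their analytic counterparts' optima: NS CPMG from
CR72, NS MMQ from MMQ CR72, NS R1ρ from MP05; MP05 copies TP02;
MMQ CR72 extends CR72 with a small ΔωH seed), and *cluster averaging*
(a clustered fit starts from the unweighted mean of the members'
single-spin optima for global symbols, members' own values for per-spin
symbols). The no-exchange model starts from the per-field data plateau.
The warm-start routes are validated against independent exhaustive
grid-plus-simplex fits on three fixtures (clustered CPMG, MMQ, R1ρ):
the protocol χ² never exceeds the exhaustive χ² by more than 1e−6
relative. The R1ρ chain is not merely a speed-up: on off-resonance
fixtures the raw grid start can land TP02 in a local minimum that the
DPL94-seeded start avoids.

## Model selection and errors

Models are ranked per cluster by AIC = χ² + 2k (χ² is −2 log-likelihood
up to a constant for Gaussian errors); ties break to fewer parameters,
then catalogue order. Before ranking, fixed elimination rules flag
failed fits: k_ex (or k_AB) within 1 % of its upper bound, pA within
1e−4 of 1 while Δω sits at its upper bound, non-convergence, or
non-finite parameters. The no-exchange model is never eliminated, so a
candidate always survives. The thresholds are configuration keys with
these defaults.

Parameter errors come from Monte Carlo simulation: each of n_sims
(default 500; the validation studies use 50) replicates back-calculates
rates from the fitted parameters, adds Gaussian noise with the measured
per-point σ, refits from the point estimate (no grid — the same
philosophy as the warm starts), applies the elimination rules, and the
error is the standard deviation over surviving replicates. Simulation i
derives its generator from (seed, i), making the estimate independent of
execution order. For a one-parameter flat dispersion the Monte Carlo
spread reproduces the closed-form weighted-least-squares standard error
σ/√N to within 1 %.

## The automated protocol

`run_protocol` executes: (1) a non-clustered pass over every spin and
every applicable model in catalogue order (simple → complex, so warm
start sources are always already fitted); (2) elimination; (3) a
clustered pass for clusters of two or more spins, seeded by cluster
averaging; (4) Monte Carlo errors for surviving fits; (5) a final AIC
selection over the stored fits — a re-evaluation, not a refit. Models
that cannot describe a spin's data (e.g. SQ-only analytic models on
multiple-quantum data, or the MMQ models on SQ-only data, where they
duplicate the SQ forms) are recorded as skipped with a reason, so every
(unit, model) pair is accounted for. Work is partitioned at the
spin/cluster level and the per-simulation seeds partition the Monte
Carlo level; results are assembled in fixed order, so any worker count
produces a bit-identical report. Reports are written as a summary CSV,
per-spin observed/back-calculated curve CSVs, one xmgrace `.agr` plot
per spin, and a run log.

## Synthetic data

The generator back-calculates rates through the same catalogue kernels
(or the numeric reference), adds Gaussian noise of standard deviation σ
directly to the rates (default) or to simulated peak intensities
I = I_ref·exp(−R·T) (exercising the intensity-conversion path), and
stores σ as the quoted error. The default CPMG study emulates a
two-field (600/800 MHz) backbone-¹⁵N experiment: 15 ν_CPMG values,
multiples of 1/(2T) from 50 to 750 Hz so every frequency fits an integer
pulse count into T = 40 ms, baseline 10 1/s, σ = 0.5 1/s, and two-site
exchange at pA = 0.95, k_ex = 2000 1/s, Δω = 2 ppm — a mid-sized
exchange contribution (Rex ≈ 14 1/s at 600 MHz) typical of published
dispersion studies. What the generator does not emulate: peak overlap
and lineshape distortions, field inhomogeneity, off-resonance effects of
the CPMG pulses, temperature drift between fields, or non-Gaussian
intensity noise. Passing tests therefore demonstrate correctness of the
analysis chain under the stated noise model, not robustness to spectral
artifacts.

Under those defaults the maximum-likelihood precision over 100
replicates is about 1.4 % (median) for pA, 7 % for k_ex and 12 % for Δω
— in every replicate examined the fitted χ² is below the χ² of the true
parameters, so this scatter is the information content of the design,
not an optimizer limitation. Two-field data at higher Δω or lower noise
tighten it rapidly.

## Known limitations

Two-site exchange only; no 3-site or multi-site models. CPMG pulses are
ideal and instantaneous. R1 is a measured per-point input for
off-resonance R1ρ models, never fitted. The M61 on-resonance condition
is enforced as a warning (|Ω̄|/ω₁ < 0.01 by default), not an error.
Covariance-matrix errors are not offered; Monte Carlo is the only error
route. The `.agr` writer emits a minimal two-set plot, not a styled
figure.
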