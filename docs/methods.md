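# Methods

## Model and regimes

The motif is two λ–ω oscillators — the Hopf normal form in rectangular
coordinates — coupled diffusively and driven by independent additive
white noise on the x coordinate only:

    dxᵢ = [λ(rᵢ) xᵢ − ω(rᵢ) yᵢ + dᵢ (xⱼ − xᵢ)] dt + δᵢ dηᵢ
    dyᵢ = [ω(rᵢ) xᵢ + λ(rᵢ) yᵢ + dᵢ (yⱼ − yᵢ)] dt

λ(r) = λ₀ + α r² + γ r⁴, ω(r) = ω₀ + ω₁ r².  With the standard set
α = γ = −0.2, ω₀ = 2, ω₁ = 0 the uncoupled unit undergoes a
supercritical Hopf bifurcation at λ₀ = 0: for λ₀ > 0 a stable cycle of
radius r* solves λ(r*) = 0 (exactly one positive root of the quadratic
in r² exists when α, γ < 0), for λ₀ < 0 the origin is stable but
excitable by noise.  All stochastic experiments run at λ₀ = −0.5 unless
scanned.

At the origin the Jacobian of the coupled system decomposes into the
rotation block λ₀ I + ω₀ J plus the coupling matrix [[−d₁, d₁], [d₂,
−d₂]], whose eigenvalues 0 and −(d₁+d₂) commute blockwise with the
rotation.  The spectrum is therefore {λ₀ ± iω₀, λ₀ − (d₁+d₂) ± iω₀}
exactly, giving the two Hopf points HB₁: λ₀ = 0 and HB₂: λ₀ = d₁ + d₂.
The package carries both this closed form and a bracketed
eigenvalue-crossing root-finder (tolerance 1e−10 over λ₀ ∈ [−0.1,
d₁+d₂+0.1]) that validates it to 1e−8.  Continuation of the periodic
orbits born at the Hopf points (their amplitudes and Floquet stability)
is out of scope; only the origin analysis and the uncoupled cycle
radius are computed.

Two-parameter loci are stored as λ₀ versus the coupling grid (slope
dλ₀/dd). Displayed with the coupling on the vertical axis — the
conventional orientation for such diagrams — the symmetric-coupling
locus λ₀ = 2d has slope 1/2 and the one-coupling-varied loci have slope
1; `HBLocus.figure_frame_slope` makes the conversion explicit.

## Stochastic integration

Euler–Maruyama with dt = 0.01 (the production step; larger steps are
warned about).  The noise is additive, so the scheme is strong order 1
and higher-order schemes would buy nothing.  Initial conditions are
drawn i.i.d. N(0, 0.008²) per coordinate, modelling trajectories
started near the quiescent state.  Defaults: horizon t_end = 500 time
units with the first t_transient = 100 discarded before any statistic
(~127 natural periods analysed); both are configurable, and the scan
drivers use shorter horizons (noted below).

Reproducibility: trial k of an ensemble uses the substream
SeedSequence(seed, spawn_key=(..., k)); within a trial the draw order
is four IC normals then, per step, the x₁ increment then the x₂
increment.  The batched JIT-compiled integrator performs the identical
scalar arithmetic as a single-trial run, so ensembles are bit-identical
to their per-trial recomputation, and every sweep cell records enough
seed lineage to be regenerated in isolation.  A high-accuracy
deterministic integrator (adaptive RK45, rtol 1e−10) serves as the
noise-free oracle; the linear-regime stationary variance is checked
against the closed-form Lyapunov solution in the test suite.

## Phases and filtering

Noisy trajectories are smoothed with a zero-phase (forward–backward)
4th-order Butterworth low-pass filter, cutoff 3 × ω₀/2π ≈ 0.955 cycles
per time unit, before phase extraction.  The cutoff keeps the
oscillation band (0.32 cycles) fully intact — in-band amplitudes are
preserved to better than 1% — while removing step-scale jitter.
Narrower cutoffs were examined and rejected: a cutoff at the natural
frequency itself distorts the oscillation band asymmetrically between
the two (differently driven) oscillators and fabricates a spurious
relative-phase lag of order 0.4 rad.

The phase is geometric: φᵢ = atan2(yᵢ, xᵢ) (the rotation is about the
origin, so the quadrant-aware angle is required), wrapped onto [0, 2π)
so that ±2π phase slips cannot compound.  The 1:1 relative phase is
Δφ = wrap(φ₂ − φ₁) ∈ (−π, π], the boundary mapping to +π.  The sign
convention (oscillator 2 minus oscillator 1) is fixed by the
density-shift phenomenology it must reproduce: with strongly uneven
coupling d₁ = 0.3, d₂ = 0.01 the Δφ density centre moves upward through
zero as δ₂ grows.  Exact (0,0) samples carry the previous phase forward
and are counted in the log.  Filtering precedes phase extraction;
statistics use the post-transient window only.

## Measures

* |Δφ|: time mean of the absolute *wrapped* difference.  Using the
  circular wrap before the absolute value (rather than a raw difference
  of cyclic phases in [0, 2π)) is the single most consequential reading
  in the package: it makes antipodal proximity count once and allows
  the signed, near-zero density peaks actually observed.
* R = |⟨e^{iΔφ}⟩|: the mean phase coherence.  The sum-of-squares form
  without the radical is R²; the modulus is the established statistic
  and is what the package reports (R = 1 under perfect locking either
  way).
* ρ = (ln M − S)/ln M with S the Shannon entropy of the M-bin Δφ
  histogram over (−π, π], 0·ln 0 := 0.  M defaults to the sample-size
  heuristic round(exp(0.626 + 0.4 ln(n−1))), floored at 8.
* β = h_p ω_p / Δω from an averaged-segment (Welch) spectrum of the
  filtered x: segments of 4096 samples (50% overlap, per-segment mean
  removal), a 3-bin boxcar over frequency, peak width measured where
  the smoothed spectrum falls to e^{−1/2} h_p with linear interpolation
  on both flanks, a crossing accepted only when three consecutive bins
  sit below threshold (one noisy dip on a broad peak must not truncate
  the width), and flanks that never cross capped at the band edge and
  flagged.  These estimator settings were calibrated against the exact
  spectrum of the linear (α = γ = 0) oscillator, where the transfer
  function is available in closed form: peak height agrees to ~10%,
  width to ~5%.  A spectrum whose maximum is below twice its median is
  declared peakless (β undefined) rather than fitted.  Angular
  frequency is used throughout; β is a ratio of same-unit quantities,
  so the cycles-vs-radians choice cancels.
* Density mode: wrapped Δφ samples are binned on a 10⁻³-rad circular
  grid and smoothed with a wrapped-Gaussian kernel, bandwidth
  σ̂_circ (4/3n)^{1/5} (circular Silverman rule).  Near-ties of
  comparable height far from the mode set a multimodality flag.

## Experiment drivers and problem sizes

Noise axes are log-spaced over [0.01, 5] — the synchrony structure
spans two decades — and coupling axes linear over [0.01, 0.3].  Trial
tiers: `paper` (N = 200, t_end = 500), `standard` (N = 50, t_end =
500), `smoke` (N = 8, t_end = 120).  Heat-map minima are reported two
ways: the absolute minimum is the raw grid argmin (ties broken toward
smaller δ₁+δ₂, then smaller δ₁); local minima are cells strictly below
their 4-neighbours after a 3×3 mean smoothing that suppresses
Monte-Carlo speckle.  The λ₀ scan fits the optimal-noise sum in two
windows (shallow: λ₀ < −0.3; steep: −0.5 < λ₀ < 0), both configurable.

Problem sizes used by `scripts/acceptance.py`: the locus slope uses 15
eigenvalue-crossing points; the β sweep 20 grid points × 200 trials
(the full trial budget, because the β plateau is flat and cell means
need tight standard errors); the δ₂ sweep 20 points × 50 trials; the
density mode pools all post-transient samples of the optimal cell's 50
trials; the coupling-regime scan uses 12-point noise grids × 20 trials
× 4 coupling pairs at t_end = 300.  The test suite uses the same or
smaller sizes so the default run stays within a desk-scale budget.

## What the simulations do and do not show

All inputs are synthetic: the generator *is* the model, so passing
tests demonstrate internal consistency of the pipeline (integration,
filtering, phase statistics, optimisation over grids) and
reproduction of the model's published phenomenology — not anything
about biological neurons.  Known limitations:

* Grid argmaxima are resolved only to the grid step, and near-flat
  objectives (the β curve between δ ≈ 1 and 2; the |Δφ| basin between
  δ₂ ≈ 0.4 and 1) make the located optimum cell seed-sensitive within
  that flat region.  Results therefore quote the grid and budget.
* The weak-noise (δ₂ ≲ 0.05) relative-phase density is broad and nearly
  flat; its mode is resolved only to roughly ±0.1 rad at N = 50 and its
  sign is filter-dependent, so only the direction of the weak→strong
  density shift is robust at desk scale.
* Inhibitory coupling (d < 0), n:m locking with (n, m) ≠ (1, 1), and
  motifs of more than two units are out of scope.
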