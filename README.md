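# motifsync

Simulation and analysis toolkit for **noise-induced synchrony in a
two-neuron motif**: a pair of excitable λ–ω oscillators (the normal form
of a supercritical Hopf bifurcation) coupled diffusively with *uneven*
strengths and driven by *asymmetric* independent additive noise.

Two-neuron motifs are the most common connectivity pattern in neuronal
networks, and real circuits are heterogeneous: the two cells rarely see
the same noise level or the same coupling strength.  This package lets
you ask, quantitatively, when such a heterogeneous pair synchronizes —
and how much noise, applied to which cell, synchronizes it best.

## Model

Each oscillator i ∈ {1, 2} obeys the stochastic differential equations

    dxᵢ = [λ(rᵢ) xᵢ − ω(rᵢ) yᵢ + dᵢ (xⱼ − xᵢ)] dt + δᵢ dηᵢ(t)
    dyᵢ = [ω(rᵢ) xᵢ + λ(rᵢ) yᵢ + dᵢ (yⱼ − yᵢ)] dt

with rᵢ² = xᵢ² + yᵢ², radial growth rate λ(r) = λ₀ + α r² + γ r⁴ and
angular frequency ω(r) = ω₀ + ω₁ r².  The standard parameter set is
α = γ = −0.2, ω₀ = 2, ω₁ = 0 (supercritical Hopf at λ₀ = 0).  For
λ₀ < 0 the pair is quiescent; independent Wiener noise of intensities
δ₁, δ₂ (applied to x only) excites sustained noise-induced oscillations.
dᵢ is the diffusive coupling strength *into* oscillator i, so d₁ ≠ d₂ is
uneven coupling.

Synchrony of the wrapped relative phase Δφ = φ₂ − φ₁ (geometric phase of
each filtered trajectory, wrapped to avoid compounding ±2π phase slips)
is quantified by three statistics computed per trial and averaged over a
seeded ensemble:

* **|Δφ|** — time-mean absolute wrapped phase difference (0 = in-phase),
* **R** — mean phase coherence, the modulus of the circular mean of
  e^{iΔφ} (1 = locked),
* **ρ** — entropy synchronization index (S_max − S)/S_max of the Δφ
  histogram (1 = a single occupied bin).

Oscillation regularity of a single noisy cell is measured by the
signal-to-noise ratio β = h_p · ω_p / Δω of the dominant power-spectrum
peak (height h_p, centre ω_p, width Δω at the e^{−1/2} h_p level) —
a coherence-resonance statistic that is maximal at intermediate noise.

## Worked example

```python
import motifsync as ms

p = ms.OscillatorParams(lambda0=-0.5)          # excitable regime
c = ms.CouplingParams(d1=0.3, d2=0.01)         # strongly uneven coupling
noise = ms.NoiseParams(delta1=0.05, delta2=0.95)
s = ms.SimSettings(t_end=500.0, t_transient=100.0, n_trials=20, seed=42)

hp = ms.hopf_points(p, c)
print(f"HB1 at lambda0 = {hp.hb1_lambda0:.2f}, HB2 at lambda0 = {hp.hb2_lambda0:.2f}")

trials = ms.ensemble(p, c, noise, s)
phases = [ms.extract_phases(t) for t in trials]
summary = ms.trial_summary(phases)
print(f"|dphi| = {summary.mean_abs_dphi:.3f} +/- {summary.sem_abs_dphi:.3f}")
print(f"R      = {summary.R:.3f} +/- {summary.sem_R:.3f}")
print(f"rho    = {summary.rho:.3f} +/- {summary.sem_rho:.3f}")
```

prints

```
HB1 at lambda0 = 0.00, HB2 at lambda0 = 0.31
|dphi| = 0.705 +/- 0.007
R      = 0.659 +/- 0.005
rho    = 0.110 +/- 0.002
```

The deterministic pair has its quiescent-to-oscillatory transition (HB₁)
at λ₀ = 0 regardless of coupling, and a second Hopf point (HB₂) at
λ₀ = d₁ + d₂ = 0.31.  At λ₀ = −0.5 the noise alone sustains
oscillations; with δ₁ = 0.05 on the strongly-coupled cell and δ₂ = 0.95
on the weakly-coupled one, the pair spends most of its time near
in-phase locking (|Δφ| ≈ 0.7 rad, R ≈ 0.66 across 20 trials).

Sweep drivers live in `motifsync.experiments` (`snr_sweep`,
`noise_sweep`, `noise_heatmap`, `optimal_noise`, `lambda_scan`,
`coupling_scan`), and a thin CLI wraps them:

```
motifsync noise-sweep --tier standard --seed 1 --out results/sweep
motifsync optimal-noise --config my_run.yaml --out results/opt
```

Each command writes tidy CSV tables plus a JSON manifest with the full
configuration, seed and per-file SHA-256 checksums.

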