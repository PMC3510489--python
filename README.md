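# helimodal

Statistical detection of binormality and bimodality in B-DNA
base-pair-step helical parameters, and elastic models that account for it.

## The problem

Mesoscopic models of DNA flexibility describe each dinucleotide step by six
inter-base-pair helical parameters — shift, slide, rise (Å) and tilt, roll,
twist (degrees) — and assume each parameter fluctuates harmonically around a
single equilibrium value, so that its distribution is Gaussian and its
stiffness is kT times the inverse variance. Large MD ensembles and curated
X-ray datasets show that this picture breaks down for some steps: twist at
CpG steps, for example, populates a second low-twist state near 25°, and
slide at ApG/CpC steps has a minor mode near −1.5 Å. This package provides
the statistical machinery to decide, per (step type, parameter, dataset
origin) ensemble, whether one Gaussian is enough — and when it is not, what
to do about it.

## What it computes

For an ensemble of values *x* the package fits

- **M1**, a single Gaussian N(μ, σ²), k = 2 free parameters, and
- **M2**, a binormal (two-component Gaussian mixture)
  g(x) = p·N(μ₁, σ₁²) + (1−p)·N(μ₂, σ₂²), k = 5,

by maximum likelihood (closed form for M1, expectation–maximization with
deterministic seeded restarts for M2), compares them with the Bayesian
Information Criterion BIC = −2 ln L + k ln n, and converts the BIC gap into
a Bayes-factor posterior p(M2|data) = F/(1+F) with F = exp((BIC₁−BIC₂)/2).
Evidence labels follow fixed thresholds: **M2** if p(M2|data) > 0.95, **M1**
if < 0.05, **IE** (insufficient evidence) otherwise.

A binormal density need not have two peaks. The generalized de Helguero
criterion separates the cases: with variance ratio r = max(σ₁²,σ₂²)/min(σ₁²,σ₂²)
and separation factor

    S(r) = √(−2 + 3r + 3r² − 2r³ + 2(1 − r + r²)^{3/2}) / (√r (1 + √r)),

the mixture is unimodal for every mixture proportion iff
|μ₂ − μ₁| ≤ S(r)(σ₁ + σ₂) (label **U**), otherwise bimodal (**B**). For equal
variances this reduces to the classical 2σ bound. Cells are therefore
reported as M1/U, M2/U (binormal but effectively one-peaked: weighted
moments and a harmonic model still apply), M2/B (genuine polymorphism) or IE.

For bimodal parameters the harmonic energy E = ½ΔXᵀKΔX is replaced by a
two-well model, E_i = ½ΔX_iᵀK_iΔX_i and E_j = ½ΔX_jᵀK_jΔX_j + ΔG_ij, with
the smooth surface taken as the lower eigenvalue of [[E_i, ε], [ε, E_j]] so
that optimization and dynamics see continuous gradients. Per-state stiffness
matrices come from responsibility-based snapshot splitting; ΔG_ij from
Boltzmann inversion of the mixture weights. A kinetics module assigns time
series frames to states and measures transition frequencies, residence
times, occupancies and windowed convergence.

## Worked example

```python
from helimodal import (BinormalSpec, sample_binormal, evidence, is_bimodal,
                       TelegraphSpec, sample_telegraph, fit_binormal,
                       assign_states, transition_stats)

# a CpG-twist-like ensemble: minor low-twist state at 25 deg, major at 35 deg
spec = BinormalSpec(mu1=25.0, sigma1=3.0, mu2=35.0, sigma2=4.0, p_r=0.25)
ens = sample_binormal(spec, n=50_000, seed=42)

ev = evidence(ens, seed=42)
print(f"BIC1={ev.bic1:.1f}  BIC2={ev.bic2:.1f}  "
      f"p(M2|data)={ev.p_m2:.4f}  label={ev.label}")
m = ev.fit2.model
mod = is_bimodal(m)
print(f"separation={mod.separation:.2f}  threshold={mod.threshold:.2f}  "
      f"modality={mod.label}")
```

prints

```
BIC1=317101.6  BIC2=313457.9  p(M2|data)=1.0000  label=M2
separation=10.05  threshold=6.73  modality=B
```

The BIC gap of ~3600 overwhelmingly favours the two-component model
(p(M2|data) rounds to 1), the fitted components land on the generating
modes (24.87±2.98 with weight 0.243, and 34.92±4.06), and their separation
10.05° exceeds the Helguero threshold 6.73°, so the cell is labelled M2/B —
a genuinely polymorphic twist distribution.

Kinetics on a synthetic switching trajectory (5/ns each way, 1 ps frames):

```python
tel = TelegraphSpec(rate_12=5.0, rate_21=5.0,
                    emission=BinormalSpec(25, 1.25, 35, 1.25, 0.5), dt=0.001)
series, truth = sample_telegraph(tel, duration_ns=200.0, seed=42)
fit = fit_binormal(series, seed=42)
st = transition_stats(assign_states(series, fit))
print(f"transitions/ns={st.rate_per_ns:.2f}  "
      f"residence=({st.mean_residence[0]:.3f}, {st.mean_residence[1]:.3f}) ns")
```

```
transitions/ns=5.28  residence=(0.193, 0.185) ns
```

i.e. the estimator chain recovers the generating kinetics (expected
residence 1/k = 0.2 ns) from the observed series alone.

A `helimodal` console script exposes the same pipeline
(`simulate`, `classify`, `modality`, `energy`, `dynamics`, `report`); see
`helimodal --help`.

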