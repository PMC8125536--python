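# oecspin

Spin-Hamiltonian CW-EPR simulation and difference-spectrum analysis for the
high-spin manganese signals of the photosystem II oxygen-evolving complex
(OEC).

## The problem

The Mn₄CaO₅ cluster of photosystem II cycles through storage states S₀–S₄
while oxidizing water. Trapped at low temperature, the S₂ state shows two
characteristic X-band CW-EPR signals: the ⁵⁵Mn hyperfine-structured
**multiline** signal of the total-spin S_T = 1/2 ground state (>20 lines
spaced ≈90 G around g ≈ 2), and the broad **g4.1** signal generated by
≈140 K near-infrared illumination, attributed to a higher-spin form of the
cluster. Deciding whether the g4.1 species is a near-rhombic S = 5/2 center
or a near-axial S = 3/2 center requires quantitative powder simulation of
the candidate spin Hamiltonians and careful difference-spectrum
decomposition of the illumination experiments. This package implements that
entire analysis chain for spectroscopists working on the OEC (or any
high-spin metalloprotein center with a g ≈ 4 signal).

## The model

For an effective electron spin S with zero-field splitting (ZFS) and
coupled ⁵⁵Mn nuclei (I = 5/2),

    H = β B·g·Ŝ + D[Ŝz² − S(S+1)/3] + E[Ŝx² − Ŝy²]
        + (a/6)[Ŝx⁴ + Ŝy⁴ + Ŝz⁴ − c(S)] + Σᵢ Ŝ·Aᵢ·Îᵢ ,

assembled in cm⁻¹ (fields in Gauss, hyperfine in MHz). Zero field leaves
(2S+1)/2 Kramers doublets; within each doublet the Zeeman splitting defines
an effective g (g_eff = lim_{B→0} ΔE/βB) that can far exceed the intrinsic
g ≈ 2. The textbook limits drop out of the matrix diagonalization: a fully
rhombic S = 5/2 center (E/D = 1/3) has an isotropic middle doublet at
g_eff = 30/7 ≈ 4.286 — the origin of ubiquitous "g 4.3" signals — while the
outer doublets give the anisotropic set {9.678, 0.857, 0.607}; an axial
S = 3/2 center gives g_eff = (4, 4, 2) for its ±1/2 doublet.

Powder spectra are computed by full matrix diagonalization on a
deterministic octant orientation grid: resonance fields are found by
bracketing ΔE = hν along a field ladder, weighted by the transition moment
for B₁ ⊥ B, the Boltzmann population difference and the 1/|d(ΔE)/dB|
frequency-to-field factor, then convolved with a Gaussian line and
differentiated. Coupled nuclei are handled either exactly (e.g. the
216-dimensional product space of S = 5/2 with two ⁵⁵Mn) or by a first-order
per-level treatment with Wigner-rotation branching between nuclear sublevel
ladders, used inside fitting loops and cross-checked against the exact
route in the test suite.

The multiline model is first order: spin-projected couplings
Aᵢ = ρᵢ·Aᵢ^ion (Σρᵢ = 1), a 6⁴-line stick spectrum, and the width identity
ΔB_total = 5·Σ|Aᵢ_eff|. The decomposition operators — light-minus-annealed
differences, tyrosine-radical removal, least-squares scaled subtraction and
double integration — recover the fraction of multiline centers that
interconvert into the g4.1 species under NIR illumination, and bounded
trust-region fits with multistart (both signs of D) rank candidate spin
states against the isolated g4.1 spectrum.

Because no experimental spectra are deposited for this system, a
synthetic-data generator emulates the three-spectrum illumination
experiment (annealed S₁ background, 240 K multiline, 140 K NIR) with known
ground truth, so every estimator is validated by recovery tests.

## Worked example

```python
import numpy as np
from oecspin import (SpinSystem, SynthConfig, doublet_effective_g,
                     difference_spectrum, estimate_conversion_fraction,
                     generate_experiment, powder_spectrum,
                     locate_signal_center, effective_g)

# closed-form limits of a fully rhombic S = 5/2 center
sys = SpinSystem(S=2.5, D=2.0, E=2.0 / 3.0, g_principal=(2.0, 2.0, 2.0))
print("middle doublet g_eff:", [f"{g:.3f}" for g in doublet_effective_g(sys, 1)])
print("lowest doublet g_eff:", [f"{g:.3f}" for g in doublet_effective_g(sys, 0)])

# powder spectrum of that center and its feature position
axis = np.linspace(400.0, 2900.0, 2500)
spec = powder_spectrum(sys, 9.369115, axis, n_orientations=600, linewidth_G=50.0)
b0 = locate_signal_center(spec, (1200.0, 1900.0))
print(f"powder line center: {b0:.1f} G  (g_eff = {effective_g(b0, 9.369115):.3f})")

# synthetic illumination experiment and interconversion fraction
exp = generate_experiment(SynthConfig(seed=1))
d240 = difference_spectrum(exp.illuminated_240K, exp.annealed)
d140 = difference_spectrum(exp.illuminated_140K_NIR, exp.annealed)
frac, resid = estimate_conversion_fraction(d240, d140)
print(f"multiline fraction lost on NIR illumination: {frac:.3f} (rms misfit {resid:.4f})")
```

prints

```
middle doublet g_eff: ['4.286', '4.286', '4.286']
lowest doublet g_eff: ['0.857', '0.607', '9.678']
powder line center: 1562.5 G  (g_eff = 4.284)
multiline fraction lost on NIR illumination: 0.351 (rms misfit 0.0121)
```

The middle doublet is isotropic at g = 4.286 and the powder simulation of
the same center collapses onto a single near-symmetric derivative line
whose zero crossing reads back that g value — the reason a rhombic S = 5/2
species produces a prominent, easily identified g ≈ 4.3 signal. The
generator's default experiment interconverts 35% of the multiline centers;
the least-squares scaled-subtraction estimator recovers 0.351 from noisy
synthetic spectra.

A command-line interface mirrors the library
(`oecspin simulate | multiline | diff | fraction | fit | synth | pipeline`);
`oecspin pipeline --seed 1 --outdir out/` runs the full decomposition on a
synthetic experiment and writes every intermediate spectrum plus a JSON
report.

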