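# Methods

## Spin Hamiltonian and conventions

All Hamiltonians are assembled in cm⁻¹ in the |S, m_S⟩ ⊗ Πᵢ|Iᵢ, m_Iᵢ⟩
product basis:

    H = β B·g·Ŝ + D[Ŝz² − S(S+1)/3] + E[Ŝx² − Ŝy²]
        + (a/6)[Ŝx⁴ + Ŝy⁴ + Ŝz⁴ − c(S)] + Σᵢ Ŝ·Aᵢ·Îᵢ

* Electronic spins S ∈ {1/2, 3/2, 5/2}; other values are rejected rather
  than silently accepted, since the analysis is built around Kramers
  systems.
* Fields are in Gauss, hyperfine couplings in MHz, temperatures in K.
  Conversion constants come from CODATA via `scipy.constants`
  (1 G·g ↔ 4.66864×10⁻⁵ cm⁻¹, 1 MHz ↔ 3.33564×10⁻⁵ cm⁻¹).
* The fine-structure terms are traceless by construction; the quartic
  offset c(S) = S(S+1)[3S(S+1)−1]/5 generalizes the usual S = 5/2 constant
  (707/16) to any spin.
* (D, E) pairs are canonicalized on construction to the standard frame
  0 ≤ E/D ≤ 1/3 by relabelling principal axes; the same permutation is
  applied to the g and A principal values, so non-canonical input describes
  identical physics. Both signs of D are accepted everywhere.
* Hyperfine tensors are collinear with the electronic frame (no Euler
  angles are defined for this system). Nuclear quadrupole couplings are
  rejected with an explicit error: no quadrupole magnitudes are defined for
  the cluster and inventing them would be worse than refusing.
* The nuclear Zeeman term is omitted; at X-band it is two orders of
  magnitude below the 140 G linewidths modelled here.
* Boltzmann weights use the temperature stored on the spin system (default
  8 K, the acquisition temperature of the g4.1 simulations; the synthetic
  experiment uses 6 K as in the multiline acquisitions).

## Powder simulation

For each orientation of a deterministic "igloo" grid (rings of constant
polar angle, ring populations ∝ sin θ, solid-angle weights) restricted to
one octant — valid because all tensors are collinear and orthorhombic — the
eigenvalues of H(B) are computed on a uniform field ladder (default 64
nodes across the sweep, batched LAPACK diagonalizations). Every ordered
level pair whose ΔE − hν changes sign between ladder nodes contributes a
resonance; the root is located by linear interpolation within the bracket
(sub-Gauss accuracy against the 140 G lines; the public
`resonance_search` refines instead by bisection to 10⁻³ G and satisfies
|ΔE(B*) − hν| ≤ 10⁻⁶ hν). Amplitudes combine

* the transition moment |⟨j|B₁·g·Ŝ|i⟩|² averaged over two orthogonal
  microwave-field directions perpendicular to B,
* the Boltzmann population difference at the nearest ladder node, and
* the frequency-to-field factor 1/|d(ΔE)/dB| (slope from the bracket,
  floored at 10⁻¹² to survive level anticrossings, whose transition
  moments vanish there anyway).

Sticks are binned area-preservingly onto the output axis (padded by four
linewidths so lines just outside the window contribute wings), convolved
with a Gaussian parameterized by its peak-to-peak derivative width
(σ = width/2), and differentiated once. Modulation amplitude (15 G in the
emulated acquisitions) is ≪ the 140 G linewidth and is carried as metadata
only, not convolved in. Resonator transfer functions are omitted; spectra
are in arbitrary units.

## Hyperfine treatment: exact and first-order routes

With nuclei attached the Hamiltonian is diagonalized either

* **exactly** in the full product space (216-dimensional for S = 5/2 with
  two ⁵⁵Mn), eigenvalues batched over the ladder and eigenvectors computed
  only at crossing-adjacent nodes — the default for final simulations and
  for the headline g4.1 computation; or
* **perturbatively**: the electronic problem is solved exactly, then each
  electronic level n shifts by m·|hₙ| with hₙ = A·⟨Ŝ⟩ₙ. Because the
  nuclear quantization axis follows hₙ and the axes of the two levels of a
  Kramers pair are nearly opposite, a transition branches over nuclear
  sublevels with rotation weights |d^I_{m'm}(θ)|² (θ the angle between h_i
  and h_j), reproducing the full 5(|h_i|+|h_j|) spread of the exact route.
  A naive common-axis fan underestimates the splitting by roughly half;
  the branching treatment agrees with the exact route to <5% RMS with
  feature extrema within 20 G (asserted in the test suite). This route is
  ~100× faster and is used inside fitting loops and the synthetic
  generator.

## Effective g extraction

Doublet effective g-values are measured as ΔE/(βB) at a 1 G probe field
along each principal axis — deep in the linear regime for any ZFS ≥ 0.1
cm⁻¹ (the leading correction is O(B³) by time-reversal symmetry). A
warning is issued when |D| < 5 hν, where the isolated-doublet picture
degrades. Signal positions on simulated spectra are read either at the
zero crossing of the dominant derivative feature (`locate_signal_center`,
refined by a straight-line fit through the locally linear stretch between
the extrema, which suppresses point noise) or at a chosen derivative
extremum (`locate_dominant_extremum`) for asymmetric patterns.

## First-order multiline model

The S_T = 1/2 multiline pattern is modelled as the 6⁴ stick spectrum of
four spin-projected couplings Aᵢ = ρᵢAᵢ^ion at B = B₀ − Σ mᵢΔBᵢ. The model
is deliberately first order — no second-order shifts, no anisotropy — with
the exact product-space route available for cross-checks. Projection sets
whose Σρᵢ deviates from 1 by more than 0.1 warn rather than fail, since
literature projections are approximate; the split of the two small
projections (only their sum ≈ 0.2 is constrained) defaults to equal halves.
"Resolved lines" are counted as extrema of the first-derivative
presentation, the form in which such patterns are displayed.

## Spectral decomposition

Differences are pointwise on a shared axis (`align_spectra` resamples onto
the intersection grid with linear interpolation when needed; frequency
mismatches above 0.01 GHz warn). The interconversion fraction is the
scalar least-squares solution of min_s ‖d₁₄₀ − s·d₂₄₀‖² over the multiline
window, reported as 1 − s with the RMS misfit; the default window is
2400–4400 G excluding 3250–3450 G (the g ≈ 2 radical region). Ordinary
least squares on the derivative spectra is used rather than double
integrals: it matches scaled-subtraction practice and is robust at 2500
points. Radical removal fits a narrow Gaussian-derivative line plus linear
baseline inside the radical window and subtracts only the line; an
interpolation mode (straight line across the window) is kept for parity
with common practice and documented to also remove overlapped multiline
intensity. Double integration subtracts the window-edge linear baseline
and integrates twice by the trapezoid rule; its window-stability holds for
compact features with signal-free edges, but not for full powder templates
whose 140 G wings and weak outlying transitions leave no quiet edges — a
property of the operator worth knowing before quoting areas.

## Fitting and model comparison

The objective is the RMS difference between simulated and target
first-derivative spectra over the fit window. Amplitude and a linear
baseline enter linearly and are profiled out exactly at each evaluation,
so the nonlinear search sees only shape parameters (subsets of gx, gy, gz,
D, E/D, linewidth, Aᵢ; box bounds, E/D constrained to [0, 1/3]).
Optimization is bounded trust-region least squares with multistart from
seeded perturbations of the template; when D is free, alternate starts
flip its sign, because +D and −D produce nearly identical powder spectra
at these temperatures — the sign is genuinely unidentifiable, so recovery
accuracy is assessed on |D| while E/D is fully identifiable (medians ≈0.03
cm⁻¹ and ≈0.002 respectively in the acceptance checks). Non-convergence
returns a flagged result rather than raising. Inside the loop the
simulation runs on a reduced grid (≈150–300 orientations, 48–64 ladder
nodes, first-order hyperfine); `compare_models` fits every candidate under
identical budgets and ranks by residual RMS.

## Synthetic experiments

`generate_experiment` emulates the three-spectrum illumination protocol on
a single 400–4650 G axis (≈1 G/point, spanning both observation windows):

    annealed      = baseline + radical + noise
    240 K light   = annealed components + multiline + noise
    140 K NIR     = annealed components + (1−f)·multiline + f·g4.1 + noise

with defaults f = 0.35; multiline couplings (255, 250, 247, 244) MHz at
g = 1.98 broadened by 20 G — illustrative values chosen to reproduce the
≈90 G dominant spacing and ≈1800 G first-order width, since no coupling
set is tabulated for the signal; the spin-5/2 g4.1 parameter set
(g 2.18/2.16/1.98, D 0.45 cm⁻¹, E/D 0.25, A 194.2/45.2 MHz, 140 G lines)
simulated over its 400–2900 G observation band and zero outside it (an
idealization that keeps the multiline window free of g4.1 intensity, as
the decomposition assumes); a Y_D-like radical at g = 2.0046, 8 G wide (a
convention, not a measured value); gentle polynomial baseline drift shared
by all three spectra; and i.i.d. Gaussian noise at 1% of the multiline
peak-to-peak amplitude, drawn independently per spectrum. All components
and noise realizations are stored as ground truth. What the generator does
**not** emulate: microwave power saturation, temperature-dependent
amplitude anomalies, cavity background, field offsets between runs, or a
radical whose amplitude differs between illuminations (it cancels exactly
in the synthetic differences) — so passing recovery tests demonstrate
estimator correctness under the stated noise model, not robustness to
every instrumental artifact of real spectra.

## Problem sizes

Production simulations default to 3000 orientations; tests and fitting
loops use 100–300, where the orientation-grid error is already well below
the 140 G lineshape scale (grid convergence is monotone from 200
orientations, asserted in the suite). The headline g4.1 computation in
`scripts/acceptance.py` uses the exact 216-dimensional route at 200
orientations on the 2500-point figure grid; recovery statistics use 100
synthetic experiments (fraction) and 20 noisy spectra (ZFS parameters),
with model discrimination over 2×20 noisy realizations.

## Known limitations

* Faithful matrix-diagonalization simulation of the published spin-5/2
  g4.1 parameter set places the dominant derivative feature's zero
  crossing near g_eff ≈ 4.3 (peak ≈1330 G, trough ≈1730 G at 9.369 GHz),
  not at the conventional g ≈ 4.10 position of the experimental signal.
  Two ingredients push it there: the intrinsic g-values (mean ≈2.17) scale
  every doublet effective g ≈8% above the values obtained with g = 2.00,
  and the 194.2/45.2 MHz couplings spread each doublet transition by
  ≈600 G, well beyond the experimental ≈350 G signal width. With intrinsic
  g = 2.00 and no hyperfine the crossing falls at g ≈ 4.04. The
  acceptance script reports the honestly computed value for the published
  set; users fitting real g4.1 data should treat that parameter set as a
  starting template, not as a validated description.
* Exchange-coupled multi-site Hamiltonians with explicit J couplings,
  integer-spin (non-Kramers) systems, pulsed-EPR observables and
  saturation/relaxation modelling are out of scope.
* The spin-3/2 candidate is a what-if comparison model for spin-state
  discrimination; no claim is made that its parameters fit any measured
  signal.
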