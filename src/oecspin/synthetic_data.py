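"""Synthetic illumination experiments with known ground truth.

No experimental spectra are deposited for this system, so every pipeline
stage is exercised against generated data whose statistical structure
matches what the analysis assumes: an annealed S₁ background (baseline
drift plus the narrow tyrosine-D radical line), a ≈240 K green-light
spectrum adding the S₂ multiline signal, and a ≈140 K NIR spectrum in
which a configurable fraction of multiline centers has interconverted to
the g4.1 species.  Additive white Gaussian noise is drawn independently
per spectrum, and every component is stored alongside the emitted spectra
so recovery tests can compare against exact truth.

The multiline template is the first-order stick spectrum of four ⁵⁵Mn
couplings (illustrative values chosen to reproduce the ≈90 G dominant
spacing and ≈1800 G width quoted for the signal); the g4.1 template is a
powder simulation of the spin-5/2 parameter set, band-limited to the field
window in which that signal is observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .cw_spectrum import (
    Spectrum, field_for_g, powder_spectrum, sticks_to_spectrum,
)
from .multiline import ml_stick_spectrum
from .spectral_ops import (
    DEFAULT_G41_WINDOW, DEFAULT_ML_WINDOW, DEFAULT_RADICAL_WINDOW, ExperimentSet,
)
from .spin_core import DomainError, Nucleus, SpinSystem, ValidationError

__all__ = [
    "SynthConfig", "generate_experiment", "generate_radical",
    "g41_spin52_system", "g41_spin32_system",
]


def g41_spin52_system(temperature_K: float = 8.0) -> SpinSystem:
    """The rhombic spin-5/2 parameter set of the g4.1 simulation
    (g 2.18/2.16/1.98, D 0.45 cm⁻¹, E/D 0.25, two ⁵⁵Mn nuclei at
    194.2 and 45.2 MHz)."""
    return SpinSystem(
        S=2.5, g_principal=(2.18, 2.16, 1.98), D=0.45, E=0.45 * 0.25,
        nuclei=(Nucleus(2.5, (194.2,) * 3), Nucleus(2.5, (45.2,) * 3)),
        temperature=temperature_K)


def g41_spin32_system(temperature_K: float = 8.0) -> SpinSystem:
    """The near-rhombic spin-3/2 alternative (D 0.3 cm⁻¹, E/D 0.3, same
    g-tensor and ⁵⁵Mn couplings) used for model comparison."""
    return SpinSystem(
        S=1.5, g_principal=(2.18, 2.16, 1.98), D=0.3, E=0.3 * 0.3,
        nuclei=(Nucleus(2.5, (194.2,) * 3), Nucleus(2.5, (45.2,) * 3)),
        temperature=temperature_K)


@dataclass
class SynthConfig:
    """Everything a synthetic illumination experiment needs.

    The defaults are the study conditions emulated throughout: a 0.35
    interconversion fraction, a multiline template with ≈90 G dominant
    spacing and ≈1800 G first-order width at g = 1.98, the spin-5/2 g4.1
    parameter set, a Y_D-like radical at g = 2.0046 (8 G wide), gentle
    polynomial baseline drift, and white noise at 1% of the multiline
    peak-to-peak amplitude.  The field grid spans both the multiline and
    g4.1 windows at ≈1 G per point.
    """

    conversion_fraction: float = 0.35
    ml_couplings_MHz: tuple[float, float, float, float] = (255.0, 250.0, 247.0, 244.0)
    ml_g_center: float = 1.98
    ml_linewidth_G: float = 20.0
    ml_amplitude: float = 1.0
    g41_system: SpinSystem = dc_field(default_factory=g41_spin52_system)
    g41_linewidth_G: float = 140.0
    g41_amplitude: float = 1.0
    g41_band_G: tuple[float, float] = (400.0, 2900.0)
    radical_g: float = 2.0046
    radical_width_G: float = 8.0
    radical_amplitude: float = 0.5
    baseline_coeffs: tuple[float, ...] = (0.0, 0.1, 0.05)
    noise_sd: float = 0.01
    grid: tuple[float, float, int] = (2525.0, 4250.0, 4251)
    frequency_GHz: float = 9.369115
    temperature_K: float = 6.0
    seed: int = 0
    sim_n_orientations: int = 300
    sim_hyperfine: str = "perturbative"
    sim_n_field_steps: int = 64

    def __post_init__(self):
        if not 0.0 <= self.conversion_fraction <= 1.0:
            raise DomainError("conversion_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        center, sweep, points = self.grid
        if points < 2 or sweep <= 0:
            raise ValidationError("grid needs a positive sweep and at least 2 points")

    def field_axis(self) -> np.ndarray:
        center, sweep, points = self.grid
        return np.linspace(center - sweep / 2.0, center + sweep / 2.0, int(points))


# ---------------------------------------------------------------------------
# Component templates
# ---------------------------------------------------------------------------

def generate_radical(g_pos: float, width_G: float, amplitude: float,
                     grid, frequency_GHz: float = 9.369115) -> Spectrum:
    """Gaussian first-derivative radical line centered at B = hν/(g β).

    ``grid`` is either a field-axis array or a (center_G, sweep_G, points)
    tuple; ``width_G`` is the peak-to-peak width of the derivative line.
    """
    if width_G <= 0:
        raise DomainError("width_G must be positive")
    if isinstance(grid, tuple):
        center, sweep, points = grid
        axis = np.linspace(center - sweep / 2.0, center + sweep / 2.0, int(points))
    else:
        axis = np.asarray(grid, dtype=float)
    b0 = field_for_g(g_pos, frequency_GHz)
    sigma = width_G / 2.0
    x = (axis - b0) / sigma
    intensity = -amplitude * x * np.exp(-(x ** 2) / 2.0)
    return Spectrum(axis, intensity, frequency_GHz,
                    metadata={"component": "radical", "g": g_pos})


def _peak_to_peak(y: np.ndarray) -> float:
    return float(y.max() - y.min())


def _ml_template(cfg: SynthConfig, axis: np.ndarray) -> np.ndarray:
    sticks = ml_stick_spectrum(cfg.ml_couplings_MHz, cfg.ml_g_center, cfg.frequency_GHz)
    spec = sticks_to_spectrum(sticks.field_G, sticks.amplitude, axis,
                              cfg.ml_linewidth_G, cfg.frequency_GHz)
    y = spec.intensity
    pp = _peak_to_peak(y)
    return y * (cfg.ml_amplitude / pp) if pp > 0 else y


_TEMPLATE_CACHE: dict = {}


def _g41_template(cfg: SynthConfig, axis: np.ndarray) -> np.ndarray:
    """Band-limited powder template of the g4.1 species on the full axis.

    The signal is simulated only over ``g41_band_G`` (the window in which
    the species is observed and decomposed); outside the band the template
    is zero, an idealization that keeps the multiline window free of g4.1
    intensity, as the decomposition assumes.
    """
    key = (tuple(np.round(axis[[0, -1]], 9)), axis.size,
           repr(cfg.g41_system.to_dict()),
           cfg.g41_linewidth_G, cfg.g41_band_G, cfg.frequency_GHz,
           cfg.sim_n_orientations, cfg.sim_hyperfine, cfg.sim_n_field_steps,
           cfg.g41_amplitude)
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key].copy()
    mask = (axis >= cfg.g41_band_G[0]) & (axis <= cfg.g41_band_G[1])
    sub_axis = axis[mask]
    spec = powder_spectrum(
        cfg.g41_system, cfg.frequency_GHz, sub_axis,
        n_orientations=cfg.sim_n_orientations,
        linewidth_G=cfg.g41_linewidth_G,
        hyperfine=cfg.sim_hyperfine,
        n_field_steps=cfg.sim_n_field_steps)
    y = np.zeros(axis.size)
    y[mask] = spec.intensity
    pp = _peak_to_peak(y)
    if pp > 0:
        y *= cfg.g41_amplitude / pp
    _TEMPLATE_CACHE[key] = y.copy()
    return y


# ---------------------------------------------------------------------------
# Experiment generation
# ---------------------------------------------------------------------------

def generate_experiment(cfg: SynthConfig) -> ExperimentSet:
    """Generate the three-spectrum set of one illumination experiment.

    annealed           = baseline + radical + noise
    illuminated_240K   = baseline + radical + multiline + noise
    illuminated_140K   = baseline + radical + (1−f)·multiline + f·g4.1 + noise

    with f = ``cfg.conversion_fraction`` and independent noise draws per
    spectrum, all seeded from ``cfg.seed``.  Ground-truth components (and the
    noise realizations themselves) are stored on ``ExperimentSet.truth`` so
    estimator tests can compare against exact values.
    """
    axis = cfg.field_axis()
    rng = np.random.default_rng(cfg.seed)
    xnorm = (axis - axis[0]) / (axis[-1] - axis[0]) * 2.0 - 1.0
    baseline = np.polynomial.polynomial.polyval(xnorm, cfg.baseline_coeffs)
    radical = generate_radical(cfg.radical_g, cfg.radical_width_G,
                               cfg.radical_amplitude, axis,
                               cfg.frequency_GHz).intensity
    ml = _ml_template(cfg, axis)
    g41 = _g41_template(cfg, axis)
    f = cfg.conversion_fraction
    noise = [rng.normal(0.0, cfg.noise_sd, axis.size) if cfg.noise_sd > 0
             else np.zeros(axis.size) for _ in range(3)]

    def spec(y, label):
        return Spectrum(axis.copy(), y, cfg.frequency_GHz,
                        temperature_K=cfg.temperature_K,
                        modulation_amplitude_G=15.0,
                        metadata={"label": label, "synthetic": True,
                                  "seed": int(cfg.seed)})

    dark = baseline + radical
    annealed = spec(dark + noise[0], "annealed")
    ill240 = spec(dark + ml + noise[1], "illuminated_240K")
    ill140 = spec(dark + (1.0 - f) * ml + f * g41 + noise[2], "illuminated_140K_NIR")
    truth = {
        "baseline": baseline, "radical": radical,
        "ml_template": ml, "g41_template": g41,
        "noise": noise, "fraction": f,
    }
    return ExperimentSet(
        annealed=annealed, illuminated_240K=ill240, illuminated_140K_NIR=ill140,
        windows={"ml": DEFAULT_ML_WINDOW, "g41": DEFAULT_G41_WINDOW,
                 "radical": DEFAULT_RADICAL_WINDOW},
        truth=truth)
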