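"""First-order model of the S₂-state multiline EPR signal.

The S₂ multiline signal arises from the exchange-coupled Mn₄ cluster in its
total-spin S_T = 1/2 ground state: the single effective electron spin sees
all four ⁵⁵Mn nuclei (I = 5/2), each through a spin-projected hyperfine
coupling A_i = ρ_i·A_i^ion, where the dimensionless projection coefficients
ρ_i sum to 1 over the cluster.  To first order the resulting spectrum is a
stick pattern of 6⁴ = 1296 lines at

    B(m₁..m₄) = B₀ − Σᵢ mᵢ·ΔBᵢ,      mᵢ ∈ {−5/2, …, +5/2},

with ΔBᵢ the field-equivalent of A_i at the center g, so the total spectral
extent is 5·Σ|ΔBᵢ| (2I = 5 per nucleus).  The full matrix-diagonalization
route in :mod:`oecspin.cw_spectrum` exists for cross-checks; this module is
the fast first-order algebra used for width/spacing reasoning and for the
synthetic multiline template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cw_spectrum import TransitionSet, field_for_g
from .spin_core import G_TO_CM, MHZ_TO_CM, DomainError

__all__ = [
    "ProjectionSet", "spin_projected_couplings", "ml_width_first_order",
    "mhz_to_gauss", "gauss_to_mhz", "ml_stick_spectrum",
]

_NUCLEAR_M = 2.5 - np.arange(6)  # m_I ladder for I = 5/2


@dataclass(frozen=True)
class ProjectionSet:
    """Spin-projection coefficients and intrinsic-ion hyperfine values.

    ``rho`` are the four dimensionless projections of the total spin onto
    each Mn ion; they should sum to ~1 for the whole cluster (a deviation
    beyond 0.1 only warns, since literature values are approximate).
    ``A_ion_MHz`` are the corresponding isolated-ion hyperfine magnitudes.
    """

    rho: tuple[float, float, float, float]
    A_ion_MHz: tuple[float, float, float, float]

    def __post_init__(self):
        rho = tuple(float(x) for x in self.rho)
        a = tuple(float(x) for x in self.A_ion_MHz)
        if len(rho) != 4 or len(a) != 4:
            raise DomainError("ProjectionSet needs exactly four rho and four A_ion values")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "A_ion_MHz", a)
        if abs(sum(rho) - 1.0) > 0.1:
            warnings.warn(
                f"projection coefficients sum to {sum(rho):.3f}, expected ~1 "
                "for the whole Mn cluster", stacklevel=2)


def spin_projected_couplings(p: ProjectionSet) -> np.ndarray:
    """Effective cluster couplings A_i = ρ_i·A_i^ion (MHz, signs retained)."""
    return np.asarray(p.rho) * np.asarray(p.A_ion_MHz)


def ml_width_first_order(a_eff) -> float:
    """First-order multiline width 5·Σ|A_i_eff| (same unit as the input).

    Each I = 5/2 nucleus spreads the pattern by 2I = 5 times its coupling;
    couplings are angularly-averaged effective magnitudes, so any unit
    (MHz or Gauss) passes through unchanged.
    """
    a = np.asarray(a_eff, dtype=float)
    if a.shape != (4,):
        raise DomainError("expected exactly four effective couplings")
    return float(5.0 * np.sum(np.abs(a)))


def mhz_to_gauss(value_MHz: float, g: float) -> float:
    """Convert a splitting in MHz to its field equivalent ΔB = hν/(gβ) in Gauss."""
    if g <= 0:
        raise DomainError("g must be positive")
    return value_MHz * MHZ_TO_CM / (g * G_TO_CM)


def gauss_to_mhz(value_G: float, g: float) -> float:
    """Inverse of :func:`mhz_to_gauss`."""
    if g <= 0:
        raise DomainError("g must be positive")
    return value_G * g * G_TO_CM / MHZ_TO_CM


def ml_stick_spectrum(a_eff_MHz, g_center: float, frequency_GHz: float,
                      merge_tol_G: float = 1e-9) -> TransitionSet:
    """First-order stick spectrum of four I = 5/2 hyperfine couplings.

    Enumerates all 6⁴ nuclear projection combinations around the center field
    B₀ = hν/(g β); sticks at coincident fields (within ``merge_tol_G``) are
    merged with their multiplicities accumulated, and the total intensity is
    the counting measure 6⁴.
    """
    a = np.asarray(a_eff_MHz, dtype=float)
    if a.shape != (4,):
        raise DomainError("expected exactly four effective couplings")
    if not np.all(np.isfinite(a)):
        raise DomainError("couplings must be finite")
    b0 = field_for_g(g_center, frequency_GHz)
    db = np.array([mhz_to_gauss(x, g_center) for x in a])
    grids = np.meshgrid(*([_NUCLEAR_M] * 4), indexing="ij")
    positions = b0 - sum(m * d for m, d in zip(grids, db)).ravel()
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    # merge coincident sticks
    uniq_pos, uniq_amp = [], []
    for p in positions:
        if uniq_pos and p - uniq_pos[-1] <= merge_tol_G:
            uniq_amp[-1] += 1.0
        else:
            uniq_pos.append(p)
            uniq_amp.append(1.0)
    fields = np.asarray(uniq_pos)
    amps = np.asarray(uniq_amp)
    return TransitionSet(orientation=None, field_G=fields, amplitude=amps,
                         lower=np.zeros(fields.size, int),
                         upper=np.zeros(fields.size, int))
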