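"""Electron-spin (and electron-nuclear) Hamiltonians for high-spin Mn centers.

This module owns every symbol of the spin Hamiltonian used throughout the
package: the electron Zeeman interaction, axial/rhombic zero-field splitting
(ZFS) ``D`` and ``E``, the cubic fine-structure term ``a``, and isotropic or
anisotropic ``⁵⁵Mn`` hyperfine couplings.  Everything downstream (powder
simulation, effective-g extraction, fitting) builds its matrices here.

Units
-----
Hamiltonians are assembled in cm⁻¹.  Magnetic fields are given in Gauss,
hyperfine couplings in MHz; the conversion constants below are derived from
CODATA values via :mod:`scipy.constants`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import constants as _const

__all__ = [
    "G_TO_CM", "MHZ_TO_CM", "K_TO_CM", "GHZ_TO_CM",
    "DomainError", "UnsupportedFeatureError", "ValidationError",
    "Nucleus", "SpinSystem", "Eigensystem",
    "spin_operators", "canonicalize_zfs",
    "build_hamiltonian", "eigensystem", "zero_field_levels",
]

# ---------------------------------------------------------------------------
# Constants (CODATA via scipy)
# ---------------------------------------------------------------------------

_MU_B = _const.physical_constants["Bohr magneton"][0]  # J/T
_H = _const.h
_C_CM = _const.c * 100.0  # speed of light in cm/s

#: Zeeman energy in cm⁻¹ of one Bohr magneton per Gauss per unit g.
G_TO_CM = _MU_B * 1e-4 / (_H * _C_CM)
#: 1 MHz expressed in cm⁻¹.
MHZ_TO_CM = 1e6 / _C_CM
#: k_B·(1 K) expressed in cm⁻¹ (Boltzmann weights).
K_TO_CM = _const.k / (_H * _C_CM)
#: 1 GHz expressed in cm⁻¹ (microwave quantum hν).
GHZ_TO_CM = 1e9 / _C_CM

_ALLOWED_S = (0.5, 1.5, 2.5)


class DomainError(ValueError):
    """A physically meaningless argument (wrong spin, negative field, ...)."""


class UnsupportedFeatureError(ValueError):
    """A requested interaction this implementation deliberately rejects."""


class ValidationError(ValueError):
    """An input violating a structural contract (non-Hermitian, bad axis...)."""


# ---------------------------------------------------------------------------
# Spin operators
# ---------------------------------------------------------------------------

def spin_operators(s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the (Sx, Sy, Sz) matrices for spin quantum number ``s``.

    Basis states are |s, m> ordered m = s, s-1, ..., -s.  Matrices are
    complex with Sx, Sz real and Sy purely imaginary.
    """
    n = int(round(2 * s + 1))
    if abs(2 * s - round(2 * s)) > 1e-12 or n < 1:
        raise DomainError(f"spin quantum number must be a multiple of 1/2, got {s}")
    m = s - np.arange(n)
    sz = np.diag(m).astype(complex)
    raise_elem = np.zeros((n, n))
    for i in range(1, n):
        raise_elem[i - 1, i] = np.sqrt(s * (s + 1) - m[i] * (m[i] + 1))
    sx = (raise_elem + raise_elem.T) / 2.0 + 0j
    sy = (raise_elem - raise_elem.T) / 2j
    return sx, sy, sz


def canonicalize_zfs(D: float, E: float) -> tuple[float, float, tuple[int, int, int]]:
    """Reorder principal ZFS axes so that ``0 <= E/D <= 1/3``.

    Any (D, E) pair describes the same traceless ZFS tensor up to axis
    relabelling; the conventional frame puts the largest principal value on
    z and makes E carry the sign of D.  Returns the canonical (D, E) and the
    permutation mapping old axis indices (x, y, z) to the new frame, which
    must also be applied to the g and hyperfine principal values.
    """
    if D == 0.0 and E == 0.0:
        return 0.0, 0.0, (0, 1, 2)
    v = np.array([-D / 3.0 + E, -D / 3.0 - E, 2.0 * D / 3.0])
    iz = int(np.argmax(np.abs(v)))
    rest = [i for i in range(3) if i != iz]
    d_new = 1.5 * v[iz]
    # pick x/y ordering so E' has the sign of D'
    e_try = (v[rest[0]] - v[rest[1]]) / 2.0
    if e_try * d_new < 0:
        rest = rest[::-1]
        e_try = -e_try
    perm = (rest[0], rest[1], iz)
    return float(d_new), float(e_try), perm


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Nucleus:
    """A magnetic nucleus hyperfine-coupled to the electron spin.

    Parameters
    ----------
    I : nuclear spin quantum number (5/2 for ⁵⁵Mn).
    A_principal : three principal hyperfine values in MHz (collinear with
        the electronic frame; a scalar is broadcast to an isotropic tensor).
    quadrupole_P : nuclear quadrupole tensor magnitude in MHz.  Must be zero:
        no quadrupole parameters are defined for this system, and silently
        guessing magnitudes would be worse than rejecting them.
    """

    I: float
    A_principal: tuple[float, float, float]
    quadrupole_P: float = 0.0

    def __post_init__(self):
        if abs(2 * self.I - round(2 * self.I)) > 1e-12 or self.I <= 0:
            raise DomainError(f"nuclear spin must be a positive half-integer, got {self.I}")
        a = np.atleast_1d(np.asarray(self.A_principal, dtype=float))
        if a.size == 1:
            a = np.repeat(a, 3)
        if a.shape != (3,):
            raise DomainError("A_principal must be a scalar or three principal values")
        object.__setattr__(self, "A_principal", tuple(float(x) for x in a))
        if self.quadrupole_P != 0.0:
            raise UnsupportedFeatureError(
                "nuclear quadrupole coupling is not supported (no parameters are "
                "defined for this system); quadrupole_P must be 0")

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.I + 1))


@dataclass(frozen=True)
class SpinSystem:
    """An effective electron spin with ZFS, g-tensor and coupled nuclei.

    ``D``/``E`` are canonicalized on construction (axes reordered so that
    0 <= E/D <= 1/3); the same permutation is applied to ``g_principal`` and
    to every nucleus' hyperfine principal values, so the physical system is
    unchanged.
    """

    S: float
    g_principal: tuple[float, float, float] = (2.0, 2.0, 2.0)
    D: float = 0.0                      # axial ZFS, cm-1
    E: float = 0.0                      # rhombic ZFS, cm-1
    a_cubic: float = 0.0                # cubic fine-structure parameter, cm-1
    nuclei: tuple[Nucleus, ...] = ()
    temperature: float = 8.0            # K, for Boltzmann weights
    axis_permutation: tuple[int, int, int] = field(default=(0, 1, 2), compare=False)

    def __post_init__(self):
        if not any(abs(self.S - s) < 1e-12 for s in _ALLOWED_S):
            raise DomainError(f"electronic spin must be one of {_ALLOWED_S}, got {self.S}")
        g = np.atleast_1d(np.asarray(self.g_principal, dtype=float))
        if g.size == 1:
            g = np.repeat(g, 3)
        if g.shape != (3,) or np.any(g <= 0):
            raise DomainError("g_principal must be three positive values")
        nuclei = tuple(self.nuclei)
        d, e, perm = canonicalize_zfs(float(self.D), float(self.E))
        if perm != (0, 1, 2):
            g = g[list(perm)]
            nuclei = tuple(
                Nucleus(n.I, tuple(np.asarray(n.A_principal)[list(perm)]), n.quadrupole_P)
                for n in nuclei)
        object.__setattr__(self, "g_principal", tuple(float(x) for x in g))
        object.__setattr__(self, "D", d)
        object.__setattr__(self, "E", e)
        object.__setattr__(self, "nuclei", nuclei)
        object.__setattr__(self, "axis_permutation", perm)
        if self.temperature <= 0:
            raise DomainError("temperature must be positive (K)")

    @property
    def E_over_D(self) -> float:
        return self.E / self.D if self.D != 0.0 else 0.0

    @property
    def electronic_dim(self) -> int:
        return int(round(2 * self.S + 1))

    @property
    def dim(self) -> int:
        d = self.electronic_dim
        for n in self.nuclei:
            d *= n.multiplicity
        return d

    @property
    def n_doublets(self) -> int:
        return self.electronic_dim // 2

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spin": self.S,
            "g": list(self.g_principal),
            "D_cm1": self.D,
            "E_over_D": self.E_over_D,
            "a_cubic_cm1": self.a_cubic,
            "nuclei": [{"I": n.I, "A_MHz": list(n.A_principal)} for n in self.nuclei],
            "temperature_K": self.temperature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        D = float(d.get("D_cm1", 0.0))
        if "E_cm1" in d:
            E = float(d["E_cm1"])
        else:
            E = float(d.get("E_over_D", 0.0)) * D
        nuclei = tuple(
            Nucleus(float(n["I"]), tuple(np.atleast_1d(n["A_MHz"]).repeat(
                3 if np.ndim(n["A_MHz"]) == 0 else 1)[:3]))
            for n in d.get("nuclei", ()))
        return cls(
            S=float(d["spin"]),
            g_principal=tuple(np.atleast_1d(d.get("g", 2.0)).repeat(
                3 if np.ndim(d.get("g", 2.0)) == 0 else 1)[:3]),
            D=D, E=E,
            a_cubic=float(d.get("a_cubic_cm1", 0.0)),
            nuclei=nuclei,
            temperature=float(d.get("temperature_K", 8.0)),
        )


@dataclass
class Eigensystem:
    """Eigen-decomposition of a spin Hamiltonian at one applied field."""

    energies: np.ndarray          # ascending, cm-1
    states: np.ndarray            # columns are eigenvectors
    field: np.ndarray             # applied field vector, Gauss

    def doublet_gap(self, lower: int, upper: int) -> float:
        return float(self.energies[upper] - self.energies[lower])


# ---------------------------------------------------------------------------
# Hamiltonian construction
# ---------------------------------------------------------------------------

def _product_operators(sys: SpinSystem):
    """Electron and per-nucleus spin operators embedded in the product basis."""
    dims = [sys.electronic_dim] + [n.multiplicity for n in sys.nuclei]
    eyes = [np.eye(d) for d in dims]

    def embed(ops, pos):
        out = []
        for op in ops:
            m = np.array([[1.0 + 0j]])
            for k, d in enumerate(dims):
                m = np.kron(m, op if k == pos else eyes[k])
            out.append(m)
        return out

    s_ops = embed(spin_operators(sys.S), 0)
    n_ops = [embed(spin_operators(n.I), 1 + i) for i, n in enumerate(sys.nuclei)]
    return s_ops, n_ops


def electronic_hamiltonian_parts(sys: SpinSystem):
    """Zero-field part and per-axis Zeeman generators of the electronic-only
    Hamiltonian (no nuclei), in cm⁻¹.

    Returns ``(H0, [Gx, Gy, Gz])`` with the full Hamiltonian at field B (G)
    being ``H0 + G_TO_CM * sum_k B_k G_k``.
    """
    sx, sy, sz = spin_operators(sys.S)
    s = sys.S
    eye = np.eye(sys.electronic_dim)
    h0 = sys.D * (sz @ sz - s * (s + 1) / 3.0 * eye) + sys.E * (sx @ sx - sy @ sy)
    if sys.a_cubic != 0.0:
        quart = sx @ sx @ sx @ sx + sy @ sy @ sy @ sy + sz @ sz @ sz @ sz
        c = s * (s + 1) * (3 * s * (s + 1) - 1) / 5.0
        h0 = h0 + sys.a_cubic / 6.0 * (quart - c * eye)
    gx, gy, gz = sys.g_principal
    gens = [gx * sx, gy * sy, gz * sz]
    return (h0 + h0.conj().T) / 2.0, gens


def build_hamiltonian(sys: SpinSystem, field_gauss: Sequence[float]) -> np.ndarray:
    """Full spin Hamiltonian in cm⁻¹ in the electron-nuclear product basis.

    Terms: electron Zeeman (anisotropic g, field in Gauss), axial + rhombic
    ZFS, cubic fine structure, and hyperfine coupling S·A·I for each nucleus.
    The nuclear Zeeman term is omitted (negligible at X-band against the
    ~140 G linewidths modelled here) and nuclear quadrupole couplings are
    rejected at :class:`Nucleus` construction.
    """
    b = np.asarray(field_gauss, dtype=float)
    if b.shape != (3,) or not np.all(np.isfinite(b)):
        raise DomainError("field_gauss must be a finite 3-vector")
    s_ops, n_ops = _product_operators(sys)
    sx, sy, sz = s_ops
    s = sys.S
    eye = np.eye(sys.dim)
    h = sys.D * (sz @ sz - s * (s + 1) / 3.0 * eye) + sys.E * (sx @ sx - sy @ sy)
    if sys.a_cubic != 0.0:
        quart = sx @ sx @ sx @ sx + sy @ sy @ sy @ sy + sz @ sz @ sz @ sz
        c = s * (s + 1) * (3 * s * (s + 1) - 1) / 5.0
        h = h + sys.a_cubic / 6.0 * (quart - c * eye)
    for k, g in enumerate(sys.g_principal):
        if b[k] != 0.0:
            h = h + G_TO_CM * g * b[k] * s_ops[k]
    for i, nuc in enumerate(sys.nuclei):
        for k in range(3):
            a_cm = nuc.A_principal[k] * MHZ_TO_CM
            if a_cm != 0.0:
                h = h + a_cm * (s_ops[k] @ n_ops[i][k])
    return (h + h.conj().T) / 2.0


def eigensystem(h: np.ndarray, field_gauss: Sequence[float] | None = None) -> Eigensystem:
    """Diagonalize a Hermitian spin Hamiltonian.

    Raises :class:`ValidationError` if ``h`` is not Hermitian to 1e-10
    relative.  Energies are returned ascending with matching eigenvector
    columns.
    """
    h = np.asarray(h)
    scale = np.linalg.norm(h)
    if scale > 0 and np.linalg.norm(h - h.conj().T) > 1e-10 * scale:
        raise ValidationError("Hamiltonian is not Hermitian")
    energies, states = np.linalg.eigh(h)
    b = np.zeros(3) if field_gauss is None else np.asarray(field_gauss, dtype=float)
    return Eigensystem(energies=energies, states=states, field=b)


def zero_field_levels(sys: SpinSystem, include_nuclei: bool = False) -> list[tuple[float, int]]:
    """Zero-field level ladder as ``(energy above lowest, degeneracy)`` pairs.

    For half-integer spin every level is at least doubly degenerate (Kramers
    theorem); for S = 5/2 the ladder has exactly three doublets.  By default
    only the electronic fine structure is reported; hyperfine-coupled nuclei
    multiply degeneracies without adding structure at this scale.
    """
    if include_nuclei:
        h = build_hamiltonian(sys, (0.0, 0.0, 0.0))
    else:
        h0, _ = electronic_hamiltonian_parts(sys)
        h = h0
    e = np.linalg.eigvalsh(h)
    e = e - e[0]
    span = max(e[-1] - e[0], 1.0)
    tol = 1e-8 * span
    levels: list[tuple[float, int]] = []
    for val in e:
        if levels and abs(val - levels[-1][0]) <= tol:
            levels[-1] = (levels[-1][0], levels[-1][1] + 1)
        else:
            levels.append((float(val), 1))
    return levels
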