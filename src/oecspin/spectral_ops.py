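"""Difference-spectrum arithmetic for illumination experiments.

A low-temperature illumination experiment on photosystem II produces three
field-swept spectra: the dark, annealed S₁ background; a ≈240 K green-light
illuminated spectrum containing the S₂ multiline signal; and a ≈140 K
NIR-illuminated spectrum in which a fraction of multiline centers has
interconverted into the g4.1 species.  This module implements the
bookkeeping that turns those raw spectra into isolated signals:

* light-minus-background difference spectra,
* removal of the narrow tyrosine-D radical line near g ≈ 2,
* least-squares estimation of the multiline fraction lost on NIR
  illumination (the interconversion fraction),
* scaled subtraction isolating the pure NIR-generated g4.1 spectrum,
* double integration for signal quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.optimize import least_squares

from .cw_spectrum import Spectrum
from .spin_core import DomainError, ValidationError

__all__ = [
    "ExperimentSet", "IllConditionedError",
    "DEFAULT_ML_WINDOW", "DEFAULT_RADICAL_WINDOW", "DEFAULT_G41_WINDOW",
    "difference_spectrum", "scaled_subtract", "estimate_conversion_fraction",
    "remove_radical", "double_integral", "align_spectra",
]

#: Field window (G) used by default to compare multiline intensities.
DEFAULT_ML_WINDOW = (2400.0, 4400.0)
#: Region around g ≈ 2 excluded from multiline comparisons (radical lives here).
DEFAULT_RADICAL_WINDOW = (3250.0, 3450.0)
#: Field window (G) holding the g4.1 signal.
DEFAULT_G41_WINDOW = (600.0, 2700.0)


class IllConditionedError(ValueError):
    """The reference spectrum is (near) zero over the comparison window."""


@dataclass
class ExperimentSet:
    """The labelled spectrum collection one illumination experiment yields."""

    annealed: Spectrum
    illuminated_240K: Spectrum
    illuminated_140K_NIR: Spectrum
    windows: dict = dc_field(default_factory=lambda: {
        "ml": DEFAULT_ML_WINDOW,
        "g41": DEFAULT_G41_WINDOW,
        "radical": DEFAULT_RADICAL_WINDOW,
    })
    truth: dict | None = None   # ground-truth components when synthetic

    def spectra(self) -> list[Spectrum]:
        return [self.annealed, self.illuminated_240K, self.illuminated_140K_NIR]


def _check_compatible(a: Spectrum, b: Spectrum) -> None:
    if a.field_G.shape != b.field_G.shape or \
            not np.allclose(a.field_G, b.field_G, rtol=0, atol=1e-6 * a.step_G):
        raise ValidationError(
            "spectra are on different field axes; run align_spectra first")
    if abs(a.frequency_GHz - b.frequency_GHz) > 0.01:
        warnings.warn(
            f"microwave frequencies differ by {abs(a.frequency_GHz - b.frequency_GHz):.4f} "
            "GHz; field axes are not strictly comparable", stacklevel=3)


def difference_spectrum(light: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise light-minus-background difference on a shared field axis."""
    _check_compatible(light, background)
    out = light.with_intensity(light.intensity - background.intensity)
    out.metadata["difference_of"] = (
        light.metadata.get("label", "light"),
        background.metadata.get("label", "background"))
    return out


def scaled_subtract(a: Spectrum, b: Spectrum, fraction: float) -> Spectrum:
    """Return ``a − fraction·b`` (the scaled-subtraction decomposition step)."""
    _check_compatible(a, b)
    if not 0.0 <= fraction <= 1.5:
        warnings.warn(f"scaling fraction {fraction} outside the expected [0, 1.5] range",
                      stacklevel=2)
    out = a.with_intensity(a.intensity - fraction * b.intensity)
    out.metadata["scaled_subtraction"] = float(fraction)
    return out


def estimate_conversion_fraction(diff_240: Spectrum, diff_140NIR: Spectrum,
                                 window: tuple[float, float] = DEFAULT_ML_WINDOW,
                                 exclude: tuple[float, float] | None = DEFAULT_RADICAL_WINDOW,
                                 ) -> tuple[float, float]:
    """Fraction of multiline centers lost on ≈140 K NIR illumination.

    Solves the scalar least-squares problem  min_s ‖d₁₄₀ − s·d₂₄₀‖² over the
    multiline window (optionally excluding the g ≈ 2 radical region) and
    returns ``(1 − s, rms_residual)``: if the NIR difference retains a
    fraction s of the 240 K multiline, the complement 1 − s interconverted
    into the g4.1 species.
    """
    _check_compatible(diff_240, diff_140NIR)
    mask = diff_240.window_mask(window)
    if exclude is not None:
        mask &= ~diff_240.window_mask(exclude)
    ref = diff_240.intensity[mask]
    tgt = diff_140NIR.intensity[mask]
    norm = float(ref @ ref)
    scale = max(np.abs(diff_240.intensity).max(), np.abs(tgt).max() if tgt.size else 0.0)
    if ref.size < 2 or norm <= (1e-9 * scale) ** 2 * max(ref.size, 1):
        raise IllConditionedError(
            "reference difference spectrum is (near) zero over the window")
    s = float(ref @ tgt) / norm
    resid = tgt - s * ref
    return 1.0 - s, float(np.sqrt(np.mean(resid ** 2)))


def _gaussian_derivative(field, center, sigma, amp):
    x = (field - center) / sigma
    return -amp * x * np.exp(-(x ** 2) / 2.0)


def remove_radical(spec: Spectrum, radical_window: tuple[float, float] = DEFAULT_RADICAL_WINDOW,
                   mode: str = "fit") -> Spectrum:
    """Remove the narrow tyrosine-radical line from a difference spectrum.

    ``mode="fit"`` (default) fits a narrow Gaussian first-derivative line plus
    a linear baseline inside the window and subtracts only the fitted line,
    preserving broader structure underneath.  ``mode="interpolate"`` replaces
    the window by a straight line between its edges — this also removes any
    multiline intensity overlapping the window, which is the documented
    trade-off of that mode, not a defect.
    """
    lo, hi = radical_window
    if lo < spec.field_G[0] or hi > spec.field_G[-1]:
        raise ValidationError("radical window must lie inside the field axis")
    sweep = spec.field_G[-1] - spec.field_G[0]
    if (hi - lo) > 0.2 * sweep:
        warnings.warn("radical window spans more than 20% of the sweep; "
                      "likely misconfigured", stacklevel=2)
    mask = spec.window_mask(radical_window)
    y = spec.intensity.copy()
    if mode == "interpolate":
        idx = np.nonzero(mask)[0]
        i0, i1 = idx[0], idx[-1]
        y[mask] = np.interp(spec.field_G[mask],
                            [spec.field_G[i0], spec.field_G[i1]],
                            [y[i0], y[i1]])
    elif mode == "fit":
        f = spec.field_G[mask]
        seg = y[mask]
        span = hi - lo

        def resid(p):
            center, sigma, amp, b0, b1 = p
            model = _gaussian_derivative(f, center, sigma, amp) + b0 + b1 * (f - lo)
            return model - seg

        amp0 = (seg.max() - seg.min()) / 2.0 or 1.0
        sol = least_squares(
            resid, x0=[(lo + hi) / 2.0, span / 10.0, amp0, float(np.median(seg)), 0.0],
            bounds=([lo, span / 200.0, -np.inf, -np.inf, -np.inf],
                    [hi, span / 2.0, np.inf, np.inf, np.inf]))
        center, sigma, amp = sol.x[:3]
        y = y - _gaussian_derivative(spec.field_G, center, sigma, amp)
    else:
        raise DomainError("mode must be 'fit' or 'interpolate'")
    out = spec.with_intensity(y)
    out.metadata["radical_removed"] = {"window": tuple(radical_window), "mode": mode}
    return out


def double_integral(spec: Spectrum, window: tuple[float, float]) -> float:
    """Double integral (a.u.·G²) of a first-derivative signal over a window.

    The linear baseline through the window edges is removed first; the first
    integration recovers the absorption line, the second its area — the
    standard spin-count proxy for CW-EPR signals.
    """
    mask = spec.window_mask(window)
    f = spec.field_G[mask]
    y = spec.intensity[mask]
    if f.size < 3:
        raise ValidationError("window must contain at least three points")
    baseline = y[0] + (y[-1] - y[0]) * (f - f[0]) / (f[-1] - f[0])
    absorption = cumulative_trapezoid(y - baseline, f, initial=0.0)
    return float(trapezoid(absorption, f))


def align_spectra(spectra: list[Spectrum]) -> list[Spectrum]:
    """Resample spectra onto their common (intersection) uniform field axis.

    Uses the step of the first spectrum and linear interpolation; each output
    records the resampling in its metadata.  Disjoint field ranges are an
    error.
    """
    if not spectra:
        return []
    lo = max(s.field_G[0] for s in spectra)
    hi = min(s.field_G[-1] for s in spectra)
    if hi <= lo:
        raise ValidationError("spectra have disjoint field ranges")
    step = spectra[0].step_G
    axis = lo + step * np.arange(int(np.floor((hi - lo) / step + 1e-9)) + 1)
    out = []
    for s in spectra:
        same = (s.field_G.size == axis.size and
                np.allclose(s.field_G, axis, rtol=0, atol=1e-9 * step))
        intensity = s.intensity if same else np.interp(axis, s.field_G, s.intensity)
        ns = Spectrum(axis.copy(), np.asarray(intensity, float), s.frequency_GHz,
                      s.temperature_K, s.modulation_amplitude_G, dict(s.metadata))
        if not same:
            ns.metadata["resampled"] = True
        out.append(ns)
    return out
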