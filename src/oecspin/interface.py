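"""File formats, pipeline orchestration and command-line entry points.

Spectra travel as two-column ASCII (field in Gauss, intensity in arbitrary
units) with ``#``-prefixed header lines carrying the acquisition metadata;
the reader tolerates missing metadata with a warning and converts a mT
field axis when the header declares one.  :func:`run_pipeline` chains the
full decomposition — differences, radical removal, interconversion-fraction
estimate, scaled subtraction, spin-state fits — and writes every
intermediate with provenance headers plus a machine-readable JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import click
import numpy as np
import yaml

from .cw_spectrum import Spectrum, locate_dominant_extremum, powder_spectrum, \
    sticks_to_spectrum, effective_g
from .fitting import FitOptions, FitResult, compare_models
from .multiline import ProjectionSet, ml_stick_spectrum, spin_projected_couplings
from .spectral_ops import (
    DEFAULT_G41_WINDOW, DEFAULT_ML_WINDOW, DEFAULT_RADICAL_WINDOW,
    align_spectra, difference_spectrum, double_integral,
    estimate_conversion_fraction, remove_radical, scaled_subtract,
)
from .spin_core import SpinSystem
from .synthetic_data import (
    SynthConfig, g41_spin32_system, g41_spin52_system, generate_experiment,
)

__all__ = [
    "ParseError", "PipelineError", "PipelineConfig",
    "read_spectrum", "write_spectrum", "run_pipeline", "cli",
]

logger = logging.getLogger("oecspin")

_META_KEYS = ("frequency_GHz", "temperature_K", "modulation_amplitude_G")


class ParseError(ValueError):
    """A spectrum file line that could not be interpreted."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Spectrum I/O
# ---------------------------------------------------------------------------

def write_spectrum(spec: Spectrum, path) -> None:
    """Write a spectrum as two-column ASCII with ``#`` metadata headers."""
    path = Path(path)
    lines = ["# oecspin spectrum", "# units: G"]
    for key in _META_KEYS:
        val = getattr(spec, key)
        if val is not None:
            lines.append(f"# {key}: {val!r}")
    if spec.metadata:
        lines.append("# metadata: " + json.dumps(spec.metadata, sort_keys=True,
                                                 default=str))
    for b, y in zip(spec.field_G, spec.intensity):
        lines.append(f"{b:.17g}\t{y:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum:
    """Read a two-column ASCII spectrum; warns when metadata are missing."""
    path = Path(path)
    meta: dict = {}
    extra: dict = {}
    unit_scale = 1.0
    fields, intens = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key = key.strip()
                val = val.strip()
                if key == "units" and val.lower() == "mt":
                    unit_scale = 10.0
                elif key == "metadata":
                    try:
                        extra = json.loads(val)
                    except json.JSONDecodeError:
                        warnings.warn(f"{path.name}:{lineno}: unreadable metadata block")
                elif key in _META_KEYS:
                    try:
                        meta[key] = float(val)
                    except ValueError as exc:
                        raise ParseError(
                            f"{path.name}:{lineno}: bad value for {key}: {val!r}") from exc
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ParseError(f"{path.name}:{lineno}: expected two columns, got {raw!r}")
        try:
            fields.append(float(parts[0]))
            intens.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: non-numeric row {raw!r}") from exc
    if "frequency_GHz" not in meta:
        warnings.warn(f"{path.name}: no frequency_GHz header; assuming X-band 9.369115 GHz")
        meta["frequency_GHz"] = 9.369115
    return Spectrum(np.asarray(fields) * unit_scale, np.asarray(intens),
                    frequency_GHz=meta["frequency_GHz"],
                    temperature_K=meta.get("temperature_K"),
                    modulation_amplitude_G=meta.get("modulation_amplitude_G"),
                    metadata=extra)


def load_spin_system(path) -> SpinSystem:
    """Load a SpinSystem from a YAML/JSON config block."""
    with open(path) as fh:
        return SpinSystem.from_dict(yaml.safe_load(fh))


def _sha(spec: Spectrum) -> str:
    h = hashlib.sha256()
    h.update(spec.field_G.tobytes())
    h.update(spec.intensity.tobytes())
    return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Inputs and knobs of the end-to-end decomposition pipeline."""

    synth: SynthConfig | None = None
    annealed_path: str | None = None
    illuminated_240K_path: str | None = None
    illuminated_140K_path: str | None = None
    ml_window: tuple[float, float] = DEFAULT_ML_WINDOW
    g41_window: tuple[float, float] = DEFAULT_G41_WINDOW
    radical_window: tuple[float, float] = DEFAULT_RADICAL_WINDOW
    outdir: str = "pipeline_out"
    seed: int = 0
    fit_options: FitOptions = dc_field(
        default_factory=lambda: FitOptions(n_starts=2, n_orientations=150,
                                           n_field_steps=48, max_nfev=40))
    remove_radical_mode: str = "fit"


def _fit_result_dict(r: FitResult) -> dict:
    return {
        "label": r.label,
        "residual_rms": round(r.residual_rms, 12),
        "converged": bool(r.converged),
        "n_evaluations": int(r.n_evaluations),
        "bounds_hit": list(r.bounds_hit),
        "parameters": {k: round(float(v), 12) for k, v in sorted(r.parameters.items())},
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full decomposition and write intermediates plus a JSON report.

    Stages (each failure aborts with the stage name): acquire spectra
    (synthetic or from files), align, light-minus-annealed differences,
    radical removal, interconversion-fraction estimate, scaled subtraction of
    the non-interconverted multiline contribution to isolate the pure
    NIR-generated g4.1 spectrum, quantification, and spin-5/2 versus
    spin-3/2 candidate fits of that spectrum.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc
        logger.info("stage %s done", name)
        return result

    def acquire():
        if cfg.synth is not None:
            return generate_experiment(cfg.synth)
        paths = (cfg.annealed_path, cfg.illuminated_240K_path, cfg.illuminated_140K_path)
        if any(p is None for p in paths):
            raise FileNotFoundError("three spectrum paths (or a synth config) required")
        from .spectral_ops import ExperimentSet
        ann, i240, i140 = (read_spectrum(p) for p in paths)
        return ExperimentSet(annealed=ann, illuminated_240K=i240,
                             illuminated_140K_NIR=i140)

    exp = stage("acquire", acquire)
    ann, i240, i140 = stage("align", lambda: align_spectra(exp.spectra()))
    for s in (ann, i240, i140):
        logger.info("input %s sha=%s", s.metadata.get("label", "?"), _sha(s))

    diff240 = stage("difference_240K", lambda: difference_spectrum(i240, ann))
    diff140 = stage("difference_140K_NIR", lambda: difference_spectrum(i140, ann))
    diff240 = stage("radical_removal", lambda: remove_radical(
        diff240, cfg.radical_window, mode=cfg.remove_radical_mode))
    diff140 = remove_radical(diff140, cfg.radical_window, mode=cfg.remove_radical_mode)

    fraction, resid = stage("fraction_estimate", lambda: estimate_conversion_fraction(
        diff240, diff140, cfg.ml_window, cfg.radical_window))
    pure_g41 = stage("scaled_subtraction", lambda: scaled_subtract(
        diff140, diff240, 1.0 - fraction))

    ml_area = stage("quantification", lambda: double_integral(diff240, cfg.ml_window))
    g41_area = double_integral(pure_g41, cfg.g41_window)

    def fits():
        mask = pure_g41.window_mask(cfg.g41_window)
        windowed = Spectrum(pure_g41.field_G[mask], pure_g41.intensity[mask],
                            pure_g41.frequency_GHz, pure_g41.temperature_K,
                            pure_g41.modulation_amplitude_G)
        cands = [g41_spin52_system(), g41_spin32_system()]
        return compare_models(windowed, cands, labels=["S=5/2", "S=3/2"],
                              seed=cfg.seed, options=cfg.fit_options)

    ranked = stage("model_fits", fits)

    for name, s in (("ml_difference_240K", diff240),
                    ("g41_difference_140K_NIR", diff140),
                    ("pure_g41_NIR", pure_g41)):
        write_spectrum(s, outdir / f"{name}.tsv")

    report = {
        "fraction_lost": round(float(fraction), 12),
        "fraction_residual_rms": round(float(resid), 12),
        "ml_double_integral_240K": round(float(ml_area), 12),
        "g41_double_integral": round(float(g41_area), 12),
        "fits": [_fit_result_dict(r) for r in ranked],
        "ranking": [r.label for r in ranked],
        "seed": int(cfg.seed),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("--verbose", is_flag=True, help="Enable info-level logging.")
def cli(verbose):
    """CW-EPR spin-Hamiltonian simulation and difference-spectrum analysis."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING,
                        format="%(name)s %(levelname)s %(message)s")


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True),
              help="YAML spin-system config.")
@click.option("--freq", default=9.369115, show_default=True, help="Microwave GHz.")
@click.option("--center", default=1650.0, show_default=True, help="Center field (G).")
@click.option("--sweep", default=2500.0, show_default=True, help="Sweep width (G).")
@click.option("--points", default=2500, show_default=True)
@click.option("--orientations", default=3000, show_default=True)
@click.option("--linewidth", default=140.0, show_default=True, help="Peak-to-peak G.")
@click.option("--hyperfine", default="exact", type=click.Choice(["exact", "perturbative"]),
              show_default=True)
@click.option("--out", required=True, type=click.Path())
def simulate(config_path, freq, center, sweep, points, orientations, linewidth,
             hyperfine, out):
    """Powder-simulate a first-derivative spectrum."""
    sys = load_spin_system(config_path)
    axis = np.linspace(center - sweep / 2, center + sweep / 2, points)
    spec = powder_spectrum(sys, freq, axis, n_orientations=orientations,
                           linewidth_G=linewidth, hyperfine=hyperfine)
    write_spectrum(spec, out)
    b = locate_dominant_extremum(spec, (axis[0], axis[-1]))
    click.echo(f"dominant feature at {b:.1f} G (g_eff = {effective_g(b, freq):.3f})")


@cli.command()
@click.option("--rho", required=True, help="Four projection coefficients, comma separated.")
@click.option("--aion", required=True, help="Four intrinsic-ion couplings (MHz).")
@click.option("--g", "g_center", default=1.98, show_default=True)
@click.option("--freq", default=9.369115, show_default=True)
@click.option("--broaden", default=20.0, show_default=True, help="Gaussian pp width (G).")
@click.option("--center", default=3400.0, show_default=True)
@click.option("--sweep", default=2500.0, show_default=True)
@click.option("--points", default=2500, show_default=True)
@click.option("--out", required=True, type=click.Path())
def multiline(rho, aion, g_center, freq, broaden, center, sweep, points, out):
    """First-order multiline stick spectrum, broadened."""
    p = ProjectionSet(tuple(float(x) for x in rho.split(",")),
                      tuple(float(x) for x in aion.split(",")))
    a_eff = spin_projected_couplings(p)
    sticks = ml_stick_spectrum(a_eff, g_center, freq)
    axis = np.linspace(center - sweep / 2, center + sweep / 2, points)
    spec = sticks_to_spectrum(sticks.field_G, sticks.amplitude, axis, broaden, freq)
    write_spectrum(spec, out)
    click.echo(f"{len(sticks.field_G)} sticks over "
               f"{sticks.field_G[-1] - sticks.field_G[0]:.0f} G")


@cli.command()
@click.option("--light", required=True, type=click.Path(exists=True))
@click.option("--background", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def diff(light, background, out):
    """Light-minus-background difference spectrum."""
    specs = align_spectra([read_spectrum(light), read_spectrum(background)])
    write_spectrum(difference_spectrum(*specs), out)


def _parse_window(text):
    lo, _, hi = text.partition(":")
    return float(lo), float(hi)


@cli.command()
@click.option("--diff240", required=True, type=click.Path(exists=True))
@click.option("--diffnir", required=True, type=click.Path(exists=True))
@click.option("--window", default="2400:4400", show_default=True)
@click.option("--exclude", default="3250:3450", show_default=True)
def fraction(diff240, diffnir, window, exclude):
    """Multiline fraction lost on NIR illumination."""
    a, b = align_spectra([read_spectrum(diff240), read_spectrum(diffnir)])
    f, resid = estimate_conversion_fraction(a, b, _parse_window(window),
                                            _parse_window(exclude))
    click.echo(json.dumps({"fraction_lost": f, "residual_rms": resid}))


@cli.command()
@click.option("--spec", "spec_path", required=True, type=click.Path(exists=True))
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--free", default="D_cm1,E_over_D", show_default=True)
@click.option("--window", default="600:2700", show_default=True)
@click.option("--seed", default=7, show_default=True)
@click.option("--out", required=True, type=click.Path())
def fit(spec_path, model_path, free, window, seed, out):
    """Fit a spin-system model to a windowed spectrum; JSON output."""
    from .fitting import fit_spectrum
    spec = read_spectrum(spec_path)
    lo, hi = _parse_window(window)
    mask = spec.window_mask((lo, hi))
    windowed = Spectrum(spec.field_G[mask], spec.intensity[mask], spec.frequency_GHz)
    result = fit_spectrum(windowed, load_spin_system(model_path),
                          free_params=tuple(free.split(",")), seed=seed)
    Path(out).write_text(json.dumps(_fit_result_dict(result), indent=2, sort_keys=True))
    click.echo(f"rms={result.residual_rms:.4g} converged={result.converged}")


@cli.command()
@click.option("--seed", default=1, show_default=True)
@click.option("--outdir", required=True, type=click.Path())
def synth(seed, outdir):
    """Generate a synthetic three-spectrum illumination experiment."""
    cfg = SynthConfig(seed=seed)
    exp = generate_experiment(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, s in (("annealed", exp.annealed),
                    ("illuminated_240K", exp.illuminated_240K),
                    ("illuminated_140K_NIR", exp.illuminated_140K_NIR)):
        write_spectrum(s, out / f"{name}.tsv")
    truth = {"fraction": exp.truth["fraction"], "seed": seed,
             "noise_sd": cfg.noise_sd}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    click.echo(f"wrote 3 spectra + ground_truth.json to {out}")


@cli.command()
@click.option("--seed", default=1, show_default=True)
@click.option("--outdir", default="pipeline_out", show_default=True, type=click.Path())
@click.option("--annealed", type=click.Path(exists=True))
@click.option("--ill240", type=click.Path(exists=True))
@click.option("--ill140", type=click.Path(exists=True))
def pipeline(seed, outdir, annealed, ill240, ill140):
    """End-to-end decomposition (synthetic unless three paths are given)."""
    if annealed and ill240 and ill140:
        cfg = PipelineConfig(annealed_path=annealed, illuminated_240K_path=ill240,
                             illuminated_140K_path=ill140, outdir=outdir, seed=seed)
    else:
        cfg = PipelineConfig(synth=SynthConfig(seed=seed), outdir=outdir, seed=seed)
    report = run_pipeline(cfg)
    click.echo(json.dumps({"fraction_lost": report["fraction_lost"],
                           "ranking": report["ranking"]}))


if __name__ == "__main__":
    cli()
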