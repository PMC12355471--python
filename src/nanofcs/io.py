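"""Text-file formats, run configuration, and the end-to-end pipeline.

All scientific artifacts are delimited text with commented ``key = value``
headers: diff-able, language-neutral, and lossless at desk scale. Files use
SI units (seconds, lag in seconds); display units (us, kHz, nm, nM) appear
only in rendered report tables. Readers reject malformed input with the
offending line number; they never silently coerce.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import infer
from .correlate import CorrelationCurve, multitau_autocorrelate
from .fit import ConfocalCalibration, FitResult, fit_curve, pool_replicates
from .infer import PhysicalConditions, report_from_fit
from .simulate import (
    SimulationConfig,
    SpeciesSpec,
    peak_for_apparent_brightness,
    simulate_brownian_trace,
)
from .trace import PhotonTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_curve",
    "write_curve",
    "write_fit_report",
    "RunConfig",
    "run_pipeline",
]


def _write_header(fh, fields: dict[str, Any]) -> None:
    for key, value in fields.items():
        if isinstance(value, (dict, list)):
            value = json.dumps(value, sort_keys=True)
        fh.write(f"# {key} = {value}\n")


def _read_header(path: Path) -> tuple[dict[str, str], int]:
    """Parse leading '# key = value' lines; return (fields, first data line)."""
    fields: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                fields[key.strip()] = value.strip()
    return fields, n_header


def write_trace(trace: PhotonTrace, path: str | Path) -> None:
    """Write a photon trace as two-column text (time_s, counts)."""
    path = Path(path)
    header = {"bin_width_s": repr(trace.bin_width), "n_bins": len(trace.counts)}
    for key, value in trace.metadata.items():
        header[key] = value
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("# columns: time_s counts\n")
        t = trace.times
        for i, c in enumerate(trace.counts):
            fh.write(f"{t[i]:.9f}\t{int(c)}\n")


def read_trace(path: str | Path) -> PhotonTrace:
    """Read a photon trace written by :func:`write_trace`."""
    path = Path(path)
    fields, n_header = _read_header(path)
    if "bin_width_s" not in fields:
        raise ValueError(f"{path}: missing bin_width_s header")
    bin_width = float(fields["bin_width_s"])
    counts: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= n_header or line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                value = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count {parts[1]!r}") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative count {value}")
            counts.append(value)
    if not counts:
        raise ValueError(f"{path}: no data rows")
    metadata = {
        k: _maybe_json(v)
        for k, v in fields.items()
        if k not in ("bin_width_s", "n_bins")
    }
    return PhotonTrace(bin_width=bin_width, counts=np.array(counts), metadata=metadata)


def _maybe_json(text: str) -> Any:
    try:
        return json.loads(text)
    except (json.JSONDecodeError, TypeError):
        return text


def write_curve(curve: CorrelationCurve, path: str | Path) -> None:
    """Write a correlation curve as three-column text (lag_s, G, sd)."""
    path = Path(path)
    header: dict[str, Any] = {}
    if curve.mean_rate is not None:
        header["mean_rate_khz"] = repr(curve.mean_rate)
    for key, value in curve.provenance.items():
        header[key] = value
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("# columns: lag_s G sd\n")
        sd = curve.sd
        for i in range(len(curve)):
            line = f"{curve.lags[i]:.12e}\t{curve.values[i]:.12e}"
            if sd is not None:
                line += f"\t{sd[i]:.12e}"
            fh.write(line + "\n")


def read_curve(path: str | Path) -> CorrelationCurve:
    """Read a correlation curve written by :func:`write_curve`."""
    path = Path(path)
    fields, n_header = _read_header(path)
    lags: list[float] = []
    values: list[float] = []
    sds: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= n_header or line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            try:
                lags.append(float(parts[0]))
                values.append(float(parts[1]))
                if len(parts) == 3:
                    sds.append(float(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    if not lags:
        raise ValueError(f"{path}: no data rows")
    if sds and len(sds) != len(lags):
        raise ValueError(f"{path}: sd column present on only some rows")
    mean_rate = float(fields["mean_rate_khz"]) if "mean_rate_khz" in fields else None
    provenance = {
        k: _maybe_json(v) for k, v in fields.items() if k != "mean_rate_khz"
    }
    return CorrelationCurve(
        lags=np.array(lags),
        values=np.array(values),
        sd=np.array(sds) if sds else None,
        mean_rate=mean_rate,
        provenance=provenance,
    )


def write_fit_report(fit: FitResult, path: str | Path) -> None:
    """Write a fit result as a key = value document."""
    p = fit.params
    fields: dict[str, Any] = {
        "occupancy": repr(p.occupancy),
        "residence_time_s": repr(p.residence_time),
        "structure_parameter": repr(p.structure_parameter),
        "offset": repr(p.offset),
        "reduced_chi_square": repr(fit.reduced_chi_square),
        "n_replicates": fit.n_replicates,
        "under_replicated": fit.under_replicated,
    }
    if fit.mean_rate is not None:
        fields["mean_rate_khz"] = repr(fit.mean_rate)
    for key, value in fit.uncertainties.items():
        fields[f"sd_{key}"] = repr(value)
    for key, value in fit.provenance.items():
        fields[f"provenance_{key}"] = value
    with open(path, "w") as fh:
        _write_header(fh, fields)


@dataclass
class RunConfig:
    """Declarative description of one simulate -> report run.

    ``samples`` entries carry a label, gel mode, stage, a species list
    (apparent_brightness in kHz is translated to peak emission), per-sample
    simulation overrides, and a replicate count. One top-level seed feeds
    every replicate through fixed offsets.
    """

    out_dir: Path
    seed: int = 1
    calibration: ConfocalCalibration | None = None
    conditions: PhysicalConditions = field(default_factory=PhysicalConditions)
    ruler_brightness: float = infer.DEFAULT_RULER_BRIGHTNESS
    correlator_m: int = 16
    fix_s: bool = True
    fit_offset: bool = True
    max_fit_lag: float | None = 0.02
    samples: list[dict[str, Any]] = field(default_factory=list)
    simulation: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cal = None
        if "calibration" in doc:
            cal = ConfocalCalibration(
                beam_radius_xy=float(doc["calibration"]["beam_radius_xy"]),
                structure_parameter=float(doc["calibration"]["structure_parameter"]),
            )
        cond = PhysicalConditions(
            temperature=float(doc.get("conditions", {}).get("temperature", 298.15)),
            viscosity=float(doc.get("conditions", {}).get("viscosity", 0.89e-3)),
        )
        samples = doc.get("samples", [])
        if not samples:
            raise ValueError(f"{path}: config lists no samples")
        if cal is None and doc.get("require_sizes", True):
            raise ValueError(
                f"{path}: no calibration given; size and concentration columns "
                "would be unavailable (set require_sizes: false to allow)"
            )
        return cls(
            out_dir=Path(doc.get("out_dir", "nanofcs_run")),
            seed=int(doc.get("seed", 1)),
            calibration=cal,
            conditions=cond,
            ruler_brightness=float(
                doc.get("ruler_brightness", infer.DEFAULT_RULER_BRIGHTNESS)
            ),
            correlator_m=int(doc.get("correlator", {}).get("m", 16)),
            fix_s=bool(doc.get("fit", {}).get("fix_s", True)),
            fit_offset=bool(doc.get("fit", {}).get("fit_offset", True)),
            max_fit_lag=doc.get("fit", {}).get("max_lag", 0.1),
            samples=samples,
            simulation=doc.get("simulation", {}),
            raw=doc,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _species_from_dict(entry: dict[str, Any]) -> SpeciesSpec:
    if "apparent_brightness" in entry:
        peak = peak_for_apparent_brightness(float(entry["apparent_brightness"]))
    else:
        peak = float(entry["peak_brightness"])
    return SpeciesSpec(
        label=str(entry.get("label", "species")),
        diffusion_coefficient=float(entry["diffusion_coefficient"]),
        peak_brightness=peak,
        concentration=float(entry["concentration"]),
        oligomer_count=int(entry.get("oligomer_count", 1)),
    )


def run_pipeline(config: RunConfig) -> "Path":
    """Run simulate -> correlate -> fit -> report for every sample.

    Writes every intermediate artifact (traces, curves, fit reports) plus
    ``report.csv`` and ``run.log`` under ``config.out_dir``. Identical
    config and seed reproduce every output bitwise; artifacts embed the
    config hash and seed so any of them can be regenerated.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import numpy
    from . import __version__

    log_lines: list[str] = [
        f"nanofcs_version = {__version__}",
        f"numpy_version = {numpy.__version__}",
        f"config_hash = {config.config_hash()}",
        f"seed = {config.seed}",
    ]
    reports = []
    stage = "init"
    try:
        for s_idx, sample in enumerate(config.samples):
            label = str(sample.get("label", f"sample{s_idx}"))
            gel_mode = str(sample.get("gel_mode", "none"))
            sample_stage = str(sample.get("stage", "before"))
            replicates = int(sample.get("replicates", 3))
            species = [_species_from_dict(e) for e in sample["species"]]
            sim_kwargs = {**config.simulation, **sample.get("simulation", {})}
            fits = []
            for rep in range(replicates):
                stage = f"simulate[{label}:{rep}]"
                sim = SimulationConfig(
                    seed=config.seed * 1000 + s_idx * 100 + rep, **sim_kwargs
                )
                trace, truth = simulate_brownian_trace(species, sim)
                trace.metadata["config_hash"] = config.config_hash()
                write_trace(trace, out / f"{label}_rep{rep}.trace.tsv")

                stage = f"correlate[{label}:{rep}]"
                curve = multitau_autocorrelate(trace, m=config.correlator_m)
                curve.provenance["config_hash"] = config.config_hash()
                curve.provenance["seed"] = sim.seed
                write_curve(curve, out / f"{label}_rep{rep}.curve.tsv")

                stage = f"fit[{label}:{rep}]"
                init = None
                if config.fix_s:
                    s_value = (
                        config.calibration.structure_parameter
                        if config.calibration
                        else sim.structure_parameter
                    )
                    from .fit import auto_init

                    init = auto_init(curve, structure_parameter=s_value)
                lag_range = (
                    (curve.lags[0], config.max_fit_lag) if config.max_fit_lag else None
                )
                fit = fit_curve(
                    curve,
                    init,
                    fix_s=config.fix_s,
                    fit_offset=config.fit_offset,
                    lag_range=lag_range,
                )
                write_fit_report(fit, out / f"{label}_rep{rep}.fit.txt")
                fits.append(fit)
                log_lines.append(
                    f"{label} rep{rep}: seed={sim.seed} "
                    f"N={fit.params.occupancy:.4g} "
                    f"tau={fit.params.residence_time:.4g}s "
                    f"chi2={fit.reduced_chi_square:.3g}"
                )
            stage = f"pool[{label}]"
            pooled = pool_replicates(fits)
            write_fit_report(pooled, out / f"{label}.pooled.txt")
            reports.append(
                report_from_fit(
                    label,
                    gel_mode,
                    sample_stage,
                    pooled,
                    cal=config.calibration,
                    cond=config.conditions,
                    ruler_brightness=config.ruler_brightness,
                )
            )
        stage = "report"
        table = infer.build_report(reports)
        report_path = out / "report.csv"
        table.to_csv(report_path, index=False, float_format="%.6g")
        log_lines.append(f"report = {report_path}")
    except Exception as exc:
        (out / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED at stage {stage}: {exc}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report_path
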