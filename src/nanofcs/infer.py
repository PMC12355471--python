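"""From fitted FCS parameters to the physically meaningful report.

Converts occupancy, residence time, and mean count rate into diffusion
coefficient, hydrodynamic size, molecular brightness, oligomeric state, and
concentration, and renders the before/after native-PAGE comparison with
compatibility verdicts.

Two hydrodynamic-size conventions are always computed side by side: the
standard Stokes-Einstein relation r = k_B T / (6 pi eta D) (default) and an
"as-printed" variant r = k_B T / (12 eta D) that omits pi; the two differ by
a factor pi/2 and only the former reproduces the ~15 nm diameter expected
for a tetramer-loaded nanodisc at D ~ 33 um^2/s in water at 25 C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.constants import Avogadro, Boltzmann

from .fit import ConfocalCalibration, FitResult

__all__ = [
    "PhysicalConditions",
    "OligomerCall",
    "SampleReport",
    "IntegrityVerdict",
    "DEFAULT_RULER_BRIGHTNESS",
    "diffusion_coefficient",
    "hydrodynamic_size",
    "molecular_brightness",
    "oligomeric_state",
    "concentration",
    "integrity_check",
    "lipid_count_estimate",
    "report_from_fit",
    "report_from_measurements",
    "build_report",
    "comparison_table",
]

#: Apparent molecular brightness of the free Alexa Fluor 647 maleimide dye
#: (kHz), the single-label ruler against which oligomer brightness is read.
DEFAULT_RULER_BRIGHTNESS = 7.5


@dataclass(frozen=True)
class PhysicalConditions:
    """Solvent conditions for hydrodynamic sizing.

    temperature in kelvin, viscosity in Pa*s. Defaults are water at 25 C.
    """

    temperature: float = 298.15
    viscosity: float = 0.89e-3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")


@dataclass(frozen=True)
class OligomerCall:
    """Integer oligomeric state read off the brightness ruler."""

    state: int
    ratio: float
    ambiguous: bool


@dataclass
class SampleReport:
    """Derived quantities for one sample at one stage.

    Rates in kHz, times in seconds, D in um^2/s, sizes in nm, concentration
    in nM. ``radius_as_printed`` carries the pi-free sizing variant next to
    the Stokes-Einstein default. Optional fields are None when the input
    needed to derive them (calibration, mean rate) was unavailable.
    """

    protein: str
    gel_mode: str
    stage: str
    brightness: float | None = None
    brightness_sd: float | None = None
    residence_time: float | None = None
    residence_time_sd: float | None = None
    diffusion: float | None = None
    diffusion_sd: float | None = None
    radius: float | None = None
    radius_sd: float | None = None
    radius_as_printed: float | None = None
    concentration: float | None = None
    concentration_sd: float | None = None
    oligomer: OligomerCall | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def diameter(self) -> float | None:
        return None if self.radius is None else 2.0 * self.radius


@dataclass(frozen=True)
class IntegrityVerdict:
    """Did electrophoresis preserve the nanodiscs?

    Residence-time compatibility within k-sigma means particle size was
    preserved; a brightness drop > 50% at preserved size is the signature
    of dye quenching (seen with Coomassie in blue native gels) rather than
    of disc disassembly.
    """

    residence_time_compatible: bool
    brightness_compatible: bool
    concentration_ratio: float | None
    quenching_flag: bool
    low_confidence: bool = False


def diffusion_coefficient(residence_time: float, cal: ConfocalCalibration) -> float:
    """D = w_xy^2 / (4 tau_D), in um^2/s for tau_D in seconds, w_xy in um."""
    if residence_time <= 0:
        raise ValueError("residence_time must be > 0")
    return cal.beam_radius_xy ** 2 / (4.0 * residence_time)


def hydrodynamic_size(
    diffusion: float,
    cond: PhysicalConditions = PhysicalConditions(),
    convention: str = "stokes_einstein",
) -> tuple[float, float]:
    """(radius, diameter) in nm from D in um^2/s.

    convention "stokes_einstein" (default): r = k_B T / (6 pi eta D);
    convention "as_printed": r = k_B T / (12 eta D), the pi-free variant.
    """
    if diffusion <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    d_si = diffusion * 1e-12  # um^2/s -> m^2/s
    kt = Boltzmann * cond.temperature
    if convention == "stokes_einstein":
        r_m = kt / (6.0 * math.pi * cond.viscosity * d_si)
    elif convention == "as_printed":
        r_m = kt / (12.0 * cond.viscosity * d_si)
    else:
        raise ValueError(f"unknown sizing convention {convention!r}")
    r_nm = r_m * 1e9
    return r_nm, 2.0 * r_nm


def molecular_brightness(mean_rate: float, occupancy: float) -> float:
    """Apparent per-particle brightness epsilon = mean rate / N, in kHz."""
    if occupancy <= 0:
        raise ValueError("occupancy must be > 0")
    return mean_rate / occupancy


def oligomeric_state(
    brightness: float,
    ruler_brightness: float = DEFAULT_RULER_BRIGHTNESS,
    ambiguity_threshold: float = 0.25,
) -> OligomerCall:
    """Read the oligomeric state off the single-label brightness ruler.

    The state is the nearest integer >= 1 to brightness/ruler; the call is
    flagged ambiguous when the ratio deviates from that integer by more
    than ``ambiguity_threshold`` relative (self-quenching between labels
    and surface effects on quantum yield make brightness an imperfect
    protomer counter).
    """
    if brightness <= 0 or ruler_brightness <= 0:
        raise ValueError("brightness and ruler_brightness must be > 0")
    ratio = brightness / ruler_brightness
    state = max(1, int(round(ratio)))
    ambiguous = abs(ratio - state) / state > ambiguity_threshold
    return OligomerCall(state=state, ratio=ratio, ambiguous=ambiguous)


def concentration(occupancy: float, cal: ConfocalCalibration) -> float:
    """Particle concentration in nM from occupancy and calibrated V_eff."""
    if occupancy <= 0:
        raise ValueError("occupancy must be > 0")
    return occupancy / (Avogadro * cal.effective_volume * 1e-15) * 1e9


def integrity_check(
    before: SampleReport, after: SampleReport, k: float = 2.0
) -> IntegrityVerdict:
    """Compare one sample before and after native PAGE.

    Residence time and brightness are each compatible when the before/after
    difference is within k times the combined standard deviation. Missing
    SDs degrade gracefully to a point-estimate comparison (10% relative)
    flagged low-confidence.
    """
    low_confidence = False

    def compatible(a, a_sd, b, b_sd) -> bool:
        nonlocal low_confidence
        if a is None or b is None:
            raise ValueError("both reports must carry the compared quantity")
        if a_sd is None or b_sd is None:
            low_confidence = True
            return abs(b - a) <= 0.1 * abs(a)
        return abs(b - a) <= k * math.hypot(a_sd, b_sd)

    tau_ok = compatible(
        before.residence_time,
        before.residence_time_sd,
        after.residence_time,
        after.residence_time_sd,
    )
    eps_ok = compatible(
        before.brightness, before.brightness_sd, after.brightness, after.brightness_sd
    )
    ratio = None
    if before.concentration and after.concentration is not None:
        ratio = after.concentration / before.concentration
    quenching = (
        tau_ok
        and not eps_ok
        and after.brightness < 0.5 * before.brightness
    )
    return IntegrityVerdict(
        residence_time_compatible=tau_ok,
        brightness_compatible=eps_ok,
        concentration_ratio=ratio,
        quenching_flag=quenching,
        low_confidence=low_confidence,
    )


def lipid_count_estimate(
    disc_diameter: float, protein_diameter: float, area_per_lipid: float = 0.7
) -> float:
    """Approximate lipids per disc from the annulus around the protein.

    Two leaflets of the annular bilayer area between the disc rim and the
    protein footprint, divided by the area per lipid (nm^2). A deliberately
    coarse geometric estimate, adequate for order-of-magnitude comparisons
    between oligomer and monomer discs only.
    """
    if area_per_lipid <= 0:
        raise ValueError("area_per_lipid must be > 0")
    if protein_diameter > disc_diameter:
        raise ValueError("protein cannot be larger than the disc")
    annulus = math.pi / 4.0 * (disc_diameter ** 2 - protein_diameter ** 2)
    return 2.0 * annulus / area_per_lipid


def _derive_size_and_state(
    report: SampleReport,
    cond: PhysicalConditions,
    ruler_brightness: float,
) -> None:
    if report.diffusion is not None:
        r, _ = hydrodynamic_size(report.diffusion, cond, "stokes_einstein")
        r_printed, _ = hydrodynamic_size(report.diffusion, cond, "as_printed")
        report.radius = r
        report.radius_as_printed = r_printed
        if report.diffusion_sd is not None:
            # first-order: r scales as 1/D
            report.radius_sd = r * report.diffusion_sd / report.diffusion
    if report.brightness is not None and report.brightness > 0:
        report.oligomer = oligomeric_state(report.brightness, ruler_brightness)


def report_from_fit(
    protein: str,
    gel_mode: str,
    stage: str,
    fit: FitResult,
    cal: ConfocalCalibration | None = None,
    cond: PhysicalConditions = PhysicalConditions(),
    ruler_brightness: float = DEFAULT_RULER_BRIGHTNESS,
) -> SampleReport:
    """Derive every reportable quantity from a (pooled) curve fit.

    Uncertainties are propagated first-order from the fit SDs. Without a
    calibration, diffusion, size, and concentration stay unset and a note
    records why.
    """
    rep = SampleReport(protein=protein, gel_mode=gel_mode, stage=stage)
    n = fit.params.occupancy
    n_sd = fit.uncertainties.get("occupancy")
    tau = fit.params.residence_time
    tau_sd = fit.uncertainties.get("residence_time")
    rep.residence_time = tau
    rep.residence_time_sd = tau_sd
    if fit.mean_rate is not None:
        rep.brightness = molecular_brightness(fit.mean_rate, n)
        if n_sd is not None:
            rep.brightness_sd = rep.brightness * n_sd / n
    if cal is not None:
        rep.diffusion = diffusion_coefficient(tau, cal)
        if tau_sd is not None:
            rep.diffusion_sd = rep.diffusion * tau_sd / tau
        rep.concentration = concentration(n, cal)
        if n_sd is not None:
            rep.concentration_sd = rep.concentration * n_sd / n
    else:
        rep.notes.append("no calibration: size and concentration unavailable")
    if fit.under_replicated:
        rep.notes.append(f"under-replicated: {fit.n_replicates} fit(s)")
    _derive_size_and_state(rep, cond, ruler_brightness)
    return rep


def report_from_measurements(
    protein: str,
    gel_mode: str,
    stage: str,
    *,
    brightness: float | None = None,
    brightness_sd: float | None = None,
    residence_time: float | None = None,
    residence_time_sd: float | None = None,
    diffusion: float | None = None,
    diffusion_sd: float | None = None,
    concentration: float | None = None,
    cond: PhysicalConditions = PhysicalConditions(),
    ruler_brightness: float = DEFAULT_RULER_BRIGHTNESS,
) -> SampleReport:
    """Build a report from already-tabulated measured quantities.

    Measured columns pass through unchanged; derived columns (size,
    oligomeric state) are recomputed from them. This is the entry point for
    published summary tables, where brightness, residence time, and D are
    given but the underlying curves are not.
    """
    rep = SampleReport(
        protein=protein,
        gel_mode=gel_mode,
        stage=stage,
        brightness=brightness,
        brightness_sd=brightness_sd,
        residence_time=residence_time,
        residence_time_sd=residence_time_sd,
        diffusion=diffusion,
        diffusion_sd=diffusion_sd,
        concentration=concentration,
    )
    _derive_size_and_state(rep, cond, ruler_brightness)
    return rep


def build_report(
    entries: Sequence[SampleReport],
    k: float = 2.0,
) -> pd.DataFrame:
    """Render reports as a table, pairing before/after stages per sample.

    Returns a tidy DataFrame (one row per sample and stage, display units:
    us, kHz, nm, nM) with integrity-verdict columns attached to the
    "after" rows where a matching "before" row exists. An empty entry list
    yields an empty table.
    """
    rows = []
    by_key: dict[tuple[str, str], dict[str, SampleReport]] = {}
    for rep in entries:
        by_key.setdefault((rep.protein, rep.gel_mode), {})[rep.stage] = rep
    for rep in entries:
        row = {
            "protein": rep.protein,
            "gel_mode": rep.gel_mode,
            "stage": rep.stage,
            "brightness_khz": rep.brightness,
            "brightness_sd_khz": rep.brightness_sd,
            "residence_time_us": _scale(rep.residence_time, 1e6),
            "residence_time_sd_us": _scale(rep.residence_time_sd, 1e6),
            "diffusion_um2_s": rep.diffusion,
            "diffusion_sd_um2_s": rep.diffusion_sd,
            "radius_nm": rep.radius,
            "diameter_nm": rep.diameter,
            "radius_as_printed_nm": rep.radius_as_printed,
            "concentration_nm": rep.concentration,
            "oligomeric_state": rep.oligomer.state if rep.oligomer else None,
            "brightness_ratio": rep.oligomer.ratio if rep.oligomer else None,
            "ambiguous_state": rep.oligomer.ambiguous if rep.oligomer else None,
            "notes": "; ".join(rep.notes),
        }
        pair = by_key.get((rep.protein, rep.gel_mode), {})
        if rep.stage == "after" and "before" in pair:
            verdict = integrity_check(pair["before"], rep, k=k)
            row.update(
                {
                    "size_preserved": verdict.residence_time_compatible,
                    "brightness_preserved": verdict.brightness_compatible,
                    "concentration_ratio": verdict.concentration_ratio,
                    "quenching_flag": verdict.quenching_flag,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_table(entries: Sequence[SampleReport], k: float = 2.0) -> pd.DataFrame:
    """Side-by-side before/after table, one row per (protein, gel mode)."""
    df = build_report(entries, k=k)
    if df.empty:
        return df
    before = df[df.stage == "before"].set_index(["protein", "gel_mode"])
    after = df[df.stage == "after"].set_index(["protein", "gel_mode"])
    keep = [
        "brightness_khz",
        "residence_time_us",
        "diffusion_um2_s",
        "diameter_nm",
        "concentration_nm",
    ]
    merged = before[keep].join(
        after[
            keep
            + [
                c
                for c in (
                    "size_preserved",
                    "brightness_preserved",
                    "concentration_ratio",
                    "quenching_flag",
                )
                if c in after.columns
            ]
        ],
        lsuffix="_before",
        rsuffix="_after",
        how="outer",
    )
    return merged.reset_index()


def _scale(x: float | None, factor: float) -> float | None:
    return None if x is None else x * factor
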