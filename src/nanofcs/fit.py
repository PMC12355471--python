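"""Fitting the single-component 3D free-diffusion model to FCS curves.

The observation volume is a 3D Gaussian with 1/e^2 radii (w_xy, w_xy,
S*w_xy); free diffusion through it gives

    G(tau) = offset + (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(S^2 tau_D))^-1/2

where N is the mean number of particles in the effective volume
V_eff = pi^(3/2) w_xy^2 (S w_xy), and tau_D = w_xy^2 / (4 D) is the lateral
residence (diffusion) time. No triplet term is included by default; a
triplet factor is available behind an explicit flag for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import lmfit
import numpy as np

from .correlate import CorrelationCurve

__all__ = [
    "DiffusionModelParams",
    "ConfocalCalibration",
    "FitResult",
    "FitConvergenceError",
    "g_diffusion_3d",
    "auto_init",
    "fit_curve",
    "calibrate_confocal",
    "pool_replicates",
]


class FitConvergenceError(RuntimeError):
    """Raised when the least-squares minimizer fails to converge."""


@dataclass(frozen=True)
class DiffusionModelParams:
    """Parameters of the single-component 3D diffusion model.

    occupancy:
        Mean particle number N in the effective volume (dimensionless).
    residence_time:
        Lateral diffusion time tau_D, in seconds.
    structure_parameter:
        Axial-to-lateral 1/e^2 radius ratio S (dimensionless, > 1).
    offset:
        Additive baseline (dimensionless), 0 for an ideal curve.
    """

    occupancy: float
    residence_time: float
    structure_parameter: float = 5.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.occupancy <= 0:
            raise ValueError(f"occupancy must be > 0, got {self.occupancy}")
        if self.residence_time <= 0:
            raise ValueError(
                f"residence_time must be > 0, got {self.residence_time}"
            )
        if self.structure_parameter <= 1:
            raise ValueError(
                "structure_parameter must be > 1, got "
                f"{self.structure_parameter}"
            )


@dataclass(frozen=True)
class ConfocalCalibration:
    """Instrument geometry from a reference-dye measurement.

    beam_radius_xy is the lateral 1/e^2 radius in micrometres;
    effective_volume is pi^(3/2) w_xy^2 (S w_xy) in femtolitres
    (1 um^3 == 1 fL), maintained as an exact invariant.
    """

    beam_radius_xy: float
    structure_parameter: float
    effective_volume: float = field(init=False)

    def __post_init__(self) -> None:
        if self.beam_radius_xy <= 0:
            raise ValueError("beam_radius_xy must be > 0")
        if self.structure_parameter <= 1:
            raise ValueError("structure_parameter must be > 1")
        object.__setattr__(
            self,
            "effective_volume",
            math.pi ** 1.5
            * self.beam_radius_xy ** 2
            * (self.structure_parameter * self.beam_radius_xy),
        )


@dataclass
class FitResult:
    """Outcome of one model fit (or of pooling several).

    uncertainties are one-standard-deviation estimates per free parameter
    (from the fit covariance for a single fit; sample SD over replicates for
    a pooled result). mean_rate is in kHz when the source curve carried one.
    """

    params: DiffusionModelParams
    uncertainties: dict[str, float]
    reduced_chi_square: float
    mean_rate: float | None = None
    n_replicates: int = 1
    under_replicated: bool = False
    provenance: dict[str, Any] = field(default_factory=dict)


def g_diffusion_3d(
    lag: float | np.ndarray,
    params: DiffusionModelParams,
    *,
    triplet_fraction: float = 0.0,
    triplet_time: float = 1e-6,
) -> float | np.ndarray:
    """Evaluate the 3D free-diffusion correlation model at one or more lags.

    With ``triplet_fraction`` T > 0 the diffusion part is multiplied by the
    standard dark-state factor (1 + T/(1-T) exp(-tau/triplet_time)).
    """
    tau = np.asarray(lag, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lag must be >= 0")
    n, tau_d, s = params.occupancy, params.residence_time, params.structure_parameter
    g = (1.0 / n) / (1.0 + tau / tau_d) / np.sqrt(1.0 + tau / (s * s * tau_d))
    if triplet_fraction > 0.0:
        if not 0.0 < triplet_fraction < 1.0:
            raise ValueError("triplet_fraction must be in (0, 1)")
        g = g * (
            1.0
            + triplet_fraction / (1.0 - triplet_fraction) * np.exp(-tau / triplet_time)
        )
    g = g + params.offset
    return float(g) if np.isscalar(lag) else g


def auto_init(
    curve: CorrelationCurve, structure_parameter: float = 5.0
) -> DiffusionModelParams:
    """Data-driven starting values: N from 1/max(G), tau_D from the lag
    where G has fallen to half of its maximum."""
    g = curve.values
    gmax = g.max()
    if gmax <= 0:
        raise ValueError("curve has no positive amplitude; cannot initialize")
    n0 = 1.0 / gmax
    below = np.nonzero(g <= 0.5 * gmax)[0]
    tau0 = curve.lags[below[0]] if len(below) else curve.lags[-1]
    return DiffusionModelParams(
        occupancy=n0,
        residence_time=float(tau0),
        structure_parameter=structure_parameter,
        offset=0.0,
    )


def fit_curve(
    curve: CorrelationCurve,
    init: DiffusionModelParams | None = None,
    *,
    fix_s: bool = True,
    fit_offset: bool = True,
    triplet: bool = False,
    lag_range: tuple[float, float] | None = None,
) -> FitResult:
    """Weighted least-squares fit of the 3D diffusion model to a curve.

    Weights are 1/sd when the curve carries per-lag standard deviations,
    uniform otherwise. With ``fix_s`` the structure parameter is held at its
    init value (standard practice: S comes from the dye calibration and is
    never free on sample curves). ``lag_range`` restricts the fit window in
    seconds. The fit is deterministic for fixed input and init.
    """
    lags = curve.lags
    values = curve.values
    sd = curve.sd
    if lag_range is not None:
        keep = (lags >= lag_range[0]) & (lags <= lag_range[1])
        lags, values = lags[keep], values[keep]
        sd = sd[keep] if sd is not None else None
    if len(lags) < 8:
        raise ValueError(f"need at least 8 lags to fit, got {len(lags)}")
    if init is None:
        init = auto_init(
            CorrelationCurve(lags=lags, values=values, sd=sd, mean_rate=curve.mean_rate)
        )

    p = lmfit.Parameters()
    p.add("occupancy", value=init.occupancy, min=1e-12)
    p.add("residence_time", value=init.residence_time, min=1e-12)
    p.add(
        "structure_parameter",
        value=init.structure_parameter,
        min=1.0 + 1e-9,
        max=1e3,
        vary=not fix_s,
    )
    p.add("offset", value=init.offset, vary=fit_offset)
    p.add("triplet_fraction", value=0.05 if triplet else 0.0,
          min=0.0, max=0.999, vary=triplet)
    p.add("triplet_time", value=5e-6, min=1e-9, max=1e-2, vary=triplet)

    if sd is not None and not np.any(sd > 0):
        sd = None  # an all-zero sd column carries no weighting information
    weights = None if sd is None else 1.0 / np.where(sd > 0, sd, np.inf)

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        m = DiffusionModelParams(
            occupancy=pars["occupancy"].value,
            residence_time=pars["residence_time"].value,
            structure_parameter=pars["structure_parameter"].value,
            offset=pars["offset"].value,
        )
        r = values - g_diffusion_3d(
            lags,
            m,
            triplet_fraction=pars["triplet_fraction"].value,
            triplet_time=pars["triplet_time"].value,
        )
        return r if weights is None else r * weights

    out = lmfit.minimize(
        residual, p, method="least_squares", xtol=1e-10, ftol=1e-10, gtol=1e-10
    )
    if not out.success:
        raise FitConvergenceError(
            f"fit did not converge: {out.message} (nfev={out.nfev})"
        )
    fitted = DiffusionModelParams(
        occupancy=out.params["occupancy"].value,
        residence_time=out.params["residence_time"].value,
        structure_parameter=out.params["structure_parameter"].value,
        offset=out.params["offset"].value,
    )
    unc = {
        name: float(out.params[name].stderr)
        for name in out.params
        if out.params[name].vary and out.params[name].stderr is not None
    }
    return FitResult(
        params=fitted,
        uncertainties=unc,
        reduced_chi_square=float(out.redchi),
        mean_rate=curve.mean_rate,
        provenance={
            "fix_s": fix_s,
            "fit_offset": fit_offset,
            "triplet": triplet,
            "n_lags": len(lags),
            "nfev": int(out.nfev),
        },
    )


def calibrate_confocal(
    dye_fit: FitResult, dye_diffusion_coefficient: float
) -> ConfocalCalibration:
    """Turn a reference-dye fit into the instrument calibration.

    The dye's literature diffusion coefficient (um^2/s) anchors the lateral
    beam radius through tau_D = w_xy^2 / (4 D); the structure parameter is
    taken from the dye fit (the only fit in which S is free).
    """
    if dye_diffusion_coefficient <= 0:
        raise ValueError("dye diffusion coefficient must be > 0")
    w_xy = math.sqrt(4.0 * dye_diffusion_coefficient * dye_fit.params.residence_time)
    return ConfocalCalibration(
        beam_radius_xy=w_xy,
        structure_parameter=dye_fit.params.structure_parameter,
    )


def pool_replicates(fits: Sequence[FitResult]) -> FitResult:
    """Mean and sample SD of the fitted parameters over replicate fits.

    Reported as value +/- SD, the convention for averages of independent
    measurements of the same sample. Fewer than 3 replicates yields a
    result flagged as under-replicated rather than an error.
    """
    if not fits:
        raise ValueError("no fits to pool")
    names = ("occupancy", "residence_time", "structure_parameter", "offset")
    cols = {k: np.array([getattr(f.params, k) for f in fits]) for k in names}
    mean_params = DiffusionModelParams(**{k: float(v.mean()) for k, v in cols.items()})
    if len(fits) >= 2:
        unc = {k: float(v.std(ddof=1)) for k, v in cols.items()}
    else:
        unc = dict(fits[0].uncertainties)
    rates = [f.mean_rate for f in fits if f.mean_rate is not None]
    return FitResult(
        params=mean_params,
        uncertainties=unc,
        reduced_chi_square=float(np.mean([f.reduced_chi_square for f in fits])),
        mean_rate=float(np.mean(rates)) if rates else None,
        n_replicates=len(fits),
        under_replicated=len(fits) < 3,
        provenance={"pooled_from": len(fits)},
    )
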