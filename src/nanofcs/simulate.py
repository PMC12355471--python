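"""Brownian-dynamics photon-trace simulator standing in for the microscope.

Labeled nanodiscs diffuse as point emitters through a 3D Gaussian
observation volume with 1/e^2 radii (w_xy, w_xy, S*w_xy) inside a periodic
box. The instantaneous detected intensity is the sum over particles of

    peak_brightness * exp(-2 x^2/w_xy^2 - 2 y^2/w_xy^2 - 2 z^2/(S w_xy)^2)

plus an uncorrelated background, and bin counts are Poisson with mean
intensity * bin_width. Because the spatial average of the Gaussian weight
over the effective volume is 2^(-3/2), the *apparent* molecular brightness
recovered by FCS (mean rate / occupancy) equals peak_brightness * 2^(-3/2).

No photophysics beyond Poisson emission is modeled: no triplet blinking,
photobleaching, or afterpulsing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.constants import Avogadro

from .correlate import CorrelationCurve
from .fit import DiffusionModelParams, g_diffusion_3d
from .trace import PhotonTrace

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "GroundTruthRecord",
    "PEAK_TO_APPARENT",
    "effective_volume",
    "peak_for_apparent_brightness",
    "simulate_brownian_trace",
    "synth_correlation_curve",
]

#: Ratio of apparent (FCS) molecular brightness to the peak per-particle
#: emission rate for a 3D Gaussian detection profile: (pi/2)^(3/2) / pi^(3/2).
PEAK_TO_APPARENT = 2.0 ** -1.5

_CHUNK_STEPS = 65536


@njit(cache=False, fastmath=True)
def _accumulate_intensity(steps, sigma, carry, box, inv2, photons, intensity):
    """Advance particles by ``sigma * steps`` with periodic wrapping and add
    their Gaussian-weighted emission (expected photons per step) to
    ``intensity``. ``carry`` holds running unwrapped positions (float64) and
    is updated in place; the wrap is applied only where the detection
    profile is evaluated."""
    n_p, _, n = steps.shape
    bx, by, bz = box[0], box[1], box[2]
    ix, iz = inv2[0], inv2[2]
    for p in range(n_p):
        x = carry[p, 0]
        y = carry[p, 1]
        z = carry[p, 2]
        for t in range(n):
            x += sigma * steps[p, 0, t]
            y += sigma * steps[p, 1, t]
            z += sigma * steps[p, 2, t]
            qx = x - bx * np.rint(x / bx)
            qy = y - by * np.rint(y / by)
            qz = z - bz * np.rint(z / bz)
            arg = ix * (qx * qx + qy * qy) + iz * (qz * qz)
            intensity[t] += photons * np.exp(-arg)
        carry[p, 0] = x
        carry[p, 1] = y
        carry[p, 2] = z


def effective_volume(beam_radius_xy: float, structure_parameter: float) -> float:
    """FCS effective volume pi^(3/2) w_xy^2 w_z in fL (w_xy in um)."""
    return math.pi ** 1.5 * beam_radius_xy ** 2 * (structure_parameter * beam_radius_xy)


def peak_for_apparent_brightness(apparent_khz: float) -> float:
    """Peak per-particle emission (kHz) giving the requested apparent
    molecular brightness."""
    return apparent_khz / PEAK_TO_APPARENT


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing species of labeled particles.

    diffusion_coefficient in um^2/s, peak_brightness in kHz per particle at
    the volume center, concentration in nM, oligomer_count the number of
    labeled protomers the species represents (used only for bookkeeping in
    ground truth and oligomer-call validation).
    """

    label: str
    diffusion_coefficient: float
    peak_brightness: float
    concentration: float
    oligomer_count: int = 1

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")
        if self.peak_brightness < 0:
            raise ValueError("peak_brightness must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.oligomer_count < 1:
            raise ValueError("oligomer_count must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, timing, and seed of one simulated acquisition.

    Lengths in um, times in seconds, rates in kHz. The box must extend at
    least 6 1/e^2 radii along every axis so that periodic images contribute
    negligibly to the detected intensity.
    """

    beam_radius_xy: float = 0.33
    structure_parameter: float = 5.0
    box_dimensions: tuple[float, float, float] = (2.0, 2.0, 10.0)
    time_step: float = 1e-6
    duration: float = 10.0
    bin_width: float = 1e-6
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beam_radius_xy <= 0:
            raise ValueError("beam_radius_xy must be > 0")
        if self.structure_parameter <= 1:
            raise ValueError("structure_parameter must be > 1")
        if self.time_step <= 0 or self.duration <= 0:
            raise ValueError("time_step and duration must be > 0")
        if self.bin_width < self.time_step:
            raise ValueError("bin_width must be >= time_step")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        w = self.beam_radius_xy
        required = (6 * w, 6 * w, 6 * self.structure_parameter * w)
        for axis, (box, req) in enumerate(zip(self.box_dimensions, required)):
            if box < req:
                raise ValueError(
                    f"box axis {axis} is {box} um but must be >= {req} um "
                    "(6x the 1/e^2 radius) to suppress periodic-image "
                    "artifacts"
                )

    @property
    def effective_volume(self) -> float:
        """fL."""
        return effective_volume(self.beam_radius_xy, self.structure_parameter)

    @property
    def box_volume(self) -> float:
        """um^3 == fL."""
        return float(np.prod(self.box_dimensions))


@dataclass
class GroundTruthRecord:
    """What the simulator actually put into a trace.

    expected_occupancy is C * N_A * V_eff per species (the amplitude a
    correlation fit should recover, up to the small fixed-particle-number
    correction); apparent_brightness is peak_brightness * 2^(-3/2) in kHz.
    n_particles is the realized (stochastically rounded) count in the box.
    """

    species: list[SpeciesSpec]
    expected_occupancy: list[float]
    apparent_brightness: list[float]
    n_particles: list[int]
    config: SimulationConfig | None = None

    @property
    def total_occupancy(self) -> float:
        return float(sum(self.expected_occupancy))


def _particle_count(
    concentration_nm: float, box_volume_fl: float, rng: np.random.Generator
) -> int:
    """Stochastic rounding of C * N_A * V_box.

    The count is fixed within a replicate (suppressing occupancy variance
    relative to a Poisson draw) but floor+Bernoulli on the fractional part
    keeps the mean density across replicates exactly equal to the requested
    concentration -- plain rounding would bias sub-nM samples by several
    percent in boxes of tens of femtolitres."""
    # box volume fL -> litres is 1e-15; concentration nM -> M is 1e-9
    x = concentration_nm * 1e-9 * Avogadro * box_volume_fl * 1e-15
    base = math.floor(x)
    return base + (1 if rng.random() < x - base else 0)


def simulate_brownian_trace(
    species: Sequence[SpeciesSpec] | SpeciesSpec,
    config: SimulationConfig,
) -> tuple[PhotonTrace, GroundTruthRecord]:
    """Simulate one binned photon-count trace for a mixture of species.

    Particles take Gaussian random-walk steps with per-axis standard
    deviation sqrt(2 D dt) in a periodic box; the per-species particle
    number is the stochastic rounding of C N_A V_box rather than a Poisson
    draw, which suppresses replicate-to-replicate variance (at the cost of
    a small V_eff/V_box reduction of occupancy fluctuations) while keeping
    the mean density equal to the concentration. All randomness flows
    from ``config.seed`` through a single Philox generator; identical seed
    gives an identical trace.
    """
    if isinstance(species, SpeciesSpec):
        species = [species]
    species = list(species)
    if not species:
        raise ValueError("at least one species is required")

    steps_per_bin = int(round(config.bin_width / config.time_step))
    if abs(steps_per_bin * config.time_step - config.bin_width) > 1e-9 * config.bin_width:
        raise ValueError("bin_width must be an integer multiple of time_step")
    n_bins = int(round(config.duration / config.bin_width))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    n_steps = n_bins * steps_per_bin

    rng = np.random.Generator(np.random.Philox(config.seed))
    box = np.asarray(config.box_dimensions, dtype=np.float64)
    half = box / 2.0
    w = config.beam_radius_xy
    wz = config.structure_parameter * w
    inv2 = np.array([2.0 / w ** 2, 2.0 / w ** 2, 2.0 / wz ** 2])

    counts_n = [
        _particle_count(sp.concentration, config.box_volume, rng) for sp in species
    ]
    sigmas = [
        math.sqrt(2.0 * sp.diffusion_coefficient * config.time_step) for sp in species
    ]
    carry = [
        rng.uniform(-half[None, :], half[None, :], size=(n, 3)) for n in counts_n
    ]

    # Expected photons per step from one particle at the focus, per species.
    photons_per_step = [sp.peak_brightness * 1e3 * config.time_step for sp in species]
    bg_per_step = config.background_rate * 1e3 * config.time_step

    lam = np.empty(n_steps, dtype=np.float64)
    start = 0
    while start < n_steps:
        stop = min(start + _CHUNK_STEPS, n_steps)
        nloc = stop - start
        intensity = np.full(nloc, bg_per_step, dtype=np.float64)
        for si, sp in enumerate(species):
            n_p = counts_n[si]
            if n_p == 0:
                continue
            steps = rng.standard_normal((n_p, 3, nloc), dtype=np.float32)
            if photons_per_step[si] == 0.0:
                # dark species: advance positions, no emission
                carry[si] += sigmas[si] * steps.sum(axis=2, dtype=np.float64)
                continue
            _accumulate_intensity(
                steps, sigmas[si], carry[si], box, inv2,
                photons_per_step[si], intensity,
            )
        lam[start:stop] = intensity
        start = stop

    if steps_per_bin > 1:
        lam = lam.reshape(n_bins, steps_per_bin).sum(axis=1)
    counts = rng.poisson(lam).astype(np.int64)

    v_eff = config.effective_volume
    truth = GroundTruthRecord(
        species=species,
        expected_occupancy=[
            sp.concentration * 1e-9 * Avogadro * v_eff * 1e-15 for sp in species
        ],
        apparent_brightness=[sp.peak_brightness * PEAK_TO_APPARENT for sp in species],
        n_particles=counts_n,
        config=config,
    )
    trace = PhotonTrace(
        bin_width=config.bin_width,
        counts=counts,
        metadata={
            "seed": config.seed,
            "ground_truth": {
                "species": [
                    {
                        "label": sp.label,
                        "diffusion_coefficient": sp.diffusion_coefficient,
                        "peak_brightness": sp.peak_brightness,
                        "apparent_brightness": sp.peak_brightness * PEAK_TO_APPARENT,
                        "concentration": sp.concentration,
                        "oligomer_count": sp.oligomer_count,
                        "n_particles": counts_n[i],
                        "expected_occupancy": truth.expected_occupancy[i],
                    }
                    for i, sp in enumerate(species)
                ],
                "effective_volume_fl": v_eff,
                "background_rate": config.background_rate,
            },
        },
    )
    return trace, truth


def synth_correlation_curve(
    params: DiffusionModelParams,
    lags: np.ndarray | Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CorrelationCurve:
    """Analytic model curve with multiplicative Gaussian noise.

    A fast stand-in for simulate -> correlate when only the fitting stage is
    under study: each model value is multiplied by (1 + sigma*z), z standard
    normal, and the per-lag SD field is set to sigma * model value.
    sigma = 0 returns the exact model.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    lags = np.asarray(lags, dtype=float)
    g = np.asarray(g_diffusion_3d(lags, params), dtype=float)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = g * (1.0 + noise_sigma * rng.standard_normal(len(g)))
    else:
        noisy = g.copy()
    return CorrelationCurve(
        lags=lags,
        values=noisy,
        sd=noise_sigma * np.abs(g),
        mean_rate=None,
        provenance={"synthetic": True, "noise_sigma": noise_sigma, "seed": seed},
    )
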