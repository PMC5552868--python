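"""Particle characterization utilities: log-normal size fits and the
Scherrer crystallite-size formula."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SizeDistribution:
    """Log-normal fit of a particle-diameter list.

    ``mean_d`` is the distribution mean exp(µ + σ²/2) in nm; ``sd_d`` its
    standard deviation; ``delta_d_pct`` the spread as % of the mean
    (coefficient of variation). The log-space σ is reported separately
    (``sigma_log``) because size-distribution captions are ambiguous about
    which of the two spreads they quote.
    """

    n: int
    mu_log: float
    sigma_log: float
    mean_d: float
    sd_d: float
    delta_d_pct: float


def fit_lognormal(diameters_nm) -> SizeDistribution:
    """Maximum-likelihood log-normal fit (µ, σ of log-diameter).

    Requires at least 30 particles for a meaningful fit and strictly
    positive diameters. The fit is invariant to data ordering, and scaling
    all diameters by c scales the mean by c while leaving δd% unchanged.
    """
    d = np.asarray(diameters_nm, dtype=float)
    if d.size < 30:
        raise ValueError("need at least 30 diameters for a log-normal fit")
    if (d <= 0).any():
        raise ValueError("diameters must be positive")
    logs = np.log(d)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))  # MLE
    mean_d = math.exp(mu + sigma**2 / 2.0)
    sd_d = mean_d * math.sqrt(math.expm1(sigma**2))
    return SizeDistribution(
        n=int(d.size),
        mu_log=mu,
        sigma_log=sigma,
        mean_d=mean_d,
        sd_d=sd_d,
        delta_d_pct=100.0 * sd_d / mean_d,
    )


def scherrer(
    fwhm_rad: float,
    theta_rad: float,
    wavelength_A: float = 1.789,  # Co Kα
    shape_factor: float = 0.9,
) -> float:
    """Crystallite size D = K·λ/(β·cosθ) from diffraction peak broadening, in nm.

    ``fwhm_rad`` is the peak full width at half maximum β and ``theta_rad``
    the Bragg angle θ, both in radians; λ in Å. K defaults to 0.9 (the common
    spherical-crystallite convention).
    """
    if not 0.0 < theta_rad < math.pi / 2:
        raise ValueError("Bragg angle must lie in (0, π/2)")
    if fwhm_rad <= 0:
        raise ValueError("peak FWHM must be positive")
    if wavelength_A <= 0:
        raise ValueError("wavelength must be positive")
    if not 0.5 < shape_factor < 1.5:
        raise ValueError("shape factor outside the plausible (0.5, 1.5) range")
    d_angstrom = shape_factor * wavelength_A / (fwhm_rad * math.cos(theta_rad))
    return d_angstrom / 10.0
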