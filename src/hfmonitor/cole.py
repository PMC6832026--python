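"""Cole–Cole impedance model: forward evaluation, spectrum fitting, daily index.

Tissue impedance measured at multiple frequencies follows a single-dispersion
Cole–Cole relaxation,

    Z(f) = R_inf + (R_0 - R_inf) / (1 + (j f / f_c)^alpha),

where ``R_0`` is the resistance at zero frequency (dominated by extracellular
fluid), ``R_inf`` the resistance at infinite frequency (total body water),
``f_c`` the characteristic frequency of the dispersion and ``alpha`` in
(0, 1] the dispersion-broadening exponent.  A daily multifrequency thoracic
measurement is reduced to a scalar *bioimpedance index* by fitting this model
and reporting the fitted ``R_0``: thoracic fluid accumulation raises
extracellular conductance and therefore lowers ``R_0``, so a sustained drop in
the index tracks congestion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ColeParameters",
    "ImpedanceSpectrum",
    "ColeFit",
    "ParameterDomainError",
    "InsufficientDataError",
    "cole_impedance",
    "fit_cole",
    "bioimpedance_index",
]

#: minimum number of measurement frequencies for a 4-parameter fit
MIN_FREQUENCIES = 4

#: relative (R0 - Rinf)/R0 below which a fit is reported as degenerate
DEGENERATE_DISPERSION_FRACTION = 1e-3


class ParameterDomainError(ValueError):
    """Cole parameters outside their physical domain."""


class InsufficientDataError(ValueError):
    """Too few frequencies to constrain the four Cole parameters."""


@dataclass(frozen=True)
class ColeParameters:
    """The four constants of a single-dispersion Cole–Cole spectrum.

    Attributes
    ----------
    r_zero : float
        Resistance at zero frequency, ohm.  Must exceed ``r_inf``.
    r_inf : float
        Resistance at infinite frequency, ohm.  Strictly positive.
    f_c : float
        Characteristic frequency of the dispersion, Hz.
    alpha : float
        Dispersion exponent, in (0, 1]; 1 gives a pure Debye relaxation.
    """

    r_zero: float
    r_inf: float
    f_c: float
    alpha: float

    def __post_init__(self) -> None:
        problems = []
        if not (self.r_inf > 0):
            problems.append(f"r_inf must be > 0 (got {self.r_inf})")
        if not (self.r_zero > self.r_inf):
            problems.append(
                f"r_zero must exceed r_inf (got r_zero={self.r_zero}, r_inf={self.r_inf})"
            )
        if not (self.f_c > 0):
            problems.append(f"f_c must be > 0 (got {self.f_c})")
        if not (0 < self.alpha <= 1):
            problems.append(f"alpha must be in (0, 1] (got {self.alpha})")
        if problems:
            raise ParameterDomainError("; ".join(problems))


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """One multifrequency impedance measurement.

    ``frequencies`` must be strictly increasing; ``impedances`` holds the
    complex impedance at each frequency (ohm).
    """

    frequencies: np.ndarray
    impedances: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.impedances, dtype=complex)
        if f.ndim != 1 or z.ndim != 1 or f.size != z.size:
            raise ValueError("frequencies and impedances must be 1-D and equal length")
        if f.size and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "impedances", z)

    def __len__(self) -> int:
        return self.frequencies.size


@dataclass(frozen=True)
class ColeFit:
    """Result of fitting a Cole model to one spectrum.

    ``residual_rms`` is the root-mean-square residual over all fitted
    components (real and imaginary parts jointly), in ohm.  Non-convergence
    and degeneracy (no measurable dispersion, R0 ≈ Rinf) are flags, not
    exceptions, so downstream quality control can act on them.
    """

    params: ColeParameters
    residual_rms: float
    converged: bool
    degenerate: bool = False


def cole_impedance(params: ColeParameters, frequency):
    """Evaluate the Cole–Cole model Z(f) at one or more frequencies (Hz).

    Returns a complex scalar for scalar input, a complex array otherwise.
    At f = 0 the model returns exactly ``r_zero``; |Z(f)| is non-increasing
    in f and tends to ``r_inf`` as f -> inf.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    jw = (1j * f / params.f_c) ** params.alpha
    z = params.r_inf + (params.r_zero - params.r_inf) / (1.0 + jw)
    if np.isscalar(frequency) or np.ndim(frequency) == 0:
        return complex(z)
    return z


def _model_and_jacobian(x: np.ndarray, f: np.ndarray):
    """Forward model and analytic Jacobian in the fit parametrization.

    x = (r_inf, delta, ln_fc, alpha) with delta = r_zero - r_inf, so the
    physical ordering r_zero > r_inf is the positivity bound delta > 0.
    """
    r_inf, delta, ln_fc, alpha = x
    fc = math.exp(ln_fc)
    with np.errstate(divide="ignore"):
        log_jf = np.where(f > 0, np.log(f / fc), -np.inf) + 1j * (math.pi / 2)
    u = np.where(f > 0, np.exp(alpha * log_jf), 0.0 + 0.0j)
    denom = 1.0 + u
    z = r_inf + delta / denom
    inv2 = denom**-2
    dz_drinf = np.ones_like(u)
    dz_ddelta = 1.0 / denom
    dz_dlnfc = delta * alpha * u * inv2
    dz_dalpha = -delta * np.where(f > 0, u * log_jf, 0.0 + 0.0j) * inv2
    jac = np.stack([dz_drinf, dz_ddelta, dz_dlnfc, dz_dalpha], axis=1)
    return z, jac


def fit_cole(spectrum: ImpedanceSpectrum, max_nfev: int = 1000) -> ColeFit:
    """Fit the Cole–Cole model to a measured spectrum.

    Box-constrained nonlinear least squares on the stacked real and imaginary
    residuals.  Initialization: r_zero = max |Z|, r_inf = min |Z|, f_c at the
    frequency of the most negative reactance, alpha = 0.8.  Bounds keep
    r_inf > 0, r_zero > r_inf and alpha in [0.3, 1].

    Raises
    ------
    InsufficientDataError
        If the spectrum has fewer than four frequencies.
    """
    if len(spectrum) < MIN_FREQUENCIES:
        raise InsufficientDataError(
            f"need >= {MIN_FREQUENCIES} frequencies to fit 4 parameters, "
            f"got {len(spectrum)}"
        )
    f = spectrum.frequencies
    z = spectrum.impedances
    mag = np.abs(z)
    r0_init = float(mag.max())
    rinf_init = max(float(mag.min()), 1e-6)
    delta_init = max(r0_init - rinf_init, 1e-3)
    fc_init = float(f[int(np.argmin(z.imag))])
    x0 = np.array([rinf_init, delta_init, math.log(fc_init), 0.8])
    lower = np.array([1e-6, 1e-6, math.log(1.0), 0.3])
    upper = np.array([np.inf, np.inf, math.log(1e9), 1.0])
    x0 = np.clip(x0, lower + 1e-12, upper - 1e-12)

    target = np.concatenate([z.real, z.imag])

    def residuals(x):
        zm, _ = _model_and_jacobian(x, f)
        return np.concatenate([zm.real, zm.imag]) - target

    def jacobian(x):
        _, jc = _model_and_jacobian(x, f)
        return np.concatenate([jc.real, jc.imag])

    result = least_squares(
        residuals,
        x0,
        jac=jacobian,
        bounds=(lower, upper),
        method="trf",
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-10,
        max_nfev=max_nfev,
    )
    r_inf, delta, ln_fc, alpha = result.x
    params = ColeParameters(
        r_zero=float(r_inf + delta),
        r_inf=float(r_inf),
        f_c=float(math.exp(ln_fc)),
        alpha=float(alpha),
    )
    rms = float(np.sqrt(np.mean(result.fun**2)))
    degenerate = delta < DEGENERATE_DISPERSION_FRACTION * (r_inf + delta)
    converged = bool(result.success)
    return ColeFit(params=params, residual_rms=rms, converged=converged, degenerate=degenerate)


def bioimpedance_index(params: ColeParameters) -> float:
    """Scalar daily bioimpedance index: the fitted zero-frequency resistance.

    R0 is governed by extracellular fluid volume, the compartment that expands
    during decompensation, so the index falls monotonically as thoracic fluid
    accumulates.  The index definition is isolated here so an alternative
    summary (a fixed-frequency magnitude, a composite) can be swapped in.
    """
    return params.r_zero
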