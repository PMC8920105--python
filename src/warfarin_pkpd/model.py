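"""Steady-state warfarin PK-PD model.

The model links a maintenance dose regimen to the steady-state PT-INR
through a power-law pharmacodynamic transform

    f(INR) = b * INR**p - a        (a = 3.36, b = 4.368, p = 0.383)

and a steady-state pharmacokinetic expression for the reciprocal response

    1/f = -(m*CL/V) / k**2 * (1 - (k*tau/24) / (1 - exp(-k*tau/24)))
          - (m/k) * ln( (Dose/V) / (C_max * (1 - exp(-(CL/V)*tau/24))) )

with tau the dosing interval in hours (tau/24 converts to days so that the
rate k [1/day] and clearance CL [L/day] keep consistent units), C_max the
steady-state peak concentration [mg/L], V the volume of distribution [L],
and m a dimensionless PD slope constant. The dose equation is the exact
algebraic inverse of the INR equation, so ``dose_for_target_inr`` and
``steady_state_inr`` round-trip to numerical precision.

The published concentration equation is identical to the INR equation, so
``steady_state_cs`` is an alias of ``steady_state_inr`` (see
docs/methods.md for discussion of this anomaly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ModelDomainError

__all__ = [
    "PDConstants",
    "PKParameters",
    "DoseRegimen",
    "DEFAULT_PD_CONSTANTS",
    "pd_transform",
    "pd_inverse",
    "steady_state_inr",
    "steady_state_cs",
    "dose_for_target_inr",
]


@dataclass(frozen=True)
class PDConstants:
    """Constants of the power-law PD transform f(INR) = b*INR**p - a."""

    a: float = 3.36
    b: float = 4.368
    p: float = 0.383

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError(f"PD scale b must be > 0, got {self.b}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"PD exponent p must be in (0, 1), got {self.p}")

    @property
    def inr_root(self) -> float:
        """INR at which the transform is zero: (a/b)**(1/p)."""
        return (self.a / self.b) ** (1.0 / self.p)


DEFAULT_PD_CONSTANTS = PDConstants()


@dataclass(frozen=True)
class PKParameters:
    """Individual steady-state PK parameter quadruple plus the PD slope m.

    Attributes
    ----------
    c_max : float
        Steady-state maximum plasma concentration, mg/L.
    k : float
        First-order elimination rate constant, 1/day.
    cl : float
        Total clearance, L/day.
    v_d : float
        Apparent volume of distribution, L.
    m : float
        Dimensionless PD slope constant of the model (default 1.0).
    """

    c_max: float
    k: float
    cl: float
    v_d: float
    m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_max", "k", "cl", "v_d", "m"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value}")

    def as_array(self) -> np.ndarray:
        """(c_max, k, cl, v_d) as a float array; m is carried separately."""
        return np.array([self.c_max, self.k, self.cl, self.v_d], dtype=float)


@dataclass(frozen=True)
class DoseRegimen:
    """Maintenance regimen: dose per administration [mg], interval tau [h]."""

    dose: float
    tau: float = 24.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dose) and self.dose > 0):
            raise ValueError(f"dose must be finite and > 0, got {self.dose}")
        if not (math.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be finite and > 0, got {self.tau}")


def pd_transform(inr, consts: PDConstants = DEFAULT_PD_CONSTANTS):
    """Forward PD transform f(INR) = b*INR**p - a.

    Strictly increasing on INR > 0; vanishes at ``consts.inr_root``.
    Accepts scalars or arrays; raises :class:`ModelDomainError` on
    non-positive INR.
    """
    inr = np.asarray(inr, dtype=float)
    if np.any(~np.isfinite(inr)) or np.any(inr <= 0):
        raise ModelDomainError("inr", f"INR must be finite and > 0, got {inr}")
    out = consts.b * inr**consts.p - consts.a
    return float(out) if out.ndim == 0 else out


def pd_inverse(f, consts: PDConstants = DEFAULT_PD_CONSTANTS):
    """Inverse PD transform INR = ((f + a)/b)**(1/p).

    Requires f > -a (otherwise the base of the fractional power is
    non-positive). Exact inverse of :func:`pd_transform` on its range.
    """
    f = np.asarray(f, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f + consts.a <= 0):
        raise ModelDomainError(
            "transform-offset", f"need f + a > 0 (a={consts.a}), got f={f}"
        )
    out = ((f + consts.a) / consts.b) ** (1.0 / consts.p)
    return float(out) if out.ndim == 0 else out


def _accumulation_terms(theta: np.ndarray, tau_h, m: float):
    """Shared sub-expressions of the steady-state equations.

    Returns (A, log_G) where

        A = -(m*CL/V)/k**2 * (1 - x/(1 - exp(-x))),   x = k*tau/24
        G = C_max * (1 - exp(-(CL/V)*tau/24))

    so that 1/f = A - (m/k)*ln(Dose/(V*G)). ``theta`` is the array
    (c_max, k, cl, v_d); tau_h may be scalar or per-visit array.
    No domain checks: used on pre-validated inputs and inside the fitter,
    where invalid proposals surface as non-finite values.
    """
    c_max, k, cl, v_d = theta
    tau_d = np.asarray(tau_h, dtype=float) / 24.0
    x = k * tau_d
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        A = -(m * cl / v_d) / k**2 * (1.0 - x / (1.0 - np.exp(-x)))
        log_G = np.log(c_max) + np.log1p(-np.exp(-(cl / v_d) * tau_d))
    return A, log_G


def transformed_response(theta: np.ndarray, doses, tau_h, m: float) -> np.ndarray:
    """Predicted f = pd_transform(INR) for doses under parameters theta.

    Fast unguarded path used by the fitter and the generator: invalid
    regions come back as non-finite entries rather than exceptions.
    """
    doses = np.asarray(doses, dtype=float)
    A, log_G = _accumulation_terms(theta, tau_h, m)
    c_max, k, cl, v_d = theta
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = A - (m / k) * (np.log(doses / v_d) - log_G)
        f = 1.0 / denom
    return f


def steady_state_inr(
    params: PKParameters,
    regimen: DoseRegimen,
    consts: PDConstants = DEFAULT_PD_CONSTANTS,
) -> float:
    """Predicted steady-state PT-INR for a maintenance regimen.

    Evaluates the reciprocal transformed response and maps it back to the
    INR scale with :func:`pd_inverse`. Raises :class:`ModelDomainError`
    naming the failing term (``ln-argument``, ``reciprocal`` or
    ``transform-offset``) when the regimen lies outside the model's valid
    dose window for these parameters.
    """
    theta = params.as_array()
    A, log_G = _accumulation_terms(theta, regimen.tau, params.m)
    log_ratio = math.log(regimen.dose / params.v_d) - log_G
    if not math.isfinite(log_ratio):
        raise ModelDomainError(
            "ln-argument",
            f"ln argument invalid for dose={regimen.dose}, params={params}",
        )
    denom = A - (params.m / params.k) * log_ratio
    if not math.isfinite(denom) or denom == 0.0:
        raise ModelDomainError(
            "reciprocal", f"1/f undefined: denominator={denom} at dose={regimen.dose}"
        )
    f = 1.0 / denom
    return pd_inverse(f, consts)


def steady_state_cs(
    params: PKParameters,
    regimen: DoseRegimen,
    consts: PDConstants = DEFAULT_PD_CONSTANTS,
) -> float:
    """Steady-state concentration expression.

    The published concentration and INR equations are textually identical,
    so this is by construction an alias of :func:`steady_state_inr`; see
    docs/methods.md. Kept as a separate name so code reads as intended.
    """
    return steady_state_inr(params, regimen, consts)


def dose_for_target_inr(
    params: PKParameters,
    target_inr: float,
    tau: float = 24.0,
    consts: PDConstants = DEFAULT_PD_CONSTANTS,
) -> float:
    """Maintenance dose [mg] producing a target steady-state INR.

    Closed-form algebraic inverse of :func:`steady_state_inr`:

        Dose = exp( (1 + A'*f_t) / ((-m/k)*f_t) ) * C_max
               * (1 - exp(-(CL/V)*tau/24)) * V

    with f_t = b*target**p - a and A' = +(m*CL/V)/k**2 * (1 - x/(1-e^-x)).
    The target INR equal to the transform root (f_t = 0) is a singularity.
    """
    f_t = pd_transform(target_inr, consts)
    if abs(f_t) < 1e-12:
        raise ModelDomainError(
            "singular-target",
            f"target INR {target_inr} is the transform root "
            f"{consts.inr_root:.6g}; dose is undefined there",
        )
    theta = params.as_array()
    A, log_G = _accumulation_terms(theta, tau, params.m)
    # A' in the printed dose equation is -A of the INR equation
    exponent = (1.0 + (-A) * f_t) / ((-params.m / params.k) * f_t)
    dose = math.exp(exponent + log_G) * params.v_d
    if not (math.isfinite(dose) and dose > 0):
        raise ModelDomainError(
            "ln-argument", f"dose expression invalid for target {target_inr}"
        )
    return dose
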