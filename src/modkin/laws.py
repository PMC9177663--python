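"""Closed-form rate laws for Michaelis-Menten, general-modifier and
substrate-inhibition (SES) kinetics.

All laws return the normalized velocity v/Etot in s^-1; multiply by the
enzyme concentration at the interface layer when absolute rates are
needed.  Substrate concentrations must be in ``p.s_unit`` and modifier
concentrations in ``p.x_unit``; the functions are vectorized over S
and X.

The general modifier law in its quasi-equilibrium form, with Km standing
in for the substrate dissociation constant so that the measured
Michaelis constant is directly a model parameter::

    v/Etot = kcat * (S/Km) * (1 + beta*X/(alpha*KX))
             -----------------------------------------
             1 + S/Km + X/KX + S*X/(alpha*Km*KX)

At X=0 this is Michaelis-Menten; as X -> inf it tends to the fully
modified branch beta*kcat*S/(alpha*Km + S); at fixed S it is a
hyperbola in X, so the direction of modification is fixed by the sign of
``beta*(Km+S) - (alpha*Km+S)``.
"""

from __future__ import annotations

import math

import numpy as np

from .params import KineticParameters, SESParameters

__all__ = [
    "mm_velocity",
    "general_modifier_velocity",
    "apparent_parameters",
    "modification_direction",
    "analytic_half_effect",
    "ses_velocity",
    "ses_velocity_with_modifier",
    "NoModificationError",
]


class NoModificationError(ValueError):
    """Raised when a half-effect midpoint is requested but the modifier
    leaves the velocity unchanged (alpha = beta = 1)."""


def _as_nonneg(name: str, value):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and >= 0 (got {value!r})")
    return arr


def mm_velocity(s, p: KineticParameters):
    """Michaelis-Menten velocity v/Etot = kcat*S/(Km+S), s^-1."""
    s = _as_nonneg("substrate concentration S", s)
    out = p.kcat * s / (p.km + s)
    return out if out.ndim else float(out)


def general_modifier_velocity(s, x, p: KineticParameters):
    """Velocity of the general (hyperbolic, nonessential) modifier scheme.

    S and X broadcast against each other.  In the ``no_ternary_complex``
    limit (alpha or KX infinite) the law degrades to linear
    (competitive-like) inhibition v = kcat*S/(Km*(1+X/KX)+S), with
    X/KX -> 0 when KX itself is infinite.
    """
    s = _as_nonneg("substrate concentration S", s)
    x = _as_nonneg("modifier concentration X", x)
    if p.no_ternary_complex:
        rel_x = 0.0 if math.isinf(p.kx) else x / p.kx
        out = p.kcat * s / (p.km * (1.0 + rel_x) + s)
        return out if np.ndim(out) else float(out)
    num = p.kcat * (s / p.km) * (1.0 + p.beta * x / (p.alpha * p.kx))
    den = 1.0 + s / p.km + x / p.kx + s * x / (p.alpha * p.km * p.kx)
    out = num / den
    return out if out.ndim else float(out)


def apparent_parameters(x, p: KineticParameters):
    """Apparent (kcat_app, Km_app) at modifier concentration X.

    kcat_app = kcat*(1 + beta*X/(alpha*KX)) / (1 + X/(alpha*KX));
    Km_app   = Km  *(1 + X/KX)              / (1 + X/(alpha*KX)).
    The modifier law equals kcat_app*S/(Km_app+S) identically in S.
    """
    x = _as_nonneg("modifier concentration X", x)
    if p.no_ternary_complex:
        raise ValueError("apparent parameters are hyperbolic-family quantities; "
                         "undefined in the no-ternary-complex (linear) limit")
    denom = 1.0 + x / (p.alpha * p.kx)
    kcat_app = p.kcat * (1.0 + p.beta * x / (p.alpha * p.kx)) / denom
    km_app = p.km * (1.0 + x / p.kx) / denom
    if np.ndim(kcat_app) == 0:
        return float(kcat_app), float(km_app)
    return kcat_app, km_app


def modification_direction(s, p: KineticParameters) -> float:
    """Sign of the modifier effect on v at substrate concentration S.

    Returns sign(beta*(Km+S) - (alpha*Km+S)): positive for activation,
    negative for inhibition, zero when the modifier is silent at this S.
    """
    s = _as_nonneg("substrate concentration S", s)
    return float(np.sign(p.beta * (p.km + s) - (p.alpha * p.km + s)))


def analytic_half_effect(s, p: KineticParameters) -> float:
    """Exact midpoint X50 of the hyperbola v(X) at fixed S.

    X50 = alpha*KX*(Km+S)/(alpha*Km+S) satisfies
    v(X50) = (v(0) + v(X->inf)) / 2 exactly.  This is the AC50 of an
    activating titration and the IC50 of an inhibitory one.  Raises
    :class:`NoModificationError` when alpha = beta = 1 (flat response,
    midpoint undefined).
    """
    s = float(_as_nonneg("substrate concentration S", s))
    if p.no_ternary_complex:
        raise ValueError("half-effect midpoint undefined in the no-ternary-complex limit")
    if p.alpha == 1.0 and p.beta == 1.0:
        raise NoModificationError("alpha = beta = 1: modifier is silent, midpoint undefined")
    if p.alpha == 1.0:  # formula collapses exactly to KX
        return p.kx
    return p.alpha * p.kx * (p.km + s) / (p.alpha * p.km + s)


def ses_velocity(s, q: SESParameters):
    """Substrate-inhibition velocity v/Etot = Vmax*S/(Km + S + S^2/Ksi).

    Unimodal in S with the maximum at S* = sqrt(Km*Ksi); Ksi = inf
    recovers Michaelis-Menten.
    """
    s = _as_nonneg("substrate concentration S", s)
    sq = np.zeros_like(s) if math.isinf(q.ksi) else s * s / q.ksi
    out = q.vmax_over_etot * s / (q.km + s + sq)
    return out if out.ndim else float(out)


def ses_velocity_with_modifier(s, x, q: SESParameters):
    """SES velocity with a modifier that deepens substrate inhibition.

    The S^2/Ksi term is scaled by (1 + X/Kx_ses), the minimal
    one-parameter coupling producing a dose-dependent accentuation of
    the high-substrate downturn.  Requires ``q.kx_ses``.
    """
    if q.kx_ses is None:
        raise ValueError("SESParameters.kx_ses is not set; the modifier-coupled "
                         "SES law needs it")
    s = _as_nonneg("substrate concentration S", s)
    x = _as_nonneg("modifier concentration X", x)
    sq = np.zeros_like(s) if math.isinf(q.ksi) else s * s / q.ksi
    out = q.vmax_over_etot * s / (q.km + s + sq * (1.0 + x / q.kx_ses))
    return out if np.ndim(out) else float(out)
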