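"""Parameter containers for the general (hyperbolic) modifier mechanism.

The scheme has four enzyme states — E, ES, EX, EXS — where X is a
nonessential modifier that binds free enzyme with dissociation constant
``KX`` and the ES complex with ``alpha * KX``; the ternary complex turns
over at ``beta * kcat``.  ``alpha`` couples modifier binding to substrate
binding (alpha > 1 weakens substrate affinity, alpha < 1 strengthens it);
``beta`` rescales turnover (beta > 1 activation, beta < 1 inhibition).

:class:`KineticParameters` is the phenomenological set the closed-form
laws use (kcat, Km, KX, alpha, beta).  :class:`MicroscopicRates` is the
mass-action realization (k1..k5 plus the coupled branch) consumed by the
ODE oracle.  :class:`SESParameters` describes substrate inhibition via a
substrate-enzyme-substrate ternary complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .units import canonical_unit, convert

__all__ = ["KineticParameters", "MicroscopicRates", "SESParameters"]


def _check_positive(**named):
    for name, value in named.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Phenomenological parameters of one enzyme-substrate-modifier triple.

    Parameters
    ----------
    kcat : float
        Catalytic constant, s^-1.
    km : float
        Michaelis constant, in ``s_unit``.
    kx : float
        Modifier dissociation constant from free enzyme, in ``x_unit``.
    alpha : float
        Dimensionless equilibrium coupling coefficient, > 0.  ``math.inf``
        is accepted as the "no ternary complex" (linear) limit.
    beta : float
        Dimensionless catalytic coefficient, >= 0.
    etot : float, optional
        Total enzyme concentration in ``x_unit``; only needed when
        absolute rates rather than v/Etot are required.
    s_unit, x_unit : str
        Concentration unit tags for substrate-side and modifier-side
        quantities respectively.
    """

    kcat: float
    km: float
    kx: float
    alpha: float
    beta: float
    etot: float | None = None
    s_unit: str = "mM"
    x_unit: str = "uM"

    def __post_init__(self):
        _check_positive(kcat=self.kcat, km=self.km)
        if not (self.kx > 0):
            raise ValueError(f"kx must be positive, got {self.kx!r}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha!r}")
        if not (self.beta >= 0) or not math.isfinite(self.beta):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta!r}")
        if self.etot is not None:
            _check_positive(etot=self.etot)
        object.__setattr__(self, "s_unit", canonical_unit(self.s_unit))
        object.__setattr__(self, "x_unit", canonical_unit(self.x_unit))

    @property
    def no_ternary_complex(self) -> bool:
        """True in the linear (alpha or KX infinite) limit: X never joins ES."""
        return math.isinf(self.alpha) or math.isinf(self.kx)

    def with_units(self, s_unit: str | None = None, x_unit: str | None = None) -> "KineticParameters":
        """Return an equivalent parameter set expressed in other units."""
        out = self
        if s_unit is not None and canonical_unit(s_unit) != self.s_unit:
            out = replace(out, km=convert(out.km, out.s_unit, s_unit), s_unit=canonical_unit(s_unit))
        if x_unit is not None and canonical_unit(x_unit) != out.x_unit:
            kx = convert(out.kx, out.x_unit, x_unit) if math.isfinite(out.kx) else out.kx
            etot = None if out.etot is None else convert(out.etot, out.x_unit, x_unit)
            out = replace(out, kx=kx, etot=etot, x_unit=canonical_unit(x_unit))
        return out


@dataclass(frozen=True)
class MicroscopicRates:
    """Mass-action rates of the four-state modifier scheme.

    E+S <-> ES (k1, k2), ES -> E+P (k3), E+X <-> EX (k4, k5),
    ES+X <-> EXS (dissociation constant alpha*KX, association rate k4),
    EX+S <-> EXS (dissociation constant alpha*KS, association rate k1),
    EXS -> EX+P (beta*k3).  Using the same alpha on both edges closes
    the thermodynamic box exactly.

    Concentration unit is ``conc_unit`` (association rates are per that
    unit per second).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    alpha: float
    beta: float
    conc_unit: str = "uM"

    def __post_init__(self):
        _check_positive(k1=self.k1, k2=self.k2, k3=self.k3, k4=self.k4, k5=self.k5, alpha=self.alpha)
        if not (self.beta >= 0):
            raise ValueError(f"beta must be >= 0, got {self.beta!r}")
        object.__setattr__(self, "conc_unit", canonical_unit(self.conc_unit))

    @property
    def ks(self) -> float:
        """Substrate dissociation constant KS = k2/k1."""
        return self.k2 / self.k1

    @property
    def kx(self) -> float:
        """Modifier dissociation constant KX = k5/k4."""
        return self.k5 / self.k4

    @property
    def km(self) -> float:
        """Briggs-Haldane Michaelis constant (k2+k3)/k1."""
        return (self.k2 + self.k3) / self.k1

    @property
    def kcat(self) -> float:
        return self.k3

    @classmethod
    def from_kinetic_parameters(cls, p: KineticParameters, scale: float = 1e4) -> "MicroscopicRates":
        """Build rates consistent with ``p`` in the rapid-equilibrium limit.

        ``scale`` sets how much faster binding is than the fastest
        catalytic step (kcat, or beta*kcat for activating modifiers):
        k1*Km = scale*kc and k5 = scale*kc with kc = kcat*max(1, beta).
        Km is matched exactly ((k2+k3)/k1 == p.km); KS then differs from
        Km by a relative 1/(scale*max(1, beta)), which is the price of
        the Km parameterization and vanishes as scale grows.  All
        concentrations are expressed in ``p.x_unit``.
        """
        if p.no_ternary_complex:
            raise ValueError("microscopic rates undefined in the no-ternary-complex limit")
        km = convert(p.km, p.s_unit, p.x_unit)
        k3 = p.kcat
        kc = k3 * max(1.0, p.beta)
        k1 = scale * kc / km
        k2 = k1 * km - k3
        if k2 <= 0:
            raise ValueError("scale too small: k2 = k1*Km - k3 must stay positive")
        k5 = scale * kc
        k4 = k5 / p.kx
        return cls(k1=k1, k2=k2, k3=k3, k4=k4, k5=k5, alpha=p.alpha, beta=p.beta, conc_unit=p.x_unit)


@dataclass(frozen=True)
class SESParameters:
    """Substrate-inhibition (substrate-enzyme-substrate complex) parameters.

    v/Etot = Vmax_over_Etot * S / (Km + S + S^2/Ksi), optionally with the
    inhibition term scaled by (1 + X/Kx_ses) when a modifier deepens the
    high-substrate downturn.  ``ksi = inf`` recovers plain
    Michaelis-Menten.
    """

    vmax_over_etot: float
    km: float
    ksi: float
    kx_ses: float | None = None
    s_unit: str = "uM"
    x_unit: str = "uM"

    def __post_init__(self):
        _check_positive(vmax_over_etot=self.vmax_over_etot, km=self.km)
        if not (self.ksi > 0):
            raise ValueError(f"ksi must be positive (inf allowed), got {self.ksi!r}")
        if self.kx_ses is not None:
            _check_positive(kx_ses=self.kx_ses)
        object.__setattr__(self, "s_unit", canonical_unit(self.s_unit))
        object.__setattr__(self, "x_unit", canonical_unit(self.x_unit))
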