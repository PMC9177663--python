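"""Classification of hyperbolic modifier mechanisms from (alpha, beta).

A nonessential modifier acts through two components: a *specific*
(binding, competitive-like) component governed by alpha, and a
*catalytic* (turnover, uncompetitive-like) component governed by beta.
``classify`` maps a fitted (alpha, beta) pair onto the canonical label
for its mechanism — e.g. "hyperbolic predominantly specific inhibition"
— using a log-distance-from-neutrality rule to decide which component
dominates.  Label strings are a stable output contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["MechanismCall", "classify"]

_INHIBITORY = "inhibitory"
_ACTIVATING = "activating"
_ABSENT = "absent"


@dataclass(frozen=True)
class MechanismCall:
    """Outcome of classifying an (alpha, beta) pair.

    ``specific_component``: effect through binding (alpha>1 inhibitory,
    alpha<1 activating, alpha~1 absent).  ``catalytic_component``:
    effect through turnover (beta<1 inhibitory, beta>1 activating,
    beta~1 absent).  ``dominance``: which component lies further from
    neutrality on a log scale ("specific" | "catalytic" | "balanced").
    ``label`` is a pure function of the components, the dominance and —
    for discordant component signs only — the net direction at the
    caller's reference substrate concentration.  ``linear_flag`` marks
    the beta=0 boundary case (complete, non-hyperbolic inhibition).
    """

    specific_component: str
    catalytic_component: str
    dominance: str
    label: str
    tolerance: float
    linear_flag: bool = False


def _component(value: float, epsilon: float, *, inhibitory_above_one: bool) -> str:
    if abs(math.log(value)) <= epsilon:
        return _ABSENT
    if value > 1:
        return _INHIBITORY if inhibitory_above_one else _ACTIVATING
    return _ACTIVATING if inhibitory_above_one else _INHIBITORY


def _near(a: float, b: float, epsilon: float) -> bool:
    return abs(a - b) / max(a, b) <= epsilon if max(a, b) > 0 else True


def classify(alpha: float, beta: float, epsilon: float = 0.05, *,
             reference_s_over_km: float | None = None,
             epsilon_equality: float | None = None) -> MechanismCall:
    """Classify a hyperbolic modifier mechanism from (alpha, beta).

    Parameters
    ----------
    alpha, beta : float
        Equilibrium coupling and catalytic coefficients.
    epsilon : float
        Relative tolerance for "approximately equal" decisions
        (alpha ~ beta, alpha ~ 1, beta ~ 1 and dominance ties);
        must lie in (0, 0.5).
    reference_s_over_km : float, optional
        Reference substrate concentration in units of Km.  Required only
        when the two components pull in opposite directions, where the
        net direction is the sign of beta*(1+s) - (alpha+s) at s = S/Km.
    epsilon_equality : float, optional
        Separate tolerance for the alpha ~ beta (coupled, purely
        catalytic) test.  Callers classifying *fitted* values can widen
        this to the estimation uncertainty of ln(alpha/beta) so that a
        coupled mechanism is not mislabelled mixed on noise alone;
        defaults to ``epsilon``.

    Notes
    -----
    alpha ~ beta is checked first so that an exactly coupled pair (the
    purely catalytic, "uncompetitive-like" case where modifier binding
    and turnover scale together) is labelled catalytic even when both
    lie far from 1.  beta = 0 falls outside the hyperbolic family and is
    flagged as complete (linear) catalytic inhibition.
    """
    if not alpha > 0:
        raise ValueError(f"alpha must be > 0, got {alpha!r}")
    if not beta >= 0:
        raise ValueError(f"beta must be >= 0, got {beta!r}")
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must lie in (0, 0.5), got {epsilon!r}")
    eps_eq = epsilon if epsilon_equality is None else epsilon_equality
    if not 0 < eps_eq < 0.5:
        raise ValueError(f"epsilon_equality must lie in (0, 0.5), got {eps_eq!r}")

    if beta == 0:
        spec = _component(alpha, epsilon, inhibitory_above_one=True)
        return MechanismCall(
            specific_component=spec, catalytic_component=_INHIBITORY,
            dominance="catalytic",
            label="complete (linear) catalytic inhibition",
            tolerance=epsilon, linear_flag=True)

    alpha_neutral = abs(math.log(alpha)) <= epsilon
    beta_neutral = abs(math.log(beta)) <= epsilon

    # purely catalytic: alpha == beta (binding and turnover coupled)
    if _near(alpha, beta, eps_eq):
        if beta_neutral and alpha_neutral:
            return MechanismCall(_ABSENT, _ABSENT, "balanced", "no modification", epsilon)
        direction = "activation" if beta > 1 else "inhibition"
        cat = _ACTIVATING if beta > 1 else _INHIBITORY
        return MechanismCall(_ABSENT, cat, "catalytic",
                             f"hyperbolic catalytic {direction}", epsilon)

    spec = _ABSENT if alpha_neutral else (_INHIBITORY if alpha > 1 else _ACTIVATING)
    cat = _ABSENT if beta_neutral else (_INHIBITORY if beta < 1 else _ACTIVATING)

    if spec == _ABSENT and cat == _ABSENT:
        return MechanismCall(spec, cat, "balanced", "no modification", epsilon)
    if spec == _ABSENT:
        direction = "activation" if cat == _ACTIVATING else "inhibition"
        return MechanismCall(spec, cat, "catalytic",
                             f"hyperbolic catalytic {direction}", epsilon)
    if cat == _ABSENT:
        direction = "inhibition" if spec == _INHIBITORY else "activation"
        return MechanismCall(spec, cat, "specific",
                             f"hyperbolic specific {direction}", epsilon)

    # mixed: both components act
    d_spec, d_cat = abs(math.log(alpha)), abs(math.log(beta))
    if abs(d_spec - d_cat) / max(d_spec, d_cat) <= epsilon:
        dominance = "balanced"
    else:
        dominance = "specific" if d_spec > d_cat else "catalytic"

    if spec == cat:  # concordant: both inhibitory or both activating
        direction = "inhibition" if spec == _INHIBITORY else "activation"
    else:  # discordant: net direction depends on the substrate level
        if reference_s_over_km is None:
            raise ValueError(
                "components act in opposite directions; pass reference_s_over_km "
                "(S/Km) so the net direction sign(beta*(1+s) - (alpha+s)) is defined")
        s = float(reference_s_over_km)
        net = beta * (1.0 + s) - (alpha + s)
        direction = "activation" if net > 0 else "inhibition" if net < 0 else "silent"

    if dominance == "balanced":
        label = f"hyperbolic mixed {direction}"
    else:
        label = f"hyperbolic predominantly {dominance} {direction}"
    return MechanismCall(spec, cat, dominance, label, epsilon)
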