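"""Mass-action ODE oracle for the four-state modifier scheme.

Integrates the full mass-action system over {E, ES, EX, EXS} at fixed
(excess) S and X until the state distribution stops changing, and
reports the turnover flux k3*[ES] + beta*k3*[EXS].  Used as an
independent check of the closed-form laws: in the rapid-equilibrium
limit (binding rates much faster than catalysis) the steady state
coincides with the hyperbolic modifier law.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import MicroscopicRates
from .units import require_same_unit

__all__ = ["OracleConvergenceError", "ode_oracle_velocity", "steady_state_fractions"]


class OracleConvergenceError(RuntimeError):
    """Steady state not reached within the integration budget."""


def _rhs(t, y, s, x, r: MicroscopicRates):
    e, es, ex, exs = y
    # ES+X <-> EXS with Kd alpha*KX (on-rate k4); EX+S <-> EXS with
    # Kd alpha*KS (on-rate k1): same alpha on both edges closes the box.
    k_off_esx = r.alpha * r.kx * r.k4
    k_off_exs = r.alpha * r.ks * r.k1
    f_es = r.k1 * e * s - (r.k2 + r.k3) * es
    f_ex = r.k4 * e * x - r.k5 * ex
    f_bind_es_x = r.k4 * es * x - k_off_esx * exs
    f_bind_ex_s = r.k1 * ex * s - k_off_exs * exs
    d_es = f_es - f_bind_es_x
    d_ex = f_ex - f_bind_ex_s + r.beta * r.k3 * exs
    d_exs = f_bind_es_x + f_bind_ex_s - r.beta * r.k3 * exs
    # -f_es already returns the k3*[ES] catalytic flux to E (ES -> E + P)
    d_e = -f_es - f_ex
    return [d_e, d_es, d_ex, d_exs]


def steady_state_fractions(s: float, x: float, r: MicroscopicRates,
                           ctol: float = 1e-10, max_doublings: int = 12):
    """Integrate to steady state; return state fractions (E, ES, EX, EXS)/Etot.

    The integration horizon starts at a few hundred relaxation times of
    the slowest first-order step and doubles until two successive
    checkpoints agree to within ``ctol`` in every state fraction.
    Raises :class:`OracleConvergenceError` on failure — never a silent
    value.
    """
    if s < 0 or x < 0:
        raise ValueError("S and X must be >= 0")
    y = np.array([1.0, 0.0, 0.0, 0.0])
    slow = min(r.k3 if r.k3 > 0 else np.inf,
               r.beta * r.k3 if r.beta > 0 else np.inf,
               r.k2, r.k5)
    horizon = 100.0 / slow
    t = 0.0
    prev = None
    for _ in range(max_doublings):
        sol = solve_ivp(_rhs, (t, t + horizon), y, args=(s, x, r),
                        method="LSODA", rtol=1e-11, atol=1e-13)
        if not sol.success:
            raise OracleConvergenceError(f"ODE integration failed: {sol.message}")
        t += horizon
        y = sol.y[:, -1]
        if prev is not None and np.max(np.abs(y - prev)) < ctol:
            return y
        prev = y
        horizon *= 2.0
    raise OracleConvergenceError(
        f"state fractions still changing by more than {ctol:g} after "
        f"{max_doublings} horizon doublings")


def ode_oracle_velocity(s: float, x: float, r: MicroscopicRates,
                        etot: float = 1.0, *, conc_unit: str | None = None,
                        ctol: float = 1e-10) -> float:
    """Steady-state velocity k3*([ES] + beta*[EXS]) of the full scheme.

    ``s`` and ``x`` must be in ``r.conc_unit`` (pass ``conc_unit`` to
    have this asserted).  Returns v/Etot in s^-1 for ``etot=1``, else
    the absolute rate in ``r.conc_unit`` per second.
    """
    if conc_unit is not None:
        require_same_unit(conc_unit, r.conc_unit, "oracle concentrations")
    frac = steady_state_fractions(float(s), float(x), r, ctol=ctol)
    return float(etot * r.k3 * (frac[1] + r.beta * frac[3]))
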