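"""Nonlinear estimation of kinetic parameters from velocity data.

Four fitting surfaces, all driven by bounded least squares on
log-transformed (strictly positive) parameters with a small fixed-seed
multi-start:

* :func:`fit_michaelis_menten` — one Michaelis-Menten fit at a single
  modifier level (kcat, Km);
* :func:`fit_michaelis_menten_family` — independent MM fits per modifier
  level, the apparent-parameter / catalytic-efficiency view;
* :func:`fit_general_modifier_global` — one global fit of the hyperbolic
  modifier law over the whole (S, X) grid for (kcat, Km, KX, alpha,
  beta), with the mechanism classification attached;
* :func:`fit_dose_response` — the mechanistic three-parameter hyperbola
  v = (v0 + vinf*X/X50)/(1 + X/X50) for AC50/IC50 at fixed S;
* :func:`fit_ses` — substrate-inhibition (SES) kinetics, optionally with
  the modifier coupling that deepens the high-substrate downturn.

Velocities are expected pre-normalized by enzyme concentration (s^-1)
unless noted; standard errors come from the Jacobian at the optimum via
the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy import stats

from . import laws
from .params import KineticParameters, SESParameters
from .taxonomy import MechanismCall, classify
from .units import canonical_unit, require_same_unit

__all__ = [
    "VelocityGrid", "MMFit", "GlobalModifierFit", "DoseResponseFit", "SESFit",
    "FitError", "FlatResponseError",
    "fit_michaelis_menten", "fit_michaelis_menten_family",
    "fit_general_modifier_global", "fit_dose_response", "fit_ses",
]

_SE_BLOWUP_LOG = 10.0  # log-scale SE beyond which a parameter is unidentifiable


class FitError(RuntimeError):
    """Fit failed to converge or the design cannot identify the model."""


class FlatResponseError(FitError):
    """Dose-response data show no modification beyond the noise floor."""


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class VelocityGrid:
    """Replicate velocities over an (S, X) grid.

    ``s``, ``x``, ``v`` are parallel arrays (one entry per well);
    ``v`` is v/Etot in s^-1.  ``replicate`` indexes repeats of the same
    (S, X) condition.
    """

    s: np.ndarray
    x: np.ndarray
    v: np.ndarray
    replicate: np.ndarray | None = None
    etot: float | None = None
    s_unit: str = "mM"
    x_unit: str = "uM"

    def __post_init__(self):
        s = np.asarray(self.s, float)
        x = np.asarray(self.x, float)
        v = np.asarray(self.v, float)
        if not (s.shape == x.shape == v.shape) or s.ndim != 1:
            raise ValueError("s, x, v must be 1-D arrays of equal length")
        rep = self.replicate
        rep = np.zeros(s.size, int) if rep is None else np.asarray(rep, int)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "replicate", rep)
        object.__setattr__(self, "s_unit", canonical_unit(self.s_unit))
        object.__setattr__(self, "x_unit", canonical_unit(self.x_unit))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, etot: float | None = None) -> "VelocityGrid":
        """Build from the velocity CSV layout (columns S0, X, replicate, v)."""
        return cls(s=frame["S0"].to_numpy(float), x=frame["X"].to_numpy(float),
                   v=frame["v"].to_numpy(float),
                   replicate=frame["replicate"].to_numpy(int) if "replicate" in frame else None,
                   etot=etot,
                   s_unit=str(frame["s_unit"].iloc[0]) if "s_unit" in frame else "mM",
                   x_unit=str(frame["x_unit"].iloc[0]) if "x_unit" in frame else "uM")

    @property
    def x_levels(self) -> np.ndarray:
        return np.unique(self.x)

    def at_x(self, x_level: float) -> tuple[np.ndarray, np.ndarray]:
        """(S, v) arrays for one modifier level."""
        m = self.x == x_level
        return self.s[m], self.v[m]

    def replicate_sd(self) -> np.ndarray | None:
        """Per-well SD of v under a pooled-CV noise model; None when any
        condition has < 2 replicates or zero scatter.

        Replicate scatter in plate assays is close to a constant
        coefficient of variation, so instead of the raw (noisy, n~6)
        per-condition SD the CV is pooled across all conditions and the
        per-well SD is pooled_cv * condition mean.
        """
        df = pd.DataFrame({"s": self.s, "x": self.x, "v": self.v})
        g = df.groupby(["s", "x"])["v"]
        sd = g.transform("std")
        n = g.transform("count")
        mean = g.transform("mean")
        if (n < 2).any() or (sd <= 0).any() or sd.isna().any() or (mean <= 0).any():
            return None
        pooled_cv = float((sd / mean).mean())
        if pooled_cv <= 0:
            return None
        return pooled_cv * mean.to_numpy(float)


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten estimates at one modifier level."""

    x: float
    kcat_hat: float
    km_hat: float
    kcat_se: float
    km_se: float
    n_points: int
    converged: bool = True
    flags: tuple = ()
    s_unit: str = "mM"
    x_unit: str = "uM"

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km, recomputed from the estimates."""
        return self.kcat_hat / self.km_hat


@dataclass(frozen=True)
class GlobalModifierFit:
    """Global (kcat, Km, KX, alpha, beta) fit with classification."""

    params: KineticParameters
    se: dict
    mechanism: MechanismCall
    rss: float
    n_obs: int
    n_starts_converged: int
    converged: bool
    flags: tuple = ()


@dataclass(frozen=True)
class DoseResponseFit:
    """Hyperbolic v-vs-X fit at fixed S: asymptotes and midpoint."""

    s_fixed: float
    v0_hat: float
    vinf_hat: float
    x50_hat: float
    x50_se: float
    n_points: int
    x_unit: str = "uM"

    @property
    def direction(self) -> str:
        return "activation" if self.vinf_hat > self.v0_hat else "inhibition"

    @property
    def half_effect_kind(self) -> str:
        """"AC50" for activation, "IC50" for inhibition."""
        return "AC50" if self.direction == "activation" else "IC50"


@dataclass(frozen=True)
class SESFit:
    """Substrate-inhibition fit (optionally modifier-coupled)."""

    params: SESParameters
    se: dict
    rss: float
    n_obs: int
    converged: bool
    flags: tuple = ()


# ---------------------------------------------------------------------------
# shared driver

def _multistart_log_ls(residual_fn, seeds_log, *, max_nfev=2000):
    """Run bounded least squares from several log-space seeds.

    Returns (best result, number converged).  Best = lowest cost; ties
    (within 1e-12 relative) broken by smallest parameter log-norm.
    """
    best, n_ok = None, 0
    for seed in seeds_log:
        try:
            res = least_squares(residual_fn, np.asarray(seed, float),
                                method="trf", xtol=1e-14, ftol=1e-14,
                                gtol=1e-14, max_nfev=max_nfev)
        except Exception:
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            continue
        n_ok += 1
        if best is None:
            best = res
            continue
        if res.cost < best.cost * (1 - 1e-12):
            best = res
        elif abs(res.cost - best.cost) <= 1e-12 * max(best.cost, 1e-300):
            if np.linalg.norm(res.x) < np.linalg.norm(best.x):
                best = res
    if best is None:
        raise FitError("no multi-start seed converged")
    return best, n_ok


def _log_se(res, n_obs):
    """Delta-method SEs of log-parameters from the Jacobian at optimum."""
    n_par = res.x.size
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.inf)
    return se


def _log_ratio_se(res, n_obs, i, j):
    """SE of the difference of two log-parameters (delta method)."""
    dof = max(n_obs - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
    except np.linalg.LinAlgError:
        return np.inf
    var = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
    return float(np.sqrt(max(var, 0.0)))


_JITTER_RNG_SEED = 20230405  # fixed: multi-start jitter is part of the algorithm


def _jittered(seed_log, n_extra=3, spread=0.7):
    rng = np.random.default_rng(_JITTER_RNG_SEED)
    seeds = [np.asarray(seed_log, float)]
    for _ in range(n_extra):
        seeds.append(seeds[0] + rng.normal(0.0, spread, size=len(seed_log)))
    return seeds


# ---------------------------------------------------------------------------
# Michaelis-Menten

def _lineweaver_burk_seed(s, v):
    """Seed (kcat, Km) from the double-reciprocal linearization."""
    m = v > 0
    if m.sum() >= 2 and np.ptp(1.0 / s[m]) > 0:
        res = stats.linregress(1.0 / s[m], 1.0 / v[m])
        if res.intercept > 0 and res.slope > 0:
            return 1.0 / res.intercept, res.slope / res.intercept
    return float(1.2 * np.max(v)), float(np.median(s))


def fit_michaelis_menten(s, v, x: float = 0.0, *, s_unit: str = "mM",
                         x_unit: str = "uM") -> MMFit:
    """Nonlinear least squares of v = kcat*S/(Km+S).

    ``v`` must be v/Etot in s^-1.  Multi-start from the
    Lineweaver-Burk seed plus three jittered seeds; a Km estimate
    pushed far outside the sampled S range is flagged
    "poorly determined".
    """
    s = np.asarray(s, float)
    v = np.asarray(v, float)
    if np.unique(s).size < 4:
        raise FitError(f"need >= 4 distinct substrate levels, got {np.unique(s).size}")
    if (v > 0).sum() < 3:
        raise FitError("need positive velocities at >= 3 substrate levels")
    if np.ptp(v) == 0:
        raise FitError("velocities show no substrate dependence; Km unidentifiable")

    def resid(theta):
        kcat, km = np.exp(theta)
        return kcat * s / (km + s) - v

    kcat0, km0 = _lineweaver_burk_seed(s, v)
    best, _ = _multistart_log_ls(resid, _jittered([math.log(kcat0), math.log(km0)]))
    kcat_hat, km_hat = np.exp(best.x)
    se_log = _log_se(best, s.size)
    flags = []
    if km_hat > 100 * np.max(s) or km_hat < np.min(s[s > 0], initial=np.inf) / 100:
        flags.append("poorly determined")
    if np.any(se_log > _SE_BLOWUP_LOG):
        flags.append("se_blowup")
    return MMFit(x=float(x), kcat_hat=float(kcat_hat), km_hat=float(km_hat),
                 kcat_se=float(kcat_hat * se_log[0]), km_se=float(km_hat * se_log[1]),
                 n_points=int(s.size), converged=True, flags=tuple(flags),
                 s_unit=s_unit, x_unit=x_unit)


def fit_michaelis_menten_family(grid: VelocityGrid) -> tuple[list[MMFit], dict]:
    """Independent MM fit at every modifier level, ordered by X.

    Returns (fits, errors): levels whose fit fails are collected in
    ``errors`` (X -> message) while the others proceed.
    """
    fits, errors = [], {}
    for x_level in grid.x_levels:
        s, v = grid.at_x(x_level)
        try:
            fits.append(fit_michaelis_menten(s, v, x=x_level,
                                             s_unit=grid.s_unit, x_unit=grid.x_unit))
        except (FitError, ValueError) as exc:
            errors[float(x_level)] = str(exc)
    return fits, errors


# ---------------------------------------------------------------------------
# global modifier fit

def _global_seed(grid: VelocityGrid):
    """Seed (kcat, Km, KX, alpha, beta) from the per-X MM family."""
    fits, _ = fit_michaelis_menten_family(grid)
    by_x = {f.x: f for f in fits}
    if 0.0 not in by_x:
        raise FitError("global fit needs a zero-modifier (X=0) condition")
    base = by_x[0.0]
    kcat0, km0 = base.kcat_hat, base.km_hat
    xs = sorted(x for x in by_x if x > 0)
    if not xs:
        raise FitError("global fit needs modifier levels beyond X=0")
    top = by_x[xs[-1]]
    alpha0 = float(np.clip(top.km_hat / km0, 1e-3, 1e3))
    beta0 = float(np.clip(top.kcat_hat / kcat0, 1e-3, 1e3))
    # KX seed: X where Km_app has moved halfway to its top-level value
    half = 0.5 * (km0 + top.km_hat)
    kx0 = None
    increasing = top.km_hat >= km0
    for x_level in xs:
        km_app = by_x[x_level].km_hat
        if (km_app >= half) == increasing:
            kx0 = x_level
            break
    if kx0 is None or kx0 <= 0:
        kx0 = float(np.median(xs))
    if abs(alpha0 - 1) < 1e-3 and abs(beta0 - 1) < 1e-3:
        # apparent parameters barely move; still try, seeded neutrally
        alpha0 = beta0 = 1.0
    return np.log([kcat0, km0, kx0, alpha0, beta0])


def fit_general_modifier_global(grid: VelocityGrid, *, epsilon: float = 0.05) -> GlobalModifierFit:
    """Global weighted least squares of the hyperbolic modifier law.

    Fits (kcat, Km, KX, alpha, beta) over all (S, X) wells at once.
    Weights are inverse replicate SD when every condition has >= 2
    replicates with scatter, else unweighted.  Needs >= 3 modifier
    levels including X=0 and >= 4 substrate levels.  Structural
    non-identifiability (e.g. no X coverage near KX) surfaces as an
    ``se_blowup:<param>`` flag, never silently.
    """
    if np.unique(grid.x).size < 3 or 0.0 not in grid.x_levels:
        raise FitError("need >= 3 modifier levels including X = 0")
    if np.unique(grid.s).size < 4:
        raise FitError("need >= 4 substrate levels")
    sd = grid.replicate_sd()
    w = 1.0 / sd if sd is not None else np.ones(grid.v.size)

    s_arr, x_arr, v_arr = grid.s, grid.x, grid.v

    def resid(theta):
        kcat, km, kx, alpha, beta = np.exp(theta)
        p = KineticParameters(kcat=kcat, km=km, kx=kx, alpha=alpha, beta=beta,
                              s_unit=grid.s_unit, x_unit=grid.x_unit)
        return w * (laws.general_modifier_velocity(s_arr, x_arr, p) - v_arr)

    seed0 = _global_seed(grid)
    best, n_ok = _multistart_log_ls(resid, _jittered(seed0), max_nfev=5000)
    kcat, km, kx, alpha, beta = np.exp(best.x)
    se_log = _log_se(best, grid.v.size)
    names = ("kcat", "km", "kx", "alpha", "beta")
    values = (kcat, km, kx, alpha, beta)
    se = {n: float(val * sl) for n, val, sl in zip(names, values, se_log)}
    flags = tuple(f"se_blowup:{n}" for n, sl in zip(names, se_log) if sl > _SE_BLOWUP_LOG)
    p_hat = KineticParameters(kcat=float(kcat), km=float(km), kx=float(kx),
                              alpha=float(alpha), beta=float(beta),
                              etot=grid.etot, s_unit=grid.s_unit, x_unit=grid.x_unit)
    # the alpha ~ beta (coupled-pair) decision uses the fit's own
    # uncertainty on ln(alpha/beta) so noise alone cannot split a
    # genuinely coupled mechanism into "mixed"
    se_log_ratio = _log_ratio_se(best, grid.v.size, i=3, j=4)
    eps_eq = float(np.clip(max(epsilon, 2.0 * se_log_ratio), epsilon, 0.3))
    mech = classify(p_hat.alpha, p_hat.beta, epsilon,
                    reference_s_over_km=float(np.median(grid.s)) / p_hat.km,
                    epsilon_equality=eps_eq)
    return GlobalModifierFit(params=p_hat, se=se, mechanism=mech,
                             rss=float(2 * best.cost), n_obs=int(grid.v.size),
                             n_starts_converged=n_ok, converged=True, flags=flags)


# ---------------------------------------------------------------------------
# dose-response

def fit_dose_response(x, v, s_fixed: float, *, x_unit: str = "uM",
                      noise_floor: float | None = None) -> DoseResponseFit:
    """Fit v = (v0 + vinf*X/X50)/(1 + X/X50) to a modifier titration.

    The modifier law is exactly hyperbolic in X at fixed S, so this
    mechanistic form (not a Hill equation) is the correct titration
    model; its midpoint X50 is the AC50 (activation) or IC50
    (inhibition).  Needs >= 5 modifier levels whose positive values
    span >= 2 decades.  A response flat to within ``noise_floor``
    (default: 2 x the replicate scatter, else 0.1% of the mean) raises
    :class:`FlatResponseError` ("no modification detected").
    """
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    if np.unique(x).size < 5:
        raise FitError(f"need >= 5 modifier levels, got {np.unique(x).size}")
    pos = np.unique(x[x > 0])
    if pos.size < 2 or pos.max() / pos.min() < 100:
        raise FitError("positive modifier levels must span >= 2 decades")

    # group means define the response span; replicate scatter the floor
    df = pd.DataFrame({"x": x, "v": v}).groupby("x")["v"]
    means, sds, counts = df.mean(), df.std(ddof=1), df.count()
    if noise_floor is None:
        if (counts >= 2).all() and sds.notna().all():
            noise_floor = 2.0 * float(sds.mean())
        else:
            noise_floor = 1e-3 * float(np.abs(means).mean())
    if float(means.max() - means.min()) <= noise_floor:
        raise FlatResponseError("no modification detected: velocity flat across the titration")

    v0_seed = float(means.iloc[0])
    vinf_seed = float(means.iloc[-1])
    mid = 0.5 * (v0_seed + vinf_seed)
    crossings = means.index[np.argmin(np.abs(means.to_numpy() - mid))]
    x50_seed = float(crossings) if crossings > 0 else float(np.median(pos))

    def resid(theta):
        v0, vinf = theta[0], theta[1]
        x50 = math.exp(theta[2])
        return (v0 + vinf * x / x50) / (1.0 + x / x50) - v

    seeds = [[v0_seed, vinf_seed, math.log(x50_seed)]]
    for fac in (0.1, 10.0):
        seeds.append([v0_seed, vinf_seed, math.log(x50_seed * fac)])
    best, _ = _multistart_log_ls(resid, seeds)
    v0_hat, vinf_hat = best.x[0], best.x[1]
    x50_hat = math.exp(best.x[2])
    se = _log_se(best, x.size)
    return DoseResponseFit(s_fixed=float(s_fixed), v0_hat=float(v0_hat),
                           vinf_hat=float(vinf_hat), x50_hat=float(x50_hat),
                           x50_se=float(x50_hat * se[2]), n_points=int(x.size),
                           x_unit=x_unit)


# ---------------------------------------------------------------------------
# substrate inhibition (SES)

def fit_ses(s, v, x=None, *, s_unit: str = "uM", x_unit: str = "uM") -> SESFit:
    """Fit substrate-inhibition kinetics, optionally modifier-coupled.

    With ``x`` absent (or all zero) fits (Vmax, Km, Ksi); with several
    modifier levels additionally fits the SES-branch coupling constant
    Kx_ses shared across the grid.  Ksi is only identifiable when the
    sampled S range extends beyond the velocity peak: if the largest
    mean velocity sits at the largest S, the fit proceeds but carries a
    "ksi_unidentifiable" flag.
    """
    s = np.asarray(s, float)
    v = np.asarray(v, float)
    x = np.zeros_like(s) if x is None else np.asarray(x, float)
    if not (s.shape == v.shape == x.shape):
        raise ValueError("s, v (and x) must have equal shapes")
    with_modifier = np.unique(x).size > 1

    # peak-location identifiability check on the X=0 (or lowest-X) slice
    x_ref = np.min(x)
    m = x == x_ref
    means = pd.DataFrame({"s": s[m], "v": v[m]}).groupby("s")["v"].mean()
    flags = []
    if means.idxmax() == means.index.max():
        flags.append("ksi_unidentifiable")

    vmax0 = float(2.0 * means.max())
    km0 = float(means.idxmax())
    ksi0 = float(means.index.max())

    if with_modifier:
        def resid(theta):
            vmax, km, ksi, kxs = np.exp(theta)
            q = SESParameters(vmax_over_etot=vmax, km=km, ksi=ksi, kx_ses=kxs,
                              s_unit=s_unit, x_unit=x_unit)
            return laws.ses_velocity_with_modifier(s, x, q) - v
        seed0 = np.log([vmax0, km0, ksi0, float(np.median(np.unique(x)[1:]))])
        names = ("vmax_over_etot", "km", "ksi", "kx_ses")
    else:
        def resid(theta):
            vmax, km, ksi = np.exp(theta)
            q = SESParameters(vmax_over_etot=vmax, km=km, ksi=ksi, s_unit=s_unit)
            return laws.ses_velocity(s, q) - v
        seed0 = np.log([vmax0, km0, ksi0])
        names = ("vmax_over_etot", "km", "ksi")

    best, _ = _multistart_log_ls(resid, _jittered(seed0), max_nfev=5000)
    vals = np.exp(best.x)
    se_log = _log_se(best, s.size)
    se = {n: float(val * sl) for n, val, sl in zip(names, vals, se_log)}
    flags.extend(f"se_blowup:{n}" for n, sl in zip(names, se_log) if sl > _SE_BLOWUP_LOG)
    q_hat = SESParameters(vmax_over_etot=float(vals[0]), km=float(vals[1]),
                          ksi=float(vals[2]),
                          kx_ses=float(vals[3]) if with_modifier else None,
                          s_unit=s_unit, x_unit=x_unit)
    return SESFit(params=q_hat, se=se, rss=float(2 * best.cost),
                  n_obs=int(s.size), converged=True, flags=tuple(flags))
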