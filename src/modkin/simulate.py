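"""Synthetic plate-assay generator.

Emulates the two assay formats the analysis is built for:

* chromogenic amino-acid p-nitroanilide (pNA) assays — continuous A405
  reads every 10 s over 30 min, substrate doubling series 0.5-8.0 mM,
  modifier titrations up to 2.0 mM, six replicates per condition;
* the PGP (Pro-Gly-Pro) fluorescamine endpoint assay — substrate
  100-1000 uM, modifier 0-0.32 uM, twenty replicates.

Velocity-level data carry multiplicative Gaussian noise with a chosen
coefficient of variation (default 5%, truncated at +/-4 sigma so signals
stay positive); progress curves integrate true substrate depletion so
the initial-velocity window logic downstream is genuinely exercised.
Concentrations are nominal (no pipetting error model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import laws
from .fitting import VelocityGrid
from .params import KineticParameters, SESParameters
from .signal import ProgressCurve, StandardCurve
from .units import canonical_unit, convert, require_same_unit

__all__ = [
    "AssayDesign", "reference_designs", "recovery_designs", "reference_truths",
    "generate_velocity_grid", "generate_progress_curves",
    "write_plate_files",
]

# 10 ug/mL LTA4H at ~69 kDa; 31.25 ng/mL for the PGP assay
_ETOT_PNA_UM = 0.145
_ETOT_PGP_UM = 4.5e-4

# p-nitroaniline A405 calibration: ~9.9 mM^-1 cm^-1 over a ~0.58 cm
# path for 200 uL in a 96-well plate, plus a small blank offset
DEFAULT_PNA_CURVE = StandardCurve(slope=0.0058, intercept=0.05, concentration_unit="uM")


@dataclass(frozen=True)
class AssayDesign:
    """One plate design: concentration grids, replication and sampling."""

    name: str
    substrate_levels: tuple
    modifier_levels: tuple
    replicates: int
    read_interval: float  # s
    duration: float  # s
    etot: float  # x_unit
    noise_cv: float = 0.05
    s_unit: str = "mM"
    x_unit: str = "uM"
    endpoint: bool = False

    def __post_init__(self):
        if not 0.0 <= self.noise_cv <= 0.2:
            raise ValueError(f"noise_cv must lie in [0, 0.2], got {self.noise_cv!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.substrate_levels or not self.modifier_levels:
            raise ValueError("substrate and modifier level lists must be nonempty")
        object.__setattr__(self, "substrate_levels", tuple(float(s) for s in self.substrate_levels))
        object.__setattr__(self, "modifier_levels", tuple(float(x) for x in self.modifier_levels))
        object.__setattr__(self, "s_unit", canonical_unit(self.s_unit))
        object.__setattr__(self, "x_unit", canonical_unit(self.x_unit))


_PNA_COMMON = dict(replicates=6, read_interval=10.0, duration=1800.0,
                   etot=_ETOT_PNA_UM, noise_cv=0.05, s_unit="mM", x_unit="uM")


def reference_designs() -> dict[str, AssayDesign]:
    """The four standard designs the analysis was built around.

    Three pNA designs (S doubling series 0.5-8.0 mM, six replicates,
    10 s reads, 30 min; substrate-specific modifier titrations) and the
    PGP endpoint design (S 100-1000 uM, X 0-0.32 uM, twenty
    replicates).
    """
    pna_s = (0.5, 1.0, 2.0, 4.0, 8.0)
    designs = {
        "arg-pna": AssayDesign(name="arg-pna", substrate_levels=pna_s,
                               modifier_levels=(0, 10, 20, 40, 60, 80, 100),
                               **_PNA_COMMON),
        "ala-pna": AssayDesign(name="ala-pna", substrate_levels=pna_s,
                               modifier_levels=(0, 0.1, 0.5, 1.0, 5.0, 10.0),
                               **_PNA_COMMON),
        "pro-pna": AssayDesign(name="pro-pna", substrate_levels=pna_s,
                               modifier_levels=(0, 100, 200, 400, 600, 800, 1000, 2000),
                               **_PNA_COMMON),
        "pgp": AssayDesign(name="pgp",
                           substrate_levels=tuple(range(100, 1001, 100)),
                           modifier_levels=(0.0, 0.04, 0.08, 0.16, 0.32),
                           replicates=20, read_interval=300.0, duration=1800.0,
                           etot=_ETOT_PGP_UM, noise_cv=0.05,
                           s_unit="uM", x_unit="uM", endpoint=True),
    }
    return designs


def recovery_designs() -> dict[str, AssayDesign]:
    """Full-range designs for parameter-recovery studies.

    The efficiency-table designs print a per-substrate selection of
    modifier levels; a global (kcat, Km, KX, alpha, beta) fit needs the
    full assay coverage — substrate doubling series 0.5-64 mM and the
    whole 0-2.0 mM modifier titration in doubling steps — to identify
    the ternary-complex branch when alpha*KX lies in the millimolar
    range.  Six replicates, velocity-level sampling.
    """
    s_ext = tuple(0.5 * 2 ** k for k in range(8))  # 0.5 .. 64 mM
    x_full = (0.0,) + tuple(2000.0 / 2 ** k for k in reversed(range(12)))
    return {name: replace(design, substrate_levels=s_ext, modifier_levels=x_full,
                          name=f"{name}-recovery")
            for name, design in reference_designs().items() if not design.endpoint}


def reference_truths() -> dict[str, KineticParameters | SESParameters]:
    """Generating parameter sets paired with :func:`reference_designs`.

    kcat, Km, alpha, beta for the three pNA substrates are the measured
    zero-modifier values of the system this package models; KX is not
    measurable from published tables and is fixed at a plausible value
    per substrate (50, 5 and 200 uM).  The PGP truth is an SES set
    with the modifier coupling that deepens substrate inhibition.
    """
    return {
        "arg-pna": KineticParameters(kcat=24.35, km=18.79, kx=50.0,
                                     alpha=30.39, beta=0.09,
                                     etot=_ETOT_PNA_UM, s_unit="mM", x_unit="uM"),
        "ala-pna": KineticParameters(kcat=1.74, km=1.60, kx=5.0,
                                     alpha=0.82, beta=25.4,
                                     etot=_ETOT_PNA_UM, s_unit="mM", x_unit="uM"),
        "pro-pna": KineticParameters(kcat=0.19, km=0.84, kx=200.0,
                                     alpha=7.88, beta=7.88,
                                     etot=_ETOT_PNA_UM, s_unit="mM", x_unit="uM"),
        "pgp": SESParameters(vmax_over_etot=0.5, km=300.0, ksi=400.0,
                             kx_ses=0.1, s_unit="uM", x_unit="uM"),
    }


def _true_velocity(s, x, truth):
    if isinstance(truth, KineticParameters):
        return laws.general_modifier_velocity(s, x, truth)
    if truth.kx_ses is not None:
        return laws.ses_velocity_with_modifier(s, x, truth)
    return laws.ses_velocity(s, truth)


def _truncated_noise(rng, cv, size):
    """Multiplicative factors 1 + eps, eps ~ N(0, cv^2) truncated at 4 sigma."""
    if cv == 0:
        return np.ones(size)
    eps = rng.normal(0.0, cv, size=size)
    while True:
        bad = np.abs(eps) > 4 * cv
        if not bad.any():
            break
        eps[bad] = rng.normal(0.0, cv, size=int(bad.sum()))
    return 1.0 + eps


def generate_velocity_grid(design: AssayDesign, truth, seed: int) -> VelocityGrid:
    """Noisy replicate velocities straight from the rate law.

    Observed v = v_true * (1 + eps), eps ~ N(0, noise_cv^2) independent
    per replicate; deterministic under a fixed seed.  Velocities are
    v/Etot in s^-1.
    """
    require_same_unit(design.s_unit, truth.s_unit, "substrate levels vs truth Km")
    if isinstance(truth, KineticParameters):
        require_same_unit(design.x_unit, truth.x_unit, "modifier levels vs truth KX")
    rng = np.random.default_rng(seed)
    s_list, x_list, v_list, rep_list = [], [], [], []
    for x in design.modifier_levels:
        for s in design.substrate_levels:
            v_true = _true_velocity(s, x, truth)
            factors = _truncated_noise(rng, design.noise_cv, design.replicates)
            for rep in range(design.replicates):
                s_list.append(s)
                x_list.append(x)
                v_list.append(v_true * factors[rep])
                rep_list.append(rep)
    return VelocityGrid(s=np.array(s_list), x=np.array(x_list), v=np.array(v_list),
                        replicate=np.array(rep_list), etot=design.etot,
                        s_unit=design.s_unit, x_unit=design.x_unit)


def generate_progress_curves(design: AssayDesign, truth, seed: int,
                             curve: StandardCurve = DEFAULT_PNA_CURVE) -> list[ProgressCurve]:
    """Full progress curves with substrate depletion and read noise.

    Integrates d[P]/dt = Etot * law(S0 - P, X) per well (so the early
    window is linear but later reads bend as substrate depletes), maps
    product to signal through the standard curve, and applies
    multiplicative read noise with the design CV to the
    product-proportional part of the signal.  Returned curves carry S0
    in the standard curve's concentration unit.
    """
    require_same_unit(design.s_unit, truth.s_unit, "substrate levels vs truth Km")
    n_reads = int(design.duration // design.read_interval) + 1
    if n_reads < 5:
        raise ValueError("duration too short: fewer than 5 reads per well")
    cu = curve.concentration_unit
    rng = np.random.default_rng(seed)
    times = np.arange(n_reads) * design.read_interval
    curves = []
    well = 0
    for x in design.modifier_levels:
        for s0 in design.substrate_levels:
            s0_cu = convert(s0, design.s_unit, cu)
            # depletion ODE in the curve's concentration unit
            etot_cu = convert(design.etot, design.x_unit, cu)
            s_unit_factor = convert(1.0, cu, design.s_unit)

            def dpdt(t, p, _x=x, _s0=s0_cu):
                s_now = max(_s0 - p[0], 0.0) * s_unit_factor  # back to law units
                return [etot_cu * _true_velocity(s_now, _x, truth)]

            sol = solve_ivp(dpdt, (0.0, times[-1]), [0.0], t_eval=times,
                            method="LSODA", rtol=1e-10, atol=1e-12 * s0_cu)
            if not sol.success:
                raise RuntimeError(f"progress-curve integration failed: {sol.message}")
            product = sol.y[0]
            for rep in range(design.replicates):
                factors = _truncated_noise(rng, design.noise_cv, n_reads)
                signal = curve.intercept + curve.slope * product * factors
                curves.append(ProgressCurve(
                    well_id=f"W{well:04d}", times=times.copy(), signal=signal,
                    s0=s0_cu, x=x, replicate_index=rep,
                    s_unit=cu, x_unit=design.x_unit))
                well += 1
    return curves


def write_plate_files(curves: list[ProgressCurve], data_path, layout_path,
                      substrate: str = "") -> None:
    """Write the long-format kinetic CSV + layout CSV that the signal
    layer reads back (self-closing loop for tests and demos)."""
    data_rows, layout_rows = [], []
    for pc in curves:
        for t, y in zip(pc.times, pc.signal):
            data_rows.append((pc.well_id, t, y))
        layout_rows.append((pc.well_id, substrate, pc.s0, pc.s_unit,
                            pc.x, pc.x_unit, pc.replicate_index))
    pd.DataFrame(data_rows, columns=["well", "time_s", "signal"]).to_csv(
        data_path, index=False)
    pd.DataFrame(layout_rows, columns=["well", "substrate", "S0", "s_unit",
                                       "X", "x_unit", "replicate"]).to_csv(
        layout_path, index=False)
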