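"""Publication-shaped outputs: efficiency tables, fit summaries, plots.

Numeric payloads keep full precision in JSON; the rendered efficiency
table rounds to 2 decimals only at serialization, matching how
catalytic-efficiency tables are conventionally printed.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import laws
from .fitting import DoseResponseFit, GlobalModifierFit, MMFit

__all__ = [
    "efficiency_table", "render_efficiency_table",
    "global_fit_payload", "dose_response_payload", "write_json",
    "plot_mm_family", "plot_lineweaver_burk", "plot_velocity_vs_substrate",
]

SCHEMA_VERSION = "1"


def efficiency_table(fits: list[MMFit]) -> pd.DataFrame:
    """Full-precision per-modifier-level table of MM estimates.

    Columns: X, kcat, kcat_se, Km, Km_se, efficiency (kcat/Km,
    recomputed from the unrounded estimates).
    """
    if not fits:
        raise ValueError("no fits to tabulate")
    rows = sorted(fits, key=lambda f: f.x)
    return pd.DataFrame({
        "X": [f.x for f in rows],
        "kcat": [f.kcat_hat for f in rows],
        "kcat_se": [f.kcat_se for f in rows],
        "Km": [f.km_hat for f in rows],
        "Km_se": [f.km_se for f in rows],
        "efficiency": [f.efficiency for f in rows],
    })


def render_efficiency_table(fits: list[MMFit], decimals: int = 2) -> pd.DataFrame:
    """Presentation view: values rounded (default 2 decimals) as strings."""
    full = efficiency_table(fits)
    fmt = f"{{:.{decimals}f}}"
    out = pd.DataFrame({
        "X": full["X"],
        "kcat": [fmt.format(v) + " ± " + fmt.format(s)
                 for v, s in zip(full["kcat"], full["kcat_se"])],
        "Km": [fmt.format(v) + " ± " + fmt.format(s)
               for v, s in zip(full["Km"], full["Km_se"])],
        "efficiency": [fmt.format(v) for v in full["efficiency"]],
    })
    return out


def global_fit_payload(fit: GlobalModifierFit) -> dict:
    """JSON-ready summary of a global modifier fit."""
    p = fit.params
    return {
        "schema_version": SCHEMA_VERSION,
        "parameters": {"kcat": p.kcat, "km": p.km, "kx": p.kx,
                       "alpha": p.alpha, "beta": p.beta},
        "units": {"km": p.s_unit, "kx": p.x_unit, "kcat": "1/s"},
        "standard_errors": fit.se,
        "mechanism": {
            "label": fit.mechanism.label,
            "specific_component": fit.mechanism.specific_component,
            "catalytic_component": fit.mechanism.catalytic_component,
            "dominance": fit.mechanism.dominance,
            "tolerance": fit.mechanism.tolerance,
        },
        "rss": fit.rss,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "flags": list(fit.flags),
    }


def dose_response_payload(fit: DoseResponseFit) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "s_fixed": fit.s_fixed,
        "v0": fit.v0_hat,
        "vinf": fit.vinf_hat,
        "x50": fit.x50_hat,
        "x50_se": fit.x50_se,
        "x50_unit": fit.x_unit,
        "direction": fit.direction,
        "half_effect_kind": fit.half_effect_kind,
        "n_points": fit.n_points,
    }


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# plots (shape-only diagnostics; nothing downstream parses these)

def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    import matplotlib.pyplot as plt
    plt.close(fig)


def plot_mm_family(grid, fits: list[MMFit], path) -> None:
    """Michaelis-Menten plot: v vs S per modifier level with fitted curves."""
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    s_dense = np.linspace(0, grid.s.max() * 1.05, 200)
    for f in sorted(fits, key=lambda f: f.x):
        s, v = grid.at_x(f.x)
        ax.plot(s, v, "o", ms=3, alpha=0.5)
        ax.plot(s_dense, f.kcat_hat * s_dense / (f.km_hat + s_dense),
                label=f"X={f.x:g} {grid.x_unit}")
    ax.set_xlabel(f"[S] ({grid.s_unit})")
    ax.set_ylabel("v/Etot (1/s)")
    ax.legend(fontsize=7)
    _save(fig, path)


def plot_lineweaver_burk(grid, fits: list[MMFit], path) -> None:
    """Double-reciprocal view of the same family."""
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    for f in sorted(fits, key=lambda f: f.x):
        s, v = grid.at_x(f.x)
        ok = (s > 0) & (v > 0)
        ax.plot(1 / s[ok], 1 / v[ok], "o", ms=3, alpha=0.5, label=f"X={f.x:g}")
    ax.set_xlabel(f"1/[S] (1/{grid.s_unit})")
    ax.set_ylabel("Etot/v (s)")
    ax.legend(fontsize=7)
    _save(fig, path)


def plot_velocity_vs_substrate(grid, path, ses_fit=None) -> None:
    """Velocity-vs-S plot per modifier level (substrate-inhibition shape)."""
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    for x_level in grid.x_levels:
        s, v = grid.at_x(x_level)
        order = np.argsort(s)
        ax.plot(s[order], v[order], "o-", ms=3, alpha=0.6,
                label=f"X={x_level:g} {grid.x_unit}")
    if ses_fit is not None:
        s_dense = np.linspace(grid.s.min(), grid.s.max(), 200)
        ax.plot(s_dense, laws.ses_velocity(s_dense, ses_fit.params), "k--", lw=1)
    ax.set_xlabel(f"[S] ({grid.s_unit})")
    ax.set_ylabel("v/Etot (1/s)")
    ax.legend(fontsize=7)
    _save(fig, path)
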