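"""Current-voltage fitting and bi-ionic permeability analysis.

Slope conductance and reversal potential come from an ordinary
least-squares line through (V, I) points, I = a V + b: the conductance is
1000 a (pS from pA/mV) and E_rev = -b/a, with standard errors from the
usual regression formulas and first-order propagation (including the
slope-intercept covariance) for E_rev.  Because the GHK current is curved,
the default fit window keeps |V| <= 40 mV, where the relation is locally
linear.

Under a bi-ionic condition -- one permeant cation per side at matched
concentration -- the reversal potential reports the permeability ratio:

    P_K / P_Na = ([Na]_bath / [K]_pipette) * exp(E_rev F / RT)

which reduces to exp(E_rev F / RT) at equal concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ghk import IonConditions, ghk_current, ghk_reversal, thermal_voltage_mV

__all__ = [
    "IVDataset",
    "IVFit",
    "fit_iv",
    "bi_ionic_permeability",
    "ghk_reversal",
    "ghk_current",
    "simulate_iv_points",
]

DEFAULT_FIT_WINDOW_MV = 40.0


@dataclass
class IVDataset:
    """Mean-current I/V table: (voltage mV, current pA, sem pA, n)."""

    points: pd.DataFrame

    @classmethod
    def from_arrays(cls, voltage_mV, current_pA, sem_pA=None, n=None) -> "IVDataset":
        v = np.asarray(voltage_mV, dtype=float)
        i = np.asarray(current_pA, dtype=float)
        sem = np.zeros_like(v) if sem_pA is None else np.asarray(sem_pA, dtype=float)
        nn = np.ones_like(v, dtype=int) if n is None else np.asarray(n, dtype=int)
        return cls(pd.DataFrame({"voltage_mV": v, "current_pA": i, "sem_pA": sem, "n": nn}))

    def __post_init__(self):
        df = self.points
        required = {"voltage_mV", "current_pA"}
        if not required.issubset(df.columns):
            raise ValueError(f"I/V table needs columns {sorted(required)}")
        if "sem_pA" not in df.columns:
            df = df.assign(sem_pA=0.0)
        if "n" not in df.columns:
            df = df.assign(n=1)
        if df["voltage_mV"].nunique() < 2:
            raise ValueError("need at least two distinct voltages")
        if (df["sem_pA"] < 0).any() or (df["n"] < 1).any():
            raise ValueError("sem must be >= 0 and n >= 1")
        self.points = df.reset_index(drop=True)


@dataclass
class IVFit:
    """Linear I/V fit: slope conductance (pS) and reversal potential (mV)."""

    slope_conductance: float
    e_rev: float
    slope_conductance_stderr: float
    e_rev_stderr: float
    n_points: int
    voltage_window: float | None


def fit_iv(data: IVDataset, voltage_window: float | None = DEFAULT_FIT_WINDOW_MV) -> IVFit:
    """OLS line through the I/V points; E_rev = -intercept/slope.

    Points with |V| > ``voltage_window`` are excluded (pass None to fit the
    full range).  E_rev's standard error uses first-order propagation of the
    slope/intercept errors including their covariance cov(a,b) = -x_bar
    var(a).  A slope indistinguishable from zero leaves E_rev undefined.
    """
    df = data.points
    if voltage_window is not None:
        inside = df[df["voltage_mV"].abs() <= voltage_window]
        # fall back to the full range when the window leaves too few points
        if inside["voltage_mV"].nunique() >= 2:
            df = inside
        else:
            voltage_window = None
    v = df["voltage_mV"].to_numpy(dtype=float)
    i = df["current_pA"].to_numpy(dtype=float)

    n = len(v)
    vbar = v.mean()
    sxx = np.sum((v - vbar) ** 2)
    a = np.sum((v - vbar) * (i - i.mean())) / sxx
    b = i.mean() - a * vbar
    resid = i - (a * v + b)
    dof = n - 2
    s2 = np.sum(resid**2) / dof if dof > 0 else 0.0
    var_a = s2 / sxx
    var_b = s2 * (1.0 / n + vbar**2 / sxx)
    cov_ab = -vbar * var_a

    se_a = float(np.sqrt(var_a))
    if a == 0.0 or (se_a > 0 and abs(a) < 2.0 * se_a):
        raise ValueError("slope indistinguishable from zero: reversal potential undefined")
    e_rev = -b / a
    # var(-b/a) to first order: (db, da) gradient = (-1/a, b/a^2)
    var_erev = var_b / a**2 + (b**2 / a**4) * var_a - 2.0 * (b / a**3) * cov_ab
    return IVFit(
        slope_conductance=float(1000.0 * a),
        e_rev=float(e_rev),
        slope_conductance_stderr=float(1000.0 * se_a),
        e_rev_stderr=float(np.sqrt(max(var_erev, 0.0))),
        n_points=n,
        voltage_window=voltage_window,
    )


def bi_ionic_permeability(e_rev: float, conditions: IonConditions) -> float:
    """P_K/P_Na from a bi-ionic reversal potential (mV).

    Requires the monovalent bi-ionic layout: K+ the only permeant cation in
    the pipette and Na+ the only one in the bath.
    """
    cations_pipette = {s for s, z, c in conditions.pipette_side if z > 0 and c > 0}
    cations_bath = {s for s, z, c in conditions.bath_side if z > 0 and c > 0}
    if cations_pipette != {"K"} or cations_bath != {"Na"}:
        raise ValueError("bi-ionic analysis requires K+ pipette / Na+ bath")
    k_conc = next(c for s, z, c in conditions.pipette_side if s == "K")
    na_conc = next(c for s, z, c in conditions.bath_side if s == "Na")
    if k_conc <= 0 or na_conc <= 0:
        raise ValueError("bi-ionic concentrations must be positive")
    rt_f = thermal_voltage_mV(conditions.temperature)
    return float((na_conc / k_conc) * np.exp(e_rev / rt_f))


def simulate_iv_points(
    conditions: IonConditions,
    voltages_mV,
    noise_sd: float,
    seed: int,
    p_scale: float | None = None,
) -> IVDataset:
    """GHK-model I/V points with Gaussian measurement noise (one draw each)."""
    from .ghk import DEFAULT_PERMEABILITY_SCALE

    rng = np.random.default_rng(seed)
    v = np.asarray(voltages_mV, dtype=float)
    scale = DEFAULT_PERMEABILITY_SCALE if p_scale is None else p_scale
    i = ghk_current(v, conditions, p_scale=scale)
    if noise_sd > 0:
        i = i + rng.normal(0.0, noise_sd, size=v.shape)
    return IVDataset.from_arrays(v, i, sem_pA=np.full_like(v, noise_sd))
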