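"""Apparent permeability (P_app) from receiver-compartment concentration series.

Applies to diffusion-chamber data from mucosa mounted on Franz cells (0.9 cm
diameter) and from bulk mucus on filter inserts (Transwell, 6.5 mm). The
receiver is sampled repeatedly (200 µL withdrawn and replaced with blank
medium), so the measured concentrations are corrected by mass balance

    Q_i = V_receiver * C_i + V_sample * sum_{j<i} C_j

before the steady-state slope is taken. P_app = (dQ/dt) / (A * C0) in cm/s.
Concentrations below the lower limit of quantification (LLOQ) are censored
and excluded from fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PermeabilityConfig",
    "PappResult",
    "FRANZ_AREA_CM2",
    "TRANSWELL_AREA_CM2",
    "apply_lloq",
    "correct_cumulative",
    "fit_papp",
    "percent_of_control",
]

#: Franz cell, 0.9 cm diameter exposed mucosa.
FRANZ_AREA_CM2 = math.pi * 0.45**2
#: Transwell filter insert, 6.5 mm diameter.
TRANSWELL_AREA_CM2 = math.pi * 0.325**2

#: Minimum coefficient of determination for the steady-state window.
R2_STEADY_STATE = 0.98
#: Minimum number of points in a slope fit.
MIN_FIT_POINTS = 4


@dataclass
class PermeabilityConfig:
    """Geometry and dosing of one diffusion experiment.

    ``C0`` is the donor concentration in the same concentration unit as the
    receiver series (µg/mL or µCi/mL — P_app is ratio-scaled, so radiolabel
    activities behave identically to masses). The receiver volume must be
    given explicitly; it cannot be inferred.
    """

    area: float  # cm²
    C0: float  # concentration units / mL
    V_receiver: float  # mL
    V_sample: float = 0.2  # mL
    lloq: float = 0.0

    def __post_init__(self) -> None:
        if min(self.area, self.C0, self.V_receiver) <= 0:
            raise ValueError("area, C0 and V_receiver must be positive")
        if not 0 <= self.V_sample <= self.V_receiver:
            raise ValueError("V_sample must be in [0, V_receiver]")
        if self.lloq < 0:
            raise ValueError("lloq must be non-negative")


@dataclass
class PappResult:
    """Steady-state apparent permeability of one sample."""

    papp: float  # cm/s
    slope: float  # amount / s
    window: tuple[int, int] | None  # index range [i0, i1) of fitted points
    r2: float
    status: str  # "ok" or "ND"

    @classmethod
    def nd(cls) -> "PappResult":
        return cls(float("nan"), float("nan"), None, float("nan"), "ND")


def apply_lloq(series: pd.DataFrame, lloq: float) -> pd.DataFrame:
    """Flag concentrations below the LLOQ as censored.

    Censored points are excluded from slope fitting downstream; if more than
    half the points are censored the sample is reported ND.
    """
    if lloq < 0:
        raise ValueError("lloq must be non-negative")
    out = series.copy()
    out["censored"] = out["conc"].to_numpy(dtype=float) < lloq
    return out


def correct_cumulative(series: pd.DataFrame, cfg: PermeabilityConfig) -> pd.DataFrame:
    """Cumulative permeated amount corrected for sample withdrawal.

    Q_i = V_receiver·C_i + V_sample·Σ_{j<i} C_j: the amount currently in the
    receiver plus everything previously carried away in the withdrawn
    aliquots. Censored points still contribute their (small) measured value
    to the running sum.
    """
    conc = series["conc"].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative concentrations are not permitted")
    prior = np.concatenate([[0.0], np.cumsum(conc)[:-1]])
    out = series.copy()
    out["Q_corrected"] = cfg.V_receiver * conc + cfg.V_sample * prior
    return out


def _ols_slope(t_s: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """OLS slope of Q vs t (per second) and R²."""
    tbar = t_s.mean()
    qbar = q.mean()
    denom = np.sum((t_s - tbar) ** 2)
    slope = np.sum((t_s - tbar) * (q - qbar)) / denom
    resid = q - (slope * t_s + (qbar - slope * tbar))
    ss_tot = np.sum((q - qbar) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return float(slope), float(r2)


def fit_papp(series: pd.DataFrame, cfg: PermeabilityConfig) -> PappResult:
    """Steady-state P_app from a corrected cumulative-amount series.

    The fit window is the longest suffix of uncensored points whose linear
    fit reaches R² ≥ 0.98 with at least 4 points (steady state develops last,
    so suffixes exclude any lag phase); if no suffix qualifies, the suffix
    with the best R² is used. The slope is converted to cm/s via
    P_app = slope / (A · C0). Negative slopes clip to P_app = 0.

    The series must already carry ``Q_corrected`` (see
    :func:`correct_cumulative`); a missing ``censored`` column means nothing
    was censored.
    """
    df = series
    if "Q_corrected" not in df.columns:
        raise ValueError("series lacks Q_corrected; run correct_cumulative first")
    censored = (
        df["censored"].to_numpy(dtype=bool)
        if "censored" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    if len(df) and censored.sum() > 0.5 * len(df):
        return PappResult.nd()
    keep = ~censored
    t_s = df["time_min"].to_numpy(dtype=float)[keep] * 60.0
    q = df["Q_corrected"].to_numpy(dtype=float)[keep]
    n = len(q)
    if n < MIN_FIT_POINTS:
        return PappResult.nd()

    fits = [
        (start, *_ols_slope(t_s[start:], q[start:]))
        for start in range(0, n - MIN_FIT_POINTS + 1)
    ]
    for start, slope, r2 in fits:
        if r2 >= R2_STEADY_STATE:
            break  # longest qualifying suffix
    else:
        start, slope, r2 = max(fits, key=lambda f: f[2])  # best-R² fallback
    papp = max(slope, 0.0) / (cfg.area * cfg.C0)
    return PappResult(float(papp), float(slope), (start, n), float(r2), "ok")


def percent_of_control(treated: PappResult, control: PappResult) -> float:
    """100 × treated / control; NaN (ND) if either side is ND or control is 0."""
    if treated.status != "ok" or control.status != "ok" or not control.papp > 0:
        return float("nan")
    return 100.0 * treated.papp / control.papp
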