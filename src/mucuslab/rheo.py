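"""Rheological descriptor extraction from the three-step sweep protocol.

From a frequency sweep (0.1–10 rad/s at 0.1 Pa), a continuous flow ramp
(0.001–3000 1/s) and a stress sweep (1 rad/s, 0.001–500 Pa) the descriptors
of a mucus gel are extracted:

* G′ and loss factor tan δ = G″/G′ at 1 rad/s (elasticity and interaction
  strength of the mucin network);
* viscosity at the biologically relevant shear rate 0.4 1/s;
* yield point — the oscillation stress at which G′ has dropped 5% from its
  stress-independent plateau;
* flow point — the minimum oscillation stress at which G′ falls below G″
  (gel-to-fluid transition);
* gel check — G′ > G″ throughout 0.1–10 rad/s.

All interpolation is linear in log-log space, matching the log-spaced grids
rheometers produce; no extrapolation beyond the measured range is performed.
Descriptors that do not exist in the measured range (no plateau, no 5% drop,
no crossover) are reported as NaN (ND).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FrequencySweep",
    "StressSweep",
    "FlowCurve",
    "RheoDescriptors",
    "interp_at",
    "gel_check",
    "yield_point",
    "flow_point",
    "describe",
]


def _validate_grid(x: np.ndarray, name: str) -> None:
    if len(x) < 2 or np.any(np.diff(x) <= 0) or x[0] <= 0:
        raise ValueError(f"{name} must be positive and strictly increasing")


@dataclass
class FrequencySweep:
    omega: np.ndarray  # rad/s
    Gp: np.ndarray  # Pa
    Gpp: np.ndarray  # Pa

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.Gp = np.asarray(self.Gp, dtype=float)
        self.Gpp = np.asarray(self.Gpp, dtype=float)
        _validate_grid(self.omega, "omega")
        if np.any(self.Gp <= 0) or np.any(self.Gpp <= 0):
            raise ValueError("moduli must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrequencySweep":
        return cls(df["omega_rad_s"].to_numpy(), df["Gp_pa"].to_numpy(), df["Gpp_pa"].to_numpy())


@dataclass
class StressSweep:
    stress: np.ndarray  # Pa
    Gp: np.ndarray
    Gpp: np.ndarray

    def __post_init__(self) -> None:
        self.stress = np.asarray(self.stress, dtype=float)
        self.Gp = np.asarray(self.Gp, dtype=float)
        self.Gpp = np.asarray(self.Gpp, dtype=float)
        _validate_grid(self.stress, "stress")
        if np.any(self.Gp <= 0) or np.any(self.Gpp <= 0):
            raise ValueError("moduli must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StressSweep":
        return cls(df["stress_pa"].to_numpy(), df["Gp_pa"].to_numpy(), df["Gpp_pa"].to_numpy())


@dataclass
class FlowCurve:
    shear_rate: np.ndarray  # 1/s
    eta: np.ndarray  # Pa·s

    def __post_init__(self) -> None:
        self.shear_rate = np.asarray(self.shear_rate, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        _validate_grid(self.shear_rate, "shear_rate")
        if np.any(self.eta <= 0):
            raise ValueError("viscosity must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FlowCurve":
        return cls(df["shear_rate_s"].to_numpy(), df["eta_pa_s"].to_numpy())


@dataclass
class RheoDescriptors:
    """The descriptor set reported per mucus sample."""

    Gp_1rad: float  # Pa
    loss_factor_1rad: float  # G''/G' (tan δ)
    eta_0p4: float  # Pa·s
    yield_point: float  # Pa, NaN if not reached
    flow_point: float  # Pa, NaN if no G' < G'' transition
    is_gel: bool


def _loglog_interp(xg: np.ndarray, yg: np.ndarray, x: float) -> float:
    lx = np.log(xg)
    return float(np.exp(np.interp(np.log(x), lx, np.log(yg))))


def interp_at(sweep, x: float):
    """Log-log interpolated value(s) of a sweep at coordinate ``x``.

    For a :class:`FrequencySweep` or :class:`StressSweep` returns (G′, G″);
    for a :class:`FlowCurve` returns the viscosity. ``x`` must lie within the
    measured range (no extrapolation). Exact at grid points.
    """
    if isinstance(sweep, FrequencySweep):
        grid, ys = sweep.omega, (sweep.Gp, sweep.Gpp)
    elif isinstance(sweep, StressSweep):
        grid, ys = sweep.stress, (sweep.Gp, sweep.Gpp)
    elif isinstance(sweep, FlowCurve):
        grid, ys = sweep.shear_rate, (sweep.eta,)
    else:
        raise TypeError(f"unsupported sweep type {type(sweep)!r}")
    if not grid[0] <= x <= grid[-1]:
        raise ValueError(f"{x} outside the measured range [{grid[0]}, {grid[-1]}]")
    vals = tuple(_loglog_interp(grid, y, x) for y in ys)
    return vals if len(vals) > 1 else vals[0]


def gel_check(fs: FrequencySweep, lo: float = 0.1, hi: float = 10.0) -> bool:
    """True iff G′ > G″ at every measured frequency within [lo, hi]."""
    sel = (fs.omega >= lo) & (fs.omega <= hi)
    return bool(np.all(fs.Gp[sel] > fs.Gpp[sel]))


def _find_plateau(ss: StressSweep, tol: float = 0.05) -> tuple[float, int] | None:
    """Stress-independent region: longest initial run within ±tol of its
    running median. Returns (plateau G′, run length) or None."""
    gp = ss.Gp
    end = 1
    for i in range(1, len(gp)):
        med = np.median(gp[: i + 1])
        if abs(gp[i] - med) > tol * med:
            break
        end = i + 1
    if end < 3:
        return None
    return float(np.mean(gp[:end])), end


def yield_point(ss: StressSweep, drop: float = 0.05) -> float:
    """Oscillation stress at which G′ first falls ``drop`` below its plateau.

    The plateau is the mean G′ over the detected stress-independent region.
    The crossing of the 0.95·plateau level is located by log-log
    interpolation between the bracketing grid points. NaN when no plateau is
    detected or G′ never drops (right-censored).
    """
    found = _find_plateau(ss)
    if found is None:
        return float("nan")
    plateau, _ = found
    level = (1.0 - drop) * plateau
    below = np.nonzero(ss.Gp < level)[0]
    if len(below) == 0:
        return float("nan")
    i = below[0]
    if i == 0:
        return float(ss.stress[0])
    # solve log G' (linear in log stress) = log level between i-1 and i
    ls0, ls1 = np.log(ss.stress[i - 1]), np.log(ss.stress[i])
    lg0, lg1 = np.log(ss.Gp[i - 1]), np.log(ss.Gp[i])
    frac = (np.log(level) - lg0) / (lg1 - lg0)
    return float(np.exp(ls0 + frac * (ls1 - ls0)))


def flow_point(ss: StressSweep) -> float:
    """Minimum oscillation stress for the G′ < G″ transition.

    The first sign change of G′ − G″ from positive to non-positive is
    bracketed, and the crossover located by intersecting the log-log linear
    interpolants of G′ and G″. NaN when no transition occurs in range.
    """
    d = ss.Gp - ss.Gpp
    for i in range(1, len(d)):
        if d[i - 1] > 0 and d[i] <= 0:
            if d[i] == 0:
                return float(ss.stress[i])
            ls0, ls1 = np.log(ss.stress[i - 1]), np.log(ss.stress[i])
            a0, a1 = np.log(ss.Gp[i - 1]), np.log(ss.Gp[i])
            b0, b1 = np.log(ss.Gpp[i - 1]), np.log(ss.Gpp[i])
            # log G' and log G'' are linear in log stress; intersect them
            num = b0 - a0
            den = (a1 - a0) - (b1 - b0)
            frac = num / den
            return float(np.exp(ls0 + frac * (ls1 - ls0)))
    return float("nan")


def describe(fs: FrequencySweep, ss: StressSweep, flow: FlowCurve) -> RheoDescriptors:
    """Extract the full descriptor set from the three protocol steps."""
    gp1, gpp1 = interp_at(fs, 1.0)
    return RheoDescriptors(
        Gp_1rad=gp1,
        loss_factor_1rad=gpp1 / gp1,
        eta_0p4=interp_at(flow, 0.4),
        yield_point=yield_point(ss),
        flow_point=flow_point(ss),
        is_gel=gel_check(fs),
    )
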