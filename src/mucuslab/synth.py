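"""Seeded synthetic-data generators with recorded ground truth.

Every input class the analysis pipeline consumes can be generated here with
known parameters, so each stage is verifiable by parameter recovery:

* mixtures of freely diffusing, confined and immobile 2D particle tracks with
  stated D and alpha (emulating nanoparticle movies recorded at 4.56 Hz,
  300 frames, 0.183 µm pixels);
* porous grayscale images with known pore areas (ground-truth twin of
  cryo-SEM micrographs);
* receiver-compartment flux curves with known P_app, propagated through the
  200-µL sample-and-replace withdrawal scheme;
* gel-like rheometer sweeps with known plateau modulus, loss factor, yield
  and flow points.

All generators are deterministic for a given seed, and each returns its
ground truth separately from the data so downstream tests read the truth only
from the sidecar, never from the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from .spt import Trajectory

__all__ = [
    "TrajectorySimSpec",
    "PoreImageSpec",
    "FluxSimSpec",
    "RheoSimSpec",
    "simulate_trajectories",
    "simulate_pore_image",
    "simulate_flux",
    "simulate_sweeps",
    "fbm_increment_autocovariance",
]

#: Frame interval of the emulated acquisition (4.56 Hz).
DEFAULT_DT = 1.0 / 4.56
#: Camera pixel size, µm.
DEFAULT_PIXEL = 0.183


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectorySimSpec:
    """Conditions for a simulated particle-tracking movie.

    The defaults reproduce the acquisition geometry of the emulated assay
    (300 frames at 4.56 Hz, 0.183 µm pixels) with the mobility mixture and
    diffusion coefficient measured in mucus of healthy term animals
    (~49/50/2 % free/confined/immobile, D = 0.057 µm²/s). ``alpha_sub`` sets
    the anomalous exponent of subdiffusive (confined-class) fractional
    Brownian particles when ``confined_model="fbm"``; ``corral_radius`` the
    reflecting-disk radius when ``confined_model="corral"``.
    """

    n_particles: int = 500
    n_frames: int = 300
    dt: float = DEFAULT_DT
    pixel: float = DEFAULT_PIXEL
    class_mix: tuple[float, float, float] = (0.488, 0.496, 0.016)  # free, confined, immobile
    D_free: float = 0.057
    alpha_sub: float = 0.3
    D_sub: float | None = None
    corral_radius: float = 0.15
    confined_model: str = "fbm"  # "fbm" or "corral"
    loc_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_frames < 2:
            raise ValueError("need n_particles >= 1 and n_frames >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.D_free <= 0:
            raise ValueError("D_free must be positive")
        if not 0 < self.alpha_sub <= 1:
            raise ValueError("alpha_sub must be in (0, 1]")
        if self.corral_radius <= 0:
            raise ValueError("corral_radius must be positive")
        if self.loc_noise_sd < 0:
            raise ValueError("loc_noise_sd must be non-negative")
        if abs(sum(self.class_mix) - 1.0) > 1e-12 or min(self.class_mix) < 0:
            raise ValueError("class_mix must be non-negative and sum to 1")
        if self.confined_model not in ("fbm", "corral"):
            raise ValueError("confined_model must be 'fbm' or 'corral'")


def _class_counts(mix: tuple[float, float, float], n: int) -> tuple[int, int, int]:
    """Deterministic largest-remainder apportionment of n particles."""
    raw = np.asarray(mix) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return tuple(int(b) for b in base)


def _fbm_cholesky(times: np.ndarray, hurst: float) -> np.ndarray:
    """Cholesky factor of the exact fBm position covariance on ``times``.

    cov(B_H(s), B_H(t)) = (s^{2H} + t^{2H} - |t-s|^{2H}) / 2 with
    Var B_H(t) = t^{2H}. Exact synthesis; adequate at the few-hundred-frame
    scale of the emulated movies (a Davies–Harte circulant embedding would be
    an acceptable faster substitute for much longer tracks).
    """
    t = times[:, None]
    s = times[None, :]
    h2 = 2.0 * hurst
    cov = 0.5 * (t**h2 + s**h2 - np.abs(t - s) ** h2)
    # tiny jitter guards against numerically semi-definite corners
    cov[np.diag_indices_from(cov)] += 1e-12
    return np.linalg.cholesky(cov)


def fbm_increment_autocovariance(k: np.ndarray, hurst: float, dt: float = 1.0) -> np.ndarray:
    """Analytic autocovariance of unit-scale fBm increments at frame lag k.

    gamma(k) = dt^{2H} * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2 — the
    closed form used as the oracle for the simulated subdiffusive tracks.
    """
    k = np.asarray(k, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * dt**h2 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def simulate_trajectories(
    spec: TrajectorySimSpec,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate a mobility mixture of 2D tracks; return (tracks, ground truth).

    * free: Brownian increments with variance 2·D_free·dt per axis (ensemble
      MSD(tau) = 4·D_free·tau, alpha = 1);
    * confined, ``fbm`` model: fractional Brownian motion with Hurst
      H = alpha_sub/2, scaled so the ensemble MSD is 4·D_sub·tau^alpha_sub
      (D_sub defaults to D_free);
    * confined, ``corral`` model: Brownian steps specularly reflected at a
      disk of ``corral_radius``;
    * immobile: a fixed point.

    Independent Gaussian localization noise of ``loc_noise_sd`` µm is added to
    every recorded position. Class counts follow the requested mixture
    deterministically, so the realized mixture equals the specification.
    """
    rng = np.random.default_rng(spec.seed)
    n_free, n_conf, n_immob = _class_counts(spec.class_mix, spec.n_particles)
    nf = spec.n_frames
    step_sd = np.sqrt(2.0 * spec.D_free * spec.dt)
    d_sub = spec.D_free if spec.D_sub is None else spec.D_sub

    chol = None
    if n_conf and spec.confined_model == "fbm":
        times = np.arange(1, nf) * spec.dt
        chol = _fbm_cholesky(times, spec.alpha_sub / 2.0)

    trajs: list[Trajectory] = []
    truth_rows = []
    frames = np.arange(nf)
    pid = 0

    for _ in range(n_free):
        xy = np.vstack([np.zeros((1, 2)), np.cumsum(rng.normal(0, step_sd, (nf - 1, 2)), axis=0)])
        trajs.append(_noisy_traj(pid, frames, xy, spec, rng))
        truth_rows.append(dict(particle_id=pid, mobility_class="free",
                               D_true=spec.D_free, alpha_true=1.0))
        pid += 1

    for _ in range(n_conf):
        if spec.confined_model == "fbm":
            z = rng.standard_normal((nf - 1, 2))
            xy = np.vstack([np.zeros((1, 2)), np.sqrt(2.0 * d_sub) * (chol @ z)])
            alpha_true: float = spec.alpha_sub
            d_true: float = d_sub
        else:
            xy = _reflected_brownian(rng, nf, step_sd, spec.corral_radius)
            alpha_true, d_true = np.nan, np.nan
        trajs.append(_noisy_traj(pid, frames, xy, spec, rng))
        truth_rows.append(dict(particle_id=pid, mobility_class="confined",
                               D_true=d_true, alpha_true=alpha_true))
        pid += 1

    for _ in range(n_immob):
        xy = np.zeros((nf, 2))
        trajs.append(_noisy_traj(pid, frames, xy, spec, rng))
        truth_rows.append(dict(particle_id=pid, mobility_class="immobile",
                               D_true=0.0, alpha_true=0.0))
        pid += 1

    return trajs, pd.DataFrame(truth_rows)


def _noisy_traj(pid, frames, xy, spec, rng) -> Trajectory:
    if spec.loc_noise_sd > 0:
        xy = xy + rng.normal(0.0, spec.loc_noise_sd, xy.shape)
    return Trajectory(pid, frames, xy, spec.dt)


def _reflected_brownian(rng, n_frames, step_sd, radius) -> np.ndarray:
    """Brownian steps inside a reflecting disk centered at the start point."""
    xy = np.zeros((n_frames, 2))
    p = np.zeros(2)
    for i in range(1, n_frames):
        p = p + rng.normal(0.0, step_sd, 2)
        r = np.hypot(*p)
        while r > radius:
            # specular (radial) reflection at the boundary
            p = p * (2.0 * radius - r) / r
            r = abs(np.hypot(*p))
        xy[i] = p
    return xy


# ---------------------------------------------------------------------------
# pore images


@dataclass
class PoreImageSpec:
    """Dark disks (pores) on a bright wall background with Gaussian noise."""

    width: int = 256
    height: int = 256
    um_per_px: float = 0.0104
    pore_centers: tuple = ()  # (x_um, y_um) pairs
    pore_radii: tuple = ()  # µm
    intensity_pore: float = 60.0
    intensity_wall: float = 180.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.intensity_pore >= self.intensity_wall:
            raise ValueError("pores must be darker than walls")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.pore_centers) != len(self.pore_radii):
            raise ValueError("pore_centers and pore_radii must have equal length")
        w_um = self.width * self.um_per_px
        h_um = self.height * self.um_per_px
        for (cx, cy), r in zip(self.pore_centers, self.pore_radii):
            if r <= 0:
                raise ValueError("pore radii must be positive")
            if not (r <= cx <= w_um - r and r <= cy <= h_um - r):
                raise ValueError("pores must lie within the image")


def simulate_pore_image(spec: PoreImageSpec) -> tuple[np.ndarray, dict]:
    """Render the pore image; return (image, ground truth).

    Ground truth records per-disk areas (π r²) and the exact union area in
    µm² (overlapping disks are merged, so the union is the honest total).
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width), spec.intensity_wall, dtype=float)
    yy = (np.arange(spec.height)[:, None] + 0.5) * spec.um_per_px
    xx = (np.arange(spec.width)[None, :] + 0.5) * spec.um_per_px
    for (cx, cy), r in zip(spec.pore_centers, spec.pore_radii):
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        img[mask] = spec.intensity_pore
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    disk_areas = [float(np.pi * r**2) for r in spec.pore_radii]
    if spec.pore_centers:
        union = unary_union(
            [Point(cx, cy).buffer(r, quad_segs=256)
             for (cx, cy), r in zip(spec.pore_centers, spec.pore_radii)]
        )
        total = float(union.area)
    else:
        total = 0.0
    truth = {
        "pore_areas_um2": disk_areas,
        "total_pore_area_um2": total,
        "n_pores": len(disk_areas),
        "um_per_px": spec.um_per_px,
    }
    return img, truth


# ---------------------------------------------------------------------------
# flux curves


@dataclass
class FluxSimSpec:
    """Steady-state permeation with the 200-µL sample-and-replace scheme.

    Defaults mirror the filter-insert (Transwell, 6.5 mm) bulk-mucus assay:
    600 µL receiver, 200 µL withdrawn and replaced with blank buffer at each
    sampling time, samples every 15 min for 4 h, donor 250 µg/mL.
    """

    papp_true: float = 2.0e-6  # cm/s
    C0: float = 250.0  # µg/mL (donor)
    area: float = 0.332  # cm² (6.5 mm insert)
    V_receiver: float = 0.6  # mL
    V_sample: float = 0.2  # mL
    times: tuple = tuple(float(t) for t in range(15, 241, 15))  # minutes
    lag: float = 0.0  # minutes
    noise_cv: float = 0.0
    lloq: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.papp_true < 0:
            raise ValueError("papp_true must be non-negative")
        if min(self.C0, self.area, self.V_receiver) <= 0:
            raise ValueError("C0, area and V_receiver must be positive")
        if not 0 <= self.V_sample <= self.V_receiver:
            raise ValueError("V_sample must be in [0, V_receiver]")
        t = np.asarray(self.times, dtype=float)
        if len(t) < 1 or np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("times must be positive and strictly increasing")
        if self.noise_cv < 0 or self.lloq < 0 or self.lag < 0:
            raise ValueError("noise_cv, lloq and lag must be non-negative")


def simulate_flux(spec: FluxSimSpec) -> tuple[pd.DataFrame, dict]:
    """Receiver concentration series under sampling dilution; plus truth.

    The cumulative permeated amount is Q(t) = papp·A·C0·(t − lag) for t > lag
    (zero before). Each withdrawal removes V_sample·C from the receiver and is
    replaced with blank medium; the recorded concentration is the receiver
    concentration at sampling time, multiplied by (1 + cv·ε) measurement
    noise. Concentrations below the LLOQ are flagged censored.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    q = spec.papp_true * spec.area * spec.C0 * 60.0 * np.clip(t - spec.lag, 0.0, None)  # µg

    conc = np.empty_like(t)
    amount = 0.0  # µg currently in receiver
    q_prev = 0.0
    for i in range(len(t)):
        amount += q[i] - q_prev
        q_prev = q[i]
        c = amount / spec.V_receiver
        conc[i] = c
        amount -= spec.V_sample * c  # withdrawal, replaced with blank

    if spec.noise_cv > 0:
        conc = conc * (1.0 + spec.noise_cv * rng.standard_normal(len(t)))
        conc = np.clip(conc, 0.0, None)

    df = pd.DataFrame(
        {"time_min": t, "conc": conc, "censored": conc < spec.lloq}
    )
    truth = {
        "papp_true": spec.papp_true,
        "Q_true_ug": q,
        "C0": spec.C0,
        "area_cm2": spec.area,
        "V_receiver_ml": spec.V_receiver,
        "V_sample_ml": spec.V_sample,
        "lag_min": spec.lag,
    }
    return df, truth


# ---------------------------------------------------------------------------
# rheometer sweeps


@dataclass
class RheoSimSpec:
    """A synthetic weak gel with prescribed descriptor ground truth.

    Frequency sweep: G′ = G0·ω^0.05 (weak power-law gel), G″ = tan_delta·G′.
    Stress sweep at 1 rad/s: G′ holds a flat plateau G0 up to a corner stress
    and then decays as a power law calibrated so G′ has dropped exactly 5%
    at ``yield_stress_true`` and crosses the (constant) G″ = tan_delta·G0
    exactly at ``flow_stress_true``. Flow curve: power-law viscosity
    eta = eta0·(shear rate)^(n−1).
    """

    G0: float = 10.0  # Pa
    tan_delta: float = 0.3
    yield_stress_true: float = 10.0  # Pa
    flow_stress_true: float = 50.0  # Pa
    eta_params: tuple[float, float] = (5.0, 0.25)  # (eta0 Pa·s, power-law index)
    omega_grid: tuple = tuple(np.geomspace(0.1, 10.0, 21))
    stress_grid: tuple = tuple(np.geomspace(0.001, 500.0, 57))
    shear_grid: tuple = tuple(np.geomspace(0.001, 3000.0, 65))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G0 <= 0:
            raise ValueError("G0 must be positive")
        if not 0 < self.tan_delta < 0.95:
            raise ValueError("tan_delta must be in (0, 0.95) for a gel with a 5% yield drop")
        if not 0 < self.yield_stress_true < self.flow_stress_true:
            raise ValueError("need 0 < yield_stress_true < flow_stress_true")
        if min(self.eta_params[0], self.eta_params[1]) <= 0:
            raise ValueError("eta_params must be positive")
        for grid in (self.omega_grid, self.stress_grid, self.shear_grid):
            g = np.asarray(grid, dtype=float)
            if len(g) < 3 or np.any(np.diff(g) <= 0) or g[0] <= 0:
                raise ValueError("grids must be positive and strictly increasing")


def simulate_sweeps(spec: RheoSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Generate (frequency sweep, stress sweep, flow curve, ground truth)."""
    omega = np.asarray(spec.omega_grid, dtype=float)
    gp_f = spec.G0 * omega**0.05
    fs = pd.DataFrame({"omega_rad_s": omega, "Gp_pa": gp_f, "Gpp_pa": spec.tan_delta * gp_f})

    # decay exponent q and corner stress s0 so that
    #   G'(yield) = 0.95 G0   and   G'(flow) = tan_delta * G0
    q = np.log(0.95 / spec.tan_delta) / np.log(spec.flow_stress_true / spec.yield_stress_true)
    s0 = spec.yield_stress_true * 0.95 ** (1.0 / q)
    stress = np.asarray(spec.stress_grid, dtype=float)
    gp_s = np.where(stress <= s0, spec.G0, spec.G0 * (stress / s0) ** (-q))
    ss = pd.DataFrame(
        {"stress_pa": stress, "Gp_pa": gp_s,
         "Gpp_pa": np.full_like(stress, spec.tan_delta * spec.G0)}
    )

    shear = np.asarray(spec.shear_grid, dtype=float)
    eta0, index = spec.eta_params
    flow = pd.DataFrame({"shear_rate_s": shear, "eta_pa_s": eta0 * shear ** (index - 1.0)})

    truth = {
        "G0": spec.G0,
        "tan_delta": spec.tan_delta,
        "Gp_1rad": spec.G0,  # G0 * 1**0.05
        "yield_stress_true": spec.yield_stress_true,
        "flow_stress_true": spec.flow_stress_true,
        "eta_at_0p4": eta0 * 0.4 ** (index - 1.0),
        "corner_stress": s0,
        "decay_exponent": q,
    }
    return fs, ss, flow, truth
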