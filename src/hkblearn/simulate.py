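"""Langevin simulation of the relative-phase dynamics and circular trial statistics.

The deterministic model phi' = -dV/dphi is extended with additive white noise
of intensity Q — the standard stochastic completion in the coordination-
dynamics literature — and integrated with a fixed-step Euler-Maruyama scheme:

    phi  <-  phi + flow(phi) * dt + sqrt(Q * dt) * xi,   xi ~ N(0, 1)

For this one-dimensional overdamped gradient system the stationary density
is the Boltzmann form  p(phi) ~ exp(-2 V(phi) / Q), which serves as the
quantitative validation instrument for the integrator.

Trial performance is summarized with the circular statistics used in
scanning-probe experiments: the signed constant error CE (circular mean of
the wrapped deviation from the required phase), its absolute value AE
(accuracy), the angular deviation SD = sqrt(2 (1 - R)) of the wrapped error
(stability; R is the resultant length), and the composite
RMSE = sqrt(CE^2 + SD^2).  All are reported in degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .angles import wrap_deg
from .model import PotentialParams, evaluate_flow, evaluate_potential, get_schedule

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "TrialSummary",
    "integrate",
    "summarize_trial",
    "stationary_histogram",
    "variability_vs_lambda",
    "circular_error_stats",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings (model time units are dimensionless).

    ``burn_in`` is the initial fraction of the trajectory discarded by the
    summary statistics, covering the relaxation transient from phi0 to the
    local attractor.
    """

    dt: float = 0.001
    duration: float = 30.0
    noise_q: float = 0.3
    seed: int = 0
    burn_in: float = 0.2
    phi0_deg: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0 <= self.burn_in < 1):
            raise ValueError("burn_in must be a fraction in [0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.noise_q < 0:
            raise ValueError("noise intensity Q must be >= 0")


@dataclass
class Trajectory:
    """Sampled relative-phase time series; phases wrapped to (-180, 180] deg."""

    times: np.ndarray
    phases_deg: np.ndarray

    def __post_init__(self):
        if len(self.times) != len(self.phases_deg):
            raise ValueError("times and phases must have equal length")


@dataclass(frozen=True)
class TrialSummary:
    """Circular performance statistics of one trial against a required phase."""

    required_deg: float
    ce_deg: float
    ae_deg: float
    sd_deg: float
    rmse_deg: float

    def __post_init__(self):
        for name in ("ce_deg", "ae_deg", "sd_deg", "rmse_deg"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    @classmethod
    def from_ce_sd(cls, required_deg: float, ce_deg: float, sd_deg: float) -> "TrialSummary":
        return cls(
            required_deg=float(required_deg),
            ce_deg=float(ce_deg),
            ae_deg=abs(float(ce_deg)),
            sd_deg=float(sd_deg),
            rmse_deg=math.hypot(ce_deg, sd_deg),
        )


@njit(cache=False)
def _em_kernel(phi0, dt, n_steps, a, amp, kappa, psi, sigma, noise):  # pragma: no cover
    out = np.empty(n_steps + 1)
    phi = phi0
    out[0] = phi
    n_orders = a.shape[0]
    for t in range(n_steps):
        f = 0.0
        for k in range(n_orders):
            if a[k] != 0.0:
                f -= (k + 1) * a[k] * math.sin((k + 1) * phi)
        if amp > 0.0 and kappa > 0.0:
            dm = phi - psi
            dp = phi + psi
            f -= amp * kappa * (
                math.sin(dm) * math.exp(kappa * (math.cos(dm) - 1.0))
                + math.sin(dp) * math.exp(kappa * (math.cos(dp) - 1.0))
            )
        phi = phi + f * dt + sigma * noise[t]
        if phi > math.pi:
            phi -= 2.0 * math.pi
        elif phi <= -math.pi:
            phi += 2.0 * math.pi
        out[t + 1] = phi
    return out


def _kernel_args(params: PotentialParams):
    a = params.skeleton.as_array()
    lt = params.learning
    if lt is None or lt.c == 0.0:
        return a, 0.0, 0.0, 0.0
    return a, lt.scaled_amplitude, lt.kappa, lt.psi_rad


def integrate(params: PotentialParams, config: SimulationConfig) -> Trajectory:
    """Integrate the noisy phase equation; bit-reproducible for a given seed."""
    n_steps = int(round(config.duration / config.dt))
    a, amp, kappa, psi = _kernel_args(params)

    # fixed-step stability check on a coarse phase grid
    probe = np.arange(-180.0, 180.1, 1.0)
    max_flow = float(np.max(np.abs(evaluate_flow(probe, params))))
    if config.dt * max_flow > 0.5:
        warnings.warn(
            f"dt * max|flow| = {config.dt * max_flow:.3g} > 0.5 rad: "
            "the Euler-Maruyama step may be unstable; reduce dt",
            RuntimeWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    if config.noise_q > 0:
        noise = rng.standard_normal(n_steps)
        sigma = math.sqrt(config.noise_q * config.dt)
    else:
        noise = np.zeros(n_steps)
        sigma = 0.0
    phi = _em_kernel(
        math.radians(wrap_deg(config.phi0_deg)),
        config.dt,
        n_steps,
        a,
        amp,
        kappa,
        psi,
        sigma,
        noise,
    )
    times = config.dt * np.arange(n_steps + 1)
    return Trajectory(times=times, phases_deg=np.degrees(phi))


def circular_error_stats(phases_deg: np.ndarray, required_deg: float) -> Tuple[float, float]:
    """(CE, SD) in degrees of the wrapped error phases - required.

    CE is the circular mean direction of the error; SD is the angular
    deviation sqrt(2 (1 - R)) with R the resultant length.
    """
    err = np.radians(wrap_deg(np.asarray(phases_deg, dtype=float) - required_deg))
    if err.size == 0:
        raise ValueError("no samples to summarize")
    c = float(np.mean(np.cos(err)))
    s = float(np.mean(np.sin(err)))
    ce = math.degrees(math.atan2(s, c))
    r = min(math.hypot(c, s), 1.0)
    sd = math.degrees(math.sqrt(2.0 * (1.0 - r)))
    return ce, sd


def summarize_trial(
    traj: Trajectory, required_deg: float, burn_in: float = 0.2
) -> TrialSummary:
    """Circular performance statistics of the post-burn-in trajectory window."""
    if not (0 <= burn_in < 1):
        raise ValueError("burn_in must be a fraction in [0, 1)")
    start = int(burn_in * len(traj.phases_deg))
    window = traj.phases_deg[start:]
    if window.size == 0:
        raise ValueError("post-burn-in window is empty")
    ce, sd = circular_error_stats(window, required_deg)
    return TrialSummary.from_ce_sd(required_deg, ce, sd)


def stationary_histogram(
    params: PotentialParams, config: SimulationConfig, bins: int = 72
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of post-burn-in phases (sums to 1).

    Returns ``(bin_centers_deg, probabilities)`` over (-180, 180].  Requires
    Q > 0 — the noise-free gradient flow has no stationary density.
    """
    if config.noise_q <= 0:
        raise ValueError("stationary density requires noise intensity Q > 0")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    traj = integrate(params, config)
    start = int(config.burn_in * len(traj.phases_deg))
    samples = traj.phases_deg[start:]
    edges = np.linspace(-180.0, 180.0, bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    probs = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, probs


def boltzmann_density(
    params: PotentialParams, noise_q: float, bins: int = 72
) -> Tuple[np.ndarray, np.ndarray]:
    """Theoretical stationary probabilities exp(-2 V / Q) on the bin grid."""
    if noise_q <= 0:
        raise ValueError("Q must be > 0")
    edges = np.linspace(-180.0, 180.0, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    v = np.asarray(evaluate_potential(centers, params))
    w = np.exp(-2.0 * (v - v.min()) / noise_q)
    return centers, w / w.sum()


def variability_vs_lambda(
    profile: str,
    lambda_list: Sequence[float],
    config: SimulationConfig,
    n_replicates: int = 10,
) -> np.ndarray:
    """Mean circular SD of the wrapped error at the schedule's target phase.

    For each lambda, trials start at phi0 = psi (the phase being practiced)
    and the SD of (phi - psi) is averaged over replicates with successive
    seeds.  Enhanced variability just below the saddle-node bifurcation is
    the fingerprint of the impending transition.
    """
    schedule = get_schedule(profile)
    out = np.empty(len(lambda_list))
    for i, lam in enumerate(lambda_list):
        params = schedule(float(lam))
        psi = params.learning.psi_deg
        sds = []
        for r in range(n_replicates):
            cfg = replace(config, seed=config.seed + 1009 * i + r, phi0_deg=psi)
            traj = integrate(params, cfg)
            sds.append(summarize_trial(traj, psi, burn_in=cfg.burn_in).sd_deg)
        out[i] = float(np.mean(sds))
    return out
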