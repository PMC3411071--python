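"""Fixed points of the phase flow, bifurcation diagrams, saddle-node detection.

A fixed point is a zero of phi' = -dV/dphi; it is an attractor where the flow
crosses zero with negative slope (a potential minimum, V'' > 0) and a
repellor where the slope is positive.  The stability of an attractor is
quantified by the curvature V'' at the minimum: the larger it is, the faster
the system relaxes back after a perturbation.

Root finding is a dense-grid scan for sign changes of the (cheap, periodic,
one-dimensional) flow followed by bisection refinement, which stays robust
near saddle-node bifurcations where Newton-type iterations stall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .angles import circular_distance_deg, wrap_deg
from .model import (
    PotentialParams,
    evaluate_curvature,
    evaluate_flow,
    get_schedule,
)

__all__ = [
    "FixedPoint",
    "MarginalCircle",
    "BifurcationDiagram",
    "BifurcationEvent",
    "find_fixed_points",
    "count_attractors",
    "sweep_bifurcation",
    "detect_saddle_node",
    "relaxation_rate",
    "NoEventBracketedError",
]

#: |flow slope| below which a fixed point is classified as marginal
MARGINAL_SLOPE_TOL = 1e-6


class NoEventBracketedError(ValueError):
    """Raised when a saddle-node search interval brackets no count change."""


@dataclass(frozen=True)
class FixedPoint:
    """A zero of the flow on the circle, with its stability classification."""

    location_deg: float  # in (-180, 180]
    stability: str  # 'attractor' | 'repellor' | 'marginal'
    flow_slope: float  # d(flow)/dphi at the fixed point (radian derivative)
    curvature: float  # V'' at the fixed point

    @property
    def is_attractor(self) -> bool:
        return self.stability == "attractor"


@dataclass(frozen=True)
class MarginalCircle:
    """Degenerate result: the flow vanishes identically, every phase is marginal."""

    def __iter__(self):
        return iter(())


@dataclass(frozen=True)
class BifurcationEvent:
    lambda_c: float
    kind: str  # 'creation' | 'annihilation'
    location_deg: float  # mean location of the colliding/born pair


@dataclass
class BifurcationDiagram:
    lambda_grid: np.ndarray
    points: List[List[FixedPoint]]  # per-lambda fixed points
    branch_ids: List[List[int]]  # parallel to points
    events: List[BifurcationEvent]
    warnings: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lam, fps, bids in zip(self.lambda_grid, self.points, self.branch_ids):
            for fp, bid in zip(fps, bids):
                rows.append(
                    {
                        "lambda": float(lam),
                        "branch_id": int(bid),
                        "phi_deg": fp.location_deg,
                        "stability": fp.stability,
                    }
                )
        return pd.DataFrame(rows, columns=["lambda", "branch_id", "phi_deg", "stability"])

    def events_records(self) -> List[dict]:
        return [
            {"lambda_c": ev.lambda_c, "type": ev.kind, "phi_deg": ev.location_deg}
            for ev in self.events
        ]

    def branch_locations(self, branch_id: int) -> List[Tuple[float, float]]:
        """(lambda, phi_deg) samples of one branch, in grid order."""
        out = []
        for lam, fps, bids in zip(self.lambda_grid, self.points, self.branch_ids):
            for fp, bid in zip(fps, bids):
                if bid == branch_id:
                    out.append((float(lam), fp.location_deg))
        return out


def _classify(slope: float) -> str:
    if abs(slope) < MARGINAL_SLOPE_TOL:
        return "marginal"
    return "attractor" if slope < 0 else "repellor"


def _flow_slope(phi_deg: float, params: PotentialParams, form: str) -> float:
    if form == "gradient":
        return -float(evaluate_curvature(phi_deg, params))
    h = 1e-6  # degrees; central difference, converted to radian derivative
    df = float(evaluate_flow(phi_deg + h, params, form)) - float(
        evaluate_flow(phi_deg - h, params, form)
    )
    return df / np.radians(2 * h)


def find_fixed_points(
    params: PotentialParams,
    grid_step_deg: float = 0.1,
    refine_tol_rad: float = 1e-8,
    form: str = "gradient",
):
    """Locate and classify all fixed points of the flow on (-180, 180] deg.

    Returns a list of :class:`FixedPoint` sorted by location, or a
    :class:`MarginalCircle` when the landscape is uniform (all parameters
    zero), in which case every phase is a marginal fixed point.
    """
    if grid_step_deg <= 0 or grid_step_deg > 0.5:
        raise ValueError("grid_step_deg must lie in (0, 0.5]")
    if form == "gradient" and params.is_flat:
        return MarginalCircle()

    n = int(round(360.0 / grid_step_deg))
    grid = -180.0 + grid_step_deg * np.arange(n + 1)  # [-180, 180]
    fv = np.asarray(evaluate_flow(grid, params, form))
    if form != "gradient" and np.max(np.abs(fv)) == 0.0:
        return MarginalCircle()

    def f(phi_deg: float) -> float:
        return float(evaluate_flow(phi_deg, params, form))

    # Treat floating-point dust (e.g. sin(n*pi) at the symmetry-pinned points
    # 0 and +-180) as exact zeros so those roots are never lost to a
    # same-sign pair of grid samples.
    scale = float(np.max(np.abs(fv)))
    atol = 1e-12 * scale
    is_zero = np.abs(fv) <= atol

    roots: List[float] = []
    for i in range(n):
        a, b = grid[i], grid[i + 1]
        fa, fb = fv[i], fv[i + 1]
        if is_zero[i]:
            roots.append(float(a))
        elif not is_zero[i + 1] and fa * fb < 0.0:
            roots.append(float(brentq(f, a, b, xtol=np.degrees(refine_tol_rad))))

    # wrap, snap the symmetry-pinned roots, and merge duplicates
    tol_deg = np.degrees(refine_tol_rad)
    cleaned: List[float] = []
    for r in sorted(wrap_deg(np.asarray(roots)).tolist()):
        if abs(r) <= max(tol_deg, 1e-9):
            r = 0.0
        elif abs(abs(r) - 180.0) <= max(tol_deg, 1e-9):
            r = 180.0
        if cleaned and circular_distance_deg(r, cleaned[-1]) <= tol_deg:
            continue
        cleaned.append(r)
    if len(cleaned) >= 2 and circular_distance_deg(cleaned[0], cleaned[-1]) <= tol_deg:
        cleaned.pop()

    out = []
    for loc in sorted(set(cleaned)):
        slope = _flow_slope(loc, params, form)
        out.append(
            FixedPoint(
                location_deg=loc,
                stability=_classify(slope),
                flow_slope=slope,
                curvature=float(evaluate_curvature(loc, params)),
            )
        )
    return out


def count_attractors(
    params: PotentialParams,
    interval_deg: Tuple[float, float] = (0.0, 180.0),
    **kwargs,
) -> int:
    """Number of attractors with location inside the closed interval."""
    lo, hi = interval_deg
    if lo > hi:
        raise ValueError("interval must be ordered (lo <= hi)")
    fps = find_fixed_points(params, **kwargs)
    if isinstance(fps, MarginalCircle):
        return 0
    return sum(1 for fp in fps if fp.is_attractor and lo <= fp.location_deg <= hi)


def _count_half_open(params: PotentialParams, form: str, grid_step_deg: float) -> int:
    """Fixed points strictly inside the open half-circle (0, 180) deg."""
    fps = find_fixed_points(params, grid_step_deg=grid_step_deg, form=form)
    if isinstance(fps, MarginalCircle):
        return 0
    return sum(1 for fp in fps if 1e-7 < fp.location_deg < 180.0 - 1e-7)


def sweep_bifurcation(
    profile: str,
    lambda_grid: Sequence[float],
    grid_step_deg: float = 0.1,
    max_jump_deg: float = 5.0,
    form: str = "gradient",
) -> BifurcationDiagram:
    """Sweep the schedule over lambda, linking fixed points into branches.

    Branches are continued by nearest location with a maximum allowed jump
    per lambda step (``max_jump_deg``); unlinked points start new branches.
    A creation/annihilation event is recorded at the midpoint of any grid
    interval across which the open-half-circle fixed-point count changes.
    """
    lam_grid = np.asarray(list(lambda_grid), dtype=float)
    if lam_grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    if np.any(np.diff(lam_grid) <= 0):
        raise ValueError("lambda_grid must be strictly increasing")
    if np.any(lam_grid < 0):
        raise ValueError("lambda values must be >= 0")
    schedule = get_schedule(profile)

    points: List[List[FixedPoint]] = []
    branch_ids: List[List[int]] = []
    events: List[BifurcationEvent] = []
    warn_msgs: List[str] = []

    next_branch = 0
    prev_fps: List[FixedPoint] = []
    prev_ids: List[int] = []
    for j, lam in enumerate(lam_grid):
        fps = find_fixed_points(schedule(float(lam)), grid_step_deg=grid_step_deg, form=form)
        if isinstance(fps, MarginalCircle):
            fps = []
        ids: List[Optional[int]] = [None] * len(fps)
        if prev_fps:
            # greedy nearest-location assignment, same stability class
            pairs = sorted(
                (
                    (circular_distance_deg(fp.location_deg, pfp.location_deg), i, k)
                    for i, fp in enumerate(fps)
                    for k, pfp in enumerate(prev_fps)
                    if fp.stability == pfp.stability
                ),
            )
            used_prev = set()
            taken = [
                (d, i, k)
                for d, i, k in pairs
                if d <= max_jump_deg
            ]
            # ambiguity check: two candidates nearly tied for the same point
            for d, i, k in taken:
                if ids[i] is None and k not in used_prev:
                    ids[i] = prev_ids[k]
                    used_prev.add(k)
            if any(ids[i] is None for i in range(len(fps))) and len(prev_fps) == len(fps):
                warn_msgs.append(
                    f"branch linking ambiguous near lambda={lam:g}: "
                    "grid may be too coarse"
                )
        for i in range(len(fps)):
            if ids[i] is None:
                ids[i] = next_branch
                next_branch += 1
        points.append(fps)
        branch_ids.append([int(x) for x in ids])

        if j > 0:
            c_prev = sum(1 for fp in prev_fps if 1e-7 < fp.location_deg < 180.0 - 1e-7)
            c_now = sum(1 for fp in fps if 1e-7 < fp.location_deg < 180.0 - 1e-7)
            if c_now != c_prev:
                kind = "creation" if c_now > c_prev else "annihilation"
                # locations of the new (or vanished) points in the half circle
                ref = prev_fps if c_now > c_prev else fps
                other = fps if c_now > c_prev else prev_fps
                fresh = [
                    fp.location_deg
                    for fp in other
                    if 1e-7 < fp.location_deg < 180.0 - 1e-7
                    and all(
                        circular_distance_deg(fp.location_deg, r.location_deg)
                        > max_jump_deg
                        for r in ref
                    )
                ]
                loc = float(np.mean(fresh)) if fresh else float("nan")
                events.append(
                    BifurcationEvent(
                        lambda_c=float(0.5 * (lam_grid[j - 1] + lam)),
                        kind=kind,
                        location_deg=loc,
                    )
                )
        prev_fps, prev_ids = fps, [int(x) for x in ids]

    return BifurcationDiagram(
        lambda_grid=lam_grid,
        points=points,
        branch_ids=branch_ids,
        events=events,
        warnings=warn_msgs,
    )


def detect_saddle_node(
    profile: str,
    lambda_lo: float,
    lambda_hi: float,
    tol: float = 1e-4,
    grid_step_deg: float = 0.1,
    form: str = "gradient",
) -> float:
    """Localize the lambda at which the open-half-circle fixed-point count changes.

    Bisects on lambda between ``lambda_lo`` and ``lambda_hi``; raises
    :class:`NoEventBracketedError` when the counts at the two ends agree.
    """
    if not (0 <= lambda_lo < lambda_hi):
        raise ValueError("need 0 <= lambda_lo < lambda_hi")
    schedule = get_schedule(profile)
    c_lo = _count_half_open(schedule(lambda_lo), form, grid_step_deg)
    c_hi = _count_half_open(schedule(lambda_hi), form, grid_step_deg)
    if c_lo == c_hi:
        raise NoEventBracketedError(
            f"no event bracketed: fixed-point count is {c_lo} at both "
            f"lambda={lambda_lo:g} and lambda={lambda_hi:g}"
        )
    lo, hi = float(lambda_lo), float(lambda_hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _count_half_open(schedule(mid), form, grid_step_deg) == c_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def relaxation_rate(fp: FixedPoint) -> float:
    """Relaxation rate (inverse time) of an attractor: the curvature V''.

    Larger curvature means faster return after a perturbation, i.e. a more
    stable pattern.  Repellors and marginal points have no relaxation rate.
    """
    if not fp.is_attractor:
        raise ValueError(
            f"relaxation rate is defined for attractors only, got {fp.stability!r}"
        )
    return fp.curvature
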