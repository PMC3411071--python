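"""Generalized HKB potential for bimanual relative phase and its gradient flow.

The relative phase phi between two rhythmically moving effectors evolves as a
gradient system, phi' = -dV/dphi.  The potential has two parts:

* a *skeleton*, a cosine-only Fourier series ``-sum_n a_n cos(n phi)`` that
  encodes the long-lived structure of the learner's repertoire (cosine terms
  only so that V is even, preserving left/right symmetry), and
* a transient *learning term*: a symmetric pair of von Mises wells of
  amplitude ``c``, concentration ``kappa`` and means ``+-psi``, normalized by
  ``2 pi I0(kappa)``, which pulls the landscape toward the phase being
  practiced.  The pair is symmetric because learning a phase psi entails
  learning -psi (swapping hands must leave the model invariant).

The classic bistable HKB potential ``-a cos phi - b cos 2phi`` is the special
case a_1 = a, a_2 = b with no learning term.

Two published practice schedules tie all learning-phase parameters to a
single control parameter lambda (a temporal measure of practice):

* bistable learners (attractors at 0 and 180 deg only) practicing 90 deg:
  ``a1=1, a2=3, a4=0.6 lam, c=0.5 lam, kappa=1.75 lam, psi=90``
* multistable learners (an extra attractor near 90 deg) practicing 135 deg:
  ``a1=1, a2=3, a4=3, a3=0.6 lam, c=0.9 lam, kappa=1.75 lam, psi=135``

All potentials, flows and curvatures are dimensionless; derivatives are taken
with respect to phi in radians, while every angle argument and angle return
value is in degrees (see :mod:`hkblearn.angles`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import i0e

__all__ = [
    "SkeletonCoefficients",
    "LearningTerm",
    "PotentialParams",
    "evaluate_potential",
    "evaluate_flow",
    "evaluate_curvature",
    "bistable_schedule",
    "multistable_schedule",
    "DEFAULT_SKELETON_ORDER",
]

#: Skeleton order used by the dense default representation; the published
#: schedules use n <= 4 but user landscapes may go higher.
DEFAULT_SKELETON_ORDER = 8


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SkeletonCoefficients:
    """Fourier-cosine skeleton ``-sum_n a_n cos(n phi)``, n = 1..N.

    ``a[k]`` is the amplitude of order ``n = k + 1``; absent orders are
    exactly zero.
    """

    a: tuple

    def __post_init__(self):
        coeffs = tuple(_check_finite(f"a{i + 1}", v) for i, v in enumerate(self.a))
        if len(coeffs) < 1:
            raise ValueError("skeleton needs at least one coefficient (N >= 1)")
        object.__setattr__(self, "a", coeffs)

    @property
    def order(self) -> int:
        return len(self.a)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.a, dtype=float)

    @property
    def is_flat(self) -> bool:
        return all(v == 0.0 for v in self.a)


@dataclass(frozen=True)
class LearningTerm:
    """Symmetric +-psi pair of von Mises wells: amplitude c, concentration kappa.

    The width of each well is roughly 1/kappa; kappa = 0 degenerates to a
    phi-independent constant (-c/pi in the potential, zero in the flow).
    Normalization is ``c / (2 pi I0(kappa))``; it is evaluated through the
    exponentially scaled Bessel function so that large kappa cannot overflow.
    """

    c: float
    kappa: float
    psi_deg: float

    def __post_init__(self):
        c = _check_finite("c", self.c)
        kappa = _check_finite("kappa", self.kappa)
        psi = _check_finite("psi_deg", self.psi_deg)
        if c < 0:
            raise ValueError(f"amplitude c must be >= 0, got {c}")
        if kappa < 0:
            raise ValueError(f"concentration kappa must be >= 0, got {kappa}")
        if not (0.0 < psi <= 180.0):
            raise ValueError(f"target phase psi_deg must lie in (0, 180], got {psi}")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "kappa", kappa)
        object.__setattr__(self, "psi_deg", psi)

    @property
    def psi_rad(self) -> float:
        return math.radians(self.psi_deg)

    @property
    def scaled_amplitude(self) -> float:
        """``c / (2 pi I0(kappa) e^{-kappa})``-safe prefactor.

        The well contributions are computed as
        ``scaled_amplitude * exp(kappa * (cos(.) - 1))`` which equals
        ``c/(2 pi I0(kappa)) * exp(kappa cos(.))`` without ever forming
        ``e^kappa`` explicitly.
        """
        return self.c / (2.0 * np.pi * float(i0e(self.kappa)))


@dataclass(frozen=True)
class PotentialParams:
    """Full parameter set of the learning potential V(phi).

    ``learning=None`` is equivalent to c = 0 (no practice force).  The
    resulting V is 2pi-periodic and even: V(phi) = V(-phi).
    """

    skeleton: SkeletonCoefficients
    learning: Optional[LearningTerm] = None
    profile: Optional[str] = None  # provenance: which schedule produced this
    lam: Optional[float] = None

    @property
    def is_flat(self) -> bool:
        """True when the flow vanishes identically (uniform landscape)."""
        learning_flat = (
            self.learning is None or self.learning.c == 0.0 or self.learning.kappa == 0.0
        )
        return self.skeleton.is_flat and learning_flat

    # -- serialization: flat key/value schema ------------------------------
    def to_dict(self) -> dict:
        d: dict = {}
        if self.profile is not None:
            d["profile"] = self.profile
        if self.lam is not None:
            d["lambda"] = self.lam
        for i, v in enumerate(self.skeleton.a, start=1):
            d[f"a{i}"] = v
        if self.learning is not None:
            d["c"] = self.learning.c
            d["kappa"] = self.learning.kappa
            d["psi_deg"] = self.learning.psi_deg
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PotentialParams":
        orders = sorted(
            int(k[1:]) for k in d if k.startswith("a") and k[1:].isdigit()
        )
        n_max = orders[-1] if orders else 1
        a = [float(d.get(f"a{n}", 0.0)) for n in range(1, n_max + 1)]
        learning = None
        if "c" in d or "kappa" in d or "psi_deg" in d:
            learning = LearningTerm(
                c=float(d.get("c", 0.0)),
                kappa=float(d.get("kappa", 0.0)),
                psi_deg=float(d.get("psi_deg", 90.0)),
            )
        return cls(
            skeleton=SkeletonCoefficients(tuple(a)),
            learning=learning,
            profile=d.get("profile"),
            lam=float(d["lambda"]) if "lambda" in d else None,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "PotentialParams":
        return cls.from_dict(json.loads(s))

    def with_learning(self, learning: Optional[LearningTerm]) -> "PotentialParams":
        return replace(self, learning=learning)


def _phi_rad(phi_deg) -> np.ndarray:
    phi = np.asarray(phi_deg, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phi must be finite")
    return np.radians(phi)


def _maybe_scalar(x: np.ndarray):
    return float(x) if x.ndim == 0 else x


def evaluate_potential(phi_deg, params: PotentialParams):
    """Evaluate V(phi).  ``phi_deg`` may be a scalar or array, in degrees."""
    phi = _phi_rad(phi_deg)
    v = np.zeros_like(phi)
    for n, a_n in enumerate(params.skeleton.a, start=1):
        if a_n != 0.0:
            v -= a_n * np.cos(n * phi)
    lt = params.learning
    if lt is not None and lt.c != 0.0:
        amp, k, psi = lt.scaled_amplitude, lt.kappa, lt.psi_rad
        v -= amp * (
            np.exp(k * (np.cos(phi - psi) - 1.0))
            + np.exp(k * (np.cos(phi + psi) - 1.0))
        )
    return _maybe_scalar(v)


def evaluate_flow(phi_deg, params: PotentialParams, form: str = "gradient"):
    """Rate of change of relative phase, phi' = -dV/dphi (radian derivative).

    ``form="gradient"`` (default) is the exact analytic negative derivative of
    the potential.  ``form="as_printed"`` reproduces an alternative typeset
    variant of the flow in which the von Mises contribution carries a common
    factor ``kappa sin(phi)`` outside the pair of exponentials; it is *not*
    the gradient of V and is provided for reproduction/sensitivity studies
    only.
    """
    if form not in ("gradient", "as_printed"):
        raise ValueError(f"unknown flow form {form!r}; use 'gradient' or 'as_printed'")
    phi = _phi_rad(phi_deg)
    f = np.zeros_like(phi)
    for n, a_n in enumerate(params.skeleton.a, start=1):
        if a_n != 0.0:
            f -= n * a_n * np.sin(n * phi)
    lt = params.learning
    if lt is not None and lt.c != 0.0 and lt.kappa != 0.0:
        amp, k, psi = lt.scaled_amplitude, lt.kappa, lt.psi_rad
        e_minus = np.exp(k * (np.cos(phi - psi) - 1.0))
        e_plus = np.exp(k * (np.cos(phi + psi) - 1.0))
        if form == "gradient":
            f -= amp * k * (np.sin(phi - psi) * e_minus + np.sin(phi + psi) * e_plus)
        else:  # as_printed
            f -= amp * (e_minus + e_plus) * k * np.sin(phi)
    return _maybe_scalar(f)


def evaluate_curvature(phi_deg, params: PotentialParams):
    """Second derivative d^2 V / dphi^2 (radian derivative).

    Positive at attractors (potential minima), negative at repellors.
    """
    phi = _phi_rad(phi_deg)
    v2 = np.zeros_like(phi)
    for n, a_n in enumerate(params.skeleton.a, start=1):
        if a_n != 0.0:
            v2 += n * n * a_n * np.cos(n * phi)
    lt = params.learning
    if lt is not None and lt.c != 0.0 and lt.kappa != 0.0:
        amp, k, psi = lt.scaled_amplitude, lt.kappa, lt.psi_rad
        s_m, s_p = np.sin(phi - psi), np.sin(phi + psi)
        c_m, c_p = np.cos(phi - psi), np.cos(phi + psi)
        e_m = np.exp(k * (c_m - 1.0))
        e_p = np.exp(k * (c_p - 1.0))
        # d/dphi of amp*k*(s e^{k cos}) terms, entering V'' with + sign
        v2 += amp * k * ((c_m - k * s_m * s_m) * e_m + (c_p - k * s_p * s_p) * e_p)
    return _maybe_scalar(v2)


def bistable_schedule(lam: float) -> PotentialParams:
    """Practice schedule of an initially bistable learner acquiring 90 deg.

    a1 = 1, a2 = 3, a4 = 0.6 lam, c = 0.5 lam, kappa = 1.75 lam, psi = 90 deg.
    At lam = 0 only a1, a2 are finite: attractors at 0 and 180 deg.
    """
    lam = _check_finite("lambda", lam)
    if lam < 0:
        raise ValueError(f"control parameter lambda must be >= 0, got {lam}")
    return PotentialParams(
        skeleton=SkeletonCoefficients((1.0, 3.0, 0.0, 0.6 * lam)),
        learning=LearningTerm(c=0.5 * lam, kappa=1.75 * lam, psi_deg=90.0),
        profile="bistable",
        lam=lam,
    )


def multistable_schedule(lam: float) -> PotentialParams:
    """Practice schedule of an initially multistable learner acquiring 135 deg.

    a1 = 1, a2 = 3, a4 = 3, a3 = 0.6 lam, c = 0.9 lam, kappa = 1.75 lam,
    psi = 135 deg.  At lam = 0 there is an extra attractor near 90 deg.
    """
    lam = _check_finite("lambda", lam)
    if lam < 0:
        raise ValueError(f"control parameter lambda must be >= 0, got {lam}")
    return PotentialParams(
        skeleton=SkeletonCoefficients((1.0, 3.0, 0.6 * lam, 3.0)),
        learning=LearningTerm(c=0.9 * lam, kappa=1.75 * lam, psi_deg=135.0),
        profile="multistable",
        lam=lam,
    )


SCHEDULES = {"bistable": bistable_schedule, "multistable": multistable_schedule}


def get_schedule(profile: str):
    try:
        return SCHEDULES[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; expected one of {sorted(SCHEDULES)}"
        ) from None
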