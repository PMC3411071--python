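"""Behavioral protocol emulation: scanning probes, classification, practice, recall.

The scanning probe presents required relative phases from 0 to 180 deg in
15-deg steps and measures per-phase accuracy (AE) and stability (SD).  The
environmental specification of the required phase is modeled solely through
the trial's initial condition (phi0 = psi_req) plus noise — the flow itself
contains no environmental forcing term, so each trial simply relaxes into
the basin that the required phase falls in.

A phase counts as *stable* when AE < 20 deg and SD < 20 deg.  A repertoire
with stable phases only at/near 0 and 180 deg is *bistable*; one with an
additional stable mid-range phase is *multistable*.  Bistable learners are
assigned 90 deg to learn, multistable learners 135 deg — in both cases a
pattern in-between those already in the repertoire.

Practice ramps the control parameter lambda (default: linearly to 5 over the
practice block).  After practice ends, the von Mises amplitude c decays
exponentially on a fast time scale while the skeleton coefficients remain
frozen at their end-of-learning values — the model's account of why a
pattern created by bifurcation is recalled later while a shifted pattern
migrates back toward its pre-learning location.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .angles import circular_distance_deg, wrap_deg
from .model import (
    LearningTerm,
    PotentialParams,
    SkeletonCoefficients,
    get_schedule,
)
from .simulate import (
    SimulationConfig,
    TrialSummary,
    circular_error_stats,
    integrate,
    summarize_trial,
)

__all__ = [
    "ScanningProbe",
    "ScanResult",
    "StabilityRule",
    "RepertoireClass",
    "LearningProtocol",
    "PostLearningModel",
    "run_scanning",
    "classify_repertoire",
    "assign_learning_task",
    "run_learning",
    "relax_post_learning",
    "run_recall",
]

DEFAULT_PROBE_PHASES = tuple(float(p) for p in range(0, 181, 15))


@dataclass(frozen=True)
class ScanningProbe:
    """Probe schedule: required phases (deg), trial duration, repetitions."""

    required_phases_deg: Tuple[float, ...] = DEFAULT_PROBE_PHASES
    trial_duration: float = 30.0
    repetitions: int = 3

    def __post_init__(self):
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for p in self.required_phases_deg:
            if not (0.0 <= p <= 180.0):
                raise ValueError(f"probe phases must lie in [0, 180], got {p}")


@dataclass
class ScanResult:
    """Per-required-phase averaged trial summaries plus run metadata."""

    summaries: List[TrialSummary]
    metadata: dict = field(default_factory=dict)

    @property
    def required_phases_deg(self) -> List[float]:
        return [s.required_deg for s in self.summaries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "required_deg": s.required_deg,
                    "CE": s.ce_deg,
                    "AE": s.ae_deg,
                    "SD": s.sd_deg,
                    "RMSE": s.rmse_deg,
                }
                for s in self.summaries
            ]
        )


@dataclass(frozen=True)
class StabilityRule:
    """A probe phase is stable when AE and SD are both below threshold."""

    ae_threshold_deg: float = 20.0
    sd_threshold_deg: float = 20.0

    def __post_init__(self):
        if self.ae_threshold_deg <= 0 or self.sd_threshold_deg <= 0:
            raise ValueError("stability thresholds must be positive")

    def is_stable(self, s: TrialSummary) -> bool:
        return s.ae_deg < self.ae_threshold_deg and s.sd_deg < self.sd_threshold_deg


@dataclass(frozen=True)
class RepertoireClass:
    label: str  # 'bistable' | 'multistable' | 'other'
    stable_phases_deg: Tuple[float, ...]
    degenerate: bool = False  # every probe phase passed the rule


@dataclass(frozen=True)
class LearningProtocol:
    """Practice block: profile schedule, target phase, trial count, lambda ramp.

    The canonical protocols pair bistable with psi = 90 deg and multistable
    with psi = 135 deg.  ``lambda_ramp`` maps trial index (0-based) to
    lambda; the default is linear from 0 to ``lambda_max`` across the block
    (practice time need not map linearly onto lambda — any saturating ramp
    can be supplied instead).
    """

    profile: str
    psi_target_deg: float
    trials: int = 50
    lambda_max: float = 5.0
    lambda_ramp: Optional[Callable[[int], float]] = None

    def ramp(self, trial: int) -> float:
        if self.lambda_ramp is not None:
            return float(self.lambda_ramp(trial))
        if self.trials <= 1:
            return self.lambda_max if self.trials == 1 else 0.0
        return self.lambda_max * trial / (self.trials - 1)

    @classmethod
    def canonical(cls, profile: str, trials: int = 50) -> "LearningProtocol":
        target = {"bistable": 90.0, "multistable": 135.0}[profile]
        return cls(profile=profile, psi_target_deg=target, trials=trials)


@dataclass(frozen=True)
class PostLearningModel:
    """Post-practice landscape: frozen skeleton, exponentially decaying c.

    ``c(elapsed) = c_end * exp(-elapsed / tau_c)`` while the skeleton stays
    at its end-of-learning values — the two time scales of reorganization.
    ``tau_c`` defaults to 5 practice-trial-equivalents (the fast scale).
    """

    frozen_skeleton: SkeletonCoefficients
    c_end: float
    kappa_end: float
    psi_deg: float
    tau_c: float = 5.0

    def __post_init__(self):
        if self.c_end < 0 or self.kappa_end < 0:
            raise ValueError("c_end and kappa_end must be >= 0")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be > 0")

    @classmethod
    def from_end_of_learning(
        cls, params: PotentialParams, tau_c: float = 5.0
    ) -> "PostLearningModel":
        lt = params.learning
        if lt is None:
            raise ValueError("end-of-learning parameters carry no learning term")
        return cls(
            frozen_skeleton=params.skeleton,
            c_end=lt.c,
            kappa_end=lt.kappa,
            psi_deg=lt.psi_deg,
            tau_c=tau_c,
        )


def run_scanning(
    params: PotentialParams,
    probe: ScanningProbe = ScanningProbe(),
    config: SimulationConfig = SimulationConfig(),
) -> ScanResult:
    """Simulate a scanning probe: one trial block per required phase.

    Each trial is initialized at the required phase; repetitions use
    successive seeds.  The per-phase summary pools the post-burn-in samples
    of all repetitions, so a probe phase whose repetitions settle into
    different basins shows up as high-SD (unstable) rather than being
    averaged into a spuriously tight pattern.
    """
    summaries = []
    for i, phase in enumerate(probe.required_phases_deg):
        pooled = []
        for r in range(probe.repetitions):
            cfg = replace(
                config,
                seed=config.seed + 100 * i + r,
                phi0_deg=phase,
                duration=probe.trial_duration,
            )
            traj = integrate(params, cfg)
            start = int(cfg.burn_in * len(traj.phases_deg))
            pooled.append(traj.phases_deg[start:])
        ce, sd = circular_error_stats(np.concatenate(pooled), phase)
        summaries.append(TrialSummary.from_ce_sd(phase, ce, sd))
    return ScanResult(
        summaries=summaries,
        metadata={
            "params": params.to_dict(),
            "seed": config.seed,
            "dt": config.dt,
            "noise_q": config.noise_q,
            "trial_duration": probe.trial_duration,
            "repetitions": probe.repetitions,
        },
    )


def classify_repertoire(
    scan: ScanResult, rule: StabilityRule = StabilityRule()
) -> RepertoireClass:
    """Label the repertoire from the stable probe phases.

    bistable: stable set within {0, 15, 165, 180} and containing 0 and 180.
    multistable: contains 0 and 180 plus at least one stable phase strictly
    inside (30, 150).  Everything else — including the degenerate case where
    every probe phase passes the rule — is 'other'.
    """
    if not scan.summaries:
        raise ValueError("scan is empty: nothing to classify")
    stable = tuple(s.required_deg for s in scan.summaries if rule.is_stable(s))
    stable_set = set(stable)
    if len(stable) == len(scan.summaries):
        return RepertoireClass("other", stable, degenerate=True)
    if {0.0, 180.0} <= stable_set:
        if any(30.0 < p < 150.0 for p in stable):
            return RepertoireClass("multistable", stable)
        if stable_set <= {0.0, 15.0, 165.0, 180.0}:
            return RepertoireClass("bistable", stable)
    return RepertoireClass("other", stable)


def assign_learning_task(cls: RepertoireClass) -> float:
    """Canonical to-be-learned phase: 90 deg for bistable, 135 for multistable."""
    if cls.label == "bistable":
        return 90.0
    if cls.label == "multistable":
        return 135.0
    raise ValueError(f"no canonical task for repertoire label {cls.label!r}")


def run_learning(
    protocol: LearningProtocol,
    config: SimulationConfig = SimulationConfig(),
) -> Tuple[List[TrialSummary], PotentialParams]:
    """Simulate a practice block; returns per-trial summaries and the
    end-of-learning (lambda_max) parameter set."""
    schedule = get_schedule(protocol.profile)
    summaries = []
    for t in range(protocol.trials):
        lam = protocol.ramp(t)
        params = schedule(lam)
        cfg = replace(config, seed=config.seed + t, phi0_deg=protocol.psi_target_deg)
        traj = integrate(params, cfg)
        summaries.append(summarize_trial(traj, protocol.psi_target_deg, burn_in=cfg.burn_in))
    final_lam = protocol.lambda_max if protocol.trials > 0 else 0.0
    return summaries, schedule(final_lam)


def relax_post_learning(model: PostLearningModel, elapsed: float) -> PotentialParams:
    """Landscape a time ``elapsed`` after practice ended: c decays, skeleton frozen."""
    if elapsed < 0:
        raise ValueError("elapsed time must be >= 0")
    c = model.c_end * math.exp(-elapsed / model.tau_c)
    return PotentialParams(
        skeleton=model.frozen_skeleton,
        learning=LearningTerm(c=c, kappa=model.kappa_end, psi_deg=model.psi_deg),
    )


def run_recall(
    model: PostLearningModel,
    elapsed: float,
    probe: ScanningProbe = ScanningProbe(),
    config: SimulationConfig = SimulationConfig(),
    rule: StabilityRule = StabilityRule(),
    recall_window_deg: float = 20.0,
) -> Tuple[ScanResult, bool]:
    """Scan the relaxed landscape and judge recall of the practiced phase.

    Recall succeeds when some probe phase passes the stability rule *and*
    the pattern actually produced there (probe phase + CE, i.e. the attractor
    the trial settles into) lies within ``recall_window_deg`` of the learned
    target.  A stable pattern that has migrated away from the target does
    not count as recall.
    """
    params = relax_post_learning(model, elapsed)
    scan = run_scanning(params, probe, config)
    verdict = False
    for s in scan.summaries:
        if not rule.is_stable(s):
            continue
        produced = wrap_deg(s.required_deg + s.ce_deg)
        if circular_distance_deg(produced, model.psi_deg) <= recall_window_deg:
            verdict = True
            break
    return scan, verdict
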