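"""Relapse classification and time-to-relapse survival analysis.

A spheroid counts as relapsed once its measured volume enlarges over a run
of consecutive time points (default: three consecutive increases); a
spheroid with no such run within the observation window is controlled and
right-censored at its last observation.  The controlled proportion over
time is summarised with the Kaplan-Meier product-limit estimator and arm
comparisons use the log-rank (Mantel-Cox) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ValidationError
from .volumetrics import SpheroidTrajectory, TreatmentArm

__all__ = [
    "ControlOutcome",
    "KMCurve",
    "detect_relapse",
    "classify_trajectories",
    "arm_scp",
    "km_curve",
    "logrank_test",
]


@dataclass(frozen=True)
class ControlOutcome:
    """Relapse status of one spheroid: an event time when relapsed, a
    censoring time (last observation) when controlled."""

    spheroid_id: str
    arm: TreatmentArm
    relapsed: bool
    event_time_d: float | None = None
    censor_time_d: float | None = None

    def __post_init__(self) -> None:
        if self.relapsed == (self.event_time_d is None) or self.relapsed == (
            self.censor_time_d is not None
        ):
            raise ValidationError(
                f"{self.spheroid_id}: exactly one of event/censor time must be set, "
                "matching the relapse flag"
            )

    @property
    def time_d(self) -> float:
        return self.event_time_d if self.relapsed else self.censor_time_d  # type: ignore[return-value]


@dataclass
class KMCurve:
    """Product-limit estimate of P(still controlled) at each relapse time."""

    times_d: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.surv) > 1e-12) or np.any((self.surv < 0) | (self.surv > 1)):
            raise ValidationError("survival estimates must be non-increasing in [0, 1]")

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times_d, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


def detect_relapse(
    traj: SpheroidTrajectory,
    min_consecutive: int = 3,
    rel_tol: float = 0.0,
    event_time: str = "first",
    rule: str = "increases",
) -> ControlOutcome:
    """Classify a trajectory as relapsed vs controlled.

    Relapse is declared at the first run of ``min_consecutive`` consecutive
    measurement-to-measurement volume increases, each exceeding the previous
    volume by a relative factor > ``1 + rel_tol``.  ``event_time='first'``
    dates the event at the first measurement of the qualifying run (the
    earliest evidence of regrowth); ``'last'`` at the run's final point.
    ``rule='points'`` switches to the alternative reading in which a run of
    ``min_consecutive`` *measurements* (hence ``min_consecutive - 1``
    increases) qualifies.
    """
    if min_consecutive < 1:
        raise ValidationError("min_consecutive must be >= 1")
    if rel_tol < 0:
        raise ValidationError("rel_tol must be >= 0")
    if event_time not in ("first", "last"):
        raise ValidationError("event_time must be 'first' or 'last'")
    if rule not in ("increases", "points"):
        raise ValidationError("rule must be 'increases' or 'points'")
    needed = min_consecutive if rule == "increases" else min_consecutive - 1
    v = traj.volumes_um3
    t = traj.times_d
    if len(traj) < needed + 1:
        warnings.warn(
            f"{traj.spheroid_id}: only {len(traj)} measurements, fewer than the "
            f"{needed + 1} needed to evidence regrowth; classified controlled"
        )
        return ControlOutcome(
            spheroid_id=traj.spheroid_id,
            arm=traj.arm,
            relapsed=False,
            censor_time_d=float(t[-1]),
        )
    increases = v[1:] > v[:-1] * (1.0 + rel_tol)
    run = 0
    for j, inc in enumerate(increases):
        run = run + 1 if inc else 0
        if run >= needed:
            start = j - needed + 1  # index of the run's first measurement
            idx = start if event_time == "first" else j + 1
            return ControlOutcome(
                spheroid_id=traj.spheroid_id,
                arm=traj.arm,
                relapsed=True,
                event_time_d=float(t[idx]),
            )
    return ControlOutcome(
        spheroid_id=traj.spheroid_id,
        arm=traj.arm,
        relapsed=False,
        censor_time_d=float(t[-1]),
    )


def classify_trajectories(
    trajectories: Iterable[SpheroidTrajectory], **kwargs
) -> list[ControlOutcome]:
    """Apply :func:`detect_relapse` to every trajectory."""
    return [detect_relapse(tr, **kwargs) for tr in trajectories]


def arm_scp(outcomes: Sequence[ControlOutcome]) -> tuple[int, int, float]:
    """Spheroid control probability of one treatment arm: the proportion of
    spheroids that lost regrowth capacity.  Returns (controlled, total, scp)."""
    if not outcomes:
        raise ValidationError("empty outcome set")
    arms = {o.arm for o in outcomes}
    if len(arms) > 1:
        raise ValidationError(f"mixed treatment arms in SCP computation: {arms}")
    total = len(outcomes)
    controlled = sum(not o.relapsed for o in outcomes)
    return controlled, total, controlled / total


def km_curve(outcomes: Sequence[ControlOutcome]) -> KMCurve:
    """Kaplan-Meier estimate of the controlled proportion over time, with
    relapse as the event and end of observation as censoring."""
    if not outcomes:
        raise ValidationError("empty outcome set")
    durations = np.array([o.time_d for o in outcomes])
    observed = np.array([o.relapsed for o in outcomes], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times_d=times,
        surv=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
    )


def logrank_test(
    group1: Sequence[ControlOutcome], group2: Sequence[ControlOutcome]
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank (Mantel-Cox) chi-square comparing the
    relapse-time distributions of two groups.  Returns (chi2, p)."""
    if not group1 or not group2:
        raise ValidationError("both groups must be non-empty")
    e1 = any(o.relapsed for o in group1)
    e2 = any(o.relapsed for o in group2)
    if not e1 and not e2:
        warnings.warn("no relapse events in either group; log-rank degenerate, p = 1")
        return 0.0, 1.0
    res = _ll_logrank(
        np.array([o.time_d for o in group1]),
        np.array([o.time_d for o in group2]),
        event_observed_A=np.array([o.relapsed for o in group1], dtype=bool),
        event_observed_B=np.array([o.relapsed for o in group2], dtype=bool),
    )
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        warnings.warn("log-rank statistic undefined on these data; p = 1")
        return 0.0, 1.0
    return chi2, p
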