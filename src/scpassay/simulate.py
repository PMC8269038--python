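"""Synthetic spheroid-trajectory generator with known ground truth.

Emulates a full-factorial hyperthermia (HT) x radiotherapy (RT) spheroid
control experiment: ~400 um spheroids, eleven radiation dose arms
(0-25 Gy in 2.5 Gy steps), >= 56 spheroids per arm, imaging every 2-3 days
over a 60-day horizon.  Each spheroid is assigned "controlled" with
probability SCP(D) = 1/(1 + exp(-(a + b*D))) where the intercept ``a``
carries an additive per-HT-condition radiosensitization shift.  Controlled
spheroids shrink monotonically toward a residual plateau; non-controlled
spheroids shrink, then regrow along a Gompertz curve after a dose-dependent
lag.  Measurements carry multiplicative lognormal noise on the diameter.

Untreated growth follows a Gompertz law
``V(t) = Vmax * exp(ln(V/Vmax) * exp(-alpha t))`` whose rate ``alpha`` is
parameterised through the early-phase doubling time, so that with the
defaults an untreated spheroid reaches 5 x V0 in about 9 days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError, ValidationError
from .volumetrics import SpheroidTrajectory, TreatmentArm, diameter_to_volume, volume_to_diameter

__all__ = [
    "GrowthParams",
    "ResponseParams",
    "ExperimentDesign",
    "TrajectorySet",
    "default_schedule",
    "simulate_trajectory",
    "simulate_experiment",
    "simulate_control_outcomes",
]

#: controlled spheroids decay to this fraction of V0 rather than vanishing,
#: so the regrowth rule (not disappearance) is the operative classifier
RESIDUAL_PLATEAU_FRACTION = 0.3


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value):
            raise ParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic parameters of spheroid volume growth and regression.

    ``doubling_time_d`` is the early-phase (V ~ V0) volume doubling time of
    untreated growth; ``v_max_fold`` the Gompertz carrying capacity as a
    multiple of V0; ``shrink_rate_per_d`` the exponential decay rate of the
    post-treatment regression phase; ``noise_cv`` the coefficient of
    variation of the multiplicative lognormal measurement noise applied to
    the diameter.
    """

    v0_diameter_um: float = 400.0
    v_max_fold: float = 50.0
    doubling_time_d: float = 3.0
    shrink_rate_per_d: float = 0.08
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        _require_finite(
            v0_diameter_um=self.v0_diameter_um,
            v_max_fold=self.v_max_fold,
            doubling_time_d=self.doubling_time_d,
            shrink_rate_per_d=self.shrink_rate_per_d,
            noise_cv=self.noise_cv,
        )
        if min(self.v0_diameter_um, self.doubling_time_d, self.shrink_rate_per_d) <= 0:
            raise ParameterError("growth parameters must be strictly positive")
        if self.noise_cv < 0 or self.noise_cv >= 0.5:
            raise ParameterError("noise_cv must be in [0, 0.5)")
        if self.v_max_fold <= 5:
            raise ParameterError("v_max_fold must exceed 5 so 5 x V0 is reachable")

    @property
    def v0_um3(self) -> float:
        return diameter_to_volume(self.v0_diameter_um)

    @property
    def gompertz_rate_per_d(self) -> float:
        """Gompertz alpha such that growth at V=V0 doubles in doubling_time_d."""
        return math.log(2.0) / (self.doubling_time_d * math.log(self.v_max_fold))


@dataclass(frozen=True)
class ResponseParams:
    """Ground-truth dose-response: logistic SCP(D) = expit(a + b*D).

    ``ht_dose_shift`` maps an HT condition (temperature degC, duration min)
    to an additive shift of the intercept ``a`` — radiosensitization as a
    left-shift of the dose-response curve.  ``lag_per_gy_d`` is the regrowth
    delay per Gy for spheroids that are not controlled.
    """

    a_true: float = -5.55
    b_true: float = 0.5
    lag_per_gy_d: float = 1.2
    ht_dose_shift: Mapping[tuple[float, float], float] = field(
        default_factory=lambda: {
            (37.0, 0.0): 0.0,
            (42.5, 30.0): 1.2,
            (42.5, 60.0): 1.9,
            (44.5, 30.0): 1.8,
            (46.5, 30.0): 3.95,
        }
    )

    def __post_init__(self) -> None:
        _require_finite(a_true=self.a_true, b_true=self.b_true, lag_per_gy_d=self.lag_per_gy_d)
        for shift in self.ht_dose_shift.values():
            _require_finite(ht_dose_shift=shift)
        if self.b_true <= 0:
            raise ParameterError("b_true must be > 0")
        if -self.a_true / self.b_true <= 0:
            raise ParameterError("implied true SCD50 = -a/b must be positive")
        if self.lag_per_gy_d < 0:
            raise ParameterError("lag_per_gy_d must be >= 0")

    def effective_intercept(self, arm: TreatmentArm) -> float:
        shift = self.ht_dose_shift.get((arm.ht_temp_c, arm.ht_duration_min), 0.0)
        return self.a_true + shift

    def control_probability(self, arm: TreatmentArm) -> float:
        """SCP(D) for the arm's effective (a, b)."""
        from .dose_response import scp_logistic

        return scp_logistic(arm.dose_gy, self.effective_intercept(arm), self.b_true)

    def true_scd50(self, arm: TreatmentArm | None = None) -> float:
        a = self.a_true if arm is None else self.effective_intercept(arm)
        return -a / self.b_true


def default_schedule(horizon_d: float = 60.0) -> tuple[float, ...]:
    """Imaging days: t=0 then alternating 2/3-day intervals up to the horizon."""
    days = [0.0]
    step = 2.0
    while days[-1] < horizon_d:
        days.append(min(days[-1] + step, horizon_d))
        step = 5.0 - step  # alternate 2, 3
    return tuple(days)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of the simulated experiment."""

    dose_arms_gy: tuple[float, ...] = tuple(np.arange(0.0, 25.01, 2.5))
    ht_conditions: tuple[tuple[float, float], ...] = (
        (37.0, 0.0),
        (42.5, 30.0),
        (42.5, 60.0),
        (44.5, 30.0),
        (46.5, 30.0),
    )
    n_per_arm: int = 56
    schedule_d: tuple[float, ...] = field(default_factory=default_schedule)
    seed: int = 0
    adjunct: str = "none"

    def __post_init__(self) -> None:
        doses = np.asarray(self.dose_arms_gy, dtype=float)
        if doses.size < 1 or np.any(doses < 0) or np.any(np.diff(doses) <= 0):
            raise ValidationError("dose arms must be non-negative and strictly increasing")
        if len(set(self.ht_conditions)) != len(self.ht_conditions):
            raise ValidationError("duplicate HT conditions in design")
        if self.n_per_arm < 1:
            raise ValidationError("n_per_arm must be >= 1")
        sched = np.asarray(self.schedule_d, dtype=float)
        if sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise ValidationError("schedule must start at 0 and strictly increase")

    @property
    def arms(self) -> list[TreatmentArm]:
        return [
            TreatmentArm(ht_temp_c=t, ht_duration_min=m, dose_gy=d, adjunct=self.adjunct)
            for (t, m) in self.ht_conditions
            for d in self.dose_arms_gy
        ]


@dataclass
class TrajectorySet:
    """Simulated trajectories plus the oracle ground-truth labels.

    The oracle table exists for recovery tests only; real data have no
    counterpart and downstream analysis never reads it.
    """

    trajectories: list[SpheroidTrajectory]
    oracle: pd.DataFrame  # columns: spheroid_id, arm fields, true_controlled, lag_d

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per measurement."""
        rows = []
        for tr in self.trajectories:
            arm = tr.arm
            d_um = volume_to_diameter(tr.volumes_um3)
            for t, v, d in zip(tr.times_d, tr.volumes_um3, d_um):
                rows.append(
                    (
                        tr.spheroid_id,
                        arm.ht_temp_c,
                        arm.ht_duration_min,
                        arm.dose_gy,
                        arm.adjunct,
                        t,
                        d,
                        v,
                        tr.v0_um3,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "spheroid_id",
                "ht_temp_c",
                "ht_duration_min",
                "dose_gy",
                "adjunct",
                "time_d",
                "diameter_um",
                "volume_um3",
                "v0_um3",
            ],
        )


def _true_volume_curve(
    times: np.ndarray,
    v0: float,
    controlled: bool,
    lag_d: float,
    growth: GrowthParams,
) -> np.ndarray:
    """Noise-free volume course: regression toward the residual plateau and,
    for non-controlled spheroids, Gompertz regrowth after the lag."""
    v_plateau = RESIDUAL_PLATEAU_FRACTION * v0
    v_max = growth.v_max_fold * v0
    alpha = growth.gompertz_rate_per_d

    def shrink(t: np.ndarray) -> np.ndarray:
        return v_plateau + (v0 - v_plateau) * np.exp(-growth.shrink_rate_per_d * t)

    if controlled:
        return shrink(times)
    v = np.empty_like(times)
    pre = times <= lag_d
    v[pre] = shrink(times[pre])
    v_nadir = float(shrink(np.asarray([lag_d]))[0])
    post = ~pre
    v[post] = v_max * np.exp(math.log(v_nadir / v_max) * np.exp(-alpha * (times[post] - lag_d)))
    return v


def _measure(volumes: np.ndarray, noise_cv: float, rng: np.random.Generator) -> np.ndarray:
    """Apply multiplicative lognormal noise on the diameter (cubed on volume)."""
    if noise_cv == 0:
        return volumes.copy()
    sigma = math.sqrt(math.log1p(noise_cv**2))
    d = volume_to_diameter(volumes)
    d_meas = d * np.exp(sigma * rng.standard_normal(d.shape))
    return diameter_to_volume(d_meas)


def simulate_trajectory(
    growth: GrowthParams,
    response: ResponseParams,
    arm: TreatmentArm,
    rng: np.random.Generator,
    schedule_d: Sequence[float] | None = None,
    spheroid_id: str = "s0",
    controlled: bool | None = None,
) -> tuple[SpheroidTrajectory, bool]:
    """Simulate one spheroid; returns the trajectory and its ground-truth
    control label.

    The label is drawn Bernoulli(SCP(dose)) from the arm's effective logistic
    parameters unless forced via ``controlled``.  The pre-treatment baseline
    measurement is noisy like every other observation.
    """
    times = np.asarray(
        default_schedule() if schedule_d is None else schedule_d, dtype=float
    )
    if controlled is None:
        controlled = bool(rng.random() < response.control_probability(arm))
    lag_d = response.lag_per_gy_d * arm.dose_gy
    v0 = growth.v0_um3
    v_true = _true_volume_curve(times, v0, controlled, lag_d, growth)
    v0_meas = float(_measure(np.asarray([v0]), growth.noise_cv, rng)[0])
    v_meas = _measure(v_true, growth.noise_cv, rng)
    traj = SpheroidTrajectory(
        spheroid_id=spheroid_id,
        arm=arm,
        times_d=times,
        volumes_um3=v_meas,
        v0_um3=v0_meas,
    )
    return traj, controlled


def simulate_experiment(
    design: ExperimentDesign,
    growth: GrowthParams | None = None,
    response: ResponseParams | None = None,
) -> TrajectorySet:
    """Simulate the full factorial experiment.

    Reproducible given ``design.seed``: each spheroid draws from its own RNG
    substream keyed by (arm index, spheroid index), so resampling or
    regenerating one arm never perturbs another.
    """
    growth = growth or GrowthParams()
    response = response or ResponseParams()
    trajectories: list[SpheroidTrajectory] = []
    oracle_rows = []
    seen: set[str] = set()
    for arm_idx, arm in enumerate(design.arms):
        for i in range(design.n_per_arm):
            ss = np.random.SeedSequence(design.seed, spawn_key=(arm_idx, i))
            rng = np.random.Generator(np.random.PCG64(ss))
            sid = f"a{arm_idx:02d}-{arm.condition}-{arm.dose_gy:g}Gy-{i:03d}"
            if sid in seen:
                raise GenerationError(f"duplicate spheroid id {sid!r}")
            seen.add(sid)
            traj, controlled = simulate_trajectory(
                growth,
                response,
                arm,
                rng,
                schedule_d=design.schedule_d,
                spheroid_id=sid,
            )
            trajectories.append(traj)
            oracle_rows.append(
                (
                    sid,
                    arm.ht_temp_c,
                    arm.ht_duration_min,
                    arm.dose_gy,
                    arm.adjunct,
                    controlled,
                    response.lag_per_gy_d * arm.dose_gy,
                )
            )
    oracle = pd.DataFrame(
        oracle_rows,
        columns=[
            "spheroid_id",
            "ht_temp_c",
            "ht_duration_min",
            "dose_gy",
            "adjunct",
            "true_controlled",
            "lag_d",
        ],
    )
    return TrajectorySet(trajectories=trajectories, oracle=oracle)


def simulate_control_outcomes(
    design: ExperimentDesign,
    response: ResponseParams | None = None,
    ht_condition: tuple[float, float] = (37.0, 0.0),
    seed: int | None = None,
) -> dict[float, np.ndarray]:
    """Draw per-spheroid control flags directly from the logistic model for
    one HT condition — the outcome layer of the simulator without volume
    kinetics.  Used when only dose-response counts matter.
    """
    response = response or ResponseParams()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    out: dict[float, np.ndarray] = {}
    for dose in design.dose_arms_gy:
        arm = TreatmentArm(
            ht_temp_c=ht_condition[0], ht_duration_min=ht_condition[1], dose_gy=dose
        )
        p = response.control_probability(arm)
        out[float(dose)] = rng.random(design.n_per_arm) < p
    return out
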