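"""Spheroid volumetry and growth-delay statistics.

A spheroid's therapeutic response is quantified on its volume trajectory
``V(t)`` relative to the pre-treatment baseline ``V0``.  The growth-delay
endpoint is the time to reach ``5 x V0``, obtained by regressing
``ln V`` on time over the measurements bracketing the threshold crossing,
and normalised by the mean time of an untreated control population.
Population comparisons use the Mann-Whitney U test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, ValidationError

__all__ = [
    "TreatmentArm",
    "SpheroidTrajectory",
    "GrowthDelayResult",
    "MannWhitneyResult",
    "diameter_to_volume",
    "volume_to_diameter",
    "time_to_kfold_volume",
    "relative_growth_delay",
    "mann_whitney",
]


@dataclass(frozen=True)
class TreatmentArm:
    """One experimental condition: hyperthermia (HT) dose, radiation dose and
    optional adjunct compound.

    ``ht_temp_c``/``ht_duration_min`` define the thermal dose (37 degC / 0 min
    is the unheated control), ``dose_gy`` the single-fraction X-ray dose, and
    ``adjunct`` an optional co-treatment label (e.g. a chemical chaperone).
    """

    ht_temp_c: float = 37.0
    ht_duration_min: float = 0.0
    dose_gy: float = 0.0
    adjunct: str = "none"

    def __post_init__(self) -> None:
        if not (37.0 <= self.ht_temp_c <= 47.0):
            raise ValidationError(
                f"ht_temp_c must be in [37, 47] degC, got {self.ht_temp_c}"
            )
        if self.ht_duration_min < 0:
            raise ValidationError("ht_duration_min must be >= 0")
        if self.dose_gy < 0:
            raise ValidationError("dose_gy must be >= 0")

    @property
    def ht_condition(self) -> str:
        """Label of the thermal condition, e.g. ``'42.5C/30min'``."""
        return f"{self.ht_temp_c:g}C/{self.ht_duration_min:g}min"

    @property
    def condition(self) -> str:
        """Thermal condition plus adjunct — the grouping key for a
        dose-response curve."""
        if self.adjunct == "none":
            return self.ht_condition
        return f"{self.ht_condition}+{self.adjunct}"

    @property
    def label(self) -> str:
        return f"{self.condition}/{self.dose_gy:g}Gy"


@dataclass
class SpheroidTrajectory:
    """Measured volume time series of one spheroid after treatment.

    Times are days post-treatment with t=0 at treatment; ``v0_um3`` is the
    volume measured directly before treatment onset.
    """

    spheroid_id: str
    arm: TreatmentArm
    times_d: np.ndarray
    volumes_um3: np.ndarray
    v0_um3: float

    def __post_init__(self) -> None:
        self.times_d = np.asarray(self.times_d, dtype=float)
        self.volumes_um3 = np.asarray(self.volumes_um3, dtype=float)
        if self.times_d.ndim != 1 or self.times_d.size < 1:
            raise ValidationError(f"{self.spheroid_id}: need >= 1 measurement")
        if self.times_d.shape != self.volumes_um3.shape:
            raise ValidationError(
                f"{self.spheroid_id}: times and volumes differ in length"
            )
        if np.any(np.diff(self.times_d) <= 0):
            raise ValidationError(
                f"{self.spheroid_id}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.volumes_um3)) or np.any(self.volumes_um3 <= 0):
            raise ValidationError(
                f"{self.spheroid_id}: volumes must be positive and finite"
            )
        if not (np.isfinite(self.v0_um3) and self.v0_um3 > 0):
            raise ValidationError(f"{self.spheroid_id}: v0 must be positive")

    def __len__(self) -> int:
        return self.times_d.size

    @property
    def relative_volumes(self) -> np.ndarray:
        """V(t)/V0 — the scale-free trajectory every statistic operates on."""
        return self.volumes_um3 / self.v0_um3


@dataclass
class GrowthDelayResult:
    """Per-spheroid times to the k-fold volume threshold and relative delays.

    ``relative_delay`` maps each treated spheroid that reached the threshold
    to its time divided by the mean time of the untreated control population;
    spheroids never reaching the threshold within observation are counted in
    ``censored_count`` and excluded from the ratio set.
    """

    per_spheroid_time_d: dict[str, float | None]
    control_mean_time_d: float
    relative_delay: dict[str, float]
    censored_count: int
    k: float = 5.0
    control_censored_count: int = 0

    @property
    def mean_relative_delay(self) -> float:
        if not self.relative_delay:
            return math.nan
        return float(np.mean(list(self.relative_delay.values())))


def diameter_to_volume(diameter_um: float | np.ndarray) -> float | np.ndarray:
    """Sphere volume (pi/6)*d^3 in um^3 from a diameter in um."""
    d = np.asarray(diameter_um, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValidationError("diameter must be positive and finite")
    v = (np.pi / 6.0) * d**3
    return float(v) if np.isscalar(diameter_um) or v.ndim == 0 else v


def volume_to_diameter(volume_um3: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`diameter_to_volume`."""
    v = np.asarray(volume_um3, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValidationError("volume must be positive and finite")
    d = (6.0 * v / np.pi) ** (1.0 / 3.0)
    return float(d) if np.isscalar(volume_um3) or d.ndim == 0 else d


def time_to_kfold_volume(
    traj: SpheroidTrajectory, k: float = 5.0, window: int = 2
) -> float | None:
    """Time (days) at which the trajectory crosses ``k * V0``.

    The first measurement at or above the threshold is located and a
    least-squares regression of ``ln V`` on ``t`` is fitted over ``window``
    measurements bracketing the crossing; the returned time is where the
    regression line equals ``ln(k * V0)``.  With the default ``window=2``
    this is exact log-linear interpolation between the bracketing pair.
    Returns ``None`` (right-censored) if the threshold is never reached.
    """
    if k <= 1:
        raise ValidationError("k must be > 1")
    if window < 2:
        raise ValidationError("window must be >= 2")
    rel = traj.relative_volumes
    above = np.nonzero(rel >= k)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        # already beyond threshold at the first observation
        return float(traj.times_d[0])
    n = len(traj)
    w = min(window, n)
    # centre the window on the crossing interval (i-1, i)
    lo = i - 1 - (w - 2) // 2
    lo = max(0, min(lo, n - w))
    t = traj.times_d[lo : lo + w]
    logv = np.log(traj.volumes_um3[lo : lo + w])
    if np.ptp(t) == 0:
        raise AnalysisError(f"{traj.spheroid_id}: degenerate regression window")
    slope, intercept = np.polyfit(t, logv, 1)
    if slope <= 0:
        # wide noisy window can produce a non-increasing fit even though the
        # bracketing pair crossed; fall back to exact pair interpolation
        t2 = traj.times_d[i - 1 : i + 1]
        logv2 = np.log(traj.volumes_um3[i - 1 : i + 1])
        slope, intercept = np.polyfit(t2, logv2, 1)
    return float((math.log(k * traj.v0_um3) - intercept) / slope)


def relative_growth_delay(
    treated: Iterable[SpheroidTrajectory],
    controls: Iterable[SpheroidTrajectory],
    k: float = 5.0,
    window: int = 2,
) -> GrowthDelayResult:
    """Relative growth delay of a treated population vs untreated controls.

    Each treated spheroid's time to ``k x V0`` is divided by the mean time of
    the control population; censored spheroids (threshold never reached) are
    excluded from the ratios and counted.
    """
    control_times = []
    control_censored = 0
    for c in controls:
        tc = time_to_kfold_volume(c, k=k, window=window)
        if tc is None:
            control_censored += 1
        else:
            control_times.append(tc)
    if not control_times:
        raise AnalysisError("no control spheroid reached the volume threshold")
    control_mean = float(np.mean(control_times))

    per_spheroid: dict[str, float | None] = {}
    delays: dict[str, float] = {}
    censored = 0
    for s in treated:
        ts = time_to_kfold_volume(s, k=k, window=window)
        per_spheroid[s.spheroid_id] = ts
        if ts is None:
            censored += 1
        else:
            delays[s.spheroid_id] = ts / control_mean
    return GrowthDelayResult(
        per_spheroid_time_d=per_spheroid,
        control_mean_time_d=control_mean,
        relative_delay=delays,
        censored_count=censored,
        k=k,
        control_censored_count=control_censored,
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # 'exact' | 'asymptotic' | 'degenerate'


def mann_whitney(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` uses the exact null distribution when ``n*m <= 400`` and
    the pooled data carry no ties, otherwise the normal approximation with
    midranks, tie correction and continuity correction.  The reported U is
    the statistic of ``x`` (so ``U + U' = n*m``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p set to 1")
        return MannWhitneyResult(u=x.size * y.size / 2.0, p_value=1.0, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue), method=method)
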