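"""Logistic SCP dose-response fitting, SCD50, bootstrap CIs and thermal
enhancement ratios.

The dose-response model is the two-parameter logistic used for tumour
control probability,

    SCP(D) = 1 / (1 + exp(-(a + b * D))),

fitted to per-arm controlled/total counts by binomial maximum likelihood.
The spheroid control dose 50% is SCD50 = -a/b, the dose at which half the
population loses regrowth capacity.  Confidence intervals come from a
nonparametric bootstrap that resamples spheroids with replacement within
each dose arm and refits per replicate.  The thermal enhancement ratio
TER = SCD50(RT alone) / SCD50(HT + RT) quantifies radiosensitization by
hyperthermia.

SCP data invite (quasi-)complete separation — 0 Gy arms are typically all
relapse and the top dose all controlled — so a Firth-penalized fit backs
up the plain MLE whenever the latter diverges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit, xlogy

from .control import ControlOutcome
from .errors import DegenerateDataError, FitError, ParameterError, ValidationError

__all__ = [
    "DoseResponsePoint",
    "SCPCurveFit",
    "TERResult",
    "scp_logistic",
    "binomial_loglik",
    "fit_scp_curve",
    "bootstrap_scd50",
    "compute_ter",
    "compare_scd50",
    "outcomes_by_dose",
    "dose_response_points",
]


@dataclass(frozen=True)
class DoseResponsePoint:
    """Controlled/total counts of one dose arm."""

    dose_gy: float
    controlled: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.controlled <= self.total) or self.total <= 0:
            raise ValidationError(
                f"need 0 <= controlled <= total with total > 0, got "
                f"{self.controlled}/{self.total}"
            )

    @property
    def scp(self) -> float:
        return self.controlled / self.total


@dataclass
class SCPCurveFit:
    """Fitted logistic dose-response for one HT condition.

    ``scd50_gy = -a/b`` exactly; ``ci95_gy`` is the percentile 95% CI of the
    bootstrap SCD50 replicates when a bootstrap was run.
    """

    a: float
    b: float
    converged: bool
    method: str = "mle"  # 'mle' | 'firth' | 'lsq'
    ci95_gy: tuple[float, float] | None = None
    bootstrap_scd50: np.ndarray | None = None
    n_boot: int = 0
    n_failed: int = 0
    points: tuple[DoseResponsePoint, ...] = ()

    @property
    def scd50_gy(self) -> float:
        return -self.a / self.b

    def predict(self, dose_gy: float | np.ndarray) -> float | np.ndarray:
        return scp_logistic(dose_gy, self.a, self.b)


@dataclass(frozen=True)
class TERResult:
    """Thermal enhancement ratio SCD50(RT)/SCD50(HT+RT) with bootstrap CI."""

    ter: float
    ci95: tuple[float, float] | None = None
    p_boot: float | None = None


def scp_logistic(dose_gy, a: float, b: float):
    """SCP(D) = 1/(1 + exp(-a - b*D)), overflow-safe."""
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ParameterError("logistic parameters must be finite")
    return expit(a + b * np.asarray(dose_gy, dtype=float)) if np.ndim(dose_gy) else float(
        expit(a + b * dose_gy)
    )


def binomial_loglik(a: float, b: float, points: Sequence[DoseResponsePoint]) -> float:
    """Binomial log-likelihood (constants dropped) of (a, b) on count data."""
    d = np.array([p.dose_gy for p in points])
    y = np.array([p.controlled for p in points], dtype=float)
    m = np.array([p.total for p in points], dtype=float)
    eta = a + b * d
    # log pi and log(1-pi) computed stably from the linear predictor
    log_pi = -np.logaddexp(0.0, -eta)
    log_1mpi = -np.logaddexp(0.0, eta)
    return float(np.sum(y * log_pi + (m - y) * log_1mpi))


def _newton_fit(
    dose: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    firth: bool = False,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Newton-Raphson for the 2-parameter binomial logistic; with
    ``firth=True`` uses the Firth-adjusted score, which stays finite under
    complete separation."""
    X = np.column_stack([np.ones_like(dose), dose])
    # start from the empirical logit fit for a sane basin
    p0 = np.clip((y + 0.5) / (m + 1.0), 1e-6, 1 - 1e-6)
    beta = np.linalg.lstsq(X, np.log(p0 / (1 - p0)), rcond=None)[0]
    for _ in range(max_iter):
        eta = X @ beta
        pi = expit(eta)
        w = m * pi * (1 - pi)
        xtwx = X.T @ (w[:, None] * X)
        resid = y - m * pi
        if firth:
            try:
                cov = np.linalg.inv(xtwx)
            except np.linalg.LinAlgError:
                return beta, False
            h = np.einsum("ij,jk,ik->i", X, cov, X) * w
            resid = resid + h * (0.5 - pi)
        score = X.T @ resid
        try:
            step = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            return beta, False
        # dampen wild steps; separation drives |beta| off to infinity
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e4:
            return beta, False
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def _lsq_fit(dose: np.ndarray, y: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, bool]:
    """Least squares on the observed proportions — a comparison mode, not the
    primary criterion."""
    from scipy.optimize import curve_fit

    prop = y / m
    p0 = np.clip((y + 0.5) / (m + 1.0), 1e-6, 1 - 1e-6)
    beta0 = np.linalg.lstsq(
        np.column_stack([np.ones_like(dose), dose]), np.log(p0 / (1 - p0)), rcond=None
    )[0]
    try:
        popt, _ = curve_fit(
            lambda d, a, b: expit(a + b * d), dose, prop, p0=beta0, maxfev=10000
        )
        return popt, True
    except RuntimeError:
        return beta0, False


def fit_scp_curve(
    points: Sequence[DoseResponsePoint], method: str = "mle"
) -> SCPCurveFit:
    """Fit the logistic dose-response to per-arm counts.

    ``method='mle'`` is binomial maximum likelihood with an automatic
    Firth-penalized fallback on (quasi-)separation, flagged in the result's
    ``method``; ``'firth'`` forces the penalized fit; ``'lsq'`` least squares
    on proportions.
    """
    points = tuple(points)
    doses = {p.dose_gy for p in points}
    if len(doses) < 2:
        raise DegenerateDataError("need >= 2 distinct doses to fit a slope")
    tot_controlled = sum(p.controlled for p in points)
    tot = sum(p.total for p in points)
    if tot_controlled == 0 or tot_controlled == tot:
        raise DegenerateDataError(
            "all spheroids controlled or all relapsed across every dose; "
            "the dose-response is unidentifiable"
        )
    d = np.array([p.dose_gy for p in points], dtype=float)
    y = np.array([p.controlled for p in points], dtype=float)
    m = np.array([p.total for p in points], dtype=float)
    if method == "lsq":
        beta, ok = _lsq_fit(d, y, m)
        used = "lsq"
    elif method in ("mle", "firth"):
        used = method
        if method == "mle":
            beta, ok = _newton_fit(d, y, m, firth=False)
            # separation manifests as divergence or absurd slope magnitude
            if not ok or np.max(np.abs(beta)) > 50.0:
                beta, ok = _newton_fit(d, y, m, firth=True)
                used = "firth"
        else:
            beta, ok = _newton_fit(d, y, m, firth=True)
    else:
        raise ValidationError(f"unknown fit method {method!r}")
    return SCPCurveFit(
        a=float(beta[0]), b=float(beta[1]), converged=bool(ok), method=used, points=points
    )


def outcomes_by_dose(outcomes: Iterable[ControlOutcome]) -> dict[float, np.ndarray]:
    """Group per-spheroid controlled flags by dose; the outcomes must all
    belong to one HT condition."""
    conditions = set()
    acc: dict[float, list[bool]] = {}
    for o in outcomes:
        conditions.add((o.arm.ht_temp_c, o.arm.ht_duration_min, o.arm.adjunct))
        acc.setdefault(o.arm.dose_gy, []).append(not o.relapsed)
    if len(conditions) > 1:
        raise ValidationError(f"outcomes span multiple HT conditions: {conditions}")
    return {dose: np.asarray(flags, dtype=bool) for dose, flags in sorted(acc.items())}


def dose_response_points(
    outcomes_or_flags: Iterable[ControlOutcome] | Mapping[float, np.ndarray],
) -> list[DoseResponsePoint]:
    """Aggregate spheroid-level outcomes (or a dose -> flags mapping) into
    per-arm controlled/total counts."""
    if isinstance(outcomes_or_flags, Mapping):
        flags = outcomes_or_flags
    else:
        flags = outcomes_by_dose(outcomes_or_flags)
    return [
        DoseResponsePoint(dose_gy=float(dose), controlled=int(np.sum(f)), total=int(f.size))
        for dose, f in sorted(flags.items())
    ]


def bootstrap_scd50(
    outcomes_by_arm: Iterable[ControlOutcome] | Mapping[float, np.ndarray],
    n_boot: int = 4000,
    seed: int | None = None,
    method: str = "mle",
) -> SCPCurveFit:
    """Point fit plus a spheroid-level bootstrap of SCD50.

    Spheroids are resampled with replacement within each dose arm and the
    logistic refitted per replicate; the 95% CI is the percentile 2.5/97.5
    interval of the replicate SCD50s.  Because the per-spheroid outcome is a
    Bernoulli flag, within-arm resampling is realised as a binomial draw of
    the controlled count — distributionally identical and much faster.
    Replicates that fail to converge (or fit a non-positive slope) are
    dropped and counted in ``n_failed``.
    """
    if n_boot < 0:
        raise ValidationError("n_boot must be >= 0")
    if isinstance(outcomes_by_arm, Mapping):
        flags = {float(k): np.asarray(v, dtype=bool) for k, v in outcomes_by_arm.items()}
    else:
        flags = outcomes_by_dose(outcomes_by_arm)
    points = dose_response_points(flags)
    fit = fit_scp_curve(points, method=method)
    if n_boot == 0:
        return fit
    rng = np.random.default_rng(seed)
    doses = np.array([p.dose_gy for p in points])
    totals = np.array([p.total for p in points])
    phat = np.array([p.scp for p in points])
    counts = rng.binomial(totals, phat, size=(n_boot, len(points)))
    reps = np.full(n_boot, np.nan)
    n_failed = 0
    for r in range(n_boot):
        yr = counts[r].astype(float)
        tot = yr.sum()
        if tot == 0 or tot == totals.sum():
            n_failed += 1
            continue
        beta, ok = _newton_fit(doses, yr, totals.astype(float), firth=False)
        if not ok or np.max(np.abs(beta)) > 50.0:
            beta, ok = _newton_fit(doses, yr, totals.astype(float), firth=True)
        if not ok or beta[1] <= 0:
            n_failed += 1
            continue
        reps[r] = -beta[0] / beta[1]
    reps = reps[np.isfinite(reps)]
    if n_failed > 0.1 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap replicates failed to converge; "
            "the CI may be unreliable"
        )
    ci = (
        (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
        if reps.size
        else None
    )
    fit.ci95_gy = ci
    fit.bootstrap_scd50 = reps
    fit.n_boot = n_boot
    fit.n_failed = n_failed
    return fit


def compute_ter(fit_rt: SCPCurveFit, fit_htrt: SCPCurveFit) -> TERResult:
    """Thermal enhancement ratio SCD50(RT alone) / SCD50(HT + RT).

    When both fits carry bootstrap distributions the CI is the percentile
    interval of ratios of index-paired (independent) replicates, and
    ``p_boot`` the two-sided bootstrap significance of TER != 1.
    """
    for f, name in ((fit_rt, "RT"), (fit_htrt, "HT+RT")):
        if not f.converged:
            raise FitError(f"{name} fit did not converge")
        if f.b <= 0 or f.scd50_gy <= 0:
            raise FitError(f"{name} fit has non-positive slope or SCD50")
    ter = fit_rt.scd50_gy / fit_htrt.scd50_gy
    if fit_rt.bootstrap_scd50 is None or fit_htrt.bootstrap_scd50 is None:
        return TERResult(ter=ter)
    n = min(fit_rt.bootstrap_scd50.size, fit_htrt.bootstrap_scd50.size)
    ratios = fit_rt.bootstrap_scd50[:n] / fit_htrt.bootstrap_scd50[:n]
    ratios = ratios[ratios > 0]
    ci = (float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5)))
    p = min(1.0, 2.0 * min(float(np.mean(ratios <= 1.0)), float(np.mean(ratios >= 1.0))))
    return TERResult(ter=ter, ci95=ci, p_boot=p)


def compare_scd50(fit1: SCPCurveFit, fit2: SCPCurveFit) -> float:
    """Two-sided bootstrap p-value for a difference in SCD50 between two
    independently fitted conditions."""
    if fit1.bootstrap_scd50 is None or fit2.bootstrap_scd50 is None:
        raise FitError("bootstrap distributions missing; run bootstrap_scd50 first")
    if fit1.n_boot != fit2.n_boot:
        raise FitError("bootstrap replicate counts must match for comparison")
    n = min(fit1.bootstrap_scd50.size, fit2.bootstrap_scd50.size)
    diff = fit1.bootstrap_scd50[:n] - fit2.bootstrap_scd50[:n]
    p_lo = float(np.mean(diff <= 0))
    p_hi = float(np.mean(diff >= 0))
    return min(1.0, 2.0 * min(p_lo, p_hi))
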