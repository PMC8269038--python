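"""End-to-end orchestration: trajectories -> outcomes -> SCP tables ->
Kaplan-Meier/log-rank -> dose-response fits -> TERs -> report.

Everything is deterministic given the configuration (which carries the
bootstrap seed); the summary records a hash of the config and of every
table so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .control import ControlOutcome, arm_scp, classify_trajectories, km_curve, logrank_test
from .dose_response import (
    SCPCurveFit,
    bootstrap_scd50,
    compare_scd50,
    compute_ter,
    outcomes_by_dose,
)
from .errors import AnalysisError
from .io import AnalysisConfig, read_trajectories, write_outcomes
from .volumetrics import SpheroidTrajectory, mann_whitney, relative_growth_delay

__all__ = ["RunReport", "run_pipeline"]

log = logging.getLogger("scpassay")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("scpassay %(levelname)s | %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunReport:
    """All pipeline products plus provenance (config echo, version, hash)."""

    scp_table: pd.DataFrame
    growth_delay_table: pd.DataFrame
    km_table: pd.DataFrame
    logrank_table: pd.DataFrame
    fit_table: pd.DataFrame
    ter_table: pd.DataFrame
    fits: dict[str, SCPCurveFit]
    config: AnalysisConfig
    warnings: list[str] = field(default_factory=list)
    version: str = __version__

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self.config), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def summary(self) -> dict:
        def table_digest(df: pd.DataFrame) -> str:
            return hashlib.sha256(df.round(10).to_csv(index=False).encode()).hexdigest()[:16]

        return {
            "version": self.version,
            "config": dataclasses.asdict(self.config),
            "config_hash": self.config_hash,
            "seed": self.config.seed,
            "n_arms": int(len(self.scp_table)),
            "fits": {
                cond: {
                    "a": f.a,
                    "b": f.b,
                    "scd50_gy": f.scd50_gy,
                    "ci95_gy": f.ci95_gy,
                    "n_boot": f.n_boot,
                    "n_failed": f.n_failed,
                    "method": f.method,
                    "converged": f.converged,
                }
                for cond, f in self.fits.items()
            },
            "ter": self.ter_table.to_dict(orient="records"),
            "table_hashes": {
                name: table_digest(getattr(self, name))
                for name in (
                    "scp_table",
                    "growth_delay_table",
                    "km_table",
                    "logrank_table",
                    "fit_table",
                    "ter_table",
                )
            },
            "warnings": self.warnings,
        }

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "scp_table",
            "growth_delay_table",
            "km_table",
            "logrank_table",
            "fit_table",
            "ter_table",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        summary_path = out / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=float)
        return summary_path


def _arm_key(o: ControlOutcome) -> tuple:
    return (o.arm.condition, o.arm.dose_gy)


def run_pipeline(
    config: AnalysisConfig,
    trajectories: list[SpheroidTrajectory] | None = None,
) -> RunReport:
    """Run every analysis stage on the configured input table.

    ``trajectories`` may be passed directly (bypassing ``config.input_csv``)
    for in-memory use.  The TER reference is the condition named in
    ``config.reference_condition`` (the RT-only arm by default).
    """
    report_warnings: list[str] = []
    if trajectories is None:
        log.info("stage=read input=%s", config.input_csv)
        trajectories = read_trajectories(config.input_csv)
    log.info("stage=classify n_spheroids=%d", len(trajectories))
    outcomes = classify_trajectories(
        trajectories, min_consecutive=config.min_consecutive, rel_tol=config.rel_tol
    )

    # per-arm SCP
    by_arm: dict[tuple, list[ControlOutcome]] = {}
    for o in outcomes:
        by_arm.setdefault(_arm_key(o), []).append(o)
    scp_rows = []
    for (cond, dose), arm_outcomes in sorted(by_arm.items()):
        controlled, total, scp = arm_scp(arm_outcomes)
        scp_rows.append(
            {"condition": cond, "dose_gy": dose, "controlled": controlled,
             "total": total, "scp": scp}
        )
    scp_table = pd.DataFrame(scp_rows)

    # growth delay vs the untreated reference population
    ref = config.reference_condition
    traj_by_arm: dict[tuple, list[SpheroidTrajectory]] = {}
    for tr in trajectories:
        traj_by_arm.setdefault((tr.arm.condition, tr.arm.dose_gy), []).append(tr)
    control_key = (ref, 0.0)
    gd_rows = []
    if control_key not in traj_by_arm:
        report_warnings.append(
            f"no untreated reference arm {ref}/0Gy; growth-delay table empty"
        )
    else:
        controls = traj_by_arm[control_key]
        try:
            ref_delay = relative_growth_delay(
                controls, controls, k=config.k_fold, window=config.regression_window
            )
        except AnalysisError as exc:
            report_warnings.append(f"growth delay skipped: {exc}")
            ref_delay = None
        if ref_delay is not None:
            ref_ratios = list(ref_delay.relative_delay.values())
            for key, trs in sorted(traj_by_arm.items()):
                res = relative_growth_delay(
                    trs, controls, k=config.k_fold, window=config.regression_window
                )
                ratios = list(res.relative_delay.values())
                if key != control_key and ratios:
                    mw = mann_whitney(ratios, ref_ratios)
                    u, p = mw.u, mw.p_value
                else:
                    u, p = np.nan, np.nan
                gd_rows.append(
                    {
                        "condition": key[0],
                        "dose_gy": key[1],
                        "n": len(trs),
                        "n_reached": len(ratios),
                        "censored": res.censored_count,
                        "mean_time_to_kv0_d": float(np.mean(
                            [t for t in res.per_spheroid_time_d.values() if t is not None]
                        )) if ratios else np.nan,
                        "mean_relative_delay": res.mean_relative_delay,
                        "mw_u_vs_ref": u,
                        "mw_p_vs_ref": p,
                    }
                )
    growth_delay_table = pd.DataFrame(gd_rows)

    # Kaplan-Meier per arm; log-rank vs reference condition at matching dose
    km_rows, lr_rows = [], []
    for (cond, dose), arm_outcomes in sorted(by_arm.items()):
        curve = km_curve(arm_outcomes)
        for t, s, r, e in zip(curve.times_d, curve.surv, curve.at_risk, curve.events):
            km_rows.append(
                {"condition": cond, "dose_gy": dose, "time_d": t,
                 "surv": s, "at_risk": r, "events": e}
            )
        if cond != ref and (ref, dose) in by_arm:
            chi2, p = logrank_test(arm_outcomes, by_arm[(ref, dose)])
            lr_rows.append(
                {"condition": cond, "dose_gy": dose, "vs": ref, "chi2": chi2, "p": p}
            )
    km_table = pd.DataFrame(km_rows)
    logrank_table = pd.DataFrame(lr_rows)

    # dose-response fit + bootstrap per condition; TER vs reference
    conditions = sorted({cond for cond, _ in by_arm})
    fits: dict[str, SCPCurveFit] = {}
    fit_rows = []
    for cond in conditions:
        cond_outcomes = [o for o in outcomes if o.arm.condition == cond]
        flags = outcomes_by_dose(cond_outcomes)
        if len(flags) < 2:
            report_warnings.append(f"condition {cond}: <2 dose arms, fit skipped")
            continue
        try:
            fit = bootstrap_scd50(flags, n_boot=config.n_boot, seed=config.seed)
        except AnalysisError as exc:
            report_warnings.append(f"condition {cond}: fit failed ({exc})")
            continue
        fits[cond] = fit
        if fit.n_failed > 0.1 * max(fit.n_boot, 1):
            report_warnings.append(
                f"condition {cond}: {fit.n_failed}/{fit.n_boot} bootstrap "
                "replicates failed"
            )
        fit_rows.append(
            {
                "condition": cond,
                "a": fit.a,
                "b": fit.b,
                "scd50_gy": fit.scd50_gy,
                "ci_lo_gy": fit.ci95_gy[0] if fit.ci95_gy else np.nan,
                "ci_hi_gy": fit.ci95_gy[1] if fit.ci95_gy else np.nan,
                "n_boot": fit.n_boot,
                "n_failed": fit.n_failed,
                "method": fit.method,
                "converged": fit.converged,
            }
        )
        log.info(
            "stage=fit condition=%s scd50=%.3f method=%s", cond, fit.scd50_gy, fit.method
        )
    fit_table = pd.DataFrame(fit_rows)

    ter_rows = []
    if ref in fits:
        for cond in conditions:
            if cond == ref or cond not in fits:
                continue
            ter = compute_ter(fits[ref], fits[cond])
            p_diff = (
                compare_scd50(fits[ref], fits[cond])
                if fits[ref].bootstrap_scd50 is not None
                and fits[cond].bootstrap_scd50 is not None
                else np.nan
            )
            ter_rows.append(
                {
                    "condition": cond,
                    "reference": ref,
                    "ter": ter.ter,
                    "ci_lo": ter.ci95[0] if ter.ci95 else np.nan,
                    "ci_hi": ter.ci95[1] if ter.ci95 else np.nan,
                    "p_boot": ter.p_boot if ter.p_boot is not None else np.nan,
                    "p_scd50_diff": p_diff,
                }
            )
    elif fits:
        report_warnings.append(f"reference condition {ref} has no fit; TER table empty")
    ter_table = pd.DataFrame(ter_rows)

    report = RunReport(
        scp_table=scp_table,
        growth_delay_table=growth_delay_table,
        km_table=km_table,
        logrank_table=logrank_table,
        fit_table=fit_table,
        ter_table=ter_table,
        fits=fits,
        config=config,
        warnings=report_warnings,
    )
    log.info("stage=done conditions=%d warnings=%d", len(fits), len(report_warnings))
    return report
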