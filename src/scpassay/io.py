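"""Reading, writing and validation of the long-format trajectory tables.

The canonical exchange format is a long CSV with one row per measurement:

    spheroid_id, ht_temp_c, ht_duration_min, dose_gy, adjunct,
    time_d, diameter_um, volume_um3, v0_um3

Times are days post-treatment (t=0 at treatment); the pre-treatment
baseline is the dedicated ``v0_um3`` column, not a negative-time row.
Either ``diameter_um`` or ``volume_um3`` may be absent — volumes are then
derived via the sphere formula V = (pi/6) d^3.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .control import ControlOutcome
from .errors import SchemaError
from .volumetrics import SpheroidTrajectory, TreatmentArm, diameter_to_volume

__all__ = [
    "AnalysisConfig",
    "read_trajectories",
    "write_trajectories",
    "read_outcomes",
    "write_outcomes",
    "load_config",
]

_ARM_COLS = ["ht_temp_c", "ht_duration_min", "dose_gy", "adjunct"]


@dataclass
class AnalysisConfig:
    """Every knob of the end-to-end pipeline, loadable from YAML."""

    input_csv: str = ""
    out_dir: str = "scp_out"
    reference_condition: str = "37C/0min"
    k_fold: float = 5.0
    regression_window: int = 2
    min_consecutive: int = 3
    rel_tol: float = 0.0
    n_boot: int = 4000
    seed: int = 17
    horizon_d: float = 60.0

    def __post_init__(self) -> None:
        if self.k_fold <= 1:
            raise SchemaError("k_fold must be > 1")
        if self.regression_window < 2:
            raise SchemaError("regression_window must be >= 2")
        if self.min_consecutive < 1:
            raise SchemaError("min_consecutive must be >= 1")
        if not (0 <= self.rel_tol < 1):
            raise SchemaError("rel_tol must be in [0, 1)")
        if self.n_boot < 0 or self.horizon_d <= 0:
            raise SchemaError("n_boot must be >= 0 and horizon_d > 0")


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def _arm_from_row(row: pd.Series) -> TreatmentArm:
    return TreatmentArm(
        ht_temp_c=float(row.get("ht_temp_c", 37.0)),
        ht_duration_min=float(row.get("ht_duration_min", 0.0)),
        dose_gy=float(row["dose_gy"]),
        adjunct=str(row.get("adjunct", "none")),
    )


def read_trajectories(source: str | Path | pd.DataFrame) -> list[SpheroidTrajectory]:
    """Parse and validate a long-format trajectory table.

    Row order is irrelevant: measurements are sorted by time per spheroid.
    Duplicate (spheroid, time) rows, non-positive values or a missing size
    column raise :class:`SchemaError` naming the offender.
    """
    df = (
        source.copy()
        if isinstance(source, pd.DataFrame)
        else pd.read_csv(source, float_precision="round_trip")
    )
    required = {"spheroid_id", "dose_gy", "time_d"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    if "volume_um3" not in df.columns:
        if "diameter_um" not in df.columns:
            raise SchemaError("need a 'volume_um3' or 'diameter_um' column")
        bad = df.index[(df["diameter_um"] <= 0) | df["diameter_um"].isna()]
        if len(bad):
            raise SchemaError(f"non-positive diameter at rows {list(bad[:5])}")
        df["volume_um3"] = diameter_to_volume(df["diameter_um"].to_numpy())
    for col in ("ht_temp_c", "ht_duration_min", "adjunct"):
        if col not in df.columns:
            df[col] = 37.0 if col == "ht_temp_c" else (0.0 if col == "ht_duration_min" else "none")
    has_v0 = "v0_um3" in df.columns
    if not has_v0:
        warnings.warn(
            "no 'v0_um3' baseline column; using each spheroid's t=0 volume as V0"
        )
    trajectories: list[SpheroidTrajectory] = []
    for sid, g in df.groupby("spheroid_id", sort=True):
        g = g.sort_values("time_d")
        if g["time_d"].duplicated().any():
            raise SchemaError(f"duplicated time point for spheroid {sid!r}")
        if has_v0:
            v0_vals = g["v0_um3"].unique()
            if len(v0_vals) != 1:
                raise SchemaError(f"inconsistent v0_um3 for spheroid {sid!r}")
            v0 = float(v0_vals[0])
        else:
            at0 = g[g["time_d"] == 0]
            if at0.empty:
                raise SchemaError(
                    f"spheroid {sid!r} has neither a v0_um3 column nor a t=0 row"
                )
            v0 = float(at0["volume_um3"].iloc[0])
        arms = g[_ARM_COLS].drop_duplicates()
        if len(arms) != 1:
            raise SchemaError(f"spheroid {sid!r} appears under multiple treatment arms")
        trajectories.append(
            SpheroidTrajectory(
                spheroid_id=str(sid),
                arm=_arm_from_row(g.iloc[0]),
                times_d=g["time_d"].to_numpy(dtype=float),
                volumes_um3=g["volume_um3"].to_numpy(dtype=float),
                v0_um3=v0,
            )
        )
    return trajectories


def write_trajectories(
    trajectories: Iterable[SpheroidTrajectory], path: str | Path
) -> pd.DataFrame:
    """Write trajectories to the canonical long CSV; returns the table."""
    from .simulate import TrajectorySet

    ts = TrajectorySet(trajectories=list(trajectories), oracle=pd.DataFrame())
    df = ts.to_frame()
    df.to_csv(path, index=False)
    return df


def write_outcomes(outcomes: Sequence[ControlOutcome], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "spheroid_id": o.spheroid_id,
                "ht_temp_c": o.arm.ht_temp_c,
                "ht_duration_min": o.arm.ht_duration_min,
                "dose_gy": o.arm.dose_gy,
                "adjunct": o.arm.adjunct,
                "relapsed": o.relapsed,
                "event_time_d": o.event_time_d,
                "censor_time_d": o.censor_time_d,
            }
            for o in outcomes
        ]
    )
    df.to_csv(path, index=False)
    return df


def read_outcomes(source: str | Path | pd.DataFrame) -> list[ControlOutcome]:
    df = (
        source
        if isinstance(source, pd.DataFrame)
        else pd.read_csv(source, float_precision="round_trip")
    )
    required = {"spheroid_id", "dose_gy", "relapsed"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        relapsed = bool(row["relapsed"])
        ev = row.get("event_time_d")
        ce = row.get("censor_time_d")
        out.append(
            ControlOutcome(
                spheroid_id=str(row["spheroid_id"]),
                arm=_arm_from_row(row),
                relapsed=relapsed,
                event_time_d=float(ev) if relapsed else None,
                censor_time_d=float(ce) if not relapsed else None,
            )
        )
    return out
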