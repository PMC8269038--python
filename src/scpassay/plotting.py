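"""Matplotlib helpers for the standard assay figures."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .control import KMCurve
from .dose_response import DoseResponsePoint, SCPCurveFit


def plot_km(curve: KMCurve, ax=None, label: str | None = None, horizon_d: float = 60.0):
    """Step plot of the controlled proportion over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.concatenate([[0.0], curve.times_d, [horizon_d]])
    s = np.concatenate([[1.0], curve.surv, [curve.surv[-1] if curve.surv.size else 1.0]])
    ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time post-treatment (d)")
    ax.set_ylabel("proportion controlled")
    ax.set_ylim(0, 1.05)
    return ax


def plot_dose_response(
    points: Sequence[DoseResponsePoint],
    fit: SCPCurveFit | None = None,
    ax=None,
    label: str | None = None,
):
    """SCP vs dose with the fitted logistic curve and SCD50 marker."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    doses = [p.dose_gy for p in points]
    ax.plot(doses, [p.scp for p in points], "o", label=label)
    if fit is not None:
        grid = np.linspace(min(doses), max(doses), 200)
        ax.plot(grid, fit.predict(grid), "-", color=ax.lines[-1].get_color())
        if 0 < fit.scd50_gy < max(doses):
            ax.axvline(fit.scd50_gy, ls=":", lw=0.8, color=ax.lines[-1].get_color())
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("SCP")
    ax.set_ylim(-0.02, 1.02)
    return ax
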