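"""Optional matplotlib views of the simulation analyses.

Layouts mirror the standard presentation: band activation trajectories
over ticks (with the word-offset tick marked) and per-tick standardized
coefficients with their ensemble error bars.  matplotlib is imported
lazily so the rest of the package has no hard plotting dependency.
"""

from __future__ import annotations

import pandas as pd

BAND_ORDER = ["highS", "lowS", "D", "nontarget"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_band_trajectories(bands: pd.DataFrame, ax=None, t_input: int = 30):
    """Mean activation per feature band across ticks.

    ``bands`` is a :func:`semdyn.simanalysis.band_trajectories` table,
    optionally stacked over ensemble members (means are taken per band and
    tick).
    """
    ax = _axes(ax)
    mean = bands.groupby(["band", "tick"])["mean_activation"].mean()
    for band in BAND_ORDER:
        if band in mean.index.get_level_values("band"):
            series = mean.xs(band, level="band")
            ax.plot(series.index, series.to_numpy(), label=band)
    ax.axvline(t_input, color="grey", ls=":", lw=1, label="word offset")
    ax.set_xlabel("time-tick")
    ax.set_ylabel("mean activation")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_tick_betas(results, predictor: str, ax=None, t_input: int = 30):
    """Per-tick standardized coefficient for one predictor, with ensemble
    standard errors; ``results`` is a TickRegressionResults."""
    ax = _axes(ax)
    sub = results.table[results.table["predictor"] == predictor]
    ax.axhline(0.0, color="grey", lw=1)
    ax.axvline(t_input, color="grey", ls=":", lw=1)
    ax.errorbar(sub["tick"], sub["beta"], yerr=sub["se"], fmt="-o",
                ms=2.5, lw=1, elinewidth=0.8, capsize=2)
    ax.set_xlabel("time-tick")
    ax.set_ylabel(f"standardized beta ({predictor})")
    return ax
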