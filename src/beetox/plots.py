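"""Best-effort diagnostic plots (SSD curve, weight-sensitivity scatter)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .allometry import AllometricModel, RegressionBand
from .endpoints import SpeciesEndpoint
from .ssd import HDEstimate, SSDFit, plotting_positions


def plot_ssd(
    fit: SSDFit,
    endpoints: Sequence[SpeciesEndpoint],
    hd: HDEstimate | None = None,
    ax=None,
):
    """SSD curve with empirical points at Hazen plotting positions.

    Returns the matplotlib Axes. Dots are observed endpoints; open circles
    mark literature entries; the fitted log-normal CDF is drawn across the
    endpoint range, with the HD estimate and its bootstrap limits marked
    when supplied.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = sorted(e.ld50 for e in endpoints)
    pos = plotting_positions(len(vals))
    lit = {e.ld50 for e in endpoints if e.source == "literature"}
    for v, q in zip(vals, pos):
        ax.plot(v, q, "o", mfc="none" if v in lit else "k", mec="k")
    grid = np.logspace(np.log10(min(vals)) - 1, np.log10(max(vals)) + 1, 200)
    cdf = stats.norm.cdf((np.log10(grid) - fit.mu_log10) / fit.sigma_log10)
    ax.plot(grid, cdf, "r-", label="fitted SSD")
    if hd is not None:
        ax.axvline(hd.hd, color="k", ls=":", label=f"HD{hd.p * 100:g}")
        ax.axvline(hd.lower_limit, color="b", ls="--", label="lower limit")
    ax.set_xscale("log")
    ax.set_xlabel("48 h LD50 (μg a.i./bee)")
    ax.set_ylabel("fraction of species affected")
    ax.legend(loc="best", fontsize="small")
    return ax


def plot_weight_sensitivity(
    model: AllometricModel,
    endpoints: Sequence[SpeciesEndpoint],
    band: RegressionBand | None = None,
    ax=None,
):
    """Log-log scatter of weight vs LD50 with the fitted power law."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    attr = "mean_fresh_weight_mg" if model.predictor == "fresh" else "mean_dry_weight_mg"
    pts = [(getattr(e, attr), e.ld50) for e in endpoints if getattr(e, attr) is not None]
    if pts:
        w, y = zip(*pts)
        ax.plot(w, y, "ko")
        grid = np.logspace(np.log10(min(w)) - 0.5, np.log10(max(w)) + 0.5, 100)
    else:
        grid = np.logspace(0, 2, 100)
    ax.plot(grid, model.predict(grid), "r-",
            label=f"a={model.slope_a:.3f}, b={model.intercept_b:.3f}")
    if band is not None:
        ax.plot(band.weights_mg, band.lower, "k--", lw=0.8)
        ax.plot(band.weights_mg, band.upper, "k--", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"{model.predictor} body weight (mg)")
    ax.set_ylabel("48 h LD50 (μg a.i./bee)")
    ax.legend(loc="best", fontsize="small")
    return ax
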