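"""A minimal cline figure: observed site frequencies with the fitted curve."""

from __future__ import annotations

import numpy as np

from .clines import ClineFit, cline_eval


def plot_cline(fit: ClineFit, ax=None, n_grid: int = 300, color: str = "k"):
    """Observed frequencies, the fitted cline, and its 2-LL envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    model = fit.model
    x_obs, k, n = model._x, model._k, model._n
    grid = np.linspace(x_obs.min(), x_obs.max(), n_grid)

    keep = fit.samples["ll"] >= fit.max_ll - 2.0
    thinned = fit.samples[keep]
    if len(thinned) > 200:
        thinned = thinned.iloc[:: len(thinned) // 200]
    curves = np.array([
        cline_eval(model.unpack(row[model.param_names].to_numpy(dtype=float)), grid)
        for _, row in thinned.iterrows()
    ])
    ax.fill_between(grid, curves.min(axis=0), curves.max(axis=0),
                    color=color, alpha=0.2, lw=0)
    ax.plot(grid, cline_eval(fit.point_estimate, grid), color=color, lw=2)
    ax.scatter(x_obs, k / n, facecolor="k", edgecolor="k", zorder=3)
    ax.set_xlabel("transect distance (km)")
    ax.set_ylabel("interior frequency")
    ax.set_ylim(-0.02, 1.02)
    return ax
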