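"""Quick-look plots for fitted models, ensembles and habitat maps.

All functions take/return matplotlib axes so they compose into figures;
nothing here is needed for the numerical pipeline.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_raster",
    "plot_paths",
    "plot_stationary_curve",
    "plot_rss_curve",
]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_raster(values, geometry, ax=None, mask=None, **imshow_kw):
    """Show a raster layer (or UD) in map coordinates; masked cells blank."""
    ax = _get_ax(ax)
    img = np.asarray(values, dtype=float)
    if mask is not None:
        img = np.where(mask, img, np.nan)
    x0, y0, x1, y1 = geometry.bounds
    imshow_kw.setdefault("origin", "lower")
    imshow_kw.setdefault("extent", (x0, x1, y0, y1))
    m = ax.imshow(img, **imshow_kw)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax, m


def plot_paths(ensemble, ax=None, max_paths=50, color_by_state=True):
    """Overlay simulated paths; slow steps grey, fast steps coloured."""
    ax = _get_ax(ax)
    n = min(ensemble.n_paths, max_paths)
    for i in range(n):
        path = ensemble.path(i)
        if color_by_state:
            fast = path.states[1:] == 1
            seg = np.stack([path.xy[:-1], path.xy[1:]], axis=1)
            for sel, c in ((~fast, "0.6"), (fast, "tab:red")):
                for s in seg[sel]:
                    ax.plot(s[:, 0], s[:, 1], color=c, lw=0.4, alpha=0.5)
        else:
            ax.plot(path.xy[:, 0], path.xy[:, 1], lw=0.4, alpha=0.5)
    ax.set_aspect("equal")
    return ax

def plot_stationary_curve(fit, covariate, grid=None, fixed=None, ax=None):
    """Stationary P(fast) as one transition covariate varies.

    ``fixed`` supplies values for the other covariates (default 0).
    """
    ax = _get_ax(ax)
    names = list(fit.params.covariate_names)
    j = names.index(covariate)
    grid = np.linspace(0, 1, 101) if grid is None else np.asarray(grid)
    x = np.zeros((len(grid), len(names)))
    for k, name in enumerate(names):
        x[:, k] = (fixed or {}).get(name, 0.0)
    x[:, j] = grid
    pi = fit.stationary_probs(x)
    ax.plot(grid, pi[:, 1])
    ax.set_xlabel(covariate)
    ax.set_ylabel("stationary P(fast)")
    ax.set_ylim(0, 1)
    return ax


def plot_rss_curve(fit, term, grid, reference=0.0, ax=None, alpha=0.05):
    """Relative selection strength along one SSF term with a delta-method CI."""
    from movescape.ssf import relative_selection_strength

    ax = _get_ax(ax)
    rss, lo, hi = [], [], []
    for v in grid:
        out = relative_selection_strength(
            fit, {term: float(v)}, {term: float(reference)}, alpha=alpha
        )
        rss.append(out["rss"])
        lo.append(out["lower"])
        hi.append(out["upper"])
    ax.plot(grid, rss)
    ax.fill_between(grid, lo, hi, alpha=0.25)
    ax.axhline(1.0, color="0.5", lw=0.8)
    ax.set_xlabel(term)
    ax.set_ylabel("relative selection strength")
    ax.set_yscale("log")
    return ax
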