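"""Utilization distributions, habitat-quality bins and Merriam connectivity.

Simulated locations are tallied on the 120 m grid into a utilization
distribution (UD), sliced by movement state.  Available cells are ranked
into ten equal-area bins of increasing use; bin rank >= 7 defines
high-quality habitat and scenario-vs-reference ratios give percent intact
habitat.  Merriam connectivity counts unique simulated paths that traverse
between two habitat patches or cross a digital cross-valley transect,
expressed relative to the reference (no-development) ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.stats import spearmanr

from movescape.landscape import GridGeometry
from movescape.simulate import PathEnsemble

__all__ = [
    "UtilizationDistribution",
    "BinMap",
    "utilization_distribution",
    "equal_area_bins",
    "spearman_validation",
    "high_quality_proportion",
    "percent_intact",
    "patch_traversal_count",
    "transect_crossing_count",
    "connectivity_ratio",
]


@dataclass
class UtilizationDistribution:
    """Normalised per-cell probability of use on the analysis grid."""

    values: np.ndarray
    geometry: GridGeometry
    state_filter: str
    scenario: str
    n_locations: int

    def __post_init__(self):
        if not np.isclose(self.values.sum(), 1.0, atol=1e-9):
            raise ValueError("UD must sum to 1")


@dataclass
class BinMap:
    """Equal-area bin ranks (1..n_bins) over in-mask cells; 0 elsewhere."""

    ranks: np.ndarray
    n_bins: int
    geometry: GridGeometry
    scenario: str = ""


def utilization_distribution(
    ensemble: PathEnsemble,
    geometry: GridGeometry,
    state_filter: str = "combined",
    clip_buffer_m: float = 5000.0,
    scenario: str | None = None,
) -> UtilizationDistribution:
    """Count simulated locations per grid cell and normalise.

    Locations within ``clip_buffer_m`` of the study-area edge are excluded
    before counting (boundary-effect control); ``state_filter`` selects
    slow-only, fast-only or all locations.
    """
    x, y, _s, _p = ensemble.locations(state_filter)
    x0, y0, x1, y1 = geometry.bounds
    keep = (
        (x >= x0 + clip_buffer_m)
        & (x < x1 - clip_buffer_m)
        & (y >= y0 + clip_buffer_m)
        & (y < y1 - clip_buffer_m)
    )
    x, y = x[keep], y[keep]
    if len(x) == 0:
        raise ValueError("no simulated locations left after clipping")
    row, col = geometry.rowcol(x, y)
    counts = np.bincount(
        row * geometry.n_cols + col, minlength=geometry.n_rows * geometry.n_cols
    ).reshape(geometry.shape)
    return UtilizationDistribution(
        values=counts / counts.sum(),
        geometry=geometry,
        state_filter=state_filter,
        scenario=scenario or ensemble.scenario,
        n_locations=int(len(x)),
    )


def equal_area_bins(
    ud: UtilizationDistribution, mask: np.ndarray, n_bins: int = 10
) -> BinMap:
    """Partition in-mask cells into ``n_bins`` equal-count groups by UD value.

    Cells are sorted by (value, row-major index) so the binning is a
    deterministic function of the UD; rank 1 is lowest use, rank ``n_bins``
    highest; group sizes differ by at most one cell.
    """
    idx = np.flatnonzero(mask.ravel())
    if len(idx) < n_bins:
        raise ValueError(f"need at least {n_bins} in-mask cells")
    vals = ud.values.ravel()[idx]
    order = np.lexsort((idx, vals))  # value first, index breaks ties
    ranks = np.zeros(ud.values.size, dtype=int)
    for b, chunk in enumerate(np.array_split(idx[order], n_bins), start=1):
        ranks[chunk] = b
    return BinMap(
        ranks=ranks.reshape(ud.values.shape),
        n_bins=n_bins,
        geometry=ud.geometry,
        scenario=ud.scenario,
    )


def spearman_validation(
    binmap: BinMap, x, y, animal_ids=None
) -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation between bin rank and per-bin location share.

    Locations landing outside the binned mask are dropped.  Returns the
    pooled coefficient and a per-animal table when ``animal_ids`` is given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    geom = binmap.geometry
    inb = geom.in_bounds(x, y)
    row, col = geom.clip_rowcol(*geom.rowcol(x, y))
    r = np.where(inb, binmap.ranks[row, col], 0)
    keep = r > 0
    if not keep.any():
        raise ValueError("no locations inside the binned area")

    def rho_of(rr) -> float:
        counts = np.bincount(rr, minlength=binmap.n_bins + 1)[1:]
        props = counts / counts.sum()
        if (counts > 0).sum() <= 1:
            warnings.warn("all locations in one bin: rho undefined")
            return np.nan
        return float(spearmanr(np.arange(1, binmap.n_bins + 1), props).statistic)

    pooled = rho_of(r[keep])
    per_animal = pd.DataFrame(columns=["animal_id", "rho", "n"])
    if animal_ids is not None:
        animal_ids = np.asarray(animal_ids)
        rows = []
        for aid in pd.unique(animal_ids[keep]):
            m = keep & (animal_ids == aid)
            rows.append({"animal_id": aid, "rho": rho_of(r[m]), "n": int(m.sum())})
        per_animal = pd.DataFrame(rows)
    return pooled, per_animal


def high_quality_proportion(
    binmap: BinMap, focal_polygon, mask: np.ndarray, threshold: int = 7
) -> float:
    """Share of focal in-mask cells classified high quality (rank >= 7)."""
    geom = binmap.geometry
    X, Y = geom.cell_centres()
    inside = shapely.contains_xy(focal_polygon, X.ravel(), Y.ravel()).reshape(
        geom.shape
    )
    cells = inside & mask & (binmap.ranks > 0)
    if not cells.any():
        raise ValueError("focal polygon contains no in-mask binned cells")
    return float((binmap.ranks[cells] >= threshold).mean())


def percent_intact(proportion_scenario: float, proportion_reference: float) -> float:
    """Scenario high-quality share relative to reference, in percent."""
    if proportion_reference <= 0:
        warnings.warn("reference proportion is zero: percent intact undefined")
        return np.nan
    return 100.0 * proportion_scenario / proportion_reference


def _paths_touching(ensemble: PathEnsemble, polygon) -> np.ndarray:
    x, y, _s, pid = ensemble.locations("combined")
    hit = shapely.contains_xy(polygon, x, y)
    touched = np.zeros(ensemble.n_paths, dtype=bool)
    touched[np.unique(pid[hit])] = True
    return touched


def patch_traversal_count(ensemble: PathEnsemble, patch_a, patch_b) -> int:
    """Unique paths with at least one location in each patch (either order)."""
    if patch_a.intersects(patch_b):
        raise ValueError("patches must be disjoint")
    in_a = _paths_touching(ensemble, patch_a)
    in_b = _paths_touching(ensemble, patch_b)
    return int((in_a & in_b).sum())


def transect_crossing_count(ensemble: PathEnsemble, transect) -> int:
    """Unique paths whose step segments intersect the transect line.

    Endpoint touches count as crossings; each path counts at most once.
    """
    if transect.length == 0:
        raise ValueError("degenerate zero-length transect")
    count = 0
    for i in range(ensemble.n_paths):
        n_used = int(ensemble.steps_used[i])
        if n_used < 1:
            continue
        line = shapely.LineString(ensemble.xy[i, : n_used + 1])
        if line.intersects(transect):
            count += 1
    return count


def connectivity_ratio(
    n_traverse: int,
    n_reference: int,
    n_paths: int | None = None,
    n_paths_reference: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Merriam connectivity ``n_traverse / n_reference``.

    When ensemble sizes are supplied, a Monte-Carlo binomial CI is attached
    by resampling both counts.  A zero reference count is flagged as
    undefined (unreliable below ~10 reference paths).
    """
    if n_reference <= 0:
        warnings.warn("n_reference is zero: connectivity undefined")
        return {"ratio": np.nan, "lower": np.nan, "upper": np.nan,
                "n_traverse": n_traverse, "n_reference": n_reference}
    out = {
        "ratio": n_traverse / n_reference,
        "n_traverse": int(n_traverse),
        "n_reference": int(n_reference),
        "lower": np.nan,
        "upper": np.nan,
    }
    if n_paths and n_paths_reference:
        rng = np.random.default_rng(seed)
        bt = rng.binomial(n_paths, n_traverse / n_paths, n_boot)
        br = rng.binomial(n_paths_reference, n_reference / n_paths_reference,
                          n_boot)
        ratios = bt / np.maximum(br, 1) * (n_paths_reference / n_paths)
        out["lower"] = float(np.quantile(ratios, alpha / 2))
        out["upper"] = float(np.quantile(ratios, 1 - alpha / 2))
    if n_reference < 10:
        warnings.warn("fewer than 10 reference paths: ratio unreliable")
    return out
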