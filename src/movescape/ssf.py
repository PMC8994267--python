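"""State-dependent step selection functions (SSF).

Each observed ("used") step is paired with 20 "available" steps drawn from
the pooled empirical step-length and turn-angle distributions, forming a
stratum of 21 candidates.  Selection coefficients are estimated by
stratified conditional logistic regression (softmax over candidates within
a stratum) with a cluster-robust sandwich covariance over animals, in the
spirit of GEE with independence working correlation.  Anthropogenic terms
interact with the probability of the fast movement state (``p_fast``) and
time of day (``c_hour``), so avoidance of development can wane when the
animal is travelling or at night.

Model organisation follows statsmodels: :class:`StepSelectionModel` holds
the stacked design; ``fit`` returns :class:`StepSelectionResults` with both
model-based and robust covariances, the quasi-likelihood information
criterion (QIC), and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "Term",
    "DesignSpec",
    "sample_available_steps",
    "assemble_design",
    "StepSelectionModel",
    "StepSelectionResults",
    "robust_cluster_vcov",
    "qic_backward_selection",
    "relative_selection_strength",
    "predict_habitat_map",
    "HabitatMap",
]

N_AVAILABLE = 20
ON_FEATURE_BUFFER_M = 30.0
MOVEMENT_BASES = ("step_km", "cos_ta")
MODIFIERS = ("p_fast", "c_hour")


# ---------------------------------------------------------------------------
# terms and design specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One design column: ``base`` raised to ``power``, optionally scaled by a
    stratum-level modifier (``p_fast`` or ``c_hour``)."""

    base: str
    power: int = 1
    modifier: str | None = None

    @property
    def name(self) -> str:
        n = self.base if self.power == 1 else f"{self.base}^{self.power}"
        return n if self.modifier is None else f"{n}:{self.modifier}"

    @classmethod
    def parse(cls, name: str) -> "Term":
        modifier = None
        if ":" in name:
            name, modifier = name.split(":", 1)
            if modifier not in MODIFIERS:
                raise ValueError(f"unknown modifier {modifier!r}")
        power = 1
        if "^" in name:
            name, p = name.split("^", 1)
            power = int(p)
        return cls(base=name, power=power, modifier=modifier)

    def depends_on(self) -> list[str]:
        """Names of lower-order terms this term presumes (hierarchy)."""
        deps = []
        if self.modifier is not None:
            deps.append(Term(self.base, self.power).name)
        if self.power > 1:
            deps.append(Term(self.base, self.power - 1, self.modifier).name)
        return deps


@dataclass
class DesignSpec:
    """Ordered term list for the SSF design matrix.

    ``anthropogenic_bases`` flags development covariates (used when zeroing
    coefficients for the reference scenario); on/off linear-feature
    indicators are bases named ``on_<class>``.
    """

    terms: tuple[str, ...]
    anthropogenic_bases: frozenset[str] = frozenset()

    def __post_init__(self):
        names = set(self.terms)
        for t in self.parsed:
            for dep in t.depends_on():
                if dep not in names:
                    raise ValueError(
                        f"term {t.name!r} requires {dep!r} in the design"
                    )

    @property
    def parsed(self) -> list[Term]:
        return [Term.parse(n) for n in self.terms]

    @property
    def endpoint_bases(self) -> list[str]:
        seen = []
        for t in self.parsed:
            if t.base not in MOVEMENT_BASES and t.base not in seen:
                seen.append(t.base)
        return seen

    @classmethod
    def default(
        cls,
        habitat_layers: tuple[str, ...] = ("habitat",),
        anthropogenic_layers: tuple[str, ...] = ("town_prox", "trail_density"),
        quadratic: tuple[str, ...] = ("trail_density",),
        onoff_classes: tuple[str, ...] = ("trail", "road", "railway"),
        movement: bool = True,
        interactions: bool = True,
    ) -> "DesignSpec":
        """The full-model layout: habitat main effects; anthropogenic terms
        (with optional quadratics and on/off indicators) interacted with
        ``p_fast`` and ``c_hour``; movement terms likewise interacted."""
        terms: list[str] = list(habitat_layers)
        anthro: list[str] = []

        def add_with_interactions(base_name: str):
            terms.append(base_name)
            if interactions:
                terms.append(f"{base_name}:p_fast")
                terms.append(f"{base_name}:c_hour")

        for layer in anthropogenic_layers:
            anthro.append(layer)
            add_with_interactions(layer)
            if layer in quadratic:
                add_with_interactions(f"{layer}^2")
        for cls_name in onoff_classes:
            base = f"on_{cls_name}"
            anthro.append(base)
            add_with_interactions(base)
        if movement:
            for base in MOVEMENT_BASES:
                add_with_interactions(base)
        return cls(terms=tuple(terms), anthropogenic_bases=frozenset(anthro))

    @classmethod
    def from_coefficients(cls, coefs: dict[str, float],
                          anthropogenic_bases=()) -> "DesignSpec":
        return cls(terms=tuple(coefs), anthropogenic_bases=frozenset(
            anthropogenic_bases))

    def drop(self, term_name: str) -> "DesignSpec":
        return DesignSpec(
            terms=tuple(t for t in self.terms if t != term_name),
            anthropogenic_bases=self.anthropogenic_bases,
        )

    def removable_terms(self) -> list[str]:
        """Terms not presumed by any other current term (hierarchy rule)."""
        needed = set()
        for t in self.parsed:
            needed.update(t.depends_on())
        return [n for n in self.terms if n not in needed]


# ---------------------------------------------------------------------------
# used/available strata
# ---------------------------------------------------------------------------


def sample_available_steps(
    series_list,
    p_fast: np.ndarray,
    geometry,
    n_avail: int = N_AVAILABLE,
    seed: int = 0,
    max_redraw: int = 10,
) -> pd.DataFrame:
    """Pair each observed step with ``n_avail`` available steps.

    Lengths and turn angles for available steps are drawn independently with
    replacement from the pooled empirical marginals of the observed steps
    and projected from the step's start location and previous bearing.
    Available endpoints outside the grid are redrawn up to ``max_redraw``
    times, after which the stratum is dropped (counted).  Strata whose step
    has no defined prior bearing (first step of a segment) are skipped.

    ``p_fast`` is the smoothed fast-state probability per step, concatenated
    across ``series_list`` in input order.

    Returns a long DataFrame with one row per candidate: columns
    ``stratum, used, animal_id, x1, y1, step_km, cos_ta, p_fast, c_hour``.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(series_list, (list, tuple)):
        series_list = [series_list]
    n_total = sum(len(s) for s in series_list)
    p_fast = np.asarray(p_fast, dtype=float)
    if len(p_fast) != n_total:
        raise ValueError("p_fast length must match total number of steps")

    pooled_len = np.concatenate([s.lengths for s in series_list])
    pooled_ang = np.concatenate(
        [s.angles[~np.isnan(s.angles)] for s in series_list]
    )
    if len(pooled_len) == 0 or len(pooled_ang) == 0:
        raise ValueError("pooled empirical distributions are empty")

    rows = []
    stratum = 0
    n_dropped = 0
    n_skipped = 0
    offset = 0
    for s in series_list:
        c_hour = s.c_hour
        for t in range(len(s)):
            theta = s.angles[t]
            if np.isnan(theta):  # no prior bearing
                n_skipped += 1
                continue
            prior_bearing = s.bearing[t] - theta
            pf, ch = p_fast[offset + t], c_hour[t]
            rows.append(
                (stratum, 1, s.animal_id, s.x1[t], s.y1[t],
                 s.lengths[t] / 1000.0, np.cos(theta), pf, ch)
            )
            ok = True
            for _ in range(n_avail):
                for attempt in range(max_redraw + 1):
                    l = pooled_len[rng.integers(len(pooled_len))]
                    ang = pooled_ang[rng.integers(len(pooled_ang))]
                    b = prior_bearing + ang
                    ex = s.x0[t] + l * np.cos(b)
                    ey = s.y0[t] + l * np.sin(b)
                    if geometry.in_bounds(ex, ey):
                        rows.append(
                            (stratum, 0, s.animal_id, ex, ey,
                             l / 1000.0, np.cos(ang), pf, ch)
                        )
                        break
                else:
                    ok = False
                    break
            if not ok:
                # unwind the partially built stratum
                rows = [r for r in rows if r[0] != stratum]
                n_dropped += 1
            else:
                stratum += 1
        offset += len(s)

    df = pd.DataFrame(
        rows,
        columns=["stratum", "used", "animal_id", "x1", "y1", "step_km",
                 "cos_ta", "p_fast", "c_hour"],
    )
    df.attrs["n_dropped_strata"] = n_dropped
    df.attrs["n_skipped_first_steps"] = n_skipped
    return df


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


def _onoff_indicator(scene, cls_name: str, x, y) -> np.ndarray:
    lines = scene.lines_of(cls_name)
    if not lines:
        return np.zeros(len(x))
    union = shapely.union_all(lines)
    pts = shapely.points(np.column_stack([np.asarray(x), np.asarray(y)]))
    return (shapely.distance(pts, union) <= ON_FEATURE_BUFFER_M).astype(float)


def _base_values(df: pd.DataFrame, stack, scene, base: str) -> np.ndarray:
    if base in MOVEMENT_BASES:
        return df[base].to_numpy()
    if base.startswith("on_"):
        return _onoff_indicator(scene, base[3:], df["x1"].to_numpy(),
                                df["y1"].to_numpy())
    if base not in stack.layers:
        raise KeyError(base)
    return stack.value_at(base, df["x1"].to_numpy(), df["y1"].to_numpy())


def assemble_design(
    strata: pd.DataFrame, stack, scene, spec: DesignSpec
) -> pd.DataFrame:
    """Design matrix (one row per candidate step) for a strata table.

    Endpoint covariates come from the raster stack; on/off indicators are 1
    when the endpoint lies within 30 m of the feature class; interactions
    multiply by the stratum's ``p_fast`` or ``c_hour``.
    """
    missing = [
        b for b in spec.endpoint_bases
        if not b.startswith("on_") and b not in stack.layers
    ]
    if missing:
        raise KeyError(f"design spec references missing layers: {missing}")
    base_cache: dict[str, np.ndarray] = {}
    cols = {}
    for term in spec.parsed:
        if term.base not in base_cache:
            base_cache[term.base] = _base_values(strata, stack, scene, term.base)
        v = base_cache[term.base] ** term.power
        if term.modifier is not None:
            v = v * strata[term.modifier].to_numpy()
        cols[term.name] = v
    return pd.DataFrame(cols, index=strata.index)


# ---------------------------------------------------------------------------
# conditional logistic model
# ---------------------------------------------------------------------------


class StepSelectionModel:
    """Stratified conditional logistic regression for step selection.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Design matrix (one row per candidate step).
    used : (n,) 0/1 array, exactly one 1 per stratum.
    strata : (n,) stratum identifiers.
    clusters : (n,) cluster identifiers (animal ids) for the sandwich.
    """

    def __init__(self, X, used, strata, clusters, term_names=None):
        if isinstance(X, pd.DataFrame):
            term_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.term_names = list(term_names) if term_names is not None else [
            f"x{i}" for i in range(self.X.shape[1])
        ]
        used = np.asarray(used)
        strata = np.asarray(strata)
        clusters = np.asarray(clusters)
        order = np.argsort(strata, kind="stable")
        self.X = self.X[order]
        self.used = used[order].astype(float)
        self.strata = strata[order]
        self.clusters = clusters[order]
        _, self.group_start, counts = np.unique(
            self.strata, return_index=True, return_counts=True
        )
        self.group_sizes = counts
        self.n_strata = len(self.group_start)
        per_stratum_used = np.add.reduceat(self.used, self.group_start)
        if not np.allclose(per_stratum_used, 1.0):
            raise ValueError("each stratum must contain exactly one used step")

    @classmethod
    def from_strata(cls, strata_df: pd.DataFrame, stack, scene,
                    spec: DesignSpec) -> "StepSelectionModel":
        X = assemble_design(strata_df, stack, scene, spec)
        return cls(X, strata_df["used"].to_numpy(),
                   strata_df["stratum"].to_numpy(),
                   strata_df["animal_id"].to_numpy())

    # -- likelihood ----------------------------------------------------------

    def _probs(self, beta: np.ndarray) -> tuple[np.ndarray, float]:
        eta = self.X @ beta
        gmax = np.maximum.reduceat(eta, self.group_start)
        eta_c = eta - np.repeat(gmax, self.group_sizes)
        w = np.exp(eta_c)
        denom = np.add.reduceat(w, self.group_start)
        p = w / np.repeat(denom, self.group_sizes)
        llf = float((self.used * eta_c).sum() - np.log(denom).sum())
        return p, llf

    def loglike(self, beta: np.ndarray) -> float:
        return self._probs(beta)[1]

    def score(self, beta: np.ndarray) -> np.ndarray:
        p, _ = self._probs(beta)
        return self.X.T @ (self.used - p)

    def information(self, beta: np.ndarray) -> np.ndarray:
        """Observed information (negative Hessian of the log-likelihood)."""
        p, _ = self._probs(beta)
        XtWX = (self.X * p[:, None]).T @ self.X
        A = np.add.reduceat(self.X * p[:, None], self.group_start, axis=0)
        return XtWX - A.T @ A

    def fit(self, tol: float = 1e-8, maxiter: int = 60) -> "StepSelectionResults":
        """Newton-Raphson to gradient norm < ``tol``; flags separation.

        Columns with no within-stratum variation carry zero information for
        the conditional likelihood; they are excluded from the Newton system
        and their coefficients fixed at zero.
        """
        p_dim = self.X.shape[1]
        info0 = self.information(np.zeros(p_dim))
        d0 = np.diag(info0)
        active = d0 > 1e-10 * max(d0.max(), 1.0)
        Xa = self.X[:, active]

        beta_a = np.zeros(active.sum())
        beta = np.zeros(p_dim)
        _, llf = self._probs(beta)
        converged = False
        separated = False
        for _ in range(maxiter):
            beta[active] = beta_a
            p, llf = self._probs(beta)
            if llf > -1e-6 * self.n_strata:
                # the used step gets probability ~1 in every stratum: the
                # conditional likelihood is maximised at infinity
                separated = True
                warnings.warn(
                    "complete separation: a covariate perfectly ranks the "
                    "used steps; coefficients diverge"
                )
                break
            g = Xa.T @ (self.used - p)
            if np.linalg.norm(g, np.inf) < tol:
                converged = True
                break
            XtWX = (Xa * p[:, None]).T @ Xa
            A = np.add.reduceat(Xa * p[:, None], self.group_start, axis=0)
            H = XtWX - A.T @ A
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            # step-halving line search
            for _ in range(30):
                trial = beta.copy()
                trial[active] = beta_a + step
                if self.loglike(trial) >= llf - 1e-12:
                    break
                step = step / 2.0
            beta_a = beta_a + step
            if np.abs(beta_a).max() > 50.0:
                separated = True
                warnings.warn(
                    "possible complete separation: coefficients diverging"
                )
                break
        beta[active] = beta_a
        llf = self.loglike(beta)
        if not converged and not separated:
            warnings.warn("conditional logit did not reach gradient tolerance")

        info = self.information(beta)
        cov_model = np.zeros((p_dim, p_dim))
        if active.any():
            sub = np.linalg.pinv(info[np.ix_(active, active)])
            cov_model[np.ix_(active, active)] = sub
        cov_robust, robust_ok = robust_cluster_vcov(
            self, beta, cov_model=cov_model
        )
        return StepSelectionResults(
            model=self,
            params=pd.Series(beta, index=self.term_names),
            cov_model=cov_model,
            cov_robust=cov_robust,
            robust_ok=robust_ok,
            llf=llf,
            converged=converged,
            separated=separated,
        )


def robust_cluster_vcov(model: StepSelectionModel, beta: np.ndarray,
                        cov_model: np.ndarray | None = None):
    """Cluster sandwich ``A^-1 M A^-1`` over animals.

    ``A`` is the observed information and ``M`` the outer-product sum of
    per-cluster scores.  With a single cluster the sandwich is undefined and
    flagged.
    """
    p, _ = model._probs(beta)
    resid = (model.used - p)[:, None] * model.X
    cdf = pd.DataFrame(resid)
    cdf["_c"] = model.clusters
    scores = cdf.groupby("_c", sort=False).sum().to_numpy()
    if scores.shape[0] < 2:
        warnings.warn("only one cluster: robust covariance undefined")
        return np.full((model.X.shape[1],) * 2, np.nan), False
    M = scores.T @ scores
    if cov_model is None:
        cov_model = np.linalg.pinv(model.information(beta))
    cov = cov_model @ M @ cov_model
    return cov, True


@dataclass
class StepSelectionResults:
    """Fitted SSF with model-based and cluster-robust covariances."""

    model: StepSelectionModel
    params: pd.Series
    cov_model: np.ndarray
    cov_robust: np.ndarray
    robust_ok: bool
    llf: float
    converged: bool
    separated: bool = False

    @property
    def term_names(self) -> list[str]:
        return list(self.params.index)

    @property
    def bse(self) -> pd.Series:
        """Cluster-robust standard errors."""
        return pd.Series(
            np.sqrt(np.maximum(np.diag(self.cov_robust), 0.0)),
            index=self.params.index,
        )

    @property
    def bse_model(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.maximum(np.diag(self.cov_model), 0.0)),
            index=self.params.index,
        )

    @property
    def qic(self) -> float:
        """Quasi-likelihood information criterion (Pan 2001):
        ``-2 QL + 2 trace(A_I V_robust)`` with A_I the independence-model
        information."""
        A = self.model.information(self.params.to_numpy())
        penalty = float(np.trace(A @ self.cov_robust))
        return -2.0 * self.llf + 2.0 * penalty

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "robust_se": self.bse,
                "model_se": self.bse_model,
                "z": self.params / self.bse.replace(0.0, np.nan),
            }
        )
        lines = [
            "Step selection function (conditional logit, cluster-robust)",
            "=" * 62,
            f"n strata: {self.model.n_strata}   "
            f"n clusters: {len(np.unique(self.model.clusters))}   "
            f"quasi-loglik: {self.llf:.3f}   QIC: {self.qic:.3f}",
            f"converged: {self.converged}   separation: {self.separated}",
            "",
            tab.to_string(float_format=lambda v: f"{v:9.4f}"),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# QIC backward selection
# ---------------------------------------------------------------------------


def qic_backward_selection(
    strata_df: pd.DataFrame, stack, scene, full_spec: DesignSpec
) -> tuple[DesignSpec, StepSelectionResults, pd.DataFrame]:
    """Backward stepwise term removal minimising QIC.

    At each iteration the removable term (hierarchy respected) whose removal
    most lowers QIC is dropped; stops when no removal lowers QIC.  Candidate
    fits that fail keep their term (logged).
    """
    spec = full_spec
    fit = StepSelectionModel.from_strata(strata_df, stack, scene, spec).fit()
    trace = [{"action": "full", "term": None, "qic": fit.qic,
              "n_terms": len(spec.terms)}]
    while True:
        best_term, best_fit, best_qic = None, None, fit.qic
        for term in spec.removable_terms():
            trial = spec.drop(term)
            if not trial.terms:
                continue
            try:
                cand = StepSelectionModel.from_strata(
                    strata_df, stack, scene, trial
                ).fit()
            except Exception as exc:  # keep term on any fitting failure
                warnings.warn(f"candidate drop of {term!r} failed: {exc}")
                continue
            if cand.qic < best_qic:
                best_term, best_fit, best_qic = term, cand, cand.qic
        if best_term is None:
            break
        spec = spec.drop(best_term)
        fit = best_fit
        trace.append({"action": "drop", "term": best_term, "qic": best_qic,
                      "n_terms": len(spec.terms)})
    return spec, fit, pd.DataFrame(trace)


# ---------------------------------------------------------------------------
# relative selection strength & habitat prediction
# ---------------------------------------------------------------------------


def relative_selection_strength(
    fit: StepSelectionResults, x1, x0, alpha: float = 0.05
) -> dict[str, float]:
    """RSS = exp(beta' (x1 - x0)) with a delta-method CI on the log scale.

    ``x1``/``x0`` may be dicts keyed by term name (missing terms = 0) or
    arrays conformable with the coefficient vector.
    """
    from scipy.stats import norm

    beta = fit.params.to_numpy()
    names = fit.term_names

    def vec(x):
        if isinstance(x, dict):
            return np.array([float(x.get(n, 0.0)) for n in names])
        return np.asarray(x, dtype=float)

    dx = vec(x1) - vec(x0)
    log_rss = float(beta @ dx)
    var = float(dx @ fit.cov_robust @ dx)
    se = np.sqrt(max(var, 0.0))
    z = norm.ppf(1 - alpha / 2)
    return {
        "rss": np.exp(log_rss),
        "log_rss": log_rss,
        "se_log_rss": se,
        "lower": np.exp(log_rss - z * se),
        "upper": np.exp(log_rss + z * se),
    }


@dataclass
class HabitatMap:
    """Normalised habitat-use prediction and its top-third mask."""

    values: np.ndarray  # normalised exp(eta) over available cells, 0 outside
    top_third: np.ndarray  # boolean
    eta: np.ndarray
    p_fast: float
    c_hour: float


def endpoint_eta_grid(
    beta: pd.Series | dict, spec: DesignSpec, stack, scene,
    p_fast: float, c_hour: float,
    base_cache: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-cell linear predictor using endpoint terms only.

    Movement terms (step length, turn angle and their interactions) are
    excluded: they describe the step, not the endpoint.  On/off indicators
    are evaluated at cell centres (within 30 m of the feature class).
    """
    if isinstance(beta, pd.Series):
        beta = beta.to_dict()
    geom = stack.geometry
    eta = np.zeros(geom.shape)
    X, Y = geom.cell_centres()
    if base_cache is None:
        base_cache = {}
    for term in spec.parsed:
        if term.base in MOVEMENT_BASES:
            continue
        coef = float(beta.get(term.name, 0.0))
        if coef == 0.0:
            continue
        if term.base not in base_cache:
            if term.base.startswith("on_"):
                base_cache[term.base] = _onoff_indicator(
                    scene, term.base[3:], X.ravel(), Y.ravel()
                ).reshape(geom.shape)
            else:
                base_cache[term.base] = stack.layers[term.base]
        v = base_cache[term.base] ** term.power
        if term.modifier == "p_fast":
            v = v * p_fast
        elif term.modifier == "c_hour":
            v = v * c_hour
        eta = eta + coef * v
    return eta


def predict_habitat_map(
    fit_or_beta, spec: DesignSpec, stack, scene,
    p_fast: float = 0.5, c_hour: float = 0.0,
    scenario=None,
) -> HabitatMap:
    """Normalised exp(eta) habitat map and top-third high-quality mask.

    ``eta`` uses endpoint covariates only; the map is normalised over
    available cells; the top-third mask contains the third of available
    cells with the highest eta (ties broken by row-major cell index).
    """
    from movescape.landscape import scenario_stack

    if scenario is not None:
        stack = scenario_stack(stack, scenario)
    beta = fit_or_beta.params if isinstance(fit_or_beta, StepSelectionResults) \
        else fit_or_beta
    eta = endpoint_eta_grid(beta, spec, stack, scene, p_fast, c_hour)
    mask = stack.availability_mask
    values = np.zeros_like(eta)
    e = np.exp(eta[mask] - eta[mask].max())
    values[mask] = e / e.sum()

    flat_idx = np.flatnonzero(mask.ravel())
    vals = eta.ravel()[flat_idx]
    # sort by (eta desc, row-major index asc) for deterministic ties
    order = np.lexsort((flat_idx, -vals))
    k = int(round(len(flat_idx) / 3.0))
    top = np.zeros(eta.size, dtype=bool)
    top[flat_idx[order[:k]]] = True
    return HabitatMap(
        values=values, top_third=top.reshape(eta.shape), eta=eta,
        p_fast=p_fast, c_hour=c_hour,
    )
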