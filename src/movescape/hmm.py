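"""Two-state hidden Markov movement models with covariate-driven transitions.

Step lengths are gamma-distributed and turn angles von Mises-distributed
within each latent state (slow = foraging/resting, fast = travelling).  The
probability of switching state follows a logit-linear model in time of day
(cosine of hour), distance to town (capped-linear decay) and trail-road
density, so animals can, e.g., speed up near towns.

The model is organised statsmodels-style: :class:`MovementHMM` holds the
data and likelihood machinery; ``fit`` returns a
:class:`MovementHMMResults` carrying estimates, covariance, AIC, state
decoding and a ``summary()`` table.  Maximisation is quasi-Newton on a
working scale (log means/sds/concentrations, unconstrained transition
coefficients) with an analytic score obtained from the Fisher identity
(posterior-weighted complete-data derivatives from a forward-backward pass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, i0e, i1e

__all__ = [
    "Track",
    "StepSeries",
    "HmmParams",
    "DecaySpec",
    "MovementHMM",
    "MovementHMMResults",
    "build_steps",
    "transition_matrix",
    "stationary_probs",
    "forward_loglik",
    "smoothed_state_probs",
    "decay_model_selection",
    "wrap_angle",
]

SLOW, FAST = 0, 1
STATE_NAMES = ("slow", "fast")
# steps are kept only when the interfix gap is the nominal interval +/- this
GAP_TOLERANCE_H = 0.25
# stationary-GPS jitter floor for step lengths (metres)
MIN_STEP_M = 1.0

DEFAULT_TRANSITION_COVARIATES = ("c_hour", "town_dist", "trail_density")


def wrap_angle(theta):
    """Wrap angles into (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    out = theta - 2 * np.pi * np.floor((theta + np.pi) / (2 * np.pi))
    # floor maps pi -> -pi; put it back on the closed upper end
    out = np.where(out <= -np.pi, np.pi, out)
    return out


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class Track:
    """A GPS fix sequence for one animal-season (nominal 2-h interval)."""

    animal_id: str
    timestamps: np.ndarray  # datetime64[s]
    x: np.ndarray
    y: np.ndarray
    season: str | None = None
    species: str | None = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.timestamps) < 3:
            raise ValueError("a track needs at least 3 fixes")
        if not (np.diff(self.timestamps.astype("int64")) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if not (len(self.x) == len(self.y) == len(self.timestamps)):
            raise ValueError("coordinate/timestamp lengths differ")

    def __len__(self):
        return len(self.timestamps)

    @property
    def hours(self) -> np.ndarray:
        """Fractional hour of day for each fix."""
        secs = self.timestamps.astype("int64")
        return (secs % 86400) / 3600.0


@dataclass
class DecaySpec:
    """A town-proximity decay transform of raw distance-to-town (metres)."""

    mode: str  # "capped_linear" | "exp_decay"
    range_m: float

    def __post_init__(self):
        if self.mode not in ("capped_linear", "exp_decay"):
            raise ValueError(f"unknown decay mode {self.mode!r}")
        if not 500.0 <= self.range_m <= 5000.0:
            raise ValueError("range_m must be in [500, 5000]")

    @property
    def name(self) -> str:
        return f"{self.mode}_{int(self.range_m)}"

    def transform(self, distance_m: np.ndarray) -> np.ndarray:
        if self.mode == "capped_linear":
            return np.minimum(distance_m, self.range_m) / self.range_m
        return np.exp(-distance_m / self.range_m)


@dataclass
class StepSeries:
    """Per-step observations and covariates derived from one track.

    ``angles[t]`` is NaN for the first step of each contiguous segment (turn
    angles need a previous bearing).  ``X`` holds the transition covariates
    at each step's start.  Segments (breaks at irregular fix gaps) are
    treated as independent likelihood blocks.
    """

    animal_id: str
    lengths: np.ndarray
    angles: np.ndarray
    X: np.ndarray  # (n, k) transition covariates at step start
    covariate_names: tuple[str, ...]
    hour: np.ndarray
    segment_id: np.ndarray
    x0: np.ndarray
    y0: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    bearing: np.ndarray
    season: str | None = None
    n_dropped: int = 0

    def __post_init__(self):
        n = len(self.lengths)
        for name in ("angles", "hour", "segment_id", "x0", "y0", "x1", "y1",
                     "bearing"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.X.shape != (n, len(self.covariate_names)):
            raise ValueError("covariate matrix shape mismatch")
        if (self.lengths < 0).any():
            raise ValueError("negative step length")

    def __len__(self):
        return len(self.lengths)

    @property
    def c_hour(self) -> np.ndarray:
        return np.cos(2 * np.pi * self.hour / 24.0)


@dataclass
class HmmParams:
    """Two-state emission and transition parameters.

    ``beta`` has two rows -- (slow->fast, fast->slow) -- each containing an
    intercept plus one coefficient per transition covariate.  States are
    ordered so that ``mu[fast] > mu[slow]``.
    """

    mu: np.ndarray  # gamma mean (m) per state
    sigma: np.ndarray  # gamma sd (m) per state
    angle_mean: np.ndarray  # von Mises mean angle per state
    kappa: np.ndarray  # von Mises concentration per state
    beta: np.ndarray  # (2, 1 + k)
    covariate_names: tuple[str, ...] = DEFAULT_TRANSITION_COVARIATES

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.angle_mean = np.asarray(self.angle_mean, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.mu.shape != (2,) or self.sigma.shape != (2,):
            raise ValueError("mu/sigma must have one value per state")
        if (self.mu <= 0).any() or (self.sigma <= 0).any():
            raise ValueError("gamma mean and sd must be positive")
        if (self.kappa < 0).any() or not np.isfinite(self.kappa).all():
            raise ValueError("kappa must be finite and non-negative")
        if self.mu[FAST] <= self.mu[SLOW]:
            raise ValueError("state ordering requires mu[fast] > mu[slow]")
        if self.beta.shape != (2, 1 + len(self.covariate_names)):
            raise ValueError(
                f"beta shape {self.beta.shape} incompatible with "
                f"{len(self.covariate_names)} transition covariates"
            )

    @property
    def n_free(self) -> int:
        return 8 + self.beta.size


# ---------------------------------------------------------------------------
# step construction
# ---------------------------------------------------------------------------


def build_steps(
    track: Track,
    stack,
    decay: DecaySpec | None = None,
    fix_interval_h: float = 2.0,
    covariate_names: tuple[str, ...] = DEFAULT_TRANSITION_COVARIATES,
) -> StepSeries:
    """Derive step lengths, turn angles and transition covariates from a track.

    Steps are retained only when the interfix gap equals the nominal interval
    within +/- 15 min; other gaps split the series into independent segments.
    Fixes outside the covariate grid are dropped (counted).  ``c_hour`` is
    ``cos(2*pi*h/24)`` so midnight maps to 1 and noon to -1.  The town
    covariate defaults to the stack's ``town_dist`` layer, or to
    ``decay.transform`` of the raw ``dist_town_m`` layer if a decay spec is
    given.
    """
    geom = stack.geometry
    inside = geom.in_bounds(track.x, track.y)
    n_dropped = int((~inside).sum())
    ts = track.timestamps[inside]
    xs, ys = track.x[inside], track.y[inside]
    hours = track.hours[inside]
    if len(ts) < 2:
        raise ValueError("fewer than 2 in-grid fixes; no steps")

    dt_h = np.diff(ts.astype("int64")) / 3600.0
    regular = np.abs(dt_h - fix_interval_h) <= GAP_TOLERANCE_H

    # a step exists between fix i and i+1 iff regular[i]
    step_idx = np.flatnonzero(regular)
    if len(step_idx) == 0:
        raise ValueError("no regular-interval steps in track")
    # segment breaks wherever consecutive steps are not contiguous fixes
    seg = np.zeros(len(step_idx), dtype=int)
    seg[1:] = np.cumsum(np.diff(step_idx) != 1)

    p0 = np.column_stack([xs[step_idx], ys[step_idx]])
    p1 = np.column_stack([xs[step_idx + 1], ys[step_idx + 1]])
    d = p1 - p0
    lengths = np.hypot(d[:, 0], d[:, 1])
    lengths = np.maximum(lengths, MIN_STEP_M)
    bearing = np.arctan2(d[:, 1], d[:, 0])

    angles = np.full(len(step_idx), np.nan)
    same_seg = np.flatnonzero((seg[1:] == seg[:-1]))
    turn = bearing[same_seg + 1] - bearing[same_seg]
    angles[same_seg + 1] = wrap_angle(turn)

    hour = hours[step_idx]
    cols = []
    for name in covariate_names:
        if name == "c_hour":
            cols.append(np.cos(2 * np.pi * hour / 24.0))
        elif name == "town_dist" and decay is not None:
            raw = stack.value_at("dist_town_m", p0[:, 0], p0[:, 1])
            cols.append(decay.transform(raw))
        else:
            cols.append(stack.value_at(name, p0[:, 0], p0[:, 1]))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("non-finite transition covariates at fix locations")

    return StepSeries(
        animal_id=track.animal_id,
        lengths=lengths,
        angles=angles,
        X=X,
        covariate_names=tuple(covariate_names),
        hour=hour,
        segment_id=seg,
        x0=p0[:, 0],
        y0=p0[:, 1],
        x1=p1[:, 0],
        y1=p1[:, 1],
        bearing=bearing,
        season=track.season,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# transition structure
# ---------------------------------------------------------------------------


def transition_matrix(beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """2x2 transition probability matrix (or batch) at covariates ``x``.

    ``logit(gamma_slow->fast) = beta[0] . (1, x)`` and likewise for row two;
    rows sum to one and all entries lie in (0, 1).
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite transition covariates")
    ones = np.ones(x.shape[:-1] + (1,))
    design = np.concatenate([ones, x], axis=-1)
    eta = design @ beta.T  # (..., 2)
    p_switch = expit(eta)
    gamma = np.empty(x.shape[:-1] + (2, 2))
    gamma[..., SLOW, FAST] = p_switch[..., 0]
    gamma[..., SLOW, SLOW] = 1.0 - p_switch[..., 0]
    gamma[..., FAST, SLOW] = p_switch[..., 1]
    gamma[..., FAST, FAST] = 1.0 - p_switch[..., 1]
    return gamma


def stationary_probs(beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Stationary distribution ``(pi_slow, pi_fast)`` of ``transition_matrix``.

    ``pi_fast = g_sf / (g_sf + g_fs)``; a degenerate (absorbing) matrix is
    resolved by its limit and flagged with a warning.
    """
    gamma = transition_matrix(beta, x)
    g_sf = gamma[..., SLOW, FAST]
    g_fs = gamma[..., FAST, SLOW]
    total = g_sf + g_fs
    if np.any(total <= 1e-300):
        warnings.warn("degenerate transition matrix; stationary probs by limit")
        total = np.where(total <= 1e-300, 1.0, total)
        g_sf = np.where(total == 1.0, 0.5, g_sf)
    pi_fast = g_sf / total
    return np.stack([1.0 - pi_fast, pi_fast], axis=-1)


# ---------------------------------------------------------------------------
# emission densities and derivatives
# ---------------------------------------------------------------------------


def _gamma_shape_scale(mu, sigma):
    shape = (mu / sigma) ** 2
    scale = sigma**2 / mu
    return shape, scale


def _log_gamma_pdf(l, mu, sigma):
    a, th = _gamma_shape_scale(mu, sigma)
    return (a - 1) * np.log(l) - l / th - gammaln(a) - a * np.log(th)


def _log_vonmises_pdf(theta, m, kappa):
    # log I0(k) = log(i0e(k)) + k, stable for all k >= 0
    return kappa * np.cos(theta - m) - kappa - np.log(i0e(kappa)) - np.log(2 * np.pi)


def _vm_mean_ratio(kappa):
    return i1e(kappa) / i0e(kappa)


# ---------------------------------------------------------------------------
# packed segments and forward-backward
# ---------------------------------------------------------------------------


class _Packed:
    """Segments from one or more StepSeries padded to a common length."""

    def __init__(self, series_list: list[StepSeries]):
        if not series_list:
            raise ValueError("no step series supplied")
        names = series_list[0].covariate_names
        segs = []
        for s_idx, s in enumerate(series_list):
            if s.covariate_names != names:
                raise ValueError("inconsistent transition covariates")
            for seg_id in np.unique(s.segment_id):
                m = s.segment_id == seg_id
                segs.append(
                    (s_idx, s.lengths[m], s.angles[m], s.X[m], s.animal_id)
                )
        self.covariate_names = names
        self.n_seg = len(segs)
        self.k = len(names)
        T = max(len(seg[1]) for seg in segs)
        self.T = T
        self.lengths = np.ones((self.n_seg, T))
        self.angles = np.full((self.n_seg, T), np.nan)
        self.X = np.zeros((self.n_seg, T, self.k))
        self.valid = np.zeros((self.n_seg, T), dtype=bool)
        self.series_index = []
        self.animal_ids = []
        for i, (s_idx, l, a, X, aid) in enumerate(segs):
            n = len(l)
            self.lengths[i, :n] = l
            self.angles[i, :n] = a
            self.X[i, :n] = X
            self.valid[i, :n] = True
            self.series_index.append(s_idx)
            self.animal_ids.append(aid)
        self.has_angle = self.valid & ~np.isnan(self.angles)
        self.angles_filled = np.where(self.has_angle, self.angles, 0.0)
        self.n_obs = int(self.valid.sum())

    def log_emission(self, params: HmmParams) -> np.ndarray:
        """(n_seg, T, 2) log emission densities (1 outside valid range)."""
        l = self.lengths[..., None]
        logf = _log_gamma_pdf(l, params.mu, params.sigma)
        logvm = _log_vonmises_pdf(
            self.angles_filled[..., None], params.angle_mean, params.kappa
        )
        logf = logf + np.where(self.has_angle[..., None], logvm, 0.0)
        return np.where(self.valid[..., None], logf, 0.0)

    def transition_mats(self, params: HmmParams) -> np.ndarray:
        gamma = transition_matrix(
            params.beta, self.X.reshape(self.n_seg * self.T, self.k)
        )
        gamma = gamma.reshape(self.n_seg, self.T, 2, 2)
        eye = np.eye(2)
        return np.where(self.valid[..., None, None], gamma, eye)


def _forward_backward(packed: _Packed, params: HmmParams, want_posteriors=False):
    """Scaled forward (and optionally backward) pass over padded segments.

    Returns (loglik, gamma_post, xi_post) where the posteriors are None
    unless requested.  Initial distribution is the stationary distribution at
    the first step's covariates.
    """
    logB = packed.log_emission(params)
    shift = logB.max(axis=2)
    dens = np.exp(logB - shift[..., None])  # (S, T, 2), 1 where invalid
    Gam = packed.transition_mats(params)

    S, T = packed.n_seg, packed.T
    delta = stationary_probs(params.beta, packed.X[:, 0, :])  # (S, 2)

    alphas = np.empty((S, T, 2))
    cs = np.empty((S, T))
    a = delta * dens[:, 0, :]
    c = a.sum(axis=1)
    a /= c[:, None]
    alphas[:, 0] = a
    cs[:, 0] = c
    for t in range(1, T):
        a = np.einsum("si,sij->sj", a, Gam[:, t]) * dens[:, t]
        c = a.sum(axis=1)
        a /= c[:, None]
        alphas[:, t] = a
        cs[:, t] = c

    loglik = float(np.log(cs).sum() + np.where(packed.valid, shift, 0.0).sum())
    if not want_posteriors:
        return loglik, None, None

    betas = np.empty((S, T, 2))
    b = np.ones((S, 2))
    betas[:, T - 1] = b
    for t in range(T - 1, 0, -1):
        b = np.einsum("sij,sj->si", Gam[:, t], dens[:, t] * b) / cs[:, t][:, None]
        betas[:, t - 1] = b

    gamma_post = alphas * betas
    gamma_post /= gamma_post.sum(axis=2, keepdims=True)

    # xi[s, t, i, j]: posterior of transition from step t-1 (i) to step t (j)
    xi = (
        alphas[:, :-1, :, None]
        * Gam[:, 1:]
        * (dens[:, 1:] * betas[:, 1:])[:, :, None, :]
        / cs[:, 1:][:, :, None, None]
    )
    return loglik, gamma_post, xi


def forward_loglik(steps, params: HmmParams) -> float:
    """Pooled log-likelihood of one or more step series under ``params``.

    Scaled forward recursion with per-step transition matrices; segments are
    independent blocks; a missing first turn angle contributes its length
    density only.
    """
    if isinstance(steps, StepSeries):
        steps = [steps]
    packed = _Packed(list(steps))
    ll, _, _ = _forward_backward(packed, params)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return ll


# ---------------------------------------------------------------------------
# working-scale parameterisation
# ---------------------------------------------------------------------------


def _pack_working(params: HmmParams) -> np.ndarray:
    return np.concatenate(
        [
            np.log(params.mu),
            np.log(params.sigma),
            params.angle_mean,
            np.log(np.maximum(params.kappa, 1e-8)),
            params.beta.ravel(),
        ]
    )


def _unpack_working(w: np.ndarray, covariate_names, ordered=False) -> HmmParams:
    k = len(covariate_names)
    mu = np.exp(w[0:2])
    sigma = np.exp(w[2:4])
    m = wrap_angle(w[4:6])
    kappa = np.exp(w[6:8])
    beta = w[8:].reshape(2, 1 + k)
    if ordered and mu[FAST] <= mu[SLOW]:
        raise ValueError("working vector violates state ordering")
    # bypass ordering enforcement during optimisation via a permissive clone
    obj = HmmParams.__new__(HmmParams)
    obj.mu, obj.sigma, obj.angle_mean, obj.kappa = mu, sigma, m, kappa
    obj.beta = beta
    obj.covariate_names = tuple(covariate_names)
    return obj


def _working_names(covariate_names) -> list[str]:
    names = [
        "log_mu[slow]", "log_mu[fast]",
        "log_sigma[slow]", "log_sigma[fast]",
        "angle_mean[slow]", "angle_mean[fast]",
        "log_kappa[slow]", "log_kappa[fast]",
    ]
    for row in ("slow_to_fast", "fast_to_slow"):
        names.append(f"beta[{row}].intercept")
        names.extend(f"beta[{row}].{c}" for c in covariate_names)
    return names


def _swap_states_working(w: np.ndarray, k: int) -> np.ndarray:
    """Permute the two state labels in a working vector."""
    w = w.copy()
    for base in (0, 2, 4, 6):
        w[[base, base + 1]] = w[[base + 1, base]]
    nb = 1 + k
    b = w[8:].reshape(2, nb)
    w[8:] = b[::-1].ravel()
    return w


def _score(packed: _Packed, params: HmmParams) -> tuple[float, np.ndarray]:
    """Log-likelihood and its gradient on the working scale (Fisher identity)."""
    ll, post, xi = _forward_backward(packed, params, want_posteriors=True)
    valid = packed.valid
    wgt = np.where(valid[..., None], post, 0.0)  # (S, T, 2)

    l = packed.lengths[..., None]
    a, th = _gamma_shape_scale(params.mu, params.sigma)
    core = np.log(l) - digamma(a) - np.log(th)
    excess = l / th - a
    d_logmu = 2 * a * core - excess
    d_logsigma = -2 * a * core + 2 * excess

    dtheta = packed.angles_filled[..., None] - params.angle_mean
    has_ang = packed.has_angle[..., None]
    d_m = np.where(has_ang, params.kappa * np.sin(dtheta), 0.0)
    d_logkappa = np.where(
        has_ang, params.kappa * (np.cos(dtheta) - _vm_mean_ratio(params.kappa)), 0.0
    )

    g_mu = (wgt * d_logmu).sum(axis=(0, 1))
    g_sigma = (wgt * d_logsigma).sum(axis=(0, 1))
    g_m = (wgt * d_m).sum(axis=(0, 1))
    g_kappa = (wgt * d_logkappa).sum(axis=(0, 1))

    # transition rows: d loglik / d beta_r = sum_t [xi(r, switch) -
    # sigma(eta_r) * gamma_{t-1}(r)] * (1, x_t)
    S, T, k = packed.n_seg, packed.T, packed.k
    ones = np.ones((S, T, 1))
    design = np.concatenate([ones, packed.X], axis=2)  # (S, T, 1+k)
    eta = np.einsum("stp,rp->str", design, params.beta)
    p_switch = expit(eta)  # (S, T, 2)

    g_beta = np.zeros((2, 1 + k))
    if T > 1:
        tv = valid[:, 1:]  # transition into step t valid iff step t valid
        for r, sw in ((SLOW, FAST), (FAST, SLOW)):
            resid = xi[:, :, r, sw] - p_switch[:, 1:, r] * post[:, :-1, r]
            resid = np.where(tv, resid, 0.0)
            g_beta[r] = np.einsum("st,stp->p", resid, design[:, 1:])

    # initial distribution is stationary at x_1 and depends on beta
    x1 = design[:, 0, :]  # (S, 1+k)
    u = p_switch[:, 0, SLOW]
    v = p_switch[:, 0, FAST]
    tot = u + v
    pi_f = u / tot
    dpi_d1 = u * (1 - u) * v / tot**2
    dpi_d2 = -u * v * (1 - v) / tot**2
    w_init = post[:, 0, FAST] / np.maximum(pi_f, 1e-300) - post[:, 0, SLOW] / (
        np.maximum(1 - pi_f, 1e-300)
    )
    g_beta[SLOW] += np.einsum("s,sp->p", w_init * dpi_d1, x1)
    g_beta[FAST] += np.einsum("s,sp->p", w_init * dpi_d2, x1)

    grad = np.concatenate([g_mu, g_sigma, g_m, g_kappa, g_beta.ravel()])
    return ll, grad


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class MovementHMM:
    """Two-state hidden Markov movement model (pooled across tracks).

    Parameters
    ----------
    steps : StepSeries or list of StepSeries
        Step data built by :func:`build_steps`; gap-separated segments are
        independent likelihood blocks.
    """

    def __init__(self, steps):
        if isinstance(steps, StepSeries):
            steps = [steps]
        self.steps = list(steps)
        self.packed = _Packed(self.steps)
        self.covariate_names = self.packed.covariate_names
        self.k = self.packed.k
        self.n_params = 8 + 2 * (1 + self.k)
        self.param_names = _working_names(self.covariate_names)

    # -- likelihood interface ------------------------------------------------

    def loglike(self, w: np.ndarray) -> float:
        params = _unpack_working(w, self.covariate_names)
        ll, _, _ = _forward_backward(self.packed, params)
        return ll

    def score(self, w: np.ndarray) -> np.ndarray:
        params = _unpack_working(w, self.covariate_names)
        _, g = _score(self.packed, params)
        return g

    def loglike_params(self, params: HmmParams) -> float:
        ll, _, _ = _forward_backward(self.packed, params)
        return ll

    # -- initial values ------------------------------------------------------

    def _default_init(self) -> np.ndarray:
        l = self.packed.lengths[self.packed.valid]
        med = np.median(l)
        lo = l[l <= med]
        hi = l[l > med]
        mu = np.array([max(lo.mean(), 2.0), max(hi.mean(), lo.mean() * 2 + 2.0)])
        sigma = np.array(
            [max(lo.std(), 1.0), max(hi.std(), 1.0)]
        )
        w = np.concatenate(
            [
                np.log(mu),
                np.log(sigma),
                np.array([0.0, 0.0]),
                np.log(np.array([0.5, 1.0])),
                np.concatenate(
                    [[-2.0], np.zeros(self.k), [-2.0], np.zeros(self.k)]
                ),
            ]
        )
        return w

    def _random_inits(self, n: int, rng: np.random.Generator) -> list[np.ndarray]:
        base = self._default_init()
        inits = [base]
        for _ in range(n - 1):
            w = base.copy()
            w[0:4] += rng.normal(0, 0.4, 4)
            w[4:6] = rng.uniform(-np.pi, np.pi, 2)
            w[6:8] += rng.normal(0, 0.5, 2)
            w[8:] += rng.normal(0, 0.5, len(w) - 8)
            inits.append(w)
        return inits

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        inits: HmmParams | None = None,
        n_restarts: int = 10,
        n_polish: int = 2,
        seed: int = 0,
        maxiter: int = 500,
        compute_cov: bool = True,
    ) -> "MovementHMMResults":
        """Maximise the pooled likelihood by seeded multi-start L-BFGS-B.

        ``n_restarts`` candidate starting points (data-driven moments plus
        random jitter) are screened by log-likelihood; full optimisation runs
        from the best ``n_polish``.  States are relabelled post-fit so the
        fast state has the larger mean step length.
        """
        rng = np.random.default_rng(seed)
        if inits is not None:
            cand = [_pack_working(inits)]
        else:
            cand = self._random_inits(max(n_restarts, 1), rng)
        if len(cand) > n_polish:
            scores = []
            for w in cand:
                with np.errstate(over="ignore", invalid="ignore",
                                 divide="ignore"):
                    try:
                        s = self.loglike(w)
                    except FloatingPointError:
                        s = -np.inf
                scores.append(s if np.isfinite(s) else -np.inf)
            order = np.argsort(scores)[::-1]
            cand = [cand[i] for i in order[:n_polish]]

        # a large finite penalty (not inf) keeps the line search backtracking
        # sanely when a trial point degenerates numerically
        PENALTY = 1e10

        def neg(w):
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                try:
                    ll, g = _score(
                        self.packed, _unpack_working(w, self.covariate_names)
                    )
                except FloatingPointError:
                    return PENALTY, np.zeros_like(w)
            if not np.isfinite(ll) or not np.isfinite(g).all():
                return PENALTY, np.zeros_like(w)
            return -ll, -g

        # generous working-scale bounds keep restarts out of overflow regions
        bounds = (
            [(-1.0, 11.0)] * 4  # log mu, log sigma (0.4 m .. 60 km)
            + [(-7.0, 7.0)] * 2  # angle means
            + [(-6.0, 6.0)] * 2  # log kappa
            + [(-15.0, 15.0)] * (2 * (1 + self.k))
        )
        best = None
        for w0 in cand:
            res = minimize(
                neg, np.clip(w0, [b[0] for b in bounds], [b[1] for b in bounds]),
                jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success) and np.isfinite(best.fun)
        if not converged:
            warnings.warn(f"HMM optimisation did not converge: {best.message}")

        w_hat = best.x
        if np.exp(w_hat[0]) > np.exp(w_hat[1]):  # enforce mu_fast > mu_slow
            w_hat = _swap_states_working(w_hat, self.k)

        cov = None
        cov_ok = False
        if compute_cov:
            from statsmodels.tools.numdiff import approx_fprime

            info = -approx_fprime(w_hat, self.score, centered=True)
            info = 0.5 * (info + info.T)
            try:
                cov = np.linalg.inv(info)
                cov_ok = bool(np.isfinite(cov).all() and (np.diag(cov) > 0).all())
            except np.linalg.LinAlgError:
                cov = None
            if not cov_ok:
                warnings.warn("observed information not invertible; cov unavailable")
                cov = None

        llf = -best.fun
        params = _unpack_working(w_hat, self.covariate_names)
        final = HmmParams(
            mu=params.mu, sigma=params.sigma, angle_mean=params.angle_mean,
            kappa=params.kappa, beta=params.beta,
            covariate_names=tuple(self.covariate_names),
        )
        return MovementHMMResults(
            model=self,
            params=final,
            working=w_hat,
            cov_working=cov,
            llf=llf,
            converged=converged,
            n_obs=self.packed.n_obs,
        )


@dataclass
class MovementHMMResults:
    """Fitted two-state movement HMM."""

    model: MovementHMM
    params: HmmParams
    working: np.ndarray
    cov_working: np.ndarray | None
    llf: float
    converged: bool
    n_obs: int

    @property
    def n_free(self) -> int:
        return self.params.n_free

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_free

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def bse(self) -> np.ndarray:
        if self.cov_working is None:
            return np.full(len(self.working), np.nan)
        return np.sqrt(np.maximum(np.diag(self.cov_working), 0.0))

    def beta_table(self) -> pd.DataFrame:
        """Transition coefficients with standard errors (direct scale)."""
        names = self.param_names
        idx = [i for i, n in enumerate(names) if n.startswith("beta[")]
        return pd.DataFrame(
            {
                "estimate": self.working[idx],
                "se": self.bse[idx],
            },
            index=[names[i] for i in idx],
        )

    def smoothed_state_probs(self, steps=None) -> np.ndarray:
        """Smoothed P(fast) per step (forward-backward), concatenated over
        segments in input order."""
        packed = self.model.packed if steps is None else _Packed(
            [steps] if isinstance(steps, StepSeries) else list(steps)
        )
        _, post, _ = _forward_backward(packed, self.params, want_posteriors=True)
        out = post[..., FAST][packed.valid]
        return out

    def stationary_probs(self, x) -> np.ndarray:
        return stationary_probs(self.params.beta, x)

    def summary(self) -> str:
        lines = [
            "Two-state hidden Markov movement model",
            "=" * 54,
            f"n steps: {self.n_obs}   log-lik: {self.llf:.3f}   AIC: {self.aic:.3f}",
            f"converged: {self.converged}",
            "",
            "Emission parameters (state: slow, fast)",
            f"  step mean (m):     {self.params.mu[0]:10.2f} {self.params.mu[1]:10.2f}",
            f"  step sd (m):       {self.params.sigma[0]:10.2f} {self.params.sigma[1]:10.2f}",
            f"  angle mean (rad):  {self.params.angle_mean[0]:10.3f} {self.params.angle_mean[1]:10.3f}",
            f"  concentration:     {self.params.kappa[0]:10.3f} {self.params.kappa[1]:10.3f}",
            "",
            "Transition coefficients (logit scale)",
            self.beta_table().to_string(float_format=lambda v: f"{v:9.4f}"),
        ]
        return "\n".join(lines)


def smoothed_state_probs(steps, fit: MovementHMMResults) -> np.ndarray:
    """Module-level convenience wrapper for state decoding."""
    return fit.smoothed_state_probs(steps)


# ---------------------------------------------------------------------------
# decay-function model selection
# ---------------------------------------------------------------------------


def decay_model_selection(
    tracks,
    stack,
    candidates: list[DecaySpec],
    fit_kwargs: dict | None = None,
) -> tuple[DecaySpec, pd.DataFrame]:
    """Fit one HMM per town-decay specification and rank them by AIC.

    Returns the best (minimum-AIC) spec and a table with log-likelihood, AIC
    and delta-AIC per candidate; non-converged candidates are excluded with a
    warning.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate decay spec")
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_cov", False)
    rows = []
    fits = {}
    for spec in candidates:
        series = [build_steps(t, stack, decay=spec) for t in tracks]
        res = MovementHMM(series).fit(**fit_kwargs)
        if not res.converged:
            warnings.warn(f"decay spec {spec.name} did not converge; excluded")
            continue
        fits[spec.name] = (spec, res)
        rows.append({"spec": spec.name, "loglik": res.llf, "aic": res.aic})
    if not rows:
        raise RuntimeError("no decay candidate converged")
    table = pd.DataFrame(rows).set_index("spec")
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best_name = table["aic"].idxmin()
    return fits[best_name][0], table.sort_values("aic")
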