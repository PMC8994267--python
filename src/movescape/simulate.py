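"""SSF-weighted, state-switching path simulation under landscape scenarios.

Each simulated step follows the fitted generative chain: transition
probabilities (from the movement HMM) give 20 candidate states; candidate
step lengths and turn angles are drawn from the state-specific gamma / von
Mises distributions; candidates crossing unavailable habitat (checked at
four equidistant points along the segment) are rejected; one surviving
candidate is selected with probability proportional to ``exp(eta)`` under
the step selection function, with the candidate's binary state standing in
for ``p_fast`` in the interactions.

Paths start in high-quality habitat (top third of SSF predictions), advance
the clock by one fix interval per step and terminate when complete, when
the running fraction of proposed candidate endpoints outside the study area
exceeds 40% (boundary), or when the animal is boxed in too long (stuck).

The engine advances all paths of an ensemble in lockstep with one seeded
PCG64 stream and a fixed draw layout, so ensembles are bit-reproducible
given the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from movescape.hmm import FAST, SLOW, HmmParams
from movescape.landscape import CovariateStack, ScenarioSpec, VectorScene, scenario_stack
from movescape.ssf import (
    MOVEMENT_BASES,
    DesignSpec,
    StepSelectionResults,
    endpoint_eta_grid,
    predict_habitat_map,
)

__all__ = [
    "SimConfig",
    "SimPath",
    "PathEnsemble",
    "ScenarioBundle",
    "scenario_coefficients",
    "seed_start_points",
    "propose_candidates",
    "reject_step",
    "select_step",
    "simulate_path",
    "simulate_ensemble",
]

TERMINATION_CODES = {0: "completed", 1: "boundary", 2: "stuck"}


@dataclass
class SimConfig:
    """Simulation settings (defaults follow the study design: 720 steps =
    60 days x 12 fixes/day, 20 candidates per step)."""

    n_paths: int = 100
    steps_per_path: int = 720
    fixes_per_day: int = 12
    n_candidates: int = 20
    checkpoint_fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    boundary_threshold: float = 0.40
    boundary_rule: str = "cumulative"  # or "per_step"
    clip_buffer_m: float = 5000.0
    max_redraws: int = 5
    max_hold: int = 10
    seed: int = 0
    fix_interval_h: float = field(init=False)

    def __post_init__(self):
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if not 0.0 < self.boundary_threshold < 1.0:
            raise ValueError("boundary threshold must be in (0, 1)")
        if self.boundary_rule not in ("cumulative", "per_step"):
            raise ValueError("boundary_rule must be cumulative or per_step")
        if self.steps_per_path % self.fixes_per_day and self.steps_per_path > 0:
            warnings.warn("steps_per_path is not a whole number of days")
        self.fix_interval_h = 24.0 / self.fixes_per_day


@dataclass
class SimPath:
    """A single simulated path (positions include the start location)."""

    xy: np.ndarray  # (n_used + 1, 2)
    states: np.ndarray
    hours: np.ndarray
    termination: str

    def __len__(self):
        return len(self.states)


@dataclass
class PathEnsemble:
    """A set of simulated paths sharing scenario and configuration."""

    scenario: str
    xy: np.ndarray  # (n_paths, T + 1, 2)
    states: np.ndarray  # (n_paths, T + 1)
    hour_index: np.ndarray  # (n_paths, T + 1)
    steps_used: np.ndarray  # (n_paths,)
    termination: np.ndarray  # (n_paths,) codes into TERMINATION_CODES
    config: SimConfig
    seed: int

    @property
    def n_paths(self) -> int:
        return self.xy.shape[0]

    @property
    def termination_counts(self) -> dict[str, int]:
        return {
            name: int((self.termination == code).sum())
            for code, name in TERMINATION_CODES.items()
        }

    @property
    def total_steps(self) -> int:
        return int(self.steps_used.sum())

    def locations(self, state_filter: str = "combined"):
        """All visited locations (including starts) as flat arrays
        ``(x, y, state, path_id)``, optionally filtered to one state."""
        n, T1 = self.states.shape
        tgrid = np.arange(T1)[None, :]
        use = tgrid <= self.steps_used[:, None]
        if state_filter == "slow":
            use = use & (self.states == SLOW)
        elif state_filter == "fast":
            use = use & (self.states == FAST)
        elif state_filter != "combined":
            raise ValueError("state_filter must be slow, fast or combined")
        pid = np.broadcast_to(np.arange(n)[:, None], (n, T1))
        return (
            self.xy[..., 0][use],
            self.xy[..., 1][use],
            self.states[use],
            pid[use],
        )

    def path(self, i: int) -> SimPath:
        n_used = int(self.steps_used[i])
        return SimPath(
            xy=self.xy[i, : n_used + 1].copy(),
            states=self.states[i, : n_used + 1].copy(),
            hours=self.hour_index[i, : n_used + 1] * self.config.fix_interval_h,
            termination=TERMINATION_CODES[int(self.termination[i])],
        )

    def to_dataframe(self) -> pd.DataFrame:
        x, y, s, pid = self.locations("combined")
        n, T1 = self.states.shape
        tgrid = np.arange(T1)[None, :]
        use = tgrid <= self.steps_used[:, None]
        hours = (self.hour_index * self.config.fix_interval_h)[use]
        step_no = np.broadcast_to(tgrid, (n, T1))[use]
        return pd.DataFrame(
            {
                "path_id": pid,
                "step": step_no,
                "x": x,
                "y": y,
                "hour": hours,
                "state": s,
                "scenario": self.scenario,
            }
        )


# ---------------------------------------------------------------------------
# scenario machinery
# ---------------------------------------------------------------------------


def scenario_coefficients(
    ssf_beta,
    spec: DesignSpec,
    hmm_params: HmmParams,
    scenario: ScenarioSpec,
    hmm_anthropogenic: tuple[str, ...] = ("town_dist", "trail_density"),
) -> tuple[pd.Series, HmmParams]:
    """Effective SSF and HMM coefficients for a scenario.

    Under a ``zero_anthropogenic`` scenario (reference) every SSF term whose
    base covariate is anthropogenic -- including quadratics, on/off
    indicators and their interactions -- is zeroed, and the HMM transition
    coefficients on anthropogenic covariates are zeroed.  Other scenarios
    return the coefficients unchanged (idempotent by construction).
    """
    if isinstance(ssf_beta, StepSelectionResults):
        ssf_beta = ssf_beta.params
    if isinstance(ssf_beta, dict):
        ssf_beta = pd.Series(ssf_beta)
    beta = ssf_beta.copy().astype(float)
    if not scenario.zero_anthropogenic:
        return beta, hmm_params
    for term in spec.parsed:
        if term.base in spec.anthropogenic_bases:
            beta[term.name] = 0.0
    B = hmm_params.beta.copy()
    for j, name in enumerate(hmm_params.covariate_names):
        if name in hmm_anthropogenic:
            B[:, 1 + j] = 0.0
    hmm_eff = HmmParams(
        mu=hmm_params.mu, sigma=hmm_params.sigma,
        angle_mean=hmm_params.angle_mean, kappa=hmm_params.kappa,
        beta=B, covariate_names=hmm_params.covariate_names,
    )
    return beta, hmm_eff


@dataclass
class ScenarioBundle:
    """Everything the simulator needs for one scenario: the scenario-adjusted
    covariate stack, effective HMM parameters and SSF coefficients."""

    name: str
    stack: CovariateStack
    scene: VectorScene
    hmm_params: HmmParams
    design_spec: DesignSpec
    beta: np.ndarray  # aligned with design_spec.terms
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def build(
        cls,
        base_stack: CovariateStack,
        scene: VectorScene,
        scenario: ScenarioSpec,
        hmm_params: HmmParams,
        spec: DesignSpec,
        ssf_beta,
    ) -> "ScenarioBundle":
        stack = scenario_stack(base_stack, scenario)
        beta_eff, hmm_eff = scenario_coefficients(
            ssf_beta, spec, hmm_params, scenario
        )
        beta_vec = np.array([beta_eff[t] for t in spec.terms])
        return cls(
            name=scenario.name, stack=stack, scene=scene,
            hmm_params=hmm_eff, design_spec=spec, beta=beta_vec,
        )

    # -- precomputed lookups -------------------------------------------------

    def _hour_values(self, fixes_per_day: int) -> np.ndarray:
        hours = np.arange(fixes_per_day) * 24.0 / fixes_per_day
        return np.cos(2 * np.pi * hours / 24.0)

    def eta_tables(self, fixes_per_day: int):
        """Per-cell endpoint eta grids indexed by (state, hour index), plus
        movement-term coefficient scalars with the same indexing."""
        key = ("eta", fixes_per_day)
        if key in self._cache:
            return self._cache[key]
        beta = pd.Series(self.beta, index=self.design_spec.terms)
        c_hours = self._hour_values(fixes_per_day)
        shape = self.stack.geometry.shape
        eta_grid = np.zeros((2, fixes_per_day) + shape)
        coef_move = np.zeros((2, fixes_per_day, 2))  # (..., [step_km, cos_ta])
        base_cache: dict = self._cache.setdefault("base_rasters", {})
        for s in (SLOW, FAST):
            for h in range(fixes_per_day):
                eta_grid[s, h] = endpoint_eta_grid(
                    beta, self.design_spec, self.stack, self.scene,
                    p_fast=float(s), c_hour=float(c_hours[h]),
                    base_cache=base_cache,
                )
                for mi, mb in enumerate(MOVEMENT_BASES):
                    c = beta.get(mb, 0.0)
                    c += beta.get(f"{mb}:p_fast", 0.0) * s
                    c += beta.get(f"{mb}:c_hour", 0.0) * c_hours[h]
                    coef_move[s, h, mi] = c
        self._cache[key] = (eta_grid, coef_move, c_hours)
        return self._cache[key]

    def transition_covariate_grids(self) -> list:
        """Per-covariate lookup: either ('hour',) for c_hour or a raster."""
        key = "tcov"
        if key in self._cache:
            return self._cache[key]
        grids = []
        for name in self.hmm_params.covariate_names:
            if name == "c_hour":
                grids.append(None)  # computed from the clock
            else:
                grids.append(self.stack.layers[name])
        self._cache[key] = grids
        return grids

    def start_mask(self, p_fast: float = 0.5, c_hour: float = 0.0) -> np.ndarray:
        key = ("start", p_fast, c_hour)
        if key in self._cache:
            return self._cache[key]
        hm = predict_habitat_map(
            pd.Series(self.beta, index=self.design_spec.terms),
            self.design_spec, self.stack, self.scene,
            p_fast=p_fast, c_hour=c_hour,
        )
        mask = hm.top_third & self.stack.availability_mask
        self._cache[key] = mask
        return mask


# ---------------------------------------------------------------------------
# elementary operations (unit-testable; the engine uses the same math
# vectorised across paths)
# ---------------------------------------------------------------------------


def seed_start_points(
    top_mask: np.ndarray,
    geometry,
    n_paths: int,
    seed,
    fixes_per_day: int = 12,
):
    """Uniform start locations among top-third cells (uniform within cell)
    and uniform start hour over the fix times."""
    rng = np.random.default_rng(seed)
    cells = np.flatnonzero(top_mask.ravel())
    if len(cells) == 0:
        raise ValueError("empty start mask")
    pick = cells[rng.integers(len(cells), size=n_paths)]
    rows, cols = np.unravel_index(pick, top_mask.shape)
    cs = geometry.cell_size
    x = geometry.origin_x + (cols + rng.random(n_paths)) * cs
    y = geometry.origin_y + (rows + rng.random(n_paths)) * cs
    hour_idx = rng.integers(fixes_per_day, size=n_paths)
    return np.column_stack([x, y]), hour_idx


def _switch_prob(params: HmmParams, state, x) -> np.ndarray:
    """P(switch out of current state) at covariates x, per path."""
    design = np.concatenate([np.ones(x.shape[:-1] + (1,)), x], axis=-1)
    eta = design @ params.beta.T  # (..., 2)
    return np.take_along_axis(
        expit(eta), np.asarray(state)[..., None], axis=-1
    )[..., 0]


def propose_candidates(
    state, xy, bearing, x_trans, params: HmmParams, rng,
    n: int = 20,
):
    """Draw ``n`` candidate (state, length, angle, endpoint) per path.

    ``state, xy, bearing`` have a leading path axis; states are sampled from
    the transition row of the current state, lengths/angles from the
    corresponding state's gamma / von Mises laws.
    """
    state = np.asarray(state)
    xy = np.atleast_2d(xy)
    m = len(state)
    p_sw = _switch_prob(params, state, np.atleast_2d(x_trans))
    switched = rng.random((m, n)) < p_sw[:, None]
    cand_state = np.where(switched, 1 - state[:, None], state[:, None])
    a, th = (params.mu / params.sigma) ** 2, params.sigma**2 / params.mu
    lengths = rng.gamma(a[cand_state], th[cand_state])
    kappa = np.maximum(params.kappa, 1e-12)  # vonmises requires kappa > 0
    angles = rng.vonmises(params.angle_mean[cand_state], kappa[cand_state])
    new_bearing = np.asarray(bearing)[:, None] + angles
    end = np.empty((m, n, 2))
    end[..., 0] = xy[:, None, 0] + lengths * np.cos(new_bearing)
    end[..., 1] = xy[:, None, 1] + lengths * np.sin(new_bearing)
    return cand_state, lengths, angles, new_bearing, end


def reject_step(start_xy, end_xy, stack: CovariateStack,
                fractions=(0.25, 0.5, 0.75, 1.0)) -> np.ndarray:
    """True where a proposed segment is rejected.

    The availability mask is evaluated at the given fractions along the
    segment (endpoint included, origin excluded as known-available); any
    unavailable or out-of-grid checkpoint rejects the step.
    """
    start = np.atleast_2d(start_xy)
    end = np.asarray(end_xy)
    single = end.ndim == 1
    end = np.atleast_2d(end)
    geom = stack.geometry
    avail = stack.availability_mask
    reject = np.zeros(end.shape[:-1], dtype=bool)
    for f in fractions:
        px = start[..., 0] + f * (end[..., 0] - start[..., 0])
        py = start[..., 1] + f * (end[..., 1] - start[..., 1])
        inb = geom.in_bounds(px, py)
        row, col = geom.clip_rowcol(*geom.rowcol(px, py))
        bad = ~inb | ~avail[row, col]
        reject |= bad
    return reject[0] if single else reject


def select_step(eta: np.ndarray, alive: np.ndarray, rng) -> np.ndarray:
    """Sample one surviving candidate per path with softmax probability.

    Gumbel-max over ``eta`` with rejected candidates at -inf; rows with no
    survivor return -1 ("stuck" signal to the caller).
    """
    eta = np.atleast_2d(eta)
    alive = np.atleast_2d(alive)
    gumbel = rng.gumbel(size=eta.shape)
    score = np.where(alive, eta + gumbel, -np.inf)
    choice = np.argmax(score, axis=1)
    choice[~alive.any(axis=1)] = -1
    return choice


# ---------------------------------------------------------------------------
# the ensemble engine
# ---------------------------------------------------------------------------


def simulate_ensemble(config: SimConfig, bundle: ScenarioBundle,
                      starts=None) -> PathEnsemble:
    """Simulate ``config.n_paths`` paths under one scenario.

    All randomness flows from ``config.seed`` (start seeding and the step
    engine use separate spawned streams); rerunning with the same seed and
    bundle reproduces the ensemble bit-for-bit.
    """
    geom = bundle.stack.geometry
    avail = bundle.stack.availability_mask
    params = bundle.hmm_params
    n, T = config.n_paths, config.steps_per_path
    fpd = config.fixes_per_day

    ss = np.random.SeedSequence(config.seed)
    start_ss, engine_ss = ss.spawn(2)
    rng = np.random.default_rng(engine_ss)

    if starts is None:
        xy0, hidx0 = seed_start_points(
            bundle.start_mask(), geom, n, start_ss, fixes_per_day=fpd
        )
    else:
        xy0, hidx0 = starts

    eta_grid, coef_move, c_hours = bundle.eta_tables(fpd)
    tcov_grids = bundle.transition_covariate_grids()

    def trans_covariates(pos, hidx):
        cols = []
        row, col = geom.clip_rowcol(*geom.rowcol(pos[:, 0], pos[:, 1]))
        for name, grid in zip(params.covariate_names, tcov_grids):
            if grid is None:
                cols.append(c_hours[hidx])
            else:
                cols.append(grid[row, col])
        return np.column_stack(cols)

    xy = np.zeros((n, T + 1, 2))
    states = np.zeros((n, T + 1), dtype=np.int8)
    hour_index = np.zeros((n, T + 1), dtype=np.int16)
    steps_used = np.zeros(n, dtype=np.int64)
    termination = np.zeros(n, dtype=np.int8)

    xy[:, 0] = xy0
    hour_index[:, 0] = hidx0
    # initial state from the stationary distribution at the start covariates
    from movescape.hmm import stationary_probs

    x0 = trans_covariates(xy0, np.asarray(hidx0))
    pi = stationary_probs(params.beta, x0)
    states[:, 0] = (rng.random(n) < pi[:, FAST]).astype(np.int8)
    bearing = rng.uniform(-np.pi, np.pi, n)

    pos = xy0.copy()
    state = states[:, 0].astype(int)
    hidx = np.asarray(hidx0, dtype=int)
    alive = np.ones(n, dtype=bool)
    hold = np.zeros(n, dtype=int)
    outside_cnt = np.zeros(n, dtype=np.int64)
    proposed_cnt = np.zeros(n, dtype=np.int64)

    for t in range(1, T + 1):
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        hidx_next = (hidx + 1) % fpd
        need = idx.copy()
        outside_step = np.zeros(n, dtype=np.int64)
        proposed_step = np.zeros(n, dtype=np.int64)
        for _round in range(config.max_redraws + 1):
            if len(need) == 0:
                break
            xt = trans_covariates(pos[need], hidx_next[need])
            cand_state, lengths, angles, cand_bearing, end = propose_candidates(
                state[need], pos[need], bearing[need], xt, params, rng,
                n=config.n_candidates,
            )
            out = ~geom.in_bounds(end[..., 0], end[..., 1])
            outside_step[need] += out.sum(axis=1)
            proposed_step[need] += config.n_candidates
            rej = reject_step(
                pos[need][:, None, :], end, bundle.stack,
                config.checkpoint_fractions,
            )
            survivors = ~rej
            row, col = geom.clip_rowcol(*geom.rowcol(end[..., 0], end[..., 1]))
            eta = (
                eta_grid[cand_state, hidx_next[need][:, None], row, col]
                + coef_move[cand_state, hidx_next[need][:, None], 0]
                * (lengths / 1000.0)
                + coef_move[cand_state, hidx_next[need][:, None], 1]
                * np.cos(angles)
            )
            choice = select_step(eta, survivors, rng)
            got = choice >= 0
            sel = need[got]
            ch = choice[got]
            ar = np.arange(len(need))[got]
            pos[sel] = end[ar, ch]
            state[sel] = cand_state[ar, ch]
            bearing[sel] = cand_bearing[ar, ch]
            hold[sel] = 0
            need = need[~got]
        if len(need):  # zero survivors after redraws: hold position
            xt = trans_covariates(pos[need], hidx_next[need])
            p_sw = _switch_prob(params, state[need], xt)
            flip = rng.random(len(need)) < p_sw
            state[need] = np.where(flip, 1 - state[need], state[need])
            hold[need] += 1

        hidx = hidx_next
        xy[idx, t] = pos[idx]
        states[idx, t] = state[idx]
        hour_index[idx, t] = hidx[idx]
        steps_used[idx] = t

        outside_cnt += outside_step
        proposed_cnt += proposed_step
        if config.boundary_rule == "cumulative":
            num, den = outside_cnt, proposed_cnt
        else:
            num, den = outside_step, proposed_step
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        boundary_hit = alive & (frac > config.boundary_threshold)
        stuck_hit = alive & (hold > config.max_hold)
        termination[boundary_hit] = 1
        termination[stuck_hit] = 2
        alive &= ~(boundary_hit | stuck_hit)

    return PathEnsemble(
        scenario=bundle.name,
        xy=xy,
        states=states,
        hour_index=hour_index,
        steps_used=steps_used,
        termination=termination,
        config=config,
        seed=config.seed,
    )


def simulate_path(start_xy, config: SimConfig, bundle: ScenarioBundle,
                  start_hour_index: int = 0) -> SimPath:
    """Simulate a single path from a given start (n_paths = 1 engine run)."""
    cfg = SimConfig(
        n_paths=1,
        steps_per_path=config.steps_per_path,
        fixes_per_day=config.fixes_per_day,
        n_candidates=config.n_candidates,
        checkpoint_fractions=config.checkpoint_fractions,
        boundary_threshold=config.boundary_threshold,
        boundary_rule=config.boundary_rule,
        clip_buffer_m=config.clip_buffer_m,
        max_redraws=config.max_redraws,
        max_hold=config.max_hold,
        seed=config.seed,
    )
    starts = (np.atleast_2d(np.asarray(start_xy, dtype=float)),
              np.array([start_hour_index]))
    if not bundle.stack.geometry.in_bounds(*starts[0][0]):
        raise ValueError("start location outside grid")
    ens = simulate_ensemble(cfg, bundle, starts=starts)
    return ens.path(0)
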