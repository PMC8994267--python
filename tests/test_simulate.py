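"""Path simulation: scenario coefficients, candidate machinery, engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, kstest

from movescape.hmm import FAST, SLOW, HmmParams
from movescape.landscape import (
    CovariateStack,
    GridGeometry,
    ScenarioSpec,
    VectorScene,
)
from movescape.simulate import (
    PathEnsemble,
    ScenarioBundle,
    SimConfig,
    propose_candidates,
    reject_step,
    scenario_coefficients,
    seed_start_points,
    select_step,
    simulate_ensemble,
    simulate_path,
)
from movescape.ssf import DesignSpec


def uniform_stack(n=60, cell=1000.0, mask=None):
    geom = GridGeometry(n_rows=n, n_cols=n, cell_size=cell)
    layers = {
        "habitat": np.zeros(geom.shape),
        "town_dist": np.ones(geom.shape),
        "town_prox": np.zeros(geom.shape),
        "trail_density": np.zeros(geom.shape),
    }
    return CovariateStack(
        geometry=geom, layers=layers,
        anthropogenic_names=frozenset({"town_dist", "town_prox",
                                       "trail_density"}),
        availability_mask=mask,
    )


def empty_scene():
    return VectorScene(towns=[], linear_features=[], patches=[], transects=[])


def null_bundle(stack=None, hmm=None, name="current"):
    from movescape.pipeline import default_true_hmm

    stack = stack if stack is not None else uniform_stack()
    hmm = hmm or default_true_hmm()
    spec = DesignSpec(terms=("habitat",))
    return ScenarioBundle(
        name=name, stack=stack, scene=empty_scene(), hmm_params=hmm,
        design_spec=spec, beta=np.zeros(1),
    )


class TestScenarioCoefficients:
    def _inputs(self, design_spec, truth_ssf, truth_hmm):
        beta = pd.Series(truth_ssf)
        return beta, design_spec, truth_hmm

    def test_reference_zeroes_all_anthropogenic_terms(
        self, design_spec, truth_ssf, truth_hmm
    ):
        beta, spec, hmm = self._inputs(design_spec, truth_ssf, truth_hmm)
        ref = ScenarioSpec(name="reference", zero_anthropogenic=True)
        beta_eff, hmm_eff = scenario_coefficients(beta, spec, hmm, ref)
        for term in spec.parsed:
            if term.base in spec.anthropogenic_bases:
                assert beta_eff[term.name] == 0.0, term.name
        # habitat and movement terms untouched
        assert beta_eff["habitat"] == beta["habitat"]
        # anthropogenic transition coefficients zeroed, others kept
        j_town = 1 + hmm.covariate_names.index("town_dist")
        j_trail = 1 + hmm.covariate_names.index("trail_density")
        j_hour = 1 + hmm.covariate_names.index("c_hour")
        assert np.all(hmm_eff.beta[:, [j_town, j_trail]] == 0.0)
        assert np.all(hmm_eff.beta[:, [0, j_hour]] == hmm.beta[:, [0, j_hour]])

    def test_current_is_identity(self, design_spec, truth_ssf, truth_hmm):
        beta, spec, hmm = self._inputs(design_spec, truth_ssf, truth_hmm)
        cur = ScenarioSpec(name="current")
        beta_eff, hmm_eff = scenario_coefficients(beta, spec, hmm, cur)
        assert beta_eff.equals(beta.astype(float))
        assert np.array_equal(hmm_eff.beta, hmm.beta)

    def test_zeroing_idempotent(self, design_spec, truth_ssf, truth_hmm):
        beta, spec, hmm = self._inputs(design_spec, truth_ssf, truth_hmm)
        ref = ScenarioSpec(name="reference", zero_anthropogenic=True)
        b1, h1 = scenario_coefficients(beta, spec, hmm, ref)
        b2, h2 = scenario_coefficients(b1, spec, h1, ref)
        assert b1.equals(b2)
        assert np.array_equal(h1.beta, h2.beta)


class TestSeedStartPoints:
    def test_starts_inside_mask_and_deterministic(self):
        geom = GridGeometry(n_rows=20, n_cols=20, cell_size=100.0)
        rng = np.random.default_rng(0)
        mask = rng.random((20, 20)) < 0.3
        xy, h = seed_start_points(mask, geom, 500, seed=4)
        rows, cols = geom.rowcol(xy[:, 0], xy[:, 1])
        assert mask[rows, cols].all()
        assert np.all((h >= 0) & (h < 12))
        xy2, h2 = seed_start_points(mask, geom, 500, seed=4)
        assert np.array_equal(xy, xy2) and np.array_equal(h, h2)

    def test_empty_mask_errors(self):
        geom = GridGeometry(n_rows=5, n_cols=5)
        with pytest.raises(ValueError, match="empty"):
            seed_start_points(np.zeros((5, 5), bool), geom, 10, seed=0)

    def test_uniform_across_cells(self):
        geom = GridGeometry(n_rows=10, n_cols=10, cell_size=100.0)
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True  # 36 cells
        n = 100_000
        xy, _ = seed_start_points(mask, geom, n, seed=9)
        rows, cols = geom.rowcol(xy[:, 0], xy[:, 1])
        counts = np.bincount(rows * 10 + cols, minlength=100)
        counts = counts[mask.ravel()]
        p = chisquare(counts).pvalue
        assert p > 0.01


class TestProposeCandidates:
    def test_returns_n_candidates_and_switch_fraction(self, truth_hmm):
        rng = np.random.default_rng(1)
        n_paths, n_cand = 5000, 20
        state = np.zeros(n_paths, dtype=int)
        xy = np.zeros((n_paths, 2))
        bearing = np.zeros(n_paths)
        # covariates chosen so the slow->fast switch probability is known
        x = np.tile([0.0, 1.0, 0.0], (n_paths, 1))
        from scipy.special import expit

        p_sw = expit(truth_hmm.beta[0, 0] + truth_hmm.beta[0, 2])
        cs, lengths, angles, nb, end = propose_candidates(
            state, xy, bearing, x, truth_hmm, rng, n=n_cand
        )
        assert cs.shape == (n_paths, n_cand)
        frac_fast = (cs == FAST).mean()
        se = np.sqrt(p_sw * (1 - p_sw) / (n_paths * n_cand))
        assert abs(frac_fast - p_sw) < 3 * se
        assert np.all(lengths > 0)

    def test_high_kappa_concentrates_angles(self):
        p = HmmParams(
            mu=[50, 500], sigma=[50, 400], angle_mean=[0.0, 1.0],
            kappa=[5000.0, 5000.0],
            beta=np.array([[-2.0], [-2.0]]), covariate_names=(),
        )
        rng = np.random.default_rng(2)
        cs, lengths, angles, _, _ = propose_candidates(
            np.array([SLOW]), np.zeros((1, 2)), np.zeros(1),
            np.zeros((1, 0)), p, rng, n=20,
        )
        mean_angle = np.where(cs == SLOW, 0.0, 1.0)
        assert np.allclose(angles, mean_angle, atol=0.1)


class TestRejectStep:
    def _stack_with_wall(self):
        mask = np.ones((60, 60), bool)
        mask[:, 30] = False  # vertical unavailable wall
        return uniform_stack(mask=mask)

    def test_clear_segment_accepted(self):
        stack = self._stack_with_wall()
        assert not reject_step(
            np.array([5000.0, 5000.0]), np.array([8000.0, 9000.0]), stack
        )

    def test_endpoint_in_unavailable_rejected(self):
        stack = self._stack_with_wall()
        assert reject_step(
            np.array([25000.0, 5000.0]), np.array([30500.0, 5000.0]), stack
        )

    def test_midpoint_barrier_rejected(self):
        stack = self._stack_with_wall()
        # endpoints on either side clear of the wall; the 0.5 checkpoint hits
        start = np.array([28000.0, 5000.0])
        end = np.array([33000.0, 5000.0])
        assert reject_step(start, end, stack)

    def test_quarter_points_checked(self):
        stack = self._stack_with_wall()
        start = np.array([29500.0, 5000.0])
        end = np.array([34000.0, 5000.0])  # 0.25 point at 30625 -> wall cell?
        # fraction 0.25 lies at x=30625 (wall column spans 30000-31000)
        assert reject_step(start, end, stack)

    def test_out_of_grid_endpoint_rejected(self):
        stack = uniform_stack()
        assert reject_step(
            np.array([1000.0, 1000.0]), np.array([-500.0, 1000.0]), stack
        )


class TestSelectStep:
    def test_single_survivor_certain(self):
        rng = np.random.default_rng(0)
        eta = np.zeros((1, 20))
        alive = np.zeros((1, 20), bool)
        alive[0, 7] = True
        for _ in range(20):
            assert select_step(eta, alive, rng)[0] == 7

    def test_no_survivor_returns_minus_one(self):
        rng = np.random.default_rng(0)
        assert select_step(np.zeros((1, 5)), np.zeros((1, 5), bool), rng)[0] == -1

    def test_equal_eta_uniform_choice(self):
        rng = np.random.default_rng(3)
        n = 100_000
        eta = np.zeros((n, 20))
        alive = np.ones((n, 20), bool)
        choices = select_step(eta, alive, rng)
        counts = np.bincount(choices, minlength=20)
        assert chisquare(counts).pvalue > 0.01

    def test_softmax_shift_invariance_in_law(self):
        rng1 = np.random.default_rng(7)
        rng2 = np.random.default_rng(7)
        eta = np.random.default_rng(1).normal(size=(1000, 10))
        alive = np.ones((1000, 10), bool)
        a = select_step(eta, alive, rng1)
        b = select_step(eta + 3.7, alive, rng2)
        assert np.array_equal(a, b)


class TestSimulatePath:
    def test_full_availability_completes_720_steps(self):
        bundle = null_bundle()
        cfg = SimConfig(n_paths=1, steps_per_path=720, seed=5)
        path = simulate_path(np.array([30000.0, 30000.0]), cfg, bundle)
        assert path.termination == "completed"
        assert len(path) == 721

    def test_basin_containment(self):
        mask = np.zeros((60, 60), bool)
        mask[20:40, 20:40] = True  # closed available basin
        stack = uniform_stack(mask=mask)
        bundle = null_bundle(stack=stack)
        cfg = SimConfig(n_paths=1, steps_per_path=200, seed=6)
        path = simulate_path(np.array([30000.0, 30000.0]), cfg, bundle)
        rows, cols = stack.geometry.rowcol(path.xy[:, 0], path.xy[:, 1])
        assert mask[rows, cols].all()

    def test_same_seed_bit_identical(self):
        bundle = null_bundle()
        cfg = SimConfig(n_paths=1, steps_per_path=100, seed=8)
        a = simulate_path(np.array([30000.0, 30000.0]), cfg, bundle)
        b = simulate_path(np.array([30000.0, 30000.0]), cfg, bundle)
        assert np.array_equal(a.xy, b.xy)
        assert np.array_equal(a.states, b.states)

    def test_start_outside_grid_errors(self):
        bundle = null_bundle()
        cfg = SimConfig(n_paths=1, steps_per_path=10, seed=0)
        with pytest.raises(ValueError):
            simulate_path(np.array([-100.0, 0.0]), cfg, bundle)


class TestSimulateEnsemble:
    def test_master_seed_reproducibility(self):
        bundle = null_bundle()
        cfg = SimConfig(n_paths=40, steps_per_path=120, seed=11)
        a = simulate_ensemble(cfg, bundle)
        b = simulate_ensemble(cfg, bundle)
        assert np.array_equal(a.xy, b.xy)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.termination, b.termination)

    def test_emissions_match_generating_laws(self, truth_hmm):
        """Null SSF on a uniform available landscape: per-state step lengths
        and turn angles follow the generating gamma / von Mises laws.

        The landscape is large enough that no candidate ever leaves the
        grid (edge rejection would truncate the laws).  Four replicate
        ensembles with consecutive seeds are pooled into one KS sample per
        state so a single unlucky replicate cannot trip the alpha = 0.01
        false-alarm rate."""
        geom = GridGeometry(n_rows=160, n_cols=160, cell_size=1000.0)
        layers = {
            "habitat": np.zeros(geom.shape),
            "town_dist": np.ones(geom.shape),
            "town_prox": np.zeros(geom.shape),
            "trail_density": np.zeros(geom.shape),
        }
        stack = CovariateStack(geometry=geom, layers=layers)
        bundle = null_bundle(stack=stack, hmm=truth_hmm)
        from scipy.stats import gamma as gamma_dist
        from scipy.stats import vonmises as vm_dist

        ln_all, st_all, tn_all, tst_all = [], [], [], []
        for seed in (12, 13, 14, 15):
            cfg = SimConfig(n_paths=20, steps_per_path=1500, seed=seed)
            ens = simulate_ensemble(cfg, bundle, starts=(
                np.full((20, 2), 80000.0), np.zeros(20, dtype=int),
            ))
            # step t runs from location t-1 to t and carries states[:, t]
            d = np.diff(ens.xy, axis=1)
            lengths = np.hypot(d[..., 0], d[..., 1])
            steps_mask = (
                np.arange(1, ens.states.shape[1])[None, :]
                <= ens.steps_used[:, None]
            )
            st_all.append(ens.states[:, 1:][steps_mask])
            ln_all.append(lengths[steps_mask])
            bearings = np.arctan2(d[..., 1], d[..., 0])
            turns = np.diff(bearings, axis=1)
            turn_mask = steps_mask[:, 1:] & steps_mask[:, :-1]
            tst_all.append(ens.states[:, 2:][turn_mask])
            tn_all.append(
                np.arctan2(np.sin(turns), np.cos(turns))[turn_mask]
            )
        st = np.concatenate(st_all)
        ln = np.concatenate(ln_all)
        tst = np.concatenate(tst_all)
        tn = np.concatenate(tn_all)
        for s in (SLOW, FAST):
            a = (truth_hmm.mu[s] / truth_hmm.sigma[s]) ** 2
            scale = truth_hmm.sigma[s] ** 2 / truth_hmm.mu[s]
            sel = ln[st == s]
            assert len(sel) > 10_000
            p = kstest(sel, gamma_dist(a, scale=scale).cdf).pvalue
            assert p > 0.01, f"step lengths, state {s}"
            # centre the angles so the von Mises CDF support (-pi, pi) applies
            delta = tn[tst == s] - truth_hmm.angle_mean[s]
            delta = np.arctan2(np.sin(delta), np.cos(delta))
            pa = kstest(delta, vm_dist(truth_hmm.kappa[s]).cdf).pvalue
            assert pa > 0.01, f"turn angles, state {s}"

    def test_accepted_steps_never_cross_unavailable(self, small_landscape,
                                                    truth_hmm, truth_ssf):
        stack, scene = small_landscape
        spec = DesignSpec.from_coefficients(truth_ssf)
        bundle = ScenarioBundle(
            name="current", stack=stack, scene=scene, hmm_params=truth_hmm,
            design_spec=spec,
            beta=np.array([truth_ssf[t] for t in spec.terms]),
        )
        cfg = SimConfig(n_paths=30, steps_per_path=150, seed=13)
        ens = simulate_ensemble(cfg, bundle)
        geom = stack.geometry
        avail = stack.availability_mask
        for i in range(ens.n_paths):
            n_used = ens.steps_used[i]
            seg = ens.xy[i, : n_used + 1]
            moved = np.hypot(*np.diff(seg, axis=0).T) > 0
            for f in (0.25, 0.5, 0.75, 1.0):
                pts = seg[:-1] + f * np.diff(seg, axis=0)
                rows, cols = geom.rowcol(pts[moved, 0], pts[moved, 1])
                assert avail[rows, cols].all()

    def test_avoidance_reduces_town_zone_occupancy(self):
        # monotone: stronger avoidance of the town zone lowers occupancy
        geom = GridGeometry(n_rows=60, n_cols=60, cell_size=500.0)
        X, Y = geom.cell_centres()
        prox = np.exp(
            -np.hypot(X - 15000, Y - 15000) / 2000.0
        )
        layers = {
            "habitat": np.zeros(geom.shape),
            "town_dist": np.ones(geom.shape),
            "town_prox": prox,
            "trail_density": np.zeros(geom.shape),
        }
        stack = CovariateStack(geometry=geom, layers=layers)
        from movescape.pipeline import default_true_hmm

        occ = []
        for strength in (0.0, -4.0, -8.0):
            spec = DesignSpec(terms=("town_prox",))
            bundle = ScenarioBundle(
                name="x", stack=stack, scene=empty_scene(),
                hmm_params=default_true_hmm(), design_spec=spec,
                beta=np.array([strength]),
            )
            cfg = SimConfig(n_paths=60, steps_per_path=250, seed=14)
            ens = simulate_ensemble(cfg, bundle, starts=(
                np.full((60, 2), 15000.0), np.zeros(60, dtype=int),
            ))
            x, y, _, _ = ens.locations()
            occ.append((np.hypot(x - 15000, y - 15000) < 4000).mean())
        assert occ[0] > occ[1] > occ[2]

    def test_termination_counts_sum(self):
        bundle = null_bundle()
        cfg = SimConfig(n_paths=25, steps_per_path=60, seed=15)
        ens = simulate_ensemble(cfg, bundle)
        assert sum(ens.termination_counts.values()) == 25

    def test_to_dataframe_roundtrip(self):
        bundle = null_bundle()
        cfg = SimConfig(n_paths=5, steps_per_path=30, seed=16)
        ens = simulate_ensemble(cfg, bundle)
        df = ens.to_dataframe()
        assert set(df.columns) >= {"path_id", "step", "x", "y", "state"}
        assert len(df) == (ens.steps_used + 1).sum()


class TestSimConfigValidation:
    def test_bad_candidates(self):
        with pytest.raises(ValueError):
            SimConfig(n_candidates=0)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            SimConfig(boundary_threshold=1.5)

    def test_bad_rule(self):
        with pytest.raises(ValueError):
            SimConfig(boundary_rule="sometimes")
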