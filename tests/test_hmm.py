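"""Two-state movement HMM: step construction, likelihood, decoding, fitting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movescape.hmm import (
    DecaySpec,
    HmmParams,
    MovementHMM,
    StepSeries,
    Track,
    _log_gamma_pdf,
    _log_vonmises_pdf,
    _pack_working,
    _swap_states_working,
    build_steps,
    decay_model_selection,
    forward_loglik,
    smoothed_state_probs,
    stationary_probs,
    transition_matrix,
    wrap_angle,
)

from conftest import simulate_hmm_series


def brute_force_loglik(series: StepSeries, p: HmmParams) -> float:
    """Exhaustive enumeration over all 2^T state sequences."""
    T = len(series)
    Gam = transition_matrix(p.beta, series.X)
    delta = stationary_probs(p.beta, series.X[0])
    total = 0.0
    for seq in itertools.product([0, 1], repeat=T):
        lp = np.log(delta[seq[0]])
        for t, s in enumerate(seq):
            lp += _log_gamma_pdf(series.lengths[t], p.mu[s], p.sigma[s])
            if not np.isnan(series.angles[t]):
                lp += _log_vonmises_pdf(
                    series.angles[t], p.angle_mean[s], p.kappa[s]
                )
            if t > 0:
                lp += np.log(Gam[t, seq[t - 1], s])
        total += np.exp(lp)
    return float(np.log(total))


@st.composite
def angles_strategy(draw):
    return draw(st.floats(-50.0, 50.0, allow_nan=False))


class TestWrapAngle:
    @given(theta=st.floats(-50, 50), k=st.integers(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_range_and_periodicity(self, theta, k):
        w = wrap_angle(theta)
        assert -np.pi < w <= np.pi
        assert np.isclose(
            float(wrap_angle(theta + 2 * np.pi * k)), float(w), atol=1e-9
        )


def make_track(xs, ys, start="2021-07-01T00:00:00", interval_h=2.0):
    n = len(xs)
    t0 = np.datetime64(start)
    ts = t0 + np.arange(n) * np.timedelta64(int(interval_h * 3600), "s")
    return Track(animal_id="w1", timestamps=ts, x=np.asarray(xs, float),
                 y=np.asarray(ys, float))


class TestBuildSteps:
    def test_collinear_gives_zero_turn(self, small_landscape):
        stack, _ = small_landscape
        yc = stack.geometry.height / 2
        track = make_track([1000, 2000, 3000, 4000], [yc] * 4)
        s = build_steps(track, stack)
        assert np.isnan(s.angles[0])
        assert np.allclose(s.angles[1:], 0.0)

    def test_c_hour_convention_midnight_one_noon_minus_one(
        self, small_landscape
    ):
        stack, _ = small_landscape
        yc = stack.geometry.height / 2
        track = make_track(
            [1000 + 100 * i for i in range(13)], [yc] * 13,
            start="2021-07-01T00:00:00",
        )
        s = build_steps(track, stack)
        ch = s.c_hour
        assert ch[0] == pytest.approx(1.0)  # midnight
        assert ch[6] == pytest.approx(-1.0)  # noon

    def test_reversal_wraps_to_pi(self, small_landscape):
        stack, _ = small_landscape
        yc = stack.geometry.height / 2
        track = make_track([1000, 2000, 1000, 2000], [yc] * 4)
        s = build_steps(track, stack)
        assert np.allclose(np.abs(s.angles[1:]), np.pi)
        assert np.all(s.angles[1:] > 0)  # wrapped into (-pi, pi]

    def test_gap_splits_segments(self, small_landscape):
        stack, _ = small_landscape
        yc = stack.geometry.height / 2
        t0 = np.datetime64("2021-07-01T00:00:00")
        hours = np.array([0, 2, 4, 12, 14, 16])  # 8-h gap in the middle
        ts = t0 + (hours * 3600).astype("timedelta64[s]")
        track = Track(
            animal_id="w1", timestamps=ts,
            x=1000.0 + 100 * np.arange(6), y=np.full(6, yc),
        )
        s = build_steps(track, stack)
        assert len(np.unique(s.segment_id)) == 2
        # first step of each segment has no turn angle
        for seg in np.unique(s.segment_id):
            first = np.flatnonzero(s.segment_id == seg)[0]
            assert np.isnan(s.angles[first])

    def test_out_of_grid_fixes_dropped(self, small_landscape):
        stack, _ = small_landscape
        yc = stack.geometry.height / 2
        xs = [1000, 2000, -9e6, 3000, 4000]
        track = make_track(xs, [yc] * 5)
        s = build_steps(track, stack)
        assert s.n_dropped == 1

    def test_zero_length_floored(self, small_landscape):
        stack, _ = small_landscape
        yc = stack.geometry.height / 2
        track = make_track([1000, 1000, 1000], [yc] * 3)
        s = build_steps(track, stack)
        assert np.all(s.lengths >= 1.0)


class TestTransitionMatrix:
    def test_zero_coefficients_give_half(self):
        G = transition_matrix(np.zeros((2, 3)), np.zeros(2))
        assert np.allclose(G, 0.5)

    def test_intercept_minus_two(self):
        G = transition_matrix(np.array([[-2.0], [-2.0]]), np.zeros(0))
        assert G[0, 1] == pytest.approx(0.11920, abs=1e-5)
        assert G[1, 0] == pytest.approx(0.11920, abs=1e-5)

    def test_town_effect_direction(self):
        # wolf-style coefficient: switching to fast becomes more likely as
        # distance to town decreases (logit rises by 0.98 per unit decrease)
        beta = np.array([[-1.0, -0.98], [-1.0, 0.0]])
        eta_near = -1.0 - 0.98 * 0.0
        eta_far = -1.0 - 0.98 * 1.0
        G_near = transition_matrix(beta, np.array([0.0]))
        G_far = transition_matrix(beta, np.array([1.0]))
        assert np.log(G_near[0, 1] / G_near[0, 0]) == pytest.approx(eta_near)
        assert np.log(G_far[0, 1] / G_far[0, 0]) == pytest.approx(eta_far)
        assert G_near[0, 1] > G_far[0, 1]

    @given(
        b=st.lists(st.floats(-3, 3), min_size=6, max_size=6),
        x=st.lists(st.floats(-2, 2), min_size=2, max_size=2),
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one_entries_open_interval(self, b, x):
        G = transition_matrix(np.array(b).reshape(2, 3), np.array(x))
        assert np.allclose(G.sum(axis=-1), 1.0)
        assert np.all((G > 0) & (G < 1))

    def test_nonfinite_covariates_error(self):
        with pytest.raises(ValueError):
            transition_matrix(np.zeros((2, 2)), np.array([np.nan]))


class TestForwardLoglik:
    def test_matches_enumeration(self, truth_hmm):
        for i, T in enumerate([1, 2, 4, 6, 8]):
            s = simulate_hmm_series(truth_hmm, T, seed=100 + i)
            assert forward_loglik(s, truth_hmm) == pytest.approx(
                brute_force_loglik(s, truth_hmm), abs=1e-10
            )

    def test_single_step_with_symmetric_stationary(self):
        # equal intercepts give stationary delta = (1/2, 1/2), so the T=1
        # likelihood is log(0.5 f_slow + 0.5 f_fast)
        p = HmmParams(
            mu=[50, 500], sigma=[50, 400], angle_mean=[0, 0], kappa=[1, 1],
            beta=np.array([[-1.0], [-1.0]]), covariate_names=(),
        )
        s = simulate_hmm_series(
            HmmParams(mu=[50, 500], sigma=[50, 400], angle_mean=[0, 0],
                      kappa=[1, 1],
                      beta=np.array([[-1.0, 0], [-1.0, 0]]),
                      covariate_names=("c_hour",)),
            1, seed=3,
        )
        l = s.lengths[0]
        f = [np.exp(_log_gamma_pdf(l, p.mu[i], p.sigma[i])) for i in (0, 1)]
        expected = np.log(0.5 * f[0] + 0.5 * f[1])
        s2 = StepSeries(
            animal_id="a", lengths=s.lengths, angles=s.angles,
            X=np.zeros((1, 0)), covariate_names=(), hour=s.hour,
            segment_id=s.segment_id, x0=s.x0, y0=s.y0, x1=s.x1, y1=s.y1,
            bearing=s.bearing,
        )
        assert forward_loglik(s2, p) == pytest.approx(expected, abs=1e-12)

    def test_kappa_zero_contributes_uniform_angle_density(self, truth_hmm):
        p0 = HmmParams(
            mu=truth_hmm.mu, sigma=truth_hmm.sigma,
            angle_mean=truth_hmm.angle_mean, kappa=[0.0, 0.0],
            beta=truth_hmm.beta, covariate_names=truth_hmm.covariate_names,
        )
        s = simulate_hmm_series(truth_hmm, 30, seed=11)
        no_angles = StepSeries(
            animal_id="a", lengths=s.lengths,
            angles=np.full(len(s), np.nan), X=s.X,
            covariate_names=s.covariate_names, hour=s.hour,
            segment_id=s.segment_id, x0=s.x0, y0=s.y0, x1=s.x1, y1=s.y1,
            bearing=s.bearing,
        )
        n_angles = np.sum(~np.isnan(s.angles))
        diff = forward_loglik(s, p0) - forward_loglik(no_angles, p0)
        assert diff == pytest.approx(n_angles * np.log(1 / (2 * np.pi)),
                                     abs=1e-9)

    def test_track_order_invariance(self, truth_hmm):
        a = simulate_hmm_series(truth_hmm, 50, seed=1)
        b = simulate_hmm_series(truth_hmm, 70, seed=2)
        assert forward_loglik([a, b], truth_hmm) == pytest.approx(
            forward_loglik([b, a], truth_hmm), abs=1e-9
        )

    def test_label_swap_symmetry(self, truth_hmm):
        s = simulate_hmm_series(truth_hmm, 60, seed=4)
        model = MovementHMM(s)
        w = _pack_working(truth_hmm)
        w_swapped = _swap_states_working(w, model.k)
        assert model.loglike(w) == pytest.approx(
            model.loglike(w_swapped), abs=1e-9
        )


class TestStationaryProbs:
    def test_closed_form_two_thirds(self):
        # g_sf = 0.2, g_fs = 0.1 -> pi_fast = 2/3
        from scipy.special import logit

        beta = np.array([[logit(0.2)], [logit(0.1)]])
        pi = stationary_probs(beta, np.zeros(0))
        assert pi[1] == pytest.approx(2 / 3, abs=1e-12)

    def test_symmetric_rates_give_half(self):
        beta = np.array([[-1.3], [-1.3]])
        pi = stationary_probs(beta, np.zeros(0))
        assert np.allclose(pi, 0.5)

    @given(b=st.lists(st.floats(-4, 4), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_fixed_point_equation(self, b):
        beta = np.array(b).reshape(2, 2)
        x = np.array([0.7])
        pi = stationary_probs(beta, x)
        G = transition_matrix(beta, x)
        assert np.linalg.norm(pi @ G - pi) < 1e-12


class TestSmoothedStateProbs:
    def test_probabilities_complement(self, truth_hmm):
        series = [simulate_hmm_series(truth_hmm, 200, seed=i) for i in (1, 2)]
        fit = MovementHMM(series).fit(inits=truth_hmm, n_restarts=1,
                                      compute_cov=False)
        p = fit.smoothed_state_probs()
        assert p.shape == (400,)
        assert np.all((p >= 0) & (p <= 1))

    def test_separated_states_recover_labels(self):
        # disjoint length supports: decoding must match the true labels
        p = HmmParams(
            mu=[10.0, 5000.0], sigma=[2.0, 100.0], angle_mean=[0, 0],
            kappa=[0.5, 0.5],
            beta=np.array([[-1.0, 0.2], [-1.0, -0.2]]),
            covariate_names=("c_hour",),
        )
        s, states = simulate_hmm_series(p, 300, seed=8, return_states=True)
        probs = smoothed_state_probs(
            s, MovementHMM(s).fit(inits=p, n_restarts=1, compute_cov=False)
        )
        assert np.array_equal(probs > 0.5, states.astype(bool))

    def test_uninformative_emissions_give_stationary(self):
        p = HmmParams(
            mu=[100.0, 100.0 + 1e-9], sigma=[50.0, 50.0],
            angle_mean=[0, 0], kappa=[1.0, 1.0],
            beta=np.array([[-1.0], [-0.5]]), covariate_names=(),
        )
        r = np.random.default_rng(0)
        T = 50
        s = StepSeries(
            animal_id="a", lengths=r.gamma(4, 25, T),
            angles=np.concatenate([[np.nan], r.vonmises(0, 1, T - 1)]),
            X=np.zeros((T, 0)), covariate_names=(),
            hour=np.zeros(T), segment_id=np.zeros(T, int),
            x0=np.zeros(T), y0=np.zeros(T), x1=np.zeros(T), y1=np.zeros(T),
            bearing=np.zeros(T),
        )
        from movescape.hmm import MovementHMMResults, _Packed

        model = MovementHMM(s)
        res = MovementHMMResults(
            model=model, params=p, working=_pack_working(p),
            cov_working=None, llf=0.0, converged=True, n_obs=T,
        )
        probs = res.smoothed_state_probs()
        pi_fast = stationary_probs(p.beta, np.zeros(0))[1]
        assert np.allclose(probs, pi_fast, atol=1e-6)


class TestFit:
    def test_quick_recovery_and_ordering(self, truth_hmm):
        series = [simulate_hmm_series(truth_hmm, 500, seed=i) for i in range(4)]
        res = MovementHMM(series).fit(seed=0, n_restarts=4, n_polish=1)
        assert res.converged
        assert res.params.mu[1] > res.params.mu[0]
        assert res.params.mu == pytest.approx(truth_hmm.mu, rel=0.15)
        assert res.params.sigma == pytest.approx(truth_hmm.sigma, rel=0.25)

    def test_aic_bookkeeping(self, truth_hmm):
        s = simulate_hmm_series(truth_hmm, 100, seed=1)
        res = MovementHMM(s).fit(inits=truth_hmm, n_restarts=1,
                                 compute_cov=False)
        assert res.n_free == 8 + truth_hmm.beta.size
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.n_free)

    def test_summary_renders(self, truth_hmm):
        s = simulate_hmm_series(truth_hmm, 120, seed=2)
        res = MovementHMM(s).fit(inits=truth_hmm, n_restarts=1)
        text = res.summary()
        assert "Transition coefficients" in text
        assert "AIC" in text


class TestDecayRecovery:
    def test_true_decay_form_wins_by_aic(self):
        """Data generated with a strong capped-linear 5 km town effect:
        the model using the generating decay transform beats a mis-specified
        exponential 1 km transform by AIC in >= 8 of 10 datasets."""
        from movescape.hmm import DecaySpec

        true_spec = DecaySpec("capped_linear", 5000.0)
        wrong_spec = DecaySpec("exp_decay", 1000.0)
        wins = 0
        for rep in range(10):
            r = np.random.default_rng(400 + rep)
            T = 1500
            d_m = r.uniform(0.0, 8000.0, T)  # distance to town per step
            hours = (np.arange(T) * 2) % 24
            base = HmmParams(
                mu=[50, 500], sigma=[50, 400], angle_mean=[np.pi, 0.0],
                kappa=[0.5, 2.0],
                beta=np.array([[-1.0, -2.5], [-1.5, 2.5]]),  # strong effect
                covariate_names=("town_dist",),
            )

            def series_with(spec):
                X = spec.transform(d_m)[:, None]
                return X

            X_true = series_with(true_spec)
            Gam = transition_matrix(base.beta, X_true)
            s = np.zeros(T, dtype=int)
            s[0] = r.random() < stationary_probs(base.beta, X_true[0])[1]
            for t in range(1, T):
                s[t] = r.random() < Gam[t, s[t - 1], 1]
            a = (base.mu / base.sigma) ** 2
            th = base.sigma**2 / base.mu
            lengths = np.maximum(r.gamma(a[s], th[s]), 1.0)
            angles = r.vonmises(base.angle_mean[s], base.kappa[s])
            angles[0] = np.nan

            aics = {}
            for name, spec in (("true", true_spec), ("wrong", wrong_spec)):
                X = series_with(spec)
                ser = StepSeries(
                    animal_id="a", lengths=lengths, angles=angles, X=X,
                    covariate_names=("town_dist",),
                    hour=hours.astype(float),
                    segment_id=np.zeros(T, dtype=int),
                    x0=np.zeros(T), y0=np.zeros(T), x1=np.zeros(T),
                    y1=np.zeros(T), bearing=np.zeros(T),
                )
                res = MovementHMM(ser).fit(seed=rep, n_restarts=2,
                                           n_polish=1, compute_cov=False)
                aics[name] = res.aic
            wins += aics["true"] < aics["wrong"]
        assert wins >= 8, wins


class TestDecaySelection:
    def test_single_candidate_zero_delta(self, small_landscape, truth_hmm,
                                         truth_ssf):
        from movescape.io import read_tracks
        from movescape.landscape import generate_labelled_tracks

        stack, scene = small_landscape
        df = generate_labelled_tracks(
            stack, scene, truth_hmm, truth_ssf, n_animals=3, n_steps=120,
            seed=3,
        )
        import io as _io

        buf = _io.StringIO()
        df.drop(columns="true_state").to_csv(buf, index=False)
        buf.seek(0)
        tracks = read_tracks(buf)
        best, table = decay_model_selection(
            tracks, stack, [DecaySpec("capped_linear", 5000.0)],
            fit_kwargs={"n_restarts": 2, "n_polish": 1, "seed": 0},
        )
        assert best.name == "capped_linear_5000"
        assert table["delta_aic"].iloc[0] == 0.0

    def test_duplicate_specs_identical_aic(self, small_landscape, truth_hmm,
                                           truth_ssf):
        from movescape.io import read_tracks
        from movescape.landscape import generate_labelled_tracks

        stack, scene = small_landscape
        df = generate_labelled_tracks(
            stack, scene, truth_hmm, truth_ssf, n_animals=3, n_steps=120,
            seed=3,
        )
        import io as _io

        buf = _io.StringIO()
        df.drop(columns="true_state").to_csv(buf, index=False)
        buf.seek(0)
        tracks = read_tracks(buf)
        specs = [DecaySpec("exp_decay", 1000.0), DecaySpec("exp_decay", 1000.0)]
        _, table = decay_model_selection(
            tracks, stack, specs,
            fit_kwargs={"n_restarts": 2, "n_polish": 1, "seed": 0},
        )
        assert table["aic"].nunique() == 1
        assert np.all(table["delta_aic"] == 0.0)
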