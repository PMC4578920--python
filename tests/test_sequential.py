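"""Serial-order copying: arrival-time law, vertex windows, error taxonomy."""

import numpy as np
import pytest
from scipy import stats

from desirmix.optimal_control import (
    ConfigurationError,
    DynamicsSpec,
    EffectorState,
    GoalSpec,
)
from desirmix.policy_mixer import TrialRecord
from desirmix.sequential import (
    ArrivalModel,
    NonArrivalError,
    ShapeSpec,
    chain_arrival_times,
    classify_copy_error,
    copy_trial_config,
    estimate_arrival_model,
    regular_polygon,
    run_copy_trial,
    segment_error_counts,
    vertex_probability,
    _segment_controller,
)


@pytest.fixture(scope="module")
def pentagon():
    return regular_polygon(5, radius=6.0)


@pytest.fixture(scope="module")
def pentagon_arrival_model(pentagon):
    dyn = DynamicsSpec(process_noise_sd=50.0)
    wp = pentagon.waypoints()
    eps = 0.06 * pentagon.mean_segment_length()  # completion tolerance (2 eps)
    ctrl = _segment_controller(dyn, wp[0], GoalSpec(position=wp[1], label="v1"))
    fitted = estimate_arrival_model(
        ctrl, 100, np.random.default_rng(0),
        start=EffectorState(wp[0], np.zeros(2)), arrival_radius=eps,
        min_sigma_frac=0.25,
    )
    return ArrivalModel(mu_tau=0.85 * fitted.mu_tau, sigma_tau=fitted.sigma_tau)


class TestShapeSpec:
    def test_regular_polygon_geometry(self, pentagon):
        assert pentagon.n_segments == 5
        w = pentagon.waypoints()
        assert len(w) == 6
        assert np.allclose(w[0], w[-1])
        lengths = np.linalg.norm(np.diff(w, axis=0), axis=1)
        assert np.allclose(lengths, lengths[0])

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ConfigurationError):
            ShapeSpec(vertices=np.array([[0.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ConfigurationError):
            ShapeSpec(
                vertices=np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
            )

    def test_clockwise_reverses_order(self):
        ccw = regular_polygon(4, direction="counterclockwise")
        cw = regular_polygon(4, direction="clockwise")
        assert np.allclose(ccw.waypoints()[1], cw.waypoints()[::-1][1])


class TestEstimateArrivalModel:
    def test_zero_noise_is_deterministic(self, pentagon):
        dyn = DynamicsSpec(process_noise_sd=0.0)
        wp = pentagon.waypoints()
        ctrl = _segment_controller(dyn, wp[0], GoalSpec(position=wp[1], label="v1"))
        model = estimate_arrival_model(
            ctrl, 10, np.random.default_rng(0),
            start=EffectorState(wp[0], np.zeros(2)),
        )
        assert model.sigma_tau == pytest.approx(0.0, abs=1e-12)
        assert model.mu_tau > 0

    def test_unreachable_segment_raises(self, pentagon):
        dyn = DynamicsSpec(process_noise_sd=0.0)
        wp = pentagon.waypoints()
        ctrl = _segment_controller(dyn, wp[0], GoalSpec(position=wp[1], label="v1"))
        with pytest.raises(NonArrivalError):
            estimate_arrival_model(
                ctrl, 5, np.random.default_rng(0),
                start=EffectorState(wp[0], np.zeros(2)),
                arrival_radius=1e-9,
            )

    def test_arrival_times_pass_normality_check(self, pentagon):
        """At moderate motor noise the sampled traversal times are
        consistent with a Normal law in at least 9 of 10 seeded replicates."""
        dyn = DynamicsSpec(process_noise_sd=50.0)
        n_pass = 0
        for rep in range(10):
            times = chain_arrival_times(
                pentagon, dyn, n_reps=50, rng=np.random.default_rng(300 + rep)
            )[:, 0]
            if stats.shapiro(times).pvalue > 0.01:
                n_pass += 1
        assert n_pass >= 9


class TestVertexProbability:
    def test_fresh_segment_points_at_next_vertex(self):
        model = ArrivalModel(mu_tau=0.3, sigma_tau=0.03)
        assert vertex_probability(1, 0.0, model, completed=0) == pytest.approx(
            1.0, abs=1e-4
        )
        assert vertex_probability(2, 0.0, model, completed=0) == pytest.approx(
            0.0, abs=1e-4
        )

    def test_window_hands_over_at_mean_arrival(self):
        model = ArrivalModel(mu_tau=0.3, sigma_tau=0.03)
        # at the mean arrival time the current window is half passed
        assert vertex_probability(1, 0.3, model, 0) == pytest.approx(0.5, abs=1e-9)

    def test_invalid_index_rejected(self):
        model = ArrivalModel(mu_tau=0.3, sigma_tau=0.03)
        with pytest.raises(ValueError):
            vertex_probability(2, 0.1, model, completed=2)

    def test_matches_monte_carlo_sum_of_segment_times(self):
        """The composed window probabilities agree with a direct Monte-Carlo
        of summed per-segment Normal traversal times on a time grid."""
        model = ArrivalModel(mu_tau=0.3, sigma_tau=0.05)
        rng = np.random.default_rng(5)
        n = 100_000
        seg_times = rng.normal(model.mu_tau, model.sigma_tau, size=(n, 3))
        arrivals = np.cumsum(seg_times, axis=1)
        for t in (0.3, 0.5, 0.65, 0.9):
            for j in (2, 3):
                mc = np.mean((arrivals[:, j - 1] > t) & (arrivals[:, j - 2] <= t))
                se = max(np.sqrt(mc * (1 - mc) / n), 1e-5)
                analytic = vertex_probability(j, t, model, completed=0)
                assert abs(analytic - mc) < 4 * se


class TestChainArrivalLaw:
    def test_vertex_j_moments_compose_linearly(self, pentagon):
        """Arrival time at vertex j has j times the single-segment mean and
        variance, within Monte-Carlo error."""
        dyn = DynamicsSpec(process_noise_sd=50.0)
        arr = chain_arrival_times(pentagon, dyn, n_reps=100,
                                  rng=np.random.default_rng(3))
        seg1 = arr[:, 0]
        mu, var = seg1.mean(), seg1.var(ddof=1)
        n = len(seg1)
        for j in range(2, 6):
            tj = arr[:, j - 1]
            se_mean = np.sqrt(j * var / n)
            se_var = j * var * np.sqrt(2.0 / (n - 1))
            assert abs(tj.mean() - j * mu) < 3 * se_mean
            assert abs(tj.var(ddof=1) - j * var) < 3 * se_var


class TestRunCopyTrial:
    def test_low_noise_copies_in_order(self, pentagon):
        cfg = copy_trial_config(process_noise_sd=5.0)
        rec = run_copy_trial(pentagon, cfg, np.random.default_rng(0))
        assert rec.visit_order == [1, 2, 3, 4, 5]
        assert rec.error_class in ("none", "corner_rounding")

    def test_weight_traces_hand_off_in_order(self, pentagon, pentagon_arrival_model):
        """Each segment's weight peaks during its own execution and the next
        segment's weight is already rising before the current completes."""
        cfg = copy_trial_config()
        rec = None
        for seed in range(10):
            cand = run_copy_trial(pentagon, cfg, np.random.default_rng(seed),
                                  arrival_model=pentagon_arrival_model)
            if cand.visit_order == [1, 2, 3, 4, 5]:
                rec = cand
                break
        assert rec is not None
        w = rec.weights_per_step
        peaks = [int(np.argmax(w[:, j])) for j in range(5)]
        assert peaks == sorted(peaks)  # ordered hand-offs
        # completion steps bracket each segment's peak
        pos = np.array([s.position for s in rec.states])
        wp = pentagon.waypoints()
        eps_c = 0.06 * pentagon.mean_segment_length()
        completions = []
        prev = 0
        for j in rec.visit_order:
            d = np.linalg.norm(pos - wp[j], axis=1)
            idx = np.where(d[prev + 1:] <= eps_c)[0][0] + prev + 1
            completions.append(idx)
            prev = idx
        starts = [0] + completions[:-1]
        for j in range(5):
            assert starts[j] <= peaks[j] <= completions[j] + 1
        # anticipation: while the current segment is still being drawn, the
        # following segment's weight is already substantial and exceeds the
        # weight of the segment after it
        for j in range(3):
            window = slice(max(completions[j] - 8, starts[j]), completions[j])
            next_w = w[window, j + 1].mean()
            later_w = w[window, j + 2].mean()
            assert next_w > 0.01
            assert next_w > later_w

    def test_timeout_produces_partial_record(self, pentagon):
        cfg = copy_trial_config(process_noise_sd=50.0)
        rec = run_copy_trial(
            pentagon, cfg, np.random.default_rng(1), max_duration_factor=0.2
        )
        assert rec.error_class == "timeout"
        assert len(rec.visit_order) < 5


class TestClassifyCopyError:
    def _record(self, pentagon, positions, visit_order):
        states = [
            EffectorState(np.asarray(p, float), np.zeros(2), i)
            for i, p in enumerate(positions)
        ]
        return TrialRecord(
            states=states,
            weights_per_step=np.ones((len(states) - 1, 5)) / 5.0,
            controls=np.zeros((len(states) - 1, 2)),
            endpoint=states[-1].position,
            selected_goal="v5",
            initial_heading=0.0,
            goal_labels=tuple(f"v{j}" for j in range(1, 6)),
            visit_order=visit_order,
        )

    def test_clean_in_order_visitation_is_error_free(self, pentagon):
        wp = pentagon.waypoints()
        rec = self._record(pentagon, list(wp), [1, 2, 3, 4, 5])
        assert classify_copy_error(rec, pentagon) == "none"

    def test_out_of_order_is_transposition(self, pentagon):
        wp = pentagon.waypoints()
        path = [wp[0], wp[2], wp[1], wp[3], wp[4], wp[5]]
        rec = self._record(pentagon, path, [2, 1, 3, 4, 5])
        assert classify_copy_error(rec, pentagon) == "transposition"

    def test_near_miss_within_tolerance_is_corner_rounding(self, pentagon):
        wp = pentagon.waypoints()
        eps = 0.03 * pentagon.mean_segment_length()
        # pass vertex 2 at 1.5 eps, all others exactly
        offset = wp[2] + np.array([1.5 * eps, 0.0])
        path = [wp[0], wp[1], offset, wp[3], wp[4], wp[5]]
        rec = self._record(pentagon, path, [1, 2, 3, 4, 5])
        assert classify_copy_error(rec, pentagon) == "corner_rounding"


def test_segment_error_attribution_charges_drawn_segment(pentagon):
    rec_states = [EffectorState(np.zeros(2), np.zeros(2), 0)]
    rec = TrialRecord(
        states=rec_states * 2,
        weights_per_step=np.ones((1, 5)) / 5.0,
        controls=np.zeros((1, 2)),
        endpoint=np.zeros(2),
        selected_goal="v5",
        initial_heading=0.0,
        goal_labels=tuple(f"v{j}" for j in range(1, 6)),
        visit_order=[2, 1, 3, 4, 5],  # captured by v2 while drawing segment 1
    )
    counts = segment_error_counts([rec], pentagon)
    assert counts[0] >= 1  # the interrupted segment is charged
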