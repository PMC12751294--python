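"""Dynamical analysis: equilibria, limit cycles, periodicity, perturbation
protocols, strategy census, robustness lattice."""

import math

import numpy as np
import pytest

from saltpursuit import RunConfig, TaskConfig
from saltpursuit.dynamics import (PerturbationRecord, classify_periodicity,
                                  classify_strategy, detect_limit_cycle,
                                  find_equilibria, perturb_nonperiodic,
                                  perturb_periodic, robustness_lattice,
                                  robustness_map, strategy_report)
from saltpursuit.examples import cruiser_params, periodic_sampler_params
from saltpursuit.network import NetworkParams

from _grid_oracle import grid_roots_1d, grid_roots_2d, stability_label


def net_1n(a=0.0, theta=0.0, tau=1.0, b=0.0):
    return NetworkParams(tau=[tau], theta=[theta], w_syn=[[a]],
                         w_sens=[[b, 0.0]])


def net_2n(W, theta, tau=(1.0, 1.0), b=None):
    b = np.zeros((2, 2)) if b is None else b
    return NetworkParams(tau=list(tau), theta=list(theta), w_syn=W,
                         w_sens=b)


def listener_params():
    """Intrinsic cruiser whose motors are strongly inhibited by signal."""
    theta = np.zeros(5)
    theta[:2] = -5.0
    w_sens = np.zeros((5, 2))
    w_sens[0] = w_sens[1] = -20.0
    return NetworkParams(tau=np.ones(5), theta=theta,
                         w_syn=np.zeros((5, 5)), w_sens=w_sens)


def chaser_params():
    """Near-stationary forager whose motors are strongly excited by
    signal."""
    theta = np.zeros(5)
    theta[:2] = 5.0
    w_sens = np.zeros((5, 2))
    w_sens[0] = w_sens[1] = 20.0
    return NetworkParams(tau=np.ones(5), theta=theta,
                         w_syn=np.zeros((5, 5)), w_sens=w_sens)


def suppressed_block_task(reliable=False):
    """Task whose perturbation signal block rounds to zero steps: the
    'perturbed' run is its own null."""
    return TaskConfig(signal_reliable=reliable, signal_fraction=1e-9)


class TestFindEquilibria:
    def test_lone_decaying_neuron_has_origin_fixed_point(self):
        eq = find_equilibria(net_1n())
        assert len(eq.points) == 1
        assert eq.points[0].x[0] == pytest.approx(0.0, abs=1e-10)
        assert eq.points[0].stability == "stable"

    def test_self_excitatory_neuron_is_bistable(self):
        """a=10, theta=5: two stable points separated by a repeller,
        matching a 1-D sign-change scan of -x + 10*sigma(x, 5).  (In one
        dimension the middle point is an unstable node; a saddle proper
        needs eigenvalues of both signs.)"""
        eq = find_equilibria(net_1n(a=10.0, theta=5.0))
        oracle = grid_roots_1d(10.0, 5.0, 0.0)
        assert len(eq.points) == len(oracle) == 3
        found = sorted(p.x[0] for p in eq.points)
        np.testing.assert_allclose(found, oracle, atol=1e-6)
        labels = [p.stability for p in
                  sorted(eq.points, key=lambda p: p.x[0])]
        assert labels == ["stable", "unstable", "stable"]

    def test_text_export_lists_points_and_labels(self):
        eq = find_equilibria(net_1n(a=10.0, theta=5.0))
        text = eq.to_text()
        assert text.count("point [") == 3
        assert "stable" in text and "unstable" in text

    def test_residuals_below_tolerance(self, rng):
        net = NetworkParams(tau=rng.uniform(0.5, 16, 5),
                            theta=rng.uniform(-8, 8, 5),
                            w_syn=rng.uniform(-8, 8, (5, 5)),
                            w_sens=rng.uniform(-20, 20, (5, 2)))
        eq = find_equilibria(net, input_level=(1.0, 1.0))
        assert len(eq.points) >= 1  # compact sigmoids guarantee one
        assert all(p.residual < 1e-8 for p in eq.points)

    def test_matches_grid_oracle_on_random_two_neuron_systems(self):
        """Spot-check against the dense-grid bracketing oracle (the full
        200-system sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            W = rng.uniform(-16, 16, (2, 2))
            theta = rng.uniform(-16, 16, 2)
            tau = rng.uniform(0.5, 16, 2)
            net = net_2n(W, theta, tau)
            eq = find_equilibria(net)
            oracle = grid_roots_2d(W, theta, np.zeros(2))
            assert len(eq.points) == len(oracle)
            found = np.array(sorted([tuple(p.x) for p in eq.points]))
            np.testing.assert_allclose(found, oracle, atol=1e-4)


class TestLimitCycle:
    def test_no_cycle_for_pure_decay(self):
        assert detect_limit_cycle(cruiser_params()) is None

    def test_oscillator_period_is_stationary(self):
        """The hand-built oscillator's period estimate is stable: doubling
        the integration window moves it by far less than 1%."""
        net = periodic_sampler_params()
        a = detect_limit_cycle(net, window=800.0)
        b = detect_limit_cycle(net, window=1600.0)
        assert a is not None and b is not None
        assert abs(a.period - b.period) / a.period < 0.01
        assert a.motor_orbit.min() < 0.1 and a.motor_orbit.max() > 0.9

    def test_cycle_survives_different_start_states(self, rng):
        net = periodic_sampler_params()
        periods = [detect_limit_cycle(net, x0=rng.uniform(0, 1, 5)).period
                   for _ in range(3)]
        assert np.ptp(periods) / np.mean(periods) < 0.01


class TestClassifyPeriodicity:
    def test_sampler_is_periodic_cruiser_is_not(self, ud_config):
        rng = np.random.default_rng(3)
        assert classify_periodicity(periodic_sampler_params(),
                                    ud_config.task, ud_config.body,
                                    rng) == "periodic"
        assert classify_periodicity(cruiser_params(), ud_config.task,
                                    ud_config.body, rng) == "nonperiodic"

    def test_labels_invariant_to_rng_stream(self, ud_config):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            assert classify_periodicity(periodic_sampler_params(),
                                        ud_config.task, ud_config.body,
                                        rng) == "periodic"

    def test_steady_rest_is_nonperiodic(self, ud_config):
        rest = NetworkParams(tau=np.ones(5), theta=np.full(5, 16.0),
                             w_syn=np.zeros((5, 5)),
                             w_sens=np.zeros((5, 2)))
        rng = np.random.default_rng(0)
        assert classify_periodicity(rest, ud_config.task, ud_config.body,
                                    rng) == "nonperiodic"


class TestPerturbNonperiodic:
    def test_listener_decelerates(self, rng):
        cfg = RunConfig.for_condition("UI")
        for dist in (5.0, 21.0):
            rec = perturb_nonperiodic(listener_params(), cfg.task,
                                      cfg.body, dist, 0.0, rng)
            assert rec.response_sign == "listening"
            assert rec.delta_distance < 0

    def test_chaser_accelerates(self, rng):
        cfg = RunConfig.for_condition("UI")
        rec = perturb_nonperiodic(chaser_params(), cfg.task, cfg.body,
                                  13.0, 0.0, rng)
        assert rec.response_sign == "chasing"
        assert rec.delta_distance > 0

    def test_suppressed_block_gives_exact_zero_deltas(self, rng):
        task = suppressed_block_task()
        cfg = RunConfig.for_condition("UI", task=task)
        rec = perturb_nonperiodic(listener_params(), cfg.task, cfg.body,
                                  13.0, 0.0, rng)
        assert rec.response_sign == "null"
        assert rec.delta_distance == 0.0
        assert rec.response_duration == 0.0


class TestPerturbPeriodic:
    def test_suppressed_block_gives_exact_zero_deltas(self, rng):
        task = suppressed_block_task()
        cfg = RunConfig.for_condition("UD", task=task)
        rec = perturb_periodic(periodic_sampler_params(), cfg.task,
                               cfg.body, 13.0, 0.0, rng)
        assert rec.delta_distance == 0.0
        assert rec.delta_period == 0.0
        assert rec.delta_sample_time == 0.0
        assert rec.response_sign == "null"

    def test_never_sampling_agent_reroutes(self, rng):
        cfg = RunConfig.for_condition("UD")
        assert perturb_periodic(cruiser_params(), cfg.task, cfg.body,
                                13.0, 0.0, rng) is None

    def test_sampler_fixture_produces_signed_records(self, rng):
        """The sampler has no sensor weights, so signal cannot move it:
        every delta must be exactly zero (a negative-control)."""
        cfg = RunConfig.for_condition("RD")
        rec = perturb_periodic(periodic_sampler_params(), cfg.task,
                               cfg.body, 13.0, 0.0, rng)
        assert rec.mode == "periodic"
        assert rec.response_sign == "null"


class TestClassifyStrategy:
    def _rec(self, sign):
        return PerturbationRecord(10.0, 0.0, "nonperiodic", sign, 0.0)

    @pytest.mark.parametrize("signs, expected", [
        (["listening"] * 20, "listening"),
        (["chasing"] * 20, "chasing"),
        (["listening"] * 12 + ["chasing"] * 8, "mixed"),   # 60/40
        (["null"] * 10, "insensitive"),
        (["listening"] * 19 + ["chasing"], "listening"),   # 95% exactly
        (["listening"] * 18 + ["chasing"] * 2, "mixed"),   # 90%
        (["listening"] * 5 + ["null"] * 15, "listening"),  # nulls excluded
    ])
    def test_purity_threshold(self, signs, expected):
        assert classify_strategy([self._rec(s) for s in signs]) == expected


class TestStrategyReport:
    def test_chaser_report(self, rng):
        cfg = RunConfig.for_condition("UI")
        rep = strategy_report(chaser_params(), cfg.task, cfg.body, rng,
                              distances=(9.0, 17.0),
                              bearings=[0.0, 0.5], n_init=3)
        assert rep.periodicity == "nonperiodic"
        assert rep.label == "chasing"
        assert len(rep.grid) == 4
        assert rep.baseline["mean_velocity"] < 0.1

    def test_listener_report(self, rng):
        cfg = RunConfig.for_condition("UI")
        rep = strategy_report(listener_params(), cfg.task, cfg.body, rng,
                              distances=(9.0, 17.0),
                              bearings=[0.0, 0.5], n_init=3)
        assert rep.periodicity == "nonperiodic"
        assert rep.label == "listening"
        # cruise baseline near the velocity ceiling
        assert rep.baseline["mean_velocity"] > 3.0


class TestRobustness:
    def test_lattice_counts(self):
        pts = robustness_lattice()
        assert pts.shape == (5400, 2)
        r = pts[:, 0]
        assert np.all((r > 0) & (r < 29.0))
        in_band = (r >= 23.0) & (r <= 27.0)
        assert in_band.sum() == 900
        assert (~in_band).sum() == 4500

    def test_stationary_agent_scores_zero_everywhere_outside_lambda(self,
                                                                    rng):
        cfg = RunConfig.for_condition("RI")
        rest = NetworkParams(tau=np.ones(5), theta=np.full(5, 16.0),
                             w_syn=np.zeros((5, 5)),
                             w_sens=np.zeros((5, 2)))
        lattice = np.array([[5.0, 0.0], [15.0, 1.0], [25.0, 2.0]])
        grid, summary = robustness_map(rest, cfg.task, cfg.body, rng,
                                       lattice=lattice, n_headings=2)
        assert np.allclose(grid[:, 2], 0.0, atol=1e-3)
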