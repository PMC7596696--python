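"""Tests of the representative quantities, cost function, adjoint gradient
and the inverse driver on small networks."""

import numpy as np
import pytest

from vasoadapt.forward import ForwardSimulator, LinearNetworkSystem, TimeAveragedField
from vasoadapt.inverse import (
    ActivationTarget,
    activated_average,
    adjoint_gradient,
    cost,
    dTtilde_dalpha,
    representative_transmissibility,
    representative_viscosity,
    run_inverse,
    update_alpha,
)
from vasoadapt.rheology import RheologyParams

from conftest import make_network

MU_P = RheologyParams().mu_p


def _field(network, q, p, t=None):
    return TimeAveragedField(
        flow=np.asarray(q, dtype=float),
        pressure=np.asarray(p, dtype=float),
        source=np.zeros(network.n_nodes),
        transmissibility=(
            np.asarray(t, dtype=float) if t is not None else np.ones(network.n_edges)
        ),
        n_steps=3,
        dt=0.4,
    )


def _target(network, act_ids, baseline_q, multiplier=1.3):
    baseline = _field(network, baseline_q, np.zeros(network.n_nodes))
    return ActivationTarget.from_baseline(network, act_ids, baseline, multiplier)


class TestRepresentativeTransmissibility:
    def test_steady_plasma_recovers_instantaneous(self, mesh_network):
        sim = ForwardSimulator(mesh_network, plasma_only=True)
        avg = sim.run_window(5)
        t_rep = representative_transmissibility(avg, mesh_network)
        np.testing.assert_allclose(t_rep, avg.transmissibility, rtol=1e-12)

    def test_hand_built_three_step_series(self, single_edge_network):
        # q = [1,2,3], dp = [1,2,3] per step: <q>/<dp> = 2/2 = 1
        avg = _field(single_edge_network, [2.0], [2.0, 0.0], t=[99.0])
        t_rep = representative_transmissibility(avg, single_edge_network)
        assert t_rep[0] == pytest.approx(1.0)

    def test_zero_pressure_drop_falls_back(self, single_edge_network):
        avg = _field(single_edge_network, [0.0], [0.0, 0.0], t=[7.0])
        t_rep = representative_transmissibility(avg, single_edge_network)
        assert t_rep[0] == 7.0  # window-mean fallback, no division by zero

    def test_counter_gradient_flow_falls_back(self, single_edge_network):
        # averaged flow against the averaged pressure gradient is a noise
        # artefact; the regularization must keep T~ positive
        avg = _field(single_edge_network, [-1.0], [5.0, 0.0], t=[3.0])
        t_rep = representative_transmissibility(avg, single_edge_network)
        assert t_rep[0] == 3.0


class TestRepresentativeViscosity:
    def test_plasma_steady_state_unity(self, mesh_network):
        sim = ForwardSimulator(mesh_network, plasma_only=True)
        avg = sim.run_window(3)
        t_rep = representative_transmissibility(avg, mesh_network)
        mu = representative_viscosity(t_rep, mesh_network, np.ones(mesh_network.n_edges), MU_P)
        np.testing.assert_allclose(mu, 1.0, rtol=1e-12)

    def test_product_identity(self, mesh_network):
        rng = np.random.default_rng(0)
        t_rep = rng.uniform(0.5, 5.0, mesh_network.n_edges)
        alpha = rng.uniform(0.9, 1.1, mesh_network.n_edges)
        mu = representative_viscosity(t_rep, mesh_network, alpha, MU_P)
        d = alpha * mesh_network.diameter
        np.testing.assert_allclose(
            mu * t_rep, np.pi * d**4 / (128.0 * mesh_network.length * MU_P), rtol=1e-12
        )

    def test_biphasic_viscosity_at_least_one_on_perfused_edges(self, hex_network):
        sim = ForwardSimulator(hex_network, rng=np.random.default_rng(2))
        sim.seed_haematocrit(0.3)
        for _ in range(200):
            sim.step()
        avg = sim.run_window(300)
        t_rep = representative_transmissibility(avg, hex_network)
        mu = representative_viscosity(t_rep, hex_network, np.ones(hex_network.n_edges), MU_P)
        scale = np.ptp(hex_network.pressure[hex_network.fixed_pressure_nodes])
        i, j = hex_network.edge_nodes[:, 0], hex_network.edge_nodes[:, 1]
        perfused = np.abs(avg.pressure[i] - avg.pressure[j]) > 1e-4 * scale
        assert np.all(mu[perfused] >= 1.0 - 1e-9)


class TestActivatedAverage:
    def test_constant_flow(self):
        net = make_network([[0, 1], [1, 2]], 3, {0: 10.0, 2: 0.0})
        tgt = _target(net, [0, 1], [3.0, 3.0])
        assert activated_average(np.array([3.0, 3.0]), tgt) == pytest.approx(3.0)

    def test_hand_weighted_mean(self):
        net = make_network(
            [[0, 1], [1, 2]], 3, {0: 10.0, 2: 0.0},
            lengths=np.array([75.0, 150.0]),
        )
        tgt = _target(net, [0, 1], [1.0, 4.0])
        # (75*1 + 150*4) / 225 = 3
        assert activated_average(np.array([1.0, 4.0]), tgt) == pytest.approx(3.0)

    def test_orientation_flip_invariance(self):
        net_a = make_network([[0, 1], [1, 2]], 3, {0: 10.0, 2: 0.0})
        net_b = make_network([[1, 0], [1, 2]], 3, {0: 10.0, 2: 0.0})
        tgt_a = _target(net_a, [0, 1], [2.0, 5.0])
        tgt_b = _target(net_b, [0, 1], [-2.0, 5.0])
        assert activated_average(np.array([2.0, 5.0]), tgt_a) == pytest.approx(
            activated_average(np.array([-2.0, 5.0]), tgt_b)
        )


class TestCost:
    def test_zero_at_target_and_rho_min(self):
        net = make_network([[0, 1], [1, 2], [1, 3]], 4, {0: 10.0, 2: 0.0, 3: 0.0})
        tgt = _target(net, [0], [4.0, 2.0, 2.0], multiplier=1.0)
        j, t1, t2, rho = cost(np.array([4.0, 2.0, 2.0]), tgt, epsilon=1.0, rho_min=0.0)
        assert j == 0.0 and t1 == 0.0 and t2 == 0.0 and rho == 0.0

    def test_ten_percent_overshoot(self):
        net = make_network([[0, 1], [1, 2]], 3, {0: 10.0, 2: 0.0})
        tgt = _target(net, [0], [1.0, 1.0], multiplier=1.0)
        j, *_ = cost(np.array([1.1, 1.0]), tgt, epsilon=0.0)
        assert j == pytest.approx(0.01, rel=1e-12)

    def test_rho_is_euclidean_norm(self):
        net = make_network([[0, 1], [1, 2], [1, 3]], 4, {0: 10.0, 2: 0.0, 3: 0.0})
        tgt = _target(net, [0], [2.0, 1.0, 1.0], multiplier=1.0)
        # two non-activated edges changed by +q_tar and -q_tar
        q = np.array([2.0, 1.0 + tgt.q_tar, 1.0 - tgt.q_tar])
        _, _, _, rho = cost(q, tgt, epsilon=1.0, rho_min=0.0)
        assert rho == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_zero_target_rejected(self):
        net = make_network([[0, 1], [1, 2]], 3, {0: 10.0, 2: 0.0})
        tgt = _target(net, [0], [1.0, 1.0])
        tgt.q_tar = 0.0
        with pytest.raises(ValueError):
            cost(np.array([1.0, 1.0]), tgt)


class TestTransmissibilityDerivative:
    def test_baseline_value(self, single_edge_network):
        net = single_edge_network
        dtda = dTtilde_dalpha(net, np.ones(1), np.ones(1), MU_P)
        t0 = np.pi * net.diameter**4 / (128.0 * net.length * MU_P)
        assert dtda[0] == pytest.approx(4.0 * t0[0], rel=1e-12)

    def test_ratio_identity(self, mesh_network):
        rng = np.random.default_rng(1)
        alpha = rng.uniform(0.85, 1.15, mesh_network.n_edges)
        mu = rng.uniform(1.0, 3.0, mesh_network.n_edges)
        t_rep = representative_viscosity(
            np.ones(mesh_network.n_edges), mesh_network, alpha, MU_P
        )  # reuse identity: mu~ for T~=1
        dtda = dTtilde_dalpha(mesh_network, alpha, mu, MU_P)
        t_tilde = np.pi * (alpha * mesh_network.diameter) ** 4 / (
            128.0 * mesh_network.length * MU_P * mu
        )
        np.testing.assert_allclose(dtda / t_tilde, 4.0 / alpha, rtol=1e-12)

    def test_matches_finite_difference_plasma(self, single_edge_network):
        net = single_edge_network

        def t_of_alpha(a):
            return np.pi * (a * net.diameter[0]) ** 4 / (128.0 * net.length[0] * MU_P)

        a0, h = 1.07, 1e-6
        fd = (t_of_alpha(a0 + h) - t_of_alpha(a0 - h)) / (2 * h)
        dtda = dTtilde_dalpha(net, np.array([a0]), np.ones(1), MU_P)
        assert dtda[0] == pytest.approx(fd, rel=1e-6)


class TestAdjointGradient:
    @staticmethod
    def _averaged_cost(network, system, alpha, mu_rep, target, eps, rho_min):
        """Independent oracle: re-solve the averaged linear system for the
        perturbed diameters with the representative viscosity frozen."""
        d = alpha * network.diameter
        t = np.pi * d**4 / (128.0 * network.length * MU_P * mu_rep)
        p = system.solve_pressure(t)
        q = t * (p[network.edge_nodes[:, 0]] - p[network.edge_nodes[:, 1]])
        return cost(q, target, eps, rho_min)[0], q, p, t

    @pytest.mark.parametrize("eps,rho_min", [(0.0, 0.0), (1.0, 0.02)])
    def test_matches_finite_differences(self, mesh_network, eps, rho_min):
        net = mesh_network
        system = LinearNetworkSystem(net)
        rng = np.random.default_rng(7)
        mu_rep = rng.uniform(1.0, 3.0, net.n_edges)
        # baseline at alpha = 1 defines the activation target
        d = net.diameter
        t_base = np.pi * d**4 / (128.0 * net.length * MU_P * mu_rep)
        p_base = system.solve_pressure(t_base)
        q_base = t_base * (p_base[net.edge_nodes[:, 0]] - p_base[net.edge_nodes[:, 1]])
        baseline = TimeAveragedField(
            flow=q_base, pressure=p_base, source=np.zeros(net.n_nodes),
            transmissibility=t_base, n_steps=1, dt=0.4,
        )
        target = ActivationTarget.from_baseline(net, [3, 8], baseline, 1.3)

        alpha = rng.uniform(0.9, 1.1, net.n_edges)
        j0, q, p, t = self._averaged_cost(net, system, alpha, mu_rep, target, eps, rho_min)
        dtda = dTtilde_dalpha(net, alpha, mu_rep, MU_P)
        grad = adjoint_gradient(system, p, q, t, dtda, target, eps, rho_min)

        h = 1e-6
        for e in range(net.n_edges):
            ap, am = alpha.copy(), alpha.copy()
            ap[e] += h
            am[e] -= h
            jp = self._averaged_cost(net, system, ap, mu_rep, target, eps, rho_min)[0]
            jm = self._averaged_cost(net, system, am, mu_rep, target, eps, rho_min)[0]
            fd = (jp - jm) / (2 * h)
            assert grad[e] == pytest.approx(fd, rel=1e-5, abs=1e-10 * abs(grad).max())

    def test_zero_gradient_at_target(self, mesh_network):
        net = mesh_network
        system = LinearNetworkSystem(net)
        sim = ForwardSimulator(net, plasma_only=True)
        fs = sim.solve()
        baseline = TimeAveragedField(
            flow=fs.flow, pressure=fs.pressure, source=fs.source,
            transmissibility=fs.transmissibility, n_steps=1, dt=0.4,
        )
        target = ActivationTarget.from_baseline(net, [3, 8], baseline, 1.0)
        dtda = dTtilde_dalpha(net, np.ones(net.n_edges), np.ones(net.n_edges), MU_P)
        grad = adjoint_gradient(
            system, fs.pressure, fs.flow, fs.transmissibility, dtda, target, 0.0, 0.0
        )
        np.testing.assert_allclose(grad, 0.0, atol=1e-14)

    def test_single_edge_closed_form(self, single_edge_network):
        # dJ/dalpha = 2 (q/q_tar - 1) (dp / q_tar) * 4 T / alpha for one
        # vessel between two fixed-pressure nodes (plasma, eps = 0)
        net = single_edge_network
        system = LinearNetworkSystem(net)
        sim = ForwardSimulator(net, plasma_only=True)
        fs = sim.solve()
        baseline = TimeAveragedField(
            flow=fs.flow, pressure=fs.pressure, source=fs.source,
            transmissibility=fs.transmissibility, n_steps=1, dt=0.4,
        )
        target = ActivationTarget.from_baseline(net, [0], baseline, 1.3)
        dtda = dTtilde_dalpha(net, np.ones(1), np.ones(1), MU_P)
        grad = adjoint_gradient(
            system, fs.pressure, fs.flow, fs.transmissibility, dtda, target, 0.0, 0.0
        )
        q, t = fs.flow[0], fs.transmissibility[0]
        dp = 100.0
        expected = 2.0 * (q / target.q_tar - 1.0) * (dp / target.q_tar) * 4.0 * t
        assert grad[0] == pytest.approx(expected, rel=1e-12)


class TestUpdateAlpha:
    def test_zero_gradient_fixed_point(self):
        alpha = np.array([1.0, 1.05])
        new = update_alpha(alpha, np.zeros(2), 0.1, np.array([True, True]))
        np.testing.assert_array_equal(new, alpha)

    def test_clipping_to_bounds(self):
        alpha = np.array([1.14])
        new = update_alpha(
            alpha, np.array([-1.0]), 0.06, np.array([True]), bounds=(0.85, 1.15)
        )
        assert new[0] == pytest.approx(1.15)

    def test_step_linear_in_gamma(self):
        alpha = np.ones(3)
        g = np.array([1.0, -2.0, 0.5])
        mask = np.ones(3, dtype=bool)
        d1 = update_alpha(alpha, g, 0.01, mask) - alpha
        d2 = update_alpha(alpha, g, 0.005, mask) - alpha
        np.testing.assert_allclose(d1, 2 * d2, rtol=1e-12)

    def test_non_adaptable_untouched(self):
        alpha = np.array([1.0, 1.0])
        new = update_alpha(alpha, np.array([1.0, 1.0]), 0.1, np.array([True, False]))
        assert new[1] == 1.0 and new[0] != 1.0


class TestDriver:
    def test_single_vessel_fourth_root_law(self, single_edge_network):
        # plasma flow scales with alpha^4, so a 1.3x flow target is met at
        # alpha = 1.3**0.25
        res = run_inverse(
            single_edge_network, [0], plasma_only=True, target_multiplier=1.3,
            n_avg=1, n_warmup=0, tol=1e-10, epsilon=0.0, gamma=0.01,
            max_iter_phase1=5000, n_final=1, rng=np.random.default_rng(0),
        )
        assert res.converged_phase1
        assert res.alpha[0] == pytest.approx(1.3**0.25, rel=1e-3)

    def test_filtered_cost_nonincreasing_plasma(self, hex_network, hex_activated):
        res = run_inverse(
            hex_network, hex_activated, plasma_only=True, target_multiplier=1.3,
            n_avg=1, n_warmup=0, tol=1e-6, epsilon=0.0, gamma=0.005,
            max_iter_phase1=2000, n_final=1, rng=np.random.default_rng(0),
        )
        assert res.converged_phase1
        j = res.history["J"].to_numpy()
        # deterministic limit: the raw cost decreases monotonically
        assert np.all(np.diff(j) <= 1e-14)

    def test_non_adaptable_edges_never_change(self, hex_network, hex_activated):
        adaptable = np.zeros(hex_network.n_edges, dtype=bool)
        adaptable[hex_network.edge_indices(hex_activated)] = True
        res = run_inverse(
            hex_network, hex_activated, plasma_only=True, target_multiplier=1.1,
            adaptable=adaptable, n_avg=1, n_warmup=0, tol=1e-6, epsilon=0.0,
            gamma=0.005, max_iter_phase1=2000, n_final=1,
            rng=np.random.default_rng(0),
        )
        assert res.converged_phase1
        assert np.all(res.alpha[~adaptable] == 1.0)

    def test_infeasible_rho_min_reverts(self, single_edge_network):
        # a second phase that demands rho below feasibility must fall back
        # to the last feasible value instead of diverging
        net = make_network(
            [[0, 1], [1, 2], [1, 3]], 4, {0: 100.0, 2: 0.0, 3: 0.0}
        )
        res = run_inverse(
            net, [1], plasma_only=True, target_multiplier=1.3, n_avg=1,
            n_warmup=0, tol=1e-8, epsilon=1.0, gamma=0.01, rho_reduction=0.01,
            max_iter_phase1=3000, max_iter_per_level=100, max_levels=2,
            n_final=1, rng=np.random.default_rng(0),
        )
        assert res.converged_phase1
        assert res.rho_min_final is not None
        # target still met after the revert
        assert res.qbar_final == pytest.approx(res.target.q_tar, rel=2e-2)
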