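"""Bundled behaviours: LIF, synaptic input, refractory, plasticity, NOX, Izhikevich."""
import numpy as np
import pytest

import behavnet as bn
from behavnet import Network, NeuronGroup, SynapseGroup
from behavnet.behaviours import (LIF, STDP, ForcedSpikes, IntrinsicPlasticity,
                                 Izhikevich, NormalizeAfferent, NOXHomeostasis,
                                 Refractory, SynapticInput, grid_laplacian)


def lif_net(size=4, seed=0, **lif_kwargs):
    net = Network(seed=seed)
    ng = NeuronGroup(net, size)
    ng.add_behaviour(1, LIF(**lif_kwargs))
    return net, ng


class TestLIF:
    def test_noise_free_decay_matches_closed_form(self):
        net, ng = lif_net(noise_amplitude=0.0, v_init=0.4, leak_factor=0.9,
                          threshold=0.5)
        net.initialize()
        for n in (1, 10, 100):
            net.simulate_iterations(n)
        total = 111
        np.testing.assert_allclose(ng.voltage, 0.4 * 0.9 ** total, rtol=1e-12)
        assert not ng.spike.any()

    def test_suprathreshold_start_spikes_then_resets(self):
        # v0=0.6, leak 0.9 -> 0.54 > 0.5: spike at step 1, voltage reset to 0
        net, ng = lif_net(noise_amplitude=0.0, v_init=0.6, leak_factor=0.9,
                          threshold=0.5)
        net.initialize()
        net.simulate_iterations(1)
        assert ng.spike.all()
        np.testing.assert_array_equal(ng.voltage, 0.0)
        net.simulate_iterations(1)
        assert not ng.spike.any()

    def test_per_neuron_leak_diversification(self):
        net, ng = lif_net(size=2, noise_amplitude=0.0, v_init=1.0, threshold=2.0,
                          leak_factor=lambda rng, size: np.array([0.8, 0.95]))
        net.initialize()
        net.simulate_iterations(20)
        np.testing.assert_allclose(ng.voltage, [0.8 ** 20, 0.95 ** 20], rtol=1e-12)

    def test_leak_outside_unit_interval_warns(self):
        net, ng = lif_net(leak_factor=1.5)
        with pytest.warns(UserWarning, match="leak_factor"):
            net.initialize()

    def test_diversified_threshold_is_registered_per_neuron(self):
        net, ng = lif_net(size=1000, threshold="normal(0.5,0.05)")
        net.initialize()
        assert ng.threshold.std() > 0.01


class TestSynapticInput:
    @staticmethod
    def _driven_pair(W, src_train, strength=0.1):
        """dst group with forced source spikes and an explicit weight matrix."""
        W = np.asarray(W, dtype=float)
        net = Network(seed=0)
        src = NeuronGroup(net, W.shape[1])
        dst = NeuronGroup(net, W.shape[0])
        sg = SynapseGroup(net, src, dst)
        src.add_behaviour(1, ForcedSpikes(train=src_train))
        dst.add_behaviour(2, SynapticInput(strength=strength))
        net.initialize()
        dst.new_state_vector("voltage", 0.0)
        sg.register_matrix("W", W)
        return net, dst

    def test_dot_product_by_hand(self):
        net, dst = self._driven_pair([[1.0, 1.0, 1.0]], [[1, 0, 1]])
        net.simulate_iterations(1)
        np.testing.assert_allclose(dst.voltage, [0.2])

    def test_no_source_spikes_leaves_voltage_unchanged(self):
        net, dst = self._driven_pair([[1.0, 1.0]], [[0, 0]])
        net.simulate_iterations(1)
        np.testing.assert_array_equal(dst.voltage, [0.0])

    def test_two_afferent_groups_contributions_sum(self):
        net = Network(seed=0)
        a = NeuronGroup(net, 2)
        b = NeuronGroup(net, 2)
        dst = NeuronGroup(net, 1)
        sga = SynapseGroup(net, a, dst)
        sgb = SynapseGroup(net, b, dst)
        a.add_behaviour(1, ForcedSpikes(train=[[1, 1]]))
        b.add_behaviour(1, ForcedSpikes(train=[[1, 0]]))
        dst.add_behaviour(2, SynapticInput(strength=1.0))
        net.initialize()
        dst.new_state_vector("voltage", 0.0)
        sga.register_matrix("W", [[0.5, 0.25]])
        sgb.register_matrix("W", [[2.0, 99.0]])
        net.simulate_iterations(1)
        np.testing.assert_allclose(dst.voltage, [0.5 + 0.25 + 2.0])

    def test_missing_matrix_rejected_naming_group(self):
        net = Network(seed=0)
        src = NeuronGroup(net, 2)
        dst = NeuronGroup(net, 2)
        SynapseGroup(net, src, dst, tag="broken_projection")
        src.add_behaviour(1, ForcedSpikes(train=[[1, 1]]))
        beh = SynapticInput()
        beh.init_params["weight_init"] = None   # suppress auto-creation
        dst.add_behaviour(2, beh)
        net.initialize()
        net.synapse_groups[0].matrices.clear()
        dst.new_state_vector("voltage", 0.0)
        with pytest.raises(bn.NetworkError, match="broken_projection"):
            net.simulate_iterations(1)


class TestRefractory:
    @staticmethod
    def _driven(refractory_steps, steps=9):
        net = Network(seed=0)
        ng = NeuronGroup(net, 1)

        class Drive(bn.Behaviour):
            """Constant suprathreshold drive applied before the model step."""

            def set_variables(self, neurons):
                neurons.new_state_vector("voltage", 0.0)

            def new_iteration(self, neurons):
                neurons.voltage = neurons.voltage + 1.0

        ng.add_behaviour(0.5, Drive())
        ng.add_behaviour(1, LIF(noise_amplitude=0.0, threshold=0.5))
        if refractory_steps is not None:
            ng.add_behaviour(2, Refractory(refractory_steps=refractory_steps))
        ng.add_behaviour(9, bn.Recorder("n.spike"))
        net.initialize()
        net.simulate_iterations(steps)
        return net["n.spike"][0].np[:, 0]

    def test_zero_steps_is_bitwise_identity(self):
        np.testing.assert_array_equal(self._driven(0), self._driven(None))

    def test_period_three_pattern_under_constant_drive(self):
        # spike, then exactly two forced-silent steps, repeating
        spikes = self._driven(2)
        np.testing.assert_array_equal(spikes.astype(int), [1, 0, 0] * 3)

    def test_negative_steps_rejected(self):
        net = Network(seed=0)
        ng = NeuronGroup(net, 1)
        ng.add_behaviour(1, LIF())
        ng.add_behaviour(2, Refractory(refractory_steps=-1))
        with pytest.raises(bn.NetworkError, match="refractory"):
            net.initialize()


def stdp_run(src_train, dst_train, eta=0.01, w0=0.5, steps=None):
    """Recurrent-free forced-spike STDP run; returns (W_after - w0) masked."""
    src_train = np.atleast_2d(np.asarray(src_train))
    dst_train = np.atleast_2d(np.asarray(dst_train))
    net = Network(seed=0)
    src = NeuronGroup(net, src_train.shape[1])
    dst = NeuronGroup(net, dst_train.shape[1])
    sg = SynapseGroup(net, src, dst)
    src.add_behaviour(1, ForcedSpikes(train=src_train))
    dst.add_behaviour(2, ForcedSpikes(train=dst_train))
    sg.add_behaviour(3, STDP(eta_stdp=eta, w_min=0.0, w_max=1.0))
    net.initialize()
    sg.register_matrix("W", np.full((dst.size, src.size), w0))
    net.simulate_iterations(steps or len(src_train))
    return sg.matrices["W"] - w0


class TestSTDP:
    def test_pre_before_post_potentiates_by_eta(self):
        dW = stdp_run(src_train=[[1], [0]], dst_train=[[0], [1]])
        np.testing.assert_allclose(dW, [[0.01]])

    def test_post_before_pre_depresses_by_eta(self):
        dW = stdp_run(src_train=[[0], [1]], dst_train=[[1], [0]])
        np.testing.assert_allclose(dW, [[-0.01]])

    def test_no_spikes_no_change(self):
        dW = stdp_run(src_train=np.zeros((5, 3)), dst_train=np.zeros((5, 2)))
        np.testing.assert_array_equal(dW, 0.0)

    def test_swapping_trains_transposes_and_negates_dw(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 3)) < 0.5
        b = rng.random((6, 3)) < 0.5
        dW_ab = stdp_run(a, b)
        dW_ba = stdp_run(b, a)
        np.testing.assert_allclose(dW_ba, -dW_ab.T)

    def test_structural_zeros_stay_zero(self):
        src_train = [[1], [0], [1], [0]]
        dst_train = [[0], [1], [0], [1]]
        net = Network(seed=0)
        src = NeuronGroup(net, 1)
        dst = NeuronGroup(net, 1)
        sg = SynapseGroup(net, src, dst)
        src.add_behaviour(1, ForcedSpikes(train=src_train))
        dst.add_behaviour(2, ForcedSpikes(train=dst_train))
        sg.add_behaviour(3, STDP(eta_stdp=0.01))
        net.initialize()
        sg.register_matrix("W", np.zeros((1, 1)))   # structurally absent
        net.simulate_iterations(4)
        np.testing.assert_array_equal(sg.matrices["W"], 0.0)

    def test_weights_clipped_to_bounds(self):
        dW = stdp_run(src_train=[[1], [0]] * 40, dst_train=[[0], [1]] * 40,
                      eta=0.1, w0=0.9)
        assert (dW + 0.9 <= 1.0 + 1e-15).all()


class TestNormalizeAfferent:
    @staticmethod
    def _normed(rows_a, rows_b=None, target=1.0):
        net = Network(seed=0)
        src = NeuronGroup(net, len(rows_a[0]))
        dst = NeuronGroup(net, len(rows_a))
        sga = SynapseGroup(net, src, dst)
        sgb = SynapseGroup(net, src, dst) if rows_b is not None else None
        dst.add_behaviour(1, NormalizeAfferent(norm_target=target))
        net.initialize()
        sga.register_matrix("W", np.asarray(rows_a, dtype=float))
        if sgb is not None:
            sgb.register_matrix("W", np.asarray(rows_b, dtype=float))
        net.simulate_iterations(1)
        return sga, sgb

    def test_already_normalized_row_unchanged(self):
        sga, _ = self._normed([[0.2, 0.6, 0.2]])
        np.testing.assert_allclose(sga.matrices["W"], [[0.2, 0.6, 0.2]])

    def test_row_rescaled_to_target(self):
        sga, _ = self._normed([[1.0, 1.0]])
        np.testing.assert_allclose(sga.matrices["W"], [[0.5, 0.5]])

    def test_cross_group_joint_sum_semantics(self):
        # group sums 0.3 and 0.7 already total 1: joint scaling leaves both alone
        sga, sgb = self._normed([[0.3, 0.0]], [[0.0, 0.7]])
        np.testing.assert_allclose(sga.matrices["W"], [[0.3, 0.0]])
        np.testing.assert_allclose(sgb.matrices["W"], [[0.0, 0.7]])
        # and unequal totals rescale jointly, preserving proportions
        sga, sgb = self._normed([[1.0, 0.0]], [[0.0, 3.0]])
        np.testing.assert_allclose(sga.matrices["W"], [[0.25, 0.0]])
        np.testing.assert_allclose(sgb.matrices["W"], [[0.0, 0.75]])

    def test_zero_rows_left_untouched(self):
        sga, _ = self._normed([[0.0, 0.0], [2.0, 2.0]])
        np.testing.assert_allclose(sga.matrices["W"], [[0.0, 0.0], [0.5, 0.5]])

    def test_negative_weights_warn_but_normalize(self):
        net = Network(seed=0)
        src = NeuronGroup(net, 2)
        dst = NeuronGroup(net, 1)
        sg = SynapseGroup(net, src, dst)
        dst.add_behaviour(1, NormalizeAfferent(norm_target=1.0))
        net.initialize()
        sg.register_matrix("W", np.array([[2.0, -1.0]]))
        with pytest.warns(UserWarning, match="negative"):
            net.simulate_iterations(1)
        np.testing.assert_allclose(sg.matrices["W"].sum(), 1.0)


class TestIntrinsicPlasticity:
    @staticmethod
    def _run(spike_value, eta=0.01, target=0.1, steps=10):
        net = Network(seed=0)
        ng = NeuronGroup(net, 1)
        ng.add_behaviour(1, ForcedSpikes(
            train=np.full((steps, 1), spike_value, dtype=bool)))
        ng.add_behaviour(2, IntrinsicPlasticity(eta_ip=eta, target_rate=target))
        net.initialize()
        ng.new_state_vector("threshold", 0.5)
        net.simulate_iterations(steps)
        return ng.threshold[0]

    def test_always_spiking_raises_threshold(self):
        assert np.isclose(self._run(True), 0.5 + 10 * 0.01 * 0.9)

    def test_silent_neuron_lowers_threshold(self):
        assert np.isclose(self._run(False), 0.5 - 10 * 0.01 * 0.1)

    def test_zero_rate_freezes_threshold(self):
        assert self._run(True, eta=0.0) == 0.5


class TestNOX:
    @staticmethod
    def _nox_net(train, **params):
        net = Network(seed=0)
        ng = NeuronGroup(net, 100)
        ng.add_spatial_layout(10, 10, 1)
        ng.add_behaviour(1, ForcedSpikes(train=train))
        ng.add_behaviour(2, NOXHomeostasis(**params))
        net.initialize()
        net.simulate_iterations(len(train))
        return net, ng

    def test_silent_network_thresholds_drift_down(self):
        train = np.zeros((10, 100), dtype=bool)
        net, ng = self._nox_net(train, alpha=0.1, diffusion=0.0, decay=0.0,
                                eta_nox=0.01, nox_target=1.0)
        np.testing.assert_array_equal(ng.nox, 0.0)
        np.testing.assert_allclose(ng.threshold, 0.5 - 10 * 0.01 * 1.0)

    def test_single_spike_mass_conserved_under_diffusion(self):
        train = np.zeros((50, 100), dtype=bool)
        train[0, 55] = True                 # one spike near the grid centre
        net, ng = self._nox_net(train, alpha=1.0, diffusion=0.2, decay=0.0,
                                eta_nox=0.0, nox_target=0.0)
        assert abs(ng.nox.sum() - 1.0) < 1e-12
        assert ng.nox.max() < 1.0           # it actually spread out

    def test_uniform_spiking_stays_spatially_uniform(self):
        train = np.ones((5, 100), dtype=bool)
        net, ng = self._nox_net(train, alpha=0.3, diffusion=0.2, decay=0.1,
                                eta_nox=0.0, nox_target=0.0)
        assert np.ptp(ng.nox) < 1e-12

    def test_missing_layout_rejected(self):
        net = Network(seed=0)
        ng = NeuronGroup(net, 10)
        ng.add_behaviour(1, NOXHomeostasis())
        with pytest.raises(bn.NetworkError, match="layout"):
            net.initialize()

    def test_laplacian_of_constant_field_is_zero(self):
        layout = bn.SpatialLayout(5, 4, 2)
        np.testing.assert_array_equal(
            grid_laplacian(np.full(40, 3.3), layout), 0.0)


class TestIzhikevich:
    @staticmethod
    def _run(steps, record=False, **params):
        net = Network(seed=0)
        ng = NeuronGroup(net, 1)
        ng.add_behaviour(1, Izhikevich(**params))
        if record:
            ng.add_behaviour(9, bn.Recorder("n.v", "n.spike"))
        net.initialize()
        net.simulate_iterations(steps)
        return net, ng

    def test_rest_is_bounded_and_silent_without_input(self):
        net, ng = self._run(1000, record=True, a=0.02, b=0.2, c=-65.0, d=8.0, I=0.0)
        trace = net["n.v"][0].np
        assert not net["n.spike"][0].np.any()
        assert np.abs(trace).max() < 100.0

    def test_regular_spiking_with_tonic_drive(self):
        net, ng = self._run(1000, record=True, a=0.02, b=0.2, c=-65.0, d=8.0, I=10.0)
        assert net["n.spike"][0].np.sum() >= 1

    def test_zero_d_reset_leaves_recovery_unchanged(self):
        net, ng = self._run(0, a=0.02, b=0.2, c=-65.0, d=0.0, I=0.0)
        u_before = ng.u.copy()
        ng.v = np.array([40.0])            # force an immediate spike
        net.simulate_iterations(1)
        assert ng.spike.all()
        np.testing.assert_allclose(ng.u, u_before + 0.02 * (0.2 * 40.0 - u_before))
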