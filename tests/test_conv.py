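"""Directional convolution: energy oracles, gate properties, layer update."""

import numpy as np
import pytest
import scipy.sparse as sp

from driverplex import nn
from driverplex.conv import (DirectionalEncoder, EncoderConfig,
                             dirichlet_energy, directional_gate)
from driverplex.graph import MultiplexGraph, normalize_directed
from driverplex.nn import Tensor
from driverplex.universe import GeneUniverse


def energy_bruteforce(H, S):
    """Per-node expansion: sum_j s_ij (h_i-h_j)^2 + (1 - sum_j s_ij) h_i^2."""
    n = H.shape[0]
    out = np.zeros_like(H)
    for i in range(n):
        acc = (1 - S[i].sum()) * H[i] ** 2
        for j in range(n):
            acc = acc + S[i, j] * (H[i] - H[j]) ** 2
        out[i] = acc
    return out


class TestDirichletEnergy:
    def test_all_ones_features(self, rng):
        S = sp.csr_matrix((rng.random((6, 6)) < 0.4).astype(float) * 0.3)
        H = np.ones((6, 2))
        e = dirichlet_energy(Tensor(H), S).data
        rowsum = np.asarray(S.sum(axis=1)).ravel()
        np.testing.assert_allclose(e, (1 - rowsum)[:, None] * np.ones((6, 2)),
                                   atol=1e-12)

    def test_zero_row_reduces_to_square(self, rng):
        S = np.zeros((4, 4))
        S[1:] = rng.random((3, 4)) * 0.2
        np.fill_diagonal(S, 0)
        H = rng.normal(size=(4, 3))
        e = dirichlet_energy(Tensor(H), sp.csr_matrix(S)).data
        np.testing.assert_allclose(e[0], H[0] ** 2, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_expansion(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 11)
        A = (rng.random((n, n)) < 0.4).astype(float)
        np.fill_diagonal(A, 0)
        S = normalize_directed(sp.csr_matrix(A)).s_fwd
        H = rng.normal(size=(n, 4))
        e = dirichlet_energy(Tensor(H), S).data
        np.testing.assert_allclose(e, energy_bruteforce(H, S.toarray()),
                                   atol=1e-6)

    def test_sink_node_under_in_operator(self):
        # DAG 0 -> 1 -> 2; node 0 has no incoming arcs, so the in-direction
        # operator has a zero row there and its energy is h*h
        A = sp.csr_matrix(np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0.]]))
        ops = normalize_directed(A)
        H = np.array([[2.0, -1.0], [0.5, 3.0], [1.0, 1.0]])
        e_in = dirichlet_energy(Tensor(H), ops.s_bwd).data
        np.testing.assert_allclose(e_in[0], H[0] ** 2, atol=1e-12)


def _gate_inputs(rng, n=5, w=3):
    e_f = Tensor(rng.normal(size=(n, w)))
    e_b = Tensor(rng.normal(size=(n, w)))
    d_f = Tensor(rng.normal(size=(n, w)))
    d_b = Tensor(rng.normal(size=(n, w)))
    wf = nn.parameter(rng.normal(size=(w, 1)))
    wb = nn.parameter(rng.normal(size=(w, 1)))
    bf = nn.parameter(np.array([0.3]))
    bb = nn.parameter(np.array([-0.2]))
    return e_f, e_b, d_f, d_b, wf, bf, wb, bb


class TestDirectionalGate:
    def test_complementarity_is_exact(self, rng):
        args = _gate_inputs(rng)
        gf, gb = directional_gate(*args, nn.parameter(np.array([0.1])))
        np.testing.assert_array_equal(gf.data + gb.data, 1.0)

    def test_equal_logits_give_half(self, rng):
        e_f, _, d_f, _, wf, bf, _, _ = _gate_inputs(rng)
        gf, gb = directional_gate(e_f, e_f, d_f, d_f, wf, bf, wf, bf,
                                  nn.parameter(np.zeros(1)))
        np.testing.assert_allclose(gf.data, 0.5, atol=1e-12)

    def test_large_temperature_washes_out(self, rng):
        args = _gate_inputs(rng)
        gf, _ = directional_gate(*args, nn.parameter(np.array([20.0])))
        np.testing.assert_allclose(gf.data, 0.5, atol=1e-6)

    def test_matches_two_way_softmax(self, rng):
        args = _gate_inputs(rng)
        tau = 0.7
        gf, _ = directional_gate(*args, nn.parameter(np.array([np.log(tau)])))
        e_f, e_b, d_f, d_b, wf, bf, wb, bb = args
        qf = ((-e_f.data + d_f.data) @ wf.data + bf.data).ravel()
        qb = ((-e_b.data + d_b.data) @ wb.data + bb.data).ravel()
        soft = np.exp(qf / tau) / (np.exp(qf / tau) + np.exp(qb / tau))
        np.testing.assert_allclose(gf.data.ravel(), soft, atol=1e-12)


def _encoder(graph, hidden=4, layers=1, seed=0, **kw):
    cfg = EncoderConfig(n_features=graph.n_features, hidden=hidden,
                        n_layers=layers, dropout=0.0, **kw)
    return DirectionalEncoder(cfg, n_graphs=graph.n_layers, seed=seed)


class TestLayerForward:
    def test_zero_transforms_leave_residual_only(self, toy_multiplex):
        enc = _encoder(toy_multiplex)
        for name, p in enc.params.items():
            if name.startswith("W_"):
                p.data[...] = 0.0
        ops = toy_multiplex.operators()
        H = Tensor(np.random.default_rng(0).normal(size=(7, 4)))
        out = enc.layer_forward(H, ops, 0)
        np.testing.assert_allclose(out.data, 0.5 * H.data, atol=1e-12)

    def test_identical_graphs_equal_single_graph(self, toy_multiplex):
        enc = _encoder(toy_multiplex)
        ops = toy_multiplex.operators()
        H = Tensor(np.random.default_rng(1).normal(size=(7, 4)))
        # make every graph slot use the same operators and embeddings
        for l in range(1):
            for d in ("fwd", "bwd"):
                base = enc.params[f"deg_{d}_{l}_0"].data
                for m in range(1, 3):
                    enc.params[f"deg_{d}_{l}_{m}"].data[...] = base
        out_multi = enc.layer_forward(H, [ops[0]] * 3, 0)
        out_single = enc.layer_forward(H, [ops[0]], 0)
        np.testing.assert_allclose(out_multi.data, out_single.data,
                                   atol=1e-12)

    def test_matches_naive_message_passing(self):
        """5-node toy, one directed graph, against an explicit per-node loop."""
        rng = np.random.default_rng(7)
        A = (rng.random((5, 5)) < 0.5).astype(float)
        np.fill_diagonal(A, 0)
        universe = GeneUniverse([f"g{i}" for i in range(5)])
        graph = MultiplexGraph(universe, [sp.csr_matrix(A)], [True],
                               rng.normal(size=(5, 3)))
        enc = _encoder(graph, hidden=3, seed=3)
        ops = graph.operators()
        H = rng.normal(size=(5, 3))
        out = enc.layer_forward(Tensor(H), ops, 0).data

        # naive reimplementation of the layer update
        sf, sb = ops[0].s_fwd.toarray(), ops[0].s_bwd.toarray()
        ef = energy_bruteforce(H, sf)
        eb = energy_bruteforce(H, sb)
        degf = enc.params["deg_fwd_0_0"].data[ops[0].deg_out]
        degb = enc.params["deg_bwd_0_0"].data[ops[0].deg_in]
        qf = (-ef + degf) @ enc.params["wgate_fwd_0"].data \
            + enc.params["bgate_fwd_0"].data
        qb = (-eb + degb) @ enc.params["wgate_bwd_0"].data \
            + enc.params["bgate_bwd_0"].data
        tau = np.exp(enc.params["log_tau_0"].data)
        gf = 1.0 / (1.0 + np.exp(-(qf - qb) / tau))
        expect = 0.5 * H.copy()
        Wf, Wb = enc.params["W_fwd_0"].data, enc.params["W_bwd_0"].data
        for i in range(5):
            msg_f = sum(sf[i, j] * H[j] for j in range(5)) @ Wf
            msg_b = sum(sb[i, j] * H[j] for j in range(5)) @ Wb
            expect[i] += gf[i] * msg_f + (1 - gf[i]) * msg_b
        np.testing.assert_allclose(out, expect, atol=1e-8)


class TestEncode:
    def test_single_layer_encoder_is_one_forward(self, toy_multiplex):
        enc = _encoder(toy_multiplex, layers=1)
        ops = toy_multiplex.operators()
        H_full, _ = enc.encode(operators=ops, X=toy_multiplex.X)
        H0 = nn.matmul(Tensor(toy_multiplex.X), enc.params["w_in"])
        H_manual = enc.layer_forward(H0, ops, 0)
        np.testing.assert_allclose(H_full.data, H_manual.data, atol=1e-12)

    def test_eval_mode_is_deterministic(self, toy_multiplex):
        enc = _encoder(toy_multiplex, layers=2)
        a, _ = enc.encode(toy_multiplex, training=False)
        b, _ = enc.encode(toy_multiplex, training=False)
        np.testing.assert_array_equal(a.data, b.data)

    def test_ablation_flag_equals_symmetrized_graph(self, toy_multiplex):
        enc = _encoder(toy_multiplex, layers=2)
        a, _ = enc.encode(toy_multiplex, symmetrize=True)
        b, _ = enc.encode(toy_multiplex.symmetrized())
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_permutation_equivariance(self, toy_multiplex):
        rng = np.random.default_rng(5)
        perm = rng.permutation(7)
        P = np.eye(7)[perm]
        enc = _encoder(toy_multiplex, layers=2, max_degree=16)
        H, _ = enc.encode(toy_multiplex)
        layers_p = [sp.csr_matrix(P @ a.toarray() @ P.T)
                    for a in toy_multiplex.layers]
        graph_p = MultiplexGraph(toy_multiplex.universe, layers_p,
                                 toy_multiplex.directed,
                                 toy_multiplex.X[perm])
        H_p, _ = enc.encode(graph_p)
        np.testing.assert_allclose(H_p.data, H.data[perm], atol=1e-9)

    def test_gradients_reach_every_parameter_group(self, toy_multiplex):
        enc = _encoder(toy_multiplex, layers=2)
        H, gates = enc.encode(toy_multiplex, collect_gates=True)
        loss = (H * H).sum() + sum((g * g).sum() for _, _, g in gates)
        loss.backward()
        for name, p in enc.params.items():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
        # at least one nonzero gradient per group kind
        for kind in ("w_in", "W_fwd", "W_bwd", "wgate", "bgate", "deg_",
                     "log_tau"):
            grads = [np.abs(p.grad).max() for n, p in enc.params.items()
                     if n.startswith(kind)]
            assert max(grads) > 0, kind

    def test_gate_complementarity_across_layers(self, toy_multiplex):
        enc = _encoder(toy_multiplex, layers=3)
        _, gates = enc.encode(toy_multiplex, collect_gates=True)
        assert len(gates) == 3 * toy_multiplex.n_layers
        for _, _, g in gates:
            assert ((g.data > 0) & (g.data < 1)).all()

    def test_checkpoint_round_trip(self, toy_multiplex, tmp_path):
        enc = _encoder(toy_multiplex, layers=2, seed=11)
        path = tmp_path / "enc.npz"
        enc.save(path)
        back = DirectionalEncoder.load(path, enc.config)
        a, _ = enc.encode(toy_multiplex)
        b, _ = back.encode(toy_multiplex)
        np.testing.assert_array_equal(a.data, b.data)
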