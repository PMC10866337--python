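"""Encoder correctness: brute-force oracle, gradients, and symmetries."""

import numpy as np
import pytest

from kinsolv.errors import ShapeError
from kinsolv.featurize import batch_graphs, build_cgr, build_mol_graph
from kinsolv.nn import (
    encoder_backward,
    encoder_forward,
    head_backward,
    head_forward,
    init_encoder,
    init_head,
    make_lr_schedule,
)
from kinsolv.reactions import parse_mapped_reaction
from kinsolv.synthetic import template_reactions


def brute_force_encode(graph, params, readout="mean"):
    """Reference implementation with explicit arc-by-arc Python loops."""
    relu = lambda v: np.maximum(v, 0.0)
    n_arcs = graph.n_arcs
    x, e = graph.atom_features, graph.arc_features
    src, dst, rev = graph.arc_src, graph.arc_dst, graph.rev
    if params.depth >= 1 and n_arcs:
        z0 = np.array(
            [np.concatenate([x[src[a]], e[a]]) @ params.W_i + params.b_i
             for a in range(n_arcs)]
        )
        h = relu(z0)
        for _ in range(params.depth):
            new = np.zeros_like(h)
            for a in range(n_arcs):
                m = np.zeros(params.hidden)
                for b in range(n_arcs):
                    # arcs incoming to src[a], excluding the reverse of a
                    if dst[b] == src[a] and b != rev[a]:
                        m += h[b]
                new[a] = relu(z0[a] + m @ params.W_h)
            h = new
    atoms = []
    for v in range(graph.n_atoms):
        m = np.zeros(params.hidden)
        if params.depth >= 1 and n_arcs:
            for b in range(n_arcs):
                if dst[b] == v:
                    m += h[b]
        atoms.append(relu(np.concatenate([x[v], m]) @ params.W_o + params.b_o))
    atoms = np.array(atoms)
    return atoms.mean(axis=0) if readout == "mean" else atoms.sum(axis=0)


@pytest.fixture(scope="module")
def ten_graphs(schema):
    solvents = ["CCO", "c1ccccc1", "CC(C)=O", "O", "CS(C)=O", "C1CCOC1"]
    graphs = [build_mol_graph(s, schema) for s in solvents]
    rxns = [smi for _, smi in template_reactions()[::23]][:4]
    cgrs = [build_cgr(parse_mapped_reaction(smi), schema) for smi in rxns]
    return graphs, cgrs


class TestBruteForceOracle:
    @pytest.mark.parametrize("readout", ["mean", "sum"])
    def test_batched_matches_dense_loops(self, schema, ten_graphs, readout):
        solvents, cgrs = ten_graphs
        enc_s = init_encoder(schema.atom_width, schema.bond_width, 12, 3, seed=2)
        enc_c = init_encoder(schema.cgr_atom_width, schema.cgr_bond_width, 12, 3, seed=3)
        batched = encoder_forward(batch_graphs(solvents), enc_s, readout)
        for i, g in enumerate(solvents):
            ref = brute_force_encode(g, enc_s, readout)
            np.testing.assert_allclose(batched[i], ref, atol=1e-6)
        batched = encoder_forward(batch_graphs(cgrs), enc_c, readout)
        for i, g in enumerate(cgrs):
            ref = brute_force_encode(g, enc_c, readout)
            np.testing.assert_allclose(batched[i], ref, atol=1e-6)


class TestEncoderProperties:
    def test_single_atom_graph_is_pure_atom_transform(self, schema):
        g = build_mol_graph("O", schema)
        enc = init_encoder(schema.atom_width, schema.bond_width, 8, 3, seed=0)
        emb = encoder_forward(batch_graphs([g]), enc, "mean")[0]
        x = np.concatenate([g.atom_features[0], np.zeros(8)])
        np.testing.assert_allclose(emb, np.maximum(x @ enc.W_o + enc.b_o, 0.0))

    @pytest.mark.parametrize("pair", [("CCO", "OCC"), ("C1CCOC1", "O1CCCC1"),
                                      ("CC(C)=O", "O=C(C)C")])
    def test_isomorphic_spellings_share_embedding(self, schema, pair):
        enc = init_encoder(schema.atom_width, schema.bond_width, 16, 3, seed=4)
        embs = [
            encoder_forward(batch_graphs([build_mol_graph(s, schema)]), enc)[0]
            for s in pair
        ]
        scale = max(1.0, np.abs(embs[0]).max())
        np.testing.assert_allclose(embs[0], embs[1], atol=1e-6 * scale)

    def test_depth_zero_ignores_bond_features(self, schema):
        g = build_mol_graph("CCO", schema)
        enc = init_encoder(schema.atom_width, schema.bond_width, 8, 0, seed=5)
        base = encoder_forward(batch_graphs([g]), enc)
        g.arc_features[:] += 10.0  # perturb every bond feature
        perturbed = encoder_forward(batch_graphs([g]), enc)
        np.testing.assert_array_equal(base, perturbed)

    def test_depth_one_sees_bond_features(self, schema):
        g = build_mol_graph("CCO", schema)
        enc = init_encoder(schema.atom_width, schema.bond_width, 8, 1, seed=5)
        base = encoder_forward(batch_graphs([g]), enc).copy()
        g.arc_features[:] += 1.0
        assert not np.allclose(base, encoder_forward(batch_graphs([g]), enc))

    def test_width_mismatch_raises(self, schema):
        g = build_mol_graph("CCO", schema)
        enc = init_encoder(schema.atom_width + 1, schema.bond_width, 8, 2, seed=0)
        with pytest.raises(ShapeError):
            encoder_forward(batch_graphs([g]), enc)

    def test_embeddings_finite(self, schema, ten_graphs):
        solvents, cgrs = ten_graphs
        enc = init_encoder(schema.atom_width, schema.bond_width, 32, 4, seed=9)
        emb = encoder_forward(batch_graphs(solvents), enc)
        assert np.all(np.isfinite(emb))


class TestGradients:
    def test_encoder_gradients_match_finite_differences(self, schema):
        rng = np.random.default_rng(0)
        graphs = [build_mol_graph(s, schema) for s in ("CCO", "CC(C)=O", "O")]
        batch = batch_graphs(graphs)
        enc = init_encoder(schema.atom_width, schema.bond_width, 10, 2, seed=1)
        target = rng.normal(size=(3, 10))

        def loss():
            emb = encoder_forward(batch, enc)
            return 0.5 * float(((emb - target) ** 2).sum())

        emb, cache = encoder_forward(batch, enc, want_cache=True)
        grads = encoder_backward(emb - target, cache, enc)
        for name, arr in (("W_i", enc.W_i), ("W_h", enc.W_h), ("W_o", enc.W_o),
                          ("b_i", enc.b_i), ("b_o", enc.b_o)):
            for _ in range(4):
                ix = tuple(rng.integers(0, s) for s in arr.shape)
                eps, old = 1e-6, arr[ix]
                arr[ix] = old + eps
                lp = loss()
                arr[ix] = old - eps
                lm = loss()
                arr[ix] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[name][ix]) < 1e-5 * max(1.0, abs(fd))

    def test_head_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        head = init_head(6, (5,), 2, seed=2)
        x = rng.normal(size=(4, 6))
        y = rng.normal(size=(4, 2))
        out, cache = head_forward(x, head, want_cache=True)
        grads, dx = head_backward(out - y, cache, head)

        def loss():
            return 0.5 * float(((head_forward(x, head) - y) ** 2).sum())

        for name, arr in (("W0", head.weights[0]), ("W1", head.weights[1]),
                          ("b0", head.biases[0])):
            for _ in range(4):
                ix = tuple(rng.integers(0, s) for s in arr.shape)
                eps, old = 1e-6, arr[ix]
                arr[ix] = old + eps
                lp = loss()
                arr[ix] = old - eps
                lm = loss()
                arr[ix] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[name][ix]) < 1e-5 * max(1.0, abs(fd))
        # gradient w.r.t. the input (feeds the encoders)
        for _ in range(4):
            ix = tuple(rng.integers(0, s) for s in x.shape)
            eps, old = 1e-6, x[ix]
            x[ix] = old + eps
            lp = loss()
            x[ix] = old - eps
            lm = loss()
            x[ix] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - dx[ix]) < 1e-5 * max(1.0, abs(fd))


class TestSchedule:
    def test_warmup_then_decay(self):
        lr = make_lr_schedule(10, 10, warmup_epochs=2, init_lr=1e-4,
                              max_lr=1e-3, final_lr=1e-4)
        assert lr(0) == pytest.approx(1e-4)
        assert lr(20) == pytest.approx(1e-3)
        assert lr(99) == pytest.approx(1e-4, rel=0.05)
        values = [lr(s) for s in range(100)]
        peak = int(np.argmax(values))
        assert all(a <= b * (1 + 1e-12) for a, b in zip(values[:peak], values[1:peak + 1]))
        assert all(a >= b for a, b in zip(values[peak:], values[peak + 1:]))
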