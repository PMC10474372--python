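import numpy as np
import pytest

import ontovnn as ov
from ontovnn.sparse_vnn import DenseLinear, SparseLinear

from conftest import make_model


def dense_forward(model, cx, dx):
    """Independent dense-matrix forward pass (no-norm, tanh models only)."""
    def run_stack(layers, x):
        from ontovnn.sparse_vnn import Tanh, Identity
        for layer in layers:
            if isinstance(layer, SparseLinear):
                x = x @ layer.to_dense().T + layer.b
            elif isinstance(layer, DenseLinear):
                x = x @ layer.W.T + layer.b
            elif isinstance(layer, Tanh):
                x = np.tanh(x)
            elif isinstance(layer, Identity):
                pass
            else:
                raise AssertionError("oracle only covers no-norm models")
        return x

    v = run_stack(model.vnn_layers, cx)
    d = run_stack(model.drug_layers, dx)
    return run_stack(model.head_layers, np.concatenate([v, d], axis=1))[:, 0]


class TestPresets:
    def test_expression_preset_matches_published_dimensions(self):
        cfg = ov.ModelConfig.expression_preset()
        assert cfg.drug_layers == (200, 100, 50)
        assert cfg.vnn_output == 30
        assert cfg.fusion == 40
        assert cfg.k == 6

    def test_mutation_preset_matches_published_dimensions(self):
        cfg = ov.ModelConfig.mutation_preset()
        assert cfg.drug_layers == (100, 50, 6)
        assert cfg.vnn_output == 6
        assert cfg.fusion == 6

    def test_single_term_hierarchy_still_yields_scalar(self):
        g = ov.load_ontology(["R\tA\tdefault"], ["A\tg1\tgene"])
        h = ov.layerize(g)
        model = make_model(h, k=6, drug_input_dim=32, vnn_output=4, fusion=4,
                           drug_layers=(8,))
        out = model.forward(np.ones((3, 1)), np.zeros((3, 32)))
        assert out.shape == (3,)


class TestForward:
    def test_zero_parameters_give_zero_output(self, small_hierarchy):
        model = make_model(small_hierarchy, norm_variant="none")
        for p in model.parameters():
            p.value[...] = 0.0
        out = model.forward(np.ones((4, len(small_hierarchy.genes))), np.ones((4, 64)))
        assert np.all(out == 0.0)

    def test_sparse_forward_equals_dense_masked_oracle(self, small_hierarchy, rng):
        model = make_model(small_hierarchy, norm_variant="none", seed=5)
        cx = rng.random((6, len(small_hierarchy.genes)))
        dx = rng.random((6, 64))
        assert np.allclose(model.forward(cx, dx), dense_forward(model, cx, dx), atol=1e-12)

    def test_batch_is_permutation_equivariant(self, small_model, rng):
        cx = rng.random((7, len(small_model.hierarchy.genes)))
        dx = rng.random((7, 64))
        out = small_model.forward(cx, dx)
        perm = rng.permutation(7)
        assert np.allclose(small_model.forward(cx[perm], dx[perm]), out[perm])

    def test_dimension_mismatch_rejected(self, small_model):
        g = len(small_model.hierarchy.genes)
        with pytest.raises(ValueError, match="gene count"):
            small_model.forward(np.ones((2, g + 1)), np.ones((2, 64)))
        with pytest.raises(ValueError, match="drug input width"):
            small_model.forward(np.ones((2, g)), np.ones((2, 65)))

    @pytest.mark.parametrize("variant", ["post", "ic", "none"])
    def test_all_norm_variants_produce_finite_outputs(self, small_hierarchy, rng, variant):
        model = make_model(small_hierarchy, norm_variant=variant)
        cx, dx = rng.random((5, len(small_hierarchy.genes))), rng.random((5, 64))
        train_out = model.forward(cx, dx, train=True, rng=rng)
        eval_out = model.forward(cx, dx, train=False)
        assert np.all(np.isfinite(train_out)) and np.all(np.isfinite(eval_out))

    def test_k_mismatch_rejected(self, small_hierarchy):
        conn = ov.build_connectivity(small_hierarchy, k=2)
        cfg = ov.ModelConfig(k=3, drug_input_dim=64)
        with pytest.raises(ValueError, match="k="):
            ov.compile_model(small_hierarchy, conn, cfg, seed=0)


class TestGradients:
    def test_gradients_match_finite_differences(self, small_hierarchy, rng):
        model = make_model(small_hierarchy, norm_variant="none", seed=3)
        cx = rng.random((5, len(small_hierarchy.genes)))
        dx = rng.random((5, 64))
        y = rng.random(5)

        def loss():
            return float(np.mean((model.forward(cx, dx) - y) ** 2))

        model.zero_grad()
        pred = model.forward(cx, dx, train=True)
        model.backward(2.0 * (pred - y) / len(y))
        h = 1e-6
        for p in model.parameters():
            flat = p.value.reshape(-1)
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + h
                up = loss()
                flat[i] = orig - h
                down = loss()
                flat[i] = orig
                num = (up - down) / (2 * h)
                assert p.grad.reshape(-1)[i] == pytest.approx(num, rel=1e-4, abs=1e-7), p.name


class TestTraining:
    def test_tiny_dataset_is_overfit(self, small_hierarchy, rng):
        model = make_model(small_hierarchy, norm_variant="none", seed=1)
        cx = rng.random((10, len(small_hierarchy.genes)))
        dx = (rng.random((10, 64)) < 0.3).astype(float)
        y = rng.random(10)
        res = ov.train(
            model, cx, dx, y,
            ov.TrainConfig(epochs=500, batch_size=10, learning_rate=0.05,
                           weight_decay=0.0, seed=0),
            validation_fraction=0.0,
        )
        assert res.train_mse[-1] < 1e-3

    def test_off_mask_weights_stay_exactly_zero(self, small_hierarchy, rng):
        model = make_model(small_hierarchy, seed=2)
        cx = rng.random((20, len(small_hierarchy.genes)))
        dx = rng.random((20, 64))
        y = rng.random(20)
        ov.train(model, cx, dx, y,
                 ov.TrainConfig(epochs=20, batch_size=8, learning_rate=0.05, seed=0))
        for layer in model.vnn_layers:
            if isinstance(layer, SparseLinear):
                dense = layer.to_dense()
                mask = layer.W.copy()
                mask.data = np.ones_like(mask.data)
                off_mask = dense * (1 - mask.toarray())
                assert np.max(np.abs(off_mask)) == 0.0

    def test_same_seed_reproduces_loss_history(self, small_hierarchy, rng):
        cx = rng.random((30, len(small_hierarchy.genes)))
        dx = rng.random((30, 64))
        y = rng.random(30)
        histories = []
        for _ in range(2):
            model = make_model(small_hierarchy, seed=4)
            res = ov.train(model, cx, dx, y,
                           ov.TrainConfig(epochs=10, batch_size=8, learning_rate=0.05,
                                          seed=9))
            histories.append(res.train_mse)
        assert histories[0] == histories[1]

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_nan_loss_aborts_with_diagnostic(self, small_hierarchy, rng):
        model = make_model(small_hierarchy, norm_variant="none", seed=1)
        cx = rng.random((8, len(small_hierarchy.genes)))
        dx = rng.random((8, 64))
        y = rng.random(8)
        with pytest.raises(RuntimeError, match="loss"):
            ov.train(model, cx, dx, y,
                     ov.TrainConfig(epochs=50, batch_size=8, learning_rate=1e9, seed=0),
                     validation_fraction=0.0)

    def test_batch_size_clamps_to_dataset(self, small_hierarchy, rng):
        model = make_model(small_hierarchy, seed=0)
        cx = rng.random((6, len(small_hierarchy.genes)))
        res = ov.train(model, cx, rng.random((6, 64)), rng.random(6),
                       ov.TrainConfig(epochs=2, batch_size=20000, learning_rate=0.01,
                                      seed=0),
                       validation_fraction=0.0)
        assert len(res.train_mse) == 2


class TestFreezeVirtual:
    def test_frozen_virtual_connections_never_move(self, rng):
        spec = ov.FixtureSpec(seed=5, depth=3, branching=2, skip_edge_fraction=0.3,
                              genes_per_bottom_term=2)
        h = ov.layerize(ov.generate_ontology(spec))
        assert h.virtual_nodes  # the fixture must actually exercise the option
        conn = ov.build_connectivity(h, 2)
        cfg = ov.ModelConfig(k=2, drug_layers=(4,), vnn_output=3, fusion=4,
                             drug_input_dim=16, freeze_virtual=True)
        model = ov.compile_model(h, conn, cfg, seed=5)
        before = {
            i: (layer.W.data.copy(), layer.pW.trainable.copy())
            for i, layer in enumerate(model.vnn_layers)
            if isinstance(layer, SparseLinear) and layer.pW.trainable is not None
        }
        assert before
        cx = rng.random((20, len(h.genes)))
        ov.train(model, cx, rng.random((20, 16)), rng.random(20),
                 ov.TrainConfig(epochs=10, batch_size=10, learning_rate=0.05, seed=0),
                 validation_fraction=0.0)
        for i, (orig, trainable) in before.items():
            layer = model.vnn_layers[i]
            frozen = trainable == 0.0
            assert np.array_equal(layer.W.data[frozen], orig[frozen])
            if (~frozen).any():
                assert np.any(layer.W.data[~frozen] != orig[~frozen])


class TestCheckpoint:
    def test_save_load_round_trip(self, small_hierarchy, rng, tmp_path):
        model = make_model(small_hierarchy, seed=6)
        cx = rng.random((4, len(small_hierarchy.genes)))
        dx = rng.random((4, 64))
        ov.train(model, cx, dx, rng.random(4),
                 ov.TrainConfig(epochs=3, batch_size=4, learning_rate=0.01, seed=0),
                 validation_fraction=0.0)
        path = tmp_path / "model.npz"
        ov.save_model(model, path)
        loaded = ov.load_model(path)
        assert np.allclose(loaded.forward(cx, dx), model.forward(cx, dx))
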