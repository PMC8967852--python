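"""Architecture shape contracts, parameter counts and gradient correctness."""

import numpy as np
import pytest

from ictalfeat.errors import ShapeError
from ictalfeat.networks import (
    ModelSpec, SeizureModel, assemble_model, build_tdbb_encoder,
    encoded_feature_names,
)
from ictalfeat.nnet import (
    BatchNorm, Conv1d, Dense, Flatten, LeakyReLU, MaxPool1d, ReLU, Sequential,
    Sigmoid,
)

# every (channels, length) pair printed for the TDBB encoder, in order
TDBB_PRINTED_SHAPES = [
    (2, 400), (4, 400), (4, 198),
    (5, 198), (7, 198), (7, 97),
    (9, 97), (10, 97), (11, 97), (11, 46),
    (12, 46), (13, 46), (14, 46), (14, 21),
    (15, 21), (15, 8),
    (16, 1),
]


class TestShapeContracts:
    def test_tdbb_intermediate_shapes_match_printed_table(self):
        enc = build_tdbb_encoder(np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((3, 1, 400))
        seen = []
        for layer in enc.layers:
            x = layer.forward(x, training=False)
            if isinstance(layer, (Conv1d, MaxPool1d)):
                seen.append((x.shape[1], x.shape[2]))
        assert seen == TDBB_PRINTED_SHAPES
        assert x.shape == (3, 16)  # flattened (N, 16, 1)

    def test_fdbb_dense_chain(self):
        m = assemble_model(ModelSpec("fdbb"), seed=0)
        x = np.random.default_rng(0).standard_normal((5, 200))
        widths = []
        for layer in m.encoder.layers:
            x = layer.forward(x, training=False)
            if isinstance(layer, Dense):
                widths.append(x.shape[1])
        assert widths == [100, 50, 16]

    def test_classifier_dense_chain(self):
        m = assemble_model(ModelSpec("emc"), seed=0)
        x = np.random.default_rng(0).standard_normal((5, 16))
        widths = []
        for layer in m.classifier.layers:
            x = layer.forward(x, training=False)
            if isinstance(layer, Dense):
                widths.append(x.shape[1])
        assert widths == [14, 12, 10, 8, 6, 4, 2, 1]

    def test_spectrum_input_is_200_bins(self):
        from ictalfeat.spectral import spectrum_representation

        assert spectrum_representation(np.zeros((2, 400))).shape == (2, 200)

    def test_encode_yields_16_features(self, rng):
        for kind, arity in (("tdbb", 400), ("fdbb", 200), ("emc", 16)):
            m = assemble_model(ModelSpec(kind), seed=0)
            z = m.encode(rng.standard_normal((4, arity)))
            assert z.shape == (4, 16)


class TestParameterCounts:
    @pytest.mark.parametrize("kind,count", [
        ("tdbb", 8725), ("fdbb", 27145), ("emc", 779),
    ])
    def test_trainable_parameter_count_stable(self, kind, count):
        assert assemble_model(ModelSpec(kind), seed=0).n_parameters() == count

    def test_counts_identical_across_instantiations(self):
        a = assemble_model(ModelSpec("fdbb"), seed=0).n_parameters()
        b = assemble_model(ModelSpec("fdbb"), seed=99).n_parameters()
        assert a == b


class TestModelBehaviour:
    def test_default_dropouts(self):
        assert ModelSpec("tdbb").dropout == 0.90
        assert ModelSpec("fdbb").dropout == 0.75
        assert ModelSpec("emc").dropout == 0.40

    def test_evaluation_mode_deterministic(self, rng):
        m = assemble_model(ModelSpec("fdbb"), seed=0)
        x = rng.standard_normal((8, 200))
        assert np.array_equal(m.predict(x), m.predict(x))

    def test_probabilities_in_open_unit_interval(self, rng):
        for kind, arity in (("tdbb", 400), ("fdbb", 200), ("emc", 16)):
            m = assemble_model(ModelSpec(kind), seed=1)
            p = m.predict(rng.standard_normal((6, arity)))
            assert p.shape == (6,)
            assert np.all(p > 0) and np.all(p < 1)
        p0 = assemble_model(ModelSpec("emc"), seed=1).predict(np.zeros((1, 16)))
        assert 0 < p0[0] < 1

    def test_arity_mismatch_rejected(self, rng):
        m = assemble_model(ModelSpec("fdbb"), seed=0)
        with pytest.raises(ShapeError):
            m.predict(rng.standard_normal((2, 400)))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        m = assemble_model(ModelSpec("fdbb"), seed=7)
        x = rng.standard_normal((5, 200))
        path = tmp_path / "fold.npz"
        m.save(path)
        loaded = SeizureModel.load(path)
        assert loaded.spec.kind == "fdbb"
        assert np.allclose(loaded.predict(x), m.predict(x))

    def test_encoded_feature_names(self):
        assert encoded_feature_names("tdbb")[:2] == ["z0", "z1"]
        assert encoded_feature_names("fdbb")[-1] == "p15"
        assert len(encoded_feature_names("emc")) == 16


class TestGradients:
    """Finite-difference check of the hand-written backward passes."""

    @staticmethod
    def _loss_and_grads(net, x, w):
        for p in net.params():
            p.grad.fill(0.0)
        out = net.forward(x, training=True)
        loss = float(np.sum(out * w))
        net.backward(w)
        return loss

    def test_conv_pool_batchnorm_dense_chain(self):
        rng = np.random.default_rng(0)
        net = Sequential([
            Conv1d(1, 3, 3, 1, rng), ReLU(), BatchNorm(3, conv=True),
            MaxPool1d(kernel=2, stride=2), Flatten(),
            Dense(12, 4, rng), LeakyReLU(), Dense(4, 1, rng), Sigmoid(),
        ])
        x = rng.standard_normal((5, 1, 8))
        w = rng.standard_normal((5, 1))
        self._loss_and_grads(net, x, w)
        eps = 1e-6
        for p in net.params():
            flat = p.value.ravel()
            gflat = p.grad.ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = self._loss_and_grads_nograd(net, x, w)
                flat[idx] = orig - eps
                lm = self._loss_and_grads_nograd(net, x, w)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(gflat[idx], rel=1e-4, abs=1e-7)

    @staticmethod
    def _loss_and_grads_nograd(net, x, w):
        # forward in training mode without disturbing the stored grads
        out = x
        for layer in net.layers:
            if isinstance(layer, BatchNorm):
                # reuse training-mode statistics without updating running stats
                mom = layer.momentum
                layer.momentum = 0.0
                out = layer.forward(out, training=True)
                layer.momentum = mom
            else:
                out = layer.forward(out, training=True)
        return float(np.sum(out * w))
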