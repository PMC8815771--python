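import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dfsvm.embedding import (
    EmbeddingConfig,
    TripletBatch,
    embed,
    gumbel,
    gumbel_grad,
    init_net,
    mine_triplets,
    train_embedding,
    triplet_loss,
    triplet_loss_and_grads,
)


class TestGumbel:
    def test_closed_form_values(self):
        assert gumbel(0.0) == pytest.approx(np.exp(-1), abs=1e-12)
        assert gumbel(-np.log(np.log(2))) == pytest.approx(0.5, abs=1e-12)
        assert gumbel(-2.0) == pytest.approx(np.exp(-np.exp(2)), rel=1e-12)

    @given(st.floats(-5, 25), st.floats(-5, 25))
    def test_strictly_increasing_and_bounded(self, a, b):
        # away from the double-exponential saturation regions, where the
        # float image of the CDF collapses to 0 or 1
        lo, hi = sorted((a, b))
        if hi - lo > 1e-9:
            assert gumbel(lo) < gumbel(hi)
        assert 0.0 <= gumbel(a) <= 1.0
        assert 0.0 <= gumbel(-40.0) and gumbel(40.0) <= 1.0

    @pytest.mark.parametrize("x", [-3.0, -1.0, 0.0, 1.0, 3.0])
    def test_gradient_matches_central_difference(self, x):
        h = 1e-6
        fd = (gumbel(x + h) - gumbel(x - h)) / (2 * h)
        assert gumbel_grad(x) == pytest.approx(fd, rel=1e-6)

    def test_gradient_saturates(self):
        assert gumbel_grad(50.0) < 1e-20
        assert gumbel_grad(-50.0) < 1e-20


class TestInitNet:
    @pytest.mark.parametrize("p, d, widths", [(7, 8, (32, 16, 8)), (3, 2, (8, 4, 2))])
    def test_layer_halving_rule(self, p, d, widths):
        net = init_net(p, EmbeddingConfig(embed_dim=d, seed=0))
        assert tuple(W.shape[1] for W in net.weights) == widths
        assert net.weights[0].shape[0] == p

    def test_seed_determinism(self):
        cfg = EmbeddingConfig(embed_dim=4, seed=5)
        a, b = init_net(6, cfg), init_net(6, cfg)
        for Wa, Wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(Wa, Wb)


class TestMineTriplets:
    def test_anchors_minority_negatives_majority(self):
        y = np.array([1] * 3 + [-1] * 10)
        batch = mine_triplets(y, 50, np.random.default_rng(0))
        assert len(batch) == 50
        assert np.all(y[batch.anchor] == 1) and np.all(y[batch.positive] == 1)
        assert np.all(y[batch.negative] == -1)
        assert np.all(batch.anchor != batch.positive)

    def test_single_minority_sample_uses_anchor_as_positive(self):
        y = np.array([1] + [-1] * 5)
        batch = mine_triplets(y, 20, np.random.default_rng(0))
        np.testing.assert_array_equal(batch.anchor, batch.positive)

    def test_seed_determinism(self):
        y = np.array([1] * 4 + [-1] * 8)
        a = mine_triplets(y, 30, np.random.default_rng(3))
        b = mine_triplets(y, 30, np.random.default_rng(3))
        np.testing.assert_array_equal(a.anchor, b.anchor)
        np.testing.assert_array_equal(a.negative, b.negative)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            mine_triplets(np.ones(5, int), 10, np.random.default_rng(0))


@pytest.mark.parametrize(
    "d_ap, d_an, m, expected",
    [(0.5, 1.0, 0.2, 0.0), (1.0, 0.5, 0.2, 0.7), (0.8, 1.0, 0.2, 0.0)],
)
def test_triplet_loss_hinge(d_ap, d_an, m, expected):
    assert triplet_loss(d_ap, d_an, m) == pytest.approx(expected, abs=1e-12)


def _flatten_params(net):
    return np.concatenate([a.ravel() for a in net.weights + net.biases])


def _set_params(net, flat):
    pos = 0
    for arr in net.weights + net.biases:
        arr[...] = flat[pos : pos + arr.size].reshape(arr.shape)
        pos += arr.size


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        y = np.array([1, 1, 1, -1, -1])
        cfg = EmbeddingConfig(embed_dim=2, margin=0.5, seed=4)
        net = init_net(3, cfg)
        batch = mine_triplets(y, 8, np.random.default_rng(1))
        loss, gW, gb = triplet_loss_and_grads(net, X, batch, cfg.margin)
        assert loss > 0  # hinge active so gradients are informative
        analytic = np.concatenate([g.ravel() for g in gW + gb])

        flat0 = _flatten_params(net).copy()
        h = 1e-5
        fd = np.empty_like(flat0)
        for i in range(len(flat0)):
            for sign, store in ((+1, "hi"), (-1, "lo")):
                flat = flat0.copy()
                flat[i] += sign * h
                _set_params(net, flat)
                val, _, _ = triplet_loss_and_grads(net, X, batch, cfg.margin)
                if sign > 0:
                    hi = val
                else:
                    lo = val
            fd[i] = (hi - lo) / (2 * h)
        _set_params(net, flat0)
        denom = np.maximum(np.abs(fd), 1e-6)
        assert np.max(np.abs(analytic - fd) / denom) < 1e-4

    def test_batch_loss_invariant_to_rigid_rotation_of_embeddings(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(12, 4))
        y = np.array([1] * 4 + [-1] * 8)
        batch = mine_triplets(y, 20, np.random.default_rng(0))
        from scipy.stats import ortho_group

        Q = ortho_group.rvs(4, random_state=7)

        def batch_loss(Zm):
            d_ap = np.linalg.norm(Zm[batch.anchor] - Zm[batch.positive], axis=1)
            d_an = np.linalg.norm(Zm[batch.anchor] - Zm[batch.negative], axis=1)
            return triplet_loss(d_ap, d_an, 0.2).mean()

        assert batch_loss(Z @ Q) == pytest.approx(batch_loss(Z), rel=1e-10)


@pytest.fixture(scope="module")
def trained():
    from dfsvm.data_io import SyntheticSpec, make_synthetic, standardize

    ds = make_synthetic(SyntheticSpec(p=4, n_maj=50, ir=5, class_separation=6.0, seed=1))
    X, _, _, _ = standardize(ds.X)
    cfg = EmbeddingConfig(embed_dim=4, epochs=60, seed=0)
    net, trace = train_embedding(X, ds.y, cfg)
    return X, ds.y, cfg, net, trace


class TestTraining:
    def test_loss_decreases_on_separable_data(self, trained):
        _, _, _, _, trace = trained
        assert trace[-1] < trace[0]

    def test_loss_trace_nonnegative(self, trained):
        assert np.all(trained[4] >= 0)

    def test_identical_seed_gives_identical_trace(self, trained):
        X, y, cfg, _, trace = trained
        _, trace2 = train_embedding(X, y, cfg)
        np.testing.assert_array_equal(trace, trace2)

    def test_training_improves_class_separation_ratio(self, trained):
        X, y, cfg, net, _ = trained

        def sep_ratio(Z):
            cm, cM = Z[y == 1].mean(0), Z[y == -1].mean(0)
            within = np.r_[
                np.linalg.norm(Z[y == 1] - cm, axis=1),
                np.linalg.norm(Z[y == -1] - cM, axis=1),
            ].mean()
            return np.linalg.norm(cm - cM) / within

        z0 = embed(init_net(X.shape[1], cfg), X)
        z1 = embed(net, X)
        assert sep_ratio(z1) > sep_ratio(z0)


class TestEmbed:
    def test_output_shape(self):
        net = init_net(7, EmbeddingConfig(embed_dim=8, seed=0))
        Z = embed(net, np.random.default_rng(0).normal(size=(50, 7)))
        assert Z.shape == (50, 8)

    def test_gumbel_output_lies_in_unit_cube(self):
        net = init_net(3, EmbeddingConfig(embed_dim=2, seed=0))
        Z = embed(net, np.random.default_rng(1).normal(size=(30, 3)))
        assert Z.min() > 0 and Z.max() < 1

    def test_linear_last_layer_escapes_unit_cube_eventually(self):
        cfg = EmbeddingConfig(embed_dim=2, seed=0, last_layer_activated=False)
        net = init_net(3, cfg)
        Z = embed(net, 100 * np.random.default_rng(1).normal(size=(30, 3)))
        assert not (Z.min() > 0 and Z.max() < 1) or Z.shape == (30, 2)

    def test_row_permutation_equivariance(self):
        net = init_net(4, EmbeddingConfig(embed_dim=2, seed=3))
        X = np.random.default_rng(2).normal(size=(10, 4))
        perm = np.random.default_rng(3).permutation(10)
        np.testing.assert_allclose(embed(net, X[perm]), embed(net, X)[perm], atol=1e-14)

    def test_column_mismatch_errors(self):
        net = init_net(4, EmbeddingConfig(embed_dim=2, seed=0))
        with pytest.raises(ValueError, match="columns"):
            embed(net, np.zeros((3, 5)))

    def test_save_load_round_trip(self, tmp_path):
        net = init_net(3, EmbeddingConfig(embed_dim=2, seed=1))
        X = np.random.default_rng(0).normal(size=(6, 3))
        path = tmp_path / "net.json"
        net.save(path)
        clone = net.load(path)
        np.testing.assert_array_equal(embed(net, X), embed(clone, X))
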