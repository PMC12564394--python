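"""Capsule network core: squash identities, routing vs a literal-loop
oracle, margin loss, parameter accounting, prediction contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pneumocaps.capsnet import (
    CapsNet,
    CapsNetConfig,
    build_model,
    dynamic_routing,
    margin_loss,
    margin_loss_grad,
    parameter_counts,
    routing_forward,
    squash,
)


# ---------------------------------------------------------------------------
# squash
# ---------------------------------------------------------------------------

class TestSquash:
    @pytest.mark.parametrize("norm_in,norm_out", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.9)])
    def test_norm_identities(self, norm_in, norm_out):
        s = np.zeros(5)
        s[2] = norm_in
        assert np.linalg.norm(squash(s)) == pytest.approx(norm_out, abs=1e-9)

    def test_direction_preserved_and_norm_below_one(self, rng):
        s = rng.normal(0, 3, (50, 8))
        v = squash(s)
        norms = np.linalg.norm(v, axis=-1)
        assert np.all(norms < 1.0)
        cos = np.sum(s * v, axis=-1) / (np.linalg.norm(s, axis=-1) * norms)
        np.testing.assert_allclose(cos, 1.0, atol=1e-7)

    def test_norm_strictly_increasing(self):
        ns = np.linspace(0.1, 10, 50)
        out = [np.linalg.norm(squash(np.array([n, 0.0]))) for n in ns]
        assert np.all(np.diff(out) > 0)


# ---------------------------------------------------------------------------
# routing
# ---------------------------------------------------------------------------

def routing_oracle(u_hat, r):
    """Independent straight-line transcription of routing-by-agreement."""
    n_in, n_out, d = u_hat.shape
    b = np.zeros((n_in, n_out))
    coupling_history = []
    for it in range(r):
        c = np.zeros_like(b)
        for i in range(n_in):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        coupling_history.append(c.copy())
        v = np.zeros((n_out, d))
        for j in range(n_out):
            s = np.zeros(d)
            for i in range(n_in):
                s += c[i, j] * u_hat[i, j]
            v[j] = squash(s)
        if it < r - 1:
            for i in range(n_in):
                for j in range(n_out):
                    b[i, j] += float(u_hat[i, j] @ v[j])
    return v, coupling_history


class TestRouting:
    def test_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_in = int(rng.integers(2, 11))
            n_out = int(rng.integers(1, 4))
            d_o = int(rng.integers(2, 7))
            r = int(rng.integers(1, 4))
            u_hat = rng.normal(0, 1, (n_in, n_out, d_o))
            v, state = dynamic_routing(u_hat, r)
            v_ref, c_hist = routing_oracle(u_hat, r)
            np.testing.assert_allclose(v, v_ref, atol=1e-6)
            for c in c_hist:  # coupling rows sum to 1 at every iteration
                np.testing.assert_allclose(c.sum(axis=-1), 1.0, atol=1e-12)
            np.testing.assert_allclose(state["c"].sum(axis=-1), 1.0, atol=1e-12)

    def test_single_output_capsule_all_couplings_one(self, rng):
        u_hat = rng.normal(0, 1, (6, 1, 4))
        v, state = dynamic_routing(u_hat, 3)
        np.testing.assert_allclose(state["c"], 1.0)
        np.testing.assert_allclose(v[0], squash(u_hat[:, 0, :].sum(axis=0)), atol=1e-12)

    def test_first_iteration_couplings_uniform(self, rng):
        u_hat = rng.normal(0, 1, (5, 3, 4))
        _, state = dynamic_routing(u_hat, 1)
        np.testing.assert_allclose(state["c"], 1.0 / 3.0)

    def test_r_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            dynamic_routing(rng.normal(0, 1, (3, 2, 4)), 0)

    def test_routing_forward_full_layer(self, rng):
        u = rng.normal(0, 1, (6, 3))
        W = rng.normal(0, 1, (6, 2, 3, 4))
        lengths, v, state = routing_forward(u, W, 3)
        u_hat = np.einsum("id,ijde->ije", u, W)
        v_ref, _ = routing_oracle(u_hat, 3)
        np.testing.assert_allclose(v, v_ref, atol=1e-6)
        np.testing.assert_allclose(lengths, np.linalg.norm(v_ref, axis=-1), atol=1e-6)
        assert np.all(lengths < 1.0)


# ---------------------------------------------------------------------------
# margin loss
# ---------------------------------------------------------------------------

class TestMarginLoss:
    @pytest.mark.parametrize(
        "lengths,label,expected",
        [
            ((0.95, 0.05), 0, 0.0),
            ((0.0, 0.0), 0, 0.81),
            ((0.9, 1.0), 0, 0.405),
        ],
    )
    def test_stated_values(self, lengths, label, expected):
        onehot = np.eye(2)[[label]]
        assert margin_loss(np.array([lengths]), onehot) == pytest.approx(expected)

    def test_zero_iff_margins_satisfied(self, rng):
        lengths = rng.random((20, 2))
        labels = np.eye(2)[rng.integers(0, 2, 20)]
        for row, lab in zip(lengths, labels):
            loss = margin_loss(row[None], lab[None])
            true_len = row[lab.argmax()]
            other = row[1 - lab.argmax()]
            assert loss >= 0
            assert (loss == 0) == (true_len >= 0.9 and other <= 0.1)

    def test_non_onehot_rejected(self):
        with pytest.raises(ValueError, match="one-hot"):
            margin_loss(np.array([[0.5, 0.5]]), np.array([[1, 1]]))

    def test_gradient_matches_finite_difference(self, rng):
        lengths = rng.random((4, 2))
        labels = np.eye(2)[[0, 1, 1, 0]]
        g = margin_loss_grad(lengths, labels)
        eps = 1e-6
        for i in range(4):
            for k in range(2):
                lp, lm = lengths.copy(), lengths.copy()
                lp[i, k] += eps
                lm[i, k] -= eps
                fd = (margin_loss(lp, labels) - margin_loss(lm, labels)) / (2 * eps)
                assert g[i, k] == pytest.approx(fd, abs=1e-6)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

class TestParameterAccounting:
    def test_reference_architecture_counts(self):
        counts = parameter_counts(CapsNetConfig())
        assert counts["conv_stem"] == 1792
        assert counts["primary_caps"] == 147_712
        assert counts["digit_caps"] == 25_690_112
        assert counts["total"] == 25_839_616

    def test_reference_primary_capsule_count(self):
        cfg = CapsNetConfig()
        assert cfg.primary_grid == 56
        assert cfg.n_primary_capsules == 56 * 56 * 32 == 100_352

    def test_toy_closed_forms(self):
        cfg = CapsNetConfig(input_size=64, n_filters=8, primary_caps_types=4,
                            primary_caps_dim=4, digit_caps_dim=8)
        counts = parameter_counts(cfg)
        assert counts["conv_stem"] == 3 * 3 * 3 * 8 + 8 == 224
        assert counts["digit_caps"] == (16 * 16 * 4) * 2 * 4 * 8 == 65_536

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        input_size=st.sampled_from([16, 32, 64]),
        n_filters=st.sampled_from([4, 8, 16]),
        types=st.sampled_from([2, 4]),
        d_p=st.sampled_from([2, 4, 8]),
        d_o=st.sampled_from([4, 8, 16]),
        drop=st.sampled_from([0.0, 0.3]),
    )
    def test_closed_form_equals_allocated_counts(self, input_size, n_filters, types, d_p, d_o, drop):
        """Closed-form accounting equals the sizes of the actually
        allocated weight arrays for arbitrary valid configs."""
        cfg = CapsNetConfig(input_size=input_size, n_filters=n_filters,
                            primary_caps_types=types, primary_caps_dim=d_p,
                            digit_caps_dim=d_o, drop_rate=drop)
        model, table = build_model(cfg)
        counts = parameter_counts(cfg)
        assert model.n_parameters() == counts["total"]
        by_layer = dict(zip(table["layer"], table["params"]))
        assert by_layer["conv_stem"] == counts["conv_stem"]
        assert by_layer["primary_caps"] == counts["primary_caps"]
        assert by_layer["digit_caps"] == counts["digit_caps"]
        assert by_layer["total"] == counts["total"]

    def test_dropout_has_no_parameters(self):
        base = CapsNetConfig(input_size=32, n_filters=4, primary_caps_types=2,
                             primary_caps_dim=2, digit_caps_dim=4)
        with_drop = CapsNetConfig(input_size=32, n_filters=4, primary_caps_types=2,
                                  primary_caps_dim=2, digit_caps_dim=4, drop_rate=0.3)
        assert parameter_counts(base) == parameter_counts(with_drop)

    def test_odd_input_size_rejected_with_shape_message(self):
        with pytest.raises(ValueError, match="even"):
            CapsNetConfig(input_size=63)


# ---------------------------------------------------------------------------
# config validation and prediction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny():
    cfg = CapsNetConfig(input_size=16, n_filters=4, primary_caps_types=2,
                        primary_caps_dim=3, digit_caps_dim=4)
    return CapsNet(cfg, seed=0)


class TestModel:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            CapsNetConfig(routing_iterations=0)
        with pytest.raises(ValueError):
            CapsNetConfig(m_plus=0.1, m_minus=0.9)
        with pytest.raises(ValueError):
            CapsNetConfig(lambda_down=0.0)

    def test_forward_lengths_bounded(self, tiny, rng):
        x = rng.random((4, 16, 16, 3))
        lengths = tiny.lengths(x)
        assert lengths.shape == (4, 2)
        assert np.all(lengths >= 0) and np.all(lengths < 1)

    def test_predict_deterministic_and_argmax(self, tiny, rng):
        x = rng.random((4, 16, 16, 3))
        l1, p1 = tiny.predict(x)
        l2, p2 = tiny.predict(x)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, l1.argmax(-1))

    def test_tie_breaks_to_lower_index(self):
        assert np.array([0.5, 0.5]).argmax() == 0  # documented tie-break

    def test_shape_mismatch_rejected(self, tiny, rng):
        with pytest.raises(ValueError, match="expected batch"):
            tiny.lengths(rng.random((2, 8, 8, 3)))

    def test_gradients_match_finite_differences(self, rng):
        """Hand-derived backward pass vs central differences on every
        parameter tensor (one random entry each)."""
        cfg = CapsNetConfig(input_size=8, in_channels=2, n_filters=3,
                            primary_caps_types=2, primary_caps_dim=3,
                            digit_caps_dim=4, routing_iterations=2)
        model = CapsNet(cfg, seed=1)
        x = rng.random((3, 8, 8, 2))
        y = np.eye(2)[[0, 1, 0]]
        cache = model.forward(x)
        _, grads = model.backward(cache, y)
        eps = 1e-6
        for name, p in model.params.items():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            vals = []
            for sign in (1, -1):
                params = {k: v.copy() for k, v in model.params.items()}
                params[name][idx] += sign * eps
                probe = CapsNet(cfg, seed=1)
                probe.params = params
                c = probe.forward(x)
                vals.append(margin_loss(c["lengths"], y))
            fd = (vals[0] - vals[1]) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=5e-3, abs=1e-9)

    def test_save_load_roundtrip(self, tiny, tmp_path, rng):
        x = rng.random((2, 16, 16, 3))
        tiny.save(tmp_path / "ckpt")
        loaded = CapsNet.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(tiny.lengths(x), loaded.lengths(x))
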