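"""Interaction map, CNN aggregation, decoder, loss and the ablation variants."""

import numpy as np
import pytest

from dtimap.fcs import MergeTable
from dtimap.model import (
    DecoderParams,
    DTIModel,
    HeadConfig,
    aggregate,
    bce_loss,
    interaction_map,
    predict_probability,
)
from dtimap.nn import Conv2d, Tensor
from dtimap.workflow import build_model
from oracles import oracle_dot_map


class TestInteractionMap:
    def test_orthogonal_vectors_give_zero(self):
        Ed = np.array([[1.0, 0.0]])
        Ep = np.array([[0.0, 1.0]])
        assert interaction_map(Ed, Ep)[0, 0] == 0.0

    def test_self_dot_is_squared_norm(self):
        v = np.array([[1.0, 2.0, 3.0]])
        assert interaction_map(v, v)[0, 0] == pytest.approx(14.0)

    def test_matches_double_loop_oracle(self, rng):
        Ed = rng.normal(size=(4, 2))
        Ep = rng.normal(size=(3, 2))
        np.testing.assert_allclose(
            interaction_map(Ed, Ep), oracle_dot_map(Ed, Ep), atol=1e-6
        )

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            interaction_map(rng.normal(size=(4, 2)), rng.normal(size=(3, 5)))

    def test_sum_and_average_functions(self):
        Ed = np.array([[1.0, 1.0]])
        Ep = np.array([[2.0, 2.0]])
        assert interaction_map(Ed, Ep, "sum")[0, 0] == pytest.approx(6.0)
        assert interaction_map(Ed, Ep, "average")[0, 0] == pytest.approx(1.5)


class TestAggregate:
    def test_zero_map_zero_output(self, rng):
        conv = Conv2d(1, 3, 3, rng)
        conv.bias.data[:] = 0.0
        O = aggregate(np.zeros((6, 7)), conv)
        assert O.shape == (3, 4, 5)
        np.testing.assert_array_equal(O, 0.0)

    def test_identity_kernel_crops_positive_map(self, rng):
        conv = Conv2d(1, 1, 3, rng)
        conv.weight.data[:] = 0.0
        conv.weight.data[0, 0, 1, 1] = 1.0
        conv.bias.data[:] = 0.0
        I = np.abs(rng.normal(size=(5, 5))) + 0.1
        np.testing.assert_allclose(aggregate(I, conv)[0], I[1:4, 1:4], atol=1e-12)

    def test_map_smaller_than_kernel_raises(self, rng):
        with pytest.raises(ValueError):
            aggregate(np.zeros((2, 2)), Conv2d(1, 3, 3, rng))


class TestDecoderAndLoss:
    def test_zero_weights_give_half(self):
        P = predict_probability(np.ones(4), DecoderParams(np.zeros(4), 0.0))
        assert P == pytest.approx(0.5)

    def test_large_bias_saturates_toward_one(self):
        P = predict_probability(np.ones(2), DecoderParams(np.zeros(2), 50.0))
        assert P > 1 - 1e-9

    def test_hand_computed_probability(self):
        O = np.array([1.0, -2.0, 0.5, 3.0])
        w = np.array([0.2, 0.1, -0.4, 0.05])
        z = float(O @ w) + 0.3
        P = predict_probability(O, DecoderParams(w, 0.3))
        assert P == pytest.approx(1 / (1 + np.exp(-z)))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            predict_probability(np.ones(3), DecoderParams(np.zeros(4), 0.0))

    def test_bce_closed_forms(self):
        assert bce_loss([0.5], [1]).item() == pytest.approx(np.log(2))
        assert bce_loss([0.9, 0.1], [1, 0]).item() == pytest.approx(-np.log(0.9))

    def test_bce_perfect_prediction_near_zero(self):
        assert bce_loss([1.0 - 1e-9, 1e-9], [1, 0]).item() < 1e-6

    def test_bce_clamps_boundary_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            loss = bce_loss([1.0], [0]).item()
        assert np.isfinite(loss)


@pytest.fixture
def batch(rng):
    d_idx = rng.integers(2, 6, (4, 6))
    p_idx = rng.integers(2, 6, (4, 7))
    d_mask = np.ones((4, 6), int)
    d_mask[:, 5] = 0
    p_mask = np.ones((4, 7), int)
    p_mask[:, 6] = 0
    return d_idx, d_mask, p_idx, p_mask


def small_model(variant, n_layers=1, seed=3):
    drug = MergeTable([], [], 1, None, list("ABCD"))
    prot = MergeTable([], [], 1, None, list("EFGH"))
    return build_model(
        drug,
        prot,
        "desk",
        variant=variant,
        embed_dim=8,
        n_heads=2,
        ffn_dim=16,
        n_layers=n_layers,
        drug_max_len=6,
        protein_max_len=7,
        seed=seed,
    )


class TestVariants:
    @pytest.mark.parametrize("variant", ["full", "no_cnn", "no_augembed", "no_interaction"])
    def test_probabilities_in_open_interval(self, variant, batch):
        model = small_model(variant)
        model.net.eval()
        p = model.net(*batch).data
        assert p.shape == (4,)
        assert np.all((p > 0) & (p < 1))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            HeadConfig(variant="bogus")

    def test_no_augembed_equals_full_with_zero_layers(self, batch):
        a = small_model("full", n_layers=0)
        b = small_model("no_augembed", n_layers=0)
        a.net.eval(), b.net.eval()
        np.testing.assert_allclose(a.net(*batch).data, b.net(*batch).data, atol=1e-12)

    def test_full_and_no_cnn_differ_only_in_aggregation(self, batch):
        """Same seed means identical encoders; the interaction maps must
        coincide even though the decoders consume different features."""
        a = small_model("full")
        b = small_model("no_cnn")
        a.net.eval(), b.net.eval()
        ia = a.net.interaction_map_batch(*batch)
        ib = b.net.interaction_map_batch(*batch)
        np.testing.assert_allclose(ia, ib, atol=1e-12)
        assert a.net.decoder.weight.shape[0] == 3 * 4 * 5
        assert b.net.decoder.weight.shape[0] == 6 * 7


def test_end_to_end_gradcheck_matches_finite_differences(batch, rng):
    """Backprop through encoder, map, CNN and decoder agrees with central
    finite differences on sampled weights (relative error < 1e-3)."""
    model = small_model("full")
    net = model.net
    net.eval()
    y = np.array([1.0, 0.0, 1.0, 0.0])

    def loss_value():
        return bce_loss(net(*batch), y).item()

    net.zero_grad()
    bce_loss(net(*batch), y).backward()
    checked = 0
    for p in net.parameters():
        flat = p.data.ravel()
        gflat = p.grad.ravel()
        i = int(rng.integers(flat.size))
        h = 1e-5
        orig = flat[i]
        flat[i] = orig + h
        fp = loss_value()
        flat[i] = orig - h
        fm = loss_value()
        flat[i] = orig
        fd = (fp - fm) / (2 * h)
        if abs(fd) < 1e-7:  # below the FD noise floor; nothing to compare
            continue
        rel = abs(fd - gflat[i]) / max(abs(fd), abs(gflat[i]))
        assert rel < 1e-3, f"param {p.shape} idx {i}: fd={fd}, bp={gflat[i]}"
        checked += 1
    assert checked >= 5


def test_checkpoint_round_trip(tmp_path, batch):
    model = small_model("full")
    model.net.eval()
    before = model.net(*batch).data
    model.save(tmp_path / "run")
    loaded = DTIModel.load(tmp_path / "run")
    loaded.net.eval()
    np.testing.assert_allclose(loaded.net(*batch).data, before, atol=1e-15)


def test_checkpoint_detects_tampered_merge_table(tmp_path):
    model = small_model("full")
    model.save(tmp_path / "run")
    p = tmp_path / "run" / "drug_merges.tsv"
    p.write_text(p.read_text() + "X\tY\t9\n")
    with pytest.raises(ValueError, match="hash"):
        DTIModel.load(tmp_path / "run")
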