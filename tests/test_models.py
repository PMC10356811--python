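"""Architecture conformance, losses, baseline, training loop."""

import numpy as np
import pytest

from ecgbench.metrics import compute_metrics
from ecgbench.models import (
    DEFAULT_INPUT_FS,
    ModelSpec,
    TrainConfig,
    _loss,
    build_cnn,
    build_gruattnet,
    build_model,
    build_resnet,
    build_rtacnn,
    dummy_majority,
    en_loss,
    predict,
    train,
)
from ecgbench.nn.autodiff import Tensor
from ecgbench.nn.layers import Conv1d, Dropout
from ecgbench.nn.optim import Adam
from ecgbench.synth import beat_dataset_in_memory

rng = np.random.default_rng(0)

# the architecture / frequency / segment-duration combinations of the
# original pipelines (short segments here; the full-length combinations are
# exercised in the acceptance suite)
SMALL_COMBOS = [
    ("cnn", 360.0, 0.72),
    ("resnet", 250.0, 2.5),
    ("gruattnet", 500.0, 0.72),
    ("rtacnn", 300.0, 2.5),
]


def _disable_dropout(net):
    for l in net.layers:
        if isinstance(l, Dropout):
            l.p = 0.0
        if hasattr(l, "drop") and isinstance(getattr(l, "drop"), Dropout):
            l.drop.p = 0.0


@pytest.mark.parametrize("arch,fs,dur", SMALL_COMBOS)
def test_build_forward_simplex_and_gradient_step(arch, fs, dur):
    L = int(round(dur * fs))
    spec = ModelSpec(arch, fs, L, 3, seed=0)
    m = build_model(spec)
    _disable_dropout(m.net)
    m.net.set_train(True)
    x = rng.standard_normal((4, 1, L))
    labels = np.array([0, 1, 2, 0])
    logits = m.net.forward(Tensor(x))
    assert logits.data.shape == (4, 3)
    probs = np.exp(logits.data - logits.data.max(1, keepdims=True))
    probs /= probs.sum(1, keepdims=True)
    assert np.abs(probs.sum(1) - 1).max() < 1e-6
    # one Adam step at small lr strictly decreases the batch loss
    loss0 = _loss(logits, labels, "cross_entropy")
    opt = Adam(m.net.parameters(), lr=1e-4)
    loss0.backward()
    opt.step()
    loss1 = _loss(m.net.forward(Tensor(x)), labels, "cross_entropy")
    assert float(loss1.data) < float(loss0.data)


def test_default_input_frequencies():
    assert DEFAULT_INPUT_FS == {
        "cnn": 360.0, "resnet": 250.0, "gruattnet": 500.0, "rtacnn": 300.0,
    }


def test_cnn_first_conv_parameter_count():
    # 5 filters x (3 taps x 1 channel) weights + 5 biases = 20 parameters
    m = build_cnn(ModelSpec("cnn", 360.0, 259, 3))
    first = m.net.blocks[0]
    assert first.w.data.size + first.b.data.size == 20


def test_cnn_rejects_too_short_input():
    with pytest.raises(ValueError, match="too short"):
        build_cnn(ModelSpec("cnn", 360.0, 7, 3))


def test_resnet_counted_conv_depth_is_9():
    m = build_resnet(ModelSpec("resnet", 250.0, 625, 3))
    assert m.net.conv_depth() == 9
    # and literally: stem + 2 convs per block, projections excluded
    n_convs = 1 + sum(1 for blk in m.net.blocks for c in (blk.c1, blk.c2))
    assert n_convs == 9


def test_resnet_projection_bridges_channel_mismatch():
    m = build_resnet(ModelSpec("resnet", 250.0, 64, 2))
    for blk in m.net.blocks:
        assert blk.proj.k == 1
        assert blk.proj.w.data.shape[0] == blk.c2.w.data.shape[0]


def test_resnet_gap_is_input_length_independent():
    for L in (64, 200):
        m = build_resnet(ModelSpec("resnet", 250.0, L, 2), filters=(8, 8, 8, 8))
        out = m.net.forward(Tensor(rng.standard_normal((2, 1, L))))
        assert out.data.shape == (2, 2)


def test_gruattnet_every_conv_has_12_filters():
    m = build_gruattnet(ModelSpec("gruattnet", 500.0, 360, 3))
    convs = [l for l in m.net.layers if isinstance(l, Conv1d)]
    assert len(convs) == 15  # 5 blocks x 3 layers
    assert all(c.w.data.shape[0] == 12 for c in convs)
    assert [c.k for c in m.net.convs[0]] == [3, 3, 24]


def test_gruattnet_attention_weights_normalized():
    m = build_gruattnet(ModelSpec("gruattnet", 500.0, 250, 3))
    m.net.set_train(False)
    m.net.forward(Tensor(rng.standard_normal((3, 1, 250))))
    w = m.net.attn.last_weights
    assert np.allclose(w.sum(axis=1), 1.0) and (w >= 0).all()


class TestRTACNN:
    def test_six_blocks_with_specified_filter_lengths(self):
        m = build_rtacnn(ModelSpec("rtacnn", 300.0, 750, 3))
        assert len(m.net.blocks) == 6
        assert [b.t1.k for b in m.net.blocks] == [32, 16, 9, 9, 3, 3]
        assert [b.t1.w.data.shape[0] for b in m.net.blocks] == [16, 32, 64, 64, 64, 128]

    def test_attention_weights_in_unit_interval(self):
        m = build_rtacnn(ModelSpec("rtacnn", 300.0, 256, 2))
        m.net.set_train(False)
        blk = m.net.blocks[0]
        att = blk.attention(Tensor(rng.standard_normal((2, 1, 256))), 256)
        assert (att.data >= 0).all() and (att.data <= 1).all()

    def test_zeroed_attention_preserves_trunk_output(self):
        # out = trunk * (1 + att): with attention forced to 0 the block
        # reduces to the trunk path exactly
        m = build_rtacnn(ModelSpec("rtacnn", 300.0, 256, 2))
        m.net.set_train(False)
        blk = m.net.blocks[0]
        x = Tensor(rng.standard_normal((1, 1, 256)))
        trunk_only = blk.act(blk.tb2(blk.t2(blk.act(blk.tb1(blk.t1(x))))))
        blk.attention = lambda inp, target_len: Tensor(
            np.zeros((1, blk.t1.w.data.shape[0], target_len))
        )
        assert np.allclose(blk(x).data, trunk_only.data)


class TestENLoss:
    def test_zero_when_true_probability_is_one(self):
        p = Tensor(np.array([[1.0, 0.0], [1.0, 0.0]]))
        loss = en_loss(p, np.array([0, 0]))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-5)

    def test_nonnegative_and_upweights_hard_examples(self):
        easy = Tensor(np.array([[0.9, 0.1]]))
        hard = Tensor(np.array([[0.2, 0.8]]))
        l_easy = float(en_loss(easy, np.array([0])).data)
        l_hard = float(en_loss(hard, np.array([0])).data)
        assert 0 <= l_easy < l_hard
        # up-weighting: the hard/easy ratio exceeds the plain CE ratio
        assert l_hard / l_easy > (-np.log(0.2)) / (-np.log(0.9))

    def test_zero_probability_clamped(self):
        p = Tensor(np.array([[0.0, 1.0]]))
        assert np.isfinite(float(en_loss(p, np.array([0])).data))


class TestDummyMajority:
    def test_predicts_majority_class_everywhere(self):
        m = dummy_majority([0] * 80 + [1] * 15 + [2] * 5)
        probs, labels = predict(m, (np.zeros((7, 4)), np.zeros(7, dtype=int)))
        assert (labels == 0).all()
        assert np.allclose(probs[:, 0], 1.0)

    def test_tie_goes_to_lowest_index(self):
        assert dummy_majority([1, 1, 0, 0, 2]).majority_class == 0

    def test_closed_form_macro_f1(self):
        # counts (80, 15, 5): majority precision 0.8, recall 1 -> macro
        # F1 = (2*0.8/1.8)/3
        y = np.array([0] * 80 + [1] * 15 + [2] * 5)
        m = dummy_majority(y)
        _, pred = predict(m, (np.zeros((100, 1)), y))
        f1 = compute_metrics(y, pred, 3).macro_f1
        assert f1 == pytest.approx((2 * 0.8 / 1.8) / 3, abs=1e-12)
        assert f1 == pytest.approx(0.2963, abs=5e-4)


class TestTrainingLoop:
    def _data(self, n=40, L=90):
        X, y = beat_dataset_in_memory(n, 0.72, 125.0, noise_sd=0.05, seed=4)
        return X, y

    def test_patience_zero_stops_at_first_non_improvement(self):
        X, y = self._data()
        spec = ModelSpec("cnn", 125.0, X.shape[1], 3, seed=0)
        m = build_cnn(spec)
        cfg = TrainConfig(max_epochs=30, batch_size=16, learning_rate=1e-3,
                          early_stop_patience=0)
        train(m, (X, y), (X[:30], y[:30]), cfg)
        h = m.training_history["val_loss"]
        # stopped the first time the metric failed to improve
        assert len(h) < 30 or all(b < a for a, b in zip(h, h[1:]))

    def test_same_seed_same_history(self):
        X, y = self._data()
        cfg = TrainConfig(max_epochs=3, batch_size=16, learning_rate=1e-3,
                          early_stop_patience=5)
        hists = []
        for _ in range(2):
            m = build_cnn(ModelSpec("cnn", 125.0, X.shape[1], 3, seed=9))
            train(m, (X, y), (X[:30], y[:30]), cfg)
            hists.append(m.training_history)
        assert hists[0] == hists[1]

    def test_empty_train_set_rejected(self):
        m = build_cnn(ModelSpec("cnn", 125.0, 90, 3, seed=0))
        with pytest.raises(ValueError, match="empty training"):
            train(m, (np.zeros((0, 90)), np.zeros(0, dtype=int)),
                  (np.zeros((2, 90)), np.array([0, 1])), TrainConfig())

    def test_predict_rejects_length_mismatch(self):
        m = build_cnn(ModelSpec("cnn", 125.0, 90, 3, seed=0))
        with pytest.raises(ValueError, match="input_len"):
            predict(m, (np.zeros((2, 50)), np.array([0, 1])))

    def test_predict_rows_on_simplex(self):
        m = build_cnn(ModelSpec("cnn", 125.0, 90, 3, seed=0))
        probs, labels = predict(m, (rng.standard_normal((5, 90)), np.zeros(5, int)))
        assert np.abs(probs.sum(1) - 1).max() < 1e-6
        assert np.array_equal(labels, probs.argmax(1))
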