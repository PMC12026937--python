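import numpy as np
import pytest

from rnadivide.divide_model import (
    DivideModel,
    ModelConfig,
    TrainConfig,
    _Adam,
    _example_loss_and_grads,
    loss,
    target_scores,
    train,
)
from rnadivide.features import MotifPattern, featurize, load_default_motifs
from rnadivide.labelgen import TrainingExample

MOTIFS = (MotifPattern("ga", "GA"), MotifPattern("keto", "KKK"))


def random_seq(rng, n):
    return "".join("ACGU"[k] for k in rng.integers(0, 4, n))


def test_target_scores_closed_form():
    y = target_scores({2}, 5, lam=0.5)
    expected = [np.exp(-1), np.exp(-0.5), 1.0, np.exp(-0.5), np.exp(-1)]
    assert np.allclose(y, expected, atol=1e-12)


def test_target_is_one_at_every_cut_and_symmetric():
    y = target_scores({3, 11}, 20, lam=0.5)
    assert y[3] == 1.0 and y[11] == 1.0
    y1 = target_scores({7}, 15, lam=0.8)
    for d in range(1, 8):
        assert y1[7 - d] == pytest.approx(y1[7 + d], abs=1e-15)


def test_target_sharpens_with_lambda():
    soft = target_scores({10}, 21, lam=0.1)
    sharp = target_scores({10}, 21, lam=5.0)
    assert sharp[0] < 1e-10 and soft[0] > 0.3


def test_target_requires_cuts():
    with pytest.raises(ValueError):
        target_scores(set(), 5)


def test_loss_closed_forms():
    y = target_scores({4}, 9, lam=0.5)
    assert loss(y, {4}, lam=0.5) == 0.0
    assert loss([0.0, 1.0, 0.0], {1}, lam=0.5) == pytest.approx(
        2 * np.exp(-1.0), abs=1e-12
    )
    eps = 1e-3
    assert loss(y + eps, {4}, lam=0.5) == pytest.approx(9 * eps**2, rel=1e-9)
    with pytest.raises(ValueError):
        loss([0.5, 0.5], {1}, n=3)


def test_model_config_dilations():
    cfg = ModelConfig()
    assert cfg.dilations == (512, 256, 128, 64, 32, 16, 8, 4, 2, 1)
    assert cfg.receptive_field == 2047


def test_predict_range_and_determinism(rng):
    model = DivideModel(MOTIFS, ModelConfig(hidden_channels=8, n_layers=4), seed=3)
    x = featurize(random_seq(rng, 120), MOTIFS)
    s1, s2 = model.predict(x), model.predict(x)
    assert np.all((s1 > 0) & (s1 < 1))
    assert np.array_equal(s1, s2)


def test_predict_rejects_wrong_feature_width(rng):
    model = DivideModel(MOTIFS, ModelConfig(hidden_channels=8, n_layers=4), seed=3)
    with pytest.raises(ValueError, match="width"):
        model.predict(np.zeros((10, 9)))


def test_gradients_match_finite_differences(rng):
    model = DivideModel(MOTIFS, ModelConfig(hidden_channels=6, n_layers=4), seed=1)
    for lay in model.layers:
        lay["a"][:] = 0.3
    model.head_w = rng.normal(size=model.head_w.shape) * 0.1
    seq = random_seq(rng, 40)
    ex = TrainingExample(seq, (12, 30), frozenset(), "t", 0)
    l0, grads = _example_loss_and_grads(model, ex, seq, 0.5)
    params = model.parameters()
    eps = 1e-6
    checks = [(0, (0, 1, 2)), (6, (1, 3, 4)), (8, (0,)), (12, (2,))]
    for pi, idx in checks:
        params[pi][idx] += eps
        l1, _ = _example_loss_and_grads(model, ex, seq, 0.5)
        params[pi][idx] -= eps
        num = (l1 - l0) / eps
        assert num == pytest.approx(grads[pi][idx], rel=1e-3, abs=1e-7)


def test_receptive_field_exceeds_1000(rng):
    """Gradient masking: the score at the centre of a long sequence has a
    nonzero input gradient over more than 1000 positions."""
    model = DivideModel(MOTIFS, seed=2)
    for lay in model.layers:
        lay["a"][:] = 0.5
    model.head_w = rng.normal(size=model.head_w.shape) * 0.05
    n = 2100
    x = featurize(random_seq(rng, n), MOTIFS)
    g = model.input_gradient(x, position=n // 2)
    touched = np.flatnonzero(np.abs(g).sum(axis=1) > 0)
    assert touched.max() - touched.min() + 1 > 1000


def test_single_example_overfit(rng):
    """Capacity sanity: 500 steps on one short example drive the loss
    below 0.05 per position."""
    seq = random_seq(rng, 60)
    ex = TrainingExample(seq, (20, 40), frozenset(), "t", 0)
    model = DivideModel(MOTIFS, ModelConfig(), seed=7)
    opt = _Adam([p.shape for p in model.parameters()],
                lr=TrainConfig().learning_rate)
    for _ in range(500):
        l, g = _example_loss_and_grads(model, ex, seq, 0.5)
        model.set_parameters(opt.step(model.parameters(), g))
    assert l < 0.05 * len(seq)


def _tiny_examples(rng, n_examples=24):
    out = []
    for _ in range(n_examples):
        n = int(rng.integers(60, 140))
        cuts = tuple(sorted(rng.choice(np.arange(10, n - 10), 2, replace=False).tolist()))
        out.append(TrainingExample(random_seq(rng, n), cuts, frozenset(), "t", 0))
    return out


def test_training_reduces_loss_and_checkpoints(rng):
    examples = _tiny_examples(rng)
    model, log = train(
        examples,
        ModelConfig(hidden_channels=16, n_layers=6),
        TrainConfig(epochs=12, seed=7, batch_size=4),
        motifs=MOTIFS,
    )
    epochs = log["epochs"]
    assert epochs[-1]["train_loss"] < epochs[0]["train_loss"]
    assert log["best_val_loss"] <= min(e["val_loss"] for e in epochs)
    assert log["config"]["lam"] == 0.5
    assert log["config"]["n_layers"] == 6
    assert log["config"]["kernel_size"] == 3


def test_training_is_bit_reproducible(rng):
    examples = _tiny_examples(rng, 10)
    kw = dict(
        mconf=ModelConfig(hidden_channels=8, n_layers=4),
        tconf=TrainConfig(epochs=3, seed=11, batch_size=4),
        motifs=MOTIFS,
    )
    m1, _ = train(examples, **kw)
    m2, _ = train(examples, **kw)
    for p1, p2 in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(p1, p2)


def test_train_rejects_empty_dataset():
    with pytest.raises(ValueError):
        train([], ModelConfig(), TrainConfig())


def test_save_load_roundtrip_and_schema_guard(tmp_path, rng):
    model = DivideModel(MOTIFS, ModelConfig(hidden_channels=8, n_layers=4), seed=5)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = DivideModel.load(path)
    x = featurize(random_seq(rng, 50), MOTIFS)
    assert np.array_equal(model.predict(x), loaded.predict(x))
    with pytest.raises(ValueError, match="schema"):
        DivideModel.load(path, expected_motifs=load_default_motifs())
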