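"""The 12-layer CNN: shape algebra, seeded construction, analytic gradients,
training dynamics, and learnability of the synthetic five-class task."""

import dataclasses

import numpy as np
import pytest

from ecgbeats import dataset as ds
from ecgbeats.model import (
    ArchitectureSpec,
    LayerSpec,
    NonFiniteLossError,
    ShapeMismatchError,
    TrainConfig,
    build_model,
    conv_out_len,
    default_architecture,
    learning_rate,
    pool_out_len,
    predict,
    shape_chain,
    train,
)
from ecgbeats.synthetic import NoiseSpec, generate_balanced_dataset

EXPECTED_CHAIN = [
    (16, 360), (16, 179), (32, 179), (32, 89), (64, 89), (64, 44),
    (128, 44), (128, 21), (128, 21), (35,), (5,), (5,),
]


def _no_dropout_arch():
    arch = default_architecture()
    layers = tuple(
        dataclasses.replace(l, rate=0.0) if l.kind == "dropout" else l
        for l in arch.layers
    )
    return ArchitectureSpec(layers=layers, expected_shapes=arch.expected_shapes)


# -- output-length algebra ---------------------------------------------------

@pytest.mark.parametrize(
    "n,k,s,pad,expected",
    [(360, 13, 1, "same", 360), (179, 15, 1, "same", 179),
     (89, 17, 1, "same", 89), (44, 19, 1, "same", 44),
     (7, 7, 1, "valid", 1), (10, 3, 2, "valid", 4), (10, 3, 2, "same", 5)],
)
def test_conv_out_len(n, k, s, pad, expected):
    assert conv_out_len(n, k, s, pad) == expected


def test_conv_out_len_valid_kernel_too_large():
    with pytest.raises(ValueError):
        conv_out_len(5, 7, 1, "valid")


@pytest.mark.parametrize("n,expected", [(360, 179), (179, 89), (89, 44), (44, 21)])
def test_pool_out_len(n, expected):
    assert pool_out_len(n) == expected


def test_pool_input_shorter_than_kernel_is_error():
    with pytest.raises(ValueError):
        pool_out_len(2)


# -- construction ------------------------------------------------------------

def test_shape_chain_matches_declared_architecture():
    arch = default_architecture()
    assert shape_chain(arch) == EXPECTED_CHAIN
    model = build_model(arch, seed=0)
    assert model.output_shapes == EXPECTED_CHAIN


def test_flattened_feature_count_is_2688():
    model = build_model(seed=0)
    dense = [l for l in model.layers if hasattr(l, "l2_factor") and l.l2_factor > 0]
    assert dense[0].W.shape == (21 * 128, 35)
    assert dense[1].W.shape == (35, 5)


def test_wrong_declared_shapes_fail_at_build():
    arch = default_architecture()
    bad = ArchitectureSpec(
        layers=arch.layers,
        expected_shapes=arch.expected_shapes[:-1] + ((7,),),
    )
    with pytest.raises(ShapeMismatchError):
        build_model(bad, seed=0)


def test_same_seed_same_initial_weights():
    a, b = build_model(seed=11), build_model(seed=11)
    c = build_model(seed=12)
    for (_, _, la, va, _), (_, _, lb, vb, _) in zip(a.parameters(), b.parameters()):
        assert np.array_equal(va, vb)
    assert any(
        not np.array_equal(va, vc)
        for (_, _, _, va, _), (_, _, _, vc, _) in zip(a.parameters(), c.parameters())
    )


# -- inference ---------------------------------------------------------------

def test_softmax_outputs_are_probabilities():
    model = build_model(seed=0)
    X = np.random.default_rng(0).normal(size=(7, 360)).astype(np.float32)
    labels, probs = predict(model, X)
    assert probs.shape == (7, 5)
    assert np.all(probs >= 0) and np.all(probs <= 1)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.array_equal(labels, probs.argmax(axis=1))


def test_inference_deterministic_on_duplicates():
    model = build_model(seed=0)
    x = np.random.default_rng(1).normal(size=360).astype(np.float32)
    X = np.tile(x, (6, 1))
    _, probs = predict(model, X)
    assert np.allclose(probs, probs[0], atol=0)


def test_batch_permutation_equivariance():
    model = build_model(seed=3)
    X = np.random.default_rng(2).normal(size=(20, 360)).astype(np.float32)
    perm = np.random.default_rng(3).permutation(20)
    _, p1 = predict(model, X)
    _, p2 = predict(model, X[perm])
    assert np.allclose(p1[perm], p2, atol=1e-6)


def test_wrong_segment_length_is_labeled_error():
    model = build_model(seed=0)
    with pytest.raises(ValueError):
        predict(model, np.zeros((2, 100), dtype=np.float32))


# -- training ----------------------------------------------------------------

def test_learning_rate_schedule():
    cfg = TrainConfig()
    assert learning_rate(cfg, 1) == pytest.approx(1e-3)
    assert learning_rate(cfg, 20) == pytest.approx(1e-3)
    assert learning_rate(cfg, 21) == pytest.approx(1e-4)
    assert learning_rate(cfg, 41) == pytest.approx(1e-5)


def test_zero_learning_rate_keeps_loss_constant():
    model = build_model(_no_dropout_arch(), seed=0)
    X = np.random.default_rng(0).normal(size=(36, 360)).astype(np.float32)
    y = np.random.default_rng(1).integers(0, 5, 36)
    fit = train(model, X, y, TrainConfig(epochs=3, initial_lr=0.0, seed=0, shuffle=False))
    assert fit.loss_trace[0] == pytest.approx(fit.loss_trace[-1], abs=1e-7)


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        train(build_model(seed=0), np.zeros((0, 360)), np.zeros(0, dtype=int))


def test_gradients_match_numerical_differentiation():
    """Analytic backprop agrees with central differences on a 4-sample batch."""
    model = build_model(default_architecture(), seed=7, dtype=np.float64)
    rng = np.random.default_rng(0)
    X = rng.normal(size=(4, 360))
    y = np.array([0, 1, 2, 3])
    base_l2 = 1e-4

    def full_loss():
        probs = model.forward_proba(X, training=False)
        ce = -np.mean(np.log(probs[np.arange(4), y]))
        reg = sum(
            0.5 * getattr(l, "l2_factor", 0.0) * base_l2 * np.sum(l.W**2)
            for l in model.layers
            if hasattr(l, "W")
        )
        return ce + reg

    model.loss_and_grads(X, y, base_l2=base_l2, training=False)
    params = list(model.parameters())
    grads = [getattr(layer, gname).copy() for _, _, layer, _, gname in params]
    picker = np.random.default_rng(1)
    n_checked = 0
    for (li, name, layer, value, gname), g in zip(params, grads):
        flat = value.ravel()
        for _ in range(2):
            i = int(picker.integers(flat.size))
            old = flat[i]
            eps = 1e-6
            flat[i] = old + eps
            lp = full_loss()
            flat[i] = old - eps
            lm = full_loss()
            flat[i] = old
            numeric = (lp - lm) / (2 * eps)
            analytic = g.ravel()[i]
            assert abs(numeric - analytic) <= 1e-4 * max(1.0, abs(numeric))
            n_checked += 1
    assert n_checked >= 10


def test_training_learns_separable_synthetic_task():
    """On mildly noisy synthetic beats the network reaches the accuracy a
    nearest-centroid oracle proves attainable."""
    pairs = generate_balanced_dataset(
        200, noise=NoiseSpec(white_sd=0.05), seed=21
    )
    segs = [s for rec, _ in pairs for s in ds.segment_beats(rec).segments]
    X, y = ds.segments_to_arrays(segs)
    rng = np.random.default_rng(5)
    order = rng.permutation(len(X))
    held = order[:100]
    fit_idx = order[100:]
    model = build_model(seed=1)
    fit = train(model, X[fit_idx], y[fit_idx], TrainConfig(epochs=20, seed=2))
    assert fit.loss_trace[-1] < fit.loss_trace[0]
    pred_tr, _ = predict(model, X[fit_idx])
    assert (pred_tr == y[fit_idx]).mean() >= 0.95
    pred_te, _ = predict(model, X[held])
    assert (pred_te == y[held]).mean() >= 0.90


def test_nonfinite_loss_aborts_with_diagnostics():
    model = build_model(seed=0)
    X = np.random.default_rng(0).normal(size=(8, 360)).astype(np.float32)
    y = np.zeros(8, dtype=int)
    # poison a weight to force a non-finite forward pass
    for layer in model.layers:
        if hasattr(layer, "W"):
            layer.W[0, 0] = np.nan
            break
    with pytest.raises(NonFiniteLossError):
        train(model, X, y, TrainConfig(epochs=1, seed=0))


def test_architecture_json_round_trip():
    arch = default_architecture()
    back = ArchitectureSpec.from_json(arch.to_json())
    assert back.layers == arch.layers
    assert shape_chain(back) == shape_chain(arch)
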