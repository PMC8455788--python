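import numpy as np
import pytest

from cystseg import (
    BinaryMask3D,
    EnsemblePredictor,
    MockOraclePredictor,
    SemanticMap3D,
    TrainConfig,
    Volume3D,
    build_inception_unet,
    encode_dilation,
    generate_phantom,
    jaccard_index,
    load_weights,
    majority_vote,
    predict_exam,
    save_weights,
    stack_slices,
    train_reduced,
)
from cystseg.edgecore import BACKGROUND, CORE, EDGE
from cystseg.phantom import PhantomSpec


# ---------------------------------------------------------------------------
# stack_slices
# ---------------------------------------------------------------------------


def test_stack_slices_zero_padding_and_channels(small_exam):
    vol, kidney, _ = small_exam
    Z = vol.shape[2]
    first = stack_slices(vol, kidney, 0)
    assert first.shape == vol.shape[:2] + (4,)
    assert not first[:, :, 0].any()  # z-1 out of range
    last = stack_slices(vol, kidney, Z - 1)
    assert not last[:, :, 2].any()  # z+1 out of range
    mid = stack_slices(vol, kidney, Z // 2)
    np.testing.assert_array_equal(mid[:, :, 3], kidney.data[:, :, Z // 2])
    assert 0.0 <= mid[:, :, 1].min() and mid[:, :, 1].max() <= 1.0  # normalised
    with pytest.raises(ValueError):
        stack_slices(vol, kidney, Z)


def test_stack_slices_constant_volume_interior():
    vol = Volume3D(np.ones((8, 8, 6), np.float32), (1, 1, 1))
    kidney = BinaryMask3D(np.ones((8, 8, 6), np.uint8), (1, 1, 1))
    s = stack_slices(vol, kidney, 3)
    np.testing.assert_array_equal(s[:, :, 0], s[:, :, 1])
    np.testing.assert_array_equal(s[:, :, 1], s[:, :, 2])


# ---------------------------------------------------------------------------
# jaccard_index
# ---------------------------------------------------------------------------


def test_jaccard_values():
    a = np.zeros((4, 4, 4))
    a[:2, 0, 0] = 1
    assert jaccard_index(a, a) == 1.0
    b = np.zeros((4, 4, 4))
    b[2:, 0, 0] = 1
    assert jaccard_index(a, b) == 0.0
    p = np.zeros((10, 1, 1))
    p[:4] = 1
    r = np.zeros((10, 1, 1))
    r[:8] = 1
    assert jaccard_index(p, r) == pytest.approx(0.5)
    assert jaccard_index(np.zeros((3, 3, 3)), np.zeros((3, 3, 3))) == 1.0
    with pytest.raises(ValueError):
        jaccard_index(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        jaccard_index(np.full((2, 2), 2.0), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# inception U-Net
# ---------------------------------------------------------------------------


def test_unet_probability_contract_and_determinism():
    net = build_inception_unet(base=2, depth=2, seed=7)
    rng = np.random.default_rng(0)
    stack = rng.random((16, 16, 4)).astype(np.float32)
    p = net(stack)
    assert p.shape == (16, 16, 3)
    assert (p >= 0).all()
    np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-5)
    # same seed -> identical weights -> identical outputs
    p2 = build_inception_unet(base=2, depth=2, seed=7)(stack)
    np.testing.assert_array_equal(p, p2)
    assert not np.array_equal(p, build_inception_unet(base=2, depth=2, seed=8)(stack))
    with pytest.raises(ValueError):
        build_inception_unet(depth=1)


def test_train_config_defaults_and_validation():
    cfg = TrainConfig()
    assert (cfg.epochs, cfg.batch_size, cfg.learning_rate) == (200, 6, 1e-3)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0)


def test_overfit_smoke_and_reproducible_trajectory():
    """Loss on a single tiny phantom decreases in trend, and a fixed seed
    reproduces the loss trajectory exactly."""
    spec = PhantomSpec(shape=(64, 64, 12), spacing=(2.0, 2.0, 4.0), n_cysts=10, seed=3)
    vol, kidney, truth = generate_phantom(spec)
    sem = encode_dilation(truth)
    cfg = TrainConfig(epochs=8, batch_size=6, learning_rate=1e-3, seed=0)
    net = train_reduced(build_inception_unet(base=2, dropout=0.0, seed=0), [(vol, kidney, sem)], cfg)
    assert net.history[-1] < net.history[0]
    net2 = train_reduced(build_inception_unet(base=2, dropout=0.0, seed=0), [(vol, kidney, sem)], cfg)
    np.testing.assert_allclose(net.history, net2.history, rtol=1e-6)
    with pytest.raises(ValueError):
        train_reduced(net, [], cfg)


def test_weight_round_trip(tmp_path):
    net = build_inception_unet(base=2, depth=2, seed=5)
    save_weights(net, tmp_path / "m.npz")
    back = load_weights(tmp_path / "m.npz")
    stack = np.random.default_rng(1).random((16, 16, 4)).astype(np.float32)
    np.testing.assert_array_equal(net(stack), back(stack))


# ---------------------------------------------------------------------------
# majority voting
# ---------------------------------------------------------------------------


def _sem(arr):
    return SemanticMap3D(np.asarray(arr, dtype=np.uint8), (1, 1, 1))


def test_majority_vote_rules():
    shape = (2, 2, 1)
    a = _sem(np.full(shape, CORE))
    assert (majority_vote([a, a, a]).data == CORE).all()  # unanimity

    b = _sem(np.full(shape, EDGE))
    out = majority_vote([b, b, a])
    assert (out.data == EDGE).all()  # 2-1 majority

    # 1-1-1 split with equal summed probabilities: core precedence wins
    p_bg = np.zeros(shape + (3,)); p_bg[..., BACKGROUND] = 1.0
    p_edge = np.zeros(shape + (3,)); p_edge[..., EDGE] = 1.0
    p_core = np.zeros(shape + (3,)); p_core[..., CORE] = 1.0
    out = majority_vote([p_bg, p_edge, p_core])
    assert (out.data == CORE).all()  # equal sums -> core precedence

    with pytest.raises(ValueError):
        majority_vote([a, b, _sem(np.zeros(shape))])  # 1-1-1 hard labels only


def test_majority_vote_summed_probability_tiebreak():
    shape = (1, 1, 1)
    mk = lambda bg, e, c: np.array([[[ [bg, e, c] ]]], dtype=float)
    # votes (background, edge, core); summed probs favour edge
    out = majority_vote([mk(0.5, 0.4, 0.1), mk(0.1, 0.8, 0.1), mk(0.3, 0.3, 0.4)])
    assert out.data[0, 0, 0] == EDGE


# ---------------------------------------------------------------------------
# predict_exam
# ---------------------------------------------------------------------------


def test_predict_exam_oracle_identity(small_exam):
    vol, kidney, truth = small_exam
    sem = encode_dilation(truth)
    ens = EnsemblePredictor([MockOraclePredictor(sem)] * 3)
    out = predict_exam(ens, vol, kidney)
    inside = kidney.data > 0
    assert np.array_equal(out.data[inside], sem.data[inside])
    assert (out.data[~inside] == BACKGROUND).all()


def test_predict_exam_masks_everything_outside_kidney(small_exam):
    vol, _, truth = small_exam
    sem = encode_dilation(truth)
    empty = BinaryMask3D(np.zeros(vol.shape, np.uint8), vol.spacing)
    out = predict_exam(EnsemblePredictor([MockOraclePredictor(sem)] * 3), vol, empty)
    assert out.data.max() == BACKGROUND


def test_vote_degeneracy_three_copies_equal_single_member():
    spec = PhantomSpec(shape=(32, 32, 8), spacing=(2, 2, 4), n_cysts=4, seed=9)
    vol, kidney, truth = generate_phantom(spec)
    net = build_inception_unet(base=2, depth=2, seed=1)
    single = predict_exam(EnsemblePredictor([net]), vol, kidney)
    triple = predict_exam(EnsemblePredictor([net] * 3), vol, kidney)
    np.testing.assert_array_equal(single.data, triple.data)


def test_ensemble_needs_members():
    with pytest.raises(ValueError):
        EnsemblePredictor([])
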