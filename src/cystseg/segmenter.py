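"""Slice-wise 3-class predictor: inception U-Net, training, ensembling.

The predictor contract is deliberately framework-free: a *slice predictor*
is any callable mapping a 4-channel 2D stack (X, Y, 4) — the previous, the
current and the next MR slice plus the kidney mask of the current slice —
to per-voxel class probabilities (X, Y, 3) that sum to 1.  The bundled
implementation is an inception U-Net written on the small numpy layer kit in
:mod:`cystseg._nn`: each encoder stage is an inception block (parallel 1x1 /
3x3 / 5x5 convolution branches, concatenated) followed by a stride-2
convolution and dropout; the decoder mirrors it with nearest-neighbour
up-sampling, skip concatenations and inception blocks; a final 1x1
convolution and softmax produce the 3 class maps.

Training minimizes ``1 - J`` where ``J`` is the smoothed soft Jaccard index
averaged over the edge and core classes.  Full-scale training on clinical
exams is out of scope; :func:`train_reduced` is the desk-scale analogue used
to overfit small phantoms and to verify the optimisation plumbing.

An :class:`EnsemblePredictor` combines (typically three) slice predictors by
voxel-wise majority voting; :class:`MockOraclePredictor` replays an encoded
ground truth so the full pipeline is exercisable without trained weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, Conv2D, Dropout, Param, ReLU, Upsample2x, softmax_channels
from .edgecore import BACKGROUND, CORE, EDGE, SemanticMap3D
from .io_volumes import BinaryMask3D, Volume3D

__all__ = [
    "TrainConfig",
    "EnsemblePredictor",
    "MockOraclePredictor",
    "InceptionUNet",
    "build_inception_unet",
    "normalize_intensity",
    "stack_slices",
    "jaccard_index",
    "train_reduced",
    "select_ensemble",
    "majority_vote",
    "predict_exam",
    "save_weights",
    "load_weights",
]

# Class precedence used whenever a vote or argmax ties: core > edge > background.
_PRECEDENCE = (CORE, EDGE, BACKGROUND)


@dataclass
class TrainConfig:
    """Optimisation settings (Adam).  Defaults are the production recipe:
    200 epochs, batch size 6, learning rate 1e-3."""

    epochs: int = 200
    batch_size: int = 6
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


# ---------------------------------------------------------------------------
# Intensity normalisation and input stacking
# ---------------------------------------------------------------------------


def normalize_intensity(mri: Volume3D, kidney: BinaryMask3D) -> Volume3D:
    """Rescale a volume to [0, 1] by its 1st-99th percentile inside the
    kidney mask (whole volume if the mask is empty), clipping outliers.
    Makes the predictor insensitive to field-strength intensity scale."""
    data = mri.data
    region = data[kidney.data > 0] if kidney.data.any() else data
    lo, hi = np.percentile(region, (1.0, 99.0))
    if hi <= lo:
        hi = lo + 1.0
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return Volume3D(out.astype(np.float32), mri.spacing, mri.affine)


def stack_slices(
    mri: Volume3D, kidney: BinaryMask3D, z: int, normalized: bool = False
) -> np.ndarray:
    """Build the 4-channel input for slice ``z``.

    Channels are ``[slice z-1, slice z, slice z+1, kidney mask at z]``;
    out-of-range neighbours are all-zero planes.  Unless ``normalized`` is
    set the volume is percentile-normalised first (see
    :func:`normalize_intensity`).
    """
    if mri.shape != kidney.shape:
        raise ValueError(f"grid mismatch: {mri.shape} vs {kidney.shape}")
    Z = mri.shape[2]
    if not 0 <= z < Z:
        raise ValueError(f"slice index {z} outside [0, {Z})")
    vol = mri if normalized else normalize_intensity(mri, kidney)
    X, Y, _ = vol.shape
    stack = np.zeros((X, Y, 4), dtype=np.float32)
    if z - 1 >= 0:
        stack[:, :, 0] = vol.data[:, :, z - 1]
    stack[:, :, 1] = vol.data[:, :, z]
    if z + 1 < Z:
        stack[:, :, 2] = vol.data[:, :, z + 1]
    stack[:, :, 3] = kidney.data[:, :, z]
    return stack


# ---------------------------------------------------------------------------
# Jaccard index / loss
# ---------------------------------------------------------------------------


def jaccard_index(p, r, smooth: float = 0.0) -> float:
    """Soft Jaccard index J = sum(p*r) / (sum(p) + sum(r) - sum(p*r)).

    ``p`` may be a soft map in [0, 1]; ``r`` is binary.  ``smooth`` is added
    to numerator and denominator (used as eps=1 by the training loss); with
    ``smooth=0`` an empty-vs-empty pair scores 1 by convention.
    """
    pa = np.asarray(p.data if hasattr(p, "data") else p, dtype=np.float64)
    ra = np.asarray(r.data if hasattr(r, "data") else r, dtype=np.float64)
    if pa.shape != ra.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {ra.shape}")
    if pa.size and (pa.min() < 0 or pa.max() > 1):
        raise ValueError("p must lie in [0, 1] per voxel")
    inter = float((pa * ra).sum())
    denom = float(pa.sum() + ra.sum() - inter)
    if denom + smooth == 0:
        return 1.0
    return (inter + smooth) / (denom + smooth)


def _jaccard_loss_and_grad(probs: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Loss 1 - mean(J_edge, J_core) over a batch, with dL/dprobs.

    probs, targets: (N, 3, H, W); targets one-hot.
    """
    g = np.zeros_like(probs)
    js = []
    for c in (EDGE, CORE):
        pc, rc = probs[:, c], targets[:, c]
        inter = float((pc * rc).sum())
        num = inter + eps
        den = float(pc.sum() + rc.sum()) - inter + eps
        js.append(num / den)
        # dJ/dp = (r*den - num*(1-r)) / den^2 ; L = 1 - (J_e + J_c)/2
        g[:, c] = -0.5 * (rc * den - num * (1.0 - rc)) / den**2
    return 1.0 - 0.5 * sum(js), g


# ---------------------------------------------------------------------------
# Inception U-Net
# ---------------------------------------------------------------------------


class _InceptionBlock:
    """Parallel 1x1 / 3x3 / 5x5 convolutions, concatenated, then ReLU."""

    def __init__(self, cin: int, branch: int, rng):
        self.convs = [Conv2D(cin, branch, k, 1, rng) for k in (1, 3, 5)]
        self.relu = ReLU()
        self.branch = branch

    @property
    def params(self):
        return [p for c in self.convs for p in c.params]

    @property
    def cout(self) -> int:
        return 3 * self.branch

    def forward(self, x):
        return self.relu.forward(np.concatenate([c.forward(x) for c in self.convs], axis=1))

    def backward(self, dout):
        d = self.relu.backward(dout)
        b = self.branch
        dx = None
        for i, c in enumerate(self.convs):
            di = c.backward(d[:, i * b : (i + 1) * b])
            dx = di if dx is None else dx + di
        return dx


class InceptionUNet:
    """Slice predictor: (X, Y, 4) stack -> (X, Y, 3) class probabilities.

    ``base`` is the per-branch channel width of the first inception block
    (stage width = 3*base, doubling at each of ``depth`` down-samplings).
    Spatial input sizes must be divisible by ``2**depth``.
    """

    needs_slice_index = False

    def __init__(
        self,
        in_channels: int = 4,
        n_classes: int = 3,
        base: int = 8,
        depth: int = 2,
        dropout: float = 0.1,
        seed: int = 0,
    ):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if base < 1:
            raise ValueError("base must be >= 1")
        self.config = dict(
            in_channels=in_channels, n_classes=n_classes, base=base,
            depth=depth, dropout=dropout, seed=seed,
        )
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc: list[_InceptionBlock] = []
        self.down: list[Conv2D] = []
        self.down_relu = [ReLU() for _ in range(depth)]
        self.drop = [Dropout(dropout, np.random.default_rng(rng.integers(2**31))) for _ in range(depth)]
        cin = in_channels
        widths = []
        for d in range(depth):
            blk = _InceptionBlock(cin, base * 2**d, rng)
            self.enc.append(blk)
            widths.append(blk.cout)
            self.down.append(Conv2D(blk.cout, blk.cout, 3, 2, rng))
            cin = blk.cout
        self.bottleneck = _InceptionBlock(cin, base * 2**depth, rng)
        cur = self.bottleneck.cout
        self.up: list[Upsample2x] = []
        self.upconv: list[Conv2D] = []
        self.up_relu = [ReLU() for _ in range(depth)]
        self.dec: list[_InceptionBlock] = []
        for d in reversed(range(depth)):
            self.up.append(Upsample2x())
            self.upconv.append(Conv2D(cur, widths[d], 3, 1, rng))
            self.dec.append(_InceptionBlock(2 * widths[d], base * 2**d, rng))
            cur = self.dec[-1].cout
        self.final = Conv2D(cur, n_classes, 1, 1, rng)
        self.history: list[float] = []

    @property
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for blk, dn in zip(self.enc, self.down):
            ps += blk.params + dn.params
        ps += self.bottleneck.params
        for uc, blk in zip(self.upconv, self.dec):
            ps += uc.params + blk.params
        ps += self.final.params
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, H, W) -> per-voxel class probabilities (N, 3, H, W)."""
        n, c, h, w = x.shape
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(f"spatial size {h}x{w} not divisible by {f}")
        skips = []
        for blk, dn, rl, dp in zip(self.enc, self.down, self.down_relu, self.drop):
            x = blk.forward(x)
            skips.append(x)
            x = dp.forward(rl.forward(dn.forward(x)), train)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, uc, rl, blk, skip in zip(
            self.up, self.upconv, self.up_relu, self.dec, reversed(skips)
        ):
            x = rl.forward(uc.forward(up.forward(x)))
            self._skip_channels.append(x.shape[1])
            x = blk.forward(np.concatenate([x, skip], axis=1))
        z = self.final.forward(x)
        self._probs = softmax_channels(z)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backprop from dL/dprobs through softmax and all layers."""
        p = self._probs
        dz = p * (dprobs - (dprobs * p).sum(axis=1, keepdims=True))
        dx = self.final.backward(dz)
        # decoder stage i consumed skips[depth - 1 - i]
        dskip = [None] * self.depth
        for i in reversed(range(self.depth)):
            dcat = self.dec[i].backward(dx)
            nch = self._skip_channels[i]
            dskip[self.depth - 1 - i] = dcat[:, nch:]
            dx = self.up[i].backward(
                self.upconv[i].backward(self.up_relu[i].backward(dcat[:, :nch]))
            )
        dx = self.bottleneck.backward(dx)
        for d in reversed(range(self.depth)):
            ds = self.down[d].backward(
                self.down_relu[d].backward(self.drop[d].backward(dx))
            )
            dx = self.enc[d].backward(ds + dskip[d])

    def __call__(self, stack: np.ndarray) -> np.ndarray:
        probs = self.forward(stack.transpose(2, 0, 1)[None].astype(np.float32))
        return probs[0].transpose(1, 2, 0)


def build_inception_unet(
    base: int = 8, depth: int = 2, dropout: float = 0.1, seed: int = 0
) -> InceptionUNet:
    """Construct an untrained inception U-Net slice predictor."""
    return InceptionUNet(base=base, depth=depth, dropout=dropout, seed=seed)


def save_weights(net: InceptionUNet, path) -> None:
    """Serialize one predictor (config + parameters) to a single .npz file."""
    arrays = {f"p{i}": p.value for i, p in enumerate(net.params)}
    np.savez(path, config=json.dumps(net.config), **arrays)


def load_weights(path) -> InceptionUNet:
    with np.load(path, allow_pickle=False) as f:
        net = InceptionUNet(**json.loads(str(f["config"])))
        for i, p in enumerate(net.params):
            p.value[...] = f[f"p{i}"]
    return net


# ---------------------------------------------------------------------------
# Training and member selection
# ---------------------------------------------------------------------------


def _exam_to_samples(mri: Volume3D, kidney: BinaryMask3D, sem: SemanticMap3D):
    """All (stack, one-hot target) pairs of one exam, normalised once."""
    if not (mri.shape == kidney.shape == sem.shape):
        raise ValueError("exam grids do not match")
    vol = normalize_intensity(mri, kidney)
    xs, ys = [], []
    for z in range(mri.shape[2]):
        xs.append(stack_slices(vol, kidney, z, normalized=True).transpose(2, 0, 1))
        tgt = sem.data[:, :, z]
        onehot = np.zeros((3,) + tgt.shape, dtype=np.float32)
        for c in (BACKGROUND, EDGE, CORE):
            onehot[c] = tgt == c
        ys.append(onehot)
    return xs, ys


def train_reduced(
    predictor: InceptionUNet, exams, cfg: TrainConfig | None = None
) -> InceptionUNet:
    """Desk-scale training of a slice predictor on (mri, kidney, semantic)
    exams, minimising 1 - smoothed soft Jaccard (mean of edge and core).

    Per-epoch mean losses are recorded in ``predictor.history``.  With a
    fixed ``cfg.seed`` the trajectory is reproducible.
    """
    cfg = cfg or TrainConfig()
    exams = list(exams)
    if not exams:
        raise ValueError("at least one training exam is required")
    xs, ys = [], []
    for mri, kidney, sem in exams:
        x, y = _exam_to_samples(mri, kidney, sem)
        xs += x
        ys += y
    X = np.stack(xs)
    Y = np.stack(ys)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(predictor.params, lr=cfg.learning_rate)
    n = len(X)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = predictor.forward(X[idx], train=True)
            loss, g = _jaccard_loss_and_grad(probs, Y[idx], eps=1.0)
            opt.zero_grad()
            predictor.backward(g.astype(np.float32))
            opt.step()
            losses.append(loss)
        predictor.history.append(float(np.mean(losses)))
    return predictor


def _hard_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax over the last (class) axis with core > edge > background ties."""
    reordered = probs[..., list(_PRECEDENCE)]
    pick = reordered.argmax(axis=-1)
    return np.asarray(_PRECEDENCE, dtype=np.uint8)[pick]


def select_ensemble(predictors, val_exams, keep: int = 3) -> "EnsemblePredictor":
    """Rank candidate predictors (e.g. the four cross-validation folds) by
    mean edge/core Jaccard on validation exams; keep the best ``keep``."""
    predictors = list(predictors)
    if len(predictors) < keep:
        raise ValueError(f"need at least {keep} candidates, got {len(predictors)}")
    scores = []
    for member in predictors:
        js = []
        for mri, kidney, sem in val_exams:
            pred = predict_exam(EnsemblePredictor([member]), mri, kidney)
            for c in (EDGE, CORE):
                js.append(jaccard_index(pred.data == c, sem.data == c))
        scores.append(float(np.mean(js)))
    order = np.argsort(scores)[::-1][:keep]
    return EnsemblePredictor([predictors[i] for i in sorted(order)])


# ---------------------------------------------------------------------------
# Ensembling and whole-exam prediction
# ---------------------------------------------------------------------------


@dataclass
class EnsemblePredictor:
    """Ordered slice predictors combined by voxel-wise majority voting."""

    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = list(self.members)
        if not self.members:
            raise ValueError("an ensemble needs at least one member")


class MockOraclePredictor:
    """Replays an encoded ground-truth semantic map slice by slice.

    Lets the full pipeline (stacking, voting, decoding) run without trained
    weights; used for end-to-end plumbing tests and the ``--mock-oracle``
    mode of the CLI.
    """

    needs_slice_index = True

    def __init__(self, truth: SemanticMap3D):
        self.truth = truth

    def __call__(self, stack: np.ndarray, z: int) -> np.ndarray:
        tgt = self.truth.data[:, :, z]
        probs = np.zeros(tgt.shape + (3,), dtype=np.float32)
        for c in (BACKGROUND, EDGE, CORE):
            probs[..., c] = tgt == c
        return probs


def _as_probs_and_labels(pred, shape):
    """Normalise one member prediction to (labels, probs-or-None)."""
    if isinstance(pred, SemanticMap3D):
        return pred.data, None
    arr = np.asarray(pred)
    if arr.shape == shape + (3,):
        return _hard_labels(arr), arr
    if arr.shape == shape:
        return arr.astype(np.uint8), None
    raise ValueError(f"prediction of shape {arr.shape} does not match grid {shape}")


def majority_vote(predictions, spacing=None) -> SemanticMap3D:
    """Voxel-wise majority vote over member predictions.

    ``predictions`` is a sequence of :class:`SemanticMap3D`, hard label
    arrays, or probability arrays of shape (..., 3).  The class voted for by
    a strict majority wins; a full tie (e.g. a 1-1-1 split of three members)
    is resolved by the largest summed probability when probabilities are
    available, and remaining ties by the precedence core > edge >
    background.  A tie between hard-label-only members raises.
    """
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to vote on")
    first = predictions[0]
    if spacing is None:
        spacing = getattr(first, "spacing", (1.0, 1.0, 1.0))
    shape = first.data.shape if isinstance(first, SemanticMap3D) else None
    if shape is None:
        arr0 = np.asarray(first)
        shape = arr0.shape[:-1] if arr0.shape[-1] == 3 and arr0.ndim >= 3 else arr0.shape
    counts = np.zeros(shape + (3,), dtype=np.int16)
    prob_sum = np.zeros(shape + (3,), dtype=np.float64)
    have_probs = True
    for pred in predictions:
        labels, probs = _as_probs_and_labels(pred, shape)
        if labels.shape != shape:
            raise ValueError("member predictions are on different grids")
        for c in (BACKGROUND, EDGE, CORE):
            counts[..., c] += labels == c
        if probs is None:
            have_probs = False
        else:
            prob_sum += probs
    winner = _hard_labels(counts.astype(np.float64))
    top = counts.max(axis=-1)
    tied = (counts == top[..., None]).sum(axis=-1) > 1
    if tied.any():
        if not have_probs:
            raise ValueError(
                "tied vote with hard-label members only; probabilities required"
            )
        winner = np.where(tied, _hard_labels(prob_sum), winner)
    return SemanticMap3D(winner.astype(np.uint8), spacing)


def predict_exam(
    ens: EnsemblePredictor, mri: Volume3D, kidney: BinaryMask3D
) -> SemanticMap3D:
    """Run every ensemble member slice-wise over an exam and vote.

    For each z the 4-channel stack is built, each member predicts class
    probabilities for the middle slice, and the per-member volumes are
    combined by :func:`majority_vote`.  Voxels outside the kidney mask are
    forced to background.
    """
    if mri.shape != kidney.shape:
        raise ValueError(f"grid mismatch: {mri.shape} vs {kidney.shape}")
    vol = normalize_intensity(mri, kidney)
    X, Y, Z = mri.shape
    member_probs = []
    for member in ens.members:
        probs = np.zeros((X, Y, Z, 3), dtype=np.float32)
        for z in range(Z):
            stack = stack_slices(vol, kidney, z, normalized=True)
            out = (
                member(stack, z)
                if getattr(member, "needs_slice_index", False)
                else member(stack)
            )
            out = np.asarray(out, dtype=np.float32)
            if out.shape != (X, Y, 3):
                raise ValueError(
                    f"member returned shape {out.shape}, expected {(X, Y, 3)}"
                )
            probs[:, :, z, :] = out
        member_probs.append(probs)
    voted = majority_vote(member_probs, spacing=mri.spacing)
    out = voted.data.copy()
    out[kidney.data == 0] = BACKGROUND
    return SemanticMap3D(out, mri.spacing, mri.affine)
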