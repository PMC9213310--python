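"""Patch-based 3D UNet-like MR-to-CT translation network.

A small encoder-decoder with skip connections maps two-channel (dual-echo)
MR patches to CT patches on the normalized [-1, 1] scale, trained with an
L1 loss and Adam.  The network, its gradients and the optimizer are
implemented directly on numpy arrays (forward/backward per layer, verified
against central-difference gradients in the test suite), which keeps the
whole pipeline runnable on a plain CPU scientific stack.

Full volumes are translated by tiling overlapping patches (stride half a
patch) and averaging the overlaps with uniform weights, which preserves
constant outputs exactly and removes seam artifacts.  A leave-one-out
cross-validation harness trains one model per held-out case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .evaluate import EvalConfig, MetricReport, evaluate_case, cohort_summary, CohortSummary
from .preprocess import (NormalizedVolume, denormalize_ct, extract_patches,
                         augment, normalize_mr, normalize_ct, HU_MIN, HU_MAX)

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TrainedModel",
    "FoldResult",
    "CVResult",
    "UNet3D",
    "build_network",
    "train",
    "predict_volume",
    "loocv",
    "prepare_case",
    "PreparedCase",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the translation network.

    ``in_channels`` is fixed at 2 by the dual-echo input contract.  The
    default ``base_filters=32`` is the full-scale setting; 8 is the
    desk-scale setting used for CPU-sized experiments and tests.
    """

    in_channels: int = 2
    out_channels: int = 1
    levels: int = 3
    base_filters: int = 32
    patch_size: int = 24

    def __post_init__(self) -> None:
        if self.in_channels != 2:
            raise ValueError("the network takes exactly two echo channels")
        if self.levels < 2:
            raise ValueError("need at least 2 resolution levels")
        if self.patch_size % (2 ** (self.levels - 1)) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by "
                f"2^(levels-1) = {2 ** (self.levels - 1)}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  The loss is fixed to L1 (mean absolute
    error on the normalized intensity scale) and the optimizer to Adam."""

    learning_rate: float = 1e-4
    #: optional final learning rate; when set, the rate decays
    #: geometrically per epoch from ``learning_rate`` down to this value
    lr_final: float | None = None
    epochs: int = 20
    batch_size: int = 8
    patches_per_volume: int = 32
    bone_fraction_min: float = 0.8
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1 or self.patches_per_volume < 1:
            raise ValueError("epochs, batch_size and patches_per_volume must be >= 1")


# ---------------------------------------------------------------------------
# Layers (numpy forward/backward)
# ---------------------------------------------------------------------------

@njit(fastmath=True, cache=True)
def _conv3_fwd_kernel(xp, w, b, out):  # pragma: no cover - exercised via _Conv3d
    nb, ci_n = xp.shape[0], xp.shape[1]
    co_n = w.shape[0]
    d_n, h_n, w_n = out.shape[2], out.shape[3], out.shape[4]
    for bb in range(nb):
        for co in range(co_n):
            o = out[bb, co]
            for ci in range(ci_n):
                xc = xp[bb, ci]
                first = ci == 0
                for d in range(d_n):
                    for h in range(h_n):
                        if first:
                            for x in range(w_n):
                                o[d, h, x] = b[co]
                        for kd in range(3):
                            for kh in range(3):
                                row = xc[d + kd, h + kh]
                                w0 = w[co, ci, kd, kh, 0]
                                w1 = w[co, ci, kd, kh, 1]
                                w2 = w[co, ci, kd, kh, 2]
                                for x in range(w_n):
                                    o[d, h, x] += (w0 * row[x] + w1 * row[x + 1]
                                                   + w2 * row[x + 2])


@njit(fastmath=True, cache=True)
def _conv3_dw_kernel(xp, dy, dw):  # pragma: no cover
    nb, ci_n = xp.shape[0], xp.shape[1]
    co_n = dy.shape[1]
    d_n, h_n, w_n = dy.shape[2], dy.shape[3], dy.shape[4]
    for bb in range(nb):
        for co in range(co_n):
            g = dy[bb, co]
            for ci in range(ci_n):
                xc = xp[bb, ci]
                for kd in range(3):
                    for kh in range(3):
                        a0 = 0.0
                        a1 = 0.0
                        a2 = 0.0
                        for d in range(d_n):
                            for h in range(h_n):
                                grow = g[d, h]
                                row = xc[d + kd, h + kh]
                                for x in range(w_n):
                                    gv = grow[x]
                                    a0 += gv * row[x]
                                    a1 += gv * row[x + 1]
                                    a2 += gv * row[x + 2]
                        dw[co, ci, kd, kh, 0] += a0
                        dw[co, ci, kd, kh, 1] += a1
                        dw[co, ci, kd, kh, 2] += a2


@njit(fastmath=True, cache=True)
def _conv3_nobias_kernel(xp, w, out):  # pragma: no cover
    """Gather convolution without bias; used for the input gradient,
    which equals a convolution of the padded output gradient with the
    channel-transposed, spatially flipped kernel."""
    nb, ci_n = xp.shape[0], xp.shape[1]
    co_n = w.shape[0]
    d_n, h_n, w_n = out.shape[2], out.shape[3], out.shape[4]
    for bb in range(nb):
        for co in range(co_n):
            o = out[bb, co]
            for ci in range(ci_n):
                xc = xp[bb, ci]
                first = ci == 0
                for d in range(d_n):
                    for h in range(h_n):
                        if first:
                            for x in range(w_n):
                                o[d, h, x] = 0.0
                        for kd in range(3):
                            for kh in range(3):
                                row = xc[d + kd, h + kh]
                                w0 = w[co, ci, kd, kh, 0]
                                w1 = w[co, ci, kd, kh, 1]
                                w2 = w[co, ci, kd, kh, 2]
                                for x in range(w_n):
                                    o[d, h, x] += (w0 * row[x] + w1 * row[x + 1]
                                                   + w2 * row[x + 2])


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class _Conv3d:
    """3D convolution, kernel 3 (pad 1) or 1 (pad 0), stride 1.

    The k=3 path runs numba-jitted direct-convolution kernels (forward
    and backward), which on a single CPU core are several times faster
    than assembling GEMMs per kernel offset; the 1x1x1 head stays a plain
    matmul.  Only the padded input is cached for the backward pass.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = cin * k**3
        self.k = k
        self.W = _Param(rng.standard_normal((cout, cin, k, k, k)).astype(dtype)
                        * np.sqrt(2.0 / fan_in))
        self.b = _Param(np.zeros(cout, dtype=dtype))
        self._xp = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, Ci, D, H, W = x.shape
        co = self.W.value.shape[0]
        self._shape = (B, Ci, D, H, W)
        if self.k == 3:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
            self._xp = xp
            y = np.empty((B, co, D, H, W), dtype=x.dtype)
            _conv3_fwd_kernel(xp, self.W.value, self.b.value, y)
            return y
        self._xp = x
        n = D * H * W
        y = np.matmul(self.W.value[:, :, 0, 0, 0][None], x.reshape(B, Ci, n))
        y = y.reshape(B, co, D, H, W)
        return y + self.b.value[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Ci, D, H, W = self._shape
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        xp = self._xp
        self._xp = None
        if self.k == 3:
            dy = np.ascontiguousarray(dy)
            _conv3_dw_kernel(xp, dy, self.W.grad)
            # input gradient = gather-conv of padded dy with the
            # channel-transposed, flipped kernel (no scatter, no extra pad buffer)
            w_flip = np.ascontiguousarray(
                self.W.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
            dx = np.empty((B, Ci, D, H, W), dtype=dy.dtype)
            _conv3_nobias_kernel(dyp, w_flip, dx)
            return dx
        n = D * H * W
        dy2 = dy.reshape(B, -1, n)
        x2 = xp.reshape(B, Ci, n)
        self.W.grad[:, :, 0, 0, 0] += np.einsum("bon,bin->oi", dy2, x2,
                                                optimize=True)
        dx = np.matmul(self.W.value[:, :, 0, 0, 0].T[None], dy2)
        return dx.reshape(B, Ci, D, H, W)


class _ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2:
    """2x2x2 max pooling, stride 2."""

    def params(self):
        return []

    def forward(self, x):
        B, C, D, H, W = x.shape
        r = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, D // 2, H // 2, W // 2, 8)
        self._arg = r.argmax(axis=-1)
        self._shape = (B, C, D, H, W)
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        B, C, D, H, W = self._shape
        out = np.zeros((B, C, D // 2, H // 2, W // 2, 8), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2)
        out = out.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(B, C, D, H, W)
        return out


class _ConvTranspose2:
    """Transposed convolution, kernel 2, stride 2 (doubles resolution)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = _Param(rng.standard_normal((cin, cout, 2, 2, 2)).astype(dtype)
                        * np.sqrt(2.0 / cin))
        self.b = _Param(np.zeros(cout, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        B, Ci, D, H, W = x.shape
        co = self.W.value.shape[1]
        self._x = x
        y = np.empty((B, co, 2 * D, 2 * H, 2 * W), dtype=x.dtype)
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    y[:, :, i::2, j::2, k::2] = np.einsum(
                        "bidhw,io->bodhw", x, self.W.value[:, :, i, j, k],
                        optimize=True)
        y += self.b.value[None, :, None, None, None]
        return y

    def backward(self, dy):
        x = self._x
        dx = np.zeros_like(x)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    dsub = dy[:, :, i::2, j::2, k::2]
                    self.W.grad[:, :, i, j, k] += np.einsum(
                        "bidhw,bodhw->io", x, dsub, optimize=True)
                    dx += np.einsum("bodhw,io->bidhw", dsub,
                                    self.W.value[:, :, i, j, k], optimize=True)
        self._x = None
        return dx


class _DoubleConv:
    """conv3 + ReLU, twice."""

    def __init__(self, cin, cout, rng, dtype):
        self.layers = [_Conv3d(cin, cout, 3, rng, dtype), _ReLU(),
                       _Conv3d(cout, cout, 3, rng, dtype), _ReLU()]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet3D:
    """Encoder-decoder with skip connections and a linear 1x1x1 head.

    ``levels`` resolution levels (levels-1 poolings); channel width
    doubles per level from ``base_filters``.  The receptive field of the
    default 3-level net is well inside a 24^3 patch footprint.
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x03E7]))
        ch = [cfg.base_filters * 2**l for l in range(cfg.levels)]
        self.enc = []
        cin = cfg.in_channels
        for l in range(cfg.levels - 1):
            self.enc.append(_DoubleConv(cin, ch[l], rng, dtype))
            cin = ch[l]
        self.pools = [_MaxPool2() for _ in range(cfg.levels - 1)]
        self.bottleneck = _DoubleConv(cin, ch[-1], rng, dtype)
        self.ups = []
        self.dec = []
        for l in reversed(range(cfg.levels - 1)):
            self.ups.append(_ConvTranspose2(ch[l + 1], ch[l], rng, dtype))
            self.dec.append(_DoubleConv(2 * ch[l], ch[l], rng, dtype))
        self.head = _Conv3d(ch[0], cfg.out_channels, 1, rng, dtype)

    # -- plumbing ----------------------------------------------------------
    def _blocks(self):
        return [*self.enc, *self.pools, self.bottleneck, *self.ups, *self.dec,
                self.head]

    def parameters(self) -> list[_Param]:
        return [p for blk in self._blocks() for p in blk.params()]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            p.value[...] = w

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(skip.shape[1])
            x = dec.forward(np.concatenate([skip, x], axis=1))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(np.ascontiguousarray(dy, dtype=self.dtype))
        dskips = []
        for up, dec, sc in zip(reversed(self.ups), reversed(self.dec),
                               reversed(self._skip_ch)):
            d = dec.backward(dy)
            dskips.append(d[:, :sc])
            dy = up.backward(d[:, sc:])
        dy = self.bottleneck.backward(dy)
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            dy = pool.backward(dy)
            dy = enc.backward(dy + dskip)

    def predict_patches(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Forward-only inference over a stack of patches (N, 2, s, s, s)."""
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i:i + batch_size]))
        return np.concatenate(outs, axis=0)


def build_network(cfg: NetworkConfig, seed: int = 0, dtype=np.float32) -> UNet3D:
    """Construct a randomly initialized (He) network for ``cfg``."""
    return UNet3D(cfg, seed=seed, dtype=dtype)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[_Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p.m[...] = b1 * p.m + (1 - b1) * p.grad
            p.v[...] = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self.t)
            vhat = p.v / (1 - b2**self.t)
            p.value[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Case preparation, training, inference
# ---------------------------------------------------------------------------

@dataclass
class PreparedCase:
    """A case after normalization, ready for patch sampling/inference."""

    case_id: str
    mr1: NormalizedVolume
    mr2: NormalizedVolume
    ct: NormalizedVolume
    bone_mask: np.ndarray


def prepare_case(case, mr_percentile: float = 95.0) -> PreparedCase:
    """Normalize a case's MR echoes (per-volume percentile clip) and CT."""
    return PreparedCase(
        case_id=case.case_id,
        mr1=normalize_mr(case.mr_echo1, mr_percentile),
        mr2=normalize_mr(case.mr_echo2, mr_percentile),
        ct=normalize_ct(case.ct),
        bone_mask=np.asarray(case.bone_mask, dtype=bool),
    )


@dataclass
class TrainedModel:
    """Weights + configs + the normalization convention needed to emit HU."""

    network: UNet3D
    net_cfg: NetworkConfig
    train_cfg: TrainConfig
    mr_percentile: float = 95.0
    log: list = field(default_factory=list)  # (epoch, train_l1, val_l1)

    def save(self, path) -> None:
        weights = self.network.get_weights()
        meta = json.dumps({
            "net_cfg": asdict(self.net_cfg),
            "train_cfg": asdict(self.train_cfg),
            "mr_percentile": self.mr_percentile,
            "log": self.log,
            "n_weights": len(weights),
        })
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{f"w{i}": w for i, w in enumerate(weights)})

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta"]).decode())
            weights = [npz[f"w{i}"] for i in range(meta["n_weights"])]
        net_cfg = NetworkConfig(**meta["net_cfg"])
        train_cfg = TrainConfig(**meta["train_cfg"])
        net = UNet3D(net_cfg, seed=0)
        net.set_weights(weights)
        return cls(net, net_cfg, train_cfg, meta["mr_percentile"],
                   [tuple(e) for e in meta["log"]])


def _l1_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def _patch_arrays(patches) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.mr_patch for p in patches])
    y = np.stack([p.ct_patch for p in patches])[:, None]
    return x, y


def train(
    model: UNet3D,
    training_cases: list[PreparedCase],
    validation_case: PreparedCase,
    tc: TrainConfig,
) -> TrainedModel:
    """Optimize L1 between predicted and true normalized CT patches.

    Per epoch: every training case is (optionally) augmented as a whole
    volume, ``patches_per_volume`` paired patches are sampled (80 %
    bone-intersecting by default), and Adam minimizes the mean absolute
    error over shuffled minibatches.  The checkpoint with the best
    validation L1 is returned; all randomness flows from ``tc.seed``.
    """
    if not training_cases:
        raise ValueError("empty training set")
    size = model.cfg.patch_size
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 0x7121]))
    val_rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 0x7A1]))
    val_patches = extract_patches(
        validation_case.mr1, validation_case.mr2, validation_case.ct,
        validation_case.bone_mask, size=size, n_patches=tc.patches_per_volume,
        bone_fraction_min=tc.bone_fraction_min, rng=val_rng)
    val_x, val_y = _patch_arrays(val_patches)

    opt = _Adam(model.parameters(), tc.learning_rate)
    best_val = np.inf
    best_weights = model.get_weights()
    log: list[tuple[int, float, float]] = []
    for epoch in range(tc.epochs):
        if tc.lr_final is not None and tc.epochs > 1:
            frac = epoch / (tc.epochs - 1)
            opt.lr = float(tc.learning_rate *
                           (tc.lr_final / tc.learning_rate) ** frac)
        xs, ys = [], []
        for case in training_cases:
            if tc.augment:
                mr_pair, ct_vol, masks = augment(
                    np.stack([case.mr1.values, case.mr2.values]),
                    case.ct.values, rng, masks=[case.bone_mask])
                mr1 = NormalizedVolume(np.clip(mr_pair[0], -1, 1), "mr", case.mr1.record)
                mr2 = NormalizedVolume(np.clip(mr_pair[1], -1, 1), "mr", case.mr2.record)
                ct = NormalizedVolume(np.clip(ct_vol, -1, 1), "ct", case.ct.record)
                bone = masks[0]
            else:
                mr1, mr2, ct, bone = case.mr1, case.mr2, case.ct, case.bone_mask
            patches = extract_patches(mr1, mr2, ct, bone, size=size,
                                      n_patches=tc.patches_per_volume,
                                      bone_fraction_min=tc.bone_fraction_min,
                                      rng=rng)
            px, py = _patch_arrays(patches)
            xs.append(px)
            ys.append(py)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            pred = model.forward(x[idx])
            loss, dpred = _l1_and_grad(pred, y[idx].astype(pred.dtype))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            model.backward(dpred)
            opt.step()
            losses.append(loss)
        val_pred = model.predict_patches(val_x, tc.batch_size)
        val_loss = float(np.mean(np.abs(val_pred - val_y.astype(val_pred.dtype))))
        log.append((epoch, float(np.mean(losses)), val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return TrainedModel(model, model.cfg, tc, log=log)


def _tile_starts(dim: int, size: int, stride: int) -> list[int]:
    starts = list(range(0, dim - size + 1, stride))
    if starts[-1] != dim - size:
        starts.append(dim - size)
    return starts


def predict_volume(
    tm: TrainedModel,
    mr1: NormalizedVolume,
    mr2: NormalizedVolume,
    batch_size: int = 8,
) -> np.ndarray:
    """Translate a whole normalized MR volume pair into an sCT in HU.

    The volume is tiled into ``patch_size`` cubes at stride patch/2;
    overlapping predictions are averaged with centre-weighted (separable
    triangular) weights, down-weighting patch borders where the network
    has the least context.  Normalized weighted averaging preserves a
    constant network output exactly.  The average is mapped back to HU
    and clipped to the representable range [-1024, 3071].
    """
    size = tm.net_cfg.patch_size
    vol = np.stack([mr1.values, mr2.values])
    shape = vol.shape[1:]
    if any(n < size for n in shape):
        raise ValueError(f"volume {shape} smaller than one {size}^3 patch")
    stride = max(size // 2, 1)
    starts = [_tile_starts(n, size, stride) for n in shape]
    # separable triangular window, strictly positive so single-cover
    # voxels are unaffected
    w1 = 1.0 - np.abs(np.arange(size) - (size - 1) / 2.0) / size
    weight = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    origins = [(i, j, k) for i in starts[0] for j in starts[1] for k in starts[2]]
    for b in range(0, len(origins), batch_size):
        batch = origins[b:b + batch_size]
        x = np.stack([vol[:, i:i + size, j:j + size, k:k + size] for i, j, k in batch])
        pred = tm.network.forward(x)[:, 0]
        for (i, j, k), p in zip(batch, pred):
            acc[i:i + size, j:j + size, k:k + size] += p * weight
            cnt[i:i + size, j:j + size, k:k + size] += weight
    sct = denormalize_ct(acc / cnt)
    return np.clip(sct, HU_MIN, HU_MAX)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    test_case_id: str
    validation_case_id: str
    train_case_ids: list[str]
    model: TrainedModel
    report_bone: MetricReport
    report_lesion: MetricReport
    baseline_bone: MetricReport
    baseline_lesion: MetricReport


@dataclass
class CVResult:
    folds: list[FoldResult]

    @property
    def reports(self) -> list[MetricReport]:
        return [r for f in self.folds for r in (f.report_bone, f.report_lesion)]

    def summary(self) -> CohortSummary:
        return cohort_summary(self.reports)


def loocv(
    cohort: list,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    eval_cfg: EvalConfig | None = None,
    mr_percentile: float = 95.0,
) -> CVResult:
    """Leave-one-out cross-validation over a cohort of cases.

    Fold i holds out case i for testing, uses case (i+1) mod n for
    validation-based checkpoint selection, and trains on the rest — so a
    cohort of nine yields nine models and each case is tested exactly
    once.  Each fold is seeded from ``train_cfg.seed`` and the fold index.
    An untrained (freshly initialized) copy of the network is also
    evaluated per fold as the learning-sanity baseline.
    """
    n = len(cohort)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 cases (train/val/test)")
    prepared = [prepare_case(c, mr_percentile) for c in cohort]
    eval_cfg = eval_cfg if eval_cfg is not None else EvalConfig()
    folds = []
    for i in range(n):
        vi = (i + 1) % n
        train_ids = [j for j in range(n) if j not in (i, vi)]
        fold_seed = int(np.random.default_rng(
            np.random.SeedSequence([train_cfg.seed, i])).integers(2**31 - 1))
        net = build_network(net_cfg, seed=fold_seed)
        baseline = TrainedModel(net, net_cfg, train_cfg, mr_percentile)
        base_sct = predict_volume(baseline, prepared[i].mr1, prepared[i].mr2)
        case = cohort[i]
        bb, bl = evaluate_case(base_sct, case.ct, case.bone_mask, case.lesion_mask,
                               case.spacing, eval_cfg, case_id=case.case_id)
        tc = TrainConfig(**{**asdict(train_cfg), "seed": fold_seed})
        tm = train(net, [prepared[j] for j in train_ids], prepared[vi], tc)
        sct = predict_volume(tm, prepared[i].mr1, prepared[i].mr2)
        rb, rl = evaluate_case(sct, case.ct, case.bone_mask, case.lesion_mask,
                               case.spacing, eval_cfg, case_id=case.case_id)
        folds.append(FoldResult(
            test_case_id=case.case_id,
            validation_case_id=cohort[vi].case_id,
            train_case_ids=[cohort[j].case_id for j in train_ids],
            model=tm,
            report_bone=rb, report_lesion=rl,
            baseline_bone=bb, baseline_lesion=bl,
        ))
    return CVResult(folds)
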