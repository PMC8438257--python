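"""2D and 3D U-Net construction, Dice-objective training, and prediction.

Both variants share one topology, generic over the number of spatial
dimensions.  The contracting path applies ``depth`` blocks of

    BatchNorm -> LeakyReLU(0.2) -> stride-2 convolution (kernel 4, pad 1)

so a 64-edge input reaches a 1-edge bottleneck after six blocks
(64 -> 32 -> 16 -> 8 -> 4 -> 2 -> 1).  The expanding path applies ``depth``
blocks of

    BatchNorm -> skip-concatenation with the same-size contracting feature
    map -> ReLU -> stride-2 transposed convolution

doubling the edge back to the input size, with dropout (rate 0.5) on the
intermediate expanded feature maps; the first expanding block has no skip
(its only same-size feature map is the bottleneck itself).  The transposed
kernel is 2 (pad 0) in 2D and 4 (pad 1) in 3D; both double each extent.
The final block emits a single channel through a sigmoid, giving a voxel-
wise tumor probability.

The objective is soft Dice, 1 - (2*sum(p*t)+eps) / (sum(p)+sum(t)+eps), the
differentiable relaxation of the Dice similarity coefficient, evaluated
per sample (per slice in 2D, per case in 3D).  Training uses Adam.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .io_formats import Case, Mask

__all__ = [
    "UNetConfig",
    "UNet",
    "TrainedModel",
    "build_unet",
    "soft_dice_loss",
    "train_model",
    "predict_case",
    "binarize",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class UNetConfig:
    dims: int = 2  # 2 or 3
    depth: int = 6
    input_edge: int = 64  # must equal 2**depth
    base_channels: int = 8
    channel_cap: int = 64
    encoder_kernel: int = 4  # stride 2, pad 1
    decoder_kernel: int | None = None  # default: 2 for dims=2, 4 for dims=3
    leaky_alpha: float = 0.2
    dropout_rate: float = 0.5
    epochs: int | None = None  # default: 5 for 2D, 70 for 3D
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer_tag: str = "adam"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.input_edge != 2**self.depth:
            raise ValueError(
                f"input_edge {self.input_edge} must equal 2**depth = {2**self.depth}"
            )
        for name, v in (("leaky_alpha", self.leaky_alpha), ("dropout_rate", self.dropout_rate)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @property
    def resolved_decoder_kernel(self) -> int:
        if self.decoder_kernel is not None:
            return self.decoder_kernel
        return 2 if self.dims == 2 else 4

    @property
    def resolved_epochs(self) -> int:
        if self.epochs is not None:
            return self.epochs
        return 5 if self.dims == 2 else 70

    def encoder_channels(self) -> list[int]:
        return [min(self.base_channels * 2**i, self.channel_cap) for i in range(self.depth)]


class UNet:
    """Encoder–decoder network with skip connections, built from a config."""

    def __init__(self, config: UNetConfig) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.rng_seed)
        ch = config.encoder_channels()
        k, a = config.encoder_kernel, config.leaky_alpha
        dk = config.resolved_decoder_kernel
        dpad = (dk - 2) // 2  # kernel 2 -> pad 0, kernel 4 -> pad 1; both double the edge

        self.enc_blocks: list[list[_nn.Layer]] = []
        c_prev = 1
        for i in range(config.depth):
            self.enc_blocks.append(
                [
                    _nn.BatchNorm(c_prev),
                    _nn.LeakyReLU(a),
                    _nn.Conv(c_prev, ch[i], k, stride=2, pad=1, rng=self.rng),
                ]
            )
            c_prev = ch[i]

        # decoder block t (t = 1..depth): input = previous decoder output
        # (+ skip for t > 1); output channels mirror the encoder, 1 at the top
        self.dec_blocks: list[list[_nn.Layer]] = []
        self.dec_has_skip: list[bool] = []
        u_ch = ch[config.depth - 1]
        for t in range(1, config.depth + 1):
            skip = t > 1
            skip_ch = ch[config.depth - t] if skip else 0
            c_in = u_ch + skip_ch
            c_out = 1 if t == config.depth else ch[config.depth - 1 - t]
            block: list[_nn.Layer] = [
                _nn.BatchNorm(c_in),
                _nn.ReLU(),
                _nn.ConvTranspose(c_in, c_out, dk, stride=2, pad=dpad, rng=self.rng),
            ]
            if t < config.depth:
                block.append(_nn.Dropout(config.dropout_rate, rng=self.rng))
            self.dec_blocks.append(block)
            self.dec_has_skip.append(skip)
            u_ch = c_out
        self.out_act = _nn.Sigmoid()
        self._skip_ch = [ch[config.depth - t] if t > 1 else 0 for t in range(1, config.depth + 1)]

    # ---- parameter plumbing -------------------------------------------

    def _all_layers(self) -> list[_nn.Layer]:
        layers: list[_nn.Layer] = []
        for b in self.enc_blocks + self.dec_blocks:
            layers.extend(b)
        layers.append(self.out_act)
        return layers

    def parameters(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        params, grads = [], []
        for layer in self._all_layers():
            params.extend(layer.params)
            grads.extend(layer.grads)
        return params, grads

    # ---- forward / backward -------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, 1, *spatial) with every spatial extent = input_edge."""
        if x.ndim != self.config.dims + 2:
            raise ValueError(f"expected {self.config.dims + 2}D input, got {x.ndim}D")
        if any(s != self.config.input_edge for s in x.shape[2:]):
            raise ValueError(
                f"spatial shape {x.shape[2:]} != input edge {self.config.input_edge}"
            )
        feats = []  # encoder outputs f_1..f_depth
        h = x.astype(np.float32)
        for block in self.enc_blocks:
            for layer in block:
                h = layer.forward(h, training)
            feats.append(h)
        self._feats = feats
        u = feats[-1]
        for t, block in enumerate(self.dec_blocks, start=1):
            if self.dec_has_skip[t - 1]:
                u = np.concatenate([u, feats[self.config.depth - t]], axis=1)
            for layer in block:
                u = layer.forward(u, training)
        return self.out_act.forward(u, training)

    def backward(self, dloss: np.ndarray) -> None:
        """Propagate gradient of the loss wrt the sigmoid output."""
        du = self.out_act.backward(dloss)
        feat_grads: list[np.ndarray | None] = [None] * self.config.depth
        for t in range(self.config.depth, 0, -1):
            block = self.dec_blocks[t - 1]
            for layer in reversed(block):
                du = layer.backward(du)
            if self.dec_has_skip[t - 1]:
                u_ch = du.shape[1] - self._skip_ch[t - 1]
                dskip = du[:, u_ch:]
                idx = self.config.depth - t
                feat_grads[idx] = dskip if feat_grads[idx] is None else feat_grads[idx] + dskip
                du = du[:, :u_ch]
        # du is now the gradient wrt the bottleneck f_depth
        feat_grads[-1] = du if feat_grads[-1] is None else feat_grads[-1] + du
        g: np.ndarray | None = None
        for i in range(self.config.depth - 1, -1, -1):
            gi = feat_grads[i] if g is None else feat_grads[i] + g if feat_grads[i] is not None else g
            for layer in reversed(self.enc_blocks[i]):
                gi = layer.backward(gi)
            g = gi
        self._feats = None

    def spatial_trace(self) -> list[int]:
        """Edge lengths through the encoder: input_edge, .., 1."""
        return [self.config.input_edge // 2**i for i in range(self.config.depth + 1)]


def build_unet(config: UNetConfig) -> UNet:
    """Instantiate the network for a config (raises on inconsistent geometry)."""
    return UNet(config)


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice loss of a prediction against a binary target (scalar)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    loss, _ = _nn.soft_dice_loss_and_grad(pred[None], target[None], eps=eps)
    return loss


@dataclass
class TrainedModel:
    config: UNetConfig
    net: UNet
    history: pd.DataFrame  # columns: epoch, loss, val_dice

    def save_history(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


def _case_to_samples(case: Case, dims: int) -> tuple[np.ndarray, np.ndarray]:
    """One case -> training samples: slices for 2D, the whole volume for 3D."""
    if case.mask is None:
        raise ValueError(f"case {case.case_id!r} has no mask; cannot train on it")
    img = case.volume.voxels.astype(np.float32)
    msk = case.mask.voxels.astype(np.float32)
    if dims == 3:
        return img[None, None], msk[None, None]
    return img[:, None], msk[:, None]  # (n_slices, 1, H, W)


def train_model(
    config: UNetConfig,
    cases: Sequence[Case],
    val_fraction: float = 0.25,
) -> TrainedModel:
    """Train a U-Net on (already augmented, normalized) cases.

    A quarter of the pooled samples (slices in 2D, cases in 3D) is held out
    for validation monitoring; the held-out samples never contribute
    gradients.  Shuffling, initialization and dropout all derive from
    ``config.rng_seed``, so two runs with the same seed and data coincide.
    """
    if len(cases) == 0:
        raise ValueError("empty training pool")
    xs, ys = zip(*(_case_to_samples(c, config.dims) for c in cases))
    X = np.concatenate(xs)
    Y = np.concatenate(ys)
    n = X.shape[0]

    rng = np.random.default_rng(config.rng_seed)
    order = rng.permutation(n)
    n_val = int(round(n * val_fraction)) if n > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise ValueError("validation fraction leaves no training samples")

    net = UNet(config)
    # lazy layer init: one tiny forward builds all parameter arrays
    net.forward(X[:1], training=False)
    params, grads = net.parameters()
    opt = _nn.Adam(params, grads, lr=config.learning_rate)

    bs = config.batch_size
    rows = []
    for epoch in range(config.resolved_epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, perm.size, bs):
            idx = perm[start : start + bs]
            pred = net.forward(X[idx], training=True)
            loss, dpred = _nn.soft_dice_loss_and_grad(pred, Y[idx])
            net.backward(dpred)
            opt.step()
            losses.append(loss)
        val_dice = np.nan
        if val_idx.size:
            dices = []
            for start in range(0, val_idx.size, bs):
                idx = val_idx[start : start + bs]
                pred = net.forward(X[idx], training=False)
                dices.append(1.0 - _nn.soft_dice_loss_and_grad(pred, Y[idx])[0])
            val_dice = float(np.mean(dices))
        rows.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_dice": val_dice})
    history = pd.DataFrame(rows, columns=["epoch", "loss", "val_dice"])
    return TrainedModel(config=config, net=net, history=history)


def predict_case(model: TrainedModel, case: Case) -> np.ndarray:
    """Voxelwise tumor probability for one case, in [0, 1].

    For the 2D variant the slices are predicted independently and restacked
    in order; for 3D the whole volume is one sample.  Dropout is inactive
    and batch-norm uses running statistics, so prediction is deterministic.
    """
    cfg = model.config
    edge = cfg.input_edge
    if any(s != edge for s in case.volume.shape[(0 if cfg.dims == 3 else 1):]):
        raise ValueError(
            f"case grid {case.volume.shape} incompatible with input edge {edge}"
        )
    img = case.volume.voxels.astype(np.float32)
    if cfg.dims == 3:
        prob = model.net.forward(img[None, None], training=False)[0, 0]
    else:
        outs = []
        for start in range(0, img.shape[0], cfg.batch_size):
            batch = img[start : start + cfg.batch_size, None]
            outs.append(model.net.forward(batch, training=False)[:, 0])
        prob = np.concatenate(outs)
    return np.clip(prob, 0.0, 1.0)


def binarize(prob: np.ndarray, spacing: tuple[float, float, float],
             threshold: float = 0.5) -> Mask:
    """Threshold a probability volume: voxel = 1 iff prob >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return Mask(voxels=(np.asarray(prob) >= threshold).astype(np.uint8), spacing=spacing)


# ------------------------------------------------------------ checkpoints


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Save parameters + config (npz with an embedded JSON config)."""
    params, _ = model.net.parameters()
    arrays = {f"p{i}": p for i, p in enumerate(params)}
    bn_state = {}
    for j, layer in enumerate(model.net._all_layers()):
        if isinstance(layer, _nn.BatchNorm):
            bn_state[f"rm{j}"] = layer.running_mean
            bn_state[f"rv{j}"] = layer.running_var
    np.savez(
        path,
        config=json.dumps(asdict(model.config)),
        history=model.history.to_json(),
        **arrays,
        **bn_state,
    )


def load_model(path: str | Path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    config = UNetConfig(**json.loads(str(data["config"])))
    net = UNet(config)
    edge = config.input_edge
    probe = np.zeros((1, 1) + (edge,) * config.dims, dtype=np.float32)
    net.forward(probe, training=False)  # build parameter arrays
    params, _ = net.parameters()
    for i, p in enumerate(params):
        p[...] = data[f"p{i}"]
    for j, layer in enumerate(net._all_layers()):
        if isinstance(layer, _nn.BatchNorm):
            layer.running_mean = data[f"rm{j}"]
            layer.running_var = data[f"rv{j}"]
    import io

    history = pd.read_json(io.StringIO(str(data["history"])))
    return TrainedModel(config=config, net=net, history=history)
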