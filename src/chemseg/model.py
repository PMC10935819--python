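"""Adapter-augmented ViT segmentation model (promptable, frozen backbone).

The image encoder is a vision transformer: patch embedding, learned
positional embeddings, then ``n_blocks`` pre-norm encoder blocks each
carrying two bottleneck adapters — the first right after multi-head
attention, the second just before the MLP sublayer. A two-layer 1x1
convolutional neck with layer normalization produces the image embedding.
A prompt encoder supplies dense (mask) and sparse (point/box) embeddings;
with no prompts a learned no-mask embedding is broadcast over the grid.
The mask decoder sums dense and image embeddings, upsamples 4x with two
transposed convolutions (implemented as per-pixel linear maps plus pixel
shuffle), and scores each pixel with a dynamic linear classifier predicted
by an MLP from the pooled embedding; outputs pass through a sigmoid. A
second head predicts a scalar IoU estimate in [0, 1].

Only adapters, the prompt embeddings and the decoder train; the backbone
(patch/positional embeddings, attention, MLPs, norms, neck) stays frozen.
Adapters are residual (x + up(relu(down(x)))) with zero-initialized
up-projections, so a freshly built model reproduces its backbone exactly.

Everything runs on NumPy via the package's reverse-mode autodiff tape;
configs are desk-scale by default in tests (see ``EncoderConfig.tiny``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.morphology import closing as _closing
from skimage.transform import resize as _sk_resize

from .autodiff import Tensor


# ------------------------------------------------------------------ configs

@dataclass(frozen=True)
class EncoderConfig:
    image_size: int = 512
    patch_size: int = 16
    embed_dim: int = 768
    n_blocks: int = 12
    n_heads: int = 12
    adapter_bottleneck_dim: int = 64
    adapters_per_block: int = 2
    neck_dim: int = 256
    mlp_ratio: int = 4
    dec_c1: int | None = None  # first upsampling width; default neck_dim // 2
    dec_c2: int | None = None  # second upsampling width; default neck_dim // 4

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError("image_size must be divisible by patch_size")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.adapter_bottleneck_dim >= self.embed_dim:
            raise ValueError("adapter bottleneck must be smaller than embed_dim")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def up1_channels(self) -> int:
        return self.dec_c1 if self.dec_c1 is not None else self.neck_dim // 2

    @property
    def up2_channels(self) -> int:
        return self.dec_c2 if self.dec_c2 is not None else self.neck_dim // 4

    @staticmethod
    def tiny() -> "EncoderConfig":
        """Desk-scale config used throughout the test suite."""
        return EncoderConfig(
            image_size=64, patch_size=8, embed_dim=48, n_blocks=2, n_heads=4,
            adapter_bottleneck_dim=8, neck_dim=32, dec_c1=32, dec_c2=16,
        )


@dataclass
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 1
    max_steps: int | None = None
    iou_loss_weight: float = 0.1
    max_grad_norm: float = 5.0
    pos_weight: float = 2.0
    head_init_least_squares: bool = True
    keep_best: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class MaskPrediction:
    prob_map: np.ndarray  # (out, out) in [0, 1]; out = 4 * grid
    iou_estimate: float


@dataclass
class PromptEmbeddings:
    dense: Tensor       # (1, grid, grid, neck_dim)
    sparse: list[Tensor]  # each (neck_dim,)


# ------------------------------------------------------------------- model

BACKBONE_PREFIXES = ("patch_", "pos", "block", "neck_")
ADAPTER_TAG = "_ad"


def _is_backbone(name: str) -> bool:
    return name.startswith(BACKBONE_PREFIXES) and ADAPTER_TAG not in name


class ChemSegModel:
    """Parameter container plus forward passes. ``params`` maps names to
    :class:`~chemseg.autodiff.Tensor`; adapter/decoder/prompt parameters are
    the only ones with ``requires_grad`` set."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        self._init_params(rng)
        # fixed random Fourier basis for point/box positional encodings
        self.fourier = np.random.default_rng(seed + 1).normal(
            scale=1.0, size=(2, cfg.neck_dim // 2)
        )

    # ---------------------------------------------------------------- init
    def _add(self, name: str, arr: np.ndarray, trainable: bool) -> None:
        self.params[name] = Tensor(arr, requires_grad=trainable)

    def _init_params(self, rng) -> None:
        c = self.cfg
        d, bd, nd = c.embed_dim, c.adapter_bottleneck_dim, c.neck_dim

        def xavier(fan_in, fan_out, *shape):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.normal(scale=scale, size=shape or (fan_in, fan_out))

        pdim = c.patch_size * c.patch_size * 3
        self._add("patch_w", xavier(pdim, d), False)
        self._add("patch_b", np.zeros(d), False)
        self._add("pos", rng.normal(scale=0.02, size=(1, c.grid * c.grid, d)), False)
        for i in range(c.n_blocks):
            p = f"block{i}_"
            self._add(p + "ln1_g", np.ones(d), False)
            self._add(p + "ln1_b", np.zeros(d), False)
            self._add(p + "qkv_w", xavier(d, 3 * d), False)
            self._add(p + "qkv_b", np.zeros(3 * d), False)
            self._add(p + "proj_w", xavier(d, d), False)
            self._add(p + "proj_b", np.zeros(d), False)
            self._add(p + "ln2_g", np.ones(d), False)
            self._add(p + "ln2_b", np.zeros(d), False)
            self._add(p + "mlp_w1", xavier(d, c.mlp_ratio * d), False)
            self._add(p + "mlp_b1", np.zeros(c.mlp_ratio * d), False)
            self._add(p + "mlp_w2", xavier(c.mlp_ratio * d, d), False)
            self._add(p + "mlp_b2", np.zeros(d), False)
            for a in (1, 2):
                q = f"{p}ad{a}_"
                self._add(q + "down_w", xavier(d, bd), True)
                self._add(q + "down_b", np.zeros(bd), True)
                # zero-init up-projection: adapters start as exact identity
                self._add(q + "up_w", np.zeros((bd, d)), True)
                self._add(q + "up_b", np.zeros(d), True)
        self._add("neck_w1", xavier(d, nd), False)
        self._add("neck_ln1_g", np.ones(nd), False)
        self._add("neck_ln1_b", np.zeros(nd), False)
        self._add("neck_w2", xavier(nd, nd), False)
        self._add("neck_ln2_g", np.ones(nd), False)
        self._add("neck_ln2_b", np.zeros(nd), False)
        # prompt encoder
        self._add("prompt_no_mask", rng.normal(scale=0.02, size=nd), True)
        self._add("prompt_mask_w", rng.normal(scale=0.02, size=nd), True)
        self._add("prompt_mask_b", np.zeros(nd), True)
        self._add("prompt_type_point", rng.normal(scale=0.02, size=nd), True)
        self._add("prompt_type_box", rng.normal(scale=0.02, size=nd), True)
        # decoder; the dynamic-classifier MLP output starts at zero so the
        # head begins as a purely static linear classifier
        c2, c4 = c.up1_channels, c.up2_channels
        self._add("dec_up1_w", xavier(nd, 4 * c2), True)
        self._add("dec_up1_b", np.zeros(4 * c2), True)
        self._add("dec_ln_g", np.ones(c2), True)
        self._add("dec_ln_b", np.zeros(c2), True)
        self._add("dec_up2_w", xavier(c2, 4 * c4), True)
        self._add("dec_up2_b", np.zeros(4 * c4), True)
        self._add("dec_static_w", np.zeros(c4), True)
        self._add("dec_hyper_w1", xavier(nd, nd), True)
        self._add("dec_hyper_b1", np.zeros(nd), True)
        self._add("dec_hyper_w2", np.zeros((nd, c4)), True)
        self._add("dec_hyper_b2", np.zeros(c4), True)
        self._add("dec_iou_w1", xavier(nd, nd), True)
        self._add("dec_iou_b1", np.zeros(nd), True)
        self._add("dec_iou_w2", xavier(nd, 1), True)
        self._add("dec_iou_b2", np.zeros(1), True)

    # ------------------------------------------------------------ utilities
    def trainable(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if v.requires_grad}

    def backbone_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.params):
            if _is_backbone(name):
                h.update(name.encode())
                h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    def zero_adapters(self) -> None:
        """Force every adapter to the exact-identity state."""
        for name, p in self.params.items():
            if ADAPTER_TAG in name and ("up_w" in name or "up_b" in name):
                p.data[...] = 0.0


# -------------------------------------------------------------- operations

def adapter_forward(x: Tensor, down_w: Tensor, down_b: Tensor,
                    up_w: Tensor, up_b: Tensor) -> Tensor:
    """Residual bottleneck adapter: x + up(ReLU(down(x)))."""
    if x.shape[-1] != down_w.shape[0]:
        raise ValueError(
            f"adapter expects last dim {down_w.shape[0]}, got {x.shape[-1]}"
        )
    return x + (((x @ down_w) + down_b).relu() @ up_w + up_b)


def _model_adapter(model: ChemSegModel, prefix: str, x: Tensor) -> Tensor:
    p = model.params
    return adapter_forward(
        x, p[prefix + "down_w"], p[prefix + "down_b"],
        p[prefix + "up_w"], p[prefix + "up_b"],
    )


def _attention(model: ChemSegModel, i: int, x: Tensor) -> Tensor:
    c = model.cfg
    p = model.params
    b, n, d = x.shape
    hd = d // c.n_heads
    qkv = x @ p[f"block{i}_qkv_w"] + p[f"block{i}_qkv_b"]  # (b, n, 3d)
    qkv = qkv.reshape(b, n, 3, c.n_heads, hd).transpose(2, 0, 3, 1, 4)
    q, k, v = (qkv_slice(qkv, j) for j in range(3))
    att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
    att = att.softmax()
    out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
    return out @ p[f"block{i}_proj_w"] + p[f"block{i}_proj_b"]


def qkv_slice(qkv: Tensor, j: int) -> Tensor:
    """Select q, k or v from a stacked (3, b, h, n, hd) tensor."""
    def backward(g):
        if qkv.requires_grad:
            full = np.zeros_like(qkv.data)
            full[j] = g
            qkv._accum(full)

    return qkv._make(qkv.data[j], (qkv,), backward)


def _patchify(image: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    """(B, H, W[, 3]) uint8/float -> (B, N, p*p*3) standardized patches."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    if img.ndim == 3:
        img = np.repeat(img[..., None], 3, axis=-1)
    b, h, w, _ = img.shape
    if (h, w) != (cfg.image_size, cfg.image_size):
        raise ValueError(
            f"encoder expects {cfg.image_size}x{cfg.image_size} input, got {h}x{w}"
        )
    if img.max() > 1.5:
        img = img / 255.0
    # per-sample ink-contrast stretch: downscaled document strokes are faint
    # against white, so inputs are normalized to inkness in [0, 1]
    ink = 1.0 - img
    peak = ink.reshape(b, -1).max(axis=1)
    ink = ink / np.where(peak > 0, peak, 1.0)[:, None, None, None]
    img = 2.0 * ink - 1.0
    ps, g = cfg.patch_size, cfg.grid
    patches = img.reshape(b, g, ps, g, ps, 3).transpose(0, 1, 3, 2, 4, 5)
    return patches.reshape(b, g * g, ps * ps * 3)


def encode_image(image: np.ndarray, model: ChemSegModel) -> Tensor:
    """Image -> (B, grid, grid, neck_dim) embedding.

    Adapter #1 follows multi-head attention; adapter #2 precedes the MLP
    sublayer of each block.
    """
    cfg = model.cfg
    p = model.params
    x = Tensor(_patchify(image, cfg)) @ p["patch_w"] + p["patch_b"]
    x = x + p["pos"]
    for i in range(cfg.n_blocks):
        h = x.layer_norm(p[f"block{i}_ln1_g"], p[f"block{i}_ln1_b"])
        h = _attention(model, i, h)
        h = _model_adapter(model, f"block{i}_ad1_", h)
        x = x + h
        h = x.layer_norm(p[f"block{i}_ln2_g"], p[f"block{i}_ln2_b"])
        h = _model_adapter(model, f"block{i}_ad2_", h)
        h = (h @ p[f"block{i}_mlp_w1"] + p[f"block{i}_mlp_b1"]).gelu()
        h = h @ p[f"block{i}_mlp_w2"] + p[f"block{i}_mlp_b2"]
        x = x + h
    # neck: two 1x1 convolutions, each followed by layer normalization
    x = (x @ p["neck_w1"]).layer_norm(p["neck_ln1_g"], p["neck_ln1_b"])
    x = (x @ p["neck_w2"]).layer_norm(p["neck_ln2_g"], p["neck_ln2_b"])
    b = x.shape[0]
    return x.reshape(b, cfg.grid, cfg.grid, cfg.neck_dim)


def encode_prompts(
    model: ChemSegModel,
    points: list[tuple[float, float]] | None = None,
    boxes: list[tuple[float, float, float, float]] | None = None,
    prior_mask: np.ndarray | None = None,
    text: str | None = None,
) -> PromptEmbeddings:
    """Dense + sparse prompt embeddings.

    Points/boxes are (row, col) coordinates at image resolution, positionally
    encoded with a fixed random Fourier basis plus a learned type embedding.
    With no prompts, the learned no-mask embedding is broadcast over the grid.
    Free-text prompts are not supported in this build.
    """
    if text is not None:
        raise NotImplementedError("free-text prompts are unsupported")
    cfg = model.cfg
    p = model.params
    g, s = cfg.grid, cfg.image_size

    if prior_mask is not None:
        m = np.asarray(prior_mask, dtype=np.float64)
        if m.shape != (s, s):
            raise ValueError("prior mask must match the model image size")
        ps = cfg.patch_size
        pooled = m.reshape(g, ps, g, ps).mean(axis=(1, 3))  # (g, g)
        dense = Tensor(pooled[None, :, :, None]) * p["prompt_mask_w"] + p["prompt_mask_b"]
    else:
        dense = (
            Tensor(np.ones((1, g, g, 1))) * p["prompt_no_mask"]
            + Tensor(np.zeros(cfg.neck_dim))
        )

    def fourier_token(r: float, c: float) -> np.ndarray:
        if not (0 <= r <= s and 0 <= c <= s):
            raise ValueError(f"prompt coordinate ({r}, {c}) outside image bounds")
        z = 2 * np.pi * (np.array([r / s, c / s]) @ model.fourier)
        return np.concatenate([np.sin(z), np.cos(z)])

    sparse: list[Tensor] = []
    for r, c in points or []:
        sparse.append(Tensor(fourier_token(r, c)) + p["prompt_type_point"])
    for r0, c0, r1, c1 in boxes or []:
        sparse.append(Tensor(fourier_token(r0, c0)) + p["prompt_type_box"])
        sparse.append(Tensor(fourier_token(r1, c1)) + p["prompt_type_box"])
    return PromptEmbeddings(dense=dense, sparse=sparse)


def _pixel_shuffle2(x: Tensor, g: int, cout: int) -> Tensor:
    """(B, g, g, 4*cout) -> (B, 2g, 2g, cout)."""
    b = x.shape[0]
    x = x.reshape(b, g, g, 2, 2, cout)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, 2 * g, 2 * g, cout)


def decode_mask_logits(
    img_emb: Tensor, prompts: PromptEmbeddings, model: ChemSegModel
) -> tuple[Tensor, Tensor]:
    """Return (logits at 4x embedding resolution, iou logit)."""
    cfg = model.cfg
    p = model.params
    if img_emb.shape[1:3] != prompts.dense.shape[1:3]:
        raise ValueError("image embedding and dense prompt grids differ")
    fused = img_emb + prompts.dense
    b, g = fused.shape[0], cfg.grid
    nd = cfg.neck_dim
    c2, c4 = cfg.up1_channels, cfg.up2_channels

    pooled = fused.reshape(b, g * g, nd).mean(axis=1)  # (b, nd)
    if prompts.sparse:
        acc = prompts.sparse[0]
        for tok in prompts.sparse[1:]:
            acc = acc + tok
        pooled = pooled + acc * (1.0 / len(prompts.sparse))

    u = _pixel_shuffle2(fused @ p["dec_up1_w"] + p["dec_up1_b"], g, c2)
    u = u.layer_norm(p["dec_ln_g"], p["dec_ln_b"]).gelu()
    u = _pixel_shuffle2(u @ p["dec_up2_w"] + p["dec_up2_b"], 2 * g, c4)

    h = (pooled @ p["dec_hyper_w1"] + p["dec_hyper_b1"]).relu()
    wdyn = (h @ p["dec_hyper_w2"] + p["dec_hyper_b2"]).reshape(b, 1, 1, c4)
    # classifier weights = learned static vector + dynamic (prompt- and
    # image-conditioned) offset from the MLP
    logits = (u * (wdyn + p["dec_static_w"])).sum(axis=-1)  # (b, 4g, 4g)

    hi = (pooled @ p["dec_iou_w1"] + p["dec_iou_b1"]).relu()
    iou_logit = hi @ p["dec_iou_w2"] + p["dec_iou_b2"]
    return logits, iou_logit


def decode_mask(
    img_emb: Tensor, prompts: PromptEmbeddings, model: ChemSegModel
) -> MaskPrediction:
    logits, iou_logit = decode_mask_logits(img_emb, prompts, model)
    prob = logits.sigmoid().data[0]
    iou = float(iou_logit.sigmoid().data.ravel()[0])
    return MaskPrediction(prob_map=prob, iou_estimate=iou)


# ---------------------------------------------------------------- training

class TrainingError(RuntimeError):
    pass


@dataclass
class Checkpoint:
    cfg: EncoderConfig
    arrays: dict[str, np.ndarray]
    losses: list[float] = field(default_factory=list)
    seed: int = 0

    def save(self, path: str | Path) -> None:
        meta = json.dumps({"cfg": asdict(self.cfg), "seed": self.seed,
                           "losses": self.losses})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.arrays)

    @staticmethod
    def load(path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        return Checkpoint(cfg=EncoderConfig(**meta["cfg"]), arrays=arrays,
                          losses=meta.get("losses", []), seed=meta.get("seed", 0))

    def build_model(self) -> ChemSegModel:
        model = ChemSegModel(self.cfg, seed=self.seed)
        for k, arr in self.arrays.items():
            model.params[k].data[...] = arr
        return model

    @staticmethod
    def from_model(model: ChemSegModel, losses=None, seed: int = 0) -> "Checkpoint":
        return Checkpoint(
            cfg=model.cfg,
            arrays={k: v.data.copy() for k, v in model.params.items()},
            losses=list(losses or []), seed=seed,
        )


FOOTPRINT_INK_FRACTION = 0.02


def _prepare_example(page: np.ndarray, mask: np.ndarray, cfg: EncoderConfig):
    """Resize a page to the model input and its mask to the decoder output.

    The training target is the structure *footprint*: an output cell is
    foreground when the corresponding page area contains structure ink
    (fraction above ``FOOTPRINT_INK_FRACTION``). The network localizes
    structure regions; exact pixel assignment is the refinement stage's job.
    """
    s = cfg.image_size
    out = 4 * cfg.grid
    img = _sk_resize(np.asarray(page, float), (s, s), order=1,
                     preserve_range=True, anti_aliasing=True)
    tgt = _sk_resize(np.asarray(mask, float), (out, out), order=1,
                     preserve_range=True, anti_aliasing=True)
    tgt = _closing(tgt > FOOTPRINT_INK_FRACTION, np.ones((3, 3), bool))
    return img, tgt.astype(np.float64)


def train_adapters(dataset, model: ChemSegModel, tcfg: TrainConfig) -> Checkpoint:
    """SGD-with-momentum training of adapters, decoder and prompt embeddings.

    ``dataset`` is a sequence of (page, mask) pairs or PageMaskPair objects.
    Pages are resized to the model's input size, masks to the decoder output
    resolution; the loss is pixelwise binary cross-entropy plus a small MSE
    term tying the predicted-IoU head to the realized IoU. Backbone
    parameters are untouched by construction (they carry no gradients).
    """
    pairs = []
    for item in dataset:
        if hasattr(item, "page"):
            pairs.append(_prepare_example(item.page, item.mask, model.cfg))
        else:
            pairs.append(_prepare_example(item[0], item[1], model.cfg))
    if not pairs:
        raise TrainingError("empty training dataset")

    steps_planned = (
        tcfg.max_steps if tcfg.max_steps is not None
        else tcfg.epochs * int(np.ceil(len(pairs) / tcfg.batch_size))
    )
    if tcfg.head_init_least_squares and steps_planned > 0:
        _init_head_least_squares(model, pairs)

    rng = np.random.default_rng(tcfg.seed)
    velocity = {k: np.zeros_like(v.data) for k, v in model.trainable().items()}
    losses: list[float] = []
    best_loss, best_state = np.inf, None
    total_steps = steps_planned
    step = 0
    while step < total_steps:
        order = rng.permutation(len(pairs))
        for start in range(0, len(pairs), tcfg.batch_size):
            if step >= total_steps:
                break
            batch = [pairs[i] for i in order[start : start + tcfg.batch_size]]
            imgs = np.stack([b[0] for b in batch])
            tgts = np.stack([b[1] for b in batch])
            emb = encode_image(imgs, model)
            prompts = encode_prompts(model)
            logits, iou_logit = decode_mask_logits(emb, prompts, model)
            loss = logits.bce_with_logits(tgts, pos_weight=tcfg.pos_weight)
            prob = 1.0 / (1.0 + np.exp(-logits.data))
            iou_target = _batch_iou(prob >= 0.5, tgts >= 0.5)[:, None]
            diff = iou_logit.sigmoid() - Tensor(iou_target)
            loss = loss + (diff * diff).mean() * tcfg.iou_loss_weight
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingError(
                    f"non-finite loss {value} at step {step}; "
                    f"last finite losses: {losses[-5:]}"
                )
            losses.append(value)
            if tcfg.keep_best and value < best_loss:
                best_loss = value
                best_state = {k: v.data.copy() for k, v in model.trainable().items()}
            for t in model.params.values():
                t.grad = None
            loss.backward()
            if tcfg.max_grad_norm is not None:
                sq = sum(
                    float((t.grad**2).sum())
                    for t in model.trainable().values() if t.grad is not None
                )
                norm = np.sqrt(sq)
                if norm > tcfg.max_grad_norm:
                    scale = tcfg.max_grad_norm / norm
                    for t in model.trainable().values():
                        if t.grad is not None:
                            t.grad = t.grad * scale
            for name, t in model.trainable().items():
                if t.grad is None:
                    continue
                velocity[name] = tcfg.momentum * velocity[name] - tcfg.learning_rate * t.grad
                t.data = t.data + velocity[name]
            step += 1
    # keep the lowest-loss parameters seen: plain SGD with momentum can
    # oscillate late in short runs
    if tcfg.keep_best and best_state is not None:
        for k, arr in best_state.items():
            model.params[k].data[...] = arr
    return Checkpoint.from_model(model, losses=losses, seed=tcfg.seed)


def _init_head_least_squares(model: ChemSegModel, pairs) -> None:
    """Data-dependent init of the static classifier vector.

    One frozen forward pass collects decoder pixel features; ridge-regressed
    against +/-2 target logits they give the static head a calibrated
    starting point (LSUV-style init), which short SGD runs then refine.
    """
    c4 = model.cfg.up2_channels
    feats, targets = [], []
    for img, tgt in pairs:
        emb = encode_image(img[None], model)
        prompts = encode_prompts(model)
        cfg, p = model.cfg, model.params
        fused = emb + prompts.dense
        g = cfg.grid
        u = _pixel_shuffle2(fused @ p["dec_up1_w"] + p["dec_up1_b"], g, cfg.up1_channels)
        u = u.layer_norm(p["dec_ln_g"], p["dec_ln_b"]).gelu()
        u = _pixel_shuffle2(u @ p["dec_up2_w"] + p["dec_up2_b"], 2 * g, c4)
        feats.append(u.data.reshape(-1, c4))
        targets.append((np.asarray(tgt).ravel() * 2 - 1) * 2.0)
    U = np.concatenate(feats)
    y = np.concatenate(targets)
    w = np.linalg.solve(U.T @ U + 1e-3 * np.eye(c4), U.T @ y)
    model.params["dec_static_w"].data[...] = w


def _batch_iou(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    axes = tuple(range(1, pred.ndim))
    inter = np.logical_and(pred, truth).sum(axis=axes)
    union = np.logical_or(pred, truth).sum(axis=axes)
    return np.where(union > 0, inter / np.maximum(union, 1), 1.0)


def mean_train_iou(model: ChemSegModel, dataset) -> float:
    """Mean IoU of thresholded predictions against targets (diagnostic)."""
    ious = []
    for item in dataset:
        page, mask = (item.page, item.mask) if hasattr(item, "page") else item
        img, tgt = _prepare_example(page, mask, model.cfg)
        emb = encode_image(img[None], model)
        pred = decode_mask(emb, encode_prompts(model), model)
        ious.append(float(_batch_iou((pred.prob_map >= 0.5)[None], (tgt >= 0.5)[None])[0]))
    return float(np.mean(ious))


def predict_page_mask(image: np.ndarray, model: ChemSegModel) -> np.ndarray:
    """Foreground-probability map for a page of any size, at page resolution.

    The page is resized to the model's square input internally; the output
    probability map is resized back to the input resolution.
    """
    page = np.asarray(image, dtype=np.float64)
    if page.ndim == 3:
        page = page @ np.array([0.299, 0.587, 0.114])
    h, w = page.shape
    s = model.cfg.image_size
    img = _sk_resize(page, (s, s), order=1, preserve_range=True, anti_aliasing=True)
    emb = encode_image(img[None], model)
    pred = decode_mask(emb, encode_prompts(model), model)
    prob = _sk_resize(pred.prob_map, (h, w), order=1, preserve_range=True)
    return np.clip(prob, 0.0, 1.0)
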