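"""The PrCRS network: temporal U-Net over MFCF transformer blocks.

Daily clinical factor vectors are embedded with a learned linear map plus
absolute positional embeddings, passed through a U-Net over the time axis
(strided depthwise convolutions halve the sequence length per level;
nearest-neighbour upsampling plus pointwise convolution restores it, with
additive skip connections), and classified per day into severe / non-severe
CRS with a softmax head.

Each processing block is an MFCF block — multi-head self-attention, a
feed-forward module, a depthwise convolution module, and a second
feed-forward module — using the post-LayerNorm-then-scaling residual form

    y = LayerNorm(x + m(s * x))

where ``s`` is a learnable per-channel scaling vector of the sub-module
``m``.  There is no pre-LayerNorm anywhere, and no Macaron-style half-step
feed-forward pair: the block order is fixed as MHA -> FFN -> Conv -> FFN.

The model is causal: the prediction for day ``t`` consumes the full history
up to and including day ``t`` but nothing later (attention keys are
restricted to past days, convolutions are left-padded, and the U-Net
up-path is right-shifted so coarse features never carry future
information).  This matches deployment, where severity 1-3 days ahead is
forecast from the data available so far.

Padded days are canonicalised to zero at every stage and masked out of the
attention, so the output at real days is identical to running the
truncated sequence alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .autograd import Tensor, depthwise_conv1d, layer_norm, log_softmax, softmax

MAX_LEN = 128  # positional-embedding capacity; patient stays are days, not months

PARAM_GROUPS = ("embedding", "encoder", "decoder", "head")


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``n_features`` depends on the panel combination; ``unet_depth`` counts
    the x2 temporal downsamplings; ``conv_kernel`` is deliberately small
    (default 9) because patient sequences average about a week.
    """

    n_features: int = 42
    d_model: int = 64
    n_heads: int = 4
    n_blocks_per_level: int = 2
    unet_depth: int = 1
    conv_kernel: int = 9
    ffn_expansion: int = 4
    dropout: float = 0.1
    scale_init: float = 1.0
    lead: int = 1
    combo: str = "1234"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError("d_model must be divisible by n_heads")
        if self.conv_kernel % 2 != 1:
            raise ConfigurationError("conv_kernel must be odd")
        if self.unet_depth < 0:
            raise ConfigurationError("unet_depth must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class PrcrsModel:
    """Parameter collection + forward pass for the U-Net/MFCF classifier."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: Dict[str, Tensor] = {}
        self.frozen: Set[str] = set()
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # -- construction ------------------------------------------------------
    def _param(self, name: str, shape: Tuple[int, ...], kind: str = "weight") -> None:
        if kind == "weight":
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            data = self._rng.standard_normal(shape) / np.sqrt(max(fan_in, 1))
        elif kind == "zeros":
            data = np.zeros(shape)
        elif kind == "ones":
            data = np.ones(shape)
        elif kind == "scale":
            data = np.full(shape, self.config.scale_init)
        else:  # pragma: no cover
            raise ValueError(kind)
        self.params[name] = Tensor(data, requires_grad=True)

    def _build_block(self, prefix: str) -> None:
        d = self.config.d_model
        h = d * self.config.ffn_expansion
        k = self.config.conv_kernel
        for sub in ("mha", "ffn1", "conv", "ffn2"):
            self._param(f"{prefix}.{sub}.scale", (d,), "scale")
            self._param(f"{prefix}.{sub}.ln_gamma", (d,), "ones")
            self._param(f"{prefix}.{sub}.ln_beta", (d,), "zeros")
        for w in ("wq", "wk", "wv", "wo"):
            self._param(f"{prefix}.mha.{w}", (d, d))
        self._param(f"{prefix}.mha.bo", (d,), "zeros")
        for ffn in ("ffn1", "ffn2"):
            self._param(f"{prefix}.{ffn}.w1", (d, h))
            self._param(f"{prefix}.{ffn}.b1", (h,), "zeros")
            self._param(f"{prefix}.{ffn}.w2", (h, d))
            self._param(f"{prefix}.{ffn}.b2", (d,), "zeros")
        self._param(f"{prefix}.conv.depthwise", (k, d))
        self._param(f"{prefix}.conv.db", (d,), "zeros")
        self._param(f"{prefix}.conv.pointwise", (d, d))
        self._param(f"{prefix}.conv.pb", (d,), "zeros")

    def _build(self) -> None:
        cfg = self.config
        d = cfg.d_model
        self._param("embedding.w", (cfg.n_features, d))
        self._param("embedding.b", (d,), "zeros")
        self._param("embedding.pos", (MAX_LEN, d))
        for lvl in range(cfg.unet_depth):
            for b in range(cfg.n_blocks_per_level):
                self._build_block(f"encoder.level{lvl}.block{b}")
            self._param(f"encoder.down{lvl}.w", (2, d))
            self._param(f"encoder.down{lvl}.b", (d,), "zeros")
        for b in range(cfg.n_blocks_per_level):
            self._build_block(f"encoder.bottleneck.block{b}")
        for lvl in range(cfg.unet_depth):
            self._param(f"decoder.up{lvl}.w", (d, d))
            self._param(f"decoder.up{lvl}.b", (d,), "zeros")
            for b in range(cfg.n_blocks_per_level):
                self._build_block(f"decoder.level{lvl}.block{b}")
        self._param("head.w", (d, 2))
        self._param("head.b", (2,), "zeros")

    # -- freezing ----------------------------------------------------------
    def group_of(self, param_name: str) -> str:
        return param_name.split(".", 1)[0]

    def parameter_groups(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {g: [] for g in PARAM_GROUPS}
        for name in self.params:
            out[self.group_of(name)].append(name)
        return {g: names for g, names in out.items() if names}

    def freeze(self, groups: Iterable[str]) -> "PrcrsModel":
        known = set(self.parameter_groups())
        groups = set(groups)
        unknown = groups - known
        if unknown:
            raise KeyError(f"unknown parameter group(s): {sorted(unknown)}; known: {sorted(known)}")
        self.frozen |= groups
        return self

    def unfreeze_all(self) -> "PrcrsModel":
        self.frozen.clear()
        return self

    def is_frozen(self, param_name: str) -> bool:
        return self.group_of(param_name) in self.frozen

    def trainable_parameters(self) -> Dict[str, Tensor]:
        return {n: p for n, p in self.params.items() if not self.is_frozen(n)}

    # -- forward -----------------------------------------------------------
    def _dropout(self, x: Tensor, rng: Optional[np.ndarray]) -> Tensor:
        p = self.config.dropout
        if rng is None or p <= 0.0:
            return x
        keep = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * keep

    def _sublayer(self, x: Tensor, prefix: str, branch, mask: Tensor,
                  rng) -> Tensor:
        """Post-LN-then-scale residual: y = LN(x + m(s*x)), re-masked."""
        p = self.params
        branch_out = branch(x * p[f"{prefix}.scale"])
        branch_out = self._dropout(branch_out, rng)
        y = layer_norm(x + branch_out, p[f"{prefix}.ln_gamma"], p[f"{prefix}.ln_beta"])
        return y * mask

    def _mha(self, prefix: str, mask_np: np.ndarray):
        cfg = self.config
        p = self.params
        dh = cfg.d_model // cfg.n_heads
        # additive key mask: large negative at padded and future key positions
        t = mask_np.shape[1]
        key_bias = (mask_np[:, None, None, :] - 1.0) * 1e9
        causal = np.triu(np.ones((t, t)), k=1) * -1e9
        key_bias = key_bias + causal[None, None, :, :]

        def branch(x: Tensor) -> Tensor:
            b, t, d = x.shape
            q = (x @ p[f"{prefix}.wq"]).reshape(b, t, cfg.n_heads, dh).swapaxes(1, 2)
            k = (x @ p[f"{prefix}.wk"]).reshape(b, t, cfg.n_heads, dh).swapaxes(1, 2)
            v = (x @ p[f"{prefix}.wv"]).reshape(b, t, cfg.n_heads, dh).swapaxes(1, 2)
            scores = q @ k.swapaxes(2, 3) * (1.0 / np.sqrt(dh)) + key_bias
            attn = softmax(scores, axis=-1)
            ctx = (attn @ v).swapaxes(1, 2).reshape(b, t, d)
            return ctx @ p[f"{prefix}.wo"] + p[f"{prefix}.bo"]

        return branch

    def _ffn(self, prefix: str):
        p = self.params

        def branch(x: Tensor) -> Tensor:
            h = (x @ p[f"{prefix}.w1"] + p[f"{prefix}.b1"]).relu()
            return h @ p[f"{prefix}.w2"] + p[f"{prefix}.b2"]

        return branch

    def _conv(self, prefix: str):
        p = self.params

        def branch(x: Tensor) -> Tensor:
            h = depthwise_conv1d(x, p[f"{prefix}.depthwise"], p[f"{prefix}.db"], causal=True).silu()
            return h @ p[f"{prefix}.pointwise"] + p[f"{prefix}.pb"]

        return branch

    def mfcf_block(self, x: Tensor, prefix: str, mask_np: np.ndarray, rng=None) -> Tensor:
        """One MFCF block: MHA -> FFN -> Conv -> FFN, each post-LN residual."""
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite input to MFCF block")
        mask = Tensor(mask_np[:, :, None])
        x = self._sublayer(x, f"{prefix}.mha", self._mha(f"{prefix}.mha", mask_np), mask, rng)
        x = self._sublayer(x, f"{prefix}.ffn1", self._ffn(f"{prefix}.ffn1"), mask, rng)
        x = self._sublayer(x, f"{prefix}.conv", self._conv(f"{prefix}.conv"), mask, rng)
        x = self._sublayer(x, f"{prefix}.ffn2", self._ffn(f"{prefix}.ffn2"), mask, rng)
        return x

    def _downsample(self, x: Tensor, mask_np: np.ndarray, lvl: int) -> Tuple[Tensor, np.ndarray]:
        p = self.params
        t = x.shape[1]
        if t % 2 == 1:
            x = x.pad_axis(1, 0, 1)
            mask_np = np.concatenate([mask_np, np.zeros((mask_np.shape[0], 1))], axis=1)
        w = p[f"encoder.down{lvl}.w"]
        y = x[:, 0::2, :] * w[0] + x[:, 1::2, :] * w[1] + p[f"encoder.down{lvl}.b"]
        mask_half = np.maximum(mask_np[:, 0::2], mask_np[:, 1::2])
        return y * Tensor(mask_half[:, :, None]), mask_half

    def _upsample(self, x: Tensor, lvl: int, t_out: int) -> Tensor:
        # nearest-neighbour repeat, right-shifted one step so a coarse
        # feature (which pools days 2t and 2t+1) never reaches day < 2t+1
        p = self.params
        y = x.repeat_axis(1, 2).pad_axis(1, 1, 0)[:, :t_out, :]
        return y @ p[f"decoder.up{lvl}.w"] + p[f"decoder.up{lvl}.b"]

    def forward(self, batch: np.ndarray, mask: Optional[np.ndarray] = None,
                rng: Optional[np.random.Generator] = None) -> Tensor:
        """Per-day two-class logits for a padded batch.

        ``batch``: (B, T, F) standardized values; ``mask``: (B, T) with 1 at
        real days, 0 at padding.  Returns logits of shape (B, T, 2).
        """
        cfg = self.config
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim != 3 or batch.shape[2] != cfg.n_features:
            raise ValueError(
                f"expected batch (B, T, {cfg.n_features}), got {batch.shape}"
            )
        b, t, _ = batch.shape
        if t > MAX_LEN:
            raise ValueError(f"sequence length {t} exceeds capacity {MAX_LEN}")
        mask_np = np.ones((b, t)) if mask is None else np.asarray(mask, dtype=np.float64)
        p = self.params
        x = Tensor(batch * mask_np[:, :, None])
        mask_t = Tensor(mask_np[:, :, None])
        h = (x @ p["embedding.w"] + p["embedding.b"] + p["embedding.pos"][:t]) * mask_t

        skips: List[Tuple[Tensor, np.ndarray]] = []
        m = mask_np
        for lvl in range(cfg.unet_depth):
            for blk in range(cfg.n_blocks_per_level):
                h = self.mfcf_block(h, f"encoder.level{lvl}.block{blk}", m, rng)
            skips.append((h, m))
            h, m = self._downsample(h, m, lvl)
        for blk in range(cfg.n_blocks_per_level):
            h = self.mfcf_block(h, f"encoder.bottleneck.block{blk}", m, rng)
        for lvl in reversed(range(cfg.unet_depth)):
            skip_h, skip_m = skips[lvl]
            h = self._upsample(h, lvl, skip_h.shape[1])
            h = (h + skip_h) * Tensor(skip_m[:, :, None])
            m = skip_m
            for blk in range(cfg.n_blocks_per_level):
                h = self.mfcf_block(h, f"decoder.level{lvl}.block{blk}", m, rng)
        logits = h @ p["head.w"] + p["head.b"]
        return logits

    # -- inference ---------------------------------------------------------
    def predict_proba(self, sequence: np.ndarray) -> np.ndarray:
        """Per-day severe-CRS probability for one (T, F) sequence."""
        seq = np.asarray(sequence, dtype=np.float64)
        if seq.ndim != 2:
            raise ValueError("sequence must be (T, F)")
        logits = self.forward(seq[None, :, :])
        probs = softmax(logits, axis=-1).data[0, :, 1]
        return probs

    def predict_call(self, sequence: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(sequence) >= threshold).astype(int)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("parameter name mismatch")
        for n, arr in state.items():
            if self.params[n].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {n}")
            self.params[n].data = np.asarray(arr, dtype=np.float64).copy()

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        sidecar = {"config": dataclasses.asdict(self.config), "hash": self.config.config_hash()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "PrcrsModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = ModelConfig(**sidecar["config"])
        if config.config_hash() != sidecar["hash"]:
            raise ValueError("checkpoint config hash mismatch")
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_dict({k: npz[k] for k in npz.files})
        return model


def init_model(config: ModelConfig) -> PrcrsModel:
    """Deterministically initialise a PrCRS model from its config seed."""
    return PrcrsModel(config)


def sequence_loss(model: PrcrsModel, batch: np.ndarray, labels: np.ndarray,
                  label_mask: np.ndarray, pad_mask: np.ndarray,
                  class_weights: Optional[Tuple[float, float]] = None,
                  rng: Optional[np.random.Generator] = None) -> Tensor:
    """Mean two-class cross-entropy over labelled, unpadded days.

    ``labels``: (B, T) int; ``label_mask``: (B, T) 1 where a label exists
    (padding and trailing lead days excluded).
    """
    logits = model.forward(batch, pad_mask, rng=rng)
    logp = log_softmax(logits, axis=-1)
    lab = np.asarray(labels, dtype=np.int64)
    onehot = np.zeros(logits.shape)
    b_idx, t_idx = np.meshgrid(np.arange(lab.shape[0]), np.arange(lab.shape[1]), indexing="ij")
    onehot[b_idx, t_idx, lab] = 1.0
    w = np.ones(lab.shape)
    if class_weights is not None:
        w0, w1 = class_weights
        if w0 <= 0 or w1 <= 0:
            raise ValueError("class weights must be positive")
        w = np.where(lab == 1, w1, w0)
    lm = np.asarray(label_mask, dtype=np.float64) * w
    nll = -(logp * onehot).sum(axis=-1) * lm
    denom = float(lm.sum())
    if denom <= 0:
        raise ValueError("no labelled days in batch")
    return nll.sum() * (1.0 / denom)
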