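"""Two-branch capsule network with convolutional block attention.

The biological feature (33 x 20) and the embedded sequence code (50 x 20)
pass through separate convolution + CBAM branches, are folded into 16-dim
primary capsules (704 biological + 544 sequence = 1248 at the default
width), and a single dynamic-routing pass over the concatenated capsules
produces two 32-dim output capsules whose L2 norms score the peptide as
detectable (capsule 0) or undetectable (capsule 1). Training minimizes the
per-capsule margin loss.

Everything runs on the package's numpy autograd engine
(:mod:`pepcaps.autograd`); no external deep-learning framework is required.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Adam, Tensor, concatenate, conv2d, embedding
from .config import CONFIG_SCHEMA_VERSION, NetworkConfig
from .features import AAC_DIM, BIO_DIM, RCC_DIM

__all__ = [
    "CapsNetCBAM",
    "CapsuleState",
    "squash",
    "dynamic_routing",
    "margin_loss",
    "classify",
    "conv_output_shape",
    "save_checkpoint",
    "load_checkpoint",
]


def conv_output_shape(hw: tuple[int, int], kernel: int, stride: int = 1, pad: int = 0):
    h = (hw[0] + 2 * pad - kernel) // stride + 1
    w = (hw[1] + 2 * pad - kernel) // stride + 1
    if h < 1 or w < 1:
        raise ValueError(f"kernel {kernel} too large for input {hw} with pad {pad}")
    return h, w


def squash(s: Tensor, axis: int = -1, eps: float = 1e-8, norm_squared: bool = True) -> Tensor:
    """Scale capsule vectors to norm < 1 keeping direction.

    Canonical form (``norm_squared=True``): v = (|s|^2 / (1 + |s|^2)) * s/|s|.
    The variant with a 1 + |s| denominator is available for comparison.
    Zero vectors map to zero.
    """
    n2 = (s * s).sum(axis=axis, keepdims=True)
    norm = (n2 + eps**2).sqrt()
    denom = (1.0 + n2) if norm_squared else (1.0 + norm)
    # |s|^2/(1+|s|^2) * s/|s| == s * |s|/(1+|s|^2); same algebra for the variant
    return s * (norm / denom)


@dataclass
class CapsuleState:
    """Intermediate capsule quantities of one forward pass (numpy copies)."""

    primary: np.ndarray  # N x n_primary x caps_dim
    predictions: np.ndarray  # N x n_primary x n_classes x out_dim
    couplings: np.ndarray  # N x n_primary x n_classes
    outputs: np.ndarray  # N x n_classes x out_dim


def dynamic_routing(
    u: Tensor,
    W: Tensor,
    iters: int = 3,
    eps: float = 1e-8,
    norm_squared: bool = True,
) -> tuple[Tensor, Tensor, Tensor]:
    """Route primary capsules to output capsules by iterative agreement.

    ``u``: (N, n, d_in) primary capsules; ``W``: (1, n, k, d_in, d_out)
    prediction weights. Logits start at zero (uniform couplings), and each
    iteration re-softmaxes the logits over the k output capsules, forms the
    weighted prediction sum, squashes it, and adds the prediction/output
    agreement to the logits. Returns (v, c, u_hat).
    """
    if iters < 1:
        raise ValueError("routing needs at least one iteration")
    N, n, d_in = u.shape
    k, d_out = W.shape[2], W.shape[4]
    u_hat = (u.reshape(N, n, 1, 1, d_in) @ W).reshape(N, n, k, d_out)
    b = Tensor(np.zeros((N, n, k), dtype=np.float32))
    for it in range(iters):
        c = b.softmax(axis=2)
        s = (c.reshape(N, n, k, 1) * u_hat).sum(axis=1)  # N,k,d_out
        v = squash(s, eps=eps, norm_squared=norm_squared)
        if it < iters - 1:
            b = b + (u_hat * v.reshape(N, 1, k, d_out)).sum(axis=3)
    return v, c, u_hat


def classify(v_norms: np.ndarray) -> np.ndarray:
    """Predicted labels from output-capsule norms (N x 2).

    Capsule 0 scores detectability; ties go to the undetectable class.
    """
    return (v_norms[:, 0] > v_norms[:, 1]).astype(np.int64)


def margin_loss(
    v: Tensor,
    labels: np.ndarray,
    m_pos: float = 0.9,
    m_neg: float = 0.1,
    lam: float = 0.5,
) -> Tensor:
    """Mean over the batch of the summed per-capsule margin losses.

    L_k = T_k * max(0, m+ - |v_k|)^2 + lam * (1 - T_k) * max(0, |v_k| - m-)^2
    with T = [label, 1-label] (capsule 0 = detectable).
    """
    labels = np.asarray(labels)
    T = np.stack([labels, 1 - labels], axis=1).astype(np.float32)  # N x 2
    norms = ((v * v).sum(axis=-1) + 1e-12).sqrt()  # N x 2
    pos = (m_pos - norms).relu() ** 2.0
    neg = (norms - m_neg).relu() ** 2.0
    per_sample = (Tensor(T) * pos + lam * Tensor(1 - T) * neg).sum(axis=1)
    return per_sample.mean()


@dataclass
class FeatureScaler:
    """Per-column standardization of the biological feature, fit on training data.

    The raw RCC block carries molecular-weight-scale coordinates (and their
    squared/cubed moments) next to composition frequencies of order 0.01;
    without standardization the first convolution saturates the capsule
    norms. The RCC and AAC blocks are z-scored (dense, informative, wildly
    different scales); the 400 sparse DPC frequencies are left raw because
    z-scoring them inflates rare-dipeptide noise. Constant columns are left
    untouched.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, bio: np.ndarray) -> "FeatureScaler":
        n = RCC_DIM + AAC_DIM
        mean = np.zeros(bio.shape[1], dtype=np.float32)
        scale = np.ones(bio.shape[1], dtype=np.float32)
        blk = bio[:, :n]
        sd = blk.std(axis=0)
        sd[sd < 1e-12] = 1.0
        mean[:n] = blk.mean(axis=0)
        scale[:n] = sd
        return cls(mean, scale)

    def transform(self, bio: np.ndarray) -> np.ndarray:
        return ((bio - self.mean) / self.scale).astype(np.float32)


class _Conv:
    def __init__(self, in_ch, out_ch, kernel, stride, pad, rng):
        fan_in = in_ch * kernel * kernel
        self.w = Tensor(
            rng.normal(0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel)).astype(
                np.float32
            ),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class _Linear:
    def __init__(self, n_in, n_out, rng):
        self.w = Tensor(
            rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self):
        return [self.w, self.b]


class ChannelAttention:
    """Squeeze H x W by average and max pooling through a shared bottleneck MLP."""

    def __init__(self, channels: int, reduction: int, rng):
        if channels < reduction:
            raise ValueError(
                f"channel attention needs channels ({channels}) >= reduction ({reduction})"
            )
        self.fc1 = _Linear(channels, channels // reduction, rng)
        self.fc2 = _Linear(channels // reduction, channels, rng)

    def _mlp(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def __call__(self, f: Tensor) -> Tensor:
        n, c = f.shape[0], f.shape[1]
        avg = f.mean(axis=(2, 3))
        mx = f.max(axis=3).max(axis=2)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid().reshape(n, c, 1, 1)

    def params(self):
        return self.fc1.params() + self.fc2.params()


class SpatialAttention:
    """Stack channel-mean and channel-max maps and gate through a wide conv."""

    def __init__(self, kernel: int, rng):
        self.conv = _Conv(2, 1, kernel, 1, kernel // 2, rng)

    def __call__(self, f: Tensor) -> Tensor:
        pooled = concatenate(
            [f.mean(axis=1, keepdims=True), f.max(axis=1, keepdims=True)], axis=1
        )
        return self.conv(pooled).sigmoid()

    def params(self):
        return self.conv.params()


class CBAM:
    """Channel attention followed by spatial attention, multiplicative gating."""

    def __init__(self, channels: int, reduction: int, spatial_kernel: int, rng):
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(spatial_kernel, rng)

    def __call__(self, f: Tensor) -> Tensor:
        f1 = f * self.channel(f)
        return f1 * self.spatial(f1)

    def params(self):
        return self.channel.params() + self.spatial.params()


class _Branch:
    """conv -> ReLU -> (CBAM) -> primary-capsule conv -> capsule reshape."""

    def __init__(self, cfg: NetworkConfig, in_shape, kernel, pad, caps_kernel, rng):
        c = cfg.conv_channels
        self.conv1 = _Conv(1, c, kernel, 1, pad, rng)
        self.conv1_out = conv_output_shape(in_shape, kernel, 1, pad)
        self.cbam = (
            CBAM(c, cfg.cbam_reduction, cfg.spatial_kernel, rng) if cfg.use_cbam else None
        )
        self.caps_conv = _Conv(c, c, caps_kernel, cfg.primary_stride, 0, rng)
        self.caps_out = conv_output_shape(self.conv1_out, caps_kernel, cfg.primary_stride, 0)
        self.caps_dim = cfg.caps_dim
        if c % self.caps_dim:
            raise ValueError("conv_channels must be divisible by caps_dim")
        self.n_caps = (c // self.caps_dim) * self.caps_out[0] * self.caps_out[1]
        self.in_shape = in_shape

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        h, w = x.shape[2], x.shape[3]
        if (h, w) != self.in_shape:
            raise ValueError(
                f"branch expects spatial input {self.in_shape}, got {(h, w)}"
            )
        f = self.conv1(x).relu()
        if self.cbam is not None:
            f = self.cbam(f)
        f = self.caps_conv(f)
        ho, wo = self.caps_out
        c = f.shape[1]
        caps = (
            f.reshape(n, c // self.caps_dim, self.caps_dim, ho, wo)
            .transpose(0, 1, 3, 4, 2)
            .reshape(n, self.n_caps, self.caps_dim)
        )
        return caps

    def params(self):
        p = self.conv1.params() + self.caps_conv.params()
        if self.cbam is not None:
            p += self.cbam.params()
        return p


class CapsNetCBAM:
    """The full two-branch (or combined-input) capsule classifier."""

    def __init__(self, cfg: NetworkConfig | None = None):
        self.cfg = cfg = cfg or NetworkConfig()
        #: optional per-column standardizer for the biological feature,
        #: fit on the training set (see :meth:`fit_scaler`)
        self.scaler: FeatureScaler | None = None
        rng = np.random.default_rng(cfg.seed)
        emb = rng.normal(0, 0.1, (21, cfg.embedding_dim)).astype(np.float32)
        emb[0] = 0.0  # pad row stays zero: pad positions are masked in forward
        self.embedding = Tensor(emb, requires_grad=True)

        if cfg.combined_input:
            in_shape = (cfg.bio_shape[0] + cfg.seq_len, cfg.embedding_dim)
            self.branch = _Branch(
                cfg, in_shape, cfg.bio_kernel, cfg.bio_pad, cfg.bio_caps_kernel, rng
            )
            self.bio_branch = self.seq_branch = None
            self.n_primary = self.branch.n_caps
        else:
            self.bio_branch = _Branch(
                cfg, cfg.bio_shape, cfg.bio_kernel, cfg.bio_pad, cfg.bio_caps_kernel, rng
            )
            self.seq_branch = _Branch(
                cfg,
                (cfg.seq_len, cfg.embedding_dim),
                cfg.seq_kernel,
                cfg.seq_pad,
                cfg.seq_caps_kernel,
                rng,
            )
            self.branch = None
            self.n_primary = self.bio_branch.n_caps + self.seq_branch.n_caps

        fan = cfg.caps_dim + cfg.out_caps_dim
        self.W = Tensor(
            rng.normal(
                0,
                np.sqrt(2.0 / fan),
                (1, self.n_primary, cfg.n_classes, cfg.caps_dim, cfg.out_caps_dim),
            ).astype(np.float32),
            requires_grad=True,
        )

    # -- forward -------------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = [self.embedding, self.W]
        for br in (self.bio_branch, self.seq_branch, self.branch):
            if br is not None:
                ps += br.params()
        return ps

    def embed_sequence(self, codes: np.ndarray) -> Tensor:
        """Embed integer codes (N x 50) into (N x 50 x emb_dim); pads embed to zero."""
        codes = np.asarray(codes)
        emb = embedding(self.embedding, codes)
        mask = (codes != 0).astype(np.float32)[..., None]
        return emb * Tensor(mask)

    def _masked_bio(self, bio: np.ndarray) -> np.ndarray:
        subs = self.cfg.feature_subsets
        if "rcc" in subs and "aac_dpc" in subs:
            return bio
        bio = bio.copy()
        if "rcc" not in subs:
            bio[:, :RCC_DIM] = 0.0
        if "aac_dpc" not in subs:
            bio[:, RCC_DIM:] = 0.0
        return bio

    def forward(
        self, bio: np.ndarray, codes: np.ndarray, return_state: bool = False
    ) -> tuple[Tensor, CapsuleState | None]:
        """Run the network; returns output capsules (N x 2 x out_dim)."""
        cfg = self.cfg
        bio = np.asarray(bio, dtype=np.float32)
        if bio.ndim != 2 or bio.shape[1] != BIO_DIM:
            raise ValueError(f"bio features must be (N, {BIO_DIM}), got {bio.shape}")
        n = bio.shape[0]
        if self.scaler is not None:
            bio = self.scaler.transform(bio)
        bio = self._masked_bio(bio)
        bio_map = Tensor(bio.reshape(n, 1, *cfg.bio_shape))
        seq = self.embed_sequence(codes)
        if "sec" not in cfg.feature_subsets:
            seq = seq * Tensor(np.zeros(1, dtype=np.float32))
        seq_map = seq.reshape(n, 1, cfg.seq_len, cfg.embedding_dim)

        if cfg.combined_input:
            stacked = concatenate([bio_map, seq_map], axis=2)
            u = self.branch(stacked)
        else:
            u = concatenate([self.seq_branch(seq_map), self.bio_branch(bio_map)], axis=1)
        if cfg.primary_squash:
            u = squash(u, eps=cfg.eps, norm_squared=cfg.squash_norm_squared)

        v, c, u_hat = dynamic_routing(
            u, self.W, cfg.routing_iters, cfg.eps, cfg.squash_norm_squared
        )
        state = None
        if return_state:
            state = CapsuleState(
                primary=u.data.copy(),
                predictions=u_hat.data.copy(),
                couplings=c.data.copy(),
                outputs=v.data.copy(),
            )
        return v, state

    def scores(self, bio: np.ndarray, codes: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        """Output-capsule norms (N x 2) computed without building gradients."""
        bs = batch_size or self.cfg.batch_size
        out = []
        for i in range(0, len(bio), bs):
            v, _ = self.forward(bio[i : i + bs], codes[i : i + bs])
            out.append(np.sqrt((v.data**2).sum(axis=-1)))
        return np.concatenate(out, axis=0)

    def predict(self, bio: np.ndarray, codes: np.ndarray) -> np.ndarray:
        return classify(self.scores(bio, codes))

    def fit_scaler(self, bio_train: np.ndarray) -> None:
        """Fit the biological-feature standardizer on training data."""
        self.scaler = FeatureScaler.fit(np.asarray(bio_train, dtype=np.float32))

    def make_optimizer(self) -> Adam:
        return Adam(self.parameters(), lr=self.cfg.lr, eps=self.cfg.eps)


# -- checkpointing -------------------------------------------------------------

CHECKPOINT_VERSION = 1


def _table_fingerprint(table) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(table.values).tobytes())
    h.update(",".join(table.columns).encode())
    return h.hexdigest()[:16]


def save_checkpoint(model: CapsNetCBAM, path: str | Path, table=None) -> None:
    """Serialize weights + config (+ property-table fingerprint) to one .npz file."""
    meta = {
        "checkpoint_version": CHECKPOINT_VERSION,
        "schema_version": CONFIG_SCHEMA_VERSION,
        "config": model.cfg.to_dict(),
        "table_fingerprint": _table_fingerprint(table) if table is not None else None,
        "residue_order": "ACDEFGHIKLMNPQRSTVWY",
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    if model.scaler is not None:
        arrays["scaler_mean"] = model.scaler.mean
        arrays["scaler_scale"] = model.scaler.scale
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[CapsNetCBAM, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta["checkpoint_version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['checkpoint_version']}")
        model = CapsNetCBAM(NetworkConfig.from_dict(meta["config"]))
        for i, p in enumerate(model.parameters()):
            arr = z[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint parameter {i} shape mismatch")
            p.data = arr.astype(np.float32)
        if "scaler_mean" in z:
            model.scaler = FeatureScaler(z["scaler_mean"], z["scaler_scale"])
    return model, meta
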