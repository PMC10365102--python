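"""TransResUNet: residual CNN encoder, transformer bottleneck, skip-connected decoder.

The network segments lung fields in frontal chest radiographs.  Its encoder is
a residual CNN that halves the spatial side three times, producing a feature
pyramid F1 (S/2), F2 (S/4), F3 (S/8).  F3 is cut into patches, linearly
embedded with an additive learned position table, and passed through a stack of
pre-norm transformer layers (multi-head self-attention + MLP) whose output Ft
re-enters a ResUNet-style decoder: at each scale the upsampled features are
concatenated with the matching pyramid level and refined by a residual block.
A 1x1 per-pixel head yields two-class (lung / background) logits at full
resolution.

Every structural hyperparameter lives in :class:`ModelConfig`, so the same code
runs as the full-size network (S=512, L=12, K=768) or as a tiny CPU instance
for testing and phantom studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import tensor as T


@dataclass
class ModelConfig:
    """Structural hyperparameters of the network.

    ``input_side`` must be divisible by ``8 * patch_stride`` so the token grid
    is integral, and ``embed_dim`` by ``attention_heads``.  ``mlp_dim`` of None
    means the conventional ``4 * embed_dim``.
    """

    input_side: int = 512
    encoder_channels: tuple[int, int, int] = (64, 128, 256)
    transformer_layers: int = 12
    embed_dim: int = 768
    attention_heads: int = 12
    mlp_dim: int | None = None
    patch_stride: int = 1
    num_classes: int = 2
    dropout: float = 0.1

    def __post_init__(self):
        self.encoder_channels = tuple(int(c) for c in self.encoder_channels)
        if len(self.encoder_channels) != 3:
            raise ValueError("encoder_channels must have exactly three entries")
        if self.patch_stride not in (1, 2, 4):
            raise ValueError("patch_stride must be 1, 2 or 4")
        if self.input_side % (8 * self.patch_stride) != 0:
            raise ValueError("input_side must be divisible by 8 * patch_stride")
        if self.embed_dim % self.attention_heads != 0:
            raise ValueError("embed_dim must be divisible by attention_heads")
        if self.num_classes != 2:
            raise ValueError("this segmentation head is two-class (lung/background)")
        if self.mlp_dim is None:
            self.mlp_dim = 4 * self.embed_dim

    @property
    def token_grid(self) -> int:
        return self.input_side // (8 * self.patch_stride)

    @property
    def num_tokens(self) -> int:
        return self.token_grid ** 2

    @classmethod
    def tiny(cls, input_side: int = 64) -> "ModelConfig":
        """A laptop-CPU instance used throughout the tests and phantom study."""
        return cls(input_side=input_side, encoder_channels=(8, 16, 32),
                   transformer_layers=2, embed_dim=64, attention_heads=4,
                   patch_stride=1, dropout=0.1)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["encoder_channels"] = tuple(d["encoder_channels"])
        return cls(**d)


class ResidualBlock(nn.Module):
    """transform(x) + shortcut(x).

    The transform is two 3x3 convolution -> batch-norm -> ReLU stages; the
    shortcut is the identity when channel counts match, else a 1x1 projection.
    The second batch-norm's scale initialises to zero so a fresh block is the
    identity map, which stabilises early training.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_channels, zero_init=True)
        self.proj = (None if in_channels == out_channels
                     else nn.Conv2d(in_channels, out_channels, 1, rng, bias=False))

    def forward(self, x):
        h = T.relu(self.bn1(self.conv1(x)))
        h = T.relu(self.bn2(self.conv2(h)))
        s = x if self.proj is None else self.proj(x)
        return h + s


class Encoder(nn.Module):
    """Three (residual block -> 2x average-pool) stages producing F1, F2, F3."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3 = cfg.encoder_channels
        self.block1 = ResidualBlock(1, c1, rng)
        self.block2 = ResidualBlock(c1, c2, rng)
        self.block3 = ResidualBlock(c2, c3, rng)

    def forward(self, x):
        f1 = T.avg_pool2(self.block1(x))    # S/2, c1
        f2 = T.avg_pool2(self.block2(f1))   # S/4, c2
        f3 = T.avg_pool2(self.block3(f2))   # S/8, c3
        return f1, f2, f3


class PatchEmbed(nn.Module):
    """Flatten F3 into p*p patches, project to the embedding dim, add positions."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c3 = cfg.encoder_channels[2]
        self.p = cfg.patch_stride
        self.proj = nn.Linear(c3 * self.p * self.p, cfg.embed_dim, rng)
        self.pos = nn.Parameter(nn.trunc_normal(rng, (cfg.num_tokens, cfg.embed_dim)))

    def forward(self, f3):
        b, c, h, w = f3.shape
        p = self.p
        x = T.reshape(f3, (b, c, h // p, p, w // p, p))
        x = T.transpose(x, (0, 2, 4, 1, 3, 5))           # B, gh, gw, C, p, p
        x = T.reshape(x, (b, (h // p) * (w // p), c * p * p))
        return self.proj(x) + self.pos


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 drop: float = 0.0):
        super().__init__()
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.out = nn.Linear(dim, dim, rng)
        self.drop = nn.Dropout(drop, rng)

    def _split(self, x, b, n):
        x = T.reshape(x, (b, n, self.heads, self.head_dim))
        return T.transpose(x, (0, 2, 1, 3))              # B, h, N, dh

    def forward(self, x):
        b, n, d = x.shape
        q = self._split(self.q(x), b, n)
        k = self._split(self.k(x), b, n)
        v = self._split(self.v(x), b, n)
        attn = T.softmax(T.matmul(q, T.transpose(k, (0, 1, 3, 2))) * self.scale)
        y = T.matmul(attn, v)                            # B, h, N, dh
        y = T.reshape(T.transpose(y, (0, 2, 1, 3)), (b, n, d))
        return self.drop(self.out(y))


class TransformerLayer(nn.Module):
    """Pre-norm residual: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(cfg.embed_dim)
        self.attn = MultiHeadSelfAttention(cfg.embed_dim, cfg.attention_heads,
                                           rng, cfg.dropout)
        self.norm2 = nn.LayerNorm(cfg.embed_dim)
        self.fc1 = nn.Linear(cfg.embed_dim, cfg.mlp_dim, rng)
        self.fc2 = nn.Linear(cfg.mlp_dim, cfg.embed_dim, rng)
        self.drop = nn.Dropout(cfg.dropout, rng)

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        h = self.drop(self.fc2(T.gelu(self.fc1(self.norm2(x)))))
        return x + h


class Decoder(nn.Module):
    """Ft+F3 -> block -> up -> +F2 -> block -> up -> +F1 -> block -> up -> head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c1, c2, c3 = cfg.encoder_channels
        k = cfg.embed_dim
        self.block3 = ResidualBlock(k + c3, c3, rng)
        self.block2 = ResidualBlock(c3 + c2, c2, rng)
        self.block1 = ResidualBlock(c2 + c1, c1, rng)
        self.head = nn.Conv2d(c1, cfg.num_classes, 1, rng)
        self.p = cfg.patch_stride

    def forward(self, ft_map, pyramid):
        f1, f2, f3 = pyramid
        x = ft_map
        p = self.p
        while p > 1:                       # bring token map back to S/8
            x = T.upsample_nearest2(x)
            p //= 2
        x = self.block3(T.concat([x, f3], axis=1))
        x = T.upsample_nearest2(x)
        x = self.block2(T.concat([x, f2], axis=1))
        x = T.upsample_nearest2(x)
        x = self.block1(T.concat([x, f1], axis=1))
        x = T.upsample_nearest2(x)         # full resolution for per-pixel head
        return self.head(x)


class TransResUNet(nn.Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.embed = PatchEmbed(cfg, rng)
        self.layers = [TransformerLayer(cfg, rng)
                       for _ in range(cfg.transformer_layers)]
        self.final_norm = nn.LayerNorm(cfg.embed_dim)
        self.decoder = Decoder(cfg, rng)

    # -- pieces, exposed for inspection and testing ------------------------
    def encode_tokens(self, f3):
        x = self.embed(f3)
        for layer in self.layers:
            x = layer(x)
        return self.final_norm(x)

    def tokens_to_map(self, tokens):
        b, n, k = tokens.shape
        g = self.cfg.token_grid
        x = T.reshape(tokens, (b, g, g, k))
        return T.transpose(x, (0, 3, 1, 2))

    def forward(self, x):
        """(B,1,S,S) image batch -> (B,2,S,S) logits."""
        if not isinstance(x, T.Tensor):
            x = T.Tensor(np.asarray(x, dtype=np.float32))
        pyramid = self.encoder(x)
        tokens = self.encode_tokens(pyramid[2])
        return self.decoder(self.tokens_to_map(tokens), pyramid)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel lung probability for one preprocessed (S,S) image."""
        was_training = self.training
        self.eval()
        logits = self.forward(image[None, None].astype(np.float32))
        probs = T.softmax(T.transpose(logits, (0, 2, 3, 1))).data[0, :, :, 1]
        if was_training:
            self.train()
        return probs

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def save_checkpoint(model: TransResUNet, path) -> None:
    """Write weights + buffers as .npz with the config embedded as JSON."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        model.cfg.to_json().encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> TransResUNet:
    with np.load(path) as data:
        cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
        model = TransResUNet(cfg)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
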