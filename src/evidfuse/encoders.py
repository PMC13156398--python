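"""Per-modality feature extractors and auxiliary classification heads.

Structured (tabular) encoders: a 3-layer MLP and a simplified tabular
ResNet, both emitting 32-dimensional features by default; further
architectures (e.g. transformer-based tabular encoders) can be plugged
in through :func:`register_encoder` as long as they satisfy the same
``encoder(x) -> features`` contract with an ``output_dim`` attribute.

Text is handled through a frozen embedding provider (a plain function
from text/tokens to a fixed-size vector, carrying no trainable state)
plus one trainable 128-unit projection layer.  The shipped provider is
:func:`hashing_stub`, a deterministic bag-of-hashed-tokens embedder that
needs no downloads and no randomness; a real pre-trained language-model
provider plugs in through the same contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .autodiff import Tensor, relu
from .nn import Dropout, Linear, Module

__all__ = [
    "StructuredEncoderConfig",
    "TextEncoderConfig",
    "MLPEncoder",
    "ResNetEncoder",
    "TextEncoder",
    "AuxHead",
    "hashing_stub",
    "embed_corpus",
    "make_structured_encoder",
    "register_encoder",
    "sphere_normalize",
    "PAD_TOKEN",
]

PAD_TOKEN = "<pad>"


@dataclass
class StructuredEncoderConfig:
    architecture: str = "mlp"
    n_layers: int = 3  # layers for the MLP, residual blocks for the ResNet
    hidden_units: int = 32
    dropout: float = 0.1
    output_dim: int = 32
    normalize_output: bool = True  # project features onto the √dim sphere

    def __post_init__(self):
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TextEncoderConfig:
    provider: str = "hashing_stub"
    embedding_dim: int = 256
    hidden_units: int = 128
    max_tokens: int = 512
    normalize_output: bool = True


def sphere_normalize(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Scale each feature row to L2 norm √dim (zero rows stay zero).

    Bounding the feature space keeps the distance-based evidential
    layer responsive while the encoders reshape their representations
    during joint training; without a bound the features can drift away
    from the prototypes, the activations underflow, and the fused mass
    saturates at total ignorance with vanishing gradient.
    """
    d = x.shape[-1]
    sumsq = (x * x).sum(axis=-1, keepdims=True)
    return x * ((sumsq + eps * eps) ** -0.5) * np.sqrt(d)


class MLPEncoder(Module):
    """Fully connected encoder: n_layers of (Linear → ReLU → Dropout)."""

    def __init__(self, n_in: int, cfg: StructuredEncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.output_dim = cfg.output_dim
        widths = [n_in] + [cfg.hidden_units] * (cfg.n_layers - 1) + [cfg.output_dim]
        self.layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.dropout = Dropout(cfg.dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = self.dropout(relu(layer(x)))
        return sphere_normalize(x) if self.cfg.normalize_output else x


class ResNetEncoder(Module):
    """Simplified tabular ResNet: an input projection followed by
    residual blocks with a direct path from block input to output."""

    def __init__(self, n_in: int, cfg: StructuredEncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.output_dim = cfg.output_dim
        self.proj = Linear(n_in, cfg.output_dim, rng)
        self.blocks = [
            (Linear(cfg.output_dim, cfg.hidden_units, rng),
             Linear(cfg.hidden_units, cfg.output_dim, rng))
            for _ in range(cfg.n_layers)
        ]
        self.dropout = Dropout(cfg.dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.proj(x)
        for lin1, lin2 in self.blocks:
            h = h + self.dropout(lin2(relu(lin1(h))))
        return sphere_normalize(h) if self.cfg.normalize_output else h


_ENCODERS: dict[str, Callable] = {"mlp": MLPEncoder, "resnet": ResNetEncoder}


def register_encoder(name: str, factory: Callable) -> None:
    """Register an external structured-encoder factory
    ``factory(n_in, cfg, rng) -> Module`` under ``name``."""
    _ENCODERS[name] = factory


def make_structured_encoder(
    n_in: int, cfg: StructuredEncoderConfig, rng: np.random.Generator
) -> Module:
    try:
        factory = _ENCODERS[cfg.architecture]
    except KeyError:
        raise ValueError(
            f"unknown encoder architecture {cfg.architecture!r}; "
            f"registered: {sorted(_ENCODERS)}"
        ) from None
    return factory(n_in, cfg, rng)


class TextEncoder(Module):
    """Frozen embedding provider + one trainable 128-unit projection.

    The provider runs outside the autodiff graph, so no gradient can
    reach it; only the projection layer trains.
    """

    def __init__(
        self,
        cfg: TextEncoderConfig,
        rng: np.random.Generator,
        provider: Callable | None = None,
    ):
        self.cfg = cfg
        self.output_dim = cfg.hidden_units
        self.provider = provider if provider is not None else (
            lambda text: hashing_stub(text, cfg.embedding_dim)
        )
        self.projection = Linear(cfg.embedding_dim, cfg.hidden_units, rng)

    def embed(self, texts: Sequence) -> np.ndarray:
        """Run the frozen provider over a corpus; returns (N, embedding_dim)."""
        name = getattr(self.provider, "__name__", repr(self.provider))
        rows = []
        for t in texts:
            try:
                rows.append(np.asarray(self.provider(t), dtype=np.float64))
            except Exception as exc:  # surface the provider's identity
                raise RuntimeError(f"text embedding provider {name!r} failed: {exc}") from exc
        return np.stack(rows)

    def __call__(self, embeddings: Tensor | np.ndarray) -> Tensor:
        if not isinstance(embeddings, Tensor):
            embeddings = Tensor(embeddings)
        h = relu(self.projection(embeddings))
        return sphere_normalize(h) if self.cfg.normalize_output else h


class AuxHead(Module):
    """Single affine map from encoder features to M class logits; used
    only by the auxiliary training losses, never at inference."""

    def __init__(self, feature_dim: int, n_classes: int, rng: np.random.Generator):
        self.linear = Linear(feature_dim, n_classes, rng)

    def __call__(self, features: Tensor) -> Tensor:
        return self.linear(features)


def _token_bucket(token: str, dim: int) -> int:
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") % dim


def hashing_stub(text, dim: int = 256) -> np.ndarray:
    """Deterministic bag-of-hashed-tokens embedding, L2-normalized.

    Accepts a raw string (lowercased, whitespace-tokenized) or an
    iterable of tokens; padding tokens are ignored.  An empty input
    yields the zero vector.
    """
    if isinstance(text, str):
        tokens: Iterable[str] = text.lower().split()
    else:
        tokens = text
    v = np.zeros(dim, dtype=np.float64)
    for tok in tokens:
        if tok == PAD_TOKEN:
            continue
        v[_token_bucket(tok, dim)] += 1.0
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def embed_corpus(token_seqs: Sequence[Sequence[str]], dim: int = 256) -> np.ndarray:
    """Apply :func:`hashing_stub` to every token sequence in a corpus."""
    return np.stack([hashing_stub(seq, dim) for seq in token_seqs])
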