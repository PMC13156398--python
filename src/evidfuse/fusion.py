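"""Multimodal assembly: per-modality evidence mapping, Dempster-rule
evidence fusion, the pignistic decision layer, and the comparison
fusion strategies (concatenation, mean, attention).

The dataset can be partitioned into evidence sources three ways:

* ``modalities``   — {structured, notes}               (K = 2)
* ``data_types``   — {numerical, categorical, notes}   (K = 3)
* ``data_sources`` — one bundle per structured source
  (demographics, vitals_labs, treatments, comorbidities) plus one per
  note type.

Every bundle owns an encoder, an evidential (prototype) layer and an
auxiliary head; the per-bundle masses are pooled with Dempster's rule
and turned into probabilities by the pignistic transform, with the
fused m(Ω) reported as the prediction's ignorance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, relu
from .belief import (EPS_CONFLICT, Frame, SimpleMass, binary_frame,
                     combine_masses_vec, combine_simple)
from .encoders import (AuxHead, StructuredEncoderConfig, TextEncoder,
                       TextEncoderConfig, make_structured_encoder)
from .evidence import EMConfig, init_prototypes
from .nn import Linear, Module

__all__ = [
    "FusionSpec",
    "BundleSpec",
    "MultimodalDataset",
    "ModalityBundle",
    "EvidentialModel",
    "BaselineModel",
    "fuse_evidence",
    "split_by_partition",
    "build_model",
]

PARTITIONS = ("modalities", "data_types", "data_sources")
STRATEGIES = ("evidential", "concatenation", "mean", "attention")


@dataclass
class FusionSpec:
    strategy: str = "evidential"
    partition: str = "modalities"
    decision_threshold: float = 0.5
    include: tuple | None = None  # restrict to named bundles (ablations)

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if self.partition not in PARTITIONS:
            raise ValueError(f"unknown partition {self.partition!r}")


@dataclass
class BundleSpec:
    """Where one evidence source's input comes from."""

    name: str
    kind: str                       # "structured" | "text"
    columns: list[int] | None = None  # structured: column indices into X
    note_group: str | None = None     # text: key into note embeddings


@dataclass
class MultimodalDataset:
    """Model-ready view of a cohort: preprocessed structured matrix with
    per-column tags, frozen note embeddings per group, and labels."""

    X: np.ndarray
    feature_tags: list            # per-column {"source", "type"}
    note_embeddings: dict         # group -> (N, embedding_dim)
    labels: np.ndarray
    ids: list = field(default_factory=list)


def split_by_partition(dataset: MultimodalDataset, partition: str) -> list[BundleSpec]:
    """Partition the inputs into disjoint, jointly exhaustive bundles."""
    tags = dataset.feature_tags
    for j, t in enumerate(tags):
        if "source" not in t or "type" not in t:
            raise ValueError(f"column {j} is missing source/type tags")
    all_cols = list(range(len(tags)))
    note_groups = sorted(dataset.note_embeddings)
    specs: list[BundleSpec] = []
    if partition == "modalities":
        specs.append(BundleSpec("structured", "structured", columns=all_cols))
        specs.append(BundleSpec("notes", "text", note_group="combined"))
    elif partition == "data_types":
        for type_name in ("numerical", "categorical"):
            cols = [j for j, t in enumerate(tags) if t["type"] == type_name]
            if cols:
                specs.append(BundleSpec(type_name, "structured", columns=cols))
        specs.append(BundleSpec("notes", "text", note_group="combined"))
    elif partition == "data_sources":
        seen: set[int] = set()
        for source in ("demographics", "vitals_labs", "treatments", "comorbidities"):
            cols = [j for j, t in enumerate(tags) if t["source"] == source]
            if cols:
                specs.append(BundleSpec(source, "structured", columns=cols))
                seen.update(cols)
        leftover = [j for j in all_cols if j not in seen]
        if leftover:
            raise ValueError(f"columns with unknown source tag: {leftover}")
        for group in note_groups:
            if group != "combined":
                specs.append(BundleSpec(f"notes:{group}", "text", note_group=group))
    else:
        raise ValueError(f"unknown partition {partition!r}")
    # verify which note groups are actually available
    for s in specs:
        if s.kind == "text" and s.note_group not in dataset.note_embeddings:
            raise ValueError(f"note group {s.note_group!r} not present in the dataset")
    return specs


def bundle_input(dataset: MultimodalDataset, spec: BundleSpec) -> np.ndarray:
    if spec.kind == "structured":
        return dataset.X[:, spec.columns]
    return dataset.note_embeddings[spec.note_group]


def fuse_evidence(masses: Sequence[SimpleMass]) -> SimpleMass:
    """Left-fold of Dempster's rule over K ≥ 1 modality masses."""
    if not masses:
        raise ValueError("need at least one mass to fuse")
    out = masses[0]
    for m in masses[1:]:
        out = combine_simple(out, m)
    return out


class ModalityBundle(Module):
    """One modality's encoder + evidential layer + auxiliary head."""

    def __init__(self, name: str, kind: str, encoder: Module, em, aux_head: AuxHead):
        if em.feature_dim != encoder.output_dim:
            raise ValueError("evidential layer dimension must match the encoder output")
        self.name = name
        self.kind = kind
        self.encoder = encoder
        self.em = em
        self.aux_head = aux_head

    def forward(self, x: Tensor):
        features = self.encoder(x)
        sing, ig = self.em(features)
        logits = self.aux_head(features)
        return sing, ig, logits, features


class EvidentialModel(Module):
    """Full model: per-bundle evidence mapping, Dempster-rule fusion,
    pignistic probabilities, fused ignorance."""

    def __init__(self, bundles: list[ModalityBundle], frame: Frame | None = None):
        self.frame = frame if frame is not None else binary_frame()
        self.bundles = bundles

    def forward(self, inputs: dict) -> dict:
        sing = ig = None
        aux_logits: dict[str, Tensor] = {}
        per_bundle: dict[str, tuple] = {}
        for bundle in self.bundles:
            if bundle.name not in inputs:
                raise KeyError(f"missing input for modality {bundle.name!r}")
            x = inputs[bundle.name]
            if not isinstance(x, Tensor):
                x = Tensor(x)
            b_sing, b_ig, logits, _ = bundle.forward(x)
            aux_logits[bundle.name] = logits
            per_bundle[bundle.name] = (b_sing, b_ig)
            if sing is None:
                sing, ig = b_sing, b_ig
            else:
                sing, ig, _ = combine_masses_vec(sing, ig, b_sing, b_ig,
                                                 floor=EPS_CONFLICT)
        m = self.frame.n_classes
        p = sing + ig * (1.0 / m)  # pignistic transform, batched
        return {
            "singletons": sing,
            "ignorance": ig,
            "p": p,
            "aux_logits": aux_logits,
            "per_bundle": per_bundle,
        }

    __call__ = forward

    def predict(self, inputs: dict) -> dict:
        """Eval-mode numpy predictions with uncertainty report."""
        self.eval()
        out = self.forward(inputs)
        return {
            "p": out["p"].data,
            "p_positive": out["p"].data[:, 1],
            "m_singletons": out["singletons"].data,
            "m_ignorance": out["ignorance"].data[:, 0],
        }


class BaselineModel(Module):
    """Comparison fusion strategies on the same encoders/aux heads.

    concatenation: concat features → two fully connected layers → logits.
    mean: per-bundle projection to a shared width, averaged → head.
    attention: learned per-bundle scores, softmax over bundles, convex
    combination of projected features → head.
    """

    def __init__(self, bundles_enc: list[tuple[str, str, Module, AuxHead]],
                 strategy: str, rng: np.random.Generator,
                 frame: Frame | None = None, proj_dim: int = 64):
        if strategy == "evidential":
            raise ValueError("use EvidentialModel for the evidential strategy")
        self.frame = frame if frame is not None else binary_frame()
        self.strategy = strategy
        self.names = [name for name, _, _, _ in bundles_enc]
        self.kinds = {name: kind for name, kind, _, _ in bundles_enc}
        self.encoders = {name: enc for name, _, enc, _ in bundles_enc}
        self.aux_heads = {name: head for name, _, _, head in bundles_enc}
        m = self.frame.n_classes
        if strategy == "concatenation":
            total = sum(enc.output_dim for enc in self.encoders.values())
            self.fc1 = Linear(total, proj_dim, rng)
            self.fc2 = Linear(proj_dim, m, rng)
        else:
            self.proj = {
                name: Linear(enc.output_dim, proj_dim, rng)
                for name, enc in self.encoders.items()
            }
            self.head = Linear(proj_dim, m, rng)
            if strategy == "attention":
                self.scorers = {name: Linear(proj_dim, 1, rng) for name in self.names}

    def forward(self, inputs: dict) -> dict:
        feats: dict[str, Tensor] = {}
        aux_logits: dict[str, Tensor] = {}
        for name in self.names:
            if name not in inputs:
                raise KeyError(f"missing input for modality {name!r}")
            x = inputs[name]
            if not isinstance(x, Tensor):
                x = Tensor(x)
            f = self.encoders[name](x)
            feats[name] = f
            aux_logits[name] = self.aux_heads[name](f)
        if self.strategy == "concatenation":
            h = ad.concatenate([feats[n] for n in self.names], axis=-1)
            logits = self.fc2(relu(self.fc1(h)))
        else:
            projected = [self.proj[n](feats[n]) for n in self.names]
            if self.strategy == "mean":
                fused = projected[0]
                for t in projected[1:]:
                    fused = fused + t
                fused = fused * (1.0 / len(projected))
            else:  # attention
                scores = ad.concatenate(
                    [self.scorers[n](p) for n, p in zip(self.names, projected)],
                    axis=-1,
                )  # (B, K)
                w = ad.softmax(scores, axis=-1)
                fused = None
                for k, t in enumerate(projected):
                    wk = w[:, k].reshape(w.shape[0], 1)
                    fused = t * wk if fused is None else fused + t * wk
            logits = self.head(fused)
        p = ad.softmax(logits, axis=-1)
        return {"logits": logits, "p": p, "aux_logits": aux_logits}

    __call__ = forward

    def predict(self, inputs: dict) -> dict:
        self.eval()
        out = self.forward(inputs)
        return {"p": out["p"].data, "p_positive": out["p"].data[:, 1]}


def build_model(
    dataset: MultimodalDataset,
    bundle_specs: Sequence[BundleSpec],
    enc_cfg: StructuredEncoderConfig,
    text_cfg: TextEncoderConfig,
    em_cfg: EMConfig,
    strategy: str,
    train_idx: np.ndarray,
    seed: int,
    frame: Frame | None = None,
):
    """Construct a fusion model; for the evidential strategy the
    prototypes are initialized from the (randomly initialized) encoder's
    outputs on the training rows."""
    frame = frame if frame is not None else binary_frame()
    rng = np.random.default_rng(seed)
    parts: list = []
    for spec in bundle_specs:
        x = bundle_input(dataset, spec)
        if spec.kind == "structured":
            encoder = make_structured_encoder(x.shape[1], enc_cfg, rng)
        else:
            encoder = TextEncoder(text_cfg, rng)
        aux = AuxHead(encoder.output_dim, frame.n_classes, rng)
        if strategy == "evidential":
            encoder.eval()
            train_feats = encoder(Tensor(x[train_idx])).data
            encoder.train()
            bank = init_prototypes(
                train_feats,
                EMConfig(em_cfg.n_prototypes, em_cfg.init_scheme,
                         feature_dim=encoder.output_dim),
                frame,
                seed=int(rng.integers(2 ** 31)),
            )
            parts.append(ModalityBundle(spec.name, spec.kind, encoder, bank, aux))
        else:
            parts.append((spec.name, spec.kind, encoder, aux))
    if strategy == "evidential":
        return EvidentialModel(parts, frame)
    return BaselineModel(parts, strategy, rng, frame)
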