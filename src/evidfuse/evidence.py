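"""Evidence mapping: the prototype-based evidential layer (ENN).

Each of H learned prototypes π_h is treated as a piece of evidence about
the class of an input feature vector x.  The evidence is discounted by
distance,

    s_h = β_h · exp(−γ_h · ‖x − π_h‖²),   β_h ∈ [0,1], γ_h > 0,

turned into a restricted mass function

    m_h({ω_c}) = u_h^(c) · s_h,     m_h(Ω) = 1 − s_h,

with u_h a learned class-membership vector on the simplex, and the H
masses are pooled with Dempster's rule into a single class mass plus an
explicit ignorance term m(Ω).

All constrained quantities are parameterized through smooth bijections
(β via logistic, γ via softplus, u via row-softmax) so the layer trains
unconstrained; every parameter is learned jointly with the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from . import autodiff as ad
from .autodiff import Tensor
from .belief import EPS_CONFLICT, Frame, SimpleMass, combine_masses_vec
from .nn import Module

__all__ = [
    "EMConfig",
    "PrototypeBank",
    "activation",
    "prototype_mass",
    "enn_forward",
    "init_prototypes",
]


@dataclass
class EMConfig:
    """Evidential-layer configuration (20 prototypes by default)."""

    n_prototypes: int = 20
    init_scheme: str = "kmeans"  # or "random_sample"
    feature_dim: int | None = None

    def __post_init__(self):
        if self.n_prototypes < 1:
            raise ValueError("need at least one prototype")
        if self.init_scheme not in ("kmeans", "random_sample"):
            raise ValueError(f"unknown init scheme {self.init_scheme!r}")


def _softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


class PrototypeBank(Module):
    """Learnable prototypes with scale, reliability and membership params."""

    def __init__(
        self,
        frame: Frame,
        prototypes: np.ndarray,
        raw_gamma: np.ndarray,
        raw_beta: np.ndarray,
        raw_membership: np.ndarray,
    ):
        prototypes = np.atleast_2d(np.asarray(prototypes, dtype=np.float64))
        h, d = prototypes.shape
        m = frame.n_classes
        if raw_membership.shape != (h, m):
            raise ValueError("membership shape must be (H, M)")
        self.frame = frame
        self.n_prototypes = h
        self.feature_dim = d
        self.prototypes = Tensor(prototypes, requires_grad=True)
        self.raw_gamma = Tensor(np.broadcast_to(raw_gamma, (h,)).copy(), requires_grad=True)
        self.raw_beta = Tensor(np.broadcast_to(raw_beta, (h,)).copy(), requires_grad=True)
        self.raw_membership = Tensor(np.asarray(raw_membership, float), requires_grad=True)

    # constrained views -------------------------------------------------
    def gamma(self) -> Tensor:
        return ad.softplus(self.raw_gamma)

    def beta(self) -> Tensor:
        return ad.sigmoid(self.raw_beta)

    def memberships(self) -> Tensor:
        return ad.softmax(self.raw_membership, axis=-1)

    @property
    def gamma_np(self) -> np.ndarray:
        return self.gamma().data

    @property
    def beta_np(self) -> np.ndarray:
        return self.beta().data

    @property
    def memberships_np(self) -> np.ndarray:
        return self.memberships().data

    # forward ------------------------------------------------------------
    def activations(self, x: Tensor) -> Tensor:
        """Distance-discounted activations s_h, shape (B, H)."""
        if x.shape[-1] != self.feature_dim:
            raise ValueError(
                f"feature dim {x.shape[-1]} does not match prototypes ({self.feature_dim})"
            )
        b = x.shape[0]
        diff = x.reshape(b, 1, self.feature_dim) - self.prototypes.reshape(
            1, self.n_prototypes, self.feature_dim
        )
        d2 = (diff * diff).sum(axis=-1)  # (B, H)
        gamma = self.gamma().reshape(1, self.n_prototypes)
        beta = self.beta().reshape(1, self.n_prototypes)
        return beta * (-(gamma * d2)).exp()

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Map features to fused masses: (singletons (B, M), ignorance (B, 1)).

        The Dempster fold over the H restricted prototype masses is
        evaluated in closed form: with w_c = Π_h (m_h({ω_c}) + m_h(Ω))
        and w_Ω = Π_h m_h(Ω), the unnormalized combination is
        (w_c − w_Ω) on each singleton and w_Ω on Ω.  A single final
        normalization is algebraically identical to per-step
        normalization; the normalizer is clamped at EPS_CONFLICT to
        keep gradients finite under (unreachable) total conflict.
        """
        b = x.shape[0]
        h, m = self.n_prototypes, self.frame.n_classes
        s = self.activations(x)  # (B, H)
        u = self.memberships()  # (H, M)
        sing_h = u.reshape(1, h, m) * s.reshape(b, h, 1)  # (B, H, M)
        ig_h = (1.0 - s).reshape(b, h, 1)  # (B, H, 1)
        w = (sing_h + ig_h).prod(axis=1)  # (B, M)
        w_ig = ig_h.prod(axis=1)  # (B, 1)
        sing = w - w_ig
        total = sing.sum(axis=-1, keepdims=True) + w_ig
        total = ad.maximum(total, EPS_CONFLICT)
        return sing / total, w_ig / total

    __call__ = forward


# -- eager, single-sample operations (used by tests and reports) --------

def activation(x: np.ndarray, bank: PrototypeBank) -> np.ndarray:
    """Activations s_h for a single feature vector."""
    return bank.activations(Tensor(np.asarray(x, float)[None, :])).data[0]


def prototype_mass(s: float, u: np.ndarray, frame: Frame) -> SimpleMass:
    """The restricted mass contributed by one prototype."""
    u = np.asarray(u, dtype=np.float64)
    return SimpleMass(frame, u * s, 1.0 - float(s))


def enn_forward(x: np.ndarray, bank: PrototypeBank) -> SimpleMass:
    """Full evidential layer on one feature vector, as a SimpleMass."""
    sing, ig = bank.forward(Tensor(np.asarray(x, float)[None, :]))
    return SimpleMass(bank.frame, sing.data[0], float(ig.data[0, 0]))


def init_prototypes(
    features: np.ndarray,
    cfg: EMConfig,
    frame: Frame,
    seed: int,
) -> PrototypeBank:
    """Initialize a bank from a sample of encoder outputs.

    Prototypes come from k-means centroids (default) or random training
    samples; the initial scale is γ = 1 / (mean squared pairwise
    prototype distance), reliabilities start at β ≈ 0.5, and memberships
    start near-uniform with small seeded noise.
    """
    features = np.asarray(features, dtype=np.float64)
    h = cfg.n_prototypes
    if features.ndim != 2 or features.shape[0] < h:
        raise ValueError(f"need at least {h} feature vectors to place prototypes")
    rng = np.random.default_rng(seed)
    if cfg.init_scheme == "kmeans":
        km = KMeans(n_clusters=h, n_init=10, random_state=seed)
        km.fit(features)
        protos = km.cluster_centers_
    else:
        idx = rng.choice(features.shape[0], size=h, replace=False)
        protos = features[idx].copy()

    if h > 1:
        d2 = ((protos[:, None, :] - protos[None, :, :]) ** 2).sum(-1)
        mean_d2 = d2[~np.eye(h, dtype=bool)].mean()
    else:
        mean_d2 = ((features - protos[0]) ** 2).sum(-1).mean()
    # widen the initial kernel by the scale of the ambient feature space
    # (mean squared distance of two random points on the sqrt(dim) sphere
    # is 2*dim): encoder features move during joint training, and a
    # kernel calibrated only to the initial prototype scatter underflows
    # once they do, silencing the layer's gradient for good.  gamma is
    # learned, so resolution recovers as the prototypes settle.
    dim = protos.shape[1]
    gamma0 = 1.0 / max(mean_d2 + 2.0 * dim, 1e-12)

    m = frame.n_classes
    return PrototypeBank(
        frame,
        protos,
        raw_gamma=np.full(h, _softplus_inv(gamma0)),
        raw_beta=np.zeros(h),  # sigmoid(0) = 0.5
        raw_membership=0.01 * rng.standard_normal((h, m)),
    )
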