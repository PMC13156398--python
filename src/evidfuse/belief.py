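"""Exact Dempster-Shafer algebra over a finite frame of discernment.

Two representations are provided:

* :class:`GeneralMass` — masses on arbitrary non-empty subsets of the
  frame (the power-set form).  Used as the exact oracle.
* :class:`SimpleMass` — the restricted family the evidential network
  works with: the M singletons plus total ignorance m(Ω), i.e. the
  (M+1)-vector (m({ω_1}), …, m({ω_M}), m(Ω)).  This family is closed
  under Dempster's rule, which is what makes the network layer cheap.

Dempster's combination rule pools two independent mass functions
conjunctively and renormalizes by 1 − κ, where the degree of conflict κ
is the total product mass landing on the empty set.  κ = 1 (total
conflict) makes the rule undefined; eager combination raises, while the
vectorized form used inside the differentiable graph clamps the
denominator at ``EPS_CONFLICT`` to keep gradients finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import autodiff as ad

__all__ = [
    "EPS_CONFLICT",
    "Frame",
    "GeneralMass",
    "SimpleMass",
    "TotalConflictError",
    "FrameMismatchError",
    "vacuous",
    "bayesian",
    "conflict_degree",
    "combine_general",
    "combine_simple",
    "combine_many",
    "combine_masses_vec",
    "pignistic",
    "mass_to_json",
    "mass_from_json",
]

EPS_CONFLICT = 1e-12
_SUM_TOL = 1e-9


class TotalConflictError(ValueError):
    """Raised when two pieces of evidence are (numerically) fully conflicting."""

    def __init__(self, kappa: float):
        self.kappa = float(kappa)
        super().__init__(
            f"total conflict: degree of conflict kappa={self.kappa!r} leaves "
            f"no mass to renormalize (kappa >= 1 - {EPS_CONFLICT})"
        )


class FrameMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class Frame:
    """An ordered frame of discernment Ω = {ω_1, …, ω_M}."""

    labels: tuple

    def __init__(self, labels: Sequence):
        object.__setattr__(self, "labels", tuple(labels))
        if len(self.labels) < 2:
            raise ValueError("a frame needs at least two hypotheses")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("frame labels must be distinct")

    @property
    def n_classes(self) -> int:
        return len(self.labels)


def binary_frame() -> Frame:
    """The two-class outcome frame used throughout the pipeline."""
    return Frame(("negative", "positive"))


def _check_frames(a, b) -> None:
    if a.frame != b.frame:
        raise FrameMismatchError(f"frames differ: {a.frame} vs {b.frame}")


def _canon(subset, m: int) -> tuple:
    idx = tuple(sorted(set(int(i) for i in subset)))
    if not idx:
        raise ValueError("the empty set cannot carry mass")
    if idx[0] < 0 or idx[-1] >= m:
        raise ValueError(f"subset {idx} out of range for a {m}-class frame")
    return idx


class GeneralMass:
    """A mass function on the power set, keyed by sorted index tuples.

    Zero-mass entries are dropped so equal masses have equal
    representations.
    """

    def __init__(self, frame: Frame, assignments: Mapping):
        self.frame = frame
        m = frame.n_classes
        acc: dict[tuple, float] = {}
        for subset, mass in assignments.items():
            mass = float(mass)
            if mass < -_SUM_TOL:
                raise ValueError(f"negative mass {mass} on {subset}")
            key = _canon(subset, m)
            acc[key] = acc.get(key, 0.0) + mass
        total = sum(acc.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"masses sum to {total}, not 1")
        self.assignments: dict[tuple, float] = {
            k: v for k, v in acc.items() if v > 0.0
        }

    def mass(self, subset) -> float:
        return self.assignments.get(_canon(subset, self.frame.n_classes), 0.0)

    def allclose(self, other: "GeneralMass", tol: float = 1e-9) -> bool:
        keys = set(self.assignments) | set(other.assignments)
        return self.frame == other.frame and all(
            abs(self.assignments.get(k, 0.0) - other.assignments.get(k, 0.0)) <= tol
            for k in keys
        )


@dataclass
class SimpleMass:
    """Restricted mass: M singleton masses plus the ignorance mass m(Ω)."""

    frame: Frame
    singletons: np.ndarray
    ignorance: float
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.singletons = np.asarray(self.singletons, dtype=np.float64)
        self.ignorance = float(self.ignorance)
        if self._validate:
            if self.singletons.shape != (self.frame.n_classes,):
                raise ValueError(
                    f"expected {self.frame.n_classes} singleton masses, "
                    f"got shape {self.singletons.shape}"
                )
            if (self.singletons < -_SUM_TOL).any() or self.ignorance < -_SUM_TOL:
                raise ValueError("masses must be non-negative")
            total = self.singletons.sum() + self.ignorance
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"masses sum to {total}, not 1")

    @property
    def vector(self) -> np.ndarray:
        """(M+1)-vector (m({ω_1}), …, m({ω_M}), m(Ω))."""
        return np.append(self.singletons, self.ignorance)

    def to_general(self) -> GeneralMass:
        m = self.frame.n_classes
        assignments: dict[tuple, float] = {
            (c,): float(v) for c, v in enumerate(self.singletons)
        }
        assignments[tuple(range(m))] = self.ignorance
        return GeneralMass(self.frame, assignments)

    def allclose(self, other: "SimpleMass", tol: float = 1e-9) -> bool:
        return (
            self.frame == other.frame
            and np.allclose(self.singletons, other.singletons, atol=tol)
            and abs(self.ignorance - other.ignorance) <= tol
        )


def vacuous(frame: Frame) -> SimpleMass:
    """Total ignorance: all mass on Ω."""
    return SimpleMass(frame, np.zeros(frame.n_classes), 1.0)


def bayesian(frame: Frame, p: Sequence[float]) -> SimpleMass:
    """A probability vector viewed as a mass with no ignorance."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (frame.n_classes,) or (p < -_SUM_TOL).any() or abs(p.sum() - 1) > _SUM_TOL:
        raise ValueError("p must be a probability vector over the frame")
    return SimpleMass(frame, p, 0.0)


def conflict_degree(m1, m2) -> float:
    """Degree of conflict κ = Σ_{B∩C=∅} m1(B)·m2(C)."""
    _check_frames(m1, m2)
    if isinstance(m1, SimpleMass) and isinstance(m2, SimpleMass):
        a, b = m1.singletons, m2.singletons
        return float(a.sum() * b.sum() - (a * b).sum())
    g1 = m1.to_general() if isinstance(m1, SimpleMass) else m1
    g2 = m2.to_general() if isinstance(m2, SimpleMass) else m2
    kappa = 0.0
    for sb, mb in g1.assignments.items():
        for sc, mc in g2.assignments.items():
            if not set(sb) & set(sc):
                kappa += mb * mc
    return kappa


def combine_general(m1: GeneralMass, m2: GeneralMass) -> GeneralMass:
    """Dempster's rule on power-set masses (the exact oracle)."""
    _check_frames(m1, m2)
    acc: dict[tuple, float] = {}
    kappa = 0.0
    for sb, mb in m1.assignments.items():
        for sc, mc in m2.assignments.items():
            inter = tuple(sorted(set(sb) & set(sc)))
            w = mb * mc
            if inter:
                acc[inter] = acc.get(inter, 0.0) + w
            else:
                kappa += w
    denom = 1.0 - kappa
    if denom < EPS_CONFLICT:
        raise TotalConflictError(kappa)
    return GeneralMass(m1.frame, {k: v / denom for k, v in acc.items()})


def combine_masses_vec(a, a_ig, b, b_ig, floor: float | None = None):
    """Dempster's rule on batches of restricted masses.

    Works on numpy arrays and on :class:`~evidfuse.autodiff.Tensor`
    alike (only operators and ``.sum`` are used).  ``a``/``b`` have the
    singleton masses in the last axis; ``a_ig``/``b_ig`` the ignorance
    with a trailing axis of size 1.  When ``floor`` is given the
    normalizer 1 − κ is clamped from below (differentiable use); when it
    is None a total conflict raises.

    Returns ``(singletons, ignorance, kappa)``.
    """
    prod = a * b
    sing = prod + a * b_ig + a_ig * b
    ig = a_ig * b_ig
    kappa = (
        a.sum(axis=-1, keepdims=True) * b.sum(axis=-1, keepdims=True)
        - prod.sum(axis=-1, keepdims=True)
    )
    denom = 1.0 - kappa
    if floor is not None:
        if isinstance(denom, ad.Tensor):
            denom = ad.maximum(denom, floor)
        else:
            denom = np.maximum(denom, floor)
    else:
        bad = np.asarray(denom) < EPS_CONFLICT
        if bad.any():
            raise TotalConflictError(float(np.asarray(kappa).max()))
    return sing / denom, ig / denom, kappa


def combine_simple(m1: SimpleMass, m2: SimpleMass) -> SimpleMass:
    """Dempster's rule within the restricted (singletons + Ω) family.

    The family is closed under combination; the result agrees with
    :func:`combine_general` on the lifted inputs to ~1e-15.
    """
    _check_frames(m1, m2)
    sing, ig, _ = combine_masses_vec(
        m1.singletons[None, :], np.array([[m1.ignorance]]),
        m2.singletons[None, :], np.array([[m2.ignorance]]),
    )
    return SimpleMass(m1.frame, sing[0], float(ig[0, 0]))


def combine_many(masses: Sequence) -> SimpleMass | GeneralMass:
    """Left-fold of pairwise Dempster combination (order-insensitive up
    to float noise, by associativity)."""
    if not masses:
        raise ValueError("need at least one mass function")
    out = masses[0]
    for m in masses[1:]:
        if isinstance(out, SimpleMass) and isinstance(m, SimpleMass):
            out = combine_simple(out, m)
        else:
            g1 = out.to_general() if isinstance(out, SimpleMass) else out
            g2 = m.to_general() if isinstance(m, SimpleMass) else m
            out = combine_general(g1, g2)
    return out


def pignistic(m) -> np.ndarray:
    """Smets' pignistic transform: p(ω) = Σ_{A∋ω} m(A)/|A|."""
    if isinstance(m, SimpleMass):
        return m.singletons + m.ignorance / m.frame.n_classes
    p = np.zeros(m.frame.n_classes)
    for subset, mass in m.assignments.items():
        share = mass / len(subset)
        for i in subset:
            p[i] += share
    return p


# -- serialization ------------------------------------------------------

def mass_to_json(m) -> str:
    if isinstance(m, SimpleMass):
        payload = {
            "labels": list(m.frame.labels),
            "singletons": m.singletons.tolist(),
            "ignorance": m.ignorance,
        }
    else:
        payload = {
            "labels": list(m.frame.labels),
            "focal_sets": [[list(k), v] for k, v in sorted(m.assignments.items())],
        }
    return json.dumps(payload)


def mass_from_json(text: str):
    payload = json.loads(text)
    frame = Frame(payload["labels"])
    if "singletons" in payload:
        return SimpleMass(frame, payload["singletons"], payload["ignorance"])
    return GeneralMass(frame, {tuple(k): v for k, v in payload["focal_sets"]})
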