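"""Tiny neural-network building blocks on top of :mod:`evidfuse.autodiff`."""

from __future__ import annotations

import numpy as np

from .autodiff import Adam, Tensor, relu  # noqa: F401  (re-exported)

__all__ = ["Module", "Linear", "Dropout", "Tensor", "Adam", "relu"]


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            mods.extend(_collect_modules(value))
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # parameter snapshots, used for best-validation checkpointing
    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match the parameter list")
        for p, s in zip(params, state):
            p.data = s.copy()


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor):
        return [value] if value.requires_grad else []
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Tensor] = []
        for v in value:
            out.extend(_collect(v))
        return out
    if isinstance(value, dict):
        out = []
        for v in value.values():
            out.extend(_collect(v))
        return out
    return []


def _collect_modules(value) -> list[Module]:
    if isinstance(value, Module):
        return value.modules()
    if isinstance(value, (list, tuple)):
        out: list[Module] = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    if isinstance(value, dict):
        out = []
        for v in value.values():
            out.extend(_collect_modules(v))
        return out
    return []


class Linear(Module):
    """Affine map with He-scaled Gaussian initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.n_in = n_in
        self.n_out = n_out
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.n_in:
            raise ValueError(f"expected input width {self.n_in}, got {x.shape[-1]}")
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)
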