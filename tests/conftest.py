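import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evidfuse.belief import Frame, SimpleMass, binary_frame

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def frame() -> Frame:
    return binary_frame()


def random_simple_mass(rng: np.random.Generator, frame: Frame) -> SimpleMass:
    """Dirichlet-sampled restricted mass (singletons + ignorance)."""
    v = rng.dirichlet(np.ones(frame.n_classes + 1))
    return SimpleMass(frame, v[:-1], v[-1])


def finite_difference_grad(fn, params, eps: float = 1e-6):
    """Central finite differences of scalar ``fn()`` w.r.t. each Tensor in
    ``params`` (perturbing .data in place)."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        flat = p.data.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn()
            flat[i] = orig - eps
            lo = fn()
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads
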