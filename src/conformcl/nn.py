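"""Small neural-network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, softplus

LN2 = float(np.log(2.0))


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))
    out._backward = lambda g: x._accum(g * (x.data > 0))
    return out


def shifted_softplus(x: Tensor) -> Tensor:
    """ssp(x) = ln(0.5 e^x + 0.5); zero at x=0, the classic SchNet nonlinearity."""
    return softplus(x) - LN2


class Dense:
    """Affine layer y = x W + b with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP2:
    """Two-layer perceptron: Dense -> shifted-softplus -> Dense."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        self.lin1 = Dense(n_in, n_hidden, rng)
        self.lin2 = Dense(n_hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(shifted_softplus(self.lin1(x)))

    def parameters(self) -> list[Tensor]:
        return self.lin1.parameters() + self.lin2.parameters()


def n_parameters(params: list[Tensor]) -> int:
    return int(sum(p.data.size for p in params))
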