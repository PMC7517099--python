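"""First-order gradient optimizers: Adam and AdaDelta.

Both are written functionally — ``step`` functions map ``(state, params,
grad)`` to ``(new_state, new_params)`` without mutation — with small
stateful wrapper classes for convenience.  Adam keeps exponentially
decayed estimates of the gradient's first and second moments with bias
correction; AdaDelta rescales the gradient by the ratio of running RMS
update to running RMS gradient, so it needs no learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class AdamState:
    """Adam moment estimates and hyperparameters.

    ``m`` and ``v`` are the first- and second-moment running averages,
    ``t`` the step counter used for bias correction.
    """

    m: np.ndarray
    v: np.ndarray
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    lr: float = 1e-3
    eps: float = 1e-8

    @classmethod
    def init(cls, shape, lr: float = 1e-3, beta1: float = 0.9,
             beta2: float = 0.999, eps: float = 1e-8) -> "AdamState":
        return cls(m=np.zeros(shape), v=np.zeros(shape), t=0,
                   beta1=beta1, beta2=beta2, lr=lr, eps=eps)


def adam_step(state: AdamState, params, grad):
    """One Adam update; returns ``(new_state, new_params)``.

    m <- b1*m + (1-b1)*g;  v <- b2*v + (1-b2)*g^2;  bias-corrected
    m_hat = m/(1-b1^t), v_hat = v/(1-b2^t);
    params <- params - lr * m_hat / (sqrt(v_hat) + eps).
    """
    params = np.asarray(params, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if params.shape != grad.shape or params.shape != state.m.shape:
        raise ValueError("parameter/gradient/state shapes disagree")
    t = state.t + 1
    m = state.beta1 * state.m + (1.0 - state.beta1) * grad
    v = state.beta2 * state.v + (1.0 - state.beta2) * grad * grad
    m_hat = m / (1.0 - state.beta1 ** t)
    v_hat = v / (1.0 - state.beta2 ** t)
    new_params = params - state.lr * m_hat / (np.sqrt(v_hat) + state.eps)
    return replace(state, m=m, v=v, t=t), new_params


@dataclass(frozen=True)
class AdaDeltaState:
    """AdaDelta running averages E[g^2] and E[dx^2]."""

    Eg2: np.ndarray
    Edx2: np.ndarray
    rho: float = 0.95
    eps: float = 1e-6

    @classmethod
    def init(cls, shape, rho: float = 0.95, eps: float = 1e-6) -> "AdaDeltaState":
        return cls(Eg2=np.zeros(shape), Edx2=np.zeros(shape), rho=rho, eps=eps)


def adadelta_step(state: AdaDeltaState, params, grad):
    """One AdaDelta update; returns ``(new_state, new_params)``.

    E[g^2] <- r*E[g^2] + (1-r)*g^2;
    dx = -sqrt(E[dx^2]+eps)/sqrt(E[g^2]+eps) * g;
    E[dx^2] <- r*E[dx^2] + (1-r)*dx^2;  params <- params + dx.
    """
    params = np.asarray(params, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if params.shape != grad.shape or params.shape != state.Eg2.shape:
        raise ValueError("parameter/gradient/state shapes disagree")
    Eg2 = state.rho * state.Eg2 + (1.0 - state.rho) * grad * grad
    dx = -np.sqrt(state.Edx2 + state.eps) / np.sqrt(Eg2 + state.eps) * grad
    Edx2 = state.rho * state.Edx2 + (1.0 - state.rho) * dx * dx
    return replace(state, Eg2=Eg2, Edx2=Edx2), params + dx


class Adam:
    """Stateful Adam wrapper: ``params = opt.step(params, grad)``."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.state = None

    def step(self, params, grad):
        if self.state is None or self.state.m.shape != np.shape(params):
            self.state = AdamState.init(
                np.shape(params), lr=self.lr, beta1=self.beta1,
                beta2=self.beta2, eps=self.eps,
            )
        self.state, new_params = adam_step(self.state, params, grad)
        return new_params

    def clone_state(self):
        return self.state

    def restore_state(self, state) -> None:
        self.state = state

    def halve_lr(self) -> None:
        self.lr /= 2.0
        if self.state is not None:
            self.state = replace(self.state, lr=self.state.lr / 2.0)


class AdaDelta:
    """Stateful AdaDelta wrapper: ``params = opt.step(params, grad)``."""

    def __init__(self, rho: float = 0.95, eps: float = 1e-6):
        self.rho = rho
        self.eps = eps
        self.state = None

    def step(self, params, grad):
        if self.state is None or self.state.Eg2.shape != np.shape(params):
            self.state = AdaDeltaState.init(
                np.shape(params), rho=self.rho, eps=self.eps
            )
        self.state, new_params = adadelta_step(self.state, params, grad)
        return new_params

    def clone_state(self):
        return self.state

    def restore_state(self, state) -> None:
        self.state = state

    def halve_lr(self) -> None:
        # AdaDelta has no learning rate; damp instead by shrinking the
        # accumulated update average, which shrinks the next steps.
        if self.state is not None:
            self.state = replace(self.state, Edx2=self.state.Edx2 / 4.0)


def make_optimizer(kind: str, lr: float = 1e-3, beta1: float = 0.9,
                   beta2: float = 0.999, rho: float = 0.95,
                   eps: float | None = None):
    """Factory for the named optimizer with per-kind default ``eps``."""
    if kind == "adam":
        return Adam(lr=lr, beta1=beta1, beta2=beta2,
                    eps=1e-8 if eps is None else eps)
    if kind == "adadelta":
        return AdaDelta(rho=rho, eps=1e-6 if eps is None else eps)
    raise ValueError(f"unknown optimizer kind {kind!r}")
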