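"""Maximum-entropy Markov model for activity-window sequences.

The model replaces an HMM's separate emission and transition tables with
one locally normalized exponential-family distribution over the next
state given the previous state and the current observation::

    P(s | s', o) = exp( sum_r w_{s,r} f_r(o, s') ) / Z(o, s')

Feature functions f_r(o, s') are, per previous state s' (including a
dedicated start state): an indicator per codebook symbol (symbol mode)
or the raw standardized feature values (dense mode), plus a bias.  The
weights therefore live in an array of shape ``(S, S + 1, d_obs + 1)``:
target state x previous state (last row = start) x observation slot
(last column = bias).

Training maximizes the conditional log-likelihood of the training
transitions minus an L2 penalty; the gradient per weight slot is
(empirical feature expectation) - (model feature expectation) - 2*l2*w,
so at an unregularized optimum the maxent constraint — empirical equals
expected feature counts — holds.  Optimization is full-batch Adam or
AdaDelta.  All probabilities are handled in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import EmptyInputError
from .optim import make_optimizer

#: Sentinel label for the designated start state s0.
START = "<start>"


@dataclass
class MEMMModel:
    """A trained maximum-entropy Markov model.

    ``weights[s, j, r]`` is the weight of feature slot r (observation
    slots then bias) for target state s given previous-state block j;
    block ``len(states)`` belongs to the start state.
    """

    states: list[str]
    observation_mode: str  # "symbol" | "dense"
    obs_dim: int  # number of symbols, or dense feature dimension
    weights: np.ndarray = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("a MEMM needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError("states must be pairwise distinct")
        if self.observation_mode not in ("symbol", "dense"):
            raise ValueError("observation_mode must be 'symbol' or 'dense'")
        shape = (len(self.states), len(self.states) + 1, self.obs_dim + 1)
        if self.weights is None:
            self.weights = np.zeros(shape)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != shape:
            raise ValueError(f"weights must have shape {shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label) -> int:
        if label == START:
            return self.n_states
        try:
            return self.states.index(label)
        except ValueError:
            raise ValueError(f"unknown state {label!r}") from None


def _phi(model: MEMMModel, obs) -> np.ndarray:
    """Observation feature vector with trailing bias slot."""
    out = np.zeros(model.obs_dim + 1)
    out[-1] = 1.0
    if model.observation_mode == "symbol":
        k = int(obs)
        if not 0 <= k < model.obs_dim:
            raise ValueError(f"symbol {k} outside [0, {model.obs_dim})")
        out[k] = 1.0
    else:
        dense = np.asarray(obs, dtype=float)
        if dense.shape != (model.obs_dim,):
            raise ValueError(
                f"dense observation must have shape ({model.obs_dim},)"
            )
        out[:-1] = dense
    return out


def _log_transition_matrix(model: MEMMModel, obs) -> np.ndarray:
    """log P(s | s', obs) as an (S_target, S_prev + 1) matrix."""
    phi = _phi(model, obs)
    scores = model.weights @ phi  # (S, S+1)
    mx = scores.max(axis=0, keepdims=True)
    log_z = mx + np.log(np.exp(scores - mx).sum(axis=0, keepdims=True))
    return scores - log_z


def transition_distribution(model: MEMMModel, prev_state, obs) -> np.ndarray:
    """P(s | s', o) over target states; sums to 1.

    ``prev_state`` is a state label or :data:`START`.  With all weights
    zero the distribution is uniform.
    """
    j = model.state_index(prev_state)
    return np.exp(_log_transition_matrix(model, obs)[:, j])


def forward(model: MEMMModel, obs_seq) -> np.ndarray:
    """Forward recursion: alpha[t, s] marginal state probabilities.

    alpha_1(s) = P(s | s0, o_1) and
    alpha_{t+1}(s) = sum_{s'} alpha_t(s') P(s | s', o_{t+1}); because the
    transitions are locally normalized each row sums to 1.
    """
    obs_seq = list(obs_seq)
    if len(obs_seq) == 0:
        raise EmptyInputError("forward: empty observation sequence")
    S = model.n_states
    alpha = np.empty((len(obs_seq), S))
    logm = _log_transition_matrix(model, obs_seq[0])
    alpha[0] = np.exp(logm[:, S])
    for t in range(1, len(obs_seq)):
        m = np.exp(_log_transition_matrix(model, obs_seq[t])[:, :S])
        alpha[t] = m @ alpha[t - 1]
    return alpha


def viterbi(model: MEMMModel, obs_seq):
    """Most probable state sequence and its log-score.

    Ties are broken toward the lower state index at every backtrack step.
    """
    obs_seq = list(obs_seq)
    if len(obs_seq) == 0:
        raise EmptyInputError("viterbi: empty observation sequence")
    T, S = len(obs_seq), model.n_states
    delta = _log_transition_matrix(model, obs_seq[0])[:, S]
    psi = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        logm = _log_transition_matrix(model, obs_seq[t])[:, :S]  # (S_t, S_prev)
        cand = logm + delta[None, :]
        delta = cand.max(axis=1)
        psi[t] = cand.argmax(axis=1)  # first max -> lowest index
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    labels = [model.states[i] for i in path]
    return labels, float(delta[path[-1]])


def sequence_log_likelihood(model: MEMMModel, obs_seq, state_seq) -> float:
    """sum_t log P(s_t | s_{t-1}, o_t); always <= 0."""
    obs_seq = list(obs_seq)
    state_seq = list(state_seq)
    if len(obs_seq) != len(state_seq):
        raise ValueError("observation and state sequences differ in length")
    if len(obs_seq) == 0:
        raise EmptyInputError("empty sequence")
    total = 0.0
    prev = model.n_states
    for obs, label in zip(obs_seq, state_seq):
        s = model.state_index(label)
        total += _log_transition_matrix(model, obs)[s, prev]
        prev = s
    return total


def classify_windows(model: MEMMModel, obs_seq) -> list[str]:
    """Per-window activity labels via Viterbi decoding."""
    return viterbi(model, obs_seq)[0]


# ---------------------------------------------------------------------------
# training


@dataclass
class MEMMTrainConfig:
    """Trainer settings.

    ``lr`` defaults to 5e-5, the rate the classifier is trained with in
    this pipeline; ``max_epochs`` is sized so full-batch training at that
    rate reaches a plateau.  ``l2`` is the coefficient of the squared-
    weight penalty (maxent training without a prior is degenerate on
    separable data).
    """

    observation_mode: str | None = None  # None -> infer from data
    n_symbols: int | None = None
    optimizer: str = "adam"
    lr: float = 5e-5
    beta1: float = 0.9
    beta2: float = 0.999
    rho: float = 0.95
    eps: float | None = None
    l2: float = 1e-3
    max_epochs: int = 2000
    tol: float = 1e-6
    lr_backoff: bool = False


def _infer_mode(dataset) -> str:
    obs0 = dataset[0][0][0]
    return "dense" if np.ndim(obs0) >= 1 else "symbol"


def _build_transitions(dataset, states, observation_mode, obs_dim):
    """Flatten sequences into (prev_idx, target_idx, X-with-bias)."""
    index = {s: i for i, s in enumerate(states)}
    S = len(states)
    prev_list, target_list, obs_list = [], [], []
    for obs_seq, state_seq in dataset:
        obs_seq = list(obs_seq)
        state_seq = list(state_seq)
        if len(obs_seq) != len(state_seq):
            raise ValueError("observation and state sequences differ in length")
        prev = S
        for obs, label in zip(obs_seq, state_seq):
            t = index[label]
            prev_list.append(prev)
            target_list.append(t)
            obs_list.append(obs)
            prev = t
    n = len(target_list)
    X = np.zeros((n, obs_dim + 1))
    X[:, -1] = 1.0
    if observation_mode == "symbol":
        symbols = np.asarray(obs_list, dtype=int)
        if symbols.min() < 0 or symbols.max() >= obs_dim:
            raise ValueError("symbol observation outside [0, n_symbols)")
        X[np.arange(n), symbols] = 1.0
    else:
        X[:, :-1] = np.asarray(obs_list, dtype=float)
    return np.asarray(prev_list), np.asarray(target_list), X


def _objective_and_grad(W, groups, X, target_idx, l2):
    """Mean conditional log-likelihood minus L2, and its gradient."""
    G = np.zeros_like(W)
    ll = 0.0
    n_total = target_idx.size
    for j, rows in enumerate(groups):
        if rows.size == 0:
            continue
        Xj = X[rows]
        scores = Xj @ W[:, j, :].T  # (n_j, S)
        mx = scores.max(axis=1, keepdims=True)
        lse = (mx + np.log(np.exp(scores - mx).sum(axis=1, keepdims=True)))[:, 0]
        tj = target_idx[rows]
        ll += float((scores[np.arange(rows.size), tj] - lse).sum())
        resid = -np.exp(scores - lse[:, None])
        resid[np.arange(rows.size), tj] += 1.0
        G[:, j, :] = resid.T @ Xj
    objective = ll / n_total - l2 * float((W ** 2).sum())
    grad = G / n_total - 2.0 * l2 * W
    return objective, grad


def empirical_feature_expectations(dataset, states, observation_mode, obs_dim):
    """Average of f_r(o_t, s'_t) over training transitions, per weight slot.

    Slot ``[s, j, r]`` accumulates feature r of transitions entering
    target state s from previous-state block j, divided by the total
    transition count.
    """
    if len(dataset) == 0:
        raise EmptyInputError("empty dataset")
    prev_idx, target_idx, X = _build_transitions(
        dataset, list(states), observation_mode, obs_dim
    )
    S = len(states)
    out = np.zeros((S, S + 1, obs_dim + 1))
    np.add.at(out, (target_idx, prev_idx), X)
    return out / target_idx.size


def model_feature_expectations(model: MEMMModel, dataset):
    """Expected feature counts under the model, averaged over the same
    transitions (the right side of the maxent constraint)."""
    if len(dataset) == 0:
        raise EmptyInputError("empty dataset")
    prev_idx, target_idx, X = _build_transitions(
        dataset, model.states, model.observation_mode, model.obs_dim
    )
    S = model.n_states
    out = np.zeros_like(model.weights)
    for j in range(S + 1):
        rows = np.flatnonzero(prev_idx == j)
        if rows.size == 0:
            continue
        Xj = X[rows]
        scores = Xj @ model.weights[:, j, :].T
        mx = scores.max(axis=1, keepdims=True)
        lse = mx + np.log(np.exp(scores - mx).sum(axis=1, keepdims=True))
        P = np.exp(scores - lse)
        out[:, j, :] = P.T @ Xj
    return out / target_idx.size


def train_memm(dataset, config: MEMMTrainConfig | None = None,
               states=None) -> MEMMModel:
    """Fit MEMM weights by penalized maximum conditional likelihood.

    ``dataset`` is a sequence of ``(obs_seq, state_seq)`` pairs.  The
    optimizer (Adam or AdaDelta per the config) runs full-batch for
    ``max_epochs`` epochs or until the gradient sup-norm drops below
    ``tol``.  Deterministic for fixed data and config.  With
    ``lr_backoff`` the step is retried at half the learning rate whenever
    the penalized objective decreases.
    """
    config = config or MEMMTrainConfig()
    if len(dataset) == 0:
        raise EmptyInputError("empty training dataset")
    mode = config.observation_mode or _infer_mode(dataset)
    if states is None:
        states = sorted({str(s) for _, seq in dataset for s in seq})
    states = [str(s) for s in states]
    if len(states) < 2:
        raise ValueError("training data must contain at least 2 distinct states")
    if mode == "symbol":
        obs_dim = config.n_symbols
        if obs_dim is None:
            obs_dim = int(max(int(o) for obs_seq, _ in dataset for o in obs_seq)) + 1
    else:
        obs_dim = int(np.asarray(dataset[0][0][0]).size)
    prev_idx, target_idx, X = _build_transitions(dataset, states, mode, obs_dim)
    S = len(states)
    groups = [np.flatnonzero(prev_idx == j) for j in range(S + 1)]

    model = MEMMModel(states=states, observation_mode=mode, obs_dim=obs_dim)
    W = model.weights
    opt = make_optimizer(config.optimizer, lr=config.lr, beta1=config.beta1,
                         beta2=config.beta2, rho=config.rho, eps=config.eps)
    prev_obj = -np.inf
    halvings = 0
    checkpoint = None
    for _ in range(config.max_epochs):
        objective, grad = _objective_and_grad(W, groups, X, target_idx, config.l2)
        if config.lr_backoff and objective < prev_obj - 1e-12:
            if checkpoint is None or halvings >= 40:
                break
            W, opt_state = checkpoint
            opt.restore_state(opt_state)
            opt.halve_lr()
            halvings += 1
            continue
        prev_obj = objective
        if np.abs(grad).max() < config.tol:
            break
        if config.lr_backoff:
            checkpoint = (W.copy(), opt.clone_state())
        W = opt.step(W, -grad)  # ascent on the objective
    model.weights = W
    return model


def save_model(model: MEMMModel, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(
            {
                "states": model.states,
                "observation_mode": model.observation_mode,
                "obs_dim": model.obs_dim,
                "weights": model.weights.tolist(),
            },
            fh,
        )
    return path


def load_model(path) -> MEMMModel:
    with open(path) as fh:
        doc = json.load(fh)
    return MEMMModel(
        states=list(doc["states"]),
        observation_mode=doc["observation_mode"],
        obs_dim=int(doc["obs_dim"]),
        weights=np.asarray(doc["weights"], dtype=float),
    )


class MEMMClassifier(BaseEstimator, ClassifierMixin):
    """Sequence classifier wrapping the MEMM trainer and Viterbi decoder.

    ``fit`` takes a list of observation sequences (1-D integer symbol
    arrays in symbol mode, 2-D float arrays in dense mode) and a matching
    list of per-window label sequences; ``predict`` returns a list of
    decoded label arrays.

    Parameters mirror :class:`MEMMTrainConfig`; ``n_symbols=None`` infers
    the symbol-space size from the training data.

    Attributes
    ----------
    classes_ : ndarray of state labels (sorted)
    model_ : MEMMModel
    """

    def __init__(self, observation_mode: str = "symbol", n_symbols=None,
                 optimizer: str = "adam", lr: float = 5e-5,
                 beta1: float = 0.9, beta2: float = 0.999, rho: float = 0.95,
                 eps=None, l2: float = 1e-3, max_epochs: int = 2000,
                 tol: float = 1e-6, lr_backoff: bool = False):
        self.observation_mode = observation_mode
        self.n_symbols = n_symbols
        self.optimizer = optimizer
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.rho = rho
        self.eps = eps
        self.l2 = l2
        self.max_epochs = max_epochs
        self.tol = tol
        self.lr_backoff = lr_backoff

    def _train_config(self) -> MEMMTrainConfig:
        return MEMMTrainConfig(
            observation_mode=self.observation_mode, n_symbols=self.n_symbols,
            optimizer=self.optimizer, lr=self.lr, beta1=self.beta1,
            beta2=self.beta2, rho=self.rho, eps=self.eps, l2=self.l2,
            max_epochs=self.max_epochs, tol=self.tol,
            lr_backoff=self.lr_backoff,
        )

    def fit(self, X, y):
        if len(X) != len(y):
            raise ValueError("X and y must hold the same number of sequences")
        dataset = list(zip(X, [np.atleast_1d(np.asarray(labels, dtype=str))
                               for labels in y]))
        self.model_ = train_memm(dataset, self._train_config())
        self.classes_ = np.asarray(self.model_.states)
        return self

    def predict(self, X) -> list[np.ndarray]:
        if not hasattr(self, "model_"):
            raise RuntimeError("MEMMClassifier is not fitted")
        return [np.asarray(classify_windows(self.model_, seq)) for seq in X]

    def score(self, X, y) -> float:
        """Window-level accuracy over all sequences."""
        preds = self.predict(X)
        correct = total = 0
        for pred, truth in zip(preds, y):
            truth = np.atleast_1d(np.asarray(truth, dtype=str))
            correct += int((pred == truth).sum())
            total += truth.size
        return correct / total
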