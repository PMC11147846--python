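"""Feed-forward reference predictor mapping SC edges to FC edges.

This reconstructs the deep-learning predictor used as a comparison point
for the null models: a fully connected network trained with a
correlation-based loss that trades off prediction accuracy against
preservation of inter-individual variation,

    L = (1 - gamma) * (1 - mean_i corr(pred_i, target_i))
        + gamma * mean_{i != j} corr(pred_i, pred_j)
        + lambda * mean(W^2),

where the first term rewards within-subject accuracy, the second penalizes
predictions collapsing onto a common (group-average-like) pattern, and the
third is weight regularization. The exact published loss is not restated in
the sources this package follows; this surrogate matches its stated intent
and two-parameter form, and is pluggable (see ``train``'s ``loss_grad``
hook) so an alternative can be swapped in without touching the training
loop.

The network is implemented directly in numpy (manual backpropagation,
Adam optimizer, He initialization, ReLU activations); the output bias is
initialized to the training-mean edge vector, which is the loss minimizer
of the accuracy term among constant predictors and the natural starting
point. Defaults follow the published architecture (10 layers of width
1024, gamma 0.4, lambda 0.01, 20000 epochs); ``MLPConfig.desk_scale`` gives
a configuration sized for interactive use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core import Cohort, FoldAssignment
from .baselines import PredictorOutput

_EPS = 1e-12


@dataclass(frozen=True)
class MLPConfig:
    n_layers: int = 10
    width: int = 1024
    gamma: float = 0.4
    lambda_reg: float = 0.01
    epochs: int = 20000
    batch_size: int | None = None  # None -> full batch
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers (one hidden)")

    @classmethod
    def desk_scale(cls, **overrides) -> "MLPConfig":
        """Sized for a laptop CPU: width 256, 2000 epochs."""
        base = cls(width=256, epochs=2000)
        return replace(base, **overrides)


def _standardize_rows(X: np.ndarray):
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1, keepdims=True))
    norms = np.maximum(norms, _EPS)
    return Xc, norms, Xc / norms


def loss(predicted_batch: np.ndarray, target_batch: np.ndarray, cfg: MLPConfig,
         weights=None) -> float:
    """Evaluate the training loss on a batch (rows = subjects)."""
    P = np.asarray(predicted_batch, float)
    Y = np.asarray(target_batch, float)
    if P.shape != Y.shape:
        raise ValueError("prediction and target batches must have equal shape")
    n = P.shape[0]
    if n < 2 and cfg.gamma > 0:
        raise ValueError("between-subject loss term undefined for a batch of 1")
    _, _, Phat = _standardize_rows(P)
    _, _, Yhat = _standardize_rows(Y)
    within = float((Phat * Yhat).sum(axis=1).mean())
    value = (1.0 - cfg.gamma) * (1.0 - within)
    if cfg.gamma > 0:
        C = Phat @ Phat.T
        value += cfg.gamma * float((C.sum() - np.trace(C)) / (n * (n - 1)))
    if weights is not None and cfg.lambda_reg > 0:
        total = sum(W.size for W in weights)
        value += cfg.lambda_reg * sum(float((W**2).sum()) for W in weights) / total
    return value


def _loss_grad_wrt_predictions(P, Y, cfg: MLPConfig):
    """Analytic gradient of the correlation loss with respect to the
    predicted batch. The centering projection is implicit: both gradient
    pieces are already mean-zero per row."""
    n = P.shape[0]
    _, Pn, Phat = _standardize_rows(P)
    _, _, Yhat = _standardize_rows(Y)
    r = (Phat * Yhat).sum(axis=1, keepdims=True)
    grad = -(1.0 - cfg.gamma) / n * (Yhat - r * Phat) / Pn
    if cfg.gamma > 0 and n > 1:
        C = Phat @ Phat.T
        S = Phat.sum(axis=0, keepdims=True)
        rowsum = C.sum(axis=1, keepdims=True)
        gB = ((S - Phat) - (rowsum - 1.0) * Phat) / Pn
        grad = grad + cfg.gamma * 2.0 / (n * (n - 1)) * gB
    return grad


@dataclass
class FoldModel:
    """Trained network for one fold: weights/biases, the config used, the
    ids of the subjects it was trained on, and its loss history."""

    weights: list
    biases: list
    cfg: MLPConfig
    fold: int
    training_ids: frozenset
    loss_history: np.ndarray

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, float)
        last = len(self.weights) - 1
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ W + b
            if l < last:
                np.maximum(a, 0.0, out=a)
        return a


def _init_net(rng, sizes, target_mean):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    biases[-1] = target_mean.copy()
    return weights, biases


def _train_single(X, Y, cfg: MLPConfig, rng, loss_grad):
    sizes = [X.shape[1]] + [cfg.width] * (cfg.n_layers - 1) + [Y.shape[1]]
    weights, biases = _init_net(rng, sizes, Y.mean(axis=0))
    total_w = sum(W.size for W in weights)
    mw = [np.zeros_like(W) for W in weights]
    vw = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = np.empty(cfg.epochs)
    n = X.shape[0]
    batch = cfg.batch_size or n
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            if idx.size < 2 and cfg.gamma > 0:
                continue
            # forward, keeping activations
            acts = [X[idx]]
            last = len(weights) - 1
            for l, (W, b) in enumerate(zip(weights, biases)):
                z = acts[-1] @ W + b
                acts.append(np.maximum(z, 0.0) if l < last else z)
            P = acts[-1]
            delta = loss_grad(P, Y[idx], cfg)
            for l in range(last, -1, -1):
                gW = acts[l].T @ delta + 2.0 * cfg.lambda_reg * weights[l] / total_w
                gb = delta.sum(axis=0)
                if l > 0:
                    delta = (delta @ weights[l].T) * (acts[l] > 0)
                t += 1
                for g, W_, m_, v_ in ((gW, weights[l], mw, vw), (gb, biases[l], mb, vb)):
                    m_[l] = b1 * m_[l] + (1 - b1) * g
                    v_[l] = b2 * v_[l] + (1 - b2) * g**2
                    mhat = m_[l] / (1 - b1**t)
                    vhat = v_[l] / (1 - b2**t)
                    W_ -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history[epoch] = loss(_forward(weights, biases, X), Y, cfg, weights)
    return weights, biases, history


def _forward(weights, biases, X):
    a = X
    last = len(weights) - 1
    for l, (W, b) in enumerate(zip(weights, biases)):
        a = a @ W + b
        if l < last:
            a = np.maximum(a, 0.0)
    return a


def train(
    cohort: Cohort,
    folds: FoldAssignment,
    cfg: MLPConfig,
    sc_edges: np.ndarray | None = None,
    loss_grad=None,
) -> list:
    """Train one network per fold on that fold's training subjects only.

    ``sc_edges`` is the (n, E) input feature matrix (rank-Gaussian
    resampled SC edges); if omitted it is derived from the cohort's SC
    matrices. ``loss_grad`` may replace the default correlation-loss
    gradient (same signature) to swap in an alternative loss.
    """
    if sc_edges is None:
        sc_edges = resampled_sc_edges(cohort, seed=cfg.seed)
    Y = cohort.efc_edges()
    X = np.asarray(sc_edges, float)
    if X.shape[0] != len(cohort):
        raise ValueError("SC feature rows must match cohort size")
    loss_grad = loss_grad or _loss_grad_wrt_predictions
    ids = cohort.subject_ids
    models = []
    for f, train_idx, _ in folds.folds():
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, f)))
        weights, biases, history = _train_single(X[train_idx], Y[train_idx], cfg, rng, loss_grad)
        models.append(
            FoldModel(
                weights=weights,
                biases=biases,
                cfg=cfg,
                fold=f,
                training_ids=frozenset(ids[i] for i in train_idx),
                loss_history=history,
            )
        )
    return models


def predict(model: FoldModel, sc_vectors: np.ndarray, subject_ids=None) -> np.ndarray:
    """Predicted FC edge vectors for held-out subjects.

    Passing ``subject_ids`` arms the leakage guard: predicting a subject
    the model was trained on raises instead of silently leaking.
    """
    X = np.atleast_2d(np.asarray(sc_vectors, float))
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model input "
            f"size {model.weights[0].shape[0]}"
        )
    if subject_ids is not None:
        leaked = set(subject_ids) & model.training_ids
        if leaked:
            raise ValueError(
                f"leakage: subjects {sorted(leaked)} were in this model's training set"
            )
    return model.forward(X)


def predict_all(
    models: list, cohort: Cohort, folds: FoldAssignment, sc_edges: np.ndarray | None = None
) -> PredictorOutput:
    """Assemble the cross-validated pFC: each subject predicted by the one
    model whose training folds excluded them."""
    if sc_edges is None:
        sc_edges = resampled_sc_edges(cohort, seed=models[0].cfg.seed)
    X = np.asarray(sc_edges, float)
    ids = cohort.subject_ids
    preds = np.empty((len(cohort), X.shape[1]))
    by_fold = {m.fold: m for m in models}
    for f, _, val in folds.folds():
        preds[val] = predict(by_fold[f], X[val], subject_ids=[ids[i] for i in val])
    return PredictorOutput("pFC", folds, preds, ids)


def resampled_sc_edges(cohort: Cohort, seed: int = 0) -> np.ndarray:
    """Rank-Gaussian-resampled SC edge vectors for every subject."""
    from .core import SC_RESAMPLED
    from .sc_transform import ResampleConfig, gaussian_resample

    rows = []
    for i, s in enumerate(cohort):
        if s.sc is None:
            raise ValueError(f"subject {s.subject_id} has no SC matrix")
        if s.sc.kind == SC_RESAMPLED:
            rows.append(s.sc.edges())
        else:
            rows.append(
                gaussian_resample(s.sc, ResampleConfig(seed=seed + i)).edges()
            )
    return np.vstack(rows)
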