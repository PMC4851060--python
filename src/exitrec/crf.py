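"""Linear-chain CRF with dynamically weighted training and exact online
(filtered) marginal inference.

The chain has per-position unary potentials ``W @ x_t + b`` and a
homogeneous K x K transition matrix. Training maximizes a per-position
weighted conditional log-likelihood

    L(theta, w) = sum_t w[y_t] * log p(y_t | x_{1..t}, theta) - vartheta*||theta||^2

where ``p(y_t | x_{1..t})`` is the same filtered marginal the online
recursion produces at prediction time, so the training objective and the
deployed inference coincide. Class weights ``w`` are re-estimated between
optimization rounds from per-class F-scores to counter class imbalance;
a proposed weight vector is kept only if macro F-score does not drop.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

K_CLASSES = 4

Seq = tuple[np.ndarray, np.ndarray]  # (X: T x D float, y: T ints in 0..K-1)


class CRFSchemaError(ValueError):
    """Sequence feature dimension disagrees with the model's schema."""


class OptimizationError(RuntimeError):
    """The training objective became non-finite."""


# --- numba kernels --------------------------------------------------------

@njit(cache=True)
def _forward_kernel(u, tr):
    """Filtered log-marginals for unary scores ``u`` (T x K) and transition
    scores ``tr`` (K x K). Returns (logm, s) where s[t] holds the
    message log-sums feeding position t (t >= 1)."""
    T, K = u.shape
    logm = np.empty((T, K))
    s = np.zeros((T, K))
    # base case: softmax of the unary scores
    mx = u[0].max()
    z = 0.0
    for k in range(K):
        z += np.exp(u[0, k] - mx)
    lz = mx + np.log(z)
    for k in range(K):
        logm[0, k] = u[0, k] - lz
    for t in range(1, T):
        for k in range(K):
            mmax = -np.inf
            for j in range(K):
                v = tr[j, k] + logm[t - 1, j]
                if v > mmax:
                    mmax = v
            acc = 0.0
            for j in range(K):
                acc += np.exp(tr[j, k] + logm[t - 1, j] - mmax)
            s[t, k] = mmax + np.log(acc)
        mx = -np.inf
        for k in range(K):
            a = u[t, k] + s[t, k]
            if a > mx:
                mx = a
        z = 0.0
        for k in range(K):
            z += np.exp(u[t, k] + s[t, k] - mx)
        lz = mx + np.log(z)
        for k in range(K):
            logm[t, k] = u[t, k] + s[t, k] - lz
    return logm, s


@njit(cache=True)
def _backward_kernel(tr, logm, s, y, w):
    """Reverse-mode pass for L = sum_t w[y_t] * logm[t, y_t].

    Returns (G, dtr) with G[t] = dL/d(unary scores at t) and
    dtr = dL/d(transition scores)."""
    T, K = logm.shape
    G = np.empty((T, K))
    dtr = np.zeros((K, K))
    ga_next = np.zeros(K)
    dl = np.zeros(K)
    for t in range(T - 1, -1, -1):
        for k in range(K):
            dl[k] = 0.0
        dl[y[t]] = w[y[t]]
        if t < T - 1:
            # backflow through s[t+1, k] = lse_j(tr[j,k] + logm[t, j])
            for j in range(K):
                acc = 0.0
                for k in range(K):
                    acc += ga_next[k] * np.exp(tr[j, k] + logm[t, j] - s[t + 1, k])
                dl[j] += acc
        tot = 0.0
        for k in range(K):
            tot += dl[k]
        for k in range(K):
            G[t, k] = dl[k] - np.exp(logm[t, k]) * tot
        if t >= 1:
            for k in range(K):
                for j in range(K):
                    dtr[j, k] += G[t, k] * np.exp(tr[j, k] + logm[t - 1, j] - s[t, k])
        for k in range(K):
            ga_next[k] = G[t, k]
    return G, dtr


# --- model ----------------------------------------------------------------

@dataclass
class CRFModel:
    """Fitted chain model: unary weights/bias, transition weights, the
    class weights the final round used, and the training hyperparameters
    tau (weight-update rounds) and vartheta (L2 coefficient)."""

    unary_weights: np.ndarray          # K x D
    bias: np.ndarray                   # K
    transition_weights: np.ndarray     # K x K
    class_weights: np.ndarray          # K, strictly positive
    tau: int
    vartheta: float
    feature_schema: list[str]
    seed: int = 0

    FORMAT_VERSION = 1

    def __post_init__(self) -> None:
        if np.any(self.class_weights <= 0):
            raise ValueError("class weights must be strictly positive")
        for arr in (self.unary_weights, self.bias, self.transition_weights):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.unary_weights.shape[1]

    def unary_scores(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise CRFSchemaError(
                f"feature matrix has {x.shape[1] if x.ndim == 2 else '?'} columns, "
                f"model expects {self.n_features}"
            )
        return x @ self.unary_weights.T + self.bias

    def to_dict(self) -> dict:
        return {
            "format_version": self.FORMAT_VERSION,
            "unary_weights": self.unary_weights.tolist(),
            "bias": self.bias.tolist(),
            "transition_weights": self.transition_weights.tolist(),
            "class_weights": self.class_weights.tolist(),
            "tau": self.tau,
            "vartheta": self.vartheta,
            "feature_schema": list(self.feature_schema),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CRFModel":
        if d.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {d.get('format_version')}")
        return cls(
            unary_weights=np.asarray(d["unary_weights"], dtype=float),
            bias=np.asarray(d["bias"], dtype=float),
            transition_weights=np.asarray(d["transition_weights"], dtype=float),
            class_weights=np.asarray(d["class_weights"], dtype=float),
            tau=int(d["tau"]),
            vartheta=float(d["vartheta"]),
            feature_schema=list(d["feature_schema"]),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "CRFModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --- inference ------------------------------------------------------------

def forward_marginals(model: CRFModel, x: np.ndarray) -> np.ndarray:
    """Filtered marginals p(y_t | x_{1..t}) for every position, (T x K)."""
    u = model.unary_scores(x)
    if len(u) == 0:
        return np.zeros((0, K_CLASSES))
    logm, _ = _forward_kernel(u, model.transition_weights)
    return np.exp(logm)


def online_marginals(model: CRFModel, x_upto_t: np.ndarray) -> np.ndarray:
    """Filtered marginal distribution at the latest position."""
    if len(x_upto_t) == 0:
        raise ValueError("need at least one observation")
    return forward_marginals(model, x_upto_t)[-1]


class MarginalTracker:
    """O(K^2)-per-observation streaming version of the forward recursion."""

    def __init__(self, model: CRFModel):
        self.model = model
        self._logm: np.ndarray | None = None

    def step(self, x_t: np.ndarray) -> np.ndarray:
        """Consume one feature vector, return the filtered marginals."""
        u = self.model.unary_scores(x_t[None, :])[0]
        tr = self.model.transition_weights
        if self._logm is None:
            a = u
        else:
            prev = self._logm
            msg = tr + prev[:, None]                      # msg[j, k]
            mmax = msg.max(axis=0)
            a = u + mmax + np.log(np.exp(msg - mmax).sum(axis=0))
        self._logm = a - _lse(a)
        return np.exp(self._logm)


def _lse(a: np.ndarray) -> float:
    m = a.max()
    return m + np.log(np.exp(a - m).sum())


# --- training -------------------------------------------------------------

def _pack(wu: np.ndarray, b: np.ndarray, tr: np.ndarray) -> np.ndarray:
    return np.concatenate([wu.ravel(), b.ravel(), tr.ravel()])


def _unpack(theta: np.ndarray, k: int, d: int):
    wu = theta[: k * d].reshape(k, d)
    b = theta[k * d : k * d + k]
    tr = theta[k * d + k :].reshape(k, k)
    return wu, b, tr


def _check_seqs(seqs: Sequence[Seq], d: int) -> None:
    for x, y in seqs:
        if x.shape[1] != d:
            raise CRFSchemaError(
                f"sequence has {x.shape[1]} feature columns, expected {d}"
            )
        if len(x) != len(y) or len(x) == 0:
            raise ValueError("features and labels must align and be nonempty")
        if y.min() < 0 or y.max() >= K_CLASSES:
            raise ValueError("labels must be encoded in 0..K-1")


def _objective(theta, seqs, w, vartheta, k, d):
    """(-L, -grad) of the weighted filtered log-likelihood."""
    wu, b, tr = _unpack(theta, k, d)
    value = 0.0
    dwu = np.zeros_like(wu)
    db = np.zeros_like(b)
    dtr = np.zeros_like(tr)
    for x, y in seqs:
        u = x @ wu.T + b
        logm, s = _forward_kernel(u, tr)
        value += float((w[y] * logm[np.arange(len(y)), y]).sum())
        g, dtr_seq = _backward_kernel(tr, logm, s, y, w)
        dwu += g.T @ x
        db += g.sum(axis=0)
        dtr += dtr_seq
    value -= vartheta * float(theta @ theta)
    grad = _pack(dwu, db, dtr) - 2.0 * vartheta * theta
    if not np.isfinite(value) or not np.all(np.isfinite(grad)):
        raise OptimizationError("non-finite training objective")
    return -value, -grad


def weighted_loglik_grad(
    model: CRFModel,
    seqs: Sequence[Seq] | Seq,
    w: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted log-likelihood L(theta, w) and its exact gradient.

    The gradient is flat, ordered (unary weights, bias, transitions),
    matching the optimizer's parameterization.
    """
    if isinstance(seqs, tuple) and isinstance(seqs[0], np.ndarray):
        seqs = [seqs]  # single sequence
    w = model.class_weights if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    _check_seqs(seqs, model.n_features)
    theta = _pack(model.unary_weights, model.bias, model.transition_weights)
    neg_v, neg_g = _objective(
        theta, seqs, w, model.vartheta, K_CLASSES, model.n_features
    )
    return -neg_v, -neg_g


def predict_positions(model: CRFModel, seqs: Sequence[Seq]) -> list[np.ndarray]:
    """Per-position argmax of the filtered marginals for each sequence."""
    return [forward_marginals(model, x).argmax(axis=1) for x, _ in seqs]


def per_class_f_scores(
    model: CRFModel, seqs: Sequence[Seq]
) -> tuple[np.ndarray, np.ndarray]:
    """(F-scores, present-mask) of per-position predictions, one per class.

    F for a class with no true and no predicted positions is NaN and the
    class is flagged absent.
    """
    preds = predict_positions(model, seqs)
    y_all = np.concatenate([y for _, y in seqs])
    p_all = np.concatenate(preds)
    f = np.full(K_CLASSES, np.nan)
    present = np.zeros(K_CLASSES, dtype=bool)
    for c in range(K_CLASSES):
        tp = int(np.sum((p_all == c) & (y_all == c)))
        fp = int(np.sum((p_all == c) & (y_all != c)))
        fn = int(np.sum((p_all != c) & (y_all == c)))
        present[c] = (tp + fn) > 0
        if 2 * tp + fp + fn > 0:
            f[c] = 2 * tp / (2 * tp + fp + fn)
    return f, present


def macro_f_score(model: CRFModel, seqs: Sequence[Seq]) -> float:
    """Macro-average F over classes present in the data."""
    f, present = per_class_f_scores(model, seqs)
    usable = present & ~np.isnan(f)
    if not usable.any():
        return float("nan")
    return float(np.nanmean(f[usable]))


def compute_class_weights(
    model: CRFModel,
    seqs: Sequence[Seq],
    alpha: float = 1.0,
) -> np.ndarray:
    """Propose class weights ``1 + alpha*(1 - F_c)``, mean-normalized to 1.

    Classes absent from ``seqs`` keep weight 1 (with a warning) and are
    excluded from the normalization.
    """
    f, present = per_class_f_scores(model, seqs)
    w = np.ones(K_CLASSES)
    if not present.all():
        absent = [c + 1 for c in range(K_CLASSES) if not present[c]]
        warnings.warn(f"classes absent from weight-update data: {absent}; "
                      "their weights stay at 1", stacklevel=2)
    idx = present & ~np.isnan(f)
    if idx.any():
        raw = 1.0 + alpha * (1.0 - f[idx])
        w[idx] = raw / raw.mean()
    return w


def fit(
    train_seqs: Sequence[Seq],
    val_seqs: Sequence[Seq] | None,
    tau: int,
    vartheta: float,
    seed: int = 0,
    feature_schema: Sequence[str] | None = None,
    alpha: float = 1.0,
    gtol: float = 1e-5,
    maxiter: int = 500,
) -> CRFModel:
    """Train a (dynamically weighted) chain CRF.

    Alternates convex optimization of the weighted likelihood at fixed
    class weights with F-score-driven weight updates, for at most ``tau``
    rounds; ``tau = 0`` is the plain unweighted CRF. Weight proposals are
    scored on ``val_seqs`` (training data if None) and rejected — ending
    the alternation — if macro F drops. Returns the round with the best
    validation macro F. Deterministic: parameters start at zero and data
    order is preserved; ``seed`` is recorded in the model.
    """
    if not train_seqs:
        raise ValueError("training set must be nonempty")
    d = train_seqs[0][0].shape[1]
    _check_seqs(train_seqs, d)
    if val_seqs:
        _check_seqs(val_seqs, d)
    schema = list(feature_schema) if feature_schema else [f"f{i}" for i in range(d)]
    if len(schema) != d:
        raise CRFSchemaError("feature_schema length disagrees with data")
    eval_seqs = val_seqs if val_seqs else train_seqs
    k = K_CLASSES

    def optimize(w: np.ndarray, theta0: np.ndarray, iters: int) -> np.ndarray:
        res = minimize(
            _objective, theta0, args=(train_seqs, w, vartheta, k, d),
            method="L-BFGS-B", jac=True,
            options={"gtol": gtol, "maxiter": iters, "ftol": 1e-12},
        )
        return res.x

    def build(theta: np.ndarray, w: np.ndarray) -> CRFModel:
        wu, b, tr = _unpack(theta, k, d)
        return CRFModel(
            unary_weights=wu.copy(), bias=b.copy(), transition_weights=tr.copy(),
            class_weights=w.copy(), tau=tau, vartheta=vartheta,
            feature_schema=schema, seed=seed,
        )

    w = np.ones(k)
    theta = optimize(w, np.zeros(k * d + k + k * k), maxiter)
    model = build(theta, w)
    cur_f = macro_f_score(model, eval_seqs)
    best = (cur_f, model)
    logger.info("round 0: macro-F=%.4f", cur_f)
    for it in range(1, tau + 1):
        w_prop = compute_class_weights(model, eval_seqs, alpha=alpha)
        if np.allclose(w_prop, w, atol=1e-12):
            logger.info("round %d: weights converged", it)
            break
        theta_prop = optimize(w_prop, theta, maxiter)
        model_prop = build(theta_prop, w_prop)
        f_prop = macro_f_score(model_prop, eval_seqs)
        logger.info("round %d: macro-F=%.4f (current %.4f)", it, f_prop, cur_f)
        if np.isnan(f_prop) or f_prop < cur_f:
            break  # monotone acceptance: reject and stop
        theta, w, model, cur_f = theta_prop, w_prop, model_prop, f_prop
        if cur_f >= best[0] or np.isnan(best[0]):
            best = (cur_f, model)
    return best[1]
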