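"""Linear-chain conditional random field for sentence-sequence labeling.

A small, self-contained CRF: node potentials are a linear function of
per-sentence feature vectors, plus start/transition/end weights over the
label alphabet.  Training minimizes the L2-regularized negative
log-likelihood with L-BFGS; gradients come from forward-backward.  Sizes
here are modest (thousands of short sequences, a few hundred features,
<= 7 labels), so everything is dense numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import issparse
from scipy.special import logsumexp

__all__ = ["LinearChainCRF"]


def _as_dense(X) -> np.ndarray:
    if issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


@dataclass
class _Params:
    W: np.ndarray  # (L, D) emission weights
    b: np.ndarray  # (L,) emission bias
    T: np.ndarray  # (L, L) transition weights, T[i, j] = score(i -> j)
    s: np.ndarray  # (L,) start weights
    e: np.ndarray  # (L,) end weights


class LinearChainCRF:
    """CRF over label sequences given per-item feature rows.

    Parameters
    ----------
    c2 : float
        L2 regularization strength on all weights.
    max_iter : int
        L-BFGS iteration cap.
    """

    def __init__(self, c2: float = 1.0, max_iter: int = 150, tol: float = 1e-6):
        self.c2 = c2
        self.max_iter = max_iter
        self.tol = tol
        self.classes_: list | None = None
        self._params: _Params | None = None

    # --- parameter packing ---------------------------------------------

    def _shapes(self, n_labels: int, n_feat: int):
        return [
            (n_labels, n_feat),
            (n_labels,),
            (n_labels, n_labels),
            (n_labels,),
            (n_labels,),
        ]

    def _unpack(self, theta: np.ndarray, n_labels: int, n_feat: int) -> _Params:
        parts = []
        off = 0
        for shape in self._shapes(n_labels, n_feat):
            size = int(np.prod(shape))
            parts.append(theta[off : off + size].reshape(shape))
            off += size
        return _Params(*parts)

    # --- inference ------------------------------------------------------

    @staticmethod
    def _node_scores(p: _Params, X: np.ndarray) -> np.ndarray:
        return X @ p.W.T + p.b  # (n, L)

    @staticmethod
    def _forward_backward(node: np.ndarray, p: _Params):
        """Log-space forward/backward for one sequence; returns
        (log_partition, node_marginals, pairwise_marginals)."""
        n, L = node.shape
        alpha = np.empty((n, L))
        beta = np.empty((n, L))
        alpha[0] = p.s + node[0]
        for t in range(1, n):
            alpha[t] = node[t] + logsumexp(alpha[t - 1][:, None] + p.T, axis=0)
        beta[-1] = p.e
        for t in range(n - 2, -1, -1):
            beta[t] = logsumexp(p.T + (node[t + 1] + beta[t + 1])[None, :], axis=1)
        logZ = logsumexp(alpha[-1] + p.e)
        gamma = np.exp(alpha + beta - logZ)  # (n, L)
        pair = np.zeros((L, L))
        for t in range(n - 1):
            m = (
                alpha[t][:, None]
                + p.T
                + (node[t + 1] + beta[t + 1])[None, :]
                - logZ
            )
            pair += np.exp(m)
        return logZ, gamma, pair

    @staticmethod
    def _viterbi(node: np.ndarray, p: _Params) -> np.ndarray:
        n, L = node.shape
        delta = p.s + node[0]
        back = np.zeros((n, L), dtype=np.intp)
        for t in range(1, n):
            scores = delta[:, None] + p.T
            back[t] = np.argmax(scores, axis=0)
            delta = node[t] + np.max(scores, axis=0)
        delta = delta + p.e
        path = np.empty(n, dtype=np.intp)
        path[-1] = int(np.argmax(delta))
        for t in range(n - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return path

    # --- training -------------------------------------------------------

    def fit(self, sequences_X, sequences_y) -> "LinearChainCRF":
        """Fit on parallel lists of feature matrices and label sequences."""
        if len(sequences_X) != len(sequences_y) or not sequences_X:
            raise ValueError("need equal-length, non-empty sequence lists")
        for i, y in enumerate(sequences_y):
            if len(y) == 0:
                raise ValueError(f"sequence {i} is empty")
        labels = sorted({lab for y in sequences_y for lab in y})
        self.classes_ = labels
        index = {lab: k for k, lab in enumerate(labels)}
        Xs = [_as_dense(X) for X in sequences_X]
        ys = [np.array([index[lab] for lab in y], dtype=np.intp) for y in sequences_y]
        L, D = len(labels), Xs[0].shape[1]

        def objective(theta: np.ndarray):
            p = self._unpack(theta, L, D)
            gW = np.zeros_like(p.W)
            gb = np.zeros_like(p.b)
            gT = np.zeros_like(p.T)
            gs = np.zeros_like(p.s)
            ge = np.zeros_like(p.e)
            nll = 0.0
            for X, y in zip(Xs, ys):
                node = self._node_scores(p, X)
                logZ, gamma, pair = self._forward_backward(node, p)
                n = len(y)
                gold = node[np.arange(n), y].sum() + p.s[y[0]] + p.e[y[-1]]
                if n > 1:
                    gold += p.T[y[:-1], y[1:]].sum()
                nll += logZ - gold
                resid = gamma.copy()
                resid[np.arange(n), y] -= 1.0
                gW += resid.T @ X
                gb += resid.sum(axis=0)
                gs[y[0]] -= 1.0
                gs += gamma[0]
                ge[y[-1]] -= 1.0
                ge += gamma[-1]
                if n > 1:
                    gT += pair
                    np.add.at(gT, (y[:-1], y[1:]), -1.0)
            nll += 0.5 * self.c2 * float(theta @ theta)
            grad = np.concatenate(
                [gW.ravel(), gb.ravel(), gT.ravel(), gs.ravel(), ge.ravel()]
            )
            grad += self.c2 * theta
            return nll, grad

        size = sum(int(np.prod(s)) for s in self._shapes(L, D))
        res = minimize(
            objective,
            np.zeros(size),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        self._params = self._unpack(res.x, L, D)
        self._n_features = D
        return self

    def predict(self, X) -> list:
        """Best-path (Viterbi) labels for one sequence."""
        labels, conf = self.predict_with_confidence(X)
        return labels

    def predict_with_confidence(self, X) -> tuple[list, np.ndarray]:
        """Viterbi labels plus each label's posterior marginal probability."""
        if self._params is None or self.classes_ is None:
            raise RuntimeError("CRF is not fitted")
        Xd = _as_dense(X)
        node = self._node_scores(self._params, Xd)
        path = self._viterbi(node, self._params)
        _, gamma, _ = self._forward_backward(node, self._params)
        conf = gamma[np.arange(len(path)), path]
        return [self.classes_[k] for k in path], conf

    def weights_hash(self) -> str:
        """Stable hash of the fitted weights (for determinism checks)."""
        import hashlib

        if self._params is None:
            raise RuntimeError("CRF is not fitted")
        h = hashlib.sha256()
        for arr in (
            self._params.W,
            self._params.b,
            self._params.T,
            self._params.s,
            self._params.e,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()
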