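"""Single-response partial least squares (PLS1) with k-fold RMSECV.

This is the regression engine behind the wavelength selectors.  The
two-class problem is coded numerically (healthy = 0, infested = 1) and
PLS regresses the class code on the centered spectra; RMSECV of that
regression is the selection objective everywhere in the package.

The NIPALS algorithm for a single response needs no inner iteration: the
weight vector of each component is the (normalised) covariance X'y, after
which X is deflated by the extracted score.  One fit at A_max yields the
coefficient vectors of every model with 1..A_max components, which keeps
cross-validation cheap inside the Monte-Carlo selectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ParameterError


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    ``b`` is the regression coefficient vector on the original variable
    scale, using all ``A`` components; ``coef_path`` row a-1 holds the
    coefficients of the a-component truncation, so ``b == coef_path[-1]``.
    """

    A: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray          # B x A weight vectors
    P: np.ndarray          # B x A loadings
    q: np.ndarray          # A response loadings
    b: np.ndarray          # B coefficients (original scale)
    coef_path: np.ndarray  # A x B coefficients for 1..A components

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.b)

    def coef(self, a: Optional[int] = None) -> np.ndarray:
        if a is None:
            return self.b
        if not 1 <= a <= self.A:
            raise ParameterError(f"a must be in 1..{self.A}")
        return self.coef_path[a - 1]

    def predict(self, X: np.ndarray, a: Optional[int] = None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef(a) + self.y_mean

    def reconstruct_b(self) -> np.ndarray:
        """Coefficients recomputed from (W, P, q): b = W (P'W)^-1 q."""
        R = np.linalg.solve((self.P.T @ self.W).T, self.W.T).T
        return R @ self.q


def fit_pls(X: np.ndarray, y: np.ndarray, a: int) -> PLSModel:
    """Fit a PLS1 model with ``a`` latent variables by NIPALS.

    Components whose residual covariance with y vanishes are dropped, so
    the fitted ``A`` can be smaller than requested on exactly-fit or
    rank-deficient data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape != (n,):
        raise ParameterError("y length must match X rows")
    if n < 2:
        raise ParameterError("need at least 2 samples")
    if np.ptp(y) == 0:
        raise ParameterError("y has zero variance")
    if not 1 <= a <= min(n - 1, p):
        raise ParameterError(f"a must be in 1..min(N-1, B) = {min(n - 1, p)}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, a))
    P = np.zeros((p, a))
    q = np.zeros(a)
    used = 0
    for _ in range(a):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        p_load = E.T @ t / tt
        q_load = float(f @ t) / tt
        E = E - np.outer(t, p_load)
        f = f - q_load * t
        W[:, used], P[:, used], q[used] = w, p_load, q_load
        used += 1
    if used == 0:
        raise ParameterError("no PLS component could be extracted")
    W, P, q = W[:, :used], P[:, :used], q[:used]

    # b for every truncation: R = W (P'W)^-1 (P'W is unit upper triangular)
    R = np.linalg.solve((P.T @ W).T, W.T).T
    coef_path = np.cumsum(R * q, axis=1).T  # a x B
    return PLSModel(A=used, x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q,
                    b=coef_path[-1].copy(), coef_path=coef_path)


@dataclass(frozen=True)
class CVPlan:
    """Deterministic, class-stratified k-fold assignment.

    Samples of each class are shuffled with a seeded generator and dealt
    round-robin to folds, so fold sizes differ by at most one and every
    fold sees both classes whenever possible.
    """

    n_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ParameterError("need at least 2 folds")

    def folds(self, n: int, y: Optional[np.ndarray] = None) -> list[np.ndarray]:
        """Test-index arrays, one per fold, partitioning range(n)."""
        if n < self.n_folds:
            raise ParameterError(f"cannot make {self.n_folds} folds from {n} samples")
        rng = np.random.default_rng(self.seed)
        assign = np.empty(n, dtype=int)
        if y is None:
            order = rng.permutation(n)
            assign[order] = np.arange(n) % self.n_folds
        else:
            y = np.asarray(y)
            counter = 0
            for cls in np.unique(y):
                idx = np.where(y == cls)[0]
                idx = rng.permutation(idx)
                for i, sample in enumerate(idx):
                    assign[sample] = (counter + i) % self.n_folds
                counter += idx.size
        return [np.where(assign == k)[0] for k in range(self.n_folds)]


@dataclass
class RmsecvResult:
    curve: np.ndarray   # RMSECV for A = 1..a_max
    best_a: int         # argmin (1-based)

    @property
    def best_rmsecv(self) -> float:
        return float(self.curve[self.best_a - 1])


def cv_pairs(n: int, folds: list) -> list:
    """(train_idx, test_idx) pairs from a list of test-fold index arrays."""
    all_idx = np.arange(n)
    return [(np.setdiff1d(all_idx, test), test) for test in folds]


def rmsecv(X: np.ndarray, y: np.ndarray, a_max: int,
           plan: CVPlan = CVPlan(), folds: Optional[list] = None,
           pairs: Optional[list] = None) -> RmsecvResult:
    """Pooled k-fold RMSECV curve over 1..a_max latent variables.

    Out-of-fold residuals from every fold are pooled into a single RMSE
    per component count (not a mean of per-fold RMSEs).  ``folds`` (test
    index arrays) or ``pairs`` (precomputed train/test index pairs) may
    be supplied to reuse an assignment; otherwise ``plan`` stratifies on
    the distinct values of y when y is binary.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if pairs is None:
        if folds is None:
            strat = y if np.unique(y).size == 2 else None
            folds = plan.folds(n, strat)
        pairs = cv_pairs(n, folds)
    min_train = min(tr.size for tr, _ in pairs)
    a_eff = int(min(a_max, min_train - 1, p))
    if a_eff < 1:
        raise ParameterError("a_max too large for the fold sizes")
    sq = np.zeros(a_eff)
    for train, test_idx in pairs:
        if np.ptp(y[train]) == 0:  # single-class training fold: constant model
            import logging
            logging.getLogger(__name__).warning(
                "rmsecv: training fold with a single class, constant prediction")
            sq += ((y[train].mean() - y[test_idx, None]) ** 2).sum(axis=0)
            continue
        model = fit_pls(X[train], y[train], a_eff)
        pred = (X[test_idx] - model.x_mean) @ model.coef_path.T + model.y_mean
        if model.A < a_eff:  # components exhausted: later truncations repeat
            pad = np.tile(pred[:, -1:], (1, a_eff - model.A))
            pred = np.hstack([pred, pad])
        sq += ((pred - y[test_idx, None]) ** 2).sum(axis=0)
    curve = np.sqrt(sq / n)
    return RmsecvResult(curve=curve, best_a=int(np.argmin(curve)) + 1)
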