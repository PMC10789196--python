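"""Infomax ICA with symmetric sphering and identity weight initialization.

The polarity mechanism studied by this package lives here.  Channels are
sphered with the *symmetric* (ZCA) whitener ``S = C^{-1/2}`` — the inverse
principal square root of the channel covariance — and the Infomax weight
matrix starts at the identity.  The iteration-0 mixing matrix is therefore
``S^{-1} = C^{1/2}``, a symmetric positive-definite matrix with a strictly
positive diagonal; for EEG-like covariances each column's peak-magnitude entry
sits on that diagonal, so every initial scalp topography is positive-dominant.
No post-hoc polarity correction is applied after learning: the whole point is
to observe which components keep, and which flip, the initial polarity.

The learning rule is natural-gradient Infomax with a logistic nonlinearity
(optionally the extended variant with sub/super-Gaussian switching), block
updates over shuffled samples, and learning-rate annealing when the
weight-update direction turns by more than 60 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "UnmixingModel",
    "sphering_matrix",
    "initial_mixing",
    "infomax",
    "order_by_variance",
    "amari_index",
    "match_components",
    "InfomaxICA",
]

_MAX_WEIGHT = 1e9


def sphering_matrix(data: np.ndarray, rank_rtol: float = 1e-10) -> np.ndarray:
    """Symmetric (ZCA) sphering matrix: inverse principal square root of the
    channel covariance of ``data`` (channels x samples, assumed centered or
    centered here).

    Raises if the covariance is rank deficient (smallest eigenvalue below
    ``rank_rtol`` times the largest): reduce the data rank first.
    """
    x = np.asarray(data, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    cov = (xc @ xc.T) / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= rank_rtol * evals[-1]:
        raise np.linalg.LinAlgError(
            "channel covariance is rank deficient; reduce the rank (e.g. drop a "
            "channel or project out the null space) before sphering"
        )
    return (evecs / np.sqrt(evals)) @ evecs.T


def initial_mixing(sphering: np.ndarray) -> np.ndarray:
    """Iteration-0 mixing matrix under identity initialization: ``S^{-1} = C^{1/2}``."""
    return np.linalg.inv(sphering)


@dataclass
class UnmixingModel:
    """Fitted decomposition: ``unmixing = weights @ sphering``; ``mixing`` is its
    inverse, whose columns are the IC scalp topographies."""

    sphering: np.ndarray
    weights: np.ndarray
    unmixing: np.ndarray
    mixing: np.ndarray
    order: np.ndarray
    n_iter: int
    converged: bool


def _logistic(u: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(u)


def infomax(data_sphered: np.ndarray, init: np.ndarray | None = None,
            lrate: float | None = None, anneal_factor: float = 0.9,
            anneal_deg: float = 60.0, max_iter: int = 512, tol: float = 1e-6,
            shuffle_seed: int = 0, block: int | None = None,
            extended: bool = False, ext_interval: int = 1,
            n_kurt_samples: int = 6000) -> tuple[np.ndarray, int, bool]:
    """Natural-gradient Infomax on sphered data (channels x samples).

    Returns ``(weights, n_iter, converged)``.  Deterministic given
    ``shuffle_seed``.  Raises if the weights blow up (reduce ``lrate``).
    """
    z = np.asarray(data_sphered, dtype=float)
    n_ch, n_samp = z.shape
    W = np.eye(n_ch) if init is None else np.array(init, dtype=float)
    if W.shape != (n_ch, n_ch) or np.linalg.matrix_rank(W) < n_ch:
        raise ValueError("init must be a full-rank square matrix")
    if lrate is None:
        lrate = 0.001 / np.log(n_ch) if n_ch > 2 else 0.001
    if block is None:
        block = int(np.ceil(np.sqrt(n_samp / 3.0)))
    rng = np.random.default_rng(shuffle_seed)
    eye = np.eye(n_ch)
    signs = np.ones(n_ch)  # +1 super-Gaussian, -1 sub-Gaussian (extended)
    olddelta = None
    oldchange = None
    n_iter = 0
    converged = False

    for step in range(1, max_iter + 1):
        perm = rng.permutation(n_samp)
        W_old = W.copy()
        for start in range(0, n_samp - block + 1, block):
            xb = z[:, perm[start:start + block]]
            u = W @ xb
            if extended:
                y = np.tanh(u)
                grad = block * eye - (signs[:, None] * y) @ u.T - u @ u.T
            else:
                y = _logistic(u)
                grad = block * eye + (1.0 - 2.0 * y) @ u.T
            W = W + lrate * grad @ W
            if np.max(np.abs(W)) > _MAX_WEIGHT:
                raise FloatingPointError(
                    "Infomax weights blew up; use a smaller lrate"
                )
        n_iter = step
        if extended and step % ext_interval == 0:
            sub = rng.choice(n_samp, size=min(n_kurt_samples, n_samp), replace=False)
            act = W @ z[:, sub]
            m2 = np.mean(act**2, axis=1)
            kurt = np.mean(act**4, axis=1) / (m2**2 + 1e-300) - 3.0
            signs = np.where(kurt >= 0, 1.0, -1.0)
        delta = (W - W_old).ravel()
        change = float(delta @ delta)
        # Anneal when the update direction turns past anneal_deg relative to the
        # direction at the previous annealing event (reference-implementation
        # style bookkeeping).
        if olddelta is None:
            olddelta, oldchange = delta, change
        elif change > 1e-300 and oldchange > 1e-300:
            cosang = float(delta @ olddelta) / np.sqrt(change * oldchange)
            angledelta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angledelta > anneal_deg:
                lrate *= anneal_factor
                olddelta, oldchange = delta, change
        if step > 2 and change < tol:
            converged = True
            break
    return W, n_iter, converged


def _fit_unmixing(data: np.ndarray, **kwargs) -> UnmixingModel:
    S = sphering_matrix(data)
    xc = np.asarray(data, float)
    xc = xc - xc.mean(axis=1, keepdims=True)
    z = S @ xc
    W, n_iter, converged = infomax(z, **kwargs)
    U = W @ S
    A = np.linalg.inv(U)
    model = UnmixingModel(sphering=S, weights=W, unmixing=U, mixing=A,
                          order=np.arange(data.shape[0]), n_iter=n_iter,
                          converged=converged)
    return order_by_variance(model, xc)


def order_by_variance(model: UnmixingModel, data: np.ndarray) -> UnmixingModel:
    """Sort components by descending mean projected variance over channels.

    The projected variance of component k is ``mean_ch(A[:, k]**2) * var(s_k)``
    — the average per-channel variance its back-projection contributes.
    """
    s = model.unmixing @ np.asarray(data, float)
    pv = np.mean(model.mixing**2, axis=0) * np.var(s, axis=1)
    order = np.argsort(-pv, kind="stable")
    return UnmixingModel(
        sphering=model.sphering,
        weights=model.weights[order],
        unmixing=model.unmixing[order],
        mixing=model.mixing[:, order],
        order=order,
        n_iter=model.n_iter,
        converged=model.converged,
    )


def projected_variances(model: UnmixingModel, data: np.ndarray) -> np.ndarray:
    s = model.unmixing @ np.asarray(data, float)
    return np.mean(model.mixing**2, axis=0) * np.var(s, axis=1)


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def match_components(unmixing: np.ndarray, mixing_true: np.ndarray) -> np.ndarray:
    """Assign each true mixing column its best-matching estimated component.

    Hungarian assignment on the absolute loadings ``|unmixing @ mixing_true|``;
    returns the estimated-component index for each true source.
    """
    from scipy.optimize import linear_sum_assignment

    P = np.abs(unmixing @ mixing_true)
    rows, cols = linear_sum_assignment(-P)
    out = np.empty(mixing_true.shape[1], dtype=int)
    out[cols] = rows
    return out


def amari_index(A_est: np.ndarray, A_true: np.ndarray) -> float:
    """Permutation- and scale-invariant Amari error, ~[0, 1], 0 iff equal up to
    permutation and scaling.

    For square inputs this is the standard Amari index of ``P = A_est^{-1}
    A_true``.  When ``A_true`` has fewer columns (undercomplete ground truth in
    a full decomposition), each true column is first assigned its best-matching
    estimated component (Hungarian on ``|P|``) and the index is computed on the
    resulting square submatrix; a non-injective match inflates the index.
    """
    A_est = np.asarray(A_est, float)
    A_true = np.asarray(A_true, float)
    if A_est.shape[0] != A_true.shape[0]:
        raise ValueError("A_est and A_true must have the same number of rows")
    try:
        P = np.abs(np.linalg.solve(A_est, A_true))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("A_est is singular") from err
    if A_true.shape[1] < A_est.shape[1]:
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-P)
        sel = np.empty(A_true.shape[1], dtype=int)
        sel[cols] = rows
        P = P[sel]
    n = P.shape[0]
    if n < 2:
        return 0.0
    row_term = np.sum(P.sum(axis=1) / P.max(axis=1) - 1.0)
    col_term = np.sum(P.sum(axis=0) / P.max(axis=0) - 1.0)
    return float((row_term + col_term) / (2.0 * n * (n - 1)))


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class InfomaxICA(TransformerMixin, BaseEstimator):
    """Identity-initialized Infomax ICA as a scikit-learn transformer.

    Follows the sklearn convention: ``X`` is (n_samples, n_channels).  The
    fitted ``mixing_`` is (n_channels, n_components); its columns are the IC
    scalp topographies, in the variance-descending component order.

    Parameters
    ----------
    lrate : initial learning rate; default ``0.001 / ln(n_channels)``.
    anneal_factor : learning-rate multiplier applied when the update direction
        turns by more than ``anneal_deg`` degrees.
    max_iter, tol : stopping rule on the squared weight change per pass.
    extended : use the extended (sub/super-Gaussian) nonlinearity.
    random_state : seed for the per-pass sample shuffling.
    """

    def __init__(self, lrate: float | None = None, anneal_factor: float = 0.9,
                 anneal_deg: float = 60.0, max_iter: int = 512, tol: float = 1e-6,
                 block: int | None = None, extended: bool = False,
                 random_state: int = 0):
        self.lrate = lrate
        self.anneal_factor = anneal_factor
        self.anneal_deg = anneal_deg
        self.max_iter = max_iter
        self.tol = tol
        self.block = block
        self.extended = extended
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_channels)")
        data = X.T
        self.mean_ = data.mean(axis=1)
        model = _fit_unmixing(
            data,
            lrate=self.lrate,
            anneal_factor=self.anneal_factor,
            anneal_deg=self.anneal_deg,
            max_iter=self.max_iter,
            tol=self.tol,
            shuffle_seed=self.random_state,
            block=self.block,
            extended=self.extended,
        )
        self.sphering_ = model.sphering
        self.weights_ = model.weights
        self.unmixing_ = model.unmixing
        self.mixing_ = model.mixing
        self.order_ = model.order
        self.n_iter_ = model.n_iter
        self.converged_ = model.converged
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "unmixing_")
        X = np.asarray(X, dtype=float)
        return (self.unmixing_ @ (X.T - self.mean_[:, None])).T

    def inverse_transform(self, S) -> np.ndarray:
        check_is_fitted(self, "mixing_")
        S = np.asarray(S, dtype=float)
        return (self.mixing_ @ S.T + self.mean_[:, None]).T

    def initial_mixing(self) -> np.ndarray:
        """Iteration-0 topographies (columns of ``C^{1/2}``)."""
        check_is_fitted(self, "sphering_")
        return initial_mixing(self.sphering_)

    def to_model(self) -> UnmixingModel:
        check_is_fitted(self, "unmixing_")
        return UnmixingModel(
            sphering=self.sphering_, weights=self.weights_,
            unmixing=self.unmixing_, mixing=self.mixing_, order=self.order_,
            n_iter=self.n_iter_, converged=self.converged_,
        )
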