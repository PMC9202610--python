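"""Five spatial-synergy extraction methods behind one transformer contract.

Each extractor factorizes a muscle-activation matrix into k synergy vectors
and k activation-coefficient time series under the linear model
``M ≈ offset + W @ C``.  The estimators follow the scikit-learn transformer
API and operate on ``X`` of shape ``(n_samples, n_channels)`` — i.e. the
transpose of the muscles-by-time matrix ``M`` — so they compose with sklearn
pipelines.  The module-level ``extract_*`` functions accept ``M`` directly
(``m x n``) and return a :class:`FactorizationResult`.

Methods
-------
PCA     SVD of the row-centered data; orthonormal components ordered by
        decreasing variance.
ICA     fixed-point iteration (cubic nonlinearity, symmetric
        orthogonalization) on data whitened to k dimensions.
FA      maximum-likelihood factor analysis with varimax rotation and
        weighted-least-squares (Bartlett) factor scores; feasible only when
        the degrees-of-freedom bound (m - k)^2 - (m + k) > 0 holds.
NMF     Lee-Seung multiplicative updates for the squared Frobenius error,
        best of several random restarts.
AE      undercomplete sparse autoencoder (saturating-linear encoder, linear
        decoder); synergies are the decoder weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FactorAnalysis as _SkFactorAnalysis

from ._ae import AEParameters, train_autoencoder

__all__ = [
    "FactorizationResult",
    "AEParameters",
    "ConvergenceError",
    "PCAExtractor",
    "FastICAExtractor",
    "FactorAnalysisExtractor",
    "NMFExtractor",
    "AutoencoderExtractor",
    "fa_degrees_of_freedom",
    "extract_pca",
    "extract_ica",
    "extract_fa",
    "extract_nmf",
    "extract_ae",
    "reconstruct",
    "METHODS",
]

_EPS = np.finfo(float).eps


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge after all restarts."""


@dataclass
class FactorizationResult:
    """Estimated synergies and coefficients from one method on one matrix.

    ``W_hat`` is ``m x k`` (synergy vectors in columns), ``C_hat`` is
    ``k x n``; ``offset`` is the per-muscle mean for PCA/ICA/FA, the decoder
    bias for AE and zeros for NMF, so that every method reconstructs as
    ``offset + W_hat @ C_hat``.
    """

    method: str
    W_hat: np.ndarray
    C_hat: np.ndarray
    offset: np.ndarray
    n_iter: int = 0
    objective: float = float("nan")
    seed: int | None = None

    def reconstruct(self) -> np.ndarray:
        return self.offset[:, None] + self.W_hat @ self.C_hat


def reconstruct(result: FactorizationResult) -> np.ndarray:
    """Deterministic part of the model: ``offset + W_hat @ C_hat``."""
    return result.reconstruct()


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite values")
    return X


class _BaseExtractor(TransformerMixin, BaseEstimator):
    """Shared surface: fit stores components_, coefficients_, offset_."""

    method: str = ""

    def _check_fit_input(self, X, k):
        X = _as_matrix(X)
        if X.shape[1] < k:
            raise ValueError(
                f"n_components={k} exceeds the number of channels {X.shape[1]}"
            )
        return X

    def transform(self, X):
        X = _as_matrix(X)
        return (X - self.mean_) @ self.unmixing_.T

    def inverse_transform(self, H):
        return np.asarray(H) @ self.components_ + self.offset_

    def reconstruct(self, X):
        """Model reconstruction of X, shape-preserving."""
        return self.inverse_transform(self.transform(X))

    def to_result(self, seed: int | None = None) -> FactorizationResult:
        """Package the fit in the muscles-by-time convention."""
        return FactorizationResult(
            method=self.method,
            W_hat=self.components_.T.copy(),
            C_hat=self.coefficients_.T.copy(),
            offset=self.offset_.copy(),
            n_iter=getattr(self, "n_iter_", 0),
            objective=getattr(self, "objective_", float("nan")),
            seed=seed,
        )


class PCAExtractor(_BaseExtractor):
    """Principal components via SVD of the centered data.

    ``components_`` rows are orthonormal and ordered by decreasing explained
    variance.
    """

    method = "PCA"

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = self._check_fit_input(X, self.n_components)
        k = self.n_components
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        self.unmixing_ = self.components_
        self.offset_ = self.mean_
        self.coefficients_ = Xc @ self.components_.T
        self.objective_ = float(np.sum(s[k:] ** 2))  # residual SSE
        self.n_iter_ = 1
        return self


class FastICAExtractor(_BaseExtractor):
    """Fixed-point ICA (cubic nonlinearity, symmetric orthogonalization).

    Data are centered and PCA-whitened to ``n_components`` dimensions before
    the fixed-point iteration.  The estimated mixing columns are rescaled to
    unit norm; the sources absorb the normalization so the reconstruction is
    unchanged.
    """

    method = "ICA"

    def __init__(self, n_components: int = 4, tol: float = 1e-6,
                 max_iter: int = 1000, n_restarts: int = 5,
                 random_state: int = 0, strict: bool = False):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.strict = strict

    @staticmethod
    def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
        s, u = np.linalg.eigh(W @ W.T)
        return (u / np.sqrt(np.maximum(s, _EPS))) @ u.T @ W

    def fit(self, X, y=None):
        X = self._check_fit_input(X, self.n_components)
        k = self.n_components
        n, m = X.shape
        self.mean_ = X.mean(axis=0)
        Xc = (X - self.mean_).T  # (m, n)

        cov = (Xc @ Xc.T) / n
        d, E = np.linalg.eigh(cov)
        order = np.argsort(d)[::-1][:k]
        d, E = d[order], E[:, order]
        if np.any(d <= 0):
            raise ValueError("rank-deficient data: cannot whiten to k dimensions")
        K = (E / np.sqrt(d)).T  # (k, m) whitening
        Z = K @ Xc  # (k, n), cov ~ I

        best = None
        for r in range(self.n_restarts):
            rng = np.random.default_rng(
                np.random.SeedSequence(self.random_state, spawn_key=(r,))
            )
            W = self._sym_decorrelate(rng.standard_normal((k, k)))
            lim, it = np.inf, 0
            for it in range(1, self.max_iter + 1):
                S = W @ Z
                W_new = (S**3) @ Z.T / n - 3.0 * W
                W_new = self._sym_decorrelate(W_new)
                lim = float(np.max(np.abs(np.abs(np.diag(W_new @ W.T)) - 1.0)))
                W = W_new
                if lim < self.tol:
                    break
            if best is None or lim < best[0]:
                best = (lim, W, it)
            if lim < self.tol:
                break
        lim, W, n_iter = best
        self.converged_ = lim < self.tol
        if not self.converged_ and self.strict:
            raise ConvergenceError(
                f"fixed-point ICA did not converge after {self.n_restarts} restarts "
                f"(last tolerance {lim:.2e})"
            )

        S = W @ Z  # (k, n) unit-variance sources
        A = (E * np.sqrt(d)) @ W.T  # (m, k) mixing
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        self.components_ = (A / norms).T  # (k, m), unit-norm synergy rows
        self.unmixing_ = norms[:, None] * (W @ K)
        self.offset_ = self.mean_
        self.coefficients_ = (norms[:, None] * S).T
        self.n_iter_ = n_iter
        self.objective_ = lim
        return self


def fa_degrees_of_freedom(m: int, k: int) -> int:
    """Degrees of freedom of the k-factor model on m variables: (m-k)^2 - (m+k)."""
    return (m - k) ** 2 - (m + k)


class FactorAnalysisExtractor(_BaseExtractor):
    """Maximum-likelihood factor analysis with WLS (Bartlett) factor scores.

    The data are standardized per channel, so loadings live in correlation
    units; ``components_`` are mapped back to the original units.  Loadings
    are varimax-rotated by default (``rotation=None`` for the unrotated
    solution).  A k-factor model on m channels is identified only when
    ``(m - k)^2 - (m + k) > 0``; violations raise ``ValueError``.
    """

    method = "FA"

    def __init__(self, n_components: int = 4, rotation: str | None = "varimax",
                 max_iter: int = 1000):
        self.n_components = n_components
        self.rotation = rotation
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = self._check_fit_input(X, self.n_components)
        m, k = X.shape[1], self.n_components
        df = fa_degrees_of_freedom(m, k)
        if df <= 0:
            raise ValueError(
                f"factor model not identified: (m-k)^2-(m+k) = ({m}-{k})^2-({m}+{k}) "
                f"= {df} <= 0; {k} factors need more channels"
            )
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ <= 0):
            raise ValueError("constant channel: cannot standardize for factor analysis")
        Z = (X - self.mean_) / self.scale_

        fa = _SkFactorAnalysis(n_components=k, rotation=self.rotation,
                               max_iter=self.max_iter)
        fa.fit(Z)
        L = fa.components_.T  # (m, k) loadings, standardized units
        psi = np.maximum(fa.noise_variance_, 1e-8)
        # Bartlett / weighted-least-squares scores: (L' Psi^-1 L)^-1 L' Psi^-1 z
        LtPi = L.T / psi
        B = np.linalg.solve(LtPi @ L, LtPi)  # (k, m)
        self.loadings_ = L
        self.noise_variance_ = psi
        self.components_ = (self.scale_[:, None] * L).T  # back to original units
        self.unmixing_ = B / self.scale_
        self.offset_ = self.mean_
        self.coefficients_ = Z @ B.T
        self.n_iter_ = getattr(fa, "n_iter_", 0)
        self.objective_ = float(fa.loglike_[-1]) if fa.loglike_ else float("nan")
        return self

    def transform(self, X):
        X = _as_matrix(X)
        return (X - self.mean_) @ self.unmixing_.T


class NMFExtractor(_BaseExtractor):
    """Non-negative matrix factorization by multiplicative updates.

    Minimizes the squared Frobenius error ``||M - W C||_F^2`` with the
    Lee-Seung multiplicative update rules, keeping the best of
    ``n_restarts`` random initializations.  Iterations stop when the relative
    objective change drops below ``tol``.  The per-iteration objective trace
    of the winning restart is stored in ``objective_trace_`` (the updates are
    provably monotone non-increasing).
    """

    method = "NMF"

    def __init__(self, n_components: int = 4, max_iter: int = 2000,
                 tol: float = 1e-6, n_restarts: int = 10, screen_iter: int = 200,
                 random_state: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.screen_iter = screen_iter
        self.random_state = random_state

    def _mu_fit(self, V: np.ndarray, rng: np.random.Generator | None,
                max_iter: int | None = None,
                WH0: tuple[np.ndarray, np.ndarray] | None = None):
        m, n = V.shape
        k = self.n_components
        if WH0 is not None:
            W, H = WH0[0].copy(), WH0[1].copy()
        else:
            avg = np.sqrt(max(V.mean(), _EPS) / k)
            W = avg * np.abs(rng.standard_normal((m, k)))
            H = avg * np.abs(rng.standard_normal((k, n)))
        max_iter = self.max_iter if max_iter is None else max_iter
        trace = []
        obj0 = float(np.linalg.norm(V - W @ H) ** 2)
        prev_checkpoint = obj0
        n_iter = 0
        for it in range(1, max_iter + 1):
            WH = W @ H
            H *= (W.T @ V) / np.maximum(W.T @ WH, _EPS)
            WH = W @ H
            W *= (V @ H.T) / np.maximum(WH @ H.T, _EPS)
            obj = float(np.linalg.norm(V - W @ H) ** 2)
            trace.append(obj)
            n_iter = it
            # checkpointed stop: progress over the last 10 iterations,
            # relative to the initial error (per-iteration changes plateau
            # long before the factors settle)
            if it % 10 == 0:
                if (prev_checkpoint - obj) / max(obj0, _EPS) < self.tol:
                    break
                prev_checkpoint = obj
        return W, H, trace, n_iter

    def fit(self, X, y=None):
        X = self._check_fit_input(X, self.n_components)
        if np.any(X < 0):
            raise ValueError("NMF requires non-negative input")
        V = X.T  # (m, n)
        # screen all restarts on a short budget, then polish the best one to
        # the full tolerance (the winner is almost always decided early)
        screen = min(self.screen_iter, self.max_iter)
        best = None
        for r in range(self.n_restarts):
            rng = np.random.default_rng(
                np.random.SeedSequence(self.random_state, spawn_key=(r,))
            )
            W, H, trace, n_iter = self._mu_fit(V, rng, max_iter=screen)
            if best is None or trace[-1] < best[2][-1]:
                best = (W, H, trace, n_iter)
        W, H, trace, n_iter = best
        if n_iter >= screen and self.max_iter > screen:
            W, H, trace2, extra = self._mu_fit(V, None, max_iter=self.max_iter - screen,
                                               WH0=(W, H))
            trace = trace + trace2
            n_iter += extra
        self.components_ = W.T  # (k, m)
        self.coefficients_ = H.T  # (n, k)
        self.offset_ = np.zeros(V.shape[0])
        self.mean_ = self.offset_
        self.objective_trace_ = trace
        self.objective_ = trace[-1]
        self.n_iter_ = n_iter
        return self

    def transform(self, X, max_iter: int = 500):
        """Non-negative coefficients for X with the fitted synergies held fixed."""
        X = _as_matrix(X)
        V = X.T
        W = self.components_.T
        rng = np.random.default_rng(self.random_state)
        avg = np.sqrt(max(V.mean(), _EPS) / self.n_components)
        H = avg * np.abs(rng.standard_normal((self.n_components, V.shape[1])))
        WtV = W.T @ V
        WtW = W.T @ W
        for _ in range(max_iter):
            H_new = H * WtV / np.maximum(WtW @ H, _EPS)
            if np.max(np.abs(H_new - H)) < 1e-10:
                H = H_new
                break
            H = H_new
        return H.T


class AutoencoderExtractor(_BaseExtractor):
    """Undercomplete sparse autoencoder; synergies are the decoder weights.

    One hidden layer of ``n_components`` units with a saturating-linear
    transfer, linear decoder.  The loss is the reconstruction MSE plus an L2
    weight penalty (``l2``) and a Bernoulli-KL sparsity penalty pulling the
    mean hidden activation of each unit toward ``sparsity_target`` with
    weight ``sparsity_weight``.  Coefficients are, by convention, the linear
    encoder output ``IW @ M + Ib`` (set ``coefficient_transfer="satlin"`` for
    the post-transfer activations instead).
    """

    method = "AE"

    def __init__(self, n_components: int = 4, l2: float = 1e-3,
                 sparsity_weight: float = 1.0, sparsity_target: float = 0.05,
                 max_iter: int = 1000, init: str = "random",
                 coefficient_transfer: str = "linear", random_state: int = 0):
        self.n_components = n_components
        self.l2 = l2
        self.sparsity_weight = sparsity_weight
        self.sparsity_target = sparsity_target
        self.max_iter = max_iter
        self.init = init
        self.coefficient_transfer = coefficient_transfer
        self.random_state = random_state

    def fit(self, X, y=None):
        X = self._check_fit_input(X, self.n_components)
        M = X.T  # (m, n)
        rng = np.random.default_rng(self.random_state)
        params, n_iter, loss = train_autoencoder(
            M, self.n_components, l2=self.l2, beta=self.sparsity_weight,
            rho=self.sparsity_target, max_iter=self.max_iter,
            init=self.init, rng=rng,
        )
        self.parameters_ = params
        self.components_ = params.OW.T  # (k, m): decoder weights are the synergies
        self.offset_ = params.Ob
        self.mean_ = params.Ob  # decoder bias plays the offset role
        self.unmixing_ = params.IW
        self.encoder_bias_ = params.Ib
        self.coefficients_ = self.transform(X)
        self.n_iter_ = n_iter
        self.objective_ = loss
        return self

    def transform(self, X):
        X = _as_matrix(X)
        A = X @ self.unmixing_.T + self.encoder_bias_
        if self.coefficient_transfer == "satlin":
            A = np.clip(A, 0.0, 1.0)
        return A


METHODS = {
    "PCA": PCAExtractor,
    "ICA": FastICAExtractor,
    "FA": FactorAnalysisExtractor,
    "NMF": NMFExtractor,
    "AE": AutoencoderExtractor,
}


# ---------------------------------------------------------------------------
# muscles-by-time convenience wrappers
# ---------------------------------------------------------------------------


def extract_pca(M: np.ndarray, k: int) -> FactorizationResult:
    return PCAExtractor(n_components=k).fit(np.asarray(M).T).to_result()


def extract_ica(M: np.ndarray, k: int, seed: int = 0, **kwargs) -> FactorizationResult:
    est = FastICAExtractor(n_components=k, random_state=seed, **kwargs)
    return est.fit(np.asarray(M).T).to_result(seed=seed)


def extract_fa(M: np.ndarray, k: int, rotation: str | None = "varimax") -> FactorizationResult:
    est = FactorAnalysisExtractor(n_components=k, rotation=rotation)
    return est.fit(np.asarray(M).T).to_result()


def extract_nmf(M: np.ndarray, k: int, seed: int = 0, **kwargs) -> FactorizationResult:
    est = NMFExtractor(n_components=k, random_state=seed, **kwargs)
    return est.fit(np.asarray(M).T).to_result(seed=seed)


def extract_ae(M: np.ndarray, k: int, seed: int = 0, **kwargs):
    """Returns (FactorizationResult, AEParameters)."""
    est = AutoencoderExtractor(n_components=k, random_state=seed, **kwargs)
    est.fit(np.asarray(M).T)
    return est.to_result(seed=seed), est.parameters_
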