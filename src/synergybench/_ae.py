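"""Training routine for the undercomplete sparse autoencoder.

Single hidden layer of width k, saturating-linear encoder
(``satlin(x) = clip(x, 0, 1)``), linear decoder.  The loss is the classic
sparse-autoencoder cost

    L = MSE(M, OW @ h + Ob) + l2/2 * (||IW||^2 + ||OW||^2)
        + beta * sum_j KL(rho || rho_hat_j)

where ``h = satlin(IW @ M + Ib)``, ``rho_hat_j`` is the mean activation of
hidden unit j over samples, and KL is the Bernoulli Kullback-Leibler
divergence.  Biases are not weight-decayed.  The contract is the loss, not
the optimizer: any converging first-order/quasi-Newton method is acceptable;
we use L-BFGS with an analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

_RHO_CLIP = 1e-8


@dataclass
class AEParameters:
    """Weights and biases of the trained autoencoder, plus its loss trace."""

    IW: np.ndarray  # encoder weights (k, m)
    Ib: np.ndarray  # encoder bias (k,)
    OW: np.ndarray  # decoder weights (m, k)
    Ob: np.ndarray  # decoder bias (m,)
    loss_trace: list = field(default_factory=list)


def satlin(x: np.ndarray) -> np.ndarray:
    """Saturating linear transfer: 0 below 0, identity on [0, 1], 1 above 1."""
    return np.clip(x, 0.0, 1.0)


def _unpack(theta: np.ndarray, m: int, k: int):
    i = 0
    IW = theta[i : i + k * m].reshape(k, m); i += k * m
    Ib = theta[i : i + k]; i += k
    OW = theta[i : i + m * k].reshape(m, k); i += m * k
    Ob = theta[i : i + m]
    return IW, Ib, OW, Ob


def _pack(IW, Ib, OW, Ob) -> np.ndarray:
    return np.concatenate([IW.ravel(), Ib, OW.ravel(), Ob])


def loss_and_grad(theta: np.ndarray, M: np.ndarray, k: int, l2: float,
                  beta: float, rho: float):
    """Sparse-AE loss and analytic gradient w.r.t. the packed parameters."""
    m, n = M.shape
    IW, Ib, OW, Ob = _unpack(theta, m, k)

    A = IW @ M + Ib[:, None]
    H = np.clip(A, 0.0, 1.0)
    R = OW @ H + Ob[:, None]
    E = R - M

    mse = float(np.mean(E**2))
    omega_w = 0.5 * (float(np.sum(IW**2)) + float(np.sum(OW**2)))
    rho_hat = np.clip(H.mean(axis=1), _RHO_CLIP, 1.0 - _RHO_CLIP)
    kl = float(np.sum(rho * np.log(rho / rho_hat)
                      + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))))
    loss = mse + l2 * omega_w + beta * kl

    dR = (2.0 / (m * n)) * E
    gOW = dR @ H.T + l2 * OW
    gOb = dR.sum(axis=1)
    dH = OW.T @ dR
    # sparsity term: d kl / d rho_hat_j, spread over the n samples of unit j
    dkl = beta * (-rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat)) / n
    dH = dH + dkl[:, None]
    dA = dH * ((A > 0.0) & (A < 1.0))
    gIW = dA @ M.T + l2 * IW
    gIb = dA.sum(axis=1)
    return loss, _pack(gIW, gIb, gOW, gOb)


def _init_params(M: np.ndarray, k: int, init: str, rng: np.random.Generator):
    m = M.shape[0]
    mean = M.mean(axis=1)
    if init == "pca":
        Xc = M - mean[:, None]
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        Uk = U[:, :k]
        proj = Uk.T @ Xc
        alpha = 0.45 / max(float(np.abs(proj).max()), 1e-12)
        IW = alpha * Uk.T
        Ib = np.full(k, 0.5) - IW @ mean
        OW = Uk / alpha
        Ob = mean - OW @ np.full(k, 0.5)
    elif init == "random":
        r_in = 1.0 / np.sqrt(m)
        IW = rng.uniform(-r_in, r_in, size=(k, m))
        Ib = np.full(k, 0.5)
        OW = rng.uniform(-1.0, 1.0, size=(m, k)) / np.sqrt(k)
        Ob = mean.copy()
    else:
        raise ValueError(f"unknown init {init!r}")
    return _pack(IW, Ib, OW, Ob)


def train_autoencoder(
    M: np.ndarray,
    k: int,
    l2: float = 1e-3,
    beta: float = 1.0,
    rho: float = 0.05,
    max_iter: int = 1000,
    init: str = "random",
    rng: np.random.Generator | None = None,
    n_retries: int = 3,
) -> tuple[AEParameters, int, float]:
    """Fit the autoencoder; returns (parameters, n_iter, final loss).

    Retries with a fresh random initialization if the optimizer produces a
    non-finite loss (divergence).
    """
    rng = np.random.default_rng() if rng is None else rng
    m = M.shape[0]
    last_err: Exception | None = None
    for attempt in range(n_retries):
        theta0 = _init_params(M, k, init if attempt == 0 else "random", rng)
        trace: list[float] = []

        def fun(theta):
            loss, grad = loss_and_grad(theta, M, k, l2, beta, rho)
            trace.append(loss)
            return loss, grad

        res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
        if np.isfinite(res.fun):
            IW, Ib, OW, Ob = _unpack(res.x, m, k)
            return AEParameters(IW, Ib, OW, Ob, trace), int(res.nit), float(res.fun)
        last_err = RuntimeError(f"autoencoder training diverged (attempt {attempt + 1})")
    raise last_err  # pragma: no cover - requires pathological input
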