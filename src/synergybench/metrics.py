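"""Similarity and reconstruction metrics against the simulated ground truth.

* VAF — variance accounted for by a reconstruction.  Two conventions are
  supported: uncentered (``1 - ||M - M_hat||_F^2 / ||M||_F^2``) and centered
  (same, after removing the per-muscle mean of ``M`` from both matrices —
  the explained-variance convention native to PCA/FA).
* component matching — globally optimal assignment (Hungarian) between true
  and estimated synergy vectors on absolute dot products of unit-normalized
  columns, with sign flipping of negatively matched estimates.
* SVS / ACS — mean signed post-flip dot product over the matched synergy
  vectors / unit-normalized coefficient rows.
* principal angles — canonical angles between the two synergy subspaces,
  reported in degrees; the scalar summary is the mean angle.
* chance baseline — the same matching applied to independently generated
  random sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import subspace_angles
from scipy.optimize import linear_sum_assignment

from .factorizers import FactorizationResult
from .synthgen import GroundTruth, SimulatedTrial

__all__ = [
    "MatchResult",
    "SimilarityReport",
    "compute_vaf",
    "match_components",
    "synergy_vector_similarity",
    "activation_coefficient_similarity",
    "principal_angles",
    "evaluate_trial",
    "chance_similarity",
    "VAF_CONVENTIONS",
]

#: per-method VAF convention used by the benchmark.  Each method reports VAF
#: in the space where it defines its fit: PCA on centered data (the
#: explained-variance convention), FA on standardized data (the correlation
#: space the maximum-likelihood factor model is estimated in), and the
#: reconstruction methods (NMF, ICA, AE) on the raw data (uncentered).
VAF_CONVENTIONS: dict[str, dict] = {
    "PCA": {"centered": True},
    "FA": {"centered": True, "standardize": True},
    "ICA": {},
    "NMF": {},
    "AE": {},
}


@dataclass(frozen=True)
class MatchResult:
    """Optimal pairing of estimated onto true components.

    ``permutation[j]`` is the index of the true component matched to
    estimated component j; ``signs[j]`` is the flip applied to the estimate;
    ``matched_dots[j]`` is the (post-flip, non-negative) dot product of pair j
    ordered by true-component index.
    """

    permutation: np.ndarray
    signs: np.ndarray
    matched_dots: np.ndarray


@dataclass(frozen=True)
class SimilarityReport:
    vaf: float
    svs: float
    acs: float
    principal_angles_deg: np.ndarray
    pa_scalar_deg: float
    method: str = ""
    n_channels: int = 0
    snr_db: float = float("nan")
    dataset_id: int = -1
    trial_id: int = -1


def compute_vaf(M: np.ndarray, M_hat: np.ndarray, centered: bool = False,
                standardize: bool = False) -> float:
    """Variance accounted for: ``1 - ||M - M_hat||_F^2 / SST``.

    ``SST`` is the total (uncentered) energy of ``M`` by default; with
    ``centered=True`` the per-muscle (row) mean of ``M`` is removed from both
    matrices first (explained-variance convention); ``standardize=True``
    additionally weights each muscle by the inverse of its standard
    deviation, i.e. VAF in correlation space (implies centering).
    """
    M = np.asarray(M, dtype=float)
    M_hat = np.asarray(M_hat, dtype=float)
    if M.shape != M_hat.shape:
        raise ValueError("M and M_hat must have equal shapes")
    if centered or standardize:
        mu = M.mean(axis=1, keepdims=True)
        if standardize:
            sd = M.std(axis=1, ddof=1, keepdims=True)
            if np.any(sd <= 0):
                raise ValueError("constant muscle row: standardized VAF undefined")
        else:
            sd = 1.0
        M = (M - mu) / sd
        M_hat = (M_hat - mu) / sd
    sst = float(np.sum(M**2))
    if sst == 0:
        raise ValueError("VAF undefined for an all-zero input matrix")
    return 1.0 - float(np.sum((M - M_hat) ** 2)) / sst


def _unit_columns(W: np.ndarray, what: str) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    norms = np.linalg.norm(W, axis=0)
    if np.any(norms == 0):
        raise ValueError(f"degenerate input: zero-norm {what}")
    return W / norms


def match_components(W_true: np.ndarray, W_est: np.ndarray,
                     greedy: bool = False) -> MatchResult:
    """Pair estimated components to true ones by largest absolute dot product.

    By default the assignment maximizes the total absolute dot product over
    all permutations (Hungarian algorithm); ``greedy=True`` instead pairs
    sequentially by the current largest absolute dot.  Estimates whose matched
    dot is negative have their sign flipped.
    """
    Wt = _unit_columns(W_true, "true synergy column")
    We = _unit_columns(W_est, "estimated synergy column")
    if Wt.shape != We.shape:
        raise ValueError("true and estimated synergy matrices must share a shape")
    k = Wt.shape[1]
    D = Wt.T @ We  # (k_true, k_est)
    absD = np.abs(D)
    perm = np.empty(k, dtype=int)  # estimated j -> true perm[j]
    if greedy:
        A = absD.copy()
        for _ in range(k):
            i, j = np.unravel_index(np.argmax(A), A.shape)
            perm[j] = i
            A[i, :] = -np.inf
            A[:, j] = -np.inf
    else:
        rows, cols = linear_sum_assignment(-absD)
        perm[cols] = rows
    signs = np.where(D[perm, np.arange(k)] < 0, -1.0, 1.0)
    dots_by_true = np.empty(k)
    dots_by_true[perm] = signs * D[perm, np.arange(k)]
    return MatchResult(permutation=perm, signs=signs, matched_dots=dots_by_true)


def synergy_vector_similarity(match: MatchResult) -> float:
    """SVS: mean of the matched, sign-resolved dot products."""
    return float(np.mean(match.matched_dots))


def activation_coefficient_similarity(C_true: np.ndarray, C_est: np.ndarray,
                                      match: MatchResult) -> float:
    """ACS: mean signed dot of unit-normalized coefficient rows, paired and
    sign-flipped exactly as the synergy vectors were."""
    Ct = _unit_columns(np.asarray(C_true, dtype=float).T, "true coefficient row")
    Ce = _unit_columns(np.asarray(C_est, dtype=float).T, "estimated coefficient row")
    k = Ct.shape[1]
    js = np.arange(k)
    dots = np.einsum("ij,ij->j", Ct[:, match.permutation], Ce[:, js]) * match.signs
    return float(np.mean(dots))


def principal_angles(W_true: np.ndarray, W_est: np.ndarray) -> tuple[np.ndarray, float]:
    """Canonical angles (degrees, sorted ascending) between the two column
    spans, and their mean as the scalar summary."""
    Wt = np.asarray(W_true, dtype=float)
    We = np.asarray(W_est, dtype=float)
    k = Wt.shape[1]
    if np.linalg.matrix_rank(Wt) < k or np.linalg.matrix_rank(We) < We.shape[1]:
        raise ValueError("rank-deficient synergy matrix: principal angles undefined")
    ang = np.sort(np.degrees(subspace_angles(Wt, We)))
    return ang, float(np.mean(ang))


def evaluate_trial(trial: SimulatedTrial, result: FactorizationResult,
                   vaf_kwargs: dict | None = None) -> SimilarityReport:
    """Full per-trial report: VAF, matching-based SVS/ACS and principal angles.

    ``vaf_kwargs=None`` selects the method's benchmark convention
    (:data:`VAF_CONVENTIONS`); pass e.g. ``{"centered": False}`` to force a
    single convention across methods.
    """
    if vaf_kwargs is None:
        vaf_kwargs = VAF_CONVENTIONS.get(result.method, {})
    vaf = compute_vaf(trial.M, result.reconstruct(), **vaf_kwargs)
    match = match_components(trial.truth.W, result.W_hat)
    svs = synergy_vector_similarity(match)
    acs = activation_coefficient_similarity(trial.truth.C, result.C_hat, match)
    angles, pa = principal_angles(trial.truth.W, result.W_hat)
    return SimilarityReport(
        vaf=vaf, svs=svs, acs=acs, principal_angles_deg=angles, pa_scalar_deg=pa,
        method=result.method, n_channels=trial.config.n_channels,
        snr_db=trial.config.snr_db, dataset_id=trial.dataset_id,
        trial_id=trial.trial_id,
    )


def chance_similarity(chance_sets: list[GroundTruth], truths: list[GroundTruth],
                      include_acs: bool = True) -> dict:
    """Chance-level similarity between random sets and (independent) truths.

    Pairs are matched exactly as in method evaluation.  Returns mean and SD of
    SVS (and ACS when coefficient rows are present) over the paired sets.
    """
    if len(chance_sets) != len(truths):
        raise ValueError("chance_sets and truths must pair one-to-one")
    if len(chance_sets) < 100:
        raise ValueError("need at least 100 pairs for a chance estimate")
    svs_vals, acs_vals = [], []
    for rand, true in zip(chance_sets, truths):
        match = match_components(true.W, rand.W)
        svs_vals.append(synergy_vector_similarity(match))
        if include_acs and true.C.shape[1] > 1 and rand.C.shape[1] > 1:
            acs_vals.append(
                activation_coefficient_similarity(true.C, rand.C, match)
            )
    out = {
        "svs_mean": float(np.mean(svs_vals)),
        "svs_sd": float(np.std(svs_vals, ddof=1)),
        "n_pairs": len(svs_vals),
    }
    if acs_vals:
        out["acs_mean"] = float(np.mean(acs_vals))
        out["acs_sd"] = float(np.std(acs_vals, ddof=1))
    return out
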