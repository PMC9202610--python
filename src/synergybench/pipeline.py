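"""End-to-end benchmark orchestration (in memory).

Runs the simulation grid through the requested extraction methods, evaluates
every fit against its ground truth and collects a flat results table with one
row per (method, trial).  The column layout is the on-disk results schema:
``method, noc, snr_db, dataset, trial, vaf, svs, acs, pa_deg, seed``.

Factor-analysis settings below the degrees-of-freedom bound are skipped and
recorded in the returned skip list rather than failing the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import factorizers as fz
from .factorizers import fa_degrees_of_freedom
from .metrics import evaluate_trial
from .synthgen import GRID_CHANNELS, GRID_SNRS_DB, SimulationConfig, SimulatedTrial, iter_grid

__all__ = ["SCALE_PRESETS", "ExtractionSettings", "extract_with", "run_benchmark"]

#: datasets x trials-per-dataset presets for desk-scale runs
SCALE_PRESETS = {"tiny": (2, 5), "reduced": (5, 20), "full": (20, 100)}

DEFAULT_METHODS = ("PCA", "ICA", "FA", "NMF", "AE")


@dataclass
class ExtractionSettings:
    """Tunable iteration budgets of the stochastic extractors."""

    nmf_restarts: int = 10
    nmf_max_iter: int = 1000
    nmf_screen_iter: int = 100
    nmf_tol: float = 1e-6
    ica_restarts: int = 5
    ica_max_iter: int = 1000
    ica_tol: float = 1e-6
    ae_max_iter: int = 400
    ae_l2: float = 1e-3
    ae_sparsity_weight: float = 1.0
    ae_sparsity_target: float = 0.05


def _trial_seed(root_seed: int, *key: int) -> int:
    """Stable per-trial integer seed (< 2^31) derived from the root seed."""
    return int(np.random.SeedSequence(root_seed, spawn_key=key).generate_state(1)[0] % (2**31))


def extract_with(method: str, M: np.ndarray, k: int, seed: int,
                 settings: ExtractionSettings | None = None) -> fz.FactorizationResult:
    """Run one extraction method on one muscles-by-time matrix."""
    s = settings or ExtractionSettings()
    method = method.upper()
    if method == "PCA":
        return fz.extract_pca(M, k)
    if method == "ICA":
        return fz.extract_ica(M, k, seed=seed, tol=s.ica_tol,
                              max_iter=s.ica_max_iter, n_restarts=s.ica_restarts)
    if method == "FA":
        return fz.extract_fa(M, k)
    if method == "NMF":
        return fz.extract_nmf(M, k, seed=seed, tol=s.nmf_tol,
                              max_iter=s.nmf_max_iter, n_restarts=s.nmf_restarts,
                              screen_iter=s.nmf_screen_iter)
    if method == "AE":
        result, _params = fz.extract_ae(
            M, k, seed=seed, l2=s.ae_l2, sparsity_weight=s.ae_sparsity_weight,
            sparsity_target=s.ae_sparsity_target, max_iter=s.ae_max_iter)
        return result
    raise ValueError(f"unknown method {method!r}; expected one of {DEFAULT_METHODS}")


def evaluate_methods(trial: SimulatedTrial, methods: Sequence[str], root_seed: int,
                     settings: ExtractionSettings | None = None,
                     skips: list | None = None) -> list[dict]:
    """Rows of the results table for one trial across the requested methods."""
    rows = []
    cfg = trial.config
    k = cfg.n_synergies
    for mi, method in enumerate(methods):
        method = method.upper()
        if method == "FA" and fa_degrees_of_freedom(cfg.n_channels, k) <= 0:
            if skips is not None:
                skips.append({"method": method, "noc": cfg.n_channels,
                              "snr_db": cfg.snr_db, "dataset": trial.dataset_id,
                              "trial": trial.trial_id,
                              "reason": "degrees-of-freedom bound violated"})
            continue
        seed = _trial_seed(root_seed, mi, cfg.n_channels, int(cfg.snr_db),
                           trial.dataset_id, trial.trial_id)
        result = extract_with(method, trial.M, k, seed, settings)
        rep = evaluate_trial(trial, result)
        rows.append({
            "method": method, "noc": cfg.n_channels, "snr_db": cfg.snr_db,
            "dataset": trial.dataset_id, "trial": trial.trial_id,
            "vaf": rep.vaf, "svs": rep.svs, "acs": rep.acs,
            "pa_deg": rep.pa_scalar_deg, "seed": seed,
        })
    return rows


def run_benchmark(
    seed: int = 0,
    scale: str = "tiny",
    methods: Sequence[str] = DEFAULT_METHODS,
    channels: Sequence[int] = GRID_CHANNELS,
    snrs_db: Sequence[float] = GRID_SNRS_DB,
    n_synergies: int = 4,
    n_samples: int = 1000,
    settings: ExtractionSettings | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate the grid at the given scale and evaluate every method.

    Returns the flat results table and the list of skipped (infeasible)
    extractions.
    """
    n_datasets, n_trials = SCALE_PRESETS[scale]
    template = SimulationConfig(
        n_synergies=n_synergies, n_samples=n_samples,
        n_datasets=n_datasets, n_trials_per_dataset=n_trials, seed=seed,
    )
    rows: list[dict] = []
    skips: list[dict] = []
    for trial in iter_grid(template, channels=channels, snrs_db=snrs_db):
        rows.extend(evaluate_methods(trial, methods, seed, settings, skips))
    return pd.DataFrame(rows), skips
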