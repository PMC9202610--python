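"""Ground-truth generation for the synergy-extraction benchmark.

Simulated muscle activations follow the spatial (time-invariant) synergy
model: an ``m x n`` activation matrix is built as ``M = g(W @ C + e)`` where
``W`` (``m x k``, non-negative, unit-norm columns) holds the synergy vectors,
``C`` (``k x n``, rows in [0, 1]) holds the activation coefficients, ``e`` is
i.i.d. zero-mean Gaussian noise scaled to a requested SNR, and ``g`` is the
half-wave threshold ``g(x) = max(x, 0)`` that keeps the data non-negative.

Synergy vectors are drawn from an exponential distribution (mean 10) and
column-normalized.  Activation coefficients emulate preprocessed surface-EMG
envelopes: rectified low-pass-filtered Gaussian noise with a small number of
randomized activity bursts, passed through a moving-RMS (window 100 samples,
75% overlap), resampled to 1,000 points and min-max normalized to [0, 1].

All randomness flows from one root seed through named substreams so every
artifact of a run is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedTrial",
    "MovementDataset",
    "sample_synergy_matrix",
    "synthesize_raw_envelope",
    "preprocess_envelope",
    "noise_power_for_snr",
    "compose_trial",
    "generate_grid",
    "iter_grid",
    "generate_chance_sets",
    "make_movement_dataset",
]

#: channel counts and SNR levels of the full benchmark grid
GRID_CHANNELS = (6, 8, 10, 12)
GRID_SNRS_DB = (10.0, 15.0, 20.0)

#: scale of the exponential distribution the synergy entries are drawn from.
#: Irrelevant after unit-normalization of the columns; kept for fidelity to
#: the generative recipe the benchmark states.
EXPONENTIAL_MEAN = 10.0

#: moving-RMS window (samples) and overlap fraction of the envelope chain
RMS_WINDOW = 100
RMS_OVERLAP = 0.75
ENVELOPE_LENGTH = 1000

#: normalized low-pass cutoff (fraction of Nyquist) of the envelope smoother
ENVELOPE_CUTOFF = 0.05
#: default raw length synthesized per envelope before preprocessing
DEFAULT_N_RAW = 4000

# named substreams hanging off the root seed
_STREAMS = {"synergy": 0, "envelope": 1, "noise": 2, "chance": 3, "movement": 4}


@lru_cache(maxsize=8)
def _butter_cached(order: int, wn: float):
    return sps.butter(order, wn)


def substream(seed: int, stream: str, *key: int) -> np.random.Generator:
    """Independent, named, index-addressable random stream under one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], *key))
    )


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one cell of the simulation grid.

    Parameters mirror the benchmark's study conditions: ``n_channels`` is the
    number of muscles m, ``snr_db`` the additive-noise level in decibels,
    ``n_synergies`` the ground-truth rank k (fixed at 4 in the benchmark),
    ``n_samples`` the trial length n, and ``n_datasets``/``n_trials_per_dataset``
    the replication structure (one synergy matrix per dataset, fresh
    coefficients and noise per trial).
    """

    n_channels: int = 10
    snr_db: float = 15.0
    n_synergies: int = 4
    n_samples: int = 1000
    n_datasets: int = 20
    n_trials_per_dataset: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < self.n_synergies:
            raise ValueError(
                f"n_channels ({self.n_channels}) must be >= n_synergies "
                f"({self.n_synergies})"
            )
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in ("n_channels", "n_synergies", "n_datasets", "n_trials_per_dataset"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """True synergy matrix W (m x k, unit-norm columns) and coefficients C (k x n)."""

    W: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        if self.W.ndim != 2 or self.C.ndim != 2 or self.W.shape[1] != self.C.shape[0]:
            raise ValueError("W (m x k) and C (k x n) have inconsistent shapes")


@dataclass(frozen=True)
class SimulatedTrial:
    """One noisy simulated activation matrix with its provenance."""

    M: np.ndarray
    truth: GroundTruth
    config: SimulationConfig
    dataset_id: int
    trial_id: int
    realized_snr_db: float


@dataclass(frozen=True)
class MovementDataset:
    """Synthetic wrist-movement trials for the classification stage.

    Emulates the structure of a 6-class wrist-movement problem recorded from
    10 forearm muscles (supination/pronation, flexion/extension,
    radial/ulnar deviation; two directions per degree of freedom).
    """

    trials: list  # of (envelope matrix [10 x T], label in 1..6, repetition id)
    class_templates: np.ndarray  # (6, n_channels), unit-norm rows
    noise_sd: float


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------


def sample_synergy_matrix(m: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an ``m x k`` non-negative synergy matrix with unit-norm columns.

    Entries are exponential with mean :data:`EXPONENTIAL_MEAN`; each column is
    then scaled to unit Euclidean norm.
    """
    if not (m >= k >= 1):
        raise ValueError(f"need m >= k >= 1, got m={m}, k={k}")
    W = rng.exponential(scale=EXPONENTIAL_MEAN, size=(m, k))
    return W / np.linalg.norm(W, axis=0, keepdims=True)


def _raw_envelopes(n_signals: int, n_raw: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized bank of raw EMG-like envelope signals, shape (n_signals, n_raw).

    Recipe: white Gaussian noise -> 4th-order Butterworth low-pass
    (zero-phase) -> full-wave rectification -> second low-pass at the
    configured envelope cutoff -> multiplication by a randomized burst
    profile (2-5 Gaussian bumps over a small tonic baseline).
    """
    if n_raw < 500:
        raise ValueError(f"n_raw must be >= 500, got {n_raw}")
    x = rng.standard_normal((n_signals, n_raw))
    # mildly band-limit the carrier, then rectify and smooth into an envelope
    b1, a1 = _butter_cached(4, 0.3)
    carrier = sps.filtfilt(b1, a1, x, axis=-1)
    b2, a2 = _butter_cached(4, ENVELOPE_CUTOFF)
    env = sps.filtfilt(b2, a2, np.abs(carrier), axis=-1)
    env = np.maximum(env, 0.0)  # filtfilt may undershoot slightly

    t = np.arange(n_raw)
    bursts = np.empty_like(env)
    for i in range(n_signals):
        n_bursts = int(rng.integers(2, 6))
        centers = rng.uniform(0, n_raw, size=n_bursts)
        widths = rng.uniform(n_raw / 20, n_raw / 6, size=n_bursts)
        amps = rng.uniform(0.5, 2.0, size=n_bursts)
        prof = 0.1 + np.sum(
            amps[:, None] * np.exp(-0.5 * ((t[None, :] - centers[:, None]) / widths[:, None]) ** 2),
            axis=0,
        )
        bursts[i] = prof
    return env * bursts


def synthesize_raw_envelope(n_raw: int, rng: np.random.Generator) -> np.ndarray:
    """One raw non-negative, band-limited, burst-like envelope signal (length n_raw)."""
    return _raw_envelopes(1, n_raw, rng)[0]


def moving_rms(x: np.ndarray, window: int = RMS_WINDOW, overlap: float = RMS_OVERLAP) -> np.ndarray:
    """Moving root-mean-square over full windows only.

    ``overlap`` is the fraction of the window shared by consecutive windows,
    so the hop is ``window * (1 - overlap)`` samples.  Works on the last axis.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < window:
        raise ValueError(f"input length {n} shorter than RMS window {window}")
    step = max(int(round(window * (1.0 - overlap))), 1)
    csum = np.cumsum(x**2, axis=-1)
    csum = np.concatenate([np.zeros((*x.shape[:-1], 1)), csum], axis=-1)
    starts = np.arange(0, n - window + 1, step)
    sq = (csum[..., starts + window] - csum[..., starts]) / window
    return np.sqrt(np.maximum(sq, 0.0))


def preprocess_envelope(sig: np.ndarray) -> np.ndarray:
    """Benchmark preprocessing chain: moving RMS -> resample to 1000 -> min-max.

    Returns a length-1000 row with min exactly 0 and max exactly 1.  Raises on
    constant input (the min-max step would be degenerate).
    """
    sig = np.atleast_2d(np.asarray(sig, dtype=float))
    rms = moving_rms(sig)
    n_win = rms.shape[-1]
    grid = np.linspace(0.0, n_win - 1.0, ENVELOPE_LENGTH)
    out = np.empty((rms.shape[0], ENVELOPE_LENGTH))
    for i in range(rms.shape[0]):
        out[i] = np.interp(grid, np.arange(n_win), rms[i])
    lo = out.min(axis=-1, keepdims=True)
    hi = out.max(axis=-1, keepdims=True)
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate (constant) envelope: min-max normalization undefined")
    out = (out - lo) / (hi - lo)
    return out[0] if out.shape[0] == 1 and sig.shape[0] == 1 else out


def sample_coefficients(k: int, rng: np.random.Generator, n_raw: int = DEFAULT_N_RAW) -> np.ndarray:
    """k fresh preprocessed activation-coefficient rows, shape (k, 1000)."""
    raw = _raw_envelopes(k, n_raw, rng)
    return np.atleast_2d(preprocess_envelope(raw))


def noise_power_for_snr(signal_power: float, snr_db: float) -> float:
    """Noise power P_n with SNR = 10 * log10(P_s / P_n)."""
    if signal_power <= 0:
        raise ValueError("signal power must be positive")
    return signal_power / 10.0 ** (snr_db / 10.0)


def compose_trial(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    dataset_id: int = 0,
    trial_id: int = 0,
) -> SimulatedTrial:
    """Assemble one noisy trial ``M = g(W @ C + e)`` at the configured SNR.

    Signal power is measured globally over ``W @ C``; the realized SNR (from
    the actually drawn noise) is recorded on the trial.
    """
    W, C = truth.W, truth.C
    if W.shape != (config.n_channels, config.n_synergies) or C.shape[1] != config.n_samples:
        raise ValueError("ground-truth shapes do not match the configuration")
    clean = W @ C
    ps = float(np.mean(clean**2))
    pn = noise_power_for_snr(ps, config.snr_db)
    e = rng.normal(0.0, np.sqrt(pn), size=clean.shape)
    M = np.maximum(clean + e, 0.0)
    realized = 10.0 * np.log10(ps / float(np.mean(e**2)))
    return SimulatedTrial(M=M, truth=truth, config=config, dataset_id=dataset_id,
                          trial_id=trial_id, realized_snr_db=realized)


# ---------------------------------------------------------------------------
# grid, chance baseline, movement dataset
# ---------------------------------------------------------------------------


def iter_grid(
    template: SimulationConfig,
    channels: Sequence[int] = GRID_CHANNELS,
    snrs_db: Sequence[float] = GRID_SNRS_DB,
) -> Iterator[SimulatedTrial]:
    """Lazily yield every trial of the (channels x SNR) benchmark grid.

    One synergy matrix W is drawn per dataset; each trial within a dataset
    gets fresh coefficient envelopes and fresh noise.  Substreams are keyed by
    (setting, dataset, trial), so the stream is independent of consumption
    order and reproducible under a fixed ``template.seed``.
    """
    seed = template.seed
    for ci, m in enumerate(channels):
        for si, snr in enumerate(snrs_db):
            cfg = replace(template, n_channels=int(m), snr_db=float(snr))
            for d in range(cfg.n_datasets):
                W = sample_synergy_matrix(
                    cfg.n_channels, cfg.n_synergies, substream(seed, "synergy", ci, si, d)
                )
                for t in range(cfg.n_trials_per_dataset):
                    C = sample_coefficients(
                        cfg.n_synergies, substream(seed, "envelope", ci, si, d, t)
                    )
                    truth = GroundTruth(W=W, C=C)
                    yield compose_trial(
                        truth, cfg, substream(seed, "noise", ci, si, d, t),
                        dataset_id=d, trial_id=t,
                    )


def generate_grid(
    template: SimulationConfig,
    channels: Sequence[int] = GRID_CHANNELS,
    snrs_db: Sequence[float] = GRID_SNRS_DB,
) -> list[SimulatedTrial]:
    """Materialize the full grid (see :func:`iter_grid`) as a list."""
    return list(iter_grid(template, channels, snrs_db))


def generate_chance_sets(
    config: SimulationConfig,
    n_sets: int,
    rng_seed: int | None = None,
    channels: Sequence[int] = GRID_CHANNELS,
    include_coefficients: bool = True,
) -> list[GroundTruth]:
    """Random synergy/coefficient sets under the same generative constraints.

    Used as the chance baseline: each set is an independent draw of a
    unit-norm exponential synergy matrix (channel count cycling through the
    grid's settings) plus, optionally, fresh preprocessed envelopes.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    seed = config.seed if rng_seed is None else rng_seed
    sets = []
    for i in range(n_sets):
        m = int(channels[i % len(channels)])
        rng = substream(seed, "chance", i)
        W = sample_synergy_matrix(m, config.n_synergies, rng)
        if include_coefficients:
            C = sample_coefficients(config.n_synergies, rng)
        else:
            C = np.zeros((config.n_synergies, 1))
        sets.append(GroundTruth(W=W, C=C))
    return sets


def _movement_templates(rng: np.random.Generator, n_channels: int = 10,
                        max_dot: float = 0.8) -> np.ndarray:
    """Six unit-norm, non-negative class templates with pairwise dot <= max_dot."""
    for _ in range(1000):
        T = sample_synergy_matrix(n_channels, 6, rng).T  # rows are templates
        G = T @ T.T
        if np.max(G - np.eye(6)) <= max_dot:
            return T
    raise RuntimeError("could not sample sufficiently distinct class templates")


def make_movement_dataset(
    n_reps_per_class: int,
    noise_sd: float,
    rng: np.random.Generator,
    templates: np.ndarray | None = None,
    n_channels: int = 10,
    n_samples: int = 400,
    mode_mix: float = 1.5,
    jitter_sd: float = 0.05,
) -> MovementDataset:
    """Synthetic 6-class wrist-movement dataset (10 channels by default).

    Each trial is rank one: a class synergy template (outer product with a
    fresh envelope) plus Gaussian noise, thresholded at zero.  Two sources of
    repetition-to-repetition variability emulate real recordings: each class
    alternates between two sub-templates pulled toward its neighbouring
    classes by ``mode_mix`` (posture/strategy changes; bimodal classes), and
    every trial perturbs its template with non-negative-projected Gaussian
    jitter of scale ``jitter_sd`` (electrode/motor variability).  Set both to
    0 for perfectly separable classes.
    """
    if n_reps_per_class < 2:
        raise ValueError("n_reps_per_class must be >= 2")
    if templates is None:
        templates = _movement_templates(rng, n_channels)
    templates = np.asarray(templates, dtype=float)
    n_classes = templates.shape[0]

    trials = []
    for label in range(1, n_classes + 1):
        u = templates[label - 1]
        nb = templates[label % n_classes]
        pb = templates[(label - 2) % n_classes]
        modes = []
        for v in (nb, pb):
            w = np.maximum(u + mode_mix * v, 0.0)
            modes.append(w / np.linalg.norm(w))
        for rep in range(n_reps_per_class):
            w = modes[rep % 2]
            if jitter_sd > 0:
                w = np.maximum(w + jitter_sd * rng.standard_normal(w.shape), 0.0)
                nrm = np.linalg.norm(w)
                w = modes[rep % 2] if nrm == 0 else w / nrm
            env = preprocess_envelope(synthesize_raw_envelope(DEFAULT_N_RAW, rng))
            env = np.interp(
                np.linspace(0, env.size - 1, n_samples), np.arange(env.size), env
            )
            M = np.outer(w, env)
            if noise_sd > 0:
                M = M + rng.normal(0.0, noise_sd, size=M.shape)
            trials.append((np.maximum(M, 0.0), label, rep))
    return MovementDataset(trials=trials, class_templates=templates, noise_sd=noise_sd)
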