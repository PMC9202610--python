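import numpy as np
import pytest

import synergybench as sb


def make_separated_truth(m: int, k: int, seed: int, max_dot: float = 0.3):
    """Well-separated ground truth: non-negative unit-norm synergies with
    pairwise dot below ``max_dot`` (each synergy dominated by its own block
    of muscles, as real synergies are) and fresh preprocessed envelopes."""
    rng = np.random.default_rng(seed)
    W = 0.05 * rng.exponential(1.0, size=(m, k))
    blocks = np.array_split(rng.permutation(m), k)
    for j, idx in enumerate(blocks):
        W[idx, j] += rng.exponential(1.0, size=len(idx)) + 0.5
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    G = np.abs(W.T @ W) - np.eye(k)
    assert G.max() < max_dot, "block construction should separate synergies"
    from synergybench.synthgen import sample_coefficients

    C = sample_coefficients(k, rng)
    return sb.GroundTruth(W=W, C=C)


def make_noiseless_trial(m: int = 10, k: int = 4, seed: int = 0, n: int = 1000):
    """A trial with zero noise (M = W C exactly)."""
    truth = make_separated_truth(m, k, seed)
    cfg = sb.SimulationConfig(n_channels=m, n_synergies=k, n_samples=n,
                              n_datasets=1, n_trials_per_dataset=1, seed=seed)
    return sb.SimulatedTrial(M=truth.W @ truth.C, truth=truth, config=cfg,
                             dataset_id=0, trial_id=0,
                             realized_snr_db=float("inf"))


@pytest.fixture(scope="session")
def noiseless_trial():
    return make_noiseless_trial(seed=42)


@pytest.fixture(scope="session")
def noisy_trial():
    """One seeded 10-channel, 15 dB trial of the standard grid."""
    cfg = sb.SimulationConfig(n_channels=10, snr_db=15.0, n_datasets=1,
                              n_trials_per_dataset=1, seed=7)
    return sb.generate_grid(cfg, channels=[10], snrs_db=[15.0])[0]
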