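"""Plain-text persistence: trials, factorization results, manifests.

Matrices are stored as headerless CSV; provenance travels in JSON sidecars.
Grid layout: ``grid/<noc>ch_<snr>db/dataset<D>/`` holding the dataset's
``W.csv`` plus per-trial ``trial<T>.csv`` (the activation matrix M) and
``trial<T>_C.csv`` (the true coefficients), with a grid-level
``config.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .factorizers import FactorizationResult
from .synthgen import GroundTruth, SimulatedTrial, SimulationConfig

__all__ = [
    "save_matrix",
    "load_matrix",
    "setting_dir",
    "save_trial",
    "load_trial",
    "save_result",
    "load_result",
    "write_manifest",
]

RESULT_COLUMNS = ["method", "noc", "snr_db", "dataset", "trial",
                  "vaf", "svs", "acs", "pa_deg", "seed"]


def save_matrix(path: Path, M: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(M), delimiter=",")


def load_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def setting_dir(root: Path, noc: int, snr_db: float) -> Path:
    return Path(root) / f"{noc}ch_{snr_db:g}db"


def save_trial(root: Path, trial: SimulatedTrial) -> Path:
    """Persist one trial under the grid layout; returns the dataset directory."""
    ddir = setting_dir(root, trial.config.n_channels, trial.config.snr_db) / (
        f"dataset{trial.dataset_id}"
    )
    ddir.mkdir(parents=True, exist_ok=True)
    wpath = ddir / "W.csv"
    if not wpath.exists():
        save_matrix(wpath, trial.truth.W)
    save_matrix(ddir / f"trial{trial.trial_id}.csv", trial.M)
    save_matrix(ddir / f"trial{trial.trial_id}_C.csv", trial.truth.C)
    meta = ddir / f"trial{trial.trial_id}.json"
    meta.write_text(json.dumps({
        "config": dataclasses.asdict(trial.config),
        "dataset_id": trial.dataset_id,
        "trial_id": trial.trial_id,
        "realized_snr_db": trial.realized_snr_db,
    }, indent=1))
    return ddir


def load_trial(root: Path, noc: int, snr_db: float, dataset_id: int,
               trial_id: int) -> SimulatedTrial:
    ddir = setting_dir(root, noc, snr_db) / f"dataset{dataset_id}"
    meta = json.loads((ddir / f"trial{trial_id}.json").read_text())
    cfg = SimulationConfig(**meta["config"])
    truth = GroundTruth(W=load_matrix(ddir / "W.csv"),
                        C=load_matrix(ddir / f"trial{trial_id}_C.csv"))
    return SimulatedTrial(
        M=load_matrix(ddir / f"trial{trial_id}.csv"), truth=truth, config=cfg,
        dataset_id=dataset_id, trial_id=trial_id,
        realized_snr_db=meta["realized_snr_db"],
    )


def iter_saved_trials(root: Path):
    """Yield every trial stored under a grid directory."""
    root = Path(root)
    for meta_path in sorted(root.glob("*ch_*db/dataset*/trial*.json")):
        meta = json.loads(meta_path.read_text())
        cfg = meta["config"]
        yield load_trial(root, cfg["n_channels"], cfg["snr_db"],
                         meta["dataset_id"], meta["trial_id"])


def save_result(outdir: Path, result: FactorizationResult) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_matrix(outdir / "W.csv", result.W_hat)
    save_matrix(outdir / "C.csv", result.C_hat)
    save_matrix(outdir / "offset.csv", result.offset)
    (outdir / "meta.json").write_text(json.dumps({
        "method": result.method, "seed": result.seed,
        "n_iter": result.n_iter, "objective": result.objective,
    }, indent=1))
    return outdir


def load_result(outdir: Path) -> FactorizationResult:
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    return FactorizationResult(
        method=meta["method"], W_hat=load_matrix(outdir / "W.csv"),
        C_hat=load_matrix(outdir / "C.csv"),
        offset=load_matrix(outdir / "offset.csv").ravel(),
        n_iter=meta["n_iter"], objective=meta["objective"], seed=meta["seed"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(root: Path, config: dict, seed: int,
                   version: str = "unknown") -> Path:
    """Run manifest: config snapshot, root seed and a content hash per file."""
    root = Path(root)
    files = {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {"config": config, "seed": seed, "tool_version": version,
                "files": files}
    out = root / "manifest.json"
    out.write_text(json.dumps(manifest, indent=1))
    return out


def append_results(path: Path, df: pd.DataFrame) -> None:
    """Append rows to the flat results CSV, writing the header once."""
    path = Path(path)
    df = df[RESULT_COLUMNS]
    df.to_csv(path, mode="a", header=not path.exists(), index=False)
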