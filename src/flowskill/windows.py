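"""Sliding-window sample assembly for multivariate time-series classification.

Feature matrices (one per video) are cut into uniformly sized W×240 windows
with stride S; windows never span two videos, and each keeps its source
trial's (subject, task, trial, skill) keys so leave-one-super-trial-out
folds can be formed downstream.  Trailing rows not covered by a full window
are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TWO_CLASS = "two_class"
THREE_CLASS = "three_class"


@dataclass(frozen=True)
class WindowParams:
    window_size: int = 60
    step: int = 30

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def tag(self) -> str:
        """Filename tag, e.g. '60x30' (window-size x step-size)."""
        return f"{self.window_size}x{self.step}"


def slide(matrix: np.ndarray, params: WindowParams) -> np.ndarray:
    """Cut (L, D) into windows starting at 0, S, 2S, …; shape (n, W, D).

    n = floor((L − W) / S) + 1.
    """
    matrix = np.asarray(matrix)
    L = matrix.shape[0]
    W, S = params.window_size, params.step
    if L < W:
        raise ValueError(f"matrix has {L} rows, shorter than window size {W}")
    n = (L - W) // S + 1
    return np.stack([matrix[i * S : i * S + W] for i in range(n)])


@dataclass
class WindowedDataset:
    """Uniform W×D samples with per-sample provenance labels."""

    X: np.ndarray  # (n_samples, W, D)
    skill: np.ndarray  # str labels
    subject: np.ndarray
    trial: np.ndarray  # int trial indices
    task: np.ndarray
    class_mode: str = THREE_CLASS

    def __post_init__(self) -> None:
        n = len(self.X)
        for name in ("skill", "subject", "trial", "task"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_samples {n}")
            setattr(self, name, arr)
        allowed = {"novice", "expert"} if self.class_mode == TWO_CLASS else set(
            ("novice", "intermediate", "expert")
        )
        bad = set(np.unique(self.skill)) - allowed
        if bad:
            raise ValueError(f"labels {bad} not allowed in {self.class_mode} mode")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, mask: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(self.X[mask], self.skill[mask], self.subject[mask],
                               self.trial[mask], self.task[mask], self.class_mode)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, X=self.X)
        idx = pd.DataFrame(dict(subject=self.subject, task=self.task,
                                trial=self.trial, skill=self.skill))
        idx.to_csv(path.with_suffix(".index.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path, class_mode: str = THREE_CLASS) -> "WindowedDataset":
        path = Path(path)
        X = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))["X"]
        idx = pd.read_csv(path.with_suffix(".index.csv"))
        return cls(X, idx["skill"].to_numpy(), idx["subject"].to_numpy(),
                   idx["trial"].to_numpy(), idx["task"].to_numpy(), class_mode)


def assemble(
    manifest: pd.DataFrame,
    features: dict | str | Path,
    params: WindowParams,
    class_mode: str = THREE_CLASS,
) -> dict[str, WindowedDataset]:
    """Group windowed samples by task, applying the class-mode label policy.

    ``features`` maps (subject, task, trial) → (L, D) array, or is a
    directory of ``<subject>_<task>_T<trial>.csv`` files written by the
    extraction stage.  In two-class mode intermediate subjects are dropped
    entirely.  Returns one dataset per task.
    """
    if class_mode not in (TWO_CLASS, THREE_CLASS):
        raise ValueError(f"unknown class_mode {class_mode!r}")
    if manifest["skill"].isna().any():
        missing = manifest.loc[manifest["skill"].isna(), "subject"].tolist()
        raise ValueError(f"missing skill label for subjects {missing}")

    def lookup(row) -> np.ndarray:
        key = (row["subject"], row["task"], int(row["trial"]))
        if isinstance(features, dict):
            if key not in features:
                raise KeyError(f"no feature matrix for {key}")
            return np.asarray(features[key])
        p = Path(features) / f"{row['subject']}_{row['task']}_T{row['trial']}.csv"
        if not p.exists():
            raise FileNotFoundError(str(p))
        return pd.read_csv(p).to_numpy(dtype=float)

    out: dict[str, WindowedDataset] = {}
    for task, group in manifest.groupby("task", sort=True):
        xs, sk, su, tr, ta = [], [], [], [], []
        for _, row in group.iterrows():
            if class_mode == TWO_CLASS and row["skill"] == "intermediate":
                continue
            wins = slide(lookup(row), params)
            xs.append(wins)
            sk += [row["skill"]] * len(wins)
            su += [row["subject"]] * len(wins)
            tr += [int(row["trial"])] * len(wins)
            ta += [task] * len(wins)
        if not xs:
            continue
        out[str(task)] = WindowedDataset(
            np.concatenate(xs), np.array(sk), np.array(su), np.array(tr), np.array(ta),
            class_mode,
        )
    return out
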