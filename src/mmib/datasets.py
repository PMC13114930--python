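"""In-memory containers for multimodal and longitudinal tabular data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class MultimodalDataset:
    """Aligned per-modality feature matrices plus a categorical label vector.

    Parameters
    ----------
    modalities
        Ordered mapping ``name -> (n_samples, d_i)`` float matrix.  All
        matrices share row count and row order.
    labels
        Integer class indices, length ``n_samples``.
    split
        Optional boolean test mask (True = test sample).
    metadata
        Free-form provenance (generator config, ground-truth structure, seed).
    """

    modalities: dict[str, np.ndarray]
    labels: np.ndarray
    split: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modalities = {
            k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in self.modalities.items()
        }
        self.labels = np.asarray(self.labels).astype(int)
        n = self.labels.shape[0]
        for name, x in self.modalities.items():
            if x.shape[0] != n:
                raise ValueError(f"modality {name!r} has {x.shape[0]} rows, expected {n}")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"modality {name!r} contains non-finite values")
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=bool)
            if self.split.shape[0] != n:
                raise ValueError("split mask length mismatch")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def modality_names(self) -> list[str]:
        return list(self.modalities)

    @property
    def dims(self) -> dict[str, int]:
        return {k: v.shape[1] for k, v in self.modalities.items()}

    def subset_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Column-concatenated features of the named modalities (all by default)."""
        names = list(names) if names is not None else self.modality_names
        missing = [n for n in names if n not in self.modalities]
        if missing:
            raise KeyError(f"unknown modalities: {missing}")
        return np.hstack([self.modalities[n] for n in names])

    def take(self, idx: np.ndarray) -> "MultimodalDataset":
        return MultimodalDataset(
            {k: v[idx] for k, v in self.modalities.items()},
            self.labels[idx],
            None if self.split is None else self.split[idx],
            dict(self.metadata),
        )

    def train_test(self) -> tuple["MultimodalDataset", "MultimodalDataset"]:
        if self.split is None:
            raise ValueError("dataset has no train/test split assigned")
        return self.take(~self.split), self.take(self.split)

    def with_split(self, test_fraction: float, seed: int, stratify: bool = True) -> "MultimodalDataset":
        """Return a copy with a fresh (stratified) train/test split mask."""
        rng = np.random.default_rng(seed)
        mask = np.zeros(self.n_samples, dtype=bool)
        if stratify:
            for c in np.unique(self.labels):
                idx = np.flatnonzero(self.labels == c)
                rng.shuffle(idx)
                n_test = max(1, int(round(test_fraction * idx.size)))
                mask[idx[:n_test]] = True
        else:
            idx = rng.permutation(self.n_samples)
            mask[idx[: int(round(test_fraction * self.n_samples))]] = True
        out = MultimodalDataset(self.modalities, self.labels, mask, dict(self.metadata))
        return out


@dataclass
class LongitudinalDataset:
    """Long-format longitudinal records: one row per (subject, visit).

    ``records`` holds columns ``subject``, ``visit``, one column per modality,
    and ``target``.  Visit indices must be strictly increasing within subject;
    history/target pairs are only ever formed within a subject.
    """

    records: pd.DataFrame
    modality_columns: list[str]
    target_column: str = "target"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"subject", "visit", self.target_column, *self.modality_columns}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        self.records = self.records.sort_values(["subject", "visit"]).reset_index(drop=True)
        for _, g in self.records.groupby("subject"):
            v = g["visit"].to_numpy()
            if np.any(np.diff(v) <= 0):
                raise ValueError("visit indices must be strictly increasing within subject")

    @property
    def n_subjects(self) -> int:
        return self.records["subject"].nunique()

    def consecutive_pairs(
        self,
        source_columns: Iterable[str],
        k: int = 1,
        ell: int = 1,
    ) -> pd.DataFrame:
        """History/target pairs within subjects.

        For each visit t with at least ``max(k, ell)`` predecessors, emits the
        source history ``<col>_lag1..k``, target history ``target_lag1..ell``,
        the current target ``target_now``, subject id, and current-visit
        modality values.
        """
        if k < 1 or ell < 1:
            raise ValueError("lag orders k and ell must be >= 1")
        source_columns = list(source_columns)
        lag = max(k, ell)
        rows = []
        for subj, g in self.records.groupby("subject"):
            g = g.reset_index(drop=True)
            for t in range(lag, len(g)):
                row: dict = {"subject": subj, "visit": g.loc[t, "visit"]}
                for j in range(1, k + 1):
                    for c in source_columns:
                        row[f"{c}_lag{j}"] = g.loc[t - j, c]
                for j in range(1, ell + 1):
                    row[f"target_lag{j}"] = g.loc[t - j, self.target_column]
                for c in self.modality_columns:
                    row[c] = g.loc[t, c]
                row["target_now"] = g.loc[t, self.target_column]
                rows.append(row)
        return pd.DataFrame(rows)
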