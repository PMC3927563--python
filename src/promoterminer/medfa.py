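"""Main-effect-difference (MED) factor analysis.

Quantifies each selected descriptor's contribution to classification
accuracy with a two-level orthogonal experimental design: the two levels
of a factor are inclusion and exclusion of the feature.  Each design row
is scored by cross-validated SVM accuracy on the included columns, and a
feature's MED is the absolute difference between the mean fitness of rows
including it and of rows excluding it, in percentage points of accuracy.
The most effective feature has the largest MED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._oa import two_level_oa
from .model import cv_accuracy

#: fitness assigned to a design row that includes no feature at all
EMPTY_ROW_FITNESS = 0.5


@dataclass
class MEDConfig:
    C: float = 1.0
    gamma: float = 1.0
    cv_folds: int = 5
    seed: int = 0


@dataclass
class MEDReport:
    feature_names: list[str]
    med: np.ndarray          # percentage points, >= 0
    config: MEDConfig
    n_rows: int              # design rows evaluated

    def ranking(self) -> list[int]:
        """Feature indices by descending MED (ties by index)."""
        return sorted(range(len(self.feature_names)),
                      key=lambda j: (-self.med[j], j))

    def to_frame(self, top_k: int | None = None) -> pd.DataFrame:
        order = self.ranking()
        if top_k is not None:
            order = order[:top_k]
        return pd.DataFrame({
            "rank": np.arange(1, len(order) + 1),
            "descriptor": [self.feature_names[j] for j in order],
            "MED": [self.med[j] for j in order],
        })

    def to_tsv(self, path: str | Path, top_k: int | None = None) -> None:
        self.to_frame(top_k).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, config: MEDConfig | None = None
                 ) -> "MEDReport":
        df = pd.read_csv(path, sep="\t")
        order = np.argsort(df["rank"].to_numpy())
        names = df["descriptor"].astype(str).to_numpy()[order].tolist()
        med = df["MED"].to_numpy(dtype=float)[order]
        return cls(names, med, config or MEDConfig(), n_rows=0)


def _design_fitness(X: np.ndarray, y: np.ndarray, design: np.ndarray,
                    config: MEDConfig) -> np.ndarray:
    fits = np.empty(design.shape[0])
    for i, row in enumerate(design):
        included = np.flatnonzero(row)
        if included.size == 0:
            fits[i] = EMPTY_ROW_FITNESS
        else:
            fits[i] = cv_accuracy(X[:, included], y, config.C, config.gamma,
                                  folds=config.cv_folds, seed=config.seed)
    return fits


def _med_from_design(design: np.ndarray, fits: np.ndarray) -> np.ndarray:
    med = np.empty(design.shape[1])
    for j in range(design.shape[1]):
        incl = fits[design[:, j] == 1].mean()
        excl = fits[design[:, j] == 0].mean()
        med[j] = abs(incl - excl) * 100.0
    return med


def compute_med(X: np.ndarray, y: np.ndarray,
                mask: np.ndarray | Sequence[int],
                feature_names: Sequence[str] | None = None,
                config: MEDConfig | None = None) -> MEDReport:
    """MED for each feature in ``mask`` using the smallest two-level
    orthogonal array with at least that many factor columns.

    Level 1 of factor j includes feature j; level 0 excludes it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mask = np.asarray(mask)
    indices = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    m = indices.size
    if m < 2:
        raise ValueError("MED analysis needs at least two selected features")
    config = config or MEDConfig()
    names = ([feature_names[j] for j in indices] if feature_names is not None
             else [f"P{j + 1}" for j in indices])

    design = two_level_oa(m)
    Xsel = X[:, indices]
    fits = _design_fitness(Xsel, y, design, config)
    med = _med_from_design(design, fits)
    return MEDReport(names, med, config, n_rows=design.shape[0])


def compute_med_full_factorial(X: np.ndarray, y: np.ndarray,
                               mask: np.ndarray | Sequence[int],
                               feature_names: Sequence[str] | None = None,
                               config: MEDConfig | None = None) -> MEDReport:
    """Exhaustive 2^m-design MED, tractable only for small m; serves as
    the exact reference for the orthogonal-array estimate."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mask = np.asarray(mask)
    indices = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
    m = indices.size
    if m < 2:
        raise ValueError("MED analysis needs at least two selected features")
    if m > 12:
        raise ValueError("full factorial is limited to m <= 12")
    config = config or MEDConfig()
    names = ([feature_names[j] for j in indices] if feature_names is not None
             else [f"P{j + 1}" for j in indices])

    design = np.array([[(i >> j) & 1 for j in range(m)]
                       for i in range(1 << m)], dtype=np.int8)
    fits = _design_fitness(X[:, indices], y, design, config)
    med = _med_from_design(design, fits)
    return MEDReport(names, med, config, n_rows=design.shape[0])


def rank_report(report: MEDReport, top_k: int | None = None) -> pd.DataFrame:
    """Ordered MED listing (descending; ties by feature index)."""
    return report.to_frame(top_k)
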