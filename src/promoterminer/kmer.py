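"""Class-discriminative k-mer scoring and top-k motif selection.

Each of the 256 4-mer motifs gets a raw score equal to the absolute
difference between its proportional occurrence frequencies in the positive
(promoter) and negative (non-promoter) training classes; scores are
linearly normalised onto an integer scale and the 128 top-ranked motifs
define the k-mer block of the descriptor vector.  Counting is overlapping
and strand-specific (promoter segments are already oriented relative to
the transcription start site).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import POSITIVE, LabeledDataset

DEFAULT_K = 4
DEFAULT_TOP = 128
DEFAULT_SCALE_MAX = 1000


def all_motifs(k: int = DEFAULT_K) -> list[str]:
    """All 4^k motifs of length k in lexicographic order."""
    if k < 1:
        raise ValueError("motif length must be >= 1")
    return ["".join(p) for p in product("ACGT", repeat=k)]


def count_kmers(dataset: LabeledDataset, k: int = DEFAULT_K
                ) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Overlapping per-class occurrence totals for all 4^k motifs.

    Returns (f, F, sum_f, sum_F) where f counts the positive class and F
    the negative class, both in lexicographic motif order.
    """
    motifs = all_motifs(k)
    index = {m: i for i, m in enumerate(motifs)}
    f = np.zeros(len(motifs), dtype=np.int64)
    F = np.zeros(len(motifs), dtype=np.int64)
    for seq, label in zip(dataset.sequences, dataset.labels):
        s = seq.residues
        if len(s) < k:
            raise ValueError(
                f"sequence {seq.id!r}: length {len(s)} < k = {k}")
        target = f if label == POSITIVE else F
        for i in range(len(s) - k + 1):
            target[index[s[i:i + k]]] += 1
    return f, F, int(f.sum()), int(F.sum())


def score_kmers(f: np.ndarray, F: np.ndarray, sum_f: int, sum_F: int
                ) -> np.ndarray:
    """Raw discriminative scores |f/sum_f - F/sum_F|."""
    if sum_f <= 0 or sum_F <= 0:
        raise ValueError("both classes must contain at least one k-mer window")
    return np.abs(np.asarray(f) / sum_f - np.asarray(F) / sum_F)


def normalize_scores(raw: np.ndarray, scale_max: int = DEFAULT_SCALE_MAX
                     ) -> np.ndarray:
    """Linearly map raw scores onto integers in [0, scale_max].

    All-equal raw scores map to all zeros.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.int64)
    return np.rint(scale_max * (raw - lo) / (hi - lo)).astype(np.int64)


def rank_and_select(raw: np.ndarray, motifs: Sequence[str],
                    k_top: int = DEFAULT_TOP
                    ) -> tuple[list[str], np.ndarray]:
    """Rank motifs by descending raw score (ties broken lexicographically)
    and return the ordered top-k list plus 1-based ranks for all motifs."""
    if k_top > len(motifs):
        raise ValueError(f"k_top = {k_top} exceeds motif universe {len(motifs)}")
    order = sorted(range(len(motifs)), key=lambda i: (-raw[i], motifs[i]))
    ranks = np.empty(len(motifs), dtype=np.int64)
    for rank_minus_1, i in enumerate(order):
        ranks[i] = rank_minus_1 + 1
    top = [motifs[i] for i in order[:k_top]]
    return top, ranks


@dataclass
class KmerScoreTable:
    """Per-motif counts, scores, ranks and top-k membership.

    Built from a labeled training dataset with :meth:`fit`; persists to a
    TSV with one row per motif.
    """

    motifs: list[str]
    f: np.ndarray
    F: np.ndarray
    sum_f: int
    sum_F: int
    raw_scores: np.ndarray
    theta: np.ndarray
    ranks: np.ndarray
    top_motifs: list[str]
    k: int = DEFAULT_K
    scale_max: int = DEFAULT_SCALE_MAX

    @classmethod
    def fit(cls, dataset: LabeledDataset, k: int = DEFAULT_K,
            k_top: int = DEFAULT_TOP, scale_max: int = DEFAULT_SCALE_MAX
            ) -> "KmerScoreTable":
        motifs = all_motifs(k)
        f, F, sum_f, sum_F = count_kmers(dataset, k)
        raw = score_kmers(f, F, sum_f, sum_F)
        theta = normalize_scores(raw, scale_max)
        top, ranks = rank_and_select(raw, motifs, k_top)
        return cls(motifs, f, F, sum_f, sum_F, raw, theta, ranks, top,
                   k=k, scale_max=scale_max)

    @property
    def selected(self) -> np.ndarray:
        chosen = set(self.top_motifs)
        return np.array([m in chosen for m in self.motifs], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "motif": self.motifs,
            "f": self.f,
            "F": self.F,
            "raw_score": self.raw_scores,
            "theta": self.theta,
            "rank": self.ranks,
            "selected": self.selected.astype(int),
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerScoreTable":
        df = pd.read_csv(path, sep="\t")
        motifs = df["motif"].astype(str).tolist()
        k = len(motifs[0])
        f = df["f"].to_numpy(dtype=np.int64)
        F = df["F"].to_numpy(dtype=np.int64)
        raw = df["raw_score"].to_numpy(dtype=float)
        theta = df["theta"].to_numpy(dtype=np.int64)
        ranks = df["rank"].to_numpy(dtype=np.int64)
        n_top = int(df["selected"].sum())
        order = sorted(range(len(motifs)), key=lambda i: ranks[i])
        top = [motifs[i] for i in order[:n_top]]
        return cls(motifs, f, F, int(f.sum()), int(F.sum()), raw, theta,
                   ranks, top, k=k, scale_max=int(theta.max()) or DEFAULT_SCALE_MAX)

    def content_hash(self) -> str:
        """Stable hash used to couple a trained model to its k-mer table."""
        h = hashlib.sha256()
        h.update(",".join(self.motifs).encode())
        h.update(self.f.tobytes())
        h.update(self.F.tobytes())
        return h.hexdigest()[:16]
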