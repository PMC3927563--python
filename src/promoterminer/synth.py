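"""Seeded synthetic two-class sequence and feature-matrix generators.

The sequence generator emulates the shape of promoter benchmark data:
fixed-length windows (252 nt, mirroring a -200..+51 window around a
transcription start site), a positive class with elevated A content in
the leading positions (so the first A tends to appear earlier, the
dominant discriminative signal in real promoter sets), an optional GC
shift between classes, and optionally planted 4-mer motifs inserted into
positives.  It does not model real promoter biology (no CpG islands,
nucleosome signals or TATA-box grammar) — it plants exactly the signals
the pipeline is designed to detect, which is what makes recovery testable.

All randomness flows from a single seed through numpy's SeedSequence
splitting, so every fixture is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .descriptors import descriptor_names
from .seqio import NEGATIVE, POSITIVE, LabeledDataset, NucleotideSequence

NT = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Generator settings.

    leading_A_boost is the excess probability mass moved onto A within the
    first ``leading_window`` positions of positive-class sequences;
    planted_motifs lists (motif, per-sequence insertion probability,
    (start, end) 0-based half-open position window) applied to positives.
    """

    n_pos: int = 100
    n_neg: int = 100
    length: int = 252
    seed: int = 0
    leading_A_boost: float = 0.3
    leading_window: int = 20
    planted_motifs: list[tuple[str, float, tuple[int, int]]] = field(
        default_factory=list)
    gc_pos: float = 0.55
    gc_neg: float = 0.50
    codon_periodicity: bool = False

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError("length must be >= 4")
        for p in (self.leading_A_boost, self.gc_pos, self.gc_neg):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        for motif, prob, (lo, hi) in self.planted_motifs:
            if hi > self.length:
                raise ValueError(f"motif window {(lo, hi)} exceeds length")
            if hi - lo < len(motif):
                raise ValueError(
                    f"motif {motif!r} longer than its window {(lo, hi)}")
            if not 0 <= prob <= 1:
                raise ValueError(f"insertion probability {prob} outside [0, 1]")


@dataclass
class PlantedTruth:
    """Descriptor names expected to be informative under the config."""

    names: list[str]

    def indices(self, all_names: Sequence[str]) -> list[int]:
        """Resolve to positions in a concrete 167-descriptor layout;
        planted-motif descriptors absent from the top-128 list are
        dropped."""
        lookup = {n: i for i, n in enumerate(all_names)}
        return [lookup[n] for n in self.names if n in lookup]


def _base_probs(gc: float) -> np.ndarray:
    # order A, C, G, T
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _boosted_probs(base: np.ndarray, boost: float) -> np.ndarray:
    p = base.copy()
    scale = (1.0 - (p[0] + boost)) / (1.0 - p[0]) if p[0] + boost < 1 else 0.0
    p[1:] *= scale
    p[0] = min(p[0] + boost, 1.0)
    return p / p.sum()


def generate_sequences(config: SynthConfig
                       ) -> tuple[LabeledDataset, PlantedTruth]:
    """Generate the two-class sequence dataset and the planted truth."""
    rng = np.random.default_rng(config.seed)
    pos_bg = _base_probs(config.gc_pos)
    neg_bg = _base_probs(config.gc_neg)
    lead = _boosted_probs(pos_bg, config.leading_A_boost)
    w = min(config.leading_window, config.length)

    sequences: list[NucleotideSequence] = []
    labels: list[int] = []
    for i in range(config.n_pos):
        head = rng.choice(4, size=w, p=lead)
        tail = rng.choice(4, size=config.length - w, p=pos_bg)
        residues = np.concatenate([head, tail])
        for motif, prob, (lo, hi) in config.planted_motifs:
            if rng.random() < prob:
                start = int(rng.integers(lo, hi - len(motif) + 1))
                residues[start:start + len(motif)] = [
                    "ACGT".index(ch) for ch in motif]
        sequences.append(NucleotideSequence(
            f"pos_{i}", "".join(NT[residues])))
        labels.append(POSITIVE)
    for i in range(config.n_neg):
        if config.codon_periodicity:
            # caricature of CDS-like period-3 composition modulation
            residues = np.empty(config.length, dtype=int)
            mods = [neg_bg,
                    _boosted_probs(neg_bg, 0.08),
                    _base_probs(min(config.gc_neg + 0.08, 1.0))]
            for pos in range(config.length):
                residues[pos] = rng.choice(4, p=mods[pos % 3])
        else:
            residues = rng.choice(4, size=config.length, p=neg_bg)
        sequences.append(NucleotideSequence(
            f"neg_{i}", "".join(NT[residues])))
        labels.append(NEGATIVE)

    truth_names: list[str] = []
    if config.leading_A_boost > 0:
        truth_names += ["D_D(A,1st)", "D_C1(A)"]
    if config.gc_pos != config.gc_neg:
        truth_names += ["D_C1(C)", "D_C1(G)", "D_EQ"]
    for motif, prob, _ in config.planted_motifs:
        if prob > 0:
            truth_names.append(f"D_C4({motif})")
    return LabeledDataset(sequences, labels), PlantedTruth(truth_names)


def generate_feature_matrix(n: int, m: int, n_informative: int,
                            effect: float, seed: int = 0
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class Gaussian feature matrix with planted informative columns.

    Informative columns are shifted by ``effect`` standard deviations
    between classes; the rest are class-independent noise.  The matrix is
    min-max scaled to [0, 1] column-wise.  Returns (X, y, truth) where
    truth holds the informative column indices.
    """
    if n_informative > m:
        raise ValueError("n_informative exceeds the number of features")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    y = np.array([POSITIVE] * n_pos + [NEGATIVE] * (n - n_pos))
    X = rng.standard_normal((n, m))
    truth = rng.choice(m, size=n_informative, replace=False)
    X[:n_pos, truth] += effect
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    X = (X - lo) / span
    return X, y, np.sort(truth)
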