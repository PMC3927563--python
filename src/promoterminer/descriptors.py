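"""The 167-dimensional DNA sequence descriptor vector.

Layout (1-based positions P1..P167):

====  =========================================================
P1-3   physicochemical averages D_AM, D_MW, D_MAC
P4-9   entropy density profile D_EH, D_EQ, D_EA, D_EC, D_EG, D_ET
P10-13 composition (1-mer frequencies) D_C1(A), D_C1(T), D_C1(C), D_C1(G)
P14-19 transitions D_T(A,C), D_T(A,G), D_T(A,T), D_T(C,G), D_T(C,T), D_T(G,T)
P20-39 distributions D_D(x, p) for x in A, C, G, T and
       p in 1st, 25%, 50%, 75%, 100%
P40-167 frequency descriptors of the 128 top-ranked 4-mer motifs
====  =========================================================

The physicochemical averages use per-nucleotide absorption maxima (nm),
molecular weight (g/mol) and molar absorption coefficient; the entropy
descriptors use base-2 logarithms (Shannon bits).  Transition and
distribution descriptors are percentages.  The 4-mer descriptors are
per-sequence overlapping-occurrence counts normalised by the number of
length-4 windows (L - 3), keeping them comparable across sequence lengths.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import NotFittedError
from sklearn.preprocessing import MinMaxScaler

from .seqio import NucleotideSequence

NUCLEOTIDES = ("A", "C", "G", "T")

#: per-nucleotide (absorption maximum at pH 7.0, molecular weight,
#: molar absorption coefficient)
DEFAULT_PHYSCHEM: dict[str, tuple[float, float, float]] = {
    "A": (259.0, 491.2, 15200.0),
    "C": (271.0, 467.2, 9300.0),
    "G": (253.0, 507.2, 13700.0),
    "T": (267.0, 482.2, 9600.0),
}

TRANSITION_PAIRS = tuple(combinations(("A", "C", "G", "T"), 2))
DISTRIBUTION_QUANTILES = (("1st", None), ("25%", 0.25), ("50%", 0.50),
                          ("75%", 0.75), ("100%", 1.00))

N_PHYSCHEM = 3
N_GLOBAL = 36
N_KMER = 128
N_DESCRIPTORS = N_PHYSCHEM + N_GLOBAL + N_KMER  # 167


@dataclass(frozen=True)
class PhysChemTable:
    """Per-nucleotide physicochemical property values."""

    values: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHYSCHEM))

    def __post_init__(self) -> None:
        if set(self.values) != set(NUCLEOTIDES):
            raise ValueError("physicochemical table must cover exactly A, C, G, T")
        for nt, props in self.values.items():
            if len(props) != 3 or any(v <= 0 for v in props):
                raise ValueError(f"invalid property triple for {nt}: {props}")


def _check_nonempty(seq: NucleotideSequence) -> str:
    if len(seq.residues) == 0:
        raise ValueError(f"sequence {seq.id!r} is empty")
    return seq.residues


def physchem_descriptors(seq: NucleotideSequence,
                         table: PhysChemTable | None = None
                         ) -> tuple[float, float, float]:
    """Sequence-averaged absorption maximum, molecular weight and molar
    absorption coefficient (D_AM, D_MW, D_MAC)."""
    s = _check_nonempty(seq)
    table = table or PhysChemTable()
    counts = {nt: s.count(nt) for nt in NUCLEOTIDES}
    n = len(s)
    out = []
    for prop in range(3):
        out.append(sum(counts[nt] * table.values[nt][prop]
                       for nt in NUCLEOTIDES) / n)
    return tuple(out)  # type: ignore[return-value]


def composition(seq: NucleotideSequence) -> tuple[float, float, float, float]:
    """1-mer frequencies (q_A, q_T, q_C, q_G)."""
    s = _check_nonempty(seq)
    n = len(s)
    return tuple(s.count(nt) / n for nt in ("A", "T", "C", "G"))  # type: ignore


def edp_descriptors(seq: NucleotideSequence
                    ) -> tuple[float, float, float, float, float, float]:
    """Entropy density profile (D_EH, D_EQ, D_EA, D_EC, D_EG, D_ET).

    D_EH is the Shannon entropy of the nucleotide composition in bits
    (0 log 0 := 0); D_EQ the sum of squared frequencies; the four D_Ei are
    the per-nucleotide entropy fractions -q_i log2 q_i / D_EH (base
    invariant) and are defined as 0 on homopolymers where D_EH = 0.
    """
    s = _check_nonempty(seq)
    n = len(s)
    q = {nt: s.count(nt) / n for nt in NUCLEOTIDES}
    d_eq = sum(v * v for v in q.values())
    terms = {nt: (-v * math.log2(v) if v > 0 else 0.0) for nt, v in q.items()}
    d_eh = sum(terms.values())
    if d_eh > 0:
        d_ei = tuple(terms[nt] / d_eh for nt in NUCLEOTIDES)
    else:
        d_ei = (0.0, 0.0, 0.0, 0.0)
    return (d_eh, d_eq) + d_ei  # type: ignore[return-value]


def transition_descriptors(seq: NucleotideSequence
                           ) -> tuple[float, float, float, float, float, float]:
    """Percent frequencies of unordered adjacent pairs, in the order
    (A,C), (A,G), (A,T), (C,G), (C,T), (G,T)."""
    s = _check_nonempty(seq)
    if len(s) < 2:
        raise ValueError(
            f"sequence {seq.id!r}: transitions need length >= 2, got {len(s)}")
    counts = {pair: 0 for pair in TRANSITION_PAIRS}
    for a, b in zip(s, s[1:]):
        if a != b:
            key = (a, b) if a < b else (b, a)
            if key in counts:
                counts[key] += 1
    denom = len(s) - 1
    return tuple(100.0 * counts[p] / denom for p in TRANSITION_PAIRS)  # type: ignore


def distribution_descriptors(seq: NucleotideSequence
                             ) -> tuple[float, ...]:
    """Positional quantiles of each nucleotide, as % of chain length.

    For nucleotide x occurring c > 0 times at 1-based positions
    pos_1..pos_c, the value at quantile p is pos_ceil(p*c) / L * 100 and
    the "1st" value is pos_1 / L * 100.  Absent nucleotides contribute
    five zeros.  Ordered A, C, G, T x (1st, 25%, 50%, 75%, 100%).
    """
    s = _check_nonempty(seq)
    n = len(s)
    out: list[float] = []
    for nt in NUCLEOTIDES:
        positions = [i + 1 for i, ch in enumerate(s) if ch == nt]
        c = len(positions)
        if c == 0:
            out.extend([0.0] * 5)
            continue
        for _, p in DISTRIBUTION_QUANTILES:
            idx = 1 if p is None else math.ceil(p * c)
            out.append(100.0 * positions[idx - 1] / n)
    return tuple(out)


def global_descriptors(seq: NucleotideSequence) -> tuple[float, ...]:
    """The 36 global descriptors P4..P39 (EDP, composition, transition,
    distribution)."""
    return (edp_descriptors(seq) + composition(seq)
            + transition_descriptors(seq) + distribution_descriptors(seq))


def kmer_frequencies(seq: NucleotideSequence, motifs: Sequence[str]) -> np.ndarray:
    """Per-sequence overlapping occurrence frequency of each motif,
    normalised by the number of windows (L - k + 1)."""
    s = _check_nonempty(seq)
    if not motifs:
        return np.zeros(0)
    k = len(motifs[0])
    if len(s) < k:
        raise ValueError(
            f"sequence {seq.id!r}: length {len(s)} < motif length {k}")
    n_windows = len(s) - k + 1
    counts = {m: 0 for m in motifs}
    for i in range(n_windows):
        w = s[i:i + k]
        if w in counts:
            counts[w] += 1
    return np.array([counts[m] / n_windows for m in motifs], dtype=float)


def descriptor_names(motifs: Sequence[str]) -> list[str]:
    """The 167 descriptor labels P1..P167 for a given top-128 motif list."""
    names = ["D_AM", "D_MW", "D_MAC",
             "D_EH", "D_EQ", "D_EA", "D_EC", "D_EG", "D_ET",
             "D_C1(A)", "D_C1(T)", "D_C1(C)", "D_C1(G)"]
    names += [f"D_T({a},{b})" for a, b in TRANSITION_PAIRS]
    names += [f"D_D({nt},{q})" for nt in NUCLEOTIDES
              for q, _ in DISTRIBUTION_QUANTILES]
    names += [f"D_C4({m})" for m in motifs]
    return names


def assemble_vector(seq: NucleotideSequence, kmer_table,
                    physchem: PhysChemTable | None = None) -> np.ndarray:
    """Assemble the full 167-dimensional descriptor vector for one
    sequence, given a fitted k-mer score table providing the ordered
    top-128 motif list."""
    motifs = list(kmer_table.top_motifs)
    if len(motifs) != N_KMER:
        raise ValueError(
            f"k-mer table selects {len(motifs)} motifs; expected {N_KMER}")
    vec = np.concatenate([
        np.array(physchem_descriptors(seq, physchem)),
        np.array(global_descriptors(seq)),
        kmer_frequencies(seq, motifs),
    ])
    assert vec.size == N_DESCRIPTORS
    return vec


def featurize(sequences: Sequence[NucleotideSequence], kmer_table,
              physchem: PhysChemTable | None = None
              ) -> tuple[np.ndarray, list[str]]:
    """Descriptor matrix (n_sequences x 167) plus column names."""
    X = np.vstack([assemble_vector(s, kmer_table, physchem)
                   for s in sequences])
    return X, descriptor_names(list(kmer_table.top_motifs))


class FeatureScaler:
    """Per-feature min-max scaling onto [0, 1], fitted on training data.

    Test-time values are clipped into [0, 1]; constant training columns map
    to 0.  Thin wrapper over sklearn's MinMaxScaler with JSON persistence.
    """

    def __init__(self) -> None:
        self._scaler = MinMaxScaler(clip=True)
        self._fitted = False

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit scaler on an empty matrix")
        self._scaler.fit(X)
        self._fitted = True
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError("FeatureScaler used before fit()")
        return self._scaler.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    @property
    def data_min_(self) -> np.ndarray:
        return self._scaler.data_min_

    @property
    def data_max_(self) -> np.ndarray:
        return self._scaler.data_max_

    def to_json(self, path: str | Path) -> None:
        if not self._fitted:
            raise NotFittedError("cannot persist an unfitted scaler")
        payload = {"min": self.data_min_.tolist(),
                   "max": self.data_max_.tolist()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScaler":
        payload = json.loads(Path(path).read_text())
        lo = np.asarray(payload["min"], dtype=float)
        hi = np.asarray(payload["max"], dtype=float)
        obj = cls()
        # re-fit on the two stored extreme rows; reproduces min/max exactly
        obj.fit(np.vstack([lo, hi]))
        return obj


def export_matrix(path: str | Path, X: np.ndarray, names: Sequence[str],
                  ids: Sequence[str] | None = None) -> None:
    """Write a descriptor matrix as TSV with named columns."""
    import pandas as pd

    df = pd.DataFrame(X, columns=list(names))
    if ids is not None:
        df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def import_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str] | None]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    ids = None
    if df.columns[0] == "id":
        ids = df["id"].astype(str).tolist()
        df = df.drop(columns=["id"])
    return df.to_numpy(dtype=float), list(df.columns), ids
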