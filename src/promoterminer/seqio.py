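"""Sequence and label I/O for two-class (promoter / non-promoter) datasets.

FASTA parsing is delegated to Biopython; this module adds alphabet
validation (the descriptor set is defined only over {A, C, G, T}),
label-table parsing, and the pairing of sequences with class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")

#: class encodings
POSITIVE = 1  # promoter
NEGATIVE = 0  # non-promoter

#: default label vocabulary accepted by :func:`read_labels`
DEFAULT_VOCABULARY: Mapping[str, int] = {
    "promoter": POSITIVE,
    "positive": POSITIVE,
    "pos": POSITIVE,
    "1": POSITIVE,
    "nonpromoter": NEGATIVE,
    "non-promoter": NEGATIVE,
    "negative": NEGATIVE,
    "neg": NEGATIVE,
    "0": NEGATIVE,
}


class FastaParseError(ValueError):
    """Malformed FASTA input (reports the offending line)."""


class SequenceValidationError(ValueError):
    """Sequence contains residues outside {A, C, G, T} in strict mode."""


class LabelError(ValueError):
    """Malformed, duplicate, or missing label entries."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the alphabet {A, C, G, T}.

    ``dropped`` records how many non-ACGT positions were removed when the
    record was loaded in lenient mode (0 for strict reads and generated
    sequences).
    """

    id: str
    residues: str
    dropped: int = 0

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Sequences paired with binary class labels (1 = promoter)."""

    sequences: list[NucleotideSequence]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise LabelError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def class_counts(self) -> dict[str, int]:
        pos = sum(1 for y in self.labels if y == POSITIVE)
        return {"positive": pos, "negative": len(self.labels) - pos}

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
        )


def read_fasta(path: str | Path, mode: str = "strict") -> list[NucleotideSequence]:
    """Read a FASTA file into validated nucleotide sequences.

    Residues are uppercased.  ``mode="strict"`` raises on any residue
    outside {A, C, G, T}; ``mode="lenient"`` silently drops such positions
    and records their count on the returned sequence.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}; use 'strict' or 'lenient'")
    path = Path(path)
    _precheck_fasta(path)
    out: list[NucleotideSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        if mode == "strict":
            for i, ch in enumerate(raw):
                if ch not in ALPHABET:
                    raise SequenceValidationError(
                        f"sequence {rec.id!r}: non-ACGT residue {ch!r} "
                        f"at position {i + 1}"
                    )
            out.append(NucleotideSequence(rec.id, raw))
        else:
            kept = "".join(ch for ch in raw if ch in ALPHABET)
            out.append(NucleotideSequence(rec.id, kept, dropped=len(raw) - len(kept)))
    return out


def _precheck_fasta(path: Path) -> None:
    # Biopython tolerates leading junk; the contract here is stricter and
    # names the first offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected a FASTA header line "
                    f"starting with '>', got {line.strip()[:40]!r}"
                )
            return
    raise FastaParseError(f"{path}: empty FASTA file")


def write_fasta(path: str | Path, sequences: Iterable[NucleotideSequence],
                width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_labels(path: str | Path,
                vocabulary: Mapping[str, int] = DEFAULT_VOCABULARY
                ) -> dict[str, int]:
    """Read a two-column (id, label) TSV into an id → {0, 1} mapping."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelError(
                    f"{path}:{lineno}: expected two tab-separated columns, "
                    f"got {len(parts)}"
                )
            sid, text = parts[0].strip(), parts[1].strip().lower()
            if sid in labels:
                raise LabelError(f"{path}:{lineno}: duplicate id {sid!r}")
            if text not in vocabulary:
                raise LabelError(
                    f"{path}:{lineno}: label {text!r} not in vocabulary "
                    f"{sorted(set(vocabulary))}"
                )
            labels[sid] = vocabulary[text]
    return labels


def write_labels(path: str | Path, labels: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for sid, y in labels.items():
            fh.write(f"{sid}\t{'promoter' if y == POSITIVE else 'nonpromoter'}\n")


def make_dataset(sequences: Sequence[NucleotideSequence],
                 labels: Mapping[str, int]) -> LabeledDataset:
    """Pair sequences with labels, preserving sequence (file) order."""
    missing = [s.id for s in sequences if s.id not in labels]
    if missing:
        raise LabelError(f"sequences without labels: {missing}")
    return LabeledDataset(list(sequences), [labels[s.id] for s in sequences])
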