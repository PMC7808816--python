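"""FASTA and label-table I/O plus the amino-acid alphabet contract.

Every encoder in :mod:`lumiprot.encoders` is defined only over the 20
canonical amino acids.  This module is the single place where sequences
enter the package, so the alphabet policy is enforced here: by default a
non-canonical residue is an error (``strict``); callers may instead strip
unknown letters or map the common ambiguity codes onto canonical ones.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids in alphabetical one-letter order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

#: Ambiguity-code resolution used by the ``map_ambiguous`` policy.
#: B (Asx) -> N, Z (Glx) -> Q, U (Sec) -> C, O (Pyl) -> K, J (Xle) -> L;
#: X (fully unknown) has no canonical image and is dropped.
AMBIGUOUS_MAP = {"B": "N", "Z": "Q", "U": "C", "O": "K", "J": "L"}

SPECIES = ("general", "bacteria", "eukaryote", "archaea")

ValidationPolicy = Literal["strict", "strip", "map_ambiguous"]


class SequenceError(ValueError):
    """Raised when a sequence violates the alphabet or length contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: identifier plus residue string.

    ``residues`` is expected to be uppercase; use :func:`validate_sequence`
    to enforce the canonical alphabet before encoding.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise SequenceError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def is_canonical(self) -> bool:
        return all(c in ALPHABET_SET for c in self.residues)


@dataclass
class LabeledDataset:
    """Parallel sequences and binary labels (1 = BLP, 0 = non-BLP)."""

    sequences: list[ProteinSequence]
    labels: list[int]
    species: str = "general"

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be binary (0 = non-BLP, 1 = BLP)")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def min_length(self) -> int:
        return min(len(s) for s in self.sequences)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    The record id is the first whitespace-delimited token of the header
    (a stable join key for label tables).  Sequence lines are uppercased
    and whitespace-stripped; record order is preserved.  Duplicate ids get
    a ``.2``, ``.3`` ... suffix with a warning; an empty record is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinSequence] = []
    seen: Counter[str] = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).replace(" ", "").replace("\t", "").upper()
        if not residues:
            raise SequenceError(f"record {rec.id!r} in {path} has an empty sequence")
        seen[rec.id] += 1
        rid = rec.id if seen[rec.id] == 1 else f"{rec.id}.{seen[rec.id]}"
        if seen[rec.id] > 1:
            warnings.warn(
                f"duplicate FASTA id {rec.id!r}; renamed to {rid!r}", stacklevel=2
            )
        records.append(ProteinSequence(rid, residues))
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences to FASTA, wrapping lines at ``width`` columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def validate_sequence(
    seq: ProteinSequence, policy: ValidationPolicy = "strict"
) -> ProteinSequence:
    """Apply the alphabet policy and return a canonical sequence.

    strict
        Any non-canonical letter raises :class:`SequenceError` naming the
        offending character and its 1-based position.
    strip
        Non-canonical letters are removed (idempotent).
    map_ambiguous
        B→N, Z→Q, U→C, O→K, J→L; X is stripped; anything else errors.
    """
    residues = seq.residues.upper()
    if all(c in ALPHABET_SET for c in residues):
        return seq if residues == seq.residues else ProteinSequence(seq.id, residues)
    if policy == "strict":
        for i, c in enumerate(residues, start=1):
            if c not in ALPHABET_SET:
                raise SequenceError(
                    f"sequence {seq.id!r}: non-canonical residue {c!r} at position {i}"
                )
    if policy == "strip":
        kept = "".join(c for c in residues if c in ALPHABET_SET)
        if not kept:
            raise SequenceError(f"sequence {seq.id!r}: no canonical residues remain")
        return ProteinSequence(seq.id, kept)
    if policy == "map_ambiguous":
        out = []
        for i, c in enumerate(residues, start=1):
            if c in ALPHABET_SET:
                out.append(c)
            elif c in AMBIGUOUS_MAP:
                out.append(AMBIGUOUS_MAP[c])
            elif c == "X":
                continue
            else:
                raise SequenceError(
                    f"sequence {seq.id!r}: unmappable residue {c!r} at position {i}"
                )
        if not out:
            raise SequenceError(f"sequence {seq.id!r}: no canonical residues remain")
        return ProteinSequence(seq.id, "".join(out))
    raise ValueError(f"unknown validation policy {policy!r}")


def validate_dataset(
    sequences: Sequence[ProteinSequence], policy: ValidationPolicy = "strict"
) -> list[ProteinSequence]:
    """Validate every sequence under one policy."""
    return [validate_sequence(s, policy) for s in sequences]


_LABEL_VOCAB = {
    "1": 1, "0": 0,
    "blp": 1, "non-blp": 0, "nonblp": 0, "non_blp": 0,
    "positive": 1, "negative": 0, "pos": 1, "neg": 0,
}


def read_labels(
    path: str | Path, sequences: Sequence[ProteinSequence]
) -> LabeledDataset:
    """Join a label TSV (``id<TAB>label[<TAB>species]``) onto sequences.

    Labels may be 0/1 or BLP/non-BLP (case-insensitive).  Every id in the
    table must resolve against ``sequences``; sequences keep their file
    order.  A missing species column defaults to ``general``.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in table.columns]
    if len(table.columns) < 2 or cols[0] != "id" or cols[1] != "label":
        raise ValueError(
            f"label table {path} must have header 'id<TAB>label[<TAB>species]', "
            f"got columns {list(table.columns)}"
        )
    by_id = {s.id: s for s in sequences}
    labels_by_id: dict[str, int] = {}
    species = "general"
    for _, row in table.iterrows():
        sid = str(row.iloc[0])
        if sid not in by_id:
            raise KeyError(f"label table id {sid!r} not found among sequences")
        raw = str(row.iloc[1]).strip().lower()
        if raw not in _LABEL_VOCAB:
            raise ValueError(f"unrecognised label {row.iloc[1]!r} for id {sid!r}")
        labels_by_id[sid] = _LABEL_VOCAB[raw]
    if len(table.columns) >= 3:
        uniq = set(table.iloc[:, 2].astype(str).str.lower())
        if len(uniq) > 1:
            raise ValueError(f"label table mixes species: {sorted(uniq)}")
        species = uniq.pop()
    ordered = [s for s in sequences if s.id in labels_by_id]
    return LabeledDataset(
        sequences=ordered,
        labels=[labels_by_id[s.id] for s in ordered],
        species=species,
    )


def write_labels(data: LabeledDataset, path: str | Path) -> None:
    """Write the label table in the dialect :func:`read_labels` reads."""
    pd.DataFrame(
        {"id": data.ids, "label": data.labels, "species": data.species}
    ).to_csv(path, sep="\t", index=False)
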