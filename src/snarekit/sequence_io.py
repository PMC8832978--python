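"""Reading, validating, writing and splitting labelled protein FASTA datasets.

The pipeline works on two-class protein data supplied as a pair of FASTA
files (one per class).  Each record is validated against the 20-letter
canonical amino-acid alphabet; what happens to records carrying
non-canonical symbols (B, J, O, U, X, Z, gaps) is controlled by a
:class:`ResiduePolicy`.  Splitting into a training pool and an independent
test set is stratified by class so the minority class keeps its proportion.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical amino acids in fixed alphabetical order.  All descriptor
#: column orderings derive from this string.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Shortest sequence the descriptor family accepts (skip-pair encoders
#: need at least one gap-2 pair).
MIN_SEQUENCE_LENGTH = 3

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"


class ResiduePolicy(str, enum.Enum):
    """How to treat records containing non-canonical residues."""

    REJECT = "reject"  # drop the whole record (default)
    STRIP = "strip"    # remove the offending characters, keep the record


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with an optional binary class label."""

    id: str
    sequence: str
    label: str = UNKNOWN
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ProteinRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def count(self, label: str) -> int:
        return sum(1 for r in self.records if r.label == label)

    @property
    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def subset(self, indices: Sequence[int]) -> "SequenceDataset":
        return SequenceDataset([self.records[i] for i in indices])

    @staticmethod
    def concatenate(datasets: Iterable["SequenceDataset"]) -> "SequenceDataset":
        records: list[ProteinRecord] = []
        for d in datasets:
            records.extend(d.records)
        return SequenceDataset(records)


@dataclass(frozen=True)
class SplitSpec:
    """Index sets of a train / independent-test partition."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    test_fraction: float
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        train, test = set(self.train_indices), set(self.test_indices)
        if train & test:
            raise ValueError("train and test index sets overlap")


def _validate_sequence(
    raw: str, record_id: str, policy: ResiduePolicy
) -> str | None:
    """Return the cleaned sequence, or None if the record is rejected."""
    seq = "".join(raw.split()).upper()
    bad = sorted(set(seq) - _ALPHABET_SET)
    if bad:
        if policy is ResiduePolicy.REJECT:
            logger.warning(
                "record %r rejected: non-canonical residue(s) %s",
                record_id, ",".join(bad),
            )
            return None
        seq = "".join(c for c in seq if c in _ALPHABET_SET)
        logger.warning(
            "record %r: stripped non-canonical residue(s) %s",
            record_id, ",".join(bad),
        )
    if len(seq) < MIN_SEQUENCE_LENGTH:
        logger.warning(
            "record %r rejected: length %d below minimum %d",
            record_id, len(seq), MIN_SEQUENCE_LENGTH,
        )
        return None
    return seq


def _disambiguate(record_id: str, seen: dict[str, int]) -> str:
    if record_id not in seen:
        seen[record_id] = 0
        return record_id
    seen[record_id] += 1
    new_id = f"{record_id}.{seen[record_id]}"
    logger.warning("duplicate id %r renamed to %r", record_id, new_id)
    return new_id


def read_fasta(
    path: str | Path,
    label: str = UNKNOWN,
    policy: ResiduePolicy = ResiduePolicy.REJECT,
) -> SequenceDataset:
    """Read a FASTA file into a :class:`SequenceDataset`, all records
    carrying `label`.

    Multi-line sequences are joined, whitespace stripped and case
    normalised to upper.  Records with non-canonical residues are handled
    per `policy`; records shorter than :data:`MIN_SEQUENCE_LENGTH` after
    cleaning are always dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    # locate the first header by hand so malformed input gets a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                break
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first '>' header"
            )
        else:
            raise FastaParseError(f"{path}: empty FASTA file")

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(str(rec.seq), rec.id, policy)
        if seq is None:
            continue
        rid = _disambiguate(rec.id, seen)
        description = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(rid, seq, label, description))
    return SequenceDataset(records)


def write_fasta(dataset: SequenceDataset, path: str | Path) -> None:
    """Write a dataset as FASTA, 60 residues per line.

    Round-trips with :func:`read_fasta` on ids and sequences.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in dataset
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


def split_dataset(
    dataset: SequenceDataset,
    test_fraction: float,
    seed: int,
    stratified: bool = True,
) -> SplitSpec:
    """Partition a dataset into train and independent-test index sets.

    Deterministic for a fixed seed.  Under stratification each class
    contributes ``floor(test_fraction * class_size)`` records to the test
    set, so the per-class test proportion is within one record of
    `test_fraction`.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(dataset)

    if not stratified:
        perm = rng.permutation(n)
        n_test = int(math.floor(test_fraction * n))
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        return SplitSpec(tuple(train.tolist()), tuple(test.tolist()),
                         test_fraction, seed, False)

    by_label: dict[str, list[int]] = {}
    for i, rec in enumerate(dataset):
        by_label.setdefault(rec.label, []).append(i)

    test_idx: list[int] = []
    train_idx: list[int] = []
    for label in sorted(by_label):
        idx = np.asarray(by_label[label])
        if len(idx) < 2:
            raise ValueError(
                f"class {label!r} has {len(idx)} record(s); "
                "stratified splitting needs at least 2 per class"
            )
        perm = idx[rng.permutation(len(idx))]
        n_test = int(math.floor(test_fraction * len(idx)))
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    return SplitSpec(tuple(sorted(train_idx)), tuple(sorted(test_idx)),
                     test_fraction, seed, True)
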