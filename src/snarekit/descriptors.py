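"""Fixed-length numeric descriptors for variable-length protein sequences.

Gradient-boosted trees need every protein represented by the same number
of features, so each encoder here maps a length-L amino-acid sequence to a
fixed-dimension vector:

========  =========  =====================================================
encoder   dimension  summary
========  =========  =====================================================
AAC       20         single-residue frequencies
GDC       400        ordered residue-pair frequencies at one fixed gap g
ASDC      400        ordered pair frequencies accumulated over ALL gaps
                     g = 1..L-1, jointly normalised (adaptive skip
                     dipeptide composition)
CKSAAP    400*(k+1)  concatenated pair-frequency blocks for spacings
                     0..kmax (block at spacing k equals GDC at g = k+1)
DDE       400        adjacent-pair frequencies standardised against a
                     codon-usage-derived mean and variance
QSOrder   40+2*nlag  residue composition plus lagged physicochemical
                     coupling terms under two distance matrices
========  =========  =====================================================

Ordered pairs are indexed ``20*index(first) + index(second)`` with amino
acids in fixed alphabetical order ``ACDEFGHIKLMNPQRSTVWY``; all column
orderings are deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._aadata import CODON_COUNTS, N_SENSE_CODONS, qsorder_distance_matrices
from .sequence_io import ALPHABET, POSITIVE, SequenceDataset

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
_CODON_VEC = np.array([CODON_COUNTS[a] for a in ALPHABET], dtype=float)

#: All 400 ordered dipeptides in canonical column order.
DIPEPTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)

DESCRIPTOR_NAMES = ("AAC", "GDC", "ASDC", "CKSAAP", "DDE", "QSOrder")


@dataclass(frozen=True)
class DescriptorConfig:
    """Which encoder to run and its parameters.

    Only the parameters relevant to ``name`` are consulted: ``g`` (GDC),
    ``kmax`` (CKSAAP), ``nlag`` and ``w`` (QSOrder).
    """

    name: str
    g: int = 1
    kmax: int = 3
    nlag: int = 2
    w: float = 0.1

    def __post_init__(self) -> None:
        if self.name not in DESCRIPTOR_NAMES:
            raise ValueError(
                f"unknown descriptor {self.name!r}; expected one of "
                f"{DESCRIPTOR_NAMES}"
            )
        if self.g < 1:
            raise ValueError("g must be >= 1")
        if self.kmax < 0:
            raise ValueError("kmax must be >= 0")
        if self.nlag < 1:
            raise ValueError("nlag must be >= 1")
        if not 0.0 < self.w <= 1.0:
            raise ValueError("w must lie in (0, 1]")

    @property
    def dimension(self) -> int:
        return {
            "AAC": 20,
            "GDC": 400,
            "ASDC": 400,
            "CKSAAP": 400 * (self.kmax + 1),
            "DDE": 400,
            "QSOrder": 40 + 2 * self.nlag,
        }[self.name]

    @property
    def min_length(self) -> int:
        """Shortest sequence the encoder is defined for."""
        return {
            "AAC": 1,
            "GDC": self.g + 1,
            "ASDC": 2,
            "CKSAAP": self.kmax + 2,
            "DDE": 2,
            "QSOrder": self.nlag + 1,
        }[self.name]

    def column_names(self) -> list[str]:
        if self.name == "AAC":
            return list(ALPHABET)
        if self.name in ("GDC", "ASDC", "DDE"):
            return list(DIPEPTIDES)
        if self.name == "CKSAAP":
            return [
                f"{pair}|k={k}"
                for k in range(self.kmax + 1)
                for pair in DIPEPTIDES
            ]
        names: list[str] = []
        for group in ("pc", "gr"):  # physicochemical, Grantham
            names.extend(f"{a}|{group}" for a in ALPHABET)
            names.extend(f"tau{d}|{group}" for d in range(1, self.nlag + 1))
        return names


@dataclass
class FeatureMatrix:
    """samples x dimension numeric table with descriptor provenance."""

    values: np.ndarray
    row_ids: list[str]
    column_names: list[str]
    descriptor: DescriptorConfig | None = None
    labels: np.ndarray | None = None  # 1 = positive class, 0 = negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length does not match values")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match values")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels length does not match values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            self.values[idx],
            [self.row_ids[i] for i in idx],
            list(self.column_names),
            self.descriptor,
            None if self.labels is None else self.labels[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.row_ids, columns=self.column_names
        )
        df.index.name = "id"
        return df

    def column_checksum(self) -> str:
        return hashlib.sha256(
            "\n".join(self.column_names).encode()
        ).hexdigest()[:16]

    def write_csv(self, path: str | Path) -> None:
        """Write values as CSV plus a one-line JSON sidecar with the
        descriptor provenance and a column checksum."""
        path = Path(path)
        df = self.to_frame()
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.to_csv(path)
        sidecar = {
            "descriptor": None
            if self.descriptor is None
            else {
                "name": self.descriptor.name,
                "g": self.descriptor.g,
                "kmax": self.descriptor.kmax,
                "nlag": self.descriptor.nlag,
                "w": self.descriptor.w,
            },
            "n_samples": self.n_samples,
            "dimension": self.dimension,
            "column_checksum": self.column_checksum(),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar) + "\n"
        )

    @staticmethod
    def read_csv(path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        descriptor = None
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            if meta.get("descriptor"):
                descriptor = DescriptorConfig(**meta["descriptor"])
        return FeatureMatrix(
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            descriptor,
            labels,
        )


def _encode_indices(sequence: str) -> np.ndarray:
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return np.array([_AA_INDEX[c] for c in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from exc


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: 20 single-residue frequencies summing to 1."""
    idx = _encode_indices(sequence)
    return np.bincount(idx, minlength=20) / len(idx)


def _gap_pair_counts(idx: np.ndarray, g: int) -> np.ndarray:
    pairs = idx[:-g] * 20 + idx[g:]
    return np.bincount(pairs, minlength=400).astype(float)


def gdc(sequence: str, g: int = 1) -> np.ndarray:
    """g-gap dipeptide composition: frequencies of ordered residue pairs
    (i, i+g), normalised by the L-g available pairs."""
    if g < 1:
        raise ValueError("g must be >= 1")
    idx = _encode_indices(sequence)
    if len(idx) <= g:
        raise ValueError(
            f"sequence length {len(idx)} admits no pairs at gap {g}"
        )
    return _gap_pair_counts(idx, g) / (len(idx) - g)


def asdc(sequence: str) -> np.ndarray:
    """Adaptive skip dipeptide composition.

    Accumulates ordered-pair counts over every gap g = 1..L-1 and
    normalises jointly, so every ordered position pair (i < j) contributes
    exactly once and the total count is L(L-1)/2.
    """
    idx = _encode_indices(sequence)
    L = len(idx)
    if L < 2:
        raise ValueError("ASDC needs a sequence of length >= 2")
    # counts[a, b] = #{i < j : seq[i] = a, seq[j] = b}, via the prefix
    # histogram before each position: O(20 L) and fully vectorised
    onehot = np.zeros((L, 20))
    onehot[np.arange(L), idx] = 1.0
    prefix = np.vstack([np.zeros(20), np.cumsum(onehot, axis=0)[:-1]])
    counts = prefix.T @ onehot
    total = counts.sum()
    assert total == L * (L - 1) / 2  # every (i < j) pair counted once
    return counts.ravel() / total


def cksaap(sequence: str, kmax: int = 3) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs: one 400-long frequency
    block per spacing k = 0..kmax; the k-block equals GDC at g = k+1."""
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    idx = _encode_indices(sequence)
    if len(idx) <= kmax + 1:
        raise ValueError(
            f"sequence length {len(idx)} too short for kmax={kmax} "
            f"(needs >= {kmax + 2})"
        )
    blocks = [
        _gap_pair_counts(idx, k + 1) / (len(idx) - k - 1)
        for k in range(kmax + 1)
    ]
    return np.concatenate(blocks)


def dde(sequence: str) -> np.ndarray:
    """Dipeptide deviation from expected mean.

    For each ordered dipeptide (r1, r2) the adjacent-pair frequency
    Dc = count/(L-1) is standardised against the theoretical mean
    Tm = (C_r1/61)(C_r2/61) implied by synonymous-codon usage, with
    variance Tv = Tm(1-Tm)/(L-1):  DDE = (Dc - Tm) / sqrt(Tv).
    """
    idx = _encode_indices(sequence)
    L = len(idx)
    if L < 2:
        raise ValueError("DDE needs a sequence of length >= 2")
    dc = _gap_pair_counts(idx, 1) / (L - 1)
    tm = np.outer(_CODON_VEC / N_SENSE_CODONS, _CODON_VEC / N_SENSE_CODONS)
    tm = tm.ravel()
    tv = tm * (1.0 - tm) / (L - 1)
    return (dc - tm) / np.sqrt(tv)


def qsorder(sequence: str, nlag: int = 2, w: float = 0.1) -> np.ndarray:
    """Quasi-sequence-order descriptor.

    For each of two residue distance matrices (a physicochemical distance
    and Grantham's distance) computes the sequence-order coupling numbers
    tau_d = sum_i dist(seq[i], seq[i+d])^2 for d = 1..nlag, then emits the
    normalisation group  [f_1..f_20, w*tau_1..w*tau_nlag] / (sum f + w sum tau)
    where f_r are residue counts.  Each group sums to 1; dimension is
    40 + 2*nlag.
    """
    if nlag < 1:
        raise ValueError("nlag must be >= 1")
    if not 0.0 < w <= 1.0:
        raise ValueError("w must lie in (0, 1]")
    idx = _encode_indices(sequence)
    L = len(idx)
    if L <= nlag:
        raise ValueError(
            f"sequence length {L} must exceed nlag={nlag}"
        )
    counts = np.bincount(idx, minlength=20).astype(float)
    out: list[np.ndarray] = []
    for matrix in qsorder_distance_matrices():
        tau = np.array(
            [
                (matrix[idx[:-d], idx[d:]] ** 2).sum()
                for d in range(1, nlag + 1)
            ]
        )
        denom = counts.sum() + w * tau.sum()
        out.append(np.concatenate([counts, w * tau]) / denom)
    return np.concatenate(out)


def encode_sequence(sequence: str, config: DescriptorConfig) -> np.ndarray:
    if config.name == "AAC":
        return aac(sequence)
    if config.name == "GDC":
        return gdc(sequence, config.g)
    if config.name == "ASDC":
        return asdc(sequence)
    if config.name == "CKSAAP":
        return cksaap(sequence, config.kmax)
    if config.name == "DDE":
        return dde(sequence)
    return qsorder(sequence, config.nlag, config.w)


def encode_dataset(
    dataset: SequenceDataset, config: DescriptorConfig
) -> FeatureMatrix:
    """Encode every record of a dataset, preserving record order.

    Labels (positive -> 1, anything else -> 0) are carried through.
    Raises if any record is shorter than the encoder's minimum length,
    naming the offending ids.
    """
    too_short = [r.id for r in dataset if len(r) < config.min_length]
    if too_short:
        raise ValueError(
            f"{config.name} needs length >= {config.min_length}; "
            f"records too short: {', '.join(too_short)}"
        )
    if len(dataset) == 0:
        raise ValueError("cannot encode an empty dataset")
    values = np.stack([encode_sequence(r.sequence, config) for r in dataset])
    labels = np.array([1 if r.label == POSITIVE else 0 for r in dataset])
    return FeatureMatrix(
        values, dataset.ids, config.column_names(), config, labels
    )


def concat_features(matrices: Iterable[FeatureMatrix]) -> FeatureMatrix:
    """Stitch several feature matrices for the same samples side by side.

    Column names are prefixed with their descriptor name so provenance
    survives concatenation.  All inputs must share identical row ids in
    identical order.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("need at least one matrix")
    if len(mats) == 1:
        return mats[0]
    first = mats[0]
    for m in mats[1:]:
        if m.row_ids != first.row_ids:
            raise ValueError("row ids differ between matrices")
    names: list[str] = []
    for m in mats:
        prefix = m.descriptor.name if m.descriptor is not None else "feat"
        names.extend(f"{prefix}:{c}" for c in m.column_names)
    labels = next((m.labels for m in mats if m.labels is not None), None)
    return FeatureMatrix(
        np.hstack([m.values for m in mats]),
        list(first.row_ids),
        names,
        None,
        labels,
    )
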