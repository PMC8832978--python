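"""Synthetic two-class sequence datasets and numeric point clouds.

Real SNARE benchmarks are downloads; everything in this package is
testable offline against synthetic data with controlled statistical
structure.  Sequences are drawn from first-order Markov chains over the
20 canonical amino acids — not i.i.d. residues — so that order-sensitive
descriptors (ASDC, CKSAAP) can be meaningfully distinguished from
composition-only encodings (AAC).

Two separation modes:

* ``composition-shift`` — the positive class residue distribution is
  tilted away from uniform by `separation`; both composition- and
  order-aware descriptors can detect this.
* ``order-shift`` — the positive transition matrix is a doubly stochastic
  perturbation of uniform (Sinkhorn-balanced), so its stationary
  single-residue composition stays exactly uniform: the classes differ in
  residue ORDER but not in residue composition, making AAC blind to the
  signal while skip-dipeptide encoders see it.

``separation = 0`` collapses both classes onto the identical generator
(the null construction).  Everything is deterministic per seed.

The generators make no attempt to imitate real SNARE motif biology
(heptad repeats, coiled coils); they are statistical stand-ins only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .descriptors import FeatureMatrix
from .sequence_io import (
    ALPHABET,
    NEGATIVE,
    POSITIVE,
    ProteinRecord,
    SequenceDataset,
    write_fasta,
)

MODES = ("composition-shift", "order-shift")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic two-class sequence dataset.

    The default 1:10 class ratio mirrors the imbalance of curated SNARE
    collections, where positives are roughly a tenth of the negatives.
    """

    n_pos: int = 200
    n_neg: int = 2000
    length_range: tuple[int, int] = (50, 200)
    separation: float = 0.5
    mode: str = "composition-shift"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        lmin, lmax = self.length_range
        if lmin < 3 or lmax < lmin:
            raise ValueError(
                "length_range must satisfy 3 <= Lmin <= Lmax"
            )
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def _sinkhorn_doubly_stochastic(
    raw: np.ndarray, iterations: int = 200
) -> np.ndarray:
    """Balance a positive matrix to doubly stochastic (rows and columns
    sum to 1), so the uniform distribution is stationary."""
    m = raw.copy()
    for _ in range(iterations):
        m /= m.sum(axis=1, keepdims=True)
        m /= m.sum(axis=0, keepdims=True)
    return m / m.sum(axis=1, keepdims=True)


def _transition_matrices(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) transition matrices per the spec's mode."""
    uniform = np.full((20, 20), 1.0 / 20)
    if spec.separation == 0.0:
        return uniform, uniform
    if spec.mode == "composition-shift":
        tilt = rng.standard_normal(20)
        probs = np.exp(spec.separation * tilt)
        probs /= probs.sum()
        positive = np.tile(probs, (20, 1))
    else:  # order-shift: stationary composition stays exactly uniform
        noise = rng.standard_normal((20, 20))
        positive = _sinkhorn_doubly_stochastic(
            np.exp(spec.separation * noise)
        )
    return positive, uniform


def _sample_chain(
    transition: np.ndarray, length: int, rng: np.random.Generator
) -> str:
    """One Markov chain realisation, initial state from the stationary
    residue distribution of `transition`."""
    cum = np.cumsum(transition, axis=1)
    # stationary distribution via the left eigenvector at eigenvalue 1
    eigvals, eigvecs = np.linalg.eig(transition.T)
    stat = np.real(eigvecs[:, np.argmax(np.real(eigvals))])
    stat = np.abs(stat) / np.abs(stat).sum()
    states = np.empty(length, dtype=np.intp)
    states[0] = rng.choice(20, p=stat)
    u = rng.random(length)
    for i in range(1, length):
        # min() guards against u landing beyond a cum row whose float
        # sum fell marginally short of 1
        states[i] = min(np.searchsorted(cum[states[i - 1]], u[i]), 19)
    return "".join(ALPHABET[s] for s in states)


def generate_dataset(spec: SyntheticSpec) -> SequenceDataset:
    """Draw a labelled two-class dataset per `spec` (deterministic per
    seed; positives first, then negatives)."""
    rng = np.random.default_rng(spec.seed)
    t_pos, t_neg = _transition_matrices(spec, rng)
    lmin, lmax = spec.length_range
    records: list[ProteinRecord] = []
    for label, prefix, count, transition in (
        (POSITIVE, "pos", spec.n_pos, t_pos),
        (NEGATIVE, "neg", spec.n_neg, t_neg),
    ):
        lengths = rng.integers(lmin, lmax + 1, size=count)
        for i, length in enumerate(lengths):
            records.append(
                ProteinRecord(
                    f"{prefix}_{i:05d}",
                    _sample_chain(transition, int(length), rng),
                    label,
                )
            )
    return SequenceDataset(records)


def write_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit pos.fasta / neg.fasta plus a JSON manifest of the generating
    spec; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = generate_dataset(spec)
    paths: dict[str, Path] = {}
    for label, stem in ((POSITIVE, "pos"), (NEGATIVE, "neg")):
        subset = SequenceDataset(
            [r for r in dataset if r.label == label]
        )
        path = out_dir / f"{stem}.fasta"
        write_fasta(subset, path)
        paths[stem] = path
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(asdict(spec), indent=1) + "\n")
    paths["manifest"] = manifest
    return paths


def generate_clusters(
    n_per_class: int,
    dim: int,
    class_means: Sequence[Sequence[float]],
    noise_sd: float,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Spherical Gaussian clouds, one per class mean, for geometry tests.

    ``class_means`` holds one mean vector per class in label order
    (label 0 first); labels beyond 1 are allowed but the pipeline is
    binary.  Returns a FeatureMatrix (with labels attached) and the label
    vector.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    means = np.asarray(class_means, dtype=float)
    if means.ndim != 2 or means.shape[0] < 1 or means.shape[1] != dim:
        raise ValueError(
            f"class_means must be (n_classes, {dim}); got {means.shape}"
        )
    rng = np.random.default_rng(seed)
    values = np.vstack(
        [
            mean + noise_sd * rng.standard_normal((n_per_class, dim))
            for mean in means
        ]
    )
    labels = np.repeat(np.arange(len(means)), n_per_class)
    row_ids = [
        f"c{c}_{i:04d}" for c in range(len(means)) for i in range(n_per_class)
    ]
    columns = [f"x{j}" for j in range(dim)]
    matrix = FeatureMatrix(values, row_ids, columns, None, labels)
    return matrix, labels
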