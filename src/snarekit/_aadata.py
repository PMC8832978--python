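"""Amino-acid reference data used by the descriptor encoders.

Three pieces of chemistry live here:

* synonymous-codon counts of the standard genetic code (61 sense codons),
  used by the dipeptide-deviation-from-expected-mean (DDE) descriptor;
* Grantham's amino-acid distance, recomputed from his composition /
  polarity / side-chain-volume formula,
  ``D_ij = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)``
  with ``rho`` fixed so the mean over the 190 unordered pairs is 100;
* a synthetic physicochemical distance built from three classical residue
  scales (Tanford-style hydrophobicity, Hopp–Woods hydrophilicity,
  side-chain mass), each standardised to zero mean and unit variance, with
  ``d_ij = sqrt(mean_k (P_k(i) - P_k(j))^2)``.  It is a stand-in
  constructed here for the Schneider–Wrede physicochemical distance
  commonly paired with Grantham's in quasi-sequence-order encoders; it is
  NOT the Schneider–Wrede matrix.

The two matrices are shipped as versioned JSON package data
(``data/grantham.json``, ``data/physchem_distance_synthetic.json``) and
loaded lazily; the generator functions here are the single source of truth
for their contents.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .sequence_io import ALPHABET

#: Number of synonymous codons per residue in the standard genetic code.
CODON_COUNTS: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2,
    "G": 4, "H": 2, "I": 3, "K": 2, "L": 6,
    "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6,
    "S": 6, "T": 4, "V": 4, "W": 1, "Y": 2,
}
N_SENSE_CODONS = 61
assert sum(CODON_COUNTS.values()) == N_SENSE_CODONS

# Grantham's residue properties: composition c (atomic-weight ratio of
# hetero elements in the side chain), polarity p, molecular volume v.
_GRANTHAM_C = {
    "A": 0.00, "C": 2.75, "D": 1.38, "E": 0.92, "F": 0.00,
    "G": 0.74, "H": 0.58, "I": 0.00, "K": 0.33, "L": 0.00,
    "M": 0.00, "N": 1.33, "P": 0.39, "Q": 0.89, "R": 0.65,
    "S": 1.42, "T": 0.71, "V": 0.00, "W": 0.13, "Y": 0.20,
}
_GRANTHAM_P = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}
_GRANTHAM_V = {
    "A": 31.0, "C": 55.0, "D": 54.0, "E": 83.0, "F": 132.0,
    "G": 3.0, "H": 96.0, "I": 111.0, "K": 119.0, "L": 111.0,
    "M": 105.0, "N": 56.0, "P": 32.5, "Q": 85.0, "R": 124.0,
    "S": 32.0, "T": 61.0, "V": 84.0, "W": 170.0, "Y": 136.0,
}
_GRANTHAM_ALPHA = 1.833
_GRANTHAM_BETA = 0.1018
_GRANTHAM_GAMMA = 0.000399

# Classical residue scales for the synthetic physicochemical distance.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

DATA_VERSION = "1.0"


def _vec(table: dict[str, float]) -> np.ndarray:
    return np.array([table[a] for a in ALPHABET], dtype=float)


def compute_grantham_matrix() -> np.ndarray:
    """20x20 Grantham distance, rows/columns in :data:`ALPHABET` order."""
    c, p, v = _vec(_GRANTHAM_C), _vec(_GRANTHAM_P), _vec(_GRANTHAM_V)
    raw = np.sqrt(
        _GRANTHAM_ALPHA * (c[:, None] - c[None, :]) ** 2
        + _GRANTHAM_BETA * (p[:, None] - p[None, :]) ** 2
        + _GRANTHAM_GAMMA * (v[:, None] - v[None, :]) ** 2
    )
    # rho scales the mean off-diagonal distance to 100
    iu = np.triu_indices(20, k=1)
    rho = 100.0 / raw[iu].mean()
    return rho * raw


def compute_physchem_matrix() -> np.ndarray:
    """Synthetic 20x20 physicochemical distance (see module docstring)."""
    props = np.stack(
        [_vec(_HYDROPHOBICITY), _vec(_HYDROPHILICITY), _vec(_SIDECHAIN_MASS)]
    )
    props = (props - props.mean(axis=1, keepdims=True)) / props.std(
        axis=1, keepdims=True
    )
    diff = props[:, :, None] - props[:, None, :]
    return np.sqrt((diff**2).mean(axis=0))


def matrix_to_json(matrix: np.ndarray, name: str) -> str:
    payload = {
        "name": name,
        "version": DATA_VERSION,
        "alphabet": ALPHABET,
        "matrix": [[round(float(x), 6) for x in row] for row in matrix],
    }
    return json.dumps(payload, indent=1)


@lru_cache(maxsize=None)
def load_distance_matrix(name: str) -> np.ndarray:
    """Load a shipped distance matrix by file stem (e.g. ``grantham``)."""
    text = (
        resources.files("snarekit").joinpath(f"data/{name}.json").read_text()
    )
    payload = json.loads(text)
    if payload["alphabet"] != ALPHABET:
        raise ValueError(f"distance matrix {name!r} has unexpected alphabet")
    m = np.asarray(payload["matrix"], dtype=float)
    if m.shape != (20, 20):
        raise ValueError(f"distance matrix {name!r} has shape {m.shape}")
    return m


def qsorder_distance_matrices() -> tuple[np.ndarray, np.ndarray]:
    """The (physicochemical, Grantham) matrix pair used by QSOrder."""
    return (
        load_distance_matrix("physchem_distance_synthetic"),
        load_distance_matrix("grantham"),
    )
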