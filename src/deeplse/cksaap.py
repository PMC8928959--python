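"""Composition of k-spaced amino acid pairs (CKSAAP) descriptor.

For each gap ``j = 0..k`` the descriptor counts every ordered residue pair
``(s[i], s[i+j+1])`` — i.e. pairs separated by exactly ``j`` intervening
residues — over all positions of the sequence.  Each gap contributes a
block of 400 ordered pairs; the blocks are stacked to a vector of length
``400*(k+1)``.

Ordering contract (part of the on-disk format): the alphabet is
alphabetical ``ACDEFGHIKLMNPQRSTVWY``; within a block pairs are ordered
``AA, AC, ..., AY, CA, ..., YY`` (pair index = ``20*first + second``);
blocks are ordered ``j = 0..k``.  Column names are ``j{gap}_{pair}``,
e.g. ``j0_AA``, ``j2_CY``.

By default each gap-``j`` block is normalised by the number of available
positions ``L - j - 1``, so entries are pair frequencies in ``[0, 1]`` and
a block sums to 1 whenever the sequence is long enough (``L > j+1``).
Raw counts are available with ``normalize=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .seqio import STANDARD_ALPHABET, LabeledDataset, ProteinRecord

_INDEX = {c: i for i, c in enumerate(STANDARD_ALPHABET)}
_PAIRS = [a + b for a in STANDARD_ALPHABET for b in STANDARD_ALPHABET]

__all__ = [
    "CksaapConfig",
    "CksaapVector",
    "cksaap_encode",
    "encode_dataset",
    "feature_names",
    "write_feature_csv",
    "read_feature_csv",
]


@dataclass(frozen=True)
class CksaapConfig:
    """Parameters of the CKSAAP encoding.

    k is the maximum gap; gaps above 9 are permitted but unusual and warned.
    """

    k: int = 6
    normalize: bool = True
    alphabet: str = field(default=STANDARD_ALPHABET)

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if self.alphabet != STANDARD_ALPHABET:
            raise ValueError("only the canonical 20-letter alphabet is supported")
        if self.k > 9:
            warnings.warn(
                f"k={self.k} is beyond the usual 0..9 range; the feature vector "
                f"will have {400 * (self.k + 1)} dimensions",
                stacklevel=2,
            )

    @property
    def n_features(self) -> int:
        return 400 * (self.k + 1)


@dataclass(frozen=True)
class CksaapVector:
    """The stacked 400*(k+1) pair-composition descriptor of one sequence."""

    values: np.ndarray
    k: int
    sequence_length: int

    def block(self, j: int) -> np.ndarray:
        """The 400-vector for gap ``j``."""
        if not 0 <= j <= self.k:
            raise IndexError(f"gap {j} outside 0..{self.k}")
        return self.values[400 * j : 400 * (j + 1)]


def feature_names(k: int) -> list[str]:
    """Column names ``j{gap}_{pair}`` in canonical order."""
    return [f"j{j}_{p}" for j in range(k + 1) for p in _PAIRS]


def _sequence_indices(sequence: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid amino-acid letter {exc.args[0]!r} in sequence") from None


def cksaap_encode(sequence: str, config: CksaapConfig) -> CksaapVector:
    """Encode one validated sequence.

    A sequence too short for some gap block (``L < j+2``) yields an
    all-zero block and a warning rather than an error, so short peptides
    remain encodable.
    """
    L = len(sequence)
    if L < 1:
        raise ValueError("sequence must be non-empty")
    idx = _sequence_indices(sequence)
    out = np.zeros(config.n_features, dtype=np.float64)
    for j in range(config.k + 1):
        n_pos = L - j - 1
        if n_pos < 1:
            warnings.warn(
                f"sequence of length {L} too short for gap {j}; block left zero",
                stacklevel=2,
            )
            continue
        pair_idx = 20 * idx[:n_pos] + idx[j + 1 :]
        counts = np.bincount(pair_idx, minlength=400).astype(np.float64)
        if config.normalize:
            counts /= n_pos
        out[400 * j : 400 * (j + 1)] = counts
    return CksaapVector(values=out, k=config.k, sequence_length=L)


def encode_dataset(
    records: Union[LabeledDataset, Sequence[ProteinRecord]],
    config: CksaapConfig,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode a dataset to a feature matrix.

    Returns ``(X, y, ids)`` where rows of ``X`` follow record order and
    ``y[i]`` is the record label (-1 where unlabelled).
    """
    recs = list(records)
    if not recs:
        raise ValueError("cannot encode an empty dataset")
    X = np.empty((len(recs), config.n_features), dtype=np.float64)
    y = np.empty(len(recs), dtype=np.int64)
    ids = []
    for i, rec in enumerate(recs):
        X[i] = cksaap_encode(rec.sequence, config).values
        y[i] = -1 if rec.label is None else rec.label
        ids.append(rec.id)
    return X, y, ids


def write_feature_csv(path, X: np.ndarray, ids: Iterable[str], k: int) -> None:
    """Write a feature matrix as CSV with the versioned column naming."""
    df = pd.DataFrame(X, columns=feature_names(k))
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False)


def read_feature_csv(path) -> tuple[np.ndarray, list[str], int]:
    """Read a feature CSV back; returns ``(X, ids, k)``."""
    df = pd.read_csv(path)
    if df.columns[0] != "id":
        raise ValueError("feature CSV must have 'id' as its first column")
    cols = list(df.columns[1:])
    k = len(cols) // 400 - 1
    if cols != feature_names(k):
        raise ValueError("feature CSV columns do not match the canonical CKSAAP ordering")
    return df[cols].to_numpy(dtype=np.float64), df["id"].astype(str).tolist(), k
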