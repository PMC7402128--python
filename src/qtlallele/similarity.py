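"""Genetic-similarity matrix on SNPLDB markers and its top eigenvectors,
used as fixed population-structure covariates in the association scan."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .snpldb import MarkerSet


def genetic_similarity(markers: MarkerSet) -> np.ndarray:
    """similarity(i, j) = fraction of markers where i and j carry the same
    allele; symmetric with unit diagonal."""
    if len(markers) == 0:
        raise DataError("empty marker set")
    codes = markers.code_matrix()  # (n_markers, n_acc)
    n_acc = codes.shape[1]
    sim = np.zeros((n_acc, n_acc))
    for row in codes:
        sim += row[:, None] == row[None, :]
    sim /= len(markers)
    np.fill_diagonal(sim, 1.0)
    return sim


@dataclass
class EigenBasis:
    """Top-k eigenpairs of the similarity matrix (descending eigenvalues);
    each vector's largest-magnitude entry is made positive."""

    vectors: np.ndarray  # (n_accessions, k)
    values: np.ndarray  # (k,)

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def top_eigenvectors(sim: np.ndarray, k: int = 10) -> EigenBasis:
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if k > n:
        raise DataError(f"k={k} exceeds matrix size n={n}")
    if k >= n:
        warnings.warn("k equals the panel size; structure covariates will "
                      "absorb all variation", stacklevel=2)
    vals, vecs = np.linalg.eigh((sim + sim.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i_max = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i_max, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return EigenBasis(vectors=vecs, values=vals)
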