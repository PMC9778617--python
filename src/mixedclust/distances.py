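"""Hamming distances, distance vectors, and their uniform-null expectations.

The method summarizes the data's geometry around a candidate cluster center
by the *distance vector* (DV): the frequency of records at each Hamming
distance 0..d from the reference position.  Under the null of no cluster
structure, records are uniform on the full product lattice and the expected
DV (the *uniform distance vector*, UDV) has a closed form

    UDV = (n / prod(levels)) * e,

where ``e[j]`` is the j-th elementary symmetric polynomial in
``(m_1 - 1, ..., m_d - 1)``: the number of lattice points at Hamming
distance exactly j from any fixed reference (the lattice is vertex
transitive, so the reference does not matter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DistanceVector",
    "UniformDistanceVector",
    "hamming",
    "pairwise_hamming",
    "distance_vector",
    "distance_vector_table",
    "uniform_star",
    "uniform_dv_categorical",
    "uniform_dv_quantized",
]


@dataclass
class DistanceVector:
    """Observed frequencies of Hamming distances from one reference point."""

    counts: np.ndarray
    ref: np.ndarray
    portion: str = "categorical"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.ref = np.asarray(self.ref)


@dataclass
class UniformDistanceVector:
    """Expected distance-vector frequencies under the uniform null.

    ``star`` is the combinatorial lattice-shell size vector (U* or V*);
    ``expected = n / total_states * star``.
    """

    expected: np.ndarray
    star: np.ndarray
    total_states: int
    n: int


def hamming(u, v) -> int:
    """Number of coordinates at which two code vectors differ."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return int(np.count_nonzero(u != v))


def pairwise_hamming(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Hamming distances between the rows of A (nA x d) and B (nB x d).

    Accumulates one attribute at a time so the intermediate is a single
    boolean (nA, nB) plane rather than an (nA, nB, d) cube.
    """
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError("row length mismatch")
    out = np.zeros((A.shape[0], B.shape[0]), dtype=np.int32)
    for j in range(A.shape[1]):
        out += A[:, j, None] != B[None, :, j]
    return out


def distance_vector(codes: np.ndarray, ref) -> DistanceVector:
    """Observed DV of the rows of ``codes`` relative to position ``ref``.

    ``counts[j]`` is the number of rows at Hamming distance exactly j;
    the counts sum to the number of rows.
    """
    codes = np.asarray(codes)
    ref = np.asarray(ref)
    if codes.shape[1] != ref.shape[0]:
        raise ValueError("reference length must equal the number of columns")
    d = codes.shape[1]
    dists = (codes != ref[None, :]).sum(axis=1)
    counts = np.bincount(dists, minlength=d + 1)
    return DistanceVector(counts=counts, ref=ref)


def distance_vector_table(codes: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """DVs of ``codes`` (n x d) against every row of ``refs`` (r x d) at once.

    Returns an (r, d+1) integer matrix whose row k is the DV for refs[k].
    """
    codes = np.asarray(codes)
    refs = np.asarray(refs)
    d = codes.shape[1]
    D = pairwise_hamming(refs, codes)  # (r, n)
    r = refs.shape[0]
    flat = (np.arange(r, dtype=np.int64)[:, None] * (d + 1) + D).ravel()
    table = np.bincount(flat, minlength=r * (d + 1))
    return table.reshape(r, d + 1)


def uniform_star(levels: Sequence[int]) -> np.ndarray:
    """Lattice shell sizes: elementary symmetric polynomials of (m_j - 1).

    Computed as the coefficients of ``prod_j (1 + (m_j - 1) x)`` by
    polynomial accumulation, algebraically identical to the sum-over-subsets
    definition but O(d^2) instead of exponential.
    """
    levels = list(levels)
    if any(m < 2 for m in levels):
        raise ValueError("every level count must be >= 2")
    coef = np.zeros(len(levels) + 1)
    coef[0] = 1.0
    for j, m in enumerate(levels):
        w = float(m - 1)
        coef[1 : j + 2] = coef[1 : j + 2] + w * coef[0 : j + 1]
    return coef


def uniform_dv_categorical(n: int, levels: Sequence[int]) -> UniformDistanceVector:
    """Closed-form UDV for a lattice with the given per-column level counts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    star = uniform_star(levels)
    total = int(np.prod([int(m) for m in levels], dtype=object))
    expected = n * star / total
    return UniformDistanceVector(expected=expected, star=star, total_states=total, n=n)


def uniform_dv_quantized(n: int, levels: Sequence[int]) -> UniformDistanceVector:
    """UDV for the quantized continuous block; same algebra with l_j levels."""
    return uniform_dv_categorical(n, levels)
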