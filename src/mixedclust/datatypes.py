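"""Core in-memory containers shared across the package.

A mixed dataset couples an ``n x p`` block of nominal categorical attributes
with an ``n x q`` block of continuous attributes.  Categorical values are
stored as integer codes into per-column level sets, which keeps Hamming
arithmetic cheap while the original labels remain available for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["MixedDataset", "QuantizedDataset"]


@dataclass
class MixedDataset:
    """Rectangular mixed-type data: categorical codes plus continuous values.

    Parameters
    ----------
    X : ndarray of shape (n, p), integer
        Categorical block, coded ``0 .. m_j - 1`` per column.
    levels : sequence of arrays
        For each categorical column, the ordered level set ``A_j``; code ``c``
        in column ``j`` means level ``levels[j][c]``.  Each ``m_j >= 2``.
    Z : ndarray of shape (n, q), float
        Continuous block; must be free of missing values.
    ids : ndarray of shape (n,)
        Record identifiers, preserved through fitting and output.
    labels : ndarray of shape (n,), optional
        Known class labels (simulation truth or a declared label column).
    """

    X: np.ndarray
    levels: Sequence[np.ndarray]
    Z: np.ndarray
    ids: np.ndarray = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.Z = np.asarray(self.Z, dtype=float)
        if self.X.ndim != 2 or self.Z.ndim != 2:
            raise ValueError("X and Z must be two-dimensional")
        if self.X.shape[0] != self.Z.shape[0]:
            raise ValueError("X and Z must have the same number of rows")
        if len(self.levels) != self.X.shape[1]:
            raise ValueError("one level set per categorical column is required")
        if self.ids is None:
            self.ids = np.arange(self.X.shape[0])
        self.ids = np.asarray(self.ids)
        if np.isnan(self.Z).any():
            raise ValueError("continuous block contains missing values")
        for j, lv in enumerate(self.levels):
            if len(lv) < 2:
                raise ValueError(f"categorical column {j} has fewer than 2 levels")
            col = self.X[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) >= len(lv):
                raise ValueError(f"code out of range in categorical column {j}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def m(self) -> tuple[int, ...]:
        """Number of levels ``m_j`` of each categorical attribute."""
        return tuple(len(lv) for lv in self.levels)

    def decode_categorical(self, codes: np.ndarray) -> list:
        """Translate a length-p code vector back to original level values."""
        codes = np.asarray(codes)
        return [self.levels[j][codes[j]] for j in range(self.p)]


@dataclass
class QuantizedDataset:
    """A :class:`MixedDataset` together with its M-level quantization.

    ``Q[i, k]`` is the grid cell (``1 .. M``) of the standardized continuous
    value ``Z[i, k]``; all q columns share the single level count ``M``.
    ``zmin``/``zmax`` are the per-column extrema used for standardization.
    """

    base: MixedDataset
    Q: np.ndarray
    M: int
    zmin: np.ndarray = None
    zmax: np.ndarray = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q)
        if self.Q.shape != self.base.Z.shape:
            raise ValueError("Q must match the shape of the continuous block")
        if self.Q.min(initial=1) < 1 or self.Q.max(initial=1) > self.M:
            raise ValueError("quantization codes must lie in 1..M")

    @property
    def n(self) -> int:
        return self.base.n

    @property
    def p(self) -> int:
        return self.base.p

    @property
    def q(self) -> int:
        return self.base.q

    @property
    def l(self) -> tuple[int, ...]:
        """Quantization level counts ``l_j`` (all equal to M)."""
        return (self.M,) * self.base.q
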