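"""Quantization of the continuous block and adaptive selection of its level.

Continuous attributes are min-max standardized onto [0, 1] columnwise and
then cut into M equal-width bins, so the continuous portion lives on the
same kind of lattice as the categorical one.  The grid resolution M is
chosen adaptively: the full clustering is run at each candidate M and the
one-way ANOVA F statistic of the continuous attributes grouped by the
resulting memberships (averaged over columns) picks the winner — the M
whose clusters best separate the raw continuous data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datatypes import MixedDataset, QuantizedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "LevelSelectionResult",
    "standardize",
    "quantize",
    "quantize_dataset",
    "select_level",
    "DEFAULT_GRID",
]

#: Default candidate quantization levels.
DEFAULT_GRID: tuple[int, ...] = tuple(range(5, 21))


@dataclass
class LevelSelectionResult:
    """Grid search over quantization levels with per-candidate F statistics."""

    grid: list
    f_stats: list
    chosen_M: int
    models: list = field(default_factory=list)


def standardize(Z: np.ndarray) -> np.ndarray:
    """Map each continuous column affinely onto [0, 1].

    ``z~ = (z - z_min) / (z_max - z_min)`` columnwise; invariant to positive
    affine transforms of any column.  A constant column (z_max == z_min)
    carries no clustering signal and is mapped to all zeros with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("Z must be an (n >= 2) x q matrix")
    zmin = Z.min(axis=0)
    zmax = Z.max(axis=0)
    span = zmax - zmin
    flat = span == 0
    if flat.any():
        logger.warning(
            "constant continuous column(s) %s standardized to 0",
            np.flatnonzero(flat).tolist(),
        )
    safe = np.where(flat, 1.0, span)
    out = (Z - zmin) / safe
    out[:, flat] = 0.0
    return out


def quantize(Zstd: np.ndarray, M: int) -> np.ndarray:
    """Cut standardized values into M equal-width bins coded 1..M.

    Value v gets code ``floor(v*M) + 1`` (half-open bins ``[(m-1)/M, m/M)``),
    except v == 1 which belongs to the top bin M so the columnwise maximum
    receives a code.  Monotone in v.
    """
    Zstd = np.asarray(Zstd, dtype=float)
    if M < 2:
        raise ValueError("M must be >= 2")
    if (Zstd < 0).any() or (Zstd > 1).any():
        raise ValueError("standardized values must lie in [0, 1]")
    codes = np.floor(Zstd * M).astype(np.int64) + 1
    return np.minimum(codes, M)


def quantize_dataset(data: MixedDataset, M: int) -> QuantizedDataset:
    """Standardize and quantize a dataset's continuous block at level M."""
    zmin = data.Z.min(axis=0)
    zmax = data.Z.max(axis=0)
    Q = quantize(standardize(data.Z), M)
    return QuantizedDataset(base=data, Q=Q, M=M, zmin=zmin, zmax=zmax)


def anova_f_summary(Z: np.ndarray, membership: np.ndarray) -> float:
    """Mean one-way ANOVA F over continuous columns, grouped by membership.

    Returns 0 when fewer than two groups exist (no between-group variation
    to test) and +inf when some column has zero within-group variance with
    distinct group means (perfect separation).
    """
    from .metrics import anova_f

    return anova_f(Z, membership)


def select_level(
    data: MixedDataset,
    grid: Sequence[int],
    cluster_fn: Callable[[MixedDataset, int], object],
) -> LevelSelectionResult:
    """Run the clustering at every candidate M and keep the largest-F level.

    ``cluster_fn(data, M)`` must return a fitted model exposing ``membership``
    and ``K``.  A candidate producing K <= 1 clusters scores F = 0.  Ties in
    the argmax go to the smaller M: a finer grid that does no better is not
    worth its cost.
    """
    grid = sorted(int(M) for M in grid)
    if not grid:
        raise ValueError("candidate grid is empty")
    if any(M < 2 for M in grid):
        raise ValueError("every candidate M must be >= 2")
    models = []
    f_stats = []
    for M in grid:
        model = cluster_fn(data, M)
        models.append(model)
        f = 0.0 if model.K <= 1 else anova_f_summary(data.Z, model.membership)
        f_stats.append(float(f))
    best = int(np.argmax(f_stats))  # first occurrence -> smallest M on ties
    return LevelSelectionResult(
        grid=list(grid), f_stats=f_stats, chosen_M=grid[best], models=models
    )
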