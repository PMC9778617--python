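"""Synthetic mixed-data generator for the method's simulation designs.

Each cluster k has a categorical center pattern C_k on the lattice and a
continuous mean mu_k.  Categorical attribute j of a record in cluster k
equals the center level with probability 0.7, and is uniform over the other
m_j - 1 levels otherwise; continuous attributes are independent normals
with the cluster mean and a shared variance.  Categorical centers are drawn
uniformly on the lattice subject to all pairwise Hamming distances
exceeding a separation floor (default 5 of p = 10 coordinates), so cluster
identity is carried redundantly by both portions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import MixedDataset
from .cluster import FitConfig, fit
from .metrics import information_gain_rate

__all__ = [
    "SimulationConfig",
    "PRESETS",
    "make_categorical_centers",
    "generate",
    "generate_null",
    "run_study",
]

_MAX_REJECTIONS = 100_000


@dataclass
class SimulationConfig:
    """Parameters of one simulated mixed dataset.

    cluster_sizes : records per cluster (their sum is n).
    p, q : numbers of categorical and continuous attributes.
    level_choices : pool from which each m_j is drawn uniformly.
    center_prob : probability mass on the center level (0.7 in the standard
        design; the remaining 0.3 is spread evenly over the other levels).
    cont_means : one continuous mean per cluster (shared by all q columns).
    cont_var : shared continuous variance.
    cont_df : optional Student-t degrees of freedom for heavy-tailed
        continuous noise (scaled by sqrt(cont_var)); None means normal.
    min_center_hd : pairwise categorical center separation floor.
    strict_separation : require HD strictly greater than the floor.
    seed : RNG seed; identical configs generate identical data.
    """

    cluster_sizes: Sequence[int] = (130, 45, 25)
    p: int = 10
    q: int = 9
    level_choices: Sequence[int] = (4, 5, 6)
    center_prob: float = 0.7
    cont_means: Sequence[float] = (2.0, 8.0, 16.0)
    cont_var: float = 0.25
    cont_df: float | None = None
    min_center_hd: int = 5
    strict_separation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cont_means) != len(self.cluster_sizes):
            raise ValueError("one continuous mean per cluster is required")
        if self.cont_var <= 0:
            raise ValueError("cont_var must be positive")
        if not (0.0 < self.center_prob <= 1.0):
            raise ValueError("center_prob must lie in (0, 1]")

    @property
    def n(self) -> int:
        return int(sum(self.cluster_sizes))

    @property
    def K(self) -> int:
        return len(self.cluster_sizes)


#: The two standard multi-cluster designs used throughout the package.
PRESETS: dict[str, dict] = {
    "table2": {"cluster_sizes": (130, 45, 25), "cont_means": (2.0, 8.0, 16.0)},
    "table3": {
        "cluster_sizes": (500, 200, 100, 100, 100),
        "cont_means": (2.0, 8.0, 16.0, 20.0, 35.0),
    },
}


def make_categorical_centers(
    K: int,
    p: int,
    levels: Sequence[int],
    min_hd: int,
    rng: np.random.Generator,
    strict: bool = True,
) -> np.ndarray:
    """Rejection-sample K lattice points with large pairwise separation.

    Draws uniform lattice points until all pairwise Hamming distances exceed
    ``min_hd`` (or reach it, with ``strict=False``).  Raises after 10^5
    rejections — the requested separation is then judged infeasible on this
    lattice (pairwise HD can never exceed p).
    """
    if strict and min_hd >= p and K >= 2:
        raise ValueError(f"pairwise Hamming distance > {min_hd} is impossible with p={p}")
    levels = np.asarray(levels)
    centers: list[np.ndarray] = []
    rejections = 0
    while len(centers) < K:
        cand = np.array([rng.integers(0, m) for m in levels])
        sep = [(cand != c).sum() for c in centers]
        ok = all(s > min_hd for s in sep) if strict else all(s >= min_hd for s in sep)
        if ok:
            centers.append(cand)
        else:
            rejections += 1
            if rejections > _MAX_REJECTIONS:
                raise ValueError(
                    f"could not place {K} centers at pairwise separation "
                    f"{'>' if strict else '>='} {min_hd} on this lattice"
                )
    return np.vstack(centers)


def generate(config: SimulationConfig) -> tuple[MixedDataset, np.ndarray]:
    """Draw one dataset from the design; returns (data, true labels 1..K).

    Fully reproducible from ``config.seed``.  All attributes are generated
    independently.
    """
    rng = np.random.default_rng(config.seed)
    p, q, K = config.p, config.q, config.K
    m = rng.choice(np.asarray(config.level_choices), size=p)
    centers = make_categorical_centers(
        K, p, m, config.min_center_hd, rng, strict=config.strict_separation
    )
    sizes = [int(s) for s in config.cluster_sizes]
    # categorical blocks first, so they are identical whichever continuous
    # noise family is chosen
    X_parts, Z_parts, lab_parts = [], [], []
    for k, nk in enumerate(sizes):
        Xk = np.tile(centers[k], (nk, 1))
        off_center = rng.random((nk, p)) >= config.center_prob
        # uniform over the m_j - 1 non-center levels
        alt = rng.integers(0, np.asarray(m) - 1, size=(nk, p))
        alt = alt + (alt >= Xk)
        X_parts.append(np.where(off_center, alt, Xk))
        lab_parts.append(np.full(nk, k + 1))
    for k, nk in enumerate(sizes):
        if config.cont_df is None:
            Zk = rng.normal(config.cont_means[k], np.sqrt(config.cont_var), (nk, q))
        else:
            Zk = config.cont_means[k] + np.sqrt(config.cont_var) * rng.standard_t(
                config.cont_df, (nk, q)
            )
        Z_parts.append(Zk)
    X = np.vstack(X_parts)
    Z = np.vstack(Z_parts)
    labels = np.concatenate(lab_parts)
    data = MixedDataset(
        X=X,
        levels=[np.arange(mj) for mj in m],
        Z=Z,
        ids=np.arange(config.n),
        labels=labels,
    )
    return data, labels


def generate_null(
    n: int,
    levels: Sequence[int],
    q: int,
    seed: int = 0,
) -> MixedDataset:
    """Structure-free data: categorical uniform on the lattice, continuous
    uniform on [0, 1].  Used to exercise the no-cluster null."""
    rng = np.random.default_rng(seed)
    levels = [int(m) for m in levels]
    X = np.column_stack([rng.integers(0, m, n) for m in levels])
    Z = rng.random((n, q))
    return MixedDataset(X=X, levels=[np.arange(m) for m in levels], Z=Z, ids=np.arange(n))


def run_study(
    design: str,
    replicates: int,
    seed: int,
    cont_var: float = 0.25,
    m_grid: Sequence[int] | None = None,
    fit_config: FitConfig | None = None,
) -> pd.DataFrame:
    """Generate -> fit -> evaluate over seeded replicates of a preset design.

    Returns a DataFrame with one row per replicate (CR, IGR, K_hat,
    chosen_M) whose ``.attrs['summary']`` holds the means and standard
    deviations.  Replicate r uses the child seed (seed, r), so any single
    replicate is reproducible in isolation.
    """
    if design not in PRESETS:
        raise ValueError(f"unknown design {design!r}; choose from {sorted(PRESETS)}")
    preset = PRESETS[design]
    cfg = fit_config or FitConfig()
    if m_grid is not None:
        cfg = FitConfig(**{**cfg.to_dict(), "m_grid": list(m_grid)})
    rows = []
    for r in range(int(replicates)):
        sim = SimulationConfig(
            cluster_sizes=preset["cluster_sizes"],
            cont_means=preset["cont_means"],
            cont_var=cont_var,
            seed=np.random.default_rng([int(seed), r]).integers(2**31),
        )
        data, labels = generate(sim)
        model = fit(data, cfg)
        report = information_gain_rate(labels, model.membership)
        rows.append(
            {
                "replicate": r,
                "cr": report.cr,
                "igr": report.igr,
                "K_hat": model.K,
                "chosen_M": model.chosen_M,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["summary"] = {
        "cr_mean": float(df["cr"].mean()),
        "cr_std": float(df["cr"].std(ddof=1)) if len(df) > 1 else 0.0,
        "igr_mean": float(df["igr"].mean()),
        "igr_std": float(df["igr"].std(ddof=1)) if len(df) > 1 else 0.0,
        "design": design,
        "cont_var": cont_var,
        "replicates": int(replicates),
    }
    return df
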