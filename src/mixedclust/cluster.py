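"""Sequential cluster extraction on the quantized product lattice.

One pass of the algorithm, at a fixed quantization level M:

1. Every distinct observed (categorical, quantized) row is a candidate
   center.  For each candidate, compute the distance vectors of the current
   data in both portions and the weighted local chi-squared statistic.
2. If the maximal statistic does not exceed the critical value, stop: no
   further significant structure.  Otherwise the argmax position becomes a
   cluster center.
3. The categorical radius R_C is the distance just before the first local
   minimum of the categorical DV (falling back to the center's optimal
   cut-off when the DV has no interior local minimum); the quantized radius
   R_Q is the center's quantized cut-off r*_Q.  All records within R_C of
   the center in the categorical portion or within R_Q in the quantized
   portion are labeled and removed, and the scan repeats on the remainder.
4. After extraction terminates, memberships are pruned: each record goes to
   its nearest center per portion; when the two portions disagree, the
   candidate backed by the portion with the smaller recorded p-value
   (stronger local evidence) wins.

The uniform-null expectations are recomputed against the *current* record
count at every iteration, always on the full original lattice.  Fitting is
fully deterministic: candidates are scanned in lexicographic order, so ties
and results are stable under record permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import MixedDataset, QuantizedDataset
from .distances import distance_vector_table, pairwise_hamming, uniform_dv_categorical, uniform_dv_quantized
from .localtest import LocalTestResult, _chi2_logsf, local_test
from .quantize import DEFAULT_GRID, quantize_dataset, select_level

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "ClusterModel", "fit", "find_center", "radius_categorical", "radius_quantized", "extract_cluster", "prune_memberships"]


@dataclass
class FitConfig:
    """Tunable knobs of the fitting procedure.

    alpha : right-tail level of the local test (default 0.05).
    m_grid : candidate quantization levels for adaptive selection.
    fixed_M : skip level selection and use this M.
    df_rule : degrees of freedom of the reference distribution
        (``head_cells`` | ``p_plus_q`` | ``fixed:<k>``).
    quantized_start : ``as_printed`` | ``symmetric`` scan convention for the
        quantized portion.
    conflict_rule : Step-9 portion disagreement resolution,
        ``stronger_evidence`` (smaller p-value wins, default) or
        ``weaker_evidence``.
    min_n : minimum number of records required to fit.
    """

    alpha: float = 0.05
    m_grid: Sequence[int] = DEFAULT_GRID
    fixed_M: int | None = None
    df_rule: str = "head_cells"
    quantized_start: str = "as_printed"
    conflict_rule: str = "stronger_evidence"
    min_n: int = 10

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "m_grid": list(self.m_grid),
            "fixed_M": self.fixed_M,
            "df_rule": self.df_rule,
            "quantized_start": self.quantized_start,
            "conflict_rule": self.conflict_rule,
            "min_n": self.min_n,
        }


@dataclass
class ClusterModel:
    """Result of one full fit: centers, radii, memberships, diagnostics."""

    K: int
    centers: list  # list of (S codes, T codes) tuples
    radii_c: list
    radii_q: list
    membership: np.ndarray  # 1..K (all ones when no structure found)
    per_cluster_tests: list  # LocalTestResult per extracted cluster
    chosen_M: int
    no_structure: bool = False
    stalled: bool = False
    ids: np.ndarray | None = None
    f_stats: dict | None = None
    config: FitConfig | None = None
    trace: list = field(default_factory=list)


def find_center(qdata: QuantizedDataset, active: np.ndarray, cfg: FitConfig) -> tuple[int, np.ndarray, np.ndarray, LocalTestResult, np.ndarray, np.ndarray]:
    """Scan every distinct observed row of the active data for the max chi2_w.

    Returns ``(cand_index, S, T, test, dist_c, dist_q)`` where ``dist_c`` /
    ``dist_q`` are the active rows' Hamming distances to the winning center
    and the candidate's DVs are reachable through them.  Candidates are
    deduplicated and lexicographically sorted, and the first maximum is
    taken, so the scan is permutation-stable.
    """
    X = qdata.base.X[active]
    Q = qdata.Q[active]
    n_cur = X.shape[0]
    joint = np.hstack([X, Q])
    cand = np.unique(joint, axis=0)  # sorted lexicographically
    p, q = qdata.p, qdata.q
    cand_c, cand_q = cand[:, :p], cand[:, p:]
    dvc = distance_vector_table(X, cand_c)
    dvq = distance_vector_table(Q, cand_q)
    udv_c = uniform_dv_categorical(n_cur, qdata.base.m).expected
    udv_q = uniform_dv_quantized(n_cur, qdata.l).expected
    best_i = -1
    best: LocalTestResult | None = None
    for i in range(cand.shape[0]):
        res = local_test(
            dvc[i], udv_c, dvq[i], udv_q, p, q,
            alpha=cfg.alpha, df_rule=cfg.df_rule, quantized_start=cfg.quantized_start,
        )
        if best is None or res.chi_w > best.chi_w:
            best, best_i = res, i
    S, T = cand_c[best_i], cand_q[best_i]
    dist_c = pairwise_hamming(X, S[None, :])[:, 0]
    dist_q = pairwise_hamming(Q, T[None, :])[:, 0]
    return best_i, S, T, best, dist_c, dist_q


def radius_categorical(dv, fallback: int) -> int:
    """Distance just before the first interior local minimum of the DV.

    Scans 0 < j < p for the first j with ``dv[j] < min(dv[j-1], dv[j+1])``
    and returns j - 1.  A DV with no interior local minimum (e.g. strictly
    decreasing) falls back to the center's optimal cut-off — the other
    dense-region boundary the method defines.
    """
    dv = np.asarray(dv)
    d = len(dv) - 1
    for j in range(1, d):
        if dv[j] < min(dv[j - 1], dv[j + 1]):
            return j - 1
    return fallback


def radius_quantized(test: LocalTestResult) -> int:
    """The quantized radius is the center's optimal cut-off r*_Q."""
    return test.r_q


def extract_cluster(dist_c: np.ndarray, dist_q: np.ndarray, R_C: int, R_Q: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Portion-wise member masks and their union (the removal set).

    A record joins the categorical portion of the cluster if its categorical
    Hamming distance to the center is <= R_C, the quantized portion if its
    quantized distance is <= R_Q; the union is removed from the current data
    so a half-extracted cluster cannot be re-detected.
    """
    if R_C < 0 or R_Q < 0:
        raise ValueError("radii must be nonnegative")
    mem_c = dist_c <= R_C
    mem_q = dist_q <= R_Q
    return mem_c, mem_q, mem_c | mem_q


def _portion_logp(test: LocalTestResult, portion: str) -> float:
    if portion == "categorical":
        return _chi2_logsf(test.chi_c, test.df_c)
    return _chi2_logsf(test.chi_q, test.df_q)


def prune_memberships(
    centers: list,
    tests: list,
    qdata: QuantizedDataset,
    conflict_rule: str = "stronger_evidence",
) -> np.ndarray:
    """Final membership: nearest center per portion, p-values break conflicts.

    For each record the nearest center is found separately in the
    categorical and quantized portions (ties to the earlier-extracted
    cluster).  Agreement decides directly; a disagreement is resolved by
    comparing the categorical candidate's recorded categorical p-value with
    the quantized candidate's quantized p-value and assigning the record to
    the candidate whose supporting portion shows stronger evidence (smaller
    p-value; ``weaker_evidence`` inverts the rule).  Records outside every
    extraction radius are assigned here by the same rule.
    """
    K = len(centers)
    if K == 0:
        raise ValueError("prune requires at least one center")
    S = np.vstack([c[0] for c in centers])
    T = np.vstack([c[1] for c in centers])
    Dc = pairwise_hamming(qdata.base.X, S)  # (n, K)
    Dq = pairwise_hamming(qdata.Q, T)
    near_c = Dc.argmin(axis=1)  # first minimum -> earliest cluster
    near_q = Dq.argmin(axis=1)
    membership = near_c + 1
    agree = near_c == near_q
    if not agree.all():
        logp_c = np.array([_portion_logp(t, "categorical") for t in tests])
        logp_q = np.array([_portion_logp(t, "quantized") for t in tests])
        for i in np.flatnonzero(~agree):
            a, b = near_c[i], near_q[i]
            take_c = logp_c[a] <= logp_q[b]
            if conflict_rule == "weaker_evidence":
                take_c = logp_c[a] >= logp_q[b]
            membership[i] = (a if take_c else b) + 1
    return membership


def _fit_at_level(data: MixedDataset, M: int, cfg: FitConfig) -> ClusterModel:
    """Run the full extraction loop at one fixed quantization level."""
    qdata = quantize_dataset(data, M)
    n = data.n
    active = np.ones(n, dtype=bool)
    centers, radii_c, radii_q, tests = [], [], [], []
    trace = []
    stalled = False
    for _ in range(n):  # each significant round removes >= 1 record
        if not active.any():
            break
        _, S, T, test, dist_c, dist_q = find_center(qdata, active, cfg)
        if not test.significant:
            trace.append({"event": "stop", "chi_w": test.chi_w, "crit": test.crit, "n_left": int(active.sum())})
            break
        R_C = radius_categorical(_dv_from(dist_c, data.p), fallback=test.r_c)
        R_Q = radius_quantized(test)
        mem_c, mem_q, removed = extract_cluster(dist_c, dist_q, R_C, R_Q)
        if not removed.any():
            stalled = True
            logger.warning("significant test with empty removal set; stopping")
            trace.append({"event": "stall"})
            break
        idx = np.flatnonzero(active)
        centers.append((S.copy(), T.copy()))
        radii_c.append(int(R_C))
        radii_q.append(int(R_Q))
        tests.append(test)
        trace.append({
            "event": "extract",
            "cluster": len(centers),
            "chi_w": test.chi_w,
            "chi_c": test.chi_c,
            "chi_q": test.chi_q,
            "R_C": int(R_C),
            "R_Q": int(R_Q),
            "n_removed": int(removed.sum()),
            "n_member_c": int(mem_c.sum()),
            "n_member_q": int(mem_q.sum()),
        })
        active[idx[removed]] = False
    K = len(centers)
    if K == 0:
        logger.info("no significant structure at M=%d; single-cluster fallback", M)
        membership = np.ones(n, dtype=np.int64)
    else:
        membership = prune_memberships(centers, tests, qdata, cfg.conflict_rule)
    return ClusterModel(
        K=K,
        centers=centers,
        radii_c=radii_c,
        radii_q=radii_q,
        membership=membership,
        per_cluster_tests=tests,
        chosen_M=M,
        no_structure=(K == 0),
        stalled=stalled,
        ids=data.ids,
        config=cfg,
        trace=trace,
    )


def _dv_from(dist: np.ndarray, d: int) -> np.ndarray:
    return np.bincount(dist, minlength=d + 1)


def fit(data: MixedDataset, config: FitConfig | None = None) -> ClusterModel:
    """Fit the clustering, selecting the quantization level adaptively.

    Runs the extraction loop at every candidate M in ``config.m_grid``,
    scores each by the mean one-way ANOVA F of the continuous columns
    grouped by the produced memberships, and returns the model of the
    largest-F level.  ``config.fixed_M`` skips the search.  Fitting involves
    no randomness: identical data and config give identical results.
    """
    cfg = config or FitConfig()
    if data.p < 1 or data.q < 1:
        raise ValueError("clustering requires p >= 1 and q >= 1")
    if data.n < cfg.min_n:
        raise ValueError(f"need at least {cfg.min_n} records, got {data.n}")
    if cfg.fixed_M is not None:
        return _fit_at_level(data, int(cfg.fixed_M), cfg)
    sel = select_level(data, cfg.m_grid, lambda d, M: _fit_at_level(d, M, cfg))
    model = sel.models[sel.grid.index(sel.chosen_M)]
    model.f_stats = dict(zip(sel.grid, sel.f_stats))
    return model
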