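"""Local significance test for cluster structure around a reference point.

For a candidate center, the observed distance vector (DV) of each data
portion is compared with its uniform-null expectation (UDV).  An optimal
cut-off ``r*`` bounds the dense head of the DV (the last index before the
observed/expected ratio first drops below 1); a modified chi-squared
statistic then compares head cells individually and pools the tail into a
single term.  The categorical and quantized statistics are combined into a
weighted statistic

    chi2_w = q/(p+q) * chi2_C + p/(p+q) * chi2_Q,

which down-weights the portion with more attributes, and is referred to the
upper-alpha quantile of a chi-squared distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "LocalTestResult",
    "cutoff",
    "modified_chisq",
    "weighted_stat",
    "local_test",
]

# Scan/head start conventions.  The categorical scan begins at distance 1 and
# its head sum at 0; the quantized scan begins at distance 2 and its head sum
# at 1 (distance 0 never enters the quantized statistic).  The asymmetry is
# kept as the procedure defines it; `quantized_start="symmetric"` flips the
# quantized portion to the categorical convention.
CATEGORICAL_START = 1
QUANTIZED_START = 2


@dataclass
class LocalTestResult:
    """Outcome of the weighted local chi-squared test at one position."""

    r_c: int
    r_q: int
    chi_c: float
    chi_q: float
    chi_w: float
    df: int
    crit: float
    significant: bool
    df_c: int = 0
    df_q: int = 0


def cutoff(dv, udv, start: int) -> int:
    """Optimal cut-off r*: last index before observed/expected drops below 1.

    Scans j = start .. d; the first scanned j with ``dv[j]/udv[j] < 1``
    yields r* = j - 1.  A zero expected cell is treated as ratio >= 1 (mass
    where none is expected indicates concentration, not dispersion, so the
    scan continues).  If no scanned ratio drops below 1, r* = d: the whole
    vector is dense and the pooled tail is empty.
    """
    dv = np.asarray(dv, dtype=float)
    udv = np.asarray(udv, dtype=float)
    if dv.shape != udv.shape:
        raise ValueError("dv and udv must have equal length")
    d = len(dv) - 1
    for j in range(start, d + 1):
        if udv[j] > 0 and dv[j] / udv[j] < 1.0:
            return j - 1
    return d


def _chisq_parts(dv, udv, r: int, start: int) -> tuple[float, int, int]:
    """Modified chi-squared value plus (head cell count, skipped cell count)."""
    dv = np.asarray(dv, dtype=float)
    udv = np.asarray(udv, dtype=float)
    d = len(dv) - 1
    lo = start - 1  # head starts one below the scan start
    if not (lo <= r <= d):
        raise ValueError(f"cut-off r={r} outside [{lo}, {d}]")
    head = slice(lo, r + 1)
    obs, exp = dv[head], udv[head]
    ok = exp > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipping %d zero-expectation head cell(s)", n_skipped)
    chi = float((((obs - exp) ** 2)[ok] / exp[ok]).sum())
    tail_exp = float(udv[r + 1 :].sum())
    if tail_exp > 0:
        chi += (obs.sum() - exp.sum()) ** 2 / tail_exp
    # tail_exp == 0 only when r == d, where head sums agree and the pooled
    # 0/0 term resolves to 0
    return chi, r + 1 - lo, n_skipped


def modified_chisq(dv, udv, r: int, start: int) -> float:
    """Head-cellwise chi-squared plus one pooled-tail term.

    Head cells run from ``start - 1`` through ``r``; the tail ``r+1 .. d``
    contributes ``(sum_head dv - sum_head udv)^2 / sum_tail udv``.
    """
    return _chisq_parts(dv, udv, r, start)[0]


def weighted_stat(chi_c: float, chi_q: float, p: int, q: int) -> float:
    """Convex combination (q*chi_c + p*chi_q)/(p+q)."""
    if p < 1 or q < 1:
        raise ValueError("p and q must be >= 1")
    return (q * chi_c + p * chi_q) / (p + q)


def _resolve_df(df_rule: str, df_c: int, df_q: int, p: int, q: int) -> int:
    if df_rule == "head_cells":
        return max(df_c + df_q, 1)
    if df_rule == "p_plus_q":
        return p + q
    if df_rule.startswith("fixed:"):
        return int(df_rule.split(":", 1)[1])
    raise ValueError(f"unknown df_rule: {df_rule!r}")


def local_test(
    dv_c,
    udv_c,
    dv_q,
    udv_q,
    p: int,
    q: int,
    alpha: float = 0.05,
    df_rule: str = "head_cells",
    quantized_start: str = "as_printed",
) -> LocalTestResult:
    """Weighted local chi-squared test of one candidate position.

    Parameters
    ----------
    dv_c, udv_c : length p+1 vectors
        Observed and expected categorical distance vectors.
    dv_q, udv_q : length q+1 vectors
        Observed and expected quantized distance vectors.
    alpha : float
        Right-tail level for the critical value (default 0.05).
    df_rule : str
        Degrees of freedom for the reference distribution: ``head_cells``
        (one per freely varying compared cell; default), ``p_plus_q``, or
        ``fixed:<k>``.
    quantized_start : str
        ``as_printed`` keeps the quantized scan starting at distance 2 and
        its head at 1; ``symmetric`` uses the categorical convention.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    q_start = CATEGORICAL_START if quantized_start == "symmetric" else QUANTIZED_START
    r_c = cutoff(dv_c, udv_c, CATEGORICAL_START)
    r_q = cutoff(dv_q, udv_q, q_start)
    chi_c, head_c, skip_c = _chisq_parts(dv_c, udv_c, r_c, CATEGORICAL_START)
    chi_q, head_q, skip_q = _chisq_parts(dv_q, udv_q, r_q, q_start)
    chi_w = weighted_stat(chi_c, chi_q, p, q)
    df_c = max(head_c - skip_c, 1)
    df_q = max(head_q - skip_q, 1)
    df = _resolve_df(df_rule, df_c, df_q, p, q)
    crit = float(stats.chi2.ppf(1.0 - alpha, df))
    return LocalTestResult(
        r_c=r_c,
        r_q=r_q,
        chi_c=chi_c,
        chi_q=chi_q,
        chi_w=chi_w,
        df=df,
        crit=crit,
        significant=bool(chi_w > crit),
        df_c=df_c,
        df_q=df_q,
    )


def _chi2_logsf(x: float, df: int) -> float:
    """log of the chi-squared upper-tail probability, stable for huge x.

    scipy's logsf underflows to -inf for the statistic magnitudes produced on
    large lattices; beyond the underflow point the standard asymptotic
    expansion of the upper incomplete gamma function is used instead.
    """
    val = float(stats.chi2.logsf(x, df))
    if math.isfinite(val):
        return val
    if x <= 0:
        return 0.0
    a = df / 2.0
    t = x / 2.0
    # Gamma(a, t) ~ t^(a-1) e^-t (1 + (a-1)/t) for t >> a
    return -t + (a - 1.0) * math.log(t) - float(gammaln(a)) + math.log1p((a - 1.0) / t)
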