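"""Bivariate screening statistics for donor-level morphology tables.

Two-tailed Spearman correlation with ROUT outlier removal at Q = 1% is the
workhorse of the screen; group contrasts use the unpaired pooled-variance
t-test and the rank-based ROC AUC with a DeLong confidence interval.

ROUT (Robust regression followed by OUTlier identification) fits a robust
straight line by iteratively reweighted least squares with a Lorentzian
loss, scales residuals by the RSDR (68.27th percentile of |residuals|
corrected by n/(n-K)), converts them to two-tailed t p-values and applies a step-up
false-discovery test over the residuals (the j-th largest tested at
Q * j / n), with maximum false-discovery rate Q.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class ConstantInputError(ValueError):
    """A statistic is undefined because an input vector is constant."""


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rs_obs: float) -> float:
    """Two-tailed p by full enumeration of permutations of y's ranks."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (pc[0] ** 2).sum())
    rs_all = pc @ rxc / denom
    return float(np.mean(np.abs(rs_all) >= abs(rs_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed p-value.

    Midrank ties; p by the t approximation, replaced by exact full
    permutation enumeration for n <= ``exact_max_n``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("spearman needs at least 4 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    rs = float(res.statistic)
    if len(x) <= exact_max_n:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        return rs, _exact_spearman_p(rx, ry, rs)
    return rs, float(res.pvalue)


# ---------------------------------------------------------------------------
# ROUT outlier removal
# ---------------------------------------------------------------------------

_RSDR_PERCENTILE = 68.27


def _robust_line(x: np.ndarray, y: np.ndarray,
                 max_iter: int = 60, tol: float = 1e-10):
    """IRLS straight-line fit with Lorentzian loss; returns (beta, residuals,
    rsdr)."""
    n = len(x)
    k = 2
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rsdr = 1.0
    for _ in range(max_iter):
        res = y - design @ beta
        rsdr = np.percentile(np.abs(res), _RSDR_PERCENTILE) * n / (n - k)
        if rsdr <= 0:
            return beta, res, 0.0
        w = 1.0 / (1.0 + (res / rsdr) ** 2)
        wd = design * w[:, None]
        beta_new = np.linalg.solve(wd.T @ design, wd.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    res = y - design @ beta
    rsdr = np.percentile(np.abs(res), _RSDR_PERCENTILE) * n / (n - k)
    return beta, res, rsdr


def rout_outliers(x, y, q_pct: float = 1.0) -> np.ndarray:
    """ROUT inlier mask for a (x, y) scatter with a straight-line baseline.

    Returns a boolean mask, True for retained points. ``q_pct`` is the
    maximum false-discovery rate in percent (Q = 1 by convention); Q = 0
    removes nothing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    k = 2
    if n <= k:
        raise ValueError(f"ROUT needs more than {k} points")
    if n < 10:
        warnings.warn("ROUT is unreliable below n = 10", stacklevel=2)
    mask = np.ones(n, dtype=bool)
    if q_pct <= 0:
        return mask
    _, res, rsdr = _robust_line(x, y)
    if rsdr <= 0:  # perfect fit: no evidence for outliers
        return mask
    t = np.abs(res) / rsdr
    p = 2.0 * sps.t.sf(t, df=n - k)
    # step-up false-discovery schedule: the j-th largest residual is tested
    # at Q * j / n; the largest j passing flags itself and everything larger
    order = np.argsort(-np.abs(res), kind="stable")  # position 0 = largest
    j = np.arange(1, n + 1)
    alpha = (q_pct / 100.0) * j / n
    flagged = p[order] <= alpha
    if flagged.any():
        cutoff = int(np.max(np.nonzero(flagged)[0])) + 1
        mask[order[:cutoff]] = False
    return mask


# ---------------------------------------------------------------------------
# Correlation screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """One screened trait-outcome pair after outlier removal."""

    x_name: str
    y_name: str
    r_s: float
    p_two_tailed: float
    n_used: int
    outlier_ids: list = field(default_factory=list)
    q_pct: float = 1.0


def correlate_screen(table: pd.DataFrame, pairs,
                     q_pct: float = 1.0,
                     id_column: str = "donor_id") -> list[CorrelationResult]:
    """ROUT (Q%) then Spearman for each named (x, y) column pair."""
    results = []
    ids = table[id_column] if id_column in table.columns else pd.Series(
        np.arange(len(table)))
    for x_name, y_name in pairs:
        for name in (x_name, y_name):
            if name not in table.columns:
                raise KeyError(f"column {name!r} not in table")
        sub = table[[x_name, y_name]].dropna()
        x = sub[x_name].to_numpy(dtype=float)
        y = sub[y_name].to_numpy(dtype=float)
        keep = rout_outliers(x, y, q_pct=q_pct)
        rs, p = spearman(x[keep], y[keep])
        outliers = list(ids.loc[sub.index[~keep]])
        results.append(CorrelationResult(x_name, y_name, rs, p,
                                         int(keep.sum()), outliers, q_pct))
    return results


def screen_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "x": r.x_name, "y": r.y_name, "r_s": r.r_s, "p": r.p_two_tailed,
        "n_used": r.n_used, "n_outliers": len(r.outlier_ids),
        "outlier_ids": ";".join(map(str, r.outlier_ids)), "Q_pct": r.q_pct,
    } for r in results], columns=["x", "y", "r_s", "p", "n_used",
                                  "n_outliers", "outlier_ids", "Q_pct"])


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def ttest_unpaired(a, b) -> tuple[float, float]:
    """Pooled-variance Student t-test, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ConstantInputError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class RocResult:
    """Rank-based ROC AUC with a DeLong confidence interval.

    ``auc`` is the raw (unoriented) Mann-Whitney estimate; ``auc_oriented``
    folds it above 0.5 with ``direction`` recording the fold (+1 when the
    raw estimate already favored the positive class).
    """

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    ci_level_pct: float = 97.5

    @property
    def direction(self) -> int:
        return 1 if self.auc >= 0.5 else -1

    @property
    def auc_oriented(self) -> float:
        return max(self.auc, 1.0 - self.auc)


def roc_auc(score, label, ci_level_pct: float = 97.5) -> RocResult:
    """ROC AUC by the midrank Mann-Whitney formulation, DeLong CI."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    if score.shape != label.shape or score.ndim != 1:
        raise ValueError("score and label must be 1-D vectors of equal length")
    classes = np.unique(label)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = score[label == classes.max()]
    neg = score[label == classes.min()]
    m, n = len(pos), len(neg)
    ranks_all = sps.rankdata(np.concatenate([pos, neg]))
    auc = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (ranks_all[:m] - sps.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - sps.rankdata(neg)) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = sps.norm.ppf(0.5 + ci_level_pct / 200.0)
    half = z * np.sqrt(var)
    return RocResult(float(auc), float(np.clip(auc - half, 0.0, 1.0)),
                     float(np.clip(auc + half, 0.0, 1.0)), m, n, ci_level_pct)
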