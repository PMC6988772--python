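"""Stability selection with per-family error-rate (PFER) control.

The multivariable analysis fits a Lasso to many random half-subsamples of
the donor table, lets exactly ``q`` variables enter per subsample (the
first ``q`` to attain nonzero coefficients along the regularization path),
and reports per-variable selection probabilities ``pi_j``; the stable set
is ``{j : pi_j >= theta}``. The subsample budget ``q`` is derived from the
selection-error bound ``PFER >= q^2 / ((2 theta - 1) p)``, so the expected
number of falsely stable variables under exchangeable nulls stays below the
configured PFER.

Model comparison uses an AIC ladder: m0 (intercept only), m1 (top stable
variable), m2 (top four variables), with AIC = n ln(RSS/n) + 2k.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lars_path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StabilityConfig:
    """Settings of the resampled-Lasso selection procedure."""

    n_subsamples: int = 50
    theta: float = 0.75          # stability threshold on pi_j
    pfer: float = 2.0            # expected false selections budget
    q: int | None = None         # per-fit active-set size (derived if None)
    subsample_fraction: float = 0.5
    seed: int = 0

    def validate(self, p: int | None = None) -> None:
        if not (0.5 < self.theta <= 1.0):
            raise ValueError("theta must lie in (0.5, 1]")
        if self.pfer <= 0:
            raise ValueError("pfer must be positive")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.q is not None and (self.q < 1 or (p is not None and self.q > p)):
            raise ValueError("q must satisfy 1 <= q <= p")


def q_from_pfer(pfer: float, theta: float, p: int) -> int:
    """Largest q with q^2 / ((2 theta - 1) p) <= PFER, at least 1.

    This inverts the stability-selection error bound
    PFER <= q^2 / ((2 theta - 1) p).
    """
    if p < 1:
        raise ValueError("need at least one predictor")
    if not (0.5 < theta <= 1.0):
        raise ValueError("theta must lie in (0.5, 1]")
    if pfer <= 0:
        raise ValueError("pfer must be positive")
    q = int(math.floor(math.sqrt(pfer * (2.0 * theta - 1.0) * p)))
    return max(1, min(q, p))


def lasso_entry_order(X: np.ndarray, y: np.ndarray) -> list[int]:
    """Column indices ordered by first entry into the Lasso path.

    The path is traversed from the fully penalized (all-zero) end; a
    variable's entry step is the first path knot at which its coefficient
    is nonzero. Simultaneous entries are broken by lowest column index
    (logged, since the event signals near-collinearity).
    """
    _, _, coefs = lars_path(X, y, method="lasso")
    nonzero = coefs != 0.0
    entry = np.full(X.shape[1], np.inf)
    for j in range(X.shape[1]):
        steps = np.nonzero(nonzero[j])[0]
        if steps.size:
            entry[j] = steps[0]
    finite = np.isfinite(entry)
    order = np.lexsort((np.arange(X.shape[1])[finite], entry[finite]))
    ordered = np.arange(X.shape[1])[finite][order]
    steps_sorted = entry[ordered]
    if len(steps_sorted) > 1 and np.any(np.diff(steps_sorted) == 0):
        logger.debug("simultaneous Lasso entries; ties broken by column index")
    return [int(j) for j in ordered]


def lasso_first_q(X, y, q: int) -> set[int]:
    """The first ``q`` distinct variables to enter the Lasso path (a set).

    Zero-variance columns are excluded with a warning (their coefficients
    are undefined after standardization).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if q < 1:
        raise ValueError("q must be >= 1")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance column(s)",
                      stacklevel=2)
    cols = np.nonzero(keep)[0]
    order = lasso_entry_order(X[:, keep], y)
    return {int(cols[j]) for j in order[:q]}


@dataclass
class StabilityResult:
    """Selection probabilities and the stable set at threshold theta."""

    selection_probability: np.ndarray  # pi_j per variable
    stable_set: list[int]              # indices with pi_j >= theta
    q_used: int
    theta: float
    pfer: float
    n_subsamples: int
    subsample_sets: list[set[int]] = field(default_factory=list)
    variable_names: list[str] | None = None

    def ranking(self) -> list[int]:
        """All variables, by decreasing pi (ties by index)."""
        pi = self.selection_probability
        return list(np.lexsort((np.arange(len(pi)), -pi)))

    def as_frame(self) -> pd.DataFrame:
        names = (self.variable_names
                 if self.variable_names is not None
                 else [f"x{j}" for j in range(len(self.selection_probability))])
        return pd.DataFrame({
            "variable": names,
            "selection_probability": self.selection_probability,
            "stable": [j in set(self.stable_set)
                       for j in range(len(names))],
        }).sort_values("selection_probability", ascending=False,
                       kind="stable").reset_index(drop=True)


def stability_selection(X, y, config: StabilityConfig = StabilityConfig(),
                        variable_names=None) -> StabilityResult:
    """Resampled-Lasso selection probabilities under a PFER budget.

    Draws ``n_subsamples`` subsamples of size ``floor(n * fraction)``
    without replacement; within each, predictors are standardized and the
    first-``q`` Lasso entrants recorded. ``pi_j`` is the relative selection
    frequency; ``q`` defaults to the PFER bound.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    config.validate(p)
    if n < 10:
        raise ValueError("stability selection needs n >= 10")
    size = int(n * config.subsample_fraction)
    if size <= 2:
        raise ValueError("subsample size must exceed 2")
    q = config.q if config.q is not None else q_from_pfer(
        config.pfer, config.theta, p)
    rng = np.random.default_rng(config.seed)
    counts = np.zeros(p)
    subsample_sets: list[set[int]] = []
    for _ in range(config.n_subsamples):
        idx = rng.choice(n, size=size, replace=False)
        xs = X[idx]
        ys = y[idx]
        mu = xs.mean(axis=0)
        sd = xs.std(axis=0)
        sd[sd == 0] = 1.0  # zero-variance columns never enter the path
        xs = (xs - mu) / sd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = lasso_first_q(xs, ys - ys.mean(), q)
        subsample_sets.append(selected)
        for j in selected:
            counts[j] += 1
    pi = counts / config.n_subsamples
    stable = [int(j) for j in np.nonzero(pi >= config.theta)[0]]
    return StabilityResult(pi, stable, q, config.theta, config.pfer,
                           config.n_subsamples, subsample_sets,
                           list(variable_names) if variable_names is not None
                           else None)


# ---------------------------------------------------------------------------
# AIC model ladder
# ---------------------------------------------------------------------------

def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of an OLS fit via pseudoinverse (tolerates
    collinear covariates, with a condition warning)."""
    if X.shape[1] > 1:
        s = np.linalg.svd(X, compute_uv=False)
        if s[-1] <= 1e-10 * s[0]:
            warnings.warn("collinear covariate set; fitting via pseudoinverse",
                          stacklevel=2)
    beta = np.linalg.pinv(X) @ y
    res = y - X @ beta
    return float(res @ res)


def aic_gaussian(rss: float, n: int, k: int) -> float:
    """AIC = n ln(RSS/n) + 2k (Gaussian likelihood up to constants)."""
    return n * math.log(max(rss, 1e-300) / n) + 2 * k


@dataclass
class AicLadder:
    """AIC comparison of nested prediction models m0/m1/m2."""

    outcome: str
    models: dict[str, list[str]]   # model name -> covariate names
    aic: dict[str, float]
    n: int
    log_transformed: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": list(self.models),
            "covariates": [";".join(v) for v in self.models.values()],
            "aic": [self.aic[m] for m in self.models],
            "n": self.n,
        })

    def best(self) -> str:
        return min(self.aic, key=self.aic.get)


def aic_ladder(table: pd.DataFrame, outcome: str, ranking,
               m2_size: int = 4, log_outcome: bool = False) -> AicLadder:
    """OLS AIC ladder: intercept-only (m0), top stable variable (m1), top
    ``m2_size`` variables (m2).

    ``ranking`` is an ordered list of covariate column names (most stable
    first); ``log_outcome`` log-transforms the outcome before fitting (used
    for the adipogenic outcome, which is strictly positive and skewed).
    """
    ranking = list(ranking)
    if outcome not in table.columns:
        raise KeyError(f"outcome {outcome!r} not in table")
    for name in ranking[:m2_size]:
        if name not in table.columns:
            raise KeyError(f"covariate {name!r} not in table")
    y = table[outcome].to_numpy(dtype=float)
    if log_outcome:
        if np.any(y <= 0):
            raise ValueError("log transform needs a strictly positive outcome")
        y = np.log(y)
    n = len(y)
    models = {"m0": [], "m1": ranking[:1], "m2": ranking[:m2_size]}
    aic = {}
    for name, covs in models.items():
        X = np.column_stack([np.ones(n)]
                            + [table[c].to_numpy(dtype=float) for c in covs])
        aic[name] = aic_gaussian(_ols_rss(X, y), n, k=X.shape[1])
    return AicLadder(outcome, models, aic, n, log_outcome)
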