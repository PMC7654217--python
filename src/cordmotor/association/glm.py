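"""Family-dispatched GLM fits and bagged bootstrap estimates.

Counts (tasks achieved out of four) get Poisson regression, binary
indicators logistic regression, and the remaining continuous outcomes
ordinary least squares. Coefficients are on the 1-unit-of-percent
scale of the spared-tissue predictors. To reduce the variance of the
small-sample estimates, the final models are bagged: the model is
refitted on B bootstrap copies of the rows and the ensemble mean is
reported as the estimate, the ensemble standard deviation as its SE,
with a normal-approximation two-sided p-value from their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["GLMResult", "fit_glm", "multivariable_model", "BaggedEstimate", "bagged_fit"]

_FAMILY_ALIASES = {
    "continuous": "linear",
    "linear": "linear",
    "gaussian": "linear",
    "count": "poisson",
    "poisson": "poisson",
    "binary": "logistic",
    "logistic": "logistic",
}


def _canon_family(family: str) -> str:
    try:
        return _FAMILY_ALIASES[family.lower()]
    except KeyError:
        raise ValueError(f"unknown family {family!r}") from None


@dataclass
class GLMResult:
    """Coefficients, SEs and p-values of one fit, with quality flags.

    ``flags`` may contain ``rank_deficient``, ``separation`` or
    ``fit_failed``; a flagged result is still returned, never raised.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    family: str
    nobs: int
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def _design(X: pd.DataFrame) -> pd.DataFrame:
    return sm.add_constant(X.astype(float), has_constant="add")


def fit_glm(y: np.ndarray | pd.Series, X: pd.DataFrame, family: str) -> GLMResult:
    """Fit one regression of ``y`` on ``X`` (intercept added).

    Maximum likelihood for Poisson/logistic, least squares for linear.
    Rank deficiency and perfect separation are flagged on the result
    rather than raised; flagged coefficients may be NaN.
    """
    fam = _canon_family(family)
    y = np.asarray(y, dtype=float)
    exog = _design(X)
    keep = np.isfinite(y) & np.all(np.isfinite(exog.to_numpy()), axis=1)
    y, exog = y[keep], exog.loc[keep]
    flags: list[str] = []
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        flags.append("rank_deficient")
    names = list(exog.columns)
    try:
        if fam == "linear":
            res = sm.OLS(y, exog).fit()
        elif fam == "poisson":
            res = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
        else:
            res = sm.GLM(y, exog, family=sm.families.Binomial()).fit()
            if np.any(np.abs(res.params) > 1e2) or not np.all(np.isfinite(res.bse)):
                flags.append("separation")
        params, bse, pvalues = res.params, res.bse, res.pvalues
    except Exception:
        nan = pd.Series(np.nan, index=names)
        params, bse, pvalues = nan, nan.copy(), nan.copy()
        flags.append("fit_failed")
    return GLMResult(
        params=pd.Series(np.asarray(params), index=names),
        bse=pd.Series(np.asarray(bse), index=names),
        pvalues=pd.Series(np.asarray(pvalues), index=names),
        family=fam,
        nobs=int(len(y)),
        flags=flags,
    )


def multivariable_model(y, X: pd.DataFrame, family: str) -> GLMResult:
    """Joint fit of one motor outcome on its significant MRI predictors.

    With a single predictor this coincides with the univariable fit; the
    coefficients are the adjusted estimates.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one predictor")
    return fit_glm(y, X, family)


@dataclass
class BaggedEstimate:
    """Ensemble summary of B bootstrap refits.

    ``params`` holds ensemble-mean coefficients, ``bse`` the ensemble
    standard deviations (reported as SEs), ``pvalues`` the two-sided
    normal-approximation p-values of mean/SD. With ``B == 1`` the SE and
    p-value are undefined and reported as NaN.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    family: str
    B: int
    seed: int
    n_redraws: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        )


def _fast_ols(y: np.ndarray, exog: np.ndarray) -> tuple[np.ndarray, int]:
    beta, _, rank, _ = np.linalg.lstsq(exog, y, rcond=None)
    return beta, rank


def bagged_fit(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    family: str,
    B: int = 1000,
    seed: int = 0,
) -> BaggedEstimate:
    """Bag a regression over B bootstrap copies of the rows.

    Rows are resampled with replacement; the model is refitted per copy.
    Degenerate resamples (a zero-variance predictor, rank deficiency, or
    a failed ML fit) are redrawn and counted; more than ``10 * B``
    consecutive redraws aborts with a diagnostic. Fully reproducible
    under a fixed seed.
    """
    fam = _canon_family(family)
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    n = len(y)
    exog_full = _design(X)
    names = list(exog_full.columns)
    p = len(names)
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows for {p} coefficients")
    exog = exog_full.to_numpy()
    rng = np.random.default_rng(seed)

    coefs = np.empty((B, p))
    n_redraws = 0
    b = 0
    consecutive = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        ye, Xe = y[idx], exog[idx]
        # degenerate draw: a predictor column collapses to a constant
        degenerate = any(np.ptp(Xe[:, j]) == 0 for j in range(1, p))
        beta = None
        if not degenerate:
            if fam == "linear":
                beta, rank = _fast_ols(ye, Xe)
                degenerate = rank < p
            else:
                try:
                    family_obj = (
                        sm.families.Poisson() if fam == "poisson" else sm.families.Binomial()
                    )
                    res = sm.GLM(ye, Xe, family=family_obj).fit(maxiter=100)
                    beta = np.asarray(res.params)
                    degenerate = not np.all(np.isfinite(beta)) or np.any(np.abs(beta) > 1e3)
                except Exception:
                    degenerate = True
        if degenerate:
            n_redraws += 1
            consecutive += 1
            if consecutive > 10 * B:
                raise RuntimeError(
                    f"bagged_fit: {consecutive} consecutive degenerate bootstrap "
                    "resamples; data too degenerate to bag"
                )
            continue
        coefs[b] = beta
        b += 1
        consecutive = 0

    mean = coefs.mean(axis=0)
    if B > 1:
        sd = coefs.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, mean / sd, np.inf * np.sign(mean))
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    else:
        sd = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    return BaggedEstimate(
        params=pd.Series(mean, index=names),
        bse=pd.Series(sd, index=names),
        pvalues=pd.Series(pvals, index=names),
        family=fam,
        B=B,
        seed=seed,
        n_redraws=n_redraws,
    )
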