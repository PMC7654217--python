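"""Variable screening: zero-variance pruning, Spearman, shadow features.

The shadow-feature selector follows the Boruta scheme: at each
iteration every real feature is paired with a permuted copy ("shadow"),
a tree ensemble is fitted on the augmented design, and a real feature
scores a "hit" when its importance exceeds the maximum shadow
importance. After ``n_iter`` iterations each feature's hit count is
compared against Binomial(n_iter, 1/2) with a two-sided test:
significantly more hits than half confirms the feature, significantly
fewer rejects it, anything else stays tentative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "drop_zero_variance",
    "spearman_screen",
    "BorutaResult",
    "boruta_select",
    "retain_variables",
]


def drop_zero_variance(table: pd.DataFrame, columns: list[str] | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns with a single unique value; returns (table, dropped).

    Nothing can be learned from a constant column. Raises if every
    candidate column would be dropped.
    """
    if table.empty:
        raise ValueError("table is empty")
    candidates = columns if columns is not None else list(table.columns)
    dropped = [c for c in candidates if table[c].nunique(dropna=True) <= 1]
    if len(dropped) == len(candidates):
        raise ValueError("all candidate columns have zero variance")
    return table.drop(columns=dropped), dropped


def spearman_screen(
    table: pd.DataFrame,
    mri_vars: list[str],
    motor_vars: list[str],
    alpha: float = 0.05,
    rho_min: float = 0.4,
) -> pd.DataFrame:
    """Pairwise Spearman correlation between MRI and motor variables.

    Rank correlation with average ranks for ties, two-sided p-value; a
    pair is flagged correlated when ``|rho| >= rho_min`` and
    ``p < alpha``. Pairs with fewer than 3 complete observations get
    NaN statistics and ``correlated=False`` with ``n`` recorded.
    """
    rows = []
    for mri in mri_vars:
        for motor in motor_vars:
            sub = table[[mri, motor]].dropna()
            n = len(sub)
            if n < 3:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(sub[mri], sub[motor])
            correlated = bool(np.isfinite(rho) and np.isfinite(p) and abs(rho) >= rho_min and p < alpha)
            rows.append({"mri_var": mri, "motor_var": motor, "n": n, "rho": rho, "p": p, "correlated": correlated})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BorutaResult:
    """Per-feature classification after the shadow-feature importance run."""

    status: dict[str, str]  # feature -> confirmed | tentative | rejected
    hits: dict[str, int]
    n_iter: int
    alpha: float

    @property
    def confirmed(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "confirmed"]

    @property
    def rejected(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "rejected"]

    @property
    def tentative(self) -> list[str]:
        return [f for f, s in self.status.items() if s == "tentative"]


def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray,
    family: str = "continuous",
    n_iter: int = 100,
    alpha: float = 0.01,
    n_estimators: int = 100,
    seed: int = 0,
    min_samples_leaf: int = 5,
    shadow_copies: int = 3,
) -> BorutaResult:
    """All-relevant feature selection against permuted shadow features.

    ``family`` picks the ensemble: a random-forest classifier for binary
    outcomes, a regressor otherwise, scored by impurity importances.

    Two defaults guard against false confirmations in small designs.
    Leaves are kept at >= ``min_samples_leaf`` samples: fully grown
    trees fit residual noise in deep splits, which systematically
    favours a real column's fixed (chance) arrangement over freshly
    permuted shadows. And each feature contributes ``shadow_copies``
    independently permuted shadows, so with few features the max-shadow
    bar is not the maximum of just a handful of draws. Deterministic
    under a fixed seed.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 observations")
    y = np.asarray(y, dtype=float)
    if np.unique(y).size <= 1:
        raise ValueError("outcome is constant; importance undefined")

    classifier = family in ("binary", "logistic") and np.unique(y).size == 2
    features = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    hits = {f: 0 for f in features}

    for it in range(n_iter):
        shadows = np.column_stack(
            [
                rng.permutation(Xv[:, j])
                for _ in range(shadow_copies)
                for j in range(Xv.shape[1])
            ]
        )
        design = np.hstack([Xv, shadows])
        forest_seed = int(rng.integers(0, 2**31 - 1))
        if classifier:
            forest = RandomForestClassifier(
                n_estimators=n_estimators,
                random_state=forest_seed,
                min_samples_leaf=min_samples_leaf,
                n_jobs=1,
            )
            forest.fit(design, y.astype(int))
        else:
            forest = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=forest_seed,
                min_samples_leaf=min_samples_leaf,
                n_jobs=1,
            )
            forest.fit(design, y)
        importances = forest.feature_importances_
        shadow_max = importances[Xv.shape[1] :].max()
        for j, f in enumerate(features):
            if importances[j] > shadow_max:
                hits[f] += 1

    status = {}
    for f in features:
        h = hits[f]
        # two-sided binomial test against p = 1/2
        p_hi = stats.binom.sf(h - 1, n_iter, 0.5)  # P[X >= h]
        p_lo = stats.binom.cdf(h, n_iter, 0.5)  # P[X <= h]
        if p_hi < alpha / 2:
            status[f] = "confirmed"
        elif p_lo < alpha / 2:
            status[f] = "rejected"
        else:
            status[f] = "tentative"
    return BorutaResult(status=status, hits=hits, n_iter=n_iter, alpha=alpha)


def retain_variables(
    screen: pd.DataFrame, boruta: dict[str, BorutaResult] | None = None
) -> tuple[list[str], list[str]]:
    """Apply the retention rule to screening output.

    An MRI variable is kept iff it is correlated with, or confirmed
    important for, at least one motor variable; a motor variable is kept
    iff at least one MRI variable is correlated with it or confirmed
    important for it. ``boruta`` maps motor variable -> BorutaResult
    over the MRI features.
    """
    boruta = boruta or {}
    mri_all = list(dict.fromkeys(screen["mri_var"]))
    motor_all = list(dict.fromkeys(screen["motor_var"]))
    important = {
        (mri, motor)
        for motor, res in boruta.items()
        for mri in res.confirmed
    }
    correlated = {
        (row.mri_var, row.motor_var)
        for row in screen.itertuples()
        if row.correlated
    }
    keep_pairs = important | correlated
    mri_kept = [m for m in mri_all if any(p[0] == m for p in keep_pairs)]
    motor_kept = [m for m in motor_all if any(p[1] == m for p in keep_pairs)]
    return mri_kept, motor_kept
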