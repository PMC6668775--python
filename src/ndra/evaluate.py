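"""Evaluation arithmetic for simulated vs. observed naming latencies.

Latencies are inverse-transformed (-1000/RT) to remove the rightward
skew of naming-latency distributions and z-scored so that effect sizes
are comparable across predictors; predictor effects are ordinary
least-squares slopes on standardized predictors, and joint structure is
assessed by principal-components regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
import statsmodels.api as sm


@dataclass(frozen=True)
class EffectEstimate:
    """Standardized OLS slope and t-statistic for one predictor."""

    predictor: str
    beta: float
    t: float
    n: int


def inverse_transform(latencies) -> np.ndarray:
    """Map latencies (ms) to -1000/RT; monotone, skew-reducing."""
    x = np.asarray(latencies, dtype=float)
    if np.any(x <= 0):
        raise ValueError("latencies must be positive")
    return -1000.0 / x


def standardize(values) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input cannot be standardized")
    return (x - x.mean()) / sd


def linear_effect(
    predictor, response, name: str = "predictor"
) -> EffectEstimate:
    """OLS slope of the response on the standardized predictor."""
    x = standardize(predictor)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predictor and response lengths differ")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return EffectEstimate(
        predictor=name,
        beta=float(fit.params[1]),
        t=float(fit.tvalues[1]),
        n=int(len(y)),
    )


def item_correlation(simulated, observed) -> float:
    """Pearson product-moment correlation between item-level latencies."""
    x = np.asarray(simulated, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of >= 3 items")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def pca_regression(
    predictors: pd.DataFrame, response, k: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regression of the response on the top-k principal components.

    Predictors are standardized, decomposed by PCA (components ordered
    by variance explained, signs fixed so each component's
    largest-magnitude loading is positive), and the response is fitted
    by OLS on the component scores.  Returns (loadings, coefficient
    table with t-values).
    """
    X = np.column_stack([standardize(predictors[c]) for c in predictors.columns])
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n <= k:
        raise ValueError("need more items than components")
    rank = np.linalg.matrix_rank(np.cov(X, rowvar=False))
    if k > rank:
        raise ValueError(f"k={k} exceeds predictor rank {rank}")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # predictors x components
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(k):
        col = loadings[:, j]
        lead = np.argmax(np.abs(col))
        if col[lead] < 0:
            loadings[:, j] = -col
            scores[:, j] = -scores[:, j]
    fit = sm.OLS(y, sm.add_constant(scores)).fit()
    comp_names = [f"PC{j + 1}" for j in range(k)]
    loadings_df = pd.DataFrame(
        loadings, index=list(predictors.columns), columns=comp_names
    )
    coef_df = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "t": fit.tvalues[1:],
            "explained_variance_ratio": pca.explained_variance_ratio_,
        },
        index=comp_names,
    )
    return loadings_df, coef_df
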