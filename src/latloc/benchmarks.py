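"""Comparison methods: PCA, reconstruction-only autoencoder, stepwise OLS.

All three consume the same standardized training matrix as the main
pipeline.  The PCA and plain-autoencoder baselines measure how much of the
outcome a latent space built *without* outcome guidance explains; the
stepwise procedure is a classical global-model alternative that screens
predictors univariately, prunes main effects by backward AIC elimination,
then forward-selects pairwise interactions among the surviving main
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .diagnostics import GlobalFit, fit_global
from .training import TrainConfig, TrainResult, train

__all__ = [
    "StepwiseConfig", "StepwiseModel", "pca_baseline", "plain_ae_baseline",
    "stepwise_interactions", "gaussian_aic",
]


@dataclass
class StepwiseConfig:
    """Thresholds of the stepwise search.

    ``screen_p_threshold`` keeps predictors with univariate p below it
    (conventional sweep values: 0.05, 0.10, 0.157).  A backward step must
    decrease the AIC by more than ``backward_aic_min_improvement``; a
    forward interaction step by more than ``forward_aic_min_improvement``.
    """

    screen_p_threshold: float = 0.05
    backward_aic_min_improvement: float = 1.0
    forward_aic_min_improvement: float = 2.0

    def validate(self) -> None:
        if not (0 < self.screen_p_threshold < 1):
            raise ValueError("screen_p_threshold must be in (0, 1)")
        if self.backward_aic_min_improvement < 0:
            raise ValueError("backward_aic_min_improvement must be >= 0")
        if self.forward_aic_min_improvement < 0:
            raise ValueError("forward_aic_min_improvement must be >= 0")


@dataclass
class StepwiseModel:
    main_effects: List[int]
    interactions: List[tuple]
    screened: List[int]
    aic: float
    r_squared: float
    trace: List[dict] = field(default_factory=list)


def pca_baseline(X_std: np.ndarray, y: np.ndarray,
                 n_components: int = 4) -> tuple[np.ndarray, GlobalFit]:
    """OLS of the outcome on the top principal-component scores."""
    X = np.atleast_2d(np.asarray(X_std, dtype=float))
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    return scores, fit_global(scores, y)


def plain_ae_baseline(X_std: np.ndarray, y: np.ndarray,
                      config: TrainConfig) -> tuple[TrainResult, GlobalFit]:
    """Autoencoder trained on the reconstruction loss only (lambda_pred=0).

    Identical to the main trainer with the prediction term switched off,
    so a lambda_pred=0 run of the main pipeline with the same seed is
    bit-identical to this baseline.
    """
    result = train(X_std, y, replace(config, lambda_pred=0.0))
    return result, fit_global(result.Z, y)


# ---------------------------------------------------------------------------
# stepwise regression with pairwise-interaction search


def gaussian_aic(y: np.ndarray, design: np.ndarray) -> tuple[float, float]:
    """OLS AIC under Gaussian errors: n log(SSE/n) + 2 (k + 1).

    ``k`` counts the regression parameters including the intercept; the +1
    accounts for the error variance.  Returns (aic, r_squared).
    """
    n = y.shape[0]
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    k = design.shape[1]
    aic = n * np.log(max(sse, 1e-300) / n) + 2.0 * (k + 1)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return aic, r2


def _design(X: np.ndarray, mains: Sequence[int],
            inters: Sequence[tuple]) -> np.ndarray:
    cols = [np.ones(X.shape[0])]
    cols.extend(X[:, j] for j in mains)
    cols.extend(X[:, a] * X[:, b] for a, b in inters)
    return np.column_stack(cols)


def stepwise_interactions(X_std: np.ndarray, y: np.ndarray,
                          config: Optional[StepwiseConfig] = None) -> StepwiseModel:
    """Univariate screen, backward AIC elimination, forward interaction search.

    Interactions are products of standardized columns (not re-standardized)
    and are only formed between selected main effects, so the final model
    respects the effect hierarchy.  Ties in AIC improvements break toward
    the lowest column index; the procedure is deterministic.
    """
    config = config or StepwiseConfig()
    config.validate()
    X = np.atleast_2d(np.asarray(X_std, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape

    # 1. univariate screen
    screened = []
    for j in range(p):
        design = np.column_stack([np.ones(n), X[:, j]])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        dof = n - 2
        se = np.sqrt((resid @ resid) / dof
                     / np.sum((X[:, j] - X[:, j].mean()) ** 2))
        tval = coef[1] / se
        pval = 2 * stats.t.sf(abs(tval), dof)
        if pval < config.screen_p_threshold:
            screened.append(j)
    if not screened:
        warnings.warn("no predictor survives the univariate screen; "
                      "returning an empty model")
        aic, r2 = gaussian_aic(y, np.ones((n, 1)))
        return StepwiseModel([], [], [], aic, r2, [])
    if n <= len(screened) + 2:
        raise ValueError(
            f"{len(screened)} screened predictors for n={n} patients; "
            f"tighten screen_p_threshold below {config.screen_p_threshold}")

    trace: List[dict] = []

    # 2. backward elimination on main effects
    mains = list(screened)
    aic_cur, _ = gaussian_aic(y, _design(X, mains, []))
    while len(mains) > 1:
        best_j, best_aic = None, np.inf
        for j in mains:  # ascending index: ties keep the earliest candidate
            cand = [m for m in mains if m != j]
            aic_j, _ = gaussian_aic(y, _design(X, cand, []))
            if aic_j < best_aic:
                best_j, best_aic = j, aic_j
        if aic_cur - best_aic > config.backward_aic_min_improvement:
            mains.remove(best_j)
            trace.append({"step": "backward", "term": best_j,
                          "aic_before": aic_cur, "aic_after": best_aic})
            aic_cur = best_aic
        else:
            break

    # 3. forward selection of pairwise interactions among remaining mains
    inters: List[tuple] = []
    pool = list(combinations(sorted(mains), 2))
    while pool:
        best_pair, best_aic = None, np.inf
        for pair in pool:
            aic_p, _ = gaussian_aic(y, _design(X, mains, inters + [pair]))
            if aic_p < best_aic:
                best_pair, best_aic = pair, aic_p
        if aic_cur - best_aic > config.forward_aic_min_improvement:
            inters.append(best_pair)
            pool.remove(best_pair)
            trace.append({"step": "forward", "term": best_pair,
                          "aic_before": aic_cur, "aic_after": best_aic})
            aic_cur = best_aic
        else:
            break

    aic_final, r2 = gaussian_aic(y, _design(X, mains, inters))
    return StepwiseModel(main_effects=mains, interactions=inters,
                         screened=screened, aic=aic_final, r_squared=r2,
                         trace=trace)
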