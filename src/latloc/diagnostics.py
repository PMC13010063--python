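"""Global-vs-local model contrast, patient flagging, subgroups, profiles.

A single OLS model of the outcome on the latent dimensions (the *global*
model) is fitted once on the training cohort.  Each patient's local
coefficients are compared against it: a patient is flagged on a latent
dimension when the local coefficient falls strictly outside the global
95% confidence interval for that dimension.  Flagged patients sharing a
dimension and deviation direction form candidate subgroups, which are then
characterized back in the original predictor space through mean Z-score
profiles, predictor clustering, and subgroup-by-predictor interaction
models.  Test patients are projected through the trained encoder and given
local fits over training-only neighbourhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .autoencoder import AutoencoderParams, encode
from .local_regression import KernelSpec, fit_local_wls

__all__ = [
    "GlobalFit", "Subgroup", "RMSEContrast", "LatentCorrelationMatrix",
    "fit_global", "deviation_profile", "form_subgroups", "latent_correlation",
    "zscore_profile", "cluster_predictors", "interaction_analysis",
    "rmse_contrast", "project_test",
]


@dataclass
class GlobalFit:
    """OLS of the outcome on (1, Z) with t-based confidence intervals."""

    coefficients: np.ndarray  # (d+1,), intercept first
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    r_squared: float
    residual_sd: float
    fitted: np.ndarray
    ci_level: float = 0.95


@dataclass
class Subgroup:
    id: str
    dim: int            # latent dimension, 1-based in reports
    sign: int           # +1 / -1 direction of deviation
    members: np.ndarray
    size: int


@dataclass
class RMSEContrast:
    rmse_global_inside: float
    rmse_local_inside: float
    rmse_global_outside: float
    rmse_local_outside: float

    @property
    def improvement_inside(self) -> float:
        return self.rmse_global_inside - self.rmse_local_inside

    @property
    def improvement_outside(self) -> float:
        return self.rmse_global_outside - self.rmse_local_outside


@dataclass
class LatentCorrelationMatrix:
    corr: np.ndarray       # d x p Pearson correlations
    top: list              # per dim, predictor indices by |corr|, best first


def fit_global(Z: np.ndarray, y: np.ndarray, ci_level: float = 0.95) -> GlobalFit:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    n, d = Z.shape
    if n <= d + 1:
        raise ValueError(f"need n > d + 1, got n={n}, d={d}")
    design = sm.add_constant(Z, has_constant="add")
    if np.linalg.matrix_rank(design) < d + 1:
        raise ValueError("rank-deficient latent design")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=1.0 - ci_level)
    return GlobalFit(
        coefficients=np.asarray(res.params),
        ci_lower=np.asarray(ci)[:, 0],
        ci_upper=np.asarray(ci)[:, 1],
        r_squared=float(res.rsquared),
        residual_sd=float(np.sqrt(res.mse_resid)),
        fitted=np.asarray(res.fittedvalues),
        ci_level=ci_level,
    )


def deviation_profile(local_beta: np.ndarray, global_fit: GlobalFit,
                      patient_ids: Optional[Sequence] = None) -> pd.DataFrame:
    """Per patient x latent dimension contrast against the global fit.

    A patient is flagged on a dimension when the local coefficient lies
    strictly outside the global confidence interval (a value exactly on the
    boundary is not flagged).  Columns: patient, dim (1-based), beta_local,
    beta_global, diff, flag, sign.
    """
    beta = np.atleast_2d(np.asarray(local_beta, dtype=float))
    n, d1 = beta.shape
    if d1 != global_fit.coefficients.shape[0]:
        raise ValueError("local and global fits disagree in dimension")
    if patient_ids is None:
        patient_ids = np.arange(n)
    rows = []
    for dim in range(1, d1):
        bl = beta[:, dim]
        bg = global_fit.coefficients[dim]
        lo, hi = global_fit.ci_lower[dim], global_fit.ci_upper[dim]
        diff = bl - bg
        flag = (bl < lo) | (bl > hi)
        rows.append(pd.DataFrame({
            "patient": patient_ids, "dim": dim, "beta_local": bl,
            "beta_global": bg, "diff": diff, "flag": flag,
            "sign": np.sign(diff).astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


def form_subgroups(profile: pd.DataFrame, min_size: int = 5) -> List[Subgroup]:
    """Collect flagged patients by (dimension, deviation direction).

    Returns subgroups of at least ``min_size`` members, largest first.
    Patients may belong to several subgroups through different dimensions.
    """
    subgroups = []
    flagged = profile[profile["flag"]]
    for (dim, sign), grp in flagged.groupby(["dim", "sign"]):
        if sign == 0 or len(grp) < min_size:
            continue
        members = np.sort(grp["patient"].to_numpy())
        label = "pos" if sign > 0 else "neg"
        subgroups.append(Subgroup(id=f"dim{dim}_{label}", dim=int(dim),
                                  sign=int(sign), members=members,
                                  size=len(members)))
    subgroups.sort(key=lambda s: (-s.size, s.dim, -s.sign))
    return subgroups


def latent_correlation(Z: np.ndarray, X_std: np.ndarray,
                       top_m: int = 5) -> LatentCorrelationMatrix:
    """Pearson correlation of each latent dimension with each predictor."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = np.atleast_2d(np.asarray(X_std, dtype=float))
    d, p = Z.shape[1], X.shape[1]
    corr = np.zeros((d, p))
    Xc = X - X.mean(axis=0)
    xs = X.std(axis=0)
    for l in range(d):
        z = Z[:, l]
        zs = z.std()
        if zs == 0:
            warnings.warn(f"latent dimension {l + 1} has zero variance; "
                          f"correlations set to 0")
            continue
        corr[l] = ((z - z.mean()) @ Xc) / (Z.shape[0] * zs * xs)
    top = [np.argsort(-np.abs(corr[l]), kind="stable")[:top_m].tolist()
           for l in range(d)]
    return LatentCorrelationMatrix(corr=corr, top=top)


def zscore_profile(X_std: np.ndarray, members: np.ndarray,
                   clusters: Optional[np.ndarray] = None) -> np.ndarray:
    """Mean standardized predictor values among subgroup members.

    With ``clusters`` (predictor -> cluster labels) the per-predictor means
    are averaged within clusters, giving one value per cluster.
    """
    X = np.atleast_2d(np.asarray(X_std, dtype=float))
    members = np.asarray(members)
    if members.dtype == bool:
        members = np.flatnonzero(members)
    if members.size == 0:
        raise ValueError("empty subgroup")
    profile = X[members].mean(axis=0)
    if clusters is None:
        return profile
    clusters = np.asarray(clusters)
    labels = np.unique(clusters)
    return np.array([profile[clusters == c].mean() for c in labels])


def cluster_predictors(X_std: np.ndarray, n_clusters: int = 21) -> np.ndarray:
    """Group predictors by hierarchical clustering on 1 - |correlation|.

    Average linkage, cut at ``n_clusters``; returns a label per predictor
    (1..n_clusters).
    """
    X = np.atleast_2d(np.asarray(X_std, dtype=float))
    p = X.shape[1]
    if p < n_clusters:
        raise ValueError(f"need p >= n_clusters, got p={p}, n_clusters={n_clusters}")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = np.flatnonzero(sds == 0)
        raise ValueError(f"constant predictor column(s): {bad.tolist()}")
    corr = np.corrcoef(X.T)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    link = linkage(squareform(dist, checks=False), method="average")
    return fcluster(link, t=n_clusters, criterion="maxclust")


def interaction_analysis(X_std: np.ndarray, y: np.ndarray,
                         members: np.ndarray,
                         predictors: Sequence[int]) -> pd.DataFrame:
    """Subgroup-by-predictor interaction models in the original space.

    For each tested predictor x, fits OLS of y on {x, g, x*g} with g the
    subgroup indicator, and reports the interaction coefficient, its
    standard error, the raw two-sided p-value and the Benjamini-Hochberg
    adjusted p-value across the tested predictors.
    """
    X = np.atleast_2d(np.asarray(X_std, dtype=float))
    y = np.asarray(y, dtype=float)
    members = np.asarray(members)
    if members.dtype == bool:
        members = np.flatnonzero(members)
    if members.size == 0:
        raise ValueError("empty subgroup")
    g = np.zeros(X.shape[0])
    g[members] = 1.0
    rows = []
    for j in predictors:
        x = X[:, j]
        design = sm.add_constant(np.column_stack([x, g, x * g]),
                                 has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(f"predictor {j}: interaction design is collinear "
                          f"(e.g. constant subgroup indicator); skipped")
            continue
        res = sm.OLS(y, design).fit()
        rows.append({"predictor": int(j), "coef": float(res.params[3]),
                     "se": float(res.bse[3]), "p_value": float(res.pvalues[3])})
    frame = pd.DataFrame(rows, columns=["predictor", "coef", "se", "p_value"])
    if len(frame):
        frame["p_bh"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    else:
        frame["p_bh"] = pd.Series(dtype=float)
    return frame


def rmse_contrast(y: np.ndarray, global_fitted: np.ndarray,
                  local_fitted: np.ndarray, members: np.ndarray) -> RMSEContrast:
    """Global vs local RMSE, inside vs outside the subgroup.

    ``local_fitted[i]`` must be patient i's own local model evaluated at
    its own latent point.
    """
    y = np.asarray(y, dtype=float)
    members = np.asarray(members)
    if members.dtype != bool:
        mask = np.zeros(y.shape[0], dtype=bool)
        mask[members] = True
        members = mask
    if members.all() or not members.any():
        raise ValueError("subgroup must be a strict, nonempty subset")

    def rmse(res, m):
        return float(np.sqrt(np.mean(res[m] ** 2)))

    eg = y - np.asarray(global_fitted, dtype=float)
    el = y - np.asarray(local_fitted, dtype=float)
    return RMSEContrast(
        rmse_global_inside=rmse(eg, members),
        rmse_local_inside=rmse(el, members),
        rmse_global_outside=rmse(eg, ~members),
        rmse_local_outside=rmse(el, ~members),
    )


def project_test(X_test_std: np.ndarray, params: AutoencoderParams,
                 train_Z: np.ndarray, train_y: np.ndarray,
                 global_fit: GlobalFit, kernel: KernelSpec,
                 ridge_eps: float = 1e-6,
                 subgroups: Optional[List[Subgroup]] = None):
    """Project test patients into the trained latent space and contrast them.

    Each test patient's local model is fitted over the *training* patients
    only: the adaptive bandwidth is the distance to the k-th nearest
    training neighbour, and weights never involve other test patients.
    Flags use the training global fit's confidence intervals.  Returns
    ``(profile, assignments)`` where ``assignments`` maps each test patient
    to the ids of subgroups whose (dimension, direction) rule it satisfies.
    """
    X_test_std = np.asarray(X_test_std, dtype=float)
    if X_test_std.size == 0:
        return pd.DataFrame(columns=["patient", "dim", "beta_local",
                                     "beta_global", "diff", "flag", "sign"]), {}
    Z_test = encode(X_test_std, params)
    train_Z = np.atleast_2d(np.asarray(train_Z, dtype=float))
    n_train = train_Z.shape[0]
    k = kernel.resolve_k(n_train)
    from scipy.spatial.distance import cdist
    D = cdist(Z_test, train_Z)
    dk = np.sort(D, axis=1, kind="stable")[:, k - 1]  # no self column here
    if np.any(dk == 0):
        raise ValueError("zero adaptive bandwidth for a test patient; raise k")
    u = D / dk[:, None]
    if kernel.family == "gaussian":
        W = np.exp(-(u ** 2) / (2.0 * kernel.sigma ** 2))
    else:
        W = np.where(u < 1.0, (1.0 - np.clip(u, 0, 1) ** 3) ** 3, 0.0)
    beta = np.vstack([fit_local_wls(train_Z, train_y, W[i], ridge_eps)
                      for i in range(Z_test.shape[0])])
    profile = deviation_profile(beta, global_fit)
    assignments = {}
    if subgroups:
        for i in range(Z_test.shape[0]):
            hits = []
            for sg in subgroups:
                row = profile[(profile["patient"] == i)
                              & (profile["dim"] == sg.dim)]
                if bool(row["flag"].iloc[0]) and int(row["sign"].iloc[0]) == sg.sign:
                    hits.append(sg.id)
            assignments[i] = hits
    return profile, assignments
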