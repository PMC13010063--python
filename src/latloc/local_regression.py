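"""Kernel-weighted patient-specific regression in the latent space.

For each patient i with latent vector z_i, neighbours j are weighted by

    w_ij = K(||z_i - z_j||_2 / d_k(z_i)),

where d_k(z_i) is the distance from z_i to its k-th nearest neighbour
(self excluded) and K is by default the Gaussian kernel
K_G(x) = exp(-x^2 / (2 sigma^2)).  A weighted least-squares fit of the
outcome on the latent coordinates (with intercept) gives the patient's
local coefficients; a weighted intercept-only fit gives the local null
model.  The per-patient prediction-loss term is the negative log of the
ratio of weighted Gaussian likelihoods of the two fits with plug-in
variances, which collapses to the closed form

    (sum_j w_ij / 2) * log(sigma2_full / sigma2_null)  <=  0.

A tricube kernel is available for comparison but is discouraged: its hard
cutoff assigns zero weight outside the bandwidth, which destabilizes local
fits in sparse latent regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec", "LocalWeights", "LocalFit", "LocalFitSet",
    "pairwise_distances", "adaptive_bandwidth", "kernel_weights",
    "fit_local_wls", "fit_local_null", "neg_log_likelihood_ratio",
    "local_fit", "fit_all_local", "prediction_loss", "default_k",
]

VARIANCE_FLOOR = 1e-8


def default_k(n: int) -> int:
    """Default neighbourhood order: ceil(0.3 n), clipped to [1, n-1]."""
    return int(min(max(1, np.ceil(0.3 * n)), n - 1))


@dataclass
class KernelSpec:
    """Kernel family, bandwidth sigma, and neighbourhood order k.

    ``k=None`` resolves to ``ceil(0.3 n)`` at fit time.
    """

    family: str = "gaussian"
    sigma: float = 1.0
    k: Optional[int] = None

    def validate(self, n: Optional[int] = None) -> None:
        if self.family not in ("gaussian", "tricube"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.k is not None:
            if self.k < 1 or (n is not None and self.k > n - 1):
                raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={self.k}")

    def resolve_k(self, n: int) -> int:
        return default_k(n) if self.k is None else int(self.k)


@dataclass
class LocalWeights:
    """Row i holds the weights w_ij for target patient i."""

    W: np.ndarray   # n x n
    dk: np.ndarray  # n adaptive bandwidths


@dataclass
class LocalFit:
    """One patient's local full and null fits."""

    beta: np.ndarray        # (d+1,) intercept first
    beta_null: float
    sigma2_full: float
    sigma2_null: float
    neg_log_ratio: float


@dataclass
class LocalFitSet:
    """Vectorized local fits for a whole cohort."""

    beta: np.ndarray         # n x (d+1)
    beta_null: np.ndarray    # n
    sigma2_full: np.ndarray  # n
    sigma2_null: np.ndarray  # n
    neg_log_ratio: np.ndarray  # n
    weights: LocalWeights
    fitted_self: np.ndarray  # n, patient i's own local model evaluated at z_i


def pairwise_distances(Z: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between latent rows."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] < 2:
        raise ValueError("need at least two patients")
    if not np.all(np.isfinite(Z)):
        raise ValueError("latent representation contains non-finite values")
    D = cdist(Z, Z)
    np.fill_diagonal(D, 0.0)
    return D


def adaptive_bandwidth(distances: np.ndarray, k: int) -> np.ndarray:
    """Distance from each point to its k-th nearest neighbour (self excluded)."""
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")
    # row-sorted distances include the self distance 0 in position 0,
    # so the k-th neighbour sits at sorted position k
    dk = np.sort(D, axis=1, kind="stable")[:, k]
    if np.any(dk == 0):
        bad = np.flatnonzero(dk == 0)
        raise ValueError(
            f"zero adaptive bandwidth for patient(s) {bad.tolist()}: duplicate "
            f"latent points up to the k-th neighbour; raise k or jitter the inputs")
    return dk


def kernel_weights(distances: np.ndarray, dk: np.ndarray,
                   spec: KernelSpec) -> LocalWeights:
    spec.validate()
    D = np.asarray(distances, dtype=float)
    u = D / np.asarray(dk, dtype=float)[:, None]
    if spec.family == "gaussian":
        W = np.exp(-(u ** 2) / (2.0 * spec.sigma ** 2))
    else:  # tricube
        W = np.where(u < 1.0, (1.0 - np.clip(u, 0, 1) ** 3) ** 3, 0.0)
    np.fill_diagonal(W, 1.0)
    return LocalWeights(W=W, dk=np.asarray(dk, dtype=float))


def fit_local_wls(Z: np.ndarray, y: np.ndarray, w_i: np.ndarray,
                  ridge_eps: float = 1e-6) -> np.ndarray:
    """Weighted least squares of y on (1, Z) under weights w_i.

    ``ridge_eps`` is added to the Gram diagonal for the slope block only
    (the intercept is never penalized); with ``ridge_eps=0`` and a
    full-rank weighted design this is the exact WLS minimizer.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    w = np.asarray(w_i, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative with at least one positive")
    A = np.column_stack([np.ones(Z.shape[0]), Z])
    G = A.T @ (w[:, None] * A)
    G[1:, 1:] += ridge_eps * np.eye(Z.shape[1])
    b = A.T @ (w * y)
    try:
        return np.linalg.solve(G, b)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular weighted Gram matrix; pass ridge_eps > 0") from err


def fit_local_null(y: np.ndarray, w_i: np.ndarray) -> float:
    """Weighted intercept-only fit: the weighted mean of y."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w_i, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative with at least one positive")
    return float(np.sum(w * y) / np.sum(w))


def neg_log_likelihood_ratio(w_i: np.ndarray, residuals_full: np.ndarray,
                             residuals_null: np.ndarray,
                             floor: float = VARIANCE_FLOOR) -> float:
    """-log of the weighted-Gaussian likelihood ratio, full over null.

    With plug-in variances sigma2 = sum(w e^2)/sum(w) the weighted
    log-likelihood is sum_j w_j [-0.5 log(2 pi sigma2) - e_j^2/(2 sigma2)]
    = -(S/2) (log(2 pi sigma2) + 1), so the ratio term reduces to
    (S/2) log(sigma2_full / sigma2_null).  A locally constant outcome
    (null variance below the floor) contributes 0 with a warning.
    """
    w = np.asarray(w_i, dtype=float)
    S = float(np.sum(w))
    s2_full = float(np.sum(w * np.asarray(residuals_full) ** 2) / S)
    s2_null = float(np.sum(w * np.asarray(residuals_null) ** 2) / S)
    if s2_null < floor:
        warnings.warn("locally constant outcome: null variance below floor, "
                      "likelihood-ratio term set to 0")
        return 0.0
    s2_full = max(s2_full, floor)
    return (S / 2.0) * float(np.log(s2_full / s2_null))


def local_fit(Z: np.ndarray, y: np.ndarray, w_i: np.ndarray,
              ridge_eps: float = 1e-6, floor: float = VARIANCE_FLOOR) -> LocalFit:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    w = np.asarray(w_i, dtype=float)
    beta = fit_local_wls(Z, y, w, ridge_eps)
    beta0 = fit_local_null(y, w)
    A = np.column_stack([np.ones(Z.shape[0]), Z])
    e_full = y - A @ beta
    e_null = y - beta0
    S = np.sum(w)
    s2_full = float(np.sum(w * e_full ** 2) / S)
    s2_null = float(np.sum(w * e_null ** 2) / S)
    nlr = neg_log_likelihood_ratio(w, e_full, e_null, floor)
    return LocalFit(beta=beta, beta_null=beta0, sigma2_full=s2_full,
                    sigma2_null=s2_null, neg_log_ratio=nlr)


def fit_all_local(Z: np.ndarray, y: np.ndarray, spec: KernelSpec,
                  ridge_eps: float = 1e-6,
                  floor: float = VARIANCE_FLOOR) -> LocalFitSet:
    """Local full and null fits for every patient, batched over the cohort."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    n, d = Z.shape
    spec.validate(n)
    D = pairwise_distances(Z)
    dk = adaptive_bandwidth(D, spec.resolve_k(n))
    lw = kernel_weights(D, dk, spec)
    W = lw.W

    A = np.column_stack([np.ones(n), Z])
    G = np.einsum("ij,ja,jb->iab", W, A, A)
    ridge = np.zeros((d + 1, d + 1))
    ridge[1:, 1:] = ridge_eps * np.eye(d)
    b = np.einsum("ij,ja,j->ia", W, A, y)
    beta = np.linalg.solve(G + ridge, b[..., None])[..., 0]

    S = W.sum(axis=1)
    fitted = beta @ A.T                        # n x n: model i at patient j
    e_full = y[None, :] - fitted
    s2_full = np.einsum("ij,ij->i", W, e_full ** 2) / S
    beta_null = (W @ y) / S
    e_null = y[None, :] - beta_null[:, None]
    s2_null = np.einsum("ij,ij->i", W, e_null ** 2) / S

    nlr = np.where(s2_null < floor, 0.0,
                   (S / 2.0) * np.log(np.maximum(s2_full, floor)
                                      / np.maximum(s2_null, floor)))
    if np.any(s2_null < floor):
        warnings.warn("locally constant outcome for some patients: "
                      "their likelihood-ratio terms set to 0")
    fitted_self = np.einsum("ia,ia->i", beta, A)
    return LocalFitSet(beta=beta, beta_null=beta_null, sigma2_full=s2_full,
                       sigma2_null=s2_null, neg_log_ratio=nlr,
                       weights=lw, fitted_self=fitted_self)


def prediction_loss(Z: np.ndarray, y: np.ndarray, spec: KernelSpec,
                    ridge_eps: float = 1e-6,
                    floor: float = VARIANCE_FLOOR) -> float:
    """Mean per-patient negative log likelihood ratio; always <= 0."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] < Z.shape[1] + 2:
        raise ValueError("need n >= d + 2 patients for local fits")
    fits = fit_all_local(Z, y, spec, ridge_eps, floor)
    return float(np.mean(fits.neg_log_ratio))
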