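"""Synthetic cohorts with a low-dimensional manifold and planted subgroups.

The downstream diagnostics assume that the patient characteristics lie near
a low-dimensional nonlinear manifold, that the outcome is linearly related
to the manifold coordinates for most patients, and that one or more
subgroups exist whose *coefficients* — not their covariate distribution —
deviate from the global relationship.  :func:`generate` produces exactly
this structure with known ground truth, so every stage of the pipeline can
be validated without access to clinical data.

Generation model
----------------
Latent coordinates ``u_i ~ N(0, I_d_true)``; predictors
``x_i = m(M u_i) + eps``, with ``M`` a p x d_true mixing matrix (random
columns scaled to unit norm unless supplied explicitly), ``m`` either the
identity or an elementwise tanh, and ``eps`` iid Gaussian noise.  The
outcome is ``y_i = u_i . beta_i + delta_i`` where ``beta_i`` equals the
global coefficient vector except for subgroup members, whose coefficient on
one designated latent direction is shifted by a configured delta.

Subgroup placement ("region" mode, the default) draws members as a random
majority (``subgroup_purity``) of the patients closest to a configurable
location on the target latent direction (default one SD above its mean),
so the subgroup forms a contiguous latent region — the geometry
kernel-localized regression can discover — while the latent coordinates
stay iid standard normal and membership is never a deterministic function
of the predictors.  A moderate, off-center location keeps the planted
coefficient deviation expressed in the outcome without handing the
subgroup the leverage to drag the global fit far from the background
relationship.  "scattered" mode draws members uniformly instead, leaving
no spatial structure to find.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig", "SyntheticDataset", "StandardizationStats",
    "generate", "standardize", "train_test_split",
    "write_dataset", "read_dataset",
]


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic cohort.

    Defaults correspond to the reference recovery scenario used throughout
    the test-bench: 200 patients, 30 predictors mixed from a 2-D tanh
    manifold, a global coefficient vector of ones, and a single subgroup of
    15% of patients — drawn as a 60% majority of a contiguous region one SD
    off-center on the second latent direction — whose coefficient on that
    direction is shifted by -1.5.
    """

    n: int = 200
    p: int = 30
    d_true: int = 2
    mixing_nonlinearity: str = "tanh"  # "none" | "tanh"
    predictor_noise_sd: float = 0.1
    beta_global_true: Optional[Sequence[float]] = None  # default: ones(d_true)
    subgroups: Sequence[tuple] = field(default_factory=lambda: [(0.15, 1, -1.5)])
    outcome_noise_sd: float = 0.3
    seed: int = 0
    subgroup_mode: str = "region"  # "region" | "scattered"
    subgroup_purity: float = 0.6   # member share inside the region (region mode)
    subgroup_region_center: float = 1.0  # region location on the target dim (SD units)
    mixing_matrix: Optional[np.ndarray] = None  # p x d_true; used as-is

    def resolved_beta(self) -> np.ndarray:
        if self.beta_global_true is None:
            return np.ones(self.d_true)
        return np.asarray(self.beta_global_true, dtype=float)

    def validate(self) -> None:
        if self.n < 10:
            raise ValueError(f"n must be >= 10, got n={self.n}")
        if not (1 <= self.d_true <= self.p):
            raise ValueError(
                f"d_true must satisfy 1 <= d_true <= p, got d_true={self.d_true}, p={self.p}")
        if self.mixing_nonlinearity not in ("none", "tanh"):
            raise ValueError(
                f"mixing_nonlinearity must be 'none' or 'tanh', got {self.mixing_nonlinearity!r}")
        if self.predictor_noise_sd < 0:
            raise ValueError(f"predictor_noise_sd must be >= 0, got {self.predictor_noise_sd}")
        if self.outcome_noise_sd < 0:
            raise ValueError(f"outcome_noise_sd must be >= 0, got {self.outcome_noise_sd}")
        beta = self.resolved_beta()
        if beta.shape != (self.d_true,):
            raise ValueError(
                f"beta_global_true must have length d_true={self.d_true}, got {beta.shape}")
        total_frac = 0.0
        for frac, dim, _delta in self.subgroups:
            if not (0 < frac < 1):
                raise ValueError(f"subgroups: fraction must be in (0, 1), got {frac}")
            if not (0 <= dim < self.d_true):
                raise ValueError(
                    f"subgroups: target latent dim {dim} out of range [0, {self.d_true})")
            total_frac += frac
        if total_frac >= 1:
            raise ValueError(
                f"subgroups: fractions must sum to < 1, got {total_frac}")
        if self.subgroup_mode not in ("region", "scattered"):
            raise ValueError(
                f"subgroup_mode must be 'region' or 'scattered', got {self.subgroup_mode!r}")
        if not (0 < self.subgroup_purity <= 1):
            raise ValueError(
                f"subgroup_purity must be in (0, 1], got {self.subgroup_purity}")
        if self.mixing_matrix is not None:
            M = np.asarray(self.mixing_matrix, dtype=float)
            if M.shape != (self.p, self.d_true):
                raise ValueError(
                    f"mixing_matrix must be p x d_true = {(self.p, self.d_true)}, got {M.shape}")


@dataclass
class SyntheticDataset:
    """Generated cohort together with its ground truth."""

    X_raw: np.ndarray          # n x p predictors
    y_raw: np.ndarray          # n outcome
    latent_true: np.ndarray    # n x d_true manifold coordinates
    subgroup_labels: np.ndarray  # n ints, 0 = background
    beta_by_patient: np.ndarray  # n x d_true true local coefficients
    config: SyntheticConfig


@dataclass
class StandardizationStats:
    """Column means/SDs of predictors plus the outcome (last entry)."""

    means: np.ndarray
    sds: np.ndarray
    computed_on: str = "all"  # "train" | "all"


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, d = config.n, config.p, config.d_true

    latent = rng.standard_normal((n, d))
    order = rng.permutation(n)

    beta_global = config.resolved_beta()
    beta = np.tile(beta_global, (n, 1))
    labels = np.zeros(n, dtype=int)
    pos = 0
    for sg_id, (frac, dim, delta) in enumerate(config.subgroups, start=1):
        count = int(round(frac * n))
        if config.subgroup_mode == "region":
            region_size = min(n, int(round(count / config.subgroup_purity)))
            closeness = np.abs(latent[:, dim] - config.subgroup_region_center)
            free = np.array([i for i in np.argsort(closeness, kind="stable")
                             if labels[i] == 0][:region_size])
            members = rng.permutation(free)[:count]
        else:
            free = order[labels[order] == 0]
            members = free[pos:pos + count]
            pos += count
        labels[members] = sg_id
        beta[members, dim] += delta

    if config.mixing_matrix is not None:
        M = np.asarray(config.mixing_matrix, dtype=float)
    else:
        M = rng.standard_normal((p, d))
        M /= np.linalg.norm(M, axis=0, keepdims=True)

    lin = latent @ M.T
    X = np.tanh(lin) if config.mixing_nonlinearity == "tanh" else lin
    if config.predictor_noise_sd > 0:
        X = X + rng.normal(0.0, config.predictor_noise_sd, size=(n, p))
    else:
        X = X.copy()

    y = np.einsum("ij,ij->i", latent, beta)
    if config.outcome_noise_sd > 0:
        y = y + rng.normal(0.0, config.outcome_noise_sd, size=n)

    return SyntheticDataset(X_raw=X, y_raw=y, latent_true=latent,
                            subgroup_labels=labels, beta_by_patient=beta,
                            config=config)


def standardize(X, y=None, stats: Optional[StandardizationStats] = None,
                computed_on: str = "all"):
    """Center/scale columns of ``X`` (and optionally ``y``) to mean 0, SD 1.

    When ``stats`` is given (e.g. derived from the training split) it is
    applied as-is, so test data are transformed on the training scale.
    Returns ``(X_std, y_std, stats)``; ``y_std`` is None when no outcome is
    passed.  SDs use the population convention (ddof=0).
    """
    X = np.asarray(X, dtype=float)
    has_y = y is not None
    if has_y:
        y = np.asarray(y, dtype=float)
    if stats is None:
        x_means = X.mean(axis=0)
        x_sds = X.std(axis=0)
        zero = np.flatnonzero(x_sds == 0)
        if zero.size:
            raise ValueError(f"zero-variance predictor column(s): {zero.tolist()}")
        if has_y:
            y_sd = y.std()
            if y_sd == 0:
                raise ValueError("zero-variance outcome column")
            means = np.append(x_means, y.mean())
            sds = np.append(x_sds, y_sd)
        else:
            means, sds = x_means, x_sds
        stats = StandardizationStats(means=means, sds=sds, computed_on=computed_on)
    expect = X.shape[1] + (1 if has_y else 0)
    if stats.means.shape[0] not in (X.shape[1], X.shape[1] + 1):
        raise ValueError(
            f"standardization stats have {stats.means.shape[0]} columns, expected {expect}")
    X_std = (X - stats.means[:X.shape[1]]) / stats.sds[:X.shape[1]]
    y_std = None
    if has_y:
        if stats.means.shape[0] != X.shape[1] + 1:
            raise ValueError("stats lack an outcome column")
        y_std = (y - stats.means[-1]) / stats.sds[-1]
    return X_std, y_std, stats


def train_test_split(n, test_fraction: float, seed: int):
    """Disjoint, exhaustive train/test index arrays; deterministic per seed.

    ``n`` may be a patient count or a :class:`SyntheticDataset`.  The test
    size is ``round(n * test_fraction)`` with a floor of one patient.
    """
    if isinstance(n, SyntheticDataset):
        n = n.X_raw.shape[0]
    if not (0 < test_fraction < 1):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n_test = max(1, int(round(n * test_fraction)))
    n_test = min(n_test, n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# CSV round trip (x1..xp, y, truth_* columns) plus a JSON config sidecar


def write_dataset(dataset: SyntheticDataset, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n, p = dataset.X_raw.shape
    d = dataset.latent_true.shape[1]
    cols = {f"x{j + 1}": dataset.X_raw[:, j] for j in range(p)}
    cols["y"] = dataset.y_raw
    cols["truth_subgroup"] = dataset.subgroup_labels
    for l in range(d):
        cols[f"truth_z{l + 1}"] = dataset.latent_true[:, l]
        cols[f"truth_beta{l + 1}"] = dataset.beta_by_patient[:, l]
    pd.DataFrame(cols).to_csv(directory / "data.csv", index=False)
    cfg = dataset.config
    sidecar = {
        "n": cfg.n, "p": cfg.p, "d_true": cfg.d_true,
        "mixing_nonlinearity": cfg.mixing_nonlinearity,
        "predictor_noise_sd": cfg.predictor_noise_sd,
        "beta_global_true": cfg.resolved_beta().tolist(),
        "subgroups": [list(s) for s in cfg.subgroups],
        "outcome_noise_sd": cfg.outcome_noise_sd,
        "seed": cfg.seed,
        "subgroup_mode": cfg.subgroup_mode,
        "subgroup_purity": cfg.subgroup_purity,
        "subgroup_region_center": cfg.subgroup_region_center,
    }
    (directory / "config.json").write_text(json.dumps(sidecar, indent=2))
    return directory / "data.csv"


def read_dataset(directory) -> SyntheticDataset:
    directory = Path(directory)
    frame = pd.read_csv(directory / "data.csv")
    sidecar = json.loads((directory / "config.json").read_text())
    config = SyntheticConfig(
        n=sidecar["n"], p=sidecar["p"], d_true=sidecar["d_true"],
        mixing_nonlinearity=sidecar["mixing_nonlinearity"],
        predictor_noise_sd=sidecar["predictor_noise_sd"],
        beta_global_true=sidecar["beta_global_true"],
        subgroups=[tuple(s) for s in sidecar["subgroups"]],
        outcome_noise_sd=sidecar["outcome_noise_sd"],
        seed=sidecar["seed"],
        subgroup_mode=sidecar["subgroup_mode"],
        subgroup_purity=sidecar["subgroup_purity"],
        subgroup_region_center=sidecar["subgroup_region_center"],
    )
    p, d = config.p, config.d_true
    X = frame[[f"x{j + 1}" for j in range(p)]].to_numpy(float)
    y = frame["y"].to_numpy(float)
    latent = frame[[f"truth_z{l + 1}" for l in range(d)]].to_numpy(float)
    beta = frame[[f"truth_beta{l + 1}" for l in range(d)]].to_numpy(float)
    labels = frame["truth_subgroup"].to_numpy(int)
    return SyntheticDataset(X_raw=X, y_raw=y, latent_true=latent,
                            subgroup_labels=labels, beta_by_patient=beta,
                            config=config)
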