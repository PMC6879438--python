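"""ComBat location-scale harmonization of radiomic feature tables.

Implements the parametric empirical-Bayes variant of the classical
gene-expression batch correction, applied directly to numeric feature
columns across scanner batches: each feature is standardized against its
grand mean and pooled variance, per-batch location (gamma) and scale
(delta^2) effects are estimated, shrunk toward batch-level priors (normal
for gamma, inverse-gamma for delta^2) by the iterative EB scheme, and the
data are adjusted as ``(z - gamma*) / delta*`` before mapping back to the
original scale.  Batch labels unseen at fit time are rejected at apply
time; row and column order are never permuted.

An optional covariate design matrix can be supplied to protect biological
variation during standardization; it is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CombatModel", "combat_fit", "combat_apply", "combat_fit_apply"]


@dataclass
class CombatModel:
    """Fitted ComBat parameters.

    Attributes
    ----------
    feature_names : list of harmonized columns, in input order.
    batches : batch labels seen at fit.
    alpha : per-feature grand mean (after covariate adjustment).
    sigma : per-feature pooled standard deviation.
    gamma_star, delta_star : EB-shrunk per-(batch, feature) location and
        scale on the standardized z-scale; ``delta_star > 0`` everywhere.
    beta : covariate coefficients (n_covariates x n_features) or None.
    """

    feature_names: list
    batches: list
    alpha: np.ndarray
    sigma: np.ndarray
    gamma_star: np.ndarray   # (n_batches, n_features)
    delta_star: np.ndarray   # (n_batches, n_features), strictly positive
    beta: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "batches": [str(b) for b in self.batches],
            "alpha": self.alpha.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "beta": self.beta.tolist() if self.beta is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CombatModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            feature_names=payload["feature_names"],
            batches=payload["batches"],
            alpha=np.asarray(payload["alpha"]),
            sigma=np.asarray(payload["sigma"]),
            gamma_star=np.asarray(payload["gamma_star"]),
            delta_star=np.asarray(payload["delta_star"]),
            beta=np.asarray(payload["beta"]) if payload["beta"] is not None else None,
        )


def _as_matrix(features: pd.DataFrame) -> tuple[np.ndarray, list]:
    num = features.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("feature table has no numeric columns")
    x = num.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains missing or non-finite values")
    return x, list(num.columns)


def _eb_iterate(
    z_b: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat_sq: np.ndarray,
    gamma_bar: float,
    tau_sq: float,
    a_prior: float,
    b_prior: float,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB posterior for one batch (Johnson-style parametric scheme)."""
    n_b = z_b.shape[0]
    gamma = gamma_hat.copy()
    delta_sq = delta_hat_sq.copy()
    for _ in range(max_iter):
        gamma_new = (n_b * tau_sq * gamma_hat + delta_sq * gamma_bar) / (
            n_b * tau_sq + delta_sq
        )
        ss = ((z_b - gamma_new) ** 2).sum(axis=0)
        delta_new = (0.5 * ss + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(gamma_new - gamma).max(), np.abs(delta_new - delta_sq).max()
        )
        gamma, delta_sq = gamma_new, delta_new
        if change < tol:
            break
    return gamma, delta_sq


def combat_fit(
    features: pd.DataFrame,
    batch,
    min_batch_size: int = 3,
    covariates: np.ndarray | None = None,
) -> CombatModel:
    """Fit ComBat location/scale batch parameters on a feature table.

    Parameters
    ----------
    features : numeric feature columns (non-numeric columns are ignored).
    batch : per-row batch label, aligned with ``features``.
    min_batch_size : smallest admissible batch.
    covariates : optional (n_samples, k) design of biological covariates to
        protect during standardization (no intercept column).
    """
    x, names = _as_matrix(features)
    batch = np.asarray(batch)
    if batch.shape[0] != x.shape[0]:
        raise ValueError("batch vector length does not match the feature table")
    labels, inv = np.unique(batch, return_inverse=True)
    if labels.size < 2:
        raise ValueError("ComBat needs at least 2 batches")
    counts = np.bincount(inv)
    small = labels[counts < min_batch_size]
    if small.size:
        raise ValueError(
            f"batches below min_batch_size={min_batch_size}: {list(small)}"
        )
    zero_var = np.asarray(names)[x.var(axis=0) == 0]
    if zero_var.size:
        raise ValueError(f"zero-variance features cannot be harmonized: {list(zero_var)}")

    n, p = x.shape
    n_batches = labels.size
    onehot = np.eye(n_batches)[inv]
    design = onehot if covariates is None else np.hstack([onehot, covariates])

    # Least-squares batch means (+ covariate effects); grand mean weights
    # batches by size.
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    batch_means = coef[:n_batches]
    alpha = (counts / n) @ batch_means
    beta = coef[n_batches:] if covariates is not None else None
    fitted = design @ coef
    sigma = np.sqrt(((x - fitted) ** 2).mean(axis=0))
    if np.any(sigma == 0):
        bad = [names[i] for i in np.flatnonzero(sigma == 0)]
        raise ValueError(f"zero residual variance for features: {bad}")

    resid = x - alpha
    if beta is not None:
        resid = resid - covariates @ beta
    z = resid / sigma

    gamma_star = np.empty((n_batches, p))
    delta_star_sq = np.empty((n_batches, p))
    for b in range(n_batches):
        z_b = z[inv == b]
        gamma_hat = z_b.mean(axis=0)
        delta_hat_sq = z_b.var(axis=0, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau_sq = float(gamma_hat.var(ddof=1))
        m = float(delta_hat_sq.mean())
        s2 = float(delta_hat_sq.var(ddof=1))
        if s2 == 0 or tau_sq == 0:
            # Fewer than ~2 distinct features: no shrinkage possible.
            gamma_star[b], delta_star_sq[b] = gamma_hat, delta_hat_sq
            continue
        a_prior = (2.0 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2
        gamma_star[b], delta_star_sq[b] = _eb_iterate(
            z_b, gamma_hat, delta_hat_sq, gamma_bar, tau_sq, a_prior, b_prior
        )
    return CombatModel(
        feature_names=names,
        batches=list(labels),
        alpha=np.asarray(alpha, dtype=float),
        sigma=sigma,
        gamma_star=gamma_star,
        delta_star=np.sqrt(delta_star_sq),
        beta=beta,
    )


def combat_apply(
    model: CombatModel,
    features: pd.DataFrame,
    batch,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Harmonize a feature table with a fitted model; row order preserved."""
    batch = np.asarray(batch)
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks fitted columns: {missing}")
    lookup = {str(b): i for i, b in enumerate(model.batches)}
    unseen = sorted({str(b) for b in batch} - set(lookup))
    if unseen:
        raise ValueError(f"batch labels unseen at fit time: {unseen}")
    idx = np.array([lookup[str(b)] for b in batch])

    x = features[model.feature_names].to_numpy(dtype=float)
    resid = x - model.alpha
    if model.beta is not None:
        if covariates is None:
            raise ValueError("model was fitted with covariates; none supplied")
        resid = resid - covariates @ model.beta
    z = resid / model.sigma
    z_adj = (z - model.gamma_star[idx]) / model.delta_star[idx]
    x_adj = z_adj * model.sigma + model.alpha
    if model.beta is not None:
        x_adj = x_adj + covariates @ model.beta

    out = features.copy()
    out[model.feature_names] = x_adj
    return out


def combat_fit_apply(
    features: pd.DataFrame, batch, min_batch_size: int = 3
) -> tuple[pd.DataFrame, CombatModel]:
    """Convenience wrapper: fit on a table and harmonize the same table."""
    model = combat_fit(features, batch, min_batch_size)
    return combat_apply(model, features, batch), model
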