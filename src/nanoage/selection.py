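"""Elastic-net selection of age-informative CpGs.

Age is regressed on the full CpG beta matrix under the elastic-net penalty

    (1/2n) sum_j (age_j - c - sum_i w_i z_ij)^2
        + lam * [ alpha * sum_i |w_i| + (1-alpha)/2 * sum_i w_i^2 ]

with predictors z standardized to zero mean and unit variance, alpha = 0.5 by
default (equal lasso/ridge mix, the standard choice when training epigenetic
clocks), and lam walked down a log-spaced path from lam_max (the smallest
penalty at which every coefficient is zero) over 3 decades.  The solver is
cyclic coordinate descent with soft-thresholding and warm starts, the penalty
path is scored by cross-validated mean squared error (leave-one-out by
default — k-fold is ill-posed at cohort sizes of seven), and the CpGs with
nonzero weight at the chosen penalty are the selected panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .agestats import AgeRegressionRow
from .cohort import BetaMatrix
from .io import CpGSite

log = logging.getLogger(__name__)

_TOL = 1e-7
_MAX_CYCLES = 1_000  # per-penalty cycle cap; the sub-CV-optimum tail of a p >> n
# path is degenerate and not worth polishing to full tolerance


@dataclass
class ElasticNetModel:
    alpha: float
    lambda_path: np.ndarray          # descending
    cv_mean: np.ndarray              # mean CV MSE per lambda
    cv_se: np.ndarray                # standard error of the CV MSE per lambda
    lambda_chosen: float
    intercept: float                 # raw (unstandardized) space
    coef: np.ndarray                 # raw-space weight per site
    sites: list[CpGSite]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    coef_path: np.ndarray = field(repr=False, default=None)  # n_lambda x p, standardized

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.coef != 0.0)

    @property
    def selected_sites(self) -> list[CpGSite]:
        return [self.sites[i] for i in self.selected]

    def predict(self, beta: np.ndarray) -> np.ndarray:
        """Predict ages from a samples x sites beta matrix (raw scale)."""
        return self.intercept + beta @ self.coef


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, matching the 1/n loss scaling
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd


def _cd_path_kernel(
    G: np.ndarray,
    b: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    tol: float,
    max_cycles: int,
    w: np.ndarray,
    g: np.ndarray,
) -> np.ndarray:
    """Warm-started cyclic coordinate descent down a penalty path.

    G = Z'Z/n (Gram), b = Z'y_c/n; the state (w, g = b - Gw) is carried from
    one penalty to the next.  Covariance updates make each coordinate step
    O(p).  Per penalty, glmnet's schedule: a full pass over all coordinates,
    then cheap passes over the active (nonzero) set until stable, repeated
    until a full pass moves no coefficient by more than ``tol``.

    Compiled with numba when available (the loop is scalar-heavy); the plain
    Python version computes the identical iterate sequence.
    """
    p = b.shape[0]
    W = np.zeros((lambdas.shape[0], p))
    for k in range(lambdas.shape[0]):
        lam = lambdas[k]
        thresh = lam * alpha
        denom_l2 = lam * (1.0 - alpha)
        cycles = 0
        converged = False
        while cycles < max_cycles and not converged:
            full_pass = True
            while cycles < max_cycles:
                cycles += 1
                max_delta = 0.0
                for i in range(p):
                    if not full_pass and w[i] == 0.0:
                        continue
                    gii = G[i, i]
                    if gii <= 0.0:  # constant predictor column: pinned at 0
                        w[i] = 0.0
                        continue
                    rho = g[i] + gii * w[i]
                    if rho > thresh:
                        wi_new = (rho - thresh) / (gii + denom_l2)
                    elif rho < -thresh:
                        wi_new = (rho + thresh) / (gii + denom_l2)
                    else:
                        wi_new = 0.0
                    delta = wi_new - w[i]
                    if delta != 0.0:
                        for j in range(p):
                            g[j] -= G[j, i] * delta
                        w[i] = wi_new
                        if abs(delta) > max_delta:
                            max_delta = abs(delta)
                if max_delta < tol:
                    converged = full_pass
                    break
                full_pass = False
        W[k] = w
    return W


try:  # compile the hot loop; the pure-Python path is identical, just slower
    from numba import njit

    _cd_path_compiled = njit(cache=True, fastmath=False)(_cd_path_kernel)
except ImportError:  # pragma: no cover
    _cd_path_compiled = _cd_path_kernel


def enet_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Standardized-space coefficient path, warm-started down the penalties.

    Returns (W, mu, sd, ybar) where W[k] are standardized coefficients at
    lambdas[k]; raw-space coefficients are W[k]/sd.
    """
    n, p = X.shape
    Z, mu, sd = _standardize(X)
    ybar = float(y.mean())
    yc = y - ybar
    G = Z.T @ Z / n
    b = Z.T @ yc / n
    w = np.zeros(p)
    g = b.copy()
    W = _cd_path_compiled(
        G, b, np.ascontiguousarray(lambdas, dtype=np.float64), alpha, _TOL, _MAX_CYCLES, w, g
    )
    return W, mu, sd, ybar


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which every coefficient is exactly zero:
    max_i |z_i . (y - ybar)| / (n alpha)."""
    Z, _, _ = _standardize(X)
    yc = y - y.mean()
    lmax = float(np.max(np.abs(Z.T @ yc)) / len(y))
    return lmax / alpha if alpha > 0 else lmax * 1000.0


def make_lambda_path(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 100,
    min_ratio: float = 1e-3,
) -> np.ndarray:
    lmax = lambda_max(X, y, alpha)
    if lmax <= 0:
        raise ValueError("response has no variance; lambda path undefined")
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def elasticnet_fit(
    m: BetaMatrix,
    alpha: float = 0.5,
    n_lambda: int = 100,
    cv: str | int = "loo",
    lambda_rule: str = "min",
    seed: int = 17,
) -> ElasticNetModel:
    """Fit the cross-validated elastic-net age model on a complete matrix.

    ``cv`` is ``"loo"`` (leave-one-out, deterministic — the default for tiny
    cohorts) or an integer fold count (folds assigned by a seeded shuffle).
    ``lambda_rule`` is ``"min"`` (CV-MSE minimizer) or ``"1se"`` (sparsest
    model within one standard error of the minimum).
    """
    if np.isnan(m.beta).any():
        raise ValueError("matrix has missing entries; apply complete_cases first")
    X = np.ascontiguousarray(m.beta.T)  # samples x sites
    y = m.ages
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("all ages equal; elastic net undefined")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")

    lambdas = make_lambda_path(X, y, alpha, n_lambda)

    # fold assignment
    if cv == "loo":
        folds = [np.array([j]) for j in range(n)]
    else:
        k = int(cv)
        if k < 2 or k > n:
            raise ValueError(f"cv folds must be in [2, {n}]; use 'loo' for tiny cohorts")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = [perm[j::k] for j in range(k)]

    # per-fold path fits on the shared lambda grid, scored on the held-out set
    sq_err = np.empty((n, len(lambdas)))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        W, mu, sd, ybar = enet_path(X[train], y[train], alpha, lambdas)
        sd_safe = np.where(sd > 0, sd, 1.0)
        coefs_raw = W / sd_safe  # n_lambda x p
        pred = ybar + (X[fold] - mu) @ coefs_raw.T
        sq_err[fold] = (pred - y[fold, None]) ** 2
    fold_means = np.stack([sq_err[fold].mean(axis=0) for fold in folds])
    cv_mean = fold_means.mean(axis=0)
    cv_se = fold_means.std(axis=0, ddof=1) / np.sqrt(len(folds))

    k_min = int(np.argmin(cv_mean))
    if lambda_rule == "min":
        k_chosen = k_min
    else:
        within = np.flatnonzero(cv_mean <= cv_mean[k_min] + cv_se[k_min])
        k_chosen = int(within[0])  # path is descending: first index = largest lambda

    W, mu, sd, ybar = enet_path(X, y, alpha, lambdas)
    sd_safe = np.where(sd > 0, sd, 1.0)
    coef = W[k_chosen] / sd_safe
    intercept = ybar - float(coef @ mu)
    model = ElasticNetModel(
        alpha=alpha,
        lambda_path=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_chosen=float(lambdas[k_chosen]),
        intercept=intercept,
        coef=coef,
        sites=list(m.sites),
        feature_means=mu,
        feature_sds=sd,
        coef_path=W,
    )
    log.info(
        "elasticnet_fit: alpha=%g, lambda=%g (%s rule), %d/%d sites selected",
        alpha, model.lambda_chosen, lambda_rule, len(model.selected), p,
    )
    return model


def elasticnet_solve(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float
) -> tuple[float, np.ndarray]:
    """Single-penalty solve (raw-space intercept and coefficients).

    ``lam = 0`` with more samples than predictors reduces to OLS.
    """
    n, p = X.shape
    Z, mu, sd = _standardize(X)
    ybar = float(y.mean())
    yc = y - ybar
    G = Z.T @ Z / n
    b = Z.T @ yc / n
    w = np.zeros(p)
    g = b.copy()
    W = _cd_path_compiled(G, b, np.array([float(lam)]), alpha, _TOL, _MAX_CYCLES, w, g)
    w = W[0]
    sd_safe = np.where(sd > 0, sd, 1.0)
    coef = w / sd_safe
    return ybar - float(coef @ mu), coef


def selected_with_stats(
    model: ElasticNetModel,
    rows: Sequence[AgeRegressionRow],
    min_r2: float = 0.8,
    max_p: float = 0.0005,
) -> list[AgeRegressionRow]:
    """Univariate regression rows for the elastic-net-selected CpGs, filtered
    by (R², p) and sorted by slope descending — the post-hoc per-CpG report
    for a selected panel."""
    by_site = {r.site.key(): r for r in rows}
    out: list[AgeRegressionRow] = []
    for site in model.selected_sites:
        row = by_site.get(site.key())
        if row is None:
            raise ValueError(f"selected site {site.chrom}:{site.pos0} missing from rows")
        if row.r2 >= min_r2 and row.p < max_p:
            out.append(row)
    out.sort(key=lambda r: (-r.slope, r.site.chrom, r.site.pos0))
    return out


def write_model(model: ElasticNetModel, weights_path: str | Path, path_path: str | Path) -> None:
    """Write the nonzero weights and the CV path as TSV reports."""
    with open(weights_path, "w") as fh:
        fh.write("#site\tpos0\tpos1\tweight\n")
        for i in model.selected:
            s = model.sites[i]
            fh.write(f"{s.chrom}_{s.pos1}\t{s.pos0}\t{s.pos1}\t{model.coef[i]:.6g}\n")
    nz = (
        np.count_nonzero(model.coef_path, axis=1)
        if model.coef_path is not None
        else np.zeros(len(model.lambda_path), dtype=int)
    )
    with open(path_path, "w") as fh:
        fh.write("#lambda\tcv_mse\tcv_se\tn_nonzero\n")
        for lam, mse, se, k in zip(model.lambda_path, model.cv_mean, model.cv_se, nz):
            fh.write(f"{lam:.6g}\t{mse:.6g}\t{se:.6g}\t{int(k)}\n")
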