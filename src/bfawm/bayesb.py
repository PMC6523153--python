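"""Weighted BayesB Gibbs sampler for single-trait whole-genome regression.

Model: y_i = mu + sum_j Z_ij u_j delta_j + e_i with e_i ~ N(0, sigma_e^2/w_i).
A fraction pi of markers has zero effect (delta_j = 0); included effects are
N(0, sigma_uj^2) with locus-specific variances under a scaled inverse
chi-square prior (df nu, scale chosen so the implied total genetic variance
matches the supplied initial value).  delta_j and u_j are sampled jointly per
locus by integrating u_j out of the inclusion odds, which avoids the
reducibility of naive Gibbs on (delta, u).

The per-iteration sweep is jitted with numba when available.  The "model
frequency" of marker j is the fraction of saved (post-burn-in, thinned)
samples with delta_j = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._jit import njit

NU_LOCUS_DEFAULT = 4.2
NU_RESIDUAL = 4.0


@dataclass(frozen=True)
class ChainConfig:
    """MCMC settings; the classical full-scale run is 110000/10000/5."""

    pi: float = 0.99
    n_iter: int = 110_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    nu_locus: float = NU_LOCUS_DEFAULT
    init_sigma_a2: float | None = None
    init_sigma_e2: float | None = None
    fix_variances: bool = False
    fit_intercept: bool = True

    def __post_init__(self):
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must lie in [0,1], got {self.pi}")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.nu_locus <= 2.0:
            raise ValueError("nu_locus must exceed 2 (finite prior mean)")

    @property
    def n_saved(self) -> int:
        return -((self.burn_in - self.n_iter) // self.thin)


@dataclass
class BayesBResult:
    marker_ids: list
    post_mean_effect: np.ndarray   # length m
    model_freq: np.ndarray         # length m, in [0,1]
    saved_u: np.ndarray            # (n_saved, m) effect samples
    saved_mu: np.ndarray
    saved_sigma_e2: np.ndarray
    col_means: np.ndarray          # dosage column means used for centering
    active: np.ndarray             # bool mask of non-constant marker columns

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "post_mean_effect": self.post_mean_effect,
                "model_freq": self.model_freq,
            }
        )


@njit(cache=True)
def _chain_kernel(Z, wZ, zwz, y, w, active, pi, n_iter, burn_in, thin, seed,
                  nu, s2_locus, nu_e, s2_resid, sigma_e2_init, fix_variances,
                  fit_intercept, n_saved):
    np.random.seed(seed)
    n, m = Z.shape
    sw = w.sum()
    mu = 0.0
    if fit_intercept:
        mu = (w * y).sum() / sw
    u = np.zeros(m)
    delta = np.zeros(m, np.int8)
    sigma_u2 = np.full(m, s2_locus)
    sigma_e2 = sigma_e2_init
    r = y - mu
    saved_u = np.zeros((n_saved, m))
    saved_mu = np.zeros(n_saved)
    saved_se = np.zeros(n_saved)
    freq = np.zeros(m)
    log_prior_odds = 0.0
    include_possible = pi < 1.0
    if include_possible and pi > 0.0:
        log_prior_odds = math.log((1.0 - pi) / pi)
    s = 0
    for it in range(n_iter):
        if fit_intercept:
            wr = 0.0
            for i in range(n):
                wr += w[i] * r[i]
            mu_new = mu + wr / sw + math.sqrt(sigma_e2 / sw) * np.random.standard_normal()
            d = mu_new - mu
            for i in range(n):
                r[i] -= d
            mu = mu_new
        for j in range(m):
            if not active[j]:
                continue
            u_old = u[j]
            rhs = zwz[j] * u_old
            for i in range(n):
                rhs += wZ[i, j] * r[i]
            mhat = 0.0
            v = 1.0
            if not include_possible:
                d1 = 0
            else:
                c = zwz[j] / sigma_e2
                v = 1.0 / (c + 1.0 / sigma_u2[j])
                mhat = v * rhs / sigma_e2
                log_bf = 0.5 * (math.log(v / sigma_u2[j]) + mhat * mhat / v)
                if pi == 0.0:
                    d1 = 1
                else:
                    t = log_prior_odds + log_bf
                    if t > 35.0:
                        p1 = 1.0
                    elif t < -35.0:
                        p1 = 0.0
                    else:
                        p1 = 1.0 / (1.0 + math.exp(-t))
                    d1 = 1 if np.random.random() < p1 else 0
            if d1 == 1:
                u_new = mhat + math.sqrt(v) * np.random.standard_normal()
            else:
                u_new = 0.0
            if u_new != u_old:
                d = u_new - u_old
                for i in range(n):
                    r[i] -= Z[i, j] * d
            u[j] = u_new
            delta[j] = d1
            if not fix_variances:
                if d1 == 1:
                    sigma_u2[j] = (nu * s2_locus + u_new * u_new) / np.random.chisquare(nu + 1.0)
                else:
                    sigma_u2[j] = nu * s2_locus / np.random.chisquare(nu)
        if not fix_variances:
            sse = 0.0
            for i in range(n):
                sse += w[i] * r[i] * r[i]
            sigma_e2 = (sse + nu_e * s2_resid) / np.random.chisquare(n + nu_e)
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                saved_u[s, j] = u[j]
                freq[j] += delta[j]
            saved_mu[s] = mu
            saved_se[s] = sigma_e2
            s += 1
    return saved_u, saved_mu, saved_se, freq / n_saved


def run_chain(dosages: np.ndarray, y: np.ndarray, cfg: ChainConfig,
              weights: np.ndarray | None = None,
              marker_ids: list | None = None) -> BayesBResult:
    """Run the Gibbs chain on an animals x markers dosage matrix.

    Dosages are column-centered internally (the intercept absorbs the mean);
    zero-variance columns are skipped and report model frequency 0.  Missing
    dosages (NaN) are mean-imputed with a warning.
    """
    Z = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != y.shape[0]:
        raise ValueError("dosage matrix and response dimensions disagree")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    n, m = Z.shape
    if np.isnan(Z).any():
        warnings.warn("missing dosages mean-imputed", stacklevel=2)
        col_mean = np.nanmean(Z, axis=0)
        nan_r, nan_c = np.where(np.isnan(Z))
        Z = Z.copy()
        Z[nan_r, nan_c] = col_mean[nan_c]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per animal")
    col_means = Z.mean(axis=0)
    Zc = Z - col_means
    col_var = Zc.var(axis=0)
    active = col_var > 0
    sum_var = float(col_var[active].sum())
    if sum_var <= 0:
        raise ValueError("all marker columns are constant")

    var_y = float(np.var(y)) or 1.0
    sigma_a2 = cfg.init_sigma_a2 if cfg.init_sigma_a2 is not None else 0.5 * var_y
    sigma_e2 = cfg.init_sigma_e2 if cfg.init_sigma_e2 is not None else 0.5 * var_y
    nu = cfg.nu_locus
    if cfg.fix_variances:
        # init_sigma_a2 is then the common (fixed) per-locus effect variance
        s2_locus = sigma_a2
    else:
        # prior mean of locus variance times expected included marker variance
        # reproduces sigma_a2:  (1-pi) * sum_j var(Z_j) * nu*s2/(nu-2) = sigma_a2
        incl = max(1.0 - cfg.pi, 1.0 / max(m, 1))
        s2_locus = sigma_a2 * (nu - 2.0) / (nu * incl * sum_var)
    s2_resid = sigma_e2 * (NU_RESIDUAL - 2.0) / NU_RESIDUAL

    saved_u, saved_mu, saved_se, model_freq = _chain_kernel(
        Zc, Zc * w[:, None], (w[:, None] * Zc * Zc).sum(axis=0), y, w,
        active, float(cfg.pi), cfg.n_iter, cfg.burn_in, cfg.thin,
        int(cfg.seed) % (2**32), float(nu), float(s2_locus),
        float(NU_RESIDUAL), float(s2_resid), float(sigma_e2),
        cfg.fix_variances, cfg.fit_intercept, cfg.n_saved,
    )
    ids = list(marker_ids) if marker_ids is not None else [f"M{j}" for j in range(m)]
    return BayesBResult(
        marker_ids=ids,
        post_mean_effect=saved_u.mean(axis=0),
        model_freq=model_freq,
        saved_u=saved_u,
        saved_mu=saved_mu,
        saved_sigma_e2=saved_se,
        col_means=col_means,
        active=active,
    )


def genomic_values(dosages: np.ndarray, u: np.ndarray, center: bool = True) -> np.ndarray:
    """Per-animal genomic value Z u (columns centered by default)."""
    Z = np.asarray(dosages, dtype=float)
    u = np.asarray(u, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != u.shape[0]:
        raise ValueError("dimension mismatch between dosages and effects")
    if center:
        Z = Z - Z.mean(axis=0)
    return Z @ u


def weighted_ridge_solution(dosages: np.ndarray, y: np.ndarray, weights: np.ndarray,
                            sigma_u2: float, sigma_e2: float, center: bool = True) -> np.ndarray:
    """Closed-form posterior mean under the ridge limit (pi=0, fixed variances).

    Solves (Z'WZ/sigma_e2 + I/sigma_u2) u = Z'W y / sigma_e2; the sampler's
    posterior-mean effects converge to this when inclusion is forced and the
    variances are held fixed.
    """
    Z = np.asarray(dosages, dtype=float)
    if center:
        Z = Z - Z.mean(axis=0)
    W = np.asarray(weights, dtype=float)
    A = (Z.T * W) @ Z / sigma_e2 + np.eye(Z.shape[1]) / sigma_u2
    b = (Z.T * W) @ np.asarray(y, dtype=float) / sigma_e2
    return np.linalg.solve(A, b)
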