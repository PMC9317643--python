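"""Multivariate-normal EM with missing data, and bootstrap-EM imputation.

``fit_em_normal`` estimates the mean vector and covariance matrix of a
multivariate normal from an incomplete observations x variables matrix by
expectation-maximisation: the E-step replaces each row's missing block with
its conditional mean given the observed block (accumulating the conditional
covariance into the second moment), the M-step updates (mu, Sigma).  A
non-negative ``ridge`` acts as a conjugate-style prior of that strength on
the diagonal: ``Sigma <- (n*Sigma_EM + ridge*D0) / (n + ridge)`` with D0 the
diagonal of the initial observed-data variances.  With ridge = 0 and
complete data the fit equals the closed-form MLE (1/n covariance).

``impute_emb`` is the bootstrap-EM imputer: subjects (columns of the
metabolite x subject input) are the i.i.d. observations.  One bootstrap
resample of subjects is drawn, EM is fitted to it, and each subject's
missing values are drawn from their conditional normal given that subject's
observed values under the fitted parameters.  Because metabolite count
exceeds subject count in these studies, the fit is performed on consecutive
metabolite blocks of ``emb_block_size`` variables to keep the covariance
well conditioned; the ridge strength is ``emb_prior_frac * n_subjects``.
``emb_m > 1`` averages several independent bootstrap imputations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import ImputerSettings


@dataclass
class NormalModelFit:
    mean: np.ndarray
    cov: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def fit_em_normal(
    x: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-4,
    track_loglik: bool = True,
) -> NormalModelFit:
    """EM fit of N(mu, Sigma) to an n x p matrix with NaN missing entries.

    ``track_loglik=False`` skips the observed-data log-likelihood trace
    (used by the bootstrap imputer, where only the parameters matter).
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n <= 2:
        raise ValueError("EM fit needs more than 2 observations")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    miss = np.isnan(x)
    if miss.all(axis=0).any():
        raise ValueError("every variable needs at least one observed value")

    mu = np.nanmean(x, axis=0)
    v0 = np.nanvar(x, axis=0)
    v0 = np.where(v0 > 0, v0, np.maximum(v0.max(initial=1.0), 1.0) * 1e-6)
    sigma = _pairwise_cov_init(x, v0)
    d0 = np.diag(v0)

    # group rows by missingness pattern so each pattern's algebra is done once
    grouped: dict[bytes, list[int]] = {}
    for i in range(n):
        grouped.setdefault(miss[i].tobytes(), []).append(i)
    patterns = []
    for key, rows in grouped.items():
        pat = np.frombuffer(key, dtype=bool)
        o_idx = np.flatnonzero(~pat)
        m_idx = np.flatnonzero(pat)
        patterns.append((
            x[np.ix_(rows, o_idx)], len(rows),
            o_idx, m_idx,
            np.ix_(o_idx, o_idx), np.ix_(o_idx, m_idx), np.ix_(m_idx, m_idx),
        ))

    log2pi = np.log(2 * np.pi)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        loglik = 0.0
        for xo, n_rows, o_idx, m_idx, ix_oo, ix_om, ix_mm in patterns:
            if o_idx.size == 0:  # fully missing row: prior moments only
                s1 += n_rows * mu
                s2 += n_rows * (sigma + np.outer(mu, mu))
                continue
            mu_o = mu[o_idx]
            soo = sigma[ix_oo]
            try:
                cho = linalg.cho_factor(soo, lower=True, check_finite=False)
            except linalg.LinAlgError:
                soo = soo + 1e-8 * np.eye(o_idx.size)
                cho = linalg.cho_factor(soo, lower=True, check_finite=False)
            resid = xo - mu_o
            if track_loglik:
                logdet = 2.0 * np.log(np.diag(cho[0])).sum()
                white = linalg.cho_solve(cho, resid.T, check_finite=False)
                loglik += -0.5 * (
                    n_rows * (o_idx.size * log2pi + logdet)
                    + float((resid * white.T).sum())
                )
            if m_idx.size == 0:
                s1[o_idx] += xo.sum(axis=0)
                s2[ix_oo] += xo.T @ xo
                continue
            som = sigma[ix_om]
            beta = linalg.cho_solve(cho, som, check_finite=False)  # o x m coefs
            cond_m = mu[m_idx] + resid @ beta  # rows x m
            cond_cov = sigma[ix_mm] - som.T @ beta
            xfull = np.zeros((n_rows, p))
            xfull[:, o_idx] = xo
            xfull[:, m_idx] = cond_m
            s1 += xfull.sum(axis=0)
            s2 += xfull.T @ xfull
            s2[ix_mm] += n_rows * cond_cov
        if track_loglik:
            trace.append(loglik)

        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new)
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        if ridge > 0:
            sigma_new = (n * sigma_new + ridge * d0) / (n + ridge)

        denom = max(np.abs(mu).max(), np.abs(sigma).max(), 1e-12)
        change = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        ) / denom
        mu, sigma = mu_new, sigma_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM did not converge within the iteration cap", RuntimeWarning)
    return NormalModelFit(mean=mu, cov=sigma, loglik_trace=trace,
                          converged=converged, n_iter=it)


def _pairwise_cov_init(x: np.ndarray, v0: np.ndarray) -> np.ndarray:
    """Pairwise-complete covariance, repaired to positive definiteness.

    Only a starting point for EM: eigenvalues are clipped to a small
    positive floor so the first E-step is well defined.
    """
    cov = np.ma.cov(np.ma.masked_invalid(x), rowvar=False).filled(0.0)
    cov = np.atleast_2d(0.5 * (cov + cov.T))
    bad = np.diag(cov) <= 0
    if bad.any():
        cov[bad, :] = 0.0
        cov[:, bad] = 0.0
        cov[bad, bad] = v0[bad]
    w, v = np.linalg.eigh(cov)
    floor = max(w.max(initial=1.0), 1.0) * 1e-6
    return (v * np.clip(w, floor, None)) @ v.T


def impute_emb(
    matrix: pd.DataFrame, settings: ImputerSettings | None = None
) -> pd.DataFrame:
    settings = settings or ImputerSettings()
    x = matrix.to_numpy(dtype=float).T  # subjects x metabolites
    if not np.isnan(x).any():
        return matrix.copy()
    draws = []
    for rep in range(settings.emb_m):
        draws.append(_emb_once(x, settings, rep))
    out = np.mean(draws, axis=0)
    miss = np.isnan(x)
    out[~miss] = x[~miss]
    return pd.DataFrame(out.T, index=matrix.index, columns=matrix.columns)


def _emb_once(x: np.ndarray, settings: ImputerSettings, rep: int) -> np.ndarray:
    n, p = x.shape
    rng = np.random.default_rng([settings.seed, 0xEB, rep])
    boot = rng.integers(0, n, size=n)
    ridge = settings.emb_prior_frac * n
    out = x.copy()
    for start in range(0, p, settings.emb_block_size):
        block = slice(start, min(start + settings.emb_block_size, p))
        xb = x[:, block]
        miss_b = np.isnan(xb)
        if not miss_b.any():
            continue
        xboot = xb[boot]
        # a bootstrap may drop every observation of some variable; redraw against that
        if np.isnan(xboot).all(axis=0).any():
            for extra in range(1, 50):
                boot2 = np.random.default_rng(
                    [settings.seed, 0xEB, rep, extra]).integers(0, n, size=n)
                xboot = xb[boot2]
                if not np.isnan(xboot).all(axis=0).any():
                    break
            else:  # pragma: no cover - pathological inputs only
                xboot = xb
        fit = _fit_block(xboot, ridge, settings.emb_max_iter)
        out[:, block] = _draw_conditional(xb, fit, rng)
    return out


def _fit_block(xboot: np.ndarray, ridge: float, max_iter: int) -> NormalModelFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_em_normal(xboot, ridge=ridge, max_iter=max_iter, track_loglik=False)


def _draw_conditional(
    xb: np.ndarray, fit: NormalModelFit, rng: np.random.Generator
) -> np.ndarray:
    """Draw missing entries of each row from N(mu_m|o, Sigma_m|o)."""
    out = xb.copy()
    mu, sigma = fit.mean, fit.cov
    for i in range(xb.shape[0]):
        m = np.isnan(xb[i])
        if not m.any():
            continue
        o = ~m
        if o.any():
            soo = sigma[np.ix_(o, o)]
            som = sigma[np.ix_(o, m)]
            beta = _safe_solve(soo, som)
            cond_mu = mu[m] + (xb[i, o] - mu[o]) @ beta
            cond_cov = sigma[np.ix_(m, m)] - som.T @ beta
        else:
            cond_mu = mu[m]
            cond_cov = sigma[np.ix_(m, m)]
        out[i, m] = cond_mu + _safe_cholesky(cond_cov) @ rng.standard_normal(m.sum())
    return out


def _safe_solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            cho = linalg.cho_factor(a + jitter * np.eye(a.shape[0]), lower=True)
            return linalg.cho_solve(cho, b)
        except linalg.LinAlgError:
            continue
    raise linalg.LinAlgError("singular conditional covariance in EMB draw")


def _safe_cholesky(c: np.ndarray) -> np.ndarray:
    c = 0.5 * (c + c.T)
    scale = np.abs(np.diag(c)).max(initial=0.0)
    if scale <= 1e-12:  # degenerate (e.g. constant variables): draw the mean exactly
        return np.zeros_like(c)
    for jitter in (0.0, 1e-12, 1e-9, 1e-6):
        try:
            return np.linalg.cholesky(c + jitter * scale * np.eye(c.shape[0]))
        except np.linalg.LinAlgError:
            continue
    # fall back to an eigenvalue square root with clipped negatives
    w, v = np.linalg.eigh(c)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
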