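"""Vectorized truncated-normal utilities: log-mass, log-pdf, sampling, MLE.

All functions broadcast over arrays of leaves. The MLE works on sufficient
statistics (count, mean, variance) because the truncated normal is an
exponential family in (x, x^2): thousands of per-leaf fits are solved
simultaneously by damped Newton iterations on (mu, log sigma) with a
finite-difference Hessian.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _std(x, mu, sigma):
    return (x - mu) / sigma


def log_mass(mu, sigma, lo, hi):
    """log P(lo < X <= hi) for X ~ N(mu, sigma^2), elementwise, stable."""
    mu, sigma, lo, hi = np.broadcast_arrays(mu, sigma, lo, hi)
    a = np.where(np.isneginf(lo), -np.inf, _std(np.where(np.isneginf(lo), 0, lo), mu, sigma))
    b = np.where(np.isposinf(hi), np.inf, _std(np.where(np.isposinf(hi), 0, hi), mu, sigma))
    # log(Phi(b) - Phi(a)) = log_ndtr(b) + log1p(-exp(log_ndtr(a) - log_ndtr(b)))
    lb = log_ndtr(b)
    la = log_ndtr(a)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.where(la < lb, np.log1p(-np.exp(la - lb)), -np.inf)
        out = lb + diff
    # symmetric form is more accurate in the upper tail
    ub = log_ndtr(-a)
    ua = log_ndtr(-b)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff2 = np.where(ua < ub, np.log1p(-np.exp(ua - ub)), -np.inf)
        out2 = ub + diff2
    return np.where(a > 0, out2, out)


def logpdf(x, mu, sigma, lo, hi, logz=None):
    """Truncated-normal log-density on the half-open interval (lo, hi]."""
    if logz is None:
        logz = log_mass(mu, sigma, lo, hi)
    z = _std(x, mu, sigma)
    core = -np.log(sigma * _SQRT2PI) - 0.5 * z * z - logz
    inside = (x > lo) & (x <= hi)
    return np.where(inside & np.isfinite(core), core, -np.inf)


def sample(mu, sigma, lo, hi, u):
    """Inverse-CDF draws; ``u`` are uniforms broadcastable with ``mu``."""
    mu, sigma, lo, hi, u = np.broadcast_arrays(mu, sigma, lo, hi, u)
    pa = np.where(np.isneginf(lo), 0.0, ndtr(_std(np.where(np.isneginf(lo), 0, lo), mu, sigma)))
    pb = np.where(np.isposinf(hi), 1.0, ndtr(_std(np.where(np.isposinf(hi), 0, hi), mu, sigma)))
    q = pa + u * (pb - pa)
    q = np.clip(q, 1e-15, 1.0 - 1e-15)
    x = mu + sigma * ndtri(q)
    # guard against round-off escaping the half-open interval (lo, hi]
    lower = np.where(np.isneginf(lo), -np.inf, np.nextafter(lo, np.inf))
    upper = np.where(np.isposinf(hi), np.inf, hi)
    return np.clip(x, lower, upper)


def _grad_obj(mu, s, m, v, lo, hi):
    """Objective (per-sample mean log-likelihood) and gradient in (mu, log sigma)."""
    sigma = np.exp(s)
    logz = log_mass(mu, sigma, lo, hi)
    with np.errstate(over="ignore", invalid="ignore"):
        a = _std(np.where(np.isneginf(lo), 0, lo), mu, sigma)
        a = np.where(np.isneginf(lo), -np.inf, a)
        b = _std(np.where(np.isposinf(hi), 0, hi), mu, sigma)
        b = np.where(np.isposinf(hi), np.inf, b)
        log_phi_a = np.where(np.isfinite(a), -0.5 * a * a - np.log(_SQRT2PI), -np.inf)
        log_phi_b = np.where(np.isfinite(b), -0.5 * b * b - np.log(_SQRT2PI), -np.inf)
        ra = np.where(np.isfinite(a), np.exp(log_phi_a - logz), 0.0)
        rb = np.where(np.isfinite(b), np.exp(log_phi_b - logz), 0.0)
        ta = np.where(np.isfinite(a), a * ra, 0.0)
        tb = np.where(np.isfinite(b), b * rb, 0.0)
        d1 = ra - rb  # (phi(a) - phi(b)) / Z
        d2 = ta - tb  # (a phi(a) - b phi(b)) / Z
        obj = -s - (v + (m - mu) ** 2) / (2 * sigma**2) - logz
        g_mu = (m - mu) / sigma**2 - d1 / sigma
        g_s = -1.0 + (v + (m - mu) ** 2) / sigma**2 - d2
    bad = ~np.isfinite(obj)
    obj = np.where(bad, -np.inf, obj)
    g_mu = np.where(np.isfinite(g_mu), g_mu, 0.0)
    g_s = np.where(np.isfinite(g_s), g_s, 0.0)
    return obj, g_mu, g_s


def mle(m, v, lo, hi, sigma_floor, max_iter=50, tol=1e-9):
    """Maximum-likelihood (mu, sigma) of a truncated normal on (lo, hi].

    ``m``/``v`` are the sample mean and (1/n) sample variance of the data in
    each leaf; with infinite bounds the optimum is exactly (m, sqrt(v)).
    The damped-Newton loop runs on a shrinking active set: entries whose
    gradient drops below ``tol`` (or that stop improving) are frozen.
    Non-converged or degenerate entries fall back to the moment estimates.
    """
    m = np.asarray(m, dtype=float)
    v = np.asarray(v, dtype=float)
    lo, hi = np.broadcast_arrays(np.asarray(lo, dtype=float), np.asarray(hi, dtype=float))
    floor = np.broadcast_to(np.asarray(sigma_floor, dtype=float), m.shape)
    sigma0 = np.sqrt(np.maximum(v, floor**2))
    mu_out = m.copy()
    sg_out = sigma0.copy()

    active = (np.isfinite(lo) | np.isfinite(hi)) & (v > floor**2)
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return mu_out, sg_out

    mu = m[idx].copy()
    s = np.log(sigma0[idx])
    ma, va, loa, hia = m[idx], v[idx], lo[idx], hi[idx]
    # parameter box to stop the optimizer from running off to infinity when
    # the likelihood is maximized in a limit (e.g. half-normal shapes)
    scale = np.maximum(sigma0[idx], floor[idx])
    mu_lo, mu_hi = ma - 50 * scale, ma + 50 * scale
    s_lo = np.log(np.maximum(floor[idx], 1e-300))
    s_hi = np.log(50 * scale)

    obj, g_mu, g_s = _grad_obj(mu, s, ma, va, loa, hia)
    for _ in range(max_iter):
        run = np.abs(g_mu) + np.abs(g_s) > tol
        if not run.all():
            # freeze converged entries and compact the working set
            done = ~run
            mu_out[idx[done]] = mu[done]
            sg_out[idx[done]] = np.exp(s[done])
            keep = np.flatnonzero(run)
            if keep.size == 0:
                idx = idx[:0]
                break
            idx = idx[keep]
            mu, s, obj, g_mu, g_s = mu[keep], s[keep], obj[keep], g_mu[keep], g_s[keep]
            ma, va, loa, hia = ma[keep], va[keep], loa[keep], hia[keep]
            mu_lo, mu_hi, s_lo, s_hi = mu_lo[keep], mu_hi[keep], s_lo[keep], s_hi[keep]
        h = 1e-5
        _, gm_p, gs_p = _grad_obj(mu + h, s, ma, va, loa, hia)
        _, gm_ps, gs_ps = _grad_obj(mu, s + h, ma, va, loa, hia)
        h11 = (gm_p - g_mu) / h
        h12 = (gm_ps - g_mu) / h
        h21 = (gs_p - g_s) / h
        h22 = (gs_ps - g_s) / h
        det = h11 * h22 - h12 * h21
        ok = np.isfinite(det) & (np.abs(det) > 1e-30)
        # normalized gradient ascent as the fallback direction
        gnorm = np.hypot(g_mu, g_s)
        f_mu = g_mu / np.maximum(gnorm, 1e-300) * np.minimum(gnorm, 1.0)
        f_s = g_s / np.maximum(gnorm, 1e-300) * np.minimum(gnorm, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_mu = np.where(ok, -(h22 * g_mu - h12 * g_s) / det, f_mu)
            d_s = np.where(ok, -(-h21 * g_mu + h11 * g_s) / det, f_s)
        # ensure an ascent direction
        asc = d_mu * g_mu + d_s * g_s
        d_mu = np.where(asc > 0, d_mu, f_mu)
        d_s = np.where(asc > 0, d_s, f_s)
        step = np.ones_like(mu)
        improved = np.zeros(mu.shape, dtype=bool)
        for _bt in range(25):
            trial = ~improved
            if not trial.any():
                break
            t_mu = np.clip(mu + step * d_mu, mu_lo, mu_hi)
            t_s = np.clip(s + step * d_s, s_lo, s_hi)
            t_obj, t_gmu, t_gs = _grad_obj(t_mu, t_s, ma, va, loa, hia)
            good = trial & (t_obj > obj)
            mu = np.where(good, t_mu, mu)
            s = np.where(good, t_s, s)
            obj = np.where(good, t_obj, obj)
            g_mu = np.where(good, t_gmu, g_mu)
            g_s = np.where(good, t_gs, g_s)
            improved |= good
            step = np.where(trial & ~good, step * 0.5, step)
        if not improved.any():
            break
        if not improved.all():
            # local optimum reached for the non-improving entries: freeze them
            done = ~improved
            mu_out[idx[done]] = mu[done]
            sg_out[idx[done]] = np.exp(s[done])
            keep = np.flatnonzero(improved)
            idx = idx[keep]
            mu, s, obj, g_mu, g_s = mu[keep], s[keep], obj[keep], g_mu[keep], g_s[keep]
            ma, va, loa, hia = ma[keep], va[keep], loa[keep], hia[keep]
            mu_lo, mu_hi, s_lo, s_hi = mu_lo[keep], mu_hi[keep], s_lo[keep], s_hi[keep]

    if idx.size:
        mu_out[idx] = mu
        sg_out[idx] = np.exp(s)
    bad = ~np.isfinite(mu_out) | ~np.isfinite(sg_out)
    mu_out = np.where(bad, m, mu_out)
    sg_out = np.where(bad, sigma0, sg_out)
    sg_out = np.maximum(sg_out, floor)
    return mu_out, sg_out
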