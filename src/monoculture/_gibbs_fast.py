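"""Numba-compiled Gibbs sweep for the BPMM.

Same update order and conditional distributions as the reference numpy
implementation in :mod:`monoculture.bpmm`; only the execution engine
differs.  Random terms are passed as padded index/count matrices so the
whole chain runs in one nopython call; the (single) phylogenetic term
is identified by its position and carries the inverse correlation
matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chain_fast"]


@njit(cache=True)
def _solve_lower(L, b):
    n = b.size
    x = b.copy()
    for i in range(n):
        s = x[i]
        for j in range(i):
            s -= L[i, j] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _solve_lower_t(L, b):
    # solves L.T x = b for lower-triangular L
    n = b.size
    x = b.copy()
    for i in range(n - 1, -1, -1):
        s = x[i]
        for j in range(i + 1, n):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _gibbs_chain(rng, X, y, v, idx_mat, qs, counts_mat, phylo_k, a_inv,
                 fixed_s2, fix_resid, has_fix_resid, prior_b, prior_shape,
                 prior_rate, iterations, burn_in, thin, n_keep):
    n, p = X.shape
    n_terms = qs.shape[0]
    qmax = counts_mat.shape[1] if n_terms > 0 else 0

    XtX = X.T @ X
    beta = np.zeros(p)
    m = np.zeros(n)
    u = np.zeros((n_terms, qmax))

    y_var = max(np.var(y), 1e-6)
    s2 = np.empty(n_terms)
    for k in range(n_terms):
        s2[k] = fixed_s2[k] if not np.isnan(fixed_s2[k]) else y_var
    s2e = fix_resid if has_fix_resid else y_var

    resid = y.copy()  # y - X beta - sum u - m, all zero at start

    keep_beta = np.empty((n_keep, p))
    keep_var = np.empty((n_keep, n_terms + 1))
    kept = 0

    for it in range(iterations):
        # ---- fixed effects (blocked)
        for i in range(n):
            s = 0.0
            for j in range(p):
                s += X[i, j] * beta[j]
            resid[i] += s
        prec = XtX / s2e
        for j in range(p):
            prec[j, j] += 1.0 / prior_b
        rhs = (X.T @ resid) / s2e
        L = np.linalg.cholesky(prec)
        mean = _solve_lower_t(L, _solve_lower(L, rhs))
        z = rng.standard_normal(p)
        beta = mean + _solve_lower_t(L, z)
        for i in range(n):
            s = 0.0
            for j in range(p):
                s += X[i, j] * beta[j]
            resid[i] -= s

        # ---- random terms in fixed order
        for k in range(n_terms):
            q = qs[k]
            b = np.zeros(q)
            for i in range(n):
                ix = idx_mat[k, i]
                resid[i] += u[k, ix]
                b[ix] += resid[i]
            b /= s2e
            if k == phylo_k:
                P = a_inv / s2[k]
                for j in range(q):
                    P[j, j] += counts_mat[k, j] / s2e
                Lk = np.linalg.cholesky(P)
                mean_k = _solve_lower_t(Lk, _solve_lower(Lk, b))
                zk = rng.standard_normal(q)
                uk = mean_k + _solve_lower_t(Lk, zk)
            else:
                uk = np.empty(q)
                for j in range(q):
                    pr = counts_mat[k, j] / s2e + 1.0 / s2[k]
                    uk[j] = b[j] / pr + rng.standard_normal() / np.sqrt(pr)
            for j in range(q):
                u[k, j] = uk[j]
            for i in range(n):
                resid[i] -= u[k, idx_mat[k, i]]

        # ---- measurement deviates (fixed variances v_i)
        for i in range(n):
            resid[i] += m[i]
            pr = 1.0 / v[i] + 1.0 / s2e
            m[i] = resid[i] / (s2e * pr) + rng.standard_normal() / np.sqrt(pr)
            resid[i] -= m[i]

        # ---- variance components
        for k in range(n_terms):
            if not np.isnan(fixed_s2[k]):
                continue
            q = qs[k]
            if k == phylo_k:
                quad = 0.0
                for a in range(q):
                    s = 0.0
                    for bb in range(q):
                        s += a_inv[a, bb] * u[k, bb]
                    quad += u[k, a] * s
            else:
                quad = 0.0
                for j in range(q):
                    quad += u[k, j] * u[k, j]
            s2[k] = (prior_rate + 0.5 * quad) / rng.standard_gamma(
                prior_shape + 0.5 * q)
        if not has_fix_resid:
            ss = 0.0
            for i in range(n):
                ss += resid[i] * resid[i]
            s2e = (prior_rate + 0.5 * ss) / rng.standard_gamma(
                prior_shape + 0.5 * n)

        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            for j in range(p):
                keep_beta[kept, j] = beta[j]
            for k in range(n_terms):
                keep_var[kept, k] = s2[k]
            keep_var[kept, n_terms] = s2e
            kept += 1

    return keep_beta, keep_var


def run_chain_fast(rng, X, y, v, terms, cfg, *, prior_b, prior_shape,
                   prior_rate, fix_resid):
    """Adapter matching the signature of the reference implementation."""
    n_terms = len(terms)
    qmax = max((t.q for t in terms), default=1)
    idx_mat = np.zeros((n_terms, len(y)), dtype=np.int64)
    qs = np.zeros(n_terms, dtype=np.int64)
    counts_mat = np.zeros((n_terms, qmax))
    fixed_s2 = np.full(n_terms, np.nan)
    phylo_k = -1
    a_inv = np.zeros((1, 1))
    for k, t in enumerate(terms):
        idx_mat[k] = t.idx
        qs[k] = t.q
        counts_mat[k, : t.q] = t.counts
        if t.fixed_variance is not None:
            fixed_s2[k] = t.fixed_variance
        if t.a_inv is not None:
            phylo_k = k
            a_inv = np.ascontiguousarray(t.a_inv)
    return _gibbs_chain(
        rng, np.ascontiguousarray(X), np.ascontiguousarray(y),
        np.ascontiguousarray(v), idx_mat, qs, counts_mat, phylo_k, a_inv,
        fixed_s2,
        0.0 if fix_resid is None else float(fix_resid),
        fix_resid is not None,
        prior_b, prior_shape, prior_rate,
        cfg.iterations, cfg.burn_in, cfg.thin, cfg.n_keep,
    )
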