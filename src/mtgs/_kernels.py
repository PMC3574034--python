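"""Numba-compiled inner loops for the per-SNP updates of both engines.

The per-SNP sweep is inherently sequential (each update conditions on the
freshest values of all other SNPs through an incrementally maintained
residual matrix), so it cannot be vectorised; these kernels keep a full
sweep at O(N * n * T + N * T^3) with small-matrix algebra hand-coded to
avoid LAPACK call overhead at T of 1-3.

The Gibbs kernel uses numba's internal np.random state, seeded once per
chain via :func:`seed_kernel_rng`; everything else is deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_kernel_rng", "gibbs_snp_sweep", "vb_snp_sweep", "accumulate_inverses"]


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _chol(A, L):
    """Lower Cholesky of SPD A into L; returns False if not SPD."""
    T = A.shape[0]
    for i in range(T):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, T):
            L[i, j] = 0.0
    return True


@njit(cache=True, inline="always")
def _inv_from_chol(L, out, tmp):
    """out = (L L')^{-1} by triangular solves against identity columns."""
    T = L.shape[0]
    for c in range(T):
        for i in range(T):
            s = 1.0 if i == c else 0.0
            for k in range(i):
                s -= L[i, k] * tmp[k]
            tmp[i] = s / L[i, i]
        for i in range(T - 1, -1, -1):
            s = tmp[i]
            for k in range(i + 1, T):
                s -= L[k, i] * out[k, c]
            out[i, c] = s / L[i, i]
    # symmetrise
    for i in range(T):
        for j in range(i):
            v = 0.5 * (out[i, j] + out[j, i])
            out[i, j] = v
            out[j, i] = v


@njit(cache=True, inline="always")
def _logdet_from_chol(L):
    T = L.shape[0]
    s = 0.0
    for i in range(T):
        s += np.log(L[i, i])
    return 2.0 * s


@njit(cache=True, inline="always")
def _wishart_factor_times_bartlett(L_scale_chol, df, B):
    """B = upper-triangular factor of scale^{-1} times a Bartlett draw.

    For scale matrix Sc with lower Cholesky L (Sc = L L'), F = (L^{-1})' is
    upper triangular with F F' = Sc^{-1}; then W = (F A)(F A)' is Wishart
    with df degrees of freedom and scale Sc^{-1}.  Writes F A into B and
    returns log|det(F A)| so the caller can form log det W cheaply.
    """
    T = L_scale_chol.shape[0]
    # A: lower Bartlett draw (in-place into B first, then multiply)
    # build A in a local array
    A = np.zeros((T, T))
    logdet = 0.0
    for i in range(T):
        d = np.sqrt(np.random.chisquare(df - i))
        A[i, i] = d
        logdet += np.log(d)
        for j in range(i):
            A[i, j] = np.random.standard_normal()
    # F = (L^{-1})': F[i,j] for j >= i; compute row i of L^{-1} by forward
    # substitution: L^{-1} is lower; (L^{-1})[j,i] = solving L x = e_i
    F = np.zeros((T, T))
    for c in range(T):
        # solve L x = e_c -> x[c:] nonzero; F[c, j] = x[j] for j >= c
        for i in range(T):
            s = 1.0 if i == c else 0.0
            for k in range(i):
                s -= L_scale_chol[i, k] * F[c, k]
            F[c, i] = s / L_scale_chol[i, i]
        logdet += -np.log(L_scale_chol[c, c])
    # B = F' ... careful: F[c, :] holds column c of L^{-1}; (L^{-1})' has
    # rows = columns of L^{-1}, so (F as stored) IS (L^{-1})' row-wise.
    for i in range(T):
        for j in range(T):
            s = 0.0
            for k in range(T):
                s += F[i, k] * A[k, j]
            B[i, j] = s
    return logdet


@njit(cache=True)
def gibbs_snp_sweep(
    Ut, u_sq, Rt, coef, g, gamma, sigma_gl_inv, logdet_gl_inv,
    re, s_diag, nu, pi, update_sigma_gl, sum_diag_out,
):
    """One Gibbs cycle over all SNPs; mutates state arrays in place.

    For each SNP l the inclusion indicator is drawn from its conditional
    with the effect vector integrated out analytically given the current
    SNP-effect covariance (collapsed step), then the effect is drawn from
    its multivariate-normal conditional when included, and the SNP-effect
    covariance is redrawn from its inverse-Wishart conditional.  The
    residual matrix Rt (trait-major, T x n, for contiguous inner loops) is
    updated incrementally.  Returns the number of
    included SNPs; accumulates diag(Sigma_gl^{-1}) sums into sum_diag_out
    for the scale-parameter update.
    """
    N, n = Ut.shape
    T = Rt.shape[0]
    A = np.empty((T, T))
    L = np.empty((T, T))
    V = np.empty((T, T))
    tmp = np.empty(T)
    rhs = np.empty(T)
    c = np.empty(T)
    m = np.empty(T)
    B = np.empty((T, T))
    Sc = np.empty((T, T))
    n_included = 0
    for t in range(T):
        sum_diag_out[t] = 0.0

    for l in range(N):
        u = Ut[l]
        for t in range(T):
            acc = u_sq[l] * coef[l, t]
            row = Rt[t]
            for i in range(n):
                acc += u[i] * row[i]
            rhs[t] = acc
        # A = Sigma_gl^{-1} + (sum u^2) Sigma_e^{-1}; V = A^{-1}
        for a in range(T):
            for b_ in range(T):
                A[a, b_] = sigma_gl_inv[l, a, b_] + u_sq[l] * re[a, b_]
        if not _chol(A, L):
            raise ValueError("non-SPD matrix in per-SNP sweep")
        _inv_from_chol(L, V, tmp)
        for t in range(T):
            s = 0.0
            for k in range(T):
                s += re[t, k] * rhs[k]
            c[t] = s
        for t in range(T):
            s = 0.0
            for k in range(T):
                s += V[t, k] * c[k]
            m[t] = s
        # collapsed inclusion draw: odds from the Gaussian integral over g
        if pi <= 0.0:
            gam_new = 1
        elif pi >= 1.0:
            gam_new = 0
        else:
            quad = 0.0
            for t in range(T):
                quad += m[t] * c[t]        # m' A m = c' V c = c' m
            log_odds = (
                np.log(1.0 - pi) - np.log(pi)
                - 0.5 * _logdet_from_chol(L)     # + 0.5 log|V|
                + 0.5 * logdet_gl_inv[l]
                + 0.5 * quad
            )
            if log_odds > 35.0:
                p1 = 1.0
            elif log_odds < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-log_odds))
            gam_new = 1 if np.random.random() < p1 else 0
        # effect draw
        if gam_new == 1:
            # g_new = m + chol(V) z
            if not _chol(V, B):
                raise ValueError("non-SPD matrix in per-SNP sweep")
            for t in range(T):
                tmp[t] = np.random.standard_normal()
            for t in range(T):
                s = m[t]
                for k in range(t + 1):
                    s += B[t, k] * tmp[k]
                g[l, t] = s
            n_included += 1
        else:
            for t in range(T):
                g[l, t] = 0.0
        # residual update with the change in gamma*g
        for t in range(T):
            tmp[t] = gam_new * g[l, t] - coef[l, t]
            coef[l, t] = gam_new * g[l, t]
        for t in range(T):
            d = tmp[t]
            if d != 0.0:
                row = Rt[t]
                for i in range(n):
                    row[i] -= u[i] * d
        gamma[l] = gam_new
        # Sigma_gl ~ IW(nu + gamma, S + gamma g g')  <=>
        # Sigma_gl^{-1} ~ Wishart(nu + gamma, (S + gamma g g')^{-1})
        if update_sigma_gl:
            for a in range(T):
                for b_ in range(T):
                    Sc[a, b_] = gam_new * g[l, a] * g[l, b_]
                Sc[a, a] += s_diag[a]
            if not _chol(Sc, L):
                raise ValueError("non-SPD matrix in per-SNP sweep")
            halflogdet = _wishart_factor_times_bartlett(L, nu + gam_new, B)
            for a in range(T):
                for b_ in range(T):
                    s = 0.0
                    for k in range(T):
                        s += B[a, k] * B[b_, k]
                    sigma_gl_inv[l, a, b_] = s
            logdet_gl_inv[l] = 2.0 * halflogdet
        for t in range(T):
            sum_diag_out[t] += sigma_gl_inv[l, t, t]
    return n_included


@njit(cache=True)
def vb_snp_sweep(
    Ut, u_sq, Rt, coef, g_hat, V_gl, e_gamma, sigma_gl_inv, logdet_gl_inv,
    ES, re, nu, pi, update_sigma_gl, s_diagonal, sum_inv_out,
):
    """One coordinate-ascent cycle over all SNPs; mutates state in place.

    Implements the variational updates for (gamma_l, g_l) and Sigma_gl:
    posterior-mean effect and covariance from the current expectations,
    inclusion probability from the determinant-and-quadratic-form odds
    (computed in log space), then the SNP-covariance expectation
    E(Sigma_gl^{-1}) = (nu + E(gamma_l)) (E(S) + E(gamma_l)(g g' + V))^{-1}.
    Returns sum_l E(gamma_l); accumulates sum_l E(Sigma_gl^{-1}) into
    sum_inv_out for the scale-matrix update.
    """
    N, n = Ut.shape
    T = Rt.shape[0]
    A = np.empty((T, T))
    L = np.empty((T, T))
    V = np.empty((T, T))
    tmp = np.empty(T)
    rhs = np.empty(T)
    c = np.empty(T)
    m = np.empty(T)
    Sc = np.empty((T, T))
    sum_eg = 0.0
    for a in range(T):
        for b_ in range(T):
            sum_inv_out[a, b_] = 0.0

    for l in range(N):
        u = Ut[l]
        for t in range(T):
            acc = u_sq[l] * coef[l, t]
            row = Rt[t]
            for i in range(n):
                acc += u[i] * row[i]
            rhs[t] = acc
        for a in range(T):
            for b_ in range(T):
                A[a, b_] = sigma_gl_inv[l, a, b_] + u_sq[l] * re[a, b_]
        if not _chol(A, L):
            raise ValueError("non-SPD matrix in per-SNP sweep")
        _inv_from_chol(L, V, tmp)
        for t in range(T):
            s = 0.0
            for k in range(T):
                s += re[t, k] * rhs[k]
            c[t] = s
        for t in range(T):
            s = 0.0
            for k in range(T):
                s += V[t, k] * c[k]
            m[t] = s
        if pi <= 0.0:
            eg = 1.0
        elif pi >= 1.0:
            eg = 0.0
        else:
            quad = 0.0
            for t in range(T):
                quad += m[t] * c[t]
            log_odds = (
                np.log(1.0 - pi) - np.log(pi)
                - 0.5 * _logdet_from_chol(L)
                + 0.5 * logdet_gl_inv[l]
                + 0.5 * quad
            )
            if log_odds > 35.0:
                eg = 1.0
            elif log_odds < -35.0:
                eg = 0.0
            else:
                eg = 1.0 / (1.0 + np.exp(-log_odds))
        e_gamma[l] = eg
        for t in range(T):
            g_hat[l, t] = m[t]
            for k in range(T):
                V_gl[l, t, k] = V[t, k]
        for t in range(T):
            tmp[t] = eg * m[t] - coef[l, t]
            coef[l, t] = eg * m[t]
        for t in range(T):
            d = tmp[t]
            if d != 0.0:
                row = Rt[t]
                for i in range(n):
                    row[i] -= u[i] * d
        if update_sigma_gl:
            # S_gl = E(S) + E(gamma)(g g' + V); E(Sigma_gl^{-1}) = (nu+eg) S_gl^{-1}
            for a in range(T):
                for b_ in range(T):
                    Sc[a, b_] = eg * (m[a] * m[b_] + V[a, b_])
                    if s_diagonal:
                        if a == b_:
                            Sc[a, b_] += ES[a, a]
                    else:
                        Sc[a, b_] += ES[a, b_]
            if not _chol(Sc, L):
                raise ValueError("non-SPD matrix in per-SNP sweep")
            _inv_from_chol(L, V, tmp)   # reuse V as S_gl^{-1}
            for a in range(T):
                for b_ in range(T):
                    sigma_gl_inv[l, a, b_] = (nu + eg) * V[a, b_]
            logdet_gl_inv[l] = T * np.log(nu + eg) - _logdet_from_chol(L)
        for a in range(T):
            for b_ in range(T):
                sum_inv_out[a, b_] += sigma_gl_inv[l, a, b_]
        sum_eg += eg
    return sum_eg


@njit(cache=True)
def accumulate_inverses(sigma_gl_inv, acc):
    """acc += inverse of each (T x T) slice; used for posterior-mean Sigma_gl."""
    N = sigma_gl_inv.shape[0]
    T = sigma_gl_inv.shape[1]
    L = np.empty((T, T))
    V = np.empty((T, T))
    tmp = np.empty(T)
    for l in range(N):
        if not _chol(sigma_gl_inv[l], L):
            raise ValueError("non-SPD matrix in per-SNP sweep")
        _inv_from_chol(L, V, tmp)
        for a in range(T):
            for b in range(T):
                acc[l, a, b] += V[a, b]
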