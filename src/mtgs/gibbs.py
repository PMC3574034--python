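"""MCBayes: Gibbs sampling of the multi-trait spike-and-slab regression.

One MCMC cycle updates, in a fixed order: sampled residuals for missing
phenotype cells (conditional multivariate normal), the non-genetic effects
b (multivariate normal), then per SNP the inclusion indicator gamma_l (from
its conditional with the effect vector integrated out analytically — a
collapsed step; naive componentwise sampling could never leave the zero
state) followed by g_l | gamma_l, then each SNP-effect covariance Sigma_gl
(inverse-Wishart), the scale parameters s_k (gamma-form conditional under
their uniform prior), the residual covariance Sigma_e (inverse-Wishart) and
pi (Beta) when inferred.

Point estimates are posterior means over retained samples; the SNP effect
used for prediction is the mean of the *product* gamma_l g_l.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _replace

import numpy as np

from . import _kernels
from ._common import ModelData, build_model_data, conditional_normal
from .datamodel import (
    FixedEffectDesign,
    GenotypeMatrix,
    PhenotypeMatrix,
    PosteriorSummary,
    PriorConfig,
)

__all__ = ["ChainConfig", "GibbsState", "fit_mcbayes", "gibbs_sweep",
           "impute_missing_residuals"]


@dataclass
class ChainConfig:
    """MCMC chain settings: total cycles, burn-in and sampling interval."""

    n_iterations: int = 11000
    burn_in: int = 1000
    thin: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class GibbsState:
    """Current values of every model parameter plus the residual cache."""

    b: np.ndarray               # (f,)
    g: np.ndarray               # (N, T) effect vectors (zero when excluded)
    gamma: np.ndarray           # (N,) inclusion indicators
    coef: np.ndarray            # (N, T) = gamma * g, the model contribution
    sigma_gl_inv: np.ndarray    # (N, T, T) current Sigma_gl^{-1}
    logdet_gl_inv: np.ndarray   # (N,)
    sigma_e: np.ndarray         # (T, T)
    sigma_e_inv: np.ndarray     # (T, T)
    s_diag: np.ndarray          # (T,)
    pi: float
    R: np.ndarray               # (n, T) residual cache y* = y - Xb - U coef
    y_work: np.ndarray          # (n, T) phenotypes with sampled missing cells


def _initial_state(data: ModelData, priors: PriorConfig,
                   rng: np.random.Generator) -> GibbsState:
    n, T, N = data.n, data.n_traits, data.n_snps
    nu = priors.nu_for(T)
    y_work = data.y.copy()
    if data.any_missing:
        means = np.array([
            data.y[data.mask[:, t], t].mean() if data.mask[:, t].any() else 0.0
            for t in range(T)
        ])
        for pat in data.patterns:
            for t in pat.missing:
                y_work[pat.rows, t] = means[t]
    cov = np.cov(y_work, rowvar=False).reshape(T, T) + 1e-12 * np.eye(T)
    # rough prior-scale start: split a small slice of phenotypic variance
    # over the SNPs; the burn-in washes the choice out
    s0 = np.maximum(np.diag(cov) / max(N, 1), 1e-8)
    sigma_gl_inv = np.broadcast_to(nu * np.diag(1.0 / s0), (N, T, T)).copy()
    sign, logdet = np.linalg.slogdet(nu * np.diag(1.0 / s0))
    pi0 = priors.pi_value if priors.pi_fixed else 0.5
    return GibbsState(
        b=np.zeros(data.n_fixed),
        g=np.zeros((N, T)),
        gamma=np.ones(N, dtype=np.int64),
        coef=np.zeros((N, T)),
        sigma_gl_inv=sigma_gl_inv,
        logdet_gl_inv=np.full(N, logdet),
        sigma_e=cov.copy(),
        sigma_e_inv=np.linalg.inv(cov),
        s_diag=s0.copy(),
        pi=pi0,
        R=y_work.copy(),
        y_work=y_work,
    )


def impute_missing_residuals(state: GibbsState, data: ModelData,
                             rng: np.random.Generator) -> None:
    """Sample e_m ~ N(S_mo S_oo^{-1} e_o, S_mm - S_mo S_oo^{-1} S_om).

    The sampled residuals replace the missing phenotype cells in the
    working response (imputed phenotype = X b + sum gamma u g + e_m) and in
    the residual cache.  Individuals with every trait missing draw from the
    marginal N(0, Sigma_e).
    """
    if not data.any_missing:
        return
    fitted = data.xb(state.b) + data.U @ state.coef
    for pat in data.patterns:
        e_obs = state.R[np.ix_(pat.rows, pat.observed)]
        mean, cov = conditional_normal(state.sigma_e, pat.missing, pat.observed, e_obs)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        z = rng.standard_normal((pat.rows.size, pat.missing.size))
        e_m = mean + z @ chol.T
        for j, t in enumerate(pat.missing):
            state.y_work[pat.rows, t] = fitted[pat.rows, t] + e_m[:, j]
            state.R[pat.rows, t] = e_m[:, j]


def _update_fixed_effects(state: GibbsState, data: ModelData,
                          rng: np.random.Generator) -> None:
    """b ~ N(GLS mean, (sum X' Sigma_e^{-1} X)^{-1})."""
    re = state.sigma_e_inv
    M = data.design_gram(re)
    d = state.R + data.xb(state.b)   # y_work - U coef
    v = data.design_rhs(re, d)
    L = np.linalg.cholesky(M)
    mean = np.linalg.solve(M, v)
    z = rng.standard_normal(mean.shape[0])
    b_new = mean + np.linalg.solve(L.T, z)
    state.b = b_new
    state.R = d - data.xb(b_new)


def _update_residual_cov(state: GibbsState, data: ModelData,
                         rng: np.random.Generator) -> None:
    """Sigma_e^{-1} ~ Wishart(n - T - 1, (sum y* y*')^{-1})."""
    n, T = data.n, data.n_traits
    scale = state.R.T @ state.R + 1e-12 * np.eye(T)
    df = n - T - 1
    if df <= T - 1:
        raise ValueError("too few individuals to update the residual covariance")
    prec = _wishart_rvs(df, np.linalg.inv(scale), rng)
    state.sigma_e_inv = prec
    state.sigma_e = np.linalg.inv(prec)


def _wishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bartlett-decomposition Wishart draw (SPD scale, df > dim - 1)."""
    T = scale.shape[0]
    L = np.linalg.cholesky(scale)
    A = np.zeros((T, T))
    for i in range(T):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        A[i, :i] = rng.standard_normal(i)
    B = L @ A
    return B @ B.T


def _update_scale(state: GibbsState, data: ModelData, nu: float,
                  sum_diag: np.ndarray, rng: np.random.Generator) -> None:
    """s_k ~ Gamma(N*nu/2 + 1, rate = sum_l (Sigma_gl^{-1})_kk / 2)."""
    N = data.n_snps
    shape = N * nu / 2.0 + 1.0
    state.s_diag = rng.gamma(shape, 2.0 / sum_diag)


def gibbs_sweep(state: GibbsState, data: ModelData, priors: PriorConfig,
                rng: np.random.Generator,
                update_sigma_gl: bool = True,
                update_sigma_e: bool = True) -> GibbsState:
    """One full Gibbs cycle in the fixed update order (pure numpy path).

    Used for small problems and verification; :func:`fit_mcbayes` runs the
    compiled kernel with identical update structure.  Mutates and returns
    ``state``.
    """
    nu = priors.nu_for(data.n_traits)
    pi = state.pi if priors.pi_mode == "inferred" else priors.pi_value
    impute_missing_residuals(state, data, rng)
    _update_fixed_effects(state, data, rng)
    T = data.n_traits
    sum_diag = np.zeros(T)
    for l in range(data.n_snps):
        _snp_update(state, data, l, nu, pi, rng, update_sigma_gl)
        sum_diag += np.diag(state.sigma_gl_inv[l])
    if update_sigma_gl:
        _update_scale(state, data, nu, sum_diag, rng)
    if update_sigma_e:
        _update_residual_cov(state, data, rng)
    if priors.pi_mode == "inferred":
        n_in = int(state.gamma.sum())
        state.pi = rng.beta(data.n_snps - n_in + 1, n_in + 1)
    return state


def _snp_update(state: GibbsState, data: ModelData, l: int, nu: float,
                pi: float, rng: np.random.Generator,
                update_sigma_gl: bool) -> None:
    """Collapsed (gamma_l, g_l) draw followed by the Sigma_gl draw."""
    re = state.sigma_e_inv
    u = data.U[:, l]
    rhs = u @ state.R + data.u_sq[l] * state.coef[l]
    A = state.sigma_gl_inv[l] + data.u_sq[l] * re
    V = np.linalg.inv(A)
    c = re @ rhs
    m = V @ c
    if pi <= 0.0:
        gam = 1
    elif pi >= 1.0:
        gam = 0
    else:
        sign, logdet_v = np.linalg.slogdet(V)
        log_odds = (
            np.log(1.0 - pi) - np.log(pi)
            + 0.5 * logdet_v + 0.5 * state.logdet_gl_inv[l]
            + 0.5 * float(m @ c)
        )
        p1 = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -35.0, 35.0)))
        gam = int(rng.random() < p1)
    if gam:
        g_new = rng.multivariate_normal(m, V, method="cholesky")
    else:
        g_new = np.zeros_like(m)
    new_coef = gam * g_new
    state.R -= np.outer(u, new_coef - state.coef[l])
    state.coef[l] = new_coef
    state.g[l] = g_new
    state.gamma[l] = gam
    if update_sigma_gl:
        scale = np.diag(state.s_diag) + gam * np.outer(g_new, g_new)
        prec = _wishart_rvs(nu + gam, np.linalg.inv(scale), rng)
        state.sigma_gl_inv[l] = prec
        sign, logdet = np.linalg.slogdet(prec)
        state.logdet_gl_inv[l] = logdet


def fit_mcbayes(
    geno: GenotypeMatrix,
    pheno: PhenotypeMatrix,
    design: FixedEffectDesign | None = None,
    priors: PriorConfig | None = None,
    chain: ChainConfig | None = None,
    rng: np.random.Generator | None = None,
    fix_sigma_e: np.ndarray | None = None,
    fix_sigma_gl: np.ndarray | None = None,
    use_kernel: bool = True,
) -> PosteriorSummary:
    """Posterior means of all parameters by Gibbs sampling.

    ``fix_sigma_e`` / ``fix_sigma_gl`` freeze those covariances at known
    values for validation runs.  With ``priors.single_trait`` the T traits
    are fitted independently (individuals missing a trait's phenotype are
    dropped from that trait's fit) and merged.
    """
    priors = priors or PriorConfig()
    chain = chain or ChainConfig()
    if rng is None:
        rng = np.random.default_rng(chain.seed)
    if priors.single_trait and pheno.n_traits > 1:
        return _fit_single_trait(geno, pheno, priors, chain, rng, use_kernel)

    data = build_model_data(geno, pheno, design)
    T, N = data.n_traits, data.n_snps
    nu = priors.nu_for(T)
    state = _initial_state(data, priors, rng)
    if fix_sigma_e is not None:
        state.sigma_e = np.asarray(fix_sigma_e, dtype=float)
        state.sigma_e_inv = np.linalg.inv(state.sigma_e)
    if fix_sigma_gl is not None:
        inv = np.linalg.inv(np.asarray(fix_sigma_gl, dtype=float))
        state.sigma_gl_inv[:] = inv
        sign, logdet = np.linalg.slogdet(inv)
        state.logdet_gl_inv[:] = logdet
    update_sigma_gl = fix_sigma_gl is None
    update_sigma_e = fix_sigma_e is None
    if use_kernel:
        _kernels.seed_kernel_rng(int(rng.integers(2 ** 31)))

    acc = {
        "coef": np.zeros((N, T)), "gamma": np.zeros(N), "b": np.zeros(data.n_fixed),
        "sigma_e": np.zeros((T, T)), "s": np.zeros(T), "pi": 0.0,
        "sigma_gl": np.zeros((N, T, T)), "count": 0,
    }
    sum_diag = np.empty(T)
    trace = []
    for it in range(1, chain.n_iterations + 1):
        if use_kernel:
            pi = state.pi if priors.pi_mode == "inferred" else priors.pi_value
            impute_missing_residuals(state, data, rng)
            _update_fixed_effects(state, data, rng)
            Rt = np.ascontiguousarray(state.R.T)
            _kernels.gibbs_snp_sweep(
                data.Ut, data.u_sq, Rt, state.coef, state.g, state.gamma,
                state.sigma_gl_inv, state.logdet_gl_inv,
                state.sigma_e_inv, state.s_diag, nu, pi,
                update_sigma_gl, sum_diag,
            )
            state.R = np.ascontiguousarray(Rt.T)
            if update_sigma_gl:
                _update_scale(state, data, nu, sum_diag, rng)
            if update_sigma_e:
                _update_residual_cov(state, data, rng)
            if priors.pi_mode == "inferred":
                n_in = int(state.gamma.sum())
                state.pi = rng.beta(N - n_in + 1, n_in + 1)
        else:
            gibbs_sweep(state, data, priors, rng, update_sigma_gl, update_sigma_e)
        if not np.isfinite(state.R).all():
            raise FloatingPointError(
                f"non-finite residual at iteration {it}; the chain diverged"
            )
        if it > chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            acc["coef"] += state.coef
            acc["gamma"] += state.gamma
            acc["b"] += state.b
            acc["sigma_e"] += state.sigma_e
            acc["s"] += state.s_diag
            acc["pi"] += state.pi
            _kernels.accumulate_inverses(state.sigma_gl_inv, acc["sigma_gl"])
            acc["count"] += 1
            trace.append(float(np.abs(state.coef).sum()))
    k = max(acc["count"], 1)
    pi_hat = 0.0 if priors.pi_mode == "fixed_zero" else acc["pi"] / k
    inclusion = np.ones(N) if priors.pi_mode == "fixed_zero" else acc["gamma"] / k
    return PosteriorSummary(
        b_hat=acc["b"] / k,
        snp_effect_hat=acc["coef"] / k,
        inclusion_prob=inclusion,
        sigma_e_hat=acc["sigma_e"] / k,
        sigma_gl_hat=acc["sigma_gl"] / k,
        s_hat=np.diag(acc["s"] / k),
        pi_hat=float(pi_hat),
        engine="mcbayes",
        snp_ids=list(geno.snp_ids),
        trait_ids=list(pheno.trait_ids),
        diagnostics={
            "n_iterations": chain.n_iterations,
            "burn_in": chain.burn_in,
            "thin": chain.thin,
            "n_retained": acc["count"],
            "abs_effect_trace": trace[-50:],
        },
    )


def _fit_single_trait(geno, pheno, priors, chain, rng, use_kernel) -> PosteriorSummary:
    T = pheno.n_traits
    N = geno.n_snps
    effects = np.zeros((N, T))
    incl = np.zeros((N, T))
    sigma_e = np.zeros((T, T))
    s_hat = np.zeros((T, T))
    sigma_gl = np.zeros((N, T, T))
    b_hat = np.zeros(T)
    pis, diags = [], {}
    st_priors = _replace(priors, single_trait=False)
    for t in range(T):
        keep = pheno.observed_mask[:, t]
        sub_geno = GenotypeMatrix(
            geno.codes[keep], geno.snp_ids,
            [geno.individual_ids[i] for i in np.flatnonzero(keep)],
        )
        sub_pheno = PhenotypeMatrix(
            pheno.values[keep][:, [t]],
            observed_mask=np.ones((int(keep.sum()), 1), dtype=bool),
            trait_ids=[pheno.trait_ids[t]],
        )
        res = fit_mcbayes(
            sub_geno, sub_pheno, priors=st_priors, chain=chain, rng=rng,
            use_kernel=use_kernel,
        )
        effects[:, t] = res.snp_effect_hat[:, 0]
        incl[:, t] = res.inclusion_prob
        sigma_e[t, t] = res.sigma_e_hat[0, 0]
        s_hat[t, t] = res.s_hat[0, 0]
        sigma_gl[:, t, t] = res.sigma_gl_hat[:, 0, 0]
        b_hat[t] = res.b_hat[0]
        pis.append(res.pi_hat)
        diags[pheno.trait_ids[t]] = res.diagnostics
    diags["inclusion_prob_by_trait"] = incl.tolist()
    return PosteriorSummary(
        b_hat=b_hat,
        snp_effect_hat=effects,
        inclusion_prob=incl.mean(axis=1),
        sigma_e_hat=sigma_e,
        sigma_gl_hat=sigma_gl,
        s_hat=s_hat,
        pi_hat=float(np.mean(pis)),
        engine="mcbayes",
        snp_ids=list(geno.snp_ids),
        trait_ids=list(pheno.trait_ids),
        diagnostics=diags,
    )
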