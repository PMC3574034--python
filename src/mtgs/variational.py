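"""varBayes: coordinate-ascent variational approximation of the posterior.

The joint posterior of the spike-and-slab multi-trait regression is
approximated by a fully factorized distribution

    q(theta) = q(b) q(Sigma_e) prod_l q(gamma_l, g_l) q(Sigma_gl) . q(S)

whose factors are a multivariate normal (b), inverse-Wisharts (Sigma_e and
each Sigma_gl), a Wishart (the scale matrix S), per-SNP normal/Bernoulli
pairs (g_l, gamma_l) and a Beta (pi, when inferred).  Coordinate ascent
cycles the expectation updates until the relative squared change of the
monitored expectation vector falls below tolerance.

The engine is fully deterministic given the data and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

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

__all__ = [
    "ConvergenceSpec",
    "VariationalState",
    "fit_varbayes",
    "initialize_state",
    "update_fixed_effects",
    "update_residual_cov",
    "update_snp_inclusion_and_effect",
    "update_snp_cov",
    "update_scale_matrix",
    "update_pi",
    "vb_impute_missing",
    "converged",
]


@dataclass
class ConvergenceSpec:
    """Stopping rule: |theta_curr - theta_prev|^2 / |theta_curr|^2 < tolerance."""

    tolerance: float = 1e-8
    max_iterations: int = 10000

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def converged(prev_vector: np.ndarray, curr_vector: np.ndarray,
              conv: ConvergenceSpec) -> bool:
    """Relative squared-change criterion on the monitored expectation vector."""
    prev = np.asarray(prev_vector, dtype=float)
    curr = np.asarray(curr_vector, dtype=float)
    if prev.shape != curr.shape:
        raise ValueError("monitored vectors differ in length")
    denom = float(curr @ curr)
    diff = curr - prev
    num = float(diff @ diff)
    if denom == 0.0:
        return num == 0.0
    return num / denom < conv.tolerance


@dataclass
class VariationalState:
    """All variational expectations, plus the maintained residual cache.

    ``coef`` holds E(gamma_l g_l) = E(gamma_l) * g_hat_l per SNP; the
    identity E(gamma g g') = E(gamma)(g g' + V_gl) is applied on demand and
    therefore holds exactly at all times.
    """

    Eb: np.ndarray                  # (f,)
    Vb: np.ndarray                  # (f, f)
    Se: np.ndarray                  # (T, T) scale of q(Sigma_e)
    E_sigma_e_inv: np.ndarray       # (T, T)
    g_hat: np.ndarray               # (N, T)
    V_gl: np.ndarray                # (N, T, T)
    e_gamma: np.ndarray             # (N,)
    sigma_gl_inv: np.ndarray        # (N, T, T) E(Sigma_gl^{-1})
    logdet_gl_inv: np.ndarray       # (N,) cached log|E(Sigma_gl^{-1})|
    ES: np.ndarray                  # (T, T)
    E_pi: float
    beta_a: float
    beta_b: float
    coef: np.ndarray                # (N, T) = e_gamma * g_hat
    R: np.ndarray                   # (n, T) residual cache
    y_work: np.ndarray              # (n, T) phenotypes with imputed cells
    n_iterations: int = 0
    metric_trace: list = field(default_factory=list)

    def e_gamma_ggt(self, l: int) -> np.ndarray:
        """E(gamma_l g_l g_l') = E(gamma_l)(g_hat g_hat' + V_gl)."""
        return self.e_gamma[l] * (
            np.outer(self.g_hat[l], self.g_hat[l]) + self.V_gl[l]
        )

    def monitored_vector(self) -> np.ndarray:
        """Eb, all E(gamma g), vec(Se), vec(E(S)) and E(pi).

        Per-SNP covariance matrices are excluded to keep the criterion
        O(N*T).
        """
        return np.concatenate([
            self.Eb.ravel(), self.coef.ravel(),
            self.Se.ravel(), self.ES.ravel(), [self.E_pi],
        ])


def _current_pi(state: VariationalState, priors: PriorConfig) -> float:
    return state.E_pi if priors.pi_mode == "inferred" else priors.pi_value


def initialize_state(data: ModelData, priors: PriorConfig) -> VariationalState:
    """Zero-effect start: first sweep reduces to single-SNP regressions.

    Fixed effects start at the GLS solution for the raw phenotype means,
    E(Sigma_e^{-1}) at the inverse phenotypic covariance, all effects at 0,
    inclusion expectations at the prior mean 1-pi, and E(S) at identity.
    """
    n, T, N = data.n, data.n_traits, data.n_snps
    nu = priors.nu_for(T)
    y_work = data.y.copy()
    if data.any_missing:
        # start missing cells at their trait's observed mean
        means = np.array([
            data.y[data.mask[:, t], t].mean() if data.mask[:, t].any() else 0.0
            for t in range(T)
        ])
        for pat in data.patterns:
            for t in pat.missing:
                y_work[pat.rows, t] = means[t]
    cov = np.cov(y_work, rowvar=False).reshape(T, T)
    cov += 1e-12 * np.eye(T)
    pi0 = priors.pi_value if priors.pi_fixed else 0.5
    ES = np.eye(T)
    sigma_gl_inv = np.broadcast_to(nu * np.eye(T), (N, T, T)).copy()
    sign, logdet = np.linalg.slogdet(nu * np.eye(T))
    state = VariationalState(
        Eb=np.zeros(data.n_fixed),
        Vb=np.eye(data.n_fixed),
        Se=cov * max(n - T - 1, 1),
        E_sigma_e_inv=np.linalg.inv(cov),
        g_hat=np.zeros((N, T)),
        V_gl=np.broadcast_to(np.eye(T), (N, T, T)).copy(),
        e_gamma=np.full(N, 1.0 - pi0),
        sigma_gl_inv=sigma_gl_inv,
        logdet_gl_inv=np.full(N, logdet),
        ES=ES,
        E_pi=pi0,
        beta_a=1.0,
        beta_b=1.0,
        coef=np.zeros((N, T)),
        R=y_work.copy(),
        y_work=y_work,
    )
    return state


# ---------------------------------------------------------------------------
# individual expectation updates (reference numpy forms; the fitting loop
# uses the compiled kernel for the per-SNP part)
# ---------------------------------------------------------------------------

def update_fixed_effects(state: VariationalState, data: ModelData) -> None:
    """q(b): multivariate normal via the generalized-least-squares solve."""
    re = state.E_sigma_e_inv
    M = data.design_gram(re)
    d = state.y_work - data.U @ state.coef
    v = data.design_rhs(re, d)
    Eb = np.linalg.solve(M, v)
    state.Vb = np.linalg.inv(M)
    state.Eb = Eb
    state.R = d - data.xb(Eb)


def update_residual_cov(state: VariationalState, data: ModelData) -> None:
    """q(Sigma_e) = IW(n - T - 1, Se) with Se the residual scatter."""
    n, T = data.n, data.n_traits
    if n <= T + 1:
        raise ValueError("need n > T + 1 individuals for the residual update")
    Se = state.R.T @ state.R
    sign, logdet = np.linalg.slogdet(Se)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("degenerate fit: residual scatter matrix is singular")
    state.Se = Se
    state.E_sigma_e_inv = (n - T - 1) * np.linalg.inv(Se)


def update_snp_inclusion_and_effect(
    state: VariationalState, data: ModelData, l: int, pi: float
) -> None:
    """Posterior-mean effect, covariance and inclusion odds for SNP l."""
    re = state.E_sigma_e_inv
    u = data.U[:, l]
    rhs = u @ state.R + data.u_sq[l] * state.coef[l]
    A = state.sigma_gl_inv[l] + data.u_sq[l] * re
    V = np.linalg.inv(A)
    c = re @ rhs
    m = V @ c
    if pi <= 0.0:
        eg = 1.0
    elif pi >= 1.0:
        eg = 0.0
    else:
        sign, logdet_v = np.linalg.slogdet(V)
        log_odds = (
            np.log(1.0 - pi) - np.log(pi)
            + 0.5 * logdet_v + 0.5 * state.logdet_gl_inv[l]
            + 0.5 * float(m @ c)
        )
        eg = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -35.0, 35.0)))
    new_coef = eg * m
    state.R -= np.outer(u, new_coef - state.coef[l])
    state.coef[l] = new_coef
    state.g_hat[l] = m
    state.V_gl[l] = V
    state.e_gamma[l] = eg


def update_snp_cov(state: VariationalState, l: int, nu: float,
                   s_diagonal: bool = False) -> None:
    """E(Sigma_gl^{-1}) = (nu + E(gamma)) (E(S) + E(gamma)(g g' + V))^{-1}."""
    ES = np.diag(np.diag(state.ES)) if s_diagonal else state.ES
    Sgl = ES + state.e_gamma_ggt(l)
    nu_gl = nu + state.e_gamma[l]
    inv = np.linalg.inv(Sgl)
    state.sigma_gl_inv[l] = nu_gl * inv
    T = Sgl.shape[0]
    sign, logdet_sgl = np.linalg.slogdet(Sgl)
    state.logdet_gl_inv[l] = T * np.log(nu_gl) - logdet_sgl


def update_scale_matrix(state: VariationalState, nu: float) -> None:
    """E(S) = (N*nu + T + 1) (sum_l E(Sigma_gl^{-1}))^{-1}."""
    N = state.sigma_gl_inv.shape[0]
    T = state.ES.shape[0]
    total = state.sigma_gl_inv.sum(axis=0)
    state.ES = (N * nu + T + 1) * np.linalg.inv(total)


def update_pi(state: VariationalState) -> None:
    """Beta posterior of pi under its uniform prior; E(pi) = a/(a+b)."""
    N = state.e_gamma.shape[0]
    sum_eg = float(state.e_gamma.sum())
    state.beta_a = N - sum_eg + 1.0
    state.beta_b = sum_eg + 1.0
    state.E_pi = state.beta_a / (state.beta_a + state.beta_b)


def vb_impute_missing(state: VariationalState, data: ModelData) -> None:
    """Replace missing cells by their conditional expectations.

    e_m = E(Sigma_mo) E(Sigma_oo)^{-1} e_o*; the inverse-Wishart scaling of
    E(Sigma_e) cancels in the product, so the ratio is formed directly from
    the Se blocks.  Individuals with no observed trait get e_m = 0.
    """
    if not data.any_missing:
        return
    fitted = data.xb(state.Eb) + data.U @ state.coef
    for pat in data.patterns:
        e_obs = state.R[np.ix_(pat.rows, pat.observed)]
        mean, _ = conditional_normal(state.Se, pat.missing, pat.observed, e_obs)
        for j, t in enumerate(pat.missing):
            state.y_work[pat.rows, t] = fitted[pat.rows, t] + mean[:, j]
            state.R[pat.rows, t] = mean[:, j]


# ---------------------------------------------------------------------------
# fitting loop
# ---------------------------------------------------------------------------

def _vb_sweep_python(state: VariationalState, data: ModelData,
                     priors: PriorConfig, nu: float,
                     update_sigma_gl: bool, update_sigma_e: bool) -> None:
    """Reference (pure numpy) sweep; the kernel path must match it exactly."""
    pi = _current_pi(state, priors)
    update_fixed_effects(state, data)
    if update_sigma_e:
        update_residual_cov(state, data)
    for l in range(data.n_snps):
        update_snp_inclusion_and_effect(state, data, l, pi)
        if update_sigma_gl:
            update_snp_cov(state, l, nu, priors.s_diagonal)
    if update_sigma_gl:
        update_scale_matrix(state, nu)
    if priors.pi_mode == "inferred":
        update_pi(state)
    vb_impute_missing(state, data)


def _vb_sweep_kernel(state: VariationalState, data: ModelData,
                     priors: PriorConfig, nu: float,
                     update_sigma_gl: bool, update_sigma_e: bool) -> None:
    pi = _current_pi(state, priors)
    update_fixed_effects(state, data)
    if update_sigma_e:
        update_residual_cov(state, data)
    sum_inv = np.empty((data.n_traits, data.n_traits))
    Rt = np.ascontiguousarray(state.R.T)
    _kernels.vb_snp_sweep(
        data.Ut, data.u_sq, Rt, state.coef, state.g_hat, state.V_gl,
        state.e_gamma, state.sigma_gl_inv, state.logdet_gl_inv,
        state.ES, state.E_sigma_e_inv, nu, pi,
        update_sigma_gl, priors.s_diagonal, sum_inv,
    )
    state.R = np.ascontiguousarray(Rt.T)
    if update_sigma_gl:
        T = data.n_traits
        state.ES = (data.n_snps * nu + T + 1) * np.linalg.inv(sum_inv)
    if priors.pi_mode == "inferred":
        update_pi(state)
    vb_impute_missing(state, data)


def fit_varbayes(
    geno: GenotypeMatrix,
    pheno: PhenotypeMatrix,
    design: FixedEffectDesign | None = None,
    priors: PriorConfig | None = None,
    conv: ConvergenceSpec | None = None,
    fix_sigma_e: np.ndarray | None = None,
    fix_sigma_gl: np.ndarray | None = None,
    use_kernel: bool = True,
) -> PosteriorSummary:
    """Fit the multi-trait (or single-trait) model by coordinate ascent.

    ``fix_sigma_e`` / ``fix_sigma_gl`` freeze the residual and SNP-effect
    covariances at known values (the corresponding updates are skipped);
    this supports validation against closed-form posteriors.  Failure to
    converge within ``max_iterations`` is reported in the diagnostics, with
    results still returned.
    """
    priors = priors or PriorConfig()
    conv = conv or ConvergenceSpec()
    if priors.single_trait and pheno.n_traits > 1:
        return _fit_single_trait(geno, pheno, priors, conv, use_kernel)
    data = build_model_data(geno, pheno, design)
    nu = priors.nu_for(data.n_traits)
    state = initialize_state(data, priors)
    if fix_sigma_e is not None:
        fix_sigma_e = np.asarray(fix_sigma_e, dtype=float)
        state.E_sigma_e_inv = np.linalg.inv(fix_sigma_e)
        state.Se = fix_sigma_e * max(data.n - data.n_traits - 1, 1)
    if fix_sigma_gl is not None:
        fix_sigma_gl = np.asarray(fix_sigma_gl, dtype=float)
        inv = np.linalg.inv(fix_sigma_gl)
        sign, logdet = np.linalg.slogdet(inv)
        state.sigma_gl_inv[:] = inv
        state.logdet_gl_inv[:] = logdet

    sweep = _vb_sweep_kernel if use_kernel else _vb_sweep_python
    update_sigma_gl = fix_sigma_gl is None
    update_sigma_e = fix_sigma_e is None
    prev = state.monitored_vector()
    status = "max_iterations"
    for it in range(1, conv.max_iterations + 1):
        sweep(state, data, priors, nu, update_sigma_gl, update_sigma_e)
        curr = state.monitored_vector()
        denom = float(curr @ curr)
        metric = float(((curr - prev) ** 2).sum()) / denom if denom else 0.0
        state.metric_trace.append(metric)
        state.n_iterations = it
        if converged(prev, curr, conv):
            status = "converged"
            break
        prev = curr
    return _summarize(state, data, priors, nu, status, geno, pheno)


def _summarize(state, data, priors, nu, status, geno, pheno) -> PosteriorSummary:
    T = data.n_traits
    # E(Sigma_gl^{-1}) = nu_gl S_gl^{-1}, so S_gl/nu_gl = inv(E(Sigma_gl^{-1}))
    sigma_gl_hat = np.linalg.inv(state.sigma_gl_inv)
    pi_hat = 0.0 if priors.pi_mode == "fixed_zero" else (
        state.E_pi if priors.pi_mode == "inferred" else priors.pi_value
    )
    return PosteriorSummary(
        b_hat=state.Eb.copy(),
        snp_effect_hat=state.coef.copy(),
        inclusion_prob=state.e_gamma.copy(),
        sigma_e_hat=state.Se / max(data.n - T - 1, 1),
        sigma_gl_hat=sigma_gl_hat,
        s_hat=state.ES.copy(),
        pi_hat=float(pi_hat),
        engine="varbayes",
        snp_ids=list(geno.snp_ids),
        trait_ids=list(pheno.trait_ids),
        diagnostics={
            "status": status,
            "n_iterations": state.n_iterations,
            "metric_trace": state.metric_trace[-50:],
            "final_metric": state.metric_trace[-1] if state.metric_trace else None,
        },
    )


def _fit_single_trait(geno, pheno, priors, conv, use_kernel) -> PosteriorSummary:
    """T independent single-trait fits merged into one summary.

    Individuals missing a trait's phenotype are dropped from that trait's
    fit (a single-trait model has no other traits to condition on).
    """
    from dataclasses import replace as _replace

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
        res = fit_varbayes(
            sub_geno, sub_pheno, priors=st_priors, conv=conv,
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
        engine="varbayes",
        snp_ids=list(geno.snp_ids),
        trait_ids=list(pheno.trait_ids),
        diagnostics=diags,
    )
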