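"""Shared in-memory layout and linear-algebra plumbing for both engines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    FixedEffectDesign,
    GenotypeMatrix,
    PhenotypeMatrix,
    validate_dataset,
)


@dataclass
class MissingPattern:
    rows: np.ndarray      # individuals sharing this pattern
    missing: np.ndarray   # trait indices missing
    observed: np.ndarray  # trait indices observed


@dataclass
class ModelData:
    """Dense arrays consumed by the samplers/updaters."""

    U: np.ndarray          # (n, N) genotype codes, float64
    Ut: np.ndarray         # (N, n) C-contiguous transpose for per-SNP access
    u_sq: np.ndarray       # (N,) sum_i u_il^2
    X: np.ndarray          # (n, T, f) fixed-effect design blocks
    y: np.ndarray          # (n, T) phenotypes, missing cells zero-filled
    mask: np.ndarray       # (n, T) observed mask
    patterns: list[MissingPattern]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]

    @property
    def n_snps(self) -> int:
        return self.U.shape[1]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[2]

    @property
    def any_missing(self) -> bool:
        return len(self.patterns) > 0

    def design_gram(self, re: np.ndarray) -> np.ndarray:
        """sum_i X_i' Re X_i  (f x f)."""
        return np.einsum("itf,ts,isg->fg", self.X, re, self.X, optimize=True)

    def design_rhs(self, re: np.ndarray, d: np.ndarray) -> np.ndarray:
        """sum_i X_i' Re d_i  (f,)."""
        return np.einsum("itf,ts,is->f", self.X, re, d, optimize=True)

    def xb(self, b: np.ndarray) -> np.ndarray:
        """(n, T) fixed-effect contribution X_i b."""
        return np.einsum("itf,f->it", self.X, b)


def build_model_data(
    geno: GenotypeMatrix,
    pheno: PhenotypeMatrix,
    design: FixedEffectDesign | None = None,
) -> ModelData:
    if design is None:
        design = FixedEffectDesign.intercepts(geno.n_individuals, pheno.n_traits)
    validate_dataset(geno, pheno, design)
    U = np.ascontiguousarray(geno.codes, dtype=np.float64)
    Ut = np.ascontiguousarray(U.T)
    mask = pheno.observed_mask
    y = np.where(mask, pheno.values, 0.0)

    patterns: list[MissingPattern] = []
    if not mask.all():
        T = pheno.n_traits
        key = mask @ (1 << np.arange(T))
        for k in np.unique(key):
            rows = np.flatnonzero(key == k)
            miss = np.flatnonzero(~mask[rows[0]])
            if miss.size == 0:
                continue
            obs = np.flatnonzero(mask[rows[0]])
            patterns.append(MissingPattern(rows, miss, obs))
    return ModelData(
        U=U, Ut=Ut, u_sq=(U ** 2).sum(axis=0),
        X=np.asarray(design.design_blocks, dtype=np.float64),
        y=y, mask=mask, patterns=patterns,
    )


def conditional_normal(
    sigma: np.ndarray, missing: np.ndarray, observed: np.ndarray, e_obs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioned-normal conditional of the missing block given the observed.

    Returns the conditional mean (len(rows) x m) for each row of ``e_obs``
    and the common conditional covariance (m x m).  With no observed traits
    the conditional reduces to the marginal N(0, sigma_mm).
    """
    s_mm = sigma[np.ix_(missing, missing)]
    if observed.size == 0:
        return np.zeros((e_obs.shape[0], missing.size)), s_mm
    s_mo = sigma[np.ix_(missing, observed)]
    s_oo = sigma[np.ix_(observed, observed)]
    coef = np.linalg.solve(s_oo, s_mo.T).T        # Sigma_mo Sigma_oo^{-1}
    mean = e_obs @ coef.T
    cov = s_mm - coef @ s_mo.T
    return mean, cov
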