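"""GBV prediction, accuracy/bias metrics, cross-validation and experiments.

Accuracy is the Pearson correlation between the reference (TBV, or
phenotype in cross-validation) and the predicted GBV; bias is the slope of
the regression of the reference ON the predicted GBV (slope 1 = unbiased).
The replicate-experiment driver simulates datasets, fits any combination of
engine and pi setting, and tabulates mean +/- SD accuracy, bias and the
cross-correlations among predicted GBVs and among simulated TBVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    FixedEffectDesign,
    GenotypeMatrix,
    PhenotypeMatrix,
    PosteriorSummary,
    PriorConfig,
)
from .gibbs import ChainConfig, fit_mcbayes
from .simulator import SimulationConfig, SimulatedDataset, generate_dataset
from .variational import ConvergenceSpec, fit_varbayes

__all__ = [
    "EvaluationResult",
    "METHODS",
    "predict_gbv",
    "accuracy_bias",
    "kfold_cv",
    "replicate_experiment",
    "fit",
]

#: method label -> (engine, pi_mode, single_trait)
METHODS = {
    "mc0": ("mcbayes", "fixed_zero", False),
    "mcvar": ("mcbayes", "inferred", False),
    "vb0": ("varbayes", "fixed_zero", False),
    "vbvar": ("varbayes", "inferred", False),
    "st0": ("mcbayes", "fixed_zero", True),
    "stvar": ("mcbayes", "inferred", True),
}


@dataclass
class EvaluationResult:
    """Per-trait accuracy/bias plus GBV cross-correlations."""

    r_tbv_pgbv: np.ndarray            # (T,)
    b_tbv_pgbv: np.ndarray            # (T,)
    r_y_pgbv: np.ndarray | None = None
    b_y_pgbv: np.ndarray | None = None
    gbv_cross_corr: np.ndarray | None = None   # (T, T)
    replicate_sd: dict = field(default_factory=dict)


def fit(
    engine: str,
    geno: GenotypeMatrix,
    pheno: PhenotypeMatrix,
    design: FixedEffectDesign | None = None,
    priors: PriorConfig | None = None,
    chain: ChainConfig | None = None,
    conv: ConvergenceSpec | None = None,
    rng: np.random.Generator | None = None,
) -> PosteriorSummary:
    """Dispatch to the requested inference engine."""
    if engine == "mcbayes":
        return fit_mcbayes(geno, pheno, design, priors, chain, rng)
    if engine == "varbayes":
        return fit_varbayes(geno, pheno, design, priors, conv)
    raise ValueError(f"unknown engine {engine!r}")


def predict_gbv(summary: PosteriorSummary, geno: GenotypeMatrix) -> np.ndarray:
    """GBV_i = sum_l u_il * E(gamma_l g_l); fixed effects are excluded.

    The correlation and slope metrics are location-invariant, so leaving
    the intercepts out keeps GBV a purely genetic quantity without
    affecting them.
    """
    if summary.n_snps != geno.n_snps:
        raise ValueError(
            f"summary holds {summary.n_snps} SNPs but genotypes have "
            f"{geno.n_snps}"
        )
    if summary.snp_ids and summary.snp_ids != geno.snp_ids:
        raise ValueError("SNP identifier sets differ between summary and genotypes")
    return geno.codes.astype(float) @ summary.snp_effect_hat


def accuracy_bias(reference: np.ndarray, predicted: np.ndarray):
    """(r, slope) of the reference against the predicted GBV.

    r is the Pearson correlation; slope = cov(reference, predicted) /
    var(predicted), i.e. the reference regressed ON the predicted values.
    A constant prediction leaves both undefined (returned as NaN).
    """
    reference = np.asarray(reference, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if reference.shape != predicted.shape or reference.ndim != 1:
        raise ValueError("reference and predicted must be equal-length vectors")
    if reference.size < 3:
        raise ValueError("need at least 3 pairs")
    var_p = predicted.var(ddof=1)
    if var_p == 0:
        return float("nan"), float("nan")
    cov = np.cov(reference, predicted, ddof=1)[0, 1]
    var_r = reference.var(ddof=1)
    r = cov / np.sqrt(var_r * var_p) if var_r > 0 else float("nan")
    return float(r), float(cov / var_p)


def _evaluate_testset(
    summary: PosteriorSummary,
    geno: GenotypeMatrix,
    tbv: np.ndarray,
    pheno: np.ndarray | None = None,
    pheno_mask: np.ndarray | None = None,
) -> EvaluationResult:
    gbv = predict_gbv(summary, geno)
    T = tbv.shape[1]
    r = np.empty(T)
    b = np.empty(T)
    for t in range(T):
        r[t], b[t] = accuracy_bias(tbv[:, t], gbv[:, t])
    r_y = b_y = None
    if pheno is not None:
        r_y = np.empty(T)
        b_y = np.empty(T)
        for t in range(T):
            keep = pheno_mask[:, t] if pheno_mask is not None else slice(None)
            r_y[t], b_y[t] = accuracy_bias(pheno[keep, t], gbv[keep, t])
    return EvaluationResult(
        r_tbv_pgbv=r, b_tbv_pgbv=b, r_y_pgbv=r_y, b_y_pgbv=b_y,
        gbv_cross_corr=np.corrcoef(gbv.T) if T > 1 else np.ones((1, 1)),
    )


def kfold_cv(
    dataset: SimulatedDataset,
    k: int = 10,
    engine: str = "varbayes",
    priors: PriorConfig | None = None,
    chain: ChainConfig | None = None,
    conv: ConvergenceSpec | None = None,
    rng: np.random.Generator | None = None,
) -> EvaluationResult:
    """k-fold cross-validation within the training generation.

    The population is split by a seeded permutation into k near-equal
    subpopulations; each serves as the test set exactly once while the
    remaining k-1 train the model.  Metrics are averaged over the k folds
    and computed against both TBV and the held-out phenotypes.
    """
    geno, pheno = dataset.train_geno, dataset.train_pheno
    n, T = pheno.n_individuals, pheno.n_traits
    if not 2 <= k <= n:
        raise ValueError(f"fold count {k} must lie in [2, {n}]")
    rng = rng or np.random.default_rng()
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    rs, bs, rys, bys = [], [], [], []
    for fold in folds:
        train_idx = np.setdiff1d(perm, fold, assume_unique=True)
        sub_geno = GenotypeMatrix(
            geno.codes[train_idx], geno.snp_ids,
            [geno.individual_ids[i] for i in train_idx],
        )
        sub_pheno = PhenotypeMatrix(
            pheno.values[train_idx], pheno.observed_mask[train_idx],
            pheno.trait_ids,
        )
        summary = fit(engine, sub_geno, sub_pheno, priors=priors, chain=chain,
                      conv=conv, rng=rng)
        test_geno = GenotypeMatrix(
            geno.codes[fold], geno.snp_ids,
            [geno.individual_ids[i] for i in fold],
        )
        res = _evaluate_testset(
            summary, test_geno, dataset.train_tbv[fold],
            pheno.values[fold], pheno.observed_mask[fold],
        )
        rs.append(res.r_tbv_pgbv)
        bs.append(res.b_tbv_pgbv)
        rys.append(res.r_y_pgbv)
        bys.append(res.b_y_pgbv)
    return EvaluationResult(
        r_tbv_pgbv=np.mean(rs, axis=0),
        b_tbv_pgbv=np.mean(bs, axis=0),
        r_y_pgbv=np.mean(rys, axis=0),
        b_y_pgbv=np.mean(bys, axis=0),
        replicate_sd={"r_tbv_pgbv": np.std(rs, axis=0, ddof=1)},
    )


def _method_priors(method: str) -> PriorConfig:
    engine, pi_mode, single = METHODS[method]
    return PriorConfig(pi_mode=pi_mode, single_trait=single)


def replicate_experiment(
    scenario: str = "data1",
    methods: tuple[str, ...] = ("mc0", "vb0", "st0"),
    n_replicates: int | None = None,
    seed: int = 0,
    config: SimulationConfig | None = None,
    chain: ChainConfig | None = None,
    conv: ConvergenceSpec | None = None,
) -> pd.DataFrame:
    """Simulate replicates, fit each method, evaluate on the test generation.

    Returns a tidy table with one row per (method, metric, trait-or-pair)
    holding the mean and SD across replicates, including the
    cross-correlations among predicted GBVs and among simulated TBVs.
    Engine failures on a replicate are recorded and the replicate excluded
    for that method.
    """
    if n_replicates is None:
        n_replicates = 3 if scenario == "data2" else 10
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    master = np.random.default_rng(seed)
    rows = []
    failures = []
    for rep in range(n_replicates):
        rep_seed = int(master.integers(2 ** 31))
        ds = generate_dataset(scenario, config, np.random.default_rng(rep_seed))
        T = ds.train_pheno.n_traits
        tbv_corr = np.corrcoef(ds.test_tbv.T)
        for a in range(T):
            for b in range(a + 1, T):
                rows.append(("simulated_tbv", "gbv_corr", f"{a}-{b}",
                             rep, tbv_corr[a, b]))
        for method in methods:
            engine = METHODS[method][0]
            try:
                summary = fit(
                    engine, ds.train_geno, ds.train_pheno,
                    priors=_method_priors(method), chain=chain, conv=conv,
                    rng=np.random.default_rng(rep_seed + 1),
                )
                res = _evaluate_testset(summary, ds.test_geno, ds.test_tbv)
            except (ValueError, FloatingPointError) as exc:
                failures.append((method, rep, str(exc)))
                continue
            for t in range(T):
                rows.append((method, "r_tbv_pgbv", str(t), rep, res.r_tbv_pgbv[t]))
                rows.append((method, "b_tbv_pgbv", str(t), rep, res.b_tbv_pgbv[t]))
            for a in range(T):
                for b in range(a + 1, T):
                    rows.append((method, "gbv_corr", f"{a}-{b}", rep,
                                 res.gbv_cross_corr[a, b]))
    long = pd.DataFrame(
        rows, columns=["method", "metric", "trait", "replicate", "value"]
    )
    table = (
        long.groupby(["method", "metric", "trait"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    table.attrs["failures"] = failures
    table.attrs["scenario"] = scenario
    table.attrs["n_replicates"] = n_replicates
    return table
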