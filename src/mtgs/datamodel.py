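"""Domain containers and delimited-text I/O for multi-trait genomic prediction.

Genotypes are biallelic SNP codes in {-1, 0, 1} (the string calls ``0_0``,
``0_1`` and ``1_1`` map to -1, 0 and 1).  Phenotypes are an n x T real matrix
with an observed/missing mask; missing cells are written as ``NA`` in files
but the boolean mask is authoritative in memory.  Fixed effects enter through
per-individual T x f design matrices; the default design is one intercept per
trait.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENOTYPE_CODES",
    "GenotypeMatrix",
    "PhenotypeMatrix",
    "FixedEffectDesign",
    "PriorConfig",
    "PosteriorSummary",
    "ValidationReport",
    "encode_genotypes",
    "decode_genotypes",
    "validate_dataset",
]

#: genotype-call string -> additive code
GENOTYPE_CODES = {"0_0": -1, "0_1": 0, "1_1": 1}
_CODE_TO_CALL = {v: k for k, v in GENOTYPE_CODES.items()}
_VALID_CODES = frozenset((-1, 0, 1))

NA_TOKEN = "NA"


def _default_ids(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


@dataclass
class GenotypeMatrix:
    """n x N matrix of SNP genotype codes u_il in {-1, 0, 1}.

    No missing genotypes are modelled; every cell must carry a valid code.
    """

    codes: np.ndarray
    snp_ids: list[str] = field(default=None)  # type: ignore[assignment]
    individual_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2 or codes.size == 0:
            raise ValueError("genotype codes must form a non-empty 2-D matrix")
        if not np.isin(codes, (-1, 0, 1)).all():
            bad = np.argwhere(~np.isin(codes, (-1, 0, 1)))[0]
            raise ValueError(
                f"invalid genotype code {codes[tuple(bad)]!r} at "
                f"individual row {bad[0]}, SNP column {bad[1]}"
            )
        self.codes = codes.astype(np.int8)
        if self.snp_ids is None:
            self.snp_ids = _default_ids("snp", self.codes.shape[1])
        if self.individual_ids is None:
            self.individual_ids = _default_ids("ind", self.codes.shape[0])
        self.snp_ids = list(self.snp_ids)
        self.individual_ids = list(self.individual_ids)
        if len(self.snp_ids) != self.codes.shape[1]:
            raise ValueError("snp_ids length does not match number of SNP columns")
        if len(self.individual_ids) != self.codes.shape[0]:
            raise ValueError("individual_ids length does not match number of rows")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def monomorphic(self) -> np.ndarray:
        """Boolean mask of SNP columns with a single genotype code throughout."""
        return (self.codes == self.codes[0]).all(axis=0)

    def save(self, path: str | Path, as_calls: bool = False) -> None:
        """Write a delimited genotype file (one row per individual)."""
        if as_calls:
            data = decode_genotypes(self.codes)
        else:
            data = self.codes
        df = pd.DataFrame(data, index=self.individual_ids, columns=self.snp_ids)
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def load(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return encode_genotypes(
            df.to_numpy(),
            snp_ids=list(df.columns),
            individual_ids=[str(i) for i in df.index],
        )


@dataclass
class PhenotypeMatrix:
    """n x T trait values with an observed/missing mask.

    ``values`` at masked-out cells are ignored by every likelihood
    computation; the mask, not any sentinel value, is authoritative.
    """

    values: np.ndarray
    observed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    trait_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("phenotype values must form a non-empty 2-D matrix")
        if self.observed_mask is None:
            self.observed_mask = np.isfinite(values)
        mask = np.asarray(self.observed_mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("observed_mask shape does not match values")
        self.values = values
        self.observed_mask = mask
        if self.trait_ids is None:
            self.trait_ids = _default_ids("trait", values.shape[1])
        self.trait_ids = list(self.trait_ids)
        if len(self.trait_ids) != values.shape[1]:
            raise ValueError("trait_ids length does not match number of traits")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def observed_counts(self) -> np.ndarray:
        return self.observed_mask.sum(axis=0)

    def save(self, path: str | Path, individual_ids: Sequence[str] | None = None) -> None:
        ids = list(individual_ids) if individual_ids is not None else _default_ids(
            "ind", self.n_individuals
        )
        out = self.values.astype(object).copy()
        out[~self.observed_mask] = NA_TOKEN
        df = pd.DataFrame(out, index=ids, columns=self.trait_ids)
        df.to_csv(path, sep="\t", index_label="id", na_rep=NA_TOKEN)

    @classmethod
    def load(cls, path: str | Path) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
        values = df.to_numpy(dtype=float)
        return cls(
            values=np.nan_to_num(values, nan=0.0),
            observed_mask=np.isfinite(values),
            trait_ids=list(df.columns),
        )


@dataclass
class FixedEffectDesign:
    """Per-individual T x f design matrices linking non-genetic effects b."""

    design_blocks: np.ndarray  # (n, T, f)

    def __post_init__(self) -> None:
        blocks = np.asarray(self.design_blocks, dtype=float)
        if blocks.ndim != 3:
            raise ValueError("design_blocks must be an (n, T, f) array")
        self.design_blocks = blocks

    @property
    def n_individuals(self) -> int:
        return self.design_blocks.shape[0]

    @property
    def n_traits(self) -> int:
        return self.design_blocks.shape[1]

    @property
    def n_effects(self) -> int:
        return self.design_blocks.shape[2]

    def stacked(self) -> np.ndarray:
        """(n*T, f) row-stacked design."""
        n, T, f = self.design_blocks.shape
        return self.design_blocks.reshape(n * T, f)

    def full_rank(self) -> bool:
        return np.linalg.matrix_rank(self.stacked()) == self.n_effects

    @classmethod
    def intercepts(cls, n_individuals: int, n_traits: int) -> "FixedEffectDesign":
        """Trait-specific intercepts: X_i = I_T for every individual (f = T)."""
        blocks = np.broadcast_to(
            np.eye(n_traits), (n_individuals, n_traits, n_traits)
        ).copy()
        return cls(blocks)


@dataclass
class PriorConfig:
    """Prior settings for the spike-and-slab model.

    pi_mode
        ``fixed_zero`` forces every SNP into the model (gamma_l == 1, pure
        shrinkage regression); ``fixed_value`` uses ``pi_value`` as a known
        exclusion probability; ``inferred`` places a uniform prior on pi and
        learns it.
    nu
        Degrees of freedom of the inverse-Wishart prior on the SNP-effect
        covariance.  Defaults to 5.0 for ``fixed_zero`` and 3.2 for
        ``inferred`` / ``fixed_value`` (must exceed T - 1).
    single_trait
        Fit T independent single-trait models instead of one joint model.
    s_diagonal
        Force the expected scale matrix S to its diagonal in the variational
        engine (the prior restricts S to diagonal form; by default the full
        expectation is used as computed).
    """

    pi_mode: str = "fixed_zero"
    pi_value: float = 0.0
    nu: float | None = None
    single_trait: bool = False
    s_diagonal: bool = False

    def __post_init__(self) -> None:
        if self.pi_mode not in ("fixed_zero", "fixed_value", "inferred"):
            raise ValueError(f"unknown pi_mode {self.pi_mode!r}")
        if not 0.0 <= self.pi_value <= 1.0:
            raise ValueError("pi_value must lie in [0, 1]")
        if self.pi_mode == "fixed_zero":
            self.pi_value = 0.0
        if self.nu is None:
            self.nu = 5.0 if self.pi_mode == "fixed_zero" else 3.2

    def nu_for(self, n_traits: int) -> float:
        nu = float(self.nu)
        if nu <= n_traits - 1:
            raise ValueError(
                f"nu={nu} must exceed T-1={n_traits - 1} for a proper prior"
            )
        return nu

    @property
    def pi_fixed(self) -> bool:
        return self.pi_mode in ("fixed_zero", "fixed_value")


@dataclass
class PosteriorSummary:
    """Point estimates sufficient for GBV prediction.

    ``snp_effect_hat`` holds E(gamma_l g_l) per SNP and trait (the posterior
    mean of the *product* in the MCMC engine, E(gamma_l) * g_hat_l in the
    variational engine); GBV prediction is its linear combination with the
    genotype codes.
    """

    b_hat: np.ndarray                 # (f,)
    snp_effect_hat: np.ndarray        # (N, T)
    inclusion_prob: np.ndarray        # (N,)
    sigma_e_hat: np.ndarray           # (T, T)
    sigma_gl_hat: np.ndarray          # (N, T, T)
    s_hat: np.ndarray                 # (T, T)
    pi_hat: float
    engine: str                       # "mcbayes" | "varbayes"
    snp_ids: list[str] = field(default_factory=list)
    trait_ids: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_effect_hat = np.asarray(self.snp_effect_hat, dtype=float)
        self.inclusion_prob = np.asarray(self.inclusion_prob, dtype=float)
        if ((self.inclusion_prob < -1e-9) | (self.inclusion_prob > 1 + 1e-9)).any():
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        if not (0.0 <= self.pi_hat <= 1.0):
            raise ValueError("pi_hat must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.snp_effect_hat.shape[0]

    @property
    def n_traits(self) -> int:
        return self.snp_effect_hat.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to a structured-text (JSON) container."""
        payload = {
            "engine": self.engine,
            "pi_hat": float(self.pi_hat),
            "b_hat": np.asarray(self.b_hat).tolist(),
            "snp_effect_hat": self.snp_effect_hat.tolist(),
            "inclusion_prob": self.inclusion_prob.tolist(),
            "sigma_e_hat": np.asarray(self.sigma_e_hat).tolist(),
            "sigma_gl_hat": np.asarray(self.sigma_gl_hat).tolist(),
            "s_hat": np.asarray(self.s_hat).tolist(),
            "snp_ids": list(self.snp_ids),
            "trait_ids": list(self.trait_ids),
            "diagnostics": _jsonable(self.diagnostics),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSummary":
        payload = json.loads(Path(path).read_text())
        return cls(
            b_hat=np.asarray(payload["b_hat"], dtype=float),
            snp_effect_hat=np.asarray(payload["snp_effect_hat"], dtype=float),
            inclusion_prob=np.asarray(payload["inclusion_prob"], dtype=float),
            sigma_e_hat=np.asarray(payload["sigma_e_hat"], dtype=float),
            sigma_gl_hat=np.asarray(payload["sigma_gl_hat"], dtype=float),
            s_hat=np.asarray(payload["s_hat"], dtype=float),
            pi_hat=float(payload["pi_hat"]),
            engine=payload["engine"],
            snp_ids=payload.get("snp_ids", []),
            trait_ids=payload.get("trait_ids", []),
            diagnostics=payload.get("diagnostics", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def encode_genotypes(
    raw_calls: np.ndarray,
    snp_ids: Sequence[str] | None = None,
    individual_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Map genotype calls to additive codes: 0_0 -> -1, 0_1 -> 0, 1_1 -> 1.

    Accepts a matrix of call strings, or a matrix already coded in
    {-1, 0, 1} (returned unchanged).  Unknown calls raise with the offending
    row/column named.
    """
    raw = np.asarray(raw_calls)
    if raw.ndim != 2:
        raise ValueError("raw_calls must be a 2-D matrix")
    if np.issubdtype(raw.dtype, np.number):
        codes = raw
    else:
        codes = np.empty(raw.shape, dtype=np.int8)
        for (i, j), call in np.ndenumerate(raw):
            call = str(call).strip()
            try:
                codes[i, j] = GENOTYPE_CODES[call] if call in GENOTYPE_CODES else int(call)
            except (KeyError, ValueError):
                raise ValueError(
                    f"unknown genotype call {call!r} at individual row {i}, "
                    f"SNP column {j}"
                ) from None
            if codes[i, j] not in _VALID_CODES:
                raise ValueError(
                    f"unknown genotype call {call!r} at individual row {i}, "
                    f"SNP column {j}"
                )
    return GenotypeMatrix(
        codes=codes,
        snp_ids=list(snp_ids) if snp_ids is not None else None,
        individual_ids=list(individual_ids) if individual_ids is not None else None,
    )


def decode_genotypes(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_genotypes`: codes back to call strings."""
    codes = np.asarray(codes)
    out = np.empty(codes.shape, dtype=object)
    for code, call in _CODE_TO_CALL.items():
        out[codes == code] = call
    if (out == None).any():  # noqa: E711  (elementwise comparison intended)
        raise ValueError("codes contain values outside {-1, 0, 1}")
    return out


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    monomorphic_snps: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_on_error(self) -> None:
        if self.errors:
            raise ValueError("; ".join(self.errors))


def validate_dataset(
    geno: GenotypeMatrix,
    pheno: PhenotypeMatrix,
    design: FixedEffectDesign | None = None,
    strict: bool = True,
) -> ValidationReport:
    """Check dimension agreement, mask consistency and design rank.

    Monomorphic SNPs are reported but retained; they stay in the model and
    are identified only through the prior.  With ``strict`` (default), hard
    errors raise immediately; otherwise they are collected in the report.
    """
    report = ValidationReport()
    if pheno.n_individuals != geno.n_individuals:
        report.errors.append(
            f"genotype rows ({geno.n_individuals}) != phenotype rows "
            f"({pheno.n_individuals})"
        )
    if design is not None:
        if design.n_individuals != geno.n_individuals:
            report.errors.append(
                f"design blocks ({design.n_individuals}) != genotype rows "
                f"({geno.n_individuals})"
            )
        elif design.n_traits != pheno.n_traits:
            report.errors.append(
                f"design trait dimension ({design.n_traits}) != phenotype "
                f"traits ({pheno.n_traits})"
            )
        elif not design.full_rank():
            report.errors.append("stacked fixed-effect design is rank deficient")
    observed = pheno.observed_counts()
    for t, count in enumerate(observed):
        if count == 0:
            report.errors.append(
                f"trait {pheno.trait_ids[t]!r} has no observed phenotype"
            )
    mono = geno.monomorphic()
    report.monomorphic_snps = [s for s, m in zip(geno.snp_ids, mono) if m]
    if report.monomorphic_snps:
        report.warnings.append(
            f"{len(report.monomorphic_snps)} monomorphic SNP(s) retained in model"
        )
    if strict:
        report.raise_on_error()
    return report
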