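"""Forward Wright-Fisher simulator for multi-trait genomic-selection data.

A neutral, randomly mating population of effective size Ne evolves for a
long burn-in to mutation-drift balance, building linkage disequilibrium
between dense marker loci and interleaved QTL.  The final two cohorts are
expanded: the first (the training generation) receives phenotypes, the
second (the test generation) carries genotypes and true breeding values
(TBVs) only.

Genome model
------------
``n_chromosomes`` chromosomes of ``chrom_length_cM``; markers equally spaced
along each chromosome, one QTL at the midpoint of a marker interval.
Recombination follows the Haldane map (no interference): along the ordered
loci of a chromosome the parental source haplotype is a two-state Markov
chain with switch probability (1 - exp(-2d))/2 for adjacent-locus distance d
in Morgans.  Mutation is infinite-alleles per locus: every event creates a
fresh allele.  At sampling time each marker is collapsed to a biallelic SNP:
the surviving mutation with the highest minor allele frequency in the
training cohort becomes allele 1, all other alleles (ancestral included)
collapse to allele 0; loci without surviving mutations are constant.

Trait model
-----------
Polymorphic QTLs (ascertained in the training generation) are randomly
assigned to four groups: Group1 affects traits A and B pleiotropically,
Group2 only A, Group3 only B, Group4 only C.  Allele-effect magnitudes are
gamma draws; Group1 pairs (x, y) share a gamma component so that
corr(x, y) = 0.9 while both marginals stay Gamma(shape 0.4, scale 1.66).  A
single random sign per QTL is applied (shared across the pleiotropic pair,
preserving the positive genetic correlation between A and B).  Environmental
effects are multivariate normal with variances set from the realized TBV
variances via sigma_E^2 = (1/h^2 - 1) * sigma_G^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .datamodel import GenotypeMatrix, PhenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TraitArchitecture",
    "SimulatedDataset",
    "fast_config",
    "simulate_base_population",
    "derive_snp_panel",
    "assign_qtl_groups",
    "sample_correlated_gamma",
    "compute_tbv",
    "generate_dataset",
    "apply_data3_missingness",
]

QTL_GROUP_NAMES = ("Group1", "Group2", "Group3", "Group4")


@dataclass
class SimulationConfig:
    """Parameters of the population, genome and trait architecture.

    Defaults reproduce the dense-marker scenario with 1010 SNPs (101 markers
    on each of 10 chromosomes of 100 cM), 1000 interleaved QTL, effective
    size 100 held for 1000 generations, then two expanded cohorts of 1000.
    """

    n_chromosomes: int = 10
    chrom_length_cM: float = 100.0
    markers_per_chromosome: int = 101
    qtl_per_chromosome: int = 100
    effective_size: int = 100
    burn_generations: int = 1000
    expanded_size: int = 1000
    marker_mutation_rate: float = 2.5e-3
    qtl_mutation_rate: float = 5.0e-5
    heritabilities: tuple[float, ...] = (0.8, 0.1, 0.1)
    group_probs: tuple[float, ...] = (0.4, 0.1, 0.1, 0.4)
    pleiotropy_corr: float = 0.9
    env_corrs: tuple[float, ...] = (0.1, 0.2, 0.3)  # (AB, AC, BC)
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ValueError("group_probs must sum to 1")
        if not all(0.0 < h < 1.0 for h in self.heritabilities):
            raise ValueError("heritabilities must lie in (0, 1)")
        if not 0.0 <= self.pleiotropy_corr <= 1.0:
            raise ValueError("pleiotropy_corr must lie in [0, 1]")
        if self.markers_per_chromosome < 2:
            raise ValueError("need at least two markers per chromosome")
        if self.qtl_per_chromosome > self.markers_per_chromosome - 1:
            raise ValueError("more QTL than marker intervals on a chromosome")

    @property
    def n_traits(self) -> int:
        return len(self.heritabilities)

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    @property
    def n_qtl(self) -> int:
        return self.n_chromosomes * self.qtl_per_chromosome

    def env_correlation_matrix(self) -> np.ndarray:
        T = self.n_traits
        C = np.eye(T)
        idx = [(a, b) for a in range(T) for b in range(a + 1, T)]
        for (a, b), rho in zip(idx, self.env_corrs):
            C[a, b] = C[b, a] = rho
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("environmental correlation matrix is not positive definite")
        return C


def fast_config(seed: int | None = None) -> SimulationConfig:
    """A miniature configuration for unit tests and smoke runs.

    Mutation rates are raised so the locus-level diversity (theta = 4*Ne*mu)
    matches the full-scale setting despite the smaller effective size.
    """
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length_cM=100.0,
        markers_per_chromosome=26,
        qtl_per_chromosome=25,
        effective_size=40,
        burn_generations=250,
        expanded_size=150,
        marker_mutation_rate=6.25e-3,   # theta = 4*40*mu = 1
        qtl_mutation_rate=1.25e-3,
        seed=seed,
    )


@dataclass
class TraitArchitecture:
    """Realized genetic architecture of one simulated replicate."""

    qtl_group: np.ndarray        # (Q,) int in {0,1,2,3} for polymorphic QTLs
    allele_effects: np.ndarray   # (Q, T) effect of the mutant allele per trait
    env_cov: np.ndarray          # (T, T) environmental covariance R_E
    qtl_positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        groups = np.asarray(self.qtl_group)
        effects = np.asarray(self.allele_effects, dtype=float)
        if groups.shape[0] != effects.shape[0]:
            raise ValueError("qtl_group and allele_effects disagree in length")
        # group structure: zero effects outside the affected traits
        T = effects.shape[1]
        if T >= 3:
            if (effects[groups == 0][:, 2:] != 0).any():
                raise ValueError("Group1 QTLs may only affect traits A and B")
            if (effects[groups == 1][:, 1:] != 0).any():
                raise ValueError("Group2 QTLs may only affect trait A")
            if (effects[groups == 2][:, [0, 2]] != 0).any():
                raise ValueError("Group3 QTLs may only affect trait B")
            if (effects[groups == 3][:, :2] != 0).any():
                raise ValueError("Group4 QTLs may only affect trait C")
        if np.linalg.eigvalsh(np.asarray(self.env_cov)).min() <= 0:
            raise ValueError("env_cov must be symmetric positive definite")
        self.qtl_group = groups
        self.allele_effects = effects
        self.env_cov = np.asarray(self.env_cov, dtype=float)


@dataclass
class SimulatedDataset:
    """Training + test cohorts with ground-truth breeding values."""

    train_geno: GenotypeMatrix
    train_pheno: PhenotypeMatrix
    test_geno: GenotypeMatrix
    train_tbv: np.ndarray     # (n_train, T)
    test_tbv: np.ndarray      # (n_test, T)
    architecture: TraitArchitecture
    scenario: str = "data1"

    def save(self, out_dir: str | Path, prefix: str = "rep") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.train_geno.save(out / f"{prefix}_train_geno.tsv")
        self.train_pheno.save(
            out / f"{prefix}_train_pheno.tsv", self.train_geno.individual_ids
        )
        self.test_geno.save(out / f"{prefix}_test_geno.tsv")
        np.savetxt(out / f"{prefix}_train_tbv.tsv", self.train_tbv, delimiter="\t")
        np.savetxt(out / f"{prefix}_test_tbv.tsv", self.test_tbv, delimiter="\t")
        cols = [self.architecture.qtl_group, self.architecture.allele_effects]
        header = "group\t" + "\t".join(
            f"effect_{t}" for t in self.train_pheno.trait_ids
        )
        if self.architecture.qtl_positions is not None:
            cols.insert(0, self.architecture.qtl_positions)
            header = "position_cM\t" + header
        arch = np.column_stack(cols)
        np.savetxt(
            out / f"{prefix}_architecture.tsv", arch, delimiter="\t",
            header=header, comments="",
        )


# ---------------------------------------------------------------------------
# population machinery
# ---------------------------------------------------------------------------

@dataclass
class _Genome:
    """Locus map shared by all generations of one replicate."""

    positions_cM: np.ndarray   # (L,) position within chromosome
    chromosome: np.ndarray     # (L,) chromosome index
    is_qtl: np.ndarray         # (L,) bool
    switch_prob: np.ndarray    # (L,) Markov switch probability per locus

    @property
    def n_loci(self) -> int:
        return self.positions_cM.shape[0]

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)


def _build_genome(config: SimulationConfig) -> _Genome:
    """Interleave equally spaced markers with QTLs at interval midpoints."""
    m = config.markers_per_chromosome
    marker_pos = np.linspace(0.0, config.chrom_length_cM, m)
    # pick qtl_per_chromosome marker intervals as evenly as possible and
    # place one QTL at the midpoint of each chosen interval
    intervals = np.linspace(0, m - 2, config.qtl_per_chromosome).round().astype(int)
    qtl_pos = 0.5 * (marker_pos[intervals] + marker_pos[intervals + 1])

    pos_list, chrom_list, qtl_list = [], [], []
    for c in range(config.n_chromosomes):
        pos = np.concatenate([marker_pos, qtl_pos])
        flag = np.concatenate(
            [np.zeros(m, dtype=bool), np.ones(len(qtl_pos), dtype=bool)]
        )
        order = np.argsort(pos, kind="stable")
        pos_list.append(pos[order])
        qtl_list.append(flag[order])
        chrom_list.append(np.full(pos.shape, c))
    positions = np.concatenate(pos_list)
    chrom = np.concatenate(chrom_list)
    is_qtl = np.concatenate(qtl_list)

    # Haldane switch probabilities; a fresh chromosome starts from a random
    # parental haplotype (probability 1/2)
    d_morgan = np.diff(positions, prepend=positions[0]) / 100.0
    switch = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    switch[np.diff(chrom, prepend=-1) != 0] = 0.5
    return _Genome(positions, chrom, is_qtl, switch)


@dataclass
class _Population:
    """Haplotypes of the final cohorts plus the locus map.

    Haplotype entries are infinite-alleles labels: 0 is ancestral, every
    mutation event writes a fresh positive label at its locus.
    """

    genome: _Genome
    train_haplotypes: np.ndarray   # (2*n_train, L) int32
    test_haplotypes: np.ndarray    # (2*n_test, L) int32


def _next_generation(
    haplotypes: np.ndarray,
    n_offspring: int,
    genome: _Genome,
    marker_rate: float,
    qtl_rate: float,
    next_allele: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random mating with Haldane recombination and infinite-alleles mutation."""
    n_parents = haplotypes.shape[0] // 2
    L = genome.n_loci
    parents = rng.integers(n_parents, size=2 * n_offspring)
    switches = rng.random((2 * n_offspring, L)) < genome.switch_prob
    source = np.cumsum(switches, axis=1) & 1
    hap_a = haplotypes[2 * parents]
    hap_b = haplotypes[2 * parents + 1]
    gametes = np.where(source == 0, hap_a, hap_b).astype(np.int32)

    for idx, rate in ((genome.marker_idx, marker_rate), (genome.qtl_idx, qtl_rate)):
        if rate <= 0 or idx.size == 0:
            continue
        n_events = rng.poisson(2 * n_offspring * idx.size * rate)
        if n_events == 0:
            continue
        rows = rng.integers(2 * n_offspring, size=n_events)
        cols = idx[rng.integers(idx.size, size=n_events)]
        for r, c in zip(rows, cols):
            gametes[r, c] = next_allele[c]
            next_allele[c] += 1
    return gametes


def simulate_base_population(
    config: SimulationConfig, rng: np.random.Generator
) -> _Population:
    """Burn in Ne diploids to mutation-drift balance, then expand twice.

    Founders are monomorphic (all-ancestral) everywhere; standing diversity
    arises from mutation during the burn-in.  The two expanded cohorts play
    the training and test roles.
    """
    genome = _build_genome(config)
    next_allele = np.ones(genome.n_loci, dtype=np.int64)
    haps = np.zeros((2 * config.effective_size, genome.n_loci), dtype=np.int32)
    for _ in range(config.burn_generations):
        haps = _next_generation(
            haps, config.effective_size, genome,
            config.marker_mutation_rate, config.qtl_mutation_rate,
            next_allele, rng,
        )
    train = _next_generation(
        haps, config.expanded_size, genome,
        config.marker_mutation_rate, config.qtl_mutation_rate, next_allele, rng,
    )
    test = _next_generation(
        train, config.expanded_size, genome,
        config.marker_mutation_rate, config.qtl_mutation_rate, next_allele, rng,
    )
    return _Population(genome, train, test)


def _collapse_biallelic(train_col: np.ndarray, test_col: np.ndarray):
    """Pick the visible mutation at one locus by the highest-MAF rule.

    Returns mutant-allele dosage vectors (per diploid individual) for the
    training and test cohorts, or ``None`` if no mutation survives in the
    training cohort.  Frequencies are measured in the training cohort; ties
    break toward the earliest mutation event (lowest allele label).
    """
    alleles, counts = np.unique(train_col, return_counts=True)
    derived = alleles > 0
    if not derived.any():
        return None
    freqs = counts[derived] / train_col.shape[0]
    maf = np.minimum(freqs, 1.0 - freqs)
    # argmax returns the first max; alleles are sorted ascending, so ties
    # resolve to the lowest allele label automatically
    chosen = alleles[derived][np.argmax(maf)]
    train_dose = (train_col.reshape(-1, 2) == chosen).sum(axis=1)
    test_dose = (test_col.reshape(-1, 2) == chosen).sum(axis=1)
    return train_dose.astype(np.int8), test_dose.astype(np.int8)


def derive_snp_panel(pop: _Population) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Collapse marker loci to biallelic SNP codes for both cohorts.

    Loci with no surviving mutation in the training cohort are constant:
    every individual is ancestral-homozygous, code -1.
    """
    marker_idx = pop.genome.marker_idx
    n_train = pop.train_haplotypes.shape[0] // 2
    n_test = pop.test_haplotypes.shape[0] // 2
    train_codes = np.full((n_train, marker_idx.size), -1, dtype=np.int8)
    test_codes = np.full((n_test, marker_idx.size), -1, dtype=np.int8)
    for j, locus in enumerate(marker_idx):
        collapsed = _collapse_biallelic(
            pop.train_haplotypes[:, locus], pop.test_haplotypes[:, locus]
        )
        if collapsed is None:
            continue
        train_dose, test_dose = collapsed
        train_codes[:, j] = train_dose - 1
        test_codes[:, j] = test_dose - 1
    snp_ids = [f"snp{j + 1}" for j in range(marker_idx.size)]
    train = GenotypeMatrix(train_codes, snp_ids, [f"tr{i+1}" for i in range(n_train)])
    test = GenotypeMatrix(test_codes, snp_ids, [f"te{i+1}" for i in range(n_test)])
    return train, test


def _qtl_dosages(pop: _Population):
    """Mutant-allele dosage (0/1/2) at QTLs polymorphic in the training cohort."""
    qtl_idx = pop.genome.qtl_idx
    train_list, test_list, kept = [], [], []
    for locus in qtl_idx:
        collapsed = _collapse_biallelic(
            pop.train_haplotypes[:, locus], pop.test_haplotypes[:, locus]
        )
        if collapsed is None:
            continue
        train_dose, test_dose = collapsed
        if train_dose.min() == train_dose.max():   # fixed in training cohort
            continue
        train_list.append(train_dose)
        test_list.append(test_dose)
        kept.append(locus)
    if not train_list:
        return (np.zeros((pop.train_haplotypes.shape[0] // 2, 0)),
                np.zeros((pop.test_haplotypes.shape[0] // 2, 0)),
                np.asarray(kept, dtype=int))
    return (
        np.column_stack(train_list).astype(float),
        np.column_stack(test_list).astype(float),
        np.asarray(kept, dtype=int),
    )


# ---------------------------------------------------------------------------
# trait architecture
# ---------------------------------------------------------------------------

def assign_qtl_groups(
    n_polymorphic: int,
    group_probs: tuple[float, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent categorical group draw per polymorphic QTL."""
    probs = np.asarray(group_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("group_probs must sum to 1")
    return rng.choice(len(probs), size=n_polymorphic, p=probs)


def sample_correlated_gamma(
    rng: np.random.Generator,
    size: int | None = None,
    shape: float = 0.4,
    scale: float = 1.66,
    shared_shape: float | None = None,
):
    """Correlated gamma magnitudes (x, y) for a pleiotropic QTL.

    x = x1 + x2 and y = x1 + x3 with x1 ~ Gamma(shape*rho) and x2, x3 ~
    Gamma(shape*(1-rho)) at a common scale, so both marginals are
    Gamma(shape, scale) and corr(x, y) = shared_shape/shape (0.36/0.40 = 0.9
    at the defaults).
    """
    if shared_shape is None:
        shared_shape = 0.36
    rest = shape - shared_shape
    if rest < 0:
        raise ValueError("shared_shape cannot exceed the marginal shape")
    x1 = rng.gamma(shared_shape, scale, size=size)
    x2 = rng.gamma(rest, scale, size=size) if rest > 0 else 0.0
    x3 = rng.gamma(rest, scale, size=size) if rest > 0 else 0.0
    return x1 + x2, x1 + x3


def _draw_allele_effects(
    groups: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-QTL T-vector of mutant-allele effects honouring the group map.

    One sign per QTL, shared across the pleiotropic pair of Group1, keeps
    the within-QTL effect correlation at +0.9.
    """
    T = config.n_traits
    shared = config.pleiotropy_corr * config.gamma_shape
    effects = np.zeros((groups.shape[0], T))
    signs = np.where(rng.random(groups.shape[0]) < 0.5, 1.0, -1.0)
    for q, grp in enumerate(groups):
        if grp == 0:
            x, y = sample_correlated_gamma(
                rng, shape=config.gamma_shape, scale=config.gamma_scale,
                shared_shape=shared,
            )
            effects[q, 0] = signs[q] * x
            effects[q, 1] = signs[q] * y
        else:
            z = rng.gamma(config.gamma_shape, config.gamma_scale)
            trait = {1: 0, 2: 1, 3: 2}[grp]
            effects[q, trait] = signs[q] * z
    return effects


def compute_tbv(qtl_dosages: np.ndarray, architecture: TraitArchitecture) -> np.ndarray:
    """TBV_t(i) = sum_q dosage(i, q) * effect(q, t)."""
    return np.asarray(qtl_dosages, dtype=float) @ architecture.allele_effects


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(
    scenario: Literal["data1", "data2", "data3"] = "data1",
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Simulate one replicate of a training + test dataset.

    ``data1``: 101 markers per chromosome, complete phenotypes.
    ``data2``: 1010 markers per chromosome, complete phenotypes.
    ``data3``: as data1 but with the structured missing-phenotype pattern.
    """
    if config is None:
        config = SimulationConfig()
    if scenario == "data2" and config.markers_per_chromosome == 101:
        config = replace(config, markers_per_chromosome=1010)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    pop = simulate_base_population(config, rng)
    train_geno, test_geno = derive_snp_panel(pop)
    train_dose, test_dose, kept_loci = _qtl_dosages(pop)

    n_poly = train_dose.shape[1]
    groups = assign_qtl_groups(n_poly, config.group_probs, rng)
    effects = _draw_allele_effects(groups, config, rng)

    # environmental covariance from realized training-generation TBV variances
    arch_tmp = TraitArchitecture(
        groups, effects, np.eye(config.n_traits),
        qtl_positions=pop.genome.positions_cM[kept_loci] if kept_loci.size else None,
    )
    train_tbv = compute_tbv(train_dose, arch_tmp)
    test_tbv = compute_tbv(test_dose, arch_tmp)
    sigma_g = train_tbv.var(axis=0, ddof=1)
    if (sigma_g <= 0).any():
        bad = int(np.argmin(sigma_g))
        raise ValueError(
            f"trait index {bad} has zero TBV variance: no polymorphic QTL "
            "affects it in this replicate"
        )
    h2 = np.asarray(config.heritabilities)
    sigma_e = (1.0 / h2 - 1.0) * sigma_g
    corr = config.env_correlation_matrix()
    sd = np.sqrt(sigma_e)
    env_cov = corr * np.outer(sd, sd)
    architecture = TraitArchitecture(
        groups, effects, env_cov, qtl_positions=arch_tmp.qtl_positions
    )

    env = rng.multivariate_normal(
        np.zeros(config.n_traits), env_cov, size=train_tbv.shape[0],
        method="cholesky",
    )
    pheno = PhenotypeMatrix(
        values=train_tbv + env,
        observed_mask=np.ones(train_tbv.shape, dtype=bool),
        trait_ids=[chr(ord("A") + t) for t in range(config.n_traits)],
    )
    dataset = SimulatedDataset(
        train_geno=train_geno,
        train_pheno=pheno,
        test_geno=test_geno,
        train_tbv=train_tbv,
        test_tbv=test_tbv,
        architecture=architecture,
        scenario=scenario,
    )
    if scenario == "data3":
        dataset = apply_data3_missingness(dataset)
    return dataset


def apply_data3_missingness(
    dataset: SimulatedDataset, strict: bool = False
) -> SimulatedDataset:
    """Delete phenotypes in the structured pattern of the missing-data scenario.

    With n = 1000 training individuals: trait A missing for i = 801-1000,
    trait B for i = 1-500, trait C for i = 201-700 (1-based), leaving
    800/500/500 observed records and exactly 100 individuals (i = 701-800)
    with all three traits.  For other n the windows scale proportionally
    unless ``strict`` is set, in which case a mismatch raises.
    """
    pheno = dataset.train_pheno
    n = pheno.n_individuals
    if pheno.n_traits < 3:
        raise ValueError("the missing-data pattern is defined for three traits")
    if n != 1000 and strict:
        raise ValueError(f"strict mode requires n=1000 training individuals, got {n}")
    scale = n / 1000.0
    windows = {  # trait -> (start, stop) 1-based inclusive at n=1000
        0: (801, 1000),
        1: (1, 500),
        2: (201, 700),
    }
    mask = pheno.observed_mask.copy()
    for trait, (start, stop) in windows.items():
        lo = int(round((start - 1) * scale))
        hi = int(round(stop * scale))
        mask[lo:hi, trait] = False
    new_pheno = PhenotypeMatrix(
        values=pheno.values.copy(), observed_mask=mask, trait_ids=pheno.trait_ids
    )
    return replace(dataset, train_pheno=new_pheno, scenario="data3")
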