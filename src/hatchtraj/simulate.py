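"""Synthetic breeding-program generator for longitudinal hatchery traits.

Emulates the data structure of a pedigreed turkey maternal line under
biweekly fertility/hatchability recording:

* a multi-generation pedigree with discrete generations and a hen:tom
  mating ratio of about 5:1 (each hen keeps one tom for her whole lay),
* gene-dropped unlinked SNP genotypes (founder allele frequencies drawn
  uniformly on (0.1, 0.9); the last chromosome is labeled non-autosomal so
  downstream quality control has something to remove),
* long-format biweekly percentage records generated from the
  random-regression model: fixed hatch-week / egg-hatch-week effects and a
  cubic fixed age trend, plus hen and tom additive and permanent-environment
  random-regression coefficients and heteroskedastic residuals per age.

Additive coefficient vectors are polygenic by default: per-marker effect
vectors on the gene-dropped genotypes, so relatives covary through their
realized genomic relationship (expectation: the pedigree A) and genomic
relationship matrices genuinely carry information about breeding values.
A "pedigree" architecture is also available that gene-drops coefficients
directly with the exact pedigree covariance (founders ~ N(0, K);
offspring = parent average + Mendelian deviation with covariance d_i K,
d_i = 1/2 - (F_s + F_d)/4), giving coefficients N(0, A x K) but markers
uninformative about them.

Records are Gaussian (no truncation to [0, 100]) so that variance-component
recovery stays unbiased and testable; set ``clamp_percentages=True`` for
bounded records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .legendre import DEFAULT_AGES, AgeGrid, legendre_matrix
from .relationships import UNKNOWN, GenotypeMatrix, Pedigree

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "default_parameters",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "SimulatedEffects",
]

# stable substream labels so each stage has its own reproducible stream
_STAGES = {"pedigree": 11, "genotypes": 23, "phenotypes": 37}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs of the synthetic breeding program."""

    n_generations: int = 6
    n_females_per_gen: int = 200
    n_males_per_gen: int = 40
    n_snps: int = 2000
    n_chromosomes: int = 10
    genotyped_fraction: float = 0.5
    ages: tuple[int, ...] = DEFAULT_AGES
    trait_means: dict = field(default_factory=lambda: {"HOF": 81.1})
    dropout: float = 0.1
    clamp_percentages: bool = False
    genetic_architecture: str = "markers"  # "markers" | "pedigree"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_generations", "n_females_per_gen", "n_males_per_gen"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_snps <= 0 or self.n_chromosomes <= 0:
            raise ValueError("marker counts must be positive")
        if not 0.0 <= self.genotyped_fraction <= 1.0:
            raise ValueError("genotyped_fraction must lie in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        ages = tuple(self.ages)
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        object.__setattr__(self, "ages", ages)
        if self.genetic_architecture not in ("markers", "pedigree"):
            raise ValueError("genetic_architecture must be 'markers' or 'pedigree'")

    @property
    def grid(self) -> AgeGrid:
        return AgeGrid(self.ages)


def _check_psd(K: np.ndarray, name: str) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if K.size and np.min(np.linalg.eigvalsh(K)) < -1e-8:
        raise ValueError(f"{name} is not positive semi-definite")
    return K


@dataclass(frozen=True)
class TrueParameters:
    """Generating variance structure and fixed effects of the simulator.

    The K matrices are covariances of random-regression coefficients on the
    normalized Legendre basis (units %^2); their sizes set the polynomial
    orders (hen additive 3, tom additive 1, hen PE 3, tom PE 2 by default).
    ``sigma2_e`` holds one residual variance per biweekly age class.
    ``beta_age`` are the fixed cubic age-regression coefficients on basis
    columns 1..3 (the intercept is carried by the overall mean).
    """

    K_aF: np.ndarray
    K_aM: np.ndarray
    K_peF: np.ndarray
    K_peM: np.ndarray
    sigma2_e: np.ndarray
    beta_age: np.ndarray
    hatch_week_effects: np.ndarray
    egg_hatch_week_effects: np.ndarray

    def __post_init__(self) -> None:
        for name in ("K_aF", "K_aM", "K_peF", "K_peM"):
            object.__setattr__(self, name, _check_psd(getattr(self, name), name))
        s2 = np.asarray(self.sigma2_e, dtype=float)
        if np.any(s2 < 0):
            raise ValueError("sigma2_e entries must be non-negative")
        object.__setattr__(self, "sigma2_e", s2)
        object.__setattr__(self, "beta_age", np.asarray(self.beta_age, dtype=float))
        object.__setattr__(
            self, "hatch_week_effects", np.asarray(self.hatch_week_effects, dtype=float)
        )
        object.__setattr__(
            self,
            "egg_hatch_week_effects",
            np.asarray(self.egg_hatch_week_effects, dtype=float),
        )


def default_parameters() -> TrueParameters:
    """Default generating values for a hatch-of-fertile-like trait.

    Chosen to sit in the published range for turkey hatchery traits under
    random regression: per-age hen additive variance near 100 %^2, hen
    permanent environment near 110 %^2, small tom contributions, residual
    variance rising with hen age from 350 to 560 %^2, so per-age
    heritability is roughly 0.12-0.16 and repeatability roughly 0.3.
    """
    return TrueParameters(
        K_aF=np.diag([200.0, 8.0, 3.0, 1.5]),
        K_aM=np.diag([10.0, 2.0]),
        K_peF=np.diag([220.0, 30.0, 10.0, 5.0]),
        K_peM=np.diag([40.0, 6.0, 3.0]),
        sigma2_e=np.linspace(350.0, 560.0, len(DEFAULT_AGES)),
        beta_age=np.array([-3.5, -1.0, 0.8]),
        hatch_week_effects=np.array([0.0, 1.2, -0.8, 2.0, -1.5, 0.6]),
        egg_hatch_week_effects=np.array(
            [0.0, 0.9, -0.5, 1.4, -1.1, 0.3, -0.7, 1.0, -0.2, 0.5]
        ),
    )


# -- pedigree ----------------------------------------------------------------

def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Discrete-generation pedigree with ~5:1 hen:tom matings.

    Generation 0 animals are founders with unknown parents.  Within each
    generation every hen is assigned one tom (toms serve about
    ``n_females/n_males`` hens); offspring of the next generation are drawn
    uniformly from these matings.  The hen -> tom assignment is stored on
    ``Pedigree.matings`` and reused by the phenotype simulator.
    """
    rng = _rng(config.seed, "pedigree")
    nf, nm, ng = config.n_females_per_gen, config.n_males_per_gen, config.n_generations
    per_gen = nf + nm
    n = ng * per_gen
    ids = np.arange(1, n + 1, dtype=np.int64)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    sex = np.empty(n, dtype=object)
    generation = np.repeat(np.arange(ng), per_gen)
    mating_rows: list[tuple[int, int]] = []

    for g in range(ng):
        base = g * per_gen
        sex[base : base + nf] = "F"
        sex[base + nf : base + per_gen] = "M"
        # matings within generation g (used to breed g+1 and to record)
        hens = base + rng.permutation(nf)
        toms = base + nf + np.arange(nm)
        mates = {int(h): int(toms[k % nm]) for k, h in enumerate(hens)}
        mating_rows += [(int(ids[h]), int(ids[t])) for h, t in mates.items()]
        if g + 1 < ng:
            nxt = (g + 1) * per_gen
            chosen = rng.choice(np.sort(list(mates.keys())), size=per_gen)
            for j, h in enumerate(chosen):
                dam[nxt + j] = h
                sire[nxt + j] = mates[int(h)]
    ped = Pedigree(ids=ids, sire=sire, dam=dam, sex=sex, generation=generation)
    ped.matings = pd.DataFrame(mating_rows, columns=["hen", "tom"]).sort_values(
        "hen", ignore_index=True
    )
    return ped


# -- genotypes ---------------------------------------------------------------

def _transmit(parent_dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per unlinked locus given the parent's dosage."""
    out = (parent_dosage == 2).astype(np.int8)
    het = parent_dosage == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def _gene_drop_dosages(ped: Pedigree, config: SimulationConfig) -> np.ndarray:
    """Dosages for every pedigree animal from the seeded genotype stream."""
    rng = _rng(config.seed, "genotypes")
    n, m = ped.n, config.n_snps
    freqs = rng.uniform(0.1, 0.9, size=m)
    dos = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pat = (
            _transmit(dos[s], rng)
            if s != UNKNOWN
            else (rng.random(m) < freqs).astype(np.int8)
        )
        mat = (
            _transmit(dos[d], rng)
            if d != UNKNOWN
            else (rng.random(m) < freqs).astype(np.int8)
        )
        dos[i] = pat + mat
    return dos


def simulate_genotypes(ped: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Gene-dropped unlinked SNP dosages for the genotyped subset.

    Founders draw alleles with per-locus frequencies ~ U(0.1, 0.9);
    non-founders receive one Mendelian allele per parent.  Markers are split
    into ``n_chromosomes`` contiguous blocks; the last block is labeled 'Z'
    (non-autosomal) to exercise the quality-control filter.  The genotyped
    subset is the youngest ``genotyped_fraction`` of animals, mirroring
    selective genotyping of recent generations.
    """
    n, m = ped.n, config.n_snps
    dos = _gene_drop_dosages(ped, config)
    bounds = np.linspace(0, m, config.n_chromosomes + 1).astype(int)
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    for c in range(config.n_chromosomes):
        lo, hi = bounds[c], bounds[c + 1]
        label = "Z" if c == config.n_chromosomes - 1 else str(c + 1)
        chrom[lo:hi] = label
        pos[lo:hi] = np.arange(1, hi - lo + 1)
    meta = pd.DataFrame(
        {"marker": [f"snp{j + 1}" for j in range(m)], "chromosome": chrom, "position": pos}
    )
    k = int(round(config.genotyped_fraction * n))
    take = np.arange(n - k, n)  # youngest animals
    return GenotypeMatrix(
        dosages=dos[take], animal_ids=ped.ids[take], marker_meta=meta
    )


# -- phenotypes --------------------------------------------------------------

@dataclass
class SimulatedEffects:
    """True effects behind a simulated phenotype table (one trait)."""

    aF: pd.DataFrame
    aM: pd.DataFrame
    peF: pd.DataFrame
    peM: pd.DataFrame


def _marker_effect_coefficients(
    centered: np.ndarray,
    scale: float,
    K: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Polygenic coefficient vectors: sums of per-marker effect vectors.

    Marker effect rows are N(0, K / scale) with scale = 2 sum p(1-p), so
    founder coefficients have covariance ~K and relatives covary through
    their realized genomic relationship (expectation: the pedigree A).
    """
    q = K.shape[0]
    L = np.linalg.cholesky(K / scale + 1e-14 * np.trace(K + np.eye(q)) * np.eye(q))
    B = rng.standard_normal((centered.shape[1], q)) @ L.T
    return centered @ B


def _gene_drop_coefficients(
    ped: Pedigree, K: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Coefficient vectors with covariance A (x) K across animals."""
    q = K.shape[0]
    L = np.linalg.cholesky(K + 1e-12 * np.eye(q))
    d = ped.mendelian_variance
    coef = np.empty((ped.n, q))
    noise = rng.standard_normal((ped.n, q)) @ L.T
    for i in range(ped.n):
        s, dd = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and dd == UNKNOWN:
            coef[i] = noise[i]
        else:
            pa = 0.0
            if s != UNKNOWN:
                pa = pa + 0.5 * coef[s]
            if dd != UNKNOWN:
                pa = pa + 0.5 * coef[dd]
            coef[i] = pa + np.sqrt(d[i]) * noise[i]
    return coef


def simulate_phenotypes(
    ped: Pedigree,
    params: TrueParameters,
    config: SimulationConfig,
    return_effects: bool = False,
):
    """Long-format biweekly records from the random-regression model.

    One row per hen x age x trait (ages thinned by the per-age ``dropout``
    probability).  Hens of every generation after the founders are recorded,
    each with the single tom assigned to her in ``ped.matings``.  Egg hatch
    week is derived from the hen's hatch week shifted by the age index.
    Returns the record table, plus the true random-effect coefficients per
    trait when ``return_effects`` is set.
    """
    if ped.matings is None:
        raise ValueError("pedigree carries no mating assignment (simulated pedigrees do)")
    rng = _rng(config.seed, "phenotypes")
    grid = config.grid
    n_ages = grid.n_ages
    if params.sigma2_e.size != n_ages:
        raise ValueError("sigma2_e must provide one residual variance per age")
    basis = {
        "aF": legendre_matrix(grid, params.K_aF.shape[0] - 1).values,
        "aM": legendre_matrix(grid, params.K_aM.shape[0] - 1).values,
        "peF": legendre_matrix(grid, params.K_peF.shape[0] - 1).values,
        "peM": legendre_matrix(grid, params.K_peM.shape[0] - 1).values,
    }
    reg = legendre_matrix(grid, params.beta_age.size).values[:, 1:]
    fixed_age = reg @ params.beta_age

    recorded = (
        (ped.generation > 0) & (ped.sex == "F")
        if ped.generation is not None
        else np.ones(ped.n, dtype=bool) & (ped.sex == "F")
    )
    hen_ids = ped.ids[recorded]
    mate = dict(zip(ped.matings["hen"], ped.matings["tom"]))
    missing = [int(h) for h in hen_ids if int(h) not in mate]
    if missing:
        raise ValueError(f"no mate assigned for hens {missing[:5]}")
    tom_ids = np.array([mate[int(h)] for h in hen_ids], dtype=np.int64)
    tom_pos = ped.positions(tom_ids)
    hen_pos = ped.positions(hen_ids)

    n_hw = params.hatch_week_effects.size
    n_ehw = params.egg_hatch_week_effects.size
    hw = rng.integers(0, n_hw, size=hen_ids.size)

    if config.genetic_architecture == "markers":
        dosages = _gene_drop_dosages(ped, config).astype(float)
        founders = (ped.sire == UNKNOWN) & (ped.dam == UNKNOWN)
        p = dosages[founders].mean(axis=0) / 2.0
        centered = dosages - 2.0 * p
        scale = float(2.0 * np.sum(p * (1.0 - p)))
    frames = []
    effects: dict[str, SimulatedEffects] = {}
    for trait, mu in config.trait_means.items():
        if config.genetic_architecture == "markers":
            aF = _marker_effect_coefficients(centered, scale, params.K_aF, rng)
            aM = _marker_effect_coefficients(centered, scale, params.K_aM, rng)
        else:
            aF = _gene_drop_coefficients(ped, params.K_aF, rng)
            aM = _gene_drop_coefficients(ped, params.K_aM, rng)
        peF = rng.multivariate_normal(
            np.zeros(params.K_peF.shape[0]), params.K_peF, size=hen_ids.size
        )
        tom_unique, tom_slot = np.unique(tom_pos, return_inverse=True)
        peM = rng.multivariate_normal(
            np.zeros(params.K_peM.shape[0]), params.K_peM, size=tom_unique.size
        )
        keep = rng.random((hen_ids.size, n_ages)) >= config.dropout
        resid = rng.standard_normal((hen_ids.size, n_ages)) * np.sqrt(params.sigma2_e)
        value = (
            mu
            + params.hatch_week_effects[hw][:, None]
            + fixed_age[None, :]
            + aF[hen_pos] @ basis["aF"].T
            + peF @ basis["peF"].T
            + aM[tom_pos] @ basis["aM"].T
            + peM[tom_slot] @ basis["peM"].T
            + resid
        )
        age_idx = np.arange(n_ages)
        ehw = (hw[:, None] + age_idx[None, :]) % n_ehw
        value = value + params.egg_hatch_week_effects[ehw]
        if config.clamp_percentages:
            value = np.clip(value, 0.0, 100.0)
        rows, cols = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "hen": hen_ids[rows],
                    "tom": tom_ids[rows],
                    "age_weeks": np.asarray(grid.ages)[cols],
                    "hatch_week": hw[rows] + 1,
                    "egg_hatch_week": ehw[rows, cols] + 1,
                    "trait": trait,
                    "value": value[rows, cols],
                }
            )
        )
        effects[trait] = SimulatedEffects(
            aF=pd.DataFrame(aF, index=ped.ids),
            aM=pd.DataFrame(aM, index=ped.ids),
            peF=pd.DataFrame(peF, index=hen_ids),
            peM=pd.DataFrame(peM, index=ped.ids[tom_unique]),
        )
    table = pd.concat(frames, ignore_index=True)
    if return_effects:
        return table, effects
    return table
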