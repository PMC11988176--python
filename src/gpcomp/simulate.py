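"""Synthetic pedigreed populations for genomic-prediction benchmarking.

Emulates a multi-generation commercial pig cohort: founders drawn at
configurable allele frequencies, descendants produced by gene dropping with
Haldane (no-interference) recombination, additive trait architectures
(polygenic, sparse, or a four-component normal mixture), categorical fixed
effects contaminating the raw phenotype, and a genotyped final cohort.

The residual standard deviation is calibrated against the *realized* additive
variance so that in-sample heritability equals the target exactly, which
keeps parameter-recovery checks sharp.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigError, GenotypeMatrix, Pedigree

__all__ = [
    "SimConfig",
    "TrueGeneticValues",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_effects_and_phenotypes",
    "select_genotyped",
    "inject_missingness",
    "write_plink",
    "read_plink",
    "write_pedigree_csv",
    "write_phenotypes_tsv",
    "simulate_dataset",
]

ARCHITECTURES = ("polygenic", "sparse", "mixture")

# BayesR-style relative variances for the mixture architecture: zero, very
# small, small, moderate. Mixing proportions put most mass on small effects.
MIXTURE_VARIANCES = (0.0, 1e-4, 1e-3, 1e-2)
MIXTURE_PROPORTIONS = (0.05, 0.50, 0.30, 0.15)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults emulate the commercial crossbred cohort the pipeline targets:
    three discrete generations reaching ~1,500 individuals in the final
    (fully genotyped) cohort, a 50 K-scale marker panel on 18 autosomes,
    trait heritability in the mid-heritability range (0.39-0.52), and four
    categorical fixed effects (sex, farm, birth year-month, slaughter lot)
    contaminating the raw phenotype.
    """

    n_founders: int = 450
    n_generations: int = 3
    offspring_per_mating: int = 3
    n_markers: int = 50_000
    indel_fraction: float = 0.0
    founder_maf_law: tuple[float, float] = (0.05, 0.5)  # uniform bounds
    n_chromosomes: int = 18
    morgans_per_chromosome: float = 1.0
    architecture: str = "polygenic"
    n_qtl: int | None = None  # default: min(1000, n_markers)
    target_h2: float = 0.5
    fixed_effect_spec: tuple[tuple[str, int, float], ...] = (
        ("sex", 2, 0.5),
        ("farm", 3, 0.3),
        ("birth_ym", 12, 0.3),
        ("slaughter_lot", 20, 0.3),
    )
    genotyped_fraction_last_gen: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigError("n_founders must be at least 2")
        for name in ("n_generations",):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("offspring_per_mating", "n_markers", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_qtl is not None:
            if self.n_qtl < 1:
                raise ConfigError("n_qtl must be positive")
            if self.n_qtl > self.n_markers:
                raise ConfigError("n_qtl cannot exceed n_markers")
        if not 0.0 < self.target_h2 < 1.0:
            raise ConfigError("target_h2 must lie strictly inside (0, 1)")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ConfigError("indel_fraction must lie in [0, 1]")
        if not 0.0 <= self.genotyped_fraction_last_gen <= 1.0:
            raise ConfigError("genotyped_fraction_last_gen must lie in [0, 1]")
        lo, hi = self.founder_maf_law
        if not (0.0 <= lo <= hi <= 0.5):
            raise ConfigError("founder_maf_law bounds must satisfy 0 <= lo <= hi <= 0.5")
        if self.morgans_per_chromosome < 0:
            raise ConfigError("morgans_per_chromosome must be non-negative")
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"architecture must be one of {ARCHITECTURES}")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    @property
    def qtl_count(self) -> int:
        """Effective QTL count (default: min(1000, n_markers))."""
        return self.n_qtl if self.n_qtl is not None else min(1_000, self.n_markers)


def desk_scale_config(**overrides) -> SimConfig:
    """A small configuration for quick end-to-end runs and examples."""
    base = SimConfig(
        n_founders=60,
        n_generations=3,
        offspring_per_mating=3,
        n_markers=2_000,
        n_qtl=100,
        n_chromosomes=5,
        fixed_effect_spec=(("sex", 2, 0.5), ("farm", 3, 0.3)),
    )
    return base.with_(**overrides) if overrides else base


@dataclass
class TrueGeneticValues:
    """Simulation ground truth for parameter-recovery tests."""

    ids: np.ndarray
    g_true: np.ndarray
    marker_effects: np.ndarray
    qtl_index: np.ndarray
    realized_var_g: float
    realized_var_e: float

    @property
    def realized_h2(self) -> float:
        return self.realized_var_g / (self.realized_var_g + self.realized_var_e)


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    # independent, reproducible streams per stage (crc32: stable across runs)
    ss = np.random.SeedSequence([cfg.seed, zlib.crc32(stream.encode())])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Random discrete-generation pedigree.

    Generation 0 holds ``n_founders`` unrelated founders. Each later
    generation is produced by randomly pairing the previous generation into
    disjoint matings (no selfing), each mating contributing
    ``offspring_per_mating`` offspring.
    """
    rng = _rng(cfg, "pedigree")
    ids = list(range(1, cfg.n_founders + 1))
    sire = [0] * cfg.n_founders
    dam = [0] * cfg.n_founders
    generation = [0] * cfg.n_founders
    prev = list(ids)
    next_id = cfg.n_founders + 1
    for gen in range(1, cfg.n_generations + 1):
        if len(prev) < 2:
            raise ConfigError("generation has fewer than 2 potential parents")
        order = rng.permutation(len(prev))
        n_pairs = len(prev) // 2
        for p in range(n_pairs):
            s = prev[order[2 * p]]
            d = prev[order[2 * p + 1]]
            for _ in range(cfg.offspring_per_mating):
                ids.append(next_id)
                sire.append(s)
                dam.append(d)
                generation.append(gen)
                next_id += 1
        prev = [i for i, g in zip(ids, generation) if g == gen]
    return Pedigree(
        ids=np.array(ids),
        sire=np.array(sire),
        dam=np.array(dam),
        generation=np.array(generation),
    )


# ---------------------------------------------------------------------------
# genotypes (gene dropping)
# ---------------------------------------------------------------------------

def _marker_map(cfg: SimConfig) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Marker metadata plus genetic positions (Morgans) and chromosome codes."""
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per_chrom[: cfg.n_markers % cfg.n_chromosomes] += 1
    chrom = np.repeat(np.arange(1, cfg.n_chromosomes + 1), per_chrom)
    gpos = np.concatenate(
        [
            np.linspace(0.0, cfg.morgans_per_chromosome, k, endpoint=False)
            + cfg.morgans_per_chromosome / (2 * max(k, 1))
            for k in per_chrom
        ]
    )
    bp = np.concatenate([np.arange(k) * 1000 + 1000 for k in per_chrom])
    markers = pd.DataFrame(
        {
            "chromosome": chrom.astype(str),
            "position": bp,
            "variant_class": "SNP",
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    return markers, gpos, chrom


def _meiosis(
    haplos: np.ndarray,
    gpos_by_chrom: list[np.ndarray],
    offsets: np.ndarray,
    length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a (2, m) pair of parental haplotypes (Haldane map)."""
    m = haplos.shape[1]
    gamete = np.empty(m, dtype=np.uint8)
    for c, gpos in enumerate(gpos_by_chrom):
        lo, hi = offsets[c], offsets[c + 1]
        start = rng.integers(0, 2)
        n_x = rng.poisson(length) if length > 0 else 0
        if n_x == 0:
            gamete[lo:hi] = haplos[start, lo:hi]
            continue
        xpos = np.sort(rng.uniform(0.0, length, size=n_x))
        # haplotype index flips at each crossover
        which = (start + np.searchsorted(xpos, gpos)) % 2
        seg = haplos[:, lo:hi]
        gamete[lo:hi] = seg[which, np.arange(hi - lo)]
    return gamete


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene-drop biallelic genotypes down the pedigree.

    Founder haplotype alleles are Bernoulli draws at per-marker frequencies
    from ``founder_maf_law``; descendants inherit recombinant gametes with
    crossovers Poisson(``morgans_per_chromosome``) per chromosome (Haldane,
    no interference). Markers are labelled INDEL with probability
    ``indel_fraction``; the label is purely a class annotation.
    """
    rng = _rng(cfg, "genotypes")
    markers, gpos, chrom = _marker_map(cfg)
    lo_f, hi_f = cfg.founder_maf_law
    freqs = rng.uniform(lo_f, hi_f, size=cfg.n_markers)
    if cfg.indel_fraction > 0:
        is_indel = rng.random(cfg.n_markers) < cfg.indel_fraction
        markers.loc[is_indel, "variant_class"] = "INDEL"

    n = len(ped)
    m = cfg.n_markers
    haplo = np.empty((n, 2, m), dtype=np.uint8)
    pos = ped.positions()
    offsets = np.concatenate([[0], np.cumsum(np.bincount(chrom - 1))])
    gpos_by_chrom = [gpos[offsets[c] : offsets[c + 1]] for c in range(cfg.n_chromosomes)]

    for row, (i, s, d) in enumerate(zip(ped.ids, ped.sire, ped.dam)):
        if s == 0 and d == 0:
            haplo[row] = (rng.random((2, m)) < freqs).astype(np.uint8)
        else:
            haplo[row, 0] = _meiosis(
                haplo[pos[int(s)]], gpos_by_chrom, offsets,
                cfg.morgans_per_chromosome, rng,
            )
            haplo[row, 1] = _meiosis(
                haplo[pos[int(d)]], gpos_by_chrom, offsets,
                cfg.morgans_per_chromosome, rng,
            )

    dosage = haplo.sum(axis=1).astype(float)
    return GenotypeMatrix(dosage=dosage, individual_ids=ped.ids.copy(), markers=markers)


# ---------------------------------------------------------------------------
# effects and phenotypes
# ---------------------------------------------------------------------------

def simulate_effects_and_phenotypes(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    trait: str = "trait",
) -> tuple[TrueGeneticValues, pd.DataFrame]:
    """Draw marker effects per architecture and build raw phenotypes.

    ``polygenic`` gives every marker a normal effect; ``sparse`` gives
    ``n_qtl`` randomly chosen markers normal effects; ``mixture`` assigns the
    chosen markers to a four-component scheme (zero / very small / small /
    moderate relative variance). Effects are rescaled so the realized
    additive variance is ``target_h2`` and the residual is orthogonalized and
    rescaled so in-sample heritability equals the target exactly (phenotypic
    variance 1 before fixed effects). Raw phenotype = fixed effects + g + e.

    Returns the ground truth and a phenotype table with columns
    ``id``, ``trait`` (raw value) and one column per fixed effect.
    """
    if geno.n_individuals == 0 or geno.n_markers == 0:
        raise ValueError("empty genotype matrix")
    rng = _rng(cfg, "effects:" + trait)
    m = geno.n_markers
    n = geno.n_individuals

    if cfg.architecture == "polygenic":
        qtl = np.arange(m)
        effects = np.zeros(m)
        effects[qtl] = rng.normal(size=m)
    elif cfg.architecture == "sparse":
        qtl = np.sort(rng.choice(m, size=min(cfg.qtl_count, m), replace=False))
        effects = np.zeros(m)
        effects[qtl] = rng.normal(size=len(qtl))
    else:  # mixture
        qtl = np.sort(rng.choice(m, size=min(cfg.qtl_count, m), replace=False))
        comp = rng.choice(4, size=len(qtl), p=MIXTURE_PROPORTIONS)
        sd = np.sqrt(np.array(MIXTURE_VARIANCES))[comp]
        effects = np.zeros(m)
        effects[qtl] = rng.normal(scale=np.where(sd > 0, sd, 1.0)) * (sd > 0)

    g = geno.dosage @ effects
    g = g - g.mean()
    var_g = float(np.var(g))
    if var_g <= 0:
        raise ValueError(
            "realized additive variance is zero (all QTL fixed or no effects); "
            "increase n_qtl or founder MAF"
        )
    # rescale so realized var(g) = target_h2 (phenotypic variance 1)
    scale = np.sqrt(cfg.target_h2 / var_g)
    effects *= scale
    g *= scale
    var_g = cfg.target_h2
    var_e = 1.0 - cfg.target_h2

    e = rng.normal(size=n)
    e -= e.mean()
    e -= g * (e @ g) / (g @ g)  # exact in-sample orthogonality to g
    e *= np.sqrt(var_e / np.var(e))

    pheno = pd.DataFrame({"id": geno.individual_ids})
    y = g + e
    for name, n_levels, effect_sd in cfg.fixed_effect_spec:
        levels = rng.integers(0, n_levels, size=n)
        values = rng.normal(scale=effect_sd, size=n_levels)
        pheno[name] = [f"{name}{k}" for k in levels]
        y = y + values[levels]
    pheno[trait] = y

    truth = TrueGeneticValues(
        ids=geno.individual_ids.copy(),
        g_true=g,
        marker_effects=effects,
        qtl_index=qtl,
        realized_var_g=var_g,
        realized_var_e=var_e,
    )
    return truth, pheno


def select_genotyped(ped: Pedigree, cfg: SimConfig) -> np.ndarray:
    """Ids of the genotyped cohort: a random fraction of the last generation."""
    if ped.generation is None:
        raise ValueError("pedigree lacks generation labels")
    last = ped.ids[ped.generation == ped.generation.max()]
    k = int(round(cfg.genotyped_fraction_last_gen * len(last)))
    rng = _rng(cfg, "genotyped")
    return np.sort(rng.choice(last, size=k, replace=False))


def inject_missingness(
    geno: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set a uniform random fraction of calls to missing (QC testing aid)."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("missingness rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dosage = geno.dosage.copy()
    mask = rng.random(dosage.shape) < rate
    dosage[mask] = np.nan
    return GenotypeMatrix(dosage, geno.individual_ids.copy(), geno.markers.copy())


# ---------------------------------------------------------------------------
# writers / readers (PLINK text dialect, pedigree CSV, phenotype TSV)
# ---------------------------------------------------------------------------

def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write whitespace-delimited .ped/.map files (alleles A/B, missing '0 0')."""
    prefix = Path(prefix)
    mk = geno.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(geno.n_markers):
            fh.write(
                f"{mk.chromosome.iloc[j]} m{j + 1} 0 {int(mk.position.iloc[j])}\n"
            )
    code = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(geno.individual_ids):
            row = geno.dosage[i]
            alleles = " ".join(
                "0 0" if np.isnan(d) else code[float(d)] for d in row
            )
            fh.write(f"FAM {iid} 0 0 0 -9 {alleles}\n")


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read the .ped/.map dialect written by :func:`write_plink`.

    Dosage counts the 'B' allele; '0 0' becomes missing. Variant class is
    inferred from allele length (multi-base = INDEL), so round-trips of
    A/B-coded files come back as SNPs.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        names=["chromosome", "marker", "cm", "position"],
        dtype={"chromosome": str},
    )
    ids = []
    rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            ids.append(int(parts[1]) if parts[1].isdigit() else parts[1])
            al = parts[6:]
            a = np.array(al[0::2])
            b = np.array(al[1::2])
            missing = (a == "0") | (b == "0")
            dose = (a == "B").astype(float) + (b == "B").astype(float)
            dose[missing] = np.nan
            rows.append(dose)
    markers = pd.DataFrame(
        {
            "chromosome": mp.chromosome.astype(str),
            "position": mp.position,
            "variant_class": "SNP",
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    return GenotypeMatrix(np.array(rows), np.array(ids), markers)


def write_pedigree_csv(ped: Pedigree, path: str | Path) -> None:
    ped.to_frame().to_csv(path, index=False)


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def simulate_dataset(cfg: SimConfig, trait: str = "trait"):
    """Convenience wrapper: pedigree, genotypes, truth, phenotypes in one call."""
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    truth, pheno = simulate_effects_and_phenotypes(geno, cfg, trait=trait)
    return ped, geno, truth, pheno
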