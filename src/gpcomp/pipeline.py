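"""End-to-end experiment orchestration.

Stages mirror the analysis order: simulate a population, quality-control the
markers, correct phenotypes for fixed effects, build variant-class/density
panels, estimate heritability by REML, then run the model x trait x fold x
panel cross-validation grid. Every stage writes its artefacts into the
output directory together with a YAML snapshot of the fully-resolved
configuration, from which any run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import panels as panels_mod
from .bayes import McmcConfig
from .containers import ConfigError
from .evaluation import ALL_MODELS, CvResult, run_experiment_grid
from .phenotypes import correct_phenotypes, corrected_name
from .relationships import compute_G
from .reml import estimate_reml
from .simulate import (
    SimConfig,
    select_genotyped,
    simulate_effects_and_phenotypes,
    simulate_genotypes,
    simulate_pedigree,
    write_pedigree_csv,
    write_phenotypes_tsv,
    write_plink,
)

logger = logging.getLogger("gpcomp")

__all__ = ["ExperimentConfig", "run_pipeline", "desk_scale_experiment"]


@dataclass
class ExperimentConfig:
    simulation: SimConfig = field(default_factory=SimConfig)
    traits: dict[str, float] = field(default_factory=lambda: {"trait": 0.5})
    qc: dict = field(
        default_factory=lambda: {
            "ind_call_rate_min": 0.9,
            "marker_call_rate_min": 0.9,
            "maf_min": 0.05,
            "autosomes_only": True,
        }
    )
    variant_classes: tuple[str, ...] = ("BOTH",)
    densities: tuple[int, ...] = ()  # empty: no thinning, one full panel
    models: tuple[str, ...] = ("GBLUP",)
    fold_counts: tuple[int, ...] = (5,)
    n_rounds: int = 5
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    k_mode: str = "per-fold"
    master_seed: int = 0
    out_dir: str = "gpcomp_results"

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ConfigError(f"unknown models: {sorted(unknown)}")
        for f in self.fold_counts:
            if not 2 <= f <= 10:
                raise ConfigError("fold counts must lie in [2, 10]")
        for h2 in self.traits.values():
            if not 0 < h2 < 1:
                raise ConfigError("trait h2 must lie in (0, 1)")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["fixed_effect_spec"] = [
            list(t) for t in self.simulation.fixed_effect_spec
        ]
        d["simulation"]["founder_maf_law"] = list(self.simulation.founder_maf_law)
        return json.loads(json.dumps(d))  # plain types only

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if "fixed_effect_spec" in sim:
            sim["fixed_effect_spec"] = tuple(
                (n, int(k), float(s)) for n, k, s in sim["fixed_effect_spec"]
            )
        if "founder_maf_law" in sim:
            sim["founder_maf_law"] = tuple(sim["founder_maf_law"])
        mcmc = d.pop("mcmc", {})
        for key in ("variant_classes", "densities", "models", "fold_counts"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(simulation=SimConfig(**sim), mcmc=McmcConfig(**mcmc), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def desk_scale_experiment(**overrides) -> ExperimentConfig:
    """Small full-pipeline preset: every model, scaled-down densities/MCMC."""
    cfg = ExperimentConfig(
        simulation=SimConfig(
            n_founders=60,
            n_generations=2,
            offspring_per_mating=3,
            n_markers=800,
            n_chromosomes=5,
            indel_fraction=0.3,
            fixed_effect_spec=(("sex", 2, 0.5), ("farm", 3, 0.3)),
        ),
        traits={"trait": 0.5},
        variant_classes=("BOTH",),
        densities=(200, 600),
        models=("GBLUP",),
        fold_counts=(5,),
        n_rounds=1,
        mcmc=McmcConfig(n_iter=1500, burn_in=300),
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def run_pipeline(cfg: ExperimentConfig) -> Path:
    """Execute the full pipeline; returns the results directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    try:
        cfg.write_yaml(out / "config_snapshot.yaml")

        # -- simulate ------------------------------------------------------
        logger.info("simulating population (%d markers)", cfg.simulation.n_markers)
        sim = cfg.simulation.with_(seed=cfg.master_seed)
        ped = simulate_pedigree(sim)
        geno_all = simulate_genotypes(ped, sim)
        genotyped = select_genotyped(ped, sim)
        pheno = None
        for trait, h2 in cfg.traits.items():
            _, pt = simulate_effects_and_phenotypes(
                geno_all, sim.with_(target_h2=h2), trait=trait
            )
            pheno = pt if pheno is None else pheno.merge(
                pt[["id", trait]], on="id", how="left"
            )
        write_pedigree_csv(ped, out / "pedigree.csv")
        write_phenotypes_tsv(pheno, out / "phenotypes_raw.tsv")

        pos = {int(i): k for k, i in enumerate(geno_all.individual_ids)}
        geno = geno_all.subset_individuals(np.array([pos[int(i)] for i in genotyped]))
        write_plink(geno, out / "genotypes")

        # -- QC ------------------------------------------------------------
        logger.info("quality control")
        geno_qc, report = panels_mod.quality_control(geno, **cfg.qc)
        report.write_tsv(out / "qc_report.tsv")

        # -- phenotype correction -------------------------------------------
        fe_names = [n for n, _, _ in sim.fixed_effect_spec]
        logger.info("correcting phenotypes for %s", fe_names)
        pheno_c = correct_phenotypes(pheno, fe_names, traits=list(cfg.traits))
        write_phenotypes_tsv(pheno_c, out / "phenotypes_corrected.tsv")
        y_table = pheno_c.set_index("id")[
            [corrected_name(t) for t in cfg.traits]
        ].rename(columns={corrected_name(t): t for t in cfg.traits})

        # -- panels ----------------------------------------------------------
        panel_set: dict[str, "panels_mod.GenotypeMatrix"] = {}
        for vc in cfg.variant_classes:
            base = panels_mod.partition_by_class(geno_qc, vc)
            if cfg.densities:
                for d in cfg.densities:
                    panel_set[f"{vc}_{d}"] = panels_mod.thin_markers(
                        base, d, seed=cfg.master_seed + d
                    )
            else:
                panel_set[vc] = base
        logger.info("panels: %s", {k: v.n_markers for k, v in panel_set.items()})

        # -- REML heritability ----------------------------------------------
        logger.info("REML variance components")
        # raw G: REML needs only a PSD kinship, and blending biases h2 up
        Gb = compute_G(geno_qc)
        rows = []
        for trait in cfg.traits:
            y = y_table[trait].dropna()
            idx = [
                k
                for k, i in enumerate(Gb.ids)
                if int(i) in set(int(j) for j in y.index)
            ]
            ids = Gb.ids[idx]
            vc = estimate_reml(
                y.loc[ids].to_numpy(float), Gb.values[np.ix_(idx, idx)]
            )
            rows.append(vc.to_frame(trait).iloc[0])
        pd.DataFrame(rows).to_csv(out / "heritability.tsv", sep="\t", index=False)

        # -- prediction grid --------------------------------------------------
        logger.info(
            "grid: %d models x %d traits x %d fold-counts x %d panels",
            len(cfg.models), len(cfg.traits), len(cfg.fold_counts), len(panel_set),
        )
        result: CvResult = run_experiment_grid(
            y_table,
            panel_set,
            models=cfg.models,
            traits=list(cfg.traits),
            fold_counts=cfg.fold_counts,
            n_rounds=cfg.n_rounds,
            master_seed=cfg.master_seed,
            ped=ped,
            mcmc=cfg.mcmc,
            k_mode=cfg.k_mode,
        )
        result.write_tsv(out / "cv_results.tsv")
        result.summary().to_csv(out / "cv_summary.tsv", sep="\t", index=False)
        logger.info("done")
        return out
    finally:
        logger.removeHandler(fh)
        fh.close()
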