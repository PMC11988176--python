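"""Cross-validated prediction accuracy and dispersion bias.

Individuals are randomly and equally partitioned into n folds (re-randomized
each round); each fold serves as the validation set once per round, the
remaining n-1 folds train the model. Accuracy is the Pearson correlation
between GEBV and corrected phenotype in the validation set; bias is the OLS
slope of corrected phenotype on GEBV (1 = no over/under-dispersion). The
default plan (5 folds x 5 rounds = 25 validation fits) matches common
practice for this design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bayes import McmcConfig, gebv_from_effects, run_mcmc
from .blup import MixedModelSpec, solve_gblup, solve_ssgblup
from .containers import GenotypeMatrix, Pedigree, PredictionResult, RelationshipMatrix
from .relationships import (
    assemble_H_inverse,
    blend_G,
    compute_A,
    compute_A22,
    compute_A_inverse,
    compute_G,
    invert_psd,
)
from .reml import estimate_reml

__all__ = [
    "CvPlan",
    "CvResult",
    "make_folds",
    "accuracy",
    "bias",
    "cross_validate",
    "make_model_runner",
    "run_experiment_grid",
    "BLUP_MODELS",
    "BAYES_MODELS",
    "ALL_MODELS",
]

BLUP_MODELS = ("GBLUP", "ssGBLUP")
BAYES_MODELS = ("BayesA", "BayesB", "BayesC", "BL", "BayesR")
ALL_MODELS = BLUP_MODELS + BAYES_MODELS


@dataclass(frozen=True)
class CvPlan:
    n_folds: int = 5
    n_rounds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_folds:
            raise ValueError("n_folds must be at least 2")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be positive")


def make_folds(ids: Sequence, plan: CvPlan) -> np.ndarray:
    """(n_rounds, n_ids) fold labels; equal sizes up to a remainder of one."""
    ids = np.asarray(ids)
    n = len(ids)
    if plan.n_folds > n:
        raise ValueError("more folds than individuals")
    rng = np.random.default_rng(plan.seed)
    out = np.empty((plan.n_rounds, n), dtype=int)
    for r in range(plan.n_rounds):
        perm = rng.permutation(n)
        labels = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, plan.n_folds)):
            labels[chunk] = f
        out[r] = labels
    return out


def accuracy(gebv: np.ndarray, y_c: np.ndarray) -> float:
    """Pearson correlation of GEBV with corrected phenotype (NaN if undefined)."""
    gebv = np.asarray(gebv, float)
    y_c = np.asarray(y_c, float)
    if len(gebv) < 3:
        raise ValueError("need at least 3 validation individuals")
    if np.std(gebv) == 0 or np.std(y_c) == 0:
        warnings.warn("constant vector: accuracy undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(gebv, y_c)[0, 1])


def bias(gebv: np.ndarray, y_c: np.ndarray) -> float:
    """OLS slope of y_c on GEBV; 1 means no dispersion bias (NaN if undefined)."""
    gebv = np.asarray(gebv, float)
    y_c = np.asarray(y_c, float)
    vg = np.var(gebv)
    if vg == 0:
        warnings.warn("zero-variance GEBV: bias undefined", stacklevel=2)
        return float("nan")
    return float(np.cov(y_c, gebv, ddof=0)[0, 1] / vg)


@dataclass
class CvResult:
    """Long-format per-fit records plus aggregation helpers."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        keys = [
            c
            for c in ("model", "trait", "n_folds", "panel")
            if c in self.records.columns
        ]
        return (
            self.records.groupby(keys, dropna=False)[["accuracy", "bias"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def write_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model runners: train ids -> GEBVs for everyone the model covers
# ---------------------------------------------------------------------------

Runner = Callable[[np.ndarray, int], PredictionResult]


def make_model_runner(
    model: str,
    geno: GenotypeMatrix,
    y: pd.Series,
    ped: Pedigree | None = None,
    mcmc: McmcConfig | None = None,
    k_mode: str = "per-fold",
    blend_eps: float = 0.05,
    k_global: float | None = None,
) -> Runner:
    """Build a ``runner(train_ids, seed) -> PredictionResult`` for one model.

    ``y`` is a corrected-phenotype Series indexed by individual id and must
    cover every individual a fold may place in training. GBLUP and the
    Bayesian models operate on the genotyped individuals in ``geno``;
    ssGBLUP additionally needs the pedigree and predicts every pedigree
    member, so ungenotyped phenotyped relatives can contribute.

    ``k_mode`` controls the variance ratio for the BLUP models: "per-fold"
    re-estimates it by REML on each training set (no leakage), "global" uses
    one REML fit on all phenotyped individuals (or ``k_global`` if given).
    """
    if model in ("GBLUP",) + BAYES_MODELS:
        if model == "GBLUP":
            G = compute_G(geno)
            if ped is not None:
                A22 = compute_A22(ped, geno.individual_ids)
                Gb = blend_G(G, A22, blend_eps)
            else:
                Gb = blend_G(G, None, blend_eps)
            Ginv = invert_psd(Gb)
            pos = {int(i): j for j, i in enumerate(Gb.ids)}

            def k_for(train_ids: np.ndarray) -> float:
                if k_mode == "global":
                    if k_global is not None:
                        return k_global
                    idx = np.array([pos[int(i)] for i in y.index])
                    vc = estimate_reml(y.to_numpy(float), Gb.values[np.ix_(idx, idx)])
                    return vc.k_ratio
                idx = np.array([pos[int(i)] for i in train_ids])
                vc = estimate_reml(
                    y.loc[train_ids].to_numpy(float), Gb.values[np.ix_(idx, idx)]
                )
                return vc.k_ratio

            def runner(train_ids: np.ndarray, seed: int) -> PredictionResult:
                spec = MixedModelSpec(
                    y=y.loc[train_ids].to_numpy(float),
                    record_ids=np.asarray(train_ids),
                    k=k_for(np.asarray(train_ids)),
                    K_inv=Ginv,
                )
                res = solve_gblup(spec)
                res.model = "GBLUP"
                return res

            return runner

        cfg = mcmc or McmcConfig(model=model)
        if cfg.model != model:
            cfg = McmcConfig(**{**cfg.__dict__, "model": model})
        pos = {int(i): j for j, i in enumerate(geno.individual_ids)}

        def bayes_runner(train_ids: np.ndarray, seed: int) -> PredictionResult:
            idx = np.array([pos[int(i)] for i in train_ids])
            sub = geno.subset_individuals(idx)
            run_cfg = McmcConfig(**{**cfg.__dict__, "seed": seed})
            summary = run_mcmc(sub, y.loc[train_ids].to_numpy(float), run_cfg)
            return gebv_from_effects(geno, summary)

        return bayes_runner

    if model == "ssGBLUP":
        if ped is None:
            raise ValueError("ssGBLUP requires a pedigree")
        A = compute_A(ped)
        Ainv = compute_A_inverse(ped)
        A22 = compute_A22(ped, geno.individual_ids, A=A)
        G = blend_G(compute_G(geno), A22, blend_eps)
        Hinv = assemble_H_inverse(Ainv, invert_psd(A22), invert_psd(G))
        H = np.linalg.inv(Hinv.values)
        pos = {int(i): j for j, i in enumerate(Hinv.ids)}

        def k_for_ss(train_ids: np.ndarray) -> float:
            if k_mode == "global":
                if k_global is not None:
                    return k_global
                train_ids = np.asarray(y.index)
            idx = np.array([pos[int(i)] for i in train_ids])
            vc = estimate_reml(y.loc[train_ids].to_numpy(float), H[np.ix_(idx, idx)])
            return vc.k_ratio

        def ss_runner(train_ids: np.ndarray, seed: int) -> PredictionResult:
            spec = MixedModelSpec(
                y=y.loc[train_ids].to_numpy(float),
                record_ids=np.asarray(train_ids),
                k=k_for_ss(np.asarray(train_ids)),
                K_inv=Hinv,
            )
            return solve_ssgblup(spec)

        return ss_runner

    raise ValueError(f"unknown model {model!r}; expected one of {ALL_MODELS}")


def cross_validate(
    y: pd.Series,
    eval_ids: Sequence,
    runner: Runner,
    plan: CvPlan,
    extra_train_ids: Sequence | None = None,
    model: str = "",
    trait: str = "trait",
    panel: str = "",
) -> CvResult:
    """Rounds x folds cross-validation of one model on one trait.

    ``eval_ids`` are partitioned into folds; ``extra_train_ids`` (e.g.
    ungenotyped phenotyped relatives for ssGBLUP) are appended to every
    training set and never validated on.
    """
    eval_ids = np.asarray(eval_ids)
    extra = np.asarray(extra_train_ids) if extra_train_ids is not None else None
    folds = make_folds(eval_ids, plan)
    rows = []
    for r in range(plan.n_rounds):
        for f in range(plan.n_folds):
            val_mask = folds[r] == f
            val_ids = eval_ids[val_mask]
            train_ids = eval_ids[~val_mask]
            assert len(np.intersect1d(val_ids, train_ids)) == 0
            if extra is not None:
                train_ids = np.concatenate([train_ids, extra])
            seed = int(
                np.random.SeedSequence([plan.seed, r, f]).generate_state(1)[0]
                % (2**31)
            )
            pred = runner(train_ids, seed)
            gebv = pred.gebv_for(val_ids)
            yv = y.loc[val_ids].to_numpy(float)
            rows.append(
                {
                    "model": model or pred.model,
                    "trait": trait,
                    "panel": panel,
                    "n_folds": plan.n_folds,
                    "round": r,
                    "fold": f,
                    "n_validation": len(val_ids),
                    "accuracy": accuracy(gebv, yv),
                    "bias": bias(gebv, yv),
                }
            )
    return CvResult(pd.DataFrame(rows))


def run_experiment_grid(
    y_table: pd.DataFrame,
    panels: dict[str, GenotypeMatrix],
    models: Sequence[str],
    traits: Sequence[str],
    fold_counts: Sequence[int],
    n_rounds: int = 5,
    master_seed: int = 0,
    ped: Pedigree | None = None,
    mcmc: McmcConfig | None = None,
    k_mode: str = "per-fold",
) -> CvResult:
    """Full factorial grid: models x traits x fold counts x marker panels.

    ``y_table`` holds corrected phenotypes (column per trait) indexed by
    individual id. Per-cell seeds are derived reproducibly from
    ``master_seed``; failed cells are recorded (error column) and the grid
    continues.
    """
    cells = list(product(models, traits, fold_counts, panels.items()))
    frames = []
    for cell_idx, (model, trait, n_folds, (panel_name, geno)) in enumerate(cells):
        cell_seed = int(
            np.random.SeedSequence([master_seed, cell_idx]).generate_state(1)[0]
            % (2**31)
        )
        y = y_table[trait].dropna()
        genotyped = np.asarray(
            [i for i in geno.individual_ids if i in set(y.index)]
        )
        extra = None
        if model == "ssGBLUP" and ped is not None:
            extra = np.asarray(
                [i for i in y.index if i not in set(geno.individual_ids)]
            )
            if len(extra) == 0:
                extra = None
        try:
            runner = make_model_runner(
                model, geno, y, ped=ped, mcmc=mcmc, k_mode=k_mode
            )
            res = cross_validate(
                y,
                genotyped,
                runner,
                CvPlan(n_folds=n_folds, n_rounds=n_rounds, seed=cell_seed),
                extra_train_ids=extra,
                model=model,
                trait=trait,
                panel=panel_name,
            )
            frames.append(res.records)
        except Exception as exc:  # noqa: BLE001 - grid robustness by contract
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "model": model,
                            "trait": trait,
                            "panel": panel_name,
                            "n_folds": n_folds,
                            "error": f"{type(exc).__name__}: {exc}",
                        }
                    ]
                )
            )
    return CvResult(pd.concat(frames, ignore_index=True))
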