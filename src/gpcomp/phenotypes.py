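"""Fixed-effect correction of raw phenotypes.

Raw records are adjusted for categorical fixed effects (sex, farm, birth
batch, slaughter lot...) by ordinary least squares with reference-level dummy
coding. The corrected phenotype is the OLS residual plus the estimated
intercept, so it stays on the grand-mean scale and the overall mean mu in
downstream mixed models remains meaningful.

By default the correction is fitted once on the full dataset (two-stage
scheme: correction precedes cross-validation). Fitting on a training subset
and applying to held-out records is supported via ``fit_index`` for
leakage-free experiments; unseen factor levels in the held-out part raise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = ["correct_phenotypes", "corrected_name", "RankDeficientDesignError"]


class RankDeficientDesignError(ValueError):
    """The fixed-effect design is confounded (aliased columns listed)."""


def corrected_name(trait: str) -> str:
    return f"{trait}_c"


def _design(pheno: pd.DataFrame, fixed_effects: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded dummies; returns matrix and column names."""
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for fe in fixed_effects:
        levels = sorted(pd.unique(pheno[fe].astype(str)))
        for lv in levels[1:]:  # first level is the reference
            cols.append((pheno[fe].astype(str) == lv).to_numpy(float))
            names.append(f"{fe}[{lv}]")
    return np.column_stack(cols), names


def correct_phenotypes(
    pheno: pd.DataFrame,
    fixed_effects: list[str],
    traits: list[str] | None = None,
    fit_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """Return a copy of ``pheno`` with a ``<trait>_c`` column per trait.

    Parameters
    ----------
    pheno
        Table with an ``id`` column, trait columns, and categorical
        fixed-effect columns.
    fixed_effects
        Names of the fixed-effect columns to adjust for. Empty list means
        the corrected phenotype equals the raw one.
    traits
        Trait columns to correct; default: every numeric column that is not
        ``id`` or a fixed effect.
    fit_index
        Optional boolean/positional index of records used to *estimate* the
        effects; the correction is then applied to all records. Records with
        factor levels absent from the fitting subset raise ``ValueError``.
    """
    if traits is None:
        traits = [
            c
            for c in pheno.columns
            if c not in fixed_effects
            and c != "id"
            and pd.api.types.is_numeric_dtype(pheno[c])
        ]
    out = pheno.copy()
    if not fixed_effects:
        for t in traits:
            out[corrected_name(t)] = out[t].astype(float)
        return out

    for fe in fixed_effects:
        if pheno[fe].isna().any():
            raise ValueError(f"fixed effect {fe!r} has missing levels")

    fit = pheno if fit_index is None else pheno.iloc[np.asarray(fit_index)]
    if len(fit) < 2:
        raise ValueError("need at least 2 records to fit the correction")
    if fit_index is not None:
        for fe in fixed_effects:
            unseen = set(pheno[fe].astype(str)) - set(fit[fe].astype(str))
            if unseen:
                raise ValueError(
                    f"levels {sorted(unseen)} of {fe!r} absent from fitting subset"
                )

    Xfit, names = _design(fit, fixed_effects)
    # pivoted QR exposes aliased (linearly dependent) columns by name
    _, R, piv = scipy.linalg.qr(Xfit, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xfit.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < Xfit.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise RankDeficientDesignError(
            f"confounded fixed-effect design; aliased columns: {aliased}"
        )

    Xall, _ = _design(pheno, fixed_effects)
    for t in traits:
        yfit = fit[t].to_numpy(float)
        beta, *_ = np.linalg.lstsq(Xfit, yfit, rcond=None)
        resid = pheno[t].to_numpy(float) - Xall @ beta
        # grand mean (not the reference-level coefficient): keeps y_c on the
        # raw scale and makes the correction invariant to level relabelling
        out[corrected_name(t)] = resid + yfit.mean()
    return out
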