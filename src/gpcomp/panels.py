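"""Marker quality control, variant-class partition and density thinning.

QC mirrors standard chip-data preparation: individuals with low call rate are
dropped first, then markers by call rate, minor allele frequency and
chromosome, all with strict (">") thresholds. MAF is computed from observed
calls only; QC never imputes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EmptyPanelError, GenotypeMatrix

__all__ = [
    "QCReport",
    "quality_control",
    "partition_by_class",
    "thin_markers",
    "DENSITY_TIERS",
]

# Density presets named after the usual chip/WGS panel sizes; the desk-scale
# column is a proportional shrink for quick synthetic runs.
DENSITY_TIERS = {
    "low": [1_000, 3_000, 7_000],
    "medium": [10_000, 30_000, 100_000],
    "high": [500_000, 1_000_000],
}
DESK_SCALE_DENSITIES = [100, 300, 700, 1_000, 3_000, 10_000, 50_000]


@dataclass
class QCReport:
    n_individuals_in: int
    n_markers_in: int
    n_individuals_removed: int
    n_markers_removed_call_rate: int
    n_markers_removed_maf: int
    n_markers_removed_non_autosomal: int
    n_individuals_retained: int
    n_markers_retained: int

    def __post_init__(self) -> None:
        assert (
            self.n_individuals_removed + self.n_individuals_retained
            == self.n_individuals_in
        )
        removed = (
            self.n_markers_removed_call_rate
            + self.n_markers_removed_maf
            + self.n_markers_removed_non_autosomal
        )
        assert removed + self.n_markers_retained == self.n_markers_in

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _is_autosomal(chrom: pd.Series) -> np.ndarray:
    """Numeric chromosome labels are autosomes; X/Y/MT/etc. are not."""
    return chrom.astype(str).str.fullmatch(r"\d+").to_numpy()


def quality_control(
    geno: GenotypeMatrix,
    ind_call_rate_min: float = 0.9,
    marker_call_rate_min: float = 0.9,
    maf_min: float = 0.05,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter individuals, then markers, with strict thresholds.

    Order: (1) individuals with call rate <= ``ind_call_rate_min`` are
    removed; (2) on the retained individuals, markers are removed when their
    call rate is <= ``marker_call_rate_min``, when MAF (from observed calls)
    is <= ``maf_min``, or when non-autosomal (if ``autosomes_only``). A
    marker failing several rules is counted against the first in that order.
    """
    if geno.n_individuals == 0 or geno.n_markers == 0:
        raise EmptyPanelError("empty genotype matrix")
    obs = ~np.isnan(geno.dosage)
    ind_cr = obs.mean(axis=1)
    keep_ind = ind_cr > ind_call_rate_min
    sub = geno.subset_individuals(np.flatnonzero(keep_ind))
    if sub.n_individuals == 0:
        raise EmptyPanelError("all individuals removed by call-rate filter")

    obs = ~np.isnan(sub.dosage)
    marker_cr = obs.mean(axis=0)
    fail_cr = ~(marker_cr > marker_call_rate_min)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(sub.dosage, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    fail_maf = ~(maf > maf_min) & ~fail_cr
    if autosomes_only:
        fail_auto = ~_is_autosomal(sub.markers["chromosome"]) & ~fail_cr & ~fail_maf
    else:
        fail_auto = np.zeros(sub.n_markers, dtype=bool)
    keep_mk = ~(fail_cr | fail_maf | fail_auto)
    if not keep_mk.any():
        raise EmptyPanelError("quality control removed every marker")

    out = sub.subset_markers(np.flatnonzero(keep_mk))
    report = QCReport(
        n_individuals_in=geno.n_individuals,
        n_markers_in=geno.n_markers,
        n_individuals_removed=int((~keep_ind).sum()),
        n_markers_removed_call_rate=int(fail_cr.sum()),
        n_markers_removed_maf=int(fail_maf.sum()),
        n_markers_removed_non_autosomal=int(fail_auto.sum()),
        n_individuals_retained=out.n_individuals,
        n_markers_retained=out.n_markers,
    )
    return out, report


def partition_by_class(geno: GenotypeMatrix, which: str) -> GenotypeMatrix:
    """Subset markers by variant class: "SNP", "INDEL" or "BOTH" (identity)."""
    which = which.upper()
    if which == "BOTH":
        return geno.subset_markers(np.arange(geno.n_markers))
    if which not in ("SNP", "INDEL"):
        raise ValueError("which must be 'SNP', 'INDEL' or 'BOTH'")
    idx = np.flatnonzero(geno.markers["variant_class"].to_numpy() == which)
    if len(idx) == 0:
        raise EmptyPanelError(f"no markers of class {which} present")
    return geno.subset_markers(idx)


def thin_markers(geno: GenotypeMatrix, target_count: int, seed: int) -> GenotypeMatrix:
    """Uniform random marker subset of size min(target, m), genome order kept."""
    if target_count < 1:
        raise ValueError("target_count must be at least 1")
    k = min(target_count, geno.n_markers)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(geno.n_markers, size=k, replace=False))
    return geno.subset_markers(idx)
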