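"""Core in-memory containers shared across the pipeline.

Genotypes are held as an additive dosage matrix (individuals x markers,
values 0/1/2 with NaN for missing) plus per-marker metadata; pedigrees as
dense-coded parent links (0 = unknown); relationship structures as labelled
symmetric matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "RelationshipMatrix",
    "PredictionResult",
    "EmptyPanelError",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid configuration (bad counts, proportions outside their range...)."""


class EmptyPanelError(ValueError):
    """A filtering or partition step left no markers (or no individuals)."""


MARKER_COLUMNS = ["chromosome", "position", "variant_class", "allele_a", "allele_b"]


@dataclass
class GenotypeMatrix:
    """Additive genotype dosages with marker metadata.

    Parameters
    ----------
    dosage
        ``(n_individuals, n_markers)`` float array with values in {0, 1, 2}
        and ``NaN`` for missing calls (AA=0, AB=1, BB=2).
    individual_ids
        Integer ids, one per dosage row.
    markers
        Per-marker table with columns ``chromosome`` (label), ``position``
        (bp), ``variant_class`` ("SNP" or "INDEL"), ``allele_a``, ``allele_b``.
    """

    dosage: np.ndarray
    individual_ids: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x markers)")
        if self.dosage.shape[0] != len(self.individual_ids):
            raise ValueError("row count does not match individual_ids")
        if self.dosage.shape[1] != len(self.markers):
            raise ValueError("column count does not match marker table")
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker table lacks columns: {missing}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a marker subset (order given by ``index``)."""
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            individual_ids=self.individual_ids.copy(),
            markers=self.markers.iloc[index].reset_index(drop=True),
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[index, :],
            individual_ids=self.individual_ids[index],
            markers=self.markers.copy(),
        )

    def allele_frequencies(self) -> np.ndarray:
        """Counted-allele (allele_b) frequency per marker from observed calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0


@dataclass
class Pedigree:
    """Parents-first pedigree with dense integer ids (0 = unknown parent)."""

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(self.sire) != n or len(self.dam) != n:
            raise ValueError("ids/sire/dam must have equal length")
        seen: set[int] = set()
        for i, s, d in zip(self.ids, self.sire, self.dam):
            if i in seen:
                raise ValueError(f"duplicate id {i}")
            for p in (s, d):
                if p != 0 and p not in seen:
                    raise ValueError(
                        f"parent {p} of {i} not declared before its offspring"
                    )
            if s != 0 and s == d:
                raise ValueError(f"individual {i} has identical sire and dam")
            seen.add(int(i))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == 0) & (self.dam == 0)))

    def positions(self) -> dict[int, int]:
        """Map id -> row position."""
        return {int(i): k for k, i in enumerate(self.ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sire": self.sire, "dam": self.dam})


@dataclass
class RelationshipMatrix:
    """Symmetric relationship structure (G, A, A22 or an assembled H-inverse)."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # "G" | "A" | "A22" | "Ainv" | "Hinv" | "Ginv"
    freqs: np.ndarray | None = None  # centering frequencies (G only)
    denominator: float | None = None  # 2*sum p(1-p) (G only)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PredictionResult:
    """Per-individual GEBVs with optional marker effects and provenance."""

    ids: np.ndarray
    gebv: np.ndarray
    model: str
    fixed_effects: np.ndarray | None = None
    marker_effects: np.ndarray | None = None
    fold: int | None = None
    round: int | None = None
    extras: dict = field(default_factory=dict)

    def gebv_for(self, ids: Sequence[int]) -> np.ndarray:
        """GEBVs for ``ids`` in the requested order."""
        pos = {int(i): k for k, i in enumerate(self.ids)}
        try:
            idx = [pos[int(i)] for i in ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"no GEBV for individual {exc.args[0]}") from exc
        return self.gebv[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "model": self.model, "gebv": self.gebv})
        if self.fold is not None:
            df["fold"] = self.fold
        if self.round is not None:
            df["round"] = self.round
        return df
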