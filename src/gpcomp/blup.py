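"""GBLUP / ssGBLUP mixed-model-equation solvers and a SNP-BLUP oracle.

The model is y = X b + Z g + e with g ~ N(0, K sigma_g2), e ~ N(0, I
sigma_e2) and variance ratio k = sigma_e2 / sigma_g2. The mixed model
equations

    [ X'X      X'Z        ] [b]   [X'y]
    [ Z'X      Z'Z + k K^-1] [g] = [Z'y]

are solved by direct dense factorization; the contract is the residual norm
of the solved system, not the factorization. For ssGBLUP the kinship inverse
is the assembled single-step H^-1, so GEBVs exist for every pedigree
individual, genotyped or not. SNP-BLUP is the equivalent ridge regression on
centred marker dosages and serves as an independent oracle for GBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix, PredictionResult, RelationshipMatrix
from .relationships import invert_psd

__all__ = ["MixedModelSpec", "solve_gblup", "solve_ssgblup", "solve_snp_blup"]


@dataclass
class MixedModelSpec:
    """One mixed-model instance: phenotypes, design, kinship and k ratio."""

    y: np.ndarray
    record_ids: np.ndarray  # individual id per phenotype record
    k: float  # sigma_e2 / sigma_g2
    K: RelationshipMatrix | None = None
    K_inv: RelationshipMatrix | None = None
    X: np.ndarray | None = None  # default: intercept only

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.record_ids = np.asarray(self.record_ids)
        if len(self.y) != len(self.record_ids):
            raise ValueError("y and record_ids lengths differ")
        if self.k <= 0:
            raise ValueError("variance ratio k must be positive")
        if (self.K is None) == (self.K_inv is None):
            raise ValueError("provide exactly one of K or K_inv")
        if self.X is None:
            self.X = np.ones((len(self.y), 1))
        elif self.X.shape[0] != len(self.y):
            raise ValueError("X row count does not match y")

    @property
    def kinship_ids(self) -> np.ndarray:
        return (self.K if self.K is not None else self.K_inv).ids

    def incidence(self) -> np.ndarray:
        """Z: records x kinship individuals."""
        pos = {int(i): j for j, i in enumerate(self.kinship_ids)}
        Z = np.zeros((len(self.y), len(self.kinship_ids)))
        for r, i in enumerate(self.record_ids):
            try:
                Z[r, pos[int(i)]] = 1.0
            except KeyError:
                raise ValueError(f"record individual {i} absent from kinship")
        return Z


def _solve_mme(spec: MixedModelSpec, Kinv: np.ndarray, model: str) -> PredictionResult:
    X, y = spec.X, spec.y
    Z = spec.incidence()
    p = X.shape[1]
    lhs = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + spec.k * Kinv]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular mixed-model equations; check kinship rank or blend G"
        ) from exc
    resid = np.linalg.norm(lhs @ sol - rhs)
    scale = np.linalg.norm(rhs) + 1e-30
    if resid / scale > 1e-6:
        raise np.linalg.LinAlgError(
            f"mixed-model solve inaccurate (relative residual {resid / scale:.2e})"
        )
    return PredictionResult(
        ids=spec.kinship_ids.copy(),
        gebv=sol[p:],
        model=model,
        fixed_effects=sol[:p],
        extras={"relative_residual": resid / scale},
    )


def solve_gblup(spec: MixedModelSpec) -> PredictionResult:
    """GBLUP: kinship is the (blended, invertible) genomic matrix G."""
    if spec.K_inv is not None:
        Kinv = spec.K_inv.values
    else:
        Kinv = invert_psd(spec.K).values
    return _solve_mme(spec, Kinv, model="GBLUP")


def solve_ssgblup(spec: MixedModelSpec) -> PredictionResult:
    """ssGBLUP: kinship inverse is the assembled H^-1 over the pedigree."""
    if spec.K_inv is None or spec.K_inv.kind != "Hinv":
        raise ValueError("ssGBLUP requires an assembled H^-1 (kind='Hinv')")
    return _solve_mme(spec, spec.K_inv.values, model="ssGBLUP")


def solve_snp_blup(
    geno: GenotypeMatrix,
    y: np.ndarray,
    record_ids: np.ndarray,
    k_marker: float,
    freqs: np.ndarray | None = None,
) -> PredictionResult:
    """Ridge regression on centred marker dosages (RRBLUP).

    Solves the marker-effect mixed model y = 1 mu + W_t a + e with a common
    ridge parameter ``k_marker`` = sigma_e2 / sigma_a2; GEBV = W a for every
    individual in ``geno``. With VanRaden G and ``k_marker`` = k * 2*sum
    p(1-p) this reproduces GBLUP GEBVs exactly.
    """
    if geno.n_markers == 0:
        raise ValueError("no markers available for SNP-BLUP")
    if k_marker <= 0:
        raise ValueError("k_marker must be positive")
    y = np.asarray(y, dtype=float)
    p = geno.allele_frequencies() if freqs is None else np.asarray(freqs, float)
    W = geno.dosage - 2.0 * p
    pos = {int(i): j for j, i in enumerate(geno.individual_ids)}
    rows = np.array([pos[int(i)] for i in record_ids])
    Wt = W[rows]
    n, m = Wt.shape
    ones = np.ones((n, 1))
    lhs = np.block(
        [[ones.T @ ones, ones.T @ Wt], [Wt.T @ ones, Wt.T @ Wt + k_marker * np.eye(m)]]
    )
    rhs = np.concatenate([ones.T @ y, Wt.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    effects = sol[1:]
    return PredictionResult(
        ids=geno.individual_ids.copy(),
        gebv=W @ effects,
        model="SNP-BLUP",
        fixed_effects=sol[:1],
        marker_effects=effects,
    )
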