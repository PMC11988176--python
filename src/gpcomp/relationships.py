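"""Genomic (G), pedigree (A, A22) and single-step (H-inverse) relationships.

G follows VanRaden's first method: M is the column-centred dosage matrix and
G = MM' / (2 * sum_i p_i (1 - p_i)). Centring uses the counted-allele
frequency by default; a literal minor-allele-frequency variant is available
for sensitivity checks but breaks the zero-mean property of M and is not
recommended. A and its sparse-structured inverse use the tabular method and
Henderson's rules with inbreeding. H-inverse adds (G^-1 - A22^-1) to the
genotyped block of A^-1.
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix, Pedigree, RelationshipMatrix

__all__ = [
    "compute_G",
    "blend_G",
    "compute_A",
    "compute_A22",
    "compute_A_inverse",
    "invert_psd",
    "assemble_H_inverse",
    "SingularKinshipError",
]


class SingularKinshipError(np.linalg.LinAlgError):
    """Kinship matrix not invertible; blending with A22 (or identity) advised."""


def compute_G(
    geno: GenotypeMatrix,
    freq_convention: str = "counted",
    freqs: np.ndarray | None = None,
    impute_missing: bool = False,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    Parameters
    ----------
    freq_convention
        "counted" (default) centres each marker at twice the counted-allele
        frequency, giving E[M] = 0; "minor" centres at twice the literal
        minor allele frequency.
    freqs
        Optional explicit centring frequencies (e.g. base-population or
        generating frequencies). Default: observed frequencies.
    impute_missing
        Replace missing dosages by the marker mean (2p). Without it, missing
        dosages raise.
    """
    dosage = geno.dosage
    if np.isnan(dosage).any():
        if not impute_missing:
            raise ValueError(
                "missing dosages present; impute first or pass impute_missing=True"
            )
        dosage = dosage.copy()
    if freqs is None:
        p = geno.allele_frequencies()
    else:
        p = np.asarray(freqs, dtype=float)
        if len(p) != geno.n_markers:
            raise ValueError("freqs length does not match marker count")
    if freq_convention == "minor":
        p = np.minimum(p, 1.0 - p)
    elif freq_convention != "counted":
        raise ValueError("freq_convention must be 'counted' or 'minor'")

    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ZeroDivisionError("all markers monomorphic: G denominator is zero")
    p = p[poly]
    M = dosage[:, poly] - 2.0 * p
    if np.isnan(M).any():
        M = np.where(np.isnan(M), 0.0, M)  # mean imputation after centring
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (M @ M.T) / denom
    return RelationshipMatrix(
        values=G, ids=geno.individual_ids.copy(), kind="G",
        freqs=p, denominator=denom,
    )


def blend_G(G: RelationshipMatrix, A22: RelationshipMatrix | None = None,
            epsilon: float = 0.05) -> RelationshipMatrix:
    """G* = (1 - eps) G + eps A22 (identity if no A22): guarantees invertibility."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must lie in [0, 1)")
    target = np.eye(G.n) if A22 is None else A22.values
    if A22 is not None and not np.array_equal(A22.ids, G.ids):
        raise ValueError("A22 and G id order differ")
    return RelationshipMatrix(
        values=(1.0 - epsilon) * G.values + epsilon * target,
        ids=G.ids.copy(), kind="G", freqs=G.freqs, denominator=G.denominator,
    )


def _tabular_A(ped: Pedigree) -> np.ndarray:
    n = len(ped)
    pos = ped.positions()
    si = np.array([pos[int(s)] if s != 0 else -1 for s in ped.sire])
    di = np.array([pos[int(d)] if d != 0 else -1 for d in ped.dam])
    A = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        # parents precede offspring, so rows < i are complete
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0:
            A[i, :i] = 0.5 * A[s, :i]
            A[i, i] = 1.0
        elif d >= 0:
            A[i, :i] = 0.5 * A[d, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def compute_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method (founders unrelated)."""
    return RelationshipMatrix(values=_tabular_A(ped), ids=ped.ids.copy(), kind="A")


def compute_A22(ped: Pedigree, genotyped_ids: np.ndarray,
                A: RelationshipMatrix | None = None) -> RelationshipMatrix:
    """Pedigree relationships among the genotyped subset, in the given order."""
    if A is None:
        A = compute_A(ped)
    pos = {int(i): k for k, i in enumerate(A.ids)}
    idx = np.array([pos[int(i)] for i in genotyped_ids], dtype=int)
    return RelationshipMatrix(
        values=A.values[np.ix_(idx, idx)], ids=np.asarray(genotyped_ids), kind="A22"
    )


def compute_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """A^-1 by Henderson's rules, accounting for inbreeding.

    Inbreeding coefficients come from the tabular A diagonal, so the result
    is exact for arbitrary (acyclic, parents-first) pedigrees.
    """
    n = len(ped)
    F = np.diag(_tabular_A(ped)) - 1.0
    pos = ped.positions()
    si = np.array([pos[int(s)] if s != 0 else -1 for s in ped.sire])
    di = np.array([pos[int(d)] if d != 0 else -1 for d in ped.dam])
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = si[i], di[i]
        Fs = F[s] if s >= 0 else 0.0
        Fd = F[d] if d >= 0 else 0.0
        if s >= 0 and d >= 0:
            mend = 0.5 - 0.25 * (Fs + Fd)
        elif s >= 0 or d >= 0:
            mend = 0.75 - 0.25 * (Fs if s >= 0 else Fd)
        else:
            mend = 1.0
        alpha = 1.0 / mend
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= alpha / 2.0
                Ainv[p, i] -= alpha / 2.0
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += alpha / 4.0
    return RelationshipMatrix(values=Ainv, ids=ped.ids.copy(), kind="Ainv")


def invert_psd(K: RelationshipMatrix, kind: str | None = None) -> RelationshipMatrix:
    """Cholesky-based inverse; raises SingularKinshipError with advice."""
    try:
        c = np.linalg.cholesky(K.values)
    except np.linalg.LinAlgError as exc:
        raise SingularKinshipError(
            f"{K.kind} is singular or indefinite; blend with A22 or the "
            "identity (blend_G) before inverting"
        ) from exc
    inv = np.linalg.inv(c)
    return RelationshipMatrix(values=inv.T @ inv, ids=K.ids.copy(),
                              kind=kind or (K.kind + "inv"))


def assemble_H_inverse(
    A_inv: RelationshipMatrix,
    A22_inv: RelationshipMatrix,
    G_inv: RelationshipMatrix,
    genotyped_ids: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Single-step H^-1 = A^-1 + [[0,0],[0, G^-1 - A22^-1]] on the genotyped block."""
    ids = np.asarray(genotyped_ids) if genotyped_ids is not None else G_inv.ids
    if not np.array_equal(G_inv.ids, ids) or not np.array_equal(A22_inv.ids, ids):
        raise ValueError("G^-1 / A22^-1 id order must match the genotyped ids")
    pos = {int(i): k for k, i in enumerate(A_inv.ids)}
    try:
        idx = np.array([pos[int(i)] for i in ids], dtype=int)
    except KeyError as exc:
        raise ValueError(f"genotyped individual {exc.args[0]} absent from pedigree")
    H = A_inv.values.copy()
    if len(idx):
        H[np.ix_(idx, idx)] += G_inv.values - A22_inv.values
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(values=H, ids=A_inv.ids.copy(), kind="Hinv")
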