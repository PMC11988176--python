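"""REML estimation of additive and residual variance and heritability.

Single-kinship linear mixed model y = Xb + g + e with g ~ N(0, K sigma_g2)
and e ~ N(0, I sigma_e2). The kinship is eigendecomposed once, so every
restricted-likelihood evaluation and every average-information (AI) update is
O(n) after the initial O(n^3) decomposition. AI updates fall back to EM-REML
steps (which are guaranteed ascent) whenever the AI step would leave the
parameter space; convergence is declared on the relative change of the
restricted log-likelihood. Standard errors come from the inverse AI matrix,
with the delta method for h2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RelationshipMatrix

__all__ = ["VarianceComponents", "estimate_reml", "heritability", "reml_loglik"]


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    se_sigma_g2: float
    se_sigma_e2: float
    se_h2: float
    loglik: float
    converged: bool
    n_iter: int

    @property
    def h2(self) -> float:
        return heritability(self)

    @property
    def k_ratio(self) -> float:
        """Variance ratio k = sigma_e2 / sigma_g2 used by the BLUP solvers."""
        if self.sigma_g2 <= 0:
            raise ZeroDivisionError("sigma_g2 is zero: k ratio undefined")
        return self.sigma_e2 / self.sigma_g2

    def to_frame(self, trait: str = "trait") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": trait,
                    "sigma_g2": self.sigma_g2,
                    "sigma_e2": self.sigma_e2,
                    "h2": self.h2,
                    "se_sigma_g2": self.se_sigma_g2,
                    "se_sigma_e2": self.se_sigma_e2,
                    "se_h2": self.se_h2,
                    "loglik": self.loglik,
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                }
            ]
        )

    def write_tsv(self, path: str | Path, trait: str = "trait") -> None:
        self.to_frame(trait).to_csv(path, sep="\t", index=False)


def heritability(vc: VarianceComponents) -> float:
    """h2 = sigma_g2 / (sigma_g2 + sigma_e2)."""
    tot = vc.sigma_g2 + vc.sigma_e2
    if tot <= 0:
        raise ZeroDivisionError("zero phenotypic variance")
    return vc.sigma_g2 / tot


class _EigenREML:
    """Restricted likelihood machinery in the eigenbasis of K."""

    def __init__(self, y: np.ndarray, K: np.ndarray, X: np.ndarray):
        s, U = np.linalg.eigh(K)
        self.s = np.clip(s, 0.0, None)
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n, self.p = X.shape

    def core(self, sg2: float, se2: float):
        d = sg2 * self.s + se2
        dinv = 1.0 / d
        XtD = self.Xt * dinv[:, None]
        XtVX = self.Xt.T @ XtD  # X'V^-1 X
        beta = np.linalg.solve(XtVX, XtD.T @ self.yt)
        r = (self.yt - self.Xt @ beta) * dinv  # P y in eigenbasis
        return d, dinv, XtVX, r

    def loglik(self, sg2: float, se2: float) -> float:
        d, dinv, XtVX, r = self.core(sg2, se2)
        ypy = float(self.yt @ r)
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        return -0.5 * (np.sum(np.log(d)) + logdet_xvx + ypy)

    def _apply_P(self, zt: np.ndarray, dinv, XtVX) -> np.ndarray:
        # P z = V^-1 z - V^-1 X (X'V^-1X)^-1 X'V^-1 z   (all in eigenbasis)
        vz = zt * dinv
        return vz - dinv * (self.Xt @ np.linalg.solve(XtVX, self.Xt.T @ vz))

    def derivatives(self, sg2: float, se2: float):
        d, dinv, XtVX, r = self.core(sg2, se2)
        XtVXinv = np.linalg.inv(XtVX)
        # tr(P K) and tr(P)
        tr_vk = float(np.sum(self.s * dinv))
        tr_v = float(np.sum(dinv))
        Q_k = self.Xt.T @ (self.Xt * (self.s * dinv**2)[:, None])
        Q_e = self.Xt.T @ (self.Xt * (dinv**2)[:, None])
        tr_pk = tr_vk - float(np.trace(XtVXinv @ Q_k))
        tr_pe = tr_v - float(np.trace(XtVXinv @ Q_e))
        yPKPy = float(r @ (self.s * r))
        yPPy = float(r @ r)
        score = np.array([-0.5 * (tr_pk - yPKPy), -0.5 * (tr_pe - yPPy)])
        # average information: 0.5 y'P Vk P Vl P y
        PKr = self._apply_P(self.s * r, dinv, XtVX)
        PIr = self._apply_P(r, dinv, XtVX)
        ai = 0.5 * np.array(
            [
                [float((self.s * r) @ PKr), float((self.s * r) @ PIr)],
                [float(r @ PKr), float(r @ PIr)],
            ]
        )
        ai = 0.5 * (ai + ai.T)
        return score, ai, (tr_pk, tr_pe, yPKPy, yPPy)


def estimate_reml(
    y: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    X: np.ndarray | None = None,
) -> VarianceComponents:
    """AI-REML with EM fallback for the one-kinship model.

    Parameters
    ----------
    y
        Corrected phenotypes (intercept-only fixed design by default, since
        fixed effects are removed upstream).
    K
        Kinship (genomic or pedigree) for the individuals in ``y`` order.
    """
    y = np.asarray(y, dtype=float)
    Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    n = len(y)
    if Kv.shape != (n, n):
        raise ValueError("kinship dimension does not match phenotypes")
    if n < 10:
        raise ValueError("need at least 10 records for REML")
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValueError("phenotype is constant")
    if X is None:
        X = np.ones((n, 1))

    eng = _EigenREML(y, Kv, X)
    floor = 1e-8 * vy
    sg2, se2 = 0.5 * vy, 0.5 * vy
    ll = eng.loglik(sg2, se2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, ai, (tr_pk, tr_pe, yPKPy, yPPy) = eng.derivatives(sg2, se2)
        step_ok = False
        try:
            delta = np.linalg.solve(ai, score)
            cand = np.array([sg2, se2]) + delta
            if np.all(cand > floor):
                cll = eng.loglik(*cand)
                # reject AI overshoots that lose likelihood; EM step instead
                if np.isfinite(cll) and cll >= ll - 1e-4 * (abs(ll) + 1.0):
                    step_ok = True
        except np.linalg.LinAlgError:
            pass
        if not step_ok:
            # EM-REML ascent step
            cand = np.array(
                [
                    sg2 + (sg2**2 / n) * (yPKPy - tr_pk),
                    se2 + (se2**2 / n) * (yPPy - tr_pe),
                ]
            )
            cand = np.maximum(cand, floor)
            cll = eng.loglik(*cand)
        new_sg2, new_se2 = float(cand[0]), float(cand[1])
        rel = abs(cll - ll) / (abs(ll) + 1.0)
        sg2, se2, ll = new_sg2, new_se2, cll
        if rel < tol:
            converged = True
            break

    # standard errors from the inverse AI matrix at the optimum
    _, ai, _ = eng.derivatives(sg2, se2)
    try:
        cov = np.linalg.inv(ai)
        se_g = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_e = float(np.sqrt(max(cov[1, 1], 0.0)))
        tot = sg2 + se2
        grad = np.array([se2, -sg2]) / tot**2  # d h2 / d(sg2, se2)
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate information
        se_g = se_e = se_h2 = float("nan")

    if sg2 <= floor * 1.01:
        sg2 = 0.0
    return VarianceComponents(
        sigma_g2=sg2,
        sigma_e2=se2,
        se_sigma_g2=se_g,
        se_sigma_e2=se_e,
        se_h2=se_h2,
        loglik=ll,
        converged=converged,
        n_iter=it,
    )


def reml_loglik(
    y: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
    X: np.ndarray | None = None,
) -> float:
    """Restricted log-likelihood (up to a constant) at the given variances."""
    y = np.asarray(y, dtype=float)
    Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    if X is None:
        X = np.ones((len(y), 1))
    return _EigenREML(y, Kv, X).loglik(sigma_g2, sigma_e2)
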