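"""Bayesian whole-genome regression by single-site Gibbs sampling.

Five marker-effect priors under one engine:

* **BayesA** — every marker effect normal, with its own scaled-inverse-chi2
  variance.
* **BayesB** — spike-and-slab: a marker has zero effect with fixed
  probability Pi, otherwise a BayesA-style normal effect with per-marker
  variance. Pi = 0 collapses to BayesA.
* **BayesC** — spike-and-slab with one common slab variance and Pi given a
  uniform prior (Beta-updated each sweep).
* **Bayesian LASSO** — double-exponential prior via the normal-exponential
  scale mixture (Park & Casella), with a Gamma hyperprior on lambda^2.
* **BayesR** — four-component normal mixture with relative variances
  (0, 0.0001, 0.001, 0.01) x sigma_g2, Dirichlet(1,1,1,1) on the mixture
  proportions and a sampled total marker-variance parameter.

The model is y = mu + sum_i X_i g_i + e with genotypes coded 0/1/2 and
centred before sampling (the shift is absorbed by mu). Residuals are
maintained incrementally on every effect update. Default hyperparameters
follow the usual weakly-informative rules: prior degrees of freedom 5 for
effect and residual variances, with scales solved from an assumed genetic
variance share R2 = 0.5 of var(y). Chains are bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .containers import GenotypeMatrix, PredictionResult

__all__ = ["McmcConfig", "PosteriorSummary", "run_mcmc", "gebv_from_effects"]

MODELS = ("BayesA", "BayesB", "BayesC", "BL", "BayesR")
_MODEL_CODE = {m: k for k, m in enumerate(MODELS)}

# BayesR relative component variances: zero / very small / small / moderate
BAYESR_GAMMA = np.array([0.0, 1e-4, 1e-3, 1e-2])


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings. Defaults follow common practice for these models
    (12,000 iterations with a 2,000-iteration burn-in)."""

    model: str = "BayesA"
    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    pi_zero: float = 0.95  # P(zero effect) for BayesB; initial value for BayesC
    fix_pi: bool = False  # BayesC: keep pi_zero fixed instead of sampling
    df_effect: float = 5.0
    df_residual: float = 5.0
    r2: float = 0.5  # assumed genetic share of var(y), sets prior scales

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if not 0 < self.burn_in < self.n_iter:
            raise ValueError("need 0 < burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 <= self.pi_zero <= 1.0:
            raise ValueError("pi_zero must lie in [0, 1]")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must lie in (0, 1)")


@dataclass
class PosteriorSummary:
    """Post-burn-in posterior summaries of one chain."""

    model: str
    effect_mean: np.ndarray  # per-marker posterior mean effect
    inclusion_prob: np.ndarray  # P(effect != 0); ones for BayesA / BL
    mu_mean: float
    sigma_e2_mean: float
    sigma_g2_mean: float  # model's marker-variance summary (see run_mcmc)
    pi_zero_mean: float
    component_occupancy: np.ndarray | None  # BayesR: mean markers per component
    sigma_e2_trace: np.ndarray
    mu_trace: np.ndarray
    n_samples: int
    seed: int
    centering: np.ndarray = field(default=None)  # 2p used to centre dosages
    diverged: bool = False

    @property
    def sigma_e2_mcse(self) -> float:
        """Monte Carlo standard error of sigma_e2 by batch means."""
        return batch_means_mcse(self.sigma_e2_trace)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": np.arange(len(self.effect_mean)),
                "effect_mean": self.effect_mean,
                "inclusion_prob": self.inclusion_prob,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def batch_means_mcse(trace: np.ndarray, n_batches: int = 20) -> float:
    """MCSE of the trace mean from non-overlapping batch means."""
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 2 * n_batches:
        n_batches = max(2, len(trace) // 2)
    size = len(trace) // n_batches
    bm = trace[: n_batches * size].reshape(n_batches, size).mean(axis=1)
    return float(np.std(bm, ddof=1) / np.sqrt(n_batches))


@njit(cache=True)
def _rand_scaled_inv_chi2(df, scale):
    # df * scale / chi2(df)
    return df * scale / np.random.chisquare(df)


@njit(cache=True)
def _rand_inv_gaussian(mean, lam):
    # Michael-Schucany-Haas
    v = np.random.standard_normal()
    w = v * v
    x = mean + (mean * mean * w) / (2.0 * lam) - (mean / (2.0 * lam)) * np.sqrt(
        4.0 * mean * lam * w + mean * mean * w * w
    )
    if x <= 0.0:
        x = mean * 1e-8
    if np.random.random() <= mean / (mean + x):
        return x
    return mean * mean / x


@njit(cache=True)
def _gibbs_core(
    Xm,  # (m, n) centred dosages, marker-major
    y,
    model,  # 0=A 1=B 2=C 3=BL 4=R
    n_iter,
    burn_in,
    thin,
    seed,
    pi_zero0,
    fix_pi,
    df0,
    S0,  # per-marker (A/B) or slab (C) prior scale
    dfe,
    Se,
    se2_init,
    lambda2_init,
    lambda_shape,
    lambda_rate,
    sg2_init,
    df0g,
    S0g,
    gamma_rel,
):
    np.random.seed(seed)
    m, n = Xm.shape
    xx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xm[j, i] * Xm[j, i]
        xx[j] = s

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu
    g = np.zeros(m)
    sgj2 = np.full(m, S0)  # per-marker effect variances (BayesA/B)
    sigma_b2 = S0  # common slab variance (BayesC)
    pi_zero = pi_zero0
    tau2 = np.ones(m)  # BL scale mixture
    lambda2 = lambda2_init
    sg2 = sg2_init  # BayesR total marker variance
    pi4 = np.full(4, 0.25)
    comp = np.zeros(m, dtype=np.int8)
    incl = np.ones(m, dtype=np.int8)
    se2 = se2_init

    n_kept = (n_iter - burn_in + thin - 1) // thin
    sum_g = np.zeros(m)
    sum_incl = np.zeros(m)
    occ_sum = np.zeros(4)
    tr_se2 = np.empty(n_kept)
    tr_mu = np.empty(n_kept)
    tr_sg2 = np.empty(n_kept)
    tr_pi = np.empty(n_kept)
    kept = 0

    for it in range(n_iter):
        # ---- marker effects -------------------------------------------
        if model == 0:
            for j in range(m):
                xj = Xm[j]
                rhs = np.dot(xj, e) + xx[j] * g[j]
                c = xx[j] + se2 / sgj2[j]
                gn = rhs / c + np.random.standard_normal() * np.sqrt(se2 / c)
                diff = g[j] - gn
                if diff != 0.0:
                    for i in range(n):
                        e[i] += xj[i] * diff
                g[j] = gn
                sgj2[j] = _rand_scaled_inv_chi2(df0 + 1.0, (df0 * S0 + gn * gn) / (df0 + 1.0))
        elif model == 1 or model == 2:
            # spike-and-slab; slab variance per-marker (B) or common (C)
            for j in range(m):
                xj = Xm[j]
                rhs = np.dot(xj, e) + xx[j] * g[j]
                sv = sgj2[j] if model == 1 else sigma_b2
                d = se2 + xx[j] * sv
                log_bf = -0.5 * np.log(d / se2) + rhs * rhs * sv / (2.0 * se2 * d)
                if pi_zero <= 0.0:
                    p_in = 1.0
                elif pi_zero >= 1.0:
                    p_in = 0.0
                else:
                    log_odds = np.log((1.0 - pi_zero) / pi_zero) + log_bf
                    if log_odds > 35.0:
                        p_in = 1.0
                    elif log_odds < -35.0:
                        p_in = 0.0
                    else:
                        p_in = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_in:
                    c = xx[j] + se2 / sv
                    gn = rhs / c + np.random.standard_normal() * np.sqrt(se2 / c)
                    incl[j] = 1
                else:
                    gn = 0.0
                    incl[j] = 0
                diff = g[j] - gn
                if diff != 0.0:
                    for i in range(n):
                        e[i] += xj[i] * diff
                g[j] = gn
                if model == 1:
                    if incl[j] == 1:
                        sgj2[j] = _rand_scaled_inv_chi2(
                            df0 + 1.0, (df0 * S0 + gn * gn) / (df0 + 1.0)
                        )
                    else:
                        sgj2[j] = _rand_scaled_inv_chi2(df0, S0)
            if model == 2:
                # common slab variance from included effects
                k_in = 0
                ss = 0.0
                for j in range(m):
                    if incl[j] == 1:
                        k_in += 1
                        ss += g[j] * g[j]
                sigma_b2 = _rand_scaled_inv_chi2(
                    df0 + k_in, (df0 * S0 + ss) / (df0 + k_in)
                )
                if fix_pi == 0:
                    # pi_zero ~ Beta(m - k_in + 1, k_in + 1) via gammas
                    a = np.random.gamma(m - k_in + 1.0, 1.0)
                    b = np.random.gamma(k_in + 1.0, 1.0)
                    pi_zero = a / (a + b)
        elif model == 3:
            # Bayesian LASSO: g_j ~ N(0, tau2_j * se2)
            for j in range(m):
                xj = Xm[j]
                rhs = np.dot(xj, e) + xx[j] * g[j]
                c = xx[j] + 1.0 / tau2[j]
                gn = rhs / c + np.random.standard_normal() * np.sqrt(se2 / c)
                diff = g[j] - gn
                if diff != 0.0:
                    for i in range(n):
                        e[i] += xj[i] * diff
                g[j] = gn
                g2 = gn * gn
                if g2 < 1e-12 * se2:
                    g2 = 1e-12 * se2
                inv_tau2 = _rand_inv_gaussian(np.sqrt(lambda2 * se2 / g2), lambda2)
                tau2[j] = 1.0 / inv_tau2
            st = 0.0
            for j in range(m):
                st += tau2[j]
            lambda2 = np.random.gamma(lambda_shape + m, 1.0 / (lambda_rate + st / 2.0))
        else:
            # BayesR four-component mixture
            logpi = np.empty(4)
            for j in range(m):
                xj = Xm[j]
                rhs = np.dot(xj, e) + xx[j] * g[j]
                maxlp = -1e300
                for cpt in range(4):
                    gv = gamma_rel[cpt] * sg2
                    if gv <= 0.0:
                        lp = np.log(pi4[cpt] + 1e-300)
                    else:
                        d = se2 + xx[j] * gv
                        lp = (
                            np.log(pi4[cpt] + 1e-300)
                            - 0.5 * np.log(d / se2)
                            + rhs * rhs * gv / (2.0 * se2 * d)
                        )
                    logpi[cpt] = lp
                    if lp > maxlp:
                        maxlp = lp
                tot = 0.0
                for cpt in range(4):
                    logpi[cpt] = np.exp(logpi[cpt] - maxlp)
                    tot += logpi[cpt]
                u = np.random.random() * tot
                acc = 0.0
                cj = 3
                for cpt in range(4):
                    acc += logpi[cpt]
                    if u <= acc:
                        cj = cpt
                        break
                comp[j] = cj
                gv = gamma_rel[cj] * sg2
                if gv <= 0.0:
                    gn = 0.0
                    incl[j] = 0
                else:
                    c = xx[j] + se2 / gv
                    gn = rhs / c + np.random.standard_normal() * np.sqrt(se2 / c)
                    incl[j] = 1
                diff = g[j] - gn
                if diff != 0.0:
                    for i in range(n):
                        e[i] += xj[i] * diff
                g[j] = gn
            # total marker variance from non-null effects
            k_nz = 0
            ss = 0.0
            for j in range(m):
                if incl[j] == 1:
                    k_nz += 1
                    ss += g[j] * g[j] / gamma_rel[comp[j]]
            sg2 = _rand_scaled_inv_chi2(df0g + k_nz, (df0g * S0g + ss) / (df0g + k_nz))
            # Dirichlet(1 + counts) via gammas
            tot = 0.0
            for cpt in range(4):
                cnt = 0.0
                for j in range(m):
                    if comp[j] == cpt:
                        cnt += 1.0
                pi4[cpt] = np.random.gamma(1.0 + cnt, 1.0)
                tot += pi4[cpt]
            for cpt in range(4):
                pi4[cpt] /= tot

        # ---- overall mean ---------------------------------------------
        s = 0.0
        for i in range(n):
            s += e[i]
        dmu = s / n + np.random.standard_normal() * np.sqrt(se2 / n)
        mu += dmu
        for i in range(n):
            e[i] -= dmu

        # ---- residual variance ----------------------------------------
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        se2 = (sse + dfe * Se) / np.random.chisquare(n + dfe)

        # ---- accumulate -----------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                sum_g[j] += g[j]
                sum_incl[j] += incl[j]
            if model == 4:
                for j in range(m):
                    occ_sum[comp[j]] += 1.0
            tr_se2[kept] = se2
            tr_mu[kept] = mu
            if model == 0 or model == 1:
                sv = 0.0
                for j in range(m):
                    sv += sgj2[j]
                tr_sg2[kept] = sv / m
            elif model == 2:
                tr_sg2[kept] = sigma_b2
            elif model == 3:
                tr_sg2[kept] = lambda2
            else:
                tr_sg2[kept] = sg2
            tr_pi[kept] = pi_zero
            kept += 1

    return sum_g, sum_incl, occ_sum, tr_se2, tr_mu, tr_sg2, tr_pi, kept


def run_mcmc(geno: GenotypeMatrix, y: np.ndarray, cfg: McmcConfig) -> PosteriorSummary:
    """Run one Gibbs chain and summarize the post-burn-in samples.

    ``sigma_g2_mean`` reports the model's marker-variance summary: the mean
    per-marker effect variance for BayesA/B, the slab variance for BayesC,
    lambda^2 for the Bayesian LASSO and the total marker variance for
    BayesR.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != geno.n_individuals:
        raise ValueError("phenotype length does not match genotypes")
    if np.isnan(geno.dosage).any():
        raise ValueError("missing dosages: impute or filter before MCMC")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotypes")
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("phenotype has zero variance: likelihood degenerate")

    p = geno.allele_frequencies()
    centering = 2.0 * p
    Xm = np.ascontiguousarray((geno.dosage - centering).T)
    msx = float(np.sum(np.var(Xm, axis=1)))
    if msx <= 0:
        raise ValueError("all markers monomorphic")

    df0 = cfg.df_effect
    dfe = cfg.df_residual
    r2 = cfg.r2
    # prior scales solved from the assumed variance split (mode-matching)
    Se = vy * (1.0 - r2) * (dfe + 2.0) / dfe
    if cfg.model in ("BayesB", "BayesC") and cfg.pi_zero < 1.0:
        share = max(1.0 - cfg.pi_zero, 1e-3)
    else:
        share = 1.0
    S0 = vy * r2 * (df0 + 2.0) / (df0 * msx * share)
    # BL: prior mode of lambda2 at the Park-Casella style guess
    lambda2_guess = 2.0 * (1.0 - r2) * msx / (r2 * max(len(y), 1)) * len(y)
    lambda2_guess = max(lambda2_guess, 1e-3)
    lambda_shape = 1.1
    lambda_rate = (lambda_shape - 1.0) / lambda2_guess + 1e-6
    # BayesR: expected genetic variance msx * sg2 * E[sum pi_c gamma_c]
    mean_gamma = float(np.mean(BAYESR_GAMMA))
    sg2_init = vy * r2 / (msx * mean_gamma)
    df0g = 4.0
    S0g = sg2_init * (df0g + 2.0) / df0g

    res = _gibbs_core(
        Xm,
        y,
        _MODEL_CODE[cfg.model],
        cfg.n_iter,
        cfg.burn_in,
        cfg.thin,
        cfg.seed % (2**31),
        cfg.pi_zero,
        1 if cfg.fix_pi else 0,
        df0,
        S0,
        dfe,
        Se,
        vy * (1.0 - r2),
        lambda2_guess,
        lambda_shape,
        lambda_rate,
        sg2_init,
        df0g,
        S0g,
        BAYESR_GAMMA,
    )
    sum_g, sum_incl, occ_sum, tr_se2, tr_mu, tr_sg2, tr_pi, kept = res
    summary = PosteriorSummary(
        model=cfg.model,
        effect_mean=sum_g / kept,
        inclusion_prob=sum_incl / kept,
        mu_mean=float(tr_mu.mean()),
        sigma_e2_mean=float(tr_se2.mean()),
        sigma_g2_mean=float(tr_sg2.mean()),
        pi_zero_mean=float(tr_pi.mean()),
        component_occupancy=occ_sum / kept if cfg.model == "BayesR" else None,
        sigma_e2_trace=tr_se2,
        mu_trace=tr_mu,
        n_samples=int(kept),
        seed=cfg.seed,
        centering=centering,
        diverged=bool(tr_se2.mean() < 1e-8 * vy),
    )
    return summary


def gebv_from_effects(
    geno: GenotypeMatrix, summary: PosteriorSummary
) -> PredictionResult:
    """GEBV = coded genotypes x posterior-mean effects (mu excluded).

    Dosages are centred with the same frequencies used during sampling, so
    training and candidate individuals are on one scale; the constant shift
    is absorbed by mu and irrelevant to correlation/slope metrics.
    """
    if geno.n_markers != len(summary.effect_mean):
        raise ValueError("marker count does not match posterior summary")
    X = geno.dosage - summary.centering
    return PredictionResult(
        ids=geno.individual_ids.copy(),
        gebv=X @ summary.effect_mean,
        model=summary.model,
        marker_effects=summary.effect_mean,
    )
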