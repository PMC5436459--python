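"""Genomic-prediction models: RR-BLUP, BayesA and Bayesian LASSO.

All three regress the phenotype on every marker jointly, markers as random
effects and an intercept as the only fixed effect. GEBVs are X g on the
training-centred dosage scale (the raw 0/1/2 design of GEBV = Xg differs
only by an intercept shift, which never affects correlations).

RR-BLUP is the closed-form ridge solution with the shrinkage parameter tied
to the REML variance ratio; BayesA places marker-specific scaled-inverse-
chi-square variances on the effects (marginally scaled-t), and the Bayesian
LASSO uses the double-exponential prior through its normal scale-mixture
representation. The Gibbs sweeps are compiled with numba; chains are fully
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datatypes import GenotypeMatrix, PhenotypeTable
from .kinship import grm_vanraden
from .varcomp import reml_h2

MODEL_NAMES = ("rrblup", "bayesa", "bl")


@dataclass
class McmcConfig:
    """Gibbs-sampler settings; defaults follow the 40,000 / 10,000 protocol.

    ``df_marker`` and ``r2`` pin the BayesA prior: nu = 5 degrees of freedom
    with the scale chosen so the prior mode of the implied genetic variance
    matches half the phenotypic variance (r2 = 0.5). The Bayesian LASSO puts
    lambda^2 ~ Gamma(``bl_shape``, rate) with the rate set by the same
    heuristic. A fast profile (4,000 / 1,000) is provided for desk-scale
    cross-validation runs.
    """

    n_iter: int = 40_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0
    df_marker: float = 5.0
    df_resid: float = 5.0
    r2: float = 0.5
    bl_shape: float = 1.1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        for name in ("n_iter", "burn_in", "thin"):
            if getattr(self, name) < (0 if name == "burn_in" else 1):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def fast(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_iter=4_000, burn_in=1_000, seed=seed)


@dataclass
class MarkerEffects:
    """Fitted per-marker additive effects plus the training geometry."""

    model: str
    marker_ids: list[str]
    g: np.ndarray
    intercept: float
    column_means: np.ndarray
    posterior_sd: np.ndarray | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.g) != len(self.marker_ids):
            raise ValueError("effect vector does not match marker ids")
        if not np.isfinite(self.g).all():
            raise ValueError(f"{self.model}: non-finite marker effects in chain")


@dataclass
class GebvVector:
    individual_ids: list[str]
    gebv: np.ndarray


def _aligned_y(genotypes: GenotypeMatrix, phenotypes, trait: str | None) -> np.ndarray:
    if isinstance(phenotypes, PhenotypeTable):
        if trait is None:
            raise ValueError("trait name required with a PhenotypeTable")
        return phenotypes.trait_vector(trait, ids=genotypes.individual_ids)
    y = np.asarray(phenotypes, dtype=float)
    if y.size != genotypes.n_individuals:
        raise ValueError("phenotype vector does not match genotype matrix")
    return y


def fit_rrblup(
    genotypes: GenotypeMatrix,
    phenotypes,
    trait: str | None = None,
    variance_ratio: float | None = None,
) -> MarkerEffects:
    """Closed-form ridge solution g = (Xc'Xc + lambda I)^-1 Xc'(y - ybar).

    ``variance_ratio`` is V_E / V_A of the genomic animal model; when absent
    it is estimated by REML on the VanRaden GRM built from the same training
    matrix. The per-marker ridge parameter is lambda = 2 sum p(1-p) *
    variance_ratio, which makes X g identical to the GBLUP breeding values
    under the same ratio. A constant phenotype returns the zero effect
    vector with the constant as intercept.
    """
    genotypes.require_complete("RR-BLUP")
    if genotypes.n_individuals < 2:
        raise ValueError("need at least 2 training individuals")
    y = _aligned_y(genotypes, phenotypes, trait)
    X = genotypes.dosages
    col_means = X.mean(axis=0)
    intercept = float(y.mean())
    if np.all(y == y[0]):
        return MarkerEffects(
            model="rrblup",
            marker_ids=list(genotypes.marker_ids),
            g=np.zeros(genotypes.n_markers),
            intercept=intercept,
            column_means=col_means,
            settings={"variance_ratio": variance_ratio},
        )
    if variance_ratio is None:
        vc = reml_h2(grm_vanraden(genotypes), y)
        variance_ratio = vc.V_E / vc.V_A
    if variance_ratio < 0:
        raise ValueError("variance_ratio must be non-negative")
    p = col_means / 2.0
    c = float(2.0 * np.sum(p * (1.0 - p)))
    if c <= 0:
        raise ValueError("all markers monomorphic")
    lam = c * variance_ratio
    Xc = X - col_means
    yc = y - intercept
    n, m = Xc.shape
    if m >= n:  # dual form: one n x n solve
        K = Xc @ Xc.T
        g = Xc.T @ np.linalg.solve(K + lam * np.eye(n), yc)
    else:
        g = np.linalg.solve(Xc.T @ Xc + lam * np.eye(m), Xc.T @ yc)
    return MarkerEffects(
        model="rrblup",
        marker_ids=list(genotypes.marker_ids),
        g=g,
        intercept=intercept,
        column_means=col_means,
        settings={"variance_ratio": float(variance_ratio), "lambda": lam},
    )


@njit(cache=True)
def _chain_bayesa(
    XT, y, xtx, n_iter, burn_in, nu, S, df_e, Se, seed,
    update_marker_var, update_resid_var, sigma2_j_init, sigma2_e_init,
):  # pragma: no cover - exercised through fit_bayes_a
    np.random.seed(seed)
    m, n = XT.shape
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    g = np.zeros(m)
    resid = y - mu
    sigma2_j = sigma2_j_init.copy()
    sigma2_e = sigma2_e_init
    g_sum = np.zeros(m)
    g_sumsq = np.zeros(m)
    mu_sum = 0.0
    n_keep = 0
    for it in range(n_iter):
        s = 0.0
        for i in range(n):
            s += resid[i]
        mu_new = (mu + s / n) + np.random.normal() * np.sqrt(sigma2_e / n)
        dmu = mu - mu_new
        for i in range(n):
            resid[i] += dmu
        mu = mu_new
        for j in range(m):
            xj = XT[j]
            rhs = xtx[j] * g[j]
            for i in range(n):
                rhs += xj[i] * resid[i]
            cj = xtx[j] + sigma2_e / sigma2_j[j]
            g_new = rhs / cj + np.random.normal() * np.sqrt(sigma2_e / cj)
            diff = g[j] - g_new
            for i in range(n):
                resid[i] += xj[i] * diff
            g[j] = g_new
            if update_marker_var:
                sigma2_j[j] = (nu * S + g[j] * g[j]) / np.random.chisquare(nu + 1.0)
        if update_resid_var:
            sse = 0.0
            for i in range(n):
                sse += resid[i] * resid[i]
            sigma2_e = (sse + df_e * Se) / np.random.chisquare(n + df_e)
        if it >= burn_in:
            n_keep += 1
            mu_sum += mu
            for j in range(m):
                g_sum[j] += g[j]
                g_sumsq[j] += g[j] * g[j]
    g_mean = g_sum / n_keep
    g_var = g_sumsq / n_keep - g_mean * g_mean
    for j in range(m):
        if g_var[j] < 0.0:
            g_var[j] = 0.0
    return g_mean, np.sqrt(g_var), mu_sum / n_keep


@njit(cache=True)
def _rinvgauss(mean, shape):  # pragma: no cover
    v = np.random.normal()
    w = v * v
    x = mean + mean * mean * w / (2.0 * shape) - mean / (2.0 * shape) * np.sqrt(
        4.0 * mean * shape * w + mean * mean * w * w
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mean / (mean + x):
        return x
    return mean * mean / x


@njit(cache=True)
def _chain_bl(
    XT, y, xtx, n_iter, burn_in, shape0, rate0, df_e, Se, seed,
    update_tau, update_lambda, update_resid_var, tau2_init, lambda2_init, sigma2_e_init,
):  # pragma: no cover - exercised through fit_bayes_lasso
    np.random.seed(seed)
    m, n = XT.shape
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    g = np.zeros(m)
    resid = y - mu
    tau2 = tau2_init.copy()
    lambda2 = lambda2_init
    sigma2_e = sigma2_e_init
    g_sum = np.zeros(m)
    g_sumsq = np.zeros(m)
    mu_sum = 0.0
    n_keep = 0
    for it in range(n_iter):
        s = 0.0
        for i in range(n):
            s += resid[i]
        mu_new = (mu + s / n) + np.random.normal() * np.sqrt(sigma2_e / n)
        dmu = mu - mu_new
        for i in range(n):
            resid[i] += dmu
        mu = mu_new
        for j in range(m):
            xj = XT[j]
            rhs = xtx[j] * g[j]
            for i in range(n):
                rhs += xj[i] * resid[i]
            cj = xtx[j] + 1.0 / tau2[j]
            g_new = rhs / cj + np.random.normal() * np.sqrt(sigma2_e / cj)
            diff = g[j] - g_new
            for i in range(n):
                resid[i] += xj[i] * diff
            g[j] = g_new
            if update_tau:
                g2 = g[j] * g[j]
                if g2 < 1e-12:
                    g2 = 1e-12
                inv_tau = _rinvgauss(np.sqrt(lambda2 * sigma2_e / g2), lambda2)
                tau2[j] = 1.0 / inv_tau
        if update_lambda:
            tsum = 0.0
            for j in range(m):
                tsum += tau2[j]
            lambda2 = np.random.gamma(shape0 + m, 1.0 / (rate0 + tsum / 2.0))
        if update_resid_var:
            sse = 0.0
            for i in range(n):
                sse += resid[i] * resid[i]
            gdg = 0.0
            for j in range(m):
                gdg += g[j] * g[j] / tau2[j]
            sigma2_e = (sse + gdg + df_e * Se) / np.random.chisquare(n + m + df_e)
        if it >= burn_in:
            n_keep += 1
            mu_sum += mu
            for j in range(m):
                g_sum[j] += g[j]
                g_sumsq[j] += g[j] * g[j]
    g_mean = g_sum / n_keep
    g_var = g_sumsq / n_keep - g_mean * g_mean
    for j in range(m):
        if g_var[j] < 0.0:
            g_var[j] = 0.0
    return g_mean, np.sqrt(g_var), mu_sum / n_keep


def _prep_design(genotypes: GenotypeMatrix, phenotypes, trait):
    genotypes.require_complete("MCMC fit")
    y = _aligned_y(genotypes, phenotypes, trait)
    X = genotypes.dosages
    col_means = X.mean(axis=0)
    Xc = X - col_means
    XT = np.ascontiguousarray(Xc.T)
    xtx = np.sum(Xc * Xc, axis=0)
    # guard fully monomorphic columns: keep the conditional proper
    xtx = np.where(xtx == 0, 1e-12, xtx)
    msx = float(np.sum(np.var(X, axis=0, ddof=1)))
    return y, col_means, XT, xtx, msx


def fit_bayes_a(
    genotypes: GenotypeMatrix,
    phenotypes,
    trait: str | None = None,
    config: McmcConfig | None = None,
    fixed_marker_variance: float | None = None,
    fixed_resid_variance: float | None = None,
) -> MarkerEffects:
    """BayesA Gibbs sampler (marker-specific scaled-inv-chi^2 variances).

    The ``fixed_*`` arguments freeze the corresponding variances at given
    constants instead of sampling them — a testing hook under which the
    posterior mean of g is the ridge solution with lambda =
    sigma2_e / sigma2_j.
    """
    config = config or McmcConfig()
    y, col_means, XT, xtx, msx = _prep_design(genotypes, phenotypes, trait)
    vy = float(np.var(y, ddof=1))
    if vy == 0:
        raise ValueError("phenotype has zero variance")
    nu = config.df_marker
    S = config.r2 * vy / msx * (nu + 2.0) / nu  # prior mode matches r2 * V_P
    Se = (1.0 - config.r2) * vy * (config.df_resid + 2.0) / config.df_resid
    sigma2_j0 = np.full(
        genotypes.n_markers,
        fixed_marker_variance if fixed_marker_variance is not None else S,
    )
    sigma2_e0 = (
        fixed_resid_variance if fixed_resid_variance is not None else (1 - config.r2) * vy
    )
    g, g_sd, mu = _chain_bayesa(
        XT, y, xtx,
        config.n_iter, config.burn_in,
        nu, S, config.df_resid, Se,
        config.seed % (2**32),
        fixed_marker_variance is None,
        fixed_resid_variance is None,
        sigma2_j0, float(sigma2_e0),
    )
    return MarkerEffects(
        model="bayesa",
        marker_ids=list(genotypes.marker_ids),
        g=g,
        intercept=float(mu),
        column_means=col_means,
        posterior_sd=g_sd,
        settings={"n_iter": config.n_iter, "burn_in": config.burn_in,
                  "seed": config.seed, "nu": nu, "scale": S},
    )


def fit_bayes_lasso(
    genotypes: GenotypeMatrix,
    phenotypes,
    trait: str | None = None,
    config: McmcConfig | None = None,
    fixed_tau2: np.ndarray | None = None,
    fixed_resid_variance: float | None = None,
) -> MarkerEffects:
    """Bayesian LASSO Gibbs sampler (double-exponential prior via the
    normal scale mixture with per-marker tau^2 and a Gamma hyperprior on
    lambda^2).

    With ``fixed_tau2`` (and a fixed residual variance) the posterior mean of
    g is the weighted-ridge solution (Xc'Xc + diag(1/tau^2))^-1 Xc'(y - ybar)
    — the conditional-conjugacy oracle used in the tests.
    """
    config = config or McmcConfig()
    y, col_means, XT, xtx, msx = _prep_design(genotypes, phenotypes, trait)
    vy = float(np.var(y, ddof=1))
    if vy == 0:
        raise ValueError("phenotype has zero variance")
    # prior guess: DE effect variance 2 sigma_e^2 / lambda^2 accounts for r2
    lambda2_hat = 2.0 * (1.0 - config.r2) * msx / config.r2
    shape0 = config.bl_shape
    rate0 = shape0 / lambda2_hat  # prior mean equals the heuristic guess
    Se = (1.0 - config.r2) * vy * (config.df_resid + 2.0) / config.df_resid
    if fixed_tau2 is not None:
        tau2_0 = np.asarray(fixed_tau2, dtype=float)
        if tau2_0.size != genotypes.n_markers:
            raise ValueError("fixed_tau2 length must match marker count")
    else:
        tau2_0 = np.full(genotypes.n_markers, 2.0 / lambda2_hat)
    sigma2_e0 = (
        fixed_resid_variance if fixed_resid_variance is not None else (1 - config.r2) * vy
    )
    g, g_sd, mu = _chain_bl(
        XT, y, xtx,
        config.n_iter, config.burn_in,
        shape0, rate0, config.df_resid, Se,
        config.seed % (2**32),
        fixed_tau2 is None,
        fixed_tau2 is None,
        fixed_resid_variance is None,
        tau2_0, float(lambda2_hat), float(sigma2_e0),
    )
    return MarkerEffects(
        model="bl",
        marker_ids=list(genotypes.marker_ids),
        g=g,
        intercept=float(mu),
        column_means=col_means,
        posterior_sd=g_sd,
        settings={"n_iter": config.n_iter, "burn_in": config.burn_in,
                  "seed": config.seed, "bl_shape": shape0, "bl_rate": rate0},
    )


def predict_gebv(effects: MarkerEffects, genotypes: GenotypeMatrix) -> GebvVector:
    """GEBV = (X - training column means) g, on the deviation scale.

    Candidate markers must match the training markers in identity and order;
    mismatches are a hard error, never silently reordered.
    """
    genotypes.require_complete("GEBV prediction")
    if list(genotypes.marker_ids) != list(effects.marker_ids):
        raise ValueError(
            "candidate markers do not match training markers (identity/order)"
        )
    gebv = (genotypes.dosages - effects.column_means) @ effects.g
    return GebvVector(individual_ids=list(genotypes.individual_ids), gebv=gebv)


def fit_model(
    model: str,
    genotypes: GenotypeMatrix,
    phenotypes,
    trait: str | None = None,
    config: McmcConfig | None = None,
    variance_ratio: float | None = None,
) -> MarkerEffects:
    """Dispatch by model name ('rrblup' | 'bayesa' | 'bl')."""
    if model == "rrblup":
        return fit_rrblup(genotypes, phenotypes, trait, variance_ratio=variance_ratio)
    if model == "bayesa":
        return fit_bayes_a(genotypes, phenotypes, trait, config=config)
    if model == "bl":
        return fit_bayes_lasso(genotypes, phenotypes, trait, config=config)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
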