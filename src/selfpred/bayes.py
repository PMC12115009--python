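"""Bayesian whole-genome regression: BRR, BayesA, BayesB, BayesC, Bayesian
LASSO, fitted by single-site Gibbs sampling.

All five share y = X beta + e with X the (centred) genotype matrix and
differ only in the prior on the marker effects beta_j:

* BRR      beta_j ~ N(0, s2b), one common variance, s2b ~ ScaledInvChi2.
* BayesA   beta_j ~ N(0, s2b_j), a variance per marker.
* BayesB   spike-and-slab: beta_j = 0 with probability pi, else
           N(0, s2b_j) with per-marker slab variances.
* BayesC   spike-and-slab with one common slab variance; pi may be
           estimated with a Beta prior.
* BL       Laplace prior via the normal-exponential hierarchy
           beta_j | tau2_j ~ N(0, s2e tau2_j), tau2_j ~ Exp(lambda2 / 2),
           lambda2 ~ Gamma(a, b).

The residual variance has a scaled-inverse-chi-square prior throughout.
Fixed effects (intercept + block) are removed from the phenotype by OLS
before marker regression, so the sampled design is exactly the marker
matrix; joint sampling of an intercept is available via ``sample_mu``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .geno_io import validate_phenotypes

MODEL_CODES = {"brr": 0, "bayesa": 1, "bayesb": 2, "bayesc": 3, "bl": 4}


class SamplerError(RuntimeError):
    pass


class BayesConfigError(ValueError):
    pass


@dataclass
class BayesPriorConfig:
    model: str = "brr"
    nu_beta: float = 5.0
    S_beta: float | None = None  # None => solved from the R2 heuristic
    nu_e: float = 5.0
    S_e: float | None = None
    pi: float = 0.99  # probability of a NULL effect (BayesB/C)
    estimate_pi: bool = False
    pi_beta_prior: tuple = (1.0, 9.0)
    lambda_shape: float = 1.1
    lambda_rate: float | None = None
    r2_heuristic: float = 0.5

    def validate(self):
        if self.model not in MODEL_CODES:
            raise BayesConfigError(
                f"model {self.model!r} not one of {sorted(MODEL_CODES)}"
            )
        if self.nu_beta <= 0 or self.nu_e <= 0:
            raise BayesConfigError("degrees of freedom must be > 0")
        if self.S_beta is not None and self.S_beta <= 0:
            raise BayesConfigError("S_beta must be > 0")
        if self.S_e is not None and self.S_e <= 0:
            raise BayesConfigError("S_e must be > 0")
        if not 0.0 <= self.pi <= 1.0:
            raise BayesConfigError("pi must be in [0, 1]")
        if self.lambda_shape <= 0 or (self.lambda_rate is not None and self.lambda_rate <= 0):
            raise BayesConfigError("lambda hyperparameters must be > 0")
        if not 0.0 < self.r2_heuristic < 1.0:
            raise BayesConfigError("r2_heuristic must be in (0, 1)")
        return self


@dataclass
class McmcSettings:
    n_iter: int = 20_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def validate(self):
        if self.burn_in >= self.n_iter:
            raise BayesConfigError("burn_in must be < n_iter")
        if self.thin < 1:
            raise BayesConfigError("thin must be >= 1")
        return self


@dataclass
class PosteriorSummary:
    model: str
    marker_ids: list
    marker_effect_means: pd.Series
    marker_effect_sds: pd.Series
    inclusion_prob: pd.Series | None
    sigma2_beta: float
    sigma2_e: float
    pi_posterior: float | None
    lambda2_posterior: float | None
    gebv: pd.Series
    centring: pd.Series  # training-column means used to centre dosages
    mu: float  # fixed-effect offset added back at prediction time is external
    ess: dict = field(default_factory=dict)
    n_kept: int = 0
    chains: dict = field(default_factory=dict)


@njit(cache=True)
def _rinvgauss(mu, lam):
    # Michael, Schucany & Haas (1976) transformation method
    nu = np.random.standard_normal()
    z = nu * nu
    x = mu + (mu * mu * z) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * z + mu * mu * z * z
    )
    if x <= 0.0:
        return mu * 1e-10
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _gibbs_kernel(
    X, y, model, n_iter, burn_in, thin,
    nu_b, S_b, nu_e, S_e,
    pi0, estimate_pi, pi_a, pi_b,
    lam_shape, lam_rate,
    fix_var, s2b_fixed, s2e_fixed,
    sample_mu, store_beta, seed,
):
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    beta = np.zeros(m)
    delta = np.ones(m, dtype=np.int64)
    if model == 2 or model == 3:
        delta[:] = 0
    s2bj = np.full(m, S_b)
    tau2 = np.ones(m)
    s2b = s2b_fixed if fix_var else S_b
    vy = np.var(y)
    s2e = s2e_fixed if fix_var else (vy / 2.0 if vy > 0 else 1.0)
    lam2 = lam_shape / lam_rate
    pi = pi0
    mu = 0.0

    r = y.copy()
    n_kept_max = (n_iter - burn_in + thin - 1) // thin
    beta_sum = np.zeros(m)
    beta_sq = np.zeros(m)
    incl_sum = np.zeros(m)
    s2b_chain = np.empty(n_kept_max)
    s2e_chain = np.empty(n_kept_max)
    pi_chain = np.empty(n_kept_max)
    lam2_chain = np.empty(n_kept_max)
    beta_chain = np.empty((n_kept_max if store_beta == 1 else 1, m))
    kept = 0
    bad_iter = -1

    for it in range(n_iter):
        if sample_mu == 1:
            old = mu
            rbar = 0.0
            for i in range(n):
                rbar += r[i]
            mean = (rbar + n * old) / n
            mu = mean + np.sqrt(s2e / n) * np.random.standard_normal()
            for i in range(n):
                r[i] += old - mu

        for j in range(m):
            old = beta[j]
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * r[i]
            rhs += xtx[j] * old

            if model == 0 or model == 1:
                v = s2b if model == 0 else s2bj[j]
                c = xtx[j] + s2e / v
                bnew = rhs / c + np.sqrt(s2e / c) * np.random.standard_normal()
            elif model == 2 or model == 3:
                v = s2bj[j] if model == 2 else s2b
                c = xtx[j] + s2e / v
                # log Bayes factor for inclusion, slab integrated over beta
                logbf = 0.5 * (np.log(s2e / v) - np.log(c)) + 0.5 * rhs * rhs / (
                    s2e * c
                )
                if pi >= 1.0:
                    p_in = 0.0
                elif pi <= 0.0:
                    p_in = 1.0
                else:
                    log_odds = logbf + np.log((1.0 - pi) / pi)
                    if log_odds > 35.0:
                        p_in = 1.0
                    elif log_odds < -35.0:
                        p_in = 0.0
                    else:
                        p_in = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p_in:
                    delta[j] = 1
                    bnew = rhs / c + np.sqrt(s2e / c) * np.random.standard_normal()
                else:
                    delta[j] = 0
                    bnew = 0.0
            else:  # BL
                c = xtx[j] + 1.0 / tau2[j]
                bnew = rhs / c + np.sqrt(s2e / c) * np.random.standard_normal()

            beta[j] = bnew
            diff = old - bnew
            if diff != 0.0:
                for i in range(n):
                    r[i] += X[i, j] * diff

        # ---- variance / hyperparameter updates ----
        if model == 1:
            for j in range(m):
                s2bj[j] = (nu_b * S_b + beta[j] * beta[j]) / np.random.chisquare(
                    nu_b + 1.0
                )
        elif model == 2:
            for j in range(m):
                if delta[j] == 1:
                    s2bj[j] = (
                        nu_b * S_b + beta[j] * beta[j]
                    ) / np.random.chisquare(nu_b + 1.0)
                else:
                    s2bj[j] = nu_b * S_b / np.random.chisquare(nu_b)
        elif model == 0:
            if fix_var == 0:
                ssb = 0.0
                for j in range(m):
                    ssb += beta[j] * beta[j]
                s2b = (nu_b * S_b + ssb) / np.random.chisquare(nu_b + m)
        elif model == 3:
            m_in = 0
            ssb = 0.0
            for j in range(m):
                if delta[j] == 1:
                    m_in += 1
                    ssb += beta[j] * beta[j]
            s2b = (nu_b * S_b + ssb) / np.random.chisquare(nu_b + m_in)
            if estimate_pi == 1:
                pi = np.random.beta(pi_a + (m - m_in), pi_b + m_in)
        else:  # BL
            sum_tau2 = 0.0
            for j in range(m):
                b2 = beta[j] * beta[j]
                if b2 < 1e-14:
                    b2 = 1e-14
                inv_t = _rinvgauss(np.sqrt(lam2 * s2e / b2), lam2)
                tau2[j] = 1.0 / inv_t
                sum_tau2 += tau2[j]
            lam2 = np.random.gamma(lam_shape + m, 1.0 / (lam_rate + sum_tau2 / 2.0))

        if fix_var == 0:
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            if model == 4:
                # beta | tau2 is scaled by s2e, so its quadratic form joins sse
                qb = 0.0
                for j in range(m):
                    qb += beta[j] * beta[j] / tau2[j]
                s2e = (nu_e * S_e + sse + qb) / np.random.chisquare(nu_e + n + m)
            else:
                s2e = (nu_e * S_e + sse) / np.random.chisquare(nu_e + n)

        if not (np.isfinite(s2e) and np.isfinite(beta[0])):
            bad_iter = it
            break

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(m):
                beta_sum[j] += beta[j]
                beta_sq[j] += beta[j] * beta[j]
                incl_sum[j] += delta[j]
            if store_beta == 1:
                for j in range(m):
                    beta_chain[kept, j] = beta[j]
            if model == 1 or model == 2:
                sb = 0.0
                for j in range(m):
                    sb += s2bj[j]
                s2b_chain[kept] = sb / m
            else:
                s2b_chain[kept] = s2b
            s2e_chain[kept] = s2e
            pi_chain[kept] = pi
            lam2_chain[kept] = lam2
            kept += 1

    return (
        beta_sum, beta_sq, incl_sum, s2b_chain[:kept], s2e_chain[:kept],
        pi_chain[:kept], lam2_chain[:kept], kept, bad_iter, mu,
        beta_chain[: (kept if store_beta == 1 else 0)],
    )


def effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS (single chain)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


def _default_scales(y, X, prior: BayesPriorConfig):
    """BGLR-style prior scales from the R2 heuristic on var(y)."""
    vy = float(np.var(y))
    if vy <= 0:
        vy = 1.0
    msx = float(np.sum(X.var(axis=0)))
    if msx <= 0:
        msx = 1.0
    r2 = prior.r2_heuristic
    S_b = prior.S_beta
    if S_b is None:
        S_b = vy * r2 / msx * (prior.nu_beta + 2.0) / prior.nu_beta
    S_e = prior.S_e
    if S_e is None:
        S_e = vy * (1.0 - r2) * (prior.nu_e + 2.0) / prior.nu_e
    lam_rate = prior.lambda_rate
    if lam_rate is None:
        lam2_guess = max(2.0 * (1.0 - r2) * msx / (r2 * max(len(y), 1)), 1e-3)
        # prior mean shape/rate == lam2_guess
        lam_rate = prior.lambda_shape / lam2_guess
    return S_b, S_e, lam_rate


def adjust_fixed_effects(pheno: pd.DataFrame):
    """OLS pre-adjustment for intercept + block; returns (residual y, model)
    where model maps a block label to its fitted fixed value."""
    pheno = validate_phenotypes(pheno)
    blocks = sorted(pheno["block"].unique())
    Xf = np.ones((len(pheno), len(blocks)))
    for k, b in enumerate(blocks[1:]):
        Xf[:, 1 + k] = (pheno["block"] == b).to_numpy(dtype=float)
    y = pheno["dbh_cm"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    fitted = Xf @ coef
    fixed_of = {}
    for b in blocks:
        x = np.zeros(len(blocks))
        x[0] = 1.0
        if b != blocks[0]:
            x[1 + blocks[1:].index(b)] = 1.0
        fixed_of[b] = float(x @ coef)
    return y - fitted, fixed_of


def fit_bayes(
    g,
    pheno: pd.DataFrame,
    prior: BayesPriorConfig,
    mcmc: McmcSettings,
    adjust_fixed: bool = True,
    sample_mu: bool = False,
    fix_variances: tuple | None = None,
    store_beta_chain: bool = False,
) -> PosteriorSummary:
    """Gibbs fit of one Bayesian whole-genome regression.

    ``g`` must hold imputed dosages for at least the phenotyped ids.
    ``fix_variances=(s2b, s2e)`` freezes both variances (degenerate priors),
    which reduces BRR to ridge regression with a known closed form.
    """
    prior.validate()
    mcmc.validate()
    pheno = validate_phenotypes(pheno)
    gs = g.subset(ids=list(pheno["id"]))
    X = np.asarray(gs.dosage, dtype=float)
    if np.isnan(X).any():
        raise BayesConfigError("genotypes contain missing dosages; impute first")
    centring = X.mean(axis=0)
    Xc = X - centring

    if adjust_fixed:
        y, fixed_of = adjust_fixed_effects(pheno)
    else:
        y = pheno["dbh_cm"].to_numpy(dtype=float)
        fixed_of = {}

    S_b, S_e, lam_rate = _default_scales(y, Xc, prior)
    fix = fix_variances is not None
    s2b_fixed, s2e_fixed = (fix_variances if fix else (1.0, 1.0))

    out = _gibbs_kernel(
        np.ascontiguousarray(Xc), np.ascontiguousarray(y, dtype=float),
        MODEL_CODES[prior.model],
        int(mcmc.n_iter), int(mcmc.burn_in), int(mcmc.thin),
        float(prior.nu_beta), float(S_b), float(prior.nu_e), float(S_e),
        float(prior.pi), int(prior.estimate_pi),
        float(prior.pi_beta_prior[0]), float(prior.pi_beta_prior[1]),
        float(prior.lambda_shape), float(lam_rate),
        int(fix), float(s2b_fixed), float(s2e_fixed),
        int(sample_mu), int(store_beta_chain), int(mcmc.seed) % (2**31 - 1),
    )
    (beta_sum, beta_sq, incl_sum, s2b_c, s2e_c, pi_c, lam2_c, kept,
     bad_iter, mu, beta_chain) = out
    if bad_iter >= 0:
        raise SamplerError(f"divergent chain (non-finite state) at iteration {bad_iter}")

    beta_mean = beta_sum / kept
    beta_var = np.maximum(beta_sq / kept - beta_mean**2, 0.0)
    incl = incl_sum / kept
    is_ssvs = prior.model in ("bayesb", "bayesc")
    gebv = Xc @ beta_mean
    ess = {
        "sigma2_beta": effective_sample_size(s2b_c),
        "sigma2_e": effective_sample_size(s2e_c),
    }
    return PosteriorSummary(
        model=prior.model,
        marker_ids=list(gs.marker_ids),
        marker_effect_means=pd.Series(beta_mean, index=gs.marker_ids),
        marker_effect_sds=pd.Series(np.sqrt(beta_var), index=gs.marker_ids),
        inclusion_prob=(pd.Series(incl, index=gs.marker_ids) if is_ssvs else None),
        sigma2_beta=float(np.mean(s2b_c)),
        sigma2_e=float(np.mean(s2e_c)),
        pi_posterior=(float(np.mean(pi_c)) if is_ssvs else None),
        lambda2_posterior=(float(np.mean(lam2_c)) if prior.model == "bl" else None),
        gebv=pd.Series(gebv, index=list(gs.ids)),
        centring=pd.Series(centring, index=gs.marker_ids),
        mu=float(mu),
        ess=ess,
        n_kept=int(kept),
        chains={
            "sigma2_beta": s2b_c,
            "sigma2_e": s2e_c,
            "fixed_of": fixed_of,
            **({"beta": beta_chain} if store_beta_chain else {}),
        },
    )


def gebv_from_markers(summary: PosteriorSummary, g) -> pd.DataFrame:
    """Score individuals with posterior-mean marker effects.

    Dosages are centred with the *training* column means, so a training
    individual scores exactly its ``summary.gebv``. Returns a ranked table
    (rank 1 = largest GEBV, ties by id)."""
    if list(g.marker_ids) != summary.marker_ids:
        extra = sorted(set(g.marker_ids) - set(summary.marker_ids))
        missing = sorted(set(summary.marker_ids) - set(g.marker_ids))
        raise BayesConfigError(
            f"marker mismatch with training set; extra={extra[:5]}, missing={missing[:5]}"
        )
    X = np.asarray(g.dosage, dtype=float)
    if np.isnan(X).any():
        raise BayesConfigError("genotypes contain missing dosages; impute first")
    Xc = X - summary.centring.to_numpy()
    gebv = Xc @ summary.marker_effect_means.to_numpy()
    ids = [str(i) for i in g.ids]
    order = sorted(range(len(ids)), key=lambda k: (-gebv[k], ids[k]))
    rank = np.empty(len(ids), dtype=int)
    for r, k in enumerate(order):
        rank[k] = r + 1
    return pd.DataFrame({"id": ids, "gebv": gebv, "rank": rank})
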