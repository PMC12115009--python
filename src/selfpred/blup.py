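"""Frequentist BLUP models: ABLUP, GBLUP, additive+dominance GBLUP, HBLUP.

Variance components are estimated by REML. Two routes are implemented:

* an exact profile-REML route for a single random term, which rotates the
  phenotyped block of the kinship to its eigenbasis and optimizes the
  variance ratio in one dimension (fast; used by default);
* EM-REML on Henderson's mixed-model equations with optional Aitken
  acceleration, which handles any number of random terms (used for the
  additive+dominance model and available everywhere via ``method="em"``).

Both return BLUPs for every individual in the kinship matrix, including
unphenotyped ones — the hybridization-orchard prediction case — by giving
those individuals empty rows in the incidence matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .geno_io import validate_phenotypes
from .relmat import RelationshipMatrix, build_A, build_D, build_G, build_H

_JITTER = 1e-6  # diagonal stabilizer applied before kinship inversion
_VC_FLOOR = 1e-8  # lower clamp on variance components during EM


class BlupError(ValueError):
    pass


@dataclass
class MixedModelSpec:
    kinship: RelationshipMatrix
    dominance: RelationshipMatrix | None = None
    response: str = "dbh_cm"


@dataclass
class ModelFit:
    model: str
    beta_hat: pd.Series
    gebv: pd.Series
    varcomp: dict
    h2_hat: float
    loglik: float
    converged: bool
    n_iter: int
    dominance_values: pd.Series | None = None
    loglik_path: list = field(default_factory=list)

    def summary_dict(self):
        return {
            "model": self.model,
            "varcomp": {k: float(v) for k, v in self.varcomp.items()},
            "h2_hat": float(self.h2_hat),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


def design_matrices(pheno: pd.DataFrame, kinship_ids):
    """Response, fixed-effect design (intercept + block dummies, reference
    level dropped) and observed-id list, in phenotype-row order."""
    pheno = validate_phenotypes(pheno)
    kin = set(str(s) for s in kinship_ids)
    missing = [i for i in pheno["id"] if i not in kin]
    if missing:
        raise BlupError(f"phenotyped ids absent from kinship: {missing[:5]}")
    y = pheno["dbh_cm"].to_numpy(dtype=float)
    blocks = sorted(pheno["block"].unique())
    X = np.ones((len(pheno), 1 + max(len(blocks) - 1, 0)))
    cols = ["intercept"]
    for k, b in enumerate(blocks[1:]):
        X[:, 1 + k] = (pheno["block"] == b).to_numpy(dtype=float)
        cols.append(f"block[{b}]")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise BlupError("fixed-effect design is rank deficient")
    return y, X, cols, list(pheno["id"])


def reml_loglik(y, X, V):
    """Restricted log-likelihood at a given phenotypic covariance V."""
    n, p = X.shape
    L = np.linalg.cholesky(V)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    yPy = r @ np.linalg.solve(V, r)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    s, logdetXVX = np.linalg.slogdet(XtViX)
    return -0.5 * (logdetV + logdetXVX + yPy) - 0.5 * (n - p) * np.log(2.0 * np.pi)


def solve_mme(y, X, K, lam, jitter: float = 0.0):
    """Henderson's mixed-model equations at a fixed variance ratio
    lam = sigma_e^2 / sigma_a^2, single random term, every individual
    phenotyped (Z = I). Returns (beta, u)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    n, p = X.shape
    Kinv = np.linalg.inv(K + jitter * np.eye(n))
    C = np.block([[X.T @ X, X.T], [X, np.eye(n) + lam * Kinv]])
    rhs = np.concatenate([X.T @ y, y])
    sol = np.linalg.solve(C, rhs)
    return sol[:p], sol[p:]


# ---------------------------------------------------------------------------
# exact 1-D profile REML (single random term)
# ---------------------------------------------------------------------------


def _fit_eigen(y, X, K_obs, K_cross):
    """Profile REML over lambda = sigma_a^2 / sigma_e^2 in the eigenbasis of
    the phenotyped kinship block. K_cross holds kinship rows (all ids x obs)
    for extending BLUPs to every individual."""
    n, p = X.shape
    d, U = np.linalg.eigh(K_obs)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg2_profile(loglam):
        lam = np.exp(loglam)
        w = lam * d + 1.0
        sw = np.sqrt(w)
        Xw = Xt / sw[:, None]
        yw = yt / sw
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        sse = float(np.sum((yw - Xw @ beta) ** 2))
        s2e = sse / (n - p)
        _, logdetXVX = np.linalg.slogdet(XtX / s2e)
        return (
            np.sum(np.log(w))
            + n * np.log(s2e)
            + logdetXVX
            + sse / s2e
        )

    res = minimize_scalar(
        neg2_profile, bounds=(-18.0, 18.0), method="bounded",
        options={"xatol": 1e-9},
    )
    lam = float(np.exp(res.x))
    w = lam * d + 1.0
    sw = np.sqrt(w)
    Xw = Xt / sw[:, None]
    yw = yt / sw
    beta = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
    s2e = float(np.sum((yw - Xw @ beta) ** 2) / (n - p))
    s2a = lam * s2e
    # BLUP: u = s2a * K_cross V^-1 (y - X beta), V^-1 r in eigenbasis
    rt = yt - Xt @ beta
    Vinv_r = U @ (rt / (s2a * d + s2e))
    u_all = s2a * (K_cross @ Vinv_r)
    V = s2a * K_obs + s2e * np.eye(n)
    ll = reml_loglik(y, X, V)
    return beta, u_all, s2a, s2e, ll, res.nfev


# ---------------------------------------------------------------------------
# EM-REML on the mixed-model equations (any number of random terms)
# ---------------------------------------------------------------------------


def _fit_em(y, X, K_list, Kinv_list, Z, tol=1e-6, max_iter=500, aitken=True,
            track_loglik=True):
    """EM-REML. K_list are kinships over all ids; Z (n_obs x q) maps
    observations to ids and is shared by all terms.

    Per iteration the MME are solved at the current variance ratios and the
    classical EM updates are applied:

        sigma_k^2 <- (u_k' K_k^-1 u_k + sigma_e^2 tr(K_k^-1 C^kk)) / q
        sigma_e^2 <- y'(y - X b - sum Z u_k) / (n - p)

    with C^kk the k-th random block of the inverse MME coefficient matrix.
    Aitken extrapolation is attempted periodically and kept only when it
    stays positive and does not reduce the restricted likelihood.
    """
    n, p = X.shape
    q = Z.shape[1]
    nr = len(K_list)
    ZtZ = Z.T @ Z
    XtX = X.T @ X
    XtZ = X.T @ Z
    Zty = Z.T @ y
    Xty = X.T @ y

    vy = float(np.var(y)) or 1.0
    s2 = np.full(nr, vy / (2 * nr))
    s2e = vy / 2.0

    def loglik_at(s2_vec, s2e_val):
        V = s2e_val * np.eye(n)
        for k in range(nr):
            ZK = Z @ K_list[k]
            V = V + s2_vec[k] * (ZK @ Z.T)
        return reml_loglik(y, X, V)

    def solve_mme(s2_vec, s2e_val):
        dim = p + nr * q
        C = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        C[:p, :p] = XtX
        rhs[:p] = Xty
        for k in range(nr):
            a = p + k * q
            C[:p, a : a + q] = XtZ
            C[a : a + q, :p] = XtZ.T
            rhs[a : a + q] = Zty
            for l in range(nr):
                b = p + l * q
                C[a : a + q, b : b + q] = ZtZ
            C[a : a + q, a : a + q] = ZtZ + (s2e_val / s2_vec[k]) * Kinv_list[k]
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        return sol, Cinv

    ll_path = []
    ll_prev = -np.inf
    hist = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sol, Cinv = solve_mme(s2, s2e)
        beta = sol[:p]
        us = [sol[p + k * q : p + (k + 1) * q] for k in range(nr)]
        e_hat = y - X @ beta - Z @ np.sum(us, axis=0)
        new_s2 = np.empty(nr)
        for k in range(nr):
            a = p + k * q
            Ckk = Cinv[a : a + q, a : a + q]
            new_s2[k] = (
                us[k] @ (Kinv_list[k] @ us[k])
                + s2e * np.trace(Kinv_list[k] @ Ckk)
            ) / q
        new_s2e = float(y @ e_hat) / (n - p)
        new_s2 = np.maximum(new_s2, _VC_FLOOR)
        new_s2e = max(new_s2e, _VC_FLOOR)

        theta_old = np.append(s2, s2e)
        theta_new = np.append(new_s2, new_s2e)
        hist.append(theta_new)
        if aitken and len(hist) >= 3 and it % 5 == 0:
            t0, t1, t2 = hist[-3], hist[-2], hist[-1]
            denom = t1 - t0
            ratio = np.divide(t2 - t1, denom, out=np.zeros_like(denom),
                              where=np.abs(denom) > 1e-14)
            ratio = np.clip(ratio, -0.99, 0.99)
            accel = t2 + (t2 - t1) * ratio / (1.0 - ratio)
            if np.all(accel > 0):
                if (not track_loglik) or loglik_at(accel[:nr], accel[nr]) >= loglik_at(
                    t2[:nr], t2[nr]
                ):
                    theta_new = accel
                    hist[-1] = accel

        rel = np.max(np.abs(theta_new - theta_old) / np.maximum(np.abs(theta_old), 1e-12))
        s2, s2e = theta_new[:nr], float(theta_new[nr])
        if track_loglik:
            ll = loglik_at(s2, s2e)
            ll_path.append(ll)
            ll_prev = ll
        if rel < tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"EM-REML did not converge in {max_iter} iterations", stacklevel=2)
    sol, _ = solve_mme(s2, s2e)
    beta = sol[:p]
    us = [sol[p + k * q : p + (k + 1) * q] for k in range(nr)]
    ll = ll_path[-1] if ll_path else loglik_at(s2, s2e)
    return beta, us, s2, s2e, ll, it, converged, ll_path


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def fit_mixed(
    spec: MixedModelSpec,
    pheno: pd.DataFrame,
    method: str = "auto",
    tol: float = 1e-6,
    max_iter: int = 500,
    track_loglik: bool | None = None,
) -> ModelFit:
    """REML fit of y = Xb + u (+ d) + e with u ~ N(0, K sigma_a^2).

    ``method``: "eigen" (single term only), "em", or "auto" (eigen when
    possible). GEBVs cover every id in the kinship.
    """
    K = spec.kinship
    if pheno is None or len(pheno) < 2:
        raise BlupError("need at least 2 phenotyped individuals")
    y, X, xcols, obs_ids = design_matrices(pheno, K.ids)
    all_ids = list(K.ids)
    kind = K.kind

    multi = spec.dominance is not None
    if method == "auto":
        method = "em" if multi else "eigen"
    if method == "eigen" and multi:
        raise BlupError("eigen path handles a single random term; use method='em'")

    if method == "eigen":
        K_obs = K.submatrix(obs_ids)
        K_cross = K.rows(all_ids)[:, [K.ids.index(i) for i in obs_ids]]
        beta, u_all, s2a, s2e, ll, nit = _fit_eigen(y, X, K_obs, K_cross)
        varcomp = {"additive": float(s2a), "residual": float(s2e)}
        fit = ModelFit(
            model=f"{kind}BLUP",
            beta_hat=pd.Series(beta, index=xcols),
            gebv=pd.Series(u_all, index=all_ids),
            varcomp=varcomp,
            h2_hat=float(s2a / (s2a + s2e)),
            loglik=float(ll),
            converged=True,
            n_iter=int(nit),
        )
        return fit

    # EM path: incidence Z over all kinship ids
    pos = {s: k for k, s in enumerate(all_ids)}
    Z = np.zeros((len(obs_ids), len(all_ids)))
    for r, i in enumerate(obs_ids):
        Z[r, pos[i]] = 1.0
    K_list = [K.values]
    names = ["additive"]
    if multi:
        D = spec.dominance
        if list(D.ids) != all_ids:
            D = RelationshipMatrix(ids=all_ids, values=D.submatrix(all_ids), kind=D.kind)
        K_list.append(D.values)
        names.append("dominance")
    Kinv_list = [
        np.linalg.inv(Kk + _JITTER * np.eye(Kk.shape[0])) for Kk in K_list
    ]
    if track_loglik is None:
        track_loglik = len(obs_ids) <= 400
    beta, us, s2, s2e, ll, nit, conv, ll_path = _fit_em(
        y, X, K_list, Kinv_list, Z, tol=tol, max_iter=max_iter,
        track_loglik=track_loglik,
    )
    varcomp = {nm: float(v) for nm, v in zip(names, s2)}
    varcomp["residual"] = float(s2e)
    tot = sum(varcomp.values())
    fit = ModelFit(
        model=("GBLUP-AD" if multi else f"{kind}BLUP"),
        beta_hat=pd.Series(beta, index=xcols),
        gebv=pd.Series(us[0], index=all_ids),
        varcomp=varcomp,
        h2_hat=float(varcomp["additive"] / tot),
        loglik=float(ll),
        converged=conv,
        n_iter=nit,
        dominance_values=(pd.Series(us[1], index=all_ids) if multi else None),
        loglik_path=ll_path,
    )
    return fit


# ---------------------------------------------------------------------------
# model wrappers over a data bundle
# ---------------------------------------------------------------------------


@dataclass
class DataBundle:
    """Everything the nine models may need. ``genotypes`` must be imputed
    (no missing dosages). ``genotyped_ids`` restricts which individuals
    count as genotyped for HBLUP (default: all in ``genotypes``)."""

    genotypes: "GenotypeMatrix"
    pedigree: "Pedigree"
    phenotypes: pd.DataFrame
    genotyped_ids: list | None = None
    hblup_blend: float = 0.05
    hblup_tau: float = 1.0
    hblup_omega: float = 1.0
    cache: dict = field(default_factory=dict)

    def matrix(self, kind: str) -> RelationshipMatrix:
        if kind in self.cache:
            return self.cache[kind]
        if kind == "A":
            M = build_A(self.pedigree)
        elif kind == "G":
            geno = self.genotypes
            if self.genotyped_ids is not None:
                geno = geno.subset(ids=self.genotyped_ids)
            M = build_G(geno)
        elif kind == "D":
            geno = self.genotypes
            if self.genotyped_ids is not None:
                geno = geno.subset(ids=self.genotyped_ids)
            M = build_D(geno)
        elif kind == "H":
            M = build_H(
                self.matrix("A"),
                self.matrix("G"),
                genotyped_ids=self.genotyped_ids or list(self.genotypes.ids),
                tau=self.hblup_tau,
                omega=self.hblup_omega,
                blend=self.hblup_blend,
            )
        else:
            raise BlupError(f"unknown matrix kind {kind!r}")
        self.cache[kind] = M
        return M


def fit_ablup(bundle: DataBundle, pheno=None, **kw) -> ModelFit:
    pheno = bundle.phenotypes if pheno is None else pheno
    return fit_mixed(MixedModelSpec(kinship=bundle.matrix("A")), pheno, **kw)


def fit_gblup(bundle: DataBundle, pheno=None, **kw) -> ModelFit:
    pheno = bundle.phenotypes if pheno is None else pheno
    return fit_mixed(MixedModelSpec(kinship=bundle.matrix("G")), pheno, **kw)


def fit_gblup_ad(bundle: DataBundle, pheno=None, **kw) -> ModelFit:
    pheno = bundle.phenotypes if pheno is None else pheno
    return fit_mixed(
        MixedModelSpec(kinship=bundle.matrix("G"), dominance=bundle.matrix("D")),
        pheno,
        **kw,
    )


def fit_hblup(bundle: DataBundle, pheno=None, **kw) -> ModelFit:
    pheno = bundle.phenotypes if pheno is None else pheno
    return fit_mixed(MixedModelSpec(kinship=bundle.matrix("H")), pheno, **kw)


FREQUENTIST_MODELS = {
    "ablup": fit_ablup,
    "gblup": fit_gblup,
    "gblup-ad": fit_gblup_ad,
    "hblup": fit_hblup,
}


def predict_unphenotyped(fit: ModelFit, ids) -> pd.DataFrame:
    """Ranked GEBV table; rank 1 is the largest GEBV, ties broken by id."""
    ids = [str(i) for i in ids]
    unknown = [i for i in ids if i not in fit.gebv.index]
    if unknown:
        raise KeyError(f"ids absent from fitted kinship: {unknown[:5]}")
    sub = fit.gebv.loc[ids]
    order = sorted(ids, key=lambda i: (-sub[i], i))
    rank_of = {i: r + 1 for r, i in enumerate(order)}
    return pd.DataFrame(
        {"id": ids, "gebv": sub.to_numpy(), "rank": [rank_of[i] for i in ids]}
    )
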