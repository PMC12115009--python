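"""Winsorization, k-fold cross-validation and model comparison.

The evaluation protocol mirrors a standard genomic-prediction benchmark:
the phenotype's lower tail is winsorized once on the full response, ids
are dealt into k folds, each fold's phenotypes are masked in turn, every
requested model is refitted on the remainder and scored on the held-out
records with predictive capacity (Pearson correlation), mean squared
error and R^2. Relationship matrices are built once on the full
individual set; only phenotypes are masked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import BayesPriorConfig, McmcSettings, fit_bayes, gebv_from_markers
from .blup import FREQUENTIST_MODELS, DataBundle
from .geno_io import validate_phenotypes

BAYES_MODELS = ("brr", "bayesa", "bayesb", "bayesc", "bl")
ALL_MODELS = tuple(FREQUENTIST_MODELS) + BAYES_MODELS


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# winsorization and metrics
# ---------------------------------------------------------------------------


def winsorize_lower(y, percentile: float = 0.05) -> np.ndarray:
    """Replace values below the given lower-tail quantile by that quantile.

    One-sided: the upper tail is untouched. The quantile uses linear
    interpolation between order statistics.
    """
    if not 0.0 < percentile < 1.0:
        raise MetricError("percentile must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise MetricError("empty vector")
    q = np.quantile(y, percentile)
    return np.where(y < q, q, y)


def predictive_capacity(y_hat, y) -> float:
    """Pearson correlation between predictions and observations."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y.size < 2:
        raise MetricError("need two equal-length vectors of size >= 2")
    if np.std(y_hat, ddof=1) == 0 or np.std(y, ddof=1) == 0:
        raise MetricError("predictive capacity undefined: zero variance")
    c = np.cov(y_hat, y, ddof=1)
    return float(c[0, 1] / np.sqrt(c[0, 0] * c[1, 1]))


def mean_squared_error(y_hat, y) -> float:
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y.size < 1:
        raise MetricError("need two equal-length vectors")
    return float(np.mean((y_hat - y) ** 2))


def r_squared(y_hat, y) -> float:
    """1 - SSres/SStot, SStot about the observed mean of the validation set.
    Negative when the predictions are worse than predicting the mean."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y.size < 2:
        raise MetricError("need two equal-length vectors of size >= 2")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise MetricError("R^2 undefined: zero total variance")
    ssres = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ssres / sstot


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    folds: pd.DataFrame  # model, fold, pc, mse, r2, n
    fold_assignment: dict  # id -> fold index
    seed: int
    k: int
    winsor_percentile: float
    failures: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.failures

    def aggregate(self) -> pd.DataFrame:
        g = self.folds.groupby("model")
        out = pd.DataFrame(
            {
                "pc_mean": g["pc"].mean(),
                "pc_sd": g["pc"].std(ddof=1),
                "mse_mean": g["mse"].mean(),
                "mse_sd": g["mse"].std(ddof=1),
                "r2_mean": g["r2"].mean(),
                "r2_sd": g["r2"].std(ddof=1),
                "n_folds": g["fold"].count(),
            }
        )
        return out.reset_index()

    def to_json(self, path=None) -> str:
        obj = {
            "seed": self.seed,
            "k": self.k,
            "winsor_percentile": self.winsor_percentile,
            "quantile_convention": "linear interpolation between order statistics",
            "metadata": self.metadata,
            "failures": self.failures,
            "fold_assignment": self.fold_assignment,
            "folds": self.folds.to_dict(orient="records"),
            "aggregate": self.aggregate().to_dict(orient="records"),
        }
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def make_folds(ids, k: int, seed: int) -> dict:
    """Shuffle ids by seed, deal round-robin into k folds of near-equal size."""
    ids = [str(i) for i in ids]
    if len(ids) < k:
        raise MetricError(f"need at least k={k} phenotyped individuals")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return {ids[j]: int(i % k) for i, j in enumerate(perm)}


def _fixed_value(beta_hat: pd.Series, block: str) -> float:
    v = float(beta_hat["intercept"])
    key = f"block[{block}]"
    if key in beta_hat.index:
        v += float(beta_hat[key])
    return v


def kfold_cv(
    models,
    bundle: DataBundle,
    k: int = 10,
    seed: int = 0,
    winsor_percentile: float = 0.05,
    mcmc: McmcSettings | None = None,
    priors: dict | None = None,
    blup_method: str = "auto",
) -> CVReport:
    """Cross-validate any mix of the nine models on one data bundle.

    Bayesian models get per-fold refits of marker effects with training-set
    centring; frequentist models reuse the full-set relationship matrices
    (phenotype masking only). ``priors`` may override the default
    ``BayesPriorConfig`` per model name.
    """
    models = [str(m).lower() for m in models]
    unknown = [m for m in models if m not in ALL_MODELS]
    if unknown:
        raise MetricError(f"unknown models {unknown}; valid: {sorted(ALL_MODELS)}")
    pheno = validate_phenotypes(bundle.phenotypes)
    pheno = pheno.assign(dbh_cm=winsorize_lower(pheno["dbh_cm"].to_numpy(), winsor_percentile))
    fold_of = make_folds(pheno["id"], k, seed)
    pheno = pheno.assign(fold=[fold_of[i] for i in pheno["id"]])
    mcmc = mcmc or McmcSettings()
    priors = priors or {}

    rows = []
    failures = []
    for model in models:
        for fold in range(k):
            train = pheno.loc[pheno["fold"] != fold, ["id", "block", "dbh_cm"]]
            test = pheno.loc[pheno["fold"] == fold, ["id", "block", "dbh_cm"]]
            try:
                if model in FREQUENTIST_MODELS:
                    fit = FREQUENTIST_MODELS[model](
                        bundle, pheno=train, method=(
                            "em" if model == "gblup-ad" else blup_method
                        ),
                    )
                    genetic = fit.gebv.loc[list(test["id"])].to_numpy()
                    if fit.dominance_values is not None:
                        genetic = genetic + fit.dominance_values.loc[
                            list(test["id"])
                        ].to_numpy()
                    fixed = np.array(
                        [_fixed_value(fit.beta_hat, b) for b in test["block"]]
                    )
                    y_hat = fixed + genetic
                else:
                    prior = priors.get(model, _default_prior(model))
                    fold_mcmc = McmcSettings(
                        n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
                        seed=int(mcmc.seed) + fold,
                    )
                    summ = fit_bayes(bundle.genotypes, train, prior, fold_mcmc)
                    scored = gebv_from_markers(
                        summ, bundle.genotypes.subset(ids=list(test["id"]))
                    ).set_index("id")
                    fixed_of = summ.chains.get("fixed_of", {})
                    default_fixed = (
                        float(np.mean(list(fixed_of.values()))) if fixed_of else 0.0
                    )
                    fixed = np.array(
                        [fixed_of.get(b, default_fixed) for b in test["block"]]
                    )
                    y_hat = fixed + scored.loc[list(test["id"]), "gebv"].to_numpy()
                y_obs = test["dbh_cm"].to_numpy()
                rows.append(
                    {
                        "model": model,
                        "fold": fold,
                        "pc": predictive_capacity(y_hat, y_obs),
                        "mse": mean_squared_error(y_hat, y_obs),
                        "r2": r_squared(y_hat, y_obs),
                        "n": len(test),
                    }
                )
            except Exception as err:  # per-fold failure is recorded, not fatal
                failures.append({"model": model, "fold": fold, "error": str(err)})
    report = CVReport(
        folds=pd.DataFrame(rows, columns=["model", "fold", "pc", "mse", "r2", "n"]),
        fold_assignment=fold_of,
        seed=seed,
        k=k,
        winsor_percentile=winsor_percentile,
        failures=failures,
        metadata={"models": models, "mcmc": mcmc.__dict__},
    )
    return report


def _default_prior(model: str) -> BayesPriorConfig:
    if model == "bayesb":
        return BayesPriorConfig(model=model, pi=0.99, estimate_pi=False)
    if model == "bayesc":
        return BayesPriorConfig(model=model, pi=0.5, estimate_pi=True)
    return BayesPriorConfig(model=model)


def comparison_report(cv: CVReport) -> pd.DataFrame:
    """Models ranked by mean predictive capacity (descending, ties broken
    alphabetically), with MSE and R^2 mean +/- SD columns."""
    agg = cv.aggregate()
    agg = agg.sort_values(["pc_mean", "model"], ascending=[False, True]).reset_index(
        drop=True
    )
    agg.insert(0, "rank", np.arange(1, len(agg) + 1))
    return agg
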