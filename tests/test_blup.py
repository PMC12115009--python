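"""Mixed-model fitting: oracle equivalence, EM behaviour, predictions."""

import numpy as np
import pandas as pd
import pytest

from selfpred.blup import (
    BlupError,
    MixedModelSpec,
    ModelFit,
    fit_ablup,
    fit_gblup,
    fit_gblup_ad,
    fit_hblup,
    fit_mixed,
    predict_unphenotyped,
    solve_mme,
)
from selfpred.experiments import _random_mixed_fixture, gls_blup_oracle
from selfpred.relmat import RelationshipMatrix


def _as_pheno(y, ids=None, blocks=None):
    n = len(y)
    ids = ids or [f"I{i}" for i in range(n)]
    blocks = blocks or ["B1"] * n
    return pd.DataFrame({"id": ids, "block": blocks, "dbh_cm": y})


def _kin(K, ids=None, kind="G"):
    ids = ids or [f"I{i}" for i in range(K.shape[0])]
    return RelationshipMatrix(ids=ids, values=K, kind=kind)


@pytest.mark.parametrize("fixture_seed", range(8))
def test_mme_equals_gls_oracle(fixture_seed):
    """Henderson MME at fixed variance ratio reproduces the direct GLS
    solve on random small instances."""
    rng = np.random.default_rng(fixture_seed)
    y, X, K, s2a, s2e = _random_mixed_fixture(rng)
    beta_m, u_m = solve_mme(y, X, K, s2e / s2a)
    beta_o, u_o = gls_blup_oracle(y, X, K, s2a, s2e)
    np.testing.assert_allclose(beta_m, beta_o, atol=1e-8)
    np.testing.assert_allclose(u_m, u_o, atol=1e-8)


def test_eigen_and_em_paths_agree(small_bundle):
    G = small_bundle.matrix("G")
    spec = MixedModelSpec(kinship=G)
    fe = fit_mixed(spec, small_bundle.phenotypes, method="eigen")
    fm = fit_mixed(spec, small_bundle.phenotypes, method="em", tol=1e-9)
    assert fm.h2_hat == pytest.approx(fe.h2_hat, abs=5e-3)
    assert np.max(np.abs(fe.gebv - fm.gebv)) < 1e-3


def test_em_loglik_nondecreasing(small_bundle):
    G = small_bundle.matrix("G")
    sub = small_bundle.phenotypes.head(80)
    fit = fit_mixed(MixedModelSpec(kinship=G), sub, method="em")
    ll = np.array(fit.loglik_path)
    assert len(ll) > 2
    assert np.all(np.diff(ll) > -1e-6)


def test_constant_phenotype_boundary():
    rng = np.random.default_rng(0)
    K = np.eye(20) + 0.2
    pheno = _as_pheno(np.full(20, 7.0))
    fit = fit_mixed(MixedModelSpec(kinship=_kin(K)), pheno)
    assert fit.varcomp["additive"] < 1e-4
    assert np.max(np.abs(fit.gebv)) < 1e-3


def test_shrinkage_bound():
    rng = np.random.default_rng(3)
    y, X, K, s2a, s2e = _random_mixed_fixture(rng)
    _, u = solve_mme(y, X, K, s2e / s2a)
    assert np.max(np.abs(u)) <= np.max(np.abs(y - y.mean())) + 1e-9


def test_ablup_equals_gblup_when_A_equals_G(small_bundle):
    """Identical kinship means identical model regardless of its label."""
    G = small_bundle.matrix("G")
    fa = fit_mixed(MixedModelSpec(kinship=RelationshipMatrix(G.ids, G.values, "A")),
                   small_bundle.phenotypes)
    fg = fit_mixed(MixedModelSpec(kinship=G), small_bundle.phenotypes)
    assert np.max(np.abs(fa.gebv - fg.gebv)) < 1e-6


def test_hblup_everyone_genotyped_blend_zero(small_bundle):
    from selfpred.blup import DataBundle

    b = DataBundle(
        genotypes=small_bundle.genotypes,
        pedigree=small_bundle.pedigree,
        phenotypes=small_bundle.phenotypes,
        hblup_blend=0.0,
    )
    fh = fit_hblup(b)
    fg = fit_gblup(b)
    assert np.max(np.abs(fh.gebv - fg.gebv)) < 1e-6


def test_gblup_ad_on_additive_data_shrinks_dominance():
    """With a purely additive trait, the dominance component hits its
    boundary in most replicates."""
    from selfpred.geno_io import impute_mean
    from selfpred.simdata import SimConfig, simulate_founders, simulate_phenotypes, simulate_progeny
    from selfpred.blup import DataBundle

    hits = 0
    n_rep = 5
    for r in range(n_rep):
        cfg = SimConfig(
            n_parents=10, offspring_per_parent=(20, 20), n_markers=300,
            n_chromosomes=3, d2_dominance=0.0, outlier_rate=0.0,
            n_orchard=0, seed=100 + r,
        )
        founders = simulate_founders(cfg)
        progeny, ped, truth = simulate_progeny(founders, cfg)
        pheno = simulate_phenotypes(progeny, truth, cfg)
        b = DataBundle(genotypes=impute_mean(progeny), pedigree=ped, phenotypes=pheno)
        fit = fit_gblup_ad(b, track_loglik=False)
        vc = fit.varcomp
        if vc["dominance"] < 0.2 * (vc["additive"] + vc["residual"]):
            hits += 1
    assert hits >= 3


def test_unphenotyped_gebv_duplicate_individual():
    """An unphenotyped clone of a phenotyped individual (identical kinship
    row) receives the same GEBV."""
    rng = np.random.default_rng(8)
    n = 15
    Z = rng.normal(size=(n, 40))
    K0 = Z @ Z.T / 40 + 0.3 * np.eye(n)
    # append a clone of individual 0: duplicate row/col
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = K0
    K[n, :n] = K0[0, :]
    K[:n, n] = K0[:, 0]
    K[n, n] = K0[0, 0]
    ids = [f"I{i}" for i in range(n)] + ["clone"]
    y = rng.normal(10, 2, size=n)
    fit = fit_mixed(MixedModelSpec(kinship=_kin(K, ids)), _as_pheno(y, ids=ids[:n]))
    assert fit.gebv["clone"] == pytest.approx(fit.gebv["I0"], abs=1e-8)


def test_predict_unphenotyped_ranking_and_ties():
    fit = ModelFit(
        model="GBLUP",
        beta_hat=pd.Series({"intercept": 0.0}),
        gebv=pd.Series({"a": 1.0, "b": 1.0, "c": 2.0}),
        varcomp={"additive": 1, "residual": 1},
        h2_hat=0.5, loglik=0.0, converged=True, n_iter=1,
    )
    tbl = predict_unphenotyped(fit, ["b", "a", "c"]).set_index("id")
    assert tbl.loc["c", "rank"] == 1
    assert tbl.loc["a", "rank"] == 2  # tie with b broken lexicographically
    assert tbl.loc["b", "rank"] == 3
    with pytest.raises(KeyError):
        predict_unphenotyped(fit, ["zzz"])


def test_orchard_prediction_tracks_truth(small_bundle, small_population):
    _, _, _, truth, _ = small_population
    fit = fit_gblup(small_bundle)
    tbl = predict_unphenotyped(fit, truth.orchard_ids).set_index("id")
    bv = truth.true_breeding_values.loc[truth.orchard_ids]
    r = np.corrcoef(tbl["gebv"], bv)[0, 1]
    assert r > 0
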