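"""Relationship matrices: tabular A, VanRaden G, dominance D, single-step H."""

import numpy as np
import pandas as pd
import pytest

from selfpred.geno_io import GenotypeMatrix, Pedigree
from selfpred.relmat import RelmatError, build_A, build_D, build_G, build_H


def _geno(dosage, ids=None):
    n, m = np.asarray(dosage).shape
    ids = ids or [f"I{i}" for i in range(n)]
    mids = [f"M{j}" for j in range(m)]
    return GenotypeMatrix(
        ids=ids, marker_ids=mids, dosage=np.asarray(dosage, dtype=float),
        marker_map=pd.DataFrame({"marker": mids, "chrom": 1, "pos_bp": range(m)}),
    )


# ---- A --------------------------------------------------------------------


def test_A_founders_identity():
    ped = Pedigree(pd.DataFrame({"id": list("abc"), "sire": [None] * 3, "dam": [None] * 3}))
    A = build_A(ped)
    np.testing.assert_allclose(A.values, np.eye(3))


def test_A_one_and_two_selfings(selfing_pedigree):
    A = build_A(selfing_pedigree)
    ids = A.ids
    a = pd.DataFrame(A.values, index=ids, columns=ids)
    assert a.loc["S1", "S1"] == pytest.approx(1.5)  # F = 0.5
    assert a.loc["P", "S1"] == pytest.approx(1.0)
    assert a.loc["S2", "S2"] == pytest.approx(1.75)  # F = 1 - 0.5^2
    assert a.loc["O", "O"] == pytest.approx(1.0)  # outcross, unrelated parents


# ---- G --------------------------------------------------------------------


def test_G_hand_values_single_marker():
    """Dosages (0,1,2) at p=0.5: denominator 0.5, diag (2,0,2), G_13 = -2."""
    G = build_G(_geno([[0], [1], [2]]))
    np.testing.assert_allclose(np.diag(G.values), [2.0, 0.0, 2.0])
    assert G.values[0, 2] == pytest.approx(-2.0)


def test_G_duplicate_individuals():
    G = build_G(_geno([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]]))
    np.testing.assert_allclose(G.values[0], G.values[1])
    assert G.values[0, 1] == pytest.approx(G.values[0, 0])


def test_G_fully_homozygous_diagonal():
    """Hom dosages at p=0.5 for all m markers give diagonal 2."""
    rng = np.random.default_rng(1)
    m = 40
    half = rng.permutation(m) < m // 2
    row = np.where(half, 0.0, 2.0)
    dos = np.vstack([row, 2.0 - row])  # keeps p = 0.5 per column
    G = build_G(_geno(dos))
    np.testing.assert_allclose(np.diag(G.values), [2.0, 2.0])


def test_G_monomorphic_error():
    with pytest.raises(RelmatError, match="monomorphic"):
        build_G(_geno([[2, 2], [2, 2]]))


# ---- D --------------------------------------------------------------------


def test_D_hand_values_single_marker():
    """p=0.5 coding (-0.5, 0.5, -0.5), denom 0.25: diag 1, D_12 = -1."""
    D = build_D(_geno([[0], [1], [2]]))
    np.testing.assert_allclose(np.diag(D.values), [1.0, 1.0, 1.0])
    assert D.values[0, 1] == pytest.approx(-1.0)


def test_D_hwe_mean_diagonal_near_one():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.2, 0.8, size=400)
    dos = rng.binomial(1, p, size=(300, 400)) + rng.binomial(1, p, size=(300, 400))
    D = build_D(_geno(dos.astype(float)))
    assert np.diag(D.values).mean() == pytest.approx(1.0, abs=0.05)


def test_D_fully_homozygous_uses_hom_codes():
    D = build_D(_geno([[0, 2], [2, 0]]))
    assert not np.allclose(D.values, 0.0)


# ---- H --------------------------------------------------------------------


def _ag_fixture(seed=0, n=12, n_geno=7):
    rng = np.random.default_rng(seed)
    ped_rows = [(f"I{i}", None, None) for i in range(4)]
    for i in range(4, n):
        s = f"I{rng.integers(0, i)}"
        d = f"I{rng.integers(0, i)}"
        ped_rows.append((f"I{i}", s, d))
    ped = Pedigree(pd.DataFrame(ped_rows, columns=["id", "sire", "dam"]))
    A = build_A(ped)
    geno_ids = [f"I{i}" for i in range(n - n_geno, n)]
    dos = rng.binomial(2, 0.5, size=(n_geno, 60)).astype(float)
    G = build_G(_geno(dos, ids=geno_ids))
    return A, G, geno_ids


def test_H_reduces_to_A():
    """G replaced by A22 at blend 0 returns A."""
    A, G, geno_ids = _ag_fixture()
    from selfpred.relmat import RelationshipMatrix

    A22 = RelationshipMatrix(ids=geno_ids, values=A.submatrix(geno_ids), kind="G")
    H = build_H(A, A22, geno_ids, blend=0.0)
    np.testing.assert_allclose(H.values, A.values, atol=1e-8)


def test_H_reduces_to_G_all_genotyped():
    A, G, _ = _ag_fixture()
    from selfpred.relmat import RelationshipMatrix

    dos = np.random.default_rng(3).binomial(2, 0.5, size=(len(A.ids), 80)).astype(float)
    Gall = build_G(_geno(dos, ids=list(A.ids)))
    H = build_H(A, Gall, list(A.ids), blend=0.0)
    np.testing.assert_allclose(H.values, Gall.values, atol=1e-8)


def test_H_symmetric_psd_after_blend():
    A, G, geno_ids = _ag_fixture(seed=9)
    H = build_H(A, G, geno_ids, blend=0.05)
    np.testing.assert_allclose(H.values, H.values.T, atol=1e-10)
    w = np.linalg.eigvalsh(H.values)
    assert w.min() > -1e-8


def test_H_tau_omega_unity_matches_direct():
    """The inverse-form construction at tau=omega=1 equals the direct one."""
    A, G, geno_ids = _ag_fixture(seed=2)
    H1 = build_H(A, G, geno_ids, blend=0.05)
    H2 = build_H(A, G, geno_ids, tau=1.0 + 1e-12, omega=1.0, blend=0.05)
    np.testing.assert_allclose(H1.values, H2.values, atol=1e-3)


# ---- simulated-data invariants -------------------------------------------


def test_genomic_inbreeding_mirrors_pedigree(small_population):
    founders, progeny, ped, truth, _ = small_population
    from selfpred.geno_io import impute_mean

    all_g = GenotypeMatrix(
        ids=founders.ids + progeny.ids,
        marker_ids=list(founders.marker_ids),
        dosage=np.vstack([founders.dosage, progeny.dosage]),
        marker_map=founders.marker_map.copy(),
    )
    G = build_G(impute_mean(all_g))
    off = ped.table[ped.table["cohort"] != "founder"]
    selfed = list(off.loc[off["sire"] == off["dam"], "id"])
    d = pd.Series(np.diag(G.values), index=G.ids)
    assert d.loc[selfed].mean() > d.loc[founders.ids].mean()


def test_A22_correlates_with_G(small_bundle):
    A = small_bundle.matrix("A")
    G = small_bundle.matrix("G")
    a = A.submatrix(G.ids)
    iu = np.triu_indices(len(G.ids), k=1)
    r = np.corrcoef(a[iu], G.values[iu])[0, 1]
    assert r > 0.5
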