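"""LD statistics, marker selection, LOD/Delta paternity, classification."""

import numpy as np
import pandas as pd
import pytest

from selfpred.geno_io import GenotypeMatrix
from selfpred.popgen import (
    DeltaThreshold,
    assign_paternity,
    classify_offspring,
    delta_threshold,
    em_gametic_D,
    expand_counts_to_assignments,
    ld_decay_curve,
    ld_pairs,
    load_reference_family_counts,
    paternity_lod,
    select_informative_markers,
)


def _geno(dosage, chrom=None, pos=None, ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    mids = [f"M{j}" for j in range(m)]
    return GenotypeMatrix(
        ids=ids or [f"I{i}" for i in range(n)],
        marker_ids=mids,
        dosage=dosage,
        marker_map=pd.DataFrame(
            {"marker": mids, "chrom": chrom or [1] * m, "pos_bp": pos or list(range(1, m + 1))}
        ),
    )


# ---- LD -------------------------------------------------------------------


def test_duplicated_marker_r2_one():
    rng = np.random.default_rng(0)
    col = rng.binomial(2, 0.4, 50).astype(float)
    g = _geno(np.column_stack([col, col]))
    pairs = ld_pairs(g, max_distance_bp=100)
    assert pairs["r2"].iloc[0] == pytest.approx(1.0)


def test_r2_invariant_to_allele_flip():
    rng = np.random.default_rng(1)
    a = rng.binomial(2, 0.4, 80).astype(float)
    b = np.clip(a + rng.binomial(2, 0.3, 80) - 1, 0, 2)
    r1 = ld_pairs(_geno(np.column_stack([a, b])), 100)["r2"].iloc[0]
    r2 = ld_pairs(_geno(np.column_stack([2 - a, b])), 100)["r2"].iloc[0]
    assert r1 == pytest.approx(r2)


def test_em_D_zero_under_independence():
    """Known phased haplotype pools with p(AB) = p(A)p(B) give D = 0."""
    # construct genotypes from independent haplotypes, all combos equally
    h1 = np.repeat([1, 1, 0, 0], 25)
    h2 = np.tile([1, 0, 1, 0], 25)
    x1 = h1[:50] + h1[50:]
    x2 = h2[:50] + h2[50:]
    D = em_gametic_D(x1, x2)
    assert D == pytest.approx(0.0, abs=0.05)


def test_em_D_perfect_coupling():
    x = np.array([0, 0, 1, 1, 2, 2] * 10)
    D = em_gametic_D(x, x)
    p = x.mean() / 2
    assert D == pytest.approx(p * (1 - p), abs=0.02)


def test_null_r2_near_one_over_n():
    rng = np.random.default_rng(2)
    n = 1000
    g = _geno(rng.binomial(2, 0.5, size=(n, 40)).astype(float))
    pairs = ld_pairs(g, max_distance_bp=10**9)
    mean_r2 = pairs["r2"].mean()
    se = pairs["r2"].std(ddof=1) / np.sqrt(len(pairs))
    assert abs(mean_r2 - 1.0 / n) < 3 * se + 5e-4


def test_same_chromosome_only_and_distance_cap():
    g = _geno(np.random.default_rng(3).binomial(2, 0.5, (30, 4)).astype(float),
              chrom=[1, 1, 2, 2], pos=[100, 200, 100, 50000])
    pairs = ld_pairs(g, max_distance_bp=1000)
    keys = set(zip(pairs["marker_i"], pairs["marker_j"]))
    assert keys == {("M0", "M1")}  # cross-chromosome and far pairs excluded


def test_decay_single_bin_and_conservation():
    rng = np.random.default_rng(4)
    g = _geno(rng.binomial(2, 0.5, (60, 10)).astype(float))
    pairs = ld_pairs(g, max_distance_bp=10**9)
    one = ld_decay_curve(pairs, bin_width_bp=10**6)
    assert len(one) == 1
    assert one["mean_r2"].iloc[0] == pytest.approx(pairs["r2"].mean())
    halved = ld_decay_curve(pairs, bin_width_bp=2)
    assert halved["n_pairs"].sum() == one["n_pairs"].sum() == len(pairs)


# ---- marker selection -----------------------------------------------------


def test_select_markers_heterozygosity_ranking():
    # p = 0.5 beats p ~ 0.05; ties fall back to id order
    dos = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 1], [2, 0, 1]], dtype=float)
    g = _geno(dos)
    p = g.allele_freq
    top = select_informative_markers(g, 1)
    assert top == [g.marker_ids[int(np.argmax(2 * p * (1 - p)))]]
    assert select_informative_markers(g, 3)  # n = all markers works
    allsel = select_informative_markers(_geno(np.ones((4, 3))), 3)
    assert allsel == ["M0", "M1", "M2"]  # all tied -> id order


# ---- paternity ------------------------------------------------------------


def test_lod_exclusion_with_zero_error():
    """Candidate carrying a unique allele: only the true father survives
    exclusion when the offspring is heterozygous for it."""
    # one marker: mother 0, true father 2, alternative father 0; offspring 1
    p = np.array([0.3])
    lod_true = paternity_lod([1], [0], [2], p, error_rate=0.0)
    lod_false = paternity_lod([1], [0], [0], p, error_rate=0.0)
    assert lod_true > 0
    assert lod_false == -np.inf


def test_identical_candidates_delta_zero():
    rng = np.random.default_rng(5)
    m = 100
    mother = rng.binomial(2, 0.5, m)
    cand = rng.binomial(2, 0.5, m)
    off = np.floor((mother + cand) / 2).astype(int)
    p = np.full(m, 0.5)
    l1 = paternity_lod(off, mother, cand, p, 0.05)
    l2 = paternity_lod(off, mother, cand.copy(), p, 0.05)
    assert l1 == pytest.approx(l2)


def test_missing_markers_skipped():
    p = np.array([0.5, 0.5])
    full = paternity_lod([1, 1], [1, 1], [1, 1], p, 0.05)
    with_missing = paternity_lod([1, np.nan], [1, 1], [1, 1], p, 0.05)
    assert with_missing == pytest.approx(full / 2)


def _candidate_pool(n_cand=10, m=200, seed=0):
    rng = np.random.default_rng(seed)
    dos = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n_cand, m)).astype(float)
    return _geno(dos, ids=[f"C{i}" for i in range(n_cand)])


def test_delta_threshold_reproducible_and_stable():
    cand = _candidate_pool()
    cfg = DeltaThreshold(n_replicates=2000)
    t1 = delta_threshold(cand, cfg, seed=7)
    t2 = delta_threshold(cand, cfg, seed=7)
    assert t1.delta_critical == t2.delta_critical
    assert t1.delta_critical >= 0
    t4 = delta_threshold(cand, DeltaThreshold(n_replicates=4000), seed=7)
    # Monte-Carlo stability: doubling replicates moves the threshold little
    assert abs(t4.delta_critical - t1.delta_critical) <= 0.05 * max(t1.delta_critical, 1.0)


def test_delta_threshold_zero_with_perfect_information():
    """Error-free, fully distinguishable candidates: every top assignment
    is correct, so the calibrated threshold is 0."""
    cand = _candidate_pool(n_cand=5, m=500, seed=1)
    t = delta_threshold(cand, DeltaThreshold(n_replicates=500, error_rate=0.0), seed=3)
    assert t.delta_critical == 0.0


def test_single_candidate_warns():
    cand = _candidate_pool(n_cand=1)
    with pytest.warns(UserWarning):
        t = delta_threshold(cand, DeltaThreshold(n_replicates=100), seed=0)
    assert t.delta_critical == 0.0


def test_assign_paternity_end_to_end():
    """Selfed and crossed offspring of a simulated pool are mostly
    recovered with the right labels."""
    rng = np.random.default_rng(11)
    cand = _candidate_pool(n_cand=8, m=300, seed=2)
    codes = np.asarray(cand.dosage, dtype=int)
    n_off = 60
    mothers = rng.integers(0, 8, n_off)
    selfed = rng.uniform(size=n_off) < 0.6
    fathers = np.where(selfed, mothers, (mothers + rng.integers(1, 8, n_off)) % 8)
    from selfpred.popgen import _mendelian_offspring

    off = _mendelian_offspring(codes[mothers], codes[fathers], rng)
    ids = [f"O{i}" for i in range(n_off)]
    all_g = GenotypeMatrix(
        ids=list(cand.ids) + ids,
        marker_ids=list(cand.marker_ids),
        dosage=np.vstack([cand.dosage, off]),
        marker_map=cand.marker_map,
    )
    mother_of = {f"O{i}": cand.ids[mothers[i]] for i in range(n_off)}
    res = assign_paternity(
        all_g, ids, mother_of, list(cand.ids), error_rate=0.02, seed=1
    )
    assert (res["delta"] >= 0).all()
    merged = res.assign(true=np.where(selfed, "selfed", "crossed"))
    assigned = merged[merged["assignment"] != "unassigned"]
    agree = (assigned["assignment"] == assigned["true"]).mean()
    assert agree > 0.9
    summ = classify_offspring(res)
    assert summ.n_selfed + summ.n_crossed + summ.n_unassigned == n_off


# ---- classification summaries --------------------------------------------


def test_reference_family_counts_summary():
    counts = load_reference_family_counts()
    summ = classify_offspring(expand_counts_to_assignments(counts))
    assert summ.n_total == 523
    assert summ.n_selfed == 326 and summ.pct_selfed == 62.33
    assert summ.n_crossed == 197 and summ.pct_crossed == 37.67
    g25 = summ.per_family.set_index("family").loc["GEN25"]
    assert g25["n_total"] == 32 and g25["n_selfed"] == 32 and g25["pct_selfed"] == 100.0


def test_all_selfed_classification():
    tbl = pd.DataFrame(
        {"known_mother": ["F1"] * 4, "assignment": ["selfed"] * 4}
    )
    summ = classify_offspring(tbl)
    assert summ.pct_selfed == 100.0 and summ.n_crossed == 0
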