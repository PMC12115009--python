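"""Population-genetic analyses: pairwise LD with distance decay, and
parentage assignment by LOD scores with the Delta statistic.

LD is reported as the squared Pearson correlation of unphased dosage
vectors (composite LD); the classical gametic D is available through a
two-locus EM haplotype-frequency estimator. Parentage follows the
likelihood framework of known-mother paternity testing: each candidate
father's LOD compares the Mendelian transition probability of the
offspring genotype against a random father drawn from allele
frequencies, with genotyping error absorbed by mixing transition
probabilities toward their Hardy-Weinberg expectation. Assignment
confidence uses the Delta statistic (top LOD minus runner-up LOD)
against a simulated threshold.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix


class PopgenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_pairs(
    g: GenotypeMatrix,
    max_distance_bp: int,
    min_maf: float = 0.05,
    with_D: bool = False,
) -> pd.DataFrame:
    """All same-chromosome marker pairs within ``max_distance_bp``.

    Returns columns marker_i, marker_j, chrom, distance_bp, r2 (and D from
    EM haplotype frequencies when ``with_D``). Markers below ``min_maf``
    or monomorphic are skipped (their count is in ``.attrs['n_skipped']``).
    Missing dosages are mean-imputed marker-wise for the correlation.
    """
    mm = g.marker_map
    if mm is None or len(mm) != g.n_markers:
        raise PopgenError("marker map required for LD analysis")
    maf = g.maf
    usable = maf >= min_maf
    n_skipped = int((~usable).sum())
    rows = []
    dos = g.dosage.copy()
    # mean-impute for the correlation only
    p = g.allele_freq
    nan_r, nan_c = np.nonzero(np.isnan(dos))
    if nan_r.size:
        dos[nan_r, nan_c] = 2.0 * p[nan_c]
    chrom_arr = mm["chrom"].to_numpy()
    pos_arr = mm["pos_bp"].to_numpy()
    marker_arr = np.asarray(g.marker_ids, dtype=object)
    for c in pd.unique(chrom_arr):
        idx = np.flatnonzero((chrom_arr == c) & usable)
        if idx.size < 2:
            continue
        sub = dos[:, idx]
        pos = pos_arr[idx]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub.T)
        r2 = corr**2
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = pos[jj] - pos[ii]
        keep = dist <= max_distance_bp
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        for a, b, d in zip(ii, jj, dist):
            rec = {
                "marker_i": marker_arr[idx[a]],
                "marker_j": marker_arr[idx[b]],
                "chrom": c,
                "distance_bp": int(d),
                "r2": float(r2[a, b]),
            }
            if with_D:
                rec["D"] = em_gametic_D(dos[:, idx[a]], dos[:, idx[b]])
            rows.append(rec)
    out = pd.DataFrame(
        rows, columns=["marker_i", "marker_j", "chrom", "distance_bp", "r2"]
        + (["D"] if with_D else [])
    )
    out.attrs["n_skipped"] = n_skipped
    return out


def em_gametic_D(x1, x2, n_iter: int = 50, tol: float = 1e-10) -> float:
    """Gametic D = p11 - p1*p2 from unphased diplotypes via two-locus EM.

    Double heterozygotes are ambiguous (coupling vs repulsion); EM splits
    them by the current haplotype-frequency estimate.
    """
    x1 = np.asarray(np.round(x1), dtype=int)
    x2 = np.asarray(np.round(x2), dtype=int)
    ok = (x1 >= 0) & (x1 <= 2) & (x2 >= 0) & (x2 <= 2)
    x1, x2 = x1[ok], x2[ok]
    n = x1.size
    if n == 0:
        raise PopgenError("no complete genotype pairs")
    p1 = x1.mean() / 2.0
    p2 = x2.mean() / 2.0
    # haplotype counts resolvable without phase: per individual the two
    # haplotypes are determined unless x1 == x2 == 1
    amb = (x1 == 1) & (x2 == 1)
    n_amb = int(amb.sum())
    # for unambiguous individuals the two haplotypes are forced; count them
    c = np.zeros(4)  # order: 11, 10, 01, 00
    for g1, g2, is_amb in zip(x1, x2, amb):
        if is_amb:
            continue
        # enumerate the forced pair of haplotypes
        a_alleles = [1] * g1 + [0] * (2 - g1)
        b_alleles = [1] * g2 + [0] * (2 - g2)
        if g1 == 1:
            # locus 1 het, locus 2 hom: pairing is forced up to symmetry
            pairs = [(1, b_alleles[0]), (0, b_alleles[1])]
        elif g2 == 1:
            pairs = [(a_alleles[0], 1), (a_alleles[1], 0)]
        else:
            pairs = list(zip(a_alleles, b_alleles))
        for a, b in pairs:
            c[(1 - a) * 2 + (1 - b)] += 1.0
    f = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])
    f = np.maximum(f, 1e-12)
    f /= f.sum()
    total = 2.0 * n
    for _ in range(n_iter):
        # split double hets between coupling (11/00) and repulsion (10/01)
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        w = coup / (coup + rep) if coup + rep > 0 else 0.5
        newc = c.copy()
        newc[0] += n_amb * w
        newc[3] += n_amb * w
        newc[1] += n_amb * (1.0 - w)
        newc[2] += n_amb * (1.0 - w)
        fn = newc / total
        if np.max(np.abs(fn - f)) < tol:
            f = fn
            break
        f = fn
    p1h = f[0] + f[1]
    p2h = f[0] + f[2]
    return float(f[0] - p1h * p2h)


def ld_decay_curve(pairs: pd.DataFrame, bin_width_bp: int) -> pd.DataFrame:
    """Distance-binned mean r^2: columns bin_mid_bp, mean_r2, n_pairs.

    Empty bins over the observed range are reported with n_pairs=0 and
    NaN mean (no interpolation).
    """
    if pairs.empty:
        raise PopgenError("empty LD pair table")
    d = pairs["distance_bp"].to_numpy()
    b = (d // bin_width_bp).astype(int)
    out = []
    for k in range(int(b.max()) + 1):
        mask = b == k
        out.append(
            {
                "bin_mid_bp": int((k + 0.5) * bin_width_bp),
                "mean_r2": float(pairs.loc[mask, "r2"].mean()) if mask.any() else np.nan,
                "n_pairs": int(mask.sum()),
            }
        )
    return pd.DataFrame(out)


def plot_ld_decay(decay: pd.DataFrame, path, title: str = "LD decay"):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ok = decay["n_pairs"] > 0
    ax.plot(decay.loc[ok, "bin_mid_bp"] / 1e3, decay.loc[ok, "mean_r2"], "o-", ms=3)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# paternity: LOD, Delta, threshold, classification
# ---------------------------------------------------------------------------


def select_informative_markers(g: GenotypeMatrix, n: int = 723) -> list:
    """Top-n markers by expected heterozygosity 2pq (ties: MAF, then id)."""
    if n > g.n_markers:
        raise PopgenError(f"requested {n} markers but only {g.n_markers} available")
    p = g.allele_freq
    het = 2.0 * p * (1.0 - p)
    maf = np.minimum(p, 1.0 - p)
    order = sorted(
        range(g.n_markers), key=lambda j: (-het[j], -maf[j], g.marker_ids[j])
    )
    return [g.marker_ids[j] for j in order[:n]]


def _transition_tables(p: np.ndarray, error_rate: float):
    """Log numerator/denominator tables for the LOD over genotype codes.

    Returns LN with shape (3 mother, 3 father, 3 offspring, m) and LD2 with
    shape (3 mother, 3 offspring, m). Mendelian transitions are mixed with
    the HWE genotype distribution: weight (1-e') Mendelian + e' HWE, where
    e' = 1-(1-e)^3 for the trio term (any of three genotypes mistyped) and
    1-(1-e)^2 for the mother-offspring term.
    """
    m = p.size
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])  # (3, m)
    trans = np.array([0.0, 0.5, 1.0])  # P(transmit counted allele | genotype)
    T3 = np.empty((3, 3, 3, m))
    for gm in range(3):
        for gf in range(3):
            pm, pf = trans[gm], trans[gf]
            probs = [
                (1 - pm) * (1 - pf),
                pm * (1 - pf) + (1 - pm) * pf,
                pm * pf,
            ]
            for go in range(3):
                T3[gm, gf, go, :] = probs[go]
    T2 = np.empty((3, 3, m))
    for gm in range(3):
        pm = trans[gm]
        T2[gm, 0] = (1 - pm) * (1 - p)
        T2[gm, 1] = pm * (1 - p) + (1 - pm) * p
        T2[gm, 2] = pm * p
    e3 = 1.0 - (1.0 - error_rate) ** 3
    e2 = 1.0 - (1.0 - error_rate) ** 2
    with np.errstate(divide="ignore"):  # log 0 -> -inf is the exclusion case
        LN = np.log((1 - e3) * T3 + e3 * hwe[None, None, :, :])
        LD2 = np.log((1 - e2) * T2 + e2 * hwe[None, :, :])
    return LN, LD2


def paternity_lod(
    offspring: np.ndarray,
    mother: np.ndarray,
    candidate: np.ndarray,
    allele_freq: np.ndarray,
    error_rate: float = 0.05,
) -> float:
    """LOD (natural log) for one candidate father given a known mother.

    Vectors are genotype codes 0/1/2 over the marker subset; NaN entries
    (missing at any of the three genotypes) drop the marker's term. With
    error_rate 0 an impossible transition gives -inf (exclusion).
    """
    off = np.asarray(offspring, dtype=float)
    mot = np.asarray(mother, dtype=float)
    can = np.asarray(candidate, dtype=float)
    p = np.asarray(allele_freq, dtype=float)
    ok = ~(np.isnan(off) | np.isnan(mot) | np.isnan(can))
    if not ok.any():
        return 0.0
    LN, LD2 = _transition_tables(p[ok], error_rate)
    o = off[ok].astype(int)
    mo = mot[ok].astype(int)
    ca = can[ok].astype(int)
    idx = np.arange(o.size)
    with np.errstate(divide="ignore"):
        terms = LN[mo, ca, o, idx] - LD2[mo, o, idx]
    return float(terms.sum())


def _lod_matrix(off_geno, mother_codes, cand_geno, p, error_rate):
    """LOD for many offspring against all candidates at once.

    off_geno: (R, m) int codes; mother_codes: (R, m); cand_geno: (C, m).
    Returns (R, C) LOD matrix. No missing values allowed here.
    """
    R, m = off_geno.shape
    C = cand_geno.shape[0]
    LN, LD2 = _transition_tables(p, error_rate)
    jdx = np.arange(m)
    den = LD2[mother_codes, off_geno, jdx[None, :]].sum(axis=1)  # (R,)
    lod = np.empty((R, C))
    for cix in range(C):
        num = LN[mother_codes, cand_geno[cix][None, :], off_geno, jdx[None, :]]
        lod[:, cix] = num.sum(axis=1) - den
    return lod


@dataclass
class DeltaThreshold:
    confidence_level: float = 0.80
    n_replicates: int = 10_000
    error_rate: float = 0.05
    delta_critical: float = float("nan")
    strict_level: float = 0.95
    delta_critical_strict: float = float("nan")


def delta_threshold(
    candidates: GenotypeMatrix,
    config: DeltaThreshold | None = None,
    seed: int = 0,
) -> DeltaThreshold:
    """Simulate the null calibration of the Delta statistic.

    Replicated offspring are generated from random (mother, father) pairs
    drawn from the candidate pool, with genotyping error applied to the
    offspring; the critical Delta is the smallest value at which the
    proportion of correct top assignments among replicates exceeding it
    reaches the confidence level (relaxed 80%, optional strict 95%).
    """
    cfg = config or DeltaThreshold()
    rng = np.random.default_rng(seed)
    geno = candidates.dosage
    if np.isnan(geno).any():
        raise PopgenError("candidate genotypes must be complete for simulation")
    cand = np.asarray(np.round(geno), dtype=int)
    C, m = cand.shape
    if C < 2:
        import warnings

        warnings.warn("single candidate: Delta threshold degenerates to 0", stacklevel=2)
        return DeltaThreshold(
            confidence_level=cfg.confidence_level,
            n_replicates=cfg.n_replicates,
            error_rate=cfg.error_rate,
            delta_critical=0.0,
            strict_level=cfg.strict_level,
            delta_critical_strict=0.0,
        )
    p = candidates.allele_freq
    R = cfg.n_replicates
    mothers = rng.integers(0, C, size=R)
    fathers = rng.integers(0, C, size=R)
    off = _mendelian_offspring(cand[mothers], cand[fathers], rng)
    off = _apply_hwe_error(off, p, cfg.error_rate, rng)
    lod = _lod_matrix(off, cand[mothers], cand, p, cfg.error_rate)
    top2 = np.argsort(lod, axis=1)[:, -2:]
    best = top2[:, 1]
    delta = lod[np.arange(R), best] - lod[np.arange(R), top2[:, 0]]
    correct = best == fathers

    def critical(level):
        order = np.argsort(delta)
        d_sorted = delta[order]
        c_sorted = correct[order].astype(float)
        # success rate among replicates with delta >= threshold, scanning up
        suffix_n = np.arange(R, 0, -1)
        suffix_correct = np.cumsum(c_sorted[::-1])[::-1]
        rate = suffix_correct / suffix_n
        hit = np.flatnonzero(rate >= level)
        if hit.size == 0:
            d = d_sorted[np.isfinite(d_sorted)]
            return float(d[-1]) if d.size else 0.0
        if hit[0] == 0:
            return 0.0  # the criterion already holds with no cut at all
        return float(max(d_sorted[hit[0]], 0.0))

    return DeltaThreshold(
        confidence_level=cfg.confidence_level,
        n_replicates=R,
        error_rate=cfg.error_rate,
        delta_critical=critical(cfg.confidence_level),
        strict_level=cfg.strict_level,
        delta_critical_strict=critical(cfg.strict_level),
    )


def _mendelian_offspring(gm, gf, rng):
    """Offspring genotype codes from parental codes (independent loci)."""
    pm = gm / 2.0
    pf = gf / 2.0
    return (
        (rng.uniform(size=gm.shape) < pm).astype(int)
        + (rng.uniform(size=gf.shape) < pf).astype(int)
    )


def _apply_hwe_error(geno, p, error_rate, rng):
    if error_rate <= 0:
        return geno
    out = geno.copy()
    err = rng.uniform(size=geno.shape) < error_rate
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2]).T  # (m, 3)
    cum = hwe.cumsum(axis=1)
    u = rng.uniform(size=geno.shape)
    redraw = (u[..., None] > cum[None, :, :]).sum(axis=2)
    out[err] = redraw[err]
    return out


def assign_paternity(
    genotypes: GenotypeMatrix,
    offspring_ids,
    mother_of: dict,
    candidate_ids,
    error_rate: float = 0.05,
    threshold: DeltaThreshold | None = None,
    use_strict: bool = False,
    seed: int = 0,
    marker_subset: list | None = None,
) -> pd.DataFrame:
    """Full paternity pipeline: LODs for every candidate, Delta, assignment.

    Returns one row per offspring: known_mother, best_candidate, lod_best,
    lod_second, delta, assignment in {selfed, crossed, unassigned} and
    confidence in {strict, relaxed, none}. An offspring is 'selfed' when
    the best candidate is its known mother with at least relaxed
    confidence.
    """
    if marker_subset is not None:
        genotypes = genotypes.subset(markers=marker_subset)
    cand = genotypes.subset(ids=[str(c) for c in candidate_ids])
    if threshold is None:
        threshold = delta_threshold(
            cand, DeltaThreshold(error_rate=error_rate), seed=seed
        )
    crit = threshold.delta_critical_strict if use_strict else threshold.delta_critical
    p = cand.allele_freq
    cand_codes = np.asarray(np.round(cand.dosage), dtype=int)
    pos = {s: k for k, s in enumerate(genotypes.ids)}
    rows = []
    for oid in offspring_ids:
        oid = str(oid)
        mid = str(mother_of[oid])
        off = genotypes.dosage[pos[oid]]
        mot = genotypes.dosage[pos[mid]]
        lods = np.array(
            [
                paternity_lod(off, mot, cand_codes[c], p, error_rate)
                for c in range(cand_codes.shape[0])
            ]
        )
        order = np.argsort(lods)
        best, second = order[-1], order[-2] if lods.size > 1 else order[-1]
        delta = float(lods[best] - lods[second]) if lods.size > 1 else float("inf")
        best_id = cand.ids[best]
        confident = delta >= crit
        if confident and np.isfinite(lods[best]):
            conf = "strict" if use_strict else "relaxed"
            assignment = "selfed" if best_id == mid else "crossed"
        else:
            conf = "none"
            assignment = "unassigned"
        rows.append(
            {
                "offspring_id": oid,
                "known_mother": mid,
                "best_candidate": best_id,
                "lod_best": float(lods[best]),
                "lod_second": float(lods[second]),
                "delta": delta,
                "assignment": assignment,
                "confidence": conf,
            }
        )
    return pd.DataFrame(rows)


def load_reference_family_counts() -> pd.DataFrame:
    """Bundled per-family selfed/crossed seed counts for a 28-parent
    selfing orchard (columns family, n_selfed, n_crossed)."""
    with importlib.resources.files("selfpred.data").joinpath(
        "reference_family_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def expand_counts_to_assignments(counts: pd.DataFrame) -> pd.DataFrame:
    """Offspring-level assignment table from per-family counts, suitable
    for :func:`classify_offspring`."""
    rows = []
    k = 0
    for _, rec in counts.iterrows():
        fam = str(rec["family"])
        for _ in range(int(rec["n_selfed"])):
            k += 1
            rows.append((f"S{k:04d}", fam, fam, "selfed"))
        for _ in range(int(rec["n_crossed"])):
            k += 1
            rows.append((f"S{k:04d}", fam, f"{fam}_X", "crossed"))
    return pd.DataFrame(
        rows, columns=["offspring_id", "known_mother", "best_candidate", "assignment"]
    )


@dataclass
class SelfingSummary:
    per_family: pd.DataFrame  # family, n_selfed, n_crossed, n_unassigned, n_total, pct_selfed
    n_total: int
    n_selfed: int
    n_crossed: int
    n_unassigned: int
    pct_selfed: float
    pct_crossed: float


def classify_offspring(results: pd.DataFrame) -> SelfingSummary:
    """Per-family and overall selfing counts from an assignment table.

    Proportions are percentages rounded to 2 decimals; counts always
    satisfy selfed + crossed + unassigned = total.
    """
    req = {"known_mother", "assignment"}
    if not req.issubset(results.columns):
        raise PopgenError(f"assignment table needs columns {sorted(req)}")
    fams = []
    for fam, grp in results.groupby("known_mother", sort=True):
        n_s = int((grp["assignment"] == "selfed").sum())
        n_c = int((grp["assignment"] == "crossed").sum())
        n_u = int((grp["assignment"] == "unassigned").sum())
        n_t = len(grp)
        fams.append(
            {
                "family": fam,
                "n_selfed": n_s,
                "n_crossed": n_c,
                "n_unassigned": n_u,
                "n_total": n_t,
                "pct_selfed": round(100.0 * n_s / n_t, 2) if n_t else float("nan"),
            }
        )
    per_family = pd.DataFrame(fams)
    n_total = int(len(results))
    n_selfed = int((results["assignment"] == "selfed").sum())
    n_crossed = int((results["assignment"] == "crossed").sum())
    n_unassigned = n_total - n_selfed - n_crossed
    return SelfingSummary(
        per_family=per_family,
        n_total=n_total,
        n_selfed=n_selfed,
        n_crossed=n_crossed,
        n_unassigned=n_unassigned,
        pct_selfed=round(100.0 * n_selfed / n_total, 2) if n_total else float("nan"),
        pct_crossed=round(100.0 * n_crossed / n_total, 2) if n_total else float("nan"),
    )


def plot_family_bars(summary: SelfingSummary, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pf = summary.per_family
    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(pf))
    ax.bar(x, pf["n_selfed"], label="selfed", color="#3b6ea5")
    ax.bar(x, pf["n_crossed"], bottom=pf["n_selfed"], label="crossed", color="#d1854f")
    bot = pf["n_selfed"] + pf["n_crossed"]
    ax.bar(x, pf["n_unassigned"], bottom=bot, label="unassigned", color="#999999")
    ax.set_xticks(x)
    ax.set_xticklabels(pf["family"], rotation=90, fontsize=7)
    ax.set_ylabel("seeds")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
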