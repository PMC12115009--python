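"""Synthetic populations for a partially self-fertilized tree breeding design.

The generator emulates the statistical structure the downstream analyses
assume: a small set of clonal parents, progeny produced mostly by selfing
with occasional outcross "pollen contamination", linkage disequilibrium
among founder haplotypes that decays with physical distance, meiosis with
Haldane recombination, and a polygenic additive+dominance trait measured
on a randomized complete block design. A held-back "orchard" subset is
genotyped but never phenotyped, mirroring the prediction use case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geno_io import GenotypeMatrix, Pedigree, validate_phenotypes


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Study-scale defaults: 20 clonal parents, 1-33 seed per parent, 62%
    selfing, ~10k SNPs on 11 chromosomes, DBH-like trait (mean 12.25 cm,
    SD 4.18 cm) with narrow-sense h2 = 0.4, 30 blocks, 62 unphenotyped
    orchard individuals."""

    n_parents: int = 20
    offspring_per_parent: tuple = (1, 33)
    selfing_rate: float = 0.62
    n_markers: int = 10_000
    n_chromosomes: int = 11
    chrom_length_bp: int = 40_000_000
    adjacent_ld_rho: float = 0.9
    maf_floor: float = 0.05
    h2_additive: float = 0.4
    d2_dominance: float = 0.1
    trait_mean: float = 12.25
    trait_sd: float = 4.18
    n_blocks: int = 30
    block_sd: float = 1.5
    outlier_rate: float = 0.02
    genotyping_error_rate: float = 0.005
    missing_rate: float = 0.01
    n_orchard: int = 62
    n_causal: int | None = None  # None => every marker is causal
    seed: int = 0

    def validate(self):
        def bad(name, msg):
            raise SimConfigError(f"{name}: {msg}")

        for name in ("n_parents", "n_markers", "n_chromosomes", "chrom_length_bp", "n_blocks"):
            if int(getattr(self, name)) < 1:
                bad(name, "must be >= 1")
        lo, hi = self.offspring_per_parent
        if not (1 <= lo <= hi):
            bad("offspring_per_parent", "need 1 <= min <= max")
        for name in ("selfing_rate", "outlier_rate", "genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, "must be a probability in [0, 1]")
        if not 0.0 <= self.adjacent_ld_rho < 1.0:
            bad("adjacent_ld_rho", "must be in [0, 1)")
        if not 0.0 < self.maf_floor < 0.5:
            bad("maf_floor", "must be in (0, 0.5)")
        if not 0.0 <= self.h2_additive < 1.0:
            bad("h2_additive", "must be in [0, 1)")
        if not 0.0 <= self.d2_dominance < 1.0:
            bad("d2_dominance", "must be in [0, 1)")
        if self.h2_additive + self.d2_dominance >= 1.0:
            bad("h2_additive", "h2_additive + d2_dominance must be < 1")
        if self.trait_sd <= 0:
            bad("trait_sd", "must be > 0")
        if self.block_sd < 0:
            bad("block_sd", "must be >= 0")
        if self.n_orchard < 0:
            bad("n_orchard", "must be >= 0")
        if self.n_parents < 2 and self.selfing_rate < 1.0:
            bad("n_parents", "need >= 2 parents unless selfing_rate == 1")
        if self.n_causal is not None and not 1 <= self.n_causal <= self.n_markers:
            bad("n_causal", "must be in [1, n_markers]")
        return self

    def to_dict(self):
        d = asdict(self)
        d["offspring_per_parent"] = list(self.offspring_per_parent)
        return d


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests (never visible to models)."""

    true_breeding_values: pd.Series  # indexed by individual id
    true_dominance_values: pd.Series
    marker_effects: pd.Series  # additive effects, indexed by marker id
    dominance_effects: pd.Series
    realized_h2: float
    parent_of: dict  # offspring id -> (mother, father)
    orchard_ids: list = field(default_factory=list)
    residual_var: float = float("nan")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # fixed per-stage derivation from the single config seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _marker_map(config: SimConfig) -> pd.DataFrame:
    per = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per[: config.n_markers % config.n_chromosomes] += 1
    rows = []
    k = 0
    for c in range(config.n_chromosomes):
        pos = np.linspace(1, config.chrom_length_bp, per[c]).round().astype(np.int64)
        for p in pos:
            rows.append((f"M{k:05d}", c + 1, int(p)))
            k += 1
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp"])


def simulate_founders(config: SimConfig) -> GenotypeMatrix:
    """Founder clone genotypes with tunable adjacent-locus LD.

    Haplotype alleles come from thresholding a stationary AR(1) Gaussian
    latent process along each chromosome (correlation ``adjacent_ld_rho``
    between neighbours), so LD decays geometrically with marker index and
    hence with distance. Realized minor-allele frequencies are forced to
    ``maf_floor`` by flipping majority alleles where drift went below it.
    """
    config.validate()
    rng = _rng(config, 0)
    mm = _marker_map(config)
    m = config.n_markers
    n_hap = 2 * config.n_parents
    p_target = rng.uniform(config.maf_floor * 2, 1 - config.maf_floor * 2, size=m)
    thr = norm.ppf(p_target)

    haps = np.empty((n_hap, m), dtype=np.int8)
    rho = config.adjacent_ld_rho
    innov_sd = np.sqrt(1.0 - rho * rho)
    for c in sorted(mm["chrom"].unique()):
        idx = np.flatnonzero(mm["chrom"].to_numpy() == c)
        eps = rng.standard_normal((n_hap, idx.size))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        for k in range(1, idx.size):
            z[:, k] = rho * z[:, k - 1] + innov_sd * eps[:, k]
        haps[:, idx] = (z < thr[idx]).astype(np.int8)

    # enforce the MAF floor: flip majority-allele haplotypes at thin loci
    need = int(np.ceil(config.maf_floor * n_hap))
    counts = haps.sum(axis=0)
    for j in np.flatnonzero(np.minimum(counts, n_hap - counts) < need):
        cnt = counts[j]
        minor = 1 if cnt <= n_hap - cnt else 0
        k_minor = cnt if minor == 1 else n_hap - cnt
        donors = np.flatnonzero(haps[:, j] != minor)
        flip = rng.choice(donors, size=need - k_minor, replace=False)
        haps[flip, j] = minor

    haps3 = haps.reshape(config.n_parents, 2, m)
    ids = [f"PAR{i + 1:02d}" for i in range(config.n_parents)]
    return GenotypeMatrix(
        ids=ids,
        marker_ids=list(mm["marker"]),
        dosage=haps3.sum(axis=1).astype(float),
        marker_map=mm,
        haplotypes=haps3,
    )


def _gamete(haps: np.ndarray, mm_pos, chrom_starts, chrom_len_bp, rng) -> np.ndarray:
    """One meiosis: Haldane crossovers, 100 cM per chromosome mapped linearly
    to ``chrom_len_bp``. ``haps`` is (2, m) for one parent."""
    m = haps.shape[1]
    out = np.empty(m, dtype=np.int8)
    for (lo, hi), pos in zip(chrom_starts, mm_pos):
        n_x = rng.poisson(1.0)  # 1 Morgan per chromosome
        cur = rng.integers(0, 2)
        if n_x == 0:
            out[lo:hi] = haps[cur, lo:hi]
            continue
        xpos = np.sort(rng.uniform(0, chrom_len_bp, size=n_x))
        # phase index flips at each crossover; count crossovers left of marker
        flips = np.searchsorted(xpos, pos)
        out[lo:hi] = haps[(cur + flips) % 2, np.arange(lo, hi)]
    return out


def simulate_progeny(
    founders: GenotypeMatrix, config: SimConfig
) -> tuple[GenotypeMatrix, Pedigree, SimTruth]:
    """Selfed/outcrossed progeny of the founder clones.

    Each offspring's seed parent is its family's founder; with probability
    ``selfing_rate`` the pollen parent is the same clone, otherwise a
    uniformly drawn other founder. True breeding/dominance values are
    computed from the clean genotypes; genotyping error (random HWE
    re-draws) and missingness are applied afterwards to the released
    dosage matrix only.
    """
    config.validate()
    if founders.haplotypes is None:
        raise SimConfigError("founders: phased haplotypes required (use simulate_founders)")
    rng = _rng(config, 1)
    m = founders.n_markers
    n_par = founders.n_individuals
    mm = founders.marker_map
    chrom_starts = []
    mm_pos = []
    chrom_vals = mm["chrom"].to_numpy()
    pos_vals = mm["pos_bp"].to_numpy()
    for c in pd.unique(chrom_vals):
        idx = np.flatnonzero(chrom_vals == c)
        chrom_starts.append((idx[0], idx[-1] + 1))
        mm_pos.append(pos_vals[idx])

    lo, hi = config.offspring_per_parent
    counts = rng.integers(lo, hi + 1, size=n_par)
    offspring_haps = []
    recs = []
    parent_of = {}
    k = 0
    for i in range(n_par):
        for _ in range(counts[i]):
            if rng.uniform() < config.selfing_rate or n_par == 1:
                father = i
            else:
                father = int(rng.integers(0, n_par - 1))
                if father >= i:
                    father += 1
            oid = f"IND{k + 1:04d}"
            g_m = _gamete(founders.haplotypes[i], mm_pos, chrom_starts, config.chrom_length_bp, rng)
            g_f = _gamete(founders.haplotypes[father], mm_pos, chrom_starts, config.chrom_length_bp, rng)
            offspring_haps.append(np.stack([g_m, g_f]))
            recs.append((oid, founders.ids[father], founders.ids[i]))
            parent_of[oid] = (founders.ids[i], founders.ids[father])
            k += 1
    n_off = k
    haps = np.stack(offspring_haps)  # (n_off, 2, m)
    true_dosage = haps.sum(axis=1).astype(float)
    off_ids = [r[0] for r in recs]

    # orchard subset: genotyped, never phenotyped
    if config.n_orchard >= n_off:
        raise SimConfigError("n_orchard: must be smaller than the number of offspring")
    orchard_idx = rng.choice(n_off, size=config.n_orchard, replace=False)
    orchard = set(np.asarray(off_ids, dtype=object)[orchard_idx])

    ped_rows = [(fid, None, None, "founder") for fid in founders.ids]
    ped_rows += [
        (oid, sire, dam, "orchard" if oid in orchard else "field")
        for oid, sire, dam in recs
    ]
    ped = Pedigree(pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "cohort"]))

    # --- trait architecture on clean genotypes --------------------------
    rng_t = _rng(config, 2)
    causal = np.arange(m)
    if config.n_causal is not None:
        causal = np.sort(rng_t.choice(m, size=config.n_causal, replace=False))
    a_raw = np.zeros(m)
    d_raw = np.zeros(m)
    a_raw[causal] = rng_t.standard_normal(causal.size)
    d_raw[causal] = rng_t.standard_normal(causal.size)

    sigma_p2 = config.trait_sd**2
    bv = (true_dosage - true_dosage.mean(axis=0)) @ a_raw
    s_bv = bv.std()
    if config.h2_additive > 0 and s_bv > 0:
        scale_a = np.sqrt(config.h2_additive * sigma_p2) / s_bv
    else:
        scale_a = 0.0
    bv *= scale_a
    a_eff = a_raw * scale_a

    het = (haps[:, 0, :] != haps[:, 1, :]).astype(float)
    dv = (het - het.mean(axis=0)) @ d_raw
    s_dv = dv.std()
    if config.d2_dominance > 0 and s_dv > 0:
        scale_d = np.sqrt(config.d2_dominance * sigma_p2) / s_dv
    else:
        scale_d = 0.0
    dv *= scale_d
    d_eff = d_raw * scale_d

    resid_var = max(sigma_p2 * (1.0 - config.h2_additive - config.d2_dominance), 1e-12)
    denom = bv.var() + dv.var() + resid_var
    realized_h2 = float(bv.var() / denom) if denom > 0 else 0.0

    truth = SimTruth(
        true_breeding_values=pd.Series(bv, index=off_ids),
        true_dominance_values=pd.Series(dv, index=off_ids),
        marker_effects=pd.Series(a_eff, index=founders.marker_ids),
        dominance_effects=pd.Series(d_eff, index=founders.marker_ids),
        realized_h2=realized_h2,
        parent_of=parent_of,
        orchard_ids=sorted(orchard),
        residual_var=resid_var,
    )

    # --- observation noise on the released matrix ----------------------
    dosage = true_dosage.copy()
    if config.genotyping_error_rate > 0:
        p = founders.allele_freq
        err = rng.uniform(size=dosage.shape) < config.genotyping_error_rate
        hwe = np.stack(
            [(1 - p) ** 2, 2 * p * (1 - p), p**2]
        ).T  # (m, 3) genotype probs
        u = rng.uniform(size=dosage.shape)
        cum = hwe.cumsum(axis=1)
        redraw = (u[..., None] > cum[None, :, :]).sum(axis=2)
        dosage[err] = redraw[err]
    if config.missing_rate > 0:
        miss = rng.uniform(size=dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    progeny = GenotypeMatrix(
        ids=off_ids,
        marker_ids=list(founders.marker_ids),
        dosage=dosage,
        marker_map=mm.copy(),
        haplotypes=haps,
    )
    return progeny, ped, truth


def simulate_phenotypes(
    progeny: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """DBH-like phenotypes for the field cohort on an RCBD.

    y = mean + block + breeding value + dominance deviation + residual,
    with the residual variance set so the planned narrow-sense h2 holds on
    the phenotypic (non-block) variance. With probability ``outlier_rate``
    a record is replaced by an extreme low value (a stunted/damaged tree),
    the case winsorization is meant to absorb. Orchard individuals get no
    record.
    """
    config.validate()
    rng = _rng(config, 3)
    orchard = set(truth.orchard_ids)
    field_ids = [i for i in progeny.ids if i not in orchard]
    n = len(field_ids)
    blocks = [f"B{(k % config.n_blocks) + 1:02d}" for k in range(n)]
    block_eff = rng.normal(0.0, config.block_sd, size=config.n_blocks)
    b_of = {f"B{j + 1:02d}": block_eff[j] for j in range(config.n_blocks)}

    bv = truth.true_breeding_values.loc[field_ids].to_numpy()
    dv = truth.true_dominance_values.loc[field_ids].to_numpy()
    eps = rng.normal(0.0, np.sqrt(truth.residual_var), size=n)
    y = config.trait_mean + np.array([b_of[b] for b in blocks]) + bv + dv + eps

    out_mask = rng.uniform(size=n) < config.outlier_rate
    if out_mask.any():
        n_out = int(out_mask.sum())
        y[out_mask] = (
            config.trait_mean
            - 5.0 * config.trait_sd
            - np.abs(rng.normal(0.0, config.trait_sd, size=n_out))
        )

    df = pd.DataFrame({"id": field_ids, "block": blocks, "dbh_cm": y})
    return validate_phenotypes(df)


def simulate_population(config: SimConfig):
    """Convenience wrapper: founders -> progeny -> phenotypes.

    Returns (genotypes of founders+progeny stacked, pedigree, phenotypes,
    truth). The stacked matrix keeps founders first.
    """
    founders = simulate_founders(config)
    progeny, ped, truth = simulate_progeny(founders, config)
    all_geno = GenotypeMatrix(
        ids=founders.ids + progeny.ids,
        marker_ids=list(founders.marker_ids),
        dosage=np.vstack([founders.dosage, progeny.dosage]),
        marker_map=founders.marker_map.copy(),
        haplotypes=np.concatenate([founders.haplotypes, progeny.haplotypes]),
    )
    pheno = simulate_phenotypes(progeny, truth, config)
    return all_geno, ped, pheno, truth


def write_population(outdir, geno, ped, pheno, truth, config):
    """Serialize a simulated population: VCF + CSV dosages, pedigree CSV,
    phenotype CSV, marker map CSV, truth CSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    geno.to_csv(out / "genotypes.csv")
    geno.to_vcf(out / "genotypes.vcf")
    geno.marker_map.to_csv(out / "marker_map.csv", index=False)
    ped.to_csv(out / "pedigree.csv")
    # %.17g round-trips doubles exactly, keeping re-runs bit-identical
    pheno.to_csv(out / "phenotypes.csv", index=False, float_format="%.17g")
    tr = pd.DataFrame(
        {
            "id": truth.true_breeding_values.index,
            "true_bv": truth.true_breeding_values.to_numpy(),
            "true_dom": truth.true_dominance_values.to_numpy(),
            "orchard": [i in set(truth.orchard_ids) for i in truth.true_breeding_values.index],
        }
    )
    tr.to_csv(out / "truth.csv", index=False)
    import json

    (out / "sim_config.json").write_text(json.dumps(config.to_dict(), indent=2))
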