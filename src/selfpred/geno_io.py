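"""Genotype, pedigree and phenotype containers with I/O, QC and imputation.

Dosages count copies of the ALT (or "counted") allele, so 0/1/2 for
hom-ref/het/hom-alt; missing calls are stored as NaN in a float matrix.
The marker map (chromosome, position in bp) travels with the genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.nan


class GenotypeIOError(ValueError):
    """Malformed genotype file or inconsistent container state."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with marker map.

    Attributes
    ----------
    ids : list of str
        Individual identifiers (rows), unique.
    marker_ids : list of str
        Marker identifiers (columns), unique.
    dosage : ndarray, shape (n, m), float
        Counted-allele dosages in {0, 1, 2}; NaN marks a missing call.
        After :func:`impute_mean` the entries may be fractional.
    marker_map : DataFrame
        Columns ``marker``, ``chrom``, ``pos_bp``; one row per marker in
        column order.
    haplotypes : ndarray or None
        Optional (n, 2, m) int8 phased haplotypes. Only populated by the
        simulator (true phase, pre-error); never read from files.
    """

    ids: list
    marker_ids: list
    dosage: np.ndarray
    marker_map: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        if len(set(self.ids)) != len(self.ids):
            raise GenotypeIOError("duplicate individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeIOError("duplicate marker ids")
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.ids), len(self.marker_ids)):
            raise GenotypeIOError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.ids)} ids x {len(self.marker_ids)} markers"
            )

    # ---- derived quantities -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per marker, from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    @property
    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    @property
    def indiv_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    # ---- subsetting ---------------------------------------------------------

    def subset(self, ids=None, markers=None) -> "GenotypeMatrix":
        ridx = np.arange(self.n_individuals)
        cidx = np.arange(self.n_markers)
        if ids is not None:
            pos = {s: k for k, s in enumerate(self.ids)}
            missing = [s for s in ids if s not in pos]
            if missing:
                raise KeyError(f"unknown individual ids: {missing[:5]}")
            ridx = np.array([pos[s] for s in ids])
        if markers is not None:
            pos = {s: k for k, s in enumerate(self.marker_ids)}
            missing = [s for s in markers if s not in pos]
            if missing:
                raise KeyError(f"unknown marker ids: {missing[:5]}")
            cidx = np.array([pos[s] for s in markers])
        haps = None
        if self.haplotypes is not None:
            haps = self.haplotypes[ridx][:, :, cidx]
        return GenotypeMatrix(
            ids=[self.ids[i] for i in ridx],
            marker_ids=[self.marker_ids[j] for j in cidx],
            dosage=self.dosage[np.ix_(ridx, cidx)],
            marker_map=self.marker_map.iloc[cidx].reset_index(drop=True),
            haplotypes=haps,
        )

    # ---- CSV dialect: header of marker ids, first column "id", missing = NA -

    def to_csv(self, path):
        df = pd.DataFrame(self.dosage, columns=self.marker_ids)
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")

    @classmethod
    def from_csv(cls, path, marker_map: pd.DataFrame | None = None):
        df = pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
        if df.columns[0] != "id":
            raise GenotypeIOError(f"{path}: first column must be 'id'")
        marker_ids = list(df.columns[1:])
        if marker_map is None:
            marker_map = pd.DataFrame(
                {"marker": marker_ids, "chrom": 0, "pos_bp": np.arange(len(marker_ids))}
            )
        return cls(
            ids=list(df["id"].astype(str)),
            marker_ids=marker_ids,
            dosage=df[marker_ids].to_numpy(dtype=float),
            marker_map=marker_map.reset_index(drop=True),
        )

    # ---- VCF ---------------------------------------------------------------

    def to_vcf(self, path):
        """Write a minimal unphased GT-only VCF (REF=A, ALT=T placeholders)."""
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            chroms = pd.unique(self.marker_map["chrom"])
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.ids)
                + "\n"
            )
            mm = self.marker_map
            for j, mid in enumerate(self.marker_ids):
                row = [
                    str(mm["chrom"].iloc[j]),
                    str(int(mm["pos_bp"].iloc[j])),
                    mid,
                    "A",
                    "T",
                    ".",
                    "PASS",
                    ".",
                    "GT",
                ]
                col = self.dosage[:, j]
                row += ["./." if np.isnan(x) else gt_of[int(round(x))] for x in col]
                fh.write("\t".join(row) + "\n")

    @classmethod
    def from_vcf(cls, path):
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        ids = list(vcf.samples)
        dosages, markers, chroms, poss = [], [], [], []
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        code = np.array([0.0, 1.0, np.nan, 2.0])
        for line_no, v in enumerate(vcf, start=1):
            gt = np.asarray(v.gt_types)
            if gt.max(initial=0) > 3 or gt.min(initial=0) < 0:
                raise GenotypeIOError(f"{path}: unparseable GT at record {line_no}")
            dosages.append(code[gt])
            markers.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
            chroms.append(v.CHROM)
            poss.append(v.POS)
        if not dosages:
            raise GenotypeIOError(f"{path}: no variant records")
        marker_map = pd.DataFrame({"marker": markers, "chrom": chroms, "pos_bp": poss})
        return cls(
            ids=ids,
            marker_ids=markers,
            dosage=np.asarray(dosages).T,
            marker_map=marker_map,
        )


def read_genotypes(path, format: str = "csv") -> GenotypeMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return GenotypeMatrix.from_vcf(path)
    if format == "csv":
        return GenotypeMatrix.from_csv(path)
    raise GenotypeIOError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """id/sire/dam records; selfing shows as sire == dam.

    Unknown parents are None. ``cohort`` is optional free-text grouping
    (founder / field / orchard in the simulator's output).
    """

    table: pd.DataFrame  # columns id, sire, dam[, cohort]

    def __post_init__(self):
        t = self.table.copy()
        for col in ("id", "sire", "dam"):
            if col not in t.columns:
                raise PedigreeError(f"pedigree table missing column {col!r}")
            t[col] = t[col].astype(object).where(t[col].notna(), None)
            t[col] = t[col].map(lambda x: None if x is None else str(x))
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise PedigreeError(f"duplicate pedigree id {dup!r}")
        known = set(t["id"])
        for col in ("sire", "dam"):
            bad = [p for p in t[col] if p is not None and p not in known]
            if bad:
                raise PedigreeError(f"{col} {bad[0]!r} is not a pedigree id")
        self.table = t.reset_index(drop=True)
        self._check_acyclic()

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    def parents_of(self, ind) -> tuple:
        row = self.table.loc[self.table["id"] == str(ind)]
        if row.empty:
            raise KeyError(ind)
        return row["sire"].iloc[0], row["dam"].iloc[0]

    def _check_acyclic(self):
        order = self.topological_order(_raise_on_cycle=True)
        assert len(order) == len(self.table)

    def topological_order(self, _raise_on_cycle=True) -> list:
        """Kahn's algorithm: parents before offspring."""
        t = self.table
        children = {i: [] for i in t["id"]}
        indeg = {i: 0 for i in t["id"]}
        for _, row in t.iterrows():
            for p in (row["sire"], row["dam"]):
                if p is not None:
                    children[p].append(row["id"])
                    indeg[row["id"]] += 1
        # selfing counts both links once each; dedupe so indegree is correct
        indeg = {i: 0 for i in t["id"]}
        for _, row in t.iterrows():
            ps = {p for p in (row["sire"], row["dam"]) if p is not None}
            indeg[row["id"]] = len(ps)
        queue = [i for i in t["id"] if indeg[i] == 0]
        order = []
        seen_child = set()
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                if (i, c) in seen_child:
                    continue
                seen_child.add((i, c))
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(t):
            stuck = sorted(set(t["id"]) - set(order))[0]
            if _raise_on_cycle:
                raise PedigreeError(f"pedigree cycle involving {stuck!r}")
        return order

    def to_csv(self, path):
        self.table.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path):
        t = pd.read_csv(path, na_values=["NA"], dtype=str)
        return cls(table=t)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ("id", "block", "dbh_cm")


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    for col in PHENO_COLUMNS:
        if col not in df.columns:
            raise GenotypeIOError(f"phenotype table missing column {col!r}")
    if df["id"].duplicated().any():
        raise GenotypeIOError("phenotype table has duplicate ids")
    out = df.loc[:, list(PHENO_COLUMNS)].copy()
    out["id"] = out["id"].astype(str)
    out["block"] = out["block"].astype(str)
    out["dbh_cm"] = out["dbh_cm"].astype(float)
    return out.reset_index(drop=True)


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, float_precision="round_trip"))


def write_phenotypes(df: pd.DataFrame, path):
    validate_phenotypes(df).to_csv(path, index=False, float_format="%.17g")


def read_marker_map(path) -> pd.DataFrame:
    mm = pd.read_csv(path)
    for col in ("marker", "chrom", "pos_bp"):
        if col not in mm.columns:
            raise GenotypeIOError(f"marker map missing column {col!r}")
    mm["marker"] = mm["marker"].astype(str)
    return mm


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    n_markers_in: int
    n_removed_maf: int
    n_removed_callrate: int
    n_markers_out: int
    n_individuals_in: int
    n_individuals_removed: int
    removed_maf: list = field(default_factory=list)
    removed_callrate: list = field(default_factory=list)
    removed_individuals: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.95,
    indiv_missing_max: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Marker QC: drop MAF < maf_min and call rate < callrate_min (strict:
    boundary values are kept), plus individuals with more than
    ``indiv_missing_max`` missing calls. A marker failing both filters is
    attributed to the MAF filter.
    """
    import warnings

    n_ind_in = g.n_individuals
    keep_ind = np.isnan(g.dosage).mean(axis=1) <= indiv_missing_max
    removed_individuals = [i for i, k in zip(g.ids, keep_ind) if not k]
    if removed_individuals:
        g = g.subset(ids=[i for i, k in zip(g.ids, keep_ind) if k])

    maf = g.maf
    cr = g.call_rate
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf >= maf_min)  # NaN-freq (all-missing) markers fail too
    fail_cr = cr < callrate_min
    removed_maf = [m for m, f in zip(g.marker_ids, fail_maf) if f]
    removed_cr = [m for m, f, fm in zip(g.marker_ids, fail_cr, fail_maf) if f and not fm]
    keep = ~(fail_maf | fail_cr)
    out = g.subset(markers=[m for m, k in zip(g.marker_ids, keep) if k])
    if out.n_markers == 0:
        warnings.warn("QC removed every marker", stacklevel=2)
    report = QCReport(
        n_markers_in=g.n_markers,
        n_removed_maf=len(removed_maf),
        n_removed_callrate=len(removed_cr),
        n_markers_out=out.n_markers,
        n_individuals_in=n_ind_in,
        n_individuals_removed=len(removed_individuals),
        removed_maf=removed_maf,
        removed_callrate=removed_cr,
        removed_individuals=removed_individuals,
    )
    return out, report


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with twice its marker's allele frequency.

    Column means are unchanged; intended to run after :func:`qc_filter`.
    """
    d = g.dosage.copy()
    p = g.allele_freq
    if np.isnan(p).any():
        j = int(np.flatnonzero(np.isnan(p))[0])
        raise GenotypeIOError(
            f"marker {g.marker_ids[j]!r} has no observed calls; cannot impute"
        )
    nan_r, nan_c = np.nonzero(np.isnan(d))
    d[nan_r, nan_c] = 2.0 * p[nan_c]
    return GenotypeMatrix(
        ids=list(g.ids),
        marker_ids=list(g.marker_ids),
        dosage=d,
        marker_map=g.marker_map.copy(),
        haplotypes=g.haplotypes,
    )
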