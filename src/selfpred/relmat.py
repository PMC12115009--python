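"""Relationship matrices: pedigree A, genomic G, dominance D, single-step H.

A comes from the tabular (recursive) method with inbreeding; G is VanRaden
method 1 on column-centred dosages; D uses the classical dominance coding
(-2p^2, 2pq, -2q^2); H combines A and G by the Legarra/Christensen
single-step construction with optional blending and tau/omega scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, Pedigree, PedigreeError


class RelmatError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    ids: list
    values: np.ndarray
    kind: str  # one of A, G, D, H

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise RelmatError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise RelmatError("matrix is not symmetric to 1e-10")
        self.values = 0.5 * (self.values + self.values.T)

    def submatrix(self, ids) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.ids)}
        idx = np.array([pos[str(s)] for s in ids])
        return self.values[np.ix_(idx, idx)]

    def rows(self, ids) -> np.ndarray:
        pos = {s: k for k, s in enumerate(self.ids)}
        idx = np.array([pos[str(s)] for s in ids])
        return self.values[idx]

    def inbreeding(self) -> pd.Series:
        """F = diagonal - 1 (meaningful for kind A and, genomically, for G)."""
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids)

    def to_csv(self, path):
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind):
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(), kind=kind)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a(sire, dam); a_ij = 0.5 * (a_j,sire + a_j,dam).
    Unknown parents contribute nothing (treated unrelated, non-inbred).
    """
    order = ped.topological_order()
    pos = {s: k for k, s in enumerate(order)}
    t = ped.table.set_index("id")
    n = len(order)
    a = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = t.loc[ind, "sire"], t.loc[ind, "dam"]
        si = pos[s] if s is not None else -1
        di = pos[d] if d is not None else -1
        if si >= 0 and di >= 0:
            a[i, i] = 1.0 + 0.5 * a[si, di]
        else:
            a[i, i] = 1.0
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += 0.5 * a[si, :i]
            if di >= 0:
                row += 0.5 * a[di, :i]
            a[i, :i] = row
            a[:i, i] = row
    # return in the pedigree's original id order
    orig = ped.ids
    idx = np.array([pos[s] for s in orig])
    return RelationshipMatrix(ids=orig, values=a[np.ix_(idx, idx)], kind="A")


def build_G(g: GenotypeMatrix, allele_freq=None) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Z = M - 2p (column-centred dosages), G = ZZ' / (2 * sum p_j (1 - p_j)).
    Allele frequencies default to the analysed sample's own.
    """
    M = np.asarray(g.dosage, dtype=float)
    if np.isnan(M).any():
        raise RelmatError("G requires imputed dosages (run impute_mean first)")
    p = g.allele_freq if allele_freq is None else np.asarray(allele_freq, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise RelmatError("all markers monomorphic: VanRaden denominator is zero")
    Z = M - 2.0 * p
    return RelationshipMatrix(ids=list(g.ids), values=(Z @ Z.T) / denom, kind="G")


def build_D(g: GenotypeMatrix, allele_freq=None) -> RelationshipMatrix:
    """Classical (Vitezica-style) genomic dominance matrix.

    Dominance design W codes dosages (0, 1, 2) as (-2p^2, 2pq, -2q^2),
    already centred under HWE; D = WW' / sum (2 p_j q_j)^2. Fractional
    (mean-imputed) dosages code to 0, the HWE expectation.
    """
    M = np.asarray(g.dosage, dtype=float)
    if np.isnan(M).any():
        raise RelmatError("D requires imputed dosages (run impute_mean first)")
    p = g.allele_freq if allele_freq is None else np.asarray(allele_freq, dtype=float)
    q = 1.0 - p
    denom = np.sum((2.0 * p * q) ** 2)
    if denom <= 0:
        raise RelmatError("all markers monomorphic: dominance denominator is zero")
    W = np.zeros_like(M)
    is_int = np.isclose(M, np.round(M))
    g0 = is_int & np.isclose(M, 0.0)
    g1 = is_int & np.isclose(M, 1.0)
    g2 = is_int & np.isclose(M, 2.0)
    W += np.where(g0, -2.0 * p**2, 0.0)
    W += np.where(g1, 2.0 * p * q, 0.0)
    W += np.where(g2, -2.0 * q**2, 0.0)
    return RelationshipMatrix(ids=list(g.ids), values=(W @ W.T) / denom, kind="D")


def build_H(
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    genotyped_ids=None,
    tau: float = 1.0,
    omega: float = 1.0,
    blend: float = 0.05,
    jitter: float = 1e-6,
) -> RelationshipMatrix:
    """Single-step H matrix combining pedigree and genomic information.

    G* = (1 - blend) G + blend A22; the pedigree projects the genomic
    correction (G* - A22) onto non-genotyped relatives:

        H11 = A11 + A12 A22^-1 (G* - A22) A22^-1 A21
        H12 = A12 A22^-1 G*
        H22 = G*

    With tau or omega != 1 the inverse form
    H^-1 = A^-1 + [0 0; 0 tau G*^-1 - omega A22^-1] is used instead.
    ``jitter`` is added to diagonals before any inversion.
    """
    if genotyped_ids is None:
        genotyped_ids = list(G.ids)
    genotyped_ids = [str(s) for s in genotyped_ids]
    aset = set(A.ids)
    missing = [s for s in genotyped_ids if s not in aset]
    if missing:
        raise RelmatError(f"genotyped ids absent from A: {missing[:5]}")
    non_geno = [s for s in A.ids if s not in set(genotyped_ids)]
    order = non_geno + genotyped_ids
    n1, n2 = len(non_geno), len(genotyped_ids)

    Afull = A.submatrix(order)
    A11 = Afull[:n1, :n1]
    A12 = Afull[:n1, n1:]
    A22 = Afull[n1:, n1:]
    G22 = G.submatrix(genotyped_ids)
    Gstar = (1.0 - blend) * G22 + blend * A22

    def inv(mat, name):
        # jitter only when the block is actually ill-conditioned, so exact
        # identity cases (G == A22) hold to numerical precision
        try:
            if np.linalg.cond(mat) > 1e10:
                mat = mat + jitter * np.eye(mat.shape[0])
            return np.linalg.inv(mat)
        except np.linalg.LinAlgError as err:
            raise RelmatError(
                f"{name} is singular; try a larger blend proportion"
            ) from err

    if tau == 1.0 and omega == 1.0:
        A22i = inv(A22, "A22")
        P = A12 @ A22i  # n1 x n2 projector
        diff = Gstar - A22
        H = np.empty((n1 + n2, n1 + n2))
        H[:n1, :n1] = A11 + P @ diff @ P.T
        H[:n1, n1:] = P @ Gstar
        H[n1:, :n1] = H[:n1, n1:].T
        H[n1:, n1:] = Gstar
    else:
        Ainv = inv(Afull, "A")
        Hinv = Ainv.copy()
        Hinv[n1:, n1:] += tau * inv(Gstar, "G*") - omega * inv(A22, "A22")
        H = inv(Hinv, "H^-1") - jitter * np.eye(n1 + n2)

    # back to A's original order
    pos = {s: k for k, s in enumerate(order)}
    idx = np.array([pos[s] for s in A.ids])
    H = H[np.ix_(idx, idx)]
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(ids=list(A.ids), values=H, kind="H")
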