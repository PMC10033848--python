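"""Genomic and pedigree relationship matrices, genomic inbreeding, LD pruning.

The genomic realized relationship matrix (GRRM) follows VanRaden's method 1
(the ``A.mat`` convention): centre dosages by twice the sample allele
frequency and scale by ``2 * sum p(1-p)``. The pedigree additive relationship
matrix uses the tabular (recursive) method with self-fertilisation supported
(sire == dam), so the diagonal is ``1 + F`` and repeated selfing gives
``F_t = 1 - (1/2)^t``. Genomic inbreeding is the correlation between uniting
gametes (the PLINK ``--ibc`` Fhat3 estimator), averaged per individual over
per-SNP ratios. LD pruning is greedy left-to-right within scaffold, mirroring
``--indep-pairwise <kb> 1 <r2>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, DosageMatrix


@dataclass
class RelationshipMatrix:
    """Symmetric relatedness over individuals; kind 'genomic' or 'pedigree'."""

    values: np.ndarray
    ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def compute_grrm(D: DosageMatrix) -> RelationshipMatrix:
    """VanRaden method-1 GRRM: ``G = W W' / (2 sum p(1-p))``.

    ``W`` is the dosage matrix centred by ``2 p_hat`` per locus with sample
    allele frequencies; missing dosages are mean-imputed per locus first
    (which leaves them at the centred value 0). Monomorphic loci contribute
    nothing; an all-monomorphic panel is an error.
    """
    if D.n_individuals < 2:
        raise ValueError("need at least two individuals")
    dos = D.imputed()
    p = dos.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("no polymorphic SNPs: GRRM denominator is zero")
    W = dos - 2.0 * p
    G = (W @ W.T) / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(G, list(D.ids), "genomic")


def compute_pedigree_a(ped: pd.DataFrame) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method, selfing allowed.

    ``ped`` needs columns id/sire/dam; unknown parents are None/NaN. Rows are
    sorted topologically (parents before offspring); a cycle is an error.
    Diagonal entries equal ``1 + F`` with F the pedigree inbreeding
    coefficient (half the parents' relationship).
    """
    ids = list(ped["id"].astype(str))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in pedigree")
    parent = {}
    for _, row in ped.iterrows():
        s = None if pd.isna(row["sire"]) else str(row["sire"])
        d = None if pd.isna(row["dam"]) else str(row["dam"])
        parent[str(row["id"])] = (s, d)

    # topological sort (parents first)
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(u: str) -> None:
        if state.get(u) == 2:
            return
        if state.get(u) == 1:
            raise ValueError(f"pedigree cycle involving {u!r}")
        state[u] = 1
        for v in parent.get(u, (None, None)):
            if v is not None and v in parent:
                visit(v)
        state[u] = 2
        order.append(u)

    for u in ids:
        visit(u)

    idx = {u: i for i, u in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, u in enumerate(order):
        s, d = parent[u]
        si = idx.get(s) if s is not None else None
        di = idx.get(d) if d is not None else None
        if si is not None and di is not None:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if si is not None:
                a += 0.5 * A[j, si]
            if di is not None:
                a += 0.5 * A[j, di]
            A[i, j] = A[j, i] = a
    # return in the input id order
    perm = [idx[u] for u in ids]
    A = A[np.ix_(perm, perm)]
    return RelationshipMatrix(A, ids, "pedigree")


def pedigree_inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Pedigree F per individual: diagonal of the A-matrix minus 1."""
    A = compute_pedigree_a(ped)
    return pd.Series(np.diag(A.values) - 1.0, index=A.ids)


@dataclass
class InbreedingEstimates:
    """Per-individual genomic inbreeding (correlation of uniting gametes)."""

    f_uni: pd.Series
    n_loci: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"f_uni": self.f_uni, "n_loci": self.n_loci})


def compute_f_uni(D: DosageMatrix, freqs: np.ndarray | None = None) -> InbreedingEstimates:
    """Correlation between uniting gametes, averaged over usable loci.

    Per SNP i and individual j with dosage x and allele frequency p:
    ``[x^2 - (1 + 2p) x + 2 p^2] / (2 p (1 - p))``. The per-individual
    estimate is the mean of these ratios over the individual's non-missing
    loci with ``p`` strictly inside (0, 1); the value is invariant to which
    allele is counted. An all-heterozygous individual scores exactly -1.
    """
    p = D.allele_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
    if len(p) != D.n_snps:
        raise ValueError("frequency vector length mismatch")
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    x = D.values.astype(float)
    miss = D.values == MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        # x^2 - (1+2p)x + 2p^2, arranged as x(x-1) - 2p(x-p) so that the
        # heterozygous case cancels to exactly -denominator in floating point
        num = x * (x - 1.0) - 2.0 * p * (x - p)
        ratio = num / (2.0 * p * (1.0 - p))
    ok = ~miss & usable[None, :]
    counts = ok.sum(axis=1)
    sums = np.where(ok, ratio, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        f = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return InbreedingEstimates(
        f_uni=pd.Series(f, index=list(D.ids)),
        n_loci=pd.Series(counts, index=list(D.ids)),
    )


@dataclass
class LDPruneConfig:
    """``--indep-pairwise``-style settings: window in kb, step 1 SNP, r^2 cut."""

    window_kb: float = 2168.0
    step: int = 1
    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.window_kb <= 0:
            raise ValueError("window must be positive")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2 threshold must be in [0, 1]")


def ld_prune(D: DosageMatrix, cfg: LDPruneConfig | None = None) -> list[int]:
    """Greedy within-scaffold LD pruning; returns kept SNP column indices.

    Scanning left to right by position within each scaffold, a SNP is dropped
    iff its squared dosage correlation with an already-kept SNP within the kb
    window exceeds the threshold. Zero-variance SNPs never enter correlations
    and are always kept.
    """
    cfg = cfg or LDPruneConfig()
    dos = D.imputed()
    sd = dos.std(axis=0)
    centred = dos - dos.mean(axis=0)
    kept: list[int] = []
    window_bp = cfg.window_kb * 1000.0
    smap = D.snp_map
    for scaffold in pd.unique(smap["scaffold"]):
        cols = np.where((smap["scaffold"] == scaffold).to_numpy())[0]
        cols = cols[np.argsort(smap["position"].to_numpy()[cols], kind="stable")]
        kept_here: list[int] = []
        for j in cols:
            pos_j = float(smap["position"].iloc[j])
            drop = False
            if sd[j] > 0:
                for k in kept_here:
                    if sd[k] == 0:
                        continue
                    if pos_j - float(smap["position"].iloc[k]) > window_bp:
                        continue
                    r = float(centred[:, j] @ centred[:, k]) / (
                        len(dos) * sd[j] * sd[k]
                    )
                    if r * r > cfg.r2_threshold:
                        drop = True
                        break
            if not drop:
                kept_here.append(int(j))
        kept.extend(kept_here)
    return sorted(kept)
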