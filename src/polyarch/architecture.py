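"""Trait-associated SNP set analysis: exclusive overlaps, linkage-group
enrichment, class-partition reports, and genic/intergenic annotation.

Exclusive intersections are the quantities behind UpSet-style plots: for each
nonempty subset of traits, the number of SNPs belonging to exactly those
traits. Linkage-group enrichment asks whether a focal SNP set (e.g. the
large-effect SNPs of one trait) is over-represented on a linkage group
relative to the full panel, with a one-sided Fisher exact (hypergeometric
tail) p-value. The partition report reproduces the per-trait table layout:
associated totals, per-class counts, no-effect counts, and annotated genes,
with both partition identities enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TraitSNPSet:
    """Associated SNP ids for one trait, optionally with class labels."""

    trait: str
    snps: set
    labels: dict | None = None  # snp id -> class label
    category: str | None = None  # foliar terpene | wood terpene | growth

    def __post_init__(self) -> None:
        self.snps = set(self.snps)


def compute_exclusive_overlaps(sets: list[TraitSNPSet]) -> pd.DataFrame:
    """Counts of SNPs in exactly each nonempty subset of traits.

    Returns a frame with columns ``traits`` (sorted tuple), ``exclusive``
    (UpSet bar height) and ``intersection`` (plain intersection size).
    The exclusive counts partition the union.
    """
    if not sets:
        raise ValueError("need at least one trait set")
    names = [s.trait for s in sets]
    by_name = {s.trait: s.snps for s in sets}
    membership: dict = {}
    for snp in set().union(*by_name.values()):
        key = tuple(sorted(t for t in names if snp in by_name[t]))
        membership[key] = membership.get(key, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for sub in combinations(sorted(names), r):
            inter = set.intersection(*(by_name[t] for t in sub))
            rows.append(
                {
                    "traits": sub,
                    "exclusive": membership.get(tuple(sorted(sub)), 0),
                    "intersection": len(inter),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    lg: object
    focal_on: int
    focal_off: int
    background_on: int
    background_off: int
    p_value: float


def lg_enrichment_test(
    focal: set, background: set, lg_assignment: dict, lg
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher exact test of focal SNPs on one linkage
    group against the background panel.

    The 2x2 table is [focal on/off LG; (background - focal) on/off LG]; the
    p-value is the upper hypergeometric tail ``P(X >= observed)``.
    """
    focal = set(focal)
    background = set(background)
    if not focal:
        raise ValueError("empty focal set")
    if not focal <= background:
        raise ValueError("focal set must be a subset of the background")
    on = {s for s in background if lg_assignment.get(s) == lg}
    k = len(focal & on)
    n_f = len(focal)
    K = len(on)
    N = len(background)
    # survival function at k-1 gives P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n_f))
    return EnrichmentResult(
        lg=lg,
        focal_on=k,
        focal_off=n_f - k,
        background_on=K - k,
        background_off=(N - K) - (n_f - k),
        p_value=min(1.0, p),
    )


def partition_report(trait_labels: dict, m_total: int, annotated_genes: dict | None = None) -> pd.DataFrame:
    """Per-trait class-partition table.

    ``trait_labels`` maps trait -> integer labels (0 no effect, 1 polygenic,
    2 small, 3 large) over the panel. Row identities enforced:
    large + small + polygenic == associated, associated + no_effect == m_total.
    """
    rows = []
    for trait, labels in trait_labels.items():
        labels = np.asarray(labels)
        if len(labels) != m_total:
            raise ValueError(f"label vector for {trait!r} does not cover the panel")
        n_large = int((labels == 3).sum())
        n_small = int((labels == 2).sum())
        n_poly = int((labels == 1).sum())
        n_zero = int((labels == 0).sum())
        assoc = n_large + n_small + n_poly
        if assoc + n_zero != m_total:
            raise ValueError("labels do not partition the panel")
        rows.append(
            {
                "trait": trait,
                "associated": assoc,
                "large": n_large,
                "small": n_small,
                "polygenic": n_poly,
                "no_effect": n_zero,
                "annotated_genes": (annotated_genes or {}).get(trait, 0),
            }
        )
    return pd.DataFrame(rows)


def check_partition_row(associated: int, large: int, small: int, polygenic: int,
                        no_effect: int, m_total: int) -> bool:
    """Verify the two partition identities on one printed report row."""
    return (large + small + polygenic == associated) and (associated + no_effect == m_total)


def annotate_snp_context(
    snp_positions: pd.DataFrame, gene_intervals: pd.DataFrame
) -> pd.DataFrame:
    """Label SNPs genic/intergenic against 1-based inclusive gene intervals.

    ``snp_positions`` needs columns snp_id/scaffold/position;
    ``gene_intervals`` needs gene_id/scaffold/start/end (1-based inclusive;
    convert BED half-open input by adding 1 to start). A SNP is genic iff its
    position lies within any interval on its scaffold; the recorded gene is
    the first by start position (ties by gene id).
    """
    gi = gene_intervals.copy()
    if (gi["end"] < gi["start"]).any():
        raise ValueError("malformed interval with end < start")
    gi = gi.sort_values(["scaffold", "start", "gene_id"], kind="stable")
    by_scaffold = {s: g for s, g in gi.groupby("scaffold", sort=False)}
    contexts, genes = [], []
    for _, row in snp_positions.iterrows():
        g = by_scaffold.get(row["scaffold"])
        hit = None
        if g is not None:
            pos = row["position"]
            within = g[(g["start"] <= pos) & (pos <= g["end"])]
            if len(within):
                hit = str(within.iloc[0]["gene_id"])
        contexts.append("genic" if hit else "intergenic")
        genes.append(hit)
    out = snp_positions.copy()
    out["context"] = contexts
    out["gene_id"] = genes
    return out


def bed_to_intervals(bed: pd.DataFrame) -> pd.DataFrame:
    """Convert 0-based half-open BED-style rows (chrom/start/end/name) to the
    1-based inclusive convention used here."""
    return pd.DataFrame(
        {
            "gene_id": bed["name"].astype(str),
            "scaffold": bed["chrom"],
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
        }
    )
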