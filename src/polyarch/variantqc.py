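"""SNP and sample filtering, dosage conversion, and selfing-line correction.

Site filters mirror a vcftools/vcflib pass: call rate >= 0.95, site quality
>= 30, mean depth over called samples in [15, 60], MAF >= 0.01, mean
heterozygote allele balance inside the retained windows (0.25, 0.75) or
(0, 0.01) / (0.99, 1), and a one-sided exact heterozygote-excess test at
p >= 0.001. Samples with more than 40% missing calls are removed afterwards.

Selfing lines get a deterministic genotype correction: under faithful
self-fertilisation homozygosity is absorbing, so a single aberrant call that
follows at least two consecutive identical homozygous calls is corrected to
that homozygote; series the rule cannot resolve are flagged for removal.
A single missing generation is imputed only when no other genotype is
logically possible given both flanking generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, DosageMatrix


@dataclass
class VariantTable:
    """Biallelic variant records with per-sample GT (012 codes), DP and AD."""

    samples: list[str]
    scaffold: list[str]
    position: np.ndarray
    ref: list[str]
    alt: list[str]
    qual: np.ndarray
    gt: np.ndarray  # (records, samples) in {0,1,2,-1}
    dp: np.ndarray  # float, NaN when absent
    ad_ref: np.ndarray
    ad_alt: np.ndarray

    def __post_init__(self) -> None:
        if (np.asarray(self.position) <= 0).any():
            raise ValueError("positions must be positive")

    @property
    def n_records(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_records(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        return VariantTable(
            samples=list(self.samples),
            scaffold=[self.scaffold[i] for i in idx],
            position=self.position[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            qual=self.qual[idx],
            gt=self.gt[idx],
            dp=self.dp[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
        )

    def subset_samples(self, keep) -> "VariantTable":
        keep = np.asarray(keep)
        return VariantTable(
            samples=[self.samples[i] for i in keep],
            scaffold=list(self.scaffold),
            position=self.position,
            ref=list(self.ref),
            alt=list(self.alt),
            qual=self.qual,
            gt=self.gt[:, keep],
            dp=self.dp[:, keep],
            ad_ref=self.ad_ref[:, keep],
            ad_alt=self.ad_alt[:, keep],
        )


@dataclass
class FilterConfig:
    """Thresholds for the site-filter pass; ``None`` disables a criterion."""

    max_missing_fraction: float | None = 0.95  # vcftools --max-missing: call rate floor
    min_quality: float | None = 30.0
    mean_depth_bounds: tuple | None = (15.0, 60.0)
    min_maf: float | None = 0.01
    allele_balance: bool = True
    excess_het_p: float | None = 0.001
    max_sample_missing: float = 0.40


@dataclass
class FilterReport:
    """Removal counts attributed to the first failing criterion per record."""

    removed: dict = field(default_factory=dict)
    kept: int = 0

    def total_removed(self) -> int:
        return sum(self.removed.values())


def excess_het_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """One-sided exact heterozygote-excess p-value.

    Conditional on the observed allele counts, the heterozygote count under
    random union of gametes follows the Levene-Haldane distribution; the
    p-value sums its probabilities over heterozygote counts >= observed
    (same parity as the minor-allele count).
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_ref + n_het  # ref allele count
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)

    def log_prob(h: int) -> float:
        # genotype counts from het count h conditioned on allele counts
        hom_ref = (n_a - h) // 2
        hom_alt = (n_b - h) // 2
        return (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(hom_ref + 1)
            - gammaln(h + 1)
            - gammaln(hom_alt + 1)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    hs = [h for h in range(rare % 2, rare + 1, 2)]
    logs = np.array([log_prob(h) for h in hs])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    tail = sum(p for h, p in zip(hs, probs) if h >= n_het)
    return float(min(1.0, tail))


def _site_stats(vt: VariantTable):
    called = vt.gt != -1
    n_called = called.sum(axis=1)
    call_rate = n_called / max(vt.n_samples, 1)
    gtf = vt.gt.astype(float)
    gtf[~called] = np.nan
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(gtf, axis=1) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    with np.errstate(invalid="ignore"):
        mean_dp = np.nanmean(np.where(called, vt.dp, np.nan), axis=1)
    return called, call_rate, maf, mean_dp


def filter_variants(vt: VariantTable, cfg: FilterConfig | None = None) -> tuple[VariantTable, FilterReport]:
    """Apply site filters; each removed record is attributed to the first
    failing criterion in the order: call rate, quality, mean depth, MAF,
    allele balance, heterozygote excess."""
    cfg = cfg or FilterConfig()
    report = FilterReport(removed={
        "call_rate": 0, "quality": 0, "mean_depth": 0, "maf": 0,
        "allele_balance": 0, "excess_het": 0,
    })
    if vt.n_records == 0:
        return vt, report
    if vt.n_samples == 0:
        raise ValueError("variant table has no samples")
    called, call_rate, maf, mean_dp = _site_stats(vt)
    ad_available = np.isfinite(vt.ad_ref).any() or np.isfinite(vt.ad_alt).any()
    if cfg.allele_balance and not ad_available:
        warnings.warn("no AD fields present; skipping allele-balance filter", stacklevel=2)
    keep = []
    for r in range(vt.n_records):
        if cfg.max_missing_fraction is not None and call_rate[r] < cfg.max_missing_fraction:
            report.removed["call_rate"] += 1
            continue
        if cfg.min_quality is not None and (
            np.isnan(vt.qual[r]) or vt.qual[r] < cfg.min_quality
        ):
            report.removed["quality"] += 1
            continue
        if cfg.mean_depth_bounds is not None:
            lo, hi = cfg.mean_depth_bounds
            if np.isnan(mean_dp[r]) or not (lo <= mean_dp[r] <= hi):
                report.removed["mean_depth"] += 1
                continue
        if cfg.min_maf is not None and (np.isnan(maf[r]) or maf[r] < cfg.min_maf):
            report.removed["maf"] += 1
            continue
        if cfg.allele_balance and ad_available:
            het = (vt.gt[r] == 1) & np.isfinite(vt.ad_ref[r]) & np.isfinite(vt.ad_alt[r])
            if het.any():
                tot = vt.ad_ref[r, het] + vt.ad_alt[r, het]
                ok = tot > 0
                if ok.any():
                    ab = float(np.mean(vt.ad_ref[r, het][ok] / tot[ok]))
                    retained = (0.25 < ab < 0.75) or ab < 0.01 or ab > 0.99
                    if not retained:
                        report.removed["allele_balance"] += 1
                        continue
        if cfg.excess_het_p is not None:
            h = int((vt.gt[r] == 1).sum())
            hr = int((vt.gt[r] == 0).sum())
            ha = int((vt.gt[r] == 2).sum())
            if excess_het_exact_p(h, hr, ha) < cfg.excess_het_p:
                report.removed["excess_het"] += 1
                continue
        keep.append(r)
    report.kept = len(keep)
    return vt.subset_records(keep), report


def remove_high_missing_samples(
    vt: VariantTable, max_missing: float = 0.40
) -> tuple[VariantTable, list[str]]:
    """Drop samples whose missing fraction is strictly greater than the cutoff."""
    if vt.n_records == 0:
        return vt, []
    miss_frac = (vt.gt == -1).mean(axis=0)
    removed = [vt.samples[i] for i in range(vt.n_samples) if miss_frac[i] > max_missing]
    keep = [i for i in range(vt.n_samples) if miss_frac[i] <= max_missing]
    if not keep:
        raise ValueError("all samples removed by missingness filter")
    return vt.subset_samples(keep), removed


def to_dosage(vt: VariantTable) -> DosageMatrix:
    """Convert calls to a dosage matrix (individuals x SNPs, missing -1),
    the vcftools ``--012`` convention; the SNP map records per-SNP MAF."""
    vals = vt.gt.T.astype(np.int8)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"{c}:{p}" for c, p in zip(vt.scaffold, vt.position)],
            "scaffold": list(vt.scaffold),
            "position": vt.position.astype(int),
        }
    )
    dm = DosageMatrix(vals, list(vt.samples), snp_map)
    dm.snp_map["maf"] = dm.minor_allele_frequencies()
    return dm


# ---------------------------------------------------------------------------
# selfing-line genotype correction


@dataclass
class CorrectionResult:
    """Outcome of correcting one line x locus series."""

    series: list[int] | None  # None when the series is flagged for removal
    removed: bool
    log: list[tuple]  # (generation index, old call, new call)


def _next_nonmissing(series: list[int], start: int) -> int | None:
    for v in series[start:]:
        if v != MISSING:
            return v
    return None


def correct_selfing_line(series: list[int]) -> CorrectionResult:
    """Correct single aberrant calls in a per-generation selfing series.

    The series holds dosage calls (0/2 homozygous, 1 heterozygous, -1 missing)
    ordered FS -> S_t. A call that conflicts with an established homozygous
    state (>= 2 consecutive identical homozygous calls, missing entries
    transparent) is corrected to that homozygote when it is a lone aberration
    (the following non-missing call, if any, returns to the established
    state). Conflicts with shorter runs, or runs of >= 2 conflicting calls,
    cannot be resolved and flag the series for removal.
    """
    non_missing = [v for v in series if v != MISSING]
    if len(non_missing) < 2:
        return CorrectionResult(None, True, [])
    out = list(series)
    run_val: int | None = None  # established homozygote, if any
    run_len = 0
    log: list[tuple] = []
    positions = [i for i, v in enumerate(series) if v != MISSING]
    for pi, i in enumerate(positions):
        v = out[i]
        if v in (0, 2):
            if run_val == v:
                run_len += 1
            elif run_len >= 2:
                # opposite homozygote after an established run
                nxt = out[positions[pi + 1]] if pi + 1 < len(positions) else None
                if nxt is None or nxt == run_val:
                    log.append((i, v, run_val))
                    out[i] = run_val
                    run_len += 1
                else:
                    return CorrectionResult(None, True, [])
            elif run_val is not None and run_len >= 1:
                # hom -> opposite hom with only one prior call: unresolvable
                return CorrectionResult(None, True, [])
            else:
                run_val, run_len = v, 1
        else:  # heterozygous
            if run_len >= 2:
                nxt = out[positions[pi + 1]] if pi + 1 < len(positions) else None
                if nxt is None or nxt == run_val:
                    log.append((i, v, run_val))
                    out[i] = run_val
                    run_len += 1
                else:
                    return CorrectionResult(None, True, [])
            elif run_val is not None and run_len >= 1:
                # het after a single homozygous call: unresolvable
                return CorrectionResult(None, True, [])
            else:
                run_val, run_len = None, 0
    return CorrectionResult(out, False, log)


def impute_missing_generation(series: list[int]) -> list[int]:
    """Fill a single internal missing generation when logically forced.

    Under faithful selfing a homozygous parent transmits its genotype, so
    the possibilities from the previous call are {g} (prev homozygous g) or
    {0, 1, 2} (prev heterozygous); the possibilities from the next call are
    {1} (next heterozygous forces a heterozygous parent) or {g, 1} (next
    homozygous g). The missing call is imputed iff the intersection is a
    single genotype; otherwise (ambiguous or inconsistent) it stays missing.
    """
    out = list(series)
    miss_idx = [i for i, v in enumerate(series) if v == MISSING]
    for i in miss_idx:
        if i == 0 or i == len(series) - 1:
            continue
        prev, nxt = series[i - 1], series[i + 1]
        if prev == MISSING or nxt == MISSING:
            continue
        from_prev = {prev} if prev in (0, 2) else {0, 1, 2}
        from_next = {1} if nxt == 1 else {nxt, 1}
        poss = from_prev & from_next
        if len(poss) == 1:
            out[i] = poss.pop()
    return out


def correct_selfing_study(genotypes: DosageMatrix, pedigree: pd.DataFrame):
    """Apply :func:`correct_selfing_line` to every line x SNP of a selfing
    study; returns (corrected DosageMatrix, log frame, removal frame).

    Removed line x SNP series have all their calls set to missing.
    """
    vals = genotypes.values.copy()
    lines = (
        pedigree[pedigree["generation"] >= 0]
        .groupby(["family", "line"], sort=True)
        .groups
    )
    log_rows, removed_rows = [], []
    for (fam, line), idx in lines.items():
        rows = pedigree.loc[idx].sort_values("generation").index.to_numpy()
        for j in range(genotypes.n_snps):
            series = [int(v) for v in vals[rows, j]]
            res = correct_selfing_line(series)
            if res.removed:
                vals[rows, j] = MISSING
                removed_rows.append((fam, line, j))
            else:
                for gi, old, new in res.log:
                    log_rows.append((fam, line, j, gi, old, new))
                vals[rows, j] = res.series
    corrected = DosageMatrix(vals, list(genotypes.ids), genotypes.snp_map.copy())
    log = pd.DataFrame(log_rows, columns=["family", "line", "snp", "generation_idx", "old", "new"])
    removed = pd.DataFrame(removed_rows, columns=["family", "line", "snp"])
    return corrected, log, removed
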