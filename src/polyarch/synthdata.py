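"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (QC, relationship matrices, REML,
the Bayesian mixture model, the selfing analyses, the ring corrections) is
exercised on data produced here, where the generative truth — per-SNP effects
and their mixture classes, breeding values, pedigree inbreeding, injected
genotyping errors, missed-pith geometry — is recorded alongside the data.

The emulated study: a training population of maternal half-sib families from
a polycross mating design planted over three sites in incomplete blocks, with
per-site means and per-site residual variances; and a selfing program of 15
unrelated full-sib founder families propagated by repeated self-fertilisation
over five generations, with "select" lines choosing the tallest seedling by
phenotype each generation and "random" lines choosing uniformly.

SNP effects are drawn from a four-component normal mixture with variances
(0, 1e-4, 1e-3, 1e-2) x sigma_g2, the same class structure the Bayesian
mixture model assumes. Loci are unlinked; transmission is Mendelian per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, DosageMatrix, default_snp_map, make_pedigree
from .dendro import RingSeries

#: Mixture variance fractions: zero, polygenic, small, large.
GAMMA = (0.0, 1e-4, 1e-3, 1e-2)
CLASS_NAMES = ("zero", "polygenic", "small", "large")


@dataclass
class SimConfig:
    """Study-level configuration for the polycross training population."""

    n_founders: int = 52
    n_families: int = 26
    progeny_per_family_per_site: int = 20
    n_sites: int = 3
    n_snps: int = 2000
    maf_distribution: tuple = ("uniform", 0.01, 0.5)
    mixture_proportions: tuple = (0.94, 0.04, 0.015, 0.005)
    # mixture scale: with the default 2000-SNP panel and MAF spectrum the
    # realized additive variance is ~0.04 * sigma_g2, so 8.0 puts the default
    # trait near h2 = 0.25 against unit-scale site residuals
    sigma_g2: float = 8.0
    site_means: tuple = (0.0, 2.0, -1.0)
    site_resid_vars: tuple = (1.0, 1.5, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.mixture_proportions, dtype=float)
        if props.shape != (4,) or abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise ValueError("mixture_proportions must be 4 non-negative values summing to 1")
        if self.sigma_g2 < 0 or any(v < 0 for v in self.site_resid_vars):
            raise ValueError("variances must be non-negative")
        _check_maf_spec(self.maf_distribution)
        if len(self.site_means) != self.n_sites or len(self.site_resid_vars) != self.n_sites:
            raise ValueError("site_means/site_resid_vars must have n_sites entries")


@dataclass
class TrueArchitecture:
    """Ground-truth per-SNP mixture class and additive effect."""

    classes: np.ndarray  # int in 0..3
    effects: np.ndarray  # per-allele effect, trait units

    @property
    def class_names(self) -> list[str]:
        return [CLASS_NAMES[k] for k in self.classes]


@dataclass
class SelfingStudy:
    """A simulated selfing program: pedigree, genotypes, BVs, phenotypes.

    ``pedigree`` has one row per tree with columns id, sire, dam, generation
    (-1 for outbred parents, 0 for the full-sib generation, t for S_t),
    family, line and line_type ("select" | "random"; parents ``None``).
    ``genotypes`` rows align with ``pedigree`` rows.
    """

    pedigree: pd.DataFrame
    genotypes: DosageMatrix
    true_bv: pd.Series
    phenotypes: pd.DataFrame
    h2_height: float
    error_log: pd.DataFrame | None = None

    def line_series(self, family: int, line: int, snp: int) -> list[int]:
        """Per-generation dosage calls for one line at one locus, FS..S_max."""
        ped = self.pedigree
        sel = ped[(ped["family"] == family) & (ped["line"] == line) & (ped["generation"] >= 0)]
        sel = sel.sort_values("generation")
        rows = sel.index.to_numpy()
        return [int(v) for v in self.genotypes.values[rows, snp]]


def _check_maf_spec(spec) -> None:
    kind = spec[0]
    if kind == "fixed":
        if not (0.0 < spec[1] <= 0.5):
            raise ValueError("fixed MAF must be in (0, 0.5]")
    elif kind == "uniform":
        lo, hi = spec[1], spec[2]
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("uniform MAF bounds must satisfy 0 < lo <= hi <= 0.5")
    else:
        raise ValueError(f"unknown MAF spec kind {kind!r}")


def _draw_mafs(m: int, spec, rng: np.random.Generator) -> np.ndarray:
    _check_maf_spec(spec)
    if spec[0] == "fixed":
        return np.full(m, float(spec[1]))
    return rng.uniform(spec[1], spec[2], size=m)


def simulate_founders(n: int, m: int, maf_spec=("uniform", 0.01, 0.5), seed: int = 0) -> DosageMatrix:
    """Unrelated founders under Hardy-Weinberg: dosage ~ Binomial(2, p) per locus."""
    if n < 1:
        raise ValueError("need at least one founder")
    if m < 0:
        raise ValueError("negative SNP count")
    rng = np.random.default_rng(seed)
    mafs = _draw_mafs(m, maf_spec, rng)
    # locus-major draw order keeps seeds reproducible when n changes
    vals = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        vals[:, j] = rng.binomial(2, mafs[j], size=n)
    snp_map = default_snp_map(m)
    snp_map["true_maf"] = mafs
    snp_map["realized_freq"] = vals.mean(axis=0) / 2.0 if n else np.nan
    ids = [f"F{i:04d}" for i in range(n)]
    return DosageMatrix(vals, ids, snp_map)


def _gametes(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Mendelian gamete per (individual, locus): 0/2 transmit faithfully, 1 segregates."""
    g = (dosages // 2).astype(np.int8)
    het = dosages == 1
    if het.any():
        g[het] = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
    return g


def simulate_polycross_progeny(
    founders: DosageMatrix,
    n_families: int,
    per_family_per_site: int,
    n_sites: int,
    seed: int = 0,
) -> tuple[DosageMatrix, pd.DataFrame]:
    """Maternal half-sib progeny: one dam per family, sire redrawn per offspring.

    Emulates a polycross: each family's dam is pollinated by a mixed pollen
    pool (all founders except the dam), so family members share the dam and
    have independently drawn sires. Site assignment is balanced per family.
    """
    if founders.n_individuals < 2:
        raise ValueError("need at least two founders")
    if founders.n_individuals < n_families:
        raise ValueError("fewer founders than families")
    rng = np.random.default_rng(seed)
    n_off = n_families * per_family_per_site * n_sites
    m = founders.n_snps
    vals = np.empty((n_off, m), dtype=np.int8)
    ids, sires, dams, fams, sites = [], [], [], [], []
    dam_idx = rng.choice(founders.n_individuals, size=n_families, replace=False)
    row = 0
    for fam in range(n_families):
        d = dam_idx[fam]
        dam_dos = founders.values[d]
        for site in range(n_sites):
            for k in range(per_family_per_site):
                s = int(rng.integers(0, founders.n_individuals - 1))
                if s >= d:
                    s += 1  # pollen pool excludes the dam
                dam_gam = _gametes(dam_dos[None, :], rng)[0]
                sire_gam = _gametes(founders.values[s][None, :], rng)[0]
                vals[row] = dam_gam + sire_gam
                ids.append(f"P{fam:02d}_{site}_{k:03d}")
                sires.append(founders.ids[s])
                dams.append(founders.ids[d])
                fams.append(fam)
                sites.append(site)
                row += 1
    progeny = DosageMatrix(vals, ids, founders.snp_map.copy())
    ped = make_pedigree(ids, sires, dams, family=fams, site=sites)
    return progeny, ped


def draw_true_architecture(
    m: int,
    mixture_proportions,
    sigma_g2: float,
    seed: int = 0,
) -> TrueArchitecture:
    """Per-SNP class ~ Multinomial(pi); effect | class k ~ N(0, gamma_k * sigma_g2)."""
    props = np.asarray(mixture_proportions, dtype=float)
    if props.shape != (4,) or abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
        raise ValueError("mixture proportions must be 4 values summing to 1")
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be non-negative")
    rng = np.random.default_rng(seed)
    classes = rng.choice(4, size=m, p=props)
    sds = np.sqrt(np.array(GAMMA) * sigma_g2)[classes]
    effects = np.where(sds > 0, rng.normal(0.0, 1.0, size=m) * sds, 0.0)
    return TrueArchitecture(classes=classes, effects=effects)


def simulate_phenotypes(
    D: DosageMatrix,
    arch: TrueArchitecture,
    sites: np.ndarray,
    site_means,
    site_resid_vars,
    seed: int = 0,
    replicates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Phenotypes y = site mean + sum_j d_ij beta_j + e_i, e ~ N(0, s2_e(site)).

    Missing dosages are mean-imputed before computing genetic values (and the
    returned frame flags whether any imputation happened). The true breeding
    value is stored per individual.
    """
    sites = np.asarray(sites)
    if len(sites) != D.n_individuals:
        raise ValueError("site assignment length mismatch")
    if len(arch.effects) != D.n_snps:
        raise ValueError("architecture size mismatch")
    rng = np.random.default_rng(seed)
    had_missing = bool((D.values == MISSING).any())
    dos = D.imputed()
    bv = dos @ arch.effects
    means = np.asarray(site_means, dtype=float)[sites]
    sds = np.sqrt(np.asarray(site_resid_vars, dtype=float))[sites]
    e = rng.normal(0.0, 1.0, size=D.n_individuals) * sds
    out = pd.DataFrame(
        {
            "id": D.ids,
            "site": sites,
            "y": means + bv + e,
            "true_bv": bv,
        }
    )
    if replicates is not None:
        out["replicate"] = np.asarray(replicates)
    out.attrs["imputed_missing"] = had_missing
    return out


def _standardized_height_effects(
    founders: DosageMatrix, h2_height: float, rng: np.random.Generator
) -> np.ndarray:
    """iid SNP effects rescaled so founder BV variance equals h2 (phenotype var 1)."""
    if h2_height == 0.0:
        return np.zeros(founders.n_snps)
    raw = rng.normal(0.0, 1.0, size=founders.n_snps)
    bv = founders.values.astype(float) @ raw
    v = bv.var()
    if v == 0:
        return np.zeros(founders.n_snps)
    return raw * np.sqrt(h2_height / v)


def simulate_selfing_program(
    founders: DosageMatrix,
    n_fs_families: int = 15,
    generations: int = 5,
    lines_per_family: int = 2,
    replicates: int = 3,
    selection_rule: str = "select_top_height",
    h2_height: float = 0.5,
    seed: int = 0,
) -> SelfingStudy:
    """A selfing-with-selection program over FS..S_generations.

    ``n_fs_families`` unrelated founder pairs are outcrossed to full-sib (FS)
    families (pedigree F = 0). From each family's FS cohort, ``lines_per_family``
    "select" lines (tallest seedlings by phenotype, standard-normal deviates)
    and ``lines_per_family`` "random" lines are founded; each line then advances
    one tree per generation by self-fertilising the current tree and choosing
    among a cohort of ``2 * replicates`` selfed offspring by the line's rule.
    Under ``selection_rule="random"`` even the select-labelled lines choose
    uniformly (a null program). Heights have heritability ``h2_height`` on a
    unit-phenotypic-variance scale.
    """
    if generations < 1:
        raise ValueError("need at least one selfed generation")
    if founders.n_individuals < 2 * n_fs_families:
        raise ValueError("need 2 founders per FS family")
    if selection_rule not in ("select_top_height", "random"):
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    rng = np.random.default_rng(seed)
    effects = _standardized_height_effects(founders, h2_height, rng)
    resid_sd = np.sqrt(max(0.0, 1.0 - h2_height))
    cohort = 2 * replicates

    rows_vals: list[np.ndarray] = []
    recs: list[dict] = []

    def add_tree(dos, tid, sire, dam, gen, fam, line, ltype):
        rows_vals.append(dos.astype(np.int8))
        recs.append(
            dict(id=tid, sire=sire, dam=dam, generation=gen, family=fam, line=line, line_type=ltype)
        )

    # founder parents (generation -1)
    for i in range(2 * n_fs_families):
        add_tree(founders.values[i], founders.ids[i], None, None, -1, i // 2, None, None)

    line_types = ["select"] * lines_per_family + ["random"] * lines_per_family
    for fam in range(n_fs_families):
        p1, p2 = 2 * fam, 2 * fam + 1
        # FS cohort for this family
        n_fs = cohort * len(line_types)
        fs_dos = np.empty((n_fs, founders.n_snps), dtype=np.int8)
        for i in range(n_fs):
            fs_dos[i] = (
                _gametes(founders.values[p1][None, :], rng)[0]
                + _gametes(founders.values[p2][None, :], rng)[0]
            )
        fs_bv = fs_dos.astype(float) @ effects
        fs_pheno = fs_bv + rng.normal(0.0, 1.0, size=n_fs) * resid_sd
        order = np.argsort(-fs_pheno, kind="stable")
        picked: list[int] = []
        for li, ltype in enumerate(line_types):
            if ltype == "select" and selection_rule == "select_top_height":
                cand = [i for i in order if i not in picked]
                choice = cand[0]
            else:
                cand = [i for i in range(n_fs) if i not in picked]
                choice = cand[int(rng.integers(0, len(cand)))]
            picked.append(choice)
            add_tree(
                fs_dos[choice],
                f"L{fam:02d}.{li}_G0",
                founders.ids[p1],
                founders.ids[p2],
                0,
                fam,
                li,
                ltype,
            )
            # advance the line by selfing
            current = fs_dos[choice]
            for t in range(1, generations + 1):
                off = np.empty((cohort, founders.n_snps), dtype=np.int8)
                for i in range(cohort):
                    off[i] = (
                        _gametes(current[None, :], rng)[0] + _gametes(current[None, :], rng)[0]
                    )
                bv = off.astype(float) @ effects
                ph = bv + rng.normal(0.0, 1.0, size=cohort) * resid_sd
                if ltype == "select" and selection_rule == "select_top_height":
                    k = int(np.argmax(ph))
                else:
                    k = int(rng.integers(0, cohort))
                parent_id = recs[-1]["id"]
                add_tree(off[k], f"L{fam:02d}.{li}_G{t}", parent_id, parent_id, t, fam, li, ltype)
                current = off[k]

    ped = pd.DataFrame(recs)
    geno = DosageMatrix(np.vstack(rows_vals), list(ped["id"]), founders.snp_map.copy())
    bv_all = geno.values.astype(float) @ effects
    pheno = pd.DataFrame(
        {
            "id": ped["id"],
            "generation": ped["generation"],
            "family": ped["family"],
            "line": ped["line"],
            "line_type": ped["line_type"],
            "true_bv": bv_all,
            "height": bv_all + rng.normal(0.0, 1.0, size=len(ped)) * resid_sd,
        }
    )
    return SelfingStudy(
        pedigree=ped,
        genotypes=geno,
        true_bv=pd.Series(bv_all, index=list(ped["id"])),
        phenotypes=pheno,
        h2_height=h2_height,
    )


def inject_genotype_errors(
    study: SelfingStudy,
    hom_to_het_rate: float,
    hom_to_opposite_rate: float = 0.0,
    seed: int = 0,
) -> SelfingStudy:
    """Flip homozygous calls to heterozygous (and optionally to the opposite
    homozygote) at the stated rates; the truth log records every flip."""
    for r in (hom_to_het_rate, hom_to_opposite_rate):
        if not (0.0 <= r <= 1.0):
            raise ValueError("error rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vals = study.genotypes.values.copy()
    hom = (vals == 0) | (vals == 2)
    u = rng.random(vals.shape)
    to_het = hom & (u < hom_to_het_rate)
    to_opp = hom & (u >= hom_to_het_rate) & (u < hom_to_het_rate + hom_to_opposite_rate)
    log_rows = []
    ridx, cidx = np.where(to_het)
    for i, j in zip(ridx, cidx):
        log_rows.append((study.genotypes.ids[i], int(i), int(j), int(vals[i, j]), 1))
        vals[i, j] = 1
    ridx, cidx = np.where(to_opp)
    for i, j in zip(ridx, cidx):
        new = 2 - int(vals[i, j])
        log_rows.append((study.genotypes.ids[i], int(i), int(j), int(vals[i, j]), new))
        vals[i, j] = new
    log = pd.DataFrame(log_rows, columns=["id", "row", "snp", "old", "new"])
    geno = DosageMatrix(vals, list(study.genotypes.ids), study.genotypes.snp_map.copy())
    return SelfingStudy(
        pedigree=study.pedigree,
        genotypes=geno,
        true_bv=study.true_bv,
        phenotypes=study.phenotypes,
        h2_height=study.h2_height,
        error_log=log,
    )


def dosage_to_variant_table(
    D: DosageMatrix, qual: float = 50.0, depth: float = 30.0, seed: int = 0
):
    """Wrap a dosage panel as a variant table with synthetic QC fields.

    Generates per-call depths around ``depth`` and allelic depths consistent
    with each call (balanced for heterozygotes), so simulated panels can be
    written as VCF and pushed through the filtering stages.
    """
    from .variantqc import VariantTable

    rng = np.random.default_rng(seed)
    gt = D.values.T.astype(np.int8)  # records x samples
    n_r, n_s = gt.shape
    dp = rng.poisson(depth, (n_r, n_s)).astype(float)
    dp[dp < 2] = 2.0
    ad_ref = np.where(gt == 1, np.round(dp / 2.0), np.where(gt == 0, dp, 0.0))
    ad_ref[gt == MISSING] = np.nan
    dpm = dp.copy()
    dpm[gt == MISSING] = np.nan
    return VariantTable(
        samples=list(D.ids),
        scaffold=[str(s) for s in D.snp_map["scaffold"]],
        position=D.snp_map["position"].to_numpy(int),
        ref=["A"] * n_r,
        alt=["G"] * n_r,
        qual=np.full(n_r, float(qual)),
        gt=gt,
        dp=dpm,
        ad_ref=ad_ref,
        ad_alt=dpm - ad_ref,
    )


def simulate_ring_core(
    n_rings: int,
    width_model=("constant", 1.0),
    pith_intercepted: bool = True,
    arc_params: dict | None = None,
    sapwood_rings: int = 0,
    seed: int = 0,
) -> RingSeries:
    """A synthetic increment core with known totals.

    When ``pith_intercepted`` is False, ``arc_params`` must give the true
    missed radius ``radius`` (mm) and the arc sagitta ``height`` (mm < radius);
    the chord is derived from the circle so the downstream chord-sagitta
    correction recovers ``radius`` exactly. Truth fields: ``missed_radius``,
    ``missed_rings`` (constant-width models), ``total_radius``.
    """
    if n_rings < 3:
        raise ValueError("need at least three rings")
    if sapwood_rings > n_rings:
        raise ValueError("sapwood ring count exceeds ring count")
    rng = np.random.default_rng(seed)
    kind = width_model[0]
    if kind == "constant":
        widths = [float(width_model[1])] * n_rings
    elif kind == "lognormal":
        mu, sd = width_model[1], width_model[2]
        widths = list(rng.lognormal(mu, sd, size=n_rings))
    else:
        raise ValueError(f"unknown width model {kind!r}")
    truth: dict = {"measured_radius": float(sum(widths))}
    arc_l = arc_h = None
    if not pith_intercepted:
        if not arc_params or "radius" not in arc_params:
            raise ValueError("arc_params with 'radius' required when pith missed")
        r = float(arc_params["radius"])
        h = float(arc_params.get("height", r / 2.0))
        if not (0 < h <= 2 * r):
            raise ValueError("sagitta must be in (0, 2r]")
        arc_h = h
        arc_l = float(np.sqrt(4.0 * h * (2.0 * r - h)))
        truth["missed_radius"] = r
        if kind == "constant":
            w = float(width_model[1])
            truth["missed_rings"] = int(np.floor(r / w + 0.5))
    else:
        truth["missed_radius"] = 0.0
        truth["missed_rings"] = 0
    truth["total_radius"] = truth["measured_radius"] + truth["missed_radius"]
    years = list(range(2016 - n_rings + 1, 2017))
    return RingSeries(
        widths=widths,
        years=years,
        arc_length=arc_l,
        arc_height=arc_h,
        sapwood_rings=sapwood_rings,
        truth=truth,
    )
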