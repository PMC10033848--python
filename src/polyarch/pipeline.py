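"""End-to-end pipeline runner driven by a single YAML-style configuration.

Stages run in declaration order over a shared in-memory context, each writing
its artifacts under ``<out_dir>/<stage>/`` and appending them to a manifest
with content checksums. The global seed derives a per-stage seed by stable
hashing of the stage name, so adding or reordering stages does not perturb
other stages' randomness and identical config + seed reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import bayesr as br
from . import quantgen as qg
from . import synthdata as sd
from .containers import write_012
from .relatedness import compute_grrm
from .variantqc import FilterConfig, filter_variants

log = logging.getLogger("polyarch")


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(cfg: dict) -> None:
    for key in ("seed", "out_dir", "stages"):
        if key not in cfg:
            raise ValueError(f"pipeline config missing required key '{key}'")
    for st in cfg["stages"]:
        if "name" not in st:
            raise ValueError("pipeline stage missing required key 'name'")


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    validate_config(cfg)
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {}
    manifest: dict = {"seed": seed, "stages": [], "files": {}}
    for st in cfg["stages"]:
        name = st["name"]
        params = st.get("params", {})
        sdir = out_dir / name
        sdir.mkdir(parents=True, exist_ok=True)
        s_seed = stage_seed(seed, name)
        t0 = time.time()
        log.info("stage=%s seed=%d starting", name, s_seed)
        try:
            files = _STAGES[st.get("type", name)](ctx, sdir, s_seed, params)
        except KeyError as exc:
            raise ValueError(f"unknown stage type for stage {name!r}") from exc
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        for f in files:
            manifest["files"][str(f.relative_to(out_dir))] = _checksum(f)
        manifest["stages"].append(name)
        log.info("stage=%s done in %.1fs", name, time.time() - t0)
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(ctx, sdir: Path, seed: int, params: dict):
    cfg = sd.SimConfig(seed=seed, **params)
    founders = sd.simulate_founders(cfg.n_founders, cfg.n_snps, cfg.maf_distribution, seed)
    progeny, ped = sd.simulate_polycross_progeny(
        founders, cfg.n_families, cfg.progeny_per_family_per_site, cfg.n_sites, seed + 1
    )
    arch = sd.draw_true_architecture(cfg.n_snps, cfg.mixture_proportions, cfg.sigma_g2, seed + 2)
    pheno = sd.simulate_phenotypes(
        progeny, arch, ped["site"].to_numpy(), cfg.site_means, cfg.site_resid_vars, seed + 3
    )
    write_012(progeny, str(sdir / "progeny"))
    ped.to_csv(sdir / "pedigree.csv", index=False)
    pheno.to_csv(sdir / "phenotypes.tsv", sep="\t", index=False)
    progeny.snp_map.to_csv(sdir / "snp_map.tsv", sep="\t", index=False)
    truth = {
        "classes": [int(c) for c in arch.classes],
        "effects": [float(b) for b in arch.effects],
        "sigma_g2": cfg.sigma_g2,
    }
    (sdir / "truth.json").write_text(json.dumps(truth))
    ctx.update(progeny=progeny, pedigree=ped, phenotypes=pheno, arch=arch, sim_cfg=cfg)
    return [
        sdir / "progeny.012", sdir / "progeny.012.indv", sdir / "progeny.012.pos",
        sdir / "pedigree.csv", sdir / "phenotypes.tsv", sdir / "snp_map.tsv",
        sdir / "truth.json",
    ]


def _stage_grm(ctx, sdir: Path, seed: int, params: dict):
    G = compute_grrm(ctx["progeny"])
    G.to_frame().to_csv(sdir / "grrm.tsv", sep="\t")
    ctx["grrm"] = G
    return [sdir / "grrm.tsv"]


def _stage_reml(ctx, sdir: Path, seed: int, params: dict):
    data = ctx["phenotypes"].copy()
    data["site"] = data["site"].astype(str)
    spec = qg.ModelSpec(response="y", fixed=["site"], residual=params.get("residual", "by_site"))
    fit = qg.fit_univariate_reml(spec, data, ctx["grrm"])
    h2 = qg.estimate_h2(fit)
    out = {
        "varcomp": fit.varcomp,
        "h2": h2.h2,
        "h2_se": h2.se,
        "loglik": fit.loglik,
        "converged": fit.converged,
    }
    (sdir / "reml.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    fit.blup.rename("blup").to_csv(sdir / "blup.tsv", sep="\t")
    ctx["reml_fit"] = fit
    return [sdir / "reml.json", sdir / "blup.tsv"]


def _stage_bayesr(ctx, sdir: Path, seed: int, params: dict):
    data = ctx["phenotypes"].copy()
    data["site"] = data["site"].astype(str)
    adj = qg.adjust_phenotypes(qg.ModelSpec(response="y", fixed=["site"]), data)
    cfg = br.desk_profile(**params)
    summary, report = br.run_bayesr(
        adj.residuals.to_numpy(), ctx["progeny"], cfg, seed=seed
    )
    summary.to_frame().to_csv(sdir / "snp_summary.tsv", sep="\t", index=False)
    conv = {"psrf": report.psrf, "passed": report.passed}
    (sdir / "convergence.json").write_text(json.dumps(conv, indent=2, sort_keys=True))
    ctx["bayesr_summary"] = summary
    return [sdir / "snp_summary.tsv", sdir / "convergence.json"]


def _stage_architecture(ctx, sdir: Path, seed: int, params: dict):
    from .architecture import partition_report

    summary = ctx["bayesr_summary"]
    labels = br.assign_snps_to_classes(summary)
    report = partition_report({"trait": labels}, len(labels))
    report.to_csv(sdir / "partition.tsv", sep="\t", index=False)
    ctx["labels"] = labels
    return [sdir / "partition.tsv"]


def _stage_filter(ctx, sdir: Path, seed: int, params: dict):
    vt = ctx["variant_table"]
    cfg = FilterConfig(**params)
    vt2, report = filter_variants(vt, cfg)
    (sdir / "filter_report.json").write_text(
        json.dumps({"removed": report.removed, "kept": report.kept}, indent=2, sort_keys=True)
    )
    ctx["variant_table"] = vt2
    return [sdir / "filter_report.json"]


_STAGES = {
    "simulate": _stage_simulate,
    "grm": _stage_grm,
    "reml": _stage_reml,
    "bayesr": _stage_bayesr,
    "architecture": _stage_architecture,
    "filter": _stage_filter,
}
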