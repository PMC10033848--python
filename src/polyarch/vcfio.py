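"""Read/write a VCF v4.2 subset (GT required, DP/AD optional, biallelic only).

Reading goes through :mod:`cyvcf2`; multi-allelic records are skipped with a
warning, genotype phase is ignored. Writing emits plain uncompressed text so
round-trips are bit-exact on calls, depths and quality.
"""

from __future__ import annotations

import warnings

import numpy as np

from .variantqc import VariantTable

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def read_vcf_subset(path: str) -> VariantTable:
    """Parse a VCF into a :class:`VariantTable`; rejects multi-allelic records."""
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # noqa: BLE001 - cyvcf2 raises plain Exception
        raise ValueError(f"failed to parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alt, qual = [], [], [], [], []
    gts, dps, ad_refs, ad_alts = [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        qual.append(rec.QUAL if rec.QUAL is not None else np.nan)
        gt = np.asarray(rec.gt_types).astype(np.int8)  # gts012: 3 == unknown
        gt[gt == 3] = -1
        gts.append(gt)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        dps.append(dp[:, 0].astype(float) if dp is not None else np.full(len(samples), np.nan))
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            ar = ad[:, 0].astype(float)
            aa = ad[:, 1].astype(float)
            ar[ar < 0] = np.nan
            aa[aa < 0] = np.nan
        else:
            ar = np.full(len(samples), np.nan)
            aa = np.full(len(samples), np.nan)
        ad_refs.append(ar)
        ad_alts.append(aa)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic record(s)", stacklevel=2)
    n = len(chrom)
    shape = (n, len(samples))
    return VariantTable(
        samples=samples,
        scaffold=chrom,
        position=np.array(pos, dtype=int),
        ref=ref,
        alt=alt,
        qual=np.array(qual, dtype=float),
        gt=np.vstack(gts).astype(np.int8) if n else np.empty(shape, dtype=np.int8),
        dp=np.vstack(dps) if n else np.empty(shape),
        ad_ref=np.vstack(ad_refs) if n else np.empty(shape),
        ad_alt=np.vstack(ad_alts) if n else np.empty(shape),
    )


def write_vcf_subset(vt: VariantTable, path: str) -> None:
    """Write a minimal VCF v4.2 with GT/DP/AD FORMAT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in dict.fromkeys(vt.scaffold):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vt.samples) + "\n")
        for r in range(vt.n_records):
            qual = "." if np.isnan(vt.qual[r]) else f"{vt.qual[r]:g}"
            cells = []
            for s in range(vt.n_samples):
                gt = _GT_STRINGS[int(vt.gt[r, s])]
                dp = "." if np.isnan(vt.dp[r, s]) else str(int(vt.dp[r, s]))
                if np.isnan(vt.ad_ref[r, s]) or np.isnan(vt.ad_alt[r, s]):
                    ad = ".,."
                else:
                    ad = f"{int(vt.ad_ref[r, s])},{int(vt.ad_alt[r, s])}"
                cells.append(f"{gt}:{dp}:{ad}")
            fh.write(
                f"{vt.scaffold[r]}\t{int(vt.position[r])}\t.\t{vt.ref[r]}\t{vt.alt[r]}"
                f"\t{qual}\t.\t.\tGT:DP:AD\t" + "\t".join(cells) + "\n"
            )
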