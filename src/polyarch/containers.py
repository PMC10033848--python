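"""Core in-memory containers shared across the pipeline.

Genotypes travel as a :class:`DosageMatrix`: an individuals x SNPs matrix of
alternate-allele counts {0, 1, 2} with ``-1`` marking missing calls, plus a
SNP map (scaffold, position, optional linkage group and genic context) and row
identifiers. Pedigrees are plain :class:`pandas.DataFrame` objects with
``id``/``sire``/``dam`` columns (missing parents encoded as ``NA``/None).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

SNP_MAP_COLUMNS = ["snp_id", "scaffold", "position"]


def default_snp_map(m: int, scaffold: str = "scaffold_1") -> pd.DataFrame:
    """A minimal SNP map: one scaffold, 1 kb spacing."""
    return pd.DataFrame(
        {
            "snp_id": [f"snp_{j}" for j in range(m)],
            "scaffold": scaffold,
            "position": np.arange(1, m + 1) * 1000,
        }
    )


@dataclass
class DosageMatrix:
    """Individuals x SNPs alternate-allele dosages with map metadata.

    Parameters
    ----------
    values
        ``(n, m)`` integer array with entries in {0, 1, 2} or ``-1`` (missing).
    ids
        Length-``n`` individual identifiers.
    snp_map
        Length-``m`` frame with at least ``snp_id``, ``scaffold``, ``position``.
    """

    values: np.ndarray
    ids: list[str]
    snp_map: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("dosage values must be 2-D (individuals x SNPs)")
        if self.values.size:
            bad = ~np.isin(self.values, (MISSING, 0, 1, 2))
            if bad.any():
                raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids length does not match row count")
        if self.snp_map is None:
            self.snp_map = default_snp_map(self.values.shape[1])
        if len(self.snp_map) != self.values.shape[1]:
            raise ValueError("snp_map length does not match column count")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls (NaN if none)."""
        vals = self.values.astype(float)
        vals[self.values == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(vals, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def imputed(self) -> np.ndarray:
        """Float copy with missing dosages replaced by the per-SNP mean."""
        vals = self.values.astype(float)
        miss = self.values == MISSING
        if miss.any():
            vals[miss] = np.nan
            col_mean = np.nanmean(np.where(miss, np.nan, vals), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(miss)
            vals[idx] = col_mean[idx[1]]
        return vals

    def subset(self, rows=None, cols=None) -> "DosageMatrix":
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        return DosageMatrix(
            self.values[np.ix_(rows, cols)],
            [self.ids[i] for i in rows],
            self.snp_map.iloc[cols].reset_index(drop=True),
        )

    def copy(self) -> "DosageMatrix":
        return replace(
            self,
            values=self.values.copy(),
            ids=list(self.ids),
            snp_map=self.snp_map.copy(),
        )


def write_012(dm: DosageMatrix, prefix: str) -> None:
    """Write the vcftools 012 triplet (``.012``, ``.012.indv``, ``.012.pos``).

    Dialect: tab-separated, first column of ``.012`` is the 0-based row index,
    missing dosage encoded as ``-1``; ``.012.pos`` holds scaffold and position.
    """
    vals = dm.values
    with open(prefix + ".012", "w") as fh:
        for i in range(vals.shape[0]):
            fh.write("\t".join([str(i)] + [str(int(v)) for v in vals[i]]) + "\n")
    with open(prefix + ".012.indv", "w") as fh:
        for ind in dm.ids:
            fh.write(ind + "\n")
    with open(prefix + ".012.pos", "w") as fh:
        for _, row in dm.snp_map.iterrows():
            fh.write(f"{row['scaffold']}\t{int(row['position'])}\n")


def read_012(prefix: str) -> DosageMatrix:
    """Read a vcftools-style 012 triplet written by :func:`write_012`."""
    rows = []
    with open(prefix + ".012") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([int(v) for v in parts[1:]])
    values = np.array(rows, dtype=np.int8) if rows else np.empty((0, 0), dtype=np.int8)
    with open(prefix + ".012.indv") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    scaff, pos = [], []
    with open(prefix + ".012.pos") as fh:
        for line in fh:
            s, p = line.rstrip("\n").split("\t")
            scaff.append(s)
            pos.append(int(p))
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"{s}:{p}" for s, p in zip(scaff, pos)],
            "scaffold": scaff,
            "position": pos,
        }
    )
    if values.size == 0 and len(snp_map):
        values = np.empty((len(ids), len(snp_map)), dtype=np.int8)
    return DosageMatrix(values, ids, snp_map)


def make_pedigree(
    ids: list[str],
    sires: list[str | None],
    dams: list[str | None],
    **extra,
) -> pd.DataFrame:
    """Assemble a pedigree frame; founders have ``None`` parents."""
    ped = pd.DataFrame({"id": ids, "sire": sires, "dam": dams})
    for key, vals in extra.items():
        ped[key] = vals
    return ped
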