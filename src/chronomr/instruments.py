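"""Instrument selection: significance filtering, LD clumping, MHC exclusion
and amalgamation of time points into age epochs.

Instruments are built per time point, then merged into epochs: a SNP reaching
genome-wide significance at more than one time point within an epoch carries
the statistics of its most strongly associated time point (smallest p-value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats import SumstatsTable

__all__ = [
    "EpochDefinition",
    "LdMatrix",
    "DEFAULT_EPOCHS",
    "GWAS_THRESHOLD",
    "MHC_REGION",
    "filter_genomewide",
    "exclude_mhc",
    "clump",
    "amalgamate_epochs",
]

logger = logging.getLogger(__name__)

#: Genome-wide significance threshold used for instrument selection.
GWAS_THRESHOLD = 5e-8

#: Extended MHC region, hg19 coordinates (1-based, inclusive).
MHC_REGION = ("6", 25_000_000, 35_000_000)


@dataclass(frozen=True)
class EpochDefinition:
    """A named, ordered set of time points forming one exposure window."""

    label: str
    timepoints: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise ValueError(f"epoch {self.label!r} has no timepoints")


#: The four developmental epochs of the childhood-BMI analysis: birth,
#: infant, toddler and child, spanning the 12 measurement time points.
DEFAULT_EPOCHS = (
    EpochDefinition("birth", ("birth", "6w")),
    EpochDefinition("infancy", ("3m", "6m", "8m", "1y", "1.5y")),
    EpochDefinition("early_childhood", ("2y", "3y", "5y")),
    EpochDefinition("later_childhood", ("7y", "8y")),
)


@dataclass
class LdMatrix:
    """Pairwise LD (r²) between candidate instrument SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError(f"LD matrix shape {self.r2.shape} != ({n}, {n})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r² values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LdMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("LD matrix row and column rsID headers differ")
        return cls(snp_ids=list(df.index), r2=df.to_numpy(dtype=float))

    def write(self, path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep=sep)


def filter_genomewide(table: SumstatsTable, threshold: float = GWAS_THRESHOLD) -> SumstatsTable:
    """Retain records with ``pval`` strictly below ``threshold`` (order kept)."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return table.subset(table.df["pval"].to_numpy() < threshold)


def exclude_mhc(
    table: SumstatsTable,
    region: tuple[str, int, int] = MHC_REGION,
) -> SumstatsTable:
    """Drop records inside the MHC (``region`` = chrom, start, end, inclusive).

    Every record must carry chromosome and position; the published instrument
    list was already MHC-filtered upstream and skips this stage.
    """
    chrom, start, end = region
    df = table.df
    missing = df["chrom"].isna() | df["pos"].isna()
    if missing.any():
        bad = df.loc[missing, "snp_id"].tolist()
        raise ValueError(f"records lack chrom/pos, cannot apply MHC filter: {bad[:5]}")
    chrom_norm = df["chrom"].astype(str).str.removeprefix("chr")
    inside = (
        (chrom_norm == str(chrom).removeprefix("chr"))
        & (df["pos"].astype(int) >= start)
        & (df["pos"].astype(int) <= end)
    )
    for snp in df.loc[inside, "snp_id"]:
        logger.info("MHC exclusion: removed %s", snp)
    return table.subset(~inside.to_numpy())


def clump(
    table: SumstatsTable,
    ld: LdMatrix | None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    *,
    allow_missing: bool = False,
) -> SumstatsTable:
    """Greedy LD clumping: keep the most significant SNP per LD region.

    Repeatedly takes the remaining record with the smallest p-value as the
    index SNP and removes remaining records both in LD with it
    (r² > ``r2_threshold``) and within ``window_kb`` of it. Records on
    different chromosomes (or with unknown positions) are never
    distance-linked; SNPs absent from ``ld`` are an error unless
    ``allow_missing``, in which case they are treated as unlinked.

    Ties at identical p are broken by smaller SE, then snp_id.
    """
    df = table.df
    if ld is None:
        present = [False] * len(df)
    else:
        present = [s in ld for s in df["snp_id"]]
        absent = [s for s, ok in zip(df["snp_id"], present) if not ok]
        if absent and not allow_missing:
            raise KeyError(
                f"SNPs absent from LD matrix: {absent[:5]} "
                "(pass allow_missing=True to treat them as unlinked)"
            )

    order = sorted(
        range(len(df)),
        key=lambda i: (df["pval"].iloc[i], df["se"].iloc[i], df["snp_id"].iloc[i]),
    )
    removed = np.zeros(len(df), dtype=bool)
    kept: list[int] = []
    for i in order:
        if removed[i]:
            continue
        kept.append(i)
        for j in order:
            if j == i or removed[j]:
                continue
            if not _within_window(df, i, j, window_kb):
                continue
            if present[i] and present[j]:
                r2 = ld.lookup(df["snp_id"].iloc[i], df["snp_id"].iloc[j])  # type: ignore[union-attr]
            else:
                r2 = 0.0
            if r2 > r2_threshold:
                removed[j] = True
                logger.info(
                    "clump: removed %s (r²=%.4g with index %s)",
                    df["snp_id"].iloc[j], r2, df["snp_id"].iloc[i],
                )
    keep_mask = np.zeros(len(df), dtype=bool)
    keep_mask[kept] = True
    return table.subset(keep_mask)


def _within_window(df: pd.DataFrame, i: int, j: int, window_kb: float) -> bool:
    ci, cj = df["chrom"].iloc[i], df["chrom"].iloc[j]
    pi, pj = df["pos"].iloc[i], df["pos"].iloc[j]
    if pd.isna(ci) or pd.isna(cj) or pd.isna(pi) or pd.isna(pj):
        # no positional information: LD alone decides
        return True
    if str(ci) != str(cj):
        return False
    return abs(int(pi) - int(pj)) <= window_kb * 1000


def amalgamate_epochs(
    tables: Mapping[str, SumstatsTable],
    epochs: Sequence[EpochDefinition] = DEFAULT_EPOCHS,
) -> dict[str, SumstatsTable]:
    """Merge per-time-point instrument tables into per-epoch tables.

    Within an epoch, a SNP significant at several time points carries the
    statistics of its smallest-p time point (ties: smaller SE, then earlier
    time point in epoch order). SNPs significant at no time point of an epoch
    are absent from it.
    """
    assignment: dict[str, str] = {}
    for ep in epochs:
        for tp in ep.timepoints:
            if tp in assignment:
                raise ValueError(f"time point {tp!r} assigned to both {assignment[tp]!r} and {ep.label!r}")
            assignment[tp] = ep.label
    traits = {t.trait for t in tables.values()}
    if len(traits) > 1:
        raise ValueError(f"tables mix traits: {sorted(traits)}")
    unknown = sorted(set(tables) - set(assignment))
    if unknown:
        raise ValueError(f"time points not covered by any epoch: {unknown}")

    out: dict[str, SumstatsTable] = {}
    for ep in epochs:
        frames = []
        for rank, tp in enumerate(ep.timepoints):
            if tp not in tables:
                continue
            df = tables[tp].df.copy()
            df["timepoint"] = tp
            df["_rank"] = rank
            frames.append(df)
        if not frames:
            continue
        merged = pd.concat(frames, ignore_index=True)
        merged = merged.sort_values(
            ["snp_id", "pval", "se", "_rank"], kind="mergesort"
        ).drop_duplicates("snp_id", keep="first")
        # restore a stable, p-ascending presentation order
        merged = merged.sort_values(["pval", "snp_id"], kind="mergesort").drop(columns="_rank")
        out[ep.label] = SumstatsTable(
            df=merged.reset_index(drop=True), trait=next(iter(traits))
        )
    return out
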