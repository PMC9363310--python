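"""GWAS summary-statistic tables: reading, validation, writing, and the
packaged per-SNP instrument data.

A summary-statistic table holds one row per SNP × trait × time point, with
per-allele effect sizes (``beta``), standard errors, p-values and effect-allele
frequencies. Exposure effects are in standardised-BMI units; binary-outcome
effects are log odds ratios per effect-allele copy.

The packaged fixture (``load_fixture``) carries the published per-SNP
associations of childhood BMI (MoBa cohort, four age epochs) and multiple
sclerosis (IMSGC discovery GWAS) used throughout the test-suite and the
worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GwasRecord",
    "SumstatsTable",
    "ValidationReport",
    "read_sumstats",
    "write_sumstats",
    "load_fixture",
    "FIXTURE_EPOCHS",
    "CANONICAL_COLUMNS",
]

VALID_BASES = frozenset("ACGT")

#: Canonical column order for tables on disk.
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "trait",
    "timepoint",
]

#: Epoch labels of the packaged fixture, in developmental order.
FIXTURE_EPOCHS = ("birth", "infancy", "early_childhood", "later_childhood")


@dataclass
class GwasRecord:
    """One SNP's association with one trait at one time point."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    trait: str = ""
    timepoint: str = ""

    def validation_errors(self) -> list[str]:
        """Hard invariant violations (reasons to reject the record)."""
        problems: list[str] = []
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_BASES or oa not in VALID_BASES:
            problems.append(f"invalid allele pair {ea}/{oa}")
        elif ea == oa:
            problems.append(f"identical alleles {ea}/{oa}")
        if not (math.isfinite(self.se) and self.se > 0):
            problems.append(f"se must be > 0, got {self.se}")
        if not math.isfinite(self.beta):
            problems.append(f"beta not finite: {self.beta}")
        if not (0 < self.pval <= 1):
            problems.append(f"pval outside (0, 1]: {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            problems.append(f"eaf outside [0, 1]: {self.eaf}")
        return problems

    def validation_warnings(self) -> list[str]:
        """Soft checks: p-value consistent with |beta/se| within a factor 2."""
        warns: list[str] = []
        if self.se > 0 and 0 < self.pval <= 1:
            z = abs(self.beta / self.se)
            p_norm = 2.0 * stats.norm.sf(z)
            # only meaningful where the normal p is representable
            if p_norm > 1e-290 and not (0.5 <= p_norm / self.pval <= 2.0):
                warns.append(
                    f"pval {self.pval:g} inconsistent with |beta/se| "
                    f"(normal two-sided p {p_norm:g})"
                )
        return warns


@dataclass
class ValidationReport:
    """Per-row outcomes of reading a summary-statistic file."""

    rejected: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[tuple[int, str, str]] = field(default_factory=list)

    def add_rejection(self, row: int, snp: str, reason: str) -> None:
        self.rejected.append((row, snp, reason))

    def add_warning(self, row: int, snp: str, reason: str) -> None:
        self.warnings.append((row, snp, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class SumstatsTable:
    """An ordered collection of :class:`GwasRecord` for one trait.

    Backed by a :class:`pandas.DataFrame` in canonical column order so that
    estimator code can work on vectorised columns.
    """

    df: pd.DataFrame
    trait: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing canonical columns: {missing}")
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)
        key = list(zip(self.df["snp_id"], self.df["timepoint"]))
        if len(set(key)) != len(key):
            dupes = sorted({k for k in key if key.count(k) > 1})
            raise ValueError(f"duplicate snp_id × timepoint pairs: {dupes[:5]}")

    @classmethod
    def from_records(cls, records: Iterable[GwasRecord], trait: str = "") -> "SumstatsTable":
        rows = [{c: getattr(r, c) for c in CANONICAL_COLUMNS} for r in records]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        if not trait and len(df):
            trait = str(df["trait"].iloc[0])
        return cls(df=df, trait=trait)

    def records(self) -> Iterator[GwasRecord]:
        for row in self.df.itertuples(index=False):
            yield GwasRecord(
                snp_id=row.snp_id,
                chrom=None if pd.isna(row.chrom) else str(row.chrom),
                pos=None if pd.isna(row.pos) else int(row.pos),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=None if pd.isna(row.n) else float(row.n),
                trait="" if pd.isna(row.trait) else str(row.trait),
                timepoint="" if pd.isna(row.timepoint) else str(row.timepoint),
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def timepoints(self) -> set[str]:
        return set(self.df["timepoint"].astype(str).unique())

    def subset(self, mask: np.ndarray | pd.Series) -> "SumstatsTable":
        return SumstatsTable(df=self.df[np.asarray(mask)].reset_index(drop=True), trait=self.trait)

    def keyed_by_snp(self) -> dict[str, GwasRecord]:
        """Map snp_id -> record; requires unique snp_ids."""
        out: dict[str, GwasRecord] = {}
        for rec in self.records():
            if rec.snp_id in out:
                raise ValueError(f"duplicate snp_id {rec.snp_id}; one timepoint at a time")
            out[rec.snp_id] = rec
        return out


_DEFAULT_COLUMN_MAP = {c: c for c in CANONICAL_COLUMNS}

_NUMERIC_FIELDS = ("pos", "eaf", "beta", "se", "pval", "n")
_REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait: str = "",
    timepoint: str = "",
    sep: str = "\t",
) -> tuple[SumstatsTable, ValidationReport]:
    """Read a delimited summary-statistic file.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from file column name to canonical field name (a subset of
        :data:`CANONICAL_COLUMNS`); omit for files already in canonical form.
    trait, timepoint
        Defaults applied to rows whose file carries no such column.

    Returns
    -------
    (table, report)
        Valid rows as a :class:`SumstatsTable` plus a per-row
        :class:`ValidationReport` of rejected rows and soft warnings.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if column_map is None:
        column_map = {c: c for c in CANONICAL_COLUMNS if c in raw.columns}
    missing = [src for src in column_map if src not in raw.columns]
    if missing:
        raise KeyError(f"mapped columns absent from {path}: {missing}")
    mapped = {dst: raw[src] for src, dst in column_map.items()}
    unknown = [dst for dst in mapped if dst not in CANONICAL_COLUMNS]
    if unknown:
        raise KeyError(f"column_map targets unknown fields: {unknown}")
    for req in _REQUIRED_FIELDS:
        if req not in mapped:
            raise KeyError(f"required field '{req}' not covered by column_map")

    report = ValidationReport()
    records: list[GwasRecord] = []
    for i in range(len(raw)):
        snp = str(mapped["snp_id"].iloc[i])
        values: dict[str, object] = {"snp_id": snp}
        row_errors: list[str] = []
        for fld in ("effect_allele", "other_allele"):
            values[fld] = str(mapped[fld].iloc[i]).strip().upper()
        for fld in _NUMERIC_FIELDS:
            if fld not in mapped or pd.isna(mapped[fld].iloc[i]):
                values[fld] = None
                continue
            text = str(mapped[fld].iloc[i]).strip()
            try:
                values[fld] = int(text) if fld == "pos" else float(text)
            except ValueError:
                row_errors.append(f"unparseable {fld}: {text!r}")
        for fld, default in (("chrom", None), ("trait", trait), ("timepoint", timepoint)):
            if fld in mapped and not pd.isna(mapped[fld].iloc[i]):
                values[fld] = str(mapped[fld].iloc[i]).strip()
            else:
                values[fld] = default
        if row_errors:
            report.add_rejection(i, snp, "; ".join(row_errors))
            continue
        for fld in ("beta", "se", "pval"):
            if values[fld] is None:
                row_errors.append(f"missing required {fld}")
        if row_errors:
            report.add_rejection(i, snp, "; ".join(row_errors))
            continue
        rec = GwasRecord(**values)  # type: ignore[arg-type]
        problems = rec.validation_errors()
        if problems:
            report.add_rejection(i, snp, "; ".join(problems))
            continue
        for w in rec.validation_warnings():
            report.add_warning(i, snp, w)
        records.append(rec)

    table = SumstatsTable.from_records(records, trait=trait)
    return table, report


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write a table in canonical tab-delimited form (read/write round-trips)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty summary-statistic table")
    df = table.df.copy()
    # repr-based float formatting so that read-back is bit-identical
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df["pos"] = df["pos"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def _fixture_frame() -> pd.DataFrame:
    ref = resources.files("chronomr.data").joinpath("moba_ms_instruments.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_fixture(epoch: str = "all") -> tuple[SumstatsTable, SumstatsTable]:
    """Packaged per-SNP childhood-BMI / MS associations, by age epoch.

    Parameters
    ----------
    epoch
        One of ``birth`` (birth–6 weeks, 8 SNPs), ``infancy``
        (3 months–1.5 years, 18 SNPs), ``early_childhood`` (2–5 years,
        4 SNPs), ``later_childhood`` (7–8 years, 5 SNPs) or ``all`` (35 rows).

    Returns
    -------
    (exposure, outcome)
        Exposure rows are standardised-BMI effects per epoch; outcome rows are
        MS log-odds for the same SNPs. The published list is already
        genome-wide significant, LD-clumped and MHC-filtered; no chromosome /
        position information is carried.
    """
    if epoch != "all" and epoch not in FIXTURE_EPOCHS:
        raise ValueError(f"unknown epoch {epoch!r}; expected one of {FIXTURE_EPOCHS + ('all',)}")
    df = _fixture_frame()
    if epoch != "all":
        df = df[df["epoch"] == epoch].reset_index(drop=True)

    def _side(beta, se, pval, trait) -> SumstatsTable:
        out = pd.DataFrame(
            {
                "snp_id": df["snp_id"],
                "chrom": None,
                "pos": None,
                "effect_allele": df["effect_allele"],
                "other_allele": df["other_allele"],
                "eaf": df["eaf"],
                "beta": df[beta],
                "se": df[se],
                "pval": df[pval],
                "n": None,
                "trait": trait,
                "timepoint": df["epoch"],
            }
        )
        return SumstatsTable(df=out, trait=trait)

    exposure = _side("beta_exp", "se_exp", "pval_exp", "childhood BMI")
    outcome = _side("beta_out", "se_out", "pval_out", "multiple sclerosis")
    return exposure, outcome
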