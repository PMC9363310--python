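"""Allele harmonisation of exposure and outcome summary statistics.

Two-sample MR requires the exposure and outcome effect of each SNP to be
expressed per copy of the same allele. Where the outcome file reports the
other allele as its effect allele, the outcome beta sign is flipped (and the
frequency complemented). Palindromic SNPs (A/T or C/G) cannot be strand
resolved from alleles alone; the default policy discards them outright, which
reproduces the published instrument counts (7 of 8 at birth, 4 of 5 in later
childhood). A frequency-based policy (drop only when the minor-allele
frequency exceeds a threshold, default 0.42) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import GwasRecord, SumstatsTable, VALID_BASES

__all__ = [
    "HarmonisedSnp",
    "InstrumentSet",
    "is_palindromic",
    "harmonise_pair",
    "harmonise_set",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = {frozenset("AT"), frozenset("CG")}


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is A/T or C/G (either order)."""
    for a in (effect_allele, other_allele):
        if a not in VALID_BASES:
            raise ValueError(f"invalid base {a!r}")
    if effect_allele == other_allele:
        raise ValueError(f"alleles must differ, got {effect_allele}/{other_allele}")
    return frozenset((effect_allele, other_allele)) in _PALINDROMES


@dataclass
class HarmonisedSnp:
    """An exposure/outcome-aligned instrument SNP with exclusion bookkeeping."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    palindromic: bool = False
    flipped: bool = False
    excluded: bool = False
    exclusion_reason: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.exclusion_reason:
            raise ValueError(f"{self.snp_id}: excluded without a reason")


@dataclass
class InstrumentSet:
    """The harmonised instruments for one epoch or time point.

    ``snps`` holds the analysis-ready (non-excluded) SNPs; ``excluded_snps``
    the audit trail. Estimators read the vectorised array properties.
    """

    label: str
    snps: list[HarmonisedSnp] = field(default_factory=list)
    excluded_snps: list[HarmonisedSnp] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate snp_ids in instrument set {self.label!r}")
        if any(s.excluded for s in self.snps):
            raise ValueError("excluded SNPs belong in excluded_snps")

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def _arr(self, attr: str) -> np.ndarray:
        return np.array([getattr(s, attr) for s in self.snps], dtype=float)

    @property
    def beta_exp(self) -> np.ndarray:
        return self._arr("beta_exp")

    @property
    def se_exp(self) -> np.ndarray:
        return self._arr("se_exp")

    @property
    def beta_out(self) -> np.ndarray:
        return self._arr("beta_out")

    @property
    def se_out(self) -> np.ndarray:
        return self._arr("se_out")

    def subset(self, snp_ids: Iterable[str], label: str | None = None) -> "InstrumentSet":
        wanted = set(snp_ids)
        return InstrumentSet(
            label=self.label if label is None else label,
            snps=[s for s in self.snps if s.snp_id in wanted],
            excluded_snps=list(self.excluded_snps),
        )

    def drop(self, snp_ids: Iterable[str], reason: str) -> "InstrumentSet":
        gone = set(snp_ids)
        kept, removed = [], list(self.excluded_snps)
        for s in self.snps:
            if s.snp_id in gone:
                removed.append(
                    HarmonisedSnp(**{**s.__dict__, "excluded": True, "exclusion_reason": reason})
                )
            else:
                kept.append(s)
        return InstrumentSet(label=self.label, snps=kept, excluded_snps=removed)

    def to_frame(self, include_excluded: bool = False) -> pd.DataFrame:
        rows = self.snps + (self.excluded_snps if include_excluded else [])
        return pd.DataFrame([s.__dict__ for s in rows])

    @classmethod
    def from_arrays(
        cls,
        beta_exp: Sequence[float],
        se_exp: Sequence[float],
        beta_out: Sequence[float],
        se_out: Sequence[float],
        snp_ids: Sequence[str] | None = None,
        label: str = "instruments",
    ) -> "InstrumentSet":
        n = len(beta_exp)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1:04d}" for i in range(n)]
        snps = [
            HarmonisedSnp(
                snp_id=snp_ids[i],
                beta_exp=float(beta_exp[i]),
                se_exp=float(se_exp[i]),
                beta_out=float(beta_out[i]),
                se_out=float(se_out[i]),
            )
            for i in range(n)
        ]
        return cls(label=label, snps=snps)


def _excluded(exp: GwasRecord, reason: str, *, palindromic: bool = False) -> HarmonisedSnp:
    return HarmonisedSnp(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=float("nan"),
        se_out=float("nan"),
        eaf_exp=exp.eaf,
        palindromic=palindromic,
        excluded=True,
        exclusion_reason=reason,
        timepoint=exp.timepoint,
    )


def harmonise_pair(
    exp: GwasRecord,
    out: GwasRecord,
    policy: str = "strict",
    maf_threshold: float = 0.42,
) -> HarmonisedSnp:
    """Align one outcome record to the exposure effect allele.

    ``policy`` is ``"strict"`` (discard every palindromic SNP) or
    ``"maf_threshold"`` (discard a palindromic SNP only when its inferred
    minor-allele frequency exceeds ``maf_threshold`` or no frequency is
    available; otherwise same-strand alignment is assumed).
    """
    if exp.snp_id != out.snp_id:
        raise ValueError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    if policy not in ("strict", "maf_threshold"):
        raise ValueError(f"unknown palindromic policy {policy!r}")

    palindromic = is_palindromic(exp.effect_allele, exp.other_allele)
    if palindromic:
        if policy == "strict":
            return _excluded(exp, "palindromic", palindromic=True)
        eaf = exp.eaf if exp.eaf is not None else out.eaf
        if eaf is None:
            return _excluded(exp, "palindromic_no_frequency", palindromic=True)
        maf = min(eaf, 1.0 - eaf)
        if maf > maf_threshold:
            return _excluded(exp, f"palindromic_maf>{maf_threshold}", palindromic=True)

    exp_pair = (exp.effect_allele, exp.other_allele)
    out_pair = (out.effect_allele, out.other_allele)
    comp_pair = (_COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele])
    if out_pair == exp_pair or (not palindromic and comp_pair == exp_pair):
        flipped = False
    elif out_pair == exp_pair[::-1] or (not palindromic and comp_pair == exp_pair[::-1]):
        flipped = True
    else:
        return _excluded(exp, "allele_mismatch", palindromic=palindromic)

    beta_out = -out.beta if flipped else out.beta
    eaf_out = out.eaf
    if flipped and eaf_out is not None:
        eaf_out = 1.0 - eaf_out
    return HarmonisedSnp(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=out.se,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        palindromic=palindromic,
        flipped=flipped,
        timepoint=exp.timepoint,
    )


def harmonise_set(
    exp: SumstatsTable,
    out: SumstatsTable,
    policy: str = "strict",
    maf_threshold: float = 0.42,
    label: str | None = None,
) -> InstrumentSet:
    """Harmonise every exposure SNP against the outcome table.

    Exposure SNPs absent from the outcome are excluded with reason
    ``not_in_outcome``; an empty exposure/outcome intersection is an error.
    """
    out_by_snp = out.keyed_by_snp()
    snps: list[HarmonisedSnp] = []
    excluded: list[HarmonisedSnp] = []
    for rec in exp.records():
        if rec.snp_id not in out_by_snp:
            excluded.append(_excluded(rec, "not_in_outcome"))
            continue
        h = harmonise_pair(rec, out_by_snp[rec.snp_id], policy=policy, maf_threshold=maf_threshold)
        (excluded if h.excluded else snps).append(h)
    if not snps and not any(e.exclusion_reason != "not_in_outcome" for e in excluded):
        raise ValueError("no exposure SNP is present in the outcome table")
    if label is None:
        tps = exp.timepoints
        label = next(iter(tps)) if len(tps) == 1 else exp.trait or "instruments"
    return InstrumentSet(label=label, snps=snps, excluded_snps=excluded)


def write_exclusion_log(instr: InstrumentSet, path) -> None:
    """Audit file of per-SNP harmonisation outcomes (snp_id, action, reason)."""
    rows = [
        {"snp_id": s.snp_id, "action": "retained", "reason": "", "flipped": s.flipped}
        for s in instr.snps
    ] + [
        {"snp_id": s.snp_id, "action": "excluded", "reason": s.exclusion_reason, "flipped": s.flipped}
        for s in instr.excluded_snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
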