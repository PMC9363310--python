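"""Multivariable MR: direct effect of the primary exposure conditional on a
secondary exposure (here, adult BMI).

Two summary-level approaches are provided:

* **Residual method** — regress SNP-outcome effects on SNP-secondary effects
  (weighted, no intercept), then regress the residuals on SNP-primary
  effects through the origin. The step-2 slope is the direct effect of the
  primary exposure not explained by the secondary one.
* **Joint method** — a single weighted multiple regression of SNP-outcome
  effects on both exposures' SNP effects without an intercept.

Both weight by 1/se_out². A sensitivity alternative restricts the
instrument to SNPs with no nominal secondary-exposure association and
re-runs univariable MR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonise import InstrumentSet
from .sumstats import SumstatsTable

__all__ = [
    "MvmrInstrument",
    "MvmrResult",
    "mvmr_residual",
    "mvmr_joint",
    "restrict_by_secondary",
    "combine_with_secondary",
]


@dataclass
class MvmrInstrument:
    """One SNP's effects on primary exposure, secondary exposure and outcome."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_sec: float
    se_sec: float
    beta_out: float
    se_out: float

    def __post_init__(self) -> None:
        for name in ("se_exp", "se_sec", "se_out"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{self.snp_id}: {name} must be > 0")


@dataclass
class MvmrResult:
    method: str  # "residual" | "joint"
    beta: float
    se: float
    pval: float
    n_snp: int
    warning: str = ""


def _unpack(instrs: Sequence[MvmrInstrument]):
    bx = np.array([i.beta_exp for i in instrs])
    bs = np.array([i.beta_sec for i in instrs])
    by = np.array([i.beta_out for i in instrs])
    sy = np.array([i.se_out for i in instrs])
    return bx, bs, by, sy


def _collinearity_warning(bx: np.ndarray, bs: np.ndarray, tol: float = 0.95) -> str:
    if np.std(bx) == 0 or np.std(bs) == 0:
        return ""
    r = float(np.corrcoef(bx, bs)[0, 1])
    if abs(r) > tol:
        return f"primary and secondary SNP effects are nearly collinear (r = {r:.3f})"
    return ""


def mvmr_residual(
    instrs: Sequence[MvmrInstrument], *, intercept_step1: bool = False
) -> MvmrResult:
    """Residual-based two-step multivariable MR.

    Step 1 regresses outcome betas on secondary-exposure betas (weighted by
    1/se_out², no intercept by default, matching summary-data conventions);
    step 2 regresses the step-1 residuals on primary-exposure betas through
    the origin with the same weights and multiplicative random-effects SE
    inflation. With all secondary effects zero this reduces exactly to
    univariable MRE-IVW.
    """
    n = len(instrs)
    if n < 3:
        raise ValueError("multivariable MR needs at least 3 SNPs")
    bx, bs, by, sy = _unpack(instrs)
    w = 1.0 / sy**2
    sw = np.sqrt(w)

    x1 = np.column_stack([np.ones_like(bs), bs]) if intercept_step1 else bs[:, None]
    coef1, *_ = np.linalg.lstsq(sw[:, None] * x1, sw * by, rcond=None)
    resid = by - x1 @ coef1

    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * resid)) / denom
    q = float(np.sum(w * (resid - beta * bx) ** 2))
    se = float(np.sqrt(1.0 / denom)) * max(1.0, float(np.sqrt(q / (n - 1))))
    p = float(2 * stats.norm.sf(abs(beta / se)))

    msg = _collinearity_warning(bx, bs)
    if msg:
        warnings.warn(msg, stacklevel=2)
    return MvmrResult(method="residual", beta=beta, se=se, pval=p, n_snp=n, warning=msg)


def mvmr_joint(instrs: Sequence[MvmrInstrument]) -> MvmrResult:
    """Joint weighted regression of outcome betas on both exposures' betas.

    No intercept; weights 1/se_out². The primary-exposure coefficient is
    reported with the weighted-least-squares SE (residual-dispersion scaled)
    and a t p-value on n − 2 df.
    """
    n = len(instrs)
    if n < 2:
        raise ValueError("multivariable MR needs at least 2 SNPs")
    bx, bs, by, sy = _unpack(instrs)
    w = 1.0 / sy**2
    if not np.any(bs):
        # no secondary signal at all: single-regressor weighted fit
        denom = float(np.sum(w * bx**2))
        beta = float(np.sum(w * bx * by)) / denom
        sigma2 = float(np.sum(w * (by - beta * bx) ** 2)) / (n - 1)
        se = float(np.sqrt(sigma2 / denom))
        p = float(2 * stats.t.sf(abs(beta / se), df=n - 1))
        return MvmrResult(method="joint", beta=beta, se=se, pval=p, n_snp=n)
    x = np.column_stack([bx, bs])
    xw = np.sqrt(w)[:, None] * x
    if np.linalg.matrix_rank(xw) < 2:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient: primary (beta_exp) and secondary "
            "(beta_sec) SNP effects are collinear"
        )
    xtwx = x.T @ (w[:, None] * x)
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    beta = float(coef[0])
    msg = _collinearity_warning(bx, bs)
    if n == 2:
        # exactly determined: coefficients solve the 2×2 system, no residual df
        return MvmrResult(
            method="joint", beta=beta, se=float("nan"), pval=float("nan"),
            n_snp=n, warning="saturated system: no residual degrees of freedom",
        )
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2)) / (n - 2)
    cov = np.linalg.inv(xtwx) * sigma2
    se = float(np.sqrt(cov[0, 0]))
    p = float(2 * stats.t.sf(abs(beta / se), df=n - 2))
    if msg:
        warnings.warn(msg, stacklevel=2)
    return MvmrResult(method="joint", beta=beta, se=se, pval=p, n_snp=n, warning=msg)


def restrict_by_secondary(
    instr: InstrumentSet, sec: SumstatsTable, p_threshold: float = 0.05
) -> InstrumentSet:
    """Keep only SNPs with secondary-exposure association p > ``p_threshold``.

    SNPs absent from the secondary table are excluded with reason
    ``not_in_secondary``; SNPs with secondary p ≤ threshold with reason
    ``secondary_associated``. An empty result is legitimate (strongly
    age-shared genetics may leave no exposure-specific instruments).
    """
    sec_by_snp = sec.keyed_by_snp()
    missing = [sid for sid in instr.snp_ids if sid not in sec_by_snp]
    associated = [
        sid
        for sid in instr.snp_ids
        if sid in sec_by_snp and not sec_by_snp[sid].pval > p_threshold
    ]
    out = instr.drop(missing, reason="not_in_secondary")
    out = out.drop(associated, reason="secondary_associated")
    return out


def combine_with_secondary(
    instr: InstrumentSet, sec: SumstatsTable
) -> list[MvmrInstrument]:
    """Join harmonised instruments with secondary-exposure betas by snp_id.

    The secondary table must already be expressed on the exposure effect
    allele (harmonise it against the exposure first). SNPs absent from the
    secondary table are dropped.
    """
    sec_by_snp = sec.keyed_by_snp()
    out = []
    for s in instr.snps:
        rec = sec_by_snp.get(s.snp_id)
        if rec is None:
            continue
        out.append(
            MvmrInstrument(
                snp_id=s.snp_id,
                beta_exp=s.beta_exp,
                se_exp=s.se_exp,
                beta_sec=rec.beta,
                se_sec=rec.se,
                beta_out=s.beta_out,
                se_out=s.se_out,
            )
        )
    return out
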