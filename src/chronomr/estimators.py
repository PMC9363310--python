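"""Univariable two-sample MR estimators and sensitivity statistics.

All estimators work from per-SNP summary statistics (exposure beta/SE,
outcome beta/SE) of a harmonised :class:`~chronomr.harmonise.InstrumentSet`:

* Wald ratio — single-SNP causal estimate ``beta_out / beta_exp``.
* IVW — weighted regression of outcome on exposure betas through the origin
  with weights 1/se_out²; the multiplicative-random-effects (MRE) variant
  inflates the SE by ``max(1, sqrt(Q / (n − 1)))`` and is the primary method.
* MR-Egger — the same regression with a free intercept; a non-zero intercept
  indicates directional pleiotropy. Following the usual convention the data
  are first oriented so every exposure beta is positive.
* Weighted median / mode — robust estimators over per-SNP Wald ratios,
  weighted by the inverse second-order delta-method ratio variance; standard
  errors by parametric bootstrap.
* Cochran's Q, per-SNP F statistics, Steiger directionality filtering,
  leave-one-out, and the Mann–Kendall trend test across ordered estimates.

Causal estimates are on the log-odds scale per 1 SD higher exposure; the
odds-ratio scale is carried alongside (``exp`` of estimate and CI).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonise import HarmonisedSnp, InstrumentSet

__all__ = [
    "MrEstimate",
    "HeterogeneityStats",
    "TrendResult",
    "FStatistics",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "cochran_q",
    "f_statistics",
    "steiger_filter",
    "effective_n",
    "leave_one_out",
    "mann_kendall",
    "wald_ratios",
]

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal 95% multiplier, used for every reported CI


@dataclass
class MrEstimate:
    """One method's causal estimate on log-odds and odds-ratio scales."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    or_: float = field(init=False)
    or_ci_low: float = field(init=False)
    or_ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.method}: se must be > 0, got {self.se}")
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se
        self.or_ = float(np.exp(self.beta))
        self.or_ci_low = float(np.exp(self.ci_low))
        self.or_ci_high = float(np.exp(self.ci_high))


@dataclass
class HeterogeneityStats:
    """Cochran's Q (and, for Egger fits, the pleiotropy intercept)."""

    q: float
    df: int
    pval: float
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


@dataclass
class TrendResult:
    """Mann–Kendall trend test over an ordered sequence of estimates."""

    n: int
    s: int
    tau: float
    pval: float


@dataclass
class FStatistics:
    """Per-SNP instrument-strength F statistics, (beta/se)² on the exposure."""

    snp_ids: list[str]
    f: np.ndarray
    mean: float


def _arrays(instr: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    return instr.beta_exp, instr.se_exp, instr.beta_out, instr.se_out


def wald_ratios(instr: InstrumentSet, variance: str = "second_order") -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their delta-method standard errors.

    ``variance="first_order"`` gives ``se_out/|beta_exp|``; ``"second_order"``
    adds the exposure-uncertainty term
    ``beta_out²·se_exp²/beta_exp⁴`` and is the weighting convention of the
    weighted-median and mode estimators.
    """
    bx, sx, by, sy = _arrays(instr)
    if np.any(bx == 0):
        raise ZeroDivisionError("zero exposure beta: Wald ratio undefined")
    r = by / bx
    if variance == "first_order":
        se = sy / np.abs(bx)
    elif variance == "second_order":
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise ValueError(f"unknown variance convention {variance!r}")
    return r, se


def wald_ratio(snp: HarmonisedSnp) -> MrEstimate:
    """Single-SNP causal estimate, first-order delta-method SE."""
    if snp.beta_exp == 0:
        raise ZeroDivisionError(f"{snp.snp_id}: exposure beta is zero")
    beta = snp.beta_out / snp.beta_exp
    se = snp.se_out / abs(snp.beta_exp)
    p = 2 * stats.norm.sf(abs(beta / se))
    return MrEstimate(method="wald", n_snp=1, beta=beta, se=se, pval=float(p))


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Through-origin weighted slope, its fixed-effect SE, and Cochran's Q."""
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se_fixed = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(instr: InstrumentSet, model: str = "mre") -> MrEstimate:
    """Inverse-variance-weighted estimate.

    ``model="fixed"`` uses the fixed-effect SE ``sqrt(1/Σ beta_exp²/se_out²)``;
    ``model="mre"`` (multiplicative random effects, the primary method)
    multiplies it by ``max(1, sqrt(Q/(n − 1)))`` so that over-dispersion
    widens but never narrows the interval. P-values are standard normal.
    """
    if model not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    n = instr.n_snp
    if n < 2:
        raise ValueError("IVW needs at least 2 SNPs; use wald_ratio for a single instrument")
    bx, _, by, sy = _arrays(instr)
    beta, se_fixed, q = _ivw_core(bx, by, sy)
    se = se_fixed
    if model == "mre":
        se = se_fixed * max(1.0, float(np.sqrt(q / (n - 1))))
    p = 2 * stats.norm.sf(abs(beta / se))
    return MrEstimate(method=f"ivw_{model}", n_snp=n, beta=beta, se=se, pval=float(p))


def egger(instr: InstrumentSet) -> tuple[MrEstimate, HeterogeneityStats]:
    """MR-Egger regression: slope (causal) and intercept (pleiotropy) terms.

    Weighted least squares of outcome on exposure betas with a free
    intercept, weights 1/se_out², after orienting all exposure betas
    positive. Both SEs carry the ``max(1, sqrt(Q_egger/(n − 2)))`` inflation;
    p-values use Student's t with n − 2 degrees of freedom.
    """
    n = instr.n_snp
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs for a meaningful fit")
    bx, _, by, sy = _arrays(instr)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    x_mat = np.column_stack([np.ones_like(bx), bx])
    xtwx = x_mat.T @ (w[:, None] * x_mat)
    coef = np.linalg.solve(xtwx, x_mat.T @ (w * by))
    resid = by - x_mat @ coef
    q = float(np.sum(w * resid**2))
    inflation = max(1.0, q / (n - 2))
    cov = np.linalg.inv(xtwx) * inflation
    se = np.sqrt(np.diag(cov))
    pvals = 2 * stats.t.sf(np.abs(coef / se), df=n - 2)
    slope = MrEstimate(
        method="egger", n_snp=n, beta=float(coef[1]), se=float(se[1]), pval=float(pvals[1])
    )
    het = HeterogeneityStats(
        q=q,
        df=n - 2,
        pval=float(stats.chi2.sf(q, n - 2)),
        egger_intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=float(pvals[0]),
    )
    return slope, het


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    below = int(np.max(np.nonzero(cum < 0.5)[0]))
    span = cum[below + 1] - cum[below]
    return float(v[below] + (v[below + 1] - v[below]) * (0.5 - cum[below]) / span)


def _parametric_boot(
    instr: InstrumentSet,
    n_boot: int,
    seed: int | None,
    statistic,
) -> np.ndarray:
    """Resample (beta_exp, beta_out) from normals and recompute a statistic."""
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(instr)
    out = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        out[b] = statistic(bxs, bys, sx, sy)
    return out


def weighted_median(instr: InstrumentSet, n_boot: int = 1000, seed: int | None = None) -> MrEstimate:
    """Weighted median of per-SNP Wald ratios.

    Consistent when SNPs contributing ≥ 50% of the weight are valid
    instruments. Weights are inverse second-order ratio variances; the SE is
    the SD of the estimate over ``n_boot`` parametric bootstrap replicates.
    """
    n = instr.n_snp
    if n < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is too small for a stable bootstrap SE", stacklevel=2)
    r, se_r = wald_ratios(instr, variance="second_order")
    point = _weighted_median(r, 1.0 / se_r**2)

    def stat(bxs, bys, sx, sy):
        rs = bys / bxs
        vs = sy**2 / bxs**2 + bys**2 * sx**2 / bxs**4
        return _weighted_median(rs, 1.0 / vs)

    boot = _parametric_boot(instr, n_boot, seed, stat)
    se = float(np.std(boot, ddof=1))
    p = 2 * stats.norm.sf(abs(point / se))
    return MrEstimate(method="weighted_median", n_snp=n, beta=point, se=se, pval=float(p))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Mode of the kernel-smoothed ratio density (modified Silverman bandwidth)."""
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    s = 0.9 * min(sd, mad if mad > 0 else sd) / n ** (1 / 5)
    h = max(1e-8, s * phi)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    w = weights / weights.sum()
    dens = (w[:, None] * stats.norm.pdf((grid[None, :] - ratios[:, None]) / h)).sum(axis=0) / h
    return float(grid[np.argmax(dens)])


def mode_estimate(
    instr: InstrumentSet,
    variant: str = "simple",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MrEstimate:
    """Mode-based estimate: the most common per-SNP Wald ratio.

    ``variant="simple"`` weights every ratio equally; ``"weighted"`` weights
    by inverse second-order ratio variance. ``phi`` scales the
    modified-Silverman kernel bandwidth. Consistent when the largest group of
    SNPs sharing a ratio are valid instruments (ZEMPA). SE by parametric
    bootstrap (median absolute deviation, as the bootstrap distribution is
    heavy-tailed); p from t with n − 1 df.
    """
    n = instr.n_snp
    if n < 3:
        raise ValueError("mode estimator needs at least 3 SNPs")
    if variant not in ("simple", "weighted"):
        raise ValueError(f"unknown mode variant {variant!r}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is too small for a stable bootstrap SE", stacklevel=2)
    r, se_r = wald_ratios(instr, variance="second_order")

    def weights_for(se_arr: np.ndarray) -> np.ndarray:
        return 1.0 / se_arr**2 if variant == "weighted" else np.ones_like(se_arr)

    point = _mode_point(r, weights_for(se_r), phi)

    def stat(bxs, bys, sx, sy):
        rs = bys / bxs
        ses = np.sqrt(sy**2 / bxs**2 + bys**2 * sx**2 / bxs**4)
        return _mode_point(rs, weights_for(ses), phi)

    boot = _parametric_boot(instr, n_boot, seed, stat)
    se = float(stats.median_abs_deviation(boot, scale="normal"))
    p = 2 * stats.t.sf(abs(point / se), df=n - 1)
    return MrEstimate(method=f"{variant}_mode", n_snp=n, beta=point, se=se, pval=float(p))


def cochran_q(instr: InstrumentSet, beta_hat: float | None = None) -> HeterogeneityStats:
    """Cochran's Q for heterogeneity of per-SNP ratios about ``beta_hat``.

    ``Q = Σ w_i (r_i − beta_hat)²`` with ``w_i = beta_exp²/se_out²`` and
    ``r_i`` the Wald ratios; defaults to the fixed-effect IVW estimate.
    Upper-tail chi-square p on n − 1 df.
    """
    n = instr.n_snp
    if n < 2:
        raise ValueError("heterogeneity needs at least 2 SNPs")
    bx, _, by, sy = _arrays(instr)
    if beta_hat is None:
        beta_hat, _, _ = _ivw_core(bx, by, sy)
    r = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (r - beta_hat) ** 2))
    return HeterogeneityStats(q=q, df=n - 1, pval=float(stats.chi2.sf(q, n - 1)))


def f_statistics(source: InstrumentSet) -> FStatistics:
    """Per-SNP instrument strength F = (beta_exp/se_exp)² and the set mean."""
    bx, sx = source.beta_exp, source.se_exp
    f = (bx / sx) ** 2
    return FStatistics(snp_ids=source.snp_ids, f=f, mean=float(np.mean(f)))


def effective_n(n_cases: float, n_controls: float) -> float:
    """Effective sample size of a case-control GWAS, 4/(1/cases + 1/controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def steiger_filter(
    instr: InstrumentSet,
    n_exp: float,
    n_cases: float,
    n_controls: float,
) -> tuple[InstrumentSet, list[str]]:
    """Drop SNPs explaining more outcome than exposure variance.

    Variance explained is approximated per SNP as ``r² = z²/(z² + N)`` on
    each side, with the outcome N the effective case-control sample size.
    SNPs with ``r²_out > r²_exp`` likely act on the outcome first (reverse
    causation) and are excluded with reason ``steiger``.
    """
    if n_exp <= 0:
        raise ValueError("exposure sample size must be positive")
    n_out = effective_n(n_cases, n_controls)
    bx, sx, by, sy = _arrays(instr)
    zx2 = (bx / sx) ** 2
    zy2 = (by / sy) ** 2
    r2_exp = zx2 / (zx2 + n_exp)
    r2_out = zy2 / (zy2 + n_out)
    flagged = [sid for sid, bad in zip(instr.snp_ids, r2_out > r2_exp) if bad]
    for sid in flagged:
        logger.info("Steiger filter: removed %s", sid)
    return instr.drop(flagged, reason="steiger"), flagged


def leave_one_out(instr: InstrumentSet) -> list[tuple[str, MrEstimate]]:
    """Re-estimate (MRE-IVW, or Wald ratio at n = 2) omitting each SNP in turn."""
    if instr.n_snp < 3:
        raise ValueError("leave-one-out needs at least 3 SNPs")
    results = []
    for sid in instr.snp_ids:
        rest = instr.subset([s for s in instr.snp_ids if s != sid])
        est = ivw(rest, model="mre") if rest.n_snp >= 2 else wald_ratio(rest.snps[0])
        results.append((sid, est))
    return results


def mann_kendall(values: Sequence[float]) -> TrendResult:
    """Mann–Kendall trend test on an ordered sequence.

    Kendall score ``S = Σ_{i<j} sign(v_j − v_i)`` (ties contribute 0),
    ``tau = S / (n(n−1)/2)``, and a two-sided p from the normal approximation
    with the tie-corrected variance and a continuity correction (|S| reduced
    by 1). A constant sequence gives tau = 0, p = 1.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("trend test needs at least 3 values")
    diffs = np.sign(v[None, :] - v[:, None])
    s = int(np.sum(np.triu(diffs, k=1)))
    tau = s / (n * (n - 1) / 2)
    _, counts = np.unique(v, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if s == 0 or var_s <= 0:
        return TrendResult(n=n, s=s, tau=float(tau), pval=1.0)
    z = (abs(s) - 1) / np.sqrt(var_s)
    p = 2 * stats.norm.sf(z)
    return TrendResult(n=n, s=s, tau=float(tau), pval=float(min(1.0, p)))
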