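"""Pleiotropy residual sum-of-squares outlier test (MR-PRESSO).

Three stages, all built on leave-one-out expected outcome effects under the
no-pleiotropy model ``beta_out = b·beta_exp``:

1. **Global test** — observed RSS (each SNP's weighted squared deviation from
   the fit excluding it) against a parametric null distribution simulated
   under no pleiotropy.
2. **Outlier test** — each SNP's observed deviation against its own simulated
   distribution, Bonferroni-adjusted over SNPs.
3. **Outlier-corrected estimate** — the through-origin weighted regression
   refitted without the flagged SNPs (SE and p follow the weighted
   least-squares convention of the original formulation: the SE scales with
   the residual dispersion and the p-value uses Student's t on n − 1 df).
4. **Distortion test** — whether removing the outliers changes the estimate
   more than removing equally many randomly chosen SNPs would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MrEstimate
from .harmonise import InstrumentSet

__all__ = ["PressoResult", "presso_global", "presso_outlier_and_correct"]


@dataclass
class PressoResult:
    """Full PRESSO output for one instrument set."""

    rss_obs: float
    global_p: float
    outlier_p: dict[str, float]  # Bonferroni-adjusted per-SNP p
    outliers: list[str]
    raw: MrEstimate
    corrected: MrEstimate
    distortion: float | None  # % change of estimate after outlier removal
    distortion_p: float | None


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out through-origin weighted slopes, one per omitted SNP."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def _loo_slopes_matrix(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise LOO slopes for a (n_sim, n_snp) batch of simulated data."""
    s_xy = np.sum(w * bx * by, axis=1, keepdims=True)
    s_xx = np.sum(w * bx**2, axis=1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def _weighted_residuals_sq(bx, by, w, slopes) -> np.ndarray:
    return w * (by - slopes * bx) ** 2


def _lm_origin(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, n_snp_label: str = "ivw_lm") -> MrEstimate:
    """Weighted through-origin least squares with lm-style SE and t p-value."""
    w = 1.0 / sy**2
    n = len(bx)
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    rss = float(np.sum(w * (by - beta * bx) ** 2))
    sigma2 = rss / (n - 1)
    se = float(np.sqrt(sigma2 / denom))
    p = float(2 * stats.t.sf(abs(beta / se), df=n - 1))
    return MrEstimate(method=n_snp_label, n_snp=n, beta=beta, se=se, pval=p)


def _simulate(instr: InstrumentSet, n_sim: int, seed: int | None):
    """Observed and simulated RSS decompositions under the no-pleiotropy null."""
    bx, sx, by, sy = instr.beta_exp, instr.se_exp, instr.beta_out, instr.se_out
    w = 1.0 / sy**2
    slopes_obs = _loo_slopes(bx, by, w)
    dif_obs = _weighted_residuals_sq(bx, by, w, slopes_obs)
    rss_obs = float(np.sum(dif_obs))

    rng = np.random.default_rng(seed)
    n = len(bx)
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    # expected outcome for SNP i under the LOO fit to the observed data
    by_sim = rng.normal(slopes_obs * bx, sy, size=(n_sim, n))
    slopes_sim = _loo_slopes_matrix(bx_sim, by_sim, w)
    dif_sim = _weighted_residuals_sq(bx_sim, by_sim, w, slopes_sim)
    rss_sim = dif_sim.sum(axis=1)
    return rss_obs, rss_sim, dif_obs, dif_sim


def presso_global(
    instr: InstrumentSet, n_sim: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Global pleiotropy test: observed RSS vs its simulated null.

    Returns ``(rss_obs, global_p)`` with the add-one p-value correction
    ``(1 + #{RSS_sim ≥ RSS_obs}) / (n_sim + 1)`` so p is never exactly zero.
    """
    if instr.n_snp < 4:
        raise ValueError("PRESSO global test needs at least 4 SNPs")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000 for a usable null")
    rss_obs, rss_sim, _, _ = _simulate(instr, n_sim, seed)
    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    return rss_obs, float(global_p)


def presso_outlier_and_correct(
    instr: InstrumentSet,
    n_sim: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    n_distortion: int = 1000,
) -> PressoResult:
    """Per-SNP outlier test, outlier-corrected estimate, and distortion test.

    Each SNP's observed weighted squared deviation is compared against its
    simulated null distribution; per-SNP p-values are Bonferroni-multiplied
    by the number of SNPs and SNPs with adjusted p < ``alpha`` are removed.
    The corrected estimate refits the remaining SNPs; the distortion test
    compares the resulting percentage change in the estimate to the change
    from removing random same-size SNP subsets.
    """
    if instr.n_snp < 4:
        raise ValueError("PRESSO needs at least 4 SNPs")
    n = instr.n_snp
    rss_obs, rss_sim, dif_obs, dif_sim = _simulate(instr, n_sim, seed)
    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)

    p_raw = (1 + np.sum(dif_sim >= dif_obs[None, :], axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * n)
    outlier_p = dict(zip(instr.snp_ids, p_adj.astype(float)))
    outliers = [sid for sid, p in outlier_p.items() if p < alpha]
    if len(outliers) == n:
        raise ValueError("every SNP flagged as an outlier; no instruments remain")

    bx, sx, by, sy = instr.beta_exp, instr.se_exp, instr.beta_out, instr.se_out
    raw = _lm_origin(bx, by, sy, n_snp_label="ivw_raw")
    keep = np.array([sid not in outliers for sid in instr.snp_ids])
    if outliers:
        corrected = _lm_origin(bx[keep], by[keep], sy[keep], n_snp_label="ivw_corrected")
        distortion = 100.0 * (corrected.beta - raw.beta) / abs(raw.beta)
        rng = np.random.default_rng(None if seed is None else seed + 1)
        non_out = np.nonzero(keep)[0]
        d_null = np.empty(n_distortion)
        for b in range(n_distortion):
            drop = rng.choice(non_out, size=len(outliers), replace=True)
            mask = np.ones(n, dtype=bool)
            mask[drop] = False
            est_b = float(
                np.sum(bx[mask] * by[mask] / sy[mask] ** 2)
                / np.sum(bx[mask] ** 2 / sy[mask] ** 2)
            )
            d_null[b] = 100.0 * (est_b - raw.beta) / abs(raw.beta)
        distortion_p = float(np.mean(np.abs(d_null) >= abs(distortion)))
    else:
        corrected = raw
        distortion = None
        distortion_p = None

    return PressoResult(
        rss_obs=rss_obs,
        global_p=float(global_p),
        outlier_p=outlier_p,
        outliers=outliers,
        raw=raw,
        corrected=corrected,
        distortion=distortion,
        distortion_p=distortion_p,
    )
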