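"""Synthetic two-sample GWAS summary statistics with known causal structure.

Summary statistics are simulated directly (no individual-level genotypes):
per-SNP true exposure effects are drawn, observed betas are the truth plus
normal sampling noise with analytic standard errors from allele frequency and
sample size, and outcome effects follow a linear causal model with optional
horizontal pleiotropy:

    beta_out_true = causal_effect · gamma + secondary_effect · beta_sec + alpha

where ``gamma`` is the true exposure effect, ``beta_sec`` an optional
secondary-trait effect (for multivariable MR scenarios) and ``alpha`` a
pleiotropic term that may be balanced (mean zero), directional, or
correlated with ``gamma`` (an InSIDE violation).

Defaults mirror the childhood-BMI / MS study conditions: exposure GWAS of
28,681 children, case-control outcome of 14,802 cases / 26,703 controls, and
per-SNP exposure effects of the size seen among the published instruments
(|beta| ≈ 0.05–0.14 SD per allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import effective_n
from .sumstats import CANONICAL_COLUMNS, SumstatsTable

__all__ = ["Pleiotropy", "SynthScenario", "SynthTruth", "simulate_two_sample", "simulate_longitudinal"]

# non-palindromic allele pairs assigned round-robin to simulated SNPs
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy model for the simulated outcome effects."""

    kind: str = "none"  # none | balanced | directional
    mean: float = 0.0
    sd: float = 0.0

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none", 0.0, 0.0)

    @classmethod
    def balanced(cls, sd: float) -> "Pleiotropy":
        return cls("balanced", 0.0, sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "Pleiotropy":
        return cls("directional", mean, sd)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("pleiotropy sd must be non-negative")


@dataclass
class SynthScenario:
    """Generative parameters for simulated two-sample summary statistics.

    ``exposure_effect_sd`` is the SD of true per-SNP exposure effects
    (standardised-trait units per allele); 0.08 puts typical instruments at
    the strength of the published childhood-BMI loci. ``inside_violation``
    is the correlation between pleiotropic and exposure effects (0 =
    InSIDE-satisfying). ``timepoints`` plus ``timepoint_corr`` activate the
    longitudinal generator; ``secondary_loading`` adds a secondary trait
    whose per-SNP effects load on the exposure effects (for MVMR tests).
    """

    n_snp: int = 50
    causal_effect: float = 0.0
    maf_range: tuple[float, float] = (0.2, 0.8)
    exposure_effect_sd: float = 0.08
    #: "normal" draws signed effects; "absnormal" folds them positive, i.e.
    #: effect alleles are oriented to the exposure-increasing allele
    exposure_effect_dist: str = "normal"
    n_exp: int = 28_681
    n_cases: int = 14_802
    n_controls: int = 26_703
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    inside_violation: float = 0.0
    frac_palindromic: float = 0.0
    timepoints: tuple[str, ...] | None = None
    timepoint_corr: np.ndarray | None = None
    causal_timepoint: str | None = None
    secondary_loading: float | None = None
    secondary_effect: float = 0.0
    secondary_noise_sd: float = 0.02
    n_sec: int = 339_224
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")
        for nm in ("n_exp", "n_cases", "n_controls", "n_sec"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if not -1 <= self.inside_violation <= 1:
            raise ValueError("inside_violation is a correlation in [-1, 1]")
        if not 0 <= self.frac_palindromic <= 1:
            raise ValueError("frac_palindromic must lie in [0, 1]")
        if self.exposure_effect_dist not in ("normal", "absnormal"):
            raise ValueError(f"unknown exposure_effect_dist {self.exposure_effect_dist!r}")
        if self.timepoints is not None:
            t = len(self.timepoints)
            c = np.asarray(self.timepoint_corr, dtype=float)
            if c.shape != (t, t):
                raise ValueError(f"timepoint_corr shape {c.shape} != ({t}, {t})")
            if not np.allclose(c, c.T):
                raise ValueError("timepoint_corr must be symmetric")
            if np.min(np.linalg.eigvalsh(c)) < -1e-8:
                raise ValueError("timepoint_corr must be positive semi-definite")
            self.timepoint_corr = c


@dataclass
class SynthTruth:
    """Latent values behind one simulated dataset."""

    gamma: np.ndarray  # true exposure effects (per timepoint: dict)
    alpha: np.ndarray  # pleiotropic outcome effects
    beta_sec_true: np.ndarray | None
    causal_effect: float
    secondary_effect: float
    seed: int
    gamma_by_timepoint: dict[str, np.ndarray] | None = None


def _se_quantitative(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _alleles(rng: np.random.Generator, n: int, frac_palindromic: float):
    pal = rng.random(n) < frac_palindromic
    ea, oa = [], []
    for i in range(n):
        pool = _PALINDROMIC_PAIRS if pal[i] else _ALLELE_PAIRS
        a, b = pool[i % len(pool)]
        ea.append(a)
        oa.append(b)
    return ea, oa


def _table(snp_ids, ea, oa, eaf, beta, se, n, trait, timepoint) -> SumstatsTable:
    from scipy import stats as _st

    pval = 2.0 * _st.norm.sf(np.abs(beta / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": None,
            "pos": None,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": float(n),
            "trait": trait,
            "timepoint": timepoint,
        },
        columns=CANONICAL_COLUMNS,
    )
    return SumstatsTable(df=df, trait=trait)


def _pleiotropy_draw(
    scn: SynthScenario, rng: np.random.Generator, gamma: np.ndarray
) -> np.ndarray:
    if scn.pleiotropy.kind == "none":
        return np.zeros(scn.n_snp)
    eps = rng.standard_normal(scn.n_snp)
    rho = scn.inside_violation
    if rho != 0.0:
        gstd = (gamma - gamma.mean()) / (gamma.std() if gamma.std() > 0 else 1.0)
        shape = rho * gstd + np.sqrt(1 - rho**2) * eps
    else:
        shape = eps
    return scn.pleiotropy.mean + scn.pleiotropy.sd * shape


def simulate_two_sample(
    scn: SynthScenario,
) -> tuple[SumstatsTable, SumstatsTable, SynthTruth] | tuple[SumstatsTable, SumstatsTable, SumstatsTable, SynthTruth]:
    """Simulate exposure and outcome summary statistics for one time point.

    Returns ``(exposure, outcome, truth)``, or
    ``(exposure, outcome, secondary, truth)`` when ``secondary_loading`` is
    set. Fully reproducible from ``scn.seed``.
    """
    rng = np.random.default_rng(scn.seed)
    n = scn.n_snp
    snp_ids = [f"snp{i + 1:04d}" for i in range(n)]
    ea, oa = _alleles(rng, n, scn.frac_palindromic)
    maf = rng.uniform(*scn.maf_range, size=n)

    gamma = rng.normal(0.0, scn.exposure_effect_sd, size=n)
    if scn.exposure_effect_dist == "absnormal":
        gamma = np.abs(gamma)
    alpha = _pleiotropy_draw(scn, rng, gamma)

    beta_sec_true = None
    if scn.secondary_loading is not None:
        beta_sec_true = scn.secondary_loading * gamma + rng.normal(
            0.0, scn.secondary_noise_sd, size=n
        )

    se_x = _se_quantitative(maf, scn.n_exp)
    bx = rng.normal(gamma, se_x)

    out_true = scn.causal_effect * gamma + alpha
    if beta_sec_true is not None:
        out_true = out_true + scn.secondary_effect * beta_sec_true
    se_y = _se_quantitative(maf, effective_n(scn.n_cases, scn.n_controls))
    by = rng.normal(out_true, se_y)

    exposure = _table(snp_ids, ea, oa, maf, bx, se_x, scn.n_exp, "sim_exposure", "t0")
    outcome = _table(snp_ids, ea, oa, maf, by, se_y, scn.n_cases + scn.n_controls, "sim_outcome", "t0")
    truth = SynthTruth(
        gamma=gamma,
        alpha=alpha,
        beta_sec_true=beta_sec_true,
        causal_effect=scn.causal_effect,
        secondary_effect=scn.secondary_effect,
        seed=scn.seed,
    )
    if beta_sec_true is None:
        return exposure, outcome, truth
    se_s = _se_quantitative(maf, scn.n_sec)
    bs = rng.normal(beta_sec_true, se_s)
    secondary = _table(snp_ids, ea, oa, maf, bs, se_s, scn.n_sec, "sim_secondary", "t0")
    return exposure, outcome, secondary, truth


def simulate_longitudinal(
    scn: SynthScenario,
) -> tuple[dict[str, SumstatsTable], SumstatsTable, SumstatsTable | None, SynthTruth]:
    """Simulate per-time-point exposure tables with correlated genetics.

    Per-SNP true effect vectors across time points are multivariate normal
    with correlation ``scn.timepoint_corr`` and marginal SD
    ``exposure_effect_sd``. The outcome responds to the exposure at
    ``causal_timepoint`` (default: the last one); an optional secondary trait
    loads on the same time point's effects. Returns
    ``(exposure_by_timepoint, outcome, secondary_or_None, truth)``.
    """
    if scn.timepoints is None or scn.timepoint_corr is None:
        raise ValueError("scenario lacks timepoints / timepoint_corr")
    rng = np.random.default_rng(scn.seed)
    tps = tuple(scn.timepoints)
    t = len(tps)
    n = scn.n_snp
    snp_ids = [f"snp{i + 1:04d}" for i in range(n)]
    ea, oa = _alleles(rng, n, scn.frac_palindromic)
    maf = rng.uniform(*scn.maf_range, size=n)

    cov = scn.exposure_effect_sd**2 * np.asarray(scn.timepoint_corr)
    g = rng.multivariate_normal(np.zeros(t), cov, size=n, method="svd")  # (n_snp, t)
    gamma_by_tp = {tp: g[:, k] for k, tp in enumerate(tps)}

    ref_tp = scn.causal_timepoint or tps[-1]
    if ref_tp not in gamma_by_tp:
        raise ValueError(f"causal_timepoint {ref_tp!r} not among timepoints")
    gamma_ref = gamma_by_tp[ref_tp]
    alpha = _pleiotropy_draw(scn, rng, gamma_ref)

    beta_sec_true = None
    if scn.secondary_loading is not None:
        beta_sec_true = scn.secondary_loading * gamma_ref + rng.normal(
            0.0, scn.secondary_noise_sd, size=n
        )

    se_x = _se_quantitative(maf, scn.n_exp)
    exposures = {}
    for tp in tps:
        bx = rng.normal(gamma_by_tp[tp], se_x)
        exposures[tp] = _table(snp_ids, ea, oa, maf, bx, se_x, scn.n_exp, "sim_exposure", tp)

    out_true = scn.causal_effect * gamma_ref + alpha
    if beta_sec_true is not None:
        out_true = out_true + scn.secondary_effect * beta_sec_true
    se_y = _se_quantitative(maf, effective_n(scn.n_cases, scn.n_controls))
    by = rng.normal(out_true, se_y)
    outcome = _table(snp_ids, ea, oa, maf, by, se_y, scn.n_cases + scn.n_controls, "sim_outcome", "outcome")

    secondary = None
    if beta_sec_true is not None:
        se_s = _se_quantitative(maf, scn.n_sec)
        bs = rng.normal(beta_sec_true, se_s)
        secondary = _table(snp_ids, ea, oa, maf, bs, se_s, scn.n_sec, "sim_secondary", "adult")

    truth = SynthTruth(
        gamma=gamma_ref,
        alpha=alpha,
        beta_sec_true=beta_sec_true,
        causal_effect=scn.causal_effect,
        secondary_effect=scn.secondary_effect,
        seed=scn.seed,
        gamma_by_timepoint=gamma_by_tp,
    )
    return exposures, outcome, secondary, truth
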