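"""End-to-end analysis orchestration: instrument selection, harmonisation,
the full estimator battery per epoch or time point, and report output.

The report mirrors the structure of a standard two-sample MR results table
(label, method, number of SNPs, beta, SE, p, OR with 95% CI) plus companion
blocks: heterogeneity / Egger intercepts, per-SNP F statistics, Steiger and
harmonisation exclusion logs, leave-one-out estimates, PRESSO, optional
multivariable MR, and the Mann–Kendall trend across time points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .harmonise import InstrumentSet, harmonise_set
from .instruments import (
    DEFAULT_EPOCHS,
    EpochDefinition,
    LdMatrix,
    amalgamate_epochs,
    clump,
    exclude_mhc,
    filter_genomewide,
)
from .mvmr import combine_with_secondary, mvmr_joint, mvmr_residual
from .presso import PressoResult, presso_outlier_and_correct
from .sumstats import SumstatsTable, load_fixture, read_sumstats

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "EpochResult", "ReportBundle", "run_epoch_analysis", "analyse_instruments"]


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    use_fixture: bool = False
    exposures: dict[str, str] = field(default_factory=dict)  # timepoint -> path
    outcome: str | None = None
    secondary: str | None = None
    mode: str = "epochs"  # epochs | timepoints
    epochs: Sequence[EpochDefinition] = DEFAULT_EPOCHS
    palindromic_policy: str = "strict"
    maf_threshold: float = 0.42
    p_threshold: float = 5e-8
    pre_clumped: bool = False
    ld_matrix: str | None = None
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    apply_mhc_filter: bool = False
    n_boot: int = 1000
    n_sim: int = 10_000
    seed: int = 0
    n_exp: float | None = 28_681
    n_cases: float | None = 14_802
    n_controls: float | None = 26_703
    out_dir: str | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "epochs" in raw:
            raw["epochs"] = [
                EpochDefinition(label=k, timepoints=tuple(v)) for k, v in raw["epochs"].items()
            ]
        cfg = cls(**raw)
        for p in [*cfg.exposures.values(), cfg.outcome, cfg.secondary, cfg.ld_matrix]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input file missing: {p}")
        return cfg


@dataclass
class EpochResult:
    """All results for one epoch / time point."""

    label: str
    instruments: InstrumentSet | None
    estimates: list[est.MrEstimate] = field(default_factory=list)
    ivw_het: est.HeterogeneityStats | None = None
    egger_het: est.HeterogeneityStats | None = None
    fstats: est.FStatistics | None = None
    steiger_removed: list[str] = field(default_factory=list)
    loo: list[tuple[str, est.MrEstimate]] = field(default_factory=list)
    presso: PressoResult | None = None
    mvmr: list = field(default_factory=list)
    note: str = ""

    @property
    def primary(self) -> est.MrEstimate | None:
        """The headline causal estimate: MRE-IVW, or the Wald ratio at n = 1."""
        for method in ("ivw_mre", "wald"):
            for e in self.estimates:
                if e.method == method:
                    return e
        return None


@dataclass
class ReportBundle:
    """Machine- and human-readable outputs of one run."""

    per_epoch: list[EpochResult]
    trend: est.TrendResult | None
    config: AnalysisConfig

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for ep in self.per_epoch:
            for e in ep.estimates:
                rows.append(
                    {
                        "label": ep.label,
                        "method": e.method,
                        "n_snp": e.n_snp,
                        "beta": e.beta,
                        "se": e.se,
                        "pval": e.pval,
                        "or": e.or_,
                        "or_ci_low": e.or_ci_low,
                        "or_ci_high": e.or_ci_high,
                    }
                )
            if not ep.estimates:
                rows.append({"label": ep.label, "method": "none", "n_snp": 0,
                             "beta": np.nan, "se": np.nan, "pval": np.nan,
                             "or": np.nan, "or_ci_low": np.nan, "or_ci_high": np.nan})
        return pd.DataFrame(rows)

    def exclusions_frame(self) -> pd.DataFrame:
        rows = []
        for ep in self.per_epoch:
            if ep.instruments is None:
                continue
            for s in ep.instruments.excluded_snps:
                rows.append({"label": ep.label, "snp_id": s.snp_id, "reason": s.exclusion_reason})
        return pd.DataFrame(rows, columns=["label", "snp_id", "reason"])

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results_frame().to_csv(out / "results.tsv", sep="\t", index=False)
        self.exclusions_frame().to_csv(out / "exclusions.tsv", sep="\t", index=False)

        het_rows = []
        for ep in self.per_epoch:
            if ep.ivw_het is not None:
                het_rows.append(
                    {
                        "label": ep.label,
                        "q": ep.ivw_het.q,
                        "q_df": ep.ivw_het.df,
                        "q_pval": ep.ivw_het.pval,
                        "egger_intercept": None if ep.egger_het is None else ep.egger_het.egger_intercept,
                        "egger_intercept_se": None if ep.egger_het is None else ep.egger_het.intercept_se,
                        "egger_intercept_p": None if ep.egger_het is None else ep.egger_het.intercept_p,
                        "mean_f": None if ep.fstats is None else ep.fstats.mean,
                    }
                )
        pd.DataFrame(het_rows).to_csv(out / "heterogeneity.tsv", sep="\t", index=False)

        loo_rows = [
            {"label": ep.label, "omitted": sid, "beta": e.beta, "se": e.se, "pval": e.pval}
            for ep in self.per_epoch
            for sid, e in ep.loo
        ]
        pd.DataFrame(loo_rows, columns=["label", "omitted", "beta", "se", "pval"]).to_csv(
            out / "leave_one_out.tsv", sep="\t", index=False
        )

        presso_block = {}
        for ep in self.per_epoch:
            if ep.presso is None:
                continue
            pr = ep.presso
            presso_block[ep.label] = {
                "rss_obs": pr.rss_obs,
                "global_p": pr.global_p,
                "outliers": pr.outliers,
                "raw_beta": pr.raw.beta,
                "raw_p": pr.raw.pval,
                "corrected_beta": pr.corrected.beta,
                "corrected_p": pr.corrected.pval,
                "distortion_pct": pr.distortion,
                "distortion_p": pr.distortion_p,
            }
        summary = {
            "presso": presso_block,
            "trend": None
            if self.trend is None
            else {"n": self.trend.n, "s": self.trend.s, "tau": self.trend.tau, "pval": self.trend.pval},
            "notes": {ep.label: ep.note for ep in self.per_epoch if ep.note},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

        cfg = {k: v for k, v in self.config.__dict__.items() if k != "epochs"}
        cfg["epochs"] = {e.label: list(e.timepoints) for e in self.config.epochs}
        from . import __version__

        cfg["chronomr_version"] = __version__
        (out / "config_echo.json").write_text(json.dumps(cfg, indent=2, default=str))
        (out / "summary.txt").write_text(self.render_text())

        if self.config.plots:
            from . import plots

            for ep in self.per_epoch:
                if ep.instruments is not None and ep.instruments.n_snp >= 2:
                    plots.epoch_panel(ep, out / f"plots_{ep.label}.png")

    def render_text(self) -> str:
        lines = ["Longitudinal two-sample MR report", "=" * 40]
        for ep in self.per_epoch:
            lines.append(f"\n[{ep.label}]")
            if ep.note:
                lines.append(f"  note: {ep.note}")
            for e in ep.estimates:
                lines.append(
                    f"  {e.method:16s} n={e.n_snp:3d}  beta={e.beta: .4f}  se={e.se:.4f}  "
                    f"p={e.pval:.4g}  OR={e.or_:.2f} ({e.or_ci_low:.2f}-{e.or_ci_high:.2f})"
                )
            if ep.ivw_het:
                lines.append(f"  Cochran Q={ep.ivw_het.q:.2f} (df={ep.ivw_het.df}, p={ep.ivw_het.pval:.3g})")
            if ep.egger_het:
                lines.append(
                    f"  Egger intercept={ep.egger_het.egger_intercept:.4f} (p={ep.egger_het.intercept_p:.3g})"
                )
            if ep.fstats:
                lines.append(f"  mean F={ep.fstats.mean:.1f}")
            if ep.steiger_removed:
                lines.append(f"  Steiger removed: {', '.join(ep.steiger_removed)}")
            if ep.presso:
                lines.append(
                    f"  PRESSO global p={ep.presso.global_p:.4g}; outliers: "
                    f"{', '.join(ep.presso.outliers) or 'none'}; corrected beta="
                    f"{ep.presso.corrected.beta:.4f} (p={ep.presso.corrected.pval:.3g})"
                )
            for mv in ep.mvmr:
                lines.append(
                    f"  MVMR ({mv.method}) n={mv.n_snp}  beta={mv.beta:.4f}  se={mv.se:.4f}  p={mv.pval:.3g}"
                )
        if self.trend:
            lines.append(
                f"\nMann-Kendall trend across time points: tau={self.trend.tau:.3f}, "
                f"S={self.trend.s}, p={self.trend.pval:.3g}"
            )
        return "\n".join(lines) + "\n"


def analyse_instruments(
    instr: InstrumentSet,
    *,
    n_boot: int = 1000,
    n_sim: int = 10_000,
    seed: int = 0,
    n_exp: float | None = None,
    n_cases: float | None = None,
    n_controls: float | None = None,
    secondary: SumstatsTable | None = None,
) -> EpochResult:
    """Run every applicable estimator and sensitivity analysis on one set."""
    res = EpochResult(label=instr.label, instruments=instr)
    if instr.n_snp == 0:
        res.note = "no SNPs remained after instrument selection"
        return res

    if None not in (n_exp, n_cases, n_controls):
        instr, removed = est.steiger_filter(instr, n_exp, n_cases, n_controls)
        res.steiger_removed = removed
        res.instruments = instr
        if instr.n_snp == 0:
            res.note = "no SNPs remained after Steiger filtering"
            return res

    res.fstats = est.f_statistics(instr)
    n = instr.n_snp
    if n == 1:
        res.estimates.append(est.wald_ratio(instr.snps[0]))
        return res

    res.estimates.append(est.ivw(instr, model="mre"))
    res.ivw_het = est.cochran_q(instr)
    if n >= 3:
        slope, ehet = est.egger(instr)
        res.estimates.append(slope)
        res.egger_het = ehet
        res.estimates.append(est.weighted_median(instr, n_boot=n_boot, seed=seed))
        res.estimates.append(est.mode_estimate(instr, variant="simple", n_boot=n_boot, seed=seed))
        res.estimates.append(est.mode_estimate(instr, variant="weighted", n_boot=n_boot, seed=seed))
        res.loo = est.leave_one_out(instr)
    if n >= 4:
        res.presso = presso_outlier_and_correct(instr, n_sim=n_sim, seed=seed)
    if secondary is not None and n >= 3:
        mv_instr = combine_with_secondary(instr, secondary)
        if len(mv_instr) >= 3:
            res.mvmr.append(mvmr_residual(mv_instr))
            try:
                res.mvmr.append(mvmr_joint(mv_instr))
            except np.linalg.LinAlgError as exc:
                res.note = (res.note + "; " if res.note else "") + f"joint MVMR skipped: {exc}"
        else:
            res.note = (
                (res.note + "; " if res.note else "")
                + f"MVMR skipped: only {len(mv_instr)} SNPs present in secondary dataset"
            )
    return res


def _load_unit_tables(cfg: AnalysisConfig) -> tuple[dict[str, SumstatsTable], SumstatsTable]:
    """Resolve configuration into per-unit exposure tables plus the outcome."""
    if cfg.use_fixture:
        units: dict[str, SumstatsTable] = {}
        outcome_frames = []
        for ep in ("birth", "infancy", "early_childhood", "later_childhood"):
            exp_t, out_t = load_fixture(ep)
            units[ep] = exp_t
            outcome_frames.append(out_t.df)
        out_df = pd.concat(outcome_frames, ignore_index=True).drop_duplicates("snp_id")
        out_df["timepoint"] = ""
        outcome = SumstatsTable(df=out_df.reset_index(drop=True), trait="multiple sclerosis")
        return units, outcome

    if not cfg.exposures or cfg.outcome is None:
        raise ValueError("config must set exposure and outcome files (or use_fixture)")
    per_tp: dict[str, SumstatsTable] = {}
    ld = LdMatrix.read(cfg.ld_matrix) if cfg.ld_matrix else None
    for tp, path in cfg.exposures.items():
        table, report = read_sumstats(path, timepoint=tp)
        if report.n_rejected:
            logger.warning("%s: rejected %d rows", path, report.n_rejected)
        table = filter_genomewide(table, cfg.p_threshold)
        if cfg.apply_mhc_filter:
            table = exclude_mhc(table)
        if not cfg.pre_clumped:
            table = clump(table, ld, cfg.clump_r2, cfg.clump_window_kb, allow_missing=ld is None)
        per_tp[tp] = table
    outcome, report = read_sumstats(cfg.outcome)
    if report.n_rejected:
        logger.warning("%s: rejected %d rows", cfg.outcome, report.n_rejected)

    if cfg.mode == "timepoints":
        return per_tp, outcome
    return amalgamate_epochs(per_tp, cfg.epochs), outcome


def run_epoch_analysis(cfg: AnalysisConfig) -> ReportBundle:
    """Run the configured analysis over every epoch / time point."""
    units, outcome = _load_unit_tables(cfg)
    secondary = None
    if cfg.secondary is not None:
        secondary, _ = read_sumstats(cfg.secondary)

    if cfg.use_fixture or cfg.mode == "epochs":
        order = [e.label for e in cfg.epochs if e.label in units] or list(units)
    else:
        order = [tp for tp in cfg.exposures if tp in units]

    per_epoch: list[EpochResult] = []
    for label in order:
        exp_t = units[label]
        if len(exp_t) == 0:
            per_epoch.append(EpochResult(label=label, instruments=None, note="no significant SNPs"))
            continue
        instr = harmonise_set(
            exp_t, outcome, policy=cfg.palindromic_policy,
            maf_threshold=cfg.maf_threshold, label=label,
        )
        per_epoch.append(
            analyse_instruments(
                instr,
                n_boot=cfg.n_boot,
                n_sim=cfg.n_sim,
                seed=cfg.seed,
                n_exp=cfg.n_exp,
                n_cases=cfg.n_cases,
                n_controls=cfg.n_controls,
                secondary=secondary,
            )
        )

    trend = None
    if cfg.mode == "timepoints":
        series = [ep.primary.beta for ep in per_epoch if ep.primary is not None]
        if len(series) >= 3:
            trend = est.mann_kendall(series)

    bundle = ReportBundle(per_epoch=per_epoch, trend=trend, config=cfg)
    if cfg.out_dir:
        bundle.write(cfg.out_dir)
    return bundle
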