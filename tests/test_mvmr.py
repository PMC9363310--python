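"""Multivariable MR: residual and joint methods, secondary-exposure
restriction."""

import numpy as np
import pytest

from chronomr.estimators import ivw
from chronomr.harmonise import InstrumentSet, harmonise_set
from chronomr.mvmr import (
    MvmrInstrument,
    combine_with_secondary,
    mvmr_joint,
    mvmr_residual,
    restrict_by_secondary,
)
from chronomr.synth import SynthScenario, simulate_two_sample


def mv_instruments(bx, bs, by, sy, sx=None):
    n = len(bx)
    sx = sx if sx is not None else [0.01] * n
    return [
        MvmrInstrument(
            snp_id=f"snp{i:03d}", beta_exp=bx[i], se_exp=sx[i],
            beta_sec=bs[i], se_sec=0.01, beta_out=by[i], se_out=sy[i],
        )
        for i in range(n)
    ]


def simulate_mvmr(direct, mediated_via_secondary, seed, n_snp=100, loading=0.0,
                  secondary_noise_sd=0.08):
    """Simulated three-trait summary statistics with known direct effect.

    With ``loading=0`` the secondary trait's per-SNP effects are independent
    of the primary ones, so the direct effect is identifiable; ``loading=1``
    with small noise reproduces the collinear, fully-age-shared case.
    """
    scn = SynthScenario(
        n_snp=n_snp,
        causal_effect=direct,
        secondary_loading=loading,
        secondary_noise_sd=secondary_noise_sd,
        secondary_effect=mediated_via_secondary,
        seed=seed,
    )
    exp, out, sec, truth = simulate_two_sample(scn)
    instr = harmonise_set(exp, out, label="sim")
    return combine_with_secondary(instr, sec), truth


class TestResidualMethod:
    def test_zero_secondary_reduces_to_ivw(self, rng):
        bx = rng.normal(0.08, 0.02, 8)
        by = 0.25 * bx + rng.normal(0, 0.01, 8)
        sy = rng.uniform(0.01, 0.03, 8)
        instrs = mv_instruments(bx, [0.0] * 8, by, sy)
        res = mvmr_residual(instrs)
        uni = ivw(
            InstrumentSet.from_arrays(bx, [0.01] * 8, by, sy), model="mre"
        )
        assert res.beta == pytest.approx(uni.beta, rel=1e-12)
        assert res.se == pytest.approx(uni.se, rel=1e-12)
        assert res.pval == pytest.approx(uni.pval, rel=1e-10)

    def test_fully_mediated_effect_vanishes(self):
        """Direct effect 0, outcome driven entirely via the secondary trait:
        the univariable estimate is positive but the conditional one is null."""
        instrs, _ = simulate_mvmr(direct=0.0, mediated_via_secondary=0.3, seed=21,
                                  loading=1.0, secondary_noise_sd=0.02)
        uni = ivw(
            InstrumentSet.from_arrays(
                [i.beta_exp for i in instrs], [i.se_exp for i in instrs],
                [i.beta_out for i in instrs], [i.se_out for i in instrs],
            ),
            model="mre",
        )
        res = mvmr_residual(instrs)
        assert uni.beta > 2 * uni.se  # mediation masquerades as causal
        assert res.beta == pytest.approx(0.0, abs=2 * res.se)

    def test_direct_effect_recovered_alongside_mediation(self):
        """With an independent secondary trait, the residual method separates
        a direct effect of 0.3 from an additional mediated pathway."""
        betas = [mvmr_residual(simulate_mvmr(0.3, 0.2, seed=300 + k)[0]).beta for k in range(20)]
        assert np.mean(betas) == pytest.approx(0.3, abs=0.05)

    def test_needs_three_snps(self):
        with pytest.raises(ValueError):
            mvmr_residual(mv_instruments([0.1, 0.2], [0, 0], [0.05, 0.1], [0.02, 0.02]))


class TestJointMethod:
    def test_zero_secondary_equals_origin_slope(self, rng):
        bx = rng.normal(0.08, 0.02, 6)
        by = 0.25 * bx + rng.normal(0, 0.005, 6)
        sy = rng.uniform(0.01, 0.03, 6)
        res = mvmr_joint(mv_instruments(bx, [0.0] * 6, by, sy))
        w = 1 / sy**2
        expected = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert res.beta == pytest.approx(expected, rel=1e-12)

    def test_two_snp_system_solved_exactly(self):
        # bx, bs form an invertible 2x2 design: coefficients solve it exactly
        instrs = mv_instruments([1.0, 0.0], [0.0, 1.0], [0.7, -0.2], [0.1, 0.1])
        res = mvmr_joint(instrs)
        assert res.beta == pytest.approx(0.7, rel=1e-12)

    def test_rank_deficiency_error_names_columns(self):
        bx = [0.1, 0.2, 0.3, 0.4]
        instrs = mv_instruments(bx, [2 * b for b in bx], [0.05] * 4, [0.02] * 4)
        with pytest.raises(np.linalg.LinAlgError, match="beta_sec"):
            mvmr_joint(instrs)

    def test_agrees_with_residual_when_exposures_weakly_correlated(self, rng):
        n = 200
        bx = rng.normal(0, 0.08, n)
        bs = rng.normal(0, 0.08, n)  # independent secondary effects
        by = 0.25 * bx + 0.1 * bs + rng.normal(0, 0.01, n)
        sy = np.full(n, 0.015)
        instrs = mv_instruments(bx, bs, by, sy)
        r1 = mvmr_residual(instrs)
        r2 = mvmr_joint(instrs)
        assert r1.beta == pytest.approx(r2.beta, abs=0.03)
        assert r2.beta == pytest.approx(0.25, abs=3 * r2.se)

    def test_order_invariance(self, rng):
        n = 10
        bx, bs = rng.normal(0, 0.08, n), rng.normal(0, 0.05, n)
        by = 0.2 * bx + 0.1 * bs + rng.normal(0, 0.01, n)
        sy = rng.uniform(0.01, 0.02, n)
        instrs = mv_instruments(bx, bs, by, sy)
        res_fwd = mvmr_joint(instrs)
        res_rev = mvmr_joint(list(reversed(instrs)))
        assert res_fwd.beta == pytest.approx(res_rev.beta, rel=1e-12)


class TestParameterRecovery:
    def test_bias_small_across_effect_grid(self):
        """Residual-method bias < 0.02 over a grid of direct/mediated effects."""
        for direct in (0.0, 0.2):
            for mediated in (0.0, 0.2):
                betas = [
                    mvmr_residual(simulate_mvmr(direct, mediated, seed=hash((direct, mediated, k)) % 2**31, n_snp=100)[0]).beta
                    for k in range(10)
                ]
                assert abs(np.mean(betas) - direct) < 0.02 + 2 * np.std(betas) / np.sqrt(10)


class TestRestrictBySecondary:
    def test_threshold_partitions_instruments(self, instrument_sets):
        from chronomr.sumstats import GwasRecord, SumstatsTable

        instr = instrument_sets["infancy"]
        # secondary table: 4 of 18 SNPs have p > 0.05, one SNP missing
        ids = instr.snp_ids
        records = []
        for k, sid in enumerate(ids[:-1]):
            p = 0.5 if k < 4 else 1e-4
            records.append(GwasRecord(snp_id=sid, effect_allele="A", other_allele="G",
                                      beta=0.01, se=0.005, pval=p))
        sec = SumstatsTable.from_records(records, trait="adult BMI")
        out = restrict_by_secondary(instr, sec, p_threshold=0.05)
        assert out.n_snp == 4
        reasons = {s.snp_id: s.exclusion_reason for s in out.excluded_snps}
        assert reasons[ids[-1]] == "not_in_secondary"
        assert sum(r == "secondary_associated" for r in reasons.values()) == 13

    def test_extreme_thresholds(self, instrument_sets):
        from chronomr.sumstats import GwasRecord, SumstatsTable

        instr = instrument_sets["early_childhood"]
        records = [GwasRecord(snp_id=sid, effect_allele="A", other_allele="G",
                              beta=0.01, se=0.005, pval=0.5) for sid in instr.snp_ids]
        sec = SumstatsTable.from_records(records, trait="adult BMI")
        assert restrict_by_secondary(instr, sec, p_threshold=0.0).n_snp == instr.n_snp
        assert restrict_by_secondary(instr, sec, p_threshold=1.0).n_snp == 0
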