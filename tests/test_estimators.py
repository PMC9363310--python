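"""Univariable MR estimators against published values, closed forms, and
brute-force oracles."""

import numpy as np
import pytest

from chronomr.estimators import (
    cochran_q,
    egger,
    f_statistics,
    ivw,
    leave_one_out,
    mann_kendall,
    mode_estimate,
    steiger_filter,
    wald_ratio,
    wald_ratios,
    weighted_median,
)
from chronomr.harmonise import HarmonisedSnp, InstrumentSet
from chronomr.synth import Pleiotropy, SynthScenario, simulate_two_sample
from chronomr.harmonise import harmonise_set


def snp(snp_id="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02):
    return HarmonisedSnp(snp_id=snp_id, beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy)


def instr_from(ratios, weights_se=None, bx=1.0):
    """Instrument set whose Wald ratios are exactly `ratios` at beta_exp = bx."""
    n = len(ratios)
    sy = weights_se if weights_se is not None else [0.02] * n
    return InstrumentSet.from_arrays(
        beta_exp=[bx] * n,
        se_exp=[1e-6] * n,
        beta_out=[r * bx for r in ratios],
        se_out=sy,
    )


def synth_instruments(scn):
    exp, out, _ = simulate_two_sample(scn)[:3]
    return harmonise_set(exp, out, label="synth")


class TestWaldRatio:
    def test_published_snp_quotient(self, instrument_sets):
        s = {x.snp_id: x for x in instrument_sets["birth"].snps}["rs11187129"]
        est = wald_ratio(s)
        assert est.beta == pytest.approx(0.094401 / -0.0471726, rel=1e-12)
        assert est.se == pytest.approx(0.01739 / 0.0471726, rel=1e-12)

    def test_zero_outcome_and_identity_scaling(self):
        assert wald_ratio(snp(by=0.0)).beta == 0.0
        est = wald_ratio(snp(bx=1.0, sy=0.2))
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(snp(bx=0.0))


class TestIvw:
    # published estimates per epoch; agreement limited by the 6-significant-
    # figure precision of the published per-SNP inputs
    TABLE = {
        "birth": (-0.20891, 0.243413, 0.390749),
        "infancy": (0.162189, 0.062848, 0.009861),
        "early_childhood": (0.267068, 0.122666, 0.029467),
        "later_childhood": (0.289007, 0.109746, 0.008453),
    }

    @pytest.mark.parametrize("epoch", list(TABLE))
    def test_reproduces_published_estimates(self, instrument_sets, epoch):
        est = ivw(instrument_sets[epoch], model="mre")
        beta, se, p = self.TABLE[epoch]
        assert est.beta == pytest.approx(beta, abs=1e-4)
        assert est.se == pytest.approx(se, abs=1e-4)
        assert est.pval == pytest.approx(p, abs=1e-4)

    def test_identical_ratios_degenerate(self):
        i = instr_from([1.7, 1.7])
        fixed = ivw(i, model="fixed")
        mre = ivw(i, model="mre")
        assert fixed.beta == pytest.approx(1.7)
        assert mre.beta == pytest.approx(1.7)
        assert mre.se == pytest.approx(fixed.se)  # Q = 0: no inflation

    def test_mre_se_never_below_fixed(self, instrument_sets):
        for i in instrument_sets.values():
            assert ivw(i, "mre").se >= ivw(i, "fixed").se - 1e-15

    def test_single_snp_directed_to_wald(self):
        with pytest.raises(ValueError, match="wald"):
            ivw(instr_from([1.0]).subset(["snp0001"]))

    def test_duplicated_ratio_recovers_it_exactly(self):
        i = instr_from([0.42] * 5)
        assert ivw(i, "mre").beta == pytest.approx(0.42, rel=1e-12)


class TestEgger:
    def test_reproduces_published_infancy_slope(self, instrument_sets):
        slope, het = egger(instrument_sets["infancy"])
        assert slope.beta == pytest.approx(0.259406, abs=1e-4)
        assert slope.se == pytest.approx(0.223306, abs=1e-4)
        assert slope.pval == pytest.approx(0.262409, abs=5e-4)

    def test_exact_line_through_three_points(self):
        # (1, 1), (2, 3), (3, 5) lie on y = 2x - 1
        i = InstrumentSet.from_arrays([1, 2, 3], [1e-6] * 3, [1, 3, 5], [0.1] * 3)
        slope, het = egger(i)
        assert slope.beta == pytest.approx(2.0, rel=1e-9)
        assert het.egger_intercept == pytest.approx(-1.0, rel=1e-9)
        assert het.q == pytest.approx(0.0, abs=1e-12)

    def test_intercept_recovers_directional_pleiotropy(self):
        scn = SynthScenario(
            n_snp=50, causal_effect=0.2, exposure_effect_dist="absnormal",
            pleiotropy=Pleiotropy.directional(0.03, 0.005), seed=11,
        )
        _, het = egger(synth_instruments(scn))
        assert het.egger_intercept == pytest.approx(0.03, abs=2 * het.intercept_se)

    def test_published_intercepts_consistent_with_no_pleiotropy(self, instrument_sets):
        for i in instrument_sets.values():
            _, het = egger(i)
            assert het.intercept_p > 0.05

    def test_too_few_snps(self):
        with pytest.raises(ValueError):
            egger(instr_from([1.0, 2.0]))


class TestWeightedMedian:
    def test_reproduces_published_infancy_estimate(self, instrument_sets):
        est = weighted_median(instrument_sets["infancy"], n_boot=1000, seed=3)
        assert est.beta == pytest.approx(0.179452, abs=1e-4)
        # published bootstrap SE 0.086761; stochastic, matched within 15%
        assert est.se == pytest.approx(0.086761, rel=0.15)

    def test_equal_weights_middle_value(self):
        est = weighted_median(instr_from([1.0, 2.0, 3.0]), n_boot=100, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_matches_bruteforce_cumulative_scan(self, rng):
        ratios = rng.normal(0.3, 0.2, size=5)
        ses = rng.uniform(0.05, 0.3, size=5)
        i = instr_from(list(ratios), weights_se=list(ses))
        est = weighted_median(i, n_boot=100, seed=0)
        # oracle: exhaustive scan over sorted ratios with standardised
        # cumulative weights, interpolating at 0.5
        r, se_r = wald_ratios(i, variance="second_order")
        w = 1.0 / se_r**2
        order = np.argsort(r)
        r, w = r[order], w[order]
        cum = (np.cumsum(w) - 0.5 * w) / w.sum()
        k = int(np.max(np.nonzero(cum < 0.5)[0]))
        expected = r[k] + (r[k + 1] - r[k]) * (0.5 - cum[k]) / (cum[k + 1] - cum[k])
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_order_invariance_and_seed_reproducibility(self, instrument_sets):
        i = instrument_sets["infancy"]
        shuffled = i.subset(list(reversed(i.snp_ids)))
        a = weighted_median(i, n_boot=200, seed=9)
        b = weighted_median(shuffled, n_boot=200, seed=9)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert weighted_median(i, n_boot=200, seed=9).se == a.se

    def test_small_bootstrap_warns(self):
        with pytest.warns(UserWarning):
            weighted_median(instr_from([1.0, 2.0, 3.0]), n_boot=50, seed=0)


class TestModeEstimators:
    def test_identical_ratios_recovered(self):
        for variant in ("simple", "weighted"):
            est = mode_estimate(instr_from([0.7, 0.7, 0.7, 0.7]), variant=variant,
                                n_boot=100, seed=0)
            assert est.beta == pytest.approx(0.7, abs=1e-6)

    @pytest.mark.parametrize("variant, published", [("simple", 0.10474), ("weighted", 0.196361)])
    def test_near_published_infancy_modes(self, instrument_sets, variant, published):
        # bandwidth convention is approximate: agreement within 0.02
        est = mode_estimate(instrument_sets["infancy"], variant=variant, n_boot=200, seed=5)
        assert est.beta == pytest.approx(published, abs=0.02)

    def test_estimate_lands_in_majority_cluster(self, rng):
        ratios = np.concatenate([rng.normal(0.3, 0.01, 12), rng.normal(2.0, 0.05, 8)])
        i = instr_from(list(ratios))
        est = mode_estimate(i, variant="simple", n_boot=100, seed=0)
        assert 0.2 < est.beta < 0.4

    def test_order_invariance(self, instrument_sets):
        i = instrument_sets["infancy"]
        shuffled = i.subset(list(reversed(i.snp_ids)))
        a = mode_estimate(i, variant="weighted", n_boot=100, seed=1)
        b = mode_estimate(shuffled, variant="weighted", n_boot=100, seed=1)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)


class TestHeterogeneityAndStrength:
    def test_birth_epoch_heterogeneous(self, instrument_sets):
        het = cochran_q(instrument_sets["birth"])
        assert het.q == pytest.approx(33.2, abs=0.5)
        assert het.pval < 0.001
        assert het.df == 6

    def test_other_epochs_homogeneous(self, instrument_sets):
        for ep in ("infancy", "early_childhood", "later_childhood"):
            assert cochran_q(instrument_sets[ep]).pval > 0.05

    def test_identical_ratios_zero_q(self):
        assert cochran_q(instr_from([1.1] * 4)).q == pytest.approx(0.0, abs=1e-18)

    def test_null_q_mean_near_df(self, rng):
        # homogeneous simulated sets: Q/(n-1) has mean ~ 1
        stats = []
        for k in range(200):
            scn = SynthScenario(n_snp=10, causal_effect=0.1, seed=1000 + k)
            stats.append(cochran_q(synth_instruments(scn)).q / 9)
        assert np.mean(stats) == pytest.approx(1.0, abs=0.1)

    def test_f_statistic_formula(self, instrument_sets):
        fs = f_statistics(instrument_sets["birth"])
        idx = fs.snp_ids.index("rs11187129")
        assert fs.f[idx] == pytest.approx((0.0471726 / 0.008338) ** 2, rel=1e-9)
        assert fs.f[idx] == pytest.approx(32.0, abs=0.05)

    def test_beta_equals_se_gives_unit_f(self):
        i = InstrumentSet.from_arrays([0.05], [0.05], [0.0], [0.1])
        assert f_statistics(i).f[0] == pytest.approx(1.0)

    def test_all_epoch_mean_f_strong(self, instrument_sets):
        for i in instrument_sets.values():
            assert f_statistics(i).mean > 10


class TestSteiger:
    SIZES = dict(n_exp=28_681, n_cases=14_802, n_controls=26_703)

    def test_no_published_snp_filtered(self, instrument_sets):
        for i in instrument_sets.values():
            filtered, removed = steiger_filter(i, **self.SIZES)
            assert removed == []
            assert filtered.n_snp == i.n_snp

    def test_reverse_causation_snp_removed(self):
        i = InstrumentSet.from_arrays(
            beta_exp=[0.05, 0.06], se_exp=[0.01, 0.01],
            beta_out=[0.5, 0.01], se_out=[0.01, 0.02],
            snp_ids=["reverse", "fine"],
        )
        filtered, removed = steiger_filter(i, n_exp=10_000, n_cases=5_000, n_controls=5_000)
        assert removed == ["reverse"]
        assert filtered.snp_ids == ["fine"]
        assert filtered.excluded_snps[-1].exclusion_reason == "steiger"

    def test_borderline_matches_direct_formula(self):
        bx, sx, by, sy = 0.06, 0.01, 0.04, 0.008
        n_exp, cases, controls = 20_000, 8_000, 12_000
        i = InstrumentSet.from_arrays([bx], [sx], [by], [sy])
        _, removed = steiger_filter(i, n_exp, cases, controls)
        n_out = 4 / (1 / cases + 1 / controls)
        zx2, zy2 = (bx / sx) ** 2, (by / sy) ** 2
        expect_removed = zy2 / (zy2 + n_out) > zx2 / (zx2 + n_exp)
        assert bool(removed) is expect_removed

    def test_bad_sample_sizes(self, instrument_sets):
        with pytest.raises(ValueError):
            steiger_filter(instrument_sets["birth"], -1, 10, 10)


class TestLeaveOneOut:
    def test_each_estimate_matches_subset_ivw(self, instrument_sets):
        i = instrument_sets["birth"]
        for omitted, est in leave_one_out(i):
            rest = i.subset([s for s in i.snp_ids if s != omitted])
            direct = ivw(rest, model="mre")
            assert est.beta == pytest.approx(direct.beta, rel=1e-12)
            assert est.se == pytest.approx(direct.se, rel=1e-12)

    def test_birth_outlier_removal_moves_to_null(self, instrument_sets):
        loo = dict(leave_one_out(instrument_sets["birth"]))
        assert loo["rs11187129"].beta == pytest.approx(-0.06, abs=0.01)

    def test_needs_three_snps(self):
        with pytest.raises(ValueError):
            leave_one_out(instr_from([1.0, 2.0]))


class TestMannKendall:
    def test_published_tau_and_p(self):
        # any tie-free length-12 sequence with 12 inversions has S = 42
        seq = [5, 4, 3, 2, 1, 7, 6, 8, 9, 10, 12, 11]
        res = mann_kendall(seq)
        assert res.s == 42
        assert res.tau == pytest.approx(42 / 66, abs=5e-4)
        assert round(res.tau, 3) == 0.636
        assert round(res.pval, 3) == 0.005

    def test_monotone_sequences(self):
        assert mann_kendall([1, 2, 3, 4, 5]).tau == 1.0
        assert mann_kendall([5, 4, 3, 2, 1]).tau == -1.0

    def test_all_equal(self):
        res = mann_kendall([2.0] * 6)
        assert res.tau == 0.0 and res.pval == 1.0

    def test_matches_bruteforce_pair_count(self, rng):
        for _ in range(5):
            v = rng.normal(size=8)
            res = mann_kendall(v)
            s = sum(np.sign(v[j] - i_val) for i in range(8) for j in range(i + 1, 8)
                    for i_val in [v[i]])
            assert res.s == int(s)

    def test_needs_three(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0])


class TestOrScale:
    def test_abstract_or_reconstruction(self):
        # beta -0.20891, se 0.243413 -> OR 0.81 (0.50-1.31)
        from chronomr.estimators import MrEstimate

        est = MrEstimate(method="ivw_mre", n_snp=7, beta=-0.20891, se=0.243413, pval=0.39)
        assert round(est.or_, 2) == 0.81
        assert round(est.or_ci_low, 2) == 0.50
        assert round(est.or_ci_high, 2) == 1.31
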