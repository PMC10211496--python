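import numpy as np
import pytest

from trpwm.align import GapPenalties
from trpwm.ga import GaConfig, optimize
from trpwm.seqio import DnaSequence
from trpwm.significance import calibrate_threshold, local_maxima, scan_periods, z_score

FAST = GaConfig(population=60, stall_generations=30, max_generations=300, seed=4)


def brute_force_maxima(z1, z0, hw):
    """Independent enumeration of the dominance definition with the
    leftmost-plateau tie rule."""
    out = []
    for k in range(len(z1)):
        if not z1[k] > z0:
            continue
        left = z1[max(0, k - hw) : k]
        right = z1[k + 1 : k + hw + 1]
        if any(v >= z1[k] for v in left):
            continue
        if any(v > z1[k] for v in right):
            continue
        out.append(k)
    return out


class TestLocalMaxima:
    def test_single_peak(self):
        assert local_maxima([1, 2, 9, 2, 1], 6, 2) == [2]

    def test_all_below_threshold(self):
        assert local_maxima([1, 2, 3, 2, 1], 6, 2) == []

    def test_plateau_keeps_leftmost(self):
        assert local_maxima([1, 9, 9, 9, 1], 6, 2) == [1]

    def test_agrees_with_enumeration_on_random_vectors(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 500))
            z1 = rng.normal(5, 3, size=m).round(1)  # rounding forces ties
            hw = int(rng.integers(1, 61))
            assert local_maxima(z1, 6.0, hw) == brute_force_maxima(list(z1), 6.0, hw)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            local_maxima([1.0, float("inf")], 0.0)


class TestCalibrateThreshold:
    # published counts from the chromosome-1 vs shuffled-chromosome scan
    REAL = {5.0: 161367, 5.5: 129788, 6.0: 97727, 6.5: 72578, 7.0: 54306}
    RANDOM = {5.0: 33033, 5.5: 10494, 6.0: 2651, 6.5: 681, 7.0: 198}

    def test_reproduces_published_fdr_row(self):
        table = calibrate_threshold(self.REAL, self.RANDOM)
        expected = [20.47, 8.08, 2.71, 0.94, 0.36]
        for got, want in zip(table.fdr_percent(), expected):
            assert got == pytest.approx(want, abs=0.01)  # printed precision

    def test_smallest_z0_below_target_flagged(self):
        table = calibrate_threshold(self.REAL, self.RANDOM, fdr_target=0.03)
        assert table.chosen_z0 == 6.0

    def test_zero_random_hits_gives_zero_fdr(self):
        t = calibrate_threshold({1.0: 10}, {1.0: 0})
        assert t.fdr == (0.0,)

    def test_zero_real_hits_reported_missing(self):
        t = calibrate_threshold({1.0: 0}, {1.0: 5})
        assert t.fdr == (None,)

    def test_fdr_non_increasing_when_counts_are(self):
        t = calibrate_threshold(self.REAL, self.RANDOM)
        vals = [f for f in t.fdr if f is not None]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold({1.0: 5}, {2.0: 5})


class TestZScore:
    def test_null_sequence_z_near_zero(self):
        """A shuffled window scored against its own null ensemble gives Z
        with no systematic excess (|Z| modest)."""
        rng = np.random.default_rng(8)
        seq = DnaSequence("s", "".join(rng.choice(list("ACGT"), 400)))
        res = optimize(seq, 5, "mono", FAST)
        z = z_score(seq, 5, res, replicates=30, seed=9, cfg=FAST)
        assert abs(z) < 6.0

    def test_strong_repeat_much_higher_than_null(self):
        seq = DnaSequence("s", "ATCGATTCGG" * 40)
        res = optimize(seq, 10, "di", FAST)
        z = z_score(seq, 10, res, replicates=30, seed=9, cfg=FAST)
        assert z > 10.0

    def test_replicate_floor(self):
        seq = DnaSequence("s", "ATCG" * 100)
        res = optimize(seq, 4, "mono", FAST)
        with pytest.raises(ValueError):
            z_score(seq, 4, res, replicates=5, seed=1)


class TestScanPeriods:
    def test_rpwm_mode_skips_monte_carlo(self):
        seq = DnaSequence("s", "ATCG" * 100)
        res = scan_periods(seq, (2, 5), "mono", FAST, seed=3)
        assert res.statistic == "v1"
        assert all(np.isnan(z) for z in res.z.values())
        assert res.n_max in res.periods

    def test_di_mode_picks_argmax_z(self):
        seq = DnaSequence("s", "ATCGATTCGG" * 40)
        res = scan_periods(seq, (4, 12), "di", FAST, replicates=20, seed=3)
        assert res.statistic == "z"
        assert res.z[res.n_max] == max(res.z.values())

    def test_empty_range_rejected(self):
        seq = DnaSequence("s", "ATCG" * 100)
        with pytest.raises(ValueError):
            scan_periods(seq, (5, 4), "mono", FAST)


class TestDivergenceResponse:
    def test_median_z_non_increasing_with_divergence(self):
        """Z(10) of the St(x) benchmark decays (stochastically) as copies
        diverge: medians over seeds are monotone down the x grid."""
        from trpwm.synth import TandemSpec, make_st, random_unit

        cfg_kw = dict(population=200, stall_generations=80, max_generations=800)
        medians = []
        for subs in (0, 500, 1000, 2400):
            zs = []
            for seed in range(3):
                seq, _ = make_st(TandemSpec(unit=random_unit(10, 300 + seed), copies=120,
                                            n_substitutions=subs, n_indels=20, seed=seed))
                cfg = GaConfig(seed=seed, **cfg_kw)
                res = optimize(seq, 10, "di", cfg)
                zs.append(z_score(seq, 10, res, replicates=25, seed=seed + 50, cfg=cfg))
            medians.append(np.median(zs))
        assert all(a >= b for a, b in zip(medians, medians[1:]))
        assert medians[0] > 20.0  # perfect tandem is unambiguous


class TestFundamentalPeriod:
    # a strong repeat plateaus Z across its harmonic family; the reported
    # period should be the family's fundamental, not a noise-tied harmonic
    PLATEAU = {2: 14.5, 4: 34.9, 6: 14.0, 8: 32.4, 10: 17.1, 12: 32.2,
               16: 33.8, 20: 35.1}

    @pytest.mark.parametrize("n_max", [4, 8, 12, 16, 20])
    def test_any_plateau_member_resolves_to_fundamental(self, n_max):
        from trpwm.significance import fundamental_period
        assert fundamental_period(self.PLATEAU, n_max, replicates=60) == 4

    def test_sub_period_below_plateau_not_taken(self):
        from trpwm.significance import fundamental_period
        assert fundamental_period({3: 5.0, 7: 4.0, 21: 8.3}, 21) == 21

    def test_no_divisors_returns_argmax(self):
        from trpwm.significance import fundamental_period
        assert fundamental_period({2: 1.0, 5: 9.0}, 5) == 5
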