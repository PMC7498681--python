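"""Tests for the stochastic community simulator."""

import numpy as np
import pandas as pd
import pytest

from phagecoi import (DomainError, EcosystemConfig, assemble_community,
                      daily_lysogen_production, evaluate_community, gut_config,
                      latin_hypercube, lysogeny_probability, marine_config,
                      phage_from_bacteria, simulate_ecosystem)
from phagecoi.calibration import RankAbundanceCurve
from phagecoi.community import CommunitySample, _NOISE_STREAM


class TestLatinHypercube:
    def test_single_sample_inside_range(self):
        pts = latin_hypercube([(1e3, 1e6)], n_samples=1, master_seed=0)
        assert pts.shape == (1, 1)
        assert 1e3 <= pts[0, 0] <= 1e6

    def test_one_sample_per_stratum_every_dimension(self):
        ranges = [(1e4, 1e7), (1e-10, 1e-6), (1.0, 1e3)]
        n = 500
        pts = latin_hypercube(ranges, n, master_seed=3)
        for dim, (lo, hi) in enumerate(ranges):
            logs = np.log10(pts[:, dim])
            strata = np.floor((logs - np.log10(lo)) / (np.log10(hi) - np.log10(lo)) * n)
            strata = np.clip(strata, 0, n - 1).astype(int)
            assert len(np.unique(strata)) == n  # exactly one draw per stratum

    def test_samples_inside_ranges(self):
        ranges = [(3.78e4, 6.75e6), (7.2e-10, 3.7e-7)]
        pts = latin_hypercube(ranges, 1000, master_seed=1)
        for dim, (lo, hi) in enumerate(ranges):
            assert np.all((pts[:, dim] >= lo) & (pts[:, dim] <= hi))

    def test_reproducible(self):
        a = latin_hypercube([(1, 10)], 100, master_seed=5)
        b = latin_hypercube([(1, 10)], 100, master_seed=5)
        np.testing.assert_array_equal(a, b)

    def test_invalid_range_rejected(self):
        with pytest.raises(DomainError):
            latin_hypercube([(10, 1)], 10, master_seed=0)


class TestPhageFromBacteria:
    def test_zero_noise_is_deterministic_power_law(self, marine_cfg):
        cfg = marine_cfg.with_overrides(noise_sd=0.0)
        rng = np.random.default_rng(0)
        value = phage_from_bacteria(1e6, cfg, rng)
        assert value == pytest.approx(10 ** (2.50 + 0.712 * 6), rel=1e-12)

    def test_clamped_into_phage_range(self, gut_cfg):
        rng = np.random.default_rng(99)
        b = 10 ** rng.uniform(np.log10(3.45e5), np.log10(7.6e9), size=5000)
        p = phage_from_bacteria(b, gut_cfg, rng)
        lo, hi = gut_cfg.phage_range
        assert np.all((p >= lo) & (p <= hi))

    def test_rejects_nonpositive(self, marine_cfg):
        with pytest.raises(DomainError):
            phage_from_bacteria(0.0, marine_cfg, np.random.default_rng(0))


class TestAssembleCommunity:
    def test_gut_commitment_is_fifth_of_duplication(self, gut_cfg):
        rng = np.random.default_rng(1)
        sample = assemble_community((1e9, 3e-7, 4.75), gut_cfg, rng)
        assert sample.commitment_time == pytest.approx(0.95)
        assert sample.duplication_time == pytest.approx(4.75)

    def test_gut_range_minimum_matches_table_minimum(self, gut_cfg):
        rng = np.random.default_rng(1)
        sample = assemble_community((1e9, 3e-7, 2.74), gut_cfg, rng)
        assert sample.commitment_time == pytest.approx(0.548)

    def test_marine_time_passes_through(self, marine_cfg):
        rng = np.random.default_rng(1)
        sample = assemble_community((1e6, 1e-8, 808.0), marine_cfg, rng)
        assert sample.commitment_time == pytest.approx(808.0)
        assert sample.duplication_time == pytest.approx(808.0 / 0.2)


def _single_rank_config() -> EcosystemConfig:
    return marine_config().with_overrides(
        phage_curve=RankAbundanceCurve(np.array([1.0]), kind="phage"),
        bacteria_curve=RankAbundanceCurve(np.array([1.0]), kind="bacteria"))


class TestEvaluateCommunity:
    def test_zero_phage_gives_zero_lysogeny(self, marine_cfg):
        sample = CommunitySample(bacteria_total=1e6, phage_total=0.0,
                                 adsorption_rate=1e-8, commitment_time=100.0,
                                 duplication_time=500.0)
        result = evaluate_community(sample, marine_cfg)
        assert result.percent_lysogeny == 0.0
        assert result.total_lysogen_conc == 0.0

    def test_single_rank_reduces_to_core_model(self):
        cfg = _single_rank_config()
        sample = CommunitySample(bacteria_total=2e6, phage_total=1e7,
                                 adsorption_rate=1e-7, commitment_time=100.0,
                                 duplication_time=500.0)
        result = evaluate_community(sample, cfg)
        expected = 100 * lysogeny_probability(1e7 * 1e-7 * 100.0)
        assert result.percent_lysogeny == pytest.approx(expected, rel=1e-12)
        assert result.rank_contributions[0] == pytest.approx(1.0)

    def test_matches_bruteforce_rank_loop(self, gut_cfg):
        sample = CommunitySample(bacteria_total=1e9, phage_total=5e8,
                                 adsorption_rate=3e-7, commitment_time=0.95,
                                 duplication_time=4.75)
        result = evaluate_community(sample, gut_cfg)
        total = 0.0
        for i in range(gut_cfg.n_ranks):
            coi_i = 5e8 * gut_cfg.phage_curve.frequencies[i] * 3e-7 * 0.95
            total += 1e9 * gut_cfg.bacteria_curve.frequencies[i] * lysogeny_probability(coi_i)
        assert result.total_lysogen_conc == pytest.approx(total, rel=1e-12)
        assert result.percent_lysogeny == pytest.approx(100 * total / 1e9, rel=1e-12)

    def test_lysogens_never_exceed_hosts(self, gut_cfg):
        sample = CommunitySample(bacteria_total=7e9, phage_total=1e10,
                                 adsorption_rate=1.2e-6, commitment_time=1.45,
                                 duplication_time=7.27)
        result = evaluate_community(sample, gut_cfg)
        assert np.all(result.lysogen_conc <= result.bacteria_conc)
        assert 0 <= result.percent_lysogeny <= 100

    def test_monotone_in_phage_total(self, gut_cfg):
        base = dict(bacteria_total=1e8, adsorption_rate=3e-7,
                    commitment_time=1.0, duplication_time=5.0)
        low = evaluate_community(CommunitySample(phage_total=1e8, **base), gut_cfg)
        high = evaluate_community(CommunitySample(phage_total=3e8, **base), gut_cfg)
        assert high.percent_lysogeny > low.percent_lysogeny


class TestSimulateEcosystem:
    def test_reproducible_from_master_seed(self, marine_cfg):
        a = simulate_ecosystem(marine_cfg, 50, master_seed=4)
        b = simulate_ecosystem(marine_cfg, 50, master_seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_all_traits_within_configured_ranges(self, marine_sim, marine_cfg):
        lo, hi = marine_cfg.adsorption_range
        assert marine_sim.adsorption_rate.between(lo, hi).all()
        lo, hi = marine_cfg.bacteria_range
        assert marine_sim.bacteria_conc.between(lo, hi).all()
        lo, hi = marine_cfg.phage_range
        assert marine_sim.phage_conc.between(lo, hi).all()
        lo, hi = marine_cfg.time_range
        assert marine_sim.commitment_time.between(lo, hi).all()

    def test_gut_commitment_times_are_scaled_duplications(self, gut_sim, gut_cfg):
        np.testing.assert_allclose(gut_sim.commitment_time,
                                   0.2 * gut_sim.duplication_time, rtol=1e-12)
        lo, hi = gut_cfg.time_range
        assert gut_sim.duplication_time.between(lo, hi).all()

    def test_seed_stability_of_summary_medians(self, gut_cfg):
        """Different seeds give different tables but agreeing medians."""
        a = simulate_ecosystem(gut_cfg, 20_000, master_seed=21)
        b = simulate_ecosystem(gut_cfg, 20_000, master_seed=22)
        assert not np.array_equal(a.bacteria_conc.values, b.bacteria_conc.values)
        med_a = np.median(a.percent_lysogeny)
        med_b = np.median(b.percent_lysogeny)
        assert med_a == pytest.approx(med_b, rel=0.10)

    def test_scalar_path_matches_vectorized_table(self, gut_cfg):
        """The per-community assemble/evaluate path reproduces the vectorized
        simulation row by row when fed the same raw draws and noise stream."""
        n, seed = 25, 13
        table = simulate_ecosystem(gut_cfg, n, master_seed=seed)
        raw = latin_hypercube([gut_cfg.bacteria_range, gut_cfg.adsorption_range,
                               gut_cfg.time_range], n, master_seed=seed)
        noise_rng = np.random.default_rng(np.random.SeedSequence([seed, _NOISE_STREAM]))
        for i in range(n):
            sample = assemble_community(raw[i], gut_cfg, noise_rng, sample_index=i)
            result = evaluate_community(sample, gut_cfg)
            row = table.iloc[i]
            assert row.phage_conc == pytest.approx(sample.phage_total, rel=1e-12)
            assert row.percent_lysogeny == pytest.approx(result.percent_lysogeny, rel=1e-12)
            assert row.coi_rank1 == pytest.approx(result.coi[0], rel=1e-12)
            assert row.contribution_rank2 == pytest.approx(
                result.rank_contributions[1], rel=1e-10)

    def test_contributions_non_increasing(self, gut_sim):
        active = gut_sim[gut_sim.percent_lysogeny > 0]
        assert (active.contribution_rank1 >= active.contribution_rank2).all()
        assert (active.contribution_rank2 >= active.contribution_rank3).all()


class TestDailyLysogenProduction:
    def test_zero_percent_gives_zero(self):
        assert daily_lysogen_production(0.0, 1.7e9, 400, 4.75) == 0.0

    def test_gut_median_estimate(self):
        value = daily_lysogen_production(47.8, 1.7e9, 400, 4.75)
        assert value == pytest.approx(1.64e12, rel=0.01)

    def test_linear_in_volume(self):
        one = daily_lysogen_production(10, 1e9, 400, 5)
        assert daily_lysogen_production(10, 1e9, 800, 5) == pytest.approx(2 * one)

    def test_nonpositive_duplication_rejected(self):
        with pytest.raises(DomainError):
            daily_lysogen_production(10, 1e9, 400, 0.0)


class TestEcosystemConfigValidation:
    def test_bad_range_rejected(self):
        with pytest.raises(DomainError):
            marine_config().with_overrides(bacteria_range=(1e6, 1e4))

    def test_bad_time_kind_rejected(self):
        from phagecoi.exceptions import UsageError
        with pytest.raises(UsageError):
            marine_config().with_overrides(time_kind="generation")
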