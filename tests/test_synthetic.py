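"""Synthetic replication landscapes, populations and measurement noise."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from repliq.copynumber import ProbeSpec, baseline_normalize, replication_index
from repliq.droplet import estimate_concentration, replicate_ci
from repliq.simulate import (
    AlleleModel,
    Asynchronous,
    Origin,
    ReplicationModel,
    SortedS,
    Synchronized,
    asynchronous_dynamic_range,
    copy_number_profile,
    simulate_allele_experiment,
    simulate_ddpcr_experiment,
    simulate_droplets,
    simulate_screen,
    simulate_sortseq_counts,
    trep_profile,
)


class TestTrepProfile:
    def test_fork_arrival_arithmetic(self):
        # origin at 100 kb firing at 10 min, forks at 1 kb/min: 105 kb at 15 min
        model = ReplicationModel(200_000, (Origin(100_000, 10.0),), fork_speed_kb_min=1.0)
        assert trep_profile(model, [105_000.0])[0] == pytest.approx(15.0)

    def test_origin_position_replicates_at_firing_time(self):
        model = ReplicationModel(200_000, (Origin(100_000, 10.0),), fork_speed_kb_min=1.0)
        assert trep_profile(model, [100_000.0])[0] == pytest.approx(10.0)

    def test_two_origin_brute_force_oracle(self, chromosome_model):
        grid = np.arange(0.0, chromosome_model.chrom_length, 1000.0)
        trep = trep_profile(chromosome_model, grid)
        v = chromosome_model.fork_speed_kb_min * 1000.0
        brute = np.minimum.reduce(
            [
                o.firing_time + np.abs(grid - o.position) / v
                for o in chromosome_model.origins
            ]
        )
        np.testing.assert_allclose(trep, brute)

    def test_inefficient_origin_delays_median(self):
        # a 50%-efficient origin leaves half the cells to passive forks,
        # so the median at the origin is later than its firing time
        model = ReplicationModel(
            200_000,
            (Origin(50_000, 5.0, efficiency=0.5), Origin(150_000, 10.0)),
            fork_speed_kb_min=1.0,
        )
        t_origin = trep_profile(model, [50_000.0], seed=0)[0]
        assert t_origin > 5.0

    def test_seeded_reproducibility(self):
        model = ReplicationModel(
            200_000, (Origin(50_000, 5.0, efficiency=0.7),), fork_speed_kb_min=1.0
        )
        a = trep_profile(model, [60_000.0, 80_000.0], seed=11)
        b = trep_profile(model, [60_000.0, 80_000.0], seed=11)
        np.testing.assert_array_equal(a, b)

    def test_no_origins_rejected(self):
        model = ReplicationModel(200_000, (), fork_speed_kb_min=1.0)
        with pytest.raises(ValueError, match="origin"):
            trep_profile(model, [1000.0])


class TestCopyNumberProfile:
    def test_pre_s_population_unreplicated(self, chromosome_model):
        cns = copy_number_profile(
            chromosome_model, Synchronized(-20.0, 0.5), [50_000.0, 200_000.0]
        )
        np.testing.assert_allclose(cns, 1.0, atol=1e-6)

    def test_post_s_population_fully_replicated(self, chromosome_model):
        cns = copy_number_profile(
            chromosome_model, Synchronized(100.0, 0.5), [50_000.0, 200_000.0]
        )
        np.testing.assert_allclose(cns, 2.0, atol=1e-6)

    def test_asynchronous_dynamic_range_is_one_plus_s_fraction(self, chromosome_model):
        # 20% S-phase cells, no G2: range exactly 1 to 1.2
        grid = np.arange(0.0, chromosome_model.chrom_length, 1000.0)
        cns = copy_number_profile(chromosome_model, Asynchronous(0.2), grid)
        assert cns.min() == pytest.approx(1.0, abs=1e-12)
        assert cns.max() == pytest.approx(1.2, abs=1e-12)
        assert asynchronous_dynamic_range(Asynchronous(0.2)) == (1.0, 1.2)

    @pytest.mark.parametrize(
        "population",
        [
            Synchronized(20.0, 3.0),
            Synchronized(20.0, 0.0),
            SortedS(),
            SortedS(0.0, 0.0),
            Asynchronous(0.2, 0.1),
        ],
    )
    def test_bounds_respected_in_all_modes(self, chromosome_model, population):
        grid = np.arange(0.0, chromosome_model.chrom_length, 2000.0)
        cns = copy_number_profile(chromosome_model, population, grid)
        assert np.all(cns >= 1.0 - 1e-9) and np.all(cns <= 2.0 + 1e-9)

    def test_sorted_gate_contamination_compresses_range(self, chromosome_model):
        grid = np.arange(0.0, chromosome_model.chrom_length, 2000.0)
        clean = copy_number_profile(chromosome_model, SortedS(0.0, 0.0), grid)
        dirty = copy_number_profile(chromosome_model, SortedS(0.05, 0.05), grid)
        assert dirty.min() == pytest.approx(1.0)
        assert dirty.max() < clean.max() == pytest.approx(2.0)


class TestSimulateDroplets:
    def test_zero_concentration_gives_no_positives(self):
        assert simulate_droplets(0.0, seed=3).n_positive == 0

    def test_positive_fraction_matches_binomial_expectation(self, rng):
        fractions = np.array(
            [simulate_droplets(1000.0, seed=rng).fraction_positive for _ in range(1000)]
        )
        expected = 1.0 - math.exp(-1.0)
        se = fractions.std(ddof=1) / math.sqrt(fractions.size)
        assert abs(fractions.mean() - expected) < 3 * se

    @pytest.mark.parametrize("lam", [0.11, 5.73])
    def test_round_trip_estimation_unbiased(self, lam, rng):
        conc_true = lam * 1000.0
        estimates = np.array(
            [
                estimate_concentration(simulate_droplets(conc_true, seed=rng)).concentration
                for _ in range(1500)
            ]
        )
        se = estimates.std(ddof=1) / math.sqrt(estimates.size)
        assert abs(estimates.mean() - conc_true) < 3 * se

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            simulate_droplets(-1.0)


class TestSimulateDdpcrExperiment:
    def test_flat_copy_numbers_mutually_consistent(self):
        wells = simulate_ddpcr_experiment({"a": 1.0, "b": 1.0, "c": 1.0}, seed=5)
        summaries = {}
        for pid in ("a", "b", "c"):
            reps = [estimate_concentration(w) for w in wells if w.probe_id == pid]
            summaries[pid] = replicate_ci(reps)
        for pid, s in summaries.items():
            others = [summaries[o].mean for o in summaries if o != pid]
            assert s.ci_low <= np.mean(others) <= s.ci_high

    def test_non_replicating_integer_ratios_recovered(self):
        # G2 diploid with unique/duplicated/triplicated probes: 1:2:3 within 2%
        probes = [
            ProbeSpec("unique", "chrT", 1000, 1100, copies_per_haploid=1),
            ProbeSpec("dup", "chrT", 2000, 2100, copies_per_haploid=2),
            ProbeSpec("tri", "chrT", 3000, 3100, copies_per_haploid=3),
        ]
        wells = simulate_ddpcr_experiment(
            {p.probe_id: 1.0 for p in probes}, probes=probes, seed=6
        )
        concs = {
            pid: np.mean(
                [estimate_concentration(w).concentration for w in wells if w.probe_id == pid]
            )
            for pid in ("unique", "dup", "tri")
        }
        values = {v.probe_id: v.value for v in baseline_normalize(concs, probes)}
        assert values["unique"] == pytest.approx(1.0, rel=0.02)
        assert values["dup"] == pytest.approx(2.0, rel=0.02)
        assert values["tri"] == pytest.approx(3.0, rel=0.02)

    def test_mid_s_early_probe_doubles_late_probe(self, chromosome_model):
        mids = {"early": 50_000.0, "late": 200_000.0}
        cns = copy_number_profile(
            chromosome_model, Synchronized(20.0, 3.0), list(mids.values())
        )
        wells = simulate_ddpcr_experiment(dict(zip(mids, cns)), seed=7)
        concs = {
            pid: np.mean(
                [estimate_concentration(w).concentration for w in wells if w.probe_id == pid]
            )
            for pid in mids
        }
        assert concs["early"] / concs["late"] == pytest.approx(2.0, rel=0.05)

    def test_saturating_occupancy_warns(self):
        with pytest.warns(UserWarning, match="quantifiable"):
            simulate_ddpcr_experiment({"a": 1.0}, base_concentration=7000.0, seed=8)


class TestSimulateSortseqCounts:
    def test_poisson_limit_cv(self, rng):
        counts = simulate_sortseq_counts(
            np.ones(10_000), mean_depth=1000.0, overdispersion=0.0, seed=rng
        )
        cv = counts.data["nonrep"].std() / counts.data["nonrep"].mean()
        assert cv == pytest.approx(1.0 / math.sqrt(1000.0), rel=0.1)

    def test_default_calibration_five_percent_cv(self, rng):
        # ~5% CV at 1000 reads/bin with the default overdispersion
        counts = simulate_sortseq_counts(np.ones(10_000), mean_depth=1000.0, seed=rng)
        cv = counts.data["nonrep"].std() / counts.data["nonrep"].mean()
        assert abs(cv - 0.05) < 0.005

    def test_copy_number_doubles_expected_depth(self, rng):
        cn = np.concatenate([np.ones(5000), np.full(5000, 2.0)])
        counts = simulate_sortseq_counts(cn, mean_depth=1000.0, seed=rng)
        rep = counts.data["rep"].to_numpy()
        assert rep[5000:].mean() / rep[:5000].mean() == pytest.approx(2.0, rel=0.02)


class TestSimulateAlleleExperiment:
    @staticmethod
    def model(origins):
        return ReplicationModel(400_000, origins, fork_speed_kb_min=1.5)

    def test_identical_haplotypes_indistinguishable(self):
        from repliq.copynumber import allele_delay

        origins = (Origin(100_000, 10.0), Origin(300_000, 20.0))
        alleles = AlleleModel(self.model(origins), self.model(origins))
        probes = [
            ProbeSpec("a_probe", "chrS", 99_900, 100_100, allele_tag="A"),
            ProbeSpec("b_probe", "chrS", 99_900, 100_100, allele_tag="B"),
        ]
        wells = simulate_allele_experiment(alleles, SortedS(), probes, seed=9)
        reps = {
            pid: [estimate_concentration(w).concentration for w in wells if w.probe_id == pid]
            for pid in ("a_probe", "b_probe")
        }
        res = allele_delay(reps["a_probe"], reps["b_probe"])
        assert not res.significant

    def test_deleted_origin_lowers_mutant_copy_number(self):
        a = self.model((Origin(100_000, 10.0), Origin(300_000, 20.0)))
        b = self.model((Origin(300_000, 20.0),))
        probes = [
            ProbeSpec("a_probe", "chrS", 99_900, 100_100, allele_tag="A"),
            ProbeSpec("b_probe", "chrS", 99_900, 100_100, allele_tag="B"),
        ]
        wells = simulate_allele_experiment(
            AlleleModel(a, b), SortedS(0.0, 0.0), probes, seed=10
        )
        conc = {
            pid: np.mean(
                [estimate_concentration(w).concentration for w in wells if w.probe_id == pid]
            )
            for pid in ("a_probe", "b_probe")
        }
        assert conc["b_probe"] < conc["a_probe"]

    def test_pan_allelic_probe_sums_alleles(self):
        a = self.model((Origin(100_000, 10.0), Origin(300_000, 20.0)))
        b = self.model((Origin(300_000, 20.0),))
        probes = [
            ProbeSpec("a_probe", "chrS", 99_900, 100_100, allele_tag="A"),
            ProbeSpec("b_probe", "chrS", 99_900, 100_100, allele_tag="B"),
            ProbeSpec("pan_probe", "chrS", 99_900, 100_100),
        ]
        wells = simulate_allele_experiment(
            AlleleModel(a, b), SortedS(), probes, n_replicates=6, seed=11
        )
        conc = {
            pid: np.mean(
                [estimate_concentration(w).concentration for w in wells if w.probe_id == pid]
            )
            for pid in ("a_probe", "b_probe", "pan_probe")
        }
        assert conc["pan_probe"] == pytest.approx(
            conc["a_probe"] + conc["b_probe"], rel=0.02
        )

    def test_unmapped_allele_tag_rejected(self):
        origins = (Origin(100_000, 10.0),)
        alleles = AlleleModel(self.model(origins), self.model(origins))
        probes = [ProbeSpec("p", "chrS", 99_900, 100_100, allele_tag="C")]
        with pytest.raises(ValueError, match="allele tag"):
            simulate_allele_experiment(alleles, SortedS(), probes, seed=12)


class ScreenFixture:
    """Wild type vs mutants delaying the mid-chromosome origin."""

    model = ReplicationModel(
        600_000,
        (Origin(100_000, 5.0), Origin(300_000, 20.0), Origin(560_000, 38.0)),
        fork_speed_kb_min=5.0,
    )
    probes = [
        ProbeSpec("early_ctrl", "chrS", 99_900, 100_100, role="early_control"),
        ProbeSpec("late_ctrl", "chrS", 449_900, 450_100, role="late_control"),
        ProbeSpec("target_left", "chrS", 294_900, 295_100),
        ProbeSpec("target_right", "chrS", 304_900, 305_100),
    ]

    @classmethod
    def indices(cls, strains):
        out = {}
        for name, wells in strains.items():
            conc = {
                pid: np.mean(
                    [
                        estimate_concentration(w).concentration
                        for w in wells
                        if w.probe_id == pid
                    ]
                )
                for pid in (p.probe_id for p in cls.probes)
            }
            out[name] = {
                pid: replication_index(conc[pid], conc["early_ctrl"], conc["late_ctrl"])
                for pid in conc
            }
        return out


class TestSimulateScreen:
    def test_zero_delay_mutant_within_wildtype_ci(self):
        strains = simulate_screen(
            ScreenFixture.model, {"null_mutant": 0.0}, ScreenFixture.probes,
            target_position=300_000.0, seed=13,
        )
        ri = ScreenFixture.indices(strains)
        assert ri["null_mutant"]["target_left"] == pytest.approx(
            ri["wt"]["target_left"], abs=0.05
        )

    def test_delayed_mutant_raises_target_index_only(self):
        strains = simulate_screen(
            ScreenFixture.model, {"slow": 8.0}, ScreenFixture.probes,
            target_position=300_000.0, seed=14,
        )
        ri = ScreenFixture.indices(strains)
        for pid in ("target_left", "target_right"):
            assert ri["slow"][pid] > ri["wt"][pid] + 0.05
        # controls define the index scale in every strain
        for strain in ("wt", "slow"):
            assert ri[strain]["early_ctrl"] == pytest.approx(0.0)
            assert ri[strain]["late_ctrl"] == pytest.approx(1.0)

    def test_recovered_indices_rank_injected_delays(self):
        # delay steps (3 min ~ 0.07 copy-number units here) sit at the
        # resolution limit of 3-replicate ddPCR, so ordering must still hold
        delays = {"m1": 3.0, "m2": 6.0, "m3": 9.0, "m4": 12.0, "m5": 15.0}
        strains = simulate_screen(
            ScreenFixture.model, delays, ScreenFixture.probes,
            target_position=300_000.0, seed=15,
        )
        ri = ScreenFixture.indices(strains)
        recovered = [ri[m]["target_left"] for m in delays]
        rho = spearmanr(recovered, list(delays.values())).statistic
        assert rho >= 0.95

    def test_deterministic_given_seed(self):
        kwargs = dict(
            mutants={"m": 4.0}, probes=ScreenFixture.probes,
            target_position=300_000.0, seed=16,
        )
        a = simulate_screen(ScreenFixture.model, **kwargs)
        b = simulate_screen(ScreenFixture.model, **kwargs)
        assert a == b
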