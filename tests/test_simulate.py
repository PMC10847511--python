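import numpy as np
import pandas as pd
import pytest

from hrdscreen.scars import compute_hrd_score
from hrdscreen.simulate import (
    CohortConfig,
    PackingError,
    ScarEventRates,
    direction_recovery_rate,
    plant_scar_events,
    simulate_cohort,
    simulate_null_family,
    simulation_genome,
    write_cohort,
)

from oracles import bruteforce_loh, bruteforce_lst, bruteforce_tai

MB = 1_000_000

FAST_NULL = CohortConfig(
    n_samples=40,
    auc_effect=0.0,
    assay_categories=("Platinum", "PARP inhibitor"),
    n_assays_per_class=2,
    seed=11,
)


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortConfig(n_samples=60, seed=42))


class TestEventGrammar:
    @pytest.mark.parametrize("counts", [(0, 0, 0), (1, 0, 0), (0, 1, 0),
                                        (0, 0, 1), (2, 1, 3), (4, 3, 5)])
    def test_planted_counts_recovered_exactly(self, counts):
        genome = simulation_genome()
        rng = np.random.default_rng(counts)
        profile = plant_scar_events("S1", counts, genome, rng)
        result = compute_hrd_score(profile, genome)
        assert (result.tai, result.lst, result.loh) == counts
        # and the independent enumerators agree
        assert bruteforce_tai(profile, genome) == counts[0]
        assert bruteforce_lst(profile, genome) == counts[1]
        assert bruteforce_loh(profile, genome) == counts[2]

    def test_too_many_telomeric_events_raise(self, arms):
        rng = np.random.default_rng(0)
        with pytest.raises(PackingError, match="larger genome"):
            plant_scar_events("S1", (50, 0, 0), arms, rng)

    def test_overfull_genome_raises(self, arms):
        rng = np.random.default_rng(0)
        with pytest.raises(PackingError):
            plant_scar_events("S1", (0, 20, 20), arms, rng)


class TestCohort:
    def test_ledger_matches_scorer_for_every_sample(self, cohort):
        from hrdscreen.scars import score_cohort

        scored = score_cohort(cohort.profiles, cohort.arms)
        merged = scored.merge(cohort.ledger, on="sample_id", validate="1:1")
        assert (merged["TAI"] == merged["tai"]).all()
        assert (merged["LST"] == merged["lst"]).all()
        assert (merged["LOH"] == merged["loh"]).all()
        assert (merged["HRD_score"] == merged["hrd_score"]).all()

    def test_same_seed_reproduces_files_byte_for_byte(self, tmp_path):
        cfg = CohortConfig(n_samples=15, seed=9)
        paths_a = write_cohort(simulate_cohort(cfg), tmp_path / "a")
        paths_b = write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortConfig(n_samples=15, seed=1))
        b = simulate_cohort(CohortConfig(n_samples=15, seed=2))
        assert not a.ledger.equals(b.ledger)

    def test_adding_assays_does_not_perturb_segments(self):
        few = simulate_cohort(CohortConfig(n_samples=10, seed=3,
                                           n_assays_per_class=1))
        many = simulate_cohort(CohortConfig(n_samples=10, seed=3,
                                            n_assays_per_class=3))
        assert few.profiles == many.profiles
        assert few.snv_table.equals(many.snv_table)

    def test_snv_mixture_weight_tracks_hrd_status(self, cohort):
        by_status = cohort.ledger.groupby("hrd")["sig3_weight"].mean()
        cfg = cohort.config
        assert by_status.get(True, cfg.sig3_weight_hrd) == cfg.sig3_weight_hrd
        assert by_status[False] == cfg.sig3_weight_non_hrd

    def test_methylated_samples_have_silencing_evidence(self, cohort):
        meth = cohort.ledger.set_index("sample_id")["brca1_methylated"]
        betas = cohort.methylation_table.set_index("sample")
        for sid, flag in meth.items():
            if flag:
                assert betas.loc[sid].min() > 0.3
        if meth.any():
            methylated_expr = cohort.expression[meth[meth].index]
            unmethylated_expr = cohort.expression[meth[~meth].index]
            assert methylated_expr.max() < unmethylated_expr.min()

    def test_affected_assays_carry_planted_beta(self, cohort):
        truth = cohort.assay_truth
        affected = truth[truth["category"].isin(cohort.config.affected_categories)]
        assert (affected["beta"] == cohort.config.auc_effect).all()
        rest = truth[~truth["category"].isin(cohort.config.affected_categories)]
        assert (rest["beta"] == 0).all()

    def test_written_files_round_trip_through_readers(self, tmp_path, cohort):
        from hrdscreen.association import read_assays
        from hrdscreen.genome import load_arm_table, read_segment_table
        from hrdscreen.spectrum import read_snv_table

        paths = write_cohort(cohort, tmp_path)
        arms = load_arm_table(paths["arms"])
        profiles = read_segment_table(paths["segments"], arms)
        assert profiles == cohort.profiles
        records = read_snv_table(paths["snvs"])
        assert len(records) == len(cohort.snv_table)
        assays = read_assays(paths["assays"], paths["auc"])
        assert [a.assay_id for a in assays] == [a.assay_id for a in cohort.assays]

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(hrd_prevalence=1.5)
        with pytest.raises(ValueError):
            CohortConfig(scar_event_rates=ScarEventRates(hrd=(-1, 0, 0)))


class TestNullFamily:
    def test_zero_rate_null_cohort_scores_zero(self):
        cfg = CohortConfig(
            n_samples=12,
            seed=5,
            auc_effect=0.0,
            scar_event_rates=ScarEventRates(hrd=(0, 0, 0), non_hrd=(0, 0, 0)),
        )
        cohort = simulate_cohort(cfg)
        assert (cohort.ledger["hrd_score"] == 0).all()
        from hrdscreen.scars import score_cohort

        assert (score_cohort(cohort.profiles, cohort.arms)["HRD_score"] == 0).all()

    def test_single_replicate_fwer_is_binary(self):
        result = simulate_null_family(FAST_NULL, 1)
        assert result.fwer in (0.0, 1.0)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            simulate_null_family(FAST_NULL, 0)

    def test_nonzero_effect_rejected(self):
        cfg = CohortConfig(n_samples=10, auc_effect=0.5)
        with pytest.raises(ValueError, match="auc_effect"):
            simulate_null_family(cfg, 2)

    def test_small_null_family_roughly_calibrated(self):
        result = simulate_null_family(FAST_NULL, 25)
        assert result.total_tests == 25 * 4
        assert result.type_i_error < 0.25  # loose sanity bound at this size
        assert 0.0 <= result.fwer <= 1.0


class TestDirectionRecovery:
    def test_planted_positive_effect_recovered(self):
        cfg = CohortConfig(
            n_samples=100,
            auc_effect=0.5,
            assay_categories=("Platinum", "PARP inhibitor", "Metabolism"),
            n_assays_per_class=1,
            seed=13,
        )
        result = direction_recovery_rate(cfg, 5)
        assert result.n_affected_assays == 2
        assert result.recovery_rate >= 0.8
        assert result.mean_rho > 0

    def test_negative_effect_recovered_with_negative_direction(self):
        cfg = CohortConfig(
            n_samples=100,
            auc_effect=-0.5,
            assay_categories=("Platinum",),
            n_assays_per_class=1,
            seed=13,
        )
        result = direction_recovery_rate(cfg, 5)
        assert result.recovery_rate >= 0.8
        assert result.mean_rho < 0

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            direction_recovery_rate(FAST_NULL, 2)
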