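from __future__ import annotations

import numpy as np
import pytest

from tcrvax.expansion import ExpansionConfig, call_expanded
from tcrvax.expansion import test_expansion as compute_expansion
from tcrvax.repertoire_io import Clonotype, Condition, MKRAS_ANTIGENS
from tcrvax.synthetic import (
    SimConfig,
    build_cohort_specs,
    simulate_cohort,
    simulate_elispot,
    simulate_repertoire,
    simulate_survival,
    toy_study_config,
)

SMALL = SimConfig(
    n_subjects=3,
    n_clonotypes=2000,
    depth=30_000,
    n_spiked_per_antigen=8,
    spike_freq_floor=0.003,
    public_clone_count=2,
    seed=5,
)


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(SMALL)


class TestDeterminism:
    def test_same_seed_identical_repertoires(self):
        spec1 = build_cohort_specs(SMALL)[0]
        spec2 = build_cohort_specs(SMALL)[0]
        r1 = simulate_repertoire(SMALL, Condition.G12V, spec1)
        r2 = simulate_repertoire(SMALL, Condition.G12V, spec2)
        assert r1.counts == r2.counts

    def test_same_seed_identical_elispot(self):
        t1, truth1 = simulate_elispot(SMALL, n_subjects=4)
        t2, truth2 = simulate_elispot(SMALL, n_subjects=4)
        assert t1.equals(t2) and truth1 == truth2

    def test_different_seeds_differ(self):
        other = SimConfig(**{**SMALL.__dict__, "seed": 6})
        r1 = simulate_repertoire(SMALL, Condition.G12V, build_cohort_specs(SMALL)[0])
        r2 = simulate_repertoire(other, Condition.G12V, build_cohort_specs(other)[0])
        assert r1.counts != r2.counts


class TestTruthConsistency:
    def test_truth_subsets_of_emitted(self, small_cohort):
        cohort, truth = small_cohort
        for subj, per_antigen in truth.expanded.items():
            for antigen, clones in per_antigen.items():
                rep = cohort[subj][Condition(antigen)]
                assert all(ct in rep for ct in clones)
            for ct in truth.baseline_present[subj]:
                assert ct in cohort[subj][Condition.BASELINE]
            for ct in truth.tumor_planted[subj]:
                assert ct in cohort[subj][Condition.TUMOR_TISSUE]

    def test_cross_reactive_iff_multiple_antigens(self, small_cohort):
        _, truth = small_cohort
        for subj, assignments in truth.antigen_assignments.items():
            expected = {ct for ct, ags in assignments.items() if len(ags) >= 2}
            assert truth.cross_reactive[subj] == expected

    def test_public_clone_count(self, small_cohort):
        _, truth = small_cohort
        assert len(truth.public) == SMALL.public_clone_count
        assert all(len(hosts) >= 2 for hosts in truth.public.values())

    def test_no_cross_reactive_when_fraction_zero(self):
        cfg = SimConfig(**{**SMALL.__dict__, "cross_reactive_fraction": 0.0})
        _, truth = simulate_cohort(cfg)
        assert all(not s for s in truth.cross_reactive.values())

    def test_baseline_excludes_non_designated_spikes(self, small_cohort):
        cohort, truth = small_cohort
        for subj, assignments in truth.antigen_assignments.items():
            baseline = cohort[subj][Condition.BASELINE]
            designated = truth.baseline_designated[subj]
            for ct in assignments:
                if ct not in designated:
                    assert ct not in baseline


class TestSpikeBehaviour:
    def test_spiked_clone_odds_ratio_near_fold(self, small_cohort):
        cohort, truth = small_cohort
        ors = []
        for subj, per_antigen in truth.expanded.items():
            ref = cohort[subj][Condition.VEHICLE_ONLY]
            for antigen, clones in per_antigen.items():
                rep = cohort[subj][Condition(antigen)]
                for ct in clones:
                    c_ref = ref.counts.get(ct, 0)
                    if c_ref:
                        ors.append(rep.counts[ct] / c_ref)
        med = float(np.median(ors))
        assert 0.5 * SMALL.spike_fold < med < 1.5 * SMALL.spike_fold

    def test_null_spike_fold_gives_calibrated_calls(self):
        cfg = SimConfig(**{**SMALL.__dict__, "spike_fold": 1.0, "n_subjects": 2})
        cohort, _ = simulate_cohort(cfg, include_tumor=False)
        config = ExpansionConfig()
        n_tests = n_q_hits = 0
        for subj, reps in cohort.items():
            ref = reps[Condition.VEHICLE_ONLY]
            for antigen in MKRAS_ANTIGENS:
                table = compute_expansion(reps[antigen], ref, config)
                n_tests += len(table)
                n_q_hits += int((table["q_value"] <= config.q_max).sum())
        assert n_q_hits / n_tests <= config.q_max

    def test_excessive_spike_mass_raises(self):
        cfg = SimConfig(
            **{
                **SMALL.__dict__,
                "n_spiked_per_antigen": 60,
                "spike_freq_floor": 0.6,
            }
        )
        with pytest.raises(ValueError, match="spike mass"):
            build_cohort_specs(cfg)


class TestEndToEndRecovery:
    def test_expansion_calls_recover_truth(self, small_cohort):
        cohort, truth = small_cohort
        config = ExpansionConfig()
        tp = fp = fn = 0
        for subj, reps in cohort.items():
            ref = reps[Condition.VEHICLE_ONLY]
            for antigen in MKRAS_ANTIGENS:
                table = call_expanded(compute_expansion(reps[antigen], ref, config), config)
                called = {
                    Clonotype(r.v_gene, r.cdr3_aa)
                    for r in table[table["expanded"]].itertuples(index=False)
                }
                true_set = truth.expanded[subj][str(antigen)]
                tp += len(called & true_set)
                fp += len(called - true_set)
                fn += len(true_set - called)
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.9 and precision >= 0.9


class TestElispotGenerator:
    def test_responders_detectable(self):
        sfu, truth = simulate_elispot(SimConfig(seed=8), responder_fraction=1.0, n_subjects=10)
        assert all(truth.values())
        means = sfu.groupby(["subject_id", "week", "stimulation"])["sfu"].mean()
        assert means.loc[("S01", 8.0, "G12V")] > means.loc[("S01", 0.0, "G12V")]

    def test_table_shape(self):
        sfu, _ = simulate_elispot(SMALL, weeks=(0, 8), n_subjects=2, n_replicates=3)
        # 2 subjects x 2 weeks x 8 stimulations x 3 replicates
        assert len(sfu) == 2 * 2 * 8 * 3


class TestSurvivalGenerator:
    def test_no_censoring_all_events(self):
        recs = simulate_survival(50, 0.2, 1.0, censor_rate=0.0, seed=1)
        assert all(r.event for r in recs)

    def test_median_ratio_tracks_hazard_ratio(self):
        recs = simulate_survival(4000, 0.2, 1.0, seed=2)
        low = np.median([r.time for r in recs if r.group == "low"])
        high = np.median([r.time for r in recs if r.group == "high"])
        assert low / high == pytest.approx(5.0, rel=0.15)


def test_toy_config_is_fast_and_valid(toy_cohort):
    cohort, truth = toy_cohort
    assert len(cohort) == toy_study_config().n_subjects
    for reps in cohort.values():
        assert Condition.VEHICLE_ONLY in reps and Condition.BASELINE in reps
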