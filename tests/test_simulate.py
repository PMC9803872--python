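"""Generators: determinism, ledger fidelity, statistical consistency."""

from collections import Counter

import numpy as np
import pytest

from mcprofiler.classification import classify_profile, default_prototypes
from mcprofiler.discovery import Epilocus, build_candidate_epiloci, index_cpg_sites
from mcprofiler.multisample import compare_conditions, stability_call, transition_table
from mcprofiler.profiles import MCProfile, jsd, profile_from_counts
from mcprofiler.simulate import (
    make_reference,
    simulate_allelic_locus,
    simulate_condition_pair,
    simulate_epiallele_counts,
    simulate_sample_set,
)


D3 = MCProfile((0.5, 0, 0, 0, 0.5))
D4 = MCProfile((1 / 16, 4 / 16, 6 / 16, 4 / 16, 1 / 16))


class TestEpialleleCounts:
    def test_support_restriction(self):
        counts = simulate_epiallele_counts(D3, coverage=200, seed=0)
        assert set(counts) <= {"0000", "1111"}
        assert sum(counts.values()) == 200

    def test_law_of_large_numbers(self):
        counts = simulate_epiallele_counts(D4, coverage=100_000, seed=1)
        assert jsd(profile_from_counts(counts), D4) < 0.02

    def test_fixed_seed_is_deterministic(self):
        a = simulate_epiallele_counts(D4, 500, seed=9)
        b = simulate_epiallele_counts(D4, 500, seed=9)
        assert a == b

    def test_coverage_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_epiallele_counts(D4, 0)


class TestAllelicLocus:
    def test_imprinting_archetype_is_bimodal(self, prototypes):
        joint, per_a, per_b = simulate_allelic_locus(
            MCProfile((1, 0, 0, 0, 0)), MCProfile((0, 0, 0, 0, 1)),
            mix=0.5, coverage=4000, seed=2,
        )
        assert set(joint) == {"0000", "1111"}
        label = classify_profile(profile_from_counts(joint), prototypes).label
        assert label == "D3"
        d = jsd(profile_from_counts(per_a), profile_from_counts(per_b))
        assert d == pytest.approx(1.0)

    def test_degenerate_mix_rejected(self):
        with pytest.raises(ValueError):
            simulate_allelic_locus(D3, D4, mix=1.0)

    def test_joint_is_sum_of_alleles(self):
        joint, per_a, per_b = simulate_allelic_locus(D3, D4, 0.3, 500, seed=4)
        assert joint == per_a + per_b


class TestSampleSet:
    def _truths(self, n=40):
        protos = list(default_prototypes().values())
        return {
            Epilocus("chrS", (i * 200, i * 200 + 10, i * 200 + 20, i * 200 + 30)): protos[i % 5]
            for i in range(n)
        }

    def test_ledger_records_draws_verbatim(self):
        truths = self._truths(10)
        ledger = simulate_sample_set(truths, n_samples=2, coverage=60, seed=5)
        assert set(ledger.sample_counts) == {"sample_1", "sample_2"}
        for tables in ledger.sample_counts.values():
            for epi, counts in tables.items():
                assert sum(counts.values()) == 60
        # draws from D1 truth only ever produce the all-zero pattern
        d1_epi = [e for e, t in truths.items() if t.abundances[0] == 1.0]
        for tables in ledger.sample_counts.values():
            for e in d1_epi:
                assert set(tables[e]) == {"0000"}

    def test_reruns_are_identical(self):
        truths = self._truths(6)
        a = simulate_sample_set(truths, 3, 50, seed=21)
        b = simulate_sample_set(truths, 3, 50, seed=21)
        assert a.sample_counts == b.sample_counts

    def test_high_coverage_consensus_recovers_truth(self):
        truths = self._truths(10)
        ledger = simulate_sample_set(truths, 3, coverage=10_000, seed=6)
        for epi, truth in truths.items():
            profiles = [
                profile_from_counts(ledger.sample_counts[s][epi])
                for s in ledger.sample_counts
            ]
            from mcprofiler.multisample import consensus_for_condition

            assert jsd(consensus_for_condition(profiles), truth) < 0.02

    def test_stable_fraction_matches_calibration_confidence(self):
        """Replicates drawn from one truth at coverage 50 should be called
        stable for ~95% of sample pairs (the cutoff's confidence level).
        Uses intermediate-methylation truths, the hardest case the
        cutoff was calibrated on."""
        uniform = MCProfile((0.2,) * 5)
        truths = {
            Epilocus("chrS", (i * 200, i * 200 + 10, i * 200 + 20, i * 200 + 30)): uniform
            for i in range(400)
        }
        ledger = simulate_sample_set(truths, n_samples=2, coverage=50, seed=7)
        stable = [
            stability_call(
                [profile_from_counts(ledger.sample_counts[s][e]) for s in ledger.sample_counts]
            ).stable
            for e in truths
        ]
        assert np.mean(stable) == pytest.approx(0.95, abs=0.04)

    def test_jitter_creates_variant_epiloci(self):
        truths = self._truths(30)
        ledger = simulate_sample_set(
            truths, 3, 200, seed=8, jitter_concentration=1.0
        )
        variant = [
            not stability_call(
                [profile_from_counts(ledger.sample_counts[s][e]) for s in ledger.sample_counts]
            ).stable
            for e in truths
        ]
        assert sum(variant) > 0


class TestConditionPair:
    def test_transition_round_trip_at_high_coverage(self, prototypes):
        """A cohort built with a known transition spec reproduces the
        intended 5x5 tally when re-analyzed."""
        protos = default_prototypes()
        truths = {}
        spec = {}
        i = 0
        for frm in ("D1", "D3"):
            for to in ("D2", "D4"):
                for _ in range(5):
                    e = Epilocus("chrS", (i * 300, i * 300 + 10, i * 300 + 20, i * 300 + 30))
                    truths[e] = protos[frm]
                    spec[e] = protos[to]
                    i += 1
        ledger = simulate_sample_set(truths, 2, 5000, seed=10)
        ledger = simulate_condition_pair(ledger, spec, 2, 5000, seed=11)
        labels_a, labels_b, changed = {}, {}, {}
        for e in truths:
            pa = profile_from_counts(ledger.sample_counts["sample_1"][e])
            pb = profile_from_counts(ledger.sample_counts_b["sample_1"][e])
            labels_a[e] = classify_profile(pa, protos).label
            labels_b[e] = classify_profile(pb, protos).label
            changed[e] = compare_conditions(pa, pb).changed
        table = transition_table(labels_a, labels_b, changed)
        assert table.loc["D1", "D2"] == 5
        assert table.loc["D1", "D4"] == 5
        assert table.loc["D3", "D2"] == 5
        assert table.loc["D3", "D4"] == 5
        assert table.values.sum() == 20

    def test_identity_spec_false_positive_rate(self):
        """Unchanged truths at coverage 50 are flagged changed ~5% of the
        time: the false-positive rate implied by the 0.26 cutoff."""
        uniform = MCProfile((0.2,) * 5)
        truths = {
            Epilocus("chrS", (i * 200, i * 200 + 10, i * 200 + 20, i * 200 + 30)): uniform
            for i in range(400)
        }
        ledger = simulate_sample_set(truths, 1, 50, seed=12)
        ledger = simulate_condition_pair(ledger, dict(truths), 1, 50, seed=13)
        flags = []
        for e in truths:
            pa = profile_from_counts(ledger.sample_counts["sample_1"][e])
            pb = profile_from_counts(ledger.sample_counts_b["sample_1"][e])
            flags.append(compare_conditions(pa, pb).changed)
        assert np.mean(flags) == pytest.approx(0.05, abs=0.035)

    def test_equal_mean_swap_changes_with_zero_delta(self):
        a = MCProfile((0.5, 0, 0, 0, 0.5))
        b = MCProfile((0, 0.5, 0, 0.5, 0))
        e = Epilocus("chrS", (0, 10, 20, 30))
        ledger = simulate_sample_set({e: a}, 1, 5000, seed=14)
        ledger = simulate_condition_pair(ledger, {e: b}, 1, 5000, seed=15)
        pa = profile_from_counts(ledger.sample_counts["sample_1"][e])
        pb = profile_from_counts(ledger.sample_counts_b["sample_1"][e])
        r = compare_conditions(pa, pb)
        assert r.changed and abs(r.delta_meth) < 0.02

    def test_unknown_epilocus_in_spec_rejected(self):
        e1 = Epilocus("chrS", (0, 10, 20, 30))
        e2 = Epilocus("chrS", (100, 110, 120, 130))
        ledger = simulate_sample_set({e1: D3}, 1, 50, seed=0)
        with pytest.raises(ValueError):
            simulate_condition_pair(ledger, {e2: D4}, 1, 50, seed=0)


class TestReference:
    def test_planted_cpgs_are_the_only_cpgs(self, small_epiloci):
        ref = make_reference(small_epiloci, seed=1)
        idx = index_cpg_sites(ref["chrS"]).tolist()
        planted = sorted({p for e in small_epiloci for p in e.cpg_positions})
        assert idx == planted

    def test_discovery_round_trip(self, small_epiloci):
        ref = make_reference(small_epiloci, seed=2)
        idx = index_cpg_sites(ref["chrS"])
        wins = build_candidate_epiloci(idx, "chrS", max_length=100)
        assert [w.cpg_positions for w in wins] == [
            e.cpg_positions for e in sorted(small_epiloci)
        ]
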