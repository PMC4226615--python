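"""m.-notation parsing, truth-panel concordance, heteroplasmy statistics."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mitostrand as m
from mitostrand.variant_concordance import ConcordanceRow, round_half_up


class TestParseMtVariant:
    def test_substitution(self):
        v = m.parse_mt_variant("m.7989T>C")
        assert (v.position, v.kind, v.ref, v.alt) == (7989, "substitution", "T", "C")

    def test_insertion(self):
        v = m.parse_mt_variant("m.5899_5900insC")
        assert (v.position, v.end, v.kind, v.alt) == (5899, 5900, "insertion", "C")

    def test_deletion_interval(self):
        v = m.parse_mt_variant("m.8470_13446del")
        assert (v.position, v.end, v.kind) == (8470, 13446, "deletion")

    @pytest.mark.parametrize(
        "text",
        ["m.7989T>C", "m.5899_5900insC", "m.309_310insC", "m.315_316insC",
         "m.16183A>C", "m.294T>C", "m.12071T>C", "m.9769T>C", "m.10866T>C",
         "m.8207C>T", "m.5609T>C", "m.7453G>A", "m.3106del", "m.8470_13446del"],
    )
    def test_round_trip(self, text):
        assert m.parse_mt_variant(text).format() == text

    @pytest.mark.parametrize("bad", ["m.12X>Y", "7989T>C", "m.5899_5901insC", "m.", "m.10_9del"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            m.parse_mt_variant(bad)


def _truth(sample, texts):
    truth = m.TruthSet()
    for t in texts:
        truth.add(sample, m.parse_mt_variant(t))
    return truth


class TestCompareCallsets:
    def test_identical_sets(self):
        texts = ["m.100A>G", "m.200C>T", "m.300_301insA"]
        truth = _truth("s1", texts)
        row = m.compare_callsets(truth, [m.parse_mt_variant(t) for t in texts], "s1", "d")
        assert (row.n_detected, row.n_false_negative, row.n_extra) == (3, 0, 0)

    def test_toy_set_arithmetic(self):
        truth = _truth("s1", ["m.100A>G", "m.200C>T", "m.300G>A"])
        calls = [m.parse_mt_variant(t) for t in ["m.100A>G", "m.200C>T", "m.400T>C"]]
        row = m.compare_callsets(truth, calls, "s1", "d")
        assert (row.n_detected, row.n_false_negative, row.n_extra) == (2, 1, 1)

    def test_allele_mismatch_is_not_a_match(self):
        truth = _truth("s1", ["m.100A>G"])
        row = m.compare_callsets(truth, [m.parse_mt_variant("m.100A>T")], "s1", "d")
        assert (row.n_detected, row.n_extra) == (0, 1)

    def test_polymorphic_region_equivalence_by_net_length(self):
        # two single-C insertions reported by the truth method; the call set
        # sees one two-C insertion in the same homopolymeric stretch
        truth = _truth("s21", ["m.309_310insC", "m.315_316insC"])
        calls = [m.parse_mt_variant("m.309_310insCC")]
        exact = m.compare_callsets(truth, calls, "s21", "d")
        assert (exact.n_detected, exact.n_extra) == (0, 1)
        relaxed = m.compare_callsets(
            truth, calls, "s21", "d", equivalence_regions=[(302, 316)]
        )
        assert (relaxed.n_detected, relaxed.n_false_negative, relaxed.n_extra) == (2, 0, 0)

    @given(
        st.sets(st.integers(1, 60), min_size=0, max_size=25),
        st.sets(st.integers(1, 60), min_size=0, max_size=25),
    )
    def test_counts_invariant_on_random_sets(self, truth_pos, call_pos):
        truth = m.TruthSet()
        for p in truth_pos:
            truth.add("s", m.parse_mt_variant(f"m.{p}A>G"))
        calls = [m.parse_mt_variant(f"m.{p}A>G") for p in call_pos]
        row = m.compare_callsets(truth, calls, "s", "d")
        assert row.n_detected + row.n_false_negative == row.n_truth
        assert row.n_detected == len(truth_pos & call_pos)
        assert row.n_extra == len(call_pos - truth_pos)


class TestDetectionRate:
    def test_all_detected(self):
        rows = [ConcordanceRow("s", "d", 5, 5, 0, 0)]
        assert m.detection_rate(rows) == 100.0

    def test_permutation_invariance_and_homogeneous_rows(self):
        rows = [ConcordanceRow(str(i), "d", 10, 9, 1, 0) for i in range(4)]
        assert m.detection_rate(rows) == m.detection_rate(rows[::-1]) == 90.0

    def test_zero_truth_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            m.detection_rate([ConcordanceRow("s", "d", 0, 0, 0, 2)])


class TestHeteroplasmySummary:
    @pytest.mark.parametrize(
        "values, mean, sd",
        [((12, 12, 23), 15.7, 6.4),
         ((17.1, 14.7, 14.1), 15.3, 1.6),
         ((8, 8, 8), 8.0, 0.0)],
    )
    def test_published_style_rows(self, values, mean, sd):
        assert m.heteroplasmy_summary(values) == (mean, sd)

    def test_requires_two_values(self):
        with pytest.raises(ValueError, match="at least two"):
            m.heteroplasmy_summary([7.0])

    @given(st.lists(st.floats(0, 100, allow_nan=False, width=32), min_size=2, max_size=12))
    def test_sd_matches_two_pass_brute_force(self, values):
        mean, sd = m.heteroplasmy_summary(values, ndigits=None)
        bf_mean = sum(values) / len(values)
        bf_sd = (sum((v - bf_mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5
        assert mean == pytest.approx(bf_mean, abs=1e-9)
        assert sd == pytest.approx(bf_sd, abs=1e-9)

    def test_round_half_up(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(15.649, 1) == 15.6


class TestEndToEndSensitivity:
    def test_variants_above_threshold_recovered_with_no_false_negatives(self, toy_ref):
        """An oracle caller (alt fraction > threshold) at depth >= 3000
        recovers every simulated variant placed above the threshold."""
        from mitostrand.genome import BASE_INDEX

        variants = []
        for pos, frac in ((150, 0.05), (700, 0.12), (1200, 0.30), (1800, 0.60)):
            r = toy_ref.sequence[pos - 1]
            alt = "C" if r != "C" else "T"
            variants.append(m.Variant(pos, r, alt, frac))
        cfg = m.SimulationConfig(mean_depth=3000, error_rate=0.003,
                                 variants=tuple(variants), seed=33)
        counts, _ = m.simulate_base_counts(toy_ref, cfg)
        threshold = m.detection_threshold(
            m.aggregate_error_rates([0.003])
        )  # 2%
        truth = m.TruthSet()
        calls = []
        pooled = counts.pooled()
        totals = counts.total_depth
        for v in variants:
            truth.add("s", m.parse_mt_variant(f"m.{v.position}{v.ref}>{v.alt}"))
        for i in range(len(toy_ref)):
            ref_base = toy_ref.sequence[i]
            for base in "ACGT":
                if base == ref_base:
                    continue
                frac = pooled[i, BASE_INDEX[base]] / totals[i]
                if m.is_callable(frac, threshold):
                    calls.append(m.parse_mt_variant(f"m.{i + 1}{ref_base}>{base}"))
        row = m.compare_callsets(truth, calls, "s", "oracle")
        assert row.n_false_negative == 0
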