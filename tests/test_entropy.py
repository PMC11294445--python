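"""Shannon-entropy variable-site profiles and class-wise summaries."""

import math

import numpy as np
import pytest

from wolbkit import simulate
from wolbkit.entropy import (
    EntropyProfile,
    column_entropy,
    effector_report,
    entropy_profile,
    summarize_variability,
)


def brute_force_entropy(column):
    """Frequency table + formula, written independently of the implementation."""
    residues = [c for c in column if c in "ACDEFGHIKLMNPQRSTVWY"]
    if len(residues) < 2:
        return None
    h = 0.0
    for aa in set(residues):
        p = residues.count(aa) / len(residues)
        h -= p * math.log(p, 2)
    return h


class TestColumnEntropy:
    @pytest.mark.parametrize("column,expected", [
        ("AAAA", 0.0),
        ("AAVV", 1.0),
        ("AAAVV", -(0.6 * math.log2(0.6) + 0.4 * math.log2(0.4))),
    ])
    def test_hand_values(self, column, expected):
        assert column_entropy(column) == pytest.approx(expected, abs=1e-12)

    def test_gaps_excluded_from_frequencies(self):
        assert column_entropy("AA--VV") == pytest.approx(1.0)

    def test_low_coverage_undefined(self):
        assert column_entropy("A----") is None
        assert column_entropy("-----") is None

    def test_empty_column_rejected(self):
        with pytest.raises(ValueError):
            column_entropy("")

    def test_agrees_with_brute_force_on_random_columns(self):
        rng = np.random.default_rng(42)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY-X")
        for _ in range(1000):
            depth = int(rng.integers(2, 30))
            column = "".join(rng.choice(alphabet, size=depth))
            expected = brute_force_entropy(column)
            actual = column_entropy(column)
            if expected is None:
                assert actual is None
            else:
                assert actual == pytest.approx(expected, abs=1e-12)


class TestEntropyProfile:
    def test_identical_rows_have_no_variable_sites(self):
        profile = entropy_profile(["MKTAYI", "MKTAYI", "MKTAYI"])
        assert profile.n_variable == 0
        assert profile.fraction_variable == 0.0

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            entropy_profile(["MKT", "MK"])

    def test_threshold_above_max_entropy_flags_nothing(self):
        profile = entropy_profile(["AV", "VA", "CD"], variable_threshold=math.log2(20))
        assert profile.n_variable == 0

    def test_invariant_to_row_permutation(self):
        rows = ["MKTAYIA", "MKTCYIA", "MRTAYIA"]
        a = entropy_profile(rows)
        b = entropy_profile(rows[::-1])
        assert a.column_entropies == b.column_entropies
        assert a.variable_flags == b.variable_flags

    def test_n_variable_non_increasing_in_threshold(self):
        rows = ["MKTAYIAC", "MKTCYIAC", "MRTAYIAD", "MRTCYIVD"]
        counts = [
            entropy_profile(rows, variable_threshold=t).n_variable
            for t in (0.0, 0.5, 1.0, 2.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_planted_variable_columns_recovered_exactly(self, small_tree):
        for n_var in (0, 5, 17):
            aln, cols = simulate.simulate_family_alignment(
                f"fam{n_var}", small_tree, length=120, n_variable=n_var, seed=31
            )
            profile = entropy_profile(aln)
            assert profile.n_variable == n_var
            flagged = {i for i, f in enumerate(profile.variable_flags) if f}
            assert flagged == cols


class TestSummarizeVariability:
    def _profiles(self, counts_by_class):
        profiles, classes = [], {}
        i = 0
        for klass, counts in counts_by_class.items():
            for n in counts:
                og = f"OG{i:03d}"
                flags = [True] * n + [False] * (40 - n)
                profiles.append(EntropyProfile(
                    og_id=og, column_entropies=[None] * 40,
                    column_coverage=[5] * 40, variable_flags=flags,
                    alignment_length=40,
                ))
                classes[og] = klass
                i += 1
        return profiles, classes

    def test_odd_count_median(self):
        profiles, classes = self._profiles({"other": [0, 1, 5]})
        summary = summarize_variability(profiles, classes)
        assert summary.class_medians["other"] == 1.0

    def test_even_count_median_is_half_integer(self):
        profiles, classes = self._profiles({"secreted": [13, 14]})
        summary = summarize_variability(profiles, classes)
        assert summary.class_medians["secreted"] == 13.5

    def test_zero_variable_counted_but_not_binned(self):
        profiles, classes = self._profiles({"other": [0, 0, 3]})
        summary = summarize_variability(profiles, classes)
        assert summary.n_zero_variable == 2
        binned = [(n, k, c) for n, k, c in summary.histogram if k == "other"]
        assert binned == [(3, "other", 1)]

    def test_all_class_aggregates_everything(self):
        profiles, classes = self._profiles({"other": [1, 2], "secreted": [10]})
        summary = summarize_variability(profiles, classes)
        assert summary.class_counts["all"] == 3
        assert summary.class_medians["all"] == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_variability([], {})

    def test_missing_class_label_rejected(self):
        profiles, _ = self._profiles({"other": [1]})
        with pytest.raises(KeyError):
            summarize_variability(profiles, {})


class TestEffectorReport:
    def test_planted_effector_fraction(self, small_tree):
        aln, _ = simulate.simulate_family_alignment(
            "eff", small_tree, length=200, n_variable=20, seed=8
        )
        profile = entropy_profile(aln, og_id="OG1")
        rows = effector_report([profile], ["TomO"], names={"OG1": "TomO_homolog"})
        assert rows == [{
            "og_id": "OG1", "name": "TomO_homolog", "n_variable": 20,
            "alignment_length": 200, "percent_variable": 10,
        }]

    def test_denominator_is_full_alignment_length(self):
        rows = ["MKTA-I", "MKTC-I"]
        profile = entropy_profile(rows, og_id="OG1")
        table = effector_report([profile], ["OG1"])
        assert table[0]["alignment_length"] == 6  # gap column included

    def test_no_match_gives_empty_table(self):
        profile = entropy_profile(["MKT", "MKT"], og_id="OG1")
        assert effector_report([profile], ["nonexistent"]) == []
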