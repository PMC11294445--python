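"""Read hygiene: duplicate removal and the gap-compressed divergence filter."""

import pytest

from wolbkit import simulate
from wolbkit.read_filter import (
    AlignmentRecord,
    DivergenceIndeterminate,
    InconsistentRecordError,
    dedup_reads,
    filter_by_divergence,
    gap_compressed_divergence,
)


def brute_force_divergence(record):
    """Independent oracle: expand runs to per-event strings and count."""
    events = []
    for op, n in record.event_runs:
        if op in ("=", "M"):
            events.extend(["match"] * n)
        elif op == "X":
            events.extend(["mismatch"] * n)
        else:
            events.append("gap")  # one event per indel run
    mismatches = events.count("mismatch")
    if record.edit_distance is not None:
        ins = record.op_total("I")
        dele = record.op_total("D")
        mismatches += record.edit_distance - ins - dele - record.op_total("X")
    matches = events.count("match")
    gaps = events.count("gap")
    return (mismatches + gaps) / (matches + mismatches + gaps)


class TestDedup:
    def test_repeated_ids_keep_first(self):
        retained, removed = dedup_reads([("a", "AC"), ("b", "GG"), ("a", "TT")])
        assert [r[0] for r in retained] == ["a", "b"]
        assert removed == 1

    def test_distinct_ids_untouched(self):
        records = [("a", "AC"), ("b", "AC"), ("c", "GT")]
        retained, removed = dedup_reads(records)
        assert retained == records and removed == 0

    def test_sequence_key_collapses_identical_sequences(self):
        records = [("a", "ACGT"), ("b", "ACGT"), ("c", "GGGG")]
        retained, removed = dedup_reads(records, key="sequence")
        # brute-force pairwise check of what should survive
        expected = []
        for i, (rid, seq) in enumerate(records):
            if not any(seq == s2 for _, s2 in records[:i]):
                expected.append((rid, seq))
        assert retained == expected and removed == 1

    def test_bad_key_rejected(self):
        with pytest.raises(ValueError):
            dedup_reads([], key="length")


class TestGapCompressedDivergence:
    @pytest.mark.parametrize(
        "runs,nm,expected",
        [
            ([("=", 100), ("X", 4)], None, 4 / 104),
            ([("=", 50), ("D", 3), ("=", 50)], 5, 3 / 103),
            ([("=", 80)], None, 0.0),
            # mismatches recovered from NM over unresolved M runs; all match-run
            # columns stay in the denominator under the NM-inference convention
            ([("M", 10)], 1, 1 / 11),
        ],
    )
    def test_formula(self, runs, nm, expected):
        rec = AlignmentRecord("r", "t", event_runs=runs, edit_distance=nm)
        assert gap_compressed_divergence(rec) == pytest.approx(expected, abs=1e-15)

    def test_each_indel_run_counts_once(self):
        rec = AlignmentRecord("r", "t", [("=", 20), ("I", 5), ("=", 20)])
        # 5 inserted bases but a single gap-open event
        assert gap_compressed_divergence(rec) == pytest.approx(1 / 41)

    def test_unmapped_raises(self):
        rec = AlignmentRecord("r", "*", [], mapped=False)
        with pytest.raises(DivergenceIndeterminate):
            gap_compressed_divergence(rec)

    def test_unresolved_cigar_without_nm_is_indeterminate(self):
        rec = AlignmentRecord("r", "t", [("M", 10)])
        assert not rec.determinate
        with pytest.raises(DivergenceIndeterminate):
            gap_compressed_divergence(rec)

    def test_nm_below_indel_bases_is_inconsistent(self):
        rec = AlignmentRecord("r", "t", [("=", 10), ("D", 5), ("=", 10)], edit_distance=2)
        with pytest.raises(InconsistentRecordError):
            gap_compressed_divergence(rec)

    def test_matches_brute_force_on_simulated_records(self):
        records, _, truth = simulate.simulate_alignment_records(
            1000, [0.0, 0.01, 0.0391, 0.04, 0.05, 0.12], seed=13
        )
        for rec in records:
            r = gap_compressed_divergence(rec)
            assert r == pytest.approx(brute_force_divergence(rec), abs=1e-12)
            assert r == pytest.approx(truth[rec.read_id], abs=1e-12)


class TestFilterByDivergence:
    def test_boundary_value_is_retained(self):
        # the rule removes reads *exceeding* the threshold, so r == 0.04 stays
        rec = AlignmentRecord("r", "t", [("=", 96), ("X", 4)])
        assert gap_compressed_divergence(rec) == pytest.approx(0.04)
        retained, report = filter_by_divergence([rec], threshold=0.04)
        assert retained == [rec]
        assert report.n_retained == 1 and report.n_failed_threshold == 0

    def test_mixture_split_at_threshold(self):
        records, _, truth = simulate.simulate_alignment_records(
            40, [0.01, 0.05], seed=3
        )
        retained, report = filter_by_divergence(records, threshold=0.04)
        kept = {r.read_id for r in retained}
        assert kept == {rid for rid, d in truth.items() if d <= 0.04}
        assert report.n_retained == len(kept)

    def test_zero_threshold_keeps_only_perfect(self):
        perfect = AlignmentRecord("p", "t", [("=", 50)])
        noisy = AlignmentRecord("n", "t", [("=", 49), ("X", 1)])
        retained, _ = filter_by_divergence([perfect, noisy], threshold=0.0)
        assert [r.read_id for r in retained] == ["p"]

    def test_monotone_nesting_over_thresholds(self):
        records, _, _ = simulate.simulate_alignment_records(
            200, [0.0, 0.005, 0.02, 0.039, 0.041, 0.08, 0.15], seed=5
        )
        previous = set()
        for threshold in (0.01, 0.04, 0.1):
            retained, _ = filter_by_divergence(records, threshold=threshold)
            current = {r.read_id for r in retained}
            assert previous <= current
            previous = current

    def test_report_reconciles_with_mixed_records(self):
        records, _, _ = simulate.simulate_alignment_records(20, [0.01, 0.06], seed=9)
        records.append(AlignmentRecord("un", "*", [], mapped=False))
        records.append(AlignmentRecord("ind", "t", [("M", 30)]))
        records.append(AlignmentRecord("sec", "t", [("=", 30)], is_primary=False))
        retained, report = filter_by_divergence(records)
        report.check()
        assert report.n_unmapped == 1
        assert report.n_indeterminate == 1
        # secondary line ignored entirely
        assert report.n_input == 22
        assert report.n_retained == len(retained)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_by_divergence([], threshold=1.5)
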