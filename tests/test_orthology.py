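"""Orthogroup inference, PAV matrices, center-star alignment, supermatrix."""

import itertools

import pytest

from wolbkit import simulate
from wolbkit.io_formats import FastaRecord, SeqRecordSet
from wolbkit.orthology import (
    Orthogroup,
    TooShortError,
    align_orthogroup,
    build_pav,
    export_supermatrix,
    extract_scos,
    infer_orthogroups,
    orthogroups_to_table,
    pairwise_similarity,
    table_to_orthogroups,
)


def _proteome(strain, seqs):
    return SeqRecordSet(
        [FastaRecord(id=f"{strain}|g{i}", description="", sequence=s)
         for i, s in enumerate(seqs)],
        "protein",
    )


class TestPairwiseSimilarity:
    def test_identical_sequences_score_one(self):
        assert pairwise_similarity("MKTAYIAKQR", "MKTAYIAKQR") == 1.0

    def test_disjoint_kmer_sets_score_zero(self):
        assert pairwise_similarity("AAAAAA", "CCCCCC") == 0.0

    def test_hand_enumerated_example(self):
        # 4-mers: {ACDE,CDEF,DEFG,EFGH} vs {ACDE,CDEF,DEFG,EFGY}
        assert pairwise_similarity("ACDEFGH", "ACDEFGY", k=4) == pytest.approx(3 / 5)

    def test_too_short_raises(self):
        with pytest.raises(TooShortError):
            pairwise_similarity("ACD", "ACDEFG", k=4)

    def test_symmetric(self):
        a, b = "MKTAYIAKQRQISFVK", "MKTAYIPKQRQISFVR"
        assert pairwise_similarity(a, b) == pairwise_similarity(b, a)


class TestInferOrthogroups:
    def test_identical_proteomes_pair_up(self):
        seqs = ["MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "GELDRWEKIRLRPGGKKKYKLKHIVWASRELER"]
        proteomes = {"s1": _proteome("s1", seqs), "s2": _proteome("s2", seqs)}
        ogs = infer_orthogroups(proteomes)
        assert len(ogs) == 2
        for og in ogs:
            assert sum(len(v) for v in og.members.values()) == 2
            assert set(og.members) == {"s1", "s2"}

    def test_min_score_one_yields_singletons_on_diverged_data(self):
        proteomes = {
            "s1": _proteome("s1", ["MKTAYIAKQRQISFVK"]),
            "s2": _proteome("s2", ["MKTAYIPKQRQISFVR"]),
        }
        ogs = infer_orthogroups(proteomes, min_score=1.0)
        assert len(ogs) == 2
        assert all(sum(len(v) for v in og.members.values()) == 1 for og in ogs)

    def test_empty_proteome_error_names_strain(self):
        proteomes = {
            "good": _proteome("good", ["MKTAYIAKQR"]),
            "bad": SeqRecordSet([], "protein"),
        }
        with pytest.raises(ValueError, match="bad"):
            infer_orthogroups(proteomes)

    def test_partition_property(self, small_dataset):
        ogs = infer_orthogroups(small_dataset.proteomes)
        all_genes = [g for og in ogs for g in og.gene_ids()]
        expected = sorted(
            rec.id for p in small_dataset.proteomes.values() for rec in p
        )
        assert sorted(all_genes) == expected  # every gene in exactly one orthogroup

    def test_family_recovery_on_simulated_strains(self, small_dataset):
        ogs = infer_orthogroups(small_dataset.proteomes)
        # genes carry their true family in the id; recovered groups must match
        for og in ogs:
            families = {g.split("|", 1)[1] for g in og.gene_ids()}
            assert len(families) == 1


class TestScosAndPav:
    def _toy_ogs(self):
        return [
            Orthogroup("OG1", {"s1": ["s1|a"], "s2": ["s2|a"], "s3": ["s3|a"]}),
            Orthogroup("OG2", {"s1": ["s1|b", "s1|b2"], "s2": ["s2|b"], "s3": ["s3|b"]}),
            Orthogroup("OG3", {"s1": ["s1|c"], "s3": ["s3|c"]}),
        ]

    def test_sco_requires_exactly_one_everywhere(self):
        strains = ["s1", "s2", "s3"]
        assert extract_scos(self._toy_ogs(), strains) == ["OG1"]

    def test_pav_counts(self):
        strains = ["s1", "s2", "s3"]
        pav = build_pav(self._toy_ogs(), strains)
        assert list(pav.counts.loc["OG2"]) == [2, 1, 1]
        assert list(pav.presence.loc["OG3"]) == [True, False, True]
        assert list(pav.counts.index) == ["OG1", "OG2", "OG3"]  # sorted rows

    def test_undeclared_strain_rejected(self):
        with pytest.raises(ValueError):
            build_pav(self._toy_ogs(), ["s1", "s2"])

    def test_pav_matches_simulated_truth_exactly(self, small_dataset):
        # group genes by their true family and compare PAV to the manifest
        strains = small_dataset.strains()
        by_family = {}
        for strain, prot in small_dataset.proteomes.items():
            for rec in prot:
                fam = rec.id.split("|", 1)[1]
                by_family.setdefault(fam, {}).setdefault(strain, []).append(rec.id)
        ogs = [Orthogroup(fam, members) for fam, members in sorted(by_family.items())]
        pav = build_pav(ogs, strains)
        truth = small_dataset.truth.pav_truth
        assert pav.presence.equals(truth.loc[pav.presence.index, strains])


class TestAlignOrthogroup:
    def test_identical_pair_gap_free(self):
        rows = align_orthogroup([("a", "MKTAYI"), ("b", "MKTAYI")])
        assert rows == {"a": "MKTAYI", "b": "MKTAYI"}

    def test_single_member_returned_unaligned(self):
        assert align_orthogroup([("a", "MKT")]) == {"a": "MKT"}

    def test_deletion_matches_brute_force_optimum(self):
        rows = align_orthogroup([("a", "ACDE"), ("b", "ACE")])
        assert rows["a"] == "ACDE"
        assert rows["b"] in {"AC-E"}  # brute-force optimum: 3 matches, 1 gap
        # brute-force: enumerate all placements of one gap in the short seq
        def score(x, y):
            s = 0
            in_gap = False
            for cx, cy in zip(x, y):
                if cy == "-":
                    s += -1 if in_gap else -2
                    in_gap = True
                else:
                    s += 1 if cx == cy else -1
                    in_gap = False
            return s
        best = max(
            ("ACE"[:i] + "-" + "ACE"[i:] for i in range(4)),
            key=lambda y: score("ACDE", y),
        )
        assert score("ACDE", rows["b"]) == score("ACDE", best)

    def test_column_content_invariant_to_input_order(self):
        members = [("a", "MKTAYIAKQR"), ("b", "MKTAYIPKQR"), ("c", "MKTAYIAKR")]
        reference = align_orthogroup(members)
        for perm in itertools.permutations(members):
            assert align_orthogroup(list(perm)) == reference

    def test_rows_share_width(self, small_dataset):
        fam = sorted(small_dataset.alignments)[0]
        rows = small_dataset.alignments[fam]
        members = [(f"{s}|{fam}", seq) for s, seq in rows.items()]
        aligned = align_orthogroup(members)
        widths = {len(v) for v in aligned.values()}
        assert len(widths) == 1


class TestSupermatrix:
    def test_concatenation_and_partitions(self):
        strains = ["s1", "s2"]
        scos = [
            ("OG1", {"s1": "A" * 10, "s2": "C" * 10}),
            ("OG2", {"s1": "D" * 20, "s2": "E" * 20}),
        ]
        matrix, partitions = export_supermatrix(scos, strains)
        assert len(matrix["s1"]) == 30
        assert partitions == [("OG1", 0, 10), ("OG2", 10, 30)]
        assert list(matrix) == strains  # declared strain order preserved

    def test_no_scos_rejected(self):
        with pytest.raises(ValueError, match="no single-copy"):
            export_supermatrix([], ["s1"])

    def test_missing_strain_row_rejected(self):
        with pytest.raises(ValueError, match="s2"):
            export_supermatrix([("OG1", {"s1": "AAA"})], ["s1", "s2"])


class TestTableConversion:
    def test_round_trip_through_table(self, small_dataset):
        ogs = infer_orthogroups(small_dataset.proteomes)
        strains = small_dataset.strains()
        table = orthogroups_to_table(ogs, strains)
        back = table_to_orthogroups(table)
        assert [og.og_id for og in back] == [og.og_id for og in ogs]
        assert [og.members for og in back] == [
            {s: sorted(v) for s, v in og.members.items()} for og in ogs
        ]
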