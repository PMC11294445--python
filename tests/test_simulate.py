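"""Simulator contracts: trees, gene content, alignments, genomes, reads."""

import itertools

import pytest

from wolbkit import simulate
from wolbkit.genome_stats import windowed_profile


def leaf_sets_of_all_clades(tree):
    """Brute-force enumeration of every clade (leaf bipartition side)."""
    out = []
    for node in tree.tree.preorder_node_iter():
        out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return out


class TestSampleStrainTree:
    def test_smallest_valid_tree(self):
        tree = simulate.sample_strain_tree(2, 1, seed=1)
        assert tree.leaf_labels() == ["S01", "S02"]
        assert set(tree.clade_labels.values()) == {"A"}

    def test_clades_are_monophyletic(self):
        tree = simulate.sample_strain_tree(8, 2, seed=7)
        clades = {}
        for leaf, label in tree.clade_labels.items():
            clades.setdefault(label, set()).add(leaf)
        assert sum(len(v) for v in clades.values()) == 8
        all_clades = leaf_sets_of_all_clades(tree)
        for members in clades.values():
            assert frozenset(members) in all_clades

    def test_deterministic_newick(self):
        a = simulate.sample_strain_tree(8, 2, seed=7).newick()
        b = simulate.sample_strain_tree(8, 2, seed=7).newick()
        assert a == b

    def test_branch_lengths_non_negative(self, small_tree):
        for edge in small_tree.tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0

    @pytest.mark.parametrize("n_strains,n_clades", [(1, 1), (4, 0), (4, 5)])
    def test_invalid_counts_rejected(self, n_strains, n_clades):
        with pytest.raises(ValueError):
            simulate.sample_strain_tree(n_strains, n_clades, seed=1)


class TestGeneContent:
    def test_root_gains_without_loss_give_all_true_pav(self, small_tree):
        _, truth = simulate.simulate_gene_content(
            small_tree, n_core=3, n_accessory=7, gain_rate=0.0, loss_rate=0.0, seed=2
        )
        assert truth.pav.values.all()

    def test_core_only_pav_is_all_true(self, small_tree):
        gene_sets, truth = simulate.simulate_gene_content(
            small_tree, n_core=5, n_accessory=0, gain_rate=1.0, loss_rate=1.0, seed=3
        )
        assert truth.pav.shape == (5, 6)
        assert truth.pav.values.all()
        assert all(len(v) == 5 for v in gene_sets.values())

    def test_negative_rates_rejected(self, small_tree):
        with pytest.raises(ValueError):
            simulate.simulate_gene_content(small_tree, 1, 1, -0.1, 0.0, seed=1)

    def test_event_log_replays_to_pav(self, small_tree):
        """Independent oracle: walk each leaf's root path through the log."""
        _, truth = simulate.simulate_gene_content(
            small_tree, n_core=0, n_accessory=40, gain_rate=2.0, loss_rate=2.0, seed=5
        )
        nodes = {}
        for node in small_tree.tree.preorder_node_iter():
            label = node.taxon.label if node.taxon else node.label
            nodes[label] = node

        def path_to_root(leaf_label):
            node = nodes[leaf_label]
            labels = []
            while node is not None:
                labels.append(node.taxon.label if node.taxon else node.label)
                node = node.parent_node
            return labels

        for fam, ev in truth.events.items():
            for leaf in truth.pav.columns:
                path = path_to_root(leaf)
                if ev["gain_node"] not in path:
                    expected = False
                else:
                    below_gain = path[: path.index(ev["gain_node"])]
                    expected = not any(loss in below_gain for loss in ev["losses"])
                assert truth.pav.loc[fam, leaf] == expected, (fam, leaf)

    def test_truth_manifest_is_complete(self, small_tree):
        gene_sets, truth = simulate.simulate_gene_content(
            small_tree, n_core=4, n_accessory=10, gain_rate=2.0, loss_rate=1.0, seed=9
        )
        for strain, fams in gene_sets.items():
            assert set(fams) == set(truth.pav.index[truth.pav[strain]])
        assert set(truth.events) == set(truth.pav.index)


class TestFamilyAlignment:
    def test_no_variable_columns_means_identical_rows(self, small_tree):
        aln, cols = simulate.simulate_family_alignment(
            "f", small_tree, length=80, n_variable=0, seed=4
        )
        assert cols == set()
        assert len(set(aln.values())) == 1

    def test_all_columns_variable_is_a_valid_boundary(self, small_tree):
        aln, cols = simulate.simulate_family_alignment(
            "f", small_tree, length=30, n_variable=30, seed=4
        )
        assert cols == set(range(30))

    def test_excess_variable_columns_rejected(self, small_tree):
        with pytest.raises(ValueError):
            simulate.simulate_family_alignment("f", small_tree, 10, 11, seed=1)

    def test_substitutions_confined_to_designated_columns(self, small_tree):
        aln, cols = simulate.simulate_family_alignment(
            "f", small_tree, length=100, n_variable=12, seed=6
        )
        rows = list(aln.values())
        for j in range(100):
            states = {r[j] for r in rows}
            if j in cols:
                assert len(states) >= 2  # forced to realize variation
            else:
                assert len(states) == 1

    def test_exclusions_respected(self, small_tree):
        exclude = set(range(0, 40))
        _, cols = simulate.simulate_family_alignment(
            "f", small_tree, length=100, n_variable=20, seed=6, exclude_columns=exclude
        )
        assert not (cols & exclude)

    def test_deterministic(self, small_tree):
        a, _ = simulate.simulate_family_alignment("f", small_tree, 50, 5, seed=8)
        b, _ = simulate.simulate_family_alignment("f", small_tree, 50, 5, seed=8)
        assert a == b


class TestPlantProteinFeatures:
    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            simulate.plant_protein_features("SSSSS", "secreted", seed=1)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            simulate.plant_protein_features("S" * 100, "golgi", seed=1)

    def test_other_on_polyserine_left_inert(self):
        seq, truth, protected = simulate.plant_protein_features("S" * 100, "other", seed=1)
        assert seq == "S" * 100
        assert truth == "other" and protected == []

    def test_deterministic(self):
        raw = "A" * 120
        a = simulate.plant_protein_features(raw, "membrane-bound", seed=3)
        b = simulate.plant_protein_features(raw, "membrane-bound", seed=3)
        assert a == b


class TestAssembleGenomes:
    GS = {"A": [f"FAM{i:04d}" for i in range(1, 21)],
          "B": [f"FAM{i:04d}" for i in range(1, 21)]}

    def test_zero_amplitude_has_no_systematic_sign_structure(self):
        genomes, _ = simulate.assemble_genomes(self.GS, seed=2, skew_amplitude=0.0)
        track = windowed_profile(genomes["A"], metric="gc_skew", window=2000, step=2000)
        values = [v for _, _, v in track.windows if v is not None]
        assert any(v > 0 for v in values) and any(v < 0 for v in values)
        assert abs(sum(values) / len(values)) < 0.05

    def test_identical_seed_identical_genomes(self):
        a, _ = simulate.assemble_genomes(self.GS, seed=2)
        b, _ = simulate.assemble_genomes(self.GS, seed=2)
        assert a["A"].sequence == b["A"].sequence

    def test_shared_content_means_shared_sequence(self):
        genomes, _ = simulate.assemble_genomes(self.GS, seed=2)
        assert genomes["A"].sequence == genomes["B"].sequence

    def test_overlapping_rearrangements_rejected(self):
        spec = [
            {"strain": "A", "type": "inversion", "start": 1000, "length": 5000},
            {"strain": "A", "type": "inversion", "start": 4000, "length": 2000},
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate.assemble_genomes(self.GS, seed=2, rearrangement_spec=spec)

    def test_invalid_amplitude_rejected(self):
        with pytest.raises(ValueError):
            simulate.assemble_genomes(self.GS, seed=2, skew_amplitude=1.5)


class TestAlignmentRecords:
    def test_zero_divergence_record_is_clean(self):
        records, _, truth = simulate.simulate_alignment_records(1, [0.0], seed=1)
        (rec,) = records
        assert rec.op_total("X") == 0
        assert rec.n_runs("I") + rec.n_runs("D") == 0
        assert truth[rec.read_id] == 0.0

    def test_event_budget_matches_request(self):
        records, _, _ = simulate.simulate_alignment_records(
            1, [0.05], seed=2, n_events=100
        )
        (rec,) = records
        bad = rec.op_total("X") + rec.n_runs("I") + rec.n_runs("D")
        assert bad == 5

    def test_truth_complete_and_within_resolution(self):
        n_events = 250
        requested = [0.013, 0.04, 0.07]
        records, seqs, truth = simulate.simulate_alignment_records(
            30, requested, seed=3, n_events=n_events
        )
        assert set(truth) == {r.read_id for r in records} == set(seqs)
        for i, rec in enumerate(records):
            want = requested[i % len(requested)]
            assert abs(truth[rec.read_id] - want) <= 1.0 / n_events

    def test_out_of_range_divergence_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_alignment_records(1, [0.6], seed=1)


class TestDatasetDeterminism:
    def test_written_dataset_is_byte_identical(self, tmp_path):
        for sub in ("one", "two"):
            ds = simulate.simulate_dataset(
                seed=19, n_strains=4, n_clades=2, n_core=10, n_accessory=5, n_reads=10
            )
            simulate.write_dataset(ds, tmp_path / sub)
        files_one = sorted(p.relative_to(tmp_path / "one")
                           for p in (tmp_path / "one").rglob("*") if p.is_file())
        files_two = sorted(p.relative_to(tmp_path / "two")
                           for p in (tmp_path / "two").rglob("*") if p.is_file())
        assert files_one == files_two
        for rel in files_one:
            assert (tmp_path / "one" / rel).read_bytes() == \
                (tmp_path / "two" / rel).read_bytes(), rel
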