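"""Alignment trimming, monophyly-support extraction and five-group assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hgtscan.io import read_newick_supports
from hgtscan.phylo import (
    DegenerateAlignmentError,
    PhyloAssessment,
    TooFewSequencesError,
    assign_group,
    build_support_tree,
    calibrate_s_min,
    extract_monophyly_supports,
    summarize_groups,
    trim_alignment,
)
from hgtscan.simulate import SimParams, generate_hit_table, generate_trees, taxon_of_leaf
from hgtscan.taxa import METAZOA


class TestTrimAlignment:
    def test_single_residue_column_dropped(self):
        out = trim_alignment(["AC-", "A-C", "A--"])
        # col0 has 3 residues (kept); col1 and col2 have exactly one (dropped)
        assert out == ["A", "A", "A"]

    def test_two_residue_column_kept(self):
        assert trim_alignment(["AC", "AC"]) == ["AC", "AC"]

    def test_all_gap_column_kept(self):
        # zero residues is not "exactly one": the rule leaves it alone
        assert trim_alignment(["A-", "A-"]) == ["A-", "A-"]

    def test_degenerate_alignment_rejected(self):
        with pytest.raises(DegenerateAlignmentError):
            trim_alignment(["A-", "-C"])

    @given(st.data())
    @settings(derandomize=True, max_examples=60)
    def test_matches_per_column_oracle(self, data):
        nrow = data.draw(st.integers(2, 6))
        ncol = data.draw(st.integers(1, 12))
        rows = [
            "".join(data.draw(st.sampled_from("ACDG-")) for _ in range(ncol))
            for _ in range(nrow)
        ]
        keep = [
            j for j in range(ncol)
            if sum(r[j] != "-" for r in rows) != 1
        ]
        expected = ["".join(r[j] for j in keep) for r in rows]
        if not keep:
            with pytest.raises(DegenerateAlignmentError):
                trim_alignment(rows)
        else:
            assert trim_alignment(rows) == expected


def taxon_map(**kwargs):
    return lambda leaf: kwargs[leaf]


class TestExtractSupports:
    def test_exemplar_tree(self):
        tree = read_newick_supports("((m1:1,m2:1)0.9:1,(b1:1,focal:1)0.86:1);")
        a = extract_monophyly_supports(
            tree, "focal",
            {"m1": METAZOA, "m2": METAZOA, "b1": "Eubacteria"},
        )
        assert a.focal_supports["Eubacteria"] == 0.86
        assert a.supports[METAZOA] == 0.9
        assert a.n_nonfocal_leaves == 3 and a.n_taxa_present == 2

    def test_star_tree_has_absent_supports(self):
        tree = read_newick_supports("(a:1,b:1,c:1,focal:1);")
        a = extract_monophyly_supports(
            tree, "focal", {"a": METAZOA, "b": METAZOA, "c": "Fungi"},
        )
        # multi-leaf taxa have no matching bipartition at all on a star tree
        assert a.supports[METAZOA] is None
        assert a.focal_supports[METAZOA] is None

    def test_focal_missing_rejected(self):
        tree = read_newick_supports("((a:1,b:1)0.9:1,(c:1,d:1)0.8:1);")
        with pytest.raises(ValueError):
            extract_monophyly_supports(tree, "zz", dict.fromkeys("abcd", METAZOA))

    @given(st.data())
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_agrees_with_exhaustive_bipartition_enumeration(self, data):
        """On random trees (<= 12 leaves), extraction equals brute force over
        every edge bipartition."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        n_leaves = data.draw(st.integers(4, 12))
        taxa = ["Metazoa", "Eubacteria", "Fungi"]
        labels = [f"L{i}" for i in range(n_leaves - 1)] + ["focal"]
        mapping = {l: taxa[rng.integers(0, 3)] for l in labels if l != "focal"}

        # random binary tree by sequential leaf attachment, random supports
        import dendropy

        taxon_ns = dendropy.TaxonNamespace(labels)
        tree = dendropy.Tree(taxon_namespace=taxon_ns)
        nodes = []
        for i, lab in enumerate(labels):
            leaf = dendropy.Node(taxon=taxon_ns.get_taxon(lab))
            if i == 0:
                tree.seed_node.add_child(leaf)
            else:
                target = nodes[rng.integers(0, len(nodes))]
                parent = target.parent_node or tree.seed_node
                new = dendropy.Node()
                parent.remove_child(target)
                parent.add_child(new)
                new.add_child(target)
                new.add_child(leaf)
            nodes.append(leaf)
        for node in tree:
            node.support = (
                None if node.is_leaf() or node.parent_node is None
                else float(np.round(rng.random(), 3))
            )

        a = extract_monophyly_supports(tree, "focal", mapping)

        # oracle: enumerate every edge side and its complement
        all_leaves = frozenset(labels)
        sides = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            sides.append((side, node.support))

        def oracle(target):
            direct = [s for side, s in sides if side == target]
            matches = direct or [
                s for side, s in sides if (all_leaves - side) == target
            ]
            if not matches:
                return "missing"
            numeric = [s for s in matches if s is not None]
            return max(numeric) if numeric else None

        for taxon in set(mapping.values()):
            tset = frozenset(l for l, t in mapping.items() if t == taxon)
            expected = oracle(tset)
            got = a.supports[taxon]
            assert (got is None and expected in (None, "missing")) or got == expected
            expected_f = oracle(tset | {"focal"})
            got_f = a.focal_supports[taxon]
            assert (got_f is None and expected_f in (None, "missing")) or got_f == expected_f


def assessment(**kwargs):
    defaults = dict(
        transcript_id="t", supports={}, focal_supports={},
        separation_support=None, n_nonfocal_leaves=6, n_taxa_present=3,
    )
    defaults.update(kwargs)
    return PhyloAssessment(**defaults)


class TestAssignGroup:
    def test_only_metazoan_hits_is_group_1(self):
        a = assessment(only_metazoan_hits=True, n_nonfocal_leaves=1, n_taxa_present=1)
        assert assign_group(a) == 1

    def test_strong_metazoan_monophyly_is_group_1(self):
        a = assessment(focal_supports={METAZOA: 0.9})
        assert assign_group(a) == 1

    def test_too_few_sequences_is_group_3(self):
        a = assessment(n_nonfocal_leaves=2, n_taxa_present=2)
        assert assign_group(a) == 3

    def test_single_taxon_is_group_3(self):
        a = assessment(n_nonfocal_leaves=5, n_taxa_present=1)
        assert assign_group(a) == 3

    def test_strong_foreign_monophyly_is_group_5(self):
        a = assessment(
            focal_supports={"Eubacteria": 0.86},
            supports={METAZOA: 0.9},
            separation_support=0.9,
        )
        assert assign_group(a) == 5

    def test_rejected_metazoan_monophyly_is_group_4(self):
        a = assessment(separation_support=0.92, focal_supports={"Eubacteria": 0.4})
        assert assign_group(a) == 4

    def test_weak_everything_is_group_2(self):
        a = assessment(
            focal_supports={"Eubacteria": 0.5, METAZOA: 0.5},
            separation_support=0.5,
        )
        assert assign_group(a) == 2

    def test_absent_support_never_passes(self):
        a = assessment(focal_supports={METAZOA: None, "Fungi": None},
                       separation_support=None)
        assert assign_group(a) == 2

    def test_raising_s_min_never_promotes_out_of_group_2(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = assessment(
                focal_supports={
                    METAZOA: float(rng.random()), "Fungi": float(rng.random())
                },
                separation_support=float(rng.random()),
            )
            lo = assign_group(a, s_min=0.6)
            hi = assign_group(a, s_min=0.9)
            if lo == 2:
                assert hi == 2

    def test_every_assessment_maps_to_exactly_one_group(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            a = assessment(
                focal_supports={
                    t: (None if rng.random() < 0.3 else float(rng.random()))
                    for t in (METAZOA, "Fungi", "Eubacteria")
                },
                separation_support=(None if rng.random() < 0.3 else float(rng.random())),
                n_nonfocal_leaves=int(rng.integers(0, 8)),
                n_taxa_present=int(rng.integers(1, 4)),
                only_metazoan_hits=bool(rng.random() < 0.1),
            )
            assert assign_group(a) in {1, 2, 3, 4, 5}


class TestSummarizeGroups:
    def test_empty_input_gives_zero_table(self):
        s = summarize_groups([])
        assert s["total"] == 0 and all(v == 0 for v in s["counts"].values())

    def test_noiseless_synthetic_set_fully_recovered(self):
        params = SimParams(
            n_transcripts=400, foreign_fraction=0.3, misleading_rate=0.0,
            support_alpha=1e6, support_beta=1e-3, seed=21,
        )
        _, truth = generate_hit_table(params)
        trees, _ = generate_trees(truth, params)
        assessments = []
        for tid, nwk in trees.items():
            a = extract_monophyly_supports(
                read_newick_supports(nwk), tid, taxon_of_leaf
            )
            assign_group(a)
            assessments.append(a)
        s = summarize_groups(assessments)
        assert s["counts"][5] == s["total"] > 0
        assert s["verified_rate"] == 1.0

    def test_no_metazoan_transcripts_count_as_verified(self):
        a = assessment(focal_supports={"Fungi": 0.95})
        assign_group(a)
        s = summarize_groups([a], n_without_metazoan=3)
        assert s["combined_verified"] == 4
        assert s["combined_verified_rate"] == 1.0

    def test_misleading_trees_fall_into_group_1(self):
        params = SimParams(
            n_transcripts=400, foreign_fraction=0.3, misleading_rate=1.0,
            support_alpha=1e6, support_beta=1e-3, seed=22,
        )
        _, truth = generate_hit_table(params)
        trees, _ = generate_trees(truth, params)
        groups = set()
        for tid, nwk in trees.items():
            a = extract_monophyly_supports(
                read_newick_supports(nwk), tid, taxon_of_leaf
            )
            groups.add(assign_group(a))
        assert groups == {1}


class TestCalibration:
    def test_calibration_recovers_generating_threshold(self):
        rng = np.random.default_rng(9)
        assessments, recorded = [], []
        for _ in range(150):
            s = float(rng.random())
            a = assessment(focal_supports={"Eubacteria": s}, separation_support=None)
            assessments.append(a)
            recorded.append(5 if s >= 0.8 else 2)
        fitted = calibrate_s_min(assessments, recorded)
        assert abs(fitted - 0.8) <= 0.02


class TestSupportTreeStandIn:
    @staticmethod
    def _clade_sequences(rng, n_per=3, length=300):
        """Two well-separated clades of similar sequences."""
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = {}
        for clade, base in (("A", rng.integers(0, 20, size=length)),
                            ("B", rng.integers(0, 20, size=length))):
            for i in range(n_per):
                mutated = base.copy()
                idx = rng.choice(length, size=10, replace=False)
                mutated[idx] = rng.integers(0, 20, size=10)
                seqs[f"{clade}{i}"] = "".join(alphabet[mutated])
        return seqs

    def test_too_few_sequences_signalled(self):
        with pytest.raises(TooFewSequencesError):
            build_support_tree({"a": "AC", "b": "AC", "c": "AC"})

    def test_bootstrap_zero_leaves_supports_absent(self):
        rng = np.random.default_rng(2)
        tree = build_support_tree(self._clade_sequences(rng), bootstrap_n=0, rng=3)
        assert all(getattr(n, "support", None) is None for n in tree)

    def test_clean_clades_recovered_with_high_support(self):
        rng = np.random.default_rng(4)
        seqs = self._clade_sequences(rng)
        tree = build_support_tree(seqs, bootstrap_n=50, rng=5)
        sides = set()
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if getattr(node, "support", None) is not None and node.support >= 0.95:
                sides.add(side)
        clade_a = frozenset({"A0", "A1", "A2"})
        clade_b = frozenset({"B0", "B1", "B2"})
        assert clade_a in sides or clade_b in sides

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        seqs = self._clade_sequences(rng)
        t1 = build_support_tree(seqs, bootstrap_n=20, rng=7)
        t2 = build_support_tree(seqs, bootstrap_n=20, rng=7)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
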