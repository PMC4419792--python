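"""Supported-clade detection, surrogate selection, reassembly, and counting."""
import numpy as np
import pytest

import copiievo as cv
from copiievo.formats import SequenceRecord, parse_newick
from copiievo.phylo import Msa
from copiievo.scrollsaw import (
    DEFAULT_THRESHOLDS,
    SelectionReport,
    SupergroupMap,
    default_taxon_of,
)

from oracles import random_unrooted_tree


def _rec(rid, seq, taxon, sg="SG"):
    return SequenceRecord(rid, taxon, sg, "C", seq)


# ---------------------------------------------------------------------------
# split_by_supergroup
# ---------------------------------------------------------------------------

class TestSplit:
    def _msa(self):
        rows = [
            _rec("a1_P", "MKVL", "a1", "G1"),
            _rec("a2_P", "MKVL", "a2", "G1"),
            _rec("b1_P", "MKVL", "b1", "G2"),
        ]
        return Msa(rows), SupergroupMap({"a1": "G1", "a2": "G1", "b1": "G2"})

    def test_partition_sizes(self):
        msa, sgmap = self._msa()
        subsets = cv.split_by_supergroup(msa, sgmap)
        assert sum(m.n_rows for m in subsets.values()) == msa.n_rows
        assert subsets["G1"].n_rows == 2

    def test_mask_propagates(self):
        msa, sgmap = self._msa()
        msa.mask[1] = False
        subsets = cv.split_by_supergroup(msa, sgmap)
        for sub in subsets.values():
            assert sub.mask.tolist() == msa.mask.tolist()

    def test_unmapped_taxon_named_in_error(self):
        msa, _ = self._msa()
        with pytest.raises(ValueError, match="b1"):
            cv.split_by_supergroup(msa, SupergroupMap({"a1": "G1", "a2": "G1"}))

    def test_singleton_subset_warns(self):
        msa, sgmap = self._msa()
        with pytest.warns(UserWarning, match="unanalyzable"):
            cv.split_by_supergroup(msa, sgmap)


# ---------------------------------------------------------------------------
# find_supported_clades
# ---------------------------------------------------------------------------

class TestSupportedClades:
    def test_threshold_application(self):
        tree = parse_newick("((a1_x:0.1,a2_x:0.1)90:0.2,(b1_x:0.1,b2_x:0.1)40:0.2);")
        calls = cv.find_supported_clades(tree, thresholds={"bootstrap": 50})
        assert [sorted(c.leaf_ids) for c in calls] == [["a1_x", "a2_x"]]

    def test_same_organism_clade_rejected(self):
        tree = parse_newick("((t1_x:0.1,t1_y:0.1)95:0.2,(b1_x:0.1,b2_x:0.1)95:0.2);")
        calls = cv.find_supported_clades(tree, thresholds={"bootstrap": 50})
        assert [sorted(c.leaf_ids) for c in calls] == [["b1_x", "b2_x"]]

    def test_dual_supports_must_both_pass(self):
        tree = parse_newick("((a1_x:0.1,a2_x:0.1)0.98/85:0.2,(b1_x:0.1,b2_x:0.1)0.95/30:0.2);")
        calls = cv.find_supported_clades(tree)
        assert [sorted(c.leaf_ids) for c in calls] == [["a1_x", "a2_x"]]

    def test_no_supports_is_error(self):
        tree = parse_newick("((a1_x:0.1,a2_x:0.1):0.2,b1_x:0.1,b2_x:0.1);")
        with pytest.raises(ValueError, match="unsupported"):
            cv.find_supported_clades(tree)

    def test_unrooted_complement_side_is_candidate(self):
        # trifurcating root: the complement of the supported cherry spans the rest
        tree = parse_newick("((a1_x:0.1,a2_x:0.1)99:0.5,b1_x:0.1,b2_x:0.1,b3_x:0.1);")
        tree.rooted = False
        calls = cv.find_supported_clades(tree, thresholds={"bootstrap": 50})
        sides = {frozenset(c.leaf_ids) for c in calls}
        assert frozenset({"b1_x", "b2_x", "b3_x"}) in sides

    def test_max_per_taxon_filters_conflated_clades(self):
        tree = parse_newick(
            "(((t1_x:0.1,t2_x:0.1)99:0.3,(t1_y:0.1,t2_y:0.1)99:0.3)99:0.2,(o1_z:0.1,o2_z:0.1)99:0.2);"
        )
        calls = cv.find_supported_clades(tree, thresholds={"bootstrap": 50}, max_per_taxon=1)
        sides = sorted(sorted(c.leaf_ids) for c in calls)
        # the 4-leaf group repeats t1/t2, so it breaks into the two paralog cherries
        assert ["t1_x", "t2_x"] in sides and ["t1_y", "t2_y"] in sides
        assert ["t1_x", "t1_y", "t2_x", "t2_y"] not in sides

    def test_reported_clades_are_disjoint_and_maximal(self, rng):
        for _ in range(20):
            tree = random_unrooted_tree(8, rng)
            for node in tree.iter_nodes():
                if not node.is_leaf and node is not tree.root:
                    node.supports = {"bootstrap": float(rng.integers(0, 101))}
            try:
                calls = cv.find_supported_clades(
                    tree, thresholds={"bootstrap": 50}, min_organisms=1
                )
            except ValueError:
                continue
            seen = set()
            for c in calls:
                assert not (c.leaf_ids & seen)
                seen |= c.leaf_ids


# ---------------------------------------------------------------------------
# surrogate selection
# ---------------------------------------------------------------------------

class TestSurrogates:
    def test_two_shortest_by_mrca_path(self):
        tree = parse_newick("(((a_x:0.05,b_x:0.10)90:0.1,c_x:0.30)90:0.2,(d_x:0.1,e_x:0.1)90:0.2);")
        clade = frozenset({"a_x", "b_x", "c_x"})
        assert cv.select_surrogates(tree, clade, k=2) == ["a_x", "b_x"]

    def test_tie_breaks_lexicographically(self):
        tree = parse_newick("((a_x:0.1,b_x:0.1,c_x:0.1)90:0.2,(d_x:0.1,e_x:0.1)90:0.2);")
        clade = frozenset({"a_x", "b_x", "c_x"})
        assert cv.select_surrogates(tree, clade, k=2) == ["a_x", "b_x"]

    def test_small_clade_returns_all(self):
        tree = parse_newick("((a_x:0.1,b_x:0.2)90:0.2,(d_x:0.1,e_x:0.1)90:0.2);")
        clade = frozenset({"a_x", "b_x"})
        assert cv.select_surrogates(tree, clade, k=2) == ["a_x", "b_x"]

    def test_terminal_metric(self):
        # a has short terminal branch but sits deep; terminal metric prefers it
        tree = parse_newick("(((a_x:0.01,b_x:0.5)90:0.4,c_x:0.05)90:0.2,(d_x:0.1,e_x:0.1)90:0.2);")
        clade = frozenset({"a_x", "b_x", "c_x"})
        assert cv.select_surrogates(tree, clade, k=2, metric="terminal") == ["a_x", "c_x"]

    def test_minimality_on_random_trees(self, rng):
        """No unselected clade member is strictly closer to the clade MRCA."""
        for _ in range(30):
            tree = random_unrooted_tree(int(rng.integers(6, 10)), rng)
            sides = [
                frozenset(n.leaf_names())
                for n in tree.iter_nodes()
                if n is not tree.root and not n.is_leaf
            ]
            sides = [s for s in sides if len(s) >= 3]
            if not sides:
                continue
            side = sides[int(rng.integers(len(sides)))]
            chosen = cv.select_surrogates(tree, side, k=2)
            node = next(
                n for n in tree.iter_nodes() if frozenset(n.leaf_names()) == side
            )

            def depth(leaf, top):
                d = 0.0
                while leaf is not top:
                    d += leaf.length
                    leaf = leaf.parent
                return d

            metric = {l.name: depth(l, node) for l in node.leaves()}
            worst_chosen = max(metric[c] for c in chosen)
            for other in side - set(chosen):
                assert metric[other] >= worst_chosen or np.isclose(metric[other], worst_chosen)


# ---------------------------------------------------------------------------
# pan dataset assembly and pruning
# ---------------------------------------------------------------------------

def _report(sg, surrogate_ids):
    clade = cv.CladeCall(
        frozenset(surrogate_ids) if len(surrogate_ids) > 1 else frozenset(surrogate_ids | {"pad"}),
        {"bootstrap": 99.0},
        frozenset(default_taxon_of(i) for i in surrogate_ids),
        frozenset({sg}),
        surrogates=sorted(surrogate_ids),
    )
    return SelectionReport(sg, [clade], [])


class TestPanAssembly:
    def _master(self, ids):
        return Msa([_rec(i, "MKVLWAAL", default_taxon_of(i)) for i in ids])

    def test_row_bookkeeping(self):
        ids = ["a1_P", "a2_P", "b1_P", "b2_P"]
        master = self._master(ids + ["c1_P"])
        pan = cv.assemble_pan_dataset(
            [_report("G1", {"a1_P", "a2_P"}), _report("G2", {"b1_P", "b2_P"})], master
        )
        assert sorted(pan.ids()) == sorted(ids)

    def test_outgroup_rows_added(self):
        master = self._master(["a1_P", "a2_P", "b1_P", "b2_P", "og1_Q", "og2_Q"])
        pan = cv.assemble_pan_dataset(
            [_report("G1", {"a1_P", "a2_P"}), _report("G2", {"b1_P", "b2_P"})],
            master,
            outgroup_ids=["og1_Q", "og2_Q"],
        )
        assert pan.n_rows == 6

    def test_columns_follow_master_mask(self):
        master = self._master(["a1_P", "a2_P", "b1_P", "b2_P"])
        master.mask[2] = False
        pan = cv.assemble_pan_dataset(
            [_report("G1", {"a1_P", "a2_P"}), _report("G2", {"b1_P", "b2_P"})], master
        )
        assert pan.n_kept_columns == master.n_kept_columns

    def test_missing_id_is_error(self):
        master = self._master(["a1_P", "a2_P", "b1_P"])
        with pytest.raises(KeyError):
            cv.assemble_pan_dataset(
                [_report("G1", {"a1_P", "zz_P"})], master
            )


class TestPruneAndReanalyze:
    def _pan(self, small_sec24_family):
        records, _ = small_sec24_family
        return Msa(list(records))

    def test_remove_nothing_reproduces_tree(self, small_sec24_family):
        pan = self._pan(small_sec24_family)
        _, t1 = cv.prune_and_reanalyze(pan, [], n_reps=20, seed=5)
        t2 = cv.bootstrap_tree(pan, n_reps=20, seed=5)
        assert t1.newick() == t2.newick()

    def test_outgroup_removal(self, small_sec24_family):
        pan = self._pan(small_sec24_family)
        out = [i for i in pan.ids() if i.endswith("Sec24III")]
        provenance = []
        sub, tree = cv.prune_and_reanalyze(pan, out, n_reps=10, seed=1, provenance=provenance)
        assert not any(l.endswith("Sec24III") for l in tree.leaf_names())
        assert provenance[0]["removed"] == sorted(out)

    def test_too_few_rows_rejected(self, small_sec24_family):
        pan = self._pan(small_sec24_family)
        with pytest.raises(ValueError):
            cv.prune_and_reanalyze(pan, pan.ids()[:-2], n_reps=10)

    def test_long_branch_rows_break_then_restore_ingroup_support(self, small_scaffold):
        """Random outgroup rows behave as infinitely long branches; removing
        them lets both ingroup paralog clades reach bootstrap >= 50."""
        from copiievo.simulate import DEFAULT_MODEL, _sample_root
        from copiievo.formats import canonical_side

        scn = cv.load_scenario("sec23")
        scn.root_length = 300
        ok = 0
        n_reps = 20
        for seed in range(n_reps):
            records, _ = cv.simulate_family(small_scaffold, scn, seed)
            rng = np.random.default_rng(1000 + seed)
            decoys = [
                _rec(f"og{i}_Z", _sample_root(300, DEFAULT_MODEL, rng), f"og{i}")
                for i in range(3)
            ]
            pan = Msa(list(records) + decoys)
            sub, tree = cv.prune_and_reanalyze(
                pan, [d.id for d in decoys], n_reps=50, seed=seed
            )
            sides = tree.bipartitions()
            all_leaves = frozenset(tree.leaf_names())
            good = 0
            for paralog in ("Sec23A", "Sec23B"):
                side = frozenset(l for l in tree.leaf_names() if l.endswith(paralog))
                entry = sides.get(canonical_side(side, all_leaves))
                if entry and entry.get("bootstrap", 0.0) >= 50.0:
                    good += 1
            ok += good == 2
        assert ok >= 18


# ---------------------------------------------------------------------------
# ancient clade counting
# ---------------------------------------------------------------------------

class TestCountAncientClades:
    def _run(self, scenario_name, seed, scaffold, sites=300):
        scn = cv.load_scenario(scenario_name)
        scn.root_length = sites
        records, truth = cv.simulate_family(scaffold, scn, seed)
        result = cv.scrollsaw_analysis(records, n_boot=50, seed=seed)
        return result, truth

    def test_single_copy_family_counts_one(self, small_scaffold):
        result, truth = self._run("null", 2, small_scaffold)
        assert result.ancient.count == 1 == truth.ancient_paralog_count

    def test_two_separated_duplicate_clades_count_two(self, small_scaffold):
        result, truth = self._run("sec23", 2, small_scaffold)
        assert truth.ancient_paralog_count == 2
        assert result.ancient.count == 2

    def test_recent_duplication_not_counted_ancient(self, scaffold):
        result, truth = self._run("sed4", 3, scaffold)
        assert truth.ancient_paralog_count == 1
        assert result.ancient.count == 1
        # the young paralog pair is reported, not silently counted
        assert all(not c.leaf_ids <= {"Opi1_Sed4", "Opi2_Sed4"} for c in result.ancient.clades)

    def test_sec24_modal_recovery(self, small_scaffold):
        counts = []
        for seed in range(5):
            result, truth = self._run("sec24", seed, small_scaffold)
            counts.append(result.ancient.count)
        assert max(set(counts), key=counts.count) == 3
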