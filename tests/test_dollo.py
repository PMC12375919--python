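import dendropy
import numpy as np
import pytest

from pseudoclock.dollo import (
    BranchAssignment,
    CharacterMatrix,
    annotate_tree_with_counts,
    branch_counts,
    counts_table,
    homoplasy_screen,
    map_origin,
)


def make_matrix(rows):
    return CharacterMatrix(rows=rows)


class TestMapOrigin:
    def test_single_carrier_terminal_branch(self, tiny_tree_3):
        node = map_origin(tiny_tree_3, {"A"})
        assert node.is_leaf() and node.taxon.label == "A"

    def test_two_carriers_internal_branch(self, tiny_tree_3):
        node = map_origin(tiny_tree_3, {"A", "B"})
        tips = {l.taxon.label for l in node.leaf_iter()}
        assert tips == {"A", "B"}

    def test_non_sister_carriers_map_to_root(self, tiny_tree_3):
        node = map_origin(tiny_tree_3, {"A", "C"})
        assert node is tiny_tree_3.seed_node

    def test_unknown_tip_rejected(self, tiny_tree_3):
        with pytest.raises(ValueError, match="not in tree"):
            map_origin(tiny_tree_3, {"Z"})

    def test_empty_carriers_rejected(self, tiny_tree_3):
        with pytest.raises(ValueError, match="empty"):
            map_origin(tiny_tree_3, set())

    def test_polytomy_mrca_assigned_to_polytomy_branch(self):
        tree = dendropy.Tree.get(data="((A,B,C),D);", schema="newick")
        tree.is_rooted = True
        node = map_origin(tree, {"A", "C"})
        assert {l.taxon.label for l in node.leaf_iter()} == {"A", "B", "C"}


class TestBranchCounts:
    def test_private_mutations_stay_terminal(self, tiny_tree_4):
        rows = {
            f"m{i}": {t: "present" if t == tip else "absent" for t in "ABCD"}
            for i, tip in enumerate(["A", "B", "C", "D", "A"])
        }
        asg = branch_counts(make_matrix(rows), tiny_tree_4)
        assert sum(asg.branch_counts.values()) == 5
        assert asg.branch_counts["A"] == 2
        assert asg.tip_private_counts == {"A": 2, "B": 1, "C": 1, "D": 1}

    def test_universal_mutation_at_root(self, tiny_tree_4):
        rows = {"m1": {t: "present" for t in "ABCD"}}
        asg = branch_counts(make_matrix(rows), tiny_tree_4)
        assert asg.branch_counts == {"mrca(A,B,C,D)": 1}
        assert asg.root_spanning == ("m1",)

    def test_mixed_matrix_hand_enumeration(self, tiny_tree_4):
        rows = {
            "shared_AB": {
                "A": "present", "B": "present", "C": "absent", "D": "absent"
            },
            "private_A": {
                "A": "present", "B": "absent", "C": "absent", "D": "absent"
            },
        }
        asg = branch_counts(make_matrix(rows), tiny_tree_4)
        assert asg.branch_counts == {"mrca(A,B)": 1, "A": 1}
        assert asg.origins == {"shared_AB": "mrca(A,B)", "private_A": "A"}

    def test_empty_matrix_empty_assignment(self, tiny_tree_4):
        rows = {"m1": {t: "absent" for t in "ABCD"}}
        asg = branch_counts(make_matrix(rows), tiny_tree_4)
        assert asg.total_mapped == 0
        assert counts_table(asg).empty

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_conservation_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(4, 12))
        taxa = [f"t{i}" for i in range(n_tips)]
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n_tips,
            rng=__import__("random").Random(seed),
        )
        for leaf, label in zip(tree.leaf_node_iter(), taxa):
            leaf.taxon.label = label
        rows = {}
        n_mut = int(rng.integers(1, 20))
        for i in range(n_mut):
            states = rng.random(n_tips) < 0.4
            rows[f"m{i}"] = {
                t: "present" if s else "absent" for t, s in zip(taxa, states)
            }
        matrix = make_matrix(rows)
        asg = branch_counts(matrix, tree)
        n_with_carriers = sum(
            1 for m in rows if matrix.carriers(m)
        )
        assert sum(asg.branch_counts.values()) == n_with_carriers
        assert len(asg.origins) == n_with_carriers

    def test_dollo_consistency_clade_carriers(self, tiny_tree_4):
        # carriers exactly one clade: descendants of the origin reproduce
        # the carrier set
        rows = {
            "m": {"A": "present", "B": "present", "C": "absent", "D": "absent"}
        }
        matrix = make_matrix(rows)
        asg = branch_counts(matrix, tiny_tree_4)
        node = map_origin(tiny_tree_4, matrix.carriers("m"))
        assert {l.taxon.label for l in node.leaf_iter()} == matrix.carriers("m")

    def test_missing_flip_to_present_moves_origin_rootward(self, tiny_tree_4):
        base = {"A": "present", "B": "absent", "C": "missing", "D": "absent"}
        with pytest.warns(UserWarning, match="missing"):
            before = branch_counts(make_matrix({"m": base}), tiny_tree_4)
        flipped = dict(base, C="present")
        after = branch_counts(make_matrix({"m": flipped}), tiny_tree_4)
        node_before = map_origin(tiny_tree_4, {"A"})
        node_after = map_origin(tiny_tree_4, {"A", "C"})
        clade_before = {l.taxon.label for l in node_before.leaf_iter()}
        clade_after = {l.taxon.label for l in node_after.leaf_iter()}
        assert clade_before <= clade_after  # strictly rootward or equal
        assert before.origins["m"] == "A"
        assert after.origins["m"] == "mrca(A,B,C,D)"


class TestHomoplasyScreen:
    def test_different_alleles_flagged_independent(self, tiny_tree_4):
        rows = {
            "geneX": {
                "A": "present", "B": "absent", "C": "present", "D": "absent"
            }
        }
        alleles = {"geneX": {"A": "stop@12", "C": "frameshift@40"}}
        flagged = homoplasy_screen(make_matrix(rows), tiny_tree_4, alleles)
        reasons = set(flagged["reason"])
        assert any("independent" in r for r in reasons)
        assert any("non-monophyletic" in r for r in reasons)

    def test_identical_descriptor_in_sisters_not_flagged(self, tiny_tree_4):
        rows = {
            "geneY": {
                "A": "present", "B": "present", "C": "absent", "D": "absent"
            }
        }
        alleles = {"geneY": {"A": "stop@12", "B": "stop@12"}}
        flagged = homoplasy_screen(make_matrix(rows), tiny_tree_4, alleles)
        assert flagged.empty

    def test_identical_descriptor_in_distant_tips_flagged(self, tiny_tree_4):
        rows = {
            "geneZ": {
                "A": "present", "B": "absent", "C": "present", "D": "absent"
            }
        }
        alleles = {"geneZ": {"A": "stop@12", "C": "stop@12"}}
        flagged = homoplasy_screen(make_matrix(rows), tiny_tree_4, alleles)
        assert list(flagged["reason"]) == [
            "carriers non-monophyletic (Dollo violation)"
        ]


class TestMatrixValidation:
    def test_all_missing_row_rejected(self):
        with pytest.raises(ValueError, match="all entries missing"):
            make_matrix({"m": {"A": "missing", "B": "missing"}})

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError, match="invalid states"):
            make_matrix({"m": {"A": "maybe"}})

    def test_from_dataframe_with_na(self):
        import pandas as pd

        df = pd.DataFrame(
            {"A": [1, 0], "B": [0, None]}, index=["m1", "m2"]
        )
        matrix = CharacterMatrix.from_dataframe(df)
        assert matrix.rows["m1"] == {"A": "present", "B": "absent"}
        assert matrix.rows["m2"] == {"A": "absent", "B": "missing"}

    def test_matrix_columns_must_be_tree_tips(self, tiny_tree_3):
        rows = {"m": {"A": "present", "Z": "absent"}}
        with pytest.raises(ValueError, match="not in tree"):
            branch_counts(make_matrix(rows), tiny_tree_3)


def test_annotated_newick_carries_counts(tiny_tree_4):
    rows = {
        "m1": {"A": "present", "B": "present", "C": "absent", "D": "absent"},
        "m2": {"A": "present", "B": "absent", "C": "absent", "D": "absent"},
    }
    asg = branch_counts(make_matrix(rows), tiny_tree_4)
    newick = annotate_tree_with_counts(tiny_tree_4, asg)
    assert "A[1]" in newick
    assert "1" in newick
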