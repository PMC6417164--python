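"""Haplotype phylogeny: NJ, Jukes-Cantor pruning likelihood, ML search and
ancestral annotation."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from haplopop import fto
from haplopop.hapfreq import table_from_frequencies
from haplopop.phylo import (
    HaplotypeTree,
    Node,
    annotate_ancestral,
    hamming_distance_matrix,
    jc_log_likelihood,
    ml_tree,
    neighbor_joining,
    optimize_branch_lengths,
    tree_from_newick,
    _jc_transition,
)

KEPT = sorted(set(range(1, 16)) - fto.DROPPED_POSITIONS)


def brute_force_jc_loglik(tree: HaplotypeTree, seqs: dict) -> float:
    """Exhaustive oracle: sum the joint probability over every assignment of
    ancestral states to the internal nodes."""
    states = "ACGT"
    idx = {c: i for i, c in enumerate(states)}
    internals = [n for n in tree.root.walk() if not n.is_leaf]
    L = len(next(iter(seqs.values())))
    lnl = 0.0
    for site in range(L):
        total = 0.0
        for combo in itertools.product(range(4), repeat=len(internals)):
            assign = dict(zip(map(id, internals), combo))
            p = 0.25  # root state prior
            ok = True
            for node in tree.root.walk():
                if node is tree.root:
                    continue
                parent = next(m for m in tree.root.walk() if node in m.children)
                ps = assign[id(parent)]
                cs = idx[seqs[node.name][site]] if node.is_leaf else assign[id(node)]
                p *= _jc_transition(node.length)[ps, cs]
            if ok:
                total += p
        lnl += np.log(total)
    return lnl


class TestHammingDistance:
    def test_published_yin_yang_cores_are_maximally_distant(self):
        D = hamming_distance_matrix(["GTTAATAACG", "ACAGGAGGTA"])
        assert D.iloc[0, 1] == 10

    def test_identical_and_single_site(self):
        D = hamming_distance_matrix(["AA", "AA", "AT"])
        assert D.iloc[0, 1] == 0
        assert D.iloc[0, 2] == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            hamming_distance_matrix(["AA", "AAA"])


class TestNeighborJoining:
    ADDITIVE = pd.DataFrame(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float,
    )

    def test_additive_fixture_recovered_exactly(self):
        """The 4-taxon additive matrix yields topology AB|CD with branch
        lengths A:1, B:2, C:3, D:4 and internal 1."""
        tree = neighbor_joining(self.ADDITIVE)
        assert frozenset({"A", "B"}) in tree.splits() or frozenset({"C", "D"}) in tree.splits()
        pd.testing.assert_frame_equal(
            tree.path_lengths(), self.ADDITIVE.astype(float), atol=1e-9, rtol=0
        )
        lengths = {n.name: n.length for n in tree.root.leaves()}
        internal = [n for n in tree.root.walk()
                    if not n.is_leaf and n is not tree.root]
        assert len(internal) == 1
        got = sorted([lengths["A"], lengths["B"], lengths["C"], lengths["D"],
                      internal[0].length])
        np.testing.assert_allclose(got, [1, 1, 2, 3, 4], atol=1e-9)

    def test_three_taxa_closed_form(self):
        D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("XYZ"), columns=list("XYZ"), dtype=float)
        tree = neighbor_joining(D)
        lengths = {n.name: n.length for n in tree.root.leaves()}
        assert lengths["X"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["Y"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["Z"] == pytest.approx((4 + 5 - 3) / 2)

    def test_ultrametric_matrix_reproduced(self):
        D = pd.DataFrame(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(D)
        pd.testing.assert_frame_equal(tree.path_lengths(), D, atol=1e-9, rtol=0)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(self.ADDITIVE.iloc[:2, :2])


class TestJukesCantorLikelihood:
    def test_zero_length_limit(self):
        tree = HaplotypeTree(root=Node(children=[Node("A", 1e-9), Node("B", 1e-9)]))
        lnl = jc_log_likelihood(tree, {"A": "A", "B": "A"})
        assert lnl == pytest.approx(np.log(0.25), abs=1e-7)

    def test_infinite_length_limit(self):
        tree = HaplotypeTree(root=Node(children=[Node("A", 50.0), Node("B", 50.0)]))
        lnl = jc_log_likelihood(tree, {"A": "A", "B": "C"})
        assert lnl == pytest.approx(np.log(1 / 16), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pruning_matches_exhaustive_oracle(self, seed):
        """Pruning equals the sum over all 4^internal ancestral assignments."""
        rng = np.random.default_rng(seed)
        names = [f"t{i}" for i in range(5)]
        seqs = {n: "".join(rng.choice(list("ACGT"), 10)) for n in names}
        dm = hamming_distance_matrix([seqs[n] for n in names])
        dm.index = dm.columns = names
        tree = neighbor_joining(dm)
        for n in tree.root.walk():
            if n is not tree.root:
                n.length = float(rng.uniform(0.01, 1.0))
        assert jc_log_likelihood(tree, seqs) == pytest.approx(
            brute_force_jc_loglik(tree, seqs), abs=1e-10
        )

    def test_invariant_to_rerooting(self):
        rng = np.random.default_rng(7)
        names = [f"t{i}" for i in range(4)]
        seqs = {n: "".join(rng.choice(list("ACGT"), 8)) for n in names}
        dm = hamming_distance_matrix([seqs[n] for n in names])
        dm.index = dm.columns = names
        tree = neighbor_joining(dm)
        for n in tree.root.walk():
            if n is not tree.root:
                n.length = float(rng.uniform(0.05, 0.5))
        base = jc_log_likelihood(tree, seqs)
        from haplopop.phylo import reroot_on_leaf_branch

        for name in names:
            rerooted = reroot_on_leaf_branch(tree, name)
            assert jc_log_likelihood(rerooted, seqs) == pytest.approx(base, abs=1e-9)

    def test_leaf_mismatch_rejected(self):
        tree = HaplotypeTree(root=Node(children=[Node("A", 0.1), Node("B", 0.1)]))
        with pytest.raises(ValueError, match="differ"):
            jc_log_likelihood(tree, {"A": "A", "C": "C"})


class TestMlTree:
    def test_three_taxa_single_topology(self):
        tree = ml_tree(["AAAA", "AATT", "TTTT"])
        assert sorted(tree.leaf_names) == ["AAAA", "AATT", "TTTT"]
        assert len(tree.root.children) == 3

    def test_recovers_generating_topology(self):
        """Four sequences split by a long internal branch: the generating
        topology (AB|CD) is recovered."""
        seqs = {"a": "AAAAAAAACC", "b": "AAAAAAAATT",
                "c": "GGGGGGGGCC", "d": "GGGGGGGGTT"}
        tree = ml_tree(seqs)
        assert frozenset({"a", "b"}) in tree.splits()

    def test_ml_no_worse_than_optimized_nj(self):
        rng = np.random.default_rng(5)
        names = [f"t{i}" for i in range(5)]
        seqs = {n: "".join(rng.choice(list("ACGT"), 12)) for n in names}
        dm = hamming_distance_matrix([seqs[n] for n in names])
        dm.index = dm.columns = names
        nj = neighbor_joining(dm)
        nj_lnl = optimize_branch_lengths(nj, seqs)
        ml = ml_tree(seqs)
        assert jc_log_likelihood(ml, seqs) >= nj_lnl - 1e-6

    def test_published_core_haplotype_clades(self, core_ml_tree):
        """The ML tree over the six published cores pairs the AFR-specific
        haplotypes and pairs the risk haplotypes, as in the published tree."""
        sp = core_ml_tree.splits()
        assert frozenset({"ATTAGAGGCG", "GTTAGAGGCG"}) in sp
        assert frozenset({"ACAGGAGGTA", "GCAGGAGGTA"}) in sp

    def test_taxa_bounds(self):
        with pytest.raises(ValueError, match="3..12"):
            ml_tree(["AA", "AT"])


class TestAncestralAnnotation:
    def test_root_placed_next_to_ancestral_majority_leaf(self):
        table = table_from_frequencies(
            {"AA": {"ANC": 0.6, "OTH": 0.1}, "TT": {"ANC": 0.4, "OTH": 0.9}}, [1, 2]
        )
        tree = HaplotypeTree(root=Node(children=[Node("AA", 0.3), Node("TT", 0.3)]))
        ann = annotate_ancestral(tree, table, "ANC")
        assert ann.rooted
        names = [c.name for c in ann.root.children]
        assert "AA" in names
        # both differing positions change along the single leaf-to-leaf path
        changed = [p for v in ann.branch_changes.values() for p in v]
        assert sorted(changed) == [1, 2]

    def test_published_cores_root_on_afr_maximum(self, core_ml_tree):
        """With AFR as the ancestral unit the root attaches to ATTAGAGGCG,
        the haplotype with the highest AFR frequency (0.35)."""
        table = table_from_frequencies(fto.CORE_HAPLOTYPE_FREQS, KEPT)
        ann = annotate_ancestral(core_ml_tree, table, "AFR", panel=fto.fto_panel())
        leaf_children = [c.name for c in ann.root.children if c.is_leaf]
        assert "ATTAGAGGCG" in leaf_children
        assert ann.leaf_annotations["ACAGGAGGTA"]["risk_load"] == 10
        assert ann.leaf_annotations["GTTAATAACG"]["risk_load"] == 0

    def test_tie_breaks_to_lexicographically_smallest(self):
        table = table_from_frequencies(
            {"AA": {"ANC": 0.3}, "CC": {"ANC": 0.3}, "GG": {"ANC": 0.3}}, [1, 2]
        )
        tree = HaplotypeTree(root=Node(children=[
            Node("CC", 0.1), Node("AA", 0.1), Node("GG", 0.1)]))
        ann = annotate_ancestral(tree, table, "ANC")
        assert any(c.name == "AA" for c in ann.root.children)

    def test_missing_unit_rejected(self):
        table = table_from_frequencies({"AA": {"U": 1.0}}, [1, 2])
        tree = HaplotypeTree(root=Node(children=[Node("AA", 0.1), Node("AT", 0.1)]))
        with pytest.raises(ValueError, match="not in table"):
            annotate_ancestral(tree, table, "NOPE")

    def test_parsimony_changes_bound_hamming_distance(self, core_ml_tree):
        """Summed per-branch changes along any leaf-to-leaf path are at least
        the Hamming distance of the two leaves."""
        table = table_from_frequencies(fto.CORE_HAPLOTYPE_FREQS, KEPT)
        ann = annotate_ancestral(core_ml_tree, table, "AFR")

        # path changes via states: distance between leaf states equals the
        # haplotype Hamming distance along the unique path
        leaves = {n.name: n for n in ann.root.leaves()}
        for a, b in itertools.combinations(leaves, 2):
            ham = sum(x != y for x, y in zip(a, b))
            path_changes = _path_change_count(ann, a, b)
            assert path_changes >= ham

    def test_newick_round_trip(self, core_ml_tree):
        tree = core_ml_tree
        back = tree_from_newick(tree.newick())
        assert sorted(back.leaf_names) == sorted(tree.leaf_names)
        assert back.splits() == tree.splits()
        D1, D2 = tree.path_lengths(), back.path_lengths()
        pd.testing.assert_frame_equal(D1, D2, atol=1e-8, rtol=0)


def _path_change_count(tree: HaplotypeTree, a: str, b: str) -> int:
    parent = {}
    for n in tree.root.walk():
        for c in n.children:
            parent[id(c)] = n
    leaves = {n.name: n for n in tree.root.leaves()}

    def ancestors(node):
        out = [node]
        while id(node) in parent:
            node = parent[id(node)]
            out.append(node)
        return out

    pa, pb = ancestors(leaves[a]), ancestors(leaves[b])
    common = next(x for x in pa if x in pb)
    count = 0
    for node in pa[:pa.index(common)] + pb[:pb.index(common)]:
        count += len(node.changes or [])
    return count
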