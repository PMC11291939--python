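"""Taxonomy parsing, lineage queries, and binarization enumeration."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xenoscan.taxonomy import (
    LineageRelation,
    TaxonomyError,
    TaxonomyTree,
    TaxonRecord,
    contract_resolved,
    double_factorial,
    enumerate_binarizations,
    n_binarizations,
    parse_taxdump,
)

from conftest import random_taxonomy


MINI_TSV = "1\t1\troot\n2\t1\tkingdom\n3\t1\tkingdom\n"

NCBI_DMP = (
    "1\t|\t1\t|\tno rank\t|\n"
    "2\t|\t1\t|\tsuperkingdom\t|\n"
    "3\t|\t1\t|\tsuperkingdom\t|\n"
)

NAMES_DMP = (
    "1\t|\troot\t|\t\t|\tscientific name\t|\n"
    "2\t|\tBacteria\t|\t\t|\tscientific name\t|\n"
    "2\t|\teubacteria\t|\t\t|\tsynonym\t|\n"
)


class TestParseTaxdump:
    def test_minimal_three_line_dump(self):
        tree = parse_taxdump(io.StringIO(MINI_TSV))
        assert tree.root == 1
        assert tree.children[1] == [2, 3]

    def test_ncbi_dialect_with_names(self):
        tree = parse_taxdump(io.StringIO(NCBI_DMP), io.StringIO(NAMES_DMP))
        assert tree.children[1] == [2, 3]
        assert tree.name(2) == "Bacteria"
        assert tree.name(3) == "3"  # no scientific name given

    def test_orphan_parent_is_hard_error(self):
        with pytest.raises(TaxonomyError, match="orphan.*4|4.*absent"):
            parse_taxdump(io.StringIO(MINI_TSV + "4\t9\tspecies\n"))

    def test_duplicate_taxid_is_hard_error(self):
        with pytest.raises(TaxonomyError, match="duplicate"):
            parse_taxdump(io.StringIO(MINI_TSV + "2\t1\tkingdom\n"))

    def test_ten_taxon_fixture_reports_one_degree4_polytomy(self):
        rows = ["1\t1\troot", "2\t1\tno rank"]
        rows += [f"{10+i}\t2\tno rank" for i in range(4)]   # degree-4 polytomy
        rows += ["3\t1\tno rank", "30\t3\tspecies", "31\t3\tspecies"]
        tree = parse_taxdump(io.StringIO("\n".join(rows) + "\n"))
        assert len(tree) == 9
        polys = tree.polytomies()
        assert polys == [2]
        assert len(tree.children[2]) == 4


class TestLca:
    def test_singleton_is_identity(self, demo_tax):
        assert demo_tax.lca([510]) == 510

    def test_caterpillar_forces_parent(self):
        tree = parse_taxdump(
            io.StringIO("1\t1\tr\n2\t1\tx\n3\t2\tx\n4\t3\tx\n5\t3\tx\n")
        )
        assert tree.lca([4, 5]) == 3

    def test_unknown_taxon_is_error(self, demo_tax):
        with pytest.raises(TaxonomyError, match="unknown"):
            demo_tax.lca([510, 999999])

    def test_agrees_with_ancestor_set_intersection_oracle(self):
        rng = np.random.default_rng(7)
        tax, _, _ = random_taxonomy(rng)
        # grow to ~50 leaves by attaching species under random internal nodes
        recs = [
            TaxonRecord(t, r.parent, r.rank, r.name) for t, r in tax.nodes.items()
        ]
        internal = [t for t in tax.nodes if tax.children[t]]
        nid = max(tax.nodes) + 1
        for _ in range(50):
            recs.append(TaxonRecord(nid, int(rng.choice(internal)), "species"))
            nid += 1
        big = TaxonomyTree(recs)
        nodes = list(big.nodes)
        for _ in range(200):
            a, b = rng.choice(nodes, size=2)
            expected = max(
                set(big.lineage(int(a))) & set(big.lineage(int(b))),
                key=big.depth,
            )
            assert big.lca([int(a), int(b)]) == expected

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_lca_monotone_under_union(self, demo_tax, data):
        leaves = demo_tax.leaves()
        a = data.draw(st.sets(st.sampled_from(leaves), min_size=1, max_size=4))
        b = data.draw(st.sets(st.sampled_from(leaves), min_size=1, max_size=4))
        joint = demo_tax.lca(a | b)
        assert demo_tax.is_ancestor(joint, demo_tax.lca(a))


class TestLineageRelation:
    def test_root_is_ancestor_of_any_focal(self, demo_tax):
        assert (
            demo_tax.lineage_relation(demo_tax.root, 5)
            == LineageRelation.ANCESTOR_OF_FOCAL
        )

    def test_focal_equals_itself(self, demo_tax):
        assert (
            demo_tax.lineage_relation(5, 5)
            == LineageRelation.EQUALS_OR_WITHIN_FOCAL
        )

    def test_polytomy_siblings_are_disjoint(self, demo_tax):
        # Viridiplantae and Oomycota sit side by side under the eukaryote polytomy
        assert demo_tax.lineage_relation(6, 9) == LineageRelation.DISJOINT
        assert demo_tax.lineage_relation(9, 6) == LineageRelation.DISJOINT


class TestBinarizations:
    def _star(self, m):
        recs = [TaxonRecord(1, 1)] + [TaxonRecord(10 + i, 1) for i in range(m)]
        return TaxonomyTree(recs)

    def test_binary_tree_yields_itself_once(self):
        tree = self._star(2)
        outs = list(enumerate_binarizations(tree))
        assert len(outs) == 1
        assert sorted(outs[0].tree.nodes) == sorted(tree.nodes)

    @pytest.mark.parametrize("m,count", [(3, 3), (4, 15), (5, 105)])
    def test_single_polytomy_counts_match_double_factorial(self, m, count):
        tree = self._star(m)
        outs = list(enumerate_binarizations(tree))
        assert len(outs) == count == double_factorial(2 * m - 3)
        assert n_binarizations(tree) == count
        # all distinct resolutions
        shapes = {tuple(sorted(map(str, b.provenance.values()))) for b in outs}
        assert len(shapes) == count

    def test_every_binarization_is_binary_and_contracts_back(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            tax, focal, _ = random_taxonomy(rng)
            rtax = tax.restrict(list(tax.leaves())[:8] + [focal])
            if n_binarizations(rtax) > 400:
                continue
            for b in enumerate_binarizations(rtax):
                # restriction leaves unary lineage anchors; what matters is
                # that no unresolved (>2-child) node survives
                assert b.tree.polytomies() == []
                back = contract_resolved(b)
                assert sorted(back.nodes) == sorted(rtax.nodes)
                assert all(
                    back.nodes[t].parent == rtax.nodes[t].parent for t in rtax.nodes
                )

    def test_refusal_beyond_max_leaves(self, demo_tax):
        with pytest.raises(TaxonomyError, match="polynomial"):
            list(enumerate_binarizations(demo_tax, max_leaves=10))

    def test_product_over_multiple_polytomies(self):
        recs = [TaxonRecord(1, 1)]
        recs += [TaxonRecord(2, 1), TaxonRecord(3, 1)]
        recs += [TaxonRecord(20 + i, 2) for i in range(3)]   # (2*3-3)!! = 3
        recs += [TaxonRecord(30 + i, 3) for i in range(4)]   # (2*4-3)!! = 15
        tree = TaxonomyTree(recs)
        assert n_binarizations(tree) == 45
        assert len(list(enumerate_binarizations(tree))) == 45


def test_newick_roundtrip(demo_tax):
    text = demo_tax.to_newick()
    back = TaxonomyTree.from_newick(text)
    assert sorted(back.nodes) == sorted(demo_tax.nodes)
    assert all(back.nodes[t].parent == demo_tax.nodes[t].parent for t in back.nodes)
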