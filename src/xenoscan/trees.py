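"""Light unrooted gene-tree container with newick I/O.

Gene trees come from single-gene phylogenies whose leaves are proteins
labelled ``proteinID|taxid``.  They are handled *unrooted* throughout: the
incongruence test never needs a root, which sidesteps the well-known
artifacts of automatic gene-tree rooting.  Newick parsing/serialisation is
delegated to dendropy; internally the tree is a plain adjacency structure,
which is what the stem-walk and subtree-extraction algorithms operate on.

Edge support conventions: values on a 0-100 scale (anything > 1) are
normalised to [0, 1]; edges without a recorded support are treated as fully
supported (1.0), which matters only for the ``min_support`` gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class GeneTreeError(ValueError):
    pass


@dataclass
class Leaf:
    protein: str
    taxid: int


def _ekey(u: int, v: int) -> frozenset:
    return frozenset((u, v))


@dataclass
class GeneTree:
    """Unrooted tree over integer node ids with protein/taxon-labelled leaves."""

    adj: dict[int, list[int]] = field(default_factory=dict)
    leaf: dict[int, Leaf] = field(default_factory=dict)
    length: dict[frozenset, float] = field(default_factory=dict)
    support: dict[frozenset, float] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, label_sep: str = "|") -> "GeneTree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
        gt = cls()
        ids: dict[object, int] = {}

        def nid(nd) -> int:
            if nd not in ids:
                ids[nd] = len(ids)
                gt.adj[ids[nd]] = []
            return ids[nd]

        supports_over_one = False
        for nd in dtree.preorder_node_iter():
            u = nid(nd)
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon else nd.label
                if lab is None or label_sep not in lab:
                    raise GeneTreeError(
                        f"leaf label {lab!r} lacks the {label_sep!r} protein/taxid separator"
                    )
                prot, taxid = lab.rsplit(label_sep, 1)
                gt.leaf[u] = Leaf(prot, int(taxid))
            for child in nd.child_nodes():
                v = nid(child)
                gt.adj[u].append(v)
                gt.adj[v].append(u)
                k = _ekey(u, v)
                gt.length[k] = child.edge.length if child.edge.length is not None else 0.0
                sup = None
                if not child.is_leaf():
                    lab = child.taxon.label if child.taxon else child.label
                    if lab is not None:
                        try:
                            sup = float(lab)
                        except ValueError:
                            sup = None
                if sup is not None and sup > 1.0:
                    supports_over_one = True
                gt.support[k] = sup
        if supports_over_one:
            for k, s in gt.support.items():
                if s is not None:
                    gt.support[k] = s / 100.0
        for k, s in gt.support.items():
            if s is None:
                gt.support[k] = 1.0
        gt._suppress_degree_two()
        gt.validate()
        return gt

    def _suppress_degree_two(self) -> None:
        # the parsed seed node of an unrooted newick has degree 2; merge its edges
        for node in [n for n in self.adj if len(self.adj[n]) == 2 and n not in self.leaf]:
            a, b = self.adj[node]
            ka, kb = _ekey(node, a), _ekey(node, b)
            k = _ekey(a, b)
            self.length[k] = self.length.pop(ka) + self.length.pop(kb)
            self.support[k] = min(self.support.pop(ka), self.support.pop(kb))
            self.adj[a] = [x if x != node else b for x in self.adj[a]]
            self.adj[b] = [x if x != node else a for x in self.adj[b]]
            del self.adj[node]

    def validate(self) -> None:
        if len(self.leaf) < 3:
            raise GeneTreeError("gene tree needs at least 3 leaves")
        prots = [l.protein for l in self.leaf.values()]
        if len(set(prots)) != len(prots):
            raise GeneTreeError("duplicate protein ids among leaves")

    # -- queries -----------------------------------------------------------

    def leaves(self) -> list[int]:
        return sorted(self.leaf)

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    def side_leaves(self, away: int, toward: int) -> list[int]:
        """Leaf node-ids on the ``toward`` side of the edge (away, toward)."""
        out, stack, seen = [], [toward], {away, toward}
        while stack:
            n = stack.pop()
            if n in self.leaf:
                out.append(n)
            for w in self.adj[n]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return sorted(out)

    def edge_support(self, u: int, v: int) -> float:
        return self.support[_ekey(u, v)]

    def edge_length(self, u: int, v: int) -> float:
        return self.length[_ekey(u, v)]

    # -- export ------------------------------------------------------------

    def to_newick(self, label_sep: str = "|") -> str:
        """Serialise, arbitrarily rooted at the lowest-id internal node."""
        internals = sorted(n for n in self.adj if n not in self.leaf)
        root = internals[0] if internals else min(self.adj)

        def fmt(node: int, parent: int | None) -> str:
            kids = [w for w in self.adj[node] if w != parent]
            if not kids:
                lf = self.leaf[node]
                core = f"{lf.protein}{label_sep}{lf.taxid}"
            else:
                core = "(" + ",".join(fmt(k, node) for k in kids) + ")"
                if parent is not None:
                    sup = self.edge_support(parent, node)
                    core += f"{sup:g}"
            if parent is not None:
                core += f":{self.edge_length(parent, node):g}"
            return core

        return fmt(root, None) + ";"


@dataclass
class RNode:
    """Minimal rooted tree node (used for reconciliation inputs)."""

    children: list["RNode"] = field(default_factory=list)
    label: str | None = None
    species: int | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list["RNode"]:
        return [n for n in self.postorder() if n.is_leaf()]


def rooted_from_genetree(gt: GeneTree, away: int, toward: int) -> RNode:
    """Extract the clade on the ``toward`` side of edge (away, toward), rooted there."""

    def build(node: int, parent: int) -> RNode:
        kids = [w for w in gt.adj[node] if w != parent]
        if not kids:
            lf = gt.leaf[node]
            return RNode(label=lf.protein, species=lf.taxid)
        return RNode(children=[build(k, node) for k in kids])

    return build(toward, away)


def rnode_from_newick(text: str, label_sep: str = "|") -> RNode:
    """Rooted newick → RNode; leaf labels ``proteinID|taxid`` or bare taxids."""
    dtree = dendropy.Tree.get(data=text, schema="newick")

    def conv(nd) -> RNode:
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon else nd.label
            if label_sep in lab:
                prot, taxid = lab.rsplit(label_sep, 1)
                return RNode(label=prot, species=int(taxid))
            return RNode(label=lab, species=int(lab))
        return RNode(children=[conv(c) for c in nd.child_nodes()])

    return conv(dtree.seed_node)
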