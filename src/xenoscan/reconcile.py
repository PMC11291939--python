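"""Duplication-loss reconciliation of focal subtrees against a species tree.

Each supported subtree, rooted at the transfer acceptor node (the stem-edge
endpoint inside the focal clade), is embedded into the target species tree
under the parsimony duplication-loss model via the classical LCA mapping:
every gene node maps to the LCA of its children's images, a node is a
duplication iff its image equals the image of at least one child, and
losses are counted along each gene edge as the species-tree path length
between the images minus one, plus one when the parent is a duplication.

The species tree must be binary; polytomies are resolved deterministically
(sorted child order, left-comb) with a warning, which can inflate the loss
count at those nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .taxonomy import TaxonomyError, TaxonomyTree, TaxonRecord
from .trees import RNode


@dataclass
class ReconciliationResult:
    duplications: int
    losses: int
    mapping: dict[int, int]  # id(gene node) keyed externally via node_of


def resolve_polytomies(species: TaxonomyTree) -> TaxonomyTree:
    """Binary copy of a species tree; polytomies combed in sorted child order."""
    polys = species.polytomies()
    if not polys:
        return species
    warnings.warn(
        f"species tree has {len(polys)} polytomies; resolving deterministically "
        "(sorted left-comb) — duplication/loss counts may be inflated there"
    )
    recs: list[TaxonRecord] = []
    counter = iter(range(-1, -10**9, -1))

    def emit(node: int, parent: int) -> None:
        src = species.nodes[node]
        recs.append(TaxonRecord(node, parent if node != species.root else node,
                                src.rank, src.name))
        kids = sorted(species.children[node])
        if len(kids) <= 2:
            for c in kids:
                emit(c, node)
            return
        anchor = node
        while len(kids) > 2:
            first = kids.pop(0)
            emit(first, anchor)
            new = next(counter)
            recs.append(TaxonRecord(new, anchor, "resolved"))
            anchor = new
        for c in kids:
            emit(c, anchor)

    emit(species.root, species.root)
    return TaxonomyTree(recs)


def lca_reconcile(sub: RNode, species: TaxonomyTree) -> ReconciliationResult:
    """Parsimony DL reconciliation of a rooted gene (sub)tree into ``species``."""
    species = resolve_polytomies(species)
    mapping: dict[int, int] = {}
    dups = 0
    losses = 0
    for node in sub.postorder():
        if node.is_leaf():
            if node.species not in species:
                raise TaxonomyError(f"species {node.species} absent from species tree")
            mapping[id(node)] = node.species
        else:
            mapping[id(node)] = species.lca([mapping[id(c)] for c in node.children])
    for node in sub.postorder():
        if node.is_leaf():
            continue
        m = mapping[id(node)]
        is_dup = any(mapping[id(c)] == m for c in node.children)
        if is_dup:
            dups += 1
        for c in node.children:
            dist = species.depth(mapping[id(c)]) - species.depth(m)
            losses += dist - 1 + (1 if is_dup else 0)
    return ReconciliationResult(dups, losses, mapping)


def min_duplications_bruteforce(sub: RNode, species: TaxonomyTree) -> int:
    """Exhaustive minimum duplication count over all valid embeddings.

    A valid embedding assigns each gene node a species node that is an
    ancestor-or-equal of the LCA image and a descendant-or-equal of its
    parent's assignment; a node is a speciation only when its children's
    images fall under distinct children of its own image.  Exponential —
    verification on small instances only.
    """
    species = resolve_polytomies(species)
    lca_map: dict[int, int] = {}
    order = list(sub.postorder())
    for node in order:
        if node.is_leaf():
            lca_map[id(node)] = node.species
        else:
            lca_map[id(node)] = species.lca([lca_map[id(c)] for c in node.children])

    def ancestors_upto(low: int, high: int) -> list[int]:
        # nodes on the path low..high inclusive (high ancestor-or-equal of low)
        out = [low]
        while out[-1] != high:
            out.append(species.parent(out[-1]))
        return out

    best = [float("inf")]
    preorder: list[RNode] = []

    def collect(n: RNode) -> None:
        preorder.append(n)
        for c in n.children:
            collect(c)

    collect(sub)
    assign: dict[int, int] = {}
    parents: dict[int, RNode] = {}

    def link(n: RNode) -> None:
        for c in n.children:
            parents[id(c)] = n
            link(c)

    link(sub)

    def score() -> int:
        ndup = 0
        for node in order:
            if node.is_leaf():
                continue
            m = assign[id(node)]
            kids = [assign[id(c)] for c in node.children]
            speciation = m not in kids and len(
                {species.child_toward(m, k) for k in kids}
            ) == len(kids)
            if not speciation:
                ndup += 1
        return ndup

    def enum(idx: int) -> None:
        if idx == len(preorder):
            best[0] = min(best[0], score())
            return
        node = preorder[idx]
        parent = parents.get(id(node))
        cap = species.root if parent is None else assign[id(parent)]
        if node.is_leaf():
            if not species.is_ancestor(cap, node.species):
                return
            assign[id(node)] = node.species
            enum(idx + 1)
            return
        if not species.is_ancestor(cap, lca_map[id(node)]):
            return
        for img in ancestors_upto(lca_map[id(node)], cap):
            assign[id(node)] = img
            enum(idx + 1)

    enum(0)
    return int(best[0])
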