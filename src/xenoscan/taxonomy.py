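"""Polytomous reference taxonomies: parsing, lineage queries, binarization.

The reference species tree used for incongruence testing is the NCBI
taxonomy, which is rooted but heavily unresolved: internal nodes may have
dozens to hundreds of children.  This module provides the tree container
with the LCA / lineage-relation queries the detection stage needs, and an
*exhaustive binarization enumerator* used purely as a verification oracle
for the polynomial incongruence test (a single polytomy of degree m has
(2m-3)!! rooted resolutions, so enumeration is only feasible on small
fixtures and refuses to run otherwise).

Two input dialects are accepted and auto-detected:

* the NCBI taxdump ``nodes.dmp``/``names.dmp`` format
  (``\\t|\\t``-separated fields, ``\\t|``-terminated lines);
* a minimal 3-column TSV ``taxid<TAB>parent<TAB>rank`` for fixtures.

Taxon ids are opaque integers; names are optional decoration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator, Sequence


class LineageRelation(Enum):
    """Position of a node relative to the focal clade."""

    ANCESTOR_OF_FOCAL = "ancestor_of_focal"
    EQUALS_OR_WITHIN_FOCAL = "equals_or_within_focal"
    DISJOINT = "disjoint"


class TaxonomyError(ValueError):
    """Malformed taxonomy input (orphans, duplicates, unknown ids)."""


@dataclass
class TaxonRecord:
    taxid: int
    parent: int
    rank: str = "no rank"
    name: str | None = None


@dataclass
class Binarization:
    """A fully resolved copy of a taxonomy plus how each polytomy was resolved.

    ``provenance`` maps each resolved polytomy's taxid to the nested-tuple
    shape chosen for its children.  Nodes introduced by resolution carry
    negative taxids and never collide with source ids.
    """

    tree: "TaxonomyTree"
    provenance: dict[int, tuple] = field(default_factory=dict)


class TaxonomyTree:
    """Rooted, possibly polytomous taxonomy with O(depth) lineage queries."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self.nodes: dict[int, TaxonRecord] = {}
        for rec in records:
            if rec.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {rec.taxid}")
            self.nodes[rec.taxid] = rec
        roots = [t for t, r in self.nodes.items() if r.parent == t or r.parent is None]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {roots}")
        self.root: int = roots[0]
        self.children: dict[int, list[int]] = {t: [] for t in self.nodes}
        for t, rec in self.nodes.items():
            if t == self.root:
                continue
            if rec.parent not in self.nodes:
                raise TaxonomyError(
                    f"orphan taxid {t}: parent {rec.parent} absent from taxonomy"
                )
            self.children[rec.parent].append(t)
        for kids in self.children.values():
            kids.sort()
        self._depth: dict[int, int] = {}
        self._compute_depths()

    # -- construction ------------------------------------------------------

    def _compute_depths(self) -> None:
        self._depth[self.root] = 0
        stack = [self.root]
        seen = 1
        while stack:
            node = stack.pop()
            for c in self.children[node]:
                self._depth[c] = self._depth[node] + 1
                stack.append(c)
                seen += 1
        if seen != len(self.nodes):
            unreachable = set(self.nodes) - set(self._depth)
            raise TaxonomyError(f"cycle or unreachable nodes: {sorted(unreachable)[:5]}")

    # -- basic queries -----------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid].parent

    def depth(self, taxid: int) -> int:
        return self._depth[taxid]

    def name(self, taxid: int) -> str:
        rec = self.nodes[taxid]
        return rec.name if rec.name is not None else str(taxid)

    def leaves(self, taxid: int | None = None) -> list[int]:
        """Leaf taxids under ``taxid`` (default: whole tree)."""
        start = self.root if taxid is None else taxid
        self._check(start)
        out, stack = [], [start]
        while stack:
            n = stack.pop()
            kids = self.children[n]
            if kids:
                stack.extend(kids)
            else:
                out.append(n)
        return out

    def descendants(self, taxid: int) -> list[int]:
        self._check(taxid)
        out, stack = [], list(self.children[taxid])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out

    def polytomies(self) -> list[int]:
        """Taxids of internal nodes with more than two children."""
        return sorted(t for t, k in self.children.items() if len(k) > 2)

    def lineage(self, taxid: int) -> list[int]:
        """Path root → taxid, inclusive."""
        self._check(taxid)
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.parent(path[-1]))
        return path[::-1]

    def _check(self, taxid: int) -> None:
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")

    # -- lineage algebra ---------------------------------------------------

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a nonempty set of taxa."""
        taxa = list(taxa)
        if not taxa:
            raise TaxonomyError("lca of empty taxon set")
        for t in taxa:
            self._check(t)
        cur = taxa[0]
        for t in taxa[1:]:
            a, b = cur, t
            while self._depth[a] > self._depth[b]:
                a = self.parent(a)
            while self._depth[b] > self._depth[a]:
                b = self.parent(b)
            while a != b:
                a, b = self.parent(a), self.parent(b)
            cur = a
        return cur

    def is_ancestor(self, anc: int, node: int, strict: bool = False) -> bool:
        self._check(anc)
        self._check(node)
        if anc == node:
            return not strict
        n = node
        while self._depth[n] > self._depth[anc]:
            n = self.parent(n)
        return n == anc

    def lineage_relation(self, node: int, focal: int) -> LineageRelation:
        """Classify ``node`` as strict ancestor of, within, or disjoint from ``focal``."""
        self._check(node)
        self._check(focal)
        if self.is_ancestor(node, focal, strict=True):
            return LineageRelation.ANCESTOR_OF_FOCAL
        if self.is_ancestor(focal, node):
            return LineageRelation.EQUALS_OR_WITHIN_FOCAL
        return LineageRelation.DISJOINT

    def child_toward(self, ancestor: int, descendant: int) -> int:
        """The child of ``ancestor`` on the path down to ``descendant``."""
        if not self.is_ancestor(ancestor, descendant, strict=True):
            raise TaxonomyError(f"{ancestor} is not a strict ancestor of {descendant}")
        n = descendant
        while self.parent(n) != ancestor:
            n = self.parent(n)
        return n

    # -- restriction and export -------------------------------------------

    def restrict(self, taxa: Iterable[int]) -> "TaxonomyTree":
        """Induced taxonomy on ``taxa``: keep them plus all their ancestors."""
        keep: set[int] = set()
        for t in taxa:
            keep.update(self.lineage(t))
        recs = [
            TaxonRecord(t, self.nodes[t].parent if t != self.root else t,
                        self.nodes[t].rank, self.nodes[t].name)
            for t in keep
        ]
        return TaxonomyTree(recs)

    def to_newick(self) -> str:
        def fmt(node: int) -> str:
            kids = self.children[node]
            if not kids:
                return str(node)
            return "(" + ",".join(fmt(c) for c in kids) + ")" + str(node)

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "TaxonomyTree":
        """Read a taxonomy written by :meth:`to_newick` (integer taxid labels)."""
        import dendropy

        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=False)
        recs: list[TaxonRecord] = []

        def label_of(nd) -> int:
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise TaxonomyError("newick taxonomy node without a taxid label")
            return int(lab)

        def walk(nd, parent_id: int | None) -> None:
            tid = label_of(nd)
            recs.append(TaxonRecord(tid, tid if parent_id is None else parent_id))
            for c in nd.child_nodes():
                walk(c, tid)

        walk(tree.seed_node, None)
        return cls(recs)


# -- taxdump parsing -------------------------------------------------------


def _split_dmp_line(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def parse_taxdump(
    nodes_stream: IO[str] | Iterable[str],
    names_stream: IO[str] | Iterable[str] | None = None,
) -> TaxonomyTree:
    """Parse NCBI ``nodes.dmp``/``names.dmp`` or the minimal 3-column TSV.

    The dialect is auto-detected per line: a ``\\t|\\t`` separator marks the
    full taxdump format, otherwise plain tab-separated ``taxid parent rank``
    is assumed.  Scientific names from ``names_stream`` are attached when
    given (the minimal dialect carries no names).
    """
    records: dict[int, TaxonRecord] = {}
    for raw in nodes_stream:
        if not raw.strip():
            continue
        fields = _split_dmp_line(raw) if "\t|" in raw else raw.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise TaxonomyError(f"unparseable nodes line: {raw!r}")
        taxid, parent = int(fields[0]), int(fields[1])
        rank = fields[2].strip() if len(fields) > 2 else "no rank"
        if taxid in records:
            raise TaxonomyError(f"duplicate taxid {taxid}")
        records[taxid] = TaxonRecord(taxid, parent, rank)
    if names_stream is not None:
        for raw in names_stream:
            if not raw.strip():
                continue
            fields = _split_dmp_line(raw) if "\t|" in raw else raw.rstrip("\n").split("\t")
            if len(fields) < 2:
                continue
            taxid, name = int(fields[0]), fields[1].strip()
            name_class = fields[3].strip() if len(fields) > 3 else "scientific name"
            if name_class == "scientific name" and taxid in records:
                records[taxid].name = name
    return TaxonomyTree(records.values())


# -- binarization enumeration (verification oracle) ------------------------


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def n_binarizations(tree: TaxonomyTree) -> int:
    """Number of full resolutions: product of (2m-3)!! over polytomies."""
    out = 1
    for p in tree.polytomies():
        out *= double_factorial(2 * len(tree.children[p]) - 3)
    return out


def _rooted_shapes(items: Sequence[int]) -> Iterator[tuple]:
    """All rooted binary shapes on labelled ``items`` (leaves are taxids).

    Shapes are nested 2-tuples.  Count is (2m-3)!! for m items, generated by
    the classical leaf-insertion recursion (insert the next item on every
    edge, or above the current root).
    """
    if len(items) == 1:
        yield items[0]
        return
    first, rest = items[0], items[1:]

    def insert_everywhere(shape, leaf) -> Iterator[tuple]:
        yield (shape, leaf)  # above the current root
        if isinstance(shape, tuple):
            left, right = shape
            for s in insert_everywhere(left, leaf):
                yield (s, right)
            for s in insert_everywhere(right, leaf):
                yield (left, s)

    def build(shape, remaining) -> Iterator[tuple]:
        if not remaining:
            yield shape
            return
        nxt, rem = remaining[0], remaining[1:]
        for s in insert_everywhere(shape, nxt):
            yield from build(s, rem)

    yield from build(first, list(rest))


def enumerate_binarizations(
    tree: TaxonomyTree, max_leaves: int = 16
) -> Iterator[Binarization]:
    """Yield every full resolution of every polytomy of ``tree``.

    Intended as a verification oracle on small fixtures only: the caller must
    pre-restrict the taxonomy; trees with more than ``max_leaves`` leaves are
    refused (use the polynomial incongruence test for production inputs).
    A fully binary input yields exactly one binarization (a copy of itself).
    """
    n_leaf = len(tree.leaves())
    if n_leaf > max_leaves:
        raise TaxonomyError(
            f"refusing to enumerate binarizations of a {n_leaf}-leaf taxonomy "
            f"(max_leaves={max_leaves}); use the polynomial incongruence test"
        )
    polys = tree.polytomies()
    shape_choices = [list(_rooted_shapes(tree.children[p])) for p in polys]
    counter = itertools.count(-1, -1)  # fresh negative ids for resolved nodes

    for combo in itertools.product(*shape_choices) if polys else [()]:
        recs: list[TaxonRecord] = []
        resolved: dict[int, tuple] = dict(zip(polys, combo))

        def emit(node: int, parent: int) -> None:
            src = tree.nodes[node]
            recs.append(TaxonRecord(node, parent if node != tree.root else node,
                                    src.rank, src.name))
            kids = tree.children[node]
            if node in resolved:
                _emit_shape(resolved[node], node)
            else:
                for c in kids:
                    emit(c, node)

        def _emit_shape(shape, parent: int) -> None:
            if isinstance(shape, tuple):
                new_id = next(counter)
                recs.append(TaxonRecord(new_id, parent, "resolved"))
                _emit_shape(shape[0], new_id)
                _emit_shape(shape[1], new_id)
            else:
                emit(shape, parent)

        emit(tree.root, tree.root)
        yield Binarization(TaxonomyTree(recs), dict(resolved))


def contract_resolved(binarization: Binarization) -> TaxonomyTree:
    """Undo a binarization: contract edges to nodes introduced by resolution."""
    tree = binarization.tree
    recs = []
    for t, rec in tree.nodes.items():
        if t < 0:
            continue
        p = rec.parent
        while p < 0:
            p = tree.nodes[p].parent
        recs.append(TaxonRecord(t, p if t != tree.root else t, rec.rank, rec.name))
    return TaxonomyTree(recs)
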