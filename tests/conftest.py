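"""Shared fixtures: the demo taxonomy and random fixture generators."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from xenoscan.synthetic import default_taxonomy
from xenoscan.taxonomy import TaxonomyTree, TaxonRecord, n_binarizations
from xenoscan.trees import GeneTree


@pytest.fixture(scope="session")
def demo_tax() -> TaxonomyTree:
    return default_taxonomy()


def random_taxonomy(rng: np.random.Generator) -> tuple[TaxonomyTree, int, list[int]]:
    """Random polytomous taxonomy (degrees ≤ 6) with a nested focal clade.

    Returns (tree, focal taxid, nonfocal species list).  The focal clade is
    nested 1-2 levels below its kingdom so that congruent placements (a
    neighbor inside a resolved ancestor) are reachable, and the root and
    kingdom nodes carry polytomies so that ambiguous placements are too.
    """
    next_id = [2]

    def fresh() -> int:
        next_id[0] += 1
        return next_id[0]

    recs = [TaxonRecord(1, 1)]
    nonfocal_species: list[int] = []
    n_kingdoms = int(rng.integers(2, 5))
    kingdom_ids = []
    for _ in range(n_kingdoms):
        k = fresh()
        recs.append(TaxonRecord(k, 1))
        kingdom_ids.append(k)
    host = kingdom_ids[0]
    # focal clade, optionally below an intermediate node with sibling species
    parent = host
    if rng.random() < 0.5:
        inter = fresh()
        recs.append(TaxonRecord(inter, host))
        sib = fresh()
        recs.append(TaxonRecord(sib, inter))
        nonfocal_species.append(sib)
        parent = inter
    focal = fresh()
    recs.append(TaxonRecord(focal, parent))
    focal_species = []
    for _ in range(int(rng.integers(2, 4))):
        s = fresh()
        recs.append(TaxonRecord(s, focal))
        focal_species.append(s)
    for _ in range(int(rng.integers(1, 3))):  # species beside the focal clade
        s = fresh()
        recs.append(TaxonRecord(s, host))
        nonfocal_species.append(s)
    for k in kingdom_ids[1:]:
        for _ in range(int(rng.integers(1, 6))):
            s = fresh()
            recs.append(TaxonRecord(s, k))
            nonfocal_species.append(s)
    return TaxonomyTree(recs), focal, nonfocal_species


def random_gene_tree(
    rng: np.random.Generator,
    focal_species: list[int],
    nonfocal_species: list[int],
    n_focal: int | None = None,
    n_nonfocal: int | None = None,
) -> GeneTree:
    """Random binary unrooted gene tree over sampled focal/nonfocal leaves."""
    n_focal = n_focal if n_focal is not None else int(rng.integers(1, 3))
    n_nonfocal = n_nonfocal if n_nonfocal is not None else int(rng.integers(3, 7))
    leaves = [
        f"f{i}|{rng.choice(focal_species)}" for i in range(n_focal)
    ] + [
        f"n{i}|{rng.choice(nonfocal_species)}" for i in range(n_nonfocal)
    ]
    parts = [f"{l}:0.1" for l in leaves]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})1.0:0.1")
    nwk = parts[0]
    if nwk.endswith("1.0:0.1"):
        nwk = nwk[: -len("1.0:0.1")]
    return GeneTree.from_newick(nwk + ";")


def random_oracle_fixture(rng: np.random.Generator, max_binarizations: int = 2000):
    """(gene tree, restricted taxonomy, full taxonomy, focal) for oracle checks."""
    while True:
        tax, focal, nonfocal = random_taxonomy(rng)
        focal_species = [s for s in tax.leaves(focal)]
        gt = random_gene_tree(rng, focal_species, nonfocal)
        taxa = {l.taxid for l in gt.leaf.values()} | {focal}
        rtax = tax.restrict(taxa)
        if n_binarizations(rtax) <= max_binarizations:
            return gt, rtax, tax, focal
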