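"""Synthetic fixtures with known ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here: a polytomous
reference taxonomy with a fungal focal kingdom, gene trees with planted
transfers (nested in a donor clade, polytomy-ambiguous, or congruent),
focal-subtree sizes drawn from the two competing generative models
(neutral birth-death → geometric; preferential attachment → Yule–Simon),
contig tables with planted contaminants, and domain tables with planted
gains and losses.  All draws go through a single seeded generator:
identical configurations give byte-identical outputs.

The default taxonomy mimics the real screening setting: a root polytomy of
kingdoms, an unresolved eukaryote radiation (Opisthokonta / Viridiplantae /
Oomycota), bacteria split into several phyla, and a resolved fungal clade
of three phyla with five species each — the target proteomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .contam import ContigTable, GeneEvidence, TopHitKingdom
from .detect import Classification
from .domains import DomainHit, DomainTable
from .taxonomy import TaxonomyTree, TaxonRecord

# well-known taxids of the default synthetic taxonomy
ROOT, EUK, BACT, ARCH = 1, 2, 3, 4
FUNGI, PLANTS, METAZOA, OPISTHO, OOMY = 5, 6, 7, 8, 9
FUNGAL_PHYLA = (51, 52, 53)
BACT_PHYLA = (31, 32, 33, 34)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_trees: int = 50
    scenario_weights: dict = field(
        default_factory=lambda: {"supported": 0.6, "ambiguous": 0.2, "congruent": 0.2}
    )
    duplication_regime: str = "preferential_attachment"  # or "birth_death"
    pa_alpha: float = 1.0
    bd_p: float = 0.47
    support_floor: float = 0.97        # minimum support drawn for defining edges
    low_support_fraction: float = 0.0  # fraction of trees given a weak stem edge
    n_contigs: int = 500
    genes_per_contig: int = 4
    contaminant_fraction: float = 0.1
    stage2_only_fraction: float = 0.05
    domain_gain_rate: float = 0.15
    domain_loss_rate: float = 0.1
    intronization_rate: float = 0.6    # introns per substitution per site


@dataclass
class PlantedTransfer:
    tree_id: str
    scenario: str
    expected: Classification
    member_proteins: list[str]
    member_taxa: list[int]
    donor_clade: int | None
    n1_taxa: list[int]
    n2_taxa: list[int]
    newick: str


def default_taxonomy() -> TaxonomyTree:
    """The fixed demo taxonomy (see module docstring); ~60 nodes, 3 polytomies."""
    recs = [
        TaxonRecord(ROOT, ROOT, "no rank", "root"),
        TaxonRecord(EUK, ROOT, "superkingdom", "Eukaryota"),
        TaxonRecord(BACT, ROOT, "superkingdom", "Bacteria"),
        TaxonRecord(ARCH, ROOT, "superkingdom", "Archaea"),
        TaxonRecord(OPISTHO, EUK, "clade", "Opisthokonta"),
        TaxonRecord(PLANTS, EUK, "kingdom", "Viridiplantae"),
        TaxonRecord(OOMY, EUK, "clade", "Oomycota"),
        TaxonRecord(FUNGI, OPISTHO, "kingdom", "Fungi"),
        TaxonRecord(METAZOA, OPISTHO, "kingdom", "Metazoa"),
        TaxonRecord(51, FUNGI, "phylum", "Chytridiomycota"),
        TaxonRecord(54, FUNGI, "no rank", "Terrestrial"),
        TaxonRecord(52, 54, "phylum", "Neocallimastigomycota"),
        TaxonRecord(53, 54, "phylum", "Mucoromycota"),
    ]
    # fungal phyla: binary caterpillars over 5 species each (resolved, so the
    # species tree used for reconciliation is binary by construction)
    for phylum in FUNGAL_PHYLA:
        s = [phylum * 10 + i for i in range(5)]
        i1, i2, i3 = phylum * 10 + 5, phylum * 10 + 6, phylum * 10 + 7
        recs += [
            TaxonRecord(s[0], phylum, "species"),
            TaxonRecord(i1, phylum, "no rank"),
            TaxonRecord(s[1], i1, "species"),
            TaxonRecord(i2, i1, "no rank"),
            TaxonRecord(s[2], i2, "species"),
            TaxonRecord(i3, i2, "no rank"),
            TaxonRecord(s[3], i3, "species"),
            TaxonRecord(s[4], i3, "species"),
        ]
    # bacterial phyla (root of each phylum polytomous over 4 species)
    for phylum in BACT_PHYLA:
        recs.append(TaxonRecord(phylum, BACT, "phylum"))
        for i in range(4):
            recs.append(TaxonRecord(phylum * 100 + i, phylum, "species"))
    for clade, base, n in ((PLANTS, 610, 4), (METAZOA, 710, 4), (OOMY, 910, 4),
                           (ARCH, 410, 2)):
        for i in range(n):
            recs.append(TaxonRecord(base + i, clade, "species"))
    return TaxonomyTree(recs)


def target_species_tree(taxonomy: TaxonomyTree) -> TaxonomyTree:
    """Species tree of the 15 target fungi (restriction of the taxonomy)."""
    species = [t for p in FUNGAL_PHYLA for t in taxonomy.leaves(p)]
    return taxonomy.restrict(species)


def target_taxa(taxonomy: TaxonomyTree) -> set[int]:
    return {t for p in FUNGAL_PHYLA for t in taxonomy.leaves(p)}


# -- size-sample generators ------------------------------------------------


def sample_yule_simon(n: int, alpha: float, seed: int | np.random.Generator) -> np.ndarray:
    """Yule–Simon(α) sample via the exponential-geometric mixture.

    W ~ Exponential(α), K | W ~ Geometric(e^{-W}) on support ≥ 1; the
    marginal pmf is α·B(k, α+1).
    """
    if n < 1 or alpha <= 0:
        raise ValueError("need n ≥ 1 and alpha > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = rng.exponential(1.0 / alpha, size=n)
    return rng.geometric(np.exp(-w))


def sample_birth_death_sizes(n: int, p: float, seed: int | np.random.Generator) -> np.ndarray:
    """Geometric(p) sizes on support ≥ 1 (neutral birth-death stationary law)."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.geometric(p, size=n)


# -- gene-tree planting ----------------------------------------------------


def _random_shape(items: list[str], rng: np.random.Generator) -> str:
    """Random binary newick shape (no lengths) over preformatted leaf strings."""
    parts = list(items)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return parts[0]


class _TreeWriter:
    """Newick assembly with exponential branch lengths and edge supports."""

    def __init__(self, rng: np.random.Generator, support_floor: float):
        self.rng = rng
        self.floor = support_floor

    def bl(self) -> float:
        return float(self.rng.exponential(0.3))

    def sup(self, low: bool = False) -> float:
        if low:
            return float(self.rng.uniform(0.3, 0.7))
        return float(self.rng.uniform(self.floor, 1.0))

    def leaf(self, protein: str, taxid: int) -> str:
        return f"{protein}|{taxid}:{self.bl():.4f}"

    def clade(self, parts: list[str], low: bool = False) -> str:
        return f"({','.join(parts)}){self.sup(low):.3f}:{self.bl():.4f}"


def _focal_members(
    cfg: SimulationConfig, taxonomy: TaxonomyTree, rng: np.random.Generator, tag: str
) -> tuple[list[str], list[int]]:
    if cfg.duplication_regime == "birth_death":
        size = int(sample_birth_death_sizes(1, cfg.bd_p, rng)[0])
    else:
        size = int(sample_yule_simon(1, cfg.pa_alpha, rng)[0])
    size = min(size, 40)  # keep trees tractable
    phylum = int(rng.choice(FUNGAL_PHYLA))
    species = taxonomy.leaves(phylum)
    taxa = [int(rng.choice(species))]
    for _ in range(size - 1):
        # posttransfer duplications stay in the recipient lineage: resample
        # near the acceptor species (same phylum)
        taxa.append(int(rng.choice(species)))
    prots = [f"{tag}x{i}" for i in range(size)]
    return prots, taxa


def plant_hgt_trees(
    config: SimulationConfig, taxonomy: TaxonomyTree
) -> tuple[list[str], list[PlantedTransfer]]:
    """Gene trees (newick) with one planted focal subtree each, plus truth.

    Scenarios: ``supported`` nests the focal clade two branchings deep in a
    single donor phylum; ``ambiguous`` places it between two eukaryote
    lineages that are separate children of the unresolved eukaryote
    radiation (every such placement is polytomy-ambiguous by construction);
    ``congruent`` places it next to a metazoan — inside Opisthokonta, the
    resolved ancestor of the focal kingdom.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.scenario_weights)
    weights = np.array([config.scenario_weights[k] for k in names], dtype=float)
    weights /= weights.sum()
    newicks: list[str] = []
    truths: list[PlantedTransfer] = []
    for idx in range(config.n_trees):
        tree_id = f"T{idx:04d}"
        scenario = str(rng.choice(names, p=weights))
        tw = _TreeWriter(rng, config.support_floor)
        low = rng.random() < config.low_support_fraction
        prots, taxa = _focal_members(config, taxonomy, rng, tree_id)
        # single-leaf focal subtrees sit on a plain leaf edge; larger ones get
        # a supported clade whose stem support exercises the min_support gate
        if len(prots) == 1:
            focal = tw.leaf(prots[0], taxa[0])
        else:
            shape = _random_shape([tw.leaf(p, t) for p, t in zip(prots, taxa)], rng)
            focal = f"{shape}{tw.sup(low):.3f}:{tw.bl():.4f}"

        if scenario == "supported":
            donor = int(rng.choice(BACT_PHYLA))
            dsp = taxonomy.leaves(donor)
            n1_t = [int(rng.choice(dsp))]
            n2_t = [int(t) for t in rng.choice(dsp, size=2)]
            rest_t = [int(t) for t in rng.choice(dsp, size=2)]
            out_t = [int(rng.choice(taxonomy.leaves(PLANTS))),
                     int(rng.choice(taxonomy.leaves(ARCH)))]
            n1 = tw.leaf(f"{tree_id}n1a", n1_t[0])
            n2 = tw.clade([tw.leaf(f"{tree_id}n2{i}", t) for i, t in enumerate(n2_t)])
            rest = tw.clade(
                [tw.clade([tw.leaf(f"{tree_id}r{i}", t) for i, t in enumerate(rest_t)]),
                 tw.clade([tw.leaf(f"{tree_id}o{i}", t) for i, t in enumerate(out_t)])]
            )
            inner = tw.clade([focal, n1], low=low)
            mid = tw.clade([inner, n2])
            nwk = f"({rest},{mid});"
            expected = (
                Classification.WEAK if low else Classification.SUPPORTED
            )
            truths.append(PlantedTransfer(
                tree_id, scenario, expected, prots, taxa, donor,
                n1_t, n2_t, nwk))
        elif scenario == "ambiguous":
            # neighbors from two eukaryote lineages that are distinct children
            # of the unresolved radiation (and not ancestors of the focal clade)
            k1, k2 = PLANTS, OOMY
            n1_t = [int(rng.choice(taxonomy.leaves(k1)))]
            n2_t = [int(t) for t in rng.choice(taxonomy.leaves(k2), size=2)]
            out_t = [int(t) for t in rng.choice(taxonomy.leaves(BACT_PHYLA[0]), size=3)]
            n1 = tw.leaf(f"{tree_id}n1a", n1_t[0])
            n2 = tw.clade([tw.leaf(f"{tree_id}n2{i}", t) for i, t in enumerate(n2_t)])
            rest = tw.clade([tw.leaf(f"{tree_id}o{i}", t) for i, t in enumerate(out_t)])
            inner = tw.clade([focal, n1], low=low)
            mid = tw.clade([inner, n2])
            nwk = f"({rest},{mid});"
            truths.append(PlantedTransfer(
                tree_id, scenario, Classification.WEAK, prots, taxa, None,
                n1_t, n2_t, nwk))
        else:  # congruent: neighbors inside Opisthokonta, the resolved ancestor
            n1_t = [int(rng.choice(taxonomy.leaves(METAZOA)))]
            n2_t = [int(t) for t in rng.choice(taxonomy.leaves(METAZOA), size=1)] + [
                int(rng.choice(taxonomy.leaves(PLANTS)))]
            out_t = [int(t) for t in rng.choice(taxonomy.leaves(BACT_PHYLA[1]), size=3)]
            n1 = tw.leaf(f"{tree_id}n1a", n1_t[0])
            n2 = tw.clade([tw.leaf(f"{tree_id}n2{i}", t) for i, t in enumerate(n2_t)])
            rest = tw.clade([tw.leaf(f"{tree_id}o{i}", t) for i, t in enumerate(out_t)])
            inner = tw.clade([focal, n1], low=low)
            mid = tw.clade([inner, n2])
            nwk = f"({rest},{mid});"
            truths.append(PlantedTransfer(
                tree_id, scenario, Classification.CONGRUENT, prots, taxa, None,
                n1_t, n2_t, nwk))
        newicks.append(nwk)
    return newicks, truths


# -- contig tables ---------------------------------------------------------


@dataclass
class ContigTruth:
    contaminant_proteins: list[str]
    stage2_only_proteins: list[str]


def plant_contig_table(config: SimulationConfig) -> tuple[ContigTable, ContigTruth]:
    """Contig table with planted contaminants.

    Contaminant contigs carry no target-homolog gene and no focal top hit
    (removed at stage 1); stage2-only contigs have a homolog but no focal
    top hit (removed at stage 2); all other contigs carry at least one gene
    with both kinds of vertical evidence.
    """
    if not 0 <= config.contaminant_fraction <= 1:
        raise ValueError("contaminant fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 1)
    contigs: dict[str, list[GeneEvidence]] = {}
    contaminants: list[str] = []
    stage2_only: list[str] = []
    n_cont = round(config.n_contigs * config.contaminant_fraction)
    n_s2 = round(config.n_contigs * config.stage2_only_fraction)
    for i in range(config.n_contigs):
        cid = f"contig{i:05d}"
        genes = []
        kind = "clean"
        if i < n_cont:
            kind = "contaminant"
        elif i < n_cont + n_s2:
            kind = "stage2"
        n_genes = int(rng.integers(1, config.genes_per_contig + 1))
        for j in range(n_genes):
            prot = f"{cid}g{j}"
            if kind == "contaminant":
                ev = GeneEvidence(prot, False, TopHitKingdom(
                    str(rng.choice(["nonfocal", "none"]))))
                contaminants.append(prot)
            elif kind == "stage2":
                ev = GeneEvidence(prot, j == 0, TopHitKingdom(
                    str(rng.choice(["nonfocal", "none"]))))
                stage2_only.append(prot)
            else:
                anchor = j == 0
                ev = GeneEvidence(
                    prot,
                    anchor or bool(rng.random() < 0.5),
                    TopHitKingdom.FOCAL if anchor or rng.random() < 0.5
                    else TopHitKingdom.NONFOCAL,
                )
            genes.append(ev)
        contigs[cid] = genes
    return ContigTable(contigs), ContigTruth(sorted(contaminants), sorted(stage2_only))


# -- domain tables ---------------------------------------------------------


@dataclass
class DomainTruth:
    gains: dict[str, set[str]]
    losses: dict[str, set[str]]


def plant_domain_table(
    call, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[DomainTable, DomainTruth]:
    """Domain table for one call with planted gains and losses.

    Every protein in the tree carries the subtree's core domain (clan CORE).
    Each xenolog independently gains a private clan (rate
    ``domain_gain_rate``) absent from all nonfocal leaves, and/or loses the
    ancestral clan ANC carried by every neighbor-clade sequence (rate
    ``domain_loss_rate``).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    table = DomainTable()
    gains: dict[str, set[str]] = {}
    losses: dict[str, set[str]] = {}
    core = DomainHit("PF00001", "CL_CORE")
    anc = DomainHit("PF00002", "CL_ANC")
    for p, _ in call.n1_proteins + call.n2_proteins:
        table.add(p, core)
        table.add(p, anc)
    for p, _ in call.nonfocal_proteins:
        if p not in table.hits:
            table.add(p, core)
    for i, (p, _) in enumerate(call.xenologs):
        table.add(p, core)
        if rng.random() < config.domain_gain_rate:
            gained = DomainHit(f"PF9{i:04d}", f"CL_GAIN{i}")
            table.add(p, gained)
            gains[p] = {gained.clan}
        if rng.random() < config.domain_loss_rate:
            losses[p] = {"CL_ANC"}
        else:
            table.add(p, anc)
    return table, DomainTruth(gains, losses)


# -- intronization ---------------------------------------------------------


def sample_intronization(
    n: int, rate: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(distances, intron counts): x ~ Exp(1), y ~ Poisson(rate·x)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.exponential(1.0, size=n)
    y = rng.poisson(rate * x)
    return x, y


# -- bundle writer ---------------------------------------------------------


def write_bundle(config: SimulationConfig, outdir) -> dict:
    """Write a full input bundle (trees, taxonomy TSV, ground truth JSON)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    taxonomy = default_taxonomy()
    with open(out / "taxonomy.tsv", "w") as fh:
        for t, rec in sorted(taxonomy.nodes.items()):
            fh.write(f"{t}\t{rec.parent}\t{rec.rank}\n")
    newicks, truths = plant_hgt_trees(config, taxonomy)
    trees_dir = out / "trees"
    trees_dir.mkdir(exist_ok=True)
    for truth, nwk in zip(truths, newicks):
        (trees_dir / f"{truth.tree_id}.nwk").write_text(nwk + "\n")
    table, ctruth = plant_contig_table(config)
    truth_doc = {
        "transfers": [
            {**asdict(t), "expected": t.expected.value} for t in truths
        ],
        "contaminants": ctruth.contaminant_proteins,
        "stage2_only": ctruth.stage2_only_proteins,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_doc, indent=1))
    return truth_doc
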