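"""End-to-end orchestration: screen → contam → detect → reconcile → stats.

The pipeline consumes a declarative :class:`RunConfig` (paths + stage
parameters), runs whichever stages have inputs, and writes three summary
tables plus a statistics report:

* ``cluster_summary.tsv`` — one row per focal subtree (classification,
  weak reason, donor, acceptor, sizes, DL counts);
* ``protein_summary.tsv`` — one row per xenolog of a supported subtree;
* ``organism_summary.tsv`` — xenolog counts per target taxon;
* ``stats_report.json`` — distribution fits over subtree sizes and
  posttransfer duplication counts.

The config is serialized next to the outputs so a run can be replayed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import contam as contam_mod
from . import detect as detect_mod
from . import stats as stats_mod
from .reconcile import lca_reconcile
from .taxonomy import TaxonomyTree, parse_taxdump
from .trees import GeneTree, rooted_from_genetree

log = logging.getLogger("xenoscan")


@dataclass
class RunConfig:
    taxonomy: str
    focal_taxid: int
    trees_dir: str
    out: str
    names: str | None = None
    species_tree: str | None = None          # newick with taxid labels
    target_taxa: list[int] = field(default_factory=list)
    hits: str | None = None
    gff: str | None = None
    target_homologs: str | None = None       # one protein id per line
    top_hits: str | None = None              # protein<TAB>focal|nonfocal|none
    min_support: float = 0.95
    max_focal_fraction: float = 0.5
    max_len: int = 2000
    size_window: tuple[int, int] = (1, 12)
    seed: int = 0
    label_sep: str = "|"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        if "size_window" in doc:
            doc["size_window"] = tuple(doc["size_window"])
        return cls(**doc)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the run report dict."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, default=str)
    )
    report: dict = {"counters": {}}

    with open(config.taxonomy) as fh:
        names = open(config.names) if config.names else None
        taxonomy = parse_taxdump(fh, names)
        if names:
            names.close()
    focal = config.focal_taxid

    # --- contamination filter (optional) ---------------------------------
    removed: set[str] = set()
    if config.gff:
        homologs = set()
        if config.target_homologs:
            homologs = {
                l.strip() for l in open(config.target_homologs) if l.strip()
            }
        tophits = {}
        if config.top_hits:
            for l in open(config.top_hits):
                if l.strip():
                    p, k = l.rstrip("\n").split("\t")[:2]
                    tophits[p] = k
        with open(config.gff) as fh:
            table = contam_mod.contig_table_from_gff(fh, homologs, tophits)
        r1, r2, _ = contam_mod.run_two_stage(table)
        removed = set(r1) | set(r2)
        with open(out / "removed_proteins.tsv", "w") as fh:
            contam_mod.write_removed_tsv(r1, r2, fh)
        report["counters"]["removed_stage1"] = len(r1)
        report["counters"]["removed_stage2"] = len(r2)
        log.info("contam: removed %d (stage 1) + %d (stage 2)", len(r1), len(r2))

    # --- detection --------------------------------------------------------
    target = set(config.target_taxa) or None
    species = None
    if config.species_tree:
        species = TaxonomyTree.from_newick(Path(config.species_tree).read_text())
    elif target:
        species = taxonomy.restrict(target)

    tree_files = sorted(Path(config.trees_dir).glob("*.nwk")) + sorted(
        Path(config.trees_dir).glob("*.newick")
    )
    rows, calls = [], []
    for tf in tree_files:
        gt = GeneTree.from_newick(tf.read_text(), label_sep=config.label_sep)
        subs = detect_mod.find_focal_subtrees(gt, taxonomy, focal)
        for i, sub in enumerate(subs):
            detect_mod.classify_subtree(
                gt, sub, taxonomy, focal, min_support=config.min_support
            )
            row = {
                "tree_id": tf.stem,
                "subtree_id": f"{tf.stem}.{i}",
                "classification": sub.classification.value,
                "weak_reason": sub.weak_reason.value if sub.weak_reason else "",
                "size": sub.size,
                "donor_taxid": sub.donor if sub.donor is not None else "",
                "donor_name": taxonomy.name(sub.donor) if sub.donor else "",
                "members": ";".join(
                    gt.leaf[l].protein for l in sub.members
                    if gt.leaf[l].protein not in removed
                ),
                "duplications": "",
                "losses": "",
                "acceptor": "",
            }
            if sub.classification == detect_mod.Classification.SUPPORTED:
                call = detect_mod.make_call(
                    tf.stem, gt, sub, taxonomy, focal, target_taxa=target
                )
                call.xenologs = [
                    (p, t) for p, t in call.xenologs if p not in removed
                ]
                if species is not None and call.xenologs:
                    mappable = [t for _, t in call.xenologs if t in species]
                    if mappable:
                        rsub = rooted_from_genetree(gt, *sub.stem)
                        try:
                            rec = lca_reconcile(
                                _prune_to_species(rsub, species), species
                            )
                            row["duplications"] = rec.duplications
                            row["losses"] = rec.losses
                        except Exception as exc:  # degenerate one-leaf prunings
                            log.warning("reconcile failed for %s: %s", tf.stem, exc)
                        row["acceptor"] = species.lca(mappable)
                if call.xenologs:
                    calls.append(call)
            rows.append(row)

    import pandas as pd

    cluster_summary = pd.DataFrame(
        rows,
        columns=[
            "tree_id", "subtree_id", "classification", "weak_reason", "size",
            "donor_taxid", "donor_name", "members", "duplications", "losses",
            "acceptor",
        ],
    )
    cluster_summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)

    prot_rows = [
        {
            "tree_id": c.tree_id,
            "protein_id": p,
            "taxid": t,
            "donor_taxid": c.subtree.donor,
        }
        for c in calls
        for p, t in c.xenologs
    ]
    protein_summary = pd.DataFrame(
        prot_rows, columns=["tree_id", "protein_id", "taxid", "donor_taxid"]
    )
    protein_summary.to_csv(out / "protein_summary.tsv", sep="\t", index=False)

    if len(protein_summary):
        org = (
            protein_summary.groupby("taxid")
            .size()
            .rename("n_xenologs")
            .reset_index()
        )
    else:
        org = pd.DataFrame(columns=["taxid", "n_xenologs"])
    org.to_csv(out / "organism_summary.tsv", sep="\t", index=False)

    report["counters"]["n_trees"] = len(tree_files)
    report["counters"]["n_subtrees"] = len(rows)
    report["counters"]["n_supported"] = int(
        (cluster_summary["classification"] == "supported").sum()
    ) if len(cluster_summary) else 0
    report["counters"]["n_xenologs"] = len(protein_summary)

    # --- statistics -------------------------------------------------------
    stats_doc: dict = {}
    sizes = [c.subtree.size for c in calls]
    lo, hi = config.size_window
    windowed = [s for s in sizes if lo <= s <= hi]
    if len(set(windowed)) >= 3:
        gfit = stats_mod.fit_geometric_ml(windowed, support=(lo, hi), truncated=True)
        stats_doc["subtree_sizes"] = {
            "n": len(sizes),
            "geometric_p_ml": gfit.parameter,
        }
        try:
            ggof = stats_mod.chisq_gof(windowed, "geometric", gfit.parameter,
                                       support=(lo, hi), ddof=1)
            ygof = stats_mod.chisq_gof(windowed, "yule_simon", 1.0,
                                       support=(lo, hi), ddof=0)
            stats_doc["subtree_sizes"]["geometric_gof_p"] = ggof.pvalue
            stats_doc["subtree_sizes"]["yule_simon1_gof_p"] = ygof.pvalue
        except ValueError as exc:  # sample too small to bin
            log.warning("size GOF skipped: %s", exc)
    dups = [
        int(d) for d in cluster_summary["duplications"]
        if d != "" and not pd.isna(d)
    ]
    dups_pos = [d for d in dups if d >= 1]
    if len(set(dups_pos)) >= 3:
        try:
            ygof2 = stats_mod.chisq_gof(dups_pos, "yule_simon", 2.0,
                                        support=(1, max(dups_pos)), ddof=0)
            stats_doc["duplications"] = {
                "n_positive": len(dups_pos),
                "yule_simon2_gof_p": ygof2.pvalue,
            }
        except ValueError as exc:
            log.warning("duplication GOF skipped: %s", exc)
    report["stats"] = stats_doc
    (out / "stats_report.json").write_text(json.dumps(report, indent=1))
    return report


def _prune_to_species(rsub, species: TaxonomyTree):
    """Drop leaves whose species are absent from the species tree."""
    from .trees import RNode

    def prune(node: RNode) -> RNode | None:
        if node.is_leaf():
            return node if node.species in species else None
        kids = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return RNode(children=kids)

    pruned = prune(rsub)
    if pruned is None or pruned.is_leaf():
        raise ValueError("subtree has fewer than two target-species leaves")
    return pruned
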