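"""Two-stage contig-level contamination filtering.

Genome assemblies of the focal kingdom frequently contain contigs from
co-sequenced organisms (endosymbionts, reagents).  Such contaminants mimic
transfers perfectly at the single-gene level — the contig context is the
discriminating evidence.  The filter keeps a focal protein only if it lies
on a contig carrying at least one gene with a homolog in another *target*
proteome (stage 1) and at least one gene whose top search hit is
focal-kingdom (stage 2, applied to stage-1 survivors).  Both criteria are
"at least one gene on the contig": whole contigs share fate.

Genes without any hit contribute to neither criterion; a top-hit tie
between focal and nonfocal is treated as focal (the filter removes clear
contaminants, retention is favored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable


class TopHitKingdom(Enum):
    FOCAL = "focal"
    NONFOCAL = "nonfocal"
    NONE = "none"


@dataclass
class GeneEvidence:
    protein: str
    has_target_homolog: bool = False
    top_hit_kingdom: TopHitKingdom = TopHitKingdom.NONE


@dataclass
class ContigTable:
    """contig id → ordered genes with their homology evidence."""

    contigs: dict[str, list[GeneEvidence]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for genes in self.contigs.values():
            for g in genes:
                if g.protein in seen:
                    raise ValueError(f"protein {g.protein} on more than one contig")
                seen.add(g.protein)

    def proteins(self) -> list[str]:
        return [g.protein for genes in self.contigs.values() for g in genes]


def _filter(
    table: ContigTable, keep_contig
) -> tuple[list[str], ContigTable]:
    removed: list[str] = []
    kept: dict[str, list[GeneEvidence]] = {}
    for contig, genes in table.contigs.items():
        if not genes:
            warnings.warn(f"contig {contig} has no genes; dropped from accounting")
            continue
        if keep_contig(genes):
            kept[contig] = genes
        else:
            removed.extend(g.protein for g in genes)
    return sorted(removed), ContigTable(kept)


def stage1_filter(table: ContigTable) -> tuple[list[str], ContigTable]:
    """Remove contigs with no gene homologous to another target proteome."""
    return _filter(table, lambda genes: any(g.has_target_homolog for g in genes))


def stage2_filter(table: ContigTable) -> tuple[list[str], ContigTable]:
    """Remove contigs with no gene whose top hit is focal-kingdom."""
    return _filter(
        table, lambda genes: any(g.top_hit_kingdom == TopHitKingdom.FOCAL for g in genes)
    )


def run_two_stage(
    table: ContigTable,
) -> tuple[list[str], list[str], ContigTable]:
    """Sequential filter: stage 2 applies to stage-1 survivors only."""
    removed1, survivors = stage1_filter(table)
    removed2, final = stage2_filter(survivors)
    return removed1, removed2, final


# -- builders --------------------------------------------------------------


def contig_table_from_gff(
    gff_stream: IO[str] | Iterable[str],
    target_homologs: set[str],
    top_hits: dict[str, TopHitKingdom | str],
) -> ContigTable:
    """Build a ContigTable from GFF3 gene rows plus homology evidence.

    Contig membership is the GFF3 ``seqid`` column; the protein id is the
    ``protein_id`` attribute (falling back to ``ID``) of gene/mRNA/CDS
    features.  ``target_homologs`` lists proteins with a homolog in another
    target proteome (computed excluding the gene's own proteome);
    ``top_hits`` maps protein → top-hit kingdom (missing → no hit).
    """
    contigs: dict[str, dict[str, GeneEvidence]] = {}
    for raw in gff_stream:
        if not raw.strip() or raw.startswith("#"):
            continue
        f = raw.rstrip("\n").split("\t")
        if len(f) < 9 or f[2] not in ("gene", "mRNA", "CDS"):
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        prot = attrs.get("protein_id") or attrs.get("ID")
        if prot is None:
            continue
        seqid = f[0]
        bucket = contigs.setdefault(seqid, {})
        if prot not in bucket:
            th = top_hits.get(prot, TopHitKingdom.NONE)
            if isinstance(th, str):
                th = TopHitKingdom(th)
            bucket[prot] = GeneEvidence(
                protein=prot,
                has_target_homolog=prot in target_homologs,
                top_hit_kingdom=th,
            )
    return ContigTable({c: list(genes.values()) for c, genes in contigs.items()})


def write_removed_tsv(
    removed1: Iterable[str], removed2: Iterable[str], stream: IO[str]
) -> None:
    stream.write("protein_id\tstage\n")
    for p in removed1:
        stream.write(f"{p}\t1\n")
    for p in removed2:
        stream.write(f"{p}\t2\n")
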