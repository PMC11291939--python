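"""Homology clustering and taxonomic screening of candidate clusters.

The first stage of the pipeline: build clusters of homologous proteins from
tabular search hits (BLAST/DIAMOND outfmt-6 style), then keep the clusters
whose taxonomic composition is predominantly *non*-focal — a focal-kingdom
protein sitting in a sea of, say, bacterial homologs is the raw signal of a
candidate transfer.  Excessively long focal sequences (default > 2,000 aa,
often multidomain or ORF-prediction chimeras) are excluded from the
candidate set.

Clusters are connected components of the undirected graph with an edge
between query and subject whenever any hit passes the e-value and coverage
thresholds (one passing direction suffices; the stringency lives in the
downstream phylogenetic test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx

from .taxonomy import LineageRelation, TaxonomyTree


@dataclass
class HitRecord:
    query: str
    subject: str
    pident: float
    evalue: float
    bitscore: float
    qcov: float             # fraction in [0, 1]
    subject_taxid: int | None = None


@dataclass
class ClusterMember:
    protein: str
    taxid: int | None = None
    length: int | None = None
    is_focal: bool | None = None
    excluded_by_length: bool = False


@dataclass
class ProteinCluster:
    cluster_id: str
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def focal_fraction(self) -> float:
        flags = [m.is_focal for m in self.members if m.is_focal is not None]
        if not flags:
            return 0.0
        return sum(flags) / len(flags)


def read_outfmt6(
    stream: IO[str] | Iterable[str],
    taxid_col: int = 12,
    qcov_col: int | None = None,
) -> Iterator[HitRecord]:
    """Parse outfmt-6 TSV with an extra subject-taxid column.

    Default column order: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore staxid [qcov].  When no qcov
    column is present, coverage is taken as 1.0 (pre-filtered input).
    """
    for raw in stream:
        if not raw.strip() or raw.startswith("#"):
            continue
        f = raw.rstrip("\n").split("\t")
        yield HitRecord(
            query=f[0],
            subject=f[1],
            pident=float(f[2]),
            evalue=float(f[10]),
            bitscore=float(f[11]),
            qcov=float(f[qcov_col]) if qcov_col is not None else 1.0,
            subject_taxid=int(f[taxid_col]) if len(f) > taxid_col else None,
        )


def build_clusters(
    hits: Iterable[HitRecord],
    max_evalue: float = 1e-5,
    min_coverage: float = 0.5,
    taxids: dict[str, int] | None = None,
    lengths: dict[str, int] | None = None,
) -> list[ProteinCluster]:
    """Connected components over proteins linked by passing hits.

    Self-hits and duplicate pairs are ignored.  Taxon ids are collected from
    subject-side columns and can be supplemented/overridden via ``taxids``;
    sequence lengths come from ``lengths`` when available (e.g. a FASTA
    index).  Every protein with at least one passing hit lands in exactly
    one cluster.
    """
    if max_evalue < 0 or min_coverage < 0:
        raise ValueError("thresholds must be nonnegative")
    g = nx.Graph()
    seen_taxids: dict[str, int] = dict(taxids or {})
    for h in hits:
        if h.subject_taxid is not None and h.subject not in seen_taxids:
            seen_taxids[h.subject] = h.subject_taxid
        if h.query == h.subject:
            continue
        if h.evalue <= max_evalue and h.qcov >= min_coverage:
            g.add_edge(h.query, h.subject)
    clusters = []
    for i, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        members = [
            ClusterMember(
                protein=p,
                taxid=seen_taxids.get(p),
                length=(lengths or {}).get(p),
            )
            for p in sorted(comp)
        ]
        clusters.append(ProteinCluster(cluster_id=f"C{i:05d}", members=members))
    return clusters


def screen_clusters(
    clusters: Iterable[ProteinCluster],
    taxonomy: TaxonomyTree,
    focal: int,
    max_focal_fraction: float = 0.5,
    max_len: int = 2000,
) -> list[ProteinCluster]:
    """Retain clusters with a predominantly nonfocal taxonomy.

    A cluster survives iff its focal fraction is ≤ ``max_focal_fraction``
    and it has at least one focal and one nonfocal member.  Focal members
    longer than ``max_len`` amino acids are flagged ``excluded_by_length``
    and do not count as focal presence (the cluster survives only if other
    focal members remain).
    """
    unknown = sorted(
        {
            m.protein
            for c in clusters
            for m in c.members
            if m.taxid is not None and m.taxid not in taxonomy
        }
    )
    if unknown:
        raise ValueError(f"taxon ids not in taxonomy for proteins: {unknown}")
    retained = []
    for c in clusters:
        n_focal = n_nonfocal = n_focal_ok = 0
        for m in c.members:
            if m.taxid is None:
                continue
            m.is_focal = (
                taxonomy.lineage_relation(m.taxid, focal)
                == LineageRelation.EQUALS_OR_WITHIN_FOCAL
            )
            if m.is_focal:
                n_focal += 1
                m.excluded_by_length = m.length is not None and m.length > max_len
                if not m.excluded_by_length:
                    n_focal_ok += 1
            else:
                n_nonfocal += 1
        total = n_focal + n_nonfocal
        if total == 0:
            continue
        if (
            n_focal_ok >= 1
            and n_nonfocal >= 1
            and n_focal / total <= max_focal_fraction
        ):
            retained.append(c)
    return retained


def write_cluster_tsv(clusters: Iterable[ProteinCluster], stream: IO[str]) -> None:
    stream.write("cluster_id\tprotein_id\ttaxid\tis_focal\tlength\n")
    for c in clusters:
        for m in c.members:
            stream.write(
                f"{c.cluster_id}\t{m.protein}\t{m.taxid if m.taxid is not None else ''}"
                f"\t{int(m.is_focal) if m.is_focal is not None else ''}"
                f"\t{m.length if m.length is not None else ''}\n"
            )
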