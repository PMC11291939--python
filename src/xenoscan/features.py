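"""Per-protein genomic and molecular features, and subtree-level summaries.

Features consumed here come from standard annotation files: intron counts
from GFF3 gene structures, sequence lengths from FASTA, and predictions of
upstream tools (signal peptide, subcellular localization, low-complexity
and disorder fractions, transmembrane helices) from a generic 3-column TSV
``protein<TAB>feature<TAB>value``.  The tools themselves are never run
here — their tabular outputs are inputs.

Intron counting uses the primary transcript, defined as the mRNA with the
longest total CDS; intron count = number of CDS segments − 1 (exon
segments as fallback when a gene has no CDS rows).
"""

from __future__ import annotations

import warnings
from typing import IO, Iterable

import pandas as pd

from .detect import HGTCall


def count_introns(gff_source: str | IO[str]) -> dict[str, int]:
    """protein id → intron count from a GFF3 file path or text stream.

    GFF3 coordinates are 1-based inclusive; features are linked through
    ``Parent`` attributes (CDS/exon → mRNA).  The protein id is the
    ``protein_id`` attribute of the mRNA or its CDS rows, falling back to
    the mRNA ``ID``.  Proteins without any CDS/exon segment are omitted
    with a warning.
    """
    import gffutils

    if hasattr(gff_source, "read"):
        data, from_string = gff_source.read(), True
    else:
        try:
            data, from_string = open(gff_source).read(), True
        except OSError:
            data, from_string = gff_source, True
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    # group CDS/exon segments per mRNA
    segments: dict[str, dict[str, list]] = {}
    protein_of: dict[str, str] = {}
    for ftype in ("CDS", "exon"):
        for feat in db.features_of_type(ftype):
            for parent in feat.attributes.get("Parent", []):
                segments.setdefault(parent, {"CDS": [], "exon": []})[ftype].append(feat)
                if "protein_id" in feat.attributes:
                    protein_of[parent] = feat.attributes["protein_id"][0]
    for feat in db.features_of_type("mRNA"):
        mrna_id = feat.id
        if "protein_id" in feat.attributes:
            protein_of[mrna_id] = feat.attributes["protein_id"][0]
        protein_of.setdefault(mrna_id, mrna_id)

    # primary transcript per gene: the mRNA with the longest total CDS
    by_gene: dict[str, list[str]] = {}
    for feat in db.features_of_type("mRNA"):
        gene = feat.attributes.get("Parent", [feat.id])[0]
        by_gene.setdefault(gene, []).append(feat.id)

    def total_cds(mrna_id: str) -> int:
        segs = segments.get(mrna_id, {"CDS": [], "exon": []})
        use = segs["CDS"] or segs["exon"]
        return sum(s.end - s.start + 1 for s in use)

    counts: dict[str, int] = {}
    for gene, mrnas in by_gene.items():
        primary = max(mrnas, key=lambda m: (total_cds(m), m))
        segs = segments.get(primary, {"CDS": [], "exon": []})
        use = segs["CDS"] or segs["exon"]
        if not use:
            warnings.warn(f"transcript {primary} has no CDS/exon segments; omitted")
            continue
        counts[protein_of.get(primary, primary)] = max(len(use) - 1, 0)
    return counts


def read_feature_tsv(stream: IO[str] | Iterable[str]) -> pd.DataFrame:
    """Generic long-format feature TSV → wide DataFrame indexed by protein."""
    rows = []
    for raw in stream:
        if not raw.strip() or raw.startswith("#"):
            continue
        prot, feat, val = raw.rstrip("\n").split("\t")[:3]
        rows.append((prot, feat, val))
    df = pd.DataFrame(rows, columns=["protein", "feature", "value"])
    wide = df.pivot_table(index="protein", columns="feature", values="value",
                          aggfunc="first")
    for col in wide.columns:
        converted = pd.to_numeric(wide[col], errors="coerce")
        if converted.notna().sum() == wide[col].notna().sum():
            wide[col] = converted
    return wide


def sequence_lengths(fasta_source: str | IO[str]) -> dict[str, int]:
    from Bio import SeqIO

    handle = fasta_source if hasattr(fasta_source, "read") else open(fasta_source)
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def subtree_consistency(
    call: HGTCall, labels: dict[str, str], quorum: float = 0.75
) -> tuple[bool, str | None]:
    """Is one categorical label shared by ≥ ``quorum`` of labeled target proteins?

    Ties for the modal label make the subtree inconsistent.  Raises when no
    target protein of the call is labeled.
    """
    observed = [labels[p] for p, _ in call.xenologs if p in labels]
    if not observed:
        raise ValueError("no labeled target proteins in this call")
    counts = pd.Series(observed).value_counts()
    top = counts.iloc[0]
    if (counts == top).sum() > 1:
        return False, None
    majority = counts.index[0]
    return top / len(observed) >= quorum, majority


def fraction_summary(
    calls: list[HGTCall],
    features: pd.DataFrame,
    background: pd.DataFrame,
    quantiles: Iterable[float] = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Xenolog-vs-background comparison per feature column.

    Boolean/indicator columns yield the fraction positive; numeric columns
    yield the mean, the zero fraction (relevant for intron counts) and
    quantile curves.  Index: feature/statistic pairs; columns: xenologs,
    background.
    """
    if background.empty:
        raise ValueError("empty background feature table")
    xeno_ids = sorted({p for c in calls for p, _ in c.xenologs})
    xeno = features.loc[features.index.intersection(xeno_ids)]
    rows = {}
    for col in background.columns:
        if col not in features.columns:
            continue
        xv = pd.to_numeric(xeno[col], errors="coerce").dropna()
        bv = pd.to_numeric(background[col], errors="coerce").dropna()
        if xv.empty or bv.empty:
            continue
        if set(bv.unique()) <= {0, 1}:
            rows[(col, "fraction")] = (xv.mean(), bv.mean())
        else:
            rows[(col, "mean")] = (xv.mean(), bv.mean())
            rows[(col, "zero_fraction")] = ((xv == 0).mean(), (bv == 0).mean())
            for q in quantiles:
                rows[(col, f"q{q:g}")] = (xv.quantile(q), bv.quantile(q))
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["xenologs", "background"])
    out.index = pd.MultiIndex.from_tuples(out.index, names=["feature", "stat"])
    return out
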