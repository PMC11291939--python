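"""Posttransfer domain gain/loss detection from pfam-scan style tables.

Domain comparisons run at the *clan* level: two domains match when they
share a clan accession, falling back to the family accession for families
without a clan.  Presence is binary per protein (at least one hit); copy
number is ignored.

* a xenolog's domain is **gained** when no nonfocal sequence in the same
  gene tree carries a clan-level sibling — the domain was apparently
  acquired during or after incorporation into the host genome;
* a domain is **lost** for a xenolog when it is present in at least 20%
  (configurable) of the sequences of *both* neighbor clades N1 and N2 but
  absent from the xenolog;
* a subtree's **representative** (functional) domains are those present in
  at least half of the focal proteins of the subtree and in at least 20%
  of the proteins of at least one neighbor clade.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .detect import HGTCall


@dataclass
class DomainHit:
    accession: str
    clan: str | None = None
    env_start: int | None = None
    env_end: int | None = None
    evalue: float | None = None

    @property
    def clan_key(self) -> str:
        """Clan accession when present, else versionless family accession."""
        if self.clan and self.clan not in ("No_clan", "NA", "-"):
            return self.clan
        return re.sub(r"\.\d+$", "", self.accession)


@dataclass
class DomainTable:
    hits: dict[str, list[DomainHit]] = field(default_factory=dict)

    def clans(self, protein: str) -> set[str]:
        """Clan-level keys for a protein; missing proteins are domain-free."""
        return {h.clan_key for h in self.hits.get(protein, [])}

    def add(self, protein: str, hit: DomainHit) -> None:
        self.hits.setdefault(protein, []).append(hit)


def read_pfamscan(
    stream: IO[str] | Iterable[str], clan_map: dict[str, str] | None = None
) -> DomainTable:
    """Parse pfam_scan.pl output (whitespace-delimited, ``#`` comments).

    Standard column layout: seq_id, aln_start, aln_end, env_start, env_end,
    hmm_acc, hmm_name, type, hmm_start, hmm_end, hmm_len, bit_score,
    E-value, significance, clan.  Shorter fixture rows of the form
    ``seq_id hmm_acc clan`` are accepted too.  ``clan_map`` (accession →
    clan) supplements rows without a clan column.
    """
    table = DomainTable()
    for raw in stream:
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        f = raw.split()
        if len(f) >= 15:
            prot, acc, clan = f[0], f[5], f[14]
            env_s, env_e, ev = int(f[3]), int(f[4]), float(f[12])
        elif len(f) >= 2:
            prot, acc = f[0], f[1]
            clan = f[2] if len(f) > 2 else None
            env_s = env_e = ev = None
        else:
            continue
        if (clan is None or clan in ("No_clan", "NA", "-")) and clan_map:
            clan = clan_map.get(re.sub(r"\.\d+$", "", acc))
        table.add(prot, DomainHit(acc, clan, env_s, env_e, ev))
    return table


def _presence_fraction(proteins: list[str], table: DomainTable, key: str) -> float:
    if not proteins:
        return 0.0
    return sum(key in table.clans(p) for p in proteins) / len(proteins)


def gained_domains(call: HGTCall, tree_domains: DomainTable) -> dict[str, set[str]]:
    """Per-xenolog clan keys with no clan-level sibling in nonfocal leaves."""
    nonfocal_clans: set[str] = set()
    for p, _ in call.nonfocal_proteins:
        nonfocal_clans |= tree_domains.clans(p)
    out: dict[str, set[str]] = {}
    for p, _ in call.xenologs:
        out[p] = {k for k in tree_domains.clans(p) if k not in nonfocal_clans}
    return out


def lost_domains(
    call: HGTCall, neighbor_domains: DomainTable, threshold: float = 0.2
) -> dict[str, set[str]]:
    """Per-xenolog clan keys present in ≥ threshold of both N1 and N2 but absent."""
    n1 = [p for p, _ in call.n1_proteins]
    n2 = [p for p, _ in call.n2_proteins]
    if not n1 or not n2:
        raise ValueError("both neighbor clades must be nonempty (SUPPORTED call)")
    candidate = set()
    for p in n1 + n2:
        candidate |= neighbor_domains.clans(p)
    qualifying = {
        k
        for k in candidate
        if _presence_fraction(n1, neighbor_domains, k) >= threshold
        and _presence_fraction(n2, neighbor_domains, k) >= threshold
    }
    out: dict[str, set[str]] = {}
    for p, _ in call.xenologs:
        own = neighbor_domains.clans(p)
        out[p] = {k for k in qualifying if k not in own}
    return out


def representative_domains(
    call: HGTCall,
    neighbor_domains: DomainTable,
    in_subtree: float = 0.5,
    in_neighbor: float = 0.2,
) -> set[str]:
    """Clan keys in ≥ ``in_subtree`` of focal members and ≥ ``in_neighbor`` of N1 or N2."""
    members = [p for p, _ in call.member_proteins]
    n1 = [p for p, _ in call.n1_proteins]
    n2 = [p for p, _ in call.n2_proteins]
    candidate = set()
    for p in members:
        candidate |= neighbor_domains.clans(p)
    return {
        k
        for k in candidate
        if _presence_fraction(members, neighbor_domains, k) >= in_subtree
        and (
            _presence_fraction(n1, neighbor_domains, k) >= in_neighbor
            or _presence_fraction(n2, neighbor_domains, k) >= in_neighbor
        )
    }


def gain_loss_bookkeeping(
    calls: Iterable[HGTCall], domains: DomainTable, threshold: float = 0.2
) -> dict[str, int]:
    """Count xenologs with gained-only, lost-only, and both event types."""
    gained_only = lost_only = both = 0
    for call in calls:
        g = gained_domains(call, domains)
        l = lost_domains(call, domains, threshold=threshold)
        for p, _ in call.xenologs:
            has_g, has_l = bool(g.get(p)), bool(l.get(p))
            if has_g and has_l:
                both += 1
            elif has_g:
                gained_only += 1
            elif has_l:
                lost_only += 1
    return {
        "gained_only": gained_only,
        "lost_only": lost_only,
        "both": both,
        "any": gained_only + lost_only + both,
    }
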