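"""Group-exclusive OTU selection from grouped amplicon read sets.

Pooled reads are clustered de novo into OTUs at a fixed identity (default
97%, the customary species proxy); OTUs whose reads all come from a single
sample group, with at least ``min_reads`` reads, are table-exclusive.
Table-exclusive OTUs are then verified by similarity search of their
representative against every group's reads: any qualifying hit
(E <= 0.001 by default) outside the owner group refutes exclusivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import seqsearch
from .seqsearch import DEFAULT_K_READS, build_kmer_index, greedy_cluster, local_search


@dataclass
class OtuRecord:
    """An OTU: representative sequence plus per-group read counts."""

    otu_id: str
    representative: str
    counts: Dict[str, int]
    member_ids: List[str] = field(default_factory=list)
    representative_id: Optional[str] = None  # read id of the representative

    def __post_init__(self):
        if not self.representative:
            raise ValueError("empty representative sequence")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


@dataclass
class ExclusivityCall:
    """Outcome of the two-step exclusivity test for one OTU."""

    otu_id: str
    owner_group: Optional[str]
    table_exclusive: bool
    search_confirmed: bool = False
    offending_groups: Set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.search_confirmed and not self.table_exclusive:
            raise ValueError("search_confirmed requires table_exclusive")
        if self.table_exclusive and self.owner_group is None:
            raise ValueError("table_exclusive requires an owner group")


def filter_reads(reads: Sequence[Tuple[str, str]],
                 qualities: Optional[Dict[str, Sequence[int]]] = None,
                 min_length: int = 200, min_mean_quality: float = 25.0,
                 max_ambiguous: int = 0) -> List[Tuple[str, str]]:
    """Optional QIIME-like quality pre-filter.

    Keeps reads longer than ``min_length`` with at most ``max_ambiguous``
    ambiguous bases; when per-base qualities are supplied, additionally
    requires mean quality above ``min_mean_quality``.
    """
    kept = []
    for rid, seq in reads:
        if len(seq) <= min_length:
            continue
        if sum(1 for c in seq.upper() if c not in "ACGT") > max_ambiguous:
            continue
        if qualities is not None and rid in qualities:
            quals = qualities[rid]
            if not quals or sum(quals) / len(quals) <= min_mean_quality:
                continue
        kept.append((rid, seq))
    return kept


def pick_otus(reads: Dict[str, Sequence[Tuple[str, str]]],
              identity_threshold: float = 0.97) -> List[OtuRecord]:
    """De novo OTU picking by greedy clustering of the pooled reads.

    ``reads`` maps group name -> [(read_id, sequence), ...].  Read ids must
    be unique across groups.  The representative is the cluster
    representative (a longest member).
    """
    if not any(len(v) for v in reads.values()):
        raise ValueError("need at least one non-empty group")
    pooled: List[Tuple[str, str]] = []
    group_of: Dict[str, str] = {}
    seqs: Dict[str, str] = {}
    for group, items in reads.items():
        for rid, seq in items:
            if rid in group_of:
                raise ValueError(f"duplicate read id across groups: {rid}")
            pooled.append((rid, seq))
            group_of[rid] = group
            seqs[rid] = seq.upper()
    clusters = greedy_cluster(pooled, identity_threshold)
    otus = []
    for i, cl in enumerate(clusters):
        counts = {g: 0 for g in reads}
        for rid in cl.member_ids:
            counts[group_of[rid]] += 1
        otus.append(OtuRecord(
            otu_id=f"OTU{i:04d}", representative=seqs[cl.representative_id],
            counts=counts, member_ids=list(cl.member_ids),
            representative_id=cl.representative_id))
    return otus


def select_exclusive(otus: Sequence[OtuRecord],
                     min_reads: int = 8) -> List[ExclusivityCall]:
    """Table-level exclusivity: exactly one group with a positive count,
    and that count at least ``min_reads`` (strict zero elsewhere)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    calls = []
    for otu in otus:
        positive = [(g, c) for g, c in otu.counts.items() if c > 0]
        if len(positive) == 1 and positive[0][1] >= min_reads:
            calls.append(ExclusivityCall(
                otu_id=otu.otu_id, owner_group=positive[0][0],
                table_exclusive=True))
        else:
            calls.append(ExclusivityCall(
                otu_id=otu.otu_id, owner_group=None, table_exclusive=False))
    return calls


def verify_exclusive(call: ExclusivityCall, representative: str,
                     reads: Dict[str, Sequence[Tuple[str, str]]],
                     max_evalue: float = 0.001,
                     min_identity: Optional[float] = None,
                     k: int = DEFAULT_K_READS) -> ExclusivityCall:
    """Search-level verification of a table-exclusive OTU.

    The representative is searched against the pooled reads of every group
    (one index, so the E-value database size is the full read set);
    ``search_confirmed`` iff every qualifying hit falls in the owner group.
    An optional identity floor (default off) additionally requires
    ``identity >= min_identity`` for a hit to count.
    """
    if not call.table_exclusive:
        raise ValueError("verify_exclusive requires a table-exclusive call")
    if call.owner_group not in reads:
        raise ValueError(f"owner group {call.owner_group!r} missing from reads")
    group_of: Dict[str, str] = {}
    pooled: List[Tuple[str, str]] = []
    for group, items in reads.items():
        for rid, seq in items:
            pooled.append((rid, seq))
            group_of[rid] = group
    index = build_kmer_index(pooled, k=k)
    hits = local_search(representative, index, max_evalue=max_evalue,
                        query_id=call.otu_id)
    offending: Set[str] = set()
    for h in hits:
        if min_identity is not None and h.identity < min_identity:
            continue
        g = group_of[h.subject_id]
        if g != call.owner_group:
            offending.add(g)
    return replace(call, search_confirmed=not offending,
                   offending_groups=offending)


def verify_all(calls: Sequence[ExclusivityCall], otus: Sequence[OtuRecord],
               reads: Dict[str, Sequence[Tuple[str, str]]],
               max_evalue: float = 0.001,
               min_identity: Optional[float] = None,
               k: int = DEFAULT_K_READS) -> List[ExclusivityCall]:
    """Batch verification, decision-equivalent to :func:`verify_exclusive`.

    Only foreign-group hits can change a call, so each foreign group is
    scanned until its first qualifying hit.  When no identity floor is
    requested, a shared exact word of length >= the qualifying score
    (match = +1, so an exact run of length s scores at least s) proves a
    qualifying hit without dynamic programming; remaining reads fall back
    to Smith-Waterman exactly as :func:`verify_exclusive` would.
    """
    import math as _math

    from ._align import revcomp, smith_waterman
    from .seqsearch import DEFAULT_SCORING, evalue, karlin_altschul_params

    sc = DEFAULT_SCORING
    n_total = sum(len(s) for items in reads.values() for _, s in items)
    lam, K, _ = karlin_altschul_params(sc["match"], sc["mismatch"])
    out = []
    for call in calls:
        if not call.table_exclusive:
            out.append(call)
            continue
        if call.owner_group not in reads:
            raise ValueError(f"owner group {call.owner_group!r} missing")
        rep = by_id_representative(otus, call.otu_id)
        m = len(rep)
        arg = K * m * n_total / max_evalue
        s_min = max(1, _math.ceil(_math.log(arg) / lam)) if arg > 1 else 1
        word = None
        if min_identity is None and sc["match"] == 1 and 8 <= s_min <= 64:
            word = {rep[i:i + s_min] for i in range(m - s_min + 1)}
            word |= {w for w in
                     (revcomp(rep)[i:i + s_min] for i in range(m - s_min + 1))}
        seed_set = {rep[i:i + k] for i in range(m - k + 1)}
        seed_set |= {revcomp(rep)[i:i + k] for i in range(m - k + 1)}
        offending = set()
        for group, items in reads.items():
            if group == call.owner_group:
                continue
            for rid, seq in items:
                seq = seq.upper()
                if word is not None and any(
                        seq[i:i + s_min] in word
                        for i in range(len(seq) - s_min + 1)):
                    offending.add(group)
                    break
                # seeding contract: only reads sharing an exact k-mer with
                # the representative (either strand) are aligned
                if not any(seq[i:i + k] in seed_set
                           for i in range(len(seq) - k + 1)):
                    continue
                best = max(smith_waterman(rep, seq, **sc)["score"],
                           smith_waterman(revcomp(rep), seq, **sc)["score"])
                if best <= 0:
                    continue
                e = evalue(best, m, n_total, sc["match"], sc["mismatch"])
                if e > max_evalue:
                    continue
                if min_identity is not None:
                    aln = smith_waterman(rep, seq, **sc)
                    alr = smith_waterman(revcomp(rep), seq, **sc)
                    pick = aln if aln["score"] >= alr["score"] else alr
                    if pick["n_matches"] / pick["n_cols"] < min_identity:
                        continue
                offending.add(group)
                break
        out.append(replace(call, search_confirmed=not offending,
                           offending_groups=offending))
    return out


def by_id_representative(otus: Sequence[OtuRecord], otu_id: str) -> str:
    for o in otus:
        if o.otu_id == otu_id:
            return o.representative.upper()
    raise KeyError(otu_id)


def otu_table(otus: Sequence[OtuRecord]) -> str:
    """TSV OTU count table (rows OTUs, columns groups)."""
    groups = sorted({g for o in otus for g in o.counts})
    lines = ["\t".join(["otu_id", "representative_length"] + groups)]
    for o in otus:
        lines.append("\t".join(
            [o.otu_id, str(len(o.representative))]
            + [str(o.counts.get(g, 0)) for g in groups]))
    return "\n".join(lines) + "\n"


def calls_tsv(calls: Sequence[ExclusivityCall]) -> str:
    lines = ["\t".join(["otu_id", "owner_group", "table_exclusive",
                        "search_confirmed", "offending_groups"])]
    for c in calls:
        lines.append("\t".join([
            c.otu_id, c.owner_group or "", str(int(c.table_exclusive)),
            str(int(c.search_confirmed)),
            ",".join(sorted(c.offending_groups))]))
    return "\n".join(lines) + "\n"
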