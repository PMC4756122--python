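"""Shared sequence-algorithm core.

Two primitives used throughout the marker-discovery pipeline:

* :func:`local_search` — k-mer-seeded local alignment search over a small
  nucleotide database, reporting BLAST-like hits with Karlin-Altschul
  E-values.  Seeds gate which (subject, strand) pairs are aligned; each
  candidate pair is then scored with a full Smith-Waterman matrix so hit
  spans and scores are optimal (the "band" is the whole matrix — exactness
  over speed at 16S amplicon scale).
* :func:`greedy_cluster` — CD-HIT-style greedy incremental clustering at a
  fixed identity threshold, with the longest sequence as cluster
  representative.

E-values follow E = K * m * n * exp(-lambda * S) with (lambda, K) computed
for the ungapped match/mismatch pair by the standard Karlin-Altschul
procedure (lambda from the moment equation, K from the Spitzer series) and
reused for gapped scores; this is the customary ungapped approximation.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from ._align import identity_over_shorter, revcomp, smith_waterman

DEFAULT_SCORING = {"match": 1, "mismatch": -2, "gap_open": -5, "gap_extend": -2}

#: default seed length for database-scale search (vs. long 16S references)
DEFAULT_K_DB = 11
#: default seed length for verification against short amplicon reads
DEFAULT_K_READS = 8


@dataclass(frozen=True)
class SearchHit:
    """One local-alignment match of a query against a database subject."""

    query_id: str
    subject_id: str
    raw_score: int
    identity: float          # matching columns / alignment columns
    q_start: int             # 0-based half-open, on the forward query
    q_end: int
    s_start: int             # 0-based half-open, on the forward subject
    s_end: int
    strand: str              # '+' or '-'
    evalue: float

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValueError("invalid query span")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError("invalid subject span")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")


@dataclass
class Cluster:
    """A greedy identity cluster; the representative is a longest member."""

    representative_id: str
    member_ids: List[str] = field(default_factory=list)
    threshold: float = 0.97


class KmerIndex:
    """Exact k-mer postings over the forward strand of a subject set.

    Queries are searched on both strands by also searching their reverse
    complement at :func:`local_search` time, so only one strand is indexed.
    """

    def __init__(self, subjects: Iterable[Tuple[str, str]], k: int):
        if not 4 <= k <= 15:
            raise ValueError(f"k must be in [4, 15], got {k}")
        self.k = k
        self.subjects: Dict[str, str] = {}
        self.postings: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        order = []
        for sid, seq in subjects:
            seq = seq.upper()
            if sid in self.subjects:
                raise ValueError(f"duplicate subject id: {sid}")
            self.subjects[sid] = seq
            order.append(sid)
            for off in range(len(seq) - k + 1):
                kmer = seq[off:off + k]
                if all(c in "ACGT" for c in kmer):
                    self.postings[kmer].append((sid, off))
        if not self.subjects:
            raise ValueError("subjects must be non-empty")
        self._order = order
        self.total_length = sum(len(s) for s in self.subjects.values())

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        return self.postings.get(kmer.upper(), [])


def build_kmer_index(subjects: Iterable[Tuple[str, str]], k: int) -> KmerIndex:
    """Build an exact k-mer index (id, offset postings) over subjects."""
    return KmerIndex(subjects, k)


@lru_cache(maxsize=32)
def karlin_altschul_params(match: int, mismatch: int,
                           p_match: float = 0.25) -> Tuple[float, float, float]:
    """(lambda, K, H) for an ungapped match/mismatch score pair.

    lambda solves sum_s p(s) exp(lambda s) = 1; K comes from the lattice
    Spitzer-series formula K = d*lambda*exp(-2*sigma) / (H*(1-exp(-lambda*d)))
    with sigma = sum_j (1/j)(E[exp(lambda S_j); S_j<0] + P(S_j>=0)).
    For +1/-2 on uniform composition this yields lambda=1.3327, K=0.6210 —
    the published blastn ungapped values.
    """
    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")
    if match + 3 * mismatch >= 0:  # expected score must be negative
        raise ValueError("expected score non-negative; no Karlin-Altschul regime")
    pm, pmm = p_match, 1.0 - p_match

    def f(lam):
        return pm * math.exp(lam * match) + pmm * math.exp(lam * mismatch) - 1.0

    lam = brentq(f, 1e-9, 20.0)
    H = lam * (match * pm * math.exp(lam * match)
               + mismatch * pmm * math.exp(lam * mismatch))
    d = math.gcd(abs(match), abs(mismatch))
    dist = {0: 1.0}
    sigma = 0.0
    for j in range(1, 80):
        nd: Dict[int, float] = defaultdict(float)
        for s, p in dist.items():
            nd[s + match] += p * pm
            nd[s + mismatch] += p * pmm
        dist = dict(nd)
        t1 = sum(p * math.exp(lam * s) for s, p in dist.items() if s < 0)
        t2 = sum(p for s, p in dist.items() if s >= 0)
        sigma += (t1 + t2) / j
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return lam, K, H


def evalue(raw_score: int, query_length: int, database_length: int,
           match: int = 1, mismatch: int = -2) -> float:
    """Karlin-Altschul E-value for a raw alignment score."""
    lam, K, _ = karlin_altschul_params(match, mismatch)
    return K * query_length * database_length * math.exp(-lam * raw_score)


def _candidate_pairs(query: str, index: KmerIndex) -> Dict[Tuple[str, str], int]:
    """(subject_id, strand) pairs sharing at least one exact k-mer with the
    query, with the shared-seed count (used only for gating, not scoring)."""
    k = index.k
    cands: Dict[Tuple[str, str], int] = defaultdict(int)
    for strand, q in (("+", query), ("-", revcomp(query))):
        seen = set()
        for off in range(len(q) - k + 1):
            kmer = q[off:off + k]
            for sid, _ in index.lookup(kmer):
                seen.add(sid)
        for sid in seen:
            cands[(sid, strand)] += 1
    return cands


def local_search(query: str, index: KmerIndex,
                 scoring: dict | None = None,
                 max_evalue: float = 1e-10,
                 query_id: str = "query") -> List[SearchHit]:
    """Seeded local alignment of ``query`` against an indexed database.

    At most one hit per subject is reported: the best-scoring local
    alignment over both strands ('+' preferred at score ties).  Hits are
    sorted by ascending E-value, ties by descending raw score then
    subject id.
    """
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    query = query.upper()
    if len(query) < index.k:
        raise ValueError("query shorter than seed length k")
    cands = _candidate_pairs(query, index)
    hits: List[SearchHit] = []
    n = index.total_length
    m = len(query)
    by_subject: Dict[str, SearchHit] = {}
    for (sid, strand), _count in sorted(cands.items()):
        subj = index.subjects[sid]
        q = query if strand == "+" else revcomp(query)
        aln = smith_waterman(q, subj, **sc)
        if aln["score"] <= 0 or aln["n_cols"] == 0:
            continue
        e = evalue(aln["score"], m, n, sc["match"], sc["mismatch"])
        if e > max_evalue:
            continue
        qs, qe = aln["a_start"], aln["a_end"]
        if strand == "-":
            qs, qe = m - aln["a_end"], m - aln["a_start"]
        hit = SearchHit(
            query_id=query_id, subject_id=sid, raw_score=aln["score"],
            identity=aln["n_matches"] / aln["n_cols"],
            q_start=qs, q_end=qe,
            s_start=aln["b_start"], s_end=aln["b_end"],
            strand=strand, evalue=e)
        prev = by_subject.get(sid)
        if prev is None or hit.raw_score > prev.raw_score or (
                hit.raw_score == prev.raw_score and prev.strand == "-"
                and hit.strand == "+"):
            by_subject[sid] = hit
    hits = sorted(by_subject.values(),
                  key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return hits


_PRESCREEN_K = 8


def greedy_cluster(seqs: Sequence[Tuple[str, str]],
                   identity_threshold: float = 0.97,
                   scoring: dict | None = None) -> List[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences are visited by descending length (ties: ascending id); each
    joins the first existing cluster whose representative it matches at
    >= ``identity_threshold`` (matching columns over the shorter sequence's
    length), else founds a new cluster.  Clusters are returned in founding
    order.

    A CD-HIT-style short-word prescreen skips provably hopeless alignments
    for thresholds >= 0.9 and sequences >= 100 nt: a pair at identity >= t
    over the shorter length Ls has at most floor((1-t)*Ls) non-matching
    columns touching the shorter sequence, each destroying at most k of its
    exact k-mers, so at least (Ls-k+1) - k*floor((1-t)*Ls) of the shorter
    sequence's k-mers must occur in the longer one.  Counting fewer shared
    k-mers than that bound (minus a k-sized safety slack) proves identity
    < t without dynamic programming.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    k = _PRESCREEN_K
    use_prescreen = identity_threshold >= 0.9
    order = sorted(seqs, key=lambda it: (-len(it[1]), it[0]))
    clusters: List[Cluster] = []
    rep_seqs: List[str] = []
    rep_kmers: List[set] = []
    for sid, seq in order:
        seq = seq.upper()
        cand_kmers = None
        placed = False
        for cl, rep_seq, rep_set in zip(clusters, rep_seqs, rep_kmers):
            Ls = min(len(seq), len(rep_seq))  # visited by descending length
            if use_prescreen and Ls >= 100:
                if cand_kmers is None:
                    cand_kmers = [seq[i:i + k]
                                  for i in range(len(seq) - k + 1)]
                shared = sum(km in rep_set for km in cand_kmers)
                m_allow = int((1.0 - identity_threshold) * Ls + 1e-9)
                bound = (Ls - k + 1) - k * m_allow - k  # slack of one word
                if shared < bound:
                    continue
            ident = identity_over_shorter(seq, rep_seq, **sc)
            if ident >= identity_threshold:
                cl.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative_id=sid, member_ids=[sid],
                                    threshold=identity_threshold))
            rep_seqs.append(seq)
            rep_kmers.append({seq[i:i + k]
                              for i in range(len(seq) - k + 1)})
    return clusters


def hits_to_tsv(hits: Iterable[SearchHit]) -> str:
    """BLAST outfmt-6-like TSV (0-based half-open coordinates)."""
    lines = ["\t".join(["qseqid", "sseqid", "pident", "length", "qstart",
                        "qend", "sstart", "send", "evalue", "score"])]
    for h in hits:
        lines.append("\t".join([
            h.query_id, h.subject_id, f"{100.0 * h.identity:.2f}",
            str(h.q_end - h.q_start), str(h.q_start), str(h.q_end),
            str(h.s_start), str(h.s_end), f"{h.evalue:.3g}",
            str(h.raw_score)]))
    return "\n".join(lines) + "\n"
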