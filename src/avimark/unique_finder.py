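"""Host-unique window discovery: the core marker-design computation.

For a candidate sequence (typically a group-exclusive OTU representative),
the pipeline is:

1. gather homologs from the fecal reference database by seeded local
   search (E <= 1e-10);
2. reduce redundancy by greedy clustering at 95% identity, keeping the
   longest representative per cluster;
3. build a query-anchored star alignment of the surviving homologs
   (pairwise overlap alignments merged on the query coordinate frame,
   "once a gap, always a gap"), trimmed to the query's span;
4. slide an 18-nt window over the ungapped query; a reference row
   "differs" in a window when it mismatches the query in at least
   ``min_mismatches`` of the window's columns (rows absent from the
   window count as fully mismatched); the window is flagged when at least
   ``difference_threshold`` of the rows differ;
5. merge maximal runs of flagged windows into candidate probe regions.

Coordinates are 0-based, half-open, on the ungapped input query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._align import _ENCODE, encode, overlap_align, revcomp
from . import seqsearch
from .seqsearch import DEFAULT_K_DB, KmerIndex, SearchHit, build_kmer_index, greedy_cluster, local_search

DEFAULT_WINDOW = 18
DEFAULT_DIFFERENCE_THRESHOLD = 0.90
DEFAULT_MIN_MISMATCHES = 2
DEFAULT_CLUSTER_IDENTITY = 0.95
DEFAULT_MAX_EVALUE = 1e-10


@dataclass
class Homolog:
    """A database match: the hit plus the subject subsequence spanning it
    (reverse-complemented for minus-strand hits, so it reads in query
    orientation)."""

    hit: SearchHit
    subsequence: str


@dataclass
class TrimmedAlignment:
    """Query-anchored multiple alignment restricted to the query's span."""

    query_id: str
    query_row: str
    reference_rows: List[Tuple[str, str]]
    column_span: Tuple[int, int]  # on the ungapped query, half-open

    def __post_init__(self):
        width = len(self.query_row)
        for rid, row in self.reference_rows:
            if len(row) != width:
                raise ValueError(f"row {rid} width {len(row)} != {width}")

    @property
    def ungapped_query(self) -> str:
        return self.query_row.replace("-", "")


@dataclass
class UniqueWindow:
    """One sliding-window difference measurement on the query."""

    q_start: int
    length: int
    difference_fraction: float
    flagged: bool
    window_sequence: str


@dataclass
class CandidateRegion:
    """A maximal run of consecutive flagged windows, merged."""

    q_start: int
    q_end: int  # half-open
    n_windows: int
    min_difference: float
    mean_difference: float


def gather_homologs(query: str, db: Sequence[Tuple[str, str]] | KmerIndex,
                    max_evalue: float = DEFAULT_MAX_EVALUE,
                    k: int = DEFAULT_K_DB,
                    query_id: str = "query") -> List[Homolog]:
    """Database homologs of the query with their matched subsequences.

    ``db`` is either (id, sequence) pairs or a prebuilt
    :class:`~avimark.seqsearch.KmerIndex`.  No homologs is a valid outcome
    (every window of the query is then unique by definition).
    """
    index = db if isinstance(db, KmerIndex) else build_kmer_index(db, k=k)
    hits = local_search(query, index, max_evalue=max_evalue, query_id=query_id)
    out = []
    for h in hits:
        sub = index.subjects[h.subject_id][h.s_start:h.s_end]
        if h.strand == "-":
            sub = revcomp(sub)
        out.append(Homolog(hit=h, subsequence=sub))
    return out


def dedupe_homologs(homologs: Sequence[Homolog],
                    identity_threshold: float = DEFAULT_CLUSTER_IDENTITY
                    ) -> List[Homolog]:
    """Greedy-cluster the homolog subsequences and keep the longest
    representative per cluster, preserving each cluster's order of first
    appearance in the input."""
    if not homologs:
        return []
    by_id = {}
    pos = {}
    seqs = []
    for i, h in enumerate(homologs):
        hid = h.hit.subject_id
        if hid in by_id:  # one hit per subject upstream; be defensive
            hid = f"{hid}#{i}"
        by_id[hid] = h
        pos[hid] = i
        seqs.append((hid, h.subsequence))
    clusters = greedy_cluster(seqs, identity_threshold)
    chosen = []
    for cl in clusters:
        first = min(pos[m] for m in cl.member_ids)
        chosen.append((first, by_id[cl.representative_id]))
    chosen.sort(key=lambda t: t[0])
    return [h for _, h in chosen]


def align_to_query(query: str, representatives: Sequence[Tuple[str, str]],
                   scoring: dict | None = None,
                   query_id: str = "query") -> TrimmedAlignment:
    """Query-centred star alignment, trimmed to the query's span.

    Each representative is aligned to the query globally with free end
    gaps; pairwise alignments are merged on the query coordinate frame
    with the "once a gap, always a gap" rule.  Columns outside the query's
    first/last residue are removed, so reference overhangs are trimmed and
    the query row has gaps only at internal insertion columns.
    """
    sc = dict(seqsearch.DEFAULT_SCORING, **(scoring or {}))
    query = query.upper()
    L = len(query)
    # per representative: residue aligned to each query position (-1 = gap)
    # and insertion runs keyed by slot q (rep residues falling between query
    # residues q-1 and q); slots 0 and L are overhangs, trimmed away
    per_rep = []
    for rid, rep in representatives:
        rep = rep.upper()
        _, pq, pr = overlap_align(query, rep, **sc)
        res_at = np.full(L, -1, dtype=int)
        ins_at: Dict[int, List[int]] = {}
        pending: List[int] = []
        for iq, ir in zip(pq, pr):
            if iq < 0:
                if ir >= 0:
                    pending.append(ir)
            else:
                if pending:
                    ins_at[iq] = pending
                    pending = []
                res_at[iq] = ir
        if pending:
            ins_at[L] = pending
        per_rep.append((rid, rep, res_at, ins_at))
    ins_len = np.zeros(L + 1, dtype=int)
    for _, _, _, ins_at in per_rep:
        for slot, residues in ins_at.items():
            if 0 < slot < L:  # overhang slots trimmed
                ins_len[slot] = max(ins_len[slot], len(residues))
    # column layout: for each query position q, ins_len[q] insertion columns
    # (left-aligned fill) then the residue column
    col_of_residue = np.zeros(L, dtype=int)
    col = 0
    for q in range(L):
        col += ins_len[q]
        col_of_residue[q] = col
        col += 1
    width = col
    qrow = ["-"] * width
    for q in range(L):
        qrow[col_of_residue[q]] = query[q]
    rows = []
    for rid, rep, res_at, ins_at in per_rep:
        row = ["-"] * width
        for q in range(L):
            if res_at[q] >= 0:
                row[col_of_residue[q]] = rep[res_at[q]]
            for off, ir in enumerate(ins_at.get(q, []) if 0 < q else []):
                row[col_of_residue[q] - ins_len[q] + off] = rep[ir]
        rows.append((rid, "".join(row)))
    return TrimmedAlignment(query_id=query_id, query_row="".join(qrow),
                            reference_rows=rows, column_span=(0, L))


def scan_windows(aln: TrimmedAlignment,
                 window: int = DEFAULT_WINDOW,
                 difference_threshold: float = DEFAULT_DIFFERENCE_THRESHOLD,
                 min_mismatches: int = DEFAULT_MIN_MISMATCHES
                 ) -> List[UniqueWindow]:
    """Slide a window over the ungapped query and measure, per window, the
    fraction of reference rows that differ from the query.

    A row differs in a window when it has >= ``min_mismatches`` mismatching
    columns there (gap or non-identical/ambiguous symbol = mismatch); rows
    with no aligned residue in the window count as fully mismatched.  With
    zero reference rows every window has difference_fraction 1.0.
    """
    query = aln.ungapped_query
    L = len(query)
    if window > L:
        warnings.warn(f"window {window} longer than trimmed query ({L} nt); "
                      "no windows emitted")
        return []
    # mismatch profile per row at each query residue column
    qcols = [i for i, c in enumerate(aln.query_row) if c != "-"]
    q_codes = encode(query)
    n_rows = len(aln.reference_rows)
    mism = np.zeros((max(n_rows, 1), L), dtype=np.int32)
    covered = np.zeros((max(n_rows, 1), L), dtype=bool)
    for r, (rid, row) in enumerate(aln.reference_rows):
        arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)[qcols]
        codes = _ENCODE[arr]  # '-' and anything non-IUPAC map to 255
        match = (codes == q_codes) & (codes < 4)
        mism[r] = (~match).astype(np.int32)
        covered[r] = arr != ord("-")
    # windowed sums via cumulative sums along the query axis
    cm = np.cumsum(mism, axis=1)
    cc = np.cumsum(covered.astype(np.int32), axis=1)
    out = []
    for w in range(L - window + 1):
        if n_rows == 0:
            frac = 1.0
        else:
            hi, lo = w + window - 1, w - 1
            wm = cm[:, hi] - (cm[:, lo] if lo >= 0 else 0)
            wc = cc[:, hi] - (cc[:, lo] if lo >= 0 else 0)
            differs = (wc == 0) | (wm >= min_mismatches)
            frac = float(np.mean(differs[:n_rows]))
        out.append(UniqueWindow(
            q_start=w, length=window, difference_fraction=frac,
            flagged=frac >= difference_threshold,
            window_sequence=query[w:w + window]))
    return out


def merge_flagged(windows: Sequence[UniqueWindow]) -> List[CandidateRegion]:
    """Merge maximal runs of consecutive flagged windows into regions
    [first q_start, last q_start + window)."""
    regions = []
    run: List[UniqueWindow] = []
    prev_start = None
    for w in sorted(windows, key=lambda w: w.q_start):
        if not w.flagged:
            continue
        if run and w.q_start == prev_start + 1:
            run.append(w)
        else:
            if run:
                regions.append(_close_region(run))
            run = [w]
        prev_start = w.q_start
    if run:
        regions.append(_close_region(run))
    return regions


def _close_region(run: List[UniqueWindow]) -> CandidateRegion:
    fracs = [w.difference_fraction for w in run]
    return CandidateRegion(
        q_start=run[0].q_start, q_end=run[-1].q_start + run[-1].length,
        n_windows=len(run), min_difference=min(fracs),
        mean_difference=sum(fracs) / len(fracs))


def find_unique(query: str, db: Sequence[Tuple[str, str]] | KmerIndex,
                max_evalue: float = DEFAULT_MAX_EVALUE,
                cluster_identity: float = DEFAULT_CLUSTER_IDENTITY,
                window: int = DEFAULT_WINDOW,
                difference_threshold: float = DEFAULT_DIFFERENCE_THRESHOLD,
                min_mismatches: int = DEFAULT_MIN_MISMATCHES,
                query_id: str = "query"):
    """Full per-candidate pipeline: gather -> dedupe -> align -> scan ->
    merge.  Returns (windows, regions, alignment)."""
    homologs = gather_homologs(query, db, max_evalue=max_evalue,
                               query_id=query_id)
    reps = dedupe_homologs(homologs, cluster_identity)
    aln = align_to_query(query,
                         [(h.hit.subject_id, h.subsequence) for h in reps],
                         query_id=query_id)
    windows = scan_windows(aln, window=window,
                           difference_threshold=difference_threshold,
                           min_mismatches=min_mismatches)
    regions = merge_flagged(windows)
    return windows, regions, aln


def windows_bed(query_id: str, windows: Sequence[UniqueWindow]) -> str:
    """BED-like TSV of per-window measurements."""
    lines = ["\t".join(["query_id", "start", "end", "difference_fraction",
                        "flagged"])]
    for w in windows:
        lines.append("\t".join([query_id, str(w.q_start),
                                str(w.q_start + w.length),
                                f"{w.difference_fraction:.4f}",
                                str(int(w.flagged))]))
    return "\n".join(lines) + "\n"


def regions_bed(query_id: str, regions: Sequence[CandidateRegion]) -> str:
    lines = ["\t".join(["query_id", "start", "end", "n_windows",
                        "min_difference", "mean_difference"])]
    for r in regions:
        lines.append("\t".join([query_id, str(r.q_start), str(r.q_end),
                                str(r.n_windows), f"{r.min_difference:.4f}",
                                f"{r.mean_difference:.4f}"]))
    return "\n".join(lines) + "\n"


def alignment_fasta(aln: TrimmedAlignment) -> str:
    lines = [f">{aln.query_id}", aln.query_row]
    for rid, row in aln.reference_rows:
        lines.extend([f">{rid}", row])
    return "\n".join(lines) + "\n"
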