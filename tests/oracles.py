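"""Independent reference implementations used as test oracles.

These deliberately do not share code with the package: alignments come
from biotite's dynamic programming, window mismatch counts from direct
string loops, run-length merging from a plain scan.
"""

from biotite.sequence import NucleotideSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

_MATRIX_CACHE = {}


def _matrix(match, mismatch):
    key = (match, mismatch)
    if key not in _MATRIX_CACHE:
        alph = NucleotideSequence.alphabet_unamb
        _MATRIX_CACHE[key] = SubstitutionMatrix(
            alph, alph, {(a, b): (match if a == b else mismatch)
                         for a in "ACGT" for b in "ACGT"})
    return _MATRIX_CACHE[key]


def sw_score(a, b, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Optimal local alignment score (biotite; gap of length n costs
    gap_open + n*gap_extend)."""
    alns = align_optimal(NucleotideSequence(a), NucleotideSequence(b),
                         _matrix(match, mismatch),
                         gap_penalty=(gap_open + gap_extend, gap_extend),
                         local=True, max_number=1)
    return max(alns[0].score, 0)


def overlap_score(a, b, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Optimal global score with free end gaps; the empty overlap (score 0)
    is allowed, matching the package's convention."""
    alns = align_optimal(NucleotideSequence(a), NucleotideSequence(b),
                         _matrix(match, mismatch),
                         gap_penalty=(gap_open + gap_extend, gap_extend),
                         local=False, terminal_penalty=False, max_number=1)
    return max(alns[0].score, 0)


def overlap_identity(a, b, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Matching columns of an optimal free-end-gap alignment over the
    shorter sequence's length."""
    alns = align_optimal(NucleotideSequence(a), NucleotideSequence(b),
                         _matrix(match, mismatch),
                         gap_penalty=(gap_open + gap_extend, gap_extend),
                         local=False, terminal_penalty=False, max_number=1)
    trace = alns[0].trace
    matches = sum(1 for ia, ib in trace
                  if ia >= 0 and ib >= 0 and a[ia] == b[ib])
    return matches / min(len(a), len(b))


def revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def exhaustive_search(query, subjects, evalue_fn, max_evalue,
                      match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """All-pairs Smith-Waterman search oracle: best local score per subject
    over both strands, filtered by the supplied E-value function.

    Returns {subject_id: best_score} for subjects passing the cutoff.
    """
    out = {}
    for sid, subj in subjects:
        best = max(sw_score(query, subj, match, mismatch, gap_open, gap_extend),
                   sw_score(revcomp(query), subj, match, mismatch, gap_open,
                            gap_extend))
        if best > 0 and evalue_fn(best) <= max_evalue:
            out[sid] = best
    return out


def window_mismatch_recount(query_row, ref_row, q_start, window):
    """Mismatch count of one reference row in one window, by direct scan of
    the alignment columns holding the window's query residues."""
    count = 0
    qpos = -1
    for qc, rc in zip(query_row, ref_row):
        if qc == "-":
            continue
        qpos += 1
        if qpos < q_start:
            continue
        if qpos >= q_start + window:
            break
        if rc == "-" or rc != qc or qc not in "ACGT" or rc not in "ACGT":
            count += 1
    return count


def rle_regions(flag_starts, window):
    """Run-length merge of flagged window starts into half-open regions."""
    regions = []
    for s in sorted(flag_starts):
        if regions and s == regions[-1][2] + 1:
            regions[-1][1] = s + window
            regions[-1][2] = s
        else:
            regions.append([s, s + window, s])
    return [(r[0], r[1]) for r in regions]
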