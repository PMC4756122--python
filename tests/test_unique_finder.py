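"""Homolog gathering, star alignment and unique-window scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from avimark import seqsearch, unique_finder
from avimark.seqsearch import build_kmer_index, evalue
from avimark.unique_finder import (TrimmedAlignment, UniqueWindow,
                                   align_to_query, dedupe_homologs,
                                   gather_homologs, merge_flagged,
                                   scan_windows)
from conftest import mutate, random_dna


def window(q_start, frac, flagged, length=18):
    return UniqueWindow(q_start=q_start, length=length,
                        difference_fraction=frac, flagged=flagged,
                        window_sequence="A" * length)


class TestGatherHomologs:
    def test_verbatim_copy_is_sole_homolog(self, rng):
        q = random_dna(rng, 200)
        db = [("copy", q), ("junk", random_dna(rng, 200))]
        homs = gather_homologs(q, db)
        assert [h.hit.subject_id for h in homs] == ["copy"]
        assert homs[0].subsequence == q

    def test_no_relatives_empty_result(self, rng):
        q = random_dna(rng, 150)
        db = [(f"s{i}", random_dna(rng, 150)) for i in range(5)]
        assert gather_homologs(q, db) == []

    def test_minus_strand_subsequence_in_query_orientation(self, rng):
        q = random_dna(rng, 150)
        db = [("rc", oracles.revcomp(q))]
        homs = gather_homologs(q, db)
        assert homs[0].hit.strand == "-"
        assert homs[0].subsequence == q

    def test_matches_exhaustive_oracle_on_toy_db(self, rng):
        base = random_dna(rng, 180)
        db = [(f"s{i}", mutate(rng, base, 0.06)) for i in range(10)] + \
             [(f"r{i}", random_dna(rng, 180)) for i in range(10)]
        q = mutate(rng, base, 0.03)
        m, n = len(q), sum(len(s) for _, s in db)
        expected = oracles.exhaustive_search(q, db,
                                             lambda s: evalue(s, m, n), 1e-10)
        homs = gather_homologs(q, db)
        assert {h.hit.subject_id: h.hit.raw_score for h in homs} == expected


class TestDedupeHomologs:
    def _homs(self, seqs):
        db = [(f"s{i}", s) for i, s in enumerate(seqs)]
        # gather each against itself to manufacture Homolog objects
        return [unique_finder.Homolog(hit=h.hit, subsequence=h.subsequence)
                for q in [seqs[0]]
                for h in gather_homologs(q, db, max_evalue=1e3)]

    def test_identical_homologs_collapse_to_one(self, rng):
        q = random_dna(rng, 150)
        db = [(f"s{i}", q) for i in range(10)]
        homs = gather_homologs(q, db)
        assert len(dedupe_homologs(homs)) == 1

    def test_distinct_homologs_below_threshold_all_kept(self, rng):
        q = random_dna(rng, 150)
        db = [("a", q), ("b", mutate(rng, q, 0.2)), ("c", mutate(rng, q, 0.2))]
        homs = gather_homologs(q, db, max_evalue=1.0)
        assert len(dedupe_homologs(homs, 0.95)) == len(homs)

    def test_mixed_fixture_matches_bruteforce_oracle(self, rng):
        """Representative set equals an all-pairs greedy oracle, and first
        appearance order is preserved."""
        q = random_dna(rng, 200)
        fams = [q, mutate(rng, q, 0.15)]
        db = [(f"s{i}", mutate(rng, fams[i % 2], 0.01)) for i in range(8)]
        homs = gather_homologs(q, db, max_evalue=10.0)
        got = dedupe_homologs(homs, 0.95)
        # oracle greedy clustering on the same subsequences
        seqs = [(h.hit.subject_id, h.subsequence) for h in homs]
        order = sorted(seqs, key=lambda it: (-len(it[1]), it[0]))
        oracle_clusters = []
        for sid, seq in order:
            for cl in oracle_clusters:
                if oracles.overlap_identity(seq, cl["rep"]) >= 0.95:
                    cl["members"].append(sid)
                    break
            else:
                oracle_clusters.append({"rep": seq, "rep_id": sid,
                                        "members": [sid]})
        assert {h.hit.subject_id for h in got} == \
            {cl["rep_id"] for cl in oracle_clusters}
        firsts = [min(i for i, h in enumerate(homs)
                      if h.hit.subject_id in cl["members"])
                  for cl in oracle_clusters]
        expect_order = [homs[i] for i in sorted(firsts)]
        assert [h.hit.subject_id for h in got] == \
            [cl["rep_id"] for _, cl in sorted(
                zip(firsts, oracle_clusters), key=lambda t: t[0])]


class TestAlignToQuery:
    def test_identical_representative_gap_free(self, rng):
        q = random_dna(rng, 60)
        aln = align_to_query(q, [("r1", q)])
        assert aln.query_row == q
        assert aln.reference_rows == [("r1", q)]
        assert aln.column_span == (0, 60)

    def test_internal_deletion_in_representative(self, rng):
        q = random_dna(rng, 40)
        rep = q[:18] + q[21:]  # 3-nt internal deletion
        aln = align_to_query(q, [("r1", rep)])
        assert aln.query_row == q  # no gap columns in the query row
        row = dict(aln.reference_rows)["r1"]
        assert len(row) == len(q)
        assert row.count("-") == 3
        assert row.replace("-", "") == rep

    def test_insertion_creates_query_gap_column(self):
        q = "ACGTACGTACGTACGTACGT"
        rep = q[:10] + "TT" + q[10:]
        aln = align_to_query(q, [("r1", rep)])
        assert aln.query_row.replace("-", "") == q
        assert aln.query_row.count("-") == 2
        row = dict(aln.reference_rows)["r1"]
        assert row.replace("-", "") == rep

    def test_reference_overhangs_trimmed(self, rng):
        q = random_dna(rng, 80)
        rep = random_dna(rng, 15) + q + random_dna(rng, 15)
        aln = align_to_query(q, [("r1", rep)])
        assert aln.query_row == q
        assert dict(aln.reference_rows)["r1"] == q  # overhangs removed

    def test_degapping_rows_reproduces_inputs(self, rng):
        """Round trip: every reference row de-gaps to its input subsequence
        (representatives chosen without overhangs)."""
        q = random_dna(rng, 120)
        reps = []
        for i in range(5):
            s = mutate(rng, q, 0.05)
            cut = rng.integers(0, 15)
            reps.append((f"r{i}", s[cut:len(s) - rng.integers(0, 15)]))
        aln = align_to_query(q, reps)
        assert aln.query_row.replace("-", "") == q
        degapped = {rid: row.replace("-", "")
                    for rid, row in aln.reference_rows}
        for rid, rep in reps:
            assert degapped[rid] == rep

    def test_empty_representatives(self):
        aln = align_to_query("ACGTACGT", [])
        assert aln.query_row == "ACGTACGT" and aln.reference_rows == []


class TestScanWindows:
    def test_identical_reference_gives_zero_difference(self, rng):
        q = random_dna(rng, 60)
        aln = align_to_query(q, [("r1", q)])
        windows = scan_windows(aln)
        assert len(windows) == 60 - 18 + 1
        assert all(w.difference_fraction == 0.0 and not w.flagged
                   for w in windows)

    def test_window_count_identity(self, rng):
        q = random_dna(rng, 45)
        windows = scan_windows(align_to_query(q, [("r", q)]), window=18)
        assert len(windows) == 45 - 18 + 1
        assert [w.q_start for w in windows] == list(range(28))
        for w in windows:
            assert w.window_sequence == q[w.q_start:w.q_start + 18]

    def test_zero_reference_rows_all_unique(self, rng):
        q = random_dna(rng, 30)
        windows = scan_windows(align_to_query(q, []))
        assert all(w.difference_fraction == 1.0 and w.flagged
                   for w in windows)

    def test_window_longer_than_query_warns_and_returns_empty(self, rng):
        q = random_dna(rng, 10)
        with pytest.warns(UserWarning):
            assert scan_windows(align_to_query(q, [("r", q)])) == []

    def test_planted_randomized_segment_flagged_against_bruteforce(self, rng):
        """With 10 references identical to the query outside a randomized
        30-nt segment, flagged windows are exactly those overlapping enough
        of the segment; per-window mismatch counts equal an independent
        brute-force recount over the alignment columns."""
        q = random_dna(rng, 120)
        seg = (50, 80)
        reps = []
        for i in range(10):
            s = list(q)
            s[seg[0]:seg[1]] = random_dna(rng, 30)
            reps.append((f"r{i}", "".join(s)))
        aln = align_to_query(q, reps)
        windows = scan_windows(aln, window=18, difference_threshold=0.9,
                               min_mismatches=2)
        rows = dict(aln.reference_rows)
        for w in windows:
            differing = 0
            for rid in rows:
                mism = oracles.window_mismatch_recount(
                    aln.query_row, rows[rid], w.q_start, 18)
                if mism >= 2:
                    differing += 1
            assert w.difference_fraction == pytest.approx(differing / 10)
            assert w.flagged == (w.difference_fraction >= 0.9)

    def test_uncovered_reference_counts_fully_mismatched(self, rng):
        q = random_dna(rng, 100)
        # reference covering only the first 40 nt of the query
        aln = align_to_query(q, [("r1", q[:40])])
        windows = scan_windows(aln)
        tail = [w for w in windows if w.q_start >= 40]
        assert all(w.difference_fraction == 1.0 for w in tail)

    def test_threshold_monotonicity(self, rng):
        q = random_dna(rng, 90)
        reps = [(f"r{i}", mutate(rng, q, 0.15)) for i in range(6)]
        aln = align_to_query(q, reps)
        flagged_sets = []
        for thr in (0.5, 0.7, 0.9, 1.0):
            ws = scan_windows(aln, difference_threshold=thr)
            flagged_sets.append({w.q_start for w in ws if w.flagged})
        for bigger, smaller in zip(flagged_sets, flagged_sets[1:]):
            assert smaller <= bigger

    def test_min_mismatch_monotonicity(self, rng):
        q = random_dna(rng, 90)
        reps = [(f"r{i}", mutate(rng, q, 0.1)) for i in range(6)]
        aln = align_to_query(q, reps)
        prev = None
        for mm in (1, 2, 3, 5):
            fracs = [w.difference_fraction
                     for w in scan_windows(aln, min_mismatches=mm)]
            if prev is not None:
                assert all(b <= a for a, b in zip(prev, fracs))
            prev = fracs

    def test_identical_rows_dilute_and_eventually_unflag(self, rng):
        """Adding copies of the query to the reference set pushes every
        difference fraction strictly below 1 and, with enough copies,
        below the flagging threshold."""
        q = random_dna(rng, 70)
        diverged = [(f"d{i}", mutate(rng, q, 0.5)) for i in range(3)]
        aln = align_to_query(q, diverged)
        assert any(w.flagged for w in scan_windows(aln))
        with_self = diverged + [("self0", q)]
        ws = scan_windows(align_to_query(q, with_self))
        assert all(w.difference_fraction < 1.0 for w in ws)
        many_self = diverged + [(f"self{i}", q) for i in range(7)]
        ws = scan_windows(align_to_query(q, many_self))
        assert not any(w.flagged for w in ws)


class TestMergeFlagged:
    def test_consecutive_run_merges(self):
        ws = [window(5, 1.0, True), window(6, 0.95, True),
              window(7, 1.0, True)]
        regions = merge_flagged(ws)
        assert len(regions) == 1
        r = regions[0]
        assert (r.q_start, r.q_end) == (5, 25)
        assert r.min_difference == pytest.approx(0.95)
        assert r.mean_difference == pytest.approx((1 + 0.95 + 1) / 3)

    def test_no_flags_no_regions(self):
        assert merge_flagged([window(i, 0.1, False) for i in range(5)]) == []

    @given(st.lists(st.booleans(), min_size=0, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_random_patterns_match_rle_oracle(self, flags):
        ws = [window(i, 1.0 if f else 0.0, f) for i, f in enumerate(flags)]
        regions = merge_flagged(ws)
        expected = oracles.rle_regions(
            [i for i, f in enumerate(flags) if f], 18)
        assert [(r.q_start, r.q_end) for r in regions] == expected
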