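"""SSR and long-repeat detection against independent brute-force oracles."""

import numpy as np
import pytest

from cpbarcode.io import SequenceRecord, revcomp
from cpbarcode.repeats import (DEFAULT_SSR_THRESHOLDS, canonical_motif,
                               find_long_repeats, find_ssrs, summarize_repeats)
from cpbarcode.structure import QuadripartitePartition

from conftest import random_dna


# ---------------------------------------------------------------------------
# oracles (independent, O(L*P) / O(L^2) scans)

def brute_force_ssrs(seq: str, thresholds=DEFAULT_SSR_THRESHOLDS):
    """Maximal perfect tandem runs via direct per-offset scanning."""
    L = len(seq)
    out = set()
    for p in range(1, 7):
        i = 0
        last_end = 0  # left run wins on same-period overlap
        while i + p <= L:
            # i must be a left-maximal run start
            if i > 0 and i + p <= L and seq[i - 1] == seq[i + p - 1] and "N" not in seq[i - 1 : i + p]:
                i += 1
                continue
            # count whole copies of seq[i:i+p]
            unit = seq[i : i + p]
            if "N" in unit:
                i += 1
                continue
            copies = 1
            while seq[i + copies * p : i + (copies + 1) * p] == unit:
                copies += 1
            if copies >= thresholds[p - 1] and i + 1 > last_end:
                span = unit * copies
                # minimal period of the whole span must be exactly p
                minp = next(d for d in range(1, len(span) + 1)
                            if len(span) % d == 0 and span == span[:d] * (len(span) // d))
                if minp == p:
                    out.add((canonical_motif(unit), p, copies, i + 1, i + p * copies))
                    last_end = i + p * copies
            i += 1
    return out


def brute_force_repeats(seq: str, min_len=30):
    """All maximal repeated pairs via full dot-plot diagonal scanning."""
    L = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = set()
    # direct: runs along diagonals d = j - i >= 1
    for d in range(1, L):
        run = 0
        for i in range(L - d):
            if seq[i] == seq[i + d] and seq[i] != "N":
                run += 1
            else:
                if run >= min_len:
                    s = i - run
                    out.add((s + 1, s + d + 1, run, "direct"))
                run = 0
        if run >= min_len:
            s = L - d - run
            out.add((s + 1, s + d + 1, run, "direct"))
    # inverted: runs along antidiagonals c = i + j, kept to the i < j half
    # so the two occurrences never overlap (a palindrome is its two halves)
    for c in range(2 * L - 1):
        run = 0
        i_lo = max(0, c - L + 1)
        i_hi = min(c - i_lo, L - 1, (c - 1) // 2)
        for i in range(i_lo, i_hi + 1):
            j = c - i
            if seq[i] != "N" and seq[i] == comp.get(seq[j], "?"):
                run += 1
            else:
                if run >= min_len:
                    a0 = i - run  # A = [a0, i), B = [c - i + 1, c - a0 + 1)
                    b0 = c - i + 1
                    out.add((a0 + 1, b0 + 1, run, "inverted"))
                run = 0
        i = i_hi + 1
        if run >= min_len:
            a0 = i - run
            b0 = c - i + 1
            out.add((a0 + 1, b0 + 1, run, "inverted"))
    return out


def _as_set_ssr(records):
    return {(r.motif, r.period, r.copies, r.start, r.end) for r in records}


def _as_set_lr(records):
    return {(r.occurrence_a[0], r.occurrence_b[0], r.length, r.orientation)
            for r in records}


# ---------------------------------------------------------------------------

class TestSSR:
    def test_planted_dinucleotide_run(self, rng):
        # quiet thresholds so the random background cannot fire
        thr = (25, 15, 10, 10, 10, 10)
        body = random_dna(rng, 900)
        seq = body[:400] + "AT" * 15 + body[400:]
        recs = find_ssrs(SequenceRecord(id="x", sequence=seq), thr)
        di = [r for r in recs if r.period == 2]
        assert len(di) == 1
        assert (di[0].motif, di[0].copies) == ("AT", 15)
        assert di[0].end - di[0].start + 1 == 30

    def test_mononucleotide_below_threshold_not_reported(self, rng):
        seq = "G" + "A" * 24 + "C" + random_dna(rng, 200)
        recs = find_ssrs(SequenceRecord(id="x", sequence=seq))
        assert not any(r.period == 1 for r in recs)

    def test_homopolymer_reported_only_as_mono(self):
        seq = "C" + "A" * 30 + "G" + "TCTG" * 3
        recs = find_ssrs(SequenceRecord(id="x", sequence=seq), (25, 15, 2, 2, 2, 2))
        mono = [r for r in recs if "A" in r.motif]
        assert len(mono) == 1 and mono[0].period == 1 and mono[0].copies == 30

    def test_runs_split_at_n(self):
        seq = "A" * 30 + "N" + "A" * 30
        recs = find_ssrs(SequenceRecord(id="x", sequence=seq))
        assert [(r.start, r.copies) for r in recs] == [(1, 30), (32, 30)]

    def test_oracle_equivalence_random_sequences(self, rng):
        for _ in range(100):
            L = int(rng.integers(200, 2000))
            seq = random_dna(rng, L)
            if rng.random() < 0.5:  # plant something detectable
                motif = random_dna(rng, int(rng.integers(1, 7)))
                pos = int(rng.integers(0, L - 120))
                seq = seq[:pos] + motif * 20 + seq[pos + len(motif) * 20:]
            rec = SequenceRecord(id="x", sequence=seq)
            assert _as_set_ssr(find_ssrs(rec)) == brute_force_ssrs(seq)

    def test_no_same_period_overlaps(self, rng):
        seq = random_dna(rng, 2000)
        recs = find_ssrs(SequenceRecord(id="x", sequence=seq))
        by_period = {}
        for r in recs:
            by_period.setdefault(r.period, []).append((r.start, r.end))
        for spans in by_period.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 > e1


class TestLongRepeats:
    def test_planted_direct_duplicate(self, rng):
        unit = random_dna(rng, 35)
        filler = random_dna(rng, 400)
        seq = "TT" + unit + filler + unit + "GG"
        recs = [r for r in find_long_repeats(SequenceRecord(id="x", sequence=seq), 30)
                if r.orientation == "direct" and r.length >= 35]
        assert any(r.length == 35 for r in recs)

    def test_x_plus_revcomp_x(self, rng):
        x = random_dna(rng, 50)
        seq = x + revcomp(x)
        recs = find_long_repeats(SequenceRecord(id="x", sequence=seq), 30)
        inv = [r for r in recs if r.orientation == "inverted"]
        assert len(inv) == 1 and inv[0].length == 50
        assert inv[0].occurrence_a == (1, 50) and inv[0].occurrence_b == (51, 100)

    def test_oracle_equivalence_with_planted_repeats(self, rng):
        for _ in range(50):
            L = int(rng.integers(300, 1000))
            seq = random_dna(rng, L)
            unit = random_dna(rng, int(rng.integers(30, 60)))
            p1 = int(rng.integers(0, L // 3))
            p2 = int(rng.integers(L // 2, L - len(unit)))
            second = unit if rng.random() < 0.5 else revcomp(unit)
            seq = seq[:p1] + unit + seq[p1 + len(unit):]
            seq = seq[:p2] + second + seq[p2 + len(second):]
            rec = SequenceRecord(id="x", sequence=seq)
            assert _as_set_lr(find_long_repeats(rec, 30)) == brute_force_repeats(seq, 30)

    def test_revcomp_maps_orientations_onto_themselves(self, rng):
        for _ in range(10):
            L = int(rng.integers(300, 800))
            seq = random_dna(rng, L)
            unit = random_dna(rng, 40)
            seq = seq[:50] + unit + seq[90:200] + revcomp(unit) + seq[240:]
            fwd = find_long_repeats(SequenceRecord(id="f", sequence=seq), 30)
            rev = find_long_repeats(SequenceRecord(id="r", sequence=revcomp(seq)), 30)
            L = len(seq)

            def mirror(records):
                out = set()
                for r in records:
                    a = (L - r.occurrence_a[1] + 1, L - r.occurrence_a[0] + 1)
                    b = (L - r.occurrence_b[1] + 1, L - r.occurrence_b[0] + 1)
                    lo, hi = sorted([a, b])
                    out.add((lo, hi, r.length, r.orientation))
                return out

            assert mirror(fwd) == {( r.occurrence_a, r.occurrence_b, r.length, r.orientation) for r in rev}


class TestSummaries:
    def _partition(self, lsc, ir, ssc):
        L = lsc + ssc + 2 * ir
        return QuadripartitePartition(
            accession="x", genome_length=L, quadripartite=True,
            lsc=(1, lsc), irb=(lsc + 1, lsc + ir),
            ssc=(lsc + ir + 1, lsc + ir + ssc), ira=(lsc + ir + ssc + 1, L))

    def test_ssrs_planted_in_lsc_counted_there(self, rng):
        from cpbarcode.repeats import SSRRecord
        part = self._partition(5000, 1200, 1000)
        ssrs = [SSRRecord("AT", 2, 15, 100 + 60 * i, 100 + 60 * i + 29)
                for i in range(4)]
        tab, _ = summarize_repeats(ssrs, [], part)
        assert tab.loc[2, "LSC"] == 4
        assert tab.drop(columns="LSC").to_numpy().sum() == 0

    def test_ir_trinucleotide_fixture_counts(self):
        # five tri-SSR loci planted inside the IR intervals
        from cpbarcode.repeats import SSRRecord
        part = self._partition(5000, 1200, 1000)
        irb0, ira0 = 5001, 5000 + 1200 + 1000 + 1
        ssrs = ([SSRRecord("AAT", 3, 4, irb0 + 50 * i, irb0 + 50 * i + 11)
                 for i in range(3)]
                + [SSRRecord("AAT", 3, 4, ira0 + 50 * i, ira0 + 50 * i + 11)
                   for i in range(2)])
        tab, _ = summarize_repeats(ssrs, [], part)
        assert tab.loc[3, ["IRa", "IRb"]].sum() == 5

    def test_junction_spanning_repeat_counted_by_midpoint(self):
        from cpbarcode.repeats import SSRRecord
        part = self._partition(5000, 1200, 1000)
        # run straddles LSC/IRb junction, midpoint inside IRb
        r = SSRRecord("A", 1, 30, 4990, 5019)
        tab, _ = summarize_repeats([r], [], part)
        assert tab.loc[1, "IRb"] == 1

    def test_structural_ir_flagged_once(self, rng):
        from cpbarcode.synthetic import build_ancestor
        from cpbarcode.structure import detect_quadripartite
        from conftest import small_ancestor_spec
        anc = build_ancestor(small_ancestor_spec(seed=77))
        part = detect_quadripartite(anc.record)
        recs = find_long_repeats(anc.record, 30, part)
        flagged = [r for r in recs if r.is_structural_ir]
        assert len(flagged) == 1
        assert flagged[0].length == part.ir_len
        assert flagged[0].orientation == "inverted"
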