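"""Perfect-SSR and exact long-repeat detection.

SSRs are maximal perfect tandem runs of a 1-6 bp motif meeting a
period-specific minimum copy number (defaults 25/15/2/2/2/2 for mono-
through hexanucleotides).  Long repeats are maximal exact repeated pairs,
direct or inverted, of at least 30 bp at 100% identity.  Compound SSRs are
not merged; each perfect run is reported separately under its smallest
period, with the motif canonicalised to its lexicographically minimal
rotation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import SequenceRecord, revcomp
from .structure import QuadripartitePartition

__all__ = [
    "SSRRecord",
    "LongRepeatRecord",
    "find_ssrs",
    "find_long_repeats",
    "summarize_repeats",
]

DEFAULT_SSR_THRESHOLDS = (25, 15, 2, 2, 2, 2)


@dataclass(frozen=True)
class SSRRecord:
    """One perfect microsatellite run; coordinates 1-based inclusive."""

    motif: str
    period: int
    copies: int
    start: int
    end: int
    region_label: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.period * self.copies:
            raise ValueError("SSR span must equal period x copies")


@dataclass(frozen=True)
class LongRepeatRecord:
    """A maximal exact repeated pair; intervals 1-based inclusive.

    occurrence_a starts before occurrence_b.  ``is_structural_ir`` marks
    the pair corresponding to the plastome's IRa/IRb copies.
    """

    length: int
    occurrence_a: tuple[int, int]
    occurrence_b: tuple[int, int]
    orientation: str  # direct | inverted
    identity: float = 1.0
    is_structural_ir: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.occurrence_a == self.occurrence_b:
            raise ValueError("repeat occurrences must be distinct intervals")


def _min_period(s: str) -> int:
    """Smallest p such that s is a whole number of repeats of s[:p]."""
    n = len(s)
    for p in range(1, n + 1):
        if n % p == 0 and s == s[:p] * (n // p):
            return p
    return n


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation of a motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(genome: SequenceRecord,
              thresholds: Sequence[int] = DEFAULT_SSR_THRESHOLDS) -> list[SSRRecord]:
    """All maximal perfect tandem runs meeting their period's copy threshold.

    Each run is reported once, under its smallest period: a homopolymer of
    30 A is a mono-SSR, never a period-2 "AA" run.  Runs are interrupted at
    N.  The input must be ungapped.
    """
    seq = genome.sequence.upper()
    if "-" in seq:
        raise ValueError("SSR detection requires an ungapped sequence")
    if len(thresholds) != 6:
        raise ValueError("need one copy threshold per period 1..6")
    L = len(seq)
    out: list[SSRRecord] = []
    for p in range(1, 7):
        i = 0
        last_end = 0  # same-period runs never overlap: left run wins
        while i + p <= L:
            if "N" in seq[i : i + p]:
                i += 1
                continue
            # longest stretch from i where seq[j] == seq[j+p]
            j = i
            while j + p < L and seq[j] == seq[j + p] and seq[j + p] != "N":
                j += 1
            run_len = (j - i) + p  # total bases in the tandem stretch
            copies = run_len // p
            if copies >= thresholds[p - 1] and i + 1 > last_end:
                span = seq[i : i + p * copies]
                if _min_period(span) == p:
                    out.append(SSRRecord(
                        motif=canonical_motif(span[:p]),
                        period=p,
                        copies=copies,
                        start=i + 1,
                        end=i + p * copies,
                    ))
                    last_end = i + p * copies
            # next maximal run at this period cannot start before j+1
            i = max(i + 1, j + 1)
    out.sort(key=lambda r: (r.start, r.period))
    return out


def _maximal_pairs(seq: str, min_len: int, inverted: bool) -> set[tuple[int, int, int]]:
    """Maximal exact repeated pairs as (a0, b0, length), 0-based starts.

    Seed-and-extend over a k-mer index with k = min_len, grouping direct
    seeds by diagonal (b-a) and inverted seeds by antidiagonal (a_start +
    b_end); every maximal match of length >= k contains a seed, so
    extending one seed per (anti)diagonal segment finds them all.
    """
    L = len(seq)
    k = min_len
    if L < k:
        return set()
    target = revcomp(seq) if inverted else seq
    # positions of each k-mer in the plain sequence
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(L - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            index[km].append(i)

    comp = str.maketrans("ACGT", "TGCA")
    found: set[tuple[int, int, int]] = set()
    covered: dict[int, list[tuple[int, int]]] = defaultdict(list)  # diag -> a-intervals done
    for a0 in range(L - k + 1):
        km = seq[a0 : a0 + k]
        if "N" in km:
            continue
        probe = revcomp(km) if inverted else km
        for b0 in index.get(probe, ()):
            if not inverted:
                if b0 <= a0:
                    continue  # each unordered pair once, a before b
                diag = b0 - a0
            else:
                # b occurrence [b0, b0+k) equals revcomp of a occurrence;
                # occurrences are disjoint by convention (a palindrome is
                # reported as its two non-overlapping halves), so the
                # touching seed b0 = a_end always exists for a real pair
                if b0 < a0 + k:
                    continue
                diag = a0 + b0 + k  # antidiagonal invariant under extension
            if any(lo <= a0 < hi for lo, hi in covered[diag if not inverted else -diag]):
                continue
            # extend
            x, u = a0, a0 + k  # a interval [x, u)
            y, v = b0, b0 + k  # b interval [y, v)
            if not inverted:
                while x > 0 and y > 0 and seq[x - 1] == seq[y - 1] and seq[x - 1] != "N":
                    x -= 1
                    y -= 1
                while u < L and v < L and seq[u] == seq[v] and seq[u] != "N":
                    u += 1
                    v += 1
            else:
                # left of a pairs with right of b
                while x > 0 and v < L and seq[x - 1] == seq[v].translate(comp) and seq[x - 1] != "N":
                    x -= 1
                    v += 1
                # right of a pairs with left of b, capped so the two
                # occurrences stay disjoint (u never passes y)
                while (u + 1 <= y - 1 and u < L and y > 0
                       and seq[u] == seq[y - 1].translate(comp) and seq[u] != "N"):
                    u += 1
                    y -= 1
            covered[diag if not inverted else -diag].append((x, u))
            length = u - x
            if x == y:
                continue
            lo_start, hi_start = min(x, y), max(x, y)
            found.add((lo_start, hi_start, length))
    return found


def find_long_repeats(genome: SequenceRecord, min_len: int = 30,
                      partition: Optional[QuadripartitePartition] = None,
                      ) -> list[LongRepeatRecord]:
    """All maximal exact repeated pairs >= min_len, direct and inverted.

    Occurrences may overlap each other (tandem duplications) but identical
    interval pairs are reported once, occurrence_a first by start position.
    When a partition is supplied (or the longest inverted pair spans
    >= 1000 bp) that pair is flagged as the structural IR.
    """
    seq = genome.sequence.upper()
    if "-" in seq:
        raise ValueError("repeat detection requires an ungapped sequence")
    records: list[LongRepeatRecord] = []
    for orientation, inverted in (("direct", False), ("inverted", True)):
        for a0, b0, n in _maximal_pairs(seq, min_len, inverted):
            records.append(LongRepeatRecord(
                length=n,
                occurrence_a=(a0 + 1, a0 + n),
                occurrence_b=(b0 + 1, b0 + n),
                orientation=orientation,
            ))
    records.sort(key=lambda r: (-r.length, r.occurrence_a, r.occurrence_b, r.orientation))

    # flag the structural IR pair
    ir_pair: Optional[tuple[tuple[int, int], tuple[int, int]]] = None
    if partition is not None and partition.quadripartite:
        # partition coordinates are canonical; translate to input coordinates
        L = partition.genome_length
        off = partition.rotation_offset

        def to_input(iv: tuple[int, int]) -> tuple[int, int]:
            s = (iv[0] - 1 + off) % L + 1
            e = (iv[1] - 1 + off) % L + 1
            return (s, e)

        pair = sorted([to_input(partition.irb), to_input(partition.ira)])
        ir_pair = (pair[0], pair[1])
    flagged: list[LongRepeatRecord] = []
    ir_done = False
    for r in records:
        is_ir = False
        if ir_pair is not None:
            is_ir = (r.occurrence_a, r.occurrence_b) == ir_pair and r.orientation == "inverted"
        elif not ir_done and r.orientation == "inverted" and r.length >= 1000:
            is_ir = r.length == max(
                x.length for x in records if x.orientation == "inverted"
            )
        if is_ir:
            ir_done = True
            r = LongRepeatRecord(length=r.length, occurrence_a=r.occurrence_a,
                                 occurrence_b=r.occurrence_b,
                                 orientation=r.orientation, is_structural_ir=True)
        flagged.append(r)
    return flagged


def _region_of(midpoint: int, partition: QuadripartitePartition) -> str:
    for label, iv in (("LSC", partition.lsc), ("IRb", partition.irb),
                      ("SSC", partition.ssc), ("IRa", partition.ira)):
        if iv[0] <= midpoint <= iv[1]:
            return label
    return "?"


def assign_regions(ssrs: Sequence[SSRRecord],
                   partition: QuadripartitePartition) -> list[SSRRecord]:
    """Label each SSR with the region containing its midpoint.

    SSR coordinates must be on the partition's canonical orientation.
    """
    out = []
    for r in ssrs:
        mid = (r.start + r.end) // 2
        out.append(SSRRecord(motif=r.motif, period=r.period, copies=r.copies,
                             start=r.start, end=r.end,
                             region_label=_region_of(mid, partition)))
    return out


def summarize_repeats(ssrs: Sequence[SSRRecord],
                      long_repeats: Sequence[LongRepeatRecord],
                      partition: QuadripartitePartition,
                      length_bins: Sequence[int] = (30, 40, 50, 100, 1000),
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count SSRs per region per period and long repeats per length class.

    A repeat spanning a junction is counted in the region containing its
    midpoint.  IRa and IRb hits are counted separately, one per genome
    copy.  Returns (ssr_table, long_repeat_table).
    """
    if not partition.quadripartite:
        raise ValueError("summary requires a quadripartite partition")
    regions = ["LSC", "IRb", "SSC", "IRa"]
    ssr_counts = pd.DataFrame(0, index=pd.Index(range(1, 7), name="period"),
                              columns=regions)
    for r in assign_regions(ssrs, partition):
        if r.region_label in regions:
            ssr_counts.loc[r.period, r.region_label] += 1

    bins = list(length_bins)
    labels = [f"{bins[i]}-{bins[i+1]-1}" for i in range(len(bins) - 1)] + [f">={bins[-1]}"]
    lr_counts = pd.DataFrame(0, index=pd.Index(labels, name="length_class"),
                             columns=["direct", "inverted"])
    for rep in long_repeats:
        cls = labels[-1]
        for i in range(len(bins) - 1):
            if bins[i] <= rep.length < bins[i + 1]:
                cls = labels[i]
                break
        lr_counts.loc[cls, rep.orientation] += 1
    return ssr_counts, lr_counts
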