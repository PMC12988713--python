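"""Quadripartite structure detection for circular plastomes.

A typical plastome is a circle partitioned into a large single-copy region
(LSC), an inverted repeat (IRb), a small single-copy region (SSC) and a
second inverted repeat (IRa) that is the exact reverse complement of IRb.
The detector finds the longest pair of disjoint reverse-complement
intervals by seed-and-extend over a k-mer index (k=21) and labels the
longer single-copy gap between them LSC.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import SequenceRecord, revcomp

__all__ = ["QuadripartitePartition", "detect_quadripartite", "compare_structures"]

_SEED_K = 21


@dataclass(frozen=True)
class QuadripartitePartition:
    """Detected LSC/IRb/SSC/IRa partition, 1-based inclusive coordinates.

    Intervals are reported on the canonical orientation: the sequence
    rotated so it starts at the IRa/LSC junction (LSC first, then IRb, SSC,
    IRa).  ``rotation_offset`` is the 0-based position in the *input*
    sequence that becomes position 1 of the canonical orientation.
    ``junctions`` holds the four boundary positions (last base of LSC, of
    IRb, of SSC, of IRa) in canonical coordinates.
    """

    accession: str
    genome_length: int
    quadripartite: bool
    lsc: Optional[tuple[int, int]] = None
    irb: Optional[tuple[int, int]] = None
    ssc: Optional[tuple[int, int]] = None
    ira: Optional[tuple[int, int]] = None
    rotation_offset: int = 0

    def __post_init__(self) -> None:
        if self.quadripartite:
            iv = [self.lsc, self.irb, self.ssc, self.ira]
            if any(v is None for v in iv):
                raise ValueError("quadripartite partition missing an interval")
            total = sum(b - a + 1 for a, b in iv)
            if total != self.genome_length:
                raise ValueError(
                    f"intervals cover {total} bp but genome is {self.genome_length} bp"
                )
            if self.ir_len_a != self.ir_len_b:
                raise ValueError("IRa and IRb lengths differ")

    @property
    def lsc_len(self) -> Optional[int]:
        return self.lsc[1] - self.lsc[0] + 1 if self.lsc else None

    @property
    def ssc_len(self) -> Optional[int]:
        return self.ssc[1] - self.ssc[0] + 1 if self.ssc else None

    @property
    def ir_len_a(self) -> Optional[int]:
        return self.ira[1] - self.ira[0] + 1 if self.ira else None

    @property
    def ir_len_b(self) -> Optional[int]:
        return self.irb[1] - self.irb[0] + 1 if self.irb else None

    @property
    def ir_len(self) -> Optional[int]:
        return self.ir_len_a

    @property
    def junctions(self) -> Optional[dict[str, int]]:
        if not self.quadripartite:
            return None
        return {
            "LSC/IRb": self.lsc[1],
            "IRb/SSC": self.irb[1],
            "SSC/IRa": self.ssc[1],
            "IRa/LSC": self.ira[1],
        }

    def to_dict(self) -> dict:
        d = {
            "accession": self.accession,
            "genome_length": self.genome_length,
            "quadripartite": self.quadripartite,
        }
        if self.quadripartite:
            d.update(
                lsc=list(self.lsc), irb=list(self.irb), ssc=list(self.ssc),
                ira=list(self.ira), lsc_len=self.lsc_len, ssc_len=self.ssc_len,
                ir_len=self.ir_len, junctions=self.junctions,
                rotation_offset=self.rotation_offset,
            )
        return d


def _maximal_inverted_pairs(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal inverted-repeat pairs on the circle, as (a0, b0, length).

    a0/b0 are 0-based start positions modulo L of the two occurrences; the
    pair sequences satisfy seq[b0:b0+len] == revcomp(seq[a0:a0+len]).
    Operates on the doubled sequence so repeats spanning the origin are
    found; pairs are deduplicated modulo L.
    """
    L = len(seq)
    k = min(_SEED_K, min_len)
    s2 = seq + seq
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(2 * L - k + 1):
        index[s2[i : i + k]].append(i)

    comp = str.maketrans("ACGTN", "TGCAN")
    found: dict[tuple[int, int, int], None] = {}
    # A match seq2[a0:a1] == revcomp(seq2[b0:b1]) is preserved under
    # simultaneous extension; a0+b1 is its antidiagonal invariant.  A seed
    # is skipped only if a previous extension on the same antidiagonal
    # already covered its position (one antidiagonal can carry several
    # separate matches, including boundary-truncated echoes of a wrapped
    # repeat).
    covered: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for a0 in range(L):
        seed = s2[a0 : a0 + k]
        if "N" in seed:
            continue
        rc = revcomp(seed)
        for b0 in index.get(rc, ()):  # b interval is [b0, b0+k)
            anti = a0 + b0 + k
            if any(lo <= a0 < hi for lo, hi in covered[anti]):
                continue
            # extend left of a / right of b
            x, y = a0, b0 + k
            while x > 0 and y < 2 * L and s2[x - 1] == s2[y].translate(comp) and s2[x - 1] != "N":
                x -= 1
                y += 1
            # extend right of a / left of b
            u, v = a0 + k, b0
            while u < 2 * L and v > 0 and s2[u] == s2[v - 1].translate(comp) and s2[u] != "N":
                u += 1
                v -= 1
            covered[anti].append((x, u))
            length = u - x
            if length < min_len or length > L:
                continue
            a_start, b_start = x % L, v % L
            # unordered pair, canonical order by start
            key = (min(a_start, b_start), max(a_start, b_start), length)
            if a_start == b_start:
                continue  # self-palindrome, single occurrence
            found[key] = None
    return [(a, b, n) for (a, b, n) in found.keys()]


def _circ_gap(end_excl: int, start: int, L: int) -> int:
    """Length of the circular gap from position end_excl to start (0-based)."""
    return (start - end_excl) % L


def detect_quadripartite(genome: SequenceRecord, min_ir_len: int = 1000,
                         max_mismatch_frac: float = 0.0) -> QuadripartitePartition:
    """Detect the LSC/IRb/SSC/IRa partition of a plastome.

    Returns the longest pair of disjoint intervals whose sequences are
    exact reverse complements (mismatches are not currently supported;
    ``max_mismatch_frac`` must be 0).  The longer single-copy gap between
    the two IR copies is labeled LSC.  If no disjoint reverse-complement
    pair of at least ``min_ir_len`` exists the partition is reported as
    non-quadripartite.
    """
    if max_mismatch_frac != 0.0:
        raise NotImplementedError("only exact IR detection (max_mismatch_frac=0) is supported")
    seq = genome.sequence.upper()
    L = len(seq)
    if L < 4 * min_ir_len:
        raise ValueError(
            f"{genome.id}: genome length {L} below 4 x min_ir_len={min_ir_len}"
        )
    if not genome.circular:
        warnings.warn(
            f"{genome.id}: sequence not marked circular; treating position 1 as origin",
            stacklevel=2,
        )

    pairs = [
        (a, b, n)
        for a, b, n in _maximal_inverted_pairs(seq, min_ir_len)
        # disjoint on the circle: gap from end of each to start of the other
        if _circ_gap((a + n) % L, b, L) + _circ_gap((b + n) % L, a, L) + 2 * n == L
        and _circ_gap((a + n) % L, b, L) > 0 and _circ_gap((b + n) % L, a, L) > 0
    ]
    if not pairs:
        return QuadripartitePartition(accession=genome.id, genome_length=L,
                                      quadripartite=False)

    def sort_key(p: tuple[int, int, int]) -> tuple[int, int, int, int]:
        a, b, n = p
        shorter_gap = min(_circ_gap((a + n) % L, b, L), _circ_gap((b + n) % L, a, L))
        # longest IR first; ties -> most balanced SSC; then position for determinism
        return (-n, -shorter_gap, a, b)

    a, b, n = min(pairs, key=sort_key)
    gap_ab = _circ_gap((a + n) % L, b, L)  # gap after copy at a, before copy at b
    gap_ba = _circ_gap((b + n) % L, a, L)
    # LSC = longer gap.  Canonical orientation: LSC, IRb, SSC, IRa.
    if gap_ba >= gap_ab:
        lsc_len, ssc_len = gap_ba, gap_ab
        irb_start0 = a  # copy following LSC
    else:
        lsc_len, ssc_len = gap_ab, gap_ba
        irb_start0 = b
    lsc_start0 = (irb_start0 - lsc_len) % L
    return QuadripartitePartition(
        accession=genome.id,
        genome_length=L,
        quadripartite=True,
        lsc=(1, lsc_len),
        irb=(lsc_len + 1, lsc_len + n),
        ssc=(lsc_len + n + 1, lsc_len + n + ssc_len),
        ira=(lsc_len + n + ssc_len + 1, L),
        rotation_offset=lsc_start0,
    )


def compare_structures(partitions: Sequence[QuadripartitePartition]) -> pd.DataFrame:
    """Tabulate per-accession region lengths and pairwise deltas.

    Returns a tidy frame with one row per accession (lengths; blank for
    non-quadripartite accessions, which are flagged) followed by one row
    per ordered accession pair holding the per-region length differences.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions to compare")
    rows = []
    for p in partitions:
        rows.append({
            "row_type": "accession",
            "accession": p.accession,
            "other": "",
            "genome_length": p.genome_length,
            "lsc_len": p.lsc_len,
            "ssc_len": p.ssc_len,
            "ir_len": p.ir_len,
            "quadripartite": p.quadripartite,
        })
    quad = [p for p in partitions if p.quadripartite]
    for i, p in enumerate(quad):
        for q in quad[i + 1:]:
            rows.append({
                "row_type": "delta",
                "accession": p.accession,
                "other": q.accession,
                "genome_length": abs(p.genome_length - q.genome_length),
                "lsc_len": abs(p.lsc_len - q.lsc_len),
                "ssc_len": abs(p.ssc_len - q.ssc_len),
                "ir_len": abs(p.ir_len - q.ir_len),
                "quadripartite": True,
            })
    return pd.DataFrame(rows)
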