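"""Barcode marker design: primer pairs anchored in conserved flanks.

Around each diversity hotspot the designer enumerates fully conserved
alignment windows of primer length (18-25 nt by default) upstream and
downstream of the hotspot's variable span, and pairs them so that every
accession's ungapped PCR product (5' end of the forward primer through the
3' end of the reverse primer binding site) lies inside the configured
product-size bounds (250-1500 bp).  Melting temperatures use the Wallace
rule Tm = 2(A+T) + 4(G+C); the reported annealing temperature is the
configured bench target closest to min(Tm_f, Tm_r) - 5 degC, a heuristic
stand-in for the bench optimisation the targets came from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .diversity import RegionDefinition
from .io import SequenceRecord, revcomp

__all__ = [
    "PrimerCandidate",
    "MarkerCandidate",
    "column_conservation",
    "wallace_tm",
    "design_marker",
    "marker_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimerCandidate:
    """A primer and the fully conserved alignment window it binds.

    ``sequence`` is the oligo to synthesise: for a reverse primer it is the
    reverse complement of the plus-strand consensus under its window.
    ``alignment_window`` is 1-based inclusive in alignment columns.
    """

    sequence: str
    alignment_window: tuple[int, int]
    tm_wallace: float
    gc_fraction: float
    conservation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction out of [0,1]")


@dataclass(frozen=True)
class MarkerCandidate:
    """A primer pair targeting one hotspot region."""

    name: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_size_range: tuple[int, int]
    annealing_temp: int
    covered_hotspot: str
    variable_columns_covered: int


def column_conservation(alignment: Sequence[SequenceRecord] | Sequence[str]) -> np.ndarray:
    """Per-column conservation fraction of an alignment.

    1.0 iff the column has no gap and all non-N residues are identical
    (with at least one non-N residue); an all-missing column scores 0.0;
    otherwise the modal non-N residue frequency over all rows.
    """
    rows = [r.sequence if isinstance(r, SequenceRecord) else r for r in alignment]
    if len(rows) < 2:
        raise ValueError("conservation needs at least two rows")
    mat = np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    n, L = mat.shape
    counts = np.stack([(mat == base).sum(axis=0) for base in (b"A", b"C", b"G", b"T")])
    modal = counts.max(axis=0)
    distinct = (counts > 0).sum(axis=0)
    gap_any = (mat == b"-").any(axis=0)
    out = np.where(~gap_any & (distinct == 1), 1.0, modal / n)
    out[distinct == 0] = 0.0
    return out


def wallace_tm(primer_sequence: str) -> int:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C), degC."""
    seq = primer_sequence.upper()
    if not seq:
        raise ValueError("empty primer")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguity codes not allowed in primers: {sorted(bad)}")
    at = seq.count("A") + seq.count("T")
    return 2 * at + 4 * (len(seq) - at)


def _consensus(mat: np.ndarray, c0: int, c1: int) -> str:
    """Plus-strand consensus of fully conserved columns [c0, c1) (0-based)."""
    out = []
    for c in range(c0, c1):
        col = mat[:, c]
        non_n = col[col != b"N"]
        out.append(non_n[0].decode())
    return "".join(out)


def design_marker(alignment: Sequence[SequenceRecord],
                  hotspot: RegionDefinition,
                  config: RunConfig | None = None,
                  max_candidates: int = 20,
                  max_windows_per_side: int = 60,
                  conservation: Optional[np.ndarray] = None) -> list[MarkerCandidate]:
    """Design primer pairs flanking one hotspot region.

    Candidates are ranked by (variable columns covered desc, maximal
    product length asc, |Tm_f - Tm_r| asc).  Returns an empty list when no
    fully conserved flanking windows exist; raises when the hotspot itself
    has no polymorphic column (nothing to discriminate).
    """
    config = config or RunConfig()
    rows = [r.sequence for r in alignment]
    mat = np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    n, L = mat.shape
    cons = conservation if conservation is not None else column_conservation(rows)
    conserved = cons >= 1.0

    h0, h1 = hotspot.alignment_columns[0] - 1, hotspot.alignment_columns[1]  # 0-based half-open
    variable = np.flatnonzero(~conserved[h0:h1]) + h0
    if variable.size == 0:
        raise ValueError(f"hotspot {hotspot.name}: nothing to discriminate "
                         "(no polymorphic column)")
    var_lo, var_hi = int(variable[0]), int(variable[-1])  # inclusive 0-based

    # ungapped prefix counts per accession for product-size arithmetic
    nongap = (mat != b"-").astype(np.int64)
    prefix = np.zeros((n, L + 1), dtype=np.int64)
    np.cumsum(nongap, axis=1, out=prefix[:, 1:])

    min_prod, max_prod = config.product_size_min, config.product_size_max
    ln_min, ln_max = config.primer_len_min, config.primer_len_max
    lo_bound = max(0, var_lo - max_prod)
    hi_bound = min(L, var_hi + 1 + max_prod)

    # runlen[c] = number of consecutive conserved columns ending at column c-1,
    # so a window [c-ln, c) is fully conserved iff runlen[c] >= ln
    pos = np.arange(1, L + 1)
    last_bad = np.maximum.accumulate(np.where(~conserved, pos, 0))
    runlen = np.zeros(L + 1, dtype=np.int64)
    runlen[1:] = pos - last_bad

    # reverse-primer windows, nearest the hotspot first
    downs: list[tuple[int, int]] = []
    for r0 in range(var_hi + 1, hi_bound - ln_min + 1):
        if len(downs) >= max_windows_per_side:
            break
        for ln in range(ln_min, ln_max + 1):
            if r0 + ln <= hi_bound and runlen[r0 + ln] >= ln:
                downs.append((r0, r0 + ln))
    if not downs:
        return []

    consensus_cache: dict[tuple[int, int], str] = {}

    def consensus(c0: int, c1: int) -> str:
        if (c0, c1) not in consensus_cache:
            consensus_cache[(c0, c1)] = _consensus(mat, c0, c1)
        return consensus_cache[(c0, c1)]

    candidates: list[MarkerCandidate] = []
    per_down_cap = 20
    for r0, r1 in downs:
        accepted = 0
        # forward-window end sweeps left from the hotspot until the product
        # bound cannot be met; products grow monotonically with the sweep
        for c1 in range(var_lo, lo_bound + ln_min - 1, -1):
            if accepted >= per_down_cap:
                break
            shortest = prefix[:, r1] - prefix[:, c1 - ln_min]
            if shortest.min() > max_prod:
                break  # every farther window overshoots for all accessions
            if runlen[c1] < ln_min:
                continue
            for ln in range(ln_min, min(ln_max, int(runlen[c1])) + 1):
                f0, f1 = c1 - ln, c1
                # product per accession: ungapped bases, forward 5' through
                # reverse-binding-site 3' inclusive
                prods = prefix[:, r1] - prefix[:, f0]
                pmin, pmax = int(prods.min()), int(prods.max())
                if pmax > max_prod:
                    break
                if pmin < min_prod:
                    continue
                fseq = consensus(f0, f1)
                rseq = revcomp(consensus(r0, r1))
                try:
                    tm_f, tm_r = wallace_tm(fseq), wallace_tm(rseq)
                except ValueError:
                    continue  # N in consensus window
                gc_f = 1 - (fseq.count("A") + fseq.count("T")) / len(fseq)
                gc_r = 1 - (rseq.count("A") + rseq.count("T")) / len(rseq)
                for label, gc in (("forward", gc_f), ("reverse", gc_r)):
                    if not config.gc_min <= gc <= config.gc_max:
                        logger.info("%s: %s primer GC %.2f outside soft bounds",
                                    hotspot.name, label, gc)
                covered = int(((variable >= f1) & (variable < r0)).sum())
                anneal = min(config.annealing_targets,
                             key=lambda t: (abs(t - (min(tm_f, tm_r) - 5)), t))
                candidates.append(MarkerCandidate(
                    name=hotspot.name,
                    forward=PrimerCandidate(fseq, (f0 + 1, f1), tm_f, gc_f, 1.0),
                    reverse=PrimerCandidate(rseq, (r0 + 1, r1), tm_r, gc_r, 1.0),
                    product_size_range=(pmin, pmax),
                    annealing_temp=anneal,
                    covered_hotspot=hotspot.name,
                    variable_columns_covered=covered,
                ))
                accepted += 1
    candidates.sort(key=lambda m: (
        -m.variable_columns_covered,
        m.product_size_range[1],
        abs(m.forward.tm_wallace - m.reverse.tm_wallace),
        m.forward.alignment_window,
        m.reverse.alignment_window,
    ))
    return candidates[:max_candidates]


def marker_table(markers: Sequence[MarkerCandidate]) -> pd.DataFrame:
    """TSV-ready table: No., Region, primers, product size range, annealing."""
    return pd.DataFrame({
        "No.": range(1, len(markers) + 1),
        "Region": [m.name for m in markers],
        "Forward primer (5'-3')": [m.forward.sequence for m in markers],
        "Reverse primer (5'-3')": [m.reverse.sequence for m in markers],
        "Product size range (bp)": [f"{m.product_size_range[0]}-{m.product_size_range[1]}"
                                    for m in markers],
        "Annealing temperature (C)": [m.annealing_temp for m in markers],
    })
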