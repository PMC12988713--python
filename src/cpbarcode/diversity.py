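"""Per-region nucleotide diversity and hotspot screening.

Regions (CDS, introns, intergenic spacers) annotated on a reference genome
are lifted into alignment coordinates gap-aware, and nucleotide diversity

    pi = 2 / (n (n - 1)) * sum_{i<j} d_ij / L_ij

(the average number of pairwise differences per compared site) is computed
per region.  Regions at or above a kind-specific threshold are flagged as
hotspots, the candidate barcode loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureRecord, SequenceRecord

__all__ = [
    "RegionDefinition",
    "RegionAlignment",
    "DiversityRecord",
    "map_annotation_to_alignment",
    "extract_region_alignment",
    "nucleotide_diversity",
    "screen_hotspots",
    "diversity_table",
]

logger = logging.getLogger(__name__)

MISSING = frozenset("N-")


@dataclass(frozen=True)
class RegionDefinition:
    """One analysable region on the reference, with its alignment columns.

    ``ref_interval`` is 1-based inclusive on the ungapped reference;
    ``alignment_columns`` is 1-based inclusive in alignment coordinates.
    Spacer (IGS) regions are named "geneA-geneB" with the upstream gene
    first.
    """

    name: str
    kind: str  # CDS | intron | IGS
    ref_interval: tuple[int, int]
    strand: str
    alignment_columns: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "intron", "IGS"):
            raise ValueError(f"region kind must be CDS/intron/IGS, got {self.kind!r}")


@dataclass(frozen=True)
class RegionAlignment:
    """Gap-aware sub-alignment of one region across accessions."""

    region: RegionDefinition
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class DiversityRecord:
    """Per-region pi with alignment length, sample size and hotspot flag."""

    region_name: str
    kind: str
    pi: float
    aligned_length: int
    n: int
    hotspot: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 0.75:
            raise ValueError(f"pi out of range for {self.region_name}: {self.pi}")


def _gap_map(ref_row: str) -> np.ndarray:
    """ungapped position p (0-based) -> alignment column (0-based)."""
    return np.flatnonzero(np.frombuffer(ref_row.encode(), dtype="S1") != b"-")


def map_annotation_to_alignment(features: Sequence[FeatureRecord],
                                alignment: Sequence[SequenceRecord],
                                ref_id: str,
                                *,
                                derive_igs: bool = True) -> list[RegionDefinition]:
    """Lift CDS/intron features into alignment columns; derive IGS spacers.

    Reference position p maps to the alignment column holding the p-th
    non-gap character of the reference row.  For each pair of genes adjacent
    on the reference an IGS region named "geneA-geneB" is derived from the
    gap between them; zero-length spacers (abutting genes) are skipped with
    a logged note.  Output is sorted by reference start and independent of
    feature input order.
    """
    ref_rows = [r for r in alignment if r.id == ref_id]
    if not ref_rows:
        raise ValueError(f"reference {ref_id!r} not present in alignment")
    gmap = _gap_map(ref_rows[0].sequence)
    ref_len = len(gmap)

    def lift(start1: int, end1: int) -> tuple[int, int]:
        if end1 > ref_len:
            raise ValueError(
                f"feature interval {start1}..{end1} beyond ungapped reference length {ref_len}"
            )
        return int(gmap[start1 - 1]) + 1, int(gmap[end1 - 1]) + 1

    feats = sorted((f for f in features if f.seq_id == ref_id),
                   key=lambda f: (f.start, f.end, f.name))
    regions: list[RegionDefinition] = []
    for f in feats:
        if f.feature_type in ("CDS", "intron", "IGS"):
            regions.append(RegionDefinition(
                name=f.name, kind=f.feature_type,
                ref_interval=(f.start, f.end), strand=f.strand,
                alignment_columns=lift(f.start, f.end),
            ))

    if derive_igs:
        genes = [f for f in feats if f.feature_type in ("gene", "tRNA", "rRNA")
                 and not f.wraps_origin]
        genes.sort(key=lambda f: (f.start, f.end, f.name))
        for a, b in zip(genes, genes[1:]):
            s, e = a.end + 1, b.start - 1
            if e < s:
                logger.info("spacer %s-%s has length 0; skipped", a.name, b.name)
                continue
            regions.append(RegionDefinition(
                name=f"{a.name}-{b.name}", kind="IGS",
                ref_interval=(s, e), strand="+",
                alignment_columns=lift(s, e),
            ))
    regions.sort(key=lambda r: (r.ref_interval, r.name))
    return regions


def extract_region_alignment(region: RegionDefinition,
                             alignment: Sequence[SequenceRecord]) -> RegionAlignment:
    """Slice the region's columns out of the whole-genome alignment."""
    c0, c1 = region.alignment_columns
    return RegionAlignment(
        region=region,
        ids=tuple(r.id for r in alignment),
        rows=tuple(r.sequence[c0 - 1 : c1] for r in alignment),
    )


def _encode(rows: Sequence[str]) -> np.ndarray:
    return np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])


def nucleotide_diversity(ra: RegionAlignment | Sequence[str],
                         gap_policy: str = "complete_deletion") -> float:
    """Nucleotide diversity pi of a region alignment.

    complete_deletion drops every column containing a gap or N before
    comparing, so every pair shares the same site count; pairwise_deletion
    excludes, per pair, only that pair's gap/N sites.  Returns 0.0 (with a
    warning) when no comparable site remains.
    """
    rows = ra.rows if isinstance(ra, RegionAlignment) else tuple(ra)
    n = len(rows)
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    if len(rows[0]) == 0:
        raise ValueError("empty alignment")
    mat = _encode(rows)
    valid = ~np.isin(mat, [b"-", b"N"])
    if gap_policy == "complete_deletion":
        keep = valid.all(axis=0)
        mat = mat[:, keep]
        if mat.shape[1] == 0:
            logger.warning("no gap-free column to compare; pi set to 0")
            return 0.0
        total = 0.0
        L = mat.shape[1]
        for i, j in combinations(range(n), 2):
            total += np.count_nonzero(mat[i] != mat[j]) / L
    elif gap_policy == "pairwise_deletion":
        total = 0.0
        any_site = False
        for i, j in combinations(range(n), 2):
            both = valid[i] & valid[j]
            L_ij = int(both.sum())
            if L_ij == 0:
                continue
            any_site = True
            total += np.count_nonzero(mat[i][both] != mat[j][both]) / L_ij
        if not any_site:
            logger.warning("no comparable site for any pair; pi set to 0")
            return 0.0
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    return 2.0 * total / (n * (n - 1))


def screen_hotspots(records: Sequence[DiversityRecord],
                    cds_threshold: float = 0.00015,
                    igs_threshold: float = 0.0001) -> list[DiversityRecord]:
    """Flag hotspot regions; thresholds are inclusive (pi >= threshold).

    CDS regions are screened against ``cds_threshold``; intergenic spacers
    and introns against ``igs_threshold``.  The returned list contains only
    hotspots, sorted by pi descending then name ascending.
    """
    out = []
    for r in records:
        thr = cds_threshold if r.kind == "CDS" else igs_threshold
        if r.pi >= thr:
            out.append(DiversityRecord(region_name=r.region_name, kind=r.kind,
                                       pi=r.pi, aligned_length=r.aligned_length,
                                       n=r.n, hotspot=True))
    out.sort(key=lambda r: (-r.pi, r.region_name))
    return out


def diversity_table(regions: Sequence[RegionDefinition],
                    alignment: Sequence[SequenceRecord],
                    gap_policy: str = "complete_deletion",
                    cds_threshold: float = 0.00015,
                    igs_threshold: float = 0.0001) -> tuple[list[DiversityRecord], pd.DataFrame]:
    """Compute pi for every region and tabulate (region, kind, Pi, length, n).

    Pi is reported to 5 decimal places in the table; the records carry full
    precision.
    """
    records = []
    hotspot_names: set[str] = set()
    for region in regions:
        ra = extract_region_alignment(region, alignment)
        pi = nucleotide_diversity(ra, gap_policy)
        records.append(DiversityRecord(
            region_name=region.name, kind=region.kind, pi=pi,
            aligned_length=ra.aligned_length, n=ra.n,
        ))
    hotspots = screen_hotspots(records, cds_threshold, igs_threshold)
    hotspot_names = {h.region_name for h in hotspots}
    records = [
        DiversityRecord(region_name=r.region_name, kind=r.kind, pi=r.pi,
                        aligned_length=r.aligned_length, n=r.n,
                        hotspot=r.region_name in hotspot_names)
        for r in records
    ]
    table = pd.DataFrame({
        "region": [r.region_name for r in records],
        "kind": [r.kind for r in records],
        "Pi": [round(r.pi, 5) for r in records],
        "alignment_length": [r.aligned_length for r in records],
        "n": [r.n for r in records],
        "hotspot": [r.hotspot for r in records],
    })
    return records, table
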