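"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (plain and aligned), 9-column GFF3 feature tables, and Newick trees
with branch lengths.  All coordinates exposed here are 1-based inclusive
(the GFF convention); internal code uses 0-based half-open slices and
converts at these boundaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "FeatureRecord",
    "FormatError",
    "CoordinateError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "write_newick",
    "revcomp",
    "write_manifest",
]

#: Residues accepted in sequences.  IUPAC ambiguity codes other than N are
#: rejected by default and only tolerated (treated as missing) when
#: ``allow_iupac`` is set.
STRICT_ALPHABET = frozenset("ACGTN-")
IUPAC_EXTRA = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV-", "TGCANYRSWMKVHDB-")


class FormatError(ValueError):
    """Malformed input file."""


class CoordinateError(ValueError):
    """Feature coordinates inconsistent with the sequence they annotate."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (gaps and N map to themselves)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence: an accession, an ancestor, or one alignment row."""

    id: str
    sequence: str
    description: str = ""
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def rotated(self, offset: int) -> "SequenceRecord":
        """Rotate a circular sequence so position ``offset`` (0-based) comes first."""
        s = self.sequence
        offset %= len(s)
        return replace(self, sequence=s[offset:] + s[:offset])


FEATURE_TYPES = ("gene", "CDS", "intron", "tRNA", "rRNA", "IGS")


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated interval, 1-based inclusive on its sequence.

    ``wraps_origin`` marks a feature crossing the circular origin, in which
    case ``end < start`` is legal and the feature covers
    ``[start, L] + [1, end]``.
    """

    seq_id: str
    feature_type: str
    start: int
    end: int
    strand: str
    name: str
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise CoordinateError(
                f"unknown feature type {self.feature_type!r} for {self.name!r}"
            )
        if self.strand not in "+-":
            raise CoordinateError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"{self.name!r}: coordinates are 1-based, got {self.start}..{self.end}")
        if self.end < self.start and not self.wraps_origin:
            raise CoordinateError(
                f"{self.name!r}: end {self.end} < start {self.start} without origin wrap"
            )

    def __len__(self) -> int:
        if self.wraps_origin:
            raise ValueError("length of a wrapping feature needs the sequence length")
        return self.end - self.start + 1

    def slice0(self) -> tuple[int, int]:
        """(start, end) as a 0-based half-open interval (non-wrapping only)."""
        return self.start - 1, self.end


def _check_alphabet(seq: str, rec_id: str, allow_iupac: bool) -> None:
    allowed = STRICT_ALPHABET | (IUPAC_EXTRA if allow_iupac else frozenset())
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise FormatError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos + 1}"
            )


def read_fasta(path: str | Path, *, allow_iupac: bool = False,
               circular: bool = False) -> list[SequenceRecord]:
    """Read FASTA records in file order.

    Lowercase is normalised to uppercase and RNA 'U' to 'T'.  Characters
    outside {A,C,G,T,N,-} raise :class:`FormatError` naming the offending
    position unless ``allow_iupac`` admits the remaining IUPAC codes.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise FormatError(f"duplicate record id {bio.id!r} in {path}")
        seen.add(bio.id)
        seq = str(bio.seq).upper().replace("U", "T")
        _check_alphabet(seq, bio.id, allow_iupac)
        records.append(SequenceRecord(id=bio.id, sequence=seq,
                                      description=bio.description[len(bio.id):].strip(),
                                      circular=circular))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def read_alignment(path: str | Path, *, allow_iupac: bool = False) -> list[SequenceRecord]:
    """Read an aligned FASTA; all rows must have equal length."""
    records = read_fasta(path, allow_iupac=allow_iupac)
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise FormatError(f"aligned records in {path} have unequal lengths {sorted(lengths)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> Path:
    path = Path(path)
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    return path


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[FeatureRecord]:
    """Read a 9-column GFF3 feature table, sorted by start position.

    Only the feature types the pipeline uses are kept.  ``Name=`` (or
    ``ID=``) supplies the feature name; a ``wraps_origin=true`` attribute
    marks circular-origin wrap.  Duplicate (seq_id, type, name) triples are
    an error.
    """
    path = Path(path)
    feats: list[FeatureRecord] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in FEATURE_TYPES:
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attr_map.get("Name") or attr_map.get("ID")
            if not name:
                raise FormatError(f"{path}:{lineno}: feature without Name/ID attribute")
            wraps = attr_map.get("wraps_origin", "").lower() == "true"
            key = (seq_id, ftype, name)
            if key in seen:
                raise FormatError(f"{path}:{lineno}: duplicate feature name {name!r} of type {ftype}")
            seen.add(key)
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            feats.append(FeatureRecord(seq_id=seq_id, feature_type=ftype,
                                       start=start, end=end, strand=strand,
                                       name=name, wraps_origin=wraps))
    feats.sort(key=lambda f: (f.seq_id, f.start, f.end, f.name))
    return feats


def write_gff3(features: Iterable[FeatureRecord], path: str | Path,
               source: str = "cpbarcode") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"Name={f.name}"
            if f.wraps_origin:
                attrs += ";wraps_origin=true"
            fh.write(
                f"{f.seq_id}\t{source}\t{f.feature_type}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Newick

def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> Path:
    """Write a tree as Newick with branch lengths.

    An empty tree (no leaves) is a structural error.
    """
    if tree.seed_node is None or all(
        leaf.taxon is None for leaf in tree.leaf_node_iter()
    ):
        raise ValueError("refusing to write an empty tree")
    path = Path(path)
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return path


# ---------------------------------------------------------------------------
# Run manifest

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, config: dict, seed: int | None,
                   inputs: Sequence[str | Path] = (),
                   outputs: Sequence[str | Path] = (),
                   warnings: Sequence[str] = ()) -> Path:
    """Write a machine-readable run manifest (JSON)."""
    manifest = {
        "config": config,
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
        "warnings": list(warnings),
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
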