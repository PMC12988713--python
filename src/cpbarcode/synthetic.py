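"""Synthetic plastome clades with known ground truth.

The generator emits an annotated quadripartite ancestor (LSC + IRb + SSC +
IRa, with IRb the exact reverse complement of IRa), evolves a clade of
accessions down a known tree under Jukes-Cantor with region-specific rate
multipliers, optionally forces groups of accessions to share one haplotype
(mimicking cultivars with a common maternal lineage), and plants SSRs and
exact long repeats.  Every stochastic choice flows from a single integer
seed, so outputs are byte-identical across runs.

Default magnitudes mirror a bread-wheat plastome: 80 014 bp LSC, 12 791 bp
SSC and 21 552 bp IRs (135 909 bp total) and a panel of 44 accessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .io import FeatureRecord, SequenceRecord, revcomp

__all__ = [
    "GeneSpec",
    "AncestorSpec",
    "CladeSpec",
    "AnnotatedPlastome",
    "TruthSet",
    "SimulatedClade",
    "build_ancestor",
    "simulate_clade",
    "default_gene_layout",
    "yule_tree",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class GeneSpec:
    name: str
    feature_type: str  # CDS | tRNA | rRNA
    length: int
    strand: str = "+"
    region: str = "LSC"  # LSC | SSC | IR


@dataclass(frozen=True)
class AncestorSpec:
    """Blueprint of the ancestral plastome."""

    lsc_len: int = 80_014
    ssc_len: int = 12_791
    ir_len: int = 21_552
    gene_layout: tuple[GeneSpec, ...] = ()
    gc_fraction: float = 0.38
    planted_ssrs: tuple[tuple[str, int, str], ...] = ()  # (motif, copies, region)
    planted_repeats: tuple[tuple[int, str, str], ...] = ()  # (length, orientation, region)
    seed: int = 0
    accession: str = "SYNREF"

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class CladeSpec:
    """Blueprint of the simulated accession panel."""

    n_taxa: int = 44
    tree_model: str = "yule"  # yule | fixed_newick
    newick: Optional[str] = None
    birth_rate: float = 1.0
    base_rate: float = 0.002  # expected root-to-tip substitutions/site
    region_rate_multipliers: dict[str, float] = field(default_factory=dict)
    identical_groups: tuple[tuple[str, ...], ...] = ()
    indel_rate: float = 0.0  # per IGS site per taxon
    hotspot_cutoff: float = 1.0  # multiplier above which a region is a truth hotspot
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("a clade needs at least two taxa")
        if any(m < 0 for m in self.region_rate_multipliers.values()):
            raise ValueError("rate multipliers must be non-negative")
        members = [t for g in self.identical_groups for t in g]
        if len(members) != len(set(members)):
            raise ValueError("identical_groups must be disjoint")

    def taxon_labels(self) -> list[str]:
        return [f"acc{i + 1:02d}" for i in range(self.n_taxa)]


@dataclass(frozen=True)
class AnnotatedPlastome:
    """Ancestor sequence, its feature table, and the planted junctions."""

    record: SequenceRecord
    features: tuple[FeatureRecord, ...]
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @property
    def region_intervals(self) -> dict[str, tuple[int, int]]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}


@dataclass(frozen=True)
class TruthSet:
    """Everything downstream stages should recover."""

    true_tree: str  # newick with branch lengths
    per_region_rates: dict[str, float]
    hotspot_names: tuple[str, ...]
    haplotype_classes: tuple[tuple[str, ...], ...]
    identical_groups: tuple[tuple[str, ...], ...]
    mutation_counts: dict[str, dict[str, int]]  # taxon -> region -> sites changed
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "true_tree": self.true_tree,
            "per_region_rates": self.per_region_rates,
            "hotspot_names": list(self.hotspot_names),
            "haplotype_classes": [list(g) for g in self.haplotype_classes],
            "identical_groups": [list(g) for g in self.identical_groups],
            "mutation_counts": self.mutation_counts,
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


@dataclass(frozen=True)
class SimulatedClade:
    alignment: tuple[SequenceRecord, ...]  # taxa rows, aligned
    reference_row: SequenceRecord  # ancestor lifted into alignment coordinates
    truth: TruthSet


# ---------------------------------------------------------------------------
# ancestor construction

# Representative plastid gene complement with plausible lengths (bp).  CDS
# lengths are multiples of 3; tRNAs ~75 bp, rRNAs at their usual sizes.
_LSC_GENES = [
    ("psbA", "CDS", 1062), ("matK", "CDS", 1536), ("rps16", "CDS", 261),
    ("psbK", "CDS", 186), ("psbI", "CDS", 111), ("trnS-GCU", "tRNA", 88),
    ("atpA", "CDS", 1524), ("atpF", "CDS", 555), ("atpH", "CDS", 246),
    ("atpI", "CDS", 744), ("rpoC2", "CDS", 4185), ("rpoC1", "CDS", 2052),
    ("rpoB", "CDS", 3213), ("petN", "CDS", 90), ("psbM", "CDS", 105),
    ("psbD", "CDS", 1062), ("psbC", "CDS", 1422), ("psaB", "CDS", 2205),
    ("psaA", "CDS", 2253), ("ycf3", "CDS", 507), ("rps4", "CDS", 606),
    ("trnT-UGU", "tRNA", 73), ("trnL-UAA", "tRNA", 85), ("trnF-GAA", "tRNA", 73),
    ("ndhJ", "CDS", 477), ("ndhK", "CDS", 678), ("ndhC", "CDS", 363),
    ("atpE", "CDS", 411), ("atpB", "CDS", 1497), ("rbcL", "CDS", 1434),
    ("psaI", "CDS", 111), ("ycf4", "CDS", 555), ("cemA", "CDS", 690),
    ("petA", "CDS", 963), ("psbJ", "CDS", 123), ("psbL", "CDS", 117),
    ("psbF", "CDS", 120), ("psbE", "CDS", 252), ("petL", "CDS", 96),
    ("petG", "CDS", 114), ("psaJ", "CDS", 135), ("rpl33", "CDS", 201),
    ("rps18", "CDS", 306), ("rpl20", "CDS", 354), ("clpP", "CDS", 591),
    ("psbB", "CDS", 1527), ("psbT", "CDS", 108), ("psbN", "CDS", 132),
    ("psbH", "CDS", 222), ("petB", "CDS", 648), ("petD", "CDS", 483),
    ("rpoA", "CDS", 1014), ("rps11", "CDS", 417), ("rpl36", "CDS", 114),
    ("rps8", "CDS", 405), ("rpl14", "CDS", 369), ("rpl16", "CDS", 408),
    ("rps3", "CDS", 657), ("rpl22", "CDS", 462), ("rps19", "CDS", 279),
]
_IR_GENES = [
    ("rpl2", "CDS", 1488), ("rpl23", "CDS", 282), ("ycf2", "CDS", 6837),
    ("ndhB", "CDS", 1533), ("rps7", "CDS", 468), ("rrn16", "rRNA", 1491),
    ("rrn23", "rRNA", 2810), ("rrn4.5", "rRNA", 103), ("rrn5", "rRNA", 121),
    ("trnN-GUU", "tRNA", 72),
]
_SSC_GENES = [
    ("ndhF", "CDS", 2220), ("rpl32", "CDS", 174), ("ccsA", "CDS", 966),
    ("ndhD", "CDS", 1503), ("psaC", "CDS", 246), ("ndhE", "CDS", 306),
    ("ndhG", "CDS", 531), ("ndhI", "CDS", 504), ("ndhA", "CDS", 1092),
    ("ndhH", "CDS", 1182), ("rps15", "CDS", 273),
]


def default_gene_layout() -> tuple[GeneSpec, ...]:
    """A representative plastid gene complement sized for the default ancestor."""
    out = [GeneSpec(n, t, l, "+", "LSC") for n, t, l in _LSC_GENES]
    out += [GeneSpec(n, t, l, "+", "IR") for n, t, l in _IR_GENES]
    out += [GeneSpec(n, t, l, "+", "SSC") for n, t, l in _SSC_GENES]
    return tuple(out)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random base codes 0..3 (A,C,G,T) with the given GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _place_genes(genes: Sequence[GeneSpec], region_len: int, offset: int,
                 region_name: str, seq_id: str) -> list[FeatureRecord]:
    """Lay genes left-to-right with evenly sized spacers; 1-based coords."""
    total = sum(g.length for g in genes)
    n_gaps = len(genes) + 1
    slack = region_len - total
    if slack < n_gaps:
        raise ValueError(
            f"gene layout overflows region {region_name}: {total} bp of genes "
            f"+ {n_gaps} spacers > {region_len} bp"
        )
    base_gap = slack // n_gaps
    extra = slack % n_gaps
    feats = []
    pos = offset  # 0-based cursor
    for k, g in enumerate(genes):
        pos += base_gap + (1 if k < extra else 0)
        start1, end1 = pos + 1, pos + g.length
        feats.append(FeatureRecord(seq_id=seq_id, feature_type="gene",
                                   start=start1, end=end1, strand=g.strand,
                                   name=g.name))
        if g.feature_type == "CDS":
            feats.append(FeatureRecord(seq_id=seq_id, feature_type="CDS",
                                       start=start1, end=end1, strand=g.strand,
                                       name=g.name))
        pos = end1
    return feats


def build_ancestor(spec: AncestorSpec) -> AnnotatedPlastome:
    """Emit the annotated quadripartite ancestor described by ``spec``.

    Layout is LSC + IRb + SSC + IRa with IRb the exact reverse complement
    of IRa.  Planted SSRs and repeats are written into spacer sequence and
    flank-blocked so they are maximal; IR/single-copy junctions are likewise
    blocked so the detector recovers the planted boundaries exactly.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.total_len
    lsc0, irb0 = 0, spec.lsc_len
    ssc0 = irb0 + spec.ir_len
    ira0 = ssc0 + spec.ssc_len

    codes = _random_seq(rng, L, spec.gc_fraction)

    by_region = {"LSC": [], "SSC": [], "IR": []}
    for g in spec.gene_layout:
        if g.region not in by_region:
            raise ValueError(f"gene {g.name}: unknown region {g.region!r}")
        by_region[g.region].append(g)

    feats: list[FeatureRecord] = []
    feats += _place_genes(by_region["LSC"], spec.lsc_len, lsc0, "LSC", spec.accession)
    feats += _place_genes(by_region["IR"], spec.ir_len, ira0, "IRa", spec.accession)
    feats += _place_genes(by_region["SSC"], spec.ssc_len, ssc0, "SSC", spec.accession)

    # spacer intervals available for planting = gaps between genes, per region
    def free_intervals(region_start: int, region_len: int) -> list[tuple[int, int]]:
        occupied = sorted(
            (f.start - 1, f.end) for f in feats
            if f.feature_type == "gene"
            and region_start < f.end <= region_start + region_len
        )
        out, cur = [], region_start
        for s, e in occupied:
            if s > cur:
                out.append((cur, s))
            cur = max(cur, e)
        if cur < region_start + region_len:
            out.append((cur, region_start + region_len))
        return out

    # planting targets IRa; the IRb copy is produced by mirroring afterwards
    region_bounds = {"LSC": (lsc0, spec.lsc_len), "SSC": (ssc0, spec.ssc_len),
                     "IR": (ira0, spec.ir_len), "IRa": (ira0, spec.ir_len)}

    def plant(payload: np.ndarray, region: str) -> int:
        """Write payload into a free spacer of the region; return 0-based start."""
        start, rlen = region_bounds[region]
        gaps = [iv for iv in free_intervals(start, rlen)
                if iv[1] - iv[0] >= len(payload) + 2]
        if not gaps:
            raise ValueError(f"no spacer large enough to plant {len(payload)} bp in {region}")
        lo, hi = gaps[int(rng.integers(len(gaps)))]
        pos = int(rng.integers(lo + 1, hi - len(payload)))
        codes[pos : pos + len(payload)] = payload
        return pos

    def block_flank(pos: int, want_not: int) -> None:
        """Force codes[pos] to differ from want_not (deterministic shift)."""
        if 0 <= pos < L and codes[pos] == want_not:
            codes[pos] = (codes[pos] + 1) % 4

    planted_spans: list[tuple[int, int]] = []
    for motif, copies, region in spec.planted_ssrs:
        unit = np.array([_CODE[c] for c in motif.upper()])
        payload = np.tile(unit, copies)
        pos = plant(payload, region)
        # stop the tandem run at both ends
        block_flank(pos - 1, int(payload[len(unit) - 1]))
        block_flank(pos + len(payload), int(payload[len(payload) - len(unit)]))
        planted_spans.append((pos, pos + len(payload)))

    for length, orientation, region in spec.planted_repeats:
        if orientation not in ("direct", "inverted"):
            raise ValueError(f"bad planted repeat orientation {orientation!r}")
        unit = _random_seq(rng, length, spec.gc_fraction)
        p1 = plant(unit, region)
        second = unit[::-1] ^ 3 if orientation == "inverted" else unit
        p2 = plant(second, region)
        # block extension on both sides so the planted pair is maximal
        if orientation == "direct":
            if p2 - 1 >= 0:
                block_flank(p1 - 1, int(codes[p2 - 1]))
            if p2 + length < L:
                block_flank(p1 + length, int(codes[p2 + length]))
        else:
            if p2 + length < L:
                block_flank(p1 - 1, int(codes[p2 + length]) ^ 3)
            if p2 - 1 >= 0:
                block_flank(p1 + length, int(codes[p2 - 1]) ^ 3)

    # IRb := reverse complement of IRa (complement = code XOR 3 under ACGT)
    ira_codes = codes[ira0 : ira0 + spec.ir_len]
    codes[irb0 : irb0 + spec.ir_len] = ira_codes[::-1] ^ 3

    # block IR extension across the four junctions:
    #  left of IRb (last LSC base) pairs with right of IRa (first LSC base, wrap)
    if codes[irb0 - 1] == codes[0] ^ 3:
        codes[irb0 - 1] = (codes[irb0 - 1] + 1) % 4
    #  right of IRb (first SSC base) pairs with left of IRa (last SSC base)
    if codes[ssc0] == codes[ira0 - 1] ^ 3:
        codes[ssc0] = (codes[ssc0] + 1) % 4

    # mirror IR gene annotations into IRb
    ir_feats = [f for f in feats if ira0 < f.end <= ira0 + spec.ir_len]
    for f in ir_feats:
        s0, e0 = f.start - 1, f.end  # 0-based half-open within genome
        rel_s, rel_e = s0 - ira0, e0 - ira0
        ns0 = irb0 + spec.ir_len - rel_e
        ne0 = irb0 + spec.ir_len - rel_s
        feats.append(FeatureRecord(
            seq_id=f.seq_id, feature_type=f.feature_type,
            start=ns0 + 1, end=ne0, strand="-" if f.strand == "+" else "+",
            name=f.name + "_IRb",
        ))

    # a region without any gene is annotated as one whole-region spacer
    region_ivs = {"LSC": (1, spec.lsc_len), "IRb": (irb0 + 1, irb0 + spec.ir_len),
                  "SSC": (ssc0 + 1, ssc0 + spec.ssc_len), "IRa": (ira0 + 1, L)}
    for rname, (s, e) in region_ivs.items():
        if not any(f.feature_type == "gene" and s <= f.start and f.end <= e
                   for f in feats):
            feats.append(FeatureRecord(seq_id=spec.accession, feature_type="IGS",
                                       start=s, end=e, strand="+",
                                       name=f"{rname}_spacer"))

    feats.sort(key=lambda f: (f.start, f.end, f.name))
    seq = _BASES[codes].tobytes().decode()
    record = SequenceRecord(id=spec.accession, sequence=seq, circular=True,
                            description="synthetic plastome ancestor")
    return AnnotatedPlastome(
        record=record, features=tuple(feats),
        lsc=(1, spec.lsc_len),
        irb=(irb0 + 1, irb0 + spec.ir_len),
        ssc=(ssc0 + 1, ssc0 + spec.ssc_len),
        ira=(ira0 + 1, L),
    )


# ---------------------------------------------------------------------------
# tree simulation

def yule_tree(n_taxa: int, labels: Sequence[str], birth_rate: float,
              rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth tree via exponential waiting times, depth-normalised to 1.

    All tips are contemporaneous; after normalisation the root-to-tip path
    length is exactly 1, so branch lengths multiply directly with the
    per-site base rate.
    """
    taxa = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth_time = 0.0
    root.split_time = 0.0
    t = 0.0
    tips = []
    for _ in range(2):  # the root splits at time zero
        child = root.new_child()
        child.birth_time = 0.0
        tips.append(child)
    while len(tips) < n_taxa:
        k = len(tips)
        t += rng.exponential(1.0 / (birth_rate * k))
        split = tips.pop(int(rng.integers(k)))
        split.split_time = t
        for _ in range(2):
            child = split.new_child()
            child.birth_time = t
            tips.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    order = rng.permutation(n_taxa)
    for i, tip in enumerate(tips):
        tip.taxon = taxa.get_taxon(labels[order[i]])
    # edge lengths from node times, normalised so root-to-tip depth is 1
    for node in tree.preorder_node_iter():
        end = getattr(node, "split_time", t_end)
        node.edge.length = (end - node.birth_time) / t_end
    tree.seed_node.edge.length = None
    return tree


def igs_intervals(ancestor: AnnotatedPlastome) -> dict[str, tuple[int, int]]:
    """Derived spacer intervals "geneA-geneB" (1-based inclusive).

    Mirrors the naming the annotation-mapping stage derives: one spacer per
    pair of genes adjacent on the genome, upstream gene first; abutting
    genes produce no spacer.
    """
    genes = sorted((f for f in ancestor.features if f.feature_type == "gene"),
                   key=lambda f: (f.start, f.end, f.name))
    out: dict[str, tuple[int, int]] = {}
    for a, b in zip(genes, genes[1:]):
        if b.start - 1 >= a.end + 1:
            out[f"{a.name}-{b.name}"] = (a.end + 1, b.start - 1)
    return out


def _named_region_masks(ancestor: AnnotatedPlastome) -> dict[str, np.ndarray]:
    """Site masks for structural regions, genes, and derived spacers."""
    L = len(ancestor.record)
    masks: dict[str, np.ndarray] = {}

    def add(name: str, s: int, e: int) -> None:
        m = masks.setdefault(name, np.zeros(L, dtype=bool))
        m[s - 1 : e] = True

    for name, (s, e) in ancestor.region_intervals.items():
        add(name, s, e)
    for f in ancestor.features:
        if f.feature_type == "gene":
            add(f.name, f.start, f.end)
    for name, (s, e) in igs_intervals(ancestor).items():
        add(name, s, e)
    return masks


def _region_site_map(ancestor: AnnotatedPlastome,
                     multipliers: dict[str, float]) -> np.ndarray:
    """Per-site rate multiplier array.

    Multiplier keys may be structural labels (LSC/SSC/IRa/IRb), gene names,
    or derived spacer names "geneA-geneB".
    """
    masks = _named_region_masks(ancestor)
    mult = np.ones(len(ancestor.record))
    for name, m in multipliers.items():
        if name not in masks:
            raise KeyError(f"rate multiplier names unknown region {name!r}")
        mult[masks[name]] = m
    return mult


def simulate_clade(ancestor: AnnotatedPlastome, clade: CladeSpec) -> SimulatedClade:
    """Evolve a clade of accessions down a known tree.

    Substitutions are applied site-wise under Jukes-Cantor: along a branch
    of normalised length t the probability a site changes is
    3/4 (1 - exp(-4/3 d)) with d = base_rate * multiplier * t, and a
    changed site takes one of the three other bases uniformly.  Members of
    an identical group all receive the first member's sequence.  With
    indel_rate > 0, short indels (geometric length, p=0.5) are placed in
    intergenic sequence and the output is re-gapped into one consistent
    alignment; otherwise the alignment is gapless.
    """
    rng = np.random.default_rng(clade.seed)
    labels = clade.taxon_labels()
    for g in clade.identical_groups:
        unknown = set(g) - set(labels)
        if unknown:
            raise ValueError(f"identical group names unknown taxa {sorted(unknown)}")

    if clade.tree_model == "yule":
        tree = yule_tree(clade.n_taxa, labels, clade.birth_rate, rng)
    elif clade.tree_model == "fixed_newick":
        if not clade.newick:
            raise ValueError("fixed_newick tree model needs a newick string")
        tree = dendropy.Tree.get(data=clade.newick, schema="newick",
                                 preserve_underscores=True)
        got = sorted(l.taxon.label for l in tree.leaf_node_iter())
        if got != sorted(labels):
            raise ValueError("newick leaf labels must be acc01..accNN")
    else:
        raise ValueError(f"unknown tree model {clade.tree_model!r}")

    mult = _region_site_map(ancestor, clade.region_rate_multipliers)
    L = len(ancestor.record)
    anc_codes = np.frombuffer(ancestor.record.sequence.encode(), dtype="S1")
    anc_codes = np.searchsorted(_BASES, anc_codes)

    tip_codes: dict[str, np.ndarray] = {}
    node_seq = {id(tree.seed_node): anc_codes}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = node_seq[id(node.parent_node)]
        t = node.edge.length or 0.0
        d = clade.base_rate * t * mult
        p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        hit = rng.random(L) < p_change
        child = parent.copy()
        n_hit = int(hit.sum())
        if n_hit:
            child[hit] = (child[hit] + rng.integers(1, 4, size=n_hit)) % 4
        node_seq[id(node)] = child
        if node.is_leaf():
            tip_codes[node.taxon.label] = child
    # free internal sequences
    del node_seq

    # enforce shared haplotypes
    for group in clade.identical_groups:
        first = tip_codes[group[0]]
        for member in group[1:]:
            tip_codes[member] = first.copy()

    # truth mutation counts: realised divergence from the ancestor per region
    count_masks = _named_region_masks(ancestor)
    mutation_counts = {
        lbl: {name: int((codes != anc_codes)[mask].sum())
              for name, mask in count_masks.items()}
        for lbl, codes in tip_codes.items()
    }

    rows = {lbl: _BASES[codes].tobytes().decode() for lbl, codes in tip_codes.items()}
    ref_row = ancestor.record.sequence

    if clade.indel_rate > 0:
        rows, ref_row = _apply_indels(rows, ref_row, ancestor, clade, rng)

    alignment = tuple(
        SequenceRecord(id=lbl, sequence=rows[lbl], circular=False)
        for lbl in labels
    )
    # realised haplotype classes over the full alignment
    by_hap: dict[str, list[str]] = {}
    for lbl in labels:
        by_hap.setdefault(rows[lbl], []).append(lbl)
    classes = tuple(tuple(v) for v in sorted(by_hap.values()))

    hotspots = tuple(sorted(
        name for name, m in clade.region_rate_multipliers.items()
        if m > clade.hotspot_cutoff
    ))
    truth = TruthSet(
        true_tree=tree.as_string(schema="newick").strip(),
        per_region_rates=dict(clade.region_rate_multipliers),
        hotspot_names=hotspots,
        haplotype_classes=classes,
        identical_groups=clade.identical_groups,
        mutation_counts=mutation_counts,
        seed=clade.seed,
    )
    reference = SequenceRecord(id=ancestor.record.id, sequence=ref_row,
                               circular=False,
                               description="reference row (ancestor)")
    return SimulatedClade(alignment=alignment, reference_row=reference, truth=truth)


def _igs_sites(ancestor: AnnotatedPlastome) -> np.ndarray:
    L = len(ancestor.record)
    in_gene = np.zeros(L, dtype=bool)
    for f in ancestor.features:
        if f.feature_type == "gene":
            in_gene[f.start - 1 : f.end] = True
    return np.flatnonzero(~in_gene)


def _apply_indels(rows: dict[str, str], ref_row: str,
                  ancestor: AnnotatedPlastome, clade: CladeSpec,
                  rng: np.random.Generator) -> tuple[dict[str, str], str]:
    """Place short indels in IGS sequence and re-gap all rows consistently.

    Deletions blank the taxon's bases; each insertion event opens a private
    gap-column block after its anchor position.  Event lengths are
    geometric (p=0.5).  Members of an identical group share the first
    member's events so forced haplotype identity survives indel placement.
    """
    labels = sorted(rows)
    rep_of = {lbl: lbl for lbl in labels}
    for group in clade.identical_groups:
        for member in group[1:]:
            rep_of[member] = group[0]
    igs = _igs_sites(ancestor)
    L = len(ref_row)
    deletions: dict[str, list[tuple[int, int]]] = {l: [] for l in labels}
    insertions: dict[int, list[tuple[tuple[str, ...], str]]] = {}
    for lbl in labels:
        if rep_of[lbl] != lbl:
            continue
        sharers = [l for l in labels if rep_of[l] == lbl]
        n_events = rng.poisson(clade.indel_rate * igs.size)
        for _ in range(n_events):
            pos = int(igs[int(rng.integers(igs.size))])
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                for l in sharers:
                    deletions[l].append((pos, min(pos + length, L)))
            else:
                ins = "".join("ACGT"[c] for c in _random_seq(rng, length, 0.38))
                insertions.setdefault(pos, []).append((tuple(sharers), ins))

    del_mask = {l: np.zeros(L, dtype=bool) for l in labels}
    for lbl, spans in deletions.items():
        for s, e in spans:
            del_mask[lbl][s:e] = True

    out: dict[str, list[str]] = {lbl: [] for lbl in labels}
    ref_out: list[str] = []
    for p in range(L):
        for lbl in labels:
            out[lbl].append("-" if del_mask[lbl][p] else rows[lbl][p])
        ref_out.append(ref_row[p])
        for ins_labels, ins in insertions.get(p, ()):  # private insertion block
            for lbl in labels:
                out[lbl].append(ins if lbl in ins_labels else "-" * len(ins))
            ref_out.append("-" * len(ins))
    return {lbl: "".join(v) for lbl, v in out.items()}, "".join(ref_out)
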