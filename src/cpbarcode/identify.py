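"""Marker-set evaluation: supermatrices, distance trees, identification rates.

A marker set identifies an accession when that accession can be told apart
from every other one.  Two operational definitions are provided:

* ``haplotype_unique`` — an accession is identified iff no other accession
  carries an identical sequence after the complete-deletion column mask
  (columns with any gap/N removed).  This yields the k-out-of-n semantics
  of a percentage that is always a multiple of 100/n.
* ``tree_singleton`` — an accession is identified iff its terminal branch
  has positive length and it does not sit in a zero-length cherry/polytomy
  with an accession whose masked sequence is identical.

Tree building uses neighbor-joining over p/JC/K2P distances as a
deterministic distance-based surrogate for likelihood tree search;
externally produced Newick trees can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .diversity import RegionAlignment, RegionDefinition

__all__ = [
    "ConcatenationSpec",
    "DistanceMatrix",
    "IdentificationReport",
    "concatenate_loci",
    "pairwise_distance",
    "nj_tree",
    "identification_rate",
    "compare_marker_sets",
    "round_rate",
]


@dataclass(frozen=True)
class ConcatenationSpec:
    """Fixed locus order and trimming policy for building a supermatrix."""

    locus_order: tuple[str, ...]
    trim_policy: str = "drop_any_gap_column"
    gap_fraction_max: float = 0.5

    def __post_init__(self) -> None:
        if self.trim_policy not in ("drop_any_gap_column", "drop_gap_fraction_above"):
            raise ValueError(f"unknown trim policy {self.trim_policy!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(self.d).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")


@dataclass(frozen=True)
class IdentificationReport:
    """Per-accession distinguishability and the identification-rate statistic."""

    method: str
    identified: dict[str, bool]
    rate: float  # percentage, rounded half-up to 2 decimals

    @property
    def n(self) -> int:
        return len(self.identified)

    @property
    def n_identified(self) -> int:
        return sum(self.identified.values())


def round_rate(k: int, n: int) -> float:
    """100*k/n as a percentage rounded half-up to 2 decimals."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(
        (Decimal(100) * Decimal(k) / Decimal(n)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def _trim(rows: Sequence[str], spec: ConcatenationSpec) -> list[str]:
    mat = np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    missing = np.isin(mat, [b"-", b"N"])
    if spec.trim_policy == "drop_any_gap_column":
        keep = ~missing.any(axis=0)
    else:
        keep = missing.mean(axis=0) <= spec.gap_fraction_max
    mat = mat[:, keep]
    return [row.tobytes().decode() for row in mat]


def concatenate_loci(alignments: Sequence[RegionAlignment],
                     spec: ConcatenationSpec) -> tuple[RegionAlignment, dict[str, tuple[int, int]]]:
    """Trim each locus, then concatenate column-wise in the fixed order.

    Every locus must carry the identical accession set; a mismatch is an
    error naming the symmetric difference.  Returns the supermatrix and a
    partition map of 1-based inclusive column spans per locus.
    """
    by_name = {a.region.name: a for a in alignments}
    unknown = [l for l in spec.locus_order if l not in by_name]
    if unknown:
        raise KeyError(f"unknown locus names in concatenation order: {unknown}")
    ordered = [by_name[l] for l in spec.locus_order]
    ref_ids = set(ordered[0].ids)
    for a in ordered[1:]:
        if set(a.ids) != ref_ids:
            diff = sorted(ref_ids ^ set(a.ids))
            raise ValueError(
                f"accession sets differ at locus {a.region.name}: {diff}"
            )
    id_order = ordered[0].ids
    partitions: dict[str, tuple[int, int]] = {}
    parts: list[list[str]] = [[] for _ in id_order]
    col = 0
    for a in ordered:
        # align rows to the common accession order
        idx = {acc: i for i, acc in enumerate(a.ids)}
        rows = [a.rows[idx[acc]] for acc in id_order]
        trimmed = _trim(rows, spec)
        width = len(trimmed[0]) if trimmed else 0
        partitions[a.region.name] = (col + 1, col + width)
        col += width
        for i, r in enumerate(trimmed):
            parts[i].append(r)
    region = RegionDefinition(
        name="+".join(spec.locus_order), kind="IGS",
        ref_interval=(1, max(col, 1)), strand="+",
        alignment_columns=(1, max(col, 1)),
    )
    super_rows = tuple("".join(p) for p in parts)
    if col == 0:
        raise ValueError("supermatrix is empty after trimming")
    return RegionAlignment(region=region, ids=id_order, rows=super_rows), partitions


def pairwise_distance(alignment: RegionAlignment | Sequence[str],
                      model: str = "p-distance",
                      labels: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Pairwise distances under p-distance, JC or K2P.

    Gaps and N are excluded pairwise.  JC applies -3/4 ln(1 - 4p/3) and
    raises on saturation (p >= 0.75); K2P uses the transition/transversion
    closed form and raises when its logs are undefined.
    """
    if isinstance(alignment, RegionAlignment):
        rows, ids = alignment.rows, alignment.ids
    else:
        rows = tuple(alignment)
        ids = tuple(labels) if labels else tuple(f"t{i}" for i in range(len(rows)))
    n = len(rows)
    if n < 2:
        raise ValueError("need at least two sequences")
    mat = np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    valid = ~np.isin(mat, [b"-", b"N"])
    purine = np.isin(mat, [b"A", b"G"])
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        L = int(both.sum())
        if L == 0:
            raise ValueError(f"no comparable site between {ids[i]} and {ids[j]}")
        diff = mat[i][both] != mat[j][both]
        p = np.count_nonzero(diff) / L
        if model == "p-distance":
            dist = p
        elif model == "JC":
            if p >= 0.75:
                raise ValueError(f"JC saturation between {ids[i]} and {ids[j]} (p={p:.3f})")
            dist = -0.75 * np.log(1 - 4 * p / 3)
        elif model == "K2P":
            transitions = diff & (purine[i][both] == purine[j][both])
            P = np.count_nonzero(transitions) / L
            Q = p - P
            a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
            if a1 <= 0 or a2 <= 0:
                raise ValueError(f"K2P saturation between {ids[i]} and {ids[j]}")
            dist = -0.5 * np.log(a1) - 0.25 * np.log(a2)
        else:
            raise ValueError(f"unknown model {model!r}")
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=ids, d=d, model=model)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (Saitou-Nei Q criterion), deterministic.

    Ties in the Q matrix are broken by the lexicographic order of the two
    cluster labels.  Negative branch-length estimates are clamped to zero.
    Consistent on additive matrices: recovers the generating tree exactly.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor-joining needs at least three taxa")
    taxa = dendropy.TaxonNamespace(list(dm.labels))
    nodes: list[dendropy.Node] = []
    for lbl in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lbl))
        nodes.append(node)
    labels = list(dm.labels)
    D = dm.d.astype(float).copy()
    active = list(range(n0))
    next_rows: dict[int, np.ndarray] = {}

    def dist(i: int, j: int) -> float:
        return D[i, j]

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # new row of distances
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            D[k, x] = D[x, k] = 0.5 * (D[i, x] + D[j, x] - dij)
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    i, j = active
    root = dendropy.Node()
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    half = max(D[i, j], 0.0)
    nodes[i].edge.length = half / 2
    nodes[j].edge.length = half - half / 2
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _masked_haplotypes(alignment: RegionAlignment) -> dict[str, str]:
    """Sequences after the complete-deletion column mask."""
    mat = np.array([np.frombuffer(r.encode(), dtype="S1") for r in alignment.rows])
    keep = ~np.isin(mat, [b"-", b"N"]).any(axis=0)
    mat = mat[:, keep]
    return {acc: mat[i].tobytes().decode() for i, acc in enumerate(alignment.ids)}


def identification_rate(alignment: RegionAlignment,
                        method: str = "haplotype_unique",
                        tree: Optional[dendropy.Tree] = None) -> IdentificationReport:
    """Score how many accessions the alignment distinguishes from all others.

    rate = 100 * identified / n, rounded half-up to two decimals.
    """
    haplos = _masked_haplotypes(alignment)
    if method == "haplotype_unique":
        counts: dict[str, int] = {}
        for h in haplos.values():
            counts[h] = counts.get(h, 0) + 1
        identified = {acc: counts[h] == 1 for acc, h in haplos.items()}
    elif method == "tree_singleton":
        if tree is None:
            raise ValueError("tree_singleton needs a tree")
        leaf_by_label: dict[str, dendropy.Node] = {}
        for leaf in tree.leaf_node_iter():
            leaf_by_label[leaf.taxon.label] = leaf
        if set(leaf_by_label) != set(alignment.ids):
            diff = sorted(set(leaf_by_label) ^ set(alignment.ids))
            raise ValueError(f"tree/alignment label mismatch: {diff}")
        identified = {}
        for acc in alignment.ids:
            leaf = leaf_by_label[acc]
            blen = leaf.edge.length or 0.0
            if blen <= 0:
                identified[acc] = False
                continue
            # reject if a same-haplotype accession shares a zero-length
            # cherry/polytomy with this leaf
            sibs = [s for s in leaf.parent_node.child_nodes() if s is not leaf]
            clash = any(
                s.is_leaf() and (s.edge.length or 0.0) == 0.0
                and haplos[s.taxon.label] == haplos[acc]
                for s in sibs
            )
            identified[acc] = not clash
    else:
        raise ValueError(f"unknown identification method {method!r}")
    k = sum(identified.values())
    return IdentificationReport(method=method, identified=identified,
                                rate=round_rate(k, len(identified)))


def compare_marker_sets(sets: dict[str, Sequence[str]],
                        alignments: Sequence[RegionAlignment],
                        methods: Sequence[str] = ("haplotype_unique",),
                        trim_policy: str = "drop_any_gap_column",
                        distance_model: str = "p-distance") -> pd.DataFrame:
    """Evaluate named marker sets: supermatrix length and identification rate.

    Single-locus sets are concatenations of one locus, so their rows agree
    with direct per-locus reports.  Output is sorted by the first method's
    rate, descending.
    """
    rows = []
    for set_name, loci in sets.items():
        spec = ConcatenationSpec(locus_order=tuple(loci), trim_policy=trim_policy)
        supermatrix, _parts = concatenate_loci(alignments, spec)
        row: dict = {
            "set": set_name,
            "loci": "+".join(loci),
            "n_loci": len(loci),
            "supermatrix_length": supermatrix.aligned_length,
        }
        for method in methods:
            tree = None
            if method == "tree_singleton":
                dmat = pairwise_distance(supermatrix, distance_model)
                tree = nj_tree(dmat)
            rep = identification_rate(supermatrix, method, tree)
            row[f"rate_{method}"] = rep.rate
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(f"rate_{methods[0]}", ascending=False,
                          kind="mergesort").reset_index(drop=True)
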