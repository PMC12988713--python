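"""End-to-end orchestration: structure -> repeats -> diversity -> markers ->
identification, with a run manifest.

``run_discovery`` drives the all-synthetic demonstration (or any
user-supplied genome + alignment + annotation bundle); ``run_benchmark``
runs the same stages over a directory of user-provided accession FASTAs.
Nothing here performs network access; accessions must already be on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import diversity as div
from . import identify as ident
from . import markers as mk
from . import repeats as rp
from . import structure as st
from .config import RunConfig
from .io import (FeatureRecord, SequenceRecord, read_alignment, read_fasta,
                 read_gff3, write_fasta, write_manifest)
from .synthetic import (AncestorSpec, CladeSpec, SimulatedClade, build_ancestor,
                        default_gene_layout, simulate_clade)

logger = logging.getLogger(__name__)

__all__ = ["ReportBundle", "run_discovery", "run_benchmark", "simulate_bundle"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    out_dir: Path
    structure_table: Optional[pd.DataFrame] = None
    ssr_summary: Optional[pd.DataFrame] = None
    long_repeat_summary: Optional[pd.DataFrame] = None
    diversity_table: Optional[pd.DataFrame] = None
    hotspots: list = field(default_factory=list)
    marker_table: Optional[pd.DataFrame] = None
    identification_table: Optional[pd.DataFrame] = None
    warnings: list = field(default_factory=list)


def simulate_bundle(out_dir: str | Path, *, ancestor_spec: AncestorSpec | None = None,
                    clade_spec: CladeSpec | None = None) -> tuple:
    """Generate and write the synthetic demonstration inputs.

    Returns (ancestor, clade) where clade is the SimulatedClade.  Files
    written: ancestor FASTA + GFF3, aligned FASTA of the panel (reference
    row included), truth tree Newick, TruthSet JSON.
    """
    from .io import write_gff3, write_newick
    import dendropy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aspec = ancestor_spec or AncestorSpec(gene_layout=default_gene_layout())
    cspec = clade_spec or CladeSpec(seed=aspec.seed)
    ancestor = build_ancestor(aspec)
    clade = simulate_clade(ancestor, cspec)
    write_fasta([ancestor.record], out_dir / "ancestor.fasta")
    write_gff3(ancestor.features, out_dir / "ancestor.gff3")
    write_fasta([clade.reference_row, *clade.alignment], out_dir / "alignment.fasta")
    tree = dendropy.Tree.get(data=clade.truth.true_tree, schema="newick",
                             preserve_underscores=True)
    write_newick(tree, out_dir / "true_tree.nwk")
    clade.truth.to_json(out_dir / "truth.json")
    return ancestor, clade


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:  # noqa: BLE001 - stage boundary
                raise StageError(name, e) from e
        return wrapped
    return deco


def run_discovery(config: RunConfig,
                  genomes: Sequence[SequenceRecord],
                  alignment: Sequence[SequenceRecord],
                  features: Sequence[FeatureRecord],
                  ref_id: str,
                  out_dir: str | Path,
                  marker_sets: Optional[dict[str, Sequence[str]]] = None,
                  methods: Sequence[str] = ("haplotype_unique", "tree_singleton"),
                  ) -> ReportBundle:
    """Run every stage over in-memory inputs and write the report bundle.

    ``genomes`` are the circular accession sequences for structure/repeat
    profiling; ``alignment`` the whole-genome multiple alignment including
    the reference row named ``ref_id``; ``features`` the reference
    annotation.  ``marker_sets`` (name -> locus list) defaults to the
    hotspot panel plus each hotspot singly.
    """
    if not features:
        raise ValueError("annotation is required before any computation")
    if not any(r.id == ref_id for r in alignment):
        raise ValueError(f"reference {ref_id!r} missing from alignment")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    outputs: list[Path] = []

    # --- structure ------------------------------------------------------
    @_stage("structure")
    def stage_structure():
        parts = [st.detect_quadripartite(g) for g in genomes]
        table = (st.compare_structures(parts) if len(parts) >= 2
                 else pd.DataFrame([parts[0].to_dict()]))
        return parts, table

    partitions, bundle.structure_table = stage_structure()
    p = out_dir / "structure.tsv"
    bundle.structure_table.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    # --- repeats --------------------------------------------------------
    @_stage("repeats")
    def stage_repeats():
        ssr_tables, lr_tables = [], []
        for g, part in zip(genomes, partitions):
            if not part.quadripartite:
                bundle.warnings.append(f"{g.id}: no quadripartite structure; repeats unsummarised")
                continue
            canonical = g.rotated(part.rotation_offset)
            ssrs = rp.find_ssrs(canonical, config.ssr_thresholds)
            lrs = rp.find_long_repeats(canonical, config.long_repeat_min_len, part)
            s_tab, l_tab = rp.summarize_repeats(ssrs, lrs, part)
            s_tab, l_tab = s_tab.assign(accession=g.id), l_tab.assign(accession=g.id)
            ssr_tables.append(s_tab)
            lr_tables.append(l_tab)
        return (pd.concat(ssr_tables) if ssr_tables else None,
                pd.concat(lr_tables) if lr_tables else None)

    bundle.ssr_summary, bundle.long_repeat_summary = stage_repeats()
    for name, tab in (("ssr_summary.tsv", bundle.ssr_summary),
                      ("long_repeats.tsv", bundle.long_repeat_summary)):
        if tab is not None:
            p = out_dir / name
            tab.to_csv(p, sep="\t")
            outputs.append(p)

    # --- diversity ------------------------------------------------------
    @_stage("diversity")
    def stage_diversity():
        regions = div.map_annotation_to_alignment(features, alignment, ref_id)
        taxa_rows = [r for r in alignment if r.id != ref_id]
        records, table = div.diversity_table(
            regions, taxa_rows, config.gap_policy,
            config.cds_pi_threshold, config.igs_pi_threshold)
        hotspots = [r for r in records if r.hotspot]
        return regions, taxa_rows, records, table, hotspots

    regions, taxa_rows, div_records, bundle.diversity_table, bundle.hotspots = stage_diversity()
    p = out_dir / "diversity.tsv"
    bundle.diversity_table.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    # --- marker design --------------------------------------------------
    @_stage("markers")
    def stage_markers():
        by_name = {r.name: r for r in regions}
        cons = mk.column_conservation(taxa_rows)
        best = []
        for h in bundle.hotspots:
            try:
                cands = mk.design_marker(taxa_rows, by_name[h.region_name],
                                         config, conservation=cons)
            except ValueError as e:
                bundle.warnings.append(str(e))
                continue
            if cands:
                best.append(cands[0])
        return mk.marker_table(best), best

    bundle.marker_table, _best_markers = stage_markers()
    p = out_dir / "markers.tsv"
    bundle.marker_table.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    # --- identification -------------------------------------------------
    @_stage("identification")
    def stage_identification():
        region_alignments = [div.extract_region_alignment(r, taxa_rows)
                             for r in regions]
        sets = marker_sets
        if sets is None:
            hotspot_names = [h.region_name for h in bundle.hotspots]
            sets = {h: [h] for h in hotspot_names}
            if len(hotspot_names) >= 2:
                sets["combined"] = hotspot_names
        return ident.compare_marker_sets(sets, region_alignments, methods)

    bundle.identification_table = stage_identification()
    p = out_dir / "identification.tsv"
    bundle.identification_table.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    write_manifest(out_dir / "manifest.json", config=config.to_dict(),
                   seed=config.seed, outputs=outputs,
                   warnings=bundle.warnings)
    return bundle


def run_benchmark(config: RunConfig, accession_dir: str | Path,
                  alignment_path: str | Path,
                  annotation_path: str | Path,
                  ref_id: str,
                  out_dir: str | Path,
                  marker_sets: Optional[dict[str, Sequence[str]]] = None,
                  ) -> ReportBundle:
    """Same stages over user-supplied accession FASTAs (no downloads).

    ``accession_dir`` holds one FASTA per accession; the whole-genome
    alignment and the reference GFF3 are precomputed inputs.
    """
    accession_dir = Path(accession_dir)
    fastas = sorted(accession_dir.glob("*.fasta")) + sorted(accession_dir.glob("*.fa"))
    if not fastas:
        raise ValueError(f"no FASTA files found in {accession_dir}")
    genomes = [rec for f in fastas for rec in read_fasta(f, circular=True)]
    if len(genomes) < 2:
        raise ValueError("benchmark needs at least two accession genomes")
    alignment = read_alignment(alignment_path)
    features = read_gff3(annotation_path)
    return run_discovery(config, genomes, alignment, features, ref_id,
                         out_dir, marker_sets)
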