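#!/usr/bin/env python
"""Design conserved-flank primer pairs for the top diversity hotspots.

For each of the highest-pi regions, enumerates fully conserved 18-25 nt
windows flanking the variable span and pairs them so every accession's
product is 250-1500 bp; reports Wallace-rule Tm-derived annealing targets
(54/58 degC).  Writes results/markers.tsv.
"""

import argparse
from pathlib import Path

from cpbarcode.config import RunConfig
from cpbarcode.diversity import diversity_table, map_annotation_to_alignment
from cpbarcode.io import read_alignment, read_gff3
from cpbarcode.markers import column_conservation, design_marker, marker_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/synthetic_panel"))
    ap.add_argument("--top", type=int, default=17,
                    help="number of top-pi hotspot regions to target")
    ap.add_argument("--out", type=Path, default=Path("results/markers.tsv"))
    args = ap.parse_args()
    config = RunConfig()

    alignment = read_alignment(args.panel / "alignment.fasta")
    features = read_gff3(args.panel / "ancestor.gff3")
    ref_id = features[0].seq_id
    taxa = [r for r in alignment if r.id != ref_id]
    regions = map_annotation_to_alignment(features, alignment, ref_id)
    records, table = diversity_table(regions, taxa, config.gap_policy,
                                     config.cds_pi_threshold,
                                     config.igs_pi_threshold)
    by_name = {r.name: r for r in regions}
    targets = [r.region_name for r in
               sorted((r for r in records if r.hotspot),
                      key=lambda r: (-r.pi, r.region_name))][:args.top]
    cons = column_conservation(taxa)
    chosen = []
    for name in targets:
        cands = design_marker(taxa, by_name[name], config, conservation=cons)
        if cands:
            chosen.append(cands[0])
        else:
            print(f"  {name}: no conserved-flank pair within product bounds")
    tab = marker_table(chosen)
    print(tab.to_string(index=False))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    tab.to_csv(args.out, sep="\t", index=False)
    print(f"{len(chosen)}/{len(targets)} hotspots yielded a marker; wrote {args.out}")


if __name__ == "__main__":
    main()
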