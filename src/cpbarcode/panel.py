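"""The published wheat chloroplast marker panels, as data.

These are the printed inputs of the study this pipeline reimplements: the
17-locus specific barcode panel (regions, primers, per-locus alignment
lengths, per-locus tree identification rates) and the traditional
three-locus plant barcode combination (matK + rbcL + trnL-UAA-trnF-GAA).
They are used for arithmetic cross-checks (panel totals, rate formatting)
and as the default locus order for real-data benchmark runs; reproducing
the per-locus numbers themselves requires the user-downloaded accession
set.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PanelLocus", "SPECIFIC_PANEL", "TRADITIONAL_PANEL",
           "PANEL_ACCESSIONS_N"]


@dataclass(frozen=True)
class PanelLocus:
    name: str
    kind: str  # CDS | IGS | intron
    forward_primer: str
    reverse_primer: str
    product_range: tuple[int, int]
    annealing_c: int
    pi: float
    alignment_length: int
    tree_identification_pct: float


#: Number of accessions in the published comparative panel.
PANEL_ACCESSIONS_N = 44

SPECIFIC_PANEL: tuple[PanelLocus, ...] = (
    PanelLocus("ccsA", "CDS", "CGAGTGGCGGCATTCTTGAAA", "CCTATCCGTTGACAGGGTAGA",
               (1200, 1300), 54, 0.00086, 1268, 11.36),
    PanelLocus("atpI", "CDS", "GTTGCTGAGTTGAGAAAGAGATG", "GTCAATTCAATGATGACCCTCCAT",
               (800, 850), 58, 0.00057, 825, 9.09),
    PanelLocus("matK", "CDS", "CCCTTTCCTGTTTCTTAATTTCG", "CTGACCATATTGCACTATGTATCATC",
               (1600, 1650), 54, 0.00131, 1647, 11.36),
    PanelLocus("ndhH", "CDS", "GTTTCTACCTCTACCCTATCTA", "CAAATACCACAAAGAGCCAGCTAT",
               (900, 950), 54, 0.00049, 936, 9.09),
    PanelLocus("psbA", "CDS", "GGAACTTCAACAGCAGCTAAGTC", "GCTTGGGAGTCCTTGCAATTTGA",
               (1000, 1100), 58, 0.00017, 1087, 6.82),
    PanelLocus("rpoA", "CDS", "GATGCTTCTCTAGAGTGTCCCA", "TAGTCTATTATGGTTCGAGAGG",
               (900, 1000), 54, 0.00038, 991, 6.82),
    PanelLocus("matK-rps16", "IGS", "CTCGGTTTATCGAATGATGATAC", "GCGTTGTTTATCTACATCTATCCC",
               (1400, 1500), 58, 0.00148, 1503, 20.46),
    PanelLocus("psbI-trnS-GCU", "IGS", "CTAATGACCCAGGACGGAATC", "CTTTCGCTTTGGAACGTGGA",
               (250, 300), 58, 0.00539, 256, 22.73),
    PanelLocus("atpF-intron", "intron", "TTTGGAAAGGGAGTGTGTGCGA", "CCGCTTCTAGTTCGACTTTCTG",
               (900, 1000), 58, 0.00012, 973, 11.36),
    PanelLocus("psaA-ycf3", "IGS", "GGTTCCGGCGAACGAATAATC", "CACAGAACTGGTTGAAGATTACGA",
               (700, 800), 58, 0.00092, 759, 20.46),
    PanelLocus("trnT-UGU-trnL-UAA", "IGS", "GGCTTACATAACGGAAATAGTG", "CGTCTACCGATTTCGCCATATC",
               (600, 700), 58, 0.00121, 640, 9.09),
    PanelLocus("trnL-UAA-trnF-GAA", "IGS", "GGGAAATGGGGATATGGCGAA", "CTCTGCCAGGAACCAGATTTGAA",
               (1100, 1200), 58, 0.00135, 1110, 11.36),
    PanelLocus("petA-psbJ", "IGS", "CGCATCCGTTATTTTGGCACA", "CATATTCTGGATTGGGTTCATC",
               (900, 950), 58, 0.00137, 933, 20.46),
    PanelLocus("psbE-petL", "IGS", "CGTGCTTCCAGACATGCTG", "GGCGTATCTTGTTCAAGCCAATA",
               (1200, 1300), 58, 0.00095, 1271, 15.91),
    PanelLocus("rpl16-rps3", "IGS", "GGTTCTCTTTCTTAGTTCCATCTC", "CTTCGGATTCTGTCCATTGATAG",
               (1100, 1200), 58, 0.00107, 1177, 18.18),
    PanelLocus("rpl32-trnL-UAG", "IGS", "CGGTAATGAGCATCCAAAACCAAA", "TTTCAAGAATGCCGCCACTCG",
               (800, 900), 58, 0.00586, 865, 13.64),
    PanelLocus("ccsA-ndhD", "IGS", "GAAGGGTACGAATTCCGCACT", "CCTATCCGTTGACAGGGTAGA",
               (300, 350), 54, 0.00423, 344, 9.09),
)

#: Traditional three-locus plant barcode combination with its per-locus
#: trimmed lengths and tree identification rates.
TRADITIONAL_PANEL: tuple[tuple[str, int, float], ...] = (
    ("matK", 1539, 11.36),
    ("rbcL", 1434, 4.55),
    ("trnL-UAA-trnF-GAA", 386, 11.36),
)
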