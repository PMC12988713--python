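"""Run configuration and threshold presets.

The defaults encode the study conditions used throughout the pipeline:
MISA-style SSR copy-number thresholds of 25/15/2/2/2/2 for mono- through
hexanucleotide motifs, exact long repeats of at least 30 bp, hotspot
screening thresholds of 0.00015 (CDS) and 0.0001 (intergenic/intron), PCR
product sizes of 250-1500 bp and bench annealing temperatures of 54/58 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "PRESETS"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide tunables.

    ssr_thresholds are minimum copy numbers indexed by motif period 1..6.
    gap_policy selects how alignment gaps/N enter the diversity statistic:
    ``complete_deletion`` drops every column containing a gap or N before
    any pairwise comparison; ``pairwise_deletion`` excludes sites per pair.
    """

    cds_pi_threshold: float = 0.00015
    igs_pi_threshold: float = 0.0001
    ssr_thresholds: tuple[int, int, int, int, int, int] = (25, 15, 2, 2, 2, 2)
    long_repeat_min_len: int = 30
    product_size_min: int = 250
    product_size_max: int = 1500
    annealing_targets: tuple[int, ...] = (54, 58)
    primer_len_min: int = 18
    primer_len_max: int = 25
    gc_min: float = 0.35
    gc_max: float = 0.65
    gap_policy: str = "complete_deletion"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ssr_thresholds) != 6:
            raise ValueError("ssr_thresholds must give one copy threshold per period 1..6")
        if any(t < 1 for t in self.ssr_thresholds):
            raise ValueError("ssr thresholds must be positive")
        if min(self.cds_pi_threshold, self.igs_pi_threshold) < 0:
            raise ValueError("pi thresholds must be non-negative")
        if not self.product_size_min < self.product_size_max:
            raise ValueError("product_size_min must be below product_size_max")
        if self.gap_policy not in ("complete_deletion", "pairwise_deletion"):
            raise ValueError(f"unknown gap_policy {self.gap_policy!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ssr_thresholds"] = list(self.ssr_thresholds)
        d["annealing_targets"] = list(self.annealing_targets)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("ssr_thresholds", "annealing_targets"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


#: Named presets.  ``default`` carries the thresholds stated with the marker
#: screen (CDS pi >= 0.00015, intergenic pi >= 0.0001); ``strict`` the
#: alternative pair quoted alongside the final marker panel (0.00017 /
#: 0.00012).  ``misa-defaults`` swaps in the stock MISA copy thresholds for
#: tri- through hexanucleotides.
PRESETS: dict[str, RunConfig] = {
    "default": RunConfig(),
    "strict": RunConfig(cds_pi_threshold=0.00017, igs_pi_threshold=0.00012),
    "misa-defaults": RunConfig(ssr_thresholds=(10, 6, 5, 5, 5, 5)),
}
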