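"""Shared fixtures: small synthetic plastomes and clades, built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cpbarcode.synthetic import (AncestorSpec, CladeSpec, GeneSpec,
                                 build_ancestor, simulate_clade)


def small_gene_layout(n_lsc: int = 10, n_ssc: int = 3, n_ir: int = 2,
                      gene_len: int = 300) -> tuple[GeneSpec, ...]:
    out = tuple(GeneSpec(f"g{i:02d}", "CDS", gene_len, "+", "LSC") for i in range(n_lsc))
    out += tuple(GeneSpec(f"s{i}", "CDS", gene_len, "+", "SSC") for i in range(n_ssc))
    out += tuple(GeneSpec(f"r{i}", "CDS", gene_len, "+", "IR") for i in range(n_ir))
    return out


def small_ancestor_spec(seed: int = 11, **kw) -> AncestorSpec:
    defaults = dict(lsc_len=8000, ssc_len=2000, ir_len=1800,
                    gene_layout=small_gene_layout(), seed=seed)
    defaults.update(kw)
    return AncestorSpec(**defaults)


@pytest.fixture(scope="session")
def small_ancestor():
    return build_ancestor(small_ancestor_spec())


@pytest.fixture(scope="session")
def small_clade(small_ancestor):
    """20 accessions, two forced-identical groups, one 10x hotspot spacer."""
    spec = CladeSpec(
        n_taxa=20, seed=23, base_rate=0.002,
        region_rate_multipliers={"g02-g03": 10.0},
        identical_groups=(("acc01", "acc02", "acc03"), ("acc10", "acc11")),
    )
    return simulate_clade(small_ancestor, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
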