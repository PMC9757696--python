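"""Shared fixtures: tiny reference sets and simulated datasets, built in-memory."""

from __future__ import annotations

import pytest

from targetasm.io_formats import write_fasta
from targetasm.simulate import SimConfig, generate_gene_family


@pytest.fixture
def ref_dir(tmp_path):
    """A directory of per-gene FASTA files for a 5-gene simulated family."""
    cfg = SimConfig(n_genes=5, gene_length_range=(300, 700), seed=11)
    sim = generate_gene_family(cfg)
    d = tmp_path / "ref"
    d.mkdir()
    for gid, homologs in sim.references.genes.items():
        write_fasta(homologs, d / f"{gid}.fasta")
    return d


@pytest.fixture
def five_gene_sim():
    """Truths + diverged references for a 5-gene family (fixed seed)."""
    cfg = SimConfig(n_genes=5, gene_length_range=(300, 700), seed=11)
    return cfg, generate_gene_family(cfg)
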