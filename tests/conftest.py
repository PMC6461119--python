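"""Shared fixtures: a small simulated polyploid dataset used across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from islandcap.core import SeqRecord
from islandcap.design import DesignSpaceContig, ProvenanceBlock
from islandcap.io import read_gff3
from islandcap.simulate import SimulationConfig, gen_genome_and_annotation
from islandcap.targets import extract_gene_targets, extract_promoter_targets


def random_seq(seed: int, n: int, alphabet: str = "ACGT") -> str:
    rng = np.random.default_rng(seed)
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def make_contig(cid: str, seq: str) -> DesignSpaceContig:
    return DesignSpaceContig(
        id=cid,
        sequence=SeqRecord(cid, seq),
        provenance=[ProvenanceBlock(0, len(seq), "test", cid, 0, len(seq))],
    )


@dataclass
class ToyData:
    cfg: SimulationConfig
    genome: list
    genes: list
    gene_targets: list
    promoter_targets: list
    truth: object
    gff_path: str


@pytest.fixture(scope="session")
def toy(tmp_path_factory) -> ToyData:
    """8 gene families x 3 subgenomes at 97% homoeolog identity."""
    cfg = SimulationConfig(seed=42, n_gene_families=8)
    genome, gff, truth = gen_genome_and_annotation(cfg)
    gff_path = tmp_path_factory.mktemp("toy") / "annotation.gff3"
    gff_path.write_text(gff)
    genes = read_gff3(gff_path, genome)
    return ToyData(
        cfg=cfg,
        genome=genome,
        genes=genes,
        gene_targets=extract_gene_targets(genome, genes),
        promoter_targets=extract_promoter_targets(genome, genes),
        truth=truth,
        gff_path=str(gff_path),
    )
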