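"""Genotype a simulated capture: plant known variants, call them from the
pileup, apply the homozygous-SNP post-filters, and build the cross-sample
comparable-position matrix for two samples."""

import dataclasses
import tempfile

from islandcap import (
    DepthTrack,
    SimulationConfig,
    TilingParams,
    build_design_space,
    comparable_positions,
    extract_gene_targets,
    extract_promoter_targets,
    filter_snps,
    gen_genome_and_annotation,
    naive_pileup_caller,
    plant_variants,
    simulate_capture,
    tile_islands,
)
from islandcap.io import read_gff3

cfg = SimulationConfig(seed=7, n_gene_families=10)
genome, gff, truth = gen_genome_and_annotation(cfg)
with tempfile.NamedTemporaryFile("w", suffix=".gff3") as fh:
    fh.write(gff)
    fh.flush()
    genes = read_gff3(fh.name, genome)
gt = extract_gene_targets(genome, genes)
pt = extract_promoter_targets(genome, genes)
gs, ps, _ = build_design_space({"sim": gt + pt})
space = gs + ps
probes = tile_islands(space, TilingParams())
tids = {t.target_id: t.interval for t in gt + pt}

samples = {}
for i, sid in enumerate(("sample1", "sample2")):
    reads, track, pileup = simulate_capture(
        probes, space, tids, genome, cfg, seed=100 + i, sample_id=sid
    )
    pileup, vtruth = plant_variants(pileup, cfg, seed=200 + i)
    calls = naive_pileup_caller(pileup)
    kept = filter_snps(calls)
    n_hom = sum(v["zygosity"] == "hom" for v in vtruth)
    print(f"{sid}: {len(vtruth)} variants planted ({n_hom} homozygous), "
          f"{len(calls)} raw calls, {len(kept)} survive the post-filters "
          "(qual >= 50, depth >= 5, allele fraction > 80%, no 3-in-10bp cluster)")
    samples[sid] = (kept, track)

matrix, n_comparable = comparable_positions(samples, depth_min=5)
print(f"\n{n_comparable} positions are comparable across both samples "
      "(each has a filtered SNP or >= 5x reference coverage)")
print(f"{len(matrix)} of them carry a SNP in at least one sample; first three:")
for (contig, pos), alleles in list(sorted(matrix.items()))[:3]:
    print(f"  {contig}:{pos} {alleles}")
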