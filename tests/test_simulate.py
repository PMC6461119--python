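"""Synthetic-data generators: determinism, planted-structure recovery, and
capture-simulation calibration."""

import numpy as np
import pytest

from islandcap.core import GenomeInterval
from islandcap.design import build_design_space, self_collapse
from islandcap.evaluate import on_target_fraction
from islandcap.io import read_gff3
from islandcap.similarity import find_local_hits
from islandcap.simulate import (
    SimulationConfig,
    design_space_footprint,
    gen_genome_and_annotation,
    gen_organelles,
    gen_premirnas,
    map_local_span,
    plant_insertions,
    plant_variants,
    simulate_capture,
)
from islandcap.targets import (
    classify_exonic_mirnas,
    extract_gene_targets,
    extract_promoter_targets,
)
from islandcap.tiling import TilingParams, tile_islands


def _targets(cfg, tmp_path, with_organelles=False):
    genome, gff, truth = gen_genome_and_annotation(cfg)
    orgs = gen_organelles(cfg) if with_organelles else []
    if with_organelles:
        genome = plant_insertions(genome, orgs, cfg, truth)
    p = tmp_path / "a.gff3"
    p.write_text(gff)
    genes = read_gff3(p, genome)
    return genome, genes, truth, orgs


class TestGenomeGeneration:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=5, n_gene_families=4)
        a = gen_genome_and_annotation(cfg)
        b = gen_genome_and_annotation(cfg)
        assert [r.residues for r in a[0]] == [r.residues for r in b[0]]
        assert a[1] == b[1]
        assert a[2].to_json() == b[2].to_json()

    def test_annotation_consistent_with_truth(self, tmp_path):
        cfg = SimulationConfig(seed=6, n_gene_families=4)
        genome, genes, truth, _ = _targets(cfg, tmp_path)
        by_id = {g.gene_id: g for g in genes}
        for gid, t in truth.genes.items():
            g = by_id[gid]
            assert (g.interval.start, g.interval.end) == (t["start"], t["end"])
            assert g.strand == t["strand"]
            assert g.confidence == t["confidence"]

    def test_identity_one_families_collapse_to_single_representative(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_gene_families=5, homoeolog_identity=1.0,
                               lowcomp_tract_rate=0.0)
        genome, genes, truth, _ = _targets(cfg, tmp_path)
        targets = extract_gene_targets(genome, genes)
        hc_families = {
            t["family"] for t in truth.genes.values() if t["confidence"] == "high"
        }
        contigs, _ = self_collapse(targets, source_reference="r")
        assert len(contigs) == len(hc_families)

    def test_identity_below_threshold_never_collapses(self, tmp_path):
        cfg = SimulationConfig(seed=8, n_gene_families=5, homoeolog_identity=0.90,
                               lowcomp_tract_rate=0.0)
        genome, genes, truth, _ = _targets(cfg, tmp_path)
        targets = extract_gene_targets(genome, genes)
        contigs, rep = self_collapse(targets, source_reference="r")
        assert len(contigs) == len(targets)
        assert rep.n_clusters == 0

    def test_planted_lowcomp_tracts_recorded(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_gene_families=6, lowcomp_tract_rate=1.0)
        genome, _, truth, _ = _targets(cfg, tmp_path)
        assert len(truth.lowcomp_tracts) >= cfg.n_gene_families
        by_id = {r.id: r for r in genome}
        for t in truth.lowcomp_tracts:
            seq = by_id[t["contig"]].residues[t["start"] : t["end"]]
            assert set(seq.upper()) <= {"A", "T"}


class TestOrganelleInsertions:
    def test_zero_rate_is_noop(self, tmp_path):
        cfg = SimulationConfig(seed=10, n_gene_families=3,
                               organelle_insertion_rate=0.0)
        genome, gff, truth = gen_genome_and_annotation(cfg)
        orgs = gen_organelles(cfg)
        modified = plant_insertions(genome, orgs, cfg, truth)
        assert [r.residues for r in modified] == [r.residues for r in genome]
        assert truth.organelle_insertions == []

    def test_planted_span_excised_close_to_truth(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_gene_families=4,
                               organelle_insertion_rate=1.0,
                               lowcomp_tract_rate=0.0)
        genome, genes, truth, orgs = _targets(cfg, tmp_path, with_organelles=True)
        assert truth.organelle_insertions
        targets = extract_gene_targets(genome, genes)
        from islandcap.design import filter_organellar, self_collapse

        contigs, _ = self_collapse(targets, source_reference="r")
        filtered = filter_organellar(contigs, orgs)
        # every surviving piece is shorter than its source: the insert is gone
        ilen = cfg.organelle_insertion_len
        total_before = sum(len(c) for c in contigs)
        total_after = sum(len(c) for c in filtered)
        n_ins_in_kept = sum(
            1
            for ins in truth.organelle_insertions
            if any(b.target_id == ins["gene"] for c in contigs for b in c.provenance)
        )
        removed = total_before - total_after
        assert abs(removed - n_ins_in_kept * ilen) <= 5 * n_ins_in_kept


class TestPremirnas:
    def test_classification_matches_truth(self, tmp_path):
        cfg = SimulationConfig(seed=12, n_gene_families=6, lowcomp_tract_rate=0.0,
                               low_confidence_fraction=0.0)
        genome, genes, truth, _ = _targets(cfg, tmp_path)
        pres, offsets = gen_premirnas(cfg, genome, truth)
        placements, targets = classify_exonic_mirnas(pres, genome, genes, offsets)
        expected = {t["id"]: t["expected"] for t in truth.premirnas}
        got = {p.mirna_id: p.classification for p in placements}
        assert got == expected
        assert all(t.kind == "mirna" for t in targets)


@pytest.fixture(scope="module")
def captured(tmp_path_factory):
    tmp_path = tmp_path_factory.mktemp("cap")
    cfg = SimulationConfig(seed=13, n_gene_families=8)
    genome, gff, truth = gen_genome_and_annotation(cfg)
    p = tmp_path / "a.gff3"
    p.write_text(gff)
    genes = read_gff3(p, genome)
    gt = extract_gene_targets(genome, genes)
    pt = extract_promoter_targets(genome, genes)
    gs, ps, _ = build_design_space({"sim": gt + pt})
    space = gs + ps
    pset = tile_islands(space, TilingParams())
    tids = {t.target_id: t.interval for t in gt + pt}
    reads, track, pileup = simulate_capture(pset, space, tids, genome, cfg)
    return cfg, genome, space, pset, tids, reads, track, pileup


class TestSimulateCapture:
    def test_on_target_fraction_within_tolerance(self, captured):
        cfg, genome, space, pset, tids, reads, track, pileup = captured
        fp = design_space_footprint(space, tids)
        ivs = [GenomeInterval(c, s, e) for c, sp in fp.items() for s, e in sp]
        got = on_target_fraction(reads, ivs)
        assert abs(got - 100 * cfg.capture.on_target_fraction) <= 2.0

    def test_full_on_target_when_fraction_one(self, captured, tmp_path):
        cfg, genome, space, pset, tids, *_ = captured
        import dataclasses

        cfg1 = dataclasses.replace(
            cfg, capture=dataclasses.replace(cfg.capture, on_target_fraction=1.0)
        )
        reads, _, _ = simulate_capture(pset, space, tids, genome, cfg1)
        fp = design_space_footprint(space, tids)
        ivs = [GenomeInterval(c, s, e) for c, sp in fp.items() for s, e in sp]
        assert on_target_fraction(reads, ivs) == 100.0

    def test_mean_depth_within_ten_percent(self, captured):
        cfg, genome, space, pset, tids, reads, track, pileup = captured
        fl = cfg.capture.fragment_len
        from islandcap.core import merge_spans

        wins = {}
        by = {c.id: c for c in space}
        for p in pset.probes:
            c = by[p.contig]
            pad = (fl - p.length) // 2
            s = max(0, p.start - pad)
            e = min(len(c), p.start - pad + fl)
            for giv in map_local_span(c, s, e, tids):
                wins.setdefault(giv.contig, []).append((giv.start, giv.end))
        chunks = [
            track[ct][s:e]
            for ct, sp in wins.items()
            for s, e in merge_spans(sp)
        ]
        mean = np.concatenate(chunks).mean()
        assert abs(mean - cfg.capture.mean_depth) <= 0.1 * cfg.capture.mean_depth

    def test_duplicate_rate_close_to_configured(self, captured):
        cfg, *_, reads, _, _ = captured
        frac = sum(r.is_duplicate for r in reads) / len(reads)
        assert abs(frac - cfg.capture.duplicate_rate) <= 0.01

    def test_depth_track_consistent_with_reads(self, captured):
        cfg, genome, space, pset, tids, reads, track, pileup = captured
        from islandcap.evaluate import DepthTrack

        rebuilt = DepthTrack.from_reads(reads, {r.id: len(r) for r in genome})
        for r in genome:
            assert np.array_equal(rebuilt[r.id], track[r.id])


class TestPlantVariants:
    def test_expected_dispositions(self, captured):
        cfg, *_, pileup = captured
        import dataclasses

        cfg2 = dataclasses.replace(
            cfg,
            variants=dataclasses.replace(cfg.variants, rate=0.01,
                                         cluster_fraction=0.15),
        )
        pile2, truth = plant_variants(pileup, cfg2)
        assert truth
        from islandcap.evaluate import filter_snps, naive_pileup_caller

        kept = {(c.contig, c.pos0) for c in filter_snps(naive_pileup_caller(pile2))}
        for v in truth:
            key = (v["contig"], v["pos0"])
            if v["expected"] == "kept":
                assert key in kept
            else:
                assert key not in kept

    def test_hom_above_af_threshold_het_below(self, captured):
        cfg, *_, pileup = captured
        pile2, truth = plant_variants(pileup, cfg)
        for v in truth:
            af = v["alt_count"] / v["depth"]
            if v["zygosity"] == "hom":
                assert af > 0.8
            else:
                assert af <= 0.8

    def test_deterministic(self, captured):
        cfg, *_, pileup = captured
        a = plant_variants(pileup, cfg)
        b = plant_variants(pileup, cfg)
        assert a[0].equals(b[0]) and a[1] == b[1]
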