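"""Raw capture-target derivation: gene bodies, 2 kbp putative promoters,
well-covered 5'UTRs (the promoter-2 extension) and exonic mature miRNAs.

A gene target spans the 5'UTR start to the 3'UTR end, introns included.
A putative promoter is the (up to) 2,000 bp immediately upstream of the
transcription start site, clipped at contig edges and dropped only when
clipping leaves nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import GeneModel, GenomeInterval, SeqRecord, TargetRegion, slice_genome
from .evaluate import DepthTrack
from .similarity import SimilarityThresholds, find_local_hits

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MirnaPlacement:
    mirna_id: str
    pre_interval: GenomeInterval | None
    mature_interval: GenomeInterval | None
    classification: str  # exonic | non_exonic | unplaced

    def __post_init__(self) -> None:
        if self.classification not in ("exonic", "non_exonic", "unplaced"):
            raise ValueError(f"bad classification {self.classification!r}")
        if (
            self.pre_interval is not None
            and self.mature_interval is not None
            and not self.pre_interval.contains(self.mature_interval)
        ):
            raise ValueError("mature interval must lie within the pre-miRNA interval")


def extract_gene_targets(
    genome: dict[str, SeqRecord] | list[SeqRecord],
    genes: list[GeneModel],
    confidence_filter: str = "high_only",
) -> list[TargetRegion]:
    """One target per passing gene spanning its full 5'UTR-to-3'UTR interval.

    '-'-strand targets carry the reverse-complemented sequence. Low-confidence
    genes are excluded under ``high_only``.
    """
    if confidence_filter not in ("high_only", "all"):
        raise ValueError("confidence_filter must be high_only or all")
    if not isinstance(genome, dict):
        genome = {r.id: r for r in genome}
    out = []
    for g in genes:
        if confidence_filter == "high_only" and g.confidence != "high":
            continue
        if len(g.interval) == 0:  # defensive; GenomeInterval forbids this
            log.warning("gene %s has zero-length span; skipped", g.gene_id)
            continue
        seq = slice_genome(genome, g.interval)
        out.append(
            TargetRegion(
                target_id=g.gene_id,
                kind="gene",
                interval=g.interval,
                sequence=SeqRecord(id=g.gene_id, residues=seq),
                source_reference=g.interval.contig,
                linked_gene=g.gene_id,
            )
        )
    return out


def extract_promoter_targets(
    genome: dict[str, SeqRecord] | list[SeqRecord],
    genes: list[GeneModel],
    promoter_len: int = 2000,
    confidence_filter: str = "high_only",
) -> list[TargetRegion]:
    """The (up to) ``promoter_len`` bp upstream of each gene's TSS.

    '+' gene with TSS t -> [max(0, t - promoter_len), t); '-' gene with TSS t
    (the interval end) -> [t, min(L, t + promoter_len)), reverse-complemented.
    Promoters are clipped at contig edges and dropped (with a warning) only
    when clipping leaves them empty.
    """
    if not isinstance(genome, dict):
        genome = {r.id: r for r in genome}
    out = []
    for g in genes:
        if confidence_filter == "high_only" and g.confidence != "high":
            continue
        clen = len(genome[g.interval.contig])
        if g.strand == "-":
            start, end = g.interval.end, min(clen, g.interval.end + promoter_len)
        else:
            start, end = max(0, g.interval.start - promoter_len), g.interval.start
        if end <= start:
            log.warning(
                "gene %s: promoter clipped to empty at contig edge; dropped",
                g.gene_id,
            )
            continue
        iv = GenomeInterval(g.interval.contig, start, end, g.strand)
        tid = f"{g.gene_id}_promoter"
        out.append(
            TargetRegion(
                target_id=tid,
                kind="promoter",
                interval=iv,
                sequence=SeqRecord(id=tid, residues=slice_genome(genome, iv)),
                source_reference=g.interval.contig,
                linked_gene=g.gene_id,
            )
        )
    return out


def extract_utr5_targets(
    genes: list[GeneModel],
    depth: DepthTrack,
    genome: dict[str, SeqRecord] | list[SeqRecord],
    cov_min: int = 10,
    breadth_min: float = 0.99,
) -> list[TargetRegion]:
    """5'UTRs with depth > cov_min across more than ``breadth_min`` of their
    bases (both strict), the rule used to extend the promoter set with up to
    two probes per 5'UTR. Genes lacking an annotated 5'UTR are skipped."""
    if not isinstance(genome, dict):
        genome = {r.id: r for r in genome}
    out = []
    for g in genes:
        if not g.utr5:
            continue
        total = passing = 0
        for iv in g.utr5:
            d = depth.get(iv.contig, len(genome[iv.contig]))[iv.start : iv.end]
            total += len(iv)
            passing += int((d > cov_min).sum())
        if total == 0 or passing / total <= breadth_min:
            continue
        for i, iv in enumerate(g.utr5):
            tid = f"{g.gene_id}_utr5" if len(g.utr5) == 1 else f"{g.gene_id}_utr5.{i+1}"
            out.append(
                TargetRegion(
                    target_id=tid,
                    kind="utr5",
                    interval=iv,
                    sequence=SeqRecord(id=tid, residues=slice_genome(genome, iv)),
                    source_reference=iv.contig,
                    linked_gene=g.gene_id,
                )
            )
    return out


def classify_exonic_mirnas(
    pre_mirnas: list[SeqRecord],
    genome: dict[str, SeqRecord] | list[SeqRecord],
    genes: list[GeneModel],
    mature_offsets: dict[str, tuple[int, int]],
    thr: SimilarityThresholds | None = None,
) -> tuple[list[MirnaPlacement], list[TargetRegion]]:
    """Place pre-miRNAs on the genome and classify their mature miRNAs.

    A miRNA is exonic iff the pre-miRNA lies wholly inside one exon, or the
    whole mature miRNA lies inside one exon (boundary equality counts as
    inside). Placement takes the best-scoring full-length hit; ties are broken
    by contig name then coordinate. Unplaceable pre-miRNAs are classified
    ``unplaced`` and excluded from the emitted targets.

    Returns the placements plus the exonic mature sequences as TargetRegions
    of kind ``mirna`` for inclusion in the promoter design space.
    """
    if not isinstance(genome, dict):
        genome = {r.id: r for r in genome}
    genome_recs = list(genome.values())
    exons = [ex for g in genes for ex in g.exons]
    placements: list[MirnaPlacement] = []
    targets: list[TargetRegion] = []
    for pre in pre_mirnas:
        if pre.id not in mature_offsets:
            raise ValueError(f"no mature offsets for pre-miRNA {pre.id!r}")
        m0, m1 = mature_offsets[pre.id]
        if not 0 <= m0 < m1 <= len(pre):
            raise ValueError(f"mature offsets of {pre.id!r} outside the pre-miRNA")
        thr_full = thr or SimilarityThresholds(length_min=min(100, len(pre)))
        hits = [
            h
            for h in find_local_hits([pre], genome_recs, thr_full)
            if h.aln_len == len(pre)
        ]
        if not hits:
            log.warning("pre-miRNA %s has no full-length genomic hit; excluded", pre.id)
            placements.append(MirnaPlacement(pre.id, None, None, "unplaced"))
            continue
        best = min(hits, key=lambda h: (-h.score, h.subject_id, h.s_start))
        strand = "+" if best.strand == "+" else "-"
        pre_iv = GenomeInterval(best.subject_id, best.s_start, best.s_end, strand)
        if strand == "+":
            mat_iv = GenomeInterval(
                best.subject_id, best.s_start + m0, best.s_start + m1, strand
            )
        else:
            mat_iv = GenomeInterval(
                best.subject_id, best.s_end - m1, best.s_end - m0, strand
            )
        exonic = any(ex.contains(pre_iv) for ex in exons) or any(
            ex.contains(mat_iv) for ex in exons
        )
        cls = "exonic" if exonic else "non_exonic"
        placements.append(MirnaPlacement(pre.id, pre_iv, mat_iv, cls))
        if exonic:
            tid = f"{pre.id}_mature"
            targets.append(
                TargetRegion(
                    target_id=tid,
                    kind="mirna",
                    interval=mat_iv,
                    sequence=SeqRecord(id=tid, residues=slice_genome(genome, mat_iv)),
                    source_reference=mat_iv.contig,
                    linked_gene=None,
                )
            )
    return placements, targets
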