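"""Readers and writers for every standard format the pipeline touches.

Internal coordinates are 0-based half-open everywhere. Exactly two
conversion boundaries exist: GFF3 (1-based inclusive) on input and VCF
(1-based) on input/output. bedGraph and BED are already half-open.
Case in FASTA is data (the low-complexity mask channel) and is preserved
verbatim on both read and write.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import GeneModel, GenomeInterval, SeqRecord
from .evaluate import DepthTrack, ReadPlacement, SnpCall

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA; case preserved, N allowed, duplicate ids rejected."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, residues=str(rec.seq)))
    return records


def write_fasta(records: list[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _confidence_from_attrs(
    attrs: dict, key: str
) -> str:
    vals = attrs.get(key)
    if not vals:
        return "high"
    v = str(vals[0]).lower()
    if v in ("high", "hc", "high_confidence"):
        return "high"
    if v in ("low", "lc", "low_confidence"):
        return "low"
    log.warning("unrecognised confidence value %r; treating as high", vals[0])
    return "high"


def read_gff3(
    path: str | Path,
    genome: list[SeqRecord] | dict[str, SeqRecord],
    confidence_key: str = "confidence",
) -> list[GeneModel]:
    """Parse gene models from GFF3 (1-based inclusive -> 0-based half-open).

    Expects gene/mRNA/exon/five_prime_UTR/three_prime_UTR features. The
    confidence label is read case-insensitively from ``confidence_key`` on the
    gene feature (missing -> high). A gene outside its contig is an error;
    child features extending past the contig or parent are clamped with a
    warning.
    """
    if not isinstance(genome, dict):
        genome = {r.id: r for r in genome}
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise ValueError(f"gene {gene.id} on unknown contig {gene.seqid!r}")
        clen = len(genome[gene.seqid])
        gstart, gend = gene.start - 1, gene.end  # GFF [a,b] -> [a-1, b)
        if gstart < 0 or gend > clen:
            raise ValueError(
                f"gene {gene.id} at {gene.seqid}:{gene.start}-{gene.end} outside "
                f"contig bounds (length {clen})"
            )
        interval = GenomeInterval(gene.seqid, gstart, gend, gene.strand or ".")

        def _children(ftype: str) -> list[GenomeInterval]:
            out = []
            spans = set()
            for f in db.children(gene, featuretype=ftype):
                s, e = f.start - 1, f.end
                if s < gstart or e > gend or e > clen:
                    log.warning(
                        "%s of gene %s at %s:%d-%d clamped to parent/contig",
                        ftype,
                        gene.id,
                        gene.seqid,
                        f.start,
                        f.end,
                    )
                    s, e = max(s, gstart), min(e, gend, clen)
                if e > s and (s, e) not in spans:
                    spans.add((s, e))
                    out.append(GenomeInterval(gene.seqid, s, e, gene.strand or "."))
            return sorted(out, key=lambda iv: iv.start)

        models.append(
            GeneModel(
                gene_id=gene.id,
                interval=interval,
                exons=_children("exon"),
                utr5=_children("five_prime_UTR"),
                utr3=_children("three_prime_UTR"),
                confidence=_confidence_from_attrs(dict(gene.attributes), confidence_key),
            )
        )
    return models


# ---------------------------------------------------------------------------
# BED


def write_bed(
    intervals: list[GenomeInterval],
    path: str | Path,
    names: list[str] | None = None,
    scores: list[float] | None = None,
) -> None:
    """3-column BED, or 6-column when names are given (score defaults to 0)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
            else:
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{names[i]}\t{score:g}"
                    f"\t{iv.strand if iv.strand != '.' else '.'}\n"
                )


def read_bed(path: str | Path) -> list[tuple[str, GenomeInterval]]:
    """Read 3- or 6-column BED; returns (name, interval) pairs.

    For 3-column BED the name is ``contig:start-end``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            try:
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            name = fields[3] if len(fields) >= 4 else f"{contig}:{start}-{end}"
            out.append((name, GenomeInterval(contig, start, end, strand)))
    return out


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path: str | Path, contig_lengths: dict[str, int] | None = None
) -> DepthTrack:
    """bedGraph (0-based half-open) -> DepthTrack.

    Arrays are sized to contig_lengths when given, else to the maximum end
    seen per contig.
    """
    spans: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line")
            try:
                contig, s, e, d = fields[0], int(fields[1]), int(fields[2]), int(
                    float(fields[3])
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line") from exc
            spans.setdefault(contig, []).append((s, e, d))
    lengths = dict(contig_lengths or {})
    for contig, sp in spans.items():
        lengths.setdefault(contig, max(e for _, e, _ in sp))
    depths = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
    for contig, sp in spans.items():
        arr = depths[contig]
        for s, e, d in sp:
            arr[s:e] = d
    return DepthTrack(depths)


def write_bedgraph(track: DepthTrack, path: str | Path) -> None:
    """Write non-zero runs as bedGraph (runs of equal depth collapsed)."""
    with open(path, "w") as fh:
        for contig in track.contigs():
            arr = track[contig]
            if len(arr) == 0:
                continue
            breaks = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(arr)]])
            for s, e in zip(starts, ends):
                d = arr[s]
                if d != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{d}\n")


# ---------------------------------------------------------------------------
# VCF


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: list[SnpCall], path: str | Path) -> None:
    """Write calls as minimal VCF 4.2 (internal 0-based -> POS 1-based)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(calls, key=lambda c: (c.contig, c.pos0)):
            fh.write(
                f"{c.contig}\t{c.pos0 + 1}\t.\t{c.ref}\t{c.alt}\t{c.qual:g}\t.\t"
                f"DP={c.depth};AF={c.alt_fraction:.6g}\n"
            )


def read_vcf(path: str | Path) -> list[SnpCall]:
    """Read VCF (POS 1-based -> internal 0-based) via pysam.

    Depth comes from INFO/DP and alt fraction from INFO/AF; both default to 0
    when absent.
    """
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            af = rec.info.get("AF", 0.0)
            if isinstance(af, tuple):
                af = af[0]
            # htslib stores Float INFO as float32; we write 6 significant
            # digits, so rounding restores the written value exactly
            af = float(f"{float(af):.6g}")
            calls.append(
                SnpCall(
                    contig=rec.chrom,
                    pos0=rec.pos - 1,
                    ref=rec.ref or ".",
                    alt=alt,
                    qual=float(rec.qual or 0.0),
                    depth=int(rec.info.get("DP", 0)),
                    alt_fraction=float(af),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# pileup TSV and read-interval TSV


def read_pileup(path: str | Path) -> pd.DataFrame:
    """4-column pileup TSV: contig, pos0, depth, alt_count."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "pos0", "depth", "alt_count"],
        dtype={"contig": str, "pos0": np.int64, "depth": np.int64, "alt_count": np.int64},
    )
    return df


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_read_table(path: str | Path) -> list[ReadPlacement]:
    """Read-interval TSV: contig, start, end, sample, dup_flag (0/1)."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: malformed read-table line")
            contig, start, end, sample, dup = fields
            reads.append(
                ReadPlacement(
                    interval=GenomeInterval(contig, int(start), int(end)),
                    sample_id=sample,
                    is_duplicate=bool(int(dup)),
                )
            )
    return reads


def write_read_table(reads: list[ReadPlacement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"{r.interval.contig}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.sample_id}\t{int(r.is_duplicate)}\n"
            )
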