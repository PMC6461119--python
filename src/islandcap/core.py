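"""Core sequence and coordinate types shared across the toolkit.

All coordinates are 0-based half-open. The only conversions from 1-based
conventions happen at the GFF3 and VCF parsing boundaries in
:mod:`islandcap.io`. Lowercase residues are the low-complexity mask channel
end to end: a dustmasked base stays lowercase through collapse, merging and
tiling, where it contributes to probe scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
VALID_ALPHABET = frozenset("ACGTNacgtn")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (mask annotation follows the base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        """Inclusive containment: exact boundary equality counts as inside."""
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N} in either case.

    Lowercase encodes the low-complexity mask. ``N`` is permitted and is
    treated as masked for probe purposes.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A gene spanning 5'UTR start to 3'UTR end, with exon structure.

    ``confidence`` distinguishes high-confidence gene models (supported by
    protein similarity / transcript evidence in the source annotation) from
    low-confidence ones; only high-confidence genes are targeted by default.
    """

    gene_id: str
    interval: GenomeInterval
    exons: list[GenomeInterval] = field(default_factory=list)
    utr5: list[GenomeInterval] = field(default_factory=list)
    utr3: list[GenomeInterval] = field(default_factory=list)
    confidence: str = "high"

    def __post_init__(self) -> None:
        if self.confidence not in ("high", "low"):
            raise ValueError(f"confidence must be high/low, got {self.confidence!r}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for ex in self.exons:
            if not self.interval.contains(ex):
                raise ValueError(f"gene {self.gene_id}: exon outside gene interval")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start: the 5'-most genomic coordinate of the gene span."""
        return self.interval.start if self.strand != "-" else self.interval.end


@dataclass
class TargetRegion:
    """A raw capture target: gene body, putative promoter, 5'UTR or mature miRNA."""

    target_id: str
    kind: str  # gene | promoter | utr5 | mirna
    interval: GenomeInterval
    sequence: SeqRecord
    source_reference: str
    linked_gene: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "promoter", "utr5", "mirna"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if len(self.sequence) != len(self.interval):
            raise ValueError(
                f"target {self.target_id}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self.interval)}"
            )


def slice_genome(genome: dict[str, SeqRecord], interval: GenomeInterval) -> str:
    """Strand-aware genomic slice: '-' intervals are reverse-complemented."""
    rec = genome[interval.contig]
    if interval.end > len(rec):
        raise ValueError(
            f"interval {interval.contig}:{interval.start}-{interval.end} exceeds "
            f"contig length {len(rec)}"
        )
    s = rec.residues[interval.start : interval.end]
    return revcomp(s) if interval.strand == "-" else s


def merge_spans(spans: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Merge overlapping spans; spans separated by < gap are also merged."""
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s - out[-1][1] < gap or s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_spans(
    length: int, remove: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Complement of ``remove`` within [0, length)."""
    merged = merge_spans(remove)
    out = []
    prev = 0
    for s, e in merged:
        s = max(0, min(s, length))
        e = max(0, min(e, length))
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out
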