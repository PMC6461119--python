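"""Design-space construction: per-reference redundancy collapse with fragment
reintegration, organelle purging, low-complexity annotation, length filtering
and cross-reference unique-sequence merging.

The collapse removes redundancy down to a non-redundant (NR) set: no two
retained sequences share a qualifying local alignment (>= 95% identity over
>= 100 bp at e <= 1e-5 by default). Redundant material is clustered by
single linkage and only the longest representative of each cluster is kept;
when that representative is a fragment cut from an otherwise-NR sequence it
is reinserted at its original coordinates so the origin sequence comes out
contiguous again ("reassembly").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .core import SeqRecord, TargetRegion, merge_spans, subtract_spans
from .dust import DEFAULT_THRESHOLD, DEFAULT_WINDOW, mask_sequence
from .similarity import (
    LocalHit,
    SimilarityThresholds,
    cluster_redundant,
    find_local_hits,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProvenanceBlock:
    """Maps a local span of a design contig back to a span of a source target."""

    local_start: int
    local_end: int
    source_reference: str
    target_id: str
    t_start: int
    t_end: int

    def __post_init__(self) -> None:
        if self.local_end - self.local_start != self.t_end - self.t_start:
            raise ValueError("provenance block spans differ in length")


@dataclass
class DesignSpaceContig:
    """A collapsed, filtered target sequence ready for probe tiling."""

    id: str
    sequence: SeqRecord
    provenance: list[ProvenanceBlock]
    reassembled: bool = False

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError(f"contig {self.id}: provenance must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, new_id: str) -> "DesignSpaceContig":
        """Sub-contig [start, end) with provenance blocks clipped and shifted."""
        if not 0 <= start < end <= len(self):
            raise ValueError(f"bad slice [{start},{end}) of contig {self.id}")
        blocks = []
        for b in self.provenance:
            s, e = max(b.local_start, start), min(b.local_end, end)
            if s < e:
                off = s - b.local_start
                blocks.append(
                    ProvenanceBlock(
                        local_start=s - start,
                        local_end=e - start,
                        source_reference=b.source_reference,
                        target_id=b.target_id,
                        t_start=b.t_start + off,
                        t_end=b.t_start + off + (e - s),
                    )
                )
        return DesignSpaceContig(
            id=new_id,
            sequence=SeqRecord(id=new_id, residues=self.sequence.residues[start:end]),
            provenance=blocks,
            reassembled=self.reassembled,
        )


@dataclass
class CollapseReport:
    """Audit counts for one collapse stage; every input sequence lands in
    exactly one disposition."""

    n_input: int = 0
    n_nr_direct: int = 0
    n_redundant_pool: int = 0
    n_clusters: int = 0
    n_reintegrated: int = 0
    n_output: int = 0
    bp_input: int = 0
    bp_output: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_nr_direct": self.n_nr_direct,
            "n_redundant_pool": self.n_redundant_pool,
            "n_clusters": self.n_clusters,
            "n_reintegrated": self.n_reintegrated,
            "n_output": self.n_output,
            "bp_input": self.bp_input,
            "bp_output": self.bp_output,
            "notes": list(self.notes),
        }


@dataclass(frozen=True)
class CollapseParams:
    """Redundant-pool construction knobs.

    A sequence enters the pool whole when at least ``whole_cov`` of its length
    is covered by qualifying hits; otherwise only its hit-covered sub-spans
    enter as fragments, merged when separated by fewer than ``merge_gap`` bp.
    """

    whole_cov: float = 0.80
    merge_gap: int = 10


def _as_records(targets) -> tuple[list[SeqRecord], dict[str, str]]:
    """Accept SeqRecords or TargetRegions; return records + source-ref map."""
    records, source = [], {}
    for t in targets:
        if isinstance(t, TargetRegion):
            records.append(t.sequence)
            source[t.sequence.id] = t.source_reference
        else:
            records.append(t)
            source[t.id] = "unknown"
    return records, source


def _fresh_contig(rec: SeqRecord, source_ref: str) -> DesignSpaceContig:
    return DesignSpaceContig(
        id=rec.id,
        sequence=SeqRecord(id=rec.id, residues=rec.residues),
        provenance=[
            ProvenanceBlock(0, len(rec), source_ref, rec.id, 0, len(rec))
        ],
    )


def self_collapse(
    targets,
    thr: SimilarityThresholds = SimilarityThresholds(),
    params: CollapseParams = CollapseParams(),
    source_reference: str | None = None,
) -> tuple[list[DesignSpaceContig], CollapseReport]:
    """Collapse a target set to non-redundant sequences.

    1. sequences with no qualifying self-set hit pass through unchanged;
    2. whole sequences (hit coverage >= whole_cov) and hit-covered sub-spans
       of partially redundant sequences form the redundant pool, while the
       unhit remainder spans of partial sequences are retained;
    3. the pool is single-linkage clustered and each cluster keeps its longest
       member (ties prefer the fragment with the longer origin sequence,
       maximising reintegration, then the lexicographically smaller id);
    4. a kept fragment is reinserted at its original coordinates, so an origin
       that also retained its non-redundant remainder comes out contiguous
       (``reassembled=True``).
    """
    records, source = _as_records(targets)
    if source_reference is not None:
        source = {rid: source_reference for rid in source}
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate target ids")
    by_id = {r.id: r for r in records}
    report = CollapseReport(
        n_input=len(records), bp_input=sum(len(r) for r in records)
    )
    if len(records) == 1:
        only = records[0]
        report.n_nr_direct = 1
        report.n_output = 1
        report.bp_output = len(only)
        return [_fresh_contig(only, source[only.id])], report

    hits = find_local_hits(records, records, thr, self_mode=True)

    hit_spans: dict[str, list[tuple[int, int]]] = {rid: [] for rid in ids}
    for h in hits:
        hit_spans[h.query_id].append((h.q_start, h.q_end))
        hit_spans[h.subject_id].append((h.s_start, h.s_end))

    nr_direct: list[SeqRecord] = []
    pool: list[SeqRecord] = []  # cluster members (wholes and fragments)
    member_origin: dict[str, str] = {}
    member_span: dict[str, tuple[int, int]] = {}
    remainders: dict[str, list[tuple[int, int]]] = {}
    for rid in ids:
        rec = by_id[rid]
        spans = merge_spans(hit_spans[rid], gap=params.merge_gap)
        if not spans:
            nr_direct.append(rec)
            continue
        covered = sum(e - s for s, e in spans)
        if covered / len(rec) >= params.whole_cov:
            pool.append(rec)
            member_origin[rid] = rid
            member_span[rid] = (0, len(rec))
        else:
            for s, e in spans:
                fid = f"{rid}|{s}-{e}"
                pool.append(SeqRecord(id=fid, residues=rec.residues[s:e]))
                member_origin[fid] = rid
                member_span[fid] = (s, e)
            remainders[rid] = subtract_spans(len(rec), spans)
    report.n_nr_direct = len(nr_direct)
    report.n_redundant_pool = len(pool)

    # map hits between original sequences onto pool members by span overlap
    def _members_overlapping(rid: str, s: int, e: int) -> list[str]:
        return [
            mid
            for mid, origin in member_origin.items()
            if origin == rid
            and member_span[mid][0] < e
            and s < member_span[mid][1]
        ]

    edges: list[LocalHit] = []
    for h in hits:
        q_members = _members_overlapping(h.query_id, h.q_start, h.q_end)
        s_members = _members_overlapping(h.subject_id, h.s_start, h.s_end)
        for qm in q_members:
            for sm in s_members:
                if qm != sm:
                    edges.append(replace(h, query_id=qm, subject_id=sm))

    origin_len = {mid: len(by_id[member_origin[mid]]) for mid in member_origin}
    clusters = cluster_redundant(edges, pool, origin_len=origin_len)
    report.n_clusters = len(clusters)
    kept_members = {c.representative_id for c in clusters}

    # assemble output: per origin, remainder spans + kept member spans
    kept_spans: dict[str, list[tuple[int, int]]] = {}
    for rid, spans in remainders.items():
        kept_spans.setdefault(rid, []).extend(spans)
    rep_origins: dict[str, set[tuple[int, int]]] = {}
    for mid in kept_members:
        rid = member_origin[mid]
        kept_spans.setdefault(rid, []).append(member_span[mid])
        rep_origins.setdefault(rid, set()).add(member_span[mid])

    contigs: list[DesignSpaceContig] = [
        _fresh_contig(r, source[r.id]) for r in nr_direct
    ]
    for rid in ids:
        spans = kept_spans.get(rid)
        if not spans:
            continue
        rec = by_id[rid]
        merged = merge_spans(spans, gap=0)
        # adjacent spans (end == next start) merge too: treat as one piece
        pieces: list[tuple[int, int]] = []
        for s, e in merged:
            if pieces and pieces[-1][1] == s:
                pieces[-1] = (pieces[-1][0], e)
            else:
                pieces.append((s, e))
        reassembled = rid in rep_origins and rid in remainders
        if reassembled:
            report.n_reintegrated += len(rep_origins[rid])
        for i, (s, e) in enumerate(pieces):
            cid = rid if len(pieces) == 1 and (s, e) == (0, len(rec)) else f"{rid}.{i+1}"
            if len(pieces) == 1 and (s, e) != (0, len(rec)):
                cid = f"{rid}.1"
            contig = DesignSpaceContig(
                id=cid,
                sequence=SeqRecord(id=cid, residues=rec.residues[s:e]),
                provenance=[
                    ProvenanceBlock(0, e - s, source[rid], rid, s, e)
                ],
                reassembled=reassembled,
            )
            contigs.append(contig)

    report.n_output = len(contigs)
    report.bp_output = sum(len(c) for c in contigs)
    return sorted(contigs, key=lambda c: c.id), report


def filter_organellar(
    contigs: list[DesignSpaceContig],
    organelle_genomes: list[SeqRecord],
    thr: SimilarityThresholds = SimilarityThresholds(),
) -> list[DesignSpaceContig]:
    """Excise spans with qualifying hits to organelle genomes.

    Remaining pieces are retained as separate contigs (suffixed .1, .2, ...);
    fully-hit sequences are removed. With no organelle genomes this is a no-op.
    """
    if not organelle_genomes:
        return list(contigs)
    recs = [c.sequence for c in contigs]
    hits = find_local_hits(recs, organelle_genomes, thr)
    spans: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        spans.setdefault(h.query_id, []).append((h.q_start, h.q_end))
    out = []
    for c in contigs:
        sp = spans.get(c.id)
        if not sp:
            out.append(c)
            continue
        keep = subtract_spans(len(c), sp)
        if not keep:
            log.info("contig %s removed entirely as organellar", c.id)
            continue
        for i, (s, e) in enumerate(keep):
            out.append(c.slice(s, e, f"{c.id}.{i+1}"))
    return out


def mask_low_complexity(
    contigs: list[DesignSpaceContig],
    window: int = DEFAULT_WINDOW,
    score_threshold: int = DEFAULT_THRESHOLD,
) -> list[DesignSpaceContig]:
    """Annotate low-complexity tracts in lowercase (SDUST); membership is
    unchanged — masked bases are kept and later steer probe scoring."""
    out = []
    for c in contigs:
        masked = mask_sequence(c.sequence.residues, window, score_threshold)
        out.append(
            DesignSpaceContig(
                id=c.id,
                sequence=SeqRecord(id=c.id, residues=masked),
                provenance=list(c.provenance),
                reassembled=c.reassembled,
            )
        )
    return out


def length_filter(
    contigs: list[DesignSpaceContig], min_len: int
) -> tuple[list[DesignSpaceContig], int]:
    """Drop contigs shorter than ``min_len`` (strict <). Returns survivors
    and the number dropped."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [c for c in contigs if len(c) >= min_len]
    return kept, len(contigs) - len(kept)


def merge_unique(
    base: list[DesignSpaceContig],
    addition: list[DesignSpaceContig],
    thr: SimilarityThresholds = SimilarityThresholds(),
    min_fragment: int = 75,
) -> list[DesignSpaceContig]:
    """Append to ``base`` the spans of ``addition`` not found in it.

    For each addition contig, spans hit by base sequence at ``thr`` are
    removed; remaining unique fragments of at least ``min_fragment`` bp are
    appended (suffixed .uN when fragmented). Base contigs are never modified.
    """
    if not addition:
        return list(base)
    if not base:
        return [c for c in addition if len(c) >= min_fragment]
    base_recs = [c.sequence for c in base]
    add_recs = [c.sequence for c in addition]
    hits = find_local_hits(add_recs, base_recs, thr)
    spans: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        spans.setdefault(h.query_id, []).append((h.q_start, h.q_end))
    out = list(base)
    for c in addition:
        sp = spans.get(c.id)
        if not sp:
            if len(c) >= min_fragment:
                out.append(c)
            continue
        keep = [(s, e) for s, e in subtract_spans(len(c), sp) if e - s >= min_fragment]
        for i, (s, e) in enumerate(keep):
            out.append(c.slice(s, e, f"{c.id}.u{i+1}"))
    return out


@dataclass(frozen=True)
class DesignParams:
    thresholds: SimilarityThresholds = SimilarityThresholds()
    collapse: CollapseParams = CollapseParams()
    dust_window: int = DEFAULT_WINDOW
    dust_threshold: int = DEFAULT_THRESHOLD
    min_len_reference: int = 120
    min_fragment_merge: int = 75


def _space_for_kind(
    per_reference_targets: dict[str, list[TargetRegion]],
    kinds: tuple[str, ...],
    organelles: list[SeqRecord],
    params: DesignParams,
    reports: dict,
) -> list[DesignSpaceContig]:
    order = list(per_reference_targets)  # insertion order = merge order
    spaces: dict[str, list[DesignSpaceContig]] = {}
    for ref in order:
        targets = [t for t in per_reference_targets[ref] if t.kind in kinds]
        if not targets:
            spaces[ref] = []
            reports[ref] = CollapseReport().as_dict()
            continue
        contigs, rep = self_collapse(
            targets, params.thresholds, params.collapse, source_reference=ref
        )
        contigs = filter_organellar(contigs, organelles, params.thresholds)
        contigs = mask_low_complexity(contigs, params.dust_window, params.dust_threshold)
        contigs, n_short = length_filter(contigs, params.min_len_reference)
        rep.notes.append(f"{n_short} contigs dropped < {params.min_len_reference} bp")
        rep.n_output = len(contigs)
        rep.bp_output = sum(len(c) for c in contigs)
        spaces[ref] = contigs
        reports[ref] = rep.as_dict()
    merged = spaces[order[0]]
    for ref in order[1:]:
        merged = merge_unique(
            merged, spaces[ref], params.thresholds, params.min_fragment_merge
        )
    merged, n_short = length_filter(merged, params.min_fragment_merge)
    reports["merge_order"] = order
    reports["final_n"] = len(merged)
    reports["final_bp"] = sum(len(c) for c in merged)
    return merged


def build_design_space(
    per_reference_targets: dict[str, list[TargetRegion]],
    organelles: list[SeqRecord] | None = None,
    params: DesignParams = DesignParams(),
    mirna_targets: list[TargetRegion] | None = None,
    include_utr5: bool = False,
) -> tuple[list[DesignSpaceContig], list[DesignSpaceContig], dict]:
    """Build the gene and promoter design spaces across references.

    Per reference: self-collapse -> organelle purge -> low-complexity masking
    -> length filter (120 bp); references are then merged in their given
    order, base first, unique additions appended, followed by the final 75 bp
    fragment filter. Exonic-miRNA targets (and, when ``include_utr5``, the
    well-covered 5'UTRs, giving the promoter-2 variant) join the promoter
    space before collapse of their reference set.
    """
    if not per_reference_targets:
        raise ValueError("need at least one reference")
    organelles = organelles or []
    reports: dict = {"gene": {}, "promoter": {}}
    gene_space = _space_for_kind(
        per_reference_targets, ("gene",), organelles, params, reports["gene"]
    )
    promoter_targets = {
        ref: list(ts) for ref, ts in per_reference_targets.items()
    }
    if mirna_targets:
        first = next(iter(promoter_targets))
        promoter_targets[first] = promoter_targets[first] + list(mirna_targets)
    kinds = ("promoter", "mirna", "utr5") if include_utr5 else ("promoter", "mirna")
    promoter_space = _space_for_kind(
        promoter_targets, kinds, organelles, params, reports["promoter"]
    )
    if not gene_space and not promoter_space:
        raise ValueError("design space is empty")
    return gene_space, promoter_space, reports
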