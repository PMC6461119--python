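"""Island-strategy probe placement and capture-coverage estimation.

Rather than overlap-tiling probes, the island strategy spaces probes at
regular intervals (default 120 bp from each probe's 5' start to the next),
exploiting the fact that a single probe pulls down a whole library fragment
(~200-500 bp): spacing maximises breadth of the design space per probe
budget. Around each nominal grid position, the best probe within a 20-bp
selection window is chosen to minimise low-complexity content and similarity
to genomic sequence outside the design space; candidate probes containing a
masked run of 40 bp or more are disregarded outright.

Off-target similarity is measured by membership of a probe's k-mers (k=17)
in an index of background k-mers absent from the design space — a
deterministic, desk-scale proxy for an alignment screen against the full
genome; the scorer is a pluggable boundary should an aligner be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import SeqRecord
from .design import DesignSpaceContig

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TilingParams:
    spacing: int = 120  # 5' start to 5' start
    selection_window: int = 20  # total window; candidates at nominal +/- half
    probe_len_min: int = 50
    probe_len_max: int = 100
    probe_len_target: int = 75
    probe_len_step: int = 5
    lowcomp_discard_run: int = 40
    capacity: int = 2_160_000
    offtarget_k: int = 17
    w_mask: float = 1.0
    w_offtarget: float = 1.0

    def __post_init__(self) -> None:
        if not self.probe_len_min <= self.probe_len_target <= self.probe_len_max:
            raise ValueError("need probe_len_min <= probe_len_target <= probe_len_max")
        if self.spacing < 1 or self.capacity < 1:
            raise ValueError("spacing and capacity must be >= 1")

    @property
    def half_window(self) -> int:
        return self.selection_window // 2

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(
            range(self.probe_len_min, self.probe_len_max + 1, self.probe_len_step)
        )


@dataclass(frozen=True)
class Probe:
    probe_id: str
    contig: str
    start: int
    length: int
    sequence: str
    masked_bases: int
    offtarget_hits: int
    score: float
    nominal_start: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class ProbeSet:
    probes: list[Probe]
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)


def pct(part: float, whole: float, ndigits: int = 1) -> float:
    """Percentage of ``part`` in ``whole`` rounded to ``ndigits`` decimals,
    the convention used for all design-space coverage figures."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, ndigits)


# ---------------------------------------------------------------------------
# off-target k-mer index

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (min of strand pair) integer codes of all valid k-mers."""
    b = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(b) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    valid = b >= 0
    ok = np.ones(n, dtype=bool)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | np.where(valid[j : j + n], b[j : j + n], 0)
        comp = np.where(valid[j : j + n], 3 - b[j : j + n], 0)
        rev = rev | (comp << (2 * j))
        ok &= valid[j : j + n]
    canon = np.minimum(fwd, rev)
    return canon[ok]


@dataclass
class OfftargetIndex:
    """Multiset of canonical background k-mers absent from the design space."""

    k: int
    counts: dict[int, int] = field(default_factory=dict)

    def __contains__(self, code: int) -> bool:
        return code in self.counts

    def __len__(self) -> int:
        return len(self.counts)


def build_offtarget_index(
    background_genome: list[SeqRecord],
    design_space: list[DesignSpaceContig],
    k: int = 17,
) -> OfftargetIndex:
    """k-mers occurring in the background but absent from the design space,
    with multiplicities; both sets canonicalised. Empty background -> empty
    index (all probes score zero off-target)."""
    design_kmers: set[int] = set()
    for c in design_space:
        design_kmers.update(_canonical_kmers(c.sequence.residues, k).tolist())
    counts: dict[int, int] = {}
    for rec in background_genome or []:
        for code in _canonical_kmers(rec.residues, k).tolist():
            if code not in design_kmers:
                counts[code] = counts.get(code, 0) + 1
    return OfftargetIndex(k=k, counts=counts)


def score_probe(
    sequence: str,
    index: OfftargetIndex,
    w_mask: float = 1.0,
    w_offtarget: float = 1.0,
) -> tuple[float, int, int]:
    """Two-term probe penalty (lower is better).

    score = w_mask * masked bases + w_offtarget * candidate k-mers present in
    the off-target index. N counts as masked. Returns (score, masked,
    offtarget_hits).
    """
    masked = sum(1 for ch in sequence if ch.islower() or ch in "Nn")
    off = 0
    if index.counts:
        for code in _canonical_kmers(sequence, index.k).tolist():
            if code in index.counts:
                off += 1
    return w_mask * masked + w_offtarget * off, masked, off


# ---------------------------------------------------------------------------
# tiling


def _mask_profile(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lower = (arr >= 97) & (arr <= 122)
    return lower | (arr == ord("N")) | (arr == ord("n"))


def _max_masked_run(is_masked: np.ndarray) -> int:
    if not is_masked.any():
        return 0
    padded = np.concatenate([[0], is_masked.view(np.int8), [0]])
    edges = np.nonzero(np.diff(padded))[0]
    return int((edges[1::2] - edges[0::2]).max())


def tile_islands(
    space: list[DesignSpaceContig],
    params: TilingParams = TilingParams(),
    index: OfftargetIndex | None = None,
) -> ProbeSet:
    """Tile probes across the design space on a regular grid.

    Per contig, nominal starts lie at 0, spacing, 2*spacing, ... while at
    least ``probe_len_min`` bases remain. For each nominal start, candidates
    are enumerated over starts within +/- half the selection window and
    lengths {50, 55, ..., 100}; candidates holding a masked run >=
    ``lowcomp_discard_run`` are discarded. The winner is the lexicographic
    minimum of (score, |length - target|, |start - nominal|, start); islands
    whose whole candidate set is discarded are skipped and recorded. A probe
    never starts at or before the previous probe's start.
    """
    if not space:
        raise ValueError("design space is empty")
    index = index or OfftargetIndex(k=params.offtarget_k)
    probes: list[Probe] = []
    skipped: list[tuple[str, int]] = []
    hw = params.half_window
    lengths = params.lengths
    for contig in sorted(space, key=lambda c: c.id):
        seq = contig.sequence.residues
        L = len(seq)
        if L < params.probe_len_min:
            skipped.append((contig.id, 0))
            log.debug("contig %s shorter than minimum probe length", contig.id)
            continue
        is_masked = _mask_profile(seq)
        mask_prefix = np.concatenate([[0], np.cumsum(is_masked)])
        if index.counts:
            codes = _canonical_kmers_positions(seq, index.k)
            off_flag = np.array(
                [1 if c >= 0 and c in index.counts else 0 for c in codes],
                dtype=np.int64,
            )
            off_prefix = np.concatenate([[0], np.cumsum(off_flag)])
        else:
            off_prefix = None
        prev_start = -1
        n_on_contig = 0
        nominal = 0
        while nominal + params.probe_len_min <= L:
            best = None
            for length in lengths:
                lo = max(0, nominal - hw, prev_start + 1)
                hi = min(nominal + hw, L - length)
                for start in range(lo, hi + 1):
                    masked = int(mask_prefix[start + length] - mask_prefix[start])
                    if masked >= params.lowcomp_discard_run:
                        if (
                            _max_masked_run(is_masked[start : start + length])
                            >= params.lowcomp_discard_run
                        ):
                            continue
                    if off_prefix is not None:
                        nk = length - index.k + 1
                        off = (
                            int(off_prefix[start + nk] - off_prefix[start])
                            if nk > 0
                            else 0
                        )
                    else:
                        off = 0
                    score = params.w_mask * masked + params.w_offtarget * off
                    key = (score, abs(length - params.probe_len_target),
                           abs(start - nominal), start)
                    if best is None or key < best[0]:
                        best = (key, start, length, masked, off, score)
            if best is None:
                skipped.append((contig.id, nominal))
            else:
                _, start, length, masked, off, score = best
                n_on_contig += 1
                probes.append(
                    Probe(
                        probe_id=f"{contig.id}_p{n_on_contig}",
                        contig=contig.id,
                        start=start,
                        length=length,
                        sequence=seq[start : start + length],
                        masked_bases=masked,
                        offtarget_hits=off,
                        score=score,
                        nominal_start=nominal,
                    )
                )
                prev_start = start
            nominal += params.spacing
    pset = ProbeSet(probes=sorted(probes, key=lambda p: (p.contig, p.start)))
    pset.stats = _stats(pset, space)
    pset.stats["islands_skipped"] = len(skipped)
    return pset


def _canonical_kmers_positions(seq: str, k: int) -> np.ndarray:
    """Per-position canonical k-mer codes (-1 where invalid), aligned to starts."""
    b = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(b) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    valid = b >= 0
    ok = np.ones(n, dtype=bool)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | np.where(valid[j : j + n], b[j : j + n], 0)
        comp = np.where(valid[j : j + n], 3 - b[j : j + n], 0)
        rev = rev | (comp << (2 * j))
        ok &= valid[j : j + n]
    canon = np.minimum(fwd, rev)
    canon[~ok] = -1
    return canon


def _stats(pset: ProbeSet, space: list[DesignSpaceContig]) -> dict:
    design_bp = sum(
        len(c) - c.sequence.residues.upper().count("N") for c in space
    )
    probe_bp = _distinct_probe_bp(pset)
    n = len(pset.probes)
    spacings = []
    by_contig: dict[str, list[int]] = {}
    for p in pset.probes:
        by_contig.setdefault(p.contig, []).append(p.start)
    for starts in by_contig.values():
        starts.sort()
        spacings.extend(b - a for a, b in zip(starts, starts[1:]))
    return {
        "n_probes": n,
        "probe_bp": probe_bp,
        "design_bp": design_bp,
        "pct_design_in_probes": pct(probe_bp, design_bp) if design_bp else 0.0,
        "mean_len": float(np.mean([p.length for p in pset.probes])) if n else 0.0,
        "mean_spacing": float(np.mean(spacings)) if spacings else 0.0,
    }


def _distinct_probe_bp(pset: ProbeSet) -> int:
    """Probe bases counted once per design-space position."""
    from .core import merge_spans

    per_contig: dict[str, list[tuple[int, int]]] = {}
    for p in pset.probes:
        per_contig.setdefault(p.contig, []).append((p.start, p.end))
    return sum(
        e - s
        for spans in per_contig.values()
        for s, e in merge_spans(spans)
    )


def enforce_capacity(
    pset: ProbeSet,
    space: list[DesignSpaceContig],
    params: TilingParams = TilingParams(),
    index: OfftargetIndex | None = None,
) -> ProbeSet:
    """Cap the probe count at the platform capacity.

    If over capacity, the spacing is inflated to ceil(spacing * n / capacity)
    and tiling rerun once; any residual excess is dropped worst-score-first
    to exactly the capacity. Both actions are logged in the stats.
    """
    n = len(pset.probes)
    if n <= params.capacity:
        return pset
    import math
    from dataclasses import replace as _replace

    new_spacing = math.ceil(params.spacing * n / params.capacity)
    log.info("capacity exceeded (%d > %d): retiling at spacing %d",
             n, params.capacity, new_spacing)
    wide = _replace(params, spacing=new_spacing)
    pset2 = tile_islands(space, wide, index)
    pset2.stats["capacity_action"] = f"retiled at spacing {new_spacing}"
    if len(pset2.probes) > params.capacity:
        ranked = sorted(
            pset2.probes, key=lambda p: (p.score, p.contig, p.start)
        )[: params.capacity]
        pset2 = ProbeSet(probes=sorted(ranked, key=lambda p: (p.contig, p.start)))
        pset2.stats = _stats(pset2, space)
        pset2.stats["capacity_action"] = (
            f"retiled at spacing {new_spacing}, then dropped to capacity by score"
        )
    return pset2


@dataclass(frozen=True)
class CoverageEstimate:
    covered_bp: int
    pct: float


def estimate_capture_coverage(
    pset: ProbeSet,
    space: list[DesignSpaceContig],
    fragment_len: int = 200,
) -> CoverageEstimate:
    """Design-space coverage if each probe captures a library fragment.

    Each probe's captured interval is the probe symmetrically extended to
    ``fragment_len`` (left pad = floor((fragment_len - len)/2), remainder on
    the right), clipped to its contig; coverage is the union over the space,
    as a fraction of the N-excluded design-space size.
    """
    lengths = {c.id: len(c) for c in space}
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for p in pset.probes:
        if fragment_len < p.length:
            raise ValueError("fragment_len must be >= probe length")
        pad_l = (fragment_len - p.length) // 2
        s = max(0, p.start - pad_l)
        e = min(lengths[p.contig], p.start - pad_l + fragment_len)
        per_contig.setdefault(p.contig, []).append((s, e))
    from .core import merge_spans

    covered = sum(
        e - s for spans in per_contig.values() for s, e in merge_spans(spans)
    )
    design_bp = sum(
        len(c) - c.sequence.residues.upper().count("N") for c in space
    )
    return CoverageEstimate(
        covered_bp=covered, pct=pct(covered, design_bp) if design_bp else 0.0
    )
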