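"""Post-capture evaluation: coverage breadth/depth, uniformity, saturation,
SNP post-filtering and cross-sample comparable positions.

The module consumes outputs of an upstream read-mapping pipeline (depth
tracks, read intervals, variant calls); it never maps reads itself. Reads are
assumed to have passed upstream QC (unique best mapping, quality >= Q10) and
carry a duplicate flag which every operation honours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeInterval

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


class DepthTrack:
    """Per-contig integer depth arrays (0-based positions)."""

    def __init__(self, depths: dict[str, np.ndarray] | None = None):
        self.depths: dict[str, np.ndarray] = {}
        for contig, arr in (depths or {}).items():
            arr = np.asarray(arr, dtype=np.int64)
            if (arr < 0).any():
                raise ValueError(f"negative depth on contig {contig}")
            self.depths[contig] = arr

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.depths[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.depths

    def contigs(self) -> list[str]:
        return sorted(self.depths)

    def get(self, contig: str, length: int | None = None) -> np.ndarray:
        if contig in self.depths:
            return self.depths[contig]
        return np.zeros(length or 0, dtype=np.int64)

    @classmethod
    def from_reads(
        cls,
        reads: list["ReadPlacement"],
        contig_lengths: dict[str, int],
        include_duplicates: bool = False,
    ) -> "DepthTrack":
        """Rebuild a depth track from read intervals (duplicates dropped)."""
        diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in contig_lengths.items()}
        for r in reads:
            if r.is_duplicate and not include_duplicates:
                continue
            d = diff[r.interval.contig]
            d[r.interval.start] += 1
            d[r.interval.end] -= 1
        return cls({c: np.cumsum(d[:-1]) for c, d in diff.items()})


@dataclass(frozen=True)
class ReadPlacement:
    """A mapped read/fragment interval with sample provenance."""

    interval: GenomeInterval
    sample_id: str = "sample"
    is_duplicate: bool = False


@dataclass(frozen=True)
class SnpCall:
    contig: str
    pos0: int
    ref: str
    alt: str
    qual: float
    depth: int
    alt_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError(f"alt_fraction {self.alt_fraction} outside [0,1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class SnpFilterParams:
    """Post-filters applied to raw variant calls.

    A call survives iff qual >= qual_min, depth >= depth_min and
    alt_fraction > hom_af_min (strict: homozygosity means the alternate
    allele in more than 80% of reads). Any surviving call that shares a
    ``window``-bp span with >= window_max_snps + 1 surviving calls is then
    removed (clustered calls are treated as alignment artefacts).
    """

    qual_min: float = 50.0
    depth_min: int = 5
    hom_af_min: float = 0.80
    window: int = 10
    window_max_snps: int = 2

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


# ---------------------------------------------------------------------------
# coverage statistics


def _target_union_positions(
    track: DepthTrack, targets: list[GenomeInterval]
) -> np.ndarray:
    """Concatenated depths over the union of target bases (each base once)."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        per_contig.setdefault(t.contig, []).append((t.start, t.end))
    chunks = []
    for contig, spans in sorted(per_contig.items()):
        if contig not in track:
            raise ValueError(f"target contig {contig!r} missing from depth track")
        arr = track[contig]
        from .core import merge_spans

        for s, e in merge_spans(spans):
            if e > len(arr):
                raise ValueError(
                    f"target {contig}:{s}-{e} outside track (len {len(arr)})"
                )
            chunks.append(arr[s:e])
    if not chunks:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(chunks)


def breadth(
    track: DepthTrack,
    targets: list[GenomeInterval],
    thresholds: tuple[int, ...] = (1, 5, 10),
) -> dict[int, dict[str, float]]:
    """Coverage breadth: bases (and %) of the target union at depth >= t.

    Overlapping targets are counted once.
    """
    depths = _target_union_positions(track, targets)
    total = len(depths)
    out = {}
    for t in thresholds:
        bp = int((depths >= t).sum())
        out[t] = {"bp": bp, "pct": 100.0 * bp / total if total else 0.0}
    return out


def per_target_stats(
    track: DepthTrack, targets: list[tuple[str, GenomeInterval]]
) -> pd.DataFrame:
    """Per-target mean depth, breadth at 1x/5x and a covered flag."""
    rows = []
    for tid, iv in targets:
        d = track[iv.contig][iv.start : iv.end]
        n = len(d)
        rows.append(
            {
                "target_id": tid,
                "mean_depth": float(d.mean()),
                "pct_1x": 100.0 * float((d >= 1).sum()) / n,
                "pct_5x": 100.0 * float((d >= 5).sum()) / n,
                "covered_flag": bool((d >= 1).any()),
            }
        )
    return pd.DataFrame(rows)


def coefficient_of_variation(
    track: DepthTrack, targets: list[GenomeInterval]
) -> float:
    """Population sd / mean of per-base depth over the target union.

    CV < 1 is conventionally read as uniform (low-variance) enrichment.
    """
    depths = _target_union_positions(track, targets)
    if len(depths) < 2:
        raise ValueError("need at least 2 target bases")
    mean = depths.mean()
    if mean == 0:
        raise ValueError("mean depth is zero; CV undefined")
    return float(depths.std() / mean)


def on_target_fraction(
    reads: list[ReadPlacement], design_intervals: list[GenomeInterval]
) -> float:
    """Percent of non-duplicate reads overlapping any design interval by >= 1 bp."""
    from .core import merge_spans

    per_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in design_intervals:
        per_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    starts_ends = {}
    for contig, spans in per_contig.items():
        merged = merge_spans(spans)
        starts_ends[contig] = (
            np.array([s for s, _ in merged]),
            np.array([e for _, e in merged]),
        )
    n = on = 0
    for r in reads:
        if r.is_duplicate:
            continue
        n += 1
        se = starts_ends.get(r.interval.contig)
        if se is None:
            continue
        starts, ends = se
        # overlap iff some merged span has start < read.end and end > read.start
        i = np.searchsorted(starts, r.interval.end, side="left")
        if i > 0 and ends[i - 1] > r.interval.start:
            on += 1
    if n == 0:
        raise ValueError("no non-duplicate reads")
    return 100.0 * on / n


def flag_high_coverage(
    track: DepthTrack,
    regions: list[tuple[str, GenomeInterval]],
    factor: float = 10.0,
    center: str = "median",
) -> list[str]:
    """Regions with excessive coverage: max depth > factor x the central
    per-region maximum (median by default; ``center='mean'`` available)."""
    if not regions:
        raise ValueError("need at least one region")
    maxima = {
        rid: float(track[iv.contig][iv.start : iv.end].max()) for rid, iv in regions
    }
    vals = np.array(list(maxima.values()))
    central = float(np.median(vals)) if center == "median" else float(vals.mean())
    return [rid for rid, m in maxima.items() if m > factor * central]


# ---------------------------------------------------------------------------
# saturation


def saturation_curve(
    reads: list[ReadPlacement],
    targets: list[GenomeInterval],
    contig_lengths: dict[str, int],
    fractions: tuple[float, ...] = (0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875, 1.0),
    threshold: int = 5,
    seed: int = 0,
    plateau_gain: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Breadth at >= threshold as a function of read subsampling fraction.

    Subsampling is per-read binomial and *nested*: each read draws one uniform
    deviate and is kept at fraction f iff the deviate is <= f, so a read kept
    at a small fraction is kept at all larger fractions and the curve is
    monotone by construction. The saturation point is the smallest fraction
    whose marginal breadth gain to the next fraction is < ``plateau_gain``
    percentage points (the last fraction if the curve never flattens).
    """
    fractions = tuple(sorted(fractions))
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = [r for r in reads if not r.is_duplicate]
    u = rng.random(len(keep))
    rows = []
    for f in fractions:
        sub = [r for r, ui in zip(keep, u) if f == 1.0 or ui <= f]
        track = DepthTrack.from_reads(sub, contig_lengths)
        b = breadth(track, targets, thresholds=(threshold,))[threshold]
        rows.append(
            {"fraction": f, "reads_used": len(sub), "pct_ge_threshold": b["pct"]}
        )
    table = pd.DataFrame(rows)
    sat = fractions[-1]
    for i in range(len(fractions) - 1):
        gain = table.pct_ge_threshold[i + 1] - table.pct_ge_threshold[i]
        if gain < plateau_gain:
            sat = fractions[i]
            break
    return table, sat


# ---------------------------------------------------------------------------
# SNP post-filtering


def filter_snps(
    calls: list[SnpCall], params: SnpFilterParams = SnpFilterParams()
) -> list[SnpCall]:
    """Apply the post-call filters: quality, depth, strict homozygosity, then
    removal of every call lying in any ``window``-bp span that holds more than
    ``window_max_snps`` stage-one survivors (windows slide per base)."""
    stage1 = [
        c
        for c in calls
        if c.qual >= params.qual_min
        and c.depth >= params.depth_min
        and c.alt_fraction > params.hom_af_min
    ]
    by_contig: dict[str, list[SnpCall]] = {}
    for c in stage1:
        by_contig.setdefault(c.contig, []).append(c)
    kept: list[SnpCall] = []
    for contig in sorted(by_contig):
        cs = sorted(by_contig[contig], key=lambda c: c.pos0)
        pos = np.array([c.pos0 for c in cs])
        bad = np.zeros(len(cs), dtype=bool)
        # every maximal run of calls fitting in a window of `window` bp
        j = 0
        for i in range(len(cs)):
            while pos[i] - pos[j] >= params.window:
                j += 1
            if i - j + 1 > params.window_max_snps:
                bad[j : i + 1] = True
        kept.extend(c for c, b in zip(cs, bad) if not b)
    return sorted(kept, key=lambda c: (c.contig, c.pos0))


def comparable_positions(
    samples: dict[str, tuple[list[SnpCall], DepthTrack]],
    depth_min: int = 5,
) -> tuple[dict[tuple[str, int], dict[str, str]], int]:
    """Cross-sample comparable positions.

    A position is comparable iff every sample has either a (filtered) SNP
    there, or depth >= depth_min with no SNP (i.e. confidently reference).
    Returns the total count plus an allele matrix restricted to comparable
    positions where at least one sample carries a SNP (values: ref/alt).
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    contigs: dict[str, int] = {}
    for _, track in samples.values():
        for c in track.contigs():
            contigs[c] = max(contigs.get(c, 0), len(track[c]))
    snp_pos: dict[str, dict[str, set[int]]] = {
        sid: {} for sid in samples
    }  # sample -> contig -> positions
    for sid, (calls, _) in samples.items():
        for c in calls:
            snp_pos[sid].setdefault(c.contig, set()).add(c.pos0)

    n_comparable = 0
    matrix: dict[tuple[str, int], dict[str, str]] = {}
    for contig, length in sorted(contigs.items()):
        ok = np.ones(length, dtype=bool)
        any_snp = np.zeros(length, dtype=bool)
        for sid, (_, track) in samples.items():
            depth = track.get(contig, length)
            if len(depth) < length:
                depth = np.pad(depth, (0, length - len(depth)))
            has_snp = np.zeros(length, dtype=bool)
            for p in snp_pos[sid].get(contig, ()):
                has_snp[p] = True
            ok &= has_snp | (depth >= depth_min)
            any_snp |= has_snp
        n_comparable += int(ok.sum())
        for p in np.nonzero(ok & any_snp)[0]:
            matrix[(contig, int(p))] = {
                sid: ("alt" if int(p) in snp_pos[sid].get(contig, set()) else "ref")
                for sid in samples
            }
    return matrix, n_comparable


def naive_pileup_caller(pileup: pd.DataFrame) -> list[SnpCall]:
    """Turn a 4-column pileup (contig, pos0, depth, alt_count) into raw calls.

    One call per position with alt_count >= 1; qual = 50 + 10*alt_count capped
    at 99. This supplies SnpCalls for synthetic tests without an external
    caller; it is not a genotyper.
    """
    calls = []
    for row in pileup.itertuples(index=False):
        if row.alt_count > row.depth:
            raise ValueError(
                f"alt_count {row.alt_count} > depth {row.depth} at "
                f"{row.contig}:{row.pos0}"
            )
        if row.alt_count >= 1:
            calls.append(
                SnpCall(
                    contig=row.contig,
                    pos0=int(row.pos0),
                    ref="N",
                    alt="A",
                    qual=min(99.0, 50.0 + 10.0 * row.alt_count),
                    depth=int(row.depth),
                    alt_fraction=row.alt_count / row.depth,
                )
            )
    return sorted(calls, key=lambda c: (c.contig, c.pos0))
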