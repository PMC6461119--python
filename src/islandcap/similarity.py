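"""Pairwise local-similarity search and single-linkage redundancy clustering.

The engine is a deterministic seed-and-extend local aligner: exact k-mer
seeds (default k=16) are extended ungapped in both directions with an X-drop
rule, scored +1/-2, and reported when they clear the redundancy thresholds
(e-value <= 1e-5, identity >= 95%, alignment length >= 100 bp). Both strands
are searched. Significance uses the ungapped Karlin-Altschul form
E = K*m*n*exp(-lambda*S) with the standard constants for +1/-2 scoring;
because the identity and length thresholds dominate the filter, the
significance constants are non-critical and are exposed as configuration.

Gapped extension is not implemented: the redundancy this stage exists to
detect (homoeologous/paralogous copies, shared fragments) is modelled here as
substitution divergence, for which the ungapped optimum coincides with the
Smith-Waterman optimum under any affine gap cost >= the mismatch cost.
A pluggable backend could substitute an external aligner producing the same
LocalHit records without changing downstream contracts.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import SeqRecord, revcomp


@dataclass(frozen=True)
class SimilarityThresholds:
    evalue_max: float = 1e-5
    identity_min: float = 0.95
    length_min: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_min <= 1.0:
            raise ValueError("identity_min must be in (0, 1]")
        if self.length_min < 1:
            raise ValueError("length_min must be >= 1")


@dataclass(frozen=True)
class AlignParams:
    """Seed-and-extend engine parameters."""

    k: int = 16
    xdrop: int = 20
    match: int = 1
    mismatch: int = -2
    ka_k: float = 0.46  # Karlin-Altschul K for +1/-2
    ka_lambda: float = 1.28  # Karlin-Altschul lambda for +1/-2
    both_strands: bool = True


DEFAULT_ALIGN = AlignParams()


@dataclass(frozen=True)
class LocalHit:
    """One qualifying local alignment between two sequences.

    Spans are 0-based half-open on the forward strand of each sequence;
    ``strand`` is '-' when the query aligned reverse-complemented.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    aln_len: int
    evalue: float
    score: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.q_end - self.q_start > self.aln_len or self.s_end - self.s_start > self.aln_len:
            raise ValueError("span longer than alignment length")


def evalue_of(
    score: int, m: int, n: int, params: AlignParams = DEFAULT_ALIGN
) -> float:
    """BLAST-style expected number of chance alignments at this score.

    E = K*m*n*exp(-lambda*score) over search space m x n (full set lengths,
    pairwise-database convention; no effective-length correction).
    """
    if m <= 0 or n <= 0:
        raise ValueError("search space sizes must be positive")
    if score < 0:
        raise ValueError("score must be >= 0")
    return params.ka_k * m * n * math.exp(-params.ka_lambda * score)


# ---------------------------------------------------------------------------
# seed indexing

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where the window contains a non-ACGT base."""
    b = _codes(seq).astype(np.int64)
    n = len(b) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    valid = b >= 0
    ok = np.ones(n, dtype=bool)
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code = (code << 2) | np.where(valid[j : j + n], b[j : j + n], 0)
        ok &= valid[j : j + n]
    code[~ok] = -1
    return code


def _extend(q: str, s: str, qs: int, ss: int, k: int, p: AlignParams):
    """Ungapped X-drop extension of an exact seed q[qs:qs+k] == s[ss:ss+k].

    Returns (q_lo, q_hi, s_lo, matches, score) at the best-scoring extents.
    """
    match, mismatch, xdrop = p.match, p.mismatch, p.xdrop
    base = k * match
    # right
    cur = 0
    best = 0
    best_r = qs + k
    best_r_matches = 0
    cur_matches = 0
    i, j = qs + k, ss + k
    nq, ns = len(q), len(s)
    while i < nq and j < ns:
        if q[i] == s[j] and q[i] != "N":
            cur += match
            cur_matches += 1
        else:
            cur += mismatch
        i += 1
        j += 1
        if cur > best:
            best, best_r, best_r_matches = cur, i, cur_matches
        elif best - cur > xdrop:
            break
    score = base + best
    # left
    cur = 0
    bl = 0
    best_l = qs
    best_l_matches = 0
    cur_matches = 0
    i, j = qs - 1, ss - 1
    while i >= 0 and j >= 0:
        if q[i] == s[j] and q[i] != "N":
            cur += match
            cur_matches += 1
        else:
            cur += mismatch
        if cur > bl:
            bl, best_l, best_l_matches = cur, i, cur_matches
        elif bl - cur > xdrop:
            break
        i -= 1
        j -= 1
    score += bl
    matches = k + best_r_matches + best_l_matches
    q_lo, q_hi = best_l, best_r
    s_lo = ss - (qs - best_l)
    return q_lo, q_hi, s_lo, matches, score


def find_local_hits(
    queries: list[SeqRecord],
    subjects: list[SeqRecord],
    thr: SimilarityThresholds = SimilarityThresholds(),
    *,
    self_mode: bool = False,
    params: AlignParams = DEFAULT_ALIGN,
) -> list[LocalHit]:
    """All qualifying local alignments of queries against subjects.

    ``self_mode`` suppresses the trivial full-length self-hit of each
    sequence against itself (forward strand, diagonal 0); other self-hits
    (internal repeats, palindromes) are still reported.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    k = params.k
    subj_up = {r.id: r.residues.upper() for r in subjects}
    index: dict[int, list[tuple[str, int]]] = defaultdict(list)
    for sid, seq in subj_up.items():
        codes = _kmer_codes(seq, k)
        for pos in range(len(codes)):
            c = codes[pos]
            if c >= 0:
                index[int(c)].append((sid, pos))

    m_total = sum(len(r) for r in queries)
    n_total = sum(len(r) for r in subjects)
    strands = ("+", "-") if params.both_strands else ("+",)
    hits: list[LocalHit] = []
    for qrec in queries:
        q_fwd = qrec.residues.upper()
        for strand in strands:
            qseq = q_fwd if strand == "+" else revcomp(q_fwd)
            codes = _kmer_codes(qseq, k)
            # group seed matches by (subject, diagonal)
            by_diag: dict[tuple[str, int], list[int]] = defaultdict(list)
            for qp in range(len(codes)):
                c = codes[qp]
                if c < 0:
                    continue
                for sid, sp in index.get(int(c), ()):
                    by_diag[(sid, sp - qp)].append(qp)
            for (sid, diag), qpos_list in sorted(by_diag.items()):
                if self_mode and sid == qrec.id and strand == "+" and diag == 0:
                    continue
                sseq = subj_up[sid]
                covered_end = -1
                for qp in qpos_list:
                    if qp + k <= covered_end:
                        continue
                    q_lo, q_hi, s_lo, matches, score = _extend(
                        qseq, sseq, qp, qp + diag, k, params
                    )
                    covered_end = q_hi
                    aln_len = q_hi - q_lo
                    identity = matches / aln_len
                    ev = evalue_of(score, m_total, n_total, params)
                    if (
                        ev <= thr.evalue_max
                        and identity >= thr.identity_min
                        and aln_len >= thr.length_min
                    ):
                        if strand == "+":
                            q_start, q_end = q_lo, q_hi
                        else:
                            q_start, q_end = len(qseq) - q_hi, len(qseq) - q_lo
                        hits.append(
                            LocalHit(
                                query_id=qrec.id,
                                subject_id=sid,
                                q_start=q_start,
                                q_end=q_end,
                                s_start=s_lo,
                                s_end=s_lo + aln_len,
                                strand=strand,
                                identity=identity,
                                aln_len=aln_len,
                                evalue=ev,
                                score=score,
                            )
                        )
    return _dedupe(hits)


def _dedupe(hits: list[LocalHit]) -> list[LocalHit]:
    """Drop duplicate hits (same pair/strand with contained spans)."""
    best: dict[tuple, LocalHit] = {}
    for h in sorted(
        hits, key=lambda h: (h.query_id, h.subject_id, h.strand, -h.score)
    ):
        key = (h.query_id, h.subject_id, h.strand)
        keep = True
        for other in best.get(key, []):
            if (
                other.q_start <= h.q_start
                and h.q_end <= other.q_end
                and other.s_start <= h.s_start
                and h.s_end <= other.s_end
            ):
                keep = False
                break
        if keep:
            best.setdefault(key, []).append(h)
    out = [h for hs in best.values() for h in hs]
    return sorted(out, key=lambda h: (h.query_id, h.subject_id, h.strand, h.q_start))


def hits_to_table(hits: list[LocalHit]):
    """Tabular export mirroring BLAST outfmt-6 column order (for debugging)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "pident": 100.0 * h.identity,
                "length": h.aln_len,
                "qstart": h.q_start + 1,
                "qend": h.q_end,
                "sstart": h.s_start + 1 if h.strand == "+" else h.s_end,
                "send": h.s_end if h.strand == "+" else h.s_start + 1,
                "evalue": h.evalue,
                "bitscore": h.score,
            }
            for h in hits
        ]
    )


# ---------------------------------------------------------------------------
# clustering


@dataclass
class RedundancyCluster:
    member_ids: frozenset[str]
    representative_id: str
    notes: str = ""

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_redundant(
    hits: list[LocalHit],
    members: list[SeqRecord],
    origin_len: dict[str, int] | None = None,
) -> list[RedundancyCluster]:
    """Single-linkage connected components over the hit graph.

    Every member lands in exactly one cluster (singletons included). The
    representative is the longest member; ties prefer the member whose origin
    sequence is longest (``origin_len``, defaulting to the member's own
    length), then the lexicographically smallest id.
    """
    lengths = {r.id: len(r) for r in members}
    origin_len = origin_len or {}
    for h in hits:
        for i in (h.query_id, h.subject_id):
            if i not in lengths:
                raise ValueError(f"hit references unknown member {i!r}")
    uf = _UnionFind(lengths)
    for h in hits:
        uf.union(h.query_id, h.subject_id)
    groups: dict[str, list[str]] = defaultdict(list)
    for mid in lengths:
        groups[uf.find(mid)].append(mid)
    clusters = []
    for mids in groups.values():
        rep = min(
            mids,
            key=lambda m: (-lengths[m], -origin_len.get(m, lengths[m]), m),
        )
        clusters.append(
            RedundancyCluster(member_ids=frozenset(mids), representative_id=rep)
        )
    return sorted(clusters, key=lambda c: c.representative_id)
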