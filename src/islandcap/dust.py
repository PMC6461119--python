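"""Symmetric DUST (SDUST) low-complexity masking.

The masker annotates low-complexity tracts in lowercase, the convention the
rest of the pipeline reads as the mask channel. Masked bases stay *in* the
design space — masking affects probe scoring and the >=40 bp probe discard
rule, not space membership.

Scoring follows the symmetric-DUST statistic: for a nucleotide interval of
length L containing k = L - 2 overlapping triplets with counts c_t, the raw
score is N = sum_t c_t (c_t - 1) / 2 and the normalised score is N / (k - 1).
An interval (capped at ``window`` = 64 bp) is *high-scoring* when
10 * N > threshold * (k - 1) (the threshold is on the conventional 10x scale,
so the default 20 means normalised score > 2.0), and *perfect* when no proper
subinterval scores strictly higher. The mask is the union of all perfect
intervals. Because masking is symmetric in this sense, the result is
independent of scanning direction.

Score comparisons are done on exact integer cross-products, never floats, so
rational ties behave identically here and in any straightforward
re-implementation. Runs are split at non-ACGT characters; masking never
crosses an N.
"""

from __future__ import annotations

import numpy as np

DEFAULT_WINDOW = 64
DEFAULT_THRESHOLD = 20  # 10x-scaled normalised score

_TRIP_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _TRIP_CODE[ord(_b)] = _i
    _TRIP_CODE[ord(_b.lower())] = _i


def _mask_run(
    codes: np.ndarray, window: int, threshold: int
) -> list[tuple[int, int]]:
    """Perfect-interval union for one run of ACGT base codes (0..3)."""
    n = len(codes)
    if n < 7:  # shortest maskable interval needs >= 5 triplets
        return []
    trip = (codes[:-2] << 4) | (codes[1:-1] << 2) | codes[2:]
    t = len(trip)
    kmax = min(window - 2, t)  # triplet-window cap
    if kmax < 2:
        return []

    # m[d-1][p] = 1 if trip[p] == trip[p-d]; cumulative over d gives
    # F(p, j) = matches of trip[p] among the previous j triplets.
    F = np.zeros((kmax, t), dtype=np.int32)  # F[j][p], j = 0..kmax-1
    for d in range(1, kmax):
        eq = np.zeros(t, dtype=np.int32)
        eq[d:] = (trip[d:] == trip[:-d]).astype(np.int32)
        F[d] = F[d - 1] + eq

    masked = np.zeros(n + 1, dtype=np.int64)  # diff array over nucleotides

    # k = 2 layer: N_2[i] = [trip[i] == trip[i+1]]
    N = (trip[:-1] == trip[1:]).astype(np.int64)  # length t-1
    Mn = N.copy()  # running max score over subintervals, as Mn/Md
    Md = np.ones(t - 1, dtype=np.int64)

    for k in range(3, kmax + 1):
        den = k - 1
        # N_k[i] = N_{k-1}[i] + F(i+k-1, k-1) for i in [0, t-k]
        width = t - k + 1
        N = N[:width] + F[k - 1][k - 1 : k - 1 + width].astype(np.int64)
        # max over proper subintervals = max(M_{k-1}[i], M_{k-1}[i+1])
        left_n, left_d = Mn[:width], Md[:width]
        right_n, right_d = Mn[1 : width + 1], Md[1 : width + 1]
        use_right = right_n * left_d > left_n * right_d
        sub_n = np.where(use_right, right_n, left_n)
        sub_d = np.where(use_right, right_d, left_d)
        candidate = 10 * N > threshold * den
        perfect = candidate & (N * sub_d >= sub_n * den)
        for i in np.nonzero(perfect)[0]:
            masked[i] += 1
            masked[i + k + 2] -= 1
        # fold this layer into the running subinterval max
        better = N * sub_d > sub_n * den
        Mn = np.where(better, N, sub_n)
        Md = np.where(better, den, sub_d)

    cov = np.cumsum(masked[:-1]) > 0
    if not cov.any():
        return []
    edges = np.nonzero(np.diff(np.concatenate([[0], cov.view(np.int8), [0]])))[0]
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def sdust_intervals(
    seq: str, window: int = DEFAULT_WINDOW, threshold: int = DEFAULT_THRESHOLD
) -> list[tuple[int, int]]:
    """0-based half-open low-complexity intervals of ``seq``."""
    codes = _TRIP_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    out: list[tuple[int, int]] = []
    n = len(codes)
    start = 0
    while start < n:
        if codes[start] < 0:
            start += 1
            continue
        end = start
        while end < n and codes[end] >= 0:
            end += 1
        for s, e in _mask_run(codes[start:end], window, threshold):
            out.append((start + s, start + e))
        start = end
    return out


def mask_sequence(
    seq: str, window: int = DEFAULT_WINDOW, threshold: int = DEFAULT_THRESHOLD
) -> str:
    """Lowercase low-complexity tracts; existing lowercase is preserved."""
    intervals = sdust_intervals(seq, window, threshold)
    if not intervals:
        return seq
    chars = list(seq)
    for s, e in intervals:
        for i in range(s, e):
            chars[i] = chars[i].lower()
    return "".join(chars)
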