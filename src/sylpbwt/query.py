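"""Long-match query against a Syllable-PBWT index.

Given an out-of-panel query haplotype z and a cutoff L, report every maximal
agreement interval of at least L sites (or L cM) between z and any panel
haplotype, each exactly once, with single-site boundaries. The pipeline:

1.  encode the query into compressed syllable codes (a raw value absent from
    a column's dictionary gets the out-of-dictionary code |r_k|) and prefix
    hashes under the index's hash parameters;
2.  virtually insert z into every positional prefix array by binary search,
    giving its would-be position t_k at each syllable;
3.  sweep the syllables: any qualifying match must fully contain a window of
    w_k syllables ending at k, and all haplotypes whose window agrees with
    z's sit in a contiguous block around t_k, so scanning outward from t_k
    with hash comparisons finds them; running counters of ongoing matches
    above/below z skip previously found ones, so each maximal full-syllable
    run is emitted once;
4.  find each run's full syllabic extent (short linear probe on compressed
    codes, then hash binary search for the rare very long runs);
5.  refine boundaries to single sites by XOR-ing the raw boundary syllables,
    and keep the match iff its refined span reaches L.

In site mode w_k is the constant l = floor((L - B + 1) / B), valid whenever
L >= 2B - 1; in genetic-distance mode w_k is derived conservatively from the
map so that no qualifying match can slip between windows (see docs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ThresholdError
from .index import SyllabicIndex, prefix_hashes
from .panel import _pack_bits, decompress_syllable

__all__ = [
    "QueryEncoding",
    "VirtualCursor",
    "PotentialMatch",
    "Match",
    "min_full_syllables",
    "min_query_length_sites",
    "encode_query",
    "compare_reverse_prefix",
    "virtual_insert",
    "window_sizes",
    "scan_for_matches",
    "match_extent",
    "refine_match",
    "query_long_matches",
]

#: Syllables probed linearly before switching to hash binary search.
LINEAR_PROBE_DEPTH = 10


@dataclass
class QueryEncoding:
    """Query in syllabic form: raw values, compressed codes, prefix hashes."""

    z_raw: list  # length-n raw syllable values (python ints)
    z: np.ndarray  # length-n codes; |r_k| flags an out-of-dictionary syllable
    h: np.ndarray  # (n+1,) prefix hashes under the index's BASE/MOD

    def interval_hash(self, j: int, k: int, mod: int) -> int:
        return (int(self.h[k]) - int(self.h[j])) % mod


@dataclass
class VirtualCursor:
    """Virtual positions of the query in every positional prefix array.

    ``t[k]`` counts panel sequences whose reversed prefix over [0, k) sorts
    at or below the query's (the query sits below tied sequences).
    ``low_anchor[k]`` is the start syllable of the query's longest
    reverse-prefix match with the panel at syllable k; it is non-decreasing
    and bounds the binary searches at the next syllable from below.
    """

    t: np.ndarray
    low_anchor: np.ndarray


@dataclass(frozen=True)
class PotentialMatch:
    """A maximal full-syllable agreement run awaiting site-level refinement."""

    hap: int
    syl_start: int
    syl_end: int

    @property
    def span(self) -> int:
        return self.syl_end - self.syl_start


@dataclass(frozen=True)
class Match:
    """One reported long match, half-open on sites, 0-based."""

    hap: int
    start: int
    end: int
    length_cm: float | None = None

    @property
    def length_sites(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[int, int, int]:
        return (self.hap, self.start, self.end)


def min_full_syllables(L: int, B: int) -> int:
    """Minimum number of full syllables inside any L-site interval.

    An interval may end B-1 sites into a syllable without covering it, so the
    worst case leaves floor((L - B + 1) / B) full syllables. Requires
    L >= 2B - 1 (equivalently B <= ceil(L/2)) so the count is at least 1.
    """
    min_L = min_query_length_sites(B)
    if L < min_L:
        raise ThresholdError(
            f"L = {L} sites is below the minimum admissible cutoff for B = {B}: "
            f"all matches are guaranteed only for L >= {min_L} sites",
            min_length=min_L,
        )
    return (L - B + 1) // B


def min_query_length_sites(B: int) -> int:
    """Smallest L for which every L-long match is guaranteed found: 2B - 1."""
    if B < 1:
        raise InputError("syllable size B must be >= 1")
    return 2 * B - 1


def encode_query(raw_query, index: SyllabicIndex) -> QueryEncoding:
    """Syllabify and compress a query against the index's dictionaries."""
    q = np.asarray(raw_query)
    if q.ndim != 1 or q.size != index.N:
        raise InputError(f"query has {q.size} sites, panel has {index.N}")
    if not np.isin(q, (0, 1)).all():
        raise InputError("query contains a non-binary symbol")
    q = q.astype(np.uint8)
    B, n = index.B, index.n
    z_raw = []
    for k in range(n):
        v = _pack_bits(q[None, k * B : (k + 1) * B], B)[0]
        z_raw.append(int(v))
    z = np.empty(n, dtype=np.int64)
    for k, r in enumerate(index.panel.dictionaries):
        v = z_raw[k]
        if isinstance(r, np.ndarray):
            pos = int(np.searchsorted(r, np.uint64(v)))
            z[k] = pos if pos < len(r) and int(r[pos]) == v else len(r)
        else:
            import bisect

            pos = bisect.bisect_left(r, v)
            z[k] = pos if pos < len(r) and r[pos] == v else len(r)
    return QueryEncoding(z_raw=z_raw, z=z, h=prefix_hashes(z, index.powers, index.mod))


def compare_reverse_prefix(
    z_enc: QueryEncoding, index: SyllabicIndex, i: int, k: int, lo: int = 0
):
    """Order the query's reversed prefix [0, k) against panel sequence i.

    Returns ``(cmp, b)`` with cmp in {-1, 0, +1} (query relative to the
    sequence) and b the most significant differing syllable (None if equal).
    Syllable k-1 is compared directly; any remaining difference is located by
    a hash binary search for the largest differing b in [lo, k-1). ``lo``
    must under-approximate the start of the query's longest reverse-prefix
    match, which makes hash equality over [lo, k) equivalent to full
    equality over [0, k).
    """
    z, comp, mod = z_enc.z, index.panel.compressed, index.mod
    if k == 0:
        return 0, None
    zk, xk = int(z[k - 1]), int(comp[i, k - 1])
    if zk != xk:
        return (-1 if zk < xk else 1), k - 1
    end = k - 1
    if z_enc.interval_hash(lo, end, mod) == index.seq_interval_hash(i, lo, end):
        return 0, None
    # Smallest m in (lo, end] with agreement over [m, end); b = m - 1.
    lo_s, hi_s = lo, end
    while hi_s - lo_s > 1:
        mid = (lo_s + hi_s) // 2
        if z_enc.interval_hash(mid, end, mod) == index.seq_interval_hash(i, mid, end):
            hi_s = mid
        else:
            lo_s = mid
    b = hi_s - 1
    return (-1 if int(z[b]) < int(comp[i, b]) else 1), b


def virtual_insert(z_enc: QueryEncoding, index: SyllabicIndex) -> VirtualCursor:
    """Compute the query's virtual position in every positional prefix array."""
    M, n, a = index.M, index.n, index.a
    t = np.empty(n + 1, dtype=np.int64)
    anchor = np.empty(n + 1, dtype=np.int64)
    t[0] = M  # empty prefixes all tie; the query sits below ties
    anchor[0] = 0
    s_prev = 0
    for k in range(1, n + 1):
        lo = max(s_prev - 1, 0)
        lo_p, hi_p = 0, M
        while lo_p < hi_p:
            mid = (lo_p + hi_p) // 2
            cmp, _ = compare_reverse_prefix(z_enc, index, int(a[k, mid]), k, lo)
            if cmp >= 0:
                lo_p = mid + 1
            else:
                hi_p = mid
        t[k] = lo_p
        # Longest reverse-prefix match start: attained at a sorted neighbour.
        s = k
        for pos in (lo_p - 1, lo_p):
            if 0 <= pos < M:
                cmp, b = compare_reverse_prefix(z_enc, index, int(a[k, pos]), k, lo)
                s = min(s, 0 if cmp == 0 else b + 1)
        s_prev = s
        anchor[k] = s
    return VirtualCursor(t=t, low_anchor=anchor)


def window_sizes(index: SyllabicIndex, L, mode: str = "sites") -> list:
    """Per-syllable detection window sizes w_1..w_n (index 0 unused).

    Site mode: the constant l = floor((L - B + 1) / B). Genetic-distance
    mode: w_k is the smallest w >= 1 such that even a match containing only
    the w full syllables [k-w, k) — maximally extended into the two flanking
    partial syllables — spans at least L cM; None marks windows that can
    never qualify (no test at that syllable).
    """
    if mode not in ("sites", "cm"):
        raise InputError(f"unknown length mode {mode!r}")
    n, B, N = index.n, index.B, index.N
    if mode == "sites":
        L = int(L)
        w = min_full_syllables(L, B)
        return [None] + [w] * n
    g = index.positions
    if g is None:
        raise InputError("genetic-distance query requires a genetic map")
    out: list = [None]
    for k in range(1, n + 1):
        right = g[min(k * B + B - 2, N - 1)]

        def span(wk: int) -> float:
            return right - g[max((k - wk) * B - (B - 1), 0)]

        if span(k) < L:
            out.append(None)
            continue
        lo, hi = 1, k  # span(hi) >= L; find smallest sufficient w
        while lo < hi:
            mid = (lo + hi) // 2
            if span(mid) >= L:
                hi = mid
            else:
                lo = mid + 1
        out.append(lo)
    return out


def match_extent(
    z_enc: QueryEncoding, i: int, k: int, index: SyllabicIndex
) -> int:
    """Largest m <= n with query/sequence agreement over syllables [k, m).

    Probes the compressed codes linearly for a few syllables; exceptionally
    long runs fall back to a hash binary search.
    """
    comp, z, n, mod = index.panel.compressed, z_enc.z, index.n, index.mod
    m = k
    steps = 0
    while m < n and steps < LINEAR_PROBE_DEPTH:
        if int(z[m]) != int(comp[i, m]):
            return m
        m += 1
        steps += 1
    if m == n:
        return n
    # Largest e in [m, n] with agreement over [m, e).
    lo, hi = m, n
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if z_enc.interval_hash(m, mid, mod) == index.seq_interval_hash(i, m, mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _extent_left(z_enc: QueryEncoding, i: int, b: int, index: SyllabicIndex) -> int:
    """Smallest b0 <= b with agreement over syllables [b0, b); mirror of match_extent."""
    comp, z, mod = index.panel.compressed, z_enc.z, index.mod
    steps = 0
    while b > 0 and steps < LINEAR_PROBE_DEPTH:
        if int(z[b - 1]) != int(comp[i, b - 1]):
            return b
        b -= 1
        steps += 1
    if b == 0:
        return 0
    lo, hi = 0, b
    while lo < hi:
        mid = (lo + hi) // 2
        if z_enc.interval_hash(mid, b, mod) == index.seq_interval_hash(i, mid, b):
            hi = mid
        else:
            lo = mid + 1
    return lo


def scan_for_matches(
    z_enc: QueryEncoding,
    cursor: VirtualCursor,
    index: SyllabicIndex,
    w: list,
    scout: bool = False,
) -> list[PotentialMatch]:
    """Sweep the syllables, emitting each maximal qualifying run exactly once.

    At syllable k the haplotypes whose last w_k syllables agree with the
    query form a contiguous block around its virtual position t_k; running
    counters of ongoing matches above/below skip runs already emitted, and
    per-syllable end tallies retire them one syllable after they close.
    With ``scout=True`` the far end of each new block is located by binary
    search before iterating (identical output, fewer hash comparisons when
    blocks are large).
    """
    a, M, n, mod = index.a, index.M, index.n, index.mod
    t = cursor.t
    up_end = [0] * (n + 2)
    down_end = [0] * (n + 2)
    up_on = down_on = 0
    found: list[PotentialMatch] = []

    def window_match(p: int, k: int, wk: int, hz: int) -> bool:
        return index.seq_interval_hash(int(a[k, p]), k - wk, k) == hz

    def emit(p: int, k: int, wk: int) -> PotentialMatch:
        hap = int(a[k, p])
        b = _extent_left(z_enc, hap, k - wk, index)
        e = match_extent(z_enc, hap, k, index)
        pm = PotentialMatch(hap=hap, syl_start=b, syl_end=e)
        found.append(pm)
        return pm

    for k in range(1, n + 1):
        up_on -= up_end[k]
        down_on -= down_end[k]
        wk = w[k]
        if wk is None or wk > k:
            continue
        hz = z_enc.interval_hash(k - wk, k, mod)

        p = int(t[k]) - 1 - up_on
        if scout and p >= 0 and window_match(p, k, wk, hz):
            lo, hi = 0, p  # smallest block position still matching
            while lo < hi:
                mid = (lo + hi) // 2
                if window_match(mid, k, wk, hz):
                    hi = mid
                else:
                    lo = mid + 1
            for q in range(p, lo - 1, -1):
                pm = emit(q, k, wk)
                up_end[pm.syl_end + 1] += 1
                up_on += 1
        else:
            while p >= 0 and window_match(p, k, wk, hz):
                pm = emit(p, k, wk)
                up_end[pm.syl_end + 1] += 1
                up_on += 1
                p -= 1

        p = int(t[k]) + down_on
        if scout and p < M and window_match(p, k, wk, hz):
            lo, hi = p, M - 1  # largest block position still matching
            while lo < hi:
                mid = (lo + hi + 1) // 2
                if window_match(mid, k, wk, hz):
                    lo = mid
                else:
                    hi = mid - 1
            for q in range(p, lo + 1):
                pm = emit(q, k, wk)
                down_end[pm.syl_end + 1] += 1
                down_on += 1
        else:
            while p < M and window_match(p, k, wk, hz):
                pm = emit(p, k, wk)
                down_end[pm.syl_end + 1] += 1
                down_on += 1
                p += 1
    return found


def refine_match(
    pm: PotentialMatch,
    z_raw: list,
    index: SyllabicIndex,
    L,
    mode: str = "sites",
) -> Match | None:
    """Sharpen a full-syllable run to site resolution; filter on length L.

    The boundary syllables' raw values are XOR-ed: the highest set bit left
    of the run and the lowest set bit right of it pinpoint the flanking
    mismatches. The right boundary is clamped to N (padded tail bits are
    zero on both sides, so they never differ, but the clamp keeps the
    contract explicit).
    """
    B, N, n = index.B, index.N, index.n
    X = index.panel
    b, e, i = pm.syl_start, pm.syl_end, pm.hap
    if b == 0:
        start = 0
    else:
        d = z_raw[b - 1] ^ decompress_syllable(X, i, b - 1)
        start = (b - 1) * B + (d.bit_length() - 1) + 1
    if e == n:
        end = N
    else:
        d = z_raw[e] ^ decompress_syllable(X, i, e)
        end = min(e * B + ((d & -d).bit_length() - 1), N)
    if mode == "sites":
        if end - start < L:
            return None
        return Match(hap=i, start=start, end=end)
    g = index.positions
    cm = float(g[end - 1] - g[start])
    if cm < L:
        return None
    return Match(hap=i, start=start, end=end, length_cm=cm)


def query_long_matches(
    index: SyllabicIndex,
    raw_query,
    L,
    mode: str = "sites",
    scout: bool = False,
    stats: dict | None = None,
) -> list[Match]:
    """Find all L-long matches between a query haplotype and the panel.

    Returns Match records sorted by (haplotype, start), each maximal
    agreement interval of at least L sites (mode "sites") or L cM
    (mode "cm", requires the index to carry a genetic map) reported once.
    ``stats``, if given, receives the potential/reported match counts.
    """
    w = window_sizes(index, L, mode)
    z_enc = encode_query(raw_query, index)
    cursor = virtual_insert(z_enc, index)
    potentials = scan_for_matches(z_enc, cursor, index, w, scout=scout)
    matches = []
    for pm in potentials:
        m = refine_match(pm, z_enc.z_raw, index, L, mode)
        if m is not None:
            matches.append(m)
    matches.sort(key=Match.key)
    if stats is not None:
        stats["potential"] = len(potentials)
        stats["reported"] = len(matches)
    return matches
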