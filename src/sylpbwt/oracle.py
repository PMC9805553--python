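"""Brute-force reference matcher.

Scans raw alleles site by site, with no syllables, hashes or prefix arrays,
so it cannot share a systematic defect with the main engine. Quadratic in
panel size; intended for correctness testing and `--verify` cross-checks,
not production querying.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .panel import HaplotypePanel
from .query import Match

__all__ = ["naive_long_matches"]


def naive_long_matches(
    panel: HaplotypePanel, raw_query, L, mode: str = "sites"
) -> list[Match]:
    """All L-long matches between a query and every panel haplotype.

    For each haplotype, collects the maximal agreement runs with the query
    and keeps those spanning at least L sites (mode "sites") or whose first
    and last matched sites lie at least L cM apart (mode "cm"). Sorted by
    (haplotype, start).
    """
    if mode not in ("sites", "cm"):
        raise InputError(f"unknown length mode {mode!r}")
    q = np.asarray(raw_query)
    if q.ndim != 1 or q.size != panel.N:
        raise InputError(f"query has {q.size} sites, panel has {panel.N}")
    if not np.isin(q, (0, 1)).all():
        raise InputError("query contains a non-binary symbol")
    g = panel.positions
    if mode == "cm" and g is None:
        raise InputError("genetic-distance query requires a genetic map")

    matches: list[Match] = []
    q = q.astype(np.uint8)
    for i in range(panel.M):
        agree = panel.alleles[i] == q
        edges = np.diff(np.concatenate(([0], agree.view(np.uint8), [0])).astype(np.int8))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for b, e in zip(starts, ends):
            b, e = int(b), int(e)
            if mode == "sites":
                if e - b >= L:
                    matches.append(Match(hap=i, start=b, end=e))
            else:
                cm = float(g[e - 1] - g[b])
                if cm >= L:
                    matches.append(Match(hap=i, start=b, end=e, length_cm=cm))
    matches.sort(key=Match.key)
    return matches
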