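"""Syllable-PBWT index: positional prefix arrays, prefix hashes, persistence.

The index over a syllabic panel X consists of

* ``a_0 .. a_n`` — positional prefix arrays: ``a_k`` permutes 0..M-1 so that
  the reversed prefixes ``x_i[0, k)`` (syllable k-1 most significant) appear
  in non-decreasing lexicographic order, ties in input order (``a_0`` is the
  identity). ``a_{k+1}`` follows from ``a_k`` by one stable sort on the
  column ``x_.[k]``, whose keys are bounded by |r_k| <= M.
* ``h_0 .. h_{M-1}`` — polynomial prefix hash arrays,
  ``h_i[k] = sum_{j<k} (x_i[j] + 1) * BASE^j mod MOD``, which replace the
  classic divergence/virtual-extension arrays: two sequences agree on a
  syllable interval [j, k) iff their interval hashes
  ``(h[k] - h[j]) mod MOD`` agree (up to a collision probability of about
  (k - j)/MOD per comparison).

MOD is the Mersenne prime 2^61 - 1, so hashes fit 64-bit words; BASE is
drawn uniformly from [2^20, MOD-2] from a stored seed and persisted with the
index so query-time hashes use identical parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import IndexIOError, InputError
from .panel import HaplotypePanel, SyllabicPanel, build_syllabic_panel

__all__ = [
    "MOD",
    "SyllabicIndex",
    "HashInterval",
    "draw_base",
    "build_prefix_arrays",
    "prefix_hashes",
    "build_hash_arrays",
    "interval_hash",
    "build_index",
    "save_index",
    "load_index",
]

#: Hash modulus: the Mersenne prime 2^61 - 1 (hash values fit in 64 bits).
MOD = (1 << 61) - 1

_MAGIC = b"SYLPBWTI"
_VERSION = 1


@dataclass(frozen=True)
class HashInterval:
    """Hash of one positional substring over syllables [lo, hi).

    Equality is only meaningful between intervals with identical (lo, hi).
    """

    value: int
    lo: int
    hi: int


def draw_base(seed: int) -> int:
    """Draw the hash BASE uniformly from [2^20, MOD-2], deterministically."""
    rng = np.random.default_rng(seed)
    return int(rng.integers(1 << 20, MOD - 1))


def build_prefix_arrays(X: SyllabicPanel) -> np.ndarray:
    """All positional prefix arrays, as an (n+1, M) int32 matrix.

    Row k lists haplotype indices by ascending reversed prefix x[0, k);
    each row follows from the previous by one stable sort keyed on the
    compressed column, so ties keep input-index order throughout.
    """
    a = np.empty((X.n + 1, X.M), dtype=np.int32)
    a[0] = np.arange(X.M, dtype=np.int32)
    for k in range(X.n):
        keys = X.compressed[a[k], k]
        a[k + 1] = a[k][np.argsort(keys, kind="stable")]
    return a


def prefix_hashes(codes, powers: list[int], mod: int = MOD) -> np.ndarray:
    """Prefix hash array of one code sequence; h[0] = 0, len(codes)+1 entries."""
    h = np.empty(len(codes) + 1, dtype=np.uint64)
    h[0] = 0
    acc = 0
    for k, c in enumerate(codes):
        acc = (acc + (int(c) + 1) * powers[k]) % mod
        h[k + 1] = acc
    return h


def _power_table(base: int, n: int, mod: int = MOD) -> list[int]:
    powers = [1] * (n + 1)
    for k in range(1, n + 1):
        powers[k] = powers[k - 1] * base % mod
    return powers


def build_hash_arrays(X: SyllabicPanel, base: int, mod: int = MOD) -> np.ndarray:
    """Prefix hash arrays for every panel sequence, (M, n+1) uint64."""
    if not (2 <= base < mod):
        raise InputError("hash BASE must satisfy 2 <= BASE < MOD")
    powers = _power_table(base, X.n, mod)
    h = np.empty((X.M, X.n + 1), dtype=np.uint64)
    for i in range(X.M):
        h[i] = prefix_hashes(X.compressed[i], powers, mod)
    return h


def interval_hash(h_i: np.ndarray, j: int, k: int, mod: int = MOD) -> HashInterval:
    """Hash of the positional substring over syllables [j, k)."""
    if j > k:
        raise InputError(f"invalid hash interval [{j}, {k})")
    return HashInterval(value=(int(h_i[k]) - int(h_i[j])) % mod, lo=j, hi=k)


@dataclass
class SyllabicIndex:
    """The persisted Syllable-PBWT: compressed panel, a-arrays, hash arrays."""

    panel: SyllabicPanel
    a: np.ndarray  # (n+1, M) int32
    h: np.ndarray  # (M, n+1) uint64
    base: int
    mod: int
    hash_seed: int
    powers: list[int]  # BASE^k mod MOD for 0 <= k <= n
    positions: np.ndarray | None = None
    hap_ids: list[str] | None = None

    @property
    def M(self) -> int:
        return self.panel.M

    @property
    def N(self) -> int:
        return self.panel.N

    @property
    def B(self) -> int:
        return self.panel.B

    @property
    def n(self) -> int:
        return self.panel.n

    def seq_interval_hash(self, i: int, j: int, k: int) -> int:
        """Interval-hash value of panel sequence i over syllables [j, k)."""
        return (int(self.h[i, k]) - int(self.h[i, j])) % self.mod

    def hap_id(self, i: int) -> str:
        return self.hap_ids[i] if self.hap_ids is not None else str(i)


def build_index(
    panel: HaplotypePanel, B: int, hash_seed: int = 0
) -> SyllabicIndex:
    """Build the full Syllable-PBWT index over a haplotype panel."""
    X = build_syllabic_panel(panel, B)
    base = draw_base(hash_seed)
    a = build_prefix_arrays(X)
    h = build_hash_arrays(X, base)
    return SyllabicIndex(
        panel=X,
        a=a,
        h=h,
        base=base,
        mod=MOD,
        hash_seed=hash_seed,
        powers=_power_table(base, X.n),
        positions=None if panel.positions is None else panel.positions.copy(),
        hap_ids=list(panel.ids) if panel.ids is not None else None,
    )


# ---------------------------------------------------------------------------
# Persistence: a single deterministic, versioned, checksummed container.
# Layout: MAGIC | meta length (8 bytes LE) | meta JSON | raw array payload.
# The payload concatenates little-endian array bytes in a fixed order; its
# SHA-256 is stored in the meta and verified on load. No timestamps, so
# identical inputs yield byte-identical files.
# ---------------------------------------------------------------------------


def _dict_words(X: SyllabicPanel) -> tuple[np.ndarray, np.ndarray, int]:
    """Flatten the ragged dictionaries into (values, offsets, words-per-value)."""
    nwords = max(1, -(-X.B // 64))
    offsets = np.zeros(X.n + 1, dtype=np.int64)
    rows = []
    for k, r in enumerate(X.dictionaries):
        offsets[k + 1] = offsets[k] + len(r)
        for v in r:
            v = int(v)
            rows.append([(v >> (64 * w)) & 0xFFFFFFFFFFFFFFFF for w in range(nwords)])
    values = np.array(rows, dtype=np.uint64).reshape(-1, nwords)
    return values, offsets, nwords


def _words_to_dicts(values: np.ndarray, offsets: np.ndarray, B: int) -> list:
    nwords = values.shape[1]
    dicts = []
    for k in range(len(offsets) - 1):
        block = values[offsets[k] : offsets[k + 1]]
        if B <= 64:
            dicts.append(block[:, 0].astype(np.uint64))
        else:
            dicts.append(
                [
                    sum(int(row[w]) << (64 * w) for w in range(nwords))
                    for row in block
                ]
            )
    return dicts


def save_index(index: SyllabicIndex, path) -> None:
    """Persist the index; ``load_index`` restores it bit-exactly."""
    X = index.panel
    dict_values, dict_offsets, nwords = _dict_words(X)
    arrays = [
        np.ascontiguousarray(X.compressed, dtype="<i4"),
        np.ascontiguousarray(dict_values, dtype="<u8"),
        np.ascontiguousarray(dict_offsets, dtype="<i8"),
        np.ascontiguousarray(index.a, dtype="<i4"),
        np.ascontiguousarray(index.h, dtype="<u8"),
        np.ascontiguousarray(np.array(index.powers, dtype=np.uint64), dtype="<u8"),
    ]
    if index.positions is not None:
        arrays.append(np.ascontiguousarray(index.positions, dtype="<f8"))
    payload = b"".join(arr.tobytes() for arr in arrays)
    meta = {
        "format": "sylpbwt-index",
        "version": _VERSION,
        "M": X.M,
        "N": X.N,
        "B": X.B,
        "n": X.n,
        "base": index.base,
        "mod": index.mod,
        "hash_seed": index.hash_seed,
        "dict_total": int(dict_offsets[-1]),
        "dict_words": nwords,
        "has_positions": index.positions is not None,
        "hap_ids": index.hap_ids,
        "checksum": hashlib.sha256(payload).hexdigest(),
    }
    meta_bytes = json.dumps(meta, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(meta_bytes).to_bytes(8, "little"))
        fh.write(meta_bytes)
        fh.write(payload)


def load_index(path) -> SyllabicIndex:
    """Load a persisted index, verifying magic, version and checksum."""
    path = Path(path)
    if not path.is_file():
        raise IndexIOError(f"index file not found: {path}")
    blob = path.read_bytes()
    if len(blob) < len(_MAGIC) + 8 or blob[: len(_MAGIC)] != _MAGIC:
        raise IndexIOError(f"{path} is not a sylpbwt index file")
    off = len(_MAGIC)
    meta_len = int.from_bytes(blob[off : off + 8], "little")
    off += 8
    try:
        meta = json.loads(blob[off : off + meta_len])
    except json.JSONDecodeError as exc:
        raise IndexIOError(f"corrupt index metadata in {path}") from exc
    off += meta_len
    if meta.get("version") != _VERSION:
        raise IndexIOError(
            f"index version {meta.get('version')} unsupported (expected {_VERSION})"
        )
    payload = blob[off:]
    if hashlib.sha256(payload).hexdigest() != meta["checksum"]:
        raise IndexIOError(f"checksum mismatch in {path} (truncated or corrupt)")

    M, N, B, n = meta["M"], meta["N"], meta["B"], meta["n"]
    total, nwords = meta["dict_total"], meta["dict_words"]
    sizes = [
        M * n * 4,
        total * nwords * 8,
        (n + 1) * 8,
        (n + 1) * M * 4,
        M * (n + 1) * 8,
        (n + 1) * 8,
    ]
    if meta["has_positions"]:
        sizes.append(N * 8)
    if len(payload) != sum(sizes):
        raise IndexIOError(f"index payload size mismatch in {path}")
    views, pos = [], 0
    for size in sizes:
        views.append(payload[pos : pos + size])
        pos += size
    compressed = np.frombuffer(views[0], dtype="<i4").reshape(M, n).astype(np.int32)
    dict_values = (
        np.frombuffer(views[1], dtype="<u8").reshape(total, nwords).astype(np.uint64)
    )
    dict_offsets = np.frombuffer(views[2], dtype="<i8").astype(np.int64)
    a = np.frombuffer(views[3], dtype="<i4").reshape(n + 1, M).astype(np.int32)
    h = np.frombuffer(views[4], dtype="<u8").reshape(M, n + 1).astype(np.uint64)
    powers = [int(v) for v in np.frombuffer(views[5], dtype="<u8")]
    positions = (
        np.frombuffer(views[6], dtype="<f8").astype(np.float64)
        if meta["has_positions"]
        else None
    )
    X = SyllabicPanel(
        B=B,
        M=M,
        N=N,
        n=n,
        compressed=compressed,
        dictionaries=_words_to_dicts(dict_values, dict_offsets, B),
    )
    return SyllabicIndex(
        panel=X,
        a=a,
        h=h,
        base=meta["base"],
        mod=meta["mod"],
        hash_seed=meta["hash_seed"],
        powers=powers,
        positions=positions,
        hap_ids=meta["hap_ids"],
    )
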