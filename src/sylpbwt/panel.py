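"""Binary haplotype panels and their syllabic representation.

A panel of M phased, bi-allelic haplotypes over N aligned sites is recoded
in blocks ("syllables") of B consecutive sites. Within a syllable, the
allele at site k*B + j occupies bit j of an unsigned integer (earliest site
in the least-significant bit), and the final syllable is zero-padded past
site N. Because linkage disequilibrium makes local haplotypes repetitive,
the distinct raw syllable values at any one syllable column number far fewer
than M; coordinate compression maps them to dense ranks through a sorted
per-column dictionary, losslessly and reversibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = [
    "HaplotypePanel",
    "SyllabicPanel",
    "syllabify_panel",
    "build_syllabic_panel",
    "compress_column",
    "decompress_syllable",
    "compression_ratio",
    "reconstruct_alleles",
]


@dataclass
class HaplotypePanel:
    """M aligned binary haplotype sequences of N sites each.

    Parameters
    ----------
    alleles
        (M, N) matrix of 0/1 values.
    positions
        Optional length-N non-decreasing genetic coordinates (cM). Required
        for genetic-distance queries.
    ids
        Optional per-haplotype identifiers (e.g. ``sample/0``); defaults to
        the row index rendered as a string.
    """

    alleles: np.ndarray
    positions: np.ndarray | None = None
    ids: list[str] | None = field(default=None)

    def __post_init__(self):
        alleles = np.asarray(self.alleles)
        if alleles.ndim != 2 or alleles.shape[0] < 1 or alleles.shape[1] < 1:
            raise InputError("panel must be a non-empty M x N matrix")
        if alleles.dtype != np.uint8:
            if not np.isin(alleles, (0, 1)).all():
                raise InputError("panel contains a non-binary allele value")
            alleles = alleles.astype(np.uint8)
        elif alleles.max(initial=0) > 1:
            raise InputError("panel contains a non-binary allele value")
        self.alleles = alleles
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=np.float64)
            if pos.shape != (self.N,):
                raise InputError(
                    f"genetic positions have length {pos.size}, expected {self.N}"
                )
            if pos.size > 1 and np.any(np.diff(pos) < 0):
                raise InputError("genetic positions must be non-decreasing")
            self.positions = pos
        if self.ids is not None and len(self.ids) != self.M:
            raise InputError("haplotype id list does not match panel size")

    @property
    def M(self) -> int:
        return self.alleles.shape[0]

    @property
    def N(self) -> int:
        return self.alleles.shape[1]

    def hap_id(self, i: int) -> str:
        return self.ids[i] if self.ids is not None else str(i)


@dataclass
class SyllabicPanel:
    """Coordinate-compressed syllabic panel with per-column dictionaries.

    ``compressed[i, k]`` is the rank of haplotype i's raw value at syllable k
    in the strictly increasing dictionary ``dictionaries[k]``; the raw matrix
    is reconstructible as ``dictionaries[k][compressed[i, k]]``.
    """

    B: int
    M: int
    N: int
    n: int
    compressed: np.ndarray  # (M, n) int32 ranks
    dictionaries: list  # per-syllable sorted raw values (uint64 array or int list)

    def dict_entries(self) -> int:
        """Total number of dictionary entries, sum_k |r_k|."""
        return sum(len(r) for r in self.dictionaries)


def _pack_bits(bits: np.ndarray, B: int):
    """Pack an (M, b) 0/1 block (b <= B) into per-row integers, bit j = site j."""
    m, b = bits.shape
    if b < B:
        bits = np.pad(bits, ((0, 0), (0, B - b)))
    packed = np.packbits(bits, axis=1, bitorder="little")  # (M, ceil(B/8)) uint8
    if B <= 64:
        buf = np.zeros((m, 8), dtype=np.uint8)
        buf[:, : packed.shape[1]] = packed
        return buf.view("<u8").ravel()
    # Wider syllables: arbitrary-precision Python integers.
    return np.array(
        [int.from_bytes(row.tobytes(), "little") for row in packed], dtype=object
    )


def _raw_column(alleles: np.ndarray, k: int, B: int):
    return _pack_bits(alleles[:, k * B : (k + 1) * B], B)


def syllabify_panel(panel: HaplotypePanel, B: int):
    """Return the (M, n) raw syllable matrix, n = ceil(N/B).

    raw[i, k] = sum_{0<=j<B, kB+j<N} allele(i, kB+j) * 2**j, with the trailing
    syllable zero-padded. Values are uint64 for B <= 64, Python ints otherwise.
    """
    if B < 1:
        raise InputError("syllable size B must be >= 1")
    n = -(-panel.N // B)
    cols = [_raw_column(panel.alleles, k, B) for k in range(n)]
    dtype = np.uint64 if B <= 64 else object
    return np.stack(cols, axis=1).astype(dtype, copy=False)


def compress_column(raw_column):
    """Coordinate-compress one syllable column.

    Returns ``(r_k, compressed)`` where ``r_k`` is the strictly increasing
    dictionary of distinct raw values and ``compressed[i]`` the rank of
    ``raw_column[i]`` in it.
    """
    raw_column = np.asarray(raw_column)
    if raw_column.size == 0:
        raise InputError("cannot compress an empty column")
    if raw_column.dtype == object:
        r = sorted({int(v) for v in raw_column})
        rank = {v: idx for idx, v in enumerate(r)}
        comp = np.array([rank[int(v)] for v in raw_column], dtype=np.int32)
        return r, comp
    r, comp = np.unique(raw_column, return_inverse=True)
    return r, comp.astype(np.int32)


def build_syllabic_panel(panel: HaplotypePanel, B: int) -> SyllabicPanel:
    """Syllabify and compress a panel column by column.

    Raw columns are packed, compressed and discarded one at a time, so the
    full raw matrix is never resident.
    """
    if B < 1:
        raise InputError("syllable size B must be >= 1")
    n = -(-panel.N // B)
    compressed = np.empty((panel.M, n), dtype=np.int32)
    dictionaries = []
    for k in range(n):
        r, comp = compress_column(_raw_column(panel.alleles, k, B))
        dictionaries.append(r)
        compressed[:, k] = comp
    return SyllabicPanel(
        B=B, M=panel.M, N=panel.N, n=n, compressed=compressed, dictionaries=dictionaries
    )


def decompress_syllable(X: SyllabicPanel, i: int, k: int) -> int:
    """Raw B-bit value of haplotype i at syllable k, via dictionary lookup."""
    if not (0 <= i < X.M and 0 <= k < X.n):
        raise IndexError(f"syllable access ({i}, {k}) outside ({X.M}, {X.n})")
    return int(X.dictionaries[k][X.compressed[i, k]])


def compression_ratio(X: SyllabicPanel) -> float:
    """rho = M*n / sum_k |r_k|; equals 1 with no repetition, M when all rows tie."""
    return X.M * X.n / X.dict_entries()


def reconstruct_alleles(X: SyllabicPanel) -> np.ndarray:
    """Invert syllabification: rebuild the (M, N) 0/1 allele matrix exactly."""
    nbytes = (X.B + 7) // 8
    out = np.empty((X.M, X.n * X.B), dtype=np.uint8)
    for k, r in enumerate(X.dictionaries):
        values = np.asarray(r, dtype=object)[X.compressed[:, k]]
        rows = np.frombuffer(
            b"".join(int(v).to_bytes(nbytes, "little") for v in values),
            dtype=np.uint8,
        ).reshape(X.M, nbytes)
        bits = np.unpackbits(rows, axis=1, bitorder="little")
        out[:, k * X.B : (k + 1) * X.B] = bits[:, : X.B]
    return out[:, : X.N]
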