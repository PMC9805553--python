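"""File I/O: phased VCF panels, 0/1 matrix text, genetic maps, match reports.

All coordinates in files are 0-based and half-open. Panels are strictly
phased and bi-allelic; anything else is a hard error naming the offending
record — silent coercion would corrupt downstream match coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .errors import InputError
from .panel import HaplotypePanel
from .query import Match

__all__ = [
    "MatchReport",
    "read_vcf_panel",
    "read_matrix_panel",
    "write_matrix_panel",
    "read_genetic_map",
    "write_matches",
]

_REPORT_HEADER = "#query_id\thap_id\tstart\tend\tn_sites\tcm"


@dataclass
class MatchReport:
    """Matches for one query, reported against haplotype identifiers."""

    query_id: str
    matches: list[Match]


def read_vcf_panel(path) -> HaplotypePanel:
    """Read a phased, bi-allelic diploid VCF into a haplotype panel.

    Each sample contributes haplotypes ``<sample>/0`` and ``<sample>/1`` in
    file order. Genetic positions are not taken from the VCF; attach them
    from a genetic-map side channel.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise InputError(f"{path}: VCF has no samples")
    columns = []
    for rec in vcf:
        where = f"{rec.chrom}:{rec.pos}"
        if rec.alts is None or len(rec.alts) != 1:
            raise InputError(f"{path}: record {where} is not bi-allelic")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for s_idx, sample in enumerate(samples):
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or any(al is None for al in gt):
                raise InputError(f"{path}: missing GT at {where} for {sample}")
            if len(gt) != 2:
                raise InputError(f"{path}: non-diploid GT at {where} for {sample}")
            if not call.phased:
                raise InputError(f"{path}: unphased GT at {where} for {sample}")
            if any(al not in (0, 1) for al in gt):
                raise InputError(f"{path}: non-binary allele at {where} for {sample}")
            col[2 * s_idx] = gt[0]
            col[2 * s_idx + 1] = gt[1]
        columns.append(col)
    if not columns:
        raise InputError(f"{path}: no sites in VCF body")
    alleles = np.stack(columns, axis=1)
    ids = [f"{s}/{j}" for s in samples for j in (0, 1)]
    return HaplotypePanel(alleles=alleles, ids=ids)


def read_matrix_panel(path) -> HaplotypePanel:
    """Read a plain text panel: one haplotype per line, characters 0/1."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if set(line) - {"0", "1"}:
                raise InputError(f"{path}:{lineno}: non-binary character in panel row")
            if width is None:
                width = len(line)
            elif len(line) != width:
                raise InputError(
                    f"{path}:{lineno}: ragged row ({len(line)} sites, expected {width})"
                )
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if not rows:
        raise InputError(f"{path}: empty panel file")
    return HaplotypePanel(alleles=np.stack(rows))


def write_matrix_panel(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        for row in panel.alleles:
            fh.write("".join("01"[v] for v in row) + "\n")


def read_genetic_map(path, n_sites: int | None = None) -> np.ndarray:
    """Read a two-column map: 0-based site index, non-decreasing cM position."""
    positions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise InputError(f"{path}:{lineno}: expected two columns")
            try:
                idx, pos = int(fields[0]), float(fields[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: unparsable map row") from exc
            if idx != len(positions):
                raise InputError(
                    f"{path}:{lineno}: site index {idx}, expected {len(positions)}"
                )
            if positions and pos < positions[-1]:
                raise InputError(f"{path}:{lineno}: decreasing genetic position")
            positions.append(pos)
    if not positions:
        raise InputError(f"{path}: empty genetic map")
    if n_sites is not None and len(positions) != n_sites:
        raise InputError(
            f"{path}: map has {len(positions)} rows, panel has {n_sites} sites"
        )
    return np.asarray(positions, dtype=np.float64)


def write_matches(reports, path, hap_id=str) -> None:
    """Write match reports as TSV: one row per match, 0-based half-open.

    ``hap_id`` maps a panel haplotype index to its identifier. Rows within a
    report are sorted by (haplotype id column order is discovery-independent:
    the underlying matches are sorted by haplotype index, then start).
    """
    with open(path, "w") as fh:
        fh.write(_REPORT_HEADER + "\n")
        for report in reports:
            for m in sorted(report.matches, key=Match.key):
                cm = "" if m.length_cm is None else f"{m.length_cm:.6f}"
                fh.write(
                    f"{report.query_id}\t{hap_id(m.hap)}\t{m.start}\t{m.end}"
                    f"\t{m.length_sites}\t{cm}\n"
                )
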