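"""Synthetic panels, queries and genetic maps for self-contained testing.

The panel generator is a mosaic-of-founders model: a handful of founder
haplotypes drawn i.i.d. Bernoulli(0.5), each panel haplotype copying one
founder at a time and switching its copy source with a small per-site
probability, plus rare per-site flips. This is not a population-genetic
simulator; it produces exactly the property the syllabic index exploits —
repeated local haplotype blocks, so per-column distinct syllable counts stay
far below M. Queries optionally carry planted segments copied verbatim from
named haplotypes; planted coordinates are advisory only (chance agreement
may extend them), so tests always take ground truth from the brute-force
oracle. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .panel import HaplotypePanel

__all__ = [
    "PanelSpec",
    "PlantSpec",
    "generate_panel",
    "generate_query",
    "generate_genetic_map",
]


@dataclass
class PanelSpec:
    """Mosaic panel parameters: M haplotypes x N sites from F founders."""

    M: int
    N: int
    founders: int = 6
    switch_rate: float = 0.005
    mut_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.M < 1 or self.N < 1:
            raise InputError("panel dimensions must be positive")
        if not 1 <= self.founders <= self.M:
            raise InputError("founder count must satisfy 1 <= F <= M")
        for name in ("switch_rate", "mut_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise InputError(f"{name} must lie in [0, 1]")


@dataclass
class PlantSpec:
    """Planted shared segments on a query: (hap index, start site, length)."""

    segments: list[tuple[int, int, int]] = field(default_factory=list)
    background: str = "random"  # "random" or "copy"
    background_hap: int = 0
    background_noise: float = 0.05
    seed: int = 0


def generate_panel(spec: PanelSpec) -> HaplotypePanel:
    """Draw a mosaic-of-founders panel; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    founders = rng.integers(0, 2, size=(spec.founders, spec.N), dtype=np.uint8)
    alleles = np.empty((spec.M, spec.N), dtype=np.uint8)
    for i in range(spec.M):
        switches = np.flatnonzero(rng.random(spec.N) < spec.switch_rate)
        bounds = np.unique(np.concatenate(([0], switches, [spec.N])))
        row = np.empty(spec.N, dtype=np.uint8)
        for b, e in zip(bounds[:-1], bounds[1:]):
            row[b:e] = founders[rng.integers(spec.founders), b:e]
        if spec.mut_rate > 0:
            row ^= (rng.random(spec.N) < spec.mut_rate).astype(np.uint8)
        alleles[i] = row
    return HaplotypePanel(alleles=alleles)


def generate_query(
    panel: HaplotypePanel, plant: PlantSpec
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Build a query haplotype with planted segments copied from the panel.

    Returns the query and the plant list. Segments must be in range and
    non-overlapping on the query; the actual match set is whatever the
    oracle reports (plants can extend by chance agreement).
    """
    N = panel.N
    taken = np.zeros(N, dtype=bool)
    for hap, start, length in plant.segments:
        if not (0 <= hap < panel.M):
            raise InputError(f"planted haplotype {hap} out of range")
        if length < 1 or start < 0 or start + length > N:
            raise InputError(f"planted segment ({hap}, {start}, {length}) out of range")
        if taken[start : start + length].any():
            raise InputError("planted segments overlap on the query")
        taken[start : start + length] = True
    rng = np.random.default_rng(plant.seed)
    if plant.background == "random":
        q = rng.integers(0, 2, size=N, dtype=np.uint8)
    elif plant.background == "copy":
        if not (0 <= plant.background_hap < panel.M):
            raise InputError("background haplotype out of range")
        q = panel.alleles[plant.background_hap].copy()
        q ^= (rng.random(N) < plant.background_noise).astype(np.uint8)
    else:
        raise InputError(f"unknown background kind {plant.background!r}")
    for hap, start, length in plant.segments:
        q[start : start + length] = panel.alleles[hap, start : start + length]
    return q, list(plant.segments)


def generate_genetic_map(
    N: int, mean_spacing_cm: float, jitter: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Non-decreasing cM positions with mean inter-site spacing as given.

    Spacings are ``mean * ((1 - jitter) + jitter * Exp(1))``: jitter 0 gives
    a uniform map, jitter 1 fully exponential spacings. positions[0] = 0.
    """
    if mean_spacing_cm <= 0:
        raise InputError("mean spacing must be positive")
    if not 0.0 <= jitter <= 1.0:
        raise InputError("jitter must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    spacings = mean_spacing_cm * ((1.0 - jitter) + jitter * rng.exponential(1.0, N - 1))
    return np.concatenate(([0.0], np.cumsum(spacings)))
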