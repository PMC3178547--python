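"""Reference genome geometry for array-style marker maps.

Chromosome lengths are an approximate build-36-era table (the annotation era
of the 50K/250K Affymetrix mapping arrays). Only the relative geometry of the
chromosomes matters for the statistics computed downstream; none of the
results depend on the exact base-pair values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Approximate chromosome lengths (bp), 22 autosomes + X.
CHROM_LENGTHS_BP: dict[str, int] = {
    "chr1": 247_250_000,
    "chr2": 242_950_000,
    "chr3": 199_500_000,
    "chr4": 191_270_000,
    "chr5": 180_860_000,
    "chr6": 170_900_000,
    "chr7": 158_820_000,
    "chr8": 146_270_000,
    "chr9": 140_270_000,
    "chr10": 135_370_000,
    "chr11": 134_450_000,
    "chr12": 132_350_000,
    "chr13": 114_140_000,
    "chr14": 106_370_000,
    "chr15": 100_340_000,
    "chr16": 88_820_000,
    "chr17": 78_770_000,
    "chr18": 76_120_000,
    "chr19": 63_810_000,
    "chr20": 62_440_000,
    "chr21": 46_940_000,
    "chr22": 49_690_000,
    "chrX": 154_910_000,
}

AUTOSOMES: tuple[str, ...] = tuple(c for c in CHROM_LENGTHS_BP if c != "chrX")

#: Designated MYCN-like amplicon locus on 2p (bp interval, 1-based inclusive).
MYCN_LOCUS: tuple[str, int, int] = ("chr2", 15_000_000, 17_000_000)


@dataclass(frozen=True)
class MarkerMap:
    """Per-chromosome marker positions emulating array probe density.

    positions are 1-based bp, strictly increasing within each chromosome and
    bounded by the chromosome length.
    """

    lengths_bp: dict[str, int]
    positions: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            if len(pos) == 0:
                continue
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
            if pos[0] < 1 or pos[-1] > self.lengths_bp[chrom]:
                raise ValueError(f"marker positions out of range on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths_bp)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.lengths_bp if c != "chrX"]

    def n_markers(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.positions[chrom])
        return sum(len(p) for p in self.positions.values())


def make_marker_map(
    chrom_lengths: dict[str, int] | None = None, marker_spacing_bp: int = 50_000
) -> MarkerMap:
    """Place markers at regular spacing, starting at spacing/2.

    Each chromosome receives floor(length / spacing) markers. A chromosome
    shorter than the spacing gets no markers (logged as a warning).
    """
    if chrom_lengths is None:
        chrom_lengths = CHROM_LENGTHS_BP
    if not chrom_lengths:
        raise ValueError("chromosome length table is empty")
    if marker_spacing_bp <= 0:
        raise ValueError(f"marker spacing must be positive, got {marker_spacing_bp}")
    positions: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n = length // marker_spacing_bp
        if n == 0:
            log.warning("spacing %d bp exceeds %s length %d bp; no markers placed",
                        marker_spacing_bp, chrom, length)
        start = max(marker_spacing_bp // 2, 1)
        positions[chrom] = start + marker_spacing_bp * np.arange(n, dtype=np.int64)
    return MarkerMap(lengths_bp=dict(chrom_lengths), positions=positions)
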