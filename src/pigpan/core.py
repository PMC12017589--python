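"""Core domain types shared across the toolkit.

All internal coordinates are 0-based half-open ``[start, end)``.  Conversion to
and from 1-based inclusive conventions (VCF, GFF3, BLAST tabular) happens only
at file boundaries in :mod:`pigpan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

#: Canonical structural-variant type labels.  "presence" and "absence" are the
#: two orientations of a presence/absence variation (PAV) relative to the
#: reference; translocations are split by whether both breakends share a
#: chromosome.
SV_TYPES = (
    "presence",
    "absence",
    "inversion",
    "translocation_intra",
    "translocation_inter",
)

#: Minimum structural-variant length in bp; shorter events are indels, not SVs.
MIN_SV_LENGTH = 50


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.': {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """Smaller of the two mutual overlap fractions (0 when disjoint)."""
        ov = self.overlap_bp(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)


@dataclass
class SVRecord:
    """A structural variant call.

    For PAVs and inversions ``interval`` spans the affected reference region.
    For insertions (``presence``) the interval is the 1-bp insertion point and
    ``length`` the inserted length.  Translocations carry the source breakpoint
    in ``interval`` and the destination breakpoint in ``mate``.
    """

    id: str
    interval: GenomicInterval
    sv_type: str
    length: int
    source_genome: str = ""
    sequence: Optional[str] = None
    repeat_fraction: Optional[float] = None
    mate: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.length < MIN_SV_LENGTH:
            raise ValueError(
                f"SV length {self.length} < {MIN_SV_LENGTH} bp minimum"
            )
        if self.repeat_fraction is not None and not (
            0.0 <= self.repeat_fraction <= 1.0
        ):
            raise ValueError("repeat_fraction outside [0, 1]")

    @property
    def breakpoints(self) -> list[tuple[str, int]]:
        """Breakpoint positions this SV contributes (both ends; translocations
        contribute the source ends and the mate position)."""
        pts = [(self.interval.chrom, self.interval.start),
               (self.interval.chrom, self.interval.end)]
        if self.mate is not None:
            pts.append((self.mate.chrom, self.mate.start))
        return pts


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (matching printed-table conventions, where
    banker's rounding would disagree on exact .5 ties)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentages(counts: dict[str, int], ndigits: int = 2) -> dict[str, float]:
    """Half-up rounded percentage share per key."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot compute percentages of an empty tally")
    return {k: round_half_up(100.0 * v / total, ndigits) for k, v in counts.items()}
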