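"""Non-redundant structural-variant cataloguing across genomes.

Per-genome SV call sets are merged iteratively: genomes are added in a fixed
order and each incoming call either matches an existing catalogue record of
the same type (setting its presence bit for the new genome) or appends a new
record.  Matching uses reciprocal overlap for span-type SVs (PAV absences,
inversions) and breakpoint proximity plus length-ratio agreement for
insertions and translocations, whose reference footprint is a point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, SVRecord, percentages

SPAN_TYPES = ("absence", "inversion")
POINT_TYPES = ("presence", "translocation_intra", "translocation_inter")


@dataclass
class SVCatalog:
    """Non-redundant SV records with per-genome presence and curves."""

    records: list[SVRecord]
    genomes: list[str]
    presence: np.ndarray  # bool, (n_records, n_genomes)
    growth_curve: list[int] = field(default_factory=list)
    shared_curve: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.records), len(self.genomes)):
            raise ValueError("presence shape mismatch")
        if len(self.records) and not self.presence.any(axis=1).all():
            raise ValueError("every record must be present in >= 1 genome")

    @property
    def frequencies(self) -> np.ndarray:
        return self.presence.sum(axis=1)


def _match_span(rec: SVRecord, cand: SVRecord, reciprocal_overlap: float) -> bool:
    return rec.interval.reciprocal_overlap(cand.interval) >= reciprocal_overlap


def _match_point(
    rec: SVRecord, cand: SVRecord, reciprocal_overlap: float, breakpoint_window: int
) -> bool:
    if abs(rec.interval.start - cand.interval.start) > breakpoint_window:
        return False
    if min(rec.length, cand.length) / max(rec.length, cand.length) < reciprocal_overlap:
        return False
    if rec.mate is not None or cand.mate is not None:
        if rec.mate is None or cand.mate is None:
            return False
        if rec.mate.chrom != cand.mate.chrom:
            return False
        if abs(rec.mate.start - cand.mate.start) > breakpoint_window:
            return False
    return True


def merge_nonredundant(
    callsets: dict[str, list[SVRecord]],
    reciprocal_overlap: float = 0.5,
    breakpoint_window: int = 100,
) -> SVCatalog:
    """Iteratively merge per-genome call sets into a non-redundant catalogue.

    ``callsets`` maps genome name to its calls; insertion order fixes the
    iteration order.  A call is redundant when a same-type record on the same
    chromosome reciprocally overlaps >= ``reciprocal_overlap`` (span types) or
    lies within ``breakpoint_window`` bp with length ratio >= the threshold
    (point types).  First-seen coordinates are kept.  Growth (catalogue size)
    and shared (records present in every genome so far) curves are recorded
    after each genome.
    """
    if not callsets:
        raise ValueError("no call sets supplied")
    if not (0 < reciprocal_overlap <= 1):
        raise ValueError("reciprocal_overlap must be in (0, 1]")
    genomes = list(callsets)
    records: list[SVRecord] = []
    presence_sets: list[set[int]] = []
    trees: dict[tuple[str, str], IntervalTree] = {}

    def _tree_key(rec: SVRecord) -> tuple[str, str]:
        return (rec.interval.chrom, rec.sv_type)

    def _query_span(rec: SVRecord):
        tree = trees.get(_tree_key(rec))
        return (iv.data for iv in tree.overlap(rec.interval.start, rec.interval.end)) if tree else ()

    def _query_point(rec: SVRecord):
        tree = trees.get(_tree_key(rec))
        if tree is None:
            return ()
        lo = rec.interval.start - breakpoint_window
        hi = rec.interval.start + breakpoint_window + 1
        return (iv.data for iv in tree.overlap(lo, hi))

    growth, shared = [], []
    for gi, genome in enumerate(genomes):
        for rec in callsets[genome]:
            if rec.sv_type in SPAN_TYPES:
                hit = next(
                    (
                        j
                        for j in _query_span(rec)
                        if _match_span(rec, records[j], reciprocal_overlap)
                    ),
                    None,
                )
            elif rec.sv_type in POINT_TYPES:
                hit = next(
                    (
                        j
                        for j in _query_point(rec)
                        if _match_point(rec, records[j], reciprocal_overlap, breakpoint_window)
                    ),
                    None,
                )
            else:  # pragma: no cover - SVRecord already validates
                raise ValueError(f"unknown sv_type {rec.sv_type!r}")
            if hit is None:
                j = len(records)
                records.append(rec)
                presence_sets.append({gi})
                key = _tree_key(rec)
                tree = trees.setdefault(key, IntervalTree())
                if rec.sv_type in SPAN_TYPES:
                    tree.addi(rec.interval.start, rec.interval.end, j)
                else:
                    tree.addi(rec.interval.start, rec.interval.start + 1, j)
            else:
                presence_sets[hit].add(gi)
        growth.append(len(records))
        shared.append(sum(1 for s in presence_sets if len(s) == gi + 1))

    presence = np.zeros((len(records), len(genomes)), dtype=bool)
    for j, s in enumerate(presence_sets):
        presence[j, list(s)] = True
    return SVCatalog(records, genomes, presence, growth, shared)


def classify_sv_frequency(
    catalog: SVCatalog, softcore_fraction: float = 0.9
) -> tuple[pd.Series, dict]:
    """Frequency classes over genome counts: core = all genomes; softcore =
    share > ``softcore_fraction`` but not all; private = exactly one genome;
    dispensable = the remainder (>= 2 genomes, share <= the threshold)."""
    n = len(catalog.genomes)
    if n < 3:
        raise ValueError("frequency classes need >= 3 genomes")
    freq = catalog.frequencies
    share = freq / n
    cls = np.where(
        freq == n,
        "core",
        np.where(
            freq == 1,
            "private",
            np.where(share > softcore_fraction, "softcore", "dispensable"),
        ),
    )
    ids = [r.id for r in catalog.records]
    ser = pd.Series(cls, index=pd.Index(ids, name="sv_id"), name="class")
    counts = {c: int((cls == c).sum()) for c in ("core", "softcore", "dispensable", "private")}
    summary = {"counts": counts, "percent": percentages(counts) if len(cls) else {}}
    return ser, summary


def annotate_repeat_fraction(
    records: list[SVRecord], repeats: list[GenomicInterval]
) -> None:
    """Set ``repeat_fraction`` on each record as intersected bp / SV length
    against the merged repeat footprint (in place)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in repeats:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        arr = np.asarray(out, dtype=int)
        merged[chrom] = (arr[:, 0], arr[:, 1])
    for rec in records:
        chrom = rec.interval.chrom
        if chrom not in merged:
            rec.repeat_fraction = 0.0
            continue
        starts, ends = merged[chrom]
        lo = np.searchsorted(ends, rec.interval.start, side="right")
        hi = np.searchsorted(starts, rec.interval.end, side="left")
        ov = 0
        for k in range(lo, hi):
            ov += max(0, min(ends[k], rec.interval.end) - max(starts[k], rec.interval.start))
        rec.repeat_fraction = ov / rec.interval.length


def repeat_filter(
    records: list[SVRecord], max_repeat_fraction: float = 0.9
) -> tuple[list[SVRecord], dict[str, int]]:
    """Drop records whose span is *more than* ``max_repeat_fraction``
    repetitive; the boundary value itself is retained."""
    missing = [r.id for r in records if r.repeat_fraction is None]
    if missing:
        raise ValueError(f"records without repeat annotation: {missing[:5]}")
    kept = [r for r in records if r.repeat_fraction <= max_repeat_fraction]
    rejected = [r for r in records if r.repeat_fraction > max_repeat_fraction]
    report: dict[str, int] = {}
    for r in rejected:
        report[r.sv_type] = report.get(r.sv_type, 0) + 1
    return kept, report


def catalogue_summary(catalog: SVCatalog) -> dict:
    """Totals by type (translocations also reported combined), total affected
    bp, and per-type length histograms (log2-spaced bins)."""
    by_type: dict[str, int] = {}
    affected = 0
    lengths: dict[str, list[int]] = {}
    for rec in catalog.records:
        by_type[rec.sv_type] = by_type.get(rec.sv_type, 0) + 1
        affected += rec.length
        lengths.setdefault(rec.sv_type, []).append(rec.length)
    translocations = by_type.get("translocation_intra", 0) + by_type.get(
        "translocation_inter", 0
    )
    bins = np.concatenate([[0], np.logspace(np.log2(50), 24, num=20, base=2.0)])
    hists = {
        t: np.histogram(np.asarray(v), bins=bins)[0].tolist() for t, v in lengths.items()
    }
    return {
        "total": len(catalog.records),
        "by_type": by_type,
        "translocations_total": translocations,
        "affected_bp": affected,
        "length_histograms": hists,
        "length_bins": bins.tolist(),
    }
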