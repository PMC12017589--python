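"""NUMT cataloguing and molecular dating.

Nuclear mitochondrial DNA segments (NUMTs) are detected by searching a
doubled (concatenated twice, to expose hits across the circular junction)
mtDNA sequence against each nuclear assembly.  Raw hits are unwrapped to the
single-copy circle, merged per assembly into NUMT intervals, clustered across
assemblies into unique records with presence frequencies, and dated with a
diagnostic-site clock: at aligned positions where the modern mtDNA and an
outgroup mtDNA differ, the fraction m/d of sites where the NUMT matches the
modern allele measures how much of the modern lineage's divergence the NUMT
carries, giving age = T_div * (1 - m/d) against the 9.7-MY pig/warthog split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import GenomicInterval, percentages


@dataclass
class Hit:
    """One alignment hit of the doubled mtDNA query against an assembly.

    Coordinates are 0-based half-open; ``q`` on the (possibly doubled) mtDNA,
    ``s`` on the nuclear subject.  ``strand`` is that of the subject interval.
    """

    query: str
    subject: str
    identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    wraps_junction: bool = False


@dataclass
class ClockParameters:
    """Dating constants: divergence time and the aging size band."""

    t_div: float = 9.7  # MY between Sus scrofa and Phacochoerus africanus
    min_size: int = 50
    max_size: int = 1000

    def __post_init__(self) -> None:
        if self.t_div <= 0:
            raise ValueError("t_div must be positive")


@dataclass
class NUMTRecord:
    nuclear: GenomicInterval
    mt_intervals: list[GenomicInterval]
    presence: np.ndarray  # bool per assembly
    assemblies: list[str]
    freq_class: Optional[str] = None
    d: Optional[int] = None
    m: Optional[int] = None
    age: Optional[float] = None

    @property
    def size(self) -> int:
        return self.nuclear.length

    @property
    def n_present(self) -> int:
        return int(np.asarray(self.presence).sum())

    @property
    def frequency(self) -> float:
        return self.n_present / len(self.assemblies)


def unwrap_doubled_hits(hits: list[Hit], mt_length: int) -> list[Hit]:
    """Reduce doubled-mtDNA query coordinates modulo the circle length.

    Hits entirely in the second copy shift down by ``mt_length``; a hit
    spanning the copy junction keeps its start in the first copy, wraps its
    end, and is flagged ``wraps_junction``.  Idempotent.
    """
    out = []
    for h in hits:
        if h.q_end - h.q_start > mt_length:
            raise ValueError(f"hit longer than mtDNA circle: {h}")
        if h.q_start >= 2 * mt_length or h.q_end > 2 * mt_length:
            raise ValueError("hit coordinates beyond the doubled sequence")
        if h.q_start >= mt_length:
            h = Hit(h.query, h.subject, h.identity, h.q_start - mt_length,
                    h.q_end - mt_length, h.s_start, h.s_end, h.strand)
        elif h.q_end > mt_length:
            h = Hit(h.query, h.subject, h.identity, h.q_start,
                    h.q_end - mt_length, h.s_start, h.s_end, h.strand,
                    wraps_junction=True)
        out.append(h)
    return out


def mt_intervals_of(hit: Hit, mt_length: int) -> list[GenomicInterval]:
    """Circle-coordinate interval(s) of an unwrapped hit (two when wrapping)."""
    if hit.wraps_junction:
        return [
            GenomicInterval("MT", hit.q_start, mt_length),
            GenomicInterval("MT", 0, hit.q_end),
        ]
    return [GenomicInterval("MT", hit.q_start, hit.q_end)]


def merge_hits_to_numts(
    hits: list[Hit], mt_length: int, max_gap: int = 1000
) -> list[NUMTRecord]:
    """Merge an assembly's hits into NUMT intervals.

    Nuclear-adjacent hits on one chromosome within ``max_gap`` bp collapse
    into a single NUMT whose size is the merged nuclear span; the mt-side
    intervals of all constituent hits are retained.
    """
    by_chrom: dict[str, list[Hit]] = {}
    for h in hits:
        by_chrom.setdefault(h.subject, []).append(h)
    records: list[NUMTRecord] = []
    for chrom in sorted(by_chrom):
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: h.s_start)
        cur: list[Hit] = []
        for h in chrom_hits:
            if cur and h.s_start - cur[-1].s_end <= max_gap:
                cur.append(h)
            else:
                if cur:
                    records.append(_hits_to_record(cur, chrom, mt_length))
                cur = [h]
        if cur:
            records.append(_hits_to_record(cur, chrom, mt_length))
    return records


def _hits_to_record(hits: list[Hit], chrom: str, mt_length: int) -> NUMTRecord:
    start = min(h.s_start for h in hits)
    end = max(h.s_end for h in hits)
    mt_ivs: list[GenomicInterval] = []
    for h in hits:
        mt_ivs.extend(mt_intervals_of(h, mt_length))
    return NUMTRecord(
        nuclear=GenomicInterval(chrom, start, end),
        mt_intervals=mt_ivs,
        presence=np.asarray([True]),
        assemblies=["self"],
    )


def cluster_across_assemblies(
    per_assembly: dict[str, list[NUMTRecord]],
    anchor_window: int = 1000,
) -> list[NUMTRecord]:
    """Collapse per-assembly NUMTs into unique cross-assembly records.

    Assemblies share the reference coordinate frame; NUMTs cluster when their
    nuclear intervals lie within ``anchor_window`` bp on the same chromosome
    and their mt intervals overlap.  Frequency F = presence count divided by
    the number of assemblies.
    """
    assemblies = list(per_assembly)
    items: list[tuple[int, NUMTRecord]] = []
    for ai, (name, recs) in enumerate(per_assembly.items()):
        for r in recs:
            items.append((ai, r))
    items.sort(key=lambda t: (t[1].nuclear.chrom, t[1].nuclear.start))
    clusters: list[list[tuple[int, NUMTRecord]]] = []
    for ai, rec in items:
        placed = False
        for cl in reversed(clusters):
            ref = cl[0][1]
            if ref.nuclear.chrom != rec.nuclear.chrom:
                break
            if rec.nuclear.start - ref.nuclear.start > anchor_window:
                continue
            near = abs(rec.nuclear.start - ref.nuclear.start) <= anchor_window
            mt_ok = any(
                a.start < b.end and b.start < a.end
                for a in rec.mt_intervals
                for b in ref.mt_intervals
            )
            if near and mt_ok:
                cl.append((ai, rec))
                placed = True
                break
        if not placed:
            clusters.append([(ai, rec)])
    out: list[NUMTRecord] = []
    for cl in clusters:
        first = cl[0][1]
        presence = np.zeros(len(assemblies), dtype=bool)
        for ai, _ in cl:
            presence[ai] = True
        out.append(
            NUMTRecord(
                nuclear=first.nuclear,
                mt_intervals=first.mt_intervals,
                presence=presence,
                assemblies=assemblies,
            )
        )
    return out


def classify_numt_frequency(
    records: list[NUMTRecord], common_threshold: float = 0.1
) -> dict:
    """Frequency classes: private (one assembly, takes precedence), common
    (F >= threshold), rare (the rest).  Sets ``freq_class`` in place and
    returns counts plus half-up percentages."""
    for r in records:
        if r.n_present == 1:
            r.freq_class = "private"
        elif r.frequency >= common_threshold:
            r.freq_class = "common"
        else:
            r.freq_class = "rare"
    counts = {
        c: sum(1 for r in records if r.freq_class == c)
        for c in ("common", "rare", "private")
    }
    return {"counts": counts, "percent": percentages(counts) if records else {}}


def numt_frequency_summary(counts: dict[str, int]) -> dict:
    """Percentage summary straight from per-class record counts."""
    return {"counts": dict(counts), "percent": percentages(counts)}


def estimate_numt_age(
    record: NUMTRecord,
    clock: ClockParameters,
    numt_seq: str,
    modern_mt: str,
    outgroup_mt: str,
) -> Optional[float]:
    """Date one NUMT from a gapless three-way alignment over its mt span.

    Diagnostic sites are positions where the modern and outgroup mtDNA carry
    different bases and the NUMT base is called (A/C/G/T); positions where the
    NUMT matches neither allele (triallelic) are excluded.  With m of d
    diagnostic sites matching the modern allele, age = T_div * (1 - m/d);
    records outside the aging size band or with d = 0 return None.  Sets
    ``d``, ``m`` and ``age`` on the record.
    """
    if not (clock.min_size <= record.size <= clock.max_size):
        return None
    if not (len(numt_seq) == len(modern_mt) == len(outgroup_mt)):
        raise ValueError("alignment sequences differ in length")
    if len(numt_seq) < record.size:
        raise ValueError("alignment shorter than the NUMT record")
    d = m = 0
    for x, mo, og in zip(numt_seq.upper(), modern_mt.upper(), outgroup_mt.upper()):
        if mo == og or x not in "ACGT":
            continue
        if x == mo:
            d += 1
            m += 1
        elif x == og:
            d += 1
    record.d, record.m = d, m
    if d == 0:
        record.age = None
        return None
    record.age = clock.t_div * (1.0 - m / d)
    return record.age


def age_classes(
    records: list[NUMTRecord],
    boundary: float = 5.3,
    epoch_bounds: dict[str, tuple[float, float]] | None = None,
) -> dict:
    """Label dated NUMTs older/younger than ``boundary`` MY and count epochs.

    Epochs bin with closed-open intervals [lo, hi); the default marks the
    Pliocene (2.5-5.3 MY).  Undated records are ignored.
    """
    if epoch_bounds is None:
        epoch_bounds = {"Pliocene": (2.5, 5.3)}
    dated = [r for r in records if r.age is not None]
    younger = sum(1 for r in dated if r.age < boundary)
    epochs = {
        name: sum(1 for r in dated if lo <= r.age < hi)
        for name, (lo, hi) in epoch_bounds.items()
    }
    return {
        "n_dated": len(dated),
        "younger": younger,
        "older": len(dated) - younger,
        "younger_fraction": younger / len(dated) if dated else float("nan"),
        "epochs": epochs,
    }
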