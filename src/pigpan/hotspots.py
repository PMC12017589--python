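"""SV breakpoint hotspot detection over sliding windows.

Breakpoints (both ends of each SV; translocations also contribute the mate
breakend) are counted per 200-kb window with 100-kb step, windows are ranked
genome-wide, the top 5% by breakpoint count become hotspot windows, and
consecutive (overlapping or abutting) hotspot windows merge into hotspot
regions.  The same machinery runs per subpopulation by restricting the
catalogue's presence matrix first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, SVRecord
from .popgen import WindowTrack, make_windows
from .svcatalog import SVCatalog


@dataclass
class HotspotRegion:
    interval: GenomicInterval
    n_windows: int
    total_breakpoints: int
    population: str = "all"

    @property
    def span(self) -> int:
        return self.interval.length


def breakpoint_window_counts(
    svs: list[SVRecord],
    chrom_lengths: dict[str, int],
    window: int = 200_000,
    step: int = 100_000,
) -> WindowTrack:
    """Count SV breakpoints per sliding window.

    Every breakpoint is counted in every window containing it (windows overlap
    when step < window).  A breakpoint at the chromosome end is assigned to
    the last window.
    """
    chroms, starts, ends = make_windows(chrom_lengths, window, step)
    vals = np.zeros(len(chroms), dtype=float)
    # per-chromosome window start offsets for O(1) breakpoint -> window mapping
    first_idx: dict[str, int] = {}
    n_win: dict[str, int] = {}
    for i, c in enumerate(chroms):
        if c not in first_idx:
            first_idx[c] = i
        n_win[c] = n_win.get(c, 0) + 1
    for rec in svs:
        for chrom, pos in rec.breakpoints:
            if chrom not in chrom_lengths:
                raise ValueError(f"SV {rec.id} on unknown chromosome {chrom!r}")
            if pos > chrom_lengths[chrom]:
                raise ValueError(
                    f"SV {rec.id} breakpoint {pos} beyond {chrom} length"
                )
            pos_eff = min(pos, chrom_lengths[chrom] - 1)
            # windows with start <= pos < start + window, start = k * step
            k_hi = pos_eff // step
            k_lo = max(0, (pos_eff - window) // step + 1)
            for k in range(k_lo, min(k_hi, n_win[chrom] - 1) + 1):
                vals[first_idx[chrom] + k] += 1
    return WindowTrack(window, step, chroms, starts, ends, vals)


def _merge_windows(
    chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray, vals: np.ndarray,
    population: str,
) -> list[HotspotRegion]:
    """Merge overlapping/abutting windows (inputs sorted by chrom, start)."""
    regions: list[HotspotRegion] = []
    cur = None
    for chrom, s, e, v in zip(chroms, starts, ends, vals):
        if cur is not None and chrom == cur[0] and s <= cur[2]:
            cur[2] = max(cur[2], e)
            cur[3] += 1
            cur[4] += v
        else:
            if cur is not None:
                regions.append(
                    HotspotRegion(
                        GenomicInterval(cur[0], cur[1], cur[2]), cur[3], int(cur[4]), population
                    )
                )
            cur = [chrom, int(s), int(e), 1, float(v)]
    if cur is not None:
        regions.append(
            HotspotRegion(
                GenomicInterval(cur[0], cur[1], cur[2]), cur[3], int(cur[4]), population
            )
        )
    return regions


def call_hotspots(
    track: WindowTrack, top_fraction: float = 0.05, population: str = "all"
) -> tuple[WindowTrack, list[HotspotRegion]]:
    """Call the top-``top_fraction`` windows by breakpoint count as hotspots.

    The threshold is the value of the ceil(f * n_windows)-th window in
    descending order; ties at the threshold are included.  Zero-count windows
    never qualify (a hotspot must contain at least one breakpoint).  Returns
    the hotspot windows as a track plus merged regions.
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    vals = track.values
    n = len(vals)
    if n == 0 or np.nanmax(vals) <= 0:
        warnings.warn("all windows have zero breakpoints; no hotspots called")
        empty = WindowTrack(track.window, track.step, [], [], [], [])
        return empty, []
    k = math.ceil(top_fraction * n)
    threshold = np.sort(vals)[::-1][k - 1]
    mask = (vals >= threshold) & (vals > 0)
    sub = WindowTrack(
        track.window,
        track.step,
        track.chroms[mask],
        track.starts[mask],
        track.ends[mask],
        vals[mask],
    )
    regions = _merge_windows(sub.chroms, sub.starts, sub.ends, sub.values, population)
    return sub, regions


def per_population_hotspots(
    catalog: SVCatalog,
    population_assignment: dict[str, str],
    chrom_lengths: dict[str, int],
    window: int = 200_000,
    step: int = 100_000,
    top_fraction: float = 0.05,
) -> dict[str, list[HotspotRegion]]:
    """Hotspot regions per subpopulation.

    SV presence is restricted to each population's genomes before windowing;
    an SV contributes to a population's track iff carried by at least one of
    its genomes.
    """
    unassigned = [g for g in catalog.genomes if g not in population_assignment]
    if unassigned:
        raise ValueError(f"genomes without population: {unassigned}")
    pops: dict[str, list[int]] = {}
    for i, g in enumerate(catalog.genomes):
        pops.setdefault(population_assignment[g], []).append(i)
    if any(len(ix) == 0 for ix in pops.values()):
        raise ValueError("empty population")
    out: dict[str, list[HotspotRegion]] = {}
    for pop, ix in pops.items():
        mask = catalog.presence[:, ix].any(axis=1)
        svs = [r for r, m in zip(catalog.records, mask) if m]
        track = breakpoint_window_counts(svs, chrom_lengths, window, step)
        if not len(svs) or np.nanmax(track.values) <= 0:
            out[pop] = []
            continue
        _, regions = call_hotspots(track, top_fraction, population=pop)
        out[pop] = regions
    return out
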