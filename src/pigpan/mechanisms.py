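"""Rule-based inference of SV formation mechanisms from breakpoint context.

The decision cascade, applied to PAVs and inversions (translocations are not
called), mirrors breakpoint-junction analyses used for large variant sets:

1. tandem-repeat coverage of the SV span >= 0.8          -> VNTR
2. transposable-element coverage >= 0.8, one TE family   -> STEI
   transposable-element coverage >= 0.8, >= 2 families   -> MTEI
3. extended homology between the two breakpoint junction
   sequences (>= 50 bp at >= 90% identity)               -> NAHR
4. otherwise (microhomology or blunt junctions)          -> NHR

Homology is detected by exact-seed extension along a shared diagonal with
mismatch tolerance — deterministic and gap-free, which suffices for calls at
the 50-bp scale.  Unassignable inputs (no sequence) return "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, SVRecord

MECHANISMS = ("NAHR", "NHR", "VNTR", "STEI", "MTEI", "unassigned")


@dataclass
class MechanismThresholds:
    repeat_coverage: float = 0.8     # tandem-repeat / TE span coverage
    min_homology: int = 50           # bp of junction homology for NAHR
    min_identity: float = 0.9        # identity within the homology run
    flank: int = 500                 # junction flank length in bp


@dataclass
class MechanismCall:
    sv_id: str
    mechanism: str
    homology_bp: int = 0
    tandem_repeat_fraction: float = 0.0
    te_fraction: float = 0.0
    n_te_families: int = 0


def _coverage(span: GenomicInterval, intervals: list[GenomicInterval]) -> float:
    """Fraction of the span covered by the (merged) intervals."""
    spans = sorted(
        (max(iv.start, span.start), min(iv.end, span.end))
        for iv in intervals
        if iv.chrom == span.chrom and iv.start < span.end and iv.end > span.start
    )
    covered = 0
    cur_end = span.start
    for s, e in spans:
        if e > cur_end:
            covered += e - max(s, cur_end)
            cur_end = e
    return covered / span.length


def _longest_homology(a: str, b: str, min_identity: float) -> int:
    """Longest gap-free homology run between two sequences.

    For every diagonal offset, the longest exact match run is found and then
    extended outward while the run identity stays >= ``min_identity``.
    """
    a_arr = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    best = 0
    la, lb = len(a_arr), len(b_arr)
    for shift in range(-(lb - 1), la):
        a_lo = max(0, shift)
        b_lo = a_lo - shift
        n = min(la - a_lo, lb - b_lo)
        if n <= best:
            continue
        eq = a_arr[a_lo : a_lo + n] == b_arr[b_lo : b_lo + n]
        # longest exact run on this diagonal (gaps between mismatch positions)
        mism = np.flatnonzero(~eq)
        bounds = np.concatenate(([-1], mism, [n]))
        runs = np.diff(bounds) - 1
        j = int(runs.argmax())
        best_run = int(runs[j])
        if best_run == 0:
            continue
        lo = int(bounds[j]) + 1
        hi = lo + best_run
        matches = best_run
        # greedy outward extension tolerating mismatches
        improved = True
        while improved:
            improved = False
            if hi < n and (matches + eq[hi]) / (hi - lo + 1) >= min_identity:
                matches += eq[hi]
                hi += 1
                improved = True
            if lo > 0 and (matches + eq[lo - 1]) / (hi - lo + 1) >= min_identity:
                lo -= 1
                matches += eq[lo]
                improved = True
        if hi - lo > best and matches / (hi - lo) >= min_identity:
            best = hi - lo
    return best


def infer_mechanism(
    sv: SVRecord,
    left_flank: str,
    right_flank: str,
    tandem_repeats: list[GenomicInterval],
    transposable_elements: list[tuple[GenomicInterval, str]],
    thresholds: MechanismThresholds | None = None,
) -> MechanismCall:
    """Classify one SV's formation mechanism via the rule cascade.

    ``left_flank``/``right_flank`` are the reference sequences immediately
    outside each breakpoint; ``transposable_elements`` carry (interval,
    family) pairs.  Flanks shorter than the configured window are an error.
    """
    th = thresholds or MechanismThresholds()
    if sv.sv_type not in ("presence", "absence", "inversion"):
        raise ValueError(f"mechanism inference not defined for {sv.sv_type}")
    if min(len(left_flank), len(right_flank)) < th.flank:
        raise ValueError(
            f"flanks shorter than homology search window ({th.flank} bp)"
        )
    tr_frac = _coverage(sv.interval, tandem_repeats)
    te_hits = [
        (iv, fam) for iv, fam in transposable_elements if iv.overlaps(sv.interval)
    ]
    te_frac = _coverage(sv.interval, [iv for iv, _ in te_hits])
    n_fam = len({fam for _, fam in te_hits})
    if tr_frac >= th.repeat_coverage:
        return MechanismCall(sv.id, "VNTR", 0, tr_frac, te_frac, n_fam)
    if te_frac >= th.repeat_coverage:
        mech = "STEI" if n_fam <= 1 else "MTEI"
        return MechanismCall(sv.id, mech, 0, tr_frac, te_frac, n_fam)
    if sv.sequence is None:
        return MechanismCall(sv.id, "unassigned", 0, tr_frac, te_frac, n_fam)
    seq = sv.sequence.upper()
    w = th.flank
    # inner window capped at half the SV so the two junction sequences never
    # share SV bases (self-overlap would fake homology on short SVs)
    w_in = min(w, len(seq) // 2)
    junction_left = left_flank[-w:] + seq[:w_in]
    junction_right = seq[len(seq) - w_in :] + right_flank[:w]
    hom = _longest_homology(junction_left, junction_right, th.min_identity)
    if hom >= th.min_homology:
        return MechanismCall(sv.id, "NAHR", hom, tr_frac, te_frac, n_fam)
    return MechanismCall(sv.id, "NHR", hom, tr_frac, te_frac, n_fam)


def mechanism_summary(
    calls: list[MechanismCall],
    sv_types: dict[str, str] | None = None,
    lengths: dict[str, int] | None = None,
    length_bins: tuple[int, ...] = (50, 1_000, 10_000, 100_000),
) -> dict:
    """Mechanism proportions over assigned calls, overall and stratified.

    The assignment rate (assigned / total) is reported separately so the
    proportions always sum to 1 over assigned calls.
    """
    assigned = [c for c in calls if c.mechanism != "unassigned"]
    n_assigned = len(assigned)
    overall = {
        m: (sum(1 for c in assigned if c.mechanism == m) / n_assigned if n_assigned else float("nan"))
        for m in MECHANISMS[:5]
    }
    out = {
        "n_total": len(calls),
        "n_assigned": n_assigned,
        "assignment_rate": n_assigned / len(calls) if calls else float("nan"),
        "overall": overall,
    }
    if sv_types:
        by_type: dict[str, dict[str, float]] = {}
        for t in sorted(set(sv_types.values())):
            sub = [c for c in assigned if sv_types.get(c.sv_id) == t]
            if sub:
                by_type[t] = {
                    m: sum(1 for c in sub if c.mechanism == m) / len(sub)
                    for m in MECHANISMS[:5]
                }
        out["by_type"] = by_type
    if lengths:
        edges = list(length_bins) + [float("inf")]
        by_len: dict[str, dict[str, float]] = {}
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub = [c for c in assigned if lo <= lengths.get(c.sv_id, -1) < hi]
            if sub:
                label = f"[{lo},{hi})"
                by_len[label] = {
                    m: sum(1 for c in sub if c.mechanism == m) / len(sub)
                    for m in MECHANISMS[:5]
                }
        out["by_length"] = by_len
    return out
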