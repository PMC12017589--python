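"""SV enrichment/depletion over annotated genomic feature classes.

Seven feature classes are supported (gene, exon, intron, CDS, promoter, UTR,
enhancer).  Enrichment uses a length-preserving positional permutation null:
each SV is re-placed uniformly at random on its own chromosome and overlaps
are recounted, so the fold is observed count / mean null count and the
p-value is the two-sided empirical tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, SVRecord

FEATURE_CLASSES = ("gene", "exon", "intron", "CDS", "promoter", "UTR", "enhancer")


def _flatten(intervals: list[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merged per-chromosome footprint as an (n, 2) array of [start, end)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=int)
    return out


@dataclass
class FeatureAnnotation:
    """Feature intervals per class plus merged footprints."""

    intervals: dict[str, list[GenomicInterval]]
    chrom_lengths: dict[str, int] | None = None
    footprints: dict[str, dict[str, np.ndarray]] = field(init=False)

    def __post_init__(self) -> None:
        unknown = set(self.intervals) - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if self.chrom_lengths:
            for cls, ivs in self.intervals.items():
                for iv in ivs:
                    if iv.chrom in self.chrom_lengths and iv.end > self.chrom_lengths[iv.chrom]:
                        raise ValueError(
                            f"{cls} feature {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome"
                        )
        self.footprints = {cls: _flatten(ivs) for cls, ivs in self.intervals.items()}

    @property
    def classes(self) -> list[str]:
        return [c for c in FEATURE_CLASSES if c in self.intervals]

    def coverage_bp(self, cls: str) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.footprints[cls].values())
        )


def _overlap_any(
    footprint: dict[str, np.ndarray], chrom: str, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Vectorised >=1 bp overlap test of intervals against a merged footprint."""
    arr = footprint.get(chrom)
    if arr is None or len(arr) == 0:
        return np.zeros(len(starts), dtype=bool)
    f_starts, f_ends = arr[:, 0], arr[:, 1]
    n_start_lt = np.searchsorted(f_starts, ends, side="left")   # features starting before SV end
    n_end_le = np.searchsorted(f_ends, starts, side="right")    # features ending at/before SV start
    return n_start_lt > n_end_le


def annotate_sv_context(
    svs: list[SVRecord], features: FeatureAnnotation
) -> tuple[pd.DataFrame, dict]:
    """Per-SV overlap flags for each feature class plus a genic/intergenic and
    whole-gene containment summary.

    An SV overlaps a class when the intersection is >= 1 bp.  Whole-gene
    containment counts genes entirely inside the SV span.
    """
    rows = []
    gene_fp = features.footprints.get("gene", {})
    gene_ivs: dict[str, np.ndarray] = {}
    for iv in features.intervals.get("gene", []):
        gene_ivs.setdefault(iv.chrom, []).append((iv.start, iv.end))
    gene_ivs = {c: np.asarray(v, dtype=int) for c, v in gene_ivs.items()}
    for rec in svs:
        row = {"id": rec.id, "sv_type": rec.sv_type}
        for cls in features.classes:
            row[cls] = bool(
                _overlap_any(
                    features.footprints[cls],
                    rec.interval.chrom,
                    np.asarray([rec.interval.start]),
                    np.asarray([rec.interval.end]),
                )[0]
            )
        genes = gene_ivs.get(rec.interval.chrom)
        contained = 0
        if genes is not None and len(genes):
            contained = int(
                np.sum((genes[:, 0] >= rec.interval.start) & (genes[:, 1] <= rec.interval.end))
            )
        row["whole_genes_contained"] = contained
        row["genic"] = row.get("gene", False)
        rows.append(row)
    df = pd.DataFrame(rows)
    n = len(df)
    summary = {
        "n_svs": n,
        "genic_fraction": float(df["genic"].mean()) if n else float("nan"),
        "with_whole_gene": int((df["whole_genes_contained"] > 0).sum()) if n else 0,
    }
    return df, summary


def _overlap_vector(
    features: FeatureAnnotation,
    cls: str,
    chrom_groups: dict[str, np.ndarray],
    starts: np.ndarray,
    ends: np.ndarray,
) -> np.ndarray:
    """Per-SV boolean overlap with one feature class (chromosome groups are
    precomputed index arrays, so repeated calls stay cheap)."""
    out = np.zeros(len(starts), dtype=bool)
    fp = features.footprints[cls]
    for chrom, idx in chrom_groups.items():
        out[idx] = _overlap_any(fp, chrom, starts[idx], ends[idx])
    return out


def permutation_enrichment(
    svs: list[SVRecord],
    features: FeatureAnnotation,
    chrom_lengths: dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
    strata: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Permutation enrichment of SV counts within each feature class.

    The null re-places each SV uniformly at random on its own chromosome,
    preserving its length (no overlap constraint).  ``strata`` optionally maps
    stratum label sets (e.g. sv_type, origin) to per-SV label arrays; results
    are reported per stratum x class plus an "all" stratum.  fold =
    observed / mean(null); two-sided p = (1 + #{|null - mean| >= |obs -
    mean|}) / (n_perm + 1); direction follows the sign of obs - mean.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    chrom_arr = np.asarray([r.interval.chrom for r in svs], dtype=object)
    starts = np.asarray([r.interval.start for r in svs], dtype=int)
    ends = np.asarray([r.interval.end for r in svs], dtype=int)
    lengths = ends - starts
    for rec in svs:
        if rec.interval.length > chrom_lengths[rec.interval.chrom]:
            raise ValueError(f"SV {rec.id} longer than its chromosome")
    clens = np.asarray([chrom_lengths[c] for c in chrom_arr], dtype=int)

    stratum_masks: dict[tuple[str, str], np.ndarray] = {("all", "all"): np.ones(len(svs), dtype=bool)}
    if strata:
        for name, labels in strata.items():
            labels = np.asarray(labels, dtype=object)
            if len(labels) != len(svs):
                raise ValueError(f"stratum {name!r} labels length mismatch")
            for lab in pd.unique(labels):
                stratum_masks[(name, str(lab))] = labels == lab

    rng = np.random.default_rng(seed)
    classes = features.classes
    chrom_groups = {
        chrom: np.flatnonzero(chrom_arr == chrom) for chrom in pd.unique(chrom_arr)
    }
    observed = {}
    for cls in classes:
        vec = _overlap_vector(features, cls, chrom_groups, starts, ends)
        for sk, m in stratum_masks.items():
            observed[(sk, cls)] = int(vec[m].sum())
    null = {key: np.empty(n_perm) for key in observed}
    for it in range(n_perm):
        new_starts = (rng.random(len(svs)) * (clens - lengths + 1)).astype(int)
        new_ends = new_starts + lengths
        for cls in classes:
            vec = _overlap_vector(features, cls, chrom_groups, new_starts, new_ends)
            for sk, m in stratum_masks.items():
                null[(sk, cls)][it] = vec[m].sum()
    rows = []
    for (stratum, cls), obs in observed.items():
        nv = null[(stratum, cls)]
        mu = float(nv.mean())
        dev = abs(obs - mu)
        p = (1 + int(np.sum(np.abs(nv - mu) >= dev))) / (n_perm + 1)
        rows.append(
            {
                "stratum_set": stratum[0],
                "stratum": stratum[1],
                "feature_class": cls,
                "observed": obs,
                "null_mean": mu,
                "null_sd": float(nv.std()),
                "fold": obs / mu if mu > 0 else float("inf") if obs else float("nan"),
                "p": p,
                "direction": "enriched" if obs >= mu else "depleted",
            }
        )
    return pd.DataFrame(rows)
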