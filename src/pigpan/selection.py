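"""V_ST selection scanning and SNP sweep cross-validation.

V_ST = (V_T - V_S) / V_T is an F_ST analogue for quantitative dosage data:
V_T is the dosage variance over all individuals pooled and V_S the
population-size-weighted mean within-population variance.  SVs in the top 1%
of V_ST are candidate selection targets; they are cross-validated against
SNP-based sweep regions (windows in the top 5% of both F_ST and the
between-population diversity ratio) via a permutation overlap test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval
from .popgen import GenotypeMatrix, PopulationSpec, WindowTrack, ld_r2


@dataclass
class VstResult:
    v_t: float
    v_s: float
    v_st_raw: float | None  # None when V_T = 0
    v_st: float | None      # floored at 0

    @property
    def defined(self) -> bool:
        return self.v_st is not None


def vst(
    dosages: np.ndarray,
    labels: list[str] | np.ndarray,
    ddof: int = 0,
) -> VstResult:
    """V_ST of one dosage vector given per-individual population labels.

    Variances use denominator n (``ddof=0``, the population-variance form
    conventional for V_ST; configurable).  Missing dosages are dropped
    per population; a population left with no call is an error.  When the
    pooled variance is zero V_ST is undefined.
    """
    d = np.asarray(dosages, dtype=float)
    labels = np.asarray(labels)
    if d.shape != labels.shape:
        raise ValueError("dosages and labels differ in length")
    ok = ~np.isnan(d)
    pops = pd.unique(labels)
    n_total = 0
    weighted = 0.0
    for pop in pops:
        vals = d[ok & (labels == pop)]
        if len(vals) == 0:
            raise ValueError(f"population {pop!r} entirely missing")
        weighted += len(vals) * np.var(vals, ddof=ddof)
        n_total += len(vals)
    v_s = weighted / n_total
    v_t = float(np.var(d[ok], ddof=ddof))
    if v_t == 0.0:
        return VstResult(v_t, v_s, None, None)
    raw = (v_t - v_s) / v_t
    return VstResult(v_t, v_s, raw, max(0.0, raw))


def _vst_vectorised(gm: GenotypeMatrix, pops: PopulationSpec, ddof: int = 0):
    """Per-variant V_ST over a dosage matrix (NaN where undefined)."""
    groups = pops.indices(gm.individuals)
    d = gm.dosages
    called = ~np.isnan(d)
    nv = d.shape[0]
    v_s_num = np.zeros(nv)
    n_tot = np.zeros(nv)
    bad = np.zeros(nv, dtype=bool)
    for ix in groups.values():
        sub = d[:, ix]
        n_k = np.sum(~np.isnan(sub), axis=1)
        bad |= n_k == 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(sub, axis=1)
            v_k = np.nanmean((sub - m[:, None]) ** 2, axis=1)
            if ddof:
                v_k = v_k * n_k / np.maximum(n_k - ddof, 1)
        v_s_num += n_k * np.where(n_k > 0, v_k, 0.0)
        n_tot += n_k
    if bad.any():
        raise ValueError("some variants have a population entirely missing")
    v_s = v_s_num / n_tot
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mt = np.nanmean(d, axis=1)
        v_t = np.nanmean((d - mt[:, None]) ** 2, axis=1)
        if ddof:
            nall = called.sum(axis=1)
            v_t = v_t * nall / np.maximum(nall - ddof, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (v_t - v_s) / v_t
    raw[v_t == 0] = np.nan
    return v_t, v_s, raw


def vst_scan(
    gm: GenotypeMatrix,
    pops: PopulationSpec,
    top_fraction: float = 0.01,
    ddof: int = 0,
) -> tuple[pd.DataFrame, pd.Index]:
    """Genome-wide V_ST with top-percentile selection.

    Ranks defined V_ST values descending; the threshold is the value at rank
    ceil(top_fraction * n_defined) and ties at the threshold are included.
    Returns the per-SV table (chrom, pos, V_ST columns, selected flag) and the
    selected ids.
    """
    v_t, v_s, raw = _vst_vectorised(gm, pops, ddof=ddof)
    floored = np.where(np.isnan(raw), np.nan, np.maximum(raw, 0.0))
    table = pd.DataFrame(
        {
            "id": gm.variants["id"],
            "chrom": gm.variants["chrom"],
            "pos": gm.variants["pos"],
            "v_t": v_t,
            "v_s": v_s,
            "v_st_raw": raw,
            "v_st": floored,
        }
    )
    defined = ~np.isnan(floored)
    n_def = int(defined.sum())
    selected = np.zeros(len(table), dtype=bool)
    if n_def:
        k = max(1, math.ceil(top_fraction * n_def))
        thr = np.sort(floored[defined])[::-1][k - 1]
        selected = defined & (floored >= thr)
    table["selected"] = selected
    return table, pd.Index(table.loc[selected, "id"])


@dataclass
class SweepRegionSet:
    regions: list[GenomicInterval]
    source: str = "fst+pi_ratio"

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def contains_point(self, chrom: str, pos: int) -> bool:
        return any(r.chrom == chrom and r.start <= pos < r.end for r in self.regions)


def _top_mask(values: np.ndarray, top_fraction: float) -> np.ndarray:
    defined = ~np.isnan(values)
    n = int(defined.sum())
    if n == 0:
        return np.zeros(len(values), dtype=bool)
    k = max(1, math.ceil(top_fraction * n))
    thr = np.sort(values[defined])[::-1][k - 1]
    return defined & (values >= thr)


def sweep_regions(
    fst_track: WindowTrack,
    pi_track_pop1: WindowTrack,
    pi_track_pop2: WindowTrack,
    top_fraction: float = 0.05,
) -> SweepRegionSet:
    """Sweep regions from SNP tracks: windows in the top 5% of F_ST *and* the
    top 5% of the pi ratio (pop1 / pop2; diversity loss in pop2 pushes the
    ratio up) are sweep windows; consecutive windows merge."""
    if not (fst_track.same_grid(pi_track_pop1) and fst_track.same_grid(pi_track_pop2)):
        raise ValueError("window grids differ between tracks")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = pi_track_pop1.values / pi_track_pop2.values
    ratio[~np.isfinite(ratio)] = np.nan
    mask = _top_mask(fst_track.values, top_fraction) & _top_mask(ratio, top_fraction)
    regions: list[GenomicInterval] = []
    cur = None
    for chrom, s, e, m in zip(
        fst_track.chroms, fst_track.starts, fst_track.ends, mask
    ):
        if not m:
            continue
        if cur is not None and chrom == cur[0] and s <= cur[2]:
            cur[2] = max(cur[2], e)
        else:
            if cur is not None:
                regions.append(GenomicInterval(cur[0], cur[1], cur[2]))
            cur = [chrom, int(s), int(e)]
    if cur is not None:
        regions.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return SweepRegionSet(regions)


def sweep_overlap_enrichment(
    selected_ids: pd.Index,
    all_svs: pd.DataFrame,
    sweeps: SweepRegionSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test for selected-SV enrichment in sweep regions.

    The null permutes SV *identity*: draw |selected| SVs uniformly without
    replacement from the full catalogue and recount sweep overlaps, which
    preserves the positional composition of the background.  ``all_svs``
    needs columns id, chrom, pos.  fold = observed / mean(null); empirical
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    ids = all_svs["id"].to_numpy()
    if not set(selected_ids).issubset(ids):
        raise ValueError("selected SVs must be a subset of the catalogue")
    in_sweep = np.array(
        [
            sweeps.contains_point(c, p)
            for c, p in zip(all_svs["chrom"], all_svs["pos"])
        ]
    )
    sel_mask = np.isin(ids, np.asarray(selected_ids))
    k = int(sel_mask.sum())
    if k == 0 or k > len(ids):
        raise ValueError("invalid selected set size")
    observed = int(in_sweep[sel_mask].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    n = len(ids)
    for i in range(n_perm):
        null[i] = int(in_sweep[rng.choice(n, size=k, replace=False)].sum())
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else math.inf
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return {
        "observed": observed,
        "null_mean": null_mean,
        "null_sd": float(null.std()),
        "fold": fold,
        "p": p,
        "n_perm": n_perm,
    }


def tag_sv_search(
    sv_gm: GenotypeMatrix,
    snp_gm: GenotypeMatrix,
    tag_snps: list[str],
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """SVs in strong LD with tag SNPs.

    For each tag SNP, every SV within ``window`` bp on the same chromosome
    with dosage r^2 > ``r2_threshold`` (computed over shared individuals) is
    reported.  Unknown tag ids are skipped with a warning.
    """
    shared = [i for i in snp_gm.individuals if i in set(sv_gm.individuals)]
    if not shared:
        raise ValueError("no shared individuals between SNP and SV matrices")
    snp_sub = snp_gm.subset_individuals(shared)
    sv_sub = sv_gm.subset_individuals(shared)
    snp_idx = {v: i for i, v in enumerate(snp_sub.variants["id"])}
    rows = []
    sv_chrom = sv_sub.variants["chrom"].to_numpy()
    sv_pos = sv_sub.variants["pos"].to_numpy()
    for tag in tag_snps:
        if tag not in snp_idx:
            warnings.warn(f"tag SNP {tag!r} not in SNP matrix; skipped")
            continue
        ti = snp_idx[tag]
        chrom = snp_sub.variants.at[ti, "chrom"]
        pos = snp_sub.variants.at[ti, "pos"]
        near = np.flatnonzero((sv_chrom == chrom) & (np.abs(sv_pos - pos) <= window))
        for j in near:
            r2 = ld_r2(snp_sub.dosages[ti], sv_sub.dosages[j])
            if not math.isnan(r2) and r2 > r2_threshold:
                rows.append(
                    {
                        "tag_snp": tag,
                        "sv_id": sv_sub.variants.at[j, "id"],
                        "chrom": chrom,
                        "snp_pos": int(pos),
                        "sv_pos": int(sv_pos[j]),
                        "r2": r2,
                    }
                )
    return pd.DataFrame(rows, columns=["tag_snp", "sv_id", "chrom", "snp_pos", "sv_pos", "r2"])
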