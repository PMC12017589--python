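"""Windowed population-genetic statistics on biallelic dosage matrices.

Implements the SNP summary tracks used to characterise diversity along the
genome — nucleotide diversity (pi), transition/transversion ratio, Tajima's D
and Weir-Cockerham F_ST — together with genotype QC, linkage disequilibrium
(r^2), and PLINK-style ``--indep-pairwise`` LD pruning.  Dosages are 0/1/2
alternate-allele counts with NaN for missing calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GenotypeMatrix:
    """Biallelic variants x individuals dosage matrix.

    ``variants`` must contain columns chrom, pos (0-based), id, ref, alt and
    optionally mean_depth.  ``dosages`` is float with NaN = missing.
    """

    variants: pd.DataFrame
    individuals: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.individuals)):
            raise ValueError("dosage shape does not match variants x individuals")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.variants.loc[np.asarray(mask)].reset_index(drop=True),
            list(self.individuals),
            self.dosages[np.asarray(mask)],
        )

    def subset_individuals(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(n) for n in names]
        return GenotypeMatrix(self.variants.copy(), list(names), self.dosages[:, idx])

    def allele_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (called chromosome count, alt allele count)."""
        called = 2 * np.sum(~np.isnan(self.dosages), axis=1)
        ac = np.nansum(self.dosages, axis=1)
        return called, ac


@dataclass
class PopulationSpec:
    """Individual -> population assignment."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        sizes = self.sizes
        for pop, n in sizes.items():
            if n < 2:
                raise ValueError(f"population {pop!r} has {n} < 2 individuals")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p)
        return list(seen)

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.assignment.values():
            out[p] = out.get(p, 0) + 1
        return out

    def indices(self, individuals: list[str]) -> dict[str, np.ndarray]:
        """Column indices per population for a given individual ordering."""
        out: dict[str, list[int]] = {p: [] for p in self.populations}
        for i, name in enumerate(individuals):
            if name in self.assignment:
                out[self.assignment[name]].append(i)
        return {p: np.asarray(ix, dtype=int) for p, ix in out.items() if ix}


@dataclass
class WindowTrack:
    """Fixed-size sliding windows with one value per window.

    Windows are sorted by (chrom, start); the last window on a chromosome may
    be truncated.  NaN marks windows where the statistic is undefined.
    """

    window: int
    step: int
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == len(self.values) == n):
            raise ValueError("window arrays must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            len(self) == len(other)
            and (self.chroms == other.chroms).all()
            and (self.starts == other.starts).all()
            and (self.ends == other.ends).all()
        )

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends, name: self.values}
        )


def make_windows(chrom_lengths: dict[str, int], window: int, step: int):
    """Sliding-window grid arrays (chroms, starts, ends) over a genome."""
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    chroms, starts, ends = [], [], []
    for chrom, length in chrom_lengths.items():
        pos = 0
        while pos < length:
            chroms.append(chrom)
            starts.append(pos)
            ends.append(min(pos + window, length))
            pos += step
    return (
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=int),
        np.asarray(ends, dtype=int),
    )


# ---------------------------------------------------------------------------
# QC and LD


def qc_filter(
    gm: GenotypeMatrix,
    min_depth: float = 5.0,
    max_missing: float = 0.05,
    min_maf: float = 0.1,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Remove variants failing depth, missingness or MAF thresholds.

    A variant is dropped when mean depth < ``min_depth`` (rule skipped when no
    depth column is present), missing fraction > ``max_missing``, or minor
    allele frequency < ``min_maf``.  The report counts variants failing each
    rule (a variant may count toward several).
    """
    n = gm.n_variants
    miss_frac = np.mean(np.isnan(gm.dosages), axis=1) if n else np.empty(0)
    called, ac = gm.allele_stats()
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(called > 0, ac / called, np.nan)
    maf = np.minimum(af, 1 - af)

    fail_depth = np.zeros(n, dtype=bool)
    if "mean_depth" in gm.variants.columns and gm.variants["mean_depth"].notna().any():
        fail_depth = gm.variants["mean_depth"].to_numpy(dtype=float) < min_depth
    fail_miss = miss_frac > max_missing
    fail_maf = ~(maf >= min_maf)  # NaN MAF (no calls) also fails

    keep = ~(fail_depth | fail_miss | fail_maf)
    report = {
        "depth": int(fail_depth.sum()),
        "missing": int(fail_miss.sum()),
        "maf": int(fail_maf.sum()),
        "removed": int((~keep).sum()),
        "retained": int(keep.sum()),
    }
    return gm.subset_variants(keep), report


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairs with a missing value in either vector are dropped; NaN is returned
    when fewer than two complete pairs remain or either vector is monomorphic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_threshold: float = 0.1,
) -> list[str]:
    """PLINK-style ``--indep-pairwise`` greedy LD pruning.

    Variants must be position-sorted.  Within each ``window``-variant block,
    any pair with r^2 > threshold drops the later variant; the block then
    slides by ``step`` variants.  Deterministic by construction.
    """
    order = gm.variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    if not np.array_equal(order, np.arange(gm.n_variants)):
        raise ValueError("variants must be sorted by position before pruning")
    removed = np.zeros(gm.n_variants, dtype=bool)
    start = 0
    while True:
        idx = [i for i in range(start, min(start + window, gm.n_variants)) if not removed[i]]
        for ii, i in enumerate(idx):
            if removed[i]:
                continue
            for j in idx[ii + 1 :]:
                if removed[j] or gm.variants.at[i, "chrom"] != gm.variants.at[j, "chrom"]:
                    continue
                r2 = ld_r2(gm.dosages[i], gm.dosages[j])
                if not math.isnan(r2) and r2 > r2_threshold:
                    removed[j] = True
        if start + window >= gm.n_variants:
            break
        start += step
    return [gm.variants.at[i, "id"] for i in range(gm.n_variants) if not removed[i]]


# ---------------------------------------------------------------------------
# Windowed statistics

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _site_pi(called: np.ndarray, ac: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference 2*p*(1-p)*n/(n-1) from allele counts."""
    n = called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * ac * (n - ac) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def _window_site_lists(gm: GenotypeMatrix, chroms, starts, ends):
    """Indices of variant sites falling in each window."""
    pos = gm.variants["pos"].to_numpy()
    vchrom = gm.variants["chrom"].to_numpy()
    out = []
    for chrom, s, e in zip(chroms, starts, ends):
        out.append(np.flatnonzero((vchrom == chrom) & (pos >= s) & (pos < e)))
    return out


def pi_windows(
    gm: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    step: int = 10_000,
) -> WindowTrack:
    """Windowed nucleotide diversity: sum of per-site pairwise differences
    divided by the window span in bp (monomorphic sites contribute zero)."""
    chroms, starts, ends = make_windows(chrom_lengths, window, step)
    called, ac = gm.allele_stats()
    site_pi = _site_pi(called, ac)
    vals = np.empty(len(chroms))
    for w, idx in enumerate(_window_site_lists(gm, chroms, starts, ends)):
        sp = site_pi[idx]
        sp = sp[~np.isnan(sp)]
        vals[w] = sp.sum() / (ends[w] - starts[w])
    return WindowTrack(window, step, chroms, starts, ends, vals)


def tstv_windows(
    gm: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    step: int = 10_000,
) -> WindowTrack:
    """Windowed transition/transversion site-count ratio (NaN when the window
    has no transversions)."""
    chroms, starts, ends = make_windows(chrom_lengths, window, step)
    ref = gm.variants["ref"].str.upper().to_numpy()
    alt = gm.variants["alt"].str.upper().to_numpy()
    is_ts = np.array([(r, a) in _TRANSITIONS for r, a in zip(ref, alt)])
    vals = np.empty(len(chroms))
    for w, idx in enumerate(_window_site_lists(gm, chroms, starts, ends)):
        ts = int(is_ts[idx].sum())
        tv = len(idx) - ts
        vals[w] = ts / tv if tv > 0 else np.nan
    return WindowTrack(window, step, chroms, starts, ends, vals)


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of the 1989 formulation plus a1 via closure."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d_windows(
    gm: GenotypeMatrix,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    step: int = 10_000,
) -> WindowTrack:
    """Windowed Tajima's D contrasting mean pairwise diversity with the
    Watterson estimate from segregating sites; NaN when S = 0.

    The sample size n is the modal number of called chromosomes across the
    window's segregating sites (sites are near-complete after QC).
    """
    chroms, starts, ends = make_windows(chrom_lengths, window, step)
    called, ac = gm.allele_stats()
    site_pi = _site_pi(called, ac)
    seg = (ac > 0) & (ac < called)
    vals = np.full(len(chroms), np.nan)
    for w, idx in enumerate(_window_site_lists(gm, chroms, starts, ends)):
        idx = idx[seg[idx]]
        S = len(idx)
        if S == 0:
            continue
        ns = called[idx]
        n = int(np.bincount(ns.astype(int)).argmax())
        if n < 4:
            continue
        a1 = sum(1.0 / i for i in range(1, n))
        theta_pi = float(np.nansum(site_pi[idx]))
        e1, e2 = _tajima_constants(n)
        var = e1 * S + e2 * S * (S - 1)
        if var <= 0:
            continue
        vals[w] = (theta_pi - S / a1) / math.sqrt(var)
    return WindowTrack(window, step, chroms, starts, ends, vals)


def _wc_components(gm: GenotypeMatrix, pops: PopulationSpec):
    """Weir-Cockerham (1984) per-site variance components a, b, c for two or
    more populations, from diploid dosages (dosage 1 = heterozygote)."""
    groups = pops.indices(gm.individuals)
    r = len(groups)
    if r < 2:
        raise ValueError("need at least two populations")
    nmat = np.stack([np.sum(~np.isnan(gm.dosages[:, ix]), axis=1) for ix in groups.values()], axis=1).astype(float)
    pmat = np.stack(
        [np.nansum(gm.dosages[:, ix], axis=1) for ix in groups.values()], axis=1
    )
    hmat = np.stack(
        [np.nansum(gm.dosages[:, ix] == 1.0, axis=1) for ix in groups.values()], axis=1
    ).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pmat = pmat / (2.0 * nmat)
        hmat = hmat / nmat
        nbar = nmat.sum(axis=1) / r
        nc = (r * nbar - (nmat**2).sum(axis=1) / (r * nbar)) / (r - 1)
        pbar = (nmat * pmat).sum(axis=1) / (r * nbar)
        s2 = (nmat * (pmat - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (nmat * hmat).sum(axis=1) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    valid = (nmat >= 1).all(axis=1) & (nbar > 1)
    return a, b, c, valid


def fst_windows(
    gm: GenotypeMatrix,
    pops: PopulationSpec,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    step: int = 10_000,
) -> WindowTrack:
    """Windowed Weir-Cockerham F_ST: ratio of summed variance components
    sum(a) / sum(a+b+c) over the window's sites.  Negative estimates are
    reported as-is; windows with no usable site are NaN."""
    chroms, starts, ends = make_windows(chrom_lengths, window, step)
    a, b, c, valid = _wc_components(gm, pops)
    vals = np.full(len(chroms), np.nan)
    for w, idx in enumerate(_window_site_lists(gm, chroms, starts, ends)):
        idx = idx[valid[idx]]
        if len(idx) == 0:
            continue
        denom = np.nansum(a[idx] + b[idx] + c[idx])
        if denom != 0 and not np.isnan(denom):
            vals[w] = np.nansum(a[idx]) / denom
    return WindowTrack(window, step, chroms, starts, ends, vals)


def fst_sites(gm: GenotypeMatrix, pops: PopulationSpec) -> np.ndarray:
    """Per-site Weir-Cockerham F_ST (a / (a+b+c)), NaN where undefined."""
    a, b, c, valid = _wc_components(gm, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = a / (a + b + c)
    out[~valid] = np.nan
    return out


def track_correlation(a: WindowTrack, b: WindowTrack) -> tuple[float, float]:
    """Missing-aware Pearson correlation between two tracks on one grid."""
    if not a.same_grid(b):
        raise ValueError("window grids differ")
    ok = ~(np.isnan(a.values) | np.isnan(b.values))
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete window pairs")
    r, p = sps.pearsonr(a.values[ok], b.values[ok])
    return float(r), float(p)
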