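"""Gene-family occupancy analysis: pan/core classification and accumulation.

A gene-family occupancy matrix records, for every orthologous gene family,
which genomes carry at least one member.  Families are binned by occupancy
into *core* (all genomes), *softcore* (just below all), *dispensable*
(intermediate) and *private* (one genome), and pan/core accumulation curves
describe how the family universe grows (pan) and the universally shared set
shrinks (core) as genomes are added in random order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import percentages

CLASS_ORDER = ("core", "softcore", "dispensable", "private")


@dataclass
class OccupancyMatrix:
    """Binary family x genome presence with per-cell gene member counts."""

    families: list[str]
    genomes: list[str]
    presence: np.ndarray  # bool, (n_families, n_genomes)
    counts: np.ndarray = None  # int member counts, same shape

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.counts is None:
            self.counts = self.presence.astype(int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.presence.shape != (len(self.families), len(self.genomes)):
            raise ValueError("presence shape does not match labels")
        if self.counts.shape != self.presence.shape:
            raise ValueError("counts shape does not match presence")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("genome ids must be unique")
        if len(set(self.families)) != len(self.families):
            raise ValueError("family ids must be unique")
        if self.presence.size and not self.presence.any(axis=1).all():
            missing = [f for f, row in zip(self.families, self.presence) if not row.any()]
            raise ValueError(f"families present in no genome: {missing[:5]}")

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def occupancy(self) -> np.ndarray:
        """Number of genomes carrying each family."""
        return self.presence.sum(axis=1)


def default_bounds(n_genomes: int) -> dict[str, tuple[int, int]]:
    """Occupancy bands for gene families: core = n, softcore = [n-2, n-1],
    dispensable = [2, n-3], private = 1 (absolute counts, inclusive)."""
    if n_genomes < 5:
        raise ValueError("default gene-family bands need >= 5 genomes")
    return {
        "core": (n_genomes, n_genomes),
        "softcore": (n_genomes - 2, n_genomes - 1),
        "dispensable": (2, n_genomes - 3),
        "private": (1, 1),
    }


def _validate_bounds(bounds: dict[str, tuple[int, int]], n: int) -> None:
    covered = np.zeros(n + 1, dtype=int)
    for lo, hi in bounds.values():
        if lo > hi:
            raise ValueError(f"empty class band [{lo}, {hi}]")
        covered[lo : hi + 1] += 1
    if (covered[1:] != 1).any():
        raise ValueError("class bands must partition 1..n_genomes with no overlap")


@dataclass
class FamilyClassSummary:
    counts: dict[str, int]
    percent: dict[str, float]
    bounds: dict[str, tuple[int, int]]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def core_softcore_percent(self) -> float:
        from .core import round_half_up

        tot = self.total
        return round_half_up(
            100.0 * (self.counts["core"] + self.counts["softcore"]) / tot
        )


def classify_families(
    occ: OccupancyMatrix, bounds: dict[str, tuple[int, int]] | None = None
) -> tuple[pd.Series, FamilyClassSummary]:
    """Assign each family its occupancy class; return classes and a summary.

    Returns a Series indexed by family id plus a :class:`FamilyClassSummary`
    with counts and half-up rounded percentages.
    """
    if bounds is None:
        bounds = default_bounds(occ.n_genomes)
    _validate_bounds(bounds, occ.n_genomes)
    k = occ.occupancy
    classes = np.empty(len(occ.families), dtype=object)
    for name, (lo, hi) in bounds.items():
        classes[(k >= lo) & (k <= hi)] = name
    ser = pd.Series(classes, index=pd.Index(occ.families, name="family"), name="class")
    counts = {c: int((classes == c).sum()) for c in CLASS_ORDER if c in bounds}
    summary = FamilyClassSummary(counts=counts, percent=percentages(counts), bounds=dict(bounds))
    return ser, summary


def class_summary_from_counts(counts: dict[str, int]) -> FamilyClassSummary:
    """Summary (percentages) straight from per-class family counts."""
    return FamilyClassSummary(counts=dict(counts), percent=percentages(counts), bounds={})


def accumulation_curves(
    occ: OccupancyMatrix, n_permutations: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Pan/core accumulation over random genome orderings.

    For each ordering, after adding the k-th genome the pan size is the number
    of families seen in at least one of the k genomes and the core size the
    number present in all k.  Returns per-k mean/min/max of both curves.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    n = occ.n_genomes
    pan = np.empty((n_permutations, n), dtype=int)
    core = np.empty((n_permutations, n), dtype=int)
    pres = occ.presence
    for p in range(n_permutations):
        order = rng.permutation(n)
        cols = pres[:, order]
        any_acc = np.logical_or.accumulate(cols, axis=1)
        all_acc = np.logical_and.accumulate(cols, axis=1)
        pan[p] = any_acc.sum(axis=0)
        core[p] = all_acc.sum(axis=0)
    return pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "pan_mean": pan.mean(axis=0),
            "pan_min": pan.min(axis=0),
            "pan_max": pan.max(axis=0),
            "core_mean": core.mean(axis=0),
            "core_min": core.min(axis=0),
            "core_max": core.max(axis=0),
        }
    )


def per_genome_class_counts(occ: OccupancyMatrix, classes: pd.Series) -> pd.DataFrame:
    """Gene (member) counts per genome split by family class.

    Uses per-cell member counts, so the units are genes rather than families;
    also reports each genome's core+softcore gene fraction.
    """
    cls = classes.reindex(occ.families).to_numpy()
    rows = {}
    for c in CLASS_ORDER:
        mask = cls == c
        rows[c] = occ.counts[mask].sum(axis=0)
    df = pd.DataFrame(rows, index=pd.Index(occ.genomes, name="genome"))
    total = df.sum(axis=1)
    df["core_softcore_fraction"] = (df["core"] + df["softcore"]) / total.where(total > 0)
    return df
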