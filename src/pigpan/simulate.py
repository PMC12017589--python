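"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments (including the seed) and
returns both the simulated dataset and a truth object covering every emitted
item, so downstream operations can be validated by truth-table recovery
rather than by re-deriving expectations from the simulator's internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, SVRecord
from .enrichment import FEATURE_CLASSES, FeatureAnnotation
from .numt import Hit
from .pangene import OccupancyMatrix
from .popgen import GenotypeMatrix, PopulationSpec

DEFAULT_CLASS_MIX = {"core": 0.47, "softcore": 0.18, "dispensable": 0.34, "private": 0.01}


# ---------------------------------------------------------------------------
# Gene-family occupancy


@dataclass
class OccupancyTruth:
    family_class: dict[str, str]
    seed: int


def _apportion(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items over the mix."""
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    raw = {k: n * v for k, v in mix.items()}
    base = {k: int(math.floor(x)) for k, x in raw.items()}
    rem = n - sum(base.values())
    order = sorted(mix, key=lambda k: raw[k] - base[k], reverse=True)
    for k in order[:rem]:
        base[k] += 1
    return base


def simulate_occupancy(
    n_genomes: int = 18,
    class_mix: dict[str, float] | None = None,
    n_families: int = 1000,
    seed: int = 0,
    mean_extra_members: float = 0.1,
) -> tuple[OccupancyMatrix, OccupancyTruth]:
    """Occupancy matrix with a planted core/softcore/dispensable/private mix.

    Families draw their genome count from their class's occupancy band
    (core = n, softcore = [n-2, n-1], dispensable = [2, n-3], private = 1)
    and their carrier genomes uniformly.  Cell member counts are 1 plus a
    Poisson(``mean_extra_members``) surplus.
    """
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    bands = {
        "core": (n_genomes, n_genomes),
        "softcore": (n_genomes - 2, n_genomes - 1),
        "dispensable": (2, n_genomes - 3),
        "private": (1, 1),
    }
    for cls, share in mix.items():
        lo, hi = bands[cls]
        if share > 0 and lo > hi:
            raise ValueError(f"class band {cls} empty for n_genomes={n_genomes}")
    rng = np.random.default_rng(seed)
    n_per_class = _apportion(n_families, mix)
    families, classes, rows_p, rows_c = [], [], [], []
    i = 0
    for cls in ("core", "softcore", "dispensable", "private"):
        for _ in range(n_per_class.get(cls, 0)):
            lo, hi = bands[cls]
            k = int(rng.integers(lo, hi + 1))
            carriers = rng.choice(n_genomes, size=k, replace=False)
            pres = np.zeros(n_genomes, dtype=bool)
            pres[carriers] = True
            cnt = np.zeros(n_genomes, dtype=int)
            cnt[carriers] = 1 + rng.poisson(mean_extra_members, size=k)
            fam = f"OG{i:06d}"
            families.append(fam)
            classes.append(cls)
            rows_p.append(pres)
            rows_c.append(cnt)
            i += 1
    genomes = [f"genome{g:02d}" for g in range(n_genomes)]
    occ = OccupancyMatrix(families, genomes, np.asarray(rows_p), np.asarray(rows_c))
    truth = OccupancyTruth(dict(zip(families, classes)), seed)
    return occ, truth


# ---------------------------------------------------------------------------
# Per-genome SV call sets with planted redundancy


@dataclass
class SVCallsetTruth:
    group_of_call: dict[str, str]      # call id -> redundancy group id
    group_carriers: dict[str, list[str]]
    group_type: dict[str, str]
    seed: int


DEFAULT_GENOME_MODEL = {"chr1": 30_000_000, "chr2": 20_000_000, "chrX": 10_000_000}
#: Per-genome expected SV counts by type; the type ratios follow the relative
#: abundance of PAVs, inversions and translocations in assembly comparisons.
DEFAULT_SV_RATES = {"absence": 900, "presence": 900, "inversion": 100, "translocation_intra": 70, "translocation_inter": 30}
#: Log-normal length modes: PAVs 1-2 kb, inversions 10-20 kb, translocations 2-3 kb.
DEFAULT_LENGTH_PARAMS = {
    "absence": (8.3, 1.0),
    "presence": (8.3, 1.0),
    "inversion": (10.2, 0.8),
    "translocation_intra": (8.1, 0.5),
    "translocation_inter": (8.1, 0.5),
}


def simulate_sv_callsets(
    n_genomes: int = 6,
    genome_model: dict[str, int] | None = None,
    rates: dict[str, int] | None = None,
    length_params: dict[str, tuple[float, float]] | None = None,
    redundancy: float = 0.5,
    jitter: int = 10,
    seed: int = 0,
) -> tuple[dict[str, list[SVRecord]], SVCallsetTruth]:
    """Per-genome SV call sets containing replicated (redundant) calls.

    A pool of SV groups is generated; with probability ``redundancy`` a group
    is shared by 2..n genomes, otherwise private to one.  Each carrier's call
    jitters both breakpoints together by up to ``jitter`` bp, so planted
    groups stay mergeable under a 50% reciprocal-overlap rule.  Distinct
    groups of the same type are placed without mutual overlap (and point-type
    groups at least 200 bp + 2x jitter apart), so every planted group remains
    a distinguishable catalogue record — the truth table stays a valid merge
    oracle by construction.
    """
    genome_model = dict(genome_model or DEFAULT_GENOME_MODEL)
    rates = dict(rates or DEFAULT_SV_RATES)
    length_params = dict(length_params or DEFAULT_LENGTH_PARAMS)
    if any(v <= 0 for v in rates.values()):
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(genome_model)
    clens = np.asarray([genome_model[c] for c in chroms])
    genomes = [f"genome{g:02d}" for g in range(n_genomes)]
    callsets: dict[str, list[SVRecord]] = {g: [] for g in genomes}
    truth = SVCallsetTruth({}, {}, {}, seed)
    gid = 0
    placed: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for sv_type, rate in rates.items():
        mu, sigma = length_params[sv_type]
        # expected calls per genome ~= rate; with sharing, fewer groups suffice
        exp_carriers = (1 - redundancy) + redundancy * (2 + n_genomes) / 2
        n_groups = max(1, int(round(rate * n_genomes / exp_carriers)))
        point_type = sv_type not in ("absence", "inversion")
        for _ in range(n_groups):
            length = max(50, int(rng.lognormal(mu, sigma)))
            if jitter >= length:
                raise ValueError("jitter must be smaller than the SV length")
            for _attempt in range(200):
                ci = int(rng.integers(len(chroms)))
                max_start = clens[ci] - length - jitter - 1
                if max_start <= jitter:
                    raise ValueError("chromosome shorter than maximum SV length")
                start = int(rng.integers(jitter, max_start))
                # keep same-type groups disjoint (incl. jitter margin) so each
                # planted group stays a distinct mergeable unit
                span = (start - jitter, start + jitter + (1 if point_type else length))
                pad = 200 if point_type else 0
                taken = placed.setdefault((ci, sv_type), [])
                if all(span[0] - pad >= e or span[1] + pad <= s for s, e in taken):
                    taken.append(span)
                    break
            else:
                raise ValueError("could not place SV group without collision")
            if redundancy > 0 and rng.random() < redundancy and n_genomes > 1:
                k = int(rng.integers(2, n_genomes + 1))
            else:
                k = 1
            carriers = rng.choice(n_genomes, size=k, replace=False)
            group = f"grp{gid:06d}"
            gid += 1
            truth.group_type[group] = sv_type
            truth.group_carriers[group] = [genomes[c] for c in carriers]
            mate = None
            if sv_type.startswith("translocation"):
                mchrom = (
                    ci
                    if sv_type == "translocation_intra"
                    else int(rng.choice([j for j in range(len(chroms)) if j != ci]))
                )
                mpos = int(rng.integers(jitter, clens[mchrom] - jitter - 2))
                mate = GenomicInterval(chroms[mchrom], mpos, mpos + 1)
            for c in carriers:
                dj = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                s = start + dj
                if sv_type in ("absence", "inversion"):
                    iv = GenomicInterval(chroms[ci], s, s + length)
                else:
                    iv = GenomicInterval(chroms[ci], s, s + 1)
                call_id = f"{group}_{genomes[c]}"
                callsets[genomes[c]].append(
                    SVRecord(call_id, iv, sv_type, length, genomes[c], mate=mate)
                )
                truth.group_of_call[call_id] = group
    return callsets, truth


# ---------------------------------------------------------------------------
# Two-population genotypes with planted differentiation


@dataclass
class GenotypeTruth:
    differentiated: np.ndarray  # bool per locus
    freqs: pd.DataFrame         # per-locus allele frequency per population
    seed: int


def simulate_population_genotypes(
    n_per_pop: tuple[int, int] = (50, 50),
    n_loci: int = 10_000,
    differentiated_fraction: float = 0.01,
    divergence: float = 0.8,
    missing_rate: float = 0.0,
    seed: int = 0,
    pop_names: tuple[str, str] = ("EUR", "ASN"),
    chrom: str = "chr1",
    spacing: int = 1000,
) -> tuple[GenotypeMatrix, PopulationSpec, GenotypeTruth]:
    """Two-population dosage matrix with a planted differentiated fraction.

    Undifferentiated loci share one allele frequency (uniform on [0.05,
    0.95]); differentiated loci get frequencies separated by ``divergence``
    with the high population chosen at random.  Dosages are Binomial(2, p)
    per individual (Hardy-Weinberg) and missingness is applied uniformly.
    """
    if not (0 <= differentiated_fraction <= 1):
        raise ValueError("differentiated_fraction outside [0, 1]")
    if not (0 <= divergence <= 1):
        raise ValueError("divergence outside [0, 1]")
    rng = np.random.default_rng(seed)
    n1, n2 = n_per_pop
    n_diff = int(round(differentiated_fraction * n_loci))
    diff = np.zeros(n_loci, dtype=bool)
    diff[rng.choice(n_loci, size=n_diff, replace=False)] = True
    p1 = np.empty(n_loci)
    p2 = np.empty(n_loci)
    shared = rng.uniform(0.05, 0.95, size=n_loci)
    p1[~diff] = shared[~diff]
    p2[~diff] = shared[~diff]
    base = rng.uniform(0.0, 1.0 - divergence, size=n_loci)
    hi_first = rng.random(n_loci) < 0.5
    p1[diff] = np.where(hi_first[diff], base[diff] + divergence, base[diff])
    p2[diff] = np.where(hi_first[diff], base[diff], base[diff] + divergence)
    dos1 = rng.binomial(2, p1[:, None], size=(n_loci, n1)).astype(float)
    dos2 = rng.binomial(2, p2[:, None], size=(n_loci, n2)).astype(float)
    dosages = np.concatenate([dos1, dos2], axis=1)
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan
    individuals = [f"{pop_names[0]}_{i}" for i in range(n1)] + [
        f"{pop_names[1]}_{i}" for i in range(n2)
    ]
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, size=n_loci)
    # transition-biased alternate alleles (Ts:Tv about 2:1)
    partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    alt = np.array(
        [
            partner[r] if rng.random() < 0.67 else rng.choice([b for b in bases if b != r and b != partner[r]])
            for r in ref
        ]
    )
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n_loci) * spacing,
            "id": [f"var{i:06d}" for i in range(n_loci)],
            "ref": ref,
            "alt": alt,
            "mean_depth": 30.0,
        }
    )
    gm = GenotypeMatrix(variants, individuals, dosages)
    pops = PopulationSpec(
        {ind: (pop_names[0] if i < n1 else pop_names[1]) for i, ind in enumerate(individuals)}
    )
    truth = GenotypeTruth(diff, pd.DataFrame({"p1": p1, "p2": p2}), seed)
    return gm, pops, truth


# ---------------------------------------------------------------------------
# NUMT landscape


@dataclass
class NUMTTruth:
    ages: list[float]
    mt_intervals: list[tuple[int, int]]
    nuclear_intervals: list[tuple[str, int, int]]
    presence: np.ndarray  # bool, (n_numts, n_assemblies)
    n_mutations_in_span: list[int]
    age_estimable: list[bool]
    seed: int


def simulate_numt_landscape(
    n_assemblies: int = 10,
    insertions: list[tuple[float, int]] | None = None,
    mt_length: int = 16_000,
    clock: float = 0.01,
    t_div: float = 9.7,
    presence_prob: float = 0.7,
    nuclear_length: int = 2_000_000,
    seed: int = 0,
) -> tuple[dict, NUMTTruth]:
    """NUMT-bearing nuclear assemblies whose insertion ages are known.

    The mt lineage accrues mutations uniformly in time over ``t_div`` MY at
    ``clock`` substitutions/site/MY; the outgroup keeps the ancestral allele
    at every mutated site.  A NUMT of age ``a`` copies the mt state at that
    age, i.e. carries exactly the mutations older than ``a``.  Assemblies
    share the reference nuclear coordinate frame; each NUMT is present per
    assembly with ``presence_prob`` (always in at least one), absent copies
    keeping the backbone sequence.  Returns a dict with the assembly FASTA
    dicts, per-assembly hit tables, modern/doubled/outgroup mtDNA, plus truth.
    """
    if clock <= 0:
        raise ValueError("clock must be positive")
    rng = np.random.default_rng(seed)
    if insertions is None:
        insertions = [
            (float(rng.uniform(0, t_div)), int(rng.integers(500, 1001)))
            for _ in range(50)
        ]
    for age, _ in insertions:
        if age > t_div:
            raise ValueError("insertion age exceeds outgroup divergence")
    bases = np.array(list("ACGT"))
    anc = rng.integers(0, 4, size=mt_length)
    n_mut = rng.poisson(clock * mt_length * t_div)
    mut_pos = rng.choice(mt_length, size=min(n_mut, mt_length), replace=False)
    mut_time = rng.uniform(0, t_div, size=len(mut_pos))  # MY before present
    derived = (anc[mut_pos] + rng.integers(1, 4, size=len(mut_pos))) % 4
    modern = anc.copy()
    modern[mut_pos] = derived
    outgroup = anc  # ancestral allele at every mutated site

    # nuclear backbone shared by all assemblies
    backbone = rng.integers(0, 4, size=nuclear_length)
    n_numts = len(insertions)
    gap = nuclear_length // (n_numts + 1)
    presence = np.zeros((n_numts, n_assemblies), dtype=bool)
    mt_ivs, nuc_ivs, n_in_span, estimable = [], [], [], []
    numt_seqs = []
    for i, (age, length) in enumerate(insertions):
        s_mt = int(rng.integers(0, mt_length - length))
        e_mt = s_mt + length
        in_span = (mut_pos >= s_mt) & (mut_pos < e_mt)
        numt = anc[s_mt:e_mt].copy()
        older = in_span & (mut_time > age)  # mutations predating the insertion
        numt[mut_pos[older] - s_mt] = derived[older]
        numt_seqs.append(numt)
        mt_ivs.append((s_mt, e_mt))
        n_in_span.append(int(in_span.sum()))
        estimable.append(bool(in_span.sum() > 0))
        pos = gap * (i + 1)
        nuc_ivs.append(("nchr1", pos, pos + length))
        pres = rng.random(n_assemblies) < presence_prob
        if not pres.any():
            pres[int(rng.integers(n_assemblies))] = True
        presence[i] = pres

    assemblies = {}
    hit_tables: dict[str, list[Hit]] = {}
    for ai in range(n_assemblies):
        name = f"asm{ai:02d}"
        seq = backbone.copy()
        hits: list[Hit] = []
        for i, (age, length) in enumerate(insertions):
            if not presence[i, ai]:
                continue
            _, s_nuc, e_nuc = nuc_ivs[i]
            seq[s_nuc:e_nuc] = numt_seqs[i]
            s_mt, e_mt = mt_ivs[i]
            # half the hits are reported against the second mt copy to
            # exercise doubled-coordinate unwrapping
            offset = mt_length if rng.random() < 0.5 else 0
            ident = 100.0 * float(np.mean(numt_seqs[i] == modern[s_mt:e_mt]))
            hits.append(
                Hit("mt_doubled", "nchr1", ident, s_mt + offset, e_mt + offset,
                    s_nuc, e_nuc, "+")
            )
        assemblies[name] = {"nchr1": "".join(bases[seq])}
        hit_tables[name] = hits

    data = {
        "assemblies": assemblies,
        "hit_tables": hit_tables,
        "modern_mt": "".join(bases[modern]),
        "doubled_mt": "".join(bases[modern]) * 2,
        "outgroup_mt": "".join(bases[outgroup]),
        "mt_length": mt_length,
    }
    truth = NUMTTruth(
        [a for a, _ in insertions], mt_ivs, nuc_ivs, presence, n_in_span, estimable, seed
    )
    return data, truth


# ---------------------------------------------------------------------------
# Feature tracks with planted SV enrichment


@dataclass
class FeatureTruth:
    planted_factors: dict[str, float]
    seed: int


def _build_gene_models(chrom_lengths: dict[str, int]) -> dict[str, list[GenomicInterval]]:
    """Deterministic gene models: a 5-kb gene every 50 kb with three 300-bp
    exons (CDS in the middle one, UTRs at the ends), a 2-kb promoter upstream
    and a 1-kb intergenic enhancer halfway to the next gene."""
    per: dict[str, list[GenomicInterval]] = {c: [] for c in FEATURE_CLASSES}
    for chrom, length in chrom_lengths.items():
        pos = 10_000
        while pos + 5_000 < length - 10_000:
            g = GenomicInterval(chrom, pos, pos + 5_000, "+")
            per["gene"].append(g)
            per["promoter"].append(GenomicInterval(chrom, pos - 2_000, pos, "+"))
            exon_starts = [pos, pos + 2_350, pos + 4_700]
            for j, es in enumerate(exon_starts):
                per["exon"].append(GenomicInterval(chrom, es, es + 300, "+"))
                if j == 1:
                    per["CDS"].append(GenomicInterval(chrom, es, es + 300, "+"))
                else:
                    per["UTR"].append(GenomicInterval(chrom, es, es + 300, "+"))
            per["intron"].append(GenomicInterval(chrom, pos + 300, pos + 2_350, "+"))
            per["intron"].append(GenomicInterval(chrom, pos + 2_650, pos + 4_700, "+"))
            per["enhancer"].append(GenomicInterval(chrom, pos + 25_000, pos + 26_000, "+"))
            pos += 50_000
    return {c: ivs for c, ivs in per.items() if ivs}


def simulate_features(
    genome_model: dict[str, int] | None = None,
    planted_factors: dict[str, float] | None = None,
    n_svs: int = 2000,
    sv_length_range: tuple[int, int] = (100, 500),
    seed: int = 0,
) -> tuple[FeatureAnnotation, list[SVRecord], FeatureTruth]:
    """Feature annotation plus SVs placed with per-class density multipliers.

    Placement uses rejection sampling: a uniform length-preserving proposal
    is accepted with probability proportional to its weight, where the weight
    of a placement is the planted multiplier of the feature class it overlaps
    (highest multiplier wins; sub-unity multipliers depress acceptance).  The
    accepted density of SVs overlapping a class is therefore multiplier x
    background density in the same units the enrichment test counts.
    """
    genome_model = dict(genome_model or {"chr1": 5_000_000, "chr2": 5_000_000})
    factors = {c: 1.0 for c in FEATURE_CLASSES}
    factors.update(planted_factors or {})
    if any(f < 0 for f in factors.values()):
        raise ValueError("multipliers must be >= 0")
    features = FeatureAnnotation(_build_gene_models(genome_model), genome_model)
    rng = np.random.default_rng(seed)

    chroms = list(genome_model)
    clens = np.asarray([genome_model[c] for c in chroms], dtype=float)
    chrom_probs = clens / clens.sum()
    w_max = max(1.0, max(factors.values()))

    def _weight(chrom: str, s: int, e: int) -> float:
        w = 1.0
        for cls in features.classes:
            arr = features.footprints[cls].get(chrom)
            if arr is None or len(arr) == 0:
                continue
            n_start_lt = np.searchsorted(arr[:, 0], e, side="left")
            n_end_le = np.searchsorted(arr[:, 1], s, side="right")
            if n_start_lt > n_end_le:
                f = factors[cls]
                w = max(w, f) if f >= 1 else min(w, f)
        return w

    svs: list[SVRecord] = []
    types = np.array(["absence", "presence", "inversion"])
    type_probs = np.array([0.6, 0.3, 0.1])
    i = 0
    while len(svs) < n_svs:
        ci = int(rng.choice(len(chroms), p=chrom_probs))
        chrom = chroms[ci]
        length = int(rng.integers(sv_length_range[0], sv_length_range[1] + 1))
        s = int(rng.integers(0, genome_model[chrom] - length))
        t = str(rng.choice(types, p=type_probs))
        # insertions occupy a 1-bp reference point; weight what will overlap
        iv = GenomicInterval(chrom, s, s + length) if t != "presence" else GenomicInterval(chrom, s, s + 1)
        if rng.random() * w_max > _weight(chrom, iv.start, iv.end):
            continue
        svs.append(SVRecord(f"sv{i:05d}", iv, t, length, "sim"))
        i += 1
    truth = FeatureTruth(factors, seed)
    return features, svs, truth
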