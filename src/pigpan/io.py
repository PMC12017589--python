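"""Readers and writers for every external format the pipeline touches.

Conversion between on-disk conventions (1-based inclusive VCF/GFF3/BLAST
coordinates) and the internal 0-based half-open convention happens here and
only here.  VCF is read through pysam; FASTA through Biopython; tabular
formats through pandas.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import MIN_SV_LENGTH, FormatError, GenomicInterval, SVRecord
from .enrichment import FEATURE_CLASSES, FeatureAnnotation
from .numt import Hit
from .pangene import OccupancyMatrix
from .popgen import GenotypeMatrix, PopulationSpec

# ---------------------------------------------------------------------------
# SV VCF

_SV_TYPE_TO_VCF = {
    "absence": "DEL",
    "presence": "INS",
    "inversion": "INV",
}
_BND_RE = re.compile(r"[\[\]](?P<chrom>[^:\[\]]+):(?P<pos>\d+)[\[\]]")


def write_sv_vcf(
    records: list[SVRecord],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write SVs as VCF 4.2.  PAV absences become DEL, presences INS,
    inversions INV; translocations become BND mate pairs with SVLEN."""
    chroms: dict[str, int] = dict(chrom_lengths or {})
    for r in records:
        chroms.setdefault(r.interval.chrom, 0)
        if r.mate is not None:
            chroms.setdefault(r.mate.chrom, 0)
        chroms[r.interval.chrom] = max(chroms[r.interval.chrom], r.interval.end + 1)
        if r.mate is not None:
            chroms[r.mate.chrom] = max(chroms[r.mate.chrom], r.mate.end + 1)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Breakend mate id">',
        '##INFO=<ID=SOURCE,Number=1,Type=String,Description="Source genome">',
        '##ALT=<ID=DEL,Description="Deletion (absence)">',
        '##ALT=<ID=INS,Description="Insertion (presence)">',
        '##ALT=<ID=INV,Description="Inversion">',
    ]
    for chrom, length in chroms.items():
        lines.append(f"##contig=<ID={chrom},length={max(length, 1)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in records:
        pos = r.interval.start + 1  # 1-based
        src = f";SOURCE={r.source_genome}" if r.source_genome else ""
        if r.sv_type in _SV_TYPE_TO_VCF:
            alt = f"<{_SV_TYPE_TO_VCF[r.sv_type]}>"
            if r.sv_type == "presence":
                if r.sequence:
                    alt = "N" + r.sequence
                info = f"SVTYPE=INS;SVLEN={r.length}{src}"
            else:
                # END only: htslib reinterprets spans when SVLEN accompanies it
                info = f"SVTYPE={_SV_TYPE_TO_VCF[r.sv_type]};END={r.interval.end}{src}"
            lines.append(
                f"{r.interval.chrom}\t{pos}\t{r.id}\tN\t{alt}\t.\tPASS\t{info}"
            )
        elif r.sv_type.startswith("translocation"):
            if r.mate is None:
                raise ValueError(f"translocation {r.id} lacks a mate breakend")
            m_pos = r.mate.start + 1
            a_id, b_id = f"{r.id}_bnd1", f"{r.id}_bnd2"
            alt_a = f"N[{r.mate.chrom}:{m_pos}["
            alt_b = f"N]{r.interval.chrom}:{pos}]"
            info_a = f"SVTYPE=BND;MATEID={b_id};SVLEN={r.length}{src}"
            info_b = f"SVTYPE=BND;MATEID={a_id};SVLEN={r.length}{src}"
            lines.append(f"{r.interval.chrom}\t{pos}\t{a_id}\tN\t{alt_a}\t.\tPASS\t{info_a}")
            lines.append(f"{r.mate.chrom}\t{m_pos}\t{b_id}\tN\t{alt_b}\t.\tPASS\t{info_b}")
        else:  # pragma: no cover
            raise ValueError(f"cannot serialise sv_type {r.sv_type!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sv_vcf(
    path: str | Path,
    min_length: int = MIN_SV_LENGTH,
    report: dict | None = None,
) -> list[SVRecord]:
    """Read an SV VCF into records (0-based half-open internally).

    DEL -> absence, INS -> presence, INV -> inversion; BND mate pairs combine
    into one translocation record (intra/inter by mate chromosome).  Records
    shorter than ``min_length`` are rejected and tallied in ``report`` when a
    dict is supplied.
    """
    records: list[SVRecord] = []
    rejected = 0
    pending_bnd: dict[str, pysam.VariantRecord] = {}
    seen_mates: set[str] = set()

    def _info(rec, key, default=None):
        try:
            return rec.info.get(key, default)
        except (KeyError, ValueError):  # key absent from the header
            return default

    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                raise FormatError(f"missing SVTYPE at {rec.chrom}:{rec.pos}")
            start = rec.pos - 1
            if svtype == "DEL" or svtype == "INV":
                svlen = _info(rec, "SVLEN")
                if svlen is not None:
                    # POS names the first affected base; span = |SVLEN|
                    svlen = svlen[0] if isinstance(svlen, tuple) else svlen
                    end = start + abs(int(svlen))
                else:
                    end = rec.stop  # pysam: 0-based exclusive from END
                    if end <= start + 1:
                        # htslib clamps END < POS to a 1-bp span with a warning
                        raise FormatError(f"END < POS at {rec.chrom}:{rec.pos}")
                if end <= start:
                    raise FormatError(f"END < POS at {rec.chrom}:{rec.pos}")
                length = end - start
                if length < min_length:
                    rejected += 1
                    continue
                records.append(
                    SVRecord(
                        rec.id or f"sv{len(records)}",
                        GenomicInterval(rec.chrom, start, end),
                        "absence" if svtype == "DEL" else "inversion",
                        length,
                        source_genome=_info(rec, "SOURCE", ""),
                    )
                )
            elif svtype == "INS":
                svlen = _info(rec, "SVLEN")
                if svlen is None:
                    alt = rec.alts[0] if rec.alts else ""
                    if not alt or alt.startswith("<"):
                        raise FormatError(
                            f"INS without SVLEN or ALT sequence at {rec.chrom}:{rec.pos}"
                        )
                    svlen = len(alt) - len(rec.ref)
                svlen = abs(int(svlen if not isinstance(svlen, tuple) else svlen[0]))
                if svlen < min_length:
                    rejected += 1
                    continue
                seq = None
                if rec.alts and not rec.alts[0].startswith("<"):
                    seq = rec.alts[0][1:]
                records.append(
                    SVRecord(
                        rec.id or f"sv{len(records)}",
                        GenomicInterval(rec.chrom, start, start + 1),
                        "presence",
                        svlen,
                        source_genome=_info(rec, "SOURCE", ""),
                        sequence=seq,
                    )
                )
            elif svtype == "BND":
                mate_id = _info(rec, "MATEID")
                if isinstance(mate_id, tuple):
                    mate_id = mate_id[0]
                if mate_id in pending_bnd:
                    first = pending_bnd.pop(mate_id)
                    if rec.id in seen_mates:
                        continue
                    seen_mates.add(mate_id)
                    m = _BND_RE.search(first.alts[0])
                    if not m:
                        raise FormatError(
                            f"unparseable breakend ALT at {first.chrom}:{first.pos}"
                        )
                    mchrom, mpos = m.group("chrom"), int(m.group("pos")) - 1
                    svlen = _info(first, "SVLEN", MIN_SV_LENGTH)
                    svlen = abs(int(svlen if not isinstance(svlen, tuple) else svlen[0]))
                    if svlen < min_length:
                        rejected += 1
                        continue
                    sv_type = (
                        "translocation_intra"
                        if first.chrom == mchrom
                        else "translocation_inter"
                    )
                    base_id = (first.id or "bnd").rsplit("_bnd", 1)[0]
                    records.append(
                        SVRecord(
                            base_id,
                            GenomicInterval(first.chrom, first.pos - 1, first.pos),
                            sv_type,
                            svlen,
                            source_genome=_info(first, "SOURCE", ""),
                            mate=GenomicInterval(mchrom, mpos, mpos + 1),
                        )
                    )
                else:
                    pending_bnd[rec.id] = rec
            else:
                raise FormatError(f"unsupported SVTYPE {svtype!r} at {rec.chrom}:{rec.pos}")
    if report is not None:
        report["too_short"] = rejected
        report["parsed"] = len(records)
    return records


# ---------------------------------------------------------------------------
# Occupancy table (orthogroup TSV dialect)


def read_occupancy_table(path: str | Path) -> OccupancyMatrix:
    """Read a family x genome member table: header names the genomes, each
    row is a family id followed by comma-separated gene lists (empty cell =
    absent in that genome)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    if not lines or not lines[0].strip():
        raise FormatError("empty occupancy table")
    header = lines[0].split("\t")
    genomes = header[1:]
    if not genomes:
        raise FormatError("occupancy table header names no genomes")
    families: list[str] = []
    counts_rows: list[list[int]] = []
    seen: set[str] = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"ragged row at line {ln}: {len(cells)} columns")
        fam = cells[0].strip()
        if fam in seen:
            raise FormatError(f"duplicate family id {fam!r} at line {ln}")
        seen.add(fam)
        families.append(fam)
        counts_rows.append(
            [
                len([g for g in cell.replace(",", " ").split() if g])
                for cell in cells[1:]
            ]
        )
    if not families:
        raise FormatError("no families in occupancy table")
    counts = np.asarray(counts_rows, dtype=int)
    return OccupancyMatrix(families, genomes, counts > 0, counts)


def write_occupancy_table(occ: OccupancyMatrix, path: str | Path) -> None:
    """Write an occupancy matrix as the orthogroup TSV dialect, synthesising
    ``fam_genome_i`` member names from the per-cell counts."""
    lines = ["family\t" + "\t".join(occ.genomes)]
    for fi, fam in enumerate(occ.families):
        cells = []
        for gi, _ in enumerate(occ.genomes):
            k = occ.counts[fi, gi]
            cells.append(", ".join(f"{fam}_{occ.genomes[gi]}_{j}" for j in range(k)))
        lines.append(fam + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular hit format (BLAST outfmt 6 dialect)

_HIT_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path: str | Path, mt_length: int | None = None) -> list[Hit]:
    """Read 12-column tabular hits (1-based inclusive coordinates).

    Subject coordinates with sstart > send are swapped and flagged minus
    strand.  Coordinates stay raw on the (possibly doubled) query so the
    caller can unwrap them against ``mt_length``.
    """
    hits: list[Hit] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 12:
            raise FormatError(f"expected 12 columns at line {ln}, got {len(cells)}")
        try:
            identity = float(cells[2])
            qstart, qend = int(cells[6]), int(cells[7])
            sstart, send = int(cells[8]), int(cells[9])
        except ValueError as exc:
            raise FormatError(f"non-numeric coordinate at line {ln}") from exc
        strand = "+"
        if sstart > send:
            sstart, send = send, sstart
            strand = "-"
        hits.append(
            Hit(
                query=cells[0],
                subject=cells[1],
                identity=identity,
                q_start=qstart - 1,
                q_end=qend,
                s_start=sstart - 1,
                s_end=send,
                strand=strand,
            )
        )
    return hits


def write_hit_table(hits: list[Hit], path: str | Path) -> None:
    lines = []
    for h in hits:
        sstart, send = (h.s_end, h.s_start + 1) if h.strand == "-" else (h.s_start + 1, h.s_end)
        length = h.q_end - h.q_start
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    h.query, h.subject, f"{h.identity:.2f}", length, 0, 0,
                    h.q_start + 1, h.q_end, sstart, send, "0.0", length * 2,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED and generic TSV


def write_bed(
    intervals: list[GenomicInterval],
    path: str | Path,
    names: list[str] | None = None,
    scores: list | None = None,
) -> None:
    """Write BED3 (or BED5/6 when names/scores given), 0-based half-open."""
    lines = []
    for i, iv in enumerate(intervals):
        cols = [iv.chrom, str(iv.start), str(iv.end)]
        if names is not None or scores is not None:
            cols.append(names[i] if names is not None else ".")
            cols.append(str(scores[i]) if scores is not None else ".")
            if iv.strand != ".":
                cols.append(iv.strand)
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            raise FormatError(f"BED line {ln} has fewer than 3 columns")
        strand = cells[5] if len(cells) >= 6 and cells[5] in "+-" else "."
        out.append(GenomicInterval(cells[0], int(cells[1]), int(cells[2]), strand))
    return out


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotypes


def read_genotype_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid GTs into a dosage matrix (0/1/2, NaN missing).

    Multi-allelic records split into one biallelic record per alternate
    allele; the dosage counts that allele.  Mean per-sample DP is kept when
    present.
    """
    rows = []
    dosages = []
    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts, start=1):
                dos = np.full(len(individuals), np.nan)
                depths = []
                for i, sample in enumerate(rec.samples.values()):
                    gt = sample.get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    dos[i] = sum(1 for a in gt if a == k)
                    dp = sample.get("DP")
                    if dp is not None:
                        depths.append(dp)
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos - 1,
                        "id": (rec.id or f"{rec.chrom}_{rec.pos}")
                        + (f"_alt{k}" if len(alts) > 1 else ""),
                        "ref": rec.ref,
                        "alt": alt,
                        "mean_depth": float(np.mean(depths)) if depths else np.nan,
                    }
                )
                dosages.append(dos)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "mean_depth"]
    )
    dmat = np.asarray(dosages, dtype=float) if dosages else np.empty((0, len(individuals)))
    return GenotypeMatrix(variants, individuals, dmat)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Dosage TSV: chrom, pos (1-based on disk), id, ref, alt, then one
    dosage column per individual (NA = missing)."""
    meta = gm.variants[["chrom", "pos", "id", "ref", "alt"]].copy()
    meta["pos"] = meta["pos"] + 1
    dose = pd.DataFrame(
        {
            name: [("NA" if np.isnan(x) else str(int(x))) for x in gm.dosages[:, i]]
            for i, name in enumerate(gm.individuals)
        }
    )
    pd.concat([meta, dose], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "id", "ref", "alt"]
    if list(df.columns[:5]) != meta_cols:
        raise FormatError(f"dosage TSV must start with columns {meta_cols}")
    individuals = list(df.columns[5:])
    variants = df[meta_cols].copy()
    variants["pos"] = variants["pos"] - 1
    variants["mean_depth"] = np.nan
    dos = (
        df[individuals]
        .replace("NA", np.nan)
        .apply(pd.to_numeric, errors="coerce")
        .to_numpy(dtype=float)
    )
    return GenotypeMatrix(variants, individuals, dos)


def read_population_tsv(path: str | Path) -> PopulationSpec:
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "population"], dtype=str)
    return PopulationSpec(dict(zip(df["individual"], df["population"])))


def write_population_tsv(pops: PopulationSpec, path: str | Path) -> None:
    lines = [f"{ind}\t{pop}" for ind, pop in pops.assignment.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Feature annotations

_GFF_TYPE_MAP = {
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "CDS": "CDS",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "UTR": "UTR",
    "enhancer": "enhancer",
    "promoter": "promoter",
}


def read_features_gff3(
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    promoter_window: int = 2000,
    derive_promoters: bool = True,
    derive_introns: bool = True,
) -> FeatureAnnotation:
    """Read GFF3 feature lines (1-based inclusive -> internal half-open).

    When the file annotates no promoters, strand-aware windows of
    ``promoter_window`` bp upstream of each gene TSS are derived; introns are
    likewise derived as intra-gene gaps between exons when absent.
    """
    per_class: dict[str, list[GenomicInterval]] = {}
    genes: list[GenomicInterval] = []
    exons: list[GenomicInterval] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 9:
            raise FormatError("GFF3 line does not have 9 columns")
        ftype = cells[2]
        if ftype not in _GFF_TYPE_MAP:
            continue
        cls = _GFF_TYPE_MAP[ftype]
        strand = cells[6] if cells[6] in "+-" else "."
        iv = GenomicInterval(cells[0], int(cells[3]) - 1, int(cells[4]), strand)
        per_class.setdefault(cls, []).append(iv)
        if cls == "gene":
            genes.append(iv)
        elif cls == "exon":
            exons.append(iv)
    if derive_promoters and "promoter" not in per_class and genes:
        proms = []
        for g in genes:
            if g.strand == "-":
                s, e = g.end, g.end + promoter_window
            else:
                s, e = max(0, g.start - promoter_window), g.start
            if chrom_lengths and g.chrom in chrom_lengths:
                e = min(e, chrom_lengths[g.chrom])
            if s < e:
                proms.append(GenomicInterval(g.chrom, s, e, g.strand))
        if proms:
            per_class["promoter"] = proms
    if derive_introns and "intron" not in per_class and genes and exons:
        introns = []
        for g in genes:
            inside = sorted(
                (max(x.start, g.start), min(x.end, g.end))
                for x in exons
                if x.chrom == g.chrom and x.start < g.end and x.end > g.start
            )
            cur = None
            for s, e in inside:
                if cur is not None and s > cur:
                    introns.append(GenomicInterval(g.chrom, cur, s, g.strand))
                cur = e if cur is None else max(cur, e)
        if introns:
            per_class["intron"] = introns
    return FeatureAnnotation(per_class, chrom_lengths)


def read_features_bed(
    path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> FeatureAnnotation:
    """Read a BED file whose 4th column names the feature class."""
    per_class: dict[str, list[GenomicInterval]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < 4:
            raise FormatError(f"feature BED needs a class in column 4 (line {ln})")
        if cells[3] not in FEATURE_CLASSES:
            raise FormatError(f"unknown feature class {cells[3]!r} at line {ln}")
        strand = cells[5] if len(cells) >= 6 and cells[5] in "+-" else "."
        per_class.setdefault(cells[3], []).append(
            GenomicInterval(cells[0], int(cells[1]), int(cells[2]), strand)
        )
    return FeatureAnnotation(per_class, chrom_lengths)


def write_features_bed(features: FeatureAnnotation, path: str | Path) -> None:
    lines = []
    for cls in features.classes:
        for iv in features.intervals[cls]:
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\t.\t{iv.strand if iv.strand != '.' else '+'}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()],
        str(path),
        "fasta",
    )
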