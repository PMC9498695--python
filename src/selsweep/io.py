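"""Readers/writers for VCF, popmap TSV, FASTA and GFF3, plus the in-memory
containers every statistic operates on.

Coordinate conventions: all on-disk formats are 1-based inclusive (VCF/GFF3
convention).  Sliding windows used elsewhere in the package are half-open
0-based internally and converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # dosage code for an uncalled genotype


class VcfParseError(ValueError):
    pass


class PopmapError(ValueError):
    pass


@dataclass
class Variant:
    """One VCF record, possibly multi-allelic or an indel.

    ``genotypes`` holds per-sample unordered allele index pairs;
    ``(-1, -1)`` marks a missing call.  Phase is discarded: unphased "0/1"
    and phased "0|1" are equivalent.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snp


@dataclass
class GenotypeMatrix:
    """Biallelic-SNP sites x samples allele-dosage matrix.

    ``dosage[i, j]`` counts ALT alleles (0, 1, 2) with ``MISSING`` (-1) for
    an uncalled genotype.  Sites are sorted by (chrom, pos).
    """

    chrom: np.ndarray          # (S,) str
    pos: np.ndarray            # (S,) int64, 1-based
    ref: np.ndarray            # (S,) str
    alt: np.ndarray            # (S,) str
    dosage: np.ndarray         # (S, N) int8
    samples: list[str]

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage dimensions inconsistent with sites/samples")
        if not self._is_sorted():
            order = np.lexsort((self.pos, self.chrom))
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.alt = self.alt[order]
            self.dosage = self.dosage[order]

    def _is_sorted(self) -> bool:
        for i in range(1, len(self.pos)):
            if (self.chrom[i], self.pos[i]) < (self.chrom[i - 1], self.pos[i - 1]):
                return False
        return True

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chrom_lengths(self) -> dict[str, int]:
        """Fallback per-chromosome lengths: the last variant position."""
        out: dict[str, int] = {}
        for c, p in zip(self.chrom, self.pos):
            out[c] = max(out.get(c, 0), int(p))
        return out

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.asarray([lookup[n] for n in names], dtype=np.intp)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[mask], self.pos[mask], self.ref[mask], self.alt[mask],
            self.dosage[mask], list(self.samples),
        )

    def filter_missingness(self, max_missing: float = 1.0) -> "GenotypeMatrix":
        """Drop sites whose missing-genotype fraction exceeds ``max_missing``.

        The default (1.0) keeps everything; inputs are assumed pre-filtered
        for call quality upstream.
        """
        if self.n_sites == 0:
            return self
        frac = (self.dosage == MISSING).mean(axis=1)
        return self.subset_sites(frac <= max_missing)


class PopulationMap:
    """sample -> population assignment, population order = first appearance."""

    def __init__(self, mapping: Mapping[str, str]):
        if not mapping:
            raise PopmapError("empty population map")
        self.mapping = dict(mapping)
        pops: list[str] = []
        for p in self.mapping.values():
            if p not in pops:
                pops.append(p)
        self.populations = pops

    def samples(self, pop: str) -> list[str]:
        return [s for s, p in self.mapping.items() if p == pop]

    def size(self, pop: str) -> int:
        return len(self.samples(pop))

    def indices(self, pop: str, sample_order: Sequence[str]) -> np.ndarray:
        members = set(self.samples(pop))
        return np.asarray(
            [i for i, s in enumerate(sample_order) if s in members], dtype=np.intp
        )

    def group_indices(self, sample_order: Sequence[str]) -> dict[str, np.ndarray]:
        return {p: self.indices(p, sample_order) for p in self.populations}

    def validate_against(self, samples: Sequence[str]) -> None:
        unmapped = [s for s in samples if s not in self.mapping]
        if unmapped:
            raise PopmapError(f"samples missing from population map: {unmapped}")


@dataclass
class GeneModel:
    """One transcript's gene structure; intervals 1-based inclusive, sorted."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str                       # '+' or '-'
    start: int                        # gene span start
    end: int                          # gene span end
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    coding_eligible: bool = True

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> tuple[list[Variant], list[str]]:
    """Read a VCF (v4.x, GT format) into Variant records.

    Returns (variants, sample names).  Multi-allelic records and indels are
    retained here; use :func:`genotype_matrix_from_variants` to reduce to the
    biallelic-SNP dosage matrix.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises bare Exceptions on bad headers
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[Variant] = []
    recno = 0
    try:
        for v in vcf:
            recno += 1
            alts = tuple(v.ALT) if v.ALT else ()
            if not alts or not v.REF:
                raise VcfParseError(
                    f"{path}: record {recno} (pos {v.POS}): missing REF/ALT"
                )
            gts = [(int(g[0]), int(g[1])) if len(g) >= 2 else (-1, -1)
                   for g in v.genotypes]
            gts = [(-1, -1) if (a < 0 or b < 0) else (min(a, b), max(a, b))
                   for a, b in gts]
            variants.append(Variant(v.CHROM, int(v.POS), v.REF, alts, gts))
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"{path}: record {recno + 1}: {exc}") from exc
    return variants, samples


def genotype_matrix_from_variants(
    variants: Iterable[Variant], samples: Sequence[str]
) -> GenotypeMatrix:
    """Reduce records to the biallelic-SNP dosage matrix (indels/multi-allelic
    records are simply skipped)."""
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for v in variants:
        if not (v.is_snp and v.is_biallelic):
            continue
        chroms.append(v.chrom)
        poss.append(v.pos)
        refs.append(v.ref)
        alts.append(v.alts[0])
        rows.append([a + b if a >= 0 else MISSING for a, b in v.genotypes])
    dosage = (np.asarray(rows, dtype=np.int8) if rows
              else np.zeros((0, len(samples)), dtype=np.int8))
    return GenotypeMatrix(
        np.asarray(chroms, dtype=object), np.asarray(poss, dtype=np.int64),
        np.asarray(refs, dtype=object), np.asarray(alts, dtype=object),
        dosage, list(samples),
    )


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    variants, samples = read_vcf(path)
    return genotype_matrix_from_variants(variants, samples)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
    extra_variants: Sequence[Variant] | None = None,
) -> None:
    """Write a minimal spec-conformant VCF v4.2 with GT-only genotypes.

    ``extra_variants`` (e.g. indels) are merged in by coordinate.
    """
    lengths = dict(chrom_lengths or matrix.chrom_lengths())
    recs: list[tuple[str, int, str]] = []
    for i in range(matrix.n_sites):
        gt = "\t".join(_GT_STR[int(d)] for d in matrix.dosage[i])
        line = (f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gt}")
        recs.append((str(matrix.chrom[i]), int(matrix.pos[i]), line))
    for v in extra_variants or []:
        gt = "\t".join(
            "./." if a < 0 else f"{a}/{b}" for a, b in v.genotypes
        )
        line = (f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS"
                f"\t.\tGT\t{gt}")
        recs.append((v.chrom, v.pos, line))
        lengths.setdefault(v.chrom, v.pos)
        lengths[v.chrom] = max(lengths[v.chrom], v.pos)
    recs.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(lengths):
            fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for _, _, line in recs:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# popmap


def read_popmap(path: str | Path) -> PopulationMap:
    """Two-column TSV: sample<TAB>population."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PopmapError(f"{path}:{lineno}: expected 2 columns")
            sample, pop = parts
            if sample in mapping and mapping[sample] != pop:
                raise PopmapError(
                    f"{path}:{lineno}: sample {sample!r} assigned to both "
                    f"{mapping[sample]!r} and {pop!r}"
                )
            mapping[sample] = pop
    if not mapping:
        raise PopmapError(f"{path}: empty population map")
    return PopulationMap(mapping)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.mapping.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by id, uppercased.  Duplicate ids are an error."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS/UTR features into per-transcript models."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        for mrna in db.children(gene, featuretype="mRNA"):
            gm = GeneModel(
                gene_id=gene.id, transcript_id=mrna.id, chrom=gene.seqid,
                strand=mrna.strand, start=gene.start, end=gene.end,
            )
            for ft, dest in (
                ("exon", gm.exons), ("CDS", gm.cds),
                ("five_prime_UTR", gm.utr5), ("three_prime_UTR", gm.utr3),
            ):
                for f in db.children(mrna, featuretype=ft, order_by="start"):
                    dest.append((f.start, f.end))
            if gm.cds and gm.cds_length() % 3 != 0:
                warnings.warn(
                    f"transcript {gm.transcript_id}: CDS length not divisible "
                    "by 3; coding effects disabled for it"
                )
                gm.coding_eligible = False
            models.append(gm)
    models.sort(key=lambda g: (g.chrom, g.start))
    return models


def write_gff(models: Sequence[GeneModel], path: str | Path) -> None:
    def line(chrom, src, ft, s, e, strand, phase, attrs):
        return (f"{chrom}\t{src}\t{ft}\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                f"{attrs}\n")

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in sorted(models, key=lambda g: (g.chrom, g.start)):
            fh.write(line(gm.chrom, "selsweep", "gene", gm.start, gm.end,
                          gm.strand, ".", f"ID={gm.gene_id}"))
            fh.write(line(gm.chrom, "selsweep", "mRNA", gm.start, gm.end,
                          gm.strand, ".",
                          f"ID={gm.transcript_id};Parent={gm.gene_id}"))
            for i, (s, e) in enumerate(gm.exons, 1):
                fh.write(line(gm.chrom, "selsweep", "exon", s, e, gm.strand,
                              ".", f"ID={gm.transcript_id}.exon{i};"
                                   f"Parent={gm.transcript_id}"))
            # CDS phase: bases to skip before the first full codon, accumulated
            # in transcription order.
            cds = sorted(gm.cds)
            order = cds if gm.strand == "+" else cds[::-1]
            phase, phased = 0, {}
            for (s, e) in order:
                phased[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e) in enumerate(cds, 1):
                fh.write(line(gm.chrom, "selsweep", "CDS", s, e, gm.strand,
                              phased[(s, e)],
                              f"ID={gm.transcript_id}.cds{i};"
                              f"Parent={gm.transcript_id}"))
            for ft, ivals in (("five_prime_UTR", gm.utr5),
                              ("three_prime_UTR", gm.utr3)):
                for i, (s, e) in enumerate(ivals, 1):
                    fh.write(line(gm.chrom, "selsweep", ft, s, e, gm.strand,
                                  ".", f"ID={gm.transcript_id}.{ft}{i};"
                                       f"Parent={gm.transcript_id}"))


# ---------------------------------------------------------------------------
# generic TSV helpers


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
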