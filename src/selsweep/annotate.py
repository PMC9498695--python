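"""Gene-based variant annotation: location category, coding effect,
mutation spectrum and indel length bookkeeping.

Location categories follow gene-based annotation conventions: a variant is
classified per transcript (coding-exon > splice site > UTR > intron) and
across transcripts by the precedence

    exonic > splice_acceptor/splice_donor > utr5/utr3 > intronic >
    upstream/downstream > intergenic

with 1 kb up/downstream flanks and 2 bp splice sites at intron ends.
"exonic" means the coding portion of an exon; UTR bases get their own
categories.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io import GeneModel, Variant

LOCATION_CATEGORIES = (
    "exonic", "splice_acceptor", "splice_donor", "utr5", "utr3",
    "intronic", "upstream", "downstream", "intergenic",
)
_PRECEDENCE = {
    "exonic": 0, "splice_acceptor": 1, "splice_donor": 1,
    "utr5": 2, "utr3": 2, "intronic": 3, "upstream": 4, "downstream": 4,
    "intergenic": 5,
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

SPECTRUM_CLASSES = (
    "T:A>C:G", "C:G>T:A", "T:A>G:C", "T:A>A:T", "C:G>A:T", "C:G>G:C",
)
# strand-collapsed ref>alt -> class
_SPECTRUM = {
    ("A", "G"): "T:A>C:G", ("T", "C"): "T:A>C:G",
    ("C", "T"): "C:G>T:A", ("G", "A"): "C:G>T:A",
    ("A", "C"): "T:A>G:C", ("T", "G"): "T:A>G:C",
    ("A", "T"): "T:A>A:T", ("T", "A"): "T:A>A:T",
    ("C", "A"): "C:G>A:T", ("G", "T"): "C:G>A:T",
    ("C", "G"): "C:G>G:C", ("G", "C"): "C:G>G:C",
}
TRANSITION_CLASSES = ("T:A>C:G", "C:G>T:A")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SiteAnnotation:
    chrom: str
    pos: int
    category: str
    gene: str | None = None
    transcript: str | None = None
    coding_effect: str = "none"  # synonymous|nonsynonymous|stopgain|stoploss|unknown|none
    aa_change: str | None = None


def _introns(gm: GeneModel) -> list[tuple[int, int]]:
    exons = sorted(gm.exons)
    return [
        (exons[i][1] + 1, exons[i + 1][0] - 1)
        for i in range(len(exons) - 1)
        if exons[i + 1][0] > exons[i][1] + 1
    ]


def _classify_in_transcript(
    pos: int, gm: GeneModel, upstream_downstream: int, splice: int
) -> str | None:
    """Category of pos relative to one transcript, or None if unrelated."""
    if not (gm.start - upstream_downstream
            <= pos <= gm.end + upstream_downstream):
        return None
    if pos < gm.start or pos > gm.end:
        before = pos < gm.start  # on the low-coordinate side
        if gm.strand == "+":
            return "upstream" if before else "downstream"
        return "downstream" if before else "upstream"
    for s, e in gm.cds:
        if s <= pos <= e:
            return "exonic"
    for s, e in _introns(gm):
        if s <= pos <= e:
            if pos - s < splice or e - pos < splice:
                low_end = pos - s < splice
                # intron's low-coordinate end follows an exon in transcription
                # order on the plus strand (donor side); reversed on minus.
                if gm.strand == "+":
                    return "splice_donor" if low_end else "splice_acceptor"
                return "splice_acceptor" if low_end else "splice_donor"
            return "intronic"
    for s, e in gm.utr5:
        if s <= pos <= e:
            return "utr5"
    for s, e in gm.utr3:
        if s <= pos <= e:
            return "utr3"
    # inside the gene span but not in any annotated feature (e.g. exon bases
    # not assigned to CDS/UTR); treat as exonic-adjacent intronic fallback
    for s, e in sorted(gm.exons):
        if s <= pos <= e:
            return "exonic"
    return "intronic"


def classify_location(
    variant: Variant,
    gene_models: list[GeneModel],
    upstream_downstream: int = 1_000,
    splice: int = 2,
) -> SiteAnnotation:
    """Single category per variant across all transcripts, by precedence."""
    best: tuple[int, str, GeneModel] | None = None
    for gm in gene_models:
        if gm.chrom != variant.chrom:
            continue
        cat = _classify_in_transcript(
            variant.pos, gm, upstream_downstream, splice
        )
        if cat is None:
            continue
        rank = _PRECEDENCE[cat]
        if best is None or rank < best[0]:
            best = (rank, cat, gm)
    if best is None:
        return SiteAnnotation(variant.chrom, variant.pos, "intergenic")
    _, cat, gm = best
    return SiteAnnotation(
        variant.chrom, variant.pos, cat, gene=gm.gene_id,
        transcript=gm.transcript_id,
    )


def _cds_positions(gm: GeneModel) -> list[int]:
    """Genomic positions of CDS bases in transcription (5'->3') order."""
    cds = sorted(gm.cds)
    pos = [p for s, e in cds for p in range(s, e + 1)]
    return pos if gm.strand == "+" else pos[::-1]


def extract_cds(gm: GeneModel, seqs: dict[str, str]) -> str:
    """Spliced, strand-corrected CDS nucleotide sequence."""
    chrom = seqs[gm.chrom]
    parts = [chrom[s - 1:e] for s, e in sorted(gm.cds)]
    seq = "".join(parts)
    return seq if gm.strand == "+" else revcomp(seq)


_STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def coding_effect(
    variant: Variant, gm: GeneModel, seqs: dict[str, str]
) -> tuple[str, str | None]:
    """(effect, aa_change) for a biallelic SNP inside the CDS of ``gm``.

    Effects: synonymous, nonsynonymous, stopgain, stoploss; "unknown" when
    the transcript is not coding-eligible or the reference base disagrees
    with the FASTA.
    """
    if not gm.coding_eligible:
        return "unknown", None
    cds_pos = _cds_positions(gm)
    try:
        i = cds_pos.index(variant.pos)
    except ValueError:
        return "none", None
    cds_seq = extract_cds(gm, seqs)
    ref, alt = variant.ref, variant.alts[0]
    if gm.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
    if cds_seq[i] != ref:
        warnings.warn(
            f"{gm.transcript_id}: reference base mismatch at "
            f"{variant.chrom}:{variant.pos}"
        )
        return "unknown", None
    ci = i // 3
    ref_codon = cds_seq[3 * ci:3 * ci + 3]
    alt_codon = ref_codon[:i % 3] + alt + ref_codon[i % 3 + 1:]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    aa_change = f"{ref_aa}{ci + 1}{alt_aa}"
    if ref_aa == alt_aa:
        return "synonymous", aa_change
    if alt_aa == "*" and ref_aa != "*":
        return "stopgain", aa_change
    if ref_aa == "*" and alt_aa != "*":
        return "stoploss", aa_change
    return "nonsynonymous", aa_change


def annotate_variants(
    variants: list[Variant],
    gene_models: list[GeneModel],
    seqs: dict[str, str] | None = None,
    upstream_downstream: int = 1_000,
    splice: int = 2,
) -> list[SiteAnnotation]:
    """Location category for every variant; coding effect for exonic
    biallelic SNPs when sequences are supplied."""
    by_tid = {gm.transcript_id: gm for gm in gene_models}
    out = []
    for v in variants:
        ann = classify_location(v, gene_models, upstream_downstream, splice)
        if (ann.category == "exonic" and seqs is not None and v.is_snp
                and v.is_biallelic and ann.transcript in by_tid):
            eff, aa = coding_effect(v, by_tid[ann.transcript], seqs)
            if eff != "none":
                ann.coding_effect = eff
                ann.aa_change = aa
        out.append(ann)
    return out


def mutation_spectrum(variants: list[Variant]) -> pd.DataFrame:
    """Strand-collapsed substitution-class counts of non-reference genotype
    observations (sample x site), split by zygosity.

    Returns (class, het, hom, total) for the six classes.
    """
    het: Counter[str] = Counter()
    hom: Counter[str] = Counter()
    for v in variants:
        if not (v.is_snp and v.is_biallelic):
            continue
        key = (v.ref.upper(), v.alts[0].upper())
        if key not in _SPECTRUM:
            warnings.warn(f"non-ACGT alleles at {v.chrom}:{v.pos}; skipped")
            continue
        cls = _SPECTRUM[key]
        for a, b in v.genotypes:
            if a < 0:
                continue
            if a != b:
                het[cls] += 1
            elif a == 1:
                hom[cls] += 1
    return pd.DataFrame({
        "class": SPECTRUM_CLASSES,
        "het": [het[c] for c in SPECTRUM_CLASSES],
        "hom": [hom[c] for c in SPECTRUM_CLASSES],
        "total": [het[c] + hom[c] for c in SPECTRUM_CLASSES],
    })


def indel_lengths(variants: list[Variant]) -> pd.DataFrame:
    """Signed length (len(alt) - len(ref)) counts for biallelic non-SNP
    records; negative lengths are deletions.  SNPs are excluded."""
    counts: Counter[int] = Counter()
    for v in variants:
        if v.is_snp or not v.is_biallelic:
            continue
        delta = len(v.alts[0]) - len(v.ref)
        if delta != 0:
            counts[delta] += 1
    items = sorted(counts.items())
    return pd.DataFrame(items, columns=["length", "count"])


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def annotation_summary(
    counts: dict[str, int], total: int
) -> pd.DataFrame:
    """Category counts and percentages of ``total`` (half-up, 2 decimals)."""
    if total <= 0:
        raise ValueError("total must be positive")
    # exact decimal division before rounding, so printed-precision worked
    # examples reproduce without binary-float drift
    rows = [
        (cat, n,
         float((Decimal(n) * 100 / Decimal(total))
               .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)))
        for cat, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def summarize_annotations(
    annotations: list[SiteAnnotation]
) -> pd.DataFrame:
    counts = Counter(a.category for a in annotations)
    total = len(annotations)
    return annotation_summary(
        {c: counts.get(c, 0) for c in LOCATION_CATEGORIES}, total
    )
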