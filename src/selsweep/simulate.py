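"""Synthetic multi-population genotype data with controlled differentiation.

Population structure follows the Balding–Nichols island model: each site
draws an ancestral allele frequency p from a (truncated) Beta distribution
and each population k draws its own frequency from
Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k), giving per-population frequency
variance F_k·p(1-p) and expected pairwise Fst on the order of the F
parameters.  Diploid genotypes are Binomial(2, population frequency) —
Hardy–Weinberg within populations — optionally mixed with an
identity-by-descent component (``inbreeding``) that produces the
heterozygote deficit (positive Fis) seen in real livestock panels, plus
uniform missingness and a transition-biased REF/ALT nucleotide assignment.

Sweeps and population-specific genotypes are implanted post hoc so that
downstream scans have exact ground truth to recover.  A toy genome (FASTA)
with intron/exon gene models (GFF3) provides the annotation substrate.

Seed policy: one master seed; every sub-generator derives an independent
stream from a fixed spawn key, so adding a stage never perturbs another
stage's draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GeneModel, GenotypeMatrix, PopulationMap

# Seven-breed defaults mirroring a goat resequencing panel: sample sizes per
# group and per-population drift parameters spanning the observed pairwise
# Fst magnitudes (~0.04-0.19).
DEFAULT_POPS = ("popA", "popB", "popC", "popD", "popE", "popF", "popG")
DEFAULT_SAMPLES = (15, 5, 16, 16, 10, 10, 15)
DEFAULT_F = (0.08, 0.04, 0.04, 0.06, 0.07, 0.16, 0.07)


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    n_pops: int = 7
    samples_per_pop: tuple[int, ...] = DEFAULT_SAMPLES
    pop_names: tuple[str, ...] = DEFAULT_POPS
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    n_sites: int = 4_000
    ancestral_beta: tuple[float, float] = (0.5, 0.5)
    ancestral_truncation: tuple[float, float] = (0.05, 0.95)
    F_per_pop: tuple[float, ...] = DEFAULT_F
    inbreeding: float = 0.15
    ts_tv_kappa: float = 2.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if len(self.samples_per_pop) != self.n_pops:
            raise ValueError("samples_per_pop length != n_pops")
        if len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names length != n_pops")
        if len(self.F_per_pop) != self.n_pops:
            raise ValueError("F_per_pop length != n_pops")
        if any(n < 1 for n in self.samples_per_pop):
            raise ValueError("each population needs >= 1 sample")
        if any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if any(not (0.0 < F < 1.0) for F in self.F_per_pop):
            raise ValueError("F parameters must lie strictly in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.inbreeding < 1.0):
            raise ValueError("inbreeding must be in [0, 1)")
        if self.ts_tv_kappa < 0:
            raise ValueError("ts_tv_kappa must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    def popmap(self) -> PopulationMap:
        mapping = {}
        for pop, n in zip(self.pop_names, self.samples_per_pop):
            for i in range(n):
                mapping[f"{pop}_s{i:02d}"] = pop
        return PopulationMap(mapping)


@dataclass
class FrequencyTable:
    """Per-site per-population allele frequencies from the island model."""

    chrom: np.ndarray       # (S,)
    pos: np.ndarray         # (S,) 1-based
    ancestral: np.ndarray   # (S,)
    freqs: np.ndarray       # (S, K)


@dataclass
class SweepSpec:
    """A region whose focal-population diversity is collapsed post hoc.

    ``diversity_reduction`` d >= 1 rescales focal heterozygosity to 1/d of
    its pre-implant value; ``divergence_boost`` in [0, 1) then pushes the
    focal frequency further toward fixation of its major allele, raising
    site Fst against the other populations.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int
    focal_pop: str
    diversity_reduction: float = 5.0
    divergence_boost: float = 0.8

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.diversity_reduction < 1:
            raise ValueError("diversity_reduction must be >= 1")
        if not (0.0 <= self.divergence_boost < 1.0):
            raise ValueError("divergence_boost must be in [0, 1)")


@dataclass
class SpecificAlleleSpec:
    """One site forced to carry a population-specific genotype class."""

    chrom: str
    pos: int
    focal_pop: str
    genotype_class: str = "hom_alt"   # hom_ref | het | hom_alt
    focal_freq: float = 0.9
    other_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.genotype_class not in ("hom_ref", "het", "hom_alt"):
            raise ValueError("bad genotype_class")


@dataclass
class ToyGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]


# ---------------------------------------------------------------------------
# frequencies and genotypes


def simulate_population_frequencies(config: SimulationConfig) -> FrequencyTable:
    rng = _stream(config.seed, 0)
    chroms_sorted = sorted(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())
    chrom_arr, pos_arr = [], []
    remaining = config.n_sites
    for i, c in enumerate(chroms_sorted):
        L = config.chrom_lengths[c]
        k = remaining if i == len(chroms_sorted) - 1 else \
            int(round(config.n_sites * L / total_len))
        k = min(k, remaining, L)
        remaining -= k
        pos = np.sort(rng.choice(L, size=k, replace=False)) + 1
        chrom_arr.extend([c] * k)
        pos_arr.append(pos)
    chrom_arr = np.asarray(chrom_arr, dtype=object)
    pos_arr = np.concatenate(pos_arr) if pos_arr else np.empty(0, dtype=np.int64)
    S = len(pos_arr)

    a, b = config.ancestral_beta
    lo, hi = config.ancestral_truncation
    p = rng.beta(a, b, size=S)
    bad = (p < lo) | (p > hi)
    while bad.any():  # rejection sampling keeps the Beta shape inside [lo,hi]
        p[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (p < lo) | (p > hi)

    freqs = np.empty((S, config.n_pops))
    for k, F in enumerate(config.F_per_pop):
        scale = (1.0 - F) / F
        freqs[:, k] = rng.beta(p * scale, (1.0 - p) * scale)
    return FrequencyTable(chrom_arr, pos_arr.astype(np.int64), p, freqs)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}
_BASES = np.array(["A", "C", "G", "T"], dtype=object)


def simulate_genotypes(
    freqs: FrequencyTable, config: SimulationConfig
) -> GenotypeMatrix:
    """Binomial(2, p_pop) diploid genotypes with missingness and
    transition-biased REF/ALT nucleotides."""
    if np.any((freqs.freqs < 0) | (freqs.freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = _stream(config.seed, 1)
    S = len(freqs.pos)
    N = sum(config.samples_per_pop)
    dosage = np.empty((S, N), dtype=np.int8)
    col = 0
    f_ibd = config.inbreeding
    for k, n in enumerate(config.samples_per_pop):
        p = np.broadcast_to(freqs.freqs[:, k][:, None], (S, n))
        hwe = rng.binomial(2, p)
        if f_ibd > 0:
            # inbreeding as an identity-by-descent mixture: with prob f the
            # two alleles are copies of one draw, halving heterozygosity
            ibd = rng.random((S, n)) < f_ibd
            autoz = 2 * rng.binomial(1, p)
            dosage[:, col:col + n] = np.where(ibd, autoz, hwe)
        else:
            dosage[:, col:col + n] = hwe
        col += n
    if config.missing_rate > 0:
        mask = rng.random((S, N)) < config.missing_rate
        dosage[mask] = -1

    ref = _BASES[rng.integers(0, 4, size=S)]
    kappa = config.ts_tv_kappa
    p_ts = kappa / (kappa + 1.0) if kappa + 1.0 > 0 else 0.0
    is_ts = rng.random(S) < p_ts
    tv_pick = rng.integers(0, 2, size=S)
    alt = np.array([
        _TRANSITION[r] if t else _TRANSVERSIONS[r][j]
        for r, t, j in zip(ref, is_ts, tv_pick)
    ], dtype=object)

    popmap = config.popmap()
    return GenotypeMatrix(
        freqs.chrom.copy(), freqs.pos.copy(), ref, alt, dosage,
        list(popmap.mapping),
    )


# ---------------------------------------------------------------------------
# implants


def implant_sweep(
    matrix: GenotypeMatrix,
    spec: SweepSpec,
    popmap: PopulationMap,
    seed: int = 0,
) -> GenotypeMatrix:
    """Collapse focal-population diversity inside the region.

    For each site in the region the focal allele frequency p is mapped to a
    target p'' with heterozygosity p''(1-p'') = p(1-p)/d shifted toward the
    focal major allele, then further moved toward fixation by the boost;
    focal genotypes are redrawn Binomial(2, p'') (called genotypes only).
    An identity spec (d=1, boost=0) returns the matrix unchanged.
    """
    if spec.diversity_reduction == 1.0 and spec.divergence_boost == 0.0:
        return matrix
    focal = popmap.indices(spec.focal_pop, matrix.samples)
    in_region = (
        (matrix.chrom == spec.chrom)
        & (matrix.pos >= spec.start) & (matrix.pos <= spec.end)
    )
    sites = np.flatnonzero(in_region)
    if len(sites) == 0:
        warnings.warn("sweep region contains no sites; matrix unchanged")
        return matrix
    rng = _stream(seed, 2)
    dosage = matrix.dosage.copy()
    d = spec.diversity_reduction
    boost = spec.divergence_boost
    for i in sites:
        row = dosage[i, focal]
        called = row != -1
        n = 2 * int(called.sum())
        if n == 0:
            continue
        p = float(row[called].sum()) / n
        het_target = p * (1.0 - p) / d
        root = np.sqrt(max(0.25 - het_target, 0.0))
        p1 = 0.5 + root if p >= 0.5 else 0.5 - root
        p2 = p1 + boost * (1.0 - p1) if p >= 0.5 else p1 * (1.0 - boost)
        new = rng.binomial(2, p2, size=int(called.sum())).astype(np.int8)
        row[called] = new
        dosage[i, focal] = row
    return GenotypeMatrix(
        matrix.chrom, matrix.pos, matrix.ref, matrix.alt, dosage,
        list(matrix.samples),
    )


_CLASS_DOSAGE = {"hom_ref": 0, "het": 1, "hom_alt": 2}


def implant_specific_snps(
    matrix: GenotypeMatrix,
    specs: list[SpecificAlleleSpec],
    popmap: PopulationMap,
    threshold: float = 0.8,
) -> GenotypeMatrix:
    """Force the named genotype class to frequency > threshold in the focal
    population and <= spec.other_freq (default 0, always < 1-threshold)
    pooled elsewhere.  Deterministic; implant sites become fully called."""
    if not specs:
        return matrix
    dosage = matrix.dosage.copy()
    key = {(c, int(p)): i for i, (c, p) in
           enumerate(zip(matrix.chrom, matrix.pos))}
    for spec in specs:
        if (spec.chrom, spec.pos) not in key:
            raise KeyError(f"no site at {spec.chrom}:{spec.pos}")
        i = key[(spec.chrom, spec.pos)]
        focal = popmap.indices(spec.focal_pop, matrix.samples)
        other = np.setdiff1d(np.arange(matrix.n_samples), focal)
        nf = len(focal)
        k = int(np.ceil(spec.focal_freq * nf))
        if k / nf <= threshold:
            raise ValueError(
                f"{spec.chrom}:{spec.pos}: {nf} focal samples cannot exceed "
                f"class frequency {threshold} at target {spec.focal_freq}"
            )
        dose = _CLASS_DOSAGE[spec.genotype_class]
        fill = 0 if dose != 0 else 2
        dosage[i, focal[:k]] = dose
        dosage[i, focal[k:]] = fill
        m = int(np.floor(spec.other_freq * len(other)))
        if len(other) and m / len(other) >= 1.0 - threshold:
            raise ValueError(
                f"{spec.chrom}:{spec.pos}: other_freq target "
                f"{spec.other_freq} not below {1 - threshold}"
            )
        dosage[i, other[:m]] = dose
        dosage[i, other[m:]] = fill
    return GenotypeMatrix(
        matrix.chrom, matrix.pos, matrix.ref, matrix.alt, dosage,
        list(matrix.samples),
    )


# ---------------------------------------------------------------------------
# neutral coalescent (calibration substrate)


def simulate_neutral_coalescent(
    n_haplotypes: int, theta: float, seed: int = 1
) -> np.ndarray:
    """Standard neutral coalescent sample: (segregating sites x haplotypes)
    0/1 matrix under the infinite-sites model with scaled mutation rate θ
    (mutations Poisson(θ·branch length/2) on the coalescent time scale).
    """
    import msprime

    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    s = int(seed) % (2**31 - 2) + 1
    ts = msprime.sim_ancestry(
        samples=n_haplotypes, ploidy=1, population_size=1.0,
        sequence_length=1.0, random_seed=s,
    )
    mts = msprime.sim_mutations(
        ts, rate=theta / 2.0, random_seed=s + 1,
        model=msprime.BinaryMutationModel(), discrete_genome=False,
    )
    if mts.num_sites == 0:
        return np.zeros((0, n_haplotypes), dtype=np.int8)
    return mts.genotype_matrix().astype(np.int8)


# ---------------------------------------------------------------------------
# toy genome + gene models

# template gene (transcription order): 120 bp 5'UTR + 90 bp CDS | 300 bp
# intron | 150 bp CDS + 180 bp 3'UTR  => 840 bp span, 240 bp CDS (80 codons)
_U5, _C1, _INT, _C2, _U3 = 120, 90, 300, 150, 180
GENE_SPAN = _U5 + _C1 + _INT + _C2 + _U3

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def generate_toy_genome(
    chrom_lengths: dict[str, int],
    genes_per_chrom: int = 2,
    seed: int = 0,
) -> ToyGenome:
    """Random genome with clean-translating two-exon genes on alternating
    strands, >= 1 gene per chromosome."""
    rng = _stream(seed, 3)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    strand_cycle = ["+", "-"]
    for ci, chrom in enumerate(sorted(chrom_lengths)):
        L = chrom_lengths[chrom]
        if L < GENE_SPAN + 2_200:
            raise ValueError(
                f"{chrom}: length {L} too short for a {GENE_SPAN} bp gene "
                "plus flanks"
            )
        seq = list(_random_seq(rng, L))
        for g in range(genes_per_chrom):
            # evenly spaced starts, keeping >= 1.1 kb clear of chrom ends
            usable = L - 2_200 - GENE_SPAN
            g0 = 1_100 + int((g + 0.5) / genes_per_chrom * usable)  # 0-based
            strand = strand_cycle[(ci + g) % 2]
            n_codons = (_C1 + _C2) // 3
            body = "".join(
                _NONSTOP_CODONS[j]
                for j in rng.integers(0, len(_NONSTOP_CODONS),
                                      size=n_codons - 2)
            )
            cds_seq = "ATG" + body + "TAA"
            gene_seq = (
                _random_seq(rng, _U5) + cds_seq[:_C1]
                + _random_seq(rng, _INT)
                + cds_seq[_C1:] + _random_seq(rng, _U3)
            )
            paste = gene_seq if strand == "+" else _revcomp(gene_seq)
            seq[g0:g0 + GENE_SPAN] = list(paste)
            gs, ge = g0 + 1, g0 + GENE_SPAN  # 1-based inclusive
            gid = f"{chrom}_g{g + 1}"
            gm = GeneModel(
                gene_id=gid, transcript_id=f"{gid}.t1", chrom=chrom,
                strand=strand, start=gs, end=ge,
            )
            if strand == "+":
                exA = (gs, gs + _U5 + _C1 - 1)
                exB = (gs + _U5 + _C1 + _INT, ge)
                gm.utr5 = [(gs, gs + _U5 - 1)]
                gm.cds = [(gs + _U5, exA[1]), (exB[0], exB[0] + _C2 - 1)]
                gm.utr3 = [(exB[0] + _C2, ge)]
            else:
                exA = (ge - (_U5 + _C1) + 1, ge)
                exB = (gs, gs + _C2 + _U3 - 1)
                gm.utr5 = [(ge - _U5 + 1, ge)]
                gm.cds = [(gs + _U3, exB[1]), (exA[0], ge - _U5)]
                gm.utr3 = [(gs, gs + _U3 - 1)]
            gm.exons = sorted([exA, exB])
            gm.cds = sorted(gm.cds)
            genes.append(gm)
        sequences[chrom] = "".join(seq)
    return ToyGenome(sequences, genes)


def harmonize_alleles_with_genome(
    matrix: GenotypeMatrix, genome: ToyGenome, seed: int = 0
) -> GenotypeMatrix:
    """Re-assign REF to the toy-genome base at each site (ALT redrawn with
    the same transition bias), so annotation against the FASTA is
    consistent."""
    rng = _stream(seed, 5)
    ref = np.array([
        genome.sequences[c][p - 1] for c, p in zip(matrix.chrom, matrix.pos)
    ], dtype=object)
    is_ts = rng.random(matrix.n_sites) < 2.0 / 3.0
    tv_pick = rng.integers(0, 2, size=matrix.n_sites)
    alt = np.array([
        _TRANSITION[r] if t else _TRANSVERSIONS[r][j]
        for r, t, j in zip(ref, is_ts, tv_pick)
    ], dtype=object)
    return GenotypeMatrix(
        matrix.chrom, matrix.pos, ref, alt, matrix.dosage,
        list(matrix.samples),
    )


def annotation_scene(seed: int = 0, n_variants: int = 1_000):
    """Toy genome plus SNPs drawn at random positions with REF taken from
    the sequence — the substrate for annotation-exhaustiveness checks.

    Returns (genome, variants) where each variant carries 4 diploid
    genotypes.
    """
    from .io import Variant

    rng = _stream(seed, 6)
    lengths = {"chrA": 20_000, "chrB": 20_000}
    genome = generate_toy_genome(lengths, genes_per_chrom=3, seed=seed)
    variants = []
    per_chrom = n_variants // len(lengths)
    counts = {c: per_chrom for c in sorted(lengths)}
    counts[sorted(lengths)[-1]] += n_variants - per_chrom * len(lengths)
    for chrom in sorted(lengths):
        pos = np.sort(rng.choice(lengths[chrom], size=counts[chrom],
                                 replace=False)) + 1
        for p in pos:
            ref = genome.sequences[chrom][p - 1]
            if rng.random() < 2.0 / 3.0:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][rng.integers(0, 2)]
            gts = []
            for _ in range(4):
                d = int(rng.integers(0, 3))
                gts.append((0, 0) if d == 0 else (0, 1) if d == 1 else (1, 1))
            variants.append(Variant(chrom, int(p), ref, (alt,), gts))
    return genome, variants


# ---------------------------------------------------------------------------
# standard scenes


def sweep_scene(
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationMap, SweepSpec, dict[str, int]]:
    """The standard sweep-recovery scene: 40 Mb genome (eight 5 Mb
    chromosomes), two populations of 20 diploids at F = 0.05, one SNP per
    ~500 bp, and a single 200 kb implant (0.5% of the genome) with 5-fold
    focal diversity loss on chr1.

    The genome is sized so that a fully recovered implant plus the expected
    drift-noise outlier mass at 5%/5% tails stays well under 2% of the
    genome (see the methods note for the feasibility arithmetic).
    """
    lengths = {f"chr{i}": 5_000_000 for i in range(1, 9)}
    config = SimulationConfig(
        n_pops=2, samples_per_pop=(20, 20), pop_names=("pop1", "pop2"),
        chrom_lengths=lengths, n_sites=80_000, F_per_pop=(0.05, 0.05),
        missing_rate=0.02, seed=seed,
    )
    freqs = simulate_population_frequencies(config)
    matrix = simulate_genotypes(freqs, config)
    popmap = config.popmap()
    spec = SweepSpec(
        chrom="chr1", start=2_400_001, end=2_600_000, focal_pop="pop1",
        diversity_reduction=5.0, divergence_boost=0.8,
    )
    matrix = implant_sweep(matrix, spec, popmap, seed=seed)
    return matrix, popmap, spec, lengths


def demo_scene(seed: int = 0) -> dict:
    """Small seven-population end-to-end scene: genotypes, popmap, toy
    genome, one implanted sweep and implanted popC-specific SNPs."""
    config = SimulationConfig(seed=seed)
    freqs = simulate_population_frequencies(config)
    matrix = simulate_genotypes(freqs, config)
    popmap = config.popmap()
    sweep = SweepSpec(
        chrom="chr1", start=300_001, end=380_000, focal_pop="popC",
        diversity_reduction=5.0, divergence_boost=0.8,
    )
    matrix = implant_sweep(matrix, sweep, popmap, seed=seed)
    rng = _stream(seed, 4)
    on_chr2 = np.flatnonzero(matrix.chrom == "chr2")
    picks = rng.choice(on_chr2, size=min(30, len(on_chr2)), replace=False)
    specs = [
        SpecificAlleleSpec(
            chrom=str(matrix.chrom[i]), pos=int(matrix.pos[i]),
            focal_pop="popC",
            genotype_class=("hom_alt", "het", "hom_ref")[j % 3],
        )
        for j, i in enumerate(sorted(picks))
    ]
    matrix = implant_specific_snps(matrix, specs, popmap)
    genome = generate_toy_genome(config.chrom_lengths, genes_per_chrom=3,
                                 seed=seed)
    matrix = harmonize_alleles_with_genome(matrix, genome, seed=seed)
    return {
        "config": config, "matrix": matrix, "popmap": popmap,
        "sweep_spec": sweep, "specific_specs": specs, "genome": genome,
    }
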