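"""Population-specific SNP calling from genotype-class frequencies.

A genotype class (hom-ref 0/0, het 0/1, hom-alt 1/1) is specific to the
focal group at a site when its frequency among called focal samples is
strictly above the threshold (default 0.8) AND strictly below
1 - threshold (default 0.2) among called samples of the comparison group.
The comparison group defaults to the pooled complement of the focal group,
matching a one-breed-vs-all-others design.

Per-chromosome counts of calls in non-overlapping 1 Mb bins anchored at
coordinate 1 are compared between groups with a two-sided Fisher exact
test; bins with p below 0.005 are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MISSING, GeneModel, GenotypeMatrix

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")
_CLASS_DOSAGE = {"hom_ref": 0, "het": 1, "hom_alt": 2}


def genotype_frequencies(
    matrix: GenotypeMatrix, groups: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-site genotype-class frequencies over CALLED samples per group.

    Tidy frame: (chrom, pos, group, n_called, hom_ref, het, hom_alt).
    A group with zero called samples at a site gets NaN frequencies (the
    site is ineligible for calling in that group).
    """
    frames = []
    for g, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {g!r} is empty")
        sub = matrix.dosage[:, idx]
        n_called = (sub != MISSING).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cols = {
                cls: np.where(
                    n_called > 0,
                    (sub == _CLASS_DOSAGE[cls]).sum(axis=1) / n_called,
                    np.nan,
                )
                for cls in GENOTYPE_CLASSES
            }
        frames.append(pd.DataFrame({
            "chrom": matrix.chrom, "pos": matrix.pos, "group": g,
            "n_called": n_called, **cols,
        }))
    return pd.concat(frames, ignore_index=True)


def call_population_specific(
    matrix: GenotypeMatrix,
    focal_idx: np.ndarray,
    other_idx: np.ndarray,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Sites/classes specific to the focal group under the strict
    >threshold / <(1-threshold) rule.

    Returns (chrom, pos, genotype_class, focal_freq, other_freq), at most
    one call per class per site.  Sites with no called sample in either
    group are ineligible.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    sub_f = matrix.dosage[:, focal_idx]
    sub_o = matrix.dosage[:, other_idx]
    nf = (sub_f != MISSING).sum(axis=1)
    no = (sub_o != MISSING).sum(axis=1)
    eligible = (nf > 0) & (no > 0)
    rows = []
    for cls, dose in _CLASS_DOSAGE.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            ff = (sub_f == dose).sum(axis=1) / nf
            fo = (sub_o == dose).sum(axis=1) / no
        hit = eligible & (ff > threshold) & (fo < 1.0 - threshold)
        for i in np.flatnonzero(hit):
            rows.append((matrix.chrom[i], int(matrix.pos[i]), cls,
                         float(ff[i]), float(fo[i])))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "genotype_class",
                       "focal_freq", "other_freq"]
    )
    return df.sort_values(["chrom", "pos", "genotype_class"]).reset_index(drop=True)


def count_per_region(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    region_size: int = 1_000_000,
) -> pd.DataFrame:
    """Counts of calls per non-overlapping bin anchored at coordinate 1.

    Bins are [1, region_size], [region_size+1, 2*region_size], ...; the
    trailing partial bin is kept.  Every bin of every chromosome appears,
    zero counts included.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        nbins = int(np.ceil(L / region_size))
        sub = calls[calls.chrom == chrom]
        binned = ((sub.pos - 1) // region_size).astype(int)
        counts = binned.value_counts()
        for b in range(nbins):
            rows.append((
                chrom, b * region_size + 1, min((b + 1) * region_size, L),
                int(counts.get(b, 0)),
            ))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "count"])


def compare_region_counts(
    counts_focal: pd.DataFrame,
    counts_other: pd.DataFrame,
    total_focal: int,
    total_other: int,
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Per-bin two-sided Fisher exact test of focal-vs-other call counts.

    Each bin contributes the 2x2 table
    [[count_focal, total_focal - count_focal],
     [count_other, total_other - count_other]].
    Bins significant at p < ``alpha`` are flagged.  Both totals zero makes
    every p undefined (NaN).
    """
    merged = counts_focal.merge(
        counts_other, on=["chrom", "bin_start", "bin_end"],
        suffixes=("_focal", "_other"),
    )
    pvals, sig = [], []
    for rec in merged.itertuples():
        if total_focal == 0 and total_other == 0:
            pvals.append(float("nan"))
            sig.append(False)
            continue
        table = [
            [rec.count_focal, total_focal - rec.count_focal],
            [rec.count_other, total_other - rec.count_other],
        ]
        if min(table[0]) < 0 or min(table[1]) < 0:
            raise ValueError("bin count exceeds its group total")
        p = float(sps.fisher_exact(table, alternative="two-sided")[1])
        pvals.append(p)
        sig.append(p < alpha)
    merged["p_value"] = pvals
    merged["significant"] = sig
    return merged


def shared_specific_summary(
    calls_by_group: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Set algebra on (chrom, pos, genotype_class) keys across groups:
    per-group totals, group-exclusive counts, and the count shared with at
    least one other group."""
    keys = {
        g: set(zip(df.chrom, df.pos, df.genotype_class))
        for g, df in calls_by_group.items()
    }
    rows = []
    for g, s in keys.items():
        others = set().union(*(v for k, v in keys.items() if k != g)) \
            if len(keys) > 1 else set()
        rows.append((g, len(s), len(s - others), len(s & others)))
    return pd.DataFrame(rows, columns=["group", "total", "exclusive", "shared"])


def annotate_specific_snps(
    calls: pd.DataFrame, gene_models: list[GeneModel]
) -> pd.DataFrame:
    """Gene ids whose genomic span contains each call position (empty string
    when intergenic)."""
    genes_col = []
    for rec in calls.itertuples():
        hits = sorted({
            gm.gene_id for gm in gene_models
            if gm.chrom == rec.chrom and gm.start <= rec.pos <= gm.end
        })
        genes_col.append(",".join(hits))
    out = calls.copy()
    out["genes"] = genes_col
    return out


def genes_per_group(
    calls_by_group: dict[str, pd.DataFrame], gene_models: list[GeneModel]
) -> pd.DataFrame:
    """Distinct overlapped genes per group (gene-level rollup of
    :func:`annotate_specific_snps`)."""
    rows = []
    for g, calls in calls_by_group.items():
        ann = annotate_specific_snps(calls, gene_models)
        genes = sorted({
            gid for cell in ann.genes for gid in cell.split(",") if gid
        })
        rows.append((g, len(genes), ",".join(genes)))
    return pd.DataFrame(rows, columns=["group", "n_genes", "genes"])
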