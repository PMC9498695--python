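"""Nucleotide diversity, Tajima's D, per-population heterozygosity summaries
and LD decay.

Windowed diversity follows the VCFtools windowed-pi convention: the sum of
per-site unbiased diversity over sites in a window, divided by the full
window span in bp (monomorphic or absent positions contribute zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window definition; defaults are 20 kb windows in 5 kb steps."""

    size: int = 20_000
    step: int = 5_000

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")

    def windows(self, chrom_length: int) -> list[tuple[int, int]]:
        """Half-open 0-based [start, end) windows.

        A window starts at every multiple of ``step`` below the chromosome
        length; the last windows are truncated at the chromosome end.
        """
        out = []
        start = 0
        while start < chrom_length:
            out.append((start, min(start + self.size, chrom_length)))
            start += self.step
        return out


@dataclass(frozen=True)
class TajimaConstants:
    """Normalizing constants of Tajima's D for n sampled haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def site_pi(alt_count: int, called_alleles: int) -> float:
    """Unbiased per-site diversity: mean pairwise difference among the
    ``called_alleles`` sampled haplotypes carrying ``alt_count`` ALT copies.

    Equals 2*k*(n-k)/(n*(n-1)), i.e. the fraction of differing haplotype
    pairs.  Undefined (NaN) for n < 2.
    """
    n, k = called_alleles, alt_count
    if n < 2:
        return float("nan")
    return (n / (n - 1)) * 2.0 * (k / n) * (1.0 - k / n)


def _site_arrays(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (alt count k, called alleles n, het count) for a dosage block."""
    called = dosage != MISSING
    n = 2 * called.sum(axis=1)
    k = np.where(called, dosage, 0).sum(axis=1)
    het = (dosage == 1).sum(axis=1)
    return k.astype(np.int64), n.astype(np.int64), het.astype(np.int64)


def per_site_pi(matrix: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    """Vectorized :func:`site_pi` over all sites for a sample subset.

    Sites with fewer than 2 called alleles get NaN.
    """
    k, n, _ = _site_arrays(matrix.dosage[:, sample_idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * k * (n - k) / (n * (n - 1.0))
    pi[n < 2] = np.nan
    return pi


def _window_sums(
    pos: np.ndarray, values: np.ndarray, windows: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of ``values`` and count of finite entries per half-open window.

    ``pos`` is 1-based and must be sorted; NaNs count as absent sites.
    """
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    p0 = pos - 1  # to 0-based
    sums = np.empty(len(windows))
    counts = np.empty(len(windows), dtype=np.int64)
    for w, (s, e) in enumerate(windows):
        lo = np.searchsorted(p0, s, side="left")
        hi = np.searchsorted(p0, e, side="left")
        sums[w] = csum[hi] - csum[lo]
        counts[w] = ccnt[hi] - ccnt[lo]
    return sums, counts


def windowed_pi(
    matrix: GenotypeMatrix,
    groups: dict[str, np.ndarray],
    scheme: WindowScheme = WindowScheme(),
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window per-group diversity (per-bp over the full window span).

    Returns a tidy frame with columns
    (chrom, start, end, pop, n_sites, pi); start/end half-open 0-based.
    """
    lengths = chrom_lengths or matrix.chrom_lengths()
    pis = {g: per_site_pi(matrix, idx) for g, idx in groups.items()}
    rows = []
    for chrom in sorted(lengths):
        on = matrix.chrom == chrom
        pos = matrix.pos[on]
        windows = scheme.windows(lengths[chrom])
        for g in groups:
            sums, counts = _window_sums(pos, pis[g][on], windows)
            for (s, e), tot, cnt in zip(windows, sums, counts):
                rows.append((chrom, s, e, g, int(cnt), tot / (e - s)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pop", "n_sites", "pi"]
    )


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's D from S segregating sites and the summed mean pairwise
    differences ``pi_sum`` among n haplotypes.  NaN when S = 0 or the
    variance term is non-positive.
    """
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        warnings.warn("non-positive variance term in Tajima's D")
        return float("nan")
    return (pi_sum - S / c.a1) / np.sqrt(var)


def tajimas_d_from_dosage(dosage: np.ndarray) -> float:
    """Tajima's D for a complete-case dosage block (sites x samples).

    Sites with any missing genotype are excluded so the haplotype count n
    stays constant at twice the sample count.
    """
    n = 2 * dosage.shape[1]
    complete = ~(dosage == MISSING).any(axis=1)
    d = dosage[complete].astype(np.int64)
    k = d.sum(axis=1)
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    pi_sum = float(np.sum(2.0 * k[seg] * (n - k[seg]) / (n * (n - 1.0))))
    return tajimas_d(S, pi_sum, n)


def windowed_tajimas_d(
    matrix: GenotypeMatrix,
    groups: dict[str, np.ndarray],
    scheme: WindowScheme = WindowScheme(),
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window Tajima's D per group (complete-case sites only)."""
    lengths = chrom_lengths or matrix.chrom_lengths()
    rows = []
    for g, idx in groups.items():
        n = 2 * len(idx)
        if n < 4:
            raise ValueError(f"group {g!r}: need >= 2 diploid samples")
        sub = matrix.dosage[:, idx]
        complete = ~(sub == MISSING).any(axis=1)
        k = np.where(complete, sub.clip(0).sum(axis=1), 0)
        seg = complete & (k > 0) & (k < n)
        pi_site = np.where(seg, 2.0 * k * (n - k) / (n * (n - 1.0)), np.nan)
        pi_site[~seg] = np.nan
        for chrom in sorted(lengths):
            on = matrix.chrom == chrom
            windows = scheme.windows(lengths[chrom])
            sums, counts = _window_sums(matrix.pos[on], pi_site[on], windows)
            for (s, e), tot, cnt in zip(windows, sums, counts):
                d = tajimas_d(int(cnt), tot, n) if cnt > 0 else float("nan")
                rows.append((chrom, s, e, g, int(cnt), d))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "pop", "n_seg_sites", "tajima_d"]
    )


def population_summary(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> pd.DataFrame:
    """Per-population diversity summary over sites variant *within* the
    population: mean observed/expected heterozygosity, mean per-site
    diversity, mean per-site inbreeding coefficient Fis = 1 - obs/exp, and
    the mean number of non-missing individuals per variant site.
    """
    popmap.validate_against(matrix.samples)
    rows = []
    for pop in popmap.populations:
        idx = popmap.indices(pop, matrix.samples)
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has no samples in matrix")
        sub = matrix.dosage[:, idx]
        k, n, het = _site_arrays(sub)
        n_indv = n // 2
        variant = (k > 0) & (k < n) & (n >= 2)
        if not variant.any():
            warnings.warn(f"population {pop!r}: no variant sites")
            rows.append((pop, len(idx), np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        k, n, het, n_indv = (a[variant] for a in (k, n, het, n_indv))
        p = k / n
        obs = het / n_indv
        exp = (n / (n - 1.0)) * 2.0 * p * (1.0 - p)
        pi = exp  # the unbiased per-site diversity estimator
        ok = exp > 0
        fis = 1.0 - obs[ok] / exp[ok]
        rows.append((
            pop, len(idx), float(n_indv.mean()), float(obs.mean()),
            float(exp.mean()), float(pi.mean()), float(fis.mean()),
        ))
    return pd.DataFrame(
        rows,
        columns=["pop", "num_sam", "num_indv", "obs_het", "exp_het", "pi", "fis"],
    )


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Genotype-correlation (Rogers–Huff) r^2 between two dosage vectors,
    over complete-case samples.  NaN if either vector is constant or fewer
    than 2 complete cases remain.
    """
    ok = (dosage_a != MISSING) & (dosage_b != MISSING)
    a = dosage_a[ok].astype(float)
    b = dosage_b[ok].astype(float)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_decay(
    matrix: GenotypeMatrix,
    sample_idx: np.ndarray | None = None,
    max_dist: int = 300_000,
    bin_size: int = 1_000,
    max_pairs_per_site: int | None = None,
) -> pd.DataFrame:
    """Mean r^2 of intra-chromosome site pairs by physical distance bin.

    Returns (bin_lo, bin_hi, mean_r2, n_pairs); bins are [lo, hi) in bp.
    """
    idx = sample_idx if sample_idx is not None else np.arange(matrix.n_samples)
    nbins = int(np.ceil(max_dist / bin_size))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for chrom in np.unique(matrix.chrom):
        on = np.flatnonzero(matrix.chrom == chrom)
        pos = matrix.pos[on]
        for ii, i in enumerate(on):
            hi = np.searchsorted(pos, pos[ii] + max_dist, side="left")
            js = on[ii + 1:hi]
            if max_pairs_per_site is not None:
                js = js[:max_pairs_per_site]
            for j in js:
                r2 = ld_r2(matrix.dosage[i, idx], matrix.dosage[j, idx])
                if np.isnan(r2):
                    continue
                b = (matrix.pos[j] - pos[ii]) // bin_size
                sums[b] += r2
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_lo": np.arange(nbins) * bin_size,
        "bin_hi": (np.arange(nbins) + 1) * bin_size,
        "mean_r2": mean,
        "n_pairs": counts,
    })
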