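"""Weir & Cockerham (1984) Fst: per-site variance components, windowed
ratio-of-sums aggregation, and genome-wide pairwise matrices.

Site values are a/(a+b+c) with a the among-population and b, c the
within-population components estimated from observed genotype (not
allele-only) counts; negative estimates are retained, matching the
VCFtools/W&C convention.  Aggregation over windows or the genome is always
the weighted ratio sum(a)/sum(a+b+c), never a mean of per-site ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap
from .diversity import WindowScheme, _window_sums


@dataclass
class SiteFst:
    chrom: str
    pos: int
    numerator: float    # a component
    denominator: float  # a + b + c

    @property
    def value(self) -> float:
        if self.denominator == 0:
            return float("nan")
        return self.numerator / self.denominator


def wc_components(
    dosage: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site W&C (1984) numerator a and denominator a+b+c.

    ``dosage`` is sites x samples; ``group_idx`` the per-population sample
    index arrays.  Sites where any population has no called diploid, or
    where mean sample size <= 1, or that are monomorphic overall
    (denominator exactly 0) come back NaN in both arrays.
    """
    r = len(group_idx)
    if r < 2:
        raise ValueError("need >= 2 populations")
    S = dosage.shape[0]
    n = np.empty((r, S))
    p = np.empty((r, S))
    h = np.empty((r, S))
    for i, idx in enumerate(group_idx):
        sub = dosage[:, idx]
        called = sub != MISSING
        ni = called.sum(axis=1).astype(float)
        ki = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p[i] = ki / (2.0 * ni)
            h[i] = (sub == 1).sum(axis=1) / ni
        n[i] = ni
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            inner - ((2 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    num = a
    den = a + b + c
    bad = (n.min(axis=0) < 1) | (nbar <= 1) | ~np.isfinite(den) | (den == 0)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def site_fst_wc(
    matrix: GenotypeMatrix, group_idx: list[np.ndarray]
) -> pd.DataFrame:
    """Per-site Fst components and values as a frame
    (chrom, pos, numerator, denominator, fst)."""
    num, den = wc_components(matrix.dosage, group_idx)
    with np.errstate(invalid="ignore"):
        val = num / den
    return pd.DataFrame({
        "chrom": matrix.chrom, "pos": matrix.pos,
        "numerator": num, "denominator": den, "fst": val,
    })


def windowed_fst(
    matrix: GenotypeMatrix,
    group_idx: list[np.ndarray],
    scheme: WindowScheme = WindowScheme(),
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window weighted (ratio-of-sums) Fst.

    Windows with no defined site get NaN and n_sites 0.
    """
    lengths = chrom_lengths or matrix.chrom_lengths()
    num, den = wc_components(matrix.dosage, group_idx)
    rows = []
    for chrom in sorted(lengths):
        on = matrix.chrom == chrom
        pos = matrix.pos[on]
        windows = scheme.windows(lengths[chrom])
        nsum, ncnt = _window_sums(pos, num[on], windows)
        dsum, _ = _window_sums(pos, den[on], windows)
        for (s, e), a, d, cnt in zip(windows, nsum, dsum, ncnt):
            val = a / d if cnt > 0 and d != 0 else float("nan")
            rows.append((chrom, s, e, int(cnt), val))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "fst"])


def genomewide_fst(matrix: GenotypeMatrix, group_idx: list[np.ndarray]) -> float:
    """Genome-wide weighted Fst over all defined sites."""
    num, den = wc_components(matrix.dosage, group_idx)
    ok = np.isfinite(den)
    if not ok.any():
        raise ValueError("no site with defined Fst")
    return float(np.nansum(num[ok]) / np.nansum(den[ok]))


def genomewide_pairwise_fst(
    matrix: GenotypeMatrix, popmap: PopulationMap
) -> pd.DataFrame:
    """Symmetric genome-wide weighted Fst matrix over all population pairs.

    Each cell uses only the two populations' samples (pairwise semantics).
    """
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    idx = {p: popmap.indices(p, matrix.samples) for p in pops}
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            val = genomewide_fst(matrix, [idx[p1], idx[p2]])
            mat.loc[p1, p2] = mat.loc[p2, p1] = val
    return mat


def fst_extremes(
    matrix: pd.DataFrame, threshold: float = 0.15
) -> dict:
    """Min/max off-diagonal pair and the unordered pairs above ``threshold``.

    Accepts the square frame produced by :func:`genomewide_pairwise_fst`
    (or read back from TSV).
    """
    pops = list(matrix.index)
    pairs = [
        (p1, p2, float(matrix.loc[p1, p2]))
        for i, p1 in enumerate(pops) for p2 in pops[i + 1:]
    ]
    lo = min(pairs, key=lambda t: t[2])
    hi = max(pairs, key=lambda t: t[2])
    above = [(p1, p2, v) for p1, p2, v in pairs if v > threshold]
    return {
        "min_pair": (lo[0], lo[1]), "min_value": lo[2],
        "max_pair": (hi[0], hi[1]), "max_value": hi[2],
        "above_threshold": above, "threshold": threshold,
    }


def write_fst_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="pop")


def read_fst_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="pop")
    df.index.name = None
    return df


def load_goat_fst_matrix() -> pd.DataFrame:
    """Bundled worked example: genome-wide pairwise Weir–Cockerham Fst among
    seven goat breeds (Longlin, Leizhou, Hainan Black, Dazu Black, Jining
    Grey, Boer, Alashan Cashmere) from a published whole-genome
    resequencing panel."""
    from importlib.resources import files

    with (files("selsweep") / "data" / "goat_breeds_fst.tsv").open() as fh:
        return read_fst_matrix(fh)
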