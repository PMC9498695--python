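"""Selective-sweep detection by outlier intersection.

Per 20 kb/5 kb sliding window the scan computes focal-group diversity,
reference-group diversity, their ratio and the weighted Weir–Cockerham Fst
between the groups.  Windows simultaneously in the chosen empirical tails of
the Fst and diversity-ratio distributions are outliers; consecutive
(overlapping or abutting) outlier windows merge into candidate selected
regions which are then annotated with overlapping genes.

Ratio orientation: ``pi_ratio = pi_ref / pi_focal``, so a diversity loss in
the focal group (the sweep signature) produces a HIGH ratio and lives in the
upper tail.  A window with ``pi_focal == 0`` but ``pi_ref > 0`` gets ratio
+inf (always in the top tail); a window with both zero is dropped as
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel, GenotypeMatrix
from .diversity import WindowScheme, windowed_pi
from .fst import windowed_fst


@dataclass(frozen=True)
class OutlierConfig:
    """Empirical-tail configuration for the outlier intersection.

    ``ratio_mode`` "top" keeps only the upper ratio tail (group-vs-group
    scan at 1%/1%); "both" keeps both ratio tails (pairwise breed scans at
    5%), where the lower tail flags sweeps in the reference breed.
    """

    fst_tail: float = 0.01
    ratio_tail: float = 0.01
    ratio_mode: str = "top"  # "top" or "both"

    def __post_init__(self) -> None:
        for t in (self.fst_tail, self.ratio_tail):
            if not (0 < t <= 0.5):
                raise ValueError("tail fractions must be in (0, 0.5]")
        if self.ratio_mode not in ("top", "both"):
            raise ValueError("ratio_mode must be 'top' or 'both'")


def compute_window_stats(
    matrix: GenotypeMatrix,
    focal_idx: np.ndarray,
    ref_idx: np.ndarray,
    scheme: WindowScheme = WindowScheme(),
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window (chrom, start, end, n_sites, pi_focal, pi_ref, pi_ratio,
    fst).  Windows with no defined Fst site are dropped.
    """
    if len(focal_idx) == 0 or len(ref_idx) == 0:
        raise ValueError("focal and reference groups must be nonempty")
    if set(focal_idx.tolist()) & set(ref_idx.tolist()):
        raise ValueError("focal and reference groups must be disjoint")
    lengths = chrom_lengths or matrix.chrom_lengths()
    pi = windowed_pi(
        matrix, {"focal": focal_idx, "ref": ref_idx}, scheme, lengths
    )
    wide = pi.pivot_table(
        index=["chrom", "start", "end"], columns="pop", values="pi"
    ).reset_index()
    fst = windowed_fst(matrix, [focal_idx, ref_idx], scheme, lengths)
    df = wide.merge(fst, on=["chrom", "start", "end"])
    df = df.rename(columns={"focal": "pi_focal", "ref": "pi_ref"})
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (df.pi_focal == 0) & (df.pi_ref == 0),
            np.nan,
            df.pi_ref / df.pi_focal,
        )
    df["pi_ratio"] = ratio
    df = df[df.n_sites > 0].reset_index(drop=True)
    return df[["chrom", "start", "end", "n_sites",
               "pi_focal", "pi_ref", "pi_ratio", "fst"]]


def select_outliers(
    stats: pd.DataFrame, cfg: OutlierConfig = OutlierConfig()
) -> pd.DataFrame:
    """Windows in the Fst upper tail AND the configured ratio tail(s).

    Thresholds are empirical order statistics over windows where the
    statistic is defined; ties at a threshold are included (inclusive
    comparisons).
    """
    fst_ok = stats.fst.notna()
    ratio_ok = stats.pi_ratio.notna()
    n_min = int(np.ceil(1.0 / min(cfg.fst_tail, cfg.ratio_tail)))
    if fst_ok.sum() < n_min or ratio_ok.sum() < n_min:
        raise ValueError(
            f"too few defined windows for tails "
            f"{cfg.fst_tail}/{cfg.ratio_tail} (need >= {n_min})"
        )
    fst_thr = float(
        np.quantile(stats.fst[fst_ok], 1 - cfg.fst_tail, method="higher")
    )
    ratio = stats.pi_ratio[ratio_ok]
    finite = ratio[np.isfinite(ratio)]
    # +inf ratios (zero focal diversity) always sit in the top tail; the
    # order statistic itself is taken over finite values with infs counted
    # above them.
    n_inf = int(np.isinf(ratio).sum())
    q = 1 - cfg.ratio_tail
    if len(finite) > 0:
        hi_thr = float(np.quantile(finite, q, method="higher"))
        lo_thr = float(np.quantile(finite, cfg.ratio_tail, method="lower"))
    else:
        hi_thr, lo_thr = np.inf, np.inf
    sel = (stats.fst >= fst_thr) & fst_ok & ratio_ok
    top = (stats.pi_ratio >= hi_thr) | np.isinf(stats.pi_ratio)
    if cfg.ratio_mode == "both":
        sel &= top | (stats.pi_ratio <= lo_thr)
    else:
        sel &= top
    out = stats[sel].reset_index(drop=True)
    out.attrs["fst_threshold"] = fst_thr
    out.attrs["ratio_threshold_hi"] = hi_thr
    out.attrs["ratio_threshold_lo"] = lo_thr if cfg.ratio_mode == "both" else np.nan
    out.attrs["n_inf_ratio"] = n_inf
    return out


def merge_regions(outliers: pd.DataFrame) -> pd.DataFrame:
    """Union overlapping/abutting outlier windows into maximal regions.

    Returns (chrom, start, end, n_windows, mean_fst, mean_pi_ratio) with
    half-open 0-based coordinates; summary stats are means over constituent
    windows (infinite ratios excluded from the ratio mean).
    """
    if outliers.empty:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "n_windows", "mean_fst", "mean_pi_ratio"
        ])
    df = outliers.sort_values(["chrom", "start"]).reset_index(drop=True)
    rows = []
    cur = None  # [chrom, start, end, fsts, ratios]
    for rec in df.itertuples():
        if cur is not None and rec.chrom == cur[0] and rec.start <= cur[2]:
            cur[2] = max(cur[2], rec.end)
            cur[3].append(rec.fst)
            cur[4].append(rec.pi_ratio)
        else:
            if cur is not None:
                rows.append(cur)
            cur = [rec.chrom, rec.start, rec.end, [rec.fst], [rec.pi_ratio]]
    rows.append(cur)
    out = []
    for chrom, s, e, fsts, ratios in rows:
        finite = [r for r in ratios if np.isfinite(r)]
        out.append((
            chrom, s, e, len(fsts), float(np.mean(fsts)),
            float(np.mean(finite)) if finite else float("inf"),
        ))
    return pd.DataFrame(out, columns=[
        "chrom", "start", "end", "n_windows", "mean_fst", "mean_pi_ratio"
    ])


def annotate_regions(
    regions: pd.DataFrame, gene_models: list[GeneModel]
) -> pd.DataFrame:
    """Attach comma-joined ids of genes whose genomic span overlaps each
    region by >= 1 bp, in coordinate order."""
    genes_col = []
    for rec in regions.itertuples():
        hits = [
            gm for gm in gene_models
            if gm.chrom == rec.chrom
            and gm.start <= rec.end          # region end half-open 0-based
            and gm.end >= rec.start + 1      # gene coords 1-based inclusive
        ]
        seen: list[str] = []
        for gm in sorted(hits, key=lambda g: g.start):
            if gm.gene_id not in seen:
                seen.append(gm.gene_id)
        genes_col.append(",".join(seen))
    out = regions.copy()
    out["genes"] = genes_col
    return out


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """True BED export: 0-based half-open, matching the internal coords."""
    return regions[["chrom", "start", "end"]].copy()


def regions_to_tsv_1based(regions: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive coordinates for the TSV report."""
    out = regions.copy()
    out["start"] = out["start"] + 1
    return out
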