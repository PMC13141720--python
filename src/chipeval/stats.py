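"""Diversity and selection statistics on genotype tables.

Implements per-line heterozygosity summaries (Ho, He, MAF), sliding-window
nucleotide diversity, windowed Weir-Cockerham (1984) F_ST as a ratio of
per-site variance components, locus-specific branch lengths (LSBL), and
empirical-quantile candidate-region calling, including the joint
F_ST / log2 pi-ratio scan for a divergent line pair.

Conventions
-----------
- Windows are 1-based inclusive, anchored at position 1 on each chromosome,
  advanced by the step; terminal partial windows are kept and normalised by
  their actual span.
- Window pi divides the summed per-site pairwise diversity by window span
  in bp (the convention of common windowed-pi tools), so sparse panels give
  proportionally smaller pi -- an intended property when comparing a chip
  panel against dense data.
- Negative F_ST values are reported as computed, never clamped; empirical
  quantiles operate on raw values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeTable, PopulationMap

WINDOW_COLS = ["chrom", "start", "end", "n_sites"]


@dataclass
class CandidateRegionSet:
    """Windows flagged by an empirical-quantile rule."""

    statistic: str
    threshold: float
    quantile: float
    windows: pd.DataFrame  # flagged windows only, WINDOW_COLS + statistic (+ labels)

    @property
    def n_flagged(self) -> int:
        return len(self.windows)

    def to_bed(self, path) -> None:
        """Write flagged windows as BED (0-based half-open: start-1, end)."""
        bed = self.windows.copy()
        bed["bed_start"] = bed["start"] - 1
        bed[["chrom", "bed_start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def _chrom_lengths(gt: GenotypeTable, chrom_lengths: dict | None) -> dict[str, int]:
    obs = gt.variants.groupby("chrom", sort=False)["pos"].max().to_dict()
    if chrom_lengths is None:
        return {c: int(p) for c, p in obs.items()}
    return {c: int(chrom_lengths.get(c, p)) for c, p in obs.items()}


def _window_grid(length: int, window_bp: int, step_bp: int):
    """(start, end) pairs, 1-based inclusive, anchored at 1."""
    out = []
    start = 1
    while start <= length:
        out.append((start, min(start + window_bp - 1, length)))
        start += step_bp
    return out


def allele_stats(gt: GenotypeTable, line: str) -> pd.DataFrame:
    """Per-site alternate-allele counts for the samples of one line.

    Returns columns ``alt_count``, ``called`` (called allele count, i.e. 2x
    called genotypes) and ``freq``; sites with zero called alleles have
    ``freq`` NaN.
    """
    idx = gt.population_map().indices(gt, line)
    d = gt.dosages[idx, :]
    called = 2 * np.sum(~np.isnan(d), axis=0)
    alt = np.nansum(d, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / called, np.nan)
    return pd.DataFrame({"alt_count": alt, "called": called, "freq": freq})


def heterozygosity_summary(
    gt: GenotypeTable,
    pops: PopulationMap | None = None,
    unbiased: bool = False,
) -> pd.DataFrame:
    """Per-line mean Ho, He and MAF over sites with >= 1 called genotype.

    He is the uncorrected 2p(1-p); ``unbiased=True`` applies the
    small-sample factor 2n/(2n-1) per site.  Means are unweighted over all
    sites regardless of polymorphism.
    """
    if pops is None:
        pops = gt.population_map()
    rows = []
    for line in pops.line_labels:
        idx = pops.indices(gt, line)
        d = gt.dosages[idx, :]
        called = np.sum(~np.isnan(d), axis=0)
        ok = called > 0
        if not ok.any():
            raise ValueError(f"line {line!r} has no called sites")
        p = np.nansum(d[:, ok], axis=0) / (2 * called[ok])
        ho = np.nansum(d[:, ok] == 1, axis=0) / called[ok]
        he = 2 * p * (1 - p)
        if unbiased:
            he = he * (2 * called[ok]) / (2 * called[ok] - 1)
        rows.append(
            {
                "line": line,
                "n_samples": len(idx),
                "Ho": float(ho.mean()),
                "He": float(he.mean()),
                "MAF": float(np.minimum(p, 1 - p).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("line")


def _per_site_pi(gt: GenotypeTable, line: str) -> np.ndarray:
    """Unbiased per-site pairwise diversity 2c(n-c)/(n(n-1)).

    ``n`` is the called allele count, ``c`` the alternate count; sites with
    n < 2 get NaN (skipped by window sums).
    """
    st = allele_stats(gt, line)
    n = st["called"].to_numpy().astype(float)
    c = st["alt_count"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 2.0 * c * (n - c) / (n * (n - 1.0))
    val[n < 2] = np.nan
    return val


def _windowed_sum(
    gt: GenotypeTable,
    site_values: np.ndarray,
    window_bp: int,
    step_bp: int,
    chrom_lengths: dict | None,
) -> pd.DataFrame:
    """Sum per-site values into the sliding-window grid.

    Returns WINDOW_COLS plus ``value_sum``; NaN site values are excluded
    and do not count toward ``n_sites``.
    """
    lengths = _chrom_lengths(gt, chrom_lengths)
    chroms = gt.variants["chrom"].to_numpy()
    pos = gt.variants["pos"].to_numpy()
    rows = []
    for chrom, L in lengths.items():
        on = chroms == chrom
        cpos = pos[on]
        cval = site_values[on]
        valid = ~np.isnan(cval)
        for start, end in _window_grid(L, window_bp, step_bp):
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="right")
            v = cval[lo:hi][valid[lo:hi]]
            rows.append((chrom, start, end, len(v), v.sum() if len(v) else 0.0))
    return pd.DataFrame(rows, columns=WINDOW_COLS + ["value_sum"])


def windowed_pi(
    gt: GenotypeTable,
    line: str,
    window_bp: int = 100_000,
    step_bp: int = 30_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity per bp for one line.

    Window pi is the sum of per-site pairwise diversities over sites in
    [start, end], divided by the window span; empty windows report pi = 0.
    """
    if not window_bp >= step_bp >= 1:
        raise ValueError("need window_bp >= step_bp >= 1")
    df = _windowed_sum(gt, _per_site_pi(gt, line), window_bp, step_bp, chrom_lengths)
    span = (df["end"] - df["start"] + 1).to_numpy().astype(float)
    df["pi"] = df.pop("value_sum") / span
    return df


def wc_site_components(
    gt: GenotypeTable, line_x: str, line_y: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site variance components for two lines.

    Returns arrays (a, b, c): among-population, among-individual-within,
    and within-individual components.  Sites where either line has no
    called genotype, or where the average sample size is <= 1, are NaN.
    """
    pops = gt.population_map()
    comp = []
    for line in (line_x, line_y):
        idx = pops.indices(gt, line)
        d = gt.dosages[idx, :]
        n = np.sum(~np.isnan(d), axis=0).astype(float)  # called diploids
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(d, axis=0) / (2 * n)
            h = np.nansum(d == 1, axis=0) / n
        comp.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comp

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def windowed_fst(
    gt: GenotypeTable,
    line_x: str,
    line_y: str,
    window_bp: int = 100_000,
    step_bp: int = 30_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST as a ratio of summed components.

    Window F_ST = sum(a) / sum(a + b + c) over valid sites in the window
    (the weighted estimator); windows with no valid site or a zero
    denominator report NaN.  Negative values are kept as computed.
    """
    a, b, c = wc_site_components(gt, line_x, line_y)
    valid = ~np.isnan(a)
    num = _windowed_sum(gt, np.where(valid, a, np.nan), window_bp, step_bp, chrom_lengths)
    den = _windowed_sum(
        gt, np.where(valid, a + b + c, np.nan), window_bp, step_bp, chrom_lengths
    )
    df = num.rename(columns={"value_sum": "a_sum"})
    df["den_sum"] = den["value_sum"]
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = df["a_sum"] / df["den_sum"]
    df["fst"] = np.where((df["n_sites"] > 0) & (df["den_sum"] != 0), fst, np.nan)
    return df.drop(columns=["a_sum", "den_sum"])


def lsbl(fst_xy, fst_xz, fst_yz):
    """Locus-specific branch length for focal population X.

    LSBL_X = (F_ST(X,Y) + F_ST(X,Z) - F_ST(Y,Z)) / 2; NaN inputs propagate.
    Accepts scalars or aligned arrays.
    """
    return (np.asarray(fst_xy) + np.asarray(fst_xz) - np.asarray(fst_yz)) / 2.0


def lsbl_windows(
    gt: GenotypeTable,
    focal: str,
    ref_y: str,
    ref_z: str,
    window_bp: int = 100_000,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """LSBL of the focal line over non-overlapping windows (step = window)."""
    kw = dict(window_bp=window_bp, step_bp=window_bp, chrom_lengths=chrom_lengths)
    fxy = windowed_fst(gt, focal, ref_y, **kw)
    fxz = windowed_fst(gt, focal, ref_z, **kw)
    fyz = windowed_fst(gt, ref_y, ref_z, **kw)
    df = fxy[WINDOW_COLS].copy()
    df["fst_xy"] = fxy["fst"]
    df["fst_xz"] = fxz["fst"]
    df["fst_yz"] = fyz["fst"]
    df["lsbl"] = lsbl(fxy["fst"], fxz["fst"], fyz["fst"])
    return df


def empirical_top_fraction(
    windows: pd.DataFrame, statistic: str, fraction: float = 0.05
) -> CandidateRegionSet:
    """Flag windows in the top ``fraction`` of an empirical distribution.

    The threshold is the ceil(fraction * N)-th largest of the N non-missing
    values; every window with value >= threshold is flagged, so ties at the
    threshold can push the flagged count above ceil(fraction * N).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    vals = windows[statistic].to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size == 0:
        raise ValueError(f"no non-missing values of {statistic!r}")
    k = math.ceil(fraction * finite.size)
    threshold = float(np.sort(finite)[::-1][k - 1])
    flagged = windows[windows[statistic] >= threshold].reset_index(drop=True)
    return CandidateRegionSet(statistic, threshold, fraction, flagged)


def fst_pi_joint_scan(
    fst_windows: pd.DataFrame,
    pi_windows_x: pd.DataFrame,
    pi_windows_y: pd.DataFrame,
    line_x: str = "X",
    line_y: str = "Y",
    fst_fraction: float = 0.05,
    ratio_tail_fraction: float = 0.025,
) -> CandidateRegionSet:
    """Joint F_ST / log2 pi-ratio scan for divergent selection between two lines.

    A window is flagged when its F_ST lies in the empirical top
    ``fst_fraction`` AND its log2(pi_x / pi_y) lies in either
    ``ratio_tail_fraction`` tail.  Flagged windows carry a ``reduced_line``
    label: the low-ratio tail marks diversity reduced in line X, the high
    tail in line Y.  Windows where either pi is zero are excluded from the
    ratio quantiles and never flagged (logged in the result via n_sites).
    """
    key = ["chrom", "start", "end"]
    df = fst_windows[key + ["n_sites", "fst"]].merge(
        pi_windows_x[key + ["pi"]].rename(columns={"pi": "pi_x"}), on=key
    )
    df = df.merge(pi_windows_y[key + ["pi"]].rename(columns={"pi": "pi_y"}), on=key)
    if df.empty:
        raise ValueError("no coordinate overlap between F_ST and pi window tables")

    pos = (df["pi_x"] > 0) & (df["pi_y"] > 0)
    ratio = np.full(len(df), np.nan)
    ratio[pos] = np.log2(df.loc[pos, "pi_x"] / df.loc[pos, "pi_y"])
    df["log2_pi_ratio"] = ratio

    fst_set = empirical_top_fraction(df.dropna(subset=["fst"]), "fst", fst_fraction)
    finite = ratio[~np.isnan(ratio)]
    lo = float(np.quantile(finite, ratio_tail_fraction))
    hi = float(np.quantile(finite, 1.0 - ratio_tail_fraction))

    in_fst = df["fst"] >= fst_set.threshold
    in_tail = (df["log2_pi_ratio"] <= lo) | (df["log2_pi_ratio"] >= hi)
    flagged = df[in_fst & in_tail & pos].copy()
    flagged["reduced_line"] = np.where(
        flagged["log2_pi_ratio"] <= lo, line_x, line_y
    )
    out = CandidateRegionSet(
        "fst+log2_pi_ratio", fst_set.threshold, fst_fraction, flagged.reset_index(drop=True)
    )
    out.ratio_bounds = (lo, hi)
    out.all_windows = df
    return out


def diversity_report(
    gt: GenotypeTable,
    pops: PopulationMap | None = None,
    window_bp: int = 100_000,
    chrom_lengths: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-line diversity summary plus windowed-pi tables.

    Genome-wide pi per line is the length-weighted mean of non-overlapping
    ``window_bp`` window values (equivalently, total pairwise diversity over
    total span covered by the window grid).
    """
    if pops is None:
        pops = gt.population_map()
    summary = heterozygosity_summary(gt, pops)
    tables: dict[str, pd.DataFrame] = {}
    pis = []
    for line in summary.index:
        w = windowed_pi(gt, line, window_bp, window_bp, chrom_lengths)
        tables[line] = w
        span = (w["end"] - w["start"] + 1).to_numpy(dtype=float)
        pis.append(float(np.sum(w["pi"] * span) / span.sum()))
    summary["pi"] = pis
    return summary, tables
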