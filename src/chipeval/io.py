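"""Genotype containers, VCF input/output, and quality-control filters.

The central container is :class:`GenotypeTable`: a samples x variants matrix
of alternate-allele dosages (0, 1, 2, or NaN for missing) together with
variant coordinates and a per-sample line (sub-population) label.  All
downstream stages -- structure inference, diversity statistics, selection
scans -- operate on this one object, so that a dense panel and a chip panel
go through byte-identical code paths.

QC follows standard SNP-array practice: biallelic autosomal SNPs only,
site-level then sample-level missingness filters, and sliding-window LD
pruning on squared genotype correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Chicken (GRCg7b) autosome names; both bare and "chr"-prefixed dialects.
CHICKEN_AUTOSOMES: tuple[str, ...] = tuple(
    str(i) for i in range(1, 40)
) + tuple(f"chr{i}" for i in range(1, 40))


@dataclass
class GenotypeTable:
    """Diploid biallelic genotypes for a set of samples.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_variants)
        Alternate-allele counts in {0, 1, 2}; missing entries are NaN.
    variants : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 1-based), ``ref``, ``alt``;
        sorted by (chrom, pos).
    sample_ids : list of str
    lines : list of str
        Line label per sample, aligned with ``sample_ids``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]
    lines: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(self.lines) != len(self.sample_ids):
            raise ValueError("lines and sample_ids must have equal length")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def population_map(self) -> "PopulationMap":
        return PopulationMap(dict(zip(self.sample_ids, self.lines)))

    def take_variants(self, idx) -> "GenotypeTable":
        """Subset to the variant columns ``idx`` (order preserved as given)."""
        idx = np.asarray(idx)
        return GenotypeTable(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
            list(self.lines),
        )

    def take_samples(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            self.dosages[idx, :],
            self.variants.copy(),
            [self.sample_ids[i] for i in idx],
            [self.lines[i] for i in idx],
        )

    def sort_variants(self) -> "GenotypeTable":
        """Return a copy sorted by (chrom, pos) with a stable sort."""
        order = self.variants.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        return self.take_variants(order)

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.lines == other.lines
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


class PopulationMap:
    """Mapping from sample id to line label with per-line index helpers."""

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    @classmethod
    def read(cls, path) -> "PopulationMap":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["sample_id", "line"], dtype=str
        )
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in population map: {dups}")
        return cls(dict(zip(df["sample_id"], df["line"])))

    def write(self, path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.mapping), "line": list(self.mapping.values())}
        ).to_csv(path, sep="\t", header=False, index=False)

    def __getitem__(self, sample_id: str) -> str:
        return self.mapping[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.mapping

    @property
    def line_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.mapping.values():
            seen.setdefault(v)
        return list(seen)

    def indices(self, gt: GenotypeTable, line: str) -> np.ndarray:
        """Row indices in ``gt`` of the samples belonging to ``line``."""
        idx = [i for i, s in enumerate(gt.sample_ids) if self.mapping.get(s) == line]
        if not idx:
            raise KeyError(f"no samples with line label {line!r}")
        return np.asarray(idx)


@dataclass
class QcConfig:
    """Thresholds for site/sample filtering and LD pruning.

    ``max_site_missing_rate`` and ``max_sample_missing_rate`` are strict
    upper bounds (a site exactly at the threshold is retained).  LD pruning
    uses a sliding window of ``ld_window_snps`` SNPs advanced by
    ``ld_step_snps``, removing the later member of any within-window pair
    whose squared Pearson dosage correlation exceeds ``ld_r2_max``.
    """

    max_site_missing_rate: float = 0.01
    max_sample_missing_rate: float = 0.05
    autosomes_only: bool = True
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.2
    autosomes: tuple[str, ...] = field(default=CHICKEN_AUTOSOMES)

    def __post_init__(self) -> None:
        for r in (self.max_site_missing_rate, self.max_sample_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing-rate threshold {r} outside [0, 1]")
        if self.ld_step_snps > self.ld_window_snps:
            raise ValueError("ld_step_snps must be <= ld_window_snps")


def read_vcf(path, population_map_path=None, population_map: PopulationMap | None = None) -> GenotypeTable:
    """Read a VCF (v4.x, GT field) into a :class:`GenotypeTable`.

    Multi-allelic records and non-SNP records (indels, MNPs) are dropped,
    with a logged count.  Phased separators are accepted; half-calls and
    other malformed GTs raise with the record coordinate.  Every VCF sample
    must appear in the population map.
    """
    if population_map is None:
        if population_map_path is None:
            raise ValueError("either population_map_path or population_map is required")
        population_map = PopulationMap.read(population_map_path)

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_from_map = [s for s in samples if s not in population_map]
    if missing_from_map:
        raise ValueError(
            f"samples in VCF but absent from population map: {missing_from_map}"
        )

    rows = []
    cols = []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        # gts012: 0/1/2 = dosage, 3 = missing
        g = np.asarray(v.gt_types, dtype=np.float64)
        bad = (g < 0) | (g > 3)
        if bad.any():
            raise ValueError(f"malformed GT at {v.CHROM}:{v.POS}")
        g[g == 3] = np.nan
        cols.append(g)
        rows.append((str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    gt = GenotypeTable(
        dosages, variants, samples, [population_map[s] for s in samples]
    )
    return gt.sort_variants()


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write a minimal VCF v4.2 with a GT-only FORMAT field.

    Unphased separators; missing genotypes as ``./.``.  The output
    round-trips through :func:`read_vcf` to an equal table.
    """
    gt = gt.sort_variants()
    chrom_max = gt.variants.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chipeval\n")
        for chrom, mx in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={int(mx) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.sample_ids)
            + "\n"
        )
        gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in enumerate(gt.variants.itertuples(index=False)):
            col = gt.dosages[:, j]
            calls = "\t".join(
                "./." if np.isnan(d) else gt_strings[d] for d in col
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{calls}\n"
            )


def apply_qc(gt: GenotypeTable, cfg: QcConfig) -> tuple[GenotypeTable, dict]:
    """Apply coordinate and missingness filters; return (table, filter report).

    Order is fixed: non-autosomal sites out first (when configured), then
    sites with missing rate strictly above ``max_site_missing_rate``, then
    samples with missing rate strictly above ``max_sample_missing_rate``.
    The report counts removals per rule.
    """
    if gt.n_variants == 0:
        raise ValueError("empty genotype table")
    report = {"input_sites": gt.n_variants, "input_samples": gt.n_samples}

    if cfg.autosomes_only:
        autosomal = gt.variants["chrom"].isin(cfg.autosomes).to_numpy()
        report["non_autosomal_sites_removed"] = int((~autosomal).sum())
        gt = gt.take_variants(np.flatnonzero(autosomal))
    else:
        report["non_autosomal_sites_removed"] = 0
    if gt.n_variants == 0:
        raise ValueError("all sites removed by autosome filter")

    miss = np.isnan(gt.dosages)
    site_rate = miss.mean(axis=0)
    keep_sites = site_rate <= cfg.max_site_missing_rate
    report["high_missing_sites_removed"] = int((~keep_sites).sum())
    gt = gt.take_variants(np.flatnonzero(keep_sites))
    if gt.n_variants == 0:
        raise ValueError("all sites removed by missingness filter")

    sample_rate = np.isnan(gt.dosages).mean(axis=1)
    keep_samples = sample_rate <= cfg.max_sample_missing_rate
    report["high_missing_samples_removed"] = int((~keep_samples).sum())
    gt = gt.take_samples(np.flatnonzero(keep_samples))
    if gt.n_samples == 0:
        raise ValueError("all samples removed by missingness filter")

    report["output_sites"] = gt.n_variants
    report["output_samples"] = gt.n_samples
    return gt, report


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns of ``X``.

    Pairwise-complete observations; pairs with fewer than 2 complete
    observations or zero variance get r^2 = 0.
    """
    M = (~np.isnan(X)).astype(np.float64)
    X0 = np.where(np.isnan(X), 0.0, X)
    n = M.T @ M
    sx = X0.T @ M          # sx[i, j] = sum of x_i over samples complete in (i, j)
    sxx = (X0 * X0).T @ M
    sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n
        r2 = cov * cov / (varx * varx.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(gt: GenotypeTable, cfg: QcConfig) -> GenotypeTable:
    """Sliding-window LD pruning on squared dosage correlation.

    Per chromosome, windows of ``ld_window_snps`` currently-kept sites are
    scanned left to right in steps of ``ld_step_snps``; within a window,
    pairs are visited in index order and the later site of any pair with
    r^2 > ``ld_r2_max`` is removed.  Passes repeat until no site is removed,
    so the retained set is deterministic for a fixed input order.  The
    left-most site of each correlated pair (and hence of each chromosome)
    is always kept.
    """
    gt = gt.sort_variants()
    keep_all: list[int] = []
    for chrom in gt.variants["chrom"].unique():
        sites = np.flatnonzero((gt.variants["chrom"] == chrom).to_numpy())
        kept = list(sites)
        changed = True
        while changed:
            changed = False
            pos = 0
            while pos < len(kept):
                win = kept[pos : pos + cfg.ld_window_snps]
                if len(win) >= 2:
                    r2 = _pairwise_r2(gt.dosages[:, win])
                    drop: set[int] = set()
                    for i in range(len(win)):
                        if i in drop:
                            continue
                        for j in range(i + 1, len(win)):
                            if j in drop:
                                continue
                            if r2[i, j] > cfg.ld_r2_max:
                                drop.add(j)
                    if drop:
                        dropped = {win[j] for j in drop}
                        kept = [s for s in kept if s not in dropped]
                        changed = True
                pos += cfg.ld_step_snps
        keep_all.extend(kept)
    return gt.take_variants(np.asarray(sorted(keep_all), dtype=int))
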