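"""Cross-platform agreement metrics for results on the same individuals.

Given the outputs of two genotyping platforms (e.g. a dense panel and a
chip-like subset), quantify how well they agree on: principal components
(sign-aligned Pearson r per component), per-line diversity (Spearman rank
correlation and an exact-ordering flag), candidate selection regions
(Jaccard of merged regions plus reciprocal-overlap counts), and ancestry
matrices (RMSE after the best column permutation).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import CandidateRegionSet
from .structure import PCAResult


def align_and_correlate_pcs(a: PCAResult, b: PCAResult, n_components: int = 2) -> dict[str, float]:
    """Per-component Pearson r between two PCA results after sign alignment.

    Component signs are arbitrary per platform, so each component's sign is
    chosen to maximise r before reporting.  Samples are matched by id.
    """
    if set(a.sample_ids) != set(b.sample_ids):
        only_a = sorted(set(a.sample_ids) - set(b.sample_ids))
        only_b = sorted(set(b.sample_ids) - set(a.sample_ids))
        raise ValueError(f"sample sets differ: only in a={only_a}, only in b={only_b}")
    order = [b.sample_ids.index(s) for s in a.sample_ids]
    out = {}
    for i in range(n_components):
        x = a.scores[:, i]
        y = b.scores[order, i]
        r = float(np.corrcoef(x, y)[0, 1])
        out[f"r_PC{i + 1}"] = abs(r) if not np.isnan(r) else np.nan
    return out


def diversity_rank_concordance(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Spearman rank agreement of per-line diversity between two platforms.

    ``a`` and ``b`` are diversity summaries indexed by line with He and pi
    columns.  Returns Spearman rho for each statistic plus an
    ``ordering_match`` flag that is True iff the rank vectors are identical;
    with fewer than 3 lines rho is undefined (NaN) and only the flag is
    meaningful.
    """
    if set(a.index) != set(b.index):
        raise ValueError("line sets differ between the two summaries")
    b = b.loc[a.index]
    out: dict = {}
    match = True
    for stat in ("He", "pi"):
        if stat not in a.columns or stat not in b.columns:
            continue
        ra = a[stat].rank()
        rb = b[stat].rank()
        match = match and bool((ra == rb).all())
        if len(a) >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = float(sps.spearmanr(a[stat], b[stat]).statistic)
        else:
            rho = float("nan")
        out[f"spearman_{stat}"] = rho
    out["ordering_match"] = match
    return out


def _merge_windows(windows: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Fuse overlapping/adjacent flagged windows into regions (1-based inclusive)."""
    regions: list[tuple[str, int, int]] = []
    for chrom, grp in windows.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur = None
        for start, end in zip(grp["start"], grp["end"]):
            if cur is None:
                cur = [start, end]
            elif start <= cur[1] + 1:
                cur[1] = max(cur[1], end)
            else:
                regions.append((chrom, cur[0], cur[1]))
                cur = [start, end]
        if cur is not None:
            regions.append((chrom, cur[0], cur[1]))
    return regions


def region_overlap(a: CandidateRegionSet, b: CandidateRegionSet) -> dict:
    """Jaccard index and reciprocal-overlap counts of two candidate sets.

    Flagged windows are first merged into regions; Jaccard is overlapping bp
    over union bp under 1-based inclusive coordinates.  Empty sets give
    Jaccard 0 with a warning rather than an error.
    """
    ra = _merge_windows(a.windows) if len(a.windows) else []
    rb = _merge_windows(b.windows) if len(b.windows) else []
    if not ra or not rb:
        warnings.warn("empty candidate-region set; Jaccard reported as 0")
        return {
            "jaccard": 0.0,
            "n_regions_a": len(ra),
            "n_regions_b": len(rb),
            "a_hit_by_b": 0,
            "b_hit_by_a": 0,
        }

    def span(regions):
        return sum(e - s + 1 for _, s, e in regions)

    inter = 0
    a_hit = set()
    b_hit = set()
    for i, (ca, sa, ea) in enumerate(ra):
        for j, (cb, sb, eb) in enumerate(rb):
            if ca != cb:
                continue
            lo, hi = max(sa, sb), min(ea, eb)
            if lo <= hi:
                inter += hi - lo + 1
                a_hit.add(i)
                b_hit.add(j)
    union = span(ra) + span(rb) - inter
    return {
        "jaccard": inter / union if union else 0.0,
        "n_regions_a": len(ra),
        "n_regions_b": len(rb),
        "a_hit_by_b": len(a_hit),
        "b_hit_by_a": len(b_hit),
    }


def q_matrix_agreement(Qa: np.ndarray, Qb: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Minimal RMSE between two ancestry matrices over column permutations.

    Ancestry components are identifiable only up to relabelling, so the RMSE
    is minimised over all K! column permutations (K <= 8 enforced).  Returns
    (rmse, permutation applied to Qb's columns).
    """
    Qa = np.asarray(Qa, dtype=float)
    Qb = np.asarray(Qb, dtype=float)
    if Qa.shape != Qb.shape:
        raise ValueError(f"Q shapes differ: {Qa.shape} vs {Qb.shape}")
    K = Qa.shape[1]
    if K > 8:
        raise ValueError("permutation search limited to K <= 8")
    best = (np.inf, tuple(range(K)))
    for perm in itertools.permutations(range(K)):
        rmse = float(np.sqrt(np.mean((Qa - Qb[:, perm]) ** 2)))
        if rmse < best[0]:
            best = (rmse, perm)
    return best


@dataclass
class ConcordanceReport:
    """Bundle of cross-platform agreement metrics, serialisable as JSON."""

    pc_correlations: dict[str, float] = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)
    ancestry_rmse: float | None = None
    ancestry_permutation: tuple[int, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "pc_correlations": self.pc_correlations,
            "diversity": self.diversity,
            "regions": self.regions,
            "ancestry_rmse": self.ancestry_rmse,
            "ancestry_permutation": (
                list(self.ancestry_permutation)
                if self.ancestry_permutation is not None
                else None
            ),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def summary(self) -> str:
        lines = ["Platform concordance", "===================="]
        for k, v in self.pc_correlations.items():
            lines.append(f"{k}: {v:.4f}")
        for k, v in self.diversity.items():
            lines.append(f"{k}: {v}")
        if self.regions:
            lines.append(f"region Jaccard: {self.regions.get('jaccard', 0.0):.4f}")
        if self.ancestry_rmse is not None:
            lines.append(f"ancestry Q RMSE: {self.ancestry_rmse:.4f}")
        return "\n".join(lines)


def concordance_report(
    pca_a: PCAResult | None = None,
    pca_b: PCAResult | None = None,
    diversity_a: pd.DataFrame | None = None,
    diversity_b: pd.DataFrame | None = None,
    regions_a: CandidateRegionSet | None = None,
    regions_b: CandidateRegionSet | None = None,
    Qa: np.ndarray | None = None,
    Qb: np.ndarray | None = None,
    n_components: int = 2,
) -> ConcordanceReport:
    """Assemble a :class:`ConcordanceReport` from whichever pairs are given."""
    rep = ConcordanceReport()
    if pca_a is not None and pca_b is not None:
        rep.pc_correlations = align_and_correlate_pcs(pca_a, pca_b, n_components)
    if diversity_a is not None and diversity_b is not None:
        rep.diversity = diversity_rank_concordance(diversity_a, diversity_b)
    if regions_a is not None and regions_b is not None:
        rep.regions = region_overlap(regions_a, regions_b)
    if Qa is not None and Qb is not None:
        rep.ancestry_rmse, rep.ancestry_permutation = q_matrix_agreement(Qa, Qb)
    return rep
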