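"""Seeded genotype simulation under the Balding-Nichols drift model.

Each marker gets an ancestral allele frequency drawn Uniform(0.05, 0.95).
A population with drift parameter ``F`` draws its frequency from a Beta
distribution centred on its parent frequency ``p`` with shape
``(p(1-F)/F, (1-p)(1-F)/F)``, so that the expected Weir-Cockerham F_ST
between two independently drifted populations is approximately the sum of
their F values.  Lines may drift from the ancestral pool directly or from
an intermediate breed-level frequency vector, and lines in a
``shared_ancestry`` group reuse a single line-frequency vector (emulating
nearly undifferentiated sister lines).  Genotypes are binomial draws from
line frequencies; optional admixed samples draw each of their two alleles
from an ancestry chosen by a per-sample proportion vector.

A chip-like platform is derived from the dense panel by MAF-ascertained
thinning (:func:`ascertain_chip`), never re-simulated, so platform
differences are purely ascertainment.  All randomness flows from one seed
through named ``numpy`` child streams (frequencies, genotypes, positions,
missingness), so any stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeTable, PopulationMap

_MIN_F = 1e-6


@dataclass
class LineSpec:
    """One breeding line: its label, sample count, drift F, and parent pool.

    ``parent`` is ``"ancestral"`` or the name of a breed-level frequency
    vector declared in :attr:`SimulationConfig.breed_F`.
    """

    label: str
    n_samples: int
    F: float
    parent: str = "ancestral"


@dataclass
class SimulationConfig:
    n_markers: int
    chromosome_lengths: dict[str, int]
    line_specs: list[LineSpec]
    breed_F: dict[str, float] = field(default_factory=dict)
    shared_ancestry: list[list[str]] = field(default_factory=list)
    admixture_rows: list[tuple[str, Sequence[float]]] = field(default_factory=list)
    selection_spikes: list[tuple[str, str, tuple[int, int], float]] = field(
        default_factory=list
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for spec in self.line_specs:
            if not _MIN_F < spec.F < 1 - _MIN_F:
                raise ValueError(f"line {spec.label}: F={spec.F} outside (0, 1)")
        for name, f in self.breed_F.items():
            if not _MIN_F < f < 1 - _MIN_F:
                raise ValueError(f"breed {name}: F={f} outside (0, 1)")
        for label, w in self.admixture_rows:
            w = np.asarray(w, dtype=float)
            if abs(w.sum() - 1.0) > 1e-8:
                raise ValueError(f"admixture row for {label} does not sum to 1")
        for line, chrom, (start, end), mag in self.selection_spikes:
            if chrom not in self.chromosome_lengths:
                raise ValueError(f"spike chromosome {chrom!r} unknown")
            if not 1 <= start <= end <= self.chromosome_lengths[chrom]:
                raise ValueError(f"spike interval ({start}, {end}) outside {chrom}")


@dataclass
class ChipAscertainmentConfig:
    """MAF-ascertained thinning to a fixed chip-like marker count."""

    maf_min: float = 0.05
    n_chip_markers: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")


def _balding_nichols(rng: np.random.Generator, parent: np.ndarray, F: float) -> np.ndarray:
    a = parent * (1.0 - F) / F
    b = (1.0 - parent) * (1.0 - F) / F
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        bad = int(np.flatnonzero(~(np.isfinite(a) & np.isfinite(b)))[0])
        raise ValueError(f"Beta parameters overflow at marker {bad} (F={F})")
    return rng.beta(a, b)


def _draw_positions(rng: np.random.Generator, lengths: dict[str, int], n: int):
    """Distribute n markers over chromosomes in proportion to length."""
    chroms = list(lengths)
    total = sum(lengths.values())
    counts = np.floor([n * lengths[c] / total for c in chroms]).astype(int)
    for i in range(n - counts.sum()):  # distribute the remainder
        counts[i % len(chroms)] += 1
    chrom_col, pos_col = [], []
    for c, m in zip(chroms, counts):
        L = lengths[c]
        if m > L:
            raise ValueError(f"chromosome {c} too short for {m} distinct positions")
        pos = np.unique(rng.integers(1, L + 1, size=m))
        while len(pos) < m:
            extra = rng.integers(1, L + 1, size=m - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chrom_col.extend([c] * m)
        pos_col.append(np.sort(pos))
    return np.asarray(chrom_col, dtype=object), np.concatenate(pos_col)


def simulate_populations(cfg: SimulationConfig) -> tuple[GenotypeTable, dict]:
    """Simulate genotypes; return (table, truth record).

    The truth record holds every frequency vector, admixture row and spike
    interval actually used, sufficient for parameter-recovery tests.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_freq, rng_geno, rng_pos, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    chrom_col, pos_col = _draw_positions(rng_pos, cfg.chromosome_lengths, cfg.n_markers)
    p_anc = rng_freq.uniform(0.05, 0.95, size=cfg.n_markers)

    breed_freqs = {
        name: _balding_nichols(rng_freq, p_anc, f) for name, f in cfg.breed_F.items()
    }

    def parent_vector(spec: LineSpec) -> np.ndarray:
        if spec.parent == "ancestral":
            return p_anc
        return breed_freqs[spec.parent]

    shared_of = {lab: grp[0] for grp in cfg.shared_ancestry for lab in grp}
    line_freqs: dict[str, np.ndarray] = {}
    for spec in cfg.line_specs:
        rep = shared_of.get(spec.label, spec.label)
        if rep in line_freqs:
            line_freqs[spec.label] = line_freqs[rep]
            continue
        q = _balding_nichols(rng_freq, parent_vector(spec), spec.F)
        line_freqs[rep] = q
        line_freqs[spec.label] = q

    # selection spikes: push the focal line's frequency toward fixation
    spiked: dict[str, np.ndarray] = {}
    for line, chrom, (start, end), mag in cfg.selection_spikes:
        q = spiked.setdefault(line, line_freqs[line].copy())
        in_iv = (chrom_col == chrom) & (pos_col >= start) & (pos_col <= end)
        q[in_iv] = q[in_iv] + mag * (1.0 - q[in_iv])
    for line, q in spiked.items():
        line_freqs[line] = q

    sample_ids: list[str] = []
    lines: list[str] = []
    blocks: list[np.ndarray] = []
    for spec in cfg.line_specs:
        q = line_freqs[spec.label]
        blocks.append(rng_geno.binomial(2, q, size=(spec.n_samples, cfg.n_markers)))
        sample_ids.extend(f"{spec.label}_{i:03d}" for i in range(spec.n_samples))
        lines.extend([spec.label] * spec.n_samples)

    line_order = [s.label for s in cfg.line_specs]
    for label, w in cfg.admixture_rows:
        w = np.asarray(w, dtype=float)
        anc = rng_geno.choice(len(line_order), size=(2, cfg.n_markers), p=w)
        freq_stack = np.stack([line_freqs[l] for l in line_order])
        alleles = rng_geno.random((2, cfg.n_markers)) < freq_stack[anc, np.arange(cfg.n_markers)]
        blocks.append(alleles.sum(axis=0, dtype=np.int64)[None, :])
        sample_ids.append(label)
        lines.append("ADMIXED")

    dosages = np.concatenate(blocks, axis=0).astype(np.float64)
    if cfg.missing_rate > 0:
        mask = rng_miss.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    variants = pd.DataFrame(
        {
            "chrom": chrom_col,
            "pos": pos_col.astype(int),
            "ref": "A",
            "alt": "G",
        }
    )
    gt = GenotypeTable(dosages, variants, sample_ids, lines).sort_variants()
    truth = {
        "ancestral_freq": p_anc,
        "breed_freqs": breed_freqs,
        "line_freqs": line_freqs,
        "admixture_rows": list(cfg.admixture_rows),
        "selection_spikes": list(cfg.selection_spikes),
        "chrom": chrom_col,
        "pos": pos_col,
    }
    return gt, truth


def pooled_maf(gt: GenotypeTable) -> np.ndarray:
    """Minor allele frequency per site over all samples (missing excluded)."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(gt.dosages, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    return np.minimum(p, 1.0 - p)


def ascertain_chip(gt: GenotypeTable, cfg: ChipAscertainmentConfig) -> GenotypeTable:
    """Thin a dense panel to a chip-like one: MAF filter then uniform draw.

    Sites with pooled MAF >= ``maf_min`` are eligible; ``n_chip_markers``
    are sampled uniformly without replacement (seeded) and returned in
    genomic order.  The sample set is unchanged.
    """
    maf = pooled_maf(gt)
    eligible = np.flatnonzero(maf >= cfg.maf_min)
    if len(eligible) < cfg.n_chip_markers:
        raise ValueError(
            f"only {len(eligible)} sites pass MAF >= {cfg.maf_min}, "
            f"cannot select {cfg.n_chip_markers}"
        )
    rng = np.random.default_rng(cfg.seed)
    chosen = rng.choice(eligible, size=cfg.n_chip_markers, replace=False)
    return gt.take_variants(np.sort(chosen))


def four_line_scenario(
    seed: int = 0,
    n_markers: int = 50_000,
    n_chip_markers: int = 5_000,
) -> tuple[GenotypeTable, GenotypeTable, PopulationMap, dict]:
    """Default two-breed, four-line evaluation scenario on two platforms.

    Lines A (n=20) and B (n=34) share one frequency vector within the first
    breed; lines C (n=34) and D (n=40) drift independently within the second
    breed, with stronger drift in C so that C-D diverge and D keeps higher
    within-line diversity.  Returns the dense table, the chip-ascertained
    table (MAF >= 0.05), the population map, and the simulation truth.
    """
    cfg = SimulationConfig(
        n_markers=n_markers,
        chromosome_lengths={str(i): 20_000_000 for i in range(1, 11)},
        line_specs=[
            LineSpec("A", 20, 0.05, parent="Arp"),
            LineSpec("B", 34, 0.05, parent="Arp"),
            LineSpec("C", 34, 0.10, parent="RIR"),
            LineSpec("D", 40, 0.03, parent="RIR"),
        ],
        breed_F={"Arp": 0.15, "RIR": 0.15},
        shared_ancestry=[["A", "B"]],
        missing_rate=0.005,
        seed=seed,
    )
    dense, truth = simulate_populations(cfg)
    chip = ascertain_chip(
        dense,
        ChipAscertainmentConfig(maf_min=0.05, n_chip_markers=n_chip_markers, seed=seed),
    )
    return dense, chip, dense.population_map(), truth
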