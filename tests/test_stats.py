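"""Diversity statistics, Weir-Cockerham F_ST, LSBL and candidate scans."""

import numpy as np
import pandas as pd
import pytest

from chipeval.simulate import LineSpec, SimulationConfig, simulate_populations
from chipeval.stats import (
    allele_stats,
    diversity_report,
    empirical_top_fraction,
    fst_pi_joint_scan,
    heterozygosity_summary,
    lsbl,
    lsbl_windows,
    wc_site_components,
    windowed_fst,
    windowed_pi,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# allele counts and heterozygosity
# ---------------------------------------------------------------------------

def test_allele_stats_basic_counts():
    gt = make_table(np.array([[0.0], [1.0], [1.0], [2.0]]))
    st = allele_stats(gt, "L")
    assert st.loc[0, "alt_count"] == 4
    assert st.loc[0, "called"] == 8
    assert st.loc[0, "freq"] == 0.5

    gt.dosages[0, 0] = np.nan
    st = allele_stats(gt, "L")
    assert st.loc[0, "called"] == 6


def test_allele_stats_matches_tally_oracle(rng):
    d = rng.integers(0, 3, size=(9, 25)).astype(float)
    d[rng.random(d.shape) < 0.2] = np.nan
    gt = make_table(d)
    st = allele_stats(gt, "L")
    for j in range(25):
        alt = called = 0
        for i in range(9):
            if not np.isnan(d[i, j]):
                alt += int(d[i, j])
                called += 2
        assert st.loc[j, "alt_count"] == alt
        assert st.loc[j, "called"] == called


def test_heterozygosity_all_het_and_monomorphic():
    gt = make_table(np.ones((10, 1)))
    s = heterozygosity_summary(gt)
    assert s.loc["L", "Ho"] == 1.0
    assert s.loc["L", "He"] == pytest.approx(0.5)
    assert s.loc["L", "MAF"] == pytest.approx(0.5)

    s0 = heterozygosity_summary(make_table(np.zeros((10, 1))))
    assert (s0.loc["L", ["Ho", "He", "MAF"]] == 0).all()


def test_heterozygosity_means_equal_hand_sums():
    d = np.array(
        [
            [0, 1, 2, 1, 0],
            [1, 1, 2, 0, 0],
            [0, 1, 2, 1, 1],
            [2, 1, 2, 0, 0],
        ],
        dtype=float,
    )
    s = heterozygosity_summary(make_table(d))
    p = d.mean(axis=0) / 2
    assert s.loc["L", "Ho"] == pytest.approx(np.mean((d == 1).mean(axis=0)))
    assert s.loc["L", "He"] == pytest.approx(np.mean(2 * p * (1 - p)))
    assert s.loc["L", "MAF"] == pytest.approx(np.mean(np.minimum(p, 1 - p)))


def test_statistics_invariant_under_relabelling(rng):
    """Sample reordering and ref/alt swap leave Ho, He, MAF and pi unchanged."""
    d = rng.integers(0, 3, size=(14, 30)).astype(float)
    gt = make_table(d)
    base = heterozygosity_summary(gt)

    perm = rng.permutation(14)
    shuffled = heterozygosity_summary(gt.take_samples(perm))
    pd.testing.assert_frame_equal(base, shuffled)

    swapped = heterozygosity_summary(make_table(2.0 - d))
    pd.testing.assert_frame_equal(base, swapped)

    w1 = windowed_pi(gt, "L", 1000, 1000)
    w2 = windowed_pi(make_table(2.0 - d), "L", 1000, 1000)
    pd.testing.assert_frame_equal(w1, w2)


# ---------------------------------------------------------------------------
# windowed pi
# ---------------------------------------------------------------------------

def test_windowed_pi_single_site_value():
    # 2 diploids, dosages (1, 1): 4 alleles, 2 alt -> per-site 2*2*2/(4*3) = 2/3
    gt = make_table(np.array([[1.0], [1.0]]), positions=[500])
    w = windowed_pi(gt, "L", 100_000, 100_000, chrom_lengths={"1": 100_000})
    assert len(w) == 1
    assert w.loc[0, "pi"] == pytest.approx((2 / 3) / 100_000)
    assert w.loc[0, "n_sites"] == 1


def test_windowed_pi_monomorphic_is_zero():
    gt = make_table(np.zeros((5, 3)))
    w = windowed_pi(gt, "L", 1000, 1000)
    assert (w["pi"] == 0).all()


def test_windowed_pi_site_assignment_matches_interval_oracle(rng):
    pos = np.sort(rng.choice(np.arange(1, 400_001), size=60, replace=False))
    d = rng.integers(0, 3, size=(8, 60)).astype(float)
    gt = make_table(d, positions=pos)
    w = windowed_pi(gt, "L", 100_000, 30_000, chrom_lengths={"1": 400_000})

    # oracle: test every site against every window interval
    per_site = []
    for j in range(60):
        n, c = 16, d[:, j].sum()
        per_site.append(2 * c * (n - c) / (n * (n - 1)))
    starts = range(1, 400_001, 30_000)
    for k, s in enumerate(starts):
        e = min(s + 100_000 - 1, 400_000)
        members = [j for j in range(60) if s <= pos[j] <= e]
        assert w.loc[k, "start"] == s and w.loc[k, "end"] == e
        assert w.loc[k, "n_sites"] == len(members)
        assert w.loc[k, "pi"] == pytest.approx(
            sum(per_site[j] for j in members) / (e - s + 1)
        )


def test_window_grid_partitions_when_step_equals_window(rng):
    pos = np.sort(rng.choice(np.arange(1, 100_001), size=40, replace=False))
    gt = make_table(rng.integers(0, 3, size=(6, 40)).astype(float), positions=pos)
    w = windowed_pi(gt, "L", 10_000, 10_000, chrom_lengths={"1": 100_000})
    # non-overlapping windows tile the chromosome and cover every site once
    assert w["n_sites"].sum() == 40
    assert (w["start"].to_numpy()[1:] == w["end"].to_numpy()[:-1] + 1).all()


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_oracle_site(gx, gy):
    """Independent scalar transcription of the 1984 two-population components."""
    gx = [g for g in gx if not np.isnan(g)]
    gy = [g for g in gy if not np.isnan(g)]
    n1, n2 = float(len(gx)), float(len(gy))
    p1 = sum(gx) / (2 * n1)
    p2 = sum(gy) / (2 * n2)
    h1 = sum(1 for g in gx if g == 1) / n1
    h2 = sum(1 for g in gy if g == 1) / n2
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - 1 / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def test_wc_components_match_independent_transcription(rng):
    d = rng.integers(0, 3, size=(17, 40)).astype(float)
    d[rng.random(d.shape) < 0.1] = np.nan
    lines = ["X"] * 9 + ["Y"] * 8
    gt = make_table(d, lines=lines)
    a, b, c = wc_site_components(gt, "X", "Y")
    for j in range(40):
        ea, eb, ec = _wc_oracle_site(d[:9, j], d[9:, j])
        assert a[j] == pytest.approx(ea, abs=1e-12)
        assert b[j] == pytest.approx(eb, abs=1e-12)
        assert c[j] == pytest.approx(ec, abs=1e-12)


def test_wc_fixed_difference_gives_fst_one():
    d = np.array([[2.0]] * 6 + [[0.0]] * 6)
    gt = make_table(d, lines=["X"] * 6 + ["Y"] * 6)
    w = windowed_fst(gt, "X", "Y", 1000, 1000)
    assert w["fst"].dropna().iloc[0] == pytest.approx(1.0)


def test_wc_identical_populations_nonpositive(rng):
    # both lines carry identical genotype columns
    block = rng.integers(0, 3, size=(7, 20)).astype(float)
    d = np.vstack([block, block])
    gt = make_table(d, lines=["X"] * 7 + ["Y"] * 7)
    w = windowed_fst(gt, "X", "Y", 10_000, 10_000)
    assert (w["fst"].dropna() <= 1e-12).all()


def test_window_fst_single_site_equals_site_ratio(rng):
    d = rng.integers(0, 3, size=(12, 1)).astype(float)
    gt = make_table(d, lines=["X"] * 6 + ["Y"] * 6, positions=[50])
    a, b, c = wc_site_components(gt, "X", "Y")
    w = windowed_fst(gt, "X", "Y", 1000, 1000)
    if not np.isnan(a[0]) and (a + b + c)[0] != 0:
        assert w.loc[0, "fst"] == pytest.approx(a[0] / (a[0] + b[0] + c[0]))


def test_wc_missing_line_reports_missing_window():
    d = np.array([[0.0, 1.0], [1.0, 0.0], [np.nan, 0.0], [np.nan, 1.0]])
    gt = make_table(d, lines=["X", "X", "Y", "Y"], positions=[10, 2000])
    w = windowed_fst(gt, "X", "Y", 1000, 1000)
    assert np.isnan(w.loc[0, "fst"])  # Y entirely missing at the only site
    assert len(w) == 2  # window reported, not dropped


# ---------------------------------------------------------------------------
# LSBL and candidate calling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "triple,expected",
    [((0.2, 0.2, 0.2), 0.1), ((0.0, 0.0, 0.0), 0.0), ((0.3, 0.1, 0.2), 0.1)],
)
def test_lsbl_arithmetic(triple, expected):
    assert lsbl(*triple) == pytest.approx(expected)


def test_lsbl_missing_propagates():
    out = lsbl(np.array([0.2, np.nan]), np.array([0.2, 0.2]), np.array([0.2, 0.2]))
    assert out[0] == pytest.approx(0.1) and np.isnan(out[1])


def test_empirical_top_fraction_rank_rule():
    w = pd.DataFrame(
        {"chrom": "1", "start": 1, "end": 10, "n_sites": 1, "v": np.arange(1.0, 101.0)}
    )
    cs = empirical_top_fraction(w, "v", 0.05)
    assert cs.threshold == 96.0
    assert sorted(cs.windows["v"]) == [96, 97, 98, 99, 100]

    tied = w.assign(v=1.0)
    cs = empirical_top_fraction(tied, "v", 0.05)
    assert cs.n_flagged == 100  # ties at the threshold are all included


def test_empirical_top_fraction_matches_sort_oracle(rng):
    vals = rng.normal(size=1000)
    assert len(np.unique(vals)) == 1000
    w = pd.DataFrame({"chrom": "1", "start": 1, "end": 2, "n_sites": 1, "v": vals})
    cs = empirical_top_fraction(w, "v", 0.05)
    top50 = set(np.sort(vals)[-50:])
    assert cs.n_flagged == 50
    assert set(cs.windows["v"]) == top50


def test_joint_scan_definition_on_constructed_windows():
    n = 200
    key = {"chrom": "1", "n_sites": 5}
    start = np.arange(1, n * 100 + 1, 100)
    fst = np.linspace(0, 0.5, n)
    base = pd.DataFrame({**key, "start": start, "end": start + 99})
    fst_w = base.assign(fst=fst)
    # ratios spread over [-1, 1], pseudo-shuffled so they are independent of F_ST
    ratio = (np.arange(n) * 37 % n) / n * 2.0 - 1.0
    ratio[n - 1] = -6.0  # top F_ST with extreme negative ratio -> flagged, reduced in X
    ratio[n - 2] = 0.0   # top F_ST, median ratio -> not flagged
    pi_y = base.assign(pi=np.full(n, 1e-3))
    pi_x = base.assign(pi=1e-3 * 2.0**ratio)
    cs = fst_pi_joint_scan(fst_w, pi_x, pi_y, line_x="X", line_y="Y")
    flagged_starts = set(cs.windows["start"])
    assert start[n - 1] in flagged_starts
    assert start[n - 2] not in flagged_starts
    row = cs.windows[cs.windows["start"] == start[n - 1]].iloc[0]
    assert row["reduced_line"] == "X"


def test_joint_scan_requires_overlap():
    a = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [10], "n_sites": [1], "fst": [0.1]})
    b = pd.DataFrame({"chrom": ["2"], "start": [1], "end": [10], "n_sites": [1], "pi": [0.1]})
    with pytest.raises(ValueError, match="overlap"):
        fst_pi_joint_scan(a, b, b)


def test_joint_scan_recovers_spiked_region():
    """A frequency spike in line D only is flagged with the reduced-D label."""
    cfg = SimulationConfig(
        n_markers=8000,
        chromosome_lengths={"1": 20_000_000},
        line_specs=[LineSpec("C", 30, 0.05), LineSpec("D", 30, 0.05)],
        selection_spikes=[("D", "1", (5_000_001, 5_600_000), 0.97)],
        seed=21,
    )
    gt, _ = simulate_populations(cfg)
    kw = dict(window_bp=100_000, step_bp=100_000, chrom_lengths={"1": 20_000_000})
    fst_w = windowed_fst(gt, "C", "D", **kw)
    cs = fst_pi_joint_scan(
        fst_w.dropna(subset=["fst"]),
        windowed_pi(gt, "C", **kw),
        windowed_pi(gt, "D", **kw),
        line_x="C",
        line_y="D",
    )
    in_spike = (cs.windows["start"] >= 5_000_001) & (cs.windows["end"] <= 5_700_000)
    assert in_spike.any(), "spiked region not flagged"
    assert (cs.windows.loc[in_spike, "reduced_line"] == "D").all()
    # false positives among unspiked windows stay below 5%
    n_windows = len(fst_w)
    n_false = (~in_spike).sum()
    assert n_false / n_windows < 0.05


def test_lsbl_windows_increase_only_on_focal_branch():
    """Perturbing only the focal line raises its LSBL, not the references'."""
    spike = [("X", "1", (2_000_001, 2_500_000), 0.95)]
    base_specs = [LineSpec("X", 25, 0.05), LineSpec("Y", 25, 0.05), LineSpec("Z", 25, 0.05)]
    cfg = SimulationConfig(
        n_markers=6000,
        chromosome_lengths={"1": 10_000_000},
        line_specs=base_specs,
        selection_spikes=spike,
        seed=8,
    )
    gt, _ = simulate_populations(cfg)
    kw = dict(window_bp=100_000, chrom_lengths={"1": 10_000_000})
    lw_x = lsbl_windows(gt, "X", "Y", "Z", **kw)
    lw_y = lsbl_windows(gt, "Y", "X", "Z", **kw)
    region = (lw_x["start"] >= 2_000_001) & (lw_x["end"] <= 2_500_000)
    outside = ~region
    assert lw_x.loc[region, "lsbl"].mean() > lw_x.loc[outside, "lsbl"].mean() + 0.2
    # the same perturbation leaves the non-focal branch near its background level
    assert abs(
        lw_y.loc[region, "lsbl"].mean() - lw_y.loc[outside, "lsbl"].mean()
    ) < 0.05


# ---------------------------------------------------------------------------
# diversity report
# ---------------------------------------------------------------------------

def test_diversity_report_orderings(small_scenario):
    dense, chip, popmap, _ = small_scenario
    sd, _ = diversity_report(dense)
    sc, _ = diversity_report(chip)
    for s in (sd, sc):
        assert s.loc["D", "He"] > s.loc["C", "He"]
        assert s.loc["D", "pi"] > s.loc["C", "pi"]
    # ascertainment inflates chip He relative to the dense panel, per line
    assert (sc["He"] >= sd["He"]).all()


def test_diversity_report_single_line(rng):
    gt = make_table(rng.integers(0, 3, size=(5, 20)).astype(float))
    s, tables = diversity_report(gt, window_bp=1000)
    assert list(s.index) == ["L"]
    assert set(tables) == {"L"}


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as hst
from hypothesis.extra import numpy as hnp


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        np.float64,
        hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=12),
        elements=hst.sampled_from([0.0, 1.0, 2.0]),
    )
)
def test_heterozygosity_allele_label_symmetry(d):
    """Ho, He and MAF are invariant under swapping ref and alt labels."""
    base = heterozygosity_summary(make_table(d))
    swapped = heterozygosity_summary(make_table(2.0 - d))
    pd.testing.assert_frame_equal(base, swapped)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    hst.lists(
        hst.floats(-10, 10, allow_nan=False), min_size=2, max_size=200, unique=True
    ),
    hst.floats(0.01, 0.5),
)
def test_top_fraction_threshold_properties(values, fraction):
    """All flagged windows sit at/above the threshold; count covers ceil(fN)."""
    import math

    w = pd.DataFrame(
        {"chrom": "1", "start": 1, "end": 2, "n_sites": 1, "v": values}
    )
    cs = empirical_top_fraction(w, "v", fraction)
    assert (cs.windows["v"] >= cs.threshold).all()
    assert cs.n_flagged >= math.ceil(fraction * len(values))
    # unflagged windows are all strictly below the threshold
    un = w[~w["v"].isin(cs.windows["v"])]
    assert (un["v"] < cs.threshold).all()
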