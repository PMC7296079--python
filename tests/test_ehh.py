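"""Haplotype-homozygosity statistics against brute-force oracles and hand
examples."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from admixscan.ehh import (
    EHHCurve,
    _hap_het,
    _integrate_side,
    _merge_small_bins,
    ehh_curve,
    ehhs_curve,
    ihh,
    ihs_scan,
    polarize_alleles,
    rsb_scan,
    standardize_ihs,
)
from admixscan.panel import HaplotypePanel


def _panel(haps, pos=None):
    haps = np.asarray(haps, dtype=np.int8)
    n_snps, n_haps = haps.shape
    if pos is None:
        pos = np.arange(1, n_snps + 1) * 100_000
    return HaplotypePanel(
        np.ones(n_snps, dtype=int), pos, haps, [f"a{i}" for i in range(n_haps // 2)]
    )


def _brute_ehh(haps, core, allele, t):
    carriers = np.flatnonzero(haps[core] == allele)
    lo, hi = min(core, t), max(core, t)
    same = sum(
        1
        for i, j in combinations(carriers, 2)
        if np.array_equal(haps[lo : hi + 1, i], haps[lo : hi + 1, j])
    )
    return 2 * same / (len(carriers) * (len(carriers) - 1))


# ---- EHH ------------------------------------------------------------------


def test_hand_example_four_carriers():
    # carriers' extended haplotypes {ACA, ACA, ACG, ACT} -> one identical
    # pair -> EHH = 2 / (4*3) = 1/6; encode A=0, C=0|1 alike, G/T via 2 SNPs
    haps = np.array(
        [
            [1, 1, 1, 1, 0, 0],  # core: carriers are the first four
            [0, 0, 0, 0, 1, 1],
            [0, 0, 1, 1, 0, 0],  # splits {1,2} vs {3,4}
            [0, 0, 0, 1, 0, 0],  # splits hap4 off
        ],
        dtype=np.int8,
    )
    panel = _panel(haps)
    c = ehh_curve(panel, 0, 1, decay=None)
    assert c.right_ehh[-1] == pytest.approx(1 / 6)
    assert c.right_ehh[-1] == pytest.approx(_brute_ehh(haps, 0, 1, 3))


def test_identical_carriers_give_unit_ehh():
    haps = np.tile(np.array([[1], [0], [1], [1]], dtype=np.int8), (1, 6))
    c = ehh_curve(_panel(haps), 0, 1, decay=None)
    assert np.allclose(c.right_ehh, 1.0)


def test_all_distinct_carriers_give_zero():
    haps = np.array(
        [[1, 1, 1, 1], [0, 0, 1, 1], [0, 1, 0, 1]], dtype=np.int8
    )
    c = ehh_curve(_panel(haps), 0, 1, decay=None)
    assert c.right_ehh[-1] == 0.0


def test_fewer_than_two_carriers_rejected():
    haps = np.array([[1, 0, 0, 0], [0, 1, 0, 1]], dtype=np.int8)
    with pytest.raises(ValueError, match="carriers"):
        ehh_curve(_panel(haps), 0, 1)


def test_ehh_matches_brute_force_on_random_panels(rng):
    checked = 0
    for _ in range(60):
        n_snps = int(rng.integers(4, 30))
        n_animals = int(rng.integers(2, 8))
        haps = (rng.random((n_snps, 2 * n_animals)) < rng.uniform(0.2, 0.8)).astype(
            np.int8
        )
        panel = _panel(haps)
        core = int(rng.integers(n_snps))
        allele = int(rng.integers(2))
        if (haps[core] == allele).sum() < 2:
            continue
        c = ehh_curve(panel, core, allele, decay=None)
        for k, t in enumerate(range(core + 1, core + 1 + len(c.right_ehh))):
            assert c.right_ehh[k] == pytest.approx(_brute_ehh(haps, core, allele, t))
        for k, t in enumerate(range(core - 1, core - 1 - len(c.left_ehh), -1)):
            assert c.left_ehh[k] == pytest.approx(_brute_ehh(haps, core, allele, t))
        checked += 1
    assert checked >= 40


def test_ehh_monotone_non_increasing(rng):
    for _ in range(20):
        haps = (rng.random((25, 12)) < 0.5).astype(np.int8)
        panel = _panel(haps)
        if (haps[10] == 1).sum() < 2:
            continue
        c = ehh_curve(panel, 10, 1, decay=None)
        assert (np.diff(c.right_ehh) <= 1e-12).all()
        assert (np.diff(c.left_ehh) <= 1e-12).all()


# ---- iHH integration ------------------------------------------------------


def test_integral_with_interpolated_crossing():
    # one-sided: (0, 1.0) then (0.01 M, 0.04); threshold 0.05 crossed at
    # x* = 0.01 * (1 - 0.05) / (1 - 0.04); trapezoid to the crossing
    area, truncated = _integrate_side(
        np.array([1_000_000]), np.array([0.04]), 0, 0.05
    )
    x_cross = 0.01 * 0.95 / 0.96
    assert area == pytest.approx(0.5 * (1 + 0.05) * x_cross)
    assert not truncated


def test_integral_truncated_rectangle():
    # EHH stays 1 over a 0.02 M flank, then the chromosome ends
    pos = np.array([1_000_000, 2_000_000])
    area, truncated = _integrate_side(pos, np.array([1.0, 1.0]), 0, 0.05)
    assert area == pytest.approx(0.02)
    assert truncated


def test_integral_linear_in_map_distance():
    pos = np.array([500_000, 1_000_000, 2_000_000])
    vals = np.array([0.8, 0.4, 0.04])
    a1, _ = _integrate_side(pos, vals, 0, 0.05)
    a2, _ = _integrate_side(2 * pos, vals, 0, 0.05)
    assert a2 == pytest.approx(2 * a1)


def test_single_point_curve_zero_with_flag():
    curve = EHHCurve(core=0, allele=1, core_pos=100)
    total, truncated = ihh(curve, 0.05)
    assert total == 0.0
    assert truncated


# ---- polarization ---------------------------------------------------------


def test_majority_allele_ancestral():
    haps = np.array([[1, 1, 1, 0, 0], [0, 0, 1, 1, 1]], dtype=np.int8)
    anc = polarize_alleles(haps)
    assert anc.tolist() == [1, 1]


def test_tie_resolves_to_reference_with_warning():
    haps = np.array([[1, 1, 0, 0]], dtype=np.int8)
    with pytest.warns(UserWarning, match="50/50"):
        anc = polarize_alleles(haps)
    assert anc[0] == 0


def test_polarity_invariant_to_sample_order(rng):
    haps = (rng.random((50, 30)) < 0.5).astype(np.int8)
    shuffled = haps[:, rng.permutation(30)]
    assert np.array_equal(polarize_alleles(haps), polarize_alleles(shuffled))


# ---- standardization ------------------------------------------------------


def test_bin_zscores_population_sd_convention():
    import pandas as pd

    raw = pd.DataFrame(
        {
            "ihs_raw": [1.0, 2.0, 3.0],
            "dfreq": [0.30, 0.31, 0.32],
            "undefined": [False] * 3,
        }
    )
    out = standardize_ihs(raw, min_bin_size=1)
    expected = np.array([-1.224744871, 0.0, 1.224744871])
    assert np.allclose(out["ihs"], expected, atol=1e-8)


def test_gaussian_p_transform_values():
    import pandas as pd

    raw = pd.DataFrame(
        {
            "ihs_raw": [0.0, 10.0, -10.0, 5.0],
            "dfreq": [0.1, 0.1, 0.1, 0.1],
            "undefined": [False] * 4,
        }
    )
    out = standardize_ihs(raw, min_bin_size=1)
    z = out["ihs"].to_numpy()
    # the standardized value 0 maps to p-transform 0
    i0 = np.argmin(np.abs(z))
    assert out["neglog10p"][i0] == pytest.approx(
        -np.log10(2 * stats.norm.sf(abs(z[i0]))), abs=1e-9
    )
    # symmetry: equal |z| gives equal p
    assert out["neglog10p"][1] != out["neglog10p"][3]


def test_two_sided_p_reference_point():
    from admixscan.ehh import _neglog10_two_sided

    assert _neglog10_two_sided(np.array([1.959964])) == pytest.approx(
        1.301, abs=1e-3
    )
    assert _neglog10_two_sided(np.array([-1.959964])) == pytest.approx(
        1.301, abs=1e-3
    )
    assert _neglog10_two_sided(np.array([0.0])) == pytest.approx(0.0, abs=1e-12)


def test_small_bins_merged(rng):
    import pandas as pd

    dfreq = np.concatenate([np.full(30, 0.2), np.full(3, 0.9)])
    raw = pd.DataFrame(
        {
            "ihs_raw": rng.normal(size=33),
            "dfreq": dfreq,
            "undefined": [False] * 33,
        }
    )
    out = standardize_ihs(raw, min_bin_size=10)
    # merged into one bin: global mean 0 / SD 1
    z = out["ihs"].to_numpy()
    assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
    assert np.std(z) == pytest.approx(1.0, abs=1e-12)


def test_merge_small_bins_helper():
    bins = np.array([0] * 20 + [1] * 2 + [5] * 15)
    merged = _merge_small_bins(bins, 10)
    uniq, counts = np.unique(merged, return_counts=True)
    assert (counts >= 10).all()


# ---- EHHS / iES / Rsb -----------------------------------------------------


def test_ehhs_matches_brute_force(rng):
    from collections import Counter

    for _ in range(30):
        n_snps = int(rng.integers(4, 20))
        n_animals = int(rng.integers(3, 8))
        haps = (rng.random((n_snps, 2 * n_animals)) < 0.5).astype(np.int8)
        panel = _panel(haps)
        core = int(rng.integers(n_snps))
        if len(np.unique(haps[core])) < 2:
            continue
        c = ehhs_curve(panel, core, decay=None)
        n = panel.n_haps
        h_s = _hap_het(np.bincount(haps[core], minlength=2).astype(float), n)
        for k, t in enumerate(range(core + 1, core + 1 + len(c.right_ehh))):
            cnt = Counter(tuple(haps[core : t + 1, i]) for i in range(n))
            h_st = _hap_het(np.array(list(cnt.values()), float), n)
            assert c.right_ehh[k] == pytest.approx((1 - h_st) / (1 - h_s))


def test_ehhs_is_one_at_zero_extension():
    # at the core itself the partition is by core allele, so h_{s,s} = h_s
    haps = (np.random.default_rng(1).random((10, 12)) < 0.5).astype(np.int8)
    panel = _panel(haps)
    n = panel.n_haps
    h_s = _hap_het(np.bincount(haps[5], minlength=2).astype(float), n)
    assert (1 - h_s) / (1 - h_s) == 1.0


def test_monomorphic_core_rejected():
    haps = np.zeros((5, 8), dtype=np.int8)
    haps[1:] = (np.random.default_rng(2).random((4, 8)) < 0.5).astype(np.int8)
    with pytest.raises(ValueError, match="monomorphic"):
        ehhs_curve(_panel(haps), 0)


def test_identical_panels_give_zero_rsb(toy_cohort):
    panel = toy_cohort["panel"].take_animals(list(range(12)))
    df = rsb_scan(panel, panel)
    ok = df["rsb_raw"].notna()
    assert ok.any()
    assert (df.loc[ok, "rsb_raw"] == 0).all()


def test_standardized_rsb_median_zero(toy_cohort):
    panel = toy_cohort["panel"]
    a = panel.take_animals(list(range(25)))
    b = panel.take_animals(list(range(25, 50)))
    df = rsb_scan(a, b)
    ok = df["rsb"].notna()
    assert np.nanmedian(df.loc[ok, "rsb"]) == pytest.approx(0.0, abs=1e-12)


def test_ihs_scan_log_ratio_semantics(toy_cohort):
    panel = toy_cohort["panel"].take_animals(list(range(30)))
    anc = polarize_alleles(panel.haps)
    df = ihs_scan(panel, anc, maf=0.05)
    ok = ~df["undefined"]
    assert ok.any()
    sub = df.loc[ok]
    assert np.allclose(sub["ihs_raw"], np.log(sub["ihh_a"] / sub["ihh_d"]))
    # sub-MAF SNPs excluded
    freqs = panel.allele_freqs()
    low_maf = np.minimum(freqs, 1 - freqs) <= 0.05
    assert df.loc[low_maf, "undefined"].all()
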