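"""Overlap rate, ISC, voxel-wise ICC, ISR, matching, group comparisons.

Every statistic is checked against an independent brute-force computation
(double loops, explicit sums of squares, hand-applied step-up procedure).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nasdbn.metrics import (
    binarize_z,
    group_compare,
    group_zmap,
    icc_label,
    icc_voxelwise,
    isc,
    isc_table,
    isr,
    match_networks,
    overlap_rate,
)
from nasdbn.synthetic import make_session_pair, planted_isc, make_dataset


# ------------------------------------------------------------ overlap rate

def test_overlap_rate_identical_and_disjoint():
    t = np.zeros(30, bool)
    t[:10] = True
    assert overlap_rate(t, t) == 1.0
    s = np.zeros(30, bool)
    s[20:] = True
    assert overlap_rate(s, t) == 0.0


def test_overlap_rate_counts_voxels():
    """|T| = 20, |S ∩ T| = 10 -> 0.5, verified by explicit voxel loop."""
    t = np.zeros(50, bool)
    t[5:25] = True
    s = np.zeros(50, bool)
    s[15:40] = True
    n_inter = sum(1 for v in range(50) if s[v] and t[v])
    assert n_inter == 10
    assert overlap_rate(s, t) == n_inter / 20


def test_overlap_rate_empty_template_rejected():
    with pytest.raises(ValueError):
        overlap_rate(np.ones(5, bool), np.zeros(5, bool))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**20 - 1), st.integers(1, 2**20 - 1))
def test_overlap_rate_bounds_and_subset_equality(s_bits, t_bits):
    """0 <= O <= 1, with O = 1 exactly when T is a subset of S."""
    s = np.array([(s_bits >> i) & 1 for i in range(20)], bool)
    t = np.array([(t_bits >> i) & 1 for i in range(20)], bool)
    o = overlap_rate(s, t)
    assert 0.0 <= o <= 1.0
    assert (o == 1.0) == bool(np.all(s[t]))


# --------------------------------------------------------------------- ISC

def test_isc_two_identical_subjects():
    x = np.vstack([np.sin(np.linspace(0, 6, 40))] * 2)
    np.testing.assert_allclose(isc(x), [1.0, 1.0], atol=1e-12)


def test_isc_negated_subject():
    base = np.sin(np.linspace(0, 6, 30))
    x = np.vstack([-base, base, base])
    vals = isc(x)
    assert vals[0] == pytest.approx(-1.0, abs=1e-12)
    assert vals[1] == pytest.approx(0.0, abs=1e-12)  # mean of {-1, +1}


def test_isc_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((4, 25))
    vals = isc(x)
    for i in range(4):
        acc = []
        for j in range(4):
            if j == i:
                continue
            acc.append(np.corrcoef(x[i], x[j])[0, 1])
        assert abs(vals[i] - np.mean(acc)) < 1e-12


def test_isc_is_invariant_to_positive_affine_rescaling():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((3, 20))
    y = x.copy()
    y[1] = 3.5 * y[1] + 2.0
    np.testing.assert_allclose(isc(x), isc(y), atol=1e-12)


def test_isc_excludes_constant_series_with_warning():
    x = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0)[::-1]])
    with pytest.warns(UserWarning):
        vals = isc(x)
    assert np.isnan(vals[0])
    assert vals[1] == pytest.approx(-1.0)


def test_isc_table_layer_structure():
    rng = np.random.default_rng(2)
    feats = [rng.standard_normal((15, 3)) for _ in range(4)]
    df = isc_table(feats, layer=2)
    assert set(df.columns) == {"layer", "atom", "subject", "isc"}
    assert len(df) == 12
    # spot-check one atom against the direct computation
    series = np.stack([f[:, 1] for f in feats])
    direct = isc(series)
    got = df[df.atom == 1].sort_values("subject")["isc"].to_numpy()
    np.testing.assert_allclose(got, direct, atol=1e-12)


def test_generator_isc_ordering_primary_above_composite():
    """Planted time courses with lambda_primary < lambda_composite show
    higher leave-one-out ISC for primary networks."""
    prim_vals, comp_vals = [], []
    for seed in range(3):
        _, truth = make_dataset(n_subjects=6, t_per_subject=50, n_voxels=150,
                                k_primary=3, k_composite=2, seed=seed)
        vals = planted_isc(truth)
        prim_vals.append(vals[:, truth.primary_indices()].mean())
        comp_vals.append(vals[:, truth.composite_indices()].mean())
    assert np.mean(prim_vals) > np.mean(comp_vals)


# --------------------------------------------------------------------- ICC

def test_icc_identical_sessions_is_one():
    rng = np.random.default_rng(3)
    a = rng.standard_normal((6, 20))
    res = icc_voxelwise([a, a.copy()])
    np.testing.assert_allclose(res["icc"], 1.0, atol=1e-12)
    assert res["mean_icc"] == pytest.approx(1.0)
    assert res["level"] == "excellent"


def test_icc_equal_mean_squares_is_zero():
    """Constructed table with MSP == MSe gives ICC = 0 by the formula's
    algebra; a table with no between-subject variance gives ICC = -1."""
    # subject means 0 and sqrt(0.5), within-subject deviations +-0.5:
    # MSP = 2 * 2 * (sqrt(0.5)/2)^2 = 0.5 and MSe = 4 * 0.25 / 2 = 0.5
    m2 = np.sqrt(0.5)
    a = np.array([[-0.5], [m2 - 0.5]])
    b = np.array([[0.5], [m2 + 0.5]])
    res = icc_voxelwise([a, b])
    assert res["icc"][0] == pytest.approx(0.0, abs=1e-12)

    # identical subject means, pure session noise: MSP = 0 -> ICC = -1
    res0 = icc_voxelwise([np.array([[1.0], [0.0]]), np.array([[0.0], [1.0]])])
    assert res0["icc"][0] == pytest.approx(-1.0)


def test_icc_hand_table_matches_sum_of_squares_oracle():
    """6 subjects x 2 sessions: explicit ANOVA arithmetic by definition."""
    a = np.array([3.1, 2.8, 4.0, 3.5, 2.2, 3.9])[:, None]
    b = np.array([3.3, 2.6, 3.7, 3.8, 2.5, 4.1])[:, None]
    res = icc_voxelwise([a, b])

    x = np.stack([a[:, 0], b[:, 0]], axis=1)  # n x d
    n, d = x.shape
    subj_mean = x.mean(axis=1)
    grand = x.mean()
    msp = d * ((subj_mean - grand) ** 2).sum() / (n - 1)
    mse = ((x - subj_mean[:, None]) ** 2).sum() / (n * (d - 1))
    expected = (msp - mse) / (msp + (d - 1) * mse)
    assert res["icc"][0] == pytest.approx(expected, abs=1e-12)


def test_icc_reliability_levels():
    assert icc_label(0.9) == "excellent"
    assert icc_label(0.7) == "good"
    assert icc_label(0.5) == "moderate"
    assert icc_label(0.25) == "fair"
    assert icc_label(0.1) == "poor"


def test_icc_zero_variance_voxels_excluded():
    a = np.ones((4, 3))
    b = np.ones((4, 3))
    b[:, 2] += np.array([0.1, -0.2, 0.3, 0.0])
    res = icc_voxelwise([a, b])
    assert res["n_undefined_voxels"] == 2


def test_icc_independent_sessions_center_near_zero():
    """With no subject effect shared across sessions, ICC is ~0 on average
    (Monte-Carlo, 17 subjects x 200 voxels, 20 seeds)."""
    means = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((17, 200))
        b = rng.standard_normal((17, 200))
        means.append(icc_voxelwise([a, b])["mean_icc"])
    assert abs(np.mean(means)) < 0.15


def test_icc_recovers_generator_reliability():
    """Voxel-wise ICC of the planted per-subject amplitude patterns tracks
    the generator's session reliability (0.8) within +-0.15."""
    means = []
    for seed in range(20):
        _, _, truth = make_session_pair(
            reliability=0.8, seed=seed, n_subjects=17, t_per_subject=25,
            n_voxels=200, k_primary=3, k_composite=1,
        )
        # amplitude value maps: voxel v in primary network k carries the
        # subject's amplitude for k
        prim = truth.primary_indices()
        vox = truth.maps[prim].any(axis=0)
        k_of_voxel = np.argmax(truth.maps[prim][:, vox], axis=0)
        a = truth.amplitudes[:, prim][:, k_of_voxel]
        b = truth.amplitudes_b[:, prim][:, k_of_voxel]
        means.append(icc_voxelwise([a, b])["mean_icc"])
    assert abs(np.mean(means) - 0.8) < 0.15


# --------------------------------------------------------------------- ISR

def _supports(*rows):
    return np.array(rows, dtype=bool)


def test_isr_identical_sets_identity_pairing():
    s = _supports([1, 1, 0, 0, 0], [0, 0, 1, 1, 0])
    res = isr(s, s)
    assert res["aggregate"] == 1.0
    assert sorted(res["pairs"]) == [(0, 0), (1, 1)]


def test_isr_disjoint_sets_all_zero():
    low = _supports([1, 1, 0, 0], [0, 0, 1, 0])
    high = _supports([0, 0, 0, 1])
    res = isr(low, high)
    assert np.nanmax(res["pairwise"]) == 0.0


def test_isr_toy_matches_brute_force_counting():
    """3x3 toy supports: every pairwise entry equals the explicit
    intersection count divided by the higher support size, and the
    aggregate follows the matched-pair sum."""
    low = _supports([1, 1, 1, 0, 0, 0, 0, 0],
                    [0, 0, 0, 1, 1, 0, 0, 0],
                    [0, 0, 0, 0, 0, 1, 1, 1])
    high = _supports([1, 1, 0, 0, 0, 0, 0, 1],
                     [0, 0, 1, 1, 1, 0, 0, 0],
                     [0, 0, 0, 0, 0, 1, 1, 0])
    res = isr(low, high)
    for a in range(3):
        for b in range(3):
            inter = int(np.sum(low[a] & high[b]))
            assert res["pairwise"][a, b] == pytest.approx(inter / high[b].sum())
    num = sum(int(np.sum(low[a] & high[b])) for a, b in res["pairs"])
    den = sum(int(high[b].sum()) for _, b in res["pairs"])
    assert res["aggregate"] == pytest.approx(num / den)


def test_isr_aggregate_is_size_weighted_mean_of_matched_entries():
    """Algebraic identity: the aggregate equals the mean of matched
    pairwise entries weighted by the higher-layer support sizes."""
    rng = np.random.default_rng(4)
    low = rng.random((4, 60)) < 0.3
    high = rng.random((4, 60)) < 0.25
    res = isr(low, high)
    sizes = np.array([high[b].sum() for _, b in res["pairs"]], float)
    entries = np.array([res["pairwise"][a, b] for a, b in res["pairs"]])
    expected = np.sum(entries * sizes) / sizes.sum()
    assert res["aggregate"] == pytest.approx(expected, abs=1e-12)


def test_isr_empty_higher_supports_reported():
    low = _supports([1, 0, 1])
    high = _supports([0, 0, 0])
    res = isr(low, high)
    assert res["n_empty_higher"] == 1
    assert np.isnan(res["aggregate"])


def test_isr_applies_to_binarized_temporal_features():
    rng = np.random.default_rng(5)
    z = rng.standard_normal((3, 100))
    sup = binarize_z(z)
    assert sup.shape == (3, 100)
    res = isr(sup, sup)
    assert res["aggregate"] == 1.0


# ---------------------------------------------------------------- matching

def test_match_networks_recovers_permutation():
    rng = np.random.default_rng(6)
    a = rng.random((5, 80)) < 0.2
    perm = np.array([3, 0, 4, 1, 2])
    b = a[perm]
    pairs, un_a, un_b = match_networks(a, b)
    assert not un_a and not un_b
    for i, j in pairs:
        assert perm[j] == i


def test_match_networks_all_empty_reference():
    a = np.ones((3, 10), bool)
    b = np.zeros((2, 10), bool)
    pairs, un_a, un_b = match_networks(a, b)
    assert pairs == []
    assert un_a == [0, 1, 2] and un_b == [0, 1]


def test_match_networks_agrees_with_correlation_pairing(recovery_results):
    """On recovered vs planted maps at high recovery quality, overlap
    matching and max-|correlation| matching agree for >= 4/5 networks."""
    from scipy.optimize import linear_sum_assignment

    res = recovery_results[1]
    maps = res["weights"]
    from nasdbn.dbn import spatial_maps

    sm = spatial_maps(maps, res["subjects"][0], 1)
    truth = res["truth"]
    pairs, _, _ = match_networks(sm.supports, truth.maps.astype(bool))
    by_overlap = {j: i for i, j in pairs}

    corr = np.corrcoef(sm.z_maps, truth.maps.astype(float))[:sm.n_atoms, sm.n_atoms:]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    by_corr = {j: i for i, j in zip(rows, cols)}

    agree = sum(1 for j in range(truth.n_networks)
                if by_overlap.get(j) == by_corr.get(j))
    assert agree >= 4


# ------------------------------------------------------- group comparisons

def test_group_compare_identical_groups():
    rng = np.random.default_rng(7)
    a = rng.standard_normal(30)
    out = group_compare(a, a.copy(), test="two_sample_t")
    assert abs(out["statistic"].iloc[0]) < 1e-12
    assert out["p"].iloc[0] > 0.99


def test_group_compare_separated_groups_significant():
    """Delta = 5 sigma at n = 20 is detected at corrected p < 0.001."""
    rng = np.random.default_rng(8)
    a = rng.standard_normal((20, 4))
    b = rng.standard_normal((20, 4)) + 5.0
    out = group_compare(a, b, test="two_sample_t", fdr=True)
    assert (out["p_fdr"] < 0.001).all()


def test_benjamini_hochberg_step_up_by_hand():
    """p = {0.01, 0.02, 0.03, 0.04}, m = 4: hand application of the
    step-up rule (adjusted_i = min over j >= i of m * p_j / j) gives 0.04
    for every member of the family; NaN entries stay NaN."""
    from nasdbn.metrics import fdr_bh

    adj = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    with_nan = fdr_bh(np.array([0.01, np.nan, 0.04]))
    assert np.isnan(with_nan[1])
    # family size 2 now: adjusted = {min(2*.01/1, 2*.04/2), 2*.04/2}
    np.testing.assert_allclose(with_nan[[0, 2]], [0.02, 0.04], atol=1e-12)


def test_group_compare_anova_single_family():
    rng = np.random.default_rng(9)
    groups = [rng.standard_normal(15), rng.standard_normal(15) + 3,
              rng.standard_normal(15)]
    out = group_compare(groups[0], groups[1:], test="anova")
    assert out["p"].iloc[0] < 0.001


def test_group_zmap_separates_signal_from_noise():
    rng = np.random.default_rng(10)
    maps = rng.standard_normal((10, 50)) * 0.2
    maps[:, :10] += 2.0  # consistent activation in 10 voxels
    z = group_zmap(maps)
    assert z[:10].min() > 1.65
    # noise voxels behave like null t-to-z deviates, far below the signal
    assert np.abs(z[10:]).mean() < 1.3
    assert z[10:].max() < z[:10].min()
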