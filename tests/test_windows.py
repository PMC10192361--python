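"""Sliding event scores, the d statistic and chi-squared contrasts."""

import numpy as np
import pytest
from scipy import stats as sps

from promdiv.windows import (
    CoverageError,
    SeProfile,
    chi_squared_vs_control,
    control_threshold,
    d_statistic,
    group_region_stats,
    heatmap_matrix,
    promoter_window,
    sliding_event_score,
)


def _profile(se, start=-1000, gene="g", channel="all"):
    se = np.asarray(se)
    return SeProfile(gene, channel, np.arange(start, start + len(se)), se)


# ------------------------------------------------------------------ Se scores


def test_zero_channel_gives_zero_profile():
    prof = sliding_event_score(np.zeros(100))
    assert prof.se.sum() == 0


def test_single_interior_event_spreads_over_eleven_positions():
    ev = np.zeros(200)
    ev[50] = 1
    prof = sliding_event_score(ev, half_window=5)
    assert list(np.flatnonzero(prof.se)) == list(range(45, 56))
    assert set(prof.se[45:56]) == {1}


def test_edge_windows_are_truncated_not_dropped():
    ev = np.ones(20)
    prof = sliding_event_score(ev, half_window=5)
    assert prof.se[0] == 6  # positions 0..5
    assert prof.se[10] == 11


def test_window_sum_matches_direct_convolution_oracle(rng):
    ev = rng.integers(0, 2, size=500)
    prof = sliding_event_score(ev, half_window=5)
    oracle = [
        ev[max(0, i - 5) : min(len(ev), i + 6)].sum() for i in range(len(ev))
    ]
    assert np.array_equal(prof.se, oracle)
    assert np.all(prof.se <= 11)


def test_empty_channel_rejected():
    with pytest.raises(ValueError):
        sliding_event_score(np.array([]))


# ------------------------------------------------------------ promoter window


def test_promoter_window_returns_exactly_350_values():
    prof = _profile(np.zeros(2000))
    assert len(promoter_window(prof)) == 350


def test_uncovered_window_raises():
    prof = _profile(np.zeros(201), start=-200)
    with pytest.raises(CoverageError):
        promoter_window(prof)


def test_window_values_equal_index_slice(rng):
    se = rng.integers(0, 12, size=2000)
    prof = _profile(se)
    vals = promoter_window(prof, (-380, -30))
    assert np.array_equal(vals, se[620:970])  # offsets -1000..; -380 -> index 620


# ------------------------------------------------------------------ threshold


def test_control_threshold_is_flat_mean():
    zero = _profile(np.zeros(2000))
    assert control_threshold([zero]) == 0.0
    a = _profile(np.full(2000, 1.0))
    b = _profile(np.full(2000, 3.0))
    assert control_threshold([a, b]) == 2.0
    with pytest.raises(ValueError):
        control_threshold([])


def test_control_threshold_matches_concatenated_mean(rng):
    profs = [_profile(rng.integers(0, 12, 2000)) for _ in range(5)]
    expected = np.mean(np.concatenate([promoter_window(p) for p in profs]))
    assert np.isclose(control_threshold(profs), expected)


# ---------------------------------------------------------------- d statistic


def test_d_statistic_frozen_example():
    d, n_above, N = d_statistic([0, 0, 1, 2, 3, 0, 0, 0, 6, 7], sec=2)
    assert (d, n_above, N) == (30.0, 3, 10)


def test_d_statistic_extremes():
    assert d_statistic([0, 1, 2], sec=2)[0] == 0.0  # ties count as not-above
    assert d_statistic([3, 4, 5], sec=2)[0] == 100.0
    with pytest.raises(ValueError):
        d_statistic([], sec=1)


def test_d_depends_only_on_value_multiset(rng):
    vals = rng.integers(0, 12, 350)
    d1, *_ = d_statistic(vals, 3.5)
    d2, *_ = d_statistic(rng.permutation(vals), 3.5)
    assert d1 == d2


def test_increasing_one_value_cannot_decrease_d(rng):
    vals = rng.integers(0, 12, 350).astype(float)
    d0, *_ = d_statistic(vals, 5.0)
    i = int(rng.integers(0, 350))
    vals[i] += 3
    d1, *_ = d_statistic(vals, 5.0)
    assert d1 >= d0


def test_d_oracle_on_random_instances(rng):
    for _ in range(200):
        vals = rng.integers(0, 12, size=int(rng.integers(1, 400)))
        sec = float(rng.uniform(0, 11))
        d, n_above, N = d_statistic(vals, sec)
        brute = sum(1 for v in vals if v > sec)
        assert (n_above, N) == (brute, len(vals))
        assert np.isclose(d, 100 * brute / len(vals))


# --------------------------------------------------------------- chi-squared


def test_chi_squared_zero_when_matching_control():
    rs = chi_squared_vs_control(n_above=40, N=100, control_d=40.0)
    assert rs.chi2 == 0.0 and rs.p == 1.0


def test_chi_squared_frozen_two_cell_example():
    rs = chi_squared_vs_control(n_above=60, N=100, control_d=40.0)
    assert np.isclose(rs.chi2, (60 - 40) ** 2 / 40 + (40 - 60) ** 2 / 60)
    assert np.isclose(rs.chi2, 16.6667, atol=1e-3)
    assert np.isclose(rs.p, sps.chi2.sf(rs.chi2, 1))
    assert np.isclose(rs.p, 4.4538e-5, rtol=1e-3)


def test_bonferroni_arithmetic_and_cap():
    rs = chi_squared_vs_control(55, 100, 40.0, m_comparisons=4)
    assert np.isclose(rs.p_adj, min(1.0, rs.p * 4))
    rs2 = chi_squared_vs_control(41, 100, 40.0, m_comparisons=1000)
    assert rs2.p_adj == 1.0


def test_pearson_matches_textbook_formula_on_integer_grid():
    for n_above in range(0, 101, 7):
        for control_d in (10.0, 33.0, 50.0, 90.0):
            rs = chi_squared_vs_control(n_above, 100, control_d)
            e1 = 100 * control_d / 100
            e2 = 100 - e1
            assert np.isclose(
                rs.chi2, (n_above - e1) ** 2 / e1 + (100 - n_above - e2) ** 2 / e2
            )


def test_degenerate_control_rejected():
    for bad in (0.0, 100.0):
        with pytest.raises(ValueError):
            chi_squared_vs_control(10, 100, bad)


# -------------------------------------------------------------------- heatmap


def test_heatmap_single_gene_rows_equal_profile(rng):
    se = rng.integers(0, 12, 2000)
    hm = heatmap_matrix({"g1": [_profile(se)]}, window=(-1000, 1000))
    assert np.array_equal(hm.loc["g1"].to_numpy(), se)


def test_heatmap_mean_of_constant_profiles():
    hm = heatmap_matrix(
        {"g": [_profile(np.zeros(2000)), _profile(np.full(2000, 2.0))]},
        window=(-1000, 1000),
    )
    assert np.allclose(hm.loc["g"], 1.0)


def test_heatmap_matches_columnwise_mean(rng):
    groups = {
        "a": [_profile(rng.integers(0, 12, 2000)) for _ in range(3)],
        "b": [_profile(rng.integers(0, 12, 2000)) for _ in range(4)],
    }
    hm = heatmap_matrix(groups, window=(-1000, 1000))
    for g, profs in groups.items():
        assert np.allclose(hm.loc[g], np.vstack([p.se for p in profs]).mean(axis=0))
    with pytest.raises(ValueError):
        heatmap_matrix({"empty": []})


# ---------------------------------------------------------------- group stats


def test_group_region_stats_control_first_and_m_default(rng):
    groups = {
        "control": [_profile(rng.integers(0, 4, 2000)) for _ in range(4)],
        "ir": [_profile(rng.integers(0, 8, 2000)) for _ in range(4)],
        "nb": [_profile(rng.integers(0, 4, 2000)) for _ in range(4)],
    }
    sec, stats_ = group_region_stats(groups, control_group="control")
    assert stats_[0].group == "control" and stats_[0].chi2 == 0.0
    others = {s.group: s for s in stats_[1:]}
    assert set(others) == {"ir", "nb"}
    for s in others.values():
        assert np.isclose(s.p_adj, min(1.0, s.p * 2))
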