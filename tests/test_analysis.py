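"""Statistical routines on synthetic batches with known answers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fissim.analysis import (
    band_summary,
    mean_days_by_transfer,
    poisson_covariate_model,
    ratio_band,
    ratio_groups,
    summarize,
    survival_curve,
    transfer_linearity,
)
from fissim.engine import BATCH_COLUMNS, BatchResult
from fissim.errors import InsufficientDataError


def make_batch(rows):
    """rows: (n, transfer, ratio, replicate, days, censored)."""
    table = pd.DataFrame(rows, columns=["n", "transfer", "ratio", "replicate",
                                        "days", "censored"])
    table["C"] = 0.005
    table["lambda1"] = table["lambda2"] = 0.25
    table["seed"] = np.arange(len(table))
    return BatchResult(table[list(BATCH_COLUMNS)])


# ---------------------------------------------------------------------------
# summaries


def test_uniform_event_batch():
    b = make_batch([(10, 50, 1.0, r, 5, False) for r in range(4)])
    s = summarize(b)
    assert (s.mean_days == 5).all() and (s.min_days == 5).all()
    assert (s.fission_fraction == 1.0).all()


def test_all_censored_batch_flagged_not_raised():
    b = make_batch([(10, 50, 1.0, r, 900, True) for r in range(4)])
    s_ex = summarize(b, censor_policy="exclude")
    assert s_ex.all_censored.all() and np.isnan(s_ex.mean_days).all()
    s_cap = summarize(b, censor_policy="cap_at_max")
    assert (s_cap.mean_days == 900).all()
    assert (s_cap.fission_fraction == 0.0).all()


def test_mixed_batch_exclude_policy():
    b = make_batch([
        (10, 50, 1.0, 0, 3, False),
        (10, 50, 1.0, 1, 7, False),
        (10, 50, 1.0, 2, 900, True),
    ])
    s = summarize(b, censor_policy="exclude").iloc[0]
    assert s.mean_days == 5 and s.min_days == 3 and s.max_days == 7
    assert s.fission_fraction == pytest.approx(2 / 3)


def test_summary_invariant_to_order_and_concatenation():
    rows = [(10, t, 1.0, r, d, False)
            for t, d0 in [(50, 100), (100, 10)]
            for r, d in enumerate([d0, d0 + 5, d0 + 9])]
    b = make_batch(rows)
    shuffled = BatchResult(b.table.sample(frac=1, random_state=0))
    pd.testing.assert_frame_equal(summarize(b), summarize(shuffled))
    merged = BatchResult.concat([
        BatchResult(b.table.iloc[:3].copy()), BatchResult(b.table.iloc[3:].copy())
    ])
    pd.testing.assert_frame_equal(summarize(b), summarize(merged))


# ---------------------------------------------------------------------------
# transfer linearity


def test_perfectly_linear_decline():
    means = {T: 1000 - 10 * T for T in range(10, 101, 10)}
    fit = transfer_linearity(means)
    assert fit.slope == pytest.approx(-10.0)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.f_statistic == np.inf


def test_constant_means_give_zero_fit():
    fit = transfer_linearity({10: 900.0, 50: 900.0, 100: 900.0})
    assert fit.r_squared == pytest.approx(0.0)
    assert fit.f_statistic == pytest.approx(0.0)
    assert fit.p_value == 1.0


def test_sign_equivariance():
    ys = {10: 900, 20: 760, 40: 600, 70: 300, 100: 40}
    down = transfer_linearity(ys)
    up = transfer_linearity({t: 900 - y for t, y in ys.items()})
    assert down.slope == pytest.approx(-up.slope)
    assert down.r_squared == pytest.approx(up.r_squared)


def test_too_few_levels_rejected():
    with pytest.raises(InsufficientDataError):
        transfer_linearity({10: 900.0, 100: 100.0})


# ---------------------------------------------------------------------------
# ratio groups (Kruskal-Wallis + Dunn)


def test_identical_distributions_form_one_group(rng):
    rows = []
    for ratio in (0.5, 1.0, 2.0):
        for r in range(40):
            rows.append((10, 50, ratio, r, int(rng.integers(100, 200)), False))
    res = ratio_groups(make_batch(rows), 10, exclude_transfers=())
    assert res.kruskal_pvalue > 0.001
    assert len(res.groups) == 1


def test_location_shifted_distributions_recover_three_groups(rng):
    rows = []
    for ratio, centre in [(0.5, 50), (1.0, 400), (2.0, 800)]:
        for r in range(40):
            rows.append((10, 50, ratio, r,
                         int(centre + rng.integers(-20, 21)), False))
    res = ratio_groups(make_batch(rows), 10, exclude_transfers=())
    assert res.kruskal_pvalue < 1e-10
    assert res.groups == ((0.5,), (1.0,), (2.0,))


def test_dunn_z_matches_hand_computation():
    """Three groups of three with no ties: pooled ranks 1..9, mean ranks
    2, 5, 8, variance factor N(N+1)/12 = 7.5, so |z| between adjacent
    groups is 3 / sqrt(7.5 * 2/3) = 1.3416."""
    rows = []
    for ratio, days in [(0.5, [1, 2, 3]), (1.0, [4, 5, 6]), (2.0, [7, 8, 9])]:
        for r, d in enumerate(days):
            rows.append((10, 50, ratio, r, d, False))
    res = ratio_groups(make_batch(rows), 10, exclude_transfers=())
    z = res.dunn_z
    assert z.loc[0.5, 1.0] == pytest.approx(-3 / np.sqrt(7.5 * 2 / 3))
    assert z.loc[0.5, 2.0] == pytest.approx(-6 / np.sqrt(7.5 * 2 / 3))
    assert z.loc[1.0, 0.5] == pytest.approx(+3 / np.sqrt(7.5 * 2 / 3))


def test_label_permutation_loses_significance(rng):
    """Permuting days across ratio levels should reject at roughly the
    nominal rate, not systematically."""
    rows = []
    days = rng.integers(50, 900, size=120)
    for idx, d in enumerate(days):
        rows.append((10, 50, [0.5, 1.0, 2.0][idx % 3], idx // 3, int(d), False))
    rejections = 0
    trials = 40
    for t in range(trials):
        perm = rng.permutation(days)
        permuted = [(n, tr, ratio, rep, int(d), c) for (n, tr, ratio, rep, _, c), d
                    in zip(rows, perm)]
        res = ratio_groups(make_batch(permuted), 10, exclude_transfers=())
        rejections += res.kruskal_pvalue < 0.05
    assert rejections / trials <= 0.2


def test_transfer_exclusion_default_drops_ten_percent():
    rows = [(10, 10, 1.0, r, 900, True) for r in range(5)]
    rows += [(10, 50, 1.0, r, 100, False) for r in range(5)]
    rows += [(10, 50, 2.0, r, 500, False) for r in range(5)]
    res = ratio_groups(make_batch(rows), 10)
    # only the transfer-50 rows enter: 1.0 vs 2.0 clearly separated
    assert res.kruskal_pvalue < 0.01


# ---------------------------------------------------------------------------
# bands


def test_band_boundaries_depend_on_group_size():
    assert ratio_band(0.25, 10) == "low"
    assert ratio_band(0.25, 20) == "mid"
    assert ratio_band(1.0, 10) == "mid"
    assert ratio_band(2.33, 10) == "mid"
    assert ratio_band(4.0, 10) == "high"


def test_band_summary_counts():
    rows = [(10, 50, 0.11, r, 900, True) for r in range(3)]
    rows += [(10, 50, 1.0, r, 100 + r, False) for r in range(3)]
    rows += [(10, 50, 9.0, r, 500 + r, False) for r in range(3)]
    bs = band_summary(make_batch(rows), 10, exclude_transfers=())
    assert bs.loc["low", "fission_fraction"] == 0.0
    assert bs.loc["mid", "mean_days"] == pytest.approx(101.0)
    assert bs.loc["high", "mean_days"] == pytest.approx(501.0)


# ---------------------------------------------------------------------------
# Poisson model


def test_poisson_recovers_transfer_coefficient(rng):
    rows = []
    for T in range(10, 101, 10):
        for ratio in (0.5, 1.0, 2.0):
            for r in range(5):
                days = int(round(np.exp(5 - 0.02 * T)))
                rows.append((10, T, ratio, r, days, False))
    table = poisson_covariate_model(make_batch(rows))
    assert table.loc["transfer", "coef"] == pytest.approx(-0.02, abs=2e-3)
    assert abs(table.loc["ratio", "coef"]) < 1e-6


def test_poisson_constant_days_all_flat():
    rows = [(n, T, ratio, 0, 50, False)
            for n in (10, 20) for T in (20, 80) for ratio in (0.5, 2.0)]
    table = poisson_covariate_model(make_batch(rows))
    for term in ("n", "transfer", "ratio"):
        assert table.loc[term, "coef"] == pytest.approx(0.0, abs=1e-8)


def test_poisson_drops_constant_covariate(rng):
    rows = [(10, T, 1.0, r, int(rng.integers(50, 500)), False)
            for T in (20, 80) for r in range(10)]
    with pytest.warns(UserWarning):
        table = poisson_covariate_model(make_batch(rows))
    assert "n" not in table.index and "ratio" not in table.index


# ---------------------------------------------------------------------------
# survival curves


def test_survival_single_step():
    b = make_batch([(10, 50, 1.0, r, 5, False) for r in range(4)])
    curve = survival_curve(b, n=10)
    lookup = dict(zip(curve.day, curve.survival))
    assert lookup[0.0] == 1.0 and lookup[5.0] == 0.0


def test_survival_all_censored_flat():
    b = make_batch([(10, 50, 1.0, r, 900, True) for r in range(4)])
    curve = survival_curve(b, n=10)
    assert (curve.survival == 1.0).all()
    assert curve.day.max() == 900.0


def test_survival_mixed_with_late_censoring():
    b = make_batch([
        (10, 50, 1.0, 0, 3, False),
        (10, 50, 1.0, 1, 7, False),
        (10, 50, 1.0, 2, 900, True),
    ])
    curve = survival_curve(b, n=10)
    lookup = dict(zip(curve.day, curve.survival))
    assert lookup[3.0] == pytest.approx(2 / 3)
    assert lookup[7.0] == pytest.approx(1 / 3)
    assert lookup[900.0] == pytest.approx(1 / 3)
    assert (np.diff(curve.survival) <= 1e-12).all()


def test_mean_days_by_transfer_caps_censored():
    b = make_batch([
        (10, 50, 1.0, 0, 100, False),
        (10, 50, 1.0, 1, 900, True),
        (10, 100, 1.0, 0, 10, False),
        (10, 100, 1.0, 1, 20, False),
    ])
    m = mean_days_by_transfer(b, 10)
    assert m[50.0] == pytest.approx(500.0)
    assert m[100.0] == pytest.approx(15.0)
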