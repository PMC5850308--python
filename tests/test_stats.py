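import numpy as np
import pytest
from scipy import integrate, stats as sps

from paleosrna.classify import ExpressionProfile
from paleosrna.stats import (
    adjust_ancient,
    compare_counts,
    estimate_r,
    likelihood_kernel,
    normalize_controls,
    profile_regression,
)


def _profile(sid, raw, total_reads):
    return ExpressionProfile(sid, raw=dict(raw), total_reads=total_reads)


def test_normalization_identity_when_ratios_equal():
    profs = [
        _profile("a", {"f1": 30, "f2": 10}, 10000),
        _profile("b", {"f1": 15, "f2": 25}, 10000),
    ]
    normalize_controls(profs)
    for p in profs:
        for fam, v in p.normalized.items():
            assert v == pytest.approx(p.raw[fam])


def test_normalization_hand_computed_oracle():
    # ratios 0.001 and 0.003, family count 30 in each -> 60 and 20
    profs = [
        _profile("a", {"f": 30}, 30000),  # ratio 0.001
        _profile("b", {"f": 30}, 10000),  # ratio 0.003
    ]
    _, constants = normalize_controls(profs)
    assert constants.mean_ratio == pytest.approx(0.002)
    assert profs[0].normalized["f"] == pytest.approx(60.0)
    assert profs[1].normalized["f"] == pytest.approx(20.0)


def test_normalization_conserves_mean_total_at_equal_depth():
    """Multiplexed controls at one depth: the cross-sample mean miRNA
    total is conserved exactly by normalization."""
    rng = np.random.default_rng(2)
    profs = [
        _profile(
            f"s{i}",
            {f"f{j}": int(rng.integers(1, 400)) for j in range(12)},
            200_000,
        )
        for i in range(19)
    ]
    raw_mean = np.mean([p.total_mirna for p in profs])
    _, constants = normalize_controls(profs)
    norm_mean = np.mean([sum(p.normalized.values()) for p in profs])
    assert norm_mean == pytest.approx(raw_mean)
    assert constants.mean_adjusted_control_total == pytest.approx(raw_mean)


def test_normalized_mean_total_equals_reported_constant():
    # at unequal depths the mean normalized total still equals the
    # mean-adjusted-control-total constant, by construction
    rng = np.random.default_rng(4)
    profs = [
        _profile(
            f"s{i}",
            {f"f{j}": int(rng.integers(1, 400)) for j in range(6)},
            int(rng.integers(50_000, 500_000)),
        )
        for i in range(7)
    ]
    _, constants = normalize_controls(profs)
    norm_mean = np.mean([sum(p.normalized.values()) for p in profs])
    assert norm_mean == pytest.approx(constants.mean_adjusted_control_total)


def test_normalization_rejects_zero_total_reads():
    profs = [_profile("ok", {"f": 1}, 100), _profile("broken", {"f": 1}, 0)]
    with pytest.raises(ValueError, match="broken"):
        normalize_controls(profs)


def test_adjustment_ratio_printed_constants():
    """Mean adjusted control total 1145.5 over ancient total 1938 -> 0.59."""
    from paleosrna.stats import NormalizationConstants

    constants = NormalizationConstants(
        per_sample_ratio={}, mean_ratio=0.00165,
        mean_adjusted_control_total=1145.5,
    )
    ancient = _profile("anc", {"f": 1938}, 59_702_667)
    adjust_ancient(ancient, constants)
    assert round(constants.adjustment_ratio, 2) == 0.59
    # adjusted counts sum back to the mean adjusted control total
    assert sum(ancient.normalized.values()) == pytest.approx(1145.5)


def test_adjustment_ratio_one_is_identity():
    from paleosrna.stats import NormalizationConstants

    ancient = _profile("anc", {"f1": 10, "f2": 5}, 1000)
    constants = NormalizationConstants(
        per_sample_ratio={}, mean_ratio=0.1, mean_adjusted_control_total=15.0
    )
    adjust_ancient(ancient, constants)
    assert ancient.normalized == pytest.approx(ancient.raw)


def test_regression_perfect_line():
    x = np.arange(1.0, 11.0)
    fit = profile_regression(x, 2 * x)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.slope == pytest.approx(2.0)


def test_regression_null_distribution():
    """Independent vectors: small R², roughly uniform p over replicates."""
    rng = np.random.default_rng(8)
    pvals = []
    for _ in range(200):
        fit = profile_regression(rng.normal(size=30), rng.normal(size=30))
        pvals.append(fit.p_value)
    pvals = np.array(pvals)
    # uniformity: KS against U(0,1) should not reject wildly
    d, p = sps.kstest(pvals, "uniform")
    assert p > 1e-3
    assert np.median(pvals) == pytest.approx(0.5, abs=0.15)


def test_regression_zero_variance_flagged():
    fit = profile_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert fit.degenerate and fit.r_squared is None


def test_estimate_r_poisson_counts_near_one():
    rng = np.random.default_rng(5)
    counts = {f"f{j}": rng.poisson(50, size=19) for j in range(30)}
    r = estimate_r(counts)
    assert r == pytest.approx(1.0, abs=0.25)


def test_estimate_r_negative_binomial_variance_three_mean():
    rng = np.random.default_rng(6)
    estimates = []
    for _ in range(50):
        counts = {}
        for j in range(30):
            mu = 60.0
            n = mu / (3.0 - 1.0)
            counts[f"f{j}"] = rng.negative_binomial(n, 1.0 / 3.0, size=19)
        estimates.append(estimate_r(counts))
    assert np.mean(estimates) == pytest.approx(3.0, abs=0.3)


def test_estimate_r_hand_arithmetic():
    # family {2, 4}: mean 3, sample variance 2 -> ratio 2/3
    assert estimate_r({"f": [2.0, 4.0]}) == pytest.approx(2.0 / 3.0)


def test_estimate_r_all_zero_rejected():
    with pytest.raises(ValueError):
        estimate_r({"f": [0.0, 0.0]})


def test_poisson_kernel_at_zero_monotone_decreasing():
    curve = likelihood_kernel(0.0, 1.0)
    assert curve.kind == "poisson"
    assert np.all(np.diff(curve.values) < 0)
    assert curve.mode() == curve.grid[0]
    # shape is exp(-λ) up to normalization
    ratio = curve.values / np.exp(-curve.grid)
    assert np.allclose(ratio, ratio[0], rtol=1e-9)


def test_extended_kernel_tracks_exact_poisson_intervals():
    """x=100, r=1: interval endpoints and mode within 2% of the exact
    Poisson-likelihood oracle over the same grid."""
    curve = likelihood_kernel(100.0, 1.0)
    exact = sps.poisson.pmf(100, curve.grid)
    exact = exact / np.trapezoid(exact, curve.grid)
    cdf = integrate.cumulative_trapezoid(exact, curve.grid, initial=0.0)
    cdf /= cdf[-1]
    exact_interval = (
        np.interp(0.025, cdf, curve.grid),
        np.interp(0.975, cdf, curve.grid),
    )
    got = curve.interval()
    for g, e in zip(got, exact_interval):
        assert abs(g - e) / e < 0.02
    exact_mode = curve.grid[np.argmax(exact)]
    assert abs(curve.mode() - exact_mode) / exact_mode < 0.02
    # pointwise agreement at peak scale stays within the documented 3% guard
    assert np.max(np.abs(curve.values - exact)) / exact.max() < 0.03


def test_extended_kernel_mode_near_observed_count():
    curve = likelihood_kernel(200.0, 2.0)
    assert curve.kind == "extended"
    assert abs(curve.mode() - 200.0) / 200.0 < 0.02


def test_kernel_normalizes_to_unit_area():
    for x, r in [(3.0, 1.0), (49.0, 2.0), (51.0, 2.0), (400.0, 3.0)]:
        curve = likelihood_kernel(x, r)
        assert np.trapezoid(curve.values, curve.grid) == pytest.approx(
            1.0, abs=1e-6
        )


def test_kernel_rejects_bad_inputs():
    with pytest.raises(ValueError):
        likelihood_kernel(-1.0, 1.0)
    with pytest.raises(ValueError):
        likelihood_kernel(10.0, 0.0)
    with pytest.raises(ValueError):
        likelihood_kernel(10.0, 1.0, grid=np.array([-1.0, 1.0, 2.0]))


def test_kernel_continuity_across_regime_switch():
    """Interval endpoints from x=49 (Poisson) and x=51 (extended) differ
    by less than 10% at r=1, where both branches model the same variance.
    For r>1 the switch widens intervals by ~sqrt(r) by design (the Poisson
    branch deliberately ignores overdispersion at low counts)."""
    lo49, hi49 = likelihood_kernel(49.0, 1.0).interval()
    lo51, hi51 = likelihood_kernel(51.0, 1.0).interval()
    assert abs(lo51 - lo49) / lo49 < 0.10
    assert abs(hi51 - hi49) / hi49 < 0.10


def test_compare_identical_counts_indistinguishable():
    call = compare_counts(30.0, [30.0, 30.0, 30.0], r=2.0)
    assert call.call == "indistinguishable"


def test_compare_large_shift_called_up():
    call = compare_counts(400.0, [50.0] * 5, r=2.0)
    assert call.call == "up"
    assert call.ancient_interval[0] > call.control_interval[1]


def test_compare_large_drop_called_down():
    call = compare_counts(5.0, [100.0] * 5, r=2.0)
    assert call.call == "down"
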