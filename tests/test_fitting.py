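"""Fit engine: nonlinear/linearized least squares, SSE bookkeeping, and
parameter recovery."""

import numpy as np
import pytest

from conftest import make_profile
from sonokinetics import (
    ReleaseProfile,
    evaluate_cfr,
    fit_all,
    fit_model,
    fit_polynomial,
    get_model,
    sse,
    transform_response,
)
from sonokinetics.exceptions import DataSizeError, DegenerateDesignError


def test_sse_arithmetic():
    assert sse([0.1, 0.2], [0.15, 0.15]) == pytest.approx(0.005, rel=1e-12)


def test_sse_invariant_to_sample_ordering():
    rng = np.random.default_rng(3)
    y, yhat = rng.normal(size=50), rng.normal(size=50)
    perm = rng.permutation(50)
    assert sse(y, yhat) == pytest.approx(sse(y[perm], yhat[perm]), rel=1e-14)


def test_constant_zero_profile_zero_order():
    profile = ReleaseProfile(t_us=np.arange(20.0), cfr=np.zeros(20))
    res = fit_model(profile, get_model("zero_order"))
    assert res.converged
    assert res["k0f"] == pytest.approx(0.0, abs=1e-6)
    assert res.sse_cfr_space == pytest.approx(0.0, abs=1e-9)


def test_noiseless_kp_recovery(kp_albumin_profile):
    res = fit_model(kp_albumin_profile, get_model("korsmeyer_peppas"))
    assert res.converged
    assert res["kkp"] == pytest.approx(3.50e-3, rel=1e-4)
    assert res["n"] == pytest.approx(0.73, rel=1e-4)
    assert res.sse_cfr_space <= 1e-10
    assert res.sse_fit_space == res.sse_cfr_space  # direct fit: one space


def test_linearized_fit_reports_both_sse_spaces():
    khc = 6e-4
    t = np.arange(1.0, 601.0)
    profile = make_profile("hixson_crowell", (khc,), t, noise_sd=0.01)
    res = fit_model(profile, get_model("hixson_crowell"))
    assert res.converged
    assert res["khc"] == pytest.approx(khc, rel=0.02)
    assert res.sse_fit_space > 0 and res.sse_cfr_space > 0
    assert res.sse_fit_space != res.sse_cfr_space
    # fit-space SSE is what the transformed regression minimized
    y_fit = transform_response(get_model("hixson_crowell"), profile.cfr)
    assert res.sse_fit_space == pytest.approx(
        sse(y_fit, 1.0 - res["khc"] * t), rel=1e-9
    )


def test_clamp_counting_on_noisy_saturation():
    t = np.arange(1.0, 101.0)
    cfr = np.minimum(0.02 * t, 1.002)  # several samples sit above 1
    profile = ReleaseProfile(t_us=t, cfr=cfr)
    res = fit_model(profile, get_model("hixson_crowell"))
    assert res.clamp_count == int(np.sum(cfr >= 1.0))
    assert np.isfinite(res.sse_fit_space)


def test_hixson_crowell_matches_grid_search_oracle():
    """Linearized slope equals brute-force SSE minimization over a khc grid."""
    khc = 7.1e-4
    t = np.arange(1.0, 601.0)
    profile = make_profile("hixson_crowell", (khc,), t)
    res = fit_model(profile, get_model("hixson_crowell"))
    y = transform_response(get_model("hixson_crowell"), profile.cfr)
    grid = np.linspace(0.0, 2e-3, 10_001)
    # SSE(a) = sum((y - 1 + a t)^2) expanded as a quadratic in a
    r = y - 1.0
    sse_grid = np.sum(r**2) + 2.0 * grid * np.sum(r * t) + grid**2 * np.sum(t**2)
    a_grid = grid[np.argmin(sse_grid)]
    assert abs(res["khc"] - a_grid) <= 2e-7  # grid spacing
    assert res["khc"] == pytest.approx(khc, rel=1e-8)


class TestPolynomial:
    def test_exact_cubic_recovery(self):
        p_true = (2e-9, -1.5e-6, 1.2e-3, 0.01)
        t = np.linspace(0.0, 600.0, 80)
        profile = make_profile("cubic", p_true, t)
        res = fit_polynomial(profile)
        assert res.params == pytest.approx(p_true, rel=1e-10, abs=1e-16)
        assert res.sse_cfr_space <= 1e-20

    def test_four_distinct_points_interpolate_exactly(self):
        t = np.array([1.0, 2.0, 5.0, 9.0])
        y = np.array([0.1, 0.15, 0.4, 0.8])
        res = fit_polynomial(ReleaseProfile(t_us=t, cfr=y))
        assert res.sse_cfr_space == pytest.approx(0.0, abs=1e-20)
        pred = evaluate_cfr(get_model("cubic"), res.params, t)
        assert np.allclose(pred, y, atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(DataSizeError):
            fit_polynomial(ReleaseProfile(t_us=np.arange(3.0), cfr=np.zeros(3)))

    def test_rank_deficient_design_rejected(self):
        profile = ReleaseProfile(t_us=np.arange(5.0) + 1, cfr=np.zeros(5))
        profile.t_us = np.ones(5)  # bypass monotonicity to force degeneracy
        with pytest.raises(DegenerateDesignError):
            fit_polynomial(profile)

    def test_cubic_beats_zero_order_on_higuchi_data(self):
        t = np.arange(1.0, 301.0)
        profile = make_profile("higuchi", (0.03,), t)
        cubic = fit_polynomial(profile)
        zero = fit_model(profile, get_model("zero_order"))
        assert cubic.sse_cfr_space < zero.sse_cfr_space


class TestFitAll:
    def test_full_catalog_yields_eleven_ordered_results(self, kp_albumin_profile, catalog):
        results = fit_all(kp_albumin_profile)
        assert [r.model_name for r in results] == [m.name for m in catalog]

    def test_single_model_catalog_equals_fit_model(self, kp_albumin_profile):
        model = get_model("weibull")
        (only,) = fit_all(kp_albumin_profile, [model])
        direct = fit_model(kp_albumin_profile, model)
        assert only.params == pytest.approx(direct.params, rel=1e-12)
        assert only.sse_cfr_space == pytest.approx(direct.sse_cfr_space, abs=1e-18)

    def test_self_fit_dominance_for_weibull_truth(self):
        t = np.arange(1.0, 601.0)
        profile = make_profile("weibull", (2.5e-3, 1.1), t)
        results = {r.model_name: r for r in fit_all(profile)}
        weibull_sse = results["weibull"].sse_cfr_space
        assert weibull_sse < 1e-12
        for name, res in results.items():
            if name not in ("weibull", "cubic"):
                assert weibull_sse <= res.sse_cfr_space, name

    def test_failures_are_flagged_not_raised(self):
        tiny = ReleaseProfile(t_us=np.arange(5.0), cfr=np.zeros(5))
        results = fit_all(tiny)  # too small for the multi-parameter models
        assert len(results) == 11
        failed = [r for r in results if not r.converged]
        assert failed and all(np.isinf(r.sse_cfr_space) for r in failed)


def test_insufficient_points_raises():
    profile = ReleaseProfile(t_us=np.arange(4.0), cfr=np.zeros(4))
    with pytest.raises(DataSizeError):
        fit_model(profile, get_model("gompertz"))


def test_non_convergence_is_flagged():
    profile = make_profile("weibull", (2.5e-3, 1.1), np.arange(1.0, 201.0))
    res = fit_model(profile, get_model("weibull"), max_nfev=1)
    assert not res.converged
    assert np.isfinite(res.sse_fit_space)


def test_truncate_release_restricts_to_leading_curve(kp_albumin_profile):
    res = fit_model(
        kp_albumin_profile, get_model("korsmeyer_peppas"), truncate_release=0.25
    )
    assert res.n_points < kp_albumin_profile.n_points
    assert res["n"] == pytest.approx(0.73, rel=1e-4)


def test_multi_start_never_worse_than_single_start():
    profile = make_profile("gompertz", (0.85, 4.0, -0.75), np.arange(1.0, 401.0))
    single = fit_model(profile, get_model("gompertz"))
    multi = fit_model(profile, get_model("gompertz"), multi_start=10)
    assert multi.sse_fit_space <= single.sse_fit_space + 1e-15


def test_deterministic_given_identical_inputs(kp_albumin_profile):
    a = fit_model(kp_albumin_profile, get_model("korsmeyer_peppas"))
    b = fit_model(kp_albumin_profile, get_model("korsmeyer_peppas"))
    assert a.params == pytest.approx(b.params, rel=0, abs=0)


@pytest.mark.parametrize(
    "name, params",
    [
        ("zero_order", (5e-4,)),
        ("higuchi", (0.02,)),
        ("hixson_crowell", (3.4e-4,)),
        ("baker_lonsdale", (4e-4,)),
    ],
)
def test_single_rate_recovery_bias_below_two_percent(name, params):
    """Relative bias of each single-rate coefficient stays < 2% over 200
    seeded replicates at n = 600, CFR noise SD 0.01."""
    t = np.arange(1.0, 601.0)
    model = get_model(name)
    truth = evaluate_cfr(model, params, t)
    rng = np.random.default_rng(12345)
    estimates = []
    for _ in range(200):
        profile = ReleaseProfile(t_us=t, cfr=truth + rng.normal(0, 0.01, t.size))
        estimates.append(fit_model(profile, model).params[0])
    bias = np.mean(estimates) / params[0] - 1.0
    assert abs(bias) < 0.02, name


def test_noise_does_not_decrease_true_model_sse():
    """One-sided: expected SSE of the generating model is larger with noise
    than without (where it is ~0)."""
    t = np.arange(1.0, 301.0)
    truth = evaluate_cfr(get_model("lu_hagen"), (0.8, 0.01), t)
    noiseless = fit_model(
        ReleaseProfile(t_us=t, cfr=truth), get_model("lu_hagen")
    ).sse_cfr_space
    rng = np.random.default_rng(99)
    noisy = [
        fit_model(
            ReleaseProfile(t_us=t, cfr=truth + rng.normal(0, 0.01, t.size)),
            get_model("lu_hagen"),
        ).sse_cfr_space
        for _ in range(20)
    ]
    assert np.mean(noisy) > noiseless
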