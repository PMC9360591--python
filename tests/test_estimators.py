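import math

import numpy as np
import pytest

from mrkit.errors import EstimationError
from mrkit.estimators import (
    heterogeneity,
    ivw_mre,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from conftest import make_instrument, random_instruments


def ivw_oracle(hs):
    """Independent weighted-least-squares route: design-matrix algebra via
    lstsq on the sqrt(weight)-scaled regression through the origin."""
    bx = np.array([h.beta_exp for h in hs])
    by = np.array([h.beta_out for h in hs])
    sy = np.array([h.se_out for h in hs])
    sw = 1.0 / sy
    X = (bx * sw)[:, None]
    beta, *_ = np.linalg.lstsq(X, by * sw, rcond=None)
    se_fe = float(np.sqrt(np.linalg.inv(X.T @ X)[0, 0]))
    return float(beta[0]), se_fe


def weighted_median_oracle(theta, w):
    """Brute-force cumulative-weight search with linear interpolation."""
    order = np.argsort(theta)
    th, ww = np.asarray(theta)[order], np.asarray(w)[order]
    ww = ww / ww.sum()
    s = np.cumsum(ww) - ww / 2
    for i in range(len(th)):
        if s[i] >= 0.5:
            if i == 0:
                return float(th[0])
            frac = (0.5 - s[i - 1]) / (s[i] - s[i - 1])
            return float(th[i - 1] + frac * (th[i] - th[i - 1]))
    return float(th[-1])


def test_wald_ratio_arithmetic():
    est = wald_ratio(make_instrument(beta_exp=0.2, beta_out=0.05, se_out=0.02))
    assert est.beta == pytest.approx(0.25) and est.se == pytest.approx(0.1)
    est = wald_ratio(make_instrument(beta_exp=0.1, beta_out=0.0, se_out=0.05))
    assert est.beta == 0.0 and est.se == pytest.approx(0.5)
    with pytest.raises(EstimationError):
        wald_ratio(make_instrument(beta_exp=0.0))


def test_wald_ratio_se_close_to_monte_carlo_for_strong_instruments(rng):
    """First-order ratio se agrees with the sampled ratio sd within 5%."""
    h = make_instrument(beta_exp=0.15, se_exp=0.005, beta_out=0.075, se_out=0.01)
    est = wald_ratio(h)
    bx = rng.normal(h.beta_exp, h.se_exp, 200_000)
    by = rng.normal(h.beta_out, h.se_out, 200_000)
    assert est.se == pytest.approx(np.std(by / bx), rel=0.05)


def test_ivw_exact_proportionality_is_degenerate():
    hs = [
        make_instrument(f"rs{i}", beta_exp=b, beta_out=0.5 * b, se_out=0.01)
        for i, b in enumerate([0.1, 0.2, 0.3])
    ]
    est, het = ivw_mre(hs)
    assert est.beta == pytest.approx(0.5, abs=1e-14)
    assert het.q == pytest.approx(0.0, abs=1e-20)
    assert het.i2 == 0.0 and het.phi == 1.0
    assert est.se == pytest.approx(math.sqrt(1 / (1e4 * (0.01 + 0.04 + 0.09))), rel=1e-12)


def test_ivw_matches_wls_oracle_on_random_sets(rng):
    for _ in range(30):
        hs = random_instruments(rng, int(rng.integers(3, 21)))
        est, _ = ivw_mre(hs)
        beta_o, se_o = ivw_oracle(hs)
        assert est.beta == pytest.approx(beta_o, abs=1e-12)


def test_ivw_two_snp_equals_weighted_mean_of_wald_ratios():
    hs = [
        make_instrument("rs1", beta_exp=0.1, beta_out=0.04, se_out=0.01),
        make_instrument("rs2", beta_exp=0.3, beta_out=0.18, se_out=0.03),
    ]
    est, _ = ivw_mre(hs)
    ratios = [h.beta_out / h.beta_exp for h in hs]
    w = [(h.beta_exp / h.se_out) ** 2 for h in hs]
    assert est.beta == pytest.approx(np.average(ratios, weights=w), abs=1e-14)


def test_ivw_point_estimate_invariant_to_common_se_rescaling(rng):
    hs = random_instruments(rng, 8)
    est1, _ = ivw_mre(hs)
    scaled = [
        make_instrument(h.snp_id, h.beta_exp, h.se_exp, h.beta_out, h.se_out * 3.7) for h in hs
    ]
    est2, _ = ivw_mre(scaled)
    assert est1.beta == pytest.approx(est2.beta, abs=1e-14)


def test_ivw_multiplicative_floor_never_shrinks_se():
    hs = [
        make_instrument(f"rs{i}", beta_exp=b, beta_out=0.5 * b + d, se_out=0.1)
        for i, (b, d) in enumerate([(0.1, 1e-6), (0.2, -1e-6), (0.3, 0.0)])
    ]
    est, het = ivw_mre(hs)  # tiny residuals: Q << df, phi floored at 1
    assert het.phi == 1.0
    assert est.se == pytest.approx(math.sqrt(1 / sum((b / 0.1) ** 2 for b in [0.1, 0.2, 0.3])))


def test_ivw_preconditions():
    with pytest.raises(EstimationError):
        ivw_mre([make_instrument()])
    with pytest.raises(EstimationError):
        ivw_mre([make_instrument("rs1", beta_exp=0.0), make_instrument("rs2", beta_exp=0.0)])


def test_heterogeneity_i2_bands():
    assert heterogeneity(0.0, 8).i2 == 0.0
    assert heterogeneity(4.0, 8).i2 == 0.0  # q <= df
    assert heterogeneity(16.0, 8).i2 == pytest.approx(50.0)
    assert heterogeneity(16.0, 8).phi == pytest.approx(math.sqrt(2))


def test_weighted_median_symmetric_case():
    hs = [
        make_instrument(f"rs{i}", beta_exp=0.1, beta_out=0.1 * t, se_out=0.01)
        for i, t in enumerate([0.2, 0.5, 0.8])
    ]
    est = weighted_median(hs, n_boot=100, seed=1)
    assert est.beta == pytest.approx(0.5)


def test_weighted_median_matches_brute_force_oracle(rng):
    for _ in range(30):
        hs = random_instruments(rng, int(rng.integers(3, 21)))
        est = weighted_median(hs, n_boot=50, seed=2)
        theta = np.array([h.beta_out / h.beta_exp for h in hs])
        w = np.array([(h.beta_exp / h.se_out) ** 2 for h in hs])
        assert est.beta == pytest.approx(weighted_median_oracle(theta, w), abs=1e-12)
        assert min(theta) <= est.beta <= max(theta)


def test_weighted_median_unequal_weights_hand_case():
    # ratios (0.1, 0.2, 0.9) with normalized weights (0.5, 0.3, 0.2)
    theta = np.array([0.1, 0.2, 0.9])
    w = np.array([0.5, 0.3, 0.2])
    hs = [
        make_instrument(f"rs{i}", beta_exp=math.sqrt(wi), beta_out=math.sqrt(wi) * t, se_out=1.0)
        for i, (t, wi) in enumerate(zip(theta, w))
    ]
    est = weighted_median(hs, n_boot=50, seed=3)
    assert est.beta == pytest.approx(weighted_median_oracle(theta, w), abs=1e-12)


def test_weighted_median_seeded_determinism():
    hs = random_instruments(np.random.default_rng(5), 9)
    a = weighted_median(hs, n_boot=200, seed=42)
    b = weighted_median(hs, n_boot=200, seed=42)
    assert a.se == b.se and a.pval == b.pval
    with pytest.raises(EstimationError):
        weighted_median(hs[:2], n_boot=10, seed=1)
    with pytest.raises(EstimationError):
        weighted_median(hs, n_boot=10, seed=None)


def test_mr_egger_exact_linear_case():
    bx = [0.1, 0.2, 0.3, 0.4]
    hs = [
        make_instrument(f"rs{i}", beta_exp=b, beta_out=0.1 + 0.4 * b, se_out=0.01)
        for i, b in enumerate(bx)
    ]
    res = mr_egger(hs)
    assert res.intercept == pytest.approx(0.1, abs=1e-12)
    assert res.slope.beta == pytest.approx(0.4, abs=1e-12)


def test_mr_egger_orientation_invariance():
    hs = random_instruments(np.random.default_rng(6), 7)
    res1 = mr_egger(hs)
    flipped = [
        make_instrument(h.snp_id, -h.beta_exp, h.se_exp, -h.beta_out, h.se_out)
        if i % 2
        else h
        for i, h in enumerate(hs)
    ]
    res2 = mr_egger(flipped)
    assert res1.slope.beta == pytest.approx(res2.slope.beta, abs=1e-12)
    assert res1.intercept == pytest.approx(res2.intercept, abs=1e-12)


def test_mr_egger_intercept_calibrated_under_balanced_pleiotropy():
    """With zero-mean pleiotropy the intercept t-test keeps ~nominal size
    (and hence ~95% non-rejection) over 500 replicates."""
    from mrkit.simulate import SimulationConfig, run_scenario_grid

    cfg = SimulationConfig(seed=0, causal_beta=0.1, pleiotropy_mean=0.0, pleiotropy_sd=0.01)
    tab = run_scenario_grid([cfg], n_reps=500, estimators=["mr_egger"])
    rate = tab.loc[tab.estimator == "egger_intercept", "rejection_rate"].item()
    # 95% binomial band around 0.05 at 500 reps: 0.05 +/- 1.96*sqrt(.05*.95/500)
    assert 0.031 <= rate <= 0.069


def test_mr_egger_preconditions():
    with pytest.raises(EstimationError):
        mr_egger(random_instruments(np.random.default_rng(1), 2))
    same = [make_instrument(f"rs{i}", beta_exp=0.2, beta_out=0.1) for i in range(4)]
    with pytest.raises(EstimationError, match="collinear"):
        mr_egger(same)


def test_all_estimators_agree_on_proportional_data():
    hs = [
        make_instrument(f"rs{i}", beta_exp=b, beta_out=0.3 * b, se_out=0.02)
        for i, b in enumerate([0.08, 0.15, 0.22, 0.29])
    ]
    ivw, het = ivw_mre(hs)
    wm = weighted_median(hs, n_boot=50, seed=1)
    eg = mr_egger(hs)
    for val in (ivw.beta, wm.beta, eg.slope.beta):
        assert val == pytest.approx(0.3, abs=1e-10)
    assert het.q == pytest.approx(0.0, abs=1e-18)
    assert eg.intercept == pytest.approx(0.0, abs=1e-12)


def test_to_odds_ratio_reproduces_published_style_interval():
    """log-OR 0.0770 (se 0.0296) prints as OR 1.08, 95% CI (1.02, 1.14)."""
    from mrkit.estimators import _normal_estimate

    est = _normal_estimate("ivw_mre", 0.0770, 0.0296, 9)
    or_, (lo, hi), _ = to_odds_ratio(est)
    assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (1.08, 1.02, 1.14)
    # monotone and null-neutral
    or0, (lo0, hi0), _ = to_odds_ratio(_normal_estimate("ivw_mre", 0.0, 0.1, 9))
    assert or0 == 1.0 and lo0 < 1.0 < hi0
    assert to_odds_ratio(_normal_estimate("ivw_mre", 0.1, 0.1, 9))[0] > or0
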