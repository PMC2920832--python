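"""CRW dispersal theory: MSD law, correlation-factor closed forms, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pseudowalk import (
    MSDCurve,
    PseudopodParams,
    crw_msd,
    directional_displacement,
    ensemble_msd,
    fit_crw,
    fit_gamma_mc,
    gamma_pairs_full,
    gamma_step,
    mean_cos_turns,
    regress_gamma_vs_s,
    step_size,
    turn_angle,
    variance_composition,
)

# observed (splitting fraction, correlation factor) pairs for the seven
# strains/conditions entering the gamma-vs-s regression
OBSERVED_S_GAMMA = [
    (0.55, 0.46),
    (0.60, 0.52),
    (0.86, 0.74),
    (0.89, 0.81),
    (0.71, 0.58),
    (0.67, 0.55),
    (0.41, 0.35),
]


def two_step_msd_oracle(lam, gamma):
    """Independent two-step oracle: E|r1+r2|^2 = 2 lam^2 + 2 lam^2 E[cos theta]."""
    return 2 * lam**2 + 2 * lam**2 * gamma


def test_crw_msd_oracles_and_branches():
    assert crw_msd(5, 2.0, 0.0) == pytest.approx(20.0)  # Brownian n*lam^2
    assert crw_msd(2, 1.0, 0.5) == pytest.approx(two_step_msd_oracle(1.0, 0.5))
    assert crw_msd(2, 1.0, 0.5) == pytest.approx(3.0)
    assert crw_msd(1, 3.7, 0.83) == pytest.approx(3.7**2)
    assert crw_msd(4, 2.0, 1.0) == pytest.approx(64.0)  # ballistic branch
    with pytest.raises(ValueError):
        crw_msd(4, 2.0, 1.2)
    with pytest.raises(ValueError):
        crw_msd(4, -1.0, 0.5)


@given(
    st.floats(0.0, 0.99),
    st.floats(0.1, 10.0),
    st.integers(1, 60),
)
def test_crw_msd_increases_with_n_and_gamma(gamma, lam, n):
    assert crw_msd(n + 1, lam, gamma) > crw_msd(n, lam, gamma)
    if gamma < 0.98:
        more = crw_msd(n, lam, gamma + 0.01)
        assert more >= crw_msd(n, lam, gamma) * (1.0 - 1e-12)


@pytest.mark.parametrize("gamma", [0.0, 0.3, 0.65, 0.9])
def test_fit_recovers_gamma_from_noiseless_curve(gamma):
    lam = 4.61
    lags = np.arange(1, 31, dtype=float)
    curve = MSDCurve(lags=lags, msd=crw_msd(lags, lam, gamma), n_traj=1)
    fit = fit_crw(curve, lam)
    assert fit.gamma == pytest.approx(gamma, abs=1e-6)
    assert fit.n_points == 30
    assert fit.rss < 1e-12 * max(curve.msd) ** 2 + 1e-9


def test_fit_crw_validates_input():
    lags = np.arange(1, 11, dtype=float)
    with pytest.raises(ValueError):
        fit_crw(MSDCurve(lags=lags, msd=lags[::-1].copy(), n_traj=1), 1.0)
    with pytest.raises(ValueError):
        MSDCurve(lags=lags, msd=-lags, n_traj=1)
    with pytest.raises(ValueError):
        fit_crw(MSDCurve(lags=lags[:2], msd=lags[:2], n_traj=1), 1.0)


def test_mean_cos_turns_estimator(rng):
    assert mean_cos_turns([0.0, 0.0, 0.0]) == 1.0
    assert mean_cos_turns([60.0, -60.0, 60.0, -60.0]) == pytest.approx(0.5)
    uniform = rng.uniform(-180.0, 180.0, 100_000)
    assert abs(mean_cos_turns(uniform)) < 0.01
    with pytest.raises(ValueError):
        mean_cos_turns([])


def test_gamma_step_closed_form_against_strain_predictions(wt5h):
    # s*cos(sigma)*sqrt(a+(1-a)cos(2 phi)) reproduces the tabulated
    # per-step predictions for the measured strains
    assert gamma_step(wt5h) == pytest.approx(0.64, abs=0.02)
    sgc_pla2 = PseudopodParams(lambda_p=5.3, s=0.41, a=0.75, phi=54, sigma_phi=27.5)
    assert gamma_step(sgc_pla2) == pytest.approx(0.31, abs=0.02)
    perfect = PseudopodParams(lambda_p=1, s=1.0, a=1.0, phi=55.0, sigma_phi=0.0)
    assert gamma_step(perfect) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gamma_step(PseudopodParams(lambda_p=1, s=1, a=0.0, phi=89.0, sigma_phi=0))


def test_gamma_step_monotonicity_and_flat_phi_at_full_alternation():
    base = dict(lambda_p=1.0, s=0.8, a=0.8, phi=55.0, sigma_phi=25.0)

    def g(**kw):
        return gamma_step(PseudopodParams(**{**base, **kw}))

    assert g(s=0.9) > g(s=0.8) > g(s=0.5)
    assert g(a=0.9) > g(a=0.8) > g(a=0.6)
    assert g(sigma_phi=10.0) > g(sigma_phi=25.0) > g(sigma_phi=40.0)
    # at a = 1 the zig-zag closes perfectly and phi has no effect
    assert g(a=1.0, phi=30.0) == pytest.approx(g(a=1.0, phi=70.0), abs=1e-12)


def test_gamma_pairs_limits_and_consistency_with_per_step_form(wt5h):
    assert gamma_pairs_full(
        PseudopodParams(lambda_p=1, s=0.0, a=0.5, phi=55, sigma_phi=28)
    ) == 0.0
    assert gamma_pairs_full(
        PseudopodParams(lambda_p=1, s=1.0, a=1.0, phi=55, sigma_phi=0.0)
    ) == pytest.approx(1.0)
    # wrapped-normal pairing: the pair form is the square of the per-step form
    # to within 5% for sigma <= 30 degrees
    for sigma in [5.0, 15.0, 25.0, 30.0]:
        p = PseudopodParams(lambda_p=1, s=0.86, a=0.77, phi=55, sigma_phi=sigma)
        pair = gamma_pairs_full(p, noise="wrapped_normal")
        rel = abs(gamma_step(p) ** 2 - pair) / pair
        assert rel <= 0.05
    # the von Mises expectation agrees in its own narrower regime
    p20 = PseudopodParams(lambda_p=1, s=0.86, a=0.77, phi=55, sigma_phi=20.0)
    pair = gamma_pairs_full(p20, noise="von_mises")
    assert abs(gamma_step(p20) ** 2 - pair) / pair <= 0.05


def test_step_size_geometry():
    assert step_size(5.0, 0.0) == pytest.approx(5.0)
    assert step_size(5.2, 55.0) == pytest.approx(4.613, abs=1e-3)
    assert step_size(5.0, 180.0) == pytest.approx(0.0, abs=1e-12)


def test_turn_angle_arccos():
    assert turn_angle(0.0) == pytest.approx(90.0)
    assert round(turn_angle(0.74)) == 42
    assert turn_angle(1.0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        turn_angle(1.5)


def test_directional_displacement_saturates_geometrically():
    lam, gamma = 4.61, 0.70
    assert directional_displacement(1, lam, 0.9) == pytest.approx(lam)
    assert directional_displacement(50, lam, 0.0) == pytest.approx(lam)
    values = [directional_displacement(n, lam, gamma) for n in range(1, 40)]
    assert np.all(np.diff(values) > 0)
    limit = directional_displacement(math.inf, lam, gamma)
    assert limit == pytest.approx(lam / (1 - gamma))
    assert limit == pytest.approx(15.4, abs=0.1)  # the ~15 µm scale
    assert values[-1] < limit


def test_regression_of_gamma_on_splitting_fraction():
    slope, intercept, r2 = regress_gamma_vs_s(OBSERVED_S_GAMMA)
    assert round(slope, 3) == 0.921
    assert round(intercept, 3) == -0.044
    assert r2 > 0.9
    s2, i2, _ = regress_gamma_vs_s([(0, 0), (0.5, 0.45), (1, 0.9)])
    assert s2 == pytest.approx(0.9, abs=1e-9)
    assert i2 == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        regress_gamma_vs_s([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])
    with pytest.raises(ValueError):
        regress_gamma_vs_s([(0, 0), (1, 1)])


def test_variance_composition_quadrature():
    assert variance_composition(24.9, 13.3) == pytest.approx(28.2, abs=0.05)
    assert variance_composition(17.0, 0.0) == 17.0
    assert variance_composition(3.0, 4.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        variance_composition(-1.0, 3.0)


def test_brownian_limit_ensemble_fit():
    # phi = 0 so the effective step size equals lambda_p: a pure de novo
    # walk has no zig-zag geometry reduction
    brownian = PseudopodParams(lambda_p=5.0, s=0.0, a=0.5, phi=0.0, sigma_phi=28.0)
    fit = fit_gamma_mc(brownian, n_traj=50_000, n_steps=30, seed=61)
    assert fit.gamma == pytest.approx(0.0, abs=0.02)


def test_simulated_dispersion_tracks_closed_form(wt5h, wt1h):
    """The fitted ensemble correlation factor sits near, and above, the
    pair-approximation closed form (which discards split-after-de-novo
    correlations)."""
    for params, tol in [(wt5h, 0.05), (wt1h, 0.08)]:
        fit = fit_gamma_mc(params, n_traj=30_000, n_steps=30, seed=71)
        g = gamma_step(params)
        assert fit.gamma >= g - 0.01
        assert abs(fit.gamma - g) < tol


def test_ensemble_msd_monotone(wt5h):
    curve = ensemble_msd(wt5h, 5_000, 30, seed=81)
    assert curve.n_traj == 5_000
    assert np.all(np.diff(curve.msd) > 0)
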