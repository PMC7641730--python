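"""1:1 isotherm prediction and per-residue K_D fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrbind.binding import (
    BindingIsothermModel,
    IsothermParams,
    bound_fraction,
    fit_kd,
    fit_kd_profile,
    predicted_delta,
)
from nmrbind.csp import compute_profile
from nmrbind.exceptions import DataError
from nmrbind.synthetic import StudyConfig, simulate_titration


def test_predicted_delta_direct_substitution():
    # bracket = (250 - 150) / 200 = 0.5
    p = IsothermParams(K_D=50.0, delta_max=0.2)
    assert predicted_delta(100.0, 100.0, p) == pytest.approx(0.1, abs=1e-12)


def test_no_ligand_no_shift():
    p = IsothermParams(50.0, 0.2)
    assert predicted_delta(100.0, 0.0, p) == 0.0


def test_stoichiometric_limit_kd_to_zero():
    p = IsothermParams(1e-9, 0.2)
    assert predicted_delta(100.0, 100.0, p) == pytest.approx(0.2, rel=1e-4)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        IsothermParams(-1.0, 0.2)
    with pytest.raises(ValueError):
        IsothermParams(50.0, 0.0)
    with pytest.raises(ValueError, match="positive"):
        bound_fraction(0.0, 10.0, 50.0)


@settings(derandomize=True, max_examples=60)
@given(
    st.floats(1.0, 500.0),       # P
    st.floats(0.0, 2000.0),      # D
    st.floats(0.01, 1000.0),     # K_D
)
def test_bound_fraction_in_physical_range(P, D, K_D):
    fb = bound_fraction(P, D, K_D)
    assert -1e-12 <= fb <= min(1.0, D / P) + 1e-9


@settings(derandomize=True, max_examples=40)
@given(st.floats(1.0, 500.0), st.floats(1.0, 1000.0), st.floats(0.1, 500.0))
def test_monotonicity_in_D_and_KD(P, D, K_D):
    p_lo = IsothermParams(K_D, 0.2)
    assert predicted_delta(P, D * 1.5, p_lo) >= predicted_delta(P, D, p_lo) - 1e-12
    p_hi = IsothermParams(K_D * 2.0, 0.2)
    assert predicted_delta(P, D, p_hi) <= predicted_delta(P, D, p_lo) + 1e-12


def test_noiseless_recovery_six_points():
    truth = IsothermParams(50.0, 0.2)
    D = [50.0, 100.0, 200.0, 300.0, 400.0, 600.0]
    obs = [predicted_delta(100.0, d, truth) for d in D]
    res = BindingIsothermModel(100.0, D, obs).fit()
    assert res.converged
    assert res.K_D == pytest.approx(50.0, rel=1e-4)
    assert res.delta_max == pytest.approx(0.2, rel=1e-4)
    assert res.chi2 < 1e-12


@pytest.mark.parametrize("sigma", [0.0, 0.001, 0.003])
def test_kd_bias_shrinks_with_noise(sigma):
    """Median K_D over seeded replicates approaches truth as noise -> 0."""
    truth = IsothermParams(45.0, 0.12)
    D = np.array([10.0, 50.0, 100.0, 200.0, 400.0, 600.0])
    clean = predicted_delta(100.0, D, truth)
    rng = np.random.default_rng(5)
    kds = []
    for _ in range(30):
        obs = np.clip(clean + rng.normal(0, sigma, size=D.size), 0, None)
        r = BindingIsothermModel(100.0, D, obs).fit()
        assert r.converged
        kds.append(r.K_D)
    tol = 1e-4 if sigma == 0 else 0.15
    assert np.median(kds) == pytest.approx(45.0, rel=tol)


def test_all_zero_series_not_converged():
    res = BindingIsothermModel(100.0, [50.0, 100.0, 200.0], [0.0, 0.0, 0.0]).fit()
    assert not res.converged
    assert "unidentifiable" in res.message


def test_too_few_informative_points_is_error():
    with pytest.raises(DataError, match="3 titration points"):
        BindingIsothermModel(100.0, [0.0, 100.0, 200.0], [0.0, 0.05, 0.08])


def test_fit_kd_requires_constant_protein():
    with pytest.raises(DataError, match="constant"):
        fit_kd([(100.0, 50.0, 0.05), (90.0, 100.0, 0.08), (100.0, 200.0, 0.1)])


def test_bootstrap_errors_are_seeded():
    truth = IsothermParams(50.0, 0.2)
    D = np.array([50.0, 100.0, 200.0, 300.0, 400.0, 600.0])
    rng = np.random.default_rng(9)
    obs = predicted_delta(100.0, D, truth) + rng.normal(0, 0.003, D.size)
    m = BindingIsothermModel(100.0, D, obs)
    r1 = m.fit(bootstrap=50, seed=123)
    r2 = m.fit(bootstrap=50, seed=123)
    assert r1.se_KD == pytest.approx(r2.se_KD)
    assert r1.se_KD > 0


def test_fit_kd_profile_recovers_all_fixture_binders(noiseless_cfg):
    series = simulate_titration(noiseless_cfg)
    prof = compute_profile(series)
    fits = fit_kd_profile(series, prof, min_tier="above_mean_plus_sd")
    truth = {b.residue_number: b for b in noiseless_cfg.binding_residues}
    assert len(fits) == len(truth)
    for r in fits:
        assert r.converged
        assert r.K_D == pytest.approx(truth[r.residue_number].K_D, rel=1e-3)


def test_fit_kd_profile_empty_when_nothing_significant():
    cfg = StudyConfig(seed=2, binding_residues=())
    series = simulate_titration(cfg)
    prof = compute_profile(series)
    # threshold at mean+SD of pure noise: some residues may top it, but a
    # pinned high threshold yields an empty selection
    prof2 = compute_profile(
        series, threshold_mode="pinned", pinned_mean=0.015, pinned_threshold=0.038
    )
    fits = fit_kd_profile(series, prof2, min_tier="above_mean_plus_sd")
    assert len(fits) == 0


def test_missing_intermediate_point_shrinks_n_points(noiseless_cfg):
    series = simulate_titration(noiseless_cfg)
    # drop one binding residue from an intermediate peak list
    target = noiseless_cfg.binding_residues[0].residue_number
    mid = series.point_peaklists[3]
    mid.peaks = [p for p in mid.peaks if p.residue_number != target]
    prof = compute_profile(series)
    fits = fit_kd_profile(series, prof)
    by_res = {r.residue_number: r for r in fits}
    assert by_res[target].n_points == series.n_points - 1
    assert by_res[target].converged


def test_global_shared_kd_fit(tmp_path):
    """With a common true K_D the global fit recovers it and each Δδmax."""
    from nmrbind.binding import fit_kd_global
    from nmrbind.synthetic import BindingResidue

    binders = tuple(
        BindingResidue(r, 45.0, 0.04 + 0.01 * i, 0.3)
        for i, r in enumerate((150, 155, 160, 165))
    )
    cfg = StudyConfig(seed=6, binding_residues=binders,
                      shift_noise_sd_H=0.0, shift_noise_sd_N=0.0)
    series = simulate_titration(cfg)
    prof = compute_profile(series)
    fits = fit_kd_global(series, prof, min_tier="above_mean_plus_sd")
    assert len(fits) == 4
    kds = {r.K_D for r in fits}
    assert len(kds) == 1  # shared parameter
    assert kds.pop() == pytest.approx(45.0, rel=1e-3)
    truth = {b.residue_number: b for b in binders}
    for r in fits:
        expected = np.hypot(truth[r.residue_number].dmax_HN,
                            truth[r.residue_number].dmax_N / 5.0)
        assert r.delta_max == pytest.approx(expected, rel=1e-3)
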