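"""R1/R2 decay fitting, hetNOE, tau_c estimation and stoichiometry."""

import math

import numpy as np
import pytest

from nmrbind.exceptions import DataError
from nmrbind.peaklist import IntensityTable
from nmrbind.relaxation import (
    FieldSpec,
    RelaxationRates,
    estimate_tauc,
    expected_tauc_from_mw,
    fit_monoexp,
    hetnoe_ratio,
    infer_stoichiometry,
    tauc_from_ratio,
)
from nmrbind.peaklist import _find_duplicate_pairs
from nmrbind.synthetic import CPMG_DELAYS_S, INVERSION_RECOVERY_DELAYS_S


def _table(delays, rate, i0=10.0, resid=1):
    t = np.asarray(delays)
    return IntensityTable(resid, t, i0 * np.exp(-rate * t),
                          _find_duplicate_pairs(t))


def test_field_spec_nitrogen_frequency():
    f = FieldSpec(500.0)
    assert f.nitrogen_frequency == pytest.approx(50.684595, abs=1e-4)
    assert FieldSpec(800.0).nitrogen_frequency / f.nitrogen_frequency == pytest.approx(1.6)


@pytest.mark.parametrize("rate", [0.5, 1.5, 12.5, 25.0])
def test_monoexp_exact_on_noiseless_decays(rate):
    schedule = CPMG_DELAYS_S if rate > 5 else INVERSION_RECOVERY_DELAYS_S
    res = fit_monoexp(_table(schedule, rate))
    assert res.decaying
    assert res.rate == pytest.approx(rate, abs=1e-8)
    assert res.I0 == pytest.approx(10.0, abs=1e-7)


def test_constant_intensities_flagged_non_decaying():
    t = np.array(CPMG_DELAYS_S)
    res = fit_monoexp(IntensityTable(1, t, np.full(t.size, 5.0),
                                     _find_duplicate_pairs(t)))
    assert not res.decaying
    assert res.rate == pytest.approx(0.0, abs=1e-6)


def test_duplicate_scatter_gives_positive_reproducible_error():
    t = np.array(CPMG_DELAYS_S)
    ideal = 10.0 * np.exp(-12.5 * t)
    noisy = ideal.copy()
    # perturb one member of each duplicate pair by 2%
    for i, j in _find_duplicate_pairs(t):
        noisy[j] *= 1.02
    tab = IntensityTable(1, t, noisy, _find_duplicate_pairs(t))
    r1 = fit_monoexp(tab)
    r2 = fit_monoexp(tab)
    assert r1.se_rate > 0
    assert r1.se_rate == pytest.approx(r2.se_rate)
    assert r1.sigma_I > 0


def test_monoexp_preconditions():
    with pytest.raises(DataError, match="distinct delays"):
        fit_monoexp(_table([0.01, 0.01, 0.05], 10.0))
    t = np.array([0.01, 0.05, 0.1])
    with pytest.raises(DataError, match="nonpositive intensity"):
        fit_monoexp(IntensityTable(1, t, np.array([-1.0, 0.5, 0.2]), []))


@pytest.mark.parametrize(
    "i_sat, i_unsat, expected",
    [(0.0, 1.0, 0.0), (0.8, 1.0, 0.8), (-0.5, 1.0, -0.5)],
)
def test_hetnoe_ratio(i_sat, i_unsat, expected):
    assert hetnoe_ratio(i_sat, i_unsat) == expected


def test_hetnoe_zero_reference_error():
    with pytest.raises(DataError, match="zero"):
        hetnoe_ratio(0.5, 0.0)


# ---------------------------------------------------------------------------
# tau_c
# ---------------------------------------------------------------------------

def test_tauc_closed_form_against_independent_evaluation():
    """tauc_from_ratio matches a one-line brute-force evaluation."""
    ratio, nu = 11.33, 50.68
    oracle_ns = math.sqrt(6 * ratio - 7) / (4 * math.pi * nu * 1e6) * 1e9
    assert tauc_from_ratio(ratio, nu) == pytest.approx(oracle_ns, rel=1e-12)
    assert tauc_from_ratio(ratio, nu) == pytest.approx(12.26, abs=0.01)


def test_tauc_zero_at_radicand_root_and_error_below():
    assert tauc_from_ratio(7.0 / 6.0, 50.68) == 0.0
    with pytest.raises(DataError, match="7/6"):
        tauc_from_ratio(1.0, 50.68)


def test_tauc_monotone_in_ratio():
    taus = [tauc_from_ratio(r, 50.68) for r in np.linspace(7 / 6, 30, 40)]
    assert all(b >= a for a, b in zip(taus, taus[1:]))


def _rates(ratios, noe=0.8, r1=1.5):
    return [
        RelaxationRates(i + 1, r1, 0.01, r1 * q, 0.02, hetnoe=noe)
        for i, q in enumerate(ratios)
    ]


def test_estimate_tauc_uniform_ratio_average_order_irrelevant():
    rates = _rates([20.0] * 12)
    f = FieldSpec(800.0)
    a = estimate_tauc(rates, f, average="ratio_then_mean")
    b = estimate_tauc(rates, f, average="mean_then_ratio")
    assert a.tau_c == pytest.approx(b.tau_c, rel=1e-12)
    assert a.n_residues_used == 12


def test_estimate_tauc_filters_low_noe_and_outliers():
    rates = _rates([11.0] * 20) + _rates([11.2] * 3, noe=-0.4)
    # rename the low-NOE residues to distinct ids
    for k, r in enumerate(rates[20:]):
        r.residue_number = 100 + k
    est = estimate_tauc(rates, FieldSpec(500.0), min_noe=0.65)
    assert all(r < 100 for r in est.residues_used)
    # a gross R2/R1 outlier is trimmed even with high NOE
    rates2 = _rates([11.0] * 20 + [60.0])
    rates2[-1].residue_number = 99
    est2 = estimate_tauc(rates2, FieldSpec(500.0))
    assert 99 not in est2.residues_used


def test_estimate_tauc_explicit_residue_list():
    rates = _rates([11.0] * 5 + [13.0] * 5)
    est = estimate_tauc(rates, FieldSpec(500.0), residues=[1, 2, 3, 4, 5])
    assert est.residues_used == [1, 2, 3, 4, 5]
    assert est.tau_c == pytest.approx(tauc_from_ratio(11.0, FieldSpec(500.0).nitrogen_frequency))


# ---------------------------------------------------------------------------
# expected tau_c from MW and stoichiometry
# ---------------------------------------------------------------------------

def test_expected_tauc_linear_rule():
    assert expected_tauc_from_mw(12.8) == pytest.approx(8.0, rel=0.10)
    assert expected_tauc_from_mw(23.2) == pytest.approx(14.0, rel=0.10)
    assert expected_tauc_from_mw(0.1) == pytest.approx(0.06, rel=1e-9)
    with pytest.raises(ValueError):
        expected_tauc_from_mw(-1.0)


def test_expected_tauc_monotone_and_stokes_einstein_lower():
    mws = np.linspace(1, 100, 25)
    emp = [expected_tauc_from_mw(m) for m in mws]
    assert all(b > a for a, b in zip(emp, emp[1:]))
    # the Stokes-Einstein sphere estimate sits below the empirical rule
    for m in (12.8, 23.2, 50.0):
        assert expected_tauc_from_mw(m, mode="stokes_einstein") < expected_tauc_from_mw(m)


def test_stoichiometry_calls():
    cands = [("free", 12.8), ("1:1", 23.2), ("1:2", 33.6)]
    assert infer_stoichiometry(13.7, cands).best == "1:1"
    assert infer_stoichiometry(8.9, cands).best == "free"
    # exact match
    assert infer_stoichiometry(expected_tauc_from_mw(33.6), cands).best == "1:2"


def test_stoichiometry_invariant_to_candidate_order():
    cands = [("free", 12.8), ("1:1", 23.2), ("1:2", 33.6)]
    for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
        shuffled = [cands[i] for i in perm]
        assert infer_stoichiometry(13.7, shuffled).best == "1:1"


def test_stoichiometry_empty_candidates_error():
    with pytest.raises(DataError, match="candidates"):
        infer_stoichiometry(10.0, [])
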