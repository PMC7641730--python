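"""Weighted CSP computation, classification and DNA flagging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrbind.csp import (
    compute_profile,
    flag_dna_bases,
    weighted_csp,
)
from nmrbind.exceptions import DataError
from nmrbind.peaklist import AmidePeak, PeakList, TitrationSeries
from nmrbind.synthetic import simulate_titration

finite = st.floats(-2.0, 2.0, allow_nan=False)


@pytest.mark.parametrize(
    "d_HN, d_N, variant, expected",
    [
        (0.0, 0.0, "unscaled", 0.0),
        (0.0, 0.0, "scaled", 0.0),
        (0.03, 0.10, "unscaled", 0.0360555),  # sqrt(0.0009 + 0.0004)
        (0.03, 0.10, "scaled", 0.0254951),    # previous / sqrt(2)
    ],
)
def test_weighted_csp_values(d_HN, d_N, variant, expected):
    assert weighted_csp(d_HN, d_N, variant) == pytest.approx(expected, abs=1e-6)


def test_weighted_csp_rejects_unknown_variant_and_nonfinite():
    with pytest.raises(ValueError, match="variant"):
        weighted_csp(0.1, 0.1, "banana")
    with pytest.raises(ValueError, match="finite"):
        weighted_csp(float("nan"), 0.1)


@settings(derandomize=True, max_examples=100)
@given(finite, finite)
def test_scale_relation_sqrt2(d_HN, d_N):
    """unscaled / scaled = sqrt(2) exactly, for any inputs."""
    u = weighted_csp(d_HN, d_N, "unscaled")
    s = weighted_csp(d_HN, d_N, "scaled")
    assert u == pytest.approx(s * math.sqrt(2.0), rel=1e-12, abs=1e-15)
    assert u >= 0 and s >= 0


@settings(derandomize=True, max_examples=50)
@given(finite, finite, st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_monotone_in_both_magnitudes(d_HN, d_N, bump_h, bump_n):
    base = weighted_csp(d_HN, d_N)
    grown = weighted_csp(
        abs(d_HN) + bump_h, abs(d_N) + bump_n
    )
    assert grown >= base - 1e-12


def _series(shifts_by_point, P=100.0):
    lists = []
    for pts in shifts_by_point:
        lists.append(
            PeakList(
                "pt",
                [AmidePeak(r, "G", h, n) for r, (h, n) in sorted(pts.items())],
            )
        )
    concs = [0.0] + [50.0 * i for i in range(1, len(lists))]
    return TitrationSeries(P, concs, lists)


def test_uniform_shift_gives_zero_sd():
    free = {r: (8.0, 120.0) for r in range(1, 11)}
    final = {r: (8.02, 120.05) for r in range(1, 11)}
    prof = compute_profile(_series([free, final]))
    deltas = [r.delta for r in prof.tracked]
    assert np.allclose(deltas, deltas[0])
    assert prof.sd_delta == pytest.approx(0.0, abs=1e-15)
    assert prof.threshold_active == pytest.approx(prof.mean_delta)


def test_residue_missing_at_endpoint_untracked():
    free = {1: (8.0, 120.0), 2: (8.5, 121.0), 3: (7.5, 119.0)}
    final = {1: (8.01, 120.1), 2: (8.52, 121.2)}  # residue 3 lost
    prof = compute_profile(_series([free, final]))
    rec = prof.get(3)
    assert rec.tier == "untracked"
    assert len(prof.tracked) == 2
    # untracked residues do not enter the statistics
    deltas = [r.delta for r in prof.tracked]
    assert prof.mean_delta == pytest.approx(np.mean(deltas))


def test_no_common_residues_is_error():
    free = {1: (8.0, 120.0)}
    final = {2: (8.0, 120.0)}
    with pytest.raises(DataError, match="common"):
        compute_profile(_series([free, final]))


def test_pinned_thresholds_override_data():
    free = {r: (8.0, 120.0) for r in range(1, 6)}
    final = {r: (8.0 + 0.01 * r, 120.0) for r in range(1, 6)}
    prof = compute_profile(
        _series([free, final]),
        threshold_mode="pinned",
        pinned_mean=0.015,
        pinned_threshold=0.038,
    )
    assert prof.mean_delta == 0.015
    assert prof.threshold_active == 0.038
    top = prof.residues_at_least("above_mean_plus_sd")
    assert top == [4, 5]  # deltas 0.04, 0.05 exceed 0.038


def test_fixture_classification_finds_exactly_true_binders(low_noise_cfg):
    """At low noise the top tier is exactly the true binding set."""
    series = simulate_titration(low_noise_cfg)
    prof = compute_profile(series)
    truth = sorted(b.residue_number for b in low_noise_cfg.binding_residues)
    assert sorted(prof.residues_at_least("above_mean_plus_sd")) == truth


# ---------------------------------------------------------------------------
# DNA flagging
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "d_h1p, d_h68, expect",
    [
        (0.03, 0.00, True),    # H1' alone exceeds the cut
        (0.00, 0.00, False),
        (0.010, 0.026, True),  # disjunction: H6/H8 alone suffices
        (-0.03, 0.0, True),    # magnitude, not sign
        (0.025, 0.025, False), # strict inequality
    ],
)
def test_dna_flag_rule(d_h1p, d_h68, expect):
    # differences constructed exactly so the strict-inequality edge is clean
    free = {"T1": (0.0, 0.0)}
    bound = {"T1": (d_h1p, d_h68)}
    rec = flag_dna_bases(free, bound)[0]
    assert rec.flagged is expect


def test_dna_flag_mismatched_bases_error():
    with pytest.raises(DataError, match="differ"):
        flag_dna_bases({"T1": (5.5, 7.2)}, {"A2": (5.5, 7.2)})
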