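"""Kitz-Wilson kinetics: pseudo-first-order fits and reciprocal estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from s9conf.kinetics import (
    InactivationSeries,
    KineticsError,
    analyze_inactivation,
    fit_kitz_wilson,
    fit_pseudo_first_order,
    fit_saturation_nonlinear,
    read_series_csv,
)
from s9conf.synth import simulate_inactivation

TIMES = np.arange(0.0, 11.0)


def series(conc=100.0, k=0.1, times=TIMES):
    return InactivationSeries(conc_uM=conc, times_min=times, activity=np.exp(-k * times))


def test_exact_exponential_recovers_rate_with_perfect_fit():
    fit = fit_pseudo_first_order(series(k=0.1))
    assert fit.k_prime == pytest.approx(0.100, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)
    assert not fit.no_inactivation


def test_constant_activity_flagged_no_inactivation():
    s = InactivationSeries(conc_uM=50.0, times_min=TIMES, activity=np.ones_like(TIMES))
    fit = fit_pseudo_first_order(s)
    assert fit.k_prime == 0.0
    assert fit.no_inactivation


def test_rate_law_oracle_at_single_concentration():
    """Noiseless simulation at [I]=100 uM gives k' = k2*[I]/(Ki+[I])."""
    Ki_mM, k2 = 0.28, 0.27
    (s,) = simulate_inactivation(Ki_mM, k2, [100.0], list(TIMES))
    fit = fit_pseudo_first_order(s)
    expected = k2 * 100.0 / (Ki_mM * 1000 + 100.0)
    assert fit.k_prime == pytest.approx(expected, abs=1e-6)


def test_series_validation():
    with pytest.raises(KineticsError, match="positive"):
        InactivationSeries(conc_uM=-1, times_min=TIMES, activity=np.exp(-0.1 * TIMES))
    with pytest.raises(KineticsError, match="increasing"):
        InactivationSeries(conc_uM=1, times_min=[0, 2, 1], activity=[1, 0.9, 0.8])
    with pytest.raises(KineticsError, match="positive"):
        InactivationSeries(conc_uM=1, times_min=[0, 1, 2], activity=[1, 0.5, 0.0])
    with pytest.raises(KineticsError, match="exceed"):
        InactivationSeries(conc_uM=1, times_min=[0, 1, 2], activity=[1.2, 0.5, 0.2])
    with pytest.raises(KineticsError, match="3 time points"):
        fit_pseudo_first_order(InactivationSeries(1.0, [0, 1], [1.0, 0.9]))


def test_reciprocal_fit_recovers_reported_constants_exactly():
    """Noiseless curves from Ki = 0.28 mM, k2 = 0.27 min^-1 at the titration
    concentrations return both constants to numerical precision."""
    data = simulate_inactivation(0.28, 0.27, [50, 100, 150, 200, 260], list(TIMES))
    fit = analyze_inactivation(data)
    assert fit.Ki_mM == pytest.approx(0.28, abs=1e-9)
    assert fit.k2_per_min == pytest.approx(0.27, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0)
    assert all(f.k_prime < fit.k2_per_min for f in fit.per_series)


def test_identical_kprime_degenerate():
    fit = fit_kitz_wilson([(50.0, 0.1), (100.0, 0.1), (200.0, 0.1)])
    assert fit.degenerate
    assert fit.Ki_mM == 0.0


def test_nonpositive_intercept_not_identifiable():
    # 1/k' decreasing faster than 1/[I] -> negative extrapolated intercept
    pairs = [(50.0, 0.02), (100.0, 0.05), (200.0, 0.2)]
    with pytest.raises(KineticsError, match="saturation"):
        fit_kitz_wilson(pairs)


def test_reciprocal_fit_input_validation():
    with pytest.raises(KineticsError, match="3 distinct"):
        fit_kitz_wilson([(50.0, 0.1), (50.0, 0.2)])
    with pytest.raises(KineticsError, match="positive"):
        fit_kitz_wilson([(50.0, 0.1), (100.0, -0.1), (200.0, 0.2)])


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    Ki=st.floats(min_value=0.05, max_value=2.0),
    k2=st.floats(min_value=0.05, max_value=2.0),
)
def test_noiseless_round_trip_identity(Ki, k2):
    data = simulate_inactivation(Ki, k2, [50, 120, 300, 800], [0, 2, 4, 6, 8, 10])
    fit = analyze_inactivation(data)
    assert fit.Ki_mM == pytest.approx(Ki, rel=1e-6)
    assert fit.k2_per_min == pytest.approx(k2, rel=1e-6)


def test_kprime_monotone_in_concentration_and_bounded_by_k2():
    data = simulate_inactivation(0.28, 0.27, [20, 50, 100, 200, 500, 2000], list(TIMES))
    fits = [fit_pseudo_first_order(s) for s in data]
    ks = [f.k_prime for f in fits]
    assert ks == sorted(ks)
    assert all(k < 0.27 for k in ks)
    # saturation limit and half-saturation point
    (sat,) = simulate_inactivation(0.28, 0.27, [1e7], list(TIMES))
    assert fit_pseudo_first_order(sat).k_prime == pytest.approx(0.27, rel=1e-4)
    (half,) = simulate_inactivation(0.28, 0.27, [280.0], list(TIMES))
    assert fit_pseudo_first_order(half).k_prime == pytest.approx(0.135, rel=1e-9)


def test_noisy_monte_carlo_median_bias_below_ten_percent():
    """5% multiplicative noise, 200 replicates: the double-reciprocal Ki
    estimate has median bias under 10%."""
    estimates = []
    for seed in range(200):
        data = simulate_inactivation(
            0.28, 0.27, [50, 100, 150, 200, 260], list(range(0, 21, 2)),
            noise_sd=0.05, seed=seed,
        )
        estimates.append(analyze_inactivation(data).Ki_mM)
    median = float(np.median(estimates))
    assert abs(median - 0.28) / 0.28 < 0.10


def test_nonlinear_cross_check_agrees_with_reciprocal_fit():
    data = simulate_inactivation(0.28, 0.27, [50, 100, 150, 200, 260], list(TIMES))
    fits = [fit_pseudo_first_order(s) for s in data]
    lin = fit_kitz_wilson(fits)
    Ki_nl, k2_nl = fit_saturation_nonlinear([(f.conc_uM, f.k_prime) for f in fits])
    assert Ki_nl == pytest.approx(lin.Ki_mM, rel=1e-6)
    assert k2_nl == pytest.approx(lin.k2_per_min, rel=1e-6)


def test_csv_round_trip(tmp_path):
    import pandas as pd

    data = simulate_inactivation(0.28, 0.27, [50, 100, 150], [0, 5, 10], noise_sd=0.02, seed=4)
    rows = [
        {"conc_uM": s.conc_uM, "time_min": t, "activity_frac": a}
        for s in data for t, a in zip(s.times_min, s.activity)
    ]
    path = tmp_path / "inact.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    back = read_series_csv(path)
    assert [s.conc_uM for s in back] == [50, 100, 150]
    assert np.allclose(back[0].activity, data[0].activity)
    bad = tmp_path / "bad.csv"
    bad.write_text("x,y\n1,2\n")
    with pytest.raises(KineticsError, match="missing columns"):
        read_series_csv(bad)
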