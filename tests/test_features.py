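"""Identifier-variable extraction against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst

from felacc.features import (
    FEATURE_NAMES,
    axis_correlations,
    axis_stats,
    extract_features,
    moving_average,
    odba,
    vector_magnitude,
)

# ---------------------------------------------------------------------------
# independent slow-path oracle


def oracle_moving_average(x, window=30):
    half_lo = window // 2 - 1
    out = np.empty(len(x))
    for i in range(len(x)):
        lo = max(0, i - half_lo)
        hi = min(len(x), i + (window - half_lo - 1) + 1)
        out[i] = sum(x[lo:hi]) / (hi - lo)
    return out


def oracle_odba(samples, epoch_len=30, mode="absolute"):
    samples = np.asarray(samples, dtype=float)
    res = np.column_stack(
        [samples[:, k] - oracle_moving_average(samples[:, k], epoch_len)
         for k in range(3)])
    n_epochs = len(samples) // epoch_len
    out = []
    for e in range(n_epochs):
        block = res[e * epoch_len:(e + 1) * epoch_len]
        if mode == "absolute":
            out.append(np.abs(block).sum())
        else:
            out.append(block.sum())
    return np.array(out)


def oracle_epoch_features(window):
    """Direct per-epoch statistics (no shared code with the fast path)."""
    vals = {}
    for k, ax in enumerate("xyz"):
        w = window[:, k]
        n = len(w)
        m = sum(w) / n
        var_pop = sum((v - m) ** 2 for v in w) / n
        sd = np.sqrt(sum((v - m) ** 2 for v in w) / (n - 1))
        if var_pop == 0:
            skew = kurt = 0.0
        else:
            skew = (sum((v - m) ** 3 for v in w) / n) / var_pop ** 1.5
            kurt = (sum((v - m) ** 4 for v in w) / n) / var_pop ** 2
        vals.update({f"mean_{ax}": m, f"sum_{ax}": sum(w), f"min_{ax}": min(w),
                     f"max_{ax}": max(w), f"sd_{ax}": sd, f"skew_{ax}": skew,
                     f"kurt_{ax}": kurt})
    for (a, b), name in zip(((0, 1), (0, 2), (1, 2)),
                            ("corr_xy", "corr_xz", "corr_yz")):
        wa, wb = window[:, a], window[:, b]
        if wa.std() == 0 or wb.std() == 0:
            vals[name] = 0.0
        else:
            vals[name] = float(np.corrcoef(wa, wb)[0, 1])
    vm = [np.sqrt(x * x + y * y + z * z) for x, y, z in window]
    n = len(vm)
    m = sum(vm) / n
    var_pop = sum((v - m) ** 2 for v in vm) / n
    vals.update({
        "vm_mean": m, "vm_sum": sum(vm), "vm_min": min(vm), "vm_max": max(vm),
        "vm_sd": np.sqrt(sum((v - m) ** 2 for v in vm) / (n - 1)),
        "vm_skew": 0.0 if var_pop == 0
        else (sum((v - m) ** 3 for v in vm) / n) / var_pop ** 1.5,
        "vm_kurt": 0.0 if var_pop == 0
        else (sum((v - m) ** 4 for v in vm) / n) / var_pop ** 2,
    })
    return vals


# ---------------------------------------------------------------------------


def test_schema_has_32_stable_fields():
    assert len(FEATURE_NAMES) == 32
    assert len(set(FEATURE_NAMES)) == 32
    trace = np.random.default_rng(0).normal(size=(90, 3))
    df = extract_features(trace)
    assert list(df.columns) == list(FEATURE_NAMES)
    assert len(df) == 3


def test_constant_window_stats_are_degenerate():
    s = axis_stats(np.full(30, 2.5))
    assert s.mean == 2.5 and s.sum == 75.0
    assert s.min == s.max == 2.5
    assert s.sd == 0.0 and s.skew == 0.0 and s.kurt == 0.0
    assert s.degenerate


def test_alternating_window_hand_computed():
    w = np.tile([-1.0, 1.0], 15)
    s = axis_stats(w)
    assert s.mean == pytest.approx(0.0)
    # sample sd of +/-1 values: sqrt(30/29); population kurtosis of a
    # two-point symmetric distribution is 1
    assert s.sd == pytest.approx(np.sqrt(30 / 29))
    assert s.skew == pytest.approx(0.0)
    assert s.kurt == pytest.approx(1.0)
    assert not s.degenerate


def test_correlations_affine_and_independent():
    rng = np.random.default_rng(42)
    x = rng.normal(size=30)
    r = axis_correlations(x, 2 * x + 1, -x)
    assert r[0] == pytest.approx(1.0)
    assert r[1] == pytest.approx(-1.0)
    # zero-variance axis pairs are flagged 0
    assert axis_correlations(x, np.zeros(30), x)[0] == 0.0
    # independent noise: mean correlation vanishes (simulation oracle)
    rs = [axis_correlations(rng.normal(size=30), rng.normal(size=30),
                            rng.normal(size=30))[0] for _ in range(10_000)]
    assert abs(np.mean(rs)) < 3 / np.sqrt(29 * 10_000)


def test_vector_magnitude_examples():
    vm = vector_magnitude(np.array([[3.0, 4.0, 0.0], [0.0, 0.0, 0.0]]))
    assert vm[0] == pytest.approx(5.0)
    assert vm[1] == 0.0


def test_static_gravity_epoch():
    trace = np.tile([0.0, 1.0, 0.0], (60, 1))
    df = extract_features(trace)
    assert np.allclose(df["vm_mean"], 1.0)
    assert np.allclose(df[["sd_x", "sd_y", "sd_z", "vm_sd"]], 0.0)
    assert np.allclose(df["odba"], 0.0)


@pytest.mark.parametrize("mode", ["absolute", "as_printed"])
def test_odba_matches_brute_force(mode):
    rng = np.random.default_rng(7)
    trace = rng.normal(0, 0.5, size=(150, 3))  # 5 epochs
    fast = odba(trace, mode=mode)
    slow = oracle_odba(trace, mode=mode)
    np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)
    if mode == "absolute":
        assert (fast >= 0).all()


def test_odba_offset_invariant_away_from_edges():
    rng = np.random.default_rng(8)
    trace = rng.normal(size=(300, 3))
    shifted = trace + np.array([1.5, -2.0, 0.25])
    a = odba(trace)
    b = odba(shifted)
    # the centred moving average removes constants except near the edges
    np.testing.assert_allclose(a[1:-1], b[1:-1], rtol=1e-9)


def test_moving_average_matches_oracle():
    rng = np.random.default_rng(9)
    x = rng.normal(size=97)
    np.testing.assert_allclose(moving_average(x), oracle_moving_average(x),
                               rtol=1e-12)


def test_extract_matches_epoch_oracle():
    rng = np.random.default_rng(10)
    trace = rng.normal(0, 1, size=(150, 3))
    df = extract_features(trace)
    for e in range(5):
        expected = oracle_epoch_features(trace[e * 30:(e + 1) * 30])
        for name, val in expected.items():
            assert df.loc[e, name] == pytest.approx(val, rel=1e-9), name


def test_axis_permutation_symmetry():
    rng = np.random.default_rng(11)
    trace = rng.normal(size=(90, 3))
    base = extract_features(trace)
    swapped = extract_features(trace[:, [1, 0, 2]])
    pd.testing.assert_series_equal(base["mean_x"], swapped["mean_y"],
                                   check_names=False)
    pd.testing.assert_series_equal(base["sd_y"], swapped["sd_x"],
                                   check_names=False)
    np.testing.assert_allclose(base["corr_xy"], swapped["corr_xy"])
    np.testing.assert_allclose(base["vm_mean"], swapped["vm_mean"])
    np.testing.assert_allclose(base["odba"], swapped["odba"])


def test_short_trace_yields_empty_frame():
    df = extract_features(np.zeros((29, 3)))
    assert df.empty and list(df.columns) == list(FEATURE_NAMES)


def test_trailing_partial_epoch_dropped():
    df = extract_features(np.zeros((75, 3)))
    assert len(df) == 2


@settings(derandomize=True, max_examples=40, deadline=None)
@given(npst.arrays(np.float64, (60, 3),
                   elements=st.floats(-8, 8, allow_nan=False)))
def test_epoch_invariants(trace):
    df, flags = extract_features(trace, return_flags=True)
    for ax in "xyz":
        assert (df[f"min_{ax}"] <= df[f"mean_{ax}"] + 1e-12).all()
        assert (df[f"mean_{ax}"] <= df[f"max_{ax}"] + 1e-12).all()
        np.testing.assert_allclose(df[f"sum_{ax}"], 30 * df[f"mean_{ax}"],
                                   rtol=1e-9, atol=1e-9)
        assert (df[f"sd_{ax}"] >= 0).all()
    assert (df["vm_min"] >= 0).all()
    assert (df["odba"] >= 0).all()
    assert df[["corr_xy", "corr_xz", "corr_yz"]].abs().le(1 + 1e-12).all().all()
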