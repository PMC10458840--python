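"""Per-epoch identifier variables from raw triaxial acceleration.

Raw 30 Hz traces are summarized into 1 s epochs. For each epoch 32
identifier variables are derived:

* per axis (X, Y, Z): mean, sum, min, max, sd, skewness, kurtosis (21),
* pairwise Pearson correlations r_XY, r_XZ, r_YZ (3),
* vector-magnitude (VM) statistics: mean, sum, min, max, sd, skewness,
  kurtosis (7),
* overall dynamic body acceleration (ODBA) (1).

VM is the per-sample Euclidean norm sqrt(x^2 + y^2 + z^2). ODBA is built
from per-axis dynamic residuals: each axis is smoothed with a centred
1 s (30-sample) moving average, truncated at the trace edges, and the
residual is the sample minus the smoothed value. The default ("absolute")
ODBA for an epoch is the sum over the epoch's samples of
|res_X| + |res_Y| + |res_Z|; an alternative "as_printed" mode sums the
signed residuals per axis over the epoch and adds the three axis sums
without absolute values.

Conventions (configurable where noted): sd is the sample standard
deviation (ddof=1); skewness and kurtosis are population moment
estimators (biased, kurtosis non-excess, so a normal distribution has
kurtosis 3). Statistics that are undefined on a zero-variance window
(skewness, kurtosis, correlations) are encoded as 0.0 and the epoch is
flagged degenerate, so downstream classifiers never see missing values.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

AXES = ("x", "y", "z")
_AXIS_STATS = ("mean", "sum", "min", "max", "sd", "skew", "kurt")

#: Fixed 32-column schema, in stable order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{ax}" for stat in _AXIS_STATS for ax in AXES
) + ("corr_xy", "corr_xz", "corr_yz") + tuple(
    f"vm_{stat}" for stat in _AXIS_STATS
) + ("odba",)

assert len(FEATURE_NAMES) == 32


class AxisStats(NamedTuple):
    mean: float
    sum: float
    min: float
    max: float
    sd: float
    skew: float
    kurt: float
    degenerate: bool


def axis_stats(window: np.ndarray, ddof: int = 1) -> AxisStats:
    """Moment statistics of a single-axis epoch window.

    ``window`` must hold exactly one epoch of samples (30 at 30 Hz).
    On a constant window the sd is 0 and skewness/kurtosis are undefined;
    both are reported as 0.0 with ``degenerate=True``.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError(f"expected a 1-D epoch window, got shape {w.shape}")
    sd = float(w.std(ddof=ddof))
    degenerate = sd == 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        skew = float(_sps.skew(w, bias=True))
        kurt = float(_sps.kurtosis(w, fisher=False, bias=True))
    return AxisStats(
        float(w.mean()), float(w.sum()), float(w.min()), float(w.max()),
        sd, skew, kurt, degenerate,
    )


def axis_correlations(
    wx: np.ndarray, wy: np.ndarray, wz: np.ndarray
) -> tuple[float, float, float]:
    """Pearson correlations (r_XY, r_XZ, r_YZ) for one epoch.

    A pair involving a zero-variance axis has undefined correlation and is
    reported as 0.0.
    """
    ws = [np.asarray(w, dtype=float) for w in (wx, wy, wz)]
    n = ws[0].size
    if any(w.size != n for w in ws):
        raise ValueError("axis windows must have equal length")
    out = []
    for a, b in ((0, 1), (0, 2), (1, 2)):
        sa, sb = ws[a].std(), ws[b].std()
        if sa == 0.0 or sb == 0.0:
            out.append(0.0)
        else:
            out.append(float(np.corrcoef(ws[a], ws[b])[0, 1]))
    return tuple(out)  # type: ignore[return-value]


def vector_magnitude(samples: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of an (n, 3) sample array."""
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValueError(f"expected (n, 3) samples, got shape {s.shape}")
    return np.sqrt((s * s).sum(axis=1))


def moving_average(x: np.ndarray, window: int = 30) -> np.ndarray:
    """Centred moving average, truncated at the edges.

    ``smoothed[i]`` averages ``x[max(0, i - (window // 2 - 1)) :
    i + window // 2 + 1]`` (a 30-sample window covers offsets −14 … +15),
    using only the samples that exist near the trace edges.
    """
    x = np.asarray(x, dtype=float)
    half_lo = window // 2 - 1
    half_hi = window - half_lo - 1
    n = x.size
    if n == 0:
        return x.copy()
    # anchor on the first sample so constant traces cancel exactly
    x0 = x.flat[0]
    csum = np.concatenate(([0.0], np.cumsum(x - x0)))
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return x0 + (csum[hi] - csum[lo]) / (hi - lo)


def dynamic_residuals(samples: np.ndarray, window: int = 30) -> np.ndarray:
    """Per-axis dynamic component: sample minus centred moving average."""
    s = np.asarray(samples, dtype=float)
    return s - np.column_stack([moving_average(s[:, k], window) for k in range(3)])


def odba(
    samples: np.ndarray,
    epoch_len: int = 30,
    mode: str = "absolute",
) -> np.ndarray:
    """Per-epoch overall dynamic body acceleration.

    ``mode="absolute"`` (default) sums absolute per-sample residuals across
    axes and over the epoch; ``mode="as_printed"`` sums the signed residuals
    per axis over the epoch and adds the three axis totals. Trailing samples
    short of a full epoch are ignored.
    """
    if mode not in ("absolute", "as_printed"):
        raise ValueError(f"unknown ODBA mode {mode!r}")
    res = dynamic_residuals(samples, window=epoch_len)
    n_epochs = res.shape[0] // epoch_len
    res = res[: n_epochs * epoch_len].reshape(n_epochs, epoch_len, 3)
    if mode == "absolute":
        return np.abs(res).sum(axis=(1, 2))
    return res.sum(axis=(1, 2))


def extract_features(
    samples: np.ndarray,
    sampling_rate: int = 30,
    ddof: int = 1,
    dba_mode: str = "absolute",
    return_flags: bool = False,
):
    """Derive the 32 identifier variables for every complete 1 s epoch.

    Parameters
    ----------
    samples : (n, 3) array of axis values in g.
    sampling_rate : samples per epoch (default 30).
    ddof : delta degrees of freedom for the sd (default 1, sample sd).
    dba_mode : ODBA construction, ``"absolute"`` or ``"as_printed"``.
    return_flags : also return a boolean per-epoch degenerate flag
        (any zero-variance axis or VM in the epoch).

    Returns
    -------
    DataFrame with exactly the 32 :data:`FEATURE_NAMES` columns, one row
    per complete epoch (empty if the trace is shorter than one epoch);
    optionally the flag Series.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValueError(f"expected (n, 3) samples, got shape {s.shape}")
    L = int(sampling_rate)
    n_epochs = s.shape[0] // L
    if n_epochs == 0:
        empty = pd.DataFrame(columns=list(FEATURE_NAMES), dtype=float)
        return (empty, pd.Series(dtype=bool)) if return_flags else empty

    odba_vals = odba(s, epoch_len=L, mode=dba_mode)

    w = s[: n_epochs * L].reshape(n_epochs, L, 3)
    vm = np.sqrt((w * w).sum(axis=2))  # (n_epochs, L)

    cols: dict[str, np.ndarray] = {}

    def _moments(block: np.ndarray, prefix: str) -> np.ndarray:
        # block: (n_epochs, L); returns per-epoch zero-variance mask
        sd = block.std(axis=1, ddof=ddof)
        zero = block.std(axis=1) == 0.0
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # near-constant windows trip scipy's precision warning; those
            # epochs are flagged degenerate and zeroed below anyway
            warnings.simplefilter("ignore", RuntimeWarning)
            sk = _sps.skew(block, axis=1, bias=True)
            ku = _sps.kurtosis(block, axis=1, fisher=False, bias=True)
        sk = np.where(zero, 0.0, sk)
        ku = np.where(zero, 0.0, ku)
        cols[f"mean{prefix}"] = block.mean(axis=1)
        cols[f"sum{prefix}"] = block.sum(axis=1)
        cols[f"min{prefix}"] = block.min(axis=1)
        cols[f"max{prefix}"] = block.max(axis=1)
        cols[f"sd{prefix}"] = sd
        cols[f"skew{prefix}"] = sk
        cols[f"kurt{prefix}"] = ku
        return zero

    zero_masks = []
    for k, ax in enumerate(AXES):
        zero_masks.append(_moments(w[:, :, k], f"_{ax}"))
    zero_x, zero_y, zero_z = zero_masks

    centred = w - w.mean(axis=1, keepdims=True)
    sds = w.std(axis=1)  # population sd per axis, (n_epochs, 3)
    for (a, b), name in zip(((0, 1), (0, 2), (1, 2)),
                            ("corr_xy", "corr_xz", "corr_yz")):
        cov = (centred[:, :, a] * centred[:, :, b]).mean(axis=1)
        denom = sds[:, a] * sds[:, b]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / denom
        cols[name] = np.where(denom == 0.0, 0.0, r)

    zero_vm = _moments(vm, "_vm")
    # reorder vm_* keys to the schema's vm_<stat> spelling
    for stat in _AXIS_STATS:
        cols[f"vm_{stat}"] = cols.pop(f"{stat}_vm")
    cols["odba"] = odba_vals

    df = pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})
    if return_flags:
        flags = pd.Series(zero_x | zero_y | zero_z | zero_vm, name="degenerate")
        return df, flags
    return df
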