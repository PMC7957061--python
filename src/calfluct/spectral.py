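"""Spectral and statistical readouts of the Ca2+ traces.

The headline quantity is the 100-500 Hz band power of the intracellular
Ca2+ concentration signal over the 12-21 ms analysis window, in dB.
With only 9 ms of stationary signal, Welch averaging cannot resolve
100 Hz, so the estimator is a single-segment rectangular-window
periodogram (one-sided density normalisation, frequency resolution
~111 Hz); band power is the integrated density over bins whose center
frequency falls in the band, expressed as 10 log10 relative to
1 (trace unit)^2.  Absolute dB values therefore carry an arbitrary
reference offset; comparisons should use differences and trends.

Also provided: ordinary least-squares regression of band power against
the astrocytic surface/volume ratio (SVR), classical one-way ANOVA
across conditions, and SVR-binned summaries (mean +- SEM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "BandPowerResult",
    "RegressionResult",
    "band_power_db",
    "power_vs_svr_regression",
    "one_way_anova",
    "group_powers_by_svr",
]


@dataclass
class BandPowerResult:
    power_db: float  # -inf for a constant (zero-variance) segment
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]
    sampling_rate_hz: float
    freq_resolution_hz: float
    n_bins: int

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.power_db)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared={self.r_squared} outside [0, 1]")
        if self.n < 3:
            raise ValueError("regression requires n >= 3")


def band_power_db(
    trace: np.ndarray,
    sampling_rate_hz: float,
    band_hz: tuple[float, float] = (100.0, 500.0),
    window_ms: tuple[float, float] | None = (12.0, 21.0),
    time_ms: np.ndarray | None = None,
) -> BandPowerResult:
    """Band power (dB) of a trace segment via a single periodogram.

    ``window_ms`` selects the analysis segment; supply ``time_ms`` for
    the trace's own time axis (else it is inferred from the sampling
    rate starting at 0).  The segment is mean-subtracted; the summed
    one-sided density times the bin width equals the band variance
    (Parseval).  A constant segment yields ``power_db = -inf`` and is
    flagged missing.
    """
    trace = np.asarray(trace, dtype=float)
    if band_hz[1] > sampling_rate_hz / 2.0:
        raise ValueError(
            f"band {band_hz} extends above Nyquist ({sampling_rate_hz / 2} Hz)"
        )
    if window_ms is not None:
        if time_ms is None:
            time_ms = np.arange(len(trace)) / sampling_rate_hz * 1e3
        sel = (time_ms >= window_ms[0]) & (time_ms < window_ms[1])
        if not sel.any() or time_ms[-1] < window_ms[1] - 1e-9:
            raise ValueError(f"window {window_ms} ms outside trace extent")
        seg = trace[sel]
    else:
        seg = trace
        window_ms = (0.0, len(trace) / sampling_rate_hz * 1e3)
    freqs, pxx = signal.periodogram(
        seg, fs=sampling_rate_hz, window="boxcar", detrend="constant",
        scaling="density",
    )
    df = freqs[1] - freqs[0]
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    band_var = float((pxx[in_band]).sum() * df)
    power_db = 10.0 * np.log10(band_var) if band_var > 0 else -np.inf
    return BandPowerResult(
        power_db=power_db,
        band_hz=tuple(band_hz),
        window_ms=tuple(window_ms),
        sampling_rate_hz=sampling_rate_hz,
        freq_resolution_hz=float(df),
        n_bins=int(in_band.sum()),
    )


def power_vs_svr_regression(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of band power (dB) on SVR (1/µm); non-finite powers dropped."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (svr, power_db) pairs")
    finite = np.isfinite(arr).all(axis=1)
    arr = arr[finite]
    if len(arr) < 3:
        raise ValueError("regression requires at least 3 finite points")
    if np.ptp(arr[:, 0]) == 0:
        raise ValueError("degenerate design: all SVR values equal")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=len(arr),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within and its
    p-value from the F distribution."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def group_powers_by_svr(
    svr: Sequence[float],
    power_db: Sequence[float],
    bin_edges: Sequence[float],
):
    """Mean +- SEM of band power within SVR bins (pandas DataFrame).

    Empty bins are reported with NaN mean/SEM and count 0.
    """
    import pandas as pd

    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    svr = np.asarray(svr, dtype=float)
    power = np.asarray(power_db, dtype=float)
    which = np.digitize(svr, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        vals = power[(which == b) & np.isfinite(power)]
        n = len(vals)
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": n,
                "mean_db": vals.mean() if n else np.nan,
                "sem_db": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
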