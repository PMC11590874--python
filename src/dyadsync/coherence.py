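"""Wavelet-transform coherence (WTC) and the inter-brain synchrony index.

The localized association between two partners' neural signals is the
magnitude-squared wavelet coherence

    R^2(s, t) = |S(s^-1 W_xy)|^2 / ( S(s^-1 |W_x|^2) * S(s^-1 |W_y|^2) )

where W_x is the continuous Morlet wavelet transform (center frequency
``omega0``, Fourier period ``4 pi s / (omega0 + sqrt(2 + omega0^2))``),
W_xy = W_x conj(W_y) the cross-wavelet spectrum, and S a smoothing
operator — Gaussian in time with standard deviation s / sqrt(2)
(matched to the squared envelope of the Morlet atom) followed by a
boxcar over scale spanning the 0.6-scale decorrelation length.  Both
kernels are positive, so R^2 lies in [0, 1] by Cauchy-Schwarz.  Edge
effects matter beyond the e-folding time sqrt(2) s: the cone of
influence (COI) marks, per time point, the longest trustworthy period.

Genuine dyads conversed; surrogate "permuted" dyads pair participants
from different real dyads and form the empirical null.  Per Fourier
period, the time-averaged coherence of the genuine group is compared to
the permuted group with Welch's t-test; Benjamini-Hochberg FDR
adjustment across periods yields q-values, and maximal contiguous runs
of periods with q below alpha where the genuine mean is the larger are
the periods of interest (POIs).  The scalar IBS index for a dyad is its
time-averaged coherence averaged over the POI periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len
from scipy.ndimage import uniform_filter1d
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WaveletParams",
    "CoherenceResult",
    "ScaleComparisonTable",
    "POI",
    "IBSIndex",
    "fourier_factor",
    "cwt_morlet",
    "wtc",
    "time_avg_coherence",
    "build_permutated_dyads",
    "compare_scales",
    "identify_poi",
    "ibs_index",
]


@dataclass(frozen=True)
class WaveletParams:
    """Morlet CWT configuration.

    ``omega0`` is the dimensionless center frequency (>= 5 for practical
    admissibility), ``scales_per_octave`` the voices per octave of the
    logarithmic period grid, and ``period_range_s`` the requested range
    of Fourier periods in seconds.
    """

    omega0: float = 6.0
    scales_per_octave: int = 12
    period_range_s: tuple = (4.0, 64.0)

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError(f"omega0 must be >= 5 for admissibility, got {self.omega0}")
        if self.scales_per_octave < 4:
            raise ValueError(f"scales_per_octave must be >= 4, got {self.scales_per_octave}")
        lo, hi = self.period_range_s
        if not 0 < lo < hi:
            raise ValueError(f"invalid period range {self.period_range_s}")

    def periods(self, n_samples: int, fs: float) -> np.ndarray:
        """Log-spaced Fourier-period grid, trimmed to fit the record.

        Periods longer than half the record (fewer than two wavelengths
        observed) are dropped with a warning.
        """
        lo, hi = self.period_range_s
        dj = 1.0 / self.scales_per_octave
        n_voices = int(np.floor(np.log2(hi / lo) / dj)) + 1
        grid = lo * 2.0 ** (dj * np.arange(n_voices))
        max_period = n_samples / fs / 2.0
        if grid[-1] > max_period:
            kept = grid[grid <= max_period]
            if len(kept) == 0:
                raise ValueError(
                    f"record of {n_samples / fs:.1f} s too short for any period >= {lo} s"
                )
            warnings.warn(
                f"periods above {max_period:.1f} s exceed half the record; grid trimmed "
                f"from {len(grid)} to {len(kept)} periods"
            )
            grid = kept
        return grid


def fourier_factor(omega0: float) -> float:
    """Ratio of Fourier period to Morlet scale: 4 pi / (omega0 + sqrt(2 + omega0^2))."""
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


@dataclass(frozen=True)
class CoherenceResult:
    """Time x period coherence matrix with its grids and cone of influence.

    ``coherence[i, j]`` is R^2 at period ``periods_s[i]`` and time
    ``times_s[j]``; ``coi_s[j]`` is the longest period free of edge
    effects at time j.
    """

    coherence: np.ndarray
    periods_s: np.ndarray
    times_s: np.ndarray
    coi_s: np.ndarray

    def coi_mask(self) -> np.ndarray:
        """Boolean [period x time] mask, True where inside the COI (valid)."""
        return self.periods_s[:, None] <= self.coi_s[None, :]


@dataclass(frozen=True)
class POI:
    """A contiguous run of significant periods (period of interest)."""

    period_lo_s: float
    period_hi_s: float
    member_periods: np.ndarray

    @property
    def band_hz(self) -> tuple:
        return (1.0 / self.period_hi_s, 1.0 / self.period_lo_s)


@dataclass(frozen=True)
class IBSIndex:
    """Scalar inter-brain synchrony: mean coherence over the POI periods."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-9:
            raise ValueError(f"IBS index {self.value} outside [0, 1]")


def _morlet_cwt(x: np.ndarray, fs: float, scales_s: np.ndarray, omega0: float) -> np.ndarray:
    """FFT-based continuous Morlet transform; rows are scales."""
    n = len(x)
    nfft = next_fast_len(2 * n)  # zero-pad against wraparound
    xf = fft(x, nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    # Analytic Morlet daughter in frequency, positive frequencies only,
    # normalized so each scale has unit total energy for white input.
    arg = scales_s[:, None] * omega[None, :]
    daughter = (np.pi**-0.25) * np.exp(-0.5 * (arg - omega0) ** 2) * (omega[None, :] > 0)
    daughter *= np.sqrt(2.0 * np.pi * scales_s[:, None] * fs)
    W = ifft(xf[None, :] * daughter, axis=1)[:, :n]
    return W


def cwt_morlet(
    values: np.ndarray,
    fs: float,
    params: WaveletParams = WaveletParams(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous Morlet wavelet transform on a log period grid.

    Parameters
    ----------
    values : 1-D real series (a cleaned neural signal's samples).
    fs : sampling rate in Hz.
    params : wavelet configuration.

    Returns
    -------
    (W, periods_s, coi_s)
        ``W`` complex [period x time]; ``periods_s`` the Fourier periods
        in seconds; ``coi_s`` the per-time-point COI boundary in seconds
        (e-folding time sqrt(2) s of the wavelet envelope).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    periods = params.periods(len(x), fs)
    ff = fourier_factor(params.omega0)
    scales_s = periods / ff
    W = _morlet_cwt(x, fs, scales_s, params.omega0)
    t = np.arange(len(x)) / fs
    dist = np.minimum(t, t[-1] - t)
    coi_s = dist * ff / np.sqrt(2.0)
    return W, periods, coi_s


def _smooth(
    field: np.ndarray, fs: float, scales_s: np.ndarray, scales_per_octave: int
) -> np.ndarray:
    """WTC smoothing operator: Gaussian in time (std s/sqrt(2)), boxcar in scale."""
    n_scales, n = field.shape
    sig_samples = scales_s * fs / np.sqrt(2.0)
    nfft = next_fast_len(int(n + 5 * sig_samples.max()))
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft)
    gauss = np.exp(-0.5 * (sig_samples[:, None] * omega[None, :]) ** 2)
    sm = ifft(fft(field, nfft, axis=1) * gauss, axis=1)[:, :n]
    if np.isrealobj(field):
        sm = sm.real
    # boxcar over scale: window covers the 0.6-scale decorrelation length,
    # truncated and renormalized at the grid edges
    width = max(1, int(round(0.6 * scales_per_octave)))
    if width > 1 and n_scales > 1:
        counts = uniform_filter1d(
            np.ones(n_scales), size=width, mode="constant", cval=0.0
        )
        if np.iscomplexobj(sm):
            sm = uniform_filter1d(sm.real, size=width, axis=0, mode="constant", cval=0.0) + (
                1j * uniform_filter1d(sm.imag, size=width, axis=0, mode="constant", cval=0.0)
            )
        else:
            sm = uniform_filter1d(sm, size=width, axis=0, mode="constant", cval=0.0)
        sm = sm / counts[:, None]
    return sm


def wtc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    params: WaveletParams = WaveletParams(),
) -> CoherenceResult:
    """Magnitude-squared wavelet coherence between two equally sampled signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"signals must be aligned: lengths {len(x)} vs {len(y)}")
    Wx, periods, coi_s = cwt_morlet(x, fs, params)
    Wy, _, _ = cwt_morlet(y, fs, params)
    scales_s = periods / fourier_factor(params.omega0)
    inv_s = 1.0 / scales_s[:, None]
    spo = params.scales_per_octave
    s_xx = _smooth(np.abs(Wx) ** 2 * inv_s, fs, scales_s, spo)
    s_yy = _smooth(np.abs(Wy) ** 2 * inv_s, fs, scales_s, spo)
    s_xy = _smooth(Wx * np.conj(Wy) * inv_s, fs, scales_s, spo)
    denom = s_xx * s_yy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(s_xy) ** 2 / denom, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    times = np.arange(len(x)) / fs
    return CoherenceResult(coherence=coh, periods_s=periods, times_s=times, coi_s=coi_s)


def smoothed_cross_spectra(
    signals: "dict[object, np.ndarray]",
    pairs: "list[tuple]",
    fs: float,
    params: WaveletParams = WaveletParams(),
    decimate: int = 1,
) -> "dict[tuple, CoherenceResult]":
    """Coherence for many pairs, caching per-signal transforms.

    Genuine and permuted pairings reuse the same participants, so the
    per-participant CWT and smoothed auto-spectra are computed once.

    ``decimate`` keeps every n-th time column of the wavelet fields
    before smoothing.  The carrier frequency cancels in the cross and
    auto products, leaving envelope-scale content (bandwidth well below
    the carrier), so modest decimation relative to the shortest
    analyzed period is alias-free; the returned time grid is the
    decimated one.
    """
    keys = list(signals)
    lengths = {len(signals[k]) for k in keys}
    if len(lengths) != 1:
        raise ValueError(f"all signals must share a length, got {sorted(lengths)}")
    first = np.asarray(signals[keys[0]], dtype=float)
    periods = params.periods(len(first), fs)
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    if decimate > 1 and decimate > periods[0] * fs / 8:
        raise ValueError(
            f"decimate={decimate} too coarse for the shortest period {periods[0]:.2f} s"
        )
    scales_s = periods / fourier_factor(params.omega0)
    inv_s = 1.0 / scales_s[:, None]
    spo = params.scales_per_octave
    fs_dec = fs / decimate
    cwts: dict = {}
    autos: dict = {}
    coi_s = None
    for k in keys:
        W, _, coi_full = cwt_morlet(np.asarray(signals[k], dtype=float), fs, params)
        W = W[:, ::decimate]
        if coi_s is None:
            coi_s = coi_full[::decimate]
        cwts[k] = W
        autos[k] = _smooth(np.abs(W) ** 2 * inv_s, fs_dec, scales_s, spo)
    times = np.arange(len(first))[::decimate] / fs
    out: dict = {}
    for a, b in pairs:
        s_xy = _smooth(cwts[a] * np.conj(cwts[b]) * inv_s, fs_dec, scales_s, spo)
        denom = autos[a] * autos[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            coh = np.where(denom > 0, np.abs(s_xy) ** 2 / denom, 0.0)
        out[(a, b)] = CoherenceResult(
            coherence=np.clip(coh, 0.0, 1.0), periods_s=periods, times_s=times, coi_s=coi_s
        )
    return out


def time_avg_coherence(
    res: CoherenceResult,
    window_s: "tuple | None" = None,
    exclude_coi: bool = True,
) -> np.ndarray:
    """Per-period mean coherence over a time window.

    ``window_s = (start, end)`` restricts to that interval (default: the
    full record).  With ``exclude_coi`` (default), cells whose period
    exceeds the local COI boundary are left out of the mean; a period
    with no valid cell yields NaN.
    """
    if window_s is None:
        in_window = np.ones(len(res.times_s), dtype=bool)
    else:
        start, end = window_s
        record_end = res.times_s[-1] + (res.times_s[1] - res.times_s[0])
        if not (res.times_s[0] <= start < end <= record_end + 1e-9):
            raise ValueError(
                f"window {window_s} outside record [0, {record_end:.1f}] s or empty"
            )
        in_window = (res.times_s >= start) & (res.times_s <= end)
    if not in_window.any():
        raise ValueError(f"window {window_s} contains no samples")
    mask = np.broadcast_to(in_window[None, :], res.coherence.shape).copy()
    if exclude_coi:
        mask &= res.coi_mask()
    counts = mask.sum(axis=1)
    sums = np.where(mask, res.coherence, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def build_permutated_dyads(
    participants: "list[tuple]",
    n_perm: int,
    seed: "int | np.random.Generator",
) -> "list[tuple]":
    """Sample surrogate pairs of participants from *different* dyads.

    ``participants`` is a list of ``(participant_id, dyad_id)``.  All
    unordered cross-dyad pairs are enumerated and ``n_perm`` of them are
    drawn without replacement, deterministically for a given seed.
    """
    if len({d for _, d in participants}) < 2:
        raise ValueError("need participants from at least 2 dyads to permute")
    admissible = [
        (participants[i][0], participants[j][0])
        for i in range(len(participants))
        for j in range(i + 1, len(participants))
        if participants[i][1] != participants[j][1]
    ]
    if n_perm > len(admissible):
        raise ValueError(
            f"requested {n_perm} permuted pairs but only {len(admissible)} admissible"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(admissible), size=n_perm, replace=False)
    return [admissible[i] for i in idx]


@dataclass(frozen=True)
class ScaleComparisonTable:
    """Per-period genuine-vs-permuted test results.

    ``table`` columns: period_s, mean_genuine, mean_permutated, t, df,
    p, q, cohens_d, degenerate.  Degenerate rows (no variance in either
    group) carry NaN statistics and are outside the FDR family.
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _welch(g: np.ndarray, p: np.ndarray) -> tuple[float, float, float, float]:
    n1, n2 = len(g), len(p)
    v1, v2 = g.var(ddof=1), p.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (g.mean() - p.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    pval = 2.0 * stats.t.sf(abs(t), df)
    pooled_sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (g.mean() - p.mean()) / pooled_sd
    return float(t), float(df), float(pval), float(d)


def compare_scales(
    genuine: np.ndarray,
    permutated: np.ndarray,
    periods_s: np.ndarray,
    alpha: float = 0.05,
) -> ScaleComparisonTable:
    """Welch's t-test per period with Benjamini-Hochberg FDR adjustment.

    ``genuine`` and ``permutated`` are [n_pairs x n_periods] matrices of
    time-averaged coherence.  Welch's unequal-variance statistic with
    Welch-Satterthwaite fractional degrees of freedom is used per
    period; two-sided p-values are BH-adjusted across all non-degenerate
    periods; Cohen's d uses the pooled standard deviation.
    """
    genuine = np.atleast_2d(np.asarray(genuine, dtype=float))
    permutated = np.atleast_2d(np.asarray(permutated, dtype=float))
    if genuine.shape[1] != len(periods_s) or permutated.shape[1] != len(periods_s):
        raise ValueError("coherence matrices must have one column per period")
    if len(genuine) < 2 or len(permutated) < 2:
        raise ValueError("need at least 2 pairs per group")
    rows = []
    for j, period in enumerate(periods_s):
        g, p = genuine[:, j], permutated[:, j]
        g, p = g[~np.isnan(g)], p[~np.isnan(p)]
        degenerate = (
            len(g) < 2 or len(p) < 2 or (g.var(ddof=1) == 0 and p.var(ddof=1) == 0)
        )
        if degenerate:
            t = df = pval = d = np.nan
            mg = g.mean() if len(g) else np.nan
            mp = p.mean() if len(p) else np.nan
        else:
            t, df, pval, d = _welch(g, p)
            mg, mp = g.mean(), p.mean()
        rows.append(
            dict(period_s=period, mean_genuine=mg, mean_permutated=mp, t=t, df=df,
                 p=pval, q=np.nan, cohens_d=d, degenerate=degenerate)
        )
    table = pd.DataFrame(rows)
    ok = ~table["degenerate"].to_numpy(dtype=bool)
    if ok.any():
        _, qvals, _, _ = multipletests(table.loc[ok, "p"], alpha=alpha, method="fdr_bh")
        table.loc[ok, "q"] = qvals
    return ScaleComparisonTable(table=table, alpha=alpha)


def identify_poi(table: ScaleComparisonTable, alpha: float = 0.05) -> "list[POI]":
    """Maximal contiguous runs of significant periods with genuine > permuted.

    A period joins a run when its FDR-adjusted q is below ``alpha`` and
    the genuine group's mean coherence exceeds the permuted group's.  No
    significant period means an empty list, not an error.
    """
    df = table.table
    sig = (
        (df["q"].to_numpy() < alpha)
        & (df["mean_genuine"].to_numpy() > df["mean_permutated"].to_numpy())
        & ~df["degenerate"].to_numpy(dtype=bool)
    )
    periods = df["period_s"].to_numpy()
    pois: list[POI] = []
    start = None
    for i, flag in enumerate(np.append(sig, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            members = periods[start:i]
            pois.append(POI(float(members[0]), float(members[-1]), members))
            start = None
    return pois


def ibs_index(per_period: np.ndarray, periods_s: np.ndarray, poi: POI) -> IBSIndex:
    """Mean of the time-averaged coherence over the POI's member periods."""
    if len(poi.member_periods) == 0:
        raise ValueError("IBS index undefined for an empty POI")
    sel = np.isin(periods_s, poi.member_periods)
    if not sel.any():
        raise ValueError("POI periods not found on this period grid")
    return IBSIndex(value=float(np.nanmean(np.asarray(per_period, dtype=float)[sel])))
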