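"""Heart-rate-variability indices from RR-interval series.

Pipeline: ectopic correction and trimming (:func:`preprocess_nn`, optionally
:func:`min_sd_window` for unstable recordings), time-domain statistics
(:func:`time_domain`), IPFM-based spectral indices (:func:`modulating_signal`
+ :func:`band_powers`), and the non-linear panel (:func:`dfa`,
:func:`poincare`).  :func:`hrv_indices` runs the whole panel.

Conventions (stated once, used everywhere):

* All standard deviations are population SDs (divide by n).  Under this one
  convention the identity ``SD1 = SDSD / sqrt(2)`` is exact.
* pNN50 counts successive differences strictly greater than 50 ms, divided
  by the number of successive differences.
* The modulating signal is ``m(n) = (dHR(n) - dMHR(n)) / dMHR(n)`` where
  dHR is the instantaneous heart rate sampled at ``fs`` (default 4 Hz) and
  dMHR its below-0.03 Hz trend, removed with a zero-phase low-pass filter.
* Spectral powers integrate the Welch PSD (Hamming, 60 s segments, 50%
  overlap) over 0.04-0.15 Hz (LF) and 0.15-0.4 Hz (HF); normalized LF power
  divides by the 0.04-0.4 Hz total by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import interpolate, signal

__all__ = [
    "RRSeries",
    "HRVIndices",
    "preprocess_nn",
    "min_sd_window",
    "time_domain",
    "modulating_signal",
    "band_powers",
    "dfa",
    "poincare",
    "hrv_indices",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class RRSeries:
    """Beat-interval series: ``rr`` in ms, ``beat_times`` (s) marking the end
    of each interval, and per-interval ectopic flags."""

    rr: np.ndarray
    beat_times: np.ndarray | None = None
    ectopic_flags: np.ndarray | None = None
    fs_hrv: float = 4.0

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if (self.rr <= 0).any():
            raise ValueError("RR intervals must be positive")
        if self.beat_times is None:
            self.beat_times = np.cumsum(self.rr) / 1000.0
        else:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if np.any(np.diff(self.beat_times) <= 0):
                raise ValueError("beat times must be strictly increasing")
        if self.ectopic_flags is None:
            self.ectopic_flags = np.zeros(len(self.rr), dtype=bool)
        else:
            self.ectopic_flags = np.asarray(self.ectopic_flags, dtype=bool)
        if not len(self.rr) == len(self.beat_times) == len(self.ectopic_flags):
            raise ValueError("rr, beat_times and ectopic_flags misaligned")

    def __len__(self) -> int:
        return len(self.rr)

    @property
    def duration(self) -> float:
        """Span of the series in seconds (first interval start to last beat)."""
        return float(self.beat_times[-1] - (self.beat_times[0]
                                            - self.rr[0] / 1000.0))

    def slice_time(self, t0: float, t1: float) -> "RRSeries":
        """Sub-series of intervals whose end beat falls in (t0, t1]."""
        keep = (self.beat_times > t0) & (self.beat_times <= t1)
        if keep.sum() < 2:
            raise ValueError("selected window contains fewer than 2 intervals")
        return RRSeries(rr=self.rr[keep], beat_times=self.beat_times[keep],
                        ectopic_flags=self.ectopic_flags[keep],
                        fs_hrv=self.fs_hrv)


@dataclass
class HRVIndices:
    """The full index panel; indices that cannot be computed stay NaN."""

    mhr: float = math.nan          # bpm
    sdnn: float = math.nan         # ms
    sdsd: float = math.nan         # ms
    rmssd: float = math.nan        # ms
    pnn50: float = math.nan        # %
    p_lf: float = math.nan
    p_hf: float = math.nan
    p_lfn: float = math.nan
    lf_hf_ratio: float = math.nan
    alpha1: float = math.nan
    alpha2: float = math.nan
    sd1: float = math.nan          # ms
    sd2: float = math.nan          # ms
    sd1_sd2: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _detect_ectopic(rr: np.ndarray, max_dev: float) -> np.ndarray:
    """Flag intervals deviating > max_dev from the median of 5 neighbours."""
    n = len(rr)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - 2)
        hi = min(n, i + 3)
        neigh = np.delete(rr[lo:hi], i - lo)
        if len(neigh) == 0:
            continue
        med = np.median(neigh)
        if med > 0 and abs(rr[i] - med) / med > max_dev:
            flags[i] = True
    return flags


def preprocess_nn(rr: RRSeries, trim_min: float = 0.5,
                  max_dev: float = 0.3) -> RRSeries:
    """Ectopic-corrected, trimmed NN series.

    Intervals flagged on input or by the neighbour-median rule (deviation
    > ``max_dev`` from the median of the 5 surrounding intervals) are
    corrected by moving the offending beat to the midpoint of its
    neighbours, i.e. the flagged interval pair is replaced by linear
    interpolation of the beat times.  Then ``trim_min`` minutes are removed
    from each end.
    """
    flags = rr.ectopic_flags | _detect_ectopic(rr.rr, max_dev)
    nn = rr.rr.copy()
    times = rr.beat_times.copy()
    for i in np.flatnonzero(flags):
        if 0 < i < len(nn) - 1:
            # move the beat ending interval i to the neighbours' midpoint
            times[i] = 0.5 * (times[i - 1] + times[i + 1])
            nn[i] = (times[i] - times[i - 1]) * 1000.0
            nn[i + 1] = (times[i + 1] - times[i]) * 1000.0
        elif i == len(nn) - 1 and i > 0:
            nn[i] = nn[i - 1]
            times[i] = times[i - 1] + nn[i] / 1000.0
    out = RRSeries(rr=nn, beat_times=times,
                   ectopic_flags=np.zeros_like(flags), fs_hrv=rr.fs_hrv)
    if trim_min <= 0:
        return out
    trim_s = trim_min * 60.0
    start = out.beat_times[0] - out.rr[0] / 1000.0
    t0, t1 = start + trim_s, out.beat_times[-1] - trim_s
    if t1 - t0 <= 0:
        raise ValueError("series too short after trimming")
    return out.slice_time(t0, t1)


def min_sd_window(rr: RRSeries, window_min: float = 4.0,
                  step_s: float = 30.0) -> RRSeries:
    """The ``window_min``-minute stretch with the lowest RR SD.

    Candidate start offsets advance every ``step_s`` seconds; ties go to the
    earliest window.  Used for recordings (e.g. centenarians' 10-min ECGs)
    too unstable for a fixed trim.
    """
    win_s = window_min * 60.0
    start0 = rr.beat_times[0] - rr.rr[0] / 1000.0
    total = rr.beat_times[-1] - start0
    if total < win_s:
        raise ValueError("recording shorter than the requested window")
    best_sd, best = np.inf, None
    t0 = start0
    while t0 + win_s <= start0 + total + 1e-9:
        keep = (rr.beat_times > t0) & (rr.beat_times <= t0 + win_s)
        if keep.sum() >= 2:
            sd = float(np.std(rr.rr[keep]))
            if sd < best_sd - 1e-12:
                best_sd, best = sd, (t0, t0 + win_s)
        t0 += step_s
    if best is None:
        raise ValueError("no candidate window contains enough beats")
    return rr.slice_time(*best)


def time_domain(nn: RRSeries) -> HRVIndices:
    """MHR, SDNN, SDSD, RMSSD and pNN50 from an NN series."""
    x = nn.rr
    if len(x) < 2:
        raise ValueError("need at least 2 NN intervals")
    d = np.diff(x)
    return HRVIndices(
        mhr=60000.0 / float(np.mean(x)),
        sdnn=float(np.std(x)),
        sdsd=float(np.std(d)),
        rmssd=float(np.sqrt(np.mean(d ** 2))),
        pnn50=100.0 * float(np.mean(np.abs(d) > 50.0)),
    )


def modulating_signal(nn: RRSeries, fs: float | None = None,
                      cutoff: float = 0.03,
                      min_duration_s: float = 60.0
                      ) -> tuple[np.ndarray, float]:
    """The autonomic modulating signal ``m(n)`` and its sampling rate.

    The instantaneous heart rate dHR is a cubic spline through 60000/NN
    placed at beat midpoints, sampled at ``fs``; its sub-``cutoff`` trend
    dMHR comes from a zero-phase 4th-order Butterworth low-pass, and
    ``m = (dHR - dMHR) / dMHR``.  Requires at least ``min_duration_s`` of
    signal so the filter transient does not dominate.
    """
    fs = fs or nn.fs_hrv
    mid = nn.beat_times - nn.rr / 2000.0
    if mid[-1] - mid[0] < min_duration_s:
        raise ValueError(
            f"window shorter than {min_duration_s} s; the {cutoff} Hz trend "
            "cannot be estimated"
        )
    hr = 60000.0 / nn.rr
    start = nn.beat_times[0] - nn.rr[0] / 1000.0
    duration = nn.beat_times[-1] - start
    # sample the full analysis window; the spline extrapolates over the
    # half-interval beyond the first/last midpoint
    grid = start + np.arange(int(np.floor(duration * fs))) / fs
    dhr = interpolate.CubicSpline(mid, hr)(grid)
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    dmhr = signal.sosfiltfilt(sos, dhr)
    return (dhr - dmhr) / dmhr, fs


def _band_power(f: np.ndarray, psd: np.ndarray,
                band: tuple[float, float]) -> float:
    """Trapezoid integral of the PSD over a band, with interpolated edges."""
    lo, hi = band
    inside = (f >= lo) & (f <= hi)
    fk = f[inside]
    pk = psd[inside]
    # add exact band edges by interpolation so half-bins are not lost
    if len(fk) == 0 or fk[0] > lo:
        fk = np.insert(fk, 0, lo)
        pk = np.insert(pk, 0, np.interp(lo, f, psd))
    if fk[-1] < hi:
        fk = np.append(fk, hi)
        pk = np.append(pk, np.interp(hi, f, psd))
    return float(np.trapezoid(pk, fk))


def band_powers(m: np.ndarray, fs: float, segment_s: float = 60.0,
                lfn_total: str = "lf+hf") -> HRVIndices:
    """LF/HF spectral powers of the modulating signal.

    Welch PSD with Hamming windows of ``segment_s`` seconds and 50% overlap;
    band powers by trapezoid integration.  ``lfn_total`` selects the
    normalization denominator for P_LFn: ``"lf+hf"`` (power in 0.04-0.4 Hz,
    the default) or ``"full"`` (total integrated power).
    """
    nperseg = int(segment_s * fs)
    if len(m) < nperseg:
        raise ValueError("signal shorter than one Welch segment")
    f, psd = signal.welch(m, fs=fs, window="hamming", nperseg=nperseg,
                          noverlap=nperseg // 2, detrend="constant")
    p_lf = _band_power(f, psd, LF_BAND)
    p_hf = _band_power(f, psd, HF_BAND)
    total = p_lf + p_hf if lfn_total == "lf+hf" else float(np.trapezoid(psd, f))
    out = HRVIndices(p_lf=p_lf, p_hf=p_hf)
    if total > 0:
        out.p_lfn = p_lf / total
    if p_hf > 0:
        out.lf_hf_ratio = p_lf / p_hf
    return out


def _dfa_white_expectation(s: int) -> float:
    """Exact RMS fluctuation of unit-variance white noise in a box of size s.

    Within one box the profile is a cumulative sum of the in-box noise (the
    carry-in offset is absorbed by the detrending intercept), so
    ``E[F^2] = tr(L' (I-H) L) / s`` with L the cumulative-sum operator and H
    the hat matrix of the linear detrend.  Used to remove the small-box bias
    of first-order DFA (modified DFA); tends to sqrt(s/15) for large s.
    """
    t = np.arange(s, dtype=float)
    X = np.column_stack([np.ones(s), t])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    L = np.tril(np.ones((s, s)))
    R = (np.eye(s) - H) @ L
    return float(np.sqrt(np.trace(R.T @ R) / s))


def _dfa_fluctuation(profile: np.ndarray, s: int) -> float:
    n_boxes = len(profile) // s
    t = np.arange(s, dtype=float)
    res2 = []
    for segs in (profile[: n_boxes * s], profile[len(profile) - n_boxes * s:]):
        boxes = segs.reshape(n_boxes, s)
        coef = np.polynomial.polynomial.polyfit(t, boxes.T, 1)
        fitted = coef[0][:, None] + coef[1][:, None] * t
        res2.append(np.mean((boxes - fitted) ** 2, axis=1))
    return float(np.sqrt(np.mean(np.concatenate(res2))))


def dfa(rr: RRSeries | np.ndarray, short_range: tuple[int, int] = (4, 16),
        long_range: tuple[int, int] = (16, 64),
        n_scales: int = 16, bias_correction: bool = True
        ) -> tuple[float, float]:
    """Detrended fluctuation analysis scaling exponents (alpha1, alpha2).

    The mean-centered interval series is integrated into a profile, split
    into non-overlapping boxes taken from both ends, linearly detrended per
    box, and the RMS fluctuation F(s) regressed against box size on log-log
    axes over the short (alpha1) and long (alpha2) beat ranges.

    With ``bias_correction`` (default) F(s) is rescaled by the exact
    white-noise expectation so that uncorrelated intervals scale at exactly
    0.5 even over the small boxes of the alpha1 range, where plain
    first-order DFA is biased upward; the correction is asymptotically
    neutral at large box sizes.
    """
    x = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    s_max = long_range[1]
    if len(x) < 4 * s_max:
        raise ValueError(f"need at least {4 * s_max} beats for DFA")
    if np.std(x) == 0:
        return math.nan, math.nan
    profile = np.cumsum(x - np.mean(x))
    scales = np.unique(np.round(np.geomspace(short_range[0], s_max,
                                             n_scales)).astype(int))
    fluct = {}
    for s in scales:
        s = int(s)
        f = _dfa_fluctuation(profile, s)
        if bias_correction:
            f *= np.sqrt(s / 15.0) / _dfa_white_expectation(s)
        fluct[s] = f

    def slope(lo: int, hi: int) -> float:
        ss = np.array([s for s in fluct if lo <= s <= hi and fluct[s] > 0])
        if len(ss) < 3:
            return math.nan
        fs_ = np.array([fluct[int(s)] for s in ss])
        return float(np.polyfit(np.log(ss), np.log(fs_), 1)[0])

    return slope(*short_range), slope(*long_range)


def poincare(rr: RRSeries | np.ndarray) -> tuple[float, float, float]:
    """Poincaré-plot dispersions SD1 (short-term), SD2 (long-term) and ratio.

    Each interval is plotted against the previous one; SD1/SD2 are the
    population SDs along the plot's minor/major diagonals.
    """
    x = rr.rr if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 intervals")
    a, b = x[:-1], x[1:]
    sd1 = float(np.std((b - a) / np.sqrt(2.0)))
    sd2 = float(np.std((b + a) / np.sqrt(2.0)))
    # SD2 that is zero to roundoff (e.g. strictly alternating series) makes
    # the ratio meaningless
    ratio = sd1 / sd2 if sd2 > 1e-9 * float(np.mean(x)) else math.nan
    return sd1, sd2, ratio


def hrv_indices(rr: RRSeries, trim_min: float = 0.5,
                window: str | None = None,
                window_min: float = 4.0) -> HRVIndices:
    """The complete HRV panel for one subject.

    ``window="minsd"`` selects the minimum-SD ``window_min``-minute window
    before analysis (used when the recording is longer than the analysis
    window, e.g. 10-min centenarian ECGs); otherwise the series is trimmed
    by ``trim_min`` minutes at each end.
    """
    nn = preprocess_nn(rr, trim_min=0.0 if window == "minsd" else trim_min)
    if window == "minsd":
        nn = min_sd_window(nn, window_min=window_min)
    out = time_domain(nn)
    try:
        m, fs = modulating_signal(nn)
        spec = band_powers(m, fs)
        out.p_lf, out.p_hf = spec.p_lf, spec.p_hf
        out.p_lfn, out.lf_hf_ratio = spec.p_lfn, spec.lf_hf_ratio
    except ValueError:
        pass  # window too short for spectral analysis; indices stay NaN
    try:
        out.alpha1, out.alpha2 = dfa(nn)
    except ValueError:
        pass
    out.sd1, out.sd2, out.sd1_sd2 = poincare(nn)
    return out
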