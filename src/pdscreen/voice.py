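"""Sustained-vowel dysphonia analysis.

A held /a/ phonation is reduced to the 22 classic dysphonia features:
fundamental-frequency statistics (Fo/Fhi/Flo), cycle-to-cycle period
perturbation (jitter family), cycle-to-cycle amplitude perturbation
(shimmer family), harmonicity (NHR/HNR) and the nonlinear measures RPDE,
DFA, D2, spread1, spread2 and PPE.

Pre-processing follows the telemonitoring acquisition protocol: discard the
first second and last three seconds of the take (breath onset and the
pressure decay at the end), band-pass 50 Hz - 8 kHz, decimate to 22.05 kHz
and peak-normalize.

Jitter/shimmer use the standard perturbation-quotient definitions on the
extracted cycle sequences: with periods T_i (s) and cycle peak amplitudes
A_i,

* Jitter(%)    = mean|T_i - T_{i-1}| / mean(T) * 100
* RAP / PPQ    = k-point perturbation quotients (k = 3, 5)
* DDP          = mean|(T_{i+1}-T_i) - (T_i-T_{i-1})| / mean(T) * 100 = 3 RAP
* Shimmer(%)   = mean|A_i - A_{i-1}| / mean(A) * 100
* Shimmer(dB)  = mean|20 log10(A_{i+1}/A_i)|
* APQ3/5/11    = k-point amplitude perturbation quotients; DDA = 3 APQ3.

The nonlinear measures are under-determined in the literature; the choices
made here (embedding parameters, normalizations, the healthy-F0 reference
for spread/PPE) are documented in the methods note and in each docstring.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import InsufficientVoicingError, ParameterError, TooShortError
from .io_formats import VOICE_FEATURE_NAMES, VoiceRecording

TARGET_FS = 22050
#: healthy-speaker F0 reference (Hz) used by spread1/spread2/PPE
F0_REFERENCE = {"male": 120.0, "female": 190.0, "unknown": 150.0}


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def preprocess_voice(rec: VoiceRecording, *, lead_s: float = 1.0,
                     tail_s: float = 3.0, band: tuple[float, float] = (50.0, 8000.0),
                     order: int = 4, target_fs: int = TARGET_FS) -> VoiceRecording:
    """Truncate, band-pass, downsample and peak-normalize a phonation.

    Output order: truncate -> band-pass (zero-phase Butterworth, -3 dB at
    the band edges) -> rational resample to ``target_fs`` -> normalize to
    max |sample| = 1. Recordings of 4 s or less raise :class:`TooShortError`
    since nothing survives the 1 s lead / 3 s tail truncation.
    """
    if rec.duration <= lead_s + tail_s:
        raise TooShortError(
            f"recording is {rec.duration:.2f} s; the first {lead_s:g} s and "
            f"last {tail_s:g} s are discarded, so > {lead_s + tail_s:g} s is needed")
    i0 = int(round(lead_s * rec.fs))
    i1 = len(rec) - int(round(tail_s * rec.fs))
    x = rec.samples[i0:i1]
    nyq = rec.fs / 2.0
    if band[1] >= nyq:
        raise ParameterError(
            f"band-pass upper edge {band[1]} Hz requires fs > {2 * band[1]} Hz")
    sos = sps.butter(order, band, btype="bandpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    frac = Fraction(int(target_fs), int(round(rec.fs))).limit_denominator(1000)
    if frac != 1:
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return VoiceRecording(x, float(target_fs))


# ---------------------------------------------------------------------------
# pitch tracking and cycle extraction
# ---------------------------------------------------------------------------

@dataclass
class F0Track:
    """Frame-level pitch track plus cycle-level period/amplitude sequences."""

    times: np.ndarray          # frame centres (s)
    period: np.ndarray         # per-frame period estimate (s); NaN unvoiced
    f0: np.ndarray             # per-frame F0 (Hz) = 1/period; NaN unvoiced
    voiced: np.ndarray         # bool per frame
    ac_peak: np.ndarray        # normalized autocorrelation peak per frame
    cycle_times: np.ndarray    # refined glottal-cycle peak times (s)
    cycle_periods: np.ndarray  # successive peak spacings (s)
    cycle_amplitudes: np.ndarray  # refined peak heights

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())


def _frame_autocorr(frame: np.ndarray, lag_min: int, lag_max: int,
                    ) -> tuple[float, float]:
    """Best normalized-cross-correlation lag in [lag_min, lag_max].

    Returns (lag with quadratic refinement, correlation value). Uses the
    amplitude-normalized form r(t) = sum x_i x_{i+t} / sqrt(E0 Et), which is
    unbiased against window tapering for HNR purposes.
    """
    n = len(frame)
    lag_max = min(lag_max, n - 2)
    if lag_max <= lag_min:
        return np.nan, 0.0
    x = frame - frame.mean()
    # full autocorrelation via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(X * np.conj(X), nfft)[:n]
    energy = np.cumsum(x ** 2)
    e0 = energy[-1]
    if e0 <= 0:
        return np.nan, 0.0
    lags = np.arange(lag_min, lag_max + 1)
    # norm factor sqrt(sum_{0..n-t-1} x^2 * sum_{t..n-1} x^2)
    head = energy[n - lags - 1]
    tail = e0 - np.concatenate(([0.0], energy))[lags]
    norm = np.sqrt(np.maximum(head * tail, 1e-30))
    r = ac[lags] / norm
    k = int(np.argmax(r))
    # subharmonic guard: prefer the smallest-lag local maximum whose
    # correlation is within 10% of the best (octave-error suppression)
    if len(r) > 2:
        local_max = np.flatnonzero(
            (r[1:-1] >= r[:-2]) & (r[1:-1] >= r[2:])) + 1
        good = local_max[r[local_max] >= 0.9 * r[k]]
        if len(good):
            k = int(good[0])
    lag = float(lags[k])
    if 0 < k < len(r) - 1:  # quadratic interpolation of the correlation peak
        a, b, c = r[k - 1], r[k], r[k + 1]
        denom = a - 2 * b + c
        if denom != 0:
            lag += float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    return lag, float(r[k])


def _refine_peak(x: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic refinement of a sampled peak position and height."""
    if 0 < i < len(x) - 1:
        a, b, c = x[i - 1], x[i], x[i + 1]
        denom = a - 2 * b + c
        if denom != 0:
            d = float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
            return i + d, b - 0.25 * (a - c) * d
    return float(i), float(x[i])


def estimate_f0_track(rec: VoiceRecording, fmin: float = 60.0,
                      fmax: float = 400.0, frame_s: float = 0.04,
                      hop_s: float = 0.01, voicing_threshold: float = 0.45,
                      ) -> F0Track:
    """Autocorrelation pitch track plus per-cycle period/amplitude sequences.

    Frames whose normalized autocorrelation peak falls below
    ``voicing_threshold`` (or whose energy is negligible) are flagged
    unvoiced. Cycle peaks are picked on the waveform at the median voiced
    period spacing and refined by parabolic interpolation; successive peak
    spacings give the period sequence T_i and peak heights the amplitude
    sequence A_i. An all-unvoiced result is returned as such — callers
    decide how to proceed.
    """
    if fmax >= rec.fs / 2:
        raise ParameterError(f"fmax={fmax} must be below Nyquist ({rec.fs / 2})")
    if fmin <= 0 or fmin >= fmax:
        raise ParameterError("need 0 < fmin < fmax")
    x = rec.samples
    frame_n = int(round(frame_s * rec.fs))
    hop_n = max(1, int(round(hop_s * rec.fs)))
    lag_min = int(np.floor(rec.fs / fmax))
    lag_max = int(np.ceil(rec.fs / fmin))
    global_rms = np.sqrt(np.mean(x ** 2))
    times, periods, acs, voiced = [], [], [], []
    for start in range(0, len(x) - frame_n + 1, hop_n):
        frame = x[start:start + frame_n]
        times.append((start + frame_n / 2) / rec.fs)
        if np.sqrt(np.mean(frame ** 2)) < 1e-3 * max(global_rms, 1e-12):
            periods.append(np.nan)
            acs.append(0.0)
            voiced.append(False)
            continue
        lag, r = _frame_autocorr(frame, lag_min, lag_max)
        ok = np.isfinite(lag) and r > voicing_threshold
        periods.append(lag / rec.fs if ok else np.nan)
        acs.append(r)
        voiced.append(bool(ok))
    times = np.asarray(times)
    periods = np.asarray(periods)
    voiced = np.asarray(voiced)
    acs = np.asarray(acs)
    f0 = np.where(voiced, 1.0 / np.where(np.isnan(periods), np.inf, periods), np.nan)

    cycle_t = np.array([])
    cycle_T = np.array([])
    cycle_A = np.array([])
    if voiced.any():
        t_med = float(np.nanmedian(periods[voiced]))
        # cycle marking runs on a low-passed copy whose passband covers
        # the whole harmonic stack:
        # broadband noise above the harmonic stack only jitters the peak
        # positions without carrying period information
        cutoff = min(14.0 / t_med, 0.45 * rec.fs)
        sos_lp = sps.butter(4, cutoff, btype="lowpass", fs=rec.fs, output="sos")
        y = sps.sosfiltfilt(sos_lp, x)
        dist = max(2, int(round(0.7 * t_med * rec.fs)))
        floor = 0.1 * np.max(np.abs(y)) if np.any(y) else 0.0
        idx, _ = sps.find_peaks(y, distance=dist, height=floor)
        # drop cycles near the signal edges (filter edge transients)
        edge = max(0.03, 4.0 * t_med) * rec.fs
        idx = idx[(idx >= edge) & (idx <= len(x) - edge)]
        # refine on a 4x sinc-upsampled copy: parabolic interpolation alone
        # biases the height with the sub-sample peak offset, which would
        # masquerade as shimmer when the periods jitter
        up = 4
        y_up = sps.resample_poly(y, up, 1)
        pos = np.empty(len(idx))
        amp = np.empty(len(idx))
        for j, i in enumerate(idx):
            lo = max(1, up * int(i) - up)
            hi = min(len(y_up) - 1, up * int(i) + up + 1)
            k = lo + int(np.argmax(y_up[lo:hi]))
            p_up, amp[j] = _refine_peak(y_up, k)
            pos[j] = p_up / up
        cycle_t = pos / rec.fs
        T = np.diff(cycle_t)
        # keep spacings consistent with one pitch period (reject octave slips)
        keep = (T > 0.6 * t_med) & (T < 1.6 * t_med)
        cycle_T = T[keep]
        cycle_A = amp
    return F0Track(times, periods, f0, voiced, acs, cycle_t, cycle_T, cycle_A)


# ---------------------------------------------------------------------------
# perturbation measures (jitter / shimmer families)
# ---------------------------------------------------------------------------

def _first_diff_ratio(v: np.ndarray) -> float:
    return float(np.mean(np.abs(np.diff(v))) / np.mean(v))


def _kpoint_quotient(v: np.ndarray, k: int) -> float:
    """Mean |v_i - local k-point mean| / mean(v); the classic k-point PQ."""
    if len(v) < k:
        return 0.0
    half = k // 2
    kernel = np.ones(k) / k
    local = np.convolve(v, kernel, mode="valid")
    centre = v[half:len(v) - half]
    return float(np.mean(np.abs(centre - local)) / np.mean(v))


def jitter_percent(T: np.ndarray) -> float:
    return 100.0 * _first_diff_ratio(np.asarray(T, float))


def jitter_abs(T: np.ndarray) -> float:
    return float(np.mean(np.abs(np.diff(np.asarray(T, float)))))


def rap(T: np.ndarray) -> float:
    return 100.0 * _kpoint_quotient(np.asarray(T, float), 3)


def ppq(T: np.ndarray) -> float:
    return 100.0 * _kpoint_quotient(np.asarray(T, float), 5)


def ddp(T: np.ndarray) -> float:
    T = np.asarray(T, float)
    if len(T) < 3:
        return 0.0
    return 100.0 * float(np.mean(np.abs(np.diff(T, 2))) / np.mean(T))


def shimmer_percent(A: np.ndarray) -> float:
    return 100.0 * _first_diff_ratio(np.asarray(A, float))


def shimmer_db(A: np.ndarray) -> float:
    A = np.asarray(A, float)
    A = A[A > 0]
    if len(A) < 2:
        return 0.0
    return float(np.mean(np.abs(20.0 * np.log10(A[1:] / A[:-1]))))


def apq(A: np.ndarray, k: int) -> float:
    return 100.0 * _kpoint_quotient(np.asarray(A, float), k)


def dda(A: np.ndarray) -> float:
    return 3.0 * apq(A, 3)


# ---------------------------------------------------------------------------
# nonlinear measures
# ---------------------------------------------------------------------------

def _autocorr_first_min(x: np.ndarray, max_lag: int) -> int:
    ac = np.correlate(x - x.mean(), x - x.mean(), mode="full")
    ac = ac[len(ac) // 2:][:max_lag]
    for i in range(1, len(ac) - 1):
        if ac[i] < ac[i - 1] and ac[i] <= ac[i + 1]:
            return i
    return max(1, max_lag // 4)


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = len(x) - (dim - 1) * delay
    if n <= 0:
        raise ParameterError("signal too short for the requested embedding")
    return np.stack([x[i * delay:i * delay + n] for i in range(dim)], axis=1)


def rpde(x: np.ndarray, fs: float, *, dim: int = 4, radius_frac: float = 0.12,
         max_samples: int = 5000, period_hint: float | None = None) -> float:
    """Normalized recurrence period density entropy in [0, 1].

    The signal (a centred excerpt of at most ``max_samples`` samples) is
    embedded in ``dim`` dimensions with the delay at the first
    autocorrelation minimum; for each point the first close return
    (Chebyshev distance < ``radius_frac`` x signal std, after at least half
    a mean period) defines a recurrence period. The entropy of the period
    histogram is normalized by the log of the number of admissible periods,
    so a perfectly periodic signal scores near 0 and broadband noise near 1.
    """
    x = np.asarray(x, float)
    if len(x) > max_samples:
        mid = len(x) // 2
        x = x[mid - max_samples // 2: mid + max_samples // 2]
    x = (x - x.mean())
    sd = x.std()
    if sd == 0:
        return 0.0
    x = x / sd
    delay = _autocorr_first_min(x, int(0.02 * fs) or 20)
    X = _embed(x, dim, delay)
    r = radius_frac  # signal already unit-variance
    period = period_hint if period_hint else delay * 4 / fs
    t_min = max(1, int(0.5 * period * fs))
    t_max = min(len(X) - 1, max(t_min + 10, int(3.5 * period * fs)))
    n = len(X)
    first_ret = np.full(n, -1, dtype=int)
    undecided = np.ones(n, dtype=bool)
    for lag in range(t_min, t_max + 1):
        m = n - lag
        if m <= 0:
            break
        close = np.max(np.abs(X[:m] - X[lag:]), axis=1) < r
        hit = np.zeros(n, dtype=bool)
        hit[:m] = close
        newly = hit & undecided
        first_ret[newly] = lag
        undecided &= ~newly
    periods = first_ret[first_ret > 0]
    if len(periods) == 0:
        return 1.0
    counts = np.bincount(periods, minlength=t_max + 1)[t_min:t_max + 1]
    p = counts / counts.sum()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return float(np.clip(h / np.log(t_max - t_min + 1), 0.0, 1.0))


def dfa(x: np.ndarray, *, box_min: int = 50, box_max: int = 1000,
        n_boxes: int = 10, max_samples: int = 30000) -> float:
    """Detrended fluctuation analysis exponent, squashed to (0, 1).

    The scaling exponent alpha is the log-log slope of the RMS fluctuation
    of the linearly detrended integrated signal over log-spaced box sizes;
    it is mapped through the logistic function 1/(1+exp(-alpha)) so the
    reported value lies in (0, 1) like the classic dysphonia tables.
    """
    x = np.asarray(x, float)
    if len(x) > max_samples:
        mid = len(x) // 2
        x = x[mid - max_samples // 2: mid + max_samples // 2]
    y = np.cumsum(x - x.mean())
    box_max = min(box_max, len(y) // 4)
    sizes = np.unique(np.round(np.logspace(
        np.log10(box_min), np.log10(box_max), n_boxes)).astype(int))
    fluct = []
    for L in sizes:
        m = len(y) // L
        segs = y[:m * L].reshape(m, L)
        t = np.arange(L)
        A = np.vstack([t, np.ones(L)]).T
        coef, *_ = np.linalg.lstsq(A, segs.T, rcond=None)
        resid = segs.T - A @ coef
        fluct.append(np.sqrt(np.mean(resid ** 2)))
    alpha = float(np.polyfit(np.log(sizes), np.log(fluct), 1)[0])
    return float(1.0 / (1.0 + np.exp(-alpha)))


def correlation_dimension(x: np.ndarray, fs: float, *, dim: int = 10,
                          n_points: int = 1200,
                          period_hint: float | None = None) -> float:
    """Grassberger-Procaccia correlation dimension estimate (D2).

    The excerpt is embedded in ``dim`` dimensions (delay at the first
    autocorrelation minimum); the correlation sum C(r) is computed over
    pairs separated by more than one mean period (Theiler window) and D2 is
    the log-log slope over the small-radius scaling region (2nd-20th
    distance percentiles).
    """
    x = np.asarray(x, float)
    x = (x - x.mean())
    sd = x.std()
    if sd == 0:
        return 0.0
    x = x / sd
    delay = _autocorr_first_min(x, int(0.02 * fs) or 20)
    X = _embed(x, dim, delay)
    stride = max(1, len(X) // n_points)
    X = X[::stride]
    n = len(X)
    period = period_hint if period_hint else delay * 4 / fs
    theiler = max(1, int(period * fs / stride))
    from scipy.spatial.distance import cdist
    d2 = cdist(X, X)
    iu = np.triu_indices(n, k=theiler + 1)
    dists = d2[iu]
    dists = dists[dists > 0]
    if len(dists) < 100:
        return 0.0
    r_lo, r_hi = np.quantile(dists, [0.02, 0.20])
    radii = np.logspace(np.log10(r_lo), np.log10(r_hi), 8)
    C = np.array([np.mean(dists < r) for r in radii])
    good = C > 0
    if good.sum() < 3:
        return 0.0
    slope = float(np.polyfit(np.log(radii[good]), np.log(C[good]), 1)[0])
    return max(0.0, slope)


def f0_variation_measures(f0: np.ndarray, f0_ref: float,
                          ) -> tuple[float, float, float]:
    """spread1, spread2 and PPE from a voiced F0 sequence.

    Working on the log-pitch scale q_t = ln(F0_t / F0_ref) relative to a
    healthy-speaker reference:

    * spread1 = ln(mean |q - median(q)|) — log-scale dispersion of pitch
      around its central value (more negative = steadier pitch);
    * spread2 = standard deviation of the whitened (AR(2) residual) q
      sequence — the unpredictable part of pitch variation;
    * PPE = normalized discrete entropy of the whitened residual
      distribution in [0, 1] (pitch period entropy).

    These are this package's documented realizations of the "nonlinear
    F0-variation" family; exact agreement with other toolchains is not
    claimed.
    """
    f0 = np.asarray(f0, float)
    f0 = f0[np.isfinite(f0) & (f0 > 0)]
    if len(f0) < 10:
        return -9.2, 0.0, 0.0
    q = np.log(f0 / f0_ref)
    mad = float(np.mean(np.abs(q - np.median(q))))
    spread1 = float(np.log(max(mad, 1e-4)))
    # AR(2) whitening
    A = np.vstack([q[1:-1], q[:-2], np.ones(len(q) - 2)]).T
    coef, *_ = np.linalg.lstsq(A, q[2:], rcond=None)
    e = q[2:] - A @ coef
    spread2 = float(np.std(e))
    span = e.max() - e.min()
    if span <= 0:
        return spread1, spread2, 0.0
    hist, _ = np.histogram(e, bins=30)
    p = hist / hist.sum()
    p = p[p > 0]
    ppe_val = float(-(p * np.log(p)).sum() / np.log(30))
    return spread1, spread2, ppe_val


# ---------------------------------------------------------------------------
# the 22-feature vector
# ---------------------------------------------------------------------------

@dataclass
class VoiceFeatureVector:
    """The 22 dysphonia features in canonical order."""

    names: tuple[str, ...]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return self.as_dict()[name]


def compute_voice_features(rec: VoiceRecording, *, gender: str = "unknown",
                           f0_ref: float | None = None,
                           min_cycles: int = 30,
                           track: F0Track | None = None) -> VoiceFeatureVector:
    """Compute the 22 dysphonia features from a pre-processed phonation.

    Requires at least ``min_cycles`` detected glottal cycles, otherwise
    :class:`InsufficientVoicingError` is raised. ``f0_ref`` overrides the
    per-gender healthy-F0 reference used by spread1/spread2/PPE.
    """
    if track is None:
        track = estimate_f0_track(rec)
    T = track.cycle_periods
    A = track.cycle_amplitudes
    if len(T) < min_cycles:
        raise InsufficientVoicingError(
            f"found {len(T)} voiced cycles, need >= {min_cycles}")
    f0_cycles = 1.0 / T
    fo, fhi, flo = float(f0_cycles.mean()), float(f0_cycles.max()), float(f0_cycles.min())
    mean_period = float(T.mean())
    # harmonicity from the frame-level normalized autocorrelation peaks
    r = np.clip(track.ac_peak[track.voiced], 1e-6, 1 - 1e-6)
    hnr_frames = 10.0 * np.log10(r / (1.0 - r))
    hnr = float(np.clip(hnr_frames.mean(), -20.0, 60.0))
    nhr = float(np.mean((1.0 - r) / r))
    if f0_ref is None:
        f0_ref = F0_REFERENCE.get(gender, F0_REFERENCE["unknown"])
    spread1, spread2, ppe_val = f0_variation_measures(
        track.f0[track.voiced], f0_ref)
    x = rec.samples
    values = {
        "MDVP:Fo(Hz)": fo,
        "MDVP:Fhi(Hz)": fhi,
        "MDVP:Flo(Hz)": flo,
        "MDVP:Jitter(%)": jitter_percent(T),
        "MDVP:Jitter(Abs)": jitter_abs(T),
        "MDVP:RAP": rap(T),
        "MDVP:PPQ": ppq(T),
        "Jitter:DDP": ddp(T),
        "MDVP:Shimmer": shimmer_percent(A),
        "MDVP:Shimmer(dB)": shimmer_db(A),
        "Shimmer:APQ3": apq(A, 3),
        "Shimmer:APQ5": apq(A, 5),
        "MDVP:APQ": apq(A, 11),
        "Shimmer:DDA": dda(A),
        "NHR": nhr,
        "HNR": hnr,
        "RPDE": rpde(x, rec.fs, period_hint=mean_period),
        "D2": correlation_dimension(x, rec.fs, period_hint=mean_period),
        "DFA": dfa(x),
        "spread1": spread1,
        "spread2": spread2,
        "PPE": ppe_val,
    }
    return VoiceFeatureVector(
        VOICE_FEATURE_NAMES,
        np.array([values[n] for n in VOICE_FEATURE_NAMES]),
    )
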