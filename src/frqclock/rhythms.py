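"""Rhythm quantification: period, phase angle, entrainment classification.

Operates on ``(time, value)`` series — dense model trajectories or
sparse noisy densitometry alike.  Periods are estimated two ways and
cross-checked: mean peak-to-peak interval, and the dominant period of a
mean-removed Lomb-Scargle periodogram over the 0.5-48 h band.

Entrainment follows the operational definition used for T-cycle work:
a rhythm is *entrained* when its period matches the forcing cycle
length T (within a relative tolerance) and its phase angle to lights-on
is stable cycle over cycle.  Failing that, a series with a dominant
spectral period in the circadian free-running band (16-32 h, which
brackets the ~22 h wild-type period and its mutant variants) is
*free-running*; anything else is *arrhythmic*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import find_peaks, lombscargle

from .protocols import LDProtocol

__all__ = [
    "RhythmReport",
    "detect_peaks",
    "estimate_period",
    "periodogram",
    "spectral_period",
    "phase_angle",
    "classify_entrainment",
    "light_response_amplitude",
    "smoothness_ratio",
    "DEFAULT_TOLERANCES",
    "FREE_RUN_BAND",
    "default_discard",
]

#: circadian free-running band (h): brackets the ~22 h WT period and
#: the short/long-period frq mutants
FREE_RUN_BAND = (16.0, 32.0)

#: classification thresholds (declared defaults; the underlying
#: experiments report categories, not numbers)
DEFAULT_TOLERANCES = {
    "period_rel_tol": 0.05,       # |period - T|/T for entrainment
    "phase_sd_floor_h": 0.5,      # phase-angle SD <= max(floor, frac*T)
    "phase_sd_frac": 0.1,
    "power_ratio_min": 3.0,       # peak power >= ratio * median power
    "min_prominence": 0.1,        # peak prominence, fraction of range
}


def default_discard(protocol: LDProtocol | None) -> float:
    """Transient discard: 96 h or 5 forcing cycles, whichever is longer."""
    if protocol is not None and protocol.periodic:
        return max(96.0, 5.0 * protocol.T)
    return 96.0


def _as_series(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, tuple) and len(series) == 2:
        t, x = series
    else:
        arr = np.asarray(series, dtype=float)
        t, x = arr[:, 0], arr[:, 1]
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.ndim != 1 or t.shape != x.shape:
        raise ValueError("series must be parallel 1-d time and value arrays")
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return t, x


def detect_peaks(series, min_prominence: float = 0.1) -> np.ndarray:
    """Times of local maxima with prominence >= min_prominence * range.

    Peak times are refined to sub-sample precision by a quadratic fit
    through the three samples around each maximum (plateaus resolve to
    their earliest sample; series endpoints are never peaks).  A
    constant series has no peaks.
    """
    t, x = _as_series(series)
    if len(t) < 3:
        raise ValueError("need at least 3 samples to detect peaks")
    rng = float(x.max() - x.min())
    if rng == 0.0:
        return np.array([])
    idx, props = find_peaks(x, prominence=min_prominence * rng, plateau_size=1)
    # ties broken toward earlier time: use the left edge of any plateau
    left = props["left_edges"]
    out = []
    for i, le in zip(idx, left):
        j = le if x[le] == x[i] else i
        if 0 < j < len(t) - 1 and x[j - 1] != x[j]:
            # quadratic (parabolic) refinement on uniform or mildly
            # nonuniform grids; falls back to the sample time if the
            # curvature degenerates
            y0, y1, y2 = x[j - 1], x[j], x[j + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                dt_loc = 0.5 * (t[j + 1] - t[j - 1])
                out.append(t[j] + np.clip(delta, -0.5, 0.5) * dt_loc)
                continue
        out.append(t[j])
    return np.array(out)


#: spectral operations decimate dense series to about this many samples;
#: the shortest period probed is 0.5 h, so a ~0.1 h effective sampling
#: interval (5000 points over 500 h) loses nothing in the 0.5-48 h band
_MAX_SPECTRAL_SAMPLES = 5000


def _decimate(t: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    stride = int(np.ceil(len(t) / _MAX_SPECTRAL_SAMPLES))
    return (t[::stride], x[::stride]) if stride > 1 else (t, x)


def periodogram(series, period_min: float = 0.5, period_max: float = 48.0,
                n_periods: int = 4000) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed Lomb-Scargle power over a uniform period grid."""
    t, x = _as_series(series)
    t, x = _decimate(t, x)
    span = t[-1] - t[0]
    period_max = min(period_max, span)  # periods longer than the record are meaningless
    periods = np.linspace(period_min, period_max, n_periods)
    w = 2.0 * np.pi / periods
    power = lombscargle(t, x - x.mean(), w)
    return periods, power


def spectral_period(series, period_min: float = 0.5, period_max: float = 48.0) -> float:
    """Dominant period (h): argmax of the periodogram."""
    periods, power = periodogram(series, period_min, period_max)
    return float(periods[np.argmax(power)])


@dataclass
class PeriodEstimate:
    """Peak-to-peak period with spectral cross-check."""

    mean: float | None
    sd: float | None
    spectral: float | None
    n_peaks: int
    defined: bool

    def __iter__(self):  # tuple-unpacking convenience: (mean, sd)
        return iter((self.mean, self.sd))


def estimate_period(series, discard: float = 96.0,
                    min_prominence: float = 0.1) -> PeriodEstimate:
    """Mean +- SD of successive peak-to-peak intervals after ``discard``.

    Returns an undefined-period result (``defined=False``) when fewer
    than 3 peaks survive the transient discard, rather than raising.
    """
    t, x = _as_series(series)
    sel = t >= t[0] + discard
    if sel.sum() < 3:
        return PeriodEstimate(None, None, None, 0, False)
    ts, xv = t[sel], x[sel]
    spec = spectral_period((ts, xv)) if sel.sum() >= 8 else None
    if spec is not None:
        # suppress sub-period measurement noise before peak picking;
        # a window well under the detected period leaves peak *intervals*
        # untouched (every peak shifts identically on a periodic signal)
        xv = _smooth(ts, xv, spec / 8.0)
    peaks = detect_peaks((ts, xv), min_prominence)
    if len(peaks) < 3:
        return PeriodEstimate(None, None, spec, len(peaks), False)
    d = np.diff(peaks)
    return PeriodEstimate(float(d.mean()), float(d.std()), spec, len(peaks), True)


def _cycle_starts(protocol: LDProtocol, t_lo: float, t_hi: float) -> np.ndarray:
    """Lights-on times (cycle starts) covering [t_lo, t_hi]."""
    T = protocol.T
    k_lo = int(np.ceil((t_lo - protocol.t0) / T))
    k_hi = int(np.floor((t_hi - protocol.t0) / T))
    return protocol.t0 + T * np.arange(k_lo, k_hi + 1)


def phase_angle(series, protocol: LDProtocol, reference: str = "peak",
                discard: float | None = None,
                min_prominence: float = 0.1) -> np.ndarray:
    """Per-cycle phase angles: lights-on to the reference event (h).

    ``reference`` is one of ``peak``, ``trough`` or ``onset`` (onset =
    upward crossing of the cycle's mid-range).  Cycles without the
    reference event are skipped.  Undefined for non-periodic protocols.
    """
    if not protocol.periodic:
        raise ValueError("phase angle is undefined for constant (DD/LL) protocols")
    if reference not in ("peak", "trough", "onset"):
        raise ValueError("reference must be 'peak', 'trough' or 'onset'")
    t, x = _as_series(series)
    if discard is None:
        discard = default_discard(protocol)
    sel = t >= t[0] + discard
    t, x = t[sel], x[sel]
    T = protocol.T
    if len(t) < 3 or t[-1] - t[0] < 3 * T:
        raise ValueError("need >= 3 complete forcing cycles after the transient")

    if reference in ("peak", "trough"):
        sig = (t, x) if reference == "peak" else (t, -x)
        events = detect_peaks(sig, min_prominence)
    else:
        mid = 0.5 * (x.max() + x.min())
        above = x >= mid
        cross = np.where(~above[:-1] & above[1:])[0]
        # linear interpolation of the upward crossing time
        events = np.array([
            t[i] + (t[i + 1] - t[i]) * (mid - x[i]) / (x[i + 1] - x[i])
            for i in cross
        ])

    offsets = []
    for start in _cycle_starts(protocol, t[0], t[-1] - T):
        in_cycle = events[(events >= start) & (events < start + T)]
        if len(in_cycle):
            offsets.append(in_cycle[0] - start)
    return np.array(offsets)


def circular_phase_sd(offsets: np.ndarray, T: float) -> float:
    """SD of phase angles in hours, computed on the circle of length T.

    Uses the circular standard deviation so a stable phase sitting near
    the cycle boundary is not inflated by wrap-around; a uniformly
    drifting phase yields a large value.
    """
    if len(offsets) < 2:
        return 0.0
    ang = np.asarray(offsets) / T * 2.0 * np.pi
    R = abs(np.exp(1j * ang).mean())
    R = min(max(R, 1e-12), 1.0)
    return float(np.sqrt(-2.0 * np.log(R)) * T / (2.0 * np.pi))


def _smooth(t: np.ndarray, x: np.ndarray, window_h: float) -> np.ndarray:
    """Centered moving average over ``window_h``; a no-op when the
    sampling is too sparse for the window (fewer than 3 samples)."""
    if len(t) < 3:
        return x
    step = float(np.median(np.diff(t)))
    k = int(round(window_h / step))
    if k < 3:
        return x
    k += 1 - k % 2  # odd length keeps the filter phase-neutral
    pad = k // 2
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]])
    return np.convolve(xp, np.ones(k) / k, mode="valid")


def _cycle_phases_harmonic(t: np.ndarray, x: np.ndarray,
                           protocol: LDProtocol) -> np.ndarray:
    """Per-cycle phase of the fundamental at the forcing frequency.

    For each complete forcing cycle, least-squares fits
    ``a + b cos(2 pi t/T) + c sin(2 pi t/T)`` to that cycle's samples
    and returns the time offset (h, in [0, T)) of the fundamental's
    maximum from lights-on.  Far more robust than per-cycle argmax on
    sparse noisy sampling; cycles with fewer than 3 samples or a
    degenerate fit are skipped.
    """
    T = protocol.T
    w = 2.0 * np.pi / T
    # sparse sampling: widen the fit window symmetrically (1-3 cycles)
    # until each fit sees at least ~12 samples; the window stays centered
    # on the cycle, so a steady phase is unbiased and a drift keeps its slope
    step = float(np.median(np.diff(t))) if len(t) > 1 else T
    n_cycles_fit = int(np.clip(np.ceil(12.0 * step / T), 1, 3))
    half_extra = 0.5 * (n_cycles_fit - 1) * T
    offsets = []
    for start in _cycle_starts(protocol, t[0], t[-1] - T):
        sel = (t >= start - half_extra) & (t < start + T + half_extra)
        if sel.sum() < 3:
            continue
        tc, xc = t[sel], x[sel]
        A = np.column_stack([np.ones(len(tc)), np.cos(w * (tc - start)),
                             np.sin(w * (tc - start))])
        coef, *_ = np.linalg.lstsq(A, xc, rcond=None)
        b, c = coef[1], coef[2]
        if b * b + c * c <= 0:
            continue
        offsets.append((np.arctan2(c, b) / w) % T)
    return np.array(offsets)


def _drift_per_cycle(offsets: np.ndarray, T: float) -> float:
    """Mean phase advance per cycle (h) after unwrapping on [0, T)."""
    unwrapped = np.unwrap(offsets / T * 2.0 * np.pi) * T / (2.0 * np.pi)
    k = np.arange(len(unwrapped))
    slope = np.polyfit(k, unwrapped, 1)[0]
    return float(slope)


@dataclass
class RhythmReport:
    """Full rhythm quantification of one series under one protocol."""

    period_peaks: float | None
    period_peaks_sd: float | None
    period_spectral: float | None
    phase_angles: list = field(default_factory=list)
    phase_sd: float | None = None
    classification: str = "arrhythmic"
    forcing_band_power_ratio: float | None = None

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(asdict(self), indent=indent)


def classify_entrainment(series, protocol: LDProtocol,
                         tolerances: dict | None = None,
                         discard: float | None = None) -> RhythmReport:
    """Classify a series as entrained / free_running / arrhythmic.

    Entrained: peak-to-peak period within ``period_rel_tol`` of the
    forcing period T *and* circular phase-angle SD within
    ``max(phase_sd_floor_h, phase_sd_frac * T)``.  Otherwise
    free-running if the dominant spectral period lies in the 16-32 h
    circadian band with power >= ``power_ratio_min`` times the median
    periodogram power.  Otherwise arrhythmic.

    For periodic protocols at least 10 cycles of post-transient data
    are required.
    """
    tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}
    t, x = _as_series(series)
    if discard is None:
        discard = default_discard(protocol)

    if protocol.periodic:
        T = protocol.T
        post = t[-1] - (t[0] + discard)
        if post < 10 * T:
            raise ValueError(
                f"insufficient data: need >= {10 * T:g} h after the {discard:g} h "
                f"transient for T={T:g} h, have {post:g} h"
            )

    # measurement noise creates spurious local maxima on densely sampled
    # series; peak-based statistics therefore run on a lightly smoothed
    # copy (window well below the period probed, so timing is preserved)
    window = protocol.T / 6.0 if protocol.periodic else 2.0
    xs = _smooth(t, x, window)
    series = (t, xs)

    est = estimate_period(series, discard=discard,
                          min_prominence=tol["min_prominence"])
    sel = t >= t[0] + discard
    sub = (t[sel], xs[sel])
    periods, power = periodogram(sub)
    med = float(np.median(power))

    report = RhythmReport(
        period_peaks=est.mean, period_peaks_sd=est.sd,
        period_spectral=est.spectral,
    )

    if protocol.periodic:
        T = protocol.T
        i_T = int(np.argmin(np.abs(periods - T)))
        report.forcing_band_power_ratio = float(power[i_T] / med) if med > 0 else np.inf

        # the forcing-frequency component must dominate the circadian
        # band before the series can count as entrained: a stable
        # phase-locked ripple riding on a large free-running rhythm is
        # superimposition, not entrainment
        lo, hi = FREE_RUN_BAND
        band = (periods >= lo) & (periods <= hi) & (np.abs(periods - T) > 0.1 * T)
        band_best = float(power[band].max()) if band.any() else 0.0
        forcing_dominant = power[i_T] >= band_best

        offs = _cycle_phases_harmonic(t[sel], xs[sel], protocol)
        report.phase_angles = [float(o) for o in offs]
        if len(offs) >= 3:
            report.phase_sd = circular_phase_sd(offs, T)
            drift = _drift_per_cycle(offs, T)
        else:
            drift = None
        if (
            forcing_dominant
            and drift is not None
            and abs(drift) / T <= tol["period_rel_tol"]
            and report.phase_sd is not None
            and report.phase_sd <= max(tol["phase_sd_floor_h"], tol["phase_sd_frac"] * T)
        ):
            report.classification = "entrained"
            return report

    # free-running: a dominant circadian-band peak well above the noise
    # floor that is not outweighed by the forcing-frequency component
    # (a strong forcing peak with 16-32 h sidelobes must not read as a
    # free run)
    lo, hi = FREE_RUN_BAND
    band = (periods >= lo) & (periods <= hi)
    if protocol.periodic:
        band &= np.abs(periods - protocol.T) > 0.1 * protocol.T
    if med > 0 and band.any():
        i_best = int(np.argmax(np.where(band, power, -np.inf)))
        # the forcing bin only competes when the sampling can resolve it;
        # below the Nyquist period its power is pure aliasing
        step = float(np.median(np.diff(t[sel]))) if sel.sum() > 1 else 0.0
        p_forcing = (power[int(np.argmin(np.abs(periods - protocol.T)))]
                     if protocol.periodic and protocol.T >= 2.0 * step else 0.0)
        if (power[i_best] >= tol["power_ratio_min"] * med
                and power[i_best] >= p_forcing):
            report.classification = "free_running"
            report.period_spectral = float(periods[i_best])
            return report

    report.classification = "arrhythmic"
    return report


def light_response_amplitude(mrna_series, protocol: LDProtocol,
                             discard: float | None = None) -> float:
    """Mean per-cycle light induction: max during the light phase minus
    the value at lights-on, averaged over post-transient cycles.

    Quantifies the direct (acute) transcriptional light response; under
    photoadaptation it shrinks as the cycle gets shorter.
    """
    if not protocol.periodic:
        raise ValueError("light response amplitude requires a periodic protocol")
    if not any(i > 0 for _, i in protocol.phases) or not any(i == 0 for _, i in protocol.phases):
        raise ValueError("protocol must contain both a light and a dark phase")
    t, x = _as_series(series=mrna_series)
    if discard is None:
        discard = default_discard(protocol)
    T = protocol.T
    light_len = protocol.phases[0][0]  # cycles start at lights-on
    amps = []
    for start in _cycle_starts(protocol, t[0] + discard, t[-1] - T):
        sel = (t >= start) & (t <= start + light_len)
        if not sel.any():
            continue
        i_on = np.searchsorted(t, start)
        amps.append(float(x[sel].max() - x[i_on]))
    if not amps:
        raise ValueError("no complete cycles after the transient discard")
    return float(np.mean(amps))


def _power_fraction_at(t: np.ndarray, x: np.ndarray, T: float) -> float:
    t, x = _decimate(t, x)
    w = np.array([2.0 * np.pi / T])
    p = float(np.atleast_1d(lombscargle(t, x - x.mean(), w))[0])
    v = float(x.var())
    return p / v if v > 0 else 0.0


def smoothness_ratio(protein_series, mrna_series, protocol: LDProtocol,
                     discard: float | None = None) -> float:
    """Variance-normalized power of protein vs mRNA at the forcing
    frequency 1/T.

    The delayed synthesis/clearance stage low-pass filters the mRNA
    signal, so the ratio falls below 1 for fast cycles: the protein
    curve is smoother than the mRNA curve.
    """
    if not protocol.periodic:
        raise ValueError("smoothness ratio requires a periodic protocol")
    tp, xp = _as_series(protein_series)
    tm, xm = _as_series(mrna_series)
    if len(tp) != len(tm) or not np.allclose(tp, tm):
        raise ValueError("protein and mRNA series must share one time grid")
    if discard is None:
        discard = default_discard(protocol)
    sel = tp >= tp[0] + discard
    T = protocol.T
    num = _power_fraction_at(tp[sel], xp[sel], T)
    den = _power_fraction_at(tm[sel], xm[sel], T)
    if den == 0:
        raise ValueError("mRNA series has no power at the forcing frequency")
    return num / den
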