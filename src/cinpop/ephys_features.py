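"""Intrinsic-property battery for current-clamp sweeps.

The features mirror the standard CIN characterisation: input resistance from
a cubic fit to the (non-linear) I-V relationship evaluated at -60 mV,
rheobase (minimum 1 s step current evoking one AP), sag ratio of the -100 pA
step (peak early deflection over late steady deflection; > 1 indicates an
HCN-mediated sag), spontaneous rate and ISI coefficient of variation over
2 min windows, I-F curves, and per-spike AP features read from phase plots
(dV/dt as a function of V): threshold, amplitude from threshold, half-width,
maximal depolarisation/repolarisation rates, mAHP amplitude and half-width,
and the presence of a rising-limb indentation.

Voltage is in mV, time in s (ms where stated), dV/dt in mV/ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .containers import SweepRecording


def dvdt(V: np.ndarray, fs: float) -> np.ndarray:
    """Centered-difference voltage derivative in mV/ms."""
    d = np.gradient(np.asarray(V, dtype=float)) * fs / 1000.0
    return d


# ---------------------------------------------------------------------------
# Spike detection and firing statistics
# ---------------------------------------------------------------------------

def detect_spikes(sweep: SweepRecording, dvdt_crossing: float = 10.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Spike times (s) at upward crossings of a dV/dt threshold.

    One detection per AP, enforced with a refractory window.  The default
    10 mV/ms crossing sits well above subthreshold charging rates and well
    below CIN depolarisation rates (30-55 mV/ms).  The trace is smoothed
    with a 0.3 ms boxcar before differentiation so that sample-level
    recording noise cannot cross the detection threshold; feature
    extraction downstream works on the raw trace.
    """
    n_box = max(3, int(round(3e-4 * sweep.fs)))
    padded = np.pad(sweep.V, n_box, mode="edge")
    V_s = np.convolve(padded, np.ones(n_box) / n_box,
                      mode="same")[n_box:-n_box]
    d = dvdt(V_s, sweep.fs)
    above = d >= dvdt_crossing
    onsets = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    if onsets.size == 0:
        return np.empty(0)
    refr = refractory_ms / 1000.0
    times = onsets / sweep.fs
    kept = [times[0]]
    for s in times[1:]:
        if s - kept[-1] >= refr:
            kept.append(s)
    return np.asarray(kept)


@dataclass
class FiringStats:
    mean_rate: float
    cv_isi: float | None
    n_spikes: int
    window: float
    spontaneous: bool


def firing_stats(sweep: SweepRecording, window: float = 120.0,
                 dvdt_crossing: float = 10.0) -> FiringStats:
    """Mean firing rate and ISI coefficient of variation over a window.

    The window defaults to the 2 min span used for spontaneous-rate
    averaging.  CV requires at least 3 spikes; otherwise only the rate is
    reported.
    """
    window = min(window, sweep.duration)
    spikes = detect_spikes(sweep, dvdt_crossing)
    spikes = spikes[spikes < window]
    spontaneous = bool(np.allclose(sweep.I, 0.0))
    if len(spikes) < 3:
        return FiringStats(len(spikes) / window, None, len(spikes), window,
                           spontaneous)
    isis = np.diff(spikes)
    cv = float(np.std(isis, ddof=1) / np.mean(isis))
    return FiringStats(len(spikes) / window, cv, len(spikes), window,
                       spontaneous)


def if_curve(sweeps: list[SweepRecording], duration: float = 1.0
             ) -> list[tuple[float, float]]:
    """Intensity-frequency pairs: spikes during the step / step duration."""
    out = []
    for sw in sweeps:
        if sw.step is None:
            raise ValueError("sweep lacks a step descriptor")
        spikes = detect_spikes(sw)
        n = int(np.sum((spikes >= sw.step.t_on) & (spikes < sw.step.t_off)))
        out.append((sw.step.amplitude_pA, n / duration))
    return sorted(out)


# ---------------------------------------------------------------------------
# Passive properties
# ---------------------------------------------------------------------------

@dataclass
class IVCurve:
    points: list[tuple[float, float]]       # (I pA, steady-state V mV)
    cubic_coeffs: np.ndarray                # np.polyfit order: x^3 ... x^0
    R_N: float                              # MΩ
    eval_point: float                       # mV
    eval_I: float                           # pA where V(I) = eval_point


def _steady_state(sweep: SweepRecording, window_s: float = 0.1) -> float:
    """Mean voltage over the last ``window_s`` of the step."""
    if sweep.step is None:
        raise ValueError("sweep lacks a step descriptor")
    lo = int(round((sweep.step.t_off - window_s) * sweep.fs))
    hi = int(round(sweep.step.t_off * sweep.fs))
    return float(sweep.V[lo:hi].mean())


def fit_iv(sweeps: list[SweepRecording], eval_at: float = -60.0,
           steady_window_s: float = 0.1) -> IVCurve:
    """Cubic fit to the I-V relationship; R_N = dV/dI at ``eval_at`` mV.

    Steady-state voltage is the mean over the last 100 ms of each
    (subthreshold) step; sweeps containing spikes are excluded.  The input
    resistance is the derivative of the fitted third-order polynomial,
    evaluated at the current where the fit crosses ``eval_at`` (nearest
    fitted point with a warning when not bracketed), converted to MΩ.
    """
    pts = []
    for sw in sweeps:
        if detect_spikes(sw).size:
            continue
        pts.append((sw.step.amplitude_pA, _steady_state(sw, steady_window_s)))
    if len(pts) < 4:
        raise ValueError("need at least 4 subthreshold sweeps to fit a cubic")
    pts.sort()
    I = np.array([p[0] for p in pts])
    V = np.array([p[1] for p in pts])
    coeffs = np.polyfit(I, V, 3)
    # current where the cubic crosses the evaluation voltage
    roots = np.roots(coeffs - np.array([0, 0, 0, eval_at]))
    real = roots[np.abs(roots.imag) < 1e-9].real
    in_range = real[(real >= I.min()) & (real <= I.max())]
    if in_range.size:
        eval_I = float(in_range[np.argmin(np.abs(in_range))])
    else:
        warnings.warn("evaluation voltage not bracketed by the fitted I-V "
                      "range; using the nearest fitted point", stacklevel=2)
        eval_I = float(I[np.argmin(np.abs(V - eval_at))])
    deriv = np.polyval(np.polyder(coeffs), eval_I)  # mV/pA = GΩ
    return IVCurve(pts, coeffs, float(deriv * 1000.0), eval_at, eval_I)


def rheobase(sweeps: list[SweepRecording] | None = None, *,
             runner=None, amplitudes: np.ndarray | None = None,
             duration: float = 1.0) -> tuple[float, float]:
    """Minimum step current (pA) evoking at least one AP within the step.

    Accepts either a pre-recorded sweep family or a ``runner(amplitude)``
    callable with an amplitude grid (e.g. 5 pA steps).  Returns
    ``(rheobase_pA, grid_resolution_pA)``.
    """
    if sweeps is None:
        if runner is None or amplitudes is None:
            raise ValueError("provide sweeps, or runner plus amplitudes")
        amps = np.sort(np.asarray(amplitudes, float))
        resolution = float(np.min(np.diff(amps))) if len(amps) > 1 else 0.0
        # ascending search stops at the first spiking amplitude
        for a in amps:
            sw = runner(a)
            spikes = detect_spikes(sw)
            spikes = spikes[(spikes >= sw.step.t_on)
                            & (spikes < sw.step.t_on + duration)]
            if spikes.size:
                return float(a), resolution
        raise ValueError(f"no tested amplitude evoked a spike "
                         f"(max tested {amps.max():.1f} pA)")
    sweeps = sorted(sweeps, key=lambda s: s.step.amplitude_pA)
    amps = np.array([s.step.amplitude_pA for s in sweeps])
    resolution = float(np.min(np.diff(amps))) if len(amps) > 1 else 0.0
    for sw in sweeps:
        spikes = detect_spikes(sw)
        spikes = spikes[(spikes >= sw.step.t_on)
                        & (spikes < sw.step.t_on + duration)]
        if spikes.size:
            return float(sw.step.amplitude_pA), resolution
    raise ValueError(f"no tested amplitude evoked a spike "
                     f"(max tested {amps.max():.1f} pA)")


def sag_ratio(sweep: SweepRecording, early_window_s: float = 0.2,
              late_window_s: float = 0.1) -> float:
    """Peak early deflection over late steady deflection of a -100 pA step.

    The deflection is measured from the pre-step baseline; the peak is taken
    within the first 200 ms of the step and the steady value as the mean over
    its last 100 ms.  A ratio of 1 means no sag.
    """
    step = sweep.step
    if step is None:
        raise ValueError("sweep lacks a step descriptor")
    if step.amplitude_pA >= 0:
        raise ValueError("sag ratio is defined for hyperpolarizing steps")
    fs = sweep.fs
    i_on = int(round(step.t_on * fs))
    i_off = int(round(step.t_off * fs))
    baseline = float(sweep.V[max(0, i_on - int(0.05 * fs)):i_on].mean()) \
        if i_on > 0 else float(sweep.V[0])
    early = sweep.V[i_on:i_on + int(early_window_s * fs)]
    late = sweep.V[i_off - int(late_window_s * fs):i_off]
    peak_defl = baseline - early.min()
    steady_defl = baseline - late.mean()
    if steady_defl < 2.0:
        raise ValueError("deflection too small (< 2 mV) to measure sag")
    return float(peak_defl / steady_defl)


# ---------------------------------------------------------------------------
# Phase plots and AP features
# ---------------------------------------------------------------------------

@dataclass
class PhasePlot:
    """dV/dt(V) curves per spike, plus the pointwise mean ± SEM."""

    V: list[np.ndarray]
    dVdt: list[np.ndarray]
    t_rel: np.ndarray
    V_mean: np.ndarray
    V_sem: np.ndarray
    dVdt_mean: np.ndarray
    dVdt_sem: np.ndarray


def phase_plot(sweep: SweepRecording, spike_times: np.ndarray | None = None,
               pre_ms: float = 5.0, post_ms: float = 15.0) -> PhasePlot:
    """Extract (V, dV/dt) curves around each spike and average them.

    Spikes are aligned on their maximal depolarisation rate; windows that
    would extend beyond the sweep are skipped with a warning.  The mean and
    SEM are computed pointwise over aligned spikes, matching the usual
    presentation of averaged phase plots.
    """
    if spike_times is None:
        spike_times = detect_spikes(sweep)
    if len(spike_times) == 0:
        raise ValueError("no spikes to analyse")
    d = dvdt(sweep.V, sweep.fs)
    n_pre = int(round(pre_ms / 1000.0 * sweep.fs))
    n_post = int(round(post_ms / 1000.0 * sweep.fs))
    Vs, Ds = [], []
    for s in spike_times:
        k = int(round(s * sweep.fs))
        # align on the local max dV/dt near the detection
        lo = max(0, k - n_pre)
        hi = min(len(d), k + n_post)
        k_peak = lo + int(np.argmax(d[lo:hi]))
        if k_peak - n_pre < 0 or k_peak + n_post > len(d):
            warnings.warn("spike window truncated; spike skipped",
                          stacklevel=2)
            continue
        Vs.append(sweep.V[k_peak - n_pre:k_peak + n_post])
        Ds.append(d[k_peak - n_pre:k_peak + n_post])
    if not Vs:
        raise ValueError("all spike windows were truncated")
    Vm = np.mean(Vs, axis=0)
    Dm = np.mean(Ds, axis=0)
    nspk = len(Vs)
    Vsem = (np.std(Vs, axis=0, ddof=1) / np.sqrt(nspk) if nspk > 1
            else np.zeros_like(Vm))
    Dsem = (np.std(Ds, axis=0, ddof=1) / np.sqrt(nspk) if nspk > 1
            else np.zeros_like(Dm))
    t_rel = (np.arange(-n_pre, n_post)) / sweep.fs
    return PhasePlot(Vs, Ds, t_rel, Vm, Vsem, Dm, Dsem)


@dataclass
class APFeatureSet:
    threshold_V: float
    amplitude_from_threshold: float
    half_width: float            # ms
    max_depol_rate: float        # mV/ms
    max_repol_rate: float        # mV/ms, signed (negative)
    mahp_amplitude: float | None
    mahp_half_width: float | None
    indented: bool
    notch_prominence: float
    spike_time: float


def detect_indentation(V: np.ndarray, d: np.ndarray,
                       prominence_frac: float = 0.10
                       ) -> tuple[bool, float]:
    """Rising-limb indentation of the phase plot.

    The rising limb runs from threshold to the AP voltage peak; an
    indentation is a local maximum of dV/dt followed by a local minimum
    whose prominence is at least ``prominence_frac * max_depol_rate``.
    Returns ``(indented, prominence in mV/ms)``.
    """
    i_peak_v = int(np.argmax(V))
    rise = d[: i_peak_v + 1]
    if len(rise) < 10:
        return False, 0.0
    vmax = float(rise.max())
    troughs, props = find_peaks(-rise, prominence=0.005 * vmax)
    best = 0.0
    for t_idx, prom in zip(troughs, props["prominences"]):
        if 0 < t_idx < len(rise) - 1 and rise[:t_idx].max() > rise[t_idx]:
            best = max(best, float(prom))
    return best >= prominence_frac * vmax, best


def ap_features(sweep: SweepRecording, spike_time: float,
                threshold_frac: float = 0.04, mahp_window_s: float = 0.5,
                next_spike_time: float | None = None) -> APFeatureSet:
    """Full per-spike feature set from the voltage trace and its phase plot.

    Threshold is the rising-limb point where dV/dt first reaches
    ``threshold_frac`` (default 4%) of that spike's maximal depolarisation
    rate; amplitude is measured from threshold to peak, half-width at half of
    that amplitude, and the mAHP from threshold to the post-spike minimum
    within 500 ms (or until the next spike).
    """
    fs = sweep.fs
    d = dvdt(sweep.V, fs)
    k = int(round(spike_time * fs))
    n_scan = int(round(0.02 * fs))
    lo = max(0, k - n_scan // 4)
    hi = min(len(d), k + n_scan)
    k_dmax = lo + int(np.argmax(d[lo:hi]))
    vmax = float(d[k_dmax])
    # peak: first local V maximum after max depolarisation rate
    k_peak = k_dmax + int(np.argmax(sweep.V[k_dmax:k_dmax + n_scan]))
    # threshold: walk back from max dV/dt to the threshold_frac crossing
    k_thr = k_dmax
    while k_thr > 0 and d[k_thr] > threshold_frac * vmax:
        k_thr -= 1
    thr = float(sweep.V[k_thr])
    peak = float(sweep.V[k_peak])
    amp = peak - thr
    if amp <= 0:
        raise ValueError("non-positive AP amplitude; not a spike?")

    half_level = thr + amp / 2
    above = sweep.V[k_thr:] >= half_level
    i_up = k_thr + int(np.argmax(above))
    rest = np.flatnonzero(~above[i_up - k_thr:])
    if rest.size == 0:
        raise ValueError("half-amplitude down-crossing not found")
    i_down = i_up + int(rest[0])
    half_width = (i_down - i_up) / fs * 1000.0

    # repolarisation rate: most negative dV/dt between peak and half-recovery
    k_end_fall = i_down + int(np.argmax(sweep.V[i_down:] <= thr)) \
        if np.any(sweep.V[i_down:] <= thr) else len(sweep.V) - 1
    max_repol = float(d[k_peak:max(k_peak + 2, k_end_fall + 1)].min())

    # mAHP: minimum within the search window after the fall below threshold
    w_end = min(len(sweep.V), k_end_fall + int(mahp_window_s * fs))
    if next_spike_time is not None:
        w_end = min(w_end, int(round(next_spike_time * fs)))
    mahp_amp = mahp_hw = None
    if w_end > k_end_fall + 2:
        seg = sweep.V[k_end_fall:w_end]
        i_min = int(np.argmin(seg))
        v_min = float(seg[i_min])
        if v_min < thr - 0.05:
            mahp_amp = thr - v_min
            half = thr - mahp_amp / 2
            below = seg <= half
            if below.any():
                i_first = int(np.argmax(below))
                after_min = below[i_min:]
                if np.any(~after_min):
                    i_last = i_min + int(np.argmax(~after_min))
                    mahp_hw = (i_last - i_first) / fs * 1000.0
                else:
                    warnings.warn("mAHP half-recovery not reached within the "
                                  "window", stacklevel=2)
        else:
            warnings.warn("no post-spike minimum below threshold; mAHP "
                          "fields left empty", stacklevel=2)
    else:
        warnings.warn("no room after spike for mAHP analysis", stacklevel=2)

    indented, prom = detect_indentation(sweep.V[k_thr:k_peak + 1],
                                        d[k_thr:k_peak + 1])
    return APFeatureSet(thr, amp, half_width, vmax, max_repol, mahp_amp,
                        mahp_hw, indented, prom, spike_time)


def ap_features_batch(sweep: SweepRecording,
                      spike_times: np.ndarray | None = None,
                      **kwargs) -> list[APFeatureSet]:
    """``ap_features`` over all spikes of a sweep, passing each spike its
    successor to bound the mAHP search."""
    if spike_times is None:
        spike_times = detect_spikes(sweep)
    out = []
    for i, s in enumerate(spike_times):
        nxt = spike_times[i + 1] if i + 1 < len(spike_times) else None
        out.append(ap_features(sweep, s, next_spike_time=nxt, **kwargs))
    return out


def ahp_half_width(trace_V: np.ndarray, fs: float,
                   baseline: float | None = None) -> float:
    """Half-width (ms) of an AHP deflection given a trace starting near its
    onset: time between the two half-amplitude crossings around the minimum.

    ``baseline`` defaults to the first sample (the pre-AHP level).
    """
    V = np.asarray(trace_V, dtype=float)
    base = float(V[0]) if baseline is None else baseline
    i_min = int(np.argmin(V))
    amp = base - V[i_min]
    if amp < 1.0:
        raise ValueError("AHP amplitude below 1 mV")
    half = base - amp / 2
    below = V <= half
    i_first = int(np.argmax(below))
    after = ~below[i_min:]
    if not after.any():
        raise ValueError("second half-amplitude crossing not reached")
    i_last = i_min + int(np.argmax(after))
    return (i_last - i_first) / fs * 1000.0
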