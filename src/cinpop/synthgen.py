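"""Synthetic ground-truth generator for every downstream analysis stage.

Striatal cholinergic interneurons (CINs) fire autonomously at 2-10 Hz, either
tonically, irregularly, or in bursts interspersed with pauses; their activity
is followed here either with a fast genetically encoded calcium indicator
(GCaMP6f-like kinetics, 6-10 frames/s) or with whole-cell current clamp.
This module emulates both recording modalities with known ground truth:

* spike trains as gamma-renewal processes (tonic/irregular) or a two-state
  burst/pause alternation;
* fluorescence traces as spike-triggered difference-of-exponentials kernels
  on a baseline, with additive Gaussian noise and optional slow drift, plus
  optionally a rendered TIFF-style movie with circular somatic ROIs;
* membrane responses to 1 s current steps from a leaky integrator with an
  optional HCN-like sag component and stereotyped action-potential waveforms
  spliced in at threshold crossings.

Everything is driven by one seeded generator per scenario, so identical
scenario + seed gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .containers import (EventRaster, FluorescenceTraceSet, StepProtocol,
                         SweepRecording)

PATTERNS = ("tonic", "irregular", "burst_pause")


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Sorted spike times (s) in [0, duration] with their generating recipe."""

    spike_times: np.ndarray
    duration: float
    pattern: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.size and (np.any(np.diff(st) <= 0) or st[0] < 0
                        or st[-1] > self.duration):
            raise ValueError("spike times must be strictly increasing "
                             "within [0, duration]")
        self.spike_times = st

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.duration

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    @property
    def cv_isi(self) -> float:
        isis = self.isis
        if len(isis) < 2:
            return float("nan")
        return float(np.std(isis, ddof=1) / np.mean(isis))


def _gamma_isis(rng: np.random.Generator, rate: float, cv: float,
                n: int) -> np.ndarray:
    if cv == 0:
        return np.full(n, 1.0 / rate)
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, 1.0 / (rate * shape), size=n)


def make_spike_train(pattern: str, rate: float, cv: float | None = None,
                     duration: float = 600.0, seed: int | None = None, *,
                     burst_rate: float | None = None, burst_len: float = 1.0,
                     pause_len: float = 2.0, min_isi: float = 0.0) -> SpikeTrain:
    """Generate a spike train of a given firing regime.

    ``tonic`` and ``irregular`` are gamma-renewal processes whose ISI
    coefficient of variation is set via the gamma shape (CV = 1/sqrt(shape));
    they differ only in default CV (0.1 vs 1.0).  ``burst_pause`` alternates
    exponential-length burst states (gamma firing at ``burst_rate``) with
    exponential-length silent pauses; ``burst_rate`` defaults to the value
    that makes the long-run mean rate equal the requested ``rate``.

    Parameters
    ----------
    rate : float
        Target mean firing rate in Hz (CINs: 2-10 Hz).
    cv : float, optional
        ISI coefficient of variation of the renewal process (or of the
        within-burst process for ``burst_pause``).
    min_isi : float
        If positive, spikes closer than this to the previous kept spike are
        dropped (useful to guarantee imaging-resolvable events).
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}")
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if cv is None:
        cv = {"tonic": 0.1, "irregular": 1.0, "burst_pause": 0.5}[pattern]
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)

    if pattern in ("tonic", "irregular"):
        n = int(rate * duration * 1.5) + 50
        times = np.cumsum(_gamma_isis(rng, rate, cv, n))
        while times[-1] <= duration:  # pragma: no cover - rare tail top-up
            times = np.concatenate(
                [times, times[-1] + np.cumsum(_gamma_isis(rng, rate, cv, n))])
        times = times[times <= duration]
    else:
        if burst_len <= 0 or pause_len <= 0:
            raise ValueError("burst_len and pause_len must be positive")
        duty = burst_len / (burst_len + pause_len)
        if burst_rate is None:
            burst_rate = rate / duty
        times_list: list[np.ndarray] = []
        t = 0.0
        # start in burst or pause with stationary probability
        in_burst = rng.random() < duty
        while t < duration:
            if in_burst:
                blen = rng.exponential(burst_len)
                n = int(burst_rate * blen * 2) + 10
                spk = t + np.cumsum(_gamma_isis(rng, burst_rate, cv, n))
                times_list.append(spk[spk < min(t + blen, duration)])
                t += blen
            else:
                t += rng.exponential(pause_len)
            in_burst = not in_burst
        times = np.concatenate(times_list) if times_list else np.empty(0)

    if min_isi > 0 and times.size:
        kept = [times[0]]
        for s in times[1:]:
            if s - kept[-1] >= min_isi:
                kept.append(s)
        times = np.asarray(kept)
    params = {"rate": rate, "cv": cv, "seed": seed, "burst_rate": burst_rate,
              "burst_len": burst_len, "pause_len": pause_len,
              "min_isi": min_isi}
    return SpikeTrain(times, duration, pattern, params)


def snap_to_frame_centers(train: SpikeTrain, fps: float) -> SpikeTrain:
    """Move each spike to the centre of its movie frame (deduplicated).

    Inference-validation scenarios use this so every spike sits a full rise
    time away from its frame boundary: the fluorescence rise then registers
    within the spike's own frame and the inferred raster can match the
    ground truth exactly.  Spikes arriving within the same frame merge, and
    spikes in the final frame are dropped (their rise would fall beyond the
    last sample, invisible to the forward difference).
    """
    frames = np.unique(np.floor(train.spike_times * fps).astype(int))
    last = int(round(train.duration * fps)) - 1
    frames = frames[frames < last]
    times = (frames + 0.5) / fps
    return replace(train, spike_times=times)


def enforce_min_isi(train: SpikeTrain, min_isi: float) -> SpikeTrain:
    """Drop spikes closer than ``min_isi`` to the previously kept spike."""
    if not train.spike_times.size:
        return train
    kept = [train.spike_times[0]]
    for s in train.spike_times[1:]:
        if s - kept[-1] >= min_isi:
            kept.append(s)
    return replace(train, spike_times=np.asarray(kept))


# ---------------------------------------------------------------------------
# Fluorescence forward model
# ---------------------------------------------------------------------------

@dataclass
class ImagingScenario:
    """A population imaging session with known ground truth.

    Fluorescence is modelled per cell as
    ``F(t) = F0 * (1 + sum_k kernel(t - t_k) + drift + noise)`` where the
    kernel is a difference of exponentials normalised to peak ``amplitude``
    (ΔF/F0 units): fast rise (``rise_tau``), slow decay (``decay_tau``),
    GCaMP6f-like by default.  ``ensemble_events`` force a coincident spike in
    each listed member cell at the stated time (optionally jittered by up to
    ``ensemble_jitter_frames`` frames per member).
    """

    n_cells: int
    duration: float = 600.0
    fps: float = 10.0
    trains: list[SpikeTrain] | None = None
    ensemble_events: list[tuple[float, Sequence[int]]] = field(default_factory=list)
    rise_tau: float = 0.05
    decay_tau: float = 0.5
    amplitude: float = 0.2
    noise_sd: float = 0.02
    baseline_F0: float | np.ndarray = 100.0
    drift_per_s: float = 0.0
    ensemble_jitter_frames: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("kernel taus must be positive")
        if self.rise_tau >= self.decay_tau:
            raise ValueError("rise_tau must be smaller than decay_tau")
        if round(self.fps * self.duration) < 2:
            raise ValueError("scenario must span at least 2 frames")
        if not (6 <= self.fps <= 10):
            warnings.warn("fps outside the typical 6-10 frames/s range",
                          stacklevel=2)
        for t_ev, members in self.ensemble_events:
            for m in members:
                if not 0 <= m < self.n_cells:
                    raise ValueError(f"ensemble member {m} is not a valid "
                                     f"cell index")
            if not 0 <= t_ev <= self.duration:
                raise ValueError("ensemble event time outside recording")
        if self.trains is not None and len(self.trains) != self.n_cells:
            raise ValueError("need one spike train per cell")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


def _kernel(t: np.ndarray, rise: float, decay: float, amp: float) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalised to ``amp``."""
    tp = np.log(decay / rise) * rise * decay / (decay - rise)
    norm = np.exp(-tp / decay) - np.exp(-tp / rise)
    out = np.where(t > 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    return amp * out / norm


def _spike_lists(scenario: ImagingScenario,
                 rng: np.random.Generator) -> list[np.ndarray]:
    if scenario.trains is not None:
        spikes = [t.spike_times.copy() for t in scenario.trains]
    else:
        spikes = [make_spike_train("irregular", 2.0, duration=scenario.duration,
                                   seed=int(rng.integers(2 ** 31))).spike_times
                  for _ in range(scenario.n_cells)]
    fps = scenario.fps
    for t_ev, members in scenario.ensemble_events:
        for m in members:
            t_m = t_ev
            if scenario.ensemble_jitter_frames:
                t_m += rng.integers(-scenario.ensemble_jitter_frames,
                                    scenario.ensemble_jitter_frames + 1) / fps
            t_m = min(max(t_m, 0.0), np.nextafter(scenario.duration, 0))
            spikes[m] = np.unique(np.append(spikes[m], t_m))
    return spikes


def ground_truth_raster(scenario: ImagingScenario,
                        spikes: list[np.ndarray] | None = None,
                        condition_tag: str = "truth") -> EventRaster:
    """Binary raster marking the frame containing each spike."""
    if spikes is None:
        spikes = _spike_lists(scenario, np.random.default_rng(scenario.seed))
    n_frames = scenario.n_frames
    A = np.zeros((scenario.n_cells, n_frames), dtype=np.uint8)
    for i, st in enumerate(spikes):
        frames = np.clip(np.floor(st * scenario.fps).astype(int), 0,
                         n_frames - 1)
        A[i, frames] = 1
    return EventRaster(A, scenario.fps, condition_tag=condition_tag)


def render_fluorescence(scenario: ImagingScenario
                        ) -> tuple[FluorescenceTraceSet, EventRaster]:
    """Render traces for a scenario; returns (traces, ground-truth raster).

    Frames are sampled at t_j = j/fps, so a spike in frame k (k = floor(t*fps))
    first raises the fluorescence sampled at frame k+1 and the forward
    difference flags frame k — consistent with the ground-truth raster.
    """
    rng = np.random.default_rng(scenario.seed)
    spikes = _spike_lists(scenario, rng)
    truth = ground_truth_raster(scenario, spikes)
    n_frames = scenario.n_frames
    t_frames = np.arange(n_frames) / scenario.fps
    F0 = np.broadcast_to(np.atleast_1d(np.asarray(scenario.baseline_F0,
                                                  dtype=float)),
                         (scenario.n_cells,))
    F = np.empty((scenario.n_cells, n_frames))
    for i, st in enumerate(spikes):
        sig = np.zeros(n_frames)
        for s in st:
            j0 = int(np.floor(s * scenario.fps)) + 1
            if j0 >= n_frames:
                continue
            # transient is negligible after ~8 decay constants
            j1 = min(n_frames, j0 + int(8 * scenario.decay_tau
                                        * scenario.fps) + 2)
            sig[j0:j1] += _kernel(t_frames[j0:j1] - s, scenario.rise_tau,
                                  scenario.decay_tau, scenario.amplitude)
        rel = 1.0 + sig + scenario.drift_per_s * t_frames
        if scenario.noise_sd > 0:
            rel = rel + rng.normal(0.0, scenario.noise_sd, size=n_frames)
        F[i] = F0[i] * rel
    np.clip(F, 0.0, None, out=F)
    traces = FluorescenceTraceSet(F, scenario.fps,
                                  background=np.array(F0, dtype=float))
    return traces, truth


# ---------------------------------------------------------------------------
# Movie rendering (ROI-extraction test path)
# ---------------------------------------------------------------------------

def render_movie(scenario: ImagingScenario, roi_radius: int = 6,
                 field: tuple[int, int] = (128, 128),
                 background_level: float = 50.0,
                 centers: Sequence[tuple[int, int]] | None = None):
    """Render a 16-bit movie with disk-shaped somata plus the ROI table.

    Returns ``(movie, roi_table, traces, truth)`` where ``movie`` is a
    (frames, H, W) uint16 stack, and ``roi_table`` a DataFrame with columns
    id, x, y, radius, is_chat_positive.  Mean pixel intensity inside each disk
    reproduces the cell's fluorescence trace up to uint16 quantisation.
    """
    import pandas as pd

    traces, truth = render_fluorescence(scenario)
    H, W = field
    n = scenario.n_cells
    if centers is None:
        margin = roi_radius + 3
        cols = max(1, int(np.ceil(np.sqrt(n))))
        rows = int(np.ceil(n / cols)) if n else 0
        xs = np.linspace(margin, W - 1 - margin, cols) if n else []
        ys = np.linspace(margin, H - 1 - margin, rows) if n else []
        centers = [(int(round(xs[k % cols])), int(round(ys[k // cols])))
                   for k in range(n)]
    if len(centers) != n:
        raise ValueError("need one center per cell")
    for x, y in centers:
        if (x - roi_radius < 0 or x + roi_radius >= W
                or y - roi_radius < 0 or y + roi_radius >= H):
            raise ValueError("ROI does not fit inside the field")
    for a in range(n):
        for b in range(a + 1, n):
            d = np.hypot(centers[a][0] - centers[b][0],
                         centers[a][1] - centers[b][1])
            if d < 2 * roi_radius + 1:
                raise ValueError("ROIs overlap")

    yy, xx = np.mgrid[0:H, 0:W]
    movie = np.full((traces.n_frames, H, W), background_level, dtype=float)
    for i, (x, y) in enumerate(centers):
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= roi_radius ** 2
        movie[:, mask] = traces.F[i][:, None]
    movie = np.clip(np.round(movie), 0, 65535).astype(np.uint16)
    roi_table = pd.DataFrame({
        "id": traces.cell_ids,
        "x": [c[0] for c in centers],
        "y": [c[1] for c in centers],
        "radius": roi_radius,
        "is_chat_positive": [lab == "chat_pos" for lab in traces.cell_labels],
    })
    return movie, roi_table, traces, truth


def write_movie(movie: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, movie)


# ---------------------------------------------------------------------------
# Membrane and action-potential synthesis
# ---------------------------------------------------------------------------

@dataclass
class APShapeParams:
    """Stereotyped action-potential shape, mirroring the extracted features.

    Units: mV, ms, mV/ms.  ``indented`` inserts a notch (local dip of depth
    ``notch_depth * max_depol_rate``) in dV/dt on the rising limb, the
    signature of axon-initial-segment spike initiation.
    """

    threshold: float = -41.2
    amplitude_from_threshold: float = 56.0
    half_width: float = 5.0
    max_depol_rate: float = 40.0
    max_repol_rate: float = 12.0
    mahp_amplitude: float = 8.0
    mahp_half_width: float = 200.0
    indented: bool = False
    notch_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_from_threshold <= 0 or self.half_width <= 0:
            raise ValueError("amplitude and half_width must be positive")
        if self.max_depol_rate <= 0 or self.max_repol_rate <= 0:
            raise ValueError("rates must be positive (repol given unsigned)")
        if not 0 <= self.notch_depth < 1:
            raise ValueError("notch_depth must be in [0, 1)")
        if self.indented != (self.notch_depth > 0):
            raise ValueError("notch_depth must be > 0 iff indented")
        if self.mahp_amplitude < 0:
            raise ValueError("mahp_amplitude must be non-negative")


_NOTCH_LO, _NOTCH_HI = 0.4, 0.6  # of rise duration


def _rise_profile(tau: np.ndarray, depth: float) -> np.ndarray:
    """Unit-peak dV/dt profile of the rising limb on tau in [0, 1].

    The notch is a raised-cosine dip carved around the velocity peak, where
    the half-sine is flat, so the resulting phase-plot trough prominence is
    close to ``depth`` times the maximal rate (the flanking local maxima stay
    near the peak rate).
    """
    f = np.sin(np.pi * tau)
    if depth > 0:
        inside = (tau >= _NOTCH_LO) & (tau <= _NOTCH_HI)
        w = np.zeros_like(f)
        w[inside] = np.sin(np.pi * (tau[inside] - _NOTCH_LO)
                           / (_NOTCH_HI - _NOTCH_LO)) ** 2
        f = f - depth * w
    return f


def min_half_width(p: APShapeParams, fs: float = 50_000.0) -> float:
    """Smallest realisable half-width (ms) for given rates and amplitude.

    The rise and fall limbs alone spend a fixed time above half amplitude
    (set by amplitude and max dV/dt); ``half_width`` beyond this minimum is
    absorbed by a flat peak plateau.
    """
    w = make_ap_waveform(replace(p, half_width=1e9), fs, _measure_only=True)
    return w


def make_ap_waveform(p: APShapeParams, fs: float = 50_000.0,
                     _measure_only: bool = False) -> np.ndarray:
    """Synthesise one AP voltage trace (mV) sampled at ``fs`` Hz.

    The waveform starts at threshold with zero velocity, rises with a
    half-sine dV/dt profile peaking at ``max_depol_rate`` (with an optional
    notch), holds a flat plateau at the peak to realise the requested
    half-width, repolarises with a half-sine profile peaking at
    ``max_repol_rate``, then descends into a raised-cosine mAHP lobe of the
    requested amplitude and half-width that recovers to
    ``threshold - 0.25 * mahp_amplitude``.
    """
    dt = 1000.0 / fs  # ms per sample
    A, vd, vr = p.amplitude_from_threshold, p.max_depol_rate, p.max_repol_rate
    depth = p.notch_depth if p.indented else 0.0

    # --- rising limb: integrate the unit profile on a midpoint grid
    tau_fine = np.linspace(0, 1, 4001)
    f_fine = _rise_profile(tau_fine, depth)
    T_r = A * f_fine.max() / (vd * np.trapezoid(f_fine, tau_fine))  # ms
    n_r = max(int(round(T_r / dt)), 8)
    tau_mid = (np.arange(n_r) + 0.5) / n_r
    v_rise = (vd / f_fine.max()) * _rise_profile(tau_mid, depth)
    rise = np.concatenate([[0.0], np.cumsum(v_rise) * (T_r / n_r)])
    rise *= A / rise[-1]  # exact amplitude
    rise = p.threshold + rise

    # --- falling limb: half-sine velocity, peak -> threshold
    T_f = np.pi * A / (2 * vr)
    n_f = max(int(round(T_f / dt)), 8)
    tau_mid = (np.arange(n_f) + 0.5) / n_f
    v_fall = -vr * np.sin(np.pi * tau_mid)
    fall = np.cumsum(v_fall) * (T_f / n_f)
    fall *= A / -fall[-1]
    fall = p.threshold + A + fall

    # time above half amplitude contributed by rise and fall
    half_level = p.threshold + A / 2
    t_r_half = dt * np.sum(rise >= half_level)
    t_f_half = dt * np.sum(fall >= half_level)
    if _measure_only:
        return (t_r_half + t_f_half)
    if p.half_width < 10 * dt:
        raise ValueError("half_width not resolvable at this sampling rate")
    n_p = int(round((p.half_width - t_r_half - t_f_half) / dt))
    if n_p < 0:
        if (t_r_half + t_f_half - p.half_width) > 0.05 * p.half_width:
            raise ValueError(
                f"half_width {p.half_width:.2f} ms is below the "
                f"{t_r_half + t_f_half:.2f} ms floor set by the amplitude "
                f"and dV/dt rates")
        n_p = 0
    plateau = np.full(n_p, p.threshold + A)

    # --- mAHP lobe: raised-cosine down/up with exact half-width
    segs = [rise, plateau, fall[:-1]]
    if p.mahp_amplitude > 0:
        m, hw = p.mahp_amplitude, p.mahp_half_width
        end_level = p.threshold - 0.25 * m
        T1 = 0.6 * hw
        # ascending limb recovers 0.75*m; it crosses half amplitude where the
        # raised cosine has completed acos(-1/3)/pi of its course
        frac_up = np.arccos(-1.0 / 3.0) / np.pi
        T2 = (hw - T1 / 2) / frac_up
        n1 = max(int(round(T1 / dt)), 4)
        n2 = max(int(round(T2 / dt)), 4)
        t1 = np.arange(1, n1 + 1) * dt / T1
        down = (p.threshold - m) + m * (1 + np.cos(np.pi * np.clip(t1, 0, 1))) / 2
        t2 = np.arange(1, n2 + 1) * dt / T2
        up = end_level - 0.75 * m * (1 + np.cos(np.pi * np.clip(t2, 0, 1))) / 2
        tail = np.full(int(round(50.0 / dt)), end_level)
        segs += [down, up, tail]
    else:
        segs += [np.full(int(round(20.0 / dt)), p.threshold)]
    return np.concatenate(segs)


@dataclass
class MembraneScenario:
    """Passive membrane plus stereotyped-AP parameters for sweep synthesis.

    A leaky integrator (R_m MΩ, tau_m ms, resting E_L mV) with a
    hyperpolarisation-activated sag: ``sag_fraction`` sets the peak/steady
    deflection ratio of a -100 pA step to ``1 / (1 - sag_fraction)``.
    Suprathreshold steps splice the APShapeParams waveform at each crossing
    of ``V_th``.
    """

    R_m: float = 235.6
    tau_m: float = 30.0
    E_L: float = -60.0
    V_th: float = -47.0
    reset: float | None = None
    sag_fraction: float = 0.0
    sag_tau: float = 40.0
    ap_shape: APShapeParams = field(default_factory=APShapeParams)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.R_m <= 0 or self.tau_m <= 0:
            raise ValueError("R_m and tau_m must be positive")
        if not 0 <= self.sag_fraction < 1:
            raise ValueError("sag_fraction must be in [0, 1)")


def sag_fraction_for_ratio(ratio: float) -> float:
    """Sag fraction giving a requested peak/steady-state deflection ratio."""
    if ratio < 1:
        raise ValueError("sag ratio must be >= 1")
    return 1.0 - 1.0 / ratio


def subthreshold_response(ms: MembraneScenario, amplitude_pA: float,
                          t: np.ndarray, t_on: float, t_off: float
                          ) -> np.ndarray:
    """Closed-form noiseless voltage (mV) for a subthreshold step.

    Base response is the RC charging curve; for hyperpolarising steps with
    ``sag_fraction > 0`` a relaxing bi-exponential sag component is added,
    scaled (by root finding) so that peak/steady deflection equals
    ``1 / (1 - sag_fraction)`` for a 1 s step.
    """
    tau = ms.tau_m / 1000.0  # s
    D_ss = ms.R_m * amplitude_pA / 1000.0  # mV
    V = np.full_like(t, ms.E_L, dtype=float)
    on = (t >= t_on) & (t < t_off)
    te = t[on] - t_on
    base = 1.0 - np.exp(-te / tau)
    defl = base.copy()
    if amplitude_pA < 0 and ms.sag_fraction > 0:
        T = t_off - t_on
        tau_s = ms.sag_tau / 1000.0
        grid = np.linspace(0, T, 2001)
        b = 1.0 - np.exp(-grid / tau)
        w = np.exp(-grid / tau_s) - np.exp(-grid / tau)
        target = 1.0 / (1.0 - ms.sag_fraction)

        def excess(g: float) -> float:
            d = b + g * w
            return d.max() / d[-1] - target

        g = brentq(excess, 0.0, 200.0)
        defl = base + g * (np.exp(-te / tau_s) - np.exp(-te / tau))
    V[on] = ms.E_L + D_ss * defl
    after = t >= t_off
    if after.any():
        idx_off = np.searchsorted(t, t_off)
        v_off = V[idx_off - 1] if idx_off > 0 else ms.E_L
        V[after] = ms.E_L + (v_off - ms.E_L) * np.exp(-(t[after] - t_off) / tau)
    return V


def simulate_current_step(ms: MembraneScenario, amplitude_pA: float,
                          t_on: float = 0.2, t_off: float = 1.2,
                          fs: float = 20_000.0, total: float | None = None
                          ) -> SweepRecording:
    """Simulate one current-clamp sweep for a square step.

    Subthreshold responses follow the closed-form RC(+sag) solution exactly;
    suprathreshold responses are integrated with the exact exponential update
    of the leaky integrator, splicing the stereotyped AP waveform (including
    its mAHP lobe) at each threshold crossing and resuming from the waveform's
    end level.
    """
    if not t_on < t_off:
        raise ValueError("t_on must precede t_off")
    if total is None:
        total = t_off + 0.3
    if t_off > total:
        raise ValueError("step must end within the sweep")
    n = int(round(total * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(ms.seed)

    # would the step reach threshold?  steady-state test is sufficient here
    v_inf_step = ms.E_L + ms.R_m * amplitude_pA / 1000.0
    spikes: list[float] = []
    if v_inf_step < ms.V_th or amplitude_pA <= 0:
        V = subthreshold_response(ms, amplitude_pA, t, t_on, t_off)
    else:
        wav = make_ap_waveform(ms.ap_shape, fs)
        reset = ms.reset if ms.reset is not None else float(wav[-1])
        V = np.empty(n)
        decay = np.exp(-1.0 / (fs * ms.tau_m / 1000.0))
        v = ms.E_L
        k = 0
        while k < n:
            V[k] = v
            if v >= ms.V_th and t_on <= t[k] < t_off:
                spikes.append(t[k])
                m = min(len(wav), n - k)
                V[k:k + m] = wav[:m]
                k += m
                v = reset
                continue
            v_inf = ms.E_L + (amplitude_pA if t_on <= t[k] < t_off else 0.0) \
                * ms.R_m / 1000.0
            v = v_inf + (v - v_inf) * decay
            k += 1
    if ms.noise_sd > 0:
        V = V + rng.normal(0.0, ms.noise_sd, size=n)
    step = StepProtocol(amplitude_pA, t_on, t_off)
    return SweepRecording(t, V, step.current(t), fs, step, ms.E_L)


def lif_rheobase(ms: MembraneScenario, duration: float = 1.0) -> float:
    """Analytic minimal step current (pA) driving the LIF to threshold in
    ``duration`` seconds: I = 1000 * (V_th - E_L) / (R_m * (1 - e^(-T/tau)))."""
    tau = ms.tau_m / 1000.0
    return 1000.0 * (ms.V_th - ms.E_L) / (ms.R_m * (1 - np.exp(-duration / tau)))


def simulate_spontaneous(ms: MembraneScenario, spike_times: np.ndarray,
                         duration: float, fs: float = 20_000.0
                         ) -> SweepRecording:
    """Render a zero-current sweep with stereotyped APs at given times.

    Between APs the voltage sits at the waveform's inter-spike level; each
    spike is preceded by a 20 ms smooth depolarising ramp to threshold.  Used
    to emulate the spontaneous-firing recordings from which AP features,
    rate, and ISI statistics are measured.
    """
    p = ms.ap_shape
    wav = make_ap_waveform(p, fs)
    base = float(wav[-1])
    n = int(round(duration * fs))
    V = np.full(n, base)
    ramp_n = int(round(0.020 * fs))
    ramp = base + (p.threshold - base) * (1 - np.cos(
        np.pi * np.arange(ramp_n) / ramp_n)) / 2
    for s in np.asarray(spike_times, dtype=float):
        k = int(round(s * fs))
        r0 = max(0, k - ramp_n)
        V[r0:k] = ramp[ramp_n - (k - r0):]
        m = min(len(wav), n - k)
        if m > 0:
            V[k:k + m] = wav[:m]
    if ms.noise_sd > 0:
        rng = np.random.default_rng(ms.seed)
        V = V + rng.normal(0.0, ms.noise_sd, size=n)
    t = np.arange(n) / fs
    return SweepRecording(t, V, np.zeros(n), fs, None, base)
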