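"""Widefield calcium-imaging response quantification.

Implements the imaging chain for whisker-stimulation trials recorded with
interleaved dual-wavelength illumination: a calcium-sensitive channel
(465 nm, GCaMP) and a calcium-insensitive channel (405 nm) that carries the
same hemodynamic artifact.  Steps: 4x4 spatial binning, optional linear
detrend + band filtering, per-pixel hemodynamic correction by ratio-scaled
subtraction of the 405 nm channel, dF/F0 against a 500 ms pre-stimulus
baseline, trial averaging, and the response metrics (peak, latency,
duration-to-20%, AUC, normalized AUC, active cortical area).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "DualChannelTrialSet",
    "ResponseTrace",
    "ResponseMetrics",
    "spatial_bin",
    "preprocess_trace",
    "hemodynamic_correct",
    "compute_dff",
    "trial_average",
    "response_metrics",
    "active_area",
    "analyze_session",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DualChannelTrialSet:
    """Per-trial frame stacks for the two illumination channels.

    ``ch465``/``ch405`` have shape ``(n_trials, n_frames, height, width)``;
    ``ch405`` is None for single-wavelength sessions.  ``frame_rate`` is the
    per-channel rate after de-interleaving; ``channel_offset_s`` records the
    half-sample timing offset between the interleaved wavelengths.
    ``pixel_size_um`` refers to the current pixel pitch and is scaled by
    :func:`spatial_bin`.
    """

    ch465: np.ndarray
    ch405: np.ndarray | None
    frame_rate: float
    stimulus_onset: float
    pixel_size_um: float = 30.0
    channel_offset_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ch465.ndim != 4:
            raise ValueError("ch465 must be (n_trials, n_frames, h, w)")
        if self.ch405 is not None and self.ch405.shape != self.ch465.shape:
            raise ValueError("channel shapes differ")
        if not 0 <= self.stimulus_onset < self.n_frames / self.frame_rate:
            raise ValueError("stimulus_onset outside trial")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_trials(self) -> int:
        return self.ch465.shape[0]

    @property
    def n_frames(self) -> int:
        return self.ch465.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def binned(self, factor: int = 4) -> "DualChannelTrialSet":
        """Spatially bin both channels, scaling the pixel size."""
        return replace(
            self,
            ch465=spatial_bin(self.ch465, factor),
            ch405=None if self.ch405 is None else spatial_bin(self.ch405, factor),
            pixel_size_um=self.pixel_size_um * factor,
        )


@dataclass
class ResponseTrace:
    """A dF/F0 time series with its stimulus onset."""

    time: np.ndarray
    dff: np.ndarray
    stimulus_onset: float
    roi: str = ""

    def __post_init__(self):
        if len(self.time) != len(self.dff):
            raise ValueError("time/dff length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class ResponseMetrics:
    """Session-level response metrics.

    ``auc`` is a plain sample sum of dF/F over the response duration
    (units dF/F * samples); ``auc_norm = auc/peak``.  ``area_mm2`` is filled
    by :func:`active_area`.  ``censored`` marks traces that never returned
    to 20% of peak; ``responsive`` is False when the post-stimulus peak is
    not positive.
    """

    peak: float
    latency: float
    duration: float
    auc: float
    auc_norm: float
    area_mm2: float = np.nan
    responsive: bool = True
    censored: bool = False

    def as_dict(self) -> dict:
        return {
            "peak": self.peak, "latency": self.latency, "duration": self.duration,
            "auc": self.auc, "auc_norm": self.auc_norm, "area_mm2": self.area_mm2,
            "responsive": self.responsive, "censored": self.censored,
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def spatial_bin(stack: np.ndarray, factor: int = 4) -> np.ndarray:
    """Bin the trailing two axes by block averaging.

    Each output pixel is the mean of its ``factor x factor`` block; leading
    axes (trials, frames) are untouched.  Dimensions not divisible by
    ``factor`` are cropped at the trailing edge (logged).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return np.asarray(stack)
    stack = np.asarray(stack)
    h, w = stack.shape[-2:]
    hc, wc = (h // factor) * factor, (w // factor) * factor
    if (hc, wc) != (h, w):
        logger.info("cropping frame from %dx%d to %dx%d before binning", h, w, hc, wc)
        stack = stack[..., :hc, :wc]
    new_shape = stack.shape[:-2] + (hc // factor, factor, wc // factor, factor)
    return stack.reshape(new_shape).mean(axis=(-3, -1))


def _zero_phase_highpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Second-order zero-phase high-pass that stays stable at extreme corners.

    For ordinary corners the Butterworth SOS is applied forward-backward.
    When the normalized corner is tiny (e.g. 0.01 Hz at tens of Hz) the
    filter poles sit so close to z = 1 that double-precision filtering is
    unstable, so instead the sub-cutoff baseline is estimated on a
    decimated copy (where the corner is well conditioned), interpolated
    back, and subtracted — the complementary low-pass route.
    """
    wn = cutoff / (fs / 2.0)
    if wn >= 1e-3:
        sos = signal.butter(2, cutoff, btype="highpass", fs=fs, output="sos")
        return signal.sosfiltfilt(sos, x, axis=0)
    n = x.shape[0]
    d = int(min(max(1, np.floor(0.02 / wn)), max(1, n // 12)))
    if d <= 1 or n // d < 6:
        # corner period far exceeds the record: beyond the linear trend
        # (already removed) there is nothing sub-cutoff to subtract
        return x
    idx = np.arange(0, n, d)
    coarse = x[idx]
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs / d, output="sos")
    padlen = min(3 * 5, len(idx) - 1)
    baseline_c = signal.sosfiltfilt(sos, coarse, axis=0, padlen=padlen)
    t_full = np.arange(n, dtype=float)
    if x.ndim == 1:
        baseline = np.interp(t_full, idx.astype(float), baseline_c)
    else:
        flat = baseline_c.reshape(len(idx), -1)
        baseline = np.stack(
            [np.interp(t_full, idx.astype(float), flat[:, j]) for j in range(flat.shape[1])],
            axis=1).reshape((n,) + x.shape[1:])
    return x - baseline


def preprocess_trace(series: np.ndarray, frame_rate: float,
                     highpass_hz: float = 0.01, lowpass_hz: float = 10.0) -> np.ndarray:
    """Linear detrend then zero-phase second-order Butterworth band filtering.

    The high-pass (default 0.01 Hz) and low-pass (default 10 Hz) filters are
    applied forward-backward (zero phase), so the effective magnitude
    response is the squared single-pass response.  Operates along the first
    axis.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("series too short to filter")
    if frame_rate <= 2 * lowpass_hz:
        raise ValueError("frame_rate must exceed twice the low-pass corner")
    out = signal.detrend(series, axis=0, type="linear")
    out = _zero_phase_highpass(out, frame_rate, highpass_hz)
    sos_lp = signal.butter(2, lowpass_hz, btype="lowpass", fs=frame_rate, output="sos")
    out = signal.sosfiltfilt(sos_lp, out, axis=0)
    return out


def hemodynamic_correct(stack465: np.ndarray, stack405: np.ndarray) -> np.ndarray:
    """Remove the hemodynamic artifact using the calcium-insensitive channel.

    The 405 nm signal is scaled per pixel by the ratio of temporal means,
    ``scale[y,x] = mean_t(465)/mean_t(405)``, and subtracted:
    ``corrected = 465 - scale * 405``.  Because both channels carry the same
    multiplicative blood-volume artifact, the subtraction cancels it while
    the calcium transient (present only at 465 nm) survives.  Pixels with a
    zero 405 nm mean are masked to NaN (logged).  Works on ``(t, h, w)``
    stacks or 1-d traces.
    """
    s465 = np.asarray(stack465, dtype=float)
    s405 = np.asarray(stack405, dtype=float)
    if s465.shape != s405.shape:
        raise ValueError("channel shapes must match")
    m465 = s465.mean(axis=0)
    m405 = s405.mean(axis=0)
    bad = m405 == 0
    if np.any(bad):
        logger.warning("masking %d pixels with zero 405 nm mean", int(np.sum(bad)))
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(bad, np.nan, m465 / m405)
    return s465 - scale * s405


def compute_dff(series: np.ndarray, frame_rate: float, stimulus_onset: float,
                pre_window: float = 0.5) -> np.ndarray:
    """dF/F0 with F0 the mean over the pre-stimulus baseline window.

    The baseline covers samples with ``stimulus_onset - pre_window <= t <
    stimulus_onset``.  Works per pixel on stacks (time on axis 0) or on 1-d
    traces.  A zero baseline raises, since the ratio is undefined.
    """
    series = np.asarray(series, dtype=float)
    t = np.arange(series.shape[0]) / frame_rate
    base = (t >= stimulus_onset - pre_window) & (t < stimulus_onset)
    if not base.any():
        raise ValueError("no samples in the pre-stimulus window")
    f0 = series[base].mean(axis=0)
    if np.any(f0 == 0):
        raise ZeroDivisionError("undefined baseline: F0 = 0")
    return (series - f0) / f0


def trial_average(trials) -> np.ndarray:
    """Pointwise mean across trials (first axis of a stacked array or a list)."""
    arrs = [np.asarray(a, dtype=float) for a in trials]
    if len(arrs) == 0:
        raise ValueError("need at least one trial")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("ragged trials: all trials must share a shape")
    return np.mean(arrs, axis=0)


def response_metrics(trace: ResponseTrace) -> ResponseMetrics:
    """Peak, latency, duration-to-20%, AUC and normalized AUC of a response.

    * peak — maximum dF/F at or after stimulus onset;
    * latency — time from stimulus to the peak sample;
    * duration — time from stimulus onset to the first post-peak sample with
      dF/F <= 20% of peak (censored at the trial end if never reached);
    * auc — sum of dF/F samples from onset through the duration endpoint;
    * auc_norm — auc / peak.
    """
    t, dff = trace.time, trace.dff
    post = t >= trace.stimulus_onset
    if not post.any():
        raise ValueError("no post-stimulus samples")
    idx_post = np.flatnonzero(post)
    i_peak = idx_post[np.argmax(dff[idx_post])]
    peak = float(dff[i_peak])
    if peak <= 0:
        return ResponseMetrics(peak=peak, latency=np.nan, duration=np.nan,
                               auc=np.nan, auc_norm=np.nan, responsive=False)
    latency = float(t[i_peak] - trace.stimulus_onset)
    after_peak = np.flatnonzero((np.arange(len(t)) > i_peak) & (dff <= 0.2 * peak))
    if len(after_peak):
        i_end = int(after_peak[0])
        censored = False
    else:
        i_end = len(t) - 1
        censored = True
    duration = float(t[i_end] - trace.stimulus_onset)
    sel = slice(idx_post[0], i_end + 1)
    auc = float(np.sum(dff[sel]))
    return ResponseMetrics(peak=peak, latency=latency, duration=duration,
                           auc=auc, auc_norm=auc / peak, censored=censored)


def active_area(dff_stack: np.ndarray, frame_rate: float, stimulus_onset: float,
                peak_time: float, pixel_size_um: float = 30.0) -> float:
    """Active cortical area (mm^2) from a stimulus-to-peak maximum projection.

    Frames from stimulus onset through the peak are max-projected; pixels
    exceeding the projection mean + 2 SD count as active; the count is
    converted with the pixel pitch.
    """
    if peak_time < stimulus_onset:
        raise ValueError("peak_time before stimulus_onset")
    t = np.arange(dff_stack.shape[0]) / frame_rate
    sel = (t >= stimulus_onset) & (t <= peak_time + 0.5 / frame_rate)
    if not sel.any():
        raise ValueError("empty stimulus-to-peak frame range")
    proj = np.nanmax(dff_stack[sel], axis=0)
    thr = np.nanmean(proj) + 2.0 * np.nanstd(proj)
    n_active = int(np.sum(proj > thr))
    px_mm = pixel_size_um / 1000.0
    return n_active * px_mm**2


# ---------------------------------------------------------------------------
# session pipeline
# ---------------------------------------------------------------------------

def analyze_session(
    trials: DualChannelTrialSet,
    roi_mask: np.ndarray | None = None,
    bin_factor: int = 4,
    correct: bool | None = None,
    preprocess: bool = False,
    pre_window: float = 0.5,
):
    """Full chain: bin, (optionally) filter, correct, dF/F, average, metrics.

    Per trial, the 405 nm channel is ratio-scaled and subtracted, the
    per-pixel temporal mean of the 465 nm channel is added back so the
    baseline fluorescence level (and hence F0) is preserved, and dF/F0 is
    computed against the pre-stimulus window.  Trials are then averaged,
    the ROI-mean trace is scored with :func:`response_metrics` and the
    active area is measured on the averaged dF/F stack.

    Parameters
    ----------
    roi_mask : boolean (h, w) mask *after binning*; defaults to the pixel
        with the largest trial-averaged response.
    correct : None selects automatically (True when a 405 nm channel exists).
    preprocess : apply linear detrend + band filters to each per-pixel trial
        series before correction.  Off by default for short trial epochs,
        where detrending a window dominated by the response biases the
        baseline; intended for drifting recordings.

    Returns ``(metrics, avg_trace, dff_avg_stack)``.
    """
    if correct is None:
        correct = trials.ch405 is not None
    if correct and trials.ch405 is None:
        raise ValueError("no 405 nm channel to correct with")
    ts = trials.binned(bin_factor) if bin_factor > 1 else trials
    dff_trials = np.empty_like(ts.ch465, dtype=float)
    for i in range(ts.n_trials):
        s465 = ts.ch465[i].astype(float)
        if preprocess:
            baseline465 = s465.mean(axis=0)
            s465 = preprocess_trace(s465, ts.frame_rate) + baseline465
        if correct:
            s405 = ts.ch405[i].astype(float)
            if preprocess:
                s405 = preprocess_trace(s405, ts.frame_rate) + ts.ch405[i].astype(float).mean(axis=0)
            corrected = hemodynamic_correct(s465, s405)
            # the corrected stack fluctuates about zero; restore the 465 nm
            # baseline level so F0 is well defined
            corrected = corrected + s465.mean(axis=0)
        else:
            corrected = s465
        dff_trials[i] = compute_dff(corrected, ts.frame_rate, ts.stimulus_onset, pre_window)
    dff_avg = trial_average(dff_trials)
    t = ts.times
    post = t >= ts.stimulus_onset
    if roi_mask is None:
        peak_img = dff_avg[post].max(axis=0)
        roi_mask = np.zeros(peak_img.shape, dtype=bool)
        roi_mask[np.unravel_index(np.nanargmax(peak_img), peak_img.shape)] = True
        roi_name = "auto-peak-pixel"
    else:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != dff_avg.shape[1:]:
            raise ValueError("roi_mask shape must match binned frame shape")
        roi_name = "mask"
    roi_trace = dff_avg[:, roi_mask].mean(axis=1)
    avg_trace = ResponseTrace(time=t, dff=roi_trace,
                              stimulus_onset=ts.stimulus_onset, roi=roi_name)
    metrics = response_metrics(avg_trace)
    if metrics.responsive:
        peak_time = ts.stimulus_onset + metrics.latency
        metrics.area_mm2 = active_area(dff_avg, ts.frame_rate, ts.stimulus_onset,
                                       peak_time, ts.pixel_size_um)
    return metrics, avg_trace, dff_avg
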