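"""Photostimulation input-map construction for slice recordings.

Glutamate-uncaging photostimulation is applied over a grid of sites
(default 15 depth rows x 28 columns) while recording EPSCs from a single
L4 neuron.  For each site, the peak amplitudes of inward-current events
whose onset falls within a post-stimulus window (default 150 ms) are
summed, producing an input map; sites are then grouped by cortical layer
and by home-column membership (intracolumnar vs transcolumnar) and
averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PhotostimRecording",
    "InputMap",
    "detect_epsc_events",
    "build_input_map",
    "bin_input_map",
]


@dataclass
class PhotostimRecording:
    """Per-site current traces on a stimulation grid.

    ``traces`` has shape ``(n_rows, n_cols, n_samples)`` in pA (inward
    currents negative); ``laminar_borders`` maps layer names to half-open
    row ranges ``(lo, hi)`` ordered pia to white matter; ``home_columns``
    is the half-open column range of the recorded cell's barrel column.
    """

    traces: np.ndarray
    sample_rate: float
    stim_time: float
    laminar_borders: dict[str, tuple[int, int]]
    home_columns: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.traces.ndim != 3:
            raise ValueError("traces must be (n_rows, n_cols, n_samples)")
        lo_prev = -1
        for name, (lo, hi) in self.laminar_borders.items():
            if lo < lo_prev:
                raise ValueError("laminar borders must be ordered pia to white matter")
            lo_prev = lo

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.traces.shape[:2]


@dataclass
class InputMap:
    """Per-site summed EPSC amplitude (pA) plus grid annotations."""

    site_sum: np.ndarray
    laminar_borders: dict[str, tuple[int, int]]
    home_columns: tuple[int, int]

    def layer_of_row(self, row: int) -> str:
        for name, (lo, hi) in self.laminar_borders.items():
            if lo <= row < hi:
                return name
        raise ValueError(f"row {row} not covered by laminar borders")


def detect_epsc_events(
    trace: np.ndarray,
    sample_rate: float,
    stim_time: float,
    window: float = 0.150,
    threshold: float | None = None,
    veto_window: float = 0.0,
    lowpass_hz: float = 1000.0,
) -> pd.DataFrame:
    """Detect inward-current events with onset inside the response window.

    The trace is low-pass filtered, and contiguous runs below ``-threshold``
    (default 3x the pre-stimulus baseline SD, floored at 1 pA for noiseless
    traces) whose onset lies within ``(stim_time + veto_window,
    stim_time + window]`` become events; the event amplitude is the absolute
    peak within the run.  The optional early-latency veto discards direct
    somatic responses.  Returns a DataFrame ``(onset_s, peak_s,
    amplitude_pa)``.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    t = np.arange(n) / sample_rate
    if not (0 <= stim_time < t[-1]) or stim_time + window > t[-1] + 1e-12:
        raise ValueError("response window must lie within the sweep")
    if lowpass_hz < sample_rate / 2:
        sos = signal.butter(2, lowpass_hz, btype="lowpass", fs=sample_rate, output="sos")
        filt = signal.sosfiltfilt(sos, trace)
    else:
        filt = trace
    if threshold is None:
        base = filt[t < stim_time]
        threshold = max(3.0 * base.std(), 1.0)
    below = filt < -threshold
    if not below.any():
        return pd.DataFrame(columns=["onset_s", "peak_s", "amplitude_pa"])
    # contiguous runs of sub-threshold samples
    edges = np.diff(below.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.concatenate([[0], starts])
    if below[-1]:
        ends = np.concatenate([ends, [n]])
    rows = []
    lo = stim_time + veto_window
    hi = stim_time + window
    for s, e in zip(starts, ends):
        onset = t[s]
        if not (lo < onset <= hi):
            continue
        i_peak = s + int(np.argmin(filt[s:e]))
        rows.append((onset, t[i_peak], float(-filt[i_peak])))
    return pd.DataFrame(rows, columns=["onset_s", "peak_s", "amplitude_pa"])


def build_input_map(rec: PhotostimRecording, window: float = 0.150,
                    threshold: float | None = None,
                    veto_window: float = 0.0) -> InputMap:
    """Sum detected event amplitudes at every stimulation site."""
    n_rows, n_cols = rec.grid_shape
    site_sum = np.zeros((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            ev = detect_epsc_events(rec.traces[r, c], rec.sample_rate,
                                    rec.stim_time, window=window,
                                    threshold=threshold, veto_window=veto_window)
            site_sum[r, c] = ev["amplitude_pa"].sum()
    return InputMap(site_sum=site_sum, laminar_borders=rec.laminar_borders,
                    home_columns=rec.home_columns)


def bin_input_map(imap: InputMap) -> pd.DataFrame:
    """Mean per-site amplitude per layer, inside vs outside the home column.

    Returns a DataFrame indexed by layer with columns ``intracolumnar`` and
    ``transcolumnar`` (NaN where a layer/column cell holds no sites) plus
    site counts.
    """
    n_rows, n_cols = imap.site_sum.shape
    lo, hi = imap.home_columns
    cols = np.arange(n_cols)
    in_home = (cols >= lo) & (cols < hi)
    rows = []
    for layer, (rlo, rhi) in imap.laminar_borders.items():
        block = imap.site_sum[rlo:rhi]
        if block.size == 0:
            rows.append((layer, np.nan, np.nan, 0, 0))
            continue
        intra = block[:, in_home]
        trans = block[:, ~in_home]
        rows.append((
            layer,
            float(intra.mean()) if intra.size else np.nan,
            float(trans.mean()) if trans.size else np.nan,
            intra.size, trans.size,
        ))
    return pd.DataFrame(
        rows, columns=["layer", "intracolumnar", "transcolumnar",
                       "n_sites_intra", "n_sites_trans"]
    ).set_index("layer")
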