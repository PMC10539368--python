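"""Quick-look figures for the pipeline outputs."""

from __future__ import annotations

import numpy as np

from .widefield import ResponseTrace
from .slicemap import InputMap


def plot_response(trace: ResponseTrace, ax=None):
    """dF/F time course with the stimulus marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.time, trace.dff, lw=1.2)
    ax.axvline(trace.stimulus_onset, color="0.5", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\Delta F/F_0$")
    return ax


def plot_input_map(imap: InputMap, ax=None):
    """Color-coded summed-EPSC map with home-column bounds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(imap.site_sum, cmap="hot", aspect="auto")
    lo, hi = imap.home_columns
    ax.axvline(lo - 0.5, color="c", lw=0.8)
    ax.axvline(hi - 0.5, color="c", lw=0.8)
    for name, (rlo, _) in imap.laminar_borders.items():
        ax.axhline(rlo - 0.5, color="w", lw=0.5)
        ax.text(-0.8, rlo, name, ha="right", va="center", fontsize=7)
    plt.colorbar(im, ax=ax, label="summed EPSC (pA)")
    return ax


def plot_group_heatmap(heatmap: np.ndarray, ax=None):
    """Fraction-of-animals heatmap of thresholded fos signal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(heatmap, cmap="viridis", vmin=0, vmax=1)
    plt.colorbar(im, ax=ax, label="fraction of animals")
    return ax
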