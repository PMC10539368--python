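"""Synthetic datasets with known ground truth for every analysis pipeline.

Each generator is a pure function of its spec and seed: the same spec
produces bit-identical data, and the parameters actually used are returned
in a :class:`GroundTruth` sidecar so downstream recovery can be checked.

The widefield generator emulates interleaved dual-wavelength acquisition:
both channels share a multiplicative hemodynamic oscillation (random phase
per trial, standing in for heart/respiration-driven blood-volume changes),
while only the calcium-sensitive 465 nm channel carries the stimulus-locked
transient — an instantaneous rise at stimulus onset decaying with a single
exponential, with a Gaussian spatial footprint.  Channels are generated
already de-interleaved, with the half-sample timing offset recorded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .widefield import DualChannelTrialSet
from .connectivity import RegionCountTable
from .slicemap import PhotostimRecording

__all__ = [
    "GroundTruth",
    "WidefieldSimSpec",
    "BarrelSimSpec",
    "make_widefield_trials",
    "make_barrel_image",
    "make_tracing_counts",
    "make_behavior_session",
    "make_morphology_data",
    "make_epsc_grid",
]


@dataclass
class GroundTruth:
    """The parameters actually used to synthesize a dataset."""

    kind: str
    params: dict

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "params": self.params},
                          sort_keys=True, default=float)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], params=d["params"])


# ---------------------------------------------------------------------------
# widefield movies
# ---------------------------------------------------------------------------

@dataclass
class WidefieldSimSpec:
    """Acquisition and signal parameters for simulated widefield trials.

    Defaults mirror the study acquisition: 2.5 s trials with a 0.5 s
    pre-stimulus period, 30 Hz per channel after de-interleaving the 60 Hz
    interleaved stream, at least 60 trials, raw frames that bin 4x4 down to
    220x200 (raw pixel pitch 7.5 um).  ``neural_amplitude`` is in dF/F
    units; ``hemo_amplitude`` is the fractional fluorescence modulation
    shared by both channels; ``channel_gains`` are the (465, 405)
    sensitivities.
    """

    raw_height: int = 880
    raw_width: int = 800
    frame_rate: float = 30.0
    trial_duration: float = 2.5
    pre_stim: float = 0.5
    n_trials: int = 60
    neural_amplitude: float = 0.03
    neural_tau: float = 0.5
    response_center: tuple[float, float] | None = None
    response_sigma: float = 60.0
    hemo_amplitude: float = 0.05
    hemo_freq: float = 1.0
    channel_gains: tuple[float, float] = (1.0, 0.8)
    noise_sd: float = 5.0
    baseline: float = 1000.0
    baseline_map: np.ndarray | None = None
    pixel_size_um: float = 7.5
    seed: int = 0

    def __post_init__(self):
        if self.raw_height <= 0 or self.raw_width <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.frame_rate <= 0 or self.trial_duration <= 0:
            raise ValueError("rates and durations must be positive")
        if not 0 <= self.pre_stim < self.trial_duration:
            raise ValueError("pre_stim must lie within the trial")
        if min(self.neural_amplitude, self.hemo_amplitude, self.noise_sd) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration * self.frame_rate))


def make_widefield_trials(spec: WidefieldSimSpec) -> tuple[DualChannelTrialSet, GroundTruth]:
    """Simulate paired 465/405 nm trial stacks with shared hemodynamics."""
    rng = np.random.default_rng(spec.seed)
    T, H, W = spec.n_frames, spec.raw_height, spec.raw_width
    t465 = np.arange(T) / spec.frame_rate
    offset = 0.5 / spec.frame_rate  # interleaved wavelengths alternate frames
    t405 = t465 + offset

    cy, cx = spec.response_center if spec.response_center is not None else (H / 2, W / 2)
    yy, xx = np.mgrid[0:H, 0:W]
    footprint = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spec.response_sigma**2))
    transient = np.where(
        t465 >= spec.pre_stim,
        spec.neural_amplitude * np.exp(-(t465 - spec.pre_stim) / spec.neural_tau),
        0.0,
    )
    f0 = spec.baseline_map if spec.baseline_map is not None else np.full((H, W), spec.baseline)
    g465, g405 = spec.channel_gains

    ch465 = np.empty((spec.n_trials, T, H, W), dtype=np.float32)
    ch405 = np.empty_like(ch465)
    for i in range(spec.n_trials):
        phase = rng.uniform(0, 2 * np.pi)
        h465 = 1.0 + spec.hemo_amplitude * np.sin(2 * np.pi * spec.hemo_freq * t465 + phase)
        h405 = 1.0 + spec.hemo_amplitude * np.sin(2 * np.pi * spec.hemo_freq * t405 + phase)
        neural = 1.0 + transient[:, None, None] * footprint[None, :, :]
        ch465[i] = f0[None] * g465 * h465[:, None, None] * neural
        ch405[i] = f0[None] * g405 * h405[:, None, None]
        if spec.noise_sd > 0:
            ch465[i] += rng.normal(0, spec.noise_sd, size=(T, H, W))
            ch405[i] += rng.normal(0, spec.noise_sd, size=(T, H, W))

    trials = DualChannelTrialSet(
        ch465=ch465, ch405=ch405, frame_rate=spec.frame_rate,
        stimulus_onset=spec.pre_stim, pixel_size_um=spec.pixel_size_um,
        channel_offset_s=offset,
        meta={"seed": spec.seed, "n_trials": spec.n_trials},
    )
    truth = GroundTruth("widefield", {
        "neural_amplitude": spec.neural_amplitude, "neural_tau": spec.neural_tau,
        "hemo_amplitude": spec.hemo_amplitude, "hemo_freq": spec.hemo_freq,
        "response_center": [cy, cx], "response_sigma": spec.response_sigma,
        "stimulus_onset": spec.pre_stim, "seed": spec.seed,
    })
    return trials, truth


# ---------------------------------------------------------------------------
# barrel-map section images
# ---------------------------------------------------------------------------

@dataclass
class BarrelSimSpec:
    """Synthetic tangential section: barrels on a grid with labeled cells.

    ``inside_rate`` is the expected number of cells in the principal barrel;
    ``outside_rate`` the expected number per surrounding barrel.  Cells are
    rendered as Gaussian spots of amplitude ``cell_intensity`` on a
    background with an optional linear gradient.
    """

    height: int = 256
    width: int = 256
    barrel_centers: Sequence[tuple[float, float]] | None = None
    barrel_radius: float = 24.0
    principal_index: int = 4
    inside_rate: float = 100.0
    outside_rate: float = 50.0
    cell_sigma: float = 1.5
    cell_intensity: float = 100.0
    background: float = 10.0
    gradient: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.barrel_centers is None:
            ys = np.linspace(0.25, 0.75, 3) * self.height
            xs = np.linspace(0.25, 0.75, 3) * self.width
            self.barrel_centers = [(y, x) for y in ys for x in xs]
        if not 0 <= self.principal_index < len(self.barrel_centers):
            raise ValueError("principal_index out of range")
        if min(self.inside_rate, self.outside_rate) < 0:
            raise ValueError("densities must be non-negative")


def make_barrel_image(spec: BarrelSimSpec):
    """Render a barrel-grid image with Poisson cell counts per barrel.

    Returns ``(image, cells, rois, truth)`` where ``cells`` is a DataFrame
    with columns ``x, y, barrel, inside_principal`` and ``rois`` maps roi
    names (``"P"`` for the principal, ``"S0"..`` for surround) to
    ``(cy, cx, r)`` circles.
    """
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    image = (spec.background + spec.gradient[0] * yy + spec.gradient[1] * xx).astype(float)
    rows, rois = [], {}
    s_i = 0
    for b, (cy, cx) in enumerate(spec.barrel_centers):
        is_principal = b == spec.principal_index
        if is_principal:
            rois["P"] = (cy, cx, spec.barrel_radius)
        else:
            rois[f"S{s_i}"] = (cy, cx, spec.barrel_radius)
            s_i += 1
        rate = spec.inside_rate if is_principal else spec.outside_rate
        n = rng.poisson(rate)
        r = spec.barrel_radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        cys, cxs = cy + r * np.sin(th), cx + r * np.cos(th)
        for y, x in zip(cys, cxs):
            rows.append((x, y, b, is_principal))
    cells = pd.DataFrame(rows, columns=["x", "y", "barrel", "inside_principal"])
    for _, c in cells.iterrows():
        d2 = (yy - c.y) ** 2 + (xx - c.x) ** 2
        image += spec.cell_intensity * np.exp(-d2 / (2 * spec.cell_sigma**2))
    n_in = int(cells.inside_principal.sum())
    n_out = int(len(cells) - n_in)
    truth = GroundTruth("barrel_image", {
        "inside_rate": spec.inside_rate, "outside_rate": spec.outside_rate,
        "n_surround": len(spec.barrel_centers) - 1,
        "n_inside": n_in, "n_outside": n_out,
        "outside_inside_ratio": (n_out / n_in) if n_in else np.nan,
        "seed": spec.seed,
    })
    return image, cells, rois, truth


# ---------------------------------------------------------------------------
# tracing counts, behavior bouts, morphology tables, EPSC grids
# ---------------------------------------------------------------------------

def make_tracing_counts(region_rates: dict, starter_count: int,
                        seed: int = 0, hemisphere: str = "ipsi"):
    """Poisson presynaptic counts per region for a given starter count."""
    if starter_count < 1:
        raise ValueError("starter_count must be >= 1")
    if any(r < 0 for r in region_rates.values()):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    regions = list(region_rates)
    counts = {r: int(rng.poisson(region_rates[r])) for r in regions}
    table = RegionCountTable(counts=counts, starter_count=starter_count,
                             hemisphere=hemisphere)
    truth = GroundTruth("tracing", {
        "region_rates": dict(region_rates), "starter_count": starter_count,
        "expected_ioc": {r: region_rates[r] / starter_count for r in regions},
        "seed": seed,
    })
    return table, truth


def make_behavior_session(
    p_novel: float, n_bouts: int, mean_bout_s: float = 2.0,
    contact_prob: float = 0.85, exclusion_prob: float = 0.05,
    inter_bout_s: float = 1.0, seed: int = 0, segment: str = "test",
):
    """Simulate a bout table for the novel-texture task.

    Each bout targets the novel texture with probability ``p_novel`` and
    has an exponential duration; a fraction are pass-throughs (no whisker
    contact) or climbing bouts (excluded), independent of texture, so the
    expected discrimination index is ``2*p_novel - 1``.
    """
    if not 0 <= p_novel <= 1:
        raise ValueError("p_novel must be in [0, 1]")
    rng = np.random.default_rng(seed)
    texture = np.where(rng.random(n_bouts) < p_novel, "novel", "familiar")
    dur = rng.exponential(mean_bout_s, n_bouts)
    gaps = rng.exponential(inter_bout_s, n_bouts)
    start = np.cumsum(gaps) + np.concatenate([[0.0], np.cumsum(dur[:-1])])
    contact = rng.random(n_bouts) < contact_prob
    excluded = rng.random(n_bouts) < exclusion_prob
    table = pd.DataFrame({
        "animal": "sim", "segment": segment, "texture": texture,
        "start": start, "end": start + dur,
        "in_zone": True, "whisker_contact": contact, "excluded": excluded,
    })
    truth = GroundTruth("behavior", {
        "p_novel": p_novel, "expected_index": 2 * p_novel - 1,
        "n_bouts": n_bouts, "seed": seed,
    })
    return table, truth


def make_morphology_data(
    n_animals: tuple[int, int], neurons_per_animal: int,
    beta: float, sigma: float, baseline_logit: float = 0.0, seed: int = 0,
):
    """Animal-clustered binary morphology outcomes under the logistic GLMM.

    Per-animal intercepts are Normal(0, sigma^2); each neuron's outcome is
    Bernoulli(logit^-1(baseline + beta*group + intercept_animal)).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    aid = 0
    for g, n_a in enumerate(n_animals):
        for _ in range(n_a):
            u = rng.normal(0, sigma) if sigma > 0 else 0.0
            eta = baseline_logit + beta * g + u
            p = 1.0 / (1.0 + np.exp(-eta))
            y = (rng.random(neurons_per_animal) < p).astype(int)
            for v in y:
                rows.append((f"a{aid:03d}", g, int(v)))
            aid += 1
    table = pd.DataFrame(rows, columns=["animal", "group", "outcome"])
    truth = GroundTruth("morphology", {
        "beta": beta, "sigma": sigma, "baseline_logit": baseline_logit,
        "n_animals": list(n_animals), "neurons_per_animal": neurons_per_animal,
        "seed": seed,
    })
    return table, truth


def make_epsc_grid(
    connection_map: dict | None = None,
    grid_shape: tuple[int, int] = (15, 28),
    sample_rate: float = 10000.0,
    sweep_duration: float = 0.4,
    stim_time: float = 0.1,
    event_tau: float = 0.01,
    event_rise: float = 0.001,
    noise_sd: float = 0.0,
    seed: int = 0,
    laminar_borders: dict | None = None,
    home_columns: tuple[int, int] | None = None,
):
    """One post-stimulus current trace per photostimulation site.

    ``connection_map`` maps ``(row, col)`` sites to lists of
    ``(amplitude_pA, latency_s)`` events (latency relative to the
    stimulus).  Events are inward (negative-going) currents with a fast
    rise and exponential decay.  Sites absent from the map yield pure
    noise.  Grid rows run pia (row 0) to white matter; columns run across
    the slice.
    """
    n_rows, n_cols = grid_shape
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    connection_map = connection_map or {}
    rng = np.random.default_rng(seed)
    n_samples = int(round(sweep_duration * sample_rate))
    t = np.arange(n_samples) / sample_rate
    traces = np.zeros((n_rows, n_cols, n_samples))
    if noise_sd > 0:
        traces += rng.normal(0, noise_sd, traces.shape)
    for (r, c), events in connection_map.items():
        for amp, lat in events:
            onset = stim_time + lat
            m = t >= onset
            shape = (1 - np.exp(-(t[m] - onset) / event_rise)) * np.exp(-(t[m] - onset) / event_tau)
            peak = shape.max() if shape.size else 1.0
            if peak > 0:
                traces[r, c, m] -= amp * shape / peak
    if laminar_borders is None:
        # 15 depth rows split into the six cortical layers (L5 split a/b)
        laminar_borders = {"L1": (0, 1), "L2/3": (1, 5), "L4": (5, 8),
                          "L5a": (8, 10), "L5b": (10, 12), "L6": (12, 15)}
    if home_columns is None:
        home_columns = (n_cols // 2 - 2, n_cols // 2 + 2)
    rec = PhotostimRecording(
        traces=traces, sample_rate=sample_rate, stim_time=stim_time,
        laminar_borders=laminar_borders, home_columns=home_columns,
    )
    truth = GroundTruth("epsc_grid", {
        "connection_map": {f"{r},{c}": [[a, l] for a, l in ev]
                           for (r, c), ev in connection_map.items()},
        "grid_shape": list(grid_shape), "noise_sd": noise_sd, "seed": seed,
    })
    return rec, truth
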