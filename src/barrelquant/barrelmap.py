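"""Section-image quantification for barrel-map experiments.

Covers the chromogenic ISH / c-fos image pipelines: rolling-ball background
subtraction, binned intensity profiles along the cortical depth axis with
per-bin log2 fold-changes (knockout vs control, 10 bins; electroporated vs
contralateral L4, 100 bins), the B2–C2–D2 row profile normalized to the
principal (C2) barrel, outside/inside fos+ cell ratios, group heatmaps of
auto-thresholded images, and the directional signed-rank shift test used
on per-gene mean log-fold-changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball

from .stats import directional_shift_test  # noqa: F401  (re-exported: part of this surface)

__all__ = [
    "SectionImage",
    "ProfileResult",
    "FosResult",
    "subtract_background",
    "binned_profile",
    "depth_profile_log2fc",
    "iue_l4_log2fc",
    "fos_row_profile",
    "fos_ratios",
    "group_heatmap",
    "directional_shift_test",
]


@dataclass
class SectionImage:
    """A grayscale section image with named rectangular/circular ROIs.

    Chromogenic (brightfield ISH) images should be inverted so that signal
    is bright; ``inverted`` records whether that was done.
    """

    image: np.ndarray
    pixel_size_um: float = 1.0
    inverted: bool = False
    rois: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D grayscale")

    @classmethod
    def from_array(cls, arr, invert: bool = False, **kw) -> "SectionImage":
        arr = np.asarray(arr, dtype=float)
        if invert:
            arr = arr.max() - arr
        return cls(image=arr, inverted=invert, **kw)


@dataclass
class ProfileResult:
    """A binned intensity profile along a normalized axis."""

    bin_centers: np.ndarray
    values: np.ndarray
    log2fc: np.ndarray | None = None
    norm_ref: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class FosResult:
    """Outside/inside quantification of fos signal around the principal barrel."""

    intensity_ratio: float
    count_ratio: float
    profile: ProfileResult | None = None


# ---------------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------------

def subtract_background(image: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background subtraction (signal-positive images).

    Estimates the background as the surface traced by a ball of the given
    radius rolled under the image and subtracts it; output is clipped at 0.
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(image.shape):
        raise ValueError("radius must be smaller than the image")
    bg = rolling_ball(image, radius=radius)
    return np.clip(image - bg, 0.0, None)


# ---------------------------------------------------------------------------
# binned profiles and log2 fold-changes
# ---------------------------------------------------------------------------

def binned_profile(image: np.ndarray, roi: tuple[slice, slice] | None = None,
                   axis: int = 0, n_bins: int = 10) -> ProfileResult:
    """Mean intensity in ``n_bins`` equal segments along ``axis`` of a ROI.

    The image (or its ROI crop) is averaged over the orthogonal axis to a
    1-d profile, which is split into ``n_bins`` near-equal contiguous
    segments (boundaries at ``floor(b * L / n_bins)``).
    """
    img = np.asarray(image, dtype=float)
    if roi is not None:
        img = img[roi]
    profile = img.mean(axis=1 - axis)
    L = len(profile)
    if n_bins < 1 or n_bins > L:
        raise ValueError("n_bins must be in [1, profile length]")
    edges = (np.arange(n_bins + 1) * L) // n_bins
    values = np.array([profile[edges[b]:edges[b + 1]].mean() for b in range(n_bins)])
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return ProfileResult(bin_centers=centers, values=values)


def depth_profile_log2fc(test_image: np.ndarray, control_image: np.ndarray,
                         roi: tuple[slice, slice] | None = None,
                         axis: int = 0, n_bins: int = 10) -> ProfileResult:
    """Per-bin log2(test/control) of cortical-depth intensity profiles.

    Both images are profiled over the same ROI geometry (normalized
    cortical depth, 10 bins by default).  Bins with zero control intensity
    are flagged undefined (NaN) with a warning.
    """
    p_test = binned_profile(test_image, roi, axis, n_bins)
    p_ctrl = binned_profile(control_image, roi, axis, n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(p_test.values / p_ctrl.values)
    bad = p_ctrl.values == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} bins with zero control intensity flagged undefined")
        lfc = np.where(bad, np.nan, lfc)
    return ProfileResult(bin_centers=p_test.bin_centers, values=p_test.values,
                         log2fc=lfc, norm_ref="control")


def iue_l4_log2fc(iue_image: np.ndarray, contra_image: np.ndarray,
                  l4_band: tuple[int, int], roi: tuple[slice, slice] | None = None,
                  axis: int = 0, n_bins: int = 100) -> float:
    """Log2 fold-change of mean L4 intensity, electroporated vs contralateral.

    Profiles are binned along the radial (depth) axis into ``n_bins``
    (default 100); ``l4_band`` is the half-open bin range covering L4 on
    that axis.
    """
    lo, hi = l4_band
    if not 0 <= lo < hi <= n_bins:
        raise ValueError("l4_band must be a valid bin range")
    p_iue = binned_profile(iue_image, roi, axis, n_bins)
    p_con = binned_profile(contra_image, roi, axis, n_bins)
    m_iue = p_iue.values[lo:hi].mean()
    m_con = p_con.values[lo:hi].mean()
    if m_con == 0:
        raise ZeroDivisionError("zero contralateral L4 mean")
    return float(np.log2(m_iue / m_con))


# ---------------------------------------------------------------------------
# fos quantification
# ---------------------------------------------------------------------------

def fos_row_profile(image: np.ndarray, row_band: tuple[int, int],
                    col_span: tuple[int, int] | None = None,
                    c2_interval: tuple[float, float] = (1 / 3, 2 / 3),
                    n_bins: int = 30) -> ProfileResult:
    """Binned intensity profile across the B2–C2–D2 barrel row.

    Pixel intensities are averaged over ``row_band`` rows, profiled along
    the columns (optionally restricted to ``col_span``), binned into
    ``n_bins``, and normalized to the mean of the bins whose centers fall
    in ``c2_interval`` (normalized position of the principal C2 barrel,
    middle third by default).
    """
    img = np.asarray(image, dtype=float)
    r0, r1 = row_band
    c0, c1 = col_span if col_span is not None else (0, img.shape[1])
    prof = binned_profile(img[r0:r1, c0:c1], axis=1, n_bins=n_bins)
    in_c2 = (prof.bin_centers >= c2_interval[0]) & (prof.bin_centers < c2_interval[1])
    if not in_c2.any():
        raise ValueError("no bins inside the C2 interval")
    c2_mean = prof.values[in_c2].mean()
    if c2_mean == 0:
        raise ZeroDivisionError("zero C2 mean intensity")
    return ProfileResult(bin_centers=prof.bin_centers, values=prof.values / c2_mean,
                         norm_ref="C2")


def _in_circle(cells: pd.DataFrame, roi: tuple[float, float, float]) -> np.ndarray:
    cy, cx, r = roi
    return (cells["x"] - cx) ** 2 + (cells["y"] - cy) ** 2 <= r**2


def fos_ratios(cells: pd.DataFrame, principal_roi, surround_rois,
               image: np.ndarray | None = None) -> FosResult:
    """Outside/inside ratios of fos+ cells (and optionally intensity).

    ROIs are ``(cy, cx, radius)`` circles; ``surround_rois`` is an iterable
    of circles for the neighboring barrels.  The count ratio is fos+ cells
    in the surround ROIs divided by cells in the principal ROI; the
    intensity ratio is the analogous ratio of raw mean image intensities
    (mean over surround ROIs vs principal ROI) when an image is supplied.
    """
    n_in = int(_in_circle(cells, principal_roi).sum())
    n_out = int(sum(_in_circle(cells, roi).sum() for roi in surround_rois))
    if n_in == 0:
        warnings.warn("zero cells in the principal barrel; count ratio undefined")
        count_ratio = np.nan
    else:
        count_ratio = n_out / n_in
    intensity_ratio = np.nan
    if image is not None:
        yy, xx = np.mgrid[0:image.shape[0], 0:image.shape[1]]

        def roi_mean(roi):
            cy, cx, r = roi
            m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            return image[m].mean()

        surround_means = [roi_mean(roi) for roi in surround_rois]
        p_mean = roi_mean(principal_roi)
        if p_mean == 0:
            warnings.warn("zero principal-barrel intensity; intensity ratio undefined")
        else:
            intensity_ratio = float(np.mean(surround_means) / p_mean)
    return FosResult(intensity_ratio=intensity_ratio, count_ratio=count_ratio)


def group_heatmap(images) -> np.ndarray:
    """Pixelwise mean of per-image Otsu-thresholded binaries, in [0, 1].

    Images must be co-registered (principal barrel centered, common crop).
    Constant images (no Otsu threshold) contribute an all-zero mask.
    """
    images = [np.asarray(im, dtype=float) for im in images]
    if len(images) < 1:
        raise ValueError("need at least one image")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("images must share a shape")
    masks = []
    for im in images:
        if np.ptp(im) == 0:
            masks.append(np.zeros(shape))
        else:
            masks.append((im > threshold_otsu(im)).astype(float))
    return np.mean(masks, axis=0)
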