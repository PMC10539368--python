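"""Novel-texture-discrimination scoring from bout tables.

An interaction is a bout in which the animal is inside the 4 cm x 4 cm
zone around a texture panel and makes whisker-directed contact; climbing
and pass-through bouts are excluded.  The discrimination index is

    NTD = (novel - familiar) / (novel + familiar)

on total interaction seconds, ranging from -1 (familiar only) to +1
(novel only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NtdResult", "interaction_times", "ntd_index", "score_session"]

TEXTURES = ("familiar", "novel")


@dataclass
class NtdResult:
    familiar_s: float
    novel_s: float
    ntd_index: float

    @property
    def total_s(self) -> float:
        return self.familiar_s + self.novel_s


def _merge_intervals(intervals: np.ndarray) -> float:
    """Total covered length of possibly overlapping [start, end) intervals."""
    if len(intervals) == 0:
        return 0.0
    order = np.argsort(intervals[:, 0])
    total, cur_s, cur_e = 0.0, None, None
    for s, e in intervals[order]:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return float(total)


def interaction_times(bouts: pd.DataFrame, segment: str | None = None) -> dict[str, float]:
    """Sum valid interaction seconds per texture.

    A bout counts when ``in_zone`` and ``whisker_contact`` are true and
    ``excluded`` is false.  Overlapping valid bouts on the same texture are
    merged (with a warning) so no time is double counted.
    """
    df = bouts
    if segment is not None and "segment" in df:
        df = df[df["segment"] == segment]
    if (df["end"] <= df["start"]).any():
        raise ValueError("bout end must exceed start")
    valid = df[df["in_zone"] & df["whisker_contact"] & ~df["excluded"]]
    out = {}
    for tex in TEXTURES:
        sub = valid[valid["texture"] == tex]
        iv = sub[["start", "end"]].to_numpy(dtype=float)
        plain = float((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0.0
        merged = _merge_intervals(iv)
        if merged < plain - 1e-9:
            warnings.warn(f"overlapping {tex} bouts merged ({plain - merged:.3f} s overlap)")
        out[tex] = merged
    return out


def ntd_index(novel_s: float, familiar_s: float) -> float:
    """(novel - familiar) / total interaction time; NaN when total is 0."""
    total = novel_s + familiar_s
    if total <= 0:
        warnings.warn("no interaction time; NTD index undefined")
        return np.nan
    return (novel_s - familiar_s) / total


def score_session(bouts: pd.DataFrame, segment: str | None = "test") -> NtdResult:
    """Interaction times and NTD index for one session segment."""
    times = interaction_times(bouts, segment=segment)
    return NtdResult(
        familiar_s=times["familiar"], novel_s=times["novel"],
        ntd_index=ntd_index(times["novel"], times["familiar"]),
    )
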