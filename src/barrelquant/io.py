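"""Reading and writing the package's file formats.

Widefield sessions are stored as one 16-bit TIFF stack per trial per
channel plus a YAML manifest (frame rate, stimulus onset, channel labels,
pixel size); tabular data as CSV; ground truth and analysis reports as
JSON.  Every CLI run also writes a provenance manifest listing inputs,
parameters, and SHA-256 hashes of the outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .widefield import DualChannelTrialSet

__all__ = [
    "write_widefield_session",
    "read_widefield_session",
    "read_roi_mask",
    "write_json",
    "sha256_of",
    "write_run_manifest",
]


def write_widefield_session(trials: DualChannelTrialSet, outdir: str | Path,
                            scale: float = 1.0) -> Path:
    """Write per-trial per-channel TIFF stacks and a session.yaml manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {"ch465": [], "ch405": []}
    for i in range(trials.n_trials):
        f465 = outdir / f"trial{i:03d}_465.tif"
        tifffile.imwrite(f465, np.clip(trials.ch465[i] * scale, 0, 65535).astype(np.uint16))
        files["ch465"].append(f465.name)
        if trials.ch405 is not None:
            f405 = outdir / f"trial{i:03d}_405.tif"
            tifffile.imwrite(f405, np.clip(trials.ch405[i] * scale, 0, 65535).astype(np.uint16))
            files["ch405"].append(f405.name)
    manifest = {
        "frame_rate": float(trials.frame_rate),
        "stimulus_onset": float(trials.stimulus_onset),
        "pixel_size_um": float(trials.pixel_size_um),
        "channel_offset_s": float(trials.channel_offset_s),
        "channels": {k: v for k, v in files.items() if v},
    }
    path = outdir / "session.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_widefield_session(manifest_path: str | Path) -> DualChannelTrialSet:
    """Load a session written by :func:`write_widefield_session`."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    for key in ("frame_rate", "stimulus_onset", "channels"):
        if key not in manifest:
            raise ValueError(f"session manifest missing key: {key!r}")
    base = manifest_path.parent
    ch465 = np.stack([
        tifffile.imread(base / f).astype(np.float64)
        for f in manifest["channels"]["ch465"]
    ])
    ch405 = None
    if manifest["channels"].get("ch405"):
        ch405 = np.stack([
            tifffile.imread(base / f).astype(np.float64)
            for f in manifest["channels"]["ch405"]
        ])
    return DualChannelTrialSet(
        ch465=ch465, ch405=ch405,
        frame_rate=float(manifest["frame_rate"]),
        stimulus_onset=float(manifest["stimulus_onset"]),
        pixel_size_um=float(manifest.get("pixel_size_um", 30.0)),
        channel_offset_s=float(manifest.get("channel_offset_s", 0.0)),
    )


def read_roi_mask(path: str | Path) -> np.ndarray:
    """ROI mask from a single-frame TIFF (nonzero = inside)."""
    return tifffile.imread(path) != 0


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")
    return path


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_manifest(outdir: str | Path, command: str, inputs: list,
                       params: dict, outputs: list) -> Path:
    """Provenance record: inputs, parameters, output hashes."""
    outdir = Path(outdir)
    manifest = {
        "command": command,
        "inputs": [str(p) for p in inputs],
        "params": params,
        "outputs": {Path(p).name: sha256_of(p) for p in outputs},
    }
    return write_json(manifest, outdir / f"{command}_manifest.json")
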