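"""TIFF / CSV input-output with voxel-size sidecars and provenance headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .puncta import VolumeStack
from .traces import TraceSet

PACKAGE_VERSION = "0.1.0"


def write_stack(path, stack: VolumeStack) -> None:
    """Write a VolumeStack as multi-page TIFF plus a YAML sidecar (.meta.yaml)."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32), photometric="minisblack")
    meta = {"voxel_size_um": list(stack.voxel_size), "channel": stack.channel}
    path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_stack(path, voxel_size=None, channel="") -> VolumeStack:
    """Read a TIFF stack; voxel size from the sidecar unless given explicitly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    vox = tifffile.imread(path).astype(np.float64)
    if vox.ndim == 2:
        vox = vox[None]
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    if voxel_size is None:
        if not sidecar.exists():
            raise FileNotFoundError(f"no voxel-size sidecar for {path}; pass voxel_size")
        meta = yaml.safe_load(sidecar.read_text())
        voxel_size = tuple(meta["voxel_size_um"])
        channel = channel or meta.get("channel", "")
    return VolumeStack(voxels=vox, voxel_size=tuple(voxel_size), channel=channel)


def provenance_header(seed=None, config=None) -> list[str]:
    """Comment lines recording version, seed and a config hash."""
    lines = [f"# ribbonquant {PACKAGE_VERSION}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha1(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_sha1: {digest}")
    return lines


def write_table(path, df: pd.DataFrame, seed=None, config=None) -> None:
    """Write a CSV table with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_header(seed=seed, config=config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, comment="#")


def write_traces(path, traces: TraceSet, seed=None, config=None) -> None:
    """Write a TraceSet as CSV (rows = frames, columns = cells) with metadata header."""
    path = Path(path)
    df = pd.DataFrame(
        traces.values.T, columns=[f"cell_{i}" for i in traces.cell_ids]
    )
    with open(path, "w") as fh:
        for line in provenance_header(seed=seed, config=config):
            fh.write(line + "\n")
        fh.write(f"# frame_rate_hz: {traces.frame_rate}\n")
        fh.write(f"# channel: {traces.channel}\n")
        windows = ";".join(f"{a},{b}" for a, b in traces.stimulus_windows)
        fh.write(f"# stimulus_windows_s: {windows}\n")
        df.to_csv(fh, index=False)


def read_traces(path) -> TraceSet:
    """Read a TraceSet written by :func:`write_traces`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    frame_rate = None
    channel = ""
    windows: tuple = ()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "frame_rate_hz:" in line:
                frame_rate = float(line.split(":", 1)[1])
            elif "channel:" in line:
                channel = line.split(":", 1)[1].strip()
            elif "stimulus_windows_s:" in line:
                raw = line.split(":", 1)[1].strip()
                if raw:
                    windows = tuple(
                        tuple(float(v) for v in w.split(",")) for w in raw.split(";")
                    )
    if frame_rate is None:
        raise ValueError(f"no frame_rate_hz metadata in {path}")
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"trace file {path} contains no frames")
    return TraceSet(
        values=df.to_numpy().T,
        frame_rate=frame_rate,
        stimulus_windows=windows,
        channel=channel,
    )
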