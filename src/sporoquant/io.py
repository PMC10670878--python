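"""Containers and file I/O for microscopy stacks, label masks and tables.

Images travel as multi-page TIFF with a JSON sidecar recording channel order
and pixel size; label masks as 16-bit TIFF; traces and peptide tables as CSV
with documented headers; run configuration round-trips through YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

#: canonical channel order used when writing stacks to disk
CHANNEL_ORDER = ("membrane", "reporter", "mito", "dapi", "phase")


@dataclass
class ImageStack:
    """Named-channel fluorescence/phase image data for one field of view.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2D intensity array in arbitrary units
        (AU). All channels must share one shape; intensities must be finite
        and nonnegative.
    pixel_size
        Physical pixel size in micrometres per pixel.
    frame_times
        Optional acquisition times in seconds for time-lapse data; ``None``
        for single-frame stacks.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um/px)")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not in stack (has {sorted(self.channels)})"
            )
        return self.channels[name]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an ImageStack as multi-page TIFF plus a JSON sidecar.

    Pages follow :data:`CHANNEL_ORDER` for the channels present, then any
    extra channels in sorted order; the sidecar (``<path>.json``) records the
    order and pixel size so the stack round-trips exactly.
    """
    path = Path(path)
    names = [c for c in CHANNEL_ORDER if c in stack.channels]
    names += sorted(set(stack.channels) - set(names))
    pages = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "channels": names,
        "pixel_size_um": stack.pixel_size,
        "frame_times_s": None
        if stack.frame_times is None
        else [float(t) for t in stack.frame_times],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    channels = {n: pages[i].astype(float) for i, n in enumerate(sidecar["channels"])}
    times = sidecar.get("frame_times_s")
    return ImageStack(
        channels=channels,
        pixel_size=float(sidecar["pixel_size_um"]),
        frame_times=None if times is None else np.asarray(times, dtype=float),
    )


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    """Write an integer label mask as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(int)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a table as CSV with a header row, no index column."""
    table.to_csv(Path(path), index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def write_config(path: str | Path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text())
    return {} if loaded is None else loaded


@dataclass
class TraceTable:
    """Long-format photobleaching trace container.

    Columns of the CSV form: ``frame`` (index), ``time_s``, ``role``
    (``bleached_fs``, ``bleached_mc``, ``reference_cell`` or ``distal_<i>``)
    and ``intensity`` (background-subtracted mean, AU).
    """

    frame_times: np.ndarray
    roles: dict[str, np.ndarray] = field(default_factory=dict)
    bleach_frame_index: int = 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role, trace in self.roles.items():
            for i, (t, v) in enumerate(zip(self.frame_times, trace)):
                rows.append(
                    {"frame": i, "time_s": t, "role": role, "intensity": v}
                )
        df = pd.DataFrame(rows)
        df.attrs["bleach_frame_index"] = self.bleach_frame_index
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, bleach_frame_index: int | None = None
    ) -> "TraceTable":
        roles = {}
        times = None
        for role, grp in df.groupby("role", sort=False):
            grp = grp.sort_values("frame")
            roles[role] = grp["intensity"].to_numpy(dtype=float)
            times = grp["time_s"].to_numpy(dtype=float)
        if bleach_frame_index is None:
            bleach_frame_index = int(df.attrs.get("bleach_frame_index", 1))
        return cls(
            frame_times=times, roles=roles, bleach_frame_index=bleach_frame_index
        )
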