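"""Calibrated TIFF / CSV / JSON input-output.

Movies travel as multi-page TIFF hyperstacks whose axes resolve to
``T, C, Z, Y, X``; calibration (voxel sizes, frame interval) is supplied
by a side-car metadata record because plain TIFF cannot carry it
reliably.  Result tables are UTF-8 CSV with a header row, and every run
writes a JSON manifest with the config hash and the seed so that runs
can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

from .model import (
    Annotation,
    AnnotationEntry,
    CalibrationError,
    LabelVolume,
    MovieStack,
    SchemaError,
    ValidationError,
)


@dataclass(frozen=True)
class MovieMeta:
    """Acquisition calibration accompanying a raw TIFF movie."""

    channel_names: tuple[str, ...]
    voxel_size_zyx: tuple[float, float, float]
    frame_interval: float


def read_movie(path, meta: MovieMeta) -> MovieStack:
    """Read a TIFF hyperstack into a :class:`MovieStack`.

    The file's axes string must resolve to a subset of ``TCZYX``;
    missing leading axes of length one are tolerated.  Intensities are
    preserved bit-exactly.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("Q", "Z")
    if not set(axes) <= set("TCZYX"):
        raise CalibrationError(f"cannot resolve TIFF axes {axes!r} to T,C,Z,Y,X")
    # insert missing axes as singletons, then order as TCZYX
    for ax in "TCZYX":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "TCZYX"]
    data = np.transpose(data, order)
    if data.shape[1] != len(meta.channel_names):
        raise SchemaError(
            f"{len(meta.channel_names)} channel names declared for a "
            f"{data.shape[1]}-channel file"
        )
    return MovieStack(
        data=data,
        channel_names=meta.channel_names,
        voxel_size_zyx=meta.voxel_size_zyx,
        frame_interval=meta.frame_interval,
    )


def write_movie(path, stack: MovieStack) -> None:
    """Write a movie as a TIFF hyperstack with a TCZYX axes tag."""
    tifffile.imwrite(Path(path), stack.data, metadata={"axes": "TCZYX"})


def write_labels(path, volume: LabelVolume) -> None:
    tifffile.imwrite(Path(path), volume.labels.astype(np.int32), metadata={"axes": "TZYX"})


def read_labels(path, identity_map, kind, voxel_size_zyx=(1.0, 1.0, 1.0)) -> LabelVolume:
    labels = tifffile.imread(Path(path))
    if labels.ndim == 3:
        labels = labels[np.newaxis]
    return LabelVolume(
        labels=labels, identity_map=dict(identity_map), kind=kind,
        voxel_size_zyx=tuple(voxel_size_zyx),
    )


def read_annotation(path, frame0_shape) -> Annotation:
    """Parse a first-frame annotation file (CSV or JSON).

    The CSV schema is ``z,y,x,identity`` with voxel coordinates in the
    first frame and identity ``polar`` or ``border``.  Labels are
    assigned automatically: polar cells get 1-2, border cells 3..c, each
    group in file order.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    required = {"z", "y", "x", "identity"}
    if not required <= set(df.columns):
        raise SchemaError(f"annotation must have columns {sorted(required)}, got {list(df.columns)}")
    polar_rows = df[df["identity"] == "polar"]
    border_rows = df[df["identity"] == "border"]
    if len(polar_rows) != 2:
        raise ValidationError(f"annotation must contain exactly 2 polar rows, got {len(polar_rows)}")
    entries = []
    label = 1
    for _, row in pd.concat([polar_rows, border_rows]).iterrows():
        center = (float(row["z"]), float(row["y"]), float(row["x"]))
        for coord, extent in zip(center, frame0_shape):
            if coord < 0 or coord >= extent:
                raise ValidationError(
                    f"annotation center {center} outside frame bounds {tuple(frame0_shape)}"
                )
        entries.append(AnnotationEntry(center_zyx=center, identity=row["identity"], label=label))
        label += 1
    return Annotation(entries=entries)


def write_annotation(path, annotation: Annotation) -> None:
    rows = [
        {"z": e.center_zyx[0], "y": e.center_zyx[1], "x": e.center_zyx[2],
         "identity": e.identity}
        for e in annotation.entries
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def _file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tables(results: Mapping[str, pd.DataFrame], outdir, *,
                 config_hash: str = "", seed: int = 0,
                 extra: Mapping[str, Any] | None = None) -> dict:
    """Write one CSV per result table plus a JSON run manifest.

    Returns the manifest, which records a sha256 digest per file so a
    rerun with identical inputs and seed is byte-comparable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, table in results.items():
        dest = outdir / f"{name}.csv"
        pd.DataFrame(table).to_csv(dest, index=False)
        files[dest.name] = _file_digest(dest)
    manifest = {
        "config_hash": config_hash,
        "seed": int(seed),
        "files": files,
    }
    if extra:
        manifest.update(extra)
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
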