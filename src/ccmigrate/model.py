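"""Core domain types shared by every pipeline stage.

All voxel indices are 0-based and ordered ``(z, y, x)``; physical
coordinates are obtained as ``index * voxel_size`` and expressed in
micrometres.  After isotropic resampling every geometric quantity lives
in isotropic micrometre space, which removes the anisotropy ambiguity
of raw confocal stacks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

Identity = Literal["polar", "border"]

VALID_CHANNELS = ("nuclei", "cell_membrane", "nurse_membrane")


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


class CalibrationError(ValidationError):
    """Raised when physical calibration metadata is missing or invalid."""


class SchemaError(ValidationError):
    """Raised when file contents do not match the declared schema."""


@dataclass
class MovieStack:
    """A calibrated 5-D multi-channel time-lapse, axes ``T, C, Z, Y, X``.

    Parameters
    ----------
    data
        Nonnegative intensities, shape ``(T, C, Z, Y, X)``.
    channel_names
        One name per channel, drawn from ``{nuclei, cell_membrane,
        nurse_membrane}``.
    voxel_size_zyx
        Physical voxel edge lengths in micrometres, ordered ``(z, y, x)``.
    frame_interval
        Time between consecutive frames in minutes.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    voxel_size_zyx: tuple[float, float, float]
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        self.voxel_size_zyx = tuple(float(v) for v in self.voxel_size_zyx)
        self.frame_interval = float(self.frame_interval)
        if self.data.ndim != 5:
            raise SchemaError(f"movie data must be 5-D (T,C,Z,Y,X), got {self.data.ndim}-D")
        if any(d < 1 for d in self.data.shape):
            raise SchemaError(f"all movie dimensions must be >= 1, got {self.data.shape}")
        if len(self.channel_names) != self.data.shape[1]:
            raise SchemaError(
                f"{len(self.channel_names)} channel names declared for "
                f"{self.data.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SchemaError("channel names must be unique")
        for name in self.channel_names:
            if name not in VALID_CHANNELS:
                raise SchemaError(f"unknown channel name {name!r}")
        if any(v <= 0 for v in self.voxel_size_zyx):
            raise CalibrationError(f"voxel sizes must be > 0, got {self.voxel_size_zyx}")
        if self.frame_interval <= 0:
            raise CalibrationError(f"frame interval must be > 0, got {self.frame_interval}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(T, Z, Y, X)`` sub-stack for one named channel."""
        if name not in self.channel_names:
            raise SchemaError(f"movie has no channel {name!r}")
        return self.data[:, self.channel_names.index(name)]

    def with_data(self, data: np.ndarray, voxel_size_zyx=None) -> "MovieStack":
        return MovieStack(
            data=data,
            channel_names=self.channel_names,
            voxel_size_zyx=voxel_size_zyx or self.voxel_size_zyx,
            frame_interval=self.frame_interval,
        )


@dataclass(frozen=True)
class AnnotationEntry:
    center_zyx: tuple[float, float, float]
    identity: Identity
    label: int


@dataclass
class Annotation:
    """First-frame nucleus centers with cell identities.

    Exactly two entries are polar (the non-motile pair at the cluster
    center, labels 1-2); the rest are border cells (labels 3..c), in
    file order.
    """

    entries: list[AnnotationEntry]

    def __post_init__(self) -> None:
        n_polar = sum(1 for e in self.entries if e.identity == "polar")
        n_border = sum(1 for e in self.entries if e.identity == "border")
        if n_polar != 2:
            raise ValidationError(f"annotation must contain exactly 2 polar cells, got {n_polar}")
        if n_border < 1:
            raise ValidationError("annotation must contain at least 1 border cell")
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError("annotation labels must be unique")
        if any(lab <= 0 for lab in labels):
            raise ValidationError("annotation labels must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.entries)

    @property
    def identity_map(self) -> dict[int, Identity]:
        return {e.label: e.identity for e in self.entries}

    def centers(self) -> np.ndarray:
        """Centers as an ``(c, 3)`` array ordered by label."""
        return np.array(
            [e.center_zyx for e in sorted(self.entries, key=lambda e: e.label)], dtype=float
        )


@dataclass
class LabelVolume:
    """Per-frame integer labelling of voxels, 0 = background."""

    labels: np.ndarray
    identity_map: dict[int, Identity]
    kind: Literal["nuclei", "cells"]
    voxel_size_zyx: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 4:
            raise SchemaError(f"label volume must be 4-D (T,Z,Y,X), got {self.labels.ndim}-D")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.identity_map)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} absent from identity map")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.labels[t]

    def voxel_counts(self, t: int) -> dict[int, int]:
        vals, counts = np.unique(self.labels[t], return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if v != 0}


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline, all dimensional fields in
    micrometres / minutes unless stated otherwise."""

    target_voxel_um: float = 0.33
    gaussian_sigma_um: float = 0.5
    background_radius_um: float = 10.0
    background_level: float = 0.0
    # nuclei GMM
    gmm_alpha: float = 1.0
    gmm_reg_um2: float = 1e-3
    gmm_tol: float = 1e-6
    gmm_max_iter: int = 200
    laplacian_kappa: float = 1.0
    min_component_um3: float = 1.0
    # tracking
    tracking_epsilon_um: float = 0.33
    # cell segmentation
    border_volume_um3: float = 1250.0
    polar_volume_um3: float = 600.0
    membrane_sigma_um: float = 0.66
    membrane_angle_step_deg: float = 30.0
    # neighbour exchange
    exchange_tau_voxels: float = 30.0
    exchange_max_step: int = 10
    # mode classifier
    classifier_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "target_voxel_um", "gaussian_sigma_um", "background_radius_um",
            "gmm_reg_um2", "gmm_tol", "tracking_epsilon_um",
            "border_volume_um3", "polar_volume_um3", "membrane_sigma_um",
            "membrane_angle_step_deg", "exchange_tau_voxels", "min_component_um3",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.gmm_max_iter < 1:
            raise ValidationError("gmm_max_iter must be >= 1")

    @property
    def exchange_tau_um(self) -> float:
        """Exchange threshold converted to micrometres (voxels x voxel size)."""
        return self.exchange_tau_voxels * self.target_voxel_um

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
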