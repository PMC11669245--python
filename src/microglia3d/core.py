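"""Core containers shared by every pipeline stage.

Conventions (used throughout the package):

* voxel indices are 0-based in ``(z, y, x)`` order;
* spacing tuples are ``(dz, dy, dx)`` in micrometres per voxel;
* physical coordinates refer to voxel *centres*, except convex-hull
  computations which use voxel *corners* (see :mod:`microglia3d.morphometry`);
* bounding boxes are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: fixed class order of the voxel classifier and every probability map
CLASSES = ("microglia", "vasculature", "background")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Voxel grid geometry of a confocal acquisition.

    Parameters
    ----------
    nx, ny : int
        Lateral pixels per axis.
    nz : int
        Number of z-slices.
    dx, dy : float
        Lateral pixel pitch in micrometres per pixel.  Lateral pixels are
        square (``dx == dy``).
    dz : float
        Axial slice spacing in micrometres.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("dx", "dy", "dz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not np.isclose(self.dx, self.dy):
            raise ValueError("lateral pixels must be square (dx == dy)")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)``."""
        return (self.nz, self.ny, self.nx)

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing ``(dz, dy, dx)`` in micrometres."""
        return (self.dz, self.dy, self.dx)

    @property
    def field_um(self) -> tuple[float, float, float]:
        """Physical extent ``(z, y, x)`` of the stack in micrometres."""
        return (self.nz * self.dz, self.ny * self.dy, self.nx * self.dx)

    @property
    def field_area_mm2(self) -> float:
        """Lateral field of view in mm** 2 (the count/mm**2 denominator)."""
        return (self.nx * self.dx) * (self.ny * self.dy) * 1e-6

    @property
    def volume_mm3(self) -> float:
        """Stack volume in mm**3 (the count/mm**3 denominator)."""
        return self.field_area_mm2 * self.nz * self.dz * 1e-3

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("nx", "ny", "nz", "dx", "dy", "dz")}

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(**{k: d[k] for k in ("nx", "ny", "nz", "dx", "dy", "dz")})


#: the acquisition used for the donor stacks: 2048 x 2048 px mapping to
#: 319.45 um x 319.45 um laterally, 1 um z-steps.
ACQUISITION_PITCH_UM = 319.45 / 2048  # ~0.156 um/px


@dataclass
class Stack:
    """A single- or multi-channel 3D image with physical voxel spacing.

    ``data`` has shape ``(z, y, x)`` or ``(channel, z, y, x)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"stack must be 3D or (channel, z, y, x) 4D, got ndim={self.data.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive floats (dz, dy, dx)")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    def channel(self, index_or_name: int | str) -> "Stack":
        """Return one channel as a 3D Stack."""
        if isinstance(index_or_name, str):
            if not self.channel_names or index_or_name not in self.channel_names:
                raise KeyError(f"unknown channel {index_or_name!r}")
            index = self.channel_names.index(index_or_name)
        else:
            index = index_or_name
        if self.data.ndim == 3:
            if index != 0:
                raise IndexError("single-channel stack")
            return Stack(self.data, self.spacing)
        return Stack(self.data[index], self.spacing)


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities for (microglia, vasculature, background).

    ``probs`` has shape ``(3, z, y, x)``; at every voxel the three components
    lie in [0, 1] and sum to one within 1e-6.
    """

    probs: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs)
        if self.probs.ndim != 4 or self.probs.shape[0] != len(CLASSES):
            raise ValueError("probs must have shape (3, z, y, x)")

    def validate(self, atol: float = 1e-6) -> None:
        if self.probs.min() < -atol or self.probs.max() > 1 + atol:
            raise ValueError("probabilities outside [0, 1]")
        total = self.probs.sum(axis=0, dtype=np.float64)
        if not np.allclose(total, 1.0, atol=atol):
            raise ValueError("probabilities do not sum to 1 at every voxel")

    def class_prob(self, name: str) -> np.ndarray:
        return self.probs[CLASSES.index(name)]


@dataclass
class LabelVolume:
    """Integer instance labelling: 0 = background, k >= 1 = instance k.

    Label ids are contiguous ``1..K`` after :func:`compact_labels`.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    connectivity: int = 26  # declared 3D connectivity of the instances

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z, y, x)")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def volumes_um3(self) -> dict[int, float]:
        """Physical volume per label id."""
        vv = float(np.prod(self.spacing))
        counts = np.bincount(self.labels.ravel())
        return {i: counts[i] * vv for i in range(1, len(counts)) if counts[i] > 0}


def compact_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels to contiguous 1..K preserving order."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=labels.dtype)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=labels.dtype)
    return lut[labels]


@dataclass
class MicrogliaROI:
    """One segmented cell: its voxels, bounding box and provenance."""

    label_id: int
    coords: np.ndarray  # (n, 3) int voxel indices (z, y, x)
    spacing: tuple[float, float, float]
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = field(default=None)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) == 0:
            raise ValueError("ROI must contain at least one voxel as an (n, 3) index array")
        if self.bbox is None:
            lo = self.coords.min(axis=0)
            hi = self.coords.max(axis=0) + 1
            self.bbox = tuple((int(a), int(b)) for a, b in zip(lo, hi))

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    @property
    def volume_um3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))

    def mask(self) -> np.ndarray:
        """Binary mask cropped to the bounding box."""
        lo = np.array([b[0] for b in self.bbox])
        shape = tuple(b[1] - b[0] for b in self.bbox)
        m = np.zeros(shape, dtype=bool)
        c = self.coords - lo
        m[c[:, 0], c[:, 1], c[:, 2]] = True
        return m


def rois_from_labels(vol: LabelVolume, provenance: dict | None = None) -> list[MicrogliaROI]:
    """Split a label volume into per-cell ROIs (ascending label id)."""
    out = []
    flat = vol.labels
    for lab in vol.ids:
        coords = np.argwhere(flat == lab)
        out.append(
            MicrogliaROI(
                label_id=int(lab),
                coords=coords,
                spacing=vol.spacing,
                provenance=dict(provenance or {}),
            )
        )
    return out
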