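"""File I/O: OME-TIFF stacks, label volumes, sparse labels, configuration.

Stacks are normalized to ``(channel, z, y, x)`` axis order with voxel
spacing attached; when a plain TIFF carries no physical-size metadata the
configured default spacing is used with a logged warning (the acquisition
default is the donor-imaging pitch, 319.45/2048 um laterally and 1 um
axially).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import ACQUISITION_PITCH_UM, LabelVolume, Stack

log = logging.getLogger("microglia3d")

DEFAULT_SPACING = (1.0, ACQUISITION_PITCH_UM, ACQUISITION_PITCH_UM)  # (dz, dy, dx) um


def write_stack(path, stack: Stack) -> None:
    """Write an OME-TIFF with axes CZYX and physical pixel sizes in metadata."""
    data = stack.data if stack.data.ndim == 4 else stack.data[None]
    dz, dy, dx = stack.spacing
    metadata = {
        "axes": "CZYX",
        "PhysicalSizeX": dx,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz,
        "PhysicalSizeZUnit": "µm",
    }
    if stack.channel_names:
        metadata["Channel"] = {"Name": list(stack.channel_names)}
    tifffile.imwrite(path, np.ascontiguousarray(data), ome=True, metadata=metadata)


def _spacing_from_ome(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        dx = px.get("PhysicalSizeX")
        dy = px.get("PhysicalSizeY")
        dz = px.get("PhysicalSizeZ")
        if dx and dy and dz:
            return (float(dz), float(dy), float(dx))
    except Exception:
        pass
    return None


def read_stack(
    path,
    default_spacing: tuple[float, float, float] | None = None,
    axes: str | None = None,
) -> Stack:
    """Read a TIFF/OME-TIFF into a ``(channel, z, y, x)``-ordered Stack.

    ``axes`` overrides the axis order for plain TIFFs (e.g. ``'ZYX'`` or
    ``'YXZ'``); OME files declare their own.  Missing spacing metadata falls
    back to ``default_spacing`` (or the acquisition default) with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        spacing = None
        file_axes = None
        if tif.is_ome and tif.ome_metadata:
            spacing = _spacing_from_ome(tif)
            file_axes = tif.series[0].axes
    order = axes or file_axes
    if order is None:
        if data.ndim == 3:
            order = "ZYX"
        elif data.ndim == 4:
            order = "CZYX"
        else:
            raise ValueError(f"cannot infer axes for {data.ndim}-D data in {path.name}")
    order = order.upper().replace("S", "C").replace("T", "Z")
    if set(order) - set("CZYX") or len(order) != data.ndim:
        raise ValueError(f"ambiguous axis order {order!r} for shape {data.shape}")
    target = "CZYX" if "C" in order else "ZYX"
    data = np.transpose(data, [order.index(ax) for ax in target])
    if spacing is None:
        spacing = default_spacing or DEFAULT_SPACING
        log.warning(
            "%s carries no voxel-size metadata; using default spacing (dz, dy, dx) = %s um",
            path.name,
            spacing,
        )
    return Stack(data=data, spacing=tuple(spacing))


def write_labels(path, vol: LabelVolume) -> None:
    """Label volume as a 16-bit label TIFF (ids must fit uint16)."""
    if vol.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as uint16")
    dz, dy, dx = vol.spacing
    tifffile.imwrite(
        path,
        vol.labels.astype(np.uint16),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
        },
    )


def read_labels(path, default_spacing=None) -> LabelVolume:
    s = read_stack(path, default_spacing=default_spacing)
    data = s.data[0] if s.data.ndim == 4 else s.data
    return LabelVolume(labels=data.astype(np.int32), spacing=s.spacing)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Every tunable pipeline parameter, round-trippable through YAML."""

    # acquisition defaults (used when files carry no metadata)
    dz: float = 1.0
    dy: float = ACQUISITION_PITCH_UM
    dx: float = ACQUISITION_PITCH_UM
    # feature bank / classifier
    sigmas: tuple[float, ...] = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0)
    anisotropy_correction: bool = False
    n_trees: int = 100
    max_depth: int | None = None
    classifier_seed: int = 0
    # segmentation
    smooth_sigma: float = 1.0
    v_threshold: float = 0.5
    min_volume_um3: float = 100.0
    min_separation_um: float = 5.0
    marker_min_distance_um: float = 1.5
    # coloc
    positivity_min_voxels: int = 2
    cd68_scope: str = "within_cells"
    # statistics
    normality_alpha: float = 0.05
    # bookkeeping
    output_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sigmas"] = list(self.sigmas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sigmas" in d:
            d["sigmas"] = tuple(d["sigmas"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Inputs, parameters and outputs of one pipeline run."""

    inputs: list[dict] = field(default_factory=list)  # {path, sha256, group}
    config_hash: str = ""
    package_version: str = ""
    stage_timings_s: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))
        tmp.replace(path)  # atomic on POSIX


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
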