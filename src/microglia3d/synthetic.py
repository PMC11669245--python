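"""Synthetic multi-channel confocal stacks with known ground truth.

The generator emulates the imaging regime of IBA-1 / CD68 dual-labelled
retinal wholemount z-stacks: sparse microglia whose morphology spans a
ramified-to-amoeboid spectrum, bright tube-like vasculature that fluoresces
in the IBA-1 channel, CD68 puncta concentrated inside most cells, Gaussian
PSF blur and Poisson + read noise.  Every object is voxelized analytically,
so the true instance labels, per-cell volumes and per-cell CD68 content are
known exactly and serve as oracles for the segmentation and measurement
stages.

A cell is modelled as an ellipsoidal soma plus ``n_processes`` random-walk
tubes.  A per-cell *amoeboid score* ``a`` in [0, 1] trades process volume
for soma volume at a fixed volume target, so amoeboid-parameterized cells
(high ``a``) are compact and ramified ones (low ``a``) are branched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import AcquisitionGeometry, LabelVolume, Stack

__all__ = [
    "SceneParams",
    "CellSpec",
    "VesselSpec",
    "SyntheticScene",
    "GroundTruth",
    "PackingError",
    "control_params",
    "ad_params",
    "generate_scene",
    "render_stack",
]


class PackingError(RuntimeError):
    """Raised when cells cannot be placed without violating spacing bounds."""


def default_geometry() -> AcquisitionGeometry:
    """Desk-scale crop of the acquisition field.

    The donor stacks are 2048 x 2048 px over 319.45 um x 319.45 um with 1 um
    z-steps.  The default synthetic field keeps a comparable physical extent
    (79.9 x 79.9 x 40 um) at a 2x coarser lateral pitch (319.45/1024 um/px)
    so that full pipelines stay desk-scale; the acquisition-pitch grid is available
    by passing a custom geometry.
    """
    return AcquisitionGeometry(nx=256, ny=256, nz=40, dx=319.45 / 1024, dy=319.45 / 1024, dz=1.0)


@dataclass(frozen=True)
class SceneParams:
    """Generator configuration.  Defaults encode the study conditions.

    ``mean_volume_um3`` defaults to the control-group mean cell volume
    (1085 um^3); :func:`ad_params` switches to the AD mean (1754 um^3) and a
    lower count.  ``cd68_positive_fraction`` defaults to 0.9, matching the
    ~90% CD68+ proportion seen in both groups.
    """

    geometry: AcquisitionGeometry = field(default_factory=default_geometry)
    n_cells: int = 30
    group: str = "control"
    mean_volume_um3: float = 1085.0
    volume_cv: float = 0.45  # lognormal spread of per-cell volume targets
    amoeboid_range: tuple[float, float] = (0.15, 0.85)
    n_process_range: tuple[int, int] = (2, 6)
    process_radius_range: tuple[float, float] = (0.4, 1.0)
    max_process_length_um: float = 35.0
    territory_radius_um: float = 18.0  # microglia are territorial: processes stay near the soma
    # cap rarely binds even for the AD volume tail; a binding cap would force
    # big cells into extra processes and couple shape to size across groups
    soma_radius_max_um: float = 7.5
    min_spacing_um: float = 12.0
    cd68_positive_fraction: float = 0.9
    cd68_puncta_range: tuple[int, int] = (1, 8)
    cd68_punctum_radius_range: tuple[float, float] = (0.5, 1.5)
    ad_puncta_multiplier: int = 2  # AD cells carry ~2x the puncta of controls
    n_vessels: int = 2
    vessel_radius_range: tuple[float, float] = (2.0, 4.0)
    vessel_bleed: bool = True
    cell_intensity: float = 100.0
    vessel_intensity: float = 170.0
    punctum_intensity: float = 140.0
    background_level: float = 10.0
    psf_sigma_um: tuple[float, float, float] = (1.0, 0.3, 0.3)  # (z, y, x)
    photon_scale: float = 4.0  # photons per intensity unit; 0 disables shot noise
    read_noise_sigma: float = 2.0  # additive Gaussian, intensity units
    max_placement_tries: int = 400

    def replace(self, **kw) -> "SceneParams":
        return dataclasses.replace(self, **kw)


def control_params(**kw) -> SceneParams:
    """Study conditions for the control group."""
    return SceneParams(**kw)


def ad_params(**kw) -> SceneParams:
    """Study conditions for the AD group: larger cells, lower count.

    The 0.69 count ratio follows the reported machine densities
    (8441 vs 12213 count/mm^3); at 30 control cells per field that gives 21.
    """
    kw.setdefault("group", "AD")
    kw.setdefault("mean_volume_um3", 1754.0)
    kw.setdefault("n_cells", 21)
    return SceneParams(**kw)


@dataclass
class CellSpec:
    """Realized geometry of one synthetic cell (all coordinates in um, (z, y, x))."""

    centroid: tuple[float, float, float]
    soma_radii: tuple[float, float, float]
    processes: list[dict]  # each {"path": [(z,y,x), ...], "radius": float}
    target_volume_um3: float
    amoeboid: float
    cd68_positive: bool
    cd68_puncta: list[dict]  # each {"center": (z,y,x), "radius": float}
    group: str

    @property
    def n_processes(self) -> int:
        return len(self.processes)

    def to_dict(self) -> dict:
        return {
            "centroid": list(self.centroid),
            "soma_radii": list(self.soma_radii),
            "processes": [
                {"path": [list(p) for p in pr["path"]], "radius": pr["radius"]}
                for pr in self.processes
            ],
            "target_volume_um3": self.target_volume_um3,
            "amoeboid": self.amoeboid,
            "cd68_positive": self.cd68_positive,
            "cd68_puncta": [
                {"center": list(p["center"]), "radius": p["radius"]} for p in self.cd68_puncta
            ],
            "group": self.group,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellSpec":
        return cls(
            centroid=tuple(d["centroid"]),
            soma_radii=tuple(d["soma_radii"]),
            processes=[
                {"path": [tuple(p) for p in pr["path"]], "radius": pr["radius"]}
                for pr in d["processes"]
            ],
            target_volume_um3=d["target_volume_um3"],
            amoeboid=d["amoeboid"],
            cd68_positive=d["cd68_positive"],
            cd68_puncta=[{"center": tuple(p["center"]), "radius": p["radius"]} for p in d["cd68_puncta"]],
            group=d["group"],
        )


@dataclass
class VesselSpec:
    """A blood-vessel analogue: a tube along a polyline."""

    path: list[tuple[float, float, float]]
    radius: float

    def to_dict(self) -> dict:
        return {"path": [list(p) for p in self.path], "radius": self.radius}

    @classmethod
    def from_dict(cls, d: dict) -> "VesselSpec":
        return cls(path=[tuple(p) for p in d["path"]], radius=d["radius"])


@dataclass
class SyntheticScene:
    """Fully realized scene: serializable and reproducible bit-for-bit."""

    geometry: AcquisitionGeometry
    cells: list[CellSpec]
    vessels: list[VesselSpec]
    psf_sigma_um: tuple[float, float, float]
    photon_scale: float
    read_noise_sigma: float
    background_level: float
    cell_intensity: float
    vessel_intensity: float
    punctum_intensity: float
    vessel_bleed: bool
    rng_seed: int

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "cells": [c.to_dict() for c in self.cells],
            "vessels": [v.to_dict() for v in self.vessels],
            "psf_sigma_um": list(self.psf_sigma_um),
            "photon_scale": self.photon_scale,
            "read_noise_sigma": self.read_noise_sigma,
            "background_level": self.background_level,
            "cell_intensity": self.cell_intensity,
            "vessel_intensity": self.vessel_intensity,
            "punctum_intensity": self.punctum_intensity,
            "vessel_bleed": self.vessel_bleed,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScene":
        return cls(
            geometry=AcquisitionGeometry.from_dict(d["geometry"]),
            cells=[CellSpec.from_dict(c) for c in d["cells"]],
            vessels=[VesselSpec.from_dict(v) for v in d["vessels"]],
            psf_sigma_um=tuple(d["psf_sigma_um"]),
            photon_scale=d["photon_scale"],
            read_noise_sigma=d["read_noise_sigma"],
            background_level=d["background_level"],
            cell_intensity=d["cell_intensity"],
            vessel_intensity=d["vessel_intensity"],
            punctum_intensity=d["punctum_intensity"],
            vessel_bleed=d["vessel_bleed"],
            rng_seed=d["rng_seed"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SyntheticScene":
        return cls.from_dict(json.loads(s))


@dataclass
class GroundTruth:
    """Unblurred voxel-level truth for one rendered scene."""

    labels: LabelVolume  # cells 1..N then vessels N+1..N+V
    n_cells: int
    cell_volumes_um3: dict[int, float]
    cd68_mask: np.ndarray  # true punctum voxels (inside cells), bool
    cd68_volumes_um3: dict[int, float]
    vessel_ids: tuple[int, ...]

    @property
    def cell_mask(self) -> np.ndarray:
        lab = self.labels.labels
        return (lab >= 1) & (lab <= self.n_cells)

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.labels.labels > self.n_cells


# ---------------------------------------------------------------------------
# voxelization primitives


def _voxel_centers_1d(n: int, d: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * d


def _paint_ellipsoid(mask: np.ndarray, geom: AcquisitionGeometry, center, radii) -> None:
    """Set voxels whose centre lies inside the ellipsoid."""
    spacing = geom.spacing
    lo, hi = [], []
    for ax in range(3):
        n = mask.shape[ax]
        lo.append(max(0, int((center[ax] - radii[ax]) / spacing[ax] - 1)))
        hi.append(min(n, int((center[ax] + radii[ax]) / spacing[ax] + 2)))
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz = _voxel_centers_1d(mask.shape[0], spacing[0])[lo[0]:hi[0]]
    yy = _voxel_centers_1d(mask.shape[1], spacing[1])[lo[1]:hi[1]]
    xx = _voxel_centers_1d(mask.shape[2], spacing[2])[lo[2]:hi[2]]
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    inside = (
        ((Z - center[0]) / radii[0]) ** 2
        + ((Y - center[1]) / radii[1]) ** 2
        + ((X - center[2]) / radii[2]) ** 2
    ) <= 1.0
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= inside


def _paint_segment(mask: np.ndarray, geom: AcquisitionGeometry, p0, p1, radius: float) -> None:
    """Set voxels whose centre lies within ``radius`` of segment p0-p1."""
    spacing = geom.spacing
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    lo, hi = [], []
    for ax in range(3):
        n = mask.shape[ax]
        a = min(p0[ax], p1[ax]) - radius
        b = max(p0[ax], p1[ax]) + radius
        lo.append(max(0, int(a / spacing[ax] - 1)))
        hi.append(min(n, int(b / spacing[ax] + 2)))
    if any(l >= h for l, h in zip(lo, hi)):
        return
    zz = _voxel_centers_1d(mask.shape[0], spacing[0])[lo[0]:hi[0]]
    yy = _voxel_centers_1d(mask.shape[1], spacing[1])[lo[1]:hi[1]]
    xx = _voxel_centers_1d(mask.shape[2], spacing[2])[lo[2]:hi[2]]
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    P = np.stack([Z, Y, X], axis=-1)
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0.0:
        closest = p0
        dist2 = ((P - closest) ** 2).sum(axis=-1)
    else:
        t = np.clip(((P - p0) @ d) / dd, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist2 = ((P - closest) ** 2).sum(axis=-1)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dist2 <= radius**2


def voxelize_cell(cell: CellSpec, geom: AcquisitionGeometry) -> np.ndarray:
    """Binary voxelization of one cell on the full grid."""
    mask = np.zeros(geom.shape, dtype=bool)
    _paint_ellipsoid(mask, geom, cell.centroid, cell.soma_radii)
    for pr in cell.processes:
        path = pr["path"]
        for a, b in zip(path[:-1], path[1:]):
            _paint_segment(mask, geom, a, b, pr["radius"])
    return mask


def voxelize_vessel(vessel: VesselSpec, geom: AcquisitionGeometry) -> np.ndarray:
    mask = np.zeros(geom.shape, dtype=bool)
    for a, b in zip(vessel.path[:-1], vessel.path[1:]):
        _paint_segment(mask, geom, a, b, vessel.radius)
    return mask


# ---------------------------------------------------------------------------
# scene generation


def _sample_cell(
    rng: np.random.Generator,
    params: SceneParams,
    centroid: np.ndarray,
    target_volume: float,
) -> CellSpec:
    geom = params.geometry
    extent = np.array(geom.field_um)
    # linear dimensions scale with the cube root of cell volume so that the
    # dimensionless shape metrics are size-invariant ("same shape, larger
    # cell"): bigger microglia span proportionally larger territories
    size_scale = (target_volume / 1085.0) ** (1.0 / 3.0)
    territory = params.territory_radius_um * size_scale
    max_len = params.max_process_length_um * size_scale
    a = rng.uniform(*params.amoeboid_range)
    soma_fraction = 0.35 + 0.5 * a  # amoeboid cells concentrate volume in the soma
    soma_vol = soma_fraction * target_volume
    r_eq = (3.0 * soma_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_eq = min(r_eq, params.soma_radius_max_um)
    # mild random anisotropy, volume preserved
    f = rng.uniform(0.85, 1.18, size=3)
    f /= f.prod() ** (1.0 / 3.0)
    soma_radii = r_eq * f
    soma_vol_actual = 4.0 / 3.0 * np.pi * soma_radii.prod()

    n_p = int(rng.integers(params.n_process_range[0], params.n_process_range[1] + 1))
    proc_vol_total = max(target_volume - soma_vol_actual, 0.05 * target_volume)
    shares = rng.uniform(0.6, 1.4, size=n_p)
    shares /= shares.sum()
    processes = []
    step = 2.5
    for k in range(n_p):
        r_p = rng.uniform(*params.process_radius_range)
        vol_k = proc_vol_total * shares[k]
        length = vol_k / (np.pi * r_p**2)
        length = float(np.clip(length, 2.0, max_len))
        r_p = float(np.sqrt(vol_k / (np.pi * length)))
        # direction biased to the lateral plane: the field is shallow in z
        d = rng.normal(size=3)
        d[0] *= 0.4
        d /= np.linalg.norm(d) + 1e-12
        start = centroid + d * (np.array(soma_radii) * np.abs(d)).sum() * 0.8
        path = [tuple(start)]
        pos = start.copy()
        n_steps = max(1, int(np.ceil(length / step)))
        for _ in range(n_steps):
            d = d + rng.normal(scale=0.35, size=3) * np.array([0.5, 1.0, 1.0])
            # territorial confinement: bend back toward the soma near the
            # territory boundary (neighbouring microglia do not interdigitate)
            radial = pos - centroid
            rnorm = np.linalg.norm(radial)
            if rnorm > 0.7 * territory:
                pull = (rnorm / territory - 0.7) * 2.0
                d = d - pull * radial / rnorm
            d /= np.linalg.norm(d) + 1e-12
            pos = pos + d * min(step, length)
            # reflect off the stack walls (margin = tube radius)
            for ax in range(3):
                m = r_p + 0.3
                if pos[ax] < m:
                    pos[ax] = 2 * m - pos[ax]
                    d[ax] = abs(d[ax])
                if pos[ax] > extent[ax] - m:
                    pos[ax] = 2 * (extent[ax] - m) - pos[ax]
                    d[ax] = -abs(d[ax])
            path.append(tuple(pos))
        processes.append({"path": path, "radius": r_p, "length": length})
    # path lengths already encode the volume budget; drop helper key
    for pr in processes:
        pr.pop("length", None)
    return CellSpec(
        centroid=tuple(centroid),
        soma_radii=tuple(soma_radii),
        processes=processes,
        target_volume_um3=target_volume,
        amoeboid=a,
        cd68_positive=False,
        cd68_puncta=[],
        group=params.group,
    )


def _calibrate_cell(cell: CellSpec, geom: AcquisitionGeometry, vox_vol: float) -> CellSpec:
    """Scale soma and process radii so the voxelized volume hits the target.

    Two or three fixed-point iterations on a single scale factor suffice to
    bring the realized volume within a few percent of ``target_volume_um3``.
    """
    target = cell.target_volume_um3
    for _ in range(4):
        realized = voxelize_cell(cell, geom).sum() * vox_vol
        if realized <= 0:
            break
        ratio = target / realized
        if abs(ratio - 1.0) < 0.015:
            break
        s = ratio ** (1.0 / 2.6)  # volume scales between r^2 (tubes) and r^3 (soma)
        cell = dataclasses.replace(
            cell,
            soma_radii=tuple(np.asarray(cell.soma_radii) * s),
            processes=[{"path": p["path"], "radius": p["radius"] * s} for p in cell.processes],
        )
    return cell


def _place_puncta(
    rng: np.random.Generator, cell: CellSpec, params: SceneParams
) -> list[dict]:
    lo_n, hi_n = params.cd68_puncta_range
    n = int(rng.integers(lo_n, hi_n + 1))
    if params.group.upper() == "AD":
        n *= params.ad_puncta_multiplier
    puncta = []
    radii = np.asarray(cell.soma_radii)
    for _ in range(n):
        r = rng.uniform(*params.cd68_punctum_radius_range)
        r = min(r, 0.65 * float(radii.min()))
        # sample inside the soma with the punctum fully contained
        frac = rng.uniform(0.0, 1.0) ** (1.0 / 3.0)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d) + 1e-12
        offset = d * frac * np.maximum(radii - r - 0.2, 0.0)
        center = np.asarray(cell.centroid) + offset
        puncta.append({"center": tuple(center), "radius": float(r)})
    return puncta


def generate_scene(params: SceneParams, seed: int) -> SyntheticScene:
    """Generate a reproducible scene under the given study conditions.

    The per-cell volume targets are lognormal draws rescaled so their sample
    mean equals ``params.mean_volume_um3`` exactly; the voxelized (true)
    volumes then land within a few percent of the target per cell.

    Raises
    ------
    PackingError
        If ``n_cells`` cannot be placed with the requested minimum centroid
        spacing inside the field.
    """
    if params.n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if params.mean_volume_um3 <= 0:
        raise ValueError("mean_volume_um3 must be positive")
    if not (0.0 <= params.cd68_positive_fraction <= 1.0):
        raise ValueError("cd68_positive_fraction must be in [0, 1]")
    geom = params.geometry
    rng = np.random.default_rng(seed)
    extent = np.array(geom.field_um)
    vox_vol = geom.voxel_volume_um3

    # volume targets: lognormal, rescaled to the requested mean
    if params.n_cells > 0:
        cv = params.volume_cv
        sigma = np.sqrt(np.log(1.0 + cv**2))
        draws = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=params.n_cells)
        targets = draws / draws.mean() * params.mean_volume_um3
    else:
        targets = np.array([])

    # placement by rejection sampling with a minimum centroid spacing
    centroids: list[np.ndarray] = []
    margin_z = 7.5  # soma radius bound + psf headroom
    margin_xy = 7.5
    for k in range(params.n_cells):
        placed = False
        for _ in range(params.max_placement_tries):
            c = np.array(
                [
                    rng.uniform(margin_z, extent[0] - margin_z),
                    rng.uniform(margin_xy, extent[1] - margin_xy),
                    rng.uniform(margin_xy, extent[2] - margin_xy),
                ]
            )
            if all(np.linalg.norm(c - o) >= params.min_spacing_um for o in centroids):
                centroids.append(c)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place cell {k + 1} of {params.n_cells}: minimum centroid "
                f"spacing {params.min_spacing_um} um is unsatisfiable in a "
                f"{extent[2]:.0f} x {extent[1]:.0f} x {extent[0]:.0f} um field"
            )

    cells = []
    n_pos_target = int(round(params.cd68_positive_fraction * params.n_cells))
    pos_flags = np.zeros(params.n_cells, dtype=bool)
    pos_flags[:n_pos_target] = True
    rng.shuffle(pos_flags)
    for k in range(params.n_cells):
        cell = _sample_cell(rng, params, centroids[k], float(targets[k]))
        cell = _calibrate_cell(cell, geom, vox_vol)
        if pos_flags[k]:
            cell = dataclasses.replace(
                cell, cd68_positive=True, cd68_puncta=_place_puncta(rng, cell, params)
            )
        cells.append(cell)

    vessels = []
    for _ in range(params.n_vessels):
        r = rng.uniform(*params.vessel_radius_range)
        axis = rng.integers(1, 3)  # traverse along y or x
        zc = rng.uniform(0.25, 0.75) * extent[0]
        other = rng.uniform(0.15, 0.85) * extent[3 - axis if axis == 2 else 2]
        n_pts = 6
        ts = np.linspace(0.0, 1.0, n_pts)
        path = []
        for t in ts:
            p = np.empty(3)
            p[0] = np.clip(zc + rng.normal(scale=1.5), r + 0.5, extent[0] - r - 0.5)
            if axis == 1:  # along y
                p[1] = t * extent[1]
                p[2] = np.clip(other + rng.normal(scale=3.0), 0.0, extent[2])
            else:  # along x
                p[2] = t * extent[2]
                p[1] = np.clip(other + rng.normal(scale=3.0), 0.0, extent[1])
            path.append(tuple(p))
        vessels.append(VesselSpec(path=path, radius=float(r)))

    return SyntheticScene(
        geometry=geom,
        cells=cells,
        vessels=vessels,
        psf_sigma_um=tuple(params.psf_sigma_um),
        photon_scale=params.photon_scale,
        read_noise_sigma=params.read_noise_sigma,
        background_level=params.background_level,
        cell_intensity=params.cell_intensity,
        vessel_intensity=params.vessel_intensity,
        punctum_intensity=params.punctum_intensity,
        vessel_bleed=params.vessel_bleed,
        rng_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# emulated expert annotation


def annotate_scene(
    truth: "GroundTruth",
    n_per_class: int = 400,
    seed: int = 0,
    background_multiplier: float = 2.25,
    shell_fraction: float = 0.5,
    process_fraction: float = 0.5,
) -> "SparseLabelMap":
    """Sparse training labels drawn from ground truth, annotator-style.

    Mirrors how experts annotate interactively: background strokes are drawn
    both far from and directly adjacent to objects (half of the background
    labels come from the 2-voxel shell around the foreground, so the PSF halo
    is explicitly taught as background), and microglia strokes deliberately
    cover thin processes (half the cell labels from voxels within 1.2 um of
    the cell surface) as well as somas.
    """
    from scipy import ndimage

    from .classify import SparseLabelMap

    tl = truth.labels.labels
    spacing = truth.labels.spacing
    rng = np.random.default_rng(seed)
    cell = truth.cell_mask
    vessel = truth.vessel_mask
    fg = tl > 0
    edt = ndimage.distance_transform_edt(cell, sampling=spacing)
    process = cell & (edt < 1.2)
    soma = cell & ~process
    shell = ndimage.binary_dilation(fg, iterations=2) & ~fg
    far = (tl == 0) & ~shell

    def pick(mask: np.ndarray, n: int) -> np.ndarray:
        coords = np.argwhere(mask)
        if len(coords) == 0 or n <= 0:
            return np.empty((0, 3), dtype=np.int64)
        sel = rng.choice(len(coords), size=min(n, len(coords)), replace=False)
        return coords[np.sort(sel)]

    n_proc = int(n_per_class * process_fraction)
    n_bg = int(n_per_class * background_multiplier)
    n_shell = int(n_bg * shell_fraction)
    coords = {
        "microglia": np.concatenate([pick(process, n_proc), pick(soma, n_per_class - n_proc)]),
        "vasculature": pick(vessel, n_per_class),
        "background": np.concatenate([pick(shell, n_shell), pick(far, n_bg - n_shell)]),
    }
    coords = {k: v for k, v in coords.items() if len(v)}
    return SparseLabelMap(coords=coords, shape=tl.shape)


def refine_annotations(
    classifier,
    stack: Stack,
    truth: "GroundTruth",
    labels: "SparseLabelMap",
    n_extra_per_class: int = 400,
    seed: int = 1,
) -> "SparseLabelMap":
    """One active-learning round: add labels where live prediction is wrong.

    Emulates the interactive workflow in which annotators inspect the live
    prediction and correct misclassified regions, then retrain.
    """
    from .classify import SparseLabelMap
    from .core import CLASSES

    tl = truth.labels.labels
    pmap = classifier.predict_probabilities(stack.channel(0))
    pred = np.argmax(pmap.probs, axis=0)
    true_cls = np.full(tl.shape, 2, dtype=np.int8)
    true_cls[truth.cell_mask] = 0
    true_cls[truth.vessel_mask] = 1
    wrong = pred != true_cls
    rng = np.random.default_rng(seed)
    merged = {}
    for k, cls in enumerate(CLASSES):
        base = labels.coords.get(cls, np.empty((0, 3), dtype=np.int64))
        cand = np.argwhere(wrong & (true_cls == k))
        if len(cand):
            sel = rng.choice(len(cand), size=min(n_extra_per_class, len(cand)), replace=False)
            extra = cand[np.sort(sel)]
            # keep at most one class per voxel: drop corrections colliding
            # with existing strokes of other classes
            taken = {tuple(c) for other, arr in labels.coords.items() if other != cls for c in arr}
            extra = np.array([c for c in extra if tuple(c) not in taken], dtype=np.int64).reshape(-1, 3)
            merged[cls] = np.unique(np.concatenate([base, extra]), axis=0)
        else:
            merged[cls] = base
    merged = {k: v for k, v in merged.items() if len(v)}
    return SparseLabelMap(coords=merged, shape=tl.shape)


# ---------------------------------------------------------------------------
# rendering


def render_stack(scene: SyntheticScene) -> tuple[Stack, GroundTruth]:
    """Render a scene to a 2-channel stack plus exact ground truth.

    Channel 0 is the IBA-1 analogue (cells, and vessels when bleed is on);
    channel 1 is the CD68 analogue (puncta only).  Ground-truth labels are
    the *unblurred* voxelized objects: cells get ids ``1..N`` (voxel
    collisions resolved in favour of the lower cell index), vessels
    ``N+1..N+V`` on voxels not claimed by any cell.
    """
    geom = scene.geometry
    vox_vol = geom.voxel_volume_um3
    labels = np.zeros(geom.shape, dtype=np.int32)

    n_cells = len(scene.cells)
    for idx, cell in enumerate(scene.cells, start=1):
        m = voxelize_cell(cell, geom)
        labels[m & (labels == 0)] = idx

    vessel_ids = []
    for vdx, vessel in enumerate(scene.vessels, start=n_cells + 1):
        m = voxelize_vessel(vessel, geom)
        claim = m & (labels == 0)
        if claim.any():
            labels[claim] = vdx
        vessel_ids.append(vdx)

    cell_volumes = {}
    counts = np.bincount(labels.ravel(), minlength=n_cells + len(scene.vessels) + 1)
    for idx in range(1, n_cells + 1):
        cell_volumes[idx] = float(counts[idx]) * vox_vol

    # CD68 truth: puncta voxels restricted to their own cell's voxels
    cd68_mask = np.zeros(geom.shape, dtype=bool)
    cd68_volumes = {}
    for idx, cell in enumerate(scene.cells, start=1):
        if not cell.cd68_puncta:
            cd68_volumes[idx] = 0.0
            continue
        pm = np.zeros(geom.shape, dtype=bool)
        for p in cell.cd68_puncta:
            _paint_ellipsoid(pm, geom, p["center"], (p["radius"],) * 3)
        pm &= labels == idx
        cd68_mask |= pm
        cd68_volumes[idx] = float(pm.sum()) * vox_vol

    # ideal images
    ch1 = np.full(geom.shape, scene.background_level, dtype=np.float32)
    cell_fg = (labels >= 1) & (labels <= n_cells)
    ch1[cell_fg] += scene.cell_intensity
    if scene.vessel_bleed and vessel_ids:
        ch1[labels > n_cells] += scene.vessel_intensity
    ch2 = np.full(geom.shape, scene.background_level * 0.3, dtype=np.float32)
    ch2[cd68_mask] += scene.punctum_intensity

    sigma_vox = tuple(s / d for s, d in zip(scene.psf_sigma_um, geom.spacing))
    rng = np.random.default_rng(np.random.SeedSequence([int(scene.rng_seed), 0x5CE17E]))
    out = []
    for ch in (ch1, ch2):
        img = ch
        if any(s > 0 for s in sigma_vox):
            img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="reflect")
        if scene.photon_scale > 0:
            img = rng.poisson(np.clip(img, 0, None) * scene.photon_scale).astype(np.float32)
            img /= scene.photon_scale
        if scene.read_noise_sigma > 0:
            img = img + rng.normal(scale=scene.read_noise_sigma, size=img.shape).astype(np.float32)
        out.append(img.astype(np.float32))

    stack = Stack(
        data=np.stack(out, axis=0),
        spacing=geom.spacing,
        channel_names=("IBA1", "CD68"),
    )
    truth = GroundTruth(
        labels=LabelVolume(labels=labels, spacing=geom.spacing),
        n_cells=n_cells,
        cell_volumes_um3=cell_volumes,
        cd68_mask=cd68_mask,
        cd68_volumes_um3=cd68_volumes,
        vessel_ids=tuple(vessel_ids),
    )
    return stack, truth
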