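"""CD68 (lysosomal marker) content per microglia.

CD68 is segmented by Otsu thresholding the CD68 channel over voxels inside
segmented cells (lysosomes outside cells carry no per-cell meaning; a
global-Otsu alternative is available).  Per cell we report the CD68 voxel
volume, its ratio to the cell volume, and a CD68+/- flag at a minimum-volume
positivity criterion (default: two voxels' physical volume, so a single
noisy voxel cannot flip a cell to CD68+).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from skimage.filters import threshold_otsu

from .core import LabelVolume, Stack


@dataclass
class ColocRecord:
    label_id: int
    cell_volume_um3: float
    cd68_volume_um3: float
    cd68_ratio: float
    cd68_positive: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StackColocSummary:
    n_cells: int
    n_cd68_positive: int

    @property
    def proportion_cd68_positive(self) -> float:
        """Percent of cells that are CD68+ (0-100)."""
        if self.n_cells == 0:
            return 0.0
        return 100.0 * self.n_cd68_positive / self.n_cells


def segment_cd68(
    cd68_channel: Stack | np.ndarray,
    cells: LabelVolume,
    scope: str = "within_cells",
    nbins: int = 256,
) -> tuple[np.ndarray, float | None]:
    """Binary CD68 mask from Otsu thresholding, with the threshold reported.

    ``scope='within_cells'`` (default) computes the threshold over voxels
    inside any cell and restricts the mask to cells; ``scope='global'``
    thresholds the whole channel.  An empty label volume yields an empty
    mask with a warning.
    """
    vol = cd68_channel.data if isinstance(cd68_channel, Stack) else np.asarray(cd68_channel)
    if vol.ndim != 3:
        raise ValueError("CD68 channel must be a single 3D channel")
    if vol.shape != cells.labels.shape:
        raise ValueError("CD68 channel and cell labels are not co-registered")
    inside = cells.labels > 0
    if scope == "within_cells":
        values = vol[inside]
    elif scope == "global":
        values = vol.ravel()
    else:
        raise ValueError("scope must be 'within_cells' or 'global'")
    if values.size == 0:
        warnings.warn("empty cell label volume; CD68 mask is empty", stacklevel=2)
        return np.zeros(vol.shape, bool), None
    if values.min() == values.max():
        warnings.warn("constant CD68 signal; no threshold exists, mask is empty", stacklevel=2)
        return np.zeros(vol.shape, bool), None
    thr = float(threshold_otsu(values, nbins=nbins))
    mask = vol > thr
    if scope == "within_cells":
        mask &= inside
    return mask, thr


def coloc_per_cell(
    cd68_mask: np.ndarray,
    cells: LabelVolume,
    positivity_min_um3: float | None = None,
) -> tuple[list[ColocRecord], StackColocSummary]:
    """Per-cell CD68 volume, CD68/IBA-1 ratio and CD68 status.

    ``positivity_min_um3`` defaults to two voxels' physical volume.
    """
    vox_vol = float(np.prod(cells.spacing))
    if positivity_min_um3 is None:
        positivity_min_um3 = 2.0 * vox_vol
    if positivity_min_um3 < 0:
        raise ValueError("positivity_min_um3 must be >= 0")
    labels = cells.labels
    if cd68_mask.shape != labels.shape:
        raise ValueError("CD68 mask and cell labels are not aligned")
    n_max = int(labels.max())
    counts = np.bincount(labels.ravel(), minlength=n_max + 1)
    cd_counts = np.bincount(labels[cd68_mask & (labels > 0)].ravel(), minlength=n_max + 1)
    records = []
    for lab in range(1, n_max + 1):
        if counts[lab] == 0:
            continue
        cell_v = counts[lab] * vox_vol
        cd_v = cd_counts[lab] * vox_vol
        records.append(
            ColocRecord(
                label_id=lab,
                cell_volume_um3=cell_v,
                cd68_volume_um3=cd_v,
                cd68_ratio=cd_v / cell_v,
                cd68_positive=bool(cd_v >= positivity_min_um3),
            )
        )
    summary = StackColocSummary(
        n_cells=len(records),
        n_cd68_positive=sum(r.cd68_positive for r in records),
    )
    return records, summary


def stratify_by_cd68(
    coloc_records: dict[str, list[ColocRecord]],
) -> "pd.DataFrame":
    """Long-format table of cell volumes stratified by group x CD68 status.

    ``coloc_records`` maps a group tag (e.g. 'control', 'AD') to that group's
    per-cell records, pooled across its stacks.  The output feeds the
    two-way ANOVA of the statistics layer; empty strata are flagged with a
    warning rather than silently dropped.
    """
    import pandas as pd

    rows = []
    for group, records in coloc_records.items():
        for r in records:
            rows.append(
                {
                    "group": group,
                    "cd68_status": "CD68+" if r.cd68_positive else "CD68-",
                    "volume_um3": r.cell_volume_um3,
                    "label_id": r.label_id,
                }
            )
    df = pd.DataFrame(rows, columns=["group", "cd68_status", "volume_um3", "label_id"])
    if len(df):
        for g in coloc_records:
            for s in ("CD68+", "CD68-"):
                if not ((df["group"] == g) & (df["cd68_status"] == s)).any():
                    warnings.warn(f"empty stratum: {g} / {s}", stacklevel=2)
    return df
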