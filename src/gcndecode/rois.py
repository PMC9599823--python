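"""Visual-cortex regions of interest: names, groups, binary mask templates.

The decoder operates on eleven functionally defined visual areas. V1--V3 are
split into dorsal/ventral halves; V4, LOC, FFA and PPA are object-, face- and
scene-selective regions; HVC (higher visual cortex) is the voxel-wise union of
LOC, FFA and PPA and is carried as an eleventh region in its own right.

Masks live on a fixed acquisition grid of 50 axial slices of 64 x 64 voxels.
Scans are stored as (time, depth, height, width) = (3, 50, 64, 64); all
mask/scan arithmetic broadcasts the 3D mask over the 3 time frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

#: Canonical ROI ordering. Every 11-row/column matrix in the pipeline
#: (feature matrices, adjacency) is indexed in this order.
ROI_NAMES: tuple[str, ...] = (
    "V1d", "V1v", "V2d", "V2v", "V3d", "V3v", "V4", "LOC", "FFA", "PPA", "HVC",
)

#: Default spatial grid (depth, height, width): 50 slices of 64 x 64.
DEFAULT_GRID: tuple[int, int, int] = (50, 64, 64)

#: Number of time frames per stimulus block (one volume per 3 s TR).
N_FRAMES = 3


class ROIGroup(str, Enum):
    """Functional hierarchy level of a visual region."""

    LOW_LEVEL = "low_level"
    MID_HIGH_LEVEL = "mid_high_level"


#: Group membership: the retinotopic dorsal/ventral areas form the low-level
#: group; V4 and the category-selective regions the mid/high-level group.
ROI_GROUPS: dict[str, ROIGroup] = {
    "V1d": ROIGroup.LOW_LEVEL,
    "V1v": ROIGroup.LOW_LEVEL,
    "V2d": ROIGroup.LOW_LEVEL,
    "V2v": ROIGroup.LOW_LEVEL,
    "V3d": ROIGroup.LOW_LEVEL,
    "V3v": ROIGroup.LOW_LEVEL,
    "V4": ROIGroup.MID_HIGH_LEVEL,
    "LOC": ROIGroup.MID_HIGH_LEVEL,
    "FFA": ROIGroup.MID_HIGH_LEVEL,
    "PPA": ROIGroup.MID_HIGH_LEVEL,
    "HVC": ROIGroup.MID_HIGH_LEVEL,
}

#: Constituents whose union defines HVC.
HVC_PARTS = ("LOC", "FFA", "PPA")


def roi_index(name: str) -> int:
    """Position of ``name`` in the canonical ordering."""
    return ROI_NAMES.index(name)


@dataclass
class Scan:
    """One stimulus block's fMRI: 3 time frames on the (depth, height, width) grid.

    ``label`` is the stimulus class in 1..10; ``subject`` identifies the
    (simulated) participant the block was recorded from.
    """

    data: np.ndarray  # (3, depth, height, width)
    subject: int
    label: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != N_FRAMES:
            raise ValueError(
                f"scan data must be ({N_FRAMES}, d, h, w), got {self.data.shape}"
            )
        if not 1 <= self.label:
            raise ValueError(f"label must be a positive class index, got {self.label}")


class TemplateError(ValueError):
    """Raised when a template violates a mask invariant."""


class GridMismatchError(ValueError):
    """Raised when a scan and template do not share one voxel grid."""


class DegenerateROIError(ValueError):
    """Raised when an operation requires a nonempty mask and the mask is empty."""


@dataclass
class ROITemplate:
    """Binary masks for the eleven ROIs on a shared voxel grid.

    Parameters
    ----------
    masks
        Mapping ROI name -> boolean/0-1 array of shape ``grid``.
    affine
        4x4 voxel-to-world affine, carried through NIfTI I/O unchanged.
    """

    masks: dict[str, np.ndarray]
    affine: np.ndarray = field(default_factory=lambda: np.diag([3.0, 3.0, 3.0, 1.0]))

    def __post_init__(self) -> None:
        self.validate()

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.masks[ROI_NAMES[0]].shape

    def validate(self) -> None:
        missing = [n for n in ROI_NAMES if n not in self.masks]
        if missing:
            raise TemplateError(f"template missing ROIs: {missing}")
        grid = self.masks[ROI_NAMES[0]].shape
        for name in ROI_NAMES:
            m = np.asarray(self.masks[name])
            if m.ndim != 3:
                raise TemplateError(f"{name}: mask must be 3D, got {m.ndim}D")
            if m.shape != grid:
                raise GridMismatchError(
                    f"{name}: grid {m.shape} differs from {ROI_NAMES[0]} grid {grid}"
                )
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise TemplateError(f"{name}: non-binary mask values {vals[:5]}")
            if m.sum() < 1:
                raise TemplateError(f"{name}: empty mask")
            self.masks[name] = m.astype(np.uint8)
        union = np.zeros(grid, dtype=np.uint8)
        for part in HVC_PARTS:
            union |= self.masks[part]
        if not np.array_equal(self.masks["HVC"], union):
            raise TemplateError("HVC union invariant violated: HVC != LOC | FFA | PPA")

    def mask_array(self) -> np.ndarray:
        """Masks stacked in canonical order, shape (11, depth, height, width)."""
        return np.stack([self.masks[n] for n in ROI_NAMES])

    # -- I/O ---------------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        """Write one NIfTI per ROI plus a JSON manifest; returns manifest path.

        A combined integer-labeled volume is written as a convenience view,
        but the manifest (per-ROI files) is the source of truth: HVC overlaps
        its constituents, which a single labeled volume cannot encode.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = {}
        for name in ROI_NAMES:
            fname = f"roi_{name}.nii"
            img = nib.Nifti1Image(
                # NIfTI convention is (x, y, z); store as (h, w, d) transposed view
                np.ascontiguousarray(self.masks[name].transpose(1, 2, 0)).astype(np.uint8),
                self.affine,
            )
            nib.save(img, directory / fname)
            entries[name] = {"file": fname, "group": ROI_GROUPS[name].value}
        labeled = np.zeros(self.grid, dtype=np.int16)
        for i, name in enumerate(ROI_NAMES[:-1], start=1):  # HVC overlaps, excluded
            labeled[self.masks[name] > 0] = i
        nib.save(
            nib.Nifti1Image(labeled.transpose(1, 2, 0), self.affine),
            directory / "labeled_combined.nii",
        )
        manifest = directory / "template_manifest.json"
        manifest.write_text(json.dumps({"rois": entries, "grid": list(self.grid)}, indent=1))
        return manifest


def load_template(path: str | Path) -> ROITemplate:
    """Load a template from a manifest (or its directory) written by :meth:`ROITemplate.save`.

    Raises
    ------
    FileNotFoundError, TemplateError, GridMismatchError
        On missing files or any mask-invariant violation (non-binary values,
        grid mismatch, HVC not equal to the LOC/FFA/PPA union).
    """
    path = Path(path)
    manifest = path / "template_manifest.json" if path.is_dir() else path
    if not manifest.exists():
        raise FileNotFoundError(f"no template manifest at {manifest}")
    spec = json.loads(manifest.read_text())
    masks = {}
    affine = None
    for name, entry in spec["rois"].items():
        img = nib.load(manifest.parent / entry["file"])
        if affine is None:
            affine = img.affine
        data = np.asarray(img.dataobj)
        masks[name] = data.transpose(2, 0, 1)  # (h, w, d) -> (d, h, w)
    return ROITemplate(masks=masks, affine=affine)


def _check_scan(scan_data: np.ndarray, template: ROITemplate) -> None:
    if scan_data.ndim != 4 or scan_data.shape[0] != N_FRAMES:
        raise GridMismatchError(
            f"scan must be ({N_FRAMES}, d, h, w), got shape {scan_data.shape}"
        )
    if scan_data.shape[1:] != template.grid:
        raise GridMismatchError(
            f"scan grid {scan_data.shape[1:]} != template grid {template.grid}"
        )


def apply_mask(scan_data: np.ndarray, roi: str, template: ROITemplate) -> np.ndarray:
    """Zero every voxel outside ``roi`` in all frames; voxels inside pass through.

    Element-wise product with the binary mask, broadcast over the time axis.
    Idempotent by construction.
    """
    _check_scan(scan_data, template)
    mask = template.masks[roi]
    return scan_data * mask[None, :, :, :]


def roi_mean_timecourse(scan_data: np.ndarray, roi: str, template: ROITemplate) -> np.ndarray:
    """Mean intensity inside ``roi`` per time frame; vector of length 3."""
    _check_scan(scan_data, template)
    mask = template.masks[roi].astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise DegenerateROIError(f"{roi}: empty mask, mean undefined")
    return scan_data[:, mask].mean(axis=1)
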