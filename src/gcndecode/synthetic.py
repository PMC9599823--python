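"""Seeded synthetic fMRI datasets with the structure the decoder assumes.

The generator emulates a blocked visual-stimulation experiment: for each
(subject, class, repetition) it emits a 3-frame volume as

    voxel = gain_s * (baseline + pattern_{c,r}(voxel) * ramp_t) + noise

where ``gain_s`` is a subject-specific multiplicative gain (lognormal,
emulating between-subject signal-level differences), ``pattern_{c,r}`` is a
fixed seeded spatial activation pattern for class c inside ROI r (zero
outside all ROIs), ``ramp_t`` = (0.8, 1.0, 0.9) is a fixed frame-wise gain
emulating a hemodynamic rise and fall, and the noise is i.i.d. Gaussian per
voxel. Patterns differ across classes within every ROI, so the class is
decodable from ROI content alone. Everything is bit-reproducible from
(config, seed).

ROI templates are generated by carving disjoint compact ellipsoidal blobs,
one per base region, into the octants of the grid; HVC is the voxel-wise
union of LOC, FFA and PPA, as in the decoder's region convention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .rois import (
    DEFAULT_GRID,
    HVC_PARTS,
    N_FRAMES,
    ROI_NAMES,
    ROITemplate,
    Scan,
)

#: Frame-wise signal gain emulating the hemodynamic ramp over the 3 frames.
FRAME_GAINS = np.array([0.8, 1.0, 0.9])

#: Baseline tissue intensity (arbitrary scanner units).
BASELINE = 100.0


class NormalizationError(ValueError):
    """A subject's voxel intensities have zero variance; z-scoring undefined."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions of a simulated experiment.

    ``effect_size`` is the mean class-signal amplitude in units of the noise
    SD; 0 produces an unsolvable (null) dataset. ``subject_gain_sd`` is the
    SD of the log of the subject gain. ``grid`` may be reduced from the
    default 50 x 64 x 64 for fast whole-pipeline experiments.
    """

    n_subjects: int = 5
    scans_per_class_per_subject: int = 20
    n_classes: int = 10
    effect_size: float = 2.0
    noise_sd: float = 1.0
    subject_gain_sd: float = 0.1
    seed: int = 0
    grid: tuple[int, int, int] = DEFAULT_GRID

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SyntheticDataset:
    """A generated template plus labeled scans, with provenance."""

    template: ROITemplate
    scans: list[Scan]
    config: GeneratorConfig

    def content_hash(self) -> str:
        """SHA-256 over all scan voxels and labels (regeneration determinism)."""
        h = hashlib.sha256()
        for scan in self.scans:
            h.update(np.int64(scan.subject).tobytes())
            h.update(np.int64(scan.label).tobytes())
            h.update(np.ascontiguousarray(scan.data).tobytes())
        return h.hexdigest()


def _partition_boxes(grid: tuple[int, int, int],
                     splits: tuple[int, int, int] = (3, 2, 2)) -> list[tuple[slice, ...]]:
    """Disjoint axis-aligned sub-boxes tiling the grid (3 x 2 x 2 = 12 boxes)."""
    edges = [np.linspace(0, g, s + 1).astype(int) for g, s in zip(grid, splits)]
    boxes = []
    for zd in range(splits[0]):
        for zh in range(splits[1]):
            for zw in range(splits[2]):
                boxes.append((
                    slice(edges[0][zd], edges[0][zd + 1]),
                    slice(edges[1][zh], edges[1][zh + 1]),
                    slice(edges[2][zw], edges[2][zw + 1]),
                ))
    return boxes


def generate_template(seed: int, grid: tuple[int, int, int] = DEFAULT_GRID) -> ROITemplate:
    """Synthetic ROI template: disjoint compact blobs plus the HVC union.

    The ten base regions (V1d..V3v, V4, LOC, FFA, PPA) are ellipsoids carved
    into distinct sub-boxes of the grid (hence mutually disjoint); HVC
    duplicates the LOC | FFA | PPA voxels. Blob sizes scale with the grid
    (100–600 voxels on the full 50 x 64 x 64 grid).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    base_names = [n for n in ROI_NAMES if n != "HVC"]
    boxes = _partition_boxes(grid)
    masks: dict[str, np.ndarray] = {}
    grid_vox = int(np.prod(grid))
    scale = grid_vox / np.prod(DEFAULT_GRID)
    # blobs scale with the grid but never shrink below the conv-kernel scale,
    # so reduced-grid regions remain spatially resolvable structures
    lo, hi = max(16, int(100 * scale)), max(40, int(600 * scale))
    occupied = np.zeros(grid, dtype=bool)
    for idx, name in enumerate(base_names):
        box = boxes[idx % len(boxes)]
        box_shape = tuple(s.stop - s.start for s in box)
        target = int(rng.integers(lo, hi + 1))
        # ellipsoid radius from target volume, clipped to fit the octant
        r = (3 * target / (4 * np.pi)) ** (1 / 3)
        radii = np.minimum(np.full(3, r), (np.array(box_shape) - 1) / 2.0)
        radii = np.maximum(radii, 0.6)
        center = np.empty(3)
        for ax, s in enumerate(box):
            lo_c = s.start + radii[ax] + 0.5
            hi_c = s.stop - radii[ax] - 0.5
            if hi_c <= lo_c:
                # tight box: sub-voxel jitter around the midpoint still varies
                # the discretized ellipsoid across seeds
                mid = (s.start + s.stop - 1) / 2.0
                lo_c, hi_c = mid - 0.4, mid + 0.4
            center[ax] = rng.uniform(lo_c, hi_c)
        zz, yy, xx = np.meshgrid(*[np.arange(g) for g in grid], indexing="ij")
        dist = (((zz - center[0]) / radii[0]) ** 2
                + ((yy - center[1]) / radii[1]) ** 2
                + ((xx - center[2]) / radii[2]) ** 2)
        blob = (dist <= 1.0) & ~occupied
        if not blob.any():  # guarantee nonemptiness on tiny grids
            free = np.argwhere(~occupied)
            pick = free[rng.integers(len(free))]
            blob = np.zeros(grid, dtype=bool)
            blob[tuple(pick)] = True
        occupied |= blob
        masks[name] = blob.astype(np.uint8)
    hvc = np.zeros(grid, dtype=np.uint8)
    for part in HVC_PARTS:
        hvc |= masks[part]
    masks["HVC"] = hvc
    return ROITemplate(masks=masks)


def _class_patterns(config: GeneratorConfig, template: ROITemplate) -> np.ndarray:
    """Fixed per-(class, voxel) activation amplitudes, zero outside all ROIs.

    Per-voxel amplitudes inside each base ROI are Gaussian with mean
    effect_size * noise_sd and SD of the same magnitude, drawn once per
    class from the dataset seed — the spatial arrangement, not the mean
    level, is what distinguishes classes.
    """
    amp = config.effect_size * config.noise_sd
    patterns = np.zeros((config.n_classes,) + tuple(config.grid))
    base_names = [n for n in ROI_NAMES if n != "HVC"]
    for c in range(config.n_classes):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1, c))
        )
        for r, name in enumerate(base_names):
            mask = template.masks[name].astype(bool)
            patterns[c][mask] = rng.normal(amp, amp if amp > 0 else 0.0,
                                           size=int(mask.sum()))
    return patterns


def generate_dataset(config: GeneratorConfig,
                     template: ROITemplate | None = None) -> SyntheticDataset:
    """Generate the labeled scans of a simulated experiment.

    Scans are emitted in (subject, class, repetition) order with labels 1..10
    balanced per subject. Identical (config, template) inputs regenerate the
    dataset bit-identically.
    """
    if template is None:
        template = generate_template(config.seed, config.grid)
    if template.grid != tuple(config.grid):
        raise ValueError(
            f"template grid {template.grid} != config grid {tuple(config.grid)}"
        )
    patterns = _class_patterns(config, template)
    scans: list[Scan] = []
    for subject in range(config.n_subjects):
        gain_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(2, subject))
        )
        gain = float(np.exp(gain_rng.normal(0.0, config.subject_gain_sd)))
        for c in range(config.n_classes):
            for rep in range(config.scans_per_class_per_subject):
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(3, subject, c, rep)
                ))
                signal = patterns[c][None] * FRAME_GAINS[:, None, None, None]
                noise = rng.normal(0.0, config.noise_sd,
                                   size=(N_FRAMES,) + tuple(config.grid))
                data = gain * (BASELINE + signal) + noise
                scans.append(Scan(data=data.astype(np.float32),
                                  subject=subject, label=c + 1))
    return SyntheticDataset(template=template, scans=scans, config=config)


def normalize_by_subject(scans: list[Scan], method: str = "zscore") -> list[Scan]:
    """Normalize voxel intensities per subject so subjects share one range.

    ``zscore`` (default): z-score every voxel with the subject's global mean
    and SD over all that subject's scans and frames, so each subject's data
    has mean 0 and SD 1. ``minmax``: map the subject's global [min, max] to
    [0, 1]. Normalization is per subject only — no statistics cross subjects,
    so applying it to held-out subjects leaks nothing.
    """
    if method not in ("zscore", "minmax"):
        raise ValueError(f"unknown normalization method {method!r}")
    subjects = sorted({s.subject for s in scans})
    out: list[Scan] = [None] * len(scans)  # type: ignore[list-item]
    for subject in subjects:
        idx = [i for i, s in enumerate(scans) if s.subject == subject]
        stacked = np.concatenate([scans[i].data.ravel() for i in idx])
        if method == "zscore":
            mu, sd = float(stacked.mean()), float(stacked.std())
            if sd == 0:
                raise NormalizationError(f"subject {subject}: zero variance")
            for i in idx:
                out[i] = Scan((scans[i].data - mu) / sd,
                              scans[i].subject, scans[i].label)
        else:
            lo, hi = float(stacked.min()), float(stacked.max())
            if hi == lo:
                raise NormalizationError(f"subject {subject}: constant intensities")
            for i in idx:
                out[i] = Scan((scans[i].data - lo) / (hi - lo),
                              scans[i].subject, scans[i].label)
    return out


# -- on-disk form --------------------------------------------------------


def save_dataset(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write template NIfTIs, one NIfTI per scan, and a CSV index."""
    import nibabel as nib
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.template.save(directory / "template")
    rows = []
    for i, scan in enumerate(dataset.scans):
        fname = f"scan_{i:05d}.nii"
        # (t, d, h, w) -> NIfTI (h, w, d, t)
        vol = np.ascontiguousarray(scan.data.transpose(2, 3, 1, 0))
        nib.save(nib.Nifti1Image(vol, dataset.template.affine), directory / fname)
        rows.append({"file": fname, "subject": scan.subject, "label": scan.label})
    index = directory / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    cfg = asdict(dataset.config)
    cfg["grid"] = list(cfg["grid"])
    (directory / "provenance.json").write_text(__import__("json").dumps(cfg, indent=1))
    return index


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Reload a dataset written by :func:`save_dataset`."""
    import json

    import nibabel as nib
    import pandas as pd

    from .rois import load_template

    directory = Path(directory)
    template = load_template(directory / "template")
    index = pd.read_csv(directory / "index.csv")
    scans = []
    for row in index.itertuples():
        vol = np.asarray(nib.load(directory / row.file).dataobj)
        scans.append(Scan(vol.transpose(3, 2, 0, 1), int(row.subject), int(row.label)))
    cfg = json.loads((directory / "provenance.json").read_text())
    cfg["grid"] = tuple(cfg["grid"])
    return SyntheticDataset(template=template, scans=scans,
                            config=GeneratorConfig(**cfg))
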