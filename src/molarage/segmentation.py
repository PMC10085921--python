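"""Intensity-threshold segmentation of third-molar MRI volumes.

A tooth imaged with a high-resolution T2 acquisition separates into three
tissue classes by signal intensity: hard tooth tissue (dentine, enamel and
cementum, collectively) is darkest, predentine intermediate, and pulp
brightest.  Voxels inside a pre-delineated tooth mask are classified by two
intensity cut points and each class is quantified as a volume in ml.

The default cut points (hard <= 63, predentine 64-100, pulp >= 101) assume
the intensity normalization of the acquisition they were calibrated on;
they are configurable because scanner intensity scales vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, ShapeError

__all__ = [
    "FDI_TEETH",
    "LABEL_BACKGROUND",
    "LABEL_HARD",
    "LABEL_PREDENTINE",
    "LABEL_PULP",
    "VoxelGrid",
    "ThresholdScheme",
    "ToothVolumes",
    "classify_voxels",
    "voxel_volume_ml",
    "compute_volumes",
    "load_voxel_grid",
    "save_voxel_grid",
    "save_labels",
]

#: FDI codes of the four third molars: upper right/left, lower left/right.
FDI_TEETH = (18, 28, 38, 48)

LABEL_BACKGROUND = 0
LABEL_HARD = 1
LABEL_PREDENTINE = 2
LABEL_PULP = 3


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D intensity image with voxel spacing and a tooth mask.

    Parameters
    ----------
    intensities
        Non-negative scalar field on a 3D lattice.  Continuous values are
        accepted and floored at classification time (the thresholds are
        defined on integer intensities).
    spacing_mm
        Voxel edge lengths in mm, all positive.
    mask
        Boolean field of the same shape; True marks voxels belonging to the
        tooth.  The mask is assumed to already embody the delineation
        conventions of the acquisition protocol (e.g. where a root apex
        ends); no morphological post-processing is applied here.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities)
        if intensities.ndim != 3:
            raise ShapeError(f"intensities must be 3D, got {intensities.ndim}D")
        mask = self.mask
        if mask is None:
            mask = np.ones(intensities.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != intensities.shape:
            raise ShapeError(
                f"mask shape {mask.shape} != intensity shape {intensities.shape}"
            )
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ConfigurationError(f"spacing_mm must be 3 positive lengths, got {self.spacing_mm}")
        if np.any(intensities < 0):
            raise ConfigurationError("intensities must be non-negative")
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


@dataclass(frozen=True)
class ThresholdScheme:
    """Intensity cut points separating the three tissue classes.

    ``hard_max`` is the largest intensity labelled hard tissue and
    ``predentine_max`` the largest labelled predentine; everything brighter
    is pulp.  Both bounds are inclusive.
    """

    hard_max: int = 63
    predentine_max: int = 100

    def __post_init__(self) -> None:
        if not (0 <= self.hard_max < self.predentine_max):
            raise ConfigurationError(
                f"require 0 <= hard_max < predentine_max, got {self.hard_max}, {self.predentine_max}"
            )


@dataclass(frozen=True)
class ToothVolumes:
    """Tissue volumes (ml) of one FDI tooth; the atomic measurement."""

    tooth_id: int
    pulp_ml: float
    predentine_ml: float
    hard_ml: float

    def __post_init__(self) -> None:
        if self.tooth_id not in FDI_TEETH:
            raise ConfigurationError(
                f"tooth_id must be one of {FDI_TEETH}, got {self.tooth_id}"
            )
        for name in ("pulp_ml", "predentine_ml", "hard_ml"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def total_ml(self) -> float:
        return self.pulp_ml + self.predentine_ml + self.hard_ml


def classify_voxels(grid: VoxelGrid, scheme: ThresholdScheme | None = None) -> np.ndarray:
    """Label every masked voxel as hard tissue, predentine or pulp.

    Returns an integer label field of the grid's shape with codes
    0 = background (outside mask), 1 = hard, 2 = predentine, 3 = pulp.
    Continuous intensities are floored before thresholding, so a voxel at
    63.9 is still hard tissue.
    """
    scheme = scheme or ThresholdScheme()
    intens = np.floor(grid.intensities).astype(np.int64)
    labels = np.full(grid.shape, LABEL_BACKGROUND, dtype=np.int8)
    labels[grid.mask & (intens <= scheme.hard_max)] = LABEL_HARD
    labels[grid.mask & (intens > scheme.hard_max) & (intens <= scheme.predentine_max)] = (
        LABEL_PREDENTINE
    )
    labels[grid.mask & (intens > scheme.predentine_max)] = LABEL_PULP
    return labels


def voxel_volume_ml(spacing_mm) -> float:
    """Volume of one voxel in ml (= cm^3) given its edge lengths in mm.

    At 0.37 mm iso-voxels one ml holds roughly 20,000 voxels, about the
    bulk of a single third molar.
    """
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_mm must be 3 positive lengths, got {spacing_mm}")
    return float(np.prod(spacing)) / 1000.0


def compute_volumes(labels: np.ndarray, spacing_mm, tooth_id: int) -> ToothVolumes:
    """Convert a label field into per-tissue volumes for one tooth.

    Each tissue volume is (voxel count of that label) x (voxel volume);
    the three volumes sum exactly to the masked volume.
    """
    vv = voxel_volume_ml(spacing_mm)
    labels = np.asarray(labels)
    return ToothVolumes(
        tooth_id=tooth_id,
        hard_ml=float(np.count_nonzero(labels == LABEL_HARD)) * vv,
        predentine_ml=float(np.count_nonzero(labels == LABEL_PREDENTINE)) * vv,
        pulp_ml=float(np.count_nonzero(labels == LABEL_PULP)) * vv,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def save_voxel_grid(grid: VoxelGrid, image_path: str | Path, mask_path: str | Path) -> None:
    """Write the intensity image and tooth mask as NIfTI files with the
    voxel spacing recorded in the affine."""
    aff = _affine(grid.spacing_mm)
    nib.save(nib.Nifti1Image(grid.intensities.astype(np.int32), aff), str(image_path))
    nib.save(nib.Nifti1Image(grid.mask.astype(np.uint8), aff), str(mask_path))


def load_voxel_grid(image_path: str | Path, mask_path: str | Path) -> VoxelGrid:
    """Read an intensity image and its tooth mask from NIfTI files."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(
        intensities=np.asarray(img.dataobj),
        spacing_mm=spacing,
        mask=np.asarray(msk.dataobj).astype(bool),
    )


def save_labels(labels: np.ndarray, spacing_mm, path: str | Path) -> None:
    """Write a label field (codes 0-3) as NIfTI."""
    nib.save(nib.Nifti1Image(labels.astype(np.uint8), _affine(spacing_mm)), str(path))
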