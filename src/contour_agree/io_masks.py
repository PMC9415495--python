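"""NIfTI volume/mask I/O, grid validation and the study manifest.

All spatial quantities are in millimetres; voxel indices are 0-based and
world coordinates come from the NIfTI affine. Volumes and masks are only
comparable when they share a grid (shape, spacing and affine within a small
absolute tolerance), which is how co-registration of the study inputs is
enforced at load time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

#: Absolute tolerance on spacing and affine entries when checking that two
#: grids describe the same physical sampling (float round-trip through headers).
GRID_ATOL = 1e-5

#: The fixed set of imaging sequences a study may contain.
SEQUENCES = ("T1-GD", "T2-FLAIR", "rCBV", "K2", "DWI_b1000", "ADC", "FET-PET")

#: Sentinel used in manifests for an exam that was never acquired or delineated.
MISSING = ""


class FormatError(ValueError):
    """Input file exists but does not describe a valid 3D volume."""


class AlignmentError(ValueError):
    """A mask and its reference grid disagree in shape, spacing or affine."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar image (PET activity or MRI intensity) on a regular grid.

    Attributes
    ----------
    data : np.ndarray
        3D scalar array.
    spacing : tuple of float
        Voxel edge lengths ``(sx, sy, sz)`` in mm, all positive.
    affine : np.ndarray
        4x4 voxel-index-to-world transform (mm).
    modality_label : str
        Free-text label, e.g. ``"FET-PET"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    modality_label: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise FormatError(f"expected a 3D volume, got shape {data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coordinates(self) -> np.ndarray:
        """World (mm) coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk1 = np.stack([idx[0], idx[1], idx[2], np.ones(self.shape)], axis=-1)
        return ijk1 @ self.affine.T[:, :3]

    def same_grid(self, other: "ImageVolume", atol: float = GRID_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0.0, atol=atol)
            and np.allclose(self.affine, other.affine, rtol=0.0, atol=atol)
        )


@dataclass(frozen=True)
class BinaryMask:
    """A reader's binary delineation aligned to an :class:`ImageVolume` grid."""

    data: np.ndarray
    grid: ImageVolume
    label: tuple[str, str, str] = ("", "", "")  # (patient, sequence, reader)

    def __post_init__(self) -> None:
        data = np.asarray(self.data).astype(bool)
        if data.shape != self.grid.shape:
            raise AlignmentError(
                f"mask shape {data.shape} does not match grid {self.grid.shape}"
            )
        object.__setattr__(self, "data", data)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()


@dataclass
class ManifestEntry:
    patient_id: str
    sequence: str
    reader: str
    path: str  # "" == MISSING


@dataclass
class StudyManifest:
    """Index of mask files over patients x sequences x readers.

    Missing exams are first-class data (an empty ``path``), never an error:
    real studies lose exams to injection failures and readers may decline to
    delineate a sequence.
    """

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for e in self.entries:
            key = (e.patient_id, e.sequence, e.reader)
            if key in seen:
                raise ValueError(f"duplicate manifest entry {key}")
            seen.add(key)
            if e.sequence not in SEQUENCES:
                raise ValueError(
                    f"unknown sequence {e.sequence!r}; expected one of {SEQUENCES}"
                )

    @property
    def patients(self) -> list[str]:
        return sorted({e.patient_id for e in self.entries})

    @property
    def readers(self) -> list[str]:
        return sorted({e.reader for e in self.entries})

    @property
    def sequences(self) -> list[str]:
        present = {e.sequence for e in self.entries}
        return [s for s in SEQUENCES if s in present]

    def lookup(self, patient: str, sequence: str, reader: str) -> str | None:
        for e in self.entries:
            if (e.patient_id, e.sequence, e.reader) == (patient, sequence, reader):
                return e.path if e.path else None
        return None


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, modality_label: str = "") -> ImageVolume:
    """Read a 3D NIfTI volume.

    A 4D file whose fourth dimension is a singleton is squeezed; any other
    extra non-singleton dimension is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        non_singleton = [d for d in data.shape[3:] if d != 1]
        if non_singleton:
            raise FormatError(
                f"{path.name}: {data.ndim}D volume with non-singleton trailing "
                f"dimensions {data.shape[3:]}"
            )
        data = data.reshape(data.shape[:3])
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected 3D data, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(
        data=data, spacing=spacing, affine=np.asarray(img.affine, float),
        modality_label=modality_label,
    )


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume to NIfTI, preserving data dtype, spacing and affine."""
    img = nib.Nifti1Image(np.asanyarray(volume.data), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, grid: ImageVolume,
              label: tuple[str, str, str] = ("", "", "")) -> BinaryMask:
    """Read a binary mask and validate it against a reference grid.

    Any nonzero voxel value is treated as foreground. A shape/spacing/affine
    disagreement beyond :data:`GRID_ATOL` signals non-co-registered inputs.
    """
    vol = read_volume(path)
    if vol.shape != grid.shape:
        raise AlignmentError(
            f"mask shape {vol.shape} does not match grid {grid.shape}"
        )
    if not np.allclose(vol.spacing, grid.spacing, rtol=0.0, atol=GRID_ATOL):
        raise AlignmentError(
            f"mask spacing {vol.spacing} does not match grid {grid.spacing}"
        )
    if not np.allclose(vol.affine, grid.affine, rtol=0.0, atol=GRID_ATOL):
        raise AlignmentError("mask affine does not match grid affine")
    return BinaryMask(data=vol.data != 0, grid=grid, label=label)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    write_volume(
        ImageVolume(
            data=mask.data.astype(np.uint8),
            spacing=mask.grid.spacing,
            affine=mask.grid.affine,
        ),
        path,
    )


# ---------------------------------------------------------------------------
# Physical volumes
# ---------------------------------------------------------------------------

def voxel_volume_mm3(grid: ImageVolume) -> float:
    """Physical volume of one voxel: sx * sy * sz, in mm^3."""
    sx, sy, sz = grid.spacing
    return sx * sy * sz


def mask_volume_cc(mask: BinaryMask) -> float:
    """Delineated volume in cc (1 cc = 1000 mm^3)."""
    return mask.voxel_count * voxel_volume_mm3(mask.grid) / 1000.0


# ---------------------------------------------------------------------------
# Manifest CSV
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("patient_id", "sequence", "reader", "path")


def read_manifest(path: str | Path) -> StudyManifest:
    """Read a study manifest CSV with columns patient_id, sequence, reader, path.

    An empty path marks a missing exam.
    """
    path = Path(path)
    entries: list[ManifestEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise ValueError(f"manifest missing columns {sorted(missing_cols)}")
        for row in reader:
            entries.append(
                ManifestEntry(
                    patient_id=row["patient_id"].strip(),
                    sequence=row["sequence"].strip(),
                    reader=row["reader"].strip(),
                    path=row["path"].strip(),
                )
            )
    return StudyManifest(entries=entries)


def write_manifest(manifest: StudyManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for e in manifest.entries:
            writer.writerow([e.patient_id, e.sequence, e.reader, e.path])
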