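"""SUV volumes and fixed-fraction SUVmax threshold segmentation.

A :class:`PETVolume` is a 3-D grid of body-weight-normalized standardized
uptake values (SUV, dimensionless) with physical voxel spacing in mm.  Total
metabolic tumour volumes (TMTV) are built by growing a region from a seed
voxel and keeping the seed's connected component of voxels at or above a
fixed fraction (default 41%) of the region's SUVmax; the threshold is
iterated to a fixed point so the result does not depend on where inside the
lesion the seed was placed.

Axis convention: ``grid[x, y, z]`` with x the fastest-varying index; voxel
indices are 0-based throughout, including the seed CSV format
(``patient_id,x,y,z``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "PETVolume",
    "TMTVMask",
    "load_volume",
    "save_volume",
    "save_mask",
    "segment_lesion",
    "build_tmtv",
]

#: 26-neighbour (full cube) structuring element for 3-D connectivity.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: 6-neighbour (faces only) structuring element.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return STRUCT_26
    if connectivity == 6:
        return STRUCT_6
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


@dataclass
class PETVolume:
    """3-D SUV grid with physical voxel spacing.

    Parameters
    ----------
    grid
        3-D float array of SUV values; finite and non-negative.
    spacing_mm
        Voxel edge lengths ``(dx, dy, dz)`` in millimetres.
    patient_id
        Identifier carried through feature tables.
    """

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"PET grid must be 3-D, got {self.grid.ndim}-D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("PET grid contains non-finite values")
        if np.any(self.grid < 0):
            raise ValueError("PET grid contains negative SUV values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz / 1000.0


@dataclass
class TMTVMask:
    """Boolean total-metabolic-tumour-volume mask aligned to a PETVolume."""

    mask: np.ndarray
    component_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_components: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.component_labels is None:
            labels, n = ndimage.label(self.mask, structure=STRUCT_26)
            self.component_labels = labels
            self.n_components = int(n)
        else:
            self.component_labels = np.asarray(self.component_labels)

    def volume_ml(self, volume: PETVolume) -> float:
        return float(self.mask.sum()) * volume.voxel_volume_ml


def load_volume(path, patient_id: str = "") -> PETVolume:
    """Read a NIfTI SUV volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: header has non-positive voxel spacing {zooms}")
    if np.any(data < 0):
        raise ValueError(f"{path}: volume contains negative SUV values")
    return PETVolume(grid=data, spacing_mm=tuple(float(z) for z in zooms), patient_id=patient_id)


def save_volume(volume: PETVolume, path) -> None:
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.grid.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def save_mask(mask: TMTVMask, volume: PETVolume, path) -> None:
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def segment_lesion(
    volume: PETVolume,
    seed: tuple[int, int, int],
    threshold_fraction: float = 0.41,
    connectivity: int = 26,
    background_floor: float = 1.0,
) -> np.ndarray:
    """Grow a single lesion mask from a seed by iterated fractional thresholding.

    The threshold is ``threshold_fraction`` times the SUVmax of the current
    region, recomputed until the region is stable: starting from the seed
    value, take the seed's connected component of ``SUV >= fraction * max``
    and update the max over that component.  The fixed point makes the mask
    independent of which in-lesion voxel was chosen as the seed.

    Parameters
    ----------
    background_floor
        Seeds with SUV below this value are rejected as background; the
        floor plays no role in the threshold itself, so the mask is
        invariant to global intensity rescaling.
    """
    seed = tuple(int(i) for i in seed)
    if len(seed) != 3 or any(i < 0 or i >= s for i, s in zip(seed, volume.grid.shape)):
        raise ValueError(f"seed {seed} outside grid of shape {volume.grid.shape}")
    seed_val = float(volume.grid[seed])
    if seed_val <= 0:
        raise ValueError(f"seed {seed} has non-positive SUV {seed_val}")
    if seed_val < background_floor:
        raise ValueError(
            f"seed {seed} SUV {seed_val:.3g} is below the background floor "
            f"{background_floor:.3g}; refusing to grow from background"
        )
    if not 0 < threshold_fraction <= 1:
        raise ValueError(f"threshold_fraction must be in (0, 1], got {threshold_fraction}")

    struct = _structure(connectivity)
    current_max = seed_val
    ref = seed  # hottest voxel of the current region; stays above threshold
    mask = None
    # Region max is non-decreasing and bounded by the global max, so the
    # iteration terminates.
    for _ in range(1000):
        thr = threshold_fraction * current_max
        above = volume.grid >= thr
        labels, _ = ndimage.label(above, structure=struct)
        mask = labels == labels[ref]
        new_max = float(volume.grid[mask].max())
        ref = tuple(
            int(i) for i in np.unravel_index(
                np.argmax(np.where(mask, volume.grid, -np.inf)), mask.shape
            )
        )
        if new_max <= current_max:
            break
        current_max = new_max
    return mask


def build_tmtv(
    volume: PETVolume,
    seeds,
    threshold_fraction: float = 0.41,
    connectivity: int = 26,
    background_floor: float = 1.0,
) -> TMTVMask:
    """Union of per-seed lesion segmentations, relabelled by connected component.

    Overlapping or touching lesions merge into a single component; the total
    metabolic tumour volume in mL is the voxel count times the voxel volume.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("at least one seed is required")
    union = np.zeros(volume.grid.shape, dtype=bool)
    for seed in seeds:
        union |= segment_lesion(
            volume, seed, threshold_fraction, connectivity, background_floor
        )
    if not union.any():
        raise ValueError("TMTV union is empty")
    labels, n = ndimage.label(union, structure=_structure(connectivity))
    return TMTVMask(mask=union, component_labels=labels, n_components=int(n))
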