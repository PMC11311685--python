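"""Circular ROI construction, cross-space transfer, and mean extraction.

ROIs are planar discs (drawn on a single slice, as on 2D FLAIR images): a
biopsy-site ROI of radius 5 pixels (2.2 mm at the FLAIR resolution) and a
contralateral normal-appearing-white-matter (NAWM) control ROI per patient.
Transfer onto parameter maps goes through world coordinates via the two
affines; disc membership is inclusive (center distance <= radius).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import PARAMETER_NAMES, ParameterMaps

logger = logging.getLogger(__name__)

ROI_ROLES = ("biopsy", "nawm")

#: Minimum fraction of disc voxels with valid fits for a mean to be reported.
MIN_VALID_FRACTION = 0.5


@dataclass
class ROIDef:
    """A planar circular ROI: center voxel, slice, radius in pixels."""

    center_x: int
    center_y: int
    slice_z: int
    radius_px: float
    role: str
    space_label: str = "native"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.role not in ROI_ROLES:
            raise ValueError(f"role must be one of {ROI_ROLES}")
        self.affine = np.asarray(self.affine, dtype=float)


def make_circular_mask(roi: ROIDef, shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean disc mask on the ROI's slice.

    A voxel (x, y) on slice z is included iff its in-plane Euclidean pixel
    distance from the center is <= radius (inclusive, so a radius-5 disc at
    an interior center contains exactly the 81 integer lattice points with
    dx^2 + dy^2 <= 25). Discs clipped by the grid edge raise a warning with
    the retained voxel count.
    """
    nx, ny, nz = shape
    if not (0 <= roi.center_x < nx and 0 <= roi.center_y < ny and 0 <= roi.slice_z < nz):
        raise ValueError(f"ROI center ({roi.center_x}, {roi.center_y}, {roi.slice_z}) outside grid {shape}")
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    disc = (xx - roi.center_x) ** 2 + (yy - roi.center_y) ** 2 <= roi.radius_px**2
    mask = np.zeros(shape, dtype=bool)
    mask[:, :, roi.slice_z] = disc

    r = int(np.floor(roi.radius_px))
    clipped = (
        roi.center_x - r < 0 or roi.center_x + r >= nx or roi.center_y - r < 0 or roi.center_y + r >= ny
    )
    if clipped:
        logger.warning(
            "ROI disc clipped by grid boundary; %d voxels retained", int(mask.sum())
        )
    return mask


def transfer_roi(
    roi: ROIDef, target_affine: np.ndarray, target_shape: tuple[int, int, int], target_space: str = "target"
) -> ROIDef:
    """Map an ROI into another grid through world coordinates.

    The center goes through target_affine^-1 @ source_affine and is rounded
    to the nearest voxel; the pixel radius is rescaled by the ratio of
    in-plane voxel sizes so the physical radius is preserved.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    src = roi.affine
    world = src @ np.array([roi.center_x, roi.center_y, roi.slice_z, 1.0])
    tvox = np.linalg.solve(target_affine, world)
    cx, cy, cz = (int(round(v)) for v in tvox[:3])
    nx, ny, nz = target_shape
    if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
        raise ValueError(
            f"transferred ROI center ({cx}, {cy}, {cz}) falls outside target grid {target_shape}"
        )

    def inplane_px(aff: np.ndarray) -> float:
        # mean of the x/y column norms = nominal in-plane pixel size
        return float(np.mean([np.linalg.norm(aff[:3, 0]), np.linalg.norm(aff[:3, 1])]))

    radius = roi.radius_px * inplane_px(src) / inplane_px(target_affine)
    return ROIDef(cx, cy, cz, radius, roi.role, space_label=target_space, affine=target_affine)


def extract_roi_means(
    maps: ParameterMaps, rois: list[ROIDef], patient_id: str | None = None
) -> dict[str, float | str | int]:
    """Per-ROI, per-parameter means over valid voxels.

    A parameter's mean is reported as NaN when fewer than half of the disc
    voxels carry valid fits. Returns one flat record with keys
    ``{role}_{parameter}`` plus voxel-count bookkeeping.
    """
    rec: dict[str, float | str | int] = {}
    if patient_id is not None:
        rec["patient_id"] = patient_id
    for roi in rois:
        if roi.space_label != maps.space_label:
            roi = transfer_roi(roi, maps.affine, maps.shape, target_space=maps.space_label)
        mask = make_circular_mask(roi, maps.shape)
        n_mask = int(mask.sum())
        ok = mask & maps.valid
        n_ok = int(ok.sum())
        rec[f"{roi.role}_n_voxels"] = n_mask
        rec[f"{roi.role}_n_valid"] = n_ok
        if n_ok < n_mask:
            logger.info("%s ROI: %d/%d valid voxels", roi.role, n_ok, n_mask)
        for name, arr in maps.maps.items():
            if n_ok < MIN_VALID_FRACTION * n_mask or n_ok == 0:
                rec[f"{roi.role}_{name}"] = float("nan")
            else:
                rec[f"{roi.role}_{name}"] = float(arr[ok].mean())
    return rec


def rois_from_table(df: pd.DataFrame) -> dict[str, list[ROIDef]]:
    """Parse ROI definitions (patient_id, role, x, y, z, radius_px) from a table."""
    out: dict[str, list[ROIDef]] = {}
    for _, row in df.iterrows():
        roi = ROIDef(
            int(row["x"]), int(row["y"]), int(row["z"]), float(row["radius_px"]),
            str(row["role"]), space_label=str(row.get("space_label", "native")),
        )
        out.setdefault(str(row["patient_id"]), []).append(roi)
    for pid, rois in out.items():
        roles = sorted(r.role for r in rois)
        if roles != ["biopsy", "nawm"]:
            raise ValueError(f"patient {pid}: expected exactly one biopsy and one nawm ROI, got {roles}")
    return out
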