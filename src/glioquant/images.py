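"""In-memory containers for 4D image series and voxel-wise parameter maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical parameter names, in reporting order. The first two are
#: diffusion-derived, the remainder DCE-derived.
PARAMETER_NAMES: tuple[str, ...] = (
    "ADC",
    "MK",
    "Ktrans",
    "Kep",
    "vp",
    "ve",
    "CBV",
    "TTP",
    "peak",
    "AUC_DCE",
    "wash_in",
    "wash_out",
)

DEFAULT_UNITS: dict[str, str] = {
    "ADC": "mm^2/s",
    "MK": "1",
    "Ktrans": "1/min",
    "Kep": "1/min",
    "vp": "fraction",
    "ve": "fraction",
    "CBV": "%",
    "TTP": "s",
    "peak": "%",
    "AUC_DCE": "%*s",
    "wash_in": "%/s",
    "wash_out": "%/s",
}


@dataclass(frozen=True)
class VolumeTag:
    """Per-volume acquisition metadata.

    Exactly one of the three tag families is populated: diffusion
    (``b_value`` + unit ``direction``), VFA (``flip_angle_deg``), or dynamic
    (``time_s``). A b = 0 volume carries no direction.
    """

    b_value: float | None = None
    direction: tuple[float, float, float] | None = None
    flip_angle_deg: float | None = None
    time_s: float | None = None

    def __post_init__(self) -> None:
        kinds = sum(x is not None for x in (self.b_value, self.flip_angle_deg, self.time_s))
        if kinds != 1:
            raise ValueError("a VolumeTag must carry exactly one of b_value, flip_angle_deg, time_s")
        if self.b_value is not None and self.b_value > 0 and self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = float(np.linalg.norm(d))
            if not np.isclose(n, 1.0, atol=1e-3):
                raise ValueError(f"gradient direction must be unit-norm, got |g| = {n:.4f}")


@dataclass
class ImageSeries:
    """A 4D acquisition: voxels (x, y, z, volume) plus per-volume tags.

    ``affine`` is the 4x4 voxel-to-world transform of the grid named by
    ``space_label``; voxel indices are 0-based.
    """

    voxels: np.ndarray
    volume_tags: list[VolumeTag]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_label: str = "native"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4D, got ndim = {self.voxels.ndim}")
        if self.voxels.shape[3] != len(self.volume_tags):
            raise ValueError(
                f"volume count mismatch: image has {self.voxels.shape[3]} volumes "
                f"but {len(self.volume_tags)} tags were supplied"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or not np.isfinite(np.linalg.cond(self.affine)):
            raise ValueError("affine must be an invertible 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.voxels.shape[3]

    def b_values(self) -> np.ndarray:
        """Per-volume b-values; raises if any volume is not diffusion-tagged."""
        vals = [t.b_value for t in self.volume_tags]
        if any(v is None for v in vals):
            raise ValueError("series is not diffusion-tagged")
        return np.asarray(vals, dtype=float)

    def flip_angles(self) -> np.ndarray:
        vals = [t.flip_angle_deg for t in self.volume_tags]
        if any(v is None for v in vals):
            raise ValueError("series is not VFA-tagged")
        return np.asarray(vals, dtype=float)

    def times(self) -> np.ndarray:
        vals = [t.time_s for t in self.volume_tags]
        if any(v is None for v in vals):
            raise ValueError("series is not dynamically tagged")
        return np.asarray(vals, dtype=float)


# physical guard ranges used by ParameterMaps.validate
_RANGE_CHECKS = {
    "ADC": (0.0, None),
    "MK": (0.0, None),
    "ve": (0.0, 1.0),
    "vp": (0.0, 1.0),
}


@dataclass
class ParameterMaps:
    """A set of co-registered 3D biomarker maps with a shared validity mask.

    ``maps`` may hold any subset of :data:`PARAMETER_NAMES`; a full
    diffusion + DCE set is assembled with :meth:`merged`. ``valid`` flags
    voxels where the underlying fits succeeded.
    """

    maps: dict[str, np.ndarray]
    units: dict[str, str]
    valid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_label: str = "native"

    def __post_init__(self) -> None:
        unknown = set(self.maps) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError(f"maps disagree on shape: {sorted(shapes)}")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.maps and self.valid.shape != next(iter(self.maps.values())).shape:
            raise ValueError("validity mask shape differs from map shape")
        for name in self.maps:
            self.units.setdefault(name, DEFAULT_UNITS[name])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.valid.shape

    def validate(self) -> None:
        """Check physical-range invariants on valid voxels; raise on violation."""
        v = self.valid
        for name, (lo, hi) in _RANGE_CHECKS.items():
            if name not in self.maps:
                continue
            arr = self.maps[name][v]
            if lo is not None and np.any(arr < lo - 1e-12):
                raise ValueError(f"{name} below {lo} on valid voxels")
            if hi is not None and np.any(arr > hi + 1e-12):
                raise ValueError(f"{name} above {hi} on valid voxels")
        if {"Ktrans", "Kep", "ve"} <= set(self.maps):
            kt, kep, ve = (self.maps[k][v] for k in ("Ktrans", "Kep", "ve"))
            ok = ve > 0
            resid = np.abs(kep[ok] * ve[ok] - kt[ok])
            scale = np.maximum(np.abs(kt[ok]), 1e-30)
            if np.any(resid / scale > 1e-6):
                raise ValueError("Kep != Ktrans / ve on valid voxels")

    def merged(self, other: "ParameterMaps") -> "ParameterMaps":
        """Combine two map sets on the same grid (e.g. DKI + DCE outputs).

        The joint validity mask is the AND of the two inputs.
        """
        if self.maps and other.maps and self.shape != other.shape:
            raise ValueError("cannot merge maps on different grids")
        overlap = set(self.maps) & set(other.maps)
        if overlap:
            raise ValueError(f"duplicate parameters in merge: {sorted(overlap)}")
        return ParameterMaps(
            maps={**self.maps, **other.maps},
            units={**self.units, **other.units},
            valid=self.valid & other.valid,
            affine=self.affine.copy(),
            space_label=self.space_label,
        )
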