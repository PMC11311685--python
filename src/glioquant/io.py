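"""NIfTI-1 readers/writers with sidecar metadata, plus table and config I/O.

Conventions: 4D volumes are NIfTI-1; diffusion metadata travels as FSL-style
``.bval``/``.bvec`` text sidecars; flip angles and dynamic frame times as a
key-value JSON sidecar (``{"flip_angles_deg": [...]}`` or
``{"frame_times_s": [...]}``). Parameter maps are written one file per
parameter plus a validity mask and a JSON manifest recording units.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .images import ImageSeries, ParameterMaps, VolumeTag


def _tags_from_bval_bvec(bval_path: Path) -> list[VolumeTag]:
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvec_path = bval_path.with_suffix(".bvec")
    if not bvec_path.exists():
        raise FileNotFoundError(f"bvec sidecar not found next to {bval_path}")
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3:  # FSL stores 3 rows x N columns
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError(f"bval/bvec length mismatch: {bvals.shape[0]} vs {bvecs.shape[0]}")
    tags = []
    for b, g in zip(bvals, bvecs):
        if b == 0:
            tags.append(VolumeTag(b_value=0.0))
        else:
            n = np.linalg.norm(g)
            tags.append(VolumeTag(b_value=float(b), direction=tuple(g / n)))
    return tags


def _tags_from_json(path: Path) -> list[VolumeTag]:
    meta = json.loads(path.read_text())
    if "flip_angles_deg" in meta:
        return [VolumeTag(flip_angle_deg=float(a)) for a in meta["flip_angles_deg"]]
    if "frame_times_s" in meta:
        return [VolumeTag(time_s=float(t)) for t in meta["frame_times_s"]]
    raise ValueError(f"{path}: JSON sidecar must define flip_angles_deg or frame_times_s")


def read_image_series(path: str | Path, tag_sidecar: str | Path) -> ImageSeries:
    """Load a 4D NIfTI-1 volume with its per-volume tag sidecar.

    ``tag_sidecar`` is either a ``.bval`` file (the matching ``.bvec`` must
    sit next to it) or a JSON file with flip angles / frame times. The
    volume count of image and sidecar must agree.
    """
    path, tag_sidecar = Path(path), Path(tag_sidecar)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got ndim = {data.ndim}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite voxel intensities")

    if tag_sidecar.suffix == ".json":
        tags = _tags_from_json(tag_sidecar)
    else:
        tags = _tags_from_bval_bvec(tag_sidecar)
    if len(tags) != data.shape[3]:
        raise ValueError(
            f"volume count mismatch: image {path.name} has {data.shape[3]} volumes "
            f"but sidecar {tag_sidecar.name} describes {len(tags)}"
        )
    return ImageSeries(data, tags, affine=np.asarray(img.affine), space_label=path.stem)


def write_image_series(series: ImageSeries, path: str | Path, sidecar: str | Path | None = None) -> list[Path]:
    """Write a series as NIfTI-1 plus the matching sidecar(s)."""
    path = Path(path)
    img = nib.Nifti1Image(series.voxels.astype(np.float64), series.affine)
    nib.save(img, str(path))
    written = [path]
    if sidecar is None:
        return written
    sidecar = Path(sidecar)
    tags = series.volume_tags
    if tags[0].b_value is not None:
        bvals = " ".join(str(t.b_value) for t in tags)
        dirs = np.array([t.direction if t.direction is not None else (0.0, 0.0, 0.0) for t in tags])
        sidecar.write_text(bvals + "\n")
        bvec = sidecar.with_suffix(".bvec")
        np.savetxt(bvec, dirs.T, fmt="%.8f")
        written += [sidecar, bvec]
    elif tags[0].flip_angle_deg is not None:
        sidecar.write_text(json.dumps({"flip_angles_deg": [t.flip_angle_deg for t in tags]}))
        written.append(sidecar)
    else:
        sidecar.write_text(json.dumps({"frame_times_s": [t.time_s for t in tags]}))
        written.append(sidecar)
    return written


def write_parameter_maps(maps: ParameterMaps, out_dir: str | Path, overwrite: bool = False) -> list[Path]:
    """One NIfTI-1 file per parameter + validity mask + JSON manifest.

    Arrays are stored as float64 so a round-trip read is bit-identical.
    Existing files are refused unless ``overwrite`` is set.
    """
    if not str(out_dir):
        raise ValueError("empty output directory path")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.nii" for name in maps.maps}
    paths["valid_mask"] = out_dir / "valid_mask.nii"
    manifest_path = out_dir / "manifest.json"
    if not overwrite:
        clashes = [str(p) for p in list(paths.values()) + [manifest_path] if p.exists()]
        if clashes:
            raise FileExistsError(f"refusing to overwrite existing files: {clashes}")

    written = []
    for name, arr in maps.maps.items():
        nib.save(nib.Nifti1Image(arr.astype(np.float64), maps.affine), str(paths[name]))
        written.append(paths[name])
    nib.save(nib.Nifti1Image(maps.valid.astype(np.uint8), maps.affine), str(paths["valid_mask"]))
    written.append(paths["valid_mask"])
    manifest = {
        "space_label": maps.space_label,
        "parameters": {name: {"file": p.name, "unit": maps.units[name]} for name, p in paths.items() if name != "valid_mask"},
        "valid_mask": "valid_mask.nii",
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written.append(manifest_path)
    return written


def read_parameter_maps(in_dir: str | Path) -> ParameterMaps:
    """Inverse of :func:`write_parameter_maps` via the JSON manifest."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    maps, units = {}, {}
    affine = None
    for name, entry in manifest["parameters"].items():
        img = nib.load(str(in_dir / entry["file"]))
        maps[name] = np.asanyarray(img.dataobj, dtype=np.float64)
        units[name] = entry["unit"]
        affine = np.asarray(img.affine)
    mask_img = nib.load(str(in_dir / manifest["valid_mask"]))
    valid = np.asanyarray(mask_img.dataobj).astype(bool)
    return ParameterMaps(maps=maps, units=units, valid=valid, affine=affine, space_label=manifest["space_label"])


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "who_grade", "idh"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_config(path: str | Path) -> dict:
    """YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
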