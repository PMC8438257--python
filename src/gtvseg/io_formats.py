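"""Case I/O: raw int16 blocks with JSON sidecars, NIfTI-1 volumes, cohort manifests.

A *case* is one patient-like unit: a 3D diffusion-weighted volume plus
(optionally) a binary tumor mask of identical geometry.  Two on-disk
representations are supported:

* **raw** — a little-endian ``int16`` block laid out slice-major
  (slice, row, col), accompanied by a JSON sidecar
  ``{"shape": [...], "dtype": "int16", "spacing_mm": [...]}``.
* **nifti** — single-volume NIfTI-1 files (via :mod:`nibabel`); voxel
  spacing lives in the ``pixdim`` header fields.

A cohort is described by a CSV manifest with columns
``case_id, volume_path, mask_path``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "Mask",
    "Case",
    "CohortManifest",
    "read_raw_volume",
    "write_raw_volume",
    "read_nifti_case",
    "write_nifti_case",
    "load_cohort",
    "save_cohort",
]

_DTYPES = {"int16": np.int16, "float32": np.float32}


@dataclass(frozen=True)
class Volume:
    """A 3D intensity grid with per-axis spacing in mm.

    ``voxels`` is indexed ``(slice, row, col)``; ``spacing`` is the matching
    ``(slice_mm, row_mm, col_mm)`` triple.  ``dtype_tag`` records the on-disk
    scalar type: ``int16`` for raw scanner exports, ``float32`` after
    normalization.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    dtype_tag: str = "int16"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"volume must be 3D with positive extents, got shape {v.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.dtype_tag not in _DTYPES:
            raise ValueError(f"dtype_tag must be one of {sorted(_DTYPES)}, got {self.dtype_tag!r}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class Mask:
    """A binary {0,1} grid geometrically aligned with a :class:`Volume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {v.shape}")
        if not np.isin(v, (0, 1)).all():
            bad = np.unique(v[~np.isin(v, (0, 1))])
            raise ValueError(f"mask voxels must be 0 or 1; found {bad[:5].tolist()}")
        object.__setattr__(self, "voxels", v.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_count(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class Case:
    """One labeled (or unlabeled) case: volume, optional mask, provenance."""

    case_id: str
    volume: Volume
    mask: Mask | None = None
    provenance: str = "file"  # "phantom" or "file"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.shape != self.volume.shape:
            raise ValueError(
                f"case {self.case_id!r}: mask shape {self.mask.shape} "
                f"!= volume shape {self.volume.shape}"
            )


@dataclass
class CohortManifest:
    """Ordered list of (case_id, volume_path, mask_path) rows."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)
    format_tag: str = "raw"  # "raw" | "nifti"

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate case_id(s) in manifest: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path, format_tag: str | None = None) -> "CohortManifest":
        df = pd.read_csv(path, dtype=str)
        required = {"case_id", "volume_path", "mask_path"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest {path} missing columns {sorted(required - set(df.columns))}")
        entries = [
            (str(r.case_id), str(r.volume_path), str(r.mask_path)) for r in df.itertuples()
        ]
        if format_tag is None:
            format_tag = "nifti" if entries and entries[0][1].endswith((".nii", ".nii.gz")) else "raw"
        return cls(entries=entries, format_tag=format_tag)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["case_id", "volume_path", "mask_path"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------- raw format


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_raw_volume(
    path: str | Path,
    shape: Sequence[int] | None = None,
    dtype_tag: str | None = None,
    spacing: Sequence[float] | None = None,
) -> Volume:
    """Read a raw slice-major block.

    Geometry may be given explicitly or, when all three are ``None``, read
    from the JSON sidecar next to ``path``.  The file size must equal
    ``prod(shape) * itemsize`` exactly.
    """
    path = Path(path)
    if shape is None and dtype_tag is None and spacing is None:
        meta = json.loads(_sidecar_path(path).read_text())
        shape, dtype_tag, spacing = meta["shape"], meta["dtype"], meta["spacing_mm"]
    if shape is None or dtype_tag is None or spacing is None:
        raise ValueError("give shape, dtype_tag and spacing together, or none of them")
    dtype = np.dtype(_DTYPES[dtype_tag]).newbyteorder("<")
    expected = int(np.prod(shape)) * dtype.itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"{path}: expected {expected} bytes for shape {tuple(shape)} "
            f"{dtype_tag}, found {actual}"
        )
    voxels = np.fromfile(path, dtype=dtype).reshape(tuple(shape))
    return Volume(voxels=voxels.astype(_DTYPES[dtype_tag]), spacing=tuple(spacing), dtype_tag=dtype_tag)


def write_raw_volume(volume: Volume, path: str | Path, sidecar: bool = True) -> None:
    """Write ``volume`` as a little-endian slice-major block (+ JSON sidecar).

    Under the ``int16`` tag, values outside the int16 range raise rather
    than being clipped.
    """
    path = Path(path)
    v = volume.voxels
    if volume.dtype_tag == "int16":
        info = np.iinfo(np.int16)
        if v.min() < info.min or v.max() > info.max:
            raise ValueError(
                f"values [{v.min()}, {v.max()}] exceed int16 range "
                f"[{info.min}, {info.max}]; refusing to clip"
            )
        if np.issubdtype(v.dtype, np.floating) and not np.array_equal(v, np.round(v)):
            raise ValueError("non-integral values under int16 dtype_tag")
    out = v.astype(np.dtype(_DTYPES[volume.dtype_tag]).newbyteorder("<"))
    path.parent.mkdir(parents=True, exist_ok=True)
    out.tofile(path)
    if sidecar:
        _sidecar_path(path).write_text(
            json.dumps(
                {
                    "shape": list(volume.shape),
                    "dtype": volume.dtype_tag,
                    "spacing_mm": list(volume.spacing),
                }
            )
        )


# -------------------------------------------------------------------- NIfTI


def _nifti_affine(spacing: Sequence[float]) -> np.ndarray:
    # axes stored (slice, row, col); nibabel data axes map directly
    return np.diag(list(spacing) + [1.0])


def write_nifti_case(case: Case, volume_path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a case's volume (and mask, if present) as NIfTI-1 files."""
    vol = case.volume
    img = nib.Nifti1Image(np.asanyarray(vol.voxels), _nifti_affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(volume_path))
    if case.mask is not None and mask_path is not None:
        m = nib.Nifti1Image(case.mask.voxels.astype(np.uint8), _nifti_affine(case.mask.spacing))
        m.header.set_zooms(case.mask.spacing)
        nib.save(m, str(mask_path))


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a single 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def read_nifti_case(
    volume_path: str | Path,
    mask_path: str | Path | None = None,
    case_id: str | None = None,
) -> Case:
    """Read a case from NIfTI files; the mask payload must be {0,1}."""
    vox, spacing = _load_nifti(volume_path)
    tag = "int16" if np.issubdtype(vox.dtype, np.integer) else "float32"
    volume = Volume(voxels=vox, spacing=spacing, dtype_tag=tag)
    mask = None
    if mask_path is not None:
        mvox, mspacing = _load_nifti(mask_path)
        mask = Mask(voxels=mvox, spacing=mspacing)  # binarity enforced here
    if case_id is None:
        case_id = Path(volume_path).name.split(".")[0]
    return Case(case_id=case_id, volume=volume, mask=mask, provenance="file")


# ------------------------------------------------------------------ cohorts


def load_cohort(manifest: CohortManifest, root: str | Path = ".") -> list[Case]:
    """Load every manifest entry, in manifest order.

    Any unreadable entry aborts with the offending ``case_id``.
    """
    root = Path(root)
    cases: list[Case] = []
    for case_id, vol_path, mask_path in manifest.entries:
        try:
            if manifest.format_tag == "nifti":
                case = read_nifti_case(root / vol_path, root / mask_path if mask_path else None,
                                       case_id=case_id)
            else:
                volume = read_raw_volume(root / vol_path)
                mask = None
                if mask_path and str(mask_path) != "nan":
                    mvol = read_raw_volume(root / mask_path)
                    mask = Mask(voxels=mvol.voxels, spacing=mvol.spacing)
                case = Case(case_id=case_id, volume=volume, mask=mask, provenance="file")
        except Exception as exc:
            raise RuntimeError(f"failed to load case {case_id!r}: {exc}") from exc
        cases.append(case)
    return cases


def save_cohort(
    cases: Iterable[Case],
    out_dir: str | Path,
    format_tag: str = "raw",
) -> CohortManifest:
    """Write a cohort to ``out_dir`` and return (and persist) its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[tuple[str, str, str]] = []
    for case in cases:
        if format_tag == "nifti":
            vp, mp = f"{case.case_id}_dwi.nii.gz", f"{case.case_id}_mask.nii.gz"
            write_nifti_case(case, out_dir / vp, out_dir / mp if case.mask is not None else None)
        else:
            vp, mp = f"{case.case_id}_dwi.raw", f"{case.case_id}_mask.raw"
            write_raw_volume(case.volume, out_dir / vp)
            if case.mask is not None:
                write_raw_volume(
                    Volume(case.mask.voxels.astype(np.int16), case.mask.spacing, "int16"),
                    out_dir / mp,
                )
        entries.append((case.case_id, vp, mp if case.mask is not None else ""))
    manifest = CohortManifest(entries=entries, format_tag=format_tag)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
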