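"""Synthetic DWI-like phantom cohorts with known ground-truth tumor masks.

On diffusion-weighted MR, cervical tumors appear as bright blobs on darker
pelvic anatomy.  The generator emulates the structures that drive both
success and failure of automatic contouring:

* an ellipsoidal bright **tumor** (the ground-truth mask),
* an optional low-intensity **necrotic cavity** inside the tumor — the
  cavity stays part of the reference mask even though its image intensity
  drops, mimicking hollow necrotic cores that a contouring oncologist still
  labels as tumor,
* an optional **hematoma** blob touching the tumor with near-tumor
  intensity (a classic confuser), and
* bright **distractor** blobs nearby (stool in the colon, normal tissue).

Geometry is defined in millimetres; a voxel belongs to a structure iff its
*center* lies inside the structure's ellipsoid, which keeps a brute-force
membership oracle exact.  Noise is additive Gaussian on the image only; the
mask is a pure function of the geometry and never of the noise draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_formats import Case, Mask, Volume

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom case.  All lengths in mm, axes (slice, row, col)."""

    tumor_center_mm: tuple[float, float, float]
    tumor_semiaxes_mm: tuple[float, float, float]
    grid_shape: tuple[int, int, int] = (64, 128, 128)
    spacing_mm: tuple[float, float, float] = (5.0, 1.25, 1.25)
    tumor_intensity: float = 900.0
    background_intensity: float = 100.0
    necrosis_fraction: float = 0.0  # 0 disables; else cavity semiaxes = f * tumor semiaxes
    necrosis_intensity: float = 250.0
    hematoma: bool = False
    hematoma_radius_mm: float = 8.0
    hematoma_intensity: float | None = None  # default: 95% of tumor intensity
    n_distractors: int = 0
    distractor_radius_mm: tuple[float, float] = (3.0, 6.0)
    distractor_intensity: tuple[float, float] = (600.0, 900.0)
    noise_sigma: float = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_intensity <= self.background_intensity:
            raise ValueError("tumor_intensity must exceed background_intensity")
        if not (0.0 <= self.necrosis_fraction < 1.0):
            raise ValueError("necrosis_fraction must be in [0, 1)")
        if self.noise_sigma < 0 or self.n_distractors < 0:
            raise ValueError("noise_sigma and n_distractors must be non-negative")
        lo = np.asarray(self.tumor_center_mm) - np.asarray(self.tumor_semiaxes_mm)
        hi = np.asarray(self.tumor_center_mm) + np.asarray(self.tumor_semiaxes_mm)
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        if (lo < 0).any() or (hi > extent).any():
            raise ValueError(
                f"tumor ellipsoid [{lo}, {hi}] mm exceeds grid extent {extent} mm"
            )


def _voxel_centers(shape: Sequence[int], spacing: Sequence[float]) -> list[np.ndarray]:
    """Per-axis physical coordinates (mm) of voxel centers, as an open grid."""
    axes = []
    for n, s, idx in zip(shape, spacing, np.ogrid[[slice(0, n) for n in shape]]):
        axes.append((idx + 0.5) * s)
    return axes


def _ellipsoid_mask(
    shape: Sequence[int],
    spacing: Sequence[float],
    center: Sequence[float],
    semiaxes: Sequence[float],
) -> np.ndarray:
    zc, yc, xc = _voxel_centers(shape, spacing)
    q = (
        ((zc - center[0]) / semiaxes[0]) ** 2
        + ((yc - center[1]) / semiaxes[1]) ** 2
        + ((xc - center[2]) / semiaxes[2]) ** 2
    )
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> Case:
    """Render one phantom case.  Identical spec + seed give an identical case."""
    rng = np.random.default_rng(spec.rng_seed)
    shape, spacing = spec.grid_shape, spec.spacing_mm
    center = np.asarray(spec.tumor_center_mm, dtype=float)
    semi = np.asarray(spec.tumor_semiaxes_mm, dtype=float)

    tumor = _ellipsoid_mask(shape, spacing, center, semi)
    image = np.full(shape, spec.background_intensity, dtype=np.float64)
    image[tumor] = spec.tumor_intensity

    if spec.necrosis_fraction > 0:
        cavity = _ellipsoid_mask(shape, spacing, center, semi * spec.necrosis_fraction)
        image[cavity & tumor] = spec.necrosis_intensity

    # hematoma: sphere touching the tumor along a random in-plane axis direction
    if spec.hematoma:
        axis = int(rng.integers(1, 3))  # row or col
        sign = 1.0 if rng.random() < 0.5 else -1.0
        hcenter = center.copy()
        hcenter[axis] += sign * (semi[axis] + spec.hematoma_radius_mm)
        hint = (
            spec.hematoma_intensity
            if spec.hematoma_intensity is not None
            else 0.95 * spec.tumor_intensity
        )
        blob = _ellipsoid_mask(shape, spacing, hcenter, [spec.hematoma_radius_mm] * 3)
        image[blob & ~tumor] = hint

    # distractors: bright blobs near (but not inside) the tumor
    extent = np.asarray(shape) * np.asarray(spacing)
    for _ in range(spec.n_distractors):
        for _attempt in range(50):
            r = rng.uniform(*spec.distractor_radius_mm)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng.uniform(1.0, 2.5) * (semi.max() + r)
            dcenter = center + direction * dist
            if (dcenter - r >= 0).all() and (dcenter + r <= extent).all():
                break
        else:
            continue  # no feasible placement; skip this distractor
        blob = _ellipsoid_mask(shape, spacing, dcenter, [r] * 3)
        image[blob & ~tumor] = rng.uniform(*spec.distractor_intensity)

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)

    voxels = np.rint(image).astype(np.int16)
    volume = Volume(voxels=voxels, spacing=spacing, dtype_tag="int16")
    mask = Mask(voxels=tumor.astype(np.uint8), spacing=spacing)
    return Case(
        case_id=f"phantom_{spec.rng_seed:06d}",
        volume=volume,
        mask=mask,
        provenance="phantom",
        seed=spec.rng_seed,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters for a whole phantom cohort.

    ``diameter_range_mm`` is the range of the tumor's largest axis diameter;
    it deliberately extends below 40 mm, the regime where small tumors make
    overlap metrics fragile.  Necrosis and hematoma prevalences default to
    the clinical mix of the cohort this generator stands in for (27/98 and
    16/98 respectively).  Tumor centers are sampled so the ellipsoid fits
    inside the central in-plane region of the grid, which guarantees a fixed
    crop window can contain every tumor of the cohort.
    """

    n_cases: int
    master_seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 128, 128)
    spacing_mm: tuple[float, float, float] = (5.0, 1.25, 1.25)
    diameter_range_mm: tuple[float, float] = (10.0, 60.0)
    aspect_range: tuple[float, float] = (0.6, 1.0)  # minor/major semiaxis ratio
    p_necrosis: float = 27 / 98
    p_hematoma: float = 16 / 98
    max_distractors: int = 2
    tumor_intensity: float = 900.0
    background_intensity: float = 100.0
    noise_sigma: float = 20.0
    roi_fraction: float = 0.5  # central in-plane fraction that must contain the tumor

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        lo, hi = self.diameter_range_mm
        if not (0 < lo < hi):
            raise ValueError("diameter range must be positive and increasing")
        for p in (self.p_necrosis, self.p_hematoma):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")

    def to_yaml(self, path) -> None:
        import dataclasses
        from pathlib import Path

        import yaml

        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        from pathlib import Path

        import yaml

        d = yaml.safe_load(Path(path).read_text())
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


def _sample_phantom_spec(cspec: CohortSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    shape = np.asarray(cspec.grid_shape)
    spacing = np.asarray(cspec.spacing_mm)
    extent = shape * spacing

    d = rng.uniform(*cspec.diameter_range_mm)
    semi = np.array([d / 2 * rng.uniform(*cspec.aspect_range) for _ in range(3)])
    semi[int(rng.integers(0, 3))] = d / 2  # the sampled diameter is the major axis

    # feasible center box: tumor inside the central in-plane ROI, fully inside along slices
    lo = semi.copy()
    hi = extent - semi
    margin = (1 - cspec.roi_fraction) / 2
    for ax in (1, 2):
        lo[ax] = max(lo[ax], margin * extent[ax] + semi[ax])
        hi[ax] = min(hi[ax], (1 - margin) * extent[ax] - semi[ax])
    if (lo >= hi).any():
        raise ValueError(f"tumor of diameter {d:.1f} mm cannot fit the central ROI")
    center = rng.uniform(lo, hi)

    return PhantomSpec(
        tumor_center_mm=tuple(center),
        tumor_semiaxes_mm=tuple(semi),
        grid_shape=tuple(cspec.grid_shape),
        spacing_mm=tuple(cspec.spacing_mm),
        tumor_intensity=cspec.tumor_intensity,
        background_intensity=cspec.background_intensity,
        necrosis_fraction=0.5 if rng.random() < cspec.p_necrosis else 0.0,
        hematoma=bool(rng.random() < cspec.p_hematoma),
        n_distractors=int(rng.integers(0, cspec.max_distractors + 1)),
        noise_sigma=cspec.noise_sigma,
        rng_seed=seed,
    )


def generate_cohort(cspec: CohortSpec, max_retries: int = 20) -> list[Case]:
    """Sample ``n_cases`` phantoms, deterministically under ``master_seed``.

    Per-case seeds are spawned from the master seed, so any single case can
    be regenerated without rebuilding the cohort.  An infeasible sampled
    geometry is resampled up to ``max_retries`` times before raising.
    """
    ss = np.random.SeedSequence(cspec.master_seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cspec.n_cases)]
    sampler = np.random.default_rng(ss.spawn(1)[0])

    cases: list[Case] = []
    for i, seed in enumerate(case_seeds):
        last_err: Exception | None = None
        for _ in range(max_retries):
            try:
                spec = _sample_phantom_spec(cspec, sampler, seed)
                case = generate_phantom(spec)
                break
            except ValueError as exc:
                last_err = exc
        else:
            raise RuntimeError(
                f"could not sample a feasible phantom for case {i} "
                f"after {max_retries} tries: {last_err}"
            )
        cases.append(replace(case, case_id=f"case_{i:03d}"))
    return cases
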