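"""Seeded synthetic cohorts of 2D cardiac-map-like images.

Real quantitative cardiac maps for this kind of study are typically not
publicly deposited, so this module generates cohorts that emulate their
statistical structure: per-subject in-plane pixel spacing drawn from the
scanner range, an annular (ring-shaped) myocardium-like ROI with realistic
physical area, a subject-specific mean relaxation time, and a spatially
correlated within-ROI texture so that downstream feature collinearity is
nontrivial.

Generation is a pure function of the :class:`CohortSpec` — identical specs
yield bit-identical cohorts, and each subject has its own RNG stream derived
from ``(seed, subject_index)`` so cohorts are order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .image import QuantitativeMap, ROIMask, check_geometry

__all__ = [
    "CohortSpec",
    "T1_SPEC",
    "T2_SPEC",
    "generate_subject",
    "generate_cohort",
    "write_subject",
    "read_subject",
    "write_cohort",
    "read_cohort",
]

#: fraction of the outer annulus radius used for the inner (cavity) radius
_INNER_FRACTION = 0.55
#: background intensity as a fraction of the cohort mean value; keeps a
#: nonzero edge response at the ROI border for gradient/wavelet filters
_BACKGROUND_FRACTION = 0.40
#: margin (mm^2) kept from the ROI-area bounds when sampling the target
#: area, absorbing pixelisation error of the discrete annulus
_AREA_MARGIN_MM2 = 80.0
#: pixels of textured-tissue support beyond the ROI (partial-volume-like
#: transition band; the background step sits outside it)
_SUPPORT_MARGIN_PX = 3


@dataclass(frozen=True)
class CohortSpec:
    """Declarative description of a synthetic cohort.

    Defaults emulate the study conditions: 26 subjects, isotropic in-plane
    spacing uniform in 1.77-2.34 mm, annular ROI area uniform in
    740-2370 mm^2, and map-kind-specific intensity parameters.
    """

    n_subjects: int = 26
    map_kind: str = "T1like"  # "T1like" | "T2like"
    spacing_range: tuple[float, float] = (1.77, 2.34)
    roi_area_range: tuple[float, float] = (740.0, 2370.0)
    mean_value: float = 997.0  # ms
    between_subject_sd: float = 50.0  # ms
    within_roi_sd: float = 60.0  # ms
    texture_correlation_length: float = 3.0  # mm
    seed: int = 0
    grid_shape: tuple[int, int] = (80, 80)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.map_kind not in ("T1like", "T2like"):
            raise ValueError(f"unknown map_kind {self.map_kind!r}")
        lo, hi = self.spacing_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid spacing_range {self.spacing_range}")
        alo, ahi = self.roi_area_range
        if not (0 < alo <= ahi):
            raise ValueError(f"invalid roi_area_range {self.roi_area_range}")
        if self.mean_value <= 0:
            raise ValueError("mean_value must be positive")
        if self.between_subject_sd < 0 or self.within_roi_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.texture_correlation_length <= 0:
            raise ValueError("texture_correlation_length must be positive")


#: T1-like study conditions (median myocardial T1 ~ 997 ms)
T1_SPEC = CohortSpec()
#: T2-like study conditions (median myocardial T2 ~ 53 ms)
T2_SPEC = CohortSpec(
    map_kind="T2like", mean_value=53.0, between_subject_sd=3.0, within_roi_sd=4.5
)


def _subject_rng(spec: CohortSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, subject_index)))


def _correlated_field(
    shape: tuple[int, int],
    rng: np.random.Generator,
    correlation_length_mm: float,
    spacing_mm: float,
) -> np.ndarray:
    """White Gaussian noise smoothed by a Gaussian kernel of width equal to
    the correlation length (converted to pixels); unnormalised."""
    noise = rng.standard_normal(shape)
    sigma_px = correlation_length_mm / spacing_mm
    return ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")


def generate_subject(
    spec: CohortSpec, subject_index: int
) -> tuple[QuantitativeMap, ROIMask]:
    """Generate one subject: an annular-ROI quantitative map plus its mask.

    Deterministic given ``(spec.seed, subject_index)``.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(
            f"subject_index {subject_index} outside [0, {spec.n_subjects})"
        )
    rng = _subject_rng(spec, subject_index)

    spacing = float(rng.uniform(*spec.spacing_range))  # isotropic in-plane
    rows, cols = spec.grid_shape

    # target annulus area, kept away from the bounds so the pixelised
    # area cannot escape the configured range
    alo, ahi = spec.roi_area_range
    margin = min(_AREA_MARGIN_MM2, 0.25 * (ahi - alo)) if ahi > alo else 0.0
    target_area = float(rng.uniform(alo + margin, ahi - margin)) if ahi > alo else alo

    outer_r = np.sqrt(target_area / (np.pi * (1.0 - _INNER_FRACTION**2)))
    inner_r = _INNER_FRACTION * outer_r

    half_extent = min(rows, cols) * spacing / 2.0
    if outer_r + 2 * spacing > half_extent:
        raise ValueError(
            f"ROI area {target_area:.0f} mm^2 infeasible: annulus outer radius "
            f"{outer_r:.1f} mm exceeds half grid extent {half_extent:.1f} mm "
            f"for grid {spec.grid_shape} at spacing {spacing:.2f} mm"
        )

    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    dist = np.hypot((yy - cy) * spacing, (xx - cx) * spacing)
    mask_arr = (dist <= outer_r) & (dist >= inner_r)

    area = mask_arr.sum() * spacing**2
    if not (alo <= area <= ahi):  # pragma: no cover - margin prevents this
        raise ValueError(
            f"pixelised ROI area {area:.0f} mm^2 outside range {spec.roi_area_range}"
        )

    subject_mean = spec.mean_value + spec.between_subject_sd * rng.standard_normal()
    background = _BACKGROUND_FRACTION * spec.mean_value
    values = np.full((rows, cols), background, dtype=float)

    # the textured tissue extends a few pixels beyond the ROI (the manual
    # ROI is conservative relative to the tissue), so that interpolation at
    # ROI-border pixels during resampling samples in-distribution values
    # instead of blending with the distant background
    support = ndimage.binary_dilation(mask_arr, iterations=_SUPPORT_MARGIN_PX)
    if spec.within_roi_sd > 0:
        field = _correlated_field(
            (rows, cols), rng, spec.texture_correlation_length, spacing
        )
        roi_field = field[mask_arr]
        std = roi_field.std()
        if std > 0:
            texture = (field - roi_field.mean()) / std * spec.within_roi_sd
        else:  # pragma: no cover - degenerate smoothing
            texture = np.zeros_like(field)
        values[support] = subject_mean + texture[support]
    else:
        values[support] = subject_mean

    qmap = QuantitativeMap(values=values, spacing=(spacing, spacing))
    mask = ROIMask(values=mask_arr, spacing=(spacing, spacing))
    return qmap, mask


def generate_cohort(spec: CohortSpec) -> list[tuple[QuantitativeMap, ROIMask]]:
    """Generate all subjects of the cohort (pure function of the spec)."""
    cohort = []
    for idx in range(spec.n_subjects):
        try:
            cohort.append(generate_subject(spec, idx))
        except ValueError as exc:
            raise ValueError(f"subject {idx}: {exc}") from exc
    return cohort


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(values))
    # SimpleITK orders (x, y) = (col, row)
    img.SetSpacing((float(spacing[1]), float(spacing[0])))
    img.SetOrigin((float(origin[1]), float(origin[0])))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    values = sitk.GetArrayFromImage(img)
    sx, sy = img.GetSpacing()[:2]
    ox, oy = img.GetOrigin()[:2]
    return values, (float(sy), float(sx)), (float(oy), float(ox))


def write_subject(
    map_path: str | Path, mask_path: str | Path, qmap: QuantitativeMap, mask: ROIMask
) -> None:
    """Write a map/mask pair as NIfTI files (.nii or .nii.gz)."""
    check_geometry(qmap, mask)
    for p in (map_path, mask_path):
        name = str(p)
        if not (name.endswith(".nii") or name.endswith(".nii.gz")):
            raise ValueError(f"expected a NIfTI path (.nii/.nii.gz), got {name}")
    sitk.WriteImage(_to_sitk(qmap.values, qmap.spacing, qmap.origin), str(map_path))
    sitk.WriteImage(
        _to_sitk(mask.values.astype(np.uint8), mask.spacing, mask.origin),
        str(mask_path),
    )


def read_subject(
    map_path: str | Path, mask_path: str | Path
) -> tuple[QuantitativeMap, ROIMask]:
    """Read a map/mask NIfTI pair; rejects non-binary masks and geometry
    mismatches between the two files."""
    mvals, mspacing, morigin = _from_sitk(sitk.ReadImage(str(map_path)))
    kvals, kspacing, korigin = _from_sitk(sitk.ReadImage(str(mask_path)))
    qmap = QuantitativeMap(values=mvals.astype(float), spacing=mspacing, origin=morigin)
    mask = ROIMask(values=kvals, spacing=kspacing, origin=korigin)
    check_geometry(qmap, mask)
    return qmap, mask


def write_cohort(out_dir: str | Path, spec: CohortSpec) -> Path:
    """Generate and write a full cohort; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for idx, (qmap, mask) in enumerate(generate_cohort(spec)):
        map_path = out / f"subject{idx:03d}_map.nii.gz"
        mask_path = out / f"subject{idx:03d}_mask.nii.gz"
        write_subject(map_path, mask_path, qmap, mask)
        entries.append(
            {
                "subject": idx,
                "map": map_path.name,
                "mask": mask_path.name,
                "spacing_mm": qmap.spacing[0],
                "roi_area_mm2": mask.area_mm2,
            }
        )
    manifest = {"spec": asdict(spec), "subjects": entries}
    manifest_path = out / "cohort.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(
    manifest_path: str | Path,
) -> tuple[CohortSpec, list[tuple[QuantitativeMap, ROIMask]]]:
    """Load a cohort previously written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    raw_spec = manifest["spec"]
    for key in ("spacing_range", "roi_area_range", "grid_shape"):
        raw_spec[key] = tuple(raw_spec[key])
    spec = CohortSpec(**raw_spec)
    base = manifest_path.parent
    cohort = [
        read_subject(base / e["map"], base / e["mask"]) for e in manifest["subjects"]
    ]
    return spec, cohort
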