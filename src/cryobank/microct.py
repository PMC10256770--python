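"""Micro-CT radiodensity analysis of vitrified organs.

Raw scanner volumes are calibrated to Hounsfield units against water and air
reference tubes imaged alongside the specimen (water -> 0 HU, air -> -1000 HU
exactly, by an affine map of the ROI means). Per-region statistics over a
label mask then support classification of tissue as vitrified (glassy, high
radiodensity) versus frozen (crystalline ice, low radiodensity), and a
gradient/connected-component heuristic flags planar or linear low-HU
structures that could indicate cracking.

Voxel grids are indexed (z, y, x), 0-based, with isotropic voxel size in mm
and physical coordinates at voxel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "DEFAULT_VITRIFIED_THRESHOLD_HU",
    "RawVolume",
    "HUCalibration",
    "HUVolume",
    "RegionStat",
    "RegionReport",
    "StateMap",
    "CrackCandidate",
    "MicroCTError",
    "calibrate_hu",
    "region_stats",
    "classify_state",
    "detect_discontinuities",
    "box_roi",
    "load_volume",
    "save_volume",
]

# Heuristic boundary between vitrified (~500 HU) and icy (~270 HU) material in
# IONP-free scans; IONP-loaded scans need a shifted threshold.
DEFAULT_VITRIFIED_THRESHOLD_HU = 400.0


class MicroCTError(ValueError):
    """Raised on malformed volumes, ROIs or label grids."""


def box_roi(z: tuple[int, int], y: tuple[int, int], x: tuple[int, int]) -> tuple[slice, slice, slice]:
    """Convenience constructor for a box ROI as (z, y, x) slice bounds."""
    return (slice(*z), slice(*y), slice(*x))


@dataclass
class RawVolume:
    """Uncalibrated scanner intensities on a (z, y, x) grid."""

    data: np.ndarray
    voxel_size_mm: float = 0.061

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise MicroCTError("volume must be a nonempty 3-D grid")
        if self.voxel_size_mm <= 0:
            raise MicroCTError("voxel size must be positive")


@dataclass(frozen=True)
class HUCalibration:
    water_mean: float
    air_mean: float
    water_roi: object = None
    air_roi: object = None


@dataclass
class HUVolume:
    """Hounsfield-calibrated voxel grid (water = 0, air = -1000)."""

    data: np.ndarray
    calibration: HUCalibration
    voxel_size_mm: float = 0.061


def _roi_values(data: np.ndarray, roi) -> np.ndarray:
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != data.shape:
            raise MicroCTError("boolean ROI mask must match the volume shape")
        return data[roi]
    return np.asarray(data[tuple(roi)]).ravel()


def calibrate_hu(v: RawVolume, water_roi, air_roi) -> HUVolume:
    """Affine-map raw intensities to HU using water/air reference ROI means:

        HU(x) = 1000 * (x - mean_water) / (mean_water - mean_air)

    ROIs are box slice-tuples or boolean masks over the raw grid; means are
    computed in raw intensity before mapping.
    """
    w = _roi_values(v.data, water_roi)
    a = _roi_values(v.data, air_roi)
    if w.size == 0 or a.size == 0:
        raise MicroCTError("reference ROIs must be nonempty")
    mean_w, mean_a = float(w.mean()), float(a.mean())
    if np.isclose(mean_w, mean_a):
        raise MicroCTError("degenerate calibration: water and air ROI means coincide")
    hu = 1000.0 * (v.data.astype(float) - mean_w) / (mean_w - mean_a)
    return HUVolume(
        data=hu,
        calibration=HUCalibration(mean_w, mean_a, water_roi, air_roi),
        voxel_size_mm=v.voxel_size_mm,
    )


@dataclass
class RegionStat:
    label: int
    name: str
    mean_hu: float
    sd_hu: float  # population SD of voxel values
    count: int
    state: str  # "vitrified" | "frozen" | "indeterminate"


@dataclass
class RegionReport:
    regions: list[RegionStat]
    excluded: list[int] = field(default_factory=list)  # empty-region labels
    threshold_hu: float | None = None

    def __getitem__(self, key: int | str) -> RegionStat:
        for r in self.regions:
            if r.label == key or r.name == key:
                return r
        raise KeyError(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"label": r.label, "name": r.name, "mean_hu": r.mean_hu,
                 "sd_hu": r.sd_hu, "count": r.count, "state": r.state}
                for r in self.regions
            ]
        )

    def to_dict(self) -> dict:
        return {
            "threshold_hu": self.threshold_hu,
            "excluded_labels": list(self.excluded),
            "regions": self.to_frame().to_dict(orient="records"),
        }


def region_stats(
    v: HUVolume,
    labels: np.ndarray,
    names: dict[int, str] | None = None,
    threshold_hu: float | None = None,
) -> RegionReport:
    """Mean/SD/count per labeled region (label 0 = background, ignored).

    SD is the population standard deviation of voxel values. Empty labels in
    ``names`` are flagged and excluded. If ``threshold_hu`` is given, each
    region also receives a vitrified/frozen state call (mean >= threshold ->
    vitrified).
    """
    labels = np.asarray(labels)
    if labels.shape != v.data.shape:
        raise MicroCTError("label grid must be congruent with the volume")
    names = names or {}
    present = [int(l) for l in np.unique(labels) if l != 0]
    wanted = sorted(set(present) | {int(k) for k in names})
    regions, excluded = [], []
    for lab in wanted:
        vals = v.data[labels == lab]
        if vals.size == 0:
            excluded.append(lab)
            continue
        mean = float(vals.mean())
        state = "indeterminate"
        if threshold_hu is not None:
            state = "vitrified" if mean >= threshold_hu else "frozen"
        regions.append(
            RegionStat(
                label=lab,
                name=names.get(lab, str(lab)),
                mean_hu=mean,
                sd_hu=float(vals.std(ddof=0)),
                count=int(vals.size),
                state=state,
            )
        )
    return RegionReport(regions=regions, excluded=excluded, threshold_hu=threshold_hu)


@dataclass
class StateMap:
    """Voxelwise vitrified/frozen classification of a calibrated volume."""

    vitrified_mask: np.ndarray
    threshold_hu: float
    frozen_components: pd.DataFrame  # label, size_voxels, size_mm3

    @property
    def frozen_mask(self) -> np.ndarray:
        return ~self.vitrified_mask


def classify_state(
    r: RegionReport | HUVolume,
    threshold_hu: float = DEFAULT_VITRIFIED_THRESHOLD_HU,
) -> RegionReport | StateMap:
    """Classify regions or voxels as vitrified (mean >= threshold) vs frozen.

    For an HUVolume the contiguous frozen components are labeled and reported
    with their sizes; for a RegionReport the per-region state calls are set.
    """
    if isinstance(r, RegionReport):
        out = []
        for s in r.regions:
            out.append(
                RegionStat(
                    label=s.label, name=s.name, mean_hu=s.mean_hu, sd_hu=s.sd_hu,
                    count=s.count,
                    state="vitrified" if s.mean_hu >= threshold_hu else "frozen",
                )
            )
        return RegionReport(regions=out, excluded=list(r.excluded),
                            threshold_hu=threshold_hu)
    vit = r.data >= threshold_hu
    lab = measure.label(~vit, connectivity=1)
    rows = []
    vox_mm3 = r.voxel_size_mm**3
    for p in measure.regionprops(lab):
        rows.append({"label": p.label, "size_voxels": int(p.area),
                     "size_mm3": float(p.area * vox_mm3)})
    comps = pd.DataFrame(rows, columns=["label", "size_voxels", "size_mm3"])
    return StateMap(vitrified_mask=vit, threshold_hu=threshold_hu,
                    frozen_components=comps)


@dataclass
class CrackCandidate:
    label: int
    size_voxels: int
    extent_mm: float  # span along the principal axis
    planarity: float  # 1 - sqrt(smallest/largest principal variance)
    centroid_mm: tuple[float, float, float]


def detect_discontinuities(
    v: HUVolume,
    min_extent_mm: float,
    low_hu: float = DEFAULT_VITRIFIED_THRESHOLD_HU,
    grad_threshold: float = 25.0,
    min_planarity: float = 0.5,
) -> list[CrackCandidate]:
    """Candidate cracks: connected low-HU structures at sharp gradients.

    Voxels below ``low_hu`` adjacent to a gradient magnitude above
    ``grad_threshold`` (HU per voxel) are grouped into connected components;
    each component is scored by PCA of its voxel coordinates, and elongated or
    planar components (planarity >= ``min_planarity``) spanning at least
    ``min_extent_mm`` along their principal axis are reported. A uniform
    volume yields an empty report. This is a conservative screening
    heuristic, not a mechanical fracture model.
    """
    from scipy.ndimage import binary_dilation

    gz, gy, gx = np.gradient(v.data.astype(float))
    gmag = np.sqrt(gz**2 + gy**2 + gx**2)
    # central differences vanish in the middle of a 1-voxel-thick feature;
    # dilating the high-gradient mask by one voxel covers the feature itself
    sharp = binary_dilation(gmag > grad_threshold)
    mask = (v.data < low_hu) & sharp
    if not mask.any():
        return []
    lab = measure.label(mask, connectivity=2)
    out: list[CrackCandidate] = []
    for p in measure.regionprops(lab):
        coords = p.coords.astype(float)
        centered = coords - coords.mean(axis=0)
        if coords.shape[0] < 3:
            extent_vox = 1.0
            planarity = 0.0
        else:
            cov = centered.T @ centered / coords.shape[0]
            evals, evecs = np.linalg.eigh(cov)
            proj = centered @ evecs[:, -1]
            extent_vox = float(proj.max() - proj.min()) + 1.0
            lam_max = max(evals[-1], 1e-12)
            planarity = float(1.0 - np.sqrt(max(evals[0], 0.0) / lam_max))
        extent_mm = extent_vox * v.voxel_size_mm
        if extent_mm >= min_extent_mm and planarity >= min_planarity:
            c = tuple(float(x) * v.voxel_size_mm for x in p.centroid)
            out.append(
                CrackCandidate(
                    label=p.label, size_voxels=int(p.area), extent_mm=extent_mm,
                    planarity=planarity, centroid_mm=c,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Volume IO (NIfTI via nibabel, DICOM series via pydicom)

def load_volume(path) -> RawVolume:
    """Read a volume from a NIfTI file or a directory of DICOM slices.

    NIfTI array axes (i, j, k) are reversed to the (z, y, x) convention used
    here; DICOM slices are stacked along z in InstanceNumber order.
    """
    path = Path(path)
    if path.is_dir():
        import pydicom

        files = sorted(path.glob("*.dcm")) or sorted(
            f for f in path.iterdir() if f.is_file()
        )
        slices = [pydicom.dcmread(str(f)) for f in files]
        slices.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
        data = np.stack([s.pixel_array for s in slices], axis=0)
        spacing = float(getattr(slices[0], "PixelSpacing", [0.061])[0])
        return RawVolume(data=data, voxel_size_mm=spacing)
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj).T  # (i, j, k) -> (z=k, y=j, x=i)
    zooms = img.header.get_zooms()
    vox = float(zooms[0]) if len(zooms) else 0.061
    return RawVolume(data=data, voxel_size_mm=vox)


def save_volume(v: RawVolume | HUVolume, path) -> None:
    """Write a volume as NIfTI (axes restored to (i, j, k))."""
    import nibabel as nib

    aff = np.diag([v.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32).T, aff)
    nib.save(img, str(path))
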