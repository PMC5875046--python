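"""ROI-based image-quality metrics: noise, CNR, insert HU, and derived tables.

Noise is the mean of the sample standard deviations of several circular
background ROIs (three 0.4 cm^2 ROIs for the Catphan; one 3.1 cm^2 ROI for
the abdomen phantom). CNR is

    CNR = |object HU - background HU| / background SD

with object and background ROIs of identical area. A pixel belongs to an ROI
iff its centre lies inside the circle; sample SDs use the n-1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantoms import Disk, PhantomLayout
from .simulate import ImageStack, ScanCondition

__all__ = [
    "CNRMeasurement",
    "HUMeasurement",
    "NoiseMeasurement",
    "ROISpec",
    "fold_improvement",
    "hu_difference_from_reference",
    "insert_rois_for_layout",
    "measure_cnr",
    "measure_hu",
    "measure_noise",
]

_MIN_ROI_PIXELS = 10


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest, centred in mm phantom coordinates."""

    label: str
    center: tuple[float, float]
    area_cm2: float

    def __post_init__(self):
        if not self.area_cm2 > 0:
            raise ValueError(f"ROI {self.label!r}: area must be > 0")

    @property
    def radius_mm(self) -> float:
        return math.sqrt(self.area_cm2 / math.pi) * 10.0

    def mask(self, shape: tuple[int, int], spacing_mm: float) -> np.ndarray:
        """Boolean pixel-membership mask (pixel centre inside the circle)."""
        h, w = shape
        extent_x, extent_y = w * spacing_mm, h * spacing_mm
        x = (np.arange(w) + 0.5) * spacing_mm - extent_x / 2.0
        y = extent_y / 2.0 - (np.arange(h) + 0.5) * spacing_mm
        X, Y = np.meshgrid(x, y)
        r = self.radius_mm
        return (X - self.center[0]) ** 2 + (Y - self.center[1]) ** 2 <= r**2

    def _check_inside_image(self, shape, spacing_mm) -> None:
        h, w = shape
        half_x, half_y = w * spacing_mm / 2.0, h * spacing_mm / 2.0
        cx, cy = self.center
        r = self.radius_mm
        if abs(cx) + r > half_x or abs(cy) + r > half_y:
            raise ValueError(f"ROI {self.label!r} is not fully inside the image")


@dataclass(frozen=True)
class NoiseMeasurement:
    condition: ScanCondition
    per_replicate: tuple[float, ...]  # mean of ROI SDs, one value per replicate
    summary: float  # arithmetic mean over replicates
    n_rois: int


@dataclass(frozen=True)
class CNRMeasurement:
    condition: ScanCondition
    object_hu: float
    background_hu: float
    background_sd: float
    per_replicate: tuple[float, ...]
    summary: float


@dataclass(frozen=True)
class HUMeasurement:
    material: str
    condition: ScanCondition
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _roi_pixels(stack: ImageStack, roi: ROISpec) -> np.ndarray:
    roi._check_inside_image(stack.shape, stack.pixel_spacing_mm)
    mask = roi.mask(stack.shape, stack.pixel_spacing_mm)
    if mask.sum() < _MIN_ROI_PIXELS:
        raise ValueError(
            f"ROI {roi.label!r} covers only {int(mask.sum())} pixels "
            f"(< {_MIN_ROI_PIXELS}); SD would be unstable"
        )
    return stack.images[:, mask]  # (N, n_pixels)


def measure_noise(stack: ImageStack, rois: list[ROISpec]) -> NoiseMeasurement:
    """Noise = mean of the sample SDs of the given ROIs, per replicate."""
    if not rois:
        raise ValueError("need at least one ROI")
    sds = np.stack([_roi_pixels(stack, r).std(axis=1, ddof=1) for r in rois])  # (R, N)
    per_rep = sds.mean(axis=0)
    return NoiseMeasurement(
        condition=stack.condition,
        per_replicate=tuple(float(v) for v in per_rep),
        summary=float(per_rep.mean()),
        n_rois=len(rois),
    )


def measure_cnr(
    stack: ImageStack,
    target_roi: ROISpec,
    background_rois: list[ROISpec],
    pool_background: bool = True,
) -> CNRMeasurement:
    """Contrast-to-noise ratio of a target against its local background.

    The background SD uses the pooled background pixels by default (the more
    stable choice); ``pool_background=False`` instead averages the per-ROI
    means and SDs.
    """
    if not background_rois:
        raise ValueError("need at least one background ROI")
    for r in background_rois:
        if not math.isclose(r.area_cm2, target_roi.area_cm2, rel_tol=1e-6):
            raise ValueError("target and background ROIs must have identical area")
    obj = _roi_pixels(stack, target_roi)  # (N, n)
    bg_per_roi = [_roi_pixels(stack, r) for r in background_rois]
    obj_mean = obj.mean(axis=1)
    if pool_background:
        bg = np.concatenate(bg_per_roi, axis=1)
        bg_mean = bg.mean(axis=1)
        bg_sd = bg.std(axis=1, ddof=1)
    else:
        bg_mean = np.mean([b.mean(axis=1) for b in bg_per_roi], axis=0)
        bg_sd = np.mean([b.std(axis=1, ddof=1) for b in bg_per_roi], axis=0)
    if np.any(bg_sd == 0):
        raise ValueError("background SD is zero (noiseless input): CNR undefined")
    cnr = np.abs(obj_mean - bg_mean) / bg_sd
    return CNRMeasurement(
        condition=stack.condition,
        object_hu=float(obj_mean.mean()),
        background_hu=float(bg_mean.mean()),
        background_sd=float(bg_sd.mean()),
        per_replicate=tuple(float(v) for v in cnr),
        summary=float(cnr.mean()),
    )


def insert_rois_for_layout(
    layout: PhantomLayout, fraction: float = 0.7, labels: list[str] | None = None
) -> dict[str, ROISpec]:
    """ROIs strictly interior to each disk insert (radius = fraction * insert)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    out = {}
    for feat in layout.features:
        if labels is not None and feat.label not in labels:
            continue
        if isinstance(feat, Disk):
            r_mm = fraction * feat.radius
            out[feat.label] = ROISpec(feat.label, feat.center, math.pi * (r_mm / 10.0) ** 2)
    return out


def measure_hu(
    stack: ImageStack,
    insert_rois: dict[str, ROISpec],
    layout: PhantomLayout | None = None,
) -> list[HUMeasurement]:
    """Mean and SD HU per material, pooled over replicates."""
    if layout is not None:
        for label in insert_rois:
            layout.feature(label)  # raises KeyError for unknown labels
    out = []
    for label, roi in insert_rois.items():
        px = _roi_pixels(stack, roi).ravel()
        out.append(
            HUMeasurement(
                material=label,
                condition=stack.condition,
                mean=float(px.mean()),
                sd=float(px.std(ddof=1)),
            )
        )
    return out


def fold_improvement(
    summaries: pd.DataFrame,
    metric: str,
    reference_algorithm: str = "FBP",
) -> pd.DataFrame:
    """Per-condition improvement ratio relative to a reference algorithm.

    ``summaries`` needs columns ``algorithm, dose, pitch, value``. For noise
    the ratio is reference/value, for CNR value/reference, so that > 1 always
    reads "better than the reference". The orientation is recorded in the
    output.
    """
    if metric not in ("noise", "cnr"):
        raise ValueError("metric must be 'noise' or 'cnr'")
    ref = summaries[summaries["algorithm"] == reference_algorithm]
    if ref.empty:
        raise ValueError(f"no rows for reference algorithm {reference_algorithm!r}")
    ref = ref.set_index(["dose", "pitch"])["value"]
    rows = []
    for _, row in summaries.iterrows():
        key = (row["dose"], row["pitch"])
        if key not in ref.index:
            raise ValueError(f"reference cell missing for dose/pitch {key}")
        rv = ref.loc[key]
        if rv == 0 or row["value"] == 0:
            raise ValueError(f"zero metric value in cell {key}")
        ratio = rv / row["value"] if metric == "noise" else row["value"] / rv
        rows.append(
            {
                "algorithm": row["algorithm"],
                "dose": row["dose"],
                "pitch": row["pitch"],
                "fold_improvement": float(ratio),
                "orientation": "reference/value" if metric == "noise" else "value/reference",
                "metric": metric,
                "reference": reference_algorithm,
            }
        )
    return pd.DataFrame(rows)


def hu_difference_from_reference(
    measurements: pd.DataFrame,
    reference: tuple[str, float] = ("FBP", 24.0),
) -> pd.DataFrame:
    """HU deltas of every condition from a reference condition, per material.

    ``measurements`` needs columns ``material, algorithm, dose, mean`` (and
    optionally ``pitch``, matched within the same pitch).
    """
    alg, dose = reference
    by_pitch = "pitch" in measurements.columns
    keys = ["material"] + (["pitch"] if by_pitch else [])
    ref = measurements[
        (measurements["algorithm"] == alg) & (measurements["dose"] == dose)
    ].set_index(keys)["mean"]
    if ref.empty:
        raise ValueError(f"reference condition {reference} not present")
    rows = []
    for _, row in measurements.iterrows():
        key = (row["material"], row["pitch"]) if by_pitch else row["material"]
        if key not in ref.index:
            raise ValueError(f"material {row['material']!r} missing in reference condition")
        rec = {
            "material": row["material"],
            "algorithm": row["algorithm"],
            "dose": row["dose"],
            "delta_hu": float(row["mean"] - ref.loc[key]),
            "reference": f"{alg}@{dose:g}mGy",
        }
        if by_pitch:
            rec["pitch"] = row["pitch"]
        rows.append(rec)
    return pd.DataFrame(rows)
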