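"""Geometric phantom scenes and their rasterization to Hounsfield-unit images.

A :class:`PhantomLayout` is a declarative scene: an elliptical body (optionally
surrounded by a fat-equivalent ring) holding labelled primitives — cylinder
inserts (disks), annuli and resolution bar patterns — each with a nominal HU.
:func:`render_layout` rasterizes a layout onto a square pixel grid with
area-weighted (anti-aliased) edges, so a noiseless ground-truth image exists
for every downstream measurement.

Coordinates are in millimetres relative to the phantom centre, which coincides
with the image centre; +x points right (increasing column), +y points up
(decreasing row). Pixel centres sit at ``(i + 0.5) * spacing`` from the
top-left image corner.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, fields

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "AIR_HU",
    "Annulus",
    "BarPattern",
    "Disk",
    "Ellipse",
    "FeatureOutsideGridError",
    "PhantomLayout",
    "builtin_layouts",
    "layout_from_dict",
    "layout_to_dict",
    "load_layout",
    "pixel_centers",
    "render_layout",
    "save_layout",
]

#: HU of the empty space surrounding the phantom.
AIR_HU = -1000.0

_HU_MIN, _HU_MAX = -1000.0, 3000.0


class FeatureOutsideGridError(ValueError):
    """A feature does not fit on the requested pixel grid."""


def pixel_centers(matrix_size: int, spacing_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, y) mm coordinates of pixel-column and pixel-row centres."""
    extent = matrix_size * spacing_mm
    x = (np.arange(matrix_size) + 0.5) * spacing_mm - extent / 2.0
    y = extent / 2.0 - (np.arange(matrix_size) + 0.5) * spacing_mm
    return x, y


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse, used for the phantom body and the surrounding ring."""

    label: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (a, b) mm along x and y
    hu: float

    def inside(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        a, b = self.semi_axes
        return ((x - self.center[0]) / a) ** 2 + ((y - self.center[1]) / b) ** 2 <= 1.0

    @property
    def circumradius(self) -> float:
        return max(self.semi_axes)

    def bbox(self) -> tuple[float, float, float, float]:
        a, b = self.semi_axes
        cx, cy = self.center
        return cx - a, cx + a, cy - b, cy + b


@dataclass(frozen=True)
class Disk:
    """Cylindrical insert seen in cross-section."""

    label: str
    center: tuple[float, float]
    radius: float  # mm
    hu: float

    def inside(self, x, y):
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2

    @property
    def circumradius(self) -> float:
        return self.radius

    def bbox(self):
        cx, cy = self.center
        r = self.radius
        return cx - r, cx + r, cy - r, cy + r


@dataclass(frozen=True)
class Annulus:
    """Circular annulus (ring-shaped insert)."""

    label: str
    center: tuple[float, float]
    r_inner: float
    r_outer: float
    hu: float

    def __post_init__(self):
        if not 0.0 <= self.r_inner < self.r_outer:
            raise ValueError(f"annulus {self.label!r}: need 0 <= r_inner < r_outer")

    def inside(self, x, y):
        d2 = (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2
        return (d2 <= self.r_outer**2) & (d2 >= self.r_inner**2)

    @property
    def circumradius(self) -> float:
        return self.r_outer

    def bbox(self):
        cx, cy = self.center
        r = self.r_outer
        return cx - r, cx + r, cy - r, cy + r


@dataclass(frozen=True)
class BarPattern:
    """High-contrast resolution bar group.

    ``frequency_lp_cm`` line pairs per cm, so the spatial period is
    ``10 / frequency_lp_cm`` mm and each bar is half a period wide. The
    frequency axis points along ``orientation_deg`` (0 = +x); bars run
    perpendicular to it with length ``bar_length``.
    """

    label: str
    center: tuple[float, float]
    frequency_lp_cm: float
    n_bars: int = 5
    bar_length: float = 10.0  # mm
    hu: float = 1000.0
    orientation_deg: float = 0.0

    def __post_init__(self):
        if self.frequency_lp_cm <= 0:
            raise ValueError(f"bar pattern {self.label!r}: frequency must be > 0")
        if self.n_bars < 2:
            raise ValueError(f"bar pattern {self.label!r}: need at least 2 bars")

    @property
    def period_mm(self) -> float:
        return 10.0 / self.frequency_lp_cm

    @property
    def bar_width_mm(self) -> float:
        return self.period_mm / 2.0

    @property
    def extent_mm(self) -> float:
        """Full width of the bar group along the frequency axis."""
        return (2 * self.n_bars - 1) * self.bar_width_mm

    def axis(self) -> tuple[float, float]:
        th = math.radians(self.orientation_deg)
        return math.cos(th), math.sin(th)

    def inside(self, x, y):
        ux, uy = self.axis()
        dx = x - self.center[0]
        dy = y - self.center[1]
        t = dx * ux + dy * uy  # along frequency axis
        s = -dx * uy + dy * ux  # along bars
        p, w = self.period_mm, self.bar_width_mm
        frac = np.mod(t + p / 2.0, p) - p / 2.0
        return (
            (np.abs(frac) <= w / 2.0)
            & (np.abs(t) <= self.extent_mm / 2.0)
            & (np.abs(s) <= self.bar_length / 2.0)
        )

    @property
    def circumradius(self) -> float:
        return math.hypot(self.extent_mm / 2.0, self.bar_length / 2.0)

    def bbox(self):
        r = self.circumradius
        cx, cy = self.center
        return cx - r, cx + r, cy - r, cy + r


Feature = Disk | Annulus | BarPattern


@dataclass(frozen=True)
class PhantomLayout:
    """Geometric scene of HU-labelled primitives defining one phantom slice."""

    name: str
    body: Ellipse
    features: tuple[Feature, ...] = ()
    ring: Ellipse | None = None

    def __post_init__(self):
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError(f"layout {self.name!r}: feature labels must be unique")
        for prim in (self.body, self.ring, *self.features):
            if prim is None:
                continue
            if not np.isfinite(prim.hu) or not _HU_MIN <= prim.hu <= _HU_MAX:
                raise ValueError(
                    f"layout {self.name!r}: HU of {prim.label!r} must be finite "
                    f"and within [{_HU_MIN:g}, {_HU_MAX:g}]"
                )
        a, b = self.body.semi_axes
        bx, by = self.body.center
        for feat in self.features:
            cx, cy = feat.center
            rho = math.hypot((cx - bx) / a, (cy - by) / b)
            if rho + feat.circumradius / min(a, b) > 1.0 + 1e-9:
                raise ValueError(
                    f"layout {self.name!r}: feature {feat.label!r} is not inside the body"
                )

    def feature(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(f"layout {self.name!r} has no feature {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self.features)


# ---------------------------------------------------------------------------
# Rasterization


def _supersample_offsets(oversample: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    off = ((np.arange(oversample) + 0.5) / oversample - 0.5) * spacing
    ox, oy = np.meshgrid(off, off)
    return ox.ravel(), oy.ravel()


@functools.lru_cache(maxsize=64)
def _coverage(shape, matrix_size: int, spacing: float, oversample: int) -> np.ndarray:
    """Pixel coverage fractions of a primitive, float32 in [0, 1].

    Interior / exterior pixels are classified by their centre; pixels within a
    two-pixel morphological band of the boundary get an
    ``oversample x oversample`` sub-pixel area estimate.
    """
    xs, ys = pixel_centers(matrix_size, spacing)
    X, Y = np.meshgrid(xs, ys)
    inside = shape.inside(X, Y)
    band = ndimage.binary_dilation(inside, iterations=2) ^ ndimage.binary_erosion(
        inside, iterations=2, border_value=0
    )
    # Thin structures (e.g. near-Nyquist bars) can vanish from the centre mask;
    # always supersample the full bounding box of small primitives.
    xmin, xmax, ymin, ymax = shape.bbox()
    small = (xmax - xmin) * (ymax - ymin) < (100 * spacing) ** 2
    if small:
        band |= (
            (X >= xmin - spacing)
            & (X <= xmax + spacing)
            & (Y >= ymin - spacing)
            & (Y <= ymax + spacing)
        )
    cov = inside.astype(np.float32)
    if band.any():
        rows, cols = np.nonzero(band)
        ox, oy = _supersample_offsets(oversample, spacing)
        sx = X[rows, cols][:, None] + ox[None, :]
        sy = Y[rows, cols][:, None] + oy[None, :]
        cov[rows, cols] = shape.inside(sx, sy).mean(axis=1, dtype=np.float64)
    cov.flags.writeable = False
    return cov


def render_layout(
    layout: PhantomLayout,
    matrix_size: int = 512,
    dfov_cm: float = 36.0,
    hu_overrides: dict[str, float] | None = None,
    oversample: int = 16,
) -> tuple[np.ndarray, float]:
    """Rasterize a layout to a noiseless HU image.

    Parameters
    ----------
    matrix_size
        Square image side in pixels (>= 64).
    dfov_cm
        Display field of view; pixel spacing is ``dfov_cm * 10 / matrix_size`` mm.
    hu_overrides
        Optional per-label HU replacing the nominal values (keys may include
        ``"body"``-like labels and the ring label); used e.g. to apply
        algorithm HU bias before rendering.

    Returns
    -------
    (image, spacing_mm)
        ``image`` is float64 ``(matrix_size, matrix_size)``; interior pixels of
        each primitive equal its (possibly overridden) HU exactly, boundary
        pixels are area-weighted.
    """
    if dfov_cm <= 0:
        raise ValueError("dfov_cm must be > 0")
    if matrix_size < 64:
        raise ValueError("matrix_size must be >= 64")
    spacing = dfov_cm * 10.0 / matrix_size
    half = dfov_cm * 10.0 / 2.0
    overrides = hu_overrides or {}

    layers: list = []
    if layout.ring is not None:
        layers.append(layout.ring)
    layers.append(layout.body)
    layers.extend(layout.features)

    for feat in layout.features:
        xmin, xmax, ymin, ymax = feat.bbox()
        if xmin < -half or xmax > half or ymin < -half or ymax > half:
            raise FeatureOutsideGridError(
                f"feature {feat.label!r} extends beyond the {dfov_cm:g} cm grid"
            )

    img = np.full((matrix_size, matrix_size), AIR_HU, dtype=np.float64)
    for prim in layers:
        hu = overrides.get(prim.label, prim.hu)
        cov = _coverage(prim, matrix_size, spacing, oversample)
        img *= 1.0 - cov
        img += hu * np.asarray(cov, dtype=np.float64)
    return img, spacing


# ---------------------------------------------------------------------------
# Built-in layouts

#: Nominal HU of the eight sensitometry inserts (CTP404-style module).
CTP404_INSERT_HU = {
    "air": -1000.0,
    "PMP": -200.0,
    "LDPE": -100.0,
    "water": 0.0,
    "polystyrene": -35.0,
    "acrylic": 120.0,
    "Delrin": 340.0,
    "Teflon": 990.0,
}

#: Background epoxy of the Catphan modules.
CATPHAN_BACKGROUND_HU = 100.0
#: Fat-equivalent oval ring wrapped around the Catphan.
FAT_RING_HU = -90.0
#: Radius of the insert circle and of each cylindrical insert.
CTP404_INSERT_RING_RADIUS = 58.4
CTP404_INSERT_RADIUS = 6.1
#: Low-contrast supraslice target: 15 mm diameter, "1%" contrast, here +10 HU
#: over the local background by convention (configurable at layout level).
CTP515_TARGET_CONTRAST_HU = 10.0


def _catphan_body() -> tuple[Ellipse, Ellipse]:
    ring = Ellipse("fat_ring", (0.0, 0.0), (175.0, 120.0), FAT_RING_HU)
    body = Ellipse("body", (0.0, 0.0), (100.0, 100.0), CATPHAN_BACKGROUND_HU)
    return body, ring


def builtin_layouts(name: str) -> PhantomLayout:
    """Return one of the built-in phantom layouts.

    ``ctp404``
        Sensitometry module: eight 12.2 mm diameter inserts (air, PMP, LDPE,
        water, polystyrene, acrylic, Delrin, Teflon) in a +100 HU background,
        wrapped in a fat-equivalent oval ring.
    ``ctp515``
        Low-contrast module: 15 mm supraslice target, +10 HU over background.
    ``ctp528``
        High-contrast module: bar groups from 1 to 8 lp/cm.
    ``abdomen``
        Simplified anthropomorphic abdomen: soft-tissue ellipse with liver,
        spleen, pancreas and kidney disks.
    """
    if name == "ctp404":
        body, ring = _catphan_body()
        order = ["Delrin", "Teflon", "air", "PMP", "LDPE", "polystyrene", "water", "acrylic"]
        feats = []
        for i, mat in enumerate(order):
            ang = math.radians(i * 45.0)
            c = (
                CTP404_INSERT_RING_RADIUS * math.cos(ang),
                CTP404_INSERT_RING_RADIUS * math.sin(ang),
            )
            feats.append(Disk(mat, c, CTP404_INSERT_RADIUS, CTP404_INSERT_HU[mat]))
        return PhantomLayout("ctp404", body, tuple(feats), ring)
    if name == "ctp515":
        body, ring = _catphan_body()
        target = Disk(
            "supra_15mm",
            (0.0, 45.0),
            7.5,
            CATPHAN_BACKGROUND_HU + CTP515_TARGET_CONTRAST_HU,
        )
        return PhantomLayout("ctp515", body, (target,), ring)
    if name == "ctp528":
        body, ring = _catphan_body()
        feats = []
        for i, f in enumerate([1, 2, 3, 4, 5, 6, 7, 8]):
            ang = i * 40.0
            rad = math.radians(ang)
            c = (45.0 * math.cos(rad), 45.0 * math.sin(rad))
            feats.append(
                BarPattern(
                    f"bars_{f}lpcm",
                    c,
                    frequency_lp_cm=float(f),
                    n_bars=3 if f <= 2 else 5,
                    bar_length=10.0,
                    hu=1000.0,
                    orientation_deg=ang,
                )
            )
        return PhantomLayout("ctp528", body, tuple(feats), ring)
    if name == "abdomen":
        body = Ellipse("body", (0.0, 0.0), (140.0, 95.0), 30.0)
        feats = (
            Disk("liver", (-55.0, 15.0), 32.0, 60.0),
            Disk("spleen", (60.0, 25.0), 16.0, 55.0),
            Disk("pancreas", (0.0, -5.0), 11.0, 45.0),
            Disk("kidney", (35.0, -45.0), 14.0, 35.0),
        )
        return PhantomLayout("abdomen", body, feats)
    raise KeyError(f"unknown built-in layout {name!r}")


# ---------------------------------------------------------------------------
# Serialization (YAML / JSON-compatible dicts)

_SHAPE_TAGS = {"disk": Disk, "annulus": Annulus, "bar_pattern": BarPattern}


def _prim_to_dict(prim) -> dict:
    tag = {Disk: "disk", Annulus: "annulus", BarPattern: "bar_pattern", Ellipse: "ellipse"}[
        type(prim)
    ]
    d = {"shape": tag}
    for f in fields(prim):
        v = getattr(prim, f.name)
        d[f.name] = list(v) if isinstance(v, tuple) else v
    return d


def _prim_from_dict(d: dict):
    d = dict(d)
    tag = d.pop("shape")
    cls = {**_SHAPE_TAGS, "ellipse": Ellipse}[tag]
    for key in ("center", "semi_axes"):
        if key in d:
            d[key] = tuple(d[key])
    return cls(**d)


def layout_to_dict(layout: PhantomLayout) -> dict:
    return {
        "name": layout.name,
        "body": _prim_to_dict(layout.body),
        "ring": None if layout.ring is None else _prim_to_dict(layout.ring),
        "features": [_prim_to_dict(f) for f in layout.features],
    }


def layout_from_dict(d: dict) -> PhantomLayout:
    ring = d.get("ring")
    return PhantomLayout(
        name=d["name"],
        body=_prim_from_dict(d["body"]),
        features=tuple(_prim_from_dict(f) for f in d.get("features", [])),
        ring=None if ring is None else _prim_from_dict(ring),
    )


def save_layout(layout: PhantomLayout, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout_to_dict(layout), fh, sort_keys=False)


def load_layout(path) -> PhantomLayout:
    with open(path) as fh:
        return layout_from_dict(yaml.safe_load(fh))
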