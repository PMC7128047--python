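"""Fundus-like phantoms with exact ground truth.

Real fundus photographs show dark vessels (full width roughly 2-12 px)
on a brighter, smoothly shaded background inside a circular aperture,
sometimes with bright lesions (exudates) nearby.  The generator renders
that geometry exactly — vessel trees as polylines with Gaussian or flat
cross-profiles, a shaded disc background, optional bright blobs and
additive Gaussian noise — and returns the analytic vessel mask, axis
(centerline) mask and FOV disc alongside the image, so every pipeline
stage can be scored against known truth without any dataset.

What the phantom does *not* emulate: the optic disc and fovea, central
light reflex on wide vessels, camera vignetting and JPEG artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import draw


@dataclass(frozen=True)
class Vessel:
    """One vessel branch: a polyline with constant half-width and depth.

    ``points`` are (row, col) vertices; ``half_width`` in pixels (full
    vessel widths 2-12 px mean half-widths 1-6); ``depth`` is the
    intensity drop at the axis on the [0, 1] scale.
    """

    points: tuple[tuple[float, float], ...]
    half_width: float = 3.0
    depth: float = 0.35


@dataclass(frozen=True)
class Lesion:
    """Bright blob emulating an exudate: center (row, col), radius, gain."""

    center: tuple[float, float]
    radius: float = 8.0
    brightness: float = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (256, 256)
    background_level: float = 0.55
    shading_amplitude: float = 0.05
    vessels: tuple[Vessel, ...] = ()
    profile: str = "gaussian"  # or "flat"
    noise_sd: float = 0.02
    lesions: tuple[Lesion, ...] = ()
    fov_radius_frac: float = 0.47
    seed: int = 0


@dataclass
class PhantomBundle:
    image: np.ndarray        # gray, float [0, 1]
    rgb: np.ndarray          # uint8 H x W x 3 rendering
    vessel_mask: np.ndarray  # analytic band |d| <= half_width
    axis_mask: np.ndarray    # rasterized polyline axes
    lesion_mask: np.ndarray
    fov: np.ndarray
    spec: PhantomSpec


def _segment_distance(
    rows: np.ndarray, cols: np.ndarray,
    p0: tuple[float, float], p1: tuple[float, float],
) -> np.ndarray:
    """Euclidean distance from each grid pixel to the segment p0-p1."""
    r0, c0 = p0
    r1, c1 = p1
    dr, dc = r1 - r0, c1 - c0
    length2 = dr * dr + dc * dc
    if length2 == 0:
        return np.hypot(rows - r0, cols - c0)
    t = ((rows - r0) * dr + (cols - c0) * dc) / length2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rows - (r0 + t * dr), cols - (c0 + t * dc))


def _vessel_distance(shape: tuple[int, int], vessel: Vessel) -> np.ndarray:
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    d = np.full(shape, np.inf)
    pts = vessel.points
    for p0, p1 in zip(pts[:-1], pts[1:]):
        np.minimum(d, _segment_distance(rows, cols, p0, p1), out=d)
    return d


def _axis_pixels(shape: tuple[int, int], vessel: Vessel) -> np.ndarray:
    mask = np.zeros(shape, bool)
    pts = [(int(round(r)), int(round(c))) for r, c in vessel.points]
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw.line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[ok], cc[ok]] = True
    return mask


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render a phantom; deterministic given ``spec.seed``.

    Raises
    ------
    ValueError
        If a vessel's half-width is outside [1, 6] px or its band leaves
        the FOV disc.
    """
    H, W = spec.shape
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.mgrid[0:H, 0:W].astype(np.float64)
    cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    radius = spec.fov_radius_frac * min(H, W)
    fov = np.hypot(rows - cr, cols - cc) <= radius

    # smoothly shaded background: gentle diagonal gradient plus radial
    # vignetting (fundus photographs are brightest near the center and
    # darken toward the aperture rim)
    shade = (
        0.5 * (rows / H + cols / W - 1.0)
        - 0.5 * (np.hypot(rows - cr, cols - cc) / max(radius, 1.0) - 0.5)
    )
    img = spec.background_level + spec.shading_amplitude * shade

    vessel_mask = np.zeros((H, W), bool)
    axis_mask = np.zeros((H, W), bool)
    drop = np.zeros((H, W), np.float64)
    for vessel in spec.vessels:
        if not (1.0 <= vessel.half_width <= 6.0):
            raise ValueError(
                f"vessel half-width {vessel.half_width} outside [1, 6] px "
                "(full widths 2-12)")
        d = _vessel_distance((H, W), vessel)
        band = d <= vessel.half_width
        if (band & ~fov).any():
            raise ValueError("vessel band extends outside the FOV disc")
        vessel_mask |= band
        axis_mask |= _axis_pixels((H, W), vessel)
        if spec.profile == "gaussian":
            # half_width is the half-width at half-maximum: the vessel
            # mask edge |d| = half_width is the half-depth contour
            s = vessel.half_width / np.sqrt(2.0 * np.log(2.0))
            np.maximum(drop, vessel.depth * np.exp(-d**2 / (2 * s * s)),
                       out=drop)
        elif spec.profile == "flat":
            np.maximum(drop, np.where(band, vessel.depth, 0.0), out=drop)
        else:
            raise ValueError(f"unknown profile {spec.profile!r}")
    img = img - drop

    lesion_mask = np.zeros((H, W), bool)
    for lesion in spec.lesions:
        d = np.hypot(rows - lesion.center[0], cols - lesion.center[1])
        blob = d <= lesion.radius
        lesion_mask |= blob
        img = img + lesion.brightness * np.exp(
            -d**2 / (2 * (lesion.radius / 2.0) ** 2))

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=(H, W))
    img = np.clip(img, 0.0, 1.0)
    img[~fov] = 0.02  # near-black outside the aperture

    # RGB rendering with fundus-like channel balance: red saturated inside
    # the aperture (drives FOV detection), green carries the contrast
    red = np.where(fov, np.clip(img + 0.3, 0.0, 1.0), 0.0)
    blue = np.clip(img * 0.35, 0.0, 1.0)
    rgb = np.stack([red, img, blue], axis=-1)
    rgb = np.round(rgb * 255).astype(np.uint8)

    axis_mask &= vessel_mask  # rounding can nudge an axis pixel off-band
    return PhantomBundle(image=img, rgb=rgb, vessel_mask=vessel_mask,
                         axis_mask=axis_mask, lesion_mask=lesion_mask,
                         fov=fov, spec=spec)


def default_test_suite_specs() -> list[PhantomSpec]:
    """Five canonical phantoms exercising all pipeline behaviours.

    (a) single straight tube; (b) Y-bifurcation; (c) two near-parallel
    tubes 21 px apart (triggers DENSE seeding); (d) curved tube plus
    three bright lesions (pathology robustness); (e) full tree covering
    vessel widths 2-12 px.
    """
    a = PhantomSpec(
        vessels=(Vessel(points=((128.0, 45.0), (128.0, 211.0)),
                        half_width=3.0),),
        seed=11,
    )
    b = PhantomSpec(
        vessels=(
            Vessel(points=((210.0, 128.0), (130.0, 128.0)), half_width=3.0),
            Vessel(points=((130.0, 128.0), (70.0, 90.0)), half_width=2.5),
            Vessel(points=((130.0, 128.0), (70.0, 166.0)), half_width=2.5),
        ),
        seed=12,
    )
    c = PhantomSpec(
        vessels=(
            Vessel(points=((118.0, 50.0), (118.0, 206.0)), half_width=2.0),
            Vessel(points=((139.0, 50.0), (139.0, 206.0)), half_width=2.0),
        ),
        seed=13,
    )
    arc = tuple(
        (128.0 + 60.0 * np.sin(t), 128.0 + 75.0 * np.cos(t) * 0.9)
        for t in np.linspace(-1.2, 1.2, 13)
    )
    d = PhantomSpec(
        vessels=(Vessel(points=arc, half_width=2.5),),
        lesions=(
            Lesion(center=(80.0, 80.0), radius=8.0),
            Lesion(center=(180.0, 90.0), radius=6.0),
            Lesion(center=(70.0, 185.0), radius=7.0),
        ),
        seed=14,
    )
    e = PhantomSpec(
        vessels=(
            Vessel(points=((235.0, 128.0), (150.0, 128.0)), half_width=6.0,
                   depth=0.38),
            Vessel(points=((150.0, 128.0), (85.0, 75.0)), half_width=4.0),
            Vessel(points=((150.0, 128.0), (85.0, 181.0)), half_width=4.0),
            Vessel(points=((85.0, 75.0), (45.0, 95.0)), half_width=2.0,
                   depth=0.3),
            Vessel(points=((85.0, 181.0), (45.0, 161.0)), half_width=1.0,
                   depth=0.3),
            Vessel(points=((117.0, 102.0), (117.0, 45.0)), half_width=1.5,
                   depth=0.3),
        ),
        seed=15,
    )
    return [a, b, c, d, e]
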