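"""Vessel centerline extraction.

Two independent centerline detectors are combined:

* **Divergence candidates** — the gradient vector field of the smoothed
  image points away from a dark vessel's axis on both sides, so after
  normalizing every gradient vector to unit length the numerical
  divergence has a sharp positive peak along the axis.  Thresholding the
  divergence over a grid of rotation angles and Gaussian scales, and
  discarding tiny 8-connected fragments, yields candidate centerlines
  that hug the axes but can merge close parallel vessels.

* **Morphological skeleton** — a multi-orientation, multi-length
  bottom-hat sum highlights dark structures thinner than the structuring
  lines; Otsu binarization and thinning then give a one-pixel skeleton
  that separates neighbors but picks up spurious branches.

The correction step keeps, from both masks, only the 4-connected regions
that agree (more than ``overlap_frac`` of the region lies on the mutual
intersection), and drops short isolated fragments.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from .io_mask import DegenerateInputError
from .vesselness import _gauss_kernel1d, gaussian_derivative

EIGHT = np.ones((3, 3), dtype=int)
FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def default_thetas(n_angles: int = 8) -> list[float]:
    """Rotation angles ``n * pi / 8`` for ``n = 0 .. n_angles - 1``."""
    return [n * np.pi / 8 for n in range(n_angles)]


def default_se_lengths() -> list[int]:
    """Structuring-element lengths 2..12 px in steps of 2 (vessel calibres)."""
    return [2, 4, 6, 8, 10, 12]


def default_se_angles() -> list[float]:
    """Structuring-element orientations 0..7pi/8 in steps of pi/8."""
    return [n * np.pi / 8 for n in range(8)]


def estimate_noise_sd(img: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Estimate additive white-noise standard deviation (Immerkaer).

    Convolves with a Laplacian-difference stencil that annihilates linear
    structure, then averages absolute responses; optionally restricted to
    an eroded ``mask`` so boundary effects do not inflate the estimate.
    """
    img = np.asarray(img, np.float64)
    stencil = np.array([[1.0, -2.0, 1.0],
                        [-2.0, 4.0, -2.0],
                        [1.0, -2.0, 1.0]])
    resp = ndimage.convolve(img, stencil, mode="reflect")
    if mask is not None:
        mask = ndimage.binary_erosion(np.asarray(mask, bool), iterations=2)
        if not mask.any():
            mask = None
    vals = np.abs(resp if mask is None else resp[mask])
    return float(np.sqrt(np.pi / 2.0) * vals.mean() / 6.0)


def _noise_gradient_sd(sigma: float) -> float:
    """Std of one gradient component of unit-variance white noise at
    scale ``sigma`` (L2 norm of the separable derivative kernel)."""
    k0 = _gauss_kernel1d(sigma, 0)
    k1 = _gauss_kernel1d(sigma, 1)
    return float(np.sqrt((k0**2).sum() * (k1**2).sum()))


def gradient_field(img: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """First Gaussian-derivative gradient ``(fx, fy)`` at scale ``sigma``.

    ``fx`` differentiates along columns (x), ``fy`` along rows (y).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    img = np.asarray(img, np.float64)
    fx = gaussian_derivative(img, sigma, order=(0, 1))
    fy = gaussian_derivative(img, sigma, order=(1, 0))
    return fx, fy


def normalize_field(
    fx: np.ndarray, fy: np.ndarray, eps: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize every vector to unit length; magnitudes below ``eps`` -> 0."""
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    mag = np.hypot(fx, fy)
    small = mag < eps
    mag_safe = np.where(small, 1.0, mag)
    nx = np.where(small, 0.0, fx / mag_safe)
    ny = np.where(small, 0.0, fy / mag_safe)
    return nx, ny


def rotated_divergence(
    nfx: np.ndarray, nfy: np.ndarray, theta: float
) -> np.ndarray:
    """Divergence of the field after rotating every vector by ``theta``.

    The rotation is the standard 2-D rotation; the divergence is computed
    by central differences, ``d(vx)/dx + d(vy)/dy`` with x = columns.
    On the axis of a dark tube the unnormalized-to-unit field expands and
    the divergence is strongly positive.
    """
    ct, st = np.cos(theta), np.sin(theta)
    rx = ct * nfx - st * nfy
    ry = st * nfx + ct * nfy
    ddx = np.gradient(rx, axis=1)
    ddy = np.gradient(ry, axis=0)
    return ddx + ddy


def literal_directional_second_derivative(
    img: np.ndarray, sigma: float, theta: float
) -> np.ndarray:
    """Alternative centerline response: ``gxx cos(theta) + gyy sin(theta)``.

    Kept for comparison; the rotated-divergence definition is the default
    detector because it is the one with the stated expanding-field
    behaviour on vessel axes.
    """
    gxx = gaussian_derivative(img, sigma, order=(0, 2))
    gyy = gaussian_derivative(img, sigma, order=(2, 0))
    return gxx * np.cos(theta) + gyy * np.sin(theta)


def _drop_small_components(
    mask: np.ndarray, min_size: int, structure: np.ndarray = EIGHT
) -> np.ndarray:
    """Remove connected components with fewer than ``min_size`` pixels."""
    if min_size <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.concatenate([[False], sizes >= min_size])
    return keep[labels]


def candidate_centerlines(
    img: np.ndarray,
    thetas: list[float] | None = None,
    sigmas: list[float] | None = None,
    phi: float = 0.45,
    delta: int = 50,
    fov: np.ndarray | None = None,
    eps: float = 1e-8,
    grad_floor: float = 0.01,
    noise_gate: float = 4.0,
    rim_margin: int = 5,
) -> np.ndarray:
    """Centerline candidates from the normalized-gradient-field divergence.

    For every (theta, sigma) pair the divergence of the rotated normalized
    gradient field is thresholded at ``phi`` and 8-connected components
    smaller than ``delta`` pixels are discarded; the union over all pairs,
    intersected with the FOV, is returned.

    Normalizing gradients to unit length erases magnitude information, so
    in flat regions pure noise produces unit vectors with random
    directions whose divergence can exceed any threshold.  A vessel axis,
    by contrast, always lies between opposing flank gradients that stand
    out from the noise.  Candidates are therefore gated on the presence,
    within 2 px, of a gradient magnitude above
    ``max(grad_floor, noise_gate * noise gradient level)``, where the
    noise gradient level at scale sigma is the estimated image noise
    times the derivative kernel's L2 norm.  ``grad_floor`` is an absolute
    contrast floor on the [0, 1] intensity scale.

    The aperture rim is itself a high-contrast circular edge whose
    expanding gradient pattern mimics a vessel axis, so candidates are
    restricted to the FOV eroded by ``rim_margin`` pixels.
    """
    from .vesselness import default_sigmas

    if thetas is None:
        thetas = default_thetas()
    if sigmas is None:
        sigmas = default_sigmas()
    if len(thetas) == 0 or len(sigmas) == 0:
        raise ValueError("theta and sigma lists must be nonempty")
    if not (0.0 < phi < 1.0):
        raise ValueError(f"phi must lie in (0, 1), got {phi}")
    if delta < 1:
        raise ValueError(f"delta must be >= 1, got {delta}")
    img = np.asarray(img, np.float64)
    noise_sd = estimate_noise_sd(img, mask=fov)
    if fov is not None and rim_margin > 0:
        fov = ndimage.binary_erosion(fov, iterations=rim_margin)
    out = np.zeros(img.shape, bool)
    for sigma in sigmas:
        fx, fy = gradient_field(img, sigma)
        floor = max(grad_floor, noise_gate * noise_sd * _noise_gradient_sd(sigma))
        gate = ndimage.grey_dilation(np.hypot(fx, fy), size=(5, 5)) > floor
        nfx, nfy = normalize_field(fx, fy, eps=eps)
        for theta in thetas:
            ng = rotated_divergence(nfx, nfy, theta)
            hit = (ng > phi) & gate
            if fov is not None:
                hit &= fov
            out |= _drop_small_components(hit, delta)
    if fov is not None:
        out &= fov
    return out


def _line_footprint(length: int, angle: float) -> np.ndarray:
    """1-px-wide linear structuring element of ``length`` px at ``angle``."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    half = (length - 1) / 2.0
    # sample the continuous segment densely and rasterize
    t = np.linspace(-half, half, max(2 * length, 2))
    cols = np.round(t * np.cos(angle)).astype(int)
    rows = np.round(t * np.sin(angle)).astype(int)
    r0, c0 = rows.min(), cols.min()
    fp = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), bool)
    fp[rows - r0, cols - c0] = True
    return fp


def bottomhat_sum(
    img: np.ndarray,
    lengths: list[int] | None = None,
    angles: list[float] | None = None,
) -> np.ndarray:
    """Sum of bottom-hat transforms over linear structuring elements.

    The bottom-hat (closing minus original) responds to dark structures
    narrower than the line; summing over lengths 2-12 px and 8
    orientations covers the full range of vessel calibres and directions.
    The sum is rescaled to ``[0, 1]`` by its maximum.
    """
    if lengths is None:
        lengths = default_se_lengths()
    if angles is None:
        angles = default_se_angles()
    if len(lengths) == 0 or len(angles) == 0:
        raise ValueError("lengths and angles must be nonempty")
    img = np.asarray(img, np.float64)
    total = np.zeros(img.shape, np.float64)
    for length in lengths:
        for angle in angles:
            fp = _line_footprint(length, angle)
            closed = ndimage.grey_closing(img, footprint=fp, mode="reflect")
            total += closed - img
    peak = total.max()
    if peak > 0:
        total /= peak
    return total


def otsu_threshold(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold maximizing between-class variance over ``nbins`` bins.

    Raises
    ------
    DegenerateInputError
        If the image is constant (no threshold separates two classes).
    """
    img = np.asarray(img, np.float64)
    if img.min() == img.max():
        raise DegenerateInputError("constant image has no Otsu threshold")
    return float(threshold_otsu(img, nbins=nbins))


def thin_to_skeleton(binary: np.ndarray) -> np.ndarray:
    """Iteratively thin a binary mask to a 1-px-wide skeleton.

    Thinning runs to fixpoint, never adds pixels, and preserves the
    8-connected component count.
    """
    return morphology.thin(np.asarray(binary, bool))


def correct_centerlines(
    c_skel: np.ndarray,
    c_can: np.ndarray,
    overlap_frac: float = 0.40,
    min_length: int = 10,
) -> np.ndarray:
    """Fuse skeleton and divergence candidates into the final centerlines.

    Both masks are split into 4-connected regions; a region survives iff
    more than ``overlap_frac`` of its pixels lie on the intersection of
    the two masks.  The union of surviving regions is cleaned of
    8-connected components shorter than ``min_length`` pixels.
    """
    c_skel = np.asarray(c_skel, bool)
    c_can = np.asarray(c_can, bool)
    if c_skel.shape != c_can.shape:
        raise ValueError(
            f"shape mismatch: {c_skel.shape} vs {c_can.shape}")
    if not (0.0 < overlap_frac < 1.0):
        raise ValueError(f"overlap_frac must lie in (0, 1), got {overlap_frac}")
    c_inter = c_skel & c_can
    # the skeleton is 1 px wide while candidate bands can be 2-3 px wide;
    # dilating the intersection by 1 px lets the skeleton credit a band's
    # full width when measuring region overlap
    c_inter_wide = ndimage.binary_dilation(c_inter, structure=EIGHT.astype(bool))
    out = np.zeros(c_skel.shape, bool)
    for mask in (c_skel, c_can):
        labels, n = ndimage.label(mask, structure=FOUR)
        if n == 0:
            continue
        idx = np.arange(1, n + 1)
        region_sizes = ndimage.sum_labels(mask, labels, index=idx)
        inter_sizes = ndimage.sum_labels(c_inter_wide, labels, index=idx)
        keep = np.concatenate(
            [[False], inter_sizes / region_sizes > overlap_frac])
        out |= keep[labels]
    return _drop_small_components(out, min_length)


def extract_centerlines(
    img: np.ndarray,
    fov: np.ndarray | None = None,
    thetas: list[float] | None = None,
    sigmas: list[float] | None = None,
    phi: float = 0.45,
    delta: int = 50,
    se_lengths: list[int] | None = None,
    se_angles: list[float] | None = None,
    overlap_frac: float = 0.40,
    min_length: int = 10,
    nbins: int = 256,
    grad_floor: float = 0.01,
    noise_gate: float = 4.0,
) -> dict[str, np.ndarray]:
    """Full centerline stage; returns candidates, skeleton and final mask.

    The Otsu threshold for the bottom-hat image is computed over in-FOV
    pixels only — the black region outside the aperture would otherwise
    dominate the histogram's background class.
    """
    c_can = candidate_centerlines(
        img, thetas=thetas, sigmas=sigmas, phi=phi, delta=delta, fov=fov,
        grad_floor=grad_floor, noise_gate=noise_gate)
    # light pre-smoothing (1 px, below the smallest 2-px structuring
    # element) keeps sensor noise out of the bottom-hat response
    i_bot = bottomhat_sum(gaussian_derivative(img, 1.0, order=(0, 0)),
                          lengths=se_lengths, angles=se_angles)
    try:
        thr = otsu_threshold(i_bot if fov is None else i_bot[fov],
                             nbins=nbins)
        i_binary = i_bot > thr
    except DegenerateInputError:
        i_binary = np.zeros(img.shape, bool)
    if fov is not None:
        i_binary &= fov
    c_skel = thin_to_skeleton(i_binary)
    c_final = correct_centerlines(c_skel, c_can,
                                  overlap_frac=overlap_frac,
                                  min_length=min_length)
    if fov is not None:
        c_final &= fov
    return {"candidates": c_can, "skeleton": c_skel, "final": c_final}
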