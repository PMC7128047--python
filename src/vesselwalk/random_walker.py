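"""Seeded random-walker segmentation on an 8-connected pixel lattice.

Every in-FOV pixel is a graph node; 8-neighbor pixels are joined by an
edge whose weight ``w_ij = exp(-beta * (v_i - v_j)**2)`` measures how
similar the guide image (the multiscale vesselness response) is across
the edge.  Foreground seeds are the centerline pixels; background seeds
are planted a vessel-radius-plus-one away from each centerline pixel
along the cross-vessel eigenvector, with the offset shrunk in "dense"
areas where parallel vessels run close together.  The probability that a
random walk started at a pixel reaches a foreground seed before a
background seed is the harmonic function solving the combinatorial
Dirichlet problem on the weighted lattice; thresholding it at 1/2 gives
the vessel mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage import morphology

from .io_mask import DegenerateInputError
from .vesselness import EigenField

UNLABELED, FOREGROUND, BACKGROUND = 0, 1, 2

# 8-neighborhood offsets covering each undirected edge once
_EDGE_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


class SeedingError(RuntimeError):
    """Raised when automatic seeding cannot produce both label classes."""


@dataclass
class WeightedLattice:
    """Sparse 8-connected lattice over in-FOV pixels.

    ``node_index`` maps pixel -> node id (-1 outside the FOV); ``edges``
    is an (E, 2) array of node-id pairs and ``weights`` the matching
    edge weights in (0, 1].
    """

    node_index: np.ndarray
    edges: np.ndarray
    weights: np.ndarray
    beta: float
    shape: tuple[int, int]

    @property
    def n_nodes(self) -> int:
        return int((self.node_index >= 0).sum())


def build_lattice(
    guide: np.ndarray, fov: np.ndarray, beta: float = 90.0
) -> WeightedLattice:
    """Build the weighted 8-connected lattice on the guide image.

    Weights follow ``exp(-beta * (v_i - v_j)**2)``; diagonal edges use
    the same formula as axial ones.  Pixels outside ``fov`` are excluded
    from the graph entirely.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    guide = np.asarray(guide, np.float64)
    fov = np.asarray(fov, bool)
    if guide.shape != fov.shape:
        raise ValueError(f"shape mismatch: {guide.shape} vs {fov.shape}")
    if not fov.any():
        raise DegenerateInputError("FOV mask is empty; no lattice to build")
    node_index = np.full(fov.shape, -1, np.int64)
    node_index[fov] = np.arange(int(fov.sum()))
    edges = []
    weights = []
    for dr, dc in _EDGE_OFFSETS:
        # slices selecting pixel i and its (dr, dc) neighbor j
        r0, r1 = (0, guide.shape[0] - dr) if dr >= 0 else (-dr, guide.shape[0])
        c0, c1 = (0, guide.shape[1] - dc) if dc >= 0 else (-dc, guide.shape[1])
        src = (slice(r0, r1), slice(c0, c1))
        dst = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        both = fov[src] & fov[dst]
        if not both.any():
            continue
        vi = guide[src][both]
        vj = guide[dst][both]
        edges.append(np.stack([node_index[src][both],
                               node_index[dst][both]], axis=1))
        weights.append(np.exp(-beta * (vi - vj) ** 2))
    if not edges:
        raise DegenerateInputError("FOV contains no adjacent pixel pairs")
    return WeightedLattice(
        node_index=node_index,
        edges=np.concatenate(edges, axis=0),
        weights=np.concatenate(weights),
        beta=float(beta),
        shape=guide.shape,
    )


def classify_density(c_final: np.ndarray, r_mid: int = 7) -> np.ndarray:
    """Flag each centerline pixel DENSE or SPARSE.

    The centerlines are dilated with a disc of radius ``r_mid``; a
    centerline pixel is DENSE iff the dilated mask, cropped to the square
    window of half-width ``2 * r_mid`` around it, splits into more than
    one 8-connected region — i.e. another vessel runs nearby and
    background seeds must stay close to avoid landing on it.

    Returns a boolean array over the full image, True = DENSE, defined
    (meaningful) only on centerline pixels.
    """
    if r_mid < 1:
        raise ValueError(f"r_mid must be >= 1, got {r_mid}")
    c_final = np.asarray(c_final, bool)
    dilated = morphology.dilation(c_final, morphology.disk(r_mid))
    dense = np.zeros(c_final.shape, bool)
    half = 2 * r_mid
    H, W = c_final.shape
    for r, c in np.argwhere(c_final):
        win = dilated[max(0, r - half):r + half + 1,
                      max(0, c - half):c + half + 1]
        _, n = ndimage.label(win, structure=np.ones((3, 3)))
        if n > 1:
            dense[r, c] = True
    return dense


def place_seeds(
    c_final: np.ndarray,
    eig: EigenField,
    density: np.ndarray,
    fov: np.ndarray,
    r_mid: int = 7,
    r_max: int = 12,
) -> np.ndarray:
    """Automatic seed map from the centerlines.

    Every centerline pixel becomes a foreground seed.  For each one, two
    background-seed candidates are placed at ``round(p +/- d*u)`` where
    ``u`` is the unit eigenvector of the larger Hessian eigenvalue (the
    cross-vessel direction) and ``d = r_mid + 1`` in dense areas,
    ``r_max + 1`` in sparse ones — one pixel beyond the largest radius a
    vessel can have, so the seed is guaranteed to sit on background.
    Candidates falling outside the FOV, on a foreground seed, or within
    1 px of any centerline pixel are dropped.

    Two further candidates per centerline pixel are placed *along* the
    vessel direction (the eigenvector of the smaller eigenvalue).  These
    are self-limiting: for interior pixels they land on the centerline
    corridor and are dropped by a 2-px exclusion zone, but at vessel
    tips they guard the region beyond the end, which the perpendicular
    rule alone leaves unseeded and which the walker would otherwise
    flood.

    Returns an int map with values UNLABELED / FOREGROUND / BACKGROUND.
    """
    c_final = np.asarray(c_final, bool)
    fov = np.asarray(fov, bool)
    if not c_final.any():
        raise SeedingError("no centerline pixels: cannot place seeds")
    labels = np.zeros(c_final.shape, np.uint8)
    labels[c_final] = FOREGROUND
    # exclusion zone: within 1 px (8-neighborhood) of any centerline pixel
    near_center = morphology.dilation(c_final, np.ones((3, 3), bool))
    H, W = c_final.shape
    coords = np.argwhere(c_final)
    d = np.where(density[coords[:, 0], coords[:, 1]],
                 r_mid + 1, r_max + 1).astype(np.float64)
    ux = eig.v2x[coords[:, 0], coords[:, 1]]
    uy = eig.v2y[coords[:, 0], coords[:, 1]]
    # wider exclusion for along-vessel candidates, so near-tangent
    # candidates on curved vessels cannot hug the centerline
    near_center2 = morphology.dilation(near_center, np.ones((3, 3), bool))
    n_bg = 0
    for dx, dy, excl in ((ux, uy, near_center), (-ux, -uy, near_center),
                         (-uy, ux, near_center2), (uy, -ux, near_center2)):
        # directions in (x, y) = (col, row) convention
        rr = np.round(coords[:, 0] + d * dy).astype(int)
        cc = np.round(coords[:, 1] + d * dx).astype(int)
        inside = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        rr, cc = rr[inside], cc[inside]
        ok2 = fov[rr, cc] & ~excl[rr, cc] & (labels[rr, cc] != FOREGROUND)
        rr, cc = rr[ok2], cc[ok2]
        labels[rr, cc] = BACKGROUND
        n_bg += len(rr)
    if n_bg == 0:
        raise SeedingError(
            f"no background seed placeable: {len(coords)} centerline pixels, "
            f"0 valid candidates")
    return labels


def solve_probabilities(
    lat: WeightedLattice, seeds: np.ndarray, tol: float = 1e-8
) -> np.ndarray:
    """Solve the random-walker Dirichlet problem on the lattice.

    The probability map is 1 at foreground seeds, 0 at background seeds,
    and at unlabeled nodes solves the sparse linear system of the graph
    Laplacian restricted to unlabeled nodes (the discrete harmonic
    extension of the seed values).  Unlabeled components containing no
    seed get probability 0 with a warning.  Pixels outside the lattice
    (outside the FOV) get probability 0.
    """
    seeds = np.asarray(seeds)
    if seeds.shape != lat.shape:
        raise ValueError(f"seed map shape {seeds.shape} != {lat.shape}")
    in_fov = lat.node_index >= 0
    fg = (seeds == FOREGROUND) & in_fov
    bg = (seeds == BACKGROUND) & in_fov
    if not fg.any() or not bg.any():
        raise SeedingError(
            f"need both seed classes inside the FOV: "
            f"{int(fg.sum())} foreground, {int(bg.sum())} background")
    n = lat.n_nodes
    values = np.zeros(n, np.float64)
    values[lat.node_index[fg]] = 1.0
    labeled = np.zeros(n, bool)
    labeled[lat.node_index[fg]] = True
    labeled[lat.node_index[bg]] = True

    i, j = lat.edges[:, 0], lat.edges[:, 1]
    w = lat.weights
    # graph Laplacian L = D - W over all nodes
    W = sparse.coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sparse.diags(deg) - W

    # lattice components with no seed at all have a singular reduced
    # block; their nodes get probability 0 with a warning
    n_comp, comp = sparse.csgraph.connected_components(W, directed=False)
    seeded_comps = np.zeros(n_comp, bool)
    seeded_comps[comp[labeled]] = True
    orphan = ~seeded_comps[comp] & ~labeled
    if orphan.any():
        warnings.warn(
            f"{int(orphan.sum())} unlabeled pixels are disconnected from "
            "all seeds; assigning probability 0", stacklevel=2)

    u_idx = np.flatnonzero(~labeled & ~orphan)
    if u_idx.size:
        L_csc = L.tocsc()
        LU = L_csc[np.ix_(u_idx, np.flatnonzero(labeled))]
        LUU = L_csc[np.ix_(u_idx, u_idx)]
        rhs = -LU @ values[labeled]
        u_solve = u_idx
        if u_solve.size:
            # the reduced Laplacian is SPD but severely ill-conditioned
            # (edge weights span ~exp(-beta)); residual-based iterative
            # stopping is unreliable there, and sparse LU is fast at
            # image sizes, so the system is solved directly
            x = spsolve(LUU.tocsc(), rhs)
            if np.abs(LUU @ x - rhs).max() > tol * max(1.0, np.abs(rhs).max()):
                warnings.warn("random-walker linear solve exceeded the "
                              "requested tolerance", stacklevel=2)
            values[u_solve] = np.clip(x, 0.0, 1.0)

    prob = np.zeros(lat.shape, np.float64)
    prob[in_fov] = values[lat.node_index[in_fov]]
    return prob


def binarize(prob: np.ndarray, fov: np.ndarray | None = None) -> np.ndarray:
    """Vessel mask: foreground probability >= 1/2 (ties count as vessel)."""
    mask = np.asarray(prob, np.float64) >= 0.5
    if fov is not None:
        mask &= np.asarray(fov, bool)
    return mask


def segment(
    guide: np.ndarray,
    c_final: np.ndarray,
    eig: EigenField,
    fov: np.ndarray,
    beta: float = 90.0,
    r_mid: int = 7,
    r_max: int = 12,
    solver_tol: float = 1e-8,
) -> dict[str, np.ndarray]:
    """Full random-walker stage: seeds, probabilities, binary mask."""
    density = classify_density(c_final, r_mid=r_mid)
    seeds = place_seeds(c_final, eig, density, fov, r_mid=r_mid, r_max=r_max)
    lat = build_lattice(guide, fov, beta=beta)
    prob = solve_probabilities(lat, seeds, tol=solver_tol)
    mask = binarize(prob, fov=fov)
    return {"density": density, "seeds": seeds, "probability": prob,
            "mask": mask}
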