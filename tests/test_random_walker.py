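import numpy as np
import pytest

from vesselwalk import random_walker as rw
from vesselwalk import synthetic
from vesselwalk.io_mask import DegenerateInputError
from vesselwalk.vesselness import EigenField


def random_lattice(rng, shape):
    """Fully-connected image lattice with i.i.d. random edge weights."""
    lat = rw.build_lattice(np.zeros(shape), np.ones(shape, bool), beta=1.0)
    return rw.WeightedLattice(
        node_index=lat.node_index,
        edges=lat.edges,
        weights=rng.uniform(0.05, 1.0, size=len(lat.weights)),
        beta=1.0, shape=shape)


def dense_oracle(lat, seeds):
    """Dirichlet solve by dense linear algebra, independent of the
    sparse implementation path."""
    n = lat.n_nodes
    L = np.zeros((n, n))
    for (a, b), w in zip(lat.edges, lat.weights):
        L[a, b] -= w
        L[b, a] -= w
        L[a, a] += w
        L[b, b] += w
    vals = np.zeros(n)
    vals[lat.node_index[seeds == rw.FOREGROUND]] = 1.0
    labeled = np.zeros(n, bool)
    labeled[lat.node_index[seeds > 0]] = True
    u = vals.copy()
    un = ~labeled
    if un.any():
        A = L[np.ix_(un, un)]
        b = -L[np.ix_(un, labeled)] @ vals[labeled]
        u[un] = np.linalg.solve(A, b)
    out = np.zeros(lat.shape)
    out[lat.node_index >= 0] = u[lat.node_index[lat.node_index >= 0]]
    return out


def random_seeds(rng, shape):
    seeds = np.zeros(shape, np.uint8)
    flat = rng.permutation(shape[0] * shape[1])
    n_fg = rng.integers(1, 3)
    n_bg = rng.integers(1, 3)
    for k in flat[:n_fg]:
        seeds[np.unravel_index(k, shape)] = rw.FOREGROUND
    for k in flat[n_fg:n_fg + n_bg]:
        seeds[np.unravel_index(k, shape)] = rw.BACKGROUND
    return seeds


class TestLattice:
    def test_equal_intensities_give_unit_weight(self):
        lat = rw.build_lattice(np.full((4, 4), 0.3), np.ones((4, 4), bool),
                               beta=90.0)
        np.testing.assert_allclose(lat.weights, 1.0)

    def test_weight_formula(self):
        guide = np.array([[0.0, 0.1]])
        lat = rw.build_lattice(guide, np.ones((1, 2), bool), beta=90.0)
        assert lat.weights[0] == pytest.approx(np.exp(-0.9))

    def test_weights_in_unit_interval(self, rng):
        lat = rw.build_lattice(rng.random((10, 10)), np.ones((10, 10), bool),
                               beta=90.0)
        assert (lat.weights > 0).all() and (lat.weights <= 1).all()

    def test_eight_connectivity_edge_count(self):
        # n x n full grid: 2n(n-1) axial + 2(n-1)^2 diagonal edges
        lat = rw.build_lattice(np.zeros((5, 5)), np.ones((5, 5), bool))
        assert len(lat.edges) == 2 * 5 * 4 + 2 * 16

    def test_empty_fov_rejected(self):
        with pytest.raises(DegenerateInputError):
            rw.build_lattice(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestDensity:
    def test_single_line_all_sparse(self):
        cf = np.zeros((64, 64), bool)
        cf[32, 8:56] = True
        assert not rw.classify_density(cf, r_mid=7).any()

    def test_parallel_lines_flagged_dense(self):
        """Two centerlines 3*r_mid apart see each other in the window."""
        cf = np.zeros((80, 80), bool)
        cf[30, 10:70] = True
        cf[51, 10:70] = True
        dense = rw.classify_density(cf, r_mid=7)
        assert dense[30, 30:50].all()
        assert dense[51, 30:50].all()

    def test_far_lines_stay_sparse(self):
        cf = np.zeros((100, 100), bool)
        cf[20, 10:90] = True
        cf[80, 10:90] = True
        assert not rw.classify_density(cf, r_mid=7).any()


def straight_tube_setup(r_max=12):
    """A horizontal centerline with a synthetic cross-vessel eigenfield."""
    shape = (64, 128)
    cf = np.zeros(shape, bool)
    cf[32, 20:108] = True
    ones = np.ones(shape)
    zeros = np.zeros(shape)
    # cross-vessel direction is vertical: v2 = (0, 1) in (x, y)
    eig = EigenField(lam1=zeros, lam2=ones, v2x=zeros, v2y=ones)
    fov = np.ones(shape, bool)
    density = np.zeros(shape, bool)
    return cf, eig, density, fov


class TestSeeding:
    def test_background_seeds_at_rmax_plus_one(self):
        """Sparse seeds sit 13 px above and below the axis (r_max=12)."""
        cf, eig, density, fov = straight_tube_setup()
        seeds = rw.place_seeds(cf, eig, density, fov, r_mid=7, r_max=12)
        assert (seeds[32, 20:108] == rw.FOREGROUND).all()
        assert (seeds[32 - 13, 20:108] == rw.BACKGROUND).all()
        assert (seeds[32 + 13, 20:108] == rw.BACKGROUND).all()

    def test_dense_seeds_at_rmid_plus_one(self):
        cf, eig, density, fov = straight_tube_setup()
        density = density.copy()
        density[cf] = True
        seeds = rw.place_seeds(cf, eig, density, fov, r_mid=7, r_max=12)
        assert (seeds[32 - 8, 20:108] == rw.BACKGROUND).all()

    def test_out_of_fov_candidates_skipped(self):
        """Centerline pixels whose candidates leave the FOV still
        contribute no error when other seeds exist."""
        cf, eig, density, fov = straight_tube_setup()
        fov = fov.copy()
        fov[:25] = False  # upper candidates now outside the FOV
        seeds = rw.place_seeds(cf, eig, density, fov, r_mid=7, r_max=12)
        assert (seeds[32 + 13, 20:108] == rw.BACKGROUND).all()
        assert (seeds[:25] == rw.UNLABELED).all()

    def test_no_centerline_raises(self):
        cf, eig, density, fov = straight_tube_setup()
        with pytest.raises(rw.SeedingError):
            rw.place_seeds(np.zeros_like(cf), eig, density, fov)

    def test_phantom_background_seeds_outside_vessels(self, bundles,
                                                      pipeline_results):
        """All background seeds land outside the true vessel mask."""
        b = bundles["a"]
        seeds = pipeline_results["a"]["seeds"]
        bg = seeds == rw.BACKGROUND
        assert bg.any()
        assert (bg & b.vessel_mask).sum() == 0


class TestSolver:
    def test_uniform_chain_is_linear(self):
        """1-D chain, fg at one end, bg at the other: u_k = 1 - k/n."""
        n = 50
        guide = np.zeros((1, n + 1))
        fov = np.ones((1, n + 1), bool)
        seeds = np.zeros((1, n + 1), np.uint8)
        seeds[0, 0] = rw.FOREGROUND
        seeds[0, n] = rw.BACKGROUND
        lat = rw.build_lattice(guide, fov)
        prob = rw.solve_probabilities(lat, seeds)
        np.testing.assert_allclose(prob[0], 1 - np.arange(n + 1) / n,
                                   atol=1e-8)

    def test_all_seeded_returns_indicator(self, rng):
        shape = (4, 4)
        lat = random_lattice(rng, shape)
        seeds = np.full(shape, rw.BACKGROUND, np.uint8)
        seeds[0, 0] = seeds[2, 3] = rw.FOREGROUND
        prob = rw.solve_probabilities(lat, seeds)
        np.testing.assert_array_equal(prob, (seeds == rw.FOREGROUND))

    def test_matches_dense_oracle_3x3(self, rng):
        lat = random_lattice(rng, (3, 3))
        seeds = np.zeros((3, 3), np.uint8)
        seeds[0, 0] = rw.FOREGROUND
        seeds[2, 2] = rw.BACKGROUND
        np.testing.assert_allclose(rw.solve_probabilities(lat, seeds),
                                   dense_oracle(lat, seeds), atol=1e-8)

    def test_missing_label_raises(self, rng):
        lat = random_lattice(rng, (3, 3))
        seeds = np.zeros((3, 3), np.uint8)
        seeds[0, 0] = rw.FOREGROUND
        with pytest.raises(rw.SeedingError):
            rw.solve_probabilities(lat, seeds)

    def test_disconnected_component_warns_and_zeroes(self):
        fov = np.ones((3, 7), bool)
        fov[:, 3] = False  # two disconnected blocks
        seeds = np.zeros((3, 7), np.uint8)
        seeds[1, 0] = rw.FOREGROUND
        seeds[0, 1] = rw.BACKGROUND
        lat = rw.build_lattice(np.zeros((3, 7)), fov)
        with pytest.warns(UserWarning, match="disconnected"):
            prob = rw.solve_probabilities(lat, seeds)
        assert (prob[:, 4:] == 0.0).all()

    def test_label_swap_antisymmetry(self, rng):
        lat = random_lattice(rng, (5, 4))
        seeds = random_seeds(rng, (5, 4))
        swapped = seeds.copy()
        swapped[seeds == rw.FOREGROUND] = rw.BACKGROUND
        swapped[seeds == rw.BACKGROUND] = rw.FOREGROUND
        u = rw.solve_probabilities(lat, seeds)
        v = rw.solve_probabilities(lat, swapped)
        np.testing.assert_allclose(u, 1.0 - v, atol=1e-8)

    def test_weight_scale_invariance(self, rng):
        lat = random_lattice(rng, (5, 5))
        seeds = random_seeds(rng, (5, 5))
        scaled = rw.WeightedLattice(node_index=lat.node_index,
                                    edges=lat.edges,
                                    weights=7.3 * lat.weights,
                                    beta=lat.beta, shape=lat.shape)
        np.testing.assert_allclose(rw.solve_probabilities(lat, seeds),
                                   rw.solve_probabilities(scaled, seeds),
                                   atol=1e-8)

    def test_harmonicity_and_maximum_principle(self, rng):
        lat = random_lattice(rng, (5, 5))
        seeds = random_seeds(rng, (5, 5))
        prob = rw.solve_probabilities(lat, seeds)
        assert prob.min() >= 0.0 and prob.max() <= 1.0
        # weighted-mean property at every unlabeled node
        flat = prob.ravel()
        num = np.zeros(lat.n_nodes)
        den = np.zeros(lat.n_nodes)
        for (a, b), w in zip(lat.edges, lat.weights):
            num[a] += w * flat[b]
            num[b] += w * flat[a]
            den[a] += w
            den[b] += w
        un = (seeds == rw.UNLABELED).ravel()
        np.testing.assert_allclose(flat[un], (num / den)[un], atol=1e-6)


class TestBinarize:
    def test_all_foreground(self):
        assert rw.binarize(np.ones((3, 3))).all()

    def test_tie_goes_to_vessel(self):
        prob = np.array([[0.4999, 0.5, 0.5001]])
        np.testing.assert_array_equal(rw.binarize(prob),
                                      [[False, True, True]])

    def test_fov_restriction(self):
        prob = np.ones((2, 2))
        fov = np.array([[True, False], [False, True]])
        np.testing.assert_array_equal(rw.binarize(prob, fov), fov)
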