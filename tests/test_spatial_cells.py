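"""Grid/place-cell models: printed-matrix transforms, hexagonal lattice
signature, and scalar oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroarena import spatial_cells as sc
from neuroarena.spatial_cells import (
    FrameTransform,
    GridCellSpec,
    PlaceCellSpec,
    grid_rate,
    inverse_transform,
    landmark_response,
    place_activity,
    place_to_grid,
    rate_map,
    transform_frame,
)


class TestPlaceToGrid:
    def test_origin_no_phase(self):
        spec = GridCellSpec(s=1.0, theta=0.3)
        assert np.allclose(place_to_grid([0, 0], spec), [0, 0])

    def test_pure_phase_shift(self):
        spec = GridCellSpec(s=1.0, theta=0.3, phi=(0.5, 0.0))
        assert np.allclose(place_to_grid([0, 0], spec), [-0.5, 0.0])

    def test_oblique_basis_product(self):
        """s=1, theta=0: basis^T @ (1,0) = (cos 0, cos 60deg) = (1, 0.5)."""
        spec = GridCellSpec(s=1.0, theta=0.0)
        assert np.allclose(place_to_grid([1, 0], spec), [1.0, 0.5])


class TestGridRate:
    def test_rate_half_at_zeta_distance(self):
        """d/s = zeta makes the arctan argument vanish -> rate 1/2."""
        spec = GridCellSpec(s=1.0, theta=0.0, kappa=0.5, zeta=0.0)
        vertex = spec.phase_origin
        assert grid_rate(vertex, spec) == pytest.approx(0.5)

    def test_scalar_oracle_values(self):
        """Frozen high-precision oracles for the arctan rate map.

        At d = s the map gives 1/2 - arctan(0.5)/pi = 0.35241638...;
        geometrically the largest reachable d in a unit lattice is
        s/sqrt(3), so grid_rate is probed at an edge midpoint (d = s/2),
        where the oracle value is 0.42202087...
        """
        spec = GridCellSpec(s=1.0, theta=0.0, kappa=0.5, zeta=0.0)
        assert 0.5 - math.atan(0.5) / math.pi == pytest.approx(
            0.35241638, abs=1e-7
        )
        midpoint = spec.phase_origin + 0.5 * spec.basis[:, 0]
        assert grid_rate(midpoint, spec) == pytest.approx(
            0.42202087, abs=1e-7
        )

    def test_rate_decreases_with_distance_and_limits(self):
        spec = GridCellSpec(s=1.0, theta=0.0, kappa=0.5, zeta=0.0)
        vertex = spec.phase_origin
        direction = np.array([0.05, 0.02])
        direction /= np.linalg.norm(direction)
        ds = np.linspace(0.0, 0.5, 30)  # within the cell, d grows with |x|
        rates = [grid_rate(vertex + d * direction, spec) for d in ds]
        assert all(b <= a + 1e-12 for a, b in zip(rates, rates[1:]))
        assert all(0.0 < r < 1.0 for r in rates)

    @given(
        n1=st.integers(-3, 3), n2=st.integers(-3, 3),
        px=st.floats(-2, 2), py=st.floats(-2, 2),
    )
    @settings(max_examples=40, deadline=None)
    def test_lattice_periodicity(self, n1, n2, px, py):
        spec = GridCellSpec(s=0.7, theta=0.4, phi=(1.0, 2.0), kappa=0.8)
        basis = spec.basis
        p = np.array([px, py])
        shifted = p + n1 * basis[:, 0] + n2 * basis[:, 1]
        assert grid_rate(shifted, spec) == pytest.approx(
            grid_rate(p, spec), abs=1e-9
        )

    def test_rotation_equivariance(self):
        """Rotating the cell orientation by delta rotates the firing
        field rigidly: rate(R @ p, rotated spec) == rate(p, spec)."""
        delta = 0.2
        spec = GridCellSpec(s=1.0, theta=0.3, phi=(0.5, 0.3))
        rotated = GridCellSpec(s=1.0, theta=0.3 + delta, phi=(0.5, 0.3))
        c, s_ = math.cos(delta), math.sin(delta)
        R = np.array([[c, -s_], [s_, c]])
        rng = np.random.default_rng(3)
        for p in rng.uniform(-1.5, 1.5, (20, 2)):
            assert grid_rate(R @ p, rotated) == pytest.approx(
                grid_rate(p, spec), abs=1e-9
            )


class TestHexagonalLattice:
    def test_six_nearest_neighbours_at_spacing(self):
        """Every interior vertex has exactly six neighbours at distance s
        (the hexagonal grid signature)."""
        spec = sc.GRID_PRESETS["unit"]
        basis = spec.basis
        origin = spec.phase_origin
        ns = range(-4, 5)
        verts = np.array(
            [origin + i * basis[:, 0] + j * basis[:, 1]
             for i in ns for j in ns]
        )
        center = origin + 0 * basis[:, 0]
        d = np.linalg.norm(verts - center, axis=1)
        neighbours = np.sum(np.abs(d - spec.s) < 1e-9)
        assert neighbours == 6

    def test_rate_map_peak_spacing(self):
        """Firing peaks of the desk-scale preset form a triangular lattice
        with nearest-peak spacing ~ the 1.0 m grid spacing."""
        spec = sc.GRID_PRESETS["unit"]
        rmap = rate_map(spec, arena_radius=1.3, resolution=0.01)
        peaks = sc.find_rate_peaks(rmap)
        assert len(peaks) >= 3
        # nearest-neighbour distances among detected peaks
        dists = []
        for i, p in enumerate(peaks):
            others = np.delete(peaks, i, axis=0)
            dists.append(np.min(np.linalg.norm(others - p, axis=1)))
        assert np.median(dists) == pytest.approx(1.0, abs=0.05)

    def test_kappa_sharpens_peaks(self):
        broad = rate_map(GridCellSpec(s=1.0, theta=math.pi / 4,
                                      phi=(0.5, 0.0), kappa=0.5))
        sharp = rate_map(GridCellSpec(s=1.0, theta=math.pi / 4,
                                      phi=(0.5, 0.0), kappa=5.0))

        def peak_to_mean(rm):
            r = rm.rates[np.isfinite(rm.rates)]
            return r.max() / r.mean()

        assert peak_to_mean(sharp) > peak_to_mean(broad)

    def test_rate_map_masks_outside_disc(self):
        rmap = rate_map(sc.GRID_PRESETS["unit"], arena_radius=1.3,
                        resolution=0.05)
        xx, yy = np.meshgrid(rmap.x, rmap.y)
        outside = xx**2 + yy**2 > 1.3**2
        assert np.all(np.isnan(rmap.rates[outside]))
        assert np.all(np.isfinite(rmap.rates[~outside]))


class TestFrameTransform:
    def test_identity(self):
        tf = FrameTransform(0.0, (0.0, 0.0))
        assert np.allclose(transform_frame([1.2, -0.7], tf), [1.2, -0.7])

    def test_quarter_turn_transposed_matrix(self):
        """phi = pi/2 with the transposed rotation sends (1,0) -> (0,-1)."""
        tf = FrameTransform(math.pi / 2, (0.0, 0.0))
        assert np.allclose(transform_frame([1, 0], tf), [0, -1], atol=1e-12)

    @given(
        phi=st.floats(-math.pi, math.pi),
        tx=st.floats(-3, 3), ty=st.floats(-3, 3),
        px=st.floats(-5, 5), py=st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_and_isometry(self, phi, tx, ty, px, py):
        tf = FrameTransform(phi, (tx, ty))
        p = np.array([px, py])
        assert np.allclose(inverse_transform(transform_frame(p, tf), tf),
                           p, atol=1e-12)
        q = np.array([px + 1.0, py - 2.0])
        d0 = np.linalg.norm(p - q)
        d1 = np.linalg.norm(transform_frame(p, tf) - transform_frame(q, tf))
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_rotation_is_special_orthogonal(self):
        R = FrameTransform(0.8).rotation
        assert np.allclose(R @ R.T, np.eye(2), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestPlaceCells:
    bank = {"g1": GridCellSpec(s=1.0, theta=0.0, kappa=0.5, zeta=0.0)}

    def test_threshold_extremes(self):
        always_off = PlaceCellSpec(("g1",), theta_sum=2.0)
        always_on = PlaceCellSpec(("g1",), theta_sum=0.0)
        for pos in [(0, 0), (0.3, 0.4), (1.0, -0.2)]:
            assert place_activity(pos, always_off, self.bank) == 0
            assert place_activity(pos, always_on, self.bank) == 1

    def test_vertex_boundary_is_active(self):
        """At a lattice vertex with zeta=0 the single-cell rate is exactly
        0.5; the >= comparison makes the place cell active."""
        spec = PlaceCellSpec(("g1",), theta_sum=0.5)
        vertex = self.bank["g1"].phase_origin
        assert place_activity(vertex, spec, self.bank) == 1

    def test_unknown_grid_id_rejected(self):
        spec = PlaceCellSpec(("nope",), theta_sum=0.5)
        with pytest.raises(KeyError, match="nope"):
            place_activity((0, 0), spec, self.bank)


class TestLandmarkResponse:
    spec = PlaceCellSpec(("g1",), sigma_d2=0.04, sigma_theta2=0.1)

    def test_perfect_match_counts_landmarks(self):
        lms = [(1.0, 0.2), (0.5, -1.0), (2.0, 3.0)]
        assert landmark_response(lms, lms, self.spec) == pytest.approx(3.0)

    def test_one_sigma_distance_mismatch(self):
        """(d - d_hat)^2 = sigma_d2 with matching bearing -> exp(-1)."""
        obs = [(1.0 + math.sqrt(self.spec.sigma_d2), 0.0)]
        rem = [(1.0, 0.0)]
        assert landmark_response(obs, rem, self.spec) == pytest.approx(
            math.exp(-1.0)
        )

    def test_angle_wrap(self):
        """Bearings pi-epsilon and -pi+epsilon differ by 2*epsilon, not
        ~2*pi."""
        eps = 0.01
        obs = [(1.0, math.pi - eps)]
        rem = [(1.0, -math.pi + eps)]
        expected = math.exp(-((2 * eps) ** 2) / self.spec.sigma_theta2)
        assert landmark_response(obs, rem, self.spec) == pytest.approx(
            expected
        )

    def test_gross_mismatch_vanishes(self):
        assert landmark_response(
            [(10.0, 0.0)], [(0.0, 0.0)], self.spec
        ) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            landmark_response([(1, 0)], [(1, 0), (2, 0)], self.spec)


def test_spec_validation():
    with pytest.raises(ValueError):
        GridCellSpec(s=-1.0, theta=0.1)
    with pytest.raises(ValueError):
        GridCellSpec(s=1.0, theta=2.0)  # beyond pi/3
    with pytest.raises(ValueError):
        PlaceCellSpec(())
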