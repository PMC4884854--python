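"""Quasi-static compression: homogeneous oracle, balance, incompressibility."""

import numpy as np
import pytest

from nlswei.compress import (rasterize_deformed, roi_statistics,
                             solve_compression, staged_compression)
from nlswei.phantom import TUMOR, build_phantom, make_test_fixture


@pytest.fixture(scope="module")
def box_state(small_box):
    return solve_compression(small_box, 0.10, spacing=1.0, substep=0.02)


@pytest.fixture(scope="module")
def mini_phantom():
    """Scaled-down heterogeneous phantom for solver tests (fast)."""
    return build_phantom(tumor_center=(6.0, 10.0), tumor_diameter=5.0,
                         platen_width=22.0)


@pytest.fixture(scope="module")
def mini_states(mini_phantom):
    return staged_compression(mini_phantom, [0.0, 0.10, 0.20], spacing=2.0,
                              substep=0.02)


class TestHomogeneousOracle:
    def test_uniform_uniaxial_state(self, box_state):
        """Frictionless full-width platen on a roller base: per-cell
        vertical strain equals the applied 10% everywhere (tol 1%)."""
        eyy = box_state.element_strain[:, 1, 1]
        assert np.abs(eyy + 0.10).max() < 0.01

    def test_near_incompressibility(self, box_state):
        J = np.linalg.det(box_state.element_F)
        assert np.abs(J - 1.0).max() < 0.02

    def test_force_balance(self, box_state):
        top = box_state.platen_reaction()
        bot = box_state.base_reaction()
        assert top == pytest.approx(-bot, rel=1e-3)
        assert top < 0  # platen pushes down

    def test_level_zero_identity(self, small_box):
        st = solve_compression(small_box, 0.0)
        assert np.all(st.nodal_displacements == 0.0)
        assert st.tangent_modulus_field == pytest.approx(4.0)


class TestPhantomCompression:
    def test_energy_increases_with_level(self, mini_states):
        e = [s.stored_energy for s in mini_states]
        assert e[0] == 0.0
        assert e[2] > e[1] > 0.0

    def test_tangent_moduli_increase_with_level(self, mini_states, mini_phantom):
        stats = [roi_statistics(s, mini_phantom, surr_offset=(5.0, 0.0))
                 for s in mini_states]
        tum = [r["tumor"]["modulus_mean"] for r in stats]
        sur = [r["surrounding"]["modulus_mean"] for r in stats]
        assert tum[0] == pytest.approx(5.64, rel=1e-6)
        assert sur[0] == pytest.approx(1.50, rel=1e-6)
        assert tum[2] > tum[1] > tum[0]
        assert sur[2] > sur[1] > sur[0]

    def test_stiff_tumor_deforms_less(self, mini_states, mini_phantom):
        r = roi_statistics(mini_states[2], mini_phantom, surr_offset=(5.0, 0.0))
        assert r["tumor"]["strain_mean"] < r["surrounding"]["strain_mean"]
        assert r["tumor"]["stress_mean"] > r["surrounding"]["stress_mean"]

    def test_incremental_matches_direct(self, mini_phantom):
        import nlswei.fem as fem
        mesh = fem.build_mesh(mini_phantom, 2.0)
        st_a = solve_compression(mini_phantom, 0.10, mesh=mesh, substep=0.02)
        st_b = solve_compression(mini_phantom, 0.15, mesh=mesh, substep=0.02,
                                 warm_start=st_a)
        st_c = solve_compression(mini_phantom, 0.15, mesh=mesh, substep=0.02)
        du = np.abs(st_b.nodal_displacements - st_c.nodal_displacements).max()
        assert du < 5e-3  # elastic path independence up to solver tolerance

    def test_levels_must_ascend(self, mini_phantom):
        with pytest.raises(ValueError):
            staged_compression(mini_phantom, [0.2, 0.1], spacing=2.0)

    def test_roi_mean_is_bruteforce_average(self, mini_states, mini_phantom):
        st = mini_states[1]
        r = roi_statistics(st, mini_phantom, surr_offset=(5.0, 0.0))
        c = st.element_centers
        cx, cy = mini_phantom.tumor_center
        mask = (c[:, 0] - cx) ** 2 + (c[:, 1] - cy) ** 2 <= 2.5 ** 2
        brute = st.tangent_modulus_field[mask].mean()
        assert r["tumor"]["modulus_mean"] == pytest.approx(brute, rel=1e-12)


class TestDeformedRasterization:
    def test_identity_rasterization_matches_labels(self, mini_phantom):
        grids = rasterize_deformed(None, mini_phantom, spacing=0.5)
        labels = mini_phantom.rasterize(0.5)[0]
        assert np.array_equal(grids["label"], labels)
        assert grids["mu"][labels == TUMOR] == pytest.approx(5.64, rel=1e-6)

    def test_deformed_tumor_moves_down(self, mini_states, mini_phantom):
        g0 = rasterize_deformed(mini_states[0], mini_phantom, spacing=0.5)
        g2 = rasterize_deformed(mini_states[2], mini_phantom, spacing=0.5)
        y0 = g0["y"][np.nonzero(g0["label"] == TUMOR)[1]].mean()
        y2 = g2["y"][np.nonzero(g2["label"] == TUMOR)[1]].mean()
        assert y2 < y0  # tumor centroid moves toward the base
        # tumor tissue is stiffer after compression
        assert g2["mu"][g2["label"] == TUMOR].mean() > 5.64
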