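"""Unit and property tests for the sub-cellular-element mechanics."""

import numpy as np
import pytest

from rhombosim.params import ForceParams
from rhombosim.scem_mechanics import (
    Cell,
    Fate,
    Tissue,
    build_cell_template,
    cell_geometry,
    pair_force,
    pair_potential,
    step_mechanics,
    total_energy,
    total_forces,
)
from conftest import make_single_cell, relax


def two_cell_tissue(forces, fates, separation, n_e=4):
    template = build_cell_template(n_e, forces)
    pos = np.concatenate([template, template + [separation, 0.0]])
    return Tissue(
        pos=pos,
        cell_of=np.repeat([0, 1], n_e),
        fate=np.array(fates, dtype=np.int8),
        domain=(-50.0, 50.0, -50.0, 50.0),
        time=0.0,
        n_e=n_e,
    )


def center_distance(tissue):
    c = tissue.centers()
    return float(np.linalg.norm(c[0] - c[1]))


class TestPairForce:
    def test_zero_at_equilibrium(self, forces):
        r_eq = forces.morse_adhesion.equilibrium_distance
        assert pair_force(r_eq, "like", forces) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("kind", ["intra", "like", "unlike"])
    def test_vanishes_beyond_cutoff(self, forces, kind):
        assert pair_force(2.5, kind, forces) == 0.0
        assert pair_force(forces.cutoff, kind, forces) == 0.0

    def test_repulsive_below_attractive_above_equilibrium(self, forces):
        r_eq = forces.morse_intra.equilibrium_distance
        assert pair_force(0.8 * r_eq, "intra", forces) > 0
        assert pair_force(1.3 * r_eq, "intra", forces) < 0

    def test_unlike_always_repulsive(self, forces):
        r = np.linspace(0.05, forces.cutoff - 1e-9, 50)
        assert np.all(pair_force(r, "unlike", forces) >= 0)

    @pytest.mark.parametrize("kind", ["intra", "like", "unlike"])
    def test_matches_negative_potential_gradient(self, forces, kind):
        # central difference of the energy, inside the untapered region
        r = 0.9 * forces.morse_intra.equilibrium_distance
        h = 1e-6
        dU = (pair_potential(r + h, kind, forces) - pair_potential(r - h, kind, forces)) / (2 * h)
        assert pair_force(r, kind, forces) == pytest.approx(-dU, abs=1e-6)

    def test_nonpositive_separation_rejected(self, forces):
        with pytest.raises(ValueError):
            pair_force(0.0, "like", forces)
        with pytest.raises(ValueError):
            pair_force(-1.0, "intra", forces)

    def test_unknown_kind_rejected(self, forces):
        with pytest.raises(ValueError, match="kind"):
            pair_force(1.0, "frictional", forces)


class TestTotalForces:
    def test_equilibrated_cell_is_force_free(self, forces, relaxed_cell):
        f = total_forces(relaxed_cell, forces)
        assert np.abs(f).max() < 1e-6

    def test_like_cells_attract(self, forces):
        t = two_cell_tissue(forces, [1, 1], 1.5)
        d0 = center_distance(t)
        for _ in range(200):
            step_mechanics(t, forces, 0.005)
        assert center_distance(t) < d0

    def test_unlike_cells_repel(self, forces):
        t = two_cell_tissue(forces, [1, -1], 1.5)
        d0 = center_distance(t)
        for _ in range(200):
            step_mechanics(t, forces, 0.005)
        assert center_distance(t) > d0

    def test_action_reaction_net_zero(self, forces):
        t = two_cell_tissue(forces, [1, -1], 1.2)
        f = total_forces(t, forces)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_cutoff_locality_bit_identical(self, forces):
        t = two_cell_tissue(forces, [1, 1], 1.5)
        f_before = total_forces(t, forces)[: t.n_e * 2]
        # add a third cell far beyond cutoff + 2 cell radii
        template = build_cell_template(4, forces)
        pos = np.concatenate([t.pos, template + [30.0, 0.0]])
        t3 = Tissue(
            pos=pos,
            cell_of=np.concatenate([t.cell_of, np.full(4, 2)]),
            fate=np.array([1, 1, -1], dtype=np.int8),
            domain=t.domain,
            time=0.0,
            n_e=4,
        )
        f_after = total_forces(t3, forces)[: t.n_e * 2]
        assert np.array_equal(f_before, f_after)

    def test_coincident_elements_resolved_not_fatal(self, forces):
        t = two_cell_tissue(forces, [1, 1], 1.5)
        t.pos[4] = t.pos[0]  # exact overlap across cells
        f = total_forces(t, forces)
        assert np.all(np.isfinite(f))
        assert not np.array_equal(t.pos[4], t.pos[0])  # perturbed apart


class TestStepMechanics:
    def test_no_force_no_motion(self, forces):
        t = make_single_cell(forces, n_e=4, seed=1)
        t.pos = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        before = t.pos.copy()
        step_mechanics(t, forces, 0.005)
        assert np.allclose(t.pos, before, atol=1e-12)
        assert t.time == pytest.approx(0.005)

    def test_dt_above_stability_bound_rejected(self, forces):
        t = make_single_cell(forces)
        before = t.pos.copy()
        with pytest.raises(ValueError, match="stability"):
            step_mechanics(t, forces, 10 * forces.max_stable_dt())
        assert np.array_equal(t.pos, before)  # no state change

    def test_relaxation_dissipates_energy(self, forces):
        t = relax(make_single_cell(forces, seed=3), forces, n_steps=500)
        t.pos[0] += [0.3, 0.1]  # displace one element
        energies = []
        dt = 0.25 * forces.max_stable_dt()
        for _ in range(40):
            energies.append(total_energy(t, forces))
            step_mechanics(t, forces, dt)
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)

    def test_two_like_cells_close_monotonically(self, forces):
        t = two_cell_tissue(forces, [1, 1], 1.8)
        d = [center_distance(t)]
        for _ in range(100):
            step_mechanics(t, forces, 0.005)
            d.append(center_distance(t))
        assert d[-1] < d[0]
        assert np.all(np.diff(d) <= 1e-9)

    def test_reflecting_walls_keep_elements_inside(self, forces):
        t = make_single_cell(forces, seed=5)
        t.domain = (-1.0, 1.0, -1.0, 1.0)
        rng = np.random.default_rng(0)
        fp = ForceParams(element_noise=0.5)
        for _ in range(200):
            step_mechanics(t, fp, 0.005, rng=rng)
        assert t.pos[:, 0].min() >= -1.0 and t.pos[:, 0].max() <= 1.0
        assert t.pos[:, 1].min() >= -1.0 and t.pos[:, 1].max() <= 1.0


class TestCellGeometry:
    def test_regular_polygon_is_spherical(self):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        elems = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        geom = cell_geometry(Cell(0, elems, Fate.A))
        assert np.allclose(geom["center"], 0.0, atol=1e-12)
        assert geom["asphericity"] == pytest.approx(0.0, abs=1e-12)

    def test_center_is_mean(self):
        elems = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        geom = cell_geometry(Cell(0, elems, Fate.A))
        assert np.allclose(geom["center"], [1.0, 0.0])

    def test_asphericity_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        elems = rng.standard_normal((12, 2))
        geom = cell_geometry(Cell(0, elems, Fate.B))
        r = np.linalg.norm(elems - elems.mean(axis=0), axis=1)
        assert geom["asphericity"] == pytest.approx(r.var() / r.mean() ** 2)

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError):
            cell_geometry(Cell(0, np.zeros((2, 2)), Fate.A))


@pytest.mark.parametrize("seed", range(5))
def test_isolated_cell_rounds_up(forces, seed):
    """Random scattered elements relax to a round cell (asphericity < 0.05)."""

    t = relax(make_single_cell(forces, seed=seed), forces)
    geom = cell_geometry(t.cell(0))
    assert geom["asphericity"] < 0.05


def test_numba_and_numpy_force_paths_agree(forces):
    from rhombosim import _kernels

    if not _kernels.HAVE_NUMBA:
        pytest.skip("numba not available")
    t = two_cell_tissue(forces, [1, -1], 1.2)
    f_kernel = total_forces(t, forces)
    try:
        _kernels.HAVE_NUMBA = False
        f_numpy = total_forces(t, forces)
    finally:
        _kernels.HAVE_NUMBA = True
    assert np.allclose(f_kernel, f_numpy, atol=1e-12)
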