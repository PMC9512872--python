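"""Energy model, analytic gradients and restrained optimization."""

import numpy as np
import pytest
from helpers import atom, single_atom_site

from growlite.chem_io import BindingSite, Molecule
from growlite.fixtures import FixtureSpec, make_core, make_fragment, plant_case
from growlite.growing import Pose, enumerate_attachments, grow
from growlite.optimizer import (EnergyModel, OptimizationSummary, energy,
                                optimize_pose, restraint_energy)


@pytest.fixture
def model():
    return EnergyModel()


def single_atom_pose(element="C", pos=(0.0, 0.0, 0.0), h=0):
    mol = Molecule([atom(0, element, pos, h=h)])
    return Pose(mol, frozenset())  # the lone atom is core


def test_isolated_pose_far_from_receptor_has_zero_energy(model):
    pose = single_atom_pose("C", (100.0, 0.0, 0.0))
    site = single_atom_site("C", (0.0, 0.0, 0.0))
    x = pose.ligand.coords
    core_ref = x.copy()
    bond_ref = np.array([])
    e, grad, breakdown = energy(pose, site, model, core_ref, bond_ref)
    assert e == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(grad, 0.0)


class TestRestraintFlatBottom:
    def test_zero_inside_flat_bottom(self, model):
        assert restraint_energy(0.0, model) == 0.0
        assert restraint_energy(0.5, model) == 0.0

    def test_quadratic_beyond(self, model):
        assert restraint_energy(1.0, model) == pytest.approx(model.restraint_k * 0.25)
        assert restraint_energy(0.7, model) == pytest.approx(model.restraint_k * 0.04)

    @pytest.mark.parametrize("disp,expected_factor", [(0.5, 0.0), (1.0, 0.25)])
    def test_full_energy_term_matches(self, model, disp, expected_factor):
        pose = single_atom_pose("C", (disp, 0.0, 0.0))
        site = single_atom_site("C", (100.0, 0.0, 0.0))
        core_ref = np.zeros((1, 3))
        e, _, breakdown = energy(pose, site, model, core_ref, np.array([]))
        assert breakdown["restraint"] == pytest.approx(
            model.restraint_k * expected_factor)


def test_hbond_well_minimum_at_ideal_distance(model):
    # ligand acceptor O vs receptor donor N: pure distance well, min at 2.9 A
    site = single_atom_site("N", (0.0, 0.0, 0.0))

    def e_at(d):
        pose = single_atom_pose("O", (d, 0.0, 0.0))
        e, _, bd = energy(pose, site, model)
        return bd["hbond"]

    e_ideal = e_at(model.hbond_ideal)
    assert e_ideal == pytest.approx(-model.hbond_weight)
    assert e_at(model.hbond_ideal - 0.2) > e_ideal
    assert e_at(model.hbond_ideal + 0.2) > e_ideal
    # stationary point: central difference of the well vanishes at the minimum
    h = 1e-5
    assert (e_at(model.hbond_ideal + h) - e_at(model.hbond_ideal - h)) / (2 * h) \
        == pytest.approx(0.0, abs=1e-6)


def test_angular_factor_gates_hbond(model):
    # donor N-H pointing away from the acceptor: angle < 120 deg, no well
    site = single_atom_site("O", (2.9, 0.0, 0.0))
    lig_toward = Molecule([atom(0, "N", [0, 0, 0]), atom(1, "H", [1.0, 0, 0]),
                           atom(2, "C", [-0.7, 1.2, 0], h=3)],
                          [(0, 1, 1.0), (0, 2, 1.0)])
    lig_away = Molecule([atom(0, "N", [0, 0, 0]), atom(1, "H", [-1.0, 0, 0]),
                         atom(2, "C", [0.7, 1.2, 0], h=3)],
                        [(0, 1, 1.0), (0, 2, 1.0)])
    e_toward = energy(Pose(lig_toward, frozenset()), site, model)[2]["hbond"]
    e_away = energy(Pose(lig_away, frozenset()), site, model)[2]["hbond"]
    assert e_toward < -0.5 * model.hbond_weight
    assert e_away == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_gradient_matches_finite_differences(seed, model):
    """Analytic gradient vs central differences on random grown poses."""
    rng = np.random.default_rng(seed)
    case = plant_case(FixtureSpec(seed=seed % 4))
    frag = ["propyl", "hydroxyethyl", "aminoethyl"][seed % 3]
    pose = enumerate_attachments(case.core, make_fragment(frag))[seed % 5]
    x0 = pose.ligand.coords + rng.normal(0, 0.05, size=(len(pose.ligand.atoms), 3))
    core_ref = np.array([pose.ligand.coords[i] for i in pose.core_atom_indices])
    bond_ref = np.array([np.linalg.norm(x0[i] - x0[j]) + 0.05
                         for i, j, _ in pose.ligand.bonds])
    site = case.growing_site
    _, grad, _ = energy(pose, site, model, core_ref, bond_ref, coords=x0)
    h = 1e-5
    for _ in range(5):
        i = int(rng.integers(len(pose.ligand.atoms)))
        k = int(rng.integers(3))
        xp, xm = x0.copy(), x0.copy()
        xp[i, k] += h
        xm[i, k] -= h
        ep = energy(pose, site, model, core_ref, bond_ref, coords=xp)[0]
        em = energy(pose, site, model, core_ref, bond_ref, coords=xm)[0]
        fd = (ep - em) / (2 * h)
        denom = max(abs(fd), abs(grad[i, k]), 1e-8)
        assert abs(fd - grad[i, k]) / denom < 1e-4


def test_angular_gradient_finite_difference(model):
    """FD check through the explicit-H angular factor of the H-bond well."""
    rng = np.random.default_rng(42)
    lig = Molecule([atom(0, "N", [0, 0, 0]), atom(1, "H", [0.9, 0.3, 0.1]),
                    atom(2, "C", [-0.7, 1.2, 0], h=3)],
                   [(0, 1, 1.0), (0, 2, 1.0)])
    pose = Pose(lig, frozenset())
    site = single_atom_site("O", (2.8, 0.4, -0.2))
    x0 = lig.coords
    _, grad, _ = energy(pose, site, model, coords=x0)
    h = 1e-6
    for i in range(3):
        for k in range(3):
            xp, xm = x0.copy(), x0.copy()
            xp[i, k] += h
            xm[i, k] -= h
            fd = (energy(pose, site, model, coords=xp)[0]
                  - energy(pose, site, model, coords=xm)[0]) / (2 * h)
            denom = max(abs(fd), abs(grad[i, k]), 1e-8)
            assert abs(fd - grad[i, k]) / denom < 1e-4


class TestOptimizePose:
    def test_already_at_minimum_stays_put(self, model):
        pose = single_atom_pose("C", (100.0, 0.0, 0.0))
        site = single_atom_site("C", (0.0, 0.0, 0.0))
        opt, summary = optimize_pose(pose, site, model)
        assert summary.iterations <= 1
        assert np.allclose(opt.ligand.coords, pose.ligand.coords, atol=1e-4)

    def test_penetration_resolved(self, model):
        # fragment atom 0.3 A inside the receptor vdW surface pushes out
        mol = Molecule([atom(0, "C", [1.70 + 1.70 - 0.3, 0.0, 0.0])])
        pose = Pose(mol, frozenset({0}))  # all-fragment: no restraint
        site = single_atom_site("C", (0.0, 0.0, 0.0))
        opt, summary = optimize_pose(pose, site, model, max_iter=2000)
        d = np.linalg.norm(opt.ligand.atoms[0].position)
        assert 1.70 + 1.70 - d <= 0.01  # residual penetration
        assert summary.e_end <= summary.e_start

    def test_monotone_energy_and_step_cap(self, model, planted):
        case = planted(7)
        hits = grow(case.core, case.growing_site, [case.target_fragment])
        opt, summary = optimize_pose(hits.poses[0], case.growing_site, model)
        assert summary.e_end <= summary.e_start
        assert summary.converged

    def test_core_dragged_by_deep_well_stays_restrained(self):
        # a strong attractive well 2 A from the core atom: the restraint
        # must balance the pull before the atom reaches the well center
        model = EnergyModel(hydrophobic_weight=20.0, hydrophobic_ideal=0.0,
                            hydrophobic_width=1.0)
        pose = single_atom_pose("C", (0.0, 0.0, 0.0))
        site = single_atom_site("C", (2.0, 0.0, 0.0))
        # disable clash so only well vs restraint compete
        model.clash_weight = 0.0
        opt, summary = optimize_pose(pose, site, model, max_iter=2000)
        disp = float(np.linalg.norm(opt.ligand.atoms[0].position))
        assert 0.5 < disp < 2.0
        # force balance at the fixed point: restraint gradient equals well pull
        x = disp
        well_force = model.hydrophobic_weight * (2.0 - x) / model.hydrophobic_width**2 \
            * np.exp(-((2.0 - x) ** 2) / (2 * model.hydrophobic_width**2))
        restraint_force = 2 * model.restraint_k * (x - model.restraint_flat_bottom)
        assert restraint_force == pytest.approx(well_force, rel=0.05)

    def test_restraint_efficacy_across_fixture_suite(self, model):
        """95th percentile of core RMSD after optimization stays small."""
        core_rmsds = []
        for seed in range(12):
            case = plant_case(FixtureSpec(seed=seed))
            hits = grow(case.core, case.growing_site, [case.target_fragment])
            pose = hits.poses[0]
            ref = np.array([pose.ligand.coords[i] for i in pose.core_atom_indices])
            opt, _ = optimize_pose(pose, case.growing_site, model)
            now = np.array([opt.ligand.coords[i] for i in opt.core_atom_indices])
            core_rmsds.append(float(np.sqrt(np.mean(np.sum((now - ref) ** 2, axis=1)))))
        assert np.percentile(core_rmsds, 95) <= 0.6
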