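"""Restrained gradient optimization of grown poses.

The energy is a small empirical interaction score in the tradition of
ChemScore/PLANTS-style functions: quadratic clash repulsion, Gaussian
hydrogen-bond and hydrophobic-contact wells, a harmonic bond-length term
that preserves the input covalent geometry, and a flat-bottom quadratic
restraint that lets core atoms drift up to 0.5 A for free and penalizes
anything beyond.  Optimization is plain steepest descent with a hard cap on
the per-atom step, which keeps the geometry changes small and the outcome
deterministic.  Receptor atoms never move.

Paper-anchored behaviors: the 0.5 A flat-bottom core restraint and the
limited-step-length philosophy.  The well depths and widths are this
package's own parameterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem_io import BindingSite
from .config import GrowConfig
from .growing import Pose
from .pharmacophore import HYDROPHOBIC_ELEMENTS, acceptor_atoms, donor_atoms

log = logging.getLogger(__name__)


@dataclass
class EnergyModel:
    """Parameters of the empirical interaction score (units: score, Angstrom).

    ``restraint_flat_bottom`` and the limited-step optimizer contract are the
    fixed behavioral anchors; every well parameter is tunable.
    """

    clash_weight: float = 5.0
    hbond_ideal: float = 2.9
    hbond_width: float = 0.4
    hbond_weight: float = 2.0
    hydrophobic_ideal: float = 3.9
    hydrophobic_width: float = 0.6
    # per-pair contact wells accumulate over many receptor neighbors (tens of
    # pairs per atom in a closed pocket); the depth is kept small so their
    # cumulative pull stays well inside the core restraint's elastic range
    hydrophobic_weight: float = 0.05
    restraint_flat_bottom: float = 0.5
    restraint_k: float = 10.0
    bond_weight: float = 50.0

    def __post_init__(self) -> None:
        if self.hbond_width <= 0 or self.hydrophobic_width <= 0:
            raise ValueError("well widths must be positive")
        if self.restraint_flat_bottom < 0:
            raise ValueError("flat bottom must be non-negative")


@dataclass
class OptimizationSummary:
    e_start: float
    e_end: float
    iterations: int
    converged: bool
    error: bool = False


def _gaussian_well(d: np.ndarray, ideal: float, width: float):
    """Well value G(d) = exp(-(d-ideal)^2 / (2 width^2)) and dG/dd."""
    delta = d - ideal
    val = np.exp(-(delta**2) / (2.0 * width**2))
    return val, -delta / width**2 * val


def energy(pose: Pose, site: BindingSite, model: EnergyModel,
           core_ref: np.ndarray | None = None,
           bond_ref: np.ndarray | None = None,
           coords: np.ndarray | None = None):
    """Energy and analytic per-atom gradient of a pose.

    ``core_ref`` holds the input positions of the core atoms (restraint
    reference); ``bond_ref`` the input bond lengths.  When either is omitted
    the corresponding term is evaluated against the current geometry and
    contributes zero.  Returns ``(E, gradient, breakdown)`` with the
    gradient shaped (n_ligand_atoms, 3).
    """
    lig = pose.ligand
    x = lig.coords if coords is None else np.asarray(coords, dtype=float)
    n = len(lig.atoms)
    grad = np.zeros((n, 3))
    breakdown = {"clash": 0.0, "hbond": 0.0, "hydrophobic": 0.0,
                 "restraint": 0.0, "bond": 0.0}

    rec_heavy = [a for a in site.receptor.atoms if a.element != "H"]
    rec_xyz = np.array([a.position for a in rec_heavy]).reshape(-1, 3)
    rec_rad = np.array([a.vdw_radius for a in rec_heavy])

    lig_heavy = [a.index for a in lig.atoms if a.element != "H"]

    # --- clash: quadratic in penetration beyond vdW contact ---------------
    if rec_xyz.size and lig_heavy:
        li = np.array(lig_heavy)
        diff = x[li][:, None, :] - rec_xyz[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        rsum = np.array([lig.atoms[i].vdw_radius for i in lig_heavy])[:, None] + rec_rad[None, :]
        pen = np.maximum(0.0, rsum - d)
        breakdown["clash"] = float(model.clash_weight * np.sum(pen**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(d[..., None] > 1e-9, diff / d[..., None], 0.0)
        g = (-2.0 * model.clash_weight * pen)[..., None] * unit
        np.add.at(grad, li, g.sum(axis=1))

    # --- hydrogen bonds ---------------------------------------------------
    rec_acc = np.array([a.position for a in rec_heavy
                        if a.element in ("N", "O")]).reshape(-1, 3)
    rec_don = np.array([a.position for a in rec_heavy
                        if a.element == "N"]).reshape(-1, 3)

    def add_distance_well(i: int, targets: np.ndarray, ideal: float,
                          width: float, weight: float, key: str,
                          angular=None) -> None:
        if targets.size == 0:
            return
        diff = x[i] - targets
        d = np.linalg.norm(diff, axis=1)
        val, dval = _gaussian_well(d, ideal, width)
        if angular is not None:
            ang, ang_grads = angular
            val_term = -weight * float(np.sum(val * ang))
            breakdown[key] += val_term
            for k in range(len(targets)):
                if d[k] > 1e-9:
                    grad[i] += -weight * dval[k] * ang[k] * diff[k] / d[k]
                for atom_idx, gvec in ang_grads[k]:
                    grad[atom_idx] += -weight * val[k] * gvec
        else:
            breakdown[key] += -weight * float(np.sum(val))
            for k in range(len(targets)):
                if d[k] > 1e-9:
                    grad[i] += -weight * dval[k] * diff[k] / d[k]

    for i in donor_atoms(lig):
        h_atoms = lig.explicit_hydrogens(i)
        if rec_acc.size == 0:
            break
        if not h_atoms:
            # implicit hydrogens: distance well only
            add_distance_well(i, rec_acc, model.hbond_ideal, model.hbond_width,
                              model.hbond_weight, "hbond")
            continue
        ang_vals = np.zeros(len(rec_acc))
        ang_grads: list[list[tuple[int, np.ndarray]]] = [[] for _ in rec_acc]
        for k, a_pos in enumerate(rec_acc):
            best_g, best = -1.0, None
            for h in h_atoms:
                u = x[i] - x[h]
                v = a_pos - x[h]
                nu, nv = np.linalg.norm(u), np.linalg.norm(v)
                if nu < 1e-9 or nv < 1e-9:
                    continue
                c = float(np.dot(u, v) / (nu * nv))
                g_ang = -1.0 - 2.0 * c  # 0 at 120 deg, 1 at 180 deg
                if g_ang > best_g:
                    best_g, best = g_ang, (h, u, v, nu, nv, c)
            if best is None:
                continue
            h, u, v, nu, nv, c = best
            if best_g <= 0.0:
                ang_vals[k] = 0.0
            elif best_g >= 1.0:
                ang_vals[k] = 1.0
            else:
                ang_vals[k] = best_g
                dc_du = v / (nu * nv) - c * u / nu**2
                dc_dv = u / (nu * nv) - c * v / nv**2
                # dg/dc = -2 inside the ramp
                ang_grads[k].append((i, -2.0 * dc_du))
                ang_grads[k].append((h, -2.0 * (-dc_du - dc_dv)))
        add_distance_well(i, rec_acc, model.hbond_ideal, model.hbond_width,
                          model.hbond_weight, "hbond",
                          angular=(ang_vals, ang_grads))

    for i in acceptor_atoms(lig):
        if rec_don.size == 0:
            break
        add_distance_well(i, rec_don, model.hbond_ideal, model.hbond_width,
                          model.hbond_weight, "hbond")

    # --- hydrophobic contacts --------------------------------------------
    rec_cs = np.array([a.position for a in rec_heavy
                       if a.element in HYDROPHOBIC_ELEMENTS]).reshape(-1, 3)
    if rec_cs.size:
        for i in lig_heavy:
            if lig.atoms[i].element not in HYDROPHOBIC_ELEMENTS:
                continue
            add_distance_well(i, rec_cs, model.hydrophobic_ideal,
                              model.hydrophobic_width,
                              model.hydrophobic_weight, "hydrophobic")

    # --- flat-bottom core restraint --------------------------------------
    if core_ref is not None:
        core_idx = pose.core_atom_indices
        for ci, ref in zip(core_idx, core_ref):
            delta = x[ci] - ref
            disp = float(np.linalg.norm(delta))
            excess = disp - model.restraint_flat_bottom
            if excess > 0.0:
                breakdown["restraint"] += model.restraint_k * excess**2
                grad[ci] += 2.0 * model.restraint_k * excess * delta / disp

    # --- covalent geometry maintenance ------------------------------------
    if bond_ref is not None:
        for (i, j, _), d_ref in zip(lig.bonds, bond_ref):
            diff = x[i] - x[j]
            d = float(np.linalg.norm(diff))
            if d < 1e-9:
                continue
            delta = d - d_ref
            breakdown["bond"] += model.bond_weight * delta**2
            g = 2.0 * model.bond_weight * delta * diff / d
            grad[i] += g
            grad[j] -= g

    total = float(sum(breakdown.values()))
    return total, grad, breakdown


def restraint_energy(displacement: float, model: EnergyModel) -> float:
    """Flat-bottom core restraint for a single atom displaced by ``displacement``."""
    excess = displacement - model.restraint_flat_bottom
    return model.restraint_k * excess**2 if excess > 0 else 0.0


def optimize_pose(pose: Pose, site: BindingSite, model: EnergyModel,
                  max_step: float = 0.1, max_iter: int = 500,
                  e_tol: float = 1e-4) -> tuple[Pose, OptimizationSummary]:
    """Steepest-descent optimization with a per-atom step cap.

    The descent step is scaled so that no atom moves more than ``max_step``
    per iteration; a step that raises the energy is halved up to 10 times
    before the run stops.  Energy is therefore non-increasing over accepted
    steps.  Core positions at entry define the restraint reference; input
    bond lengths define the covalent reference.
    """
    lig = pose.ligand
    x = lig.coords.copy()
    core_ref = np.array([x[i] for i in pose.core_atom_indices]).reshape(-1, 3)
    bond_ref = np.array([np.linalg.norm(x[i] - x[j]) for i, j, _ in lig.bonds])

    e_curr, grad, _ = energy(pose, site, model, core_ref, bond_ref, coords=x)
    if not np.isfinite(e_curr):
        log.error("non-finite starting energy; pose returned unmodified")
        return pose, OptimizationSummary(e_curr, e_curr, 0, False, error=True)

    e_start = e_curr
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        gnorm = np.linalg.norm(grad, axis=1)
        gmax = float(gnorm.max())
        if gmax < 1e-12:
            converged = True
            break
        scale = max_step / gmax
        accepted = False
        for _ in range(11):  # initial step + up to 10 halvings
            step = -grad * scale
            assert np.linalg.norm(step, axis=1).max() <= max_step + 1e-12
            x_new = x + step
            e_new, grad_new, _ = energy(pose, site, model, core_ref, bond_ref,
                                        coords=x_new)
            if e_new <= e_curr:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            converged = True
            break
        delta_e = e_curr - e_new
        x, e_curr, grad = x_new, e_new, grad_new
        if delta_e < e_tol:
            converged = True
            break

    optimized = Pose(lig.set_coords(x), pose.fragment_atom_indices,
                     pose.score_breakdown, pose.frame_id, pose.fragment_id)
    return optimized, OptimizationSummary(e_start, e_curr, iterations, converged)
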