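"""Pose generation and ranking for fragment growing.

A fragment is attached to the core's open valence by a new single bond,
its torsion about that bond is sampled on a fixed grid, and every candidate
pose is scored against the pocket shape descriptor plus a close-contact
bonus.  Poses that bury a fragment atom deep inside a receptor atom are
rejected outright; everything else is kept -- pose generation is
deliberately clash tolerant and leaves fine repairs to the optimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .chem_io import Atom, BindingSite, CoreAnchor, Molecule, new_bond_length
from .config import GrowConfig
from .errors import InputError, ValenceError
from .pharmacophore import SearchPoint, match_pose, vdw_overlap_pct
from .shape import RayDescriptor, ScoreBreakdown, cast_fragment, cast_pocket, shape_score

log = logging.getLogger(__name__)


@dataclass
class Pose:
    """A grown ligand (core + fragment) with provenance and score terms."""

    ligand: Molecule
    fragment_atom_indices: frozenset[int]
    score_breakdown: ScoreBreakdown | None = None
    frame_id: str = ""
    fragment_id: str = ""

    @property
    def fragment_heavy_indices(self) -> list[int]:
        return [i for i in sorted(self.fragment_atom_indices)
                if self.ligand.atoms[i].element != "H"]

    @property
    def core_atom_indices(self) -> list[int]:
        frag = self.fragment_atom_indices
        return [a.index for a in self.ligand.atoms if a.index not in frag]


@dataclass
class HitList:
    """Poses in descending combined-score order (ties: fragment_id)."""

    poses: list[Pose] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def fragment_ids(self) -> list[str]:
        return [p.fragment_id for p in self.poses]


# ---------------------------------------------------------------------------
# Attachment enumeration
# ---------------------------------------------------------------------------

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector ``a`` onto unit vector ``b``."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    cross = np.cross(a, b)
    dot = float(np.dot(a, b))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = cross / np.linalg.norm(cross)
    angle = np.arccos(np.clip(dot, -1.0, 1.0))
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _fragment_attachment(fragment: Molecule,
                         attachment_atom: int | None = None
                         ) -> tuple[Molecule, int, np.ndarray, bool]:
    """Pick the fragment-side attachment atom and its valence direction.

    Returns a fragment copy (explicit H removed if one was consumed), the
    attachment index in that copy, the unit open-valence direction, and
    whether an explicit hydrogen defined it.  The lowest-index heavy atom
    with an open valence is used unless the caller names one; multiple open
    valences are resolved the same way and logged.
    """
    candidates = [i for i in fragment.heavy_indices if fragment.open_valence(i) > 0
                  or fragment.explicit_hydrogens(i)]
    if attachment_atom is not None:
        if attachment_atom not in candidates:
            raise ValenceError(f"named attachment atom {attachment_atom} has no open valence")
        chosen = attachment_atom
    else:
        if not candidates:
            raise ValenceError(f"fragment {fragment.name!r} has no open valence")
        if len(candidates) > 1:
            log.debug("fragment %s has %d open valences; using lowest index",
                      fragment.name, len(candidates))
        chosen = candidates[0]
    from .chem_io import mark_core  # same geometry rules as core marking

    used_h = bool(fragment.explicit_hydrogens(chosen))
    anchor = mark_core(fragment, chosen)
    return anchor.core, anchor.attachment_atom, anchor.growth_vector, used_h


def _internal_rotatable_bonds(frag: Molecule) -> list[tuple[int, int]]:
    """Acyclic single bonds between heavy atoms with heavy substituents on
    both sides (torsions worth sampling)."""
    g = frag.graph(heavy_only=True)
    bridges = set()
    for u, v in nx.bridges(g):
        bridges.add((min(u, v), max(u, v)))
    out = []
    for i, j, order in frag.bonds:
        if order != 1.0:
            continue
        if frag.atoms[i].element == "H" or frag.atoms[j].element == "H":
            continue
        key = (min(i, j), max(i, j))
        if key not in bridges:
            continue  # ring bond
        heavy_i = [n for n in frag.neighbors(i) if frag.atoms[n].element != "H" and n != j]
        heavy_j = [n for n in frag.neighbors(j) if frag.atoms[n].element != "H" and n != i]
        if heavy_i and heavy_j:
            out.append(key)
    return out


def _rotate_about_bond(coords: np.ndarray, frag: Molecule, bond: tuple[int, int],
                       angle_rad: float, anchor_side: int) -> np.ndarray:
    """Rotate the part of the fragment distal to ``anchor_side`` about the bond."""
    i, j = bond
    g = frag.graph()
    g.remove_edge(i, j)
    comp_j = nx.node_connected_component(g, j)
    if anchor_side in comp_j:
        i, j = j, i
        comp_j = nx.node_connected_component(g, j)
    axis = coords[j] - coords[i]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return coords
    rot = Rotation.from_rotvec(angle_rad * axis / norm).as_matrix()
    out = coords.copy()
    moving = sorted(comp_j)
    out[moving] = (coords[moving] - coords[j]) @ rot.T + coords[j]
    return out


def _assemble(anchor: CoreAnchor, frag: Molecule, frag_att: int,
              frag_coords: np.ndarray, fragment_id: str) -> Pose:
    """Join core and a posed fragment into one ligand molecule."""
    n_core = len(anchor.core.atoms)
    atoms = [replace(a) for a in anchor.core.atoms]
    for a in frag.atoms:
        atoms.append(Atom(n_core + a.index, a.element, frag_coords[a.index],
                          vdw_radius=a.vdw_radius, formal_charge=a.formal_charge,
                          attached_hydrogens=a.attached_hydrogens))
    bonds = list(anchor.core.bonds)
    bonds.append((anchor.attachment_atom, n_core + frag_att, 1.0))
    bonds.extend((n_core + i, n_core + j, o) for i, j, o in frag.bonds)
    ligand = Molecule(atoms, bonds, name=fragment_id)
    return Pose(ligand, frozenset(range(n_core, n_core + len(frag.atoms))),
                fragment_id=fragment_id)


def enumerate_attachments(anchor: CoreAnchor, fragment: Molecule,
                          config: GrowConfig | None = None,
                          attachment_atom: int | None = None,
                          sample_internal: bool = True) -> list[Pose]:
    """Enumerate unscored candidate poses of ``fragment`` grown on ``anchor``.

    The new bond takes its length from covalent radii; the torsion about it
    is sampled on a fixed grid, optionally combined with a coarse scan of
    acyclic torsions inside the fragment.  Near-duplicate geometries (below
    ``config.dedup_rmsd`` on fragment heavy atoms) are merged and the total
    is capped at ``config.max_poses``.
    """
    config = config or GrowConfig()
    frag, frag_att, v_frag, used_h = _fragment_attachment(fragment, attachment_atom)
    g = anchor.growth_vector
    bond_len = new_bond_length(anchor.core.atoms[anchor.attachment_atom].element,
                               frag.atoms[frag_att].element)
    target = anchor.attachment_point + bond_len * g

    base = frag.coords
    rot0 = _rotation_between(v_frag, -g)
    placed = (base - base[frag_att]) @ rot0.T + target

    # With one neighbor and no explicit H the idealized valence direction is
    # anti-bond, which would make the junction linear; tilt to the idealized
    # tetrahedral (sp3) or trigonal (unsaturated) angle.  The torsion scan
    # below sweeps the azimuth, so the tilt-axis choice only shifts phase.
    neighbors = frag.neighbors(frag_att)
    if not used_h and len(neighbors) == 1:
        saturated = all(o == 1.0 for i, j, o in frag.bonds if frag_att in (i, j))
        ideal = np.arccos(-1.0 / 3.0) if saturated else np.deg2rad(120.0)
        tilt = np.pi - ideal
        perp = np.array([0.0, 0.0, 1.0])
        if abs(g[2]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(g, perp)
        axis /= np.linalg.norm(axis)
        rot_t = Rotation.from_rotvec(tilt * axis).as_matrix()
        placed = (placed - target) @ rot_t.T + target

    internal_bonds = _internal_rotatable_bonds(frag) if sample_internal else []
    internal_bonds = internal_bonds[:2]  # combinatorics guard
    internal_angles = np.deg2rad(
        np.arange(0.0, 360.0, config.internal_torsion_step_deg))

    torsions = np.deg2rad(np.arange(0.0, 360.0, config.torsion_step_deg))

    variants = [placed]
    for bond in internal_bonds:
        new_variants = []
        for coords in variants:
            for ang in internal_angles:
                new_variants.append(
                    _rotate_about_bond(coords, frag, bond, ang, frag_att))
        variants = new_variants

    poses: list[Pose] = []
    kept_frag_coords: list[np.ndarray] = []
    heavy = [i for i in range(len(frag.atoms)) if frag.atoms[i].element != "H"]
    truncated = False
    for coords in variants:
        for ang in torsions:
            rot = Rotation.from_rotvec(ang * g).as_matrix()
            posed = (coords - target) @ rot.T + target
            hv = posed[heavy]
            dup = any(
                np.sqrt(np.mean(np.sum((hv - prev) ** 2, axis=1))) < config.dedup_rmsd
                for prev in kept_frag_coords
            )
            if dup:
                continue
            if len(poses) >= config.max_poses:
                truncated = True
                break
            kept_frag_coords.append(hv)
            poses.append(_assemble(anchor, frag, frag_att, posed,
                                   fragment_id=fragment.name))
        if truncated:
            break
    if truncated:
        log.warning("pose enumeration for %s truncated at max_poses=%d",
                    fragment.name, config.max_poses)
    return poses


# ---------------------------------------------------------------------------
# Scoring terms and filters
# ---------------------------------------------------------------------------

def close_contacts(pose: Pose, site: BindingSite,
                   config: GrowConfig | None = None) -> int:
    """Count fragment/receptor heavy-atom pairs in the contact window."""
    config = config or GrowConfig()
    lo, hi = config.contact_range
    frag_xyz = np.array([pose.ligand.atoms[i].position
                         for i in pose.fragment_heavy_indices]).reshape(-1, 3)
    rec = [a for a in site.receptor.atoms if a.element != "H"]
    if frag_xyz.size == 0 or not rec:
        return 0
    rec_xyz = np.array([a.position for a in rec])
    d = np.linalg.norm(frag_xyz[:, None, :] - rec_xyz[None, :, :], axis=2)
    return int(np.sum((d >= lo) & (d <= hi)))


def hard_clash(pose: Pose, site: BindingSite,
               config: GrowConfig | None = None) -> bool:
    """True if any fragment heavy atom penetrates a receptor heavy atom
    beyond the vdW-overlap threshold."""
    config = config or GrowConfig()
    frag_atoms = [pose.ligand.atoms[i] for i in pose.fragment_heavy_indices]
    rec = [a for a in site.receptor.atoms if a.element != "H"]
    if not frag_atoms or not rec:
        return False
    fx = np.array([a.position for a in frag_atoms])
    fr = np.array([a.vdw_radius for a in frag_atoms])
    rx = np.array([a.position for a in rec])
    rr = np.array([a.vdw_radius for a in rec])
    d = np.linalg.norm(fx[:, None, :] - rx[None, :, :], axis=2)
    pct = vdw_overlap_pct(d, fr[:, None], rr[None, :], metric=config.overlap_metric)
    return bool(np.any(pct > config.overlap_threshold_pct))


# ---------------------------------------------------------------------------
# Growing
# ---------------------------------------------------------------------------

def grow(anchor: CoreAnchor, site: BindingSite, fragment_library: list[Molecule],
         search_points: list[SearchPoint] | None = None,
         config: GrowConfig | None = None,
         pocket: RayDescriptor | None = None) -> HitList:
    """Grow every library fragment on the anchor and rank the survivors.

    Per fragment: enumerate candidate poses, reject hard clashes, reject
    poses that do not satisfy every search point, score the rest and keep
    the ``top_k`` best.  Records sharing a name are treated as conformers of
    one fragment.  Fragments with no surviving pose are excluded and counted
    in the summary.
    """
    config = config or GrowConfig()
    if not fragment_library:
        raise InputError("fragment library is empty")

    if pocket is None:
        pocket = cast_pocket(site, anchor, config)

    groups: dict[str, list[Molecule]] = {}
    for k, frag in enumerate(fragment_library):
        fid = frag.name or f"frag{k}"
        groups.setdefault(fid, []).append(frag)

    best: dict[str, list[Pose]] = {}
    filtered: list[str] = []
    for fid in sorted(groups):
        conformers = groups[fid]
        survivors: list[Pose] = []
        for conf in conformers:
            try:
                candidates = enumerate_attachments(
                    anchor, conf, config,
                    sample_internal=(len(conformers) == 1))
            except ValenceError as exc:
                log.warning("fragment %s skipped: %s", fid, exc)
                continue
            for pose in candidates:
                if hard_clash(pose, site, config):
                    continue
                if search_points:
                    ok, _ = match_pose(pose, search_points, config)
                    if not ok:
                        continue
                frag_mol = Molecule(
                    [pose.ligand.atoms[i] for i in sorted(pose.fragment_atom_indices)])
                desc = cast_fragment(frag_mol, pocket.origin, pocket.directions, config)
                contacts = close_contacts(pose, site, config)
                pose.score_breakdown = shape_score(pocket, desc, config, contacts)
                pose.frame_id = site.frame_id
                pose.fragment_id = fid
                survivors.append(pose)
        if not survivors:
            filtered.append(fid)
            continue
        survivors.sort(key=lambda p: -p.score_breakdown.combined)
        best[fid] = survivors[: config.top_k]

    poses = [p for fid in best for p in best[fid]]
    poses.sort(key=lambda p: (-p.score_breakdown.combined, p.fragment_id))
    if not poses:
        log.warning("all %d fragments were filtered out", len(groups))
    return HitList(poses, summary={
        "n_fragments": len(groups),
        "n_hits": len(best),
        "n_filtered": len(filtered),
        "filtered_ids": filtered,
    })
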