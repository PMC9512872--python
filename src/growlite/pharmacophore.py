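"""Typed pharmacophore search points and constraint matching.

Search points abstract protein-ligand interactions as typed points (donor,
acceptor, hydrophobic) with a tolerance radius, placed on the ligand side of
the interaction.  They are generated from protein-ligand geometry, from
crystallographic waters displaced by a ligand, or supplied by the user, and
act as hard filters during growing: a pose survives only if every point is
matched by a compatible ligand feature within its tolerance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np

from .chem_io import BindingSite, Molecule
from .config import GrowConfig

if TYPE_CHECKING:  # pragma: no cover - type-only import avoids a cycle
    from .growing import Pose

log = logging.getLogger(__name__)

POINT_TYPES = ("donor", "acceptor", "hydrophobic")
HYDROPHOBIC_ELEMENTS = {"C", "S"}


@dataclass
class SearchPoint:
    """A typed interaction constraint with a tolerance radius (Angstrom)."""

    type: str
    position: np.ndarray
    tolerance: float = 2.0
    source: str = "user"

    def __post_init__(self) -> None:
        if self.type not in POINT_TYPES:
            raise ValueError(f"unknown search point type {self.type!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        self.position = np.asarray(self.position, dtype=float)


def load_search_points(path: str) -> list[SearchPoint]:
    """Read search points from a JSON list of {type, x, y, z, tolerance}."""
    with open(path) as fh:
        records = json.load(fh)
    return [
        SearchPoint(r["type"], np.array([r["x"], r["y"], r["z"]]),
                    float(r.get("tolerance", 2.0)), source=r.get("source", "user"))
        for r in records
    ]


def save_search_points(points: list[SearchPoint], path: str) -> None:
    records = [
        {"type": p.type, "x": float(p.position[0]), "y": float(p.position[1]),
         "z": float(p.position[2]), "tolerance": p.tolerance, "source": p.source}
        for p in points
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


# ---------------------------------------------------------------------------
# vdW overlap
# ---------------------------------------------------------------------------

def vdw_overlap_pct(d, r1, r2, metric: str = "linear"):
    """Percentage vdW overlap of two spheres at center distance ``d``.

    ``linear`` (default): penetration fraction of the radii sum,
    ``max(0, (r1 + r2 - d) / (r1 + r2)) * 100``.  ``volume``: intersection
    volume of the two spheres as a percentage of the smaller sphere's
    volume.  Works on scalars or broadcastable arrays.
    """
    d = np.asarray(d, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if metric == "linear":
        return np.maximum(0.0, (r1 + r2 - d) / (r1 + r2)) * 100.0
    if metric == "volume":
        rsum = r1 + r2
        rmin = np.minimum(r1, r2)
        v_small = 4.0 / 3.0 * np.pi * rmin**3
        with np.errstate(divide="ignore", invalid="ignore"):
            lens = (np.pi * (rsum - d) ** 2
                    * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
                    / (12 * np.maximum(d, 1e-12)))
        contained = d <= np.abs(r1 - r2)
        inter = np.where(d >= rsum, 0.0, np.where(contained, v_small, lens))
        return np.clip(inter / v_small, 0.0, 1.0) * 100.0
    raise ValueError(f"unknown overlap metric {metric!r}")


# ---------------------------------------------------------------------------
# Ligand feature perception
# ---------------------------------------------------------------------------

def _total_hydrogens(mol: Molecule, i: int) -> int:
    return mol.atoms[i].attached_hydrogens + len(mol.explicit_hydrogens(i))


def donor_atoms(mol: Molecule) -> list[int]:
    """N/O atoms bearing at least one hydrogen."""
    return [i for i in mol.heavy_indices
            if mol.atoms[i].element in ("N", "O") and _total_hydrogens(mol, i) >= 1]


def acceptor_atoms(mol: Molecule) -> list[int]:
    """N/O atoms with an available lone pair.

    Simplified perception: any uncharged/anionic oxygen accepts; a nitrogen
    accepts only when it carries no hydrogen (pyridine-like).  Deliberately
    conservative so that pyrrole-type NH groups count as donors only.
    """
    out = []
    for i in mol.heavy_indices:
        a = mol.atoms[i]
        if a.formal_charge > 0:
            continue
        if a.element == "O":
            out.append(i)
        elif a.element == "N" and _total_hydrogens(mol, i) == 0:
            out.append(i)
    return out


def _idealized_h_direction(mol: Molecule, i: int) -> np.ndarray:
    pos = mol.atoms[i].position
    vecs = []
    for j in mol.neighbors(i):
        v = mol.atoms[j].position - pos
        n = np.linalg.norm(v)
        if n > 1e-8:
            vecs.append(v / n)
    if not vecs:
        return np.array([1.0, 0.0, 0.0])
    mean = -np.sum(vecs, axis=0)
    n = np.linalg.norm(mean)
    return mean / n if n > 1e-8 else np.array([1.0, 0.0, 0.0])


def _dha_angle_ok(mol: Molecule, donor_idx: int, acceptor_pos: np.ndarray,
                  min_angle_deg: float) -> bool:
    """Donor-H...acceptor angle criterion, idealizing H when not explicit."""
    d_pos = mol.atoms[donor_idx].position
    h_positions = [mol.atoms[j].position for j in mol.explicit_hydrogens(donor_idx)]
    if not h_positions:
        h_positions = [d_pos + 1.0 * _idealized_h_direction(mol, donor_idx)]
    for h in h_positions:
        u = d_pos - h
        v = acceptor_pos - h
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-8 or nv < 1e-8:
            continue
        cos_t = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
        if np.degrees(np.arccos(cos_t)) >= min_angle_deg:
            return True
    return False


def hydrophobic_features(mol: Molecule, config: GrowConfig | None = None
                         ) -> list[np.ndarray]:
    """Positions of hydrophobic features of a molecule.

    Default (validation-grade): centroids of fully hydrophobic rings (all
    ring atoms C/S, no polar substituent on any ring atom) and positions of
    terminal hydrophobic heavy atoms whose neighbors are all C/S/H.  The
    permissive mode emits every apolar C/S atom instead.
    """
    config = config or GrowConfig()
    feats: list[np.ndarray] = []
    if config.permissive_hydrophobic:
        for i in mol.heavy_indices:
            a = mol.atoms[i]
            if a.element in HYDROPHOBIC_ELEMENTS and all(
                mol.atoms[j].element in HYDROPHOBIC_ELEMENTS | {"H"}
                for j in mol.neighbors(i)
            ):
                feats.append(a.position.copy())
        return feats
    g = mol.graph(heavy_only=True)
    for ring in nx.cycle_basis(g):
        if not all(mol.atoms[i].element in HYDROPHOBIC_ELEMENTS for i in ring):
            continue
        ring_set = set(ring)
        polar = False
        for i in ring:
            for j in mol.neighbors(i):
                if j in ring_set:
                    continue
                if mol.atoms[j].element not in HYDROPHOBIC_ELEMENTS | {"H"}:
                    polar = True
        if polar:
            continue
        feats.append(np.mean([mol.atoms[i].position for i in ring], axis=0))
    for i in mol.heavy_indices:
        a = mol.atoms[i]
        if a.element not in HYDROPHOBIC_ELEMENTS:
            continue
        heavy_nbrs = [j for j in mol.neighbors(i) if mol.atoms[j].element != "H"]
        if len(heavy_nbrs) != 1:
            continue  # graph-terminal heavy atoms only
        if all(mol.atoms[j].element in HYDROPHOBIC_ELEMENTS | {"H"}
               for j in mol.neighbors(i)):
            feats.append(a.position.copy())
    return feats


def ligand_features(mol: Molecule, config: GrowConfig | None = None
                    ) -> dict[str, list[np.ndarray]]:
    """All typed feature positions of a molecule, keyed by point type."""
    config = config or GrowConfig()
    return {
        "donor": [mol.atoms[i].position.copy() for i in donor_atoms(mol)],
        "acceptor": [mol.atoms[i].position.copy() for i in acceptor_atoms(mol)],
        "hydrophobic": hydrophobic_features(mol, config),
    }


# ---------------------------------------------------------------------------
# Interaction detection against a receptor
# ---------------------------------------------------------------------------

def detect_interactions(site: BindingSite, ligand: Molecule,
                        config: GrowConfig | None = None) -> list[SearchPoint]:
    """Generate search points from protein-ligand interaction geometry.

    Donor points sit on ligand N/O-H groups hydrogen bonding to a receptor
    N/O; acceptor points sit on ligand N/O lone-pair atoms near a receptor
    nitrogen (receptor protons are rarely resolved, so the receptor side of
    an acceptor interaction is distance-gated only); hydrophobic points sit
    on fully hydrophobic ring centroids or terminal hydrophobic atoms with a
    receptor carbon/sulfur in the contact window.  All points are placed on
    the ligand side.
    """
    config = config or GrowConfig()
    lo, hi = config.hbond_dist_range
    points: list[SearchPoint] = []

    rec = site.receptor
    rec_no = [a for a in rec.atoms if a.element in ("N", "O")]
    rec_acceptors = np.array([a.position for a in rec_no]).reshape(-1, 3)
    rec_donors = np.array([a.position for a in rec.atoms
                           if a.element == "N"]).reshape(-1, 3)
    rec_cs = np.array([a.position for a in rec.atoms
                       if a.element in HYDROPHOBIC_ELEMENTS]).reshape(-1, 3)

    for i in donor_atoms(ligand):
        pos = ligand.atoms[i].position
        if rec_acceptors.size == 0:
            break
        dist = np.linalg.norm(rec_acceptors - pos, axis=1)
        for k in np.flatnonzero((dist >= lo) & (dist <= hi)):
            if _dha_angle_ok(ligand, i, rec_acceptors[k], config.hbond_min_angle_deg):
                points.append(SearchPoint("donor", pos.copy(),
                                          config.search_point_tolerance, "ligand"))
                break

    for i in acceptor_atoms(ligand):
        pos = ligand.atoms[i].position
        if rec_donors.size == 0:
            break
        dist = np.linalg.norm(rec_donors - pos, axis=1)
        if np.any((dist >= lo) & (dist <= hi)):
            points.append(SearchPoint("acceptor", pos.copy(),
                                      config.search_point_tolerance, "ligand"))

    f_lo, f_hi = config.hydrophobic_dist_range
    for centroid in hydrophobic_features(ligand, config):
        if rec_cs.size == 0:
            break
        dist = np.linalg.norm(rec_cs - centroid, axis=1)
        if np.any((dist >= f_lo) & (dist <= f_hi)):
            points.append(SearchPoint("hydrophobic", centroid.copy(),
                                      config.search_point_tolerance, "ligand"))
    return points


# ---------------------------------------------------------------------------
# Stability and matching
# ---------------------------------------------------------------------------

def stable_points(points_a: list[SearchPoint], points_b: list[SearchPoint],
                  radius: float = 2.0) -> list[SearchPoint]:
    """Subset of ``points_a`` with a same-type partner in ``points_b``.

    Greedy one-to-one matching by increasing distance; each b-point is used
    at most once, so the matched cardinality is symmetric in the two lists.
    """
    pairs = []
    for ia, pa in enumerate(points_a):
        for ib, pb in enumerate(points_b):
            if pa.type != pb.type:
                continue
            d = float(np.linalg.norm(pa.position - pb.position))
            if d <= radius:
                pairs.append((d, ia, ib))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
    return [points_a[ia] for ia in sorted(used_a)]


def match_pose(pose: "Pose | Molecule", points: list[SearchPoint],
               config: GrowConfig | None = None
               ) -> tuple[bool, list[tuple[int, np.ndarray]]]:
    """Check whether a grown pose satisfies every search point.

    Each point must find a compatible ligand feature (donor point -> donor
    atom, acceptor -> acceptor atom, hydrophobic -> hydrophobic feature)
    within its tolerance radius; one ligand feature may satisfy several
    points.  Returns the pass flag and per-point feature assignments.
    """
    config = config or GrowConfig()
    ligand = getattr(pose, "ligand", pose)
    feats = ligand_features(ligand, config)
    assignments: list[tuple[int, np.ndarray]] = []
    for k, point in enumerate(points):
        candidates = feats.get(point.type, [])
        best = None
        best_d = np.inf
        for fpos in candidates:
            d = float(np.linalg.norm(fpos - point.position))
            if d <= point.tolerance and d < best_d:
                best, best_d = fpos, d
        if best is None:
            return False, []
        assignments.append((k, best))
    return True, assignments


# ---------------------------------------------------------------------------
# Water replacement
# ---------------------------------------------------------------------------

@dataclass
class WaterReplacementResult:
    """Water-derived query points plus the site with those waters removed."""

    points: list[SearchPoint]
    replaced_water_indices: list[int]
    site: BindingSite
    overlaps_pct: dict[int, float] = field(default_factory=dict)


def water_replacement_query(site: BindingSite, ligand_to_grow: Molecule,
                            config: GrowConfig | None = None
                            ) -> WaterReplacementResult:
    """Build a growing query from waters the ligand displaces.

    A water counts as replaced when its vdW overlap with any ligand heavy
    atom exceeds the threshold (default 60 %).  Each replaced water emits
    donor, acceptor and dummy hydrophobic points at its oxygen; only points
    corroborated by a same-type ligand-derived point within the stability
    radius are kept.  Replaced waters are removed from the returned site, as
    they are during growing.
    """
    config = config or GrowConfig()
    if not site.waters:
        log.warning("water replacement query on a site without waters")
        return WaterReplacementResult([], [], site)

    lig_atoms = [a for a in ligand_to_grow.atoms if a.element != "H"]
    lx = np.array([a.position for a in lig_atoms])
    lr = np.array([a.vdw_radius for a in lig_atoms])

    replaced: list[int] = []
    overlaps: dict[int, float] = {}
    candidates: list[SearchPoint] = []
    for k, water in enumerate(site.waters):
        d = np.linalg.norm(lx - water.position, axis=1)
        pct = vdw_overlap_pct(d, lr, water.vdw_radius, metric=config.overlap_metric)
        best = float(np.max(pct))
        overlaps[k] = best
        if best > config.overlap_threshold_pct:
            replaced.append(k)
            for ptype in POINT_TYPES:
                candidates.append(
                    SearchPoint(ptype, water.position.copy(),
                                config.search_point_tolerance, "water"))

    ligand_points = detect_interactions(site, ligand_to_grow, config)
    kept: list[SearchPoint] = []
    for cand in candidates:
        for lp in ligand_points:
            if lp.type != cand.type:
                continue
            if np.linalg.norm(lp.position - cand.position) <= config.stable_point_radius:
                kept.append(cand)
                break
    stripped = site.without_waters(set(replaced))
    return WaterReplacementResult(kept, replaced, stripped, overlaps)
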