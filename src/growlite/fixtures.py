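"""Deterministic synthetic fixtures: pockets, planted growing cases and
labeled enrichment libraries.

The fixtures are geometric rather than chemically realistic.  Their purpose
is to make every stage of the workflow testable against analytic or
exhaustive oracles: a spherical cavity has a known ray profile, a planted
case has a known best pose, and an enrichment library has known labels tied
to shape complementarity.  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem_io import Atom, BindingSite, CoreAnchor, Molecule, mark_core
from .config import GrowConfig, vdw_radius
from .errors import SpecError
from .evaluate import CrossGrowCase
from .growing import enumerate_attachments
from .shape import fibonacci_sphere


@dataclass
class FixtureSpec:
    """Parameters of a synthetic pocket / planted case.

    ``pocket_radius`` is the distance from the cavity center to the wall
    atom centers; rays from the center therefore measure radius minus the
    wall vdW radius.  ``planted_fragment`` names a built-in fragment
    topology.  ``noise_sigma`` jitters the reference coordinates only.
    """

    seed: int = 0
    pocket_kind: str = "spherical"
    pocket_radius: float = 6.0
    wall_spacing: float = 1.5
    planted_fragment: str = "propyl"
    noise_sigma: float = 0.0
    wall_element: str = "C"
    polar_wall: list[tuple[str, float, float]] = field(default_factory=list)
    waters: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Fragment topologies
# ---------------------------------------------------------------------------

_TET = np.arccos(-1.0 / 3.0)  # tetrahedral angle
_CC = 1.54


def _zigzag_chain(elements: list[str]) -> Molecule:
    """Planar zig-zag chain with tetrahedral angles; atom 0 is the
    attachment end."""
    coords = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    sign = 1.0
    for _ in elements[1:]:
        coords.append(coords[-1] + _CC * direction)
        # alternate direction in the xy-plane keeping the tetrahedral angle
        ang = (np.pi - _TET) * sign
        c, s = np.cos(ang), np.sin(ang)
        direction = np.array([c * direction[0] - s * direction[1],
                              s * direction[0] + c * direction[1], 0.0])
        sign = -sign
    atoms = []
    for k, (el, pos) in enumerate(zip(elements, coords)):
        atoms.append(Atom(k, el, pos, vdw_radius=vdw_radius(el)))
    bonds = [(k, k + 1, 1.0) for k in range(len(elements) - 1)]
    mol = Molecule(atoms, bonds)
    _saturate(mol)
    return mol


def _branched(center: str, substituents: list[str]) -> Molecule:
    """A center atom with 1-3 substituents on tetrahedral directions;
    the remaining tetrahedral slot is the attachment valence."""
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                   dtype=float) / np.sqrt(3.0)
    atoms = [Atom(0, center, np.zeros(3), vdw_radius=vdw_radius(center))]
    bonds = []
    for k, el in enumerate(substituents):
        atoms.append(Atom(k + 1, el, _CC * tet[k + 1], vdw_radius=vdw_radius(el)))
        bonds.append((0, k + 1, 1.0))
    mol = Molecule(atoms, bonds)
    _saturate(mol)
    return mol


def _saturate(mol: Molecule) -> None:
    """Fill attached_hydrogens so that standard valences are satisfied."""
    from .chem_io import STANDARD_VALENCE

    for atom in mol.atoms:
        std = STANDARD_VALENCE.get(atom.element, 4)
        atom.attached_hydrogens = max(0, int(std - mol.bond_order_sum(atom.index)))


def make_fragment(name: str) -> Molecule:
    """Built-in fragment topology by name (atom 0 is the attachment end)."""
    builders = {
        "methyl": lambda: _zigzag_chain(["C"]),
        "ethyl": lambda: _zigzag_chain(["C", "C"]),
        "propyl": lambda: _zigzag_chain(["C", "C", "C"]),
        "butyl": lambda: _zigzag_chain(["C", "C", "C", "C"]),
        "hydroxyethyl": lambda: _zigzag_chain(["C", "C", "O"]),
        "aminoethyl": lambda: _zigzag_chain(["C", "C", "N"]),
        "methoxymethyl": lambda: _zigzag_chain(["C", "O", "C"]),
        "isopropyl": lambda: _branched("C", ["C", "C"]),
        "tert-butyl": lambda: _branched("C", ["C", "C", "C"]),
        "thiomethyl": lambda: _zigzag_chain(["C", "S"]),
    }
    if name not in builders:
        raise SpecError(f"unknown fragment {name!r}; choose from {sorted(builders)}")
    mol = builders[name]()
    mol.name = name
    return mol


def make_core() -> CoreAnchor:
    """Two-carbon core with its open valence along +x at the origin."""
    atoms = [
        Atom(0, "C", np.array([-_CC, 0.0, 0.0]), vdw_radius=vdw_radius("C"),
             attached_hydrogens=3),
        Atom(1, "C", np.zeros(3), vdw_radius=vdw_radius("C"),
             attached_hydrogens=3),
    ]
    core = Molecule(atoms, [(0, 1, 1.0)], name="core")
    return mark_core(core, 1)


# ---------------------------------------------------------------------------
# Pockets
# ---------------------------------------------------------------------------

def _shell_points(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    n = max(8, int(np.ceil(4.0 * np.pi * radius**2 / spacing**2)))
    return center + radius * fibonacci_sphere(n)


def make_pocket(spec: FixtureSpec) -> BindingSite:
    """Build a closed synthetic cavity as a shell of wall atoms.

    ``spherical``: one shell centered at the origin.  ``two-lobe``: two
    overlapping shells (ray profile is bimodal from the first center).
    ``channel``: a cylindrical tube along +x with a capped far end.
    """
    if spec.pocket_radius < 2.0:
        raise SpecError("pocket_radius must be at least 2 A")
    r = spec.pocket_radius
    s = spec.wall_spacing
    if spec.pocket_kind == "spherical":
        pts = _shell_points(np.zeros(3), r, s)
    elif spec.pocket_kind == "two-lobe":
        c2 = np.array([1.2 * r, 0.0, 0.0])
        shell1 = _shell_points(np.zeros(3), r, s)
        shell2 = _shell_points(c2, 0.6 * r, s)
        shell1 = shell1[np.linalg.norm(shell1 - c2, axis=1) > 0.6 * r - 1e-9]
        shell2 = shell2[np.linalg.norm(shell2, axis=1) > r - 1e-9]
        pts = np.vstack([shell1, shell2])
    elif spec.pocket_kind == "channel":
        length = 2.0 * r
        n_axial = max(2, int(np.ceil(length / s)))
        n_ring = max(6, int(np.ceil(2.0 * np.pi * r / s)))
        rows = []
        for xk in np.linspace(0.0, length, n_axial):
            for t in np.linspace(0.0, 2.0 * np.pi, n_ring, endpoint=False):
                rows.append([xk, r * np.cos(t), r * np.sin(t)])
        cap = _shell_points(np.array([length, 0.0, 0.0]), r, s)
        cap = cap[cap[:, 0] > length]
        rows.extend(cap.tolist())
        pts = np.array(rows)
    else:
        raise SpecError(f"unknown pocket kind {spec.pocket_kind!r}")

    atoms = [Atom(k, spec.wall_element, p,
                  vdw_radius=vdw_radius(spec.wall_element), residue="WAL")
             for k, p in enumerate(pts)]
    for element, lat_deg, lon_deg in spec.polar_wall:
        lat, lon = np.deg2rad(lat_deg), np.deg2rad(lon_deg)
        target = r * np.array([np.cos(lat) * np.cos(lon),
                               np.cos(lat) * np.sin(lon), np.sin(lat)])
        nearest = int(np.argmin(np.linalg.norm(pts - target, axis=1)))
        atoms[nearest] = replace(atoms[nearest], element=element,
                                 vdw_radius=vdw_radius(element))
    waters = [Atom(k, "O", np.array(w), is_water=True,
                   vdw_radius=vdw_radius("O"), residue="HOH")
              for k, w in enumerate(spec.waters)]
    receptor = Molecule(atoms, [], name=f"{spec.pocket_kind}_pocket")
    return BindingSite(receptor, waters, frame_id=f"fixture_{spec.seed}")


# ---------------------------------------------------------------------------
# Planted cross-growing cases
# ---------------------------------------------------------------------------

#: Wall standoff from ligand heavy atoms when carving a cavity (Angstrom).
CARVE_CLEARANCE = 3.5


def carve_cavity(ligand: Molecule, spacing: float = 1.2,
                 clearance: float = CARVE_CLEARANCE,
                 wall_element: str = "C") -> Molecule:
    """Wall atoms on the union-of-spheres surface around a ligand.

    The cavity hugs the ligand at a fixed standoff, so the carved pose
    maximizes shape complementarity by construction.
    """
    heavy = [a for a in ligand.atoms if a.element != "H"]
    centers = np.array([a.position for a in heavy])
    candidates = []
    for c in centers:
        pts = _shell_points(c, clearance, spacing)
        dmin = np.min(np.linalg.norm(pts[:, None, :] - centers[None, :, :],
                                     axis=2), axis=1)
        candidates.append(pts[dmin > clearance - 1e-6])
    candidates = np.vstack(candidates)
    kept: list[np.ndarray] = []
    for p in candidates:  # thin to roughly uniform spacing
        if all(np.linalg.norm(p - q) >= 0.8 * spacing for q in kept):
            kept.append(p)
    atoms = [Atom(k, wall_element, p, vdw_radius=vdw_radius(wall_element),
                  residue="WAL") for k, p in enumerate(kept)]
    return Molecule(atoms, [], name="carved_pocket")


def plant_case(spec: FixtureSpec, config: GrowConfig | None = None
               ) -> CrossGrowCase:
    """Plant a recoverable cross-growing case.

    The reference ligand is one of the exact poses the torsion grid can
    produce (chosen by the seed), the cavity is carved around it, and the
    reference coordinates are jittered by ``noise_sigma``.  The growing
    inputs carry no reference coordinates, so recovery is a genuine search.
    """
    config = config or GrowConfig()
    anchor = make_core()
    fragment = make_fragment(spec.planted_fragment)
    poses = enumerate_attachments(anchor, fragment, config)
    rng = np.random.default_rng(spec.seed)
    planted = poses[int(rng.integers(len(poses)))]

    extent = max(np.linalg.norm(planted.ligand.atoms[i].position -
                                anchor.attachment_point)
                 for i in planted.fragment_heavy_indices)
    if extent > spec.pocket_radius:
        raise SpecError(
            f"fragment {spec.planted_fragment!r} (extent {extent:.1f} A) "
            f"does not fit a cavity of radius {spec.pocket_radius:.1f} A")

    receptor = carve_cavity(planted.ligand)
    waters = [Atom(k, "O", np.array(w), is_water=True,
                   vdw_radius=vdw_radius("O"), residue="HOH")
              for k, w in enumerate(spec.waters)]
    site = BindingSite(receptor, waters, frame_id=f"planted_{spec.seed}")

    reference = planted.ligand
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=(len(reference.atoms), 3))
        reference = reference.set_coords(reference.coords + noise)
    reference = Molecule(reference.atoms, reference.bonds,
                         name=f"reference_{spec.seed}")
    return CrossGrowCase(site, anchor, fragment, reference,
                         case_id=f"planted_{spec.seed}")


# ---------------------------------------------------------------------------
# Enrichment libraries
# ---------------------------------------------------------------------------

ACTIVE_SHAPES = ["propyl", "butyl", "hydroxyethyl", "aminoethyl", "ethyl"]
DECOY_SHAPES = ["tert-butyl", "isopropyl", "methoxymethyl", "thiomethyl",
                "methyl"]


def make_enrichment_set(seed: int, n_actives: int, n_decoys: int
                        ) -> tuple[list[Molecule], dict[str, int]]:
    """A labeled screening library for a planted elongated cavity.

    Actives are slim, extended fragments that fit the carved channel of the
    default planted case; decoys are branched or truncated shapes with
    similar Rule-of-Three properties but poorer shape complementarity.
    Returns the library and a fragment_id -> label map (1 = active).
    """
    if n_actives < 1:
        raise SpecError("need at least one active")
    rng = np.random.default_rng(seed)
    library: list[Molecule] = []
    labels: dict[str, int] = {}
    for k in range(n_actives):
        shape = ACTIVE_SHAPES[k % len(ACTIVE_SHAPES)]
        mol = make_fragment(shape)
        jitter = rng.normal(0.0, 0.03, size=(len(mol.atoms), 3))
        mol = mol.set_coords(mol.coords + jitter)
        mol = Molecule(mol.atoms, mol.bonds, name=f"active_{k:04d}_{shape}")
        library.append(mol)
        labels[mol.name] = 1
    for k in range(n_decoys):
        shape = DECOY_SHAPES[k % len(DECOY_SHAPES)]
        mol = make_fragment(shape)
        jitter = rng.normal(0.0, 0.03, size=(len(mol.atoms), 3))
        mol = mol.set_coords(mol.coords + jitter)
        mol = Molecule(mol.atoms, mol.bonds, name=f"decoy_{k:04d}_{shape}")
        library.append(mol)
        labels[mol.name] = 0
    return library, labels
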