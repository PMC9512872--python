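"""Ray-length shape descriptor for pockets and fragments.

The descriptor casts a deterministic fan of rays from the attachment point.
For a pocket, each ray reports the distance to the first receptor vdW
surface; for a fragment posed in the same frame, each ray reports the last
exit from the fragment's vdW volume.  Because the two descriptions share the
origin and direction set they can be compared ray-by-ray: overlap of the two
profiles is filled volume, fragment rays exceeding pocket rays are clash.
The descriptor is purely steric; it carries no electrostatic information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem_io import BindingSite, CoreAnchor, Molecule
from .config import GrowConfig
from .errors import ContractError

log = logging.getLogger(__name__)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-angle spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class RayDescriptor:
    """Ray lengths from one origin along a shared direction set."""

    origin: np.ndarray
    directions: np.ndarray
    lengths: np.ndarray
    max_range: float = 10.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.directions.shape[0] != self.lengths.shape[0]:
            raise ValueError("directions and lengths must have equal length")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("directions must be unit vectors")
        if np.any(self.lengths < -1e-9) or np.any(self.lengths > self.max_range + 1e-9):
            raise ValueError("lengths outside [0, max_range]")


def _ray_sphere_roots(origin: np.ndarray, directions: np.ndarray,
                      centers: np.ndarray, radii: np.ndarray):
    """Both intersection parameters for every (ray, sphere) pair.

    Returns (t_near, t_far, hit) arrays of shape (D, N); entries are valid
    only where ``hit`` is True.
    """
    oc = centers[None, :, :] - origin[None, None, :]           # 1 x N x 3
    proj = np.einsum("dk,ank->dn", directions, oc)             # D x N
    d2 = np.sum(oc * oc, axis=2) - proj**2                     # squared miss distance
    disc = radii[None, :] ** 2 - d2
    hit = disc >= 0.0
    sqrt_disc = np.sqrt(np.where(hit, disc, 0.0))
    return proj - sqrt_disc, proj + sqrt_disc, hit


def cast_pocket(site: BindingSite, anchor: CoreAnchor,
                config: GrowConfig | None = None,
                directions: np.ndarray | None = None,
                origin: np.ndarray | None = None) -> RayDescriptor:
    """Cast pocket rays from the anchor's attachment point.

    Rays run against receptor heavy atoms only (waters are ignored) and stop
    at the first vdW-surface crossing; rays that hit nothing report
    ``max_range``.  If no receptor atom lies within range at all an "open
    pocket" warning is logged and the descriptor is all-max.
    """
    config = config or GrowConfig()
    if directions is None:
        directions = fibonacci_sphere(config.n_rays)
    if origin is None:
        origin = anchor.attachment_point
    origin = np.asarray(origin, dtype=float)

    heavy = [a for a in site.receptor.atoms if a.element != "H"]
    if not heavy:
        log.warning("open pocket: no receptor heavy atoms near anchor")
        return RayDescriptor(origin, directions,
                             np.full(len(directions), config.max_range),
                             config.max_range)
    centers = np.array([a.position for a in heavy])
    radii = np.array([a.vdw_radius for a in heavy])
    within = np.linalg.norm(centers - origin, axis=1) <= config.max_range + radii.max()
    if not np.any(within):
        log.warning("open pocket: no receptor heavy atom within max_range")
        return RayDescriptor(origin, directions,
                             np.full(len(directions), config.max_range),
                             config.max_range)
    centers, radii = centers[within], radii[within]

    t_near, t_far, hit = _ray_sphere_roots(origin, directions, centers, radii)
    # first surface crossing with t >= 0 (origin inside a sphere exits at t_far)
    first = np.where(t_near >= 0.0, t_near, np.where(t_far >= 0.0, t_far, np.inf))
    first = np.where(hit, first, np.inf)
    lengths = np.clip(first.min(axis=1), 0.0, config.max_range)
    return RayDescriptor(origin, directions, lengths, config.max_range)


def cast_fragment(frag_pose: Molecule, origin: np.ndarray,
                  directions: np.ndarray,
                  config: GrowConfig | None = None) -> RayDescriptor:
    """Cast fragment rays: distance to the last exit from the vdW volume.

    A ray that never enters the fragment reports 0.
    """
    config = config or GrowConfig()
    directions = np.asarray(directions, dtype=float)
    if directions.size == 0 or np.any(np.linalg.norm(directions, axis=1) < 1e-12):
        raise ContractError("zero-length direction in direction set")
    origin = np.asarray(origin, dtype=float)
    heavy = [a for a in frag_pose.atoms if a.element != "H"]
    if not heavy:
        return RayDescriptor(origin, directions,
                             np.zeros(len(directions)), config.max_range)
    centers = np.array([a.position for a in heavy])
    radii = np.array([a.vdw_radius for a in heavy])
    _, t_far, hit = _ray_sphere_roots(origin, directions, centers, radii)
    exits = np.where(hit & (t_far > 0.0), t_far, 0.0)
    lengths = np.clip(exits.max(axis=1), 0.0, config.max_range)
    return RayDescriptor(origin, directions, lengths, config.max_range)


@dataclass
class ScoreBreakdown:
    """Pose score terms: filled volume proxy, contacts, clash, combined."""

    filled: float
    contacts: int
    clash: float
    combined: float


def shape_score(pocket: RayDescriptor, frag: RayDescriptor,
                config: GrowConfig | None = None,
                contacts: int = 0) -> ScoreBreakdown:
    """Compare two descriptors sharing a direction set.

    filled = sum_d min(frag_d, pocket_d); clash = sum_d of the fragment ray
    excess beyond pocket + tolerance; combined = filled - w_clash * clash
    (+ w_contact * contacts when a contact count is supplied).  Higher is
    better.
    """
    config = config or GrowConfig()
    if pocket.directions.shape != frag.directions.shape or not np.allclose(
        pocket.directions, frag.directions, atol=1e-9
    ):
        raise ContractError("descriptors do not share a direction set")
    filled = float(np.minimum(frag.lengths, pocket.lengths).sum())
    clash = float(
        np.maximum(0.0, frag.lengths - pocket.lengths - config.clash_tolerance).sum()
    )
    combined = filled - config.w_clash * clash + config.w_contact * contacts
    return ScoreBreakdown(filled, contacts, clash, combined)
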