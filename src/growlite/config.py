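"""Central configuration for the growing workflow.

Every numeric knob of the pipeline lives here so that runs are reproducible
and the defaults are visible in one place.  The defaults were chosen once for
desk-scale synthetic benchmarks and are documented in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Element-keyed van der Waals radii in Angstrom (Bondi-style, fixed table).
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.09,
    "P": 1.80,
}

#: Fallback radius for elements missing from the table.
VDW_DEFAULT = 1.70

#: Single-bond covalent radii in Angstrom, used for new attachment bonds.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "Cl": 1.02,
    "Br": 1.20,
}


@dataclass
class GrowConfig:
    """Tunable parameters of pose generation, scoring and filtering.

    Attributes
    ----------
    n_rays:
        Number of ray directions in the shape descriptor (Fibonacci sphere).
    max_range:
        Ray length cap in Angstrom; rays that hit nothing report this value.
    clash_tolerance:
        Slack (Angstrom) a fragment ray may exceed the pocket ray before it
        counts as clash.  Pose generation is deliberately clash tolerant.
    w_clash:
        Weight of the clash term in the combined pose score.
    w_contact:
        Weight of the close-contact count in the combined pose score.
    contact_range:
        (lo, hi) heavy-atom distance window in Angstrom that counts as a
        favourable close contact.
    torsion_step_deg:
        Increment for sampling the torsion about the new attachment bond.
    internal_torsion_step_deg:
        Increment for acyclic torsions inside single-conformer fragments.
    dedup_rmsd:
        Heavy-atom RMSD below which two candidate poses are duplicates.
    max_poses:
        Cap on candidate poses per fragment (truncation is logged).
    overlap_threshold_pct:
        vdW penetration percentage above which two atoms hard-clash; the same
        rule flags a crystallographic water as replaced by the ligand.
    prep_clash_overlap_pct:
        Overlap rule used when stripping site molecules that clash with the
        input core during preparation.
    hbond_dist_range:
        Donor/acceptor heavy-atom distance window for hydrogen bonds.
    hbond_min_angle_deg:
        Minimum donor-H...acceptor angle for a hydrogen bond.
    hydrophobic_dist_range:
        Centroid-to-receptor-carbon window for hydrophobic points.
    search_point_tolerance:
        Default tolerance radius of a search point in Angstrom.
    stable_point_radius:
        Match radius for deciding that two same-type points describe the
        same interaction (stability and maintenance checks).
    top_k:
        Number of poses kept per fragment in the hit list.
    max_conformers:
        Conformer cap when building fragment libraries.
    max_ensemble_members:
        Upper bound on binding-site conformations screened at once.
    permissive_hydrophobic:
        If True every apolar C/S atom generates a hydrophobic feature;
        default restricts to fully hydrophobic rings and terminal groups.
    overlap_metric:
        'linear' penetration fraction (default) or 'volume' intersection.
    """

    n_rays: int = 128
    max_range: float = 10.0
    clash_tolerance: float = 0.75
    w_clash: float = 3.0
    w_contact: float = 0.3
    contact_range: tuple[float, float] = (3.2, 4.0)
    torsion_step_deg: float = 30.0
    internal_torsion_step_deg: float = 120.0
    dedup_rmsd: float = 0.1
    max_poses: int = 600
    overlap_threshold_pct: float = 60.0
    prep_clash_overlap_pct: float = 60.0
    hbond_dist_range: tuple[float, float] = (2.5, 3.5)
    hbond_min_angle_deg: float = 120.0
    hydrophobic_dist_range: tuple[float, float] = (3.5, 4.5)
    search_point_tolerance: float = 2.0
    stable_point_radius: float = 2.0
    top_k: int = 1
    max_conformers: int = 25
    max_ensemble_members: int = 5
    permissive_hydrophobic: bool = False
    overlap_metric: str = "linear"
    receptor_hetnames: tuple[str, ...] = field(default_factory=tuple)


DEFAULT_CONFIG = GrowConfig()


def vdw_radius(element: str) -> float:
    """Return the tabulated vdW radius for ``element`` (fallback 1.70 A)."""
    return VDW_RADII.get(element, VDW_DEFAULT)
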