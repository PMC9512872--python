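"""Screening against an ensemble of aligned binding-site conformations.

Members must already sit in one alignment frame (they typically come from a
directory of superposed PDB files).  Each fragment is grown in every member
independently and only its best-scoring pose across members enters the hit
list, tagged with the member it came from.  A fragment survives the
ensemble if it survives in at least one member.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem_io import BindingSite, CoreAnchor
from .config import GrowConfig
from .errors import InputError
from .growing import HitList, Molecule, Pose, grow
from .pharmacophore import SearchPoint


@dataclass
class EnsembleSite:
    """2-5 aligned binding-site conformations sharing one anchor."""

    members: list[BindingSite]
    anchor: CoreAnchor

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise InputError("an ensemble needs at least two binding-site conformations")
        max_members = GrowConfig().max_ensemble_members
        if len(self.members) > max_members:
            raise InputError(f"ensemble limited to {max_members} conformations")
        ids = [m.frame_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise InputError("ensemble members must have distinct frame_ids")


def grow_ensemble(ensemble: EnsembleSite, library: list[Molecule],
                  search_points: list[SearchPoint] | None = None,
                  config: GrowConfig | None = None) -> HitList:
    """Grow the library in every member and keep each fragment's best pose.

    Ties between members resolve to the lexicographically smallest frame_id
    so results are deterministic.
    """
    config = config or GrowConfig()
    per_member: list[HitList] = []
    for member in sorted(ensemble.members, key=lambda m: m.frame_id):
        per_member.append(grow(ensemble.anchor, member, library,
                               search_points, config))

    best: dict[str, Pose] = {}
    for hits in per_member:
        for pose in hits.poses:
            cur = best.get(pose.fragment_id)
            if cur is None or pose.score_breakdown.combined > cur.score_breakdown.combined:
                best[pose.fragment_id] = pose

    poses = sorted(best.values(),
                   key=lambda p: (-p.score_breakdown.combined, p.fragment_id))
    all_ids = set()
    for hits in per_member:
        all_ids.update(hits.summary.get("filtered_ids", []))
        all_ids.update(h.fragment_id for h in hits.poses)
    filtered = sorted(all_ids - set(best))
    return HitList(poses, summary={
        "n_fragments": len(all_ids),
        "n_hits": len(best),
        "n_filtered": len(filtered),
        "filtered_ids": filtered,
        "n_members": len(ensemble.members),
    })
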