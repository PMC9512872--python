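"""Validation machinery: cross-growing cases, RMSD success statistics,
interaction maintenance and screening enrichment.

Cross-growing simulates prospective growing retrospectively: two ligands
crystallized in the same (aligned) binding site share a common core and
differ by exactly one substituent attached through one single bond.  The
growing input is the core posed from structure A; the held-out crystal pose
of ligand B scores the result.  Success is the conventional fragment-atom
RMSD below 2 A, aggregated with a normal approximation to the binomial
confidence interval.  Screening power is summarized by ROC/AUC with
stratified bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .chem_io import BindingSite, CoreAnchor, Molecule, mark_core, to_rdkit
from .config import GrowConfig
from .errors import ContractError, InputError
from .growing import Pose
from .pharmacophore import SearchPoint, detect_interactions, stable_points

Z_95 = 1.96  # two-sided 95 % normal quantile


# ---------------------------------------------------------------------------
# Cross-growing case construction
# ---------------------------------------------------------------------------

@dataclass
class CrossGrowCase:
    """One cross-growing test case with a held-out reference pose."""

    growing_site: BindingSite
    core: CoreAnchor
    target_fragment: Molecule
    reference_ligand: Molecule
    case_id: str = ""


@dataclass
class CaseRejection:
    """A ligand pair that does not form a valid cross-growing case."""

    reason: str
    detail: str = ""


MAX_CASE_HEAVY_ATOMS = 40


def _heavy_submolecule(mol: Molecule, heavy_atoms: set[int]) -> Molecule:
    """Induced submolecule on ``heavy_atoms`` plus their hydrogens."""
    keep = set(heavy_atoms)
    for i in heavy_atoms:
        keep.update(j for j in mol.neighbors(i) if mol.atoms[j].element == "H")
    drop = {a.index for a in mol.atoms} - keep
    sub, _ = mol.remove_atoms(drop)
    return sub


def _node_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"]


def _edge_match(a: dict, b: dict) -> bool:
    return np.isclose(a["order"], b["order"])


def build_case(complex_a: tuple[BindingSite, Molecule],
               complex_b: tuple[BindingSite, Molecule],
               case_id: str = "") -> CrossGrowCase | CaseRejection:
    """Pair two aligned complexes into a cross-growing case.

    Accepts the pair iff ligand B equals ligand A (the common core, taken
    with A's coordinates) plus exactly one connected substituent joined by
    one acyclic single bond.  Ring-fusion differences, multi-substituent
    differences and oversized ligands are rejected with a coded reason.
    """
    site_a, ligand_a = complex_a
    _, ligand_b = complex_b
    ga = ligand_a.graph(heavy_only=True)
    gb = ligand_b.graph(heavy_only=True)
    if ga.number_of_nodes() > MAX_CASE_HEAVY_ATOMS or \
            gb.number_of_nodes() > MAX_CASE_HEAVY_ATOMS:
        return CaseRejection("too_large", "exact matching limited to 40 heavy atoms")
    if gb.number_of_nodes() <= ga.number_of_nodes():
        return CaseRejection("no_growth", "ligand B is not larger than ligand A")

    bridges = {tuple(sorted(e)) for e in nx.bridges(gb)} if gb.number_of_edges() else set()
    single_acyclic = [
        (i, j) for i, j, o in ligand_b.bonds
        if o == 1.0 and tuple(sorted((i, j))) in bridges
    ]
    if not single_acyclic:
        return CaseRejection("ring_bond_cut",
                             "ligands differ by a ring fusion, not a substituent")

    for i, j in single_acyclic:
        g_cut = gb.copy()
        g_cut.remove_edge(i, j)
        comp_i = nx.node_connected_component(g_cut, i)
        comp_j = nx.node_connected_component(g_cut, j)
        for core_nodes, frag_nodes, core_att_b, frag_att_b in (
            (comp_i, comp_j, i, j),
            (comp_j, comp_i, j, i),
        ):
            if len(core_nodes) != ga.number_of_nodes():
                continue
            matcher = isomorphism.GraphMatcher(
                gb.subgraph(core_nodes), ga,
                node_match=_node_match, edge_match=_edge_match)
            mapping = next(matcher.isomorphisms_iter(), None)
            if mapping is None:
                continue
            attachment_a = mapping[core_att_b]
            try:
                anchor = mark_core(ligand_a, attachment_a)
            except Exception:
                continue
            fragment = _heavy_submolecule(ligand_b, set(frag_nodes))
            fragment.name = fragment.name or f"{case_id}_fragment"
            return CrossGrowCase(site_a, anchor, fragment, ligand_b, case_id)
    return CaseRejection("no_common_core",
                         "no single-bond cut of ligand B matches ligand A")


# ---------------------------------------------------------------------------
# Fragment RMSD
# ---------------------------------------------------------------------------

MAX_ISOMORPHISMS = 10000


def fragment_rmsd(pose: Pose, reference: Molecule) -> float:
    """Heavy-atom RMSD of the grown fragment against its reference pose.

    Coordinates are compared in place (frames are pre-aligned; nothing is
    superposed).  The minimum over all graph isomorphisms of the fragment's
    heavy-atom graph makes the measure symmetry-aware: a 180-degree flip of
    a symmetric ring scores 0.
    """
    frag_idx = pose.fragment_heavy_indices
    pose_frag = _heavy_submolecule(pose.ligand, set(frag_idx))
    g_pose = pose_frag.graph(heavy_only=True)
    g_ref = reference.graph(heavy_only=True)
    if g_pose.number_of_nodes() != g_ref.number_of_nodes():
        raise ContractError("fragment atom graphs differ in size")
    matcher = isomorphism.GraphMatcher(g_pose, g_ref,
                                       node_match=_node_match,
                                       edge_match=_edge_match)
    best = np.inf
    found = False
    for k, mapping in enumerate(matcher.isomorphisms_iter()):
        found = True
        if k >= MAX_ISOMORPHISMS:
            break
        sq = 0.0
        for pi, ri in mapping.items():
            diff = pose_frag.atoms[pi].position - reference.atoms[ri].position
            sq += float(np.dot(diff, diff))
        rmsd = np.sqrt(sq / len(mapping))
        best = min(best, rmsd)
    if not found:
        raise ContractError("pose fragment and reference are not isomorphic")
    return float(best)


# ---------------------------------------------------------------------------
# Success statistics
# ---------------------------------------------------------------------------

@dataclass
class SuccessStats:
    """Binomial success summary with a 95 % normal-approximation CI."""

    n: int
    successes: int
    rate: float
    ci_half_width: float


def binomial_ci_half_width(rate: float, n: int) -> float:
    """95 % half-width of a binomial proportion, normal approximation."""
    if n < 1:
        raise InputError("n must be >= 1")
    return Z_95 * float(np.sqrt(rate * (1.0 - rate) / n))


def success_stats_from_counts(successes: int, n: int) -> SuccessStats:
    if n < 1:
        raise InputError("n must be >= 1")
    if not 0 <= successes <= n:
        raise InputError("successes out of range")
    rate = successes / n
    return SuccessStats(n, successes, rate, binomial_ci_half_width(rate, n))


def success_stats(rmsds: list[float], threshold: float = 2.0) -> SuccessStats:
    """Fraction of RMSDs below the success threshold, with its 95 % CI."""
    if not rmsds:
        raise InputError("success_stats needs at least one case")
    successes = int(sum(1 for r in rmsds if r < threshold))
    return success_stats_from_counts(successes, len(rmsds))


# ---------------------------------------------------------------------------
# Interaction maintenance
# ---------------------------------------------------------------------------

def interaction_maintenance(input_points: list[SearchPoint], grown_pose: Pose,
                            site: BindingSite,
                            config: GrowConfig | None = None
                            ) -> dict[str, SuccessStats]:
    """Per-type fraction of input search points the grown pose regenerates.

    Points are regenerated from the grown pose; an input point counts as
    maintained when a same-type regenerated point lies within the stability
    radius (default 2 A).
    """
    config = config or GrowConfig()
    regenerated = detect_interactions(site, grown_pose.ligand, config)
    out: dict[str, SuccessStats] = {}
    for ptype in ("donor", "acceptor", "hydrophobic"):
        inputs = [p for p in input_points if p.type == ptype]
        if not inputs:
            continue
        maintained = stable_points(inputs, regenerated, config.stable_point_radius)
        out[ptype] = success_stats_from_counts(len(maintained), len(inputs))
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)


def auc_mid_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney rank statistic (mid-ranks on ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_act = int(labels.sum())
    n_dec = int(len(labels) - n_act)
    if n_act == 0 or n_dec == 0:
        raise InputError("enrichment needs at least one active and one inactive")
    ranks = rankdata(scores)  # mid-ranks for ties
    return float((ranks[labels == 1].sum() - n_act * (n_act + 1) / 2.0)
                 / (n_act * n_dec))


def enrichment(scores, labels, n_boot: int = 1000,
               seed: int = 7) -> EnrichmentResult:
    """ROC/AUC of labeled scores with a stratified bootstrap 95 % CI.

    Actives and inactives are resampled separately (``n_boot`` replicates,
    percentile interval), so both class sizes are preserved in every
    replicate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = auc_mid_rank(scores, labels)
    act = scores[labels == 1]
    dec = scores[labels == 0]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        sa = rng.choice(act, size=len(act), replace=True)
        sd = rng.choice(dec, size=len(dec), replace=True)
        boots[b] = auc_mid_rank(
            np.concatenate([sa, sd]),
            np.concatenate([np.ones(len(sa), int), np.zeros(len(sd), int)]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    fpr, tpr, _ = roc_curve(labels, scores)
    return EnrichmentResult(auc, float(lo), float(hi), fpr, tpr)


def mw_baseline(library: list[Molecule], labels: list[int]) -> float:
    """AUC of ranking by descending molecular weight (heavier scores higher)."""
    weights = [ro3_properties(mol)["molecular_weight"] for mol in library]
    return auc_mid_rank(np.asarray(weights), np.asarray(labels))


# ---------------------------------------------------------------------------
# Rule-of-Three properties and decoy matching
# ---------------------------------------------------------------------------

RO3_KEYS = ("molecular_weight", "hbond_donors", "hbond_acceptors",
            "clogp", "rotatable_bonds", "tpsa")


def ro3_properties(fragment: Molecule) -> dict[str, float]:
    """Rule-of-Three property record used for decoy property matching."""
    try:
        rd = to_rdkit(fragment, sanitize=True)
    except Exception:
        rd = to_rdkit(fragment, sanitize=False)
        rd.UpdatePropertyCache(strict=False)
    return {
        "molecular_weight": float(Descriptors.MolWt(rd)),
        "hbond_donors": float(Lipinski.NumHDonors(rd)),
        "hbond_acceptors": float(Lipinski.NumHAcceptors(rd)),
        "clogp": float(Crippen.MolLogP(rd)),
        "rotatable_bonds": float(Lipinski.NumRotatableBonds(rd)),
        "tpsa": float(rdMolDescriptors.CalcTPSA(rd)),
    }


def property_match_decoys(actives: list[Molecule], pool: list[Molecule],
                          n_decoys: int) -> list[Molecule]:
    """Pick decoys property-matched to the actives.

    Greedy nearest-neighbor in z-scored Rule-of-Three property space,
    without replacement, cycling through the actives.
    """
    if not actives or not pool:
        raise InputError("need actives and a decoy pool")
    n_decoys = min(n_decoys, len(pool))
    table = np.array([[ro3_properties(m)[k] for k in RO3_KEYS]
                      for m in actives + pool])
    mean = table.mean(axis=0)
    std = table.std(axis=0)
    std[std < 1e-9] = 1.0
    z = (table - mean) / std
    z_act, z_pool = z[: len(actives)], z[len(actives):]
    available = list(range(len(pool)))
    chosen: list[int] = []
    k = 0
    while len(chosen) < n_decoys and available:
        target = z_act[k % len(actives)]
        dists = [float(np.linalg.norm(z_pool[i] - target)) for i in available]
        pick = available[int(np.argmin(dists))]
        chosen.append(pick)
        available.remove(pick)
        k += 1
    return [pool[i] for i in chosen]
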