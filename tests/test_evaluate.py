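"""Cross-growing cases, fragment RMSD, success statistics and enrichment."""

import numpy as np
import pytest
from helpers import atom, hexagon_ring
from hypothesis import given, settings
from hypothesis import strategies as st

from growlite.chem_io import BindingSite, Molecule
from growlite.errors import ContractError, InputError
from growlite.evaluate import (CaseRejection, CrossGrowCase, auc_mid_rank,
                               build_case, enrichment, fragment_rmsd,
                               interaction_maintenance, mw_baseline,
                               property_match_decoys, ro3_properties,
                               success_stats, success_stats_from_counts)
from growlite.fixtures import FixtureSpec, make_fragment, plant_case
from growlite.growing import Pose
from growlite.pharmacophore import SearchPoint


def _empty_site():
    return BindingSite(Molecule([atom(0, "C", [50.0, 0, 0])]), [], "s")


class TestBuildCase:
    def test_single_substituent_pair_accepted(self):
        case0 = plant_case(FixtureSpec(seed=2))
        result = build_case((case0.growing_site, case0.core.core),
                            (case0.growing_site, case0.reference_ligand), "c")
        assert isinstance(result, CrossGrowCase)
        assert len(result.target_fragment.heavy_indices) == 3

    def test_ring_fusion_rejected(self):
        ring = hexagon_ring()
        bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
                 (4, 6), (6, 7), (7, 8), (8, 9), (9, 5)]
        fused = Molecule([atom(i, "C", [np.cos(i), np.sin(i), 0.0], h=1)
                          for i in range(10)],
                         [(i, j, 1.0) for i, j in bonds], "fused")
        result = build_case((_empty_site(), ring), (_empty_site(), fused))
        assert isinstance(result, CaseRejection)
        assert result.reason == "ring_bond_cut"

    def test_two_substituent_difference_rejected(self):
        core = Molecule([atom(0, "C", [0, 0, 0], h=2),
                         atom(1, "C", [1.5, 0, 0], h=2)], [(0, 1, 1.0)])
        double = Molecule(
            [atom(0, "C", [0, 0, 0], h=1), atom(1, "C", [1.5, 0, 0], h=1),
             atom(2, "O", [-0.8, 1.2, 0], h=1), atom(3, "N", [2.3, 1.2, 0], h=2)],
            [(0, 1, 1.0), (0, 2, 1.0), (1, 3, 1.0)], "double")
        result = build_case((_empty_site(), core), (_empty_site(), double))
        assert isinstance(result, CaseRejection)
        assert result.reason == "no_common_core"


class TestFragmentRMSD:
    def _pose_with_fragment(self, frag):
        case = plant_case(FixtureSpec(seed=0))
        n_core = len(case.core.core.atoms)
        atoms = list(case.core.core.atoms) + [
            atom(n_core + a.index, a.element, a.position,
                 h=a.attached_hydrogens) for a in frag.atoms]
        bonds = list(case.core.core.bonds) + \
            [(n_core + i, n_core + j, o) for i, j, o in frag.bonds]
        lig = Molecule(atoms, bonds)
        return Pose(lig, frozenset(range(n_core, n_core + len(frag.atoms))))

    def test_identical_pose_zero(self):
        frag = make_fragment("propyl")
        pose = self._pose_with_fragment(frag)
        assert fragment_rmsd(pose, frag) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation_equals_shift(self):
        frag = make_fragment("propyl")
        pose = self._pose_with_fragment(frag)
        shifted = frag.translated([0.0, 2.0, 0.0])
        assert fragment_rmsd(pose, shifted) == pytest.approx(2.0, abs=1e-9)

    def test_symmetric_ring_flip_zero_under_automorphism(self):
        ring = hexagon_ring()
        ring_uniform = Molecule(ring.atoms, [(i, (i + 1) % 6, 1.0)
                                             for i in range(6)], "c6")
        pose = self._pose_with_fragment(ring_uniform)
        flipped = ring_uniform.set_coords(ring_uniform.coords * [1.0, -1.0, 1.0])
        assert fragment_rmsd(pose, flipped) == pytest.approx(0.0, abs=1e-9)

    def test_graph_mismatch_raises(self):
        pose = self._pose_with_fragment(make_fragment("propyl"))
        with pytest.raises(ContractError):
            fragment_rmsd(pose, make_fragment("hydroxyethyl"))


class TestSuccessStats:
    # printed (rate %, n, half-width %) pairs from the validation statistics
    PRINTED = [
        (66.8, 425, 4.5), (70.8, 425, 4.3), (77.0, 252, 5.2), (64.3, 252, 5.9),
        (30.6, 85, 9.8), (55.3, 85, 10.6), (68.2, 85, 9.9), (76.2, 21, 18.2),
        (64.2, 162, 7.4), (72.8, 162, 6.8),
    ]

    @pytest.mark.parametrize("rate_pct,n,printed_hw", PRINTED)
    def test_reproduces_printed_half_widths(self, rate_pct, n, printed_hw):
        successes = int(round(rate_pct / 100.0 * n))
        stats = success_stats_from_counts(successes, n)
        assert 100.0 * stats.ci_half_width == pytest.approx(printed_hw, abs=0.05)

    def test_from_rmsd_list(self):
        stats = success_stats([0.5, 1.9, 2.0, 3.1])
        assert stats.successes == 2  # strict < 2.0 A
        assert stats.rate == 0.5

    def test_all_successes_zero_width(self):
        stats = success_stats([0.1] * 10)
        assert stats.rate == 1.0 and stats.ci_half_width == 0.0

    def test_empty_input_error(self):
        with pytest.raises(InputError):
            success_stats([])


class TestInteractionMaintenance:
    def _donor_ligand(self, y=0.0):
        return Molecule(
            [atom(0, "N", [0, y, 0]), atom(1, "H", [0, y + 1.0, 0]),
             atom(2, "C", [-1.2, y - 0.8, 0], h=2),
             atom(3, "C", [1.2, y - 0.8, 0], h=2)],
            [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])

    def test_identical_pose_maintains_all(self, cfg):
        site = BindingSite(Molecule([atom(0, "O", [0, 3.0, 0])]), [], "s")
        lig = self._donor_ligand()
        from growlite.pharmacophore import detect_interactions

        points = detect_interactions(site, lig, cfg)
        assert points
        pose = Pose(lig, frozenset())
        result = interaction_maintenance(points, pose, site, cfg)
        assert result["donor"].rate == 1.0

    def test_moved_donor_not_maintained(self, cfg):
        site = BindingSite(Molecule([atom(0, "O", [0, 3.0, 0])]), [], "s")
        points = [SearchPoint("donor", np.zeros(3))]
        pose = Pose(self._donor_ligand(y=-3.0), frozenset())
        result = interaction_maintenance(points, pose, site, cfg)
        assert result["donor"].rate == 0.0

    def test_partial_maintenance_two_of_three(self, cfg):
        site = BindingSite(Molecule([atom(0, "O", [0, 3.0, 0]),
                                     atom(1, "C", [4.0, 0, 4.0])]), [], "s")
        lig = Molecule(
            self._donor_ligand().atoms +
            [atom(4, "C", [4.0, 0, 0.2], h=3)],
            [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0), (3, 4, 1.0)])
        points = [SearchPoint("donor", np.zeros(3)),
                  SearchPoint("hydrophobic", np.array([4.0, 0, 0.2])),
                  SearchPoint("hydrophobic", np.array([0.0, 0, 9.0]))]
        pose = Pose(lig, frozenset())
        result = interaction_maintenance(points, pose, site, cfg)
        maintained = result["donor"].successes + result["hydrophobic"].successes
        total = result["donor"].n + result["hydrophobic"].n
        assert (maintained, total) == (2, 3)


class TestEnrichment:
    def test_perfect_separation(self):
        res = enrichment([1.0, 0.9, 0.8, 0.2, 0.1, 0.0],
                         [1, 1, 1, 0, 0, 0], n_boot=50, seed=1)
        assert res.auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        res = enrichment([0.5] * 6, [1, 1, 1, 0, 0, 0], n_boot=50, seed=1)
        assert res.auc == pytest.approx(0.5)

    def test_single_class_error(self):
        with pytest.raises(InputError):
            enrichment([1.0, 0.5], [1, 1], n_boot=10, seed=1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        act = scores[labels == 1]
        dec = scores[labels == 0]
        concordant = sum((a > d) + 0.5 * (a == d) for a in act for d in dec)
        expected = concordant / (len(act) * len(dec))
        assert auc_mid_rank(scores, labels) == pytest.approx(expected)

    def test_bootstrap_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(3)

        def width(n):
            scores = np.concatenate([rng.normal(1.0, 1.0, n),
                                     rng.normal(0.0, 1.0, n)])
            labels = np.concatenate([np.ones(n, int), np.zeros(n, int)])
            res = enrichment(scores, labels, n_boot=300, seed=5)
            return res.ci_high - res.ci_low

        widths_small = [width(25) for _ in range(3)]
        widths_large = [width(100) for _ in range(3)]
        assert np.median(widths_large) < np.median(widths_small)


class TestMWBaseline:
    def test_identical_weights_give_half(self):
        lib = [make_fragment("propyl"), make_fragment("propyl"),
               make_fragment("propyl"), make_fragment("propyl")]
        assert mw_baseline(lib, [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_heavier_actives_above_half(self):
        lib = [make_fragment("butyl"), make_fragment("propyl"),
               make_fragment("ethyl"), make_fragment("methyl")]
        assert mw_baseline(lib, [1, 1, 0, 0]) > 0.5

    def test_lighter_actives_below_half(self):
        lib = [make_fragment("butyl"), make_fragment("propyl"),
               make_fragment("ethyl"), make_fragment("methyl")]
        assert mw_baseline(lib, [0, 0, 1, 1]) < 0.5


class TestRo3Properties:
    def test_benzene(self):
        props = ro3_properties(hexagon_ring())
        assert props["hbond_donors"] == 0
        assert props["hbond_acceptors"] == 0
        assert props["rotatable_bonds"] == 0

    def test_ethanol_one_donor(self):
        ethanol = Molecule(
            [atom(0, "C", [0, 0, 0], h=3), atom(1, "C", [1.5, 0, 0], h=2),
             atom(2, "O", [2.2, 1.2, 0], h=1)],
            [(0, 1, 1.0), (1, 2, 1.0)], "ethanol")
        assert ro3_properties(ethanol)["hbond_donors"] == 1

    def test_property_matching_preserves_means(self):
        actives = [make_fragment(n) for n in
                   ("propyl", "butyl", "hydroxyethyl")]
        pool = [make_fragment(n) for n in
                ("methyl", "ethyl", "isopropyl", "tert-butyl",
                 "aminoethyl", "methoxymethyl", "thiomethyl")]
        decoys = property_match_decoys(actives, pool, 3)
        assert len(decoys) == 3
        for key in ("molecular_weight",):
            a_vals = [ro3_properties(m)[key] for m in actives]
            d_vals = [ro3_properties(m)[key] for m in decoys]
            pooled_sd = np.std(a_vals + d_vals) or 1.0
            assert abs(np.mean(a_vals) - np.mean(d_vals)) <= pooled_sd
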