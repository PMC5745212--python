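import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import hawkrank as hr
from hawkrank.docking_eval import case_f, perfect_f
from hawkrank.structures_io import Atom, ComplexPartition, ProteinStructure

from conftest import random_rigid


def _chain(xs, chain, name="CA"):
    atoms = [
        Atom(k + 1, name, "C", "GLY", k + 1, "", chain, np.asarray(x, float))
        for k, x in enumerate(xs)
    ]
    return ProteinStructure(atoms)


class TestInterfaceResidues:
    @pytest.mark.parametrize("d,expected", [(9.9, 1), (10.0, 1), (10.1, 0)])
    def test_ten_angstrom_boundary_inclusive(self, d, expected):
        rec = _chain([(0, 0, 0), (50, 0, 0), (100, 0, 0)], "A")
        lig = _chain([(-d, 0, 0)], "B")
        rec_if, lig_if = hr.interface_residues(ComplexPartition(rec, lig))
        assert len(lig_if) == expected
        assert len([r for r in rec_if]) == expected

    def test_distant_partners_have_empty_interface(self, toy_complex):
        far = hr.apply_transform(
            toy_complex.ligand,
            hr.RigidTransform(np.eye(3), np.array([100.0, 0, 0])),
        )
        rec_if, lig_if = hr.interface_residues(
            ComplexPartition(toy_complex.receptor, far)
        )
        assert rec_if == set() and lig_if == set()


class TestRmsds:
    def test_identical_decoy_scores_zero(self, toy_complex):
        r = hr.compute_rmsds(toy_complex, toy_complex)
        assert r.l_rmsd == pytest.approx(0.0, abs=1e-9)
        assert r.i_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_translation_gives_exact_l_rmsd(self, toy_complex):
        t = hr.RigidTransform(np.eye(3), np.array([3.0, 4.0, 0.0]))  # |t| = 5
        decoy = ComplexPartition(
            toy_complex.receptor, hr.apply_transform(toy_complex.ligand, t)
        )
        r = hr.compute_rmsds(toy_complex, decoy)
        assert r.l_rmsd == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_superposition_oracle(self, seed, toy_complex):
        """Randomized decoys agree with a scipy-based Kabsch oracle to 1e-6 A."""
        rng = np.random.default_rng(seed)
        t_l = random_rigid(rng)
        t_all = random_rigid(rng)  # additionally move the whole decoy complex
        decoy = ComplexPartition(
            hr.apply_transform(toy_complex.receptor, t_all),
            hr.apply_transform(hr.apply_transform(toy_complex.ligand, t_l), t_all),
        )
        got = hr.compute_rmsds(toy_complex, decoy)

        def ca(s):
            return np.array([a.coords for a in s.atoms if a.name == "CA"])

        def oracle_rmsd(mob_fit, ref_fit, mob_measure, ref_measure):
            rot, _rssd = Rotation.align_vectors(
                ref_fit - ref_fit.mean(0), mob_fit - mob_fit.mean(0)
            )
            moved = rot.apply(mob_measure - mob_fit.mean(0)) + ref_fit.mean(0)
            return float(np.sqrt(((moved - ref_measure) ** 2).sum(1).mean()))

        l_oracle = oracle_rmsd(
            ca(decoy.receptor), ca(toy_complex.receptor),
            ca(decoy.ligand), ca(toy_complex.ligand),
        )
        rec_if, lig_if = hr.interface_residues(toy_complex)

        def ca_if(s, keep):
            return np.array(
                [a.coords for a in s.atoms if a.name == "CA" and a.residue_id in keep]
            )

        nat_if = np.vstack([
            ca_if(toy_complex.receptor, rec_if), ca_if(toy_complex.ligand, lig_if)
        ])
        dec_if = np.vstack([
            ca_if(decoy.receptor, rec_if), ca_if(decoy.ligand, lig_if)
        ])
        i_oracle = oracle_rmsd(dec_if, nat_if, dec_if, nat_if)
        assert got.l_rmsd == pytest.approx(l_oracle, abs=1e-6)
        assert got.i_rmsd == pytest.approx(i_oracle, abs=1e-6)

    def test_too_few_calpha_pairs_rejected(self):
        rec = _chain([(0, 0, 0), (3.8, 0, 0)], "A")
        lig = _chain([(8, 0, 0)], "B")
        part = ComplexPartition(rec, lig)
        with pytest.raises(ValueError, match=">= 3"):
            hr.compute_rmsds(part, part)


class TestHitsAndRates:
    @pytest.mark.parametrize(
        "l,i,hit", [(9.5, 5.0, True), (12.0, 3.5, True), (12.0, 5.0, False)]
    )
    def test_hit_rule(self, l, i, hit):
        assert hr.classify_hit(hr.RmsdPair(l, i)) is hit

    def _cases(self, first_hit_ranks, n=200):
        cases = []
        for k, fr in enumerate(first_hit_ranks):
            hits = np.zeros(n, bool)
            if fr is not None:
                hits[fr - 1] = True
            cases.append(hr.RankedCase(f"c{k}", hits))
        return cases

    def test_success_rate_counts_cases_with_a_top_n_hit(self):
        cases = self._cases([3, 150, None, 12])
        assert hr.success_rate(cases, 10) == 0.25
        assert hr.success_rate(cases, 200) == 0.75

    def test_success_rate_saturates_at_one(self):
        cases = self._cases([3, 150, 12])
        assert hr.success_rate(cases, 200) == 1.0

    def test_sr_non_decreasing_in_n(self):
        cases = self._cases([3, 150, None, 12, 77])
        srs = [hr.success_rate(cases, N) for N in (1, 5, 20, 100, 200)]
        assert srs == sorted(srs)


class TestMsr:
    def test_single_hit_at_rank_one(self):
        case = hr.RankedCase("c", np.array([True] + [False] * 9))
        out = hr.msr([case], N=5)
        assert out.F_per_case["c"] == pytest.approx(2.0)
        assert out.Y == pytest.approx(2.0)

    def test_hits_at_ranks_one_and_four(self):
        hits = np.zeros(10, bool)
        hits[[0, 3]] = True
        case = hr.RankedCase("c", hits)
        assert case_f(case, N=4) == pytest.approx(1.625)
        assert case_f(case, N=10) == pytest.approx(1.625)

    def test_no_hit_in_top_n_gives_zero_f(self):
        hits = np.zeros(600, bool)
        hits[550] = True
        case = hr.RankedCase("c", hits)
        assert case_f(case, N=500) == 0.0

    def test_hit_denominator_uses_full_list(self):
        # hits buried deep in the list dilute the top-N sum
        hits = np.zeros(100, bool)
        hits[[0, 60, 70, 80]] = True
        case = hr.RankedCase("c", hits)
        assert case_f(case, N=10) == pytest.approx((1 + 1 / 1) / 4)

    def test_hitless_case_excluded_with_warning(self):
        good = hr.RankedCase("good", np.array([True, False]))
        bad = hr.RankedCase("bad", np.array([False, False]))
        with pytest.warns(UserWarning, match="bad"):
            out = hr.msr([good, bad], N=2)
        assert set(out.F_per_case) == {"good"}

    def test_y_is_mean_of_f(self):
        h1 = np.zeros(10, bool); h1[0] = True
        h2 = np.zeros(10, bool); h2[[0, 3]] = True
        out = hr.msr([hr.RankedCase("a", h1), hr.RankedCase("b", h2)], N=10)
        assert out.Y == pytest.approx((2.0 + 1.625) / 2)

    def test_y_non_decreasing_in_n(self):
        rng = np.random.default_rng(5)
        cases = [
            hr.RankedCase(f"c{k}", rng.random(300) < 0.05) for k in range(6)
        ]
        ys = [hr.msr(cases, N).Y for N in (1, 10, 50, 150, 300)]
        assert ys == sorted(ys)

    def test_perfect_ranking_attains_the_closed_form_maximum(self):
        for n_hits in (1, 3, 7):
            hits = np.zeros(50, bool)
            hits[:n_hits] = True
            case = hr.RankedCase("c", hits)
            assert case_f(case, N=50) == pytest.approx(perfect_f(n_hits))
            # any worse placement scores lower
            worse = np.zeros(50, bool)
            worse[5:5 + n_hits] = True
            assert case_f(hr.RankedCase("w", worse), N=50) < perfect_f(n_hits)


class TestBuriedArea:
    def test_separated_partners_bury_nothing(self, bundle, toy_complex):
        far = ComplexPartition(
            toy_complex.receptor,
            hr.apply_transform(
                toy_complex.ligand,
                hr.RigidTransform(np.eye(3), np.array([200.0, 0, 0])),
            ),
        )
        assert hr.buried_area_pct(far, bundle.radii) == pytest.approx(0.0, abs=1e-9)

    def test_contacting_pose_buries_area_symmetrically(self, bundle, toy_complex):
        pct = hr.buried_area_pct(toy_complex, bundle.radii)
        swapped = ComplexPartition(
            hr.ProteinStructure(list(toy_complex.ligand.atoms)),
            hr.ProteinStructure(list(toy_complex.receptor.atoms)),
        )
        assert pct > 0.0
        assert hr.buried_area_pct(swapped, bundle.radii) == pytest.approx(pct, abs=1e-9)
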