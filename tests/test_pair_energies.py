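import math

import numpy as np
import pytest

import hawkrank as hr
from hawkrank.pair_energies import (
    COULOMB_CONSTANT,
    build_pairlist,
    elec_energy,
    vdw_energy,
)
from hawkrank.parameters import FFAtomParam
from hawkrank.structures_io import Atom, ComplexPartition, ProteinStructure

from conftest import random_rigid


def _one_atom(x, chain, serial=1):
    return ProteinStructure(
        [Atom(serial, "CA", "C", "ALA", 1, "", chain, np.array([x, 0.0, 0.0]))]
    )


def _pair_at(r):
    part = ComplexPartition(_one_atom(0.0, "A"), _one_atom(r, "B"))
    return build_pairlist(part, cutoff=None)


class TestPairlist:
    @pytest.mark.parametrize("r,included", [(11.9, True), (12.1, False)])
    def test_cutoff_is_strict(self, r, included):
        part = ComplexPartition(_one_atom(0.0, "A"), _one_atom(r, "B"))
        pairs = build_pairlist(part, cutoff=12.0)
        assert (len(pairs) == 1) is included

    def test_intramolecular_pairs_never_appear(self):
        rec = ProteinStructure([
            Atom(1, "CA", "C", "ALA", 1, "", "A", np.zeros(3)),
            Atom(2, "CB", "C", "ALA", 1, "", "A", np.array([3.0, 0, 0])),
        ])
        lig = _one_atom(100.0, "B")
        pairs = build_pairlist(ComplexPartition(rec, lig), cutoff=12.0)
        assert len(pairs) == 0

    def test_coincident_atoms_rejected(self):
        part = ComplexPartition(_one_atom(0.0, "A"), _one_atom(0.0, "B"))
        with pytest.raises(ValueError, match="coincident"):
            build_pairlist(part, cutoff=12.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_spatial_index_matches_brute_force(self, seed):
        """Cell-index pairlist equals the O(n^2) double loop."""
        rng = np.random.default_rng(seed)
        part = hr.make_toy_complex(
            n_rec=8, n_lig=5, gap=float(rng.uniform(-2, 6)), seed=seed
        )
        pairs = build_pairlist(part, cutoff=12.0)
        got = set(zip(pairs.i.tolist(), pairs.j.tolist()))
        d = np.linalg.norm(
            part.receptor.coords[:, None, :] - part.ligand.coords[None, :, :], axis=-1
        )
        expect = set(zip(*np.nonzero(d < 12.0)))
        assert got == expect


class TestVdw:
    def test_minimum_of_the_6_12_form(self):
        p = [FFAtomParam(1.7, 0.1, 0.0)]
        pairs = _pair_at(3.4)
        attr, repu = vdw_energy(pairs, p, p)
        assert attr == pytest.approx(0.1 * (1 - 2), abs=1e-12)
        assert repu == 0.0

    def test_linear_ramp_at_half_onset(self):
        p = [FFAtomParam(1.7, 0.1, 0.0)]
        r = 0.445 * 3.4
        attr, repu = vdw_energy(_pair_at(r), p, p)
        assert repu == pytest.approx(5.0, abs=1e-12)
        assert attr == 0.0

    def test_zero_beyond_cutoff(self):
        p = [FFAtomParam(1.7, 0.5, 0.0)]
        attr, repu = vdw_energy(_pair_at(13.0), p, p)
        assert attr == 0.0 and repu == 0.0

    def test_boundary_goes_to_attractive_branch(self):
        p = [FFAtomParam(1.7, 0.1, 0.0)]
        attr, repu = vdw_energy(_pair_at(0.89 * 3.4), p, p)
        assert repu == 0.0
        assert attr != 0.0

    def test_small_documented_jump_at_onset(self):
        # the piecewise form leaves |E_attr(0.89 sigma)| ~ 0.024 eps
        eps = 0.25
        p = [FFAtomParam(1.7, eps, 0.0)]
        attr, _ = vdw_energy(_pair_at(0.89 * 3.4), p, p)
        assert abs(attr) < 0.03 * eps

    def test_combination_rules(self):
        # sigma = sum of rmin/2, eps = geometric mean
        pa = [FFAtomParam(1.0, 0.04, 0.0)]
        pb = [FFAtomParam(2.0, 0.09, 0.0)]
        attr, _ = vdw_energy(_pair_at(3.0), pa, pb)
        assert attr == pytest.approx(math.sqrt(0.04 * 0.09) * (1 - 2), abs=1e-12)


class TestElec:
    def test_attractive_example(self):
        pa = [FFAtomParam(1.0, 0.1, 0.5)]
        pb = [FFAtomParam(1.0, 0.1, -0.5)]
        attr, repu = elec_energy(_pair_at(4.0), pa, pb)
        assert attr == pytest.approx(COULOMB_CONSTANT * (-0.25) / 4.0)
        assert repu == 0.0

    def test_repulsive_example(self):
        pa = [FFAtomParam(1.0, 0.1, 0.4)]
        attr, repu = elec_energy(_pair_at(8.0), pa, pa)
        assert repu == pytest.approx(332 * 0.16 / 8.0)
        assert attr == 0.0

    def test_zero_charge_routed_to_repulsive_contributes_nothing(self):
        pa = [FFAtomParam(1.0, 0.1, 0.4)]
        pb = [FFAtomParam(1.0, 0.1, 0.0)]
        attr, repu = elec_energy(_pair_at(5.0), pa, pb)
        assert attr == 0.0 and repu == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_split_conserves_the_unsplit_sum(self, seed, bundle):
        part = hr.make_toy_complex(n_rec=8, n_lig=6, gap=1.0, seed=seed)
        rp = hr.assign_ff_params(part.receptor, bundle.ff)
        lp = hr.assign_ff_params(part.ligand, bundle.ff)
        pairs = build_pairlist(part, cutoff=12.0)
        attr, repu = elec_energy(pairs, rp, lp)
        q_r = np.array([p.charge for p in rp])
        q_l = np.array([p.charge for p in lp])
        unsplit = math.fsum(332 * q_r[pairs.i] * q_l[pairs.j] / pairs.r)
        assert attr + repu == pytest.approx(unsplit, abs=1e-9)


class TestInvariance:
    def _terms(self, part, bundle):
        rp = hr.assign_ff_params(part.receptor, bundle.ff)
        lp = hr.assign_ff_params(part.ligand, bundle.ff)
        pairs = build_pairlist(part, cutoff=12.0)
        return (*vdw_energy(pairs, rp, lp), *elec_energy(pairs, rp, lp))

    def test_rigid_motion_of_whole_complex(self, bundle, toy_complex, rng):
        t = random_rigid(rng)
        moved = ComplexPartition(
            hr.apply_transform(toy_complex.receptor, t),
            hr.apply_transform(toy_complex.ligand, t),
        )
        a = self._terms(toy_complex, bundle)
        b = self._terms(moved, bundle)
        np.testing.assert_allclose(b, a, rtol=1e-9, atol=1e-9)

    def test_relative_motion_changes_terms(self, bundle, toy_complex):
        shift = hr.RigidTransform(np.eye(3), np.array([1.0, 0.5, 0.0]))
        moved = ComplexPartition(
            toy_complex.receptor, hr.apply_transform(toy_complex.ligand, shift)
        )
        a = np.array(self._terms(toy_complex, bundle))
        b = np.array(self._terms(moved, bundle))
        assert np.any(np.abs(a - b) > 1e-6)
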