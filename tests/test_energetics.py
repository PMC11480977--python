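import numpy as np
import pytest

from conftest import random_terms
from glycodock.energetics import (EnergyReport, NonbondedParams, PartnerTerms,
                                  ScoringWeights, bsa, coulomb, desolvation,
                                  haddock_score, lennard_jones, resolve_params,
                                  sasa, score_pose)

COULOMB_K = 332.0636


def brute_force_lj(a: PartnerTerms, b: PartnerTerms, p: NonbondedParams) -> float:
    total = 0.0
    for i in range(len(a.coords)):
        for j in range(len(b.coords)):
            r = float(np.linalg.norm(a.coords[i] - b.coords[j]))
            if r >= p.cutoff:
                continue
            eps = np.sqrt(a.epsilon[i] * b.epsilon[j])
            sig = 0.5 * (a.sigma[i] + b.sigma[j])
            x = np.clip((r - (p.cutoff - p.switch_width)) / p.switch_width, 0, 1)
            s = 1 - x * x * (3 - 2 * x)
            total += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6) * s
    return total


def brute_force_coulomb(a, b, p):
    total = 0.0
    for i in range(len(a.coords)):
        for j in range(len(b.coords)):
            r = float(np.linalg.norm(a.coords[i] - b.coords[j]))
            if r >= p.cutoff:
                continue
            x = np.clip((r - (p.cutoff - p.switch_width)) / p.switch_width, 0, 1)
            s = 1 - x * x * (3 - 2 * x)
            total += COULOMB_K * a.charge[i] * b.charge[j] / \
                (p.relative_permittivity * r) * s
    return total


def _single(coord, eps=0.2, sig=3.0, q=0.0):
    return PartnerTerms(np.array([coord], dtype=float), np.array([eps]),
                        np.array([sig]), np.array([q]), np.zeros(1),
                        np.array([1.7]))


class TestLennardJones:
    def test_minimum_depth(self):
        p = NonbondedParams()
        a = _single([0, 0, 0])
        b = _single([2 ** (1 / 6) * 3.0, 0, 0])
        assert lennard_jones(a, b, p) == pytest.approx(-0.2, rel=1e-12)

    def test_zero_crossing_at_sigma(self):
        p = NonbondedParams()
        assert lennard_jones(_single([0, 0, 0]), _single([3.0, 0, 0]),
                             p) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = NonbondedParams()
        a = random_terms(rng, 10)
        b = random_terms(rng, 10, offset=4.0)
        fast = lennard_jones(a, b, p)
        slow = brute_force_lj(a, b, p)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_vanishes_at_separation(self):
        rng = np.random.default_rng(7)
        a = random_terms(rng, 8)
        b = random_terms(rng, 8, offset=50.0)
        assert lennard_jones(a, b, NonbondedParams()) == 0.0


class TestCoulomb:
    def test_closed_form_pair(self):
        p = NonbondedParams(relative_permittivity=10.0)
        a = _single([0, 0, 0], q=1.0)
        b = _single([3.32, 0, 0], q=-1.0)
        expected = COULOMB_K * -1.0 / (10.0 * 3.32)
        assert coulomb(a, b, p) == pytest.approx(expected, rel=1e-12)
        assert coulomb(a, b, p) == pytest.approx(-10.0, abs=0.01)

    def test_zero_charge_no_contribution(self):
        p = NonbondedParams()
        assert coulomb(_single([0, 0, 0], q=0.0), _single([3, 0, 0], q=1.0),
                       p) == 0.0

    def test_coincident_raises(self):
        p = NonbondedParams()
        with pytest.raises(ValueError):
            coulomb(_single([0, 0, 0], q=1.0), _single([0, 0, 0], q=1.0), p)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = NonbondedParams()
        a = random_terms(rng, 12)
        b = random_terms(rng, 9, offset=3.0)
        assert coulomb(a, b, p) == pytest.approx(
            brute_force_coulomb(a, b, p), rel=1e-10)


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        area = sasa(np.array([[0.0, 0, 0]]), np.array([1.7]), probe=1.4,
                    n_points=960)
        assert area[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.01)

    def test_fully_buried_atom(self):
        # central atom caged by 14 large neighbours
        shell = []
        for x in (-1, 1):
            for axis in range(3):
                v = np.zeros(3); v[axis] = 2.2 * x
                shell.append(v)
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    shell.append(np.array([sx, sy, sz]) * 1.6)
        coords = np.vstack([[0.0, 0, 0]] + shell)
        radii = np.full(len(coords), 1.9)
        areas = sasa(coords, radii, n_points=960)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [30.0, 0, 0]])
        radii = np.array([1.7, 1.52])
        areas = sasa(coords, radii, n_points=960)
        iso = [sasa(coords[i:i + 1], radii[i:i + 1], n_points=960)[0]
               for i in range(2)]
        np.testing.assert_allclose(areas, iso, rtol=1e-12)

    def test_independent_implementation_within_2pct(self, toy3):
        biotite_struct = pytest.importorskip("biotite.structure")
        p = NonbondedParams()
        terms = resolve_params(toy3.receptor, p)
        mine = sasa(terms.coords, terms.radii, n_points=960).sum()
        arr = biotite_struct.AtomArray(len(terms.coords))
        arr.coord = terms.coords
        arr.element = np.array(
            [a.element for a in toy3.receptor.atoms if a.is_heavy])
        theirs = biotite_struct.sasa(
            arr, vdw_radii=terms.radii, point_number=960).sum()
        assert mine == pytest.approx(theirs, rel=0.02)


class TestSurfaceTerms:
    def test_bsa_zero_when_far(self, toy3):
        far = toy3.glycan.with_coords(toy3.glycan.coords() + 40.0)
        p = NonbondedParams()
        rec = resolve_params(toy3.receptor, p)
        lig = resolve_params(far, p)
        assert bsa(rec, lig, n_points=240) == pytest.approx(0.0, abs=1e-6)

    def test_bsa_positive_and_deterministic_in_contact(self, toy3):
        p = NonbondedParams()
        rec = resolve_params(toy3.receptor, p)
        lig = resolve_params(toy3.glycan, p)
        b1 = bsa(rec, lig, n_points=240)
        b2 = bsa(rec, lig, n_points=240)
        assert b1 == b2
        assert b1 > 50.0

    def test_desolvation_identity_with_unit_solvation(self, toy3):
        p = NonbondedParams()
        rec = resolve_params(toy3.receptor, p)
        lig = resolve_params(toy3.glycan, p)
        rec.solv = np.ones_like(rec.solv)
        lig.solv = np.ones_like(lig.solv)
        d = desolvation(rec, lig, n_points=240)
        b = bsa(rec, lig, n_points=240)
        assert d == pytest.approx(b, rel=1e-9)

    def test_desolvation_zero_params_zero(self, toy3):
        p = NonbondedParams()
        rec = resolve_params(toy3.receptor, p)
        lig = resolve_params(toy3.glycan, p)
        rec.solv = np.zeros_like(rec.solv)
        lig.solv = np.zeros_like(lig.solv)
        assert desolvation(rec, lig, n_points=240) == 0.0


class TestHaddockScore:
    def test_all_zero_report(self):
        assert haddock_score(EnergyReport(), ScoringWeights.rigid_default()) == 0.0

    def test_vdw_weight_presets(self):
        report = EnergyReport(E_vdW=100.0)
        assert haddock_score(report, ScoringWeights.rigid_default()) == \
            pytest.approx(1.0)
        assert haddock_score(report, ScoringWeights.rigid_vdw()) == \
            pytest.approx(100.0)

    def test_hand_computed_combination(self):
        r = EnergyReport(E_vdW=2.0, E_elec=-3.0, E_desolv=1.5, E_BSA=100.0,
                         E_air=40.0)
        w = ScoringWeights(1.0, 1.0, 1.0, 0.0, 0.1)
        assert haddock_score(r, w) == pytest.approx(2.0 - 3.0 + 1.5 + 4.0)

    def test_linear_in_each_term(self):
        rng = np.random.default_rng(5)
        w = ScoringWeights.rigid_vdw()
        base = EnergyReport(*rng.normal(size=5))
        base.E_BSA = abs(base.E_BSA)
        s0 = haddock_score(base, w)
        for name, weight in [("E_vdW", w.w_vdW), ("E_elec", w.w_elec),
                             ("E_desolv", w.w_desolv), ("E_BSA", w.w_BSA),
                             ("E_air", w.w_air)]:
            bumped = EnergyReport(**{**base.__dict__, name:
                                     getattr(base, name) + 2.0})
            assert haddock_score(bumped, w) - s0 == pytest.approx(2 * weight)

    def test_vdw_weight_separates_clashing_pose(self):
        clash = EnergyReport(E_vdW=500.0, E_elec=-5.0)
        good = EnergyReport(E_vdW=-10.0, E_elec=-5.0)
        gap_default = (haddock_score(clash, ScoringWeights.rigid_default())
                       - haddock_score(good, ScoringWeights.rigid_default()))
        gap_vdw = (haddock_score(clash, ScoringWeights.rigid_vdw())
                   - haddock_score(good, ScoringWeights.rigid_vdw()))
        assert gap_vdw > gap_default > 0

    def test_non_finite_report_rejected(self):
        with pytest.raises(ValueError):
            EnergyReport(E_vdW=np.nan)


def test_score_pose_terms_vanish_at_separation(toy3):
    far = toy3.glycan.with_coords(toy3.glycan.coords() + 50.0)
    report, score = score_pose(toy3.receptor, far, None,
                               ScoringWeights.rigid_vdw(), sasa_points=240)
    assert report.E_vdW == 0.0
    assert report.E_elec == 0.0
    assert report.E_BSA == pytest.approx(0.0, abs=1e-6)
    assert report.E_desolv == pytest.approx(0.0, abs=1e-6)
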