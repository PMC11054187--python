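"""Binding free-energy terms, bookkeeping identities, decomposition, entropy."""

import numpy as np
import pytest

from mdbind.energetics import (COULOMB_CONSTANT, EnergyComponents,
                               aggregate_binding_free_energy, compare_systems,
                               components_from_means, coulomb_energy,
                               dg_from_ic50, ensemble_components, gb_energy,
                               lj_energy, nonpolar_energy,
                               per_residue_decomposition,
                               quasiharmonic_entropy, snapshot_components)
from mdbind.energetics import _cross_pairs
from mdbind.published import BRD4_TABLE, BRD9_TABLE, binding_energy
from mdbind.synthetic import generate_ligand_system

from conftest import make_ensemble, make_topology


class TestCoulomb:
    def test_unit_charges_at_ke_over_100(self):
        coords = np.array([[0.0, 0, 0], [COULOMB_CONSTANT / 100.0, 0, 0]])
        e = coulomb_energy(coords, np.array([1.0, 1.0]), [(0, 1)], eps_in=1.0)
        assert e == pytest.approx(100.0, rel=1e-12)

    def test_neutral_partner_is_zero(self, rng):
        coords = rng.normal(size=(2, 3))
        assert coulomb_energy(coords, np.array([1.0, 0.0]), [(0, 1)]) == 0.0

    def test_linearity_in_charge(self, rng):
        coords = rng.normal(scale=4, size=(2, 3))
        q = np.array([0.4, -0.7])
        e1 = coulomb_energy(coords, q, [(0, 1)])
        e2 = coulomb_energy(coords, q * np.array([2.0, 1.0]), [(0, 1)])
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_coincident_charges_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            coulomb_energy(np.zeros((2, 3)), np.array([1.0, 1.0]), [(0, 1)])


class TestLennardJones:
    sigma = np.array([3.2, 3.2])
    eps = np.array([0.3, 0.3])

    def _pair_energy(self, r):
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        return lj_energy(coords, self.sigma, self.eps, [(0, 1)])

    def test_minimum_at_r_min(self):
        assert self._pair_energy(2 ** (1 / 6) * 3.2) == pytest.approx(-0.3, rel=1e-12)

    def test_zero_at_sigma(self):
        assert self._pair_energy(3.2) == pytest.approx(0.0, abs=1e-12)

    def test_decay(self):
        assert abs(self._pair_energy(32.0)) < 1e-5 * 0.3

    def test_lorentz_berthelot_combining(self):
        sigma = np.array([3.0, 4.0])
        eps = np.array([0.1, 0.4])
        r = 0.5 * (3.0 + 4.0) * 2 ** (1 / 6)
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        e = lj_energy(coords, sigma, eps, [(0, 1)])
        assert e == pytest.approx(-np.sqrt(0.1 * 0.4), rel=1e-12)


class TestGeneralizedBorn:
    def test_born_ion_closed_form(self):
        """Single ion q=1, alpha=2 A, eps 1/78.5: the Born formula, -81.96."""
        e = gb_energy(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]),
                      eps_in=1.0, eps_solv=78.5)
        expected = -(COULOMB_CONSTANT / 2) * (1 - 1 / 78.5) / 2.0
        assert e == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(-81.96, abs=5e-3)

    def test_zero_charges_zero(self, rng):
        e = gb_energy(rng.normal(size=(4, 3)), np.zeros(4), np.ones(4))
        assert e == 0.0

    def test_equal_dielectrics_vanish(self, rng):
        e = gb_energy(rng.normal(scale=4, size=(3, 3)), np.array([1.0, -0.5, 0.3]),
                      np.ones(3) * 1.5, eps_in=4.0, eps_solv=4.0 + 1e-12)
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_zero_radius_on_charged_atom_rejected(self):
        with pytest.raises(ValueError, match="Born radius"):
            gb_energy(np.zeros((1, 3)), np.array([1.0]), np.array([0.0]))


class TestNonpolar:
    def test_published_coefficients(self):
        assert nonpolar_energy(100.0) == pytest.approx(0.72, rel=1e-12)
        assert nonpolar_energy(0.0) == 0.0
        assert nonpolar_energy(50.0) == pytest.approx(nonpolar_energy(100.0) / 2)


class TestSnapshotComponents:
    def test_separated_partners_vanish(self):
        """Ligand pulled far away: every interaction component ~ 0."""
        topo, ens, idx = generate_ligand_system(seed=0)
        coords = ens.coords[0].copy()
        coords[idx["ligand"]] += np.array([5000.0, 0.0, 0.0])
        comp = snapshot_components(coords, topo, idx)
        assert abs(comp.dele[0]) < 0.05
        assert abs(comp.dvdw[0]) < 1e-6
        assert abs(comp.dggb[0]) < 0.05
        assert abs(comp.dgsurf[0]) < 1e-6

    def test_cross_term_cancellation_oracle(self, rng):
        """Single-trajectory dEele/dEvdW equal direct cross sums exactly."""
        for seed in range(3):
            topo, ens, idx = generate_ligand_system(seed=seed)
            comp = snapshot_components(ens.coords[0], topo, idx)
            pairs = _cross_pairs(idx["receptor"], idx["ligand"])
            ele = coulomb_energy(ens.coords[0], topo.charge, pairs)
            vdw = lj_energy(ens.coords[0], topo.sigma, topo.epsilon, pairs)
            assert comp.dele[0] == pytest.approx(ele, abs=1e-9)
            assert comp.dvdw[0] == pytest.approx(vdw, abs=1e-9)

    def test_hand_computed_toy(self):
        """Two-bead receptor + one-bead ligand, every term by hand."""
        topo = make_topology(3)
        topo.charge = np.array([0.5, -0.5, 1.0])
        topo.sigma = np.array([3.0, 3.0, 3.0])
        topo.epsilon = np.array([0.2, 0.2, 0.2])
        topo.born_radius = np.array([1.5, 1.5, 1.5])
        topo.mass = np.full(3, 12.0)
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 5.0, 0]])
        idx = {"receptor": np.array([0, 1]), "ligand": np.array([2])}
        comp = snapshot_components(coords, topo, idx)
        r02, r12 = 5.0, np.sqrt(16 + 25)
        ele = COULOMB_CONSTANT * (0.5 * 1.0 / r02 + (-0.5) * 1.0 / r12)
        assert comp.dele[0] == pytest.approx(ele, abs=1e-9)

        def lj(r):
            return 4 * 0.2 * ((3.0 / r) ** 12 - (3.0 / r) ** 6)
        assert comp.dvdw[0] == pytest.approx(lj(r02) + lj(r12), abs=1e-12)

    def test_overlapping_index_sets_rejected(self):
        topo, ens, idx = generate_ligand_system(seed=0)
        bad = {"receptor": np.arange(10), "ligand": np.arange(5, 15)}
        with pytest.raises(ValueError, match="overlap"):
            snapshot_components(ens.coords[0], topo, bad)

    def test_identity_dh_equals_sum(self):
        topo, ens, idx = generate_ligand_system(seed=1, n_frames=3, noise_sigma=0.05)
        comp = ensemble_components(ens, idx)
        np.testing.assert_allclose(
            comp.dh, comp.dele + comp.dvdw + comp.dggb + comp.dgsurf, atol=1e-9)
        np.testing.assert_allclose(comp.dh, comp.dgpol + comp.dghydro, atol=1e-9)


class TestAggregation:
    @pytest.mark.parametrize("table,inhibitor,dgbind,exact", [
        (BRD4_TABLE, "H1B", -16.09, True),
        (BRD4_TABLE, "JQ1", -6.38, True),
        (BRD4_TABLE, "TVU", -16.85, True),
        (BRD9_TABLE, "H1B", -21.38, False),   # two-decimal input rounding
        (BRD9_TABLE, "JQ1", -11.94, True),
        (BRD9_TABLE, "TVU", -23.17, False),
    ])
    def test_published_tables_reproduced(self, table, inhibitor, dgbind, exact):
        row = table[inhibitor]
        comp = components_from_means(row["dele"][0], row["dvdw"][0],
                                     row["dggb"][0], row["dgsurf"][0])
        energy = aggregate_binding_free_energy(comp, row["-TdS"][0])
        tol = 1e-9 if exact else 0.011
        assert energy.dgbind == pytest.approx(dgbind, abs=tol)
        assert energy.dgpol == pytest.approx(row["dele"][0] + row["dggb"][0],
                                             abs=1e-9)

    def test_zero_components_zero_binding(self):
        comp = components_from_means(0.0, 0.0, 0.0, 0.0)
        assert aggregate_binding_free_energy(comp, 0.0).dgbind == 0.0

    def test_mean_and_std_over_frames(self, rng):
        vals = rng.normal(size=(4, 10))
        comp = EnergyComponents(*vals)
        energy = aggregate_binding_free_energy(comp, -1.0)
        assert energy.mean["dele"] == pytest.approx(vals[0].mean())
        assert energy.std["dvdw"] == pytest.approx(vals[1].std(ddof=1))
        assert energy.std["dvdw"] >= 0


class TestCompareSystems:
    @pytest.mark.parametrize("inhibitor,vdw,surf,fav,ent,dgb", [
        ("H1B", 6.96, 0.59, 7.55, 6.46, 5.29),
        ("JQ1", 11.86, 1.08, 12.94, 5.23, 5.56),
        ("TVU", 5.67, 0.36, 6.03, 3.24, 6.32),
    ])
    def test_published_cross_system_deltas(self, inhibitor, vdw, surf, fav,
                                           ent, dgb):
        """Strengthening of favorable forces and entropy penalty, per inhibitor."""
        a = binding_energy("BRD4", inhibitor)
        b = binding_energy("BRD9", inhibitor)
        delta = compare_systems(a, b)
        assert -delta["dvdw"] == pytest.approx(vdw, abs=1e-9)
        assert -delta["dgsurf"] == pytest.approx(surf, abs=1e-9)
        assert -delta["favorable_sum"] == pytest.approx(fav, abs=1e-9)
        assert delta["minus_t_ds"] == pytest.approx(ent, abs=1e-9)
        assert -delta["dgbind"] == pytest.approx(dgb, abs=0.011)

    def test_self_comparison_zero_and_antisymmetry(self):
        a = binding_energy("BRD4", "H1B")
        b = binding_energy("BRD9", "H1B")
        zero = compare_systems(a, a)
        assert all(v == 0.0 for v in zero.values())
        fwd = compare_systems(a, b)
        rev = compare_systems(b, a)
        for key in fwd:
            assert fwd[key] == pytest.approx(-rev[key], abs=1e-12)


class TestDecomposition:
    def test_salt_bridge_residue_is_top_and_key(self, toy_complex):
        topo, ens, idx = toy_complex
        table = per_residue_decomposition(ens, idx, n_frames=1)
        best = table.sort_values("total").iloc[0]
        salt_res = len(idx["receptor"]) // 2 + 1     # anchor bead, 1-based
        assert best.res_id == salt_res
        assert bool(best.key)

    def test_conservation_of_gas_phase_shares(self, toy_complex):
        topo, ens, idx = toy_complex
        table = per_residue_decomposition(ens, idx, n_frames=1)
        comp = snapshot_components(ens.coords[0], topo, idx)
        share_sum = (table.ele + table.vdw).sum()
        assert share_sum == pytest.approx(comp.dele[0] + comp.dvdw[0], abs=1e-6)

    def test_distant_neutral_residue_negligible(self):
        """A chargeless residue far from the ligand contributes ~0, not key."""
        topo = make_topology(4)
        topo.charge = np.array([0.3, 0.0, -0.4, 0.5])      # residue 2 neutral
        topo.sigma = np.full(4, 3.0)
        topo.epsilon = np.full(4, 0.2)
        topo.born_radius = np.full(4, 1.6)
        topo.mass = np.full(4, 12.0)
        coords = np.array([[0.0, 0, 0], [40.0, 0, 0], [4.0, 0, 0],
                           [0.0, 4.0, 0.0]])
        ens = make_ensemble(coords[None], topo)
        idx = {"receptor": np.array([0, 1, 2]), "ligand": np.array([3])}
        table = per_residue_decomposition(ens, idx, n_frames=1)
        far = table[table.res_id == 2].iloc[0]
        assert abs(far.total) < 0.01
        assert not far.key


class TestEntropy:
    def test_zero_fluctuation_zero_entropy(self, rng):
        base = rng.normal(size=(5, 3))
        ens = make_ensemble(np.stack([base] * 4))
        est = quasiharmonic_entropy(ens, superpose=False)
        assert est.minus_t_ds == pytest.approx(0.0, abs=1e-9)

    def test_1d_oscillator_closed_form(self, rng):
        """Single coordinate of variance sigma^2: Schlitter in closed form."""
        import mdbind.energetics as en
        sigma = 0.4
        coords = np.zeros((4000, 1, 3))
        coords[:, 0, 0] = rng.normal(scale=sigma, size=4000)
        ens = make_ensemble(coords, make_topology(1))
        est = quasiharmonic_entropy(ens, selection="all", superpose=False,
                                    temperature=300.0)
        var = coords[:, 0, 0].var()
        alpha = en._KB_SI * 300.0 * np.e ** 2 / en._HBAR_SI ** 2
        s = (0.5 * en._KB_SI * np.log1p(alpha * 12.0 * en._AMU_KG * var * en._A2_M2)
             * en._NA / en._J_PER_KCAL)
        assert est.minus_t_ds == pytest.approx(-300.0 * s, rel=1e-6)

    def test_monotone_in_fluctuation(self, rng):
        base = rng.normal(scale=5, size=(6, 3))
        ents = []
        for sigma in (0.1, 0.3, 0.6):
            frames = base[None] + rng.normal(scale=sigma, size=(200, 6, 3))
            est = quasiharmonic_entropy(make_ensemble(frames), superpose=False)
            ents.append(est.entropy)
        assert ents[0] < ents[1] < ents[2]


class TestExperimentalDg:
    def test_reference_ic50(self):
        assert dg_from_ic50(1.0, 300.0) == 0.0
        assert dg_from_ic50(1e-8, 300.0) == pytest.approx(-10.98, abs=5e-3)

    def test_tenfold_shift(self):
        shift = dg_from_ic50(1e-9, 300.0) - dg_from_ic50(1e-8, 300.0)
        assert shift == pytest.approx(-0.0019872 * 300.0 * np.log(10), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dg_from_ic50(0.0)
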