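"""Restraint thermodynamics, the separation term, and stage assembly."""

import math

import numpy as np
import pytest

from cycbind.georoute import (
    RestraintDefinition,
    SeparationInputs,
    StageResult,
    assemble_standard_free_energy,
    deltaG_to_kd,
    kd_to_deltaG,
    orientational_restraint_analytic,
    reference_stages,
    restraint_free_energy,
    separation_term,
)
from cycbind.pmf import PMFProfile
from cycbind.synth.toyroute import ToyBindingModel
from cycbind.thermo import ThermoState, standard_volume_A3


def _flat_pmf(lo, hi, spacing=0.01):
    grid = np.arange(lo, hi + spacing / 2, spacing)
    return PMFProfile(grid, np.zeros_like(grid), "raw")


class TestRestraintFreeEnergy:
    def test_zero_restraint_is_exactly_zero(self, thermo300):
        pmf = _flat_pmf(-5, 5)
        u = RestraintDefinition("rmsd", 0.0, 0.0)
        assert restraint_free_energy(pmf, u, "apply", thermo300) == 0.0

    def test_flat_pmf_gaussian_closed_form(self, thermo300):
        # stiff harmonic on a flat PMF of width L:
        # dG = -kT ln( sqrt(2 pi / (beta k)) / L )
        k, L = 10.0, 20.0
        pmf = _flat_pmf(-L / 2, L / 2)
        u = RestraintDefinition("rmsd", 0.0, k)
        dg = restraint_free_energy(pmf, u, "apply", thermo300)
        closed = -thermo300.kT * math.log(
            math.sqrt(2 * math.pi / (thermo300.beta * k)) / L
        )
        assert dg == pytest.approx(closed, abs=1e-4)

    def test_nonnegative_for_nonnegative_restraint(self, thermo300):
        rng = np.random.default_rng(2)
        grid = np.linspace(-4, 4, 801)
        pmf = PMFProfile(grid, np.abs(np.cumsum(rng.normal(0, 0.01, grid.size))), "raw")
        u = RestraintDefinition("rmsd", 0.5, 3.0)
        assert restraint_free_energy(pmf, u, "apply", thermo300) >= 0.0

    def test_apply_release_antisymmetry(self, thermo300):
        grid = np.linspace(-4, 4, 401)
        pmf = PMFProfile(grid, 0.3 * (grid - 1.0) ** 2, "raw")
        u = RestraintDefinition("rmsd", 0.0, 2.0)
        total = (restraint_free_energy(pmf, u, "apply", thermo300)
                 + restraint_free_energy(pmf, u, "release", thermo300))
        assert abs(total) < 1e-12

    def test_insufficient_domain_rejected(self, thermo300):
        pmf = _flat_pmf(-0.5, 0.5)  # weak restraint leaks past the boundary
        u = RestraintDefinition("rmsd", 0.0, 0.1)
        with pytest.raises(ValueError, match="extend"):
            restraint_free_energy(pmf, u, "apply", thermo300)

    def test_quadrature_refinement_stable(self, thermo300):
        u = RestraintDefinition("rmsd", 0.0, 5.0)
        coarse = restraint_free_energy(_flat_pmf(-10, 10, 0.02), u, "apply", thermo300)
        fine = restraint_free_energy(_flat_pmf(-10, 10, 0.01), u, "apply", thermo300)
        assert abs(fine - coarse) < 1e-4


class TestOrientationalStage:
    def _restraints(self, k):
        return {
            "euler_Theta": RestraintDefinition("euler_Theta", 90.0, k, "deg"),
            "euler_Phi": RestraintDefinition("euler_Phi", 0.0, k, "deg"),
            "euler_Psi": RestraintDefinition("euler_Psi", 0.0, k, "deg"),
        }

    def test_zero_force_constants_warn_and_return_zero(self, thermo300):
        with pytest.warns(UserWarning):
            res = orientational_restraint_analytic(self._restraints(0.0), thermo300)
        assert res.free_energy == 0.0
        assert res.uncertainty == 0.0

    def test_matches_monte_carlo_oracle(self, thermo300):
        k = 0.02
        res = orientational_restraint_analytic(self._restraints(k), thermo300)
        rng = np.random.default_rng(7)
        beta = thermo300.beta
        # sample (Theta, Phi, Psi) from the unrestrained measure sin(Theta),
        # accumulating in chunks so the MC error sits well under the tolerance
        total, n = 0.0, 0
        for _ in range(8):
            m = 4_000_000
            theta = np.degrees(np.arccos(rng.uniform(-1, 1, m)))
            phi = rng.uniform(-180, 180, m)
            psi = rng.uniform(-180, 180, m)
            total += np.exp(-beta * 0.5 * k * ((theta - 90.0) ** 2 + phi**2 + psi**2)).sum()
            n += m
        mc = -thermo300.kT * math.log(total / n)
        assert res.free_energy == pytest.approx(mc, abs=1e-3)

    def test_stiffer_restraints_cost_more(self, thermo300):
        weak = orientational_restraint_analytic(self._restraints(0.05), thermo300)
        stiff = orientational_restraint_analytic(self._restraints(0.10), thermo300)
        assert stiff.free_energy > weak.free_energy > 0


class TestSeparationTerm:
    def test_flat_pmf_unrestrained_limits(self, thermo300):
        grid = np.linspace(16.0, 26.0, 501)
        inputs = SeparationInputs(W=PMFProfile(grid, np.zeros_like(grid), "raw"))
        res = separation_term(inputs, thermo300)
        # I = r* - a = 10 and S* = 4 pi r*^2 in the unrestrained flat limit
        expected = -thermo300.kT * math.log(
            10.0 * 4 * math.pi * 26.0**2 / standard_volume_A3()
        )
        assert res.free_energy == pytest.approx(expected, abs=1e-6)

    def test_square_well_matches_brute_force(self, thermo300):
        grid = np.linspace(16.0, 26.0, 2001)
        w = np.where((grid >= 17.0) & (grid <= 18.0), -5.0, 0.0)
        stiff = 1.0  # kcal/mol/deg^2 on both direction angles
        u_theta = RestraintDefinition("polar_theta", 90.0, stiff, "deg")
        u_phi = RestraintDefinition("polar_phi", 0.0, stiff, "deg")
        inputs = SeparationInputs(W=PMFProfile(grid, w, "raw"), u_dir=(u_theta, u_phi))
        res = separation_term(inputs, thermo300)

        # independent two-line numeric integration of the same definition
        beta = thermo300.beta
        i_val = np.trapezoid(np.exp(-beta * (w - 0.0)), grid)
        th = np.linspace(0, np.pi, 20001)
        ph = np.linspace(-np.pi, np.pi, 20001)
        ang_t = np.trapezoid(np.sin(th) * np.exp(-beta * 0.5 * stiff * (np.degrees(th) - 90) ** 2), th)
        ang_p = np.trapezoid(np.exp(-beta * 0.5 * stiff * np.degrees(ph) ** 2), ph)
        expected = -thermo300.kT * math.log(26.0**2 * ang_t * ang_p * i_val / standard_volume_A3())
        assert res.free_energy == pytest.approx(expected, abs=1e-6)

    def test_deeper_well_more_negative(self, thermo300):
        grid = np.linspace(16.0, 26.0, 1001)
        shallow = np.where((grid >= 17.0) & (grid <= 18.0), -2.0, 0.0)
        deep = np.where((grid >= 17.0) & (grid <= 18.0), -6.0, 0.0)
        r_shallow = separation_term(SeparationInputs(W=PMFProfile(grid, shallow, "raw")), thermo300)
        r_deep = separation_term(SeparationInputs(W=PMFProfile(grid, deep, "raw")), thermo300)
        assert r_deep.free_energy < r_shallow.free_energy

    def test_w_must_cover_domain(self, thermo300):
        grid = np.linspace(18.0, 26.0, 101)
        with pytest.raises(ValueError, match="cover"):
            separation_term(SeparationInputs(W=PMFProfile(grid, np.zeros(101), "raw")),
                            thermo300)


class TestAssembly:
    def test_reference_stage_table_sums_to_minus_6_63(self, thermo300):
        result = assemble_standard_free_energy(reference_stages(), thermo300)
        assert result.total == pytest.approx(-6.63, abs=1e-12)

    def test_reference_quadrature_uncertainty(self, thermo300):
        result = assemble_standard_free_energy(reference_stages(), thermo300)
        assert result.total_uncertainty == pytest.approx(3.4577, abs=1e-4)
        assert round(result.total_uncertainty, 1) == 3.5

    def test_all_zero_stages(self, thermo300):
        stages = [StageResult(i, 0.0, 0.0) for i in range(1, 10)]
        result = assemble_standard_free_energy(stages, thermo300)
        assert result.total == 0.0
        assert result.total_uncertainty == 0.0
        assert result.kd == pytest.approx(1.0)

    def test_missing_and_duplicate_stages_named(self, thermo300):
        stages = [StageResult(i, 0.0) for i in range(1, 9)]
        with pytest.raises(ValueError, match="1-9"):
            assemble_standard_free_energy(stages, thermo300)
        stages = [StageResult(i, 0.0) for i in [1, 2, 3, 4, 5, 6, 7, 8, 8]]
        with pytest.raises(ValueError):
            assemble_standard_free_energy(stages, thermo300)

    def test_table_rendering_includes_total(self, thermo300):
        text = assemble_standard_free_energy(reference_stages(), thermo300).as_table()
        assert "-6.63" in text
        assert text.count("\n") == 10  # header + 9 stages + total


class TestKdConversion:
    def test_standard_state_zero(self, thermo300):
        assert deltaG_to_kd(0.0, thermo300) == pytest.approx(1.0)

    def test_micromolar_closed_form(self, thermo300):
        dg = -thermo300.kT * math.log(1e6)
        assert deltaG_to_kd(dg, thermo300) == pytest.approx(1e-6, rel=1e-12)

    def test_round_trip(self, thermo300):
        for dg in (-12.0, -6.63, 0.0, 3.0):
            assert kd_to_deltaG(deltaG_to_kd(dg, thermo300), thermo300) == pytest.approx(
                dg, abs=1e-12)

    def test_strictly_increasing(self, thermo300):
        dgs = np.linspace(-15, 5, 50)
        kds = [deltaG_to_kd(d, thermo300) for d in dgs]
        assert np.all(np.diff(kds) > 0)


class TestPathConsistency:
    def test_total_invariant_to_restraint_stiffness(self, thermo300):
        base = ToyBindingModel(thermo=thermo300).assemble()
        doubled = ToyBindingModel(k_conf=20.0, k_orient=0.1, k_dir=0.1,
                                  thermo=thermo300).assemble()
        assert abs(base.total - doubled.total) < 0.05

    def test_total_matches_separable_closed_form(self, thermo300):
        model = ToyBindingModel(thermo=thermo300)
        assert model.assemble().total == pytest.approx(model.analytic_total(), abs=1e-4)
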