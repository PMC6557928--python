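"""Steady states, stability, elasticities, control coefficients, sensitivities."""

import numpy as np
import pytest

from srcmkin.errors import ConfigurationError, ConvergenceError
from srcmkin.mca import (
    elasticity_matrix,
    find_steady_state,
    flux_control_coefficients,
    jacobian_eigenvalues,
    local_sensitivity,
)
from srcmkin.network import (
    Compartment,
    KineticModel,
    RateLaw,
    Reaction,
    Species,
    evaluate_fluxes,
)
from srcmkin.simulate import SimulationSettings

from conftest import (
    make_decay,
    make_fcc_toy,
    make_inflow_mm_sink,
    make_mm_depletion,
    make_random_gma_network,
)


def make_inflow_linear_sink(v0=1.0, k=2.0):
    return KineticModel(
        [Compartment("C")],
        [Species("X", "C", initial_concentration=0.1)],
        [
            Reaction("IN", {"X": 1}, RateLaw("GENERALIZED_MASS_ACTION", k=v0, exponents={})),
            Reaction("OUT", {"X": -1},
                     RateLaw("GENERALIZED_MASS_ACTION", k=k, exponents={"X": 1.0})),
        ],
    )


class TestSteadyState:
    def test_linear_sink_closed_form(self):
        ss = find_steady_state(make_inflow_linear_sink(v0=1.0, k=2.0))
        assert ss.state["X"] == pytest.approx(0.5, abs=1e-8)  # x* = v0/k
        assert ss.residual_norm < 1e-9
        assert ss.stable

    def test_mm_sink_closed_form(self):
        """x* = Km v0/(Vmax - v0) = 2*0.5/(1-0.5) = 2."""
        ss = find_steady_state(make_inflow_mm_sink(v0=0.5, vmax=1.0, km=2.0))
        assert ss.state["X"] == pytest.approx(2.0, abs=1e-7)

    def test_saturated_sink_has_no_steady_state(self):
        with pytest.raises(ConvergenceError) as err:
            find_steady_state(make_inflow_mm_sink(v0=1.5, vmax=1.0, km=2.0),
                              relax_horizon=50.0)
        assert err.value.best_residual > 0

    def test_fluxes_reported_at_root(self):
        ss = find_steady_state(make_inflow_linear_sink())
        np.testing.assert_allclose(ss.fluxes.to_numpy(), [1.0, 1.0], atol=1e-8)


class TestJacobianEigenvalues:
    def test_single_decay_eigenvalue(self):
        eig, stable = jacobian_eigenvalues(make_decay(k=0.3), [1.0])
        assert eig == pytest.approx([-0.3], abs=1e-6)
        assert stable

    def test_linear_cascade_matches_analytic_jacobian(self):
        """A -> B -> with J = [[-k1, 0], [k1, -k2]]: eigenvalues {-k1, -k2}."""
        k1, k2 = 0.8, 1.7
        m = KineticModel(
            [Compartment("C")],
            [Species("A", "C", initial_concentration=1.0),
             Species("B", "C", initial_concentration=0.5)],
            [Reaction("R1", {"A": -1, "B": 1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=k1, exponents={"A": 1.0})),
             Reaction("R2", {"B": -1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=k2, exponents={"B": 1.0}))],
        )
        eig, stable = jacobian_eigenvalues(m, [1.0, 0.5])
        np.testing.assert_allclose(sorted(eig.real), sorted([-k1, -k2]), atol=1e-6)
        assert stable

    def test_stability_verdict_at_steady_state(self):
        ss = find_steady_state(make_inflow_linear_sink(v0=1.0, k=2.0))
        assert ss.stable and ss.eigenvalues.real.max() == pytest.approx(-2.0, abs=1e-6)


class TestElasticities:
    def test_mm_elasticity_half_at_km(self):
        m = make_mm_depletion(vmax=1.0, km=0.5, s0=0.5)
        ca = elasticity_matrix(m, [0.5])
        assert ca.elasticities.loc["R", "S"] == pytest.approx(0.5)

    def test_gma_elasticity_equals_kinetic_order(self):
        m = make_decay(k=2.0)
        m.reactions[0].rate_law.exponents["A"] = 1.7
        m.invalidate_caches()
        ca = elasticity_matrix(m, [3.0])
        assert ca.elasticities.loc["D", "A"] == pytest.approx(1.7)
        # state-independence of the power-law elasticity
        ca2 = elasticity_matrix(m, [0.01])
        assert ca2.elasticities.loc["D", "A"] == pytest.approx(1.7)

    def test_absent_species_has_zero_elasticity(self, srcm_model):
        x = np.maximum(srcm_model.initial_state(), 0.1)
        ca = elasticity_matrix(srcm_model, x)
        assert ca.elasticities.loc["R13", "gly_c"] == 0.0  # glycine not in the MCR law

    def test_zero_flux_flagged_not_zeroed(self):
        m = make_mm_depletion(s0=0.0)
        ca = elasticity_matrix(m, [0.0])
        assert np.isnan(ca.elasticities.loc["R", "S"])
        assert ("R", "S") in ca.undefined

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_finite_difference_oracle(self, trial):
        """Analytic elasticities agree with central finite differences."""
        rng = np.random.default_rng(50 + trial)
        m = make_random_gma_network(rng)
        x = rng.uniform(0.5, 2.0, len(m.species))
        ca = elasticity_matrix(m, x)
        v0 = evaluate_fluxes(m, x)
        h = 1e-6
        for j, r in enumerate(m.reactions):
            for sid in r.rate_law.referenced_species():
                i = m.species_index(sid)
                xp, xm = x.copy(), x.copy()
                xp[i] *= 1 + h
                xm[i] *= 1 - h
                dvdx = (evaluate_fluxes(m, xp)[j] - evaluate_fluxes(m, xm)[j]) / (2 * h * x[i])
                expected = x[i] / v0[j] * dvdx
                assert ca.elasticities.iloc[j, i] == pytest.approx(expected, abs=1e-6)


class TestFluxControl:
    def test_two_step_reversible_closed_form(self):
        """C1 = k2/(krev+k2) = 0.75, C2 = krev/(krev+k2) = 0.25."""
        toy = make_fcc_toy(k1=2.0, krev=1.0, k2=3.0)
        ss = find_steady_state(toy)
        ca = flux_control_coefficients(toy, ss)
        assert ca.fcc.loc["E2", "E1"] == pytest.approx(0.75, abs=1e-3)
        assert ca.fcc.loc["E2", "E2"] == pytest.approx(0.25, abs=1e-3)

    def test_summation_theorem(self):
        toy = make_fcc_toy()
        ss = find_steady_state(toy)
        ca = flux_control_coefficients(toy, ss)
        np.testing.assert_allclose(ca.fcc.sum(axis=1).to_numpy(), 1.0, atol=1e-3)

    def test_connectivity_theorem(self):
        """sum_j C^J_j * eps_{j,X} = 0 for the internal metabolite."""
        toy = make_fcc_toy()
        ss = find_steady_state(toy)
        ca = flux_control_coefficients(toy, ss)
        eps = elasticity_matrix(toy, ss.state.to_numpy()).elasticities["X"]
        resid = float((ca.fcc.loc["E2"] * eps).sum())
        assert abs(resid) < 1e-3

    def test_supply_limited_irreversible_chain(self):
        """A -> X -> with clamped A: all control in the first step."""
        m = KineticModel(
            [Compartment("C")],
            [Species("A", "C", initial_concentration=1.0, boundary=True),
             Species("X", "C", initial_concentration=0.1)],
            [Reaction("E1", {"A": -1, "X": 1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=1.0, exponents={"A": 1.0})),
             Reaction("E2", {"X": -1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=2.0, exponents={"X": 1.0}))],
        )
        ss = find_steady_state(m)
        ca = flux_control_coefficients(m, ss)
        assert ca.fcc.loc["E2", "E1"] == pytest.approx(1.0, abs=1e-3)
        assert ca.fcc.loc["E2", "E2"] == pytest.approx(0.0, abs=1e-3)


class TestLocalSensitivity:
    def test_decay_rate_sensitivity_matches_analytic(self):
        """d/dk exp(-kt) = -t exp(-kt)."""
        m = make_decay(k=0.5, x0=1.0)
        res = local_sensitivity(m, SimulationSettings(t_end=5, interval=0.5), "D.k",
                                perturbation=0.01)
        analytic = -res.time * np.exp(-0.5 * res.time)
        np.testing.assert_allclose(res.sensitivity["A"].to_numpy(), analytic, atol=1e-4)

    def test_disconnected_parameter_has_no_effect(self):
        m = KineticModel(
            [Compartment("C")],
            [Species("A", "C", initial_concentration=1.0),
             Species("Z", "C", initial_concentration=0.0)],
            [Reaction("D", {"A": -1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=0.5, exponents={"A": 1.0})),
             Reaction("ZZ", {"Z": 1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=0.0, exponents={}))],
        )
        res = local_sensitivity(m, SimulationSettings(t_end=5, interval=1.0), "ZZ.k",
                                perturbation=0.5)
        # the dead inflow parameter moves only its own product pool
        np.testing.assert_allclose(res.sensitivity["A"].to_numpy(), 0.0, atol=1e-10)
        assert res.auc["A"] == pytest.approx(0.0, abs=1e-10)

    def test_central_difference_is_second_order(self):
        """Halving the step shrinks the error about fourfold (Richardson)."""
        m = make_decay(k=0.5, x0=1.0)
        settings = SimulationSettings(t_end=4, interval=0.5, rtol=1e-10, atol=1e-14)
        analytic = None
        errs = {}
        for p in (0.4, 0.2):
            res = local_sensitivity(m, settings, "D.k", perturbation=p)
            if analytic is None:
                analytic = -res.time * np.exp(-0.5 * res.time)
            errs[p] = np.max(np.abs(res.sensitivity["A"].to_numpy() - analytic))
        ratio = errs[0.4] / errs[0.2]
        assert 3.0 < ratio < 5.0

    def test_missing_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            local_sensitivity(make_decay(), SimulationSettings(t_end=1), "D.vmax")


class TestStepSizeVerification:
    def test_smooth_toy_has_no_step_unstable_entries(self):
        toy = make_fcc_toy()
        ss = find_steady_state(toy)
        ca = flux_control_coefficients(toy, ss, verify_steps=True)
        well_defined = [(r, e) for r in ca.fcc.index for e in ca.fcc.columns
                        if not np.isnan(ca.fcc.loc[r, e])]
        assert all(pair not in ca.undefined or np.isnan(ca.fcc.loc[pair])
                   for pair in well_defined)
        # the downstream flux's coefficients are step-size stable
        assert ("E2", "E1") not in ca.undefined
        assert ("E2", "E2") not in ca.undefined
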