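"""Rate laws, stoichiometry, mass-balance right-hand side and validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import srcmkin as sk
from srcmkin.errors import (
    ConfigurationError,
    ParameterDomainError,
    SingularityError,
    StructuralError,
)
from srcmkin.network import (
    Compartment,
    KineticModel,
    RateLaw,
    Reaction,
    Species,
    build_stoich_matrix,
    evaluate_fluxes,
    get_parameter,
    gma_rate,
    mm_rate,
    ode_rhs,
    set_parameter,
    validate_model,
)

from conftest import make_chain, make_interconversion, make_random_gma_network


class TestMichaelisMenten:
    @pytest.mark.parametrize(
        "vmax,km,s,expected",
        [
            (2.0, 0.5, 0.5, 1.0),   # half saturation: rate = Vmax/2 at S = Km
            (5.0, 1.0, 0.0, 0.0),   # zero substrate
            (1.0, 0.25, 0.75, 0.75),
        ],
    )
    def test_closed_form(self, vmax, km, s, expected):
        assert mm_rate(vmax, km, s) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "vmax,km,s", [(-1.0, 0.5, 1.0), (1.0, 0.0, 1.0), (1.0, 0.5, -0.1), (0.0, 1.0, 1.0)]
    )
    def test_domain_errors(self, vmax, km, s):
        with pytest.raises(ParameterDomainError):
            mm_rate(vmax, km, s)

    @given(
        vmax=st.floats(0.01, 100),
        km=st.floats(0.001, 50),
        s1=st.floats(0, 1e4),
        ds=st.floats(1e-6, 1e3),
    )
    def test_monotone_and_bounded(self, vmax, km, s1, ds):
        """Rate increases strictly with substrate and saturates below Vmax."""
        lo, hi = mm_rate(vmax, km, s1), mm_rate(vmax, km, s1 + ds)
        assert lo < hi < vmax


class TestGeneralizedMassAction:
    @pytest.mark.parametrize(
        "k,c,g,expected",
        [
            (2.0, [3.0], [1.0], 6.0),
            (1.0, [4.0], [0.5], 2.0),
            (5.0, [0.0, 2.0], [1.0, 1.0], 0.0),  # zero factor annihilates
            (3.0, [2.0], [0.0], 3.0),            # zero order: concentration-free
        ],
    )
    def test_power_law(self, k, c, g, expected):
        assert gma_rate(k, c, g) == pytest.approx(expected)

    def test_domain_and_singularity_errors(self):
        with pytest.raises(ParameterDomainError):
            gma_rate(-1.0, [1.0], [1.0])
        with pytest.raises(ParameterDomainError):
            gma_rate(1.0, [-0.5], [1.0])
        with pytest.raises(SingularityError):
            gma_rate(1.0, [0.0], [-1.0])

    @given(
        k=st.floats(0, 10),
        c=st.lists(st.floats(0, 10), min_size=1, max_size=4),
    )
    def test_unit_exponents_reduce_to_elementary_mass_action(self, k, c):
        expected = k * float(np.prod(c))
        assert gma_rate(k, c, [1.0] * len(c)) == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestStoichiometricMatrix:
    def test_linear_chain(self):
        sm = build_stoich_matrix(make_chain())
        assert sm.species_ids == ["A", "B", "Cp"]
        np.testing.assert_array_equal(sm.matrix, [[-1, 0], [1, -1], [0, 1]])

    def test_reversible_column_is_net(self):
        m = KineticModel(
            [Compartment("C")],
            [Species("A", "C", initial_concentration=1.0),
             Species("B", "C", initial_concentration=0.0)],
            [Reaction("R", {"A": -1, "B": 1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=1.0, exponents={"A": 1.0},
                              k_reverse=0.5, exponents_reverse={"B": 1.0}),
                      reversible=True)],
        )
        np.testing.assert_array_equal(build_stoich_matrix(m).matrix, [[-1], [1]])

    def test_boundary_species_excluded(self):
        m = make_chain()
        m.get_species("A").boundary = True
        m.invalidate_caches()
        sm = build_stoich_matrix(m)
        assert sm.species_ids == ["B", "Cp"]
        assert sm.shape == (2, 2)

    def test_closed_network_conserves_total(self):
        """1^T S = 0 for a closed interconversion network."""
        sm = build_stoich_matrix(make_interconversion())
        np.testing.assert_allclose(sm.matrix.sum(axis=0), 0.0)

    def test_unknown_species_rejected(self):
        m = make_chain()
        m.reactions[0].stoichiometry["ghost"] = 1.0
        m.invalidate_caches()
        with pytest.raises(StructuralError):
            build_stoich_matrix(m)


class TestFluxEvaluation:
    def test_two_step_chain(self):
        v = evaluate_fluxes(make_chain(k1=1.0, k2=2.0), [1.0, 1.0, 0.0])
        np.testing.assert_allclose(v, [1.0, 2.0])

    def test_all_zero_state_gives_zero_fluxes(self):
        v = evaluate_fluxes(make_chain(), [0.0, 0.0, 0.0])
        np.testing.assert_array_equal(v, [0.0, 0.0])

    def test_mm_reaction_at_half_saturation(self):
        m = KineticModel(
            [Compartment("C")],
            [Species("S", "C", initial_concentration=1.0),
             Species("P", "C", initial_concentration=0.0)],
            [Reaction("U", {"S": -1, "P": 1},
                      RateLaw("MICHAELIS_MENTEN", vmax=4.0, km={"S": 1.0})),
             Reaction("D", {"P": -1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=1.0, exponents={"P": 1.0}))],
        )
        v = evaluate_fluxes(m, [1.0, 0.0])
        np.testing.assert_allclose(v, [2.0, 0.0])  # Vmax/2 at S = Km

    def test_negative_state_rejected(self):
        with pytest.raises(ParameterDomainError):
            evaluate_fluxes(make_chain(), [-0.1, 1.0, 0.0])

    def test_boundary_clamp_applied_before_evaluation(self):
        m = make_chain()
        m.get_species("A").boundary = True
        m.get_species("A").initial_concentration = 2.0
        m.invalidate_caches()
        v = evaluate_fluxes(m, [0.0, 1.0, 0.0])  # A's entry overridden by clamp
        np.testing.assert_allclose(v, [2.0, 2.0])


class TestOdeRhs:
    def test_chain_by_hand(self):
        np.testing.assert_allclose(
            ode_rhs(make_chain(k1=1.0, k2=2.0), [1.0, 1.0, 0.0]), [-1.0, -1.0, 2.0]
        )

    def test_zero_at_steady_state(self):
        """Inflow/outflow balance: net production of each internal pool is zero."""
        m = make_interconversion(kf=0.7, kr=0.3)
        total = 2.5
        a_star = total * 0.3 / (0.7 + 0.3)
        np.testing.assert_allclose(
            ode_rhs(m, [a_star, total - a_star]), 0.0, atol=1e-12
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_explicit_matrix_product_oracle(self, trial):
        """S·v recomputed by brute force equals ode_rhs to 1e-12."""
        rng = np.random.default_rng(1000 + trial)
        m = make_random_gma_network(rng)
        state = rng.uniform(0.0, 3.0, len(m.species))
        # independent oracle: per-species sum of coefficient * power-law rate
        expected = np.zeros(len(m.species))
        for j, r in enumerate(m.reactions):
            law = r.rate_law
            rate = law.k
            for sid, g in law.exponents.items():
                c = state[m.species_index(sid)]
                rate = 0.0 if (c == 0 and g > 0) else rate * c**g
            for sid, coef in r.stoichiometry.items():
                expected[m.species_index(sid)] += coef * rate
        np.testing.assert_allclose(ode_rhs(m, state), expected, atol=1e-12)


class TestValidation:
    def test_shipped_model_with_full_table_is_clean(self, srcm_model):
        assert validate_model(srcm_model).ok

    def test_unknown_species_reference(self):
        m = make_chain()
        m.reactions[1].stoichiometry["ghost"] = 1.0
        report = validate_model(m)
        assert len(report) == 1 and "ghost" in report.violations[0]

    def test_nonpositive_km_flagged(self):
        m = KineticModel(
            [Compartment("C")],
            [Species("S", "C", initial_concentration=1.0)],
            [Reaction("R", {"S": -1}, RateLaw("MICHAELIS_MENTEN", vmax=1.0, km={"S": 0.0}))],
        )
        report = validate_model(m)
        assert len(report) == 1 and "km" in report.violations[0]

    def test_negative_initial_concentration_flagged(self):
        m = make_chain()
        m.get_species("B").initial_concentration = -1.0
        assert any("negative initial" in v for v in validate_model(m))

    def test_transporter_must_span_two_compartments(self):
        m = KineticModel(
            [Compartment("C1"), Compartment("C2")],
            [Species("A", "C1", initial_concentration=1.0),
             Species("B", "C1", initial_concentration=0.0)],
            [Reaction("T", {"A": -1, "B": 1},
                      RateLaw("GENERALIZED_MASS_ACTION", k=1.0, exponents={"A": 1.0}),
                      transporter_class="DIFFUSION")],
        )
        assert any("connects 1 compartments" in v for v in validate_model(m))


class TestParameterAccess:
    def test_round_trip(self, srcm_model):
        m = srcm_model.copy()
        set_parameter(m, "R13.vmax", 3.21)
        assert get_parameter(m, "R13.vmax") == 3.21
        set_parameter(m, "T7.k", 0.5)
        assert get_parameter(m, "T7.k") == 0.5
        km0 = get_parameter(m, "R2.km.gly_c")
        set_parameter(m, "R2.km.gly_c", km0 * 2)
        assert get_parameter(m, "R2.km.gly_c") == km0 * 2

    def test_missing_parameter_errors(self, srcm_model):
        with pytest.raises(ConfigurationError):
            get_parameter(srcm_model, "R13.k")          # MM reaction has no k
        with pytest.raises(ConfigurationError):
            get_parameter(srcm_model, "R13.km.ghost")
        with pytest.raises(StructuralError):
            get_parameter(srcm_model, "R99.vmax")
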