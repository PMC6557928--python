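"""Shared toy-model factories and the session-scoped SRCM fixture."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import srcmkin as sk
from srcmkin.network import Compartment, KineticModel, RateLaw, Reaction, Species

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_decay(k: float = 0.1, x0: float = 1.0) -> KineticModel:
    """First-order decay A -> (sink), dx/dt = -k x."""
    return KineticModel(
        [Compartment("C")],
        [Species("A", "C", initial_concentration=x0)],
        [Reaction("D", {"A": -1}, RateLaw("GENERALIZED_MASS_ACTION", k=k, exponents={"A": 1.0}))],
    )


def make_chain(k1: float = 1.0, k2: float = 2.0, a0: float = 1.0, b0: float = 1.0) -> KineticModel:
    """Linear conversion chain A -> B -> C with mass-action steps."""
    return KineticModel(
        [Compartment("C")],
        [
            Species("A", "C", initial_concentration=a0),
            Species("B", "C", initial_concentration=b0),
            Species("Cp", "C", initial_concentration=0.0),
        ],
        [
            Reaction("R1", {"A": -1, "B": 1},
                     RateLaw("GENERALIZED_MASS_ACTION", k=k1, exponents={"A": 1.0})),
            Reaction("R2", {"B": -1, "Cp": 1},
                     RateLaw("GENERALIZED_MASS_ACTION", k=k2, exponents={"B": 1.0})),
        ],
    )


def make_interconversion(kf: float = 0.7, kr: float = 0.3) -> KineticModel:
    """Closed two-pool interconversion A <-> B (two irreversible reactions)."""
    return KineticModel(
        [Compartment("C")],
        [
            Species("A", "C", initial_concentration=2.0),
            Species("B", "C", initial_concentration=0.5),
        ],
        [
            Reaction("F", {"A": -1, "B": 1},
                     RateLaw("GENERALIZED_MASS_ACTION", k=kf, exponents={"A": 1.0})),
            Reaction("B", {"B": -1, "A": 1},
                     RateLaw("GENERALIZED_MASS_ACTION", k=kr, exponents={"B": 1.0})),
        ],
    )


def make_mm_depletion(vmax: float = 1.0, km: float = 0.5, s0: float = 10.0) -> KineticModel:
    """Single Michaelis–Menten consumption S -> (sink)."""
    return KineticModel(
        [Compartment("C")],
        [Species("S", "C", initial_concentration=s0)],
        [Reaction("R", {"S": -1}, RateLaw("MICHAELIS_MENTEN", vmax=vmax, km={"S": km}))],
    )


def make_inflow_mm_sink(v0: float = 0.5, vmax: float = 1.0, km: float = 2.0) -> KineticModel:
    """Constant inflow v0 into a Michaelis–Menten sink; x* = km*v0/(vmax-v0)."""
    return KineticModel(
        [Compartment("C")],
        [Species("X", "C", initial_concentration=0.1)],
        [
            Reaction("IN", {"X": 1}, RateLaw("GENERALIZED_MASS_ACTION", k=v0, exponents={})),
            Reaction("OUT", {"X": -1}, RateLaw("MICHAELIS_MENTEN", vmax=vmax, km={"X": km})),
        ],
    )


def make_fcc_toy(k1: float = 2.0, krev: float = 1.0, k2: float = 3.0) -> KineticModel:
    """A (clamped) <-> X -> (sink): closed-form control coefficients
    C1 = k2/(krev+k2), C2 = krev/(krev+k2)."""
    return KineticModel(
        [Compartment("C")],
        [
            Species("A", "C", initial_concentration=1.0, boundary=True),
            Species("X", "C", initial_concentration=0.1),
        ],
        [
            Reaction("E1", {"A": -1, "X": 1},
                     RateLaw("GENERALIZED_MASS_ACTION", k=k1, exponents={"A": 1.0},
                             k_reverse=krev, exponents_reverse={"X": 1.0}),
                     reversible=True),
            Reaction("E2", {"X": -1},
                     RateLaw("GENERALIZED_MASS_ACTION", k=k2, exponents={"X": 1.0})),
        ],
    )


def make_random_gma_network(rng: np.random.Generator, n_species: int = 4,
                            n_reactions: int = 5) -> KineticModel:
    """Random mass-action network for oracle-equivalence property tests."""
    species = [
        Species(f"S{i}", "C", initial_concentration=float(rng.uniform(0.1, 2.0)))
        for i in range(n_species)
    ]
    reactions = []
    for j in range(n_reactions):
        picks = rng.choice(n_species, size=2, replace=False)
        stoich = {f"S{picks[0]}": -1.0, f"S{picks[1]}": 1.0}
        exps = {f"S{picks[0]}": float(rng.uniform(0.5, 2.0))}
        reactions.append(
            Reaction(f"R{j}", stoich,
                     RateLaw("GENERALIZED_MASS_ACTION", k=float(rng.uniform(0.1, 3.0)),
                             exponents=exps))
        )
    return KineticModel([Compartment("C")], species, reactions)


@pytest.fixture(scope="session")
def srcm_table():
    return sk.generate_parameter_table(seed=0)


@pytest.fixture(scope="session")
def srcm_model(srcm_table):
    return sk.build_srcm_model(srcm_table)


@pytest.fixture(scope="session")
def pair_model(srcm_model):
    return sk.apply_scenario(srcm_model, sk.ScenarioSpec("PAIR"))
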