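"""Compartmental kinetic networks: domain types, rate laws, stoichiometry, ODE right-hand side.

A :class:`KineticModel` is a set of compartments, species and reactions.
Species may be *boundary* (clamped concentration, excluded from mass
balance — the model's input vector) or internal (mass-balanced).  Reaction
rate laws are either Michaelis–Menten (product of saturation terms over the
driving substrates, Vmax scaled by modifier/enzyme levels) or generalized
mass action (power law with arbitrary real kinetic orders, optionally
reversible as a net forward-minus-reverse law).

All concentrations are in mmol/ml and all fluxes in mmol/min/ml; every
compartment has unit volume so amount and concentration balances coincide.
"""

from __future__ import annotations

import copy as _copy
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ParameterDomainError, SingularityError, StructuralError

__all__ = [
    "RateLawKind",
    "TransporterClass",
    "Compartment",
    "Species",
    "RateLaw",
    "Reaction",
    "KineticModel",
    "StoichiometricMatrix",
    "ValidationReport",
    "mm_rate",
    "gma_rate",
    "build_stoich_matrix",
    "evaluate_fluxes",
    "ode_rhs",
    "validate_model",
    "get_parameter",
    "set_parameter",
    "list_parameters",
]


class RateLawKind(str, enum.Enum):
    MICHAELIS_MENTEN = "MICHAELIS_MENTEN"
    GENERALIZED_MASS_ACTION = "GENERALIZED_MASS_ACTION"


class TransporterClass(str, enum.Enum):
    DIFFUSION = "DIFFUSION"
    SYMPORTER = "SYMPORTER"
    PROTON_TRANSLOCATION = "PROTON_TRANSLOCATION"
    ABC = "ABC"
    FNT = "FNT"
    AAPO = "AAPO"
    DAACS = "DAACS"


@dataclass(frozen=True)
class Compartment:
    id: str
    label: str = ""


@dataclass
class Species:
    """A metabolite, carrier or enzyme pool belonging to one compartment.

    Boundary species have clamped concentration: they are held at
    ``initial_concentration`` throughout a simulation and excluded from the
    stoichiometric mass balance.
    """

    id: str
    compartment: str
    name: str = ""
    initial_concentration: float = 0.0
    charge: int = 0
    boundary: bool = False


@dataclass
class RateLaw:
    """Michaelis–Menten or generalized-mass-action kinetics.

    MM:  v = vmax * prod_m (c_m / c_m0) * prod_s c_s / (km_s + c_s)
         over driving substrates ``km`` and modifier species (enzymes) whose
         level scales vmax relative to its declared initial level.
    GMA: v = k * prod_i c_i ** g_i  (minus an analogous reverse term when
         ``k_reverse`` is set).
    """

    kind: RateLawKind
    vmax: float | None = None
    km: dict[str, float] = field(default_factory=dict)
    k: float | None = None
    exponents: dict[str, float] = field(default_factory=dict)
    k_reverse: float | None = None
    exponents_reverse: dict[str, float] = field(default_factory=dict)
    modifiers: tuple[str, ...] = ()

    def __post_init__(self):
        self.kind = RateLawKind(self.kind)
        self.modifiers = tuple(self.modifiers)

    def referenced_species(self) -> set[str]:
        refs = set(self.km) | set(self.exponents) | set(self.exponents_reverse)
        refs.update(self.modifiers)
        return refs


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    rate_law: RateLaw
    name: str = ""
    reversible: bool = False
    ec_number: str | None = None
    transporter_class: TransporterClass | None = None

    def __post_init__(self):
        if self.transporter_class is not None:
            self.transporter_class = TransporterClass(self.transporter_class)

    @property
    def is_transport(self) -> bool:
        return self.transporter_class is not None

    def referenced_species(self) -> set[str]:
        return set(self.stoichiometry) | self.rate_law.referenced_species()


@dataclass
class StoichiometricMatrix:
    """m x n signed coefficient matrix over internal species and reactions."""

    species_ids: list[str]
    reaction_ids: list[str]
    matrix: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __iter__(self):
        return iter(self.violations)

    def __len__(self):
        return len(self.violations)


class KineticModel:
    """A validated-on-demand compartmental kinetic network."""

    def __init__(
        self,
        compartments: Iterable[Compartment],
        species: Iterable[Species],
        reactions: Iterable[Reaction],
        metadata: Mapping[str, object] | None = None,
    ):
        self.compartments: list[Compartment] = list(compartments)
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        self.metadata: dict = dict(metadata or {})
        self.metadata.setdefault("units", "mmol, ml, min (fluxes mmol/min/ml)")
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._sidx = {s.id: i for i, s in enumerate(self.species)}
        self._ridx = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups ---------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def species_index(self, sid: str) -> int:
        try:
            return self._sidx[sid]
        except KeyError:
            raise StructuralError(f"unknown species id {sid!r}") from None

    def get_species(self, sid: str) -> Species:
        return self.species[self.species_index(sid)]

    def get_reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._ridx[rid]]
        except KeyError:
            raise StructuralError(f"unknown reaction id {rid!r}") from None

    def internal_species(self) -> list[Species]:
        return [s for s in self.species if not s.boundary]

    def boundary_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.species) if s.boundary], dtype=int)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], dtype=float)

    def copy(self) -> "KineticModel":
        m = _copy.deepcopy(self)
        m.invalidate_caches()
        return m

    def invalidate_caches(self) -> None:
        """Drop derived arrays; call after mutating laws, species or boundaries."""
        self.__dict__.pop("_stoich_full", None)
        self.__dict__.pop("_eval_cache", None)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"KineticModel({len(self.compartments)} compartments, "
            f"{len(self.species)} species, {len(self.reactions)} reactions)"
        )


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def mm_rate(vmax: float, km: float, s: float) -> float:
    """Irreversible Michaelis–Menten rate vmax*s/(km+s), in mmol/min/ml.

    Saturates at ``vmax``; equals vmax/2 at the half-saturation point s=km.
    """
    if vmax <= 0:
        raise ParameterDomainError(f"vmax must be positive, got {vmax}")
    if km <= 0:
        raise ParameterDomainError(f"km must be positive, got {km}")
    if s < 0:
        raise ParameterDomainError(f"substrate concentration must be >= 0, got {s}")
    return vmax * s / (km + s)


def gma_rate(k: float, concentrations: Sequence[float], exponents: Sequence[float]) -> float:
    """Generalized mass action (power-law) rate k * prod c_i**g_i.

    Defined as 0 whenever a factor has zero concentration and positive
    kinetic order; zero raised to a negative order is a singularity.
    """
    if k < 0:
        raise ParameterDomainError(f"rate constant must be >= 0, got {k}")
    conc = np.asarray(concentrations, dtype=float)
    expo = np.asarray(exponents, dtype=float)
    if conc.shape != expo.shape:
        raise ConfigurationError("concentrations and exponents must have equal length")
    if np.any(conc < 0):
        raise ParameterDomainError("concentrations must be >= 0")
    if not np.all(np.isfinite(expo)):
        raise ParameterDomainError("kinetic orders must be finite")
    rate = k
    for c, g in zip(conc, expo):
        if c == 0.0:
            if g > 0:
                return 0.0
            if g < 0:
                raise SingularityError("zero concentration raised to a negative kinetic order")
            continue  # g == 0 contributes a factor of 1
        rate *= c ** g
    return rate


def _law_rate(law: RateLaw, conc_of, reversible: bool) -> float:
    """Evaluate one rate law given a concentration lookup ``conc_of(sid)``."""
    if law.kind is RateLawKind.MICHAELIS_MENTEN:
        if law.vmax is None:
            raise ConfigurationError("Michaelis–Menten law missing vmax")
        v = law.vmax
        for sid, km in law.km.items():
            s = conc_of(sid)
            v *= mm_rate(1.0, km, s) if s > 0 else 0.0
        for sid in law.modifiers:
            c, c0 = conc_of(sid), conc_of(sid, initial=True)
            if c0 > 0:
                v *= c / c0
        return v
    # generalized mass action
    if law.k is None:
        raise ConfigurationError("mass-action law missing rate constant k")
    ids = list(law.exponents)
    v = gma_rate(law.k, [conc_of(i) for i in ids], [law.exponents[i] for i in ids])
    if reversible and law.k_reverse is not None:
        ids_r = list(law.exponents_reverse)
        v -= gma_rate(
            law.k_reverse, [conc_of(i) for i in ids_r], [law.exponents_reverse[i] for i in ids_r]
        )
    return v


# ---------------------------------------------------------------------------
# model-level evaluation
# ---------------------------------------------------------------------------

def build_stoich_matrix(model: KineticModel) -> StoichiometricMatrix:
    """Signed stoichiometry over *internal* species, in declaration order."""
    internal = model.internal_species()
    row = {s.id: i for i, s in enumerate(internal)}
    mat = np.zeros((len(internal), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for sid, coef in rxn.stoichiometry.items():
            if sid not in model._sidx:
                raise StructuralError(f"reaction {rxn.id!r} references unknown species {sid!r}")
            if sid in row:
                mat[row[sid], j] = coef
    return StoichiometricMatrix([s.id for s in internal], model.reaction_ids, mat)


def _clamped_state(model: KineticModel, state: np.ndarray) -> np.ndarray:
    x = np.array(state, dtype=float)
    for i in model.boundary_indices():
        x[i] = model.species[i].initial_concentration
    return x


class _EvalCache:
    """Vectorized rate-law evaluation arrays for a fixed model structure."""

    def __init__(self, model: KineticModel):
        self.init = model.initial_state()
        self.bidx = model.boundary_indices()
        n = len(model.reactions)
        self.base = np.zeros(n)
        self.rev_base = np.zeros(n)
        mm_rows, mm_cols, mm_km = [], [], []
        mod_rows, mod_cols, mod_init = [], [], []
        gma_rows, gma_cols, gma_exp = [], [], []
        rev_rows, rev_cols, rev_exp = [], [], []
        self.has_reverse = False
        for j, r in enumerate(model.reactions):
            law = r.rate_law
            if law.kind is RateLawKind.MICHAELIS_MENTEN:
                if law.vmax is None:
                    raise ConfigurationError(f"reaction {r.id!r}: Michaelis–Menten law missing vmax")
                self.base[j] = law.vmax
                for sid, km in law.km.items():
                    mm_rows.append(j)
                    mm_cols.append(model.species_index(sid))
                    mm_km.append(km)
                for sid in law.modifiers:
                    i = model.species_index(sid)
                    if self.init[i] > 0:
                        mod_rows.append(j)
                        mod_cols.append(i)
                        mod_init.append(self.init[i])
            else:
                if law.k is None:
                    raise ConfigurationError(f"reaction {r.id!r}: mass-action law missing k")
                self.base[j] = law.k
                for sid, g in law.exponents.items():
                    gma_rows.append(j)
                    gma_cols.append(model.species_index(sid))
                    gma_exp.append(g)
                if r.reversible and law.k_reverse is not None:
                    self.has_reverse = True
                    self.rev_base[j] = law.k_reverse
                    for sid, g in law.exponents_reverse.items():
                        rev_rows.append(j)
                        rev_cols.append(model.species_index(sid))
                        rev_exp.append(g)
        asarr = lambda v, dt=float: np.asarray(v, dtype=dt)
        self.mm = (asarr(mm_rows, int), asarr(mm_cols, int), asarr(mm_km))
        self.mod = (asarr(mod_rows, int), asarr(mod_cols, int), asarr(mod_init))
        self.gma = (asarr(gma_rows, int), asarr(gma_cols, int), asarr(gma_exp))
        self.rev = (asarr(rev_rows, int), asarr(rev_cols, int), asarr(rev_exp))

    def fluxes(self, state: np.ndarray) -> np.ndarray:
        x = state.copy()
        if self.bidx.size:
            x[self.bidx] = self.init[self.bidx]
        np.maximum(x, 0.0, out=x)
        f = self.base.copy()
        rows, cols, km = self.mm
        if rows.size:
            xs = x[cols]
            np.multiply.at(f, rows, xs / (km + xs))
        rows, cols, c0 = self.mod
        if rows.size:
            np.multiply.at(f, rows, x[cols] / c0)
        rows, cols, g = self.gma
        if rows.size:
            with np.errstate(divide="ignore"):
                pw = x[cols] ** g
            if not np.all(np.isfinite(pw)):
                raise SingularityError("zero concentration raised to a negative kinetic order")
            np.multiply.at(f, rows, pw)
        if self.has_reverse:
            r = self.rev_base.copy()
            rows, cols, g = self.rev
            if rows.size:
                with np.errstate(divide="ignore"):
                    pw = x[cols] ** g
                if not np.all(np.isfinite(pw)):
                    raise SingularityError("zero concentration raised to a negative kinetic order")
                np.multiply.at(r, rows, pw)
            f -= r
        return f


def _compiled(model: KineticModel) -> _EvalCache:
    cache = getattr(model, "_eval_cache", None)
    if cache is None:
        cache = _EvalCache(model)
        model._eval_cache = cache
    return cache


def evaluate_fluxes(model: KineticModel, state: Sequence[float]) -> np.ndarray:
    """One flux per reaction (mmol/min/ml) at the given concentration state.

    Boundary clamps are applied before evaluation; rate-law kind dispatch
    per reaction.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (len(model.species),):
        raise ConfigurationError(
            f"state length {x.shape} does not match species count {len(model.species)}"
        )
    if np.any(x < 0):
        raise ParameterDomainError("state concentrations must be >= 0")
    return _compiled(model).fluxes(x)


def ode_rhs(model: KineticModel, state: Sequence[float], t: float = 0.0) -> np.ndarray:
    """Mass balance dx/dt = S·v over internal species; boundary rows are 0."""
    v = evaluate_fluxes(model, state)
    sm = _cached_stoich_full(model)
    return sm @ v


def _cached_stoich_full(model: KineticModel) -> np.ndarray:
    """Full species x reactions matrix with zero rows for boundary species."""
    cache = getattr(model, "_stoich_full", None)
    if cache is not None and cache.shape == (len(model.species), len(model.reactions)):
        return cache
    mat = np.zeros((len(model.species), len(model.reactions)))
    bidx = set(model.boundary_indices().tolist())
    for j, rxn in enumerate(model.reactions):
        for sid, coef in rxn.stoichiometry.items():
            i = model.species_index(sid)
            if i not in bidx:
                mat[i, j] = coef
    model._stoich_full = mat
    return mat


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: KineticModel) -> ValidationReport:
    """Collect every invariant violation; an empty report means usable."""
    v: list[str] = []
    comp_ids = [c.id for c in model.compartments]
    if len(set(comp_ids)) != len(comp_ids):
        v.append("duplicate compartment ids")
    sids = model.species_ids
    if len(set(sids)) != len(sids):
        v.append("duplicate species ids")
    rids = model.reaction_ids
    if len(set(rids)) != len(rids):
        v.append("duplicate reaction ids")
    comp_set = set(comp_ids)
    for s in model.species:
        if s.compartment not in comp_set:
            v.append(f"species {s.id!r}: unknown compartment {s.compartment!r}")
        if s.initial_concentration < 0:
            v.append(f"species {s.id!r}: negative initial concentration")

    referenced: set[str] = set()
    for r in model.reactions:
        if not any(c != 0 for c in r.stoichiometry.values()):
            v.append(f"reaction {r.id!r}: no nonzero stoichiometric coefficient")
        for sid in r.referenced_species():
            if sid not in model._sidx:
                v.append(f"reaction {r.id!r}: unknown species {sid!r}")
            else:
                referenced.add(sid)
        law = r.rate_law
        if law.kind is RateLawKind.MICHAELIS_MENTEN:
            if law.vmax is None:
                v.append(f"reaction {r.id!r}: missing vmax")
            elif law.vmax <= 0:
                v.append(f"reaction {r.id!r}: vmax must be positive")
            if not law.km:
                v.append(f"reaction {r.id!r}: Michaelis–Menten law with no driving substrate")
            for sid, km in law.km.items():
                if km <= 0:
                    v.append(f"reaction {r.id!r}: km for {sid!r} must be positive")
            if r.reversible:
                v.append(f"reaction {r.id!r}: reversible Michaelis–Menten laws are not supported")
        else:
            if law.k is None:
                v.append(f"reaction {r.id!r}: missing rate constant k")
            elif law.k < 0:
                v.append(f"reaction {r.id!r}: rate constant k must be >= 0")
            for sid, g in law.exponents.items():
                if not math.isfinite(g):
                    v.append(f"reaction {r.id!r}: non-finite kinetic order for {sid!r}")
        if r.is_transport:
            comps = {
                model.get_species(sid).compartment
                for sid in r.stoichiometry
                if sid in model._sidx
            }
            if len(comps) != 2:
                v.append(
                    f"transport reaction {r.id!r} connects {len(comps)} compartments (expected 2)"
                )
    for s in model.internal_species():
        if s.id not in referenced:
            v.append(f"internal species {s.id!r} appears in no reaction")
    return ValidationReport(v)


# ---------------------------------------------------------------------------
# parameter addressing ("R5.vmax", "R3.km.gly_c", "T1.k", "R9.exponent.co2_m")
# ---------------------------------------------------------------------------

def _resolve(model: KineticModel, pid: str):
    parts = pid.split(".")
    if len(parts) < 2:
        raise ConfigurationError(f"malformed parameter id {pid!r}")
    law = model.get_reaction(parts[0]).rate_law
    return law, parts[1:]


def get_parameter(model: KineticModel, pid: str) -> float:
    law, rest = _resolve(model, pid)
    name = rest[0]
    if name in ("vmax", "k", "k_reverse"):
        val = getattr(law, name)
        if val is None:
            raise ConfigurationError(f"parameter {pid!r} is not set")
        return val
    if name in ("km", "exponent", "exponent_reverse") and len(rest) == 2:
        table = {"km": law.km, "exponent": law.exponents, "exponent_reverse": law.exponents_reverse}[name]
        if rest[1] not in table:
            raise ConfigurationError(f"parameter {pid!r} does not exist")
        return table[rest[1]]
    raise ConfigurationError(f"malformed parameter id {pid!r}")


def set_parameter(model: KineticModel, pid: str, value: float) -> None:
    model.invalidate_caches()
    law, rest = _resolve(model, pid)
    name = rest[0]
    if name in ("vmax", "k", "k_reverse"):
        if getattr(law, name) is None:
            raise ConfigurationError(f"parameter {pid!r} is not set")
        setattr(law, name, float(value))
        return
    if name in ("km", "exponent", "exponent_reverse") and len(rest) == 2:
        table = {"km": law.km, "exponent": law.exponents, "exponent_reverse": law.exponents_reverse}[name]
        if rest[1] not in table:
            raise ConfigurationError(f"parameter {pid!r} does not exist")
        table[rest[1]] = float(value)
        return
    raise ConfigurationError(f"malformed parameter id {pid!r}")


def list_parameters(model: KineticModel) -> list[str]:
    out: list[str] = []
    for r in model.reactions:
        law = r.rate_law
        if law.kind is RateLawKind.MICHAELIS_MENTEN:
            out.append(f"{r.id}.vmax")
            out.extend(f"{r.id}.km.{sid}" for sid in law.km)
        else:
            out.append(f"{r.id}.k")
            out.extend(f"{r.id}.exponent.{sid}" for sid in law.exponents)
            if law.k_reverse is not None:
                out.append(f"{r.id}.k_reverse")
                out.extend(f"{r.id}.exponent_reverse.{sid}" for sid in law.exponents_reverse)
    return out
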