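"""Synthetic study inputs: kinetic-parameter tables, gelatin feeds, noisy time courses.

Nothing in the package downloads data.  The parameter generator draws
log-uniform kinetic constants per reaction of a network structure, the feed
generator reproduces the gelatin-hydrolysate amino-acid composition, and the
observation generator adds multiplicative lognormal noise to deterministic
trajectories for parameter-recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "ParameterTable",
    "SyntheticDataset",
    "DEFAULT_RANGES",
    "GELATIN_COMPOSITION",
    "generate_parameter_table",
    "gelatin_feed",
    "generate_observations",
]

#: log-uniform draw ranges for kinetic constants (mmol, ml, min units)
DEFAULT_RANGES = {
    "km": (0.01, 10.0),     # mmol/ml
    "vmax": (0.1, 10.0),    # mmol/min/ml
    "k": (0.01, 10.0),      # 1/min for first-order transport
}

#: mass fractions of the major amino acids in pure gelatin hydrolysate
GELATIN_COMPOSITION = {"glycine": 0.214, "proline": 0.124, "alanine": 0.089}

_KINETIC_COLUMNS = ["reaction", "kind", "enzyme", "substrate", "km", "vmax", "k", "exponent"]


@dataclass
class ParameterTable:
    """Per-reaction kinetic constants plus initial concentrations.

    ``kinetics`` holds one row per (reaction, driving substrate): MM rows
    carry ``vmax``/``km``, mass-action rows carry ``k``/``exponent``.
    ``initials`` holds initial metabolite and enzyme concentrations.  The
    schema mirrors a kinetic-parameter supplement (reaction id, enzyme,
    substrate, Km, Vmax, initial concentration); values generated by
    :func:`generate_parameter_table` are synthetic stand-ins.
    """

    kinetics: pd.DataFrame
    initials: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["species", "initial_concentration"])
    )
    metadata: dict = field(default_factory=dict)

    def reactions(self) -> list[str]:
        return list(self.kinetics["reaction"].unique())

    def _rows(self, rid: str) -> pd.DataFrame:
        rows = self.kinetics[self.kinetics["reaction"] == rid]
        if rows.empty:
            raise ConfigurationError(f"parameter table has no rows for reaction {rid!r}")
        return rows

    def vmax_of(self, rid: str) -> float:
        return float(self._rows(rid)["vmax"].iloc[0])

    def km_of(self, rid: str) -> dict[str, float]:
        rows = self._rows(rid)
        return {r.substrate: float(r.km) for r in rows.itertuples() if pd.notna(r.km)}

    def k_of(self, rid: str) -> float:
        return float(self._rows(rid)["k"].iloc[0])

    def exponents_of(self, rid: str) -> dict[str, float]:
        rows = self._rows(rid)
        return {r.substrate: float(r.exponent) for r in rows.itertuples() if pd.notna(r.exponent)}

    def initial_concentrations(self) -> dict[str, float]:
        return dict(
            zip(self.initials["species"], self.initials["initial_concentration"].astype(float))
        )

    # -- delimited-table round trip -------------------------------------
    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(prefix)
        kin = prefix.with_name(prefix.name + "_kinetics.csv")
        ini = prefix.with_name(prefix.name + "_initials.csv")
        self.kinetics.to_csv(kin, index=False)
        self.initials.to_csv(ini, index=False)
        return kin, ini

    @classmethod
    def read(cls, prefix: str | Path) -> "ParameterTable":
        prefix = Path(prefix)
        kin = pd.read_csv(prefix.with_name(prefix.name + "_kinetics.csv"))
        ini_path = prefix.with_name(prefix.name + "_initials.csv")
        ini = (
            pd.read_csv(ini_path)
            if ini_path.exists()
            else pd.DataFrame(columns=["species", "initial_concentration"])
        )
        return cls(kin, ini)


@dataclass
class SyntheticDataset:
    """Noisy observed time courses in tidy form (time, species, replicate, value)."""

    data: pd.DataFrame
    noise_cv: float
    seed: int
    species: list[str] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["time"].unique())

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path


def _check_ranges(ranges: dict) -> dict:
    merged = dict(DEFAULT_RANGES)
    merged.update(ranges or {})
    for name, (lo, hi) in merged.items():
        if not (0 < lo < hi):
            raise ConfigurationError(f"range for {name!r} must satisfy 0 < low < high")
    return merged


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_parameter_table(
    structure: dict | None = None,
    seed: int = 0,
    ranges: dict | None = None,
) -> ParameterTable:
    """Draw a complete synthetic :class:`ParameterTable` for a network structure.

    Km, Vmax and mass-action k are drawn log-uniformly from ``ranges``
    (defaults: Km in [0.01, 10] mmol/ml, Vmax in [0.1, 10] mmol/min/ml,
    k in [0.01, 10]); kinetic orders default to 1.  Deterministic under
    ``seed``.  Initial concentrations are copied from the structure file.
    """
    if structure is None:
        from .srcm import load_network_structure

        structure = load_network_structure()
    rng = np.random.default_rng(seed)
    bounds = _check_ranges(ranges or {})

    rows = []
    for entry in structure["reactions"]:
        rid = entry["id"]
        kind = entry["kind"]
        enzyme = entry.get("enzyme", "")
        driving = list(entry.get("driving", []))
        if kind == "MICHAELIS_MENTEN":
            vmax = _loguniform(rng, *bounds["vmax"])
            for sid in driving:
                rows.append(
                    dict(
                        reaction=rid,
                        kind=kind,
                        enzyme=enzyme,
                        substrate=sid,
                        km=_loguniform(rng, *bounds["km"]),
                        vmax=vmax,
                        k=np.nan,
                        exponent=np.nan,
                    )
                )
        else:
            k = _loguniform(rng, *bounds["k"])
            for sid in driving:
                rows.append(
                    dict(
                        reaction=rid,
                        kind=kind,
                        enzyme=enzyme,
                        substrate=sid,
                        km=np.nan,
                        vmax=np.nan,
                        k=k,
                        exponent=1.0,
                    )
                )
    kinetics = pd.DataFrame(rows, columns=_KINETIC_COLUMNS)
    initials = pd.DataFrame(
        [
            {"species": e["id"], "initial_concentration": float(e.get("initial", 0.0))}
            for e in structure["species"]
        ]
    )
    meta = {"seed": int(seed), "ranges": {k: list(v) for k, v in bounds.items()},
            "provenance": "synthetic stand-in parameter table"}
    return ParameterTable(kinetics, initials, meta)


def gelatin_feed(total: float, composition: dict[str, float] | None = None) -> dict[str, float]:
    """Amino-acid amounts (mmol) released by hydrolysing ``total`` units of gelatin.

    Default composition: glycine 21.4%, proline 12.4%, alanine 8.9% — the
    major amino acids of pure gelatin.
    """
    if total < 0:
        raise ConfigurationError("total amino-acid units must be >= 0")
    comp = dict(GELATIN_COMPOSITION) if composition is None else dict(composition)
    if any(f < 0 for f in comp.values()):
        raise ConfigurationError("composition fractions must be >= 0")
    if sum(comp.values()) > 1.0 + 1e-12:
        raise ConfigurationError("composition fractions must sum to at most 1")
    feed = {name: 0.0 for name in GELATIN_COMPOSITION}
    feed.update({name: total * frac for name, frac in comp.items()})
    return feed


def generate_observations(
    model,
    settings,
    noise_cv: float = 0.05,
    replicates: int = 1,
    seed: int = 0,
    species: list[str] | None = None,
) -> SyntheticDataset:
    """Simulate the model and contaminate it with multiplicative lognormal noise.

    The noise factor ``exp(sigma*Z - sigma^2/2)`` with
    ``sigma^2 = ln(1 + cv^2)`` is mean-one with coefficient of variation
    exactly ``noise_cv``, applied independently per point and replicate.
    Observations of a zero concentration stay zero.
    """
    from .simulate import simulate_deterministic

    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    traj = simulate_deterministic(model, settings)
    cols = species if species is not None else list(traj.concentrations.columns)
    truth = traj.concentrations[cols]

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    frames = []
    for rep in range(replicates):
        values = truth.to_numpy(copy=True)
        if noise_cv > 0:
            z = rng.standard_normal(values.shape)
            values = values * np.exp(sigma * z - 0.5 * sigma**2)
        values = np.maximum(values, 0.0)
        frame = pd.DataFrame(values, columns=cols)
        frame.insert(0, "time", traj.time)
        frame = frame.melt(id_vars="time", var_name="species", value_name="value")
        frame.insert(2, "replicate", rep)
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    return SyntheticDataset(data=data, noise_cv=float(noise_cv), seed=int(seed), species=list(cols))
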