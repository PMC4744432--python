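"""Reaction network for gene expression with local supercoiling, and its exact
stochastic simulation.

Each supercoiling domain carries two bookkeeping species, ``RCoil`` (remaining
transcribable capacity) and ``PCoil`` (accumulated positive supercoiling),
whose sum is fixed at ``max_rcoil``, plus a single gyrase binding site that is
either empty or occupied.  Per gene ``g`` in domain ``D`` the reactions are

1. transcription   propensity a_o(g) * RCoil(D)   RCoil-1, PCoil+1, mRNA+1
2. mRNA decay      gamma * mRNA(g)
3. translation     b_o(g) * gamma * mRNA(g)       Protein+1 (mRNA catalytic)
4. protein decay   d * Protein(g)

and per domain

5. gyrase binding    K1 (site empty)
6. gyrase unbinding  K2 (site occupied)
7. relaxation        R * PCoil (site occupied)    PCoil-1, RCoil+1

All genes in a domain read the same RCoil, which couples their transcriptional
bursts.  Time is measured in protein lifetimes (d = 1) except for the in-vitro
mode, whose rate is specified in 1/s.  Simulation uses the Gillespie direct
method (numba-compiled; see :mod:`topoburst._ssa`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _ssa

__all__ = [
    "GeneSpec",
    "DomainSpec",
    "GlobalRates",
    "SystemSpec",
    "ReactionNetwork",
    "Trajectory",
    "EventLog",
    "StationarySample",
    "build_network",
    "simulate",
    "simulate_events",
    "sample_cells",
    "invitro_simulate",
    "single_gene_system",
]


class ConfigError(ValueError):
    """Invalid network configuration (negative rate, empty domain, ...)."""


@dataclass(frozen=True)
class GeneSpec:
    name: str
    a_o: float                 #: per-RCoil initiation rate, 1/time
    b_o: float = 2.0           #: burst size (proteins per mRNA), dimensionless
    translated: bool = True    #: off for in-vitro / mRNA-only simulations

    def __post_init__(self) -> None:
        if self.a_o < 0 or self.b_o < 0:
            raise ConfigError(f"gene {self.name!r}: rates must be nonnegative")


@dataclass(frozen=True)
class DomainSpec:
    name: str
    genes: tuple[GeneSpec, ...]
    max_rcoil: int = 4         #: transcription events before stalling
    K1: float = 10.0           #: gyrase binding rate, 1/time
    K2: float = 35.0           #: gyrase unbinding rate, 1/time
    R: float = 1000.0          #: relaxation rate per PCoil while bound, 1/time

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ConfigError(f"domain {self.name!r} has no genes")
        if self.max_rcoil < 1:
            raise ConfigError(f"domain {self.name!r}: max_rcoil must be >= 1")
        if min(self.K1, self.K2, self.R) < 0:
            raise ConfigError(f"domain {self.name!r}: rates must be nonnegative")


@dataclass(frozen=True)
class GlobalRates:
    gamma: float = 50.0        #: mRNA decay rate, 1/time
    d: float = 1.0             #: protein decay rate; time unit is 1/d

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.d < 0:
            raise ConfigError("global rates must be nonnegative")


@dataclass(frozen=True)
class SystemSpec:
    """Full network definition: domains with their genes plus global rates."""

    domains: tuple[DomainSpec, ...]
    global_rates: GlobalRates = field(default_factory=GlobalRates)

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        if not self.domains:
            raise ConfigError("system needs at least one domain")
        names = [g.name for d in self.domains for g in d.genes]
        if len(set(names)) != len(names):
            raise ConfigError("gene names must be unique across the system")

    @property
    def genes(self) -> tuple[GeneSpec, ...]:
        return tuple(g for d in self.domains for g in d.genes)

    def to_dict(self) -> dict:
        return {
            "globals": {"gamma": self.global_rates.gamma, "d": self.global_rates.d},
            "domains": [
                {
                    "name": d.name,
                    "max_rcoil": d.max_rcoil,
                    "K1": d.K1,
                    "K2": d.K2,
                    "R": d.R,
                    "genes": [
                        {"name": g.name, "a_o": g.a_o, "b_o": g.b_o, "translated": g.translated}
                        for g in d.genes
                    ],
                }
                for d in self.domains
            ],
        }

    def config_hash(self) -> str:
        return hashlib.sha1(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def single_gene_system(
    a_o: float,
    b_o: float = 2.0,
    translated: bool = True,
    max_rcoil: int = 4,
    K1: float = 10.0,
    K2: float = 35.0,
    R: float = 1000.0,
    gamma: float = 50.0,
    d: float = 1.0,
    name: str = "gene1",
) -> SystemSpec:
    """One gene in one supercoiling domain with the standard default rates."""
    gene = GeneSpec(name=name, a_o=a_o, b_o=b_o, translated=translated)
    dom = DomainSpec(name="domain1", genes=(gene,), max_rcoil=max_rcoil, K1=K1, K2=K2, R=R)
    return SystemSpec(domains=(dom,), global_rates=GlobalRates(gamma=gamma, d=d))


@dataclass
class ReactionNetwork:
    """Compiled mass-action representation of a :class:`SystemSpec`."""

    spec: SystemSpec
    supercoiling: bool
    species_names: list[str]
    x0: np.ndarray
    rates: np.ndarray
    stoich: np.ndarray
    reactants: np.ndarray
    reaction_labels: list[str]
    gene_species: dict[str, dict[str, int]]    # gene name -> {"mrna": idx, "protein": idx|-1}
    domain_species: dict[str, dict[str, int]]  # domain name -> {"rcoil","pcoil","gyr_free","gyr_bound"}

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.rates)

    def propensities(self, x: np.ndarray) -> np.ndarray:
        """Reference propensity evaluation (used for inspection and tests)."""
        a = np.asarray(self.rates, dtype=float).copy()
        for j in range(self.n_reactions):
            for r in self.reactants[j]:
                if r >= 0:
                    a[j] *= x[r]
        return a


def build_network(
    spec: SystemSpec,
    supercoiling: bool = True,
    initial_gyrase_bound: bool = False,
) -> ReactionNetwork:
    """Compile a :class:`SystemSpec` into stoichiometry/propensity arrays.

    With ``supercoiling=False`` transcription fires at the constant rate
    ``a_o * max_rcoil`` and the RCoil/PCoil/gyrase machinery is omitted: this
    is the plain birth-death (burst-model) reference network.

    Initial state: every domain fully relaxed (RCoil = max_rcoil, PCoil = 0),
    gyrase site empty unless ``initial_gyrase_bound``, no mRNA or protein.
    """
    g = spec.global_rates
    species: list[str] = []
    x0: list[int] = []
    domain_species: dict[str, dict[str, int]] = {}
    gene_species: dict[str, dict[str, int]] = {}

    def add_species(name: str, count: int) -> int:
        species.append(name)
        x0.append(count)
        return len(species) - 1

    if supercoiling:
        for d in spec.domains:
            domain_species[d.name] = {
                "rcoil": add_species(f"RCoil_{d.name}", d.max_rcoil),
                "pcoil": add_species(f"PCoil_{d.name}", 0),
                "gyr_free": add_species(f"Gyrase_{d.name}", 0 if initial_gyrase_bound else 1),
                "gyr_bound": add_species(f"GyraseBound_{d.name}", 1 if initial_gyrase_bound else 0),
            }
    for d in spec.domains:
        for gene in d.genes:
            gene_species[gene.name] = {
                "mrna": add_species(f"mRNA_{gene.name}", 0),
                "protein": add_species(f"Protein_{gene.name}", 0) if gene.translated else -1,
            }

    n_sp = len(species)
    rates: list[float] = []
    labels: list[str] = []
    stoich_rows: list[np.ndarray] = []
    react_rows: list[tuple[int, int]] = []

    def add_reaction(label: str, rate: float, reactants: tuple[int, ...], changes: dict[int, int]) -> None:
        if rate < 0:
            raise ConfigError(f"reaction {label!r} has negative rate")
        row = np.zeros(n_sp, dtype=np.int64)
        for idx, delta in changes.items():
            row[idx] = delta
        rates.append(rate)
        labels.append(label)
        stoich_rows.append(row)
        r = tuple(reactants) + (-1, -1)
        react_rows.append((r[0], r[1]))

    for d in spec.domains:
        ds = domain_species.get(d.name)
        for gene in d.genes:
            gs = gene_species[gene.name]
            if supercoiling:
                add_reaction(
                    f"transcription_{gene.name}",
                    gene.a_o,
                    (ds["rcoil"],),
                    {ds["rcoil"]: -1, ds["pcoil"]: +1, gs["mrna"]: +1},
                )
            else:
                add_reaction(
                    f"transcription_{gene.name}", gene.a_o * d.max_rcoil, (), {gs["mrna"]: +1}
                )
            add_reaction(f"mrna_decay_{gene.name}", g.gamma, (gs["mrna"],), {gs["mrna"]: -1})
            if gene.translated:
                add_reaction(
                    f"translation_{gene.name}", gene.b_o * g.gamma, (gs["mrna"],), {gs["protein"]: +1}
                )
                add_reaction(
                    f"protein_decay_{gene.name}", g.d, (gs["protein"],), {gs["protein"]: -1}
                )
        if supercoiling:
            add_reaction(
                f"gyrase_binding_{d.name}", d.K1, (ds["gyr_free"],),
                {ds["gyr_free"]: -1, ds["gyr_bound"]: +1},
            )
            add_reaction(
                f"gyrase_unbinding_{d.name}", d.K2, (ds["gyr_bound"],),
                {ds["gyr_free"]: +1, ds["gyr_bound"]: -1},
            )
            add_reaction(
                f"relaxation_{d.name}", d.R, (ds["gyr_bound"], ds["pcoil"]),
                {ds["pcoil"]: -1, ds["rcoil"]: +1},
            )

    return ReactionNetwork(
        spec=spec,
        supercoiling=supercoiling,
        species_names=species,
        x0=np.array(x0, dtype=np.int64),
        rates=np.array(rates, dtype=float),
        stoich=np.vstack(stoich_rows),
        reactants=np.array(react_rows, dtype=np.int64),
        reaction_labels=labels,
        gene_species=gene_species,
        domain_species=domain_species,
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate 32-bit seed streams from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32).astype(np.int64)


@dataclass
class Trajectory:
    """Fixed-interval state record of one simulation."""

    times: np.ndarray
    states: np.ndarray
    species_names: list[str]
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species_names)
        df.insert(0, "time", self.times)
        return df

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class EventLog:
    """Full (time, reaction) log of one simulation."""

    times: np.ndarray
    reaction_ids: np.ndarray
    reaction_labels: list[str]
    final_state: np.ndarray
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "reaction_id": self.reaction_ids})

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class StationarySample:
    """End-state counts of independent replicate cells."""

    counts: pd.DataFrame
    seed: int
    burn_in: float
    config_hash: str

    @property
    def n_cells(self) -> int:
        return len(self.counts)

    def gene_counts(self, gene: str, species: str = "mrna") -> np.ndarray:
        col = {"mrna": f"mRNA_{gene}", "protein": f"Protein_{gene}"}[species]
        return self.counts[col].to_numpy()

    def metadata(self) -> dict:
        return {
            "seed": int(self.seed),
            "burn_in": self.burn_in,
            "n_cells": self.n_cells,
            "config_hash": self.config_hash,
        }

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def simulate(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    record_interval: float | None = None,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Exact SSA sample path, recorded on a fixed time grid.

    If every propensity vanishes before ``t_end`` (absorbing state) the final
    state is held for the remaining record times.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if record_interval is None:
        record_interval = t_end / 200.0
    record_times = np.arange(0.0, t_end + 0.5 * record_interval, record_interval)
    start = network.x0 if x0 is None else np.asarray(x0, dtype=np.int64)
    run_seed = int(_child_seeds(seed, 1)[0])
    states = _ssa.ssa_record(
        start, network.rates, network.stoich, network.reactants, record_times, run_seed
    )
    return Trajectory(times=record_times, states=states, species_names=list(network.species_names), seed=seed)


def simulate_events(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    max_events: int = 2_000_000,
    x0: np.ndarray | None = None,
) -> EventLog:
    """Exact SSA sample path returned as a full event log."""
    start = network.x0 if x0 is None else np.asarray(x0, dtype=np.int64)
    run_seed = int(_child_seeds(seed, 1)[0])
    times, rxn, _n, overflowed, final = _ssa.ssa_events(
        start, network.rates, network.stoich, network.reactants, float(t_end), max_events, run_seed
    )
    if overflowed:
        raise RuntimeError(
            f"event log exceeded max_events={max_events}; raise the cap or shorten t_end"
        )
    return EventLog(
        times=times, reaction_ids=rxn, reaction_labels=list(network.reaction_labels),
        final_state=final, seed=seed,
    )


def sample_cells(
    network: ReactionNetwork,
    n_cells: int,
    seed: int,
    burn_in: float = 10.0,
    x0: np.ndarray | None = None,
) -> StationarySample:
    """One stationary end-state snapshot per replicate cell.

    Each cell runs an independent RNG stream for ``burn_in`` time units
    (default ten protein lifetimes) from the standard initial state, which
    avoids autocorrelation between the sampled cells entirely.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    start = network.x0 if x0 is None else np.asarray(x0, dtype=np.int64)
    seeds = _child_seeds(seed, n_cells)
    states = _ssa.ssa_final_many(
        start, network.rates, network.stoich, network.reactants, float(burn_in), seeds
    )
    counts = pd.DataFrame(states, columns=network.species_names)
    return StationarySample(
        counts=counts, seed=seed, burn_in=burn_in, config_hash=network.spec.config_hash()
    )


def invitro_simulate(
    a_o_total: float = 0.0032,
    max_rcoil: int = 13,
    n_templates: int = 160,
    t_end: float | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Transcription event times for an ensemble of circular templates without
    gyrase (single-molecule in-vitro mode; time unit is seconds).

    Per template the only reaction is transcription with propensity
    ``a_o * RCoil`` where ``a_o = a_o_total / max_rcoil``; every event converts
    one RCoil, so at most ``max_rcoil`` events occur before the template stalls
    permanently.  By default templates run to exhaustion.
    """
    if a_o_total <= 0 or max_rcoil < 1 or n_templates < 1:
        raise ValueError("a_o_total must be > 0 and max_rcoil, n_templates >= 1")
    a_o = a_o_total / max_rcoil
    horizon = np.inf if t_end is None else float(t_end)
    out: list[np.ndarray] = []
    for child in np.random.SeedSequence(seed).spawn(n_templates):
        rng = np.random.default_rng(child)
        events = []
        t = 0.0
        for rcoil in range(max_rcoil, 0, -1):
            t += rng.exponential(1.0 / (a_o * rcoil))
            if t > horizon:
                break
            events.append(t)
        out.append(np.array(events))
    return out


def check_conservation(network: ReactionNetwork, trajectory: Trajectory) -> bool:
    """RCoil + PCoil = max_rcoil and gyrase occupancy in {0,1} at every record."""
    if not network.supercoiling:
        return True
    df = trajectory.to_dataframe()
    for d in network.spec.domains:
        ds = network.domain_species[d.name]
        rc = df.iloc[:, 1 + ds["rcoil"]].to_numpy()
        pc = df.iloc[:, 1 + ds["pcoil"]].to_numpy()
        gf = df.iloc[:, 1 + ds["gyr_free"]].to_numpy()
        gb = df.iloc[:, 1 + ds["gyr_bound"]].to_numpy()
        if not np.all(rc + pc == d.max_rcoil):
            return False
        if not (np.all(gf + gb == 1) and np.all((gb == 0) | (gb == 1))):
            return False
    return True
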