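"""Exact stochastic simulation (Gillespie direct method) of small reaction networks.

Networks are built from :class:`Species` and :class:`Reaction` objects.  A
reaction propensity is composed of a base rate constant, an optional
count-dependence on reactant copy numbers (falling-factorial for
multiplicity, i.e. mass-action combinatorics), and optional Hill
activation / repression factors evaluated on the current copy number of a
regulator species:

    h_act(x; K, n) = x^n / (K^n + x^n)
    h_rep(x; K, n) = 1 / (1 + (x/K)^n)

The simulator is the first-family "direct" method: the waiting time to the
next reaction is exponential with rate equal to the total propensity, and
the reaction fired is chosen with probability proportional to its
propensity.  States are integer copy numbers and are non-negative at all
times (validation requires every consumed species to contribute a count
factor, so its propensity vanishes at zero copies).

The per-event loop is compiled with numba; ensembles of independent runs
use child seeds spawned deterministically from a base seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from numba import njit

__all__ = [
    "Species",
    "HillTerm",
    "Reaction",
    "ReactionNetwork",
    "EndpointEnsemble",
    "Trajectory",
    "hill_activation",
    "hill_repression",
    "simulate_ssa",
    "simulate_endpoint_ensemble",
    "network_from_config",
    "network_to_config",
    "load_network",
]


def hill_activation(x, K, n):
    """Hill activation fraction x^n / (K^n + x^n), in [0, 1].

    Parameters
    ----------
    x : array_like, non-negative copy number(s)
    K : dissociation constant, > 0
    n : Hill coefficient, > 0
    """
    if K <= 0 or n <= 0:
        raise ValueError(f"Hill parameters must be positive (K={K}, n={n})")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("copy number x must be non-negative")
    ratio = (x / K) ** n
    out = ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def hill_repression(x, K, n):
    """Hill repression fraction 1 / (1 + (x/K)^n), in (0, 1]."""
    if K <= 0 or n <= 0:
        raise ValueError(f"Hill parameters must be positive (K={K}, n={n})")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("copy number x must be non-negative")
    out = 1.0 / (1.0 + (x / K) ** n)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Species:
    """A chemical species with an integer initial copy number."""

    name: str
    initial_count: int = 0

    def __post_init__(self):
        if self.initial_count < 0 or int(self.initial_count) != self.initial_count:
            raise ValueError(f"initial_count of {self.name!r} must be a non-negative integer")


@dataclass(frozen=True)
class HillTerm:
    """A Hill factor modulating a reaction propensity.

    ``kind`` is ``"activation"`` (x^n/(K^n+x^n)) or ``"repression"``
    (1/(1+(x/K)^n)); ``species`` names the regulator whose copy number is x.
    """

    species: str
    K: float
    n: float
    kind: str = "activation"

    def __post_init__(self):
        if self.kind not in ("activation", "repression"):
            raise ValueError(f"Hill kind must be 'activation' or 'repression', got {self.kind!r}")
        if self.K <= 0 or self.n <= 0:
            raise ValueError(f"Hill parameters must be positive (K={self.K}, n={self.n})")


@dataclass(frozen=True)
class Reaction:
    """A reaction channel.

    ``stoichiometry`` maps species name -> integer copy-number change on
    firing.  ``reactants`` maps species name -> multiplicity; each listed
    reactant contributes a falling-factorial count factor
    x (x-1) ... (x-m+1) to the propensity (catalytic species may appear in
    ``reactants`` without appearing in ``stoichiometry``).  Zero-order
    productions list no reactants and fire at the bare rate.
    """

    name: str
    rate: float
    stoichiometry: Mapping[str, int]
    reactants: Mapping[str, int] = field(default_factory=dict)
    hill: tuple[HillTerm, ...] = ()

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError(f"rate of reaction {self.name!r} must be >= 0")
        for sp, m in self.reactants.items():
            if m <= 0 or int(m) != m:
                raise ValueError(f"reactant multiplicity of {sp!r} in {self.name!r} must be a positive integer")


_MAX_HILL = 2  # slots per reaction in the compiled representation


@dataclass
class ReactionNetwork:
    """A validated reaction network: the simulation substrate."""

    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        declared = set(names)
        for rxn in self.reactions:
            for sp in list(rxn.stoichiometry) + list(rxn.reactants) + [h.species for h in rxn.hill]:
                if sp not in declared:
                    raise ValueError(f"reaction {rxn.name!r} references undeclared species {sp!r}")
            if len(rxn.hill) > _MAX_HILL:
                raise ValueError(f"reaction {rxn.name!r} carries more than {_MAX_HILL} Hill factors")
            # Non-negativity guard: any species consumed must contribute a
            # count factor at least as large as the consumption, so the
            # propensity is zero whenever firing would drive it negative.
            for sp, change in rxn.stoichiometry.items():
                if change < 0 and rxn.reactants.get(sp, 0) < -change:
                    raise ValueError(
                        f"reaction {rxn.name!r} consumes {sp!r} without a matching reactant "
                        "count factor; propensity could fire at zero copies"
                    )
        self._compiled = None

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_count for s in self.species], dtype=np.int64)

    def _compile(self):
        """Lower the network to flat arrays for the numba kernel."""
        if self._compiled is not None:
            return self._compiled
        idx = {s.name: i for i, s in enumerate(self.species)}
        S, R = len(self.species), len(self.reactions)
        stoich = np.zeros((R, S), dtype=np.int64)
        order = np.zeros((R, S), dtype=np.int64)
        rates = np.zeros(R, dtype=np.float64)
        hill_sp = np.full((R, _MAX_HILL), -1, dtype=np.int64)
        hill_K = np.ones((R, _MAX_HILL), dtype=np.float64)
        hill_n = np.ones((R, _MAX_HILL), dtype=np.float64)
        hill_kind = np.zeros((R, _MAX_HILL), dtype=np.int64)
        for r, rxn in enumerate(self.reactions):
            rates[r] = rxn.rate
            for sp, change in rxn.stoichiometry.items():
                stoich[r, idx[sp]] = change
            for sp, m in rxn.reactants.items():
                order[r, idx[sp]] = m
            for h, term in enumerate(rxn.hill):
                hill_sp[r, h] = idx[term.species]
                hill_K[r, h] = term.K
                hill_n[r, h] = term.n
                hill_kind[r, h] = 1 if term.kind == "activation" else -1
        self._compiled = (stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind)
        return self._compiled

    def propensities(self, state: Sequence[float]) -> np.ndarray:
        """Propensity vector at an (integer or continuous) state.

        Continuous states use plain power-law count factors x^m, which is
        the mean-field reading of the mass-action combinatorics.
        """
        state = np.asarray(state, dtype=float)
        stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind = self._compile()
        a = rates.copy()
        for r in range(len(a)):
            for s in np.nonzero(order[r])[0]:
                a[r] *= max(state[s], 0.0) ** order[r, s]
            for h in range(_MAX_HILL):
                sp = hill_sp[r, h]
                if sp >= 0:
                    x = max(state[sp], 0.0)
                    frac = (x / hill_K[r, h]) ** hill_n[r, h]
                    a[r] *= frac / (1.0 + frac) if hill_kind[r, h] > 0 else 1.0 / (1.0 + frac)
        return a

    def mean_field_rhs(self, state: Sequence[float]) -> np.ndarray:
        """dx/dt of the deterministic (mean-field) rate equations."""
        stoich = self._compile()[0]
        return stoich.T @ self.propensities(state)


@njit(cache=False)
def _ssa_endpoint(state0, stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind, t_end, seed):
    np.random.seed(seed)
    state = state0.copy()
    R = rates.shape[0]
    S = state.shape[0]
    props = np.empty(R)
    t = 0.0
    while True:
        a0 = 0.0
        for r in range(R):
            a = rates[r]
            for s in range(S):
                m = order[r, s]
                if m > 0:
                    c = state[s]
                    for k in range(m):
                        a *= c - k if c > k else 0
            for h in range(hill_sp.shape[1]):
                sp = hill_sp[r, h]
                if sp >= 0:
                    frac = (state[sp] / hill_K[r, h]) ** hill_n[r, h]
                    if hill_kind[r, h] > 0:
                        a *= frac / (1.0 + frac)
                    else:
                        a *= 1.0 / (1.0 + frac)
            props[r] = a
            a0 += a
        if a0 <= 0.0:
            break  # frozen system: state holds to t_end
        t += np.random.exponential(1.0 / a0)
        if t >= t_end:
            break
        u = np.random.random() * a0
        acc = 0.0
        r_sel = R - 1
        for r in range(R):
            acc += props[r]
            if u < acc:
                r_sel = r
                break
        for s in range(S):
            state[s] += stoich[r_sel, s]
    return state


@njit(cache=False)
def _ssa_record(state0, stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind, t_end, seed, times, states):
    """Like _ssa_endpoint but records every event; returns (n_events, overflow)."""
    np.random.seed(seed)
    state = state0.copy()
    R = rates.shape[0]
    S = state.shape[0]
    cap = times.shape[0]
    props = np.empty(R)
    t = 0.0
    n = 0
    while True:
        a0 = 0.0
        for r in range(R):
            a = rates[r]
            for s in range(S):
                m = order[r, s]
                if m > 0:
                    c = state[s]
                    for k in range(m):
                        a *= c - k if c > k else 0
            for h in range(hill_sp.shape[1]):
                sp = hill_sp[r, h]
                if sp >= 0:
                    frac = (state[sp] / hill_K[r, h]) ** hill_n[r, h]
                    if hill_kind[r, h] > 0:
                        a *= frac / (1.0 + frac)
                    else:
                        a *= 1.0 / (1.0 + frac)
            props[r] = a
            a0 += a
        if a0 <= 0.0:
            return n, False
        t += np.random.exponential(1.0 / a0)
        if t >= t_end:
            return n, False
        u = np.random.random() * a0
        acc = 0.0
        r_sel = R - 1
        for r in range(R):
            acc += props[r]
            if u < acc:
                r_sel = r
                break
        for s in range(S):
            state[s] += stoich[r_sel, s]
        if n >= cap:
            return n, True
        times[n] = t
        for s in range(S):
            states[n, s] = state[s]
        n += 1


@dataclass
class Trajectory:
    """Event-resolved trajectory of a single SSA run."""

    species_names: list[str]
    times: np.ndarray  # event times, shape (n_events,)
    states: np.ndarray  # post-event states, shape (n_events, n_species)
    t_end: float
    seed: int

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1] if len(self.times) else self.states[:0].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species_names)
        df.insert(0, "time", self.times)
        return df


def _as_seed(seed) -> int:
    seed = int(seed)
    if not 0 <= seed < 2**32:
        raise ValueError("seed must fit in an unsigned 32-bit integer")
    return seed


def simulate_ssa(network: ReactionNetwork, t_end: float, seed: int, record: bool = False):
    """Run one exact SSA realization to ``t_end``.

    Returns the endpoint state (int64 vector over ``network.species_names``),
    or a :class:`Trajectory` when ``record=True``.  Identical
    (network, t_end, seed) inputs give bit-identical outputs.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    seed = _as_seed(seed)
    stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind = network._compile()
    state0 = network.initial_state()
    if not record:
        return _ssa_endpoint(state0, stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind, float(t_end), seed)
    # crude capacity estimate from the initial total propensity; grow and
    # re-run (same seed, so the realization is unchanged) on overflow
    cap = max(int(4 * network.propensities(state0).sum() * t_end), 4096)
    while True:
        times = np.empty(cap, dtype=np.float64)
        states = np.empty((cap, len(state0)), dtype=np.int64)
        n, overflow = _ssa_record(
            state0, stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind, float(t_end), seed, times, states
        )
        if not overflow:
            return Trajectory(network.species_names, times[:n].copy(), states[:n].copy(), float(t_end), seed)
        cap *= 2


@dataclass
class EndpointEnsemble:
    """Endpoint copy numbers of ``n_runs`` independent SSA realizations."""

    species_names: list[str]
    counts: np.ndarray  # (n_runs, n_species) int64
    t_end: float
    seeds: np.ndarray  # per-run child seeds
    base_seed: int

    @property
    def n_runs(self) -> int:
        return self.counts.shape[0]

    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    def sd(self) -> np.ndarray:
        if self.n_runs < 2:
            warnings.warn("ensemble of one run: SD/CV undefined", stacklevel=2)
            return np.full(self.counts.shape[1], np.nan)
        return self.counts.std(axis=0, ddof=1)

    def cv_percent(self) -> np.ndarray:
        """Per-species CV = 100 x SD/mean; NaN where mean is zero or n_runs < 2."""
        mean = self.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mean > 0, 100.0 * self.sd() / mean, np.nan)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean(), "sd": self.sd(), "cv_percent": self.cv_percent()},
            index=pd.Index(self.species_names, name="species"),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.species_names)
        df.insert(0, "run_id", np.arange(self.n_runs))
        return df

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write counts as delimited text plus a JSON sidecar of run metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, sep=sep, index=False)
        sidecar = {
            "t_end": self.t_end,
            "n_runs": self.n_runs,
            "base_seed": int(self.base_seed),
            "species": self.species_names,
            "seeds": [int(s) for s in self.seeds],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def simulate_endpoint_ensemble(
    network: ReactionNetwork, t_end: float, n_runs: int, base_seed: int
) -> EndpointEnsemble:
    """Run ``n_runs`` independent SSA realizations and collect endpoints.

    Run i uses the i-th 32-bit child seed of ``SeedSequence(base_seed)``, so
    ensembles are reproducible and extending ``n_runs`` preserves the
    earlier runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_runs == 1:
        warnings.warn("ensemble of one run: SD/CV will be undefined", stacklevel=2)
    seeds = np.random.SeedSequence(int(base_seed)).generate_state(n_runs, dtype=np.uint32)
    stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind = network._compile()
    state0 = network.initial_state()
    counts = np.empty((n_runs, len(state0)), dtype=np.int64)
    for i in range(n_runs):
        counts[i] = _ssa_endpoint(
            state0, stoich, order, rates, hill_sp, hill_K, hill_n, hill_kind, float(t_end), int(seeds[i])
        )
    return EndpointEnsemble(network.species_names, counts, float(t_end), seeds, int(base_seed))


# ---------------------------------------------------------------------------
# structured config I/O
#
# species:
#   - {name: X, initial: 5}
# reactions:
#   - name: birth
#     rate: 10.0
#     stoichiometry: {X: 1}
#     reactants: {}                         # optional
#     hill:                                 # optional, <= 2 terms
#       - {species: TF, K: 200, n: 2, kind: activation}
# ---------------------------------------------------------------------------


def network_from_config(config: Mapping) -> ReactionNetwork:
    """Build a network from a mapping in the documented schema."""
    try:
        species = [Species(s["name"], int(s.get("initial", 0))) for s in config["species"]]
        reactions = [
            Reaction(
                name=r["name"],
                rate=float(r["rate"]),
                stoichiometry={k: int(v) for k, v in r["stoichiometry"].items()},
                reactants={k: int(v) for k, v in r.get("reactants", {}).items()},
                hill=tuple(
                    HillTerm(h["species"], float(h["K"]), float(h["n"]), h.get("kind", "activation"))
                    for h in r.get("hill", [])
                ),
            )
            for r in config["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed network config: {exc}") from exc
    return ReactionNetwork(species, reactions)


def network_to_config(network: ReactionNetwork) -> dict:
    return {
        "species": [{"name": s.name, "initial": int(s.initial_count)} for s in network.species],
        "reactions": [
            {
                "name": r.name,
                "rate": r.rate,
                "stoichiometry": dict(r.stoichiometry),
                "reactants": dict(r.reactants),
                "hill": [{"species": h.species, "K": h.K, "n": h.n, "kind": h.kind} for h in r.hill],
            }
            for r in network.reactions
        ],
    }


def load_network(path: str | Path) -> ReactionNetwork:
    """Load a network from a YAML (or JSON, a YAML subset) config file."""
    with open(path) as fh:
        return network_from_config(yaml.safe_load(fh))
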