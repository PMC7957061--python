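"""Markov kinetic schemes for membrane transporters.

Declarative single-ring Markov state machines for the astrocytic
glutamate transporter (13-step EAAT cycle: separate binding/unbinding of
3 Na+, 1 H+, 1 Glu and K+ countertransport) and the Na+/Ca2+ exchanger
(6-step NCX cycle, 3 Na+ : 1 Ca2+).  Rate laws are

    k = base * temperature_factor * [ligand]^order * exp(-z F V / (2 R T))

with ``z`` the elementary charge moved inward by the transition
(symmetric Eyring barrier).  Schemes ship as editable YAML parameter
files under ``calfluct/data``; both shipped sets satisfy exact cycle
detailed balance, so transporter directionality (including the NCX
reversal point) is purely thermodynamic.

The module offers the analytic steady state (null vector of the
generator matrix), the net cycle flux, fixed-step Bernoulli stochastic
stepping of molecule populations at the engine clock (1 µs), and an
exact Gillespie sampler used as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "RT_MV",
    "Transition",
    "KineticScheme",
    "RateContext",
    "TransporterPopulation",
    "SchemeStepper",
    "build_eaat_scheme",
    "build_ncx_scheme",
    "load_scheme",
    "rate_matrix",
    "steady_state",
    "cycle_flux",
    "apply_q10",
    "gillespie_occupancy",
]

#: Thermal voltage RT/F in mV at 37 C (310.15 K).
RT_MV = 8.31446 * 310.15 / 96485.33 * 1000.0

#: order of ligand keys in a concentration vector
LIGANDS = ("glu_e", "na_e", "na_i", "k_e", "k_i", "ca_e", "ca_i", "glu_i", "h")


class TimeStepViolation(RuntimeError):
    """A transition probability per step reached 1 (rate * dt too large)."""


@dataclass(frozen=True)
class Transition:
    """One directed edge of a kinetic ring.

    ``ions`` gives the net change of *intracellular* amounts when the
    transition fires (e.g. ``{"na": 1}`` for a Na+ release into the
    cytosol).  ``particle`` declares explicit-particle bookkeeping:
    ``{"action": "bind"|"release", "species": "glu"|"ca",
    "source"/"dest": "pool"|"bath"}`` — pool means a tracked diffusing
    particle is sequestered/restored, bath means an untracked constant
    compartment.
    """

    name: str
    source: str
    target: str
    rate: float
    ligand: str | None = None
    order: int = 1
    z: float = 0.0
    ions: Mapping[str, int] = field(default_factory=dict)
    particle: Mapping[str, str] | None = None


@dataclass
class RateContext:
    """Concentrations (mM), membrane potential (mV) and the dimensionless
    temperature factor applied to all rates (Q10 correction)."""

    glu_e: float = 3.0e-4
    na_e: float = 140.0
    na_i: float = 15.0
    k_e: float = 3.0
    k_i: float = 130.0
    ca_e: float = 2.0
    ca_i: float = 1.0e-4
    glu_i: float = 3.0
    h: float = 1.0  # pseudo-ligand: pH is fixed and folded into base rates
    membrane_potential_mv: float = -70.0
    temperature_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in LIGANDS:
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be >= 0")
        if self.temperature_factor <= 0:
            raise ValueError("temperature_factor must be > 0")

    def ligand_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in LIGANDS], dtype=float)


class KineticScheme:
    """A single-ring Markov scheme with per-transition rate laws."""

    def __init__(
        self,
        name: str,
        states: Sequence[str],
        transitions: Sequence[Transition],
        forward_cycle: Sequence[str],
    ):
        self.name = name
        self.states = list(states)
        self.transitions = list(transitions)
        self.forward_cycle = list(forward_cycle)
        self.state_index = {s: i for i, s in enumerate(self.states)}
        for t in self.transitions:
            if t.source not in self.state_index or t.target not in self.state_index:
                raise ValueError(f"transition {t.name}: unknown state")
            if t.rate < 0:
                raise ValueError(f"transition {t.name}: negative rate")
        if self.forward_cycle[0] != self.forward_cycle[-1]:
            raise ValueError("forward_cycle must close (first state == last state)")
        self._edge_lookup = {(t.source, t.target): t for t in self.transitions}
        for a, b in zip(self.forward_cycle[:-1], self.forward_cycle[1:]):
            if (a, b) not in self._edge_lookup or (b, a) not in self._edge_lookup:
                raise ValueError(f"forward_cycle edge {a}->{b} lacks a transition pair")
        if not self._strongly_connected():
            raise ValueError(f"scheme {name}: transition graph not strongly connected")

    # -- structure --------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_steps(self) -> int:
        """Number of reversible steps (transition pairs) in the cycle."""
        return len(self.transitions) // 2

    def edge(self, source: str, target: str) -> Transition:
        return self._edge_lookup[(source, target)]

    def forward_edges(self) -> list[Transition]:
        return [
            self.edge(a, b)
            for a, b in zip(self.forward_cycle[:-1], self.forward_cycle[1:])
        ]

    def cycle_stoichiometry(self, direction: str = "forward") -> dict[str, int]:
        """Net intracellular species change per completed cycle."""
        net: dict[str, int] = {}
        for t in self.forward_edges():
            for sp, n in t.ions.items():
                net[sp] = net.get(sp, 0) + n
        if direction == "reverse":
            net = {sp: -n for sp, n in net.items()}
        elif direction != "forward":
            raise ValueError("direction must be 'forward' or 'reverse'")
        return {sp: n for sp, n in net.items() if n != 0}

    def detailed_balance_ratio(self) -> float:
        """Product of forward base rates over product of reverse base rates
        around the cycle (1.0 for a thermodynamically neutral ring)."""
        num = den = 1.0
        for a, b in zip(self.forward_cycle[:-1], self.forward_cycle[1:]):
            num *= self.edge(a, b).rate
            den *= self.edge(b, a).rate
        return num / den

    def _strongly_connected(self) -> bool:
        n = self.n_states
        adj = [[] for _ in range(n)]
        radj = [[] for _ in range(n)]
        for t in self.transitions:
            i, j = self.state_index[t.source], self.state_index[t.target]
            adj[i].append(j)
            radj[j].append(i)

        def reach(start: int, graph: list[list[int]]) -> set[int]:
            seen = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in graph[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            return seen

        return len(reach(0, adj)) == n and len(reach(0, radj)) == n

    # -- rates ------------------------------------------------------------
    def transition_rates(self, ctx: RateContext) -> np.ndarray:
        """Rate of every transition (ms^-1) under the given context."""
        conc = ctx.ligand_vector()
        lig_idx = np.array(
            [LIGANDS.index(t.ligand) if t.ligand else -1 for t in self.transitions]
        )
        base = np.array([t.rate for t in self.transitions])
        order = np.array([t.order for t in self.transitions], dtype=float)
        z = np.array([t.z for t in self.transitions])
        lig_factor = np.where(
            lig_idx >= 0, conc[np.maximum(lig_idx, 0)] ** order, 1.0
        )
        volt = np.exp(-z * ctx.membrane_potential_mv / (2.0 * RT_MV))
        return base * ctx.temperature_factor * lig_factor * volt


def _parse_transition(d: Mapping) -> Transition:
    return Transition(
        name=d["name"],
        source=d["from"],
        target=d["to"],
        rate=float(d["rate"]),
        ligand=d.get("ligand"),
        order=int(d.get("order", 1)),
        z=float(d.get("z", 0.0)),
        ions=dict(d.get("ions", {})),
        particle=dict(d["particle"]) if d.get("particle") else None,
    )


def load_scheme(
    source: str | Path, rates: Mapping[str, float] | None = None
) -> KineticScheme:
    """Load a kinetic scheme from YAML (shipped name or file path).

    ``rates`` optionally overrides base rates by transition name; unknown
    names are rejected, and transitions missing a rate in the file are
    reported together.
    """
    if isinstance(source, str) and not source.endswith((".yml", ".yaml")):
        text = (resources.files("calfluct.data") / f"{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    missing = [d.get("name", f"#{i}") for i, d in enumerate(doc["transitions"]) if "rate" not in d]
    if missing:
        raise ValueError(f"scheme {doc.get('name')}: transitions missing rates: {missing}")
    transitions = [_parse_transition(d) for d in doc["transitions"]]
    if rates:
        by_name = {t.name: i for i, t in enumerate(transitions)}
        unknown = sorted(set(rates) - set(by_name))
        if unknown:
            raise ValueError(f"rate overrides for unknown transitions: {unknown}")
        for name, r in rates.items():
            i = by_name[name]
            t = transitions[i]
            transitions[i] = Transition(
                name=t.name, source=t.source, target=t.target, rate=float(r),
                ligand=t.ligand, order=t.order, z=t.z, ions=t.ions, particle=t.particle,
            )
    return KineticScheme(
        name=doc["name"],
        states=doc["states"],
        transitions=transitions,
        forward_cycle=doc["forward_cycle"],
    )


def build_eaat_scheme(rates: Mapping[str, float] | None = None) -> KineticScheme:
    """The 13-step glutamate-transporter cycle (shipped defaults)."""
    scheme = load_scheme("eaat", rates)
    if scheme.n_steps != 13:
        raise ValueError(f"EAAT scheme must have 13 steps, got {scheme.n_steps}")
    return scheme


def build_ncx_scheme(rates: Mapping[str, float] | None = None) -> KineticScheme:
    """The 6-step Na+/Ca2+ exchanger cycle (shipped defaults)."""
    scheme = load_scheme("ncx", rates)
    if scheme.n_steps != 6:
        raise ValueError(f"NCX scheme must have 6 steps, got {scheme.n_steps}")
    return scheme


# ---------------------------------------------------------------------------
# analytic solutions
# ---------------------------------------------------------------------------

def rate_matrix(scheme: KineticScheme, ctx: RateContext) -> np.ndarray:
    """Generator matrix Q (columns sum to zero): dp/dt = Q p."""
    n = scheme.n_states
    Q = np.zeros((n, n))
    rates = scheme.transition_rates(ctx)
    for t, k in zip(scheme.transitions, rates):
        i, j = scheme.state_index[t.source], scheme.state_index[t.target]
        Q[j, i] += k
        Q[i, i] -= k
    return Q


def steady_state(scheme: KineticScheme, ctx: RateContext) -> np.ndarray:
    """Stationary occupancy distribution p with Q p = 0, sum(p) = 1.

    Unique because the ring is strongly connected; an all-zero generator
    (every rate zero under the context) is rejected.
    """
    Q = rate_matrix(scheme, ctx)
    if not np.any(Q):
        raise ValueError("degenerate generator: all rates are zero under this context")
    A = np.vstack([Q, np.ones(scheme.n_states)])
    b = np.zeros(scheme.n_states + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.min(p) < -1e-9:
        raise ValueError(f"steady state has negative occupancy: {p}")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def cycle_flux(scheme: KineticScheme, ctx: RateContext) -> float:
    """Net steady-state cycling rate per molecule along the forward
    direction (completed forward cycles per ms; negative = reverse)."""
    p = steady_state(scheme, ctx)
    a, b = scheme.forward_cycle[0], scheme.forward_cycle[1]
    fwd, rev = scheme.edge(a, b), scheme.edge(b, a)
    rates = scheme.transition_rates(ctx)
    idx = {t.name: i for i, t in enumerate(scheme.transitions)}
    k_f = rates[idx[fwd.name]]
    k_r = rates[idx[rev.name]]
    i, j = scheme.state_index[a], scheme.state_index[b]
    return float(p[i] * k_f - p[j] * k_r)


def apply_q10(
    base_rates: Mapping[str, float] | np.ndarray | float,
    q10: float = 3.0,
    t_ref_c: float = 27.0,
    t_sim_c: float = 37.0,
):
    """Scale rates by q10 ** ((t_sim - t_ref) / 10)."""
    if q10 <= 0:
        raise ValueError("q10 must be > 0")
    factor = q10 ** ((t_sim_c - t_ref_c) / 10.0)
    if isinstance(base_rates, Mapping):
        return {k: v * factor for k, v in base_rates.items()}
    return base_rates * factor


# ---------------------------------------------------------------------------
# stochastic stepping
# ---------------------------------------------------------------------------

@dataclass
class TransporterPopulation:
    """Per-molecule state of one transporter species on the astrocyte
    surface.  ``bound`` marks molecules holding a tracked ligand;
    ``bound_from_pool`` distinguishes pool-sequestered particles (which
    are restored on reverse unbinding) from bath-origin ligands."""

    scheme: KineticScheme
    states: np.ndarray
    positions_nm: np.ndarray
    bound: np.ndarray | None = None
    bound_from_pool: np.ndarray | None = None
    #: a point just inside the astrocyte voxel behind each site (release
    #: target for intracellular ligands) and just outside it (extracellular)
    site_in_nm: np.ndarray | None = None
    site_out_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.positions_nm = np.atleast_2d(np.asarray(self.positions_nm, dtype=float))
        n = len(self.states)
        if self.positions_nm.shape != (n, 3):
            raise ValueError("positions_nm must have shape (n_molecules, 3)")
        if np.any(self.states < 0) or np.any(self.states >= self.scheme.n_states):
            raise ValueError("invalid state index")
        if self.bound is None:
            self.bound = np.zeros(n, dtype=bool)
        if self.bound_from_pool is None:
            self.bound_from_pool = np.zeros(n, dtype=bool)
        if self.site_in_nm is None:
            self.site_in_nm = self.positions_nm
        if self.site_out_nm is None:
            self.site_out_nm = self.positions_nm

    @property
    def n(self) -> int:
        return len(self.states)

    def occupancy(self) -> np.ndarray:
        return np.bincount(self.states, minlength=self.scheme.n_states) / max(self.n, 1)


class SchemeStepper:
    """Vectorised fixed-step Bernoulli sampler for a molecule population.

    Per step each molecule makes at most one transition, with probability
    ``k_ij * dt`` per outgoing transition; the per-state exit probability
    must stay below 1 (enforced; violation raises
    :class:`TimeStepViolation` naming the worst transition).  Voltage and
    temperature factors are frozen at construction; ligand concentrations
    are updated per step, and a per-molecule local override is supported
    for a designated ligand (the glutamate microdomain rule).
    """

    def __init__(self, scheme: KineticScheme, ctx: RateContext, dt_ms: float):
        self.scheme = scheme
        self.dt_ms = float(dt_ms)
        self.n_states = scheme.n_states
        trans = scheme.transitions
        self.src = np.array([scheme.state_index[t.source] for t in trans])
        self.dst = np.array([scheme.state_index[t.target] for t in trans])
        self.lig_idx = np.array(
            [LIGANDS.index(t.ligand) if t.ligand else -1 for t in trans]
        )
        self.order = np.array([t.order for t in trans], dtype=float)
        z = np.array([t.z for t in trans])
        base = np.array([t.rate for t in trans])
        self.static_k = (
            base
            * ctx.temperature_factor
            * np.exp(-z * ctx.membrane_potential_mv / (2.0 * RT_MV))
        )
        # padded per-state slots
        max_out = int(np.max(np.bincount(self.src, minlength=self.n_states)))
        self.max_out = max_out
        self.slot_of = np.zeros(len(trans), dtype=np.int64)
        counts = np.zeros(self.n_states, dtype=np.int64)
        for i, s in enumerate(self.src):
            self.slot_of[i] = counts[s]
            counts[s] += 1
        self.state_trans = np.full((self.n_states, max_out), -1, dtype=np.int64)
        for i, (s, sl) in enumerate(zip(self.src, self.slot_of)):
            self.state_trans[s, sl] = i
        self._conc = ctx.ligand_vector()
        self._prob = np.zeros((self.n_states, max_out))
        self._cum = np.zeros_like(self._prob)
        # per-state multinomial table: transition slots + "no transition"
        self._pfull = np.zeros((self.n_states, max_out + 1))
        self._log_none = np.zeros(self.n_states)
        self._k = np.zeros(len(trans))
        self._full_update()
        # transitions depending on each ligand, for fast partial updates
        self._by_ligand: dict[str, np.ndarray] = {
            name: np.nonzero(self.lig_idx == i)[0]
            for i, name in enumerate(LIGANDS)
        }
        self._affected_cache: dict[frozenset, tuple[np.ndarray, np.ndarray]] = {}

    def _full_update(self) -> None:
        lig = np.where(
            self.lig_idx >= 0,
            self._conc[np.maximum(self.lig_idx, 0)] ** self.order,
            1.0,
        )
        self._k = self.static_k * lig
        self._prob[self.src, self.slot_of] = self._k * self.dt_ms
        self._check_and_cum(np.arange(self.n_states))

    def _check_and_cum(self, states: np.ndarray) -> None:
        total = self._prob[states].sum(axis=1)
        if np.any(total >= 1.0):
            s = int(states[np.argmax(total)])
            worst = self.state_trans[s][np.argmax(self._prob[s])]
            raise TimeStepViolation(
                f"state {self.scheme.states[s]}: exit probability "
                f"{self._prob[s].sum():.3f} >= 1 per step (transition "
                f"{self.scheme.transitions[worst].name}); reduce dt"
            )
        rows = np.cumsum(self._prob[states], axis=1)
        self._cum[states] = rows
        self._pfull[states, : self.max_out] = self._prob[states]
        p_none = 1.0 - rows[:, -1]
        self._pfull[states, self.max_out] = p_none
        with np.errstate(divide="ignore"):
            self._log_none[states] = np.log(p_none)

    def update_concentrations(self, conc: Mapping[str, float]) -> None:
        """Refresh ligand concentrations (mM) and the probability tables.

        Only the transitions depending on the supplied ligands are
        recomputed, so per-step updates of the dynamic species are cheap.
        """
        key = tuple(sorted(conc))
        cached = self._affected_cache.get(key)
        if cached is None:
            names = list(key)
            tis = (
                np.concatenate([self._by_ligand[n] for n in names]).astype(np.int64)
                if names
                else np.empty(0, dtype=np.int64)
            )
            which = (
                np.concatenate(
                    [np.full(len(self._by_ligand[n]), i) for i, n in enumerate(names)]
                ).astype(np.int64)
                if names
                else np.empty(0, dtype=np.int64)
            )
            states = np.unique(self.src[tis]) if len(tis) else np.empty(0, dtype=np.int64)
            lig_pos = np.array([LIGANDS.index(n) for n in names], dtype=np.int64)
            cached = (
                names,
                tis,
                which,
                states,
                self.src[tis],
                self.slot_of[tis],
                self.order[tis],
                self.static_k[tis],
                lig_pos,
            )
            self._affected_cache[key] = cached
        names, tis, which, states, src, slots, order, static, lig_pos = cached
        v_names = np.array([conc[n] for n in names])
        self._conc[lig_pos] = v_names
        if len(tis):
            k = static * v_names[which] ** order
            self._k[tis] = k
            self._prob[src, slots] = k * self.dt_ms
            self._check_and_cum(states)

    def step(
        self,
        states: np.ndarray,
        rng: np.random.Generator,
        local_glu_mM: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Advance all molecules one step in place.

        ``local_glu_mM`` optionally gives per-molecule glutamate
        concentrations used for transitions whose ligand is ``glu_e``
        (NaN entries fall back to the global value).  Returns
        ``(molecule_indices, transition_indices)`` of fired transitions,
        ordered by molecule index.
        """
        n = len(states)
        u = rng.random(n)
        if local_glu_mM is None:
            cum = self._cum[states]
        else:
            rows = self._prob[states].copy()
            glu_t = np.where(self.lig_idx == LIGANDS.index("glu_e"))[0]
            for ti in glu_t:
                s, sl = self.src[ti], self.slot_of[ti]
                in_state = states == s
                if not np.any(in_state):
                    continue
                loc = local_glu_mM[in_state]
                k_loc = self.static_k[ti] * np.where(
                    np.isnan(loc), self._conc[self.lig_idx[ti]], loc
                ) ** self.order[ti]
                p_loc = k_loc * self.dt_ms
                if np.any(rows[in_state].sum(axis=1) - rows[in_state][:, sl] + p_loc >= 1.0):
                    raise TimeStepViolation(
                        f"local ligand drove exit probability >= 1 per step "
                        f"(transition {self.scheme.transitions[ti].name}); reduce dt"
                    )
                col = rows[:, sl]
                col[in_state] = p_loc
            cum = np.cumsum(rows, axis=1)
        slot = (u[:, None] >= cum).sum(axis=1)
        fired = slot < self.max_out
        mols = np.nonzero(fired)[0]
        trans = self.state_trans[states[mols], slot[mols]]
        valid = trans >= 0
        mols, trans = mols[valid], trans[valid]
        states[mols] = self.dst[trans]
        return mols, trans

    def step_grouped(
        self,
        states: np.ndarray,
        rng: np.random.Generator,
        counts: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Equivalent to :meth:`step` but samples transition *counts* per
        state from the exact multinomial law and then assigns them to
        uniformly chosen molecules.  Molecules in the same state are
        exchangeable (no per-molecule rate differences), so the sampled
        process is identical in distribution while costing O(n_states)
        per quiet step instead of O(n_molecules).  Not usable with local
        ligand overrides.

        ``counts`` may carry the per-state occupancy (updated in place);
        the quiet-step shortcut first decides "no transition anywhere"
        with its exact probability and otherwise draws the multinomial
        conditioned on at least one event by rejection.
        """
        empty = np.empty(0, dtype=np.int64)
        if counts is None:
            counts = np.bincount(states, minlength=self.n_states)
            track = False
        else:
            track = True
        log_none = float(counts @ self._log_none)
        if rng.random() < np.exp(log_none):
            return empty, empty
        for _ in range(100_000):
            fired = rng.multinomial(counts, self._pfull)[:, : self.max_out]
            if fired.any():
                break
        else:  # pragma: no cover - probability ~0
            return empty, empty
        mols_out, trans_out = [], []
        for s in np.nonzero(fired.sum(axis=1))[0]:
            members = np.nonzero(states == s)[0]
            n_fire = fired[s]
            chosen = rng.choice(members, size=int(n_fire.sum()), replace=False)
            off = 0
            for slot in range(self.max_out):
                ti = self.state_trans[s, slot]
                c = int(n_fire[slot])
                if c and ti >= 0:
                    mols_out.append(chosen[off : off + c])
                    trans_out.append(np.full(c, ti, dtype=np.int64))
                    off += c
        mols = np.concatenate(mols_out)
        trans = np.concatenate(trans_out)
        states[mols] = self.dst[trans]
        if track:
            np.add.at(counts, self.src[trans], -1)
            np.add.at(counts, self.dst[trans], 1)
        return mols, trans


def step_population(
    pop: TransporterPopulation,
    ctx: RateContext,
    dt_ms: float = 1e-3,
    rng: np.random.Generator | None = None,
    n_steps: int = 1,
    local_glu_mM: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Convenience wrapper: step a population under a fixed context.

    Returns the per-step event lists; ``pop.states`` is updated in place.
    Deterministic for a given rng state.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    stepper = SchemeStepper(pop.scheme, ctx, dt_ms)
    events = []
    for _ in range(n_steps):
        events.append(stepper.step(pop.states, rng, local_glu_mM))
    return events


def gillespie_occupancy(
    scheme: KineticScheme,
    ctx: RateContext,
    t_total_ms: float,
    rng: np.random.Generator,
    start_state: int = 0,
) -> np.ndarray:
    """Exact continuous-time occupancy of a single molecule (test oracle).

    Simulates the CTMC with exponential dwell times and returns the
    time-weighted fraction spent in each state.
    """
    rates = scheme.transition_rates(ctx)
    n = scheme.n_states
    out_trans: list[list[int]] = [[] for _ in range(n)]
    for i, t in enumerate(scheme.transitions):
        out_trans[scheme.state_index[t.source]].append(i)
    occ = np.zeros(n)
    state = start_state
    t = 0.0
    while t < t_total_ms:
        ks = rates[out_trans[state]]
        total = ks.sum()
        if total <= 0:
            occ[state] += t_total_ms - t
            break
        dwell = rng.exponential(1.0 / total)
        dwell = min(dwell, t_total_ms - t)
        occ[state] += dwell
        t += dwell
        if t >= t_total_ms:
            break
        choice = out_trans[state][rng.choice(len(ks), p=ks / total)]
        state = scheme.state_index[scheme.transitions[choice].target]
    return occ / occ.sum()
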