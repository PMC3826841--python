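"""Synchronous simulation engine: stepping, cycle detection, growth rates.

All nodes are updated simultaneously each time-step from the previous full
state.  Under a :class:`~cyclogic.dosage.DosageSpec` every occurrence of a
dosed gene inside a rule expression is independently read as 0 with
probability ``1 - d``, and the dosed gene's own proposed update is reset to 0
with the same probability.  Replicates are simulated in vectorised blocks on
a fixed absolute grid (see :mod:`cyclogic.dosage`), which makes runs
reproducible and replicate-range additive.

A division is detected as a run of more than two consecutive steps with the
cytokinesis node at its completion level; the cycle closes when the mass
node subsequently returns to one.  The relative growth rate of a perturbed
strain is the wild-type period divided by its mean cycle period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dosage import DosageSpec, RngContract
from .logic_model import ModelDefinition, eval_expr

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "CycleEvent",
    "GrowthResult",
    "SimulationSummary",
    "step",
    "simulate",
    "detect_cycles",
    "growth_rate",
    "wild_type_period",
    "deterministic_cycle",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_steps: int = 10_000
    n_replicates: int = 10_000
    seed: int = 0
    record_trajectory: bool = False
    #: absolute index of the first replicate (runs over disjoint ranges with
    #: the same seed pool exactly like one combined run)
    replicate_start: int = 0
    #: if True (default) an event additionally requires the mass node to
    #: return to one after the cytokinesis run; if False the run alone counts
    require_mass_return: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_replicates < 1:
            raise ValueError("n_steps and n_replicates must be >= 1")


@dataclass(frozen=True)
class CycleEvent:
    start_step: int
    cytokinesis_run: tuple[int, int]  # (first step, length)
    end_step: int

    @property
    def period(self) -> int:
        return self.end_step - self.start_step


@dataclass
class Trajectory:
    node_names: tuple[str, ...]
    states: np.ndarray  # (n_steps + 1, n_nodes)
    events: list[CycleEvent] = field(default_factory=list)

    def column(self, node: str) -> np.ndarray:
        return self.states[:, self.node_names.index(node)]


@dataclass
class SimulationSummary:
    """Streaming per-replicate summaries of a simulation run."""

    n_replicates: int
    n_steps: int
    phase_names: tuple[str, ...]
    phase_counts: np.ndarray          # (n_replicates, len(phase_names) + 1)
    event_counts: np.ndarray          # (n_replicates,) completed events
    period_sums: np.ndarray           # (n_replicates,) sum of completed periods
    period_sumsqs: np.ndarray
    trajectory: Trajectory | None = None
    deterministic: bool = False

    @property
    def unclassified_counts(self) -> np.ndarray:
        return self.phase_counts[:, -1]


@dataclass(frozen=True)
class GrowthResult:
    completed_events: float
    mean_period: float
    relative_growth_rate: float
    period_ratio: float
    arrested: bool
    se: float
    wt_period: int
    n_replicates: int


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

class _Compiled:
    """Model + dosage compiled to vectorised update closures."""

    def __init__(self, model: ModelDefinition, dosage: DosageSpec) -> None:
        self.model = model
        self.dosage = dosage
        self.names = model.node_names()
        self.index = {n: i for i, n in enumerate(self.names)}
        self.n_nodes = len(self.names)
        active = set(model.active_node_names())
        by_target = model.rules_by_target()

        # per-node update plans, in fixed node order (draw-order stability)
        self.plans: list[tuple[int, list[tuple[int, Callable]], float]] = []
        for name in self.names:
            if name not in active:
                continue  # clamped at 0, no draws
            rules = by_target.get(name, ())
            fns = [(r.target_level, self._compile(r.expr)) for r in rules]
            self.plans.append((self.index[name], fns, dosage.fraction(name)))

        self.sig_fns = [
            (sig.phase, self._compile(sig.expr, sample=False))
            for sig in model.signatures
        ]
        start = model.full_start_state()
        for mod in model.modules:
            if not mod.enabled:
                for nd in mod.nodes:
                    start[nd.name] = 0
        self.start = np.array([start[n] for n in self.names], dtype=np.int16)

    def _compile(self, expr, sample: bool = True) -> Callable:
        op = expr[0]
        if op in ("GE", "EQ"):
            idx = self.index[expr[1]]
            lvl = expr[2]
            d = self.dosage.fraction(expr[1]) if sample else 1.0
            if d >= 1.0:
                if op == "GE":
                    return lambda s, rng: s[:, idx] >= lvl
                return lambda s, rng: s[:, idx] == lvl
            if op == "GE":
                def ge(s, rng, idx=idx, lvl=lvl, d=d):
                    read = np.where(rng.random(s.shape[0]) < d, s[:, idx], 0)
                    return read >= lvl
                return ge
            def eq(s, rng, idx=idx, lvl=lvl, d=d):
                read = np.where(rng.random(s.shape[0]) < d, s[:, idx], 0)
                return read == lvl
            return eq
        if op == "NOT":
            sub = self._compile(expr[1], sample)
            return lambda s, rng: ~sub(s, rng)
        subs = [self._compile(e, sample) for e in expr[1:]]
        if op == "AND":
            def all_(s, rng, subs=subs):
                out = subs[0](s, rng)
                for f in subs[1:]:   # no short-circuit: draw order is fixed
                    out = out & f(s, rng)
                return out
            return all_
        def any_(s, rng, subs=subs):
            out = subs[0](s, rng)
            for f in subs[1:]:
                out = out | f(s, rng)
            return out
        return any_

    def step(self, state: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        nxt = np.zeros_like(state)
        m = state.shape[0]
        for idx, fns, d in self.plans:
            col = nxt[:, idx]
            if fns:
                assigned = np.zeros(m, dtype=bool)
                for lvl, fn in fns:
                    sat = fn(state, rng) & ~assigned
                    col[sat] = lvl
                    assigned |= sat
            if d < 1.0:
                keep = rng.random(m) < d
                col[~keep] = 0
        return nxt

    def classify(self, state: np.ndarray) -> np.ndarray:
        """Phase index per replicate; -1 for unclassified states."""
        out = np.full(state.shape[0], -1, dtype=np.int8)
        hit = np.zeros(state.shape[0], dtype=bool)
        for k, (_, fn) in enumerate(self.sig_fns):
            mask = fn(state, None)
            if np.any(mask & hit):
                raise ValueError(
                    "state matched by more than one phase signature "
                    "(inconsistent model file)"
                )
            out[mask] = k
            hit |= mask
        return out


def _compiled(model: ModelDefinition, dosage: DosageSpec) -> _Compiled:
    return _Compiled(model, dosage)


# ---------------------------------------------------------------------------
# public stepping / deterministic utilities
# ---------------------------------------------------------------------------

def step(state: dict[str, int] | Sequence[int], model: ModelDefinition,
         dosage: DosageSpec | None = None,
         rng: np.random.Generator | None = None) -> dict[str, int]:
    """Single synchronous update of one full state (scalar convenience API).

    Accepts and returns ``{node: level}`` mappings.  With no dosage (or all
    fractions 1.0) this is the deterministic step map.
    """
    dosage = dosage or DosageSpec()
    if rng is None:
        rng = np.random.default_rng(0)
        if not dosage.is_deterministic():
            raise ValueError("stochastic step needs an explicit rng")
    comp = _compiled(model, dosage)
    if isinstance(state, dict):
        vec = np.array([state[n] for n in comp.names], dtype=np.int16)
    else:
        vec = np.asarray(state, dtype=np.int16)
    out = comp.step(vec[None, :], rng)[0]
    return dict(zip(comp.names, (int(v) for v in out)))


def deterministic_cycle(model: ModelDefinition,
                        max_period: int = 512) -> list[tuple[int, ...]] | None:
    """States of the unperturbed cycle, from start_state up to (but not
    including) its first recurrence; None if it does not recur."""
    comp = _compiled(model, DosageSpec())
    rng = np.random.default_rng(0)  # never consulted: no dosed nodes
    state = comp.start[None, :].copy()
    start = tuple(int(v) for v in comp.start)
    states = [start]
    for _ in range(max_period):
        state = comp.step(state, rng)
        tup = tuple(int(v) for v in state[0])
        if tup == start:
            return states
        states.append(tup)
    return None


def wild_type_period(model: ModelDefinition) -> int:
    """Cycle period of the unperturbed model (recurrence time of START)."""
    states = deterministic_cycle(model, max_period=4096)
    if states is None:
        raise ValueError(f"model {model.name!r} has no unperturbed cycle")
    return len(states)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(model: ModelDefinition, dosage: DosageSpec | None,
             config: SimulationConfig) -> SimulationSummary:
    """Run replicated stochastic simulations with streaming summaries.

    Occupancy counts classify the ``n_steps`` states at steps 0..n_steps-1.
    Event machinery scans for qualifying cytokinesis runs as the simulation
    streams; full states are retained only for the first replicate and only
    when ``config.record_trajectory`` is set.
    """
    dosage = dosage or DosageSpec()
    comp = _compiled(model, dosage)
    n_reps = config.n_replicates
    deterministic = dosage.is_deterministic()
    sim_reps = 1 if deterministic else n_reps

    n_phases = len(comp.sig_fns)
    phase_counts = np.zeros((sim_reps, n_phases + 1), dtype=np.int64)
    event_counts = np.zeros(sim_reps, dtype=np.int64)
    period_sums = np.zeros(sim_reps, dtype=np.float64)
    period_sumsqs = np.zeros(sim_reps, dtype=np.float64)
    trajectory: Trajectory | None = None

    cyto = comp.index[model.cytokinesis_node] if model.event_nodes else None
    mass = comp.index[model.mass_node] if model.event_nodes else None
    clevel = model.cytokinesis_level if model.event_nodes else None

    contract = RngContract(config.seed)
    r0 = config.replicate_start
    for block, lo, hi in contract.blocks(r0, r0 + sim_reps):
        rng = contract.block_generator(block)
        if deterministic:
            state = comp.start[None, :].copy()
            sel = out = slice(0, 1)
        else:
            # always simulate the full block and slice: range additivity
            state = np.tile(comp.start, (256, 1))
            sel = slice(lo - block * 256, hi - block * 256)
            out = slice(lo - r0, hi - r0)

        m = state.shape[0]
        run_len = np.zeros(m, dtype=np.int64)
        if cyto is not None:
            run_len += state[:, cyto] == clevel
        pending = np.zeros(m, dtype=bool)
        last_close = np.zeros(m, dtype=np.int64)

        record = config.record_trajectory and lo == r0
        if record:
            traj_states = np.empty((config.n_steps + 1, comp.n_nodes),
                                   dtype=np.int16)
            traj_states[0] = state[0 if deterministic else sel.start]

        for t in range(1, config.n_steps + 1):
            if n_phases:
                ph = comp.classify(state)
                for k in range(n_phases):
                    phase_counts[out, k] += (ph == k)[sel]
                phase_counts[out, -1] += (ph == -1)[sel]
            state = comp.step(state, rng)
            if record:
                traj_states[t] = state[0 if deterministic else sel.start]
            if cyto is None:
                continue
            at_level = state[:, cyto] == clevel
            ended = (~at_level) & (run_len > 2)
            if config.require_mass_return:
                pending |= ended
                close = pending & (~at_level) & (state[:, mass] == 1)
            else:
                close = ended
            run_len = np.where(at_level, run_len + 1, 0)
            if np.any(close):
                periods = (t - last_close)[close].astype(np.float64)
                csel = close[sel]
                event_counts[out] += csel
                psel = np.zeros(m); psel[close] = periods
                period_sums[out] += psel[sel]
                period_sumsqs[out] += (psel ** 2)[sel]
                last_close[close] = t
                pending[close] = False

        if record:
            traj = Trajectory(comp.names, traj_states)
            if model.event_nodes:
                traj.events = detect_cycles(
                    traj, model, require_mass_return=config.require_mass_return)
            trajectory = traj

    if deterministic and n_reps > 1:
        # identical replicates: broadcast the single simulated one
        phase_counts = np.repeat(phase_counts, n_reps, axis=0)
        event_counts = np.repeat(event_counts, n_reps)
        period_sums = np.repeat(period_sums, n_reps)
        period_sumsqs = np.repeat(period_sumsqs, n_reps)

    return SimulationSummary(
        n_replicates=n_reps,
        n_steps=config.n_steps,
        phase_names=tuple(p for p, _ in comp.sig_fns),
        phase_counts=phase_counts,
        event_counts=event_counts,
        period_sums=period_sums,
        period_sumsqs=period_sumsqs,
        trajectory=trajectory,
        deterministic=deterministic,
    )


# ---------------------------------------------------------------------------
# cycle detection on recorded trajectories
# ---------------------------------------------------------------------------

def detect_cycles(trajectory: Trajectory, model: ModelDefinition,
                  require_mass_return: bool = True) -> list[CycleEvent]:
    """Scan a trajectory for complete cycle events.

    A qualifying cytokinesis run has strictly more than two consecutive steps
    at the completion level; a run still open at the trajectory end is
    discarded.  With ``require_mass_return`` (default) the event closes at
    the first later step where the mass node is back at one.
    """
    cyto = trajectory.column(model.cytokinesis_node)
    mass = trajectory.column(model.mass_node)
    lvl = model.cytokinesis_level
    events: list[CycleEvent] = []
    run_start = None
    pending_run = None
    cycle_start = 0
    for t in range(len(cyto)):
        at = cyto[t] == lvl
        if at and run_start is None:
            run_start = t
        if not at and run_start is not None:
            length = t - run_start
            if length > 2:
                if require_mass_return:
                    pending_run = (run_start, length)
                else:
                    events.append(CycleEvent(cycle_start, (run_start, length), t))
                    cycle_start = t
            run_start = None
        if pending_run is not None and not at and mass[t] == 1:
            events.append(CycleEvent(cycle_start, pending_run, t))
            cycle_start = t
            pending_run = None
    return events


# ---------------------------------------------------------------------------
# growth rate
# ---------------------------------------------------------------------------

def growth_rate(model: ModelDefinition, dosage: DosageSpec | None,
                config: SimulationConfig,
                wt_period: int | None = None,
                summary: SimulationSummary | None = None) -> GrowthResult:
    """Relative growth rate of a (possibly perturbed) strain.

    Per replicate the rate is ``T_WT / mean completed-cycle period`` (0 for
    replicates that complete no event); the reported relative growth rate is
    the replicate mean, with its Monte-Carlo standard error.  A strain is
    flagged arrested only if no replicate completes any event.
    """
    if wt_period is None:
        wt_period = wild_type_period(model)
    if summary is None:
        summary = simulate(model, dosage, config)
    counts = summary.event_counts
    sums = summary.period_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        per_rep_period = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        rates = np.where(counts > 0, wt_period / per_rep_period, 0.0)
    total_events = int(counts.sum())
    arrested = total_events == 0
    mean_period = float(sums.sum() / total_events) if total_events else float("nan")
    rel = float(rates.mean())
    if summary.deterministic or len(rates) < 2:
        se = 0.0
    else:
        se = float(rates.std(ddof=1) / np.sqrt(len(rates)))
    return GrowthResult(
        completed_events=float(counts.mean()),
        mean_period=mean_period,
        relative_growth_rate=0.0 if arrested else rel,
        period_ratio=(mean_period / wt_period) if total_events else float("inf"),
        arrested=arrested,
        se=se,
        wt_period=wt_period,
        n_replicates=summary.n_replicates,
    )
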