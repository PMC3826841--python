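"""Exact Markov-chain analysis of small dosed models.

For a model whose state space fits within the enumeration bound, the
per-occurrence / per-outcome dosage sampling defines an exact Markov chain:
given the current state, the next value of each node depends only on that
node's own rule evaluations and reset draw, so the one-step transition
distribution factorises over nodes.  This module enumerates those
distributions exactly and assembles the row-stochastic transition matrix,
which serves as ground truth for the Monte-Carlo engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .dosage import DosageSpec
from .logic_model import ENUMERATION_BOUND, ModelDefinition, eval_expr

__all__ = ["ChainModel", "build_chain", "transient_occupancy"]

#: per-rule-set joint enumeration cap: at most this many stochastic
#: occurrences of dosed genes per target node
OCCURRENCE_CAP = 16


@dataclass
class ChainModel:
    model: ModelDefinition
    dosage: DosageSpec
    node_names: tuple[str, ...]       # active nodes, enumeration order
    radices: tuple[int, ...]          # max_level + 1 per node
    transition: sparse.csr_matrix    # row-stochastic

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def encode(self, state: dict[str, int]) -> int:
        code = 0
        for name, radix in zip(self.node_names, self.radices):
            code = code * radix + int(state.get(name, 0))
        return code

    def decode(self, code: int) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, radix in zip(reversed(self.node_names), reversed(self.radices)):
            out[name] = code % radix
            code //= radix
        return {name: out[name] for name in self.node_names}


def _node_distribution(node: str, max_level: int, rules, state: dict[str, int],
                       dosage: DosageSpec) -> dict[int, float]:
    """Exact distribution of a node's next value given the current state.

    ``rules`` are that node's active rules in descending target-level order.
    Enumerates every joint outcome of the independent occurrence draws (one
    per dosed-gene occurrence whose current level is non-zero) and, on top of
    the proposed level, the outcome-level reset draw of the node itself.
    """
    # collect stochastic occurrences in fixed evaluation order
    occs: list[str] = []
    for rule in rules:
        for name in _occurrences_in(rule.expr):
            occs.append(name)
    stochastic = [
        i for i, name in enumerate(occs)
        if dosage.fraction(name) < 1.0 and state.get(name, 0) != 0
    ]
    if len(stochastic) > OCCURRENCE_CAP:
        raise ValueError(
            f"node {node!r}: {len(stochastic)} stochastic occurrences exceed "
            f"the enumeration cap {OCCURRENCE_CAP}"
        )

    dist: dict[int, float] = {}
    for outcome in itertools.product((1, 0), repeat=len(stochastic)):
        prob = 1.0
        reads = dict(zip(stochastic, outcome))
        for pos, keep in reads.items():
            d = dosage.fraction(occs[pos])
            prob *= d if keep else (1.0 - d)
        if prob == 0.0:
            continue
        proposed = 0
        pos = 0
        for rule in rules:
            sat, pos = _eval_at(rule.expr, state, reads, pos)
            if proposed == 0 and sat:
                proposed = rule.target_level
        dist[proposed] = dist.get(proposed, 0.0) + prob

    # outcome-level reset of the dosed node itself
    d_self = dosage.fraction(node)
    if d_self < 1.0:
        reset: dict[int, float] = {}
        for level, prob in dist.items():
            if level == 0:
                reset[0] = reset.get(0, 0.0) + prob
            else:
                reset[level] = reset.get(level, 0.0) + prob * d_self
                reset[0] = reset.get(0, 0.0) + prob * (1.0 - d_self)
        dist = reset
    return dist


def _eval_at(expr, state, reads: dict[int, int], pos: int) -> tuple[bool, int]:
    """Evaluate without short-circuiting, tracking leaf positions.

    ``reads`` maps a stochastic occurrence position to 1 (read the true
    level) or 0 (occurrence reset); positions not in the map read the true
    level.  Every leaf advances the position counter so indices stay aligned
    with the enumeration in :func:`_node_distribution`.
    """
    op = expr[0]
    if op in ("GE", "EQ"):
        value = state.get(expr[1], 0)
        if pos in reads and not reads[pos]:
            value = 0
        result = value >= expr[2] if op == "GE" else value == expr[2]
        return result, pos + 1
    if op == "NOT":
        sub, pos = _eval_at(expr[1], state, reads, pos)
        return (not sub), pos
    results = []
    for child in expr[1:]:
        sub, pos = _eval_at(child, state, reads, pos)
        results.append(sub)
    return (all(results) if op == "AND" else any(results)), pos


def _occurrences_in(expr):
    op = expr[0]
    if op in ("GE", "EQ"):
        yield expr[1]
    elif op == "NOT":
        yield from _occurrences_in(expr[1])
    else:
        for sub in expr[1:]:
            yield from _occurrences_in(sub)


def build_chain(model: ModelDefinition, dosage: DosageSpec | None = None) -> ChainModel:
    """Enumerate the exact one-step transition matrix under a dosage spec.

    Raises if the active state space exceeds the enumeration bound — large
    models are Monte-Carlo territory.
    """
    dosage = dosage or DosageSpec()
    active = model.active_node_names()
    levels = model.levels()
    radices = tuple(levels[n] + 1 for n in active)
    n_states = 1
    for radix in radices:   # python ints: no overflow on large models
        n_states *= radix
    if n_states > ENUMERATION_BOUND:
        raise ValueError(
            f"state space of {n_states} states exceeds the enumeration bound "
            f"{ENUMERATION_BOUND}; use the Monte-Carlo engine instead"
        )
    by_target = model.rules_by_target()

    chain = ChainModel(model, dosage, tuple(active), radices,
                       sparse.csr_matrix((n_states, n_states)))
    rows, cols, vals = [], [], []
    for code in range(n_states):
        state = chain.decode(code)
        # per-node next-value distributions (factorised)
        node_dists = [
            _node_distribution(name, levels[name], by_target.get(name, ()),
                               state, dosage)
            for name in active
        ]
        # joint product, accumulated sparsely
        joint: dict[int, float] = {0: 1.0}
        for radix, nd in zip(radices, node_dists):
            new: dict[int, float] = {}
            for partial, p in joint.items():
                for level, q in nd.items():
                    key = partial * radix + level
                    new[key] = new.get(key, 0.0) + p * q
            joint = new
        for nxt, p in joint.items():
            rows.append(code)
            cols.append(nxt)
            vals.append(p)
    chain.transition = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_states, n_states))
    return chain


def transient_occupancy(chain: ChainModel, start: dict[str, int] | int,
                        n_steps: int) -> np.ndarray:
    """Expected fraction of time spent in each state over ``n_steps`` steps.

    Counts the states at steps 0..n_steps-1 (matching the engine's occupancy
    convention) starting from a point mass on ``start``.
    """
    n = chain.n_states
    v = np.zeros(n)
    v[start if isinstance(start, (int, np.integer)) else chain.encode(start)] = 1.0
    acc = np.zeros(n)
    P = chain.transition
    for _ in range(n_steps):
        acc += v
        v = v @ P
    return acc / n_steps


def phase_occupancy(chain: ChainModel, start: dict[str, int] | int,
                    n_steps: int) -> dict[str, float]:
    """Exact expected phase fractions, via the model's signatures."""
    occ = transient_occupancy(chain, start, n_steps)
    sums = {sig.phase: 0.0 for sig in chain.model.signatures}
    sums["unclassified"] = 0.0
    for code, mass in enumerate(occ):
        if mass == 0.0:
            continue
        state = chain.decode(code)
        matched = [s.phase for s in chain.model.signatures
                   if eval_expr(s.expr, lambda n: state.get(n, 0))]
        key = matched[0] if len(matched) == 1 else "unclassified"
        sums[key] += mass
    return sums
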