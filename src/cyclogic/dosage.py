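"""Gene-dosage perturbation semantics.

A :class:`DosageSpec` maps gene nodes to a copy fraction ``d`` in [0, 1]
(1.0 = wild type, 0.0 = homozygous deletion).  During simulation a dosed
node is stochastically read as absent: each *occurrence* of the node inside a
rule expression is independently reset to 0 with probability ``p = 1 - d``,
and the node's own update outcome (when its rule proposes a positive level)
is likewise reset to 0 with probability ``p``.  With ``d = 1`` the dynamics
are exactly the deterministic model; with ``d = 0`` the node behaves as a
hard knockout clamped at 0.

The same mechanism serves inhibitor / stress titration: an inhibitor leaving
residual activity ``a`` is represented by dosage fraction ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "DosageSpec",
    "inhibitor_spec",
    "RngContract",
    "sample_occurrence",
    "apply_target_reset",
]

#: replicates are grouped on a fixed absolute grid of this many columns; each
#: block owns an independent substream, so results are invariant to how a
#: replicate range is split across runs
REPLICATE_BLOCK = 256


@dataclass(frozen=True)
class DosageSpec:
    """Per-gene copy fractions; unlisted nodes behave exactly as d = 1.0."""

    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for gene, d in dict(self.fractions).items():
            d = float(d)
            if not (0.0 <= d <= 1.0):
                raise ValueError(
                    f"dosage fraction for {gene!r} must be in [0, 1], got {d}"
                )
            clean[str(gene)] = d
        object.__setattr__(self, "fractions", clean)

    def fraction(self, node: str) -> float:
        return self.fractions.get(node, 1.0)

    def reset_probability(self, node: str) -> float:
        return 1.0 - self.fraction(node)

    def dosed_nodes(self) -> tuple[str, ...]:
        """Nodes whose dosage actually perturbs the dynamics (d < 1)."""
        return tuple(g for g, d in self.fractions.items() if d < 1.0)

    def is_deterministic(self) -> bool:
        return not self.dosed_nodes()

    def merged(self, other: "DosageSpec | Mapping[str, float]") -> "DosageSpec":
        frac = dict(self.fractions)
        other_map = other.fractions if isinstance(other, DosageSpec) else other
        frac.update(other_map)
        return DosageSpec(frac)


def inhibitor_spec(node: str, activity: float) -> DosageSpec:
    """Residual-activity spec for an inhibitor (or stress) acting on one node.

    ``activity = 0.25`` is statistically identical to single-copy (25%)
    dosage; ``activity = 0`` is a knockout; ``activity = 1`` is wild type.
    """
    activity = float(activity)
    if not (0.0 <= activity <= 1.0):
        raise ValueError(f"activity must be in [0, 1], got {activity}")
    return DosageSpec({node: activity})


@dataclass(frozen=True)
class RngContract:
    """Deterministic substream policy for replicated simulations.

    Streams are keyed by the absolute replicate-block index (blocks of
    :data:`REPLICATE_BLOCK` replicates on a fixed grid), so identical
    ``(seed, replicate index)`` always yields an identical trajectory and a
    run over replicates ``[lo, hi)`` is bit-compatible with any split of that
    range across separate runs.
    """

    seed: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.seed) < 2**31):
            raise ValueError("seed must be a non-negative 31-bit integer")

    def block_generator(self, block_index: int) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=int(self.seed),
                                    spawn_key=(int(block_index),))
        return np.random.Generator(np.random.Philox(ss))

    def blocks(self, lo: int, hi: int) -> Iterator[tuple[int, int, int]]:
        """Yield (block_index, start, stop) covering replicate range [lo, hi)."""
        if lo < 0 or hi < lo:
            raise ValueError("bad replicate range")
        b = lo // REPLICATE_BLOCK
        while b * REPLICATE_BLOCK < hi:
            start = max(lo, b * REPLICATE_BLOCK)
            stop = min(hi, (b + 1) * REPLICATE_BLOCK)
            yield b, start, stop
            b += 1


# ---------------------------------------------------------------------------
# scalar reference semantics (the engine vectorises the same two operations)
# ---------------------------------------------------------------------------

def sample_occurrence(node: str, value: int, dosage: DosageSpec,
                      rng: np.random.Generator) -> int:
    """Value at which one expression occurrence observes ``node``.

    With probability ``1 - d`` the occurrence reads 0; otherwise it reads the
    true current level.  Every call is an independent draw.
    """
    d = dosage.fraction(node)
    if d >= 1.0 or value == 0:
        return value
    return value if rng.random() < d else 0


def apply_target_reset(node: str, proposed_level: int, dosage: DosageSpec,
                       rng: np.random.Generator) -> int:
    """Outcome-level reset of a dosed node's own update.

    A proposed level of 0 stays 0; a positive proposed level survives with
    probability ``d`` and is reset to 0 otherwise.  Multi-valued nodes keep
    the full proposed level when they survive the draw.
    """
    if proposed_level == 0:
        return 0
    d = dosage.fraction(node)
    if d >= 1.0:
        return proposed_level
    return proposed_level if rng.random() < d else 0
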