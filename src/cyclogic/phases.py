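"""Cell-cycle phase classification and WT-normalised occupancy profiles.

Each simulated state is classified into G1, S_G2 or M by the model's phase
signatures (S and G2 are pooled, as in DNA-content measurements).  A profile
is the mean fraction of time-steps spent in each phase, averaged over
replicates; the *relative* profile divides by the wild-type profile of the
same model and configuration, so WT is identically 1 per phase.  States
reachable only under perturbation may match no signature; they are reported
as unclassified and excluded from the phase fractions rather than forced
into a nearest phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dosage import DosageSpec
from .engine import SimulationConfig, SimulationSummary, simulate
from .logic_model import ModelDefinition, eval_expr

__all__ = ["PhaseProfile", "classify_phase", "phase_profile"]


@dataclass(frozen=True)
class PhaseProfile:
    raw_fraction: Mapping[str, float]
    relative: Mapping[str, float]
    se: Mapping[str, float]
    unclassified_fraction: float
    n_steps_classified: int
    n_replicates: int

    def __getitem__(self, phase: str) -> float:
        return self.raw_fraction[phase]


def classify_phase(state: Mapping[str, int], model: ModelDefinition) -> str:
    """Phase label of one full state; ``"unclassified"`` if nothing matches.

    Raises if more than one signature matches — signatures are required to be
    mutually exclusive, so a double match signals a bad model file.
    """
    matches = [
        sig.phase for sig in model.signatures
        if eval_expr(sig.expr, lambda n: int(state.get(n, 0)))
    ]
    if len(matches) > 1:
        raise ValueError(
            f"state matches multiple phase signatures {matches}: "
            "signatures must be mutually exclusive"
        )
    return matches[0] if matches else "unclassified"


def _profile_from_summary(summary: SimulationSummary,
                          wt_raw: Mapping[str, float] | None) -> PhaseProfile:
    counts = summary.phase_counts.astype(np.float64)
    per_rep = counts / summary.n_steps          # fractions incl. unclassified
    mean = per_rep.mean(axis=0)
    if summary.deterministic or counts.shape[0] < 2:
        se = np.zeros(mean.shape)
    else:
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(counts.shape[0])
    phases = summary.phase_names
    raw = {p: float(mean[k]) for k, p in enumerate(phases)}
    raw_se = {p: float(se[k]) for k, p in enumerate(phases)}
    if wt_raw is None:
        rel = {p: 1.0 for p in phases}
    else:
        rel = {
            p: (raw[p] / wt_raw[p]) if wt_raw[p] > 0 else float("nan")
            for p in phases
        }
    return PhaseProfile(
        raw_fraction=raw,
        relative=rel,
        se=raw_se,
        unclassified_fraction=float(mean[-1]),
        n_steps_classified=summary.n_steps,
        n_replicates=summary.n_replicates,
    )


def phase_profile(model: ModelDefinition, dosage: DosageSpec | None,
                  config: SimulationConfig,
                  wt_profile: PhaseProfile | None = None,
                  summary: SimulationSummary | None = None) -> PhaseProfile:
    """Phase-occupancy profile of a (possibly perturbed) strain.

    The relative map is normalised against ``wt_profile`` when given;
    otherwise the unperturbed model is simulated under the same
    configuration (cheap: the WT is deterministic) and used as reference.
    A WT profile normalised against itself is identically 1.
    """
    if not model.signatures:
        raise ValueError(f"model {model.name!r} has no phase signatures")
    dosage = dosage or DosageSpec()
    if wt_profile is None and not dosage.is_deterministic():
        wt_summary = simulate(model, DosageSpec(), config)
        wt_profile = _profile_from_summary(wt_summary, None)
    if summary is None:
        summary = simulate(model, dosage, config)
    wt_raw = wt_profile.raw_fraction if wt_profile is not None else None
    return _profile_from_summary(summary, wt_raw)
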