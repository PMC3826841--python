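"""Dosage-series experiments and flux-control coefficients.

In metabolic control analysis the flux-control coefficient of an effector E
on a flux J is C = (dJ/J) / (dE/E).  Here the effector is a gene's copy
fraction (equivalently its relative mRNA level) and the flux is the relative
growth rate from cycle simulation.  Because dose–flux relationships in this
system are strongly non-linear, coefficients are reported per adjacent dose
interval with midpoint denominators rather than as one global number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .dosage import DosageSpec
from .engine import GrowthResult, SimulationConfig, growth_rate, simulate, \
    wild_type_period
from .logic_model import ModelDefinition
from .phases import PhaseProfile, phase_profile, _profile_from_summary

__all__ = [
    "DoseSeriesRow",
    "DoseSeriesResult",
    "ControlCoefficient",
    "run_dose_series",
    "control_coefficients",
]


@dataclass(frozen=True)
class DoseSeriesRow:
    dose: float
    growth: GrowthResult
    profile: PhaseProfile | None

    @property
    def relative_growth_rate(self) -> float:
        return self.growth.relative_growth_rate

    @property
    def arrested(self) -> bool:
        return self.growth.arrested


@dataclass(frozen=True)
class DoseSeriesResult:
    gene: str
    rows: tuple[DoseSeriesRow, ...]

    def rates(self) -> dict[float, float]:
        return {r.dose: r.relative_growth_rate for r in self.rows}


@dataclass(frozen=True)
class ControlCoefficient:
    gene: str
    interval: tuple[float, float]     # (d_low, d_high)
    C: float
    dJ_over_J: float
    dE_over_E: float


def run_dose_series(model: ModelDefinition, gene: str,
                    doses: Sequence[float], config: SimulationConfig,
                    with_profiles: bool = True) -> DoseSeriesResult:
    """Growth rate (and optionally phase profile) across a dosage series.

    Doses are sorted descending; the unperturbed point (dose 1.0) is
    simulated once and reused as the WT reference for normalisation.  An
    arrested strain (no completed events at low dose) is a valid outcome,
    not an error.
    """
    if gene not in model.node_names():
        raise KeyError(f"gene {gene!r} not in model {model.name!r}")
    doses = sorted({float(d) for d in doses}, reverse=True)
    if any(not (0.0 <= d <= 1.0) for d in doses):
        raise ValueError("doses must lie in [0, 1]")

    wt_period = wild_type_period(model)
    wt_summary = simulate(model, DosageSpec(), config)
    wt_profile = (_profile_from_summary(wt_summary, None)
                  if model.signatures and with_profiles else None)

    rows = []
    for d in doses:
        dosage = DosageSpec({gene: d})
        summary = (wt_summary if d == 1.0
                   else simulate(model, dosage, config))
        growth = growth_rate(model, dosage, config, wt_period=wt_period,
                             summary=summary)
        profile = None
        if with_profiles and model.signatures:
            profile = phase_profile(model, dosage, config,
                                    wt_profile=wt_profile, summary=summary)
        rows.append(DoseSeriesRow(dose=d, growth=growth, profile=profile))
    return DoseSeriesResult(gene=gene, rows=tuple(rows))


def control_coefficients(series: DoseSeriesResult) -> list[ControlCoefficient]:
    """Finite-difference flux-control coefficients per adjacent dose pair.

    Uses midpoint denominators E = (E_hi + E_lo)/2 and J = (J_hi + J_lo)/2.
    Arrested rows are excluded; at least two usable rows are required.
    C = 0 exactly whenever the flux difference is zero.  A flux that rises
    as dosage falls (haploproficient-like) gives C < 0; one that falls with
    dosage (haploinsufficient-like) gives C > 0.
    """
    usable = [r for r in series.rows if not r.arrested]
    if len(usable) < 2:
        raise ValueError(
            f"series for {series.gene!r} has {len(usable)} non-arrested rows; "
            "need at least 2"
        )
    out: list[ControlCoefficient] = []
    for hi, lo in zip(usable, usable[1:]):
        dE = hi.dose - lo.dose
        dJ = hi.relative_growth_rate - lo.relative_growth_rate
        E_mid = (hi.dose + lo.dose) / 2.0
        J_mid = (hi.relative_growth_rate + lo.relative_growth_rate) / 2.0
        if dJ == 0.0:
            C = 0.0
            rel_dJ = 0.0
        else:
            rel_dJ = dJ / J_mid
            C = rel_dJ / (dE / E_mid)
        out.append(ControlCoefficient(
            gene=series.gene,
            interval=(lo.dose, hi.dose),
            C=C,
            dJ_over_J=rel_dJ,
            dE_over_E=dE / E_mid,
        ))
    return out
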