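"""The packaged extended yeast cell-cycle model.

A reconstruction of a multi-valued logical cell-cycle network for
*S. cerevisiae*: a 22-node core (cyclin/CDK machinery, cell-cycle state
variables and event markers) extended with 30 growth-rate-controlling
regulators, including the G2/M checkpoint module studied in tetraploid
dosage series (HOG1, SLT2, SWE1, HSL1, MIH1, CLB1, CLB2, CDC28).

Design of the unperturbed cycle (31 synchronous steps):

* G1 (steps 0-11, mass low, unbudded).  START fires CLN3, activating SBF
  (SWI4/SWI6).  A cell-wall-integrity segment (PKC1 signal sustained by
  SLT2/RLM1) holds SBF targets back for five steps; afterwards the G1
  cyclins (CLN1, CLN2, CLB6 — each needing Cdc28) must stay active three
  consecutive steps (progressive Whi5 phosphorylation, WHI5P) to commit to S.
* S/G2 (steps 12-23, mass high).  CLB5 triggers replication licensing and
  bud emergence; Clb2 accumulates to its full level; Swe1 appears with the
  bud and is degraded once Hsl1 reaches the bud neck; spindle assembly
  requires high Cdc28-Clb2 activity (CKS1/CDC37-assisted); a late segment in
  which Clb1, competing for Cdc28, retards mitotic entry (CDC55 counter).
  If Swe1 persists, a septin-collar timer (SEPTIN) eventually triggers
  checkpoint adaptation (ZDS1), letting mitosis start late and roughened.
* M (steps 24-30).  Cdc20/APC activation defines mitotic entry; Cdc14
  release, a >2-step cytokinesis run at level 2, mitotic exit (EXIT pulse)
  and the return of mass to one, which is the next START.

Under gene dosage ``d`` each occurrence of the gene in a rule is read as 0
with probability ``1 - d`` and the gene's own update is reset likewise,
which converts the deterministic brakes and gates above into the observed
dosage phenotypes: slt2/clb1 partials release their brakes (~20% faster
cycles), hsl1 loss prolongs Swe1-dependent S/G2 down to ~65% growth,
cdc28 dosage first stalls spindle assembly (G2 pile-up, peaking near
two-copy dosage) and, at the lowest dosages, blocks G1 commitment.

The rule set is a behavioural reconstruction calibrated against the
documented wild-type period and dosage-series phenotypes, not a transcript
of any published rule table.
"""

from __future__ import annotations

import json
from importlib import resources

from .logic_model import (
    ModelDefinition,
    ModuleBlock,
    NodeDef,
    PhaseSignature,
    RuleDef,
    parse_model_dict,
)

__all__ = ["build_extended_model", "load_extended_model", "MODEL_RESOURCE"]

MODEL_RESOURCE = "yeast_extended.json"


def GE(node: str, level: int = 1) -> list:
    return ["GE", node, level]


def EQ(node: str, level: int) -> list:
    return ["EQ", node, level]


def AND(*args) -> list:
    return ["AND", *args]


def OR(*args) -> list:
    return ["OR", *args]


def NOT(arg) -> list:
    return ["NOT", arg]


#: 22 core nodes: cyclins/CDK, transcription factors, structural state
#: variables and the two event markers
CORE_NODES = [
    ("MASS", 2, "event-marker"),      # cell mass: 1 in G1, 2 after S entry
    ("CYTO", 2, "event-marker"),      # cytokinesis variable; completion = 2
    ("CLN3", 1, "gene"),              # START trigger
    ("SWI4", 1, "gene"),              # SBF subunit (G1 latch)
    ("SWI6", 1, "gene"),
    ("WHI5", 1, "gene"),              # SBF inhibitor, early-G1 marker
    ("WHI5P", 3, "state-variable"),   # sustained Cln-Cdc28 commitment counter
    ("CLN2", 1, "gene"),
    ("SIC1", 1, "gene"),              # B-cyclin inhibitor, G1 marker
    ("CDH1", 1, "gene"),              # APC activator, G1
    ("CLB5", 1, "gene"),              # S cyclin, fires at commitment
    ("CLB2", 2, "gene"),              # mitotic B cyclin, multi-valued
    ("CDC28", 1, "gene"),             # the CDK, constitutive
    ("SWE1", 1, "gene"),              # G2/M inhibitory kinase
    ("MIH1", 1, "gene"),              # counteracting phosphatase
    ("MCM1", 1, "gene"),              # mitotic-entry TF (latched)
    ("CDC20", 1, "gene"),             # APC activator: mitosis marker
    ("CDC14", 1, "gene"),             # mitotic-exit phosphatase
    ("CDC5", 1, "gene"),              # polo kinase (entry-network echo)
    ("BUD", 1, "state-variable"),     # bud emergence
    ("SPINDLE", 1, "state-variable"), # spindle assembled
    ("SEPTIN", 16, "state-variable"), # septin-collar / checkpoint timer
]

#: 30 added growth-rate-controlling regulators
ADDED_NODES = [
    ("HSL1", 1, "gene"),
    ("SLT2", 1, "gene"),
    ("HOG1", 1, "gene"),
    ("CLB1", 1, "gene"),
    ("PKC1", 6, "gene"),              # CWI signal strength (counter-like)
    ("RLM1", 1, "gene"),              # CWI transcription factor
    ("NET1", 7, "gene"),              # Cdc14 sequestration release counter
    ("CDC55", 7, "gene"),             # PP2A: mitotic-entry restraint counter
    ("ZDS1", 1, "gene"),              # checkpoint adaptation latch
    ("PBS2", 1, "gene"),              # HOG cascade (inactive unstressed)
    ("SSK1", 1, "gene"),
    ("SHO1", 1, "gene"),
    ("STE11", 1, "gene"),
    ("OSMO", 1, "state-variable"),    # osmotic-stress input (0 = unstressed)
    ("GIN4", 1, "gene"),              # septin-collar kinases
    ("KCC4", 1, "gene"),
    ("ELM1", 1, "gene"),
    ("NAP1", 1, "gene"),              # Clb-associated factor
    ("CLN1", 1, "gene"),
    ("CLB6", 1, "gene"),
    ("CDC6", 1, "gene"),              # replication licensing
    ("CDC45", 1, "gene"),
    ("MCM2", 1, "gene"),
    ("TEM1", 1, "gene"),              # mitotic-exit network
    ("CKS1", 1, "gene"),              # CDK accessory subunit
    ("CDC37", 1, "gene"),             # CDK chaperone
    ("CDC34", 1, "gene"),             # SCF ubiquitination
    ("CDC4", 1, "gene"),
    ("MKK1", 1, "gene"),              # CWI MAP2K (echo of PKC1 activity)
    ("EXIT", 1, "state-variable"),    # mitotic-exit pulse
]

# the cell-wall-integrity brake releases either on completion (PKC1 at top
# level) or as soon as the signal has collapsed with SBF already on
_G1_RELEASE = OR(EQ("PKC1", 6), AND(GE("SWI4"), EQ("PKC1", 0)))

# Clb1-restraint release: counter complete, or collapsed after the entry
# network (MCM1 -> CDC5) is armed
_G2_RELEASE = OR(EQ("CDC55", 7), AND(EQ("CDC55", 0), GE("CDC5")))

_SLT2_HOLD = [GE("SLT2"), GE("SLT2"), GE("SLT2"), GE("SLT2"), GE("RLM1")]
_CLB1_HOLD = [GE("CLB1"), GE("CLB1"), GE("NAP1")]


def _core_rules() -> list[RuleDef]:
    R: list[tuple[str, int, list]] = []

    # ---- mass and cytokinesis (event machinery) -------------------------
    R.append(("MASS", 2, OR(
        AND(EQ("MASS", 2), NOT(AND(GE("EXIT"), EQ("CYTO", 2)))),
        GE("CLB5"))))
    R.append(("MASS", 1, GE("MASS", 0)))  # mass never drops to zero
    R.append(("CYTO", 2, AND(GE("CYTO", 1), GE("CDC14"), NOT(GE("EXIT")))))
    R.append(("CYTO", 1, AND(GE("CDC14"), EQ("CYTO", 0), NOT(GE("EXIT")))))

    # ---- START and SBF --------------------------------------------------
    R.append(("CLN3", 1, AND(EQ("MASS", 2), GE("EXIT"))))
    R.append(("SWI4", 1, OR(GE("CLN3"), AND(GE("SWI4"), EQ("MASS", 1)))))
    R.append(("SWI6", 1, OR(GE("CLN3"), AND(GE("SWI6"), EQ("MASS", 1)))))
    R.append(("WHI5", 1, OR(
        AND(GE("EXIT"), EQ("MASS", 2)),
        AND(GE("WHI5"), EQ("MASS", 1), NOT(_G1_RELEASE)))))

    # ---- cell-wall-integrity brake (SLT2-sustained) ---------------------
    R.append(("PKC1", 1, AND(EQ("PKC1", 0), GE("CLN3"), GE("WHI5"),
                             *_SLT2_HOLD)))
    for k in range(2, 7):
        R.append(("PKC1", k, AND(EQ("PKC1", k - 1), *_SLT2_HOLD)))

    # ---- G1 cyclins and commitment --------------------------------------
    for cln in ("CLN1", "CLN2", "CLB6"):
        R.append((cln, 1, AND(EQ("MASS", 1), GE("CDC28"), _G1_RELEASE)))
    cln_any = OR(GE("CLN1"), GE("CLN2"), GE("CLB6"))
    for k in range(1, 4):
        R.append(("WHI5P", k, AND(EQ("WHI5P", k - 1), cln_any, EQ("MASS", 1))))
    R.append(("CLB5", 1, AND(EQ("WHI5P", 3), EQ("MASS", 1),
                             NOT(GE("RAD9")))))

    # ---- G1 markers ------------------------------------------------------
    R.append(("SIC1", 1, OR(
        AND(GE("EXIT"), EQ("MASS", 2)),
        AND(GE("SIC1"), EQ("MASS", 1), NOT(GE("CLB5"))))))
    R.append(("CDH1", 1, OR(
        AND(GE("EXIT"), EQ("MASS", 2)),
        AND(GE("CDH1"), EQ("MASS", 1)))))
    R.append(("CDC28", 1, GE("MASS", 0)))  # constitutive CDK supply

    # ---- replication, bud, Clb2 accumulation ----------------------------
    R.append(("CDC6", 1, GE("CLB5")))
    R.append(("MCM2", 1, GE("CDC6")))
    R.append(("CDC45", 1, GE("MCM2")))
    R.append(("BUD", 1, AND(OR(GE("CDC6"), GE("BUD")), EQ("MASS", 2),
                            NOT(GE("EXIT")))))
    R.append(("CLB2", 2, AND(GE("CLB2", 1), GE("BUD"), EQ("MASS", 2),
                             NOT(GE("CDC14")))))
    R.append(("CLB2", 1, OR(
        GE("MCM2"),
        AND(EQ("MASS", 2), GE("BUD"), NOT(GE("CDC14"))))))

    # ---- morphogenesis checkpoint ---------------------------------------
    R.append(("SWE1", 1, OR(
        AND(GE("CDC6"), EQ("MASS", 2)),
        AND(GE("SWE1"), EQ("MASS", 2), EQ("CDC20", 0), NOT(GE("HSL1"))),
        AND(GE("SWE1"), EQ("MASS", 2), EQ("CDC20", 0), GE("HOG1")))))
    R.append(("HSL1", 1, AND(GE("BUD"), EQ("MASS", 2), EQ("CDC20", 0))))
    for k in range(1, 16):
        R.append(("SEPTIN", k, AND(EQ("SEPTIN", k - 1), GE("SWE1"),
                                   EQ("MASS", 2), EQ("CDC20", 0))))
    R.append(("SEPTIN", 16, AND(OR(EQ("SEPTIN", 15), EQ("SEPTIN", 16)),
                                GE("SWE1"), EQ("MASS", 2), EQ("CDC20", 0))))
    R.append(("ZDS1", 1, OR(
        AND(EQ("SEPTIN", 16), EQ("MASS", 2)),
        AND(GE("ZDS1"), EQ("MASS", 2), NOT(GE("EXIT"))))))

    # ---- spindle assembly: the high-Cdc28-activity gate ------------------
    R.append(("CKS1", 1, AND(GE("CLB2", 1), EQ("MASS", 2),
                             GE("CDC28"), GE("CDC28"))))
    R.append(("CDC37", 1, AND(GE("CLB2", 1), EQ("MASS", 2),
                              GE("CDC28"), GE("CDC28"))))
    R.append(("SPINDLE", 1, OR(
        AND(GE("SPINDLE"), EQ("MASS", 2), NOT(GE("EXIT"))),
        AND(EQ("CLB2", 2), GE("CKS1"), GE("CDC37"),
            GE("CDC28"), GE("CDC28"), GE("CDC28"), GE("CDC28")))))

    # ---- mitotic entry: MCM1 latch, Clb1 restraint, Cdc20 ---------------
    R.append(("MCM1", 1, OR(
        AND(GE("MCM1"), EQ("MASS", 2), NOT(GE("EXIT"))),
        AND(GE("SPINDLE"), EQ("CLB2", 2),
            OR(EQ("SWE1", 0), GE("ZDS1"))))))
    R.append(("CDC5", 1, AND(GE("MCM1"), EQ("MASS", 2), NOT(GE("EXIT")))))
    R.append(("CDC55", 1, AND(EQ("CDC55", 0), GE("SPINDLE"),
                              OR(EQ("SWE1", 0), GE("ZDS1")),
                              NOT(GE("MCM1")), *_CLB1_HOLD)))
    for k in range(2, 8):
        R.append(("CDC55", k, AND(EQ("CDC55", k - 1), NOT(GE("EXIT")),
                                  *_CLB1_HOLD)))
    R.append(("CDC20", 1, OR(
        AND(GE("CDC20"), EQ("MASS", 2), NOT(GE("EXIT"))),
        AND(GE("MCM1"), EQ("MASS", 2), _G2_RELEASE,
            NOT(GE("MAD2")), NOT(GE("EXIT"))))))

    # ---- mitotic exit ----------------------------------------------------
    for k in range(1, 8):
        R.append(("NET1", k, AND(EQ("NET1", k - 1), GE("CDC20"),
                                 EQ("MASS", 2), NOT(GE("EXIT")))))
    R.append(("CDC14", 1, OR(
        AND(GE("CDC14"), EQ("MASS", 2), NOT(GE("EXIT"))),
        AND(GE("CDC20"), EQ("ZDS1", 0), GE("NET1", 1), NOT(GE("EXIT"))),
        AND(GE("CDC20"), GE("ZDS1"), GE("NET1", 3), NOT(GE("EXIT"))))))
    R.append(("EXIT", 1, AND(EQ("CYTO", 2), NOT(GE("EXIT")), OR(
        AND(EQ("ZDS1", 0), GE("NET1", 5)),
        AND(GE("ZDS1"), GE("NET1", 7))))))
    R.append(("TEM1", 1, AND(GE("CDC14"), OR(GE("MIH1"), GE("CDC14")),
                             NOT(GE("EXIT")))))
    R.append(("MIH1", 1, AND(GE("CDC20"), EQ("MASS", 2), NOT(GE("EXIT")))))

    # ---- CWI pathway context --------------------------------------------
    R.append(("SLT2", 1, OR(
        AND(GE("EXIT"), EQ("MASS", 2)),
        AND(EQ("MASS", 1), GE("CDH1")))))
    R.append(("RLM1", 1, OR(
        AND(GE("EXIT"), EQ("MASS", 2)),
        AND(EQ("MASS", 1), GE("SLT2"), GE("SLT2"), GE("SLT2"), GE("SLT2")))))
    R.append(("MKK1", 1, AND(GE("PKC1", 1), EQ("MASS", 1))))

    # ---- HOG pathway (silent without osmotic stress) ---------------------
    R.append(("SSK1", 1, GE("OSMO")))
    R.append(("SHO1", 1, GE("OSMO")))
    R.append(("STE11", 1, GE("SHO1")))
    R.append(("PBS2", 1, AND(GE("OSMO"), OR(GE("SSK1"), GE("STE11")))))
    R.append(("HOG1", 1, AND(GE("OSMO"), GE("PBS2"))))

    # ---- septin-collar kinases and SCF decorations ----------------------
    for g in ("GIN4", "KCC4", "ELM1"):
        R.append((g, 1, AND(GE("BUD"), EQ("MASS", 2), EQ("CDC20", 0))))
    R.append(("NAP1", 1, AND(GE("CLB1"), GE("CLB1"), GE("CLB1"),
                             EQ("MASS", 2))))
    R.append(("CLB1", 1, AND(GE("CLB2", 1), EQ("MASS", 2),
                             NOT(GE("CDC14")))))
    R.append(("CDC34", 1, OR(GE("CLN1"), GE("CLB2", 1))))
    R.append(("CDC4", 1, GE("CDC34")))

    return [RuleDef(t, l, e) for t, l, e in R]


START_STATE = {
    "MASS": 1, "CDC28": 1, "CLN3": 1, "SIC1": 1, "CDH1": 1,
    "SLT2": 1, "RLM1": 1, "WHI5": 1,
}


def build_extended_model() -> ModelDefinition:
    """Construct (and fully validate) the extended cell-cycle model."""
    nodes = tuple(NodeDef(n, m, r) for n, m, r in CORE_NODES + ADDED_NODES)
    start = {nd.name: START_STATE.get(nd.name, 0) for nd in nodes}
    signatures = (
        PhaseSignature("G1", EQ("MASS", 1)),
        PhaseSignature("S_G2", AND(EQ("MASS", 2), EQ("CDC20", 0))),
        PhaseSignature("M", AND(EQ("MASS", 2), GE("CDC20"))),
    )
    modules = (
        # Checkpoint circuits are represented as minimal toggleable stubs:
        # the stress inputs stay 0 unless driven, and core rules consult the
        # sensor nodes under NOT-guards (a disabled module clamps them to 0).
        # The internal wiring of the full published checkpoint circuits is
        # intentionally not reproduced here.
        ModuleBlock(
            name="spindle_checkpoint",
            nodes=(NodeDef("SPC_STRESS", 1, "state-variable"),
                   NodeDef("MAD2", 1, "gene")),
            rules=(RuleDef("MAD2", 1, AND(GE("SPC_STRESS"), GE("SPINDLE"))),),
            enabled=False,
        ),
        ModuleBlock(
            name="dna_damage",
            nodes=(NodeDef("DNA_DAMAGE", 1, "state-variable"),
                   NodeDef("RAD9", 1, "gene")),
            rules=(RuleDef("RAD9", 1, GE("DNA_DAMAGE")),),
            enabled=False,
        ),
    )
    model = ModelDefinition(
        nodes=nodes,
        rules=tuple(_core_rules()),
        signatures=signatures,
        start_state=start,
        event_nodes={"cytokinesis": "CYTO", "mass": "MASS",
                     "cytokinesis_level": 2},
        modules=modules,
        name="yeast-extended",
    )
    model.validate_static()
    model.validate_dynamics(max_period=256)
    return model


def load_extended_model() -> ModelDefinition:
    """Load the packaged JSON copy of the extended model."""
    text = resources.files("cyclogic.models").joinpath(MODEL_RESOURCE).read_text()
    return parse_model_dict(json.loads(text), name="yeast-extended")
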