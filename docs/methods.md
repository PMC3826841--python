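# Methods

## Model formalism

A model is a finite set of nodes, each holding an integer level
0..`max_level`, updated **fully synchronously**: every node's next level is
computed from the complete previous state.  Rules are threshold expressions
(`node ≥ ℓ`, `node = ℓ`, AND/OR/NOT); for a multi-valued target the rules
are evaluated in descending target level and the first satisfied rule wins,
with 0 as the default.  Synchronous updating is what makes a fixed
wild-type period (and hence "time in fractions of a cell cycle") well
defined; asynchronous or priority-class schemes used by some logical
cell-cycle models are deliberately out of scope.

Time is dimensionless.  One step is 1/31 of a wild-type cycle; no
calibration to minutes is attempted, because chronological cycle length
varies with nutrients while the relative step structure does not.

## Dosage semantics

Copy fraction *d* of a gene is simulated by two stochastic reset sites,
applied every time-step with reset probability *p* = 1 − *d*:

1. **occurrence-level** — each occurrence of the gene in any rule
   expression independently reads the gene as 0 with probability *p*
   (including occurrences under NOT, which therefore become *satisfied*
   when the gene is missed);
2. **outcome-level** — when the gene's own rules propose a positive level,
   the result is reset to 0 with probability *p*; multi-valued genes that
   survive the draw keep the full proposed level ("maintained at the level
   for which the logical requirements are satisfied").

Both sites are needed for the two natural readings of a dosage rubric —
the gene as an input to other rules and the gene's own activation — to be
consistent simultaneously; the exact-chain oracle implements the identical
semantics, so the choice is pinned by tests rather than convention.  The
limits are exact: *d* = 1 is the deterministic model, *d* = 0 a hard clamp
at 0.  Dosage is not restricted to quarters; any *d* ∈ [0, 1] is accepted
so DAmP-like alleles (~0.2) and continuous inhibitor titrations can be
expressed through the same mechanism (`inhibitor_spec`).

## Random-number contract

Replicates draw from Philox streams keyed by `(seed, block)` on a fixed
absolute grid of 256 replicates per block.  A run covering any replicate
range simulates whole blocks and slices, so (a) identical seeds give
byte-identical outputs, and (b) a run of *a* + *b* replicates equals the
concatenation of two runs over the sub-ranges — replicate-range
additivity, which the suite asserts exactly.  Within a time-step the draw
order is fixed (nodes in declaration order, rules in descending level,
expression leaves depth-first, no short-circuiting), which is also the
enumeration order used by the oracle.

## Event counting and growth rate

A division is a run of **> 2** consecutive steps with CYTOKINESIS at its
completion level (level 2 in the packaged model); the cycle closes when
MASS next returns to 1.  Runs truncated by the simulation horizon are
discarded.  Whether the mass-return condition is required for *counting*
(rather than only for delimiting the period) is switchable
(`require_mass_return`, default on); for the packaged model both readings
coincide in the wild type.

Per replicate the relative growth rate is `T_WT / mean(period)`, 0 if no
event completed; the strain value is the replicate mean with its
Monte-Carlo standard error, and `arrested` is flagged only when *no*
replicate divides.  The raw period ratio is exposed alongside, since the
inverse convention appears in the literature; the inverse is used here
because growth rate is proportional to the inverse of the doubling time.
Incomplete terminal cycles are excluded from the mean period (unbiased at
the cost of a little data).

## Phase classification

Signatures are mutually exclusive by construction in the packaged model
(G1: mass = 1; S–G2: mass = 2 before APC/Cdc20 activation; M: mass = 2
with Cdc20 on) and validated over the whole wild-type cycle at load time.
S and G2 are pooled, matching what DNA-content measurements resolve.
States matching no signature are reported as `unclassified` and excluded
from phase fractions rather than forced into a nearest phase — silent
misclassification would corrupt perturbed profiles.  Occupancy counts the
`n_steps` states at steps 0..n_steps−1.

## The packaged extended model

The packaged network (22 core + 30 added nodes, 4 stub checkpoint nodes in
toggleable modules) is a **behavioural reconstruction**: the published
supplementary rule script of the study model was not available, so the
wiring was engineered from the documented biology and calibrated so that
the documented wild-type period (31 steps; G1/S–G2/M = 12/12/7 steps) and
the documented dosage-series phenotypes hold.  Node names follow the real
genes whose roles they play, but individual rules should be read as
effective logic, not literature-curated interactions.  The load-bearing
mechanisms are:

* **SLT2 brake (G1).**  A cell-wall-integrity signal (PKC1 counter,
  sustained by SLT2 reads via RLM1) delays SBF-driven commitment by five
  steps.  Any dosage reduction makes the multi-read hold fail quickly
  (per-step hold probability ≈ d⁸), collapsing the brake: partial and null
  slt2 run ~26-step cycles, ~19% faster than WT.
* **Cdc28 commitment gate (G1).**  Three redundant G1/S cyclins (CLN1,
  CLN2, CLB6), each requiring a Cdc28 read, must fire on three consecutive
  steps (WHI5P counter).  The redundancy keeps the gate robust at moderate
  dosage and lets it collapse sharply below ~25%, producing G1 arrest at
  the lowest CDC28 dosages.
* **Spindle-assembly gate (S/G2).**  SPINDLE formation needs Clb2 at full
  level plus four Cdc28 reads and two Cdc28-dependent helpers (CKS1,
  CDC37) — an effectively ~9th-power dosage dependence.  At intermediate
  CDC28 dosage this is the rate-limiting step, piling occupancy into S/G2
  (peak ≈ 2.5× WT at 50% dosage) before the G1 gate takes over at low
  dosage: the bimodal arrest transition.
* **Morphogenesis checkpoint (S/G2).**  Swe1 appears with the bud and is
  degraded when Hsl1 is read (per-step success d²).  Under HSL1 loss a
  septin timer (SEPTIN, cap 16) eventually triggers adaptation (ZDS1),
  which also roughens mitotic exit (+2 M steps): the null runs a
  deterministic 47-step cycle (66% of WT) with S/G2 occupancy ≈ 1.43× WT.
* **Clb1 restraint (late S/G2).**  After the entry network arms, a CDC55
  counter sustained by CLB1 reads (≈ d⁷ per step, with NAP1) holds Cdc20
  activation back five steps; any CLB1 reduction releases it (~19%
  faster), while CLB2 — wired into Clb2-level maintenance and the spindle
  gate instead — arrests at low copy number.  This implements the
  divergence of the two B-cyclins.
* **HOG1 / MIH1 neutrality.**  The HOG cascade requires the OSMO stress
  input, which is 0 in unstressed simulations, and Mih1's contribution at
  mitotic exit is redundant with Cdc14; dosage of either gene provably
  leaves the dynamics unchanged (rates exactly 1.0).

Known limitations of the reconstruction: SWE1 dosage is near-neutral here,
whereas the study model predicted (and its authors flagged as its own
fault) a growth decrease at low swe1 copy number; the slt2/clb1 brakes sit
in single phases, so those deletion profiles shift phase composition more
than the reported "comparable to WT" profiles; checkpoint module internals
are illustrative stubs (their toggling mechanics, not their biology, are
the supported feature).

## Monte-Carlo problem sizes

Dosage-series checks in the test suite use 256 replicates × 2,000 steps;
`scripts/acceptance.py` uses 512 × 2,000.  At these sizes the reported
quantities are stable to well under the tolerance of any comparison made
(e.g. the CDC28 G2 peak varies by < 0.01 between seeds) while a full series
runs in seconds to a minute on one CPU.  Occupancies at strongly arrested
dosages (CDC28 ≤ 25%) are horizon-dependent by nature — cells that never
pass G1 within the window count as G1 — which matches how finite-length
simulated profiles are assembled in practice.

## Oracle

For models whose active state space is ≤ 4096 states, the one-step
transition distribution factorises over target nodes (each node's next
level depends only on its own rule reads and reset draw), so the exact
row-stochastic transition matrix is assembled by enumerating, per node, the
joint outcomes of its stochastic occurrence reads (capped at 16 per node)
and the outcome reset.  Transient occupancy is accumulated by iterated
vector–matrix products with the same step-counting convention as the
engine.  The suite requires exact engine/oracle agreement at d ∈ {0, 1}
and agreement within 3 standard errors at intermediate dosages.

## Numerical and design notes

* Expression evaluation never short-circuits, keeping draw counts
  state-independent and engine/oracle enumeration aligned.
* Counters reset to 0 on a failed hold (no rule satisfied); release
  detection uses armed-marker nodes so a collapsed brake is taken at the
  next step, giving the sharp partial-dosage release the phenotypes need.
* Control coefficients are reported per adjacent dose interval with
  midpoint denominators; dose–flux curves here are strongly non-linear and
  a single global coefficient would mislead.  `C = 0` exactly when
  `ΔJ = 0`; arrested rows are excluded.
* Model files are canonical JSON (sorted keys, fixed indentation):
  re-serialising a model is byte-stable and diff-able.
* The CLI writes a manifest (configuration + seed + version) next to every
  output; outputs are reproducible from the manifest alone.
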