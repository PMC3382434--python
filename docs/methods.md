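# Methods

## Model overview

A cell is a weighted directed network over triplets (gene/mRNA → protein →
modified protein).  Node values are molecule counts; edges carry a signed
weight `w` and a regulator sigmoid (midpoint `m̃`, slope `s̃`) applied to the
source's count; each node carries a basal expression probability, a
production sigmoid (midpoint `m`, slope `s`), and a per-molecule, per-step
degradation probability.  Two external signals S1/S2 act as edge sources with
value 0 (off) or 10 (on) — the top of the regulator-midpoint range — so
signal edges use the same sigmoid machinery as internal edges.

### Update semantics

All nodes update synchronously from the previous step's counts:

1. production: node *i* gains one molecule with probability
   `G_i = clamp(basal + (1 - basal)·tanh((Σ w f - m)/s))`.  Production of a
   protein requires its triplet's mRNA count ≥ 1 (not consumed); production
   of a modified protein requires a protein and converts it (the consumed
   protein is taken after degradation, floored at zero).
2. degradation: survivors are Binomial(v, 1 - degr) per node, i.e. each
   molecule decays independently.

Bounded production (at most one molecule per node per step) gives bounded
stationary counts around `G/degr`; with the default parameter ranges typical
counts are O(10), so traces carry substantial Poisson-scale noise (see
*Limitations*).  Whether a modified protein reverts to the unmodified state
or is lost is not resolved by the model; degradation of the modified form
plus fresh translation approximates reversion.

### Energy economy

Per step, `ΔE = v_RP0 · (50·[nutrient] − 1) − 10·(n_nodes − 1)`: each RP₀
molecule metabolizes nutrients for 50 energy units per step when they are
present and costs 1 unit per step to maintain; every other node type in the
genome costs a flat 10 units per step.  Scaling the metabolic terms with the
RP₀ molecule count (rather than a flat on/off bonus) is what makes
multi-triplet genomes energetically viable: a flat 50-unit gain could never
cover the maintenance of more than a couple of triplets, whereas here a
well-timed responder with a few dozen RP₀ molecules sustains and divides.
Cells divide at 1,600,000 units (parent and daughter take half each — the
daughter replaces a competitor drawn with probability ∝ 1/energy) and start
at 800,000; a cell at zero energy is replaced by a fresh random genome.
Mutation events can be given an energy cost (default 0).

### Environments

One epoch is 4,500 steps split into four equal windows cycling
(s1,s2) = (0,0), (1,0), (1,1), (0,1).  Nutrient presence is the gate value
(A: s1∧¬s2, B: ¬s1∧s2, XOR) of the signals 300 steps earlier, with periodic
wrap-around.  Window length 1,125 and delay 300 are package defaults chosen
so XOR gets two nutrient pulses per epoch and A/B one each; both are
configurable.  The nutrient schedules satisfy N_A ∨ N_B = N_XOR pointwise.

## Random genomes

Unevolved cells carry T0 plus 1–15 random triplets.  Node parameters are
uniform on basal ∈ [0, 0.5], m ∈ [−1, 1], s ∈ [1, 4], degr ∈ [0.01, 0.1]
(the degradation range is a package choice); edge parameters uniform on
m̃ ∈ [0, 10], s̃ ∈ [1, 4]; initial molecule counts are 0.  Weight magnitudes
follow a Pareto law with density exponent 1.5 above w_min = 0.04 — fixed by
the tail condition P(|w| > 4) = 0.10 — with signs equiprobable and magnitudes
capped at 100.  The cap is applied by clipping rather than truncation so the
printed tail probability is preserved exactly.  The edge budget is a sparsity
fraction drawn from [0, 0.2] of all (source, target) pairs with signals
counted as sources; signal edges are assigned first by a sequential process
accepting the (n+1)-th attachment with probability e^(−n), the rest uniformly.

## Mutation

Per triplet per step: weak 1e-5, strong 4e-6, creation 1e-6, destruction
1e-6.  A weak event perturbs one uniformly chosen parameter of the triplet's
nodes or incident edges with a Gaussian of width 10% of its legal range
(weights: σ = 0.4), clipped; a strong event redraws the parameter from its
initialization distribution (weights from the power law).  Signal
(re)connection is one extra slot in the weak menu; the target node is chosen
with probability ∝ e^(−n) in its current signal-regulation count, and an
existing (signal, node) edge is replaced, never duplicated.  Creation
duplicates a uniformly chosen triplet (parameters and incident edges copied)
or inserts a fresh random triplet with probability ½ each; destruction
removes a uniform non-metabolic triplet and never T0.

## Horizontal gene transfer

Fragment sizes follow `p(x) ∝ 1 − tanh((x − m)/s)` on x ≥ 0 with closed-form
normalization `Z = 2m + s·ln(1 + e^(−2m/s))`.  The model exposes both the
continuous law (CDF and mean, used for analytic summaries: with s = m the
CDF at m is 0.674 and the mean for m = 5 is 4.13) and a discrete renormalized
pmf on 1..support_max (default 20) used for actual sampling, truncated to the
donor's non-metabolic triplet count.  An event copies the sampled number of
uniformly chosen donor triplets with their internal edges, incoming signal
edges, and edges to/from the donor's T0; on integration the fragment gets
fresh triplet ids, T0-side endpoints are remapped onto the recipient's T0,
and no other cross-edges are created (an optional "random rewiring" mode can
add Bernoulli-sparse cross-edges; off by default).  Copying the T0→fragment
direction is flag-controlled and on by default.  Population mode is pairwise
(uniform donor) or pool (naked-DNA fragments); the default rate is 5e-5 per
cell per step.

## Fitness and the DFE

Fitness w is the Pearson correlation between the RP₀ count trace and the
nutrient trace over one epoch, clamped below at 0; constant traces score 0;
multi-epoch fitness is the mean of per-epoch values.  Measurements run on a
clone with energy bookkeeping disabled, so they have no side effects.

The fitness effect of a single event is `w_after/w_before − 1`, with both
sides measured over one epoch on clones; events with w_before < 0.01 are
excluded (the ratio is meaningless without measurable function), lethal means
w_after = 0 exactly, and distribution moments are computed over viable events
(effect > −0.8) with bias-corrected sample skewness and excess kurtosis.
Event classes are drawn ∝ their rates within a source ("mutation" or "hgt").

## Network reduction and phenotype calls

Reduction severs one edge at a time, re-measures fitness averaged over 10
epochs, and makes the removal permanent when the relative change is below 5%;
full passes repeat to a fixed point, then triplets with no remaining
undirected connection to T0 or a signal are dropped.  Validated reference
networks keep ≥ 95% of their full fitness through reduction, and the
procedure is idempotent on them.  Phenotypes are called by 10-epoch fitness
in the A, B and XOR environments with threshold 0.6 (XOR wins ties because an
XOR responder partially matches both single schedules).

## Reference fixtures

`build_reference_cell` wires minimal delayed-AND responders by hand: a slow
"follower" protein (production 0.06, degradation 0.005, rise time ≈ 200
steps) integrates the activating signal and provides the delay; a second
follower integrates the other signal as a veto; a fast gate protein computes
activator-AND-NOT-veto and drives the RP₀ modification of T0.  The A cell
uses triplets T1–T3, the B cell T4–T6, and the XOR cell is their union on a
shared T0 — which is also exactly what one whole-mechanism HGT event
produces.  Measured fitness (10-epoch averages): A ≈ 0.86–0.89 in A,
B ≈ 0.86–0.87 in B, XOR ≈ 0.78–0.85 in XOR.  Because the two mechanisms were
designed orthogonal, their union is functional by construction; genomes
evolved de novo generally interfere when combined, so union-based controls
should be read with that difference in mind.

## Scheduling and problem sizes

The population loop advances epochs in 450-step segments: expression and
energy are exact per step inside a compiled (numba) kernel; mutation, HGT,
division and death-replacement settle at segment boundaries with per-segment
event counts drawn at the per-step rates.  Events are rare at the default
rates, so the quantization leaves event statistics unchanged.  Per-epoch
trajectory fitness comes from each cell's live RP₀ trace (daughters inherit
the parent's trace-so-far; cells replaced after death score from their
replacement's partial trace).  Event before/after fitness recording in the
population loop is opt-in, since it adds two measurement epochs per event;
DFE collection uses the dedicated explicit path instead.

Default experiment sizes are desk-scale — populations of 48–64, tens to
hundreds of epochs, ≥ 8 replicate seeds — chosen so the full test suite and
the reproduction script complete on one CPU; `--full-scale` switches to 256
cells and thousands of epochs.  All runs are reproducible from (config,
seed); the engine draws every random number from seeds supplied by the
caller's generator.

## Limitations

* **Single-molecule expression noise.**  With at most one molecule produced
  per node per step, stationary counts are O(10) and single-epoch fitness of
  a *non-functional* cell is a clamped near-zero correlation with null
  standard deviation ≈ 0.10.  Randomly generated genomes essentially never
  carry reproducible nutrient-timing function, so single-event fitness
  effects measured on unevolved populations are dominated by measurement
  noise: the lethal fraction approaches the clamped-null coin flip (≈ 50%
  for any event class) and viable ratio effects are strongly positively
  biased.  On functional genomes (the validated fixtures) the same estimator
  is well behaved — mutation effects there average ≈ −6% with variance
  ≈ 0.04, strong left skew, and a near-zero lethal fraction — and the lethal
  fraction drops sharply from unevolved to adapted populations for both
  mutations and HGT.  Quantitative DFE statistics from this package are
  therefore trustworthy for adapted populations and for contrasts
  (unevolved vs adapted), not as absolute unevolved-population values.
* **Drift at desk scale.**  Populations below ~32 cells lose function to
  mutation load and replacement churn; the dual-step experiments use ≥ 48.
* **No spatial structure, no mechanism-specific HGT, no resource depletion;**
  nutrient limitation enters only through per-cell energy gain.
* The energy-selection gradient for *timing* (as opposed to expressing RP₀
  at all) is shallow, so de-novo evolution of high-fitness phenotypes needs
  population sizes and epoch counts well beyond desk scale.
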