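# Methods

## Propagation model

The interactome is a signed, directed graph: an edge `u -> v` with sign
+1 (activation) or -1 (inhibition). The model treats it as a recurrent
network of saturating units. Protein activities live in [-1, 1]; a
stimulus is a clamp set (protein, ±1); all other activities start at 0.
One update is synchronous across the whole network,

    y_v <- tanh( sum over incoming edges u->v of w_uv * y_u ),

with clamped proteins re-imposed after every step. The published
description of this modelling style leaves the transfer function, step
count and optimizer unspecified (the original technology is
proprietary), so those are this package's own choices:

- **Squashing:** `tanh` — odd, monotone, maps the reals onto (-1, 1)
  with squash(0) = 0. Oddness buys an exact symmetry (negating every
  clamp negates every activity) that the test suite exploits.
- **Steps `T`:** default 5. Signal through `tanh` with |w| ≤ 1 decays
  geometrically, so depth beyond the typical directed diameter of the
  benchmark networks contributes nothing measurable;
  `network_model.default_steps` computes a diameter-capped value for
  other networks.
- **Updates are synchronous**, making results independent of node
  ordering and bit-reproducible.
- **Activity threshold `tau_act`:** 0.05. "Stimulated" needs a floor
  because `tanh` never reaches 0 exactly; 0.05 is far above
  double-precision noise yet below any signal one planted edge can
  produce. Configurable everywhere it matters.

Edge weights are sign-constrained: a weight may be zero but a nonzero
weight must carry its edge's curated sign. Models therefore differ in
*how much* of each curated interaction they use, never in its direction.

## Training and the solution ensemble

Training data is a truth table of (stimulus clamp set, response protein,
required sign) constraints. A constraint is satisfied when the
propagated response activity has the required sign and magnitude ≥
`tau_act`; accuracy is the satisfied fraction.

One solution is trained by simulated annealing over weight magnitudes:

- initial magnitudes uniform on [0.1, 1] (a nonzero start avoids the
  all-zero fixed point), signs fixed by the edges;
- proposals change one weight: half redraw its magnitude uniformly on
  [0.05, 1], half jitter it by N(0, 0.15), clipped to [0, 1];
- 6,000 proposals per solution, geometric cooling from T=0.05 to 1e-3.
  The initial temperature is deliberately of the same order as the
  objective's quantum (one constraint flipping changes accuracy by
  1/n_constraints); a hotter start simply random-walks. The proposal
  budget is sized so that mean ensemble compliance on the solvable
  reference benchmark sits comfortably in the mid-90s (%), the working
  range reported for this class of models;
- the objective is accuracy plus 0.01 × mean signed response margin.
  The margin term is two orders of magnitude below one accuracy
  quantum, so it can never trade away a satisfied constraint; it only
  breaks ties between plateaus and gives the annealer a direction.

An ensemble ("universe of solutions") is n independent runs with seeds
`base_seed + i`; solutions with accuracy below the acceptance threshold
(default 0.9) are dropped, though every accuracy is recorded. Retained
solutions are weighted uniformly in all ensemble summaries: no density
over solution space is available from the published description, and
uniform weighting over threshold-passing solutions is the assumption
this package makes explicitly.

All stochastic operations take explicit seeds; the same seed reproduces
the same parameters bit-for-bit, and serialized ensembles (JSON header
plus full-precision weight TSVs) reload bit-exactly.

## Triggering analysis

For an evaluated protein p, a mode (clamp p at -1 "inhibited" or +1
"activated"), and a process defined by effectors with expected signs
v_i: propagate through each solution and count effectors at directed
distance d ∈ {1, 2, 3} from p whose activity has sign v_i and magnitude
≥ tau_act, weighted w_d. The published description says distances 1-3
are "positively pondered" without giving weights; this package uses
w = (1, 1/2, 1/3), configurable. Distances follow edge direction from
the stimulus (signal flows downstream); an undirected fallback is not
provided — use a symmetrized network if needed. The source protein
itself (distance 0) never counts toward any tier.

Raw scores are ensemble means; ensemble averaging happens *before*
normalization. Normalization divides each process's scores (both modes)
by that process's maximum over all evaluated proteins and both modes,
so normalized scores lie in [0, 1] and the difference

    D = score_inhibited - score_activated

lies in [-1, 1]. A (protein, process) cell triggers when D > 0.2,
strictly.

**Scale caveat.** Published score tables produced with the proprietary
pipeline contain differences as large as |D| = 2.88, which no
[0,1]-normalized pair can produce; whether their normalization was
per-process, per-mode, or global is not recoverable from the published
text. This package therefore makes no claim of reproducing published
*score values* — only the classification rule, which is
normalization-agnostic and is verified exactly against the published
difference matrices and trigger calls.

## Mechanism-of-action models

Given the triggering-positive ("flagged") off-targets of a drug for a
process, the MoA model clamps *every* drug target at -1 — the flagged
off-targets are the stimulus of interest, the rest are held inhibited to
reproduce the administered drug — and propagates through each solution.

Pathways are simple directed paths, at most `max_len = 4` edges, from a
flagged off-target to a process effector. A path is active in a
solution when every node on it is suprathreshold and every step is
sign-consistent (sign of child activity = edge sign × sign of parent
activity). Support is the fraction of solutions in which the path is
active; paths with support ≥ `min_support = 0.5` are reported, sorted
by support, then length, then lexicographic node order. No support
cutoff is published; 0.5 ("present in most solutions") is this
package's default and both knobs are exposed.

Literature agreement scores a drug's MoA models against a
literature-described response set: a literature protein is *present* in
a model when it is not clamped there (clamped proteins have imposed,
not predicted, signs) and its ensemble-mean activity is suprathreshold;
agreement is the percentage of present proteins whose predicted sign
matches the described direction in **every** model where present. The
any-model alternative sits behind `require_all_models=False`. When no
literature protein is present at all the result is `None` — undefined,
deliberately not 0. DOT export renders nodes colored by mean-activity
sign and inhibiting steps as dashed/tee edges, with deterministic
ordering.

## tSignal and cotreatment interference

For a process with n effectors, expected signs v_i and activities y_i,

    tSignal = -(1/n) * sum_i v_i * y_i ,

implemented verbatim, so a stimulus that drives effectors in their
disease-expected directions scores *negative*. Narratively, "more
signal over the process" reads as positive, so the package also reports
the induction scale, -tSignal, and the headline **Diff Effect** of a
cotreatment is the induction-scale difference

    DiffEffect = tSignal(drug alone) - tSignal(drug + cotreatment),

per solution: a cotreatment that damps the drug-evoked process signal
gets a negative Diff Effect, matching the published sign convention for
interference tables, while both raw tSignal samples are stored and
printed. Both scales appear in the output precisely because the
published equation and the published narrative pull in opposite
directions; neither silently replaces the other.

Overlapping targets with conflicting clamp directions between drug and
cotreatment are an error naming the protein; same-direction overlaps
merge. Effectors missing from the network contribute 0 (logged).

Statistics: the screen runs one two-sided Wilcoxon rank-sum
(Mann-Whitney) test per (cotreatment class, process) comparing the
combined-vs-alone tSignal samples across solutions — the paired
signed-rank alternative on per-solution differences sits behind
`paired=True` — with exact enumeration for tie-free samples up to
n = 20 and the tie-corrected normal approximation above. BH adjustment
spans every test in one screen invocation. A pair is flagged when
q ≤ alpha (0.05) **and** |mean Diff Effect| > 0.05. Two identical
constant samples yield p = 1.0 by convention.

## Synthetic benchmarks

The generator emulates the *structure* of literature-curated inputs,
not any real interactome or target list:

- **Topology:** Barabási–Albert preferential attachment (heavy-tailed
  degrees, like real interactomes — the triggering analysis is
  distance-sensitive, so topology matters), edges oriented uniformly at
  random, inhibition signs with probability 0.3, planted weights of
  magnitude 0.3–0.9 (core) and 0.6–0.95 (effector chains).
- **Drugs:** two profiles sharing a primary target and shared
  off-targets; drug A adds specific off-targets plus one low-potency
  decoy (IC50 above the 500 nM cutoff) and one regulatory-document
  target without an IC50, exercising both branches of the potency
  filter.
- **Planted inducers:** per process, designated off-targets get
  dedicated effector chains at distances 1–3 whose expected signs are
  recorded from propagation under the planted parameters with the
  inducer clamped at -1. Chain nodes have a single parent, so their
  activity signs are structural (independent of magnitudes), and the
  model's odd symmetry makes the activated mode score zero — the
  decision rule recovers inducers by construction. Off-targets are
  placed pairwise ≥ 3 directed steps apart where the network allows
  (falling back to 2 on dense small networks), keeping every
  non-inducer outside the 3-step scoring horizon of every planted
  effector.
- **Antagonist cotreatment:** a dedicated protein with strong edges
  into every effector, signed so that clamping it pushes each effector
  against its expected sign — guaranteeing a negative Diff Effect.
  Null cotreatments draw targets from proteins with no directed path to
  any effector, guaranteeing exactly zero Diff Effect.
- **Truth table:** stimuli of 1–2 random core proteins; responses are
  recorded from planted-model propagation with margin 2 × tau_act, so a
  100%-compliant solution exists by construction.

Generation ends with a hard verification: the planted parameters must
score accuracy 1.0 on the generated truth table and the triggering rule
under the planted parameters must recover the designated inducers
*exactly*; otherwise generation fails loudly rather than handing out a
broken benchmark. Everything is deterministic given the spec seed, to
the byte.

**What passing on synthetic data does not show.** The generator's
effector chains are exclusive-input by design; real effectors receive
convergent, conflicting inputs, so real-data specificity will be worse
than the benchmark's. Real interactomes also carry curation noise,
directionality errors and missing edges that the benchmark does not
model, and real truth tables are not guaranteed satisfiable. The
benchmark establishes that the machinery is correct and recoverable
under controlled conditions — not that any particular biological
conclusion transfers.

## Problem sizes

The reference benchmark is 200 proteins / ~560 edges with 30
constraints and 10-solution ensembles — sized so that a full
generate-train-analyze cycle completes in well under a minute on one
CPU while leaving the training problem genuinely non-trivial (random
initial weights satisfy roughly 60–80% of constraints; annealing closes
the rest). The recovery study spans 10 generator seeds with 8-solution
ensembles. Statistical floor: an 8-vs-8 rank-sum has minimum two-sided
p ≈ 1.6e-4, small enough to survive BH across a 4-test screen at
alpha = 0.05.

## Known limitations

- Uniform weighting over retained solutions is an assumption, not an
  inference; no solution-space density is estimated.
- The triggering normalization is per-process over both modes; other
  conventions produce other scales (see the scale caveat above) and
  only the classification rule is comparable across conventions.
- `T`, `tau_act`, the proximity weights, `min_support` and `max_len`
  are defaults with rationales, not fitted quantities.
- Propagation is deterministic given parameters; biological
  stochasticity enters only through ensemble diversity.
- No pharmacokinetics: interference is purely network-topological
  (metabolic interactions such as CYP3A-mediated ones are out of
  scope).
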