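# Model and methods

## Overview

The package simulates a paired-associate memory paradigm in a
rate-coded neural network with two interacting learning systems. Each
of 12 scene cues is paired with two words ("pairmates"); one pairmate
of half the scenes is retrieval-practiced after study; the final test
cues every association with its scene and first letter only. The
simulation crosses temporal distance (pairmates studied under one
temporal context vs. in two lists with different contexts), semantic
relatedness (whether the semantic layer was pretrained on the pairmate
mapping) and sleep (whether a context-free replay phase follows
retrieval practice), and asks how retrieval practice changes memory
for the *unpracticed* pairmate relative to list-matched controls.

## Stimuli and design

All stimuli are random binary patterns over 7×7 pools with 20% of
units active (10 of 49; rounding is half-up). The input layer holds
six pools: scene, two word slots, first letter, and two temporal
context pools. A stimulus bank per run contains 12 scenes, 24 words,
24 unique letter patterns, two context patterns (each spanning both
context pools) and 24 unused filler words for unrelated pretraining.
Pairmates occupy different word slots. In the far condition, slot-1
words are studied in list 0 under context A and slot-2 words in list 1
under context B, so the nontarget always precedes its target; in the
close condition everything shares context A and pairmates are studied
adjacently. Control baselines use the list-position-matched control
pairmate (the earlier-list pairmate in far; both pairmates averaged in
close), which removes a serial-position confound the design would
otherwise carry.

## Network

Layers (default reduced-scale preset, see "Simulation scale"):
Input/ECin/ECout/Output 6×(7×7); DG 30×30 (2% active); CA3 24×24 (4%);
CA1 6×(8×8) (10% per pool); Letter and Semantic 14×14; Cortex 20×20.
Unit activity follows a logistic rate function of (net input −
inhibitory threshold) with gain 10; pooled k-winners-take-all
inhibition sets the threshold at the midpoint between the k-th and
(k+1)-th largest net inputs. Two refinements matter for behaviour:

* an absolute net-input floor (0.15) keeps undriven pools silent
  instead of letting k noise units win;
* CA3 and CA1 use a *graded inhibition tail* (units within a small
  margin below threshold keep low activity) approximating soft
  feedforward/feedback inhibition; a hard top-k cut would annihilate
  the partial co-activation of a cued competitor on which the
  close-condition effects depend.

Net input is fan-in normalised by the expected number of *active*
inputs (fan-in × the sender layer's activity fraction), so sparse
layers such as DG and CA3 drive their targets as strongly as dense
ones. Weights are initialised uniformly in [0.25, 0.75]; hippocampal
pathway weights in [0.05, 0.30] so that rapidly learned synapses stand
out against the unlearned background.

Projections follow the standard cortico-hippocampal circuit: fixed
one-to-one Input→ECin; random-sparse perforant-path ECin→DG (25%) and
ECin→CA3 (25%); sparse strong mossy DG→CA3 (5%, relative scale 3);
CA3 recurrents; CA3→CA1; the pool-aligned monosynaptic loop
ECin→CA1→ECout with ECout→CA1 feedback; fixed one-to-one ECout→Output;
and the cortical routes Input(scene,words)→Cortex→Output with an
Output→Cortex feedback that lets error signals shape the association
cortex. Letter and Semantic are driven by fixed sparse random
encodings of the letter and word pools and project into the word pools
of both Output and ECin.

## Trial dynamics (theta quarters)

A trial is a sequence of settling "quarters" with pathway gating:

1. **encode** — CA1 is slaved to ECin (CA3→CA1 off);
2. **retrieve** — CA3 drives CA1 (ECin→CA1 attenuated to 0.1) and
   mossy input is attenuated (0.2), so completion is carried by the
   perforant path and CA3 recurrents rather than by the
   pattern-separated DG response to a partial cue; the end state is
   the expectation (minus) snapshot;
3. **outcome** — with an external target, ECin returns to full
   strength over CA1 and the binarised ECin pattern drives ECout (and,
   through it, the cortical Output); the end state is the outcome
   (plus) snapshot.

Two asymmetries in the outcome clamp are deliberate and load-bearing:

* **Missing evidence is not negative evidence.** Only pools that carry
  content are clamped on ECout; an undriven pool keeps its own
  prediction (its CA3 drive is unchanged between the two snapshots, so
  it is neither confirmed nor punished). Without this, each pairmate's
  study trial would actively unbind the other pairmate — in the close
  condition the two pairmates share essentially the same CA3 code, and
  hard-clamping the absent word pool to silence erases the sibling
  association as fast as it is learned. The same rule applies to the
  cortical target during sleep replay; during online study the task
  context licenses the full clamp (the cortical delta rule trained
  toward the complete pattern is what produces competition-dependent
  weakening).
* **Committing to retrieval.** When no target is available (retrieval
  practice), the model commits to its own retrieval: ECout units above
  a threshold (0.4) are driven to 1 (sub-threshold units stay free),
  and the full binarised pattern is the cortical target. Spurious
  cortical candidates the hippocampus did not retrieve are therefore
  suppressed — the source of retrieval-induced forgetting — while
  co-retrieved content (the close-condition pairmate) is strengthened.

## Learning

Each plastic projection mixes CPCA Hebbian learning
(Δw = lr·y·(x−w)) with contrastive error-driven learning
(Δw = lr·(x⁺y⁺ − x⁻y⁻)); updates are soft-bounded so weights stay in
[0, 1]. Defaults: 5% Hebbian mix on error-driven projections;
hippocampal learning rate 0.4 vs. cortical 0.1 and task-time semantic
0.005 — none of these rates are published for the original
implementation; the normative constraint is the CLS fast-hippocampus /
slow-cortex ordering. CA3→CA1 is purely error-driven (a Hebbian
component would slowly bind sustained predictions to whatever code is
active); CA3 recurrents are Hebbian-dominant (0.9) because the phase
contrast barely reaches them. During retrieval practice the Hebbian
rate on the perforant-path encodings is scaled by 0.3: practice should
strengthen retrieval routes, not re-encode the impoverished cue
pattern (CPCA's decay of absent cue elements would otherwise erode
intact traces).

Two pretraining stages precede the task proper:

* **Codec pretraining** (4 epochs over the item vocabulary): the
  monosynaptic ECin↔CA1↔ECout loop is trained as a sparse
  auto-encoder. CA1's auto-encoder role is long-term knowledge, not
  episodic memory; because these projections are pool-aligned they
  cannot store any cross-pool (associative) content, so no episodic
  information leaks in. During the task they learn only slowly (0.05).
* **Semantic pretraining** (30 epochs per word): each word is
  presented alone and the ECin target contains the word plus its
  pairmate (related condition) or plus an unused random filler
  (unrelated), training Semantic→ECin by error-driven learning.

## The context gate and sleep

Semantic input to ECin is scaled by 1.0 when no temporal context is
present and by 0.01 when context is present (a top-down, task-based
bias). Consequently a studied word co-activates its pairmate inside
the hippocampal input only during context-free processing — i.e.,
during sleep replay. Sleep presents each association (scene + word +
letter, no context) for one base epoch, then replays the
retrieval-practiced associations for five additional epochs (the
prioritization assumption). The alternative regimes change only this
schedule: Sleep-PriWeak gives the extra epochs to the unpracticed
associations, Sleep-All gives uniform replay, Sleep-AddRP replaces the
sleep session with a copy of the retrieval-practice session (context
and all). Epoch counts are configuration values; the original report
does not print them.

## Scoring and statistics

At final test learning is disabled and only scene and letter are
presented — identically for wake and sleep cells. The tested word's
Output pool is scored with d′ = Z(hit) − Z(fa) (activity threshold
0.5; rates clipped to [1/2N, 1−1/2N]). Per run and cell we compute
mean nontarget d′ minus mean matched-control d′; planned comparisons
are paired t tests across runs with Cohen's d = mean/sd of the paired
differences; the omnibus test is a balanced split-plot ANOVA (sleep
between-run with 20 runs per group, temporal and semantic within-run),
computed by explicit sums-of-squares decomposition and verified in the
test suite against an independent contrast-based computation. With 20
runs per group the interaction degrees of freedom are (1, 38).

## Simulation scale

The default network is a proportionally reduced preset (DG 30×30,
CA3 24×24, CA1 pools 8×8, 12 cycles per settling quarter) that
preserves the architecture, the size ordering DG > CA3 > CA1 pool >
EC pool, and the sparsity structure, while letting the full 20-run ×
8-cell experiment plus variants run in minutes on one CPU core.
`TeachConfig.full_scale()` restores the full-size architecture (DG
70×70, CA3 50×50, CA1 pools 30×35, 25 cycles). Condition cells that share a
pipeline prefix (pretraining; everything up to the end of retrieval
practice) can branch from cached network states; this is an exact
optimisation, verified bit-identical in the tests.

## What the synthetic stimuli do and do not capture

Patterns are independent uniform random binary vectors: "semantic
relatedness" exists only as a learned mapping in the semantic layer,
not as feature overlap between word patterns; letters are unique per
word rather than shared within pairmates as in the behavioural
stimuli; lists have fixed length and no serial-position structure
beyond the two-list split. Passing tests therefore speak to the
mechanism — context-gated semantic spillover during prioritized replay
— and not to item-level properties of real verbal material.

## Output integration

The Output layer combines the hippocampal ECout (one-to-one, relative
scale 0.4) with the graded cortical routes (Cortex, Letter, Semantic).
The balance matters: with a dominant binary ECout drive the
k-winners competition at test is decided almost entirely by the
all-or-none hippocampal retrieval, whose per-item outcome is bimodal,
and the slowly accumulated cortical weight differences never express
at test. With the cortical route visible, the retrieval-practice
effects carried by the cortical delta rule (suppression of candidates
the hippocampus did not retrieve; strengthening of what replay
reinstates) appear as graded, run-stable differences.

## Known limitations

* The close-condition (single context) facilitation is the weak point
  of the reduced-scale simulation: all 24 associations share one
  temporal context, pairmate CA3 codes overlap almost fully at this
  CA3 size, and the co-retrieval advantage of close over far during
  retrieval practice — the mechanism behind the large close-condition
  benefits in the original report — is small. In our runs the
  close-cell nontarget-control differences hover around zero in wake
  and the behavioural facilitation there is not reliably reproduced.
  The far-condition pattern (wake impairment, sleep-dependent
  facilitation for related pairs) is the robust part of the model.
* Between-run variability is large relative to the mean effects
  (6 nontarget/6 matched-control items per run, near-binary per-item
  retrieval), so effect sizes are not comparable in magnitude to the
  original full-scale implementation.
* Effect magnitudes depend on learning rates and epoch counts that the
  original report does not publish; reported effect sizes should be
  compared qualitatively.
* SWS/REM alternation, feedback-based retrieval practice, restudy
  controls and spiking detail are out of scope.
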