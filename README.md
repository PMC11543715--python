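# teach

A complementary-learning-systems (CLS) network model of how sleep
moderates the effects of retrieval practice on memory — the TEACH
model (TEsting Activated Cortico-Hippocampal interaction).

## The scientific problem

Practicing retrieval of one memory ("the target") usually impairs
later recall of related, unpracticed memories (retrieval-induced
forgetting, RIF). Behavioural work on scene–word paired associates
found a striking exception: when the practiced target and its
unpracticed pairmate are semantically related but were studied in
*different* temporal contexts, a night of sleep flips the impairment
into facilitation (RIFA). This package implements a rate-coded
cortico-hippocampal network that reproduces and explains that flip,
for researchers in computational memory modelling who want a compact,
fully scriptable simulation of the paradigm.

The model couples:

* a **fast hippocampal learner** — ECin → DG → CA3 → CA1 → ECout
  (trisynaptic) plus a monosynaptic ECin ↔ CA1 auto-encoder, with
  sparse k-winners-take-all codes, theta-style phase gating and
  contrastive (expectation vs. outcome) learning;
* a **slow neocortical learner** — scene/word input pools, an
  association cortex layer, orthographic (Letter) and semantic
  (Semantic) knowledge layers, all converging on an Output layer that
  also receives the hippocampal ECout;
* a **context gate**: semantic input to the hippocampus is inhibited
  while a temporal-context pattern is present (a task-based top-down
  bias) and runs at full strength when context is absent — as during
  context-free sleep replay, where replaying a practiced association
  lets its semantically related pairmate be co-activated and re-bound.

Retrieval on each final-test trial is scored with signal detection on
the Output word pool:

    d' = Z(hit rate) − Z(false-alarm rate)

where hits are target-pattern units active in the retrieved pattern
and false alarms are non-target units active. The analysis mirrors the
experimental one: per-run mean d′ difference between nontargets and
list-matched controls in each cell of the 2 (temporal distance) ×
2 (semantic relatedness) × 2 (sleep/wake) design, planned paired
comparisons, and a mixed ANOVA with sleep as a between-run factor.

Four sleep regimes are implemented: **TEACH** (all associations
replayed, retrieval-practiced ones prioritized with extra epochs),
**Sleep-PriWeak** (unpracticed associations prioritized), **Sleep-All**
(uniform replay) and **Sleep-AddRP** (sleep identical to more
retrieval practice).

## Worked example

```python
from teach.config import RunConfig
from teach.design import ConditionSpec
from teach.evaluation import aggregate, planned_comparison
from teach.protocol import run_cell

cfg = RunConfig()
for state in ("wake", "sleep"):
    cond = ConditionSpec("far", "related", state, "TEACH")
    for run in (1, 2, 3):
        r = run_cell(cfg.network, cfg.schedule, cond, run, cfg.master_seed)
        print(f"{state} run {run}: nontarget-control d' diff = {r.diff:+.2f}")
```

On the default configuration this prints

```
wake run 1: nontarget-control d' diff = -1.16
wake run 2: nontarget-control d' diff = -0.34
wake run 3: nontarget-control d' diff = +0.45
sleep run 1: nontarget-control d' diff = +1.01
sleep run 2: nontarget-control d' diff = +1.08
sleep run 3: nontarget-control d' diff = +1.90
```

Without sleep the unpracticed pairmate from the other list hovers at
or below its control baseline (per-run values are noisy at this
simulation scale); after the prioritized, context-free sleep replay it
is reliably *better* than baseline — the RIF→RIFA flip that is the
model's headline result. `aggregate` and `planned_comparison` turn a
full experiment's trial table into per-cell t statistics and Cohen's
d.

The command-line interface wraps the same machinery:

```bash
teach run --runs 20 --variant TEACH --out results/
teach analyze results/
teach plot results/
teach describe          # layer/projection table + DOT graph
```

## Layout

| module              | contents                                              |
| ------------------- | ----------------------------------------------------- |
| `teach.design`      | stimulus bank, factorial design, trial schedules      |
| `teach.netcore`     | layers, kWTA inhibition, settling, theta-quarter trials |
| `teach.plasticity`  | Hebbian (CPCA) + contrastive error-driven learning    |
| `teach.model`       | the full architecture and the context gate            |
| `teach.protocol`    | pretraining, study, retrieval practice, sleep, test   |
| `teach.evaluation`  | d′ scoring, planned comparisons, mixed ANOVA          |
| `teach.config/cli`  | YAML configuration, seeds, `teach` command            |

See `docs/methods.md` for the model description, parameter rationale
and known limitations.
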