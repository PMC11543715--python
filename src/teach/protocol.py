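"""Experiment execution: pretraining, study, retrieval practice, sleep
variants and the final test, across condition cells and seeded runs.

Each run seed fixes the stimulus bank, the initial weights and the
trial orders; every condition cell of a run is re-initialised from the
same seeds, so cells differ only in the manipulation itself.  Wake
cells skip the sleep phase; everything else is shared code.  At final
test, learning is disabled and only the scene and first-letter cues are
presented (no temporal context), identically for wake and sleep cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import design
from .design import (
    Association,
    ConditionSpec,
    ItemBank,
    ScheduleParams,
    TrialSpec,
    POOLS,
)
from .evaluation import dprime
from .model import TeachConfig, build_teach_network, context_gate_mults, theta_mults
from .netcore import Network, QuarterSpec

__all__ = [
    "RunResult",
    "assemble_layer_clamp",
    "trial_quarters",
    "execute_trial",
    "pretrain_semantics",
    "run_initial_study",
    "run_retrieval_practice",
    "run_sleep",
    "run_final_test",
    "run_cell",
    "run_experiment",
    "all_cells",
]

#: Layers that participate in semantic pretraining (the rest stay silent).
SEMANTIC_LAYERS = {"Input", "Semantic", "ECin"}
SEMANTIC_PROJECTIONS = {"Semantic->ECin"}

#: The monosynaptic EC<->CA1 auto-encoder ("codec").  Its projections
#: are pool-aligned, so it can encode item content but can never store
#: cross-pool (associative) information.
CODEC_LAYERS = {"Input", "ECin", "CA1", "ECout"}
CODEC_PROJECTIONS = {"ECin->CA1", "CA1->ECout", "ECout->CA1"}

TrialProbe = Callable[[TrialSpec, dict], None]


@dataclass
class RunResult:
    """Final-test scores for one (run, condition) cell."""

    run: int
    condition: ConditionSpec
    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records)
        df["run"] = self.run
        df["temporal"] = self.condition.temporal
        df["semantic"] = self.condition.semantic
        df["sleep_state"] = self.condition.sleep_state
        df["variant"] = self.condition.sleep_variant
        return df

    def mean_dprime(self, role: str, matched_only: bool = True) -> float:
        vals = [
            r["dprime"]
            for r in self.records
            if r["role"] == role
            and (role != "control" or not matched_only or r["matched_control"])
        ]
        return float(np.mean(vals))

    @property
    def diff(self) -> float:
        return self.mean_dprime("nontarget") - self.mean_dprime("control")


def assemble_layer_clamp(
    clamps: dict, cfg: TeachConfig
) -> np.ndarray:
    """Build a full Input-layer vector from per-pool patterns."""
    size = cfg.ec_pool_size
    vec = np.zeros(cfg.n_pools * size)
    for pool_name, pattern in clamps.items():
        idx = POOLS.index(pool_name)
        vec[idx * size : (idx + 1) * size] = pattern.units
    return vec


def trial_quarters(
    trial: TrialSpec, cfg: TeachConfig
) -> list[QuarterSpec]:
    """Theta-style quarter sequence for one trial.

    Quarter 1 (encode): CA1 slaved to ECin.  Quarter 2 (retrieve): CA3
    drives CA1; its end state is the expectation (minus) snapshot.
    Quarter 3 (outcome/plus): retrieval gating is kept and the outcome
    is clamped — ECout (and Output) copy the settled ECin state when the
    trial provides a target, or the hippocampus's own ECout retrieval
    serves as the cortical target when it does not ("self").
    """
    gate = context_gate_mults(trial.context_present, cfg)
    n = cfg.cycles_per_quarter
    if trial.phase == "pretrain":
        # Only the Input/Semantic/ECin loop runs: a plain minus quarter
        # followed by a plus quarter with the ECin target clamped.
        return [
            QuarterSpec(n, scale_mults=gate, snapshot="minus"),
            QuarterSpec(
                n,
                clamps={
                    "ECin": assemble_layer_clamp(
                        dict(trial.ec_plus_clamp), cfg
                    )
                },
                scale_mults=gate,
                snapshot="plus",
            ),
        ]
    q1 = QuarterSpec(n, scale_mults={**theta_mults("encode", cfg), **gate})
    q2 = QuarterSpec(
        n,
        scale_mults={**theta_mults("retrieve", cfg), **gate},
        snapshot="minus",
    )
    if trial.phase == "test":
        return [q1, q2]
    if trial.hippocampal_target == "ecin":
        # Outcome quarter: ECin returns to full strength over CA1 (so
        # driven pools settle into their decodable encoding state) and
        # the binarised ECin pattern drives ECout.  Only pools that
        # carry content are clamped: an undriven pool is missing
        # evidence, not evidence of absence, and its CA3 drive is
        # unchanged from the expectation phase, so its prediction is
        # neither confirmed nor punished.
        outcome_mults = {**theta_mults("outcome", cfg), **gate}
        plus_clamps: dict = {}
        size = cfg.ec_pool_size

        def _ecin_pattern(net):
            return (net.acts("ECin") > 0.5).astype(float)

        def _ecout_target(net):
            pat = _ecin_pattern(net)
            pools = pat.reshape(cfg.n_pools, size)
            driven = pools.sum(axis=1) > 0
            mask = np.repeat(driven, size)
            return pat, mask

        plus_clamps["ECout"] = _ecout_target
        if trial.cortical_target_source == "ecout":
            # Online (study) trials clamp the full Output pattern: the
            # task context licenses treating absent content as wrong.
            # Offline replay only reinstates what is replayed, so the
            # cortical target too is restricted to driven pools.
            plus_clamps["Output"] = (
                _ecout_target if trial.phase == "sleep" else _ecin_pattern
            )
        q3 = QuarterSpec(
            n, clamps=plus_clamps, scale_mults=outcome_mults, snapshot="plus"
        )
        return [q1, q2, q3]

    plus_clamps: dict = {}
    if trial.ec_plus_clamp is not None:
        plus_clamps["ECin"] = assemble_layer_clamp(
            dict(trial.ec_plus_clamp), cfg
        )
    if trial.hippocampal_target == "self":
        # No feedback: the model commits to its own retrieval.  Units
        # retrieved above threshold are driven fully (self-training);
        # for the hippocampus sub-threshold units stay free, while the
        # cortical target is the full binarised pattern, so spurious
        # cortical candidates that the hippocampus did not retrieve are
        # suppressed.
        thr = cfg.retrieval_threshold

        def _self_hippo_target(net):
            retrieved = net.acts("ECout") > thr
            return retrieved.astype(float), retrieved

        plus_clamps["ECout"] = _self_hippo_target
        if trial.cortical_target_source == "ecout":
            plus_clamps["Output"] = lambda net: (
                net.acts("ECout") > thr
            ).astype(float)
    # With an external target the plus quarter is ECin-dominant (late
    # theta phase): CA1 settles into its encoding state so the
    # trisynaptic pathway learns to reproduce decodable CA1 codes,
    # while CA3 keeps predictions alive in pools the input leaves
    # silent.  Self-targeted trials stay in retrieval gating.
    plus_theta = "outcome" if trial.hippocampal_target == "ecin" else "retrieve"
    q3 = QuarterSpec(
        n,
        clamps=plus_clamps,
        scale_mults={**theta_mults(plus_theta, cfg), **gate},
        snapshot="plus",
    )
    return [q1, q2, q3]


def execute_trial(
    net: Network,
    trial: TrialSpec,
    cfg: TeachConfig,
    active_layers: Optional[set] = None,
    lr_override: Optional[dict] = None,
) -> dict:
    """Run one trial and apply learning as the trial prescribes."""
    base = {"Input": assemble_layer_clamp(dict(trial.clamps), cfg)}
    quarters = trial_quarters(trial, cfg)
    snaps = net.run_trial(base, quarters, active_layers=active_layers)
    if trial.learning == "all":
        if lr_override is None and trial.phase == "sleep":
            if cfg.sleep_lr_scale != 1.0:
                lr_override = {
                    p.name: p.spec.learn.lr * cfg.sleep_lr_scale
                    for p in net.projections.values()
                    if p.spec.learn is not None
                }
        elif lr_override is None and trial.phase == "rp":
            lr_override = {
                p.name: p.spec.learn.lr * cfg.rp_hebb_scale
                for p in net.projections.values()
                if p.spec.learn is not None and p.spec.learn.hebb_mix == 1.0
            }
            if cfg.rp_cortex_scale != 1.0:
                for p in net.projections.values():
                    if p.spec.learn is not None and (
                        "Output" in p.name or "Cortex" in p.name
                    ):
                        lr_override[p.name] = (
                            p.spec.learn.lr * cfg.rp_cortex_scale
                        )
        net.learn(snaps, lr_override=lr_override)
    elif trial.learning == "semantic":
        net.learn(
            snaps,
            only=SEMANTIC_PROJECTIONS,
            lr_override=lr_override
            or {"Semantic->ECin": cfg.lr_pretrain},
        )
    elif trial.learning != "none":
        raise ValueError(f"unknown learning mode {trial.learning!r}")
    return snaps


def _train_phase(
    net: Network,
    schedule: Sequence[TrialSpec],
    cfg: TeachConfig,
    active_layers: Optional[set] = None,
    probe: Optional[TrialProbe] = None,
) -> Network:
    for trial in schedule:
        snaps = execute_trial(net, trial, cfg, active_layers=active_layers)
        if probe is not None:
            probe(trial, snaps)
    return net


def pretrain_codec(
    net: Network, bank: ItemBank, cfg: TeachConfig
) -> Network:
    """Pre-establish the CA1 auto-encoder over the item vocabulary.

    CA1 functions as a sparse auto-encoder for EC content; that mapping
    is long-term knowledge rather than episodic memory, so it is
    trained before the task: every pool pattern in the bank is driven
    through ECin while ECout is clamped to the same (binarised) state,
    and only the pool-aligned monosynaptic projections learn.  Because
    those projections are pool-local, no scene-word binding can leak
    into them; associative content remains the trisynaptic pathway's
    job.
    """
    lr = {name: cfg.lr_mono_pretrain for name in CODEC_PROJECTIONS}
    for epoch in range(cfg.codec_epochs):
        ctx = bank.contexts[epoch % len(bank.contexts)]
        for word_id, word in enumerate(bank.words):
            slot = bank.word_slot(word_id)
            clamps = {
                "scene": bank.scenes[bank.scene_of(word_id)],
                ("word1" if slot == 0 else "word2"): word,
                "letter": bank.letters[word_id],
                "ctx1": ctx[0],
                "ctx2": ctx[1],
            }
            trial = TrialSpec(
                clamps=clamps,
                hippocampal_target="ecin",
                cortical_target_source=None,
                context_present=True,
                learning="none",  # handled manually below
                phase="codec",
            )
            base = {"Input": assemble_layer_clamp(clamps, cfg)}
            snaps = net.run_trial(
                base, trial_quarters(trial, cfg), active_layers=CODEC_LAYERS
            )
            net.learn(snaps, only=CODEC_PROJECTIONS, lr_override=lr)
    return net


def pretrain_semantics(
    net: Network, schedule: Sequence[TrialSpec], cfg: TeachConfig
) -> Network:
    """Teach the semantic pathway its word -> pairmate (or filler) map.

    Only the Semantic->ECin projection learns; dynamics are restricted
    to the Input/Semantic/ECin loop, which is all that is active.
    """
    return _train_phase(
        net, schedule, cfg, active_layers=SEMANTIC_LAYERS
    )


def run_initial_study(
    net: Network,
    schedule: Sequence[TrialSpec],
    cfg: TeachConfig,
    probe: Optional[TrialProbe] = None,
) -> Network:
    return _train_phase(net, schedule, cfg, probe=probe)


def run_retrieval_practice(
    net: Network,
    schedule: Sequence[TrialSpec],
    cfg: TeachConfig,
    probe: Optional[TrialProbe] = None,
) -> Network:
    return _train_phase(net, schedule, cfg, probe=probe)


def run_sleep(
    net: Network,
    schedule: Sequence[TrialSpec],
    cfg: TeachConfig,
    probe: Optional[TrialProbe] = None,
) -> Network:
    return _train_phase(net, schedule, cfg, probe=probe)


def run_final_test(
    net: Network,
    schedule: Sequence[TrialSpec],
    cfg: TeachConfig,
    run: int,
    cond: ConditionSpec,
    active_threshold: float = 0.5,
) -> RunResult:
    """Score every tested pairmate with learning disabled."""
    result = RunResult(run=run, condition=cond)
    size = cfg.ec_pool_size
    for trial in schedule:
        assert not trial.learning_enabled, "learning must be off at test"
        execute_trial(net, trial, cfg)
        a = trial.association
        pool = 1 + a.word_pool_slot  # word pools sit at indices 1, 2
        out = net.acts("Output")[pool * size : (pool + 1) * size]
        score = dprime(trial.score_target, out, active_threshold)
        result.records.append(
            {
                "association_id": a.word_id,
                "scene_id": a.scene_id,
                "role": a.role,
                "matched_control": a.matched_control,
                "hit_rate": score.hit_rate,
                "fa_rate": score.fa_rate,
                "dprime": score.dprime,
            }
        )
    return result


# ----------------------------------------------------------------------
# Run orchestration


def _child_rng(master_seed: int, run: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(run), int(stream)])
    )


def build_run_inputs(
    master_seed: int,
    run: int,
    cond: ConditionSpec,
    n_scenes: int,
    pool_size: int,
    pct_active: float,
) -> tuple[ItemBank, list[Association]]:
    """Stimulus bank and role assignment for one (run, cell).

    Streams 0 (bank) and 1 (roles) depend only on the run seed, so every
    cell of a run sees the identical bank and RP-scene split.
    """
    bank = design.build_item_bank(
        n_scenes, _child_rng(master_seed, run, 0), pool_size, pct_active
    )
    assoc = design.build_associations(
        bank, cond, _child_rng(master_seed, run, 1)
    )
    return bank, assoc


def run_cell(
    cfg: TeachConfig,
    sched: ScheduleParams,
    cond: ConditionSpec,
    run: int,
    master_seed: int,
    n_scenes: int = 12,
    pct_active: float = 0.2,
    active_threshold: float = 0.5,
    probes: Optional[dict] = None,
    cache: Optional[dict] = None,
) -> RunResult:
    """Execute the full pipeline for one condition cell of one run.

    ``probes`` optionally maps phase names (``"study"``, ``"rp"``,
    ``"sleep"``) to callables ``probe(trial, snapshots)`` for mechanism
    inspection.  ``cache`` (a per-run dict) lets condition cells that
    share a prefix of the pipeline — pretraining depends only on the
    relatedness condition, the post-retrieval-practice state also on
    the temporal condition — branch from a stored copy of the trained
    network instead of recomputing it; results are identical either
    way because the phase schedules are rebuilt deterministically from
    the run seed.
    """
    probes = probes or {}
    use_cache = cache is not None and not probes
    pool_size = cfg.ec_pool_size
    bank, assoc = build_run_inputs(
        master_seed, run, cond, n_scenes, pool_size, pct_active
    )
    order_rng = _child_rng(master_seed, run, 3)

    def schedule(phase):
        return design.build_schedule(phase, assoc, bank, cond, sched, order_rng)

    # Schedules must be built in pipeline order even when execution is
    # skipped: each build advances the shared order stream.
    pre_sched = schedule("pretrain")
    study_sched = schedule("study")
    rp_sched = schedule("rp")

    key_pre = ("pretrained", run, cond.semantic)
    key_rp = ("post_rp", run, cond.semantic, cond.temporal)
    if use_cache and key_rp in cache:
        net = cache[key_rp].copy()
    elif use_cache and key_pre in cache:
        net = cache[key_pre].copy()
        run_initial_study(net, study_sched, cfg)
        run_retrieval_practice(net, rp_sched, cfg)
        cache[key_rp] = net.copy()
    else:
        net = build_teach_network(cfg, _child_rng(master_seed, run, 2))
        pretrain_codec(net, bank, cfg)
        pretrain_semantics(net, pre_sched, cfg)
        if use_cache:
            cache[key_pre] = net.copy()
        run_initial_study(net, study_sched, cfg, probe=probes.get("study"))
        run_retrieval_practice(net, rp_sched, cfg, probe=probes.get("rp"))
        if use_cache:
            cache[key_rp] = net.copy()
    if cond.sleep_state == "sleep":
        run_sleep(net, schedule("sleep"), cfg, probe=probes.get("sleep"))
    return run_final_test(
        net, schedule("test"), cfg, run, cond,
        active_threshold=active_threshold,
    )


def all_cells(variant: str = "TEACH") -> list[ConditionSpec]:
    """The eight cells of the 2x2x2 design for one sleep variant."""
    return [
        ConditionSpec(t, s, w, variant)
        for t in ("close", "far")
        for s in ("related", "unrelated")
        for w in ("wake", "sleep")
    ]


def run_experiment(
    cfg: TeachConfig,
    sched: ScheduleParams,
    n_runs: int = 20,
    master_seed: int = 2024,
    cells: Optional[Iterable[ConditionSpec]] = None,
    n_scenes: int = 12,
    pct_active: float = 0.2,
    active_threshold: float = 0.5,
    progress: Optional[Callable[[str], None]] = None,
) -> pd.DataFrame:
    """Run every requested cell for runs 1..n_runs; tidy trial table."""
    cells = list(cells) if cells is not None else all_cells()
    frames = []
    for run in range(1, n_runs + 1):
        cache: dict = {}
        for cond in cells:
            if progress:
                progress(
                    f"run {run}/{n_runs} "
                    f"{cond.temporal}/{cond.semantic}/{cond.sleep_state}"
                    f"/{cond.sleep_variant}"
                )
            result = run_cell(
                cfg,
                sched,
                cond,
                run,
                master_seed,
                n_scenes=n_scenes,
                pct_active=pct_active,
                active_threshold=active_threshold,
                cache=cache,
            )
            frames.append(result.to_frame())
    return pd.concat(frames, ignore_index=True)
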