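"""Assembly of the full cortico-hippocampal architecture.

Cortical side: an Input layer of six 7x7 pools (scene, two word pools,
first letter, two temporal-context pools) feeds a mirrored ECin layer
one-to-one; Letter and Semantic layers encode orthographic and semantic
long-term knowledge and project into the word pools of both the Output
layer and ECin; a Cortex layer learns scene-word associations slowly
and drives the corresponding Output pools.  Hippocampal side: ECin
projects to DG (very sparse) and CA3; DG drives CA3 through strong
mossy-like synapses; CA3 recurrents support pattern completion; CA3 and
ECin both drive CA1, which auto-encodes EC content back onto ECout; the
monosynaptic loop ECin->CA1->ECout coexists with the trisynaptic loop
ECin->DG->CA3->CA1->ECout.  ECout projects one-to-one onto Output, so
hippocampal retrieval and cortical retrieval are combined there.

Semantic input to ECin is gated by temporal context: when a context
pattern is present the semantic pathway is strongly attenuated (a
task-based top-down bias); when context is absent (sleep, pretraining)
it runs at full strength, letting a studied word co-activate its
semantically related pairmate inside the hippocampal input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .netcore import LayerSpec, Network, ProjectionSpec, init_network
from .plasticity import LearnParams

__all__ = ["TeachConfig", "build_teach_network", "context_gate_mults",
           "theta_mults", "describe_network"]

# Pool indices within the six-pool Input/ECin/ECout/Output layout.
P_SCENE, P_WORD1, P_WORD2, P_LETTER, P_CTX1, P_CTX2 = range(6)
WORD_POOLS = (P_WORD1, P_WORD2)


@dataclass(frozen=True)
class TeachConfig:
    """Architecture and learning hyperparameters.

    The default layer sizes are the package's standard reduced-scale
    preset, preserving the size ordering and sparsity structure of the
    full architecture (``full_scale`` restores the full-size architecture:
    DG 70x70, CA3 50x50, CA1 pools 30x35, 25 cycles per quarter).
    Learning rates implement the complementary-learning-systems
    contrast: fast hippocampal learning, slow cortical learning.
    """

    ec_pool_shape: tuple[int, int] = (7, 7)
    n_pools: int = 6
    dg_shape: tuple[int, int] = (30, 30)
    ca3_shape: tuple[int, int] = (24, 24)
    ca1_pool_shape: tuple[int, int] = (8, 8)
    letter_shape: tuple[int, int] = (14, 14)
    semantic_shape: tuple[int, int] = (14, 14)
    cortex_shape: tuple[int, int] = (20, 20)

    # Per-pool target activity fractions.
    kwta: Mapping[str, float] = field(
        default_factory=lambda: {
            "Input": 0.2, "ECin": 0.2, "ECout": 0.2, "Output": 0.2,
            "DG": 0.02, "CA3": 0.04, "CA1": 0.1,
            "Letter": 0.1, "Semantic": 0.1, "Cortex": 0.15,
        }
    )

    # Context-dependent gating of Semantic->ECin.
    semantic_gate_on: float = 0.01   # context present: inhibited
    semantic_gate_off: float = 1.0   # context absent: full strength

    # Trial dynamics.
    cycles_per_quarter: int = 12
    dt: float = 0.4
    gain: float = 10.0
    act_floor: float = 0.15
    # Theta gating: CA1 driven by ECin in the first (encoding) quarter,
    # by CA3 in the retrieval quarter and the outcome quarter.
    theta_ecin_ca1_low: float = 0.1
    theta_ca3_ca1_low: float = 0.0
    # Mossy-fibre drive is a strong "detonator" during encoding but is
    # attenuated during retrieval, when completion should be driven by
    # the perforant path and CA3 recurrents rather than by the
    # pattern-separated DG response to a partial cue.
    theta_dg_retrieval: float = 0.2
    # Graded inhibition tails (net-input units) for attractor layers.
    ca3_soft_margin: float = 0.15
    ca1_soft_margin: float = 0.10
    # Units above this activity count as "retrieved" when the model
    # commits to its own retrieval (no external feedback): they are
    # driven to 1 in the outcome phase, sub-threshold units are not
    # treated as evidence of absence.
    retrieval_threshold: float = 0.4
    # Optional global learning-rate multiplier for replay trials
    # (sensitivity control; 1.0 = replay learns at online rates).
    sleep_lr_scale: float = 1.0
    # During retrieval practice the cue is partial; Hebbian encoding of
    # the cue pattern is scaled down so practice strengthens retrieval
    # routes rather than re-encoding an impoverished trace (the CPCA
    # decay of absent cue elements would otherwise erode intact
    # traces).
    rp_hebb_scale: float = 0.3
    # Cortical learning-rate multiplier during retrieval practice.
    rp_cortex_scale: float = 1.0

    # Learning rates (none are published; the fast-hippocampus /
    # slow-cortex ordering is the normative constraint).
    lr_hippo: float = 0.4
    # The monosynaptic EC<->CA1 auto-encoder is long-term knowledge: it
    # is pretrained on the item vocabulary and learns only slowly during
    # the task, so episodic binding lives in the trisynaptic pathway.
    lr_mono_pretrain: float = 0.3
    lr_mono_task: float = 0.05
    codec_epochs: int = 4
    lr_cortex: float = 0.1
    lr_task_semantic: float = 0.005
    lr_pretrain: float = 0.1
    hebb_mix: float = 0.05
    ca3_rec_hebb: float = 0.9
    # Hippocampal pathway weights start low so rapidly learned synapses
    # stand out sharply against the unlearned background.
    hippo_init: tuple[float, float] = (0.05, 0.30)

    # Connectivity densities.
    p_ecin_dg: float = 0.25
    p_ecin_ca3: float = 0.25
    p_dg_ca3: float = 0.05
    p_encoder: float = 0.25

    # Relative projection strengths.
    scales: Mapping[str, float] = field(
        default_factory=lambda: {
            "Input->ECin": 3.0,
            "Semantic->ECin": 1.0,
            "Letter->ECin": 0.5,
            "ECin->DG": 2.0,
            "ECin->CA3": 1.5,
            "DG->CA3": 3.0,
            "CA3->CA3": 0.8,
            "CA3->CA1": 1.0,
            "ECin->CA1": 2.0,
            "CA1->ECout": 3.0,
            "ECout->CA1": 0.8,
            "ECout->Output": 0.4,
            "Input->Cortex": 2.5,
            "Cortex->Output": 1.5,
            "Output->Cortex": 0.3,
            "Input->Letter": 2.0,
            "Input->Semantic": 2.0,
            "Letter->Output": 1.2,
            "Semantic->Output": 0.5,
        }
    )

    def __post_init__(self) -> None:
        # Equality is allowed for the gate-ablation control, in which
        # wake and sleep semantic influence are made identical.
        if not self.semantic_gate_off >= self.semantic_gate_on >= 0:
            raise ValueError("require gate_off >= gate_on >= 0")
        if self.cycles_per_quarter < 1:
            raise ValueError("cycles_per_quarter must be >= 1")

    @classmethod
    def full_scale(cls, **overrides) -> "TeachConfig":
        """Full-size layer dimensions (slower; same architecture)."""
        defaults = dict(
            dg_shape=(70, 70),
            ca3_shape=(50, 50),
            ca1_pool_shape=(30, 35),
            cycles_per_quarter=25,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def ec_pool_size(self) -> int:
        return self.ec_pool_shape[0] * self.ec_pool_shape[1]


def _layer_specs(cfg: TeachConfig) -> list[LayerSpec]:
    def spec(name, pool_shape, n_pools=1, **kw):
        return LayerSpec(
            name=name,
            pool_shape=pool_shape,
            n_pools=n_pools,
            kwta_pct=cfg.kwta[name],
            gain=cfg.gain,
            act_floor=cfg.act_floor,
            **kw,
        )

    ec = cfg.ec_pool_shape
    return [
        spec("Input", ec, cfg.n_pools),
        spec("ECin", ec, cfg.n_pools),
        spec("ECout", ec, cfg.n_pools),
        spec("Output", ec, cfg.n_pools),
        spec("DG", cfg.dg_shape),
        spec("CA3", cfg.ca3_shape, soft_margin=cfg.ca3_soft_margin),
        spec("CA1", cfg.ca1_pool_shape, cfg.n_pools,
             soft_margin=cfg.ca1_soft_margin),
        spec("Letter", cfg.letter_shape),
        spec("Semantic", cfg.semantic_shape),
        spec("Cortex", cfg.cortex_shape),
    ]


def _projection_specs(cfg: TeachConfig) -> list[ProjectionSpec]:
    s = cfg.scales
    hip = LearnParams(lr=cfg.lr_hippo, hebb_mix=cfg.hebb_mix)
    hip_hebb = LearnParams(lr=cfg.lr_hippo, hebb_mix=1.0)
    ca3_rec = LearnParams(lr=cfg.lr_hippo, hebb_mix=cfg.ca3_rec_hebb)
    mono = LearnParams(lr=cfg.lr_mono_task, hebb_mix=cfg.hebb_mix)
    ctx = LearnParams(lr=cfg.lr_cortex, hebb_mix=cfg.hebb_mix)
    sem = LearnParams(lr=cfg.lr_task_semantic, hebb_mix=cfg.hebb_mix)

    def P(src, dst, **kw):
        kw.setdefault("wt_scale", s[f"{src}->{dst}"])
        return ProjectionSpec(src=src, dst=dst, **kw)

    return [
        # Fixed sensory plumbing.
        P("Input", "ECin", connectivity="one_to_one", init_weight=1.0),
        P("Input", "Letter", connectivity=("random_sparse", cfg.p_encoder),
          src_pools=(P_LETTER,)),
        P("Input", "Semantic", connectivity=("random_sparse", cfg.p_encoder),
          src_pools=WORD_POOLS),
        # Long-term-knowledge layers into hippocampal input and Output.
        P("Semantic", "ECin", dst_pools=WORD_POOLS, learn=sem),
        P("Letter", "ECin", dst_pools=WORD_POOLS, learn=hip_hebb),
        P("Semantic", "Output", dst_pools=WORD_POOLS, learn=sem),
        P("Letter", "Output", dst_pools=WORD_POOLS, learn=ctx),
        # Hippocampus: trisynaptic pathway.
        P("ECin", "DG", connectivity=("random_sparse", cfg.p_ecin_dg),
          learn=hip_hebb, init_range=cfg.hippo_init),
        P("ECin", "CA3", connectivity=("random_sparse", cfg.p_ecin_ca3),
          learn=hip_hebb, init_range=cfg.hippo_init),
        P("DG", "CA3", connectivity=("random_sparse", cfg.p_dg_ca3),
          learn=hip_hebb, init_range=cfg.hippo_init),
        P("CA3", "CA3", learn=ca3_rec, init_range=cfg.hippo_init),
        # Pure error-driven: Hebbian co-activity here would slowly bind
        # sustained predictions to whatever code is active.
        P("CA3", "CA1", learn=LearnParams(lr=cfg.lr_hippo, hebb_mix=0.0),
          init_range=cfg.hippo_init),
        # Monosynaptic pathway (EC <-> CA1 auto-encoder).
        P("ECin", "CA1", connectivity="pool_aligned", learn=mono),
        P("CA1", "ECout", connectivity="pool_aligned", learn=mono),
        P("ECout", "CA1", connectivity="pool_aligned", learn=mono),
        # Hippocampal output into cortex.
        P("ECout", "Output", connectivity="one_to_one", init_weight=1.0),
        # Slow cortical association pathway.
        P("Input", "Cortex", src_pools=(P_SCENE, *WORD_POOLS), learn=ctx),
        P("Cortex", "Output", dst_pools=(P_SCENE, *WORD_POOLS), learn=ctx),
        P("Output", "Cortex", src_pools=(P_SCENE, *WORD_POOLS), learn=ctx),
    ]


def build_teach_network(cfg: TeachConfig, rng: np.random.Generator) -> Network:
    """Instantiate the architecture with fresh random weights."""
    return init_network(
        _layer_specs(cfg),
        _projection_specs(cfg),
        rng,
        dt=cfg.dt,
    )


def context_gate_mults(context_present: bool, cfg: TeachConfig) -> dict:
    """Scale multiplier for the context-gated semantic pathway."""
    gate = cfg.semantic_gate_on if context_present else cfg.semantic_gate_off
    return {"Semantic->ECin": gate}


def theta_mults(quarter: str, cfg: TeachConfig) -> dict:
    """Pathway gating for one theta quarter.

    ``"encode"``: CA1 slaved to ECin (monosynaptic drive), CA3 input
    suppressed.  ``"retrieve"``: CA3 drives CA1, direct ECin drive
    attenuated.  The outcome (plus) quarter keeps retrieval gating.
    """
    if quarter == "encode":
        return {"CA3->CA1": cfg.theta_ca3_ca1_low}
    if quarter == "retrieve":
        return {
            "ECin->CA1": cfg.theta_ecin_ca1_low,
            "DG->CA3": cfg.theta_dg_retrieval,
        }
    if quarter == "outcome":
        # ECin->CA1 returns to full strength so driven pools settle
        # into their decodable encoding state; CA3 keeps a sub-dominant
        # drive that sustains predictions in undriven pools.  The
        # expectation snapshot is taken under this same gating, so the
        # phase difference reflects only the outcome clamp.
        return {"DG->CA3": cfg.theta_dg_retrieval}
    raise ValueError(f"unknown theta quarter {quarter!r}")


def describe_network(cfg: TeachConfig) -> str:
    """Human-readable summary of the instantiated graph (plus DOT)."""
    lines = ["layers:"]
    for ls in _layer_specs(cfg):
        lines.append(
            f"  {ls.name:<9} {ls.n_pools} pool(s) of "
            f"{ls.pool_shape[0]}x{ls.pool_shape[1]} "
            f"(k={ls.k}/{ls.pool_size})"
        )
    lines.append("projections:")
    for ps in _projection_specs(cfg):
        kind = "fixed" if ps.learn is None else (
            "hebb" if ps.learn.hebb_mix == 1.0 else "err+hebb"
        )
        lines.append(
            f"  {ps.name:<18} {str(ps.connectivity):<22} "
            f"scale={ps.wt_scale:<4} {kind}"
        )
    lines.append("")
    lines.append("digraph teach {")
    for ps in _projection_specs(cfg):
        style = "dotted" if ps.learn is None else (
            "dashed" if ps.learn.hebb_mix == 1.0 else "solid"
        )
        lines.append(f'  "{ps.src}" -> "{ps.dst}" [style={style}];')
    lines.append("}")
    return "\n".join(lines)
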