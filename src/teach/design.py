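"""Synthetic stimulus bank and factorial experimental design.

The simulated paradigm pairs each of 12 scene cues with two words
("pairmates"), yielding 24 scene-word associations.  Stimuli are random
binary activation patterns over 7x7 pools (20% of units active).  The
design crosses retrieval practice (target / nontarget / control) with
temporal distance (close: both pairmates studied under one temporal
context; far: the two pairmates studied in different lists under
different contexts), semantic relatedness (whether the semantic layer is
pretrained on the pairmate mapping), and sleep (whether an offline
replay phase follows retrieval practice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PoolPattern",
    "ItemBank",
    "Association",
    "ConditionSpec",
    "TrialSpec",
    "POOLS",
    "SLEEP_VARIANTS",
    "generate_pool_pattern",
    "build_item_bank",
    "build_associations",
    "build_schedule",
]

#: Canonical pool layout of the Input / ECin / ECout / Output layers.
POOLS = ("scene", "word1", "word2", "letter", "ctx1", "ctx2")

SLEEP_VARIANTS = ("TEACH", "PriWeak", "All", "AddRP")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PoolPattern:
    """Binary activation pattern for a single pool."""

    units: np.ndarray  # int8 vector of 0/1

    def __post_init__(self) -> None:
        u = np.asarray(self.units, dtype=np.int8)
        if u.ndim != 1:
            raise ValueError("pattern must be a 1-D vector")
        if not np.isin(u, (0, 1)).all():
            raise ValueError("pattern entries must be 0 or 1")
        object.__setattr__(self, "units", u)

    @property
    def size(self) -> int:
        return int(self.units.size)

    @property
    def n_active(self) -> int:
        return int(self.units.sum())

    @property
    def active_idx(self) -> np.ndarray:
        return np.flatnonzero(self.units)

    def overlap(self, other: "PoolPattern") -> float:
        """Fraction of this pattern's active units shared with `other`."""
        if self.n_active == 0:
            return 0.0
        return float((self.units & other.units).sum() / self.n_active)


def generate_pool_pattern(
    size: int, pct_active: float, rng: np.random.Generator
) -> PoolPattern:
    """Draw a random binary pattern with round(pct_active*size) active units.

    Rounding is half-up, so the default 20% of a 49-unit pool gives
    exactly 10 active units.  Active positions are uniform without
    replacement.
    """
    if size <= 0:
        raise ValueError(f"pool size must be positive, got {size}")
    if not 0.0 <= pct_active <= 1.0:
        raise ValueError(f"pct_active must be in [0, 1], got {pct_active}")
    n_active = _round_half_up(pct_active * size)
    units = np.zeros(size, dtype=np.int8)
    if n_active:
        units[rng.choice(size, size=n_active, replace=False)] = 1
    return PoolPattern(units)


@dataclass(frozen=True)
class ItemBank:
    """Complete stimulus set for one run.

    Scene ``i`` owns words ``2i`` (word pool 1) and ``2i+1`` (word
    pool 2); word ``j`` has letter pattern ``j``.  ``contexts[c]`` is a
    pair of patterns spanning the two temporal-context pools.
    ``fillers[j]`` is the unused random word paired with word ``j``
    during unrelated pretraining.
    """

    scenes: tuple[PoolPattern, ...]
    words: tuple[PoolPattern, ...]
    letters: tuple[PoolPattern, ...]
    contexts: tuple[tuple[PoolPattern, PoolPattern], ...]
    fillers: tuple[PoolPattern, ...]

    @property
    def n_scenes(self) -> int:
        return len(self.scenes)

    def pairmate(self, word_id: int) -> int:
        """Pairmate of a word: the other word sharing its scene."""
        return word_id + 1 if word_id % 2 == 0 else word_id - 1

    def word_slot(self, word_id: int) -> int:
        """0 if the word lives in word pool 1, 1 if in word pool 2."""
        return word_id % 2

    def scene_of(self, word_id: int) -> int:
        return word_id // 2


def build_item_bank(
    n_scenes: int,
    rng: np.random.Generator,
    pool_size: int = 49,
    pct_active: float = 0.2,
) -> ItemBank:
    """Generate scenes, words, letters, contexts and pretraining fillers."""
    if n_scenes < 1:
        raise ValueError("need at least one scene")

    def draw() -> PoolPattern:
        return generate_pool_pattern(pool_size, pct_active, rng)

    scenes = tuple(draw() for _ in range(n_scenes))
    words = tuple(draw() for _ in range(2 * n_scenes))
    letters = tuple(draw() for _ in range(2 * n_scenes))
    contexts = tuple((draw(), draw()) for _ in range(2))
    fillers = tuple(draw() for _ in range(2 * n_scenes))
    return ItemBank(scenes, words, letters, contexts, fillers)


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the 2x2x2 design (plus the sleep-variant label)."""

    temporal: str  # "close" | "far"
    semantic: str  # "related" | "unrelated"
    sleep_state: str  # "wake" | "sleep"
    sleep_variant: str = "TEACH"

    def __post_init__(self) -> None:
        if self.temporal not in ("close", "far"):
            raise ValueError(f"unknown temporal condition {self.temporal!r}")
        if self.semantic not in ("related", "unrelated"):
            raise ValueError(f"unknown semantic condition {self.semantic!r}")
        if self.sleep_state not in ("wake", "sleep"):
            raise ValueError(f"unknown sleep state {self.sleep_state!r}")
        if self.sleep_variant not in SLEEP_VARIANTS:
            raise ValueError(f"unknown sleep variant {self.sleep_variant!r}")


@dataclass(frozen=True)
class Association:
    """One scene-word association with its design bookkeeping."""

    scene_id: int
    word_id: int
    word_pool_slot: int  # 0 -> word pool 1, 1 -> word pool 2
    context_id: int  # 0 -> context A, 1 -> context B
    list_index: int
    role: str  # "target" | "nontarget" | "control"
    is_rp_target: bool
    matched_control: bool = False  # list-position-matched control pairmate


def build_associations(
    bank: ItemBank, cond: ConditionSpec, rng: np.random.Generator
) -> list[Association]:
    """Assign roles, contexts and list positions for one condition cell.

    Half the scenes are retrieval-practiced (one pairmate becomes the
    target, the other the nontarget); the remaining scenes are controls.
    In the far condition pairmate slot 1 is studied in list 0 under
    context A and slot 2 in list 1 under context B, so every nontarget
    precedes its target.  In the close condition everything shares
    context A and a single list, with pairmates adjacent.  The control
    pairmate whose list position matches the nontargets' is flagged
    ``matched_control`` (both pairmates in the close condition).
    """
    n = bank.n_scenes
    if n % 2:
        raise ValueError("scene count must be even to split RP vs control")
    rp_scenes = set(rng.choice(n, size=n // 2, replace=False).tolist())

    far = cond.temporal == "far"
    out: list[Association] = []
    for scene in range(n):
        for slot in (0, 1):
            word = 2 * scene + slot
            if far:
                context, list_index = slot, slot
            else:
                context, list_index = 0, 0
            if scene in rp_scenes:
                # Far: the nontarget is always studied in the earlier
                # list, so the later-list pairmate is the target.
                role = "target" if slot == 1 else "nontarget"
            else:
                role = "control"
            matched = role == "control" and (not far or list_index == 0)
            out.append(
                Association(
                    scene_id=scene,
                    word_id=word,
                    word_pool_slot=slot,
                    context_id=context,
                    list_index=list_index,
                    role=role,
                    is_rp_target=(role == "target"),
                    matched_control=matched,
                )
            )
    return out


@dataclass(frozen=True)
class TrialSpec:
    """Everything the network needs to run one trial.

    ``clamps`` maps pool names (subset of :data:`POOLS`) to patterns;
    absent pools stay silent.  ``hippocampal_target`` selects the
    plus-phase ECout drive: ``"ecin"`` copies the settled ECin state
    (study/sleep encoding), ``"self"`` leaves ECout to its own retrieval
    (retrieval practice: no feedback), ``None`` means no plus phase
    distinction matters (test).  ``ec_plus_clamp`` optionally clamps the
    ECin layer itself in the plus phase (semantic pretraining target).
    """

    clamps: Mapping[str, PoolPattern]
    hippocampal_target: Optional[str] = "ecin"
    cortical_target_source: Optional[str] = "ecout"  # "ecout" | None
    ec_plus_clamp: Optional[Mapping[str, PoolPattern]] = None
    context_present: bool = True
    learning: str = "all"  # "all" | "semantic" | "none"
    phase: str = "study"
    association: Optional[Association] = None
    score_target: Optional[PoolPattern] = None

    @property
    def learning_enabled(self) -> bool:
        return self.learning != "none"


@dataclass(frozen=True)
class ScheduleParams:
    """Epoch counts for each training phase."""

    pretrain_epochs: int = 30
    study_epochs: int = 4
    rp_epochs: int = 3
    sleep_base_epochs: int = 1
    sleep_extra_epochs: int = 5


def _context_clamps(bank: ItemBank, context_id: int) -> dict[str, PoolPattern]:
    c1, c2 = bank.contexts[context_id]
    return {"ctx1": c1, "ctx2": c2}


def _study_trial(bank: ItemBank, a: Association) -> TrialSpec:
    clamps = {
        "scene": bank.scenes[a.scene_id],
        ("word1" if a.word_pool_slot == 0 else "word2"): bank.words[a.word_id],
        "letter": bank.letters[a.word_id],
        **_context_clamps(bank, a.context_id),
    }
    return TrialSpec(
        clamps=clamps,
        hippocampal_target="ecin",
        cortical_target_source="ecout",
        context_present=True,
        learning="all",
        phase="study",
        association=a,
    )


def _rp_trial(bank: ItemBank, a: Association) -> TrialSpec:
    # Cue only: scene + first letter + temporal context.  The correct
    # word is never shown; the hippocampus trains on its own retrieval.
    clamps = {
        "scene": bank.scenes[a.scene_id],
        "letter": bank.letters[a.word_id],
        **_context_clamps(bank, a.context_id),
    }
    return TrialSpec(
        clamps=clamps,
        hippocampal_target="self",
        cortical_target_source="ecout",
        context_present=True,
        learning="all",
        phase="rp",
        association=a,
    )


def _sleep_trial(bank: ItemBank, a: Association) -> TrialSpec:
    # Context pools silent; semantic input to ECin runs ungated.
    clamps = {
        "scene": bank.scenes[a.scene_id],
        ("word1" if a.word_pool_slot == 0 else "word2"): bank.words[a.word_id],
        "letter": bank.letters[a.word_id],
    }
    return TrialSpec(
        clamps=clamps,
        hippocampal_target="ecin",
        cortical_target_source="ecout",
        context_present=False,
        learning="all",
        phase="sleep",
        association=a,
    )


def _test_trial(bank: ItemBank, a: Association) -> TrialSpec:
    clamps = {
        "scene": bank.scenes[a.scene_id],
        "letter": bank.letters[a.word_id],
    }
    return TrialSpec(
        clamps=clamps,
        hippocampal_target=None,
        cortical_target_source=None,
        context_present=False,
        learning="none",
        phase="test",
        association=a,
        score_target=bank.words[a.word_id],
    )


def _shuffled(items: Sequence, rng: np.random.Generator) -> list:
    order = rng.permutation(len(items))
    return [items[i] for i in order]


def _study_order(
    associations: Sequence[Association],
    cond: ConditionSpec,
    rng: np.random.Generator,
) -> list[Association]:
    if cond.temporal == "close":
        # Shuffle scenes but keep pairmates adjacent.
        by_scene: dict[int, list[Association]] = {}
        for a in associations:
            by_scene.setdefault(a.scene_id, []).append(a)
        out: list[Association] = []
        for scene in _shuffled(sorted(by_scene), rng):
            out.extend(sorted(by_scene[scene], key=lambda a: a.word_pool_slot))
        return out
    lists: dict[int, list[Association]] = {}
    for a in associations:
        lists.setdefault(a.list_index, []).append(a)
    out = []
    for li in sorted(lists):
        out.extend(_shuffled(lists[li], rng))
    return out


def build_schedule(
    phase: str,
    associations: Sequence[Association],
    bank: ItemBank,
    cond: ConditionSpec,
    params: ScheduleParams,
    rng: np.random.Generator,
) -> list[TrialSpec]:
    """Build the ordered trial list for one experimental phase.

    ``pretrain``: 30 epochs per word; the plus-phase ECin target is the
    word plus its pairmate (related) or plus an unused random filler
    (unrelated), driving error-driven learning of the semantic mapping.
    ``study``: one full input clamp per association per epoch, with
    temporal context.  ``rp``: targets only, cue = scene+letter+context,
    no correct answer supplied.  ``sleep``: context-free replay of whole
    associations; the variant decides which associations get the extra
    epochs.  ``test``: scene+letter cue only, learning disabled.
    """
    if phase == "pretrain":
        related = cond.semantic == "related"
        trials = []
        for _ in range(params.pretrain_epochs):
            for word_id in _shuffled(range(len(bank.words)), rng):
                slot = bank.word_slot(word_id)
                if related:
                    other_id = bank.pairmate(word_id)
                    other = bank.words[other_id]
                else:
                    other = bank.fillers[word_id]
                ec_target = {
                    ("word1" if slot == 0 else "word2"): bank.words[word_id],
                    ("word2" if slot == 0 else "word1"): other,
                }
                trials.append(
                    TrialSpec(
                        clamps={
                            ("word1" if slot == 0 else "word2"): bank.words[
                                word_id
                            ]
                        },
                        hippocampal_target=None,
                        cortical_target_source=None,
                        ec_plus_clamp=ec_target,
                        context_present=False,
                        learning="semantic",
                        phase="pretrain",
                    )
                )
        return trials

    if phase == "study":
        trials = []
        for _ in range(params.study_epochs):
            for a in _study_order(associations, cond, rng):
                trials.append(_study_trial(bank, a))
        return trials

    if phase == "rp":
        targets = [a for a in associations if a.is_rp_target]
        trials = []
        for _ in range(params.rp_epochs):
            for a in _shuffled(targets, rng):
                trials.append(_rp_trial(bank, a))
        return trials

    if phase == "sleep":
        variant = cond.sleep_variant
        if variant not in SLEEP_VARIANTS:
            raise ValueError(f"unknown sleep variant {variant!r}")
        if variant == "AddRP":
            # Sleep indistinguishable from more retrieval practice.
            return build_schedule("rp", associations, bank, cond, params, rng)
        trials = []
        for _ in range(params.sleep_base_epochs):
            for a in _shuffled(associations, rng):
                trials.append(_sleep_trial(bank, a))
        if variant == "TEACH":
            extra = [a for a in associations if a.is_rp_target]
        elif variant == "PriWeak":
            extra = [a for a in associations if not a.is_rp_target]
        else:  # All: uniform replay, no prioritization
            extra = []
        for _ in range(params.sleep_extra_epochs):
            for a in _shuffled(extra, rng):
                trials.append(_sleep_trial(bank, a))
        return trials

    if phase == "test":
        return [_test_trial(bank, a) for a in associations]

    raise ValueError(f"unknown phase {phase!r}")
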