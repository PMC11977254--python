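"""Stimulus registry, block and session construction for the affective bias task (ABT).

The ABT presents morphed photographs of human faces whose expression runs
from maximally sad through neutral to maximally happy.  Here stimuli are
pure metadata records: an exemplar is identified by the posing identity and
its morph level, never by pixels.  The canonical stimulus coordinate is the
*signed intensity*, an integer in [-100, 100] that is negative for sad
morphs, zero for neutral, and positive for happy morphs; the (valence,
percent-intensity) pair is kept alongside for reporting.

The default registry matches the task as administered: six identities
(three female, three male) crossed with nine morph levels (100/50/30/10%
sad, neutral, 10/30/50/100% happy) = 54 exemplars.  A block shows every
exemplar of one emotional valence plus every neutral exemplar exactly once,
in seeded random order (30 trials for the default registry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusFace",
    "Block",
    "Session",
    "DEFAULT_SIGNED_LEVELS",
    "build_registry",
    "build_block",
    "build_session",
    "session_frame",
    "registry_frame",
]

#: Nine default morph levels on the signed-intensity axis.
DEFAULT_SIGNED_LEVELS = (-100, -50, -30, -10, 0, 10, 30, 50, 100)

VALENCES = ("sad", "neutral", "happy")


def _valence_of(signed_intensity: int) -> str:
    if signed_intensity < 0:
        return "sad"
    if signed_intensity > 0:
        return "happy"
    return "neutral"


@dataclass(frozen=True, order=True)
class StimulusFace:
    """One morphed-face exemplar (metadata only, no image handling)."""

    identity: str
    signed_intensity: int
    sex: str = field(compare=False, default="")

    @property
    def valence(self) -> str:
        return _valence_of(self.signed_intensity)

    @property
    def intensity(self) -> int:
        """Unsigned morph intensity in percent (0 iff neutral)."""
        return abs(self.signed_intensity)


@dataclass
class Block:
    """One ABT block: every eligible exemplar once, in randomized order."""

    block_valence: str  # 'positive' or 'negative'
    trials: list[StimulusFace]
    block_index: int = 0
    stim_on: bool = True


@dataclass
class Session:
    """One visit's worth of ABT blocks for a single subject."""

    subject_id: str
    cohort: str  # 'E' or 'B'
    week_since_implant: float
    blocks: list[Block]
    session_date: object = None  # pandas Timestamp or None


def build_registry(
    n_identities: int = 6,
    signed_levels: tuple[int, ...] = DEFAULT_SIGNED_LEVELS,
) -> list[StimulusFace]:
    """Build the exemplar registry: every identity at every morph level.

    Identities are labelled F1, M1, F2, M2, ... alternating female/male so
    that an even count splits evenly by sex.  Ordering is deterministic by
    (identity, signed_intensity).

    Raises
    ------
    ValueError
        If ``n_identities < 1``, the level list is empty or contains
        duplicates, or the neutral level 0 is not present exactly once.
    """
    if n_identities < 1:
        raise ValueError("n_identities must be >= 1")
    levels = tuple(int(s) for s in signed_levels)
    if len(levels) == 0:
        raise ValueError("signed_levels must be nonempty")
    if len(set(levels)) != len(levels):
        raise ValueError(f"duplicate signed intensity levels: {sorted(levels)}")
    if levels.count(0) != 1:
        raise ValueError("signed_levels must include the neutral level 0 exactly once")
    if any(not -100 <= s <= 100 for s in levels):
        raise ValueError("signed intensities must lie in [-100, 100]")

    identities = []
    for i in range(n_identities):
        sex = "female" if i % 2 == 0 else "male"
        label = f"{'F' if sex == 'female' else 'M'}{i // 2 + 1}"
        identities.append((label, sex))

    registry = [
        StimulusFace(identity=label, signed_intensity=s, sex=sex)
        for (label, sex) in sorted(identities)
        for s in sorted(levels)
    ]
    return registry


def _eligible_for(registry: list[StimulusFace], block_valence: str) -> list[StimulusFace]:
    want = {"positive": "happy", "negative": "sad"}
    if block_valence not in want:
        raise ValueError(f"block_valence must be 'positive' or 'negative', got {block_valence!r}")
    keep = {want[block_valence], "neutral"}
    return [f for f in registry if f.valence in keep]


def build_block(
    registry: list[StimulusFace],
    block_valence: str,
    rng: np.random.Generator | int,
    block_index: int = 0,
    stim_on: bool = True,
) -> Block:
    """One presentation of each eligible exemplar, in seeded random order.

    Eligible exemplars are the neutral faces plus the faces matching the
    block's valence (happy for positive blocks, sad for negative).  Every
    identity must contribute the full set of required levels.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eligible = _eligible_for(registry, block_valence)
    if not eligible:
        raise ValueError("registry has no eligible exemplars for this block valence")

    # Each identity must carry the identical level set (one neutral plus the
    # same-valence intensities); a missing exemplar is a structural error.
    by_id: dict[str, set[int]] = {}
    for f in eligible:
        by_id.setdefault(f.identity, set()).add(f.signed_intensity)
    level_sets = set(frozenset(v) for v in by_id.values())
    all_ids = {f.identity for f in registry}
    if len(level_sets) != 1 or set(by_id) != all_ids:
        raise ValueError(
            "registry is missing required exemplars for a "
            f"{block_valence} block (identities x levels incomplete)"
        )

    order = rng.permutation(len(eligible))
    trials = [eligible[i] for i in order]
    return Block(block_valence=block_valence, trials=trials,
                 block_index=block_index, stim_on=stim_on)


def build_session(
    subject_id: str,
    cohort_style: str,
    week: float,
    rng: np.random.Generator | int,
    registry: list[StimulusFace] | None = None,
    stim_plan: str = "standard",
    counterbalance: int = 0,
    session_date=None,
) -> Session:
    """Assemble one visit's blocks with the site-appropriate structure.

    monthly-visit ('E') style ('E') visits collect the task twice — two block pairs, the
    first administration under active stimulation and the second after a
    transient discontinuation — with the negative block first in each
    administration.  biweekly-visit ('B') style ('B') visits collect three block pairs,
    all under active stimulation, with positive/negative order
    counterbalanced across subjects (``counterbalance`` parity).

    ``stim_plan`` overrides: 'standard' applies the per-style pattern above;
    'all_off' forces stimulation off (used for the first outpatient visit
    before stimulation onset).  Pre-implant visits (``week < 0``) are always
    stimulation-off.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if registry is None:
        registry = build_registry()
    if stim_plan not in ("standard", "all_off"):
        raise ValueError(f"unknown stim_plan {stim_plan!r}")

    if cohort_style == "E":
        n_admin, order = 2, ("negative", "positive")
        # stimulation pattern (on, on, off, off) across the four blocks
        stim_by_admin = (True, False)
    elif cohort_style == "B":
        n_admin = 3
        order = ("negative", "positive") if counterbalance % 2 == 0 else ("positive", "negative")
        stim_by_admin = (True, True, True)
    else:
        raise ValueError(f"cohort_style must be 'E' or 'B', got {cohort_style!r}")

    force_off = stim_plan == "all_off" or week < 0
    blocks: list[Block] = []
    for admin in range(n_admin):
        stim = False if force_off else stim_by_admin[admin]
        for val in order:
            blocks.append(
                build_block(registry, val, rng, block_index=len(blocks), stim_on=stim)
            )
    return Session(subject_id=subject_id, cohort=cohort_style,
                   week_since_implant=float(week), blocks=blocks,
                   session_date=session_date)


def session_frame(session: Session) -> pd.DataFrame:
    """Flatten a session to one row per trial (the serializable schedule)."""
    rows = []
    for block in session.blocks:
        for t_idx, face in enumerate(block.trials):
            rows.append(
                {
                    "subject_id": session.subject_id,
                    "cohort": session.cohort,
                    "session_date": session.session_date,
                    "week": session.week_since_implant,
                    "block_index": block.block_index,
                    "block_valence": block.block_valence,
                    "trial_index": t_idx,
                    "identity": face.identity,
                    "valence": face.valence,
                    "intensity": face.intensity,
                    "signed_intensity": face.signed_intensity,
                    "stim_on": block.stim_on,
                }
            )
    return pd.DataFrame(rows)


def registry_frame(registry: list[StimulusFace]) -> pd.DataFrame:
    """Registry as a table keyed by (identity, valence, intensity)."""
    return pd.DataFrame(
        {
            "identity": [f.identity for f in registry],
            "sex": [f.sex for f in registry],
            "valence": [f.valence for f in registry],
            "intensity": [f.intensity for f in registry],
            "signed_intensity": [f.signed_intensity for f in registry],
        }
    )
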