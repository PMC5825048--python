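"""From fitted mixture models to block, trajectory and subject scores.

The score of a block is the posterior probability that it belongs to the
unquiet (UB) component of the condition's mixture; the score of a trajectory
is the mean of its block scores; the global score of a subject is the mean of
the eyes-open and eyes-closed trajectory scores.  UB occupancy (the fraction
of blocks with posterior strictly above 0.5) is additionally reported for the
eyes-closed condition, where it separates fallers from non-fallers most
clearly.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Optional, Sequence

import numpy as np

from .cop_data import Condition, Label
from .exceptions import InsufficientDataError, StateError
from .gmm_em import GMMModel, e_step

logger = logging.getLogger(__name__)

DEFAULT_UB_THRESHOLD = 0.5


def block_scores(model: GMMModel, Z: np.ndarray) -> np.ndarray:
    """UB-posterior of every row of ``Z`` (normalized descriptors)."""
    if model.ub_index is None:
        raise StateError("model has no UB designation; run label_ub_cluster first")
    return e_step(model, Z).p[:, model.ub_index]


def block_score(model: GMMModel, z: np.ndarray) -> float:
    """UB-posterior of a single normalized descriptor."""
    return float(block_scores(model, np.atleast_2d(z))[0])


def trajectory_score(scores: Sequence[float]) -> float:
    """Arithmetic mean of the block scores of one trajectory."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise InsufficientDataError("trajectory has no block scores")
    return float(scores.mean())


def global_score(eo: Optional[float], ec: Optional[float]) -> float:
    """Mean of the available condition scores.

    With both conditions present this is (eo + ec) / 2; with one condition it
    is that condition's score (a warning is logged, since the protocol expects
    both).
    """
    if eo is None and ec is None:
        raise StateError("subject has no condition scores")
    if eo is None or ec is None:
        logger.warning("global score computed from a single condition")
        return float(eo if ec is None else ec)
    return float((eo + ec) / 2.0)


def ub_fraction(
    scores: Sequence[float], threshold: float = DEFAULT_UB_THRESHOLD
) -> float:
    """Fraction of blocks whose score is strictly above ``threshold``."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise InsufficientDataError("no block scores")
    return float(np.mean(scores > threshold))


@dataclasses.dataclass
class SubjectScore:
    """All scores derived for one subject."""

    subject_id: str
    label: Label
    eo_score: Optional[float]
    ec_score: Optional[float]
    global_score: float
    ub_fraction_ec: Optional[float]
    block_scores_by_condition: Dict[Condition, np.ndarray] = dataclasses.field(
        default_factory=dict
    )


def score_subject(
    subject_id: str,
    label: Label,
    per_condition_scores: Dict[Condition, np.ndarray],
    ub_threshold: float = DEFAULT_UB_THRESHOLD,
) -> SubjectScore:
    """Assemble a :class:`SubjectScore` from per-condition block scores."""
    traj_scores = {
        cond: trajectory_score(s) for cond, s in per_condition_scores.items()
    }
    eo = traj_scores.get(Condition.EO)
    ec = traj_scores.get(Condition.EC)
    ec_blocks = per_condition_scores.get(Condition.EC)
    return SubjectScore(
        subject_id=subject_id,
        label=Label(label),
        eo_score=eo,
        ec_score=ec,
        global_score=global_score(eo, ec),
        ub_fraction_ec=(
            None if ec_blocks is None else ub_fraction(ec_blocks, ub_threshold)
        ),
        block_scores_by_condition=dict(per_condition_scores),
    )


def scores_to_frame(subject_scores: Sequence[SubjectScore]):
    """Per-subject score table in the canonical column order."""
    import pandas as pd

    rows = []
    for s in subject_scores:
        rows.append(
            {
                "subject_id": s.subject_id,
                "label": s.label.value,
                "eo_score": s.eo_score,
                "ec_score": s.ec_score,
                "global_score": s.global_score,
                "ub_fraction_ec": s.ub_fraction_ec,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "label",
            "eo_score",
            "ec_score",
            "global_score",
            "ub_fraction_ec",
        ],
    )
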