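"""Per-participant prosodic-phrasing score on a 0-20 scale.

The expected phrasing is ONE_AP when the noun's discourse status is given
(noun and adjective grouped in one accentual phrase) and TWO_AP when it is
contrastive (noun parsed as its own phrase).  A participant's score is the
overall proportion of tokens whose produced phrasing matches the expected
one, pooled across both conditions and scaled to 0-20 so it is directly
comparable with the hinting task's theory-of-mind score.

Example: 3 matches out of 9 given tokens plus 6 matches out of 9
contrastive tokens is 9/18, i.e. a score of 10/20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotations import Dataset
from .boundary import Phrasing, PhrasingResult
from .errors import JoinError, UndefinedStatisticError

#: Expected phrasing per discourse condition.
EXPECTED = {"given": Phrasing.ONE_AP, "contrastive": Phrasing.TWO_AP}


@dataclass(frozen=True)
class ParticipantScore:
    participant_id: str
    group: str
    n_given: int
    n_given_one_ap: int
    n_contrastive: int
    n_contrastive_two_ap: int
    phrasing_score: float
    hinting_score: Optional[int] = None


def phrasing_score(
    participant_id: str,
    group: str,
    labels: Sequence[tuple[str, Phrasing]],
    hinting_score: Optional[int] = None,
) -> ParticipantScore:
    """Score one participant from (condition, label) pairs.

    Raises :class:`UndefinedStatisticError` for zero analyzable tokens — an
    absent score is not a score of 0.
    """
    if not labels:
        raise UndefinedStatisticError(
            f"participant {participant_id!r} has no analyzable tokens; "
            "the phrasing score is undefined"
        )
    n_given = n_given_match = n_contr = n_contr_match = 0
    for condition, label in labels:
        label = Phrasing(label)
        if condition not in EXPECTED:
            raise UndefinedStatisticError(
                f"unknown condition {condition!r} for participant {participant_id!r}"
            )
        if condition == "given":
            n_given += 1
            n_given_match += label == Phrasing.ONE_AP
        else:
            n_contr += 1
            n_contr_match += label == Phrasing.TWO_AP
    total = n_given + n_contr
    score = 20.0 * (n_given_match + n_contr_match) / total
    return ParticipantScore(
        participant_id=participant_id,
        group=group,
        n_given=n_given,
        n_given_one_ap=n_given_match,
        n_contrastive=n_contr,
        n_contrastive_two_ap=n_contr_match,
        phrasing_score=score,
        hinting_score=hinting_score,
    )


def score_table(
    dataset: Dataset, results: Iterable[PhrasingResult]
) -> list[ParticipantScore]:
    """One score per participant with analyzable tokens, joined with the
    hinting score from participant metadata.

    Participants whose tokens were all filtered out simply do not appear.
    A scored token whose participant lacks metadata raises JoinError.
    """
    tokens_by_id = {tok.token_id: tok for tok in dataset.tokens}
    meta_by_id = {m.participant_id: m for m in dataset.participants}
    per_participant: dict[str, list[tuple[str, Phrasing]]] = {}
    order: list[str] = []
    for res in results:
        tok = tokens_by_id.get(res.token_id)
        if tok is None:
            raise JoinError(
                f"result for token {res.token_id!r} has no matching dataset token"
            )
        if tok.participant_id not in per_participant:
            per_participant[tok.participant_id] = []
            order.append(tok.participant_id)
        per_participant[tok.participant_id].append((tok.condition, res.label))

    scores = []
    for pid in order:
        meta = meta_by_id.get(pid)
        if meta is None:
            raise JoinError(f"participant {pid!r} has tokens but no metadata record")
        scores.append(
            phrasing_score(pid, meta.group, per_participant[pid], meta.hinting_score)
        )
    return scores


def scores_frame(scores: Iterable[ParticipantScore]) -> pd.DataFrame:
    columns = [
        "participant_id",
        "group",
        "n_given",
        "n_given_one_ap",
        "n_contrastive",
        "n_contrastive_two_ap",
        "phrasing_score",
        "hinting_score",
    ]
    return pd.DataFrame(
        [{c: getattr(s, c) for c in columns} for s in scores], columns=columns
    )
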