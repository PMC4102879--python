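"""Canonical data model for token-level prosodic annotations.

One row per elicited noun token: the durations of the noun's first (S1) and
last (S2) full syllables, the f0 of the early L minimum and of the H maximum
associated with S2, the discourse condition the token was produced in, and
validity flags.  Participant metadata (group, theory-of-mind hinting score,
optional dialogue-level measures) lives in a separate table keyed by
participant id.

The canonical interchange format is a flat CSV; Praat TextGrid/PitchTier
files are an import path only (see :mod:`prosocontrast.praat`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import JoinError, SchemaError, ValidationError

GROUPS = ("HC", "SZ")
CONDITIONS = ("given", "contrastive")

#: Canonical token CSV columns, in order.
TOKEN_COLUMNS = [
    "token_id",
    "participant_id",
    "group",
    "item_id",
    "condition",
    "dur_s1",
    "dur_s2",
    "f0_l",
    "f0_h",
    "disfluent",
    "labeling_error",
]

#: Canonical participant-metadata CSV columns, in order.
PARTICIPANT_COLUMNS = [
    "participant_id",
    "group",
    "hinting_score",
    "total_time",
    "speaking_turns",
]


@dataclass(frozen=True)
class TokenAnnotation:
    """Acoustic measurements and metadata for one noun token.

    Durations are in seconds, f0 values in Hz; all four must be strictly
    positive and finite.
    """

    token_id: str
    participant_id: str
    group: str
    item_id: str
    condition: str
    dur_s1: float
    dur_s2: float
    f0_l: float
    f0_h: float
    disfluent: bool = False
    labeling_error: bool = False

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"token {self.token_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"token {self.token_id!r}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        for name in ("dur_s1", "dur_s2", "f0_l", "f0_h"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)) or value <= 0:
                raise ValidationError(
                    f"token {self.token_id!r}: {name} must be strictly "
                    f"positive and finite, got {value!r}"
                )


@dataclass(frozen=True)
class ParticipantMeta:
    """Per-participant metadata: group, hinting-task theory-of-mind score
    (0-20), and optional dialogue-level measures."""

    participant_id: str
    group: str
    hinting_score: Optional[int] = None
    total_time: Optional[float] = None
    speaking_turns: Optional[int] = None

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"participant {self.participant_id!r}: group must be one of "
                f"{GROUPS}, got {self.group!r}"
            )
        if self.hinting_score is not None and not 0 <= self.hinting_score <= 20:
            raise ValidationError(
                f"participant {self.participant_id!r}: hinting_score must lie "
                f"in [0, 20], got {self.hinting_score}"
            )
        if self.total_time is not None and self.total_time < 0:
            raise ValidationError(
                f"participant {self.participant_id!r}: total_time must be >= 0"
            )
        if self.speaking_turns is not None and self.speaking_turns < 0:
            raise ValidationError(
                f"participant {self.participant_id!r}: speaking_turns must be >= 0"
            )


@dataclass
class Dataset:
    """An ordered collection of token annotations plus participant metadata.

    Invariants: (participant_id, item_id) pairs are unique across tokens and
    every token's participant resolves to exactly one metadata record.
    """

    tokens: list[TokenAnnotation] = field(default_factory=list)
    participants: list[ParticipantMeta] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for tok in self.tokens:
            tok.validate()
            key = (tok.participant_id, tok.item_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate (participant_id, item_id) pair {key} "
                    f"at token {tok.token_id!r}"
                )
            seen.add(key)
        by_id: dict[str, ParticipantMeta] = {}
        for meta in self.participants:
            meta.validate()
            if meta.participant_id in by_id:
                raise ValidationError(
                    f"duplicate participant metadata for {meta.participant_id!r}"
                )
            by_id[meta.participant_id] = meta
        for tok in self.tokens:
            if tok.participant_id not in by_id:
                raise JoinError(
                    f"token {tok.token_id!r} references participant "
                    f"{tok.participant_id!r} with no metadata record"
                )

    def participant(self, participant_id: str) -> ParticipantMeta:
        for meta in self.participants:
            if meta.participant_id == participant_id:
                return meta
        raise JoinError(f"no metadata for participant {participant_id!r}")

    def tokens_frame(self) -> pd.DataFrame:
        """Token annotations as a DataFrame in canonical column order."""
        return pd.DataFrame(
            [
                {col: getattr(tok, col) for col in TOKEN_COLUMNS}
                for tok in self.tokens
            ],
            columns=TOKEN_COLUMNS,
        )

    def participants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {col: getattr(meta, col) for col in PARTICIPANT_COLUMNS}
                for meta in self.participants
            ],
            columns=PARTICIPANT_COLUMNS,
        )


def _parse_bool(value, *, token_id: str, column: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", "", "nan"):
        return False
    raise ValidationError(
        f"token {token_id!r}: cannot interpret {column}={value!r} as boolean"
    )


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(round(float(value)))


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def tokens_from_frame(frame: pd.DataFrame) -> list[TokenAnnotation]:
    """Build validated token annotations from a DataFrame with the canonical
    columns; extra columns are ignored by the caller's contract."""
    missing = [c for c in TOKEN_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            "token table is missing required column(s): " + ", ".join(missing)
        )
    tokens = []
    for row in frame.itertuples(index=False):
        token_id = str(row.token_id)
        tok = TokenAnnotation(
            token_id=token_id,
            participant_id=str(row.participant_id),
            group=str(row.group),
            item_id=str(row.item_id),
            condition=str(row.condition),
            dur_s1=float(row.dur_s1),
            dur_s2=float(row.dur_s2),
            f0_l=float(row.f0_l),
            f0_h=float(row.f0_h),
            disfluent=_parse_bool(row.disfluent, token_id=token_id, column="disfluent"),
            labeling_error=_parse_bool(
                row.labeling_error, token_id=token_id, column="labeling_error"
            ),
        )
        tok.validate()
        tokens.append(tok)
    return tokens


def participants_from_frame(frame: pd.DataFrame) -> list[ParticipantMeta]:
    required = ["participant_id", "group", "hinting_score"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            "participant table is missing required column(s): " + ", ".join(missing)
        )
    metas = []
    for _, row in frame.iterrows():
        meta = ParticipantMeta(
            participant_id=str(row["participant_id"]),
            group=str(row["group"]),
            hinting_score=_opt_int(row["hinting_score"]),
            total_time=_opt_float(row.get("total_time")),
            speaking_turns=_opt_int(row.get("speaking_turns")),
        )
        meta.validate()
        metas.append(meta)
    return metas


def read_tokens_csv(path, participants_path=None) -> Dataset:
    """Read the canonical token CSV (and optionally a participant metadata
    CSV) into a validated :class:`Dataset`.

    Tokens preserve file order.  Unknown columns are noted in provenance.
    If no participant table is given, minimal metadata records are derived
    from the tokens' own participant/group columns.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    tokens = tokens_from_frame(frame)
    provenance = [f"tokens read from {path}"]
    extra = [c for c in frame.columns if c not in TOKEN_COLUMNS]
    if extra:
        provenance.append("unknown token columns preserved: " + ", ".join(extra))

    if participants_path is not None:
        participants_path = Path(participants_path)
        participants = participants_from_frame(
            pd.read_csv(participants_path, float_precision="round_trip")
        )
        provenance.append(f"participants read from {participants_path}")
    else:
        participants = derive_participants(tokens)
        provenance.append("participants derived from token table (no metadata file)")

    dataset = Dataset(tokens=tokens, participants=participants, provenance=provenance)
    dataset.validate()
    return dataset


def derive_participants(tokens: Iterable[TokenAnnotation]) -> list[ParticipantMeta]:
    """Minimal participant records (id + group) from a token stream."""
    seen: dict[str, str] = {}
    for tok in tokens:
        if tok.participant_id not in seen:
            seen[tok.participant_id] = tok.group
        elif seen[tok.participant_id] != tok.group:
            raise ValidationError(
                f"participant {tok.participant_id!r} appears in two groups"
            )
    return [ParticipantMeta(pid, grp) for pid, grp in seen.items()]


def write_tokens_csv(dataset: Dataset, path) -> Path:
    """Write the canonical token CSV; re-reading yields an equal Dataset."""
    path = Path(path)
    dataset.validate()
    frame = dataset.tokens_frame()
    frame["disfluent"] = frame["disfluent"].map({True: "true", False: "false"})
    frame["labeling_error"] = frame["labeling_error"].map({True: "true", False: "false"})
    frame.to_csv(path, index=False)
    return path


def write_participants_csv(dataset: Dataset, path) -> Path:
    path = Path(path)
    frame = dataset.participants_frame()
    frame.to_csv(path, index=False)
    return path


def read_participants_csv(path) -> list[ParticipantMeta]:
    return participants_from_frame(pd.read_csv(path, float_precision="round_trip"))


def with_participants(dataset: Dataset, participants: list[ParticipantMeta]) -> Dataset:
    """A copy of *dataset* with participant metadata replaced."""
    out = Dataset(
        tokens=list(dataset.tokens),
        participants=list(participants),
        provenance=list(dataset.provenance) + ["participant metadata replaced"],
    )
    out.validate()
    return out
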