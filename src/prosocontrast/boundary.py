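"""Accentual-phrase (AP) boundary classification from acoustic annotations.

In French the right edge of an AP is cued by a rising pitch accent and
lengthening on the phrase-final full syllable.  A noun is classified as
phrased in its own AP (separate from the following adjective, ``TWO_AP``)
when both hold on its last syllable S2:

* pitch criterion — the H maximum is at least 10% above the preceding
  early L minimum (f0_h >= 1.10 * f0_l);
* lengthening criterion — S2 is at least 10% longer than the noun's first
  syllable S1 (dur_s2 >= 1.10 * dur_s1).

Both thresholds are inclusive (a ratio of exactly 1.10 meets the
criterion) and configurable for sensitivity analyses.  The conjunction of
the two criteria is required for a TWO_AP label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .annotations import Dataset, TokenAnnotation
from .errors import ValidationError

#: Default relative excess for both criteria: "at least 10% higher/longer".
DEFAULT_PITCH_THRESHOLD = 0.10
DEFAULT_LENGTH_THRESHOLD = 0.10


class Phrasing(str, Enum):
    ONE_AP = "ONE_AP"
    TWO_AP = "TWO_AP"


@dataclass(frozen=True)
class PhrasingResult:
    """The 1AP/2AP decision for one token plus per-criterion diagnostics."""

    token_id: str
    pitch_criterion_met: bool
    lengthening_criterion_met: bool
    f0_ratio: float
    dur_ratio: float
    label: Phrasing


@dataclass(frozen=True)
class FilterReport:
    """Accounting of the disfluency/labeling-error filter."""

    n_input: int
    n_retained: int
    n_removed_disfluent: int
    n_removed_error: int

    @property
    def retained_pct(self) -> float:
        if self.n_input == 0:
            return 100.0
        return 100.0 * self.n_retained / self.n_input


def _require_positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value)) or value <= 0:
        raise ValidationError(f"{name} must be strictly positive and finite, got {value!r}")


def pitch_accent_present(
    f0_h: float, f0_l: float, threshold: float = DEFAULT_PITCH_THRESHOLD
) -> bool:
    """True iff the S2-region maximum exceeds the early L by >= *threshold*."""
    _require_positive("f0_h", f0_h)
    _require_positive("f0_l", f0_l)
    # inclusive threshold; the relative slack keeps exact 10% ties "met"
    # despite float rounding of (1 + threshold) * f0_l
    return f0_h >= (1.0 + threshold) * f0_l * (1.0 - 1e-12)


def lengthening_present(
    dur_s2: float, dur_s1: float, threshold: float = DEFAULT_LENGTH_THRESHOLD
) -> bool:
    """True iff S2 is at least *threshold* longer than S1."""
    _require_positive("dur_s2", dur_s2)
    _require_positive("dur_s1", dur_s1)
    return dur_s2 >= (1.0 + threshold) * dur_s1 * (1.0 - 1e-12)


def classify_phrasing(
    token: TokenAnnotation,
    pitch_threshold: float = DEFAULT_PITCH_THRESHOLD,
    length_threshold: float = DEFAULT_LENGTH_THRESHOLD,
) -> PhrasingResult:
    """Classify one token as ONE_AP or TWO_AP.

    TWO_AP iff both the pitch and the lengthening criterion hold.
    """
    try:
        pitch = pitch_accent_present(token.f0_h, token.f0_l, pitch_threshold)
        length = lengthening_present(token.dur_s2, token.dur_s1, length_threshold)
    except ValidationError as exc:
        raise ValidationError(f"token {token.token_id!r}: {exc}") from exc
    return PhrasingResult(
        token_id=token.token_id,
        pitch_criterion_met=pitch,
        lengthening_criterion_met=length,
        f0_ratio=token.f0_h / token.f0_l,
        dur_ratio=token.dur_s2 / token.dur_s1,
        label=Phrasing.TWO_AP if (pitch and length) else Phrasing.ONE_AP,
    )


def classify_dataset(
    dataset: Dataset,
    pitch_threshold: float = DEFAULT_PITCH_THRESHOLD,
    length_threshold: float = DEFAULT_LENGTH_THRESHOLD,
) -> list[PhrasingResult]:
    return [
        classify_phrasing(tok, pitch_threshold, length_threshold)
        for tok in dataset.tokens
    ]


def filter_tokens(dataset: Dataset) -> tuple[Dataset, FilterReport]:
    """Drop tokens flagged as disfluent or as labeling errors.

    A token carrying both flags counts once, under disfluency.  The report
    accounts for every input token: n_retained + removals == n_input.
    """
    retained: list[TokenAnnotation] = []
    n_disfluent = 0
    n_error = 0
    for tok in dataset.tokens:
        if tok.disfluent:
            n_disfluent += 1
        elif tok.labeling_error:
            n_error += 1
        else:
            retained.append(tok)
    report = FilterReport(
        n_input=len(dataset.tokens),
        n_retained=len(retained),
        n_removed_disfluent=n_disfluent,
        n_removed_error=n_error,
    )
    filtered = Dataset(
        tokens=retained,
        participants=list(dataset.participants),
        provenance=list(dataset.provenance)
        + [
            f"filtered disfluent/error tokens: kept {report.n_retained}/"
            f"{report.n_input} ({report.retained_pct:.2f}%)"
        ],
    )
    return filtered, report


def results_frame(dataset: Dataset, results: Iterable[PhrasingResult]):
    """Join token fields with their phrasing results into a DataFrame."""
    import pandas as pd

    by_id = {tok.token_id: tok for tok in dataset.tokens}
    rows = []
    for res in results:
        tok = by_id[res.token_id]
        rows.append(
            {
                "token_id": tok.token_id,
                "participant_id": tok.participant_id,
                "group": tok.group,
                "item_id": tok.item_id,
                "condition": tok.condition,
                "dur_s1": tok.dur_s1,
                "dur_s2": tok.dur_s2,
                "f0_l": tok.f0_l,
                "f0_h": tok.f0_h,
                "pitch_criterion_met": res.pitch_criterion_met,
                "lengthening_criterion_met": res.lengthening_criterion_met,
                "f0_ratio": res.f0_ratio,
                "dur_ratio": res.dur_ratio,
                "label": res.label.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "token_id",
            "participant_id",
            "group",
            "item_id",
            "condition",
            "dur_s1",
            "dur_s2",
            "f0_l",
            "f0_h",
            "pitch_criterion_met",
            "lengthening_criterion_met",
            "f0_ratio",
            "dur_ratio",
            "label",
        ],
    )
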