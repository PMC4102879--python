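import textwrap

import pytest

from prosocontrast.annotations import Dataset, ParticipantMeta, TokenAnnotation

# acoustic templates that the threshold classifier maps deterministically
ONE_AP_ACOUSTICS = dict(dur_s1=0.20, dur_s2=0.20, f0_l=180.0, f0_h=185.0)
TWO_AP_ACOUSTICS = dict(dur_s1=0.20, dur_s2=0.26, f0_l=180.0, f0_h=220.0)


def make_token(
    token_id,
    participant_id="P01",
    group="HC",
    item_id=None,
    condition="given",
    disfluent=False,
    labeling_error=False,
    **acoustics,
):
    fields = dict(ONE_AP_ACOUSTICS)
    fields.update(acoustics)
    return TokenAnnotation(
        token_id=token_id,
        participant_id=participant_id,
        group=group,
        item_id=item_id or f"item_{token_id}",
        condition=condition,
        disfluent=disfluent,
        labeling_error=labeling_error,
        **fields,
    )


def participant_tokens(participant_id, group, n_given, n_given_one_ap,
                       n_contrastive, n_contrastive_two_ap):
    """Tokens whose classifier labels reproduce the requested per-condition
    counts for one participant."""
    tokens = []
    idx = 0
    for i in range(n_given):
        idx += 1
        acoustics = ONE_AP_ACOUSTICS if i < n_given_one_ap else TWO_AP_ACOUSTICS
        tokens.append(
            make_token(
                f"{participant_id}_t{idx:02d}",
                participant_id=participant_id,
                group=group,
                item_id=f"item{idx:02d}",
                condition="given",
                **acoustics,
            )
        )
    for i in range(n_contrastive):
        idx += 1
        acoustics = TWO_AP_ACOUSTICS if i < n_contrastive_two_ap else ONE_AP_ACOUSTICS
        tokens.append(
            make_token(
                f"{participant_id}_t{idx:02d}",
                participant_id=participant_id,
                group=group,
                item_id=f"item{idx:02d}",
                condition="contrastive",
                **acoustics,
            )
        )
    return tokens


@pytest.fixture
def p29_dataset():
    """One SZ participant with the worked-example counts: 9 given tokens of
    which 3 phrased as one AP, 9 contrastive tokens of which 6 as two APs."""
    tokens = participant_tokens("P29", "SZ", 9, 3, 9, 6)
    return Dataset(
        tokens=tokens,
        participants=[ParticipantMeta("P29", "SZ", hinting_score=12)],
    )


LONG_TEXTGRID = textwrap.dedent('''\
    File type = "ooTextFile"
    Object class = "TextGrid"

    xmin = 0
    xmax = 2
    tiers? <exists>
    size = 2
    item []:
        item [1]:
            class = "IntervalTier"
            name = "syllables"
            xmin = 0
            xmax = 2
            intervals: size = 5
            intervals [1]:
                xmin = 0
                xmax = 0.30
                text = ""
            intervals [2]:
                xmin = 0.30
                xmax = 0.50
                text = "S1"
            intervals [3]:
                xmin = 0.50
                xmax = 0.76
                text = "S2"
            intervals [4]:
                xmin = 0.76
                xmax = 1.20
                text = "S1"
            intervals [5]:
                xmin = 1.20
                xmax = 1.41
                text = "S2"
        item [2]:
            class = "TextTier"
            name = "tones"
            xmin = 0
            xmax = 2
            points: size = 4
            points [1]:
                number = 0.40
                mark = "L"
            points [2]:
                number = 0.70
                mark = "H"
            points [3]:
                number = 1.00
                mark = "L"
            points [4]:
                number = 1.35
                mark = "H"
''')

SHORT_TEXTGRID = textwrap.dedent('''\
    File type = "ooTextFile"
    Object class = "TextGrid"

    0
    2
    <exists>
    2
    "IntervalTier"
    "syllables"
    0
    2
    5
    0
    0.30
    ""
    0.30
    0.50
    "S1"
    0.50
    0.76
    "S2"
    0.76
    1.20
    "S1"
    1.20
    1.41
    "S2"
    "TextTier"
    "tones"
    0
    2
    4
    0.40
    "L"
    0.70
    "H"
    1.00
    "L"
    1.35
    "H"
''')

PITCHTIER = textwrap.dedent('''\
    File type = "ooTextFile"
    Object class = "PitchTier"

    xmin = 0
    xmax = 2
    points: size = 3
    points [1]:
        number = 0
        value = 180
    points [2]:
        number = 1
        value = 200
    points [3]:
        number = 2
        value = 240
''')


@pytest.fixture
def praat_fixture(tmp_path):
    """Long-format TextGrid + PitchTier with two S1/S2 pairs and matching
    L/H points; hand-checked durations 0.20/0.26 and 0.44/0.21 s."""
    tg = tmp_path / "rec.TextGrid"
    pt = tmp_path / "rec.PitchTier"
    tg.write_text(LONG_TEXTGRID)
    pt.write_text(PITCHTIER)
    return tg, pt
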