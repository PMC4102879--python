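"""Data model, CSV round trips, and Praat TextGrid/PitchTier import."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prosocontrast.annotations import (
    Dataset,
    ParticipantMeta,
    TokenAnnotation,
    read_tokens_csv,
    write_participants_csv,
    write_tokens_csv,
)
from prosocontrast.errors import (
    AssociationError,
    SchemaError,
    StructureError,
    ValidationError,
)
from prosocontrast.praat import import_textgrid_tokens, read_pitchtier

from conftest import PITCHTIER, SHORT_TEXTGRID, make_token


class TestValidation:
    def test_positive_acoustics_required(self):
        with pytest.raises(ValidationError, match="dur_s2"):
            make_token("t1", dur_s2=0.0).validate()
        with pytest.raises(ValidationError, match="f0_l"):
            make_token("t1", f0_l=-5.0).validate()
        with pytest.raises(ValidationError, match="f0_h"):
            make_token("t1", f0_h=math.nan).validate()

    def test_enums_restricted(self):
        with pytest.raises(ValidationError, match="group"):
            make_token("t1", group="XX").validate()
        with pytest.raises(ValidationError, match="condition"):
            make_token("t1", condition="focus").validate()

    def test_duplicate_participant_item_pair_rejected(self):
        tokens = [
            make_token("t1", item_id="item01"),
            make_token("t2", item_id="item01"),
        ]
        ds = Dataset(tokens=tokens, participants=[ParticipantMeta("P01", "HC")])
        with pytest.raises(ValidationError, match="duplicate"):
            ds.validate()

    def test_hinting_score_bounds(self):
        with pytest.raises(ValidationError, match="hinting"):
            ParticipantMeta("P01", "HC", hinting_score=21).validate()

    @given(st.lists(st.booleans(), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=40)
    def test_rejects_exactly_the_invalid_rows(self, valid_flags):
        """Validation rejects each row with a non-positive field and only
        those rows."""
        for i, ok in enumerate(valid_flags):
            tok = make_token(f"t{i}", dur_s1=0.2 if ok else 0.0)
            if ok:
                tok.validate()
            else:
                with pytest.raises(ValidationError):
                    tok.validate()


class TestCsvRoundTrip:
    def _dataset(self, n=4):
        tokens = [
            make_token(
                f"t{i}",
                participant_id=f"P{i % 2}",
                group="HC" if i % 2 == 0 else "SZ",
                item_id=f"item{i:02d}",
                condition="given" if i % 2 == 0 else "contrastive",
                dur_s1=0.1 + 0.01 * i,
                dur_s2=0.2 + 0.01 * i,
                f0_l=100.0 + i,
                f0_h=150.0 + i,
                disfluent=(i == 3),
            )
            for i in range(n)
        ]
        participants = [
            ParticipantMeta("P0", "HC", hinting_score=18, total_time=170.0,
                            speaking_turns=30),
            ParticipantMeta("P1", "SZ", hinting_score=12),
        ]
        return Dataset(tokens=tokens, participants=participants)

    def test_wellformed_file(self, tmp_path):
        path = write_tokens_csv(self._dataset(), tmp_path / "tokens.csv")
        ppath = write_participants_csv(self._dataset(), tmp_path / "parts.csv")
        ds = read_tokens_csv(path, ppath)
        assert len(ds.tokens) == 4
        assert len(ds.participants) == 2

    def test_missing_column_names_the_column(self, tmp_path):
        path = write_tokens_csv(self._dataset(), tmp_path / "tokens.csv")
        import pandas as pd

        frame = pd.read_csv(path).drop(columns=["dur_s2"])
        frame.to_csv(tmp_path / "broken.csv", index=False)
        with pytest.raises(SchemaError, match="dur_s2"):
            read_tokens_csv(tmp_path / "broken.csv")

    def test_empty_dataset_writes_header_only(self, tmp_path):
        path = write_tokens_csv(Dataset(), tmp_path / "empty.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("token_id,")

    def test_single_token_two_lines(self, tmp_path):
        ds = Dataset(tokens=[make_token("t0")],
                     participants=[ParticipantMeta("P01", "HC")])
        path = write_tokens_csv(ds, tmp_path / "one.csv")
        assert len(path.read_text().strip().splitlines()) == 2

    def test_round_trip_identity(self, tmp_path):
        original = self._dataset()
        path = write_tokens_csv(original, tmp_path / "t.csv")
        ppath = write_participants_csv(original, tmp_path / "p.csv")
        again = read_tokens_csv(path, ppath)
        assert again.tokens == original.tokens
        assert again.participants == original.participants

    @given(
        rows=st.lists(
            st.tuples(
                st.floats(0.01, 2.0), st.floats(0.01, 2.0),
                st.floats(50.0, 500.0), st.floats(50.0, 500.0),
                st.booleans(), st.booleans(),
                st.sampled_from(["given", "contrastive"]),
            ),
            min_size=1,
            max_size=25,
        )
    )
    @settings(derandomize=True, max_examples=30)
    def test_round_trip_lossless_randomized(self, rows, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        tokens = [
            make_token(
                f"t{i}", item_id=f"item{i:03d}", condition=cond,
                dur_s1=d1, dur_s2=d2, f0_l=fl, f0_h=fh,
                disfluent=dis, labeling_error=err,
            )
            for i, (d1, d2, fl, fh, dis, err, cond) in enumerate(rows)
        ]
        ds = Dataset(tokens=tokens, participants=[ParticipantMeta("P01", "HC")])
        path = write_tokens_csv(ds, tmp / "t.csv")
        ppath = write_participants_csv(ds, tmp / "p.csv")
        assert read_tokens_csv(path, ppath).tokens == tokens


class TestPraatImport:
    def test_fixture_durations_and_interpolated_f0(self, praat_fixture):
        tg, pt = praat_fixture
        frags = import_textgrid_tokens(tg, pt)
        assert len(frags) == 2
        # durations read off the fixture's interval bounds by hand
        assert frags[0].dur_s1 == pytest.approx(0.20)
        assert frags[0].dur_s2 == pytest.approx(0.26)
        assert frags[1].dur_s1 == pytest.approx(0.44)
        assert frags[1].dur_s2 == pytest.approx(0.21)
        # PitchTier is 180 Hz at t=0, 200 at t=1, 240 at t=2 (linear)
        assert frags[0].f0_l == pytest.approx(188.0)  # t=0.40
        assert frags[0].f0_h == pytest.approx(194.0)  # t=0.70
        assert frags[1].f0_h == pytest.approx(214.0)  # t=1.35

    def test_point_at_sample_time_returns_sample_value(self, praat_fixture):
        _, pt = praat_fixture
        tier = read_pitchtier(pt)
        assert tier.interpolate(1.0) == pytest.approx(200.0)

    def test_short_format_parses_identically(self, praat_fixture, tmp_path):
        tg, pt = praat_fixture
        short = tmp_path / "short.TextGrid"
        short.write_text(SHORT_TEXTGRID, encoding="utf-16")
        a = import_textgrid_tokens(tg, pt)
        b = import_textgrid_tokens(short, pt)
        for fa, fb in zip(a, b):
            assert (fa.dur_s1, fa.dur_s2, fa.f0_l, fa.f0_h) == pytest.approx(
                (fb.dur_s1, fb.dur_s2, fb.f0_l, fb.f0_h)
            )

    def test_tier_order_does_not_matter(self, praat_fixture, tmp_path):
        tg, pt = praat_fixture
        # rebuild the short-format file with the point tier first
        lines = SHORT_TEXTGRID.splitlines(keepends=True)
        header, body = lines[:7], lines[7:]
        split = body.index('"TextTier"\n')
        swapped = "".join(header + body[split:] + body[:split])
        other = tmp_path / "swapped.TextGrid"
        other.write_text(swapped)
        a = import_textgrid_tokens(tg, pt)
        b = import_textgrid_tokens(other, pt)
        assert [f.dur_s1 for f in a] == pytest.approx([f.dur_s1 for f in b])
        assert [f.f0_h for f in a] == pytest.approx([f.f0_h for f in b])

    def test_s1_followed_by_s1_is_structure_error(self, praat_fixture, tmp_path):
        tg, pt = praat_fixture
        bad = tmp_path / "bad.TextGrid"
        bad.write_text(tg.read_text().replace('text = "S2"', 'text = "S1"', 1))
        with pytest.raises(StructureError, match="S1"):
            import_textgrid_tokens(bad, pt)

    def test_point_outside_pitchtier_range_rejected(self, praat_fixture, tmp_path):
        tg, _ = praat_fixture
        clipped = tmp_path / "clipped.PitchTier"
        clipped.write_text(
            PITCHTIER.replace("points: size = 3", "points: size = 2").rsplit(
                "points [3]:", 1
            )[0]
        )
        with pytest.raises(AssociationError, match="outside"):
            import_textgrid_tokens(tg, clipped)

    def test_stray_tone_point_rejected(self, praat_fixture, tmp_path):
        tg, pt = praat_fixture
        text = tg.read_text().replace("points: size = 4", "points: size = 5")
        text += '            points [5]:\n                number = 1.9\n                mark = "H"\n'
        bad = tmp_path / "stray.TextGrid"
        bad.write_text(text)
        with pytest.raises(AssociationError):
            import_textgrid_tokens(bad, pt)
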