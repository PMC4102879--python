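"""Praat TextGrid and PitchTier text-format parsing and token import.

Supports both of Praat's text serialisations — the verbose "long" format
(``item [1]:``, ``intervals [1]:`` with ``name = value`` lines) and the
terse "short" format (bare values, one per line) — in UTF-8 or UTF-16, the
two encodings Praat writes.

The importer expects the segmentation convention used for noun tokens: an
interval tier in which each token contributes an adjacent S1/S2 interval
pair (first and last full syllable of the noun), and a point tier with one
"L" and one "H" point per token marking the early f0 minimum and the
S2-region f0 maximum.  f0 at the point times is read off the PitchTier by
linear interpolation between bracketing samples, which is Praat's own
PitchTier semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AssociationError, StructureError

DEFAULT_TIER_CONFIG = {"syllables": "syllables", "tones": "tones"}


@dataclass(frozen=True)
class Interval:
    xmin: float
    xmax: float
    text: str


@dataclass(frozen=True)
class Point:
    time: float
    mark: str


@dataclass(frozen=True)
class Tier:
    name: str
    kind: str  # "interval" or "point"
    intervals: tuple[Interval, ...] = ()
    points: tuple[Point, ...] = ()


@dataclass(frozen=True)
class TextGrid:
    xmin: float
    xmax: float
    tiers: tuple[Tier, ...]

    def tier(self, name: str) -> Tier:
        for t in self.tiers:
            if t.name == name:
                return t
        raise StructureError(
            f"TextGrid has no tier named {name!r}; available: "
            + ", ".join(repr(t.name) for t in self.tiers)
        )


@dataclass(frozen=True)
class PitchTier:
    xmin: float
    xmax: float
    times: np.ndarray
    values: np.ndarray

    def interpolate(self, time: float) -> float:
        """f0 at *time*, linearly interpolated between bracketing samples."""
        if self.times.size == 0:
            raise AssociationError("PitchTier contains no samples")
        if time < self.times[0] or time > self.times[-1]:
            raise AssociationError(
                f"time {time:g} s lies outside the PitchTier's sampled range "
                f"[{self.times[0]:g}, {self.times[-1]:g}]"
            )
        return float(np.interp(time, self.times, self.values))


def _read_text(path) -> str:
    raw = Path(path).read_bytes()
    if raw[:2] in (b"\xfe\xff", b"\xff\xfe"):
        return raw.decode("utf-16")
    return raw.decode("utf-8-sig")


_QUOTED = re.compile(r'"((?:[^"]|"")*)"')
_BARE = re.compile(r"[^\s\"]+")


def _tokenize(text: str) -> list[str]:
    """Flatten a Praat text file into a stream of strings and numbers.

    Works uniformly for long and short formats: the long format's
    ``name = value`` furniture, bracketed indices and ``class`` keywords are
    discarded, leaving the same value stream the short format spells out.
    """
    tokens: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        pos = 0
        while pos < len(line):
            ch = line[pos]
            if ch.isspace():
                pos += 1
                continue
            if ch == '"':
                match = _QUOTED.match(line, pos)
                if match is None:  # unterminated quote: treat rest as literal
                    tokens.append("\x00" + line[pos + 1 :])
                    break
                tokens.append("\x00" + match.group(1).replace('""', '"'))
                pos = match.end()
            else:
                match = _BARE.match(line, pos)
                word = match.group(0)
                # keep only bare numbers; "xmin", "=", "[1]:", "<exists>"
                # and friends are long-format furniture
                try:
                    float(word)
                    tokens.append(word)
                except ValueError:
                    pass
                pos = match.end()
    return tokens


class _Stream:
    def __init__(self, tokens: list[str]):
        self._tokens = tokens
        self._pos = 0

    def number(self) -> float:
        while self._pos < len(self._tokens):
            tok = self._tokens[self._pos]
            self._pos += 1
            if not tok.startswith("\x00"):
                return float(tok)
        raise StructureError("unexpected end of Praat file (expected a number)")

    def string(self) -> str:
        while self._pos < len(self._tokens):
            tok = self._tokens[self._pos]
            self._pos += 1
            if tok.startswith("\x00"):
                return tok[1:]
        raise StructureError("unexpected end of Praat file (expected a string)")


def read_textgrid(path) -> TextGrid:
    """Parse a Praat TextGrid (long or short text format)."""
    text = _read_text(path)
    if "TextGrid" not in text.split("\n", 3)[1]:
        raise StructureError(f"{path}: not a TextGrid file")
    stream = _Stream(_tokenize(text))
    xmin = stream.number()
    xmax = stream.number()
    # long format: "tiers? <exists>" then size; short: "<exists>" then size.
    # After tokenisation both reduce to: size (the <exists> flag only appears
    # as text "<exists>" in long format and is dropped; short format writes
    # "<exists>" too).  The next number is the tier count.
    n_tiers = int(stream.number())
    tiers = []
    for _ in range(n_tiers):
        klass = stream.string()
        name = stream.string()
        t_xmin = stream.number()
        t_xmax = stream.number()
        del t_xmin, t_xmax
        count = int(stream.number())
        if klass == "IntervalTier":
            intervals = []
            for _ in range(count):
                ixmin = stream.number()
                ixmax = stream.number()
                label = stream.string()
                intervals.append(Interval(ixmin, ixmax, label))
            tiers.append(Tier(name=name, kind="interval", intervals=tuple(intervals)))
        elif klass == "TextTier":
            points = []
            for _ in range(count):
                time = stream.number()
                mark = stream.string()
                points.append(Point(time, mark))
            tiers.append(Tier(name=name, kind="point", points=tuple(points)))
        else:
            raise StructureError(f"unsupported tier class {klass!r}")
    return TextGrid(xmin=xmin, xmax=xmax, tiers=tuple(tiers))


def read_pitchtier(path) -> PitchTier:
    """Parse a Praat PitchTier (long or short text format)."""
    text = _read_text(path)
    head = "\n".join(text.splitlines()[:2])
    if "PitchTier" not in head:
        raise StructureError(f"{path}: not a PitchTier file")
    stream = _Stream(_tokenize(text))
    xmin = stream.number()
    xmax = stream.number()
    count = int(stream.number())
    times = np.empty(count)
    values = np.empty(count)
    for i in range(count):
        times[i] = stream.number()
        values[i] = stream.number()
    order = np.argsort(times, kind="stable")
    return PitchTier(xmin=xmin, xmax=xmax, times=times[order], values=values[order])


@dataclass(frozen=True)
class TokenFragment:
    """Acoustic fields of one token read from TextGrid + PitchTier: interval
    durations for S1/S2 and interpolated f0 at the L/H point times."""

    token_id: str
    dur_s1: float
    dur_s2: float
    f0_l: float
    f0_h: float
    span: tuple[float, float]  # S1 start .. S2 end, seconds


def import_textgrid_tokens(
    textgrid_path,
    pitchtier_path,
    tier_config: dict | None = None,
) -> list[TokenFragment]:
    """Extract per-token acoustic measurements from a TextGrid/PitchTier pair.

    ``tier_config`` maps the roles ``"syllables"`` (interval tier of adjacent
    S1/S2 pairs) and ``"tones"`` (point tier of L/H marks) to tier names in
    the file; defaults are the role names themselves.

    Each S1 interval must be immediately followed by its S2 interval
    (intervening unlabeled/pause intervals are not permitted between the two
    syllables of one noun).  Each token's span (S1 start to S2 end) must
    contain exactly one L and one H point; an H placed beyond the S2 offset
    is deliberately rejected rather than silently accepted.
    """
    config = dict(DEFAULT_TIER_CONFIG)
    if tier_config:
        config.update(tier_config)
    grid = read_textgrid(textgrid_path)
    pitch = read_pitchtier(pitchtier_path)

    syll = grid.tier(config["syllables"])
    if syll.kind != "interval":
        raise StructureError(f"tier {syll.name!r} is not an interval tier")
    tones = grid.tier(config["tones"])
    if tones.kind != "point":
        raise StructureError(f"tier {tones.name!r} is not a point tier")

    labeled = [iv for iv in syll.intervals if iv.text.strip()]
    pairs: list[tuple[Interval, Interval]] = []
    i = 0
    while i < len(labeled):
        iv = labeled[i]
        label = iv.text.strip().upper()
        if label == "S1":
            if i + 1 >= len(labeled) or labeled[i + 1].text.strip().upper() != "S2":
                follower = (
                    labeled[i + 1].text.strip() if i + 1 < len(labeled) else "<end>"
                )
                raise StructureError(
                    f"S1 interval at {iv.xmin:g}s is followed by "
                    f"{follower!r}, expected S2"
                )
            pairs.append((iv, labeled[i + 1]))
            i += 2
        elif label == "S2":
            raise StructureError(
                f"S2 interval at {iv.xmin:g}s has no preceding S1"
            )
        else:
            i += 1

    fragments = []
    stem = Path(textgrid_path).stem
    used_points: set[float] = set()
    for idx, (s1, s2) in enumerate(pairs, start=1):
        span = (s1.xmin, s2.xmax)
        in_span = [p for p in tones.points if span[0] <= p.time <= span[1]]
        l_points = [p for p in in_span if p.mark.strip().upper() == "L"]
        h_points = [p for p in in_span if p.mark.strip().upper() == "H"]
        if len(l_points) != 1 or len(h_points) != 1:
            raise AssociationError(
                f"token span [{span[0]:g}, {span[1]:g}]s must contain exactly "
                f"one L and one H point; found {len(l_points)} L and "
                f"{len(h_points)} H"
            )
        used_points.update((l_points[0].time, h_points[0].time))
        fragments.append(
            TokenFragment(
                token_id=f"{stem}_tok{idx:03d}",
                dur_s1=s1.xmax - s1.xmin,
                dur_s2=s2.xmax - s2.xmin,
                f0_l=pitch.interpolate(l_points[0].time),
                f0_h=pitch.interpolate(h_points[0].time),
                span=span,
            )
        )

    stray = [
        p.time
        for p in tones.points
        if p.mark.strip().upper() in ("L", "H") and p.time not in used_points
    ]
    if stray:
        raise AssociationError(
            "L/H point(s) outside any token's span at time(s): "
            + ", ".join(f"{t:g}" for t in sorted(stray))
        )
    return fragments
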