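"""Shared fixtures: an in-memory MusicXML builder and corpus helpers."""

from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

from meloinfo.score_io import MelodyLine, NoteEvent

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_SHARP_NAMES = [
    ("C", 0), ("C", 1), ("D", 0), ("D", 1), ("E", 0), ("F", 0),
    ("F", 1), ("G", 0), ("G", 1), ("A", 0), ("A", 1), ("B", 0),
]


def _pitch_xml(midi: int) -> str:
    octave, pc = divmod(midi, 12)
    step, alter = _SHARP_NAMES[pc]
    alter_el = f"<alter>{alter}</alter>" if alter else ""
    return f"<pitch><step>{step}</step>{alter_el}<octave>{octave - 1}</octave></pitch>"


def make_musicxml(notes, divisions: int = 4) -> bytes:
    """Build a one-part score-partwise document.

    ``notes`` is a list of dicts with keys: pitch (MIDI int, or None for a
    rest), dur (in divisions, default = divisions i.e. a quarter), chord,
    grace, tie_stop, slur_stop, voice.
    """
    body = []
    for n in notes:
        parts = []
        if n.get("grace"):
            parts.append("<grace/>")
        if n.get("chord"):
            parts.append("<chord/>")
        if n.get("pitch") is None:
            parts.append("<rest/>")
        else:
            parts.append(_pitch_xml(n["pitch"]))
        if not n.get("grace"):
            parts.append(f"<duration>{n.get('dur', divisions)}</duration>")
        if n.get("voice"):
            parts.append(f"<voice>{n['voice']}</voice>")
        if n.get("tie_stop"):
            parts.append('<tie type="stop"/><notations><tied type="stop"/></notations>')
        if n.get("slur_stop"):
            parts.append('<notations><slur type="stop" number="1"/></notations>')
        body.append("<note>" + "".join(parts) + "</note>")
    xml = (
        '<?xml version="1.0" encoding="UTF-8"?>'
        '<score-partwise version="3.1">'
        "<part-list><score-part id=\"P1\"><part-name>Test</part-name></score-part></part-list>"
        '<part id="P1"><measure number="1">'
        f"<attributes><divisions>{divisions}</divisions></attributes>"
        + "".join(body)
        + "</measure></part></score-partwise>"
    )
    return xml.encode()


@pytest.fixture
def musicxml_builder():
    return make_musicxml


def note(onset, pitch, dur=1, **kw) -> NoteEvent:
    return NoteEvent(
        onset=Fraction(onset), pitch=pitch, duration=Fraction(dur),
        grace=kw.get("grace", False),
        tie_or_slur_continuation=kw.get("cont", False),
        staff_voice=kw.get("sv", "1/1"),
    )


@pytest.fixture
def melody():
    def build(pitches, piece_no=1, movement_no=1):
        return MelodyLine(piece_no=piece_no, movement_no=movement_no, pitches=tuple(pitches))

    return build
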