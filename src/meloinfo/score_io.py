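"""Score input/output: MusicXML melody extraction, plain-text sequences, corpus manifests.

The analysis operates on *melody lines*: for every movement, the sequence of
highest sounding pitches over time.  Extraction follows three rules:

1. at every onset, keep only the highest pitch sounding at that moment
   (across all staves and voices — voice crossings are resolved by pitch);
2. grace notes are excluded before selection;
3. a note repeated at the same pitch under a tie or slur continuation is
   counted once (the continuation is merged into the note it prolongs).

Slurs spanning *different* pitches retain every note: merging those would
delete melody tones (scale runs under a slur must survive extraction).

MusicXML support is a deliberately small reader for score-partwise documents
(plain ``.xml`` and compressed ``.mxl``): pitches, chords, grace notes, ties
and slurs, multiple voices/staves, ``backup``/``forward`` cursor moves, and
``divisions`` changes.  Onsets and durations are kept as exact rationals in
quarter-note units so tuplets never suffer float-equality problems.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from lxml import etree

__all__ = [
    "NoteEvent",
    "MelodyLine",
    "CorpusManifest",
    "ManifestEntry",
    "ScoreFormatError",
    "ManifestError",
    "SequenceParseError",
    "read_movement",
    "extract_highest_line",
    "read_plaintext_sequence",
    "write_plaintext_sequence",
    "load_corpus",
]

PIANO_RANGE = (21, 108)  # A0..C8, MIDI

_STEP_TO_SEMITONE = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}

PERIOD_LABELS = ("early", "middle", "late")


class ScoreFormatError(ValueError):
    """Raised when a MusicXML document cannot be interpreted."""


class ManifestError(ValueError):
    """Raised for invalid corpus manifests (missing paths, duplicates, bad labels)."""


class SequenceParseError(ValueError):
    """Raised when a plain-text pitch sequence fails to parse."""


@dataclass(frozen=True)
class NoteEvent:
    """One sounding note: onset/duration in quarter-note units, MIDI pitch."""

    onset: Fraction
    pitch: int
    duration: Fraction
    grace: bool = False
    tie_or_slur_continuation: bool = False
    staff_voice: str = "1/1"


@dataclass(frozen=True)
class MelodyLine:
    """Ordered highest-pitch sequence for one movement of one piece."""

    piece_no: int
    movement_no: int
    pitches: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.pitches)


@dataclass(frozen=True)
class ManifestEntry:
    piece_no: int
    opus_label: str
    movement_no: int
    period_label: str
    source_path: Path


@dataclass
class CorpusManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def pieces(self) -> list[int]:
        return sorted({e.piece_no for e in self.entries})

    def period_of(self, piece_no: int) -> str:
        for e in self.entries:
            if e.piece_no == piece_no:
                return e.period_label
        raise KeyError(piece_no)


# ---------------------------------------------------------------------------
# MusicXML reading
# ---------------------------------------------------------------------------


def _midi_pitch(note_el: etree._Element) -> int | None:
    p = note_el.find("pitch")
    if p is None:
        return None
    step = p.findtext("step")
    if step is None or step not in _STEP_TO_SEMITONE:
        raise ScoreFormatError(f"bad or missing <step> in <pitch>: {step!r}")
    octave_text = p.findtext("octave")
    if octave_text is None:
        raise ScoreFormatError("missing <octave> in <pitch>")
    alter = p.findtext("alter")
    midi = 12 * (int(octave_text) + 1) + _STEP_TO_SEMITONE[step]
    if alter is not None:
        midi += int(round(float(alter)))
    return midi


def _is_continuation(note_el: etree._Element) -> bool:
    # <tie type="stop"> on the note, or <tied>/<slur type="stop"> in notations
    for tie in note_el.findall("tie"):
        if tie.get("type") == "stop":
            return True
    for notations in note_el.findall("notations"):
        for tag in ("tied", "slur"):
            for el in notations.findall(tag):
                if el.get("type") == "stop":
                    return True
    return False


def _load_xml_root(source) -> etree._Element:
    """Accept a path (str/Path) to .xml/.mxl, bytes, or a file-like object."""
    data: bytes
    if isinstance(source, (str, Path)):
        path = Path(source)
        data = path.read_bytes()
    elif isinstance(source, bytes):
        data = source
    else:
        data = source.read()
        if isinstance(data, str):
            data = data.encode()
    if data[:2] == b"PK":  # compressed .mxl container
        with zipfile.ZipFile(io.BytesIO(data)) as zf:
            rootfile = None
            try:
                container = etree.fromstring(zf.read("META-INF/container.xml"))
                rf = container.find(".//rootfile")
                if rf is not None:
                    rootfile = rf.get("full-path")
            except KeyError:
                pass
            if rootfile is None:
                candidates = [n for n in zf.namelist() if n.endswith(".xml") and not n.startswith("META-INF")]
                if not candidates:
                    raise ScoreFormatError("mxl archive contains no score xml")
                rootfile = candidates[0]
            data = zf.read(rootfile)
    try:
        parser = etree.XMLParser(resolve_entities=False, no_network=True, recover=False)
        root = etree.fromstring(data, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise ScoreFormatError(f"unparsable MusicXML: {exc}") from exc
    return root


def read_movement(source) -> list[NoteEvent]:
    """Read all sounding notes of one movement from a MusicXML document.

    Returns events ordered by (onset, staff/voice); rests are omitted, grace
    notes carry ``grace=True`` with zero duration, and tie/slur *stop* marks
    set ``tie_or_slur_continuation``.
    """
    root = _load_xml_root(source)
    tag = etree.QName(root).localname if root.tag else ""
    if tag != "score-partwise":
        raise ScoreFormatError(f"unsupported root element <{tag}>; expected <score-partwise>")

    events: list[NoteEvent] = []
    for part in root.findall("part"):
        divisions = Fraction(1)
        cursor = Fraction(0)  # in quarter notes
        prev_onset = Fraction(0)
        for measure in part.findall("measure"):
            for el in measure:
                name = etree.QName(el).localname
                if name == "attributes":
                    div_text = el.findtext("divisions")
                    if div_text is not None:
                        divisions = Fraction(int(div_text))
                elif name == "backup":
                    cursor -= Fraction(int(el.findtext("duration"))) / divisions
                elif name == "forward":
                    cursor += Fraction(int(el.findtext("duration"))) / divisions
                elif name == "note":
                    grace = el.find("grace") is not None
                    chord = el.find("chord") is not None
                    dur_text = el.findtext("duration")
                    dur = Fraction(0) if dur_text is None else Fraction(int(dur_text)) / divisions
                    onset = prev_onset if chord else cursor
                    pitch = _midi_pitch(el)
                    if pitch is not None:
                        voice = el.findtext("voice") or "1"
                        staff = el.findtext("staff") or "1"
                        events.append(
                            NoteEvent(
                                onset=onset,
                                pitch=pitch,
                                duration=dur,
                                grace=grace,
                                tie_or_slur_continuation=_is_continuation(el),
                                staff_voice=f"{staff}/{voice}",
                            )
                        )
                    if not chord:
                        prev_onset = cursor
                        if not grace:
                            cursor += dur
    events.sort(key=lambda e: (e.onset, e.staff_voice, -e.pitch))
    return events


# ---------------------------------------------------------------------------
# Highest-line extraction
# ---------------------------------------------------------------------------


def extract_highest_line(
    events: Sequence[NoteEvent], piece_no: int = 0, movement_no: int = 1
) -> MelodyLine:
    """Reduce a movement's events to its highest-pitch melody line.

    Grace notes are dropped first; per distinct onset the maximum pitch wins;
    consecutive equal pitches are merged when the later note is a tie or slur
    continuation.  Empty input yields an empty line.
    """
    sounding = [e for e in events if not e.grace]
    by_onset: dict[Fraction, list[NoteEvent]] = {}
    for e in sounding:
        by_onset.setdefault(e.onset, []).append(e)
    pitches: list[int] = []
    for onset in sorted(by_onset):
        group = by_onset[onset]
        top = max(group, key=lambda e: e.pitch)
        if (
            pitches
            and top.pitch == pitches[-1]
            and top.tie_or_slur_continuation
        ):
            continue
        pitches.append(top.pitch)
    return MelodyLine(piece_no=piece_no, movement_no=movement_no, pitches=tuple(pitches))


# ---------------------------------------------------------------------------
# Plain-text sequence format
# ---------------------------------------------------------------------------
#
#   #piece=<int> movement=<int>
#   60 62 64 ...
# Pitches may wrap across lines; blank lines ignored.


def write_plaintext_sequence(path, line: MelodyLine) -> None:
    path = Path(path)
    tokens = " ".join(str(p) for p in line.pitches)
    path.write_text(f"#piece={line.piece_no} movement={line.movement_no}\n{tokens}\n")


def read_plaintext_sequence(path) -> MelodyLine:
    path = Path(path)
    piece_no = 0
    movement_no = 1
    pitches: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            if text.startswith("#"):
                for kv in text.lstrip("#").split():
                    if "=" in kv:
                        key, _, val = kv.partition("=")
                        if key == "piece":
                            piece_no = int(val)
                        elif key == "movement":
                            movement_no = int(val)
                continue
            for col, tok in enumerate(text.split(), start=1):
                try:
                    pitches.append(int(tok))
                except ValueError:
                    raise SequenceParseError(
                        f"{path}: non-integer token {tok!r} at line {lineno}, token {col}"
                    ) from None
    return MelodyLine(piece_no=piece_no, movement_no=movement_no, pitches=tuple(pitches))


# ---------------------------------------------------------------------------
# Corpus manifest
# ---------------------------------------------------------------------------


def _normalize_period(label: str) -> str:
    norm = label.strip().lower()
    if norm not in PERIOD_LABELS:
        raise ManifestError(f"unknown period label {label!r} (expected one of {PERIOD_LABELS})")
    return norm


def read_manifest(manifest_path) -> CorpusManifest:
    """Read a TSV manifest with columns piece_no, opus, movement_no, period, path."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    entries: list[ManifestEntry] = []
    seen: set[tuple[int, int]] = set()
    problems: list[str] = []
    with manifest_path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["piece_no", "opus", "movement_no", "period", "path"]
        if [h.strip() for h in header] != expected:
            raise ManifestError(f"manifest header {header} != {expected}")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 5:
                problems.append(f"line {lineno}: expected 5 columns, got {len(cols)}")
                continue
            piece_no = int(cols[0])
            movement_no = int(cols[2])
            key = (piece_no, movement_no)
            if key in seen:
                problems.append(f"line {lineno}: duplicate (piece, movement) {key}")
                continue
            seen.add(key)
            try:
                period = _normalize_period(cols[3])
            except ManifestError as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            src = (manifest_path.parent / cols[4]).resolve() if not Path(cols[4]).is_absolute() else Path(cols[4])
            if not src.exists():
                problems.append(f"line {lineno}: missing source file {src}")
                continue
            entries.append(ManifestEntry(piece_no, cols[1], movement_no, period, src))
    if problems:
        raise ManifestError("invalid manifest:\n  " + "\n  ".join(problems))
    return CorpusManifest(entries=entries)


def load_corpus(manifest_path, log=None) -> tuple[CorpusManifest, dict[tuple[int, int], MelodyLine]]:
    """Load every movement named in a manifest.

    Sources ending in ``.xml``/``.mxl`` go through the MusicXML reader and
    highest-line extraction; anything else is read as a plain-text sequence.
    Returns the manifest and a dict keyed by (piece_no, movement_no).
    """
    manifest = read_manifest(manifest_path)
    movements: dict[tuple[int, int], MelodyLine] = {}
    for entry in manifest.entries:
        suffix = entry.source_path.suffix.lower()
        if suffix in (".xml", ".mxl", ".musicxml"):
            events = read_movement(entry.source_path)
            line = extract_highest_line(events, entry.piece_no, entry.movement_no)
        else:
            line = read_plaintext_sequence(entry.source_path)
            line = MelodyLine(entry.piece_no, entry.movement_no, line.pitches)
        movements[(entry.piece_no, entry.movement_no)] = line
        if log is not None:
            log(f"piece {entry.piece_no} movement {entry.movement_no}: {len(line)} notes")
    return manifest, movements
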