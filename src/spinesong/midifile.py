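"""Minimal Standard MIDI File (format 1) writer and reader.

Only the events this package emits are supported: tempo meta, program
change, controller (pan, CC10), note-on and note-off.  Times are absolute
ticks at a fixed division; variable-length quantities and running status
are handled per the SMF specification.  The reader exists so rendered files
can be decoded and checked without an external MIDI library.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

__all__ = ["MidiTrack", "MidiNote", "write_midi_file", "read_midi_file", "extract_notes"]

TICKS_PER_QUARTER = 480
DEFAULT_TEMPO_US = 500_000  # 120 BPM


def _vlq(value: int) -> bytes:
    """Encode a variable-length quantity."""
    if value < 0:
        raise ValueError("negative delta time")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


@dataclass
class MidiTrack:
    """Absolute-tick event list for one SMF track.

    Events are tuples ``(tick, kind, data)`` with kinds ``tempo``,
    ``program`` (channel, program), ``control`` (channel, controller,
    value), ``note_on`` / ``note_off`` (channel, note, velocity) and
    ``name`` (str).
    """

    events: list[tuple] = field(default_factory=list)

    def add(self, tick: int, kind: str, *data) -> None:
        self.events.append((tick, kind, data))

    def to_bytes(self) -> bytes:
        # stable sort keeps same-tick emission order (program before note-on)
        order = {"name": 0, "tempo": 1, "program": 2, "control": 3, "note_off": 4, "note_on": 5}
        evts = sorted(self.events, key=lambda e: (e[0], order[e[1]]))
        out = bytearray()
        prev = 0
        for tick, kind, data in evts:
            out += _vlq(tick - prev)
            prev = tick
            if kind == "tempo":
                out += bytes([0xFF, 0x51, 0x03]) + struct.pack(">I", data[0])[1:]
            elif kind == "name":
                enc = data[0].encode("utf-8")
                out += bytes([0xFF, 0x03]) + _vlq(len(enc)) + enc
            elif kind == "program":
                ch, prog = data
                out += bytes([0xC0 | ch, prog])
            elif kind == "control":
                ch, cc, val = data
                out += bytes([0xB0 | ch, cc, val])
            elif kind == "note_on":
                ch, note, vel = data
                out += bytes([0x90 | ch, note, vel])
            elif kind == "note_off":
                ch, note, vel = data
                out += bytes([0x80 | ch, note, vel])
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        out += _vlq(0) + bytes([0xFF, 0x2F, 0x00])  # end of track
        return bytes(out)


def write_midi_file(tracks: list[MidiTrack], path, division: int = TICKS_PER_QUARTER) -> None:
    """Write an SMF format-1 file with the given tracks."""
    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 1, len(tracks), division))
        for tr in tracks:
            body = tr.to_bytes()
            fh.write(b"MTrk" + struct.pack(">I", len(body)) + body)


# ---------------------------------------------------------------------------
# Reader

@dataclass(frozen=True)
class MidiNote:
    """One decoded note with the program and pan in force at its note-on."""

    track: int
    tick: int
    channel: int
    note: int
    velocity: int
    program: int
    pan: int
    duration_ticks: int


def read_midi_file(path):
    """Decode an SMF file into (division, list-of-track-event-lists).

    Each event is ``(tick, kind, data)`` mirroring :class:`MidiTrack`.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File")
    hlen, fmt, ntracks, division = struct.unpack(">IHHH", data[4:14])
    pos = 8 + hlen
    tracks = []
    for _ in range(ntracks):
        if data[pos : pos + 4] != b"MTrk":
            raise ValueError("missing MTrk chunk")
        length = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        body = data[pos + 8 : pos + 8 + length]
        pos += 8 + length
        tracks.append(_decode_track(body))
    return division, tracks


def _read_vlq(body: bytes, i: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = body[i]
        i += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, i


def _decode_track(body: bytes):
    events = []
    i = 0
    tick = 0
    status = 0
    while i < len(body):
        delta, i = _read_vlq(body, i)
        tick += delta
        byte = body[i]
        if byte & 0x80:
            status = byte
            i += 1
        if status == 0xFF:
            meta = body[i]
            i += 1
            length, i = _read_vlq(body, i)
            payload = body[i : i + length]
            i += length
            if meta == 0x51:
                events.append((tick, "tempo", (int.from_bytes(payload, "big"),)))
            elif meta == 0x03:
                events.append((tick, "name", (payload.decode("utf-8"),)))
            elif meta == 0x2F:
                break
        else:
            kind = status & 0xF0
            ch = status & 0x0F
            if kind == 0xC0:
                events.append((tick, "program", (ch, body[i])))
                i += 1
            elif kind == 0xB0:
                events.append((tick, "control", (ch, body[i], body[i + 1])))
                i += 2
            elif kind == 0x90:
                note, vel = body[i], body[i + 1]
                i += 2
                events.append((tick, "note_on" if vel else "note_off", (ch, note, vel)))
            elif kind == 0x80:
                events.append((tick, "note_off", (ch, body[i], body[i + 1])))
                i += 2
            else:
                raise ValueError(f"unsupported status byte 0x{status:02X}")
    return events


def extract_notes(path) -> list[MidiNote]:
    """All notes in a file, with program/pan state captured at note-on."""
    _, tracks = read_midi_file(path)
    notes = []
    for ti, events in enumerate(tracks):
        program = {ch: 0 for ch in range(16)}
        pan = {ch: 64 for ch in range(16)}
        open_notes: dict[tuple[int, int], list] = {}
        for tick, kind, data in events:
            if kind == "program":
                program[data[0]] = data[1]
            elif kind == "control" and data[1] == 10:
                pan[data[0]] = data[2]
            elif kind == "note_on":
                ch, note, vel = data
                open_notes.setdefault((ch, note), []).append(
                    [ti, tick, ch, note, vel, program[ch], pan[ch]]
                )
            elif kind == "note_off":
                ch, note, _ = data
                stack = open_notes.get((ch, note))
                if stack:
                    rec = stack.pop(0)
                    notes.append(MidiNote(*rec, duration_ticks=tick - rec[1]))
        for stack in open_notes.values():  # unterminated notes: zero length
            for rec in stack:
                notes.append(MidiNote(*rec, duration_ticks=0))
    notes.sort(key=lambda n: (n.track, n.tick, n.note))
    return notes
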