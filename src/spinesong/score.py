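"""Score assembly and rendering.

Turns unrolled spines plus a mapping configuration into a time-ordered
score (one note per spine, constant duration, onset = s / scanning speed)
and renders it as a Standard MIDI File and as a machine-readable event
list.  When the first spine lies some distance from the soma, a low
sustained drone -- the "basal sound" -- fills the gap from t = 0 until the
first note.

MIDI realization constants: dynamics pp/mf/f/ff map to velocities
32/64/96/120; timbres map to General MIDI programs pizzicato strings = 45,
acoustic grand piano = 0, trumpet = 56, violin = 40; the drone is a synth
pad (program 89) at note 36, velocity 20.  Stereo side is realized with
controller 10 (left = 0, right = 127, center = 64).  The tempo is fixed at
120 BPM with 480 ticks per quarter note, so onsets quantize to ~1 ms and
output files are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .mapping import (
    Channel,
    Dynamic,
    Instrument,
    MappingConfig,
    angle_to_pitch_bi,
    angle_to_pitch_uni,
    degree_to_midi,
    length_to_dynamics,
    length_to_timbre,
    midi_to_solfege,
    onset_time,
    volume_to_dynamics,
)
from .midifile import TICKS_PER_QUARTER, MidiTrack, write_midi_file
from .unroll import UnrolledSpine

__all__ = [
    "NoteEvent",
    "Score",
    "build_score",
    "render_midi",
    "render_event_list",
    "compose_ensemble",
    "VELOCITY",
    "PROGRAM",
    "PAN",
]

VELOCITY = {Dynamic.pp: 32, Dynamic.mf: 64, Dynamic.f: 96, Dynamic.ff: 120}
PROGRAM = {
    Instrument.pizzicato: 45,
    Instrument.piano: 0,
    Instrument.trumpet: 56,
    Instrument.violin: 40,
}
PAN = {Channel.left: 0, Channel.right: 127, Channel.both: 64}

DRONE_ID = "drone"
DRONE_PROGRAM = 89  # GM pad 2 (warm)
DRONE_NOTE = 36
DRONE_VELOCITY = 20

TICKS_PER_SECOND = TICKS_PER_QUARTER * 2  # 120 BPM -> 0.5 s per quarter


@dataclass(frozen=True)
class NoteEvent:
    """One musical note, fully realized for MIDI plus readable labels."""

    spine_id: str
    onset: float
    duration: float
    midi_note: int
    velocity: int
    program: int
    pan: int
    dynamic: str = "mf"
    instrument: str = "piano"
    channel: str = "both"

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("onset must be >= 0 and duration > 0")
        if not (0 <= self.midi_note <= 127 and 1 <= self.velocity <= 127 and 0 <= self.pan <= 127):
            raise ValueError("MIDI fields out of range")


@dataclass(frozen=True)
class Score:
    """Time-ordered note events, grouped in named tracks for ensembles."""

    events: tuple[NoteEvent, ...]
    total_duration: float
    tracks: dict[str, tuple[NoteEvent, ...]] = field(default_factory=dict)
    note_duration: float = 0.25

    @property
    def n_spine_notes(self) -> int:
        """Event count excluding the drone -- equals the spine count."""
        return sum(1 for e in self.events if e.spine_id != DRONE_ID)


def _map_one(u: UnrolledSpine, cfg: MappingConfig, speed: float) -> NoteEvent:
    if cfg.enable_volume:
        dyn = volume_to_dynamics(u.volume_um3, cfg)
    elif cfg.enable_length:
        dyn = length_to_dynamics(u.length_um, cfg)
    else:
        dyn = Dynamic.mf
    if cfg.enable_length and cfg.enable_volume:
        timbre = length_to_timbre(u.length_um, cfg)
    else:
        timbre = Instrument.piano
    if cfg.enable_angle:
        if cfg.direction_mode == "unidirectional":
            degree, chan = angle_to_pitch_uni(u.theta, cfg.n_wedges)
            note = degree_to_midi(degree, cfg.n_wedges, cfg.scale_root)
        else:
            degree, chan = angle_to_pitch_bi(u.theta, cfg.n_intervals)
            note = degree_to_midi(degree, cfg.n_intervals // 2, cfg.scale_root)
    else:
        chan = Channel.both
        note = cfg.scale_root
    return NoteEvent(
        spine_id=u.spine_id,
        onset=onset_time(u.s, speed),
        duration=cfg.note_duration,
        midi_note=note,
        velocity=VELOCITY[dyn],
        program=PROGRAM[timbre],
        pan=PAN[chan],
        dynamic=dyn.value,
        instrument=timbre.value,
        channel=chan.value,
    )


def build_score(
    unrolled: list[UnrolledSpine],
    cfg: MappingConfig | None = None,
    axis_length: float | None = None,
    track_name: str = "main",
) -> Score:
    """Map unrolled spines to a score: one note per spine plus the drone.

    ``axis_length`` resolves the "auto" scanning speed and extends the
    total duration to the full sweep; if omitted, the span of the spine
    positions is used.
    """
    cfg = cfg or MappingConfig()
    if not unrolled:
        return Score(events=(), total_duration=0.0, tracks={track_name: ()}, note_duration=cfg.note_duration)
    length = axis_length if axis_length is not None else max(u.s for u in unrolled)
    speed = cfg.resolve_speed(length)
    events = sorted(
        (_map_one(u, cfg, speed) for u in unrolled), key=lambda e: (e.onset, e.spine_id)
    )
    first_onset = events[0].onset
    if first_onset > 0:
        drone = NoteEvent(
            spine_id=DRONE_ID,
            onset=0.0,
            duration=first_onset,
            midi_note=DRONE_NOTE,
            velocity=DRONE_VELOCITY,
            program=DRONE_PROGRAM,
            pan=PAN[Channel.both],
            dynamic="pp",
            instrument="drone",
            channel="both",
        )
        events = [drone] + events
    total = max(max(e.onset + e.duration for e in events), length / speed)
    events = tuple(events)
    return Score(
        events=events,
        total_duration=total,
        tracks={track_name: events},
        note_duration=cfg.note_duration,
    )


def compose_ensemble(scores: list[Score], labels: list[str]) -> Score:
    """Merge scores on a shared time axis, one named track each.

    Inputs must have been rendered with the same note duration (they are
    meant to be matched in spine size and scanning speed); a mismatch is an
    error.
    """
    if len(scores) != len(labels):
        raise ValueError("need one label per score")
    if len(set(labels)) != len(labels):
        raise ValueError("ensemble labels must be unique")
    durs = {s.note_duration for s in scores}
    if len(durs) > 1:
        raise ValueError(f"mismatched note_duration across ensemble parts: {sorted(durs)}")
    tracks = {}
    merged: list[NoteEvent] = []
    for sc, label in zip(scores, labels):
        evts = tuple(replace(e, spine_id=f"{label}/{e.spine_id}") for e in sc.events)
        tracks[label] = evts
        merged.extend(evts)
    merged.sort(key=lambda e: (e.onset, e.spine_id))
    total = max((s.total_duration for s in scores), default=0.0)
    return Score(
        events=tuple(merged),
        total_duration=total,
        tracks=tracks,
        note_duration=durs.pop() if durs else 0.25,
    )


def _sec_to_tick(sec: float) -> int:
    return round(sec * TICKS_PER_SECOND)


def render_midi(score: Score, path) -> None:
    """Write the score as an SMF format-1 file.

    Track 0 carries the fixed 120 BPM tempo; each score track becomes one
    MIDI track.  MIDI channels are allocated one per (program, pan)
    combination (skipping the GM percussion channel) so overlapping notes
    with different timbres or stereo sides never interfere; the program
    change and pan controller are emitted on each channel before its first
    note.
    """
    channel_pool = [c for c in range(16) if c != 9]
    channel_of: dict[tuple[int, int], int] = {}
    announced: set[int] = set()

    tempo = MidiTrack()
    tempo.add(0, "name", "tempo")
    tempo.add(0, "tempo", 500_000)
    tracks = [tempo]
    for name, events in score.tracks.items():
        tr = MidiTrack()
        tr.add(0, "name", name)
        for e in sorted(events, key=lambda e: (e.onset, e.spine_id)):
            key = (e.program, e.pan)
            if key not in channel_of:
                if not channel_pool:
                    raise ValueError("more than 15 distinct (program, pan) combinations")
                channel_of[key] = channel_pool.pop(0)
            ch = channel_of[key]
            tick = _sec_to_tick(e.onset)
            if ch not in announced:
                tr.add(tick, "program", ch, e.program)
                tr.add(tick, "control", ch, 10, e.pan)
                announced.add(ch)
            off = max(tick + 1, _sec_to_tick(e.onset + e.duration))
            tr.add(tick, "note_on", ch, e.midi_note, e.velocity)
            tr.add(off, "note_off", ch, e.midi_note, 0)
        tracks.append(tr)
    write_midi_file(tracks, path)


def render_event_list(score: Score) -> pd.DataFrame:
    """Event list as a table: one onset-sorted row per note (drone included)."""
    rows = [
        {
            "spine_id": e.spine_id,
            "onset_s": e.onset,
            "note_name": midi_to_solfege(e.midi_note),
            "dynamic": e.dynamic,
            "instrument": e.instrument,
            "channel": e.channel,
        }
        for e in sorted(score.events, key=lambda e: (e.onset, e.spine_id))
    ]
    return pd.DataFrame(rows, columns=["spine_id", "onset_s", "note_name", "dynamic", "instrument", "channel"])


def write_event_list(score: Score, path) -> None:
    render_event_list(score).to_csv(path, index=False, float_format="%.6g")
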