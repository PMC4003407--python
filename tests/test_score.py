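import numpy as np
import pytest

from spinesong import (
    MappingConfig,
    UnrolledSpine,
    build_score,
    compose_ensemble,
    render_event_list,
    render_midi,
)
from spinesong.midifile import extract_notes, read_midi_file
from spinesong.score import DRONE_ID


def spine(i, s, theta=0.0, length=1.5, volume=0.3):
    return UnrolledSpine(f"s{i:03d}", s, theta, 0.5, length, volume)


@pytest.fixture
def cfg():
    return MappingConfig(scan_speed=1.0, note_duration=0.25)


class TestBuildScore:
    def test_three_spines_and_drone(self, cfg):
        sc = build_score([spine(i, s) for i, s in enumerate([1.0, 2.0, 3.0])], cfg)
        assert [e.onset for e in sc.events] == [0.0, 1.0, 2.0, 3.0]
        drone = sc.events[0]
        assert drone.spine_id == DRONE_ID and drone.duration == pytest.approx(1.0)
        assert sc.n_spine_notes == 3

    def test_empty_input_empty_score(self, cfg):
        sc = build_score([], cfg)
        assert sc.events == () and sc.total_duration == 0.0

    def test_no_drone_when_first_spine_at_origin(self, cfg):
        sc = build_score([spine(0, 0.0), spine(1, 2.0)], cfg)
        assert all(e.spine_id != DRONE_ID for e in sc.events)

    def test_equal_onsets_tie_break_by_id(self, cfg):
        sc = build_score([spine(2, 5.0), spine(1, 5.0)], cfg)
        notes = [e for e in sc.events if e.spine_id != DRONE_ID]
        assert [e.spine_id for e in notes] == ["s001", "s002"]
        assert notes[0].onset == notes[1].onset  # a chord

    def test_500_random_spines_conserved_and_sorted(self, cfg, rng):
        spines = [spine(i, float(rng.uniform(0, 100))) for i in range(500)]
        sc = build_score(spines, cfg)
        onsets = [e.onset for e in sc.events]
        assert onsets == sorted(onsets)
        assert sc.n_spine_notes == 500
        assert sc.total_duration >= max(e.onset + e.duration for e in sc.events)

    def test_disabled_features_take_defaults(self):
        cfg = MappingConfig(scan_speed=1.0, enable_angle=False, enable_volume=False)
        sc = build_score([spine(0, 1.0, theta=200.0, volume=0.9)], cfg)
        (note,) = [e for e in sc.events if e.spine_id != DRONE_ID]
        assert note.midi_note == cfg.scale_root
        assert note.dynamic == "mf" and note.velocity == 64
        assert note.instrument == "piano" and note.program == 0
        assert note.channel == "both" and note.pan == 64

    def test_length_only_drives_dynamics_not_timbre(self):
        cfg = MappingConfig(scan_speed=1.0, enable_volume=False, enable_length=True)
        sc = build_score([spine(0, 1.0, length=4.0)], cfg)
        (note,) = [e for e in sc.events if e.spine_id != DRONE_ID]
        assert note.dynamic == "ff"
        assert note.instrument == "piano"


class TestMidiRendering:
    def test_single_event_round_trip(self, cfg, tmp_path):
        sc = build_score([spine(0, 0.0, theta=0.0, volume=0.3)], cfg)
        path = tmp_path / "one.mid"
        render_midi(sc, path)
        notes = extract_notes(path)
        assert len(notes) == 1
        assert notes[0].note == 60 and notes[0].velocity == 64 and notes[0].program == 0

    def test_empty_score_is_valid_midi(self, cfg, tmp_path):
        path = tmp_path / "empty.mid"
        render_midi(build_score([], cfg), path)
        division, tracks = read_midi_file(path)
        assert division == 480
        assert not any(k.startswith("note") for tr in tracks for _, k, _ in tr)

    def test_header_and_tempo(self, cfg, tmp_path):
        path = tmp_path / "x.mid"
        render_midi(build_score([spine(0, 1.0)], cfg), path)
        raw = path.read_bytes()
        assert raw[:4] == b"MThd" and raw[8:10] == b"\x00\x01"  # format 1
        _, tracks = read_midi_file(path)
        assert (0, "tempo", (500_000,)) in tracks[0]

    def test_round_trip_recovers_all_attributes(self, tmp_path, rng):
        cfg = MappingConfig(scan_speed=2.0, enable_length=True, direction_mode="bidirectional")
        spines = [
            spine(i, float(rng.uniform(0, 50)), theta=float(rng.uniform(0, 360)),
                  length=float(rng.lognormal(0.2, 0.6)), volume=float(rng.lognormal(-1.2, 0.8)))
            for i in range(120)
        ]
        sc = build_score(spines, cfg)
        path = tmp_path / "r.mid"
        render_midi(sc, path)
        notes = sorted(extract_notes(path), key=lambda n: (n.tick, n.note))
        events = sorted(sc.events, key=lambda e: (round(e.onset * 960), e.midi_note))
        assert len(notes) == len(events)
        assert sorted(n.note for n in notes) == sorted(e.midi_note for e in events)
        assert sorted(n.velocity for n in notes) == sorted(e.velocity for e in events)
        assert sorted(n.program for n in notes) == sorted(e.program for e in events)
        assert sorted(n.pan for n in notes) == sorted(e.pan for e in events)
        assert set(n.velocity for n in notes if n.program != 89) <= {32, 64, 96, 120}

    def test_determinism_byte_identical(self, cfg, tmp_path, rng):
        spines = [spine(i, float(rng.uniform(0, 20)), theta=float(rng.uniform(0, 360))) for i in range(30)]
        sc = build_score(spines, cfg)
        p1, p2 = tmp_path / "a.mid", tmp_path / "b.mid"
        render_midi(sc, p1)
        render_midi(sc, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestEventList:
    def test_note_names_and_sorting(self, cfg):
        sc = build_score([spine(0, 2.0, theta=0.0), spine(1, 1.0, theta=300.0)], cfg)
        df = render_event_list(sc)
        assert list(df.columns) == ["spine_id", "onset_s", "note_name", "dynamic", "instrument", "channel"]
        assert df.onset_s.is_monotonic_increasing
        by_id = df.set_index("spine_id")
        assert by_id.loc["s000", "note_name"] == "Do4"  # theta 0 -> degree 0 at root 60

    def test_row_count_matches_midi_note_count(self, cfg, tmp_path, rng):
        spines = [spine(i, float(rng.uniform(0, 30)), theta=float(rng.uniform(0, 360))) for i in range(57)]
        sc = build_score(spines, cfg)
        path = tmp_path / "x.mid"
        render_midi(sc, path)
        assert len(render_event_list(sc)) == len(extract_notes(path))


class TestEnsemble:
    def test_two_part_merge(self, cfg, tmp_path):
        a = build_score([spine(0, 1.0)], cfg, track_name="young")
        b = build_score([spine(0, 2.0)], cfg, track_name="old")
        ens = compose_ensemble([a, b], ["young", "old"])
        assert set(ens.tracks) == {"young", "old"}
        assert len(ens.events) == len(a.events) + len(b.events)

    def test_trio_triples_event_count(self, cfg):
        part = build_score([spine(i, float(i + 1)) for i in range(10)], cfg)
        trio = compose_ensemble([part] * 3, ["a", "b", "c"])
        assert len(trio.events) == 3 * len(part.events)

    def test_mismatched_note_duration_rejected(self, cfg):
        other = MappingConfig(scan_speed=1.0, note_duration=0.5)
        with pytest.raises(ValueError, match="note_duration"):
            compose_ensemble(
                [build_score([spine(0, 1.0)], cfg), build_score([spine(0, 1.0)], other)],
                ["a", "b"],
            )

    def test_midi_round_trip_preserves_per_track_counts(self, cfg, tmp_path, rng):
        parts = [
            build_score([spine(i, float(rng.uniform(0, 20))) for i in range(n)], cfg)
            for n in (5, 8, 11)
        ]
        ens = compose_ensemble(parts, ["a", "b", "c"])
        path = tmp_path / "ens.mid"
        render_midi(ens, path)
        notes = extract_notes(path)
        # track 0 is the tempo track; parts land on tracks 1..3
        counts = {t: sum(1 for n in notes if n.track == t) for t in (1, 2, 3)}
        assert counts == {1: len(parts[0].events), 2: len(parts[1].events), 3: len(parts[2].events)}
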