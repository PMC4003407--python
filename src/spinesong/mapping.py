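"""Feature-to-music mapping rules.

Morphological features of unrolled spines are translated to musical
attributes:

* position along the axis -> note onset (rhythm), via a constant scanning
  speed in μm/s (or "auto": total length / target duration);
* angular position -> pitch on a diatonic (C-major) scale, either
  unidirectional (pitch rises monotonically over 0-360°) or bidirectional
  (rises to 180°, then mirrors back, disambiguated by stereo side);
* volume -> dynamics (pp / mf / f / ff);
* length -> timbre (pizzicato / piano / trumpet / violin) when volume is
  also mapped, otherwise length -> dynamics with the same four-level rule.

All category intervals are left-closed right-open ([a, b)); the printed
threshold notations overlap at the exact boundaries, so one consistent
convention is adopted and documented.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from typing import Literal, Union

from pydantic import BaseModel, field_validator, model_validator

__all__ = [
    "Dynamic",
    "Instrument",
    "Channel",
    "MappingConfig",
    "MusicalAttributes",
    "volume_to_dynamics",
    "length_to_timbre",
    "length_to_dynamics",
    "angle_to_pitch_uni",
    "angle_to_pitch_bi",
    "onset_time",
    "auto_speed",
    "degree_to_midi",
    "midi_to_solfege",
]

logger = logging.getLogger(__name__)


class Dynamic(str, Enum):
    pp = "pp"
    mf = "mf"
    f = "f"
    ff = "ff"


class Instrument(str, Enum):
    pizzicato = "pizzicato"
    piano = "piano"
    trumpet = "trumpet"
    violin = "violin"


class Channel(str, Enum):
    left = "left"
    right = "right"
    both = "both"


#: ordering used by the monotonicity property of the categorical mappers
DYNAMIC_ORDER = [Dynamic.pp, Dynamic.mf, Dynamic.f, Dynamic.ff]
INSTRUMENT_ORDER = [Instrument.pizzicato, Instrument.piano, Instrument.trumpet, Instrument.violin]

#: C-major semitone offsets of the 7 scale degrees
_MAJOR = (0, 2, 4, 5, 7, 9, 11)
#: pitch realization of the 4-wedge variant: a major triad plus the octave
_FOUR = (0, 4, 7, 12)

_SOLFEGE = {0: "Do", 2: "Re", 4: "Mi", 5: "Fa", 7: "Sol", 9: "La", 11: "Ti"}
_SOLFEGE_SHARP = {1: "Do#", 3: "Re#", 6: "Fa#", 8: "Sol#", 10: "La#"}


class MappingConfig(BaseModel):
    """Every threshold, wedge count, speed and toggle of the mapping.

    Defaults follow the published categories: volume thresholds
    0.20/0.40/0.60 μm³, length thresholds 1/2/3 μm, 7 pitch wedges
    (one diatonic octave), auto scanning speed targeting a 60 s rendering,
    constant note duration.
    """

    volume_thresholds: tuple[float, float, float] = (0.20, 0.40, 0.60)
    length_thresholds: tuple[float, float, float] = (1.0, 2.0, 3.0)
    n_wedges: Literal[4, 7, 14] = 7
    n_intervals: int = 8
    direction_mode: Literal["unidirectional", "bidirectional"] = "unidirectional"
    enable_volume: bool = True
    enable_length: bool = False
    enable_angle: bool = True
    scan_speed: Union[float, Literal["auto"]] = "auto"
    target_duration: float = 60.0
    note_duration: float = 0.25
    scale_root: int = 60

    @field_validator("volume_thresholds", "length_thresholds")
    @classmethod
    def _ascending(cls, v):
        if not (v[0] < v[1] < v[2]):
            raise ValueError(f"thresholds must be strictly ascending, got {v}")
        return v

    @field_validator("n_intervals")
    @classmethod
    def _even(cls, v):
        if v < 2 or v % 2:
            raise ValueError(f"n_intervals must be a positive even integer, got {v}")
        return v

    @field_validator("note_duration", "target_duration")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("duration must be > 0")
        return v

    @model_validator(mode="after")
    def _speed_positive(self):
        if self.scan_speed != "auto" and self.scan_speed <= 0:
            raise ValueError(f"scan_speed must be > 0 or 'auto', got {self.scan_speed}")
        return self

    def resolve_speed(self, total_length: float | None) -> float:
        """Numeric scanning speed; auto mode needs the axis length."""
        if self.scan_speed != "auto":
            return float(self.scan_speed)
        if total_length is None:
            raise ValueError("auto scan_speed requires the total axis length")
        return auto_speed(total_length, self.target_duration)


class MusicalAttributes(BaseModel):
    """Abstract musical attributes of one spine, before MIDI realization."""

    spine_id: str
    onset: float
    dynamic: Dynamic = Dynamic.mf
    timbre: Instrument = Instrument.piano
    pitch_degree: int = 0
    midi_note: int = 60
    channel: Channel = Channel.both


def _bin4(x: float, thresholds, categories, what: str):
    if x < 0:
        raise ValueError(f"negative {what}: {x}")
    for thr, cat in zip(thresholds, categories):
        if x < thr:
            return cat
    return categories[3]


def volume_to_dynamics(v: float, cfg: MappingConfig | None = None) -> Dynamic:
    """Spine volume (μm³) to dynamic level; four bins, left-closed."""
    cfg = cfg or MappingConfig()
    return _bin4(v, cfg.volume_thresholds, DYNAMIC_ORDER, "volume")


def length_to_timbre(l: float, cfg: MappingConfig | None = None) -> Instrument:
    """Spine length (μm) to instrument; used when volume drives dynamics."""
    cfg = cfg or MappingConfig()
    return _bin4(l, cfg.length_thresholds, INSTRUMENT_ORDER, "length")


def length_to_dynamics(l: float, cfg: MappingConfig | None = None) -> Dynamic:
    """Spine length (μm) to dynamics; the volume rule applied to length,
    used when only the length feature is enabled."""
    cfg = cfg or MappingConfig()
    return _bin4(l, cfg.length_thresholds, DYNAMIC_ORDER, "length")


def _normalize_theta(theta: float) -> float:
    if not 0.0 <= theta < 360.0:
        logger.warning("theta %.6g outside [0, 360); normalizing modulo 360", theta)
        theta = theta % 360.0
    return theta


def angle_to_pitch_uni(theta: float, n_wedges: int) -> tuple[int, Channel]:
    """Unidirectional mapping: pitch rises monotonically over 0-360°.

    The circle is cut into ``n_wedges`` equal wedges; the scale degree is
    the wedge index, heard from both loudspeakers.
    """
    if n_wedges < 1:
        raise ValueError("n_wedges must be >= 1")
    theta = _normalize_theta(theta)
    degree = min(int(theta * n_wedges / 360.0), n_wedges - 1)
    return degree, Channel.both


def angle_to_pitch_bi(theta: float, n_intervals: int) -> tuple[int, Channel]:
    """Bidirectional mapping: pitch rises to 180° then mirrors back.

    The first ``n/2`` intervals ascend degrees 0..n/2-1 on the left channel;
    the last ``n/2`` intervals descend the same degrees on the right, so the
    peak degree is shared by the last ascending and first descending
    interval.  With 8 intervals of 45°, 15° is a Do from the left and 345°
    a Do from the right.
    """
    if n_intervals < 2 or n_intervals % 2:
        raise ValueError(f"n_intervals must be a positive even integer, got {n_intervals}")
    theta = _normalize_theta(theta)
    k = min(int(theta * n_intervals / 360.0), n_intervals - 1)
    half = n_intervals // 2
    if k < half:
        return k, Channel.left
    return n_intervals - 1 - k, Channel.right


def onset_time(s: float, scan_speed: float) -> float:
    """Note onset in seconds for a spine at arc position ``s`` (μm)."""
    if scan_speed <= 0:
        raise ValueError(f"scan_speed must be > 0, got {scan_speed}")
    return s / scan_speed


def auto_speed(total_length: float, target_duration: float) -> float:
    """Scanning speed (μm/s) so the sweep lasts ``target_duration`` seconds."""
    if total_length <= 0 or target_duration <= 0:
        raise ValueError("total_length and target_duration must be > 0")
    return total_length / target_duration


def degree_to_midi(degree: int, n_steps: int, root: int = 60) -> int:
    """Realize a diatonic scale degree as a MIDI note number.

    ``n_steps`` is the number of distinct degrees in play: 7 -> one C-major
    octave, 14 -> two octaves, 4 -> root/major third/fifth/octave.  Any
    other count walks the major scale from the root across octaves.
    """
    if not 0 <= degree < n_steps:
        raise ValueError(f"degree {degree} out of range for {n_steps} steps")
    if n_steps == 4:
        return root + _FOUR[degree]
    return root + _MAJOR[degree % 7] + 12 * (degree // 7)


def midi_to_solfege(note: int) -> str:
    """Solfège name with octave, e.g. 60 -> 'Do4' (middle C)."""
    pc = note % 12
    octave = note // 12 - 1
    name = _SOLFEGE.get(pc) or _SOLFEGE_SHARP[pc]
    return f"{name}{octave}"
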