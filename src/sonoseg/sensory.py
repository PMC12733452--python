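"""Perceptual back-ends: color maps, stereo sonification, and MIDI.

Region features from the anomaly stage are mapped onto musical structure:
musical scale by region character (high-intensity -> major, low-intensity ->
minor, large areas -> pentatonic, small/complex shapes -> blues, with
morphology taking precedence over size over intensity), dissonant intervals
by severity (tritone for high, minor seventh for moderate), constant-power
stereo panning from the region centroid column, and amplitude modulation
from the region's z-score.  Audio is additive synthesis (harmonics at 1/n
amplitude) rendered to 16-bit stereo WAV; the symbolic path emits a Standard
MIDI File (format 0).  Every render is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import struct
import wave
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .anomaly import AnomalyReport, RegionFeatures, SEVERITY_LEVELS

# ---------------------------------------------------------------------------
# Musical scaffolding
# ---------------------------------------------------------------------------

SCALE_PITCH_CLASSES = {
    "major": (0, 2, 4, 5, 7, 9, 11),
    "minor": (0, 2, 3, 5, 7, 8, 10),
    "pentatonic": (0, 2, 4, 7, 9),
    "blues": (0, 3, 5, 6, 7, 10),
}

DISSONANCE_INTERVALS = {"high": (0, 6), "moderate": (0, 10), "none": (0,)}

MIDI_PPQ = 480  # ticks per quarter note


@dataclass
class ScaleMapping:
    scale_name: str
    root_pitch: int
    pitch_classes: tuple

    def __post_init__(self):
        offs = self.pitch_classes
        if list(offs) != sorted(set(offs)) or min(offs) < 0 or max(offs) > 11:
            raise ValueError("pitch classes must be strictly increasing within [0, 11]")


@dataclass
class SonificationConfig:
    sample_rate: int = 44100
    duration_per_region: float = 2.0  # seconds; also the empty-render length
    base_pitch: int = 60  # C4
    tempo: float = 90.0  # BPM
    harmonic_count: int = 4
    intensity_high: float = 0.66
    intensity_low: float = 0.33
    area_large_frac: float = 0.02  # fraction of image pixels
    area_small_frac: float = 0.005
    complexity_high: float = 1.8
    small_complex_conjunction: bool = True  # blues needs small AND complex
    notes_per_phrase: int = 8  # melody length in the MIDI rendering
    velocity_floor: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.intensity_low < self.intensity_high:
            raise ValueError("require intensity_low < intensity_high")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class AudioBuffer:
    left: np.ndarray
    right: np.ndarray
    sample_rate: int

    def __post_init__(self):
        if self.left.shape != self.right.shape:
            raise ValueError("stereo channels must have equal length")

    @property
    def stereo(self) -> np.ndarray:
        return np.stack([self.left, self.right], axis=1)


@dataclass
class NoteEvent:
    onset_beats: float
    duration_beats: float
    pitch: int
    velocity: int
    channel: int = 0


@dataclass
class MidiSequence:
    notes: list
    tempo: float = 90.0
    program: int = 0

    def __post_init__(self):
        onsets = [n.onset_beats for n in self.notes]
        if any(b > a for a, b in zip(onsets[1:], onsets)):
            raise ValueError("note onsets must be non-decreasing")
        for n in self.notes:
            if not 0 <= n.pitch <= 127:
                raise ValueError(f"pitch {n.pitch} outside [0, 127]")
            if not 1 <= n.velocity <= 127:
                raise ValueError(f"velocity {n.velocity} outside [1, 127]")


# ---------------------------------------------------------------------------
# Color rendering
# ---------------------------------------------------------------------------


def render_colormap(grid: np.ndarray, colormap: np.ndarray) -> np.ndarray:
    """Min-max normalize a scalar grid and interpolate into an RGB table.

    The colormap is an ordered (n >= 2, 3) table of 8-bit RGB rows; the grid
    minimum maps exactly to the first row and the maximum to the last.  A
    constant grid maps everywhere to the first row.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if not np.isfinite(grid).all():
        raise ValueError("grid must be finite")
    cmap = np.asarray(colormap, dtype=np.float64)
    if cmap.ndim != 2 or cmap.shape[0] < 2 or cmap.shape[1] != 3:
        raise ValueError("colormap needs at least 2 RGB entries")
    lo, hi = grid.min(), grid.max()
    norm = np.zeros_like(grid) if hi == lo else (grid - lo) / (hi - lo)
    pos = norm * (cmap.shape[0] - 1)
    i0 = np.clip(np.floor(pos).astype(int), 0, cmap.shape[0] - 2)
    frac = (pos - i0)[..., None]
    rgb = cmap[i0] * (1.0 - frac) + cmap[i0 + 1] * frac
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def render_overlay(
    image: np.ndarray, probability: np.ndarray, colormap: np.ndarray, alpha: float = 0.6
) -> np.ndarray:
    """Blend a colormapped probability grid over the grayscale base.

    The per-pixel blend weight is alpha * p, so zero-probability pixels show
    the unmodified base image.
    """
    prob = np.asarray(probability, dtype=np.float64)
    gray = image.mean(axis=-1) if image.ndim == 3 else np.asarray(image, dtype=np.float64)
    if prob.shape != gray.shape:
        raise ValueError(f"shape mismatch: image {gray.shape} vs probability {prob.shape}")
    base = np.repeat(np.clip(gray * 255.0, 0, 255)[..., None], 3, axis=-1)
    cmap = np.asarray(colormap, dtype=np.float64)
    colored = cmap[np.clip(np.rint(prob * (cmap.shape[0] - 1)).astype(int), 0, cmap.shape[0] - 1)]
    w = (alpha * prob)[..., None]
    return np.clip(np.rint(base * (1.0 - w) + colored * w), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Feature -> music mappings
# ---------------------------------------------------------------------------


def region_to_musical_scale(
    region: RegionFeatures, config: SonificationConfig, total_pixels: int
) -> ScaleMapping:
    """Decision ladder: small-and-complex -> blues; large -> pentatonic;
    bright -> major; dark -> minor; otherwise major.

    Morphology outranks size outranks intensity: shape anomalies are the
    rarest, most diagnostic cue, so they must not be masked by the others.
    """
    area_frac = region.area / float(total_pixels)
    small = area_frac < config.area_small_frac
    complex_ = region.complexity >= config.complexity_high
    blues_gate = (small and complex_) if config.small_complex_conjunction else (small or complex_)
    if blues_gate:
        name = "blues"
    elif area_frac >= config.area_large_frac:
        name = "pentatonic"
    elif region.mean_intensity >= config.intensity_high:
        name = "major"
    elif region.mean_intensity <= config.intensity_low:
        name = "minor"
    else:
        name = "major"
    return ScaleMapping(name, config.base_pitch, SCALE_PITCH_CLASSES[name])


def anomaly_to_dissonance(severity: str, base_pitch: int) -> tuple:
    """Severity -> simultaneous pitch set: high = tritone dyad (+6 st),
    moderate = minor-seventh dyad (+10 st), none = the bare base pitch."""
    if severity not in SEVERITY_LEVELS:
        raise ValueError(f"unknown severity {severity!r}; expected one of {SEVERITY_LEVELS}")
    return tuple(base_pitch + iv for iv in DISSONANCE_INTERVALS[severity])


def _scale_pitch(mapping: ScaleMapping, degree: int) -> int:
    """Degree -> MIDI pitch across octaves, staying inside the scale."""
    n = len(mapping.pitch_classes)
    octave, idx = divmod(int(degree), n)
    return int(np.clip(mapping.root_pitch + 12 * octave + mapping.pitch_classes[idx], 0, 127))


def _melody_degrees(region: RegionFeatures, mapping: ScaleMapping, n_notes: int,
                    rng: np.random.Generator) -> list:
    """Intensity-ordered walk over scale degrees: brighter regions start
    higher; steps of +-1/+-2 degrees, reflected into a two-octave compass."""
    n = len(mapping.pitch_classes)
    top = 2 * n - 1
    start = int(round(np.clip(region.mean_intensity, 0.0, 1.0) * top))
    degrees = [start]
    for _ in range(n_notes - 1):
        step = int(rng.choice([-2, -1, 1, 2]))
        nxt = degrees[-1] + step
        if nxt < 0 or nxt > top:
            nxt = degrees[-1] - step
        degrees.append(int(np.clip(nxt, 0, top)))
    return degrees


def _quantize_duration(area_frac: float) -> float:
    """Region area -> note value in beats, quantized to {1/4, 1/2, 1, 2}."""
    if area_frac < 0.005:
        return 0.25
    if area_frac < 0.02:
        return 0.5
    if area_frac < 0.05:
        return 1.0
    return 2.0


def _velocity(region: RegionFeatures, config: SonificationConfig) -> int:
    v = config.velocity_floor + region.mean_intensity * (127 - config.velocity_floor)
    return int(np.clip(round(v), 1, 127))


# ---------------------------------------------------------------------------
# Stereo sonification
# ---------------------------------------------------------------------------


def _tone(freq: float, duration: float, sr: int, harmonics: int) -> np.ndarray:
    """Additive tone with `harmonics` partials at 1/n amplitude and a 10 ms
    raised-cosine attack/release."""
    t = np.arange(int(round(duration * sr))) / sr
    wavef = np.zeros_like(t)
    for h in range(1, harmonics + 1):
        wavef += np.sin(2 * np.pi * freq * h * t) / h
    edge = max(1, int(0.01 * sr))
    if len(wavef) >= 2 * edge:
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, edge)))
        wavef[:edge] *= ramp
        wavef[-edge:] *= ramp[::-1]
    return wavef


def _pitch_to_freq(pitch: int) -> float:
    return 440.0 * 2.0 ** ((pitch - 69) / 12.0)


def create_advanced_brain_sonification(
    image: np.ndarray,
    mask: np.ndarray,
    report: AnomalyReport,
    config: SonificationConfig,
) -> AudioBuffer:
    """Render the anomaly report as stereo audio.

    Regions are voiced in descending-area order, one time slot each.  Melody
    notes come from the region's scale mapping; note density grows with the
    region count (denser pathology, denser rhythm); severity mixes in its
    dissonance dyad during the final beat of the slot; constant-power panning
    follows the centroid column (column 0 hard left); the voice amplitude is
    modulated by the region's mean z-score.  Output is peak-normalized to
    0.9 and bit-reproducible for a fixed config seed.
    """
    sr = config.sample_rate
    regions = report.regions
    n_regions = len(regions)
    slot = config.duration_per_region
    total = max(1, n_regions) * slot
    n_samples = int(round(total * sr))
    left = np.zeros(n_samples)
    right = np.zeros(n_samples)
    if n_regions == 0:
        return AudioBuffer(left, right, sr)

    width = report.image_shape[1]
    total_pixels = int(np.prod(report.image_shape))
    for ridx, region in enumerate(regions):
        rng = np.random.default_rng((config.seed, ridx))
        mapping = region_to_musical_scale(region, config, total_pixels)
        n_notes = max(2, int(round(slot * (config.tempo / 60.0) * n_regions)))
        degrees = _melody_degrees(region, mapping, n_notes, rng)
        note_len = slot / n_notes
        theta = (region.centroid[1] / max(width - 1, 1)) * (np.pi / 2.0)
        gain_l, gain_r = np.cos(theta), np.sin(theta)
        amp = 0.4 + 0.6 * float(np.clip(region.mean_zscore / report.z_high, 0.0, 1.0))
        start = int(round(ridx * slot * sr))
        voice = np.zeros(int(round(slot * sr)))
        for i, deg in enumerate(degrees):
            tone = amp * _tone(
                _pitch_to_freq(_scale_pitch(mapping, deg)), note_len, sr, config.harmonic_count
            )
            s = int(round(i * note_len * sr))
            voice[s : s + len(tone)] += tone[: max(0, len(voice) - s)]
        dyad = anomaly_to_dissonance(region.severity, mapping.root_pitch)
        if len(dyad) > 1:
            beat = 60.0 / config.tempo
            dlen = min(beat, slot)
            dstart = len(voice) - int(round(dlen * sr))
            for p in dyad:
                tone = 0.5 * amp * _tone(_pitch_to_freq(p), dlen, sr, config.harmonic_count)
                voice[dstart : dstart + len(tone)] += tone
        left[start : start + len(voice)] += gain_l * voice
        right[start : start + len(voice)] += gain_r * voice

    peak = max(np.abs(left).max(), np.abs(right).max())
    if peak > 0:
        left *= 0.9 / peak
        right *= 0.9 / peak
    return AudioBuffer(left, right, sr)


def write_wav(buffer: AudioBuffer, path) -> None:
    """Write 16-bit PCM stereo RIFF WAV."""
    samples = np.clip(buffer.stereo, -1.0, 1.0)
    pcm = np.rint(samples * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(2)
        fh.setsampwidth(2)
        fh.setframerate(buffer.sample_rate)
        fh.writeframes(pcm.tobytes())


# ---------------------------------------------------------------------------
# MIDI
# ---------------------------------------------------------------------------


def create_advanced_midi_from_brain(report: AnomalyReport, config: SonificationConfig) -> MidiSequence:
    """Translate the anomaly report into a symbolic note sequence.

    One phrase per region (descending area): a melodic walk over the
    region's scale with note duration quantized from area and velocity an
    affine map of mean intensity into [velocity_floor, 127]; the severity
    dissonance dyad is appended as simultaneous notes closing the phrase.
    """
    total_pixels = int(np.prod(report.image_shape))
    notes = []
    clock = 0.0
    for ridx, region in enumerate(report.regions):
        rng = np.random.default_rng((config.seed, ridx))
        mapping = region_to_musical_scale(region, config, total_pixels)
        degrees = _melody_degrees(region, mapping, config.notes_per_phrase, rng)
        dur = _quantize_duration(region.area / float(total_pixels))
        vel = _velocity(region, config)
        for deg in degrees:
            notes.append(NoteEvent(clock, dur, _scale_pitch(mapping, deg), vel))
            clock += dur
        dyad = anomaly_to_dissonance(region.severity, mapping.root_pitch)
        if len(dyad) > 1:
            for p in dyad:
                notes.append(NoteEvent(clock, 1.0, int(p), 100))
            clock += 1.0
    return MidiSequence(notes=notes, tempo=config.tempo)


def _varlen(value: int) -> bytes:
    """MIDI variable-length quantity."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def midi_bytes(seq: MidiSequence) -> bytes:
    """Serialize as a Standard MIDI File, format 0, one track."""
    events = []  # (tick, order, message)
    tempo_us = int(round(60_000_000 / seq.tempo))
    events.append((0, 0, b"\xff\x51\x03" + tempo_us.to_bytes(3, "big")))
    events.append((0, 1, bytes([0xC0, seq.program & 0x7F])))
    for n in seq.notes:
        on = int(round(n.onset_beats * MIDI_PPQ))
        off = int(round((n.onset_beats + n.duration_beats) * MIDI_PPQ))
        events.append((on, 2, bytes([0x90 | n.channel, n.pitch, n.velocity])))
        events.append((off, 1, bytes([0x80 | n.channel, n.pitch, 64])))
    events.sort(key=lambda e: (e[0], e[1]))
    track = bytearray()
    tick = 0
    for t, _, msg in events:
        track += _varlen(t - tick) + msg
        tick = t
    track += _varlen(0) + b"\xff\x2f\x00"
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, MIDI_PPQ)
    return header + b"MTrk" + struct.pack(">I", len(track)) + bytes(track)


def write_midi(seq: MidiSequence, path) -> None:
    Path(path).write_bytes(midi_bytes(seq))


# ---------------------------------------------------------------------------
# Spectrogram (QC rendering)
# ---------------------------------------------------------------------------


def compute_spectrogram(buffer: AudioBuffer, window: int = 1024, hop: int = 256):
    """Hann-windowed short-time Fourier magnitudes of the channel mean.

    Returns (freqs_hz, times_s, magnitude) with magnitude shaped
    (n_freq_bins, n_frames).  Used for documentation/QC imagery.
    """
    from scipy.signal import get_window

    mono = 0.5 * (buffer.left + buffer.right)
    if len(mono) < window:
        mono = np.pad(mono, (0, window - len(mono)))
    win = get_window("hann", window, fftbins=True)
    n_frames = 1 + (len(mono) - window) // hop
    frames = np.stack([mono[i * hop : i * hop + window] * win for i in range(n_frames)])
    mag = np.abs(np.fft.rfft(frames, axis=1)).T
    freqs = np.fft.rfftfreq(window, d=1.0 / buffer.sample_rate)
    times = (np.arange(n_frames) * hop + window / 2) / buffer.sample_rate
    return freqs, times, mag
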