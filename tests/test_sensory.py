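import struct

import numpy as np
import pytest
from scipy.io import wavfile

from sonoseg.anomaly import AnomalyReport, RegionFeatures, analyze
from sonoseg.phantom import PhantomParams, generate_phantom
from sonoseg.sensory import (
    SCALE_PITCH_CLASSES,
    AudioBuffer,
    SonificationConfig,
    anomaly_to_dissonance,
    compute_spectrogram,
    create_advanced_brain_sonification,
    create_advanced_midi_from_brain,
    midi_bytes,
    region_to_musical_scale,
    render_colormap,
    render_overlay,
    write_midi,
    write_wav,
)

# ---------------------------------------------------------------------------
# Independent Standard-MIDI-File reader (separate code path from the writer)
# ---------------------------------------------------------------------------


def parse_smf(data: bytes):
    """Minimal SMF parser: returns (division, notes) where each note is a
    dict with tick/pitch/velocity for every note-on with velocity > 0."""
    assert data[:4] == b"MThd"
    hlen, fmt, ntrk, division = struct.unpack(">IHHH", data[4:14])
    assert hlen == 6 and fmt == 0 and ntrk == 1
    pos = 14
    assert data[pos : pos + 4] == b"MTrk"
    tlen = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
    pos += 8
    end = pos + tlen
    tick = 0
    notes = []
    running = None
    while pos < end:
        delta = 0
        while True:
            byte = data[pos]
            pos += 1
            delta = (delta << 7) | (byte & 0x7F)
            if not byte & 0x80:
                break
        tick += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            running = status
        else:
            status = running
        kind = status & 0xF0
        if status == 0xFF:  # meta
            meta_type = data[pos]
            pos += 1
            length = data[pos]
            pos += 1
            pos += length
            if meta_type == 0x2F:
                break
        elif kind in (0x80, 0x90):
            pitch, vel = data[pos], data[pos + 1]
            pos += 2
            if kind == 0x90 and vel > 0:
                notes.append({"tick": tick, "pitch": pitch, "velocity": vel})
        elif kind in (0xC0, 0xD0):
            pos += 1
        else:
            pos += 2
    return division, notes


def _region(area=60, centroid=(32.0, 32.0), mean_intensity=0.5, complexity=1.2,
            mean_z=2.0, max_z=2.5, severity="moderate", rid=1):
    return RegionFeatures(rid, area, centroid, mean_intensity, mean_intensity + 0.1,
                         40.0, complexity, mean_z, max_z, severity)


def _report(regions, shape=(64, 64)):
    return AnomalyReport(regions=regions, reference_mean=0.4, reference_sd=0.05,
                         image_shape=shape)


# ---------------------------------------------------------------------------
# Color rendering
# ---------------------------------------------------------------------------


class TestColormap:
    CMAP = np.array([[0, 0, 0], [255, 255, 255]], dtype=np.uint8)

    def test_endpoints_map_exactly(self):
        grid = np.array([[0.2, 0.9], [0.5, 0.4]])
        rgb = render_colormap(grid, self.CMAP)
        np.testing.assert_array_equal(rgb[0, 0], [0, 0, 0])
        np.testing.assert_array_equal(rgb[0, 1], [255, 255, 255])

    def test_midpoint_is_mid_gray(self):
        grid = np.array([[0.0, 0.5, 1.0]])
        rgb = render_colormap(grid, self.CMAP)
        assert np.all(np.abs(rgb[0, 1].astype(int) - 128) <= 1)

    def test_constant_grid_maps_to_first_color(self):
        rgb = render_colormap(np.full((4, 4), 3.7), self.CMAP)
        np.testing.assert_array_equal(rgb, np.zeros((4, 4, 3), np.uint8))

    def test_short_colormap_rejected(self):
        with pytest.raises(ValueError):
            render_colormap(np.zeros((2, 2)), np.array([[0, 0, 0]]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            render_colormap(np.array([[np.nan]]), self.CMAP)


class TestOverlay:
    CMAP = np.array([[0, 0, 0], [255, 0, 0]], dtype=np.uint8)

    def test_zero_probability_shows_base(self):
        image = np.random.default_rng(0).random((8, 8)).astype(np.float32)
        out = render_overlay(image, np.zeros((8, 8)), self.CMAP)
        expected = np.repeat(np.rint(image * 255)[..., None], 3, axis=-1)
        np.testing.assert_array_equal(out, expected.astype(np.uint8))

    def test_full_probability_full_alpha_shows_colormap_max(self):
        image = np.full((4, 4), 0.5, np.float32)
        out = render_overlay(image, np.ones((4, 4)), self.CMAP, alpha=1.0)
        np.testing.assert_array_equal(out, np.broadcast_to([255, 0, 0], (4, 4, 3)))

    def test_half_alpha_blends_mean(self):
        image = np.zeros((2, 2), np.float32)
        out = render_overlay(image, np.ones((2, 2)), self.CMAP, alpha=0.5)
        np.testing.assert_array_equal(out, np.broadcast_to([128, 0, 0], (2, 2, 3)))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            render_overlay(np.zeros((4, 4)), np.zeros((5, 5)), self.CMAP)


# ---------------------------------------------------------------------------
# Scale and dissonance mappings
# ---------------------------------------------------------------------------


class TestScaleMapping:
    CFG = SonificationConfig()

    def map(self, region):
        return region_to_musical_scale(region, self.CFG, total_pixels=64 * 64)

    def test_bright_region_major(self):
        assert self.map(_region(mean_intensity=0.8)).scale_name == "major"

    def test_dark_region_minor(self):
        assert self.map(_region(mean_intensity=0.2)).scale_name == "minor"

    def test_large_area_pentatonic_regardless_of_intensity(self):
        big = _region(area=int(0.05 * 64 * 64), mean_intensity=0.9)
        assert self.map(big).scale_name == "pentatonic"

    def test_small_complex_blues_has_top_precedence(self):
        tiny_jagged = _region(area=10, complexity=2.5, mean_intensity=0.9)
        assert self.map(tiny_jagged).scale_name == "blues"

    def test_small_but_round_is_not_blues(self):
        tiny_round = _region(area=10, complexity=1.1, mean_intensity=0.8)
        assert self.map(tiny_round).scale_name == "major"

    def test_pitch_class_tables(self):
        assert SCALE_PITCH_CLASSES["major"] == (0, 2, 4, 5, 7, 9, 11)
        assert SCALE_PITCH_CLASSES["blues"] == (0, 3, 5, 6, 7, 10)


class TestDissonance:
    def test_high_is_tritone(self):
        assert anomaly_to_dissonance("high", 60) == (60, 66)

    def test_moderate_is_minor_seventh(self):
        assert anomaly_to_dissonance("moderate", 60) == (60, 70)

    def test_none_is_bare_pitch(self):
        assert anomaly_to_dissonance("none", 60) == (60,)

    def test_unknown_severity_raises(self):
        with pytest.raises(ValueError, match="unknown severity"):
            anomaly_to_dissonance("catastrophic", 60)


# ---------------------------------------------------------------------------
# Audio synthesis
# ---------------------------------------------------------------------------


def _phantom_report(seed=3, center=(32.0, 16.0)):
    pair = generate_phantom(
        PhantomParams(image_size=64, tumor_center=center, tumor_radius=8.0, seed=seed)
    )
    return pair, analyze(pair.image, pair.mask)


class TestSonification:
    CFG = SonificationConfig(seed=11)

    def test_empty_report_renders_exact_silence(self):
        buf = create_advanced_brain_sonification(
            np.zeros((64, 64)), np.zeros((64, 64)), _report([]), self.CFG
        )
        assert len(buf.left) == int(self.CFG.duration_per_region * self.CFG.sample_rate)
        assert np.all(buf.left == 0) and np.all(buf.right == 0)

    def test_left_region_louder_on_left_channel(self):
        pair, report = _phantom_report(center=(32.0, 12.0))
        buf = create_advanced_brain_sonification(pair.image, pair.mask, report, self.CFG)
        rms_l = np.sqrt(np.mean(buf.left**2))
        rms_r = np.sqrt(np.mean(buf.right**2))
        assert rms_l > rms_r

    def test_mirroring_swaps_channel_rms(self):
        pair, report = _phantom_report(center=(32.0, 12.0))
        buf = create_advanced_brain_sonification(pair.image, pair.mask, report, self.CFG)
        mirrored = analyze(pair.image[:, ::-1], pair.mask[:, ::-1])
        buf_m = create_advanced_brain_sonification(
            pair.image[:, ::-1], pair.mask[:, ::-1], mirrored, self.CFG
        )
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert rms(buf.left) == pytest.approx(rms(buf_m.right), rel=1e-6)
        assert rms(buf.right) == pytest.approx(rms(buf_m.left), rel=1e-6)

    def test_no_clipping_and_peak_normalized(self):
        pair, report = _phantom_report()
        buf = create_advanced_brain_sonification(pair.image, pair.mask, report, self.CFG)
        peak = max(np.abs(buf.left).max(), np.abs(buf.right).max())
        assert peak == pytest.approx(0.9, abs=1e-9)

    def test_bit_identical_under_fixed_seed(self):
        pair, report = _phantom_report()
        a = create_advanced_brain_sonification(pair.image, pair.mask, report, self.CFG)
        b = create_advanced_brain_sonification(pair.image, pair.mask, report, self.CFG)
        np.testing.assert_array_equal(a.stereo, b.stereo)

    def test_wav_round_trip(self, tmp_path):
        pair, report = _phantom_report()
        buf = create_advanced_brain_sonification(pair.image, pair.mask, report, self.CFG)
        path = tmp_path / "s.wav"
        write_wav(buf, path)
        rate, data = wavfile.read(path)
        assert rate == self.CFG.sample_rate
        expected = np.rint(np.clip(buf.stereo, -1, 1) * 32767).astype(np.int16)
        np.testing.assert_array_equal(data, expected)

    def test_unequal_channels_rejected(self):
        with pytest.raises(ValueError):
            AudioBuffer(np.zeros(10), np.zeros(11), 44100)


# ---------------------------------------------------------------------------
# MIDI
# ---------------------------------------------------------------------------


class TestMidi:
    CFG = SonificationConfig(seed=2)

    def test_melodic_pitches_stay_in_scale_across_reports(self):
        checked = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            region = _region(
                area=int(rng.integers(8, 400)),
                mean_intensity=float(rng.random()),
                complexity=float(rng.uniform(1.0, 3.0)),
                severity="none",  # no dyad: every note is melodic
            )
            report = _report([region])
            seq = create_advanced_midi_from_brain(report, SonificationConfig(seed=seed))
            mapping = region_to_musical_scale(region, self.CFG, 64 * 64)
            for note in seq.notes:
                assert (note.pitch - mapping.root_pitch) % 12 in mapping.pitch_classes
                checked += 1
        assert checked >= 50

    def test_velocity_monotone_in_intensity(self):
        bright = _region(mean_intensity=0.9, rid=1)
        dim = _region(mean_intensity=0.3, rid=2)
        seq = create_advanced_midi_from_brain(_report([bright, dim]), self.CFG)
        velocities = {}
        for n in seq.notes:
            velocities.setdefault(n.velocity, 0)
        vels = sorted({n.velocity for n in seq.notes if n.velocity != 100})
        assert len(vels) == 2 and vels[1] > vels[0]

    def test_high_severity_emits_simultaneous_tritone(self):
        seq = create_advanced_midi_from_brain(_report([_region(severity="high")]), self.CFG)
        dyads = _simultaneous_intervals(seq)
        assert 6 in dyads

    def test_moderate_only_has_no_tritone(self):
        seq = create_advanced_midi_from_brain(_report([_region(severity="moderate")]), self.CFG)
        dyads = _simultaneous_intervals(seq)
        assert 10 in dyads and 6 not in dyads

    def test_empty_report_parses_with_zero_notes(self):
        seq = create_advanced_midi_from_brain(_report([]), self.CFG)
        division, notes = parse_smf(midi_bytes(seq))
        assert division == 480 and notes == []

    def test_event_count_round_trips_through_independent_parser(self, tmp_path):
        _, report = _phantom_report()
        seq = create_advanced_midi_from_brain(report, self.CFG)
        path = tmp_path / "s.mid"
        write_midi(seq, path)
        _, notes = parse_smf(path.read_bytes())
        assert len(notes) == len(seq.notes) > 0

    def test_velocity_bounds_enforced(self):
        from sonoseg.sensory import MidiSequence, NoteEvent

        with pytest.raises(ValueError, match="velocity"):
            MidiSequence([NoteEvent(0.0, 1.0, 60, 0)])


def _simultaneous_intervals(seq):
    by_onset = {}
    for n in seq.notes:
        by_onset.setdefault(n.onset_beats, []).append(n.pitch)
    out = set()
    for pitches in by_onset.values():
        for i, a in enumerate(pitches):
            for b in pitches[i + 1 :]:
                out.add(abs(a - b))
    return out


# ---------------------------------------------------------------------------
# Spectrogram
# ---------------------------------------------------------------------------


class TestSpectrogram:
    def test_pure_tone_peaks_at_its_frequency(self):
        sr = 44100
        t = np.arange(sr) / sr
        tone = np.sin(2 * np.pi * 440.0 * t)
        buf = AudioBuffer(tone, tone, sr)
        freqs, _, mag = compute_spectrogram(buf, window=2048, hop=512)
        peak = freqs[mag.mean(axis=1).argmax()]
        assert abs(peak - 440.0) <= freqs[1] - freqs[0]

    def test_silence_gives_zero_magnitudes(self):
        buf = AudioBuffer(np.zeros(8000), np.zeros(8000), 8000)
        _, _, mag = compute_spectrogram(buf, window=1024, hop=256)
        assert np.all(mag == 0)

    def test_parseval_identity_per_frame(self):
        from scipy.signal import get_window

        rng = np.random.default_rng(0)
        sig = rng.standard_normal(4096)
        buf = AudioBuffer(sig, sig, 8000)
        window, hop = 1024, 256
        freqs, _, mag = compute_spectrogram(buf, window=window, hop=hop)
        win = get_window("hann", window, fftbins=True)
        mono = sig  # channel mean of identical channels
        for frame in range(mag.shape[1]):
            xw = mono[frame * hop : frame * hop + window] * win
            spec = mag[:, frame] ** 2
            # one-sided spectrum: double the interior bins
            total = spec[0] + spec[-1] + 2 * spec[1:-1].sum()
            assert total == pytest.approx(window * (xw**2).sum(), rel=1e-2)
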