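"""Synthetic nights: hypnogram, stage-conditioned audio and ground truth.

The generator embodies the physiological regularities the staging method
relies on:

* sleep architecture — an initial wake bout, then alternating NREM/REM
  cycles of ~95 min with brief awakenings and an optional terminal wake bout;
* NREM — slow, regular breathing (periodic inhale/exhale bursts, low
  inter-breath variability), occasional body movements;
* REM — slightly faster breathing with markedly higher rate variability and
  *no* body movements (REM atonia);
* wake — sparse, faint breathing sounds and frequent movement bursts;
* everywhere — stationary background noise plus sparse loud transients
  (door slams, barks) that belong to the "other" event class.

Breath bursts are amplitude-modulated band-limited noise (inhale 300–2000 Hz,
exhale 200–1000 Hz, movement 100–8000 Hz): spectrally separable yet
overlapping, so event detection is learnable but not trivial. One night-level
seed drives everything through deterministic per-epoch substreams, so a night
is bit-reproducible whether it is materialized at once or streamed epoch by
epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.fft

from .audio_io import (
    EPOCH_SAMPLES,
    EPOCH_SECONDS,
    FRAME_SAMPLES,
    FRAMES_PER_EPOCH,
    SAMPLE_RATE,
    AudioStream,
    EpochAudio,
    write_wav,
)
from .detection import FrameLabel
from .features import SubjectMeta


@dataclass
class SimConfig:
    """Study conditions of a simulated night (all rates/levels configurable).

    Breathing rates: NREM 14 breaths/min with small within-epoch spread,
    REM 16 breaths/min with a four-fold larger spread (faster, more variable
    REM breathing); wake breathes too, but most breaths are inaudible at the
    microphone. Movement events/epoch: frequent in wake, rare in NREM, absent
    in REM. Intensities are dBFS; breath bursts sit 15 dB above the
    stationary noise floor, movements 25 dB, transients 30 dB.
    """

    seed: int = 0
    night_epochs: int = 840                     # 7 h

    wake_latency_mean_min: float = 15.0
    wake_latency_sd_min: float = 5.0
    wake_latency_min_min: float = 3.0
    terminal_wake_mean_min: float = 5.0
    terminal_wake_sd_min: float = 2.0

    cycle_period_mean_min: float = 95.0
    cycle_period_sd_min: float = 10.0
    rem_duration_mean_min: float = 18.0
    rem_duration_sd_min: float = 5.0
    rem_duration_min_min: float = 2.5
    first_cycle_rem_skip_prob: float = 0.25     # delayed first REM (first-night-like)
    awakenings_per_cycle: float = 0.7
    awakening_duration_mean_min: float = 1.5

    nrem_breath_rate: float = 14.0              # breaths/min
    nrem_breath_rate_sd: float = 0.5            # within-epoch spread
    rem_breath_rate: float = 16.0
    rem_breath_rate_sd: float = 2.0
    wake_breath_rate: float = 13.0
    wake_breath_audible_prob: float = 0.15
    inhale_duration_s: float = 1.0
    exhale_duration_s: float = 1.2
    breath_pause_s: float = 0.15

    movement_rate_wake: float = 2.5             # events/epoch
    movement_rate_nrem: float = 0.15
    movement_rate_rem: float = 0.0
    movement_duration_range_s: tuple = (0.5, 2.0)

    noise_rms_dbfs: float = -45.0
    breath_snr_db: float = 15.0
    wake_breath_snr_db: float = 7.0
    movement_snr_db: float = 25.0
    transient_snr_db: float = 30.0
    transient_rate_per_epoch: float = 0.05
    transient_duration_range_s: tuple = (0.1, 0.4)

    inhale_band_hz: tuple = (300.0, 2000.0)
    exhale_band_hz: tuple = (200.0, 1000.0)
    movement_band_hz: tuple = (100.0, 8000.0)
    transient_band_hz: tuple = (300.0, 6000.0)

    age_range: tuple = (20, 75)
    bmi_range: tuple = (20.0, 40.0)

    def __post_init__(self) -> None:
        if self.night_epochs < 20:
            raise ValueError("night_epochs must be >= 20")
        for name in ("nrem_breath_rate", "rem_breath_rate", "wake_breath_rate",
                     "movement_rate_wake", "movement_rate_nrem",
                     "movement_rate_rem", "transient_rate_per_epoch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimulatedNight:
    """Ground-truth container: audio + hypnogram + frame labels + metadata."""

    audio: AudioStream
    hypnogram: np.ndarray            # (T,) of {W,R,N}
    frame_labels: np.ndarray         # (600·T,) FrameLabel ints
    meta: SubjectMeta
    config: SimConfig = field(repr=False, default=None)


def _epoch_rngs(config: SimConfig):
    """Deterministic substreams: child 0 → hypnogram, 1 → meta, 2+t → epoch t."""
    return np.random.SeedSequence(config.seed)


def simulate_hypnogram(config: SimConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Semi-Markov hypnogram: wake latency, NREM/REM cycling, awakenings.

    Brief awakenings replace NREM epochs in place, so consecutive REM-onset
    intervals keep the configured cycle-period distribution.
    """
    if rng is None:
        rng = np.random.default_rng(_epoch_rngs(config).spawn(2)[0])
    ep = lambda minutes: int(round(minutes / 0.5))
    latency = max(config.wake_latency_min_min,
                  rng.normal(config.wake_latency_mean_min,
                             config.wake_latency_sd_min))
    seq: list[str] = ["W"] * ep(latency)
    first_cycle = True
    while len(seq) < config.night_epochs:
        period = max(60.0, rng.normal(config.cycle_period_mean_min,
                                      config.cycle_period_sd_min))
        rem = max(config.rem_duration_min_min,
                  rng.normal(config.rem_duration_mean_min,
                             config.rem_duration_sd_min))
        skip_rem = first_cycle and rng.random() < config.first_cycle_rem_skip_prob
        nrem = max(10.0, period - rem)
        block = ["N"] * ep(nrem)
        for _ in range(rng.poisson(config.awakenings_per_cycle)):
            dur = max(1, ep(rng.exponential(config.awakening_duration_mean_min)))
            if len(block) > dur + 4:
                pos = int(rng.integers(2, len(block) - dur - 1))
                block[pos:pos + dur] = ["W"] * dur
        seq.extend(block)
        if not skip_rem:
            seq.extend(["R"] * ep(rem))
        first_cycle = False
    seq = seq[: config.night_epochs]
    terminal = max(0, ep(rng.normal(config.terminal_wake_mean_min,
                                    config.terminal_wake_sd_min)))
    if terminal:
        seq[-terminal:] = ["W"] * min(terminal, len(seq))
    return np.asarray(seq, dtype="<U1")


def _band_noise(rng: np.random.Generator, n: int, band: tuple) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise, synthesized spectrally.

    Complex-Gaussian coefficients are drawn only inside the band and inverse
    transformed at an FFT-friendly length, then truncated to n samples.
    """
    nfft = scipy.fft.next_fast_len(n)
    lo = int(band[0] * nfft / SAMPLE_RATE)
    hi = min(int(band[1] * nfft / SAMPLE_RATE), nfft // 2)
    spec = np.zeros(nfft // 2 + 1, dtype=np.complex64)
    width = max(hi - lo, 1)
    spec[lo:lo + width] = (rng.standard_normal(width, dtype=np.float32)
                           + 1j * rng.standard_normal(width, dtype=np.float32))
    x = scipy.fft.irfft(spec, n=nfft).astype(np.float32)[:n]
    rms = np.sqrt(np.mean(x ** 2)) + 1e-12
    return x / rms


_ENV_TABLE = np.hanning(8192).astype(np.float32)
_ENV_GRID = np.linspace(0.0, 1.0, 8192).astype(np.float32)


def _envelope(n: int) -> np.ndarray:
    """Hann-shaped amplitude envelope (table lookup for speed)."""
    return np.interp(np.linspace(0.0, 1.0, n, dtype=np.float32),
                     _ENV_GRID, _ENV_TABLE).astype(np.float32)


def _add_burst(samples: np.ndarray, events: list,
               rng: np.random.Generator, start_s: float, dur_s: float,
               band: tuple, rms_dbfs: float, label: int | None) -> None:
    start = int(start_s * SAMPLE_RATE)
    n = int(dur_s * SAMPLE_RATE)
    if start >= samples.size or n < 32:
        return
    n = min(n, samples.size - start)
    burst = _band_noise(rng, n, band) * _envelope(n)
    target = 10.0 ** (rms_dbfs / 20.0)
    burst *= target / (np.sqrt(np.mean(burst ** 2)) + 1e-12)
    samples[start:start + n] += burst
    if label is not None:
        events.append((start, start + n, int(label)))


def _frame_labels_from_events(events: list) -> np.ndarray:
    """Majority frame labels from event sample intervals.

    A frame takes an event class when that class's samples cover at least
    half of it; movement takes precedence over breathing on overlap.
    """
    coverage = np.zeros((FRAMES_PER_EPOCH, 3), dtype=np.int64)
    for start, end, label in events:
        f0, f1 = start // FRAME_SAMPLES, (end - 1) // FRAME_SAMPLES
        for f in range(f0, min(f1, FRAMES_PER_EPOCH - 1) + 1):
            lo = max(start, f * FRAME_SAMPLES)
            hi = min(end, (f + 1) * FRAME_SAMPLES)
            coverage[f, label] += hi - lo
    labels = np.full(FRAMES_PER_EPOCH, int(FrameLabel.OTHER), dtype=np.int64)
    half = FRAME_SAMPLES // 2
    for cls in (FrameLabel.INHALE, FrameLabel.EXHALE, FrameLabel.MOVEMENT):
        labels[coverage[:, cls] >= half] = int(cls)
    return labels


def synthesize_epoch_audio(
    stage: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[EpochAudio, np.ndarray]:
    """One 30-s epoch of stage-conditioned audio with frame-level labels.

    Returns the epoch (index 1; callers re-index) and 600 frame labels. A
    frame is labeled with an event class when event samples cover at least
    half of it, with movement taking precedence over breathing.
    """
    noise_rms = 10.0 ** (config.noise_rms_dbfs / 20.0)
    samples = rng.standard_normal(EPOCH_SAMPLES, dtype=np.float32)
    samples *= noise_rms
    events: list[tuple[int, int, int]] = []

    if stage == "N":
        rate, rate_sd, snr, audible = (config.nrem_breath_rate,
                                       config.nrem_breath_rate_sd,
                                       config.breath_snr_db, 1.0)
        move_rate = config.movement_rate_nrem
    elif stage == "R":
        rate, rate_sd, snr, audible = (config.rem_breath_rate,
                                       config.rem_breath_rate_sd,
                                       config.breath_snr_db, 1.0)
        move_rate = config.movement_rate_rem
    elif stage == "W":
        rate, rate_sd, snr, audible = (config.wake_breath_rate,
                                       config.nrem_breath_rate_sd,
                                       config.wake_breath_snr_db,
                                       config.wake_breath_audible_prob)
        move_rate = config.movement_rate_wake
    else:
        raise ValueError(f"unknown stage {stage!r}")

    base_interval = 60.0 / rate
    cv = rate_sd / rate
    min_interval = (config.inhale_duration_s + config.breath_pause_s
                    + config.exhale_duration_s + 0.3)
    breath_db = config.noise_rms_dbfs + snr
    t = float(rng.uniform(0.0, base_interval))
    while t < EPOCH_SECONDS:
        if rng.random() < audible:
            inh = config.inhale_duration_s * float(rng.uniform(0.9, 1.1))
            exh = config.exhale_duration_s * float(rng.uniform(0.9, 1.1))
            _add_burst(samples, events, rng, t, inh,
                       config.inhale_band_hz, breath_db, FrameLabel.INHALE)
            _add_burst(samples, events, rng,
                       t + inh + config.breath_pause_s, exh,
                       config.exhale_band_hz, breath_db - 2.0,
                       FrameLabel.EXHALE)
        t += max(min_interval,
                 base_interval * (1.0 + cv * float(rng.standard_normal())))

    for _ in range(rng.poisson(move_rate)):
        dur = float(rng.uniform(*config.movement_duration_range_s))
        start = float(rng.uniform(0.0, EPOCH_SECONDS - dur))
        _add_burst(samples, events, rng, start, dur,
                   config.movement_band_hz,
                   config.noise_rms_dbfs + config.movement_snr_db,
                   FrameLabel.MOVEMENT)

    for _ in range(rng.poisson(config.transient_rate_per_epoch)):
        dur = float(rng.uniform(*config.transient_duration_range_s))
        start = float(rng.uniform(0.0, EPOCH_SECONDS - dur))
        _add_burst(samples, events, rng, start, dur,
                   config.transient_band_hz,
                   config.noise_rms_dbfs + config.transient_snr_db,
                   None)  # transients stay in the "other" class

    frame_labels = _frame_labels_from_events(events)
    frames = samples.reshape(FRAMES_PER_EPOCH, FRAME_SAMPLES)
    return EpochAudio(frames, 1), frame_labels


def _draw_meta(config: SimConfig, rng: np.random.Generator) -> SubjectMeta:
    return SubjectMeta(
        age=float(rng.integers(config.age_range[0], config.age_range[1] + 1)),
        gender=int(rng.integers(0, 2)),
        bmi=float(np.round(rng.uniform(*config.bmi_range), 1)),
    )


def iter_night_epochs(config: SimConfig):
    """Stream a night without materializing its audio.

    Yields ``(t, stage, EpochAudio, frame_labels)`` for t = 1…T after the
    hypnogram and metadata; retrieve those from the returned generator's
    ``hypnogram``/``meta`` attributes (set before the first yield) or use
    :func:`simulate_night` for the materialized form.
    """
    children = _epoch_rngs(config).spawn(2 + config.night_epochs)
    hypnogram = simulate_hypnogram(config, np.random.default_rng(children[0]))
    meta = _draw_meta(config, np.random.default_rng(children[1]))

    def gen():
        for t, stage in enumerate(hypnogram, start=1):
            rng = np.random.default_rng(children[1 + t])
            epoch, frame_labels = synthesize_epoch_audio(stage, config, rng)
            yield t, stage, EpochAudio(epoch.frames, t), frame_labels

    return hypnogram, meta, gen()


def simulate_night(config: SimConfig) -> SimulatedNight:
    """Materialize a full night (audio length == 2205·600·T samples).

    Memory scales with night length (≈ 5.3 MB/epoch float32); stream long
    nights with :func:`iter_night_epochs` instead.
    """
    hypnogram, meta, epochs = iter_night_epochs(config)
    T = hypnogram.size
    samples = np.empty(T * EPOCH_SAMPLES, dtype=np.float32)
    frame_labels = np.empty(T * FRAMES_PER_EPOCH, dtype=np.int64)
    for t, _stage, epoch, labels in epochs:
        samples[(t - 1) * EPOCH_SAMPLES: t * EPOCH_SAMPLES] = epoch.samples
        frame_labels[(t - 1) * FRAMES_PER_EPOCH: t * FRAMES_PER_EPOCH] = labels
    return SimulatedNight(AudioStream(samples), hypnogram, frame_labels,
                          meta, config)


def write_night_streaming(directory, config: SimConfig) -> np.ndarray:
    """Simulate a night directly to disk, one epoch at a time.

    Writes the same artifact set as :func:`write_night` but never holds more
    than one epoch of audio in memory, so full-length nights (840 epochs ≈
    4.4 GB of float samples) are safe. Returns the hypnogram. Bit-identical
    to materializing via :func:`simulate_night` and writing that.
    """
    import json
    import wave

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    hypnogram, meta, epochs = iter_night_epochs(config)
    with wave.open(str(d / "audio.wav"), "wb") as wav, \
            open(d / "frame_labels.csv", "w") as flab:
        wav.setnchannels(1)
        wav.setsampwidth(2)
        wav.setframerate(SAMPLE_RATE)
        flab.write("frame_index,label\n")
        for t, _stage, epoch, labels in epochs:
            pcm = np.clip(epoch.samples, -1.0, 1.0)
            wav.writeframes(np.round(pcm * 32767.0).astype("<i2").tobytes())
            base = (t - 1) * FRAMES_PER_EPOCH
            flab.writelines(
                f"{base + i},{FrameLabel(lab).name}\n"
                for i, lab in enumerate(labels))
    with open(d / "hypnogram.csv", "w") as fh:
        fh.write("epoch_index,label\n")
        for i, lab in enumerate(hypnogram, start=1):
            fh.write(f"{i},{lab}\n")
    with open(d / "meta.json", "w") as fh:
        json.dump({"age": meta.age, "gender": meta.gender, "bmi": meta.bmi}, fh)
    return hypnogram


def write_night(directory, night: SimulatedNight) -> None:
    """Write WAV + hypnogram CSV + frame-label CSV + metadata JSON."""
    import json

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_wav(d / "audio.wav", night.audio)
    with open(d / "hypnogram.csv", "w") as fh:
        fh.write("epoch_index,label\n")
        for i, lab in enumerate(night.hypnogram, start=1):
            fh.write(f"{i},{lab}\n")
    with open(d / "frame_labels.csv", "w") as fh:
        fh.write("frame_index,label\n")
        for i, lab in enumerate(night.frame_labels):
            fh.write(f"{i},{FrameLabel(lab).name}\n")
    with open(d / "meta.json", "w") as fh:
        json.dump({"age": night.meta.age, "gender": night.meta.gender,
                   "bmi": night.meta.bmi}, fh)
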