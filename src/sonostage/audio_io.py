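"""Frame/epoch partitioning of night-long audio and cross-correlation alignment.

The whole pipeline operates on a fixed grid: mono PCM audio at 44.1 kHz is cut
into contiguous, non-overlapping 50-ms frames (2205 samples) which are
aggregated into 30-s epochs (600 frames), the standard sleep-scoring unit.
Trailing partial frames and epochs are discarded rather than padded so that no
fabricated audio ever enters the feature path.

Amplitudes are normalized to full scale ±1 on read; every intensity downstream
is therefore expressed in dB relative to full scale (dBFS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import correlate, resample_poly

SAMPLE_RATE = 44100
FRAME_SAMPLES = 2205          # 50 ms at 44.1 kHz
FRAMES_PER_EPOCH = 600        # 30 s epoch
EPOCH_SAMPLES = FRAME_SAMPLES * FRAMES_PER_EPOCH
EPOCH_SECONDS = 30.0
FRAME_SECONDS = FRAME_SAMPLES / SAMPLE_RATE
FRAME_RATE = SAMPLE_RATE / FRAME_SAMPLES  # 20 frames per second


class SampleRateError(ValueError):
    """Raised when input audio is not at the required 44.1 kHz grid.

    The pipeline never resamples silently; call :func:`resample_to_standard`
    explicitly (the CLI exposes this as ``--resample``).
    """


class AlignmentError(ValueError):
    """Raised when cross-correlation alignment is undefined (zero variance)."""


@dataclass
class AudioStream:
    """Mono audio at the pipeline's native rate, full-scale ±1 amplitudes."""

    samples: np.ndarray
    rate: int = SAMPLE_RATE
    channel_count: int = field(default=1)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 1:
            raise ValueError("AudioStream must be mono (1-D samples)")
        if self.samples.size == 0:
            raise ValueError("empty audio")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite sample values")
        if self.rate != SAMPLE_RATE:
            raise SampleRateError(
                f"sample rate {self.rate} Hz unsupported: resample to "
                f"{SAMPLE_RATE} Hz first (see resample_to_standard)"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class EpochAudio:
    """One 30-s analysis unit: 600 contiguous enhanced or raw 50-ms frames."""

    frames: np.ndarray          # (600, 2205)
    epoch_index: int            # 1-based

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.shape != (FRAMES_PER_EPOCH, FRAME_SAMPLES):
            raise ValueError(
                f"EpochAudio requires shape {(FRAMES_PER_EPOCH, FRAME_SAMPLES)},"
                f" got {self.frames.shape}"
            )
        if self.epoch_index < 1:
            raise ValueError("epoch indices are 1-based")

    @property
    def samples(self) -> np.ndarray:
        return self.frames.reshape(-1)


def read_wav(path, *, resample: bool = False) -> AudioStream:
    """Read a PCM WAV file into an :class:`AudioStream`.

    Integer PCM is normalized to full scale ±1. Stereo input is rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("stereo/multi-channel WAV unsupported: supply mono audio")
    if data.dtype == np.int16:
        samples = data.astype(np.float32) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float32) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float32) - 128.0) / 128.0
    else:  # float WAV
        samples = data.astype(np.float32)
    if rate != SAMPLE_RATE:
        if not resample:
            raise SampleRateError(
                f"{path}: sample rate {rate} Hz; expected {SAMPLE_RATE} Hz "
                "(pass resample=True / --resample to convert explicitly)"
            )
        return resample_to_standard(samples, rate)
    return AudioStream(samples, rate)


def write_wav(path, stream: AudioStream) -> None:
    """Write an :class:`AudioStream` as 16-bit PCM WAV."""
    clipped = np.clip(stream.samples, -1.0, 1.0)
    wavfile.write(path, stream.rate,
                  np.round(clipped * 32767.0).astype(np.int16))


def resample_to_standard(samples: np.ndarray, rate: int) -> AudioStream:
    """Polyphase-resample arbitrary-rate mono audio to 44.1 kHz."""
    from math import gcd

    g = gcd(SAMPLE_RATE, int(rate))
    out = resample_poly(np.asarray(samples, dtype=np.float64),
                        SAMPLE_RATE // g, int(rate) // g)
    return AudioStream(out.astype(np.float32), SAMPLE_RATE)


def stream_frames(audio: AudioStream) -> np.ndarray:
    """Partition audio into contiguous non-overlapping 50-ms frames.

    Returns a ``(n_frames, 2205)`` view in emission order (row k is strictly
    earlier than row k+1, so causal consumption is row-by-row iteration).
    The trailing partial frame, if any, is discarded.
    """
    if not isinstance(audio, AudioStream):
        audio = AudioStream(np.asarray(audio))
    n = audio.samples.size // FRAME_SAMPLES
    if n == 0:
        raise ValueError(
            f"audio shorter than one frame ({FRAME_SAMPLES} samples)")
    return audio.samples[: n * FRAME_SAMPLES].reshape(n, FRAME_SAMPLES)


def frames_to_epochs(frames: np.ndarray) -> list[EpochAudio]:
    """Aggregate contiguous frames into 1-based 30-s epochs.

    Epoch t contains frames 600·(t−1) … 600·t−1; a final incomplete epoch is
    discarded.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 2 or frames.shape[1] != FRAME_SAMPLES:
        raise ValueError(f"frames must be (n, {FRAME_SAMPLES})")
    n_epochs = frames.shape[0] // FRAMES_PER_EPOCH
    return [
        EpochAudio(frames[t * FRAMES_PER_EPOCH:(t + 1) * FRAMES_PER_EPOCH],
                   epoch_index=t + 1)
        for t in range(n_epochs)
    ]


def iter_epochs(audio: AudioStream):
    """Yield :class:`EpochAudio` causally from a night stream."""
    frames = stream_frames(audio)
    yield from frames_to_epochs(frames)


def frame_energies_csv(audio: AudioStream, path) -> None:
    """Debug export: per-frame dBFS energy on the 50-ms grid."""
    frames = stream_frames(audio)
    ms = np.mean(frames.astype(np.float64) ** 2, axis=1)
    db = 10.0 * np.log10(ms + 1e-12)
    with open(path, "w") as fh:
        fh.write("frame_index,time_s,energy_dbfs\n")
        for i, v in enumerate(db):
            fh.write(f"{i},{i * FRAME_SECONDS:.2f},{max(v, -80.0):.2f}\n")


@dataclass(frozen=True)
class AlignmentResult:
    lag_s: float
    correlation: float


def align_by_crosscorrelation(
    envelope_a: np.ndarray,
    envelope_b: np.ndarray,
    max_lag_s: float,
    grid_s: float = 0.01,
) -> AlignmentResult:
    """Lag (in seconds, on the 10-ms grid) of series b relative to series a.

    A positive lag means b is a delayed copy of a. The lag maximizing the
    normalized cross-correlation within ±max_lag_s is returned together with
    the peak correlation. Two sensor channels (e.g. a PSG snore-intensity
    channel and an audio energy envelope resampled to the same 10-ms grid)
    can be synchronized this way.
    """
    a = np.asarray(envelope_a, dtype=np.float64)
    b = np.asarray(envelope_b, dtype=np.float64)
    min_len = int(round(2.0 / grid_s))
    if a.size < min_len or b.size < min_len:
        raise ValueError("envelopes must span at least 2 s")
    max_lag = int(round(max_lag_s / grid_s))
    if max_lag >= min(a.size, b.size):
        raise ValueError("max_lag exceeds series length")
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom = np.sqrt(np.sum(a0 ** 2) * np.sum(b0 ** 2))
    if denom == 0.0:
        raise AlignmentError("constant (zero-variance) envelope: alignment undefined")
    cc = correlate(b0, a0, mode="full") / denom
    lags = np.arange(-(a.size - 1), b.size)
    keep = np.abs(lags) <= max_lag
    cc, lags = cc[keep], lags[keep]
    i = int(np.argmax(cc))
    return AlignmentResult(lag_s=float(lags[i] * grid_s), correlation=float(cc[i]))
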