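"""Frame-level sound-event detection: inhale / exhale / body movement / other.

A shallow supervised classifier (multinomial logistic regression — a linear
softmax model) over 17 per-frame acoustic descriptors emits four normalized
probability curves per epoch at 50-ms resolution, one per event class. One
unified 4-class model plays the role of the classical pair of detectors
(breathing detector + body-movement detector): the outputs are identical in
form and share a single normalization.

Breathing periodicity — markedly stronger in NREM than in REM and nearly
absent in wake — is quantified by the autocorrelation of the inhalation curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.signal import find_peaks
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .audio_io import FRAME_RATE, FRAME_SAMPLES, FRAMES_PER_EPOCH, SAMPLE_RATE
from .enhancement import DB_FLOOR, frame_spectra

_EPS = 1e-12


class FrameLabel(IntEnum):
    """Closed set of frame-level event classes (= probability-curve columns)."""

    INHALE = 0
    EXHALE = 1
    MOVEMENT = 2
    OTHER = 3


N_CLASSES = 4

# Fixed order and identity of the per-frame acoustic descriptors.
FRAME_FEATURE_NAMES: tuple[str, ...] = (
    "log_energy_dbfs",
    "spectral_entropy",
    "spectral_centroid_hz",
    "spectral_rolloff_hz",
    "zero_crossing_rate",
    "band_ratio_0_200",
    "band_ratio_200_1000",
    "band_ratio_1000_4000",
    "band_ratio_4000_nyq",
    "cepstrum_1", "cepstrum_2", "cepstrum_3", "cepstrum_4",
    "cepstrum_5", "cepstrum_6", "cepstrum_7", "cepstrum_8",
)
N_FRAME_FEATURES = len(FRAME_FEATURE_NAMES)

_BAND_EDGES_HZ = (0.0, 200.0, 1000.0, 4000.0, SAMPLE_RATE / 2)
_FREQS = np.fft.rfftfreq(FRAME_SAMPLES, d=1.0 / SAMPLE_RATE)
_FREQS32 = _FREQS.astype(np.float32)
_EPS32 = 1e-10  # float32-safe epsilon for normalized quantities

# Real-cepstrum coefficients 1..8 as an explicit cosine matmul: for a real
# half-spectrum of K bins the inverse rfft at sample q is
# (X_0 + 2·Σ X_k cos(2πkq/N) + (−1)^q X_{K−1})/N with N = 2(K−1); evaluating
# only q = 1..8 is ~50× cheaper than the full transform.
_N_CEP = 8
_K_BINS = FRAME_SAMPLES // 2 + 1
_N_FULL = 2 * (_K_BINS - 1)
_CEP_BASIS = np.empty((_K_BINS, _N_CEP), dtype=np.float32)
for _q in range(1, _N_CEP + 1):
    _col = 2.0 * np.cos(2.0 * np.pi * np.arange(_K_BINS) * _q / _N_FULL)
    _col[0] = 1.0
    _col[-1] = (-1.0) ** _q
    _CEP_BASIS[:, _q - 1] = _col / _N_FULL
_BAND_SLICES = [
    (_FREQS >= lo) & (_FREQS < hi)
    for lo, hi in zip(_BAND_EDGES_HZ[:-1], _BAND_EDGES_HZ[1:])
]
# Silence convention: deterministic feature vector for all-zero frames —
# energy at the dBFS floor, entropy at its maximum, flat band occupancy.
_SILENCE_ROW = np.array(
    [DB_FLOOR, 1.0, 0.0, 0.0, 0.0, 0.25, 0.25, 0.25, 0.25] + [0.0] * 8,
    dtype=np.float64,
)


def frame_features_matrix(frames: np.ndarray,
                          spectra: np.ndarray | None = None) -> np.ndarray:
    """Acoustic descriptors for a block of frames, shape (n, 17).

    Columns follow :data:`FRAME_FEATURE_NAMES`: dBFS log energy, normalized
    spectral entropy, centroid and 85%-roll-off (Hz), zero-crossing rate,
    four band-energy ratios, and real-cepstrum coefficients 1–8.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 1:
        frames = frames[None, :]
    if frames.shape[1] != FRAME_SAMPLES:
        raise ValueError(f"frames must have {FRAME_SAMPLES} samples")
    n = frames.shape[0]
    if spectra is None:
        spectra = frame_spectra(frames)
    spectra = spectra.astype(np.complex64, copy=False)
    power = spectra.real ** 2 + spectra.imag ** 2          # float32
    total = power.sum(axis=1, dtype=np.float64)
    mean_sq = np.mean(frames ** 2, axis=1, dtype=np.float64)

    out = np.empty((n, N_FRAME_FEATURES), dtype=np.float64)
    out[:, 0] = np.maximum(10.0 * np.log10(mean_sq + _EPS), DB_FLOOR)

    p = power / (total[:, None].astype(np.float32) + np.float32(_EPS32))
    out[:, 1] = (-np.sum(p * np.log(p + np.float32(_EPS32)), axis=1)
                 / np.log(power.shape[1]))
    out[:, 2] = p @ _FREQS32
    cum = np.cumsum(p, axis=1)
    out[:, 3] = _FREQS[np.argmax(cum >= 0.85, axis=1)]
    signs = np.signbit(frames)
    out[:, 4] = np.mean(signs[:, 1:] != signs[:, :-1], axis=1)
    for b, sl in enumerate(_BAND_SLICES):
        out[:, 5 + b] = (power[:, sl].sum(axis=1, dtype=np.float64)
                         / (total + _EPS))
    log_mag = 0.5 * np.log(power + np.float32(_EPS32))
    out[:, 9:17] = log_mag @ _CEP_BASIS

    silent = mean_sq <= 1e-14
    if silent.any():
        out[silent] = _SILENCE_ROW
    return out


def frame_acoustic_features(frame: np.ndarray) -> np.ndarray:
    """Descriptor vector of a single (enhanced) 50-ms frame."""
    return frame_features_matrix(np.asarray(frame)[None, :])[0]


@dataclass
class DetectorModel:
    """Trained frame-event classifier with its feature scaling statistics.

    ``kind == "uniform"`` is the untrained prior: every frame gets
    (0.25, 0.25, 0.25, 0.25). Inference is deterministic given parameters.
    """

    kind: str                      # "logistic" | "uniform"
    estimator: object | None
    feature_mean: np.ndarray | None
    feature_scale: np.ndarray | None
    classes: np.ndarray | None     # label ints present at training time
    seed: int | None = None
    holdout_accuracy: float | None = None
    format_version: int = 1

    def predict_curves(self, features: np.ndarray) -> np.ndarray:
        """Per-frame normalized probability quadruples (n, 4)."""
        features = np.asarray(features, dtype=np.float64)
        n = features.shape[0]
        if self.kind == "uniform":
            return np.full((n, N_CLASSES), 1.0 / N_CLASSES)
        z = (features - self.feature_mean) / self.feature_scale
        proba = self.estimator.predict_proba(z)
        curves = np.zeros((n, N_CLASSES), dtype=np.float64)
        curves[:, np.asarray(self.classes, dtype=int)] = proba
        curves /= curves.sum(axis=1, keepdims=True)
        return curves


def uniform_detector() -> DetectorModel:
    """Untrained prior emitting (0.25, 0.25, 0.25, 0.25) for every frame."""
    return DetectorModel("uniform", None, None, None, None)


def train_detector(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    holdout_fraction: float = 0.2,
    max_iter: int = 300,
) -> DetectorModel:
    """Fit the frame-event classifier on labeled (enhanced) frames.

    Features are z-scored with training-set statistics stored in the model;
    classes are weighted by inverse frequency. A stratified holdout fraction
    reports generalization accuracy. Reproducible under a fixed seed.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[1] != N_FRAME_FEATURES:
        raise ValueError(f"features must be (n, {N_FRAME_FEATURES})")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set must contain at least two classes")
    holdout_acc = None
    X_fit, y_fit = X, y
    if holdout_fraction > 0 and np.min(np.bincount(y)[classes]) >= 2:
        X_fit, X_hold, y_fit, y_hold = train_test_split(
            X, y, test_size=holdout_fraction, random_state=seed, stratify=y)
    else:
        X_hold = y_hold = None
    mean = X_fit.mean(axis=0)
    scale = X_fit.std(axis=0)
    scale[scale < 1e-9] = 1.0
    clf = LogisticRegression(
        max_iter=max_iter, class_weight="balanced", C=1.0, random_state=seed)
    clf.fit((X_fit - mean) / scale, y_fit)
    if X_hold is not None:
        holdout_acc = float(
            np.mean(clf.predict((X_hold - mean) / scale) == y_hold))
    return DetectorModel("logistic", clf, mean, scale,
                         classes=clf.classes_, seed=seed,
                         holdout_accuracy=holdout_acc)


def detect_events(epoch_or_features, model: DetectorModel) -> np.ndarray:
    """Probability curves (600, 4) for one epoch at 50-ms resolution.

    Accepts an :class:`~sonostage.audio_io.EpochAudio` (features computed
    here) or a precomputed (600, 17) descriptor matrix. Each frame's output
    depends on that frame only, so inference is causal.
    """
    feats = np.asarray(getattr(epoch_or_features, "frames", epoch_or_features))
    if feats.ndim == 2 and feats.shape[1] == FRAME_SAMPLES:
        feats = frame_features_matrix(feats)
    if feats.shape != (FRAMES_PER_EPOCH, N_FRAME_FEATURES):
        raise ValueError("expected one full epoch of frames or frame features")
    return model.predict_curves(feats)


def curves_to_csv(curves: np.ndarray, path, start_time_s: float = 0.0) -> None:
    """Export probability curves as per-frame CSV
    (night_time_s, p_in, p_ex, p_bm, p_os)."""
    curves = np.asarray(curves)
    if curves.ndim == 3:              # (epochs, 600, 4) -> flatten the night
        curves = curves.reshape(-1, N_CLASSES)
    with open(path, "w") as fh:
        fh.write("night_time_s,p_in,p_ex,p_bm,p_os\n")
        for i, row in enumerate(curves):
            t = start_time_s + i / FRAME_RATE
            fh.write(f"{t:.2f}," + ",".join(f"{v:.4f}" for v in row) + "\n")


@dataclass(frozen=True)
class AutocorrResult:
    acf: np.ndarray               # normalized, acf[0] == 1
    peak_lag_s: float | None
    peak_height: float | None
    degenerate: bool              # constant (zero-variance) input curve


def breathing_autocorrelation(
    curves: np.ndarray,
    min_lag_s: float = 1.0,
    prominence: float = 0.02,
) -> AutocorrResult:
    """Periodicity of the inhalation curve via normalized autocorrelation.

    The mean-removed inhalation probability curve is autocorrelated and
    normalized to 1 at zero lag; the first local peak at lag ≥ ``min_lag_s``
    is returned. A constant curve is flagged degenerate with no peak —
    exactly the wake situation where breathing periodicity vanishes.
    """
    curves = np.asarray(curves, dtype=np.float64)
    p_in = curves[:, FrameLabel.INHALE] if curves.ndim == 2 else curves
    if p_in.size != FRAMES_PER_EPOCH:
        raise ValueError(f"curve length must be {FRAMES_PER_EPOCH}")
    x = p_in - p_in.mean()
    var = np.dot(x, x)
    if var < 1e-18:
        return AutocorrResult(np.zeros(FRAMES_PER_EPOCH), None, None, True)
    n = x.size
    full = np.correlate(x, x, mode="full")[n - 1:]
    # unbiased estimate: an exactly periodic curve peaks at 1.0 at its period
    acf = full / full[0] * (n / (n - np.arange(n)))
    acf = np.clip(acf, -1.0, 1.0)
    min_lag = int(round(min_lag_s * FRAME_RATE))
    peaks, _ = find_peaks(acf[: n // 2 + 1], prominence=prominence)
    # a genuine periodicity repeat is a positive-correlation peak; local
    # bumps inside the negative trough (e.g. at half period) do not count
    peaks = peaks[(peaks >= min_lag) & (acf[peaks] > 0)]
    if peaks.size == 0:
        return AutocorrResult(acf, None, None, False)
    k = int(peaks[0])
    return AutocorrResult(acf, k / FRAME_RATE, float(acf[k]), False)
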