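"""The 67-feature epoch representation used by the staging cascades.

Five families with fixed sizes 33/12/10/8/4:

* within-breathing — properties of individual detected breath events
  (counts, durations, intensities, spectral shape of breath frames);
* between-breathing — the breathing *pattern* (inter-breath intervals,
  periodicity via autocorrelation, dominant respiratory frequency,
  regularity, duty-cycle stability);
* body-movement — movement-event statistics (near-absent in REM because of
  REM atonia, frequent in wake);
* background-noise — transient third-party sounds and the tracked noise floor;
* personalization — age, gender, BMI and the epoch index t (wake is a priori
  likelier early in the recording).

The registry order below is frozen and versioned: feature index ↔ name is a
bijection, and every serialized model stores the registry hash. The exact
identities of the features are this package's reconstruction from the family
descriptions; the registry is configurable in the sense that downstream code
addresses features only by name.

Undefined statistics (e.g. breath-interval spread in an epoch without
breaths) carry a NaN sentinel; by default they are replaced by documented
neutral values so vectors are finite, while the training harness re-imputes
sentinels with training-set medians (stored in the model) to avoid biasing
the classifier toward any class.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .audio_io import FRAME_RATE, FRAMES_PER_EPOCH, EpochAudio
from .detection import (
    DB_FLOOR,
    AutocorrResult,
    FrameLabel,
    breathing_autocorrelation,
    frame_features_matrix,
)
from .enhancement import NoiseProfile

_SEC_PER_FRAME = 1.0 / FRAME_RATE

WITHIN_BREATHING_NAMES = (
    "wb_inhale_count", "wb_exhale_count",
    "wb_inhale_dur_mean_s", "wb_inhale_dur_sd_s", "wb_inhale_dur_max_s",
    "wb_exhale_dur_mean_s", "wb_exhale_dur_sd_s", "wb_exhale_dur_max_s",
    "wb_inhale_intensity_mean_dbfs", "wb_inhale_intensity_sd_db",
    "wb_exhale_intensity_mean_dbfs", "wb_exhale_intensity_sd_db",
    "wb_inhale_exhale_intensity_ratio",
    "wb_breath_centroid_mean_hz", "wb_breath_centroid_sd_hz",
    "wb_breath_entropy_mean", "wb_breath_entropy_sd",
    "wb_breath_rolloff_mean_hz", "wb_breath_rolloff_sd_hz",
    "wb_breath_band0_ratio_mean", "wb_breath_band1_ratio_mean",
    "wb_breath_band2_ratio_mean", "wb_breath_band3_ratio_mean",
    "wb_breath_zcr_mean", "wb_breath_zcr_sd",
    "wb_breath_cep1_mean", "wb_breath_cep2_mean", "wb_breath_cep3_mean",
    "wb_breath_cep4_mean", "wb_breath_cep5_mean", "wb_breath_cep6_mean",
    "wb_harmonicity_fraction",
    "wb_breathing_duty_cycle",
)
BETWEEN_BREATHING_NAMES = (
    "bb_ibi_mean_s", "bb_ibi_sd_s", "bb_ibi_cv",
    "bb_acf_peak_height", "bb_acf_peak_lag_s",
    "bb_dominant_freq_hz", "bb_dominant_freq_power",
    "bb_regularity_ratio",
    "bb_duty_cycle_var_thirds",
    "bb_in_to_ex_interval_mean_s", "bb_in_to_ex_interval_sd_s",
    "bb_detectable_breathing_fraction",
)
BODY_MOVEMENT_NAMES = (
    "bm_event_count", "bm_duration_fraction",
    "bm_dur_mean_s", "bm_dur_max_s",
    "bm_intensity_mean_dbfs", "bm_intensity_max_dbfs",
    "bm_frames_since_last_event", "bm_mean_prob",
    "bm_longest_free_run_frames", "bm_half_count_difference",
)
BACKGROUND_NOISE_NAMES = (
    "bg_other_event_count", "bg_other_duration_fraction",
    "bg_other_intensity_mean_dbfs", "bg_other_intensity_max_dbfs",
    "bg_noise_floor_dbfs", "bg_noise_floor_delta_db",
    "bg_other_centroid_mean_hz", "bg_transient_rate_per_min",
)
PERSONALIZATION_NAMES = (
    "pers_age_years", "pers_gender", "pers_bmi", "pers_epoch_index",
)

FEATURE_NAMES: tuple[str, ...] = (
    WITHIN_BREATHING_NAMES + BETWEEN_BREATHING_NAMES + BODY_MOVEMENT_NAMES
    + BACKGROUND_NOISE_NAMES + PERSONALIZATION_NAMES
)
FAMILY_SIZES = {"within_breathing": 33, "between_breathing": 12,
                "body_movement": 10, "background_noise": 8,
                "personalization": 4}
N_FEATURES = 67
assert len(FEATURE_NAMES) == N_FEATURES
assert tuple(FAMILY_SIZES.values()) == (
    len(WITHIN_BREATHING_NAMES), len(BETWEEN_BREATHING_NAMES),
    len(BODY_MOVEMENT_NAMES), len(BACKGROUND_NOISE_NAMES),
    len(PERSONALIZATION_NAMES))
FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

REGISTRY_VERSION = 1


def registry_hash() -> str:
    """Stable hash of (version, ordered names); embedded in saved models."""
    payload = f"v{REGISTRY_VERSION}:" + ",".join(FEATURE_NAMES)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# Neutral fallback for each NaN-sentinel feature (default imputation path).
_IMPUTE_DEFAULTS = {name: 0.0 for name in FEATURE_NAMES}
_IMPUTE_DEFAULTS.update({
    "wb_inhale_intensity_mean_dbfs": DB_FLOOR,
    "wb_exhale_intensity_mean_dbfs": DB_FLOOR,
    "wb_inhale_exhale_intensity_ratio": 1.0,
    "wb_breath_entropy_mean": 1.0,
    "wb_breath_band0_ratio_mean": 0.25, "wb_breath_band1_ratio_mean": 0.25,
    "wb_breath_band2_ratio_mean": 0.25, "wb_breath_band3_ratio_mean": 0.25,
    "bm_intensity_mean_dbfs": DB_FLOOR, "bm_intensity_max_dbfs": DB_FLOOR,
    "bg_other_intensity_mean_dbfs": DB_FLOOR,
    "bg_other_intensity_max_dbfs": DB_FLOOR,
})
IMPUTE_DEFAULT_VECTOR = np.array([_IMPUTE_DEFAULTS[n] for n in FEATURE_NAMES])


@dataclass(frozen=True)
class SubjectMeta:
    """Anthropometric metadata: age (years), gender coded {0,1}, BMI (kg/m²)."""

    age: float
    gender: int
    bmi: float

    def __post_init__(self) -> None:
        for name in ("age", "gender", "bmi"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                raise ValueError(f"missing subject metadata: {name}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if int(self.gender) not in (0, 1):
            raise ValueError("gender must be coded 0 or 1")


@dataclass(frozen=True)
class BreathEvent:
    """A detected inhale or exhale run of frames within one epoch."""

    kind: str                 # "inhale" | "exhale"
    onset_frame: int          # 0-based, inclusive
    offset_frame: int         # exclusive
    mean_intensity_dbfs: float

    @property
    def duration_s(self) -> float:
        return (self.offset_frame - self.onset_frame) * _SEC_PER_FRAME


def _class_runs(curves: np.ndarray, cls: int, threshold: float,
                min_frames: int, extra_mask: np.ndarray | None = None
                ) -> list[tuple[int, int]]:
    """Maximal runs of frames whose argmax class is `cls` with prob ≥ threshold."""
    active = (np.argmax(curves, axis=1) == cls) & (curves[:, cls] >= threshold)
    if extra_mask is not None:
        active &= extra_mask
    runs: list[tuple[int, int]] = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            if i - start >= min_frames:
                runs.append((start, i))
            start = None
    if start is not None and len(active) - start >= min_frames:
        runs.append((start, len(active)))
    return runs


def segment_breath_events(
    curves: np.ndarray,
    threshold: float = 0.5,
    frame_feats: np.ndarray | None = None,
    min_frames: int = 3,
) -> list[BreathEvent]:
    """Segment inhalation/exhalation events from the probability curves.

    Runs shorter than ``min_frames`` (150 ms at defaults) are discarded as
    detector flicker. Event intensity is the mean dBFS log-energy of its
    frames (0 dB if no frame features are supplied).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    curves = np.asarray(curves, dtype=np.float64)
    energies = (frame_feats[:, 0] if frame_feats is not None
                else np.zeros(curves.shape[0]))
    events: list[BreathEvent] = []
    for kind, cls in (("inhale", FrameLabel.INHALE), ("exhale", FrameLabel.EXHALE)):
        for s, e in _class_runs(curves, cls, threshold, min_frames):
            events.append(BreathEvent(kind, s, e, float(energies[s:e].mean())))
    return sorted(events, key=lambda ev: ev.onset_frame)


def _stats(values: list[float]) -> tuple[float, float, float]:
    """(mean, sd, max) with NaN sentinels when undefined."""
    if not values:
        return np.nan, np.nan, np.nan
    arr = np.asarray(values, dtype=np.float64)
    sd = float(arr.std()) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, float(arr.max())


def within_breathing_features(
    epoch: EpochAudio | None,
    curves: np.ndarray,
    events: list[BreathEvent],
    frame_feats: np.ndarray | None = None,
    harmonic_entropy_threshold: float = 0.85,
) -> np.ndarray:
    """33 values describing the epoch's individual breaths (registry order)."""
    if frame_feats is None:
        if epoch is None:
            raise ValueError("need either an epoch or precomputed frame features")
        frame_feats = frame_features_matrix(epoch.frames)
    out = np.full(len(WITHIN_BREATHING_NAMES), np.nan)
    inh = [e for e in events if e.kind == "inhale"]
    exh = [e for e in events if e.kind == "exhale"]
    out[0], out[1] = len(inh), len(exh)
    out[2:5] = _stats([e.duration_s for e in inh])
    out[5:8] = _stats([e.duration_s for e in exh])
    im, isd, _ = _stats([e.mean_intensity_dbfs for e in inh])
    em, esd, _ = _stats([e.mean_intensity_dbfs for e in exh])
    out[8:10] = (im, isd)
    out[10:12] = (em, esd)
    if inh and exh:
        out[12] = 10.0 ** (im / 20.0) / 10.0 ** (em / 20.0)
    mask = np.zeros(FRAMES_PER_EPOCH, dtype=bool)
    for e in events:
        mask[e.onset_frame:e.offset_frame] = True
    if mask.any():
        bf = frame_feats[mask]
        out[13:15] = (bf[:, 2].mean(), bf[:, 2].std())
        out[15:17] = (bf[:, 1].mean(), bf[:, 1].std())
        out[17:19] = (bf[:, 3].mean(), bf[:, 3].std())
        out[19:23] = bf[:, 5:9].mean(axis=0)
        out[23:25] = (bf[:, 4].mean(), bf[:, 4].std())
        out[25:31] = bf[:, 9:15].mean(axis=0)
        out[31] = float(np.mean(bf[:, 1] < harmonic_entropy_threshold))
    out[32] = float(mask.mean())  # breathing duty cycle, defined even w/o events
    return out


def between_breathing_features(
    curves: np.ndarray,
    events: list[BreathEvent],
    acf: AutocorrResult | None = None,
) -> np.ndarray:
    """12 values describing the breathing *pattern* across the epoch."""
    curves = np.asarray(curves, dtype=np.float64)
    out = np.full(len(BETWEEN_BREATHING_NAMES), np.nan)
    inh = [e for e in events if e.kind == "inhale"]
    onsets = np.array([e.onset_frame for e in inh], dtype=np.float64)
    if onsets.size >= 2:
        ibi = np.diff(onsets) * _SEC_PER_FRAME
        out[0], out[1] = ibi.mean(), ibi.std()
        out[2] = out[1] / out[0] if out[0] > 0 else np.nan
    if acf is None:
        acf = breathing_autocorrelation(curves)
    if acf.peak_height is not None:
        out[3], out[4] = acf.peak_height, acf.peak_lag_s
        out[7] = acf.peak_height / 1.0  # first peak over (normalized) zero lag
    p_in = curves[:, FrameLabel.INHALE]
    x = p_in - p_in.mean()
    if np.dot(x, x) > 1e-18:
        f, pxx = periodogram(x, fs=FRAME_RATE, nfft=4096)
        band = (f >= 1.0 / 30.0) & (f <= 1.5)
        if pxx[band].sum() > 0:
            i = int(np.argmax(pxx[band]))
            out[5] = float(f[band][i])
            out[6] = float(pxx[band][i] / pxx[band].sum())
    breath_mask = np.zeros(FRAMES_PER_EPOCH, dtype=bool)
    for e in events:
        breath_mask[e.onset_frame:e.offset_frame] = True
    third = FRAMES_PER_EPOCH // 3
    duties = [breath_mask[i * third:(i + 1) * third].mean() for i in range(3)]
    out[8] = float(np.std(duties))
    exh_onsets = sorted(e.onset_frame for e in events if e.kind == "exhale")
    pairs = []
    for o in onsets:
        nxt = next((x_ for x_ in exh_onsets if x_ > o), None)
        if nxt is not None:
            pairs.append((nxt - o) * _SEC_PER_FRAME)
    if pairs:
        arr = np.asarray(pairs)
        out[9], out[10] = arr.mean(), (arr.std() if arr.size > 1 else 0.0)
    block = 100  # 5-s blocks
    blocks = breath_mask.reshape(-1, block).any(axis=1)
    out[11] = float(blocks.mean())
    return out


def body_movement_features(
    curves: np.ndarray,
    frame_feats: np.ndarray | None = None,
    frames_since_prev_movement: float = 600.0,
    threshold: float = 0.5,
    min_frames: int = 3,
) -> np.ndarray:
    """10 values quantifying body-movement sound events.

    ``frames_since_prev_movement`` carries night-level state: frames elapsed
    since the end of the last movement event before this epoch (already
    capped at 600 by the caller).
    """
    curves = np.asarray(curves, dtype=np.float64)
    out = np.zeros(len(BODY_MOVEMENT_NAMES))
    runs = _class_runs(curves, FrameLabel.MOVEMENT, threshold, min_frames)
    energies = (frame_feats[:, 0] if frame_feats is not None
                else np.full(curves.shape[0], DB_FLOOR))
    out[0] = len(runs)
    move_frames = sum(e - s for s, e in runs)
    out[1] = move_frames / FRAMES_PER_EPOCH
    if runs:
        durs = [(e - s) * _SEC_PER_FRAME for s, e in runs]
        out[2], out[3] = float(np.mean(durs)), float(np.max(durs))
        ints = [float(energies[s:e].mean()) for s, e in runs]
        out[4], out[5] = float(np.mean(ints)), float(np.max(ints))
        out[6] = min(600.0, FRAMES_PER_EPOCH - runs[-1][1])
    else:
        out[4], out[5] = np.nan, np.nan
        out[6] = min(600.0, frames_since_prev_movement + FRAMES_PER_EPOCH)
    out[7] = float(curves[:, FrameLabel.MOVEMENT].mean())
    active = np.zeros(FRAMES_PER_EPOCH, dtype=bool)
    for s, e in runs:
        active[s:e] = True
    longest = run = 0
    for a in active:
        run = 0 if a else run + 1
        longest = max(longest, run)
    out[8] = longest
    half = FRAMES_PER_EPOCH // 2
    first = sum(1 for s, _ in runs if s < half)
    out[9] = first - (len(runs) - first)
    return out


def background_noise_features(
    curves: np.ndarray,
    frame_feats: np.ndarray,
    profile: NoiseProfile,
    prev_floor_dbfs: float | None = None,
    trailing_other_counts: list[int] | None = None,
    threshold: float = 0.5,
    min_frames: int = 3,
    transient_margin_db: float = 10.0,
) -> np.ndarray:
    """8 values describing transient 'other' sounds and the noise floor.

    An 'other' *event* is a run of other-class frames at least
    ``transient_margin_db`` above the tracked noise floor — quiet background
    frames are the ambient default, not events.
    """
    curves = np.asarray(curves, dtype=np.float64)
    out = np.zeros(len(BACKGROUND_NOISE_NAMES))
    floor = profile.floor_dbfs
    loud = frame_feats[:, 0] >= floor + transient_margin_db
    runs = _class_runs(curves, FrameLabel.OTHER, threshold, min_frames,
                       extra_mask=loud)
    out[0] = len(runs)
    ev_frames = sum(e - s for s, e in runs)
    out[1] = ev_frames / FRAMES_PER_EPOCH
    if runs:
        frame_idx = np.concatenate([np.arange(s, e) for s, e in runs])
        out[2] = float(frame_feats[frame_idx, 0].mean())
        out[3] = float(frame_feats[frame_idx, 0].max())
        out[6] = float(frame_feats[frame_idx, 2].mean())
    else:
        out[2] = out[3] = DB_FLOOR
        out[6] = 0.0
    out[4] = floor
    out[5] = 0.0 if prev_floor_dbfs is None else floor - prev_floor_dbfs
    counts = list(trailing_other_counts or []) + [len(runs)]
    counts = counts[-5:]
    out[7] = sum(counts) / (0.5 * len(counts))  # events per minute
    return out


def personalization_features(meta: SubjectMeta, t: int) -> np.ndarray:
    """(age, gender, bmi, epoch index) in registry order; t is 1-based."""
    if not isinstance(meta, SubjectMeta):
        meta = SubjectMeta(**meta)  # validates; raises on missing fields
    if t < 1:
        raise ValueError("epoch index t is 1-based")
    return np.array([meta.age, float(int(meta.gender)), meta.bmi, float(t)])


def impute_sentinels(vector: np.ndarray,
                     values: np.ndarray | None = None) -> np.ndarray:
    """Replace NaN sentinels with per-feature values (registry defaults or
    training-set medians)."""
    vec = np.array(vector, dtype=np.float64)
    fill = IMPUTE_DEFAULT_VECTOR if values is None else np.asarray(values)
    nan = ~np.isfinite(vec)
    vec[nan] = fill[nan]
    return vec


def extract_epoch_features(
    epoch: EpochAudio | None,
    curves: np.ndarray,
    profile: NoiseProfile,
    meta: SubjectMeta,
    t: int,
    frame_feats: np.ndarray | None = None,
    prev_floor_dbfs: float | None = None,
    trailing_other_counts: list[int] | None = None,
    frames_since_prev_movement: float = 600.0,
    impute: bool = True,
) -> np.ndarray:
    """Concatenate the five families into the 67-vector (registry order).

    With ``impute=True`` (default) NaN sentinels are replaced by the registry
    defaults so the result is finite everywhere; the training harness passes
    ``impute=False`` and re-imputes with training-set medians.
    """
    if frame_feats is None:
        if epoch is None:
            raise ValueError("need either an epoch or precomputed frame features")
        frame_feats = frame_features_matrix(epoch.frames)
    events = segment_breath_events(curves, frame_feats=frame_feats)
    vec = np.concatenate([
        within_breathing_features(epoch, curves, events, frame_feats),
        between_breathing_features(curves, events),
        body_movement_features(curves, frame_feats, frames_since_prev_movement),
        background_noise_features(curves, frame_feats, profile,
                                  prev_floor_dbfs, trailing_other_counts),
        personalization_features(meta, t),
    ])
    assert vec.shape == (N_FEATURES,)
    return impute_sentinels(vec) if impute else vec


def write_feature_matrix(X: np.ndarray, path, manifest_path=None) -> None:
    """Per-night feature matrix as CSV (rows = epochs, columns = registry
    names) with a sidecar JSON registry manifest."""
    import csv
    import json

    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected a (T, {N_FEATURES}) matrix")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("epoch_index",) + FEATURE_NAMES)
        for t, row in enumerate(X, start=1):
            w.writerow([t] + [f"{v:.6g}" for v in row])
    manifest = {
        "registry_version": REGISTRY_VERSION,
        "registry_hash": registry_hash(),
        "families": FAMILY_SIZES,
        "names": list(FEATURE_NAMES),
    }
    mp = manifest_path or (str(path) + ".registry.json")
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2)


class NightFeatureExtractor:
    """Stateful per-night extractor maintaining the causal history features.

    Tracks the previous epoch's noise floor, the trailing-5-epoch transient
    counts and the frames elapsed since the last movement event — all strictly
    backward-looking, so features of epoch t depend only on epochs ≤ t.
    """

    def __init__(self, meta: SubjectMeta, impute: bool = True):
        self.meta = meta
        self.impute = impute
        self._prev_floor: float | None = None
        self._other_counts: list[int] = []
        self._frames_since_move = 600.0
        self._t = 0

    def process_epoch(self, epoch: EpochAudio | None, curves: np.ndarray,
                      profile: NoiseProfile,
                      frame_feats: np.ndarray | None = None) -> np.ndarray:
        self._t += 1
        if frame_feats is None:
            frame_feats = frame_features_matrix(epoch.frames)
        vec = extract_epoch_features(
            epoch, curves, profile, self.meta, self._t,
            frame_feats=frame_feats,
            prev_floor_dbfs=self._prev_floor,
            trailing_other_counts=self._other_counts,
            frames_since_prev_movement=self._frames_since_move,
            impute=self.impute,
        )
        # update night state from this epoch's observations
        self._prev_floor = profile.floor_dbfs
        self._other_counts = (self._other_counts
                              + [int(vec[FEATURE_INDEX["bg_other_event_count"]])])[-4:]
        self._frames_since_move = float(
            vec[FEATURE_INDEX["bm_frames_since_last_event"]])
        return vec
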