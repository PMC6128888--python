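"""End-to-end night processing: audio → enhancement → curves → features → stages.

Every step is strictly causal: the noise profile is updated from each raw
epoch before that epoch is enhanced, and features of epoch t see only epochs
≤ t, so the real-time staging contract holds through the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioStream, iter_epochs
from .detection import DetectorModel, frame_features_matrix
from .enhancement import (
    EnhancementConfig,
    NoiseProfile,
    enhance_epoch,
    frame_spectra,
    update_noise_profile,
)
from .features import NightFeatureExtractor, SubjectMeta
from .simulator import SimConfig, iter_night_epochs
from .staging import OfflineCascade, RealtimeCascade, scores_to_labels


@dataclass
class NightFeatures:
    """Feature matrix of one processed night plus optional diagnostics."""

    X: np.ndarray                               # (T, 67), NaN sentinels kept
    hypnogram: np.ndarray | None = None         # ground truth if simulated
    meta: SubjectMeta | None = None
    curves: np.ndarray | None = None            # (T, 600, 4) if requested
    frame_labels: np.ndarray | None = None      # simulator ground truth


def process_epochs(
    epochs,
    detector: DetectorModel,
    meta: SubjectMeta,
    enhancement: EnhancementConfig | None = None,
    keep_curves: bool = False,
) -> NightFeatures:
    """Run the causal per-epoch pipeline over an iterable of raw EpochAudio."""
    cfg = enhancement or EnhancementConfig()
    extractor = NightFeatureExtractor(meta, impute=False)
    profile: NoiseProfile | None = None
    rows, curves_out = [], []
    for epoch in epochs:
        raw_spectra = frame_spectra(epoch.frames)
        raw_power = raw_spectra.real ** 2 + raw_spectra.imag ** 2
        profile = update_noise_profile(epoch, profile, cfg, power=raw_power)
        enhanced, enh_spectra = enhance_epoch(epoch, profile, cfg,
                                              spectra=raw_spectra,
                                              power=raw_power)
        feats = frame_features_matrix(enhanced.frames, spectra=enh_spectra)
        curves = detector.predict_curves(feats)
        rows.append(extractor.process_epoch(enhanced, curves, profile,
                                            frame_feats=feats))
        if keep_curves:
            curves_out.append(curves)
    if not rows:
        raise ValueError("no complete epochs in input")
    return NightFeatures(
        X=np.vstack(rows), meta=meta,
        curves=np.stack(curves_out) if keep_curves else None)


def process_night_audio(
    audio: AudioStream,
    detector: DetectorModel,
    meta: SubjectMeta,
    enhancement: EnhancementConfig | None = None,
    keep_curves: bool = False,
) -> NightFeatures:
    """Feature matrix of a recorded night (WAV already loaded)."""
    return process_epochs(iter_epochs(audio), detector, meta,
                          enhancement, keep_curves)


def process_simulated_night(
    sim_config: SimConfig,
    detector: DetectorModel,
    enhancement: EnhancementConfig | None = None,
    keep_curves: bool = False,
    keep_frame_labels: bool = False,
) -> NightFeatures:
    """Stream a simulated night through the pipeline without holding its audio."""
    hypnogram, meta, epochs = iter_night_epochs(sim_config)
    labels_out = [] if keep_frame_labels else None

    def raw_epochs():
        for _t, _stage, epoch, frame_labels in epochs:
            if labels_out is not None:
                labels_out.append(frame_labels)
            yield epoch

    nf = process_epochs(raw_epochs(), detector, meta, enhancement, keep_curves)
    nf.hypnogram = hypnogram
    if labels_out is not None:
        nf.frame_labels = np.concatenate(labels_out)
    return nf


def enhance_wav(in_path, out_path,
                enhancement: EnhancementConfig | None = None,
                resample: bool = False) -> int:
    """Denoise a night WAV and write the enhanced audio back as PCM16 WAV.

    Streams epoch by epoch (constant memory); returns the number of epochs
    written. Trailing audio shorter than one epoch is dropped, matching the
    analysis grid.
    """
    import wave

    from .audio_io import SAMPLE_RATE, read_wav

    cfg = enhancement or EnhancementConfig()
    audio = read_wav(in_path, resample=resample)
    profile = None
    n = 0
    with wave.open(str(out_path), "wb") as out:
        out.setnchannels(1)
        out.setsampwidth(2)
        out.setframerate(SAMPLE_RATE)
        for epoch in iter_epochs(audio):
            profile = update_noise_profile(epoch, profile, cfg)
            enhanced, _ = enhance_epoch(epoch, profile, cfg)
            pcm = np.clip(enhanced.samples, -1.0, 1.0)
            out.writeframes(
                np.round(pcm * 32767.0).astype("<i2").tobytes())
            n += 1
    return n


def collect_detector_frames(
    sim_configs: list[SimConfig],
    enhancement: EnhancementConfig | None = None,
    max_frames_per_night: int | None = 60_000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Enhanced-frame features + ground-truth labels for detector training.

    Frames pass through exactly the enhancement the detector will see at
    inference. Optionally subsamples frames per night (seeded) to bound the
    training-set size.
    """
    cfg = enhancement or EnhancementConfig()
    rng = rng or np.random.default_rng(0)
    feats_all, labels_all = [], []
    for sc in sim_configs:
        _hyp, _meta, epochs = iter_night_epochs(sc)
        profile = None
        night_feats, night_labels = [], []
        for _t, _stage, epoch, frame_labels in epochs:
            raw_spectra = frame_spectra(epoch.frames)
            raw_power = raw_spectra.real ** 2 + raw_spectra.imag ** 2
            profile = update_noise_profile(epoch, profile, cfg,
                                           power=raw_power)
            enhanced, enh_spectra = enhance_epoch(epoch, profile, cfg,
                                                  spectra=raw_spectra,
                                                  power=raw_power)
            night_feats.append(
                frame_features_matrix(enhanced.frames, spectra=enh_spectra))
            night_labels.append(frame_labels)
        F = np.vstack(night_feats)
        L = np.concatenate(night_labels)
        if max_frames_per_night is not None and F.shape[0] > max_frames_per_night:
            idx = rng.choice(F.shape[0], max_frames_per_night, replace=False)
            F, L = F[idx], L[idx]
        feats_all.append(F)
        labels_all.append(L)
    return np.vstack(feats_all), np.concatenate(labels_all)


@dataclass
class NightEstimate:
    """Per-epoch stage scores and labels for both passes of one night."""

    rt_scores: np.ndarray            # (T, 3)
    rt_labels: np.ndarray            # (T,) of {W,R,N}
    off_scores: np.ndarray | None
    off_labels: np.ndarray | None
    T: int = field(init=False)

    def __post_init__(self) -> None:
        self.T = self.rt_scores.shape[0]


def stage_night(
    X: np.ndarray,
    realtime: RealtimeCascade,
    offline: OfflineCascade | None = None,
) -> NightEstimate:
    """Apply the real-time cascade (and, after night completion, the offline
    backward pass) to a night's feature matrix."""
    rt_scores = realtime.scores_for_night(np.asarray(X))
    off_scores = off_labels = None
    if offline is not None:
        off_scores = offline.scores_for_night(rt_scores)
        off_labels = scores_to_labels(off_scores)
    return NightEstimate(rt_scores, scores_to_labels(rt_scores),
                         off_scores, off_labels)


def estimate_to_csv(est: NightEstimate, path) -> None:
    """Write the per-night staging output table."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["epoch_index", "rt_pW", "rt_pR", "rt_pN", "rt_label"]
        if est.off_scores is not None:
            header += ["off_pW", "off_pR", "off_pN", "off_label"]
        w.writerow(header)
        for t in range(est.T):
            row = [t + 1, *(f"{v:.6f}" for v in est.rt_scores[t]),
                   est.rt_labels[t]]
            if est.off_scores is not None:
                row += [*(f"{v:.6f}" for v in est.off_scores[t]),
                        est.off_labels[t]]
            w.writerow(row)
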