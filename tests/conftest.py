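"""Shared fixtures: a trained frame-event detector and per-stage epoch banks.

Everything is generated programmatically from the simulator with fixed seeds;
expensive artifacts are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from sonostage.detection import frame_features_matrix, train_detector
from sonostage.enhancement import (
    EnhancementConfig,
    enhance_epoch,
    frame_spectra,
    update_noise_profile,
)
from sonostage.features import SubjectMeta
from sonostage.pipeline import collect_detector_frames
from sonostage.simulator import SimConfig, synthesize_epoch_audio


@pytest.fixture(scope="session")
def detector():
    """Frame-event classifier trained on two short simulated nights."""
    cfgs = [SimConfig(seed=900 + s, night_epochs=30) for s in range(2)]
    F, L = collect_detector_frames(cfgs, max_frames_per_night=30_000,
                                   rng=np.random.default_rng(0))
    return train_detector(F, L, seed=0)


def make_detector_stub():
    """Cheap stand-in detector (uniform prior) for orchestration tests."""
    from sonostage.detection import uniform_detector

    return uniform_detector()


@pytest.fixture(scope="session")
def default_meta():
    return SubjectMeta(age=40.0, gender=1, bmi=27.0)


def make_stage_epoch(stage: str, seed: int, config: SimConfig | None = None):
    """One synthesized epoch: (enhanced epoch, frame feats, labels, profile).

    The noise profile is estimated from the epoch itself (single-epoch
    bootstrap), which is how an isolated epoch enters the pipeline.
    """
    cfg = config or SimConfig(seed=0, night_epochs=20)
    stage_key = {"W": 0, "R": 1, "N": 2}[stage]
    rng = np.random.default_rng(np.random.SeedSequence((seed, stage_key)))
    epoch, labels = synthesize_epoch_audio(stage, cfg, rng)
    enh_cfg = EnhancementConfig()
    spectra = frame_spectra(epoch.frames)
    profile = update_noise_profile(epoch, None, enh_cfg, spectra=spectra)
    enhanced, enh_spec = enhance_epoch(epoch, profile, enh_cfg, spectra=spectra)
    feats = frame_features_matrix(enhanced.frames, spectra=enh_spec)
    return enhanced, feats, labels, profile


@pytest.fixture(scope="session")
def end_to_end_run(detector):
    """The full desk-scale recovery protocol, computed once per session:

    50 simulated nights of 300 epochs (seeds 1–50), cascades trained on the
    first 40 with thinned hidden layers, the last 10 staged as held-out test
    subjects. Returns per-night ground truth and both estimation passes.
    """
    from sonostage.pipeline import process_simulated_night, stage_night
    from sonostage.simulator import SimConfig
    from sonostage.staging import StagingTrainConfig, train_cascades

    nights = []
    for seed in range(1, 51):
        nf = process_simulated_night(
            SimConfig(seed=seed, night_epochs=300), detector)
        nights.append((nf.X, nf.hypnogram))
    cfg = StagingTrainConfig(seed=0, hidden_scale=0.1)
    rt, off, report = train_cascades(nights[:40], cfg)
    test = [(y, stage_night(X, rt, off)) for X, y in nights[40:]]
    return {"realtime": rt, "offline": off, "train_report": report,
            "test": test}


@pytest.fixture(scope="session")
def stage_epoch_bank(detector):
    """50 epochs per stage with detector curves and ground-truth labels."""
    bank = {}
    for stage in ("W", "R", "N"):
        epochs = []
        for i in range(50):
            enhanced, feats, labels, profile = make_stage_epoch(stage, i)
            curves = detector.predict_curves(feats)
            epochs.append({"epoch": enhanced, "feats": feats,
                           "labels": labels, "curves": curves,
                           "profile": profile})
        bank[stage] = epochs
    return bank
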