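"""Versioned serialized container for the trained detector and cascades."""

from __future__ import annotations

import joblib

from .detection import DetectorModel
from .features import registry_hash
from .nn import SoftmaxNetwork
from .staging import OfflineCascade, RealtimeCascade, _SubClassifier

FORMAT_VERSION = 1


def _sub_to_dict(sub: _SubClassifier) -> dict:
    return {"net": sub.net.to_dict(), "mean": sub.mean, "scale": sub.scale}


def _sub_from_dict(d: dict) -> _SubClassifier:
    return _SubClassifier(SoftmaxNetwork.from_dict(d["net"]),
                          d["mean"], d["scale"])


def save_models(path, detector: DetectorModel, realtime: RealtimeCascade,
                offline: OfflineCascade, config_hash: str = "",
                seed: int | None = None) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "registry_hash": registry_hash(),
        "config_hash": config_hash,
        "seed": seed,
        "detector": detector,
        "realtime": {
            "subs": {p: _sub_to_dict(s) for p, s in realtime.subs.items()},
            "impute_medians": realtime.impute_medians,
            "seed": realtime.seed,
            "hidden_scale": realtime.hidden_scale,
        },
        "offline": {
            "subs": {p: _sub_to_dict(s) for p, s in offline.subs.items()},
            "seed": offline.seed,
            "hidden_scale": offline.hidden_scale,
        },
    }
    joblib.dump(payload, path)


def load_models(path):
    payload = joblib.load(path)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported model container version")
    if payload.get("registry_hash") != registry_hash():
        raise ValueError("model was trained with a different feature registry")
    rt = RealtimeCascade(
        {p: _sub_from_dict(d) for p, d in payload["realtime"]["subs"].items()},
        payload["realtime"]["impute_medians"],
        seed=payload["realtime"]["seed"],
        hidden_scale=payload["realtime"]["hidden_scale"],
    )
    off = OfflineCascade(
        {p: _sub_from_dict(d) for p, d in payload["offline"]["subs"].items()},
        seed=payload["offline"]["seed"],
        hidden_scale=payload["offline"]["hidden_scale"],
    )
    return payload["detector"], rt, off, payload
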