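"""Cascaded real-time and offline macro-sleep-stage classifiers.

The real-time classifier C(r) maps the feature matrix X (one 67-vector per
30-s epoch) to wake/REM/NREM scores using only the current and past epochs.
It is a cascade of six period sub-classifiers: the first five epochs are
declared wake outright (recording starts with the subject awake, lights off),
and later epochs use progressively longer lookback windows — 5, 20, 50, 100
and 200 epochs — the longest spanning a full ~100-min sleep cycle:

    period 1:        t ≤ 5      rule 'Wake'        (no network)
    period 2:   5 <  t ≤ 20     lookback   5, hidden 100
    period 3:  20 <  t ≤ 50     lookback  20, hidden 400
    period 4:  50 <  t ≤ 100    lookback  50, hidden 1000
    period 5: 100 <  t ≤ 200    lookback 100, hidden 1000
    period 6: 200 <  t          lookback 200, hidden 1000

The offline classifier C(o) runs backward over the completed night's
real-time score sequence, using "future" scores to revise each epoch; the
last five epochs keep their real-time estimate:

    period 1:  T−5  ≤ t         pass-through       (no network)
    period 2:  T−20 ≤ t < T−5   lookahead   5, hidden  20
    period 3:  T−50 ≤ t < T−20  lookahead  20, hidden  50
    period 4: T−100 ≤ t < T−50  lookahead  50, hidden 100
    period 5: T−200 ≤ t < T−100 lookahead 100, hidden 200
    period 6:    0  < t < T−200 lookahead 200, hidden 200

Each sub-classifier is a one-hidden-layer tangent-sigmoid network with a
softmax output (see :mod:`sonostage.nn`). Lookback/lookahead windows include
the current epoch. Because the period conditions are evaluated first-match in
the order above, the selected window always fits inside the night, also for
short nights where the later inequalities become vacuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import N_FEATURES, registry_hash
from .nn import SoftmaxNetwork

STAGES: tuple[str, ...] = ("W", "R", "N")
STAGE_TO_INT = {s: i for i, s in enumerate(STAGES)}
N_STAGES = 3


def stages_to_ints(labels) -> np.ndarray:
    arr = np.asarray(labels)
    try:
        return np.array([STAGE_TO_INT[str(s)] for s in arr], dtype=int)
    except KeyError as e:
        raise ValueError(f"unknown stage label {e.args[0]!r}") from None


@dataclass(frozen=True)
class PeriodSpec:
    period: int
    window: int        # lookback (real-time) or lookahead (offline), epochs
    hidden: int        # hidden units of the displayed equation


REALTIME_CASCADE_SPEC: tuple[PeriodSpec, ...] = (
    PeriodSpec(1, 0, 0),
    PeriodSpec(2, 5, 100),
    PeriodSpec(3, 20, 400),
    PeriodSpec(4, 50, 1000),
    PeriodSpec(5, 100, 1000),
    PeriodSpec(6, 200, 1000),
)
OFFLINE_CASCADE_SPEC: tuple[PeriodSpec, ...] = (
    PeriodSpec(1, 0, 0),
    PeriodSpec(2, 5, 20),
    PeriodSpec(3, 20, 50),
    PeriodSpec(4, 50, 100),
    PeriodSpec(5, 100, 200),
    PeriodSpec(6, 200, 200),
)
_RT_UPPER = (5, 20, 50, 100, 200)     # inclusive upper epoch bound per period


class CascadeTrainingError(RuntimeError):
    pass


def select_period_realtime(t: int) -> int:
    """Piecewise period index of the real-time cascade for epoch t (1-based)."""
    if t < 1:
        raise ValueError("epoch index t is 1-based")
    for p, upper in enumerate(_RT_UPPER, start=1):
        if t <= upper:
            return p
    return 6


def select_period_offline(t: int, T: int) -> int:
    """Period index of the offline cascade for epoch t of a T-epoch night.

    Conditions are checked period 1 → 6, first match wins, which guarantees
    the selected lookahead window t…t+k fits within the night.
    """
    if not 1 <= t <= T:
        raise ValueError("need 1 <= t <= T")
    for p, upper in enumerate(_RT_UPPER, start=1):
        if t >= T - upper:
            return p
    return 6


def build_realtime_input(X: np.ndarray, t: int, lookback: int) -> np.ndarray:
    """Concatenated feature vectors of epochs t−k … t (current included)."""
    X = np.asarray(X)
    if t - lookback < 1:
        raise ValueError(f"insufficient history: t={t}, lookback={lookback}")
    if t > X.shape[0]:
        raise ValueError("features for epoch t not available")
    return X[t - lookback - 1:t].reshape(-1)


def build_offline_input(rt_scores: np.ndarray, t: int, lookahead: int) -> np.ndarray:
    """Flattened real-time score triplets of epochs t … t+k, plus t itself."""
    rt_scores = np.asarray(rt_scores)
    T = rt_scores.shape[0]
    if t + lookahead > T:
        raise ValueError(f"insufficient lookahead: t={t}, k={lookahead}, T={T}")
    return np.concatenate([rt_scores[t - 1:t + lookahead].reshape(-1),
                           [float(t)]])


def scores_to_label(scores: np.ndarray) -> str:
    """Argmax stage; exact ties broken with fixed priority N > R > W."""
    s = np.asarray(scores, dtype=np.float64)
    rev = s[::-1]                      # (N, R, W): argmax takes the first max
    return STAGES[2 - int(np.argmax(rev))]


def scores_to_labels(scores: np.ndarray) -> np.ndarray:
    s = np.asarray(scores, dtype=np.float64)
    idx = 2 - np.argmax(s[:, ::-1], axis=1)
    return np.array(STAGES, dtype="<U1")[idx]


@dataclass
class _SubClassifier:
    net: SoftmaxNetwork
    mean: np.ndarray
    scale: np.ndarray

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        z = (inputs - self.mean) / self.scale
        return self.net.predict_proba(z.astype(np.float32))


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-9] = 1.0
    return mean, scale


@dataclass
class RealtimeCascade:
    """Trained causal cascade; period 1 is the constant-wake rule."""

    subs: dict[int, _SubClassifier]
    impute_medians: np.ndarray
    seed: int
    hidden_scale: float = 1.0
    registry: str = field(default_factory=registry_hash)
    format_version: int = 1

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=np.float64)
        nan = ~np.isfinite(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.impute_medians, X.shape)[nan]
        return X

    def scores_for_night(self, X: np.ndarray) -> np.ndarray:
        """(T, 3) wake/REM/NREM scores; epoch t uses only rows 1…t of X."""
        X = self._impute(X)
        T = X.shape[0]
        out = np.zeros((T, N_STAGES))
        out[: min(5, T), 0] = 1.0
        by_period: dict[int, list[int]] = {}
        for t in range(6, T + 1):
            by_period.setdefault(select_period_realtime(t), []).append(t)
        for p, ts in by_period.items():
            k = REALTIME_CASCADE_SPEC[p - 1].window
            if p not in self.subs:
                raise CascadeTrainingError(
                    f"real-time period {p} sub-classifier is untrained")
            batch = np.stack([build_realtime_input(X, t, k) for t in ts])
            out[np.asarray(ts) - 1] = self.subs[p].predict(batch)
        return out

    def classify_epoch(self, X: np.ndarray, t: int) -> np.ndarray:
        """Scores for epoch t; strictly causal (only X[:t] is consulted)."""
        if t < 1:
            raise ValueError("epoch index t is 1-based")
        if t <= 5:
            return np.array([1.0, 0.0, 0.0])
        X_past = self._impute(np.asarray(X)[:t])
        p = select_period_realtime(t)
        if p not in self.subs:
            raise CascadeTrainingError(
                f"real-time period {p} sub-classifier is untrained")
        k = REALTIME_CASCADE_SPEC[p - 1].window
        return self.subs[p].predict(build_realtime_input(X_past, t, k)[None, :])[0]


@dataclass
class OfflineCascade:
    """Backward pass over the real-time scores; last 5 epochs pass through."""

    subs: dict[int, _SubClassifier]
    seed: int
    hidden_scale: float = 1.0
    format_version: int = 1

    def scores_for_night(self, rt_scores: np.ndarray) -> np.ndarray:
        rt = np.asarray(rt_scores, dtype=np.float64)
        T = rt.shape[0]
        out = rt.copy()
        if T < 6:
            return out
        by_period: dict[int, list[int]] = {}
        for t in range(T, 0, -1):           # backward in time
            p = select_period_offline(t, T)
            if p == 1:
                continue
            by_period.setdefault(p, []).append(t)
        for p, ts in by_period.items():
            k = OFFLINE_CASCADE_SPEC[p - 1].window
            if p not in self.subs:
                raise CascadeTrainingError(
                    f"offline period {p} sub-classifier is untrained")
            batch = np.stack([build_offline_input(rt, t, k) for t in ts])
            out[np.asarray(ts) - 1] = self.subs[p].predict(batch)
        return out


def classify_epoch_realtime(X: np.ndarray, t: int,
                            cascade: RealtimeCascade) -> np.ndarray:
    """Real-time stage scores for epoch t (strictly causal)."""
    return cascade.classify_epoch(X, t)


def classify_night_offline(rt_scores: np.ndarray, T: int,
                           cascade: OfflineCascade) -> np.ndarray:
    """Backward offline pass over a completed night's real-time scores."""
    rt_scores = np.asarray(rt_scores)
    if rt_scores.shape[0] != T:
        raise ValueError("T must equal the number of real-time score rows")
    return cascade.scores_for_night(rt_scores)


@dataclass
class StagingTrainConfig:
    """Training hyperparameters for both cascades.

    ``hidden_scale`` multiplies every hidden-layer size (floored at
    ``min_hidden``); 1.0 reproduces the canonical architecture, smaller values
    give the reduced preset used for quick runs. The canonical neuron counts
    themselves are fixed constants (:data:`REALTIME_CASCADE_SPEC`).
    """

    seed: int = 0
    dev_fraction: float = 0.2
    hidden_scale: float = 1.0
    min_hidden: int = 8
    max_iter: int = 60
    offline_max_iter: int = 120
    batch_size: int = 128
    lr: float = 1e-3
    patience: int = 8
    l2: float = 1e-4


@dataclass
class TrainingReport:
    """Development-set accuracies of both passes.

    The real-time figure is honest held-out performance (development nights
    never enter real-time sub-classifier fits). The offline figure is mildly
    optimistic: development nights' score sequences are part of offline
    training, so only a fresh test night measures it without bias.
    """

    dev_accuracy_realtime: float
    dev_accuracy_offline: float
    n_train_nights: int
    n_dev_nights: int
    class_counts: dict[str, int]


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-class-frequency loss weights, clipped to [0.25, 4].

    Unclipped weights explode when a stage is nearly absent from a cascade
    period (e.g. wake in the middle of the night), letting a handful of
    epochs dominate the loss; the clip keeps the rebalancing bounded.
    """
    counts = np.bincount(y, minlength=N_STAGES).astype(np.float64)
    w = np.zeros(N_STAGES)
    present = counts > 0
    w[present] = np.clip(counts.sum() / (N_STAGES * counts[present]), 0.25, 4.0)
    return w


def _collect_realtime(nights_X, nights_y, period: int):
    k = REALTIME_CASCADE_SPEC[period - 1].window
    rows, labs = [], []
    for X, y in zip(nights_X, nights_y):
        T = X.shape[0]
        ts = [t for t in range(6, T + 1) if select_period_realtime(t) == period]
        rows.extend(build_realtime_input(X, t, k) for t in ts)
        labs.extend(y[t - 1] for t in ts)
    return rows, labs


def _collect_offline(nights_rt, nights_y, period: int):
    k = OFFLINE_CASCADE_SPEC[period - 1].window
    rows, labs = [], []
    for rt, y in zip(nights_rt, nights_y):
        T = rt.shape[0]
        ts = [t for t in range(1, T + 1) if select_period_offline(t, T) == period]
        rows.extend(build_offline_input(rt, t, k) for t in ts)
        labs.extend(y[t - 1] for t in ts)
    return rows, labs


def _train_sub(rows, labs, dev_rows, dev_labs, hidden, cfg, tag,
               class_weight=True, max_iter=None):
    if not rows:
        raise CascadeTrainingError(
            f"no training epochs for {tag}: nights are too short")
    X = np.stack(rows).astype(np.float32)
    y = np.asarray(labs, dtype=int)
    mean, scale = _fit_scaler(X.astype(np.float64))
    Xz = ((X - mean) / scale).astype(np.float32)
    Xv = yv = None
    if dev_rows:
        Xv = ((np.stack(dev_rows) - mean) / scale).astype(np.float32)
        yv = np.asarray(dev_labs, dtype=int)
    net = SoftmaxNetwork(X.shape[1], hidden, N_STAGES,
                         seed=int(cfg.seed) % 2**31, l2=cfg.l2)
    net.fit(Xz, y, class_weight=_class_weights(y) if class_weight else None,
            X_val=Xv, y_val=yv,
            max_iter=max_iter or cfg.max_iter, batch_size=cfg.batch_size,
            lr=cfg.lr, patience=cfg.patience)
    return _SubClassifier(net, mean, scale)


def train_cascades(
    design_nights: list[tuple[np.ndarray, np.ndarray]],
    config: StagingTrainConfig | None = None,
) -> tuple[RealtimeCascade, OfflineCascade, TrainingReport]:
    """Train both cascades from design nights (feature matrix, hypnogram).

    Nights are split 80/20 at the *subject* level into training and
    development sets (never epoch-level); development nights drive early
    stopping. Classes are weighted by inverse frequency (NREM dominates real
    hypnograms). The offline cascade is trained afterward on the trained
    real-time cascade's score sequences. All randomness derives from
    ``config.seed``.
    """
    cfg = config or StagingTrainConfig()
    if len(design_nights) < 5:
        raise ValueError("need at least 5 design nights for a subject-level split")
    nights_X = [np.asarray(X, dtype=np.float64) for X, _ in design_nights]
    nights_y = [stages_to_ints(y) for _, y in design_nights]
    for X, y in zip(nights_X, nights_y):
        if X.shape[1] != N_FEATURES or X.shape[0] != y.shape[0]:
            raise ValueError("each night needs a (T, 67) matrix and T labels")
    all_train_labels = np.concatenate(nights_y)
    missing = [STAGES[c] for c in range(N_STAGES)
               if not np.any(all_train_labels == c)]
    if missing:
        raise ValueError(f"stage(s) {missing} absent from training hypnograms")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(nights_X))
    n_dev = max(1, int(round(cfg.dev_fraction * len(nights_X))))
    dev_idx, train_idx = order[:n_dev], order[n_dev:]

    medians = np.nanmedian(np.vstack([nights_X[i] for i in train_idx]), axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)

    def imputed(i):
        X = nights_X[i].copy()
        nan = ~np.isfinite(X)
        X[nan] = np.broadcast_to(medians, X.shape)[nan]
        return X

    tX = [imputed(i) for i in train_idx]
    ty = [nights_y[i] for i in train_idx]
    dX = [imputed(i) for i in dev_idx]
    dy = [nights_y[i] for i in dev_idx]

    def hidden_units(spec: PeriodSpec) -> int:
        return max(cfg.min_hidden, int(round(spec.hidden * cfg.hidden_scale)))

    rt_subs: dict[int, _SubClassifier] = {}
    for spec in REALTIME_CASCADE_SPEC[1:]:
        rows, labs = _collect_realtime(tX, ty, spec.period)
        dev_rows, dev_labs = _collect_realtime(dX, dy, spec.period)
        rt_subs[spec.period] = _train_sub(
            rows, labs, dev_rows, dev_labs, hidden_units(spec), cfg,
            tag=f"real-time period {spec.period}")
    rt = RealtimeCascade(rt_subs, medians, seed=cfg.seed,
                         hidden_scale=cfg.hidden_scale)

    t_rt = [rt.scores_for_night(X) for X in tX]
    d_rt = [rt.scores_for_night(X) for X in dX]

    # The offline refinement trains on the real-time score sequences of the
    # whole design set (training + development nights): the development
    # nights contribute honestly noisy scores — the real-time cascade never
    # fit them directly — which the backward pass must learn to handle. Its
    # small networks train for a fixed budget without reweighting: class
    # imbalance was already corrected by the weighted real-time stage.
    all_rt = t_rt + d_rt
    all_y = ty + dy
    off_subs: dict[int, _SubClassifier] = {}
    for spec in OFFLINE_CASCADE_SPEC[1:]:
        rows, labs = _collect_offline(all_rt, all_y, spec.period)
        off_subs[spec.period] = _train_sub(
            rows, labs, [], [], hidden_units(spec), cfg,
            tag=f"offline period {spec.period}",
            class_weight=False, max_iter=cfg.offline_max_iter)
    off = OfflineCascade(off_subs, seed=cfg.seed, hidden_scale=cfg.hidden_scale)

    rt_correct = total = off_correct = 0
    for scores, y in zip(d_rt, dy):
        rt_correct += int(np.sum(stages_to_ints(scores_to_labels(scores)) == y))
        off_scores = off.scores_for_night(scores)
        off_correct += int(
            np.sum(stages_to_ints(scores_to_labels(off_scores)) == y))
        total += y.size
    counts = np.bincount(all_train_labels, minlength=N_STAGES)
    report = TrainingReport(
        dev_accuracy_realtime=rt_correct / total,
        dev_accuracy_offline=off_correct / total,
        n_train_nights=len(train_idx), n_dev_nights=len(dev_idx),
        class_counts={STAGES[i]: int(counts[i]) for i in range(N_STAGES)},
    )
    return rt, off, report
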