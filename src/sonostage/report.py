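"""Sleep-quality report: the eight standard parameters from a hypnogram.

All parameters operate on a 1-based sequence of 30-s epoch labels in
{W, R, N}. Sleep latency is measured from the start of the recording (the
recording is assumed to begin with the subject in bed), and WASO counts wake
strictly between sleep onset and the final awakening (wake after the last
sleep epoch is terminal wake, not WASO), so that

    SL + TST + WASO + terminal wake  ==  total recording time, exactly.

REM and NREM percentages use total sleep time as the denominator by default
(the textbook definition); a time-in-bed denominator is available via
``percent_denominator="recording"``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .staging import STAGES

EPOCH_MINUTES = 0.5

# REM-cycle merging defaults: REM runs closer than 30 min are one cycle, and
# a cluster must contain at least 2 REM epochs (1 min) to count.
REM_CYCLE_MERGE_GAP_EPOCHS = 60
REM_CYCLE_MIN_EPOCHS = 2


def _validate(h) -> np.ndarray:
    arr = np.asarray(h, dtype="<U1")
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("hypnogram must be a non-empty 1-D label sequence")
    bad = set(arr.tolist()) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    return arr


@dataclass(frozen=True)
class SleepReport:
    """The eight sleep-quality parameters, units embedded in field names."""

    tst_min: float          # total sleep time
    sl_min: float | None    # sleep latency (None if no sleep at all)
    se_pct: float           # sleep efficiency
    waso_min: float         # wake after sleep onset, before final awakening
    rl_min: float | None    # REM latency (None if no REM)
    rp_pct: float           # REM percentage
    np_pct: float           # NREM percentage
    rc_count: int           # number of REM cycles
    recording_min: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_csv(self, path) -> None:
        """One-row CSV with units embedded in the column names."""
        d = self.to_dict()
        with open(path, "w") as fh:
            fh.write(",".join(d.keys()) + "\n")
            fh.write(",".join("" if v is None else str(v)
                              for v in d.values()) + "\n")


def count_rem_cycles(
    h,
    merge_gap_epochs: int = REM_CYCLE_MERGE_GAP_EPOCHS,
    min_cluster_epochs: int = REM_CYCLE_MIN_EPOCHS,
) -> int:
    """Number of REM cycles: maximal R runs merged across gaps shorter than
    ``merge_gap_epochs`` non-R epochs, discarding merged clusters with fewer
    than ``min_cluster_epochs`` R epochs."""
    arr = _validate(h)
    is_r = arr == "R"
    runs: list[tuple[int, int]] = []       # (start, end) exclusive
    start = None
    for i, r in enumerate(is_r):
        if r and start is None:
            start = i
        elif not r and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(arr)))
    if not runs:
        return 0
    clusters: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        if run[0] - clusters[-1][-1][1] < merge_gap_epochs:
            clusters[-1].append(run)
        else:
            clusters.append([run])
    return sum(
        1 for cl in clusters
        if sum(e - s for s, e in cl) >= min_cluster_epochs
    )


def compute_report(h, percent_denominator: str = "tst") -> SleepReport:
    """Compute the eight-parameter sleep report from a hypnogram.

    TST = minutes scored R or N; SL = minutes from recording start to the
    first non-wake epoch; SE = 100·TST/recording time; WASO = wake minutes
    after sleep onset and before the final awakening; RL = minutes from start
    to the first R epoch (missing without REM); RP/NP = 100·R/TST and
    100·N/TST (or /recording with ``percent_denominator="recording"``);
    RC from :func:`count_rem_cycles`.
    """
    if percent_denominator not in ("tst", "recording"):
        raise ValueError("percent_denominator must be 'tst' or 'recording'")
    arr = _validate(h)
    T = arr.size
    recording_min = T * EPOCH_MINUTES
    sleep = arr != "W"
    n_r = int(np.sum(arr == "R"))
    n_n = int(np.sum(arr == "N"))
    tst = (n_r + n_n) * EPOCH_MINUTES
    se = 100.0 * tst / recording_min

    if not sleep.any():
        return SleepReport(0.0, None, 0.0, 0.0, None, 0.0, 0.0, 0,
                           recording_min)

    onset = int(np.argmax(sleep))                 # first non-W epoch
    last_sleep = T - 1 - int(np.argmax(sleep[::-1]))
    sl = onset * EPOCH_MINUTES
    waso = float(np.sum(arr[onset:last_sleep + 1] == "W")) * EPOCH_MINUTES
    r_idx = np.flatnonzero(arr == "R")
    rl = float(r_idx[0]) * EPOCH_MINUTES if r_idx.size else None
    denom = tst if percent_denominator == "tst" else recording_min
    rp = 100.0 * n_r * EPOCH_MINUTES / denom if denom > 0 else 0.0
    np_ = 100.0 * n_n * EPOCH_MINUTES / denom if denom > 0 else 0.0
    return SleepReport(
        tst_min=tst, sl_min=sl, se_pct=se, waso_min=waso, rl_min=rl,
        rp_pct=rp, np_pct=np_, rc_count=count_rem_cycles(arr),
        recording_min=recording_min,
    )
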