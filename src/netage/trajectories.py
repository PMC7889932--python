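"""From detection tables to velocities, proximity events, trophallaxis
candidates, and per-contact velocity-change records.

Detections are binned to the nominal frame grid (1/frame_rate seconds);
proximity requires tag distance below a threshold over a minimum number of
strictly consecutive co-detected frames on the same comb side. A single
missing frame breaks a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: thorax-to-head offset along the body axis, mm
HEAD_OFFSET_MM = 3.19

#: candidate gate on thorax distance for trophallaxis scoring, cm
TROPHALLAXIS_GATE_CM = (0.731, 1.204)


# ---------------------------------------------------------------------------
# velocity


def compute_velocity(detections: pd.DataFrame, kernel: int = 3) -> pd.DataFrame:
    """Per-bee movement speed with a rolling median filter.

    Speed at step k is the Euclidean distance between consecutive detections
    divided by the elapsed time; the series is median-filtered with the given
    odd kernel (endpoints use shrunken windows). Duplicate (bee, timestamp)
    rows must have been dropped beforehand. Returns a DataFrame with columns
    ``bee_id, timestamp_utc, day, speed`` (mm/s).
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be a positive odd count")
    out = []
    for bee, grp in detections.groupby("bee_id", sort=True):
        if len(grp) < 2:
            continue
        t = grp["timestamp_utc"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone timestamps for bee {bee}")
        xy = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        speed = np.linalg.norm(np.diff(xy, axis=0), axis=1) / np.diff(t)
        speed = (pd.Series(speed).rolling(kernel, center=True, min_periods=1)
                 .median().to_numpy())
        out.append(pd.DataFrame({
            "bee_id": bee,
            "timestamp_utc": t[1:],
            "day": grp["day"].to_numpy()[1:],
            "speed": speed,
        }))
    if not out:
        return pd.DataFrame(columns=["bee_id", "timestamp_utc", "day", "speed"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# proximity events


@dataclass(frozen=True)
class ProximityEvent:
    """A maximal run of consecutive co-detected frames below the distance gate."""

    bee_a: int
    bee_b: int
    day: int
    start: float
    end: float
    n_frames: int


def detect_proximity_events(detections: pd.DataFrame, frame_rate: float = 3.0,
                            max_dist_cm: float = 2.0, min_frames: int = 3
                            ) -> pd.DataFrame:
    """Find proximity events: pairs closer than ``max_dist_cm`` over at least
    ``min_frames`` consecutive frames on the same comb side.

    Detections are snapped to the frame grid ``round(t * frame_rate)``.
    Downstream affinity construction uses event *counts*, not durations, to
    limit the influence of bees resting next to each other. Returns a
    DataFrame ``bee_a, bee_b, day, start_utc, end_utc, n_frames`` with
    ``bee_a < bee_b``.
    """
    max_dist_mm = max_dist_cm * 10.0
    det = detections.copy()
    det["frame"] = np.round(det["timestamp_utc"].to_numpy() * frame_rate).astype(np.int64)
    # per-side frame stride: 1 for a single-side stream, 2 when sides
    # alternate between grid frames
    stride = {}
    for side, grp in det.groupby("side"):
        diffs = np.diff(np.unique(grp["frame"].to_numpy()))
        stride[side] = int(np.min(diffs)) if diffs.size else 1
    runs: dict[tuple, list] = {}
    events = []

    def _flush(key, run):
        if run["n"] >= min_frames:
            a, b = key[:2]
            events.append((a, b, run["day"], run["start"], run["end"], run["n"]))

    for (frame, side), grp in det.groupby(["frame", "side"], sort=True):
        if len(grp) < 2:
            continue
        xy = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        ids = grp["bee_id"].to_numpy()
        ts = grp["timestamp_utc"].to_numpy(dtype=float)
        days = grp["day"].to_numpy()
        pairs = cKDTree(xy).query_pairs(max_dist_mm, output_type="ndarray")
        current = set()
        for i, j in pairs:
            a, b = sorted((ids[i], ids[j]))
            if a == b:
                continue
            key = (a, b, side)
            current.add(key)
            run = runs.get(key)
            if run is not None and frame == run["last_frame"] + stride[side]:
                run["n"] += 1
                run["end"] = ts[i]
                run["last_frame"] = frame
            else:
                if run is not None:
                    _flush(key, run)
                runs[key] = {"n": 1, "start": ts[i], "end": ts[i],
                             "day": days[i], "last_frame": frame}
        # close runs that were not extended this frame and cannot continue
        stale = [k for k, r in runs.items()
                 if k[2] == side and k not in current and r["last_frame"] < frame]
        for k in stale:
            _flush(k, runs.pop(k))
    for key, run in runs.items():
        _flush(key, run)
    df = pd.DataFrame(events, columns=["bee_a", "bee_b", "day", "start_utc",
                                       "end_utc", "n_frames"])
    return df.sort_values(["day", "start_utc", "bee_a", "bee_b"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# trophallaxis stage 1


@dataclass(frozen=True)
class PairGeometry:
    """Geometric features of a co-detected pair used by the stage-1 classifier."""

    thorax_distance_cm: float
    head_distance_cm: float
    relative_orientation: float


def pair_geometry(xy_i, alpha_i: float, xy_j, alpha_j: float) -> PairGeometry:
    """Thorax distance, approximate head distance, and heading dot product.

    The head position is the thorax position advanced 3.19 mm along the body
    axis; the relative orientation is the dot product of the two unit heading
    vectors (1 = parallel, -1 = facing each other head-on... i.e. antiparallel).
    """
    xy_i = np.asarray(xy_i, dtype=float)
    xy_j = np.asarray(xy_j, dtype=float)
    hi = xy_i + HEAD_OFFSET_MM * np.array([np.cos(alpha_i), np.sin(alpha_i)])
    hj = xy_j + HEAD_OFFSET_MM * np.array([np.cos(alpha_j), np.sin(alpha_j)])
    return PairGeometry(
        thorax_distance_cm=float(np.linalg.norm(xy_i - xy_j)) / 10.0,
        head_distance_cm=float(np.linalg.norm(hi - hj)) / 10.0,
        relative_orientation=float(np.cos(alpha_i) * np.cos(alpha_j)
                                   + np.sin(alpha_i) * np.sin(alpha_j)),
    )


class TrophallaxisStage1:
    """Fast logistic gate for trophallaxis candidates.

    Pairs with thorax distance outside the candidate gate
    [0.731, 1.204] cm are rejected without scoring. Inside the gate, a
    logistic regression on (thorax distance, head distance, relative
    orientation) yields a probability; the decision threshold is calibrated
    on validation data to reach a target recall. A second-stage classifier
    (any callable mapping geometry rows to scores) can be plugged in; the
    default passes the stage-1 probability through.
    """

    FEATURES = ["thorax_distance_cm", "head_distance_cm", "relative_orientation"]

    def __init__(self, gate_cm: tuple = TROPHALLAXIS_GATE_CM, stage2=None):
        self.gate_cm = gate_cm
        self.stage2 = stage2
        self._model = None
        self.threshold = 0.5

    def fit(self, geometry: pd.DataFrame, labels, target_recall: float = 0.85,
            seed: int = 0) -> "TrophallaxisStage1":
        """Fit on labeled gated pairs; calibrate the threshold to a recall."""
        from sklearn.linear_model import LogisticRegression
        X = geometry[self.FEATURES].to_numpy(dtype=float)
        y = np.asarray(labels, dtype=int)
        self._model = LogisticRegression(max_iter=1000, random_state=seed).fit(X, y)
        probs = self._model.predict_proba(X)[:, 1]
        pos = np.sort(probs[y == 1])
        if pos.size:
            # highest threshold that keeps >= target_recall of positives
            k = int(np.floor((1.0 - target_recall) * pos.size))
            self.threshold = float(pos[min(k, pos.size - 1)])
        return self

    def predict_proba(self, geometry: pd.DataFrame) -> np.ndarray:
        """Probabilities for gated rows; NaN for rows rejected by the gate."""
        if self._model is None:
            raise RuntimeError("classifier not fitted")
        X = geometry[self.FEATURES].to_numpy(dtype=float)
        gated = (X[:, 0] >= self.gate_cm[0]) & (X[:, 0] <= self.gate_cm[1])
        out = np.full(len(X), np.nan)
        if gated.any():
            p = self._model.predict_proba(X[gated])[:, 1]
            if self.stage2 is not None:
                p = np.asarray(self.stage2(geometry[gated], p), dtype=float)
            out[gated] = p
        return out

    def predict(self, geometry: pd.DataFrame) -> np.ndarray:
        p = self.predict_proba(geometry)
        return (p >= self.threshold) & ~np.isnan(p)


# ---------------------------------------------------------------------------
# interaction effects


def extract_interaction_effects(events: pd.DataFrame, velocities: pd.DataFrame,
                                max_duration_s: float = 60.0, min_gap_s: float = 5.0,
                                window_s: float = 30.0) -> pd.DataFrame:
    """Speed change of each partner across a proximity event.

    For each qualifying event and each partner as focal, the record holds the
    difference of mean speeds in the 30 s windows after vs. before the event
    (``delta_mean``, mm/s) and the analogous difference of summed speeds
    (``delta_cumulative``, mm). Events longer than ``max_duration_s`` (resting
    pairs) or starting within ``min_gap_s`` of the same pair's previous event
    are skipped, as are focals with no velocity samples in either window.
    """
    vel_by_bee = {bee: (grp["timestamp_utc"].to_numpy(dtype=float),
                        grp["speed"].to_numpy(dtype=float))
                  for bee, grp in velocities.groupby("bee_id")}
    records = []
    events = events.sort_values(["bee_a", "bee_b", "start_utc"])
    last_end: dict[tuple, float] = {}
    for ev in events.itertuples(index=False):
        pair = (ev.bee_a, ev.bee_b)
        prev = last_end.get(pair)
        last_end[pair] = ev.end_utc
        if ev.end_utc - ev.start_utc > max_duration_s:
            continue
        if prev is not None and ev.start_utc - prev < min_gap_s:
            continue
        for focal, partner in ((ev.bee_a, ev.bee_b), (ev.bee_b, ev.bee_a)):
            if focal not in vel_by_bee:
                continue
            t, v = vel_by_bee[focal]
            before = v[(t >= ev.start_utc - window_s) & (t < ev.start_utc)]
            after = v[(t > ev.end_utc) & (t <= ev.end_utc + window_s)]
            if before.size == 0 or after.size == 0:
                logger.debug("no velocity samples around event for bee %s", focal)
                continue
            records.append((focal, partner, ev.day, ev.start_utc, ev.end_utc,
                            float(after.mean() - before.mean()),
                            float(after.sum() - before.sum())))
    return pd.DataFrame(records, columns=[
        "focal", "partner", "day", "start_utc", "end_utc",
        "delta_mean", "delta_cumulative"])
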