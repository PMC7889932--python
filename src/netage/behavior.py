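"""Task descriptor and movement metrics.

The task descriptor is the fraction of a bee's sampled positions (at most
one high-confidence detection per minute) falling into each of the four
annotated nest areas (brood, dance floor, honey storage, exit region);
samples outside every area are ignored. Movement metrics are computed from
median-filtered velocities over a 3-day rolling window: circadian power
(variance explained by a 24 h sinusoid), the clock time of peak activity,
and mean day / night speeds over fixed UTC windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .config import AREAS
from .simulate import DAY_SECONDS

#: overlap resolution priority (first match wins)
AREA_PRIORITY = ("exit", "dance_floor", "brood", "honey")

DAY_WINDOW_UTC = (9.0, 18.0)     # daytime velocity window, hours UTC
NIGHT_WINDOW_UTC = (21.0, 6.0)   # wraps midnight


def load_area_maps(records: list[dict]) -> dict[int, list[tuple[str, int, Polygon]]]:
    """Group {day, side, label, polygon} records into per-day polygon lists."""
    by_day: dict[int, list] = {}
    for rec in records:
        by_day.setdefault(int(rec["day"]), []).append(
            (rec["label"], int(rec.get("side", 0)), Polygon(rec["polygon"])))
    return by_day


def compute_task_descriptor(detections: pd.DataFrame, area_maps,
                            confidence_min: float = 0.9) -> pd.DataFrame:
    """Per (bee, day) fractions of minute-sampled positions per nest area.

    For each bee and minute, the highest-confidence detection above
    ``confidence_min`` is sampled. Membership uses the even-odd rule with
    boundary points counted inside; overlapping annotations resolve by the
    priority order exit > dance_floor > brood > honey. Bee-days with no
    in-area samples are omitted (the descriptor is undefined there).

    Returns ``bee_id, day, p_brood, p_dance_floor, p_honey, p_exit,
    n_samples``.
    """
    if isinstance(area_maps, list):
        area_maps = load_area_maps(area_maps)
    det = detections[detections["confidence"] > confidence_min].copy()
    det["minute"] = (det["timestamp_utc"] // 60).astype(np.int64)
    det = (det.sort_values("confidence", kind="mergesort")
           .groupby(["bee_id", "day", "minute"], as_index=False).last())
    rows = []
    for day, grp in det.groupby("day"):
        if day not in area_maps:
            raise ValueError(f"no area map for day {day}")
        polys = {label: (side, poly) for label, side, poly in area_maps[day]}
        x = grp["x_mm"].to_numpy(dtype=float)
        y = grp["y_mm"].to_numpy(dtype=float)
        side = grp["side"].to_numpy()
        label_idx = np.full(len(grp), -1)
        for label in reversed(AREA_PRIORITY):  # earlier priority overwrites
            if label not in polys:
                continue
            a_side, poly = polys[label]
            inside = shapely.intersects_xy(poly, x, y) & (side == a_side)
            label_idx[inside] = AREAS.index(label)
        grp = grp.assign(area_idx=label_idx)
        for bee, bee_grp in grp.groupby("bee_id"):
            counts = np.bincount(bee_grp.loc[bee_grp["area_idx"] >= 0, "area_idx"],
                                 minlength=len(AREAS))
            n = counts.sum()
            if n == 0:
                continue
            rows.append((bee, day, *(counts / n), int(n)))
    return pd.DataFrame(rows, columns=["bee_id", "day"] +
                        [f"p_{a}" for a in AREAS] + ["n_samples"])


# ---------------------------------------------------------------------------
# circadian metrics


def _window_samples(velocity: pd.DataFrame, bee, center_day: int,
                    window_days: int) -> tuple[np.ndarray, np.ndarray]:
    lo = (center_day - (window_days - 1) // 2) * DAY_SECONDS
    hi = lo + window_days * DAY_SECONDS
    v = velocity[(velocity["bee_id"] == bee)
                 & (velocity["timestamp_utc"] >= lo)
                 & (velocity["timestamp_utc"] < hi)]
    return v["timestamp_utc"].to_numpy(dtype=float), v["speed"].to_numpy(dtype=float)


def circadian_power(velocity: pd.DataFrame, bee, center_day: int,
                    window_days: int = 3) -> dict:
    """Fit a fixed-frequency 24 h sinusoid to a bee's velocities.

    Least squares of a sin(wt) + b cos(wt) + c with w = 2 pi / 24 h over a
    ``window_days`` interval centered on ``center_day``. The circadian power
    is P = 1 - SSE_sine / SSE_constant, the fraction of velocity variance
    explained by the oscillation (0 for a constant series, 1 for a pure
    sinusoid); ``peak_time_h`` is the UTC hour of the fitted maximum.
    Returns NaNs when the fit is under-determined (< 4 samples).
    """
    t, v = _window_samples(velocity, bee, center_day, window_days)
    if t.size < 4 or np.ptp(v) == 0:
        p = 0.0 if (t.size >= 4 and v.size) else np.nan
        return {"power": p, "peak_time_h": np.nan,
                "sse_sine": np.nan, "sse_constant": np.nan}
    omega = 2 * np.pi / DAY_SECONDS
    X = np.column_stack([np.sin(omega * t), np.cos(omega * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    sse_sine = float(resid @ resid)
    dev = v - v.mean()
    sse_const = float(dev @ dev)
    power = 1.0 - sse_sine / sse_const if sse_const > 0 else 0.0
    a, b, _ = coef
    # a sin(wt) + b cos(wt) peaks where wt = pi/2 - atan2(b, a) ... solve:
    # = R sin(wt + phi), phi = atan2(b, a); max at wt = pi/2 - phi
    peak_t = (np.pi / 2 - np.arctan2(b, a)) / omega
    peak_h = (peak_t / 3600.0) % 24.0
    return {"power": float(power), "peak_time_h": float(peak_h),
            "sse_sine": sse_sine, "sse_constant": sse_const}


def day_night_velocity(velocity: pd.DataFrame, bee, center_day: int,
                       window_days: int = 3) -> tuple[float, float]:
    """Mean speeds in the 09:00-18:00 and 21:00-06:00 UTC windows."""
    t, v = _window_samples(velocity, bee, center_day, window_days)
    if t.size == 0:
        return (np.nan, np.nan)
    hours = (t % DAY_SECONDS) / 3600.0
    day_mask = (hours >= DAY_WINDOW_UTC[0]) & (hours < DAY_WINDOW_UTC[1])
    night_mask = (hours >= NIGHT_WINDOW_UTC[0]) | (hours < NIGHT_WINDOW_UTC[1])
    day_v = float(v[day_mask].mean()) if day_mask.any() else np.nan
    night_v = float(v[night_mask].mean()) if night_mask.any() else np.nan
    return (day_v, night_v)


def movement_metrics(velocity: pd.DataFrame, days, window_days: int = 3
                     ) -> pd.DataFrame:
    """Circadian power, peak time and day/night speeds for all bees and days."""
    rows = []
    for bee in velocity["bee_id"].unique():
        for day in days:
            c = circadian_power(velocity, bee, day, window_days)
            dv, nv = day_night_velocity(velocity, bee, day, window_days)
            rows.append((bee, day, c["power"], c["peak_time_h"], dv, nv))
    return pd.DataFrame(rows, columns=["bee_id", "day", "power", "peak_time_h",
                                       "day_velocity", "night_velocity"])
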