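"""Synthetic colony generator with known ground truth.

Generates an age-structured colony in which each worker follows a latent
developmental role trajectory rho(b, t) in [0, 1] (0 = nurse-like,
1 = forager-like). Workers fall into three developmental clusters: an early
transition to the forager-like role, a late transition, or no transition
within the focal period. The latent role drives everything downstream:

* spatial occupancy over four task-associated nest areas (task mixture),
* a Gaussian role-similarity kernel for pairwise interaction rates,
* circadian modulation of movement speed for forager-like bees,
* and, after death, collapse of detections to a false-positive floor.

Every generated quantity is recorded in :class:`GroundTruth`, so each
pipeline stage has a recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .config import AREAS, CLUSTERS, ColonyConfig
from .networks import AffinityMatrix

DAY_SECONDS = 86400.0

#: columns of the on-disk detection table
DETECTION_COLUMNS = ["bee_id", "timestamp_utc", "day", "x_mm", "y_mm",
                     "orientation_rad", "side", "confidence"]


@dataclass
class GroundTruth:
    """Planted truth of a simulated colony.

    Attributes
    ----------
    bees : DataFrame
        One row per bee: ``bee_id, emergence_day, death_day, cluster,
        transition_day``. A bee is alive on day t iff
        ``emergence_day <= t < death_day``.
    roles : DataFrame
        ``bee_id, day, role`` for every alive focal day; the latent role is
        non-decreasing in time for each bee.
    task_mixture : DataFrame
        ``bee_id, day, p_brood, p_dance_floor, p_honey, p_exit`` (rows sum
        to 1) for every alive focal day.
    """

    bees: pd.DataFrame
    roles: pd.DataFrame
    task_mixture: pd.DataFrame

    def alive_on(self, day: int) -> list:
        b = self.bees
        mask = (b["emergence_day"] <= day) & (day < b["death_day"])
        return b.loc[mask, "bee_id"].tolist()

    def roles_on(self, day: int) -> pd.Series:
        r = self.roles[self.roles["day"] == day]
        return r.set_index("bee_id")["role"]

    def biological_ages(self) -> pd.DataFrame:
        """Per (bee, day) biological age in days, over alive focal days."""
        out = self.roles[["bee_id", "day"]].merge(
            self.bees[["bee_id", "emergence_day"]], on="bee_id")
        out["age"] = out["day"] - out["emergence_day"]
        return out[["bee_id", "day", "age"]]


# ---------------------------------------------------------------------------
# ground truth


def _rng(config: ColonyConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def role_trajectory(age: np.ndarray, transition_day: float, scale: float) -> np.ndarray:
    """Logistic latent role in day-of-life; transition_day = inf means never."""
    age = np.asarray(age, dtype=float)
    if np.isinf(transition_day):
        return np.zeros_like(age)
    return 1.0 / (1.0 + np.exp(-(age - transition_day) / scale))


def task_mixture_from_role(rho: np.ndarray) -> np.ndarray:
    """Map latent role to occupancy probabilities over the four areas.

    Nurse-like bees sit on the brood nest; forager-like bees shift to the
    dance floor and exit; honey storage attracts a constant share.
    Returns an array of shape (..., 4) in the order of :data:`AREAS`.
    """
    rho = np.asarray(rho, dtype=float)
    w = np.stack([
        0.10 + 0.90 * (1.0 - rho),   # brood
        0.05 + 0.75 * rho,           # dance_floor
        np.full_like(rho, 0.15),     # honey
        0.05 + 0.25 * rho,           # exit
    ], axis=-1)
    return w / w.sum(axis=-1, keepdims=True)


def simulate_ground_truth(config: ColonyConfig) -> GroundTruth:
    """Draw emergence days, clusters, lifespans and role/mixture tables."""
    rng = _rng(config, 0)
    emergence = np.concatenate([
        np.full(size, day, dtype=int) for day, size in config.emergence_schedule
    ])
    n = emergence.size
    bee_ids = np.arange(n)
    cluster_idx = rng.choice(3, size=n, p=np.asarray(config.cluster_probs, dtype=float))
    means = np.asarray(config.transition_day_means, dtype=float)
    sds = np.asarray(config.transition_day_sds, dtype=float)
    transition = np.where(
        np.isinf(means[cluster_idx]), np.inf,
        np.maximum(1.0, means[cluster_idx] + sds[cluster_idx] * rng.standard_normal(n)))
    lifespan = config.lifespan_prior_mean + config.lifespan_prior_sd * rng.standard_normal(n)
    lifespan = np.maximum(1, np.round(lifespan)).astype(int)
    bees = pd.DataFrame({
        "bee_id": bee_ids,
        "emergence_day": emergence,
        "death_day": emergence + lifespan,
        "cluster": [CLUSTERS[c] for c in cluster_idx],
        "transition_day": transition,
    })
    rows = []
    for row in bees.itertuples(index=False):
        lo = max(row.emergence_day, 0)
        hi = min(row.death_day, config.n_days)
        for day in range(lo, hi):
            rho = float(role_trajectory(day - row.emergence_day, row.transition_day,
                                        config.role_scale))
            rows.append((row.bee_id, day, rho))
    roles = pd.DataFrame(rows, columns=["bee_id", "day", "role"])
    mix = task_mixture_from_role(roles["role"].to_numpy())
    task = roles[["bee_id", "day"]].copy()
    for i, area in enumerate(AREAS):
        task[f"p_{area}"] = mix[:, i]
    return GroundTruth(bees=bees, roles=roles, task_mixture=task)


# ---------------------------------------------------------------------------
# detections


def _uniform_in_polygon(poly: Polygon, size: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample uniform points from a polygon's bounding box."""
    if size == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((size, 2))
    filled = 0
    import shapely
    while filled < size:
        m = max(2 * (size - filled), 16)
        pts = np.column_stack([rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)])
        ok = shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])
        take = pts[ok][: size - filled]
        out[filled:filled + len(take)] = take
        filled += len(take)
    return out


def _block_area_assignment(mixture: np.ndarray, n_frames: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Per-frame area index (n_bees x n_frames), contiguous blocks per bee.

    Frame counts per area are multinomial draws from the bee's task mixture,
    so occupancy fractions converge to the mixture; contiguous blocks keep
    positions temporally coherent within a visit.
    """
    n_bees = mixture.shape[0]
    out = np.empty((n_bees, n_frames), dtype=np.int8)
    for b in range(n_bees):
        counts = rng.multinomial(n_frames, mixture[b])
        order = rng.permutation(len(AREAS))
        seq = np.concatenate([np.full(counts[a], a, dtype=np.int8) for a in order])
        out[b] = seq
    return out


def simulate_colony(config: ColonyConfig
                    ) -> tuple[pd.DataFrame, list[dict], GroundTruth]:
    """Simulate detections, daily area maps, and ground truth.

    Returns
    -------
    detections : DataFrame
        Columns :data:`DETECTION_COLUMNS` plus a generator-only boolean
        ``false_positive`` column flagging spurious decodings of dead or
        not-yet-introduced tags.
    area_maps : list of dict
        ``{day, side, label, polygon}`` records covering every focal day.
    ground_truth : GroundTruth
    """
    gt = simulate_ground_truth(config)
    rng = _rng(config, 1)
    polys = config.polygons()
    area_polys = [polys[a][0] for a in AREAS]
    area_sides = np.array([polys[a][1] for a in AREAS])

    F = config.frames_per_day
    dt = DAY_SECONDS / F
    dt_eff = min(dt, 10.0)  # bees move in short bouts; see methods note
    frame_sides = np.arange(F) % 2
    frame_hours = (np.arange(F) + 0.5) * 24.0 / F

    frames = []
    roles_wide = gt.roles.pivot(index="bee_id", columns="day", values="role")
    mix_cols = [f"p_{a}" for a in AREAS]
    for day in range(config.n_days):
        alive = gt.alive_on(day)
        if not alive:
            import warnings
            warnings.warn(f"no bees alive on day {day}")
            continue
        nb = len(alive)
        rho = roles_wide.loc[alive, day].to_numpy()
        mixture = gt.task_mixture.set_index(["bee_id", "day"]).loc[
            [(b, day) for b in alive], mix_cols].to_numpy()
        areas = _block_area_assignment(mixture, F, rng)

        # pre-draw a uniform target point per bee-frame, grouped by area
        targets = np.empty((nb, F, 2))
        for a in range(len(AREAS)):
            mask = areas == a
            targets[mask] = _uniform_in_polygon(area_polys[a], int(mask.sum()), rng)

        # circadian speed: forager-like bees move faster around the peak hour
        speed = np.full((nb, F), config.base_speed_mm_s)
        forager = rho > 0.5
        if forager.any():
            modulation = 1.0 + config.circadian_amplitude * np.cos(
                2 * np.pi * (frame_hours - config.circadian_peak_hour) / 24.0)
            speed[forager] = config.base_speed_mm_s * np.clip(modulation, 0.05, None)

        # bounded walk: convex step toward the target keeps positions inside
        # the assigned (convex) area; area changes jump to the new area
        pos = np.empty((nb, F, 2))
        pos[:, 0] = targets[:, 0]
        for f in range(1, F):
            q = targets[:, f]
            step = speed[:, f] * dt_eff
            delta = q - pos[:, f - 1]
            dist = np.linalg.norm(delta, axis=1)
            lam = np.minimum(1.0, np.divide(step, dist, out=np.ones(nb), where=dist > 0))
            lam = np.where(areas[:, f] != areas[:, f - 1], 1.0, lam)
            pos[:, f] = pos[:, f - 1] + lam[:, None] * delta

        # a frame images one comb side; the bee is detected only if it is on
        # the imaged side, with additional dropout
        bee_side = area_sides[areas]
        detected = (bee_side == frame_sides[None, :]) & \
            (rng.random((nb, F)) < config.detect_prob)
        b_idx, f_idx = np.nonzero(detected)
        nd = b_idx.size
        a, bpar = config.confidence_ab
        frames.append(pd.DataFrame({
            "bee_id": np.asarray(alive)[b_idx],
            "timestamp_utc": day * DAY_SECONDS + (f_idx + 0.5) * dt,
            "day": day,
            "x_mm": pos[b_idx, f_idx, 0],
            "y_mm": pos[b_idx, f_idx, 1],
            "orientation_rad": rng.uniform(-np.pi, np.pi, nd),
            "side": bee_side[b_idx, f_idx],
            "confidence": rng.beta(a, bpar, nd),
            "false_positive": False,
        }))

    # false positives: spurious decodings of tags that are not in the hive
    fp_frames = _false_positive_detections(gt, config, rng)
    if fp_frames is not None:
        frames.append(fp_frames)
    detections = (pd.concat(frames, ignore_index=True)
                  if frames else pd.DataFrame(columns=DETECTION_COLUMNS + ["false_positive"]))
    detections = detections.sort_values(
        ["day", "timestamp_utc", "bee_id"], kind="mergesort").reset_index(drop=True)

    area_maps = [
        {"day": day, "side": int(polys[label][1]), "label": label,
         "polygon": [list(map(float, xy)) for xy in config.area_geometry[label]["polygon"]]}
        for day in range(config.n_days) for label in AREAS
    ]
    return detections, area_maps, gt


def _false_positive_detections(gt: GroundTruth, config: ColonyConfig,
                               rng: np.random.Generator) -> pd.DataFrame | None:
    if config.detection_noise <= 0:
        return None
    polys = config.polygons()
    xs = [p.bounds[i] for p, _ in polys.values() for i in (0, 2)]
    ys = [p.bounds[i] for p, _ in polys.values() for i in (1, 3)]
    lo = (min(xs), min(ys))
    hi = (max(xs), max(ys))
    rows = []
    a, b = config.fp_confidence
    for bee in gt.bees.itertuples(index=False):
        for day in range(config.n_days):
            if bee.emergence_day <= day < bee.death_day:
                continue
            k = rng.poisson(config.detection_noise)
            if k == 0:
                continue
            ts = np.sort(rng.uniform(0, DAY_SECONDS, k))
            rows.append(pd.DataFrame({
                "bee_id": bee.bee_id,
                "timestamp_utc": day * DAY_SECONDS + ts,
                "day": day,
                "x_mm": rng.uniform(lo[0], hi[0], k),
                "y_mm": rng.uniform(lo[1], hi[1], k),
                "orientation_rad": rng.uniform(-np.pi, np.pi, k),
                "side": rng.integers(0, 2, k),
                "confidence": rng.beta(a, b, k),
                "false_positive": True,
            }))
    return pd.concat(rows, ignore_index=True) if rows else None


# ---------------------------------------------------------------------------
# affinities and detection counts


def role_kernel(rho_i, rho_j, config: ColonyConfig) -> np.ndarray:
    """Expected daily contact count for a pair: Gaussian in role difference."""
    d = np.asarray(rho_i, dtype=float) - np.asarray(rho_j, dtype=float)
    return config.affinity_rate_max * np.exp(-d ** 2 / (2 * config.role_bandwidth ** 2))


#: relative Poisson rates of the generated modes (proximity defines the scale)
_MODE_RATE = {
    "proximity_count": 1.0,
    "trophallaxis_count": 0.2,
    "effect_mean_pos": 0.3,
    "effect_mean_neg": 0.3,
    "effect_cum_pos": 0.3,
    "effect_cum_neg": 0.3,
}


def simulate_affinity_timeseries(ground_truth: GroundTruth, config: ColonyConfig
                                 ) -> dict[int, dict[str, AffinityMatrix]]:
    """Daily affinity matrices for all eight interaction modes.

    Count modes draw symmetric Poisson counts with the role-similarity kernel
    mean; distance modes derive from a latent mean distance that grows with
    role difference, transformed exactly as the real distance constructor
    does (Gaussian similarity with gamma = max(D)/4, and max(D) - d);
    the four effect modes are directed Poisson draws at reduced rates.
    """
    rng = _rng(config, 2)
    out: dict[int, dict[str, AffinityMatrix]] = {}
    roles_wide = ground_truth.roles.pivot(index="bee_id", columns="day", values="role")
    for day in range(config.n_days):
        alive = ground_truth.alive_on(day)
        n = len(alive)
        if n == 0:
            continue
        rho = roles_wide.loc[alive, day].to_numpy()
        K = role_kernel(rho[:, None], rho[None, :], config)
        np.fill_diagonal(K, 0.0)
        iu = np.triu_indices(n, k=1)
        mats: dict[str, AffinityMatrix] = {}

        def _sym_poisson(rate_scale: float) -> np.ndarray:
            vals = np.zeros((n, n))
            vals[iu] = rng.poisson(rate_scale * K[iu])
            return vals + vals.T

        mats["proximity_count"] = AffinityMatrix(
            day=day, mode="proximity_count", index=alive,
            values=_sym_poisson(_MODE_RATE["proximity_count"]))
        mats["trophallaxis_count"] = AffinityMatrix(
            day=day, mode="trophallaxis_count", index=alive,
            values=_sym_poisson(_MODE_RATE["trophallaxis_count"]))

        # latent mean pairwise distance: near for similar roles, far otherwise
        dist = np.zeros((n, n))
        dist[iu] = np.clip(
            20.0 + 250.0 * np.abs(rho[:, None] - rho[None, :])[iu]
            + 10.0 * rng.standard_normal(iu[0].size), 1.0, None)
        dist = dist + dist.T
        dmax = dist.max() if n > 1 else 1.0
        gamma = dmax / 4.0
        gauss = np.exp(-dist ** 2 / (2 * gamma ** 2))
        maxminus = dmax - dist
        np.fill_diagonal(gauss, 0.0)
        np.fill_diagonal(maxminus, 0.0)
        mats["distance_gaussian"] = AffinityMatrix(
            day=day, mode="distance_gaussian", index=alive, values=gauss)
        mats["distance_max_minus"] = AffinityMatrix(
            day=day, mode="distance_max_minus", index=alive, values=maxminus)

        offdiag = ~np.eye(n, dtype=bool)
        for mode in ("effect_mean_pos", "effect_mean_neg", "effect_cum_pos", "effect_cum_neg"):
            vals = np.zeros((n, n))
            vals[offdiag] = rng.poisson(_MODE_RATE[mode] * K[offdiag])
            mats[mode] = AffinityMatrix(day=day, mode=mode, index=alive,
                                        values=vals, symmetric=False)
        out[day] = mats
    return out


def simulate_detection_counts(ground_truth: GroundTruth, config: ColonyConfig
                              ) -> pd.DataFrame:
    """Per-bee daily detection counts: high while alive, noise floor otherwise.

    Alive days draw Poisson counts around a per-bee mean (lognormal spread
    around ``alive_count_mean``); days before emergence or after death draw
    from the false-positive rate ``detection_noise``.
    """
    rng = _rng(config, 3)
    bees = ground_truth.bees
    per_bee_mean = config.alive_count_mean * np.exp(0.2 * rng.standard_normal(len(bees)))
    rows = []
    for mean, bee in zip(per_bee_mean, bees.itertuples(index=False)):
        days = np.arange(config.n_days)
        alive = (bee.emergence_day <= days) & (days < bee.death_day)
        counts = np.where(alive, rng.poisson(mean, config.n_days),
                          rng.poisson(config.detection_noise, config.n_days))
        rows.append(pd.DataFrame({"bee_id": bee.bee_id, "day": days, "count": counts}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O


def write_colony(out_dir, detections: pd.DataFrame, area_maps: list[dict],
                 ground_truth: GroundTruth) -> None:
    """Write the generator outputs in their on-disk formats."""
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    detections[DETECTION_COLUMNS].to_csv(out / "detections.csv", index=False)
    (out / "area_maps.json").write_text(json.dumps(area_maps))
    ground_truth.bees.to_csv(out / "ground_truth_bees.csv", index=False)
    ground_truth.roles.to_csv(out / "ground_truth_roles.csv", index=False)
    ground_truth.task_mixture.to_csv(out / "ground_truth_task_mixture.csv", index=False)
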