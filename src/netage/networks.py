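"""Daily affinity matrices over the bees alive on each day.

Eight interaction modes are supported: proximity contact counts,
trophallaxis counts, two transforms of mean pairwise distance (Gaussian
similarity and max-minus-distance), and four directed interaction-effect
modes (mean / cumulative speed change after contact, split into positive and
negative parts so that every affinity matrix is nonnegative).

All matrices are aggregated over 24 h without overlap and rank-normalized
to [0, 1] before embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

#: symmetric count / distance modes followed by the directed effect modes
SYMMETRIC_MODES = ("proximity_count", "distance_gaussian", "distance_max_minus",
                   "trophallaxis_count")
DIRECTED_MODES = ("effect_mean_pos", "effect_mean_neg", "effect_cum_pos",
                  "effect_cum_neg")
ALL_MODES = SYMMETRIC_MODES + DIRECTED_MODES


@dataclass
class AffinityMatrix:
    """One interaction mode on one day, indexed by the bees alive that day."""

    day: int
    mode: str
    index: list
    values: np.ndarray
    symmetric: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n with n = len(index)")
        if np.any(self.values < 0):
            raise ValueError("affinities must be nonnegative")
        np.fill_diagonal(self.values, 0.0)
        if self.symmetric and not np.allclose(self.values, self.values.T):
            raise ValueError("symmetric flag set but matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.index)

    def to_files(self, stem: str | Path) -> None:
        """Write ``<stem>.mtx`` plus a ``<stem>.index.csv`` row->bee_id map."""
        stem = Path(stem)
        mmwrite(str(stem.with_suffix(".mtx")), csr_matrix(self.values))
        pd.DataFrame({"row": range(self.n), "bee_id": self.index}).to_csv(
            stem.with_suffix(".index.csv"), index=False)

    @classmethod
    def from_files(cls, stem: str | Path, day: int, mode: str,
                   symmetric: bool = True) -> "AffinityMatrix":
        stem = Path(stem)
        values = np.asarray(mmread(str(stem.with_suffix(".mtx"))).todense())
        idx = pd.read_csv(stem.with_suffix(".index.csv"))["bee_id"].tolist()
        return cls(day=day, mode=mode, index=idx, values=values, symmetric=symmetric)


@dataclass
class DistanceParams:
    """Daily mean pairwise distances and the derived Gaussian bandwidth."""

    D: np.ndarray
    gamma: float = field(init=False)

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        dmax = np.nanmax(self.D) if self.D.size else 0.0
        if not dmax > 0:
            raise ValueError("no positive pairwise distances available")
        self.gamma = dmax / 4.0


def build_count_matrix(events: pd.DataFrame, alive_bees, day: int,
                       mode: str = "proximity_count") -> AffinityMatrix:
    """Symmetric matrix of daily interaction counts between alive bees.

    ``events`` needs columns ``bee_a``, ``bee_b`` and (optionally) ``day``;
    events involving bees outside the alive set are dropped with a warning.
    """
    alive = list(alive_bees)
    pos = {b: i for i, b in enumerate(alive)}
    n = len(alive)
    values = np.zeros((n, n))
    if events.empty:
        return AffinityMatrix(day=day, mode=mode, index=alive, values=values)
    if "day" in events.columns:
        events = events[events["day"] == day]
    dropped = 0
    for a, b in zip(events["bee_a"].to_numpy(), events["bee_b"].to_numpy()):
        ia, ib = pos.get(a), pos.get(b)
        if ia is None or ib is None:
            dropped += 1
            continue
        values[ia, ib] += 1
        values[ib, ia] += 1
    if dropped:
        warnings.warn(f"dropped {dropped} events referencing bees not alive on day {day}")
    return AffinityMatrix(day=day, mode=mode, index=alive, values=values, symmetric=True)


def build_distance_matrices(detections: pd.DataFrame, alive_bees, day: int
                            ) -> tuple[AffinityMatrix, AffinityMatrix, DistanceParams]:
    """Gaussian-similarity and max-minus affinity matrices from mean distances.

    The mean pairwise distance d between two bees is averaged over the frames
    in which both were visible (same timestamp, same comb side). The Gaussian
    affinity is exp(-d^2 / (2 gamma^2)) with gamma = max(D)/4; the second
    variant is max(D) - d. Pairs never co-visible get affinity 0.
    """
    alive = list(alive_bees)
    pos = {b: i for i, b in enumerate(alive)}
    n = len(alive)
    dsum = np.zeros((n, n))
    dcount = np.zeros((n, n))
    det = detections[detections["day"] == day]
    det = det[det["bee_id"].isin(pos)]
    for (_, _), grp in det.groupby(["timestamp_utc", "side"], sort=False):
        if len(grp) < 2:
            continue
        idx = np.array([pos[b] for b in grp["bee_id"]])
        xy = grp[["x_mm", "y_mm"]].to_numpy()
        dm = squareform(pdist(xy))
        ii = np.ix_(idx, idx)
        dsum[ii] += dm
        dcount[ii] += 1
    np.fill_diagonal(dcount, 0)
    seen = dcount > 0
    if not seen.any():
        raise ValueError(f"no co-visible pairs on day {day}: cannot build distance matrices")
    D = np.full((n, n), np.nan)
    D[seen] = dsum[seen] / dcount[seen]
    params = DistanceParams(D=np.where(seen, D, np.nan))
    dmax = params.gamma * 4.0
    gauss = np.zeros((n, n))
    gauss[seen] = np.exp(-D[seen] ** 2 / (2 * params.gamma ** 2))
    maxminus = np.zeros((n, n))
    maxminus[seen] = dmax - D[seen]
    gauss = (gauss + gauss.T) / 2  # symmetrize one-sided co-visibility
    maxminus = np.clip((maxminus + maxminus.T) / 2, 0, None)
    return (
        AffinityMatrix(day=day, mode="distance_gaussian", index=alive, values=gauss),
        AffinityMatrix(day=day, mode="distance_max_minus", index=alive, values=maxminus),
        params,
    )


def build_interaction_effect_matrices(records: pd.DataFrame, alive_bees, day: int
                                      ) -> dict[str, AffinityMatrix]:
    """Directed matrices of post-contact speed changes.

    For a record with focal i and partner j, a positive delta accumulates at
    (i, j) in the ``*_pos`` matrix and the absolute value of a negative delta
    in the ``*_neg`` matrix; mean vs. cumulative deltas populate the
    ``effect_mean_*`` vs. ``effect_cum_*`` matrices. Multiple same-pair
    records in a day sum.
    """
    alive = list(alive_bees)
    pos = {b: i for i, b in enumerate(alive)}
    n = len(alive)
    mats = {m: np.zeros((n, n)) for m in DIRECTED_MODES}
    if "day" in records.columns:
        records = records[records["day"] == day]
    for row in records.itertuples(index=False):
        i, j = pos.get(row.focal), pos.get(row.partner)
        if i is None or j is None or i == j:
            continue
        for delta, stem in ((row.delta_mean, "effect_mean"), (row.delta_cumulative, "effect_cum")):
            if delta >= 0:
                mats[stem + "_pos"][i, j] += delta
            else:
                mats[stem + "_neg"][i, j] += -delta
    return {
        m: AffinityMatrix(day=day, mode=m, index=alive, values=v, symmetric=False)
        for m, v in mats.items()
    }


def rank_transform(matrix: AffinityMatrix) -> AffinityMatrix:
    """Rank-normalize affinities so 0 is the lowest and 1 the highest.

    Ties share a rank (dense ranking), so e.g. affinities {1, 1, 3} map to
    {0, 0, 1}. Symmetric matrices are ranked over unordered pairs to preserve
    symmetry; the diagonal stays 0 and never participates in the ranking.
    A constant positive matrix maps to 0.5 everywhere off-diagonal.
    """
    n = matrix.n
    values = matrix.values
    out = np.zeros_like(values)
    if n > 1:
        if matrix.symmetric:
            iu = np.triu_indices(n, k=1)
            flat = values[iu]
            ranked = _rank01(flat)
            out[iu] = ranked
            out = out + out.T
        else:
            mask = ~np.eye(n, dtype=bool)
            out[mask] = _rank01(values[mask])
    return AffinityMatrix(day=matrix.day, mode=matrix.mode, index=list(matrix.index),
                          values=out, symmetric=matrix.symmetric)


def _rank01(flat: np.ndarray) -> np.ndarray:
    if flat.size == 0:
        return flat
    ranks = rankdata(flat, method="dense").astype(float)
    rmax = ranks.max()
    if rmax <= 1:  # all affinities identical: no order to assert
        return np.full_like(flat, 0.5)
    return (ranks - 1.0) / (rmax - 1.0)
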