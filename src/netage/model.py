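"""Network age: the linear map from daily spectral factors to a per-bee,
per-day scalar describing the individual's position in the colony's
multimodal interaction network.

The map is fitted in one of three variants:

``cca``
    Canonical correlation analysis between the pooled standardized factors
    and the 4-area task descriptor; the first canonical factor-side
    direction is network age, with two further dimensions available.
``pca``
    Unsupervised: principal directions of the pooled standardized factors.
``targeted``
    CCA against an arbitrary per-(bee, day) scalar property (e.g. days
    until death), yielding a one-dimensional targeted embedding.

After projection, each dimension is robust-scaled per day so the 5th
percentile maps to 0 and the 95th to 40 (so 90% of values fall in [0, 40],
a range comparable to a worker's summer lifespan in days), and the sign of
the first dimension is oriented so that network age and biological age
increase together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .config import AREAS

SCALE_MAX = 40.0
PERCENTILES = (5.0, 95.0)

DESCRIPTOR_COLUMNS = [f"p_{a}" for a in AREAS]


def _factor_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("f_")]


# ---------------------------------------------------------------------------
# linear algebra: classic CCA via whitened SVD


def _inv_sqrt(cov: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Symmetric pseudo-inverse square root (handles rank deficiency)."""
    evals, evecs = scipy.linalg.eigh(cov)
    cut = rcond * evals.max()
    keep = evals > cut
    return (evecs[:, keep] / np.sqrt(evals[keep])) @ evecs[:, keep].T

def cca_directions(X: np.ndarray, Y: np.ndarray, k: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First k canonical directions of centered X and Y.

    Returns (Wx, Wy, correlations); columns of Wx project X onto the
    canonical variates. Uses the whitened-SVD formulation
    Cxx^{-1/2} Cxy Cyy^{-1/2} = U S V', Wx = Cxx^{-1/2} U.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    # slight ridge keeps the whitening stable for near-collinear factors
    Cxx += 1e-8 * np.trace(Cxx) / Cxx.shape[0] * np.eye(Cxx.shape[0])
    Kx = _inv_sqrt(Cxx)
    Ky = _inv_sqrt(np.atleast_2d(Cyy))
    u, s, vt = scipy.linalg.svd(Kx @ Cxy @ Ky, full_matrices=False)
    k = min(k, s.size)
    return Kx @ u[:, :k], Ky @ vt[:k].T, s[:k]


# ---------------------------------------------------------------------------
# the fitted map


@dataclass
class NetworkAgeMap:
    """Standardization parameters plus the factor-side projection."""

    variant: str
    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    projection: np.ndarray  # F x k
    canonical_correlations: np.ndarray | None = None
    orientation_sign: float = 1.0

    @property
    def k(self) -> int:
        return self.projection.shape[1]

    def transform(self, factors: pd.DataFrame) -> pd.DataFrame:
        """Apply the map: standardized factors times projection (raw values)."""
        cols = _factor_columns(factors)
        if cols != self.feature_names:
            raise ValueError("factor columns do not match the columns seen at fit "
                             "time (order matters)")
        X = (factors[cols].to_numpy(dtype=float) - self.mean) / self.std
        raw = X @ (self.projection * self.orientation_sign_vector())
        out = factors[["bee_id", "day"]].copy()
        for j in range(raw.shape[1]):
            out[f"raw_{j + 1}"] = raw[:, j]
        return out

    def orientation_sign_vector(self) -> np.ndarray:
        v = np.ones(self.k)
        v[0] = self.orientation_sign
        return v

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "variant": self.variant,
            "feature_names": self.feature_names,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "projection": self.projection.tolist(),
            "canonical_correlations": (None if self.canonical_correlations is None
                                       else self.canonical_correlations.tolist()),
            "orientation_sign": self.orientation_sign,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkAgeMap":
        d = json.loads(Path(path).read_text())
        return cls(
            variant=d["variant"], feature_names=d["feature_names"],
            mean=np.array(d["mean"]), std=np.array(d["std"]),
            projection=np.array(d["projection"]),
            canonical_correlations=(None if d["canonical_correlations"] is None
                                    else np.array(d["canonical_correlations"])),
            orientation_sign=d["orientation_sign"])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)  # constant columns contribute nothing
    return (X - mean) / std, mean, std


def fit_cca_map(factors: pd.DataFrame, descriptors: pd.DataFrame, k: int = 3
                ) -> NetworkAgeMap:
    """CCA between pooled standardized factors and the 4-area task descriptor.

    Rows are matched on (bee_id, day); rows without a descriptor are dropped.
    The fit pools all days, so network age can only represent interaction
    patterns that are consistent over the focal period.
    """
    cols = _factor_columns(factors)
    merged = factors.merge(descriptors[["bee_id", "day"] + DESCRIPTOR_COLUMNS],
                           on=["bee_id", "day"], how="inner").dropna()
    if len(merged) <= len(cols):
        raise ValueError(f"only {len(merged)} matched rows for {len(cols)} factor "
                         "columns; reduce dimensionality or provide more data")
    X, mean, std = _standardize(merged[cols].to_numpy(dtype=float))
    Y = merged[DESCRIPTOR_COLUMNS].to_numpy(dtype=float)
    Wx, _, corr = cca_directions(X, Y, k)
    return NetworkAgeMap(variant="cca_task", feature_names=cols, mean=mean,
                         std=std, projection=Wx, canonical_correlations=corr)


def fit_pca_map(factors: pd.DataFrame, k: int = 1) -> NetworkAgeMap:
    """Unsupervised variant: principal directions of the pooled factors."""
    from sklearn.decomposition import PCA
    cols = _factor_columns(factors)
    clean = factors.dropna(subset=cols)
    if len(clean) <= len(cols):
        raise ValueError("fewer rows than factor columns")
    X, mean, std = _standardize(clean[cols].to_numpy(dtype=float))
    pca = PCA(n_components=k, svd_solver="full").fit(X)
    return NetworkAgeMap(variant="pca", feature_names=cols, mean=mean, std=std,
                         projection=pca.components_.T)


def fit_targeted_map(factors: pd.DataFrame, target: pd.DataFrame,
                     target_col: str, k: int = 1) -> NetworkAgeMap:
    """Targeted embedding: CCA against a scalar per-(bee, day) property."""
    cols = _factor_columns(factors)
    merged = factors.merge(target[["bee_id", "day", target_col]],
                           on=["bee_id", "day"], how="inner").dropna()
    y = merged[target_col].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant target has no direction to correlate with")
    if len(merged) <= len(cols):
        raise ValueError("fewer rows than factor columns")
    X, mean, std = _standardize(merged[cols].to_numpy(dtype=float))
    Wx, _, corr = cca_directions(X, y[:, None], k)
    return NetworkAgeMap(variant=f"targeted:{target_col}", feature_names=cols,
                         mean=mean, std=std, projection=Wx,
                         canonical_correlations=corr)


def apply_map(factors: pd.DataFrame, nmap: NetworkAgeMap) -> pd.DataFrame:
    """Project factors through a fitted map (raw, unscaled values)."""
    return nmap.transform(factors)


# ---------------------------------------------------------------------------
# scaling and orientation


def robust_scale(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-day affine map sending the 5th percentile to 0 and the 95th to 40.

    Applied independently per day and dimension; values outside the
    percentiles extend linearly (network age may be < 0 or > 40). A
    degenerate day (all values equal) maps to the midpoint 20. Percentiles
    use linear interpolation between order statistics.
    """
    import warnings
    out = raw.copy()
    raw_cols = [c for c in raw.columns if c.startswith("raw_")]
    for col in raw_cols:
        scaled = np.empty(len(raw))
        for _, idx in raw.groupby("day").indices.items():
            v = raw[col].to_numpy(dtype=float)[idx]
            p5, p95 = np.percentile(v, PERCENTILES)
            if p95 > p5:
                scaled[idx] = SCALE_MAX * (v - p5) / (p95 - p5)
            else:
                warnings.warn("degenerate day in robust_scale: all values equal")
                scaled[idx] = SCALE_MAX / 2.0
        out[col.replace("raw_", "na_")] = scaled
    out = out.rename(columns={"na_1": "network_age"})
    return out


def orientation_sign(scaled: pd.DataFrame, ages: pd.DataFrame) -> float:
    """+1 if network age already increases with biological age, else -1.

    Compares the mean biological age of bees below the 5th-percentile value
    (scaled <= 0) with those above the 95th (scaled >= 40).
    """
    merged = scaled.merge(ages, on=["bee_id", "day"], how="inner")
    low = merged.loc[merged["network_age"] <= 0.0, "age"]
    high = merged.loc[merged["network_age"] >= SCALE_MAX, "age"]
    if len(low) == 0 or len(high) == 0:
        return 1.0
    return -1.0 if low.mean() > high.mean() else 1.0


def orient_directionality(raw: pd.DataFrame, ages: pd.DataFrame
                          ) -> tuple[pd.DataFrame, float]:
    """Flip-then-rescale so network age and biological age share direction."""
    scaled = robust_scale(raw)
    sign = orientation_sign(scaled, ages)
    if sign < 0:
        flipped = raw.copy()
        flipped["raw_1"] = -flipped["raw_1"]
        scaled = robust_scale(flipped)
    return scaled, sign


# ---------------------------------------------------------------------------
# Model / Results


class NetworkAgeModel:
    """Maps daily spectral factors to network age.

    Parameters
    ----------
    factors : DataFrame
        Pooled daily factors (``bee_id, day, f_000..``) over all days.
    descriptors : DataFrame, optional
        Task descriptor rows (``bee_id, day, p_brood, p_dance_floor,
        p_honey, p_exit``); required for the ``cca`` variant.
    ages : DataFrame, optional
        ``bee_id, day, age`` biological ages used to orient the sign.
    variant : {"cca", "pca", "targeted"}
    target, target_col
        For ``targeted``: DataFrame and column holding the scalar property.
    k : int
        Number of output dimensions (3 for CCA by default).
    """

    def __init__(self, factors: pd.DataFrame, descriptors: pd.DataFrame | None = None,
                 ages: pd.DataFrame | None = None, variant: str = "cca",
                 target: pd.DataFrame | None = None, target_col: str | None = None,
                 k: int | None = None):
        self.factors = factors
        self.descriptors = descriptors
        self.ages = ages
        self.variant = variant
        self.target = target
        self.target_col = target_col
        self.k = k if k is not None else (3 if variant == "cca" else 1)

    def fit(self) -> "NetworkAgeResults":
        if self.variant == "cca":
            if self.descriptors is None:
                raise ValueError("cca variant requires task descriptors")
            nmap = fit_cca_map(self.factors, self.descriptors, k=self.k)
        elif self.variant == "pca":
            nmap = fit_pca_map(self.factors, k=self.k)
        elif self.variant == "targeted":
            if self.target is None or self.target_col is None:
                raise ValueError("targeted variant requires target and target_col")
            nmap = fit_targeted_map(self.factors, self.target, self.target_col, k=self.k)
        else:
            raise ValueError(f"unknown variant {self.variant!r}")
        raw = nmap.transform(self.factors)
        if self.ages is not None:
            scaled, sign = orient_directionality(raw, self.ages)
            nmap.orientation_sign = sign
            if sign < 0:
                raw = nmap.transform(self.factors)
        else:
            scaled = robust_scale(raw)
        return NetworkAgeResults(model=self, map=nmap, raw=raw, series=scaled)


@dataclass
class NetworkAgeResults:
    """Fitted network-age map and the per-(bee, day) series it produces."""

    model: NetworkAgeModel
    map: NetworkAgeMap
    raw: pd.DataFrame
    series: pd.DataFrame = field(repr=False)

    @property
    def network_age(self) -> pd.DataFrame:
        cols = ["bee_id", "day", "network_age"] + \
            [c for c in self.series.columns if c.startswith("na_")]
        return self.series[cols]

    def transform(self, factors: pd.DataFrame) -> pd.DataFrame:
        """Scaled network age for new factor rows (per-day robust scaling)."""
        return robust_scale(self.map.transform(factors))

    def summary(self) -> str:
        s = self.series["network_age"]
        lines = [
            "Network Age Results",
            "=" * 46,
            f"variant:            {self.map.variant}",
            f"components:         {self.map.k}",
            f"factor columns:     {len(self.map.feature_names)}",
            f"rows (bee, day):    {len(self.series)}",
            f"orientation sign:   {self.map.orientation_sign:+.0f}",
        ]
        if self.map.canonical_correlations is not None:
            cc = ", ".join(f"{c:.3f}" for c in self.map.canonical_correlations)
            lines.append(f"canonical corrs:    {cc}")
        lines += [
            f"scaling:            per-day {PERCENTILES[0]:g}th pct -> 0, "
            f"{PERCENTILES[1]:g}th pct -> {SCALE_MAX:g}",
            f"network age range:  [{s.min():.2f}, {s.max():.2f}]  "
            f"median {s.median():.2f}",
        ]
        return "\n".join(lines)

    def plot_trajectories(self, bee_ids=None, ax=None):
        """Plot per-bee network-age trajectories over days."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        data = self.series
        if bee_ids is not None:
            data = data[data["bee_id"].isin(bee_ids)]
        for bee, grp in data.groupby("bee_id"):
            ax.plot(grp["day"], grp["network_age"], alpha=0.5, lw=1)
        ax.set_xlabel("day")
        ax.set_ylabel("network age")
        return ax
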