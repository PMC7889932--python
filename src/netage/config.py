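"""Colony configuration for the synthetic colony generator.

The generator emulates the data regime of a fully tracked honey bee
observation hive: an age-structured colony in which same-aged workers follow
heterogeneous developmental trajectories (early, late, or no transition to a
forager-like role), occupy four task-associated nest areas according to their
current role, interact preferentially with individuals of similar role, and
stop producing genuine detections after death (leaving only a low false
positive floor of erroneously decoded tags).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

import yaml

#: Canonical order of the four task-associated nest areas.
AREAS = ("brood", "dance_floor", "honey", "exit")

#: Developmental clusters: transition to a forager-like role early, late, or never.
CLUSTERS = ("early", "late", "none")


def _default_area_geometry() -> dict:
    """Four disjoint rectangular nest areas on a 350 x 200 mm comb.

    The dance floor and exit sit on side 0 near the entrance; honey storage is
    placed on side 1 so that downstream code is exercised with detections on
    both comb sides. Coordinates are metric mm on the nest plane.
    """
    return {
        "brood": {"polygon": [[60, 40], [200, 40], [200, 160], [60, 160]], "side": 0},
        "dance_floor": {"polygon": [[220, 10], [340, 10], [340, 90], [220, 90]], "side": 0},
        "honey": {"polygon": [[20, 20], [160, 20], [160, 120], [20, 120]], "side": 1},
        "exit": {"polygon": [[220, 110], [340, 110], [340, 190], [220, 190]], "side": 0},
    }


def _default_emergence_schedule(n_bees: int, n_days: int) -> list[tuple[int, int]]:
    """Staggered cohorts: half the colony emerges before the focal period.

    Mirrors a hive where tagging starts roughly a month before recording, so
    that on any focal day the colony spans biological ages from 0 to ~6 weeks.
    """
    days = [-28, -21, -14, -7, 0, 4, 8, 12]
    base, rem = divmod(n_bees, len(days))
    sizes = [base + (1 if i < rem else 0) for i in range(len(days))]
    return [(d, s) for d, s in zip(days, sizes) if s > 0]


@dataclass
class ColonyConfig:
    """Parameters of the synthetic colony.

    Parameters
    ----------
    n_bees, n_days
        Colony size and length of the focal recording period (days).
    emergence_schedule
        List of ``(day, cohort_size)``; negative days emerge before recording.
        ``None`` selects a staggered default spanning ~6 weeks of ages.
    cluster_probs
        Probabilities of the {early, late, none} developmental clusters.
    transition_day_means, transition_day_sds
        Per-cluster mean/sd of the day-of-life at which the latent role
        crosses 0.5 (the nurse-to-forager transition); the "none" cluster
        never transitions (mean is ignored).
    role_scale
        Steepness (days) of the logistic role trajectory.
    lifespan_prior_mean, lifespan_prior_sd
        Truncated-normal lifespan distribution (days, truncated at >= 1).
    frame_rate
        Nominal camera rate in Hz (sides alternate between frames).
    frames_per_day
        Number of frames actually emitted per day, evenly spaced over 24 h.
    detect_prob
        Probability that an alive bee on the imaged side yields a detection.
    affinity_rate_max
        Expected daily contact count for a role-identical pair.
    role_bandwidth
        Bandwidth of the Gaussian role-similarity kernel (role units).
    detection_noise
        Daily false-positive detection rate for dead / not-yet-emerged bees.
    fp_confidence
        ``(a, b)`` of the Beta distribution for false-positive confidences
        (low tail); genuine detections use ``confidence_ab``.
    base_speed_mm_s, circadian_amplitude, circadian_peak_hour
        Movement speed scale and the 24 h sinusoidal modulation applied to
        forager-like bees (latent role > 0.5), peaking at the given UTC hour.
    alive_count_mean
        Mean daily detection count used by :func:`simulate_detection_counts`.
    seed
        Base RNG seed; all generator randomness derives from it.
    """

    n_bees: int = 200
    n_days: int = 25
    emergence_schedule: list | None = None
    cluster_probs: tuple = (0.4, 0.35, 0.25)
    transition_day_means: tuple = (11.0, 21.0, float("inf"))
    transition_day_sds: tuple = (2.0, 2.0, 0.0)
    role_scale: float = 2.5
    lifespan_prior_mean: float = 35.0
    lifespan_prior_sd: float = 15.0
    frame_rate: float = 3.0
    frames_per_day: int = 288
    detect_prob: float = 0.8
    affinity_rate_max: float = 50.0
    role_bandwidth: float = 0.2
    detection_noise: float = 2.0
    fp_confidence: tuple = (2.0, 5.0)
    confidence_ab: tuple = (18.0, 1.0)
    base_speed_mm_s: float = 4.0
    circadian_amplitude: float = 0.8
    circadian_peak_hour: float = 13.5
    alive_count_mean: float = 1000.0
    area_geometry: dict = field(default_factory=_default_area_geometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.emergence_schedule is None:
            self.emergence_schedule = _default_emergence_schedule(self.n_bees, self.n_days)
        self.emergence_schedule = [(int(d), int(s)) for d, s in self.emergence_schedule]
        probs = np.asarray(self.cluster_probs, dtype=float)
        if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("cluster_probs must be a 3-vector summing to 1")
        if self.role_bandwidth <= 0:
            raise ValueError("role_bandwidth must be positive")
        for name in ("affinity_rate_max", "detection_noise", "frame_rate",
                     "base_speed_mm_s", "alive_count_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if set(self.area_geometry) != set(AREAS):
            raise ValueError(f"area_geometry must define exactly the areas {AREAS}")
        self._check_polygons()

    def _check_polygons(self) -> None:
        polys = {}
        for label, spec in self.area_geometry.items():
            poly = Polygon(spec["polygon"])
            if not poly.is_valid or poly.area <= 0:
                raise ValueError(f"area polygon {label!r} is invalid or empty")
            # the position random walk uses convex combinations, which only
            # stay inside convex regions
            if poly.convex_hull.area > poly.area * (1 + 1e-9):
                raise ValueError(f"area polygon {label!r} must be convex")
            polys[label] = (poly, spec.get("side", 0))
        labels = list(polys)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if polys[a][1] == polys[b][1] and polys[a][0].intersection(polys[b][0]).area > 0:
                    raise ValueError(f"area polygons {a!r} and {b!r} overlap")

    def polygons(self) -> dict:
        """Return {label: (shapely Polygon, side)}."""
        return {
            label: (Polygon(spec["polygon"]), spec.get("side", 0))
            for label, spec in self.area_geometry.items()
        }

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transition_day_means"] = [
            None if np.isinf(v) else v for v in self.transition_day_means
        ]
        d["emergence_schedule"] = [list(x) for x in self.emergence_schedule]
        for key in ("cluster_probs", "transition_day_sds", "fp_confidence",
                    "confidence_ab"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ColonyConfig":
        d = dict(d)
        if "transition_day_means" in d:
            d["transition_day_means"] = tuple(
                float("inf") if v is None else float(v) for v in d["transition_day_means"]
            )
        for key in ("cluster_probs", "transition_day_sds", "fp_confidence", "confidence_ab"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ColonyConfig":
        """Load from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))
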