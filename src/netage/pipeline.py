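"""End-to-end pipelines: from a synthetic colony (or a detection table) to
network age.

Two network sources are supported. The generator's affinity path draws
daily interaction matrices directly from the latent role kernel (fast, used
for colony-scale experiments); the detection path reconstructs events,
velocities and affinity matrices from the raw detection table exactly as a
real deployment would.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import AREAS, ColonyConfig
from .embeddings import embed_daily_networks
from .model import NetworkAgeModel, NetworkAgeResults
from .networks import (DIRECTED_MODES, build_count_matrix,
                       build_distance_matrices,
                       build_interaction_effect_matrices, rank_transform)
from .simulate import (GroundTruth, simulate_affinity_timeseries,
                       simulate_colony, simulate_ground_truth)
from .trajectories import (compute_velocity, detect_proximity_events,
                           extract_interaction_effects)


@dataclass
class ColonyPipelineResult:
    """Everything the synthetic-colony pipeline produces."""

    config: ColonyConfig
    ground_truth: GroundTruth
    factors: pd.DataFrame
    descriptors: pd.DataFrame
    ages: pd.DataFrame
    results: NetworkAgeResults

    @property
    def network_age(self) -> pd.DataFrame:
        return self.results.network_age


def descriptors_from_ground_truth(gt: GroundTruth, n_samples: int = 240) -> pd.DataFrame:
    """Task descriptor rows equal to the planted task mixture.

    ``n_samples`` is the per-row weight used by the task models (the
    equivalent of the number of minute samples behind each row).
    """
    desc = gt.task_mixture.copy()
    desc["n_samples"] = n_samples
    return desc


def rank_transform_all(networks: dict) -> dict:
    return {day: {mode: rank_transform(m) for mode, m in mats.items()}
            for day, mats in networks.items()}


def run_colony_pipeline(config: ColonyConfig, variant: str = "cca",
                        n_dims: int = 8, k: int | None = None,
                        descriptors: pd.DataFrame | None = None
                        ) -> ColonyPipelineResult:
    """Simulate a colony and compute network age from its affinity matrices.

    The task descriptor defaults to the planted task mixture; pass
    ``descriptors`` (e.g. computed from detections with
    :func:`netage.behavior.compute_task_descriptor`) to override.
    """
    gt = simulate_ground_truth(config)
    networks = rank_transform_all(simulate_affinity_timeseries(gt, config))
    factors = embed_daily_networks(networks, n_dims=n_dims)
    if descriptors is None:
        descriptors = descriptors_from_ground_truth(gt)
    ages = gt.biological_ages()
    results = NetworkAgeModel(factors, descriptors=descriptors, ages=ages,
                              variant=variant, k=k).fit()
    return ColonyPipelineResult(config=config, ground_truth=gt, factors=factors,
                                descriptors=descriptors, ages=ages, results=results)


def networks_from_detections(detections: pd.DataFrame, alive_sets: dict,
                             frame_rate: float = 3.0, max_dist_cm: float = 2.0,
                             min_frames: int = 3) -> dict:
    """Reconstruct all eight daily affinity matrices from a detection table.

    ``alive_sets`` maps day -> list of alive bee ids (from the lifetime
    model). Trophallaxis counts here use the proximity events as candidate
    contacts (a fitted stage-1 classifier can thin them beforehand).
    """
    events = detect_proximity_events(detections, frame_rate=frame_rate,
                                     max_dist_cm=max_dist_cm, min_frames=min_frames)
    velocities = compute_velocity(detections)
    effects = extract_interaction_effects(events, velocities)
    out: dict = {}
    for day, alive in alive_sets.items():
        day_events = events[events["day"] == day]
        mats = {}
        mats["proximity_count"] = build_count_matrix(day_events, alive, day)
        gauss, maxminus, _ = build_distance_matrices(detections, alive, day)
        mats["distance_gaussian"] = gauss
        mats["distance_max_minus"] = maxminus
        troph = build_count_matrix(day_events, alive, day, mode="trophallaxis_count")
        mats["trophallaxis_count"] = troph
        mats.update(build_interaction_effect_matrices(effects, alive, day))
        out[day] = mats
    return out


def simulate_and_write(config: ColonyConfig, out_dir) -> None:
    """Generate a colony and write detections, area maps and ground truth."""
    from .simulate import write_colony
    detections, area_maps, gt = simulate_colony(config)
    write_colony(out_dir, detections, area_maps, gt)
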