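"""Spectral and bispectral embeddings of daily affinity matrices.

Each symmetric affinity matrix is embedded with Laplacian-eigenmap
coordinates: eigenvectors of the symmetrically degree-normalized adjacency
D^{-1/2} A D^{-1/2}, skipping the trivial leading eigenvector and keeping
the next ``n_dims``. Directed matrices are co-embedded with an SVD of the
degree-normalized matrix (bispectral decomposition), yielding one coordinate
set for the rows and one for the columns. A uniform epsilon added to
off-diagonal affinities guarantees a connected graph so every alive bee
receives coordinates.

Eigenvector signs are arbitrary and can invert between days; signs are
aligned by flipping a day when its Spearman correlation with the previous
day (over shared bees) is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import spearmanr

from .networks import (ALL_MODES, DIRECTED_MODES, SYMMETRIC_MODES, AffinityMatrix)

#: uniform off-diagonal regularization guaranteeing connectivity
EPSILON = 1e-8

#: fixed order of the embedding sets concatenated into daily factors
FACTOR_BLOCKS = tuple(
    [m for m in SYMMETRIC_MODES]
    + [f"{m}:{side}" for m in DIRECTED_MODES for side in ("row", "col")]
)


@dataclass
class ModeEmbedding:
    """Per-bee spectral coordinates for one mode on one day."""

    day: int
    mode: str
    index: list
    coordinates: np.ndarray  # n x n_dims

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.index):
            raise ValueError("coordinate rows must match index length")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")


def _regularized(matrix: AffinityMatrix) -> np.ndarray:
    # epsilon scales with the affinities so the embedding is exactly
    # invariant to a global rescaling of the matrix
    scale = matrix.values.max()
    a = matrix.values + EPSILON * (scale if scale > 0 else 1.0)
    np.fill_diagonal(a, 0.0)
    return a


def _fix_column_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic per-column sign: the largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(coords), axis=0)
    signs = np.sign(coords[idx, np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    return coords * signs


def spectral_embed(matrix: AffinityMatrix, n_dims: int = 8) -> ModeEmbedding:
    """Laplacian-eigenmap coordinates of a symmetric affinity matrix.

    Equivalent to the smallest nontrivial eigenvectors of the symmetric
    normalized Laplacian; invariant to a global rescaling of the affinities.
    """
    if not matrix.symmetric:
        raise ValueError("spectral_embed requires a symmetric matrix; "
                         "use bispectral_embed for directed modes")
    n = matrix.n
    if n <= n_dims:
        raise ValueError(f"need more than n_dims={n_dims} bees, got {n}; "
                         "reduce n_dims")
    a = _regularized(matrix)
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    norm = a * dinv[:, None] * dinv[None, :]
    evals, evecs = scipy.linalg.eigh(norm)
    order = np.argsort(evals)[::-1]  # descending; first is the trivial vector
    coords = _fix_column_signs(evecs[:, order[1:n_dims + 1]])
    return ModeEmbedding(day=matrix.day, mode=matrix.mode, index=list(matrix.index),
                         coordinates=coords)


def bispectral_embed(matrix: AffinityMatrix, n_dims: int = 8
                     ) -> tuple[ModeEmbedding, ModeEmbedding]:
    """SVD co-embedding of a directed affinity matrix.

    Left singular vectors of the degree-normalized matrix embed the rows
    (bees as actors), right singular vectors embed the columns (bees as
    targets); the trivial leading pair is skipped.
    """
    n = matrix.n
    if n <= n_dims:
        raise ValueError(f"need more than n_dims={n_dims} bees, got {n}; "
                         "reduce n_dims")
    a = _regularized(matrix)
    dr = a.sum(axis=1)
    dc = a.sum(axis=0)
    norm = a / np.sqrt(dr)[:, None] / np.sqrt(dc)[None, :]
    u, s, vt = scipy.linalg.svd(norm, full_matrices=False)
    rows = _fix_column_signs(u[:, 1:n_dims + 1])
    cols = _fix_column_signs(vt.T[:, 1:n_dims + 1])
    idx = list(matrix.index)
    return (ModeEmbedding(day=matrix.day, mode=f"{matrix.mode}:row", index=idx,
                          coordinates=rows),
            ModeEmbedding(day=matrix.day, mode=f"{matrix.mode}:col", index=idx,
                          coordinates=cols))


def align_signs(embeddings: list[ModeEmbedding]) -> tuple[list[ModeEmbedding], list[list[int]]]:
    """Chain sign flips forward through a day-ordered embedding sequence.

    For each dimension, day t is flipped when its Spearman correlation with
    the (already aligned) day t-1 over shared bees is negative. Returns the
    aligned sequence and, per dimension, the list of flipped day positions.
    """
    if not embeddings:
        return [], []
    aligned = [replace(embeddings[0], coordinates=embeddings[0].coordinates.copy())]
    n_dims = embeddings[0].coordinates.shape[1]
    flipped: list[list[int]] = [[] for _ in range(n_dims)]
    for t in range(1, len(embeddings)):
        prev, cur = aligned[-1], embeddings[t]
        prev_pos = {b: i for i, b in enumerate(prev.index)}
        shared = [(prev_pos[b], i) for i, b in enumerate(cur.index) if b in prev_pos]
        coords = cur.coordinates.copy()
        if len(shared) < 2:
            warnings.warn(f"fewer than 2 shared bees between days "
                          f"{prev.day} and {cur.day}; signs kept")
        else:
            ip, ic = map(np.array, zip(*shared))
            for j in range(n_dims):
                rho = spearmanr(prev.coordinates[ip, j], coords[ic, j]).statistic
                if np.isfinite(rho) and rho < 0:
                    coords[:, j] = -coords[:, j]
                    flipped[j].append(t)
        aligned.append(replace(cur, coordinates=coords))
    return aligned, flipped


def assemble_factors(mode_embeddings: dict[str, ModeEmbedding], day: int
                     ) -> pd.DataFrame:
    """Concatenate one day's aligned embeddings into the daily factor table.

    Blocks follow the fixed order :data:`FACTOR_BLOCKS`; every block must be
    present with an identical bee index. Returns a DataFrame with columns
    ``bee_id, day, f_000..f_{F-1}``.
    """
    missing = [b for b in FACTOR_BLOCKS if b not in mode_embeddings]
    if missing:
        raise ValueError(f"missing embedding blocks for day {day}: {missing}")
    first = mode_embeddings[FACTOR_BLOCKS[0]]
    blocks = []
    for name in FACTOR_BLOCKS:
        emb = mode_embeddings[name]
        if list(emb.index) != list(first.index):
            raise ValueError(f"index mismatch between blocks "
                             f"{FACTOR_BLOCKS[0]!r} and {name!r} on day {day}")
        blocks.append(emb.coordinates)
    mat = np.hstack(blocks)
    cols = [f"f_{i:03d}" for i in range(mat.shape[1])]
    out = pd.DataFrame(mat, columns=cols)
    out.insert(0, "day", day)
    out.insert(0, "bee_id", list(first.index))
    return out


def embed_daily_networks(networks: dict[int, dict[str, AffinityMatrix]],
                         n_dims: int = 8) -> pd.DataFrame:
    """Full embedding stage: embed, sign-align per mode, concatenate.

    ``networks`` maps day -> mode -> (already rank-transformed)
    AffinityMatrix. Sign alignment is applied per mode across days before
    concatenation. Returns the pooled daily-factor table over all days.
    """
    days = sorted(networks)
    per_block: dict[str, list[ModeEmbedding]] = {b: [] for b in FACTOR_BLOCKS}
    for day in days:
        mats = networks[day]
        for mode in SYMMETRIC_MODES:
            per_block[mode].append(spectral_embed(mats[mode], n_dims))
        for mode in DIRECTED_MODES:
            row, col = bispectral_embed(mats[mode], n_dims)
            per_block[f"{mode}:row"].append(row)
            per_block[f"{mode}:col"].append(col)
    aligned = {b: align_signs(seq)[0] for b, seq in per_block.items()}
    frames = []
    for k, day in enumerate(days):
        frames.append(assemble_factors({b: aligned[b][k] for b in FACTOR_BLOCKS}, day))
    return pd.concat(frames, ignore_index=True)
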