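"""Spatial statistics on lattice snapshots and the randomization experiment.

Given a snapshot of the lattice (an integer grid of type labels, 1 for
type A and 0 for type B) this module computes the observables the
analytical theory predicts — global composition, mean local partner
frequency around each type, community mean growth rate — and runs the
clustered-versus-randomized productivity experiment: compare the mean
growth rate of a spatially structured snapshot against copies whose cell
positions were permuted at fixed composition.  Clustering depresses the
growth of cross-feeders (cells sit in clonal patches, away from their
partners), so the ratio is below one for equilibrated cross-feeding
lattices and about one for unstructured ones.

Also here: generators for synthetic lattices with known ground truth
(random, checkerboard, striped, patchy), used throughout the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cellular_automaton import (
    CAConfig,
    _growth_rate_arrays,
    partner_counts,
    state_from_grid,
)

__all__ = [
    "SnapshotStats",
    "snapshot_stats",
    "randomize_lattice",
    "clustered_vs_randomized",
    "random_lattice",
    "checkerboard",
    "striped_lattice",
    "patchy_lattice",
    "save_snapshot",
    "load_snapshot",
]


@dataclass(frozen=True)
class SnapshotStats:
    """Observables of one lattice snapshot.

    Local frequencies are means over focal cells of the respective type,
    each using that type's interaction range; they are ``nan`` when the
    focal type is absent (never silently zero).
    """

    P_A: float
    P_BgA_local: float
    P_AgB_local: float
    mean_growth: float


def snapshot_stats(grid: np.ndarray, config: CAConfig) -> SnapshotStats:
    """Global frequency, mean local partner frequencies, mean growth rate.

    The global frequency is the plain count fraction.  The local
    frequency of, say, B around A is computed per focal A cell as the
    fraction of B among its ``r_A`` Moore neighbors, then averaged over
    all A cells.  The mean growth rate applies the configured growth
    model to every cell.
    """
    grid = np.asarray(grid, dtype=np.int32)
    state = state_from_grid(grid, config)
    n = grid.size
    n_a = int(grid.sum())
    p_a = n_a / n
    is_a = grid == 1
    if n_a > 0:
        p_bga = float(np.mean((config.r_A - state.cnt_A_dA[is_a]) / config.r_A))
    else:
        p_bga = math.nan
    if n_a < n:
        p_agb = float(np.mean(state.cnt_A_dB[~is_a] / config.r_B))
    else:
        p_agb = math.nan
    mean_growth = float(np.mean(_growth_rate_arrays(state, config)))
    return SnapshotStats(p_a, p_bga, p_agb, mean_growth)


def randomize_lattice(grid: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Uniform random permutation of site labels; composition preserved
    exactly."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    flat = np.asarray(grid).ravel().copy()
    rng.shuffle(flat)
    return flat.reshape(np.asarray(grid).shape)


def clustered_vs_randomized(
    grid: np.ndarray,
    config: CAConfig,
    n_randomizations: int = 20,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Productivity of the snapshot relative to its randomized copies.

    Returns ``(ratio, table)`` where ``ratio`` is the snapshot's mean
    growth rate divided by the average mean growth rate over
    ``n_randomizations`` independent label permutations, and ``table``
    lists each randomization's value.  Growth rates come from the
    configured lattice growth model applied to each arrangement.
    """
    grid = np.asarray(grid, dtype=np.int32)
    n_a = int(grid.sum())
    if n_a == 0 or n_a == grid.size:
        raise ValueError("randomization experiment needs both types present")
    clustered = snapshot_stats(grid, config).mean_growth
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_randomizations):
        rand_growth = snapshot_stats(randomize_lattice(grid, rng), config).mean_growth
        rows.append({"randomization": k, "mean_growth": rand_growth})
    table = pd.DataFrame(rows)
    randomized = float(table["mean_growth"].mean())
    ratio = clustered / randomized if randomized > 0 else math.nan
    return ratio, table


# ---------------------------------------------------------------------------
# synthetic lattices with known ground truth


def random_lattice(
    height: int, width: int, freq_A: float, seed: int = 0
) -> np.ndarray:
    """Independent per-site draws at frequency ``freq_A`` (no clustering)."""
    rng = np.random.default_rng(seed)
    return (rng.random((height, width)) < freq_A).astype(np.int32)


def checkerboard(height: int, width: int) -> np.ndarray:
    """Alternating types; every d=1 Moore neighborhood is half partner."""
    i, j = np.indices((height, width))
    return ((i + j) % 2).astype(np.int32)


def striped_lattice(height: int, width: int, freq_A: float = 0.5) -> np.ndarray:
    """Fully segregated: a single block of A rows above B rows."""
    grid = np.zeros((height, width), dtype=np.int32)
    grid[: int(round(freq_A * height)), :] = 1
    return grid


def patchy_lattice(
    height: int,
    width: int,
    freq_A: float,
    n_seeds: int = 12,
    seed: int = 0,
) -> np.ndarray:
    """Clustered lattice built by seeded patch growth.

    ``n_seeds`` seed sites are dropped at random and each remaining site
    takes the type of its nearest seed (toroidal distance); seed types
    are assigned to approximate the target composition, then single
    sites are flipped at patch boundaries until the composition matches
    ``freq_A`` exactly (up to integer count).
    """
    rng = np.random.default_rng(seed)
    si = rng.integers(0, height, n_seeds)
    sj = rng.integers(0, width, n_seeds)
    stype = (rng.random(n_seeds) < freq_A).astype(np.int32)
    i, j = np.indices((height, width))
    di = np.minimum(np.abs(i[..., None] - si), height - np.abs(i[..., None] - si))
    dj = np.minimum(np.abs(j[..., None] - sj), width - np.abs(j[..., None] - sj))
    nearest = np.argmin(di**2 + dj**2, axis=-1)
    grid = stype[nearest]
    target = int(round(freq_A * height * width))
    # adjust composition by flipping majority-type sites with the most
    # opposite-type neighbors (keeps patch structure intact)
    while grid.sum() != target:
        need_a = grid.sum() < target
        cand = np.argwhere(grid == (0 if need_a else 1))
        cnt = partner_counts(grid.astype(np.int32), 1)
        # neighbors of the type we want to grow
        score = cnt[cand[:, 0], cand[:, 1]] if need_a else 8 - cnt[cand[:, 0], cand[:, 1]]
        best = cand[np.argmax(score)]
        grid[best[0], best[1]] = 1 if need_a else 0
    return grid.astype(np.int32)


def save_snapshot(path, grid: np.ndarray) -> None:
    """Write a lattice as a plain integer matrix, one row per line."""
    np.savetxt(path, np.asarray(grid, dtype=int), fmt="%d")


def load_snapshot(path) -> np.ndarray:
    """Read a lattice written by :func:`save_snapshot`."""
    return np.loadtxt(path, dtype=np.int32, ndmin=2)
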