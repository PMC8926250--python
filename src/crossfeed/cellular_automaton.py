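"""Stochastic lattice simulation of the birth-replacement process.

Cells of two types fully occupy a square grid with periodic boundaries.
Each type interacts within its own extended Moore neighborhood (all
sites within Chebyshev distance ``d``, i.e. ``(2d+1)^2 - 1`` neighbors),
so the two types can have different interaction ranges.  One simulation
step is one replacement event: a cell is picked to reproduce with
probability proportional to its growth rate and its offspring overwrites
a uniformly random site in the replication neighborhood (range ``d_R``,
by default the smaller of the two interaction ranges).  Overwriting a
same-type neighbor is allowed — it leaves the composition unchanged but
still consumes the event.

The simulator is the independent numerical check on the pair
approximation, and the tool of choice in regimes (strong asymmetry,
strong clustering) where the moment closure degrades.

Implementation notes: growth rates are never recomputed globally.  Two
partner-count arrays (one per interaction range) are updated
incrementally over the affected window whenever a site flips type, and
the reproducing cell is drawn by rejection sampling against the maximum
attainable rate, giving O(1) amortized cost per event.  Runs are
bit-reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .biophysics import GrowthModel

__all__ = [
    "CAConfig",
    "LatticeState",
    "RunResult",
    "moore_offsets",
    "moore_size",
    "moore_range_for_size",
    "cell_growth_rate",
    "partner_counts",
    "link_counts",
    "step",
    "run",
    "ensemble",
]

_REJECTION_BATCH = 4096


def moore_size(d: int) -> int:
    """Neighbors in an extended Moore neighborhood of range d: (2d+1)^2 - 1."""
    return (2 * d + 1) ** 2 - 1


def moore_range_for_size(r: float) -> int:
    """Smallest Moore range whose neighborhood size is >= r (inverse of
    :func:`moore_size`, rounding the continuous size to the lattice)."""
    return max(1, round((np.sqrt(r + 1.0) - 1.0) / 2.0))


def moore_offsets(d: int) -> list[tuple[int, int]]:
    """Coordinate offsets of the extended Moore neighborhood of range d.

    All ``(i, j)`` with ``max(|i|, |j|) <= d`` except the origin;
    ``(2d+1)^2 - 1`` offsets (8 at d=1, 120 at d=5, empty at d=0).
    """
    if d < 0:
        raise ValueError("Moore range must be >= 0")
    return [
        (i, j)
        for i in range(-d, d + 1)
        for j in range(-d, d + 1)
        if (i, j) != (0, 0)
    ]


@dataclass(frozen=True)
class CAConfig:
    """Parameters of one lattice simulation.

    ``d_A`` / ``d_B`` are the extended Moore interaction ranges of the
    two types (neighborhood sizes ``(2d+1)^2 - 1``); ``d_R`` the
    replication range, defaulting to ``min(d_A, d_B)``.  ``n_events``
    counts replacement events (one reproducing cell per event).
    """

    d_A: int
    d_B: int
    mu_hat_A: float
    mu_hat_B: float
    height: int = 100
    width: int = 100
    periodic: bool = True
    d_R: int | None = None
    growth_model: GrowthModel = GrowthModel.FREQUENCY_LINEAR
    init_freq_A: float = 0.5
    seed: int = 0
    n_events: int = 100_000

    def __post_init__(self) -> None:
        if not self.periodic:
            raise NotImplementedError("only periodic boundaries are implemented")
        if min(self.d_A, self.d_B) < 1:
            raise ValueError("interaction ranges must be >= 1")
        if 2 * max(self.d_A, self.d_B, self.replication_range) + 1 > min(
            self.height, self.width
        ):
            raise ValueError("neighborhood does not fit on the lattice")
        if not 0.0 <= self.init_freq_A <= 1.0:
            raise ValueError("init_freq_A must be in [0, 1]")
        if self.mu_hat_A < 0 or self.mu_hat_B < 0:
            raise ValueError("growth rates must be >= 0")
        if not isinstance(self.growth_model, GrowthModel):
            object.__setattr__(self, "growth_model", GrowthModel(self.growth_model))

    @property
    def replication_range(self) -> int:
        return self.d_R if self.d_R is not None else min(self.d_A, self.d_B)

    @property
    def r_A(self) -> int:
        return moore_size(self.d_A)

    @property
    def r_B(self) -> int:
        return moore_size(self.d_B)


@dataclass
class LatticeState:
    """Mutable simulation state.

    ``grid`` holds 1 for type A and 0 for type B.  ``cnt_A_dA[x]`` /
    ``cnt_A_dB[x]`` cache the number of A cells within range ``d_A`` /
    ``d_B`` of site ``x`` (excluding ``x`` itself); they are maintained
    incrementally.  ``rng`` is the seeded generator whose state makes
    trajectories reproducible and resumable.
    """

    grid: np.ndarray
    cnt_A_dA: np.ndarray
    cnt_A_dB: np.ndarray
    n_A: int
    event_count: int
    rng: np.random.Generator
    absorbed: bool = False


def partner_counts(grid: np.ndarray, d: int) -> np.ndarray:
    """Number of A cells (value 1) within Chebyshev range d of each site,
    excluding the site itself; periodic boundaries."""
    c = np.zeros(grid.shape, dtype=np.int32)
    for di in range(-d, d + 1):
        for dj in range(-d, d + 1):
            c += np.roll(np.roll(grid, di, axis=0), dj, axis=1)
    return c - grid


def _init_state(config: CAConfig) -> LatticeState:
    rng = np.random.default_rng(config.seed)
    grid = (rng.random((config.height, config.width)) < config.init_freq_A).astype(
        np.int32
    )
    return state_from_grid(grid, config, rng)


def state_from_grid(
    grid: np.ndarray, config: CAConfig, rng: np.random.Generator | None = None
) -> LatticeState:
    """Wrap an existing lattice snapshot into a simulation state."""
    grid = np.asarray(grid, dtype=np.int32)
    if grid.shape != (config.height, config.width):
        raise ValueError("snapshot shape does not match config")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return LatticeState(
        grid=grid,
        cnt_A_dA=partner_counts(grid, config.d_A),
        cnt_A_dB=partner_counts(grid, config.d_B),
        n_A=int(grid.sum()),
        event_count=0,
        rng=rng,
    )


def _growth_rate_arrays(state: LatticeState, config: CAConfig) -> np.ndarray:
    """Growth rate of every cell on the lattice (vectorized)."""
    is_a = state.grid == 1
    n_b_for_a = config.r_A - state.cnt_A_dA  # partners of A cells
    n_a_for_b = state.cnt_A_dB               # partners of B cells
    model = config.growth_model
    if model is GrowthModel.FREQUENCY_LINEAR:
        rate_a = config.mu_hat_A * n_b_for_a / config.r_A
        rate_b = config.mu_hat_B * n_a_for_b / config.r_B
    elif model is GrowthModel.DENSITY_LINEAR:
        rate_a = config.mu_hat_A * n_b_for_a
        rate_b = config.mu_hat_B * n_a_for_b
    elif model is GrowthModel.INHIBITION_LINEAR:
        rate_a = config.mu_hat_A * (1.0 - n_b_for_a / config.r_A)
        rate_b = config.mu_hat_B * (1.0 - n_a_for_b / config.r_B)
    else:
        raise ValueError(f"no lattice growth rule for model {model}")
    return np.where(is_a, rate_a, rate_b)


def cell_growth_rate(state: LatticeState, position: tuple[int, int],
                     config: CAConfig) -> float:
    """Growth rate of the cell at ``position``.

    Frequency-linear: ``mu_hat * (partner count) / r`` with the cell's
    own range — zero in a monoculture neighborhood, ``mu_hat`` when
    fully surrounded by partners.  Density: ``mu_hat * count``.
    Inhibition: ``mu_hat * (1 - count / r)``.
    """
    i, j = position
    if state.grid[i, j] == 1:
        n_partner, r, mu = (
            config.r_A - state.cnt_A_dA[i, j], config.r_A, config.mu_hat_A,
        )
    else:
        n_partner, r, mu = state.cnt_A_dB[i, j], config.r_B, config.mu_hat_B
    model = config.growth_model
    if model is GrowthModel.FREQUENCY_LINEAR:
        return mu * n_partner / r
    if model is GrowthModel.DENSITY_LINEAR:
        return mu * float(n_partner)
    if model is GrowthModel.INHIBITION_LINEAR:
        return mu * (1.0 - n_partner / r)
    raise ValueError(f"no lattice growth rule for model {model}")


def _max_rate(config: CAConfig) -> float:
    if config.growth_model is GrowthModel.DENSITY_LINEAR:
        return max(config.mu_hat_A * config.r_A, config.mu_hat_B * config.r_B)
    return max(config.mu_hat_A, config.mu_hat_B)


def _flip(state: LatticeState, config: CAConfig, i: int, j: int, new_type: int) -> None:
    """Overwrite site (i, j) with ``new_type`` and update count caches."""
    h, w = config.height, config.width
    delta = 1 if new_type == 1 else -1
    state.grid[i, j] = new_type
    state.n_A += delta
    for cnt, d in ((state.cnt_A_dA, config.d_A), (state.cnt_A_dB, config.d_B)):
        rows = (i + np.arange(-d, d + 1)) % h
        cols = (j + np.arange(-d, d + 1)) % w
        cnt[np.ix_(rows, cols)] += delta
        cnt[i, j] -= delta  # a site does not count itself


def _is_fixed(state: LatticeState, config: CAConfig) -> bool:
    return state.n_A == 0 or state.n_A == config.height * config.width


def step(state: LatticeState, config: CAConfig) -> LatticeState:
    """Execute one replacement event in place (also returns the state).

    A reproducing cell is drawn with probability proportional to its
    growth rate (rejection sampling against the maximal rate); one site
    in its replication neighborhood is overwritten with its type.  In an
    absorbing state (fixation, where composition can no longer change)
    the state is returned unchanged with ``absorbed`` set.
    """
    if _is_fixed(state, config):
        state.absorbed = True
        return state
    h, w = config.height, config.width
    g_max = _max_rate(config)
    offs = moore_offsets(config.replication_range)
    rng = state.rng
    batch = 32  # single event: small draws keep repeated step() calls cheap
    while True:
        sites = rng.integers(0, h * w, batch)
        accepts = rng.random(batch)
        picks = rng.integers(0, len(offs), batch)
        for t in range(batch):
            i, j = divmod(int(sites[t]), w)
            if accepts[t] * g_max >= cell_growth_rate(state, (i, j), config):
                continue
            oi, oj = offs[int(picks[t])]
            ni, nj = (i + oi) % h, (j + oj) % w
            state.event_count += 1
            if state.grid[ni, nj] != state.grid[i, j]:
                _flip(state, config, ni, nj, int(state.grid[i, j]))
            return state


@dataclass
class RunResult:
    """Trajectory of observables plus the final lattice."""

    trajectory: pd.DataFrame
    final_grid: np.ndarray
    absorbed: bool
    config: CAConfig
    n_plus: int = 0   # A-replaced-B events
    n_minus: int = 0  # B-replaced-A events


def _observables(state: LatticeState, config: CAConfig) -> tuple[float, ...]:
    n = config.height * config.width
    p_a = state.n_A / n
    is_a = state.grid == 1
    if state.n_A > 0:
        p_bga = float(
            np.mean((config.r_A - state.cnt_A_dA[is_a]) / config.r_A)
        )
    else:
        p_bga = np.nan
    if state.n_A < n:
        p_agb = float(np.mean(state.cnt_A_dB[~is_a] / config.r_B))
    else:
        p_agb = np.nan
    mean_growth = float(np.mean(_growth_rate_arrays(state, config)))
    return p_a, p_bga, p_agb, mean_growth


def run(config: CAConfig, n_samples: int = 51) -> RunResult:
    """Run ``config.n_events`` replacement events, sampling observables.

    Observables (``P_A``, the two mean local partner frequencies, and
    the community mean growth rate) are recorded on an evenly spaced
    event grid of ``n_samples`` points including event 0 and the final
    event.  Fixation terminates the run early with ``absorbed=True``.
    The whole trajectory is reproducible from ``(config, seed)``.
    """
    state = _init_state(config)
    sample_at = np.unique(
        np.linspace(0, config.n_events, n_samples).astype(np.int64)
    )
    rows = [(0, *_observables(state, config))]
    n_plus = n_minus = 0
    h, w = config.height, config.width
    g_max = _max_rate(config)
    offs = moore_offsets(config.replication_range)
    rng = state.rng
    next_sample = 1
    done = False
    while not done:
        if _is_fixed(state, config):
            state.absorbed = True
            break
        sites = rng.integers(0, h * w, _REJECTION_BATCH)
        accepts = rng.random(_REJECTION_BATCH)
        picks = rng.integers(0, len(offs), _REJECTION_BATCH)
        for t in range(_REJECTION_BATCH):
            i, j = divmod(int(sites[t]), w)
            if accepts[t] * g_max >= cell_growth_rate(state, (i, j), config):
                continue
            oi, oj = offs[int(picks[t])]
            ni, nj = (i + oi) % h, (j + oj) % w
            state.event_count += 1
            parent = int(state.grid[i, j])
            if state.grid[ni, nj] != parent:
                _flip(state, config, ni, nj, parent)
                if parent == 1:
                    n_plus += 1
                else:
                    n_minus += 1
            if (
                next_sample < len(sample_at)
                and state.event_count >= sample_at[next_sample]
            ):
                rows.append((state.event_count, *_observables(state, config)))
                next_sample += 1
            if state.event_count >= config.n_events or _is_fixed(state, config):
                done = True
                break
    if _is_fixed(state, config):
        state.absorbed = True
    if rows[-1][0] != state.event_count:
        rows.append((state.event_count, *_observables(state, config)))
    traj = pd.DataFrame(
        rows, columns=["event", "P_A", "P_BgA", "P_AgB", "mean_growth"]
    )
    return RunResult(
        trajectory=traj,
        final_grid=state.grid.copy(),
        absorbed=state.absorbed,
        config=config,
        n_plus=n_plus,
        n_minus=n_minus,
    )


def link_counts(grid: np.ndarray, config: CAConfig) -> tuple[float, float, float, float]:
    """Directed link counts (N_AA, N_AB, N_BA, N_BB) of a snapshot.

    A cells receive from their ``r_A`` Moore neighbors, B cells from
    their ``r_B`` neighbors; used by the single-event bookkeeping
    checks against the pair approximation.
    """
    is_a = grid == 1
    c_a = partner_counts(np.asarray(grid, dtype=np.int32), config.d_A)
    c_b = partner_counts(np.asarray(grid, dtype=np.int32), config.d_B)
    n_aa = float(c_a[is_a].sum())
    n_ab = float((config.r_A - c_a[is_a]).sum())
    n_ba = float(c_b[~is_a].sum())
    n_bb = float((config.r_B - c_b[~is_a]).sum())
    return n_aa, n_ab, n_ba, n_bb


def ensemble(
    config: CAConfig,
    n_replicates: int,
    seeds: Sequence[int] | None = None,
    n_samples: int = 51,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate runs with distinct seeds; summary with normal-theory CI.

    Returns ``(summary, per_replicate)``: the per-replicate table holds
    the final value of each observable for each seed; the summary holds
    mean, standard error and a 95 percent confidence interval per
    observable.
    """
    if n_replicates < 2:
        raise ValueError("ensemble needs n_replicates >= 2")
    if seeds is None:
        seeds = [config.seed + k for k in range(n_replicates)]
    if len(seeds) != n_replicates:
        raise ValueError("need one seed per replicate")
    rows = []
    for s in seeds:
        res = run(replace(config, seed=int(s)), n_samples=n_samples)
        last = res.trajectory.iloc[-1]
        rows.append(
            {
                "seed": int(s),
                "events": int(last["event"]),
                "P_A": last["P_A"],
                "P_BgA": last["P_BgA"],
                "P_AgB": last["P_AgB"],
                "mean_growth": last["mean_growth"],
                "absorbed": res.absorbed,
            }
        )
    per_rep = pd.DataFrame(rows)
    obs = ["P_A", "P_BgA", "P_AgB", "mean_growth"]
    summary_rows = []
    for name in obs:
        vals = per_rep[name].to_numpy(dtype=float)
        mean = float(np.nanmean(vals))
        sem = float(np.nanstd(vals, ddof=1) / np.sqrt(len(vals)))
        summary_rows.append(
            {
                "observable": name,
                "mean": mean,
                "sem": sem,
                "ci95_low": mean - 1.96 * sem,
                "ci95_high": mean + 1.96 * sem,
            }
        )
    return pd.DataFrame(summary_rows), per_rep
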