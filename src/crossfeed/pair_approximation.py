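"""Directed-graph pair approximation for two-type spatial communities.

The community is a constant-size population of two cell types, A and B,
on a regular directed interaction graph: every A cell receives building
blocks from ``r_A`` neighbors, every B cell from ``r_B`` neighbors
(``r_B >= r_A`` by convention).  A directed link ``X<-Y`` means focal
cell X receives from neighbor Y; unequal neighborhood sizes make the
graph directed and the total link count dynamic.

Reproduction follows a birth-replacement (Moran-like) process: a cell is
picked to reproduce proportionally to its growth rate, and its offspring
overwrites a random cell in the *replication neighborhood*, taken equal
to the smaller interaction neighborhood (``r_R = r_A``).

Pair approximation closes the dynamics on three variables: the global
frequency ``P(A)`` and the two local (conditional) partner frequencies
``P(B|A, r_A)`` and ``P(A|B, r_B)``.  Link counts evolve as

    dN_{X<-Y}/dt = T+ * Delta+_{XY} + T- * Delta-_{XY}

where ``T+`` (``T-``) is the rate of A-replaces-B (B-replaces-A) events
and the Delta vectors do the link bookkeeping of a single replacement.

Closure across ranges
---------------------
The conditional composition of a neighborhood depends on its radius: a
small neighborhood is dominated by the focal cell's own clonal patch, a
large one approaches the global composition.  The dynamics only track
each type's conditional at its *native* range (``P(B|A, r_A)`` and
``P(A|B, r_B)``), but the bookkeeping also needs the other two
conditionals.  We close them with the universal local-to-global law:
``P(A|B, r_A) = g(r_A) P(A)`` and ``P(B|A, r_B) = g(r_B) P(B)`` with
``g(r) = (r - 2)/(r - 1)``, the steady-state ratio of local to global
partner frequency.  In particular the probability that the A neighbor of
a reproducing B lies inside the (smaller) replication neighborhood is
``kappa = g(r_A) P(A) / P(A|B, r_B)``, which tends to ``g(r_A)/g(r_B)``
at steady state.  This closure is self-consistent at equilibrium and
makes the interior fixed point unique: the ODE fixed point coincides, to
machine precision, with the closed-form equilibrium
:func:`steady_state_frequency` and the local-structure law
:func:`local_to_global_ratio` — and the local-structure law emerges for
*every* growth model, because the bookkeeping vectors do not depend on
the growth function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import binom

from .biophysics import GrowthModel, LocalRules

__all__ = [
    "PairState",
    "CompositionProbabilities",
    "EquilibriumResult",
    "probabilities_from_links",
    "state_from_probabilities",
    "transition_rates",
    "link_change_vectors",
    "ode_rhs",
    "integrate",
    "steady_state_frequency",
    "well_mixed_frequency",
    "local_to_global_ratio",
    "productivity",
    "collapse_interval",
    "steady_state_general",
    "equilibrium",
]

# declared equilibrium when max |dN/dt| / N falls below this (per unit time)
EQUILIBRIUM_RATE_TOL = 1e-9
_RTOL, _ATOL = 1e-8, 1e-10
_BRACKET_EPS = 1e-9


class InconsistentStateError(ValueError):
    """Link counts violate the regular-graph bookkeeping identities."""


@dataclass(frozen=True)
class PairState:
    """Directed link counts of the community.

    ``N_XY`` counts ``X<-Y`` links (focal X receives from neighbor Y).
    Counts are real-valued: pair approximation tracks expectations, not
    integer realizations.  Consistency with the regular graph requires
    ``(N_AA + N_AB)/r_A + (N_BA + N_BB)/r_B == N``, i.e. in-degrees
    ``r_A`` per A cell and ``r_B`` per B cell.
    """

    N: float
    N_AA: float
    N_AB: float
    N_BA: float
    N_BB: float

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise InconsistentStateError("total cell count N must be > 0")
        for name in ("N_AA", "N_AB", "N_BA", "N_BB"):
            if getattr(self, name) < -1e-9:
                raise InconsistentStateError(f"{name} must be >= 0")

    def n_cells(self, rules: LocalRules) -> tuple[float, float]:
        """(N_A, N_B) implied by the in-degree identities; validates."""
        n_a = (self.N_AA + self.N_AB) / rules.r_A
        n_b = (self.N_BA + self.N_BB) / rules.r_B
        if abs(n_a + n_b - self.N) > 1e-6 * self.N:
            raise InconsistentStateError(
                "link counts inconsistent: (N_AA+N_AB)/r_A + (N_BA+N_BB)/r_B != N"
            )
        return n_a, n_b


@dataclass(frozen=True)
class CompositionProbabilities:
    """Global composition and local (conditional) partner frequencies.

    ``P_A`` is the global frequency of type A; ``P_BgA`` the mean
    frequency of B within the interaction neighborhood of an A cell;
    ``P_AgB`` the mean frequency of A within a B cell's neighborhood.
    """

    P_A: float
    P_BgA: float
    P_AgB: float

    def __post_init__(self) -> None:
        for name in ("P_A", "P_BgA", "P_AgB"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class EquilibriumResult:
    """Steady state of the community: composition, structure, productivity."""

    P_A: float
    P_BgA: float
    P_AgB: float
    productivity_spatial: float
    productivity_wm: float
    productivity_ratio: float
    collapsed: str  # "none" | "A_fixed" | "B_fixed"


def probabilities_from_links(
    state: PairState, rules: LocalRules
) -> CompositionProbabilities:
    """Change variables from link counts to composition probabilities.

    ``P(A) = (N_AA + N_AB) / (r_A N)``; ``P(B|A) = N_AB / (N_AA +
    N_AB)``; ``P(A|B) = N_BA / (N_BA + N_BB)``.  A conditional whose
    focal type is absent is reported as 0 (convention).
    """
    n_a, n_b = state.n_cells(rules)
    p_a = min(max(n_a / state.N, 0.0), 1.0)
    in_a = state.N_AA + state.N_AB
    in_b = state.N_BA + state.N_BB
    p_bga = state.N_AB / in_a if in_a > 0 else 0.0
    p_agb = state.N_BA / in_b if in_b > 0 else 0.0
    return CompositionProbabilities(p_a, min(p_bga, 1.0), min(p_agb, 1.0))


def state_from_probabilities(
    probs: CompositionProbabilities, rules: LocalRules, N: float = 1.0
) -> PairState:
    """Inverse of :func:`probabilities_from_links` (exact round trip)."""
    n_a = probs.P_A * N
    n_b = N - n_a
    return PairState(
        N=N,
        N_AA=rules.r_A * n_a * (1.0 - probs.P_BgA),
        N_AB=rules.r_A * n_a * probs.P_BgA,
        N_BA=rules.r_B * n_b * probs.P_AgB,
        N_BB=rules.r_B * n_b * (1.0 - probs.P_AgB),
    )


def local_to_global_ratio(r: float) -> float:
    """Steady-state ratio of local to global partner frequency, (r-2)/(r-1).

    With three neighbors the partner frequency seen by a cell is half
    the global one; the ratio approaches 1 (well-mixed) as ``r`` grows,
    exceeding 0.99 from ``r = 101`` on.
    """
    if r < 2:
        raise ValueError("local/global ratio requires r >= 2")
    return (r - 2.0) / (r - 1.0)


def _kappa(probs: CompositionProbabilities, rules: LocalRules) -> float:
    """P(partner in replication neighborhood | partner in interaction
    neighborhood): P(A|B, r_A) / P(A|B, r_B) with the numerator closed
    as g(r_A) P(A).  Falls back to the steady-state value g(r_A)/g(r_B)
    when the denominator vanishes; clamped to [0, 1]."""
    g_a = local_to_global_ratio(rules.r_A)
    if probs.P_AgB <= 1e-12:
        return g_a / local_to_global_ratio(rules.r_B)
    return min(1.0, g_a * probs.P_A / probs.P_AgB)


def _mean_growth_given_partner_freq(
    f: float, r: float, mu: float, model: GrowthModel,
    custom: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> float:
    """E[growth rate] of a cell whose neighborhood has partner frequency f."""
    if model is GrowthModel.FREQUENCY_LINEAR:
        return mu * f
    if model is GrowthModel.DENSITY_LINEAR:
        return mu * r * f
    if model is GrowthModel.INHIBITION_LINEAR:
        return mu * (1.0 - f)
    n = np.arange(int(round(r)) + 1)
    pmf = binom.pmf(n, int(round(r)), f)
    return float(np.sum(pmf * custom(n, r)))


def _event_factor(
    q: float, r: float, mu: float, model: GrowthModel,
    custom: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> float:
    """E[g(n) * n] / r for n ~ Binomial(r, q): growth-weighted chance that
    the replaced neighbor is of the partner type.

    Closed forms for the linear models; a binomial sum for custom growth
    functions (which then require integer ``r``).
    """
    if model is GrowthModel.FREQUENCY_LINEAR:
        # E[n^2] / r^2 = q (1 + (r-1) q) / r
        return mu * q * (1.0 + (r - 1.0) * q) / r
    if model is GrowthModel.DENSITY_LINEAR:
        # E[n^2] / r = q (1 - q + r q)
        return mu * q * (1.0 - q + r * q)
    if model is GrowthModel.INHIBITION_LINEAR:
        # E[(1 - n/r) n] / r = q (1 - q) (r - 1) / r
        return mu * q * (1.0 - q) * (r - 1.0) / r
    if custom is None:
        raise ValueError("custom growth model requires a growth function")
    ri = int(round(r))
    n = np.arange(ri + 1)
    pmf = binom.pmf(n, ri, q)
    return float(np.sum(pmf * custom(n, r) * n)) / ri


def transition_rates(
    probs: CompositionProbabilities,
    rules: LocalRules,
    growth_A: Callable[[np.ndarray, float], np.ndarray] | None = None,
    growth_B: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> tuple[float, float]:
    """Per-capita rates of the two composition-changing events.

    ``T+`` is the rate at which an A reproduces *and* its offspring
    overwrites a B; ``T-`` the reverse.  For the frequency-linear model,

        T+ = P(A) P(B|A) [1 + P(B|A)(r_A - 1)] / r_A * mu_hat_A
        T- = P(B) P(A|B) [1 + P(A|B)(r_B - 1)] / r_B * mu_hat_B * kappa

    where ``kappa`` corrects for the replaced A having to lie inside the
    smaller replication neighborhood of the reproducing B.  Other growth
    models replace the bracketed growth-weighting factor accordingly.
    """
    model = rules.growth_model
    t_plus = probs.P_A * _event_factor(
        probs.P_BgA, rules.r_A, rules.mu_hat_A, model, growth_A
    )
    t_minus = (
        (1.0 - probs.P_A)
        * _event_factor(probs.P_AgB, rules.r_B, rules.mu_hat_B, model, growth_B)
        * _kappa(probs, rules)
    )
    return t_plus, t_minus


def link_change_vectors(
    probs: CompositionProbabilities, rules: LocalRules
) -> tuple[np.ndarray, np.ndarray]:
    """Expected link-count changes per replacement event.

    Returns ``(delta_plus, delta_minus)``, each a length-4 array ordered
    ``(N_AA, N_AB, N_BA, N_BB)``.  ``delta_plus`` is the expected change
    when an A offspring overwrites a B cell; ``delta_minus`` the mirror
    event.

    Bookkeeping: the overwritten cell loses its in-links (typed by the
    conditional composition of its neighborhood, which contains the
    reproducing parent for certain) and the cells that received from it
    re-type those links; the new cell gains in-links per its own degree.
    Neighborhood compositions at radii other than a type's native one
    are obtained with the cross-range closure (see module docstring) and
    clamped to [0, 1].

    Conservation: after ``delta_plus``, ``N_AA + N_AB`` rises by exactly
    ``r_A`` and ``N_BA + N_BB`` falls by exactly ``r_B`` (one B cell
    became an A cell); mirrored for ``delta_minus``.
    """
    r_a, r_b = rules.r_A, rules.r_B
    g_a, g_b = local_to_global_ratio(r_a), local_to_global_ratio(r_b)
    s = probs.P_AgB                          # P(A | B, r_B), dynamical
    s_a = min(1.0, g_a * probs.P_A)          # P(A | B, r_A) via closure
    p = probs.P_BgA                          # P(B | A, r_A), dynamical
    p_b = min(1.0, g_b * (1.0 - probs.P_A))  # P(B | A, r_B) via closure

    # A-replaces-B: composition of the removed B's neighborhood, with the
    # reproducing A known to be present in the replication (r_A) range.
    nA_rA = 1.0 + (r_a - 1.0) * s_a
    nB_rA = (r_a - 1.0) * (1.0 - s_a)
    nA_rB = 1.0 + (r_b - 1.0) * s
    nB_rB = (r_b - 1.0) * (1.0 - s)
    delta_plus = np.array(
        [
            2.0 * nA_rA,            # new A<-A in-links + A<-site retyped
            nB_rA - nA_rA,          # new A<-B in-links - retyped A<-site
            nB_rB - nA_rB,          # B<-site retyped - removed B<-A
            -2.0 * nB_rB,           # removed B<-B in-links + retyped B<-site
        ]
    )

    # B-replaces-A: mirror, around the removed A cell.
    mB_rA = 1.0 + (r_a - 1.0) * p
    mA_rA = (r_a - 1.0) * (1.0 - p)
    mB_rB = 1.0 + (r_b - 1.0) * p_b
    mA_rB = (r_b - 1.0) * (1.0 - p_b)
    delta_minus = np.array(
        [
            -2.0 * mA_rA,
            mA_rA - mB_rA,
            mA_rB - mB_rB,
            2.0 * mB_rB,
        ]
    )
    return delta_plus, delta_minus


def ode_rhs(state: PairState, rules: LocalRules, **growth) -> np.ndarray:
    """dN_XY/dt = T+ Delta+_XY + T- Delta-_XY, ordered (AA, AB, BA, BB).

    Only three components are independent: the in-degree identities tie
    the fourth to the total cell count, which the dynamics conserve.
    """
    probs = probabilities_from_links(state, rules)
    if probs.P_A <= 0.0 or probs.P_A >= 1.0:
        return np.zeros(4)  # absorbing monoculture
    t_plus, t_minus = transition_rates(probs, rules, **growth)
    d_plus, d_minus = link_change_vectors(probs, rules)
    return state.N * (t_plus * d_plus + t_minus * d_minus)


def _consistent_state(y: np.ndarray, rules: LocalRules, N: float) -> PairState:
    """Project reduced coordinates (N_AA, N_AB, N_BA) onto a consistent
    PairState: counts non-negative, in-degree identities exact."""
    n_aa, n_ab, n_ba = np.maximum(y, 0.0)
    in_a = n_aa + n_ab
    if in_a > rules.r_A * N:  # P_A cannot exceed 1
        scale = rules.r_A * N / in_a
        n_aa, n_ab = n_aa * scale, n_ab * scale
        in_a = rules.r_A * N
    n_b = N - in_a / rules.r_A
    n_ba = min(n_ba, rules.r_B * n_b)
    n_bb = rules.r_B * n_b - n_ba
    return PairState(N=N, N_AA=n_aa, N_AB=n_ab, N_BA=n_ba, N_BB=n_bb)


def _rhs_reduced(y: np.ndarray, rules: LocalRules, N: float, **growth) -> np.ndarray:
    """RHS on the three independent coordinates (N_AA, N_AB, N_BA)."""
    state = _consistent_state(y, rules, N)
    return ode_rhs(state, rules, **growth)[:3] / N


def integrate(
    state0: PairState,
    rules: LocalRules,
    t_end: float,
    t_eval: Sequence[float] | None = None,
    **growth,
) -> pd.DataFrame:
    """Integrate the link dynamics; return the composition trajectory.

    Stiff-capable (LSODA) integration at rtol 1e-8 / atol 1e-10.
    Returns a DataFrame with columns ``t, P_A, P_BgA, P_AgB``.  Raises
    ``RuntimeError`` with the solver message on failure.
    """
    y0 = np.array([state0.N_AA, state0.N_AB, state0.N_BA]) / state0.N
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return _rhs_reduced(y, rules, 1.0, **growth)

    def absorbed(t: float, y: np.ndarray) -> float:
        # hits zero when either type is (numerically) extinct
        p_a = min(max((y[0] + y[1]) / rules.r_A, 0.0), 1.0)
        return min(p_a, 1.0 - p_a) - 1e-9

    def settled(t: float, y: np.ndarray) -> float:
        return float(np.max(np.abs(rhs(t, y)))) - EQUILIBRIUM_RATE_TOL

    absorbed.terminal = True  # type: ignore[attr-defined]
    settled.terminal = True  # type: ignore[attr-defined]
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        y0,
        method="LSODA",
        t_eval=np.asarray(t_eval, dtype=float),
        events=[absorbed, settled],
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"pair-approximation integration failed: {sol.message}")
    rows = []
    for t, y in zip(sol.t, sol.y.T):
        probs = probabilities_from_links(_consistent_state(y, rules, 1.0), rules)
        rows.append((t, probs.P_A, probs.P_BgA, probs.P_AgB))
    # if an event stopped the run early, append the terminal point
    if sol.status == 1 and (len(rows) == 0 or sol.t_events is not None):
        for te, ye in zip(sol.t_events, sol.y_events):
            for t, y in zip(te, ye):
                if len(rows) == 0 or t > rows[-1][0]:
                    probs = probabilities_from_links(
                        _consistent_state(y, rules, 1.0), rules
                    )
                    rows.append((t, probs.P_A, probs.P_BgA, probs.P_AgB))
    return pd.DataFrame(rows, columns=["t", "P_A", "P_BgA", "P_AgB"])


def _unclamped_frequency(rules: LocalRules) -> float:
    r_a, r_b = rules.r_A, rules.r_B
    mu_a, mu_b = rules.mu_hat_A, rules.mu_hat_B
    num = mu_a * (r_a - 2.0) / r_a + (mu_a / r_a - mu_b / r_b)
    den = mu_a * (r_a - 2.0) / r_a + mu_b * (r_b - 2.0) / r_b
    if den == 0:
        raise ValueError("degenerate rules: both effective growth terms vanish")
    return num / den


def steady_state_frequency(rules: LocalRules) -> float:
    """Closed-form equilibrium global frequency of type A (clamped).

    For the frequency-linear model,

        P(A) = [mu_A (r_A - 2)/r_A + mu_A/r_A - mu_B/r_B]
               / [mu_A (r_A - 2)/r_A + mu_B (r_B - 2)/r_B]

    Values outside (0, 1) mean one type fixes (community collapse for
    cross-feeders); the result is clamped to [0, 1].  Use
    :func:`equilibrium` to obtain the collapse flag alongside.
    """
    if rules.r_A < 2:
        raise ValueError("closed-form equilibrium requires r_A >= 2")
    if rules.growth_model is not GrowthModel.FREQUENCY_LINEAR:
        raise ValueError("closed form applies to the frequency_linear model")
    return min(max(_unclamped_frequency(rules), 0.0), 1.0)


def well_mixed_frequency(rules: LocalRules) -> float:
    """Equilibrium frequency of A in a well-mixed system: mu_A/(mu_A+mu_B)."""
    tot = rules.mu_hat_A + rules.mu_hat_B
    if tot <= 0:
        raise ValueError("well-mixed equilibrium undefined when both rates are 0")
    return rules.mu_hat_A / tot


def collapse_interval(r_A: float, r_B: float) -> tuple[float, float]:
    """Open interval of mu_A/mu_B ratios with stable coexistence.

    Outside it the equilibrium leaves (0, 1) and one type fixes even
    though the pair could coexist in a well-mixed system.  Endpoints
    solve the closed-form equilibrium equal to 0 and 1:

        lower = r_A / (r_B (r_A - 1)),  upper = r_A (r_B - 1) / r_B

    Symmetric case r_A = r_B = 3 gives (1/2, 2); both bounds diverge
    away from each other as the neighborhoods grow (well-mixed systems
    coexist at any ratio).
    """
    if r_A < 2 or r_B < 2:
        raise ValueError("collapse interval requires r_A, r_B >= 2")
    return r_A / (r_B * (r_A - 1.0)), r_A * (r_B - 1.0) / r_B


def _collapse_state(rules: LocalRules, a_fixed: bool) -> EquilibriumResult:
    x_wm = well_mixed_frequency(rules)
    wm = _wm_productivity(rules, x_wm)
    return EquilibriumResult(
        P_A=1.0 if a_fixed else 0.0,
        P_BgA=0.0,
        P_AgB=0.0,
        productivity_spatial=0.0,
        productivity_wm=wm,
        productivity_ratio=0.0,
        collapsed="A_fixed" if a_fixed else "B_fixed",
    )


def _wm_productivity(rules: LocalRules, x: float, growth_A=None, growth_B=None) -> float:
    ga = _mean_growth_given_partner_freq(
        1.0 - x, rules.r_A, rules.mu_hat_A, rules.growth_model, growth_A
    )
    gb = _mean_growth_given_partner_freq(
        x, rules.r_B, rules.mu_hat_B, rules.growth_model, growth_B
    )
    return x * ga + (1.0 - x) * gb


def equilibrium(rules: LocalRules) -> EquilibriumResult:
    """Full steady state for the frequency-linear model (closed forms).

    Combines the equilibrium composition, the local partner frequencies
    via the (r-2)/(r-1) law, and the community productivity — the mean
    birth rate ``P(A) mu_A P(B|A) + P(B) mu_B P(A|B)`` — compared with
    the equivalent well-mixed community at its own equilibrium.  For
    cross-feeders the spatial productivity never exceeds the well-mixed
    one; fixation of either type zeroes it (community collapse).
    """
    x_raw = _unclamped_frequency(rules)
    if rules.r_A < 2:
        raise ValueError("closed-form equilibrium requires r_A >= 2")
    if x_raw <= 0.0 or x_raw >= 1.0:
        return _collapse_state(rules, a_fixed=x_raw >= 1.0)
    p_bga = local_to_global_ratio(rules.r_A) * (1.0 - x_raw)
    p_agb = local_to_global_ratio(rules.r_B) * x_raw
    spatial = x_raw * rules.mu_hat_A * p_bga + (1.0 - x_raw) * rules.mu_hat_B * p_agb
    x_wm = well_mixed_frequency(rules)
    wm = _wm_productivity(rules, x_wm)
    return EquilibriumResult(
        P_A=x_raw,
        P_BgA=p_bga,
        P_AgB=p_agb,
        productivity_spatial=spatial,
        productivity_wm=wm,
        productivity_ratio=spatial / wm if wm > 0 else math.nan,
        collapsed="none",
    )


def productivity(rules: LocalRules) -> EquilibriumResult:
    """Alias for :func:`equilibrium`: steady state incl. productivity."""
    return equilibrium(rules)


def steady_state_general(
    rules: LocalRules,
    growth_A: Callable[[np.ndarray, float], np.ndarray] | None = None,
    growth_B: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> EquilibriumResult:
    """Steady state for any growth model by solving the rate balance.

    At equilibrium the two event rates balance (``T+ = T-``) and the
    local structure obeys the (r-2)/(r-1) law regardless of the growth
    model, so the problem reduces to a single root-find for ``P(A)`` on
    (0, 1).  No sign change on the bracket means one type always
    outgrows the other there: fixation (collapse) is reported.  When
    several roots exist (e.g. mutual inhibition is bistable around its
    interior balance point) the root closest to the frequency reached by
    integration from a 50:50 start is returned.

    For the density-linear model the balance point puts the type with
    the larger ``mu_hat * r`` product in the majority; at exactly equal
    products the equilibrium is 50:50.

    The well-mixed reference replaces local with global composition in
    the growth functions; its equilibrium solves ``G_A(1-x) = G_B(x)``
    for the mean-growth functions ``G``.
    """
    if rules.r_A < 2:
        raise ValueError("steady state requires r_A >= 2")
    g_a_fac = local_to_global_ratio(rules.r_A)
    g_b_fac = local_to_global_ratio(rules.r_B)
    model = rules.growth_model
    if model is GrowthModel.CUSTOM and (growth_A is None or growth_B is None):
        raise ValueError("custom growth model requires growth_A and growth_B")

    def balance(x: float) -> float:
        p = g_a_fac * (1.0 - x)
        s = g_b_fac * x
        probs = CompositionProbabilities(x, p, s)
        t_plus, t_minus = transition_rates(probs, rules, growth_A, growth_B)
        return t_plus - t_minus

    eps = _BRACKET_EPS
    xs = np.linspace(eps, 1.0 - eps, 2001)
    vals = np.array([balance(x) for x in xs])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_changes) == 0:
        return _collapse_state(rules, a_fixed=vals.mean() > 0)
    roots = [
        brentq(balance, xs[i], xs[i + 1], xtol=1e-12) for i in sign_changes
    ]
    if len(roots) > 1:
        # pick the root reachable from a 50:50 start by integration
        start = state_from_probabilities(
            CompositionProbabilities(0.5, g_a_fac * 0.5, g_b_fac * 0.5), rules
        )
        traj = integrate(start, rules, t_end=500.0, growth_A=growth_A,
                         growth_B=growth_B)
        target = traj["P_A"].iloc[-1]
        roots.sort(key=lambda x: abs(x - target))
    x = roots[0]
    p_bga = g_a_fac * (1.0 - x)
    p_agb = g_b_fac * x
    ga = _mean_growth_given_partner_freq(
        p_bga, rules.r_A, rules.mu_hat_A, model, growth_A
    )
    gb = _mean_growth_given_partner_freq(
        p_agb, rules.r_B, rules.mu_hat_B, model, growth_B
    )
    spatial = x * ga + (1.0 - x) * gb

    def wm_balance(x: float) -> float:
        ga = _mean_growth_given_partner_freq(
            1.0 - x, rules.r_A, rules.mu_hat_A, model, growth_A
        )
        gb = _mean_growth_given_partner_freq(
            x, rules.r_B, rules.mu_hat_B, model, growth_B
        )
        return x * ga * (1.0 - x) - (1.0 - x) * gb * x

    try:
        x_wm = brentq(wm_balance, eps, 1.0 - eps, xtol=1e-12)
    except ValueError:
        x_wm = well_mixed_frequency(rules)
    wm = _wm_productivity(rules, x_wm, growth_A, growth_B)
    return EquilibriumResult(
        P_A=x,
        P_BgA=p_bga,
        P_AgB=p_agb,
        productivity_spatial=spatial,
        productivity_wm=wm,
        productivity_ratio=spatial / wm if wm > 0 else math.nan,
        collapsed="none",
    )
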