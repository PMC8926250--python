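"""Local interaction rules from the biophysics of molecular exchange.

Two cell types that cross-feed (each consumes a metabolite the other
leaks) interact over a finite distance set by the competition between
diffusion of the exchanged molecule and its removal by uptake.  This
module turns molecular parameters -- diffusion coefficient, uptake and
leakage rates, cell geometry and packing density -- into the three
quantities that drive community-level behaviour:

* the *interaction range* ``R``: the physical distance over which a
  molecule released by one cell can still be captured by another;
* the *neighborhood size* ``r``: the number of cells found within that
  range, in a 2D monolayer or a 3D aggregate;
* the *maximum growth rate* ``mu_hat``: the growth rate a consumer
  reaches when its entire interaction neighborhood consists of
  producers, bounded by the wild-type (prototrophic) rate.

Two parameterizations are supported.  :class:`MolecularParams` assumes
both cell types share uptake/leakage machinery for a given molecule, so
rates differ between molecules but not between types.
:class:`AsymmetricExchangeParams` lifts that restriction and carries
per-type rates; its formulas reduce exactly to the shared-rate ones when
the producer and non-producer rates coincide.

Units are the caller's choice: declare one time unit and one length unit
and use them consistently; no conversion happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

__all__ = [
    "GrowthModel",
    "MolecularParams",
    "AsymmetricExchangeParams",
    "LocalRules",
    "interaction_range",
    "interaction_range_general",
    "max_growth_rate",
    "max_growth_rate_general",
    "neighborhood_size_2d",
    "neighborhood_size_3d",
    "local_rules_from_biophysics",
    "round_half_up",
]


class InvalidParameterError(ValueError):
    """A biophysical parameter combination gives a non-finite or
    physically meaningless result."""


class GrowthModel(str, Enum):
    """How a cell's growth rate depends on its interaction neighborhood.

    frequency_linear
        Growth increases linearly with the *frequency* of the partner
        type among the ``r`` interaction neighbors (cross-feeding on a
        molecule that is actively taken up; saturates at ``mu_hat``).
    density_linear
        Growth increases linearly with the *number* of partner cells in
        the neighborhood (molecules that are sensed but not depleted,
        e.g. growth factors degraded in the matrix).
    inhibition_linear
        Growth decreases linearly with the frequency of the other type
        (mutual growth inhibition).
    custom
        User-supplied growth functions; equilibria are found
        numerically.
    """

    FREQUENCY_LINEAR = "frequency_linear"
    DENSITY_LINEAR = "density_linear"
    INHIBITION_LINEAR = "inhibition_linear"
    CUSTOM = "custom"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class MolecularParams:
    """Biophysics of one exchanged molecule, shared-rate scenario.

    Parameters
    ----------
    D : float
        Diffusion coefficient of the molecule (length^2 / time).
    r_u, r_l : float
        Uptake and leakage rates (1 / time).
    rho : float
        Volume fraction occupied by cells, ``0 <= rho < 1``.
    beta : float
        Dimensionless calibration constant of the range formula.  No
        default: it must be supplied explicitly.
    gamma : float
        Composite rate constant; ``r_l / gamma`` is the dimensionless
        leakage ratio.  Equivalent to ``2 * mu_wt * K / I_C`` (Monod
        constant ``K``, internal concentration ``I_C``) but stored as a
        single number because that is how the shared-rate formulas are
        parameterized.
    mu_wt : float
        Wild-type (prototrophic) growth rate (1 / time); upper bound on
        any cross-fed growth rate.
    l, w : float
        Mean cell length and width (length), ``l >= w > 0``.
    rho_2D : float
        Areal cell density (cells / length^2), for monolayers.
    rho_3D : float
        Volumetric cell density (cells / length^3), for 3D aggregates.
    """

    D: float
    r_u: float
    r_l: float
    rho: float
    beta: float
    gamma: float
    mu_wt: float
    l: float
    w: float
    rho_2D: float
    rho_3D: float

    def __post_init__(self) -> None:
        for name in ("D", "r_u", "r_l", "beta", "gamma", "mu_wt", "rho_2D", "rho_3D"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0 <= self.rho < 1, "rho must satisfy 0 <= rho < 1")
        _require(self.l >= self.w > 0, "cell geometry requires l >= w > 0")


@dataclass(frozen=True)
class AsymmetricExchangeParams:
    """Biophysics of one exchanged molecule with per-type rates.

    The subscript ``p`` marks the producer of this molecule, ``n`` the
    non-producer (the consumer whose growth the molecule supports).

    Parameters
    ----------
    r_u_p, r_l_p : float
        Uptake and leakage rates of the producer type (1 / time).
    r_u_n, r_l_n : float
        Uptake and leakage rates of the non-producer type (1 / time).
    I_C_p : float
        Internal concentration of the molecule inside producers.
    K_n : float
        Monod constant of the consumer (> 0).
    mu_n : float
        Maximal consumer growth rate with excess substrate (> 0).
    D, rho, beta : float
        As in :class:`MolecularParams`.
    """

    r_u_p: float
    r_l_p: float
    r_u_n: float
    r_l_n: float
    I_C_p: float
    K_n: float
    mu_n: float
    D: float
    rho: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("r_u_p", "r_l_p", "r_u_n", "r_l_n", "I_C_p", "D", "beta"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.K_n > 0, "K_n must be > 0")
        _require(self.mu_n > 0, "mu_n must be > 0")
        _require(0 <= self.rho < 1, "rho must satisfy 0 <= rho < 1")

    @property
    def theta(self) -> float:
        """Dimensionless driver of the maximum growth rate.

        Product of the leakage flux in producers relative to the flux a
        consumer needs to grow well, ``r_l_p * I_C_p / (2 mu_n K_n)``,
        and the effective uptake rate in non-producers relative to
        producers, ``(r_u_n + r_l_n) / (r_u_p + r_l_p)``.
        """
        s_p = self.r_u_p + self.r_l_p
        s_n = self.r_u_n + self.r_l_n
        _require(s_p > 0, "producer rate sum r_u_p + r_l_p must be > 0")
        return (self.r_l_p * self.I_C_p / (2.0 * self.mu_n * self.K_n)) * (s_n / s_p)

    @property
    def delta(self) -> float:
        """Dimensionless driver of the interaction range.

        Three factors: the relative leakage flux (as in :attr:`theta`),
        the diffusion length scale in non-producer regions relative to
        the average length scale (length scale ~ 1/sqrt(r_u + r_l)),
        and the relative effective uptake rate.
        """
        s_p = self.r_u_p + self.r_l_p
        s_n = self.r_u_n + self.r_l_n
        _require(s_p > 0, "producer rate sum r_u_p + r_l_p must be > 0")
        _require(s_n > 0, "non-producer rate sum r_u_n + r_l_n must be > 0")
        leak = self.r_l_p * self.I_C_p / (2.0 * self.mu_n * self.K_n)
        length = 2.0 * math.sqrt(s_p) / (math.sqrt(s_n) + math.sqrt(s_p))
        uptake = s_n / s_p
        return leak * length * uptake


@dataclass(frozen=True)
class LocalRules:
    """The four-number interface between the molecular and community layers.

    ``r_A`` and ``r_B`` are interaction-neighborhood sizes (``r_B >=
    r_A`` by labeling convention), ``mu_hat_A`` / ``mu_hat_B`` the
    maximum growth rates.  Neighborhood sizes are kept continuous here;
    they are rounded to integers only when a lattice simulation is
    constructed.  The closed-form equilibria require ``r_A >= 2``.

    ``swapped`` records whether the A/B labels were exchanged to honor
    the ``r_B >= r_A`` convention (see
    :func:`local_rules_from_biophysics`).
    """

    r_A: float
    r_B: float
    mu_hat_A: float
    mu_hat_B: float
    growth_model: GrowthModel = GrowthModel.FREQUENCY_LINEAR
    swapped: bool = False

    def __post_init__(self) -> None:
        _require(self.r_A >= 1, "r_A must be >= 1")
        _require(self.r_B >= self.r_A, "labeling convention requires r_B >= r_A")
        _require(self.mu_hat_A >= 0 and self.mu_hat_B >= 0, "growth rates must be >= 0")
        if not isinstance(self.growth_model, GrowthModel):
            object.__setattr__(self, "growth_model", GrowthModel(self.growth_model))


def _log_argument(x: float) -> float:
    # x (1 + sqrt(1 + 4/x)) + 4 rewritten as x + sqrt(x^2 + 4 x) + 4,
    # which is finite and equals 4 at x = 0.
    return x + math.sqrt(x * x + 4.0 * x) + 4.0


def _range_prefactor(beta: float, rho: float, D: float, rate_sum: float) -> float:
    _require(rate_sum > 0, "uptake + leakage rate sum must be > 0")
    _require(rho > 0, "interaction range diverges at zero cell density (rho = 0)")
    pref = beta / (2.0 * (1.0 - rho)) * math.sqrt(
        2.0 * D / (rho * (2.0 + rho) * rate_sum)
    )
    if not math.isfinite(pref):
        raise InvalidParameterError("non-finite interaction range (check rho, D, rates)")
    return pref


def interaction_range(params: MolecularParams) -> float:
    """Distance over which the exchanged molecule couples two cells.

    ``R = beta / (2 (1 - rho)) * sqrt(2 D / (rho (2 + rho) (r_u + r_l)))
    * ln[ x (1 + sqrt(1 + 4/x)) + 4 ]`` with ``x = r_l / gamma``.

    The square-root factor is the diffusion length scale of the molecule
    (distance travelled before uptake removes it), so ``R`` shrinks as
    the uptake rate grows and grows with the diffusion coefficient.  In
    the limit of vanishing leakage the logarithm tends to ``ln 4``.
    """
    x = params.r_l / params.gamma if params.gamma > 0 else 0.0
    if params.gamma == 0 and params.r_l > 0:
        raise InvalidParameterError("gamma must be > 0 when r_l > 0")
    pref = _range_prefactor(params.beta, params.rho, params.D, params.r_u + params.r_l)
    return pref * math.log(_log_argument(x))


def interaction_range_general(params: AsymmetricExchangeParams) -> float:
    """Interaction range with per-type uptake/leakage rates.

    Same structure as :func:`interaction_range` with the consumer's rate
    sum in the diffusion length scale and the composite constant
    ``delta`` in the logarithm.  When producer and non-producer rates
    are identical, ``delta`` reduces to ``r_l / gamma`` and the result
    equals the shared-rate formula.
    """
    d = params.delta
    pref = _range_prefactor(
        params.beta, params.rho, params.D, params.r_u_n + params.r_l_n
    )
    return pref * math.log(_log_argument(d))


def max_growth_rate(params: MolecularParams) -> float:
    """Growth rate of a consumer completely surrounded by producers.

    ``mu_hat = mu_wt * x (sqrt(1 + 2/x) - 1)`` with ``x = r_l / gamma``,
    evaluated as ``mu_wt * (sqrt(x^2 + 2x) - x)``.  Increases
    monotonically with the leakage rate and saturates at the wild-type
    rate ``mu_wt``: cross-fed growth can never beat growth on an
    external saturating supply.
    """
    _require(params.gamma > 0, "gamma must be > 0")
    x = params.r_l / params.gamma
    return params.mu_wt * (math.sqrt(x * x + 2.0 * x) - x)


def max_growth_rate_general(params: AsymmetricExchangeParams) -> float:
    """Maximum growth rate with per-type rates, via the constant theta.

    ``mu_max = mu_n * (sqrt(theta^2 + 2 theta) - theta)``; reduces to
    :func:`max_growth_rate` when the two types share rates, and
    saturates at ``mu_n`` for large theta.
    """
    t = params.theta
    return params.mu_n * (math.sqrt(t * t + 2.0 * t) - t)


def neighborhood_size_2d(R: float, l: float, w: float, rho_2D: float) -> float:
    """Number of cells a rod-shaped cell interacts with in a monolayer.

    Area of the shell of width ``R`` around a stadium-shaped cell
    (rectangle ``(l - w) x w`` with semicircular caps of radius
    ``w/2``), times the areal density:

    ``r = [2 R (l - w) + pi (R + w/2)^2 - pi (w/2)^2] * rho_2D``

    The returned value is continuous; round only at the lattice
    boundary (see :func:`round_half_up`).
    """
    _require(R >= 0, "R must be >= 0")
    _require(l >= w > 0, "cell geometry requires l >= w > 0")
    _require(rho_2D >= 0, "rho_2D must be >= 0")
    shell = 2.0 * R * (l - w) + math.pi * (R + w / 2.0) ** 2 - math.pi * (w / 2.0) ** 2
    return shell * rho_2D


def neighborhood_size_3d(R: float, l: float, w: float, rho_3D: float) -> float:
    """Number of cells within range ``R`` of a spherocylindrical cell.

    Volume of the shell of width ``R`` around a spherocylinder of
    length ``l`` and diameter ``w`` (cylinder of length ``l - w`` with
    hemispherical caps), times the volumetric density.  Scales as
    ``R^3`` for ``R >> l``, which is why 3D aggregates put far more
    cells within reach than 2D monolayers at the same range.
    """
    _require(R >= 0, "R must be >= 0")
    _require(l >= w > 0, "cell geometry requires l >= w > 0")
    _require(rho_3D >= 0, "rho_3D must be >= 0")

    def spherocyl_volume(radius: float) -> float:
        return math.pi * radius**2 * (l - w) + 4.0 / 3.0 * math.pi * radius**3

    shell = spherocyl_volume(w / 2.0 + R) - spherocyl_volume(w / 2.0)
    return shell * rho_3D


def round_half_up(r: float) -> int:
    """Round a continuous neighborhood size to an integer, halves up.

    Used only at the boundary to the lattice simulator; the analytical
    layer works with the continuous value.
    """
    return int(math.floor(r + 0.5))


Params = Union[MolecularParams, AsymmetricExchangeParams]


def local_rules_from_biophysics(
    params_A: Params,
    params_B: Params,
    dimension: int = 2,
    geometry: MolecularParams | None = None,
) -> LocalRules:
    """Compose range, neighborhood size and growth rate into local rules.

    ``params_A`` describes the molecule *consumed by* type A (its
    availability sets A's interaction range and maximum growth rate),
    and symmetrically for ``params_B``.  ``dimension`` selects the 2D
    stadium-shell or 3D spherocylinder-shell neighbor count.

    Cell geometry (``l``, ``w``, densities) is read from the parameter
    objects when they are :class:`MolecularParams`;
    :class:`AsymmetricExchangeParams` carries no geometry, so a
    ``geometry`` template must then be supplied.

    The output honors the ``r_B >= r_A`` labeling convention: if the
    computed sizes violate it the two types are relabeled and
    ``swapped=True`` is recorded, so "A" in the returned rules is always
    the smaller-neighborhood type.
    """
    if dimension not in (2, 3):
        raise InvalidParameterError("dimension must be 2 or 3")

    def rules_for(p: Params) -> tuple[float, float]:
        if isinstance(p, AsymmetricExchangeParams):
            R = interaction_range_general(p)
            mu = max_growth_rate_general(p)
            geo = geometry
            if geo is None:
                raise InvalidParameterError(
                    "per-type rate parameters carry no cell geometry; "
                    "pass geometry=MolecularParams(...)"
                )
        else:
            R = interaction_range(p)
            mu = max_growth_rate(p)
            geo = p
        if dimension == 2:
            r = neighborhood_size_2d(R, geo.l, geo.w, geo.rho_2D)
        else:
            r = neighborhood_size_3d(R, geo.l, geo.w, geo.rho_3D)
        return r, mu

    r_A, mu_A = rules_for(params_A)
    r_B, mu_B = rules_for(params_B)
    swapped = r_B < r_A
    if swapped:
        r_A, r_B = r_B, r_A
        mu_A, mu_B = mu_B, mu_A
    return LocalRules(
        r_A=max(r_A, 1.0),
        r_B=max(r_B, 1.0),
        mu_hat_A=mu_A,
        mu_hat_B=mu_B,
        growth_model=GrowthModel.FREQUENCY_LINEAR,
        swapped=swapped,
    )
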