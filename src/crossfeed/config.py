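"""Configuration loading and validation.

A run is described by a small YAML file with these sections (all
optional except ``units``, unknown keys anywhere are rejected):

``units``
    ``time`` and ``length``: the names of the units every rate and
    length in the file is expressed in.  Purely declarative — nothing is
    converted — but required so that files are self-describing.
``molecule_A`` / ``molecule_B``
    Biophysics of the molecule consumed by type A / B: either
    shared-rate parameters (``D, r_u, r_l, gamma``) or per-type rate
    parameters (``r_u_p, r_l_p, r_u_n, r_l_n, I_C_p, K_n, mu_n, D``).
``geometry``
    ``beta, rho, mu_wt, l, w, rho_2D, rho_3D`` and ``dimension`` (2 or
    3), shared by both molecules.
``local_rules``
    Direct specification of ``r_A, r_B, mu_hat_A, mu_hat_B`` and
    ``growth_model`` — used as-is when no molecular sections are given.
``ca``
    Lattice simulation settings (``height, width, d_A, d_B, d_R,
    init_freq_A, n_events, seed, replicates``); ``d_A``/``d_B`` default
    to the Moore ranges matching the local rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .biophysics import (
    AsymmetricExchangeParams,
    GrowthModel,
    LocalRules,
    MolecularParams,
    local_rules_from_biophysics,
)
from .cellular_automaton import CAConfig, moore_range_for_size

__all__ = ["ConfigError", "RunConfig", "load_config", "dump_config"]


class ConfigError(ValueError):
    """A configuration file is malformed; the message names the key."""


_UNIT_KEYS = {"time", "length"}
_SHARED_MOL_KEYS = {"D", "r_u", "r_l", "gamma"}
_ASYM_MOL_KEYS = {"r_u_p", "r_l_p", "r_u_n", "r_l_n", "I_C_p", "K_n", "mu_n", "D"}
_GEOM_KEYS = {"beta", "rho", "mu_wt", "l", "w", "rho_2D", "rho_3D", "dimension"}
_RULE_KEYS = {"r_A", "r_B", "mu_hat_A", "mu_hat_B", "growth_model"}
_CA_KEYS = {
    "height", "width", "d_A", "d_B", "d_R", "init_freq_A",
    "n_events", "seed", "replicates", "growth_model",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameter bundle for one analysis run.

    ``params_A`` / ``params_B`` hold the parsed molecular parameters
    when the config is biophysical (else None).
    """

    units: dict
    rules: LocalRules
    ca: CAConfig
    replicates: int
    raw: dict
    from_biophysics: bool
    params_A: object | None = None
    params_B: object | None = None


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")


def _molecule(section: dict, geom: dict, name: str):
    keys = set(section)
    if keys <= _SHARED_MOL_KEYS:
        missing = _SHARED_MOL_KEYS - keys
        if missing:
            raise ConfigError(f"[{name}] missing key(s): {sorted(missing)}")
        return MolecularParams(
            D=section["D"], r_u=section["r_u"], r_l=section["r_l"],
            gamma=section["gamma"], beta=geom["beta"], rho=geom["rho"],
            mu_wt=geom["mu_wt"], l=geom["l"], w=geom["w"],
            rho_2D=geom["rho_2D"], rho_3D=geom["rho_3D"],
        )
    if keys <= _ASYM_MOL_KEYS:
        missing = _ASYM_MOL_KEYS - keys
        if missing:
            raise ConfigError(f"[{name}] missing key(s): {sorted(missing)}")
        return AsymmetricExchangeParams(
            r_u_p=section["r_u_p"], r_l_p=section["r_l_p"],
            r_u_n=section["r_u_n"], r_l_n=section["r_l_n"],
            I_C_p=section["I_C_p"], K_n=section["K_n"], mu_n=section["mu_n"],
            D=section["D"], rho=geom["rho"], beta=geom["beta"],
        )
    raise ConfigError(
        f"[{name}] keys {sorted(keys)} match neither the shared-rate "
        f"({sorted(_SHARED_MOL_KEYS)}) nor the per-type "
        f"({sorted(_ASYM_MOL_KEYS)}) parameter set"
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    All type invariants are checked at load time; violations raise
    :class:`ConfigError` naming the offending key or invariant.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at top level")
    allowed_sections = {
        "units", "molecule_A", "molecule_B", "geometry", "local_rules", "ca",
    }
    _check_keys(raw, allowed_sections, "top level")

    units = raw.get("units")
    if not units:
        raise ConfigError("a [units] section with 'time' and 'length' is required")
    _check_keys(units, _UNIT_KEYS, "units")
    if _UNIT_KEYS - set(units):
        raise ConfigError("[units] must declare both 'time' and 'length'")

    has_mol = "molecule_A" in raw or "molecule_B" in raw
    from_biophysics = False
    par_a = par_b = None
    if has_mol:
        if not ("molecule_A" in raw and "molecule_B" in raw and "geometry" in raw):
            raise ConfigError(
                "molecular parameterization needs [molecule_A], [molecule_B] "
                "and [geometry]"
            )
        geom = raw["geometry"]
        _check_keys(geom, _GEOM_KEYS, "geometry")
        missing = (_GEOM_KEYS - {"dimension"}) - set(geom)
        if missing:
            raise ConfigError(f"[geometry] missing key(s): {sorted(missing)}")
        dimension = geom.get("dimension", 2)
        geometry_template = MolecularParams(
            D=1.0, r_u=1.0, r_l=0.0, gamma=1.0, beta=geom["beta"],
            rho=geom["rho"], mu_wt=geom["mu_wt"], l=geom["l"], w=geom["w"],
            rho_2D=geom["rho_2D"], rho_3D=geom["rho_3D"],
        )
        _check_keys(raw["molecule_A"], _SHARED_MOL_KEYS | _ASYM_MOL_KEYS, "molecule_A")
        _check_keys(raw["molecule_B"], _SHARED_MOL_KEYS | _ASYM_MOL_KEYS, "molecule_B")
        par_a = _molecule(raw["molecule_A"], geom, "molecule_A")
        par_b = _molecule(raw["molecule_B"], geom, "molecule_B")
        try:
            rules = local_rules_from_biophysics(
                par_a, par_b, dimension=dimension, geometry=geometry_template
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if "local_rules" in raw:
            raise ConfigError(
                "give either molecular sections or [local_rules], not both"
            )
        from_biophysics = True
    elif "local_rules" in raw:
        sec = raw["local_rules"]
        _check_keys(sec, _RULE_KEYS, "local_rules")
        missing = (_RULE_KEYS - {"growth_model"}) - set(sec)
        if missing:
            raise ConfigError(f"[local_rules] missing key(s): {sorted(missing)}")
        try:
            rules = LocalRules(
                r_A=float(sec["r_A"]), r_B=float(sec["r_B"]),
                mu_hat_A=float(sec["mu_hat_A"]), mu_hat_B=float(sec["mu_hat_B"]),
                growth_model=GrowthModel(sec.get("growth_model", "frequency_linear")),
            )
        except ValueError as exc:
            raise ConfigError(f"[local_rules] invalid: {exc}") from exc
    else:
        raise ConfigError(
            "config needs either molecular sections or a [local_rules] section"
        )

    ca_sec = dict(raw.get("ca", {}))
    _check_keys(ca_sec, _CA_KEYS, "ca")
    replicates = int(ca_sec.pop("replicates", 5))
    ca_sec.setdefault("d_A", moore_range_for_size(rules.r_A))
    ca_sec.setdefault("d_B", moore_range_for_size(rules.r_B))
    ca_sec.setdefault("growth_model", rules.growth_model)
    try:
        ca = CAConfig(
            mu_hat_A=rules.mu_hat_A, mu_hat_B=rules.mu_hat_B, **ca_sec
        )
    except ValueError as exc:
        raise ConfigError(f"[ca] invalid: {exc}") from exc
    return RunConfig(
        units=dict(units), rules=rules, ca=ca, replicates=replicates,
        raw=raw, from_biophysics=from_biophysics,
        params_A=par_a, params_B=par_b,
    )


def dump_config(config: RunConfig) -> str:
    """Serialize the raw configuration back to YAML (load/dump idempotent)."""
    return yaml.safe_dump(config.raw, sort_keys=True)
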