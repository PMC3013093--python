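"""Run configuration: YAML/JSON loading, validation, and the one-shot runner.

A config file carries either a physical ``scenario`` block (or a preset
name), or a ``dimensionless`` block, plus a method selector and numerical
controls.  If both blocks are present the dimensionless one wins (with a
warning) — the dimensionless triple is the model's native state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .params import (
    DimensionlessParams,
    PhysicalScenario,
    regime_product,
    snap_epsilon,
)
from .fixtures import get_preset
from .microscale import build_profile, solve_exact, solve_fd
from .homogenized import solve_homogenized, semianalytic_solution, volumetric_mean
from .caseb import build_caseb

__all__ = ["RunConfig", "ConfigError", "NumericalError", "load_config",
           "dump_config", "run"]

logger = logging.getLogger(__name__)

METHODS = ("exact", "fd", "homog", "semianalytic", "caseb")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class NumericalError(RuntimeError):
    """Solver failure during a run (CLI exit code 3)."""


@dataclass(frozen=True)
class RunConfig:
    dimensionless: DimensionlessParams | None = None
    scenario: PhysicalScenario | None = None
    method: str = "exact"
    out: str | None = None
    n_out: int = 1001
    fd_nodes: int = 20_000
    points_per_period: int = 200
    cutoff_transition_width: float = 0.5
    layer_cut_length: float | None = None
    placement: str = "centered"
    seed: int = 0  # reserved; every method is deterministic

    def __post_init__(self) -> None:
        if (self.dimensionless is None) == (self.scenario is None):
            raise ConfigError(
                "exactly one of the 'dimensionless' and 'scenario' blocks must "
                "be present after normalization"
            )
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        if not (2 <= self.n_out <= 10_000_000):
            raise ConfigError(f"n_out out of range: {self.n_out}")
        if not (100 <= self.fd_nodes <= 10_000_000):
            raise ConfigError(f"fd_nodes out of range: {self.fd_nodes}")
        if not (10 <= self.points_per_period <= 100_000):
            raise ConfigError(f"points_per_period out of range: {self.points_per_period}")
        if not (0 < self.cutoff_transition_width <= 1):
            raise ConfigError(
                f"cutoff_transition_width out of range: {self.cutoff_transition_width}")
        if self.layer_cut_length is not None and self.layer_cut_length <= 0:
            raise ConfigError(f"layer_cut_length out of range: {self.layer_cut_length}")
        if self.placement not in ("centered", "start"):
            raise ConfigError(f"placement must be 'centered' or 'start'")

    @property
    def params(self) -> DimensionlessParams:
        if self.dimensionless is not None:
            return self.dimensionless
        return DimensionlessParams.from_scenario(self.scenario)


_SCENARIO_KEYS = {f.name for f in dataclasses.fields(PhysicalScenario)}
_DIMENSIONLESS_KEYS = {f.name for f in dataclasses.fields(DimensionlessParams)}
_TOP_KEYS = {
    "scenario", "dimensionless", "method", "out", "n_out", "fd_nodes",
    "points_per_period", "cutoff_transition_width", "layer_cut_length",
    "placement", "seed",
}


def _check_keys(block: dict, allowed: set, where: str, errors: list) -> None:
    for key in block:
        if key not in allowed:
            errors.append(f"unknown key {key!r} in {where}")


def parse_config(data: dict) -> RunConfig:
    """Validate a raw mapping into a :class:`RunConfig`, collecting every
    violation before raising."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []
    _check_keys(data, _TOP_KEYS, "config", errors)

    scenario = None
    raw_scenario = data.get("scenario")
    if isinstance(raw_scenario, str):
        try:
            scenario = get_preset(raw_scenario)
        except KeyError as exc:
            errors.append(str(exc))
    elif isinstance(raw_scenario, dict):
        _check_keys(raw_scenario, _SCENARIO_KEYS, "scenario", errors)
        if not errors:
            try:
                scenario = PhysicalScenario(**raw_scenario)
            except (TypeError, ValueError) as exc:
                errors.append(f"scenario: {exc}")
    elif raw_scenario is not None:
        errors.append("scenario must be a mapping or a preset name")

    dimensionless = None
    raw_dim = data.get("dimensionless")
    if isinstance(raw_dim, dict):
        _check_keys(raw_dim, _DIMENSIONLESS_KEYS, "dimensionless", errors)
        if not errors:
            try:
                if "eps" in raw_dim:
                    raw_dim = dict(raw_dim, eps=snap_epsilon(raw_dim["eps"]))
                dimensionless = DimensionlessParams(**raw_dim)
            except (TypeError, ValueError) as exc:
                errors.append(f"dimensionless: {exc}")
    elif raw_dim is not None:
        errors.append("dimensionless must be a mapping")

    if scenario is not None and dimensionless is not None:
        logger.warning("both 'scenario' and 'dimensionless' given; "
                       "dimensionless wins")
        scenario = None

    if errors:
        raise ConfigError("invalid config: " + "; ".join(errors))
    kwargs = {k: v for k, v in data.items() if k not in ("scenario", "dimensionless")}
    return RunConfig(dimensionless=dimensionless, scenario=scenario, **kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON config file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return parse_config(data if data is not None else {})


def dump_config(config: RunConfig) -> dict:
    """Plain-dict form of a config; round-trips through parse_config."""
    out: dict = {}
    if config.dimensionless is not None:
        out["dimensionless"] = dataclasses.asdict(config.dimensionless)
    if config.scenario is not None:
        out["scenario"] = dataclasses.asdict(config.scenario)
    for f in dataclasses.fields(RunConfig):
        if f.name in ("dimensionless", "scenario"):
            continue
        value = getattr(config, f.name)
        if value != f.default:
            out[f.name] = value
    return out


def _solve_with_method(config: RunConfig):
    params = config.params
    profile = build_profile(params, placement=config.placement)
    f, g0, g1 = params.f, params.g0, params.g1
    if config.method == "exact":
        return params, profile, solve_exact(profile, f, g0, g1)
    if config.method == "fd":
        return params, profile, solve_fd(profile, f, g0, g1, config.fd_nodes)
    if config.method == "homog":
        return params, profile, solve_homogenized(volumetric_mean(profile), f, g0, g1)
    if config.method == "semianalytic":
        return params, profile, semianalytic_solution(
            profile, f, g0, g1, config.layer_cut_length)
    if config.method == "caseb":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return params, profile, build_caseb(
                params, config.cutoff_transition_width)
    raise ConfigError(f"unknown method {config.method!r}")  # pragma: no cover


def solution_table(config: RunConfig):
    """Sampled (x, u, uprime, K) table for the configured method."""
    import pandas as pd

    params, profile, sol = _solve_with_method(config)
    xs = np.linspace(0.0, 1.0, config.n_out)
    u = np.asarray(sol.evaluate(xs), dtype=float)
    if hasattr(sol, "derivative_at"):
        up = np.asarray(sol.derivative_at(xs), dtype=float)
    else:
        up = np.gradient(u, xs)
    return params, profile, pd.DataFrame(
        {"x": xs, "u": u, "uprime": up, "K": profile.kappa_at(xs)})


def run(config: RunConfig, out_dir) -> dict:
    """Execute a config: write ``solution.csv`` and ``manifest.json``.

    The manifest records the package version, a hash of the canonical config,
    and every derived parameter, making runs reproducible byte for byte.
    Partial outputs are removed on failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "solution.csv"
    manifest_path = out_dir / "manifest.json"
    try:
        params, profile, table = solution_table(config)
        indicator = regime_product(params)
        table.to_csv(csv_path, index=False, float_format="%.17g")
        canonical = json.dumps(dump_config(config), sort_keys=True)
        manifest = {
            "package": "vesselhomog",
            "version": __version__,
            "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
            "method": config.method,
            "eps": params.eps,
            "delta": params.delta,
            "kappa": params.kappa,
            "f": params.f,
            "g0": params.g0,
            "g1": params.g1,
            "product_p": indicator.product_p,
            "classification": indicator.regime_label,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        logger.info("run complete: %s (%s)", csv_path, indicator.regime_label)
        return manifest
    except ConfigError:
        raise
    except Exception as exc:
        for p in (csv_path, manifest_path):
            p.unlink(missing_ok=True)
        raise NumericalError(f"run failed: {exc}") from exc
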