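"""Run configuration: file parsing and override resolution.

Config files mirror the published parameter names exactly (``f_max``,
``k_L``, ``m``, ``alpha``, ``m_L``, ``T_max``, ``E0``, ``L0``, ``E_min``,
``L_min``, ``u_min``, ``u_max``) at the top level, in any of three
dialects, auto-detected: JSON, TOML, or flat ``key = value`` lines
(``#`` comments allowed).  Optional ``solver`` and ``classifier`` tables
hold :class:`~lifephases.collocation.SolverOptions` and
:class:`~lifephases.phases.PhaseTolerances` fields.  Unknown keys are
rejected with an explicit message.  An empty config reproduces the
baseline problem.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .collocation import SolverOptions
from .params import BoundaryConstraints, ModelParams
from .phases import PhaseTolerances

__all__ = ["RunConfig", "load_config", "parse_mapping"]

_PARAM_KEYS = tuple(f.name for f in fields(ModelParams))
_BOUND_KEYS = tuple(f.name for f in fields(BoundaryConstraints))
_SOLVER_KEYS = tuple(f.name for f in fields(SolverOptions))
_CLASSIFIER_KEYS = tuple(f.name for f in fields(PhaseTolerances))


@dataclass
class RunConfig:
    """Fully-resolved configuration for one command."""

    params: ModelParams = field(default_factory=ModelParams)
    constraints: BoundaryConstraints = field(default_factory=BoundaryConstraints)
    solver: SolverOptions = field(default_factory=SolverOptions)
    classifier: PhaseTolerances = field(default_factory=PhaseTolerances)
    seed: int = 0

    def echo(self) -> dict:
        """JSON-serialisable dump of the resolved configuration."""
        return {
            "params": self.params.to_dict(),
            "constraints": self.constraints.to_dict(),
            "solver": dataclasses.asdict(self.solver),
            "classifier": dataclasses.asdict(self.classifier),
            "seed": self.seed,
        }


def _parse_keyvalue(text: str) -> dict:
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            out[key] = json.loads(val)
        except json.JSONDecodeError:
            out[key] = val
    return out


def read_config_text(text: str) -> dict:
    """Parse config text in JSON, TOML or key=value form (auto-detected)."""
    stripped = text.strip()
    if not stripped:
        return {}
    if stripped.startswith("{"):
        return json.loads(stripped)
    try:
        return tomllib.loads(text)
    except tomllib.TOMLDecodeError:
        return _parse_keyvalue(text)


def parse_mapping(mapping: dict) -> RunConfig:
    """Validate a raw mapping and build a RunConfig; unknown keys raise."""
    mapping = dict(mapping)
    solver_map = mapping.pop("solver", {}) or {}
    classifier_map = mapping.pop("classifier", {}) or {}
    seed = mapping.pop("seed", 0)

    known = set(_PARAM_KEYS) | set(_BOUND_KEYS)
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; accepted top-level keys: "
            f"{sorted(known) + ['solver', 'classifier', 'seed']}"
        )
    bad = set(solver_map) - set(_SOLVER_KEYS)
    if bad:
        raise ValueError(f"unknown solver option(s) {sorted(bad)}")
    bad = set(classifier_map) - set(_CLASSIFIER_KEYS)
    if bad:
        raise ValueError(f"unknown classifier tolerance(s) {sorted(bad)}")

    params = ModelParams(**{k: v for k, v in mapping.items() if k in _PARAM_KEYS})
    bounds = BoundaryConstraints(**{k: v for k, v in mapping.items() if k in _BOUND_KEYS})
    solver = SolverOptions(**solver_map)
    classifier = PhaseTolerances(**classifier_map)
    return RunConfig(params, bounds, solver, classifier, seed=int(seed))


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Read a config file (optional) and apply flat key=value overrides.

    Overrides use the same names as the file; ``solver.mesh``-style dotted
    keys reach into the sections.
    """
    mapping: dict = {}
    if path is not None:
        mapping = read_config_text(Path(path).read_text())
    # the flat key=value dialect spells sections as dotted keys
    for key in [k for k in mapping if "." in k]:
        section, sub = key.split(".", 1)
        value = mapping.pop(key)
        mapping.setdefault(section, {})
        mapping[section][sub] = value
    for key, value in (overrides or {}).items():
        if "." in key:
            section, sub = key.split(".", 1)
            mapping.setdefault(section, {})
            if not isinstance(mapping[section], dict):
                raise ValueError(f"cannot apply dotted override to scalar {section!r}")
            mapping[section][sub] = value
        else:
            mapping[key] = value
    return parse_mapping(mapping)
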