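"""YAML configuration: loading, validation, defaults, provenance echo.

A config document has four optional blocks — ``composition``,
``physiology``, ``allometry`` and ``run`` — each a flat mapping.  Missing
keys fall back to the documented defaults; unknown blocks or keys are
rejected with the offending name; constraint violations name the key and
the constraint.  The fully resolved config can be echoed back to YAML, and
``load(echo(load(x)))`` equals ``load(x)``.

Keys and defaults
-----------------
composition (counts are positive integers, volumes µm³ > 0):
  n_trichomes 2, vegetative_per_trichome 4, heterocysts_per_trichome 1,
  volume_diatom 3493.5, volume_vegetative 18.8, volume_heterocyst 61.0
physiology:
  e_diatom/e_vegetative/e_heterocyst 0.38 (≥ 0), fcn_fix 2.07 (> 0),
  vmax_nh4 1.16 (> 0), km_nh4 0.483 (> 0), rcn 6.6 (> 0),
  pmax_per_n 15.0 (> 0), alpha 0.3 (> 0)
allometry (log10-intercept / exponent per cell class, exponent > 0):
  intercept_diatom −0.933, exponent_diatom 0.881,
  intercept_vegetative −0.665, exponent_vegetative 0.939,
  intercept_heterocyst −0.665, exponent_heterocyst 0.939
run:
  mu 0.51 (> 0), nh4 0.0 (≥ 0), irradiance null (light-replete) or ≥ 0,
  variant "none" | "double_vegetative_E" | "half_vegetative_pmax"
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .composition import AllometricCoefficients, DDAComposition
from .core import VARIANTS, LightResponse, PhysiologyParams, Scenario

__all__ = ["ConfigError", "RunSettings", "ModelConfig", "load_config", "echo_config"]


class ConfigError(ValueError):
    """Invalid configuration: names the offending key and constraint."""


@dataclass(frozen=True)
class RunSettings:
    """Default scenario selected by the config's ``run`` block."""

    mu: float = 0.51
    nh4: float = 0.0
    irradiance: float | None = None
    variant: str = "none"


@dataclass(frozen=True)
class ModelConfig:
    composition: DDAComposition = field(default_factory=DDAComposition)
    physiology: PhysiologyParams = field(default_factory=PhysiologyParams)
    allometry: AllometricCoefficients = field(default_factory=AllometricCoefficients)
    run: RunSettings = field(default_factory=RunSettings)

    def scenario(self, **overrides) -> Scenario:
        """The scenario this config describes, with optional overrides."""
        values = {
            "mu": self.run.mu,
            "nh4": self.run.nh4,
            "irradiance": self.run.irradiance,
            "variant": self.run.variant,
            "composition": self.composition,
            "params": self.physiology,
            "allometry": self.allometry,
        }
        values.update({k: v for k, v in overrides.items() if v is not None})
        return Scenario(**values)


_COMPOSITION_KEYS = {
    "n_trichomes": ("posint", 2),
    "vegetative_per_trichome": ("posint", 4),
    "heterocysts_per_trichome": ("posint", 1),
    "volume_diatom": ("positive", 3493.5),
    "volume_vegetative": ("positive", 18.8),
    "volume_heterocyst": ("positive", 61.0),
}
_PHYSIOLOGY_KEYS = {
    "e_diatom": ("nonneg", 0.38),
    "e_vegetative": ("nonneg", 0.38),
    "e_heterocyst": ("nonneg", 0.38),
    "fcn_fix": ("positive", PhysiologyParams().fcn_fix),
    "vmax_nh4": ("positive", 1.16),
    "km_nh4": ("positive", 0.483),
    "rcn": ("positive", 6.6),
    "pmax_per_n": ("positive", 15.0),
    "alpha": ("positive", 0.3),
}
_ALLOMETRY_KEYS = {
    "intercept_diatom": ("number", -0.933),
    "exponent_diatom": ("positive", 0.881),
    "intercept_vegetative": ("number", -0.665),
    "exponent_vegetative": ("positive", 0.939),
    "intercept_heterocyst": ("number", -0.665),
    "exponent_heterocyst": ("positive", 0.939),
}
_RUN_KEYS = {
    "mu": ("positive", 0.51),
    "nh4": ("nonneg", 0.0),
    "irradiance": ("optional_nonneg", None),
    "variant": ("variant", "none"),
}
_SCHEMA = {
    "composition": _COMPOSITION_KEYS,
    "physiology": _PHYSIOLOGY_KEYS,
    "allometry": _ALLOMETRY_KEYS,
    "run": _RUN_KEYS,
}


def _check(block: str, key: str, kind: str, value):
    where = f"{block}.{key}"
    if kind == "posint":
        if not isinstance(value, int) or isinstance(value, bool) or value < 1:
            raise ConfigError(f"{where} must be a positive integer, got {value!r}")
        return value
    if kind == "variant":
        if value not in VARIANTS:
            raise ConfigError(f"{where} must be one of {VARIANTS}, got {value!r}")
        return value
    if kind == "optional_nonneg":
        if value is None:
            return None
        kind = "nonneg"
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{where} must be a number, got {value!r}")
    value = float(value)
    if kind == "positive" and not value > 0:
        raise ConfigError(f"{where} must be > 0, got {value!r}")
    if kind == "nonneg" and value < 0:
        raise ConfigError(f"{where} must be >= 0, got {value!r}")
    return value


def _resolve_block(block: str, supplied: dict | None) -> dict:
    schema = _SCHEMA[block]
    supplied = supplied or {}
    if not isinstance(supplied, dict):
        raise ConfigError(f"block {block!r} must be a mapping")
    unknown = set(supplied) - set(schema)
    if unknown:
        raise ConfigError(f"unknown key(s) in {block!r}: {sorted(unknown)}")
    return {
        key: _check(block, key, kind, supplied.get(key, default))
        for key, (kind, default) in schema.items()
    }


def load_config(source: str | Path | dict | None = None) -> ModelConfig:
    """Load and validate a config from a YAML file, YAML text, or mapping.

    ``None`` or an empty document yields the full default config.  A short
    string naming an existing file is read as a path; any other string is
    parsed as inline YAML.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = source
    else:
        text = None
        if isinstance(source, Path):
            text = source.read_text()
        elif (source.strip() and len(source) < 4096 and "\n" not in source
              and Path(source).is_file()):
            text = Path(source).read_text()
        else:
            text = source
        try:
            parsed = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML: {exc}") from exc
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ConfigError("config document must be a mapping of blocks")
        raw = parsed

    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config block(s): {sorted(unknown)}")

    comp = _resolve_block("composition", raw.get("composition"))
    phys = _resolve_block("physiology", raw.get("physiology"))
    allo = _resolve_block("allometry", raw.get("allometry"))
    run = _resolve_block("run", raw.get("run"))

    try:
        composition = DDAComposition(**comp)
        physiology = PhysiologyParams(
            e_diatom=phys["e_diatom"],
            e_vegetative=phys["e_vegetative"],
            e_heterocyst=phys["e_heterocyst"],
            fcn_fix=phys["fcn_fix"],
            vmax_nh4=phys["vmax_nh4"],
            km_nh4=phys["km_nh4"],
            rcn=phys["rcn"],
            light=LightResponse(pmax_per_n=phys["pmax_per_n"], alpha=phys["alpha"]),
        )
        allometry = AllometricCoefficients(
            diatom=(allo["intercept_diatom"], allo["exponent_diatom"]),
            vegetative=(allo["intercept_vegetative"], allo["exponent_vegetative"]),
            heterocyst=(allo["intercept_heterocyst"], allo["exponent_heterocyst"]),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return ModelConfig(
        composition=composition,
        physiology=physiology,
        allometry=allometry,
        run=RunSettings(**run),
    )


def echo_config(config: ModelConfig) -> str:
    """Fully resolved config as YAML text (for provenance)."""
    doc = {
        "composition": {
            "n_trichomes": config.composition.n_trichomes,
            "vegetative_per_trichome": config.composition.vegetative_per_trichome,
            "heterocysts_per_trichome": config.composition.heterocysts_per_trichome,
            "volume_diatom": config.composition.volume_diatom,
            "volume_vegetative": config.composition.volume_vegetative,
            "volume_heterocyst": config.composition.volume_heterocyst,
        },
        "physiology": {
            "e_diatom": config.physiology.e_diatom,
            "e_vegetative": config.physiology.e_vegetative,
            "e_heterocyst": config.physiology.e_heterocyst,
            "fcn_fix": config.physiology.fcn_fix,
            "vmax_nh4": config.physiology.vmax_nh4,
            "km_nh4": config.physiology.km_nh4,
            "rcn": config.physiology.rcn,
            "pmax_per_n": config.physiology.light.pmax_per_n,
            "alpha": config.physiology.light.alpha,
        },
        "allometry": {
            "intercept_diatom": config.allometry.diatom[0],
            "exponent_diatom": config.allometry.diatom[1],
            "intercept_vegetative": config.allometry.vegetative[0],
            "exponent_vegetative": config.allometry.vegetative[1],
            "intercept_heterocyst": config.allometry.heterocyst[0],
            "exponent_heterocyst": config.allometry.heterocyst[1],
        },
        "run": {
            "mu": config.run.mu,
            "nh4": config.run.nh4,
            "irradiance": config.run.irradiance,
            "variant": config.run.variant,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
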