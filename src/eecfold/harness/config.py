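"""Flat key-value configuration files.

Syntax: one ``key = value`` per line, ``#`` comments, blank lines ignored.
Keys are namespaced with a dot, e.g. ``thermo.temperature`` or
``predictor.min_strand_len``; matching dataclass fields are coerced to the
field's annotated type.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Type, TypeVar

from ..gibbs_surface import GibbsParams
from ..ss_predict import PredictorParams
from ..thermo import ThermoParams

__all__ = [
    "load_config",
    "params_from_config",
    "predictor_params",
    "thermo_params",
    "gibbs_params",
]

T = TypeVar("T")


def load_config(path: str | Path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _coerce(value: str, annotation: Any) -> Any:
    text = str(annotation)
    if "bool" in text:
        return value.lower() in ("1", "true", "yes", "on")
    if "int" in text:
        return int(value)
    if "Tuple[float" in text or "tuple[float" in text:
        return tuple(float(v) for v in value.replace(",", " ").split())
    if "float" in text:
        return float(value)
    return value


def params_from_config(cls: Type[T], cfg: Dict[str, str], prefix: str) -> T:
    """Build a params dataclass from config entries ``prefix.<field>``."""
    kwargs: Dict[str, Any] = {}
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in cfg.items():
        if not key.startswith(prefix + "."):
            continue
        name = key[len(prefix) + 1 :]
        if name not in fields:
            raise ValueError(f"unknown config key {key!r} for {cls.__name__}")
        kwargs[name] = _coerce(value, fields[name].type)
    return cls(**kwargs)


def predictor_params(cfg: Dict[str, str]) -> PredictorParams:
    return params_from_config(PredictorParams, cfg, "predictor")


def thermo_params(cfg: Dict[str, str]) -> ThermoParams:
    return params_from_config(ThermoParams, cfg, "thermo")


def gibbs_params(cfg: Dict[str, str]) -> GibbsParams:
    return params_from_config(GibbsParams, cfg, "gibbs")
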