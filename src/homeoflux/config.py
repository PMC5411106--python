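"""Flat key-value run configuration (YAML, one document per run).

A config names the model variant, overrides rate constants, and describes the
external-concentration grid; subcommand-specific options (target robustness,
rho grid, cycle rates, ...) live in the same flat namespace.  The raw file
text is carried along so every output can echo it bit-exactly in its header.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .models import ParameterSet

__all__ = ["RunConfig", "ConfigError", "load_config", "format_header"]

_PARAM_FIELDS = {f.name for f in fields(ParameterSet)}

_GRID_KEYS = ("S_ext_min", "S_ext_max", "S_ext_points")


class ConfigError(ValueError):
    """Malformed configuration; message carries file/line context."""


@dataclass
class RunConfig:
    """Parsed run configuration plus the raw text for echoing."""

    path: str
    raw_text: str
    data: dict
    model: str | None
    params: ParameterSet

    def grid(self, default=(1e-2, 1e2, 41)) -> np.ndarray:
        """Log-spaced S_ext grid in units of Kext (overridable per key)."""
        lo = float(self.data.get("S_ext_min", default[0]))
        hi = float(self.data.get("S_ext_max", default[1]))
        num = int(self.data.get("S_ext_points", default[2]))
        if not (0 < lo < hi) or num < 2:
            raise ConfigError(
                f"{self.path}: need 0 < S_ext_min < S_ext_max and "
                f"S_ext_points >= 2, got ({lo}, {hi}, {num})")
        return np.geomspace(lo, hi, num) * self.params.Kext

    def get(self, key, default=None):
        return self.data.get(key, default)

    def require(self, key):
        if key not in self.data:
            raise ConfigError(f"{self.path}: missing required key {key!r}")
        return self.data[key]


def load_config(path) -> RunConfig:
    """Parse a flat YAML config; errors carry line references."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" (line {mark.line + 1}, column {mark.column + 1})" if mark else ""
        raise ConfigError(f"{path}: invalid YAML{where}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a flat mapping, "
                          f"got {type(data).__name__}")
    param_kwargs = {}
    for key, value in data.items():
        if key in _PARAM_FIELDS:
            try:
                param_kwargs[key] = None if value is None else float(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(
                    f"{path}: parameter {key!r} must be a number, "
                    f"got {value!r}") from exc
    try:
        params = ParameterSet(**param_kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    model = data.get("model")
    if model is not None and not isinstance(model, str):
        raise ConfigError(f"{path}: 'model' must be a string, got {model!r}")
    return RunConfig(path=str(path), raw_text=text, data=data,
                     model=model, params=params)


def format_header(config: RunConfig, extra: dict | None = None) -> str:
    """Comment block echoing the config verbatim, plus run metadata."""
    from . import __version__

    lines = [f"# homeoflux {__version__}", f"# config: {config.path}"]
    if extra:
        for k, v in extra.items():
            lines.append(f"# {k}: {v}")
    lines.append("# --- begin config echo ---")
    for raw in config.raw_text.splitlines():
        lines.append(f"# {raw}")
    lines.append("# --- end config echo ---")
    return "\n".join(lines) + "\n"
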