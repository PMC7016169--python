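"""Plain-text run configuration.

An INI-style file with sections ``[lowpass]``, ``[loess]``, ``[nlm]``,
``[qc]`` and ``[features]`` overrides the documented defaults of the
corresponding stage dataclasses.  Unknown sections or keys are rejected so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .denoise import LoessSpec, LowpassSpec, NLMConfig
from .features import FeatureConfig
from .qc import QCPolicy


class ConfigError(ValueError):
    """Unknown section/key or unparsable value in a config file."""


@dataclass(frozen=True)
class RunConfig:
    lowpass: LowpassSpec = LowpassSpec()
    loess: LoessSpec = LoessSpec()
    nlm: NLMConfig = NLMConfig()
    qc: QCPolicy = QCPolicy()
    features: FeatureConfig = FeatureConfig()


_SECTIONS = {
    "lowpass": LowpassSpec,
    "loess": LoessSpec,
    "nlm": NLMConfig,
    "qc": QCPolicy,
    "features": FeatureConfig,
}


def _coerce(field: dataclasses.Field, raw: str):
    text = raw.strip()
    typ = field.type
    if text.lower() in ("none", ""):
        return None
    if "int" in str(typ) and "float" not in str(typ):
        return int(text)
    if "float" in str(typ):
        return float(text)
    return text


def load_config(path: str | Path | None) -> RunConfig:
    """Read a config file (or return all defaults when ``path`` is None)."""
    if path is None:
        return RunConfig()
    parser = configparser.ConfigParser()
    read = parser.read(Path(path))
    if not read:
        raise ConfigError(f"config file {path} not found or unreadable")
    kwargs = {}
    for section in parser.sections():
        if section not in _SECTIONS:
            raise ConfigError(
                f"unknown config section [{section}]; valid: {sorted(_SECTIONS)}")
        cls = _SECTIONS[section]
        fields = {f.name: f for f in dataclasses.fields(cls)}
        overrides = {}
        for key, raw in parser.items(section):
            if key not in fields:
                raise ConfigError(
                    f"unknown key {key!r} in [{section}]; valid: {sorted(fields)}")
            try:
                overrides[key] = _coerce(fields[key], raw)
            except ValueError as exc:
                raise ConfigError(f"bad value for {section}.{key}: {exc}") from None
        kwargs[section] = cls(**overrides)
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig) -> str:
    """Render the effective configuration as INI text (for provenance logs)."""
    lines = []
    for section, obj in (("lowpass", cfg.lowpass), ("loess", cfg.loess),
                         ("nlm", cfg.nlm), ("qc", cfg.qc), ("features", cfg.features)):
        lines.append(f"[{section}]")
        for f in dataclasses.fields(obj):
            lines.append(f"{f.name} = {getattr(obj, f.name)}")
        lines.append("")
    return "\n".join(lines)
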