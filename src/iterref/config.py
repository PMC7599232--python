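"""Pipeline configuration: one flat key=value file covering every stage.

Keys are dotted (``mapper.k = 17``); unknown keys are rejected so typos fail
loudly instead of silently running defaults.  Precedence elsewhere is
CLI flags > config file > defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .align import MapperParams
from .call import CallerParams
from .simulate import BreedSimParams, ReadSimParams


@dataclass
class PipelineConfig:
    """Every tunable block of the pipeline plus run-level settings."""

    breed: BreedSimParams = field(default_factory=BreedSimParams)
    reads: ReadSimParams = field(default_factory=ReadSimParams)
    mapper: MapperParams = field(default_factory=MapperParams)
    caller: CallerParams = field(default_factory=CallerParams)
    max_rounds: int = 30
    hom_only: bool = True
    tau: float = 1e-4
    log_base: float = 2.0
    seed: int = 0
    out_dir: str = "iterref_out"
    log_level: str = "INFO"

    _BLOCKS = ("breed", "reads", "mapper", "caller")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for block in self._BLOCKS:
            obj = getattr(self, block)
            for f in fields(obj):
                lines.append(f"{block}.{f.name} = {getattr(obj, f.name)!r}")
        for f in fields(self):
            if f.name in self._BLOCKS:
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        config = cls()
        top = {f.name: f for f in fields(cls) if f.name not in cls._BLOCKS}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            parsed = _parse_literal(value)
            if "." in key:
                block, attr = key.split(".", 1)
                if block not in cls._BLOCKS:
                    raise ValueError(f"{path}:{lineno}: unknown section {block!r}")
                obj = getattr(config, block)
                if attr not in {f.name for f in fields(obj)}:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                setattr(obj, attr, parsed)
            else:
                if key not in top:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                setattr(config, key, parsed)
        for block in cls._BLOCKS:
            getattr(config, block).__post_init__()  # re-validate edited blocks
        return config

    def digest(self) -> str:
        """Short stable hash of the effective configuration, for provenance."""
        lines = []
        for block in self._BLOCKS:
            obj = getattr(self, block)
            lines.extend(f"{block}.{f.name}={getattr(obj, f.name)!r}" for f in fields(obj))
        lines.extend(
            f"{f.name}={getattr(self, f.name)!r}"
            for f in fields(self)
            if f.name not in self._BLOCKS
        )
        return hashlib.sha256("\n".join(lines).encode()).hexdigest()[:12]


def _parse_literal(text: str):
    text = text.strip().strip("'\"")
    if text in ("True", "true"):
        return True
    if text in ("False", "false"):
        return False
    if text.startswith("(") and text.endswith(")"):
        parts = [p for p in text[1:-1].split(",") if p.strip()]
        return tuple(_parse_literal(p) for p in parts)
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text
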