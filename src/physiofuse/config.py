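"""Key/value configuration document support.

One line per setting, ``key = value``; blank lines and ``#`` comments are
ignored.  Every key maps onto a :class:`~physiofuse.model.PipelineConfig`
field and all defaults are the published values.
"""
from __future__ import annotations

from pathlib import Path

from .model import PipelineConfig

__all__ = ["load_config", "save_config"]


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        mapping[key.strip()] = value.strip()
    return PipelineConfig.from_mapping(mapping)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")
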