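"""Flat key-value run configuration files.

Format: one ``key = value`` per line, ``#`` comments, blank lines
ignored, and ``include <path>`` lines that splice in another file
(relative to the including file) before local keys — local keys override
included ones.  Values are parsed as int, float, bool or string.
"""

from __future__ import annotations

from pathlib import Path

__all__ = ["ConfigError", "parse_value", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Malformed configuration file or unusable key."""


def parse_value(raw: str):
    s = raw.strip()
    low = s.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        pass
    return s


def load_config(path) -> dict:
    """Read a flat config file, following ``include`` lines."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    out: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.split("#", 1)[0].strip()
        if not s:
            continue
        if s.startswith("include "):
            inc = s[len("include "):].strip()
            out.update(load_config(path.parent / inc))
            continue
        if "=" not in s:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = s.split("=", 1)
        out[key.strip()] = parse_value(raw)
    return out


def dump_config(cfg: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in sorted(cfg.items())]
    Path(path).write_text("\n".join(lines) + "\n")
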