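"""Flat key=value configuration files.

Every tunable exposed by the pipeline can be set in a single config file;
CLI flags override config values, which override built-in defaults.
"""

from __future__ import annotations

from pathlib import Path


def parse_value(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in {"true", "false"}:
        return low == "true"
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        pass
    if "," in raw:
        return [parse_value(part) for part in raw.split(",")]
    return raw


def load_config(path: str | Path | None) -> dict:
    """Parse ``key = value`` lines; '#' starts a comment; blank lines ignored."""
    if path is None:
        return {}
    cfg: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        cfg[key.strip()] = parse_value(value)
    return cfg
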