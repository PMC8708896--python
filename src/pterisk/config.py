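"""Load and override the packaged default constants.

The defaults ship as a human-editable YAML resource (``defaults.yaml``).
``load_defaults()`` parses it; ``load_defaults(path)`` reads a user file with
the same schema instead.  A user file only needs the keys it overrides —
missing sections fall back to the packaged values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

_REQUIRED_TOP_KEYS = ("exposure", "toxicity", "standards")


def _packaged_text() -> str:
    return resources.files("pterisk").joinpath("defaults.yaml").read_text(encoding="utf-8")


def load_defaults(path: str | Path | None = None) -> dict[str, Any]:
    """Return the constants dict, optionally overlaying a user YAML file.

    The overlay is shallow-merged per top-level section: an ``exposure`` block
    in the user file replaces individual group entries, a ``toxicity`` block
    replaces individual element entries, and ``standards`` (a list) replaces
    the packaged list wholesale when present.
    """
    base = yaml.safe_load(_packaged_text())
    if path is None:
        return base
    user = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    for key, value in user.items():
        if key not in _REQUIRED_TOP_KEYS:
            raise ConfigError(f"unknown config section {key!r}; expected one of {_REQUIRED_TOP_KEYS}")
        if key == "standards":
            base[key] = value
        else:
            for sub, subval in value.items():
                merged = dict(base[key].get(sub, {}))
                merged.update(subval)
                base[key][sub] = merged
    return base
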