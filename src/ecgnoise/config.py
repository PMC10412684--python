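"""Run configuration with validated defaults.

Defaults reflect the study conditions: 200 Hz sampling, 5-s blocks with a 1-s
gap, 50 Hz powerline notch, a 0.5-40 Hz analysis band, and 5-s / 4-s-overlap
tracking windows.  Any stochastic stage requires an explicit seed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "fs": 200.0,            # sampling rate, Hz
    "t_b": 5.0,             # block length, s (admissible 3-6 s)
    "gap": 1.0,             # gap between consecutive blocks, s
    "knot_window": 1.2,     # baseline-knot window, s
    "notch_freq": 50.0,     # powerline frequency, Hz
    "notch_q": 30.0,        # notch quality factor
    "band": [0.5, 40.0],    # bandpass edges, Hz
    "butter_order": 5,      # Butterworth order per section
    "window": 5.0,          # tracking window, s
    "overlap": 4.0,         # tracking window overlap, s
    "seed": None,           # mandatory for stochastic stages
}


class ConfigError(ValueError):
    """An invalid configuration value."""


def _validate(cfg: dict) -> dict:
    if cfg["fs"] <= 0:
        raise ConfigError(f"fs must be positive, got {cfg['fs']}")
    if not (0 < cfg["t_b"]):
        raise ConfigError(f"t_b must be positive, got {cfg['t_b']}")
    if cfg["gap"] < 0:
        raise ConfigError(f"gap must be >= 0, got {cfg['gap']}")
    if cfg["knot_window"] <= 0:
        raise ConfigError(f"knot_window must be positive, got {cfg['knot_window']}")
    low, high = cfg["band"]
    if not (0 < low < high < cfg["fs"] / 2):
        raise ConfigError(f"band {cfg['band']} must satisfy 0 < low < high < fs/2")
    if not (0 < cfg["notch_freq"] < cfg["fs"] / 2):
        raise ConfigError(f"notch_freq {cfg['notch_freq']} outside (0, fs/2)")
    if not (0 <= cfg["overlap"] < cfg["window"]):
        raise ConfigError(
            f"overlap {cfg['overlap']} must be in [0, window={cfg['window']})"
        )
    return cfg


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Load a YAML/JSON config mapping, fill defaults, and validate.

    Unknown keys produce a warning (they are retained); invalid values raise
    :class:`ConfigError`.  An empty or missing file yields the full defaults.
    """
    cfg = dict(DEFAULTS)
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if text.strip():
            loaded = (
                json.loads(text)
                if str(path).endswith(".json")
                else yaml.safe_load(text)
            )
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: config must be a mapping")
            user = loaded
    user.update(overrides)
    unknown = sorted(set(user) - set(DEFAULTS))
    if unknown:
        warnings.warn(f"unknown config keys: {unknown}", stacklevel=2)
    cfg.update(user)
    return _validate(cfg)
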